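"""Signed-network edge arithmetic.

The comparison of condition networks is done on edge sets: each
intercropping (IC) network is *cleaned* by subtracting every edge that
also occurs in the bare-soil or sole-crop interference networks, and
the two cleaned IC networks are then intersected into a common fraction
and two crop-unique fractions.

Edge identity is the unordered OTU pair; by default matching ignores
the edge sign (an interference edge of either sign removes the pair),
with a ``sign_sensitive`` flag to retain pairs whose signs disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .containers import SignedNetwork

__all__ = [
    "edge_difference",
    "edge_intersection",
    "clean_ic_network",
    "split_fractions",
    "ArithmeticRecord",
]


@dataclass
class ArithmeticRecord:
    """Provenance of one arithmetic step: operands, flags, before/after counts."""

    operation: str
    operands: list[str]
    sign_sensitive: bool
    edges_before: int
    edges_after: int
    notes: dict = field(default_factory=dict)


def edge_difference(a: SignedNetwork, b: SignedNetwork,
                    sign_sensitive: bool = False,
                    name: str | None = None) -> SignedNetwork:
    """Edges of ``a`` whose OTU pair is absent from ``b``.

    With ``sign_sensitive=True`` a pair present in both networks with
    *opposite* signs is retained (the co-occurrence relationship
    differs, so it is not treated as interference). Weights come from
    ``a``; the node set is recomputed from the surviving edges.
    """
    out: dict[tuple[str, str], float] = {}
    for pair, w in a.edges.items():
        if pair not in b.edges:
            out[pair] = w
        elif sign_sensitive and (w > 0) != (b.edges[pair] > 0):
            out[pair] = w
    return SignedNetwork(
        name=name if name is not None else f"{a.name}-minus-{b.name}",
        edges=out,
        stability={p: f for p, f in a.stability.items() if p in out},
    )


def edge_intersection(a: SignedNetwork, b: SignedNetwork,
                      sign_sensitive: bool = False,
                      name: str | None = None) -> SignedNetwork:
    """Pairs present in both networks; weight is the mean of the two.

    The sign is taken from ``a``'s weight. Pairs whose signs conflict
    are *excluded* when ``sign_sensitive=True``; otherwise they are kept
    (with ``a``'s weight, since averaging opposite signs is
    meaningless) and reported in the returned network's
    ``sign_conflicts`` attribute.
    """
    out: dict[tuple[str, str], float] = {}
    conflicts: list[tuple[str, str]] = []
    for pair, w in a.edges.items():
        if pair not in b.edges:
            continue
        wb = b.edges[pair]
        if (w > 0) == (wb > 0):
            out[pair] = (w + wb) / 2.0
        else:
            conflicts.append(pair)
            if not sign_sensitive:
                out[pair] = w
    net = SignedNetwork(
        name=name if name is not None else f"{a.name}-and-{b.name}",
        edges=out,
        stability={p: f for p, f in a.stability.items() if p in out},
    )
    net.sign_conflicts = conflicts  # type: ignore[attr-defined]
    return net


def clean_ic_network(ic: SignedNetwork,
                     interference: Iterable[SignedNetwork],
                     sign_sensitive: bool = False) -> SignedNetwork:
    """Remove from an IC network every edge present in any interference network.

    Sequential set difference against each interference network; the
    result is independent of the interference ordering (set semantics).
    """
    interference = list(interference)
    if not interference:
        raise ValueError("at least one interference network is required")
    out = ic
    for other in interference:
        out = edge_difference(out, other, sign_sensitive=sign_sensitive)
    out.name = f"cleaned-{ic.name}"
    return out


def split_fractions(
    cleaned_wheat: SignedNetwork,
    cleaned_pea: SignedNetwork,
    sign_sensitive: bool = False,
) -> tuple[SignedNetwork, SignedNetwork, SignedNetwork]:
    """Split two cleaned IC networks into unique and common fractions.

    Returns ``(unique_wheat, unique_pea, common)`` where *common* is the
    pair intersection and each unique fraction is that network's pairs
    absent from the other. The three edge-pair sets partition the union
    of the inputs' pairs; this is asserted.
    """
    common = edge_intersection(cleaned_wheat, cleaned_pea,
                               sign_sensitive=sign_sensitive, name="common")
    unique_wheat = edge_difference(cleaned_wheat, cleaned_pea,
                                   sign_sensitive=False, name="unique_wheat")
    unique_pea = edge_difference(cleaned_pea, cleaned_wheat,
                                 sign_sensitive=False, name="unique_pea")
    if sign_sensitive:
        # sign-conflicting pairs fall out of `common`; they stay out of the
        # uniques too, so the three sets remain disjoint but may not cover
        # conflicted pairs — report them instead of silently asserting.
        covered = (set(common.edges) | set(unique_wheat.edges)
                   | set(unique_pea.edges))
        leftover = (set(cleaned_wheat.edges) | set(cleaned_pea.edges)) - covered
        common.sign_conflicts = sorted(leftover)  # type: ignore[attr-defined]
    else:
        union = set(cleaned_wheat.edges) | set(cleaned_pea.edges)
        parts = [set(common.edges), set(unique_wheat.edges), set(unique_pea.edges)]
        assert parts[0] | parts[1] | parts[2] == union
        assert not (parts[0] & parts[1]) and not (parts[0] & parts[2]) \
            and not (parts[1] & parts[2])
    return unique_wheat, unique_pea, common
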