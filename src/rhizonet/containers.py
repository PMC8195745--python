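"""Core data containers shared across the pipeline.

Two objects travel through every stage: :class:`CountTable` (an OTU ×
sample integer matrix with per-sample metadata) and
:class:`SignedNetwork` (an undirected graph over OTU identifiers with
signed, weighted edges — partial correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["CountTable", "SignedNetwork", "canonical_pair"]

#: Metadata columns every sample must carry.
REQUIRED_METADATA = ("experiment", "condition")

#: The five study conditions, in canonical order.
CONDITIONS = ("bare_soil", "wheat_SC", "wheat_IC", "pea_SC", "pea_IC")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered OTU pair as a sorted tuple; self-pairs are rejected."""
    if a == b:
        raise ValueError(f"self-loop pair ({a!r}, {b!r}) is not allowed")
    return (a, b) if a < b else (b, a)


@dataclass
class CountTable:
    """OTU × sample non-negative integer count matrix plus sample metadata.

    Parameters
    ----------
    counts
        Integer matrix of shape ``(n_otus, n_samples)``.
    otu_ids, sample_ids
        Row / column identifiers, unique within the table.
    metadata
        DataFrame indexed by sample id. Must contain at least the columns
        ``experiment`` and ``condition``; ``species``, ``cultivar`` and
        ``genotype`` are carried along when present.
    """

    counts: np.ndarray
    otu_ids: list[str]
    sample_ids: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.ndim != 2 or c.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {c.shape} does not match "
                f"{len(self.otu_ids)} OTUs × {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.equal(np.mod(c, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = c = c.astype(np.int64)
        neg = np.argwhere(c < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative count at OTU {self.otu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        missing = set(self.sample_ids) - set(map(str, self.metadata.index))
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in REQUIRED_METADATA:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata is missing required column {col!r}")
        # align metadata to the table's sample order
        self.metadata = self.metadata.loc[[str(s) for s in self.sample_ids]]

    # ------------------------------------------------------------------
    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def experiments(self) -> list[str]:
        return list(pd.unique(self.metadata["experiment"]))

    def conditions(self) -> list[str]:
        return list(pd.unique(self.metadata["condition"]))

    # ------------------------------------------------------------------
    def select_otus(self, keep: Iterable[str]) -> "CountTable":
        keep = set(keep)
        idx = [i for i, o in enumerate(self.otu_ids) if o in keep]
        return CountTable(
            self.counts[idx, :],
            [self.otu_ids[i] for i in idx],
            list(self.sample_ids),
            self.metadata.copy(),
        )

    def select_samples(self, keep: Iterable[str]) -> "CountTable":
        keep = set(keep)
        idx = [j for j, s in enumerate(self.sample_ids) if s in keep]
        sids = [self.sample_ids[j] for j in idx]
        return CountTable(
            self.counts[:, idx], list(self.otu_ids), sids,
            self.metadata.loc[sids].copy(),
        )

    def subset_condition(self, condition: str) -> "CountTable":
        mask = self.metadata["condition"] == condition
        return self.select_samples(self.metadata.index[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def copy(self) -> "CountTable":
        return CountTable(
            self.counts.copy(), list(self.otu_ids), list(self.sample_ids),
            self.metadata.copy(),
        )


@dataclass
class SignedNetwork:
    """Undirected signed weighted graph over OTU identifiers.

    Edges are keyed by the unordered OTU pair; the weight is the partial
    correlation and the sign of an edge is the sign of its weight. Nodes
    are, by convention, exactly the endpoints of the edges — isolated
    nodes are not represented.
    """

    name: str = ""
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    #: optional StARS selection frequency per edge
    stability: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: dict[tuple[str, str], float] = {}
        for (a, b), w in self.edges.items():
            pair = canonical_pair(a, b)
            if pair in canon:
                raise ValueError(f"duplicate edge {pair}")
            if w == 0:
                raise ValueError(f"edge {pair} has zero weight")
            canon[pair] = float(w)
        self.edges = canon
        self.stability = {canonical_pair(*p): float(f) for p, f in self.stability.items()}

    # ------------------------------------------------------------------
    @classmethod
    def from_edge_list(
        cls,
        edge_weights: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]],
        name: str = "",
    ) -> "SignedNetwork":
        if isinstance(edge_weights, Mapping):
            return cls(name=name, edges=dict(edge_weights))
        return cls(name=name, edges={(a, b): w for a, b, w in edge_weights})

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_positive(self) -> int:
        return sum(1 for w in self.edges.values() if w > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for w in self.edges.values() if w < 0)

    def sign(self, pair: tuple[str, str]) -> int:
        return 1 if self.edges[canonical_pair(*pair)] > 0 else -1

    def edge_pairs(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(name=self.name)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w, sign=1 if w > 0 else -1,
                       abs_weight=abs(w))
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return self.edges == other.edges

    def __len__(self) -> int:
        return len(self.edges)
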