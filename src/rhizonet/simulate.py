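"""Synthetic multi-condition, multi-experiment OTU count tables.

The generator mirrors the structure the inference side assumes: per
condition, latent log-abundances follow a multivariate Gaussian whose
sparse precision matrix encodes the planted co-occurrence network;
observed counts are conditionally Poisson around the exponentiated
latent layer, with a log-normal per-sample sequencing-depth offset.

Five conditions share a backbone network; each crop adds sole-cropping
(SC) edges, each intercropping (IC) condition adds crop-specific edges,
and a *common-IC* edge set is present in both IC conditions only — the
target of the downstream edge arithmetic. Two "experiments" draw on
partially overlapping OTU subsets so the cross-experiment pooling rule
has work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CONDITIONS, CountTable, SignedNetwork

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "build_precision",
    "simulate_pln_counts",
    "simulate_study",
    "default_design",
]

Edge = tuple[int, int]


def _canon(i: int, j: int) -> Edge:
    if i == j:
        raise ValueError(f"self-pair ({i}, {j})")
    return (i, j) if i < j else (j, i)


def _canon_edges(edges) -> dict[Edge, int]:
    """Normalize an edge collection to {sorted index pair: sign}.

    Accepts ``{(i, j), ...}`` (sign +1), ``{(i, j): sign}`` or an
    iterable of ``(i, j, sign)`` triples.
    """
    out: dict[Edge, int] = {}
    if isinstance(edges, dict):
        items = [(i, j, s) for (i, j), s in edges.items()]
    else:
        items = []
        for e in edges:
            e = tuple(e)
            items.append(e if len(e) == 3 else (e[0], e[1], 1))
    for i, j, s in items:
        pair = _canon(int(i), int(j))
        if s not in (-1, 1):
            raise ValueError(f"edge sign must be ±1, got {s!r}")
        if pair in out and out[pair] != s:
            raise ValueError(f"conflicting signs for pair {pair}")
        out[pair] = int(s)
    return out


# ----------------------------------------------------------------------
def build_precision(
    n_otus: int,
    edges,
    strength: float,
    *,
    min_eigenvalue: float = 0.05,
    max_inflation: float = 5.0,
) -> tuple[np.ndarray, float]:
    """Sparse precision matrix with planted signed partial correlations.

    Off-diagonal entries are ``-sign * strength`` at planted pairs (so
    the implied partial correlation has the requested sign) and zero
    elsewhere; the diagonal starts at one. If the result is not
    positive definite it is repaired by uniform diagonal inflation
    ``Θ + δI`` with the smallest δ that lifts the minimum eigenvalue to
    ``min_eigenvalue`` — inflation shrinks planted partial-correlation
    magnitudes to ``strength / (1 + δ)`` but preserves their signs and
    the sparsity pattern.

    Returns ``(Theta, delta)`` where ``delta`` is the applied inflation.
    """
    if not 0 < strength < 1:
        raise ValueError(f"strength must be in (0, 1), got {strength}")
    edge_signs = _canon_edges(edges)
    theta = np.eye(n_otus)
    for (i, j), s in edge_signs.items():
        if not (0 <= i < n_otus and 0 <= j < n_otus):
            raise ValueError(f"edge ({i}, {j}) outside 0..{n_otus - 1}")
        theta[i, j] = theta[j, i] = -s * strength
    lam = np.linalg.eigvalsh(theta)[0] if n_otus else 1.0
    delta = max(0.0, min_eigenvalue - lam)
    if delta > max_inflation:
        density = 2 * len(edge_signs) / max(n_otus, 1)
        raise ValueError(
            f"cannot make precision positive definite: strength {strength} "
            f"too large for mean planted degree {density:.2f} "
            f"(required inflation {delta:.2f} exceeds {max_inflation})"
        )
    if delta > 0:
        theta = theta + delta * np.eye(n_otus)
    return theta, delta


def simulate_pln_counts(
    precision: np.ndarray,
    mu: np.ndarray,
    n_samples: int,
    depth_log_mean: float = 0.0,
    depth_log_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
    *,
    otu_ids: list[str] | None = None,
    sample_prefix: str = "s",
    experiment: str = "exp1",
    condition: str = "bare_soil",
    extra_metadata: dict[str, list] | None = None,
) -> tuple[CountTable, np.ndarray]:
    """Draw a Poisson log-normal count table from a known precision.

    For each sample *i*: a log depth offset ``o_i ~ N(depth_log_mean,
    depth_log_sd²)``, a latent vector ``Z_i ~ MVN(mu, Θ⁻¹)``, and counts
    ``Y_ij ~ Poisson(exp(o_i + Z_ij))``.

    Returns the table (OTUs × samples) and the vector of true log
    offsets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    precision = np.asarray(precision, dtype=float)
    p = precision.shape[0]
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (p,))
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lam_min = np.linalg.eigvalsh(precision)[0]
    if lam_min <= 0:
        raise ValueError(
            f"precision is not positive definite (min eigenvalue {lam_min:.3g})"
        )
    sigma = np.linalg.inv(precision)
    offsets = rng.normal(depth_log_mean, depth_log_sd, size=n_samples)
    chol = np.linalg.cholesky(sigma)
    z = mu[None, :] + rng.standard_normal((n_samples, p)) @ chol.T
    lam = np.exp(offsets[:, None] + z)
    counts = rng.poisson(lam).T  # OTUs × samples

    if otu_ids is None:
        otu_ids = [f"OTU_{k:04d}" for k in range(p)]
    sample_ids = [f"{sample_prefix}{i + 1:02d}" for i in range(n_samples)]
    meta = {
        "experiment": [experiment] * n_samples,
        "condition": [condition] * n_samples,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    metadata = pd.DataFrame(meta, index=sample_ids)
    return CountTable(counts, list(otu_ids), sample_ids, metadata), offsets


# ----------------------------------------------------------------------
@dataclass
class StudyDesign:
    """Blueprint for the five-condition, two-experiment synthetic study.

    Edge sets are over integer OTU indices (``0..n_otus-1``) and are
    mappings pair → sign (±1); plain pair sets are accepted and read as
    all-positive. The per-condition precision matrices are composed as

    ==========  ====================================================
    bare_soil   backbone
    wheat_SC    backbone + sc[wheat]
    wheat_IC    backbone + sc[wheat] + ic_specific[wheat] + common_ic
    pea_SC      backbone + sc[pea]
    pea_IC      backbone + sc[pea] + ic_specific[pea] + common_ic
    ==========  ====================================================

    ``n_samples_per_condition`` is per experiment, so the pooled sample
    size per condition is ``n_experiments`` times larger.
    """

    n_otus: int = 200
    n_samples_per_condition: int = 35
    conditions: tuple[str, ...] = CONDITIONS
    backbone_edges: dict[Edge, int] = field(default_factory=dict)
    sc_edges: dict[str, dict[Edge, int]] = field(default_factory=dict)
    ic_specific_edges: dict[str, dict[Edge, int]] = field(default_factory=dict)
    common_ic_edges: dict[Edge, int] = field(default_factory=dict)
    edge_strength: float = 0.35
    mu_log_mean: float = 3.0
    mu_log_sd: float = 0.7
    depth_log_mean: float = 0.0
    depth_log_sd: float = 0.3
    n_experiments: int = 2
    experiment_otu_overlap: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 2 or self.n_samples_per_condition < 1:
            raise ValueError("n_otus >= 2 and n_samples_per_condition >= 1 required")
        if not 0 < self.edge_strength < 1:
            raise ValueError("edge_strength must be in (0, 1)")
        if not 0 < self.experiment_otu_overlap <= 1:
            raise ValueError("experiment_otu_overlap must be in (0, 1]")
        self.backbone_edges = _canon_edges(self.backbone_edges)
        self.common_ic_edges = _canon_edges(self.common_ic_edges)
        self.sc_edges = {k: _canon_edges(v) for k, v in self.sc_edges.items()}
        self.ic_specific_edges = {
            k: _canon_edges(v) for k, v in self.ic_specific_edges.items()
        }
        self.check_disjoint()

    @property
    def species(self) -> tuple[str, ...]:
        return ("wheat", "pea")

    def check_disjoint(self) -> None:
        """Planted sets must not collide; report colliding pairs."""
        groups = [("backbone", set(self.backbone_edges)),
                  ("common_ic", set(self.common_ic_edges))]
        groups += [(f"sc[{s}]", set(v)) for s, v in self.sc_edges.items()]
        groups += [(f"ic_specific[{s}]", set(v))
                   for s, v in self.ic_specific_edges.items()]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                na, ea = groups[a]
                nb, eb = groups[b]
                if na.startswith("sc[") and nb.startswith("sc["):
                    continue  # the two species' SC sets may legitimately share pairs
                clash = ea & eb
                if clash:
                    raise ValueError(
                        f"planted edge sets {na} and {nb} overlap: {sorted(clash)}"
                    )

    # ------------------------------------------------------------------
    def condition_edges(self, condition: str) -> dict[Edge, int]:
        """Signed planted edge set of one condition."""
        edges = dict(self.backbone_edges)
        if condition == "bare_soil":
            return edges
        species, phase = condition.rsplit("_", 1)
        edges.update(self.sc_edges.get(species, {}))
        if phase == "IC":
            edges.update(self.ic_specific_edges.get(species, {}))
            edges.update(self.common_ic_edges)
        return edges

    def otu_ids(self) -> list[str]:
        return [f"OTU_{k:04d}" for k in range(self.n_otus)]


@dataclass
class GroundTruth:
    """Everything the design implies, for recovery scoring.

    ``networks`` holds the TRUE signed edge list per condition (over OTU
    id strings); ``fractions`` the three target edge sets the pipeline's
    edge arithmetic should return; ``precisions`` the per-condition
    precision matrices over the full OTU grid.
    """

    otu_ids: list[str]
    precisions: dict[str, np.ndarray]
    networks: dict[str, SignedNetwork]
    fractions: dict[str, SignedNetwork]
    inflation: dict[str, float]
    experiment_otus: dict[str, list[str]]


def _edges_to_network(edges: dict[Edge, int], otu_ids: list[str],
                      strength: float, name: str) -> SignedNetwork:
    return SignedNetwork(
        name=name,
        edges={(otu_ids[i], otu_ids[j]): s * strength for (i, j), s in edges.items()},
    )


def simulate_study(design: StudyDesign) -> tuple[dict[tuple[str, str], CountTable], GroundTruth]:
    """Simulate the full study: one count table per experiment × condition.

    Each experiment draws on its own OTU subset (a shared core of
    ``experiment_otu_overlap × n_otus`` OTUs plus experiment-private
    OTUs); planted edges live on the shared core so the pooling rule
    never discards them. Latent log-means are drawn once and shared by
    all conditions, so condition differences come only from the planted
    dependence structure.

    Returns ``(tables, truth)`` with ``tables`` keyed by
    ``(experiment, condition)``.
    """
    rng = np.random.default_rng(design.seed)
    otu_ids = design.otu_ids()
    p = design.n_otus

    n_shared = int(round(design.experiment_otu_overlap * p))
    shared = list(range(n_shared))
    private = list(range(n_shared, p))
    max_idx = max((max(e) for e in _all_planted(design)), default=-1)
    if max_idx >= n_shared:
        raise ValueError(
            f"planted edges must lie on the shared OTU core (indices < {n_shared}); "
            f"found index {max_idx}"
        )

    exp_names = [f"exp{k + 1}" for k in range(design.n_experiments)]
    exp_otus: dict[str, list[int]] = {}
    chunks = np.array_split(np.array(private, dtype=int), design.n_experiments)
    for name, chunk in zip(exp_names, chunks):
        exp_otus[name] = shared + [int(x) for x in chunk]

    mu = rng.normal(design.mu_log_mean, design.mu_log_sd, size=p)

    precisions: dict[str, np.ndarray] = {}
    inflation: dict[str, float] = {}
    networks: dict[str, SignedNetwork] = {}
    for cond in design.conditions:
        edges = design.condition_edges(cond)
        theta, delta = build_precision(p, edges, design.edge_strength)
        precisions[cond] = theta
        inflation[cond] = delta
        networks[cond] = _edges_to_network(edges, otu_ids, design.edge_strength, cond)

    fractions = {
        "unique_wheat": _edges_to_network(
            design.ic_specific_edges.get("wheat", {}), otu_ids,
            design.edge_strength, "unique_wheat"),
        "unique_pea": _edges_to_network(
            design.ic_specific_edges.get("pea", {}), otu_ids,
            design.edge_strength, "unique_pea"),
        "common": _edges_to_network(
            design.common_ic_edges, otu_ids, design.edge_strength, "common"),
    }

    tables: dict[tuple[str, str], CountTable] = {}
    child = np.random.SeedSequence(design.seed).spawn(
        design.n_experiments * len(design.conditions))
    k = 0
    for exp in exp_names:
        idx = exp_otus[exp]
        for cond in design.conditions:
            theta_sub = precisions[cond][np.ix_(idx, idx)]
            species = None if cond == "bare_soil" else cond.rsplit("_", 1)[0]
            n = design.n_samples_per_condition
            extra = {
                "species": [species or "none"] * n,
                "genotype": [("Hr" if i % 2 == 0 else "hr") if species == "pea"
                             else "na" for i in range(n)],
            }
            table, _ = simulate_pln_counts(
                theta_sub, mu[idx], n,
                design.depth_log_mean, design.depth_log_sd,
                seed=np.random.default_rng(child[k]),
                otu_ids=[otu_ids[i] for i in idx],
                sample_prefix=f"{exp}_{cond}_",
                experiment=exp, condition=cond,
                extra_metadata=extra,
            )
            tables[(exp, cond)] = table
            k += 1

    truth = GroundTruth(
        otu_ids=otu_ids,
        precisions=precisions,
        networks=networks,
        fractions=fractions,
        inflation=inflation,
        experiment_otus={e: [otu_ids[i] for i in idx] for e, idx in exp_otus.items()},
    )
    return tables, truth


def experiment_tables(
    tables: dict[tuple[str, str], CountTable]
) -> list[CountTable]:
    """Merge per-(experiment, condition) tables into one table per experiment.

    The merged table holds all of an experiment's samples over the union
    of its OTUs (conditions of one experiment share the OTU set by
    construction). This is the shape the pipeline expects as input.
    """
    import pandas as pd

    by_exp: dict[str, list[CountTable]] = {}
    for (exp, _), t in tables.items():
        by_exp.setdefault(exp, []).append(t)
    out = []
    for exp in sorted(by_exp):
        ts = by_exp[exp]
        df = pd.concat([t.to_frame() for t in ts], axis=1).fillna(0).astype(int)
        meta = pd.concat([t.metadata for t in ts], axis=0)
        out.append(CountTable(df.to_numpy(), list(df.index),
                              list(df.columns), meta))
    return out


def _all_planted(design: StudyDesign):
    yield from design.backbone_edges
    yield from design.common_ic_edges
    for v in design.sc_edges.values():
        yield from v
    for v in design.ic_specific_edges.values():
        yield from v


# ----------------------------------------------------------------------
def default_design(
    seed: int = 0,
    *,
    n_otus: int = 200,
    n_samples_per_condition: int = 35,
    edge_strength: float = 0.35,
    n_backbone: int = 40,
    n_sc: int = 15,
    n_ic_specific: int = 15,
    n_common_ic: int = 12,
    negative_fraction: float = 0.15,
    **kwargs,
) -> StudyDesign:
    """The default study design with randomly planted, disjoint edge sets.

    Edge counts are chosen so each condition network stays sparse (≤ 82
    planted edges over 200 OTUs); ``negative_fraction`` of planted edges
    carry a negative partial correlation, echoing the minority of
    negative co-occurrences seen in real rhizosphere networks.
    """
    rng = np.random.default_rng(seed)
    overlap = kwargs.get("experiment_otu_overlap", 0.8)
    n_shared = int(round(overlap * n_otus))
    n_total = n_backbone + 2 * n_sc + 2 * n_ic_specific + n_common_ic

    pairs: set[Edge] = set()
    while len(pairs) < n_total:
        i, j = rng.integers(0, n_shared, size=2)
        if i != j:
            pairs.add(_canon(int(i), int(j)))
    pool = sorted(pairs)
    rng.shuffle(pool)

    def take(n: int) -> dict[Edge, int]:
        out = {}
        for _ in range(n):
            pair = pool.pop()
            sign = -1 if rng.random() < negative_fraction else 1
            out[pair] = sign
        return out

    return StudyDesign(
        n_otus=n_otus,
        n_samples_per_condition=n_samples_per_condition,
        backbone_edges=take(n_backbone),
        sc_edges={"wheat": take(n_sc), "pea": take(n_sc)},
        ic_specific_edges={"wheat": take(n_ic_specific), "pea": take(n_ic_specific)},
        common_ic_edges=take(n_common_ic),
        edge_strength=edge_strength,
        seed=seed,
        **kwargs,
    )
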