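"""Diversity statistics: α-diversity indices, unweighted UniFrac,
PCoA ordination, and strata-aware PERMANOVA.

Shannon uses the natural logarithm; "Simpson" is the Gini–Simpson form
1 − Σp² (switchable to inverse Simpson). UniFrac is delegated to
scikit-bio; PERMANOVA is computed here because permutations must be
restricted to within-stratum shuffles (e.g. within experiments), which
the scikit-bio implementation does not support. Group comparisons of
the indices are thin wrappers over standard rank-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from .containers import CountTable

__all__ = [
    "alpha_diversity",
    "unweighted_unifrac",
    "pcoa",
    "permanova",
    "PcoaResult",
    "PermanovaResult",
    "compare_alpha_groups",
]


def alpha_diversity(table: CountTable, simpson: str = "gini") -> pd.DataFrame:
    """Observed richness, Shannon and Simpson indices per sample.

    richness = number of OTUs with count > 0; shannon = −Σ p ln p over
    positive proportions; simpson = 1 − Σ p² (``simpson="gini"``) or
    1 / Σ p² (``simpson="inverse"``).
    """
    if simpson not in ("gini", "inverse"):
        raise ValueError("simpson must be 'gini' or 'inverse'")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j].astype(float)
        total = col.sum()
        if total <= 0:
            raise ValueError(f"sample {sid!r} has zero total count")
        p = col[col > 0] / total
        shannon = float(-(p * np.log(p)).sum())
        d2 = float((p ** 2).sum())
        rows.append({
            "observed_richness": int((col > 0).sum()),
            "shannon": shannon,
            "simpson": (1.0 - d2) if simpson == "gini" else 1.0 / d2,
        })
    return pd.DataFrame(rows, index=table.sample_ids)


def unweighted_unifrac(table: CountTable, tree) -> DistanceMatrix:
    """Pairwise unweighted UniFrac distances between samples.

    For two samples, the distance is the branch length unique to either
    sample's presence set divided by the total branch length spanned by
    their union (presence = count > 0). Every table OTU must be a tip
    of the (rooted) tree.
    """
    from skbio.diversity import beta_diversity

    if isinstance(tree, TreeNode):
        tr = tree
    else:
        import io, os

        # convert_underscores=False: OTU ids routinely contain underscores
        if isinstance(tree, (str, os.PathLike)) and os.path.exists(tree):
            tr = TreeNode.read(str(tree), convert_underscores=False)
        else:
            tr = TreeNode.read(io.StringIO(str(tree)),
                               convert_underscores=False)
    tips = {t.name for t in tr.tips()}
    missing = sorted(set(table.otu_ids) - tips)
    if missing:
        raise ValueError(f"OTUs missing from the tree: {missing}")
    counts = table.counts.T  # samples × OTUs
    try:
        return beta_diversity("unweighted_unifrac", counts,
                              ids=table.sample_ids, taxa=table.otu_ids, tree=tr)
    except TypeError:  # older scikit-bio keyword
        return beta_diversity("unweighted_unifrac", counts,
                              ids=table.sample_ids, otu_ids=table.otu_ids,
                              tree=tr)


@dataclass
class PcoaResult:
    """Classical metric scaling of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray   # samples × axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray   # all eigenvalues, sorted non-increasing
    proportion_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dist: DistanceMatrix | np.ndarray,
         sample_ids: list[str] | None = None) -> PcoaResult:
    """Principal Coordinate Analysis (classical metric scaling).

    Double-centers −½ D∘D, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues. Negative
    eigenvalues — possible for non-Euclidean distances — are reported
    but contribute no axis. Axes are ordered by decreasing eigenvalue.
    """
    if isinstance(dist, DistanceMatrix):
        d = dist.data
        ids = list(dist.ids)
    else:
        d = np.asarray(dist, dtype=float)
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix has a nonzero diagonal")
        ids = sample_ids or [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = 1e-12 * max(1.0, float(np.abs(eigvals).max())) if n else 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])[None, :]
    total = eigvals[eigvals > 0].sum()
    prop = np.where(eigvals > 0, eigvals, 0.0) / total if total > 0 else np.zeros(n)
    return PcoaResult(ids, coords, eigvals, prop)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    strata: list | None = None

    def __post_init__(self) -> None:
        if not self.p_value >= 1.0 / (self.n_permutations + 1):
            raise ValueError("p-value below the permutation floor")


def _group_ss(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, ss_total: float) -> float:
    n = len(labels)
    a = len(np.unique(labels))
    ss_within = _group_ss(d2, labels)
    ss_among = ss_total - ss_within
    denom = ss_within / (n - a)
    if denom <= 0:
        return np.inf
    return (ss_among / (a - 1)) / denom


def permanova(
    dist: DistanceMatrix | np.ndarray,
    factor,
    n_permutations: int = 999,
    strata=None,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with optional within-strata permutations.

    Pseudo-F partitions the sum of squared distances into among- and
    within-group parts; the p-value is ``(1 + #{F* ≥ F}) / (1 + n_perm)``
    (the observed statistic counts, so p can never be 0). When
    ``strata`` is given, labels are shuffled only within each stratum —
    the exchangeable units are samples within a block (e.g. an
    experiment).
    """
    d = dist.data if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    labels = np.asarray(list(factor))
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("factor length does not match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    strata_arr = None
    if strata is not None:
        strata_arr = np.asarray(list(strata))
        if len(strata_arr) != n:
            raise ValueError("strata length does not match the distance matrix")
        # a stratum holding a single factor level is unpermutable; shuffles
        # there are no-ops, and if every stratum is like that p = 1 by
        # construction — warn rather than fail so the degenerate design is
        # still reported
        dead = [s for s in np.unique(strata_arr)
                if len(np.unique(labels[strata_arr == s])) < 2]
        if dead:
            import warnings

            warnings.warn(
                f"strata {dead} contain a single factor level and are "
                "unpermutable; the test loses power (p = 1 if all strata "
                "are degenerate)", RuntimeWarning, stacklevel=2)

    d2 = d ** 2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    f_obs = _pseudo_f(d2, labels, ss_total)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = labels.copy()
        if strata_arr is None:
            rng.shuffle(perm)
        else:
            for s in np.unique(strata_arr):
                idx = np.flatnonzero(strata_arr == s)
                perm[idx] = perm[idx[rng.permutation(len(idx))]]
        if _pseudo_f(d2, perm, ss_total) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations,
                           strata=None if strata is None else list(strata))


def compare_alpha_groups(alpha: pd.DataFrame, labels) -> pd.DataFrame:
    """Rank-based group comparison of α-diversity indices.

    Two groups → Wilcoxon–Mann–Whitney; more → Kruskal–Wallis. A thin
    delegation to scipy's implementations, one row per index.
    """
    labels = np.asarray(list(labels))
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for col in alpha.columns:
        samples = [alpha[col].to_numpy()[labels == g] for g in groups]
        if len(groups) == 2:
            res = stats.mannwhitneyu(samples[0], samples[1],
                                     alternative="two-sided")
            test = "wilcoxon-mann-whitney"
        else:
            res = stats.kruskal(*samples)
            test = "kruskal-wallis"
        rows.append({"index": col, "test": test,
                     "statistic": float(res.statistic),
                     "p_value": float(res.pvalue)})
    return pd.DataFrame(rows).set_index("index")
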