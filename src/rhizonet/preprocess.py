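"""Table-level filtering: prevalence trimming, cross-experiment pooling,
and rarefaction to even depth.

Networks are fitted on unrarefied counts with per-sample offsets (the
latent-Gaussian model handles depth explicitly); rarefaction is applied
only where diversity indices need a common depth.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountTable

__all__ = ["prevalence_filter", "pool_experiments", "rarefy_even_depth"]

logger = logging.getLogger(__name__)


def prevalence_filter(table: CountTable, min_fraction: float = 0.5) -> CountTable:
    """Keep OTUs present (count > 0) in at least ``min_fraction`` of ALL samples.

    The boundary is inclusive: an OTU present in exactly half the
    samples survives ``min_fraction=0.5``. Prevalence is computed over
    the entire table — all conditions and experiments together — not per
    group. Sample set and OTU order are preserved.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if table.n_samples == 0 or table.n_otus == 0:
        return table.copy()
    prevalence = (table.counts > 0).mean(axis=1)
    keep = [o for o, f in zip(table.otu_ids, prevalence) if f >= min_fraction]
    return table.select_otus(keep)


def pool_experiments(tables: list[CountTable]) -> CountTable:
    """Concatenate per-experiment tables, keeping only OTUs seen in every one.

    An OTU "occurs" in an experiment if it has a positive count in at
    least one of that experiment's samples; the pooled OTU set is the
    strict intersection across experiments (OTUs private to a subset of
    experiments are eliminated). Sample identifiers must be globally
    unique.
    """
    if len(tables) < 2:
        raise ValueError("pooling requires at least two experiment tables")
    labels = [tuple(sorted(set(t.metadata["experiment"]))) for t in tables]
    if len(set(labels)) != len(labels):
        raise ValueError(f"experiment labels are not distinct across tables: {labels}")

    all_samples: list[str] = []
    for t in tables:
        all_samples.extend(t.sample_ids)
    dupes = {s for s in all_samples if all_samples.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate sample identifiers across tables: {sorted(dupes)}")

    occurring = [
        {o for o, row in zip(t.otu_ids, t.counts) if row.sum() > 0} for t in tables
    ]
    shared = set.intersection(*occurring)
    # keep first table's OTU ordering for determinism
    otu_order = [o for o in tables[0].otu_ids if o in shared]

    frames = [t.to_frame().reindex(otu_order, fill_value=0) for t in tables]
    counts = pd.concat(frames, axis=1)
    metadata = pd.concat([t.metadata for t in tables], axis=0)
    return CountTable(
        counts.to_numpy(), otu_order, list(counts.columns), metadata
    )


def rarefy_even_depth(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Each sample's counts are drawn from a multivariate hypergeometric
    distribution (reads drawn without replacement), the convention of
    the standard even-depth rarefaction. Samples whose total is below
    ``depth`` are dropped with a warning; OTUs left with all-zero counts
    are removed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    keep_cols: list[int] = []
    new_cols: list[np.ndarray] = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        total = int(col.sum())
        if total < depth:
            logger.warning(
                "dropping sample %s: total %d below rarefaction depth %d",
                sid, total, depth,
            )
            continue
        if total == depth:
            new_cols.append(col.copy())
        else:
            new_cols.append(rng.multivariate_hypergeometric(col, depth))
        keep_cols.append(j)
    if not keep_cols:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    counts = np.column_stack(new_cols)
    sample_ids = [table.sample_ids[j] for j in keep_cols]
    keep_rows = counts.sum(axis=1) > 0
    out = CountTable(
        counts[keep_rows],
        [o for o, k in zip(table.otu_ids, keep_rows) if k],
        sample_ids,
        table.metadata.loc[sample_ids].copy(),
    )
    return out
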