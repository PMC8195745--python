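"""Recovery scoring against simulated ground truth."""

from __future__ import annotations

from typing import Iterable

from .containers import SignedNetwork
from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .simulate import GroundTruth, default_design, experiment_tables, simulate_study

__all__ = ["edge_f1", "recovery_experiment"]


def edge_f1(estimated: SignedNetwork | Iterable[tuple[str, str]],
            truth: SignedNetwork | Iterable[tuple[str, str]]) -> float:
    """F1 score between two edge-pair sets (sign-insensitive)."""
    got = set(estimated.edge_pairs() if isinstance(estimated, SignedNetwork)
              else estimated)
    true = set(truth.edge_pairs() if isinstance(truth, SignedNetwork)
               else truth)
    if not got and not true:
        return 1.0
    if not got or not true:
        return 0.0
    tp = len(got & true)
    precision = tp / len(got)
    recall = tp / len(true)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def recovery_experiment(
    seed: int,
    config: PipelineConfig | None = None,
    **design_kwargs,
) -> tuple[dict, PipelineResult, GroundTruth]:
    """Simulate the default study, run the pipeline, score against truth.

    Returns ``(scores, result, truth)`` where scores holds the F1 of the
    common-IC fraction, of each unique fraction, and the mean
    per-condition network F1.
    """
    design = default_design(seed=seed, **design_kwargs)
    tables, truth = simulate_study(design)
    config = config or PipelineConfig(seed=seed, n_penalties=10,
                                      run_diversity=False)
    result = run_pipeline(experiment_tables(tables), config)
    per_condition = {
        cond: edge_f1(result.condition_networks[cond], truth.networks[cond])
        for cond in result.condition_networks
    }
    scores = {
        "common_f1": edge_f1(result.fractions["common"],
                             truth.fractions["common"]),
        "unique_wheat_f1": edge_f1(result.fractions["unique_wheat"],
                                   truth.fractions["unique_wheat"]),
        "unique_pea_f1": edge_f1(result.fractions["unique_pea"],
                                 truth.fractions["unique_pea"]),
        "per_condition_f1": per_condition,
        "mean_condition_f1": sum(per_condition.values()) / len(per_condition),
    }
    return scores, result, truth
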