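"""End-to-end orchestration: pool → trim → five PLN networks → StARS →
edge arithmetic → fractions → metrics (+ diversity side-channel).

The stage order mirrors the analysis the package implements: samples of
the two experiments are pooled per condition to enlarge the dataset,
OTUs are trimmed by prevalence over the entire pooled table, one sparse
PLN network is inferred per condition with StARS-selected penalty, the
two intercropping networks are cleaned of bare-soil and sole-crop
interference edges, and the cleaned networks are intersected into
unique and common fractions. Networks use unrarefied counts with log
total-count offsets; diversity indices use rarefied counts.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .containers import CONDITIONS, CountTable, SignedNetwork
from .preprocess import pool_experiments, prevalence_filter, rarefy_even_depth
from .pln import default_offsets, fit_pln, partial_correlation, penalty_grid, threshold_network
from .stars import StarsConfig, stars_select
from .algebra import ArithmeticRecord, clean_ic_network, split_fractions
from .metrics import metrics_report
from . import io as rio

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the study defaults.

    ``min_abs_r`` (0.06) is the per-condition partial-correlation
    threshold applied before edge arithmetic; ``min_abs_r_common``
    (0.03) is re-applied to the common fraction after intersection.
    ``min_frequency`` is the StARS selection frequency an edge must
    reach to count as significant.
    """

    prevalence_min_fraction: float = 0.5
    rarefaction_depth: int | None = None  # None: minimum sample total
    n_penalties: int = 30
    penalty_min_ratio: float = 0.01
    n_subsamples: int = 30
    instability_threshold: float = 0.05
    min_abs_r: float = 0.06
    min_abs_r_common: float = 0.03
    min_frequency: float = 0.9
    keystone_k: float = 3.0
    sign_sensitive: bool = False
    permanova_permutations: int = 999
    run_diversity: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.min_abs_r < 1 or not 0 <= self.min_abs_r_common < 1:
            raise ValueError("|r| thresholds must be in [0, 1)")
        if not 0 < self.min_frequency <= 1:
            raise ValueError("min_frequency must be in (0, 1]")


@dataclass
class PipelineResult:
    pooled: CountTable
    filtered: CountTable
    condition_networks: dict[str, SignedNetwork]
    cleaned: dict[str, SignedNetwork]
    fractions: dict[str, SignedNetwork]
    selected_penalties: dict[str, float]
    pseudo_r2: dict[str, float]
    metrics: dict[str, dict]
    diversity: dict
    manifest: dict


def _stage(manifest: dict, name: str):
    manifest["stages"].append(name)
    logger.info("[stage] %s", name)


def run_pipeline(
    tables: list[CountTable],
    config: PipelineConfig | None = None,
    *,
    taxonomy: dict[str, str] | None = None,
    tree=None,
) -> PipelineResult:
    """Run the full pipeline on per-experiment count tables.

    ``tables`` is one CountTable per experiment, each containing samples
    of all five conditions. Deterministic given (inputs, config.seed).
    Writes networks, metrics, diversity tables and a manifest to
    ``config.output_dir`` when set.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    manifest: dict = {
        "package_version": _pkg_version,
        "config": asdict(config),
        "seed": config.seed,
        "stages": [],
        "counts": {},
    }
    seeds = np.random.SeedSequence(config.seed).spawn(8)

    def seed_int(i: int) -> int:
        return int(seeds[i].generate_state(1)[0] % (2 ** 31))

    try:
        stage = "pool"
        _stage(manifest, stage)
        pooled = pool_experiments(tables) if len(tables) > 1 else tables[0].copy()
        manifest["counts"]["pooled_otus"] = pooled.n_otus
        manifest["counts"]["pooled_samples"] = pooled.n_samples

        stage = "prevalence_filter"
        _stage(manifest, stage)
        filtered = prevalence_filter(pooled, config.prevalence_min_fraction)
        manifest["counts"]["filtered_otus"] = filtered.n_otus

        stage = "check_conditions"
        present = set(filtered.conditions())
        missing = [c for c in CONDITIONS if c not in present]
        if missing:
            raise ValueError(f"missing conditions in metadata: {missing}")

        stage = "diversity"
        diversity_out: dict = {}
        if config.run_diversity:
            _stage(manifest, stage)
            diversity_out = _diversity_block(filtered, config, tree,
                                             seed_int(0), seed_int(1))

        stage = "infer_networks"
        _stage(manifest, stage)
        condition_networks: dict[str, SignedNetwork] = {}
        selected_penalties: dict[str, float] = {}
        pseudo_r2: dict[str, float] = {}
        for i, cond in enumerate(CONDITIONS):
            sub = filtered.subset_condition(cond)
            net, pen, r2 = infer_condition_network(
                sub, config, name=cond, seed=seed_int(2) + i)
            condition_networks[cond] = net
            selected_penalties[cond] = pen
            pseudo_r2[cond] = r2
            manifest["counts"][f"network_{cond}_edges"] = net.n_edges
            logger.info("[network] %s: %d nodes, %d edges, penalty %.4g, R2 %.3f",
                        cond, net.n_nodes, net.n_edges, pen, r2)

        stage = "edge_arithmetic"
        _stage(manifest, stage)
        interference = [condition_networks["bare_soil"],
                        condition_networks["wheat_SC"],
                        condition_networks["pea_SC"]]
        cleaned = {
            "wheat_IC": clean_ic_network(condition_networks["wheat_IC"],
                                         interference, config.sign_sensitive),
            "pea_IC": clean_ic_network(condition_networks["pea_IC"],
                                       interference, config.sign_sensitive),
        }
        unique_wheat, unique_pea, common = split_fractions(
            cleaned["wheat_IC"], cleaned["pea_IC"], config.sign_sensitive)
        if config.min_abs_r_common > 0:
            kept = {p: w for p, w in common.edges.items()
                    if abs(w) > config.min_abs_r_common}
            common = SignedNetwork(
                name="common", edges=kept,
                stability={p: f for p, f in common.stability.items() if p in kept},
            )
        fractions = {"unique_wheat": unique_wheat, "unique_pea": unique_pea,
                     "common": common}
        # provenance sidecar: which operands each arithmetic step consumed
        manifest["edge_arithmetic"] = [
            ArithmeticRecord(
                operation="clean_ic_network", operands=[key] + [n.name for n in interference],
                sign_sensitive=config.sign_sensitive,
                edges_before=condition_networks[key].n_edges,
                edges_after=cleaned[key].n_edges).__dict__
            for key in ("wheat_IC", "pea_IC")
        ] + [
            ArithmeticRecord(
                operation="split_fractions",
                operands=["cleaned_wheat_IC", "cleaned_pea_IC"],
                sign_sensitive=config.sign_sensitive,
                edges_before=cleaned["wheat_IC"].n_edges + cleaned["pea_IC"].n_edges,
                edges_after=sum(n.n_edges for n in fractions.values()),
                notes={"common_min_abs_r": config.min_abs_r_common}).__dict__
        ]
        for key, net in {**cleaned, **fractions}.items():
            manifest["counts"][f"{'cleaned_' if key in cleaned else ''}{key}_edges"] = net.n_edges

        stage = "metrics"
        _stage(manifest, stage)
        metrics: dict[str, dict] = {}
        for key, net in {**condition_networks,
                         **{f"cleaned_{k}": v for k, v in cleaned.items()},
                         **fractions}.items():
            if net.n_edges == 0:
                metrics[key] = {"name": key, "n_nodes": 0, "n_edges": 0}
                continue
            rep = metrics_report(net, taxonomy=taxonomy,
                                 keystone_k=config.keystone_k,
                                 seed=seed_int(3))
            metrics[key] = rep.to_dict()

        manifest["selected_penalties"] = selected_penalties
        manifest["pseudo_r2"] = pseudo_r2
        manifest["runtime_seconds"] = round(time.time() - t0, 2)

        result = PipelineResult(
            pooled=pooled, filtered=filtered,
            condition_networks=condition_networks, cleaned=cleaned,
            fractions=fractions, selected_penalties=selected_penalties,
            pseudo_r2=pseudo_r2, metrics=metrics,
            diversity=diversity_out, manifest=manifest,
        )
        if config.output_dir:
            _write_outputs(result, config)
        return result
    except PipelineError:
        raise
    except Exception as exc:
        manifest["failed_stage"] = stage
        if config.output_dir:
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            rio.write_json(manifest, out / "manifest.partial.json")
        raise PipelineError(stage, str(exc)) from exc


def infer_condition_network(
    sub: CountTable,
    config: PipelineConfig,
    name: str,
    seed: int,
) -> tuple[SignedNetwork, float, float]:
    """Infer one condition's signed network: PLN fit, StARS, threshold."""
    offsets = default_offsets(sub)
    init = fit_pln(sub, offsets=offsets, penalty=1e6, on_nonconvergence="warn")
    penalties = penalty_grid(init.latent_covariance, config.n_penalties,
                             config.penalty_min_ratio)
    stars_cfg = StarsConfig(n_subsamples=config.n_subsamples,
                            instability_threshold=config.instability_threshold,
                            seed=seed)
    result, fit = stars_select(sub, offsets=offsets, penalties=penalties,
                               config=stars_cfg, full_fit=init)
    parcor = partial_correlation(fit.precision)
    net = threshold_network(parcor, min_abs_r=config.min_abs_r,
                            stability=result.frequencies,
                            min_frequency=config.min_frequency, name=name)
    return net, result.selected_penalty, fit.criteria.pseudo_r2


def _diversity_block(filtered: CountTable, config: PipelineConfig, tree,
                     rarefy_seed: int, permanova_seed: int) -> dict:
    from . import diversity as dv

    depth = config.rarefaction_depth or int(filtered.sample_totals.min())
    rarefied = rarefy_even_depth(filtered, depth, seed=rarefy_seed)
    alpha = dv.alpha_diversity(rarefied)
    out: dict = {"rarefaction_depth": depth, "alpha": alpha}
    if tree is not None:
        dm = dv.unweighted_unifrac(rarefied, tree)
        out["unifrac"] = dm
        out["pcoa"] = dv.pcoa(dm)
        meta = rarefied.metadata
        strata = (list(meta["experiment"])
                  if meta["experiment"].nunique() > 1 else None)
        try:
            out["permanova_condition"] = dv.permanova(
                dm, meta["condition"], config.permanova_permutations,
                strata=strata, seed=permanova_seed)
        except ValueError as exc:
            out["permanova_condition_error"] = str(exc)
    return out


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    nets = {**result.condition_networks,
            **{f"cleaned_{k}": v for k, v in result.cleaned.items()},
            **result.fractions}
    for key, net in nets.items():
        rio.write_network_tsv(net, out / f"network_{key}.tsv")
        if net.n_edges:
            rio.write_network_graphml(net, out / f"network_{key}.graphml")
    rio.write_json(result.metrics, out / "metrics.json")
    if result.diversity:
        result.diversity["alpha"].rename_axis("sample_id") \
            .to_csv(out / "alpha_diversity.tsv", sep="\t")
        if "unifrac" in result.diversity:
            rio.write_distance_matrix(result.diversity["unifrac"],
                                      out / "unifrac.tsv")
    rio.write_json(result.manifest, out / "manifest.json")
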