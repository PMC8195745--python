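"""End-to-end recovery experiment at reduced scale.

Simulates a smaller variant of the study, runs the complete pipeline
(pool -> filter -> five PLN/StARS networks -> clean -> intersect ->
metrics) and scores every recovered fraction against the planted truth.

The full-size defaults (200 OTUs, 35 samples/condition/experiment) are
what scripts/acceptance.py measures; this narrative version trades an
OTU-set reduction for a ~30 s runtime.
"""

import rhizonet as rz
from rhizonet.evaluate import recovery_experiment

config = rz.PipelineConfig(seed=1, n_penalties=10, run_diversity=False)
scores, result, truth = recovery_experiment(
    seed=1, config=config,
    n_otus=80, n_backbone=16, n_sc=6, n_ic_specific=6, n_common_ic=5)

print("selected penalties and network sizes:")
for cond, net in result.condition_networks.items():
    print(f"  {cond:9s}: penalty {result.selected_penalties[cond]:.3f}, "
          f"{net.n_edges:3d} edges (true {truth.networks[cond].n_edges}), "
          f"pseudo-R2 {result.pseudo_r2[cond]:.2f}")
print("\nrecovery F1 against planted truth:")
for key in ("common_f1", "unique_wheat_f1", "unique_pea_f1",
            "mean_condition_f1"):
    print(f"  {key:18s}: {scores[key]:.3f}")
# F1 below 1 reflects the hard detection limit at this sample size:
# a partial correlation of 0.35 sits only ~3 null standard errors from
# zero, so stability selection keeps just the most reproducible edges.
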