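"""Simulate the five-condition, two-experiment study with known truth.

Builds the default design (200 OTUs, 35 samples per condition per
experiment, planted partial correlations of 0.35), draws Poisson
log-normal count tables, and prints what was planted where.
"""

import rhizonet as rz

design = rz.default_design(seed=42)
tables, truth = rz.simulate_study(design)

print(f"design: {design.n_otus} OTUs, "
      f"{design.n_samples_per_condition} samples/condition/experiment, "
      f"edge strength {design.edge_strength}")
for cond in rz.CONDITIONS:
    net = truth.networks[cond]
    print(f"  true {cond:9s}: {net.n_edges:3d} planted edges "
          f"({net.n_positive}+ / {net.n_negative}-)")
for name, net in truth.fractions.items():
    print(f"  target fraction {name:12s}: {net.n_edges} edges")

table = tables[("exp1", "wheat_IC")]
print(f"\none table: {table.n_otus} OTUs x {table.n_samples} samples, "
      f"median depth {int(sorted(table.sample_totals)[table.n_samples // 2])} reads")
# The planted fractions are what the pipeline's edge arithmetic should
# recover; counts are overdispersed Poisson draws around a latent
# Gaussian whose sparse precision matrix encodes the planted edges.
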