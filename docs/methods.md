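# Methods

## Model

Counts are modelled per condition by a Poisson log-normal (PLN)
graphical model. For sample *i* with known log offset `o_i` and OTU
*j*:

    Z_i ~ N(mu, Sigma),        Y_ij | Z_i ~ Poisson(exp(o_i + Z_ij))

The latent precision matrix `Theta = Sigma^{-1}` carries the
conditional-dependence structure; an edge between OTUs *j* and *k* is a
nonzero partial correlation `r_jk = -Theta_jk / sqrt(Theta_jj
Theta_kk)`. Offsets default to the log of per-sample total counts, so
sequencing depth is handled in the model and **networks are fitted on
unrarefied counts**; rarefaction is used only for diversity indices.

Assumptions worth keeping in mind: a single Gaussian layer per
condition (no covariate adjustment — experiments are pooled, and the
experiment label is carried in the metadata but not regressed out),
independence of samples within a condition, and edges defined by
conditional (not marginal) association.

## Fitting

The likelihood is intractable; we maximize an evidence lower bound
(ELBO) with a mean-field Gaussian variational family per observation
(mean `m_ij`, variance `s²_ij`), alternating:

- **E-step** — joint L-BFGS on all `(m, log s²)` with analytic
  gradients;
- **M-step** — closed-form `mu = mean(m_i)` and latent covariance
  `S = cov(m) + diag(mean s²)`, followed by a graphical-lasso step on
  the **correlation** matrix of `S` (scikit-learn's solver, warm
  started along paths). Penalizing on the correlation scale makes one
  penalty value mean the same partial-correlation cutoff for every OTU
  pair regardless of marginal latent variance; the precision is
  rescaled back to the covariance scale afterwards.

Convergence: relative penalized-ELBO change < 1e-4, at most 200 outer
iterations (30 for warm-started path fits); the penalized ELBO trace is
monotone non-decreasing up to numerical tolerance and is checked in
tests. Positive-definiteness is maintained by the glasso itself (or a
ridge-escalated Cholesky inverse at penalty 0).

Model criteria: `BIC = ELBO - k/2 log n` with `k = 2p + |support|`, and
a nested pseudo-R²,

    R² = (ELBO - ll_null) / (ll_saturated - ll_null)

with the null being the intercept+offset Poisson model and the
saturated model one rate per observation, clipped to [0, 1]. With a
single OTU and total-count offsets the null *is* saturated and the
criteria computation refuses (degenerate by construction).

## Penalty selection (StARS)

The penalty grid has 30 (default) log-spaced values from the
empty-support penalty (the largest off-diagonal latent correlation)
down to 1/100 of it. StARS draws 30 random sample subsets of size
`min(floor(10 sqrt(n)), ceil(0.8 n))` — the 0.8·n cap is the convention
of the reference implementations; the alternative n−1 cap degenerates
at this study's n ≈ 70, where near-complete subsamples make every edge
look perfectly stable. Each subsample's latent correlation matrix
(variational means restricted to the subsample, plus the diagonal
variational-variance correction) is refitted with the same penalized
inverse-covariance step; the whole variational layer is estimated once
on the full data, which changes the cost of stability selection by
~30x and not its target (the support of Theta).

Per penalty, each candidate edge gets a selection frequency `f` and
instability `2f(1-f)`; the total instability is the mean over all
p(p-1)/2 pairs. Scanning sparse → dense, the instability is monotonized
by a running maximum and the **densest penalty with monotonized
instability ≤ 0.05** is selected. The scan stops at the first threshold
crossing — exact, because a running maximum cannot decrease — which
prunes the expensive dense end of the path. Subsample support fits use
a loosened glasso tolerance (5e-3, ≤ 30 iterations); on study-scale
data the resulting supports are identical to the tight setting.

Edges of the selected model must pass `|r| > 0.06` (per-condition
networks, applied before edge arithmetic) and StARS frequency ≥ 0.9;
the common fraction is re-thresholded at `|r| > 0.03` after
intersection. All three are `PipelineConfig` fields.

## Edge arithmetic

Edge identity is the unordered OTU pair, **sign-insensitive by
default** (an interference edge of either sign removes the pair); a
`sign_sensitive` flag retains sign-conflicting pairs in differences and
excludes them from intersections. Cleaning subtracts bare-soil and both
sole-crop networks from each IC network sequentially (order-invariant,
set semantics). Intersections average the two weights; unique fractions
inherit the IC weights. Node sets are always recomputed as edge
endpoints — reported node counts therefore refer to connected OTUs, not
to all analyzed OTUs. Difference and intersection of any pair of
networks partition the first operand's edges; `split_fractions` asserts
the three-way partition.

## Network metrics

Shortest-path statistics (node and edge betweenness, unnormalized pair
counts with even splitting across ties) run on the **unweighted**
topology: partial-correlation magnitudes are association strengths, not
distances. Keystones are nodes with degree > mean + k·SD (k = 3
default) — a documented operationalization of "outstanding degree";
module detection is greedy modularity maximization on absolute weights
with deterministic module labelling. Between-network comparisons
delegate to two-sided Wilcoxon–Mann–Whitney on the metric
distributions.

## Diversity

Shannon uses the natural log; "Simpson" is Gini–Simpson `1 - sum p²`
(switchable to inverse Simpson). Unweighted UniFrac and PCoA reference
implementations: UniFrac is delegated to scikit-bio (the tree must be
rooted and cover all OTUs; underscores in ids are preserved), PCoA is
classical metric scaling with negative eigenvalues reported and
excluded from coordinates. PERMANOVA is computed in-package because
permutations must be restrictable to strata (e.g. experiments);
p-values use the `(1 + hits) / (1 + n_perm)` convention and can never
be zero. A stratum containing a single factor level is unpermutable:
it triggers a warning, and if all strata are degenerate the test
returns p = 1 by construction. Two-way questions are answered as
one-way tests with the second factor as strata; interaction terms are
not modelled and the output says so. Rank-based group comparisons of
diversity indices are thin wrappers over scipy.

## Synthetic data

The generator emulates the study layout: five conditions sharing a
backbone edge set, per-crop sole-cropping edges, per-crop IC-specific
edges, and a common-IC set present in both IC conditions only; two
experiments draw partially overlapping OTU subsets (80% shared core by
default) and planted edges live on the shared core, since pooling
provably removes everything else. Precision matrices have unit
diagonal, off-diagonal `-sign * strength` at planted pairs, and are
repaired to positive definiteness by the smallest uniform diagonal
inflation `delta * I` reaching a minimum eigenvalue of 0.05 — this
preserves signs and sparsity and shrinks planted partial correlations
to `strength / (1 + delta)`; with the default low-degree random edge
sets, delta is 0 or negligible, so realized partial correlations equal
the design strength. Counts are drawn per condition and experiment with
log-normal depth offsets (sd 0.3) and latent log-means N(3, 0.7²),
giving realistic per-sample depths of a few thousand reads and
overdispersed marginals (variance > mean, checked in tests).

Defaults: 200 OTUs, 35 samples per condition **per experiment** (70
pooled), edge strength 0.35, 40 backbone / 15 SC / 15 IC-specific per
crop / 12 common-IC edges, 15% negative edges — sparse, module-poor
graphs. What the generator does *not* emulate: compositionality
(fixed-total constraints), taxonomy-correlated abundance structure,
chimeras/OTU-picking artifacts, or condition-dependent mean shifts
(latent means are shared across conditions so that co-occurrence, not
composition, is the only condition signal). Passing tests therefore
demonstrate correct inference under the model's own assumptions, not
robustness to real-data violations of them.

## Detection limits at the default study size

At n = 70 pooled samples per condition and p = 160 pooled OTUs
(12 720 candidate pairs), a planted partial correlation of 0.35 on
near-isolated pairs yields a latent marginal correlation of ≈ 0.35,
about three null standard errors (Fisher z, sd ≈ 0.122) from zero,
while the null's multiplicity-adjusted tail reaches |r| ≈ 0.28–0.45.
Support recovery is therefore intrinsically partial: measured
latent-layer estimates sit at this theoretical noise floor, and the
StARS-selected networks (instability threshold 0.05 is deliberately
conservative) recover the most reproducible edges at high precision
but bounded recall. The common-IC fraction compounds two recalls and
so lands well below 1 (the acceptance script reports the measured F1,
≈ 0.16 at the prescribed settings; an oracle-chosen penalty caps near
0.65–0.7). Recovery becomes near-complete when strength or sample
size grows — the reduced-scale example with |r| = 0.45 and n = 120
calls only planted edges.

## Problem sizes used in tests

The unit suite runs on 6–40 OTU fixtures; the acceptance layer uses
the full default design (5 seeds of the complete pipeline, 10-penalty
grid), 20 random designs for the algebra exactness check, 100 random
graphs (≤ 12 nodes) for the betweenness oracle, and 500 simulated null
datasets (199 permutations each) for the PERMANOVA size check. The
whole suite completes in a few minutes on one CPU.
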