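# Methods

This note documents the models, numerical conventions, and design choices
behind `neonet`, and what the synthetic cohorts do and do not establish
about real data.

## Network construction

A subject's raw matrix holds streamline counts between 90 parcels. The
pipeline divides every entry by the mean over **all** n(n−1)/2 node pairs,
zeros included (so the scaled matrix has mean off-diagonal weight exactly
1); reading "all pairs" as connected-pairs-only is available via
`fractional_scale(..., include_zeros=False)` but is not the default. The
weakest 5% of the *nonzero* edges are then set to zero, with the quota
⌊0.05·E⌋ and ties at the cutoff broken in ascending (weight, i, j) order
so the operation is deterministic. Scaling commutes with pruning in the
sense that the same edges are weakest in either order; the configuration
records scale→prune. Binarization at sparsity s keeps the ⌊s·n(n−1)/2⌋
strongest pairs (descending weight, deterministic tie order) and is used
only for the robustness analysis at s = 0.10…0.25.

Short- and long-range subnetworks split edges at a fiber-length threshold.
No biologically canonical value exists for neonates, so the threshold is a
parameter (the pipeline defaults to the cohort median edge length).
Hemispheric subnetworks are produced by masking the whole-brain matrix to
each hemisphere's 45 nodes, not by re-deriving connectivity.

## Graph metrics

Link lengths are inverse weights, f(w) = 1/w — the standard convention
when only "inversely related" is specified. The characteristic path
length is the mean of all-pairs shortest path lengths (Dijkstra on the
inverse-weight graph) over off-diagonal pairs; infinite entries of a
disconnected graph are excluded with a warning. Weighted clustering is
Onnela's measure: weights scaled by the network maximum, per-node mean
geometric triangle intensity, C_i = 0 for degree < 2, and the network mean
taken over all nodes (including degree-0/1 nodes as zeros, keeping n
constant across subjects). Because of the max-weight scaling, C^w is
invariant to a global rescaling of the matrix, and all L^w_ij scale as 1/c
when weights are multiplied by c.

Null models preserve the degree sequence by double-edge swaps (quota 10×
the edge count) and then reassign the original weight multiset uniformly
at random to the surviving edges. Degrees and the weight multiset are
preserved exactly; the strength sequence is not — a known limitation of
this null class. Small-worldness S^w and the binary γ, λ are ratios
against means over n_null rewired graphs (default 100; tests and the
acceptance script use 5–30 for speed, which changes only the Monte-Carlo
error of the denominator).

## Modules and hubs

Modularity uses the full-matrix convention: l^w sums every entry of the
symmetric matrix, i.e. each undirected edge counts twice. Under this
convention two disconnected unit-weight triangles partitioned into their
cliques score Q = 0.5. Louvain (resolution γ = 1) provides the
optimization; a consensus partition repeats it 150 times, forms the
co-assignment probability matrix D, zeroes entries below τ = 0.5, and
re-clusters D until all repetitions agree (cap 20 rounds, modal partition
with a warning otherwise). Consensus re-runs on D also use γ = 1.

Within-module degree z uses the **population** standard deviation of the
within-module strength distribution (σ = 0 ⇒ z = 0, avoiding infinities);
the participation coefficient uses strengths, not binary degrees, since
the networks are weighted. Hubs follow the two literal conjunctions —
provincial: z ≥ 1 ∧ P < 0.3; connector: z < 1 ∧ P ≥ 0.3 — which leaves
high-z/high-P nodes in neither class; the thresholds are parameters.
Group prevalence maps flag nodes held as a hub class by strictly more
than 20% of a group's subjects, computed from per-subject partitions.

## Statistics

The longitudinal contrast (PB-AB vs PB-TEA) is a classical paired t-test;
the cross-sectional contrast (PB-TEA vs TB) is OLS of the metric on an
intercept, a group indicator, and the covariates age at scan, head
circumference, and number of gestation embryos (head motion joins as an
extra covariate on request; sex is excluded by default because the groups
are sex-matched). The group coefficient's t-test is equivalent to the
two-group ANCOVA F. Covariate columns that are constant in a given cohort
(e.g. no twins) are dropped. All tests are two-sided. FDR correction is
Benjamini–Hochberg at q = 0.05, applied within one family per metric type
per contrast (the 90 nodal p-values together; the global topology metrics
together — density is reported descriptively, not tested). Partial
correlations are Pearson correlations of covariate residuals with
p-values on n − 2 − n_cov degrees of freedom.

## Classification

Nodal clustering, z and P are concatenated (block order fixed) into a
1×270 vector per subject. Within every cross-validation fold the training
rows are standardized, reduced by PCA to the fewest components explaining
≥90% of variance (typically ~30), and classified by a linear SVM with
C = 1 and no class weighting; the held-out rows are transformed with the
training-fold statistics only. LOO is deterministic; 5-fold and 3-fold
are stratified and repeated 10 times from a seed sequence. The chance
band is the 5th–95th percentile of accuracies from re-running the entire
fold-safe procedure under label permutations (class counts preserved);
the observed accuracy is significant when it exceeds the 95th percentile.
AUC pools signed decision values across folds.

## Synthetic cohort generator

The generator emulates the study design — 28 preterm infants scanned at
birth and again at term-equivalent age plus 28 matched term controls —
with a sparse planted-partition model chosen to reproduce the *joint*
qualitative behaviour of the real metrics:

- A connection exists with probability p_in = 0.85 within a module and
  p_out = 0.20 between modules, and carries a truncated-Gaussian weight
  (means w_in = 10, w_out = 3, SD 1; weights are counts-like, so noise is
  truncated at zero). Sparseness matters: in dense weighted graphs extra
  weak edges *raise* Onnela clustering (the cube root inflates weak
  triangles), and only at realistic densities (~0.25–0.35, matching real
  neonatal connectomes) do clustering and modularity fall together as
  between-module connections are added.
- Planted modules: sizes [28, 12, 25, 25] for 90 nodes, with the 12-node
  limbic/subcortical community (bilateral INS, ACG, DCG, HIP, AMYG, THA)
  more weakly self-connected (w = 5) than the cortical modules, as
  subcortical streamline counts are in real data.
- **PB-AB effect**: between-module presence ×0.4 — preterm-at-birth
  networks lack long between-module connections, so their clustering,
  modularity and path structure are more segregated and density is lower.
- **TB effect (nodal)**: the limbic community's internal weights ×0.70,
  the removed weight spread over the other modules' internal connections,
  plus four small multipliers (w_out ×1.0091, p_in ×1.0005,
  p_out ×0.9769, noise ×1.0057) solved once, numerically, so that the TB
  group's mean clustering, path length, modularity, density and null-node
  participation coincide with PB-TEA's to within 0.2 between-subject SD.
  The planted PB-TEA vs TB contrast is therefore purely nodal: higher
  clustering and lower participation at the affected nodes in PB-TEA. An
  exactly zero global footprint is impossible — any nodal weight change
  propagates through fractional scaling and the modularity bookkeeping —
  so "no global effect" is implemented as "below detectability at the
  study's sample size".
- **Subject random effect** (σ = 0.15): a per-infant multiplier on
  between-module presence, shared by an infant's two scans, giving
  realistic between-subject variance in the global metrics (~5–10%
  relative SD) and longitudinal pairing; an overall lognormal scale
  factor emulates per-subject streamline yield and is removed by
  fractional scaling.
- **FA surrogate**: mean_fa = 0.35 − 0.50·(subject mean clustering) +
  N(0, 0.015), clipped into (0, 1) — whole-brain FA rises with maturation
  while clustering falls, yielding the negative partial correlation.
- Covariates are drawn independently of the network effects by default
  (PMA 29–37 wk at preterm birth, 38–45 wk at term-equivalent age;
  head circumference, twin status, sex, motion from plausible neonatal
  ranges); a `confound` toggle couples scan age to both group and network
  scale so that covariate adjustment and its omission are testable.
- Reproducibility: one global seed spawns a per-subject seed sequence, so
  identical specs give bitwise-identical cohorts and individual subjects
  are stable under partial regeneration.

What the generator does **not** emulate: tractography error structure,
distance-dependent connection probability (edge lengths are independent
of weights), integer streamline counts, motion artifacts (motion is a
scalar covariate only), hemispheric asymmetries (none are planted), or
the real data's direction for the longitudinal change in path length —
under this model the sparser birth networks have slightly *shorter*
weighted paths after fractional scaling, so FA–path-length associations
are not planted either. Passing tests therefore demonstrate that the
pipeline recovers planted segregation, nodal and FA-coupling effects at
the study's sample size, not that it reproduces any particular empirical
value from imaging data.

## Problem sizes and tolerances

Oracle tests run on 50 random graphs with n ≤ 12 (|Δ| < 1e−10 for paths
and clustering) and brute-force modularity on n ≤ 10 (|Δ| < 1e−12);
Louvain optimality is checked against exhaustive set-partition search on
20 planted graphs with n ≤ 7. Statistical calibration uses 500 replicate
null cohorts at reduced size (20 nodes, 6 pairs + 6 controls) with exact
binomial 99% acceptance intervals around the nominal 5% level. Effect
recovery runs 20 full-size cohorts (90 nodes, 28 + 28) with one seeded
Louvain partition per subject; the 150-repetition consensus is the
pipeline default but is statistically equivalent here and ~50× slower.
Permutation calibration uses 60 replicate null datasets with
100-permutation tests; the headline permutation band in the acceptance
script uses 200 shuffles. Matrix I/O uses 17-significant-digit text so
write/read round trips are exact.

## Known limitations

- The rewired null preserves degrees and the weight multiset but not
  strengths; strength-preserving nulls would change γ, λ and S^w somewhat.
- The consensus procedure assumes the agreement matrix is itself well
  clustered; for graphs with genuinely ambiguous structure it returns the
  modal partition with a warning rather than iterating forever.
- ANCOVA assumes homogeneous covariate slopes across groups; no
  interaction terms are fitted.
- Efficiency-style metrics (harmonic-mean inverse path length) are not
  computed; the characteristic path length L^w is the integration measure
  throughout.
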