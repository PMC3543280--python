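# Methods

This note documents the models, statistics and design choices behind
`adiponet`, in the order the pipeline runs them.

## Per-cohort preparation

**Detection filtering.** Microarray platforms flag probes "expressed above
background"; when no such calls are supplied, a detection mask is derived
by thresholding each sample at its 10th expression percentile (a value
counts as detected if it exceeds that quantile). A probe is kept when it is
detected in at least `ceil(min_fraction × n_samples)` samples
(`min_fraction` default 0.5). The rule is idempotent and preserves feature
order.

**Probe collapsing.** Platforms carry several probes per gene; to merge
cohorts measured on different platforms, each gene is represented by its
probe with the largest sample variance, ties broken by the
lexicographically smallest probe id. The max-variance rule presumes the
most variable probe carries the most biological signal — true when probe
noise is comparable across probes and sensitivity varies, which is how the
synthetic generator models probes (below).

**Covariate residualization.** Each feature is replaced by the residuals
of an ordinary-least-squares fit on the chosen covariates (with
intercept). Twin/family structure is removed as a fixed effect by centering
residuals within each `pair_id` group (`pair_center`), which removes all
shared-pair variance exactly and needs no variance-component estimation.
Rank-deficient designs are rejected with the names of the collinear
covariates.

**Trait adjustment.** Serum TG is log-transformed (natural log — the base
only rescales, it does not change correlations) and adjusted for
significant covariates by bidirectional stepwise OLS: forward steps add the
candidate with the smallest partial p if p ≤ α, backward steps drop the
worst retained covariate if p > α, iterating to a fixed point (α default
0.05). Entry uses p ≤ α (not <) so that α = 1 selects every candidate
exactly. Note the calibration this implies: with k pure-noise candidates,
the probability that at least one enters spuriously is ≈ 1 − (1−α)^k
(~10% for k = 2 at α = 0.05); the test suite asserts rates consistent with
that, not an idealized 100% exact selection.

**Dichotomization.** Case/control labels use the clinical cutoff
TG > 1.5 mmol/L, *strictly* — a sample at exactly 1.5 is a control.

**FPKM.** For RNA-seq counts, value = count / (gene length in kb × mapped
reads in millions). Downstream log-transformation uses log(FPKM + 1) to
keep zero counts finite.

## Network construction

The network is **unsigned** with Pearson correlation and soft-threshold
power β (default 6, the conventional unsigned choice): adjacency
`a_ij = |cor(x_i, x_j)|^β`, `a_ii = 0`. β can instead be chosen by the
scale-free criterion: for each candidate, connectivity `k_i = Σ_j a_ij` is
binned on log10(k) into 10 equal-width bins, log10 frequency is regressed
on log10 mean connectivity, and the smallest β with signed fit
R² = −sign(slope)·R² ≥ 0.8 wins; if none qualifies (e.g. pure noise has no
scale-free structure) the declared fallback 6 is used with a warning.

The clustering distance is one minus the **topological overlap**

    ω_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

which credits genes for sharing neighbors and is far more stable than raw
correlation at these sample sizes.

**Module detection.** Average-linkage hierarchical clustering of the TOM
dissimilarity, followed by a *static* cut at a quantile of the merge
heights (default 0.90). Branches smaller than `min_module_size` (default
30) are assigned to grey, the reserved label for unclustered background
genes. The cut quantile was chosen by measuring recovery on planted
two-module data (60/40 members, loading 0.8, 20 samples, 200 noise genes):
at 0.90 exactly two modules are recovered in 20/20 seeds with mean
adjusted-Rand 0.97 over planted genes, while pure-noise matrices go
entirely grey; higher cuts (≥0.99) merge distinct modules into one giant
cluster and promote the noise background into a spurious module. This is a
deliberately simple, deterministic stand-in for dynamic tree cutting; the
variant is recorded in the run log so results are not misattributed to the
hybrid algorithm.

Modules whose eigengenes are nearly collinear (dissimilarity
1 − cor(ME_a, ME_b) below `merge_cut_height`, default 0.25) are merged
iteratively — among eligible pairs, the largest combined pair first, ties
by smallest dissimilarity — then everything is relabeled by size with the
canonical color sequence (turquoise, blue, brown, …) and eigengenes/kME are
recomputed.

**Eigengenes.** A module's eigengene is the first principal component of
its standardized member expression (SVD score scaled to unit variance),
sign-oriented so the mean correlation with members is positive (exact ties
orient to the first member). `var_explained` is the leading squared
singular value over the total. kME is computed for *all* features against
all module eigengenes, so non-members can be screened for near-membership.

**Module–trait correlation.** Pearson r between each eigengene (grey
included — it can harbor trait-associated genes that failed to cluster) and
each trait, with two-sided p from the exact t transform (n−2 df). The
Bonferroni threshold is 0.05 / (n_modules × n_traits), with grey counted as
a module. Per module, the percentage of member genes whose expression
correlates with the trait at p < 0.05 is reported alongside.

## Module preservation

For each non-grey reference module, seven statistics are computed on the
gene set in the test cohort — four *density* statistics (mean intra-module
|cor|, mean adjacency |cor|^β, eigengene variance explained, mean |kME| of
members) and three *connectivity* statistics (correlation between reference
and test of: intramodular connectivity vectors, |kME| vectors, and the
vectorized intra-module correlation matrices). Each observed statistic is
compared with its permutation null over `n_permutations` (default 200, 50
in tests) uniform random gene sets of identical size drawn from the genes
shared by both cohorts; the same random set is used on the reference side
of the connectivity statistics, so the null mirrors the observed
construction. Component Z = (obs − null mean)/null sd; Zdensity and
Zconnectivity are medians of their components; Zsummary is the median of
the two. Zero-null-sd components become +∞ sentinels and are excluded from
medians with a warning. Decision rule: Zsummary > 10 strong preservation,
2–10 moderate, < 2 none.

Two practical caveats, both visible in the test suite: the uniform null is
contaminated by module members when a module is a large fraction of the
shared background, deflating Z — the decision thresholds assume modules are
small relative to the network; and the connectivity statistics are only
informative when member loadings *vary* (a module whose members all have
identical coupling has no hub ordering to preserve).

## Cross-cohort comparison

**Harmonization.** Cohorts are collapsed to gene symbols and intersected;
the sorted shared-symbol list is the default background N for all overlap
tests (N is never hard-coded; printed headline p-values from other
backgrounds are not reproducible without the same N).

**Module overlap.** The 2×2 contingency (in A / not-A × in B / not-B over
the background) is tested with Fisher's exact test, two-sided by default.
The overlap percentage is defined relative to set B (the second, usually
smaller module) — e.g. modules of 320 and 123 genes sharing 115 overlap at
115/123 = 93.5%.

**Empirical hub overlap.** Whether the same genes are hubs (top-kME
members) of the TG module in several cohorts is tested against a fully
specified Monte-Carlo null: per trial, each dataset independently draws a
uniform random member subset of the criterion-implied size (`kme_above(t)`:
as many as exceed t; `top_rank(k)`: k; `top_fraction(q)`: ⌈q·module
size⌉), and the statistic is the number of candidate genes in *all* draws.
p = (1 + #{stat ≥ observed}) / (trials + 1), never zero; trials default
10⁶ (≥10⁴ enforced). Hub rank is computed within module members, and
draws are without replacement — so candidate inclusions are weakly
negatively dependent within a dataset, and the Bin(candidates, Πq_d)
approximation is only exact in the sparse-candidate limit (candidates ≪
module). The tests verify the MC estimator against the exact
hypergeometric-chain tail in the dependent regime and against the binomial
tail in the sparse limit.

**Other comparisons.** kME cross-correlation over shared TG-module genes
(Pearson; under a shared-loading model with independent estimation noise σ
the expected r attenuates to var(λ)/(var(λ)+σ²)); Welch-t differential
expression between TG cases and controls ranked by p (ties: |t|, then
symbol) with top-N Fisher overlap; upper-tail hypergeometric
over-representation of a query list against GMT gene sets intersected with
the expressed background, Bonferroni over sets with nonzero intersection;
and Pearson association of additive SNP dosages (0/1/2 or imputed) with an
eigengene or a single gene's expression.

## Synthetic studies

The generator emulates the three-cohort design the pipeline targets:
cohort sizes default to 53 (twins), 70 and 20; ~2000 genes with planted
modules (default 150/100/60); per-module latent factors f ~ N(0, 1) across
samples; member genes x = λf + √(1−λ²)ε with loadings λ ~ U(0.5, 0.9)
drawn once and shared across cohorts where the module is flagged
preserved. Where not preserved, the module's loadings are re-assigned to a
random background gene set in that cohort and the original members become
pure noise — membership is destroyed while marginal structure is kept.
Background genes are pure noise. Inter-module factor correlation defaults
to 0 (an equicorrelation parameter is available, since real adipose
modules are correlated through shared physiology).

Serum TG is log-normal: log TG = log(1.2) + b·f_tg + σ·e with b = 0.6 and
σ = 0.3, putting the median at ≈1.2 mmol/L with roughly a third of samples
above the 1.5 mmol/L case cutoff — the order of magnitude seen in adult
European-origin cohorts. BMI is mildly coupled to the TG factor; twins
share age, sex and a pair noise component giving intra-pair expression
correlation ≈ 0.5. Microarray-like cohorts expand each gene into 1–3
probes (probabilities 0.6/0.3/0.1) as probe = a·gene + 0.3·ε with
sensitivity a ~ U(0.5, 1.5), so the most variable probe is also the most
signal-rich — the property the max-variance collapse rule needs. One
cohort (default the third) is emitted at gene level, RNA-seq style.

All randomness flows through one `numpy.random.default_rng` (PCG64) stream
per study, so a seed fully reproduces a study bit-for-bit across platforms.

What the generator does *not* model: microarray intensity physics,
count-level sequencing noise (expression is emitted directly on the
continuous scale), correlated linkage structure in genotypes (dosages are
independent Hardy–Weinberg draws), batch effects, and non-linear
covariate–expression relationships. Passing tests therefore demonstrate
correctness of the statistical machinery under a faithful factor-model
idealization, not robustness to every artifact of real platforms.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled study sizes chosen once as
representative: preservation checks run 2-cohort studies with 600 genes
(modules 60/50, samples 53/70) at 50 permutations over 20 seeds; TG-module
recovery runs 1200 genes (modules 150/100/60, n = 70) over 20 seeds; the
hub-overlap calibration uses 10⁵ trials. Medians across seeds are reported
for preservation Z.

Degenerate inputs are rejected loudly rather than patched: zero-variance
features (named), constant traits or genotypes, rank-deficient designs
(collinear covariates named), empty gene-set intersections, observations
exceeding the attainable hub-overlap maximum. Correlations are clipped to
[−1, 1] before the t transform; expression TSVs are written with `repr`
precision and parsed with numpy's correctly-rounded reader, so round-trips
are bit-exact. Eigengene sign ties (mean member correlation exactly zero)
orient by the first member, making partitions deterministic.

## Known limitations

- Static quantile tree cutting is simpler than the dynamic hybrid
  algorithm; very unevenly sized or nested modules may be split or
  absorbed differently than WGCNA's `blockwiseModules` would.
- The preservation statistic set is a documented 4+3 subset of the full
  composite; output is labeled as Zsummary over that subset. The 2/10
  decision thresholds were calibrated in the literature on a richer set,
  so borderline calls (Z near 2 or 10) deserve caution.
- The uniform permutation null for preservation and the member-uniform hub
  null are not degree-matched; both are documented interpretations of
  their respective procedures.
- Fisher-overlap p-values depend strongly on the background N; only the
  overlap counts and percentages are comparable across choices of
  background.
- No blockwise decomposition: networks above ~20k features would need
  O(p²) memory for the TOM and are out of scope.
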