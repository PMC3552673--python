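# Methods

This note documents the models, defaults and numerical choices behind the
`cdtox` pipeline, and what its synthetic studies do and do not establish
about real array data.

## Study design and analysis universe

The pipeline targets a two-block, single-replicate dose design: a 1-day
Cd²⁺ exposure at 0/9/27/45 μM and a 13-day exposure at 0/4.5/9/27 μM, one
array per condition (8 samples total). Inputs are MAS5-style summaries:
a probes × samples signal matrix, per-cell detection calls (P/A/M), a sample
sheet, a probe annotation and GMT gene sets. The analysis universe is the
set of probes called Present in at least one sample; Marginal is treated as
not-Present, since the filtering criterion names presence only.

## Per-gene dose regression

Within one block, each probe's expression is regressed on concentration by
OLS; significance is the two-sided t test on the slope with n − 2 = 2
residual df. The default scale is the raw signal (no transform is assumed
of the source data); `log2` is a flag and is the scale used throughout the
simulated analyses, where noise is lognormal by construction. Selection
uses strict inequality (P < cutoff) with 0.05 as the analysis cutoff and
0.01 for reporting, matching the convention of reporting both tiers.

Degenerate fits at n = 4 are handled, not rejected: a zero-variance
response reports slope 0, direction `flat`, P = 1; a numerically perfect
fit (residual SS ≤ 1e-12 × response SS) reports P = 0 with a
`perfect_fit` flag and an infinite t. BH q values (statsmodels step-up)
are always attached; with 2 df they rarely clear 0.05, which is the
expected behavior of this design, not an error.

## Hypergeometric enrichment and overlap

Both set-level tests use the same statistic: with universe M, marked genes
K (the significant list), draw n (a pathway, or the second list) and
observed intersection r, the P value is the strictly-greater upper tail
P(X > r) = Σ_{k=r+1}^{min(K,n)} C(K,k) C(M−K,n−k) / C(M,n). It is computed
from log-gamma binomials with a log-sum-exp reduction, exact to ~1e-12
against brute-force enumeration and stable for M ≈ 30,000 with tails below
1e-300 in individual terms. Enrichment runs at gene level by default
(probes collapsed to their minimum-P representative; `max_abs_t` is the
alternative rule), skips sets with no member in the universe, and appends
BH q values across sets; the overlap test reports the expected overlap
K·n/M alongside.

## Pooled clustering

The pooled 8-sample matrix is shifted by one global constant to grand mean
0 (per-gene centering is deliberately not the default — the filter
"SD > threshold" then acts on absolute expression variability). Per-gene SD
uses ddof = 1 and the filter is strict. Samples are clustered on Pearson
dissimilarity d = 1 − r with Ward linkage in the squared-dissimilarity
(Ward.D2) dialect — what `scipy.cluster.hierarchy.linkage(method="ward")`
computes on a condensed distance matrix; the historical unsquared Ward.D
variant is available behind a flag via an explicit Lance–Williams
recurrence (which doubles as the test oracle). Genes are clustered the same
way solely to order heat-map columns. Trees are exported as Newick (merge
heights as node heights) and merge tables; `cut_tree` produces exactly k
groups with labels stable in leaf order.

The default SD threshold is 1.0 on the raw MAS5-like scale, as appropriate
for real signal exports. For the simulated studies, which are analyzed on
the log2 scale, the threshold used in the analysis scripts and studies is
0.5 — just above the generator's noise floor (noise SD 0.3) — so that the
retained "high-variability" set is signal-bearing rather than empty or
noise-dominated.

## Mutual-information network modules

Relations among the high-variability genes are scored by plug-in mutual
information in bits on a B × B joint histogram of equal-frequency bin
labels (B = 3 for n = 8 samples; sizes differ by at most one, ties broken
by value order then input order, and a constant gene collapses to one
occupied bin). MI is computed for all pairs with one-hot matrix products
(exact, and fast for the few hundred genes retained); the diagonal holds
the marginal entropies. The distance is 1 − MI/√(H_i H_j) by default
(bounded, entropy-comparable; zero-entropy genes are pushed to distance 1
and flagged), with a max-shift rescaling as the alternative.

Modules are found by average-linkage clustering of that distance — Ward is
reserved for sample clustering because MI distances are not Euclidean-like
— scoring every cluster of size ≥ 4 appearing in tree cuts k = 2…31 by
separation = mean intra-pair MI − mean MI to non-members. Because
candidates from different cuts are nested, the reported modules are a
greedy non-overlapping selection in separation order; only positive
separations are reported. Raw plug-in MI at n = 8 carries a large upward
bias (~0.4–0.5 bits at B = 3), but the bias is common to all pairs, so
module significance is judged against a permutation null — independently
shuffling each gene's profile, re-detecting, and taking the 95th percentile
of the best separation — rather than against absolute MI. A Miller–Madow
correction is available behind a flag and defaults off.

## The synthetic-data generator

Per gene g and sample s, on the log2 scale:

    log2 signal = baseline_g + slope_g(block) · dose_s
                  + strength · loading_g · driver(s)    [module members]
                  + N(0, noise_sd)

with baseline ~ N(6, 1.5) (log2 units), dose-responder slopes
±slope_scale·U(0.5, 1.5) per μM, noise SD 0.3, and signal = 2^log2 (hence
strictly positive). Defaults emulate the profiled design: 2,000 genes, 2%
induced and 2% repressed per block, half of the per-sign responder count
shared between blocks with consistent sign, one module of 8 genes at
driver strength 1.5. Detection calls are Present except for genes in the
lowest baseline quartile, which draw Absent with probability 0.3 per
sample; a 5% fraction of probes shares another probe's symbol to exercise
probe→gene collapsing. Everything is drawn from one seeded generator; the
same config + seed reproduces the study byte for byte.

**The module driver.** Each module shares one latent profile: a monotone
dose trend (linear by default; saturating and random-monotone shapes are
available) standardized to unit SD, mixed with a module-specific shared
per-sample component (`driver_jitter_sd`, default 1.0 — half trend, half
module fingerprint) and re-standardized, so `driver_strength` is the
module's effect size in log2 units exactly as `slope_scale` sizes the
responders. The module-specific component is essential, not cosmetic:
equal-frequency binning is rank-based, and any purely monotone function of
dose has the same rank profile across the 8 samples — a monotone-only
driver is therefore label-identical to a strong dose responder and cannot
be distinguished as a module by an MI estimator at all. The draw is also
repeated (deterministically, up to 200 times) until the profile's tertile
boundaries are separated by ≥ 0.4 SD (`driver_min_gap`), so that planted
module membership is a well-posed ground truth relative to the noise level
rather than a property of one lucky noise realization.

**What the generator does not emulate:** probe-level (PM/MM) array data or
the MAS5 algorithm itself, spatial artifacts, batch effects, heteroscedastic
(intensity-dependent) noise, or correlated null genes. Consequently,
passing recovery tests demonstrates that the pipeline's statistics behave
as designed under their own assumptions — calibrated type-I error, power
that grows with effect size, recoverable planted structure — not that any
particular biological module in real data would be recovered.

## Validation studies and their conditions

The simulation studies shipped in the tests and analysis scripts use these
conditions (sizes chosen to keep the full suite in the low minutes):

- **Null calibration**: all effect fractions 0, 20 seeds × 2,000 genes;
  the fraction of P < 0.05 genes must sit within 3 binomial SDs of 5% in
  ≥ 18/20 seeds, and no 20-bin histogram cell may deviate by > 4 Poisson
  SDs in a typical seed. Uniformity additionally checked by KS test across
  25 seeds at n = 400.
- **Module recovery**: one 8-gene module at driver strength 3.0 ("high";
  2× the generator default) against an otherwise independent background,
  20 seeds; the top module must reach Jaccard ≥ 0.8 with the planted set
  in ≥ 80% of seeds. Against a background containing strong dose
  responders this criterion is unattainable in principle: the responders
  form a label-identical family under rank binning that is itself the
  best-separated cluster, at any driver strength.
- **Null network**: nothing planted, 20 seeds; the best observed
  separation must stay at or below the permutation 95th percentile in
  ≥ 90% of seeds (a 5%-level test of the calibration itself).
- **Sample clustering**: slope_scale 0.08 ("strong" effects — chosen
  analytically, see below), 20 seeds; the k = 2 Ward cut must isolate a
  cluster containing the 45 μM sample made up only of ≥ 27 μM samples
  (at least two of them) away from every ≤ 9 μM sample in ≥ 90% of seeds.
  The dose-grouping regime is a genuine property of the model's correlation
  geometry: cross-sample Pearson correlation combines a shared-baseline
  anchor (σ_b² ≈ 2.25) with within-block responder coupling that grows as
  slope²·d·d′, so very strong effects glue mid-dose samples to their
  block while very weak effects dissolve all structure; moderate effects
  (~0.08 log2/μM) are where high-dose samples detach as a group, which is
  also the qualitative pattern reported for the real data.

## Known limitations

- With 2 residual df the per-gene test is calibrated but weak; sensitivity
  at P < 0.01 for slope_scale 0.05 is ~10–30%. Set-level statistics are
  where this design has power.
- MI from 8 samples at B = 3 distinguishes only coarse rank patterns; any
  two strictly monotone dose responses are indistinguishable, and module
  boundaries blur once per-gene noise flips bin labels. The separation
  score prefers tight cores, so recovered modules may shed their
  weakest-loading member (Jaccard 7/8 rather than 1.0).
- The overlap/enrichment tails are exact under the hypergeometric null of
  uniformly random draws from a fixed universe; gene–gene correlation
  (which real co-expression guarantees) makes them anti-conservative, as
  for any over-representation test.
- Ward on Pearson dissimilarity treats d = 1 − r as if squared-Euclidean
  compatible; this is conventional but heuristic. The result for the
  simulated studies is robust to switching to average or complete linkage,
  mirroring the robustness reported for the original analysis.
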