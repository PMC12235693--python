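# Methods

This note documents the statistical models, the synthetic-study generator,
the numerical choices, and the design decisions behind gliomaprot, along
with their limitations.

## Reporter-ion quantification

Input is a long-format PSM table (protein group, plex, channel, raw
reporter intensity), assumed already filtered for identification FDR by the
upstream search engine. Processing:

1. **Aggregation.** Intensities are summed within protein group per
   (plex, channel). A channel with no PSM for a protein is *missing*, not
   zero; duplicate records are summed, not deduplicated (the table carries
   no PSM identity, so deduplication would be guesswork). Results are
   invariant to record order.
2. **Quantile normalization, per plex.** All 16 channels of a plex —
   including the reference; at this stage it is an ordinary channel — are
   mapped to a common target profile, the across-channel mean of the sorted
   columns. Ties receive the mean of the target quantiles they span (the
   common convention). Channels with missing cells are mapped by rank
   interpolation on the unit interval.
3. **Reference bridging.** For each protein, g = geometric mean of its
   reference intensities over the plexes where the reference is present and
   positive; each plex is multiplied by g/reference, so the protein's
   reference intensity equals g in every contributing plex. A zero or
   missing reference makes the protein missing in that whole plex (no
   exception): without a bridge the plex's values are not comparable.
   Within-plex sample ratios are untouched by this step. If only one plex
   contributes, the factor is that plex's own value ratio, i.e. 1.
4. **Complete cases + log2.** Reference columns are dropped, proteins with
   any missing or non-positive value are removed (raw zeros are treated as
   missing; no pseudocount), and the rest is log2-transformed.

## Protein-wise linear models with variance moderation

For each protein g, log2 abundance is modelled as

    y_g = X β_g + ε_g,   ε_g ~ N(0, σ_g² I)

with design columns: intercept; indicators for IDH HGG, GB PN, GB CL,
GB MES (diffuse LGG is the reference level); age (years), sex, prior
chemotherapy, prior radiotherapy, prior steroids, epilepsy (binary); and
the log2 abundances of PTPRC/CD45, HG2A, and SEPT3 as tumor-purity
covariates — 14 columns for the full cohort. The marker proteins
themselves are removed from the tested set. Rank deficiency is diagnosed
with the offending column named.

Residual variances are moderated empirically: s_g² is modelled as
s₀²·F(d, d₀); (d₀, s₀²) are estimated by method of moments on
log s² using digamma/trigamma identities, with the trigamma inverse solved
by Newton iteration. The posterior variance is (d₀s₀² + d·s²)/(d₀ + d) and
moderated t statistics carry d + d₀ degrees of freedom. When the spread of
log s² does not exceed what sampling noise alone explains, d₀ = ∞ and every
posterior variance equals the pooled mean of the s² (exact when all s²
tie). Contrast tests select the subgroup coefficient (positive log2FC =
higher in the HGG subgroup); subgroup-vs-pooled-others contrasts are also
provided. p-values are BH-adjusted *within* each contrast; DEP means
adjusted p < 0.05.

**Numerical zero tolerance.** Coefficients below 1e-9 (relative to the
per-protein data scale) and residual variances below its square are snapped
to exact zero. On exactly noise-free data both the effect and its standard
error are rounding artefacts, and 0/0 must read "no evidence" (t = 0,
p = 1), while a true planted effect over zero residual variance reads
p = 0. Real data are never affected (1e-9 relative is far below any
biological signal).

## Tumor-purity adjustment

Gliomas are infiltrated by non-neoplastic cells, and the infiltration
fraction differs systematically between subgroups, so protein differences
can reflect purity rather than tumor biology. The marker covariates absorb
this: the three markers proxy the non-neoplastic fraction, and any protein
whose abundance tracks them is suspect.

The association screen is a **joint moderated F-test** on the block of
marker coefficients, thresholded on **raw** p (default 0.05). Two
deliberate choices:

- *Joint, not per-marker.* The markers are strongly correlated proxies of
  the same purity variable; per-coefficient t-tests split the association
  evidence across collinear columns and lose most of it (in our
  contamination studies a per-marker rule missed nearly every contaminated
  protein). The F-test pools the evidence. A per-marker "any significant"
  rule remains available (`marker_association(method="any")`).
- *Raw p, not BH.* This is an exclusion screen: the cost of a miss is a
  purity artefact reported as biology, while the cost of a false flag is
  one lost protein in ~20. BH controls false discoveries — the wrong error
  for a screen — and under-excludes badly. BH thresholding remains
  available (`adjust="bh"`).

Flagged proteins get `excluded=True` when they are DEPs and are dropped
from the reported lists (`dep_final`). The exclusion report counts, per
contrast, DEPs removed, and — when the marker-free counterfactual model is
also fitted — how many DEPs the adjustment removed from and added to the
lists.

*Known cost:* when purity is genuinely confounded with subgroup, the
marker covariates are correlated with the subgroup indicators and inflate
the variance of the subgroup coefficients, so absolute detection of true
effects drops a few percent relative to the (biased) marker-free model.
That is the price of unbiasedness, not a defect of the screen; on our
contamination studies the screen itself retains ~95% of the true DEPs the
adjusted model detects while removing essentially all contaminant false
positives.

## Enrichment

**ORA**: one-sided hypergeometric upper tail of the overlap between a
query set (e.g. a DEP list) and each gene set intersected with the
universe (all tested proteins); BH across sets.

**GSEA**: proteins are ranked by a score — the contrast log2FC, or the
signed p metric sign(log2FC)·(−log10 raw p), capped at ±320 when p
underflows; ties break by protein id so rankings are order-invariant.
Walking down the ranking, set members add |score|^w (w = 1 by default)
normalized by the set total, non-members subtract 1/(N − |S|); ES is the
deviation of maximal absolute value, so |ES| ≤ 1. The null is gene-label
permutation (random same-size sets, cached per set size), chosen because
sample-label permutation is infeasible with subgroups as small as n = 9.
NES = ES / mean(|null ES| of the same sign); the permutation p counts
same-sign nulls at least as extreme with the +1 correction, so
p ≥ 1/(n_perm + 1); BH across tested sets per run. Defaults: n_perm = 1000,
min_size = 10, max_size = 500, seed required. An exhaustive mode enumerates
every labeling for toy-scale problems and is used by the tests as an exact
cross-check.

**Consensus**: a set counts as robustly enriched only if its BH-adjusted p
is below α under *both* ranking metrics with agreeing NES sign. Extreme
terms are the top-k by highest and by lowest NES, ties broken by set name.

## Survival

Candidate proteins (by default the three most over- and underexpressed
DEPs per contrast) are assessed two ways: (i) abundance dichotomized at
the cohort median (ties to "low"; a constant vector is an error),
Kaplan–Meier curves per group and the log-rank test; (ii) univariable Cox
proportional-hazards regression on the continuous log2 abundance, Efron
handling of tied event times, two-sided Wald p, CI = exp(β ± 1.96·SE).
KM/log-rank/Cox are computed with lifelines; the test suite checks them
against hand-computed product-limit tables, an observed-minus-expected
log-rank table, and a brute-force Efron partial-likelihood grid search.
Monotone-likelihood separation is reported via `converged=False`, never
silently. Log-rank uses the chi-square asymptotics (adequate at cohort
sample sizes); no proportional-hazards diagnostics or multivariable models
are attempted.

## Exact r×c contingency tests

The two-sided exact conditional test generalizes Fisher's 2×2 test:
conditional on both margins, table probability is multivariate
hypergeometric, and p is the total probability of all margin-consistent
tables no more probable than the observed one. The comparison uses a
relative tolerance of 1e-7 (table probabilities can tie only up to
floating point). Enumeration is row-recursive over bounded integer
compositions, rows sorted ascending by total so the recursion stays
shallow, with the last two rows fully vectorized; a visited-node budget
(default 5e7) guards runaway problems, directing the caller to the seeded
Monte-Carlo mode, which samples margin-conditioned tables by sequential
multivariate-hypergeometric draws (grouped by identical remaining margins
for vectorization) and applies the same rule. The two modes agree within
Monte-Carlo error on every fixture; the exact mode reproduces the cohort
baseline-table p-values (sex 0.692, epilepsy 0.139, surgery type 0.496,
tumor side 0.379) in under a second each. Kruskal–Wallis uses the
tie-corrected H with chi-square p; all-identical input is the defined
degenerate case H = 0, p = 1.

## Dose–response

Raw luminescence is divided by the mean of the untreated control wells per
(sample, compound), so controls average exactly 1 and plates with
different raw scales become comparable. The variable-slope 4PL
Y = bottom + (top − bottom)/(1 + 10^((logIC50 − X)·hill)) is fitted by
least squares on X = log10 molar concentration (controls excluded from the
fit), with four starts (hill ±1, logIC50 at/around the median X) to guard
the hill-sign ambiguity; best SSE wins, ties to the first start. Data with
response range below 1e-3 are flagged degenerate (flat line; hill
unidentifiable) rather than raised. No constraint forces top ≥ bottom —
an inert compound is a legitimate fit. Across-patient comparisons per
(compound, concentration) use Kruskal–Wallis followed by Dunn's z-tests
with tie correction and Bonferroni multiplication over pairs.

## Synthetic-study generator

The generator emulates the study design so that every stage has ground
truth; defaults are the study conditions:

- **Cohort**: 82 samples in subgroups 34/12/9/14/13; age ~ subgroup-mean
  normal (means 44.5/38/60/66/59, SD 10, clipped to 20–80); sex and
  epilepsy Bernoulli at the cohort rates; chemo/radio/steroids assigned as
  exact counts at the cohort prevalences (2/82, 1/82, 46/82) — Bernoulli
  sampling of events this rare would regularly produce constant design
  columns. Samples are block-randomized over six 16-channel plexes, one
  channel per plex reserved for the pooled reference.
- **Abundance** (log2): baseline N(20, 1.5²) per protein, plus a planted
  subgroup effect for a fraction frac_dep = 0.1 of proteins (each affects
  exactly one HGG subgroup, sign ± at random, magnitude 1.0), confounder
  effects on 50 proteins (coefficients N(0, 0.2²)), a contamination term
  `contamination_beta × c` (β = 2) on 50 contaminant proteins, and
  N(0, 0.5²) biological noise.
- **Contamination** c ∈ (0,1) per sample: Beta(2,5) i.i.d. by default
  (right-skewed, mostly < 0.5). Setting `contamination_mean_per_subgroup`
  shifts the Beta mean per subgroup at fixed concentration a+b = 7,
  emulating purity confounded with subgroup (infiltrative LGG carry the
  most non-neoplastic tissue); the purity-adjustment tests use
  (0.40, 0.25, 0.20, 0.20, 0.20). Marker proteins follow
  log2 = baseline + offset + slope·log2(c) with slope 1: the measured
  marker amount is proportional to the non-neoplastic cell fraction, the
  mechanistically natural model for bulk tissue.
- **Measurement**: per-sample intensity 2^abundance, multiplied by a
  per-plex batch factor 2^b, b ~ N(0, 0.25²); the reference channel
  carries the arithmetic mean of all sample intensities (study-wide by
  default; per-plex pooling is available via `reference_scope`, since
  either composition is plausible) under the same batch factor. Each
  protein/plex intensity is split over 3 PSM records with Dirichlet(5)
  shares and multiplicative log-normal noise (SD 0.1 log2).
- **Survival**: the cohort draws a latent risk score z ~ N(0,1) per
  sample; survival is exponential with hazard = (1/24)·exp(0.7·z) months,
  administratively censored at 60 months. Three designated proteins add z
  to their abundance, so their measured log2 values predict survival. Cox
  on the *measured* protein recovers ~0.8 × 0.7 ≈ 0.56 — classical
  attenuation from the 0.5-SD measurement noise on a unit-variance signal;
  Cox on noiseless scores recovers 0.7.
- **Gene sets**: one planted set per contrast built from that contrast's
  *up-regulated* DEPs (members shifted in opposite directions cancel in a
  running sum, so a directionally coherent set is what "enriched" means),
  padded with random proteins; plus random sets. Written as GMT.
- **Dose plates**: 9-point log-dilution series, 4 replicates, 8 untreated
  control wells, per-curve true 4PL parameters drawn from realistic ranges
  (bottom ∈ [0, 0.25], logIC50 well inside the tested range,
  hill ∈ [0.6, 2]), Gaussian noise SD 0.05 on the viability scale, raw
  luminescence scale drawn per sample.

All randomness flows from a single seed through named child streams
(`SeedSequence([seed, stream])`); identical configurations are
byte-identical, and no global RNG state is touched.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: peptide-level effects (missed cleavages,
modification states, shared peptides), intensity-dependent missingness
(the synthetic data are complete), non-Gaussian heavy-tailed noise,
ratio compression from co-isolation interference, batch effects beyond a
single multiplicative plex factor, and correlation structure among
proteins beyond the planted contamination/confounder terms. Recovery
results here demonstrate correctness of the statistical machinery under
the generative model, not field performance.

## The noise-free limit and quantile normalization

With every noise term at zero, the planted DEP lists are recovered
*exactly* — but only with the quantile step disabled. Quantile
normalization forces identical sorted vectors on all channels of a plex;
noise-free planted data violate its premise by construction (columns with
planted shifts have genuinely different distributions), and the forced
equalization perturbs non-planted proteins that have zero residual
variance, which any consistent test must then flag. The pipeline therefore
exposes `quantile` as a stage option (default on); the noise-free
ground-truth checks run with it off (aggregation → reference bridging →
log2 is exactly invertible). Two further consequences of exact zero noise:
the three markers become exactly collinear (each is the same affine
function of contamination), so noise-free fixtures use a single marker
covariate; and the survival proteins' risk tracking is unmodeled variance,
so those fixtures set `n_survival_proteins = 0`.

## Problem sizes used in tests

The test suite and acceptance script run simulations at 200–2000 proteins
and 10–20 seeds per check, with the purity-adjustment and FDR checks at the
full default scale (2000 proteins × 82 samples). These sizes put
Monte-Carlo noise well below the asserted margins; the FDR bound carries an
explicit slack (0.05 nominal, 0.08 asserted) for the same reason.
Moderation strength grows with the number of proteins (the prior df is
better identified), so screens are evaluated at default scale rather than
on toy matrices.
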