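# Methods

## Model and assumptions

The package implements two-sample summary-statistics MR.  Exposure and
outcome associations come from non-overlapping GWAS cohorts; each instrument
is assumed (i) associated with the exposure, (ii) independent of
confounders, and (iii) affecting the outcome only through the exposure.
Estimation works entirely on per-SNP (β, SE) pairs; individual-level data
never enter.  Quantitative traits are in SD units, binary outcomes on the
log-odds scale, so causal effects on a binary outcome are log-ORs per SD of
exposure and are reported with their exponentiated OR and 95 % CI.

## Instrument processing

- **Selection**: p < 1e-5 (locus-wide, the convention for modest-n
  microbiome GWAS) and common alleles.  The frequency filter is applied in
  the minor-allele sense min(EAF, 1−EAF) > 0.01: a literal "EAF > 0.01"
  would keep a 0.995-frequency allele whose minor form is rare, defeating
  the filter's purpose.  The literal reading is available via
  `minor_allele_sense=False`.
- **Clumping**: greedy, smallest-p index SNP first; removes candidates with
  r² ≥ 0.1 within ±1000 kb on the same chromosome.  Pairs missing from the
  LD table, on different chromosomes, or beyond the window are unlinked by
  definition.  Output is invariant to input order (p-value order with rsid
  tie-break decides everything).
- **Harmonization**: allele-order swaps negate βY and complement the
  outcome EAF; strand flips are resolved by complementing alleles before
  matching; allele sets that disagree even after a strand flip drop the SNP
  (never guessed).  Palindromic (A/T, C/G) SNPs cannot be oriented from
  alleles alone: by default they are dropped when min(EAF, 1−EAF) ∈
  [0.42, 0.50] in either dataset and otherwise oriented by frequency
  agreement; `strict` mode drops them all.  Harmonization is idempotent.
- **Proxies**: when an index SNP is absent from the outcome table, the
  instrument is replaced wholesale by the best partner with r² > 0.8 that is
  present in both the outcome and the exposure tables (ties: higher r²,
  then smaller exposure p, then rsid).  Cross-variant allele alignment via
  LD sign would need haplotype data, which summary statistics do not carry;
  replacing the instrument keeps the per-SNP record internally consistent.
  Proxied instruments carry a `proxy_of` flag.
- **Minimum count**: exposures with fewer than 3 harmonized instruments are
  skipped (logged), matching the sensitivity analyses' requirement.
- **Strength**: R² = 2β²f(1−f)/(2β²f(1−f)+2N·SE²·f(1−f)) per SNP (the
  2f(1−f) factor cancels but mirrors the estimating equation), and
  F = (N−2)R²/(1−R²); a set with min F < 10 raises a weak-instrument flag.

## Estimators and inference

- **IVW**: closed-form weighted regression through the origin, weights
  1/seY² (first-order/NOME).  Default model is multiplicative random
  effects with inflation floor 1 — over-dispersion widens the SE, chance
  under-dispersion never shrinks it.  The fixed-effect model is available
  by flag and is the one used for null-calibration checks: under a
  homogeneous null it is the correctly specified test (measured rejection
  0.049 at α = 0.05 over 10,000 replicates), whereas the floor makes the
  random-effects test conservative (0.040).  Real microbiome data are
  expected to be over-dispersed, hence the random-effects default for
  analysis.  Normal p-values.
- **MR-Egger**: weighted regression with free intercept after orienting
  βX > 0; classical WLS inference with σ² the weighted residual mean square
  on J−2 df and t(J−2) tests for slope and intercept.  The SEs scale with
  σ (no floor): this is exactly calibrated under homogeneity and still
  widens under pleiotropy heterogeneity.
- **Weighted median**: weights (βX/seY)² normalised; the estimate
  interpolates the sorted ratios at cumulative weight midpoint 0.5.  The SE
  is a seeded parametric bootstrap (default 1000 draws) redrawing βX and βY
  from normals at their SEs.  Known property, quantified by the acceptance
  script: because the bootstrap re-noises ratios around already-noisy
  centres, the density near the median is understated and the SE
  over-estimated by roughly 18 % in this data regime, making the
  weighted-median test conservative (null rejection ≈ 0.024 at α = 0.05).
  Reported as-is; no ad-hoc deflation is applied.
- **Wald ratio**: first-order SE seY/|βX| by default; the second-order
  delta-method term is available by flag.
- **MR-PRESSO**: observed RSS = Σ w_j (βY_j − β̂(−j)βX_j)² with
  leave-one-out IVW slopes; the null distribution regenerates
  βY* ~ N(β̂(−j)βX_j, seY_j) and refits the leave-one-out slopes per draw
  (1000 simulations by default, fully vectorised).  Per-SNP outlier
  p-values are empirical tail probabilities of the squared weighted
  residual, Bonferroni-corrected across instruments; flagged SNPs are
  removed for the corrected IVW estimate.  The distortion test compares the
  all-SNP and outlier-removed estimates against a null built by resampling
  pseudo-outlier sets from the unflagged pool (seed offset derived from the
  master seed).  All empirical p-values carry an add-one pseudo-count, so
  finite simulation never reports p = 0.
- **Mediation**: proportion mediated = β1·β2/β3 from three IVW estimates.
  Uncertainty by parametric bootstrap (default 10,000 draws) sampling the
  three estimates independently — justified because they come from three
  non-overlapping cohorts; this independence is an assumption, and
  correlated sampling error would narrow or widen the CI accordingly.
  Draws with |β3*| < 1e-12 are discarded and counted; more than 50 %
  discarded is a hard error.  Proportions outside [0, 1] are reported as
  computed with a qualitative flag — inconsistent mediation is informative.
  The screen requires all three links nominally significant (two-sided
  α = 0.05) before decomposing a pathway.

## Multiple testing and replication

The screening phase uses nominal two-sided α = 0.05 with no correction by
default, mirroring how microbiome-wide MR screens are usually reported;
Bonferroni and Benjamini–Hochberg adjustments are available by flag.  A
replication row is `replicated` when the IVW direction matches discovery
and p < α; hits replicating in some but not all testable outcomes are
labelled `partially replicated`, and outcomes yielding fewer than 3
instruments are `not testable`.

## Synthetic data generator

The generator works at the summary-statistics level and emulates:

- a quantitative exposure GWAS, n = 1539, EAF ~ Uniform(0.05, 0.95),
  SE = 1/√(2N·f(1−f)); true instrument effects γ ~ N(0, 0.08²).  γ_sd =
  0.08 makes selected instruments' F-statistics land in the low-20s
  (median ≈ 25, minimum ≈ 19.5), matching the instrument-strength regime
  of the motivating study design.  Instruments are rejection-resampled
  until the *observed* association passes p < 1e-5, so winner's-curse
  selection is part of the data-generating process rather than hidden; its
  consequence — IVW attenuation of roughly 15–20 % with measured exposure
  betas — is quantified in the test suite.
- a binary outcome with 489 cases / 75,531 controls; log-OR SEs via the
  effective sample size N_eff = 4/(1/cases + 1/controls):
  SE = √(2/(f(1−f)·N_eff)).  A quantitative outcome mode (default
  n = 241,112, the BUN/eGFR meta-GWAS scale) is available for replication
  scenarios.
- horizontal pleiotropy in units of each SNP's outcome SE, in four modes
  (none, balanced, directional, InSiDE-violating).  Directional offsets
  follow the exposure-increasing orientation, sign(γ): with symmetric
  allele coding a literally constant offset would cancel in any regression
  through the origin and bias nothing.  Per-SNP contamination offsets use
  the same convention.
- an optional protein mediator chain: the exposure's instruments act on the
  mediator through β1, the mediator has its own 15 instruments (absent from
  the exposure GWAS) acting on the outcome through β2, and the exposure's
  total outcome effect θ decomposes as direct + β1·β2.  Mediator GWAS
  n = 2000, the scale of a protein-GWAS sub-cohort.
- exchangeable LD blocks (one per instrument; block members carry the
  attenuated effect r·β with independent estimation noise and appear in the
  pairwise r² table), enough structure to exercise clumping and proxy
  search.  A configurable share of outcome rows is stored allele-swapped
  so harmonization is always exercised; optional palindromic variants and
  outcome-missing index SNPs exercise the remaining branches.

What it does **not** emulate: real LD maps and allele-frequency spectra,
microbiome compositionality, sample overlap between cohorts, population
stratification, or correlated pleiotropy beyond the InSiDE-violating mode.
Passing tests therefore demonstrate correctness of the estimators and
pipeline logic under the stated generative model, not robustness to every
failure mode of real data.

## Numerical choices

- Single seeded `numpy` generator per run; per-stage seeds derived from the
  master seed via `SeedSequence` spawning (kept below 2³¹).  Identical
  configs reproduce byte-identical outputs.
- Empirical p-values: (1 + exceedances)/(n_sim + 1).
- Ties in selection and clumping broken by (p-value, rsid); proxy ties by
  (r², exposure p, rsid).
- Report tables: fixed column order, %.6g floats, mergesort row ordering —
  byte-stable across reruns.
- Degenerate inputs are hard errors rather than NaNs: zero exposure beta in
  a Wald ratio, identical oriented exposure betas in Egger, r² ≥ 1 in the
  F-statistic, < 2/3/4 instruments for IVW/Egger-median/PRESSO.
- Validation never silently edits: rows failing invariants are dropped and
  logged; a β/SE-vs-p mismatch beyond 10 % (two-sided normal) is a warning
  only.

## Problem sizes used by the test and acceptance runs

Null calibration uses 2000 replicates at J = 20 instruments; robustness and
outlier studies 500 replicates; mediation coverage 1000 runs of a
10,000/2000-draw bootstrap; the screening false-positive check 500 null
features.  These sizes give binomial CIs tight enough to be informative
while the whole suite completes in about a minute.

## Known limitations

- The weighted-median bootstrap SE is conservative (above); its null test
  under-rejects by about half the nominal rate in this regime.
- MR-Egger's intercept test has intrinsically low power here: p < 1e-5
  selection compresses the spread of oriented exposure betas (all selected
  z-scores sit just above the threshold), making intercept and slope nearly
  collinear; at a 2-outcome-SE directional offset, power is ≈ 0.3 at J = 40.
  Detecting such offsets reliably needs ~80+ instruments or larger offsets.
- Winner's-curse attenuation is reproduced, not corrected; no Steiger
  filtering, mode-based estimation, multivariable MR, or reverse-direction
  MR (the exposure GWAS is available only as an exposure).
- LD is consumed precomputed; no genotype processing or liftover.
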