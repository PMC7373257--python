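# Methods

This note documents the statistical methods implemented in `cafescore` and
the design decisions behind them, in the order the pipeline runs.

## Synthetic cohort generator

**Genotypes.** Variants are laid out in blocks of equal size on chromosomes
1–22, with 2 kb spacing inside a block and >500 kb gaps between blocks so
that inter-block LD is structurally zero for a 250 kb clumping window.
Within a block, haplotypes follow a first-order Markov copying process: each
successive variant copies the previous haplotype allele with probability
√r², producing adjacent-pair dosage correlation close to the configured
`block_r2` (verified empirically by the test suite). All variants in a block
share one minor-allele frequency drawn uniformly from `maf_range`; dosages
are sums of two independent haplotypes, so single-site genotypes are in
Hardy–Weinberg proportions by construction.

**Genetic architecture.** A configurable fraction of variants is causal for
BMI, at most one per LD block (so clumping at the default r² cutoff can in
principle isolate each signal). The true polygenic liability is the
standardized causal-dosage sum; BMI is built as baseline + liability scaled
to an `bmi_h2` heritable fraction + age and sex terms + Gaussian residual.

**Discovery weights.** The external weight table is emulated by adding
sampling noise to the true per-allele effects with the standard error
1/√(2·p·(1−p)·N) of a single-SNP regression in a discovery study of N
individuals, and converting the resulting z-scores to two-sided P values.
Null variants therefore carry uniform P values and noisy near-zero betas —
the threshold scan operates on realistic inputs.

**Purchases and surveys.** Each participant gets a negative-binomial item
count over a 13-week pre-enrollment window (weekday purchases only),
breakfast/lunch/other time slots, and traffic-light colors drawn from a
multinomial whose log-probabilities are tilted by the genetic liability.
The tilt coefficient is calibrated so a configured effect in Healthy
Purchasing Score percentage points per SD of liability is reproduced in
expectation. Meal times shift linearly with liability; survey behaviours are
Bernoulli on a logit scale. Setting all purchase effects to zero yields an
exact null generator, used for type-I calibration.

## Genotype quality control

- **Hardy–Weinberg**: exact conditional test. Given the allele count, the
  probability of each heterozygote count compatible with it (same parity) is
  computed from the exact conditional distribution via log-gamma arithmetic,
  and the two-sided P is the sum of probabilities no larger than the
  observed table's. The acceptance suite checks this against a full
  rational-arithmetic enumeration for every table with n ≤ 50.
- **Filters**: variants need HWE P ≥ 1e-6, MAF ≥ 0.01, call rate ≥ 0.98, and
  imputation quality ≥ 0.50; samples need call rate ≥ 0.95 and
  heterozygosity below median + 3 × IQR (one-sided — low heterozygosity is
  not penalized).
- **Relatedness**: moment-based pi-hat from identity-by-state counts.
  Per-pair IBS0/IBS1/IBS2 totals are solved against their allele-frequency
  expectations under IBD 0/1/2 to give P(IBD=k), clipped to [0, 1], with
  pi-hat = P(IBD=1)/2 + P(IBD=2). Pairs above 0.25 are pruned greedily by
  degree (ties broken lexicographically for determinism). *Limitation*: this
  estimator assumes many independent loci. On desk-scale panels (hundreds of
  effective loci) its sampling noise has heavy tails, so a noticeable share
  of truly unrelated pairs can exceed the 0.25 threshold and be pruned; with
  genome-scale panels the noise is negligible. The acceptance suite checks
  separation of duplicate (≈1), parent-offspring (≈0.5), and unrelated (≈0)
  pairs at 5,000 independent variants.
- **Ancestry**: principal components of the standardized dosage matrix via
  SVD, with each component's sign fixed so its largest-magnitude variant
  loading is positive (deterministic output).

## Polygenic scores

**Fixed-loci score.** A 97-variant weight table partitioned into 54 CNS and
43 non-CNS loci. Effect alleles are matched to genotype metadata allowing
allele swaps and strand complements; variants with negative discovery betas
are flipped to risk orientation so all weights are non-negative; missing
dosages are mean-imputed at twice the effect-allele frequency. The raw score
is the weighted risk-allele sum. The scaled score is raw × 2M / (2Σβ) — a
rescaling to a weighted risk-allele-count scale in [0, 2M], so downstream
effects read per risk allele. Sub-scores of a partition sum exactly to the
full raw score.

**Genome-wide score.** Greedy LD clumping: variants are visited in ascending
discovery-P order (ties: position, then ID), each retained variant retires
unvisited variants on the same chromosome within ±250 kb whose in-sample
r² exceeds 0.1. The retained set is then thresholded on discovery P over a
fixed grid, and the best-fit threshold is the one maximizing model R² of
inverse-normalized BMI on the standardized score (ties go to the smaller,
sparser threshold). Clumping is threshold-independent and computed once per
scan.

## Purchase phenotypes

All phenotypes are computed over a half-open 91-day baseline window:
enrollment − 91 days ≤ t < enrollment. The Healthy Purchasing Score is
100 × the mean of green = 1, yellow = 0.5, red = 0 over labeled items;
unlabeled items drop out of numerator and denominator, and a participant
with no labeled item is excluded (NaN) rather than scored. Meal timing is
the median over days of the first food purchase inside the breakfast
(06:00–10:00) or lunch (11:00–14:00) window, bounds inclusive. Survey
items are dichotomized as: meal skipping — "Never" = 0 versus any skipping;
home preparation — fewer than 3 days/week = 0 versus 3 or more (en/em
dashes in category labels are normalized before matching, and unknown
categories are an error, not a silent NaN).

## Association models

Exposures enter as population quartiles (Q1 = lowest risk, reference) and,
as a sensitivity analysis, as the standardized continuous score. Models
adjust for age, sex, seasonality harmonics (sin/cos of scaled day-of-year,
θ = 2π(day − 1)/365.25), and ancestry PCs.

- **Continuous outcomes** are fit twice: ordinary least squares on the
  untransformed outcome gives the effect and 95% CI in natural units
  (percentage points, items, minutes); the reported P comes from the same
  design on the rank-based inverse-normal transform of the outcome,
  z = Φ⁻¹((rank − 0.5)/n) with ties averaged. This keeps effects
  interpretable while protecting the tests from skew.
- **Binary outcomes** use logistic regression with Wald 95% CIs on the odds
  ratio. Separation or non-convergence is flagged (`converged = False`, CI
  set to NaN) rather than reported as a spuriously precise estimate.
- **Trend** enters the quartile index 1–4 as a single ordinal term.
- **Heterogeneity** between the CNS and non-CNS scores is tested with
  z = (b₁ − b₂)/√(se₁² + se₂²) on the model scale (log-odds for binary
  outcomes).
- **Multiple testing**: Benjamini–Hochberg step-up FDR applied within
  outcome families (purchase-record outcomes; survey outcomes) over the
  primary quartile contrasts.

Design matrices are rank-checked before fitting and singularities are
reported with the names of the collinear columns; every model requires at
least 10 complete cases per parameter.

## Validation strategy

Because no real cohort ships with the package, correctness is established
by construction and recovery, and the test suite encodes it:

- the combinatorial primitives (clumping, exact HWE, BH-FDR) are checked
  against independent brute-force oracles — exhaustively for HWE tables up
  to n = 50 and for permutations of small P-value sets;
- the best-fit genome-wide score recovers a generative heritable fraction of
  0.15 within ±0.03 across 20 seeds at n = 5,000;
- a planted Q4−Q1 purchase-quality deficit of −5 percentage points at
  n = 2,000 is recovered with 95% CI coverage within the binomially expected
  band over 100 seeds when quartiles are formed on the true liability.
  Quartiles of the *estimated* score attenuate the contrast toward zero
  (classical measurement-error attenuation, since the estimated score is a
  noisy proxy of the liability), so the estimated-score check asserts
  direction rather than unbiasedness;
- under the null generator, quartile-contrast, trend, and heterogeneity
  tests hold a 5% type-I error within ±2 percentage points over 1,000
  replicates;
- identical configs and seeds produce byte-identical outputs, verified by
  SHA-256 checksums recorded in the run manifest.
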