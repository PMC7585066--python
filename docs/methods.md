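# Methods

## Stochastic epigenetic mutations and mutation load

A stochastic epigenetic mutation (SEM) is a per-person outlier in DNA
methylation: at a given CpG, a sample whose beta value (methylation
fraction, in [0, 1]) lies strictly beyond the Tukey-style fences

    lower = Q1 - k * IQR,    upper = Q3 + k * IQR

of the cohort's distribution at that CpG. The default multiplier is
k = 3; k = 2 ("loose") and k = 4 ("stringent") are sensitivity settings.
Quartiles are estimated across all non-missing samples of the matrix
being analyzed — fences are cohort-specific, and the evaluated sample is
included in its own fence estimate (no leave-one-out). Quantiles use
linear interpolation at position p*(n-1); because call counts are
sensitive to the quantile rule, `compute_fences` exposes numpy's
`method` vocabulary for sensitivity analyses.

Numerical conventions:

- Inequalities at the fences are strict; a value exactly on a fence is
  not a mutation.
- A constant probe has IQR = 0 and degenerate fences; only values that
  differ from the constant in the right direction can be called. No
  minimum-IQR floor is imposed.
- Probes with fewer than 4 non-missing values get unusable fences and
  are excluded from calling with a warning.

The epigenetic mutation load (EML) is a person's total SEM count. EML
distributions are heavy-tailed, so analyses use ln(EML). A zero count
has no defined log; `compute_eml` flags it as missing rather than
inventing a pseudocount (a pseudocount can be supplied explicitly; the
desk-scale simulations in the test suite use `pseudocount=1` where small
probe universes make zero counts possible). Directional (hypo/hyper),
region-specific, regulatory-feature, island-context, and clock-specific
EMLs count the same calls restricted to probe subsets; a probe annotated
to several gene-region groups increments each group once, so region EMLs
deliberately do not partition the total. Recurrent ("consistent") SEMs
are (probe, direction) pairs mutated in the same direction in strictly
more than 10 participants by default.

## Methylome Shannon entropy

Per sample,

    H = 1 / (N * log2(1/2)) * sum_i [ b_i log2 b_i + (1 - b_i) log2(1 - b_i) ]

with 0*log2(0) = 0; N is the number of probes actually used for that
sample (missing values skipped). H = 1 when every beta is 0.5 and H = 0
when every beta is 0 or 1. Betas are clipped to [1e-12, 1 - 1e-12]
before the logs purely to avoid -inf*0 float artifacts; exact 0/1 values
are handled by the convention first. Entropy is computed on the filtered
probe set by default (whatever matrix is passed in).

## Epigenetic age acceleration

A clock is a linear predictor: DNAm age = intercept + sum_j w_j b_j over
a fixed CpG set. Published coefficient sets are not bundled (licensing
and array-version pinning); the module reads user-supplied coefficient
files or accepts precomputed DNAm-age columns, which matches how
practitioners obtain clock estimates from external calculators.
Acceleration is the residual of OLS of DNAm age on chronological age
with intercept, fit within each cohort separately (cohorts are analyzed
separately throughout, so pooled fitting would leak between-cohort age
structure into the residuals). By construction the residuals have mean
zero and exactly zero sample correlation with chronological age.
Intrinsic acceleration (IEAA-style) is not a separate code path: pass
the estimated cell fractions as additional covariates to the
residualization step.

## Association analysis

The pattern is residualize-then-correlate. The outcome (ln EML or
entropy) is regressed on the confounders — age, sex, race/ethnicity, and
the five estimated blood-cell fractions (naive CD8, exhausted
CD8+CD28-CD45RA-, plasmablasts, CD4 T, granulocytes) — and only the
residuals are correlated with the targets, which enter untouched.
Categorical covariates are treatment-coded against the alphabetically
first level; rows with any missing field are dropped listwise;
a rank-deficient design raises an error naming the collinear columns.

Correlation uses the biweight midcorrelation (bicor): with m = median(x)
and d = median(|x - m|) (raw MAD, no 1.4826 factor), u = (x - m)/(9d),
Tukey weights w = (1 - u^2)^2 zeroed where |u| >= 1, and x~ = (x - m)w,

    r = sum(x~ y~) / sqrt(sum x~^2) / sqrt(sum y~^2).

If a vector's MAD is zero it falls back to plain mean-centering with a
warning. Two-sided p-values use the Student-t transform
t = r sqrt((n-2)/(1-r^2)) on n - 2 df. Stratified scans (by sex, or by
the sign of an acceleration measure with zeros excluded) emit one row
per (target, stratum); strata with fewer than 4 complete pairs are
flagged rather than estimated. Nominal p-values are reported without
multiplicity correction, matching how such correlation scans are
conventionally summarized.

QC checks: one-way ANOVA of ln EML across slide/position labels (batch),
and Pearson correlation of ln EML with the mean bisulfite-conversion
control intensity (incomplete-conversion artifact).

## Meta-analysis

Cohorts are combined with Stouffer's method on the Fisher-z scale:

- meta r = sum(n_i * atanh(r_i)) / sum(n_i), reported on the z scale by
  default. For the weak correlations this method targets (|r| < 0.35)
  the z scale and the r scale differ only in the third decimal; a
  `back_transform` option applies tanh for users who want a proper
  correlation-scale estimate.
- meta p: Z = sum(sqrt(n_i) s_i) / sqrt(sum n_i) mapped to a two-sided
  normal tail. The default per-cohort deviate is the normal score of the
  correlation itself, s_i = atanh(r_i) sqrt(n_i - 3); this is the
  variance-stabilized Fisher-z test statistic and is the package's
  primary definition. An alternative (`deviates="p-value"`) converts
  each cohort's two-sided p back to a signed normal quantile, which is
  useful when only p-values are available but loses precision for very
  small p.
- Weights n_i (for meta r) versus n_i - 3 change nothing at three
  decimals for cohort sizes in the hundreds and above; n_i is used.

## Per-participant enrichment

For each participant and probe set, the SEM probes are treated as n
draws without replacement from the N-probe analysis universe; with K
set members and k observed hits, p = P(X >= k) for X ~
hypergeometric(N, K, n) — upper tail only, since the question is
over-representation. The significance indicator uses alpha = 0.05 with
no per-participant multiplicity correction; prevalence (how many
participants are significant per set) is interpreted descriptively. The
universe defaults to all probes surviving filtering, not only annotated
probes, because the fences — and therefore the draws — are defined on
the analysis matrix; a restricted universe can be passed explicitly.
Pathway gene sets (GMT files) are expanded to probe level through the
manifest's probe-to-gene mapping: a probe joins every set containing any
of its annotated genes. Gene-level draws would be the alternative
convention; probe-level is used because SEM events are probe-level.

The pathway-to-acceleration model is, per pathway j and acceleration
measure,

    AgeAccel_i = b0 + b1 * Enrich_ij + b2 * ln(EML_i) + e_i

with Enrich the 0/1 indicator; b1 and its two-sided t-based p are
reported. A constant indicator is flagged inestimable.

## Synthetic cohorts

The generator produces cohorts with the statistical structure the
analysis assumes, plus truth tables, so every stage is testable without
access-controlled data.

- **Baselines.** Probe-level mean betas are drawn per island context:
  Island ~ Beta(2, 18) (low), OpenSea ~ Beta(18, 2) (high), Shore
  Beta(6, 14) and Shelf Beta(14, 6) intermediate; context frequencies
  are Island 30%, Shore 25%, Shelf 10%, OpenSea 35%. Per-cell values are
  Beta around the probe mean with concentration 150 (within-probe SD of
  a few percent, typical of array betas).
- **Mutations.** Each sample's SEM count is Poisson with
  lambda_i = exp(alpha + gamma_age age_i + gamma_acc acc_i). Defaults:
  base rate 0.0046 expected mutations per probe at the midpoint age
  (the per-probe rate implied by mean loads of a few thousand on
  450K/EPIC-scale arrays), gamma_age = ln(2)/50 per year (load doubles
  across the default 40-90 age range), gamma_acc = 0.02 per year, and
  latent acceleration acc_i ~ Normal(0, 5 years). Mutated probes are
  chosen with direction following island context (hyper fraction 0.9 in
  islands down to 0.1 in open sea), and values are placed strictly
  beyond the k = 3 fences of the finished matrix by a margin of
  delta = 0.5 IQR. Because injection itself shifts the quantiles,
  placement iterates (place, recompute fences, re-place) to a fixpoint;
  placements that would leave [0, 1] are re-assigned, and total
  infeasibility raises with advice to lower delta.
- **Clock.** A designated CpG subset (default 30) encodes
  DNAm age_i = age_i + acc_i + Normal(0, 2 years) as betas centered at
  0.5, with matching linear-clock coefficients, so `apply_linear_clock`
  recovers the programmed DNAm age up to the stated noise. Clock CpGs
  are excluded from mutation injection to keep that recovery exact.
- **Metadata.** Sex, a three-level ancestry label, slide/position labels
  (12 samples per slide), a bisulfite-control intensity, BMI, and
  Dirichlet cell fractions with small additive estimation noise (so
  they do not sum exactly to one, as with real deconvolution estimates
  — exact compositions would be collinear with the regression
  intercept). None of these carry planted effects.
- **Spiking (optional).** For pathway-analysis tests, a designated probe
  set can attract the mutations of positively accelerated samples via an
  exp(strength * acc) weight multiplier; the set is recorded in the
  truth table.

What the generator does **not** emulate: probe-level co-methylation/LD
structure, array normalization artifacts, detection-p/bead-count error
processes (QC inputs are exercised with hand-built fixtures), relatedness
between participants, and non-linear clock calibration. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated generative model, not robustness to every
property of real array data.

## Problem sizes used in the test suite

Desk-scale defaults were chosen so the full statistical structure is
present while suites stay quick: single-cohort checks use 120-500
samples by 600-5,000 probes; the multi-cohort parameter-recovery
rehearsal runs 100 seeds of four cohorts at n = 500 x 5,000 probes; the
null-calibration study runs 200 replicates of two cohorts at n = 120 x
600 probes with the base mutation rate raised to 0.013 so that log
loads are well-defined on the small universe. Full 450K/EPIC-scale
matrices (438,050 / 793,869 probes) are supported but not generated by
default.

## Known limitations

- The bicor p-value uses the t approximation; exact permutation p's are
  not implemented.
- Meta r on the Fisher-z scale slightly overstates |r| for large
  effects; use `back_transform=True` when effects exceed ~0.5.
- Family/relatedness structure is not modeled in the association layer
  (no mixed effects).
- Longitudinal within-person mutation accumulation is out of scope; the
  design is cross-sectional.
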