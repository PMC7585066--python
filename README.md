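# semload

Stochastic epigenetic mutation (SEM) analysis for DNA methylation
arrays: outlier calling by interquartile-range fences, epigenetic
mutation load (EML), methylome Shannon entropy, epigenetic age
acceleration, and robust multi-cohort association analysis.

## Who this is for

Epigenetic epidemiologists working with Illumina 450K/EPIC-style beta
matrices who want to quantify failures of the epigenetic maintenance
system — rare, person-specific methylation outliers — and relate their
accumulation to chronological age, epigenetic clocks, and blood-cell
composition across several cohorts analyzed separately.

## The statistics at the core

**SEM calling.** At CpG *j*, sample *i* carries a mutation when its
beta value β<sub>ij</sub> lies strictly outside

> Q1<sub>j</sub> − k·IQR<sub>j</sub>  or  Q3<sub>j</sub> + k·IQR<sub>j</sub>,  k = 3 (loose 2, stringent 4)

with quartiles estimated across all samples of the cohort at that CpG.
Hypomethylated (below) and hypermethylated (above) calls are tracked
separately. **EML** is the per-person total call count, analyzed as
ln(EML), overall and within gene-region groups (TSS1500, TSS200, 5'UTR,
1stExon, Body, 3'UTR), regulatory features, island contexts, and clock
CpG sets.

**Shannon entropy.** Per sample,
H = 1/(N·log₂½) Σ [βᵢ log₂ βᵢ + (1−βᵢ) log₂(1−βᵢ)] — 1 when the
methylome sits at 50% everywhere, 0 when fully polarized.

**Age acceleration.** Residual of OLS of DNAm age (any linear clock or
precomputed column) on chronological age, per cohort; uncorrelated with
age by construction.

**Association.** ln(EML) or entropy is residualized on age, sex,
ancestry, and five estimated blood-cell fractions, then correlated with
each target by biweight midcorrelation (median/MAD-based Tukey-weighted
correlation, robust to outliers) with t-based p-values. Per-cohort
results combine by Stouffer's method on the Fisher-z scale:
meta r = Σnᵢ·atanh(rᵢ)/Σnᵢ and meta Z = Σ√nᵢ·zᵢ/√Σnᵢ with
zᵢ = atanh(rᵢ)√(nᵢ−3).

**Enrichment.** Per participant and probe set, an upper-tail
hypergeometric test of whether the person's SEMs over-represent the set;
pathway indicators then feed
AgeAccel = β₀ + β₁·Enrich + β₂·ln(EML) + ε.

A bundled synthetic-cohort generator plants all of this structure
(context-dependent beta baselines, Poisson mutation counts rising with
age and a latent acceleration factor, a recoverable linear clock,
direction-by-context placement) with full truth tables, so the whole
pipeline is testable end-to-end without access-controlled cohort data.

## Worked example

```python
import numpy as np
from semload import (SimulationConfig, simulate_cohort, compute_fences,
                     call_sems, compute_eml, methylome_entropy,
                     apply_linear_clock, age_acceleration, residualize,
                     bicor_test, stouffer_meta)
from semload.ingest import CELL_TYPES

rows = []
for c in range(2):
    cfg = SimulationConfig(n_samples=300, n_probes=2000, seed=42 + c,
                           cohort_name=f"C{c}")
    beta, meta, annot, clock, truth = simulate_cohort(cfg)
    calls = call_sems(beta, compute_fences(beta, k=3.0))
    eml = compute_eml(calls)
    accel = age_acceleration(apply_linear_clock(beta, clock), meta["age"])
    resid = residualize(eml["log_eml"], meta[["sex", "ethnicity", *CELL_TYPES]])
    rows.append(bicor_test(meta["age"], resid, "age", "log_eml", cfg.cohort_name))

m = stouffer_meta(rows)
print("meta_r:", round(m.meta_r, 3), "meta_p:", f"{m.meta_p:.2e}",
      "total_n:", m.total_n)
```

This prints

```
meta_r: 0.467 meta_p: 5.32e-30 total_n: 600
```

— the two simulated cohorts of 300 people each carry 2,977 and a
similar number of mutation calls over 2,000 probes (mean EML ≈ 10; the
small probe universe scales the load down from array-scale thousands),
the per-cohort robust correlations between covariate-adjusted ln(EML)
and age are 0.455 and 0.416, and the pooled Fisher-z meta-correlation
is 0.467 with overwhelming evidence against independence, recovering
the age-dependence the generator planted (its default mutation rate
doubles across the 40–90-year age range). The acceleration residuals
have mean ~1e−14 and correlation ~1e−15 with age, zero to machine
precision.

The same stages are scriptable from a shell:

```sh
semload simulate --config sim.yaml --outdir cohortA/
semload call    --beta cohortA/beta.tsv --k 3 --out calls.tsv --fences fences.tsv
semload eml     --calls calls.tsv --beta cohortA/beta.tsv --annot cohortA/manifest.csv --out eml.tsv
semload entropy --beta cohortA/beta.tsv --out entropy.tsv
semload accel   --beta cohortA/beta.tsv --clock cohortA/clock.csv --samples cohortA/samples.tsv --out accel.tsv
semload assoc   --eml eml.tsv --meta cohortA/samples.tsv --accel accel.tsv \
                --targets age,accel_clock --covariates sex,ethnicity --cohort A --out assocA.tsv
semload meta    --in assocA.tsv,assocB.tsv --out meta.tsv
```

or orchestrated in one shot from a YAML config with a reproducible run
manifest: `semload run --config run.yaml`.

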