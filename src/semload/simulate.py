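"""Synthetic methylation cohorts with planted SEMs, a planted linear
clock, and full truth tables.

The generator emulates the statistical structure the analysis assumes,
so every pipeline stage is testable without access-controlled cohort
data:

* per-CpG baseline betas drawn by island context — CpG-island probes
  sit low (Beta(2, 18)), open-sea probes high (Beta(18, 2)), shores and
  shelves in between — with tight within-probe variation;
* rare per-person outlier "mutations": each sample's SEM count is
  Poisson with log-rate linear in age and a latent acceleration factor,
  lambda_i = exp(alpha + gamma_age*age_i + gamma_acc*acc_i); injected
  values are placed strictly beyond the k = 3 fences of the finished
  matrix by a margin delta (in IQR units), with hypermethylated
  mutations concentrated in islands and hypomethylated ones in open
  sea;
* a clock-CpG subset whose betas encode DNAm age = age + acc + noise so
  that applying the bundled linear clock recovers the programmed age;
* metadata (sex, ethnicity, Dirichlet cell fractions, slide/position
  batch labels, bisulfite-control intensity) with no planted effects.

Defaults target the study conditions of large blood-methylation
cohorts: a ~0.46% per-probe mutation rate (mean EML of a few thousand
on a 450K-scale array), mutation load doubling across a 40-90 year age
range, and acceleration SD of 5 years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ageaccel import ClockModel
from .ingest import BetaMatrix, CELL_TYPES

ISLAND_PROBS = {"Island": 0.30, "Shore": 0.25, "Shelf": 0.10, "OpenSea": 0.35}

BASELINE_SHAPES = {
    "Island": (2.0, 18.0),
    "Shore": (6.0, 14.0),
    "Shelf": (14.0, 6.0),
    "OpenSea": (18.0, 2.0),
}

HYPER_FRAC = {"Island": 0.90, "Shore": 0.60, "Shelf": 0.40, "OpenSea": 0.10}


@dataclass
class SimulationConfig:
    n_samples: int = 500
    n_probes: int = 5000
    seed: int = 0
    age_range: tuple[float, float] = (40.0, 90.0)
    # Expected SEMs per probe at the midpoint age with acc = 0;
    # 450K/EPIC-scale blood cohorts average ~0.0046 mutations per probe.
    base_sem_rate: float = 0.0046
    # log-rate slopes: lambda doubles across a 50-year age span by default.
    gamma_age: float = float(np.log(2.0) / 50.0)
    gamma_acc: float = 0.02
    sigma_acc: float = 5.0
    delta: float = 0.5  # fence-exceedance margin, IQR units
    island_probs: dict = field(default_factory=lambda: dict(ISLAND_PROBS))
    baseline_shapes: dict = field(default_factory=lambda: dict(BASELINE_SHAPES))
    hyper_frac: dict = field(default_factory=lambda: dict(HYPER_FRAC))
    within_probe_concentration: float = 150.0
    n_clock_cpgs: int = 30
    clock_noise_sd: float = 2.0
    slide_size: int = 12
    cell_dirichlet: tuple = (5.0, 2.0, 1.0, 12.0, 40.0)
    n_genes: int = 200
    # Optional pathway spiking: samples with positive acceleration place
    # their SEMs preferentially inside a designated probe set.
    spike_set_size: int = 0
    spike_strength: float = 0.0
    cohort_name: str = "SIM"

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("placement margin delta must be positive")
        if self.base_sem_rate <= 0:
            raise ValueError("base_sem_rate must be positive")


@dataclass
class TruthTable:
    """What the generator planted: the injected calls, each sample's
    latent acceleration and Poisson rate, the clock probes, and any
    spiked probe set."""

    calls: pd.DataFrame  # sample_id, probe_id, direction
    acc: pd.Series
    lam: pd.Series
    clock_probes: pd.Index
    spike_probes: pd.Index


def _simulate_annotation(rng, probe_ids, cfg: SimulationConfig) -> pd.DataFrame:
    n = len(probe_ids)
    contexts = rng.choice(
        list(cfg.island_probs), size=n, p=list(cfg.island_probs.values())
    )
    gene_idx = rng.integers(0, cfg.n_genes, n)
    region_pool = np.array(["TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR"])
    reg_feat_pool = np.array(["Enhancer", "DHS", "OpenChromatin", "TFBS", "Promoter"])
    # 0-2 region groups per probe, drawn as independent membership bits.
    region_bits = rng.random((n, len(region_pool))) < 0.22
    feat_bits = rng.random((n, len(reg_feat_pool))) < 0.08
    chroms = rng.integers(1, 23, n)
    annot = pd.DataFrame(
        {
            "chromosome": [f"chr{c}" for c in chroms],
            "gene_region_groups": [
                frozenset(region_pool[row]) for row in region_bits
            ],
            "genes": [
                frozenset([f"GENE{g:04d}"]) if row.any() else frozenset()
                for g, row in zip(gene_idx, region_bits)
            ],
            "regulatory_features": [frozenset(reg_feat_pool[row]) for row in feat_bits],
            "island_context": contexts,
            "clock_memberships": [frozenset()] * n,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return annot


def _build_clock(rng, clock_probes, ages_target: np.ndarray, cfg) -> tuple[ClockModel, np.ndarray]:
    """Encode target DNAm ages into clock-probe betas and return the
    matching linear clock plus the (n_clock, n_samples) beta block."""
    m = len(clock_probes)
    mu = float(ages_target.mean())
    rho = max(float(np.max(np.abs(ages_target - mu))), 1e-9) / 0.45
    z = (ages_target - mu) / rho  # in [-0.45, 0.45]
    sign = np.where(np.arange(m) % 2 == 0, 1.0, -1.0)
    g = rng.uniform(0.5, 1.0, size=m)
    betas = 0.5 + (sign * g)[:, None] * z[None, :]
    w = sign * rho * g / np.sum(g**2)
    intercept = mu - 0.5 * float(np.sum(w))
    clock = ClockModel(
        name="simclock",
        intercept=intercept,
        coefficients=pd.Series(w, index=pd.Index(clock_probes)),
    )
    return clock, betas


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, ClockModel, TruthTable]:
    """Generate one cohort.

    Returns (beta, sample_meta, annotation, clock, truth).  Fixed seed
    implies bit-reproducible output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(cfg.n_probes)], name="probe_id")
    sample_ids = pd.Index(
        [f"{cfg.cohort_name}_{i:05d}" for i in range(cfg.n_samples)], name="sample_id"
    )

    annot = _simulate_annotation(rng, probe_ids, cfg)
    contexts = annot["island_context"].to_numpy()

    # Baseline betas: probe-level mean from the context Beta, cell-level
    # values from a tight Beta around it.
    a = np.array([cfg.baseline_shapes[c][0] for c in contexts])
    b = np.array([cfg.baseline_shapes[c][1] for c in contexts])
    mu_p = rng.beta(a, b)
    mu_p = np.clip(mu_p, 0.02, 0.98)
    c = cfg.within_probe_concentration
    values = rng.beta(
        (mu_p * c)[:, None], ((1 - mu_p) * c)[:, None], size=(cfg.n_probes, cfg.n_samples)
    )

    # Demographics and latent structure.
    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], cfg.n_samples)
    acc = rng.normal(0.0, cfg.sigma_acc, cfg.n_samples)
    mid_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    alpha = np.log(cfg.base_sem_rate * cfg.n_probes) - cfg.gamma_age * mid_age
    lam = np.exp(alpha + cfg.gamma_age * ages + cfg.gamma_acc * acc)

    # Clock block (excluded from injection so the planted DNAm age stays
    # exactly recoverable).
    clock_idx = rng.choice(cfg.n_probes, size=cfg.n_clock_cpgs, replace=False)
    clock_probes = probe_ids[np.sort(clock_idx)]
    dnam_age = ages + acc + rng.normal(0.0, cfg.clock_noise_sd, cfg.n_samples)
    clock, clock_betas = _build_clock(rng, clock_probes, dnam_age, cfg)
    values[np.sort(clock_idx), :] = clock_betas
    annot.loc[clock_probes, "clock_memberships"] = [
        frozenset(["simclock"]) for _ in clock_probes
    ]

    # Spiked pathway probes (optional).
    non_clock = np.setdiff1d(np.arange(cfg.n_probes), clock_idx)
    if cfg.spike_set_size > 0:
        spike_idx = rng.choice(non_clock, size=cfg.spike_set_size, replace=False)
    else:
        spike_idx = np.array([], dtype=int)
    spike_probes = probe_ids[np.sort(spike_idx)]
    spike_mask = np.zeros(cfg.n_probes, dtype=bool)
    spike_mask[spike_idx] = True

    def _fences(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        q1, q3 = np.quantile(v, [0.25, 0.75], axis=1)
        iqr = q3 - q1
        return q1 - 3.0 * iqr, q3 + 3.0 * iqr, iqr

    # Candidate feasibility from pre-injection fences: a direction is
    # feasible at a probe if the fence plus a safety margin stays in [0,1].
    lo0, up0, iqr0 = _fences(values)
    safety = cfg.delta + 1.0
    feas_hyper = (up0 + safety * iqr0 < 1.0) & (iqr0 > 0)
    feas_hypo = (lo0 - safety * iqr0 > 0.0) & (iqr0 > 0)
    feas_hyper[clock_idx] = False
    feas_hypo[clock_idx] = False

    hyper_frac = np.array([cfg.hyper_frac[c_] for c_ in contexts])
    base_weight = np.ones(cfg.n_probes)
    base_weight[clock_idx] = 0.0
    base_weight[~(feas_hyper | feas_hypo)] = 0.0

    counts = rng.poisson(lam)
    counts = np.minimum(counts, int(base_weight.sum()))
    inj_sample: list[int] = []
    inj_probe: list[int] = []
    inj_dir: list[str] = []
    for i in range(cfg.n_samples):
        k_i = counts[i]
        if k_i == 0:
            continue
        w = base_weight.copy()
        if cfg.spike_strength > 0 and acc[i] > 0 and cfg.spike_set_size > 0:
            w[spike_mask] *= np.exp(cfg.spike_strength * acc[i])
        p = w / w.sum()
        chosen = rng.choice(cfg.n_probes, size=k_i, replace=False, p=p)
        for j in chosen:
            want_hyper = rng.random() < hyper_frac[j]
            if want_hyper and feas_hyper[j]:
                d = "hyper"
            elif (not want_hyper) and feas_hypo[j]:
                d = "hypo"
            elif feas_hyper[j]:
                d = "hyper"
            else:
                d = "hypo"
            inj_sample.append(i)
            inj_probe.append(int(j))
            inj_dir.append(d)

    inj_sample_a = np.array(inj_sample, dtype=int)
    inj_probe_a = np.array(inj_probe, dtype=int)
    is_hyper = np.array([d == "hyper" for d in inj_dir])

    # Place beyond the fences of the finished matrix: injection shifts the
    # quantiles, so iterate place -> recompute -> verify to a fixpoint.
    for _ in range(25):
        lo, up, iqr = _fences(values)
        iqr = np.maximum(iqr, 1e-4)
        target = np.where(
            is_hyper,
            up[inj_probe_a] + cfg.delta * iqr[inj_probe_a],
            lo[inj_probe_a] - cfg.delta * iqr[inj_probe_a],
        )
        if np.any(target < 0) or np.any(target > 1):
            raise RuntimeError(
                "infeasible SEM placement: margin delta pushes values outside "
                "[0, 1]; use a smaller delta"
            )
        cur = values[inj_probe_a, inj_sample_a]
        ok = np.where(is_hyper, cur > up[inj_probe_a], cur < lo[inj_probe_a])
        if ok.all():
            break
        redo = ~ok
        values[inj_probe_a[redo], inj_sample_a[redo]] = target[redo]
    else:
        raise RuntimeError("SEM placement did not converge; use a smaller delta")

    beta = BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))

    # Metadata with no planted effects beyond age/acc.
    sex = rng.choice(["F", "M"], size=cfg.n_samples)
    ethnicity = rng.choice(
        ["groupA", "groupB", "groupC"], size=cfg.n_samples, p=[0.6, 0.3, 0.1]
    )
    # Imputed cell fractions: compositional draw plus estimation noise,
    # so they do not sum exactly to one (as with reference-based
    # deconvolution estimates in real data).
    cells = rng.dirichlet(cfg.cell_dirichlet, size=cfg.n_samples)
    cells = np.clip(cells + rng.normal(0.0, 0.01, cells.shape), 0.0, 1.0)
    slide = np.arange(cfg.n_samples) // cfg.slide_size
    position = np.arange(cfg.n_samples) % cfg.slide_size
    meta = pd.DataFrame(
        {
            "age": ages,
            "sex": sex,
            "ethnicity": ethnicity,
            "cohort": cfg.cohort_name,
            **{ct: cells[:, k] for k, ct in enumerate(CELL_TYPES)},
            "slide": [f"slide{s:03d}" for s in slide],
            "position": [f"R{p:02d}" for p in position],
            "bisulfite_control_intensity": rng.normal(10000.0, 500.0, cfg.n_samples),
            "bmi": rng.normal(27.0, 4.5, cfg.n_samples).clip(16, 55),
        },
        index=sample_ids,
    )

    truth_calls = pd.DataFrame(
        {
            "sample_id": sample_ids[inj_sample_a] if len(inj_sample_a) else [],
            "probe_id": probe_ids[inj_probe_a] if len(inj_probe_a) else [],
            "direction": inj_dir,
        }
    )
    truth = TruthTable(
        calls=truth_calls,
        acc=pd.Series(acc, index=sample_ids, name="acc"),
        lam=pd.Series(lam, index=sample_ids, name="lambda"),
        clock_probes=clock_probes,
        spike_probes=spike_probes,
    )
    return beta, meta, annot, clock, truth


def simulate_multicohort(
    configs: list[SimulationConfig],
    gamma_age: float | None = None,
    gamma_acc: float | None = None,
) -> list[tuple]:
    """Generate several cohorts sharing the effect parameters but free to
    differ in size, age range, and probe count."""
    if len(configs) < 2:
        raise ValueError("need at least 2 cohort configs")
    out = []
    for cfg in configs:
        updates = {}
        if gamma_age is not None:
            updates["gamma_age"] = gamma_age
        if gamma_acc is not None:
            updates["gamma_acc"] = gamma_acc
        if updates:
            cfg = dataclasses.replace(cfg, **updates)
        out.append(simulate_cohort(cfg))
    return out


def write_cohort(outdir, beta, meta, annot, clock, truth) -> None:
    """Write a simulated cohort in the package's on-disk formats
    (beta.tsv, samples.tsv, manifest.csv, clock.csv, truth.tsv)."""
    import os

    from .ageaccel import write_clock

    os.makedirs(outdir, exist_ok=True)
    beta.to_tsv(os.path.join(outdir, "beta.tsv"))
    meta.reset_index().to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index=False)
    man = pd.DataFrame(
        {
            "Name": annot.index,
            "CHR": annot["chromosome"].to_numpy(),
            "UCSC_RefGene_Group": [";".join(sorted(g)) for g in annot["gene_region_groups"]],
            "UCSC_RefGene_Name": [";".join(sorted(g)) for g in annot["genes"]],
            "Relation_to_UCSC_CpG_Island": annot["island_context"].to_numpy(),
            "Enhancer": ["TRUE" if "Enhancer" in f else "" for f in annot["regulatory_features"]],
            "DHS": ["TRUE" if "DHS" in f else "" for f in annot["regulatory_features"]],
            "Regulatory_Feature_Group": [
                ";".join(sorted(f - {"Enhancer", "DHS"})) for f in annot["regulatory_features"]
            ],
        }
    )
    man.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    write_clock(clock, os.path.join(outdir, "clock.csv"))
    truth.calls.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
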