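"""Synthetic T-ALL relapse cohorts with known ground truth.

The study cohort (paired primary/relapse whole genomes of adult T-ALL
patients) is access-protected, so every downstream stage is exercised on
forward-simulated patients instead:

* clock-like SBS5 mutation counts accumulate from birth at a healthy
  baseline rate, accelerate at a hidden time before diagnosis (constant or
  linear model), and the lineage duplicates at a hidden divergence time --
  giving shared / primary-private / relapse-private branch counts with the
  true divergence recorded;
* read-count tables with a clonal peak at CCF 1 plus optional subclones
  under chosen purity and depth;
* logistic blast-growth trajectories observed at two timepoints whose
  clinical time annotations carry a shared per-patient error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .clonality import MutationRecord
from .divergence_clock import PatientClock
from .doubling_time import BlastObservation, logistic
from .mutation_process import DAYS_PER_YEAR, interval_increment, day_increments

__all__ = [
    "CohortConfig",
    "SyntheticPatient",
    "gen_patient_clock",
    "gen_blast_observations",
    "gen_mutation_table",
    "gen_cohort",
    "apply_true_clonality",
]

_PATIENT_SEED_STRIDE = 7919  # fixed offset deriving per-patient seeds


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of the simulated cohort.

    Defaults encode the study conditions: a healthy SBS5 clock of ~12.21
    mutations/year, acceleration starting 1-6 years before diagnosis with a
    constant-model rate of 0.3-1.5 mutations/day (enough to accumulate the
    few-hundred-mutation leukemic excess over 1-2 years), divergence a few
    months to 1.5 years before diagnosis, and relapse 4-18 months after.
    """

    n_patients: int = 19
    age_range: tuple[float, float] = (20.0, 65.0)  # years at diagnosis
    baseline_slope: float = 12.21  # SBS5 mutations / year
    baseline_intercept: float = 0.0
    acceleration_model: str = "constant"
    acceleration_time_range: tuple[float, float] = (365.0, 2190.0)  # d pre-dx
    accelerated_rate_range: tuple[float, float] = (0.3, 1.5)  # mu (mut/day) or r (/day)
    divergence_time_range: tuple[float, float] = (90.0, 540.0)  # d pre-dx
    relapse_interval_range: tuple[float, float] = (120.0, 540.0)  # d post-dx
    rho: float = 2e-4
    purity_range: tuple[float, float] = (0.7, 0.95)
    depth_mean: float = 80.0
    n_subclonal: int = 100
    subclone_ccf_range: tuple[float, float] = (0.15, 0.4)
    n_other_signature: int = 60  # clonal non-SBS5 mutations (signature filter fodder)
    blast_a_true: float = np.log(2) / 10.79  # logistic truth: T_D = 10.79 d
    blast_offset_sd: float = 10.0  # d of annotation error
    blast_noise_sd: float = 0.25  # logit-scale fraction noise
    seed: int = 0

    def __post_init__(self):
        for name in (
            "age_range",
            "acceleration_time_range",
            "accelerated_rate_range",
            "divergence_time_range",
            "relapse_interval_range",
            "purity_range",
            "subclone_ccf_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy low <= high")
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if self.baseline_slope <= 0:
            raise ValueError("baseline_slope must be positive")
        if self.acceleration_model not in ("constant", "linear"):
            raise ValueError("acceleration_model must be 'constant' or 'linear'")
        if self.baseline_slope / DAYS_PER_YEAR < 0 or self.accelerated_rate_range[0] < 0:
            raise ValueError("daily mutation rates must be non-negative")

    @property
    def baseline_daily(self) -> float:
        return self.baseline_slope / DAYS_PER_YEAR


@dataclass
class SyntheticPatient:
    """One simulated patient with full ground truth."""

    patient_id: str
    age_dx: float  # years
    age_rel: float  # years
    true_t_accel: float  # days pre-diagnosis
    true_t_div: float  # days pre-diagnosis
    true_rate_param: float
    counts: PatientClock
    blast_obs: BlastObservation | None = None
    mutations: list = field(default_factory=list)
    purity: dict = field(default_factory=dict)


def _linear_advance(n: int, n_days: int, r: float, rng: np.random.Generator) -> int:
    """Advance a count through ``n_days`` of the linear (compounding) model."""
    g = np.log1p(r)
    for _ in range(int(n_days)):
        mean = g * n
        if mean > 0:
            n += int(day_increments(np.array([mean]), rng)[0])
    return n


def gen_patient_clock(
    cfg: CohortConfig,
    patient_seed: int,
    patient_id: str = "SYN",
    age_dx_years: float | None = None,
    t_accel: float | None = None,
    t_div: float | None = None,
    rate_param: float | None = None,
    relapse_interval: float | None = None,
) -> SyntheticPatient:
    """Simulate one patient's mutation-count history and branch counts.

    A single lineage accrues mutations from birth at the baseline daily
    rate, switches to the accelerated regime at the (drawn or given)
    acceleration age, duplicates at the divergence age, and both branches
    run to their sampling ages.  Shared = count at divergence; the branch
    totals minus shared give the private counts, so conservation is exact.
    Divergence may precede or follow the acceleration onset.
    """
    rng = np.random.default_rng(patient_seed)
    age_dx_years = (
        rng.uniform(*cfg.age_range) if age_dx_years is None else age_dx_years
    )
    interval = (
        rng.uniform(*cfg.relapse_interval_range)
        if relapse_interval is None
        else relapse_interval
    )
    t_accel = rng.uniform(*cfg.acceleration_time_range) if t_accel is None else t_accel
    t_div = rng.uniform(*cfg.divergence_time_range) if t_div is None else t_div
    rate = rng.uniform(*cfg.accelerated_rate_range) if rate_param is None else rate_param

    age_dx = int(round(age_dx_years * DAYS_PER_YEAR))
    age_rel = age_dx + int(round(interval))
    a_acc = age_dx - int(round(t_accel))
    a_div = age_dx - int(round(t_div))
    b = cfg.baseline_daily
    n0 = int(round(cfg.baseline_intercept))

    if cfg.acceleration_model == "constant":

        def advance(n, u, v):
            base_days = max(0, min(v, a_acc) - u) if u < a_acc else 0
            acc_days = max(0, v - max(u, a_acc))
            n += int(interval_increment(b, base_days, rng))
            n += int(interval_increment(rate, acc_days, rng))
            return n

    else:

        def advance(n, u, v):
            base_days = max(0, min(v, a_acc) - u) if u < a_acc else 0
            acc_days = max(0, v - max(u, a_acc))
            n += int(interval_increment(b, base_days, rng))
            return _linear_advance(n, acc_days, rate, rng)

    shared = advance(n0, 0, a_div)
    primary_total = advance(shared, a_div, age_dx)
    relapse_total = advance(shared, a_div, age_rel)

    counts = PatientClock(
        patient_id=patient_id,
        age_dx_days=float(age_dx),
        age_rel_days=float(age_rel),
        n_primary_private=primary_total - shared,
        n_shared=shared,
        n_relapse_private=relapse_total - shared,
    )
    return SyntheticPatient(
        patient_id=patient_id,
        age_dx=age_dx / DAYS_PER_YEAR,
        age_rel=age_rel / DAYS_PER_YEAR,
        true_t_accel=float(t_accel),
        true_t_div=float(t_div),
        true_rate_param=float(rate),
        counts=counts,
    )


def gen_blast_observations(
    a_true: float,
    n_patients: int,
    offset_sd: float,
    fraction_noise_sd: float,
    seed=None,
) -> list[BlastObservation]:
    """Two-timepoint logistic blast observations with annotation error.

    True measurement times straddle the 50% crossing; each patient's two
    annotated times share one Normal(0, offset_sd) error (the fitted
    Delta_t_i), and fractions are perturbed on the logit scale so they stay
    strictly inside (0, 1).
    """
    if a_true <= 0:
        raise ValueError("a_true must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for i in range(n_patients):
        t0 = rng.uniform(-80.0, -15.0)
        t1 = rng.uniform(15.0, 80.0)
        offset = rng.normal(0.0, offset_sd) if offset_sd > 0 else 0.0
        ys = []
        for t in (t0, t1):
            logit = a_true * t
            if fraction_noise_sd > 0:
                logit += rng.normal(0.0, fraction_noise_sd)
            ys.append(1.0 / (1.0 + np.exp(-logit)))
        out.append(
            BlastObservation(
                patient_id=f"SYN{i + 1}",
                t0=t0 + offset,
                t1=t1 + offset,
                y0=float(np.clip(ys[0], 1e-4, 1 - 1e-4)),
                y1=float(np.clip(ys[1], 1e-4, 1 - 1e-4)),
                true_offset=float(offset),
            )
        )
    return out


_BASES = ("A", "C", "G", "T")


def gen_mutation_table(
    purity: float,
    depth_mean: float,
    clonal_n: int,
    subclone_ccfs: Sequence[float] = (),
    subclone_ns: Sequence[int] = (),
    seed=None,
    patient_id: str = "SYN",
    sample: str = "primary",
    chrom: str = "1",
    start_pos: int = 1,
    cn: int = 2,
    signature: str = "SBS5",
) -> list[MutationRecord]:
    """Read-count table with a clonal peak plus optional subclones.

    Per mutation: depth ~ Poisson(depth_mean) and alt reads ~
    Binomial(depth, purity * CCF / CN).  Records carry the true clonality
    label.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    if len(subclone_ccfs) != len(subclone_ns):
        raise ValueError("subclone_ccfs and subclone_ns must align")
    for c in subclone_ccfs:
        if not 0 < c < 1:
            raise ValueError("subclone CCFs must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    records = []
    pos = start_pos
    groups = [(1.0, clonal_n, True)] + [
        (c, n, False) for c, n in zip(subclone_ccfs, subclone_ns)
    ]
    for ccf, n, is_clonal in groups:
        p = min(purity * ccf / cn, 1.0)
        for _ in range(int(n)):
            depth = int(rng.poisson(depth_mean))
            alt = int(rng.binomial(depth, p)) if depth > 0 else 0
            ref = _BASES[pos % 4]
            records.append(
                MutationRecord(
                    patient_id=patient_id,
                    sample=sample,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=_BASES[(pos + 1) % 4],
                    alt_reads=alt,
                    depth=depth,
                    cn=cn,
                    signature=signature,
                    true_clonal=is_clonal,
                )
            )
            pos += 1
    return records


def apply_true_clonality(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Set each record's clonality call from its generator ground truth."""
    out = []
    for r in records:
        if r.true_clonal is None:
            raise ValueError("record carries no ground-truth clonality")
        out.append(replace(r, clonality="clonal" if r.true_clonal else "subclonal"))
    return out


def _patient_mutations(
    p: SyntheticPatient, cfg: CohortConfig, rng: np.random.Generator
) -> tuple[list[MutationRecord], dict]:
    """Paired-sample read-count records realizing the patient's branch counts."""
    purities = {
        "primary": rng.uniform(*cfg.purity_range),
        "relapse": rng.uniform(*cfg.purity_range),
    }
    c = p.counts
    records: list[MutationRecord] = []
    pos = 1

    def emit(n, samples, signature, ccf=1.0, clonal=True):
        nonlocal pos
        for s in samples:
            sub_ccfs, sub_ns = ((), ()) if clonal else ((ccf,), (n,))
            records.extend(
                gen_mutation_table(
                    purities[s],
                    cfg.depth_mean,
                    n if clonal else 0,
                    sub_ccfs,
                    sub_ns,
                    seed=rng,
                    patient_id=p.patient_id,
                    sample=s,
                    start_pos=pos,
                    signature=signature,
                )
            )
        pos += n

    emit(c.n_shared, ("primary", "relapse"), "SBS5")
    emit(c.n_primary_private, ("primary",), "SBS5")
    emit(c.n_relapse_private, ("relapse",), "SBS5")
    emit(cfg.n_other_signature, ("primary", "relapse"), "SBS1")
    if cfg.n_subclonal:
        sub_ccf = rng.uniform(*cfg.subclone_ccf_range)
        emit(cfg.n_subclonal, ("primary",), "SBS5", ccf=sub_ccf, clonal=False)
        pos += cfg.n_subclonal
        emit(cfg.n_subclonal, ("relapse",), "SBS5", ccf=sub_ccf, clonal=False)
    return records, purities


def gen_cohort(cfg: CohortConfig) -> list[SyntheticPatient]:
    """Full synthetic cohort: branch counts, read tables, blast observations.

    Per-patient seeds are the cohort seed plus a fixed stride, so any
    patient can be regenerated in isolation.
    """
    patients = []
    blast_rng = np.random.default_rng(cfg.seed + _PATIENT_SEED_STRIDE * (cfg.n_patients + 1))
    blasts = gen_blast_observations(
        cfg.blast_a_true, cfg.n_patients, cfg.blast_offset_sd, cfg.blast_noise_sd, blast_rng
    )
    for i in range(cfg.n_patients):
        pid = f"SYN{i + 1}"
        seed_i = cfg.seed + _PATIENT_SEED_STRIDE * (i + 1)
        p = gen_patient_clock(cfg, seed_i, patient_id=pid)
        rng = np.random.default_rng(seed_i + 1)
        p.mutations, p.purity = _patient_mutations(p, cfg, rng)
        interval = p.counts.age_rel_days - p.counts.age_dx_days
        p.blast_obs = replace(
            blasts[i],
            patient_id=pid,
            biopsy_blast_frac=float(rng.uniform(0.5, 0.95)),
            delta_t_days=float(interval),
        )
        patients.append(p)
    return patients
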