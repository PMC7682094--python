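"""Molecular-clock timing of the primary/relapse clone divergence.

From the counts of clonal SBS5 (clock-like) mutations private to the primary
tumor, private to the relapse, and shared between them, this module
estimates how many days before diagnosis the relapse-founding lineage split
from the primary clone.

The healthy hematopoietic baseline accrues SBS5 mutations linearly with age
(~12 per year).  At some unknown time t_n before diagnosis the leukemic rate
accelerates, either as a one-off jump to a constant rate mu (constant model)
or as a per-day compounding increase r (linear model); the two models
bracket the family of multi-step acceleration histories.  For each candidate
acceleration time on a grid spanning the 10 years before diagnosis, the
accelerated rate is solved so that the mean curve passes through the average
of the primary and relapse mutation totals at the midpoint of the two
sampling ages.  Stochastic mutation curves (overdispersed daily Bernoulli
counts, see :mod:`tallevo.mutation_process`) then yield a simulation-based
likelihood for each hypothesis from the simulated count distributions at the
two sampling ages, a cohort-level posterior reweights the per-patient grids,
and the divergence time follows from inverting the mean curve at the shared
mutation count, averaged over the retained (top-likelihood) hypotheses.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clonality import MutationRecord
from .mutation_process import DAYS_PER_YEAR, baseline_count, day_increments, interval_increment

__all__ = [
    "PatientClock",
    "AccelerationHypothesis",
    "ClockConfig",
    "HypothesisGrid",
    "PatientEstimate",
    "count_branches",
    "fit_rate_regression",
    "solve_rate",
    "simulate_mutation_curve",
    "hypothesis_likelihood",
    "divergence_from_shared",
    "evaluate_patient_grid",
    "cohort_posterior",
    "estimate_patient",
    "estimate_cohort",
]

MODELS = ("constant", "linear")


@dataclass(frozen=True)
class PatientClock:
    """Signature-5 clonal branch counts and sampling ages for one patient."""

    patient_id: str
    age_dx_days: float
    age_rel_days: float
    n_primary_private: int
    n_shared: int
    n_relapse_private: int

    def __post_init__(self):
        if min(self.n_primary_private, self.n_shared, self.n_relapse_private) < 0:
            raise ValueError("branch counts must be non-negative")
        if self.age_rel_days <= self.age_dx_days:
            raise ValueError("relapse age must exceed diagnosis age")

    @property
    def primary_total(self) -> int:
        return self.n_shared + self.n_primary_private

    @property
    def relapse_total(self) -> int:
        return self.n_shared + self.n_relapse_private


@dataclass
class AccelerationHypothesis:
    """One (model, acceleration time) grid cell with its fitted rate."""

    model: str
    t_accel: float  # days before diagnosis
    rate_param: float  # mu (mutations/day) or r (per-day growth)
    likelihood: float = np.nan
    divergence_days: float = np.nan
    feasible: bool = True


@dataclass(frozen=True)
class ClockConfig:
    """Grid, simulation, and pooling settings for the divergence clock."""

    n_grid: int = 120
    window_years: float = 10.0
    n_sims: int = 100
    rho: float = 2e-4
    baseline_slope: float = 12.21  # SBS5 mutations / year in healthy blood
    baseline_intercept: float = 0.0
    percentile_keep: float = 0.10
    pooling: str = "geometric"  # or "arithmetic"
    cohort_reweight: bool = True
    min_bandwidth: float = 0.5

    def __post_init__(self):
        if self.n_sims < 2:
            raise ValueError("need at least 2 simulated curves")
        if not 0 < self.percentile_keep <= 1:
            raise ValueError("percentile_keep must be in (0, 1]")
        if self.pooling not in ("geometric", "arithmetic"):
            raise ValueError("pooling must be 'geometric' or 'arithmetic'")

    @property
    def window_days(self) -> float:
        return self.window_years * DAYS_PER_YEAR

    @property
    def baseline_daily(self) -> float:
        return self.baseline_slope / DAYS_PER_YEAR

    def baseline(self, age_days):
        return baseline_count(age_days, self.baseline_slope, self.baseline_intercept)


# ---------------------------------------------------------------------------
# branch counting and the rate regression
# ---------------------------------------------------------------------------


def count_branches(
    records: Sequence[MutationRecord],
    age_dx_days: float,
    age_rel_days: float,
    signature: str = "SBS5",
    patient_id: str | None = None,
) -> PatientClock:
    """Count clonal, signature-matched mutations private to each sample or shared.

    Mutations are matched across samples by (chrom, pos, ref, alt).  Raises
    if either the primary or the relapse sample is absent.
    """
    by_sample: dict[str, set] = {"primary": set(), "relapse": set()}
    pid = patient_id
    for r in records:
        if pid is None:
            pid = r.patient_id
        if r.sample not in by_sample:
            continue
        if r.clonality == "clonal" and r.signature == signature:
            by_sample[r.sample].add(r.locus)
    samples_present = {r.sample for r in records}
    for needed in ("primary", "relapse"):
        if needed not in samples_present:
            raise ValueError(f"patient {pid!r} lacks a {needed} sample")
    shared = by_sample["primary"] & by_sample["relapse"]
    return PatientClock(
        patient_id=pid or "",
        age_dx_days=age_dx_days,
        age_rel_days=age_rel_days,
        n_primary_private=len(by_sample["primary"] - shared),
        n_shared=len(shared),
        n_relapse_private=len(by_sample["relapse"] - shared),
    )


@dataclass(frozen=True)
class RateRegression:
    slope: float
    intercept: float
    pearson_r: float
    slope_se: float
    intercept_se: float


def fit_rate_regression(ages_years, counts) -> RateRegression:
    """OLS of signature-5 burden on age, with standard errors on both terms."""
    ages = np.asarray(ages_years, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(ages) < 3:
        raise ValueError("need at least 3 points for the rate regression")
    if np.ptp(ages) < 1e-12:
        raise ValueError("ages are constant; regression is degenerate")
    res = stats.linregress(ages, counts)
    return RateRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


# ---------------------------------------------------------------------------
# per-hypothesis rate, curve simulation, likelihood, divergence
# ---------------------------------------------------------------------------


def solve_rate(
    model: str, t_accel: float, clock: PatientClock, cfg: ClockConfig
) -> tuple[float, bool]:
    """Accelerated rate that carries the mean curve through N(t*).

    t* is the midpoint of the two sampling ages and N(t*) the mean of the
    two observed totals.  Returns (rate, feasible); a hypothesis is
    infeasible when it implies a mutation-rate decrease (the leukemic rate
    can only exceed the healthy baseline).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    t_star = 0.5 * (clock.age_dx_days + clock.age_rel_days)
    n_star = 0.5 * (clock.primary_total + clock.relapse_total)
    t_n_age = clock.age_dx_days - t_accel
    n_n = float(cfg.baseline(t_n_age))
    dt = t_star - t_n_age
    if dt <= 0:
        return np.nan, False
    if model == "constant":
        mu = (n_star - n_n) / dt
        return mu, bool(mu >= max(cfg.baseline_daily, 1e-12))
    if n_n <= 0 or n_star <= 0:
        return np.nan, False
    r = (n_star / n_n) ** (1.0 / dt) - 1.0
    feasible = r > 0 and np.log1p(r) * n_n >= cfg.baseline_daily
    return r, bool(feasible)


def simulate_mutation_curve(
    model: str,
    rate_param: float,
    horizon_days: int,
    cfg: ClockConfig,
    seed=None,
    start_count: int = 0,
) -> np.ndarray:
    """One stochastic cumulative mutation curve sampled day by day.

    Returns an integer array of length ``horizon_days + 1`` starting at
    ``start_count``.  Constant model: daily mean ``rate_param``; linear
    model: daily mean ``log(1 + r) * N(previous day)``.  Days whose mean
    exceeds one are split into equal Bernoulli substeps.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    traj = np.empty(horizon_days + 1, dtype=np.int64)
    traj[0] = start_count
    n = start_count
    if model == "constant":
        if rate_param > 0:
            inc = day_increments(np.full(horizon_days, float(rate_param)), rng)
            traj[1:] = start_count + np.cumsum(inc)
        else:
            traj[1:] = start_count
        return traj
    g = np.log1p(rate_param)
    for d in range(1, horizon_days + 1):
        mean = g * n
        if mean > 0:
            n += int(day_increments(np.array([mean]), rng)[0])
        traj[d] = n
    return traj


def _simulate_counts_constant(
    mu: float, t_accel: float, clock: PatientClock, cfg: ClockConfig, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of n_sims constant-model curves at the two sampling ages."""
    t_n_age = clock.age_dx_days - t_accel
    n0 = int(round(cfg.baseline(t_n_age)))
    d1 = max(int(round(t_accel)), 0)
    d2 = max(int(round(clock.age_rel_days - clock.age_dx_days)), 0)
    prim = n0 + interval_increment(mu, d1, rng, size=cfg.n_sims)
    rel = prim + interval_increment(mu, d2, rng, size=cfg.n_sims)
    return prim, rel


def _simulate_counts_linear_grid(
    rates: np.ndarray,
    t_accels: np.ndarray,
    clock: PatientClock,
    cfg: ClockConfig,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized linear-model curves for a whole grid of hypotheses.

    Returns arrays of shape (n_hyp, n_sims) with the counts at the
    diagnosis and relapse ages.  Hypotheses activate at their own start day;
    inactive rows have zero mean and therefore zero increments.
    """
    n_h = len(rates)
    start_age = np.round(clock.age_dx_days - t_accels).astype(np.int64)
    age_dx = int(round(clock.age_dx_days))
    age_rel = int(round(clock.age_rel_days))
    n0 = np.round(cfg.baseline(start_age)).astype(np.int64)
    g = np.log1p(rates)[:, None]
    n = np.repeat(n0[:, None], cfg.n_sims, axis=1).astype(np.int64)
    prim = n.copy()  # correct when no simulated day precedes the diagnosis age
    first = int(start_age.min()) if n_h else age_dx
    active = np.zeros((n_h, 1), dtype=bool)
    for day in range(first + 1, age_rel + 1):
        active[:, 0] = start_age < day
        mean = np.where(active, g * n, 0.0)
        m = np.maximum(np.ceil(mean).astype(np.int64), 1)
        n = n + rng.binomial(m, mean / m)
        if day == age_dx:
            prim = n.copy()
    return prim, n


def _kde_density(samples: np.ndarray, x: float, min_bw: float) -> float:
    """Gaussian KDE (Silverman bandwidth, floored) evaluated at one point."""
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    sd = samples.std()
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    a = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = max(0.9 * a * n ** (-0.2), min_bw)
    z = (x - samples) / h
    return float(np.mean(np.exp(-0.5 * z * z)) / (h * np.sqrt(2 * np.pi)))


def hypothesis_likelihood(
    hyp: AccelerationHypothesis, clock: PatientClock, cfg: ClockConfig, seed=None
) -> float:
    """Simulation-based likelihood of one hypothesis.

    n_sims stochastic curves are run through both sampling ages; the
    likelihood is the product of the kernel-smoothed densities of the
    simulated counts evaluated at the observed primary and relapse totals.
    """
    if not hyp.feasible:
        return 0.0
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if hyp.model == "constant":
        prim, rel = _simulate_counts_constant(hyp.rate_param, hyp.t_accel, clock, cfg, rng)
    else:
        prim, rel = _simulate_counts_linear_grid(
            np.array([hyp.rate_param]), np.array([hyp.t_accel]), clock, cfg, rng
        )
        prim, rel = prim[0], rel[0]
    lp = _kde_density(prim, clock.primary_total, cfg.min_bandwidth)
    lr = _kde_density(rel, clock.relapse_total, cfg.min_bandwidth)
    return lp * lr


def divergence_from_shared(
    model: str, t_accel: float, rate_param: float, clock: PatientClock, cfg: ClockConfig
) -> float:
    """Days before diagnosis at which the mean curve reaches the shared count.

    Inverts the deterministic mean mutation curve (baseline line up to the
    acceleration age, accelerated segment after) at n_shared; clipped to
    [0, age at diagnosis].
    """
    if clock.n_shared >= clock.primary_total:
        return 0.0
    t_n_age = clock.age_dx_days - t_accel
    n_n = float(cfg.baseline(t_n_age))
    s = float(clock.n_shared)
    if s <= n_n:
        b = cfg.baseline_daily
        age_div = (s - cfg.baseline_intercept) / b if b > 0 else 0.0
    elif model == "constant":
        age_div = t_n_age + (s - n_n) / rate_param
    else:
        age_div = t_n_age + np.log(s / n_n) / np.log1p(rate_param)
    return float(np.clip(clock.age_dx_days - age_div, 0.0, clock.age_dx_days))


# ---------------------------------------------------------------------------
# grid evaluation and cohort pooling
# ---------------------------------------------------------------------------


@dataclass
class HypothesisGrid:
    """Aligned per-hypothesis arrays for one patient's full grid."""

    patient_id: str
    model: np.ndarray  # str array
    t_accel: np.ndarray
    rate: np.ndarray
    feasible: np.ndarray
    likelihood: np.ndarray
    divergence_days: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "model": self.model,
                "t_accel_days": self.t_accel,
                "rate_param": self.rate,
                "feasible": self.feasible,
                "likelihood": self.likelihood,
                "divergence_days": self.divergence_days,
            }
        )


def evaluate_patient_grid(
    clock: PatientClock, cfg: ClockConfig, seed=None
) -> HypothesisGrid:
    """Likelihood and implied divergence for every (model, t_accel) cell.

    The grid has ``n_grid`` acceleration times, evenly spaced and inclusive
    of both ends of the 10-year window, for each of the two models.
    Infeasible cells keep likelihood 0 so grids stay aligned across
    patients.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t_grid = np.linspace(0.0, cfg.window_days, cfg.n_grid)
    models, t_acc, rates, feas, like, div = [], [], [], [], [], []

    for model in MODELS:
        r_arr = np.empty(cfg.n_grid)
        f_arr = np.zeros(cfg.n_grid, dtype=bool)
        for j, t_a in enumerate(t_grid):
            r_arr[j], f_arr[j] = solve_rate(model, t_a, clock, cfg)
        lik = np.zeros(cfg.n_grid)
        if model == "constant":
            for j in np.flatnonzero(f_arr):
                prim, rel = _simulate_counts_constant(r_arr[j], t_grid[j], clock, cfg, rng)
                lik[j] = _kde_density(prim, clock.primary_total, cfg.min_bandwidth) * \
                    _kde_density(rel, clock.relapse_total, cfg.min_bandwidth)
        else:
            idx = np.flatnonzero(f_arr)
            if idx.size:
                prim, rel = _simulate_counts_linear_grid(
                    r_arr[idx], t_grid[idx], clock, cfg, rng
                )
                for k, j in enumerate(idx):
                    lik[j] = _kde_density(prim[k], clock.primary_total, cfg.min_bandwidth) * \
                        _kde_density(rel[k], clock.relapse_total, cfg.min_bandwidth)
        d_arr = np.full(cfg.n_grid, np.nan)
        for j in np.flatnonzero(f_arr):
            d_arr[j] = divergence_from_shared(model, t_grid[j], r_arr[j], clock, cfg)
        models.append(np.full(cfg.n_grid, model, dtype=object))
        t_acc.append(t_grid)
        rates.append(r_arr)
        feas.append(f_arr)
        like.append(lik)
        div.append(d_arr)

    return HypothesisGrid(
        patient_id=clock.patient_id,
        model=np.concatenate(models),
        t_accel=np.concatenate(t_acc),
        rate=np.concatenate(rates),
        feasible=np.concatenate(feas),
        likelihood=np.concatenate(like),
        divergence_days=np.concatenate(div),
    )


def cohort_posterior(grids: Sequence[HypothesisGrid], cfg: ClockConfig) -> np.ndarray:
    """Posterior weight of each grid cell pooled across the cohort.

    Uniform prior times the geometric mean (default) of the per-patient
    normalized likelihood profiles, computed in log space; cells that are
    impossible for any patient get vanishing weight.
    """
    if not grids:
        raise ValueError("cohort_posterior needs at least one patient grid")
    logs = []
    for g in grids:
        tot = g.likelihood.sum()
        if tot <= 0:
            raise ValueError(f"patient {g.patient_id!r}: all hypotheses have zero likelihood")
        norm = g.likelihood / tot
        logs.append(np.log(np.maximum(norm, 1e-300)))
    if cfg.pooling == "geometric":
        pooled = np.exp(np.mean(logs, axis=0))
    else:
        pooled = np.mean(np.exp(logs), axis=0)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("cohort posterior is identically zero")
    return pooled / total


@dataclass
class PatientEstimate:
    patient_id: str
    divergence_days: float
    divergence_by_model: dict
    n_retained: int
    weights_sum: float


def estimate_patient(
    grid: HypothesisGrid, cfg: ClockConfig, posterior: np.ndarray | None = None
) -> PatientEstimate:
    """Weighted divergence estimate over the retained top-likelihood cells.

    Weights are the per-patient likelihoods, optionally multiplied by the
    cohort posterior; only the top ``percentile_keep`` fraction of
    positive-weight hypotheses is retained before the weighted mean, which
    guards against a long tail of poorly fitting scenarios.
    """
    w = grid.likelihood.copy()
    if posterior is not None:
        w = w * posterior
    w[~grid.feasible] = 0.0
    pos = np.flatnonzero(w > 0)
    if pos.size == 0:
        raise ValueError(f"patient {grid.patient_id!r}: no hypothesis has positive weight")
    k = max(int(np.ceil(cfg.percentile_keep * pos.size)), 1)
    retained = pos[np.argsort(w[pos])[::-1][:k]]
    est = float(np.average(grid.divergence_days[retained], weights=w[retained]))

    by_model = {}
    for model in MODELS:
        sel = retained[grid.model[retained] == model]
        if sel.size:
            by_model[model] = float(
                np.average(grid.divergence_days[sel], weights=w[sel])
            )
        else:
            by_model[model] = np.nan
    return PatientEstimate(
        patient_id=grid.patient_id,
        divergence_days=est,
        divergence_by_model=by_model,
        n_retained=int(k),
        weights_sum=float(w[retained].sum()),
    )


def estimate_cohort(
    clocks: Sequence[PatientClock], cfg: ClockConfig, seed=None
) -> tuple[pd.DataFrame, np.ndarray | None, list[HypothesisGrid]]:
    """Full cohort run: grids, posterior pooling, per-patient estimates.

    Per-patient randomness derives from ``seed`` and the patient id (via
    CRC32), so results are invariant to patient ordering.
    """
    base = seed if isinstance(seed, int) else 0
    grids = [
        evaluate_patient_grid(
            c,
            cfg,
            np.random.default_rng(
                np.random.SeedSequence([base, zlib.crc32(c.patient_id.encode())])
            ),
        )
        for c in clocks
    ]
    posterior = cohort_posterior(grids, cfg) if cfg.cohort_reweight else None
    rows = []
    for g in grids:
        e = estimate_patient(g, cfg, posterior)
        rows.append(
            {
                "patient_id": e.patient_id,
                "divergence_days": e.divergence_days,
                "divergence_constant": e.divergence_by_model["constant"],
                "divergence_linear": e.divergence_by_model["linear"],
                "n_retained": e.n_retained,
            }
        )
    return pd.DataFrame(rows), posterior, grids
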