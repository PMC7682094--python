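"""Clock-like somatic mutation accumulation.

Shared machinery for the synthetic cohort generator and the divergence-clock
inference: SBS5-like mutations accrue day by day as overdispersed Bernoulli
counts.  The daily increment is beta-binomial with a given mean and
intra-class correlation ``rho``; with one trial per step this reduces exactly
to a Bernoulli draw with the given mean, and a day whose mean rate exceeds 1
is split into ``ceil(mean)`` equal substeps (equivalently one binomial draw).
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365.25


def betabinom_params(mean_per_trial: float, rho: float) -> tuple[float, float]:
    """Map (mean success probability, intra-class correlation) to (alpha, beta).

    Uses the standard correspondence rho = 1 / (alpha + beta + 1).
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    if not 0 <= mean_per_trial <= 1:
        raise ValueError("mean per trial must be in [0, 1]")
    s = 1.0 / rho - 1.0
    return mean_per_trial * s, (1.0 - mean_per_trial) * s


def betabinom_rvs(
    mean: float, rho: float, n_trials: int, size, rng: np.random.Generator
) -> np.ndarray:
    """Sample beta-binomial counts with ``n_trials`` trials and total mean
    ``mean`` (so the per-trial success probability is ``mean / n_trials``)."""
    p = mean / n_trials
    if n_trials == 1:
        # single trial: the beta mixture integrates out exactly
        return (rng.random(size) < p).astype(np.int64)
    a, b = betabinom_params(p, rho)
    probs = rng.beta(a, b, size=size)
    return rng.binomial(n_trials, probs)


def day_increments(means, rng: np.random.Generator) -> np.ndarray:
    """One day's mutation-count increment for an array of daily mean rates.

    Each day is ``ceil(mean)`` Bernoulli substeps of equal mean (a single
    substep when mean <= 1), i.e. a Binomial(ceil(mean), mean/ceil(mean))
    draw — the exact distribution of the single-trial beta-binomial scheme.
    """
    means = np.asarray(means, dtype=float)
    m = np.maximum(np.ceil(means).astype(np.int64), 1)
    return rng.binomial(m, means / m)


def interval_increment(mean_per_day: float, n_days: int, rng: np.random.Generator, size=None):
    """Total increment over ``n_days`` at a constant daily mean rate.

    Sum of i.i.d. daily increments; with the substep scheme this is exactly
    Binomial(n_days * ceil(mean), mean / ceil(mean)).
    """
    if n_days <= 0 or mean_per_day <= 0:
        return np.zeros(() if size is None else size, dtype=np.int64)
    m = max(int(np.ceil(mean_per_day)), 1)
    return rng.binomial(n_days * m, mean_per_day / m, size=size)


def baseline_count(age_days, slope_per_year: float, intercept: float = 0.0):
    """Deterministic healthy-hematopoiesis SBS5 burden at a given age."""
    return intercept + (slope_per_year / DAYS_PER_YEAR) * np.asarray(age_days, dtype=float)
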