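"""Sample purity, cancer cell fractions, and clonal/subclonal calls.

Purity is read off the variant-allele-frequency distribution: for a mostly
diploid tumor, VAF x copy-number is a rough proxy of the cancer cell
fraction (CCF), and the mode of its kernel density estimate is the purity.
CCFs are then recomputed as VAF x CN / purity, and each mutation is tested
against a beta-binomial model of the clonal read-count peak: mutations whose
lower-tail probability under the clonal model falls below a threshold
(default 0.01) are called subclonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MutationRecord",
    "PuritatedSample",
    "estimate_purity",
    "assign_ccf",
    "classify_clonality",
]

MIN_RECORDS_FOR_PURITY = 30


@dataclass
class MutationRecord:
    """One somatic mutation in one sample."""

    patient_id: str
    sample: str  # "primary" or "relapse"
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    depth: int
    cn: int = 2
    ccf: float | None = None
    clonality: str = "unset"  # "clonal" | "subclonal" | "unset"
    signature: str = "SBS5"
    true_clonal: bool | None = None  # generator ground truth, if synthetic

    def __post_init__(self):
        if self.depth < 0 or self.alt_reads < 0 or self.alt_reads > self.depth:
            raise ValueError(
                f"invalid read counts at {self.chrom}:{self.pos}: "
                f"alt_reads={self.alt_reads}, depth={self.depth}"
            )
        if self.cn < 0:
            raise ValueError("copy number must be >= 0")

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else float("nan")

    @property
    def locus(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PuritatedSample:
    """Purity estimate plus the fitted clonal-peak beta-binomial."""

    purity: float
    betabinom_params: tuple[float, float]  # (mean VAF, overdispersion rho)
    clonality_threshold: float = 0.01

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if not 0 < self.clonality_threshold < 1:
            raise ValueError("clonality threshold must be in (0, 1)")


def _vaf_cn(records: Sequence[MutationRecord]) -> np.ndarray:
    vals = [r.vaf * r.cn for r in records if r.depth > 0]
    return np.asarray(vals, dtype=float)


def estimate_purity(
    records: Sequence[MutationRecord],
    mode_window: tuple[float, float] = (0.1, 1.1),
) -> float:
    """Purity as the KDE mode of VAF x CN, searched in ``mode_window``.

    The window excludes the subclonal shoulder below 0.1; Silverman's rule
    sets the bandwidth.  Requires at least 30 covered records.
    """
    x = _vaf_cn(records)
    if len(x) < MIN_RECORDS_FOR_PURITY:
        raise ValueError(
            f"need >= {MIN_RECORDS_FOR_PURITY} covered mutations to estimate "
            f"purity, got {len(x)}"
        )
    if np.ptp(x) < 1e-12:
        return float(min(max(x[0], 1e-6), 1.0))
    kde = stats.gaussian_kde(x, bw_method="silverman")
    lo, hi = mode_window
    grid = np.linspace(lo + 1e-9, hi, 512)
    mode = grid[np.argmax(kde(grid))]
    return float(min(max(mode, 1e-6), 1.0))


def assign_ccf(records: Iterable[MutationRecord], purity: float) -> list[MutationRecord]:
    """CCF = VAF x CN / purity, clipped to [0, 2]; zero-depth records stay unset."""
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    out = []
    for r in records:
        if r.depth > 0:
            ccf = float(np.clip(r.vaf * r.cn / purity, 0.0, 2.0))
        else:
            ccf = None
        out.append(replace(r, ccf=ccf))
    return out


def fit_clonal_betabinom(
    records: Sequence[MutationRecord], purity: float, peak_halfwidth: float = 0.1
) -> tuple[float, float]:
    """Method-of-moments beta-binomial fit to the clonal read-count peak.

    Fits (mean VAF, overdispersion rho) on mutations whose VAF x CN lies
    within ``peak_halfwidth`` of the purity mode.
    """
    peak = [
        r for r in records if r.depth > 0 and abs(r.vaf * r.cn - purity) <= peak_halfwidth
    ]
    if not peak:
        raise ValueError("clonal peak is empty; cannot fit the clonal model")
    alt = np.array([r.alt_reads for r in peak], dtype=float)
    dep = np.array([r.depth for r in peak], dtype=float)
    m = alt.sum() / dep.sum()
    p_i = alt / dep
    var_obs = float(np.mean((p_i - m) ** 2))
    nbar = float(np.mean(dep))
    if m <= 0 or m >= 1 or nbar <= 1:
        return float(np.clip(m, 1e-6, 1 - 1e-6)), 1e-6
    rho = (var_obs * nbar / (m * (1 - m)) - 1.0) / (nbar - 1.0)
    rho = float(np.clip(rho, 1e-6, 0.5))
    return float(m), rho


def classify_clonality(
    records: Sequence[MutationRecord],
    purity: float,
    threshold: float = 0.01,
) -> tuple[list[MutationRecord], PuritatedSample]:
    """Call each mutation clonal or subclonal against the clonal peak model.

    For every covered mutation the one-sided lower-tail probability
    P(X <= alt_reads) under BetaBinom(depth, mean, rho) is computed;
    mutations with tail probability >= ``threshold`` are clonal (they have
    enough alt reads to be consistent with the clonal peak), others
    subclonal.  Subclonality here means too *few* alt reads; the sidedness
    choice is deliberate and configurable via the returned parameters.
    """
    m, rho = fit_clonal_betabinom(records, purity)
    s = 1.0 / rho - 1.0
    a, b = m * s, (1.0 - m) * s
    out = []
    for r in records:
        if r.depth <= 0:
            out.append(replace(r, clonality="unset"))
            continue
        tail = float(stats.betabinom.cdf(r.alt_reads, r.depth, a, b))
        call = "clonal" if tail >= threshold else "subclonal"
        out.append(replace(r, clonality=call))
    sample = PuritatedSample(
        purity=purity, betabinom_params=(m, rho), clonality_threshold=threshold
    )
    return out, sample


def annotate(
    records: Sequence[MutationRecord], threshold: float = 0.01
) -> tuple[list[MutationRecord], PuritatedSample]:
    """Full pass for one sample: purity -> CCF -> clonality calls."""
    purity = estimate_purity(records)
    with_ccf = assign_ccf(records, purity)
    return classify_clonality(with_ccf, purity, threshold)
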