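"""Bootstrap variance of the period and per-motif period tests.

Spacings are striped round-robin into subsets as they are discovered (so
each subset samples the whole region analyzed); a bootstrap iterate draws
subsets with replacement, rebuilds the histogram, and refits the period.
The spread of refitted periods estimates the variance of the genuine
period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .motifscan import MAX_SPACING, SmoothedSeries, SpacingHistogram, smooth
from .periodfit import (
    DEFAULT_PERIOD_RANGE,
    autocorrelate,
    fit_at_fixed_period,
    fit_damped_sine,
)

DEFAULT_N_SUBSETS = 1000
DEFAULT_N_BOOT = 1000


@dataclass
class BootstrapDistribution:
    periods: np.ndarray
    n_subsets: int
    n_iter: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_iter = len(self.periods)

    @property
    def mean(self) -> float:
        return float(np.mean(self.periods))

    @property
    def sd(self) -> float:
        return float(np.std(self.periods, ddof=1))


def partition_spacings(
    spacings: Sequence[int] | Iterable[int],
    k: int = DEFAULT_N_SUBSETS,
    max_spacing: int = MAX_SPACING,
) -> SpacingHistogram:
    """Round-robin partition of a spacing stream (in discovery order) into
    ``k`` sub-histograms.  Subset totals differ by at most one."""
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(list(spacings), dtype=np.int64)
    if d.size and (d.min() < 1 or d.max() > max_spacing):
        raise ValueError(f"spacings must lie in 1..{max_spacing}")
    raw = np.bincount(d, minlength=max_spacing + 1)
    sub = np.arange(d.size, dtype=np.int64) % k
    subsets = np.bincount(
        sub * (max_spacing + 1) + d, minlength=k * (max_spacing + 1)
    ).reshape(k, max_spacing + 1)
    return SpacingHistogram(raw.astype(np.int64), subsets.astype(np.int64))


def bootstrap_period(
    h: SpacingHistogram,
    n_iter: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator = 0,
    lam_range: tuple[float, float] = DEFAULT_PERIOD_RANGE,
    fixed_period: float | None = None,
) -> BootstrapDistribution:
    """Bootstrap the fitted period by resampling subsets with replacement.

    Each iterate draws k subsets with replacement, sums their histograms,
    smooths, autocorrelates and refits; the fitted periods form the
    bootstrap distribution.
    """
    if h.subset_counts is None:
        raise ValueError("histogram has no subset partition; collate with n_subsets")
    subsets = h.subset_counts
    k = subsets.shape[0]
    if subsets.sum() == 0:
        raise ValueError("empty subsets; nothing to resample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    periods = np.empty(n_iter, dtype=float)
    for i in range(n_iter):
        mult = np.bincount(rng.integers(0, k, size=k), minlength=k)
        raw = mult @ subsets
        series = smooth(SpacingHistogram(raw))
        ac = autocorrelate(series)
        if fixed_period is not None:
            periods[i] = fit_at_fixed_period(ac, fixed_period).lambda_bp
        else:
            periods[i] = fit_damped_sine(ac, lam_range).lambda_bp
    return BootstrapDistribution(periods=periods, n_subsets=k)


def period_vs_genomic_test(
    motif_boot: BootstrapDistribution, genomic_boot: BootstrapDistribution
) -> float:
    """Welch two-sample t-test of a motif's bootstrap periods against the
    genomic-period bootstrap.  Returns the two-sided p-value."""
    a, b = motif_boot.periods, genomic_boot.periods
    if a.size == 0 or b.size == 0:
        raise ValueError("empty bootstrap distribution")
    if np.std(a) == 0 and np.std(b) == 0:
        if np.mean(a) == np.mean(b):
            return 1.0
        raise ValueError("both distributions have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(min(max(res.pvalue, np.nextafter(0, 1)), 1.0))


def normalized_period_ks(
    periods: Sequence[float],
    sds: Sequence[float],
    genomic_period: float,
) -> float:
    """KS normality test of variance-normalized motif periods.

    Each robustly periodic motif's period is standardized as
    (lambda_i - lambda_genomic) / sd_i and the set is compared against the
    standard normal (fully specified; the normalization already fixes the
    location and scale).  Returns the KS p-value.
    """
    lam = np.asarray(periods, dtype=float)
    sd = np.asarray(sds, dtype=float)
    if lam.size < 5:
        raise ValueError("need at least 5 robustly periodic motifs")
    if np.any(sd <= 0):
        raise ValueError("all period standard deviations must be positive")
    z = (lam - genomic_period) / sd
    if np.ptp(z) == 0:
        raise ValueError("all normalized periods identical; untestable")
    return float(stats.kstest(z, "norm").pvalue)
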