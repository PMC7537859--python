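"""Cross-genome comparison of periodicity profiles.

A genome's profile is the vector of goodness-of-fit / amplitude / strength
values over the 55 palindromic or complement-paired dinucleotide sets,
each fitted at the genomic period.  Profiles are compared by Pearson
correlation of their GdF vectors and by orthogonal (Deming) regression;
periods are compared by absolute difference; and per-set periodicity
frequencies across taxa are estimated by resampling one genome per taxon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motifscan import (
    MAX_SPACING,
    GenomeRecord,
    MotifSet,
    build_motif_sets,
    class_pair_counts,
    enumerate_patterns,
    histogram_from_class_counts,
    smooth,
)
from .periodfit import (
    DEFAULT_PERIOD_RANGE,
    DampedSineFit,
    autocorrelate,
    fit_at_fixed_period,
    fit_damped_sine,
    is_significant,
)

PROFILE_COLUMNS = ["gdf", "amplitude", "strength", "significant"]


@dataclass
class GdfProfile:
    """Per-genome periodicity profile over the 55 motif sets."""

    genome_id: str
    genomic_period: float
    genomic_fit: DampedSineFit
    table: pd.DataFrame  # index: set label; columns: gdf, amplitude, strength, significant

    @property
    def gdf(self) -> np.ndarray:
        return self.table["gdf"].to_numpy(dtype=float)

    @property
    def significant(self) -> np.ndarray:
        return self.table["significant"].to_numpy(dtype=bool)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def build_profile(
    genome: GenomeRecord,
    genomic_fit: DampedSineFit | None = None,
    lam_range: tuple[float, float] = DEFAULT_PERIOD_RANGE,
    max_spacing: int = MAX_SPACING,
) -> GdfProfile:
    """Fit all 55 motif sets at the genomic period.

    The genomic period comes from a free fit to the pooled histogram of all
    100 patterns (or from ``genomic_fit`` if already computed); each set's
    pooled member histogram is then fitted with the period held there.
    Sets with too little signal to autocorrelate get NaN entries.
    """
    cls = genome.dinucleotide_classes()
    counts = class_pair_counts(cls, max_spacing)
    if genomic_fit is None:
        pooled = histogram_from_class_counts(counts, enumerate_patterns())
        genomic_fit = fit_damped_sine(autocorrelate(smooth(pooled)), lam_range)
    rows = []
    labels = []
    for mset in build_motif_sets():
        h = histogram_from_class_counts(counts, mset.members)
        try:
            ac = autocorrelate(smooth(h))
            fit = fit_at_fixed_period(ac, genomic_fit.lambda_bp)
            rows.append(
                (fit.gdf, fit.amplitude, fit.strength, is_significant(fit.gdf))
            )
        except ValueError:
            rows.append((np.nan, np.nan, np.nan, False))
        labels.append(mset.label)
    table = pd.DataFrame(rows, index=labels, columns=PROFILE_COLUMNS)
    return GdfProfile(
        genome_id=genome.id,
        genomic_period=genomic_fit.lambda_bp,
        genomic_fit=genomic_fit,
        table=table,
    )


def correlate_profiles(a: GdfProfile, b: GdfProfile) -> float:
    """Pearson correlation of two genomes' 55 GdF values."""
    if not a.table.index.equals(b.table.index):
        raise ValueError("profiles have different motif-set orderings")
    x, y = a.gdf, b.gdf
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a profile; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def deming_fit(
    xs: np.ndarray, ys: np.ndarray, delta: float = 1.0
) -> tuple[float, float]:
    """Orthogonal (Deming, error-variance ratio delta) regression slope and
    intercept, by the standard closed form."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxx == 0 and syy == 0:
        raise ValueError("degenerate input: no variance on either axis")
    if sxy == 0:
        raise ValueError("zero covariance; Deming slope undefined")
    slope = (
        syy - delta * sxx + np.sqrt((syy - delta * sxx) ** 2 + 4 * delta * sxy**2)
    ) / (2 * sxy)
    intercept = np.mean(y) - slope * np.mean(x)
    return float(slope), float(intercept)


def period_difference(fit_a: DampedSineFit, fit_b: DampedSineFit) -> float:
    """|delta lambda| between two genomes' significant genomic fits."""
    for fit in (fit_a, fit_b):
        if not is_significant(fit.gdf):
            raise ValueError(
                f"fit with GdF {fit.gdf:.3f} is not significant; excluded from "
                "pairwise period comparison"
            )
    return abs(fit_a.lambda_bp - fit_b.lambda_bp)


def summarize_differences(values: np.ndarray) -> tuple[float, float, float]:
    """Median plus the medians of values below and above it (the error-bar
    convention used for relatedness-class summaries)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("no values to summarize")
    med = float(np.median(v))
    lower = v[v < med]
    upper = v[v > med]
    lo = float(np.median(lower)) if lower.size else med
    hi = float(np.median(upper)) if upper.size else med
    return med, lo, hi


def periodic_fraction_by_taxon(
    profiles: list[GdfProfile],
    taxa: pd.DataFrame,
    rank: str,
    n_iter: int = 1500,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Mean +- sd percentage of taxa in which each motif set is periodic.

    Per iteration one genome is drawn uniformly from each taxon at ``rank``
    (guarding against oversampled genera/families); the per-set fraction of
    drawn genomes with a significant fit is recorded.  Returns a DataFrame
    indexed by set label with columns ``mean_pct`` and ``sd_pct``.
    """
    if taxa.empty:
        raise ValueError("empty taxon table")
    if rank not in taxa.columns:
        raise ValueError(f"rank {rank!r} not in taxon table columns")
    by_id = {p.genome_id: p for p in profiles}
    missing = [g for g in by_id if g not in taxa.index]
    if missing:
        raise ValueError(f"genomes missing from taxon table: {missing}")
    labels = profiles[0].table.index
    flags = np.vstack([p.significant for p in profiles])  # genomes x 55
    ids = list(by_id)
    groups = [
        [ids.index(g) for g in members]
        for _, members in taxa.loc[ids].groupby(rank, observed=True).groups.items()
    ]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fracs = np.empty((n_iter, flags.shape[1]), dtype=float)
    for i in range(n_iter):
        chosen = [grp[rng.integers(0, len(grp))] for grp in groups]
        fracs[i] = flags[chosen].mean(axis=0) * 100.0
    return pd.DataFrame(
        {"mean_pct": fracs.mean(axis=0), "sd_pct": fracs.std(axis=0, ddof=1)},
        index=labels,
    )


def match_gc_differences(
    pairs: pd.DataFrame,
    class_col: str = "relatedness",
    gc_col: str = "delta_gc",
    bin_width: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Resample pairwise comparisons so every relatedness class has the same
    distribution of GC-content differences (histogram matching with
    ``bin_width``-wide bins)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bins = np.floor(pairs[gc_col].to_numpy(dtype=float) / bin_width).astype(int)
    pairs = pairs.assign(_gc_bin=bins)
    counts = pairs.groupby([class_col, "_gc_bin"], observed=True).size().unstack(
        fill_value=0
    )
    target = counts.min(axis=0)
    kept = []
    for (cls, b), group in pairs.groupby([class_col, "_gc_bin"], observed=True):
        n = int(target.get(b, 0))
        if n == 0:
            continue
        idx = rng.choice(group.index.to_numpy(), size=n, replace=False)
        kept.append(pairs.loc[idx])
    if not kept:
        return pairs.iloc[0:0].drop(columns="_gc_bin")
    return pd.concat(kept).drop(columns="_gc_bin")


def period_metadata_r2(periods: np.ndarray, metadata: np.ndarray) -> float:
    """R^2 of a simple linear regression of genomic period on a metadata
    covariate (e.g. growth temperature)."""
    res = stats.linregress(np.asarray(metadata, float), np.asarray(periods, float))
    return float(res.rvalue**2)
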