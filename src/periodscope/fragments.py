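"""Fragment-level periodicity scanning and catenation rescue.

To ask whether the genomic period is a property of the whole chromosome or
of a few loci, randomly positioned fragments (40 kb by default) are fitted
over a window of periods centered on the genomic period, using only the
motif sets with strong genome-wide periodicity.  Fragments whose fitted
period lands in the outermost 1-bp bands of the window ("extreme") can be
pooled ("catenated") — summing their spacing histograms — to test whether
a shared weak signal at the genomic period becomes detectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .motifscan import (
    MAX_SPACING,
    DegeneratePattern,
    GenomeRecord,
    MotifSet,
    SpacingHistogram,
    class_pair_counts,
    histogram_from_class_counts,
    smooth,
)
from .periodfit import DampedSineFit, autocorrelate, fit_damped_sine
from .compare import GdfProfile

STRONG_GDF_MAX = 1.5
STRONG_AMP_MIN = 0.2
DEFAULT_FRAGMENT_LENGTH = 40_000
DEFAULT_WINDOW = 5.0
GENOMIC_TOLERANCE = 0.6
EXTREME_BAND = 1.0


@dataclass
class FragmentRecord:
    start: int
    length: int
    lambda_bp: float
    gdf: float
    amplitude: float
    category: str


def strong_sets(
    profile: GdfProfile,
    gdf_max: float = STRONG_GDF_MAX,
    amp_min: float = STRONG_AMP_MIN,
) -> list[MotifSet]:
    """Motif sets with strong genome-wide periodicity: GdF strictly below
    ``gdf_max`` AND amplitude strictly above ``amp_min``."""
    if profile.table.empty:
        raise ValueError("empty profile")
    from .motifscan import build_motif_sets

    keep = []
    for mset in build_motif_sets():
        row = profile.table.loc[mset.label]
        if row["gdf"] < gdf_max and row["amplitude"] > amp_min:
            keep.append(mset)
    return keep


def _set_patterns(sets: Sequence[MotifSet]) -> list[DegeneratePattern]:
    return [p for s in sets for p in s.members]


def sample_fragments(
    genome: GenomeRecord,
    n: int,
    length: int = DEFAULT_FRAGMENT_LENGTH,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Uniform random fragment start positions on [0, L - length]."""
    L = len(genome)
    if length > L:
        raise ValueError(f"fragment length {length} exceeds genome length {L}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.integers(0, L - length + 1, size=n)


def fragment_histogram(
    genome: GenomeRecord,
    start: int,
    length: int,
    patterns: Sequence[DegeneratePattern],
    max_spacing: int = MAX_SPACING,
) -> SpacingHistogram:
    """Pooled spacing histogram of the given patterns within one fragment."""
    cls = genome.dinucleotide_classes()[start : start + length - 1]
    counts = class_pair_counts(cls, max_spacing)
    return histogram_from_class_counts(counts, patterns)


def fit_fragment(
    genome: GenomeRecord,
    start: int,
    length: int,
    sets: Sequence[MotifSet],
    center: float,
    window: float = DEFAULT_WINDOW,
    max_spacing: int = MAX_SPACING,
) -> FragmentRecord:
    """Fit a fragment's pooled strong-set spacings over center +- window bp."""
    if not sets:
        raise ValueError("no strong motif sets supplied")
    if length < 2 * max_spacing:
        raise ValueError(
            f"fragment length {length} shorter than 2x max spacing {max_spacing}"
        )
    h = fragment_histogram(genome, start, length, _set_patterns(sets), max_spacing)
    ac = autocorrelate(smooth(h))
    fit = fit_damped_sine(ac, (center - window, center + window))
    return FragmentRecord(
        start=start,
        length=length,
        lambda_bp=fit.lambda_bp,
        gdf=fit.gdf,
        amplitude=fit.amplitude,
        category=classify_period(fit.lambda_bp, center, window=window),
    )


def classify_period(
    lambda_bp: float,
    center: float,
    tol: float = GENOMIC_TOLERANCE,
    window: float = DEFAULT_WINDOW,
    band: float = EXTREME_BAND,
) -> str:
    """Classify a fragment's period relative to the genomic period.

    Within ``tol`` of the center -> "genomic"; in the lowest/highest
    ``band``-wide interval of the search window -> "low-extreme" /
    "high-extreme"; otherwise "other".
    """
    if abs(lambda_bp - center) <= tol:
        return "genomic"
    if lambda_bp <= center - window + band:
        return "low-extreme"
    if lambda_bp >= center + window - band:
        return "high-extreme"
    return "other"


def catenate_and_refit(
    genome: GenomeRecord,
    fragments: Sequence[FragmentRecord] | Sequence[tuple[int, int]],
    sets: Sequence[MotifSet],
    center: float,
    window: float = DEFAULT_WINDOW,
    max_spacing: int = MAX_SPACING,
) -> DampedSineFit:
    """Pool several non-overlapping fragments' histograms and refit.

    Catenation sums the per-fragment spacing histograms, so no artificial
    spacings spanning fragment junctions are created; within-fragment
    spacings are preserved exactly.
    """
    spans = [
        (f.start, f.length) if isinstance(f, FragmentRecord) else tuple(f)
        for f in fragments
    ]
    if not spans:
        raise ValueError("no fragments given")
    spans_sorted = sorted(spans)
    for (s1, l1), (s2, _) in zip(spans_sorted, spans_sorted[1:]):
        if s1 + l1 > s2:
            raise ValueError(f"fragments ({s1},{l1}) and ({s2},...) overlap")
    total: SpacingHistogram | None = None
    patterns = _set_patterns(sets)
    for s, l in spans:
        h = fragment_histogram(genome, s, l, patterns, max_spacing)
        total = h if total is None else total + h
    ac = autocorrelate(smooth(total))
    return fit_damped_sine(ac, (center - window, center + window))
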