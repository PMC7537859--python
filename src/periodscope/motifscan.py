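"""Degenerate dinucleotide scanning and spacing collation.

A "pattern" is an ordered pair of IUPAC symbols drawn from the 10-letter
subset ``G A T C R Y W S M K`` (the four concrete bases plus the six
two-base ambiguity codes).  There are exactly 100 such dinucleotide
patterns; grouping each with its reverse complement yields 10 palindromes
and 45 complementary pairs, i.e. 55 motif sets.

Occurrence positions of a pattern in a genome are turned into a histogram
of start-to-start spacings up to 202 bp (all ordered pairs of occurrences
within that range, not just adjacent ones), which is then averaged over a
sliding 3-bp window to suppress the reading-frame periodicity of coding
sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

IUPAC_ORDER = "GATCRYWSMK"
COMPLEMENT = dict(zip("GATCRYWSMK", "CTAGYRWSKM"))
MATCH_SETS = {
    "G": frozenset("G"),
    "A": frozenset("A"),
    "T": frozenset("T"),
    "C": frozenset("C"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
}

MAX_SPACING = 202
MIN_REPORTED_SPACING = 6  # spacings below this are dominated by homopolymer runs

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_AMBIG = 4  # any non-ACGT genome character
# dinucleotide class: 4*code(first) + code(second) in 0..15, or 16 if either
# position is ambiguous / past the end
N_DINUC_CLASSES = 17


@dataclass(frozen=True)
class DegeneratePattern:
    """A two-symbol degenerate dinucleotide motif, e.g. ``WW`` or ``GA``."""

    first: str
    second: str

    def __post_init__(self) -> None:
        for sym in (self.first, self.second):
            if sym not in MATCH_SETS:
                raise ValueError(f"symbol {sym!r} not in the 10-letter IUPAC subset")

    @property
    def match_sets(self) -> tuple[frozenset, frozenset]:
        return MATCH_SETS[self.first], MATCH_SETS[self.second]

    def reverse_complement(self) -> "DegeneratePattern":
        return DegeneratePattern(COMPLEMENT[self.second], COMPLEMENT[self.first])

    @property
    def is_palindromic(self) -> bool:
        return self.reverse_complement() == self

    def match_vector(self) -> np.ndarray:
        """Boolean vector over the 17 dinucleotide classes this pattern matches."""
        v = np.zeros(N_DINUC_CLASSES, dtype=bool)
        for b1 in MATCH_SETS[self.first]:
            for b2 in MATCH_SETS[self.second]:
                v[4 * _BASE_CODE[b1] + _BASE_CODE[b2]] = True
        return v

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.first + self.second

    @classmethod
    def from_string(cls, s: str) -> "DegeneratePattern":
        s = s.strip().upper()
        if len(s) != 2:
            raise ValueError("a dinucleotide pattern has exactly two symbols")
        return cls(s[0], s[1])


@dataclass(frozen=True)
class MotifSet:
    """A pattern together with its reverse complement (or alone, if palindromic)."""

    members: tuple[DegeneratePattern, ...]
    palindromic: bool

    @property
    def label(self) -> str:
        return "|".join(str(m) for m in self.members)


def enumerate_patterns() -> list[DegeneratePattern]:
    """All 100 ordered degenerate dinucleotides, in IUPAC-table order."""
    return [
        DegeneratePattern(a, b)
        for a, b in itertools.product(IUPAC_ORDER, repeat=2)
    ]


def reverse_complement(p: DegeneratePattern) -> DegeneratePattern:
    return p.reverse_complement()


def build_motif_sets() -> list[MotifSet]:
    """Group the 100 patterns into 10 palindromes + 45 complementary pairs."""
    sets: list[MotifSet] = []
    seen: set[DegeneratePattern] = set()
    for p in enumerate_patterns():
        if p in seen:
            continue
        rc = p.reverse_complement()
        if rc == p:
            sets.append(MotifSet(members=(p,), palindromic=True))
            seen.add(p)
        else:
            sets.append(MotifSet(members=(p, rc), palindromic=False))
            seen.update((p, rc))
    return sets


# ---------------------------------------------------------------------------
# Genomes


@dataclass(frozen=True)
class Gene:
    """A protein-coding interval: 0-based half-open, frame = phase of first codon base."""

    start: int
    end: int
    strand: str  # "+" or "-"
    frame: int = 0


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    origin: int | None = None
    terminus: int | None = None
    genes: list[Gene] | None = None
    _classes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        L = len(self.sequence)
        for name in ("origin", "terminus"):
            v = getattr(self, name)
            if v is not None and not (0 <= v < max(L, 1)):
                raise ValueError(f"{name} {v} outside sequence of length {L}")
        if self.genes:
            for g in self.genes:
                if not (0 <= g.start < g.end <= L):
                    raise ValueError(f"gene interval ({g.start}, {g.end}) outside sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def dinucleotide_classes(self) -> np.ndarray:
        """Per-position dinucleotide class codes (cached)."""
        if self._classes is None:
            self._classes = dinucleotide_classes(self.sequence)
        return self._classes


def dinucleotide_classes(sequence: str) -> np.ndarray:
    """Encode each position's dinucleotide (seq[i], seq[i+1]) as a class in 0..16.

    Class 16 marks ambiguous bases (N etc.) and the final position; such
    positions never match any pattern.
    """
    codes = np.full(len(sequence), _AMBIG, dtype=np.int16)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    if len(sequence) < 2:
        return np.full(len(sequence), N_DINUC_CLASSES - 1, dtype=np.int16)
    cls = np.full(len(sequence) - 1, N_DINUC_CLASSES - 1, dtype=np.int16)
    ok = (codes[:-1] != _AMBIG) & (codes[1:] != _AMBIG)
    cls[ok] = 4 * codes[:-1][ok] + codes[1:][ok]
    return cls


def scan(
    genome: GenomeRecord | str,
    pattern: DegeneratePattern | str,
    region: tuple[int, int] | None = None,
) -> np.ndarray:
    """0-based start positions of every (possibly overlapping) match.

    ``region`` is a half-open interval restricting the returned starts; a
    match must lie entirely within it.
    """
    if isinstance(pattern, str):
        pattern = DegeneratePattern.from_string(pattern)
    if isinstance(genome, GenomeRecord):
        cls = genome.dinucleotide_classes()
        L = len(genome)
    else:
        cls = dinucleotide_classes(genome)
        L = len(genome)
    if L < 2:
        return np.empty(0, dtype=np.int64)
    hit = pattern.match_vector()[cls]
    if region is not None:
        lo, hi = region
        if not (0 <= lo <= hi <= L):
            raise ValueError(f"region {region} outside sequence of length {L}")
        mask = np.zeros_like(hit)
        mask[lo : max(hi - 1, lo)] = True
        hit = hit & mask
    return np.flatnonzero(hit).astype(np.int64)


# ---------------------------------------------------------------------------
# Spacing histograms


@dataclass
class SpacingHistogram:
    """Counts of start-to-start spacings 1..max_spacing between occurrences.

    ``raw_counts[d]`` is the number of ordered occurrence pairs separated by
    exactly ``d`` bp (index 0 unused).  ``subset_counts`` (optional) holds the
    round-robin partition used for bootstrapping; its columns sum to
    ``raw_counts``.
    """

    raw_counts: np.ndarray
    subset_counts: np.ndarray | None = None

    @property
    def max_spacing(self) -> int:
        return len(self.raw_counts) - 1

    @property
    def n_spacings(self) -> int:
        return int(self.raw_counts.sum())

    def __add__(self, other: "SpacingHistogram") -> "SpacingHistogram":
        if self.max_spacing != other.max_spacing:
            raise ValueError("histograms have different max_spacing")
        subsets = None
        if self.subset_counts is not None and other.subset_counts is not None:
            if self.subset_counts.shape != other.subset_counts.shape:
                raise ValueError("histograms have different subset partitions")
            subsets = self.subset_counts + other.subset_counts
        return SpacingHistogram(self.raw_counts + other.raw_counts, subsets)


@dataclass
class SmoothedSeries:
    """Sliding 3-bp means of spacing counts, reported for spacings 6..max-2."""

    values: np.ndarray
    start: int = MIN_REPORTED_SPACING

    @property
    def spacings(self) -> np.ndarray:
        return np.arange(self.start, self.start + len(self.values))


def collate_spacings(
    positions: Sequence[int] | np.ndarray,
    max_spacing: int = MAX_SPACING,
    n_subsets: int | None = None,
    subset_start: int = 0,
) -> SpacingHistogram:
    """Histogram of all pairwise start-to-start spacings <= max_spacing.

    With ``n_subsets`` set, each spacing is additionally assigned round-robin
    (in discovery order: anchor position ascending, then partner distance
    ascending) to one of ``n_subsets`` sub-histograms, starting from subset
    ``subset_start``.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    raw = np.zeros(max_spacing + 1, dtype=np.int64)
    if n_subsets is None:
        d = np.diff(pos)
        t = 1
        dist = d
        while dist.size:
            valid = dist[dist <= max_spacing]
            if not valid.size:
                break
            raw += np.bincount(valid, minlength=max_spacing + 1)
            t += 1
            if t > pos.size - 1:
                break
            dist = pos[t:] - pos[:-t]
        return SpacingHistogram(raw)

    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    k = n_subsets
    # partner count per anchor, then stream offsets for round-robin assignment
    hi = np.searchsorted(pos, pos + max_spacing, side="right")
    m = hi - np.arange(pos.size) - 1  # partners within range for each anchor
    offsets = np.concatenate(([0], np.cumsum(m)[:-1])) + subset_start
    subsets = np.zeros((k, max_spacing + 1), dtype=np.int64)
    t = 1
    while True:
        anchors = np.flatnonzero(m >= t)
        if not anchors.size:
            break
        dist = pos[anchors + t] - pos[anchors]
        sub = (offsets[anchors] + (t - 1)) % k
        np.add.at(raw, dist, 1)
        flat = sub * (max_spacing + 1) + dist
        subsets += np.bincount(flat, minlength=k * (max_spacing + 1)).reshape(
            k, max_spacing + 1
        )
        t += 1
    return SpacingHistogram(raw, subsets)


def smooth(h: SpacingHistogram, start: int = MIN_REPORTED_SPACING) -> SmoothedSeries:
    """Sliding 3-term mean: value[s] = mean(raw[s], raw[s+1], raw[s+2])."""
    raw = h.raw_counts.astype(float)
    stop = h.max_spacing - 2  # last reported spacing
    vals = (raw[start : stop + 1] + raw[start + 1 : stop + 2] + raw[start + 2 :]) / 3.0
    return SmoothedSeries(vals, start=start)


# ---------------------------------------------------------------------------
# Fast class-count route for pooled and per-set histograms


def class_pair_counts(
    classes: np.ndarray, max_spacing: int = MAX_SPACING
) -> np.ndarray:
    """N[d, a, b] = number of positions i with class a at i and class b at i+d.

    This joint count tensor lets the spacing histogram of *any* degenerate
    pattern (or pooled collection) be obtained by contraction with its match
    matrix, in O(L * max_spacing) total instead of per-pattern pair loops.
    """
    K = N_DINUC_CLASSES
    L = classes.size
    N = np.zeros((max_spacing + 1, K, K), dtype=np.int64)
    c = classes.astype(np.int64)
    for d in range(1, min(max_spacing, L - 1) + 1):
        joint = c[:-d] * K + c[d:]
        N[d] = np.bincount(joint, minlength=K * K).reshape(K, K)
    return N


def match_matrix(patterns: Iterable[DegeneratePattern]) -> np.ndarray:
    """M[a, b] = number of given patterns matching dinucleotide class a AND b."""
    K = N_DINUC_CLASSES
    M = np.zeros((K, K), dtype=np.int64)
    for p in patterns:
        v = p.match_vector().astype(np.int64)
        M += np.outer(v, v)
    return M


def histogram_from_class_counts(
    N: np.ndarray, patterns: Iterable[DegeneratePattern]
) -> SpacingHistogram:
    M = match_matrix(patterns)
    raw = np.einsum("dab,ab->d", N, M)
    raw[0] = 0
    return SpacingHistogram(raw)


def pooled_histogram(
    genome: GenomeRecord | str,
    patterns: Iterable[DegeneratePattern] | None = None,
    max_spacing: int = MAX_SPACING,
    n_subsets: int | None = None,
    class_counts: np.ndarray | None = None,
) -> SpacingHistogram:
    """Element-wise sum of per-pattern spacing histograms.

    Defaults to all 100 degenerate dinucleotides (the "genomic" pooled
    histogram).  Occurrence pairs counted by several overlapping degenerate
    patterns contribute once per pattern, deliberately.  When ``n_subsets``
    is given, the slower pair-enumeration route is used so each pattern's
    spacings are striped round-robin across subsets in discovery order.
    """
    patterns = list(patterns) if patterns is not None else enumerate_patterns()
    if n_subsets is None:
        if class_counts is None:
            cls = (
                genome.dinucleotide_classes()
                if isinstance(genome, GenomeRecord)
                else dinucleotide_classes(genome)
            )
            class_counts = class_pair_counts(cls, max_spacing)
        return histogram_from_class_counts(class_counts, patterns)
    total: SpacingHistogram | None = None
    for p in patterns:
        pos = scan(genome, p)
        h = collate_spacings(pos, max_spacing, n_subsets=n_subsets)
        total = h if total is None else total + h
    if total is None:
        total = SpacingHistogram(
            np.zeros(max_spacing + 1, dtype=np.int64),
            np.zeros((n_subsets, max_spacing + 1), dtype=np.int64),
        )
    return total


# ---------------------------------------------------------------------------
# Replicores, codon-position filtering, count equalization


def split_replicores(genome: GenomeRecord) -> tuple[GenomeRecord, GenomeRecord]:
    """Split a circular replicon at the replication origin and terminus.

    Returns (right, left): the ori->ter arc and the ter->ori arc, each as a
    contiguous linear record (wrapping across the end of the stored string),
    so that spacings built per replicore never span the ori or ter.
    """
    if genome.origin is None or genome.terminus is None:
        raise ValueError(
            "origin/terminus not set; analyze the whole replicon instead "
            "(replicore mode needs both coordinates)"
        )
    seq = genome.sequence
    ori, ter = genome.origin, genome.terminus
    if ori <= ter:
        right = seq[ori:ter]
        left = seq[ter:] + seq[:ori]
    else:
        right = seq[ori:] + seq[:ter]
        left = seq[ter:ori]
    return (
        GenomeRecord(id=f"{genome.id}|right", sequence=right),
        GenomeRecord(id=f"{genome.id}|left", sequence=left),
    )


def annotate_codon_positions(genome: GenomeRecord) -> tuple[np.ndarray, np.ndarray]:
    """Per-base gene index (-1 intergenic) and codon position (1/2/3, 0 intergenic).

    For overlapping genes the later gene in the list wins; the codon position
    of a dinucleotide is that of its first base.
    """
    if not genome.genes:
        raise ValueError("genome has no gene models")
    L = len(genome)
    gene_idx = np.full(L, -1, dtype=np.int64)
    codon_pos = np.zeros(L, dtype=np.int8)
    for gi, g in enumerate(genome.genes):
        idx = np.arange(g.start, g.end)
        if g.strand == "+":
            cp = ((idx - g.start - g.frame) % 3) + 1
        else:
            cp = ((g.end - 1 - idx - g.frame) % 3) + 1
        gene_idx[idx] = gi
        codon_pos[idx] = cp
    return gene_idx, codon_pos


def codon_position_filter(
    positions: np.ndarray,
    gene_idx: np.ndarray,
    codon_pos: np.ndarray,
    excluded_pair: tuple[int, int] | None,
    max_spacing: int = MAX_SPACING,
) -> SpacingHistogram:
    """Collate spacings, dropping pairs of occurrences that sit in the same
    gene at the excluded (unordered) codon-position combination.

    ``excluded_pair=None`` reproduces the unfiltered collation exactly.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if excluded_pair is None:
        return collate_spacings(pos, max_spacing)
    r1, r2 = excluded_pair
    raw = np.zeros(max_spacing + 1, dtype=np.int64)
    g = gene_idx[pos]
    c = codon_pos[pos].astype(np.int64)
    t = 1
    while t < pos.size:
        dist = pos[t:] - pos[:-t]
        ok = dist <= max_spacing
        if not ok.any():
            break
        ga, gb = g[:-t][ok], g[t:][ok]
        ca, cb = c[:-t][ok], c[t:][ok]
        same_gene = (ga == gb) & (ga >= 0)
        drop = same_gene & (
            ((ca == r1) & (cb == r2)) | ((ca == r2) & (cb == r1))
        )
        raw += np.bincount(dist[ok][~drop], minlength=max_spacing + 1)
        t += 1
    return SpacingHistogram(raw)


def subsample_spacings(
    h: SpacingHistogram, n_total: int, seed: int | np.random.Generator = 0
) -> SpacingHistogram:
    """Uniform subsample of spacings without replacement, for equalizing the
    number of spacings between genomes of different sizes."""
    if n_total > h.n_spacings:
        raise ValueError(f"cannot subsample {n_total} from {h.n_spacings} spacings")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new = rng.multivariate_hypergeometric(h.raw_counts, n_total)
    return SpacingHistogram(new.astype(np.int64))
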