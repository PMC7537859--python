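"""Synthetic genome generators.

Three fixtures stand in for downloaded genomes so the whole pipeline is
verifiable offline:

* ``planted_genome`` — i.i.d. background at a chosen GC content with a
  dinucleotide motif written at jittered multiples of a known period,
  plus a truth sidecar (the positive control).
* ``random_genome`` — plain i.i.d. background (the trivial null).
* ``markov_artificial_genome`` — a genome regenerated from a source's
  codon-position-specific tetranucleotide statistics, gene-length
  distribution and strand bias.  Such a genome keeps the short-range
  composition of real coding sequence but no long-range spacing
  structure, so it is the stringent periodicity-free null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motifscan import (
    COMPLEMENT,
    DegeneratePattern,
    Gene,
    GenomeRecord,
    MATCH_SETS,
)

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _gc_probs(gc: float) -> np.ndarray:
    if not (0.0 < gc < 1.0):
        raise ValueError("GC content must be in (0, 1)")
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])  # A C G T


def random_genome(
    length: int, gc: float = 0.5, seed: int | np.random.Generator = 0
) -> str:
    """i.i.d. random sequence at the given GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = _rng(seed)
    return "".join(_BASES[rng.choice(4, size=length, p=_gc_probs(gc))])


@dataclass
class PlantedTruth:
    period: float
    motif: str
    positions: np.ndarray
    density: float
    jitter: float
    gc: float
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "motif": self.motif,
            "positions": self.positions.tolist(),
            "density": self.density,
            "jitter": self.jitter,
            "gc": self.gc,
            "seed": self.seed,
        }


def planted_genome(
    length: int,
    period: float = 10.5,
    motif: str | DegeneratePattern = "AA",
    density: float = 3.0,
    jitter: float = 1.0,
    gc: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[GenomeRecord, PlantedTruth]:
    """Plant a dinucleotide motif at jittered multiples of ``period``.

    Anchor sites sit on a lattice whose fractional pitch is accumulated and
    rounded per anchor, so the mean pitch equals ``period`` exactly; the
    lattice is first thinned to ``density`` expected motifs per 100 bp.
    The Gaussian jitter then accumulates along the chain of kept
    occurrences (a drift-free random walk about the lattice), so the
    spacing between consecutive planted motifs has sd exactly ``jitter``
    and pairs further apart decohere progressively — emulating the phase
    decoherence that small insertions and deletions impose on real
    genomes, and giving the autocorrelation its damped envelope.  The
    motif (a concrete instantiation drawn uniformly from the pattern's
    match sets, per occurrence) overwrites the background, leaving genome
    length exact.
    """
    if length <= 0 or period <= 2 or density <= 0:
        raise ValueError("need length > 0, period > 2, density > 0")
    pattern = (
        motif
        if isinstance(motif, DegeneratePattern)
        else DegeneratePattern.from_string(str(motif))
    )
    keep_prob = density * period / 100.0
    if keep_prob > 1.0:
        raise ValueError(
            f"density {density}/100 bp exceeds the anchor lattice rate "
            f"({100.0 / period:.2f}/100 bp)"
        )
    seed_val = seed if isinstance(seed, int) else None
    rng = _rng(seed)
    bases = rng.choice(4, size=length, p=_gc_probs(gc))

    n_anchor = int(length // period) + 1
    kept_idx = np.flatnonzero(rng.random(n_anchor) < keep_prob)
    walk = (
        np.cumsum(rng.normal(0.0, jitter, size=kept_idx.size))
        if jitter > 0
        else np.zeros(kept_idx.size)
    )
    kept = np.round(kept_idx * period + walk).astype(np.int64)
    pos = kept[(kept >= 0) & (kept <= length - 2)]
    pos = np.unique(pos)
    if kept.size and pos.size < 0.5 * kept.size:
        raise ValueError("more than 50% of planted motifs collided; lower the density")

    first_choices = sorted(MATCH_SETS[pattern.first])
    second_choices = sorted(MATCH_SETS[pattern.second])
    b1 = rng.choice([_BASE_INDEX[b] for b in first_choices], size=pos.size)
    b2 = rng.choice([_BASE_INDEX[b] for b in second_choices], size=pos.size)
    bases[pos] = b1
    bases[pos + 1] = b2

    record = GenomeRecord(
        id=f"planted_p{period}_d{density}", sequence="".join(_BASES[bases])
    )
    truth = PlantedTruth(
        period=float(period),
        motif=str(pattern),
        positions=pos,
        density=float(density),
        jitter=float(jitter),
        gc=float(gc),
        seed=seed_val,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Synthetic gene models (for codon-position filters and the Markov shuffler)


def synthetic_gene_models(
    length: int,
    seed: int | np.random.Generator = 0,
    mean_gene_codons: int = 300,
    strand_bias: float = 0.75,
    mean_intergenic: int = 120,
) -> list[Gene]:
    """Tile a sequence with non-overlapping gene models.

    Gene lengths are geometric around ``mean_gene_codons`` codons, strands
    drawn with ``strand_bias`` probability of '+', and intergenic gaps
    geometric around ``mean_intergenic`` bp — a caricature of a compact
    prokaryotic chromosome sufficient for frame bookkeeping.
    """
    rng = _rng(seed)
    genes: list[Gene] = []
    cursor = int(rng.geometric(1.0 / mean_intergenic))
    while True:
        n_codons = max(30, int(rng.geometric(1.0 / mean_gene_codons)))
        end = cursor + 3 * n_codons
        if end > length:
            break
        strand = "+" if rng.random() < strand_bias else "-"
        genes.append(Gene(start=cursor, end=end, strand=strand, frame=0))
        cursor = end + int(rng.geometric(1.0 / mean_intergenic))
    return genes


# ---------------------------------------------------------------------------
# Codon-structure-preserving artificial genomes


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _coding_sequence(genome: GenomeRecord, gene: Gene) -> str:
    s = genome.sequence[gene.start : gene.end]
    return s if gene.strand == "+" else _revcomp(s)


class _ConditionalChain:
    """Order-3 base chain with order-2/1/0 backoff, optionally conditioned on
    the codon position of the emitted base."""

    def __init__(self, n_conditions: int) -> None:
        self.n_conditions = n_conditions
        self.c3 = np.zeros((n_conditions, 64, 4), dtype=np.int64)
        self.c2 = np.zeros((n_conditions, 16, 4), dtype=np.int64)
        self.c1 = np.zeros((n_conditions, 4, 4), dtype=np.int64)
        self.c0 = np.zeros((n_conditions, 4), dtype=np.int64)

    def observe(self, seq: str, cond_of: "np.ndarray | None" = None) -> None:
        codes = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)
        ok = codes >= 0
        for i in range(3, len(seq)):
            if not (ok[i] and ok[i - 1] and ok[i - 2] and ok[i - 3]):
                continue
            cond = int(cond_of[i]) if cond_of is not None else 0
            ctx3 = codes[i - 3] * 16 + codes[i - 2] * 4 + codes[i - 1]
            self.c3[cond, ctx3, codes[i]] += 1
            self.c2[cond, ctx3 % 16, codes[i]] += 1
            self.c1[cond, codes[i - 1], codes[i]] += 1
            self.c0[cond, codes[i]] += 1

    def finalize(self) -> None:
        def cum(counts: np.ndarray) -> np.ndarray:
            totals = counts.sum(axis=-1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(totals > 0, counts / totals, 0.0)
            return np.cumsum(p, axis=-1)

        self.t3 = self.c3.sum(axis=-1)
        self.t2 = self.c2.sum(axis=-1)
        self.t1 = self.c1.sum(axis=-1)
        self.cum3 = cum(self.c3)
        self.cum2 = cum(self.c2)
        self.cum1 = cum(self.c1)
        self.cum0 = cum(self.c0)
        self.backoffs = 0

    def draw(self, prev3: int, prev2: int, prev1: int, cond: int, u: float) -> int:
        ctx3 = prev3 * 16 + prev2 * 4 + prev1
        if self.t3[cond, ctx3] > 0:
            row = self.cum3[cond, ctx3]
        elif self.t2[cond, prev2 * 4 + prev1] > 0:
            self.backoffs += 1
            row = self.cum2[cond, prev2 * 4 + prev1]
        elif self.t1[cond, prev1] > 0:
            self.backoffs += 1
            row = self.cum1[cond, prev1]
        else:
            self.backoffs += 1
            row = self.cum0[cond]
        return int(np.searchsorted(row, u, side="right").clip(0, 3))


def markov_artificial_genome(
    source: GenomeRecord,
    seed: int | np.random.Generator = 0,
    codon_conditioning: bool = True,
) -> GenomeRecord:
    """Regenerate a genome from a source's local statistics.

    Coding sequence is emitted by an order-3 chain whose transition
    frequencies are estimated separately for each codon position of the
    emitted base, reproducing the source's codon-position-specific
    dinucleotide/trinucleotide/tetranucleotide frequencies; gene lengths
    are resampled from the source's gene-length distribution, strands
    match the source's strand bias, and intergenic gaps use intergenic
    statistics.  Long-range spacing structure is not preserved.
    """
    if not source.genes:
        raise ValueError("source genome must carry gene models with frames")
    rng = _rng(seed)

    n_cond = 3 if codon_conditioning else 1
    coding = _ConditionalChain(n_cond)
    starts: list[str] = []
    gene_lengths: list[int] = []
    strand_plus = 0
    for g in source.genes:
        cds = _coding_sequence(source, g)
        if len(cds) < 6:
            continue
        gene_lengths.append(len(cds))
        strand_plus += g.strand == "+"
        starts.append(cds[:3])
        cond = (
            (np.arange(len(cds)) - g.frame) % 3 if codon_conditioning else None
        )
        coding.observe(cds, cond)
    if not gene_lengths:
        raise ValueError("no usable genes in source")
    coding.finalize()

    intergenic = _ConditionalChain(1)
    gaps: list[int] = []
    prev_end = 0
    for g in sorted(source.genes, key=lambda g: g.start):
        if g.start > prev_end:
            seg = source.sequence[prev_end : g.start]
            gaps.append(len(seg))
            intergenic.observe(seg)
        prev_end = max(prev_end, g.end)
    if prev_end < len(source):
        seg = source.sequence[prev_end:]
        gaps.append(len(seg))
        intergenic.observe(seg)
    if not gaps:
        gaps = [1]
    intergenic.finalize()

    p_plus = strand_plus / len(gene_lengths)
    L = len(source)
    out = np.empty(L, dtype="<U1")
    genes: list[Gene] = []

    def emit_chain(chain: _ConditionalChain, n: int, init: str) -> str:
        u = rng.random(n)
        prev = [_BASE_INDEX[b] for b in init]
        chars = list(init)
        for i in range(len(init), n):
            cond = i % 3 if chain.n_conditions == 3 else 0
            b = chain.draw(prev[-3], prev[-2], prev[-1], cond, u[i])
            chars.append("ACGT"[b])
            prev = [prev[-2], prev[-1], b]
        return "".join(chars)

    cursor = 0
    while cursor < L:
        gap = gaps[int(rng.integers(0, len(gaps)))]
        gap = min(gap, L - cursor)
        if gap >= 4:
            seg = emit_chain(intergenic, gap, starts[0][:3])[:gap]
        else:
            seg = "".join(_BASES[rng.integers(0, 4, size=gap)])
        out[cursor : cursor + gap] = list(seg)
        cursor += gap
        if cursor >= L:
            break
        n = gene_lengths[int(rng.integers(0, len(gene_lengths)))]
        n = min(n, L - cursor)
        if n < 6:
            out[cursor:L] = list("".join(_BASES[rng.integers(0, 4, size=L - cursor)]))
            cursor = L
            break
        init = starts[int(rng.integers(0, len(starts)))]
        cds = emit_chain(coding, n, init)
        strand = "+" if rng.random() < p_plus else "-"
        placed = cds if strand == "+" else _revcomp(cds)
        out[cursor : cursor + n] = list(placed)
        genes.append(Gene(start=cursor, end=cursor + n, strand=strand, frame=0))
        cursor += n

    return GenomeRecord(
        id=f"{source.id}|artificial", sequence="".join(out), genes=genes
    )
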