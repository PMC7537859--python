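"""Scanning, spacing collation, smoothing, replicores and filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import periodscope as ps
from periodscope.motifscan import (
    Gene,
    GenomeRecord,
    annotate_codon_positions,
    codon_position_filter,
    collate_spacings,
    dinucleotide_classes,
    pooled_histogram,
    scan,
    smooth,
    split_replicores,
    subsample_spacings,
)

COMP = str.maketrans("ACGT", "TGCA")


def brute_force_spacings(positions, max_spacing=202):
    counts = np.zeros(max_spacing + 1, dtype=np.int64)
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            d = positions[j] - positions[i]
            if 0 < d <= max_spacing:
                counts[d] += 1
    return counts


@pytest.mark.parametrize(
    "seq,pattern,expected",
    [
        ("AATAA", "AA", [0, 3]),
        ("AATAA", "WW", [0, 1, 2, 3]),
        ("AATAA", "SS", []),
        ("", "AA", []),
        ("A", "AA", []),
        ("ANAA", "AA", [2]),  # ambiguous bases never match
    ],
)
def test_scan_examples(seq, pattern, expected):
    assert scan(seq, pattern).tolist() == expected


def test_scan_region():
    assert scan("AAAAAA", "AA", region=(2, 5)).tolist() == [2, 3]
    with pytest.raises(ValueError):
        scan("AAAA", "AA", region=(0, 10))


def test_scan_complement_duality():
    """Scanning p on the reverse-complemented sequence mirrors scanning
    revcomp(p) on the original; the spacing histograms are identical."""
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    rc_seq = seq.translate(COMP)[::-1]
    for pat in ("AA", "GA", "WR", "SM"):
        p = ps.DegeneratePattern.from_string(pat)
        fwd = scan(rc_seq, p)
        mirrored = np.sort(len(seq) - 2 - scan(seq, p.reverse_complement()))
        assert np.array_equal(fwd, mirrored)
        h1 = collate_spacings(fwd)
        h2 = collate_spacings(np.sort(scan(seq, p.reverse_complement())))
        assert np.array_equal(h1.raw_counts, h2.raw_counts)


def test_collate_examples():
    h = collate_spacings([0, 11, 22])
    assert h.raw_counts[11] == 2 and h.raw_counts[22] == 1
    assert h.n_spacings == 3
    assert collate_spacings([5]).n_spacings == 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 2000), min_size=0, max_size=300))
def test_collate_matches_brute_force(raw_positions):
    pos = np.unique(raw_positions)
    h = collate_spacings(pos)
    assert np.array_equal(h.raw_counts, brute_force_spacings(pos))


def test_collate_with_subsets_matches_and_conserves():
    rng = np.random.default_rng(2)
    pos = np.unique(rng.integers(0, 30_000, size=2000))
    for k in (7, 1000):
        h = collate_spacings(pos, n_subsets=k)
        assert np.array_equal(h.raw_counts, brute_force_spacings(pos))
        assert np.array_equal(h.subset_counts.sum(axis=0), h.raw_counts)
        totals = h.subset_counts.sum(axis=1)
        assert totals.max() - totals.min() <= 1  # round-robin balance


def test_collate_unsorted_rejected():
    with pytest.raises(ValueError):
        collate_spacings([5, 3, 9])


def test_smooth_rule():
    raw = np.zeros(203, dtype=np.int64)
    raw[200], raw[201], raw[202] = 3, 6, 0
    s = smooth(ps.SpacingHistogram(raw))
    assert len(s.values) == 195
    assert s.spacings[0] == 6 and s.spacings[-1] == 200
    assert s.values[-1] == pytest.approx(3.0)


def test_smooth_constant_and_oracle():
    rng = np.random.default_rng(3)
    raw = rng.integers(0, 50, size=203)
    s = smooth(ps.SpacingHistogram(raw))
    direct = np.array([(raw[i] + raw[i + 1] + raw[i + 2]) / 3 for i in range(6, 201)])
    assert np.allclose(s.values, direct)
    s_const = smooth(ps.SpacingHistogram(np.full(203, 9, dtype=np.int64)))
    assert np.allclose(s_const.values, 9.0)


def test_pooled_linearity_and_class_count_route():
    """Pooled histogram = element-wise sum over per-pattern histograms, and
    the fast class-count route agrees with per-pattern scanning."""
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=4000))
    g = GenomeRecord(id="t", sequence=seq)
    patterns = [ps.DegeneratePattern.from_string(x) for x in ("AA", "WW", "GC", "RY")]
    total = np.zeros(203, dtype=np.int64)
    n_tot = 0
    for p in patterns:
        h = collate_spacings(scan(g, p))
        total += h.raw_counts
        n_tot += h.n_spacings
    pooled = pooled_histogram(g, patterns)
    assert np.array_equal(pooled.raw_counts, total)
    assert pooled.n_spacings == n_tot
    single = pooled_histogram(g, [patterns[0]])
    assert np.array_equal(single.raw_counts, collate_spacings(scan(g, patterns[0])).raw_counts)


def test_split_replicores():
    seq = "".join(np.random.default_rng(5).choice(list("ACGT"), size=1000))
    g = GenomeRecord(id="t", sequence=seq, origin=0, terminus=500)
    right, left = split_replicores(g)
    assert len(right) == 500 and len(left) == 500
    assert right.sequence == seq[:500] and left.sequence == seq[500:]
    g2 = GenomeRecord(id="t", sequence=seq, origin=700, terminus=200)
    right2, left2 = split_replicores(g2)
    assert right2.sequence == seq[700:] + seq[:200]
    assert left2.sequence == seq[200:700]
    assert len(right2) + len(left2) == 1000
    with pytest.raises(ValueError, match="whole replicon"):
        split_replicores(GenomeRecord(id="t", sequence=seq))


def test_replicore_strand_symmetry():
    """Complement-scan duality holds on a replicore arc as a unit."""
    rng = np.random.default_rng(6)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    g = GenomeRecord(id="t", sequence=seq, origin=0, terminus=6000)
    _, left = split_replicores(g)
    p = ps.DegeneratePattern.from_string("GA")
    rc_left = left.sequence.translate(COMP)[::-1]
    h_comp = collate_spacings(scan(rc_left, p))
    h_rc = collate_spacings(scan(left.sequence, p.reverse_complement()))
    assert np.array_equal(h_comp.raw_counts, h_rc.raw_counts)


def _toy_gene_genome():
    # gene 0: [3, 18) frame 0 '+'; gene 1: [24, 36) frame 0 '+'
    seq = "T" * 40
    return GenomeRecord(
        id="t",
        sequence=seq,
        genes=[Gene(3, 18, "+", 0), Gene(24, 36, "+", 0)],
    )


def test_codon_position_annotation():
    g = _toy_gene_genome()
    gene_idx, codon_pos = annotate_codon_positions(g)
    assert codon_pos[3] == 1 and codon_pos[4] == 2 and codon_pos[5] == 3
    assert codon_pos[6] == 1
    assert gene_idx[0] == -1 and codon_pos[0] == 0
    assert gene_idx[24] == 1 and codon_pos[24] == 1


def test_codon_position_filter_rules():
    g = _toy_gene_genome()
    gene_idx, codon_pos = annotate_codon_positions(g)
    # occurrences at codon positions 1 (pos 3) and 2 (pos 7) of gene 0,
    # and position 1 of gene 1 (pos 24)
    occ = np.array([3, 7, 24])
    unfiltered = codon_position_filter(occ, gene_idx, codon_pos, None)
    assert unfiltered.raw_counts[4] == 1  # 3->7 within gene 0
    assert unfiltered.raw_counts[21] == 1  # 3->24 across genes
    filt = codon_position_filter(occ, gene_idx, codon_pos, (1, 2))
    assert filt.raw_counts[4] == 0  # same gene, positions {1,2}: dropped
    assert filt.raw_counts[21] == 1  # spans two genes: retained
    assert filt.raw_counts[17] == 1  # 7->24 spans genes: retained
    # rule (3,1) does not touch a {1,2} pair
    filt31 = codon_position_filter(occ, gene_idx, codon_pos, (3, 1))
    assert np.array_equal(filt31.raw_counts, unfiltered.raw_counts)


def test_subsample_spacings():
    rng = np.random.default_rng(8)
    raw = rng.integers(0, 40, size=203).astype(np.int64)
    raw[0] = 0
    h = ps.SpacingHistogram(raw)
    same = subsample_spacings(h, h.n_spacings, seed=0)
    assert np.array_equal(same.raw_counts, raw)
    zero = subsample_spacings(h, 0, seed=0)
    assert zero.n_spacings == 0
    with pytest.raises(ValueError):
        subsample_spacings(h, h.n_spacings + 1, seed=0)
    # expected counts scale as n_total / n
    n_half = h.n_spacings // 2
    acc = np.zeros(203)
    for s in range(300):
        acc += subsample_spacings(h, n_half, seed=s).raw_counts
    acc /= 300
    expected = raw * (n_half / h.n_spacings)
    big = raw > 10
    assert np.allclose(acc[big], expected[big], rtol=0.25)


def test_genome_record_validation():
    with pytest.raises(ValueError):
        GenomeRecord(id="t", sequence="ACGT", origin=10)
    with pytest.raises(ValueError):
        GenomeRecord(id="t", sequence="ACGT", genes=[Gene(0, 9, "+", 0)])


def test_dinucleotide_classes_encoding():
    cls = dinucleotide_classes("ACGTN")
    # AC=0*4+1=1, CG=1*4+2=6, GT=2*4+3=11, TN ambiguous=16
    assert cls.tolist() == [1, 6, 11, 16]
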