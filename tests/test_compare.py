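"""Profiles, Deming regression, period differences and taxon resampling."""

import numpy as np
import pandas as pd
import pytest

import periodscope as ps
from periodscope.compare import (
    GdfProfile,
    PROFILE_COLUMNS,
    build_profile,
    correlate_profiles,
    deming_fit,
    match_gc_differences,
    period_difference,
    period_metadata_r2,
    periodic_fraction_by_taxon,
    summarize_differences,
)
from periodscope.motifscan import build_motif_sets


def _profile_from_gdf(genome_id, gdf_values, significant=None):
    sets = build_motif_sets()
    gdf = np.asarray(gdf_values, float)
    sig = (
        np.asarray(significant, bool)
        if significant is not None
        else gdf < 3.0
    )
    table = pd.DataFrame(
        {
            "gdf": gdf,
            "amplitude": np.full(55, 0.3),
            "strength": np.log(np.maximum(gdf, 1e-9) / 0.3),
            "significant": sig,
        },
        index=[s.label for s in sets],
    )[PROFILE_COLUMNS]
    fit = ps.DampedSineFit(11.0, 0.3, 30.0, 0.1, 0.5, 0.0, (6, 16))
    return GdfProfile(genome_id, 11.0, fit, table)


def test_correlate_profiles_basic():
    rng = np.random.default_rng(0)
    g = rng.random(55) * 6
    a = _profile_from_gdf("a", g)
    assert correlate_profiles(a, a) == pytest.approx(1.0)
    b = _profile_from_gdf("b", 2 * g.mean() - g)
    assert correlate_profiles(a, b) == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="variance"):
        correlate_profiles(a, _profile_from_gdf("c", np.full(55, 2.0)))


def test_correlate_profiles_toy_value():
    # hand-computed Pearson on 5 points, embedded in the 55-vector
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    r_expected = np.corrcoef(x, y)[0, 1]
    gx = np.concatenate([x, np.full(50, np.nan)])
    gy = np.concatenate([y, np.full(50, np.nan)])
    a = _profile_from_gdf("a", gx)
    b = _profile_from_gdf("b", gy)
    assert correlate_profiles(a, b) == pytest.approx(r_expected)


def test_deming_identity_symmetry_and_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert deming_fit(x, x) == pytest.approx((1.0, 0.0))
    rng = np.random.default_rng(1)
    xs = rng.random(30)
    ys = 1.7 * xs + 0.3 + rng.normal(0, 0.05, 30)
    slope, intercept = deming_fit(xs, ys)
    back_slope, _ = deming_fit(ys, xs)
    assert back_slope == pytest.approx(1.0 / slope)
    # closed-form oracle, written out independently
    sxx = np.var(xs, ddof=1)
    syy = np.var(ys, ddof=1)
    sxy = np.cov(xs, ys, ddof=1)[0, 1]
    s_expected = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    assert slope == pytest.approx(s_expected)
    assert intercept == pytest.approx(ys.mean() - s_expected * xs.mean())
    with pytest.raises(ValueError):
        deming_fit([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="degenerate|covariance"):
        deming_fit([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


def test_period_difference():
    mk = lambda lam, gdf: ps.DampedSineFit(lam, 0.3, 30.0, 0.1, gdf, 0.0, (6, 16))
    assert period_difference(mk(11.07, 0.5), mk(11.07, 0.5)) == 0.0
    assert period_difference(mk(11.07, 0.5), mk(9.93, 0.5)) == pytest.approx(1.14)
    with pytest.raises(ValueError, match="not significant"):
        period_difference(mk(11.07, 0.5), mk(9.93, 4.2))


def test_summarize_differences_matches_sort_oracle():
    rng = np.random.default_rng(2)
    v = rng.random(51)
    med, lo, hi = summarize_differences(v)
    sv = np.sort(v)
    assert med == pytest.approx(np.median(sv))
    assert lo == pytest.approx(np.median(sv[sv < med]))
    assert hi == pytest.approx(np.median(sv[sv > med]))


def test_periodic_fraction_by_taxon():
    rng = np.random.default_rng(3)
    profiles = [
        _profile_from_gdf(f"g{i}", rng.random(55) * 6) for i in range(6)
    ]
    taxa = pd.DataFrame(
        {
            "genus": ["A", "A", "B", "B", "B", "C"],
            "family": ["F1"] * 3 + ["F2"] * 3,
        },
        index=[f"g{i}" for i in range(6)],
    )
    out = periodic_fraction_by_taxon(profiles, taxa, "genus", n_iter=50, seed=4)
    assert out.shape == (55, 2)
    assert ((out["mean_pct"] >= 0) & (out["mean_pct"] <= 100)).all()
    out2 = periodic_fraction_by_taxon(profiles, taxa, "genus", n_iter=50, seed=4)
    pd.testing.assert_frame_equal(out, out2)
    # one genome per taxon: deterministic, sd 0, equals the flag average
    single = [profiles[0], profiles[2], profiles[5]]
    taxa_single = taxa.loc[["g0", "g2", "g5"]]
    out3 = periodic_fraction_by_taxon(single, taxa_single, "genus", n_iter=20, seed=0)
    assert (out3["sd_pct"] == 0).all()
    flags = np.vstack([p.significant for p in single]).mean(axis=0) * 100
    assert np.allclose(out3["mean_pct"].to_numpy(), flags)
    with pytest.raises(ValueError):
        periodic_fraction_by_taxon(profiles, taxa.iloc[0:0], "genus")
    with pytest.raises(ValueError):
        periodic_fraction_by_taxon(profiles, taxa, "division")


def test_match_gc_differences_equalizes_bins():
    rng = np.random.default_rng(5)
    pairs = pd.DataFrame(
        {
            "relatedness": ["near"] * 300 + ["far"] * 300,
            "delta_gc": np.concatenate(
                [rng.uniform(0, 0.05, 300), rng.uniform(0, 0.15, 300)]
            ),
        }
    )
    matched = match_gc_differences(pairs, seed=0)
    bins_near = np.floor(
        matched.query("relatedness == 'near'")["delta_gc"] / 0.01
    ).value_counts()
    bins_far = np.floor(
        matched.query("relatedness == 'far'")["delta_gc"] / 0.01
    ).value_counts()
    assert bins_near.sort_index().equals(bins_far.sort_index())


def test_period_metadata_r2_null():
    rng = np.random.default_rng(6)
    periods = rng.normal(10.8, 0.4, 100)
    temps = rng.uniform(0, 90, 100)
    r2 = period_metadata_r2(periods, temps)
    assert 0.0 <= r2 < 0.1


def test_build_profile_and_replicore_consistency(planted_150kb):
    """Profiles of the two halves of a uniformly planted genome agree."""
    genome, truth = planted_150kb
    prof = build_profile(genome)
    assert len(prof.table) == 55
    assert (prof.table["significant"] == (prof.table["gdf"] < 3.0)).all()
    # the planted AA|TT set must be robustly periodic
    assert prof.table.loc["AA|TT", "significant"]
    half = len(genome) // 2
    left = ps.GenomeRecord(id="L", sequence=genome.sequence[:half])
    right = ps.GenomeRecord(id="R", sequence=genome.sequence[half:])
    pl = build_profile(left, genomic_fit=prof.genomic_fit)
    pr = build_profile(right, genomic_fit=prof.genomic_fit)
    assert correlate_profiles(pl, pr) > 0.8
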