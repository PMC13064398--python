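"""Bootstrap resampling and the rank-based simultaneous band construction."""

import numpy as np
import pytest

import tetrasweep as ts
from tetrasweep.bands import BootstrapTrack, band_coverage, select_rank_depth
from conftest import toy_windows


def make_track(matrix, chrom="c1"):
    B, W = matrix.shape
    w = toy_windows(chrom, np.arange(W), np.arange(W), mids=np.arange(1, W + 1))
    return BootstrapTrack(w, matrix, "he", "all", 0)


def brute_force_k(matrix, alpha):
    """Exhaustive k-scan: largest k whose closed band contains >= 1-alpha of
    the rows at every window simultaneously."""
    B = matrix.shape[0]
    order = np.sort(matrix, axis=0)
    best = None
    for k in range(1, (B + 1) // 2 + 1):
        lo, hi = order[k - 1], order[B - k]
        inside = ((matrix >= lo) & (matrix <= hi)).all(axis=1).mean()
        if inside >= 1 - alpha:
            best = (k, inside)
    return best


def test_single_window_k26():
    """W=1, B=1000, alpha=0.05: depth 26, band [t_(26), t_(975)], coverage 0.95."""
    rng = np.random.default_rng(1)
    mat = rng.normal(size=(1000, 1))
    band = ts.scs_rank_band(make_track(mat), alpha=0.05)
    assert band.k["c1"] == 26
    assert band.achieved_coverage["c1"] == pytest.approx(0.95)
    srt = np.sort(mat[:, 0])
    assert band.lower[0] == srt[25] and band.upper[0] == srt[974]


def test_degenerate_identical_rows():
    mat = np.tile(np.array([[0.1, -0.2, 0.3]]), (200, 1))
    band = ts.scs_rank_band(make_track(mat), alpha=0.05)
    assert np.array_equal(band.lower, band.upper)
    assert band.k["c1"] == (200 + 1) // 2
    assert band.achieved_coverage["c1"] == 1.0


def test_many_windows_need_smaller_k():
    rng = np.random.default_rng(2)
    band = ts.scs_rank_band(make_track(rng.normal(size=(1000, 50))), alpha=0.05)
    assert band.k["c1"] < 26


@pytest.mark.parametrize("B,W,alpha", [(200, 5, 0.05), (100, 3, 0.10), (500, 12, 0.05)])
def test_k_matches_exhaustive_scan(B, W, alpha):
    rng = np.random.default_rng(B + W)
    mat = rng.normal(size=(B, W))
    band = ts.scs_rank_band(make_track(mat), alpha=alpha)
    k, cov = brute_force_k(mat, alpha)
    assert band.k["c1"] == k
    assert band.achieved_coverage["c1"] == pytest.approx(cov)
    assert band_coverage(make_track(mat), band, "c1") == pytest.approx(cov)


def test_coverage_monotone_in_k():
    rng = np.random.default_rng(4)
    mat = rng.normal(size=(300, 8))
    order = np.sort(mat, axis=0)
    covs = []
    for k in range(1, 150):
        inside = ((mat >= order[k - 1]) & (mat <= order[300 - k])).all(axis=1).mean()
        covs.append(inside)
    assert all(a >= b for a, b in zip(covs, covs[1:]))


def test_band_monotone_in_alpha():
    rng = np.random.default_rng(5)
    track = make_track(rng.normal(size=(500, 10)))
    tight = ts.scs_rank_band(track, alpha=0.10)
    wide = ts.scs_rank_band(track, alpha=0.02)
    assert (wide.lower <= tight.lower).all() and (wide.upper >= tight.upper).all()


def test_bands_are_per_chromosome():
    rng = np.random.default_rng(6)
    mat = np.hstack([rng.normal(size=(1000, 1)), rng.normal(size=(1000, 30))])
    w = toy_windows("c1", [0], [0])
    w2 = toy_windows("c2", np.arange(30), np.arange(30))
    import pandas as pd
    track = BootstrapTrack(pd.concat([w, w2], ignore_index=True), mat, "he", "all", 0)
    band = ts.scs_rank_band(track, alpha=0.05)
    assert band.k["c1"] == 26 > band.k["c2"]


def test_small_B_rejected_and_nonfinite_rejected():
    with pytest.raises(ValueError):
        ts.scs_rank_band(make_track(np.zeros((30, 2))), alpha=0.05)
    mat = np.zeros((100, 2))
    mat[0, 0] = np.nan
    with pytest.raises(Exception):
        ts.scs_rank_band(make_track(mat), alpha=0.05)


# -- bootstrap ---------------------------------------------------------------


def test_bootstrap_seeded_determinism(null_sim):
    panel, m, _ = null_sim
    w = ts.make_snp_windows(m, 50, 25)
    a = ts.bootstrap_deviations(panel, m, w, "he", B=20, seed=5)
    b = ts.bootstrap_deviations(panel, m, w, "he", B=20, seed=5)
    assert np.array_equal(a.deviations, b.deviations)
    c = ts.bootstrap_deviations(panel, m, w, "he", B=20, seed=6)
    assert not np.array_equal(a.deviations, c.deviations)


def test_bootstrap_identical_samples_zero_variance():
    d = np.tile(np.array([[0.0, 1, 2, 3, 4, 2, 1, 3, 0, 4]]), (25, 1))
    panel = ts.DosagePanel([f"s{i}" for i in range(25)], d, 4)
    m = ts.SnpMap([f"m{i}" for i in range(10)], ["c1"] * 10, np.arange(1, 11) * 100)
    w = ts.make_snp_windows(m, 5, 5)
    boot = ts.bootstrap_deviations(panel, m, w, "ho", B=30, seed=1)
    assert np.allclose(boot.deviations.std(axis=0), 0.0)


def test_bootstrap_mean_consistency():
    """Bootstrap mean of window deviations stays near the point estimate."""
    cfg = ts.SimConfig(n_chromosomes=1, chrom_length_bp=2_000_000, snps_per_mb=100,
                       n_samples_per_group={"A": 200}, missing_rate=0.0, seed=13)
    sim = ts.simulate_panel(cfg)
    panel, m, _ = sim
    w = ts.make_snp_windows(m, 50, 50)
    point = ts.windowize(ts.per_locus_metric(panel.dosages, "he", 4), m, w)
    B = 200
    boot = ts.bootstrap_deviations(panel, m, w, "he", B=B, seed=2)
    bmean = boot.deviations.mean(axis=0)
    bsd = boot.deviations.std(axis=0)
    assert (np.abs(bmean - point.deviation) <= 4 * bsd / np.sqrt(B) + 1e-4).all()


def test_bootstrap_stratified_preserves_group_sizes(small_sim):
    panel, m, _ = small_sim
    w = ts.make_snp_windows(m, 100, 100)
    boot = ts.bootstrap_deviations(panel, m, w, "ho", B=5, seed=3, stratify_by_group=True)
    assert boot.deviations.shape == (5, len(w))


def test_bootstrap_unknown_metric(null_sim):
    panel, m, _ = null_sim
    w = ts.make_snp_windows(m, 50, 50)
    with pytest.raises(ValueError):
        ts.bootstrap_deviations(panel, m, w, "tajima_d", B=5, seed=1)


def test_null_band_calibration_is_simultaneous():
    """On sweep-free panels a data half's deviation track exits the
    simultaneous band bootstrapped from that same half only rarely — far
    below the ~W*alpha rate a pointwise band would allow."""
    exits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        cfg = ts.SimConfig(n_chromosomes=1, chrom_length_bp=2_000_000, snps_per_mb=100,
                           n_samples_per_group={"P": 80}, missing_rate=0.0,
                           group_divergence=0.0, seed=900 + seed)
        sim = ts.simulate_panel(cfg)
        panel, m, _ = sim
        rng = np.random.default_rng(seed)
        half = panel.subset_samples(rng.permutation(panel.n_samples)[:40])
        w = ts.make_snp_windows(m, 50, 10)
        boot = ts.bootstrap_deviations(half, m, w, "he", B=200, seed=1000 + seed)
        band = ts.scs_rank_band(boot, alpha=0.05)
        track = ts.windowize(ts.per_locus_metric(half.dosages, "he", 4), m, w)
        dev = track.deviation
        if ((dev < band.lower) | (dev > band.upper)).any():
            exits += 1
    assert exits / n_seeds < 0.25
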