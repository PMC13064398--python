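"""Local-minima rule, the two sweep callers, merging and consensus."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tetrasweep as ts
from tetrasweep.calling import SweepRegion, _local_maxima
from tetrasweep.windows import WindowTrack
from conftest import toy_windows

NA = np.nan


# -- local minima ------------------------------------------------------------


def brute_force_minima(values, nb):
    """Normative double loop: strict < to the left, <= to the right, over the
    edge-truncated neighborhood; NaNs transparent."""
    v = list(values)
    out = []
    for i, vi in enumerate(v):
        if not np.isfinite(vi):
            continue
        ok = True
        for j in range(max(0, i - nb), min(len(v), i + nb + 1)):
            if j == i or not np.isfinite(v[j]):
                continue
            if (j < i and not vi < v[j]) or (j > i and not vi <= v[j]):
                ok = False
                break
        if ok:
            out.append(i)
    return out


def test_minima_spec_example():
    assert ts.find_local_minima([-1, -3, -2, -1, -5, -2], 2) == [1, 4]


def test_minima_edges_and_ties():
    assert ts.find_local_minima([1, 2, 3, 4, 5], 2) == [0]
    assert ts.find_local_minima([2, 2, 2, 2], 2) == [0]
    assert ts.find_local_minima([3, 1, 1, 3], 1) == [1]


def test_minima_nan_transparent():
    assert ts.find_local_minima([0.5, NA, -1, 0.0], 2) == [2]
    assert ts.find_local_minima([NA, NA], 1) == []


@pytest.mark.parametrize("nb", [1, 2])
def test_minima_agree_with_brute_force(nb):
    rng = np.random.default_rng(17)
    for _ in range(300):
        n = rng.integers(1, 40)
        v = np.round(rng.normal(size=n), 1)  # rounding induces ties
        v[rng.random(n) < 0.1] = np.nan
        assert ts.find_local_minima(v, nb) == brute_force_minima(v, nb)


def test_maxima_mirror_minima():
    v = [1.0, 3.0, 2.0, 3.0, 0.0]
    assert _local_maxima(v, 1) == ts.find_local_minima([-x for x in v], 1)


# -- within-group caller -----------------------------------------------------


def track_from_devs(devs, chrom="Chr1", genome_mean=0.3, mid_step=1_000_000, metric="ho"):
    devs = np.asarray(devs, dtype=float)
    n = len(devs)
    mids = (np.arange(n) + 1) * mid_step
    w = toy_windows(chrom, np.arange(n), np.arange(n), mids=mids)
    return WindowTrack(w, genome_mean + devs, genome_mean, metric=metric, group="all")


def test_no_negative_deviations_no_regions():
    track = track_from_devs([0.0, 0.1, 0.2, 0.05])
    assert ts.call_sweeps(track) == []


def test_single_deep_dip_gives_one_extended_region():
    devs = np.array([0.01, 0.02, -0.01, -0.005, -0.30, -0.02, 0.01, 0.0,
                     -0.008, 0.03, 0.02, 0.01, -0.003, 0.0, 0.02, 0.01,
                     0.005, 0.0, 0.01, 0.02])
    track = track_from_devs(devs)  # dip at window 5 -> mid 5 Mb
    regions = ts.call_sweeps(track, quantile=0.05, neighborhood=2,
                             extend_bp=1_000_000,
                             chrom_lengths={"Chr1": 20_000_000})
    assert len(regions) == 1
    r = regions[0]
    assert (r.start_bp, r.end_bp, r.peak_mid_bp) == (4_000_000, 6_000_000, 5_000_000)
    assert r.direction == "reduced_in_all" and r.provenance == "within_group"


def test_region_clipped_to_chromosome():
    devs = np.array([-0.5, 0.1, 0.1, 0.1, 0.1, -0.01])
    track = track_from_devs(devs, mid_step=400_000)
    regions = ts.call_sweeps(track, chrom_lengths={"Chr1": 2_400_000})
    assert regions[0].start_bp == 1
    assert regions[0].end_bp == 1_400_000


def test_quantile_monotonicity():
    rng = np.random.default_rng(23)
    devs = rng.normal(scale=0.05, size=120)
    track = track_from_devs(devs)
    def calls(q):
        return {(r.chromosome, r.peak_mid_bp) for r in ts.call_sweeps(track, quantile=q)}
    assert calls(0.05) <= calls(0.25) <= calls(0.8)


def test_band_gating_and_annotation():
    devs = np.array([0.02, -0.30, 0.01, 0.0, -0.25, 0.02])
    track = track_from_devs(devs)
    upper = np.array([0.1, -0.05, 0.1, 0.1, 0.05, 0.1])  # dip 2 not band-significant
    band = ts.SimultaneousBand(track.windows, upper - 0.5, upper, 0.05,
                               {"Chr1": 10}, {"Chr1": 0.95})
    loose = ts.call_sweeps(track, band=band, quantile=1.0)
    assert [r.band_significant for r in loose] == [True, False]
    strict = ts.call_sweeps(track, band=band, quantile=1.0, require_band=True)
    assert len(strict) == 1 and strict[0].peak_mid_bp == 2_000_000


def test_recovery_on_small_panel(small_sim):
    panel, m, sweeps = small_sim
    panel, m, _ = ts.filter_missingness(panel, m)
    w = ts.make_snp_windows(m, 100, 10)
    per = {}
    for metric in ("ho", "he", "pi"):
        vals = ts.per_locus_metric(panel.dosages, metric, panel.ploidy)
        per[metric] = ts.call_sweeps(ts.windowize(vals, m, w, metric=metric),
                                     chrom_lengths={"Chr1": 5_000_000, "Chr2": 5_000_000})
    cons = ts.consensus_regions(per, min_metrics=2)
    truth = sweeps[0]
    assert any(r.chromosome == truth.chromosome and r.start_bp <= truth.end_bp
               and truth.start_bp <= r.end_bp for r in cons)
    for r in cons:
        assert r.start_bp >= 1 and len(r.metrics) >= 2


# -- merging and consensus ---------------------------------------------------


def mk_region(start, end, metric="ho", chrom="c1", peak=None):
    peak = peak if peak is not None else (start + end) // 2
    return SweepRegion(chrom, start, end, peak, {metric}, "reduced_in_all",
                       "within_group", peaks=[peak], peak_values=[-0.1])


def test_merge_example():
    merged = ts.merge_regions([mk_region(1_000_000, 3_000_000), mk_region(2_000_000, 5_000_000, "he")])
    assert len(merged) == 1
    assert (merged[0].start_bp, merged[0].end_bp) == (1_000_000, 5_000_000)
    assert merged[0].metrics == {"ho", "he"}
    assert len(merged[0].peaks) == 2


def test_merge_keeps_disjoint():
    regions = [mk_region(1, 10), mk_region(20, 30)]
    assert len(ts.merge_regions(regions)) == 2


interval = st.tuples(st.integers(1, 80), st.integers(1, 25), st.sampled_from(["ho", "he", "pi"]))


@settings(max_examples=60, derandomize=True)
@given(st.lists(interval, min_size=1, max_size=12))
def test_merge_idempotent_order_invariant_coverage_preserving(spec):
    regions = [mk_region(s, s + l, m) for s, l, m in spec]
    merged = ts.merge_regions(regions)
    # idempotent
    again = ts.merge_regions(merged)
    assert [(r.start_bp, r.end_bp) for r in again] == [(r.start_bp, r.end_bp) for r in merged]
    # order invariant
    rev = ts.merge_regions(list(reversed(regions)))
    assert [(r.start_bp, r.end_bp) for r in rev] == [(r.start_bp, r.end_bp) for r in merged]
    # covered bp preserved and non-overlapping output
    def covered(rs):
        out = set()
        for r in rs:
            out |= set(range(r.start_bp, r.end_bp + 1))
        return out
    assert covered(regions) == covered(merged)
    for a, b in zip(merged, merged[1:]):
        assert a.end_bp < b.start_bp


def test_consensus_rules():
    ho = mk_region(1_000_000, 3_000_000, "ho")
    pi = mk_region(2_500_000, 4_500_000, "pi")
    lone = mk_region(20_000_000, 22_000_000, "ho")
    out = ts.consensus_regions({"ho": [ho, lone], "pi": [pi]}, min_metrics=2)
    assert len(out) == 1
    assert (out[0].start_bp, out[0].end_bp) == (1_000_000, 4_500_000)
    assert out[0].metrics == {"ho", "pi"}
    # identical region from two metrics retained; single metric dropped
    same = ts.consensus_regions({"ho": [mk_region(1, 10, "ho")], "pi": [mk_region(1, 10, "pi")]})
    assert len(same) == 1 and same[0].metrics == {"ho", "pi"}
    assert ts.consensus_regions({"ho": [mk_region(1, 10, "ho")]}, min_metrics=2) == []


def test_consensus_min_metrics_monotone():
    per = {"ho": [mk_region(1, 10, "ho")], "he": [mk_region(5, 15, "he")],
           "pi": [mk_region(40, 50, "pi")]}
    n = [len(ts.consensus_regions(per, min_metrics=k)) for k in (1, 2, 3)]
    assert n[0] >= n[1] >= n[2]


# -- comparative caller ------------------------------------------------------


def comparative_tracks(n=200, fst_peaks=(), dho_dips=(), pir_dips=()):
    wiggle = 0.004 * np.sin(np.arange(n))
    mids = (np.arange(n) + 1) * 100_000
    w = toy_windows("Chr1", np.arange(n), np.arange(n), mids=mids)
    fst = 0.05 + wiggle.copy()
    dho = wiggle.copy()
    pir = 1.0 + wiggle.copy()
    fst[list(fst_peaks)] = 0.6
    dho[list(dho_dips)] = -0.3
    pir[list(pir_dips)] = 0.1
    return {
        "fst": WindowTrack(w, fst, float(fst.mean()), "fst", "A_vs_B"),
        "delta_ho": WindowTrack(w, dho, float(dho.mean()), "delta_ho", "A_vs_B"),
        "pi_ratio": WindowTrack(w, pir, float(pir.mean()), "pi_ratio", "A_vs_B"),
    }


def test_comparative_two_metric_cluster():
    """Adjacent FST-top-1% and delta-Ho-bottom-1% runs form one region with
    direction 'reduced in A'."""
    tracks = comparative_tracks(fst_peaks=(100, 101), dho_dips=(101, 102))
    out = ts.call_comparative_sweeps(tracks, group_a="A", group_b="B")
    assert len(out) == 1
    r = out[0]
    assert r.metrics == {"fst", "delta_ho"}
    assert r.direction == "reduced_in_A"
    center = (101 + 102 + 103) * 100_000 // 3
    assert abs(r.peak_mid_bp - center) <= 100_000
    assert r.provenance == "comparative"


def test_comparative_single_metric_no_region():
    assert ts.call_comparative_sweeps(comparative_tracks(fst_peaks=(100, 101))) == []


def test_comparative_isolated_single_windows_no_region():
    """One extreme window per metric (no adjacent run) is not enough."""
    tracks = comparative_tracks(fst_peaks=(100,), dho_dips=(101,))
    assert ts.call_comparative_sweeps(tracks) == []


def test_comparative_direction_reduced_in_b():
    tracks = comparative_tracks()
    tracks["delta_ho"].window_mean[[50, 51]] = 0.3   # high delta_ho -> B poorer
    tracks["pi_ratio"].window_mean[[51, 52]] = 3.0
    out = ts.call_comparative_sweeps(tracks, group_a="A", group_b="B")
    assert len(out) == 1 and out[0].direction == "reduced_in_B"


def test_comparative_mismatched_windows_rejected():
    a = comparative_tracks()
    b = comparative_tracks(n=100)
    with pytest.raises(Exception):
        ts.call_comparative_sweeps({"fst": a["fst"], "delta_ho": b["delta_ho"]})


def test_name_regions():
    regions = [mk_region(1, 10, chrom="Chr2"), mk_region(50, 60, chrom="Chr2"),
               mk_region(5, 15, chrom="Chr5")]
    named = ts.name_regions(regions)
    assert [r.name for r in named] == ["Peak 2.1", "Peak 2.2", "Peak 5.1"]
    comp = ts.name_regions(regions, comparative=True)
    assert comp[0].name == "Peak C2.1"
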