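"""Sweep callers on windowed deviation tracks.

Two callers are provided.  The within-group caller scans one metric's
deviation track per chromosome: only negative deviations are candidates,
local minima are found in a +/-``neighborhood``-window sliding neighborhood,
minima falling in the lowest ``quantile`` of that chromosome's negative
deviations are retained, and each retained minimum is extended by
``extend_bp`` on both sides.  Overlapping regions are merged and regions
supported by at least ``min_metrics`` diversity metrics form the consensus.

The comparative caller contrasts two groups: windows in the extreme
``quantile`` tail of each metric's distribution (FST upper tail only;
delta-Ho and pi-ratio both tails) are screened for local extrema
(+/-1 window), extrema from different metrics in adjacent or overlapping
windows form clusters, and clusters supported by at least two distinct
metrics become regions around the cluster center.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .bands import SimultaneousBand
from .io import ValidationError
from .windows import WindowTrack

logger = logging.getLogger(__name__)

#: Which distribution tails mark a window as extreme, per comparative metric.
COMPARATIVE_TAILS: dict[str, tuple[str, ...]] = {
    "fst": ("high",),
    "delta_ho": ("low", "high"),
    "delta_he": ("low", "high"),
    "pi_ratio": ("low", "high"),
}

#: Direction vote implied by each (metric, tail): 'a' means reduced diversity
#: in group A, 'b' in group B; None is a differentiation-only signal.
_TAIL_VOTE = {
    ("fst", "high"): None,
    ("delta_ho", "low"): "a",
    ("delta_ho", "high"): "b",
    ("delta_he", "low"): "a",
    ("delta_he", "high"): "b",
    ("pi_ratio", "low"): "a",
    ("pi_ratio", "high"): "b",
}


@dataclass
class SweepRegion:
    """A called sweep interval (1-based inclusive, clipped to the chromosome)."""

    chromosome: str
    start_bp: int
    end_bp: int
    peak_mid_bp: int
    metrics: set[str]
    direction: str
    provenance: str  # "within_group" | "comparative"
    band_significant: bool | None = None
    name: str = ""
    peaks: list[int] = field(default_factory=list)
    peak_values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValidationError("region start_bp > end_bp")
        if not self.metrics:
            raise ValidationError("region without supporting metrics")
        if not self.peaks:
            self.peaks = [self.peak_mid_bp]
        if not (self.start_bp <= self.peak_mid_bp <= self.end_bp):
            raise ValidationError("peak outside region")

    def overlaps(self, other: "SweepRegion") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )

    @property
    def center_bp(self) -> int:
        return (self.start_bp + self.end_bp) // 2


# ---------------------------------------------------------------------------
# local minima
# ---------------------------------------------------------------------------


def find_local_minima(values, neighborhood: int = 2) -> list[int]:
    """Indices of local minima within +/-``neighborhood`` positions.

    Index i qualifies iff values[i] is finite and, over all finite j != i in
    the (edge-truncated) neighborhood, values[i] is strictly below every
    value to its left and at most every value to its right — so of a tied
    run only the leftmost member qualifies, and a constant sequence has a
    single minimum at index 0.  NaNs are transparent: they are neither
    candidates nor comparators.
    """
    if neighborhood < 1:
        raise ValueError("neighborhood must be >= 1")
    v = np.asarray(values, dtype=np.float64)
    out = []
    for i in range(len(v)):
        if not np.isfinite(v[i]):
            continue
        ok = True
        for j in range(max(0, i - neighborhood), min(len(v), i + neighborhood + 1)):
            if j == i or not np.isfinite(v[j]):
                continue
            if j < i:
                if not v[i] < v[j]:
                    ok = False
                    break
            else:
                if not v[i] <= v[j]:
                    ok = False
                    break
        if ok:
            out.append(i)
    return out


def _local_maxima(values, neighborhood: int) -> list[int]:
    v = np.asarray(values, dtype=np.float64)
    return find_local_minima(np.negative(v), neighborhood)


# ---------------------------------------------------------------------------
# within-group caller
# ---------------------------------------------------------------------------


def call_sweeps(
    track: WindowTrack,
    band: SimultaneousBand | None = None,
    quantile: float = 0.05,
    neighborhood: int = 2,
    extend_bp: int = 1_000_000,
    require_band: bool = False,
    chrom_lengths: dict[str, int] | None = None,
) -> list[SweepRegion]:
    """Within-group sweep caller on one metric's deviation track.

    Per chromosome: local minima of the deviation profile restricted to
    negative windows, kept if at or below the ``quantile`` quantile of that
    chromosome's negative deviations; each kept minimum extends
    ``extend_bp`` both ways, clipped to [1, chromosome length].  With a band
    supplied, ``band_significant`` records whether the simultaneous upper
    limit is below zero at the minimum; ``require_band`` makes that a filter.
    """
    if band is not None and not track.windows.equals(band.windows):
        raise ValidationError("band and track are on different windows")
    if require_band and band is None:
        raise ValidationError("require_band needs a band")
    direction = "reduced_in_all" if track.group == "all" else f"reduced_in_{track.group}"
    regions: list[SweepRegion] = []
    dev = track.deviation
    mids = track.windows["mid_bp"].to_numpy()
    for chrom in dict.fromkeys(track.windows["chromosome"]):
        cols = track.chromosome_indices(chrom)
        d = dev[cols]
        negatives = d[np.isfinite(d) & (d < 0)]
        if negatives.size == 0:
            continue
        threshold = float(np.quantile(negatives, quantile))
        for i in find_local_minima(d, neighborhood):
            if not (d[i] < 0 and d[i] <= threshold):
                continue
            col = cols[i]
            sig = bool(band.upper[col] < 0) if band is not None else None
            if require_band and not sig:
                continue
            mid = int(mids[col])
            end_cap = chrom_lengths.get(chrom) if chrom_lengths else None
            start = max(1, mid - extend_bp)
            end = mid + extend_bp if end_cap is None else min(mid + extend_bp, end_cap)
            regions.append(
                SweepRegion(
                    chromosome=chrom,
                    start_bp=start,
                    end_bp=end,
                    peak_mid_bp=mid,
                    metrics={track.metric} if track.metric else {"metric"},
                    direction=direction,
                    provenance="within_group",
                    band_significant=sig,
                    peaks=[mid],
                    peak_values=[float(d[i])],
                )
            )
    logger.info("call_sweeps[%s/%s]: %d regions", track.metric, track.group, len(regions))
    return regions


# ---------------------------------------------------------------------------
# merging and consensus
# ---------------------------------------------------------------------------


def merge_regions(regions) -> list[SweepRegion]:
    """Merge overlapping regions per chromosome (union of bp, metrics, peaks).

    Idempotent and input-order invariant; output sorted by
    (chromosome, start, end).
    """
    def sort_key(r: SweepRegion):
        return (r.chromosome, r.start_bp, r.end_bp)

    out: list[SweepRegion] = []
    for r in sorted(regions, key=sort_key):
        if out and out[-1].overlaps(r):
            cur = out[-1]
            peaks = sorted(set(cur.peaks) | set(r.peaks))
            values = dict(zip(cur.peaks, cur.peak_values)) | dict(zip(r.peaks, r.peak_values))
            peak_values = [values.get(p, float("nan")) for p in peaks]
            if peak_values and np.isfinite(peak_values).any():
                deepest = peaks[int(np.nanargmin(peak_values))]
            else:
                deepest = peaks[0]
            band = None
            if cur.band_significant is not None or r.band_significant is not None:
                band = bool(cur.band_significant) or bool(r.band_significant)
            direction = cur.direction if cur.direction == r.direction else "mixed"
            out[-1] = replace(
                cur,
                end_bp=max(cur.end_bp, r.end_bp),
                start_bp=min(cur.start_bp, r.start_bp),
                metrics=cur.metrics | r.metrics,
                peaks=peaks,
                peak_values=peak_values,
                peak_mid_bp=deepest,
                band_significant=band,
                direction=direction,
            )
        else:
            out.append(replace(r, metrics=set(r.metrics), peaks=list(r.peaks),
                               peak_values=list(r.peak_values)))
    return out


def consensus_regions(
    per_metric: dict[str, list[SweepRegion]], min_metrics: int = 2
) -> list[SweepRegion]:
    """Regions supported by at least ``min_metrics`` distinct metrics.

    Each metric's regions are merged first; a region is retained iff the
    distinct metrics of itself plus everything overlapping it reach
    ``min_metrics``; retained regions are unioned and re-merged.
    """
    if not per_metric:
        raise ValidationError("consensus needs at least one metric track")
    merged_all: list[SweepRegion] = []
    for regions in per_metric.values():
        merged_all.extend(merge_regions(regions))
    retained = []
    for r in merged_all:
        metrics = set(r.metrics)
        for s in merged_all:
            if s is not r and r.overlaps(s):
                metrics |= s.metrics
        if len(metrics) >= min_metrics:
            retained.append(r)
    result = merge_regions(retained)
    logger.info("consensus (>=%d metrics): %d regions", min_metrics, len(result))
    return result


# ---------------------------------------------------------------------------
# comparative caller
# ---------------------------------------------------------------------------


def call_comparative_sweeps(
    tracks: dict[str, WindowTrack],
    quantile: float = 0.01,
    neighborhood: int = 1,
    min_metrics: int = 2,
    extend_bp: int = 1_000_000,
    min_windows_per_metric: int = 2,
    per_chromosome_tails: bool = False,
    chrom_lengths: dict[str, int] | None = None,
    group_a: str = "A",
    group_b: str = "B",
    tails: dict[str, tuple[str, ...]] | None = None,
) -> list[SweepRegion]:
    """Two-group caller over {fst, delta_ho, pi_ratio} (optionally delta_he).

    Extreme windows are those in the designated ``quantile`` tail(s) of each
    metric's distribution of window values (FST upper tail only; delta-Ho
    and pi-ratio both tails).  Runs of adjacent extreme windows (index
    distance <= 1, any metric) form clusters; a cluster becomes a region
    when at least ``min_metrics`` distinct metrics each contribute
    ``min_windows_per_metric`` or more extreme windows to it.  The region
    extends ``extend_bp`` around the mean member mid-position; its peaks are
    the local extrema (+/-``neighborhood`` windows, leftmost-of-run tie
    rule) inside the cluster.  Direction comes from the tail signs: high FST
    with low pi-ratio / low delta-Ho means reduced diversity in group A.

    By default the tail thresholds come from the genome-wide distribution of
    a metric's window values; ``per_chromosome_tails`` switches to
    chromosome-specific thresholds, which by construction flag every
    chromosome's extremum and are therefore far less specific (see the
    methods note).
    """
    if not tracks:
        raise ValidationError("no comparative tracks supplied")
    tails = dict(COMPARATIVE_TAILS) if tails is None else tails
    items = list(tracks.items())
    ref = items[0][1].windows
    for name, tr in items[1:]:
        if not tr.windows.equals(ref):
            raise ValidationError(f"track {name!r} is on different windows")

    # collect extreme windows as (window row, metric, tail) events; record
    # which are also local extrema (peak anchors)
    events: list[tuple[str, int, str, str, bool]] = []
    for metric, tr in items:
        if metric not in tails:
            raise ValidationError(f"no tail rule for metric {metric!r}")
        genome_vals = tr.window_mean[np.isfinite(tr.window_mean)]
        if genome_vals.size == 0:
            continue
        for chrom in dict.fromkeys(ref["chromosome"]):
            cols = tr.chromosome_indices(chrom)
            vals = tr.window_mean[cols]
            finite = vals[np.isfinite(vals)]
            if finite.size == 0:
                continue
            source = finite if per_chromosome_tails else genome_vals
            for tail in tails[metric]:
                if tail == "low":
                    thr = float(np.quantile(source, quantile))
                    hits = np.flatnonzero(vals <= thr)
                    extrema = set(find_local_minima(vals, neighborhood))
                else:
                    thr = float(np.quantile(source, 1.0 - quantile))
                    hits = np.flatnonzero(vals >= thr)
                    extrema = set(_local_maxima(vals, neighborhood))
                events.extend(
                    (chrom, int(cols[i]), metric, tail, bool(i in extrema))
                    for i in hits
                )

    # cluster: runs of adjacent extreme windows on the same chromosome
    mids = ref["mid_bp"].to_numpy()
    regions: list[SweepRegion] = []
    by_chrom: dict[str, list[tuple[int, str, str, bool]]] = {}
    for chrom, col, metric, tail, is_peak in events:
        by_chrom.setdefault(chrom, []).append((col, metric, tail, is_peak))
    for chrom in sorted(by_chrom):
        evs = sorted(by_chrom[chrom])
        clusters: list[list[tuple[int, str, str, bool]]] = []
        for ev in evs:
            if clusters and ev[0] - max(e[0] for e in clusters[-1]) <= 1:
                clusters[-1].append(ev)
            else:
                clusters.append([ev])
        for cluster in clusters:
            windows_per_metric: dict[str, set[int]] = {}
            for c, m, _, _ in cluster:
                windows_per_metric.setdefault(m, set()).add(c)
            supporting = {
                m for m, ws in windows_per_metric.items()
                if len(ws) >= min_windows_per_metric
            }
            if len(supporting) < min_metrics:
                continue
            member_mids = sorted({int(mids[c]) for c, _, _, _ in cluster})
            center = int(np.mean(member_mids))
            votes = [_TAIL_VOTE[(m, t)] for _, m, t, _ in cluster]
            n_a, n_b = votes.count("a"), votes.count("b")
            if n_a > n_b:
                direction = f"reduced_in_{group_a}"
            elif n_b > n_a:
                direction = f"reduced_in_{group_b}"
            else:
                direction = "elevated_differentiation"
            peaks = sorted({int(mids[c]) for c, _, _, is_peak in cluster if is_peak})
            end_cap = chrom_lengths.get(chrom) if chrom_lengths else None
            end = center + extend_bp if end_cap is None else min(center + extend_bp, end_cap)
            regions.append(
                SweepRegion(
                    chromosome=chrom,
                    start_bp=max(1, center - extend_bp),
                    end_bp=end,
                    peak_mid_bp=center,
                    metrics=supporting,
                    direction=direction,
                    provenance="comparative",
                    peaks=peaks or [center],
                    peak_values=[],
                )
            )
    result = merge_regions(regions)
    logger.info("comparative caller: %d regions", len(result))
    return result


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------


def name_regions(regions, comparative: bool = False) -> list[SweepRegion]:
    """Assign 'Peak <chrom>.<rank>' names by ascending position per
    chromosome ('Peak C<chrom>.<rank>' for comparative regions)."""
    counters: dict[str, int] = {}
    named = []
    for r in sorted(regions, key=lambda r: (r.chromosome, r.start_bp, r.end_bp)):
        m = re.search(r"(\d+)$", str(r.chromosome))
        label = m.group(1) if m else str(r.chromosome)
        counters[label] = counters.get(label, 0) + 1
        prefix = "Peak C" if comparative else "Peak "
        named.append(replace(r, name=f"{prefix}{label}.{counters[label]}"))
    return named
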