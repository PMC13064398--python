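"""Sliding windows over a SNP map and window summaries of per-locus metrics.

Two complementary schemes are supported, per chromosome:

* SNP-count windows: a fixed number of consecutive SNPs (default 100)
  shifted in steps of a fixed SNP count (default 10); only full windows are
  emitted, so trailing partial windows are dropped.
* physical windows: fixed width in bp (default 1 Mb) shifted by a fixed step
  (default 500 kb), anchored at bp 1; windows with fewer than ``min_loci``
  SNPs are dropped.

A :class:`WindowTrack` holds the per-window mean of a per-locus metric
together with the genome-wide mean over loci (not over windows, so the
overlapping-window baseline does not multiply-count loci) and the deviation
of each window from that baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DosagePanel, SnpMap, ValidationError

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = ["chromosome", "first", "last", "start_bp", "end_bp", "mid_bp", "n_loci"]


def _windows_frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    for col in WINDOW_COLUMNS[1:]:
        df[col] = df[col].astype(np.int64)
    return df


def make_snp_windows(snp_map: SnpMap, size: int = 100, step: int = 10) -> pd.DataFrame:
    """Windows of ``size`` consecutive SNPs shifted by ``step`` SNPs.

    Window bounds are the first/last member SNP positions.  ``first``/``last``
    index into the map's locus order.
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    if not 1 <= step <= size:
        raise ValueError("step must be in [1, size]")
    rows = []
    for chrom in snp_map.chromosome_names():
        sl = snp_map.chromosome_slice(chrom)
        pos = snp_map.positions[sl]
        n = len(pos)
        for start in range(0, n - size + 1, step):
            first, last = sl.start + start, sl.start + start + size - 1
            s_bp, e_bp = int(pos[start]), int(pos[start + size - 1])
            rows.append((chrom, first, last, s_bp, e_bp, (s_bp + e_bp) // 2, size))
    return _windows_frame(rows)


def make_physical_windows(
    snp_map: SnpMap,
    width_bp: int = 1_000_000,
    step_bp: int = 500_000,
    min_loci: int = 10,
) -> pd.DataFrame:
    """Fixed-width physical windows anchored at bp 1 of each chromosome.

    Anchors advance by ``step_bp`` up to the chromosome's last SNP; windows
    holding fewer than ``min_loci`` SNPs are dropped (count logged), guarding
    window means against sparse-window noise.
    """
    if step_bp > width_bp:
        raise ValueError("step_bp must be <= width_bp")
    rows = []
    n_dropped = 0
    for chrom in snp_map.chromosome_names():
        sl = snp_map.chromosome_slice(chrom)
        pos = snp_map.positions[sl]
        if len(pos) == 0:
            continue
        anchor = 1
        last_pos = int(pos[-1])
        while anchor <= last_pos:
            s_bp, e_bp = anchor, anchor + width_bp - 1
            first = int(np.searchsorted(pos, s_bp, side="left"))
            last = int(np.searchsorted(pos, e_bp, side="right")) - 1
            n = last - first + 1
            if n >= min_loci:
                rows.append(
                    (chrom, sl.start + first, sl.start + last, s_bp, e_bp, (s_bp + e_bp) // 2, n)
                )
            else:
                n_dropped += 1
            anchor += step_bp
    if n_dropped:
        logger.info("physical windows: dropped %d windows with < %d loci", n_dropped, min_loci)
    return _windows_frame(rows)


@dataclass
class WindowTrack:
    """Per-window means of one metric and deviations from the genome mean."""

    windows: pd.DataFrame
    window_mean: np.ndarray
    genome_mean: float
    metric: str = ""
    group: str = "all"

    @property
    def deviation(self) -> np.ndarray:
        return self.window_mean - self.genome_mean

    def chromosome_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.windows["chromosome"] == chrom).to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        df = self.windows.copy()
        df["metric"] = self.metric
        df["group"] = self.group
        df["window_mean"] = self.window_mean
        df["genome_mean"] = self.genome_mean
        df["deviation"] = self.deviation
        return df


def _segment_sums(arr: np.ndarray, first: np.ndarray, last: np.ndarray) -> np.ndarray:
    """Sums of ``arr[first[i] : last[i]+1]`` via one reduceat pass; agrees
    with a naive per-window loop to summation-order rounding (~1e-14)."""
    a = np.append(arr, 0.0)  # allow last+1 == len(arr) as a reduceat index
    idx = np.empty(2 * len(first), dtype=np.intp)
    idx[0::2] = first
    idx[1::2] = last + 1
    return np.add.reduceat(a, idx)[0::2]


def windowize(
    values: np.ndarray,
    snp_map: SnpMap,
    windows: pd.DataFrame,
    metric: str = "",
    group: str = "all",
) -> WindowTrack:
    """Summarise a per-locus metric into window means and deviations.

    The window mean averages non-missing member loci; an all-missing window
    is NaN and excluded downstream.  The genome mean averages all non-missing
    loci of the map, windowed or not.
    """
    values = np.asarray(values, dtype=np.float64)
    if len(values) != len(snp_map):
        raise ValidationError("values not aligned with SNP map")
    if len(windows) and int(windows["last"].max()) >= len(values):
        raise ValidationError("windows reference stale locus indices")
    finite = np.isfinite(values)
    v0 = np.where(finite, values, 0.0)
    first = windows["first"].to_numpy(dtype=np.intp)
    last = windows["last"].to_numpy(dtype=np.intp)
    if len(windows):
        sums = _segment_sums(v0, first, last)
        counts = _segment_sums(finite.astype(np.float64), first, last)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, sums / counts, np.nan)
    else:
        means = np.empty(0, dtype=np.float64)
    n_total = float(finite.sum())
    if n_total > 0:
        genome_mean = float(np.add.reduceat(np.append(v0, 0.0), [0])[0] / n_total)
    else:
        genome_mean = float("nan")
    return WindowTrack(windows=windows, window_mean=means, genome_mean=genome_mean,
                       metric=metric, group=group)


def ld_decay(
    panel: DosagePanel,
    snp_map: SnpMap,
    max_dist_bp: int,
    bin_bp: int = 10_000,
) -> pd.DataFrame:
    """Mean squared dosage correlation (r^2) in physical-distance bins.

    r^2 is the squared Pearson correlation of two loci's dosage vectors over
    the samples non-missing at both; pairs with fewer than 3 shared samples
    or zero variance are skipped.  Only same-chromosome pairs within
    ``max_dist_bp`` contribute.  Returns bin midpoint, mean r^2 and pair
    count per bin.
    """
    if panel.n_loci != len(snp_map):
        raise ValidationError("panel and SNP map have different locus counts")
    n_bins = max(1, int(np.ceil(max_dist_bp / bin_bp)))
    sum_r2 = np.zeros(n_bins)
    n_pairs = np.zeros(n_bins, dtype=np.int64)
    for chrom in snp_map.chromosome_names():
        sl = snp_map.chromosome_slice(chrom)
        pos = snp_map.positions[sl]
        X = panel.dosages[:, sl]
        M = np.isfinite(X).astype(np.float64)
        X0 = np.where(M > 0, X, 0.0)
        X2 = X0 * X0
        m = X.shape[1]
        for i in range(m - 1):
            jmax = int(np.searchsorted(pos, pos[i] + max_dist_bp, side="right"))
            if jmax <= i + 1:
                continue
            js = slice(i + 1, jmax)
            mi, xi = M[:, i], X0[:, i]
            n = mi @ M[:, js]
            with np.errstate(invalid="ignore", divide="ignore"):
                sx = xi @ M[:, js]
                sy = mi @ X0[:, js]
                sxy = xi @ X0[:, js]
                vx = (xi * xi) @ M[:, js] - sx * sx / n
                vy = mi @ X2[:, js] - sy * sy / n
                cov = sxy - sx * sy / n
                r2 = (cov * cov) / (vx * vy)
            valid = (n >= 3) & (vx > 1e-12) & (vy > 1e-12)
            if not valid.any():
                continue
            dist = pos[js] - pos[i]
            b = np.minimum((dist - 1) // bin_bp, n_bins - 1).astype(np.intp)
            np.add.at(sum_r2, b[valid], r2[valid])
            np.add.at(n_pairs, b[valid], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(n_pairs > 0, sum_r2 / n_pairs, np.nan)
    mids = (np.arange(n_bins) + 0.5) * bin_bp
    return pd.DataFrame({"bin_midpoint": mids, "mean_r2": mean_r2, "n_pairs": n_pairs})
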