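"""Accession-level bootstrap of windowed deviation tracks and rank-based
simultaneous confidence bands.

Windowed deviation profiles along a chromosome are heavily dependent
(overlapping windows, linked loci) and the sampling distribution of
dosage-based heterozygosity is awkward at modest sample sizes, so pointwise
intervals are both miscalibrated and massively multiple.  The band built
here is distribution-free: accessions (matrix rows) are resampled with
replacement — preserving LD, since loci are never resampled — and every
quantity (per-locus metric, window means, genome mean, deviations) is
recomputed per replicate.  For each chromosome the band takes, at every
window w, the symmetric order statistics [t_(k),w , t_(B+1-k),w] of the B
bootstrap deviations, with one shared rank depth k chosen as the largest
integer such that the fraction of bootstrap replicates lying inside the band
at *all* windows simultaneously is at least 1 - alpha.  The exhaustive
k-scan is the normative definition; ties are handled with closed (<=, >=)
comparisons, which can only raise coverage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import per_locus_metric
from .io import DosagePanel, SnpMap, ValidationError
from .windows import WindowTrack, windowize

logger = logging.getLogger(__name__)


@dataclass
class BootstrapTrack:
    """B x W matrix of bootstrap deviation rows over a window set."""

    windows: pd.DataFrame
    deviations: np.ndarray  # shape (B, W)
    metric: str
    group: str
    seed: int | None
    recenter: str = "replicate"

    @property
    def n_replicates(self) -> int:
        return self.deviations.shape[0]

    def chromosome_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.windows["chromosome"] == chrom).to_numpy())


@dataclass
class SimultaneousBand:
    """Per-window band limits with joint per-chromosome coverage >= 1-alpha."""

    windows: pd.DataFrame
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    k: dict[str, int]
    achieved_coverage: dict[str, float]

    def chromosome_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.windows["chromosome"] == chrom).to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        df = self.windows.copy()
        df["lower"] = self.lower
        df["upper"] = self.upper
        df["alpha"] = self.alpha
        df["k"] = [self.k[c] for c in df["chromosome"]]
        df["achieved_coverage"] = [self.achieved_coverage[c] for c in df["chromosome"]]
        return df


def bootstrap_deviations(
    panel: DosagePanel,
    snp_map: SnpMap,
    windows: pd.DataFrame,
    metric: str,
    B: int = 1000,
    seed: int | None = None,
    stratify_by_group: bool = False,
    recenter: str = "replicate",
    group: str | None = None,
) -> BootstrapTrack:
    """Bootstrap the windowed deviation track of one metric.

    Accessions are resampled with replacement, jointly for all loci.  With
    ``stratify_by_group`` the resampling happens within each group,
    preserving group sizes (use this when group tracks are compared);
    ``group`` restricts the whole computation to one group's samples.
    ``recenter='replicate'`` subtracts each replicate's own recomputed genome
    mean (the default); ``'point'`` subtracts the point-estimate genome mean.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if len(windows) == 0:
        raise ValidationError("no windows to bootstrap")
    if recenter not in ("replicate", "point"):
        raise ValueError("recenter must be 'replicate' or 'point'")
    rng = np.random.default_rng(seed)
    base_idx = panel.sample_indices(group)
    labels = panel.group_labels()[base_idx]
    strata = (
        [base_idx[labels == g] for g in dict.fromkeys(labels)]
        if stratify_by_group
        else [base_idx]
    )
    point_mean = None
    if recenter == "point":
        values = per_locus_metric(panel.dosages[base_idx], metric, panel.ploidy)
        point_mean = windowize(values, snp_map, windows).genome_mean

    rows = np.empty((B, len(windows)), dtype=np.float64)
    for b in range(B):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        values = per_locus_metric(panel.dosages[idx], metric, panel.ploidy)
        track = windowize(values, snp_map, windows)
        baseline = track.genome_mean if recenter == "replicate" else point_mean
        rows[b] = track.window_mean - baseline
    return BootstrapTrack(
        windows=windows, deviations=rows, metric=metric,
        group=group or "all", seed=seed, recenter=recenter,
    )


def _rank_depths(block: np.ndarray) -> np.ndarray:
    """Per-replicate simultaneous rank depth over a B x w block.

    For element x in a column with B sorted values, x lies inside the closed
    band [t_(k), t_(B+1-k)] iff k <= min(#{values <= x}, #{values >= x});
    the replicate's depth is the minimum of that quantity over windows.
    """
    B, w = block.shape
    depth = np.full(B, B, dtype=np.int64)
    for j in range(w):
        col = block[:, j]
        order = np.sort(col)
        c_le = np.searchsorted(order, col, side="right")
        c_ge = B - np.searchsorted(order, col, side="left")
        depth = np.minimum(depth, np.minimum(c_le, c_ge))
    return depth


def select_rank_depth(depths: np.ndarray, B: int, alpha: float) -> tuple[int, float]:
    """Largest k with simultaneous coverage >= 1-alpha (k capped at (B+1)//2).

    Returns (k, achieved coverage).  Falls back to k=1 when even the
    outermost band misses the target (B too small), with a warning.
    """
    k_cap = (B + 1) // 2
    best_k, best_cov = 1, float(np.mean(depths >= 1))
    for k in range(k_cap, 0, -1):
        cov = float(np.mean(depths >= k))
        if cov >= 1.0 - alpha:
            return k, cov
    warnings.warn(
        f"rank band: coverage {best_cov:.3f} < {1 - alpha:.3f} even at k=1; increase B",
        stacklevel=2,
    )
    return best_k, best_cov


def scs_rank_band(track: BootstrapTrack, alpha: float = 0.05) -> SimultaneousBand:
    """Symmetric rank-depth simultaneous band, per chromosome.

    Requires B >= ceil(2/alpha) so that a valid depth can exist, and finite
    bootstrap rows throughout.
    """
    B = track.n_replicates
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if B < int(np.ceil(2.0 / alpha)):
        raise ValueError(f"B={B} too small for alpha={alpha}; need B >= {int(np.ceil(2 / alpha))}")
    if not np.isfinite(track.deviations).all():
        raise ValidationError("non-finite bootstrap deviations; check for all-missing windows")
    W = track.deviations.shape[1]
    lower = np.empty(W)
    upper = np.empty(W)
    k_by_chrom: dict[str, int] = {}
    cov_by_chrom: dict[str, float] = {}
    for chrom in dict.fromkeys(track.windows["chromosome"]):
        cols = track.chromosome_indices(chrom)
        block = track.deviations[:, cols]
        depths = _rank_depths(block)
        k, cov = select_rank_depth(depths, B, alpha)
        order = np.sort(block, axis=0)
        lower[cols] = order[k - 1]
        upper[cols] = order[B - k]
        k_by_chrom[chrom] = k
        cov_by_chrom[chrom] = cov
    return SimultaneousBand(
        windows=track.windows, lower=lower, upper=upper,
        alpha=alpha, k=k_by_chrom, achieved_coverage=cov_by_chrom,
    )


def band_coverage(track: BootstrapTrack, band: SimultaneousBand, chrom: str) -> float:
    """Fraction of bootstrap rows inside the band at every window of a
    chromosome simultaneously (diagnostic / test helper)."""
    cols = track.chromosome_indices(chrom)
    dev = track.deviations[:, cols]
    inside = (dev >= band.lower[cols]) & (dev <= band.upper[cols])
    return float(inside.all(axis=1).mean())
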