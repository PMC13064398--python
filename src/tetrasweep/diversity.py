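"""Per-locus diversity metrics from allele dosages.

For a biallelic locus genotyped as dosages d in {0..ploidy} over n
non-missing samples:

    p  = (sum of dosages) / (ploidy * n)        alternative-allele frequency
    Ho = n_het / n                              n_het: dosages in 1..ploidy-1
    He = 1 - (p^2 + q^2),  q = 1 - p            expected heterozygosity
    pi = n/(n-1) * 2 p (1-p)                    unbiased per-site diversity

so pi = He * n/(n-1) identically.  Missing calls are excluded from every
count; loci where a quantity is undefined (n = 0, or n < 2 for pi) carry NaN
and propagate as missing through window means, never as 0.

Between two groups A and B the comparative metrics are

    pi_ratio = pi_A / pi_B          (NaN when pi_B = 0)
    delta_Ho = Ho_A - Ho_B,  delta_He = He_A - He_B
    FST      = (H_T - H_S) / H_T    (NaN when H_T = 0)

with H_T = 2 p_bar (1 - p_bar) from the unweighted mean frequency
p_bar = (p_A + p_B)/2 and H_S the average within-group expected
heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DosagePanel, SnpMap, ValidationError

#: Metric names accepted by the within-group scan machinery.
WITHIN_GROUP_METRICS = ("ho", "he", "pi")
#: Metric names produced by the two-group comparison.
COMPARATIVE_METRICS = ("delta_ho", "fst", "pi_ratio")


@dataclass
class LocusStats:
    """Vectorised per-locus statistics (one entry per locus)."""

    p: np.ndarray
    q: np.ndarray
    n: np.ndarray
    n_het: np.ndarray
    ho: np.ndarray
    he: np.ndarray
    pi: np.ndarray


def locus_stats(dosages: np.ndarray, ploidy: int) -> LocusStats:
    """Compute p, Ho, He and pi for every locus of a samples x loci matrix.

    Accepts a single column (1-D) or a full matrix; missing entries are NaN.
    All-missing loci yield NaN in every field.
    """
    if ploidy < 2:
        raise ValueError("ploidy must be >= 2")
    d = np.atleast_2d(np.asarray(dosages, dtype=np.float64))
    if d.shape[0] == 1 and np.ndim(dosages) == 1:
        d = d.T
    finite = np.isfinite(d)
    n = finite.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        total = np.where(finite, d, 0.0).sum(axis=0)
        p = np.where(n > 0, total / (ploidy * n), np.nan)
        q = 1.0 - p
        n_het = (finite & (d >= 1) & (d <= ploidy - 1)).sum(axis=0).astype(np.float64)
        ho = np.where(n > 0, n_het / n, np.nan)
        he = 1.0 - (p**2 + q**2)
        pi = np.where(n >= 2, he * (n / np.maximum(n - 1.0, 1.0)), np.nan)
    return LocusStats(p=p, q=q, n=n, n_het=n_het, ho=ho, he=he, pi=pi)


def per_locus_metric(
    dosages: np.ndarray, metric: str, ploidy: int
) -> np.ndarray:
    """One within-group metric ('ho', 'he' or 'pi') per locus."""
    if metric not in WITHIN_GROUP_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {WITHIN_GROUP_METRICS}")
    stats = locus_stats(dosages, ploidy)
    return getattr(stats, metric)


@dataclass
class GroupComparison:
    """Per-locus comparative metrics between two sample groups."""

    group_a: str
    group_b: str
    p_a: np.ndarray
    p_b: np.ndarray
    ho_a: np.ndarray
    ho_b: np.ndarray
    he_a: np.ndarray
    he_b: np.ndarray
    pi_a: np.ndarray
    pi_b: np.ndarray
    pi_ratio: np.ndarray
    delta_ho: np.ndarray
    delta_he: np.ndarray
    p_bar: np.ndarray
    h_t: np.ndarray
    h_s: np.ndarray
    fst: np.ndarray

    def metric(self, name: str) -> np.ndarray:
        if name not in COMPARATIVE_METRICS + ("delta_he",):
            raise ValueError(f"unknown comparative metric {name!r}")
        return getattr(self, name)


def group_comparison(
    panel: DosagePanel,
    group_a: str,
    group_b: str,
    snp_map: SnpMap | None = None,
    weighted: bool = False,
) -> GroupComparison:
    """Per-locus differentiation and diversity contrasts between two groups.

    ``weighted=True`` averages H_S (and p_bar) by group sample size instead
    of the default unweighted two-group mean.  FST is NaN where H_T = 0
    (monomorphic across both groups) and pi_ratio is NaN where pi_B = 0;
    such loci are excluded from window means downstream rather than set to 0.
    """
    if snp_map is not None and len(snp_map) != panel.n_loci:
        raise ValidationError("SNP map and panel have different locus counts")
    idx_a = panel.sample_indices(group_a)
    idx_b = panel.sample_indices(group_b)
    sa = locus_stats(panel.dosages[idx_a], panel.ploidy)
    sb = locus_stats(panel.dosages[idx_b], panel.ploidy)
    if weighted:
        wa = sa.n / np.maximum(sa.n + sb.n, 1.0)
    else:
        wa = np.full_like(sa.p, 0.5)
    wb = 1.0 - wa
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = wa * sa.p + wb * sb.p
        h_t = 2.0 * p_bar * (1.0 - p_bar)
        h_s = wa * sa.he + wb * sb.he
        # H_T - H_S == 2*wa*wb*(p_A - p_B)^2 algebraically; this form cannot
        # go negative by cancellation when p_A ~ p_B
        numerator = 2.0 * wa * wb * (sa.p - sb.p) ** 2
        fst = np.where(h_t > 0, numerator / h_t, np.nan)
        pi_ratio = np.where(sb.pi > 0, sa.pi / sb.pi, np.nan)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        p_a=sa.p, p_b=sb.p,
        ho_a=sa.ho, ho_b=sb.ho,
        he_a=sa.he, he_b=sb.he,
        pi_a=sa.pi, pi_b=sb.pi,
        pi_ratio=pi_ratio,
        delta_ho=sa.ho - sb.ho,
        delta_he=sa.he - sb.he,
        p_bar=p_bar, h_t=h_t, h_s=h_s, fst=fst,
    )
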