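"""Seeded simulator for tetraploid dosage panels with known sweep regions.

The generator mirrors the structure of an array-genotyped cultivated-rose
panel: seven chromosomes, ~87 SNPs per Mb, two accession groups of 95 and
190 samples, tetraploid dosages (0-4) and around 8% missing calls.  Each
sample's dosage at a locus is drawn binomially with size = ploidy from the
group's per-locus allele frequency — the random-bivalent-pairing
idealisation of an autotetraploid, which is the minimal model for unphased
array dosages.

Selective sweeps are injected by moving the *generating* allele frequency
toward the nearer of 0/1 inside the sweep interval, for the affected groups
only.  Acting on frequencies rather than on drawn dosages makes the expected
diversity reduction analytically known, so downstream callers can be tested
against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DosagePanel, SnpMap, ValidationError

ALL_GROUPS = "all"


@dataclass(frozen=True)
class TruthSweep:
    """Ground-truth sweep interval used by the generator.

    ``intensity`` is the fraction by which the generating frequency is pushed
    toward fixation inside the interval: p <- p*(1-intensity) for p <= 0.5,
    symmetric toward 1 otherwise.  ``intensity=1`` fixes every locus.
    """

    chromosome: str
    start_bp: int
    end_bp: int
    affected_groups: tuple[str, ...] | str = ALL_GROUPS
    intensity: float = 0.8

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("sweep start_bp > end_bp")
        if not 0 < self.intensity <= 1:
            raise ValueError("sweep intensity must be in (0, 1]")

    def affects(self, group: str) -> bool:
        if self.affected_groups == ALL_GROUPS:
            return True
        return group in self.affected_groups

    @property
    def center_bp(self) -> int:
        return (self.start_bp + self.end_bp) // 2


@dataclass(frozen=True)
class SimConfig:
    """Panel-scale parameters of the simulator.

    Defaults emulate the study panel the package targets: 7 chromosomes,
    87 SNPs/Mb, 95 + 190 accessions in two groups, tetraploid dosages,
    ancestral frequencies uniform on [0.05, 0.95], ~8% missing calls and a
    mild per-locus between-group frequency jitter that yields a nonzero
    background FST.  Chromosomes default to 10 Mb, the desk-scale genome used
    throughout the examples and tests.
    """

    n_chromosomes: int = 7
    chrom_length_bp: int = 10_000_000
    snps_per_mb: float = 87.0
    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"cut": 95, "garden": 190}
    )
    ploidy: int = 4
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.08
    group_divergence: float = 0.05
    sweep_specs: tuple[TruthSweep, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1 or self.ploidy < 2:
            raise ValueError("counts must be >= 1 and ploidy >= 2")
        if any(n < 1 for n in self.n_samples_per_group.values()):
            raise ValueError("each group needs >= 1 sample")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        lo, hi = self.base_freq_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("base_freq_range must satisfy 0 <= lo <= hi <= 1")

    def chromosome_names(self) -> list[str]:
        return [f"Chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SimResult:
    """Simulated panel plus the generator's internal truth.

    Iterating yields ``(panel, snp_map, sweeps)`` so the result unpacks as a
    triple; ``group_freqs`` keeps the generating per-locus frequencies per
    group for oracle computations in tests.
    """

    panel: DosagePanel
    snp_map: SnpMap
    sweeps: list[TruthSweep]
    group_freqs: dict[str, np.ndarray]
    base_freqs: np.ndarray

    def __iter__(self):
        return iter((self.panel, self.snp_map, self.sweeps))


def _sweep_shift(p: np.ndarray, intensity: float, toward_zero: np.ndarray) -> np.ndarray:
    """Push frequencies toward 0 or 1 by ``intensity`` (direction per locus)."""
    return np.where(toward_zero, p * (1.0 - intensity), 1.0 - (1.0 - p) * (1.0 - intensity))


def simulate_panel(config: SimConfig) -> SimResult:
    """Simulate a dosage panel, its SNP map and the injected truth sweeps.

    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = config.chromosome_names()
    groups = list(config.n_samples_per_group)

    for sweep in config.sweep_specs:
        if sweep.chromosome not in chrom_names:
            raise ValidationError(f"sweep on unknown chromosome {sweep.chromosome!r}")
        if sweep.end_bp > config.chrom_length_bp or sweep.start_bp < 1:
            raise ValidationError(f"sweep outside chromosome bounds: {sweep}")
        if sweep.affected_groups != ALL_GROUPS:
            unknown = set(sweep.affected_groups) - set(groups)
            if unknown:
                raise ValidationError(f"sweep references unknown groups {sorted(unknown)}")

    n_per_chrom = max(1, int(round(config.snps_per_mb * config.chrom_length_bp / 1e6)))
    chroms, positions = [], []
    for chrom in chrom_names:
        pos = np.sort(rng.integers(1, config.chrom_length_bp + 1, size=n_per_chrom))
        for i in range(1, len(pos)):  # resolve collisions with +1 bp shifts
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        chroms.extend([chrom] * len(pos))
        positions.append(pos)
    positions = np.concatenate(positions)
    chroms = np.asarray(chroms, dtype=object)
    m = len(positions)
    locus_ids = np.asarray(
        [f"{c}_snp{i}" for i, c in enumerate(chroms)], dtype=object
    )
    snp_map = SnpMap(locus_ids, chroms, positions)

    lo, hi = config.base_freq_range
    base = rng.uniform(lo, hi, size=m)

    # per-group frequencies: base + clipped normal jitter, then sweep shifts
    group_freqs: dict[str, np.ndarray] = {}
    for g in groups:
        if config.group_divergence > 0:
            jitter = rng.normal(0.0, config.group_divergence, size=m)
            p = np.clip(base + jitter, 0.01, 0.99)
        else:
            p = base.copy()
        group_freqs[g] = p
    for sweep in config.sweep_specs:
        sl = snp_map.chromosome_slice(sweep.chromosome)
        inside = slice(
            sl.start + int(np.searchsorted(positions[sl], sweep.start_bp, side="left")),
            sl.start + int(np.searchsorted(positions[sl], sweep.end_bp, side="right")),
        )
        # one swept haplotype per locus: every affected group moves toward the
        # boundary nearer to the ancestral (base) frequency
        toward_zero = base[inside] <= 0.5
        for g in groups:
            if sweep.affects(g):
                p = group_freqs[g]
                p[inside] = _sweep_shift(p[inside], sweep.intensity, toward_zero)

    # dosages per sample: binomial(ploidy, group frequency)
    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    blocks = []
    for g in groups:
        n = config.n_samples_per_group[g]
        ids = [f"{g}_{i:03d}" for i in range(n)]
        sample_ids.extend(ids)
        group_of.update({s: g for s in ids})
        blocks.append(
            rng.binomial(config.ploidy, group_freqs[g][None, :], size=(n, m)).astype(np.float64)
        )
    dosages = np.vstack(blocks)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    panel = DosagePanel(sample_ids, dosages, ploidy=config.ploidy, groups=group_of)
    return SimResult(panel, snp_map, list(config.sweep_specs), group_freqs, base)


def simulate_gene_annotations(
    snp_map: SnpMap, n_genes: int, n_terms: int, seed: int,
    mean_terms_per_gene: float = 2.0,
) -> tuple["pd.DataFrame", "pd.DataFrame"]:
    """Place genes uniformly over the map's chromosomes and assign terms.

    Gene lengths are uniform on 1-20 kb; each gene receives a Poisson number
    of distinct terms (mean ``mean_terms_per_gene``, possibly zero) drawn
    uniformly from the term universe.  Returns ``(gene_table, gene2term)``
    frames matching the on-disk formats in :mod:`tetrasweep.io`.
    """
    import pandas as pd

    if n_genes < 1 or n_terms < 1:
        raise ValueError("n_genes and n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_names = snp_map.chromosome_names()
    spans = {
        c: int(snp_map.positions[snp_map.chromosome_slice(c)].max())
        for c in chrom_names
    }
    chrom_choice = [chrom_names[i] for i in rng.integers(0, len(chrom_names), size=n_genes)]
    rows = []
    for i, chrom in enumerate(chrom_choice):
        length = int(rng.integers(1_000, 20_001))
        start = int(rng.integers(1, max(2, spans[chrom] - length)))
        rows.append((f"gene{i:05d}", chrom, start, start + length - 1))
    genes = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start_bp", "end_bp"])
    genes = genes.sort_values(["chromosome", "start_bp"], kind="stable").reset_index(drop=True)

    terms = [f"TERM:{i:04d}" for i in range(n_terms)]
    pairs = []
    for gene_id in genes["gene_id"]:
        k = min(int(rng.poisson(mean_terms_per_gene)), n_terms)
        for t in rng.choice(n_terms, size=k, replace=False):
            pairs.append((gene_id, terms[int(t)]))
    gene2term = pd.DataFrame(pairs, columns=["gene_id", "term_id"])
    return genes, gene2term
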