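"""Readers and writers for dosage panels, SNP maps, gene tables and sweep regions.

The interchange format for genotypes is a plain dosage TSV::

    marker_id  chrom  pos  sample1  sample2 ...

with integer allele dosages in ``0..ploidy`` or the literal ``NA`` for a
missing call.  Array-based tetraploid dosage calling has no single standard
container format, so this flat table is the primary on-disk representation;
a VCF reader (``FORMAT/DS`` or ``GT``) is provided for convenience.

Coordinates are 1-based inclusive everywhere inside the package; BED
conversion (0-based half-open) happens only at the write boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel used for missing dosages in the in-memory float matrix.
MISSING = np.nan

DEFAULT_GROUP = "all"


class DosageParseError(ValueError):
    """Raised when a dosage table cell cannot be interpreted."""


class ValidationError(ValueError):
    """Raised when a panel, map or region violates a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SnpMap:
    """Ordered locus coordinates: id, chromosome and 1-based bp position.

    Loci are sorted by (chromosome, position) with strictly increasing
    positions within each chromosome, so each chromosome occupies one
    contiguous index range.
    """

    locus_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if not (len(self.locus_ids) == len(self.chromosomes) == len(self.positions)):
            raise ValidationError("locus_ids, chromosomes and positions must have equal length")
        ids, counts = np.unique(self.locus_ids, return_counts=True)
        if (counts > 1).any():
            dupes = ", ".join(map(str, ids[counts > 1][:5]))
            raise ValidationError(f"duplicate locus ids: {dupes}")
        for chrom in self.chromosome_names():
            pos = self.positions[self.chromosome_slice(chrom)]
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValidationError(f"positions not strictly increasing on {chrom}")

    def __len__(self) -> int:
        return len(self.locus_ids)

    def chromosome_names(self) -> list[str]:
        """Chromosome labels in map order (sorted lexicographically on read)."""
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(c)
        return list(seen)

    def chromosome_slice(self, chrom: str) -> slice:
        """Contiguous index range of a chromosome's loci."""
        idx = np.flatnonzero(self.chromosomes == chrom)
        if len(idx) == 0:
            return slice(0, 0)
        if idx[-1] - idx[0] + 1 != len(idx):
            raise ValidationError(f"loci of {chrom} are not contiguous; sort the map first")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, keep: np.ndarray) -> "SnpMap":
        return SnpMap(self.locus_ids[keep], self.chromosomes[keep], self.positions[keep])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.locus_ids,
                "chrom": self.chromosomes,
                "pos": self.positions,
            }
        )


@dataclass
class DosagePanel:
    """Accessions x loci integer dosage matrix with group labels.

    ``dosages`` is a float matrix (samples x loci) holding integers in
    ``0..ploidy`` and ``NaN`` for missing calls, which keeps missing distinct
    from dosage 0 while allowing vectorised arithmetic.
    """

    sample_ids: list[str]
    dosages: np.ndarray
    ploidy: int = 4
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.sample_ids):
            raise ValidationError("dosage matrix must be samples x loci")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not self.groups:
            self.groups = {s: DEFAULT_GROUP for s in self.sample_ids}
        missing_groups = [s for s in self.sample_ids if s not in self.groups]
        if missing_groups:
            raise ValidationError(f"samples without group label: {missing_groups[:5]}")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and ((finite < 0) | (finite > self.ploidy)).any():
            raise ValidationError(f"dosages outside 0..{self.ploidy}")
        if finite.size and not np.array_equal(finite, np.round(finite)):
            raise ValidationError("dosages must be integers (or NA)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def group_labels(self) -> np.ndarray:
        return np.array([self.groups[s] for s in self.sample_ids], dtype=object)

    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.groups[s])
        return list(seen)

    def sample_indices(self, group: str | None = None) -> np.ndarray:
        """Row indices of a group's samples (all samples when group is None)."""
        if group is None:
            return np.arange(self.n_samples)
        labels = self.group_labels()
        idx = np.flatnonzero(labels == group)
        if len(idx) == 0:
            raise ValidationError(f"unknown or empty group: {group!r}")
        return idx

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_loci(self, keep: np.ndarray) -> "DosagePanel":
        return replace(self, dosages=self.dosages[:, keep])

    def subset_samples(self, idx: np.ndarray) -> "DosagePanel":
        ids = [self.sample_ids[i] for i in idx]
        return DosagePanel(ids, self.dosages[idx], self.ploidy,
                           {s: self.groups[s] for s in ids})


# ---------------------------------------------------------------------------
# dosage TSV
# ---------------------------------------------------------------------------


def read_dosage_tsv(path, ploidy: int | None = None) -> tuple[DosagePanel, SnpMap]:
    """Read a dosage TSV into a (panel, map) pair, sorted by (chrom, pos).

    ``ploidy`` defaults to the maximum observed dosage (at least 2); pass it
    explicitly for panels where the top dosage class is absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    required = ["marker_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise DosageParseError(f"dosage TSV must start with columns {required}, got {list(df.columns[:3])}")
    sample_cols = list(df.columns[3:])
    if not sample_cols:
        raise DosageParseError("dosage TSV has no sample columns")

    raw = df[sample_cols]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    bad = np.isnan(values) & ~raw.isna().to_numpy()
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise DosageParseError(
            f"non-integer dosage cell at marker {df['marker_id'].iloc[r]!r}, "
            f"sample {sample_cols[c]!r}: {raw.iloc[r, c]!r}"
        )
    finite = values[np.isfinite(values)]
    if finite.size and not np.array_equal(finite, np.round(finite)):
        raise DosageParseError("fractional dosage values are not allowed")

    if not df.sort_values(["chrom", "pos"], kind="stable").index.equals(df.index):
        logger.info("dosage TSV not sorted by (chrom, pos); sorting")
    order = np.lexsort((df["pos"].to_numpy(), df["chrom"].to_numpy()))
    df = df.iloc[order]
    values = values[order]

    if ploidy is None:
        ploidy = int(max(2, np.nanmax(values))) if finite.size else 2
    snp_map = SnpMap(df["marker_id"].to_numpy(), df["chrom"].to_numpy(), df["pos"].to_numpy())
    panel = DosagePanel(sample_cols, values.T, ploidy=ploidy)
    return panel, snp_map


def write_dosage_tsv(panel: DosagePanel, snp_map: SnpMap, path) -> None:
    df = snp_map.to_dataframe()
    mat = panel.dosages.T
    for j, sample in enumerate(panel.sample_ids):
        col = pd.array(mat[:, j], dtype="float64")
        df[sample] = pd.Series(col).astype("Int64")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_groups_tsv(path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>group`` table (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DosageParseError("group table needs two columns: sample_id, group")
    if list(df.iloc[0]) [:2] == ["sample_id", "group"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_groups_tsv(groups: dict[str, str], path) -> None:
    pd.DataFrame(sorted(groups.items()), columns=["sample_id", "group"]).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# missingness filter
# ---------------------------------------------------------------------------


def filter_missingness(
    panel: DosagePanel,
    snp_map: SnpMap,
    max_missing: float = 0.10,
    per_group: bool = False,
) -> tuple[DosagePanel, SnpMap, int]:
    """Drop loci whose missing-call fraction strictly exceeds ``max_missing``.

    A locus missing in exactly ``max_missing`` of the samples is kept: the
    rule is "more than", not "at least".  Samples are never removed.  By
    default the fraction is taken across the full panel; with ``per_group``
    a locus is dropped as soon as it exceeds the threshold within any single
    group.
    """
    if not 0 <= max_missing < 1:
        raise ValueError("max_missing must be in [0, 1)")
    # compare counts, not float fractions, so 1/10 vs 0.10 is exact
    if per_group:
        keep = np.ones(panel.n_loci, dtype=bool)
        for group in panel.group_names():
            idx = panel.sample_indices(group)
            n_missing = np.isnan(panel.dosages[idx]).sum(axis=0)
            keep &= n_missing <= max_missing * len(idx) + 1e-9
    else:
        n = panel.n_samples
        n_missing = np.isnan(panel.dosages).sum(axis=0)
        keep = n_missing <= max_missing * n + 1e-9
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("missingness filter (> %.2f): removed %d of %d loci", max_missing, n_removed, len(snp_map))
    return panel.subset_loci(keep), snp_map.subset(keep), n_removed


# ---------------------------------------------------------------------------
# gene tables and gene -> term maps
# ---------------------------------------------------------------------------


def read_gene_table(path) -> pd.DataFrame:
    """Read gene intervals from BED4 or GFF3 into 1-based inclusive coordinates.

    Returns a frame with columns ``gene_id, chromosome, start_bp, end_bp``
    (plus ``description`` when present).  For GFF3 only ``gene`` features are
    kept and the id comes from the ``ID=`` attribute.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID") or attrs.get("Name")
                if gene_id is None:
                    raise ValidationError(f"GFF3 gene feature without ID: {line.strip()!r}")
                rows.append((gene_id, f[0], int(f[3]), int(f[4])))
        df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start_bp", "end_bp"])
    else:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chromosome", "start", "end", "gene_id"],
            usecols=[0, 1, 2, 3], dtype={0: str, 3: str},
        )
        df = pd.DataFrame(
            {
                "gene_id": df["gene_id"],
                "chromosome": df["chromosome"],
                "start_bp": df["start"].astype(np.int64) + 1,  # BED is 0-based half-open
                "end_bp": df["end"].astype(np.int64),
            }
        )
    if (df["start_bp"] > df["end_bp"]).any():
        raise ValidationError("gene with start_bp > end_bp")
    if df["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene ids in gene table")
    return df


def write_gene_table_bed(genes: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": genes["chromosome"],
            "start": genes["start_bp"].astype(np.int64) - 1,
            "end": genes["end_bp"].astype(np.int64),
            "name": genes["gene_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_gene2term_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DosageParseError("gene2term table needs two columns: gene_id, term_id")
    if list(df.iloc[0])[:2] == ["gene_id", "term_id"]:
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "term_id"]
    return df.reset_index(drop=True)


def write_gene2term_tsv(gene2term: pd.DataFrame, path) -> None:
    gene2term.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# sweep-region report files
# ---------------------------------------------------------------------------

_REGION_TSV_COLUMNS = [
    "name", "chromosome", "start_bp", "end_bp", "peak_mid_bp",
    "metrics", "direction", "provenance", "band_significant",
]


def write_regions(regions, path, dialect: str = "tsv") -> None:
    """Write sweep regions as 1-based TSV or 0-based half-open BED.

    The TSV dialect round-trips through :func:`read_regions_tsv`; BED keeps
    only (chrom, start, end, name) and shifts start by -1.
    """
    from .calling import SweepRegion  # local import: avoid cycle

    regions = list(regions)
    if dialect == "tsv":
        rows = []
        for r in regions:
            rows.append(
                {
                    "name": r.name,
                    "chromosome": r.chromosome,
                    "start_bp": r.start_bp,
                    "end_bp": r.end_bp,
                    "peak_mid_bp": r.peak_mid_bp,
                    "metrics": ",".join(sorted(r.metrics)),
                    "direction": r.direction,
                    "provenance": r.provenance,
                    "band_significant": "" if r.band_significant is None else str(r.band_significant),
                }
            )
        with open(path, "w") as fh:
            fh.write("# tetrasweep regions; coordinates 1-based inclusive\n")
            pd.DataFrame(rows, columns=_REGION_TSV_COLUMNS).to_csv(fh, sep="\t", index=False)
    elif dialect == "bed":
        with open(path, "w") as fh:
            fh.write('track name="tetrasweep_regions" description="0-based half-open"\n')
            for r in regions:
                fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{r.name or '.'}\n")
    else:
        raise ValueError(f"unknown region dialect: {dialect!r}")


def read_regions_tsv(path):
    """Inverse of :func:`write_regions` for the TSV dialect."""
    from .calling import SweepRegion

    df = pd.read_csv(path, sep="\t", comment="#")
    regions = []
    for row in df.itertuples(index=False):
        band = None
        if isinstance(row.band_significant, str):
            band = row.band_significant == "True"
        elif isinstance(row.band_significant, (bool, np.bool_)):
            band = bool(row.band_significant)
        metrics = set() if pd.isna(row.metrics) else set(str(row.metrics).split(","))
        regions.append(
            SweepRegion(
                chromosome=str(row.chromosome),
                start_bp=int(row.start_bp),
                end_bp=int(row.end_bp),
                peak_mid_bp=int(row.peak_mid_bp),
                metrics=metrics,
                direction=str(row.direction),
                provenance=str(row.provenance),
                band_significant=band,
                name="" if pd.isna(row.name) else str(row.name),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# optional VCF ingest
# ---------------------------------------------------------------------------


def read_vcf_dosages(path, ploidy: int = 4) -> tuple[DosagePanel, SnpMap]:
    """Read dosages from a VCF: FORMAT/DS rounded, else GT alt-allele counts.

    Requires :mod:`cyvcf2`.  Multi-allelic records are skipped with a notice.
    VCF writing is deliberately not supported.
    """
    from cyvcf2 import VCF  # imported lazily: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, cols = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        try:
            ds = np.asarray(var.format("DS"), dtype=np.float64).reshape(-1)
            col = np.round(ds)
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.genotype.array(), dtype=np.float64)
            alleles = gt[:, :-1]  # last column is phasing
            col = np.where((alleles < 0).any(axis=1), np.nan, (alleles == 1).sum(axis=1))
        col = np.where(np.isfinite(col), np.clip(col, 0, ploidy), np.nan)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        cols.append(col)
    if n_skipped:
        logger.info("skipped %d multi-allelic VCF records", n_skipped)
    if not cols:
        raise ValidationError("no usable biallelic records in VCF")
    order = np.lexsort((np.asarray(poss), np.asarray(chroms, dtype=object)))
    mat = np.stack(cols, axis=1)[:, order]
    snp_map = SnpMap(np.asarray(ids, dtype=object)[order],
                     np.asarray(chroms, dtype=object)[order],
                     np.asarray(poss)[order])
    return DosagePanel(samples, mat, ploidy=ploidy), snp_map
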