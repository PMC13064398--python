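"""Gene overlap and term enrichment for called sweep regions.

Genes are assigned to a region when their 1-based inclusive intervals share
at least one bp.  Term over-representation among a region's genes relative
to the genome-wide background uses the one-sided Fisher exact test
(hypergeometric upper tail), with Benjamini-Hochberg correction across the
terms tested within each region.  Depletion and term-hierarchy handling are
out of scope: the term universe is exactly what the gene-to-term map
supplies.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "term_id", "k", "K", "m", "M", "fold_enrichment", "p_value", "p_adjusted",
]


def genes_in_regions(genes: pd.DataFrame, regions) -> dict[str, list[str]]:
    """Map each region to the genes overlapping it by >= 1 bp.

    ``genes`` needs columns gene_id, chromosome, start_bp, end_bp (1-based
    inclusive).  Regions on chromosomes absent from the gene table get an
    empty list and a logged warning.  Keys are region names (or
    ``chrom:start-end`` when unnamed); a gene may appear under several
    regions.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        trees.setdefault(str(row.chromosome), IntervalTree()).addi(
            int(row.start_bp), int(row.end_bp) + 1, str(row.gene_id)
        )
    out: dict[str, list[str]] = {}
    for r in regions:
        key = r.name or f"{r.chromosome}:{r.start_bp}-{r.end_bp}"
        tree = trees.get(r.chromosome)
        if tree is None:
            logger.warning("no genes annotated on chromosome %s", r.chromosome)
            out[key] = []
            continue
        hits = tree.overlap(r.start_bp, r.end_bp + 1)
        out[key] = sorted(iv.data for iv in hits)
    return out


def _terms_by_gene(gene2term: pd.DataFrame) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(gene2term["gene_id"], gene2term["term_id"]):
        mapping.setdefault(str(gene), set()).add(str(term))
    return mapping


def fisher_enrichment(
    sweep_genes, background_genes, gene2term: pd.DataFrame
) -> pd.DataFrame:
    """Term over-representation of ``sweep_genes`` against the background.

    For a term annotated on m of M background genes and k of the K sweep
    genes, the p-value is the upper hypergeometric tail
    P[X >= k | M, m, K] (one-sided Fisher); BH adjustment runs across all
    terms tested here (terms with k = 0 are skipped).  Returns a frame
    sorted by adjusted then raw p-value.
    """
    background = sorted(set(map(str, background_genes)))
    sweep = sorted(set(map(str, sweep_genes)))
    if not background:
        raise ValidationError("empty background gene set")
    if not set(sweep) <= set(background):
        raise ValidationError("sweep genes must be a subset of the background")
    terms = _terms_by_gene(gene2term)
    if not terms:
        raise ValidationError("gene2term map supplies no terms")

    M, K = len(background), len(sweep)
    term_bg: dict[str, int] = {}
    term_fg: dict[str, int] = {}
    sweep_set = set(sweep)
    for gene in background:
        for t in terms.get(gene, ()):
            term_bg[t] = term_bg.get(t, 0) + 1
            if gene in sweep_set:
                term_fg[t] = term_fg.get(t, 0) + 1

    rows = []
    for t in sorted(term_fg):
        k, m = term_fg[t], term_bg[t]
        table = [[k, K - k], [m - k, (M - K) - (m - k)]]
        p = float(fisher_exact(table, alternative="greater")[1])
        fold = (k / K) / (m / M)
        rows.append((t, k, K, m, M, fold, p))
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p_adjusted", "p_value", "term_id"], kind="stable")
    else:
        df["p_adjusted"] = np.empty(0)
    return df.reset_index(drop=True)


def enrich_regions(
    regions, genes: pd.DataFrame, gene2term: pd.DataFrame
) -> pd.DataFrame:
    """Per-region enrichment table (BH within each region).

    The background is every gene in the supplied table; regions without
    genes or without annotated genes yield no rows.
    """
    hits = genes_in_regions(genes, regions)
    background = genes["gene_id"].tolist()
    frames = []
    for key, gene_list in hits.items():
        if not gene_list:
            continue
        df = fisher_enrichment(gene_list, background, gene2term)
        if len(df):
            df.insert(0, "region", key)
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["region", *ENRICHMENT_COLUMNS])
    return pd.concat(frames, ignore_index=True)
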