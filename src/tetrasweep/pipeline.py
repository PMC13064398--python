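"""Config-driven orchestration of the full scan.

Stages run in a fixed order: missingness filter -> per-locus metrics ->
windows -> bootstrap/simultaneous bands -> within-group caller and
cross-metric consensus -> comparative caller (when two groups are present)
-> gene overlap and term enrichment (when annotation inputs are present).
Identical config and seed give byte-identical outputs; every output row is
traceable to a (metric, chromosome, window scheme).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import enrich_regions
from .bands import bootstrap_deviations, scs_rank_band
from .calling import (
    call_comparative_sweeps,
    call_sweeps,
    consensus_regions,
    name_regions,
)
from .diversity import group_comparison, per_locus_metric
from .io import (
    DosagePanel,
    SnpMap,
    ValidationError,
    filter_missingness,
    read_dosage_tsv,
    read_gene2term_tsv,
    read_gene_table,
    read_groups_tsv,
    write_regions,
)
from .simulate import SimConfig, TruthSweep, simulate_panel
from .windows import make_physical_windows, make_snp_windows, windowize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; either file inputs or a simulate block."""

    # inputs (either these...)
    dosage_tsv: str | None = None
    groups_tsv: str | None = None
    gene_table: str | None = None
    gene2term: str | None = None
    # ... or a simulation block
    simulate: SimConfig | None = None

    max_missing: float = 0.10
    # window schemes ("snp", "physical"); both by default
    schemes: tuple[str, ...] = ("snp", "physical")
    snp_window_size: int = 100
    snp_window_step: int = 10
    physical_window_bp: int = 1_000_000
    physical_step_bp: int = 500_000
    min_loci: int = 10

    metrics: tuple[str, ...] = ("ho", "he", "pi")
    B: int = 1000  # bootstrap replicates; 0 disables bands
    alpha: float = 0.05
    seed: int | None = None

    quantile: float = 0.05
    neighborhood: int = 2
    min_metrics: int = 2
    extend_bp: int = 1_000_000
    require_band: bool = False

    comparative_metrics: tuple[str, ...] = ("delta_ho", "fst", "pi_ratio")
    comparative_quantile: float = 0.01
    comparative_neighborhood: int = 1
    comparative_min_metrics: int = 2
    compare_groups: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if (self.dosage_tsv is None) == (self.simulate is None):
            raise ValidationError("config needs exactly one of dosage_tsv or a simulate block")
        if self.seed is None and (self.simulate is not None or self.B > 0):
            raise ValidationError("seed is mandatory when simulation or bootstrap runs")

    # -- YAML round trip ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sweeps = tuple(
                TruthSweep(
                    chromosome=s["chromosome"],
                    start_bp=int(s["start_bp"]),
                    end_bp=int(s["end_bp"]),
                    affected_groups=(
                        "all" if s.get("affected_groups", "all") == "all"
                        else tuple(s["affected_groups"])
                    ),
                    intensity=float(s.get("intensity", 0.8)),
                )
                for s in sim.pop("sweep_specs", [])
            )
            sim = SimConfig(**{**sim, "sweep_specs": sweeps})
        for key in ("schemes", "metrics", "comparative_metrics", "compare_groups"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["sweep_specs"] = [
                {
                    "chromosome": s.chromosome,
                    "start_bp": s.start_bp,
                    "end_bp": s.end_bp,
                    "affected_groups": (
                        s.affected_groups if s.affected_groups == "all" else list(s.affected_groups)
                    ),
                    "intensity": s.intensity,
                }
                for s in self.simulate.sweep_specs
            ]
            sim["base_freq_range"] = list(self.simulate.base_freq_range)
            d["simulate"] = sim
        for key in ("schemes", "metrics", "comparative_metrics", "compare_groups"):
            if d.get(key) is not None:
                d[key] = list(d[key])
        return d


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = simulate_panel(config.simulate)
        chrom_lengths = {
            c: config.simulate.chrom_length_bp for c in config.simulate.chromosome_names()
        }
        return sim.panel, sim.snp_map, chrom_lengths, sim.sweeps
    panel, snp_map = read_dosage_tsv(config.dosage_tsv)
    if config.groups_tsv:
        groups = read_groups_tsv(config.groups_tsv)
        panel = DosagePanel(panel.sample_ids, panel.dosages, panel.ploidy, groups)
    return panel, snp_map, None, []


def _build_windows(config: RunConfig, snp_map: SnpMap) -> dict[str, pd.DataFrame]:
    schemes = {}
    for scheme in config.schemes:
        if scheme == "snp":
            schemes["snp"] = make_snp_windows(
                snp_map, size=config.snp_window_size, step=config.snp_window_step
            )
        elif scheme == "physical":
            schemes["physical"] = make_physical_windows(
                snp_map,
                width_bp=config.physical_window_bp,
                step_bp=config.physical_step_bp,
                min_loci=config.min_loci,
            )
        else:
            raise ValidationError(f"unknown window scheme {scheme!r}")
    return schemes


def run_scan(config: RunConfig, out_dir) -> dict[str, Path]:
    """Execute the full pipeline and write its report files into ``out_dir``.

    Returns a name -> path map of everything written.  Outputs contain no
    timestamps, so reruns with the same config and seed are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    seeds = np.random.SeedSequence(config.seed if config.seed is not None else 0)
    boot_seed, _ = (int(s.generate_state(1)[0] % (2**31)) for s in seeds.spawn(2))

    logger.info("stage input: loading panel")
    panel, snp_map, chrom_lengths, truth = _load_inputs(config)
    logger.info("loaded %d samples x %d loci", panel.n_samples, panel.n_loci)

    logger.info("stage filter: missingness > %.2f", config.max_missing)
    panel, snp_map, n_removed = filter_missingness(panel, snp_map, config.max_missing)
    logger.info("filtered %d loci; %d retained", n_removed, len(snp_map))

    logger.info("stage windows: schemes %s", list(config.schemes))
    window_schemes = _build_windows(config, snp_map)

    track_frames = []
    band_frames = []
    all_named: list = []
    for scheme, windows in window_schemes.items():
        logger.info("scheme %s: %d windows", scheme, len(windows))
        per_metric_regions = {}
        for metric in config.metrics:
            values = per_locus_metric(panel.dosages, metric, panel.ploidy)
            track = windowize(values, snp_map, windows, metric=metric, group="all")
            df = track.to_dataframe()
            df["scheme"] = scheme
            track_frames.append(df)
            band = None
            if config.B > 0:
                boot = bootstrap_deviations(
                    panel, snp_map, windows, metric,
                    B=config.B, seed=boot_seed, stratify_by_group=False,
                )
                band = scs_rank_band(boot, alpha=config.alpha)
                bdf = band.to_dataframe()
                bdf["metric"] = metric
                bdf["scheme"] = scheme
                band_frames.append(bdf)
            regions = call_sweeps(
                track,
                band=band,
                quantile=config.quantile,
                neighborhood=config.neighborhood,
                extend_bp=config.extend_bp,
                require_band=config.require_band,
                chrom_lengths=chrom_lengths,
            )
            per_metric_regions[metric] = regions
            logger.info("scheme %s metric %s: %d candidate regions", scheme, metric, len(regions))
        consensus = name_regions(
            consensus_regions(per_metric_regions, min_metrics=config.min_metrics)
        )
        paths[f"regions_{scheme}_tsv"] = out / f"regions_{scheme}.tsv"
        paths[f"regions_{scheme}_bed"] = out / f"regions_{scheme}.bed"
        write_regions(consensus, paths[f"regions_{scheme}_tsv"], "tsv")
        write_regions(consensus, paths[f"regions_{scheme}_bed"], "bed")
        all_named.extend(consensus)

    # comparative stage (needs two groups)
    group_names = panel.group_names()
    pair = config.compare_groups or (tuple(group_names[:2]) if len(group_names) >= 2 else None)
    if pair is not None and len(group_names) >= 2:
        ga, gb = pair
        logger.info("stage comparative: %s vs %s", ga, gb)
        comp = group_comparison(panel, ga, gb)
        windows = window_schemes["snp"] if "snp" in window_schemes else next(iter(window_schemes.values()))
        ctracks = {
            m: windowize(comp.metric(m), snp_map, windows, metric=m, group=f"{ga}_vs_{gb}")
            for m in config.comparative_metrics
        }
        for m, tr in ctracks.items():
            df = tr.to_dataframe()
            df["scheme"] = "snp"
            track_frames.append(df)
        comparative = name_regions(
            call_comparative_sweeps(
                ctracks,
                quantile=config.comparative_quantile,
                neighborhood=config.comparative_neighborhood,
                min_metrics=config.comparative_min_metrics,
                extend_bp=config.extend_bp,
                chrom_lengths=chrom_lengths,
                group_a=ga,
                group_b=gb,
            ),
            comparative=True,
        )
        paths["regions_comparative_tsv"] = out / "regions_comparative.tsv"
        write_regions(comparative, paths["regions_comparative_tsv"], "tsv")
        all_named.extend(comparative)
    else:
        logger.info("stage comparative: skipped (fewer than two groups)")

    paths["window_tracks"] = out / "window_tracks.tsv"
    pd.concat(track_frames, ignore_index=True).to_csv(paths["window_tracks"], sep="\t", index=False)
    if band_frames:
        paths["bands"] = out / "bands.tsv"
        pd.concat(band_frames, ignore_index=True).to_csv(paths["bands"], sep="\t", index=False)

    # annotation stage
    if config.gene_table and config.gene2term:
        logger.info("stage annotation: %d regions", len(all_named))
        genes = read_gene_table(config.gene_table)
        gene2term = read_gene2term_tsv(config.gene2term)
        enrichment = enrich_regions(all_named, genes, gene2term)
        paths["enrichment"] = out / "enrichment.tsv"
        enrichment.to_csv(paths["enrichment"], sep="\t", index=False)
    else:
        logger.info("stage annotation: skipped (no gene table / gene2term)")

    resolved = {"tetrasweep_version": __version__, "config": config.to_dict()}
    paths["resolved_config"] = out / "resolved_config.yaml"
    with open(paths["resolved_config"], "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    if truth:
        truth_df = pd.DataFrame(
            [
                {
                    "chromosome": s.chromosome,
                    "start_bp": s.start_bp,
                    "end_bp": s.end_bp,
                    "affected_groups": (
                        s.affected_groups if s.affected_groups == "all" else ",".join(s.affected_groups)
                    ),
                    "intensity": s.intensity,
                }
                for s in truth
            ]
        )
        paths["truth_sweeps"] = out / "truth_sweeps.tsv"
        truth_df.to_csv(paths["truth_sweeps"], sep="\t", index=False)
    return paths
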