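"""End-to-end orchestration: simulate -> count -> activity -> allelic -> enrich.

A plain-text ``key = value`` config drives a reproducible run; every run
writes its fully resolved config, a log, and a run report with per-stage
record counts alongside the stage outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import _io, __version__
from .activity_calling import call_activity
from .allelic_analysis import allelic_test, pooled_allele_table
from .enrichment import overlap_enrichment
from .fragment_processing import FragmentFilterStats, count_matrices, load_fragments
from .synthetic_data import SimulationConfig, simulate_annotations, simulate_dataset, write_screen

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_all", "load_config"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "starr_run"
    seed: int = 0
    # simulation (used when simulate = True; otherwise inputs are read from paths)
    simulate: bool = True
    n_tag_snps: int = 10
    linked_per_tag: int = 9
    fragments_per_region: float = 200.0
    pre_fraction: float = 0.1
    nre_fraction: float = 0.1
    regsnp_fraction: float = 0.05
    nb_dispersion: float = 0.02
    replicates: int = 2
    # external inputs (used when simulate = False)
    panel_path: str = ""
    fragments_path: str = ""
    region_counts_path: str = ""
    allele_counts_path: str = ""
    peaks_path: str = ""
    # thresholds
    min_fragment_len: int = 400
    max_fragment_len: int = 600
    min_base_quality: int = 20
    activity_fdr: float = 0.01
    min_base_mean: float = 10.0
    allelic_fdr: float = 0.1
    min_pooled: float = 10.0
    delta_threshold: float = 3.0
    # annotation simulation
    annotation_or: float = 3.0
    annotation_baseline: float = 0.05
    # stage toggles
    run_counting: bool = True
    run_activity: bool = True
    run_allelic: bool = True
    run_enrichment: bool = True

    def validate(self) -> None:
        for name in ("min_fragment_len", "max_fragment_len", "min_base_quality",
                     "activity_fdr", "min_base_mean", "allelic_fdr", "min_pooled",
                     "delta_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be non-negative")
        if not self.simulate:
            for name in ("panel_path", "region_counts_path", "allele_counts_path"):
                p = getattr(self, name)
                if not p or not Path(p).exists():
                    raise FileNotFoundError(
                        f"config references missing input: {name} = {p!r}")


@dataclass
class RunReport:
    seed: int = 0
    version: str = ""
    regions_total: int = 0
    regions_filtered: int = 0
    regions_pre: int = 0
    regions_nre: int = 0
    regions_inactive: int = 0
    snps_tested: int = 0
    snps_dropped_low_count: int = 0
    regulatory_snps: int = 0
    enrichment_or: float | None = None
    warnings: int = 0
    config: dict = field(default_factory=dict)

    def consistent(self) -> bool:
        return (self.regions_pre + self.regions_nre + self.regions_inactive
                + self.regions_filtered == self.regions_total)


def load_config(path) -> RunConfig:
    """Parse a plain-text ``key = value`` config file (``#`` comments)."""
    values: dict[str, object] = {}
    valid = {f.name: f.type for f in fields(RunConfig)}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line (expected key = value): {line!r}")
            key, raw = (t.strip() for t in line.split("=", 1))
            if key not in valid:
                raise ValueError(f"unknown config key: {key!r}")
            default = getattr(RunConfig(), key)
            if isinstance(default, bool):
                values[key] = raw.lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int):
                values[key] = int(raw)
            elif isinstance(default, float):
                values[key] = float(raw)
            else:
                values[key] = raw
    return RunConfig(**values)


def run_all(config: RunConfig) -> RunReport:
    """Execute enabled stages in dependency order; write outputs + report.

    Identical config (including seed) yields byte-identical outputs. Any
    stage error halts the run; the failing stage is named in the log.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("starr_regvar")
    root.addHandler(handler)
    report = RunReport(seed=config.seed, version=__version__, config=asdict(config))

    try:
        # --- inputs ------------------------------------------------------
        if config.simulate:
            logger.info("stage simulate: generating synthetic screen")
            sim_cfg = SimulationConfig(
                n_tag_snps=config.n_tag_snps,
                linked_per_tag=config.linked_per_tag,
                fragments_per_region=config.fragments_per_region,
                pre_fraction=config.pre_fraction,
                nre_fraction=config.nre_fraction,
                regsnp_fraction=config.regsnp_fraction,
                nb_dispersion=config.nb_dispersion,
                replicates=config.replicates,
                seed=config.seed,
            )
            screen = simulate_dataset(sim_cfg)
            write_screen(screen, out / "simulated")
            panel = screen.panel
            truth = screen.truth
            fragments = screen.fragments
            peaks = simulate_annotations(panel, truth, config.annotation_or,
                                         config.annotation_baseline, seed=config.seed + 1)
            _io.write_bed(peaks, out / "simulated" / "peaks.bed")
        else:
            panel = _io.read_panel(config.panel_path)
            truth = None
            fragments = (_io.read_fragments(config.fragments_path)
                         if config.fragments_path else None)
            peaks = _io.read_bed(config.peaks_path) if config.peaks_path else None

        # --- counting ----------------------------------------------------
        if config.run_counting and fragments is not None and len(fragments):
            logger.info("stage count: filtering and tallying fragments")
            stats = FragmentFilterStats()
            kept = load_fragments(fragments, panel,
                                  min_len=config.min_fragment_len,
                                  max_len=config.max_fragment_len,
                                  min_base_quality=config.min_base_quality,
                                  stats=stats)
            region_counts, allele_counts = count_matrices(kept, panel)
        elif config.simulate:
            region_counts, allele_counts = screen.region_counts, screen.allele_counts
        else:
            region_counts = _io.read_counts(config.region_counts_path)
            allele_counts = _io.read_table(config.allele_counts_path)
        _io.write_counts(region_counts, out / "region_counts.tsv")
        report.regions_total = len(region_counts)

        # --- activity ----------------------------------------------------
        activity = None
        if config.run_activity:
            logger.info("stage activity: NB Wald test on %d regions", len(region_counts))
            design = {c: ("output" if str(c).startswith("out") else "input")
                      for c in region_counts.columns}
            activity = call_activity(region_counts, design,
                                     fdr_alpha=config.activity_fdr,
                                     min_base_mean=config.min_base_mean)
            _io.write_table(activity, out / "activity.tsv", index=True)
            vc = activity["class"].value_counts()
            report.regions_pre = int(vc.get("PRE", 0))
            report.regions_nre = int(vc.get("NRE", 0))
            report.regions_inactive = int(vc.get("inactive", 0))
            report.regions_filtered = int(vc.get("filtered", 0))

        # --- allelic -----------------------------------------------------
        allelic = None
        if config.run_allelic:
            logger.info("stage allelic: imbalance test")
            pooled, dropped = pooled_allele_table(allele_counts,
                                                  min_pooled=config.min_pooled)
            allelic = allelic_test(pooled, activity, fdr_alpha=config.allelic_fdr)
            _io.write_table(allelic, out / "allelic.tsv", index=True)
            report.snps_tested = len(allelic)
            report.snps_dropped_low_count = len(dropped)
            report.regulatory_snps = int(allelic["regulatory"].sum())

        # --- enrichment --------------------------------------------------
        if config.run_enrichment and activity is not None and peaks is not None and len(peaks):
            logger.info("stage enrichment: peak overlap")
            pos = panel.set_index("snp_id")[["chrom", "pos"]]
            by_class = {}
            for cls in ("PRE", "NRE", "inactive"):
                ids = activity.index[activity["class"] == cls]
                by_class[cls] = pos.loc[pos.index.intersection(ids)].reset_index()
            by_class["active"] = pd.concat([by_class["PRE"], by_class["NRE"]],
                                           ignore_index=True)
            if len(by_class["active"]) and len(by_class["inactive"]):
                enr = overlap_enrichment(by_class, peaks, "active", "inactive")
                with open(out / "enrichment.json", "w") as fh:
                    json.dump(enr, fh, indent=1)
                report.enrichment_or = enr["odds_ratio"]

        with open(out / "run_report.json", "w") as fh:
            json.dump(asdict(report), fh, indent=1, default=str)
        with open(out / "resolved_config.txt", "w") as fh:
            for key, val in asdict(config).items():
                fh.write(f"{key} = {val}\n")
        return report
    except Exception:
        logger.exception("pipeline halted")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
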