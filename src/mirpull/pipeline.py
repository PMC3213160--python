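"""End-to-end orchestration of the pull-down analysis stages.

Stage order mirrors the analysis: per-cell-line enrichment-ratio hit
calling, down-regulation calling, cross-cell-line hit overlap, CDF/KS
comparison of fold-change distributions, positional hexamer enrichment, and
pathway over-representation with a pathway-overlap network.  A run manifest
records versions, seeds and thresholds so any output can be reproduced.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .downreg import (
    DEFAULT_DOWN_CUTOFF,
    call_down,
    cdf_compare,
    comparisons_to_tsv,
    fold_change,
    stratify_by_enrichment,
)
from .enrichment import (
    GeneSet,
    call_hits,
    enrichment_ratio,
    fit_background,
    overlap,
    overlap_report,
)
from .errors import ConfigError, MirpullError
from .expression import flag_expressed, read_matrix
from .hexamer import MIR34A, REGIONS, MatureMiRNA, RegionSequenceSet, hexamer_scan_all
from .pathways import (
    DEFAULT_P_CUT,
    PathwayCollection,
    build_network,
    enrich,
    write_node_attributes,
    write_sif,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    cell_lines: dict            # name -> {matrix, design, probe_map}
    sequences_fasta: str
    pathways_gmt: str
    output_dir: str
    n_sd: float = 1.0
    down_cutoff: float = DEFAULT_DOWN_CUTOFF
    pathway_p_cut: float = DEFAULT_P_CUT
    background_quantile: float = 0.05
    hexamer_n_sims: int = 1000
    hexamer_rng_seed: int = 0
    hexamer_regions: tuple = REGIONS
    mirna_name: str = MIR34A.name
    mirna_sequence: str = MIR34A.sequence
    stratify_cutoffs: tuple = (2.0, 4.0)

    @property
    def mirna(self) -> MatureMiRNA:
        return MatureMiRNA(name=self.mirna_name, sequence=self.mirna_sequence)


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration file.

    Referenced input files must exist; thresholds must lie in their
    documented ranges.  Errors name the offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for key in ("cell_lines", "sequences_fasta", "pathways_gmt", "output_dir"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required key {key!r}")
    thresholds = raw.get("thresholds", {}) or {}
    hexamer = raw.get("hexamer", {}) or {}
    cfg = PipelineConfig(
        cell_lines=raw["cell_lines"],
        sequences_fasta=raw["sequences_fasta"],
        pathways_gmt=raw["pathways_gmt"],
        output_dir=raw["output_dir"],
        n_sd=float(thresholds.get("n_sd", 1.0)),
        down_cutoff=float(thresholds.get("down_cutoff", DEFAULT_DOWN_CUTOFF)),
        pathway_p_cut=float(thresholds.get("pathway_p_cut", DEFAULT_P_CUT)),
        background_quantile=float(thresholds.get("background_quantile", 0.05)),
        hexamer_n_sims=int(hexamer.get("n_sims", 1000)),
        hexamer_rng_seed=int(hexamer.get("rng_seed", 0)),
        hexamer_regions=tuple(hexamer.get("regions", list(REGIONS))),
        mirna_name=raw.get("mirna", {}).get("name", MIR34A.name),
        mirna_sequence=raw.get("mirna", {}).get("sequence", MIR34A.sequence),
        stratify_cutoffs=tuple(raw.get("stratify_cutoffs", (2.0, 4.0))),
    )
    if cfg.n_sd < 0:
        raise ConfigError(f"thresholds.n_sd must be >= 0, got {cfg.n_sd}")
    if not 0 < cfg.down_cutoff < 1:
        raise ConfigError(
            f"thresholds.down_cutoff must be in (0, 1), got {cfg.down_cutoff}"
        )
    if not 0 < cfg.pathway_p_cut <= 1:
        raise ConfigError(
            f"thresholds.pathway_p_cut must be in (0, 1], got {cfg.pathway_p_cut}"
        )
    if cfg.hexamer_n_sims < 100:
        raise ConfigError(
            f"hexamer.n_sims must be >= 100, got {cfg.hexamer_n_sims}"
        )
    for region in cfg.hexamer_regions:
        if region not in REGIONS:
            raise ConfigError(f"hexamer.regions: unknown region {region!r}")
    if not isinstance(cfg.cell_lines, dict) or not cfg.cell_lines:
        raise ConfigError("cell_lines must map cell-line names to input files")
    for cl, files in cfg.cell_lines.items():
        for key in ("matrix", "design", "probe_map"):
            if key not in files:
                raise ConfigError(f"cell_lines.{cl}: missing key {key!r}")
            if not Path(files[key]).exists():
                raise ConfigError(
                    f"cell_lines.{cl}.{key}: file not found: {files[key]}"
                )
    for key in ("sequences_fasta", "pathways_gmt"):
        if not Path(getattr(cfg, key)).exists():
            raise ConfigError(f"{key}: file not found: {getattr(cfg, key)}")
    cfg.mirna  # validates the miRNA sequence
    return cfg


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle.

    Returns a summary dict (also written as ``manifest.json``).  Any stage
    failure is re-raised with the stage name attached.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"cell_lines": {}}
    stage = "setup"
    try:
        hit_sets: dict[str, GeneSet] = {}
        down_sets: dict[str, GeneSet] = {}
        fc_tables = {}
        enr_tables = {}
        flags_by_line = {}
        for cl, files in config.cell_lines.items():
            stage = f"read[{cl}]"
            t0 = _stage(stage)
            matrix = read_matrix(files["matrix"], files["design"], files["probe_map"])
            flags = flag_expressed(matrix, quantile=config.background_quantile)
            flags_by_line[cl] = flags

            stage = f"enrichment[{cl}]"
            _stage(stage)
            table = enrichment_ratio(matrix, flags, cell_line=cl)
            threshold = fit_background(table, n_sd=config.n_sd)
            hits = call_hits(table, threshold, label=f"{cl}_hits")
            table.to_tsv(outdir / f"{cl}.enrichment.tsv")
            hits.to_file(outdir / f"{cl}.hits.txt")
            enr_tables[cl] = table
            hit_sets[cl] = hits

            stage = f"downregulation[{cl}]"
            _stage(stage)
            fc = fold_change(matrix, flags, cell_line=cl)
            down = call_down(fc, cutoff=config.down_cutoff, label=f"{cl}_down")
            fc.to_tsv(outdir / f"{cl}.fold_change.tsv")
            down.to_file(outdir / f"{cl}.down.txt")
            fc_tables[cl] = fc
            down_sets[cl] = down

            down_and_hit = overlap(down, hits)
            summary["cell_lines"][cl] = {
                "n_expressed_genes": int(flags.gene.sum()),
                "n_hits": len(hits),
                "threshold_fold": threshold.fold_equivalent,
                "threshold_mu_log2": threshold.mu,
                "threshold_sigma_log2": threshold.sigma,
                "n_down": len(down),
                "n_down_and_hit": len(down_and_hit),
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }

        stage = "overlap"
        _stage(stage)
        names = list(config.cell_lines)
        if len(names) >= 2:
            both = overlap(hit_sets[names[0]], hit_sets[names[1]])
            report = overlap_report(hit_sets[names[0]], hit_sets[names[1]])
            both.to_file(outdir / "hits.overlap.txt")
            pd.DataFrame([report]).to_csv(
                outdir / "hits.overlap_report.tsv", sep="\t", index=False
            )
            summary["hit_overlap"] = report
        else:
            both = hit_sets[names[0]]

        stage = "ks"
        _stage(stage)
        for cl in names:
            fc = fc_tables[cl]
            universe = GeneSet(
                label=f"{cl}_expressed", members=frozenset(fc.table.index)
            )
            strata = stratify_by_enrichment(
                enr_tables[cl], sorted(config.stratify_cutoffs)
            )
            compare_sets = [hit_sets[cl], *strata]
            if len(names) >= 2:
                compare_sets.append(both)
            comparisons, cdfs = cdf_compare(fc, compare_sets, universe)
            comparisons_to_tsv(comparisons, outdir / f"{cl}.ks_comparisons.tsv")
            for label, frame in cdfs.items():
                frame.to_csv(outdir / f"{cl}.cdf.{label}.tsv", sep="\t", index=False)
            summary["cell_lines"][cl]["ks"] = [
                {"set": c.set_a_label, "D": c.ks_statistic, "p": c.p_value}
                for c in comparisons
            ]

        stage = "hexamer"
        _stage(stage)
        seqs = RegionSequenceSet.from_fasta(config.sequences_fasta)
        hexamer_sets = [hit_sets[cl] for cl in names]
        if len(names) >= 2:
            hexamer_sets.append(both)
        background = GeneSet(
            label="expressed_background",
            members=frozenset().union(*(flags_by_line[cl].expressed_genes()
                                        for cl in names)),
        )
        grid = hexamer_scan_all(
            config.mirna,
            hexamer_sets,
            background,
            seqs,
            regions=config.hexamer_regions,
            n_sims=config.hexamer_n_sims,
            rng_seed=config.hexamer_rng_seed,
        )
        grid.to_csv(outdir / "hexamer_grid.tsv", sep="\t", index=False)
        seed_start = config.mirna.seed_window[0]
        seed_rows = grid[
            (grid["hexamer_start"] == seed_start) & (grid["region"] == "utr3")
        ]
        summary["hexamer_seed_utr3"] = seed_rows[
            ["set_label", "fold", "p_empirical", "p_tail"]
        ].to_dict("records")

        stage = "pathways"
        _stage(stage)
        collection = PathwayCollection.from_gmt(config.pathways_gmt)
        for label, query in [
            *[(f"{cl}_hits", hit_sets[cl]) for cl in names],
            *[(f"{cl}_down", down_sets[cl]) for cl in names],
        ]:
            usable = GeneSet(
                label=query.label, members=query.members & collection.universe
            )
            if not usable.members:
                logger.warning("query %s has no genes in pathway universe", label)
                continue
            results = enrich(usable, collection, p_cut=config.pathway_p_cut)
            results.to_csv(outdir / f"{label}.pathways.tsv", sep="\t", index=False)
            network = build_network(
                results, usable, collection, p_cut=config.pathway_p_cut
            )
            write_sif(network, outdir / f"{label}.network.sif")
            write_node_attributes(network, outdir / f"{label}.network_nodes.tsv")
            summary.setdefault("pathways", {})[label] = {
                "n_significant": int(results["significant"].sum()),
                "min_p": float(results["p"].min()),
            }

        stage = "manifest"
        _stage(stage)
        manifest = {
            "mirpull_version": __version__,
            "numpy_version": np.__version__,
            "scipy_version": scipy.__version__,
            "pandas_version": pd.__version__,
            "thresholds": {
                "n_sd": config.n_sd,
                "down_cutoff": config.down_cutoff,
                "pathway_p_cut": config.pathway_p_cut,
                "background_quantile": config.background_quantile,
            },
            "hexamer": {
                "n_sims": config.hexamer_n_sims,
                "rng_seed": config.hexamer_rng_seed,
                "regions": list(config.hexamer_regions),
                "mirna": config.mirna_name,
            },
            "inputs": {
                "cell_lines": config.cell_lines,
                "sequences_fasta": config.sequences_fasta,
                "pathways_gmt": config.pathways_gmt,
            },
            "summary": summary,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:  # attach the failing stage
        raise MirpullError(f"stage {stage!r} failed: {exc}") from exc
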