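"""End-to-end pipeline: simulate -> convert -> filter -> digest -> analytics.

The RunConfig is a single declarative document (YAML on disk); unknown keys
are rejected, every random stage receives an explicit seed, and defaults
follow the standard protocol parameters (capture threshold 100, CH filter 3,
promoter 1000/500, 100-kb windows, variance 0.009, TSS flank 2000).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .cohort import CohortDesign, loo_classify, feature_prefilter, qc_filter, simulate_cohort
from .digestion import EnzymePanel, cg_fraction, converted_site_map, digest_library
from .enrichment import (accumulate_coverage, fragment_length_stats,
                         read_fraction_by_element, saturation_curve)
from .genome import simulate_genome, write_beta_tsv, write_fasta
from .intervals import write_bed
from .library import ConversionParams, convert_library, filter_non_conversion, write_fastq

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Declarative pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    # genome
    n_islands: int = 25
    island_gc: float = 0.65
    background_gc: float = 0.30
    # library
    n_fragments: int = 20_000
    fragment_mode: str = "cfdna"
    mean_fragment_len: int = 170
    conversion_rate: float = 1.0
    protection_rate: float = 1.0
    max_ch: int = 3
    # digestion
    panel: str = "four_cut"
    # analytics
    capture_threshold: int = 100
    depth_grid: list[int] = [10_000, 30_000, 60_000]
    # cohort (optional stage)
    classify: bool = False
    cohort_n_bc: int = 30
    cohort_n_nbc: int = 30
    cohort_tumor_fraction: float = 0.3
    cohort_effect_delta: float = 0.5
    cohort_depth: int = 200
    cohort_n_informative: int = 100
    n_features_select: int = 50
    version: str = __version__

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full in silico workflow; returns (and writes) the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    logger.info("stage: simulate genome")
    genome, annotations, profile = simulate_genome(
        n_islands=config.n_islands, island_gc=config.island_gc,
        background_gc=config.background_gc, seed=seed)
    write_fasta(genome, outdir / "genome.fasta")
    write_bed(annotations["cpg_island"], outdir / "islands.bed")
    write_bed(annotations["tss"], outdir / "tss.bed")
    write_bed(annotations["promoter"], outdir / "promoters.bed")
    write_beta_tsv(profile, outdir / "betas.tsv")

    logger.info("stage: simulate and convert library")
    from .library import fragment_genome
    fragments = fragment_genome(genome, mode=config.fragment_mode,
                                mean_len=config.mean_fragment_len,
                                n_fragments=config.n_fragments, seed=seed + 1)
    params = ConversionParams(config.conversion_rate, config.protection_rate,
                              seed=seed + 2)
    molecules = convert_library(fragments, genome, profile, params)
    converted, removed = filter_non_conversion(molecules, max_ch=config.max_ch)

    logger.info("stage: digest")
    panel = EnzymePanel.from_name(config.panel)
    retained, digested = digest_library(converted, panel)
    write_fastq(retained, outdir / "retained.fastq")

    logger.info("stage: analytics")
    cg_in = float(np.mean([cg_fraction(m.sequence) for m in converted]))
    cg_out = (float(np.mean([cg_fraction(m.sequence) for m in retained]))
              if retained else float("nan"))
    fractions_in = read_fraction_by_element(converted, annotations)
    fractions_out = read_fraction_by_element(retained, annotations)
    _, modal_len = fragment_length_stats(retained)

    islands = annotations["cpg_island"]
    grid = [g for g in config.depth_grid]
    curve_rrmp = saturation_curve(retained, islands, grid,
                                  threshold=config.capture_threshold, seed=seed + 3)
    curve_all = saturation_curve(converted, islands, grid,
                                 threshold=config.capture_threshold, seed=seed + 3)
    track = accumulate_coverage(retained)
    track.write_bismark_cov(outdir / "coverage.cov")
    site_map = converted_site_map(genome, profile, panel)
    site_map.to_bed(outdir / "sites.bed")

    summary = {
        "version": config.version,
        "seed": seed,
        "n_fragments": len(fragments),
        "n_converted": len(converted),
        "n_removed_non_conversion": len(removed),
        "n_retained": len(retained),
        "n_digested": len(digested),
        "retained_fraction": len(retained) / len(converted) if converted else None,
        "mean_cg_input": cg_in,
        "mean_cg_retained": cg_out,
        "cg_rate_gain": cg_out / cg_in if cg_in else None,
        "island_fraction_input": fractions_in["cpg_island"],
        "island_fraction_retained": fractions_out["cpg_island"],
        "modal_fragment_length": modal_len,
        "islands_total": len(islands),
        "islands_captured_rrmp": dict(zip(map(str, grid), curve_rrmp.captured())),
        "islands_captured_unfiltered": dict(zip(map(str, grid), curve_all.captured())),
    }

    if config.classify:
        logger.info("stage: cohort classification")
        design = CohortDesign(
            n_bc=config.cohort_n_bc, n_nbc=config.cohort_n_nbc,
            tumor_fraction=config.cohort_tumor_fraction,
            n_informative_cpgs=config.cohort_n_informative,
            effect_delta=config.cohort_effect_delta,
            depth=config.cohort_depth, seed=seed + 4)
        matrix = simulate_cohort(design, genome, annotations["tss"], profile)
        matrix, qc_report = qc_filter(matrix)
        matrix = feature_prefilter(matrix, annotations["tss"])
        result = loo_classify(matrix, n_features_select=config.n_features_select,
                              seed=seed + 5)
        summary["cohort_auc"] = result.auc
        summary["cohort_n_features_prefiltered"] = matrix.n_sites
        summary["cohort_samples_excluded"] = len(qc_report["samples_excluded"])
        result.scores.rename("tumor_score").to_csv(outdir / "tumor_scores.tsv",
                                                   sep="\t")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
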