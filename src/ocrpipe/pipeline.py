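"""End-to-end orchestration: consensus -> histone subsets -> permutation
enrichment -> partitioned heritability -> SNP prioritization.

The pipeline is driven by a single declarative YAML config naming every
input file and threshold; each stage writes its outputs to the run
directory and the run report records input checksums, parameters and
per-stage counts, so identical config + seed reproduces identical outputs
and any stage can be re-run from the files on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .intervals import GenomeModel, read_bed, read_genes, write_bed
from .consensus import (
    attribute_fractions,
    high_confidence,
    histone_subset,
    write_attribution,
)
from .perm_enrich import AnnotationMap, permutation_enrichment, write_enrichment_tsv
from .h2 import (
    GwasSummary,
    annotate_snps,
    bonferroni_threshold,
    fit_partitioned,
    fold_enrichment,
    ld_scores,
    read_gwas_tsv,
    read_panel_tsv,
    write_h2_results_tsv,
)
from .prioritize import SnpRecord, Thresholds, prioritize, write_prioritized_tsv

logger = logging.getLogger("ocrpipe")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; see ``from_yaml``."""

    chrom_sizes: str
    replicate_beds: list[str]
    pooled_bed: str
    blacklist_bed: str
    states_manifest: str
    gwas_tsv: str
    panel_tsv: str
    eqtl_tsv: str
    out_dir: str
    neun_pos_bed: str | None = None
    neun_neg_bed: str | None = None
    h3k4me1_bed: str | None = None
    h3k4me3_bed: str | None = None
    genes_tsv: str | None = None
    min_count: int = 2
    n_sim: int = 1000
    flank: int = 500
    n_jackknife_blocks: int = 20
    ld_window_bp: int = 1_000_000
    gwas_p: float = 5e-8
    r2: float = 0.8
    eqtl_p: float = 5e-5
    locus_window: int = 500_000
    tss_upstream: int = 30_000
    tss_downstream: int = 100
    bonferroni_n_traits: int = 7
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["consensus", "perm_enrich", "h2_enrich", "prioritize"]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        required = [self.chrom_sizes, self.pooled_bed, self.blacklist_bed,
                    self.states_manifest, self.gwas_tsv, self.panel_tsv,
                    self.eqtl_tsv, *self.replicate_beds]
        optional = [self.neun_pos_bed, self.neun_neg_bed, self.h3k4me1_bed,
                    self.h3k4me3_bed, self.genes_tsv]
        for p in required + [p for p in optional if p is not None]:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        for name, value in (("n_sim", self.n_sim), ("gwas_p", self.gwas_p),
                            ("r2", self.r2), ("eqtl_p", self.eqtl_p)):
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive")


def _md5(path: str | Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)

    report: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "input_checksums": {},
        "stages": {},
    }
    for p in [config.chrom_sizes, config.pooled_bed, config.blacklist_bed,
              config.gwas_tsv, config.panel_tsv, config.eqtl_tsv, *config.replicate_beds]:
        report["input_checksums"][str(p)] = _md5(p)

    genome = GenomeModel.from_chrom_sizes(config.chrom_sizes)
    stage = "setup"
    try:
        stage = "consensus"
        replicates = [read_bed(p) for p in config.replicate_beds]
        pooled = read_bed(config.pooled_bed, label="pooled")
        blacklist = read_bed(config.blacklist_bed, label="blacklist")
        hc = high_confidence(pooled, replicates, blacklist, min_count=config.min_count)
        write_bed(hc, out / "high_confidence.bed")
        counts = {"n_pooled": len(pooled), "n_high_confidence": len(hc)}
        attribution = None
        if config.neun_pos_bed and config.neun_neg_bed:
            neun_pos = read_bed(config.neun_pos_bed)
            neun_neg = read_bed(config.neun_neg_bed)
            labels, label_counts = attribute_fractions(hc, neun_pos, neun_neg)
            write_attribution(hc, labels, out / "attribution.tsv")
            counts["attribution"] = label_counts
            attribution = (hc, labels)
        histone_sets = {}
        for key, path in (("h3k4me1", config.h3k4me1_bed), ("h3k4me3", config.h3k4me3_bed)):
            if path:
                hist = read_bed(path, label=key)
                histone_sets[key] = hist
                sub = histone_subset(hc, hist, label=f"hc_{key}")
                write_bed(sub, out / f"hc_{key}.bed")
                counts[f"n_hc_{key}"] = len(sub)
        report["stages"]["consensus"] = counts
        logger.info("consensus: %s", counts)

        if "perm_enrich" in config.stages:
            stage = "perm_enrich"
            annotation = AnnotationMap.from_manifest(config.states_manifest)
            results = permutation_enrichment(
                hc, annotation, n_sim=config.n_sim, genome=genome, rng_seed=config.seed
            )
            write_enrichment_tsv(results, out / "perm_enrichment.tsv")
            report["stages"]["perm_enrich"] = {
                r.state_label: {"fold": r.fold, "p_over": r.p_over} for r in results
            }
            logger.info("perm_enrich: %d states", len(results))

        if "h2_enrich" in config.stages:
            stage = "h2_enrich"
            gwas_df = read_gwas_tsv(config.gwas_tsv)
            panel = read_panel_tsv(config.panel_tsv)
            ocr_col = annotate_snps(panel, hc, flank=config.flank, genome=genome)
            A = np.column_stack([np.ones(panel.n_snps, dtype=np.int64), ocr_col])
            names = ["base", "ocr"]
            ell = ld_scores(panel, A, window_bp=config.ld_window_bp)
            gwas = GwasSummary(gwas_df["chisq"].to_numpy(), float(gwas_df["N"].iloc[0]))
            fit = fit_partitioned(
                gwas, ell, n_blocks=config.n_jackknife_blocks, category_names=names
            )
            res = fold_enrichment(fit, A, "ocr")
            write_h2_results_tsv([res], out / "h2_enrichment.tsv")
            report["stages"]["h2_enrich"] = {
                "fold": res.fold,
                "prop_snps": res.prop_snps,
                "prop_h2": res.prop_h2,
                "z": res.z,
                "p": res.p_two_tailed,
                "bonferroni_threshold": bonferroni_threshold(0.05, config.bonferroni_n_traits),
            }
            logger.info("h2_enrich: fold=%.2f p=%.3g", res.fold, res.p_two_tailed)

        if "prioritize" in config.stages:
            stage = "prioritize"
            gwas_df = read_gwas_tsv(config.gwas_tsv)
            panel = read_panel_tsv(config.panel_tsv)
            import pandas as pd

            eqtl = pd.read_csv(config.eqtl_tsv, sep="\t")
            records = [
                SnpRecord(str(r.snp), str(r.chr), int(r.pos), float(r.p))
                for r in gwas_df.itertuples()
            ]
            h3k4me1 = read_bed(config.h3k4me1_bed) if config.h3k4me1_bed else None
            h3k4me3 = read_bed(config.h3k4me3_bed) if config.h3k4me3_bed else None
            prioritized, log = prioritize(
                records,
                hc,
                panel,
                h3k4me1=h3k4me1,
                h3k4me3=h3k4me3,
                attribution=attribution,
                eqtl=eqtl,
                thresholds=Thresholds(
                    gwas_p=config.gwas_p,
                    r2=config.r2,
                    eqtl_p=config.eqtl_p,
                    locus_window=config.locus_window,
                ),
            )
            write_prioritized_tsv(prioritized, out / "prioritized_snps.tsv")
            report["stages"]["prioritize"] = {
                "n_prioritized": len(prioritized),
                "n_logged": len(log),
            }
            logger.info("prioritize: %d SNPs", len(prioritized))
    except Exception as exc:
        report["failed_stage"] = stage
        (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
        logger.removeHandler(fh)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    logger.removeHandler(fh)
    return report
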