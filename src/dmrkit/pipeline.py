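"""End-to-end orchestration: tags -> DMRs -> enrichment -> GSEA.

Stage order follows the study design: pairwise candidate-region discovery,
tag counting and centile filtering, TMM-normalized NB exact testing,
feature-overlap enrichment, then (when expression counts are supplied)
rank-score construction and preranked GSEA against methylation-derived
gene sets. A single global seed fans out to per-stage child seeds by
stable hashing of the stage name, so each stage is individually
reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential as diff
from . import enrichment as enr
from . import gsea as gseamod
from . import io as dio
from . import regions as reg
from .intervals import GeneModel, GenomicInterval

logger = logging.getLogger("dmrkit")


@dataclass
class PipelineConfig:
    """Thresholds and seeds for a pipeline run.

    Defaults are the reference workflow's constants: MACS-style peak cutoff
    1e-5 with 75 bp shift, DMR significance 0.01, 50th/30th centile
    non-differential filters for methylation/expression, non-differential
    background at -log10 p < 0.25, GSEA FDR 0.25 with 1000 permutations.
    """

    case_group: str
    control_group: str
    seed: int = 0
    peak_p_cutoff: float = 1e-5
    shift: int = 75
    region_p_cutoff: float = 0.01
    methyl_centile: float = 50.0
    expr_centile: float = 30.0
    nondiff_neglog10p: float = 0.25
    gsea_fdr: float = 0.25
    n_permutations: int = 1000
    prior_df: float = 10.0
    window_step: int | None = None

    def __post_init__(self) -> None:
        for name in ("peak_p_cutoff", "region_p_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("methyl_centile", "expr_centile"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")

    def stage_seed(self, stage: str) -> int:
        """Child seed for a stage: stable hash of the stage name and seed."""
        return (zlib.crc32(stage.encode()) ^ (self.seed * 2654435761)) % (2**31)


@dataclass
class RunReport:
    parameters: dict
    stage_counts: dict[str, int] = field(default_factory=dict)
    output_files: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def check_outputs(self) -> None:
        missing = [f for f in self.output_files if not Path(f).exists()]
        if missing:
            raise RuntimeError(f"missing pipeline outputs: {missing}")


def run_pipeline(tags: pd.DataFrame, genes: list[GeneModel],
                 cgis: list[GenomicInterval], chrom_lengths: dict[str, int],
                 groups: pd.Series, config: PipelineConfig,
                 expression: pd.DataFrame | None = None,
                 expression_groups: pd.Series | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run the full analysis; returns a dict of stage outputs plus a report.

    ``tags`` has columns chrom, pos5, strand, sample; ``groups`` maps
    sample -> group; only the configured case/control samples are used.
    When ``expression`` (genes x samples counts) is given, the expression
    arm and GSEA coupling run too. With ``outdir``, stage tables are
    written as TSV/BED and listed in the report manifest.
    """
    report = RunReport(parameters=asdict(config))
    out: dict = {"report": report}
    keep = groups[groups.isin([config.case_group, config.control_group])]
    tags = tags[tags["sample"].isin(keep.index)]
    if keep.groupby(keep).size().min() < 2:
        raise ValueError("need >= 2 samples per group for differential testing")

    def stage(name: str):
        logger.info("stage %s", name)
        return name

    try:
        stage("deduplicate")
        tags = reg.deduplicate_tags(tags)
        report.stage_counts["tags_after_dedup"] = len(tags)

        stage("region_discovery")
        logger.info("peak cutoff %.3g, shift %d bp", config.peak_p_cutoff, config.shift)
        pair_regions = reg.pairwise_candidate_regions(
            tags, chrom_lengths, shift=config.shift,
            p_cutoff=config.peak_p_cutoff, step=config.window_step)
        catalog_regions = reg.candidate_region_catalog(pair_regions)
        report.stage_counts["pairwise_regions"] = len(pair_regions)
        report.stage_counts["candidate_regions"] = len(catalog_regions)
        out["candidate_regions"] = catalog_regions
        if not catalog_regions:
            raise RuntimeError("no candidate regions discovered")

        stage("counting_filtering")
        lib_size = tags.groupby("sample").size().reindex(keep.index).astype(float)
        counts = diff.count_tags_per_region(
            catalog_regions, tags, shift=config.shift, chrom_lengths=chrom_lengths,
            samples=list(keep.index))
        logger.info("centile filter at %.0f", config.methyl_centile)
        counts = diff.centile_filter(counts, config.methyl_centile)
        report.stage_counts["regions_after_filter"] = len(counts)
        out["region_counts"] = counts

        stage("differential_methylation")
        model = diff.DifferentialAbundanceModel(
            counts, keep, case=config.case_group, control=config.control_group,
            prior_df=config.prior_df, lib_size=lib_size)
        dm = model.fit()
        out["dmr_results"] = dm
        dmr_table = dm.table.copy()
        coords = dmr_table.index.str.extract(r"(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)")
        dmr_table[["chrom", "start", "end"]] = coords.set_index(dmr_table.index)
        dmr_table[["start", "end"]] = dmr_table[["start", "end"]].astype(int)
        out["dmr_table"] = dmr_table
        n_sig = int((dmr_table["p"] < config.region_p_cutoff).sum())
        report.stage_counts["dmrs_significant"] = n_sig
        logger.info("%d DMRs at p < %.3g", n_sig, config.region_p_cutoff)

        stage("feature_enrichment")
        catalog = enr.FeatureCatalog(genes, cgis, chrom_lengths)
        sig = dmr_table[dmr_table["p"] < config.region_p_cutoff]
        hyper = [GenomicInterval(r.chrom, r.start, r.end)
                 for r in sig[sig["logFC"] > 0].itertuples(index=False)]
        hypo = [GenomicInterval(r.chrom, r.start, r.end)
                for r in sig[sig["logFC"] < 0].itertuples(index=False)]
        if hyper and hypo:
            enrich_rows = []
            for feature in enr.FEATURE_ORDER:
                try:
                    table = enr.build_contingency(hyper, hypo,
                                                  catalog.features[feature])
                    enrich_rows.append(enr.enrichment_from_table(feature, table))
                except ValueError:  # zero margin at toy scale
                    report.warnings.append(f"enrichment degenerate: {feature}")
            out["enrichment"] = enrich_rows
        else:
            report.warnings.append("one direction empty: feature enrichment skipped")
        nondiff = dmr_table[-np.log10(dmr_table["p"]) < config.nondiff_neglog10p]
        report.stage_counts["nondiff_background"] = len(nondiff)
        background = [GenomicInterval(r.chrom, r.start, r.end)
                      for r in nondiff.itertuples(index=False)]
        if background:
            bg_rows = []
            for direction, ivs in (("hyper", hyper), ("hypo", hypo)):
                if not ivs:
                    continue
                for feature in enr.FEATURE_ORDER:
                    try:
                        r = enr.background_frequency_enrichment(
                            ivs, background, catalog.features[feature], feature)
                    except ValueError:  # zero margin at toy scale
                        report.warnings.append(
                            f"background enrichment degenerate: {direction}/{feature}")
                        continue
                    bg_rows.append({"direction": direction, "feature": feature,
                                    "log2_or": r.log2_or, "ci_low": r.ci_low,
                                    "ci_high": r.ci_high, "p": r.p})
            out["background_enrichment"] = pd.DataFrame(bg_rows)
        out["feature_catalog"] = catalog

        if expression is not None:
            stage("differential_expression")
            egroups = expression_groups if expression_groups is not None else keep
            egroups = egroups[egroups.isin([config.case_group, config.control_group])]
            emodel = diff.DifferentialAbundanceModel(
                expression.loc[:, egroups.index], egroups,
                case=config.case_group, control=config.control_group,
                centile=config.expr_centile, prior_df=config.prior_df)
            de = emodel.fit()
            out["de_results"] = de
            report.stage_counts["de_genes_significant"] = int(
                (de.table["p"] < config.region_p_cutoff).sum())

            stage("gsea")
            ranked = gseamod.rank_scores(de.table)
            gene_sets = gseamod.build_methylation_gene_sets(
                dmr_table, catalog, p_cut=config.region_p_cutoff)
            gene_sets = [g for g in gene_sets
                         if ranked.index.isin(g.members).sum() > 0]
            if gene_sets:
                gres = gseamod.PrerankedGSEA(ranked, gene_sets).fit(
                    n_perm=config.n_permutations, seed=config.stage_seed("gsea"))
                out["gsea"] = gres
                report.stage_counts["gsea_sets"] = len(gres.table)
            else:
                report.warnings.append("no methylation gene sets overlap the ranking")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_outputs(out, outdir, report)
        report.check_outputs()
    return out


def _write_outputs(out: dict, outdir: Path, report: RunReport) -> None:
    regions = out.get("candidate_regions", [])
    path = outdir / "candidate_regions.bed"
    dio.write_intervals(regions, path)
    report.output_files.append(str(path))
    if "dmr_table" in out:
        path = outdir / "dmr_table.tsv"
        out["dmr_table"][["chrom", "start", "end", "logFC", "p", "fdr"]].to_csv(
            path, sep="\t")
        report.output_files.append(str(path))
    if "enrichment" in out:
        path = outdir / "feature_enrichment.tsv"
        rows = [{
            "feature": r.feature, "Up_OL": r.table.up_ol, "Up_NOL": r.table.up_nol,
            "Down_OL": r.table.down_ol, "Down_NOL": r.table.down_nol,
            "log2_or": r.log2_or, "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
        } for r in out["enrichment"]]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        report.output_files.append(str(path))
    if "de_results" in out:
        path = outdir / "de_table.tsv"
        out["de_results"].table.to_csv(path, sep="\t")
        report.output_files.append(str(path))
    if "gsea" in out:
        path = outdir / "gsea_results.tsv"
        out["gsea"].table.to_csv(path, sep="\t")
        report.output_files.append(str(path))
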