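"""End-to-end pipeline: QC -> DE (+ chromosome enrichment) -> DMP/DMR ->
cis pairing -> eQTM -> GSEA, with a reproducibility manifest.

The pipeline is a pure function of (inputs, config, seed): every randomized
stage draws an independent child seed from the root seed, and the manifest
records parameters, seeds, input checksums and per-stage feature counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, genomic, integration, methylation, qc

logger = logging.getLogger("trisomics")

__all__ = ["PipelineConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "deg_fdr", "dmr_fdr", "gsea_fdr", "eqtm_p", "cis_window",
    "dmp_fdr", "prefilter_min_count", "prefilter_min_samples",
    "dmr_cutoff", "dmr_min_cpgs", "dmr_maxgap", "dmr_n_perm",
    "eqtm_n_boot", "eqtm_n_perm", "eqtm_scope", "gsea_n_perm",
    "gsea_min_size", "gsea_max_size", "n_sv", "rpca_k", "run_qc",
    "run_gsea", "seed",
}


@dataclass
class PipelineConfig:
    """All stage thresholds and parameters of the analysis."""

    deg_fdr: float = 0.05       # DEG significance
    dmp_fdr: float = 0.05       # DMP significance
    dmr_fdr: float = 0.01       # DMR significance
    gsea_fdr: float = 0.01      # gene-set significance
    eqtm_p: float = 0.05        # eQTM raw-p significance
    cis_window: int = 2000      # bp around the gene span
    prefilter_min_count: int = 10
    prefilter_min_samples: int = 4
    dmr_cutoff: float = 0.05    # beta area per-CpG cutoff
    dmr_min_cpgs: int = 3
    dmr_maxgap: int = 500
    dmr_n_perm: int = 100
    eqtm_n_boot: int = 100_000
    eqtm_n_perm: int = 10_000
    eqtm_scope: str = "deg-pairs"
    gsea_n_perm: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    n_sv: int = 1
    rpca_k: int = 2
    run_qc: bool = True
    run_gsea: bool = True
    seed: int = 0

    def __post_init__(self):
        for thr in ("deg_fdr", "dmp_fdr", "dmr_fdr", "gsea_fdr", "eqtm_p"):
            v = getattr(self, thr)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{thr} must be in (0, 1), got {v}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _checksum(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes())
    return h.hexdigest()[:16]


@dataclass
class PipelineResult:
    qc_report: "qc.QcReport | None"
    de: diffexpr.DEResults
    chrom_enrichment: dict
    dmp: methylation.DMPResults
    dmr: methylation.DMRResults
    eqtm: integration.EqtmResults
    gsea: "enrichment.GseaResults | None"
    manifest: dict = field(default_factory=dict)


def run_pipeline(counts: pd.DataFrame, betas: pd.DataFrame,
                 samples: pd.DataFrame, gene_annotation: pd.DataFrame,
                 cpg_annotation: pd.DataFrame,
                 gene_sets: dict[str, set[str]] | None = None,
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis; optionally write every intermediate TSV."""
    cfg = config or PipelineConfig()
    root = np.random.SeedSequence(cfg.seed)
    seed_dmr, seed_eqtm, seed_gsea = [np.random.default_rng(s)
                                      for s in root.spawn(3)]
    manifest: dict = {
        "parameters": asdict(cfg),
        "inputs": {"counts": _checksum(counts), "betas": _checksum(betas),
                   "samples": _checksum(samples)},
        "counts": {}, "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        # ---- QC -------------------------------------------------------
        stage("qc")
        if cfg.run_qc:
            report = qc.run_qc(counts, samples, gene_annotation, k=cfg.rpca_k)
            kept = report.kept_samples
        else:
            report, kept = None, list(counts.columns)
        kept = [s for s in kept if s in betas.columns]
        manifest["counts"]["samples_kept"] = len(kept)
        if report is not None:
            manifest["counts"]["samples_excluded"] = dict(report.excluded)

        # ---- differential expression ---------------------------------
        stage("differential_expression")
        de_model = diffexpr.NegativeBinomialDE(
            counts[kept], samples, gene_annotation,
            min_count=cfg.prefilter_min_count,
            min_samples=cfg.prefilter_min_samples)
        de_res = de_model.fit(fdr_cutoff=cfg.deg_fdr)
        manifest["counts"]["genes_after_prefilter"] = len(de_model.counts)
        manifest["counts"]["degs"] = len(de_res.significant)
        stage("chromosome_enrichment")
        chrom_enr = de_res.chromosome_enrichment()

        # ---- methylation ---------------------------------------------
        stage("dmp")
        dmp_model = methylation.MethylationLM(betas[kept], samples,
                                              cpg_annotation, n_sv=cfg.n_sv)
        dmp_res = dmp_model.fit(fdr_cutoff=cfg.dmp_fdr)
        manifest["counts"]["cpgs_after_filter"] = len(dmp_model.betas)
        manifest["counts"]["dmps"] = len(dmp_res.significant)

        # bump hunting runs with condition + sex only: the permutation null
        # must stay well-populated for the pooled area p-values, and
        # unmodelled batch structure inflates the null conservatively
        stage("dmr")
        bump = methylation.BumpHunter(
            betas[kept], samples, cpg_annotation,
            surrogates=None, cutoff=cfg.dmr_cutoff,
            min_cpgs=cfg.dmr_min_cpgs, maxgap=cfg.dmr_maxgap)
        dmr_res = bump.fit(n_perm=cfg.dmr_n_perm, seed=seed_dmr,
                           fdr_cutoff=cfg.dmr_fdr)
        manifest["counts"]["dmrs"] = len(dmr_res.significant)

        # ---- integration ---------------------------------------------
        stage("eqtm")
        eqtm_model = integration.EqtmAnalysis(
            dmr_res, de_res, betas[kept], de_model.counts,
            de_model.size_factors, gene_annotation,
            window=cfg.cis_window, scope=cfg.eqtm_scope)
        eqtm_res = eqtm_model.fit(n_boot=cfg.eqtm_n_boot,
                                  n_perm=cfg.eqtm_n_perm, seed=seed_eqtm)
        manifest["counts"]["dmr_deg_pairs"] = len(eqtm_res.table)
        manifest["counts"]["eqtm_significant"] = len(eqtm_res.significant)

        # ---- GSEA -----------------------------------------------------
        gsea_res = None
        if cfg.run_gsea and gene_sets:
            stage("gsea")
            gsea_model = enrichment.PrerankedGSEA(
                de_res, gene_sets, min_size=cfg.gsea_min_size,
                max_size=cfg.gsea_max_size)
            gsea_res = gsea_model.fit(n_perm=cfg.gsea_n_perm, seed=seed_gsea,
                                      fdr_cutoff=cfg.gsea_fdr)
            manifest["counts"]["gene_sets_significant"] = len(gsea_res.significant)
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else None
        if outdir is not None:
            Path(outdir).mkdir(parents=True, exist_ok=True)
            with open(Path(outdir) / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(
            f"pipeline failed in stage {manifest.get('failed_stage')!r}: {exc}"
        ) from exc

    result = PipelineResult(report, de_res, chrom_enr, dmp_res, dmr_res,
                            eqtm_res, gsea_res, manifest)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if result.qc_report is not None:
        result.qc_report.marker_table.to_csv(outdir / "qc_markers.tsv", sep="\t",
                                             index_label="sample_id")
        if result.qc_report.scores is not None:
            tab = result.qc_report.scores.copy()
            tab["robust_distance"] = result.qc_report.distances
            tab["outlier_flag"] = result.qc_report.outlier_flags
            tab.to_csv(outdir / "qc_rpca.tsv", sep="\t", index_label="sample_id")
    result.de.table.to_csv(outdir / "de.tsv", sep="\t", index_label="gene_id")
    result.dmp.table.to_csv(outdir / "dmp.tsv", sep="\t", index_label="probe_id")
    result.dmr.table.to_csv(outdir / "dmr.tsv", sep="\t", index=False)
    if len(result.dmr.significant):
        genomic.write_regions_bed(result.dmr.significant, outdir / "dmr.bed")
    result.eqtm.table.to_csv(outdir / "eqtm.tsv", sep="\t", index=False)
    if result.gsea is not None:
        result.gsea.table.to_csv(outdir / "gsea.tsv", sep="\t", index_label="set")
    chrom = {k: {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv)
                 for kk, vv in v.items()} if isinstance(v, dict) else v
             for k, v in result.chrom_enrichment.items()}
    with open(outdir / "chromosome_enrichment.json", "w") as fh:
        json.dump(chrom, fh, indent=2, default=str)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
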