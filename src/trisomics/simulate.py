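"""Synthetic paired expression + methylation trisomy studies.

Generates a small two-group fetal-tissue-like cohort with the statistical
structure a trisomy-21 multi-omics analysis assumes:

* every chromosome-21 gene carries a 1.5x dosage effect in trisomic (DS)
  samples (three copies of the chromosome, expression scaling with copy
  number);
* planted differentially expressed genes elsewhere in the genome;
* planted differentially methylated regions (runs of >= 3 consecutive CpGs
  with a concordant group shift in the methylation fraction beta);
* planted cis methylation->expression couplings of both signs;
* nuisance structure: sex effects, a surrogate batch effect, contaminant
  samples whose expression looks like skeletal muscle rather than thyroid,
  and one high-variance outlier sample.

All randomness flows from a single root seed through spawned child
generators, so a study is a pure function of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study", "write_study"]

CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]

THYROID_MARKERS = {"TPO": "chr2", "TG": "chr8", "TSHR": "chr14", "SLC5A5": "chr19"}
MUSCLE_MARKERS = {"MYH1": "chr17", "MYOD1": "chr11"}
# thyroid-function genes beyond the markers, used by the thyroid-related filters
THYROID_RELATED_EXTRA = {"FOXE1": "chr9", "IYD": "chr6", "DIO2": "chr14"}

GENE_SPAN = 2_000          # bp per gene
GENE_PITCH = 12_000        # spacing between gene starts on the toy genome
DMR_CPG_SPACING = 100      # bp between planted DMR member CpGs
DMR_RANDOM_EFFECT_SD = 0.10   # per-sample, per-region logit-scale random effect
CIS_GAIN = 6.0             # log2 expression units per unit change in region beta
OUTLIER_LOGNOISE_SD = 1.0  # extra per-gene log2 noise for outlier samples
QUALITY_SCORE_SD = 0.05     # per-sample score sd on the shared quality axis
OUTLIER_QUALITY_SCORE = 2.5  # |score| of outlier samples on the quality axis


@dataclass
class SimulationConfig:
    """Study design and effect sizes for :func:`simulate_study`.

    Defaults emulate the analyzed cohort: six trisomic (DS) and six control
    samples, plus two muscle-contaminated DS-labelled samples and one
    deviant control that quality control is expected to remove.
    """

    n_ds: int = 6
    n_control: int = 6
    n_genes: int = 2000
    n_chr21_genes: int = 145
    dosage_factor: float = 1.5
    frac_chr21_dosage_affected: float = 1.0
    n_planted_de: int = 130
    planted_lfc_range: tuple[float, float] = (0.32, 1.75)  # |log2 FC| in [1.25x, 3.37x]
    nb_dispersion: float = 0.02
    library_size_range: tuple[int, int] = (4_000_000, 6_000_000)
    n_cpgs: int = 10_000
    n_planted_dmrs: int = 20
    dmr_n_cpgs: int = 5
    dmr_delta_beta: float = 0.15
    beta_noise_sd: float = 0.3   # logit-scale sd of per-sample CpG noise
    n_cis_effects: int = 6
    cis_effect_slope_signs: tuple[int, ...] = (1, -1)
    sex_effect_sd: float = 0.2
    batch_effect_sd: float = 0.2
    n_contaminant_samples: int = 2
    n_outlier_samples: int = 1
    seed: int = 2021

    def validate(self) -> None:
        if self.n_chr21_genes > self.n_genes:
            raise ValueError("n_chr21_genes cannot exceed n_genes")
        if not 0.0 <= self.frac_chr21_dosage_affected <= 1.0:
            raise ValueError("frac_chr21_dosage_affected must be in [0, 1]")
        if self.dosage_factor <= 0 or self.nb_dispersion <= 0:
            raise ValueError("dosage_factor and nb_dispersion must be positive")
        if self.dmr_n_cpgs < 3:
            raise ValueError("dmr_n_cpgs must be >= 3 (region definition)")
        if self.n_cis_effects > self.n_planted_dmrs:
            raise ValueError("n_cis_effects cannot exceed n_planted_dmrs")
        for name in ("n_ds", "n_control", "n_genes", "n_cpgs", "n_planted_de",
                     "n_planted_dmrs", "n_contaminant_samples", "n_outlier_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        n_other = self.n_genes - self.n_chr21_genes
        reserved = (len(THYROID_MARKERS) + len(MUSCLE_MARKERS)
                    + len(THYROID_RELATED_EXTRA))
        if self.n_planted_de + self.n_planted_dmrs + reserved > n_other:
            raise ValueError("not enough non-chr21 genes for the planted effects")


@dataclass
class SimulatedStudy:
    """A paired study: count and beta matrices, annotation, and the truth ledger."""

    counts: pd.DataFrame          # genes x samples, integer
    betas: pd.DataFrame           # CpGs x samples, in [0, 1]
    samples: pd.DataFrame         # index sample_id; condition, sex, batch
    gene_annotation: pd.DataFrame  # index gene_id; chrom/start/end/strand/...
    cpg_annotation: pd.DataFrame   # index probe_id; chrom/position/flags
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)
    config: SimulationConfig | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _build_gene_annotation(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay genes on a toy genome: chr21 gets its quota, markers get their real
    chromosomes, the rest round-robin over the other autosomes and chrX."""
    records = []
    named = {}
    named.update({g: (c, "thyroid", True) for g, c in THYROID_MARKERS.items()})
    named.update({g: (c, "muscle", False) for g, c in MUSCLE_MARKERS.items()})
    named.update({g: (c, "none", True) for g, c in THYROID_RELATED_EXTRA.items()})

    n_named = len(named)
    n_anon = cfg.n_genes - cfg.n_chr21_genes - n_named
    other_chroms = [c for c in CHROMOSOMES if c not in ("chr21", "chrY")]

    chrom_of: list[tuple[str, str, str, bool]] = []  # gene_id, chrom, marker_class, thyroid_related
    for i in range(cfg.n_chr21_genes):
        chrom_of.append((f"G21_{i:04d}", "chr21", "none", False))
    for gid, (chrom, mclass, thy) in named.items():
        chrom_of.append((gid, chrom, mclass, thy))
    for i in range(n_anon):
        chrom_of.append((f"G{i:04d}", other_chroms[i % len(other_chroms)], "none", False))

    next_start = {c: 10_001 for c in CHROMOSOMES}
    strands = ["+", "-"]
    for j, (gid, chrom, mclass, thy) in enumerate(chrom_of):
        start = next_start[chrom]
        next_start[chrom] = start + GENE_PITCH
        records.append({
            "gene_id": gid, "chrom": chrom, "start": start,
            "end": start + GENE_SPAN - 1, "strand": strands[j % 2],
            "symbol": gid, "marker_class": mclass, "thyroid_related": thy,
        })
    ann = pd.DataFrame.from_records(records).set_index("gene_id")
    return ann


def _promoter_positions(gene: pd.Series, n: int) -> np.ndarray:
    """Positions for a planted DMR inside the strand-aware promoter window."""
    if gene["strand"] == "+":
        lo = gene["start"] - 1_600
    else:
        lo = gene["end"] + 100
    return lo + DMR_CPG_SPACING * np.arange(n)


def simulate_study(config: SimulationConfig | None = None, **overrides) -> SimulatedStudy:
    """Generate a paired expression + methylation study.

    Parameters may be given as a :class:`SimulationConfig` or as keyword
    overrides of the defaults. Returns a :class:`SimulatedStudy` whose
    ``truth`` ledger records every planted effect for downstream
    recovery checks.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    cfg = config
    cfg.validate()

    root = np.random.SeedSequence(cfg.seed)
    (ss_layout, ss_expr, ss_meth, ss_noise) = root.spawn(4)
    rng_layout = np.random.default_rng(ss_layout)
    rng_expr = np.random.default_rng(ss_expr)
    rng_meth = np.random.default_rng(ss_meth)
    rng_noise = np.random.default_rng(ss_noise)

    genes = _build_gene_annotation(cfg, rng_layout)
    gene_ids = genes.index.to_numpy()

    # ---- samples ------------------------------------------------------
    sample_rows = []
    for i in range(cfg.n_ds):
        sample_rows.append((f"DS{i + 1}", "DS", "none"))
    for i in range(cfg.n_control):
        sample_rows.append((f"CTRL{i + 1}", "control", "none"))
    for i in range(cfg.n_contaminant_samples):
        sample_rows.append((f"DS{cfg.n_ds + i + 1}", "DS", "contaminant"))
    for i in range(cfg.n_outlier_samples):
        sample_rows.append((f"CTRL{cfg.n_control + i + 1}", "control", "outlier"))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "condition", "role"])
    samples["sex"] = ["F" if i % 2 == 0 else "M" for i in range(len(samples))]
    samples["batch"] = rng_layout.integers(0, 2, size=len(samples))
    samples = samples.set_index("sample_id")
    n_samples = len(samples)
    is_ds = (samples["condition"] == "DS").to_numpy()
    is_male = (samples["sex"] == "M").to_numpy()
    in_batch = (samples["batch"] == 1).to_numpy()
    is_contam = (samples["role"] == "contaminant").to_numpy()
    is_outlier = (samples["role"] == "outlier").to_numpy()

    # ---- choose planted gene effects ---------------------------------
    chr21_mask = (genes["chrom"] == "chr21").to_numpy()
    chr21_ids = gene_ids[chr21_mask]
    n_affected = int(round(cfg.frac_chr21_dosage_affected * len(chr21_ids)))
    affected_chr21 = rng_layout.choice(chr21_ids, size=n_affected, replace=False)

    anon_mask = (~chr21_mask
                 & (genes["marker_class"] == "none").to_numpy()
                 & ~genes["thyroid_related"].to_numpy())
    anon_pool = gene_ids[anon_mask]
    picked = rng_layout.choice(anon_pool, size=cfg.n_planted_de + cfg.n_planted_dmrs,
                               replace=False)
    planted_de_ids = picked[:cfg.n_planted_de]
    dmr_gene_ids = picked[cfg.n_planted_de:]

    lfc_lo, lfc_hi = cfg.planted_lfc_range
    planted_lfc = rng_layout.uniform(lfc_lo, lfc_hi, size=cfg.n_planted_de)
    planted_lfc *= rng_layout.choice([-1.0, 1.0], size=cfg.n_planted_de)

    # ---- methylation layout -------------------------------------------
    signs = np.array(sorted(cfg.cis_effect_slope_signs), dtype=float)
    probe_rows = []
    dmr_rows = []
    cis_rows = []
    dmr_member_idx: list[np.ndarray] = []
    dmr_sign = np.empty(cfg.n_planted_dmrs)
    pid = 0
    for d in range(cfg.n_planted_dmrs):
        gene = genes.loc[dmr_gene_ids[d]]
        pos = _promoter_positions(gene, cfg.dmr_n_cpgs)
        sign = rng_layout.choice([-1.0, 1.0])
        dmr_sign[d] = sign
        members = []
        for p in pos:
            probe_rows.append((f"cg{pid:07d}", gene["chrom"], int(p),
                               False, False, False, False))
            members.append(pid)
            pid += 1
        dmr_member_idx.append(np.array(members))
        dmr_rows.append({
            "dmr_id": f"DMR{d + 1:03d}", "gene_id": dmr_gene_ids[d],
            "chrom": gene["chrom"], "start": int(pos[0]), "end": int(pos[-1]),
            "n_cpgs": cfg.dmr_n_cpgs,
            "probe_ids": ";".join(f"cg{i:07d}" for i in members),
            "true_delta_beta": sign * cfg.dmr_delta_beta,
            "is_cis": d < cfg.n_cis_effects,
        })

    # background probes, a fraction carrying each exclusion flag
    n_bg = cfg.n_cpgs - pid
    flag_kind = rng_layout.choice(
        ["none", "allosomal", "chr21", "polymorphic", "crossreactive"],
        size=n_bg, p=[0.91, 0.03, 0.02, 0.02, 0.02])
    host = rng_layout.integers(0, len(genes), size=n_bg)
    offset = rng_layout.integers(-3_000, GENE_SPAN + 3_000, size=n_bg)
    bg_chrom = genes["chrom"].to_numpy()[host].astype(object)
    bg_pos = np.maximum(1, genes["start"].to_numpy()[host] + offset)
    rnd_pos = rng_layout.integers(10_000, 5_000_000, size=n_bg)
    allo = flag_kind == "allosomal"
    bg_chrom[allo] = np.where(rng_layout.random(int(allo.sum())) < 0.8,
                              "chrX", "chrY")
    bg_pos[allo] = rnd_pos[allo]
    on21 = flag_kind == "chr21"
    bg_chrom[on21] = "chr21"
    bg_pos[on21] = rnd_pos[on21]
    for k in range(n_bg):
        kind = flag_kind[k]
        probe_rows.append((f"cg{pid:07d}", bg_chrom[k], int(bg_pos[k]),
                           kind == "allosomal", kind == "chr21",
                           kind == "polymorphic", kind == "crossreactive"))
        pid += 1

    cpgs = pd.DataFrame(probe_rows, columns=[
        "probe_id", "chrom", "position", "flag_allosomal", "flag_chr21",
        "flag_polymorphic", "flag_crossreactive"]).set_index("probe_id")

    # ---- methylation values -------------------------------------------
    n_cpgs = len(cpgs)
    base_beta = np.clip(rng_meth.beta(0.4, 0.4, size=n_cpgs), 0.02, 0.98)
    for d in range(cfg.n_planted_dmrs):
        # keep room for the shift on the beta scale
        base_beta[dmr_member_idx[d]] = rng_meth.uniform(0.30, 0.70, cfg.dmr_n_cpgs)

    mu_logit = np.tile(_logit(base_beta)[:, None], (1, n_samples))
    delta_logit = np.zeros(n_cpgs)
    for d in range(cfg.n_planted_dmrs):
        idx = dmr_member_idx[d]
        shifted = np.clip(base_beta[idx] + dmr_sign[d] * cfg.dmr_delta_beta, 0.01, 0.99)
        delta_logit[idx] = _logit(shifted) - _logit(base_beta[idx])
    mu_logit += np.outer(delta_logit, is_ds.astype(float))

    sex_coef_m = rng_meth.normal(0.0, cfg.sex_effect_sd, size=n_cpgs)
    batch_coef_m = rng_meth.normal(0.0, cfg.batch_effect_sd, size=n_cpgs)
    mu_logit += np.outer(sex_coef_m, is_male.astype(float))
    mu_logit += np.outer(batch_coef_m, in_batch.astype(float))

    # per-sample regional random effect: shared across a DMR's members, so the
    # region's median methylation varies between samples (drives cis coupling)
    region_effect = rng_meth.normal(0.0, DMR_RANDOM_EFFECT_SD,
                                    size=(cfg.n_planted_dmrs, n_samples))
    for d in range(cfg.n_planted_dmrs):
        mu_logit[dmr_member_idx[d]] += region_effect[d][None, :]

    latent_beta = _expit(mu_logit)  # pre-noise, used for cis coupling
    noise = rng_noise.normal(0.0, cfg.beta_noise_sd, size=(n_cpgs, n_samples))
    betas = _expit(mu_logit + noise)

    # ---- expression ----------------------------------------------------
    weights = rng_expr.lognormal(0.0, 1.0, size=cfg.n_genes)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    thy_idx = [gidx[g] for g in THYROID_MARKERS]
    mus_idx = [gidx[g] for g in MUSCLE_MARKERS]
    weights[thy_idx] = rng_expr.lognormal(0.0, 0.25, size=len(thy_idx)) * 50.0
    weights[mus_idx] = rng_expr.lognormal(0.0, 0.25, size=len(mus_idx)) * 0.02
    rel = weights / weights.sum()

    log2_shift = np.zeros((cfg.n_genes, n_samples))
    aff_idx = np.array([gidx[g] for g in affected_chr21], dtype=int)
    if len(aff_idx):
        log2_shift[np.ix_(aff_idx, np.where(is_ds)[0])] += np.log2(cfg.dosage_factor)
    for g, l2 in zip(planted_de_ids, planted_lfc):
        log2_shift[gidx[g], is_ds] += l2

    # cis couplings: expression tracks the region's latent median beta
    cis_true_lfc = {}
    for d in range(cfg.n_cis_effects):
        sign = signs[d % len(signs)]
        g = dmr_gene_ids[d]
        med = np.median(latent_beta[dmr_member_idx[d]], axis=0)
        centred = med - med.mean()
        log2_shift[gidx[g]] += CIS_GAIN * sign * centred
        grp = (centred[is_ds & ~is_contam].mean()
               - centred[~is_ds & ~is_outlier].mean())
        cis_true_lfc[g] = CIS_GAIN * sign * grp
        cis_rows.append({"dmr_id": f"DMR{d + 1:03d}", "gene_id": g,
                         "slope_sign": int(sign),
                         "true_delta_beta": dmr_sign[d] * cfg.dmr_delta_beta})

    sex_coef_e = rng_expr.normal(0.0, cfg.sex_effect_sd, size=cfg.n_genes)
    batch_coef_e = rng_expr.normal(0.0, cfg.batch_effect_sd, size=cfg.n_genes)
    log2_shift += np.outer(sex_coef_e, is_male.astype(float))
    log2_shift += np.outer(batch_coef_e, in_batch.astype(float))

    # contaminants: swap tissue identity at the marker genes
    for s in np.where(is_contam)[0]:
        for ti, mi in zip(thy_idx, list(mus_idx) * 2):
            log2_shift[ti, s] += np.log2(weights[mi] / weights[ti])
        for mi, ti in zip(mus_idx, thy_idx):
            log2_shift[mi, s] += np.log2(weights[ti] / weights[mi])

    # sample-quality latent factor (degradation-like shared gene profile);
    # outliers sit at an extreme score and carry extra per-gene noise, so
    # their expression profile has inflated variance along a low-rank axis
    quality_profile = rng_expr.normal(0.0, 1.0, size=cfg.n_genes)
    quality_score = rng_expr.normal(0.0, QUALITY_SCORE_SD, size=n_samples)
    for s in np.where(is_outlier)[0]:
        quality_score[s] = OUTLIER_QUALITY_SCORE * rng_noise.choice([-1.0, 1.0])
        log2_shift[:, s] += rng_noise.normal(0.0, OUTLIER_LOGNOISE_SD, cfg.n_genes)
    log2_shift += np.outer(quality_profile, quality_score)

    lib = rng_expr.uniform(cfg.library_size_range[0], cfg.library_size_range[1],
                           size=n_samples)
    mu = rel[:, None] * lib[None, :] * np.exp2(log2_shift)

    r = 1.0 / cfg.nb_dispersion
    p_nb = r / (r + mu)
    counts = rng_noise.negative_binomial(r, p_nb).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples.index)
    betas_df = pd.DataFrame(betas, index=cpgs.index, columns=samples.index)

    # ---- truth ledger --------------------------------------------------
    de_rows = [{"gene_id": g, "true_log2fc": np.log2(cfg.dosage_factor),
                "kind": "chr21_dosage"} for g in affected_chr21
               if cfg.dosage_factor != 1.0]
    de_rows += [{"gene_id": g, "true_log2fc": l2, "kind": "planted"}
                for g, l2 in zip(planted_de_ids, planted_lfc)]
    de_rows += [{"gene_id": g, "true_log2fc": l2, "kind": "cis"}
                for g, l2 in cis_true_lfc.items()]
    truth = {
        "de_genes": pd.DataFrame(de_rows),
        "dmrs": pd.DataFrame(dmr_rows),
        "cis_pairs": pd.DataFrame(cis_rows),
        "samples": samples.reset_index()[["sample_id", "role"]].query("role != 'none'"),
    }

    return SimulatedStudy(counts=counts_df, betas=betas_df, samples=samples,
                          gene_annotation=genes, cpg_annotation=cpgs,
                          truth=truth, config=cfg)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write all study tables as TSV (features as rows, samples as columns)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    study.betas.to_csv(outdir / "betas.tsv", sep="\t", index_label="probe_id")
    study.samples.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample_id")
    study.gene_annotation.to_csv(outdir / "genes.tsv", sep="\t", index_label="gene_id")
    study.cpg_annotation.to_csv(outdir / "cpgs.tsv", sep="\t", index_label="probe_id")
    for name, tab in study.truth.items():
        tab.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)
    if study.config is not None:
        meta = pd.Series(asdict(study.config)).astype(str)
        meta.to_csv(outdir / "simulation_metadata.tsv", sep="\t", header=False)
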