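"""Differential methylation: probe filtering, DMP linear models, and
bump-hunting DMR detection with a sample-permutation null.

Positions (DMPs) are tested per CpG by ordinary least squares on M-values
(logit2 of the methylation fraction beta) with condition, sex and
surrogate-batch covariates. Regions (DMRs) are found by bump hunting on the
beta scale: per-CpG condition coefficients are smoothed within clusters of
nearby CpGs, runs of at least ``min_cpgs`` consecutive CpGs whose smoothed
coefficient exceeds the cutoff with a single sign become candidate regions
scored by their area (sum of absolute smoothed coefficients), and p-values
come from re-running the search under permuted condition labels, pooling all
null-region areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_probes", "beta_to_m", "m_to_beta", "estimate_surrogate",
    "dmp_test", "find_dmrs", "MethylationLM", "DMPResults",
    "BumpHunter", "DMRResults", "build_design",
]

EPS = 1e-6
FILTER_FLAGS = ["flag_allosomal", "flag_chr21", "flag_polymorphic",
                "flag_crossreactive"]


def filter_probes(betas: pd.DataFrame, cpg_annotation: pd.DataFrame) -> pd.Index:
    """Retain probes carrying none of the exclusion flags.

    Flags mark allosomal probes, chromosome-21 probes (trisomic copy number
    confounds intensity), probes at polymorphic sites (minor allele
    frequency > 0.01) and cross-reactive probes.
    """
    missing = betas.index.difference(cpg_annotation.index)
    if len(missing):
        raise ValueError(f"probes missing annotation: {list(missing[:5])}")
    ann = cpg_annotation.loc[betas.index]
    flagged = ann[FILTER_FLAGS].any(axis=1)
    return betas.index[~flagged.to_numpy()]


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)), beta clipped to [1e-6, 1 - 1e-6]."""
    b = np.clip(np.asarray(beta, dtype=float), EPS, 1.0 - EPS)
    out = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (2^M + 1)."""
    x = np.exp2(np.asarray(m, dtype=float))
    out = x / (1.0 + x)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index)
    return out


def build_design(samples: pd.DataFrame, sample_ids,
                 surrogates: np.ndarray | None = None) -> np.ndarray:
    """Intercept + condition + sex (+ surrogate columns) design matrix."""
    cond = (samples.loc[sample_ids, "condition"] == "DS").astype(float).to_numpy()
    sex = (samples.loc[sample_ids, "sex"] == "M").astype(float).to_numpy()
    cols = [np.ones(len(sample_ids)), cond, sex]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X = np.column_stack(cols[:2])
    if surrogates is not None:
        sv = np.asarray(surrogates, dtype=float)
        if sv.ndim == 1:
            sv = sv[:, None]
        X = np.column_stack([X, sv])
    return X


def _ols_all(Y: np.ndarray, X: np.ndarray):
    """OLS of every row of Y on X. Returns (coef, resid, XtX_inv)."""
    pinv = np.linalg.pinv(X)              # p x n
    coef = Y @ pinv.T                      # features x p
    resid = Y - coef @ X.T
    XtX_inv = np.linalg.inv(X.T @ X)
    return coef, resid, XtX_inv


def estimate_surrogate(M: pd.DataFrame, samples: pd.DataFrame,
                       n_sv: int = 1) -> np.ndarray:
    """Surrogate covariates from residual principal components.

    Residualizes the M matrix on the nuisance design (intercept + sex,
    deliberately NOT the condition) and takes the first ``n_sv`` right
    singular vectors of the residual matrix over samples, scaled to unit
    variance. Leaving the condition out lets the surrogate capture the
    full batch direction even when batch is chance-correlated with
    condition in a small cohort; projecting the condition out first would
    leave that correlated batch component in the condition coefficient and
    inflate its test. By construction the surrogate is orthogonal to the
    nuisance columns.
    """
    sex = (samples.loc[M.columns, "sex"] == "M").astype(float).to_numpy()
    X = np.column_stack([np.ones(len(sex)), sex])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X = X[:, :1]
    n = X.shape[0]
    if n_sv >= n - np.linalg.matrix_rank(X):
        raise ValueError(f"n_sv={n_sv} >= residual degrees of freedom")
    _, resid, _ = _ols_all(M.to_numpy(dtype=float), X)
    # SVD over samples of the residual matrix
    _, _, Vt = np.linalg.svd(resid - resid.mean(axis=1, keepdims=True),
                             full_matrices=False)
    sv = Vt[:n_sv].T
    sv = sv / sv.std(axis=0, ddof=1)
    return sv


def dmp_test(M: pd.DataFrame, betas: pd.DataFrame, samples: pd.DataFrame,
             surrogates: np.ndarray | None = None) -> pd.DataFrame:
    """Per-CpG OLS of M-values on condition + sex (+ surrogates).

    Returns delta_beta (group mean difference on the beta scale),
    m_coefficient (condition effect on the M scale), t statistic with
    residual degrees of freedom, two-sided p and BH FDR.
    """
    X = build_design(samples, M.columns, surrogates)
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    for cond in ("DS", "control"):
        if (samples.loc[M.columns, "condition"] == cond).sum() < 2:
            raise ValueError(f"need >= 2 samples in condition {cond!r}")
    Y = M.to_numpy(dtype=float)
    coef, resid, XtX_inv = _ols_all(Y, X)
    sigma2 = (resid ** 2).sum(axis=1) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef[:, 1] / se, np.inf * np.sign(coef[:, 1]))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    is_ds = (samples.loc[M.columns, "condition"] == "DS").to_numpy()
    B = betas.loc[M.index, M.columns].to_numpy(dtype=float)
    delta_beta = B[:, is_ds].mean(axis=1) - B[:, ~is_ds].mean(axis=1)
    return pd.DataFrame({
        "delta_beta": delta_beta, "m_coefficient": coef[:, 1],
        "t_stat": t, "p": pvals,
        "fdr": multipletests(pvals, method="fdr_bh")[1],
    }, index=M.index)


def _cluster_positions(chrom: np.ndarray, pos: np.ndarray, maxgap: int) -> np.ndarray:
    """Cluster ids for position-sorted CpGs: a new cluster starts at each
    chromosome change or gap > maxgap."""
    newc = np.ones(len(pos), dtype=bool)
    if len(pos) > 1:
        same = chrom[1:] == chrom[:-1]
        near = (pos[1:] - pos[:-1]) <= maxgap
        newc[1:] = ~(same & near)
    return np.cumsum(newc) - 1


def _running_mean_within(values: np.ndarray, cluster: np.ndarray,
                         window: int = 3) -> np.ndarray:
    """Centered running mean (window truncated at cluster edges)."""
    out = np.empty_like(values, dtype=float)
    half = window // 2
    start = 0
    n = len(values)
    while start < n:
        end = start
        while end < n and cluster[end] == cluster[start]:
            end += 1
        v = values[start:end]
        m = len(v)
        csum = np.concatenate([[0.0], np.cumsum(v)])
        idx = np.arange(m)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, m)
        out[start:end] = (csum[hi] - csum[lo]) / (hi - lo)
        start = end
    return out


def _beta_condition_coef(B: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Covariate-adjusted condition coefficient on the beta scale, per CpG."""
    coef, _, _ = _ols_all(B, X)
    return coef[:, 1]


def _find_candidates(smoothed: np.ndarray, cluster: np.ndarray,
                     cutoff: float, min_cpgs: int) -> list[tuple[int, int, float]]:
    """Maximal single-sign runs of >= min_cpgs CpGs with |smoothed| >= cutoff.

    Returns (start_idx, end_idx_inclusive, area) triples.
    """
    n = len(smoothed)
    out = []
    i = 0
    while i < n:
        if abs(smoothed[i]) < cutoff:
            i += 1
            continue
        sign = np.sign(smoothed[i])
        j = i
        while (j + 1 < n and cluster[j + 1] == cluster[i]
               and abs(smoothed[j + 1]) >= cutoff
               and np.sign(smoothed[j + 1]) == sign):
            j += 1
        if j - i + 1 >= min_cpgs:
            out.append((i, j, float(np.abs(smoothed[i:j + 1]).sum())))
        i = j + 1
    return out


def find_dmrs(betas: pd.DataFrame, samples: pd.DataFrame,
              cpg_annotation: pd.DataFrame,
              surrogates: np.ndarray | None = None,
              cutoff: float = 0.05, min_cpgs: int = 3, maxgap: int = 500,
              n_perm: int = 100, smooth_window: int = 3,
              seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Bump-hunting DMR detection with a permutation null.

    Per CpG the condition coefficient on the beta scale (covariate-adjusted)
    is smoothed by a running mean of ``smooth_window`` within clusters of
    CpGs at most ``maxgap`` bp apart; candidate regions are maximal
    single-sign runs of at least ``min_cpgs`` CpGs with |coefficient| >=
    ``cutoff``, scored by area = sum |coefficient|. The null pools the areas
    of all candidate regions found under ``n_perm`` permutations of the
    condition labels (covariates stay attached to samples);
    p = (1 + #null areas >= area) / (1 + #null areas), BH-adjusted.
    """
    if n_perm < 10:
        import warnings
        warnings.warn("n_perm < 10 gives an unstable permutation p floor")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    ann = cpg_annotation.loc[betas.index, ["chrom", "position"]]
    order = np.lexsort((ann["position"].to_numpy(), ann["chrom"].to_numpy()))
    probe_ids = betas.index.to_numpy()[order]
    chrom = ann["chrom"].to_numpy()[order]
    pos = ann["position"].to_numpy()[order]
    B = betas.to_numpy(dtype=float)[order]

    X = build_design(samples, betas.columns, surrogates)
    cluster = _cluster_positions(chrom, pos, maxgap)

    coef = _beta_condition_coef(B, X)
    smoothed = _running_mean_within(coef, cluster, smooth_window)
    candidates = _find_candidates(smoothed, cluster, cutoff, min_cpgs)

    is_ds = (samples.loc[betas.columns, "condition"] == "DS").to_numpy()
    delta_beta_cpg = B[:, is_ds].mean(axis=1) - B[:, ~is_ds].mean(axis=1)

    # permutation null: shuffle the condition column, keep other covariates.
    # Balanced permutations (pseudo-groups drawing equally from each true
    # condition) are used when group sizes allow: they keep the null
    # orthogonal to the true grouping, so planted effects cannot leak into
    # the null distribution.
    null_areas: list[float] = []
    cond = X[:, 1].copy()
    ds_idx = np.where(cond == 1)[0]
    ct_idx = np.where(cond == 0)[0]
    n_ds = len(ds_idx)
    balanced = n_ds % 2 == 0 and len(ct_idx) % 2 == 0 and min(n_ds, len(ct_idx)) >= 2
    Xp = X.copy()
    for _ in range(n_perm):
        if balanced:
            lab = np.zeros(len(cond))
            lab[rng.choice(ds_idx, n_ds // 2, replace=False)] = 1.0
            lab[rng.choice(ct_idx, n_ds - n_ds // 2, replace=False)] = 1.0
            Xp[:, 1] = lab
        else:
            Xp[:, 1] = rng.permutation(cond)
        if np.linalg.matrix_rank(Xp) < Xp.shape[1]:
            continue
        c_p = _beta_condition_coef(B, Xp)
        s_p = _running_mean_within(c_p, cluster, smooth_window)
        null_areas.extend(a for _, _, a in _find_candidates(s_p, cluster,
                                                            cutoff, min_cpgs))
    null = np.sort(np.asarray(null_areas))

    rows = []
    for rank, (i, j, area) in enumerate(candidates, start=1):
        members = probe_ids[i:j + 1]
        n_ge = len(null) - np.searchsorted(null, area, side="left")
        pval = (1.0 + n_ge) / (1.0 + len(null))
        rows.append({
            "region_id": f"dmr_{rank:04d}", "chrom": chrom[i],
            "start": int(pos[i]), "end": int(pos[j]),
            "n_cpgs": j - i + 1, "probe_ids": ";".join(members),
            "mean_delta_beta": float(np.mean(delta_beta_cpg[i:j + 1])),
            "area": area, "p": pval,
        })
    out = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end",
                                      "n_cpgs", "probe_ids", "mean_delta_beta",
                                      "area", "p"])
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


class MethylationLM:
    """Position-level differential-methylation model (M ~ condition + sex + SV)."""

    def __init__(self, betas: pd.DataFrame, samples: pd.DataFrame,
                 cpg_annotation: pd.DataFrame, n_sv: int = 1):
        kept = filter_probes(betas, cpg_annotation)
        self.betas = betas.loc[kept]
        self.samples = samples
        self.cpg_annotation = cpg_annotation.loc[kept]
        self.M = beta_to_m(self.betas)
        self.surrogates = (estimate_surrogate(self.M, samples, n_sv)
                           if n_sv > 0 else None)

    def fit(self, fdr_cutoff: float = 0.05) -> "DMPResults":
        table = dmp_test(self.M, self.betas, self.samples, self.surrogates)
        return DMPResults(table, self, fdr_cutoff=fdr_cutoff)


@dataclass
class DMPResults:
    table: pd.DataFrame
    model: "MethylationLM | None" = None
    fdr_cutoff: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["fdr"] < self.fdr_cutoff]

    def near_genes(self, genes: pd.DataFrame, window: int = 2000,
                   thyroid_related_only: bool = False) -> pd.DataFrame:
        """Restrict the DMP table to CpGs within ``window`` bp of genes
        (optionally only thyroid-related genes)."""
        from .genomic import annotate_region_to_genes
        if thyroid_related_only:
            genes = genes[genes["thyroid_related"].astype(bool)]
        ann = self.model.cpg_annotation if self.model is not None else None
        if ann is None:
            raise ValueError("needs a fitted model carrying CpG annotation")
        keep, gene_of = [], []
        for probe, row in ann.loc[self.table.index].iterrows():
            hits = annotate_region_to_genes(
                (row["chrom"], int(row["position"]), int(row["position"])),
                genes, window=window)
            if hits:
                keep.append(probe)
                gene_of.append(";".join(g for g, _ in hits))
        out = self.table.loc[keep].copy()
        out["genes"] = gene_of
        return out

    def summary(self) -> str:
        sig = self.significant
        hypo = int((sig["delta_beta"] < 0).sum())
        return ("Differential methylation positions (M ~ condition + sex + SV)\n"
                f"  CpGs tested: {len(self.table)}\n"
                f"  DMPs at FDR < {self.fdr_cutoff:g}: {len(sig)} "
                f"({hypo} hypomethylated in DS)")


class BumpHunter:
    """Region-level differential-methylation model (bump hunting)."""

    def __init__(self, betas: pd.DataFrame, samples: pd.DataFrame,
                 cpg_annotation: pd.DataFrame,
                 surrogates: np.ndarray | None = None,
                 cutoff: float = 0.05, min_cpgs: int = 3, maxgap: int = 500,
                 smooth_window: int = 3):
        kept = filter_probes(betas, cpg_annotation)
        self.betas = betas.loc[kept]
        self.samples = samples
        self.cpg_annotation = cpg_annotation.loc[kept]
        self.surrogates = surrogates
        self.cutoff = cutoff
        self.min_cpgs = min_cpgs
        self.maxgap = maxgap
        self.smooth_window = smooth_window

    def fit(self, n_perm: int = 100, seed: int | np.random.Generator = 0,
            fdr_cutoff: float = 0.01) -> "DMRResults":
        table = find_dmrs(self.betas, self.samples, self.cpg_annotation,
                          surrogates=self.surrogates, cutoff=self.cutoff,
                          min_cpgs=self.min_cpgs, maxgap=self.maxgap,
                          n_perm=n_perm, smooth_window=self.smooth_window,
                          seed=seed)
        return DMRResults(table, self, fdr_cutoff=fdr_cutoff)


@dataclass
class DMRResults:
    table: pd.DataFrame
    model: "BumpHunter | None" = None
    fdr_cutoff: float = 0.01

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["fdr"] < self.fdr_cutoff]

    def summary(self) -> str:
        sig = self.significant
        return ("Bump-hunting differentially methylated regions\n"
                f"  candidate regions: {len(self.table)}\n"
                f"  DMRs at FDR < {self.fdr_cutoff:g}: {len(sig)} "
                f"({int((sig['mean_delta_beta'] > 0).sum())} hypermethylated in DS)")
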