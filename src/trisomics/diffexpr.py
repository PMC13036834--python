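"""Negative-binomial Wald differential expression with dosage-enrichment tests.

The model per gene g and sample s is

    K_gs ~ NB(mu_gs, alpha_g),   log mu_gs = log sf_s + x_s' beta_g

with ``sf`` the median-of-ratios size factors, a design of intercept +
condition (control as reference, so positive log2 fold change = up in the
trisomic group) + sex, and a trended dispersion alpha(mu) = a0 + a1/mu
fitted across genes from design-residual method-of-moments estimates (the
per-gene estimates are too noisy at ~10 samples to use directly and serve
only to fit the trend). The condition coefficient is tested with a Wald z
statistic from the expected-information matrix, p-values are BH-adjusted,
and fold changes are optionally shrunk with an empirical-Bayes normal prior.

Chromosome-level enrichment statistics (chi-squared) quantify the excess of
differentially expressed genes on chromosome 21 expected under a trisomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "prefilter_genes", "size_factors", "nb_wald_test", "shrink_lfc",
    "chromosome_enrichment", "NegativeBinomialDE", "DEResults",
]

LN2 = np.log(2.0)


def prefilter_genes(counts: pd.DataFrame, min_count: int = 10,
                    min_samples: int = 4) -> pd.Index:
    """Keep genes with at least ``min_count`` counts in ``min_samples`` samples."""
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    return counts.index[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    Per gene the geometric mean across samples is the reference (genes with a
    zero in any sample are excluded); a sample's factor is the median over
    genes of count/reference.
    """
    X = counts.to_numpy(dtype=float)
    all_pos = (X > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has nonzero counts in every sample; "
                         "a pseudo-reference fallback is not implemented")
    logX = np.log(X[all_pos])
    log_geo = logX.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logX - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _mom_dispersion(q: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion per gene from normalized counts.

    Uses the residual variance after projecting out the design (so modelled
    group structure does not masquerade as biological dispersion):
    Var(K) = mu + alpha * mu^2  =>  alpha = (s2_resid - mu) / mu^2.
    """
    n, p = X.shape
    H = X @ np.linalg.pinv(X)
    resid = q - q @ H.T
    s2 = (resid ** 2).sum(axis=1) / (n - p)
    mu = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (s2 - mu) / mu ** 2
    return np.where(np.isfinite(disp), disp, 0.0)


def _dispersion_trend(mu: np.ndarray, disp: np.ndarray,
                      trim: float = 0.3) -> tuple[float, float]:
    """Fit disp ~ a0 + a1/mu by trimmed least squares (drop the ``trim``
    fraction of largest absolute residuals, refit once)."""
    ok = (mu > 0) & (disp > 0)
    if ok.sum() < 10:
        return float(np.median(disp[disp > 0])) if (disp > 0).any() else 0.01, 0.0
    x = 1.0 / mu[ok]
    y = disp[ok]
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = np.abs(y - X @ coef)
    keep = resid <= np.quantile(resid, 1.0 - trim)
    if keep.sum() >= 2:
        coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
    a0 = max(float(coef[0]), 1e-8)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
             max_iter: int = 50, tol: float = 1e-8):
    """Fit one NB log-link GLM; returns (beta, cov, converged)."""
    n, p = X.shape
    # start from the (offset-adjusted) log mean
    beta = np.zeros(p)
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    for _ in range(max_iter):
        eta = offset + X @ beta
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        A = XtW @ X
        b = XtW @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return beta, None, False
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        eta = np.clip(offset + X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        A = (X.T * W) @ X
        try:
            return beta, np.linalg.inv(A), False
        except np.linalg.LinAlgError:
            return beta, None, False
    eta = np.clip(offset + X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha * mu)
    A = (X.T * W) @ X
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return beta, None, False
    return beta, cov, True


def _build_design(samples: pd.DataFrame, sample_ids) -> np.ndarray:
    cond = (samples.loc[sample_ids, "condition"] == "DS").astype(float).to_numpy()
    sex = (samples.loc[sample_ids, "sex"] == "M").astype(float).to_numpy()
    X = np.column_stack([np.ones(len(sample_ids)), cond, sex])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # sex confounded (single-sex cohort): drop it
        X = X[:, :2]
    return X


def nb_wald_test(counts: pd.DataFrame, sf: pd.Series,
                 samples: pd.DataFrame,
                 gene_annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene NB Wald test of condition (DS vs control) with sex covariate.

    Returns a DataFrame indexed by gene with base_mean, log2fc, se, wald_z,
    p, fdr (BH) and chromosome (when annotation is given). Genes whose IRLS
    fit fails get p = NaN and are excluded from the BH adjustment.
    """
    for cond, nmin in (("DS", 2), ("control", 2)):
        if (samples.loc[counts.columns, "condition"] == cond).sum() < nmin:
            raise ValueError(f"need >= {nmin} samples in condition {cond!r}")
    X = _build_design(samples, counts.columns)
    offset = np.log(sf.loc[counts.columns].to_numpy(dtype=float))
    Y = counts.to_numpy(dtype=float)
    q = Y / np.exp(offset)[None, :]
    base_mean = q.mean(axis=1)

    # Trended dispersion: per-gene method-of-moments values are far too
    # noisy at ~10 samples to plug in directly (taking max(trend, MoM)
    # inflates alpha by the half-normal noise and makes the Wald test
    # conservative), so they only inform the mean-dispersion trend, which
    # supplies the working dispersion for every gene.
    mom = _mom_dispersion(q, X)
    trend_mask = (Y > 0).sum(axis=1) >= 3
    a0, a1 = _dispersion_trend(base_mean[trend_mask], mom[trend_mask])
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(base_mean > 0, base_mean, np.inf)
    alpha = np.clip(trend, 1e-8, 10.0)

    n_genes = Y.shape[0]
    df_resid = X.shape[0] - X.shape[1]
    log2fc = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    z = np.full(n_genes, np.nan)
    p = np.full(n_genes, np.nan)
    for g in range(n_genes):
        beta, cov, ok = _irls_nb(Y[g], X, offset, alpha[g])
        if cov is None:
            continue
        b = beta[1]
        s = np.sqrt(max(cov[1, 1], 0.0))
        if not ok and s == 0.0:
            continue
        log2fc[g] = b / LN2
        se[g] = s / LN2
        if s > 0:
            z[g] = b / s
            p[g] = 2.0 * stats.norm.sf(abs(z[g]))

    fdr = np.full(n_genes, np.nan)
    tested = np.isfinite(p)
    if tested.any():
        fdr[tested] = multipletests(p[tested], method="fdr_bh")[1]

    out = pd.DataFrame({
        "base_mean": base_mean, "log2fc": log2fc, "se": se,
        "wald_z": z, "p": p, "fdr": fdr, "dispersion": alpha,
    }, index=counts.index)
    if gene_annotation is not None:
        out["chrom"] = gene_annotation.reindex(out.index)["chrom"]
    return out


def shrink_lfc(de: pd.DataFrame) -> pd.Series:
    """Empirical-Bayes normal-prior shrinkage of log2 fold changes.

    The prior variance tau^2 is moment-matched from the marginal spread of
    the estimates: Var(log2fc) = tau^2 + E[se^2], so
    tau^2 = Var(log2fc) - mean(se^2), falling back to median(se^2) when the
    estimate is non-positive. The posterior mean under a N(0, tau^2) prior is
    log2fc * tau^2 / (tau^2 + se^2), a contraction toward zero scaled by the
    standard error.
    """
    ok = de["log2fc"].notna() & de["se"].notna()
    lfc = de.loc[ok, "log2fc"].to_numpy()
    se2 = de.loc[ok, "se"].to_numpy() ** 2
    tau2 = float(np.var(lfc, ddof=1) - np.mean(se2)) if len(lfc) > 1 else 0.0
    if tau2 <= 0:
        tau2 = float(np.median(se2))
    shrunk = pd.Series(np.nan, index=de.index, name="shrunken_log2fc")
    shrunk.loc[ok] = lfc * tau2 / (tau2 + se2)
    return shrunk


def _pearson_chi2(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-squared without continuity correction for an r x c table."""
    table = np.asarray(table, dtype=float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0:
        return 0.0, 1.0, 0
    expected = rowsum * colsum / total
    ok = expected > 0
    chi2 = float(((table[ok] - expected[ok]) ** 2 / expected[ok]).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, df)), df


def _pool_small(observed: np.ndarray, expected: np.ndarray,
                min_expected: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Merge cells with expected < min_expected into one pooled cell."""
    small = expected < min_expected
    if small.sum() <= 1:
        return observed, expected
    obs = np.append(observed[~small], observed[small].sum())
    exp = np.append(expected[~small], expected[small].sum())
    return obs, exp


def chromosome_enrichment(de: pd.DataFrame, fdr_cutoff: float = 0.05) -> dict:
    """Chromosome-level enrichment statistics for the DEG set.

    Returns three chi-squared tests:

    * ``chr21`` — 2x2 (DEG vs not) x (chr21 vs other), Pearson statistic
      without continuity correction;
    * ``uniformity`` — goodness of fit of per-chromosome DEG counts to the
      expressed-gene distribution, chr21 excluded, small expected cells
      pooled;
    * ``direction`` — homogeneity of up/down DEG counts across chromosomes,
      chr21 excluded, chromosomes with small expected counts pooled.
    """
    if "chrom" not in de.columns:
        raise ValueError("DE table lacks a 'chrom' column")
    d = de[de["p"].notna() & de["chrom"].notna()]
    is_deg = d["fdr"] < fdr_cutoff
    res: dict[str, dict] = {}
    if is_deg.sum() == 0:
        flat = {"chi2": 0.0, "p": 1.0, "df": 0}
        return {"chr21": dict(flat), "uniformity": dict(flat),
                "direction": dict(flat), "warning": "empty DEG set"}

    on21 = d["chrom"] == "chr21"
    table = np.array([
        [int((is_deg & on21).sum()), int((is_deg & ~on21).sum())],
        [int((~is_deg & on21).sum()), int((~is_deg & ~on21).sum())],
    ])
    chi2, pval, df = _pearson_chi2(table)
    res["chr21"] = {"chi2": chi2, "p": pval, "df": df, "table": table}

    rest = d[~on21]
    deg_rest = rest[is_deg.loc[rest.index]]
    expressed = rest.groupby("chrom").size()
    observed = deg_rest.groupby("chrom").size().reindex(expressed.index, fill_value=0)
    expected = expressed / expressed.sum() * observed.sum()
    obs, exp = _pool_small(observed.to_numpy(dtype=float), expected.to_numpy())
    if len(obs) > 1 and observed.sum() > 0:
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        df = len(obs) - 1
        res["uniformity"] = {"chi2": chi2, "p": float(stats.chi2.sf(chi2, df)),
                             "df": df}
    else:
        res["uniformity"] = {"chi2": 0.0, "p": 1.0, "df": 0}

    up = deg_rest["log2fc"] > 0
    tab = pd.crosstab(deg_rest["chrom"], up.map({True: "up", False: "down"}))
    if tab.shape[0] > 1 and tab.shape[1] == 2:
        # pool chromosomes whose smaller expected cell is < 5
        t = tab.to_numpy(dtype=float)
        exp_t = t.sum(axis=1, keepdims=True) * t.sum(axis=0, keepdims=True) / t.sum()
        small = (exp_t < 5.0).any(axis=1)
        if small.sum() > 1:
            t = np.vstack([t[~small], t[small].sum(axis=0)])
        if t.shape[0] > 1:
            chi2, pval, df = _pearson_chi2(t)
            res["direction"] = {"chi2": chi2, "p": pval, "df": df}
        else:
            res["direction"] = {"chi2": 0.0, "p": 1.0, "df": 0}
    else:
        res["direction"] = {"chi2": 0.0, "p": 1.0, "df": 0}
    return res


class NegativeBinomialDE:
    """Differential-expression model: counts ~ NB(condition + sex).

    Parameters
    ----------
    counts : DataFrame
        Gene x sample integer counts (already QC'd samples).
    samples : DataFrame
        Sample sheet indexed by sample id with ``condition`` (DS/control)
        and ``sex`` columns.
    gene_annotation : DataFrame, optional
        Indexed by gene id with at least a ``chrom`` column.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame,
                 gene_annotation: pd.DataFrame | None = None,
                 min_count: int = 10, min_samples: int = 4):
        self.counts_raw = counts
        self.samples = samples
        self.gene_annotation = gene_annotation
        kept = prefilter_genes(counts, min_count=min_count, min_samples=min_samples)
        self.counts = counts.loc[kept]
        self.size_factors = size_factors(self.counts)

    @classmethod
    def from_study(cls, study, qc_report=None, **kw) -> "NegativeBinomialDE":
        keep = (qc_report.kept_samples if qc_report is not None
                else list(study.counts.columns))
        return cls(study.counts[keep], study.samples,
                   study.gene_annotation, **kw)

    def fit(self, fdr_cutoff: float = 0.05) -> "DEResults":
        table = nb_wald_test(self.counts, self.size_factors, self.samples,
                             self.gene_annotation)
        table["shrunken_log2fc"] = shrink_lfc(table)
        return DEResults(table, self, fdr_cutoff=fdr_cutoff)


@dataclass
class DEResults:
    """Fitted differential-expression results."""

    table: pd.DataFrame
    model: NegativeBinomialDE | None = None
    fdr_cutoff: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["fdr"] < self.fdr_cutoff]

    def chromosome_enrichment(self) -> dict:
        return chromosome_enrichment(self.table, fdr_cutoff=self.fdr_cutoff)

    def summary(self) -> str:
        sig = self.significant
        lines = [
            "Negative-binomial Wald differential expression (DS vs control)",
            f"  genes tested: {int(self.table['p'].notna().sum())}",
            f"  DEGs at FDR < {self.fdr_cutoff:g}: {len(sig)} "
            f"({int((sig['log2fc'] > 0).sum())} up, "
            f"{int((sig['log2fc'] < 0).sum())} down)",
        ]
        if "chrom" in self.table.columns and self.table["chrom"].notna().any():
            enr = self.chromosome_enrichment()
            on21 = sig[sig["chrom"] == "chr21"]
            lines.append(f"  chr21 DEGs: {len(on21)}; chr21 enrichment "
                         f"chi2 p = {enr['chr21']['p']:.3g}")
            if len(on21):
                mean_fc = float(np.mean(2.0 ** np.abs(on21["log2fc"])))
                lines.append(f"  mean |fold change| of chr21 DEGs: {mean_fc:.2f}")
        return "\n".join(lines)
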