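"""Two-step sample quality control for small bulk cohorts.

Step 1 checks tissue identity from marker-gene expression (thyroid markers
TPO/TG/TSHR/SLC5A5 against skeletal-muscle markers MYH1/MYOD1) and flags
samples whose profile looks muscular. Step 2 runs a robust PCA by grid
projection pursuit (the PCAgrid idea: loadings maximise the MAD of the
projected samples instead of the variance) on the survivors and flags
samples whose robust distance exceeds the chi-squared 97.5% cutoff.

Also provides covariate residualization for visualisation (the
removeBatchEffect-style OLS adjustment) and Euclidean sample distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "log2_cpm", "marker_gene_check", "rpca_grid", "detect_outliers",
    "residualize", "sample_distances", "run_qc", "QcReport",
]

MAD_CONSISTENCY = 1.4826  # makes the MAD consistent for the normal sd

THYROID_MARKERS = ("TPO", "TG", "TSHR", "SLC5A5")
MUSCLE_MARKERS = ("MYH1", "MYOD1")


@dataclass
class QcReport:
    """Per-sample QC metrics and the resulting exclusion list."""

    marker_table: pd.DataFrame            # thyroid/muscle log2-CPM medians + flag
    scores: pd.DataFrame | None = None    # robust PC scores (post-marker samples)
    robust_scales: np.ndarray | None = None
    distances: pd.Series | None = None
    outlier_flags: pd.Series | None = None
    excluded: dict[str, str] = field(default_factory=dict)  # sample -> reason

    @property
    def kept_samples(self) -> list[str]:
        return [s for s in self.marker_table.index if s not in self.excluded]


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(counts-per-million + 1) per sample."""
    lib = counts.sum(axis=0).astype(float)
    return np.log2(counts.divide(lib, axis=1) * 1e6 + 1.0)


def marker_gene_check(counts: pd.DataFrame, gene_annotation: pd.DataFrame,
                      thyroid_markers=THYROID_MARKERS,
                      muscle_markers=MUSCLE_MARKERS) -> pd.DataFrame:
    """Flag samples whose muscle-marker expression dominates thyroid markers.

    Returns a per-sample table with median log2-CPM over each marker panel and
    ``contaminant_flag``. Ties (equal medians, e.g. an all-zero sample) flag
    the sample — conservative exclusion.
    """
    missing = [g for g in list(thyroid_markers) + list(muscle_markers)
               if g not in gene_annotation.index or g not in counts.index]
    if missing:
        raise ValueError(f"marker genes absent from counts/annotation: {missing}")
    lc = log2_cpm(counts)
    thy = lc.loc[list(thyroid_markers)].median(axis=0)
    mus = lc.loc[list(muscle_markers)].median(axis=0)
    return pd.DataFrame({
        "thyroid_log2cpm": thy, "muscle_log2cpm": mus,
        "contaminant_flag": mus >= thy,
    })


def _robust_scale(x: np.ndarray) -> float:
    return MAD_CONSISTENCY * float(np.median(np.abs(x - np.median(x))))


def rpca_grid(matrix: np.ndarray, k: int = 2, n_angles: int = 10,
              n_sweeps: int = 25) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Robust PCA by grid projection pursuit.

    ``matrix`` is samples x features (already residualized / transformed).
    For each component the loading direction maximises the scaled MAD of the
    projected samples. The search starts from the unit coordinate axis with
    the largest robust projection scale, then sweeps a regular grid of angles
    in the plane spanned by the current direction and each coordinate axis,
    keeping the argmax and halving the grid aperture each sweep. Data are
    deflated by the found component before the next one.

    Returns ``(scores, loadings, scales)`` with ``scores`` (n x k),
    ``loadings`` (p x k, orthonormal) and ``scales`` the robust scale of each
    score column. Columns are median-centered before the search.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("rpca_grid needs at least 3 samples")
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n_samples, n_features)={min(n, p)}")
    X = X - np.median(X, axis=0, keepdims=True)
    if not np.any(np.abs(X) > 0):
        raise ValueError("zero-variance matrix")

    loadings = np.zeros((p, k))
    scores = np.zeros((n, k))
    scales = np.zeros(k)
    Xd = X.copy()
    for comp in range(k):
        # start: coordinate axis with the largest robust projection scale
        col_scales = MAD_CONSISTENCY * np.median(
            np.abs(Xd - np.median(Xd, axis=0, keepdims=True)), axis=0)
        a = np.zeros(p)
        a[int(np.argmax(col_scales))] = 1.0
        proj_a = Xd @ a
        best = _robust_scale(proj_a)

        aperture = np.pi / 2.0
        for _ in range(n_sweeps):
            thetas = np.linspace(-aperture, aperture, n_angles)
            cos_t, sin_t = np.cos(thetas), np.sin(thetas)
            for j in range(p):
                # orthonormalised axis e_orth = (e_j - a_j * a) / norm, whose
                # projection is a column combination: no p-vector product needed
                norm2 = 1.0 - a[j] ** 2
                if norm2 < 1e-24:
                    continue
                norm = np.sqrt(norm2)
                proj_e = (Xd[:, j] - a[j] * proj_a) / norm
                # candidate projections for all angles at once
                cand = np.outer(proj_a, cos_t) + np.outer(proj_e, sin_t)
                med = np.median(cand, axis=0)
                s = MAD_CONSISTENCY * np.median(np.abs(cand - med), axis=0)
                i_best = int(np.argmax(s))
                if s[i_best] > best:
                    best = s[i_best]
                    e_orth = np.zeros(p)
                    e_orth[j] = 1.0
                    e_orth = (e_orth - a[j] * a) / norm
                    a = cos_t[i_best] * a + sin_t[i_best] * e_orth
                    a /= np.linalg.norm(a)
                    proj_a = Xd @ a
            aperture /= 2.0

        # re-orthogonalise against previous components (numerical guard)
        for c in range(comp):
            a -= (a @ loadings[:, c]) * loadings[:, c]
        a /= np.linalg.norm(a)
        s_comp = X @ a
        loadings[:, comp] = a
        scores[:, comp] = s_comp
        scales[comp] = _robust_scale(s_comp)
        Xd = Xd - np.outer(Xd @ a, a)
    return scores, loadings, scales


def detect_outliers(scores: np.ndarray, scales: np.ndarray,
                    quantile: float = 0.975) -> np.ndarray:
    """Flag samples whose robust score distance exceeds sqrt(chi2_k(q)).

    distance_i = sqrt(sum_j (score_ij / scale_j)^2) over the k components.
    """
    scores = np.asarray(scores, dtype=float)
    scales = np.asarray(scales, dtype=float)
    k = scores.shape[1]
    safe = np.where(scales > 0, scales, np.inf)
    d = np.sqrt(((scores / safe[None, :]) ** 2).sum(axis=1))
    cutoff = np.sqrt(stats.chi2.ppf(quantile, df=k))
    return d > cutoff


def residualize(matrix: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Remove covariate effects from a feature x sample matrix by OLS.

    Fits, per feature, an OLS model on an intercept plus the covariate
    columns and subtracts the covariate contribution, keeping the intercept
    (grand mean) and residual. Covariates must be numeric and the design
    full rank.
    """
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = C.shape[0]
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    Y = matrix.to_numpy(dtype=float)  # features x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (1+q) x features
    adjusted = Y - (C @ beta[1:, :]).T
    return pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns)


def sample_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between sample columns (for heatmaps/clustering)."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.to_numpy(dtype=float).T
    sq = (X ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    d = np.sqrt(np.clip(d2, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def run_qc(counts: pd.DataFrame, samples: pd.DataFrame,
           gene_annotation: pd.DataFrame, k: int = 2,
           quantile: float = 0.975) -> QcReport:
    """Full QC: marker check, then robust PCA outlier detection on survivors.

    The rPCA input is log2-CPM residualized for condition and sex, so
    outlyingness is judged against within-group variation.
    """
    marker = marker_gene_check(counts, gene_annotation)
    report = QcReport(marker_table=marker)
    for s in marker.index[marker["contaminant_flag"]]:
        report.excluded[s] = "marker_check: muscle-like expression profile"

    kept = [s for s in counts.columns if s not in report.excluded]
    if len(kept) < 3:
        return report
    # rPCA on expressed genes only: log2-CPM of near-zero-count genes is
    # discrete and would dominate the robust-scale search
    from .diffexpr import prefilter_genes
    expressed = prefilter_genes(counts[kept])
    lc = log2_cpm(counts.loc[expressed, kept])
    cov = pd.DataFrame({
        "condition": (samples.loc[kept, "condition"] == "DS").astype(float),
        "sex": (samples.loc[kept, "sex"] == "M").astype(float),
    })
    resid = residualize(lc, cov)
    scores, _loadings, scales = rpca_grid(resid.to_numpy().T, k=k)
    flags = detect_outliers(scores, scales, quantile=quantile)
    report.scores = pd.DataFrame(scores, index=kept,
                                 columns=[f"rPC{i + 1}" for i in range(k)])
    report.robust_scales = scales
    safe = np.where(scales > 0, scales, np.inf)
    report.distances = pd.Series(
        np.sqrt(((scores / safe[None, :]) ** 2).sum(axis=1)), index=kept)
    report.outlier_flags = pd.Series(flags, index=kept)
    for s in report.outlier_flags.index[report.outlier_flags]:
        report.excluded[s] = "rpca: robust distance above chi-squared 97.5% cutoff"
    return report
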