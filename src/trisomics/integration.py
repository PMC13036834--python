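"""Integrative methylation-expression (eQTM) analysis.

Significant DMRs are paired with nearby differentially expressed genes
(within a +/- 2000 bp cis window of the gene span); for each pair, the
DMR's per-sample median methylation is correlated (Pearson) with the gene's
log2 normalized expression. Confidence intervals come from a paired
percentile bootstrap; p-values from a permutation null that shuffles the
expression vector against the methylation vector. Associations with
permutation p < 0.05 are called significant; their sign records whether
higher methylation tracks higher (+) or lower (-) expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genomic import annotate_region_to_genes

__all__ = [
    "pair_dmrs_to_degs", "dmr_median_methylation", "eqtm_test",
    "run_integration", "EqtmAnalysis", "EqtmResults",
]


def pair_dmrs_to_degs(dmrs: pd.DataFrame, degs: pd.DataFrame,
                      gene_annotation: pd.DataFrame,
                      window: int = 2000) -> pd.DataFrame:
    """All (DMR, gene) pairs where the DMR lies within the gene's cis window.

    ``dmrs`` is a significant-DMR table with region_id/chrom/start/end;
    ``degs`` a significant DE table indexed by gene id. One gene may pair
    with several DMRs. The annotation category (promoter / gene_body /
    flanking) is reported per pair.
    """
    rows = []
    deg_ids = set(degs.index)
    for _, dmr in dmrs.iterrows():
        hits = annotate_region_to_genes(
            (dmr["chrom"], int(dmr["start"]), int(dmr["end"])),
            gene_annotation, window=window)
        for gid, cat in hits:
            if gid in deg_ids:
                rows.append({"dmr_id": dmr["region_id"], "gene_id": gid,
                             "category": cat})
    return pd.DataFrame(rows, columns=["dmr_id", "gene_id", "category"])


def dmr_median_methylation(betas: pd.DataFrame, probe_ids) -> pd.Series:
    """Per-sample median beta over a DMR's member probes."""
    missing = [p for p in probe_ids if p not in betas.index]
    if missing:
        raise ValueError(f"probes missing from beta matrix: {missing[:5]}")
    return betas.loc[list(probe_ids)].median(axis=0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else np.nan


def eqtm_test(median_beta: np.ndarray, expression: np.ndarray,
              n_boot: int = 100_000, n_perm: int = 10_000,
              seed: int | np.random.Generator = 0) -> dict:
    """Pearson correlation with bootstrap CI and permutation p.

    ``expression`` should already be log2(normalized count + 1). The CI is
    the 2.5/97.5 percentile of r over ``n_boot`` paired resamples (degenerate
    zero-variance resamples are redrawn); the two-sided p compares |r| with
    ``n_perm`` permutations of the expression vector,
    p = (1 + #{|r_perm| >= |r|}) / (n_perm + 1), so the smallest attainable
    p is 1/(n_perm + 1).
    """
    x = np.asarray(median_beta, dtype=float)
    y = np.asarray(expression, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 paired samples")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    r = _pearson(x, y)
    if not np.isfinite(r):
        return {"r": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "significant": False, "direction": 0,
                "note": "zero variance"}

    # bootstrap CI (vectorised in chunks; redraw degenerate resamples)
    boot = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        m = min(n_boot - filled, 20_000)
        idx = rng.integers(0, n, size=(m, n))
        bx = x[idx]
        by = y[idx]
        bxc = bx - bx.mean(axis=1, keepdims=True)
        byc = by - by.mean(axis=1, keepdims=True)
        denom = np.sqrt((bxc ** 2).sum(axis=1) * (byc ** 2).sum(axis=1))
        ok = denom > 0
        k = int(ok.sum())
        boot[filled:filled + k] = (bxc * byc).sum(axis=1)[ok] / denom[ok]
        filled += k
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    # permutation null: shuffle expression against methylation
    xc = x - x.mean()
    sx = np.sqrt((xc ** 2).sum())
    count = 0
    abs_r = abs(r)
    for start in range(0, n_perm, 20_000):
        m = min(n_perm - start, 20_000)
        perm = y[np.argsort(rng.random((m, n)), axis=1)]
        pc = perm - perm.mean(axis=1, keepdims=True)
        denom = sx * np.sqrt((pc ** 2).sum(axis=1))
        r_perm = (pc @ xc) / denom
        count += int((np.abs(r_perm) >= abs_r - 1e-15).sum())
    p = (1.0 + count) / (n_perm + 1.0)
    return {"r": r, "ci_low": float(ci_low), "ci_high": float(ci_high),
            "p": float(p), "significant": p < 0.05,
            "direction": int(np.sign(r))}


def run_integration(dmrs: pd.DataFrame, degs: pd.DataFrame,
                    betas: pd.DataFrame, counts: pd.DataFrame,
                    sf: pd.Series, gene_annotation: pd.DataFrame,
                    window: int = 2000, n_boot: int = 100_000,
                    n_perm: int = 10_000,
                    seed: int | np.random.Generator = 0,
                    scope: str = "deg-pairs") -> pd.DataFrame:
    """Pair DMRs with genes and test every pair.

    ``scope='deg-pairs'`` pairs significant DMRs with significant DEGs (the
    cis DMR-DEG analysis); ``scope='all-dmr-genes'`` pairs significant DMRs
    with every annotated gene in the cis window regardless of DE status.
    Output is sorted by p, with a BH-adjusted column as a convenience beyond
    the raw p < 0.05 call.
    """
    if scope == "deg-pairs":
        universe = degs
    elif scope == "all-dmr-genes":
        universe = pd.DataFrame(index=gene_annotation.index)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    pairs = pair_dmrs_to_degs(dmrs, universe, gene_annotation, window=window)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    common = [s for s in betas.columns if s in counts.columns]
    logexpr = np.log2(counts[common].divide(sf.loc[common], axis=1) + 1.0)
    dmr_by_id = dmrs.set_index("region_id")
    rows = []
    for _, pair in pairs.iterrows():
        probes = dmr_by_id.loc[pair["dmr_id"], "probe_ids"].split(";")
        med = dmr_median_methylation(betas[common], probes)
        res = eqtm_test(med.to_numpy(), logexpr.loc[pair["gene_id"]].to_numpy(),
                        n_boot=n_boot, n_perm=n_perm, seed=rng)
        rows.append({"dmr_id": pair["dmr_id"], "gene_id": pair["gene_id"],
                     "category": pair["category"], "n_cpgs": len(probes),
                     **{k: v for k, v in res.items() if k != "note"}})
    out = pd.DataFrame(rows, columns=["dmr_id", "gene_id", "category", "n_cpgs",
                                      "r", "ci_low", "ci_high", "p",
                                      "significant", "direction"])
    if len(out):
        tested = out["p"].notna()
        out["fdr"] = np.nan
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"],
                                               method="fdr_bh")[1]
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def distinct_cpg_count(associations: pd.DataFrame, dmrs: pd.DataFrame) -> int:
    """Total distinct CpGs across the significant associations (set semantics:
    a DMR shared by two associations contributes its CpGs once)."""
    dmr_by_id = dmrs.set_index("region_id")
    probes: set[str] = set()
    for dmr_id in associations.loc[associations["significant"], "dmr_id"].unique():
        probes.update(dmr_by_id.loc[dmr_id, "probe_ids"].split(";"))
    return len(probes)


class EqtmAnalysis:
    """eQTM model over upstream DMR and DE results."""

    def __init__(self, dmr_results, de_results, betas: pd.DataFrame,
                 counts: pd.DataFrame, sf: pd.Series,
                 gene_annotation: pd.DataFrame, window: int = 2000,
                 scope: str = "deg-pairs"):
        self.dmrs = (dmr_results.significant if hasattr(dmr_results, "significant")
                     else dmr_results)
        self.degs = (de_results.significant if hasattr(de_results, "significant")
                     else de_results)
        self.betas = betas
        self.counts = counts
        self.sf = sf
        self.gene_annotation = gene_annotation
        self.window = window
        self.scope = scope

    def fit(self, n_boot: int = 100_000, n_perm: int = 10_000,
            seed: int | np.random.Generator = 0) -> "EqtmResults":
        table = run_integration(self.dmrs, self.degs, self.betas, self.counts,
                                self.sf, self.gene_annotation,
                                window=self.window, n_boot=n_boot,
                                n_perm=n_perm, seed=seed, scope=self.scope)
        return EqtmResults(table, self)


@dataclass
class EqtmResults:
    table: pd.DataFrame
    model: "EqtmAnalysis | None" = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]

    def summary(self) -> str:
        sig = self.significant
        neg = int((sig["direction"] < 0).sum())
        pos = int((sig["direction"] > 0).sum())
        n_cpg = (distinct_cpg_count(self.table, self.model.dmrs)
                 if self.model is not None else 0)
        return ("Integrative methylation-expression (eQTM) analysis\n"
                f"  candidate DMR-gene pairs: {len(self.table)}\n"
                f"  significant associations (p < 0.05): {len(sig)} "
                f"({neg} negative, {pos} positive), "
                f"encompassing {n_cpg} distinct CpGs")
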