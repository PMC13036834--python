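"""Preranked gene-set enrichment analysis (GSEA) with NES, plus
overrepresentation, parent-set collapsing and Jaccard clustering.

Genes are ranked by their differential-expression Wald z statistic
(descending: most upregulated first). The enrichment score of a set is the
signed extremum of the classic weighted Kolmogorov-Smirnov running sum
(weight exponent p = 1); nulls come from random gene sets of the same size
drawn from the ranked universe (gene-label permutation, appropriate for the
preranked setting with a small cohort), the NES divides the ES by the mean
absolute null ES of matching sign, and p-values use the sign-matched null
tail. Significant sets (BH FDR < 0.01) can be collapsed (greedy, by overlap)
and clustered into connected components of the Jaccard >= 0.25 graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rank_genes", "enrichment_score", "gsea", "overrepresentation",
    "collapse_sets", "cluster_sets", "jaccard", "PrerankedGSEA", "GseaResults",
]


def rank_genes(de: pd.DataFrame, metric: str = "wald_z") -> pd.Series:
    """Ranked gene list: scores sorted descending, ties broken by gene id.

    ``metric`` may be any numeric DE column (default the Wald z; switchable
    to ``shrunken_log2fc``).
    """
    s = de[metric].dropna()
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def enrichment_score(ranked: pd.Series, gene_set,
                     p: float = 1.0) -> tuple[float, list[str]]:
    """Weighted KS running-sum enrichment score and leading edge.

    Walking the ranking, set members increment the sum by |score|^p
    normalised over member scores; non-members decrement by 1/(N - N_hits).
    The ES is the extremum of larger magnitude; the leading edge contains
    the members at or before the extremum (positive ES) or after it
    (negative ES).
    """
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    n_hits = int(hit.sum())
    N = len(genes)
    if n_hits == 0:
        raise ValueError("gene set has no members in the ranked universe")
    if n_hits == N:
        return 0.0, list(genes)
    w = np.abs(scores) ** p
    w_hit = np.where(hit, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:  # all member scores zero: fall back to equal weights
        w_hit = hit.astype(float)
        denom = w_hit.sum()
    inc = w_hit / denom
    dec = (~hit).astype(float) / (N - n_hits)
    running = np.cumsum(inc - dec)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = [g for g, h in zip(genes[:i_max + 1], hit[:i_max + 1]) if h]
    else:
        es = float(running[i_min])
        leading = [g for g, h in zip(genes[i_min + 1:], hit[i_min + 1:]) if h]
    return es, leading


def _es_many(scores: np.ndarray, hit_matrix: np.ndarray, p: float = 1.0) -> np.ndarray:
    """Enrichment scores for many boolean hit vectors at once (null sets)."""
    w = np.abs(scores) ** p
    wh = hit_matrix * w[None, :]
    denom = wh.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    n_hits = hit_matrix.sum(axis=1, keepdims=True)
    miss = (1.0 - hit_matrix) / (len(scores) - n_hits)
    running = np.cumsum(wh / denom - miss, axis=1)
    mx = running.max(axis=1)
    mn = running.min(axis=1)
    return np.where(mx >= -mn, mx, mn)


def gsea(ranked: pd.Series, collection: dict[str, set[str]],
         n_perm: int = 1000, min_size: int = 15, max_size: int = 500,
         seed: int | np.random.Generator = 0,
         weight: float = 1.0) -> pd.DataFrame:
    """Preranked GSEA over a collection.

    Null per set size s: ES of ``n_perm`` random s-subsets of the universe.
    NES = ES / mean(|null ES| of matching sign);
    p = (1 + #{sign-matched null ES at least as extreme}) / (#sign-matched + 1).
    Sets outside [min_size, max_size] members-in-universe are skipped.
    """
    if n_perm < 100:
        import warnings
        warnings.warn("n_perm < 100 gives unstable GSEA p-values")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    universe = set(ranked.index)
    N = len(ranked)
    scores = ranked.to_numpy(dtype=float)

    sizes_needed: dict[int, list[str]] = {}
    observed: dict[str, tuple[float, list[str], int]] = {}
    for name, members in collection.items():
        present = members & universe
        s = len(present)
        if s < min_size or s > max_size:
            continue
        es, leading = enrichment_score(ranked, present, p=weight)
        observed[name] = (es, leading, s)
        sizes_needed.setdefault(s, []).append(name)
    if not observed:
        return pd.DataFrame(columns=["set", "size", "es", "nes", "p", "fdr",
                                     "leading_edge"]).set_index("set")

    rows = []
    for s, names in sizes_needed.items():
        hit = np.zeros((n_perm, N), dtype=float)
        for i in range(n_perm):
            hit[i, rng.choice(N, size=s, replace=False)] = 1.0
        null = _es_many(scores, hit)
        pos = null[null > 0]
        neg = null[null < 0]
        mean_pos = pos.mean() if len(pos) else np.nan
        mean_neg = np.abs(neg).mean() if len(neg) else np.nan
        for name in names:
            es, leading, size = observed[name]
            if es >= 0:
                nes = es / mean_pos if np.isfinite(mean_pos) else np.nan
                pval = (1.0 + int((pos >= es - 1e-15).sum())) / (len(pos) + 1.0)
            else:
                nes = -abs(es) / mean_neg if np.isfinite(mean_neg) else np.nan
                pval = (1.0 + int((neg <= es + 1e-15).sum())) / (len(neg) + 1.0)
            rows.append({"set": name, "size": size, "es": es, "nes": nes,
                         "p": pval, "leading_edge": ";".join(leading)})
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out[["size", "es", "nes", "p", "fdr", "leading_edge"]]


def overrepresentation(hits: set[str], universe: set[str],
                       collection: dict[str, set[str]]) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a hit list in each set."""
    N = len(universe)
    K = len(hits & universe)
    rows = []
    for name, members in collection.items():
        m = len(members & universe)
        if m == 0:
            continue
        k = len(members & hits & universe)
        pval = float(stats.hypergeom.sf(k - 1, N, m, K))
        rows.append({"set": name, "set_size": m, "overlap": k, "p": pval})
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def collapse_sets(results: pd.DataFrame, collection: dict[str, set[str]],
                  threshold: float = 0.5) -> pd.DataFrame:
    """Greedy collapse of overlapping significant sets.

    Walk sets by ascending p; keep a set iff its Jaccard with every
    already-kept set is below ``threshold``. Returns the input restricted to
    kept sets with a ``collapsed`` column listing the sets each keeper
    absorbed.
    """
    order = results.sort_values(["p", "fdr"], kind="mergesort").index
    kept: list[str] = []
    absorbed: dict[str, list[str]] = {}
    for name in order:
        owner = next((k for k in kept
                      if jaccard(collection[name], collection[k]) >= threshold),
                     None)
        if owner is None:
            kept.append(name)
            absorbed[name] = []
        else:
            absorbed[owner].append(name)
    out = results.loc[kept].copy()
    out["collapsed"] = [";".join(absorbed[k]) for k in kept]
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_sets(results: pd.DataFrame, collection: dict[str, set[str]],
                 threshold: float = 0.25) -> pd.DataFrame:
    """Connected components of the Jaccard >= threshold graph over sets.

    Returns a table with a ``cluster`` id per set and a ``representative``
    flag marking the lowest-p member of each cluster.
    """
    names = list(results.index)
    uf = _UnionFind(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if jaccard(collection[a], collection[b]) >= threshold:
                uf.union(a, b)
    roots: dict[str, int] = {}
    cluster_id = []
    for name in names:
        r = uf.find(name)
        if r not in roots:
            roots[r] = len(roots) + 1
        cluster_id.append(roots[r])
    out = results.copy()
    out["cluster"] = cluster_id
    rep = out.groupby("cluster")["p"].idxmin()
    out["representative"] = out.index.isin(rep.to_numpy())
    return out


class PrerankedGSEA:
    """Preranked GSEA model over a DE result and a GMT collection."""

    def __init__(self, de_results, collection: dict[str, set[str]],
                 metric: str = "wald_z", min_size: int = 15,
                 max_size: int = 500):
        table = de_results.table if hasattr(de_results, "table") else de_results
        self.ranked = rank_genes(table, metric=metric)
        self.collection = collection
        self.min_size = min_size
        self.max_size = max_size

    def fit(self, n_perm: int = 1000, seed: int | np.random.Generator = 0,
            fdr_cutoff: float = 0.01) -> "GseaResults":
        table = gsea(self.ranked, self.collection, n_perm=n_perm,
                     min_size=self.min_size, max_size=self.max_size, seed=seed)
        return GseaResults(table, self, fdr_cutoff=fdr_cutoff)


@dataclass
class GseaResults:
    table: pd.DataFrame
    model: "PrerankedGSEA | None" = None
    fdr_cutoff: float = 0.01

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["fdr"] < self.fdr_cutoff]

    def collapse(self, threshold: float = 0.5) -> pd.DataFrame:
        return collapse_sets(self.significant, self.model.collection, threshold)

    def clusters(self, threshold: float = 0.25) -> pd.DataFrame:
        return cluster_sets(self.significant, self.model.collection, threshold)

    def summary(self) -> str:
        sig = self.significant
        return ("Preranked gene-set enrichment analysis\n"
                f"  sets tested: {len(self.table)}\n"
                f"  significant at FDR < {self.fdr_cutoff:g}: {len(sig)} "
                f"({int((sig['nes'] > 0).sum())} positive NES, "
                f"{int((sig['nes'] < 0).sum())} negative NES)")
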