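"""Table IO, genomic-interval arithmetic and gene-relative region annotation.

Internal coordinates are 1-based inclusive throughout (the convention of the
annotation tables and of printed DMR coordinates such as chr5:2753876-2754148);
BED export converts to 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix", "write_matrix", "read_gmt", "read_table",
    "annotate_region_to_genes", "write_regions_bed", "read_regions_bed",
    "MatrixFormatError", "GmtFormatError",
]


class MatrixFormatError(ValueError):
    """A matrix TSV violates its kind's cell constraints."""


class GmtFormatError(ValueError):
    """A GMT gene-set file is malformed."""


def read_matrix(path: str | Path, kind: str = "counts") -> pd.DataFrame:
    """Read a feature x sample TSV matrix.

    ``kind='counts'`` requires non-negative integer cells; ``kind='beta'``
    requires values in [0, 1]. The first column holds feature ids, the header
    row sample ids. Row/column order of the file is preserved.
    """
    if kind not in ("counts", "beta"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate feature ids: {dups[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise MatrixFormatError(
            f"non-finite cell at feature {df.index[i]!r}, sample {df.columns[j]!r}")
    if kind == "counts":
        if (values < 0).any() or not np.allclose(values, np.round(values)):
            i, j = np.argwhere((values < 0) | (values != np.round(values)))[0]
            raise MatrixFormatError(
                f"count matrix requires non-negative integers; offending cell at "
                f"feature {df.index[i]!r}, sample {df.columns[j]!r}")
        return df.astype(np.int64)
    bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MatrixFormatError(
            f"beta value {values[i, j]} outside [0, 1] at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r}")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    """Read an annotation/sample TSV table."""
    df = pd.read_csv(path, sep="\t")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: ``name<TAB>description<TAB>gene...``.

    Member genes are de-duplicated within a set; duplicate set names are an
    error; empty sets are an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(f"{path}:{ln}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise GmtFormatError(f"{path}:{ln}: duplicate set name {name!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise GmtFormatError(f"{path}:{ln}: set {name!r} has no members")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na"] + sorted(members)) + "\n")


def _overlaps(a_start: int, a_end: int, b_start, b_end) -> np.ndarray:
    return (a_start <= np.asarray(b_end)) & (np.asarray(b_start) <= a_end)


def annotate_region_to_genes(region: tuple[str, int, int],
                             genes: pd.DataFrame,
                             window: int = 2000) -> list[tuple[str, str]]:
    """Pair a region with every gene within ``window`` bp and categorise it.

    ``region`` is (chrom, start, end), 1-based inclusive. A gene pairs if its
    span extended by ``window`` on both sides overlaps the region by >= 1 bp.
    Category is ``"promoter"`` if the region overlaps the strand-aware
    [TSS - window, TSS] interval, else ``"gene_body"`` if it overlaps the gene
    span, else ``"flanking"``. A region overlapping both promoter and body is
    called promoter (the more specific regulatory claim). Unknown chromosome
    yields an empty list.
    """
    chrom, start, end = region
    if start > end:
        raise ValueError(f"region start {start} > end {end}")
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return []
    gs = sub["start"].to_numpy()
    ge = sub["end"].to_numpy()
    hit = _overlaps(start, end, gs - window, ge + window)
    out: list[tuple[str, str]] = []
    for gid, g_start, g_end, strand in zip(sub.index[hit], gs[hit], ge[hit],
                                           sub["strand"].to_numpy()[hit]):
        if strand == "+":
            prom_lo, prom_hi = g_start - window, g_start
        else:
            prom_lo, prom_hi = g_end, g_end + window
        if start <= prom_hi and prom_lo <= end:
            cat = "promoter"
        elif start <= g_end and g_start <= end:
            cat = "gene_body"
        else:
            cat = "flanking"
        out.append((gid, cat))
    return out


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write regions as BED (0-based half-open).

    Expects columns ``chrom``, ``start``, ``end`` (1-based inclusive) and
    optionally ``region_id`` (name column) and ``fdr`` (score column,
    -log10(FDR) capped at 1000).
    """
    with open(path, "w") as fh:
        for _, row in regions.iterrows():
            name = str(row["region_id"]) if "region_id" in row.index else "."
            if "fdr" in row.index and pd.notna(row["fdr"]):
                fdr = float(row["fdr"])
                score = 1000.0 if fdr <= 0 else min(-np.log10(fdr), 1000.0)
            else:
                score = 0.0
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}"
                     f"\t{name}\t{score:g}\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file back to the internal 1-based inclusive convention."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append({"chrom": f[0], "start": int(f[1]) + 1, "end": int(f[2]),
                         "region_id": f[3] if len(f) > 3 else ".",
                         "score": float(f[4]) if len(f) > 4 else 0.0})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id", "score"])
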