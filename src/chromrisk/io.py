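"""Readers and writers for the pipeline's plain-text dialects.

Fragments files follow the 10x-style dialect: tab-separated chrom, start,
end, barcode, count with 0-based half-open coordinates and no header.
Summit/peak files are BED (3 columns, optionally a name/score).  Tables
(credible sets, GWAS summary statistics, allele counts, scores) are
tab-separated with a header row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = FRAGMENT_COLUMNS[: df.shape[1]]
    return df


def write_fragments(df: pd.DataFrame, path, barcode: str = ".") -> None:
    out = df[["chrom", "start", "end"]].copy()
    out["barcode"] = df["barcode"] if "barcode" in df.columns else barcode
    out["count"] = df["count"] if "count" in df.columns else 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, cols=("chrom", "start", "end")) -> None:
    df[list(cols)].to_csv(path, sep="\t", header=False, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_summits(path) -> pd.DataFrame:
    """Summit BED: single-bp features; returns chrom/pos (0-based)."""
    bed = read_bed(path)
    return pd.DataFrame({"chrom": bed["chrom"], "pos": bed["start"]})


def write_summits(summits: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": summits["chrom"],
            "start": summits["pos"],
            "end": summits["pos"] + 1,
        }
    )
    write_bed(out, path)
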