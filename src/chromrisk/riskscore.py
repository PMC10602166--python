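"""PPA-weighted chromatin-accessibility scores attributing GWAS loci to cell types.

For each fine-mapped locus, every credible-set variant is extended ±50 bp;
base-overlapping extensions merge into one region carrying the highest member
PPA.  Each region's pseudo-bulk fragment count per cell type is depth-
normalized to reads-per-million, weighted by the region PPA, and summed over
the locus to give one raw score per cell type.  Loci with no variant inside
any cell type's reproducible broad peak are dropped, and raw scores are
Z-transformed per locus across cell types, so the top-Z cell type is the
candidate effector cell type for that locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import count_overlaps, overlaps_any

__all__ = [
    "CellTypeSignal",
    "LocusScoreMatrix",
    "extend_and_merge",
    "score_regions",
    "filter_loci",
    "zscore_rows",
    "attribute_loci",
    "score_loci",
]


@dataclass
class CellTypeSignal:
    """A cell type's pseudo-bulk fragment set plus its sequencing depth.

    `total_depth` defaults to the number of fragments; an external depth may
    be supplied instead, e.g. the pre-subsampling depth for subsampled
    inputs.
    """

    celltype: str
    fragments: pd.DataFrame  # chrom/start/end
    total_depth: int | None = None

    def __post_init__(self) -> None:
        if self.total_depth is None:
            self.total_depth = len(self.fragments)
        if self.total_depth <= 0 and len(self.fragments):
            raise ValueError("total_depth must be positive")


@dataclass
class LocusScoreMatrix:
    raw: pd.DataFrame  # loci x cell types, PPA-weighted RPM
    zscore: pd.DataFrame  # per-locus Z across cell types
    kept: pd.Series  # per-locus broad-peak filter flag
    degenerate: pd.Series  # rows with zero variance (z set to 0)


def extend_and_merge(variants: pd.DataFrame, flank: int = 50) -> pd.DataFrame:
    """Extend each variant of one locus by `flank` bp and merge overlaps.

    `variants` has chrom, pos (1-based), ppa.  A variant at 1-based p becomes
    the 0-based interval [p-1-flank, p+flank); base-overlapping extensions
    merge into their union span with the maximum member PPA (touching
    intervals stay separate).  Returns chrom/start/end/ppa regions.
    """
    ppa = variants["ppa"].to_numpy(dtype=float)
    if (ppa < 0).any() or (ppa > 1).any():
        raise ValueError("PPA outside [0, 1]")
    df = pd.DataFrame(
        {
            "chrom": variants["chrom"].to_numpy(),
            "start": np.maximum(variants["pos"].to_numpy() - 1 - flank, 0),
            "end": variants["pos"].to_numpy() + flank,
            "ppa": ppa,
        }
    ).sort_values(["chrom", "start", "end"])
    regions = []
    for chrom, g in df.groupby("chrom", sort=True):
        cur = None
        for s, e, p in zip(g["start"], g["end"], g["ppa"]):
            if cur is not None and s < cur[1]:
                cur[1] = max(cur[1], e)
                cur[2] = max(cur[2], p)
            else:
                if cur is not None:
                    regions.append((chrom, *cur))
                cur = [s, e, p]
        regions.append((chrom, *cur))
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "ppa"])


def score_regions(regions: pd.DataFrame, signal: CellTypeSignal) -> float:
    """Raw locus score for one cell type.

    score = sum over regions of (overlap count * 1e6 / depth) * region PPA.
    """
    if signal.total_depth <= 0:
        raise ValueError("cell-type signal has zero sequencing depth")
    counts = count_overlaps(regions, signal.fragments)
    rpm = counts * 1e6 / signal.total_depth
    return float(np.sum(rpm * regions["ppa"].to_numpy()))


def filter_loci(
    credible_sets: pd.DataFrame, broad_peaks: dict[str, pd.DataFrame]
) -> pd.Series:
    """Keep loci with >= 1 variant inside any cell type's broad peak.

    Variant positions are 1-based; the test point is the 1-bp interval
    [pos-1, pos).
    """
    points = pd.DataFrame(
        {
            "chrom": credible_sets["chrom"],
            "start": credible_sets["pos"] - 1,
            "end": credible_sets["pos"],
        }
    )
    in_any = np.zeros(len(points), dtype=bool)
    for bp in broad_peaks.values():
        in_any |= overlaps_any(points, bp)
    kept = pd.Series(in_any).groupby(credible_sets["locus_id"].to_numpy()).any()
    kept.name = "kept"
    return kept


def zscore_rows(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-locus Z across cell types (sample SD, ddof=1).

    Degenerate rows (zero SD) become all-zero and are flagged.
    """
    if raw.shape[1] < 2:
        raise ValueError("Z-scoring needs >= 2 cell types")
    mean = raw.mean(axis=1)
    sd = raw.std(axis=1, ddof=1)
    degenerate = sd == 0
    z = raw.sub(mean, axis=0).div(sd.where(~degenerate, 1.0), axis=0)
    z.loc[degenerate] = 0.0
    degenerate.name = "degenerate"
    return z, degenerate


def attribute_loci(zscore: pd.DataFrame, margin: float = 1.0) -> pd.DataFrame:
    """Rank cell types per locus; label the top one "specific" when it leads
    the runner-up by >= `margin` Z units."""
    rows = []
    for locus, row in zscore.iterrows():
        order = row.sort_values(ascending=False)
        specific = len(order) >= 2 and (order.iloc[0] - order.iloc[1]) >= margin
        rows.append(
            {
                "locus_id": locus,
                "top_celltype": order.index[0],
                "top_z": order.iloc[0],
                "second_z": order.iloc[1] if len(order) >= 2 else np.nan,
                "specific": specific,
                "ranking": ",".join(order.index),
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")


def score_loci(
    credible_sets: pd.DataFrame,
    signals: dict[str, CellTypeSignal],
    broad_peaks: dict[str, pd.DataFrame] | None = None,
    flank: int = 50,
) -> LocusScoreMatrix:
    """Full locus x cell-type scoring pipeline.

    `credible_sets` has locus_id, variant_id, chrom, pos (1-based), ppa.
    When `broad_peaks` is None every locus is kept.
    """
    loci = credible_sets["locus_id"].unique()
    celltypes = list(signals)
    raw = pd.DataFrame(0.0, index=pd.Index(loci, name="locus_id"), columns=celltypes)
    for locus, group in credible_sets.groupby("locus_id", sort=False):
        regions = extend_and_merge(group, flank=flank)
        for ct in celltypes:
            raw.loc[locus, ct] = score_regions(regions, signals[ct])
    if broad_peaks is not None:
        kept = filter_loci(credible_sets, broad_peaks).reindex(raw.index)
    else:
        kept = pd.Series(True, index=raw.index, name="kept")
    z, degenerate = zscore_rows(raw)
    return LocusScoreMatrix(raw=raw, zscore=z, kept=kept, degenerate=degenerate)
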