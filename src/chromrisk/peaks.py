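"""Extended-summit peak construction and cross-library reproducibility.

Peaks are built by extending single-bp summit calls by a fixed flank on each
side, then keeping only the "primary" (all-libraries) extended summits that
are supported by extended summits from at least ``min_libraries`` distinct
libraries and that avoid a mappability blacklist.  The merged union of a cell
type's reproducible extended summits serves as its broad-peak set downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import count_overlaps, merge_intervals, overlaps_any

__all__ = [
    "ReproduciblePeakSet",
    "extend_summits",
    "reproducible_peaks",
    "broad_peaks",
    "count_overlaps",
]


@dataclass
class ReproduciblePeakSet:
    celltype: str
    intervals: pd.DataFrame  # chrom/start/end, sorted
    min_libraries: int
    provenance: list[str] = field(default_factory=list)


def extend_summits(
    summits: pd.DataFrame, flank: int = 150, chrom_sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Extend single-bp summit positions by `flank` bp in both directions.

    `summits` has chrom/pos columns (0-based summit coordinate).  A summit at
    s becomes [s-flank, s+flank+1), clipped at the chromosome start.  Summits
    beyond the chromosome end (when sizes are given) are rejected.
    """
    if len(summits) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    pos = summits["pos"].to_numpy()
    chrom = summits["chrom"].to_numpy()
    if chrom_sizes is not None:
        sizes = np.array([chrom_sizes.get(c, np.inf) for c in chrom])
        if (pos >= sizes).any():
            bad = summits[pos >= sizes].iloc[0]
            raise ValueError(
                f"summit at {bad['chrom']}:{bad['pos']} beyond chromosome end"
            )
    start = np.maximum(pos - flank, 0)
    end = pos + flank + 1
    return pd.DataFrame({"chrom": chrom, "start": start, "end": end})


def reproducible_peaks(
    primary: pd.DataFrame,
    per_library: dict[str, pd.DataFrame],
    blacklist: pd.DataFrame | None = None,
    min_libraries: int = 2,
    celltype: str = "",
) -> ReproduciblePeakSet:
    """Keep primary intervals supported by >= `min_libraries` distinct libraries.

    Support means >= 1 bp overlap with that library's extended summits
    (duplicates within a library collapse to one, and multiple summits from
    the same library still count once).  Any overlap with a blacklist
    interval drops the peak.
    """
    primary = primary.reset_index(drop=True)
    n_support = np.zeros(len(primary), dtype=int)
    for lib, ivs in per_library.items():
        dedup = ivs.drop_duplicates(subset=["chrom", "start", "end"])
        n_support += overlaps_any(primary, dedup).astype(int)
    keep = n_support >= min_libraries
    if blacklist is not None and len(blacklist):
        keep &= ~overlaps_any(primary, blacklist)
    kept = (
        primary.loc[keep]
        .sort_values(["chrom", "start", "end"])
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return ReproduciblePeakSet(
        celltype=celltype,
        intervals=kept,
        min_libraries=min_libraries,
        provenance=sorted(per_library),
    )


def broad_peaks(peakset: ReproduciblePeakSet) -> pd.DataFrame:
    """Merged union of a cell type's reproducible extended summits."""
    return merge_intervals(peakset.intervals)
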