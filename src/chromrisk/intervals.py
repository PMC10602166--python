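"""Genomic interval primitives and the shared overlap-counting engine.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Two intervals overlap iff they share at least one base, so intervals that
merely touch (``a.end == b.start``) do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "intervals_to_frame",
    "frame_to_intervals",
    "count_overlaps",
    "merge_intervals",
    "overlaps_any",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]


def _as_frame(x) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x
    return intervals_to_frame(x)


def count_overlaps(intervals, fragments) -> np.ndarray:
    """Count fragments overlapping each query interval.

    A fragment counts toward an interval iff they share >= 1 bp on the same
    chromosome; one fragment may count toward several intervals.  Both
    arguments are DataFrames with chrom/start/end columns (or sequences of
    :class:`GenomicInterval`).

    Per chromosome, a fragment [s, e) overlaps [S, E) iff ``s < E and e > S``.
    The complement splits into the disjoint "entirely left" (e <= S) and
    "entirely right" (s >= E) sets, so two sorted searches per query give the
    count without enumerating pairs.
    """
    q = _as_frame(intervals)
    f = _as_frame(fragments)
    out = np.zeros(len(q), dtype=np.int64)
    if len(q) == 0 or len(f) == 0:
        return out
    for chrom, fg in f.groupby("chrom", sort=False):
        mask = (q["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = np.sort(fg["start"].to_numpy())
        ends = np.sort(fg["end"].to_numpy())
        n = len(fg)
        qs = q.loc[mask, "start"].to_numpy()
        qe = q.loc[mask, "end"].to_numpy()
        left = np.searchsorted(ends, qs, side="right")  # fragments with end <= S
        right = n - np.searchsorted(starts, qe, side="left")  # start >= E
        out[mask] = n - left - right
    return out


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of base-overlapping intervals per chromosome (touching kept apart)."""
    df = _as_frame(df)
    if len(df) == 0:
        return df.copy()
    pieces = []
    for chrom, g in df.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:  # strict: touching does not merge
                cur_e = max(cur_e, e)
            else:
                pieces.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        pieces.append((chrom, cur_s, cur_e))
    return pd.DataFrame(pieces, columns=["chrom", "start", "end"])


def overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: does it overlap any target interval?"""
    return count_overlaps(query, targets) > 0
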