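"""Barcode-level quality control for snATAC-seq and scRNA-seq nuclei.

ATAC barcodes pass on read depth (high-quality autosomal alignments, HQAA),
signal-to-noise (TSS enrichment) and nuclear integrity (fraction of reads on
the single most-covered autosome).  RNA barcodes pass on UMI depth and a
per-library mitochondrial-fraction threshold found as the knee of the ranked
%-mito curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeMetrics",
    "filter_atac_barcodes",
    "filter_rna_barcodes",
    "mito_knee",
]


@dataclass
class BarcodeMetrics:
    barcode: str
    hqaa: int = 0
    tss_enrichment: float = 0.0
    max_autosome_fraction: float = 0.0
    n_umis: int = 0
    pct_mito: float = 0.0


def _metrics_frame(metrics) -> pd.DataFrame:
    if isinstance(metrics, pd.DataFrame):
        return metrics
    return pd.DataFrame([vars(m) for m in metrics])


def _reject_negative(df: pd.DataFrame, cols) -> pd.Series:
    """Mark records with negative metrics invalid, with a diagnostic."""
    bad = pd.Series(False, index=df.index)
    for c in cols:
        if c in df.columns:
            bad |= df[c] < 0
    if bad.any():
        warnings.warn(
            f"rejecting {int(bad.sum())} barcode record(s) with negative metrics"
        )
    return bad


def filter_atac_barcodes(
    metrics,
    hqaa_min: int = 5000,
    tss_range: tuple[float, float] = (3.0, 20.0),
    max_autosome: float = 0.15,
) -> pd.Series:
    """Pass/fail per ATAC barcode.

    Pass iff HQAA >= `hqaa_min`, TSS enrichment within `tss_range`
    (inclusive at both ends) and max-single-autosome fraction <=
    `max_autosome`.  Records with negative metrics are rejected outright.
    """
    df = _metrics_frame(metrics)
    bad = _reject_negative(df, ["hqaa", "tss_enrichment", "max_autosome_fraction"])
    ok = (
        (df["hqaa"] >= hqaa_min)
        & (df["tss_enrichment"] >= tss_range[0])
        & (df["tss_enrichment"] <= tss_range[1])
        & (df["max_autosome_fraction"] <= max_autosome)
        & ~bad
    )
    ok.name = "pass"
    return ok


def filter_rna_barcodes(metrics, umi_min: int = 1000, mito_threshold: float = 10.0) -> pd.Series:
    """Pass iff UMIs >= `umi_min` and %mito strictly below `mito_threshold`."""
    df = _metrics_frame(metrics)
    bad = _reject_negative(df, ["n_umis", "pct_mito"])
    ok = (df["n_umis"] >= umi_min) & (df["pct_mito"] < mito_threshold) & ~bad
    ok.name = "pass"
    return ok


def mito_knee(pct_mito_values) -> float:
    """Knee of the ranked %-mitochondrial curve, used as the QC threshold.

    Values are sorted ascending into a rank curve; both axes are rescaled to
    [0, 1] (making the estimate invariant to affine changes of units) and the
    knee is the point of maximum perpendicular distance to the chord joining
    the curve's endpoints.  Returns the %-mito value at that rank.
    """
    y = np.asarray(pct_mito_values, dtype=float)
    if y.size < 10:
        raise ValueError("mito_knee needs at least 10 values")
    y = np.sort(y)
    if y[0] == y[-1]:
        warnings.warn("constant %mito distribution; knee undefined, returning the constant")
        return float(y[0])
    x = np.arange(y.size, dtype=float)
    xn = x / x[-1]
    yn = (y - y[0]) / (y[-1] - y[0])
    # distance from (xn, yn) to the chord from (0,0) to (1,1); the chord has
    # unit-normal (1,-1)/sqrt(2) so |xn-yn| is proportional to the distance
    dist = np.abs(xn - yn)
    if dist.max() < 1e-9:  # curve coincides with its chord: no interior knee
        return float(y[-1])
    knee = int(np.argmax(dist))
    return float(y[knee])
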