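"""Effect-size-based differential accessibility calling.

Instead of p-value thresholds — unstable for pseudo-bulk comparisons with few
libraries — regions are ranked by absolute log2 fold-change *within bins of
matched mean accessibility*, and the top percentiles of each bin are flagged
as differentially accessible.  Binning removes the strong mean/variance
dependence of fold-change estimates, so a region is only called against peers
of similar coverage; the unflagged members of each bin form a coverage-matched
background set.

The fold-change itself may come from any upstream model; :func:`naive_log2fc`
provides a simple shrunken estimator when none is available.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "prefilter",
    "bin_by_mean",
    "percentile_select",
    "dar_pipeline",
    "naive_log2fc",
]

DEFAULT_PERCENTILES = (80, 85, 90, 95, 99)


def prefilter(
    features: pd.DataFrame, min_mean: float = 3.0, max_abs_lfc: float = 10.0
) -> pd.DataFrame:
    """Drop low-coverage features (mean < `min_mean`) and fold-change
    artifacts (|log2fc| > `max_abs_lfc`, strict)."""
    keep = (features["mean_reads"] >= min_mean) & (
        features["log2fc"].abs() <= max_abs_lfc
    )
    return features.loc[keep].reset_index(drop=True)


def bin_by_mean(features: pd.DataFrame, n_bins: int = 50) -> pd.Series:
    """Assign each feature to one of `n_bins` equal-width bins of mean reads.

    Bins cover [min(mean), max(mean)], left-closed right-open except the last
    bin which is closed; bin indices are 1-based.
    """
    if len(features) == 0:
        raise ValueError("bin_by_mean needs at least one feature")
    m = features["mean_reads"].to_numpy(dtype=float)
    lo, hi = m.min(), m.max()
    if lo == hi:
        warnings.warn("all mean values identical; assigning a single bin")
        return pd.Series(np.ones(len(m), dtype=int), index=features.index, name="bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.searchsorted(edges, m, side="right")  # boundary values go right
    idx = np.clip(idx, 1, n_bins)  # max value lands in the closed last bin
    return pd.Series(idx, index=features.index, name="bin")


def percentile_select(
    features: pd.DataFrame,
    bins: pd.Series,
    percentiles=DEFAULT_PERCENTILES,
) -> pd.DataFrame:
    """Flag features whose |log2fc| reaches each per-bin percentile.

    Within each bin and for each percentile p the threshold is the p-th
    linear-interpolation quantile of that bin's |log2fc|; features at or
    above it carry flag column ``p{p}``.  Bins with fewer than two features
    get no flags.  Flags are nested by construction (p99 implies p95, ...).
    """
    out = features.copy()
    out["bin"] = bins
    abs_lfc = out["log2fc"].abs()
    for p in percentiles:
        out[f"p{p}"] = False
    for _, idx in out.groupby("bin").groups.items():
        vals = abs_lfc.loc[idx]
        if len(vals) < 2:
            continue
        for p in percentiles:
            thr = np.quantile(vals.to_numpy(), p / 100.0)  # linear interpolation
            out.loc[idx, f"p{p}"] = (vals >= thr).to_numpy()
    return out


def dar_pipeline(
    features: pd.DataFrame,
    min_mean: float = 3.0,
    max_abs_lfc: float = 10.0,
    n_bins: int = 50,
    percentiles=DEFAULT_PERCENTILES,
) -> pd.DataFrame:
    """prefilter -> bin (over the post-filter set) -> percentile flags."""
    kept = prefilter(features, min_mean=min_mean, max_abs_lfc=max_abs_lfc)
    bins = bin_by_mean(kept, n_bins=n_bins)
    return percentile_select(kept, bins, percentiles=percentiles)


def naive_log2fc(
    mean_a: np.ndarray, mean_b: np.ndarray, pseudocount: float = 0.5
) -> np.ndarray:
    """log2((a + c)/(b + c)) on library-size-normalized mean counts."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    return np.log2((a + pseudocount) / (b + pseudocount))
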