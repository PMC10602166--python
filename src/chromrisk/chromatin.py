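"""Bound-motif prediction and chromatin-information (f-VICE) scoring.

Most transcription factors cannot open chromatin on their own, so motif
instances that sit in highly accessible regions — and in clusters of
same-motif instances — are the likely bound ones.  Two negative binomial
distributions are fit per motif, one to the ATAC fragment count over each
instance and one to the number of co-occurring same-motif instances within
100 bp; upper-tail p-values are combined by Fisher's method and instances
with small combined p (BH-corrected) are called bound.

Bound TFs that phase nucleosomes leave a structured "V" pattern in the
distribution of ATAC fragment midpoints around their motifs.  The f-VICE
score quantifies that structure as the log2 enrichment of midpoint mass in
the TF-adjacent (+/-25 bp) and TF-proximal (+/-50-70 bp) windows relative to
a uniformly shuffled midpoint distribution.  Because raw f-VICE tracks the
number of fragments and of co-occurring motifs, scores are normalized as
residuals of f-VICE ~ log10(total fragments) + log10(total co-occurring
motifs) before cross-condition comparison via per-condition Z-scores and
per-motif medians across donors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .intervals import count_overlaps

__all__ = [
    "VPlot",
    "count_motif_features",
    "fit_negative_binomial",
    "predict_bound",
    "deduplicate_sites",
    "build_vplot",
    "fvice",
    "normalize_fvice",
    "condition_zscores",
    "ADJACENT_WINDOW",
    "PROXIMAL_WINDOWS",
]

# strand-oriented offset windows (bp from motif center, inclusive)
ADJACENT_WINDOW = (-25, 25)
PROXIMAL_WINDOWS = ((-70, -50), (50, 70))


def count_motif_features(motifs: pd.DataFrame, fragments: pd.DataFrame) -> pd.DataFrame:
    """Per-instance ATAC fragment count and same-motif co-occurrence count.

    `motifs` has motif_id/chrom/start/end (and optionally strand).  The
    co-occurrence count is the number of *other* instances of the same motif
    whose interval comes within <= 100 bp edge-to-edge (overlap counts as
    distance 0; the 100 bp boundary is inclusive).
    """
    out = motifs.reset_index(drop=True).copy()
    out["atac_count"] = count_overlaps(out, fragments)
    cooccur = np.zeros(len(out), dtype=np.int64)
    for (_, _), g in out.groupby(["motif_id", "chrom"], sort=False):
        starts = np.sort(g["start"].to_numpy())
        ends = np.sort(g["end"].to_numpy())
        s = g["start"].to_numpy()
        e = g["end"].to_numpy()
        # neighbors: start_j <= e_i + 100 and end_j >= s_i - 100; self excluded
        near = np.searchsorted(starts, e + 100, side="right")
        far = np.searchsorted(ends, s - 100, side="left")
        cooccur[g.index] = near - far - 1
    out["cooccur_count"] = cooccur
    return out


def fit_negative_binomial(counts: np.ndarray) -> tuple[float, float, bool]:
    """MLE fit of an NB(r, p) to counts; returns (r, p, is_poisson_fallback).

    The mean is profiled out (its MLE is the sample mean) and the dispersion
    r found by bounded 1-D optimization from a method-of-moments start.
    Counts without over-dispersion (variance <= mean) fall back to Poisson.
    """
    x = np.asarray(counts, dtype=float)
    mu = x.mean()
    var = x.var(ddof=1) if len(x) > 1 else 0.0
    if var <= mu or mu == 0:
        warnings.warn("no over-dispersion; falling back to a Poisson fit")
        return np.inf, mu, True

    def nll(log_r: float) -> float:
        r = np.exp(log_r)
        p = r / (r + mu)
        return -stats.nbinom.logpmf(x, r, p).sum()

    mom_r = mu**2 / (var - mu)
    res = minimize_scalar(
        nll, bounds=(np.log(mom_r) - 5, np.log(mom_r) + 5), method="bounded"
    )
    r = float(np.exp(res.x))
    return r, r / (r + mu), False


def _upper_tail(counts: np.ndarray, r: float, p_or_mu: float, poisson: bool) -> np.ndarray:
    """P(X >= x) under the fitted count model."""
    x = np.asarray(counts)
    if poisson:
        return stats.poisson.sf(x - 1, p_or_mu)
    return stats.nbinom.sf(x - 1, r, p_or_mu)


def predict_bound(
    instances: pd.DataFrame, fdr: float = 0.05, refine: int = 1
) -> pd.DataFrame:
    """Call bound motif instances from ATAC and co-occurrence counts.

    Fits one NB to each of {atac_count} and {cooccur_count} (per motif_id),
    computes per-instance upper-tail p-values, combines them by Fisher's
    method (chi-square, 4 df) and calls an instance bound when its
    BH-adjusted combined p is below `fdr`.

    The NBs describe the *unbound* background, but a first fit necessarily
    includes the bound instances, which inflate the fitted dispersion and
    cost power.  `refine` extra rounds therefore refit the NBs on the
    instances not called bound in the previous round and re-score everything
    (a one-step contamination trim; 0 disables it).
    """
    pieces = []
    for motif, g in instances.groupby("motif_id", sort=False):
        if len(g) < 100:
            raise ValueError(
                f"motif {motif}: need >= 100 instances to fit occupancy model"
            )
        g = g.copy()
        keep = np.ones(len(g), dtype=bool)
        for _ in range(refine + 1):
            for col, pcol in (("atac_count", "p_atac"), ("cooccur_count", "p_cooccur")):
                r, pm, pois = fit_negative_binomial(g.loc[keep, col].to_numpy())
                g[pcol] = _upper_tail(g[col].to_numpy(), r, pm, pois)
            chi2 = -2 * (np.log(np.clip(g["p_atac"], 1e-300, None))
                         + np.log(np.clip(g["p_cooccur"], 1e-300, None)))
            g["p_combined"] = stats.chi2.sf(chi2, df=4)
            g["p_adjusted"] = multipletests(g["p_combined"].to_numpy(), method="fdr_bh")[1]
            g["bound"] = g["p_adjusted"] < fdr
            keep = (~g["bound"]).to_numpy()
            if keep.all():  # nothing called; refitting would change nothing
                break
        pieces.append(g)
    return pd.concat(pieces).sort_index()


def deduplicate_sites(bound: pd.DataFrame, min_separation: int = 500) -> pd.DataFrame:
    """Greedy selection of well-separated bound sites.

    Sites are visited in descending atac_count (ties by genomic position)
    and kept iff their center lies more than `min_separation` bp from every
    already-kept center on the same chromosome.
    """
    df = bound.copy()
    df["center"] = (df["start"] + df["end"]) // 2
    df = df.sort_values(
        ["atac_count", "chrom", "center"], ascending=[False, True, True]
    )
    kept_centers: dict[str, list[int]] = {}
    keep_idx = []
    for idx, row in df.iterrows():
        centers = kept_centers.setdefault(row["chrom"], [])
        if all(abs(row["center"] - c) > min_separation for c in centers):
            centers.append(row["center"])
            keep_idx.append(idx)
    return bound.loc[sorted(keep_idx)]


@dataclass
class VPlot:
    motif_id: str
    midpoint_histogram: np.ndarray  # counts at offsets -half_window..+half_window
    half_window: int = 100
    size_matrix: np.ndarray | None = field(default=None, repr=False)

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_window, self.half_window + 1)

    @property
    def total(self) -> int:
        return int(self.midpoint_histogram.sum())


def build_vplot(
    sites: pd.DataFrame,
    fragments: pd.DataFrame,
    half_window: int = 100,
    motif_id: str = "",
    with_size_matrix: bool = False,
) -> VPlot:
    """Aggregate fragment-midpoint distribution around motif centers.

    The midpoint of fragment [s, e) is floor((s+e)/2) and the motif center
    floor((start+end)/2); a fragment contributes at its offset from each
    site center within +/-`half_window`, with offsets sign-flipped at
    minus-strand motifs.  The optional size matrix bins fragment length
    30-500 bp by 5 bp.
    """
    width = 2 * half_window + 1
    hist = np.zeros(width, dtype=np.int64)
    size_edges = np.arange(30, 505, 5)
    size_mat = np.zeros((len(size_edges) - 1, width), dtype=np.int64) if with_size_matrix else None
    strands = sites["strand"] if "strand" in sites.columns else pd.Series("+", index=sites.index)
    for chrom, fg in fragments.groupby("chrom", sort=False):
        sel = sites["chrom"] == chrom
        if not sel.any():
            continue
        mids = (fg["start"].to_numpy() + fg["end"].to_numpy()) // 2
        lengths = fg["end"].to_numpy() - fg["start"].to_numpy()
        order = np.argsort(mids)
        mids = mids[order]
        lengths = lengths[order]
        for center, strand in zip(
            (sites.loc[sel, "start"].to_numpy() + sites.loc[sel, "end"].to_numpy()) // 2,
            strands[sel],
        ):
            lo = np.searchsorted(mids, center - half_window, side="left")
            hi = np.searchsorted(mids, center + half_window, side="right")
            off = mids[lo:hi] - center
            if strand == "-":
                off = -off
            hist += np.bincount(off + half_window, minlength=width)
            if size_mat is not None:
                sb = np.clip((lengths[lo:hi] - 30) // 5, 0, len(size_edges) - 2)
                np.add.at(size_mat, (sb, off + half_window), 1)
    return VPlot(
        motif_id=motif_id,
        midpoint_histogram=hist,
        half_window=half_window,
        size_matrix=size_mat,
    )


def _structured_mask(half_window: int) -> np.ndarray:
    offsets = np.arange(-half_window, half_window + 1)
    mask = (offsets >= ADJACENT_WINDOW[0]) & (offsets <= ADJACENT_WINDOW[1])
    for lo, hi in PROXIMAL_WINDOWS:
        mask |= (offsets >= lo) & (offsets <= hi)
    return mask


def fvice(vplot: VPlot, n_shuffles: int = 100, seed: int = 0) -> float:
    """Raw f-VICE: log2 observed/expected midpoint mass in the A u P windows.

    O is the observed midpoint count at TF-adjacent ([-25, 25]) plus
    TF-proximal ([-70, -50] u [50, 70]) offsets; E is the mean count over
    `n_shuffles` uniform redistributions of the same total across all
    offsets.  Both get a pseudocount of 1.
    """
    total = vplot.total
    if total == 0:
        raise ValueError("empty V-plot; f-VICE undefined")
    mask = _structured_mask(vplot.half_window)
    observed = int(vplot.midpoint_histogram[mask].sum())
    rng = np.random.default_rng(seed)
    width = len(vplot.midpoint_histogram)
    shuffled = rng.multinomial(total, np.full(width, 1.0 / width), size=n_shuffles)
    expected = shuffled[:, mask].sum(axis=1).mean()
    return float(np.log2((observed + 1) / (expected + 1)))


def normalize_fvice(records: pd.DataFrame) -> pd.DataFrame:
    """Residuals of fvice_raw ~ log10(total fragments) + log10(total cooccur).

    Removes the dependence of raw f-VICE on motif abundance and overall
    accessibility; requires >= 10 motifs.
    """
    if len(records) < 10:
        raise ValueError("normalize_fvice needs >= 10 motifs")
    X = sm.add_constant(
        np.column_stack(
            [
                np.log10(records["total_fragments"].to_numpy(dtype=float) + 1),
                np.log10(records["total_cooccur"].to_numpy(dtype=float) + 1),
            ]
        )
    )
    fit = sm.OLS(records["fvice_raw"].to_numpy(dtype=float), X).fit()
    out = records.copy()
    out["fvice_norm"] = fit.resid
    return out


def condition_zscores(
    records: pd.DataFrame,
    condition_col: str = "celltype",
    donor_col: str = "donor",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-condition comparison of normalized f-VICE.

    Within each donor x condition, fvice_norm is Z-transformed across
    motifs; the per-motif, per-condition median Z across donors gives one
    value per motif and condition.  The second return is the display matrix:
    each motif row Z-scaled across conditions (constant rows become 0).
    """
    df = records.copy()

    def _z(v: pd.Series) -> pd.Series:
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(0.0, index=v.index)
        return (v - v.mean()) / sd

    df["z"] = df.groupby([donor_col, condition_col])["fvice_norm"].transform(_z)
    median_z = (
        df.groupby(["motif_id", condition_col])["z"].median().unstack(condition_col)
    )
    row_z, _ = _rowwise_z(median_z)
    return median_z, row_z


def _rowwise_z(mat: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    sd = mat.std(axis=1, ddof=1)
    degenerate = (sd == 0) | ~np.isfinite(sd)
    z = mat.sub(mat.mean(axis=1), axis=0).div(sd.where(~degenerate, 1.0), axis=0)
    z.loc[degenerate] = 0.0
    return z, degenerate
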