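"""Annotation-informed GWAS enrichment and functional fine-mapping.

The model is the standard one-causal-variant-per-window hierarchical form:
each window of (at most) 5,000 consecutive variants harbors an association
with probability pi; conditional on association, variant i is the causal one
with prior probability softmax(gamma . x_i) over the window, where x_i is a
binary annotation vector (e.g. "overlaps a reproducible extended summit in
cell type k") and gamma the log-scale enrichment per annotation.  Evidence
per variant is the Wakefield approximate Bayes factor computed from the
marginal effect estimate and its standard error.  The marginal likelihood of
a window is therefore

    (1 - pi) + pi * sum_i softmax_w(gamma . x_i) * ABF_i

and (pi, gamma) are estimated jointly by maximum likelihood.  Posterior
probabilities of association (PPAs) within a window are the annotation-
reweighted, ABF-weighted priors, and the 99% credible set is the smallest
set of variants whose PPAs reach 0.99.

Windows are built to contain known GWAS loci whole: each lead variant gets a
window of 5,000 variants centered on it, and the remaining variants are
chunked consecutively, shortening chunks that would straddle a lead window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "Window",
    "EnrichmentModel",
    "wakefield_abf",
    "build_windows",
    "fit_enrichment",
    "reweighted_ppa",
    "credible_set",
    "finemap_pipeline",
]


@dataclass
class Window:
    window_id: str
    start: int  # first variant index (inclusive), in genomic order
    stop: int  # past-the-end variant index
    lead_variant: str | None = None

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass
class EnrichmentModel:
    pi: float
    gamma: np.ndarray
    loglik: float


def wakefield_abf(beta, se, W: float = 0.04):
    """Wakefield approximate Bayes factor in favor of association.

    abf = sqrt(se^2/(se^2+W)) * exp(z^2 W / (2 (se^2+W))), with z = beta/se
    and W the prior variance of the true effect (default 0.04, i.e. prior SD
    0.2 on the log-odds scale).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if W <= 0:
        raise ValueError("prior variance W must be positive")
    z2 = (beta / se) ** 2
    shrink = se**2 / (se**2 + W)
    return np.sqrt(shrink) * np.exp(z2 * W / (2 * (se**2 + W)))


def log_wakefield_abf(beta, se, W: float = 0.04):
    """log ABF, safe for very large |z|."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    z2 = (beta / se) ** 2
    return 0.5 * np.log(se**2 / (se**2 + W)) + z2 * W / (2 * (se**2 + W))


def build_windows(
    variants: pd.DataFrame, leads=(), window_size: int = 5000
) -> list[Window]:
    """Partition genomically ordered variants into windows of <= `window_size`.

    Each lead variant gets a window of `window_size` variants centered on it
    (floor(w/2) on each side), truncated at chromosome ends; two overlapping
    lead windows are truncated at the midpoint between their leads.  Leftover
    stretches are chunked consecutively.  Chromosomes are hard boundaries.
    """
    leads = list(leads)
    missing = set(leads) - set(variants["variant_id"])
    if missing:
        raise ValueError(f"lead variants not present: {sorted(missing)}")
    id_to_idx = {v: i for i, v in enumerate(variants["variant_id"])}
    windows: list[Window] = []
    wid = 0
    offset = 0
    for chrom, g in variants.groupby("chrom", sort=False):
        n = len(g)
        lead_idx = sorted(
            (id_to_idx[v] - offset, v) for v in leads if id_to_idx[v] in range(offset, offset + n)
        )
        half = window_size // 2
        spans = []  # (lo, hi, lead_id) local to this chromosome
        for li, lv in lead_idx:
            spans.append([max(li - half, 0), min(li + half, n), lv, li])
        for k in range(len(spans) - 1):
            if spans[k + 1][0] < spans[k][1]:  # overlapping lead windows
                mid = (spans[k][3] + spans[k + 1][3] + 1) // 2
                spans[k][1] = min(spans[k][1], mid)
                spans[k + 1][0] = max(spans[k + 1][0], mid)
        cursor = 0
        for lo, hi, lv, _ in spans:
            while cursor < lo:  # chunk the gap before this lead window
                stop = min(cursor + window_size, lo)
                windows.append(Window(f"w{wid}", offset + cursor, offset + stop))
                wid += 1
                cursor = stop
            windows.append(Window(f"w{wid}", offset + lo, offset + hi, lead_variant=lv))
            wid += 1
            cursor = hi
        while cursor < n:
            stop = min(cursor + window_size, n)
            windows.append(Window(f"w{wid}", offset + cursor, offset + stop))
            wid += 1
            cursor = stop
        offset += n
    return windows


def _segment_logsumexp(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """logsumexp over contiguous segments given their start offsets."""
    mx = np.maximum.reduceat(values, starts)
    seg_mx = np.repeat(mx, np.diff(np.append(starts, len(values))))
    sums = np.add.reduceat(np.exp(values - seg_mx), starts)
    return mx + np.log(sums)


def _neg_loglik(theta, starts, log_abf, X):
    lp = theta[0]
    gamma = theta[1:]
    pi = expit(lp)
    gx = X @ gamma
    # log sum_i softmax(gx)*abf = lse(gx + log abf) - lse(gx), per window
    log_s = _segment_logsumexp(gx + log_abf, starts) - _segment_logsumexp(gx, starts)
    # log((1-pi) + pi * S)
    ll = np.logaddexp(np.log1p(-pi), np.log(pi) + log_s)
    return -float(ll.sum())


def fit_enrichment(
    windows: list[Window],
    abfs: np.ndarray | None,
    annotations: np.ndarray,
    log_abfs: np.ndarray | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> EnrichmentModel:
    """Joint MLE of (pi, gamma) by bounded quasi-Newton from multiple starts.

    `annotations` is an (n_variants, n_annotations) 0/1 matrix in the same
    order as the variants the windows index.  Pass `log_abfs` for numerical
    safety at very large |z| (otherwise logs are taken of `abfs`).
    """
    if len(windows) < 20:
        raise ValueError("need >= 20 windows to fit the enrichment model")
    X = np.atleast_2d(np.asarray(annotations, dtype=float))
    if X.shape[0] != sum(len(w) for w in windows):
        raise ValueError("annotation matrix does not match window variant count")
    if log_abfs is None:
        log_abfs = np.log(np.asarray(abfs, dtype=float))
    order = np.concatenate([w.indices for w in windows])
    log_abf = np.asarray(log_abfs, dtype=float)[order]
    Xo = X[order]
    starts = np.cumsum([0] + [len(w) for w in windows[:-1]])
    k = X.shape[1]
    rng = np.random.default_rng(seed)
    bounds = [(-10.0, 10.0)] + [(-20.0, 20.0)] * k
    best = None
    trace = []
    for s in range(n_starts):
        if s == 0:
            x0 = np.zeros(1 + k)
        else:
            x0 = rng.normal(0.0, 1.0, size=1 + k)
        res = minimize(
            _neg_loglik,
            x0,
            args=(starts, log_abf, Xo),
            method="L-BFGS-B",
            bounds=bounds,
        )
        trace.append((s, res.success, res.fun))
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"enrichment fit failed to converge; trace: {trace}")
    return EnrichmentModel(
        pi=float(expit(best.x[0])),
        gamma=best.x[1:].copy(),
        loglik=-float(best.fun),
    )


def loglik_at(pi: float, gamma, windows, annotations, log_abfs) -> float:
    """Log-likelihood at given parameters (for model comparison)."""
    X = np.atleast_2d(np.asarray(annotations, dtype=float))
    order = np.concatenate([w.indices for w in windows])
    starts = np.cumsum([0] + [len(w) for w in windows[:-1]])
    theta = np.concatenate([[logit(pi)], np.atleast_1d(gamma)])
    return -_neg_loglik(theta, starts, np.asarray(log_abfs)[order], X[order])


def reweighted_ppa(
    window: Window, log_abfs: np.ndarray, model: EnrichmentModel, annotations: np.ndarray
) -> np.ndarray:
    """Per-variant PPA conditional on the window holding an association.

    ppa_i = softmax_w(gamma . x_i) * abf_i / sum_j softmax_w(gamma . x_j) * abf_j.
    """
    X = np.atleast_2d(np.asarray(annotations, dtype=float))
    idx = window.indices
    s = X[idx] @ model.gamma + np.asarray(log_abfs)[idx]
    s = s - s.max()
    w = np.exp(s)
    return w / w.sum()


def credible_set(ppas: np.ndarray, pos: np.ndarray | None = None, level: float = 0.99) -> np.ndarray:
    """Indices of the smallest PPA-descending set with cumulative PPA >= level.

    Ties in PPA are broken by genomic position (ascending) when `pos` is
    given, otherwise by input order.
    """
    ppas = np.asarray(ppas, dtype=float)
    if pos is None:
        pos = np.arange(len(ppas))
    order = np.lexsort((np.asarray(pos), -ppas))
    cum = np.cumsum(ppas[order])
    k = int(np.searchsorted(cum, level, side="left")) + 1
    k = min(k, len(ppas))
    return np.sort(order[:k])


def finemap_pipeline(
    gwas: pd.DataFrame,
    annotations: np.ndarray,
    leads=(),
    window_size: int = 5000,
    W: float = 0.04,
    level: float = 0.99,
    seed: int = 0,
) -> tuple[EnrichmentModel, pd.DataFrame, list[Window]]:
    """ABFs -> windows -> enrichment fit -> reweighted PPAs -> credible sets.

    `gwas` has variant_id, chrom, pos (1-based), beta, se, in genomic order.
    Returns the fitted model, a per-variant table with abf/ppa/in_cs columns,
    and the window list.
    """
    log_abf = log_wakefield_abf(gwas["beta"].to_numpy(), gwas["se"].to_numpy(), W=W)
    windows = build_windows(gwas, leads=leads, window_size=window_size)
    model = fit_enrichment(windows, None, annotations, log_abfs=log_abf, seed=seed)
    out = gwas.copy()
    out["abf"] = np.exp(log_abf)
    out["ppa"] = 0.0
    out["window_id"] = ""
    out["in_cs"] = False
    pos = gwas["pos"].to_numpy()
    for w in windows:
        ppa = reweighted_ppa(w, log_abf, model, annotations)
        out.iloc[w.indices, out.columns.get_loc("ppa")] = ppa
        out.iloc[w.indices, out.columns.get_loc("window_id")] = w.window_id
        cs = credible_set(ppa, pos=pos[w.indices], level=level)
        col = out.columns.get_loc("in_cs")
        out.iloc[w.indices[cs], col] = True
    return model, out, windows
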