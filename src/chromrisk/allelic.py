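"""Allelic-imbalance testing at heterozygous SNPs in accessible chromatin.

Read counts over the two alleles of a heterozygous SNP should be ~equal
unless the variant alters chromatin accessibility in cis.  Residual mapping
bias favors the reference allele even after remapping-based correction, so
the null is not 0.5: the genome-wide reference fraction p0 is estimated by
pooling counts over all heterozygous sites and each site is tested with an
exact two-tailed binomial test against p0.  Sites with significant imbalance
and a confident sequence-model prediction (|score| >= 2) are then checked
for direction agreement between observed and predicted allelic effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "estimate_reference_bias",
    "test_site",
    "test_sites",
    "concordance",
    "ConcordanceResult",
]

# relative tolerance when comparing point probabilities in the two-sided
# test, to keep ties robust to floating-point noise (scipy's convention)
_TIE_GAMMA = 1 + 1e-7


def estimate_reference_bias(sites: pd.DataFrame) -> float:
    """Genome-wide residual reference bias: sum(ref) / sum(ref + alt)."""
    ref = sites["ref_count"].to_numpy(dtype=float)
    alt = sites["alt_count"].to_numpy(dtype=float)
    total = ref.sum() + alt.sum()
    if total <= 0:
        raise ValueError("no covered sites to estimate reference bias from")
    return float(ref.sum() / total)


@lru_cache(maxsize=4096)
def _pvalue_table(n: int, p0: float, method: str) -> np.ndarray:
    """Two-sided p-value for every outcome k = 0..n at one (n, p0)."""
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    if method == "min-likelihood":
        order = np.argsort(pmf)
        cum = np.cumsum(pmf[order])
        table = np.empty(n + 1)
        # p(k) = sum of pmf over outcomes no more likely than k (with a
        # relative tie tolerance); computed by ranking outcomes by pmf
        sorted_pmf = pmf[order]
        for rank, k in enumerate(order):
            j = np.searchsorted(sorted_pmf, pmf[k] * _TIE_GAMMA, side="right")
            table[k] = cum[j - 1] if j > 0 else 0.0
    elif method == "double":
        lower = np.cumsum(pmf)
        upper = np.cumsum(pmf[::-1])[::-1]
        table = 2 * np.minimum(lower, upper)
    else:
        raise ValueError(f"unknown two-sided method: {method}")
    return np.minimum(table, 1.0)


def test_site(ref: int, alt: int, p0: float, method: str = "min-likelihood") -> float:
    """Exact two-tailed binomial test of `ref` successes in ref+alt trials at p0.

    "min-likelihood" (default) sums the probabilities of all outcomes whose
    point probability does not exceed the observed one; "double" doubles the
    smaller one-sided tail (capped at 1).
    """
    n = ref + alt
    if n < 1:
        raise ValueError("site has no coverage")
    return float(_pvalue_table(n, float(p0), method)[ref])


def test_sites(
    sites: pd.DataFrame,
    p0: float | None = None,
    min_coverage: int = 10,
    fdr: float = 0.05,
    use_fdr: bool = True,
    method: str = "min-likelihood",
) -> pd.DataFrame:
    """Test every site with >= `min_coverage` reads; add pvalue/fdr/significant.

    p0 defaults to the pooled estimate over all input sites (computed before
    the coverage floor is applied).  Significance is Benjamini-Hochberg FDR <
    `fdr` across tested sites, or raw p < `fdr` when `use_fdr` is False.
    """
    out = sites.copy()
    if p0 is None:
        p0 = estimate_reference_bias(out)
    cov = out["ref_count"] + out["alt_count"]
    tested = cov >= min_coverage
    out["tested"] = tested
    out["pvalue"] = np.nan
    out.loc[tested, "pvalue"] = [
        test_site(int(r), int(a), p0, method=method)
        for r, a in zip(out.loc[tested, "ref_count"], out.loc[tested, "alt_count"])
    ]
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(
            out.loc[tested, "pvalue"].to_numpy(), method="fdr_bh"
        )[1]
    sig_col = "fdr" if use_fdr else "pvalue"
    out["significant"] = tested & (out[sig_col] < fdr)
    out.attrs["p0"] = p0
    return out


@dataclass
class ConcordanceResult:
    n: int
    n_agree: int
    fraction: float
    pvalue: float  # two-sided binomial test of the agreement fraction vs 0.5


def concordance(
    tested: pd.DataFrame, p0: float, score_min: float = 2.0
) -> ConcordanceResult:
    """Direction agreement between observed imbalance and predicted effects.

    Restricted to sites with |pred_score| >= `score_min` and significant
    observed imbalance (the `significant` column from :func:`test_sites`).
    A site agrees when the sign of (alt fraction - (1 - p0)) matches the
    sign of the predicted alt-minus-ref effect.
    """
    elig = tested.loc[
        tested["significant"] & (tested["pred_score"].abs() >= score_min)
    ]
    n = len(elig)
    if n == 0:
        return ConcordanceResult(n=0, n_agree=0, fraction=np.nan, pvalue=np.nan)
    alt_frac = elig["alt_count"] / (elig["ref_count"] + elig["alt_count"])
    observed = np.sign(alt_frac - (1 - p0))
    predicted = np.sign(elig["pred_score"])
    n_agree = int((observed == predicted).sum())
    p = stats.binomtest(n_agree, n, 0.5, alternative="two-sided").pvalue
    return ConcordanceResult(
        n=n, n_agree=n_agree, fraction=n_agree / n, pvalue=float(p)
    )
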