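"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator emits, alongside its data, a truth table for the latent
structure it drew (causal cell type, causal variant, allelic-effect sites,
bound motifs), so each downstream stage has an explicit recovery target.
Randomness is deterministic: one RNG stream per output role, derived from
the master seed by stable hashing of the role name, so adding one output
never perturbs another.

What is emulated (and what is not): cell-type-specific accessibility peaks
with configurable depth and in-peak fraction; per-library summit calls with
positional jitter and dropout; fine-mapped loci whose top-PPA variant sits
in a peak private to the causal cell type; one-causal-per-window GWAS
effects with annotation-dependent causal priors; reference-biased allele
counts with a subset of true-imbalance sites; and phased-nucleosome fragment
midpoints around bound motifs.  Raw reads, barcode-level sparsity, doublets
and ambient contamination are not simulated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, softmax

__all__ = [
    "SimulationConfig",
    "simulate_celltype_fragments",
    "simulate_credible_sets",
    "simulate_gwas_windows",
    "simulate_allelic_sites",
    "simulate_footprint_fragments",
]


@dataclass
class EnrichmentTruth:
    pi: float = 0.3
    gamma: tuple[float, ...] = (1.5,)


@dataclass
class AllelicTruth:
    p0: float = 0.53  # residual reference bias after remapping correction
    effect_sites_fraction: float = 0.1
    effect_size: float = 2.0  # log-odds shift of the alt-allele fraction
    sign_correct_fraction: float = 0.9  # predictions matching the true direction


@dataclass
class SimulationConfig:
    seed: int = 0
    n_celltypes: int = 5
    n_libraries_per_celltype: int = 3
    genome: tuple[tuple[str, int], ...] = (("chr1", 10_000_000),)
    depth_per_celltype: int = 100_000
    peak_width_bp: int = 301
    peak_fraction: float = 0.6  # fraction of fragments placed inside peaks
    summit_jitter_bp: int = 20
    library_dropout: float = 0.1  # per-library chance of missing a peak summit
    enrichment_truth: EnrichmentTruth = field(default_factory=EnrichmentTruth)
    allelic_truth: AllelicTruth = field(default_factory=AllelicTruth)
    abf_prior_variance: float = 0.04  # W; matches the fine-mapping ABF default

    def __post_init__(self) -> None:
        if not self.genome or any(length <= 0 for _, length in self.genome):
            raise ValueError("genome must list chromosomes of positive length")
        for p in (
            self.peak_fraction,
            self.library_dropout,
            self.enrichment_truth.pi,
            self.allelic_truth.p0,
            self.allelic_truth.effect_sites_fraction,
            self.allelic_truth.sign_correct_fraction,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.peak_width_bp <= 0 or self.depth_per_celltype < 0:
            raise ValueError("lengths and depths must be positive")

    def rng(self, role: str) -> np.random.Generator:
        """Independent stream for one output role."""
        return np.random.default_rng(
            [self.seed, zlib.crc32(role.encode()) & 0x7FFFFFFF]
        )

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.genome)


def _fragment_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    """Sub-nucleosomal / mono-nucleosomal length mixture, clipped to 30-500."""
    sub = rng.random(n) < 0.6
    lengths = np.where(
        sub, rng.normal(80, 15, size=n), rng.normal(200, 30, size=n)
    )
    return np.clip(np.round(lengths), 30, 500).astype(np.int64)


def _fragments_from_midpoints(
    chroms: np.ndarray, mids: np.ndarray, lengths: np.ndarray, sizes: dict[str, int]
) -> pd.DataFrame:
    starts = mids - lengths // 2
    ends = starts + lengths
    limits = np.array([sizes[c] for c in chroms])
    shift = np.maximum(-starts, 0) - np.maximum(ends - limits, 0)
    starts = starts + shift
    ends = ends + shift
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def simulate_celltype_fragments(
    config: SimulationConfig, peak_map: dict[str, pd.DataFrame]
) -> tuple[dict[str, pd.DataFrame], dict[str, dict[str, pd.DataFrame]]]:
    """Pseudo-bulk fragments per cell type plus per-library summit calls.

    Each cell type gets exactly `depth_per_celltype` fragments: a
    `peak_fraction` Bernoulli share with midpoints uniform inside a
    uniformly chosen peak of that cell type, the rest with midpoints uniform
    over the genome.  Each library reports each peak's midpoint as a summit,
    jittered +/-`summit_jitter_bp`, independently dropping peaks with
    probability `library_dropout`.
    """
    sizes = config.chrom_sizes
    for ct, peaks in peak_map.items():
        for chrom, g in peaks.groupby("chrom"):
            if chrom not in sizes or (g["end"] > sizes[chrom]).any():
                raise ValueError(f"{ct}: peak outside genome bounds on {chrom}")
    chrom_names = [c for c, _ in config.genome]
    chrom_lengths = np.array([l for _, l in config.genome], dtype=float)
    fragments: dict[str, pd.DataFrame] = {}
    summits: dict[str, dict[str, pd.DataFrame]] = {}
    for ct, peaks in peak_map.items():
        rng = config.rng(f"fragments/{ct}")
        n = config.depth_per_celltype
        in_peak = rng.random(n) < config.peak_fraction
        n_in = int(in_peak.sum())
        mids = np.empty(n, dtype=np.int64)
        chroms = np.empty(n, dtype=object)
        if n_in and len(peaks):
            pk = rng.integers(0, len(peaks), size=n_in)
            ps = peaks["start"].to_numpy()[pk]
            pe = peaks["end"].to_numpy()[pk]
            mids[in_peak] = ps + rng.integers(0, pe - ps)
            chroms[in_peak] = peaks["chrom"].to_numpy()[pk]
        else:
            in_peak[:] = False
        n_bg = int((~in_peak).sum())
        ci = rng.choice(len(chrom_names), size=n_bg, p=chrom_lengths / chrom_lengths.sum())
        chroms[~in_peak] = np.array(chrom_names, dtype=object)[ci]
        mids[~in_peak] = (rng.random(n_bg) * chrom_lengths[ci]).astype(np.int64)
        lengths = _fragment_lengths(rng, n)
        fragments[ct] = _fragments_from_midpoints(chroms, mids, lengths, sizes)
        summits[ct] = {}
        srng = config.rng(f"summits/{ct}")
        for lib in range(config.n_libraries_per_celltype):
            keep = srng.random(len(peaks)) >= config.library_dropout
            jitter = srng.integers(
                -config.summit_jitter_bp, config.summit_jitter_bp + 1, size=len(peaks)
            )
            pos = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2 + jitter
            pos = np.clip(pos, 0, [sizes[c] - 1 for c in peaks["chrom"]])
            summits[ct][f"{ct}_lib{lib}"] = pd.DataFrame(
                {"chrom": peaks["chrom"].to_numpy()[keep], "pos": pos[keep]}
            ).reset_index(drop=True)
    return fragments, summits


def _random_peaks(
    rng: np.random.Generator, config: SimulationConfig, n: int, occupied: list
) -> pd.DataFrame:
    """`n` non-overlapping peaks avoiding already-occupied spans."""
    sizes = config.chrom_sizes
    chrom_names = [c for c, _ in config.genome]
    lengths = np.array([l for _, l in config.genome], dtype=float)
    w = config.peak_width_bp
    rows = []
    tries = 0
    while len(rows) < n and tries < 100 * n:
        tries += 1
        ci = rng.choice(len(chrom_names), p=lengths / lengths.sum())
        chrom = chrom_names[ci]
        start = int(rng.integers(0, sizes[chrom] - w))
        span = (chrom, start - w, start + 2 * w)  # keep a peak-width gap
        if any(c == chrom and s < start + w and start - w < e for c, s, e in occupied):
            continue
        occupied.append(span)
        rows.append((chrom, start, start + w))
    if len(rows) < n:
        raise RuntimeError("could not place non-overlapping peaks; genome too small")
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_credible_sets(
    config: SimulationConfig,
    n_loci: int = 20,
    celltype_truth: dict[str, str] | None = None,
    n_shared_peaks: int = 200,
    max_variants: int = 20,
    top_ppa: float = 0.6,
):
    """Fine-mapped loci whose top-PPA variant marks a cell-type-private peak.

    Builds per-cell-type peak maps (shared background peaks present in every
    cell type, plus one private peak per locus present only in its causal
    cell type), centers the top-PPA variant in the private peak, scatters
    the remaining credible-set variants nearby with smaller PPAs (per-locus
    PPA total <= 1), and generates matching pseudo-bulk fragments.

    Returns (credible_sets, truth, peak_map, fragments, summits).
    """
    rng = config.rng("credible_sets")
    celltypes = [f"ct{i}" for i in range(config.n_celltypes)]
    if celltype_truth is None:
        celltype_truth = {
            f"locus{i}": celltypes[int(rng.integers(0, len(celltypes)))]
            for i in range(n_loci)
        }
    unknown = set(celltype_truth.values()) - set(celltypes)
    if unknown:
        raise ValueError(f"causal cell types not in config: {sorted(unknown)}")
    occupied: list = []
    shared = _random_peaks(rng, config, n_shared_peaks, occupied)
    private = {
        locus: _random_peaks(rng, config, 1, occupied)
        for locus in celltype_truth
    }
    peak_map = {
        ct: pd.concat(
            [shared]
            + [private[l] for l, c in celltype_truth.items() if c == ct],
            ignore_index=True,
        )
        for ct in celltypes
    }
    rows = []
    sizes = config.chrom_sizes
    for locus, ct in celltype_truth.items():
        pk = private[locus].iloc[0]
        center_1based = int((pk["start"] + pk["end"]) // 2) + 1
        n_var = int(rng.integers(1, max_variants + 1))
        ppa_top = top_ppa if n_var > 1 else 1.0
        rows.append((locus, f"{locus}_v0", pk["chrom"], center_1based, ppa_top))
        if n_var > 1:
            rest = rng.dirichlet(np.ones(n_var - 1)) * (0.95 - ppa_top)
            offsets = rng.integers(500, 5000, size=n_var - 1) * rng.choice(
                [-1, 1], size=n_var - 1
            )
            for j, (off, pp) in enumerate(zip(offsets, rest), start=1):
                pos = int(np.clip(center_1based + off, 1, sizes[pk["chrom"]]))
                rows.append((locus, f"{locus}_v{j}", pk["chrom"], pos, float(pp)))
    credible = pd.DataFrame(
        rows, columns=["locus_id", "variant_id", "chrom", "pos", "ppa"]
    )
    truth = pd.DataFrame(
        [(l, c) for l, c in celltype_truth.items()],
        columns=["locus_id", "causal_celltype"],
    )
    fragments, summits = simulate_celltype_fragments(config, peak_map)
    return credible, truth, peak_map, fragments, summits


def simulate_gwas_windows(
    config: SimulationConfig,
    n_windows: int = 500,
    variants_per_window: int = 50,
    annotation_prob: float = 0.2,
    se_range: tuple[float, float] = (0.025, 0.035),
    spacing_bp: int = 500,
):
    """One-causal-per-window GWAS summary statistics with annotated priors.

    Each window holds an association with probability pi (from
    `config.enrichment_truth`); within associated windows the causal variant
    is drawn with probability proportional to exp(gamma . x), its true
    effect from N(0, W) with W = `config.abf_prior_variance`, and every
    variant's observed beta from N(true effect, se^2).

    Returns (gwas, annotations, truth) where truth carries pi, gamma, and
    per-window association flags and causal indices (-1 for null windows).
    """
    pi = config.enrichment_truth.pi
    gamma = np.asarray(config.enrichment_truth.gamma, dtype=float)
    if not 0 <= pi <= 1:
        raise ValueError("pi must lie in [0, 1]")
    rng = config.rng("gwas_windows")
    n = n_windows * variants_per_window
    k = len(gamma)
    X = (rng.random((n, k)) < annotation_prob).astype(np.int64)
    se = rng.uniform(*se_range, size=n)
    beta_true = np.zeros(n)
    assoc = rng.random(n_windows) < pi
    causal_idx = np.full(n_windows, -1, dtype=np.int64)
    W = config.abf_prior_variance
    for w in range(n_windows):
        if not assoc[w]:
            continue
        lo = w * variants_per_window
        idx = np.arange(lo, lo + variants_per_window)
        probs = softmax(X[idx] @ gamma)
        causal = int(rng.choice(idx, p=probs))
        causal_idx[w] = causal
        beta_true[causal] = rng.normal(0.0, np.sqrt(W))
    beta = beta_true + rng.normal(0.0, 1.0, size=n) * se
    gwas = pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(n)],
            "chrom": "chr1",
            "pos": np.arange(1, n + 1) * spacing_bp,
            "beta": beta,
            "se": se,
        }
    )
    truth = {
        "pi": pi,
        "gamma": gamma,
        "associated": assoc,
        "causal_index": causal_idx,
        "beta_true": beta_true,
        "variants_per_window": variants_per_window,
    }
    return gwas, X, truth


def simulate_allelic_sites(
    config: SimulationConfig, n_sites: int = 1000, coverage_mean: float = 50.0
):
    """Reference-biased allele counts with a subset of true-imbalance sites.

    Null sites draw ref counts Binomial(n, p0); effect sites shift the ALT
    fraction by +/-`effect_size` log-odds (random direction).  Predicted
    effect scores (alt minus ref) match the true direction for
    `sign_correct_fraction` of effect sites; null sites get N(0, 1) scores.

    Returns (sites, truth) with truth columns is_effect and direction.
    """
    at = config.allelic_truth
    rng = config.rng("allelic_sites")
    if n_sites == 0:
        cols = ["site_id", "chrom", "pos", "ref_count", "alt_count", "pred_score"]
        return pd.DataFrame(columns=cols), pd.DataFrame(
            columns=["site_id", "is_effect", "direction"]
        )
    n = rng.poisson(coverage_mean, size=n_sites)
    n = np.maximum(n, 1)
    is_effect = rng.random(n_sites) < at.effect_sites_fraction
    direction = np.where(rng.random(n_sites) < 0.5, 1, -1)
    direction[~is_effect] = 0
    p_alt = np.full(n_sites, 1 - at.p0)
    shift = logit(1 - at.p0) + direction * at.effect_size
    p_alt[is_effect] = expit(shift[is_effect])
    alt = rng.binomial(n, p_alt)
    ref = n - alt
    pred = rng.normal(0.0, 1.0, size=n_sites)
    mag = np.abs(rng.normal(3.0, 1.0, size=n_sites))
    sign_ok = rng.random(n_sites) < at.sign_correct_fraction
    eff = is_effect
    pred[eff] = mag[eff] * np.where(sign_ok[eff], direction[eff], -direction[eff])
    chrom = config.genome[0][0]
    pos = rng.integers(1, config.genome[0][1] + 1, size=n_sites)
    sites = pd.DataFrame(
        {
            "site_id": [f"site{i}" for i in range(n_sites)],
            "chrom": chrom,
            "pos": pos,
            "ref_count": ref,
            "alt_count": alt,
            "pred_score": pred,
        }
    )
    truth = pd.DataFrame(
        {
            "site_id": sites["site_id"],
            "is_effect": is_effect,
            "direction": direction,
        }
    )
    return sites, truth


def simulate_footprint_fragments(
    config: SimulationConfig,
    motif_sites: pd.DataFrame,
    bound_flags: np.ndarray,
    mixture_weight: float = 0.95,
    bound_mean: float = 30.0,
    unbound_mean: float = 3.0,
    nb_r: float = 5.0,
    half_window: int = 100,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Fragment midpoints around motifs with a phased-nucleosome pattern.

    Bound sites draw per-site fragment counts from an NB with mean
    `bound_mean` and midpoint offsets from a mixture: with probability
    `mixture_weight` a structured component wholly inside the TF-adjacent
    (+/-25 bp, sub-nucleosomal lengths) or TF-proximal (50-70 bp,
    mono-nucleosomal) windows, otherwise uniform over +/-`half_window`.
    Unbound sites draw NB(mean `unbound_mean`) counts with uniform offsets.
    Offsets are strand-oriented.  Returns (fragments, per-site counts).
    """
    rng = config.rng("footprints")
    sizes = config.chrom_sizes
    bound_flags = np.asarray(bound_flags, dtype=bool)
    if len(bound_flags) != len(motif_sites):
        raise ValueError("bound_flags length must match motif_sites")
    p_b = nb_r / (nb_r + bound_mean)
    p_u = nb_r / (nb_r + unbound_mean)
    counts = np.where(
        bound_flags,
        rng.negative_binomial(nb_r, p_b, size=len(motif_sites)),
        rng.negative_binomial(nb_r, p_u, size=len(motif_sites)),
    )
    strands = (
        motif_sites["strand"].to_numpy()
        if "strand" in motif_sites.columns
        else np.full(len(motif_sites), "+")
    )
    centers = (motif_sites["start"].to_numpy() + motif_sites["end"].to_numpy()) // 2
    chroms_all, mids_all, lens_all = [], [], []
    for i in range(len(motif_sites)):
        c = int(counts[i])
        if c == 0:
            continue
        if bound_flags[i]:
            structured = rng.random(c) < mixture_weight
            adjacent = rng.random(c) < 0.6
            off = np.empty(c, dtype=np.int64)
            # TF-adjacent: tight around the motif; TF-proximal: phased
            # nucleosome edges at ~60 bp either side
            off_adj = np.clip(np.round(rng.normal(0, 10, size=c)), -25, 25)
            side = rng.choice([-1, 1], size=c)
            off_prox = side * np.clip(np.round(rng.normal(60, 4, size=c)), 50, 70)
            off_unif = rng.integers(-half_window, half_window + 1, size=c)
            off = np.where(structured, np.where(adjacent, off_adj, off_prox), off_unif)
            lengths = np.where(
                structured & adjacent,
                rng.normal(80, 15, size=c),
                rng.normal(200, 30, size=c),
            )
        else:
            off = rng.integers(-half_window, half_window + 1, size=c)
            lengths = np.where(
                rng.random(c) < 0.6,
                rng.normal(80, 15, size=c),
                rng.normal(200, 30, size=c),
            )
        off = off.astype(np.int64)
        if strands[i] == "-":
            off = -off
        lengths = np.clip(np.round(lengths), 30, 500).astype(np.int64)
        chroms_all.append(np.full(c, motif_sites["chrom"].iloc[i], dtype=object))
        mids_all.append(centers[i] + off)
        lens_all.append(lengths)
    if not chroms_all:
        frags = pd.DataFrame(columns=["chrom", "start", "end"])
    else:
        frags = _fragments_from_midpoints(
            np.concatenate(chroms_all),
            np.concatenate(mids_all),
            np.concatenate(lens_all),
            sizes,
        )
    return frags, counts
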