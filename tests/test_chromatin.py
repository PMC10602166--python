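import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromrisk.chromatin import (
    build_vplot,
    condition_zscores,
    count_motif_features,
    deduplicate_sites,
    fit_negative_binomial,
    fvice,
    normalize_fvice,
    predict_bound,
    VPlot,
)
from chromrisk.synthetic import SimulationConfig, simulate_footprint_fragments


def motifs(rows):
    return pd.DataFrame(rows, columns=["motif_id", "chrom", "start", "end"])


def no_fragments():
    return pd.DataFrame(columns=["chrom", "start", "end"])


class TestCountMotifFeatures:
    def test_cooccurrence_100bp_inclusive(self):
        m = motifs([("M", "chr1", 1000, 1015), ("M", "chr1", 1115, 1130)])
        out = count_motif_features(m, no_fragments())
        assert out["cooccur_count"].tolist() == [1, 1]  # gap exactly 100

    def test_cooccurrence_101bp_excluded(self):
        m = motifs([("M", "chr1", 1000, 1015), ("M", "chr1", 1116, 1131)])
        out = count_motif_features(m, no_fragments())
        assert out["cooccur_count"].tolist() == [0, 0]

    def test_different_motifs_do_not_cooccur(self):
        m = motifs([("M", "chr1", 1000, 1015), ("N", "chr1", 1010, 1025)])
        out = count_motif_features(m, no_fragments())
        assert out["cooccur_count"].tolist() == [0, 0]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(6)
        n = 150
        m = motifs(
            [
                ("M", "chr1", int(s), int(s) + 15)
                for s in rng.integers(0, 20_000, n)
            ]
        )
        out = count_motif_features(m, no_fragments())
        starts = m["start"].to_numpy()
        ends = m["end"].to_numpy()
        expected = np.zeros(n, dtype=int)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                gap = max(starts[j] - ends[i], starts[i] - ends[j])
                if gap <= 100:
                    expected[i] += 1
        np.testing.assert_array_equal(out["cooccur_count"].to_numpy(), expected)


class TestNegativeBinomialFit:
    def test_recovers_simulated_dispersion(self):
        rng = np.random.default_rng(0)
        r_true, mu = 4.0, 10.0
        x = rng.negative_binomial(r_true, r_true / (r_true + mu), size=20_000)
        r, p, pois = fit_negative_binomial(x)
        assert not pois
        assert r == pytest.approx(r_true, rel=0.15)
        assert r * (1 - p) / p == pytest.approx(mu, rel=0.05)  # fitted mean

    def test_poisson_fallback_without_overdispersion(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(10, 0.2, size=5000)  # under-dispersed, mean 2
        with pytest.warns(UserWarning, match="Poisson"):
            r, mu, pois = fit_negative_binomial(x)
        assert pois and mu == pytest.approx(2.0, rel=0.1)
        # under-dispersed counts still yield valid upper-tail p-values
        from chromrisk.chromatin import _upper_tail

        assert _upper_tail(np.array([0]), r, mu, pois)[0] == pytest.approx(1.0)


class TestPredictBound:
    def test_fisher_combination_closed_form(self):
        # two p-values of 0.01 combine to chi2 = -2(ln .01 + ln .01) ~ 18.42 on 4 df
        chi2 = -2 * (np.log(0.01) + np.log(0.01))
        assert chi2 == pytest.approx(18.4207, abs=1e-3)
        assert stats.chi2.sf(chi2, 4) == pytest.approx(0.00102, rel=0.01)

    def test_central_instances_not_called(self):
        rng = np.random.default_rng(2)
        n = 500
        inst = motifs([("M", "chr1", 100 * i, 100 * i + 15) for i in range(n)])
        inst["atac_count"] = rng.negative_binomial(5, 5 / 8, size=n)
        inst["cooccur_count"] = rng.negative_binomial(5, 5 / 6, size=n)
        out = predict_bound(inst)
        med = out["atac_count"].median()
        central = out[(out["atac_count"] == med) & (out["cooccur_count"] == 1)]
        assert len(central) > 0
        assert not central["bound"].any()
        assert (central["p_combined"] > 0.2).all()

    def test_requires_100_instances(self):
        inst = motifs([("M", "chr1", 0, 15)])
        inst["atac_count"] = [3]
        inst["cooccur_count"] = [0]
        with pytest.raises(ValueError):
            predict_bound(inst)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovery_of_high_count_bound_subset(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, frac = 2000, 0.05
        bound = rng.random(n) < frac
        inst = motifs([("M", "chr1", 2000 * i, 2000 * i + 15) for i in range(n)])
        r_null, r_bound = 5.0, 10.0
        inst["atac_count"] = np.where(
            bound,
            rng.negative_binomial(r_bound, r_bound / (r_bound + 30.0), size=n),  # 10x mean
            rng.negative_binomial(r_null, r_null / (r_null + 3.0), size=n),
        )
        inst["cooccur_count"] = np.where(
            bound,
            rng.negative_binomial(r_bound, r_bound / (r_bound + 10.0), size=n),
            rng.negative_binomial(r_null, r_null / (r_null + 1.0), size=n),
        )
        out = predict_bound(inst)
        calls = out["bound"].to_numpy()
        sensitivity = calls[bound].mean()
        fdr_obs = (~bound[calls]).mean() if calls.any() else 0.0
        assert sensitivity >= 0.8
        assert fdr_obs <= 0.10


class TestDeduplicateSites:
    def frame(self, centers, counts):
        df = motifs([("M", "chr1", c - 7, c + 8) for c in centers])
        df["atac_count"] = counts
        return df

    def test_within_500_keeps_higher_count(self):
        out = deduplicate_sites(self.frame([1000, 1400], [5, 9]))
        assert len(out) == 1 and out["atac_count"].iloc[0] == 9

    def test_501_apart_keeps_both(self):
        assert len(deduplicate_sites(self.frame([1000, 1501], [5, 9]))) == 2

    def test_equal_counts_lower_coordinate_kept(self):
        out = deduplicate_sites(self.frame([1400, 1000], [5, 5]))
        assert out["start"].iloc[0] == 993

    def test_all_pairwise_separations_exceed_threshold(self):
        rng = np.random.default_rng(8)
        df = self.frame(rng.integers(0, 100_000, 300), rng.integers(1, 50, 300))
        out = deduplicate_sites(df)
        centers = np.sort((out["start"] + out["end"]) // 2)
        assert (np.diff(centers) > 500).all()


class TestBuildVplot:
    def test_no_fragments_zero_histogram(self):
        sites = motifs([("M", "chr1", 140, 161)])
        vp = build_vplot(sites, no_fragments())
        assert vp.total == 0

    def test_fragment_midpoint_at_center_offset_zero(self):
        sites = motifs([("M", "chr1", 140, 161)])  # center 150
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        vp = build_vplot(sites, frags)
        assert vp.midpoint_histogram[vp.half_window] == 1 and vp.total == 1

    def test_minus_strand_flips_offsets_symmetrically(self):
        sites = motifs([("M", "chr1", 140, 161)])
        sites["strand"] = "+"
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [120], "end": [200]})  # mid 160
        plus = build_vplot(sites, frags)
        sites["strand"] = "-"
        minus = build_vplot(sites, frags)
        assert plus.midpoint_histogram[plus.half_window + 10] == 1
        assert minus.midpoint_histogram[minus.half_window - 10] == 1


class TestFvice:
    def test_uniform_histogram_scores_near_zero(self):
        total = 201 * 500  # exactly uniform, large total
        vp = VPlot("M", np.full(201, 500, dtype=np.int64))
        assert abs(fvice(vp, seed=0)) <= 0.05

    def test_all_adjacent_mass_closed_form(self):
        T = 10_000
        hist = np.zeros(201, dtype=np.int64)
        hist[75:126] = T // 51  # offsets -25..25
        T = hist.sum()
        vp = VPlot("M", hist)
        expected = np.log2((T + 1) / (T * 93 / 201 + 1))
        assert fvice(vp, n_shuffles=400, seed=1) == pytest.approx(expected, abs=0.02)
        assert fvice(vp, seed=1) > 0

    def test_empty_vplot_rejected(self):
        with pytest.raises(ValueError):
            fvice(VPlot("M", np.zeros(201, dtype=np.int64)))

    def test_strand_flip_invariance(self):
        rng = np.random.default_rng(4)
        hist = rng.integers(0, 50, 201)
        assert fvice(VPlot("M", hist), seed=2) == pytest.approx(
            fvice(VPlot("M", hist[::-1].copy()), seed=2), abs=1e-12
        )


class TestNormalizeFvice:
    def records(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        tf = rng.integers(100, 100_000, n)
        return pd.DataFrame(
            {
                "motif_id": [f"M{i}" for i in range(n)],
                "fvice_raw": 2 * np.log10(tf + 1) + rng.normal(0, 0.1, n),
                "total_fragments": tf,
                "total_cooccur": rng.integers(10, 1000, n),
            }
        )

    def test_ols_identities(self):
        out = normalize_fvice(self.records())
        r = out["fvice_norm"].to_numpy()
        assert abs(r.sum()) < 1e-9
        for col in ("total_fragments", "total_cooccur"):
            x = np.log10(out[col].to_numpy() + 1)
            assert abs(np.corrcoef(r, x)[0, 1]) < 1e-7

    def test_depth_confound_removed(self):
        out = normalize_fvice(self.records(seed=3))
        depth = np.log10(out["total_fragments"].to_numpy() + 1)
        assert abs(np.corrcoef(out["fvice_norm"], depth)[0, 1]) < 0.05

    def test_requires_ten_motifs(self):
        with pytest.raises(ValueError):
            normalize_fvice(self.records(n=9))


class TestConditionZscores:
    def test_single_donor_median_equals_z(self):
        df = pd.DataFrame(
            {
                "motif_id": list("ABC"),
                "donor": "d1",
                "celltype": "beta",
                "fvice_norm": [1.0, 2.0, 3.0],
            }
        )
        med, _ = condition_zscores(df)
        np.testing.assert_allclose(med["beta"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_within_condition_distributions_standardized(self):
        rng = np.random.default_rng(9)
        rows = []
        for donor in ("d1", "d2"):
            for ct in ("beta", "alpha"):
                for m in range(30):
                    rows.append((f"M{m}", donor, ct, rng.normal(donor == "d1", 2)))
        df = pd.DataFrame(rows, columns=["motif_id", "donor", "celltype", "fvice_norm"])
        df["z"] = df.groupby(["donor", "celltype"])["fvice_norm"].transform(
            lambda v: (v - v.mean()) / v.std(ddof=1)
        )
        med, row_z = condition_zscores(df)
        for _, g in df.groupby(["donor", "celltype"]):
            assert g["z"].mean() == pytest.approx(0.0, abs=1e-9)
            assert g["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert med.shape == (30, 2) and row_z.shape == (30, 2)

    def test_constant_motif_row_z_is_zero(self):
        df = pd.DataFrame(
            {
                "motif_id": ["A", "B", "C"] * 2,
                "donor": "d1",
                "celltype": ["x"] * 3 + ["y"] * 3,
                "fvice_norm": [1.0, 2.0, 3.0] * 2,
            }
        )
        med, row_z = condition_zscores(df)
        np.testing.assert_allclose(row_z.to_numpy(), 0.0, atol=1e-12)


class TestEndToEndFootprints:
    def test_bound_vs_unbound_fvice_discrimination_and_rank(self):
        cfg = SimulationConfig(seed=21, genome=(("chr1", 5_000_000),))
        rng = np.random.default_rng(5)
        n_motifs, sites_per = 12, 150
        records = []
        bound_fracs = np.linspace(0, 1, n_motifs)
        for mi, bf in enumerate(bound_fracs):
            centers = rng.integers(1000, 4_999_000, sites_per)
            sites = motifs(
                [(f"M{mi}", "chr1", int(c) - 7, int(c) + 8) for c in centers]
            )
            flags = rng.random(sites_per) < bf
            frags, _ = simulate_footprint_fragments(cfg, sites, flags)
            if len(frags) == 0:
                continue
            vp = build_vplot(sites, frags, motif_id=f"M{mi}")
            records.append(
                {
                    "motif_id": f"M{mi}",
                    "bound_frac": bf,
                    "fvice_raw": fvice(vp, seed=3),
                    "total_fragments": len(frags),
                    "total_cooccur": 1,
                }
            )
        rec = pd.DataFrame(records)
        rho = stats.spearmanr(rec["bound_frac"], rec["fvice_raw"]).statistic
        assert rho >= 0.5

    def test_fully_bound_vs_fully_unbound_median_gap(self):
        cfg = SimulationConfig(seed=22, genome=(("chr1", 5_000_000),))
        rng = np.random.default_rng(6)
        scores = {True: [], False: []}
        for mi in range(10):
            all_bound = mi < 5
            centers = rng.integers(1000, 4_999_000, 150)
            sites = motifs(
                [(f"M{mi}", "chr1", int(c) - 7, int(c) + 8) for c in centers]
            )
            flags = np.full(150, all_bound)
            frags, _ = simulate_footprint_fragments(cfg, sites, flags)
            vp = build_vplot(sites, frags, motif_id=f"M{mi}")
            scores[all_bound].append(fvice(vp, seed=3))
        gap = np.median(scores[True]) - np.median(scores[False])
        assert gap >= 1.0
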