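import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from riboneutral import (
    DesignLibrary,
    FitError,
    InputError,
    NoiseModel,
    ScreenCounts,
    activity_scores,
    activity_threshold,
    active_fraction_curve,
    binomial_pvalue,
    estimate_L50_Lmax,
    fit_noise_model,
    map_reads,
)


@pytest.fixture()
def library():
    return DesignLibrary(
        designs={"d1": "ACGUACGUACGU", "d2": "GGGGCCCCAAAA"},
        s2_tag="UUUCCC",
    )


class TestMapReads:
    def test_full_design_plus_tag_counts_both(self, library):
        read = "ACGUACGUACGU" + "UUUCCC"
        counts = map_reads([read], library).counts
        assert counts.loc["d1", "count_ref"] == 1
        assert counts.loc["d1", "count_sel"] == 1

    def test_half_coverage_not_counted(self, library):
        counts = map_reads(["ACGUAC"], library, min_cov=0.7).counts
        assert counts["count_ref"].sum() == 0

    def test_untagged_read_counts_pre_only(self, library):
        read = "ACGUACGUACGU" + "GGAAGG"  # exon-like tail, not S2
        counts = map_reads([read], library).counts
        assert counts.loc["d1", "count_ref"] == 1
        assert counts.loc["d1", "count_sel"] == 0

    def test_tag_must_follow_three_prime_end(self, library):
        # S2 stuck mid-design does not make the read substrate-tagged
        read = "UUUCCC" + "ACGUACGUACGU"
        counts = map_reads([read], library).counts
        assert counts.loc["d1", "count_sel"] == 0

    def test_ambiguous_read_dropped(self):
        lib = DesignLibrary(designs={"a": "ACGUACGUAC", "b": "ACGUACGUAG"},
                            s2_tag="UUU")
        # contains >= 70% stretches of both designs
        counts = map_reads(["ACGUACGUA"], lib).counts
        assert counts["count_ref"].sum() == 0

    def test_empty_library_rejected(self):
        with pytest.raises(InputError):
            DesignLibrary(designs={}, s2_tag="UUU")


def make_counts(rows):
    df = pd.DataFrame(rows).set_index("design_id")
    return ScreenCounts(counts=df)


class TestActivityScores:
    def test_reference_scores_zero_and_proportionality(self):
        counts = make_counts([
            {"design_id": "ref", "count_ref": 100, "count_sel": 200},
            {"design_id": "x", "count_ref": 100, "count_sel": 200},
            {"design_id": "y", "count_ref": 100, "count_sel": 20},
        ])
        t = activity_scores(counts, ref_id="ref")
        assert t.loc["ref", "act"] == pytest.approx(0.0)
        assert t.loc["x", "act"] == pytest.approx(0.0)
        assert t.loc["y", "act"] == pytest.approx(-1.0)

    def test_depth_rescaling_invariance(self):
        rows = [
            {"design_id": "ref", "count_ref": 50, "count_sel": 500},
            {"design_id": "x", "count_ref": 80, "count_sel": 40},
        ]
        t1 = activity_scores(make_counts(rows), ref_id="ref")
        rows2 = [dict(r, count_sel=r["count_sel"] * 7) for r in rows]
        t2 = activity_scores(make_counts(rows2), ref_id="ref")
        assert t1.loc["x", "act"] == pytest.approx(t2.loc["x", "act"])

    def test_low_coverage_excluded_and_zero_sel_inactive(self):
        counts = make_counts([
            {"design_id": "ref", "count_ref": 100, "count_sel": 100},
            {"design_id": "shallow", "count_ref": 4, "count_sel": 10},
            {"design_id": "dead", "count_ref": 50, "count_sel": 0},
        ])
        t = activity_scores(counts, ref_id="ref")
        assert bool(t.loc["shallow", "excluded"])
        assert bool(t.loc["dead", "inactive"])
        assert np.isnan(t.loc["dead", "act"])

    def test_missing_reference_is_error(self):
        counts = make_counts([
            {"design_id": "x", "count_ref": 10, "count_sel": 10},
        ])
        with pytest.raises(InputError):
            activity_scores(counts, ref_id="ref")

    def test_threshold_score_percent_meaning(self):
        # an activity of -2.76 corresponds to 0.17% of the reference
        assert 100 * 10 ** (-2.76) == pytest.approx(0.17, abs=0.005)


class TestNoiseModel:
    def _table(self, scores, distance=150):
        n = len(scores)
        return pd.DataFrame({
            "act": scores,
            "distance": [distance] * n,
            "excluded": [False] * n,
            "inactive": [False] * n,
        })

    def test_recovers_planted_gaussian(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(-4.0, 0.5, size=500)
        noise = fit_noise_model(self._table(scores))
        assert abs(noise.mu + 4.0) < 0.07   # 3 sigma of the mean estimator
        assert abs(noise.sigma - 0.5) < 0.05

    def test_two_point_symmetric_mean(self):
        noise = fit_noise_model(self._table([-3.0, -5.0] * 20))
        assert noise.mu == pytest.approx(-4.0)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(FitError):
            fit_noise_model(self._table([-3.0] * 100))

    def test_too_few_scores_rejected(self):
        with pytest.raises(FitError):
            fit_noise_model(self._table([-3.0, -4.0]))

    def test_near_designs_not_used(self):
        t = pd.concat([
            self._table([-4.0, -4.5, -3.5] * 20, distance=150),
            self._table([0.0] * 50, distance=5),
        ])
        noise = fit_noise_model(t)
        assert noise.mu < -3.0


class TestThreshold:
    def test_standard_normal_quantile(self):
        thr = activity_threshold(NoiseModel(mu=0.0, sigma=1.0, n_fit=100), 1e-3)
        assert round(thr.z, 2) == 3.09

    def test_linearity_in_mu_sigma(self):
        thr = activity_threshold(NoiseModel(mu=1.0, sigma=2.0, n_fit=100), 1e-3)
        assert thr.threshold == pytest.approx(1 + 2 * 3.0902, abs=1e-3)

    def test_invalid_p(self):
        with pytest.raises(InputError):
            activity_threshold(NoiseModel(0, 1, 10), 0.7)


class TestBinomialPvalue:
    def test_zero_successes_is_one(self):
        assert binomial_pvalue(100, 0, 0.001) == 1.0

    def test_validation_pool_significance(self):
        p = binomial_pvalue(991, 22, 1e-3)
        assert p <= 1e-21
        # frozen from the exact rational summation (scipy sf cross-checks below)
        assert p == pytest.approx(2.2830516e-22, rel=1e-6)

    def test_small_bin(self):
        assert binomial_pvalue(150, 3, 1e-3) == pytest.approx(4.9e-4, rel=0.05)

    @pytest.mark.parametrize("N,n,pi", [(50, 5, 0.01), (991, 22, 1e-3),
                                        (20, 18, 0.5), (150, 3, 1e-3)])
    def test_matches_scipy_tail(self, N, n, pi):
        assert binomial_pvalue(N, n, pi) == pytest.approx(
            float(sps.binom.sf(n - 1, N, pi)), rel=1e-9
        )


class TestActiveFractionCurve:
    def _table(self):
        rows = []
        for k in range(10):  # bin (0,5]: all well above threshold
            rows.append({"act": 0.0, "distance": 3, "excluded": False,
                         "inactive": False})
        for k in range(10):  # bin (5,10]: straddles the threshold within 0.3
            rows.append({"act": -2.9 + 0.04 * k, "distance": 8,
                         "excluded": False, "inactive": False})
        for k in range(10):  # bin (10,15]: inactive-flagged
            rows.append({"act": np.nan, "distance": 13, "excluded": False,
                         "inactive": True})
        rows.append({"act": 5.0, "distance": 13, "excluded": True,
                     "inactive": False})
        return pd.DataFrame(rows)

    def test_band_and_flags(self):
        bins = active_fraction_curve(self._table(), threshold=-2.76)
        b1, b2, b3 = bins.iloc[0], bins.iloc[1], bins.iloc[2]
        assert b1["fraction"] == b1["upper"] == b1["lower"] == 1.0
        assert b2["lower"] < b2["fraction"] < b2["upper"]
        assert b3["N"] == 10 and b3["fraction"] == 0.0  # excluded left out

    def test_empty_bins_reported(self):
        t = pd.DataFrame([{"act": 0.0, "distance": 12, "excluded": False,
                           "inactive": False}])
        bins = active_fraction_curve(t, threshold=-1.0)
        assert bins.iloc[0]["N"] == 0 and np.isnan(bins.iloc[0]["fraction"])


class TestL50Lmax:
    def _bins(self, rows):
        df = pd.DataFrame(rows)
        df["pvalue"] = [
            binomial_pvalue(int(r.N), int(r.n), 1e-3) for r in df.itertuples()
        ]
        return df

    def test_staircase(self):
        bins = self._bins([
            {"lo": 0, "hi": 5, "N": 150, "n": 150, "fraction": 1.0},
            {"lo": 5, "hi": 10, "N": 150, "n": 150, "fraction": 1.0},
            {"lo": 10, "hi": 15, "N": 150, "n": 150, "fraction": 1.0},
            {"lo": 15, "hi": 20, "N": 150, "n": 150, "fraction": 1.0},
            {"lo": 20, "hi": 25, "N": 150, "n": 0, "fraction": 0.0},
        ])
        s = estimate_L50_Lmax(bins)
        assert s.L50 == 20 and s.Lmax == 20

    def test_one_hit_fails_both_criteria(self):
        bins = self._bins([
            {"lo": 0, "hi": 5, "N": 150, "n": 1, "fraction": 1 / 150},
        ])
        s = estimate_L50_Lmax(bins)
        assert s.L50 is None and s.Lmax is None

    def test_three_hits_meet_lmax(self):
        bins = self._bins([
            {"lo": 0, "hi": 5, "N": 150, "n": 3, "fraction": 0.02},
        ])
        s = estimate_L50_Lmax(bins)
        assert s.Lmax == 5 and s.L50 is None

    def test_empty_input(self):
        s = estimate_L50_Lmax(pd.DataFrame(columns=["lo", "hi", "N", "n",
                                                    "fraction", "pvalue"]))
        assert s.L50 is None and s.Lmax is None
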