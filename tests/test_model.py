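"""Logistic occurrence model: threshold extraction, uncertainty and skill."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from firethresh import (
    FireOccurrenceModel,
    NonIncreasingResponseError,
    PlantedFireLaw,
    UnfittableError,
    fit_all_strata,
    generate_occurrence_samples,
    roc_auc,
    threshold_uncertainty,
    vpd_p50,
)


def brute_force_auc(y, scores):
    """O(n^2) Mann-Whitney pair fraction: the AUC oracle, ties count half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestVpdP50:
    @pytest.mark.parametrize("b0, b1, expected", [(-5.0, 2.0, 2.5), (0.0, 3.0, 0.0)])
    def test_analytic_inversion(self, b0, b1, expected):
        assert vpd_p50(b0, b1) == expected

    def test_probability_at_threshold_is_half(self):
        b0, b1 = -3.7, 1.9
        assert expit(b0 + b1 * vpd_p50(b0, b1)) == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize("b1", [0.0, -1.0])
    def test_nonincreasing_response_rejected(self, b1):
        with pytest.raises(NonIncreasingResponseError):
            vpd_p50(-5.0, b1)


class TestThresholdUncertainty:
    def test_zero_covariance_degenerates_to_point(self):
        se, ci = threshold_uncertainty(-5.0, 2.0, np.zeros((2, 2)))
        assert se == 0.0
        assert ci == (2.5, 2.5)

    def test_nonfinite_covariance_flagged_not_raised(self):
        se, ci = threshold_uncertainty(-5.0, 2.0, np.full((2, 2), np.inf))
        assert np.isnan(se) and np.isnan(ci[0])

    def test_delta_method_matches_bootstrap(self):
        law = PlantedFireLaw(-5.0, 2.0)
        df = generate_occurrence_samples(law, 2000, seed=8)
        res = FireOccurrenceModel.from_dataframe(df).fit()
        rng = np.random.default_rng(17)
        boots = []
        for _ in range(500):
            idx = rng.integers(0, len(df), len(df))
            b = FireOccurrenceModel.from_dataframe(df.iloc[idx]).fit()
            boots.append(b.vpd_p50)
        assert res.se_p50 == pytest.approx(np.std(boots, ddof=1), rel=0.10)

    def test_large_n_ci_narrower_than_hundredth_kpa(self):
        # at n = 1e6 the +/-2 SE interval collapses below 0.01 kPa half-width
        law = PlantedFireLaw(-5.0, 2.0)
        df = generate_occurrence_samples(law, 1_000_000, seed=4)
        res = FireOccurrenceModel.from_dataframe(df).fit()
        assert (res.ci_p50[1] - res.ci_p50[0]) / 2 < 0.01
        assert res.ci_p50[0] < 2.5 < res.ci_p50[1]


class TestFit:
    def test_symmetric_separated_toy_crosses_at_midpoint(self):
        df = pd.DataFrame(
            {
                "vpd_kpa": [1.0] * 50 + [3.0] * 50,
                "burned": [0] * 50 + [1] * 50,
                "year": 2003,
                "stratum": "s0",
            }
        )
        res = FireOccurrenceModel.from_dataframe(df).fit()
        assert res.separated
        assert res.vpd_p50 == 2.0
        assert res.auc == 1.0

    def test_parameter_recovery_within_3se(self):
        law = PlantedFireLaw(-5.0, 2.0)
        df = generate_occurrence_samples(law, 10_000, seed=1)
        res = FireOccurrenceModel.from_dataframe(df).fit()
        assert res.converged
        assert abs(res.beta0 - (-5.0)) < 3 * res.bse[0]
        assert abs(res.beta1 - 2.0) < 3 * res.bse[1]

    def test_fit_is_likelihood_optimum(self):
        law = PlantedFireLaw(-5.0, 2.0)
        df = generate_occurrence_samples(law, 5000, seed=2)
        res = FireOccurrenceModel.from_dataframe(df).fit()

        def loglik(b0, b1):
            p = np.clip(expit(b0 + b1 * df["vpd_kpa"].values), 1e-12, 1 - 1e-12)
            y = df["burned"].values
            return np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        best = loglik(res.beta0, res.beta1)
        for db0 in (-0.1, 0.1):
            for db1 in (-0.1, 0.1):
                assert best >= loglik(res.beta0 + db0, res.beta1 + db1)

    def test_single_label_input_unfittable(self):
        df = pd.DataFrame(
            {"vpd_kpa": [1.0, 2.0, 3.0], "burned": [1, 1, 1], "year": 2003, "stratum": "s0"}
        )
        with pytest.raises(UnfittableError):
            FireOccurrenceModel.from_dataframe(df).fit()

    def test_predicted_probability_at_threshold_is_half(self):
        df = generate_occurrence_samples(PlantedFireLaw(-4.0, 1.6), 5000, seed=3)
        res = FireOccurrenceModel.from_dataframe(df).fit()
        assert float(res.predict(res.vpd_p50)) == pytest.approx(0.5, abs=1e-12)


class TestRocAuc:
    def test_matches_brute_force_with_ties(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]  # ensure both classes
        scores = np.round(rng.uniform(0, 4, 200), 1)  # rounding forces ties
        assert roc_auc(y, scores) == pytest.approx(brute_force_auc(y, scores), abs=1e-12)

    def test_perfect_separation_gives_one(self):
        y = np.array([0] * 5 + [1] * 5)
        assert roc_auc(y, np.arange(10.0)) == 1.0

    def test_independent_labels_near_half(self, rng):
        y = rng.integers(0, 2, 20_000)
        scores = rng.normal(size=20_000)
        assert roc_auc(y, scores) == pytest.approx(0.5, abs=0.02)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        s = rng.uniform(0.1, 5, 300)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, np.log(s)), abs=1e-12)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, expit(3 * s - 2)), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.ones(5), np.arange(5.0))


class TestFitAllStrata:
    def test_planted_thresholds_recovered_within_ci(self):
        frames = []
        for sid, theta in [("s_a", 1.3), ("s_b", 2.3), ("s_c", 2.7)]:
            law = PlantedFireLaw(-3.0 * theta, 3.0)
            frames.append(
                generate_occurrence_samples(law, 6000, seed=hashint(sid), stratum=sid)
            )
        samples = pd.concat(frames, ignore_index=True)
        table, medians, unfittable = fit_all_strata(samples)
        assert not unfittable
        for sid, theta in [("s_a", 1.3), ("s_b", 2.3), ("s_c", 2.7)]:
            row = table[table["stratum"] == sid].iloc[0]
            assert abs(row["vpd_p50"] - theta) < 3 * row["se"]
            assert row["ci_lo"] < row["vpd_p50"] < row["ci_hi"]

    def test_identical_data_gives_identical_models(self):
        df = generate_occurrence_samples(PlantedFireLaw(-5, 2), 2000, seed=5)
        both = pd.concat(
            [df.assign(stratum="x"), df.assign(stratum="y")], ignore_index=True
        )
        table, _, _ = fit_all_strata(both)
        a, b = table.set_index("stratum").loc["x"], table.set_index("stratum").loc["y"]
        assert a["vpd_p50"] == b["vpd_p50"] and a["auc"] == b["auc"]

    def test_median_over_identically_planted_strata(self):
        law = PlantedFireLaw(-5.0, 2.0)
        frames = [
            generate_occurrence_samples(law, 4000, seed=100 + k, stratum=f"s{k}")
            for k in range(5)
        ]
        table, medians, _ = fit_all_strata(pd.concat(frames, ignore_index=True))
        mc_se = table["se"].median() / np.sqrt(5)
        assert medians["overall"] == pytest.approx(2.5, abs=max(3 * mc_se, 3 * table["se"].max()))

    def test_unfittable_stratum_listed_not_dropped_silently(self):
        good = generate_occurrence_samples(PlantedFireLaw(-5, 2), 1000, seed=6, stratum="ok")
        bad = pd.DataFrame(
            {"vpd_kpa": [1.0, 2.0], "burned": [1, 1], "year": 2003, "stratum": "allfire"}
        )
        table, _, unfittable = fit_all_strata(pd.concat([good, bad], ignore_index=True))
        assert unfittable == ["allfire"]
        assert list(table["stratum"]) == ["ok"]

    def test_biome_group_medians(self):
        frames = []
        for k in range(3):
            frames.append(
                generate_occurrence_samples(
                    PlantedFireLaw(-5, 2), 3000, seed=200 + k, stratum=f"t{k}"
                )
            )
        samples = pd.concat(frames, ignore_index=True)
        groups = {f"t{k}": "tropical" for k in range(3)}
        _, medians, _ = fit_all_strata(samples, biome_groups=groups)
        assert "tropical" in medians and "tropical_tpr" in medians
        assert medians["tropical"] == pytest.approx(medians["overall"])


def hashint(s: str) -> int:
    return sum(ord(c) for c in s)
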