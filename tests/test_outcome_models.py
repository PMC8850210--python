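"""Model battery: c-statistics, DeLong, AIC, logistic and ordinal fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

from fivmap import outcome_models as om
from fivmap.synthetic import CohortConfig, draw_covariates, simulate_outcomes

from oracles import pairwise_auc, pairwise_ordinal_concordance


def _labels_scores(draw_n=12):
    scores = st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=4, max_size=draw_n
    )
    return scores


class TestCStatisticBinary:
    def test_perfect_separation(self):
        assert om.c_statistic_binary([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert om.c_statistic_binary([1.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    @given(_labels_scores(), st.data())
    def test_matches_pair_oracle(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        ours = om.c_statistic_binary(scores, labels)
        assert ours == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        labels[0], labels[1] = 0, 1
        assert om.c_statistic_binary(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            om.c_statistic_binary([1, 2, 3], [1, 1, 1])


class TestCStatisticOrdinal:
    def test_reduces_to_binary_at_two_levels(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        assert om.c_statistic_ordinal(scores, labels) == pytest.approx(
            om.c_statistic_binary(scores, labels), abs=1e-14
        )

    def test_strictly_monotone_scores_give_one(self):
        labels = [0, 1, 2, 3, 4, 5, 6]
        scores = [10 * l for l in labels]
        assert om.c_statistic_ordinal(scores, labels) == 1.0

    @given(_labels_scores(), st.data())
    def test_matches_discordant_pair_oracle(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 4), min_size=len(scores), max_size=len(scores))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 4
        ours = om.c_statistic_ordinal(scores, labels)
        assert ours == pytest.approx(pairwise_ordinal_concordance(scores, labels), abs=1e-12)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            om.c_statistic_ordinal([1.0, 2.0], [3, 3])


class TestDeLong:
    def test_identical_scores_degenerate(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        res = om.delong_compare(scores, scores, labels)
        assert res["z"] == 0.0 and res["p"] == 1.0 and res["degenerate"]

    def test_argument_swap_negates_z(self, rng):
        a, b = rng.normal(size=80), rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        ab = om.delong_compare(a, b, labels)
        ba = om.delong_compare(b, a, labels)
        assert ab["z"] == pytest.approx(-ba["z"], abs=1e-12)
        assert ab["p"] == pytest.approx(ba["p"], abs=1e-12)

    def test_auc_matches_c_statistic(self, rng):
        a, b = rng.normal(size=80), rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        res = om.delong_compare(a, b, labels)
        assert res["auc_a"] == pytest.approx(om.c_statistic_binary(a, labels), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            om.delong_compare([1, 2], [1, 2, 3], [0, 1, 1])


@pytest.mark.parametrize("loglik,k,expected", [(0.0, 0, 0.0), (-148.0, 2, 300.0)])
def test_aic_closed_form(loglik, k, expected):
    assert om.aic(loglik, k) == expected


def _synthetic_cohort(n, config, rng, with_effect=True):
    """Parametric cohort (no image pipeline): volumes + covariates + outcomes."""
    fiv_high = np.exp(rng.normal(3.0, 0.9, n))
    fiv_mod = np.where(rng.random(n) < 0.4, np.exp(rng.normal(2.5, 1.0, n)), 0.0)
    fiv_low = np.where(rng.random(n) < 0.1, np.exp(rng.normal(2.0, 1.0, n)), 0.0)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "fiv_high": fiv_high,
            "fiv_mod": fiv_mod,
            "fiv_low": fiv_low,
        }
    )
    df["fiv_total"] = df[["fiv_high", "fiv_mod", "fiv_low"]].sum(axis=1)
    df = pd.concat([df, draw_covariates(n, config, rng)], axis=1)
    return simulate_outcomes(df, config, rng=rng)


def _plain_config(**kw):
    """Generator config with no covariate effects (correctly specified volume model)."""
    return CohortConfig(gamma={}, **kw)


class TestFitLogistic:
    def test_intercept_only_recovers_prevalence(self, rng):
        cfg = _plain_config(beta_high=0.0)
        cohort = _synthetic_cohort(300, cfg, rng)
        spec = om.ModelSpec("favorable_binary", ())
        res = om.fit_logistic(cohort, spec)
        import scipy.special

        prevalence = om.favorable(cohort["mrs_90d"]).mean()
        assert scipy.special.expit(res.estimates["const"].beta) == pytest.approx(
            prevalence, abs=1e-6
        )

    def test_recovers_generating_coefficient_at_large_n(self, rng):
        cfg = _plain_config(beta_high=-0.05)
        cohort = _synthetic_cohort(5000, cfg, rng)
        res = om.fit_logistic(cohort, om.ModelSpec("favorable_binary", ("fiv_high",)))
        assert res.estimate("fiv_high").beta == pytest.approx(-0.05, abs=0.005)

    def test_or_reporting_identity(self, rng):
        cfg = _plain_config()
        cohort = _synthetic_cohort(400, cfg, rng)
        res = om.fit_logistic(
            cohort, om.ModelSpec("favorable_binary", ("fiv_high", "fiv_mod", "fiv_low"))
        )
        for pred in res.spec.predictors:
            e = res.estimate(pred)
            assert e.or_per_10mL == pytest.approx(np.exp(10 * e.beta), rel=1e-12)
            assert e.or_ci95_low <= e.or_per_10mL <= e.or_ci95_high

    def test_scale_convention_beta_to_or(self):
        # a per-mL coefficient of ln(0.83)/10 reports as OR 0.83 per 10 mL
        beta = np.log(0.83) / 10
        assert np.exp(10 * beta) == pytest.approx(0.83, abs=1e-12)

    def test_single_class_outcome_rejected(self, rng):
        cfg = _plain_config()
        cohort = _synthetic_cohort(100, cfg, rng)
        cohort["mrs_90d"] = 6
        with pytest.raises(ValueError):
            om.fit_logistic(cohort, om.ModelSpec("favorable_binary", ("fiv_high",)))

    def test_too_few_cases_rejected(self, rng):
        cfg = _plain_config()
        cohort = _synthetic_cohort(10, cfg, rng)
        with pytest.raises(ValueError, match="20"):
            om.fit_logistic(cohort, om.ModelSpec("favorable_binary", ("fiv_high",)))


class TestFitOrdinal:
    def test_two_level_outcome_collapses_to_binary_fit(self, rng):
        cfg = _plain_config()
        cohort = _synthetic_cohort(400, cfg, rng)
        # force a two-level outcome straddling the favorable cut
        cohort["mrs_90d"] = np.where(om.favorable(cohort["mrs_90d"]) == 1, 2, 5)
        ordinal = om.fit_ordinal(cohort, om.ModelSpec("mrs_ordinal", ("fiv_high",)))
        binary = om.fit_logistic(cohort, om.ModelSpec("favorable_binary", ("fiv_high",)))
        assert ordinal.estimate("fiv_high").beta == pytest.approx(
            binary.estimate("fiv_high").beta, abs=1e-5
        )

    def test_constant_outcome_rejected(self, rng):
        cfg = _plain_config()
        cohort = _synthetic_cohort(50, cfg, rng)
        cohort["mrs_90d"] = 4
        with pytest.raises(ValueError):
            om.fit_ordinal(cohort, om.ModelSpec("mrs_ordinal", ("fiv_high",)))

    def test_ordinal_beta_direction_matches_binary(self, rng):
        """Harmful volumes get negative favorable-direction beta in both models."""
        cfg = _plain_config(beta_high=-0.05)
        cohort = _synthetic_cohort(1500, cfg, rng)
        ordinal = om.fit_ordinal(cohort, om.ModelSpec("mrs_ordinal", ("fiv_high",)))
        assert ordinal.estimate("fiv_high").beta < 0
        assert ordinal.estimate("fiv_high").beta == pytest.approx(-0.05, abs=0.01)


def test_model_spec_rejects_total_with_subvolumes():
    with pytest.raises(ValueError, match="collinear"):
        om.ModelSpec("favorable_binary", ("fiv_total", "fiv_high"))


def test_roster_has_ten_models():
    assert len(om.MODEL_ROSTER) == 10
    assert sum(s.outcome == "favorable_binary" for s in om.MODEL_ROSTER) == 5


def test_aic_prefers_generating_model(rng):
    """On data generated from the high-relevance volume, the volume model has
    lower AIC than a pure-noise predictor model."""
    cfg = _plain_config(beta_high=-0.05)
    cohort = _synthetic_cohort(2000, cfg, rng)
    good = om.fit_logistic(cohort, om.ModelSpec("favorable_binary", ("fiv_high",)))
    cohort_noise = cohort.copy()
    cohort_noise["fiv_low"] = rng.normal(50, 10, len(cohort))  # noise predictor
    noise = om.fit_logistic(cohort_noise, om.ModelSpec("favorable_binary", ("fiv_low",)))
    assert good.aic < noise.aic
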