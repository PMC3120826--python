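"""Simulated observers, logistic fits, exact binomial and normality tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from moonwalk import (
    ExperimentDesign,
    GatingPsychometricModel,
    PsychometricModel,
    SeparationError,
    StimulusSpec,
    binomial_proportions_test,
    fit_logistic,
    residual_normality_chisq,
    run_experiment_2,
    simulate_responses,
)


def _table_from_counts(levels, ks, n):
    rows = []
    for c, k in zip(levels, ks):
        rows += [("far", c)] * int(k) + [("near", c)] * int(n - k)
    return pd.DataFrame(rows, columns=["report", "coherence_pct"])


class TestSimulation:
    def test_deterministic_given_seed(self):
        design = ExperimentDesign(n_subjects=2, n_trials_per_condition=5)
        a = simulate_responses(PsychometricModel(), design, seed=3)
        b = simulate_responses(PsychometricModel(), design, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_saturated_model_reports_all_far(self):
        model = PsychometricModel(beta0=1e3, beta1=0.0, lapse_rate=0.0)
        design = ExperimentDesign(n_subjects=2, n_trials_per_condition=10,
                                  subject_intercept_sd=0.0)
        df = simulate_responses(model, design, seed=0)
        assert (df["report"] == "far").all()

    def test_balanced_model_near_half(self):
        model = PsychometricModel(beta0=0.0, beta1=0.0, lapse_rate=0.0)
        design = ExperimentDesign(
            coherences_pct=(75.0,), n_subjects=1,
            n_trials_per_condition=4000, subject_intercept_sd=0.0,
        )
        df = simulate_responses(model, design, seed=1)
        p = (df["report"] == "far").mean()
        assert p == pytest.approx(0.5, abs=2 * 0.5 / np.sqrt(4000))

    def test_proportions_converge_to_model(self):
        model = PsychometricModel(beta0=-20.0, beta1=0.25, lapse_rate=0.02)
        design = ExperimentDesign(
            coherences_pct=(60.0, 80.0, 100.0), n_subjects=1,
            n_trials_per_condition=10_000, subject_intercept_sd=0.0,
        )
        df = simulate_responses(model, design, seed=2)
        for c in design.coherences_pct:
            p_true = float(model.p_far(c))
            sub = df[df["coherence_pct"] == c]
            p_hat = (sub["report"] == "far").mean()
            se = np.sqrt(p_true * (1 - p_true) / len(sub))
            # 3 SE: three levels are checked jointly
            assert abs(p_hat - p_true) <= 3 * se + 1e-9


class TestLogisticFit:
    def test_recovers_known_parameters(self):
        rng = np.random.default_rng(5)
        levels = np.linspace(50, 100, 7)
        b0, b1 = -20.0, 0.25
        p = 1 / (1 + np.exp(-(b0 + b1 * levels)))
        df = _table_from_counts(levels, rng.binomial(400, p), 400)
        fit = fit_logistic(df)
        assert fit.converged
        assert fit.beta0 == pytest.approx(b0, abs=3 * fit.se_beta0)
        assert fit.beta1 == pytest.approx(b1, abs=3 * fit.se_beta1)
        assert np.all((fit.fitted["p_fit"] > 0) & (fit.fitted["p_fit"] < 1))

    def test_wald_coverage_over_replicates(self):
        # 95% intervals should cover the truth in [90%, 98%] of 200 fits
        rng = np.random.default_rng(7)
        levels = np.linspace(50, 100, 7)
        b0, b1 = -20.0, 0.25
        p = 1 / (1 + np.exp(-(b0 + b1 * levels)))
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            df = _table_from_counts(levels, rng.binomial(100, p), 100)
            fit = fit_logistic(df)
            lo, hi = fit.wald_interval(1)
            cover += lo <= b1 <= hi
        assert 0.90 <= cover / n_rep <= 0.98

    def test_balanced_responses_give_zero_slope(self):
        df = _table_from_counts([50, 70, 90], [50, 50, 50], 100)
        fit = fit_logistic(df)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_data_raise(self):
        with pytest.raises(SeparationError):
            fit_logistic(_table_from_counts([70.0], [30], 60))  # one level
        with pytest.raises(SeparationError):
            fit_logistic(_table_from_counts([50, 100], [60, 60], 60))  # all far


class TestBinomialTest:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(1, 1, 1.0), (20, 20, 2 * 0.5**20), (0, 20, 2 * 0.5**20)],
    )
    def test_exact_values(self, k, n, expected):
        assert binomial_proportions_test(k, n, 0.5) == pytest.approx(
            expected, rel=1e-12
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=1, max_value=60), st.data())
    def test_symmetric_at_half(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        p1 = binomial_proportions_test(k, n, 0.5)
        p2 = binomial_proportions_test(n - k, n, 0.5)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_type_one_error_by_enumeration(self):
        # exact-test conservatism at n = 20, alpha = 0.05
        n, alpha = 20, 0.05
        rate = sum(
            stats.binom.pmf(k, n, 0.5)
            for k in range(n + 1)
            if binomial_proportions_test(k, n, 0.5) <= alpha
        )
        assert rate <= alpha

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_proportions_test(5, 4)
        with pytest.raises(ValueError):
            binomial_proportions_test(1, 4, 0.0)


class TestResidualNormality:
    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        rejected = sum(
            residual_normality_chisq(rng.normal(size=10_000)) < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejected / 1000 <= 0.08

    def test_bimodal_residuals_rejected(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-3, 1, 500), rng.normal(3, 1, 500)])
        assert residual_normality_chisq(x) < 0.01

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            residual_normality_chisq(np.arange(10.0))


@pytest.fixture(scope="module")
def table():
    base = StimulusSpec(
        frame_size_px=(96, 96), stimulus_diameter_deg=3.0, duration_s=0.8
    )
    return run_experiment_2(seed=5, base_spec=base)


class TestExperiment2:
    def test_ideal_observer_far_in_all_conditions(self, table):
        assert (table["ideal_observer"] == "F").all()

    def test_static_conditions_report_far(self, table):
        static = table[table["coherence_pct"] == 100.0]
        assert (static["p_far"] > 0.5).all()

    def test_flicker_without_segmentation_reverses(self, table):
        row = table.query("condition == 'none' and coherence_pct == 50.0")
        assert float(row["p_far"].iloc[0]) < 0.5

    def test_segmentation_cue_restores_far_percept(self, table):
        gated = table.query("condition != 'none' and coherence_pct == 50.0")
        assert (gated["p_far"] > 0.5).all()

    def test_reruns_identical(self, table):
        base = StimulusSpec(
            frame_size_px=(96, 96), stimulus_diameter_deg=3.0, duration_s=0.8
        )
        again = run_experiment_2(seed=5, base_spec=base)
        pd.testing.assert_frame_equal(table, again)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            run_experiment_2(
                seed=0,
                base_spec=StimulusSpec(
                    frame_size_px=(96, 96), stimulus_diameter_deg=3.0, duration_s=0.4
                ),
                design=ExperimentDesign(contrast_conditions=("sideways",)),
            )

    def test_gating_model_probabilities(self):
        m = GatingPsychometricModel(beta0=-20, beta1=0.25, lapse_rate=0.0,
                                    segmentation_boost=15.0)
        assert float(m.p_far(50.0, segmented=False)) < 0.01
        assert float(m.p_far(50.0, segmented=True)) > 0.99
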