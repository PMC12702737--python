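"""Response-surface regression: design, recovery, bootstrap, mediation, CV."""

import numpy as np
import pandas as pd
import pytest

from neuroaffect import (
    AffectRegressionModel,
    EstimationError,
    GenerativeConfig,
    InputError,
    build_design_matrix,
    compare_models,
    generate_cohort,
    mediation_indirect,
)
from neuroaffect.synthetic import COEFFICIENT_NAMES


def cohort_from_arrays(theta, gamma, shift, outcome, name="delta_negative"):
    frame = pd.DataFrame({"theta_change": theta, "gamma_change": gamma,
                          "affective_shift": shift})
    frame[name] = outcome
    return frame


@pytest.fixture(scope="module")
def unit_scale_config():
    """Well-conditioned generative truth with all predictors ~O(1)."""
    return GenerativeConfig(
        n_participants=200,
        coef_negative=(0.5, -1.2, 0.8, -2.0, 0.3, 1.1, -0.7),
        coef_positive=(1.0, 0.4, -0.9, 1.5, -0.2, 0.6, 0.25),
        theta_mean=0.2, theta_sd=1.0, gamma_mean=-0.1, gamma_sd=0.8,
        shift_mean=0.5, shift_sd=1.2,
        noise_sd_positive=0.0, noise_sd_negative=0.0, seed=7,
    )


class TestDesignMatrix:
    def test_row_arithmetic(self):
        frame = cohort_from_arrays([2.0], [3.0], [4.0], [0.0])
        row = build_design_matrix(frame).values[0]
        assert np.array_equal(row, [1, 2, 3, 4, 8, 9, 16])

    def test_all_zero_predictors(self):
        row = build_design_matrix(cohort_from_arrays([0.0], [0.0], [0.0],
                                                     [0.0])).values[0]
        assert np.array_equal(row, [1, 0, 0, 0, 0, 0, 0])

    def test_duplicate_rows_preserved(self, ref_cohort_frame):
        doubled = pd.concat([ref_cohort_frame, ref_cohort_frame],
                            ignore_index=True)
        design = build_design_matrix(doubled)
        assert len(design.frame) == 2 * len(ref_cohort_frame)

    def test_missing_columns_listed(self):
        frame = pd.DataFrame({"theta_change": [1.0, 2.0]})
        with pytest.raises(InputError) as err:
            build_design_matrix(frame)
        assert "gamma_change" in str(err.value)
        assert "affective_shift" in str(err.value)


class TestFit:
    def test_exact_recovery_well_conditioned(self, unit_scale_config):
        frame = generate_cohort(unit_scale_config).to_frame()
        for outcome, truth in [("delta_negative", unit_scale_config.coef_negative),
                               ("delta_positive", unit_scale_config.coef_positive)]:
            res = AffectRegressionModel(frame, outcome=outcome).fit()
            assert np.allclose(res.params.to_numpy(), truth, rtol=1e-9)
            assert res.rsquared == pytest.approx(1.0, abs=1e-9)

    def test_reference_noiseless_recovers_shift_terms(self, noiseless_config):
        frame = generate_cohort(noiseless_config).to_frame()
        neg = AffectRegressionModel(frame, outcome="delta_negative").fit()
        pos = AffectRegressionModel(frame, outcome="delta_positive").fit()
        assert neg.params["affective_shift"] == pytest.approx(-3.96, rel=1e-6)
        assert pos.params["affective_shift"] == pytest.approx(1.69, rel=1e-6)
        assert pos.params["shift_sq"] == pytest.approx(79.43, rel=1e-6)

    def test_constant_outcome(self, unit_scale_config):
        frame = generate_cohort(unit_scale_config).to_frame()
        frame["delta_negative"] = 3.25
        res = AffectRegressionModel(frame, outcome="delta_negative").fit()
        assert res.params["intercept"] == pytest.approx(3.25, abs=1e-8)
        assert np.allclose(res.params.to_numpy()[1:], 0.0, atol=1e-8)

    def test_too_few_rows(self, ref_cohort_frame):
        with pytest.raises(InputError, match="rows"):
            AffectRegressionModel(ref_cohort_frame.iloc[:5]).fit()

    def test_rank_deficiency_names_columns(self, ref_cohort_frame):
        frame = ref_cohort_frame.copy()
        frame["gamma_change"] = 0.0  # gamma and gamma^2 collapse to constants
        with pytest.raises(EstimationError, match="gamma"):
            AffectRegressionModel(frame, outcome="delta_negative").fit()

    def test_standardized_and_original_predictions_agree(self, big_cohort_frame):
        # mandatory conditioning check at 1e-11 / 1e-12 predictor scales
        frame = big_cohort_frame.iloc[:5000]
        res = AffectRegressionModel(frame, outcome="delta_positive").fit()
        a = res.predict()
        b = res.predict_standardized()
        scale = np.max(np.abs(a))
        assert np.max(np.abs(a - b)) / scale < 1e-8

    def test_summary_mentions_outcome_and_terms(self, ref_cohort_frame):
        res = AffectRegressionModel(ref_cohort_frame).fit()
        text = res.summary()
        assert "delta_negative" in text and "affective_shift" in text


class TestBootstrapCoefficients:
    def test_noiseless_cis_degenerate_on_shift_terms(self, noiseless_config):
        frame = generate_cohort(noiseless_config).to_frame()
        res = AffectRegressionModel(frame, outcome="delta_negative").fit()
        table = res.bootstrap_ci(n_resamples=200, seed=0)
        width = table.loc["affective_shift", "ci_high"] - \
            table.loc["affective_shift", "ci_low"]
        assert width <= 1e-6

    def test_determinism(self, ref_cohort_frame):
        res = AffectRegressionModel(ref_cohort_frame).fit()
        a = res.bootstrap_ci(n_resamples=100, seed=5)
        b = res.bootstrap_ci(n_resamples=100, seed=5)
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_shift_effect_detected_in_default_cohorts(self, ref_config):
        # power check: the AS -> delta_negative effect is far from 0
        hits = 0
        reps = 20
        for rep in range(reps):
            frame = generate_cohort(ref_config.with_(seed=1000 + rep)).to_frame()
            res = AffectRegressionModel(frame, outcome="delta_negative").fit()
            table = res.bootstrap_ci(n_resamples=200, seed=rep)
            lo, hi = table.loc["affective_shift", ["ci_low", "ci_high"]]
            hits += not (lo <= 0.0 <= hi)
        assert hits >= 0.9 * reps


class TestMediation:
    def test_known_product_of_paths(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        m = 2.0 * x + 0.1 * rng.normal(size=n)
        y = 3.0 * m + 0.5 * x + 0.1 * rng.normal(size=n)
        frame = cohort_from_arrays(x, rng.normal(size=n), m, y)
        res = mediation_indirect(frame, "theta_change", "delta_negative",
                                 mediator="affective_shift", n_boot=100, seed=0)
        assert res.indirect == pytest.approx(6.0, rel=0.02)
        assert res.path_a == pytest.approx(2.0, rel=0.02)
        assert res.direct == pytest.approx(0.5, abs=0.05)

    def test_null_mediation_ci_contains_zero(self, rng):
        contains = 0
        reps = 10
        for rep in range(reps):
            r = np.random.default_rng(rep)
            n = 200
            x = r.normal(size=n)
            m = r.normal(size=n)  # independent of x
            y = m + r.normal(size=n)
            frame = cohort_from_arrays(x, r.normal(size=n), m, y)
            res = mediation_indirect(frame, "theta_change", "delta_negative",
                                     n_boot=300, seed=rep)
            contains += res.ci_low <= 0.0 <= res.ci_high
        assert contains >= 9

    def test_zero_variance_mediator(self, ref_cohort_frame):
        frame = ref_cohort_frame.copy()
        frame["affective_shift"] = 1.0
        with pytest.raises(EstimationError, match="zero variance"):
            mediation_indirect(frame, "theta_change", "delta_negative",
                               n_boot=10, seed=0)


class TestCompareModels:
    def test_determinism(self, ref_cohort_frame):
        a = compare_models(ref_cohort_frame, repeats=3, seed=2)
        b = compare_models(ref_cohort_frame, repeats=3, seed=2)
        assert a == b

    def test_pure_noise_outcome_has_no_skill(self, ref_cohort_frame, rng):
        frame = ref_cohort_frame.copy()
        frame["delta_positive"] = rng.normal(size=len(frame))
        comp = compare_models(frame, repeats=5, seed=0)
        assert all(r2 <= 0.1 for r2 in comp.r2_mean.values())

    def test_nested_in_sample_monotonicity(self, ref_cohort_frame):
        comp = compare_models(ref_cohort_frame, repeats=2, seed=1)
        assert comp.in_sample_r2["multimodal"] >= comp.in_sample_r2["panas_only"] >= 0
        assert comp.in_sample_r2["multimodal"] >= comp.in_sample_r2["eeg_only"]

    def test_too_few_rows_for_folds(self, ref_cohort_frame):
        with pytest.raises(InputError, match="folds"):
            compare_models(ref_cohort_frame.iloc[:3], folds=5)
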