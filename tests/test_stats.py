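"""Outlier screening, standardisation, model formulas and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from fpvstag.stats import (
    ModelSpec,
    fit_model,
    gaze_neural_correlation,
    mad_outliers,
    model_formula,
    prepare_table,
    remove_outliers,
    standardize,
    standardize_scores,
)
from fpvstag.synthgen import SimulationConfig, simulate_cohort


class TestMadOutliers:
    def test_hand_computed_example(self):
        # median 2.5, MAD 1.0 -> robust z of 100 is 65.8
        flags = mad_outliers([1, 2, 3, 100])
        assert flags.tolist() == [False, False, False, True]

    def test_constant_vector_flags_nothing(self):
        with pytest.warns(UserWarning, match="MAD is zero"):
            flags = mad_outliers([5.0] * 10)
        assert not flags.any()

    def test_gaussian_flag_rate_matches_normal_tail(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20_000)
        rate = mad_outliers(x).mean()
        expected = 2 * (1 - norm.cdf(3))  # ~0.0027
        assert rate == pytest.approx(expected, abs=0.002)

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError):
            mad_outliers([1.0, 2.0])


class TestStandardize:
    def test_simple_example(self):
        assert standardize([1, 2, 3]).tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        x = np.random.default_rng(1).normal(3, 5, 50)
        z = standardize(x)
        assert np.allclose(standardize(z), z, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        a=st.floats(0.01, 100),
        b=st.floats(-50, 50),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(0, 1, 30)
        assert np.allclose(standardize(a * x + b), standardize(x), atol=1e-8)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])


class TestModelSpecs:
    def test_model_1_oddball_crosses_group_content_roi(self):
        f = model_formula(ModelSpec(1, "oddball"))
        assert "group_c * content_c * C(roi, Sum)" in f
        assert "age" in f and "sex_c" in f

    def test_model_2_uses_continuous_adversity_with_symptoms(self):
        f = model_formula(ModelSpec(2, "oddball"))
        for s in ("adversity_z", "depression_z", "anxiety_z", "psychosis_z"):
            assert f"{s} * content_c" in f
        assert "threat" not in f

    def test_model_3_splits_threat_and_neglect(self):
        f = model_formula(ModelSpec(3, "oddball"))
        assert "threat_z" in f and "neglect_z" in f and "adversity_z" not in f

    def test_multiinput_models_cross_valence_and_content(self):
        f = model_formula(ModelSpec(1, "multiinput_neural"))
        assert "group_c * valence_c * content_c" in f

    def test_models_2_and_3_run_within_the_adversity_group_only(self):
        cohort = simulate_cohort(SimulationConfig(seed=5, n_control=10, n_adversity=12))
        res = fit_model(ModelSpec(2, "oddball"), cohort.oddball)
        assert res.fit.n_groups == 12

    def test_standardized_scores_have_unit_variance_across_subjects(self):
        cohort = simulate_cohort(SimulationConfig(seed=6, n_control=10, n_adversity=15))
        tbl, _ = prepare_table(ModelSpec(2, "oddball"), cohort.oddball)
        per_subj = tbl.drop_duplicates("subject")
        assert per_subj["adversity_z"].mean() == pytest.approx(0, abs=1e-9)
        assert per_subj["adversity_z"].std(ddof=1) == pytest.approx(1, abs=1e-9)


class TestRemoveOutliers:
    def test_flags_within_cells_not_globally(self):
        rng = np.random.default_rng(2)
        rows = []
        for cell, mu in (("A", 0.0), ("B", 100.0)):
            for i in range(30):
                rows.append({"cell": cell, "y": mu + rng.normal()})
        rows.append({"cell": "A", "y": 30.0})  # outlier within A, not globally
        df = pd.DataFrame(rows)
        kept, n = remove_outliers(df, ["cell"])
        assert n == 1
        assert not ((kept["cell"] == "A") & (kept["y"] > 20)).any()


class TestGazeNeuralCorrelation:
    def _tables(self, d_gaze, d_neural):
        rows_g, rows_n = [], []
        for i, (g, n) in enumerate(zip(d_gaze, d_neural)):
            for content in ("social", "nonsocial"):
                rows_g += [
                    {"subject": i, "content": content, "valence": "negative", "y": g},
                    {"subject": i, "content": content, "valence": "neutral", "y": 0.0},
                ]
                rows_n += [
                    {"subject": i, "content": content, "valence": "negative", "y": n},
                    {"subject": i, "content": content, "valence": "neutral", "y": 0.0},
                ]
        return pd.DataFrame(rows_g), pd.DataFrame(rows_n)

    def test_identical_difference_scores_give_r_one(self):
        x = np.random.default_rng(3).normal(0, 1, 20)
        g, n = self._tables(x, x)
        out = gaze_neural_correlation(g, n)
        assert np.allclose(out["r"], 1.0)
        assert (out["df"] == 18).all()

    def test_independent_measures_give_small_r(self):
        rng = np.random.default_rng(4)
        g, n = self._tables(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
        out = gaze_neural_correlation(g, n)
        assert np.all(np.abs(out["r"]) < 0.15)

    def test_shared_latent_factor_attenuation_matches_closed_form(self):
        """r = s^2 / sqrt((s^2+e1^2)(s^2+e2^2)) for loadings of one."""
        rng = np.random.default_rng(5)
        m = 4000
        s, e1, e2 = 1.0, 0.5, 0.8
        latent = rng.normal(0, s, m)
        g, n = self._tables(
            latent + rng.normal(0, e1, m), latent + rng.normal(0, e2, m)
        )
        out = gaze_neural_correlation(g, n)
        expected = s**2 / np.sqrt((s**2 + e1**2) * (s**2 + e2**2))
        assert np.allclose(out["r"], expected, atol=0.03)

    def test_too_few_subjects_is_an_error(self):
        g, n = self._tables([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            gaze_neural_correlation(g, n)
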