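"""Mixture service-time models and the bimodal threshold classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biopsim.rng import NormalSpec, UniformSource
from biopsim.service_times import (
    ANALYSIS_MODEL,
    CUTTING_MODEL,
    BimodalServiceModel,
    ClassificationRule,
    MixtureComponent,
    classify_bimodal,
    mixture_moments,
    sample_service_time,
    weights_from_counts,
)


class TestModelValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            BimodalServiceModel(
                "bad",
                (
                    MixtureComponent(NormalSpec(1, 1), 0.5),
                    MixtureComponent(NormalSpec(2, 1), 0.4),
                ),
            )

    def test_component_means_must_be_ordered(self):
        with pytest.raises(ValueError):
            BimodalServiceModel(
                "bad",
                (
                    MixtureComponent(NormalSpec(5, 1), 0.5),
                    MixtureComponent(NormalSpec(2, 1), 0.5),
                ),
            )

    def test_weights_from_counts(self):
        w1, w2 = weights_from_counts(35, 19)
        assert w1 == pytest.approx(0.648, abs=1e-3)
        assert w2 == pytest.approx(0.352, abs=1e-3)
        with pytest.raises(ValueError):
            weights_from_counts(0, 0)


class TestMixtureMoments:
    def test_analysis_model_mean(self):
        mean, var = mixture_moments(ANALYSIS_MODEL)
        assert mean == pytest.approx(15.639, abs=1e-3)
        assert var > 0

    def test_cutting_model_mean(self):
        mean, _ = mixture_moments(CUTTING_MODEL)
        assert mean == pytest.approx(3.781, abs=1e-3)

    def test_degenerate_weight_collapses_to_component(self):
        model = BimodalServiceModel(
            "deg",
            (
                MixtureComponent(NormalSpec(4.0, 1.5), 1.0),
                MixtureComponent(NormalSpec(20.0, 2.0), 0.0),
            ),
        )
        mean, var = mixture_moments(model)
        assert mean == pytest.approx(4.0)
        assert var == pytest.approx(1.5**2)


class TestSampling:
    def test_empty(self):
        assert sample_service_time(ANALYSIS_MODEL, 0, UniformSource(1)).size == 0

    def test_monte_carlo_mean_matches_closed_form(self):
        n = 10**5
        vals = sample_service_time(ANALYSIS_MODEL, n, UniformSource(8))
        mean, var = mixture_moments(ANALYSIS_MODEL)
        # 3 standard errors plus the small positive-truncation bias
        assert abs(vals.mean() - mean) < max(0.15, 3 * np.sqrt(var / n) + 0.12)

    def test_component_identity_fraction(self):
        vals, comp = sample_service_time(
            ANALYSIS_MODEL, 10**5, UniformSource(9), return_components=True
        )
        assert abs((comp == 0).mean() - 0.648) < 0.01
        assert (vals > 0).all()

    def test_reproducible(self):
        a = sample_service_time(CUTTING_MODEL, 200, UniformSource(5))
        b = sample_service_time(CUTTING_MODEL, 200, UniformSource(5))
        np.testing.assert_array_equal(a, b)


class TestClassification:
    def test_study_shaped_sample_recovers_two_to_one_split(self, source):
        # 35 fast durations under 16 min, 19 slow ones over 20 min
        from biopsim.rng import sample_normal

        g1 = np.clip(sample_normal(NormalSpec(9.2571, 2.0), 35, source), 0.1, 15.9)
        g2 = np.clip(sample_normal(NormalSpec(27.389, 3.0), 19, source), 20.1, None)
        res = classify_bimodal(np.concatenate([g1, g2]))
        assert res.counts == (35, 19)
        assert res.proportions[0] == pytest.approx(0.648, abs=1e-3)
        assert res.proportions[1] == pytest.approx(0.352, abs=1e-3)

    def test_all_fast(self):
        res = classify_bimodal([1.0, 2.0, 3.0])
        assert res.proportions == (1.0, 0.0)

    def test_gap_values_go_to_nearer_threshold_tie_to_group_one(self):
        res = classify_bimodal([5.0, 25.0, 17.0, 19.0, 18.0])
        # 17 -> group 1 (nearer 16), 19 -> group 2 (nearer 20), 18 -> tie -> group 1
        assert list(res.labels) == [1, 2, 1, 2, 1]

    def test_all_in_gap_is_an_error(self):
        with pytest.raises(ValueError):
            classify_bimodal([17.0, 18.0, 19.0])

    def test_rule_must_be_ordered(self):
        with pytest.raises(ValueError):
            ClassificationRule(low_threshold=20, high_threshold=16)

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10**6))
    def test_permutation_invariance_and_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.uniform(1, 15, 20), rng.uniform(21, 40, 10)])
        base = classify_bimodal(x)
        perm = rng.permutation(x)
        shuffled = classify_bimodal(perm)
        assert shuffled.proportions == base.proportions
        # group statistics invariant up to float summation order
        for a, b in zip(shuffled.group_specs, base.group_specs):
            assert a.mu == pytest.approx(b.mu, abs=1e-9)
            assert a.sigma == pytest.approx(b.sigma, abs=1e-9)
        # idempotence: classifying each group alone reproduces its spec
        again = classify_bimodal(x[base.labels == 1])
        assert again.group_specs[0].mu == pytest.approx(base.group_specs[0].mu, abs=1e-9)
        assert again.group_specs[0].sigma == pytest.approx(base.group_specs[0].sigma, abs=1e-9)

    def test_round_trip_parameter_recovery_both_models(self):
        # the cutting modes sit at 1.2 vs 30 min, so the split thresholds
        # differ from the 16/20-minute analysis rule
        cases = (
            (ANALYSIS_MODEL, ClassificationRule()),
            (CUTTING_MODEL, ClassificationRule(3.0, 5.0)),
        )
        for model, rule in cases:
            vals = sample_service_time(model, 5000, UniformSource(41))
            res = classify_bimodal(vals, rule)
            for got, comp in zip(res.group_specs, model.components):
                assert abs(got.mu - comp.spec.mu) < 0.5
            assert abs(res.proportions[0] - model.components[0].weight) < 0.05
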