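import numpy as np
import pytest

from panelscrutiny import (
    CommonCauseSpec,
    CorrelationTriple,
    MoslaParams,
    build_spec,
    closed_form_effects,
    implied_corr_common_cause,
    implied_cov_mosla,
    implied_cov,
    simulate_common_cause,
    simulate_from_corr,
    simulate_mosla,
)
from panelscrutiny.exceptions import ParameterError, SpecificationError

from conftest import STUDY_PARAMS, three_construct_target, triple_target


class TestImpliedCovMosla:
    def test_pure_traits_give_block_constant_matrix(self):
        params = MoslaParams(1.0, 1.0, 0.0, 0.0, 0.0, 0.0)
        _, cov = implied_cov_mosla(params, 3)
        w = 3
        assert np.allclose(cov[:w, :w], 1.0)
        assert np.allclose(cov[w:, w:], 1.0)
        assert np.allclose(cov[:w, w:], 0.0)

    def test_study_parameter_values(self, study_params):
        labels, cov = implied_cov_mosla(study_params, 3)
        i_n1 = labels.index(("N", 1))
        i_c1, i_c2 = labels.index(("C", 1)), labels.index(("C", 2))
        assert cov[i_n1, i_c1] == pytest.approx(0.4, abs=1e-15)
        assert cov[i_n1, i_c2] == pytest.approx(0.25, abs=1e-15)
        assert np.allclose(np.diag(cov), 1.0)

    def test_zero_autocorrelation_flattens_lagged_cross_cov(self):
        params = MoslaParams(0.4, 0.4, 0.15, 0.2, 0.0, 0.3)
        _, cov = implied_cov_mosla(params, 3)
        for lag in (1, 2):
            for t in range(3 - lag):
                assert cov[t, 3 + t + lag] == pytest.approx(0.15, abs=1e-15)

    def test_matches_ram_derivation_over_random_draws(self, rng):
        """Two independent derivations (closed form vs RAM path matrices)
        of the implied covariance agree to 1e-12."""
        for _ in range(100):
            waves = int(rng.integers(2, 5))
            phi_n, phi_c = rng.uniform(0.1, 1.0, 2)
            r = rng.uniform(-0.9, 0.9)
            params = MoslaParams(
                phi_n, phi_c, r * np.sqrt(phi_n * phi_c),
                rng.uniform(0.0, 0.8), rng.uniform(-0.9, 0.9), rng.uniform(0.05, 0.8),
            )
            _, closed = implied_cov_mosla(params, waves)
            ram = implied_cov(build_spec(waves), params)
            assert np.max(np.abs(closed - ram)) < 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            MoslaParams(-0.1, 0.4, 0.0, 0.3, 0.5, 0.3)
        with pytest.raises(ParameterError):
            MoslaParams(0.4, 0.4, 0.0, 0.3, 1.0, 0.3)
        with pytest.raises(ParameterError):
            MoslaParams(0.4, 0.4, 0.9, 0.3, 0.5, 0.3)  # |phi_nc| > sqrt product
        with pytest.raises(ParameterError):
            implied_cov_mosla(STUDY_PARAMS, waves=1)


class TestSimulateMosla:
    def test_large_sample_covariance_approaches_implied(self, study_params):
        data = simulate_mosla(study_params, n=100_000, waves=3, seed=7)
        _, implied = implied_cov_mosla(study_params, 3)
        sample = data.covariance()
        assert np.max(np.abs(sample - implied)) < 0.02

    def test_noiseless_process_repeats_waves(self):
        params = MoslaParams(0.5, 0.5, 0.2, 0.0, 0.0, 0.0)
        data = simulate_mosla(params, n=50, waves=3, seed=1)
        for construct in ("N", "C"):
            col1 = data.column(construct, 1)
            for wave in (2, 3):
                np.testing.assert_array_equal(col1, data.column(construct, wave))

    def test_seed_determinism(self, study_params):
        a = simulate_mosla(study_params, n=100, waves=3, seed=42)
        b = simulate_mosla(study_params, n=100, waves=3, seed=42)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_adding_waves_preserves_earlier_draws(self, study_params):
        """Sub-stream seeding: the first three waves are identical whether
        three or four waves are simulated."""
        short = simulate_mosla(study_params, n=80, waves=3, seed=5)
        long = simulate_mosla(study_params, n=80, waves=4, seed=5)
        for construct in ("N", "C"):
            for wave in (1, 2, 3):
                np.testing.assert_array_equal(
                    short.column(construct, wave), long.column(construct, wave)
                )


class TestSimulateFromCorr:
    def test_exact_mode_reproduces_target(self):
        target = three_construct_target()
        data = simulate_from_corr(target, n=561, seed=3, exact=True)
        emp = data.correlation_matrix().values
        assert np.max(np.abs(emp - target.values)) < 1e-10
        assert data.standardized

    def test_exact_mode_identity_target(self):
        target = triple_target(CorrelationTriple(0.0, 0.0, 0.0))
        data = simulate_from_corr(target, n=200, seed=11, exact=True)
        emp = data.correlation_matrix().values
        off = emp[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-10

    def test_exact_mode_restandardization_is_idempotent(self):
        target = three_construct_target()
        data = simulate_from_corr(target, n=100, seed=9, exact=True)
        again = data.standardize()
        assert np.max(np.abs(again.scores - data.scores)) < 1e-12

    def test_exact_mode_needs_more_subjects_than_variables(self):
        target = three_construct_target()
        with pytest.raises(ParameterError):
            simulate_from_corr(target, n=target.p, seed=0, exact=True)

    def test_sampled_mode_population_correlation(self):
        target = three_construct_target()
        data = simulate_from_corr(target, n=200_000, seed=13, exact=False)
        emp = data.correlation_matrix().values
        assert np.max(np.abs(emp - target.values)) < 0.02


class TestCommonCause:
    SPEC = CommonCauseSpec(load_cc_x1=0.7, load_cc_y1=0.7, load_cc_y2=0.7,
                           auto_y1_y2=0.3)

    def test_null_loadings_imply_null_correlations_and_effect(self):
        spec = CommonCauseSpec(0.0, 0.0, 0.0, 0.0)
        r = implied_corr_common_cause(spec)
        assert r == (0.0, 0.0, 0.0)
        assert closed_form_effects(CorrelationTriple(*r)).a1 == 0.0

    def test_path_tracing_worked_example(self):
        r_x1y1, r_x1y2, r_y1y2 = implied_corr_common_cause(self.SPEC)
        assert r_x1y1 == pytest.approx(0.49, abs=1e-15)
        assert r_x1y2 == pytest.approx(0.637, abs=1e-15)
        assert r_y1y2 == pytest.approx(0.79, abs=1e-15)
        # no direct X1 -> Y2 path, yet the cross-lagged effect is nonzero
        a1 = closed_form_effects(CorrelationTriple(r_x1y1, r_x1y2, r_y1y2)).a1
        assert abs(a1) > 0.1

    def test_negative_effect_when_cross_lagged_correlation_vanishes(self):
        """With r_x1y2 = 0 but r_x1y1 * r_y1y2 > 0 the adjusted effect is
        negative — the sign is read off the closed-form numerator."""
        spec = CommonCauseSpec(0.7, 0.7, -0.21, 0.3)  # l_y2 = -auto * l_y1
        r = CorrelationTriple(*implied_corr_common_cause(spec))
        assert r.r_x1y2 == pytest.approx(0.0, abs=1e-15)
        assert r.r_x1y1 * r.r_y1y2 > 0
        assert closed_form_effects(r).a1 < 0.0

    def test_overloaded_specification_rejected(self):
        with pytest.raises(SpecificationError):
            CommonCauseSpec(0.9, 0.9, 0.9, 0.9)

    def test_monte_carlo_agrees_with_path_tracing(self):
        data = simulate_common_cause(self.SPEC, n=1_000_000, seed=17)
        emp = data.correlation_matrix()
        want = implied_corr_common_cause(self.SPEC)
        got = (
            emp.corr(("X", 1), ("Y", 1)),
            emp.corr(("X", 1), ("Y", 2)),
            emp.corr(("Y", 1), ("Y", 2)),
        )
        assert np.max(np.abs(np.subtract(got, want))) < 0.005

    def test_unit_variance_construction(self):
        data = simulate_common_cause(self.SPEC, n=100_000, seed=23)
        assert np.max(np.abs(data.scores.std(axis=0) - 1)) < 0.01

    def test_seed_determinism(self):
        a = simulate_common_cause(self.SPEC, n=100, seed=2)
        b = simulate_common_cause(self.SPEC, n=100, seed=2)
        np.testing.assert_array_equal(a.scores, b.scores)
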