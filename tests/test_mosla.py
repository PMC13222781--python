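import math

import numpy as np
import pytest

from panelscrutiny import (
    MoslaModel,
    MoslaParams,
    build_spec,
    chi2_pvalue,
    compute_fit_indices,
    fit_ml,
    implied_cov,
    implied_cov_mosla,
    rmsea,
    rmsea_ci,
    simulate_mosla,
)
from panelscrutiny.exceptions import ParameterError, SchemaError

from conftest import STUDY_PARAMS


class TestSpec:
    @pytest.mark.parametrize("waves, df", [(3, 15), (2, 4), (4, 30)])
    def test_degrees_of_freedom(self, waves, df):
        spec = build_spec(waves)
        assert spec.n_free == 6
        assert spec.df == df

    def test_label_counts(self):
        spec = build_spec(3)
        assert len(spec.observed) == 6
        assert len(spec.latents) == 5
        assert spec.n_moments == 21

    def test_too_few_waves(self):
        with pytest.raises(ParameterError):
            build_spec(1)


class TestImpliedCov:
    def test_no_state_process_gives_compound_symmetry(self):
        params = MoslaParams(0.5, 0.3, 0.1, 0.0, 0.0, 0.2)
        sigma = implied_cov(build_spec(3), params)
        block_n = sigma[:3, :3]
        off = block_n[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])
        assert np.allclose(np.diag(block_n), 0.7)

    def test_vanishing_residual_variance_makes_sigma_singular(self):
        params = MoslaParams(0.4, 0.4, 0.1, 0.3, 0.5, 1e-8)
        sigma = implied_cov(build_spec(3), params)
        assert np.linalg.eigvalsh(sigma).min() < 1e-7


class TestIdentification:
    def test_two_wave_model_is_not_identified(self):
        """With only two waves the six parameters trace a one-parameter
        ridge: psi -> psi + d, rho -> (psi*rho + d)/(psi + d) with all
        trait (co)variances shifted by -d leaves the implied covariance
        exactly unchanged.  Three waves break the ridge."""
        p = MoslaParams(0.5, 0.6, 0.2, 0.3, 0.4, 0.2)
        d = 0.15
        q = MoslaParams(
            p.phi_n - d, p.phi_c - d, p.phi_nc - d,
            p.psi + d, (p.psi * p.rho + d) / (p.psi + d), p.theta,
        )
        _, s2p = implied_cov_mosla(p, 2)
        _, s2q = implied_cov_mosla(q, 2)
        assert np.max(np.abs(s2p - s2q)) < 1e-14
        _, s3p = implied_cov_mosla(p, 3)
        _, s3q = implied_cov_mosla(q, 3)
        assert np.max(np.abs(s3p - s3q)) > 0.01

    def test_three_wave_population_fit_recovers_parameters(self, study_params):
        _, sigma = implied_cov_mosla(study_params, 3)
        res = fit_ml(build_spec(3), sigma, n=200)
        for name, truth in study_params.as_dict().items():
            assert getattr(res.params, name) == pytest.approx(truth, abs=1e-5)


class TestFit:
    def test_population_recovery_is_exact(self, study_params):
        _, sigma = implied_cov_mosla(study_params, 3)
        res = fit_ml(build_spec(3), sigma, n=561)
        assert res.f_min < 1e-10
        assert res.chi2 == pytest.approx(0.0, abs=1e-7)
        for name, truth in study_params.as_dict().items():
            assert getattr(res.params, name) == pytest.approx(truth, abs=1e-5)

    def test_sample_fit_reasonable(self, study_params):
        data = simulate_mosla(study_params, n=561, waves=3, seed=99)
        res = MoslaModel.from_data(data).fit()
        assert res.converged
        assert res.df == 15
        assert 0 <= res.p_value <= 1
        assert all(se > 0 and np.isfinite(se) for se in res.se.values())
        # estimates in the neighbourhood of the generating values
        for name, truth in study_params.as_dict().items():
            assert abs(getattr(res.params, name) - truth) < 0.25

    def test_independence_structure_kills_shared_components(self):
        res = MoslaModel(np.eye(6), n=561).fit()
        assert abs(res.params.phi_nc) < 1e-3
        assert res.params.psi < 1e-3

    def test_input_validation(self):
        with pytest.raises(SchemaError):
            MoslaModel(np.eye(5), n=100)  # odd size
        bad = np.eye(6)
        bad[0, 0] = -1.0
        with pytest.raises(SchemaError):
            MoslaModel(bad, n=100)
        with pytest.raises(SchemaError):
            MoslaModel(np.eye(6), n=6)

    def test_chi2_multiplier_switch(self, study_params):
        data = simulate_mosla(study_params, n=561, waves=3, seed=7)
        model = MoslaModel.from_data(data)
        nm1 = model.fit(chi2_multiplier="nm1")
        n = model.fit(chi2_multiplier="n")
        assert n.chi2 / nm1.chi2 == pytest.approx(561 / 560, rel=1e-6)


class TestStandardErrorCalibration:
    def test_reported_se_matches_sampling_variability(self, study_params):
        """Delta-method standard errors track the Monte-Carlo sampling SD
        of the estimates to within 20% for every parameter."""
        reps = 150
        names = ("phi_n", "phi_c", "phi_nc", "psi", "rho", "theta")
        est = {k: [] for k in names}
        ses = {k: [] for k in names}
        for rep in range(reps):
            data = simulate_mosla(study_params, n=561, waves=3, seed=40_000 + rep)
            res = MoslaModel.from_data(data).fit()
            for k in names:
                est[k].append(getattr(res.params, k))
                ses[k].append(res.se[k])
        for k in names:
            empirical = np.std(est[k], ddof=1)
            reported = np.mean(ses[k])
            assert abs(empirical - reported) / reported < 0.20


class TestFitStatistics:
    def test_chi2_pvalue_boundaries(self):
        assert chi2_pvalue(0.0, 7) == pytest.approx(1.0)
        assert chi2_pvalue(100_000, 100_000) == pytest.approx(0.5, abs=0.01)
        with pytest.raises(ParameterError):
            chi2_pvalue(-1.0, 5)

    def test_rmsea_at_boundary(self):
        assert rmsea(15.0, 15, 561) == 0.0
        assert rmsea(10.4, 15, 561) == 0.0

    def test_rmsea_ci_collapses_when_chi2_below_df(self):
        lo, hi = rmsea_ci(2.0, 15, 561)
        assert (lo, hi) == (0.0, 0.0)

    def test_rmsea_ci_upper_increases_in_chi2(self):
        uppers = [rmsea_ci(chi2, 15, 561)[1] for chi2 in np.linspace(8, 60, 14)]
        assert all(b > a for a, b in zip(uppers, uppers[1:]))

    def test_fit_indices_at_exact_fit(self):
        ind = compute_fit_indices(15.0, 15, 561, baseline_chi2=900.0, baseline_df=15)
        assert ind.cfi == pytest.approx(1.0)
        assert ind.rmsea == 0.0
        assert ind.rmsea_ci_low <= ind.rmsea_ci_high

    def test_tli_exceeds_one_when_chi2_below_df(self):
        ind = compute_fit_indices(10.4, 15, 561, baseline_chi2=900.0, baseline_df=15)
        assert ind.tli > 1.0
        assert ind.cfi == 1.0

    def test_degenerate_baseline_flags_tli_undefined(self):
        ind = compute_fit_indices(20.0, 15, 561, baseline_chi2=10.0, baseline_df=15)
        assert math.isnan(ind.tli)


class TestStandardizedSolution:
    def test_population_standardized_loadings(self, study_params):
        """At a standardized generating model the standardized trait
        loading equals sqrt(phi) and variance shares sum to one."""
        _, sigma = implied_cov_mosla(study_params, 3)
        res = fit_ml(build_spec(3), sigma, n=561)
        table = res.standardized_solution()
        gn = table[(table.lhs == "gN") & (table.op == "=~")]
        assert np.allclose(gn.standardized, math.sqrt(0.4), atol=1e-6)
        for construct in ("N", "C"):
            shares = table[
                table.op.str.startswith("var%") & (table.lhs == construct)
            ].standardized
            assert shares.sum() == pytest.approx(1.0, abs=1e-8)

    def test_trait_correlation_sign_follows_phi_nc(self):
        params = MoslaParams(0.4, 0.4, -0.15, 0.2, 0.3, 0.4)
        _, sigma = implied_cov_mosla(params, 3)
        res = fit_ml(build_spec(3), sigma, n=200)
        table = res.standardized_solution()
        corr = table[table.op == "~~"].standardized.iloc[0]
        assert corr < 0
        assert np.sign(corr) == np.sign(res.params.phi_nc)

    def test_summary_reports_fit_line(self, study_params):
        data = simulate_mosla(study_params, n=561, waves=3, seed=3)
        res = MoslaModel.from_data(data).fit()
        text = res.summary()
        assert "chi2" in text and "RMSEA" in text and "phi_nc" in text
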