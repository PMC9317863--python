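import numpy as np
import pytest

import utilsurv as u
from utilsurv.glm import _irls
from utilsurv.windows import design_matrix

from _oracles import poisson_mle_oracle, random_small_design


class TestIrlsAgainstOracle:
    def test_matches_generic_optimizer_on_small_designs(self):
        rng = np.random.default_rng(314)
        checked = 0
        while checked < 25:
            case = random_small_design(rng)
            if case is None:
                continue
            X, y = case
            coef, converged, _ = _irls(X, y)
            assert converged
            oracle = poisson_mle_oracle(X, y)
            scale = np.maximum(np.abs(oracle), 1e-8)
            assert np.max(np.abs(coef - oracle) / scale) < 1e-6
            checked += 1

    def test_matches_statsmodels_glm(self, study_series, default_config):
        """Coefficients and Pearson dispersion agree with statsmodels' GLM."""
        import statsmodels.api as sm

        d = u.build_reference_design(study_series, u.MonthStamp(2020, 6),
                                     default_config)
        fit = u.fit_quasipoisson(d)
        X, y, names, _ = design_matrix(d)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        mine = np.array([fit.coefficients[n] for n in names])
        assert np.allclose(mine, ref.params, rtol=1e-8, atol=1e-10)
        assert fit.phi_raw == pytest.approx(ref.pearson_chi2 / ref.df_resid,
                                            rel=1e-8)

    def test_score_equations_vanish(self, study_series, default_config):
        d = u.build_reference_design(study_series, u.MonthStamp(2020, 6),
                                     default_config)
        fit = u.fit_quasipoisson(d)
        X, y, _, _ = design_matrix(d)
        score = X.T @ (y - fit.fitted_means)
        assert np.max(np.abs(score)) < 1e-4 * np.sum(y)


class TestFitQuasipoisson:
    def test_constant_series(self, constant_series, default_config):
        d = u.build_reference_design(constant_series, u.MonthStamp(2020, 6),
                                     default_config)
        fit = u.fit_quasipoisson(d)
        assert fit.converged
        assert fit.alpha == pytest.approx(np.log(100), abs=1e-6)
        assert fit.beta == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(fit.fitted_means, 100.0)
        assert fit.phi_raw == pytest.approx(0.0, abs=1e-10)
        assert fit.phi == 1.0

    def test_trend_shift_equivariance(self, study_series, default_config):
        """Re-originating the trend index changes only the intercept."""
        target = u.MonthStamp(2020, 6)
        d = u.build_reference_design(study_series, target, default_config)
        fit = u.fit_quasipoisson(d)
        c = 24
        shifted = u.ReferenceDesign(
            target=d.target, series_start=d.series_start, config=d.config,
            block_map=d.block_map,
            points=tuple(
                u.ReferencePoint(p.month, p.trend_index + c, p.block, p.value)
                for p in d.points
            ),
        )
        fit2 = u.fit_quasipoisson(shifted)
        assert fit2.beta == pytest.approx(fit.beta, rel=1e-6)
        assert fit2.alpha == pytest.approx(fit.alpha - c * fit.beta, rel=1e-6)
        for b in fit.gamma:
            assert fit2.gamma[b] == pytest.approx(fit.gamma[b], abs=1e-6)

    def test_all_zero_response_raises(self, default_config):
        months = tuple(u.MonthStamp(2015, 3).shift(k) for k in range(70))
        s = u.UtilizationSeries(u.Outcome.NEW_HOSPITALIZATIONS, "ltci", months,
                                (0,) * 70)
        d = u.build_reference_design(s, u.MonthStamp(2020, 6), default_config)
        with pytest.raises(u.FitError):
            u.fit_quasipoisson(d)

    def test_diagnostics_report(self, study_series, default_config):
        d = u.build_reference_design(study_series, u.MonthStamp(2020, 6),
                                     default_config)
        fit = u.fit_quasipoisson(d)
        diag = fit.diagnostics()
        assert diag["n_points"] == 58
        assert set(diag["coefficients"]) == {
            "intercept", "trend", "block_1", "block_2", "block_3"
        }
        assert diag["phi"] >= 1.0


class TestDispersion:
    def test_raw_vs_floored(self, constant_series, default_config):
        d = u.build_reference_design(constant_series, u.MonthStamp(2020, 6),
                                     default_config)
        fit = u.fit_quasipoisson(d)
        assert u.dispersion(fit, raw=True) == pytest.approx(0.0, abs=1e-10)
        assert u.dispersion(fit) == 1.0

    def test_unconverged_fit_rejected(self, constant_series, default_config):
        d = u.build_reference_design(constant_series, u.MonthStamp(2020, 6),
                                     default_config)
        fit = u.fit_quasipoisson(d)
        bad = u.BaselineFit(
            design=fit.design, alpha=fit.alpha, beta=fit.beta, gamma=fit.gamma,
            phi=fit.phi, phi_raw=fit.phi_raw, fitted_means=fit.fitted_means,
            n_points=fit.n_points, converged=False, iterations=100,
        )
        with pytest.raises(u.NotConvergedError):
            u.dispersion(bad)
        with pytest.raises(u.NotConvergedError):
            u.predict_expected(bad)

    def test_nb_variance_recovered(self):
        """With variance 2*mean, Pearson dispersion concentrates near 2."""
        rng = np.random.default_rng(77)
        phis = []
        cfg = u.WindowConfig()
        for _ in range(60):
            spec = u.GeneratorSpec(alpha=np.log(800), beta=0.0, phi=2.0,
                                   seed=int(rng.integers(2**31)))
            s = u.simulate_series(spec)
            d = u.build_reference_design(s, u.MonthStamp(2020, 6), cfg)
            phis.append(u.fit_quasipoisson(d).phi_raw)
        assert np.mean(phis) == pytest.approx(2.0, abs=0.3)

    def test_poisson_data_floored_about_half_the_time(self):
        """Pearson/df ~ 1 for Poisson data, so flooring bites in ~half of fits."""
        rng = np.random.default_rng(88)
        floored = 0
        cfg = u.WindowConfig()
        n_rep = 60
        for _ in range(n_rep):
            spec = u.GeneratorSpec(alpha=np.log(800), beta=0.0, phi=1.0,
                                   seed=int(rng.integers(2**31)))
            s = u.simulate_series(spec)
            fit = u.fit_quasipoisson(
                u.build_reference_design(s, u.MonthStamp(2020, 6), cfg)
            )
            floored += fit.phi_raw < 1.0
            assert fit.phi >= 1.0
        assert 0.2 < floored / n_rep < 0.8
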