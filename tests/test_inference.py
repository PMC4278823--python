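"""MLE/MCMC engines, indirect regression, direct estimation, dispatch."""

import warnings

import numpy as np
import pytest

from thermopop import (
    KB,
    ArrheniusModel,
    ChainConfig,
    ExperimentalDesign,
    LikelihoodSpec,
    LogisticParams,
    ObservedSeries,
    derive_logistic,
    direct_ea,
    fit_mcmc,
    fit_mle,
    indirect_ea,
    logistic_mean,
    run_method,
    run_methods,
    scale_model,
    simulate_design,
)
from thermopop.inference import FitResult, extract_log_param
from thermopop.simulate import Dataset


def noiseless_series(r, K, n0, f, times, temperature=301.15):
    lp = LogisticParams(r=r, K=K, n0=n0)
    counts = np.rint(f * logistic_mean(np.asarray(times, float), lp)).astype(np.int64)
    return ObservedSeries(temperature, 0, np.asarray(times, float), counts,
                          np.full(len(times), f))


class TestFitMLE:
    def test_noiseless_phenomenological_recovery(self):
        """Zero-noise logistic counts: (r, K) recovered to ~1e-4 relative."""
        series = noiseless_series(1.0, 10000.0, 100.0, 1.0, np.arange(1.0, 16.0))
        fit = fit_mle(LikelihoodSpec("PHEN"), series, n0=100.0)
        assert fit.status in ("ok", "na-variance")
        assert np.exp(fit.params["log_r"]) == pytest.approx(1.0, rel=1e-3)
        assert np.exp(fit.params["log_K"]) == pytest.approx(10000.0, rel=1e-3)

    def test_demographic_recovery_large_data(self, ref_model):
        """L1 MLE at f=1 with many replicates recovers r and K within ~2 SE."""
        design = ExperimentalDesign(
            temperatures=(301.15,), reps=25, sample_times=tuple(np.arange(1.0, 16.0)),
            frac_samp=1.0, n0=100,
        )
        ds = simulate_design(ref_model, design, seed=77)
        fit = fit_mle(LikelihoodSpec("DEMOG"), ds.series, n0=100.0)
        fit.diagnostics["N"] = 15000
        assert fit.status == "ok"
        log_r, se_r = extract_log_param(fit, "r")
        log_k, se_k = extract_log_param(fit, "K")
        assert abs(log_r - 0.0) < 3 * max(se_r, 0.01)
        assert abs(log_k - np.log(10000.0)) < 3 * max(se_k, 0.01)

    def test_all_zero_counts_fail_with_reason(self):
        series = ObservedSeries(301.15, 0, np.arange(1.0, 6.0),
                                np.zeros(5, dtype=np.int64), np.full(5, 0.001))
        fit = fit_mle(LikelihoodSpec("DEMOG"), series, n0=100.0)
        assert fit.status == "failed"
        assert "degenerate" in fit.reason

    def test_too_few_observations_fail(self):
        series = ObservedSeries(301.15, 0, np.array([1.0, 2.0]),
                                np.array([3, 5], dtype=np.int64), np.full(2, 0.01))
        fit = fit_mle(LikelihoodSpec("DEMOG"), series, n0=100.0)
        assert fit.status == "failed"


class TestFitMCMC:
    def test_same_seed_identical_chains(self, small_dataset):
        group = small_dataset.at_temperature(small_dataset.temperatures[-1])
        cfg = ChainConfig(3000, 0.5, 1000, seed=42)
        a = fit_mcmc(LikelihoodSpec("DEMOG_SAMP"), group, n0=100, chain=cfg)
        b = fit_mcmc(LikelihoodSpec("DEMOG_SAMP"), group, n0=100, chain=cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_posterior_concentrates_near_mle(self, ref_model):
        """Abundant data: posterior mean of log r within ~1 posterior SD of MLE."""
        design = ExperimentalDesign(
            temperatures=(301.15,), reps=10, sample_times=tuple(np.arange(1.0, 16.0)),
            frac_samp=0.05, n0=100,
        )
        ds = simulate_design(ref_model, design, seed=4)
        mle = fit_mle(LikelihoodSpec("DEMOG_SAMP"), ds.series, n0=100)
        mc = fit_mcmc(LikelihoodSpec("DEMOG_SAMP"), ds.series, n0=100,
                      chain=ChainConfig(12000, 0.5, 1000, seed=9))
        mle.diagnostics["N"] = mc.diagnostics["N"] = 15000
        lr_mle, _ = extract_log_param(mle, "r")
        lr_mc, sd_mc = extract_log_param(mc, "r")
        assert abs(lr_mc - lr_mle) < max(1.5 * sd_mc, 0.02)

    def test_prior_only_run_reproduces_prior_moments(self):
        """With the likelihood switched off the chain samples the prior."""
        series = ObservedSeries(301.15, 0, np.array([1.0, 2.0, 3.0]),
                                np.array([5, 9, 11], dtype=np.int64),
                                np.full(3, 0.01))
        mu = np.array([0.3, -0.5, 0.1])
        sd = np.array([0.7, 0.4, 1.1])
        fit = fit_mcmc(LikelihoodSpec("DEMOG"), series, n0=100,
                       chain=ChainConfig(40000, 0.5, 1000, seed=11),
                       prior_only=True, prior=(mu, sd))
        draws = fit.draws
        # MC error on the mean of ~1000 correlated draws: use a generous 5x band
        for k in range(3):
            assert abs(draws[:, k].mean() - mu[k]) < 0.25 * sd[k]
            assert draws[:, k].std(ddof=1) == pytest.approx(sd[k], rel=0.35)

    def test_retains_at_least_1000_draws(self, small_dataset):
        group = small_dataset.at_temperature(small_dataset.temperatures[0])
        fit = fit_mcmc(LikelihoodSpec("DEMOG_SAMP"), group, n0=100,
                       chain=ChainConfig(2500, 0.5, 1000, seed=1))
        assert fit.draws.shape[0] >= 1000
        assert "normality_pvalue" in fit.diagnostics


class TestIndirectEA:
    @staticmethod
    def fits_from_values(temps_k, values, ses, family="PHEN"):
        out = []
        for T, v, s in zip(temps_k, values, ses):
            out.append(FitResult(
                spec=LikelihoodSpec("PHEN"), engine="mle",
                param_names=("log_r", "log_K", "log_sigma"),
                params={"log_r": v, "log_K": v}, se={"log_r": s, "log_K": s},
                temperature=T,
            ))
        return out

    def test_exact_log_r_recovery_machine_precision(self):
        """Noiseless log r from the Arrhenius law: E_A back to ~1e-12."""
        ea = 0.67
        temps = np.array([291.15, 296.15, 301.15])
        vals = [-(ea / KB) * (1 / T - 1 / 301.15) + np.log(1.0) for T in temps]
        est = indirect_ea(self.fits_from_values(temps, vals, [0.1] * 3), "r")
        assert est.mean == pytest.approx(ea, rel=1e-10)
        assert est.se == pytest.approx(0.0, abs=1e-8)

    def test_exact_log_k_sign_convention(self):
        ea = 0.4
        temps = np.array([291.15, 296.15, 301.15])
        vals = [np.log(10000.0) + (ea / KB) * (1 / T - 1 / 301.15) for T in temps]
        est = indirect_ea(self.fits_from_values(temps, vals, [0.1] * 3), "K")
        assert est.mean == pytest.approx(ea, rel=1e-10)

    def test_weighted_regression_matches_wls_oracle(self, rng):
        """Noisy estimates with known SEs: matches a hand-coded WLS solution."""
        ea, temps = 0.8, np.array([291.15, 293.15, 296.15, 298.15, 301.15])
        ses = np.array([0.05, 0.2, 0.05, 0.3, 0.1])
        x = 1.0 / (KB * temps)
        y = -ea * x + 3.0 + rng.normal(0, ses)
        est = indirect_ea(self.fits_from_values(temps, y, ses), "r")
        # hand-coded weighted least squares
        w = 1.0 / ses**2
        X = np.column_stack([np.ones_like(x), x])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        cov = np.linalg.inv(X.T @ W @ X)
        s2 = ((y - X @ beta) ** 2 * w).sum() / (len(y) - 2)
        assert est.mean == pytest.approx(-beta[1], rel=1e-9)
        assert est.se == pytest.approx(np.sqrt(s2 * cov[1, 1]), rel=1e-9)
        assert est.intercept == pytest.approx(beta[0], rel=1e-9)

    def test_t0_invariance(self):
        """The regression never sees T0: estimates are invariant to it."""
        ea, temps = 0.5, np.array([291.15, 296.15, 301.15])
        for T0 in (296.15, 301.15, 310.0):
            vals = [-(ea / KB) * (1 / T - 1 / T0) for T in temps]
            est = indirect_ea(self.fits_from_values(temps, vals, [0.1] * 3), "r")
            assert est.mean == pytest.approx(ea, rel=1e-10)

    def test_insufficient_temperatures_error(self):
        fits = self.fits_from_values([291.15, 301.15], [0.1, 0.2], [0.1, 0.1])
        with pytest.raises(ValueError, match="insufficient temperatures"):
            indirect_ea(fits, "r")

    def test_failed_fits_excluded_with_warning(self):
        temps = np.array([291.15, 294.15, 297.15, 301.15])
        fits = self.fits_from_values(temps, [0.5, 0.4, 0.3, 0.2], [0.1] * 4)
        fits[1] = FitResult(spec=LikelihoodSpec("PHEN"), engine="mle",
                            param_names=(), params={}, se={}, status="failed",
                            reason="x", temperature=294.15)
        with pytest.warns(UserWarning, match="excluding temperature"):
            est = indirect_ea(fits, "r")
        assert est.n_temperatures == 3


class TestDirectEA:
    def test_single_temperature_unidentifiable(self, ref_model):
        design = ExperimentalDesign(temperatures=(301.15,), reps=2,
                                    sample_times=(3.0, 6.0, 9.0), frac_samp=0.01)
        ds = simulate_design(ref_model, design, seed=3)
        with pytest.raises(ValueError, match="2 temperatures"):
            direct_ea(ds, corrected=True)

    def test_recovers_shared_ea(self, small_dataset):
        est = direct_ea(small_dataset, corrected=True,
                        chain=ChainConfig(6000, 0.5, 1000, seed=21))
        assert est.ci95[0] < 0.6 < est.ci95[1] or abs(est.mean - 0.6) < 0.1

    def test_two_ea_recovery(self):
        """Distinct growth-rate and carrying-capacity activation energies are
        separated by the two-E_A direct model."""
        model = ArrheniusModel.from_r_k(1.5, 1.0, 0.5, e_a_r=0.8, e_a_k=0.3)
        design = ExperimentalDesign.from_levels(6, 3, 10, 0.01)
        ds = simulate_design(model, design, seed=3)
        est_r, est_k = direct_ea(ds, corrected=True, two_ea=True,
                                 chain=ChainConfig(8000, 0.5, 1000, seed=5))
        assert est_r.mean == pytest.approx(0.8, abs=0.12)
        assert est_k.mean == pytest.approx(0.3, abs=0.15)
        assert est_r.mean - est_k.mean > 0.2


class TestRunMethod:
    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown method"):
            run_method("M11", small_dataset)

    def test_m1_on_noiseless_data_recovers_ea(self, ref_model):
        """Deterministic counts at 3 temperatures: indirect phen-MLE is exact."""
        ea, f, times = 0.6, 1.0, np.arange(1.0, 16.0)
        series = []
        for T in (291.15, 296.15, 301.15):
            lp = derive_logistic(scale_model(ref_model, T), n0=100.0)
            counts = np.rint(f * logistic_mean(times, lp)).astype(np.int64)
            series.append(ObservedSeries(T, 0, times, counts, np.full(15, f)))
        ds = Dataset(series=series, n0=100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = run_method("M1", ds, chain=ChainConfig(seed=0))
        assert est.mean == pytest.approx(ea, abs=0.02)

    def test_shared_fits_match_separate_runs(self, small_dataset):
        """M5 and M6 from one batch equal separately dispatched runs."""
        cfg = ChainConfig(3000, 0.5, 1000, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            batch = run_methods(["M5", "M6"], small_dataset, chain=cfg)
            solo = run_method("M5", small_dataset, chain=cfg)
        assert batch["M5"].mean == pytest.approx(solo.mean, rel=1e-12)
        assert batch["M5"].source == "r" and batch["M6"].source == "K"

    def test_m5_m7_differ_only_through_variance_term(self, small_dataset):
        cfg = ChainConfig(3000, 0.5, 1000, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_methods(["M5", "M7"], small_dataset, chain=cfg)
        assert out["M5"].mean != out["M7"].mean  # same data, different likelihood
        assert out["M5"].source == out["M7"].source == "r"

    def test_all_ten_methods_return_estimates(self, small_dataset):
        cfg = ChainConfig(2500, 0.5, 1000, seed=17)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_methods([f"M{i}" for i in range(1, 11)], small_dataset,
                              chain=cfg)
        finite = {m: e for m, e in out.items() if not isinstance(e, Exception)}
        # MLE variants may legitimately fail with NA variance; MCMC ones must not
        for m in ("M5", "M6", "M7", "M8", "M9", "M10"):
            assert m in finite, f"{m} failed: {out[m]}"
            assert np.isfinite(finite[m].mean) and finite[m].se >= 0
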