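"""Activation-energy estimators: MLE and MCMC engines, indirect and direct methods.

Ten named methods are supported, following the convention

=========  ============  =========  ======  ==========
method     likelihood    scope      engine  source
=========  ============  =========  ======  ==========
M1 / M2    PHEN          indirect   MLE     r / K
M3 / M4    DEMOG         indirect   MLE     r / K
M5 / M6    DEMOG         indirect   MCMC    r / K
M7 / M8    DEMOG_SAMP    indirect   MCMC    r / K
M9         DEMOG         direct     MCMC    joint
M10        DEMOG_SAMP    direct     MCMC    joint
=========  ============  =========  ======  ==========

Indirect methods fit each temperature separately and regress the log of the
chosen logistic parameter (r or K) on the inverse thermal energy 1/(kB*T);
the activation energy is minus (for r) or plus (for K) the regression slope.
Direct methods fit all temperatures jointly with E_A an explicit parameter.
All free parameters are optimized/sampled on the log scale (enforcing
positivity); the two-activation-energy variant of M10 samples E_A,K on the
natural scale so the carrying-capacity scaling may be flat or inverted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import _kernels
from ._kernels import DT_DEFAULT
from .core import KB, ArrheniusModel, T0_DEFAULT
from .likelihoods import (
    LikelihoodSpec,
    loglik_phen,
    pack_dataset,
    pack_group,
)
from .simulate import Dataset, ObservedSeries

__all__ = [
    "METHOD_TABLE",
    "ChainConfig",
    "FitResult",
    "EAEstimate",
    "fit_mle",
    "fit_mcmc",
    "indirect_ea",
    "direct_ea",
    "run_method",
    "extract_log_param",
]

#: method id -> (family, engine, scope, source)
METHOD_TABLE: dict[str, tuple[str, str, str, str]] = {
    "M1": ("PHEN", "mle", "indirect", "r"),
    "M2": ("PHEN", "mle", "indirect", "K"),
    "M3": ("DEMOG", "mle", "indirect", "r"),
    "M4": ("DEMOG", "mle", "indirect", "K"),
    "M5": ("DEMOG", "mcmc", "indirect", "r"),
    "M6": ("DEMOG", "mcmc", "indirect", "K"),
    "M7": ("DEMOG_SAMP", "mcmc", "indirect", "r"),
    "M8": ("DEMOG_SAMP", "mcmc", "indirect", "K"),
    "M9": ("DEMOG", "mcmc", "direct", "joint"),
    "M10": ("DEMOG_SAMP", "mcmc", "direct", "joint"),
}


@dataclass(frozen=True)
class ChainConfig:
    """Random-walk Metropolis settings.

    ``n_iter`` total iterations, the first ``burn_frac`` discarded (step size
    is adapted toward 20--40% acceptance during burn-in only), and the
    post-burn-in chain thinned to ``n_keep`` retained draws.
    """

    n_iter: int = 20000
    burn_frac: float = 0.5
    n_keep: int = 1000
    seed: int = 0

    @property
    def n_burn(self) -> int:
        return int(self.n_iter * self.burn_frac)

    def __post_init__(self) -> None:
        if self.n_iter - self.n_burn < self.n_keep:
            raise ValueError("post-burn-in chain shorter than n_keep")


@dataclass
class FitResult:
    """Point estimates (log scale), uncertainties, and draws for one fit."""

    spec: LikelihoodSpec
    engine: str  # "mle" | "mcmc"
    param_names: tuple[str, ...]
    params: dict[str, float]
    se: dict[str, float]
    status: str = "ok"  # ok | failed | na-variance
    reason: str | None = None
    temperature: float | None = None
    loglik: float = np.nan
    cov: np.ndarray | None = None
    draws: np.ndarray | None = None  # (n_keep, dim), log scale
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status == "failed" and not self.reason:
            raise ValueError("failed fits must carry a machine-readable reason")
        if self.engine == "mcmc" and self.status == "ok":
            if self.draws is None or len(self.draws) < 1000:
                raise ValueError("MCMC results must retain >= 1000 draws")


@dataclass
class EAEstimate:
    """Activation-energy estimate: mean and standard error in eV."""

    mean: float
    se: float
    method_id: str
    source: str  # "r" | "K" | "joint"
    intercept: float | None = None
    ci95: tuple[float, float] | None = None
    n_temperatures: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.se) and self.se < 0:
            raise ValueError("se must be >= 0")
        if self.ci95 is None and np.isfinite(self.se):
            self.ci95 = (self.mean - 1.96 * self.se, self.mean + 1.96 * self.se)


# ----------------------------------------------------------------------------
# crude data-driven initializers (also used as weakly-informative prior centers)
# ----------------------------------------------------------------------------

def _crude_r_k(series_list, n0: float, N: float) -> tuple[float, float]:
    """Rough (r, K) from the pooled scaled counts of one temperature group.

    K from the mean of the last two sampling occasions rescaled by 1/f; r from
    the early-time slope of log abundance.  Values are clipped to a broad
    plausible range -- they only center the priors / start the optimizer.
    """
    times = np.concatenate([s.times for s in series_list])
    scaled = np.concatenate([s.counts / s.frac_samp for s in series_list])
    order = np.argsort(times)
    times, scaled = times[order], scaled[order]
    uniq = np.unique(times)
    late = np.isin(times, uniq[-2:]) if len(uniq) >= 2 else slice(None)
    k_hat = float(np.clip(np.mean(scaled[late]), max(10.0, 2.0 * n0), 5.0 * N))
    # early phase: observations below half the plateau
    early = scaled < 0.5 * k_hat
    r_hat = 1.0
    if np.sum(early) >= 2 and len(np.unique(times[early])) >= 2:
        y = np.log(np.maximum(scaled[early], 1.0))
        slope = np.polyfit(times[early], y, 1)[0]
        r_hat = float(np.clip(slope, 0.05, 5.0))
    return r_hat, k_hat


def _theta_init(r_hat: float, k_hat: float, N: float) -> np.ndarray:
    """Map (r, K) to log-thetas assuming births ~ 3x deaths at baseline."""
    theta1 = 1.5 * r_hat
    theta3 = 0.5 * r_hat
    theta2 = N * r_hat / (theta1 * k_hat)
    return np.log([theta1, theta2, theta3])


def _is_degenerate(series_list) -> bool:
    return all(np.all(s.counts == 0) for s in series_list)


def _as_list(series) -> list[ObservedSeries]:
    if isinstance(series, ObservedSeries):
        return [series]
    return list(series)


# ----------------------------------------------------------------------------
# maximum likelihood
# ----------------------------------------------------------------------------

def fit_mle(
    spec: LikelihoodSpec,
    series,
    n0: float,
    N: float = 15000,
    n_starts: int = 3,
    seed: int = 0,
    dt: float = DT_DEFAULT,
) -> FitResult:
    """Multi-start local MLE on log-parameters; Wald SEs from the numerical Hessian.

    A non-invertible / non-positive-definite Hessian yields status
    ``na-variance`` (point estimates kept, SEs NaN), the failure mode that in
    practice affects the deterministic-likelihood fits most often.
    """
    if spec.scope != "single":
        raise ValueError("fit_mle supports per-temperature (single) fits only")
    series_list = _as_list(series)
    n_obs = sum(len(s.times[s.times > 0]) for s in series_list)
    names = spec.param_names
    if n_obs < 3:
        return FitResult(spec, "mle", names, {}, {}, status="failed",
                         reason="fewer than 3 observations",
                         temperature=series_list[0].temperature)
    if _is_degenerate(series_list):
        return FitResult(spec, "mle", names, {}, {}, status="failed",
                         reason="degenerate data (all counts zero)",
                         temperature=series_list[0].temperature)

    r_hat, k_hat = _crude_r_k(series_list, n0, N)
    if spec.family == "PHEN":
        counts = np.concatenate([s.counts for s in series_list])
        sigma0 = max(1.0, 0.2 * float(np.max(counts)))
        x_init = np.log([r_hat, k_hat, sigma0])

        def negll(x):
            r, K, sig = np.exp(x)
            return -loglik_phen((r, K, sig), series_list, n0)
    else:
        idx, counts_f, fracs, nstep = pack_group(series_list, dt=dt)
        corrected = spec.corrected
        x_init = _theta_init(r_hat, k_hat, N)

        def negll(x):
            return -_kernels.loglik_group_kernel(
                np.exp(x[0]), np.exp(x[1]), np.exp(x[2]), float(N), float(n0),
                idx, counts_f, fracs, nstep, dt, corrected,
            )

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        x0 = x_init if k == 0 else x_init + rng.normal(0.0, 0.4, size=len(x_init))
        try:
            res = optimize.minimize(
                negll, x0, method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
            )
        except (FloatingPointError, OverflowError):
            continue
        if not np.isfinite(res.fun):
            continue
        if (
            best is None
            or res.fun < best.fun - 1e-12
            or (abs(res.fun - best.fun) <= 1e-12
                and np.linalg.norm(res.x) < np.linalg.norm(best.x))
        ):
            best = res
    if best is None:
        return FitResult(spec, "mle", names, {}, {}, status="failed",
                         reason="optimizer did not converge from any start",
                         temperature=series_list[0].temperature)

    xhat = best.x
    params = dict(zip(names, xhat))
    from statsmodels.tools.numdiff import approx_hess1

    status, reason = "ok", None
    cov = None
    ses = {n: np.nan for n in names}
    try:
        with np.errstate(all="ignore"):
            hess = approx_hess1(xhat, negll)
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.any(~np.isfinite(diag)) or np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive-definite Hessian")
        ses = dict(zip(names, np.sqrt(diag)))
    except (np.linalg.LinAlgError, ValueError):
        status, reason = "na-variance", "non-positive-definite Hessian"
        cov = None
    return FitResult(
        spec, "mle", names, params, ses, status=status, reason=reason,
        temperature=series_list[0].temperature, loglik=-best.fun, cov=cov,
        diagnostics={"n_starts": n_starts, "n_obs": n_obs},
    )


# ----------------------------------------------------------------------------
# MCMC
# ----------------------------------------------------------------------------

def _thin(chain: np.ndarray, n_keep: int) -> np.ndarray:
    idx = np.linspace(0, len(chain) - 1, n_keep).astype(int)
    return chain[idx]


def fit_mcmc(
    spec: LikelihoodSpec,
    data,
    n0: float,
    N: float = 15000,
    chain: ChainConfig = ChainConfig(),
    dt: float = DT_DEFAULT,
    prior_only: bool = False,
    prior: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Adaptive random-walk Metropolis over the spec's free parameters.

    Priors are independent Gaussians on the sampled (log) scale, centered on
    crude data-driven initializers with SD 2 natural-log units unless
    ``prior=(mu, sd)`` overrides them.  ``prior_only=True`` switches the
    likelihood off (sampler sanity checks).  The Gaussianity of the primary
    marginal is recorded as a normality-test p-value in ``diagnostics``.
    """
    names = spec.param_names
    if spec.scope == "single":
        if spec.family == "PHEN":
            raise ValueError("MCMC is not used with the phenomenological likelihood")
        series_list = _as_list(data)
        if _is_degenerate(series_list) and not prior_only:
            return FitResult(spec, "mcmc", names, {}, {}, status="failed",
                             reason="degenerate data (all counts zero)",
                             temperature=series_list[0].temperature)
        idx, counts, fracs, nstep = pack_group(series_list, dt=dt)
        if prior is None:
            r_hat, k_hat = _crude_r_k(series_list, n0, N)
            mu = _theta_init(r_hat, k_hat, N)
            sd = np.full(3, 2.0)
        else:
            mu, sd = np.asarray(prior[0], float), np.asarray(prior[1], float)
        raw, acc = _kernels.chain_group_kernel(
            float(N), float(n0), idx, counts, fracs, nstep, dt, spec.corrected,
            mu.copy(), mu, sd, chain.n_iter, chain.n_burn,
            np.uint32(chain.seed), prior_only,
        )
        temperature = series_list[0].temperature
    elif spec.scope in ("direct", "direct_2ea"):
        dataset: Dataset = data
        if len(dataset.temperatures) < 2:
            raise ValueError("direct fits require a dataset spanning >= 2 temperatures")
        temps, ptr, idx, counts, fracs, nstep = pack_dataset(dataset, dt=dt)
        two_ea = spec.scope == "direct_2ea"
        if prior is None:
            mu, sd = _direct_prior(dataset, n0, N, two_ea)
        else:
            mu, sd = np.asarray(prior[0], float), np.asarray(prior[1], float)
        T0 = dataset.truth.T0 if dataset.truth is not None else T0_DEFAULT
        raw, acc = _kernels.chain_direct_kernel(
            T0, float(N), float(n0), temps, ptr, idx, counts, fracs,
            nstep, dt, spec.corrected, two_ea,
            mu.copy(), mu, sd, chain.n_iter, chain.n_burn,
            np.uint32(chain.seed), prior_only,
        )
        temperature = None
    else:  # pragma: no cover
        raise ValueError(f"unknown scope {spec.scope}")

    if acc < 0.01:
        return FitResult(spec, "mcmc", names, {}, {}, status="failed",
                         reason=f"acceptance rate {acc:.3f} < 1% after adaptation",
                         temperature=temperature,
                         diagnostics={"acceptance": acc})
    draws = _thin(raw, chain.n_keep)
    params = dict(zip(names, draws.mean(axis=0)))
    ses = dict(zip(names, draws.std(axis=0, ddof=1)))
    # normality check on the leading marginal (as used downstream)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm_p = float(stats.normaltest(draws[:, -1]).pvalue)
    return FitResult(
        spec, "mcmc", names, params, ses, temperature=temperature,
        draws=draws,
        diagnostics={"acceptance": float(acc), "normality_pvalue": norm_p},
    )


def _direct_prior(dataset: Dataset, n0, N, two_ea: bool):
    """Prior centers for direct fits: baselines from the warmest temperature,
    activation energies from a crude per-temperature regression."""
    temps = dataset.temperatures
    T0 = dataset.truth.T0 if dataset.truth is not None else T0_DEFAULT
    r_hats, k_hats = [], []
    for T in temps:
        r_hat, k_hat = _crude_r_k(dataset.at_temperature(T), n0, N)
        r_hats.append(r_hat)
        k_hats.append(k_hat)
    x = 1.0 / (KB * temps)
    ea_r = 0.6
    if len(temps) >= 2 and np.ptp(x) > 0:
        ea_r = float(np.clip(-np.polyfit(x, np.log(r_hats), 1)[0], 0.05, 3.0))
    # baseline thetas at T0 from the temperature closest to T0
    j = int(np.argmin(np.abs(temps - T0)))
    delta = 1.0 / temps[j] - 1.0 / T0
    r0 = r_hats[j] * np.exp(ea_r / KB * delta)
    mu3 = _theta_init(float(np.clip(r0, 0.05, 5.0)), k_hats[j], N)
    if two_ea:
        ea_k = 0.0
        if len(temps) >= 2 and np.ptp(x) > 0:
            ea_k = float(np.clip(np.polyfit(x, np.log(k_hats), 1)[0], -3.0, 3.0))
        mu = np.concatenate([mu3, [np.log(ea_r), ea_k]])
        sd = np.array([2.0, 2.0, 2.0, 2.0, 1.0])
    else:
        mu = np.concatenate([mu3, [np.log(ea_r)]])
        sd = np.array([2.0, 2.0, 2.0, 2.0])
    return mu, sd


# ----------------------------------------------------------------------------
# extracting log r / log K from per-temperature fits
# ----------------------------------------------------------------------------

def extract_log_param(fit: FitResult, source: str) -> tuple[float, float]:
    """(estimate, se) of log r or log K from a per-temperature fit.

    PHEN fits carry log r / log K directly; demographic fits derive them from
    the log-thetas -- via the delta method (MLE) or per-draw transformation
    (MCMC).  Returns NaNs when the quantity is undefined (e.g. the posterior
    mass sits at theta1 <= theta3, where r <= 0).
    """
    if source not in ("r", "K"):
        raise ValueError("source must be 'r' or 'K'")
    if fit.status == "failed":
        return np.nan, np.nan
    if fit.spec.family == "PHEN":
        key = "log_r" if source == "r" else "log_K"
        return fit.params.get(key, np.nan), fit.se.get(key, np.nan)
    if fit.engine == "mcmc" and fit.draws is not None:
        th = np.exp(fit.draws)
        r = th[:, 0] - th[:, 2]
        pos = r > 0
        if pos.mean() < 0.5 or pos.sum() < 100:
            return np.nan, np.nan
        if source == "r":
            vals = np.log(r[pos])
        else:
            # K = N (th1 - th3) / (th1 th2); N cancels into the intercept only,
            # but keep it for interpretability of the estimate itself
            N = fit.diagnostics.get("N", 15000)
            vals = np.log(N) + np.log(r[pos]) - fit.draws[pos, 0] - fit.draws[pos, 1]
        return float(vals.mean()), float(vals.std(ddof=1))
    # MLE: delta method on x = (log th1, log th2, log th3)
    th1 = np.exp(fit.params["log_theta1"])
    th3 = np.exp(fit.params["log_theta3"])
    r = th1 - th3
    if r <= 0:
        return np.nan, np.nan
    if source == "r":
        est = np.log(r)
        grad = np.array([th1 / r, 0.0, -th3 / r])
    else:
        N = fit.diagnostics.get("N", 15000)
        est = np.log(N) + np.log(r) - fit.params["log_theta1"] - fit.params["log_theta2"]
        grad = np.array([th1 / r - 1.0, -1.0, -th3 / r])
    if fit.cov is None:
        return float(est), np.nan
    var = float(grad @ fit.cov @ grad)
    return float(est), float(np.sqrt(var)) if var > 0 else np.nan


# ----------------------------------------------------------------------------
# indirect estimator: Arrhenius regression over per-temperature fits
# ----------------------------------------------------------------------------

def indirect_ea(
    fits: list[FitResult],
    source: str,
    method_id: str = "",
    weighted: bool = True,
    max_se: float | None = 2.0,
) -> EAEstimate:
    """Weighted least-squares Arrhenius regression of log r (or log K) on 1/(kB*T).

    E_A is minus the slope for r and plus the slope for K; weights are 1/se^2
    (``weighted=False`` falls back to ordinary least squares).  Fits with
    failed status or undefined values are excluded with a warning; at least
    three usable temperatures are required.

    A regression whose slope SE exceeds ``max_se`` (default 2 eV, the top of
    the plausible metabolic range) carries no information about the
    activation energy and raises a non-identified error, mirroring the
    exclusion of runs without a usable variance from reported summaries.
    Pass ``max_se=None`` to disable the check.
    """
    import statsmodels.api as sm

    temps, ys, ses = [], [], []
    for fit in fits:
        est, se = extract_log_param(fit, source)
        if not np.isfinite(est):
            warnings.warn(
                f"excluding temperature {fit.temperature} from the Arrhenius "
                f"regression (status={fit.status}, reason={fit.reason})",
                stacklevel=2,
            )
            continue
        temps.append(fit.temperature)
        ys.append(est)
        ses.append(se)
    temps, ys, ses = map(np.asarray, (temps, ys, ses))
    has_se = np.isfinite(ses) & (ses > 0)
    if weighted and has_se.sum() >= 3:
        # NA-variance fits carry no weight information: exclude them, as runs
        # without a usable variance are excluded from the reported estimates
        if not has_se.all():
            warnings.warn(
                f"excluding {int((~has_se).sum())} temperature(s) without "
                "usable SEs from the weighted Arrhenius regression",
                stacklevel=2,
            )
        temps, ys, ses = temps[has_se], ys[has_se], ses[has_se]
    elif weighted:
        if len(temps) >= 3:
            warnings.warn(
                "per-temperature SEs unavailable; using unweighted regression",
                stacklevel=2,
            )
        weighted = False
    if len(temps) < 3:
        raise ValueError(
            f"insufficient temperatures for the Arrhenius regression: "
            f"{len(temps)} usable of {len(fits)}"
        )
    x = 1.0 / (KB * temps)
    X = sm.add_constant(x)
    w = 1.0 / ses**2 if weighted else np.ones(len(x))
    res = sm.WLS(ys, X, weights=w).fit()
    slope, slope_se = res.params[1], res.bse[1]
    if max_se is not None and slope_se > max_se:
        raise ValueError(
            f"non-identified estimate: se(E_A) = {slope_se:.2f} eV exceeds "
            f"{max_se} eV (the plausible activation-energy range)"
        )
    sign = -1.0 if source == "r" else 1.0
    return EAEstimate(
        mean=float(sign * slope),
        se=float(slope_se),
        method_id=method_id,
        source=source,
        intercept=float(res.params[0]),
        n_temperatures=int(len(temps)),
        diagnostics={"r_squared": float(res.rsquared) if len(temps) > 2 else np.nan},
    )


# ----------------------------------------------------------------------------
# direct estimator
# ----------------------------------------------------------------------------

def direct_ea(
    dataset: Dataset,
    corrected: bool = False,
    two_ea: bool = False,
    chain: ChainConfig = ChainConfig(),
    dt: float = DT_DEFAULT,
):
    """Joint MCMC fit of all temperatures; E_A summarized from its posterior.

    Returns one :class:`EAEstimate` (source "joint") in the shared-E_A case,
    or a pair ``(estimate_r, estimate_K)`` in the two-activation-energy case.
    The 95% interval is taken from posterior percentiles of the retained draws.
    """
    if len(dataset.temperatures) < 2:
        raise ValueError("direct estimation requires >= 2 temperatures")
    family = "DEMOG_SAMP" if corrected else "DEMOG"
    scope = "direct_2ea" if two_ea else "direct"
    spec = LikelihoodSpec(family, scope)
    fit = fit_mcmc(spec, dataset, n0=dataset.n0, N=dataset.N, chain=chain, dt=dt)
    method_id = "M10" if corrected else "M9"
    if fit.status != "ok":
        raise RuntimeError(f"direct MCMC failed: {fit.reason}")
    if not two_ea:
        ea = np.exp(fit.draws[:, 3])
        lo, hi = np.percentile(ea, [2.5, 97.5])
        return EAEstimate(
            mean=float(ea.mean()), se=float(ea.std(ddof=1)),
            method_id=method_id, source="joint", ci95=(float(lo), float(hi)),
            n_temperatures=len(dataset.temperatures),
            diagnostics=dict(fit.diagnostics),
        )
    ea_r = np.exp(fit.draws[:, 3])
    ea_k = fit.draws[:, 4]
    out = []
    for vals, src in ((ea_r, "r"), (ea_k, "K")):
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out.append(
            EAEstimate(
                mean=float(vals.mean()), se=float(vals.std(ddof=1)),
                method_id=method_id, source=src, ci95=(float(lo), float(hi)),
                n_temperatures=len(dataset.temperatures),
                diagnostics=dict(fit.diagnostics),
            )
        )
    return tuple(out)


# ----------------------------------------------------------------------------
# dispatch
# ----------------------------------------------------------------------------

def _per_temperature_fits(
    family: str,
    engine: str,
    dataset: Dataset,
    chain: ChainConfig,
    dt: float,
    mle_starts: int,
) -> list[FitResult]:
    spec = LikelihoodSpec(family, "single")
    fits = []
    for j, T in enumerate(dataset.temperatures):
        group = dataset.at_temperature(T)
        if engine == "mle":
            fit = fit_mle(spec, group, n0=dataset.n0, N=dataset.N,
                          n_starts=mle_starts, seed=chain.seed + 977 * j, dt=dt)
        else:
            sub = ChainConfig(chain.n_iter, chain.burn_frac, chain.n_keep,
                              seed=(chain.seed + 977 * j) % (2**31))
            fit = fit_mcmc(spec, group, n0=dataset.n0, N=dataset.N,
                           chain=sub, dt=dt)
        fit.diagnostics["N"] = dataset.N
        fits.append(fit)
    return fits


def run_methods(
    method_ids,
    dataset: Dataset,
    chain: ChainConfig | None = None,
    seed: int = 0,
    dt: float = DT_DEFAULT,
    mle_starts: int = 3,
) -> dict[str, "EAEstimate | Exception"]:
    """Run several methods on one dataset, sharing per-temperature fits.

    Methods that differ only in the source parameter (e.g. M5 on r and M6 on
    K use the same per-temperature posterior) reuse one set of fits, so
    paired method comparisons are both cheaper and exactly matched.  Failures
    are returned per method as the raised exception rather than aborting the
    whole batch.
    """
    if chain is None:
        chain = ChainConfig(seed=seed)
    results: dict[str, EAEstimate | Exception] = {}
    fit_cache: dict[tuple[str, str], list[FitResult] | Exception] = {}
    for method_id in method_ids:
        if method_id not in METHOD_TABLE:
            raise ValueError(f"unknown method id {method_id!r}; expected M1..M10")
        family, engine, scope, source = METHOD_TABLE[method_id]
        try:
            if scope == "direct":
                results[method_id] = direct_ea(
                    dataset, corrected=(family == "DEMOG_SAMP"),
                    chain=chain, dt=dt,
                )
                continue
            key = (family, engine)
            if key not in fit_cache:
                try:
                    fit_cache[key] = _per_temperature_fits(
                        family, engine, dataset, chain, dt, mle_starts
                    )
                except Exception as exc:  # noqa: BLE001 -- recorded per method
                    fit_cache[key] = exc
            cached = fit_cache[key]
            if isinstance(cached, Exception):
                raise cached
            results[method_id] = indirect_ea(cached, source=source,
                                             method_id=method_id)
        except Exception as exc:  # noqa: BLE001
            results[method_id] = exc
    return results


def run_method(
    method_id: str,
    dataset: Dataset,
    chain: ChainConfig | None = None,
    seed: int = 0,
    dt: float = DT_DEFAULT,
    mle_starts: int = 3,
) -> EAEstimate:
    """Run one of the ten named methods on a dataset and return its E_A estimate.

    Per-temperature MCMC seeds are derived deterministically from ``seed``
    (or from ``chain.seed`` when a chain config is given).
    """
    out = run_methods([method_id], dataset, chain=chain, seed=seed, dt=dt,
                      mle_starts=mle_starts)[method_id]
    if isinstance(out, Exception):
        raise out
    return out
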