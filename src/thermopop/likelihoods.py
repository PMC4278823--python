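"""Likelihood families for temperature-stratified abundance counts.

Three observation models, all Gaussian on the count scale:

* ``PHEN`` -- phenomenological: counts are iid Gaussian around
  ``f * n(t)`` with the deterministic logistic mean ``n(t)`` and a free
  standard deviation ``sigma``.
* ``DEMOG`` -- demographic: the mean and variance of abundance follow the
  moment (diffusion-approximation) ODEs of the birth--death process; counts
  are Gaussian with mean ``f * m(t)`` and variance ``f^2 * V(t)``.  Sampling
  error is ignored.
* ``DEMOG_SAMP`` -- demographic + sampling correction: adds the Poisson
  sampling variance of the observation layer, giving observation variance
  ``f^2 * V(t) + f * m(t)``.

Direct (multi-temperature) likelihoods sum the chosen per-temperature
likelihood over all series with the rate parameters tied across temperatures
by the Arrhenius model.  Observations within a series are treated as
independent given the moment path (marginal moments only); observations at
t = 0 are excluded by default because the initial abundance is known there
and V(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import DT_DEFAULT, VAR_FLOOR
from .core import ArrheniusModel, BDPParams, LogisticParams
from .simulate import Dataset, ObservedSeries

__all__ = [
    "DT_DEFAULT",
    "VAR_FLOOR",
    "FAMILIES",
    "SCOPES",
    "MomentPath",
    "LikelihoodSpec",
    "moment_odes",
    "loglik_phen",
    "loglik_demog",
    "loglik_corrected",
    "direct_loglik",
]

FAMILIES = ("PHEN", "DEMOG", "DEMOG_SAMP")
SCOPES = ("single", "direct", "direct_2ea")

#: free-parameter layouts (all sampled/optimized coordinates; log scale unless noted)
_PARAM_LAYOUTS = {
    ("PHEN", "single"): ("log_r", "log_K", "log_sigma"),
    ("DEMOG", "single"): ("log_theta1", "log_theta2", "log_theta3"),
    ("DEMOG_SAMP", "single"): ("log_theta1", "log_theta2", "log_theta3"),
    ("DEMOG", "direct"): ("log_theta01", "log_theta02", "log_theta03", "log_e_a"),
    ("DEMOG_SAMP", "direct"): ("log_theta01", "log_theta02", "log_theta03", "log_e_a"),
    # e_a_k is on the natural scale: the case study allows it to be ~0 or negative
    ("DEMOG_SAMP", "direct_2ea"): (
        "log_theta01", "log_theta02", "log_theta03", "log_e_a_r", "e_a_k",
    ),
    ("DEMOG", "direct_2ea"): (
        "log_theta01", "log_theta02", "log_theta03", "log_e_a_r", "e_a_k",
    ),
}


@dataclass(frozen=True)
class MomentPath:
    """Mean and variance of abundance along a time grid."""

    times: np.ndarray
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.var) < 0):
            raise ValueError("variance path must be non-negative")


@dataclass(frozen=True)
class LikelihoodSpec:
    """Which likelihood family and scope a fit uses.

    Only the family/scope combinations used by the ten inference methods are
    valid (phenomenological fits are per-temperature only).
    """

    family: str
    scope: str = "single"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")
        if (self.family, self.scope) not in _PARAM_LAYOUTS:
            raise ValueError(
                f"unsupported likelihood configuration {(self.family, self.scope)}"
            )

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_LAYOUTS[(self.family, self.scope)]

    @property
    def corrected(self) -> bool:
        return self.family == "DEMOG_SAMP"


# ----------------------------------------------------------------------------
# moment ODEs
# ----------------------------------------------------------------------------

def moment_odes(
    params: BDPParams,
    n0: float,
    times,
    dt: float = DT_DEFAULT,
    solver: str = "rk4",
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> MomentPath:
    """Integrate the mean/variance ODEs of the birth--death process.

    dm/dt = B(m) - D(m);  dV/dt = 2 V (B'(m) - D'(m)) + B(m) + D(m)
    with B(n) = theta1 n (1 - theta2 n / N) and D(n) = theta3 n.

    ``solver="rk4"`` (default) uses the fixed-step kernel shared with the
    likelihoods; ``solver="lsoda"`` uses scipy's stiff-safe adaptive
    integrator with the given tolerances.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0) or np.any(np.diff(times) <= 0) and times.size > 1:
        raise ValueError("times must be non-negative and strictly increasing")
    if solver == "rk4":
        m, V = _kernels.moment_path_at_times_kernel(
            params.theta1, params.theta2, params.theta3, float(params.N),
            float(n0), times, dt,
        )
        return MomentPath(times=times, mean=m, var=V)
    if solver == "lsoda":
        from scipy.integrate import solve_ivp

        th1, th2, th3, N = params.theta1, params.theta2, params.theta3, params.N

        def rhs(_t, y):
            m, V = y
            B = max(th1 * m * (1.0 - th2 * m / N), 0.0)
            Bp = th1 * (1.0 - 2.0 * th2 * m / N) if B > 0 else 0.0
            D = th3 * m
            return [B - D, 2.0 * V * (Bp - th3) + B + D]

        sol = solve_ivp(
            rhs, (0.0, float(times[-1])), [float(n0), 0.0],
            t_eval=times, method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"moment ODE integration failed: {sol.message}")
        return MomentPath(times=times, mean=sol.y[0], var=np.maximum(sol.y[1], 0.0))
    raise ValueError(f"unknown solver {solver!r}")


# ----------------------------------------------------------------------------
# packing observations for the kernels
# ----------------------------------------------------------------------------

def _as_series_list(series) -> list[ObservedSeries]:
    if isinstance(series, ObservedSeries):
        return [series]
    return list(series)


def pack_group(
    series, dt: float = DT_DEFAULT, include_t0: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Concatenate series at one temperature into kernel arrays.

    Returns (times_idx, counts, fracs, nstep); observation times are snapped
    to the RK4 grid of spacing ``dt``.
    """
    ts, cs, fs = [], [], []
    for s in _as_series_list(series):
        keep = np.ones(len(s), dtype=bool) if include_t0 else s.times > 0
        ts.append(s.times[keep])
        cs.append(s.counts[keep])
        fs.append(s.frac_samp[keep])
    times = np.concatenate(ts) if ts else np.empty(0)
    counts = np.concatenate(cs).astype(np.float64) if cs else np.empty(0)
    fracs = np.concatenate(fs) if fs else np.empty(0)
    idx = np.rint(times / dt).astype(np.int64)
    if times.size and np.any(np.abs(idx * dt - times) > dt / 2 + 1e-12):
        raise ValueError("observation times do not lie on the likelihood time grid")
    nstep = int(idx.max()) if idx.size else 1
    return idx, counts, fracs, max(nstep, 1)


def pack_dataset(
    dataset: Dataset, dt: float = DT_DEFAULT, include_t0: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Pack a multi-temperature dataset into CSR-style kernel arrays.

    Returns (temps, group_ptr, times_idx, counts, fracs, nstep).
    """
    temps = dataset.temperatures
    ptr = [0]
    all_idx, all_counts, all_fracs = [], [], []
    nstep = 1
    for T in temps:
        idx, counts, fracs, ns = pack_group(
            dataset.at_temperature(T), dt=dt, include_t0=include_t0
        )
        all_idx.append(idx)
        all_counts.append(counts)
        all_fracs.append(fracs)
        ptr.append(ptr[-1] + len(idx))
        nstep = max(nstep, ns)
    return (
        temps.astype(np.float64),
        np.asarray(ptr, dtype=np.int64),
        np.concatenate(all_idx),
        np.concatenate(all_counts),
        np.concatenate(all_fracs),
        nstep,
    )


# ----------------------------------------------------------------------------
# log-likelihoods
# ----------------------------------------------------------------------------

def loglik_phen(params, series, n0: float, include_t0: bool = False) -> float:
    """Phenomenological log-likelihood; ``params = (r, K, sigma)``, sigma > 0."""
    r, K, sigma = params
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    ll = 0.0
    for s in _as_series_list(series):
        keep = np.ones(len(s), dtype=bool) if include_t0 else s.times > 0
        ll += _kernels.loglik_phen_kernel(
            float(r), float(K), float(sigma), float(n0),
            s.times[keep], s.counts[keep].astype(np.float64), s.frac_samp[keep],
        )
    return float(ll)


def _loglik_moment(params, series, n0, dt, corrected, include_t0):
    idx, counts, fracs, nstep = pack_group(series, dt=dt, include_t0=include_t0)
    return float(
        _kernels.loglik_group_kernel(
            params.theta1, params.theta2, params.theta3, float(params.N),
            float(n0), idx, counts, fracs, nstep, dt, corrected,
        )
    )


def loglik_demog(
    params: BDPParams, series, n0: float,
    dt: float = DT_DEFAULT, include_t0: bool = False,
) -> float:
    """Demographic log-likelihood: Gaussian(f*m(t), f^2*V(t)), no sampling error."""
    return _loglik_moment(params, series, n0, dt, False, include_t0)


def loglik_corrected(
    params: BDPParams, series, n0: float,
    dt: float = DT_DEFAULT, include_t0: bool = False,
) -> float:
    """Sampling-corrected log-likelihood: variance f^2*V(t) + f*m(t)."""
    return _loglik_moment(params, series, n0, dt, True, include_t0)


def direct_loglik(
    model: ArrheniusModel, dataset: Dataset, corrected: bool = False,
    dt: float = DT_DEFAULT, include_t0: bool = False,
) -> float:
    """Joint log-likelihood over all temperatures with Arrhenius-tied rates.

    The per-theta activation energies come from ``model.e_a`` (a shared value
    or a triple, e.g. built via ``ArrheniusModel.from_r_k``), so the same
    entry point serves the shared-E_A and the two-activation-energy variants.
    """
    if dataset.n0 is None:
        raise ValueError("dataset must carry n0 for the direct likelihood")
    temps, ptr, idx, counts, fracs, nstep = pack_dataset(
        dataset, dt=dt, include_t0=include_t0
    )
    ltheta0 = np.log([model.theta01, model.theta02, max(model.theta03, 1e-300)])
    eas = np.asarray(model.e_a_triple, dtype=float)
    return float(
        _kernels.direct_loglik_kernel(
            ltheta0, eas, temps, model.T0, float(model.N), float(dataset.n0),
            ptr, idx, counts, fracs, nstep, dt, corrected,
        )
    )
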