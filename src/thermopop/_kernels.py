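"""Numba-compiled kernels: exact simulation, moment ODEs, likelihoods, samplers.

Everything in this module works on plain numpy arrays so it can be jitted;
the public modules wrap these kernels with the domain types.  Observation
times are represented as indices into a fixed RK4 time grid of spacing
``dt`` (observation times are snapped to the nearest grid point; with the
default ``dt = 0.0125`` day all design-preset times lie exactly on the grid).
"""

from __future__ import annotations

import numpy as np
from numba import njit

KB = 8.617333262e-5

#: default RK4 step (days) for the moment ODEs
DT_DEFAULT = 0.0125

#: floor on observation variances (counts^2); guards t ~ 0 where V(0) = 0
VAR_FLOOR = 1e-6

LOG2PI = float(np.log(2.0 * np.pi))


# ----------------------------------------------------------------------------
# exact stochastic simulation
# ----------------------------------------------------------------------------

@njit(cache=True)
def gillespie_kernel(theta1, theta2, theta3, N, n0, horizon, seed):
    """Exact sample path of the birth--death process up to ``horizon`` days.

    Returns (event_times, sizes) with the initial state at t=0 in slot 0.
    Birth propensity theta1*n*(1 - theta2*n/N) (clamped at 0), death
    propensity theta3*n; absorbing at n=0.
    """
    np.random.seed(seed)
    cap = 4096
    times = np.empty(cap)
    sizes = np.empty(cap, dtype=np.int64)
    times[0] = 0.0
    sizes[0] = n0
    k = 1
    t = 0.0
    n = n0
    while n > 0:
        b = theta1 * n * (1.0 - theta2 * n / N)
        if b < 0.0:
            b = 0.0
        d = theta3 * n
        tot = b + d
        if tot <= 0.0:
            break
        t += np.random.exponential(1.0 / tot)
        if t > horizon:
            break
        if np.random.random() * tot < b:
            n += 1
        else:
            n -= 1
        if k >= cap:
            cap *= 2
            nt = np.empty(cap)
            ns = np.empty(cap, dtype=np.int64)
            nt[:k] = times[:k]
            ns[:k] = sizes[:k]
            times = nt
            sizes = ns
        times[k] = t
        sizes[k] = n
        k += 1
    return times[:k], sizes[:k]


# ----------------------------------------------------------------------------
# moment (diffusion-approximation) ODEs
# ----------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _moment_deriv(m, V, theta1, theta2, theta3, N):
    B = theta1 * m * (1.0 - theta2 * m / N)
    if B < 0.0:
        B = 0.0
        Bp = 0.0
    else:
        Bp = theta1 * (1.0 - 2.0 * theta2 * m / N)
    D = theta3 * m
    dm = B - D
    dV = 2.0 * V * (Bp - theta3) + B + D
    return dm, dV


@njit(cache=True)
def moment_path_kernel(theta1, theta2, theta3, N, n0, nstep, dt):
    """Fixed-step RK4 integration of the mean/variance ODEs on a uniform grid.

    Returns arrays (m, V) of length nstep+1 with node i at time i*dt.
    """
    m = np.empty(nstep + 1)
    V = np.empty(nstep + 1)
    mm = n0
    vv = 0.0
    m[0] = mm
    V[0] = vv
    for i in range(nstep):
        k1m, k1v = _moment_deriv(mm, vv, theta1, theta2, theta3, N)
        k2m, k2v = _moment_deriv(mm + 0.5 * dt * k1m, vv + 0.5 * dt * k1v,
                                 theta1, theta2, theta3, N)
        k3m, k3v = _moment_deriv(mm + 0.5 * dt * k2m, vv + 0.5 * dt * k2v,
                                 theta1, theta2, theta3, N)
        k4m, k4v = _moment_deriv(mm + dt * k3m, vv + dt * k3v,
                                 theta1, theta2, theta3, N)
        mm += dt * (k1m + 2.0 * k2m + 2.0 * k3m + k4m) / 6.0
        vv += dt * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0
        if mm < 0.0:
            mm = 0.0
        if vv < 0.0:
            vv = 0.0
        m[i + 1] = mm
        V[i + 1] = vv
    return m, V


@njit(cache=True)
def moment_path_at_times_kernel(theta1, theta2, theta3, N, n0, times, dt):
    """RK4 integration of the moment ODEs, landing exactly on arbitrary times.

    Steps of size <= dt; each requested output time is hit with a shortened
    final step, so off-grid times carry no snapping error.
    """
    m_out = np.empty(times.shape[0])
    v_out = np.empty(times.shape[0])
    mm = n0
    vv = 0.0
    t = 0.0
    for j in range(times.shape[0]):
        target = times[j]
        while t < target - 1e-12:
            h = dt if t + dt <= target else target - t
            k1m, k1v = _moment_deriv(mm, vv, theta1, theta2, theta3, N)
            k2m, k2v = _moment_deriv(mm + 0.5 * h * k1m, vv + 0.5 * h * k1v,
                                     theta1, theta2, theta3, N)
            k3m, k3v = _moment_deriv(mm + 0.5 * h * k2m, vv + 0.5 * h * k2v,
                                     theta1, theta2, theta3, N)
            k4m, k4v = _moment_deriv(mm + h * k3m, vv + h * k3v,
                                     theta1, theta2, theta3, N)
            mm += h * (k1m + 2.0 * k2m + 2.0 * k3m + k4m) / 6.0
            vv += h * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0
            if mm < 0.0:
                mm = 0.0
            if vv < 0.0:
                vv = 0.0
            t += h
        m_out[j] = mm
        v_out[j] = vv
    return m_out, v_out


# ----------------------------------------------------------------------------
# likelihood kernels (one temperature group: all series share one moment path)
# ----------------------------------------------------------------------------

@njit(cache=True)
def loglik_group_kernel(theta1, theta2, theta3, N, n0, times_idx, counts, fracs,
                        nstep, dt, corrected):
    """Gaussian log-likelihood of counts at one temperature.

    Observation mean f*m(t); variance f^2*V(t), plus the Poisson sampling
    variance f*m(t) when ``corrected``.
    """
    m, V = moment_path_kernel(theta1, theta2, theta3, N, n0, nstep, dt)
    ll = 0.0
    for j in range(times_idx.shape[0]):
        i = times_idx[j]
        f = fracs[j]
        mu = f * m[i]
        var = f * f * V[i]
        if corrected:
            var += mu
        if var < VAR_FLOOR:
            var = VAR_FLOOR
        resid = counts[j] - mu
        ll += -0.5 * (LOG2PI + np.log(var) + resid * resid / var)
    return ll


@njit(cache=True)
def loglik_phen_kernel(r, K, sigma, n0, times, counts, fracs):
    """Gaussian iid log-likelihood around the deterministic logistic mean."""
    ll = 0.0
    s2 = sigma * sigma
    for j in range(times.shape[0]):
        if r == 0.0:
            mean_n = n0
        else:
            ert = np.exp(r * times[j])
            mean_n = K * n0 * ert / (K + n0 * (ert - 1.0))
        resid = counts[j] - fracs[j] * mean_n
        ll += -0.5 * (LOG2PI + np.log(s2) + resid * resid / s2)
    return ll


@njit(cache=True)
def direct_loglik_kernel(ltheta0, eas, temps, T0, N, n0, group_ptr,
                         times_idx, counts, fracs, nstep, dt, corrected):
    """Sum of per-temperature log-likelihoods with rates tied by Arrhenius scaling.

    ``ltheta0``: log baseline thetas at T0 (length 3); ``eas``: per-theta
    activation energies (length 3); ``temps``: Kelvin, one per group;
    ``group_ptr``: CSR-style pointers into the concatenated observation arrays.
    """
    ll = 0.0
    for g in range(temps.shape[0]):
        delta = 1.0 / temps[g] - 1.0 / T0
        th1 = np.exp(ltheta0[0] - eas[0] / KB * delta)
        th2 = np.exp(ltheta0[1] - eas[1] / KB * delta)
        th3 = np.exp(ltheta0[2] - eas[2] / KB * delta)
        lo, hi = group_ptr[g], group_ptr[g + 1]
        ll += loglik_group_kernel(th1, th2, th3, N, n0,
                                  times_idx[lo:hi], counts[lo:hi], fracs[lo:hi],
                                  nstep, dt, corrected)
    return ll


# ----------------------------------------------------------------------------
# adaptive random-walk Metropolis samplers (log posterior = log lik + log prior)
# ----------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _log_prior(x, prior_mu, prior_sd):
    lp = 0.0
    for k in range(x.shape[0]):
        z = (x[k] - prior_mu[k]) / prior_sd[k]
        lp += -0.5 * z * z
    return lp


@njit(cache=True)
def chain_group_kernel(N, n0, times_idx, counts, fracs, nstep, dt, corrected,
                       x0, prior_mu, prior_sd, n_iter, n_burn, seed,
                       prior_only):
    """Adaptive RW-Metropolis over x = (log theta1, log theta2, log theta3).

    Step size is adapted every 100 iterations during burn-in toward ~30%
    acceptance and frozen afterwards.  Returns (post-burn chain, acceptance
    rate after burn-in).
    """
    np.random.seed(seed)
    dim = x0.shape[0]
    x = x0.copy()
    if prior_only:
        ll = 0.0
    else:
        ll = loglik_group_kernel(np.exp(x[0]), np.exp(x[1]), np.exp(x[2]), N, n0,
                                 times_idx, counts, fracs, nstep, dt, corrected)
    lp = ll + _log_prior(x, prior_mu, prior_sd)
    step = 0.1
    out = np.empty((n_iter - n_burn, dim))
    acc_window = 0
    acc_post = 0
    for it in range(n_iter):
        prop = x + step * np.random.standard_normal(dim)
        if prior_only:
            llp = 0.0
        else:
            llp = loglik_group_kernel(np.exp(prop[0]), np.exp(prop[1]),
                                      np.exp(prop[2]), N, n0,
                                      times_idx, counts, fracs, nstep, dt,
                                      corrected)
        lpp = llp + _log_prior(prop, prior_mu, prior_sd)
        if np.log(np.random.random()) < lpp - lp:
            x = prop
            lp = lpp
            acc_window += 1
            if it >= n_burn:
                acc_post += 1
        if it < n_burn and (it + 1) % 100 == 0:
            rate = acc_window / 100.0
            step *= np.exp(0.66 * (rate - 0.3))
            if step < 1e-4:
                step = 1e-4
            elif step > 10.0:
                step = 10.0
            acc_window = 0
        if it >= n_burn:
            out[it - n_burn] = x
    n_post = n_iter - n_burn
    return out, acc_post / max(n_post, 1)


@njit(cache=True)
def chain_direct_kernel(T0, N, n0, temps, group_ptr, times_idx, counts, fracs,
                        nstep, dt, corrected, two_ea,
                        x0, prior_mu, prior_sd, n_iter, n_burn, seed,
                        prior_only):
    """Adaptive RW-Metropolis for the direct (multi-temperature) likelihood.

    Shared-E_A mode (``two_ea`` false): x = (ltheta01, ltheta02, ltheta03,
    log E_A).  Two-E_A mode: x = (ltheta01, ltheta02, ltheta03, log E_A,r,
    E_A,K) with E_A,K on the natural scale so it may be negative.
    """
    np.random.seed(seed)
    dim = x0.shape[0]
    x = x0.copy()
    eas = np.empty(3)

    def _fill_eas(xv, eas_out):
        if two_ea:
            ear = np.exp(xv[3])
            eas_out[0] = ear
            eas_out[1] = xv[4]
            eas_out[2] = ear
        else:
            ea = np.exp(xv[3])
            eas_out[0] = ea
            eas_out[1] = ea
            eas_out[2] = ea

    _fill_eas(x, eas)
    if prior_only:
        ll = 0.0
    else:
        ll = direct_loglik_kernel(x[:3], eas, temps, T0, N, n0, group_ptr,
                                  times_idx, counts, fracs, nstep, dt, corrected)
    lp = ll + _log_prior(x, prior_mu, prior_sd)
    step = 0.1
    out = np.empty((n_iter - n_burn, dim))
    acc_window = 0
    acc_post = 0
    for it in range(n_iter):
        prop = x + step * np.random.standard_normal(dim)
        _fill_eas(prop, eas)
        if prior_only:
            llp = 0.0
        else:
            llp = direct_loglik_kernel(prop[:3], eas, temps, T0, N, n0,
                                       group_ptr, times_idx, counts, fracs,
                                       nstep, dt, corrected)
        lpp = llp + _log_prior(prop, prior_mu, prior_sd)
        if np.log(np.random.random()) < lpp - lp:
            x = prop
            lp = lpp
            acc_window += 1
            if it >= n_burn:
                acc_post += 1
        if it < n_burn and (it + 1) % 100 == 0:
            rate = acc_window / 100.0
            step *= np.exp(0.66 * (rate - 0.3))
            if step < 1e-4:
                step = 1e-4
            elif step > 10.0:
                step = 10.0
            acc_window = 0
        if it >= n_burn:
            out[it - n_burn] = x
    n_post = n_iter - n_burn
    return out, acc_post / max(n_post, 1)
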