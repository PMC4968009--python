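"""Maximum-likelihood fitting of aperiodic movement models.

The periodicity test compares an observed periodogram peak against
periodograms simulated from a fitted aperiodic model — the null
hypothesis "there is no periodic pattern of space use".  This module
supplies that null: exact Gaussian log-likelihoods for BM, OU, IOU, and
OUF at arbitrary (possibly irregular) observation times, numeric
maximization on log-scale parameters, and small-sample information-
criterion (AICc) selection among families.

Likelihood conventions
----------------------
Coordinates are modeled as independent dimensions with shared
parameters.  Stationary families (OU, OUF) use the full likelihood,
including the stationary density of the first fix, with the location
mean profiled out per dimension (its conditional MLE is substituted
analytically).  Non-stationary families (BM, IOU) condition on the first
fix, which absorbs the location; IOU initializes the latent velocity at
its stationary distribution.  Latent-velocity families are evaluated with
a forward Kalman recursion over the state (position, velocity) with the
position observed exactly; fully observed families reduce to products of
one-step conditional densities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .movement_sim import (
    MovementModelSpec,
    iou_transition,
    ou_transition,
    ouf_transition,
)
from .track_model import TrackSeries

__all__ = ["FittedModel", "gaussian_loglik", "fit_model", "select_model"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FittedModel:
    """A fitted aperiodic movement model and its selection score."""

    spec: MovementModelSpec
    loglik: float
    aicc: float
    n_params: int
    n_records: int
    mean: np.ndarray | None = None
    converged: bool = True

    def __str__(self):
        s = self.spec
        bits = [f"family={s.family}", f"sigma={s.sigma:.6g}"]
        if s.tau_pos is not None:
            bits.append(f"tau_pos={s.tau_pos:.6g}")
        if s.tau_vel is not None:
            bits.append(f"tau_vel={s.tau_vel:.6g}")
        bits += [f"loglik={self.loglik:.4f}", f"aicc={self.aicc:.4f}"]
        return "FittedModel(" + ", ".join(bits) + ")"


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected information criterion."""
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# Exact log-likelihoods
# ---------------------------------------------------------------------------

def _profile_ll(nu: np.ndarray, nu1: np.ndarray, s: np.ndarray):
    """Profiled-mean Gaussian loglik from innovations.

    ``nu`` (n, K) are zero-mean-filter innovations of the data, ``nu1``
    (n,) those of the all-ones series, ``s`` (n,) innovation variances.
    The location mean enters innovations linearly, so its MLE and the
    profiled likelihood are closed-form.
    """
    inv_s = 1.0 / s
    b = (nu1**2 * inv_s).sum()
    c = (nu * (nu1 * inv_s)[:, None]).sum(axis=0)
    ssr = (nu**2 * inv_s[:, None]).sum(axis=0) - c**2 / b
    n = s.size
    ll = -0.5 * (n * _LOG2PI + np.log(s).sum() + ssr).sum()
    return ll, c / b


def _ou_loglik(times, x, sigma, tau):
    dts = np.diff(times)
    phi = np.exp(-dts / tau)
    s = np.concatenate([[sigma], sigma * (1.0 - phi**2)])
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        return -math.inf, None
    nu = np.concatenate([x[:1], x[1:] - phi[:, None] * x[:-1]])
    nu1 = np.concatenate([[1.0], 1.0 - phi])
    return _profile_ll(nu, nu1, s)


def _bm_loglik(times, x, sigma):
    dts = np.diff(times)
    d = np.diff(x, axis=0)
    s = sigma * dts
    ll = -0.5 * (
        x.shape[1] * (np.log(2.0 * np.pi * s)).sum()
        + (d**2 / s[:, None]).sum()
    )
    return ll, None


def _latent_steps(times, family, params):
    """Per-interval transition coefficients for (position, velocity) filters."""
    dts = np.diff(times)
    uniq = np.unique(dts)
    if family == "IOU":
        sigma, tau_v = params
        eta2 = sigma / (2.0 * tau_v)
        table = {d: iou_transition(tau_v, eta2, d) for d in uniq}
        pv0 = eta2
    else:
        sigma, tau_p, tau_v = params
        table = {d: ouf_transition(tau_p, tau_v, sigma, d) for d in uniq}
        pv0 = sigma / (tau_p * tau_v)
    return dts, table, pv0


def _latent_loglik(times, x, family, params, profile_mean):
    """Kalman loglik for latent-velocity families (IOU conditioned on the
    first fix; OUF stationary with optional mean profiling).

    With the position observed exactly, the filtered covariance collapses
    each step to a scalar velocity variance, so the gain/variance
    sequence is computed by a cheap scalar recursion and the innovation
    recursion reduces to a first-order linear filter (run at C speed on
    even grids).
    """
    n, k = x.shape
    dts, table, pv = _latent_steps(times, family, params)
    for _, q in table.values():
        if not np.all(np.isfinite(q)) or q[0, 0] < 0 or q[1, 1] < 0:
            return -math.inf, None

    m = n - 1  # number of transition steps
    p00 = np.empty(m)
    p01 = np.empty(m)
    p10 = np.empty(m)
    p11 = np.empty(m)
    s_arr = np.empty(m)
    k1_arr = np.empty(m)
    single = len(table) == 1
    j = 0
    for d in dts:
        phi, q = table[d]
        f00, f01 = phi[0, 0], phi[0, 1]
        f10, f11 = phi[1, 0], phi[1, 1]
        pp00 = f01 * f01 * pv + q[0, 0]
        pp01 = f01 * f11 * pv + q[0, 1]
        pp11 = f11 * f11 * pv + q[1, 1]
        if pp00 <= 0 or not math.isfinite(pp00):
            return -math.inf, None
        k1 = pp01 / pp00
        pv_new = max(pp11 - pp01 * k1, 0.0)
        p00[j], p01[j], p10[j], p11[j] = f00, f01, f10, f11
        s_arr[j] = pp00
        k1_arr[j] = k1
        converged = single and abs(pv_new - pv) <= 1e-15 * max(pv_new, 1e-300)
        pv = pv_new
        j += 1
        if converged:  # gain has reached steady state: fill the remainder
            p00[j:], p01[j:] = f00, f01
            p10[j:], p11[j:] = f10, f11
            s_arr[j:] = pp00
            k1_arr[j:] = k1
            break

    cols = x if not profile_mean else np.hstack([x, np.ones((n, 1))])
    # velocity estimate recursion: v_j = a_j v_{j-1} + u_j
    a = p11 - k1_arr * p01
    u = (
        (p10 - k1_arr * p00)[:, None] * cols[:-1]
        + k1_arr[:, None] * cols[1:]
    )
    # The gain sequence converges geometrically on even grids; once a_j is
    # constant the recursion is a first-order linear filter (C speed).
    if m:
        tol = 1e-13 * max(1.0, abs(a[-1]))
        off = np.flatnonzero(np.abs(a - a[-1]) >= tol)
        jc = int(off[-1]) + 1 if off.size else 0
    else:
        jc = 0
    v_prev = np.empty((m, cols.shape[1]))
    v = np.zeros(cols.shape[1])
    for j in range(jc):
        v_prev[j] = v
        v = a[j] * v + u[j]
    if jc < m:
        v_prev[jc] = v
        if jc + 1 < m:
            out, _ = signal.lfilter(
                [1.0], [1.0, -a[-1]], u[jc:-1], axis=0,
                zi=(a[-1] * v)[None, :],
            )
            v_prev[jc + 1:] = out
    nu = cols[1:] - p00[:, None] * cols[:-1] - p01[:, None] * v_prev

    if family == "IOU":  # first fix conditioned away; no mean parameter
        ll = -0.5 * (
            k * (m * _LOG2PI + np.log(s_arr).sum())
            + (nu[:, :k] ** 2 / s_arr[:, None]).sum()
        )
        return ll, None
    sigma = params[0]
    s_full = np.concatenate([[sigma], s_arr])
    nu_full = np.vstack([cols[:1], nu])  # prior mean 0 at the first fix
    if profile_mean:
        return _profile_ll(nu_full[:, :k], nu_full[:, k], s_full)
    ll = -0.5 * (
        k * (n * _LOG2PI + np.log(s_full).sum())
        + (nu_full**2 / s_full[:, None]).sum()
    )
    return ll, None


def gaussian_loglik(track: TrackSeries, spec: MovementModelSpec) -> float:
    """Exact Gaussian log-likelihood of a track under an aperiodic model.

    The location mean is profiled out per dimension for stationary
    families; degenerate parameters yield ``-inf``.
    """
    if spec.mean is not None:
        raise ValueError("the null model is aperiodic; spec.mean must be None")
    x = track.coords
    t = track.times
    fam = spec.family
    if fam == "OU":
        if track.n < 1:
            raise ValueError("empty track")
        ll, _ = _ou_loglik(t, x, spec.sigma, spec.tau_pos)
    elif fam == "BM":
        if track.n < 2:
            raise ValueError("BM likelihood needs >= 2 records")
        ll, _ = _bm_loglik(t, x, spec.sigma)
    elif fam == "IOU":
        if track.n < 2:
            raise ValueError("IOU likelihood needs >= 2 records")
        ll, _ = _latent_loglik(t, x, "IOU", (spec.sigma, spec.tau_vel), False)
    else:
        ll, _ = _latent_loglik(
            t, x, "OUF", (spec.sigma, spec.tau_pos, spec.tau_vel), True
        )
    return float(ll) if np.isfinite(ll) else -math.inf


# ---------------------------------------------------------------------------
# Fitting and selection
# ---------------------------------------------------------------------------

def _fitted(track, spec, ll, mean):
    k = spec.n_params + (track.k if spec.family in ("OU", "OUF") else 0)
    return FittedModel(
        spec=spec,
        loglik=ll,
        aicc=aicc(ll, k, track.n),
        n_params=k,
        n_records=track.n,
        mean=mean,
    )


def _canonical_ouf(log_sigma, log_tp, log_tv):
    tp, tv = math.exp(log_tp), math.exp(log_tv)
    if tp < tv:
        tp, tv = tv, tp
    if tp <= tv:  # exactly equal: nudge apart for the spec invariant
        tp = tv * (1.0 + 1e-6)
    return math.exp(log_sigma), tp, tv


def fit_model(track: TrackSeries, family: str, maxiter: int = 400) -> FittedModel:
    """Fit one family by maximum likelihood.

    Optimization runs on log-scale parameters (variances and timescales
    are positive and span decades) from three fixed starting points with
    timescales at 0.1x, 1x and 10x the median sampling interval; BM has a
    closed-form MLE.  Non-convergence raises, carrying the best iterate
    in the exception message.
    """
    if track.n < 10:
        raise ValueError("need at least 10 records to fit a movement model")
    fam = family.upper().replace("-", "")
    fam = {"OUP": "OU", "OUV": "IOU"}.get(fam, fam)
    t, x = track.times, track.coords
    med = float(np.median(np.diff(t)))
    var0 = float(x.var(axis=0).mean())
    var0 = max(var0, 1e-300)
    bm_rate = float((np.diff(x, axis=0) ** 2
                     / np.diff(t)[:, None]).mean())
    bm_rate = max(bm_rate, 1e-300)

    if fam == "BM":
        ll, _ = _bm_loglik(t, x, bm_rate)
        return _fitted(track, MovementModelSpec("BM", bm_rate), ll, None)

    if fam == "OU":
        def negll(p):
            ll, _ = _ou_loglik(t, x, math.exp(p[0]), math.exp(p[1]))
            return -ll if np.isfinite(ll) else 1e300

        starts = [[math.log(var0), math.log(m * med)] for m in (0.1, 1, 10)]
    elif fam == "IOU":
        def negll(p):
            ll, _ = _latent_loglik(
                t, x, "IOU", (math.exp(p[0]), math.exp(p[1])), False
            )
            return -ll if np.isfinite(ll) else 1e300

        starts = [[math.log(bm_rate), math.log(m * med)] for m in (0.1, 1, 10)]
    elif fam == "OUF":
        def negll(p):
            sig, tp, tv = _canonical_ouf(*p)
            ll, _ = _latent_loglik(t, x, "OUF", (sig, tp, tv), True)
            return -ll if np.isfinite(ll) else 1e300

        starts = [
            [math.log(var0), math.log(m * 10 * med), math.log(m * med)]
            for m in (0.3, 3, 30)
        ]
    else:
        raise ValueError(f"unknown family {family!r}")

    best = None
    ok = False
    for s0 in starts:
        res = optimize.minimize(
            negll, s0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-7},
        )
        ok = ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    if not ok and best.fun >= 1e300:
        raise RuntimeError(
            f"optimizer failed for {fam}; best iterate {best.x} "
            f"(negloglik {best.fun:.6g})"
        )

    p = best.x
    if fam == "OU":
        spec = MovementModelSpec("OU", math.exp(p[0]), tau_pos=math.exp(p[1]))
        ll, mean = _ou_loglik(t, x, spec.sigma, spec.tau_pos)
        # tau below a third of the sampling interval means lag-1
        # correlation < 0.05: effectively the white-noise boundary, where
        # the likelihood is flat in log tau
        if spec.tau_pos < med / 3.0:
            warnings.warn(
                "tau_pos hit the short-timescale boundary (white-noise limit)",
                stacklevel=2,
            )
    elif fam == "IOU":
        spec = MovementModelSpec("IOU", math.exp(p[0]), tau_vel=math.exp(p[1]))
        ll, mean = _latent_loglik(t, x, "IOU", (spec.sigma, spec.tau_vel), False)
    else:
        sig, tp, tv = _canonical_ouf(*p)
        spec = MovementModelSpec("OUF", sig, tau_pos=tp, tau_vel=tv)
        ll, mean = _latent_loglik(t, x, "OUF", (sig, tp, tv), True)
    fit = _fitted(track, spec, float(ll), mean)
    if not ok:
        warnings.warn(f"{fam} fit did not formally converge; using best iterate",
                      stacklevel=2)
        object.__setattr__(fit, "converged", False)
    return fit


def select_model(
    track: TrackSeries, families=("BM", "OU", "IOU", "OUF")
) -> FittedModel:
    """Fit each family and return the lowest-AICc model.

    Ties (within 1e-9) are broken toward the model with fewer parameters.
    """
    if track.n < 20:
        raise ValueError("need at least 20 records for model selection")
    fits = []
    for fam in families:
        try:
            fits.append(fit_model(track, fam))
        except (RuntimeError, ValueError) as err:
            warnings.warn(f"{fam} fit failed: {err}", stacklevel=2)
    if not fits:
        raise RuntimeError("all candidate model fits failed")
    best = min(f.aicc for f in fits)
    cands = [f for f in fits if f.aicc <= best + 1e-9]
    cands.sort(key=lambda f: (f.n_params, f.aicc))
    return cands[0]
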