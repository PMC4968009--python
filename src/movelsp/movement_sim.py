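"""Exact simulators for continuous-time Gaussian movement models.

Four standard aperiodic models serve as background-noise generators and as
null models for periodicity testing:

``BM``
    Brownian motion; ``sigma`` is the diffusion rate (m^2/s per
    dimension), position variance grows linearly, spectrum ~ f^-2.
``OU``
    Ornstein-Uhlenbeck position process (range residency); ``sigma`` is
    the stationary position variance (m^2), ``tau_pos`` the position
    autocorrelation time.  Lorentzian spectrum: flat beyond period
    2*pi*tau_pos, ~ f^-2 below.
``IOU``
    Integrated OU, i.e. autocorrelated velocity with non-stationary
    position (ballistic at short times, diffusive at long times);
    ``sigma`` is the long-time diffusion rate, ``tau_vel`` the velocity
    autocorrelation time.  Spectrum ~ f^-2 at long periods, ~ f^-4 below
    period 2*pi*tau_vel.
``OUF``
    OU position with OU velocity ("foraging"): autocorrelation in both
    position and velocity; stationary.  ``sigma`` is the stationary
    position variance, with position timescale ``tau_pos`` > velocity
    timescale ``tau_vel``.

Simulation is exact: each family is a (possibly two-state) Gaussian
Markov process, so sampling proceeds by the closed-form transition
distribution over each (arbitrary) time interval — no discretization
error.  Dimensions are independent with shared parameters.  An optional
deterministic periodic mean (sinusoid, ellipse, or square loop) is added
afterwards to emulate periodic patterns of space use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .track_model import TrackSeries

__all__ = [
    "PeriodicMean",
    "MovementModelSpec",
    "MissingnessSpec",
    "simulate_track",
    "simulate_batch",
    "apply_missingness",
    "theoretical_lsp",
    "periodic_mean_offsets",
    "ou_transition",
    "iou_transition",
    "ouf_transition",
]

FAMILIES = ("BM", "OU", "IOU", "OUF")


@dataclass(frozen=True)
class PeriodicMean:
    """Deterministic periodic mean component.

    ``amplitude`` may be a scalar (shared) or per-dimension sequence of
    meters.  Waveforms: "sinusoid" (cosine per dimension), "ellipse"
    (cosine/sine quadrature across the first two dimensions), and
    "square_loop" (constant-speed traversal of a square perimeter — a
    non-elliptical repeated pattern that activates harmonic series).
    """

    period: float
    amplitude: float | tuple = 1.0
    waveform: str = "sinusoid"
    phase: float = 0.0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        amp = np.atleast_1d(np.asarray(self.amplitude, float))
        if np.any(amp < 0):
            raise ValueError("amplitude must be >= 0")
        if self.waveform not in ("sinusoid", "ellipse", "square_loop"):
            raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class MovementModelSpec:
    """Family plus variance/timescale parameters of a movement model."""

    family: str
    sigma: float
    tau_pos: float | None = None
    tau_vel: float | None = None
    mean: PeriodicMean | None = None

    def __post_init__(self):
        fam = self.family.upper().replace("-", "")
        aliases = {"OUP": "OU", "OUV": "IOU"}
        fam = aliases.get(fam, fam)
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "family", fam)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if fam in ("OU", "OUF") and (self.tau_pos is None or self.tau_pos <= 0):
            raise ValueError(f"{fam} requires tau_pos > 0")
        if fam in ("IOU", "OUF") and (self.tau_vel is None or self.tau_vel <= 0):
            raise ValueError(f"{fam} requires tau_vel > 0")
        if fam == "OUF" and self.tau_pos <= self.tau_vel:
            raise ValueError("OUF requires tau_pos > tau_vel")

    @property
    def n_params(self) -> int:
        return {"BM": 1, "OU": 2, "IOU": 2, "OUF": 3}[self.family]


@dataclass(frozen=True)
class MissingnessSpec:
    """Structured-missingness generator settings.

    Kinds: "none"; "iid" Bernoulli thinning with retention ``p_keep``;
    "duty_cycle" deterministic blocks of ``on_len`` kept / ``off_len``
    dropped records; "autocorrelated" a copy-or-redraw Markov chain with
    persistence ``p_stay`` and marginal retention ``p_keep``, optionally
    modulated over a cycle (``cycle_period`` seconds, depth
    ``cycle_depth``) to emulate time-of-day-dependent fix failure — the
    mechanism behind artefactual periodicities.
    """

    kind: str = "none"
    p_keep: float = 1.0
    on_len: int = 1
    off_len: int = 1
    p_stay: float = 0.0
    cycle_period: float | None = None
    cycle_depth: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "iid", "duty_cycle", "autocorrelated"):
            raise ValueError(f"unknown missingness kind {self.kind!r}")
        for p in (self.p_keep, self.p_stay, self.cycle_depth):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.on_len < 1 or self.off_len < 1:
            raise ValueError("block lengths must be >= 1")


# ---------------------------------------------------------------------------
# Exact Gaussian transition distributions over an interval dt.
# ---------------------------------------------------------------------------

def ou_transition(tau: float, sigma: float, dt: float):
    """OU position: x' = phi * x + N(0, q), stationary variance sigma."""
    phi = math.exp(-dt / tau)
    return phi, sigma * (1.0 - phi * phi)


def iou_transition(tau_v: float, eta2: float, dt: float):
    """Integrated OU joint transition of (position, velocity).

    ``eta2`` is the stationary velocity variance.  Returns (Phi, Q) for
    the state z = (x, v):  z' = Phi z + N(0, Q).
    """
    th = dt / tau_v
    e = math.exp(-th)
    phi = np.array([[1.0, tau_v * (1.0 - e)], [0.0, e]])
    var_i = eta2 * tau_v**2 * (2.0 * th - 3.0 + 4.0 * e - e * e)
    cov = eta2 * tau_v * (1.0 - e) ** 2
    var_v = eta2 * (1.0 - e * e)
    q = np.array([[var_i, cov], [cov, var_v]])
    return phi, q


def _ouf_stationary_cov(tau_p: float, tau_v: float, sigma: float):
    return np.diag([sigma, sigma / (tau_p * tau_v)])


def ouf_transition(tau_p: float, tau_v: float, sigma: float, dt: float):
    """OUF joint transition of (position, velocity), stationary process.

    The state obeys a second-order linear SDE with characteristic rates
    1/tau_p and 1/tau_v; the transition matrix is the matrix exponential,
    written in closed form for distinct rates, and the innovation
    covariance follows from stationarity: Q = S - Phi S Phi'.
    """
    a, b = 1.0 / tau_p, 1.0 / tau_v
    ea, eb = math.exp(-a * dt), math.exp(-b * dt)
    if abs(a - b) > 1e-9 * (a + b):
        d = a - b
        phi = np.array(
            [
                [(a * eb - b * ea) / d, (eb - ea) / d],
                [a * b * (ea - eb) / d, (a * ea - b * eb) / d],
            ]
        )
    else:  # nearly repeated rate: (1 + r dt) e^{-r dt} limit
        r = 0.5 * (a + b)
        er = math.exp(-r * dt)
        phi = np.array(
            [
                [(1.0 + r * dt) * er, dt * er],
                [-r * r * dt * er, (1.0 - r * dt) * er],
            ]
        )
    s = _ouf_stationary_cov(tau_p, tau_v, sigma)
    q = s - phi @ s @ phi.T
    return phi, q


def _chol2(q: np.ndarray):
    """Cholesky factor of a 2x2 covariance, tolerant of tiny negatives."""
    l11 = math.sqrt(max(q[0, 0], 0.0))
    l21 = q[0, 1] / l11 if l11 > 0 else 0.0
    l22 = math.sqrt(max(q[1, 1] - l21 * l21, 0.0))
    return l11, l21, l22


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_batch(
    spec: MovementModelSpec,
    grid_times,
    k: int = 1,
    n_series: int = 1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate ``n_series`` independent tracks at the given times.

    Returns an array of shape (n_series, n_times, k).  All series and
    dimensions are independent with shared parameters; the deterministic
    periodic mean (if any) is added to every series.  Sampling is exact
    via the per-interval Gaussian transition distributions.
    """
    times = np.asarray(grid_times, float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("grid_times must be a non-empty vector")
    if np.any(np.diff(times) <= 0):
        raise ValueError("grid_times must be strictly increasing")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = times.size
    b = n_series * k
    dts = np.diff(times)
    uniq = np.unique(dts)
    fam = spec.family
    out = np.empty((n, b))

    if fam == "BM":
        out[0] = 0.0
        if n > 1:
            incr = rng.standard_normal((n - 1, b)) * np.sqrt(
                spec.sigma * dts
            )[:, None]
            out[1:] = np.cumsum(incr, axis=0)
    elif fam == "OU":
        trans = {d: ou_transition(spec.tau_pos, spec.sigma, d) for d in uniq}
        x = rng.standard_normal(b) * math.sqrt(spec.sigma)
        out[0] = x
        for j, d in enumerate(dts):
            phi, q = trans[d]
            x = phi * x + math.sqrt(q) * rng.standard_normal(b)
            out[j + 1] = x
    else:
        if fam == "IOU":
            eta2 = spec.sigma / (2.0 * spec.tau_vel)
            trans = {d: iou_transition(spec.tau_vel, eta2, d) for d in uniq}
            x = np.zeros(b)
            v = rng.standard_normal(b) * math.sqrt(eta2)
        else:  # OUF
            trans = {
                d: ouf_transition(spec.tau_pos, spec.tau_vel, spec.sigma, d)
                for d in uniq
            }
            s = _ouf_stationary_cov(spec.tau_pos, spec.tau_vel, spec.sigma)
            x = rng.standard_normal(b) * math.sqrt(s[0, 0])
            v = rng.standard_normal(b) * math.sqrt(s[1, 1])
        chols = {d: _chol2(q) for d, (_, q) in trans.items()}
        out[0] = x
        for j, d in enumerate(dts):
            phi, _ = trans[d]
            l11, l21, l22 = chols[d]
            z1 = rng.standard_normal(b)
            z2 = rng.standard_normal(b)
            if fam == "IOU":  # position increment, not position, is Markov
                dx = phi[0, 1] * v + l11 * z1
                v = phi[1, 1] * v + l21 * z1 + l22 * z2
                x = x + dx
            else:
                x_new = phi[0, 0] * x + phi[0, 1] * v + l11 * z1
                v = phi[1, 0] * x + phi[1, 1] * v + l21 * z1 + l22 * z2
                x = x_new
            out[j + 1] = x

    out = out.reshape(n, n_series, k).transpose(1, 0, 2)
    if spec.mean is not None:
        out += periodic_mean_offsets(spec.mean, times, k)[None]
    return out


def simulate_track(
    spec: MovementModelSpec,
    grid_times,
    k: int = 1,
    seed: int | np.random.Generator = 0,
    track_id: str = "sim",
) -> TrackSeries:
    """Simulate one track; see :func:`simulate_batch` for the model math."""
    coords = simulate_batch(spec, grid_times, k=k, n_series=1, seed=seed)[0]
    return TrackSeries(id=track_id, times=np.asarray(grid_times, float),
                       coords=coords)


def periodic_mean_offsets(mean: PeriodicMean, times, k: int) -> np.ndarray:
    """Deterministic periodic displacement per time and dimension."""
    times = np.asarray(times, float)
    amp = np.atleast_1d(np.asarray(mean.amplitude, float))
    if amp.size == 1:
        amp = np.full(k, amp[0])
    if amp.size != k:
        raise ValueError("amplitude must be scalar or length-K")
    theta = 2.0 * np.pi * times / mean.period + mean.phase
    out = np.zeros((times.size, k))
    if mean.waveform == "sinusoid":
        out[:] = amp[None, :] * np.cos(theta)[:, None]
    elif mean.waveform == "ellipse":
        if k < 2:
            raise ValueError("ellipse waveform needs at least 2 dimensions")
        out[:, 0] = amp[0] * np.cos(theta)
        out[:, 1] = amp[1] * np.sin(theta)
    else:  # square_loop: constant-speed traversal of a square perimeter
        u = (theta / (2.0 * np.pi)) % 1.0
        sx = np.empty_like(u)
        sy = np.empty_like(u)
        seg = np.minimum((u * 4).astype(int), 3)
        r = u * 4 - seg
        for s, (fx, fy) in enumerate(
            [
                (lambda r: np.ones_like(r), lambda r: 1 - 2 * r),
                (lambda r: 1 - 2 * r, lambda r: -np.ones_like(r)),
                (lambda r: -np.ones_like(r), lambda r: -1 + 2 * r),
                (lambda r: -1 + 2 * r, lambda r: np.ones_like(r)),
            ]
        ):
            m = seg == s
            sx[m] = fx(r[m])
            sy[m] = fy(r[m])
        out[:, 0] = amp[0] * sx
        if k >= 2:
            out[:, 1] = amp[1] * sy
    return out


def apply_missingness(
    track: TrackSeries, mspec: MissingnessSpec, seed: int | np.random.Generator = 0
) -> TrackSeries:
    """Drop records according to a structured-missingness scheme.

    Periodic or autocorrelated gaps transfer structure from the sampling
    schedule into the gridded signal, which is how spurious periodogram
    peaks arise even for aperiodic movement.
    """
    n = track.n
    if mspec.kind == "none":
        return track
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if mspec.kind == "iid":
        keep = rng.random(n) < mspec.p_keep
    elif mspec.kind == "duty_cycle":
        cycle = mspec.on_len + mspec.off_len
        keep = (np.arange(n) % cycle) < mspec.on_len
    else:  # autocorrelated copy-or-redraw chain
        t0 = track.times[0]
        if mspec.cycle_period:
            p = mspec.p_keep + mspec.cycle_depth * np.cos(
                2.0 * np.pi * (track.times - t0) / mspec.cycle_period
            )
            p = np.clip(p, 0.01, 0.99)
        else:
            p = np.full(n, mspec.p_keep)
        u_copy = rng.random(n)
        u_draw = rng.random(n)
        keep = np.empty(n, dtype=bool)
        keep[0] = u_draw[0] < p[0]
        for j in range(1, n):
            if u_copy[j] < mspec.p_stay:
                keep[j] = keep[j - 1]
            else:
                keep[j] = u_draw[j] < p[j]
    if keep.sum() < 3:
        raise ValueError("missingness scheme retained fewer than 3 records")
    return TrackSeries(track.id, track.times[keep], track.coords[keep],
                       track.dim_names)


def theoretical_lsp(spec: MovementModelSpec, freqs) -> np.ndarray:
    """Two-sided continuous spectral density of an aperiodic model.

    Shapes (log power vs log period): BM has slope 2 everywhere; OU is
    flat beyond period 2*pi*tau_pos and slope 2 below; IOU has slope 2 at
    long periods and 4 below period 2*pi*tau_vel; OUF combines all three
    regimes.  Asymptote pairs intersect at period 2*pi*tau.  The absolute
    scale is the continuous-time density (m^2 s); a gridded periodogram's
    expectation is approximately this divided by its sampling interval.
    """
    if spec.mean is not None:
        warnings.warn("theoretical spectrum covers the aperiodic component only",
                      stacklevel=2)
    f = np.asarray(freqs, float)
    w2 = (2.0 * np.pi * f) ** 2
    fam = spec.family
    if fam == "BM":
        return spec.sigma / w2
    if fam == "OU":
        tp = spec.tau_pos
        return 2.0 * spec.sigma * tp / (1.0 + w2 * tp**2)
    if fam == "IOU":
        tv = spec.tau_vel
        return spec.sigma / (w2 * (1.0 + w2 * tv**2))
    tp, tv = spec.tau_pos, spec.tau_vel
    return (2.0 * spec.sigma * (tp + tv)
            / ((1.0 + w2 * tp**2) * (1.0 + w2 * tv**2)))
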