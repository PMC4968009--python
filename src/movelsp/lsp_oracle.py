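"""Exact least-squares Lomb-Scargle reference implementation.

At each frequency f the data are fit, by weighted least squares, to

    X(t) ~ A(f) e^{2 pi i f t} + A(f)* e^{-2 pi i f t}

and the periodogram value is half the energy explained by the fit:

    LSP(f) = 1/2 ( sum_j w_j X_j^2  -  min_A L(f) )

with L the weighted squared error.  Nothing here assumes an even time
grid: the fit runs at the true record times, which makes this the
certifying reference for the O(N log N) FFT algorithm and for its
grid-snapping approximation.  Complexity is O(N) per frequency, so use
above N ~ 1e4 is discouraged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lsp_core import FrequencyGrid, Periodogram

__all__ = ["LSQFit", "lsq_fit", "lsq_lsp"]

_CHUNK = 256  # frequencies per vectorized block


@dataclass(frozen=True)
class LSQFit:
    """Least-squares sinusoid fit at a single frequency.

    ``amplitude`` holds the complex A(f) per dimension, ``cost`` the
    residual weighted squared error per dimension, and ``power`` the
    periodogram value per dimension.
    """

    frequency: float
    amplitude: np.ndarray
    cost: np.ndarray
    power: np.ndarray


def _center(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    mean = (weights[:, None] * values).sum(axis=0) / weights.sum()
    return values - mean


def _solve_block(times, values, weights, freqs):
    """Normal-equation solve for a block of frequencies.

    Returns (a, b, power) with model a*cos + b*sin per dimension;
    A = (a - i b)/2.  Near-singular systems (schedule degeneracies such as
    the Nyquist frequency of an even grid) use the minimum-norm solution;
    fully degenerate ones yield zero power with a warning.
    """
    theta = 2.0 * np.pi * freqs[:, None] * times[None, :]  # (F, N)
    c = np.cos(theta)
    s = np.sin(theta)
    wc = weights * c
    ws = weights * s
    cc = (wc * c).sum(axis=1)
    ss = (ws * s).sum(axis=1)
    cs = (wc * s).sum(axis=1)
    xc = wc @ values  # (F, K)
    xs = ws @ values
    det = cc * ss - cs**2
    scale = (cc + ss) ** 2
    ok = det > 1e-12 * scale
    det_safe = np.where(ok, det, 1.0)
    # standard 2x2 inverse, vectorized over frequencies and dimensions
    a = np.where(ok[:, None], (ss[:, None] * xc - cs[:, None] * xs) / det_safe[:, None], 0.0)
    b = np.where(ok[:, None], (cc[:, None] * xs - cs[:, None] * xc) / det_safe[:, None], 0.0)
    if np.any(~ok):
        for i in np.flatnonzero(~ok):
            g = np.array([[cc[i], cs[i]], [cs[i], ss[i]]])
            rhs = np.vstack([xc[i], xs[i]])
            if np.abs(g).max() <= 0:
                warnings.warn(
                    f"singular sinusoid fit at f={freqs[i]:g}; power set to 0",
                    stacklevel=3,
                )
                continue
            sol, *_ = np.linalg.lstsq(g, rhs, rcond=None)
            a[i], b[i] = sol[0], sol[1]
    power = 0.5 * (a * xc + b * xs)
    return a, b, power


def lsq_lsp(times, values, weights, freqs) -> Periodogram:
    """Lomb-Scargle periodogram by direct least squares at exact times.

    Parameters
    ----------
    times : array, shape (n,)
        Record times in seconds (need not be evenly spaced).
    values : array, shape (n, K)
        Coordinates; centered internally by the weighted mean per
        dimension (same centering as the fast algorithm).
    weights : array, shape (n,)
        0/1 schedule weights.
    freqs : array, shape (F,)
        Frequencies (1/s) at which to evaluate.
    """
    times = np.asarray(times, float)
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] != times.size:
        values = values.T
    weights = np.asarray(weights, float)
    freqs = np.atleast_1d(np.asarray(freqs, float))
    if weights.sum() < 3:
        raise ValueError("need at least 3 weighted records")
    values = _center(values, weights)

    power = np.empty((freqs.size, values.shape[1]))
    for lo in range(0, freqs.size, _CHUNK):
        hi = min(lo + _CHUNK, freqs.size)
        *_, p = _solve_block(times, values, weights, freqs[lo:hi])
        power[lo:hi] = p

    nyq = float(freqs[-1])
    df = float(freqs[1] - freqs[0]) if freqs.size > 1 else nyq
    fgrid = FrequencyGrid(freqs=freqs, nyquist=max(nyq, freqs[-1]), df=df)
    return Periodogram(
        freqs=fgrid,
        power_by_dim=power,
        n_effective=int(weights.sum()),
        meta={"kind": "lsq_oracle"},
    )


def lsq_fit(times, values, weights, frequency: float) -> LSQFit:
    """Full least-squares fit at one frequency (amplitude, cost, power)."""
    times = np.asarray(times, float)
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] != times.size:
        values = values.T
    weights = np.asarray(weights, float)
    values = _center(values, weights)
    a, b, power = _solve_block(times, values, weights, np.array([frequency]))
    a, b, power = a[0], b[0], power[0]
    theta = 2.0 * np.pi * frequency * times
    model = np.outer(np.cos(theta), a) + np.outer(np.sin(theta), b)
    cost = (weights[:, None] * (values - model) ** 2).sum(axis=0)
    return LSQFit(
        frequency=frequency,
        amplitude=0.5 * (a - 1j * b),
        cost=cost,
        power=power,
    )
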