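"""Fast FFT-based Lomb-Scargle periodogram for gappy, gridded telemetry.

The Lomb-Scargle periodogram (LSP) at frequency f equals a least-squares
fit of the data to sinusoids of frequency f, and therefore tolerates
missing records.  Once the records sit on an even grid with schedule
function w, the LSP can be written entirely in terms of discrete Fourier
transforms of w and of the gridded signal wX:

    LSP(f) = [ W0 |P(f)|^2 - Re( conj(W(2f)) P(f)^2 ) ]
             / [ W0^2 - |W(2f)|^2 ]

with W = DFT{w}, W0 = W(0) = sum(w), and P = DFT{wX}.  Both transforms
are evaluated with a single zero-padded FFT so that f and 2f lie on the
transform grid, giving O(N log N) complexity.  When no data are missing
(w == 1) the schedule transform vanishes at every positive frequency and
the LSP reduces to the classical DFT periodogram.

For a K-dimensional signal the periodogram is computed per dimension and
combined as the arithmetic mean over dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .track_model import SampleGrid

__all__ = [
    "FrequencyGrid",
    "Periodogram",
    "SpectralSummary",
    "frequency_grid",
    "fast_lsp",
    "dft_periodogram",
    "schedule_periodogram",
    "prewhitened_lsp",
    "average_periodograms",
    "fit_loglog_slope",
    "combine_individuals",
    "local_maxima",
    "classify_harmonics",
    "weighted_center",
]

#: Eq-denominator floor, relative to W0^2: below this the direct
#: least-squares solution is used instead of the FFT formula.
_DENOM_FLOOR = 1e-12


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing positive frequencies (1/s), f = 0 excluded.

    ``nyquist`` = 1/(2 dt) is the largest detectable frequency,
    ``df`` = 1/(n dt) the base resolution, and ``res_freq`` the
    oversampling factor: grid spacing is df / res_freq.
    """

    freqs: np.ndarray
    nyquist: float
    df: float
    res_freq: int = 1

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("freqs must be a non-empty vector")
        if f[0] <= 0 or np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing and positive")
        if f[-1] > self.nyquist * (1 + 1e-12):
            raise ValueError("frequencies exceed the Nyquist frequency")
        object.__setattr__(self, "freqs", f)

    @property
    def periods(self) -> np.ndarray:
        return 1.0 / self.freqs


@dataclass(frozen=True)
class Periodogram:
    """Per-dimension and combined spectral power on a frequency grid."""

    freqs: FrequencyGrid
    power_by_dim: np.ndarray  # (n_freqs, K)
    n_effective: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.power_by_dim, dtype=float))
        if p.shape[0] != self.freqs.freqs.size:
            p = p.T
        if p.shape[0] != self.freqs.freqs.size:
            raise ValueError("power_by_dim rows must match frequency grid")
        object.__setattr__(self, "power_by_dim", p)

    @property
    def power(self) -> np.ndarray:
        """Combined power: arithmetic mean over dimensions."""
        return self.power_by_dim.mean(axis=1)

    @property
    def k(self) -> int:
        return self.power_by_dim.shape[1]


@dataclass(frozen=True)
class SpectralSummary:
    """Local maxima of a periodogram, sorted by descending power."""

    peak_periods: np.ndarray
    peak_powers: np.ndarray
    fundamental: float

    def __post_init__(self):
        pp = np.asarray(self.peak_periods, dtype=float)
        pw = np.asarray(self.peak_powers, dtype=float)
        if pp.shape != pw.shape:
            raise ValueError("periods and powers must align")
        if pp.size and not np.isclose(self.fundamental, pp[np.argmax(pw)]):
            raise ValueError("fundamental must be the period of the global maximum")
        object.__setattr__(self, "peak_periods", pp)
        object.__setattr__(self, "peak_powers", pw)


def weighted_center(w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Subtract the schedule-weighted mean per dimension; zeros stay zero."""
    w = np.asarray(w, float)
    x = np.asarray(x, float)
    mean = (w[:, None] * x).sum(axis=0) / w.sum()
    return w[:, None] * (x - mean)


def frequency_grid(grid: SampleGrid, res_freq: int = 1) -> FrequencyGrid:
    """Frequencies k * df / res_freq for k = 1 .. res_freq*N/2, capped at Nyquist.

    f = 0 is excluded (the least-squares problem is degenerate there and the
    mean is removed anyway).  ``res_freq`` > 1 refines the frequency spacing
    below the base resolution df = 1/(N dt); beyond res_freq the data carry
    no new information and the periodogram merely smooths.
    """
    res_freq = int(res_freq)
    if res_freq < 1:
        raise ValueError("res_freq must be >= 1")
    nyq = 1.0 / (2.0 * grid.dt)
    df = 1.0 / (grid.n * grid.dt)
    kmax = (res_freq * grid.n) // 2
    freqs = np.arange(1, kmax + 1) * (df / res_freq)
    freqs = freqs[freqs <= nyq * (1 + 1e-12)]
    return FrequencyGrid(freqs=freqs, nyquist=nyq, df=df, res_freq=res_freq)


def _fft_bins(grid: SampleGrid, fgrid: FrequencyGrid):
    """Map grid frequencies to indices of the zero-padded FFT.

    The padded transform has length M = 2 * res_freq * N (rounded up to
    even), so that grid frequency k*df/res_freq sits on bin 2k and its
    double on bin 4k.
    """
    m = 2 * fgrid.res_freq * grid.n
    idx = fgrid.freqs * (m * grid.dt)
    bins = np.rint(idx).astype(int)
    if np.abs(idx - bins).max() > 1e-6:
        raise ValueError(
            "frequency grid is not commensurate with the FFT bins; "
            "build it with frequency_grid() from the same SampleGrid"
        )
    return m, bins


def fast_lsp(grid: SampleGrid, fgrid: FrequencyGrid | None = None) -> Periodogram:
    """FFT-based Lomb-Scargle periodogram of a gridded track.

    The signal is centered by its schedule-weighted mean per dimension
    before transforming.  Frequencies at which the formula's denominator
    W0^2 - |W(2f)|^2 falls below a numeric floor (e.g. exactly at the
    Nyquist frequency of a fully even series) are recomputed with the
    exact least-squares solution.
    """
    if grid.w.sum() < 3:
        raise ValueError("need at least 3 recorded fixes")
    if fgrid is None:
        fgrid = frequency_grid(grid)
    m, bins = _fft_bins(grid, fgrid)
    w = grid.w
    wx = weighted_center(w, grid.wx)
    w0 = w.sum()

    # real-input transforms; DFT{w}(2f) above the fold via conjugate symmetry
    fw = np.fft.rfft(w, n=m)
    fwx = np.fft.rfft(wx, n=m, axis=0)
    p = fwx[bins]                     # DFT{wX}(f),  (n_freqs, K)
    bins2 = (2 * bins) % m
    high = bins2 > m // 2
    w2 = fw[np.where(high, m - bins2, bins2)]
    np.conjugate(w2, where=high, out=w2)

    denom = w0**2 - np.abs(w2) ** 2
    numer = w0 * np.abs(p) ** 2 - np.real(np.conj(w2)[:, None] * p**2)
    bad = denom < _DENOM_FLOOR * w0**2
    denom_safe = np.where(bad, 1.0, denom)
    power = numer / denom_safe[:, None]

    if np.any(bad):
        # degenerate denominator (e.g. the exact Nyquist bin of an even
        # complete series): solve the sinusoid fit's 2x2 normal equations
        # directly; their coefficients are functions of the transforms
        # already computed (minimum-norm solution where singular)
        warnings.warn(
            f"{int(bad.sum())} frequencies had a near-singular denominator; "
            "their power was computed by direct least squares",
            stacklevel=2,
        )
        for i in np.flatnonzero(bad):
            cc = 0.5 * (w0 + w2[i].real)
            ss = 0.5 * (w0 - w2[i].real)
            cs = -0.5 * w2[i].imag
            xc, xs = p[i].real, -p[i].imag
            gram = np.array([[cc, cs], [cs, ss]])
            sol, *_ = np.linalg.lstsq(gram, np.vstack([xc, xs]), rcond=None)
            power[i] = 0.5 * (sol[0] * xc + sol[1] * xs)

    return Periodogram(
        freqs=fgrid,
        power_by_dim=power,
        n_effective=int(w0),
        meta={**grid.meta, "n": grid.n, "dt": grid.dt,
              "sum_w": int(w0), "res_freq": fgrid.res_freq,
              "kind": "lsp"},
    )


def dft_periodogram(grid: SampleGrid, fgrid: FrequencyGrid | None = None) -> Periodogram:
    """Classical DFT periodogram, P(f) = |DFT{X}(f)|^2 / N per dimension.

    Only defined for complete series (w == 1 everywhere); gappy series
    must use :func:`fast_lsp`.
    """
    if not np.all(grid.w == 1):
        raise ValueError("series has missing records; use fast_lsp instead")
    if fgrid is None:
        fgrid = frequency_grid(grid)
    m, bins = _fft_bins(grid, fgrid)
    x = weighted_center(grid.w, grid.wx)
    fx = np.fft.rfft(x, n=m, axis=0)
    power = np.abs(fx[bins]) ** 2 / grid.n
    return Periodogram(
        freqs=fgrid,
        power_by_dim=power,
        n_effective=grid.n,
        meta={**grid.meta, "n": grid.n, "dt": grid.dt,
              "sum_w": grid.n, "res_freq": fgrid.res_freq,
              "kind": "dft"},
    )


def schedule_periodogram(grid: SampleGrid, fgrid: FrequencyGrid | None = None) -> Periodogram:
    """Periodogram of the sampling schedule w itself.

    The schedule is treated as a complete 1-D series on the grid
    (mean-subtracted), so this is its DFT periodogram.  Peaks here reveal
    periodic structure in when fixes were recorded — the raw material of
    artefactual periodicities in the data periodogram.
    """
    if fgrid is None:
        fgrid = frequency_grid(grid)
    sched = SampleGrid(
        t1=grid.t1, dt=grid.dt, n=grid.n,
        w=np.ones(grid.n), wx=grid.w[:, None],
        res_time=grid.res_time,
        meta={**grid.meta, "signal": "schedule"},
    )
    pg = dft_periodogram(sched, fgrid)
    pg.meta["kind"] = "schedule"
    return pg


def prewhitened_lsp(grid: SampleGrid) -> Periodogram:
    """Periodogram with first-difference prewhitening (complete series only).

    The raw rectangular-window periodogram of a steep red spectrum is
    floored by spectral leakage: the Fejer kernel's sidelobes decay only
    as f^-2, so spectra falling faster (integrated-velocity processes
    fall as f^-4) are masked at high frequency.  The classical remedy is
    to difference the series first — the differenced process of a
    non-stationary movement model is (near-)stationary with modest
    variance — and divide the resulting periodogram by the exact transfer
    function of differencing, |1 - e^{-2 pi i f dt}|^2 = 4 sin^2(pi f dt).
    """
    if not np.all(grid.w == 1):
        raise ValueError("prewhitening requires a complete series")
    diff_grid = SampleGrid(
        t1=grid.t1, dt=grid.dt, n=grid.n - 1,
        w=np.ones(grid.n - 1), wx=np.diff(grid.wx, axis=0),
        res_time=grid.res_time, meta=dict(grid.meta),
    )
    pg = dft_periodogram(diff_grid)
    transfer = 4.0 * np.sin(np.pi * pg.freqs.freqs * grid.dt) ** 2
    return Periodogram(
        freqs=pg.freqs,
        power_by_dim=pg.power_by_dim / transfer[:, None],
        n_effective=grid.n,
        meta={**pg.meta, "kind": "prewhitened"},
    )


def average_periodograms(periodograms: list[Periodogram]) -> Periodogram:
    """Plain mean of periodograms on one common frequency grid.

    Used to Monte-Carlo-estimate the expected periodogram of a stochastic
    process from replicate simulations (contrast
    :func:`combine_individuals`, which variance-normalizes heterogeneous
    individuals).
    """
    if not periodograms:
        raise ValueError("no periodograms to average")
    base = periodograms[0]
    for pg in periodograms[1:]:
        if not np.allclose(pg.freqs.freqs, base.freqs.freqs):
            raise ValueError("periodograms must share one frequency grid")
    power = np.mean([pg.power_by_dim for pg in periodograms], axis=0)
    return Periodogram(
        freqs=base.freqs, power_by_dim=power,
        n_effective=base.n_effective,
        meta={**base.meta, "kind": "averaged",
              "n_replicates": len(periodograms)},
    )


def fit_loglog_slope(
    pgram: Periodogram,
    period_min: float,
    period_max: float,
    n_bins: int | None = None,
) -> float:
    """Least-squares slope of log10 power vs log10 period over a band.

    With ``n_bins`` set, power is first averaged within log-spaced period
    bins (each bin's abscissa is the geometric mean of its periods),
    which stabilizes the regression in sparse long-period bands.
    """
    per = pgram.freqs.periods
    sel = (per >= period_min) & (per <= period_max)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 frequencies in the requested band")
    x, y = per[sel], pgram.power[sel]
    if n_bins:
        edges = np.geomspace(x.min() * (1 - 1e-9), x.max() * (1 + 1e-9),
                             n_bins + 1)
        idx = np.digitize(x, edges) - 1
        xs, ys = [], []
        for b in range(n_bins):
            m = idx == b
            if m.any():
                xs.append(np.exp(np.log(x[m]).mean()))
                ys.append(y[m].mean())
        x, y = np.array(xs), np.array(ys)
    design = np.vstack([np.log10(x), np.ones(x.size)]).T
    coef, *_ = np.linalg.lstsq(design, np.log10(y), rcond=None)
    return float(coef[0])


def combine_individuals(periodograms: list[Periodogram]) -> Periodogram:
    """Pool periodograms from individuals sharing the same periodic behavior.

    Each periodogram is normalized by its mean combined power (individuals
    differ in movement variance), interpolated onto the coarsest common
    frequency grid, then averaged with weights proportional to each
    individual's number of recorded fixes.  Pooling augments sample size
    and separates shared periodic patterns from individual noise.
    """
    if not periodograms:
        raise ValueError("no periodograms to combine")
    if len(periodograms) == 1:
        pg = periodograms[0]
        norm = pg.power.mean()
        return Periodogram(pg.freqs, pg.power_by_dim / norm, pg.n_effective,
                           {**pg.meta, "kind": "combined", "n_individuals": 1})
    base = min(periodograms, key=lambda p: p.freqs.freqs.size)
    fmax = min(p.freqs.freqs[-1] for p in periodograms)
    fmin = max(p.freqs.freqs[0] for p in periodograms)
    if fmax < base.freqs.freqs[-1] or fmin > base.freqs.freqs[0]:
        warnings.warn("incompatible frequency ranges; truncating to overlap",
                      stacklevel=2)
    keep = (base.freqs.freqs >= fmin) & (base.freqs.freqs <= fmax)
    freqs = base.freqs.freqs[keep]
    fgrid = FrequencyGrid(freqs=freqs, nyquist=base.freqs.nyquist,
                          df=base.freqs.df, res_freq=base.freqs.res_freq)
    total = 0.0
    acc = np.zeros(freqs.size)
    for pg in periodograms:
        p = pg.power / pg.power.mean()
        pi = np.interp(freqs, pg.freqs.freqs, p)
        acc += pg.n_effective * pi
        total += pg.n_effective
    ids = [p.meta.get("id") for p in periodograms]
    return Periodogram(
        freqs=fgrid,
        power_by_dim=(acc / total)[:, None],
        n_effective=int(total),
        meta={"kind": "combined", "n_individuals": len(periodograms),
              "ids": ids},
    )


def local_maxima(pgram: Periodogram, study_duration: float) -> SpectralSummary:
    """Retain local maxima of the periodogram, merged at the 1/D scale.

    The periodogram's error term oscillates with period 1/D on the
    frequency scale (D = study duration), so raw local maxima closer than
    1/D apart are artefacts of that oscillation; of each such cluster only
    the highest is kept.  Boundary points count as maxima when they exceed
    their single neighbor.
    """
    p = pgram.power
    f = pgram.freqs.freqs
    if p.size == 1:
        is_max = np.array([True])
    else:
        is_max = np.empty(p.size, dtype=bool)
        is_max[0] = p[0] > p[1]
        is_max[-1] = p[-1] > p[-2]
        is_max[1:-1] = (p[1:-1] > p[:-2]) & (p[1:-1] > p[2:])
    cand = np.flatnonzero(is_max)
    if cand.size == 0:  # plateau-only pathological case
        cand = np.array([int(np.argmax(p))])
    order = cand[np.argsort(p[cand])[::-1]]
    kept: list[int] = []
    min_gap = 1.0 / study_duration
    for i in order:
        if all(abs(f[i] - f[j]) >= min_gap for j in kept):
            kept.append(i)
    kept = np.array(kept)
    return SpectralSummary(
        peak_periods=1.0 / f[kept],
        peak_powers=p[kept],
        fundamental=1.0 / f[kept[0]],
    )


def classify_harmonics(summary: SpectralSummary, tolerance: float = 0.05):
    """Label periodogram peaks as harmonics of the fundamental or independent.

    A non-fundamental peak at period T is a harmonic when the fundamental
    period is an integer multiple of T (the ratio within ``tolerance`` of
    an integer, absolutely) and its power lies below the fundamental's.
    Peaks at
    periods that are not integer submultiples of the fundamental — or
    peaks at long periods when a shorter period dominates — indicate a
    multi-periodic signal; otherwise the signal is likely mono-periodic
    with harmonics (non-sinusoidal waveforms always generate harmonic
    series).

    Returns
    -------
    labels : list of str
        One of "fundamental", "harmonic", "independent-period" per peak,
        aligned with ``summary.peak_periods``.
    overall : str
        "mono-periodic" or "multi-periodic".
    """
    if summary.peak_periods.size == 0:
        raise ValueError("no peaks to classify")
    t0 = summary.fundamental
    p0 = summary.peak_powers.max()
    labels = []
    for t, p in zip(summary.peak_periods, summary.peak_powers):
        if np.isclose(t, t0) and np.isclose(p, p0):
            labels.append("fundamental")
            continue
        ratio = t0 / t
        is_int_multiple = ratio >= 1 - tolerance and (
            abs(ratio - round(ratio)) <= tolerance
        )
        if is_int_multiple and p < p0:
            labels.append("harmonic")
        else:
            labels.append("independent-period")
    overall = ("mono-periodic"
               if all(l != "independent-period" for l in labels)
               else "multi-periodic")
    return labels, overall
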