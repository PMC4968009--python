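"""Artefactual-periodicity diagnostics.

Duty-cycled collars and autocorrelated fix failure put periodic structure
into the sampling schedule, and that structure leaks into the data
periodogram even when the movement itself is aperiodic.  The diagnostic
overlays the periodogram of the locations with the periodogram of the
schedule function w, both rescaled to a maximum of zero on the log scale:
a peak occurring at the same period in both is likely artefactual.  The
flag indicates a *risk* of false positive only — a true periodicity can
be superimposed on an artefactual one, so coincidence of peaks does not
prove the absence of a periodic pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .lsp_core import Periodogram

__all__ = [
    "DiagnosticReport",
    "rescale_zero_max",
    "artefact_flag",
    "log_prominence_at",
]

CAVEAT = (
    "A coincident schedule peak indicates risk of an artefactual "
    "periodicity; it does not prove the absence of a true periodic pattern."
)


@dataclass(frozen=True)
class DiagnosticReport:
    """Outcome of the schedule-coincidence diagnostic at one period."""

    period: float
    data_peak: float
    schedule_peak: float
    schedule_peak_is_local_max: bool
    artefact_suspected: bool
    prominence: float
    caveat: str = CAVEAT

    def __post_init__(self):
        if self.artefact_suspected and not self.schedule_peak_is_local_max:
            raise ValueError(
                "artefact can only be suspected at a schedule local maximum"
            )

    def __str__(self):
        verdict = ("ARTEFACT SUSPECTED" if self.artefact_suspected
                   else "no schedule coincidence")
        return (
            f"Diagnostic(period={self.period:g}s, data_peak={self.data_peak:.3f}, "
            f"schedule_peak={self.schedule_peak:.3f}, "
            f"prominence={self.prominence:.3f} decades, {verdict})"
        )


def _log_power(p: np.ndarray) -> np.ndarray:
    """log10 power with exact zeros floored to the smallest positive value."""
    pos = p[p > 0]
    if pos.size == 0:
        raise ValueError("all-zero periodogram cannot be rescaled")
    return np.log10(np.where(p > 0, p, pos.min()))


def rescale_zero_max(pgram: Periodogram) -> Periodogram:
    """Rescale to log10 power with maximum exactly zero.

    The monotone transform preserves peak ordering and makes periodograms
    of different processes (data vs schedule) directly comparable in one
    plot.  The returned periodogram carries the rescaled combined power as
    a single dimension.
    """
    lp = _log_power(pgram.power)
    return Periodogram(
        freqs=pgram.freqs,
        power_by_dim=(lp - lp.max())[:, None],
        n_effective=pgram.n_effective,
        meta={**pgram.meta, "kind": "rescaled-log10"},
    )


def log_prominence_at(
    pgram: Periodogram, period: float, window: float | None = None
) -> float:
    """Prominence (decades) of the strongest local max near 1/period.

    ``window`` is the half-width of the search window on the frequency
    scale; it defaults to the periodogram's base resolution df.  Returns
    0.0 when no local maximum falls inside the window.
    """
    f0 = 1.0 / period
    freqs = pgram.freqs.freqs
    window = pgram.freqs.df if window is None else window
    lp = _log_power(pgram.power)
    peaks, props = signal.find_peaks(lp, prominence=0.0)
    near = np.abs(freqs[peaks] - f0) <= window + 0.5 * pgram.freqs.df / pgram.freqs.res_freq
    if not np.any(near):
        return 0.0
    return float(props["prominences"][near].max())


def artefact_flag(
    data_pgram: Periodogram,
    sched_pgram: Periodogram,
    period: float,
    prominence_threshold: float = 0.5,
) -> DiagnosticReport:
    """Flag a candidate periodicity as potentially schedule-induced.

    The flag is raised when the sampling-schedule periodogram has a local
    maximum within one frequency-resolution step (±df) of 1/period whose
    prominence on the log10 scale reaches ``prominence_threshold``
    decades.  Both periodograms must share the same frequency grid.
    """
    fd, fs = data_pgram.freqs.freqs, sched_pgram.freqs.freqs
    if fd.size != fs.size or not np.allclose(fd, fs):
        raise ValueError("periodograms must share one frequency grid")
    f0 = 1.0 / period
    df = data_pgram.freqs.df
    spacing = df / data_pgram.freqs.res_freq

    data_log = _log_power(data_pgram.power)
    data_log -= data_log.max()
    window = np.abs(fd - f0) <= df + 0.5 * spacing
    if not np.any(window):
        raise ValueError("period falls outside the frequency grid")
    data_peak = float(data_log[window].max())

    if sched_pgram.power.max() <= 0:  # complete schedule: flat, nothing to flag
        return DiagnosticReport(
            period=period, data_peak=data_peak, schedule_peak=-np.inf,
            schedule_peak_is_local_max=False, artefact_suspected=False,
            prominence=0.0,
        )
    sched_log = _log_power(sched_pgram.power)
    sched_log -= sched_log.max()
    sched_peak = float(sched_log[window].max())

    peaks, props = signal.find_peaks(sched_log, prominence=0.0)
    near = np.abs(fs[peaks] - f0) <= df + 0.5 * spacing
    is_local_max = bool(np.any(near))
    prom = float(props["prominences"][near].max()) if is_local_max else 0.0
    return DiagnosticReport(
        period=period,
        data_peak=data_peak,
        schedule_peak=sched_peak,
        schedule_peak_is_local_max=is_local_max,
        artefact_suspected=is_local_max and prom >= prominence_threshold,
        prominence=prom,
    )
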