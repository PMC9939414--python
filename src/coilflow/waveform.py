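"""Pulsatile inlet waveform with identifiable cardiac phases.

A parametric analytic stand-in for a measured internal-carotid inflow trace:
a raised-cosine-squared systolic pulse on a diastolic baseline, followed by a
small dicrotic wave.  The four cardiac phase markers used throughout the
analysis (maximum acceleration, peak systole, maximum deceleration, early
diastole) are detected from the sampled signal exactly as they would be on a
measured trace: extrema of du/dt around the systolic peak, and the first
local minimum of u after maximum deceleration for early diastole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Waveform", "synth_waveform", "PHASE_NAMES"]

PHASE_NAMES = ("max_accel", "peak_systole", "max_decel", "early_diastole")

_DICROTIC_AMP = 0.10   # fraction of the systolic amplitude
_DICROTIC_SPAN = 0.30  # fraction of the period (shrunk if diastole is short)


@dataclass(frozen=True)
class Waveform:
    """Periodic inlet mean-velocity signal with four phase markers.

    ``times``/``u_mean`` sample one period on a uniform grid *without* the
    duplicated endpoint (the signal is periodic by construction).  ``phases``
    maps each name in :data:`PHASE_NAMES` to a marker time in ``[0, period)``.
    The analytic closure parameters are retained so the signal can be
    evaluated exactly at arbitrary times via :meth:`u_at`.
    """

    period: float
    times: np.ndarray
    u_mean: np.ndarray
    phases: dict
    u_dia: float
    u_peak: float
    systole_fraction: float
    dicrotic_amp: float = field(default=_DICROTIC_AMP)
    dicrotic_span: float = field(default=_DICROTIC_SPAN)

    def u_at(self, t) -> np.ndarray:
        """Evaluate the analytic waveform at time(s) ``t`` (periodic)."""
        tau = np.mod(np.asarray(t, dtype=float), self.period) / self.period
        fs = self.systole_fraction
        amp = self.u_peak - self.u_dia
        u = np.full_like(tau, self.u_dia, dtype=float)
        sys = tau < fs
        u = np.where(sys, self.u_dia + amp * np.sin(np.pi * tau / fs) ** 2, u)
        span = self.dicrotic_span
        dic = (~sys) & (tau < fs + span)
        u = np.where(
            dic,
            self.u_dia + self.dicrotic_amp * amp * np.sin(np.pi * (tau - fs) / span) ** 2,
            u,
        )
        return u if u.ndim else float(u)

    @property
    def cycle_mean(self) -> float:
        """Exact analytic mean of the waveform over one period."""
        amp = self.u_peak - self.u_dia
        return (
            self.u_dia
            + 0.5 * amp * self.systole_fraction
            + 0.5 * self.dicrotic_amp * amp * self.dicrotic_span
        )

    def phase_times(self) -> np.ndarray:
        return np.array([self.phases[name] for name in PHASE_NAMES])


def _detect_phases(times: np.ndarray, u: np.ndarray, period: float) -> dict:
    """Locate the four cardiac phase markers on a sampled periodic signal."""
    n = len(times)
    dudt = (np.roll(u, -1) - np.roll(u, 1)) / (times[1] - times[0]) / 2.0
    ip = int(np.argmax(u))
    if ip == 0:
        raise ValueError("cannot place phase markers: peak at cycle start")
    ia = int(np.argmax(dudt[:ip]))
    after = np.arange(ip + 1, n)
    if len(after) == 0:
        raise ValueError("cannot place phase markers: peak at cycle end")
    idec = after[int(np.argmin(dudt[after]))]
    # first strict local minimum of u after maximum deceleration
    ied = None
    for k in range(idec + 1, n - 1):
        if u[k] <= u[k - 1] and u[k] < u[k + 1] - 1e-15:
            ied = k
            break
    if ied is None:
        raise ValueError("no early-diastolic minimum found after maximum deceleration")
    return {
        "max_accel": float(times[ia]),
        "peak_systole": float(times[ip]),
        "max_decel": float(times[idec]),
        "early_diastole": float(times[ied]),
    }


def synth_waveform(
    period: float = 0.8,
    u_dia: float = 0.15,
    u_peak: float = 0.55,
    systole_fraction: float = 0.35,
    n_samples: int = 256,
) -> Waveform:
    """Build the analytic pulsatile waveform and detect its phase markers.

    Parameters
    ----------
    period : float
        Cardiac period, s.
    u_dia, u_peak : float
        Diastolic baseline and systolic peak of the inlet cross-section mean
        velocity, m/s; requires ``0 < u_dia < u_peak``.
    systole_fraction : float
        Fraction of the period occupied by the systolic pulse, in (0, 1).
    n_samples : int
        Samples per period (>= 64).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if not 0 < u_dia < u_peak:
        raise ValueError("need 0 < u_dia < u_peak (constant signal has no phase markers)")
    if not 0 < systole_fraction < 1:
        raise ValueError("systole_fraction must lie in (0, 1)")
    if n_samples < 64:
        raise ValueError("n_samples must be at least 64")
    span = min(_DICROTIC_SPAN, 0.85 * (1.0 - systole_fraction))
    times = np.arange(n_samples) * period / n_samples
    wf = Waveform(
        period=period,
        times=times,
        u_mean=np.empty(n_samples),
        phases={},
        u_dia=u_dia,
        u_peak=u_peak,
        systole_fraction=systole_fraction,
        dicrotic_span=span,
    )
    u = wf.u_at(times)
    phases = _detect_phases(times, u, period)
    object.__setattr__(wf, "u_mean", u)
    object.__setattr__(wf, "phases", phases)
    return wf
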