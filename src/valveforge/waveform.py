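"""Pulsatile pump forcing: the programmable aortic flow waveform and the
hydrostatic afterload of an open-circuit water column.

The driving waveform is modelled as a half-sine systolic lobe with an
optional negative dicrotic lobe immediately after systole and zero flow in
diastole.  Three pump settings pin the default shape: a peak flow of
100 mL/s, a rate of 60 beats/min, and a cycle-mean (net) flow of
27.74 mL/s; the systolic duration is solved from the closed-form mean of
the half-sine so that all three hold simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

#: mm of water per mmHg: density ratio mercury/water at reference conditions.
MM_WATER_PER_MMHG = 13.5951

#: Pump settings of the normal-aortic calibration: peak flow (mL/s),
#: heart rate (beats/min) and cycle-mean flow (mL/s).
DEFAULT_PEAK_FLOW = 100.0
DEFAULT_HEART_RATE = 60.0
DEFAULT_MEAN_FLOW = 27.74


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of the parametric pump waveform.

    ``systolic_duration=None`` requests calibration: the duration is solved
    so the cycle-mean flow equals ``target_mean_flow``.
    """

    peak_flow: float = DEFAULT_PEAK_FLOW
    heart_rate: float = DEFAULT_HEART_RATE
    systolic_duration: float | None = None
    target_mean_flow: float = DEFAULT_MEAN_FLOW
    dicrotic_backflow_fraction: float = 0.0
    dicrotic_duration: float = 0.0
    n_samples_per_cycle: int = 1000

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    def __post_init__(self):
        if self.peak_flow <= 0:
            raise ParameterError("peak_flow", "must be > 0")
        if self.heart_rate <= 0:
            raise ParameterError("heart_rate", "must be > 0")
        if not (0.0 <= self.dicrotic_backflow_fraction < 0.2):
            raise ParameterError("dicrotic_backflow_fraction",
                                 "must be in [0, 0.2)")
        if self.dicrotic_duration < 0:
            raise ParameterError("dicrotic_duration", "must be >= 0")
        if self.n_samples_per_cycle < 3:
            raise ParameterError("n_samples_per_cycle", "must be >= 3")
        tsys = self.systolic_duration
        if tsys is not None:
            if tsys <= 0:
                raise ParameterError("systolic_duration", "must be > 0")
            if tsys + self.dicrotic_duration >= self.period:
                raise ParameterError(
                    "systolic_duration",
                    "systolic + dicrotic duration must fit inside the cycle")

    def resolved(self) -> "WaveformParams":
        """Return a copy with ``systolic_duration`` made concrete."""
        if self.systolic_duration is not None:
            return self
        tsys = calibrate_systolic_duration(
            self.peak_flow, self.target_mean_flow, self.period)
        return replace(self, systolic_duration=tsys)


@dataclass(frozen=True)
class FlowWaveform:
    """One cycle of volumetric flow rate q(t), mL/s.

    ``times`` are uniform over [0, period) (endpoint excluded; the waveform
    continues periodically).  ``q_fn`` evaluates the underlying analytic
    waveform at arbitrary times with periodic extension.
    """

    times: np.ndarray
    q: np.ndarray
    period: float
    q_fn: Callable[[np.ndarray], np.ndarray] = field(
        default=None, compare=False, repr=False)
    peak_flow: float = field(default=np.nan, compare=False)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=np.float64)
        q = np.asarray(self.q, dtype=np.float64)
        if t.shape != q.shape:
            raise ParameterError("q", "times and q must have equal length")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ParameterError(
                "times", "must start at 0 and be strictly increasing")
        if t[-1] >= self.period:
            raise ParameterError("times", "must stay inside one period")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "q", q)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "flow_mL_per_s": self.q}).to_csv(
            path, index=False)

    @staticmethod
    def from_csv(path: str | Path) -> "FlowWaveform":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        q = df["flow_mL_per_s"].to_numpy()
        period = t[-1] + (t[1] - t[0]) if len(t) > 1 else 1.0

        def q_fn(tt, _t=t, _q=q, _p=period):
            return np.interp(np.mod(tt, _p), _t, _q, period=_p)

        return FlowWaveform(times=t, q=q, period=period, q_fn=q_fn,
                            peak_flow=float(q.max()))


def make_aortic_waveform(params: WaveformParams | None = None) -> FlowWaveform:
    """Build the half-sine (plus optional dicrotic lobe) aortic waveform.

    q(t) = peak · sin(π t / T_sys) on [0, T_sys]; a negative half-sine lobe
    of depth ``dicrotic_backflow_fraction · peak`` and width
    ``dicrotic_duration`` follows systole; zero elsewhere.  The maximum is
    exactly ``peak_flow`` at t = T_sys / 2.
    """
    params = (params or WaveformParams()).resolved()
    peak = params.peak_flow
    tsys = params.systolic_duration
    dfrac = params.dicrotic_backflow_fraction
    tdic = params.dicrotic_duration
    period = params.period

    def q_fn(t):
        t = np.mod(np.asarray(t, dtype=np.float64), period)
        q = np.where(t <= tsys, peak * np.sin(np.pi * t / tsys), 0.0)
        if dfrac > 0 and tdic > 0:
            in_lobe = (t > tsys) & (t <= tsys + tdic)
            q = np.where(
                in_lobe,
                -dfrac * peak * np.sin(np.pi * (t - tsys) / tdic), q)
        return q

    times = np.arange(params.n_samples_per_cycle) * (
        period / params.n_samples_per_cycle)
    return FlowWaveform(times=times, q=q_fn(times), period=period,
                        q_fn=q_fn, peak_flow=peak)


def mean_flow(w: FlowWaveform) -> float:
    """Cycle-mean flow rate (mL/s) by trapezoidal quadrature.

    The sampled cycle is closed periodically (a wrap point at t = period
    with q = q[0]) before integrating.
    """
    if len(w.times) < 3:
        raise InputError("waveform must have at least 3 samples")
    t = np.append(w.times, w.period)
    q = np.append(w.q, w.q[0])
    return float(np.trapezoid(q, t) / w.period)


def calibrate_systolic_duration(peak_flow: float, target_mean: float,
                                period: float) -> float:
    """Systolic duration T such that the half-sine cycle mean equals
    ``target_mean``: mean = 2·peak·T/(π·period)  ⇒  T = mean·π·period/(2·peak).
    """
    if peak_flow <= 0:
        raise ParameterError("peak_flow", "must be > 0")
    if period <= 0:
        raise ParameterError("period", "must be > 0")
    if not (0.0 < target_mean < 2.0 * peak_flow / np.pi):
        raise InputError(
            f"target_mean {target_mean} infeasible: must lie in "
            f"(0, {2.0 * peak_flow / np.pi:.4f}) for a half-sine of peak "
            f"{peak_flow} in period {period}")
    tsys = target_mean * np.pi * period / (2.0 * peak_flow)
    if tsys >= period:
        raise InputError("calibrated systole does not fit inside the cycle")
    return float(tsys)


def water_column_to_mmHg(height_mm: float) -> float:
    """Hydrostatic pressure of a water column (mm of water → mmHg)."""
    if height_mm < 0:
        raise InputError("water column height must be >= 0")
    return float(height_mm) / MM_WATER_PER_MMHG
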