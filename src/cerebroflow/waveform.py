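"""Periodic carotid inflow-pressure boundary condition.

The control waveform is a synthetic one-period shape (half-cosine systolic
upstroke followed by an exponential diastolic decay) calibrated so that its
maximum, minimum and period mean match the control systolic/diastolic
pressures (121/83 mmHg) and the control time-averaged inflow pressure
(99.2 mmHg).  To simulate other mean arterial pressures the control wave is
transformed pointwise, P_new(t) = a P_control(t) + b, where a and b follow
from an empirical linear systolic-diastolic relation (S = 1.58 Dy - 10.14
through the control point) combined with the standard MAP estimate
MAP = Dy + (S - Dy)/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

CONTROL_SYSTOLIC = 121.0  # mmHg
CONTROL_DIASTOLIC = 83.0  # mmHg
CONTROL_TIME_AVERAGE = 99.2  # mmHg, period mean of the control inflow wave
SD_SLOPE = 1.58  # slope of the systolic-vs-diastolic regression line


class WaveformError(ValueError):
    """Raised for infeasible waveform parameters or transforms."""


def map_from_sd(systolic: float, diastolic: float) -> float:
    """Mean arterial pressure estimate MAP = Dy + (S - Dy)/3."""
    if not systolic > diastolic:
        raise WaveformError(f"systolic ({systolic}) must exceed diastolic ({diastolic})")
    return diastolic + (systolic - diastolic) / 3.0


def sd_line_intercept(
    slope: float = SD_SLOPE,
    anchor_systolic: float = CONTROL_SYSTOLIC,
    anchor_diastolic: float = CONTROL_DIASTOLIC,
) -> float:
    """Vertical intercept of the S-vs-Dy line through the anchor point."""
    if not slope > 0:
        raise WaveformError("slope must be positive")
    return anchor_systolic - slope * anchor_diastolic


def _sd_coefficients(slope: float = SD_SLOPE) -> tuple[float, float, float, float]:
    """Full-precision coefficients of S(MAP) and Dy(MAP).

    Eliminating S between MAP = Dy + (S - Dy)/3 and S = m Dy + c gives
    Dy = (3 MAP - c)/(m + 2)  and  S = (3 m MAP + 2 c)/(m + 2).
    Returned as (s_slope, s_intercept, dy_divisor, dy_shift) so that
    S = s_slope*MAP + s_intercept and Dy = (MAP + dy_shift)/dy_divisor.
    """
    c = sd_line_intercept(slope)
    s_slope = 3.0 * slope / (slope + 2.0)
    s_intercept = 2.0 * c / (slope + 2.0)
    dy_divisor = (slope + 2.0) / 3.0
    dy_shift = -c / 3.0
    # cross-check against the tabulated 3-dp coefficients
    assert abs(s_slope - 1.324) < 5e-4, s_slope
    assert abs(s_intercept - (-5.664)) < 5e-3, s_intercept
    assert abs(dy_divisor - 1.193) < 5e-4, dy_divisor
    assert abs(dy_shift - 3.38) < 5e-3, dy_shift
    return s_slope, s_intercept, dy_divisor, dy_shift


def sd_from_map(map_target: float, bounds: tuple[float, float] = (30.0, 200.0)) -> tuple[float, float]:
    """Systolic and diastolic pressure implied by a target MAP."""
    lo, hi = bounds
    if not lo <= map_target <= hi:
        raise WaveformError(f"MAP {map_target} outside physiologic range [{lo}, {hi}]")
    s_slope, s_intercept, dy_divisor, dy_shift = _sd_coefficients()
    systolic = s_slope * map_target + s_intercept
    diastolic = (map_target + dy_shift) / dy_divisor
    return systolic, diastolic


@dataclass(frozen=True)
class WaveformTransform:
    """Affine pointwise transform P -> a*P + b tied to a target MAP."""

    a: float
    b: float
    map_target: float


class PressureWaveform:
    """Periodic pressure function with systolic/diastolic/mean metadata."""

    def __init__(self, evaluate: Callable[[np.ndarray], np.ndarray], period: float):
        if not period > 0:
            raise WaveformError("period must be positive")
        self._evaluate = evaluate
        self.period = float(period)
        t = np.linspace(0.0, period, 4001)
        p = self(t)
        self.systolic = float(np.max(p))
        self.diastolic = float(np.min(p))
        if not self.systolic > self.diastolic:
            raise WaveformError("degenerate waveform: systolic must exceed diastolic")
        tf = np.linspace(0.0, period, 20001)
        self.time_average = float(np.trapezoid(self(tf), tf) / period)
        if not self.diastolic < self.time_average < self.systolic:
            raise WaveformError("waveform mean must lie strictly between min and max")

    @property
    def map_value(self) -> float:
        """Clinical MAP estimate Dy + (S - Dy)/3 of this waveform."""
        return map_from_sd(self.systolic, self.diastolic)

    def __call__(self, t):
        tt = np.asarray(t, dtype=float) % self.period
        return self._evaluate(tt)

    def transformed(self, a: float, b: float) -> "PressureWaveform":
        if not a > 0:
            raise WaveformError("scale a must be positive")
        return PressureWaveform(lambda t: a * self._evaluate(t) + b, self.period)

    def to_csv(self, path, n: int = 200) -> None:
        """Export one period as two-column CSV (time_s, pressure_mmHg)."""
        import pandas as pd

        t = np.linspace(0.0, self.period, n, endpoint=False)
        pd.DataFrame({"time_s": t, "pressure_mmHg": self(t)}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PressureWaveform":
        """Rebuild a waveform from CSV by periodic linear interpolation."""
        import pandas as pd

        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        p = df["pressure_mmHg"].to_numpy()
        period = t[-1] + (t[1] - t[0])
        tg = np.concatenate([t, [period]])
        pg = np.concatenate([p, [p[0]]])
        return cls(lambda s: np.interp(s, tg, pg), period)


def _shape_mean(decay_rate: float, systolic_fraction: float) -> float:
    """Period mean of the unit shape (0 at foot, 1 at peak) for a decay rate."""
    ts = systolic_fraction
    g = 1.0 / decay_rate - math.exp(-decay_rate) / (1.0 - math.exp(-decay_rate))
    return ts * 0.5 + (1.0 - ts) * g


def build_control_waveform(
    period: float = 1.0,
    systolic: float = CONTROL_SYSTOLIC,
    diastolic: float = CONTROL_DIASTOLIC,
    time_average: float = CONTROL_TIME_AVERAGE,
    systolic_fraction: float = 0.35,
) -> PressureWaveform:
    """Synthetic control inflow wave with calibrated period mean.

    The shape rises from the diastolic foot to the systolic peak over
    ``systolic_fraction`` of the period as a half cosine, then decays back
    exponentially.  The decay rate is the single free shape parameter and is
    solved (Brent) so the period mean matches ``time_average``.  Deterministic.
    """
    if not systolic > diastolic:
        raise WaveformError("systolic must exceed diastolic")
    if not diastolic < time_average < systolic:
        raise WaveformError("time_average must lie strictly between diastolic and systolic")
    if not 0.05 <= systolic_fraction <= 0.8:
        raise WaveformError("systolic_fraction outside supported range [0.05, 0.8]")

    target = (time_average - diastolic) / (systolic - diastolic)
    lo, hi = 1e-6, 60.0
    if not _shape_mean(hi, systolic_fraction) < target < _shape_mean(lo, systolic_fraction):
        raise WaveformError(
            f"time_average {time_average} not reachable with systolic_fraction {systolic_fraction}"
        )
    k = brentq(lambda r: _shape_mean(r, systolic_fraction) - target, lo, hi, xtol=1e-12)

    ts = systolic_fraction * period
    denom = 1.0 - math.exp(-k)

    def shape(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        rising = t < ts
        w = np.empty_like(t)
        w[rising] = 0.5 * (1.0 - np.cos(math.pi * t[rising] / ts))
        u = (t[~rising] - ts) / (period - ts)
        w[~rising] = (np.exp(-k * u) - math.exp(-k)) / denom
        return diastolic + (systolic - diastolic) * w

    return PressureWaveform(shape, period)


def rescale_waveform(
    control: PressureWaveform, map_target: float
) -> tuple[PressureWaveform, WaveformTransform]:
    """Affine-transform the control wave to a target mean arterial pressure.

    Solves S = a Sc + b, Dy = a Dyc + b with (S, Dy) from the S-Dy line and
    the MAP identity; the rescaled wave has systolic/diastolic exactly S/Dy.
    """
    systolic, diastolic = sd_from_map(map_target)
    if not systolic > diastolic:
        raise WaveformError(f"MAP {map_target} yields non-positive pulse pressure")
    a = (systolic - diastolic) / (control.systolic - control.diastolic)
    b = systolic - a * control.systolic
    return control.transformed(a, b), WaveformTransform(a=a, b=b, map_target=map_target)
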