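"""Strength-duration (rheobase/chronaxie) measurement and fit.

Before a pattern sweep the excitability of the phrenic nerve is mapped by
finding, for each pulse width, the smallest burst voltage that elicits a
detectable inspiratory flow.  A breath counts as *excited* when the peak
airway flow during the burst exceeds 0.05 L/s (strictly).  Thresholds are
searched by bisection on a flat burst (no ramp) at a fixed 100 Hz pulse
rate, and the classical Lapicque hyperbola

    v_exc(T_pw) = v_rh * (1 + T_ch / T_pw)

is fitted to the measured points by linear least squares in 1/T_pw.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scheduler import VentilatorSettings
from .virtual_pig import BreathTrace, PigParams, simulate_breath
from .waveforms import (
    MAX_VOLTAGE_V,
    BurstSettings,
    Direction,
    PulseSettings,
    build_pulse_train,
)

__all__ = [
    "EXCITATION_FLOW_LPS",
    "StrengthDurationPoint",
    "SDCurve",
    "is_excited",
    "measure_threshold",
    "measure_curve",
    "fit_lapicque",
]

#: peak-flow criterion for nerve excitation (L/s, strict inequality)
EXCITATION_FLOW_LPS = 0.05
#: pulse rate used during threshold measurement (Hz)
MEASUREMENT_FREQUENCY_HZ = 100.0
#: bisection resolution on the threshold voltage (V)
DEFAULT_RESOLUTION_V = 0.05


def is_excited(trace: BreathTrace, flow_threshold_lps: float = EXCITATION_FLOW_LPS) -> bool:
    """True iff the peak flow during the burst window exceeds the
    excitation criterion (strictly)."""
    in_burst = trace.phase == "stim_insp"
    if not np.any(in_burst):
        return False
    return float(np.max(trace.flow_lps[in_burst])) > flow_threshold_lps


@dataclass(frozen=True)
class StrengthDurationPoint:
    """Threshold measurement at one pulse width.

    ``threshold_v`` is NaN when 20 V failed to excite (``excited=False``).
    """

    pulse_width_ms: float
    threshold_v: float
    excited: bool

    def __post_init__(self) -> None:
        if self.excited and not self.threshold_v <= MAX_VOLTAGE_V:
            raise ValueError("excitable threshold cannot exceed the 20 V ceiling")


@dataclass(frozen=True)
class SDCurve:
    """Measured strength-duration points plus the Lapicque fit."""

    points: tuple
    rheobase_v: float
    chronaxie_ms: float

    @property
    def v_exc_max(self) -> float:
        """Largest measured threshold, used to normalise the curve."""
        vals = [p.threshold_v for p in self.points if p.excited]
        return float(np.max(vals))

    def to_frame(self) -> pd.DataFrame:
        vmax = self.v_exc_max
        return pd.DataFrame(
            {
                "T_pw_ms": [p.pulse_width_ms for p in self.points],
                "v_exc_V": [p.threshold_v for p in self.points],
                "v_exc_norm": [
                    p.threshold_v / vmax if p.excited else np.nan
                    for p in self.points
                ],
                "excited": [p.excited for p in self.points],
            }
        )

    def export(self, csv_path, json_path) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        Path(json_path).write_text(
            json.dumps(
                {
                    "rheobase_v": self.rheobase_v,
                    "chronaxie_ms": self.chronaxie_ms,
                    "v_exc_max": self.v_exc_max,
                },
                indent=1,
            )
        )


def _flat_burst(voltage: float, burst_duration_s: float,
                burst_rate_per_min: float) -> BurstSettings:
    return BurstSettings(
        start_voltage=voltage,
        end_voltage=voltage,
        slope_time_s=0.0,
        burst_duration_s=burst_duration_s,
        burst_rate_per_min=burst_rate_per_min,
    )


def measure_threshold(
    pulse_width_ms: float,
    pig: PigParams,
    direction: Direction = Direction.BIP,
    vent: Optional[VentilatorSettings] = None,
    *,
    pulse_frequency_hz: float = MEASUREMENT_FREQUENCY_HZ,
    resolution_v: float = DEFAULT_RESOLUTION_V,
    burst_duration_s: float = 1.10,
    bip_total_width: bool = True,
) -> StrengthDurationPoint:
    """Bisect the excitation threshold at one pulse width.

    Uses a flat (ramp-free) burst at the measurement pulse rate and a
    noise-free simulation, searching the smallest voltage in [0, 20] whose
    breath satisfies the excitation criterion, to ``resolution_v``.  When
    even 20 V fails the point is flagged not excitable — a valid outcome
    given the safety ceiling.
    """
    vent = vent or VentilatorSettings()
    quiet = pig.noiseless()

    def excited_at(voltage: float) -> bool:
        if voltage <= 0.0:
            return False
        pulse = PulseSettings(
            pulse_voltage=voltage,
            pulse_width_ms=pulse_width_ms,
            pulse_frequency_hz=pulse_frequency_hz,
            direction=direction,
        )
        wf = build_pulse_train(pulse, _flat_burst(voltage, burst_duration_s,
                                                  vent.mandatory_rate_per_min))
        trace = simulate_breath(
            wf, vent, quiet, noise=False, bip_total_width=bip_total_width,
            exp_duration_s=1.0,
        )
        return is_excited(trace)

    if not excited_at(MAX_VOLTAGE_V):
        return StrengthDurationPoint(pulse_width_ms, math.nan, excited=False)
    lo, hi = 0.0, MAX_VOLTAGE_V
    while hi - lo > resolution_v:
        mid = 0.5 * (lo + hi)
        if excited_at(mid):
            hi = mid
        else:
            lo = mid
    return StrengthDurationPoint(pulse_width_ms, hi, excited=True)


def fit_lapicque(points: Sequence[StrengthDurationPoint]) -> tuple[float, float]:
    """Least-squares Lapicque fit via the linearisation v = a + b / T_pw.

    Returns ``(rheobase_v, chronaxie_ms)`` with ``v_rh = a`` and
    ``T_ch = b / a``.  Requires at least three excitable points at distinct
    widths; exact on noiseless synthetic points.
    """
    usable = [p for p in points if p.excited]
    widths = np.array([p.pulse_width_ms for p in usable])
    if len(usable) < 3:
        raise ValueError("need at least three excitable points for the fit")
    if len(np.unique(widths)) < 2:
        raise ValueError("points must cover at least two distinct pulse widths")
    volts = np.array([p.threshold_v for p in usable])
    slope, intercept = np.polyfit(1.0 / widths, volts, 1)
    if intercept <= 0.0 or slope <= 0.0:
        raise ValueError("degenerate fit: non-positive rheobase or chronaxie")
    return float(intercept), float(slope / intercept)


def measure_curve(
    widths_ms: Sequence[float],
    pig: PigParams,
    direction: Direction = Direction.BIP,
    vent: Optional[VentilatorSettings] = None,
    **kwargs,
) -> SDCurve:
    """Measure thresholds over a width list and fit the Lapicque curve."""
    points = tuple(
        measure_threshold(w, pig, direction, vent, **kwargs)
        for w in sorted(widths_ms)
    )
    v_rh, t_ch = fit_lapicque(points)
    return SDCurve(points=points, rheobase_v=v_rh, chronaxie_ms=t_ch)
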