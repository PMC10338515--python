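"""Stimulation waveform synthesis.

A stimulated breath is driven by a *burst*: a train of voltage pulses whose
amplitude follows a trapezoidal envelope.  Each pulse is characterised by a
pulse voltage ``v_p`` (V), a pulse width ``T_pw`` (ms), a repetition rate
``f_p`` (Hz) and a polarity scheme:

* ``UNI`` — every pulse has the same polarity,
* ``ALT`` — polarity alternates between consecutive pulses,
* ``BIP`` — each pulse consists of two back-to-back phases of opposite
  polarity (charge balanced).

The burst envelope ramps linearly from ``v_start`` to ``v_end`` over
``T_slope`` seconds, stays at ``v_end`` until ``T_burst``, and is zero
afterwards.  Bursts repeat at the stimulated breathing rate ``f_rr``
(1/min).  For safety the stimulator clamps voltages to 20 V and limits the
output current through a series resistor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

#: acquisition frame of the measurement chain (seconds)
FRAME_DT_S = 0.01

#: hard safety ceiling on the pulse voltage (volts)
MAX_VOLTAGE_V = 20.0


class Direction(str, Enum):
    """Pulse polarity scheme."""

    UNI = "UNI"
    ALT = "ALT"
    BIP = "BIP"


class WaveformError(ValueError):
    """Invalid pulse/burst parameterisation."""


@dataclass(frozen=True)
class PulseSettings:
    """Per-pulse stimulation parameters.

    Parameters
    ----------
    pulse_voltage:
        Peak pulse voltage ``v_p`` in volts, ``0 <= v_p <= 20``.
    pulse_width_ms:
        Pulse width ``T_pw`` in milliseconds (for BIP this is the *total*
        width of both phases).
    pulse_frequency_hz:
        Within-burst repetition rate ``f_p`` in hertz.
    direction:
        Polarity scheme.
    """

    pulse_voltage: float
    pulse_width_ms: float
    pulse_frequency_hz: float
    direction: Direction = Direction.BIP

    def __post_init__(self) -> None:
        if not 0.0 <= self.pulse_voltage <= MAX_VOLTAGE_V:
            raise WaveformError(
                f"pulse_voltage: {self.pulse_voltage} V outside [0, {MAX_VOLTAGE_V}] V"
            )
        if self.pulse_width_ms <= 0.0:
            raise WaveformError(f"pulse_width_ms: {self.pulse_width_ms} must be > 0")
        if self.pulse_frequency_hz <= 0.0:
            raise WaveformError(
                f"pulse_frequency_hz: {self.pulse_frequency_hz} must be > 0"
            )
        if self.pulse_width_ms * 1e-3 > 1.0 / self.pulse_frequency_hz:
            raise WaveformError(
                f"pulse_width_ms: {self.pulse_width_ms} ms exceeds the pulse period "
                f"{1e3 / self.pulse_frequency_hz:.3f} ms (pulses would overlap)"
            )
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))

    @property
    def period_s(self) -> float:
        return 1.0 / self.pulse_frequency_hz


@dataclass(frozen=True)
class BurstSettings:
    """Burst envelope parameters.

    ``start_voltage`` and ``end_voltage`` in volts, ``slope_time_s`` and
    ``burst_duration_s`` in seconds, ``burst_rate_per_min`` (``f_rr``) in
    breaths per minute.
    """

    start_voltage: float
    end_voltage: float
    slope_time_s: float
    burst_duration_s: float
    burst_rate_per_min: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.start_voltage <= self.end_voltage <= MAX_VOLTAGE_V:
            raise WaveformError(
                f"burst voltages: need 0 <= start ({self.start_voltage}) <= "
                f"end ({self.end_voltage}) <= {MAX_VOLTAGE_V} V"
            )
        if not 0.0 <= self.slope_time_s <= self.burst_duration_s:
            raise WaveformError(
                f"slope_time_s: {self.slope_time_s} outside [0, burst_duration_s="
                f"{self.burst_duration_s}]"
            )
        if self.burst_rate_per_min <= 0.0:
            raise WaveformError("burst_rate_per_min must be > 0")
        if self.burst_duration_s >= 60.0 / self.burst_rate_per_min:
            raise WaveformError(
                f"burst_duration_s: {self.burst_duration_s} s does not fit in one "
                f"breath cycle of {60.0 / self.burst_rate_per_min:.2f} s"
            )


@dataclass(frozen=True)
class HardwareLimits:
    """Output-stage safety limits: series resistance and voltage ceiling."""

    limiting_resistance_ohm: float = 1667.0
    max_voltage: float = MAX_VOLTAGE_V

    def __post_init__(self) -> None:
        if self.limiting_resistance_ohm <= 0.0:
            raise WaveformError("limiting_resistance_ohm must be > 0")


def burst_envelope(t, burst: BurstSettings):
    """Burst voltage envelope at time ``t`` (seconds from burst start).

    Linear ramp from ``start_voltage`` to ``end_voltage`` on
    ``[0, slope_time_s)``, flat at ``end_voltage`` on
    ``[slope_time_s, burst_duration_s]`` and zero afterwards.  Accepts
    scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if burst.slope_time_s > 0.0:
        ramp = burst.start_voltage + (
            burst.end_voltage - burst.start_voltage
        ) * t / burst.slope_time_s
    else:
        ramp = np.full_like(t, burst.end_voltage)
    v = np.where(t < burst.slope_time_s, ramp, burst.end_voltage)
    v = np.where(t > burst.burst_duration_s, 0.0, v)
    v = np.where(t < 0.0, 0.0, v)
    return float(v) if v.ndim == 0 else v


@dataclass
class StimWaveform:
    """A realised pulse train for one burst.

    ``onsets_s`` are pulse start times from burst start, ``amplitudes_v``
    the envelope voltage at each onset, and ``phase_plans`` one list of
    ``(duration_ms, polarity)`` tuples per pulse.
    """

    pulse: PulseSettings
    burst: BurstSettings
    onsets_s: np.ndarray
    amplitudes_v: np.ndarray
    phase_plans: list = field(repr=False)

    @property
    def n_pulses(self) -> int:
        return len(self.onsets_s)

    def pulse_charge_balance(self, i: int) -> float:
        """Signed sum of duration x polarity x amplitude for pulse ``i``."""
        return sum(
            dur * pol * self.amplitudes_v[i] for dur, pol in self.phase_plans[i]
        )

    def frames(self, dt_s: float = FRAME_DT_S) -> pd.DataFrame:
        """Sample the waveform on the acquisition grid.

        Each frame reports the instantaneous voltage and polarity at the
        frame start (0 when no phase is active).
        """
        n = int(np.floor(self.burst.burst_duration_s / dt_s)) + 1
        t = np.arange(n) * dt_s
        volts = np.zeros(n)
        pol = np.zeros(n, dtype=int)
        for i, onset in enumerate(self.onsets_s):
            offset = onset
            for dur_ms, p in self.phase_plans[i]:
                dur = dur_ms * 1e-3
                sel = (t >= offset) & (t < offset + dur)
                volts[sel] = self.amplitudes_v[i]
                pol[sel] = p
                offset += dur
        return pd.DataFrame({"time_s": t, "voltage_V": volts, "polarity": pol})

    def export(self, csv_path, json_path) -> None:
        """Write frame-resolution CSV plus an exact event list as JSON."""
        self.frames().to_csv(csv_path, index=False)
        events = [
            {
                "onset_s": float(o),
                "amplitude_V": float(a),
                "phase_plan": [[float(d), int(p)] for d, p in plan],
            }
            for o, a, plan in zip(self.onsets_s, self.amplitudes_v, self.phase_plans)
        ]
        Path(json_path).write_text(json.dumps({"pulses": events}, indent=1))


def build_pulse_train(pulse: PulseSettings, burst: BurstSettings) -> StimWaveform:
    """Expand pulse/burst settings into an explicit pulse train.

    The burst contains every pulse whose onset ``i / f_p`` lies strictly
    below ``T_burst`` (half-open burst interval: a pulse exactly at
    ``T_burst`` is excluded), so the count is ``f_p * T_burst`` when the
    product is integral — e.g. 110 pulses at 100 Hz over 1.10 s — and
    ``ceil(f_p * T_burst)`` otherwise.  Pulse ``i`` takes its amplitude
    from the envelope at its onset.  BIP pulses are split into two equal,
    opposite phases of ``T_pw / 2`` with no interphase gap; ALT pulses
    alternate sign starting positive; UNI pulses are all positive.
    """
    if pulse.pulse_width_ms * 1e-3 >= 1.0 / pulse.pulse_frequency_hz:
        raise WaveformError(
            f"pulse width {pulse.pulse_width_ms} ms must be strictly below the "
            f"period {1e3 / pulse.pulse_frequency_hz:.3f} ms"
        )
    # onsets strictly below T_burst; epsilon guards against
    # 100 * 1.1 = 110.00000000000001-style float noise at the boundary
    n = int(np.ceil(pulse.pulse_frequency_hz * burst.burst_duration_s - 1e-9))
    onsets = np.arange(n) / pulse.pulse_frequency_hz
    amplitudes = np.asarray(burst_envelope(onsets, burst), dtype=float).reshape(-1)
    w = pulse.pulse_width_ms
    if pulse.direction is Direction.BIP:
        plans = [[(w / 2.0, +1), (w / 2.0, -1)] for _ in range(n)]
    elif pulse.direction is Direction.ALT:
        plans = [[(w, +1 if i % 2 == 0 else -1)] for i in range(n)]
    else:
        plans = [[(w, +1)] for _ in range(n)]
    return StimWaveform(
        pulse=pulse, burst=burst, onsets_s=onsets, amplitudes_v=amplitudes,
        phase_plans=plans,
    )


def peak_current(pulse_voltage: float, hw: HardwareLimits = HardwareLimits()) -> float:
    """Peak output current in milliamps through the limiting resistor."""
    if not 0.0 <= pulse_voltage <= hw.max_voltage:
        raise WaveformError(
            f"pulse_voltage: {pulse_voltage} V outside [0, {hw.max_voltage}] V"
        )
    return pulse_voltage / hw.limiting_resistance_ohm * 1e3
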