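"""Virtual-pig respiratory model.

Generates physiologically plausible airway flow/pressure traces in response
to either a mandatory (pressure-controlled) ventilator breath or a
stimulation burst.  The model is deliberately minimal but captures the
statistical structure the downstream analysis assumes:

* a single-compartment linear lung (compliance ``C``, airway resistance
  ``R_aw``) driven by either ventilator pressure or diaphragm muscle
  pressure,
* nerve excitability following the classical Lapicque (Weiss hyperbola)
  strength-duration law with rheobase ``v_rh`` and chronaxie ``T_ch``,
* graded motor-unit recruitment: a logistic function of the margin between
  the instantaneous burst voltage and the strength-duration threshold,
* force-frequency saturation of the diaphragm: a Hill function of the
  effective pulse rate, half-saturating at ``f50``,
* polarity-scheme effects: biphasic (BIP) pulses act with half the pulse
  width per phase; alternating (ALT) pulses drive each electrode site at
  half the pulse rate and are subject to a slow electrode-polarisation
  random walk on the threshold (the "inconsistent ALT" phenotype),
* multiplicative breath-to-breath noise on muscle pressure and additive
  sensor noise on flow.

All randomness is injected through numpy Generators so that one root seed
reproduces every trace bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional, Union

import numpy as np

from .waveforms import Direction, StimWaveform, burst_envelope
from .scheduler import VentilatorSettings

__all__ = [
    "PigParams",
    "BreathTrace",
    "MandatoryBreath",
    "IntegrationError",
    "excitation_voltage",
    "recruitment_fraction",
    "frequency_gain",
    "effective_pulse",
    "simulate_breath",
    "sample_animal",
    "ANIMAL_PRESETS",
]

#: output sampling interval of every trace (seconds)
SAMPLE_DT_S = 0.01
#: internal integrator step (seconds)
DEFAULT_STEP_S = 0.001


class IntegrationError(RuntimeError):
    """The fixed-step integration would be unstable or produced non-finite state."""


@dataclass(frozen=True)
class PigParams:
    """Physiology of one virtual animal.

    Lung mechanics
        ``body_weight_kg`` body mass; ``compliance_ml_per_cmh2o`` respiratory
        system compliance; ``airway_resistance_cmh2o_s_per_l`` airway
        resistance; ``max_diaphragm_pressure_cmh2o`` muscle pressure at full
        recruitment and full force-frequency gain.

    Excitability
        ``rheobase_v`` / ``chronaxie_ms`` Lapicque strength-duration
        parameters of the phrenic nerve; ``recruitment_slope_v`` logistic
        slope of graded recruitment around the threshold.

    Force-frequency
        ``force_freq_half_hz`` (half-saturation rate) and
        ``force_freq_exponent`` (Hill exponent).

    Variability
        ``breath_noise_sd`` multiplicative sd on muscle pressure per breath;
        ``flow_noise_sd_lps`` additive sd on each flow sample;
        ``alt_instability`` scales the per-burst electrode-polarisation walk
        affecting ALT pulses (0 = consistent, ~2 = inconsistent);
        ``drift_rate`` fractional change of muscle pressure per breath.
    """

    body_weight_kg: float = 49.0
    compliance_ml_per_cmh2o: float = 30.0
    airway_resistance_cmh2o_s_per_l: float = 20.0
    max_diaphragm_pressure_cmh2o: float = 11.5
    rheobase_v: float = 2.6
    chronaxie_ms: float = 0.13
    recruitment_slope_v: float = 0.5
    force_freq_half_hz: float = 25.0
    force_freq_exponent: float = 2.5
    breath_noise_sd: float = 0.05
    flow_noise_sd_lps: float = 0.01
    alt_instability: float = 0.0
    drift_rate: float = 0.0

    def __post_init__(self) -> None:
        positive = (
            "body_weight_kg", "compliance_ml_per_cmh2o",
            "airway_resistance_cmh2o_s_per_l", "max_diaphragm_pressure_cmh2o",
            "rheobase_v", "chronaxie_ms", "recruitment_slope_v",
            "force_freq_half_hz", "force_freq_exponent",
        )
        for name in positive:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        for name in ("breath_noise_sd", "flow_noise_sd_lps", "alt_instability",
                     "drift_rate"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def time_constant_s(self) -> float:
        """Expiratory time constant R_aw * C in seconds."""
        return (
            self.airway_resistance_cmh2o_s_per_l
            * self.compliance_ml_per_cmh2o
            / 1000.0
        )

    def noiseless(self) -> "PigParams":
        return replace(self, breath_noise_sd=0.0, flow_noise_sd_lps=0.0)


#: Animal presets: I is the consistent reference animal; II is lighter,
#: slightly stiffer and shows the unstable-ALT phenotype.
ANIMAL_PRESETS = {
    "animal_I": PigParams(),
    "animal_II": PigParams(body_weight_kg=41.0,
                           compliance_ml_per_cmh2o=27.0,
                           alt_instability=2.0),
}


@dataclass(frozen=True)
class MandatoryBreath:
    """Marker describing a ventilator-delivered breath (settings come from
    :class:`~phrenosweep.scheduler.VentilatorSettings`)."""

    insp_duration_s: Optional[float] = None  # default: vent.t_insp_s


@dataclass
class BreathTrace:
    """One breath sampled at 10 ms: flow (L/s), airway pressure (cmH2O) and
    a ventilation-phase label per sample."""

    t0_s: float
    time_s: np.ndarray
    flow_lps: np.ndarray
    pressure_cmh2o: np.ndarray
    phase: np.ndarray  # of {mand_insp, mand_exp, stim_insp, stim_exp}

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.flow_lps) == len(self.pressure_cmh2o) == len(self.phase) == n):
            raise ValueError("trace arrays must have equal length")
        if n >= 2:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("trace must be uniformly sampled")

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.t0_s + self.time_s,
                "flow_Lps": self.flow_lps,
                "pressure_cmH2O": self.pressure_cmh2o,
                "phase": self.phase,
            }
        )


def excitation_voltage(width_ms, pig: PigParams):
    """Lapicque strength-duration threshold ``v_rh * (1 + T_ch / T_pw)``.

    Strictly decreasing in the effective pulse width and approaching the
    rheobase for long pulses.  Accepts scalars or arrays.
    """
    width_ms = np.asarray(width_ms, dtype=float)
    if np.any(width_ms <= 0.0):
        raise ValueError("pulse width must be > 0")
    v = pig.rheobase_v * (1.0 + pig.chronaxie_ms / width_ms)
    return float(v) if v.ndim == 0 else v


def recruitment_fraction(voltage, width_ms, pig: PigParams,
                         threshold_shift_v: float = 0.0):
    """Fraction of phrenic motor units recruited at a given voltage.

    Logistic in the margin between ``voltage`` and the strength-duration
    threshold (optionally shifted by electrode polarisation), equal to 0.5
    exactly at threshold.
    """
    v_exc = excitation_voltage(width_ms, pig) + threshold_shift_v
    x = (np.asarray(voltage, dtype=float) - v_exc) / pig.recruitment_slope_v
    r = 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))
    return float(r) if np.ndim(r) == 0 else r


def frequency_gain(f_hz, pig: PigParams):
    """Force-frequency (tetanic fusion) gain: Hill saturation in the
    effective pulse rate, 0 at 0 Hz and 0.5 at ``force_freq_half_hz``."""
    f = np.asarray(f_hz, dtype=float)
    if np.any(f < 0.0):
        raise ValueError("frequency must be >= 0")
    n = pig.force_freq_exponent
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(f > 0.0, f ** n / (f ** n + pig.force_freq_half_hz ** n), 0.0)
    return float(g) if g.ndim == 0 else g


def effective_pulse(direction: Direction, width_ms: float, freq_hz: float,
                    bip_total_width: bool = True) -> tuple[float, float]:
    """Map the nominal pulse parameters to the (width, rate) the nerve sees.

    BIP splits the pulse into two opposite phases, so the depolarising
    phase lasts ``T_pw / 2`` (set ``bip_total_width=False`` if the hardware
    convention is per-phase width).  ALT excites each electrode site on
    every other pulse, so the effective rate is ``f_p / 2``.
    """
    if direction is Direction.BIP:
        return (width_ms / 2.0 if bip_total_width else width_ms), freq_hz
    if direction is Direction.ALT:
        return width_ms, freq_hz / 2.0
    return width_ms, freq_hz


def _integrate_linear_lung(p_drive_fine: np.ndarray, pig: PigParams,
                           step_s: float) -> np.ndarray:
    """Fixed-step RK4 integration of ``dV/dt = (P(t) - V/C) / R_aw``.

    ``p_drive_fine`` holds the driving pressure on a ``step_s / 2`` grid
    (values at t, t+h/2, t+h, ...).  Returns lung volume above FRC in
    liters on the ``step_s`` grid.
    """
    tau = pig.time_constant_s
    if step_s > tau:
        raise IntegrationError(
            f"integration step {step_s} s exceeds the time constant {tau:.3f} s"
        )
    c_l = pig.compliance_ml_per_cmh2o / 1000.0
    r = pig.airway_resistance_cmh2o_s_per_l
    n = (len(p_drive_fine) - 1) // 2
    v = np.empty(n + 1)
    v[0] = 0.0
    h = step_s
    vol = 0.0
    for i in range(n):
        p0 = p_drive_fine[2 * i]
        p1 = p_drive_fine[2 * i + 1]
        p2 = p_drive_fine[2 * i + 2]
        k1 = (p0 - vol / c_l) / r
        k2 = (p1 - (vol + 0.5 * h * k1) / c_l) / r
        k3 = (p1 - (vol + 0.5 * h * k2) / c_l) / r
        k4 = (p2 - (vol + h * k3) / c_l) / r
        vol = vol + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        v[i + 1] = vol
    if not np.all(np.isfinite(v)):
        raise IntegrationError("non-finite lung volume; reduce the step size")
    return v


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_breath(
    breath: Union[StimWaveform, MandatoryBreath],
    vent: VentilatorSettings,
    pig: PigParams,
    seed_or_rng=None,
    *,
    exp_duration_s: Optional[float] = None,
    threshold_shift_v: float = 0.0,
    pmax_scale: float = 1.0,
    noise: bool = True,
    step_s: float = DEFAULT_STEP_S,
    bip_total_width: bool = True,
    t0_s: float = 0.0,
) -> BreathTrace:
    """Simulate one breath and return its 10 ms trace.

    For a :class:`MandatoryBreath` the airway pressure steps to ``p_insp``
    for the inspiration time and back to PEEP.  For a stimulation burst the
    diaphragm generates ``P_mus(t) = P_max * recruit(envelope(t)) *
    freq_gain`` during the burst, followed by passive expiration.  The
    breath window is burst (or inspiration) plus ``exp_duration_s``
    (default 3 s, enough for near-complete passive emptying at the default
    time constant).

    Noise (if enabled): one multiplicative Gaussian factor on muscle/driving
    pressure per breath (sd ``breath_noise_sd``) and additive Gaussian flow
    noise per output sample (sd ``flow_noise_sd_lps``).
    """
    rng = _as_rng(seed_or_rng)
    if exp_duration_s is None:
        exp_duration_s = 3.0

    if isinstance(breath, MandatoryBreath):
        t_insp = breath.insp_duration_s or vent.t_insp_s
        phases = ("mand_insp", "mand_exp")
        delta_p = vent.p_insp_cmh2o - vent.p_peep_cmh2o

        def drive(t):
            return np.where(t < t_insp, float(delta_p), 0.0)

        pressure_of = lambda t: np.where(  # noqa: E731  (simple trace labelling)
            t < t_insp, vent.p_insp_cmh2o, vent.p_peep_cmh2o
        )
    else:
        t_insp = breath.burst.burst_duration_s
        phases = ("stim_insp", "stim_exp")
        eff_w, eff_f = effective_pulse(
            breath.pulse.direction, breath.pulse.pulse_width_ms,
            breath.pulse.pulse_frequency_hz, bip_total_width,
        )
        gain = frequency_gain(eff_f, pig)
        p_peak = pig.max_diaphragm_pressure_cmh2o * pmax_scale
        if noise:
            p_peak *= max(0.0, 1.0 + rng.normal(0.0, pig.breath_noise_sd))

        def drive(t):
            env = burst_envelope(t, breath.burst)
            rec = recruitment_fraction(env, eff_w, pig, threshold_shift_v)
            return np.where(t <= t_insp, p_peak * gain * rec, 0.0)

        pressure_of = lambda t: np.full_like(  # noqa: E731
            np.asarray(t, dtype=float), vent.p_peep_cmh2o
        )

    total_s = t_insp + exp_duration_s
    n_steps = int(round(total_s / step_s))
    t_fine = np.arange(2 * n_steps + 1) * (step_s / 2.0)
    p_fine = drive(t_fine)
    volume = _integrate_linear_lung(p_fine, pig, step_s)

    # flow from the equation of motion at the step grid
    c_l = pig.compliance_ml_per_cmh2o / 1000.0
    flow = (p_fine[::2] - volume / c_l) / pig.airway_resistance_cmh2o_s_per_l

    # decimate to the 10 ms acquisition grid
    dec = max(1, int(round(SAMPLE_DT_S / step_s)))
    idx = np.arange(0, n_steps + 1, dec)
    time = idx * step_s
    flow_out = flow[idx].copy()
    if noise and pig.flow_noise_sd_lps > 0.0:
        flow_out += rng.normal(0.0, pig.flow_noise_sd_lps, size=len(flow_out))
    pressure = np.asarray(pressure_of(time), dtype=float)
    phase = np.where(time < t_insp, phases[0], phases[1]).astype(object)
    return BreathTrace(
        t0_s=t0_s, time_s=time, flow_lps=flow_out,
        pressure_cmh2o=pressure, phase=phase,
    )


#: multiplicative sampling bounds for inter-animal variability
_SAMPLE_SPREAD = {
    "body_weight_kg": (0.10, 0.75, 1.30),
    "compliance_ml_per_cmh2o": (0.15, 0.60, 1.60),
    "airway_resistance_cmh2o_s_per_l": (0.15, 0.60, 1.60),
    "max_diaphragm_pressure_cmh2o": (0.15, 0.60, 1.60),
    "rheobase_v": (0.15, 0.60, 1.60),
    "chronaxie_ms": (0.15, 0.60, 1.60),
    "recruitment_slope_v": (0.15, 0.60, 1.60),
    "force_freq_half_hz": (0.10, 0.70, 1.40),
    "force_freq_exponent": (0.08, 0.80, 1.25),
}


def sample_animal(seed, preset: str = "animal_I") -> PigParams:
    """Draw one virtual animal around a preset.

    Each physiological parameter is multiplied by a log-normal factor
    (sigma per parameter in ``_SAMPLE_SPREAD``) clipped to its configured
    range; noise and instability settings are inherited from the preset.
    Identical seeds give bitwise-identical parameter sets.
    """
    base = ANIMAL_PRESETS[preset]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values = {}
    for f in fields(PigParams):
        name = f.name
        if name in _SAMPLE_SPREAD:
            sigma, lo, hi = _SAMPLE_SPREAD[name]
            factor = float(np.clip(rng.lognormal(0.0, sigma), lo, hi))
            values[name] = getattr(base, name) * factor
        else:
            values[name] = getattr(base, name)
    return PigParams(**values)


def sample_range(preset: str, name: str) -> tuple[float, float]:
    """Configured (low, high) bounds for one sampled parameter."""
    base = getattr(ANIMAL_PRESETS[preset], name)
    _, lo, hi = _SAMPLE_SPREAD[name]
    return base * lo, base * hi
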