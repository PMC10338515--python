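"""Automated stimulation-pattern sweep.

The sweep engine enumerates a grid of stimulation patterns (pulse width x
pulse frequency per polarity/ramp subgroup), stimulates five breaths per
pattern, and interleaves a fixed *baseline* pattern before the first
pattern and after every block of ten patterns to track drift of overall
stimulation effectiveness.  Per breath the effectiveness statistic is the
body-weight-scaled tidal volume

    V_T,bw = max over T of  integral_{t_k}^{t_k+T} flow(tau) / m_body dtau

i.e. the largest cumulative inspired volume over the breath, in mL/kg.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid

from .scheduler import VentilatorSettings, plan_cycle
from .virtual_pig import BreathTrace, PigParams, simulate_breath
from .waveforms import BurstSettings, Direction, PulseSettings, build_pulse_train

__all__ = [
    "CANONICAL_FREQUENCIES_HZ",
    "CANONICAL_WIDTHS_MS",
    "GridConfig",
    "PatternSpec",
    "PatternGrid",
    "EvaluationRecord",
    "SweepResult",
    "BaselineStats",
    "tidal_volume",
    "enumerate_grid",
    "run_sweep",
    "baseline_stats",
    "BREATHS_PER_PATTERN",
]

#: canonical evaluation grid: 10 frequencies x 7 widths = 70 per subgroup
CANONICAL_FREQUENCIES_HZ = (10.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0, 142.0,
                            200.0, 208.0)
CANONICAL_WIDTHS_MS = (0.05, 0.10, 0.15, 0.20, 0.30, 0.50, 1.00)

FREQUENCY_RANGE_HZ = (10.0, 208.0)
WIDTH_RANGE_MS = (0.05, 1.0)

BREATHS_PER_PATTERN = 5
BASELINE_EVERY = 10


class GridError(ValueError):
    """Grid definition violates the evaluation parameter ranges."""


@dataclass(frozen=True)
class BaselinePattern:
    """Reference pattern interleaved through the sweep."""

    pulse_width_ms: float = 4.0
    pulse_frequency_hz: float = 200.0
    slope_time_s: float = 1.0
    direction: Direction = Direction.ALT


@dataclass(frozen=True)
class GridConfig:
    """Definition of the pattern grid and the shared burst settings."""

    frequencies_hz: Sequence[float] = CANONICAL_FREQUENCIES_HZ
    widths_ms: Sequence[float] = CANONICAL_WIDTHS_MS
    slope_times_s: Sequence[float] = (0.5, 1.0)
    directions: Sequence[Direction] = (Direction.ALT, Direction.BIP)
    start_voltage: float = 6.5
    end_voltage: float = 10.0
    burst_duration_s: float = 1.10
    burst_rate_per_min: float = 13.0
    baseline: BaselinePattern = field(default_factory=BaselinePattern)

    def __post_init__(self) -> None:
        lo_f, hi_f = FREQUENCY_RANGE_HZ
        for f in self.frequencies_hz:
            if not lo_f <= f <= hi_f:
                raise GridError(
                    f"pulse_frequency: {f} Hz outside the evaluation range "
                    f"{lo_f}-{hi_f} Hz"
                )
        lo_w, hi_w = WIDTH_RANGE_MS
        for w in self.widths_ms:
            if not lo_w <= w <= hi_w:
                raise GridError(
                    f"pulse_width: {w} ms outside the evaluation range "
                    f"{lo_w}-{hi_w} ms"
                )
        for d in self.directions:
            if Direction(d) is Direction.UNI:
                raise GridError("pulse_direction: UNI is excluded from evaluation")


def subgroup_label(direction: Direction, slope_time_s: float) -> str:
    return f"{Direction(direction).value}/{slope_time_s:.1f}"


@dataclass(frozen=True)
class PatternSpec:
    """One grid entry: pulse settings plus its burst envelope and labels."""

    pattern_id: str
    subgroup: str
    pulse: PulseSettings
    burst: BurstSettings
    is_baseline_pattern: bool = False


@dataclass(frozen=True)
class PatternGrid:
    """Ordered pattern list with the interleaved baseline definition."""

    patterns: tuple
    baseline: PatternSpec
    config: GridConfig

    def subgroup(self, label: str) -> tuple:
        return tuple(p for p in self.patterns if p.subgroup == label)

    def subgroup_counts(self) -> dict:
        counts: dict = {}
        for p in self.patterns:
            counts[p.subgroup] = counts.get(p.subgroup, 0) + 1
        return counts


def _make_burst(config: GridConfig, slope_time_s: float) -> BurstSettings:
    return BurstSettings(
        start_voltage=config.start_voltage,
        end_voltage=config.end_voltage,
        slope_time_s=slope_time_s,
        burst_duration_s=config.burst_duration_s,
        burst_rate_per_min=config.burst_rate_per_min,
    )


def enumerate_grid(config: Optional[GridConfig] = None) -> PatternGrid:
    """Enumerate the evaluation grid deterministically.

    Subgroup-major order (directions outer, then ramp times), widths outer
    and frequencies inner within a subgroup.  The baseline pattern is
    appended to its matching subgroup (direction x its ramp time), which is
    why that subgroup counts one pattern more than the others.
    """
    config = config or GridConfig()
    patterns: list[PatternSpec] = []
    for direction, slope in itertools.product(config.directions,
                                              config.slope_times_s):
        label = subgroup_label(direction, slope)
        burst = _make_burst(config, slope)
        for width, freq in itertools.product(config.widths_ms,
                                             config.frequencies_hz):
            pulse = PulseSettings(
                pulse_voltage=config.end_voltage,
                pulse_width_ms=width,
                pulse_frequency_hz=freq,
                direction=Direction(direction),
            )
            patterns.append(
                PatternSpec(
                    pattern_id=f"{label}/w{width:g}/f{freq:g}",
                    subgroup=label,
                    pulse=pulse,
                    burst=burst,
                )
            )
    bl = config.baseline
    bl_label = subgroup_label(bl.direction, bl.slope_time_s)
    baseline = PatternSpec(
        pattern_id=f"baseline/{bl_label}/w{bl.pulse_width_ms:g}/f{bl.pulse_frequency_hz:g}",
        subgroup=bl_label,
        pulse=PulseSettings(
            pulse_voltage=config.end_voltage,
            pulse_width_ms=bl.pulse_width_ms,
            pulse_frequency_hz=bl.pulse_frequency_hz,
            direction=Direction(bl.direction),
        ),
        burst=_make_burst(config, bl.slope_time_s),
        is_baseline_pattern=True,
    )
    block = [i for i, p in enumerate(patterns) if p.subgroup == bl_label]
    if block:
        # the baseline counts as a member of its matching subgroup: insert
        # it at the end of that subgroup's block
        patterns.insert(block[-1] + 1, baseline)
    return PatternGrid(patterns=tuple(patterns), baseline=baseline, config=config)


def tidal_volume(trace: BreathTrace, body_weight_kg: float) -> float:
    """Body-weight-scaled tidal volume of one breath in mL/kg.

    Maximum of the cumulative trapezoidal integral of flow over all breath
    prefixes; the empty prefix is included, so the result is never
    negative.
    """
    if len(trace.time_s) < 2:
        raise ValueError("trace must contain at least two samples")
    if body_weight_kg <= 0.0:
        raise ValueError("body_weight_kg must be > 0")
    vol_l = cumulative_trapezoid(trace.flow_lps, dx=trace.dt_s, initial=0.0)
    return max(0.0, float(vol_l.max())) / body_weight_kg * 1000.0


@dataclass(frozen=True)
class EvaluationRecord:
    """Per-pattern evaluation: five breath volumes and their mean."""

    position: int
    pattern_id: str
    subgroup: str
    pulse_width_ms: float
    pulse_frequency_hz: float
    direction: str
    slope_time_s: float
    breath_volumes_ml_per_kg: tuple
    is_baseline: bool

    def __post_init__(self) -> None:
        if any(v < 0.0 for v in self.breath_volumes_ml_per_kg):
            raise ValueError("tidal volumes must be >= 0")

    @property
    def mean_vt(self) -> float:
        return float(np.mean(self.breath_volumes_ml_per_kg))


@dataclass
class SweepResult:
    """All evaluation records in execution order plus run provenance."""

    records: list
    seed: int
    pig: PigParams
    vent: VentilatorSettings
    breaths_per_pattern: int = BREATHS_PER_PATTERN

    def baseline_records(self) -> list:
        return [r for r in self.records if r.is_baseline]

    def pattern_records(self) -> list:
        return [r for r in self.records if not r.is_baseline]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "position": r.position,
                "pattern_id": r.pattern_id,
                "subgroup": r.subgroup,
                "pulse_width_ms": r.pulse_width_ms,
                "pulse_frequency_hz": r.pulse_frequency_hz,
                "direction": r.direction,
                "slope_time_s": r.slope_time_s,
                "is_baseline": r.is_baseline,
            }
            for i, v in enumerate(r.breath_volumes_ml_per_kg, start=1):
                row[f"vt_breath{i}_ml_per_kg"] = v
            row["mean_vt_ml_per_kg"] = r.mean_vt
            rows.append(row)
        return pd.DataFrame(rows)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def expected_baseline_count(n_patterns: int) -> int:
    """Baselines executed for a grid of ``n_patterns``: one before the
    first pattern and one after every (possibly partial) block of ten."""
    if n_patterns == 0:
        return 1
    return 1 + int(np.ceil(n_patterns / BASELINE_EVERY))


def run_sweep(
    grid: PatternGrid,
    pig: PigParams,
    vent: VentilatorSettings,
    seed: int,
    breaths_per_pattern: int = BREATHS_PER_PATTERN,
    bip_total_width: bool = True,
) -> SweepResult:
    """Execute the automated sweep on a virtual pig.

    Order: baseline, ten patterns, baseline, ... , final baseline after the
    last (possibly partial) block.  Every breath draws from its own seed
    split off the root seed, so identical inputs reproduce the result
    exactly.  Feasibility of the breath schedule is checked for every
    pattern up front; a failed breath simulation aborts the sweep but the
    completed records are preserved on the raised exception.
    """
    # schedule feasibility for every distinct burst duration (incl. baseline)
    for spec in (*grid.patterns, grid.baseline):
        plan_cycle(vent, spec.burst.burst_duration_s)
    schedule = plan_cycle(vent, grid.config.burst_duration_s)
    stim_exp_s = schedule.interval("stim_exp")[1] - schedule.interval("stim_exp")[0]

    ss = np.random.SeedSequence(seed)
    walk_rng = np.random.default_rng(ss.spawn(1)[0])
    breath_seeds = iter(ss.spawn(
        (len(grid.patterns) + expected_baseline_count(len(grid.patterns)))
        * breaths_per_pattern
    ))

    records: list[EvaluationRecord] = []
    state = {"breath_index": 0, "alt_shift_v": 0.0}

    def eval_pattern(spec: PatternSpec, is_baseline: bool) -> None:
        waveform = build_pulse_train(spec.pulse, spec.burst)
        volumes = []
        for _ in range(breaths_per_pattern):
            rng = np.random.default_rng(next(breath_seeds))
            shift = 0.0
            if spec.pulse.direction is Direction.ALT:
                step = walk_rng.normal(0.0, 0.5) * pig.alt_instability
                # electrode polarisation: reflecting random walk on the
                # threshold shift (magnitude accumulates, capped at 15 V)
                state["alt_shift_v"] = float(
                    min(abs(state["alt_shift_v"] + step), 15.0)
                )
                shift = state["alt_shift_v"]
            pmax_scale = (1.0 + pig.drift_rate) ** state["breath_index"]
            try:
                trace = simulate_breath(
                    waveform, vent, pig, rng,
                    exp_duration_s=stim_exp_s,
                    threshold_shift_v=shift,
                    pmax_scale=pmax_scale,
                    bip_total_width=bip_total_width,
                )
            except Exception as exc:
                exc.completed_records = records  # type: ignore[attr-defined]
                raise
            volumes.append(tidal_volume(trace, pig.body_weight_kg))
            state["breath_index"] += 1
        records.append(
            EvaluationRecord(
                position=len(records),
                pattern_id=spec.pattern_id,
                subgroup=spec.subgroup,
                pulse_width_ms=spec.pulse.pulse_width_ms,
                pulse_frequency_hz=spec.pulse.pulse_frequency_hz,
                direction=spec.pulse.direction.value,
                slope_time_s=spec.burst.slope_time_s,
                breath_volumes_ml_per_kg=tuple(volumes),
                is_baseline=is_baseline,
            )
        )

    eval_pattern(grid.baseline, is_baseline=True)
    for i, spec in enumerate(grid.patterns, start=1):
        eval_pattern(spec, is_baseline=False)
        if i % BASELINE_EVERY == 0:
            eval_pattern(grid.baseline, is_baseline=True)
    if grid.patterns and len(grid.patterns) % BASELINE_EVERY != 0:
        eval_pattern(grid.baseline, is_baseline=True)

    return SweepResult(records=records, seed=seed, pig=pig, vent=vent,
                       breaths_per_pattern=breaths_per_pattern)


@dataclass(frozen=True)
class BaselineStats:
    """Drift summary of the interleaved baseline series."""

    mean_ml_per_kg: float
    sd_ml_per_kg: float
    trend_r: float
    trend_p: float

    @property
    def trend_detected(self) -> bool:
        return self.trend_p < 0.05


def baseline_stats(result: SweepResult) -> BaselineStats:
    """Mean and sample SD of the baseline record means plus a two-tailed
    Pearson trend test of baseline mean against sweep position."""
    baselines = result.baseline_records()
    if len(baselines) < 2:
        raise ValueError("need at least two baseline records")
    means = np.array([r.mean_vt for r in baselines])
    positions = np.array([r.position for r in baselines], dtype=float)
    if np.allclose(means, means[0]):
        r_val, p_val = 0.0, 1.0  # constant series: no trend by definition
    else:
        r_val, p_val = stats.pearsonr(positions, means)
    return BaselineStats(
        mean_ml_per_kg=float(means.mean()),
        sd_ml_per_kg=float(means.std(ddof=1)),
        trend_r=float(r_val),
        trend_p=float(p_val),
    )
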