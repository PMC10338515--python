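"""Breath-cycle planning.

Stimulated breaths must be placed *between* mandatory ventilator breaths so
the two never overlap.  One cycle of length ``60 / f_mv`` seconds is laid
out as

    mandatory inspiration | mandatory expiration | burst | stimulated expiration

with user-set minimum expiration times for both breath types; any slack is
assigned to the mandatory expiration (the burst starts as late as
possible).  Interval boundaries follow a half-open convention: a boundary
instant belongs to the following interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


class InfeasibleCycleError(ValueError):
    """The requested breath components do not fit into one cycle."""


@dataclass(frozen=True)
class VentilatorSettings:
    """Pressure-controlled mandatory ventilation settings.

    ``fio2`` is held for completeness but unused by the lung model.
    Pressures in cmH2O, times in seconds, rate in breaths per minute.
    """

    fio2: float = 0.30
    mandatory_rate_per_min: float = 13.0
    p_peep_cmh2o: float = 5.0
    p_insp_cmh2o: float = 17.0
    t_insp_s: float = 1.4
    t_mand_exp_min_s: float = 0.5
    t_stim_exp_min_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.fio2 <= 1.0:
            raise ValueError("fio2 must be a fraction in [0, 1]")
        if self.mandatory_rate_per_min <= 0.0:
            raise ValueError("mandatory_rate_per_min must be > 0")
        if self.t_insp_s >= 60.0 / self.mandatory_rate_per_min:
            raise ValueError("t_insp_s must be shorter than one cycle")
        if self.t_insp_s <= 0.0:
            raise ValueError("t_insp_s must be > 0")
        if self.t_mand_exp_min_s < 0.0 or self.t_stim_exp_min_s < 0.0:
            raise ValueError("minimum expiration times must be >= 0")
        if self.p_insp_cmh2o < self.p_peep_cmh2o:
            raise ValueError("p_insp_cmh2o must be >= p_peep_cmh2o")

    @property
    def cycle_s(self) -> float:
        return 60.0 / self.mandatory_rate_per_min


@dataclass(frozen=True)
class CycleSchedule:
    """Planned intervals (label, start, end) covering exactly one cycle."""

    cycle_s: float
    intervals: tuple  # of (label, start_s, end_s)

    @property
    def burst_start_s(self) -> float:
        for label, start, _ in self.intervals:
            if label == "stim_insp":
                return start
        raise KeyError("schedule has no stimulated inspiration")

    def interval(self, label: str) -> tuple[float, float]:
        for lab, start, end in self.intervals:
            if lab == label:
                return start, end
        raise KeyError(label)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cycle_s": self.cycle_s,
                    "intervals": [
                        {"label": lab, "start_s": a, "end_s": b}
                        for lab, a, b in self.intervals
                    ],
                },
                indent=1,
            )
        )


def plan_cycle(vent: VentilatorSettings, burst_duration_s: float) -> CycleSchedule:
    """Lay one breath cycle out around a burst of the given duration.

    Raises :class:`InfeasibleCycleError` when inspiration, burst and the
    two expiration minimums cannot fit into ``60 / f_mv`` seconds.  With a
    zero burst duration the schedule degenerates to pure mandatory
    ventilation (zero-length stimulation intervals).
    """
    if burst_duration_s < 0.0:
        raise ValueError("burst_duration_s must be >= 0")
    cycle = vent.cycle_s
    slack = (
        cycle
        - vent.t_insp_s
        - vent.t_mand_exp_min_s
        - burst_duration_s
        - vent.t_stim_exp_min_s
    )
    if slack < -1e-12:
        raise InfeasibleCycleError(
            f"mandatory inspiration ({vent.t_insp_s} s) + mandatory expiration "
            f"minimum ({vent.t_mand_exp_min_s} s) + burst ({burst_duration_s} s) + "
            f"stimulated expiration minimum ({vent.t_stim_exp_min_s} s) exceed the "
            f"cycle of {cycle:.3f} s"
        )
    # anchor from the cycle end so rounding never pushes an interval past it:
    # the stimulated expiration keeps exactly its minimum, slack goes to the
    # mandatory expiration
    t1 = vent.t_insp_s
    t3 = cycle - vent.t_stim_exp_min_s
    t2 = max(t1, t3 - burst_duration_s)
    intervals = (
        ("mand_insp", 0.0, t1),
        ("mand_exp", t1, t2),
        ("stim_insp", t2, t3),
        ("stim_exp", t3, cycle),
    )
    return CycleSchedule(cycle_s=cycle, intervals=intervals)


def phase_at(t: float, schedule: CycleSchedule) -> str:
    """Phase label at absolute time ``t`` (wraps around the cycle).

    Boundary instants belong to the later interval; zero-length intervals
    are never returned.
    """
    if t < 0.0:
        raise ValueError("t must be >= 0")
    tc = t % schedule.cycle_s
    for label, start, end in schedule.intervals:
        if start <= tc < end:
            return label
    # tc == cycle_s can only occur through floating wrap; map to cycle start
    return schedule.intervals[0][0]
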