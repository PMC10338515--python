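#!/usr/bin/env python
"""Measure the strength-duration curve of the default virtual animal.

Probes the excitation threshold (flow criterion 0.05 L/s, flat 100 Hz
burst) over the canonical pulse-width list for both polarity schemes,
fits the Lapicque hyperbola, and writes the curves plus fit parameters to
results/.  The biphasic thresholds sit above the alternating ones because
only half the pulse width depolarises; both fits should agree on the
underlying excitability up to that width convention.
"""

import json
from pathlib import Path

from phrenosweep.sdcurve import measure_curve
from phrenosweep.virtual_pig import PigParams
from phrenosweep.scheduler import VentilatorSettings
from phrenosweep.waveforms import Direction

OUT = Path(__file__).resolve().parents[1] / "results"
WIDTHS_MS = (0.05, 0.10, 0.15, 0.20, 0.30, 0.50, 1.00)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    pig = PigParams()
    vent = VentilatorSettings()
    fits = {}
    for direction in (Direction.ALT, Direction.BIP):
        curve = measure_curve(WIDTHS_MS, pig, direction, vent)
        name = direction.value.lower()
        curve.export(OUT / f"sdcurve_{name}.csv", OUT / f"sdcurve_{name}_fit.json")
        fits[direction.value] = (curve.rheobase_v, curve.chronaxie_ms)
        print(f"{direction.value}: rheobase {curve.rheobase_v:.2f} V, "
              f"chronaxie {curve.chronaxie_ms:.3f} ms, "
              f"v_exc_max {curve.v_exc_max:.2f} V")
    print(f"\ngenerating animal: rheobase {pig.rheobase_v} V, "
          f"chronaxie {pig.chronaxie_ms} ms")
    print(f"curves written to {OUT}/sdcurve_*.csv")
    (OUT / "sdcurve_summary.json").write_text(json.dumps(
        {k: {"rheobase_v": v[0], "chronaxie_ms": v[1]} for k, v in fits.items()},
        indent=1))


if __name__ == "__main__":
    main()
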