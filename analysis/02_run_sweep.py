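#!/usr/bin/env python
"""Run the automated 281-pattern sweep on both animal presets.

For each preset (animal_I: consistent reference animal, ALT baseline;
animal_II: lighter, unstable-ALT animal, BIP baseline) this executes the
full interleaved sweep — baseline, ten patterns, baseline, ... — with
five stimulated breaths per pattern, and writes the per-record results
and baseline drift statistics under results/.
"""

import json
from pathlib import Path

from phrenosweep.config import from_dict
from phrenosweep.evaluation import baseline_stats, enumerate_grid, run_sweep

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for preset in ("animal_I", "animal_II"):
        cfg = from_dict({"preset": preset, "seed": SEED})
        result = run_sweep(enumerate_grid(cfg.grid), cfg.pig, cfg.vent, SEED)
        name = preset.lower()
        result.save_csv(OUT / f"sweep_{name}.csv")
        stats = baseline_stats(result)
        doc = {
            "mean_ml_per_kg": stats.mean_ml_per_kg,
            "sd_ml_per_kg": stats.sd_ml_per_kg,
            "trend_r": stats.trend_r,
            "trend_p": stats.trend_p,
            "trend_detected": stats.trend_detected,
        }
        (OUT / f"baseline_{name}.json").write_text(json.dumps(doc, indent=1))
        print(f"{preset}: {len(result.records)} records "
              f"({len(result.baseline_records())} baselines); "
              f"baseline {stats.mean_ml_per_kg:.2f} +/- "
              f"{stats.sd_ml_per_kg:.2f} mL/kg, trend p = {stats.trend_p:.2f}"
              f" ({'drift!' if stats.trend_detected else 'no drift'})")
    print(f"sweeps written to {OUT}/sweep_*.csv")


if __name__ == "__main__":
    main()
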