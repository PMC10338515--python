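#!/usr/bin/env python
"""Statistical analysis of the sweep results from 02_run_sweep.py.

Per animal preset and subgroup: box statistics of the per-pattern mean
tidal volumes, two-tailed Pearson correlations of tidal volume against
pulse frequency and pulse width, plateau onsets on both axes, and the
interpolated response-surface tables.  Prints the findings the sweep
supports: frequency correlates strongly with tidal volume everywhere,
biphasic responses saturate near 80 Hz and 0.15 ms, the ramp time has a
weak effect, and the unstable-ALT animal separates ALT from BIP medians.
"""

from pathlib import Path

import pandas as pd

from phrenosweep.analysis import (
    box_table,
    correlation_table,
    plateau_onset,
    surface_table,
)
from phrenosweep.evaluation import CANONICAL_FREQUENCIES_HZ, CANONICAL_WIDTHS_MS

OUT = Path(__file__).resolve().parents[1] / "results"


def analyze(preset: str) -> None:
    name = preset.lower()
    df = pd.read_csv(OUT / f"sweep_{name}.csv")
    corr = correlation_table(df)
    corr.to_csv(OUT / f"correlations_{name}.csv", index=False)
    box = box_table(df)
    box.to_csv(OUT / f"boxstats_{name}.csv", index=False)

    print(f"\n=== {preset} ===")
    fp = corr[corr["parameter"] == "f_p"].set_index("subgroup")
    print("r(f_p, V_T,bw):",
          ", ".join(f"{sg} {row.r:.2f} (p={row.p:.1e})"
                    for sg, row in fp.iterrows()))
    print("medians (mL/kg):",
          ", ".join(f"{r.subgroup} {r['median']:.2f}"
                    for _, r in box.iterrows()))
    for sg in sorted(df["subgroup"].unique()):
        sub = df[(df["subgroup"] == sg) & (~df["is_baseline"])]
        surface_table(df, sg).to_csv(
            OUT / f"surface_{name}_{sg.replace('/', '_').replace('.', 'p')}.csv",
            index=False,
        )
        if sg.startswith("BIP"):
            f_on = plateau_onset(sub, "frequency", 0.3, CANONICAL_FREQUENCIES_HZ)
            w_on = plateau_onset(sub, "width", 80.0, CANONICAL_WIDTHS_MS)
            print(f"{sg}: frequency plateau {f_on.onset:g} Hz, "
                  f"width plateau {w_on.onset:g} ms")
    # ramp-time effect: compare subgroup medians across T_slope
    bx = box.set_index("subgroup")
    for d in ("ALT", "BIP"):
        m05, m10 = bx.loc[f"{d}/0.5", "median"], bx.loc[f"{d}/1.0", "median"]
        rel = abs(m05 - m10) / max(m05, m10) if max(m05, m10) > 0 else 0.0
        print(f"{d}: ramp-time median difference {rel * 100:.1f}%")


def main() -> None:
    for preset in ("animal_I", "animal_II"):
        analyze(preset)
    print(f"\ntables written to {OUT}/")


if __name__ == "__main__":
    main()
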