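#!/usr/bin/env python
"""Behavioral learning curves: d', percent correct, phases, slopes.

Reads the per-day trial tables written by 01_simulate_cohort.py, computes
each animal's learning curve, segments it into early/late/expert phases
(40% progress rule with expert-criterion precedence) and fits per-phase
slopes. Writes results/behavior.csv.
"""

import json
from pathlib import Path

import pandas as pd

from spikeflex import io
from spikeflex.behavior import behavior_table

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"


def main() -> None:
    manifest = json.loads((SIM / "manifest.json").read_text())
    frames = []
    for entry in manifest["animals"]:
        bdir = SIM / entry["behavior"]
        days = [io.read_trials(p) for p in sorted(bdir.glob("day*.csv"))]
        df = behavior_table(days)
        df.insert(0, "animal", entry["animal"])
        frames.append(df)
        phases = " ".join(df["phase"])
        print(
            f"{entry['animal']}: d' {df['dprime'].iloc[0]:.2f} -> "
            f"{df['dprime'].iloc[-1]:.2f}; phases: {phases}"
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(ROOT / "behavior.csv", index=False)
    late = out[out["phase"] == "late"]["phase_slope"].mean()
    early = out[out["phase"] == "early"]["phase_slope"].mean()
    print(
        f"mean slope early {early:.3f} vs late {late:.3f} d'/session "
        "(steepest gains expected during late learning)"
    )


if __name__ == "__main__":
    main()
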