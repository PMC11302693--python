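#!/usr/bin/env python
"""Participation-ratio dimensionality of population activity by cell class.

Builds per-trial spike-count activity matrices (stimulus-aligned 200-ms
window), then estimates the large-n dimensionality D_inf separately for
the classically and non-classically responsive subpopulations with the
two-level bootstrap (units resampled within animal for the variance
moment, sessions resampled for the covariance moment). Writes
results/dimensionality.json.
"""

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from spikeflex import io
from spikeflex.dimensionality import (
    activity_matrix,
    bootstrap_dimensionality,
    session_covariance,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"
SEED = 31
B = 2000


def main() -> None:
    manifest = json.loads((SIM / "manifest.json").read_text())
    profiles = pd.read_csv(ROOT / "profiles.csv").set_index("unit_id")
    out = {}
    for group in ("CR", "NCR", "all"):
        animal_vars: dict[str, np.ndarray] = {}
        covs = []
        for entry in manifest["animals"]:
            for name in entry["sessions"]:
                session, _ = io.read_session(SIM / name)
                units = [
                    u
                    for u in session.units
                    if group == "all" or profiles.loc[u, "final_label"] == group
                ]
                if len(units) < 2:
                    continue
                A = activity_matrix(session, units)
                C = session_covariance(A)
                covs.append(C)
                a = entry["animal"]
                animal_vars[a] = np.concatenate(
                    [animal_vars.get(a, np.empty(0)), np.diag(C)]
                )
        est = bootstrap_dimensionality(animal_vars, covs, b=B, seed=SEED)
        out[group] = asdict(est)
        print(
            f"{group:>4}: D_inf = {est.d_inf:.1f} "
            f"(bootstrap {est.bootstrap_mean:.1f} +/- {est.bootstrap_sem:.1f}, "
            f"n = {est.n} units)"
        )
    (ROOT / "dimensionality.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
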