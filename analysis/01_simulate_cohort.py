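#!/usr/bin/env python
"""Simulate the synthetic cohort every downstream analysis consumes.

Three "animals", two sessions each, 16 simultaneously recorded units per
session (half rate-modulated, half rate-flat with ISI-shape coding, plus
a weak shared trial gain to induce pairwise correlations), and an
eight-day learning trajectory of trial tables per animal. Outputs go to
results/sim/.
"""

import json
from pathlib import Path

import numpy as np

from spikeflex import io
from spikeflex.experiments import mixed_population
from spikeflex.synth import SessionGenSpec, simulate_learning_curve, simulate_session

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 42

N_ANIMALS = 3
SESSIONS_PER_ANIMAL = 2
N_UNITS = 16
N_TRIALS = 200
SHARED_GAIN_SD = 0.25

DAYS = 8
HIT_TRAJ = np.linspace(0.55, 0.92, DAYS)
FA_TRAJ = np.linspace(0.45, 0.12, DAYS)
TRIALS_PER_DAY = 200


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = {"animals": [], "seed": SEED}
    root = np.random.SeedSequence(SEED)
    for a, animal_ss in enumerate(root.spawn(N_ANIMALS)):
        animal = f"m{a:02d}"
        sess_dirs = []
        for s, child in enumerate(animal_ss.spawn(SESSIONS_PER_ANIMAL + 1)[:-1]):
            seed = int(np.random.default_rng(child).integers(2**31 - 1))
            units = mixed_population(N_UNITS)
            units = [
                type(u)(**{**u.__dict__, "unit_id": f"{animal}s{s}_{u.unit_id}"})
                for u in units
            ]
            session, truth = simulate_session(
                SessionGenSpec(
                    n_units=N_UNITS,
                    n_trials=N_TRIALS,
                    shared_gain_sd=SHARED_GAIN_SD,
                    seed=seed,
                ),
                units,
            )
            d = OUT / f"{animal}_session{s}"
            io.write_session(session, truth, d)
            sess_dirs.append(d.name)
        behav_seed = int(
            np.random.default_rng(animal_ss.spawn(SESSIONS_PER_ANIMAL + 1)[-1]).integers(
                2**31 - 1
            )
        )
        days = simulate_learning_curve(
            DAYS, HIT_TRAJ, FA_TRAJ, TRIALS_PER_DAY, seed=behav_seed
        )
        bdir = OUT / f"{animal}_behavior"
        bdir.mkdir(exist_ok=True)
        for day, trials in enumerate(days):
            io.write_trials(trials, bdir / f"day{day:02d}.csv")
        manifest["animals"].append(
            {"animal": animal, "sessions": sess_dirs, "behavior": bdir.name}
        )
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"wrote {N_ANIMALS} animals x {SESSIONS_PER_ANIMAL} sessions to {OUT}")


if __name__ == "__main__":
    main()
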