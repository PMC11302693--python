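"""Columnar on-disk formats shared by the generator and the analyses.

Trials: CSV with trial_id, onset_s, stimulus, response_time_s, outcome.
Spikes: CSV with unit_id, spike_time_s. Ground truth: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synth import GroundTruth, RecordingSession

TRIAL_COLUMNS = ["trial_id", "onset_s", "stimulus", "response_time_s", "outcome"]
SPIKE_COLUMNS = ["unit_id", "spike_time_s"]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials file missing columns: {sorted(missing)}")
    return df


def write_spikes(spikes: pd.DataFrame, path: str | Path) -> None:
    spikes[SPIKE_COLUMNS].to_csv(path, index=False)


def read_spikes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spikes file missing columns: {sorted(missing)}")
    return df


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_session(session: RecordingSession, truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trials(session.trials, out / "trials.csv")
    write_spikes(session.spikes, out / "spikes.csv")
    write_ground_truth(truth, out / "ground_truth.json")


def read_session(
    in_dir: str | Path, tone_duration: float = 0.1, response_window: float = 2.5
) -> tuple[RecordingSession, GroundTruth | None]:
    src = Path(in_dir)
    trials = read_trials(src / "trials.csv")
    spikes = read_spikes(src / "spikes.csv")
    truth = None
    gt_path = src / "ground_truth.json"
    if gt_path.exists():
        truth = read_ground_truth(gt_path)
        tone_duration = truth.session_spec.tone_duration
        response_window = truth.session_spec.response_window
    units = sorted(spikes["unit_id"].unique().tolist())
    session = RecordingSession(
        trials=trials,
        spikes=spikes,
        units=units,
        tone_duration=tone_duration,
        response_window=response_window,
    )
    return session, truth
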