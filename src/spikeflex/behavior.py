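"""Behavioral performance, learning-phase segmentation, movement onsets.

d' follows the standard signal-detection convention
``d' = z(hit rate) - z(false-alarm rate)`` with rates clipped to
[1/(2N), 1 - 1/(2N)] per stimulus class so perfect sessions stay finite.
Learning phases: a session is *expert* when d' >= 1.5 and percent correct
>= 70 (the criterion takes precedence), *early* when progress from the
animal's minimum to maximum d' is below 40%, *late* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

EXPERT_DPRIME = 1.5
EXPERT_PERCENT_CORRECT = 70.0
EARLY_PROGRESS = 0.40

PHASE_ORDER = ("early", "late", "expert")


def compute_dprime(trials: pd.DataFrame, clip: float | None = None) -> tuple[float, float]:
    """d' and percent correct for one session's trial table.

    ``clip`` overrides the per-class default rate clip of 1/(2N).
    """
    stim = trials["stimulus"].to_numpy()
    outcome = trials["outcome"].to_numpy()
    n_t = int((stim == "target").sum())
    n_nt = int((stim == "nontarget").sum())
    if n_t == 0 or n_nt == 0:
        raise ValueError("need at least one target and one nontarget trial")
    hits = int((outcome == "hit").sum())
    fas = int((outcome == "false_alarm").sum())
    crs = int((outcome == "correct_reject").sum())

    clip_t = clip if clip is not None else 1.0 / (2 * n_t)
    clip_nt = clip if clip is not None else 1.0 / (2 * n_nt)
    hit_rate = np.clip(hits / n_t, clip_t, 1.0 - clip_t)
    fa_rate = np.clip(fas / n_nt, clip_nt, 1.0 - clip_nt)
    dprime = float(norm.ppf(hit_rate) - norm.ppf(fa_rate))
    percent_correct = 100.0 * (hits + crs) / len(trials)
    return dprime, percent_correct


def segment_learning_phases(
    dprimes: Sequence[float], percent_corrects: Sequence[float]
) -> list[str]:
    """Label each session early / late / expert from the animal's d' range."""
    d = np.asarray(dprimes, dtype=float)
    pc = np.asarray(percent_corrects, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 sessions to segment")
    lo, hi = float(d.min()), float(d.max())
    if hi <= lo:
        raise ValueError("flat learning curve: unsegmentable (max d' == min d')")
    progress = (d - lo) / (hi - lo)
    labels = []
    for p, di, pci in zip(progress, d, pc):
        if di >= EXPERT_DPRIME and pci >= EXPERT_PERCENT_CORRECT:
            labels.append("expert")
        elif p < EARLY_PROGRESS:
            labels.append("early")
        else:
            labels.append("late")
    return labels


def phase_slopes(
    dprimes: Sequence[float], phases: Sequence[str]
) -> dict[str, float]:
    """OLS slope of d' vs session index per phase.

    Non-expert phases include the first session of the next phase present,
    mirroring how learning-curve slopes bridge phase boundaries. A phase
    whose point set has fewer than 2 sessions gets NaN (flagged by warning).
    """
    d = np.asarray(dprimes, dtype=float)
    phases = list(phases)
    if len(phases) != d.size:
        raise ValueError("phases and dprimes must align")
    slopes: dict[str, float] = {}
    present = [p for p in PHASE_ORDER if p in phases]
    for k, phase in enumerate(present):
        idx = [i for i, p in enumerate(phases) if p == phase]
        if phase != "expert":
            for nxt in present[k + 1 :]:
                nxt_idx = [i for i, p in enumerate(phases) if p == nxt]
                if nxt_idx:
                    idx = idx + [nxt_idx[0]]
                    break
        idx = sorted(set(idx))
        if len(idx) < 2:
            warnings.warn(f"phase '{phase}' has a single session; slope undefined")
            slopes[phase] = float("nan")
            continue
        x = np.asarray(idx, dtype=float)
        y = d[idx]
        slopes[phase] = float(np.polyfit(x, y, 1)[0])
    return slopes


@dataclass
class MovementOnset:
    onset_frame: int | None
    speed_before: float
    speed_after: float


def detect_movement_onset(
    speed: Sequence[float],
    frame_rate: float = 100.0,
    window: int = 100,
    mode: str = "first_crossing",
) -> MovementOnset:
    """Detect movement onset from a per-frame speed trace.

    For each frame f, diff(f) = mean(speed[f:f+window]) -
    mean(speed[f-window:f]). Onset is the first frame whose diff exceeds
    mean(diff) + 2*sd(diff) over the whole trace (``mode='first_crossing'``,
    the default). Because diff ramps up over ``window`` frames before a
    step, the first crossing precedes the true step by up to ``window``
    frames; ``mode='peak'`` instead returns the argmax of diff within the
    first above-threshold run, which recovers a step onset to within a few
    frames. ``mode='lookahead'`` returns the first frame with a crossing
    within the next ``window`` frames.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size <= 3 * window:
        raise ValueError(f"trace must be longer than {3 * window} frames")
    csum = np.concatenate([[0.0], np.cumsum(speed)])
    frames = np.arange(window, speed.size - window)
    fwd = (csum[frames + window] - csum[frames]) / window
    bwd = (csum[frames] - csum[frames - window]) / window
    diff = fwd - bwd
    thresh = diff.mean() + 2.0 * diff.std()
    above = diff > thresh
    if not above.any():
        return MovementOnset(None, float("nan"), float("nan"))
    first = int(np.argmax(above))
    if mode == "lookahead":
        # earliest frame with a crossing somewhere in the next `window` frames
        first = max(0, first - window + 1)
    elif mode == "peak":
        run_end = first
        while run_end < above.size and above[run_end]:
            run_end += 1
        first = first + int(np.argmax(diff[first:run_end]))
    elif mode != "first_crossing":
        raise ValueError("mode must be 'first_crossing', 'peak' or 'lookahead'")
    onset = int(frames[first])
    half = int(round(0.5 * frame_rate))
    before = float(speed[max(0, onset - half) : onset].mean())
    after = float(speed[onset : onset + half].mean())
    return MovementOnset(onset, before, after)


def behavior_table(day_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-session summary (day, d', percent correct, phase, slope)."""
    rows = []
    for day, trials in enumerate(day_tables):
        dp, pc = compute_dprime(trials)
        rows.append({"day": day, "dprime": dp, "percent_correct": pc,
                     "n_trials": len(trials)})
    df = pd.DataFrame(rows)
    df["phase"] = segment_learning_phases(df["dprime"], df["percent_correct"])
    slopes = phase_slopes(df["dprime"].to_numpy(), df["phase"])
    df["phase_slope"] = df["phase"].map(slopes)
    return df
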