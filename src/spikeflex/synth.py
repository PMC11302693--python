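"""Synthetic recording sessions with known ground truth.

Generates sessions of simultaneously recorded spike trains over a go/no-go
trial structure so that every downstream stage (responsiveness
classification, ISI decoding, dimensionality) can be exercised against
known unit properties.

Spiking model: gamma-renewal process with shape ``k`` and rate ``k * r``
(mean ISI ``1/r``), so the mean firing rate and the ISI regularity can be
controlled independently. Poisson spiking is the ``k = 1`` special case.
A unit can carry task information either in its rate (``stim_delta``,
``choice_delta``; the classically responsive regime) or purely in its ISI
statistics (condition-dependent shape at matched rate; the
non-classically responsive regime).

Rates are piecewise constant at window boundaries. Each maximal
constant-parameter segment is sampled from a warm-started (approximately
equilibrium) gamma-renewal chain, so expected counts equal rate times
window length for every shape; the renewal age restarts only where the
rate or shape actually switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

REFRACTORY_S = 0.001

GO_OUTCOMES = ("hit", "false_alarm")


@dataclass(frozen=True)
class UnitGenSpec:
    """Ground-truth generative parameters of one unit.

    ``true_label`` records the intended responsiveness class: "CR" for
    rate-modulated units, "NCR" for rate-flat units (which may still be
    ISI-shape coded via the two shape parameters).
    """

    unit_id: str
    baseline_rate: float
    stim_delta: float = 0.0
    choice_delta: float = 0.0
    isi_shape_target: float = 1.0
    isi_shape_nontarget: float = 1.0
    true_label: str = "NCR"
    # rate change on nontarget trials; None means equal to stim_delta
    # (tone-selective classically responsive cells respond unequally)
    stim_delta_nontarget: float | None = None

    def delta_for(self, stimulus: str) -> float:
        if stimulus == "target" or self.stim_delta_nontarget is None:
            return self.stim_delta
        return self.stim_delta_nontarget

    def validate(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        deltas = [self.stim_delta, self.choice_delta]
        if self.stim_delta_nontarget is not None:
            deltas.append(self.stim_delta_nontarget)
        if self.baseline_rate + min(*deltas, 0.0) < 0:
            raise ValueError("negative instantaneous rate: delta exceeds baseline")
        if self.isi_shape_target <= 0 or self.isi_shape_nontarget <= 0:
            raise ValueError("ISI shape parameters must be > 0")
        if self.true_label not in ("CR", "NCR"):
            raise ValueError("true_label must be 'CR' or 'NCR'")


@dataclass(frozen=True)
class SessionGenSpec:
    """Parameters of one simulated behavioral session.

    Tone duration and response window default to the task values
    (100 ms tone, 2.5 s response window). ``shared_gain_sd`` is the
    log-domain SD of a per-trial multiplicative gain shared by all units;
    it induces positive pairwise spike-count correlations without changing
    any unit's label. Behavioral parameters (``p_hit``, ``p_fa``,
    ``go_latency``) are needed to place choice windows.
    """

    n_units: int = 10
    n_trials: int = 100
    p_target: float = 0.5
    tone_duration: float = 0.1
    response_window: float = 2.5
    shared_gain_sd: float = 0.0
    seed: int = 0
    p_hit: float = 0.85
    p_fa: float = 0.15
    go_latency: tuple[float, float] = (0.35, 1.2)
    iti: tuple[float, float] = (3.0, 7.0)

    def validate(self) -> None:
        if not (0.0 < self.p_target < 1.0):
            raise ValueError("p_target must be in (0, 1)")
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials")
        if self.tone_duration >= self.response_window:
            raise ValueError("tone_duration must be < response_window")
        if self.shared_gain_sd < 0:
            raise ValueError("shared_gain_sd must be >= 0")


@dataclass
class RecordingSession:
    """One simulated session: shared trial table plus per-unit spikes."""

    trials: pd.DataFrame
    spikes: pd.DataFrame
    units: list[str]
    tone_duration: float = 0.1
    response_window: float = 2.5

    def unit_spike_times(self, unit_id: str) -> np.ndarray:
        sel = self.spikes.loc[self.spikes["unit_id"] == unit_id, "spike_time_s"]
        return sel.to_numpy(dtype=float)


@dataclass
class GroundTruth:
    """Losslessly serializable record of everything the generator used."""

    unit_specs: list[UnitGenSpec]
    session_spec: SessionGenSpec
    behavioral_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "unit_specs": [asdict(u) for u in self.unit_specs],
            "session_spec": asdict(self.session_spec),
            "behavioral_params": self.behavioral_params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        sess = dict(d["session_spec"])
        for key in ("go_latency", "iti"):
            sess[key] = tuple(sess[key])
        return cls(
            unit_specs=[UnitGenSpec(**u) for u in d["unit_specs"]],
            session_spec=SessionGenSpec(**sess),
            behavioral_params=dict(d["behavioral_params"]),
        )


def make_trial_table(
    n_trials: int,
    p_target: float,
    p_hit: float,
    p_fa: float,
    rng: np.random.Generator,
    tone_duration: float = 0.1,
    response_window: float = 2.5,
    iti: tuple[float, float] = (3.0, 7.0),
    go_latency: tuple[float, float] = (0.35, 1.2),
) -> pd.DataFrame:
    """Build a trial table with onsets, stimulus labels, outcomes and RTs.

    Stimulus labels use an exact split (round(n * p_target) targets),
    shuffled. Outcomes are Bernoulli draws: hit with ``p_hit`` on target
    trials, false alarm with ``p_fa`` on nontarget trials; go responses
    get a uniform latency inside ``go_latency``.
    """
    n_target = int(round(n_trials * p_target))
    if n_target == 0 or n_target == n_trials:
        raise ValueError("p_target yields a single-class session")
    stimulus = np.array(["target"] * n_target + ["nontarget"] * (n_trials - n_target))
    rng.shuffle(stimulus)
    onsets = np.cumsum(rng.uniform(iti[0], iti[1], size=n_trials)) + 1.0

    responded = np.where(
        stimulus == "target",
        rng.random(n_trials) < p_hit,
        rng.random(n_trials) < p_fa,
    )
    latency = rng.uniform(go_latency[0], go_latency[1], size=n_trials)
    latency = np.minimum(latency, response_window - 1e-3)
    response_time = np.where(responded, onsets + latency, np.nan)
    outcome = np.where(
        stimulus == "target",
        np.where(responded, "hit", "miss"),
        np.where(responded, "false_alarm", "correct_reject"),
    )
    return pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "onset_s": onsets,
            "stimulus": stimulus,
            "response_time_s": response_time,
            "outcome": outcome,
        }
    )


def choice_centers(trials: pd.DataFrame) -> np.ndarray:
    """Choice-window centers: the response time on go trials, onset plus
    the session's mean go latency on no-go trials."""
    onsets = trials["onset_s"].to_numpy(dtype=float)
    rts = trials["response_time_s"].to_numpy(dtype=float)
    has_rt = np.isfinite(rts)
    if not has_rt.any():
        raise ValueError("session has no go trials; choice windows undefined")
    mean_latency = float(np.mean(rts[has_rt] - onsets[has_rt]))
    return np.where(has_rt, rts, onsets + mean_latency)


def _gamma_segment(
    rng: np.random.Generator,
    rate: float,
    shape: float,
    t0: float,
    t1: float,
    warmup_isis: float = 12.0,
) -> np.ndarray:
    """Sample a gamma-renewal train on [t0, t1).

    The chain is warm-started ``warmup_isis`` mean intervals before t0 and
    spikes before t0 discarded, so the process is approximately in
    equilibrium at t0: the expected count in any sub-window is rate times
    its length for every shape. (A cold start at age 0 under- or
    over-counts by ~(1/shape - 1)/2 spikes near t0, which would turn a
    pure ISI-shape contrast into a spurious rate contrast.)
    """
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    scale = 1.0 / (shape * rate)
    start = t0 - warmup_isis / rate
    expected = rate * (t1 - start)
    out = []
    t = start
    while True:
        block = max(16, int(expected + 4.0 * np.sqrt(expected + 1.0)))
        isis = rng.gamma(shape, scale, size=block)
        times = t + np.cumsum(isis)
        out.append(times[(times >= t0) & (times < t1)])
        if times[-1] >= t1:
            break
        t = times[-1]
        expected = rate * (t1 - t)
    return np.concatenate(out)


def _merge_segments(
    segments: list[tuple[float, float, float, float]]
) -> list[tuple[float, float, float, float]]:
    """Fuse adjacent segments with identical rate and shape so that no
    renewal restart happens where nothing actually changes."""
    merged: list[list[float]] = []
    for a, b, rate, shape in segments:
        if b <= a:
            continue
        if merged and merged[-1][1] == a and merged[-1][2] == rate and merged[-1][3] == shape:
            merged[-1][1] = b
        else:
            merged.append([a, b, rate, shape])
    return [tuple(m) for m in merged]


def enforce_refractory(times: np.ndarray, refractory: float = REFRACTORY_S) -> np.ndarray:
    """Greedy deletion of any spike within ``refractory`` of the last kept one."""
    if times.size == 0:
        return times
    kept = [times[0]]
    last = times[0]
    for t in times[1:]:
        if t - last >= refractory:
            kept.append(t)
            last = t
    return np.asarray(kept)


def simulate_unit(
    spec: UnitGenSpec,
    trials: pd.DataFrame,
    gain: Sequence[float],
    seed: int | np.random.SeedSequence,
    tone_duration: float = 0.1,
    response_window: float = 2.5,
    stim_window: float = 0.2,
    choice_halfwidth: float = 0.05,
    trial_pre: float = 0.5,
) -> np.ndarray:
    """Simulate one unit's spike train over the whole session.

    Within each trial's span ([onset - trial_pre, onset + response_window])
    the hazard rate is ``baseline_rate * gain`` except in the stimulus
    window ([onset, onset + stim_window]; ``+ stim_delta``) and the 100-ms
    choice window centered on the behavioral response (``+ choice_delta``),
    and the ISI shape is set by the trial's stimulus condition. Between
    trials the unit fires at baseline with shape 1 and unit gain.
    """
    spec.validate()
    if len(trials) == 0:
        raise ValueError("empty trial table")
    gain = np.asarray(gain, dtype=float)
    if gain.shape[0] != len(trials):
        raise ValueError("gain must have one entry per trial")
    if (gain <= 0).any():
        raise ValueError("gains must be positive")

    rng = np.random.default_rng(seed)
    onsets = trials["onset_s"].to_numpy(dtype=float)
    stims = trials["stimulus"].to_numpy()
    centers = choice_centers(trials)

    segments: list[tuple[float, float, float, float]] = []  # (t0, t1, rate, shape)
    prev_end = 0.0
    for onset, stim, center, g in zip(onsets, stims, centers, gain):
        t_start = onset - trial_pre
        t_end = onset + response_window
        if t_start > prev_end:
            segments.append((prev_end, t_start, spec.baseline_rate, 1.0))
        shape = (
            spec.isi_shape_target if stim == "target" else spec.isi_shape_nontarget
        )
        # breakpoints within the trial span
        pts = sorted(
            {
                t_start,
                onset,
                onset + stim_window,
                center - choice_halfwidth,
                center + choice_halfwidth,
                t_end,
            }
        )
        pts = [p for p in pts if t_start <= p <= t_end]
        for a, b in zip(pts[:-1], pts[1:]):
            mid = 0.5 * (a + b)
            rate = spec.baseline_rate
            if onset <= mid < onset + stim_window:
                rate += spec.delta_for(stim)
            if center - choice_halfwidth <= mid < center + choice_halfwidth:
                rate += spec.choice_delta
            rate = max(rate, 0.0) * g
            segments.append((a, b, rate, shape))
        prev_end = t_end

    trains = [
        _gamma_segment(rng, rate, shape, a, b)
        for a, b, rate, shape in _merge_segments(segments)
    ]
    times = np.sort(np.concatenate(trains)) if trains else np.empty(0)
    return enforce_refractory(times)


def simulate_session(
    spec: SessionGenSpec, unit_specs: Sequence[UnitGenSpec]
) -> tuple[RecordingSession, GroundTruth]:
    """Simulate a session: one shared trial table, per-unit trains sharing
    the same per-trial log-normal gain (mean 1)."""
    spec.validate()
    for u in unit_specs:
        u.validate()
    ss = np.random.SeedSequence(spec.seed)
    trial_seed, gain_seed, *unit_seeds = ss.spawn(2 + len(unit_specs))
    trials = make_trial_table(
        spec.n_trials,
        spec.p_target,
        spec.p_hit,
        spec.p_fa,
        np.random.default_rng(trial_seed),
        tone_duration=spec.tone_duration,
        response_window=spec.response_window,
        iti=spec.iti,
        go_latency=spec.go_latency,
    )
    grng = np.random.default_rng(gain_seed)
    if spec.shared_gain_sd > 0:
        s = spec.shared_gain_sd
        gain = grng.lognormal(mean=-0.5 * s * s, sigma=s, size=spec.n_trials)
    else:
        gain = np.ones(spec.n_trials)

    frames = []
    for u, child in zip(unit_specs, unit_seeds):
        times = simulate_unit(
            u,
            trials,
            gain,
            child,
            tone_duration=spec.tone_duration,
            response_window=spec.response_window,
        )
        frames.append(pd.DataFrame({"unit_id": u.unit_id, "spike_time_s": times}))
    spikes = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["unit_id", "spike_time_s"])
    )
    session = RecordingSession(
        trials=trials,
        spikes=spikes,
        units=[u.unit_id for u in unit_specs],
        tone_duration=spec.tone_duration,
        response_window=spec.response_window,
    )
    truth = GroundTruth(
        unit_specs=list(unit_specs),
        session_spec=spec,
        behavioral_params={"p_hit": spec.p_hit, "p_fa": spec.p_fa},
    )
    return session, truth


def simulate_learning_curve(
    days: int,
    hit_traj: Sequence[float],
    fa_traj: Sequence[float],
    trials_per_day: int,
    seed: int,
    p_target: float = 0.5,
) -> list[pd.DataFrame]:
    """Per-day trial tables following given hit/false-alarm trajectories."""
    hit_traj = np.asarray(hit_traj, dtype=float)
    fa_traj = np.asarray(fa_traj, dtype=float)
    if days < 1 or hit_traj.size != days or fa_traj.size != days:
        raise ValueError("need one hit and one false-alarm probability per day")
    if ((hit_traj <= 0) | (hit_traj >= 1) | (fa_traj <= 0) | (fa_traj >= 1)).any():
        raise ValueError("probabilities must be in (0, 1)")
    ss = np.random.SeedSequence(seed)
    tables = []
    for child, ph, pf in zip(ss.spawn(days), hit_traj, fa_traj):
        tables.append(
            make_trial_table(
                trials_per_day, p_target, ph, pf, np.random.default_rng(child)
            )
        )
    return tables


def simulate_speed_trace(
    n_frames: int,
    onset_frame: int,
    pre_speed: float,
    post_speed: float,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Step-change kinematic speed trace with additive Gaussian noise."""
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if not (100 < onset_frame < n_frames - 100):
        raise ValueError("onset_frame must leave 100 frames on either side")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    trace = np.full(n_frames, pre_speed, dtype=float)
    trace[onset_frame:] = post_speed
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, size=n_frames)
    return trace
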