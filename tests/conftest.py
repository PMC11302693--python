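import numpy as np
import pandas as pd
import pytest

from spikeflex.synth import SessionGenSpec, UnitGenSpec, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trials(onsets, stimulus=None, response_times=None):
    """Minimal trial table for hand-constructed fixtures."""
    onsets = np.asarray(onsets, dtype=float)
    n = onsets.size
    if stimulus is None:
        stimulus = np.where(np.arange(n) % 2 == 0, "target", "nontarget")
    if response_times is None:
        response_times = np.where(
            np.asarray(stimulus) == "target", onsets + 0.5, np.nan
        )
    rts = np.asarray(response_times, dtype=float)
    outcome = np.where(
        np.asarray(stimulus) == "target",
        np.where(np.isfinite(rts), "hit", "miss"),
        np.where(np.isfinite(rts), "false_alarm", "correct_reject"),
    )
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "onset_s": onsets,
            "stimulus": stimulus,
            "response_time_s": rts,
            "outcome": outcome,
        }
    )


@pytest.fixture
def small_session():
    """8 units (4 rate-modulated, 4 flat), 60 trials; cheap but realistic."""
    units = [
        UnitGenSpec(f"cr{i}", 5.0, stim_delta=6.0, true_label="CR") for i in range(4)
    ] + [UnitGenSpec(f"ncr{i}", 5.0, true_label="NCR") for i in range(4)]
    session, truth = simulate_session(
        SessionGenSpec(n_units=8, n_trials=60, seed=99), units
    )
    return session, truth
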