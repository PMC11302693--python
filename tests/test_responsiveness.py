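"""Responsiveness metrics against recount/brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeflex.responsiveness import (
    WindowConfig,
    best_frequency,
    bootstrap_classify,
    choice_modulation,
    classify_by_threshold,
    evoked_rate,
    fit_separating_threshold,
    spontaneous_rate,
    stimulus_modulation,
    tone_selectivity,
)

from conftest import make_trials

CFG = WindowConfig()


def regular_baseline_train(onsets, spikes_per_baseline=3):
    """Exactly k spikes inside every 150-ms baseline window, nothing else."""
    out = []
    for o in onsets:
        out.extend(o - 0.15 + 0.15 * (np.arange(spikes_per_baseline) + 0.5) /
                   spikes_per_baseline)
    return np.sort(np.asarray(out))


class TestSpontaneousRate:
    def test_three_spikes_per_window_is_twenty_hz(self):
        onsets = 5.0 * np.arange(1, 11)
        st_times = regular_baseline_train(onsets, 3)
        assert spontaneous_rate(st_times, onsets) == pytest.approx(20.0)

    def test_empty_train_is_zero(self):
        assert spontaneous_rate(np.empty(0), np.array([5.0, 10.0])) == 0.0

    def test_matches_recount_oracle(self, rng):
        onsets = np.sort(rng.uniform(5, 500, 40))
        onsets = onsets[np.diff(np.concatenate([[0], onsets])) > 4][:20]
        spikes = np.sort(rng.uniform(0, 510, 2000))
        expected = np.mean(
            [((spikes >= o - 0.15) & (spikes < o)).sum() / 0.15 for o in onsets]
        )
        assert spontaneous_rate(spikes, onsets) == pytest.approx(expected)


class TestEvokedRate:
    def test_burst_window_gives_plus_sixty(self):
        # baseline 20 spikes/s; one 50-ms window at 80 spikes/s, others silent
        onsets = 5.0 * np.arange(1, 21)
        base = regular_baseline_train(onsets, 3)
        burst = np.concatenate([o + np.array([0.06, 0.07, 0.08, 0.09]) for o in onsets])
        spikes = np.sort(np.concatenate([base, burst]))
        # extremal window [onset+0.05, onset+0.10) holds 4 spikes -> 80 Hz
        assert evoked_rate(spikes, onsets) == pytest.approx(60.0)

    def test_silenced_unit_is_suppressed(self):
        onsets = 5.0 * np.arange(1, 21)
        spikes = regular_baseline_train(onsets, 3)  # 20 Hz baseline, silent after
        assert evoked_rate(spikes, onsets) == pytest.approx(-20.0)

    def test_rate_identical_to_baseline_gives_zero(self):
        onsets = np.array([10.0, 20.0])
        assert evoked_rate(np.empty(0), onsets) == 0.0


class TestToneSelectivity:
    @pytest.mark.parametrize(
        "rt,rnt,expected",
        [(2.0, 2.0, 0.0), (1.0, 0.0, 1.0), (1.0, 3.0, -0.5), (-1.0, 3.0, -0.5)],
    )
    def test_values(self, rt, rnt, expected):
        assert tone_selectivity(rt, rnt) == pytest.approx(expected)

    @given(
        rt=st.floats(-50, 50), rnt=st.floats(-50, 50)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_antisymmetric(self, rt, rnt):
        if abs(rt) + abs(rnt) == 0:
            return
        si = tone_selectivity(rt, rnt)
        assert -1.0 <= si <= 1.0
        assert tone_selectivity(rnt, rt) == pytest.approx(-si, abs=1e-12)

    def test_both_zero_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(tone_selectivity(0.0, 0.0))


def brute_force_modulation(spikes, onsets, cfg=CFG):
    """Exhaustive window scan recomputation of the modulation metric."""
    bl = np.mean(
        [((spikes >= o - cfg.baseline) & (spikes < o)).sum() for o in onsets]
    ) / cfg.baseline
    best = 0.0
    for off in cfg.stim_offsets:
        r = np.mean(
            [
                ((spikes >= o + off) & (spikes < o + off + cfg.stim_window)).sum()
                for o in onsets
            ]
        ) / cfg.stim_window
        best = max(best, abs(r - bl))
    return best


class TestStimulusModulation:
    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            onsets = 5.0 * np.arange(1, 16) + rng.uniform(0, 1, 15)
            spikes = np.sort(rng.uniform(0, 85, rng.integers(50, 800)))
            assert stimulus_modulation(spikes, onsets) == pytest.approx(
                brute_force_modulation(spikes, onsets), abs=1e-9
            )

    def test_equals_abs_evoked_on_single_condition(self, rng):
        onsets = 5.0 * np.arange(1, 16)
        spikes = np.sort(rng.uniform(0, 85, 400))
        r = stimulus_modulation(spikes, onsets)
        assert r == pytest.approx(abs(evoked_rate(spikes, onsets)), abs=1e-9)

    def test_nonnegative(self, rng):
        onsets = 5.0 * np.arange(1, 6)
        spikes = np.sort(rng.uniform(0, 30, 100))
        assert stimulus_modulation(spikes, onsets) >= 0.0


class TestChoiceModulation:
    def test_burst_in_choice_window(self):
        onsets = 5.0 * np.arange(1, 21)
        trials = make_trials(onsets)  # go trials respond at onset + 0.5
        from spikeflex.synth import choice_centers

        centers = choice_centers(trials)
        spikes = np.sort(
            np.concatenate([c - 0.05 + 0.1 * (np.arange(5) + 0.5) / 5 for c in centers])
        )
        # 5 extra spikes in every 100-ms choice window, zero baseline
        assert choice_modulation(spikes, trials) == pytest.approx(50.0)

    def test_translation_invariance(self, rng):
        # shifting spikes, onsets and responses by the same constant moves
        # every analysis window identically, so the modulation is unchanged
        onsets = 6.0 * np.arange(1, 16)
        trials = make_trials(onsets)
        spikes = np.sort(rng.uniform(0, 100, 500))
        r0 = choice_modulation(spikes, trials)
        shifted = trials.copy()
        shifted["onset_s"] = trials["onset_s"] + 0.3
        shifted["response_time_s"] = trials["response_time_s"] + 0.3
        r1 = choice_modulation(spikes + 0.3, shifted)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_matches_recount_oracle(self, rng):
        onsets = 6.0 * np.arange(1, 16)
        trials = make_trials(onsets)
        spikes = np.sort(rng.uniform(0, 100, 500))
        from spikeflex.synth import choice_centers

        centers = choice_centers(trials)
        counts = np.array(
            [((spikes >= c - 0.05) & (spikes < c + 0.05)).sum() for c in centers]
        )
        bl = np.mean(
            [((spikes >= o - 0.15) & (spikes < o)).sum() for o in onsets]
        ) / 0.15
        expected = abs(counts.mean() / 0.1 - bl)
        assert choice_modulation(spikes, trials) == pytest.approx(expected, abs=1e-9)

    def test_no_go_trials_error(self):
        onsets = np.array([5.0, 10.0])
        trials = make_trials(onsets, ["target", "nontarget"], [np.nan, np.nan])
        with pytest.raises(ValueError):
            choice_modulation(np.array([1.0, 2.0]), trials)


class TestBootstrapClassify:
    def test_degenerate_all_zero_deltas_is_ncr(self):
        onsets = 5.0 * np.arange(1, 31)
        trials = make_trials(onsets)
        res = bootstrap_classify(np.empty(0), trials, seed=0)
        assert res.label == "NCR"
        assert res.frac_inside == 1.0

    def test_too_few_trials_indeterminate(self):
        onsets = 5.0 * np.arange(1, 6)
        trials = make_trials(onsets)
        with pytest.warns(UserWarning):
            res = bootstrap_classify(np.empty(0), trials, seed=0)
        assert res.label == "indeterminate"

    def test_strong_modulation_is_cr(self):
        from spikeflex.synth import SessionGenSpec, UnitGenSpec, simulate_session

        sess, _ = simulate_session(
            SessionGenSpec(n_units=1, n_trials=200, seed=4),
            [UnitGenSpec("u", 5.0, stim_delta=5.0, true_label="CR")],
        )
        res = bootstrap_classify(sess.unit_spike_times("u"), sess.trials, seed=1)
        assert res.label == "CR"


class TestSeparatingThreshold:
    def test_separable_midpoint(self):
        fit = fit_separating_threshold(
            np.array([0.1, 0.2, 4.0, 5.0, 0.15, 0.12, 0.18, 4.5, 4.2, 4.8]),
            np.array(["NCR", "NCR", "CR", "CR", "NCR", "NCR", "NCR", "CR", "CR", "CR"]),
        )
        assert fit.threshold == pytest.approx(2.1, abs=1e-6)
        # separable data: the margin spans the whole gap, no slack
        assert fit.margin == pytest.approx(3.8, abs=1e-5)

    def test_duplicate_interior_point_does_not_move_boundary(self):
        x = np.array([0.1, 0.2, 4.0, 5.0])
        y = np.array(["NCR", "NCR", "CR", "CR"])
        t0 = fit_separating_threshold(x, y).threshold
        x2 = np.append(x, 5.0)  # duplicate a non-support CR point
        y2 = np.append(y, "CR")
        assert fit_separating_threshold(x2, y2).threshold == pytest.approx(t0)

    def test_matches_brute_force_objective_scan(self, rng):
        """Fitted boundary attains the scan-minimal soft-margin objective."""
        from spikeflex.responsiveness import svm_objective

        for _ in range(10):
            ncr = rng.gamma(2.0, 0.4, 15)
            cr = rng.gamma(3.0, 1.5, 12) + 1.0
            x = np.concatenate([ncr, cr])
            y = np.array(["NCR"] * 15 + ["CR"] * 12)
            fit = fit_separating_threshold(x, y)
            mu, sigma = x.mean(), x.std()
            crs, ncrs = (cr - mu) / sigma, (ncr - mu) / sigma
            obj_fit = svm_objective(
                2.0 / fit.margin * sigma, (fit.threshold - mu) / sigma, crs, ncrs, 1.0
            )
            xs = (x - mu) / sigma
            ws = np.linspace(0.01, 20.0, 300)
            ts = np.linspace(xs.min() - 1, xs.max() + 1, 300)
            scan = min(
                svm_objective(w, t, crs, ncrs, 1.0) for w in ws for t in ts
            )
            assert obj_fit <= scan + 1e-3 * (1 + scan)

    def test_outlier_does_not_drag_threshold(self):
        """A lone mislabeled point inside the gap is sacrificed by the
        soft margin rather than becoming the boundary support."""
        ncr = np.concatenate([np.linspace(0.5, 2.0, 30)])
        cr = np.concatenate([[2.3], np.linspace(4.5, 8.0, 30)])
        x = np.concatenate([ncr, cr])
        y = np.array(["NCR"] * 30 + ["CR"] * 31)
        fit = fit_separating_threshold(x, y)
        assert fit.threshold > 2.5

    def test_empty_class_error(self):
        with pytest.raises(ValueError):
            fit_separating_threshold(np.array([1.0, 2.0]), np.array(["CR", "CR"]))

    def test_classify_tie_is_cr(self):
        fit = fit_separating_threshold(
            np.array([0.1, 0.2, 4.0, 5.0]), np.array(["NCR", "NCR", "CR", "CR"])
        )
        assert classify_by_threshold(fit.threshold, fit) == "CR"
        assert classify_by_threshold(0.0, fit) == "NCR"


class TestBestFrequency:
    def test_single_responsive_frequency(self):
        bf, _ = best_frequency({4.0: 0.0, 8.0: 5.0, 16.0: 0.0})
        assert bf == 8.0

    def test_suppression_counts_via_absolute_value(self):
        bf, _ = best_frequency({4.0: 1.0, 8.0: -6.0, 16.0: 2.0})
        assert bf == 8.0

    def test_centered_curve_symmetric(self):
        bf, centered = best_frequency({4.0: 1.0, 8.0: 5.0, 16.0: 1.0})
        assert bf == 8.0
        assert centered[-1] == centered[1]

    def test_argmax_matches_direct_scan(self, rng):
        freqs = 4.0 * 2 ** np.arange(5)
        resp = rng.normal(0, 3, 5)
        bf, _ = best_frequency(dict(zip(freqs, resp)))
        assert bf == freqs[np.argmax(np.abs(resp))]

    def test_all_zero_flagged(self):
        with pytest.warns(UserWarning):
            bf, _ = best_frequency({4.0: 0.0, 8.0: 0.0})
        assert np.isnan(bf)
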