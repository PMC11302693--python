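"""Canonical simulated experiments at desk scale.

These are the study-condition simulations the analyses and validation
checks run: a standard cell population (half rate-modulated, half
rate-flat but ISI-shape coded), chance-level decoding of resampled-ISI
controls, end-to-end responsiveness-label recovery, and the
dimensionality-vs-shared-gain curve. All sizes are configurable; the
defaults are chosen to run on a laptop in minutes.
"""

from __future__ import annotations

import numpy as np

from .decoder import (
    crossval_decode,
    isi_table,
    make_synthetic_control,
    significance_vs_control,
)
from .dimensionality import (
    activity_matrix,
    cov_moments,
    dimensionality_decomposed,
    session_covariance,
)
from .responsiveness import profile_cohort
from .synth import SessionGenSpec, UnitGenSpec, simulate_session

BASELINE_RATE = 5.0  # spikes/s, typical auditory-cortex spontaneous rate
CR_DELTA = 5.0  # spikes/s, a highly classically responsive modulation
NCR_SHAPES = (1.0, 3.0)  # gamma ISI shapes per condition for timing coding


def rate_modulated_unit(uid: str, delta: float = CR_DELTA) -> UnitGenSpec:
    """A classically responsive profile: stimulus-locked rate change of
    the same size on both tones (no selectivity)."""
    return UnitGenSpec(uid, BASELINE_RATE, stim_delta=delta, true_label="CR")


def selective_unit(
    uid: str, delta_target: float = CR_DELTA, delta_nontarget: float = 1.0
) -> UnitGenSpec:
    """A tone-selective classically responsive profile: unequal evoked
    rate changes on target vs nontarget tones, so the stimulus identity
    is decodable from its firing."""
    return UnitGenSpec(
        uid,
        BASELINE_RATE,
        stim_delta=delta_target,
        stim_delta_nontarget=delta_nontarget,
        true_label="CR",
    )


def timing_coded_unit(uid: str) -> UnitGenSpec:
    """A non-classically responsive profile: rate-flat, condition coded
    purely in ISI regularity (gamma shape)."""
    return UnitGenSpec(
        uid,
        BASELINE_RATE,
        isi_shape_target=NCR_SHAPES[0],
        isi_shape_nontarget=NCR_SHAPES[1],
        true_label="NCR",
    )


def mixed_population(n_cells: int) -> list[UnitGenSpec]:
    """Alternating tone-selective rate-modulated / timing-coded profiles."""
    return [
        selective_unit(f"cell{i:03d}") if i % 2 == 0
        else timing_coded_unit(f"cell{i:03d}")
        for i in range(n_cells)
    ]


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(np.random.default_rng(ss).integers(2**31 - 1))


def _single_unit_session(spec: UnitGenSpec, n_trials: int, seed):
    if isinstance(seed, np.random.SeedSequence):
        seed = _seed_int(seed)
    sess, _ = simulate_session(
        SessionGenSpec(n_units=1, n_trials=n_trials, seed=seed), [spec]
    )
    st = sess.unit_spike_times(spec.unit_id)
    tables, durs = isi_table(st, sess.trials)
    labels = sess.trials["stimulus"].to_numpy()
    return tables, labels, durs


def control_chance_accuracies(
    n_cells: int = 50,
    n_trials: int = 100,
    k: int = 10,
    iterations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Mean decoding accuracy of ISI-resampled synthetic controls, per cell.

    Each cell's control dataset destroys condition-specific ISI structure
    while preserving trial lengths and the pooled ISI distribution, so
    decoding it measures the chance distribution of the decoder.
    """
    ss = np.random.SeedSequence(seed)
    pop = mixed_population(n_cells)
    accs = np.empty(n_cells)
    for i, (spec, child) in enumerate(zip(pop, ss.spawn(n_cells))):
        sim_seed, ctrl_seed, cv_seed = child.spawn(3)
        tables, labels, durs = _single_unit_session(
            spec, n_trials, sim_seed
        )
        surro = make_synthetic_control(tables, durs, ctrl_seed)
        res = crossval_decode(surro, labels, k=k, iterations=iterations, seed=cv_seed)
        accs[i] = res.mean_accuracy
    return accs


def rate_matched_significance(
    n_replicates: int = 50,
    n_trials: int = 100,
    k: int = 10,
    iterations: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fraction of timing-coded (rate-matched) cells decoding significantly
    above their synthetic controls; also the per-replicate accuracies."""
    ss = np.random.SeedSequence(seed)
    sig = np.zeros(n_replicates, dtype=bool)
    true_acc = np.empty(n_replicates)
    ctrl_acc = np.empty(n_replicates)
    for i, child in enumerate(ss.spawn(n_replicates)):
        sim_seed, true_seed, ctrl_build, ctrl_seed = child.spawn(4)
        tables, labels, durs = _single_unit_session(
            timing_coded_unit(f"rep{i}"), n_trials, sim_seed
        )
        res = crossval_decode(tables, labels, k=k, iterations=iterations, seed=true_seed)
        surro = make_synthetic_control(tables, durs, ctrl_build)
        ctrl = crossval_decode(surro, labels, k=k, iterations=iterations, seed=ctrl_seed)
        p, is_sig = significance_vs_control(
            res.accuracy_samples, ctrl.accuracy_samples
        )
        sig[i] = is_sig and res.mean_accuracy > ctrl.mean_accuracy
        true_acc[i] = res.mean_accuracy
        ctrl_acc[i] = ctrl.mean_accuracy
    return float(sig.mean()), true_acc, ctrl_acc


def classifier_recovery(
    n_sessions: int = 10,
    per_class: int = 10,
    n_trials: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """End-to-end CR/NCR label recovery on simulated sessions.

    Each session holds ``per_class`` rate-modulated (true CR, 5 spikes/s
    modulation) and ``per_class`` rate-flat (true NCR) units; units are
    bootstrap-labeled within their session and one separating threshold is
    fitted across the cohort. Returns the fraction of true-CR and true-NCR
    units recovered by the final labels.
    """
    ss = np.random.SeedSequence(seed)
    sessions, truths = [], []
    prof_seed, *children = ss.spawn(n_sessions + 1)
    for s, child in enumerate(children):
        units = [rate_modulated_unit(f"s{s}cr{i}") for i in range(per_class)] + [
            UnitGenSpec(f"s{s}ncr{i}", BASELINE_RATE, true_label="NCR")
            for i in range(per_class)
        ]
        sess, truth = simulate_session(
            SessionGenSpec(
                n_units=len(units), n_trials=n_trials, seed=_seed_int(child)
            ),
            units,
        )
        sessions.append(sess)
        truths.extend(truth.unit_specs)
    prof = profile_cohort(sessions, seed=_seed_int(prof_seed))
    labels = dict(zip(prof.profiles["unit_id"], prof.profiles["final_label"]))
    cr_ok = ncr_ok = cr_n = ncr_n = 0
    for u in truths:
        if u.true_label == "CR":
            cr_n += 1
            cr_ok += labels[u.unit_id] == "CR"
        else:
            ncr_n += 1
            ncr_ok += labels[u.unit_id] == "NCR"
    return cr_ok / cr_n, ncr_ok / ncr_n


def gain_dimensionality_curve(
    gain_levels: tuple[float, ...] = (0.1, 0.3, 0.6),
    n_replicates: int = 50,
    n_units: int = 12,
    n_trials: int = 120,
    seed: int = 0,
) -> list[float]:
    """Mean estimated D_inf per shared-gain level (should fall with gain)."""
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(gain_levels) * n_replicates))
    means = []
    for sd in gain_levels:
        vals = []
        for _ in range(n_replicates):
            child = next(children)
            units = [UnitGenSpec(f"u{i}", BASELINE_RATE) for i in range(n_units)]
            sess, _ = simulate_session(
                SessionGenSpec(
                    n_units=n_units,
                    n_trials=n_trials,
                    shared_gain_sd=sd,
                    seed=_seed_int(child),
                ),
                units,
            )
            C = session_covariance(activity_matrix(sess))
            m = cov_moments(C)
            _, d_inf = dimensionality_decomposed(
                m["mean_var_sq"], m["mean_var_prod"], m["mean_cov_sq"], m["n"]
            )
            vals.append(d_inf)
        means.append(float(np.mean(vals)))
    return means
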