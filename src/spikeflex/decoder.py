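"""Single-trial Bayesian decoding of task condition from ISI sequences.

The decoder estimates, per task condition (target/nontarget tone, or
go/no-go choice), the density of single interspike intervals via Gaussian
kernel density estimation on log-ISIs, with the bandwidth chosen by
cross-validated maximum likelihood. A trial's posterior over conditions
is the prior times the product of per-ISI likelihoods (ISIs treated as
independent given the condition), evaluated in log space. Accuracy is
estimated by stratified 10-fold cross-validation repeated over many
random fold assignments; the per-fold fraction correct is the unit of
observation ("accuracy sample").

Ensembles generalize the single-cell case: every member's ISI likelihoods
independently update the same posterior, with fold assignments shared
across members. A single-member ensemble is computationally identical to
single-cell decoding.

Synthetic controls rebuild each trial by resampling ISIs i.i.d. with
replacement from the unit's pooled ISI set (all conditions), preserving
the trial's window length; decoding controls measures the chance
distribution against which real accuracy is tested (Mann-Whitney U).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import mannwhitneyu
from sklearn.neighbors import KernelDensity

DENSITY_FLOOR = 1e-12
DEFAULT_BANDWIDTH_GRID = np.logspace(-1.5, 0.5, 10)  # in log-ISI units


def extract_isis(spike_times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Ordered ISIs between successive spikes falling inside [t0, t1]."""
    st = np.asarray(spike_times, dtype=float)
    inside = st[(st >= t0) & (st <= t1)]
    if inside.size < 2:
        return np.empty(0)
    return np.diff(inside)


def isi_table(
    spike_times: np.ndarray,
    trials: pd.DataFrame,
    window: str = "response",
    response_window: float = 2.5,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-trial ISI arrays and the matching window durations.

    ``window='response'`` (default): tone onset to end of the response
    window. ``'to_response'``: onset to the trial's response time (full
    response window when no response).
    """
    onsets = trials["onset_s"].to_numpy(dtype=float)
    if window == "response":
        ends = onsets + response_window
    elif window == "to_response":
        rts = trials["response_time_s"].to_numpy(dtype=float)
        ends = np.where(np.isfinite(rts), rts, onsets + response_window)
    else:
        raise ValueError("window must be 'response' or 'to_response'")
    tables = [extract_isis(spike_times, a, b) for a, b in zip(onsets, ends)]
    return tables, ends - onsets


@dataclass
class ISIDensity:
    """KDE over log-ISIs for one condition, with CV-selected bandwidth."""

    condition: str
    bandwidth: float
    n_isis: int
    log_isis: np.ndarray
    _kde: KernelDensity = field(repr=False)

    def log_pdf(self, isis: np.ndarray) -> np.ndarray:
        """Log density per ISI (seconds), including the 1/isi Jacobian of
        the log transform, floored at the density floor."""
        isis = np.asarray(isis, dtype=float)
        z = np.log(isis)
        lp = self._kde.score_samples(z[:, None]) - z
        return np.maximum(lp, np.log(DENSITY_FLOOR))

    def pdf(self, isis: np.ndarray) -> np.ndarray:
        return np.exp(self.log_pdf(isis))


def select_bandwidth(
    log_isis: np.ndarray,
    cv_folds: int = 5,
    bandwidth_grid: np.ndarray | None = None,
    seed: int = 0,
) -> float:
    """Bandwidth maximizing held-out mean log-likelihood over a grid."""
    grid = DEFAULT_BANDWIDTH_GRID if bandwidth_grid is None else np.asarray(
        bandwidth_grid, dtype=float
    )
    z = np.asarray(log_isis, dtype=float)
    n = z.size
    if n < cv_folds:
        return float(grid.max())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, cv_folds)
    scores = np.zeros(grid.size)
    for test in folds:
        train = np.setdiff1d(perm, test, assume_unique=True)
        for gi, h in enumerate(grid):
            kde = KernelDensity(kernel="gaussian", bandwidth=h).fit(z[train, None])
            lp = np.maximum(kde.score_samples(z[test, None]), np.log(DENSITY_FLOOR))
            scores[gi] += lp.sum()
    return float(grid[int(np.argmax(scores))])


def fit_isi_density(
    isis: np.ndarray,
    cv_folds: int = 5,
    bandwidth_grid: np.ndarray | None = None,
    min_isis: int = 10,
    seed: int = 0,
    condition: str = "",
) -> ISIDensity:
    """Fit the per-condition ISI density (Gaussian KDE on log-ISIs)."""
    isis = np.asarray(isis, dtype=float)
    if (isis <= 0).any():
        raise ValueError("ISIs must be strictly positive")
    grid = DEFAULT_BANDWIDTH_GRID if bandwidth_grid is None else np.asarray(
        bandwidth_grid, dtype=float
    )
    z = np.log(isis)
    if isis.size < min_isis:
        warnings.warn(
            f"only {isis.size} ISIs (< {min_isis}); using widest grid bandwidth"
        )
        bw = float(grid.max())
    else:
        bw = select_bandwidth(z, cv_folds, grid, seed)
    kde = KernelDensity(kernel="gaussian", bandwidth=bw).fit(z[:, None])
    return ISIDensity(condition, bw, int(isis.size), z, kde)


def decode_trial(
    densities: dict[str, ISIDensity],
    isis: np.ndarray,
    priors: dict[str, float],
) -> dict[str, float]:
    """Posterior over conditions for one trial's ISI sequence (Bayes rule
    with independent ISIs, computed in log space). Empty ISI sequences
    return the priors."""
    conds = sorted(densities)
    p = np.array([priors[c] for c in conds], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("priors must sum to 1")
    isis = np.asarray(isis, dtype=float)
    if isis.size == 0:
        return {c: float(pi) for c, pi in zip(conds, p)}
    logpost = np.log(p) + np.array(
        [densities[c].log_pdf(isis).sum() for c in conds]
    )
    logpost -= logsumexp(logpost)
    post = np.exp(logpost)
    return {c: float(v) for c, v in zip(conds, post)}


def _stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random k folds, stratified so each fold mixes both conditions."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cond in np.unique(labels):
        idx = np.flatnonzero(labels == cond)
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk.tolist())
    return [np.array(sorted(f), dtype=int) for f in folds]


def _fold_log_densities(
    z_train: np.ndarray, bw: float, z_test: np.ndarray
) -> np.ndarray:
    kde = KernelDensity(kernel="gaussian", bandwidth=bw).fit(z_train[:, None])
    return np.maximum(kde.score_samples(z_test[:, None]), np.log(DENSITY_FLOOR))


def _crossval_core(
    member_tables: Sequence[Sequence[np.ndarray]],
    labels: np.ndarray,
    k: int = 10,
    iterations: int = 500,
    seed: int | np.random.SeedSequence = 0,
    priors: dict[str, float] | None = None,
    bandwidth_grid: np.ndarray | None = None,
    min_isis: int = 10,
    bandwidths: Sequence[float] | None = None,
) -> np.ndarray:
    """Cross-validated decoding shared by single cells and ensembles.

    ``bandwidths`` (one per member) skips the per-member CV bandwidth
    selection — useful when the same units appear in many ensembles.

    Returns per-fold accuracy samples (length k * iterations). ISIs are
    compared in log space throughout; the log-transform Jacobian is
    condition-independent and cancels in the posterior.
    """
    labels = np.asarray(labels)
    conds = sorted(np.unique(labels).tolist())
    if len(conds) != 2:
        raise ValueError("decoding requires exactly two conditions")
    n_trials = labels.size
    if any(len(t) != n_trials for t in member_tables):
        raise ValueError("every member needs one ISI array per trial")
    counts = np.bincount([conds.index(l) for l in labels], minlength=2)
    if counts.min() < k:
        raise ValueError(f"need >= {k} trials per condition for {k}-fold CV")
    if priors is None:
        priors = {c: 0.5 for c in conds}
    log_prior = np.array([np.log(priors[c]) for c in conds])

    members = [
        [np.log(np.asarray(t, dtype=float)) if len(t) else np.empty(0) for t in mt]
        for mt in member_tables
    ]
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    bw_seed, cv_seed = ss.spawn(2)
    # bandwidth: selected once per member on its pooled ISIs irrespective
    # of condition — the smoothing scale is a property of the cell's ISI
    # distribution, and a condition-blind choice cannot leak label
    # information into the cross-validated accuracy
    bw_rng = np.random.default_rng(bw_seed)
    grid = DEFAULT_BANDWIDTH_GRID if bandwidth_grid is None else np.asarray(
        bandwidth_grid, dtype=float
    )
    if bandwidths is not None:
        bandwidths = np.asarray(bandwidths, dtype=float)
        if bandwidths.size != len(members):
            raise ValueError("need one bandwidth per member")
    else:
        bandwidths = np.empty(len(members))
        for mi, mt in enumerate(members):
            z = np.concatenate(mt) if len(mt) else np.empty(0)
            if z.size >= min_isis:
                bandwidths[mi] = select_bandwidth(
                    z, bandwidth_grid=grid, seed=int(bw_rng.integers(2**31 - 1))
                )
            else:
                bandwidths[mi] = float(grid.max())

    rng = np.random.default_rng(cv_seed)
    true_ci = np.array([conds.index(l) for l in labels])
    samples = np.empty(iterations * k)
    s = 0
    for _ in range(iterations):
        folds = _stratified_folds(labels, k, rng)
        for test_idx in folds:
            train_mask = np.ones(n_trials, dtype=bool)
            train_mask[test_idx] = False
            logpost = np.tile(log_prior, (test_idx.size, 1))
            for mi, mt in enumerate(members):
                test_z = [mt[i] for i in test_idx]
                lens = np.array([t.size for t in test_z])
                if lens.sum() == 0:
                    continue
                z_test = np.concatenate(test_z)
                member_ok = True
                per_cond = []
                for ci, cond in enumerate(conds):
                    tr = np.flatnonzero(train_mask & (labels == np.array(cond)))
                    z_train = np.concatenate([mt[i] for i in tr]) if tr.size else np.empty(0)
                    if z_train.size < 2:
                        member_ok = False
                        break
                    per_cond.append(
                        _fold_log_densities(z_train, bandwidths[mi], z_test)
                    )
                if not member_ok:
                    continue  # member contributes nothing in this fold
                bounds = np.concatenate([[0], np.cumsum(lens)])
                for ci in range(2):
                    sums = np.add.reduceat(per_cond[ci], bounds[:-1])
                    sums[lens == 0] = 0.0
                    logpost[:, ci] += sums
            diff = logpost[:, 0] - logpost[:, 1]
            win = np.where(diff > 1e-12, 0, np.where(diff < -1e-12, 1, -1))
            correct = np.where(win == -1, 0.5, (win == true_ci[test_idx]) * 1.0)
            samples[s] = correct.mean()
            s += 1
    return samples


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracy for one cell or ensemble."""

    level: str  # single_cell | ensemble
    task: str
    accuracy_samples: np.ndarray
    mean_accuracy: float
    control_mean_accuracy: float | None = None
    p_vs_control: float | None = None
    is_significant: bool | None = None
    is_task_encoder: bool | None = None


def crossval_decode(
    trial_isis: Sequence[np.ndarray],
    labels: np.ndarray,
    task: str = "stimulus",
    k: int = 10,
    iterations: int = 500,
    seed: int | np.random.SeedSequence = 0,
    **kwargs,
) -> DecodingResult:
    """Single-cell cross-validated decoding from per-trial ISI arrays."""
    samples = _crossval_core([trial_isis], labels, k, iterations, seed, **kwargs)
    return DecodingResult("single_cell", task, samples, float(samples.mean()))


def decode_ensemble(
    member_tables: Sequence[Sequence[np.ndarray]],
    labels: np.ndarray,
    task: str = "stimulus",
    k: int = 10,
    iterations: int = 500,
    seed: int | np.random.SeedSequence = 0,
    **kwargs,
) -> DecodingResult:
    """Ensemble decoding: members' likelihoods jointly update the posterior."""
    samples = _crossval_core(member_tables, labels, k, iterations, seed, **kwargs)
    return DecodingResult("ensemble", task, samples, float(samples.mean()))


def make_synthetic_control(
    trial_isis: Sequence[np.ndarray],
    durations: Sequence[float],
    seed: int | np.random.SeedSequence = 0,
) -> list[np.ndarray]:
    """Surrogate per-trial ISI sets: i.i.d. resamples (with replacement)
    from the pooled observed ISIs, filling each trial until its window
    duration would be exceeded. Condition labels are kept by the caller."""
    pooled = (
        np.concatenate([np.asarray(t, dtype=float) for t in trial_isis])
        if len(trial_isis)
        else np.empty(0)
    )
    if pooled.size < 2:
        raise ValueError("need >= 2 pooled ISIs to build synthetic controls")
    rng = np.random.default_rng(seed)
    mean_isi = pooled.mean()
    out = []
    for dur in np.asarray(durations, dtype=float):
        draw = max(8, int(dur / mean_isi + 6 * np.sqrt(dur / mean_isi + 1)))
        isis = rng.choice(pooled, size=draw, replace=True)
        while isis.cumsum()[-1] <= dur:
            isis = np.concatenate([isis, rng.choice(pooled, size=draw, replace=True)])
        keep = np.searchsorted(isis.cumsum(), dur, side="right")
        out.append(isis[:keep])
    return out


def significance_vs_control(
    true_samples: np.ndarray, control_samples: np.ndarray, alpha: float = 0.05
) -> tuple[float, bool]:
    """Two-sided Mann-Whitney U of true vs control accuracy samples."""
    res = mannwhitneyu(true_samples, control_samples, alternative="two-sided")
    return float(res.pvalue), bool(res.pvalue < alpha)


def decode_with_control(
    trial_isis: Sequence[np.ndarray],
    labels: np.ndarray,
    durations: Sequence[float],
    task: str = "stimulus",
    k: int = 10,
    iterations: int = 500,
    seed: int | np.random.SeedSequence = 0,
    **kwargs,
) -> DecodingResult:
    """True-data decoding plus its matched synthetic-control run."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    true_seed, ctrl_build, ctrl_seed = ss.spawn(3)
    result = crossval_decode(
        trial_isis, labels, task, k, iterations, true_seed, **kwargs
    )
    surrogate = make_synthetic_control(trial_isis, durations, ctrl_build)
    ctrl = crossval_decode(surrogate, labels, task, k, iterations, ctrl_seed, **kwargs)
    p, sig = significance_vs_control(result.accuracy_samples, ctrl.accuracy_samples)
    result.control_mean_accuracy = ctrl.mean_accuracy
    result.p_vs_control = p
    result.is_significant = sig
    return result


def task_encoder_threshold(
    mean_accuracies: Sequence[float], chance: float = 0.5, min_below: int = 20
) -> float:
    """Accuracy threshold for 'task encoder' cells: chance plus the gap
    between chance and the 5th percentile of the below-chance accuracy
    distribution (below-chance cells estimate the noise around chance)."""
    accs = np.asarray(mean_accuracies, dtype=float)
    below = accs[accs <= chance]
    if below.size < min_below:
        warnings.warn(
            f"only {below.size} below-chance cells (< {min_below}); "
            "task-encoder threshold undefined"
        )
        return float("nan")
    p5 = float(np.percentile(below, 5))
    return chance + (chance - p5)


@dataclass
class EnsembleRecord:
    members: list[str]
    n1: int
    n2: int
    fraction_ncr: float | None = None
    category: str | None = None


def sample_ensembles(
    unit_ids: Sequence[str], n1: int, seed: int | np.random.SeedSequence = 0
) -> list[EnsembleRecord]:
    """Draw exactly n2 ensembles of n1 distinct units from a session of
    n2 units, so every session contributes ensembles in proportion to its
    yield and every unit is equally represented on average."""
    ids = list(unit_ids)
    n2 = len(ids)
    if n1 > n2:
        raise ValueError("ensemble size n1 exceeds session unit count n2")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n2):
        members = rng.choice(ids, size=n1, replace=False).tolist()
        out.append(EnsembleRecord(members=members, n1=n1, n2=n2))
    return out


def categorize_ensemble(member_labels: Sequence[str]) -> str:
    """Composition category from members' final CR/NCR labels.

    CR ensembles: 70-100% classically responsive (NCR fraction <= 0.30);
    mixed: 50-70% NCR; NCR ensembles: >= 80% NCR; the uncovered gaps are
    'uncategorized' and dropped from category contrasts.
    """
    labels = np.asarray(member_labels)
    f = float((labels == "NCR").mean())
    if f <= 0.30:
        return "CR_ensemble"
    if 0.50 <= f <= 0.70:
        return "mixed"
    if f >= 0.80:
        return "NCR_ensemble"
    return "uncategorized"
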