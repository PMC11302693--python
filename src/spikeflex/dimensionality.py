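"""Participation-ratio dimensionality of population activity.

D = (Tr C)^2 / Tr C^2 for the trials-by-units activity covariance C —
an effective count of independent activity modes. Expanding the traces
in population moments gives the equivalent finite-n form

    D = [1 + (n-1) <Vi Vj> / <Vi^2>] / [1 + (n-1) <Cij^2> / <Vi^2>]

and, as n grows, the large-n limit D_inf = <Vi Vj> / <Cij^2> (i != j
throughout). Uncertainty comes from a two-level bootstrap: single-unit
variances (the numerator moment) are resampled with replacement within
each animal, while covariances — measurable only within a simultaneous
recording — are resampled at the session level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import RecordingSession
from .responsiveness import count_in_windows


def activity_matrix(
    session: RecordingSession,
    units: list[str] | None = None,
    window: tuple[float, float] = (0.0, 0.2),
) -> pd.DataFrame:
    """Per-trial spike counts per unit in an onset-aligned window.

    Default window is the 200 ms from tone onset. Zero-variance units are
    retained but reported via a warning (they are degenerate for
    covariance estimation).
    """
    units = session.units if units is None else list(units)
    onsets = session.trials["onset_s"].to_numpy(dtype=float)
    if onsets.size < 2:
        raise ValueError("need >= 2 trials for an activity matrix")
    t0, t1 = window
    cols = {}
    for u in units:
        st = session.unit_spike_times(u)
        cols[u] = count_in_windows(st, onsets + t0, t1 - t0)
    df = pd.DataFrame(cols, index=session.trials["trial_id"])
    flat = [u for u in units if df[u].var() == 0]
    if flat:
        warnings.warn(f"{len(flat)} unit(s) with zero variance in window: {flat}")
    return df


def participation_ratio(C: np.ndarray) -> float:
    """D = (Tr C)^2 / Tr C^2. NaN (flagged) for the zero matrix."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("covariance matrix must be symmetric")
    tr2 = float(np.sum(C * C))  # Tr C^2 for symmetric C
    if tr2 == 0:
        warnings.warn("zero covariance matrix; participation ratio undefined")
        return float("nan")
    return float(np.trace(C)) ** 2 / tr2


def cov_moments(C: np.ndarray) -> dict[str, float]:
    """Population moments of a covariance matrix: <Vi^2>, <Vi Vj>,
    <Cij^2>, <|Cij|> (i != j), and n."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    v = np.diag(C)
    off = ~np.eye(n, dtype=bool)
    mean_var_sq = float((v**2).mean())
    mean_var_prod = (
        float((v.sum() ** 2 - (v**2).sum()) / (n * (n - 1))) if n > 1 else float("nan")
    )
    mean_cov_sq = float((C[off] ** 2).mean()) if n > 1 else float("nan")
    mean_abs_cov = float(np.abs(C[off]).mean()) if n > 1 else float("nan")
    return {
        "n": n,
        "mean_var_sq": mean_var_sq,
        "mean_var_prod": mean_var_prod,
        "mean_cov_sq": mean_cov_sq,
        "mean_abs_cov": mean_abs_cov,
    }


def dimensionality_decomposed(
    mean_var_sq: float, mean_var_prod: float, mean_cov_sq: float, n: int
) -> tuple[float, float]:
    """(D_finite, D_inf) from population moments; D_inf is +inf when the
    mean squared covariance vanishes."""
    if n < 2:
        raise ValueError("need n >= 2")
    if mean_var_sq == 0:
        raise ValueError("zero <Vi^2>; dimensionality undefined")
    d_finite = (1.0 + (n - 1) * mean_var_prod / mean_var_sq) / (
        1.0 + (n - 1) * mean_cov_sq / mean_var_sq
    )
    d_inf = mean_var_prod / mean_cov_sq if mean_cov_sq > 0 else float("inf")
    return float(d_finite), float(d_inf)


@dataclass
class DimensionalityEstimate:
    n: int
    mean_var_sq: float
    mean_var_prod: float
    mean_cov_sq: float
    mean_abs_cov: float
    d_finite: float
    d_inf: float
    bootstrap_mean: float
    bootstrap_sem: float
    b: int
    n_excluded: int


def _pair_product_mean(values: np.ndarray) -> float:
    s, s2, m = values.sum(), (values**2).sum(), values.size
    return float((s * s - s2) / (m * (m - 1)))


def _pooled_cov_sq(
    covs: list[np.ndarray], exclude_duplicate_pairs: bool = False
) -> tuple[float, float]:
    """Mean squared and mean absolute off-diagonal covariance pooled over
    all within-session pairs of the given covariance matrices."""
    sq, ab, cnt = 0.0, 0.0, 0
    for C in covs:
        n = C.shape[0]
        if n < 2:
            continue
        off = ~np.eye(n, dtype=bool)
        vals = C[off]
        sq += (vals**2).sum()
        ab += np.abs(vals).sum()
        cnt += vals.size
    if cnt == 0:
        return float("nan"), float("nan")
    return sq / cnt, ab / cnt


def bootstrap_dimensionality(
    animal_variances: dict[str, np.ndarray],
    session_covariances: list[np.ndarray],
    b: int = 2000,
    seed: int = 0,
) -> DimensionalityEstimate:
    """Two-level bootstrap of the large-n dimensionality D_inf.

    Numerator (<Vi Vj>): per replicate, each animal's single-unit
    variances are resampled with replacement at original size and pooled;
    pairs duplicating the same resampled slot are excluded by the pair
    formula over the pooled draw. Denominator (<Cij^2>): sessions are
    resampled with replacement and all within-session off-diagonal
    covariances of the sampled sessions are pooled. Replicates with zero
    pooled squared covariance are excluded (counted).
    """
    for a, v in animal_variances.items():
        if np.asarray(v).size < 2:
            raise ValueError(f"animal {a!r} has < 2 units")
    if not session_covariances:
        raise ValueError("need >= 1 session covariance matrix")
    pooled_v = np.concatenate(
        [np.asarray(v, dtype=float) for v in animal_variances.values()]
    )
    n_units = pooled_v.size
    mean_var_sq = float((pooled_v**2).mean())
    mean_var_prod = _pair_product_mean(pooled_v)
    mean_cov_sq, mean_abs_cov = _pooled_cov_sq(list(session_covariances))
    d_finite, d_inf = dimensionality_decomposed(
        mean_var_sq, mean_var_prod, mean_cov_sq, n_units
    )

    rng = np.random.default_rng(seed)
    n_sessions = len(session_covariances)
    reps = []
    excluded = 0
    for _ in range(b):
        draws = []
        for v in animal_variances.values():
            v = np.asarray(v, dtype=float)
            draws.append(rng.choice(v, size=v.size, replace=True))
        num = _pair_product_mean(np.concatenate(draws))
        sess_idx = rng.integers(0, n_sessions, size=n_sessions)
        den, _ = _pooled_cov_sq([session_covariances[i] for i in sess_idx])
        if not np.isfinite(den) or den == 0:
            excluded += 1
            continue
        reps.append(num / den)
    reps = np.asarray(reps)
    if reps.size == 0:
        warnings.warn("all bootstrap replicates excluded (zero covariance)")
        bmean, bsem = float("nan"), float("nan")
    else:
        bmean = float(reps.mean())
        # SD of the bootstrap distribution = standard error of D_inf
        bsem = float(reps.std(ddof=1)) if reps.size > 1 else 0.0
    return DimensionalityEstimate(
        n=n_units,
        mean_var_sq=mean_var_sq,
        mean_var_prod=mean_var_prod,
        mean_cov_sq=mean_cov_sq,
        mean_abs_cov=mean_abs_cov,
        d_finite=d_finite,
        d_inf=d_inf,
        bootstrap_mean=bmean,
        bootstrap_sem=bsem,
        b=b,
        n_excluded=excluded,
    )


def session_covariance(activity: pd.DataFrame) -> np.ndarray:
    """Unbiased (n-1) sample covariance of a trials-by-units matrix."""
    return np.cov(activity.to_numpy(dtype=float), rowvar=False, ddof=1)
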