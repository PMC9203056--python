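"""Permutation split-half reliability with Spearman-Brown correction.

The estimator: repeatedly split each participant's trials into two random
halves, compute per-half means, correlate the two half-mean vectors across
participants, and apply the Spearman-Brown prophecy formula
``r' = 2 r / (1 + r)``. The permutation distribution of corrected
correlations summarizes as a mean, sd and 2.5/97.5 percentile interval.

The titration analysis repeats the estimate at increasing per-participant
trial counts k, keeping only participants with at least k trials and
subsampling exactly k of them (without replacement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReliabilityEstimate", "spearman_brown", "split_half", "titration"]


@dataclass(frozen=True)
class ReliabilityEstimate:
    metric: str
    r_mean: float
    r_sd: float
    ci: tuple
    n_perm: int
    n_trials_used: int  # total trials entering the estimate
    n_participants: int
    negative_fraction: float = 0.0  # permutations with corrected r < 0

    def __post_init__(self) -> None:
        if self.ci[0] > self.ci[1]:
            raise ValueError("CI bounds out of order")


def spearman_brown(r: float) -> float:
    """Spearman-Brown step-up of a half-test correlation: r' = 2r/(1+r)."""
    if r == -1:
        raise ValueError("Spearman-Brown correction undefined at r = -1")
    return 2.0 * r / (1.0 + r)


def _half_means(values: np.ndarray, n_perm: int, rng: np.random.Generator,
                k: int | None = None):
    """Per-permutation means of two random halves of one participant's
    values. With ``k`` set, first subsample k values without replacement.
    Odd counts split into floor(n/2) / ceil(n/2) halves."""
    order = np.argsort(rng.random((n_perm, values.size)), axis=1)
    if k is not None:
        order = order[:, :k]
    n = order.shape[1]
    picked = values[order]
    h1 = picked[:, : n // 2].mean(axis=1)
    h2 = picked[:, n // 2 :].mean(axis=1)
    return h1, h2


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def split_half(values_by_participant: dict, n_perm: int = 10000,
               seed: int | np.random.Generator = 0, metric: str = "",
               method: str = "pearson", k: int | None = None) -> ReliabilityEstimate:
    """Permutation split-half reliability across participants.

    Parameters
    ----------
    values_by_participant : dict
        participant -> 1-d array of per-trial values. Participants with
        fewer than 2 (or ``k``) trials are excluded.
    n_perm : int
        Number of random splits.
    seed : int or Generator
        Reproducibility: the summary is bit-for-bit identical for a given
        seed.
    method : {"pearson", "spearman"}
        Correlation across participants; Pearson is the split-half default.
    k : int, optional
        Subsample exactly k trials per participant before splitting.

    Negative corrected correlations are kept as-is and counted in
    ``negative_fraction`` rather than truncated.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    need = 2 if k is None else k
    kept = {
        p: np.asarray(v, float)[~np.isnan(np.asarray(v, float))]
        for p, v in values_by_participant.items()
    }
    kept = {p: v for p, v in kept.items() if v.size >= need}
    if len(kept) < 3:
        raise ValueError("need at least 3 participants with enough trials")
    h1 = np.empty((n_perm, len(kept)))
    h2 = np.empty((n_perm, len(kept)))
    n_trials = 0
    for j, (_, vals) in enumerate(sorted(kept.items(), key=lambda kv: str(kv[0]))):
        a, b = _half_means(vals, n_perm, rng, k)
        h1[:, j], h2[:, j] = a, b
        n_trials += vals.size if k is None else k
    if method == "pearson":
        r = _rowwise_pearson(h1, h2)
    elif method == "spearman":
        r = _rowwise_pearson(
            np.argsort(np.argsort(h1, axis=1), axis=1).astype(float),
            np.argsort(np.argsort(h2, axis=1), axis=1).astype(float),
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    corrected = 2.0 * r / (1.0 + r)
    corrected = corrected[np.isfinite(corrected)]
    # Spearman-Brown maps r < -1/3 below -1; clip to the admissible range
    # (negative permutations stay visible through negative_fraction)
    corrected = np.maximum(corrected, -1.0)
    lo, hi = np.percentile(corrected, [2.5, 97.5])
    return ReliabilityEstimate(
        metric=metric,
        r_mean=float(corrected.mean()),
        r_sd=float(corrected.std(ddof=1)),
        ci=(float(lo), float(hi)),
        n_perm=n_perm,
        n_trials_used=n_trials,
        n_participants=len(kept),
        negative_fraction=float((corrected < 0).mean()),
    )


def titration(values_by_participant: dict, k_min: int = 6, k_max: int | None = None,
              n_reps: int = 1000, seed: int = 0, metric: str = "",
              method: str = "pearson") -> pd.DataFrame:
    """Reliability-versus-trial-count curve.

    For each k from ``k_min`` upward, participants with at least k trials
    are retained, exactly k of their trials are subsampled per permutation,
    and the split-half estimate is recomputed with ``n_reps`` permutations.
    The curve stops at ``k_max`` (default: the largest k leaving at least 3
    participants). Returns one row per k.
    """
    rng = np.random.default_rng(seed)
    counts = {p: int(np.sum(~np.isnan(np.asarray(v, float))))
              for p, v in values_by_participant.items()}
    if k_max is None:
        sizes = sorted(counts.values(), reverse=True)
        k_max = sizes[2] if len(sizes) >= 3 else 0
    rows = []
    for k in range(k_min, k_max + 1):
        eligible = {p: v for p, v in values_by_participant.items() if counts[p] >= k}
        if len(eligible) < 3:
            break
        est = split_half(eligible, n_perm=n_reps, seed=rng, metric=metric,
                         method=method, k=k)
        rows.append({
            "k": k,
            "n_participants": est.n_participants,
            "r_mean": est.r_mean,
            "r_sd": est.r_sd,
            "ci_low": est.ci[0],
            "ci_high": est.ci[1],
        })
    return pd.DataFrame(rows)


def burst_metric_by_participant(bursts: pd.DataFrame, column: str,
                                emg_class: str = "premg") -> dict:
    """Extract participant -> per-trial values of a burst-table column
    (burst table with a ``participant`` column), for feeding split_half."""
    sub = bursts[bursts["emg_class"] == emg_class]
    return {
        pid: grp[column].dropna().to_numpy(float)
        for pid, grp in sub.groupby("participant")
    }
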