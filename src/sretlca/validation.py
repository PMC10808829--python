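"""Cluster validation indices and the seed-perturbation stability study.

Two geometric validation indices are computed on the raw 0/1 endorsement
vectors with Euclidean distances:

* Davies-Bouldin index (DBI): average over clusters of the worst-case ratio
  (sigma_i + sigma_j) / d(c_i, c_j), with sigma the mean member-to-centroid
  distance. Lower means better-separated clusters.
* Calinski-Harabasz index (CHI): [B / (K-1)] / [W / (n-K)], the ratio of
  between- to within-cluster variance. Higher is better; +inf when the
  within-cluster scatter is exactly zero.

For mixture solutions the natural centroid is the model's probability row
p_k (the responsibility-weighted mean), and that is what the stability study
uses both for the indices and for matching cluster centers across seeds.

The perturbation study refits the whole model-selection procedure once per
initialization seed, records selected K, criterion value, log-likelihood,
DBI and CHI per criterion, and summarizes their means and SDs. Cluster
centers are matched between each seed's solution and a representative-seed
reference by optimal one-to-one assignment on the Pearson correlation
matrix; a matched pair with r >= 0.7 counts as stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .exceptions import DataError
from .mixture import ClusterSolution, fit_range

DEFAULT_MATCH_THRESHOLD = 0.7
DEFAULT_REPRESENTATIVE_SEED = 3


def _centroid_stats(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray = None):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DataError("validation indices need at least 2 non-empty clusters")
    if centroids is None:
        centroids = np.vstack([X[labels == k].mean(axis=0) for k in uniq])
    else:
        centroids = np.asarray(centroids, dtype=float)[uniq]
    return X, labels, uniq, centroids


def davies_bouldin(X, labels, centroids=None) -> float:
    """Davies-Bouldin index; ``centroids`` default to per-cluster means.

    Returns +inf when two cluster centroids coincide.
    """
    X, labels, uniq, C = _centroid_stats(X, labels, centroids)
    K = uniq.size
    sigma = np.asarray([
        np.linalg.norm(X[labels == k] - C[i], axis=1).mean() for i, k in enumerate(uniq)
    ])
    D = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=2)
    ratios = np.full((K, K), -np.inf)
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            if D[i, j] == 0:
                return np.inf
            ratios[i, j] = (sigma[i] + sigma[j]) / D[i, j]
    return float(ratios.max(axis=1).mean())


def calinski_harabasz(X, labels) -> float:
    """Calinski-Harabasz variance-ratio index; +inf for zero within scatter."""
    X, labels, uniq, C = _centroid_stats(X, labels, None)
    n, K = X.shape[0], uniq.size
    if n <= K:
        raise DataError("calinski_harabasz: need n > K")
    grand = X.mean(axis=0)
    sizes = np.asarray([(labels == k).sum() for k in uniq])
    B = float((sizes * ((C - grand) ** 2).sum(axis=1)).sum())
    W = float(sum(((X[labels == k] - C[i]) ** 2).sum() for i, k in enumerate(uniq)))
    if W == 0:
        return np.inf
    return (B / (K - 1)) / (W / (n - K))


@dataclass
class MatchResult:
    """Optimal one-to-one matching between two sets of cluster centers."""

    correlation: np.ndarray    # K_a x K_b Pearson correlations (NaN if undefined)
    pairs: list                # [(a, b), ...] sorted by a
    stable: list               # parallel booleans: matched and r >= threshold
    threshold: float

    @property
    def stable_fraction(self) -> float:
        return float(np.mean(self.stable)) if self.stable else 0.0


def match_centroids(P_a, P_b, threshold: float = DEFAULT_MATCH_THRESHOLD) -> MatchResult:
    """Match centroid rows of two solutions by maximal total correlation.

    Accepts ClusterSolution objects or raw (K, J) centroid matrices. Pairs
    whose Pearson correlation is undefined (a constant centroid) are
    recorded as unmatched (never stable).
    """
    if isinstance(P_a, ClusterSolution):
        P_a = P_a.model.P
    if isinstance(P_b, ClusterSolution):
        P_b = P_b.model.P
    A = np.asarray(P_a, dtype=float)
    B = np.asarray(P_b, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise DataError("match_centroids: solutions must share the same word set")
    Ka, Kb = A.shape[0], B.shape[0]
    corr = np.full((Ka, Kb), np.nan)
    a_sd = A.std(axis=1)
    b_sd = B.std(axis=1)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (Ac @ Bc.T) / (A.shape[1] * np.outer(a_sd, b_sd))
    defined = np.outer(a_sd > 0, b_sd > 0)
    corr[defined] = raw[defined]
    cost = np.where(np.isnan(corr), -2.0, corr)   # undefined worse than any r
    rows, cols = linear_sum_assignment(-cost)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    stable = [bool(np.isfinite(corr[a, b]) and corr[a, b] >= threshold) for a, b in pairs]
    return MatchResult(correlation=corr, pairs=pairs, stable=stable, threshold=threshold)


@dataclass
class StabilityReport:
    """Output of the seed-perturbation study."""

    per_seed: pd.DataFrame     # seed, criterion, K, criterion_value, loglik, dbi, chi
    summary: pd.DataFrame      # per-criterion mean/SD of each metric
    centroid_match: pd.DataFrame  # per-criterion stable fraction vs reference seed
    reference_seed: int
    n_failed: int = 0


def perturbation_study(X, seeds=range(1, 31), criteria=("bic", "icl", "nec"),
                       kmin: int = 2, kmax: int = None,
                       n_restarts: int = 10,
                       representative_seed: int = DEFAULT_REPRESENTATIVE_SEED,
                       match_threshold: float = DEFAULT_MATCH_THRESHOLD) -> StabilityReport:
    """Refit model selection for every seed and summarize metric stability.

    For each seed the full K range is fitted once and each criterion selects
    its own solution from those fits. Centroid matching compares every
    seed's selected solution against the representative-seed solution for
    the same criterion. Deterministic given the seed list.
    """
    seeds = list(seeds)
    if not seeds:
        raise DataError("perturbation_study: seed list must be non-empty")
    Xarr = X.X if hasattr(X, "X") else np.asarray(X)
    rows = []
    selected = {}
    n_failed = 0
    for seed in seeds:
        try:
            solutions = fit_range(Xarr, seed=seed, kmin=kmin, kmax=kmax, n_restarts=n_restarts)
        except Exception as exc:  # a failed seed is recorded and excluded
            warnings.warn(f"perturbation_study: seed {seed} failed ({exc})")
            n_failed += 1
            continue
        for crit in criteria:
            cand = sorted(k for k in solutions if k >= 2)
            vals = [solutions[k].criteria[crit] for k in cand]
            best_K = cand[int(np.argmin(vals))]
            sol = solutions[best_K]
            selected[(seed, crit)] = sol
            rows.append(
                {
                    "seed": seed,
                    "criterion": crit,
                    "K": best_K,
                    "criterion_value": sol.criteria[crit],
                    "loglik": sol.model.loglik,
                    "dbi": davies_bouldin(Xarr, sol.labels, sol.model.P),
                    "chi": calinski_harabasz(Xarr, sol.labels),
                }
            )
    per_seed = pd.DataFrame(rows)
    metrics = ["K", "criterion_value", "loglik", "dbi", "chi"]
    summaries = []
    for crit in criteria:
        sub = per_seed[per_seed["criterion"] == crit]
        for m in metrics:
            summaries.append(
                {
                    "criterion": crit,
                    "metric": m,
                    "mean": float(sub[m].mean()),
                    "sd": float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0,
                }
            )
    summary = pd.DataFrame(summaries)

    ref_seed = representative_seed if representative_seed in seeds else seeds[0]
    match_rows = []
    for crit in criteria:
        ref = selected.get((ref_seed, crit))
        if ref is None:
            continue
        fractions = []
        for seed in seeds:
            sol = selected.get((seed, crit))
            if sol is None or seed == ref_seed:
                continue
            fractions.append(match_centroids(ref, sol, threshold=match_threshold).stable_fraction)
        match_rows.append(
            {
                "criterion": crit,
                "stable_fraction_mean": float(np.mean(fractions)) if fractions else 1.0,
                "n_comparisons": len(fractions),
            }
        )
    centroid_match = pd.DataFrame(match_rows)
    return StabilityReport(
        per_seed=per_seed, summary=summary, centroid_match=centroid_match,
        reference_seed=ref_seed, n_failed=n_failed,
    )
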