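"""Finite mixtures of multivariate Bernoulli distributions (latent classes).

The latent-class model for an n x J binary endorsement matrix X assumes each
participant i belongs to one of K classes with mixing proportions pi_k, and
conditional on the class the J endorsements are independent Bernoulli with
class-specific probabilities p_kj:

    P(x_i) = sum_k pi_k prod_j p_kj^{x_ij} (1 - p_kj)^{1 - x_ij}

The unrestricted parameterization has nu = (K - 1) + K * J free parameters.
Fitting is by EM from random responsibilities (symmetric Dirichlet), with
multiple restarts all seeded deterministically from one integer; the
log-likelihood is checked to be non-decreasing every iteration.

Model selection over the Bezdek cluster range uses, per the study design:

* BIC = -2 * loglik + nu * ln(n)                        (lower is better)
* ICL = BIC + 2 * entropy of the responsibilities      (lower is better)
* NEC = entropy / (loglik_K - loglik_1), NEC(1) := 1   (lower is better)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .exceptions import DataError, PipelineError
from .metrics import EndorsementMatrix

EPS_PROB = 1e-6          # clamp for p_kj, keeps the log-likelihood finite
DEFAULT_TOL = 1e-8       # relative log-likelihood change declaring convergence
DEFAULT_MAX_ITER = 500
DEFAULT_N_RESTARTS = 10


@dataclass
class BernoulliMixtureModel:
    """Fitted mixture: mixing proportions pi (K,) and probabilities P (K, J)."""

    K: int
    pi: np.ndarray
    P: np.ndarray
    loglik: float
    nu: int
    converged: bool
    n_iter: int
    seed: int

    def log_responsibilities(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        """Log posterior class memberships and the total log-likelihood."""
        logP = np.log(self.P)
        log1P = np.log1p(-self.P)
        logw = X @ logP.T + (1 - X) @ log1P.T + np.log(self.pi)[None, :]
        norm = logsumexp(logw, axis=1)
        return logw - norm[:, None], float(norm.sum())

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "pi": self.pi.tolist(),
            "P": self.P.tolist(),
            "loglik": self.loglik,
            "nu": self.nu,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }


@dataclass
class ClusterSolution:
    """A fitted model with responsibilities, MAP labels and criterion values."""

    model: BernoulliMixtureModel
    responsibilities: np.ndarray
    labels: np.ndarray
    entropy: float
    criteria: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.model.K

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.model.K)


def _as_binary(X) -> np.ndarray:
    if isinstance(X, EndorsementMatrix):
        X = X.X
    X = np.asarray(X)
    if X.ndim != 2 or not np.isin(X, (0, 1)).all():
        raise DataError("fit_em: X must be a 2-D binary matrix")
    return X.astype(np.float64)


def _em_once(X: np.ndarray, K: int, rng: np.random.Generator,
             tol: float, max_iter: int) -> tuple:
    """One EM run from a random-responsibility start.

    Returns (pi, P, loglik, converged, n_iter) or None when the run is
    abandoned after a recurring empty component.
    """
    n, J = X.shape
    T = rng.dirichlet(np.ones(K), size=n)     # responsibilities
    floor = 1.0 / (10.0 * n)
    reinitialized = set()
    pi = P = None
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step
        mass = T.sum(axis=0)
        low = np.nonzero(mass < floor)[0]
        if low.size:
            again = [k for k in low if k in reinitialized]
            if again:
                return None                    # failed restart, excluded
            for k in low:
                reinitialized.add(int(k))
                T[:, k] = rng.random(n)
            T /= T.sum(axis=1, keepdims=True)
            mass = T.sum(axis=0)
            loglik = -np.inf                   # restart monotonicity after the jump
        pi = mass / n
        P = np.clip((T.T @ X) / mass[:, None], EPS_PROB, 1.0 - EPS_PROB)
        # E-step
        logw = X @ np.log(P).T + (1 - X) @ np.log1p(-P).T + np.log(pi)[None, :]
        norm = logsumexp(logw, axis=1)
        new_loglik = float(norm.sum())
        if new_loglik < loglik - 1e-8 * max(1.0, abs(loglik)):
            raise PipelineError(
                f"EM log-likelihood decreased at iteration {it}: {loglik} -> {new_loglik}"
            )
        T = np.exp(logw - norm[:, None])
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * abs(loglik):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return pi, P, loglik, converged, it


def fit_em(X, K: int, seed: int, n_restarts: int = DEFAULT_N_RESTARTS,
           tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER) -> BernoulliMixtureModel:
    """Fit a K-class Bernoulli mixture by EM, best of ``n_restarts`` starts.

    All restart RNG streams derive deterministically from ``seed``.
    """
    X = _as_binary(X)
    n, J = X.shape
    if K < 1:
        raise DataError("fit_em: K must be >= 1")
    if n <= K:
        raise DataError(f"fit_em: need n > K (n={n}, K={K})")
    if K == 1:
        # Closed form: p_j is the column mean; no restarts needed.
        P = np.clip(X.mean(axis=0, keepdims=True), EPS_PROB, 1.0 - EPS_PROB)
        loglik = float((X @ np.log(P).T + (1 - X) @ np.log1p(-P).T).sum())
        return BernoulliMixtureModel(
            K=1, pi=np.ones(1), P=P, loglik=loglik,
            nu=J, converged=True, n_iter=1, seed=seed,
        )
    streams = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for ss in streams:
        result = _em_once(X, K, np.random.default_rng(ss), tol, max_iter)
        if result is None:
            continue
        if best is None or result[2] > best[2]:
            best = result
    if best is None:
        raise PipelineError(f"fit_em: all {n_restarts} restarts failed for K={K}")
    pi, P, loglik, converged, n_iter = best
    return BernoulliMixtureModel(
        K=K, pi=pi, P=P, loglik=loglik,
        nu=(K - 1) + K * J, converged=converged, n_iter=n_iter, seed=seed,
    )


def make_solution(model: BernoulliMixtureModel, X) -> ClusterSolution:
    """Attach responsibilities, MAP labels and entropy to a fitted model."""
    X = _as_binary(X)
    logT, _ = model.log_responsibilities(X)
    T = np.exp(logT)
    labels = np.argmax(T, axis=1)           # ties break to the lowest index
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_terms = np.where(T > 0, -T * logT, 0.0)
    return ClusterSolution(
        model=model, responsibilities=T, labels=labels,
        entropy=float(ent_terms.sum()),
    )


def bic(model: BernoulliMixtureModel, n: int) -> float:
    """Bayesian Information Criterion; lower is better."""
    return float(-2.0 * model.loglik + model.nu * np.log(n))


def icl(solution: ClusterSolution, n: int) -> float:
    """Integrated Completed Likelihood: BIC plus twice the assignment entropy."""
    return bic(solution.model, n) + 2.0 * solution.entropy


def nec(solution: ClusterSolution, loglik_k1: float) -> float:
    """Normalized Entropy Criterion; NEC(1) is 1 by convention."""
    if solution.model.K == 1:
        return 1.0
    gain = solution.model.loglik - loglik_k1
    if gain <= 0:
        warnings.warn("NEC undefined: loglik(K) <= loglik(1); returning +inf")
        return np.inf
    return float(solution.entropy / gain)


def kmax_bezdek(n: int) -> int:
    """Smallest integer strictly greater than the cube root of n."""
    if n < 8:
        raise DataError("kmax_bezdek: need n >= 8")
    m = 2
    while m ** 3 <= n:
        m += 1
    return m


def fit_range(X, seed: int, kmin: int = 2, kmax: int = None,
              n_restarts: int = DEFAULT_N_RESTARTS, tol: float = DEFAULT_TOL,
              max_iter: int = DEFAULT_MAX_ITER) -> dict:
    """Fit every K in [kmin, kmax] plus the K=1 reference.

    Returns ``{K: ClusterSolution}`` with all three criteria filled in; the
    K=1 solution (needed by NEC) is included under key 1. Per-K fitting seeds
    derive deterministically from ``seed``.
    """
    Xb = _as_binary(X)
    n = Xb.shape[0]
    if kmax is None:
        kmax = kmax_bezdek(n)
    if kmin < 2 or kmax < kmin:
        raise DataError("fit_range: need 2 <= kmin <= kmax")
    model1 = fit_em(Xb, 1, seed=seed)
    solutions = {1: make_solution(model1, Xb)}
    for K in range(kmin, kmax + 1):
        # Distinct deterministic substream per K, still reproducible from seed.
        sub_seed = int(np.random.SeedSequence((seed, K)).generate_state(1)[0] % (2**31))
        model = fit_em(Xb, K, seed=sub_seed, n_restarts=n_restarts, tol=tol, max_iter=max_iter)
        solutions[K] = make_solution(model, Xb)
    for K, sol in solutions.items():
        sol.criteria = {
            "bic": bic(sol.model, n),
            "icl": icl(sol, n),
            "nec": nec(sol, model1.loglik),
        }
    return solutions


def select_model(X, criterion: str = "bic", seed: int = 0, kmin: int = 2,
                 kmax: int = None, n_restarts: int = DEFAULT_N_RESTARTS,
                 tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER) -> ClusterSolution:
    """Fit the whole K range and return the lowest-criterion solution.

    ``criterion`` is one of ``bic``, ``icl``, ``nec``. Ties break to the
    smaller K; the K=1 reference is fitted only for the NEC denominator and
    is not a candidate.
    """
    criterion = criterion.lower()
    if criterion not in ("bic", "icl", "nec"):
        raise DataError(f"select_model: unknown criterion {criterion!r}")
    solutions = fit_range(X, seed=seed, kmin=kmin, kmax=kmax,
                          n_restarts=n_restarts, tol=tol, max_iter=max_iter)
    best_K = None
    best_val = np.inf
    for K in sorted(k for k in solutions if k >= 2):
        val = solutions[K].criteria[criterion]
        if val < best_val:                   # strict: ties keep the smaller K
            best_val = val
            best_K = K
    if best_K is None:
        raise PipelineError("select_model: no candidate model could be fitted")
    return solutions[best_K]
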