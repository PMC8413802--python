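"""Latent class analysis for dichotomous indicators.

Model: respondent i's binary response vector y_i arises from one of K
latent classes. Class k has weight pi_k and endorses item j with
probability rho_jk, independently across items given class
(local independence):

    P(y_i) = sum_k pi_k * prod_j rho_jk^{y_ij} (1 - rho_jk)^{1 - y_ij}

Estimation is maximum likelihood via EM with multiple random starts.
All per-respondent work is done in log space with log-sum-exp
stabilization, so likelihoods stay finite even with many items and
near-boundary probabilities. rho is clamped to [eps, 1-eps] at every
M-step; clamp events are counted.

Label switching is inherent to mixtures: `align_labels` finds the
permutation of estimated classes best matching a reference solution by
optimal assignment on the conditional-probability columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

RHO_EPS = 1e-5
#: two best-start log-likelihoods within this tolerance count as replicates
REPLICATION_TOL = 1e-4


@dataclass
class LCAParameters:
    """Class weights and conditional item probabilities.

    pi: (K,) mixing proportions summing to 1.
    rho: (J, K); rho[j, k] = P(item j endorsed | class k).
    """

    pi: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, float)
        self.rho = np.asarray(self.rho, float)
        if self.pi.ndim != 1 or self.rho.ndim != 2 or self.rho.shape[1] != len(self.pi):
            raise ValueError("shape mismatch between pi and rho")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")
        if len(self.pi) > 1 and (np.any(self.pi <= 0) or np.any(self.pi >= 1)):
            raise ValueError("each class weight must lie in (0, 1)")
        if np.any(self.rho < 0) or np.any(self.rho > 1):
            raise ValueError("rho entries must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.pi)

    @property
    def n_items(self) -> int:
        return self.rho.shape[0]

    def clamped(self, eps: float = RHO_EPS) -> "LCAParameters":
        return LCAParameters(self.pi, np.clip(self.rho, eps, 1 - eps))

    def permuted(self, perm: np.ndarray) -> "LCAParameters":
        perm = np.asarray(perm)
        return LCAParameters(self.pi[perm], self.rho[:, perm])


@dataclass
class StartPolicy:
    """Multi-start EM settings (estimation plumbing, not model content)."""

    n_starts: int = 50
    max_iter: int = 1000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class FitResult:
    """A converged multi-start EM solution."""

    params: LCAParameters
    loglik: float
    n_params: int
    posteriors: np.ndarray  # (N, K), rows sum to 1
    assignments: np.ndarray  # (N,), modal classes, 1-based
    converged: bool
    n_starts_replicating_best: int
    seed: int
    n_clamped: int = 0
    tie_flags: np.ndarray | None = None
    ll_trace: np.ndarray | None = None

    @property
    def unique_solution(self) -> bool:
        """Best log-likelihood replicated by at least two starts.

        With a single start (including the closed-form K=1 fit) the
        solution is trusted by construction.
        """
        return self.n_starts_replicating_best >= 2


def _log_component_matrix(params: LCAParameters, Y: np.ndarray) -> np.ndarray:
    """(N, K) matrix of log pi_k + log P(y_i | class k)."""
    rho = np.clip(params.rho, RHO_EPS, 1 - RHO_EPS)
    log_rho = np.log(rho)
    log_1mrho = np.log1p(-rho)
    return np.log(params.pi)[None, :] + Y @ log_rho + (1 - Y) @ log_1mrho


def log_likelihood(params: LCAParameters, Y: np.ndarray) -> float:
    """Observed-data log-likelihood of the binary mixture."""
    Y = np.asarray(Y, float)
    if Y.shape[1] != params.n_items:
        raise ValueError("item dimension mismatch")
    return float(logsumexp(_log_component_matrix(params, Y), axis=1).sum())


def posterior_probabilities(params: LCAParameters, Y: np.ndarray) -> np.ndarray:
    """(N, K) class-membership posteriors tau."""
    log_comp = _log_component_matrix(params, np.asarray(Y, float))
    log_tau = log_comp - logsumexp(log_comp, axis=1, keepdims=True)
    return np.exp(log_tau)


def n_parameters(K: int, J: int) -> int:
    """Free parameters of the K-class model on J binary items: K*J + (K-1)."""
    if K < 1 or J < 1:
        raise ValueError("K and J must be >= 1")
    return K * J + (K - 1)


def modal_assignment(posteriors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each respondent to the highest-posterior class (1-based).

    Exact ties break toward the lowest class index and are flagged.
    Returns ``(assignments, tie_flags)``.
    """
    tau = np.asarray(posteriors, float)
    if np.any(~np.isfinite(tau)) or not np.allclose(tau.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must be finite and sum to 1")
    W = tau.argmax(axis=1)
    row_max = tau[np.arange(len(tau)), W]
    ties = (tau == row_max[:, None]).sum(axis=1) > 1
    return W + 1, ties


def _em_single_start(Yu, counts, pi0, rho0, max_iter, tol):
    """Run EM from one start on unique response patterns with counts.

    Collapsing duplicate rows is an exact reformulation of the
    likelihood (sufficient statistics are pattern counts) and makes
    small-J fits, e.g. inside the bootstrap, dramatically cheaper.
    Returns (params, ll, trace, converged, n_clamped, tau_patterns).
    """
    pi = np.asarray(pi0, float)
    rho = np.clip(np.asarray(rho0, float), RHO_EPS, 1 - RHO_EPS)
    trace = []
    prev_ll = -np.inf
    converged = False
    n_clamped = 0
    tau = None
    cY = counts[:, None]
    # With few items the per-pattern log-density cannot underflow
    # (bounded below by J * log(RHO_EPS)), so the cheaper linear-space
    # E-step is exact; many items need log-sum-exp stabilization.
    linear_ok = Yu.shape[1] * (-np.log(RHO_EPS)) < 600
    for _ in range(max_iter):
        log_cond = Yu @ np.log(rho) + (1 - Yu) @ np.log1p(-rho)
        if linear_ok:
            comp = np.exp(log_cond) * pi[None, :]
            mix = comp.sum(axis=1, keepdims=True)
            ll = float((counts * np.log(mix[:, 0])).sum())
            tau = comp / mix
        else:
            log_comp = np.log(pi)[None, :] + log_cond
            log_norm = logsumexp(log_comp, axis=1, keepdims=True)
            ll = float((counts * log_norm[:, 0]).sum())
            tau = np.exp(log_comp - log_norm)
        trace.append(ll)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        # M-step; tiny floor on weights keeps a collapsing class finite
        wtau = tau * cY
        weight = np.maximum(wtau.sum(axis=0), 1e-10)  # (K,)
        pi = weight / weight.sum()
        new_rho = (Yu.T @ wtau) / weight[None, :]
        rho = np.clip(new_rho, RHO_EPS, 1 - RHO_EPS)
        n_clamped += int((rho != new_rho).sum())
    params = LCAParameters(pi, rho)
    return params, trace[-1], np.asarray(trace), converged, n_clamped, tau


def _random_start(rng, K, J):
    pi = rng.dirichlet(np.ones(K))
    rho = rng.uniform(0.1, 0.9, size=(J, K))
    return pi, rho


def em_fit(Y: np.ndarray, K: int, policy: StartPolicy | None = None, *,
           warm_starts: list[LCAParameters] | None = None,
           require_convergence: bool = True) -> FitResult:
    """Fit the K-class model by multi-start EM and keep the best solution.

    Parameters
    ----------
    Y
        N x J binary matrix (numpy array or DataFrame ``.values``-like).
    K
        Number of latent classes (>= 1). K=1 is closed form: rho are the
        column means, no EM needed.
    policy
        Start count, iteration cap, absolute log-likelihood tolerance and
        master seed. Per-start random streams are spawned from the master
        seed, so runs are bit-reproducible.
    warm_starts
        Optional parameter sets tried in addition to the random starts
        (used by the bootstrap likelihood-ratio test to reuse the parent
        solution).

    Returns the best-likelihood ``FitResult``; its
    ``n_starts_replicating_best`` counts starts whose converged
    log-likelihood lies within 1e-4 of the best, the operational check
    that a unique maximum was found.
    """
    policy = policy or StartPolicy()
    Y = np.asarray(Y, float)
    N, J = Y.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if N <= K:
        raise ValueError("need more respondents than classes")
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("Y must be a 0/1 matrix")

    if K == 1:
        rho = np.clip(Y.mean(axis=0), RHO_EPS, 1 - RHO_EPS)[:, None]
        params = LCAParameters(np.array([1.0]), rho)
        ll = log_likelihood(params, Y)
        tau = np.ones((N, 1))
        W, ties = modal_assignment(tau)
        return FitResult(params, ll, n_parameters(1, J), tau, W, True, 1,
                         policy.seed, 0, ties, np.array([ll]))

    Yu, inverse, counts = np.unique(Y, axis=0, return_inverse=True,
                                    return_counts=True)
    n_patterns = len(Yu)
    if K > n_patterns:
        import warnings

        warnings.warn(
            f"K={K} exceeds the {n_patterns} distinct response patterns; "
            "solution is at risk of degeneracy"
        )

    ss = np.random.SeedSequence(policy.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(policy.n_starts)]
    results = []
    starts = [(None, w.pi, w.rho) for w in (warm_starts or [])]
    starts += [(rng, None, None) for rng in streams]
    for rng, pi0, rho0 in starts:
        if pi0 is None:
            pi0, rho0 = _random_start(rng, K, J)
        res = _em_single_start(Yu, counts, pi0, rho0, policy.max_iter, policy.tol)
        results.append(res)

    lls = np.array([r[1] for r in results])
    best_idx = int(lls.argmax())
    params, ll, trace, converged, n_clamped, tau_u = results[best_idx]
    n_replicating = int(np.sum(lls >= ll - REPLICATION_TOL))
    if require_convergence and not any(r[3] for r in results):
        raise RuntimeError(f"no EM start converged for K={K}")
    tau = tau_u[inverse]
    W, ties = modal_assignment(tau)
    return FitResult(params, ll, n_parameters(K, J), tau, W, converged,
                     n_replicating, policy.seed, n_clamped, ties, trace)


def align_labels(est: LCAParameters, ref: LCAParameters) -> np.ndarray:
    """Permutation of estimated classes best matching a reference.

    Minimizes the total absolute difference between conditional-
    probability columns via optimal assignment. ``perm[k]`` is the index
    of the estimated class matched to reference class k, so
    ``est.permuted(perm)`` is in reference order.
    """
    if est.n_classes != ref.n_classes or est.n_items != ref.n_items:
        raise ValueError("parameter shapes must match for alignment")
    cost = np.abs(ref.rho[:, :, None] - est.rho[:, None, :]).sum(axis=0)
    _, cols = linear_sum_assignment(cost)
    return cols


def apply_alignment(fit: FitResult, perm: np.ndarray) -> FitResult:
    """Return a copy of ``fit`` with classes reordered by ``perm``."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    tau = fit.posteriors[:, perm]
    W = inv[fit.assignments - 1] + 1
    return FitResult(fit.params.permuted(perm), fit.loglik, fit.n_params, tau,
                     W, fit.converged, fit.n_starts_replicating_best, fit.seed,
                     fit.n_clamped, fit.tie_flags, fit.ll_trace)
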