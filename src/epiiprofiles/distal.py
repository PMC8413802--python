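"""Class comparisons on distal outcomes with classification-error correction.

Modal assignment misclassifies some respondents, which attenuates
between-class differences on outcomes compared outside the measurement
model. The 3-step remedy: (1) fit the class model without outcomes,
(2) assign classes modally, (3) compare classes on the outcome treating
the assignment as an error-prone indicator of the true class, with the
error distribution fixed at

    q_ks = P(assigned = s | true class = k)
         = sum_i tau_ik 1[W_i = s] / sum_i tau_ik.

Step 3 maximizes, over the outcome parameters only (pi-hat and Q held
fixed),

    LL = sum_i log sum_k pi_k q_{k, W_i} f(y_i | theta_k)

with f a class-specific normal (continuous outcomes, unequal variances;
the DU3STEP analogue) or a class-specific categorical distribution (the
DCAT analogue). Standard errors come from the observed information of
this step-3 likelihood, so they ignore step-1 sampling error, as in the
source procedures. Overall equality is a Wald chi-square; pairwise
contrasts are Wald tests with Bonferroni-adjusted alpha.

These corrections are trustworthy only when classes are reasonably
separated; below relative entropy 0.60 a warning is raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tools.numdiff import approx_hess1

ENTROPY_FLOOR = 0.60
_PCLIP = 1e-9


def classification_error_matrix(posteriors: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """K x K matrix Q with q_ks = P(assigned s | true k), rows sum to 1."""
    tau = np.asarray(posteriors, float)
    W = np.asarray(assignments)
    K = tau.shape[1]
    mass = tau.sum(axis=0)
    if np.any(mass <= 0):
        raise ValueError("a class has zero posterior mass")
    Q = np.empty((K, K))
    for s in range(1, K + 1):
        Q[:, s - 1] = tau[W == s].sum(axis=0) if (W == s).any() else 0.0
    return Q / mass[:, None]


@dataclass
class DistalEstimate:
    """Class-specific outcome estimates with corrected tests."""

    estimates: np.ndarray          # (K,) means or (K, C) category probabilities
    ses: np.ndarray                # same shape as estimates
    overall_stat: float | None
    overall_df: int | None
    overall_p: float | None
    pairwise: pd.DataFrame | None  # pair, statistic, p, significant
    alpha_adjusted: float | None
    loglik: float = np.nan
    unstable: bool = False
    extra: dict = field(default_factory=dict)


def _check_entropy(entropy: float | None):
    if entropy is not None and entropy < ENTROPY_FLOOR:
        warnings.warn(
            f"relative entropy {entropy:.3f} < {ENTROPY_FLOOR}: "
            "classification-error-corrected comparisons may be unreliable"
        )


def _prior_weight(W: np.ndarray, Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """(N, K) matrix pi_k q_{k, W_i}: the fixed part of the step-3 mixture."""
    return pi[None, :] * Q[:, W - 1].T


def pairwise_tests(pairs: list[tuple[int, int]], stats_: np.ndarray,
                   pvals: np.ndarray, family_alpha: float, K: int) -> tuple[pd.DataFrame, float]:
    """Assemble a pairwise table with Bonferroni-adjusted significance.

    ``alpha_adjusted = family_alpha / (K(K-1)/2)``; each pair is flagged
    significant iff its p-value falls below the adjusted level.
    """
    n_pairs = K * (K - 1) // 2
    alpha_adj = family_alpha / n_pairs
    table = pd.DataFrame({
        "pair": [f"C{a}-C{b}" for a, b in pairs],
        "class_a": [a for a, _ in pairs],
        "class_b": [b for _, b in pairs],
        "statistic": stats_,
        "p_value": pvals,
        "significant": pvals < alpha_adj,
    })
    return table, alpha_adj


def _wald_overall(theta: np.ndarray, cov: np.ndarray) -> tuple[float, int, float]:
    """Wald chi-square for equality of a parameter vector across classes.

    ``theta`` is (K,) or (K, C-1) flattened by class; the contrast takes
    differences against the last class.
    """
    theta = np.atleast_2d(np.asarray(theta, float).reshape(len(theta), -1))
    K, P = theta.shape
    # contrast rows: theta_k - theta_K for k < K, each parameter column
    C = np.zeros(((K - 1) * P, K * P))
    for k in range(K - 1):
        for p in range(P):
            C[k * P + p, k * P + p] = 1.0
            C[k * P + p, (K - 1) * P + p] = -1.0
    diff = C @ theta.ravel()
    V = C @ cov @ C.T
    try:
        stat = float(diff @ np.linalg.solve(V, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(V) @ diff)
    df = (K - 1) * P
    return stat, df, float(stats.chi2.sf(stat, df))


def du3step_continuous(y: np.ndarray, W: np.ndarray, Q: np.ndarray,
                       pi_hat: np.ndarray, *, family_alpha: float = 0.05,
                       entropy: float | None = None, tol: float = 1e-8,
                       max_iter: int = 5000) -> DistalEstimate:
    """Corrected class-specific means of a continuous outcome.

    Fits class-specific normals with unequal variances by EM in the
    fixed-(pi, Q) mixture, then tests mean equality overall (Wald
    chi-square, K-1 df) and pairwise (Wald z, Bonferroni-adjusted).
    """
    y = np.asarray(y, float)
    W = np.asarray(W)
    pi_hat = np.asarray(pi_hat, float)
    K = len(pi_hat)
    _check_entropy(entropy)

    if K == 1:
        return DistalEstimate(np.array([y.mean()]),
                              np.array([y.std(ddof=1) / np.sqrt(len(y))]),
                              None, None, None, None, None)

    prior = _prior_weight(W, Q, pi_hat)  # (N, K)
    # init from naive assigned-class summaries
    mu = np.array([y[W == k + 1].mean() if (W == k + 1).any() else y.mean()
                   for k in range(K)])
    var = np.array([y[W == k + 1].var() if (W == k + 1).sum() > 1 else y.var()
                    for k in range(K)])
    var = np.maximum(var, 1e-8)

    def loglik_of(mu_, var_):
        dens = stats.norm.pdf(y[:, None], mu_[None, :], np.sqrt(var_)[None, :])
        mix = np.maximum((prior * dens).sum(axis=1), 1e-300)
        return np.log(mix).sum(), prior * dens / mix[:, None]

    prev = -np.inf
    unstable = False
    for _ in range(max_iter):
        ll, resp = loglik_of(mu, var)
        if abs(ll - prev) < tol:
            break
        prev = ll
        wk = np.maximum(resp.sum(axis=0), 1e-12)
        mu = (resp * y[:, None]).sum(axis=0) / wk
        var = (resp * (y[:, None] - mu[None, :]) ** 2).sum(axis=0) / wk
        if np.any(var < 1e-8):
            unstable = True
            var = np.maximum(var, 1e-8)

    # observed information on (mu, log var)
    def nll(theta):
        m = theta[:K]
        v = np.exp(theta[K:])
        dens = stats.norm.pdf(y[:, None], m[None, :], np.sqrt(v)[None, :])
        mix = np.maximum((prior * dens).sum(axis=1), 1e-300)
        return -np.log(mix).sum()

    theta_hat = np.concatenate([mu, np.log(var)])
    H = approx_hess1(theta_hat, nll)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        unstable = True
    cov_mu = cov[:K, :K]
    ses = np.sqrt(np.maximum(np.diag(cov_mu), 0))

    stat, df, p = _wald_overall(mu, cov_mu)
    pairs = list(combinations(range(1, K + 1), 2))
    zstats, pvals = [], []
    for a, b in pairs:
        i, j = a - 1, b - 1
        se = np.sqrt(max(cov_mu[i, i] + cov_mu[j, j] - 2 * cov_mu[i, j], 1e-300))
        z = (mu[i] - mu[j]) / se
        zstats.append(z)
        pvals.append(2 * stats.norm.sf(abs(z)))
    table, alpha_adj = pairwise_tests(pairs, np.array(zstats), np.array(pvals),
                                      family_alpha, K)
    return DistalEstimate(mu, ses, stat, df, p, table, alpha_adj, prev,
                          unstable, {"variances": var})


def dcat_categorical(y: np.ndarray, W: np.ndarray, Q: np.ndarray,
                     pi_hat: np.ndarray, *, family_alpha: float = 0.05,
                     entropy: float | None = None, tol: float = 1e-10,
                     max_iter: int = 10000) -> DistalEstimate:
    """Corrected class-specific category probabilities of a discrete outcome.

    Estimates p_kc in the fixed-(pi, Q) mixture, tests homogeneity
    overall (Wald chi-square on baseline-category logits,
    (K-1)(C-1) df) and pairwise per class pair (chi-square, C-1 df;
    for a binary outcome this is the squared log-odds-difference z).
    """
    y = np.asarray(y)
    W = np.asarray(W)
    pi_hat = np.asarray(pi_hat, float)
    K = len(pi_hat)
    _check_entropy(entropy)

    cats_all, counts = np.unique(y, return_counts=True)
    present = counts > 0
    if present.sum() < cats_all.size:
        warnings.warn("dropping outcome categories absent from the data")
    cats = cats_all[present]
    C = len(cats)
    ycode = np.searchsorted(cats, y)
    onehot = np.eye(C)[ycode]  # (N, C)

    if C < 2:
        warnings.warn("outcome is constant; no class comparison possible")
        est = np.ones((K, 1))
        return DistalEstimate(est, np.zeros((K, 1)), None, None, None,
                              None, None, extra={"categories": cats})

    prior = _prior_weight(W, Q, pi_hat)  # (N, K)
    # init near the naive assigned-class proportions, smoothed
    p = np.vstack([
        (onehot[W == k + 1].sum(axis=0) + 1.0) / ((W == k + 1).sum() + C)
        for k in range(K)
    ])

    def e_step(p_):
        like = p_[:, ycode].T  # (N, K): P(y_i | class k)
        mix = np.maximum((prior * like).sum(axis=1), 1e-300)
        return np.log(mix).sum(), prior * like / mix[:, None]

    prev = -np.inf
    for _ in range(max_iter):
        ll, resp = e_step(p)
        if abs(ll - prev) < tol:
            break
        prev = ll
        num = resp.T @ onehot  # (K, C)
        p = num / np.maximum(num.sum(axis=1, keepdims=True), 1e-12)
        p = np.clip(p, _PCLIP, 1.0)
        p /= p.sum(axis=1, keepdims=True)

    # observed information on baseline-category logits (C-1 per class)
    def nll(theta):
        logits = np.concatenate(
            [theta.reshape(K, C - 1), np.zeros((K, 1))], axis=1)
        logits -= logits.max(axis=1, keepdims=True)
        pm = np.exp(logits)
        pm /= pm.sum(axis=1, keepdims=True)
        like = pm[:, ycode].T
        mix = np.maximum((prior * like).sum(axis=1), 1e-300)
        return -np.log(mix).sum()

    logit_hat = np.log(p[:, :-1]) - np.log(p[:, -1:])
    theta_hat = logit_hat.ravel()
    H = approx_hess1(theta_hat, nll)
    unstable = False
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        unstable = True

    # delta method for SEs of probabilities: dp/dlogit within each class
    ses = np.zeros_like(p)
    for k in range(K):
        block = cov[k * (C - 1):(k + 1) * (C - 1), k * (C - 1):(k + 1) * (C - 1)]
        pk = p[k]
        Jac = np.zeros((C, C - 1))
        for c in range(C):
            for m in range(C - 1):
                Jac[c, m] = pk[c] * ((1.0 if c == m else 0.0) - pk[m])
        var_p = Jac @ block @ Jac.T
        ses[k] = np.sqrt(np.maximum(np.diag(var_p), 0))

    stat, df, pval = _wald_overall(logit_hat, cov)
    pairs = list(combinations(range(1, K + 1), 2))
    pstats, ppvals = [], []
    m = C - 1
    for a, b in pairs:
        ia, ib = a - 1, b - 1
        d = logit_hat[ia] - logit_hat[ib]
        Vaa = cov[ia * m:(ia + 1) * m, ia * m:(ia + 1) * m]
        Vbb = cov[ib * m:(ib + 1) * m, ib * m:(ib + 1) * m]
        Vab = cov[ia * m:(ia + 1) * m, ib * m:(ib + 1) * m]
        V = Vaa + Vbb - Vab - Vab.T
        try:
            s = float(d @ np.linalg.solve(V, d))
        except np.linalg.LinAlgError:
            s = float(d @ np.linalg.pinv(V) @ d)
        pstats.append(s)
        ppvals.append(stats.chi2.sf(s, m))
    table, alpha_adj = pairwise_tests(pairs, np.array(pstats), np.array(ppvals),
                                      family_alpha, K)
    return DistalEstimate(p, ses, stat, df, pval, table, alpha_adj, prev,
                          unstable, {"categories": cats})
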