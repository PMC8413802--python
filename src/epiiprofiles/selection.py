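"""Class enumeration and the fit-index battery.

For each candidate number of classes K the battery reports:

* information criteria — BIC, sample-size-adjusted BIC (SABIC),
  consistent AIC (CAIC, Bozdogan), and the approximate weight of
  evidence (AWE, Banfield-Raftery), all on the -2LL + penalty scale
  where smaller is better:

      BIC   = -2 LL + d ln N
      SABIC = -2 LL + d ln((N + 2) / 24)
      CAIC  = -2 LL + d (ln N + 1)
      AWE   = -2 LL + 2 d (ln N + 1.5)

* evidence weights — the Schwarz-information approximation
  SIC = -BIC/2 gives pairwise Bayes factors BF(A,B) = exp(SIC_A - SIC_B)
  for adjacent K and the approximate correct-model probability
  cmP_A = exp(SIC_A - SIC_max) / sum_j exp(SIC_j - SIC_max);

* classification diagnostics — relative entropy
  E = 1 - sum_i sum_k (-tau_ik ln tau_ik) / (N ln K), its single-item
  analogue ("univariate entropy"), and the assigned-class-by-class mean
  posterior matrix;

* a parametric bootstrap likelihood-ratio test of K vs K-1 (the naive
  LR statistic's null distribution is simulated from the fitted K-1
  model, since the regularity conditions for a chi-square reference fail
  at the boundary of mixture models).

Enumeration starts at K=1 and adds classes until K_max or until the
best log-likelihood is no longer replicated across starts — the
operational meaning of "a unique solution could not be determined".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, xlogy

from .lca import FitResult, LCAParameters, StartPolicy, em_fit


def information_criteria(loglik: float, d: int, n: int) -> dict[str, float]:
    """BIC, SABIC, CAIC and AWE from a maximized log-likelihood."""
    if n <= 1:
        raise ValueError("need n > 1")
    if d < 0:
        raise ValueError("need d >= 0")
    m2ll = -2.0 * loglik
    return {
        "BIC": m2ll + d * np.log(n),
        "SABIC": m2ll + d * np.log((n + 2) / 24),
        "CAIC": m2ll + d * (np.log(n) + 1),
        "AWE": m2ll + 2 * d * (np.log(n) + 1.5),
    }


def evidence_weights(bics) -> tuple[np.ndarray, np.ndarray]:
    """Adjacent-model Bayes factors and correct-model probabilities.

    ``bics`` is ordered by candidate model (typically ascending K).
    Returns ``(bf, cmp)`` where ``bf[m]`` is the evidence for model m
    over model m+1 (length M-1; > 1 favors the simpler model) and
    ``cmp`` are normalized evidence weights over the candidate set.
    All arithmetic is in log space.
    """
    bics = np.asarray(bics, float)
    if bics.size < 2:
        return np.array([]), np.ones(bics.size)
    sic = -bics / 2.0
    log_bf = sic[:-1] - sic[1:]
    log_cmp = sic - logsumexp(sic)
    return np.exp(log_bf), np.exp(log_cmp)


def relative_entropy(posteriors: np.ndarray) -> float:
    """Normalized classification certainty in [0, 1]; 1 = fully separated.

    Undefined for a single class (raises)."""
    tau = np.asarray(posteriors, float)
    N, K = tau.shape
    if K < 2:
        raise ValueError("relative entropy is undefined for K=1")
    total = -xlogy(tau, tau).sum()
    return float(1.0 - total / (N * np.log(K)))


def univariate_entropy(params: LCAParameters, j: int) -> float:
    """Relative entropy achievable from item j alone.

    Single-item posteriors tau_k(y) ∝ pi_k rho_jk^y (1-rho_jk)^(1-y) are
    averaged over the model-implied distribution of y_j:

        e_j = 1 - E_y[ H(tau(y)) ] / ln K

    Items with class-invariant endorsement probabilities contribute
    nothing (e_j = 0); an item endorsed by exactly one class approaches 1.
    """
    K = params.n_classes
    if K < 2:
        raise ValueError("univariate entropy is undefined for K=1")
    if not 0 <= j < params.n_items:
        raise ValueError(f"item index {j} outside the model")
    rho_j = params.rho[j]
    expected_H = 0.0
    for y in (0, 1):
        joint = params.pi * np.where(y, rho_j, 1 - rho_j)
        p_y = joint.sum()
        if p_y <= 0:
            continue
        tau = joint / p_y
        expected_H += p_y * float(-xlogy(tau, tau).sum())
    return float(1.0 - expected_H / np.log(K))


def avg_posterior_table(posteriors: np.ndarray, assignments: np.ndarray) -> pd.DataFrame:
    """Assigned-class-by-class matrix of mean posterior probabilities.

    Row s is the mean posterior vector among respondents modally
    assigned to class s; a well-separated solution has a dominant
    diagonal. Empty classes yield NaN rows with a warning.
    """
    tau = np.asarray(posteriors, float)
    W = np.asarray(assignments)
    K = tau.shape[1]
    rows = np.full((K, K), np.nan)
    for s in range(1, K + 1):
        mask = W == s
        if not mask.any():
            warnings.warn(f"no respondents assigned to class {s}")
            continue
        rows[s - 1] = tau[mask].mean(axis=0)
    labels = [f"class{k}" for k in range(1, K + 1)]
    return pd.DataFrame(rows, index=pd.Index(labels, name="assigned"), columns=labels)


def simulate_from(params: LCAParameters, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an n x J binary matrix from a fitted class model."""
    labels = rng.choice(params.n_classes, size=n, p=params.pi)
    u = rng.random((n, params.n_items))
    return (u < params.rho.T[labels]).astype(float)


def bootstrap_lrt(Y: np.ndarray, K: int, B: int = 99,
                  policy: StartPolicy | None = None, *,
                  fit_null: FitResult | None = None,
                  fit_alt: FitResult | None = None,
                  refit_starts: int = 2) -> dict:
    """Parametric bootstrap likelihood-ratio test of K classes vs K-1.

    The observed statistic LR = 2 (LL_K - LL_{K-1}) is referred to its
    simulated null distribution: B datasets are drawn from the fitted
    (K-1)-class model and both models are refit to each. Refits use the
    parent solution as a warm start plus ``refit_starts - 1`` random
    starts to bound runtime. The p-value uses the add-one convention
    p = (1 + #{LR_b >= LR_obs}) / (B + 1).

    Returns a dict with ``lr``, ``p_value``, ``lr_boot`` and
    ``n_refit_failures``.
    """
    if K < 2:
        raise ValueError("bootstrap LRT needs K >= 2")
    if B < 1:
        raise ValueError("B must be >= 1")
    policy = policy or StartPolicy()
    Y = np.asarray(Y, float)
    # best-available solutions suffice for the LR statistic: on data
    # with little K-class structure EM may creep along a flat ridge
    # past the iteration cap without moving the log-likelihood
    if fit_null is None:
        fit_null = em_fit(Y, K - 1, policy, require_convergence=False)
    if fit_alt is None:
        fit_alt = em_fit(Y, K, policy, require_convergence=False)
    lr_obs = 2.0 * (fit_alt.loglik - fit_null.loglik)

    ss = np.random.SeedSequence([policy.seed, K, B])
    # refits tolerate slightly looser convergence and accept the best
    # start even when the cap is hit (a lower bound on the refit LL is
    # acceptable for building the null LR distribution); such
    # non-converged refits are counted.
    boot_tol = max(policy.tol, 1e-4)
    lr_boot = []
    failures = 0
    for child in ss.spawn(B):
        rng = np.random.default_rng(child)
        Yb = simulate_from(fit_null.params, Y.shape[0], rng)
        pol = StartPolicy(refit_starts, policy.max_iter, boot_tol,
                          seed=int(rng.integers(2**31)))
        fb0 = em_fit(Yb, K - 1, pol, warm_starts=[fit_null.params],
                     require_convergence=False)
        fb1 = em_fit(Yb, K, pol, warm_starts=[fit_alt.params],
                     require_convergence=False)
        if not (fb0.converged and fb1.converged):
            failures += 1
        lr_boot.append(2.0 * (fb1.loglik - fb0.loglik))
    lr_boot = np.asarray(lr_boot)
    n_eff = len(lr_boot)
    p = (1 + int((lr_boot >= lr_obs).sum())) / (n_eff + 1)
    return {"lr": lr_obs, "p_value": p, "lr_boot": lr_boot,
            "n_refit_failures": failures}


@dataclass
class EnumerationResult:
    """Fits and the assembled fit-index table for K = 1..K_fitted."""

    fits: dict[int, FitResult]
    table: pd.DataFrame
    selected_K: int
    stopped_early: bool

    @property
    def selected(self) -> FitResult:
        return self.fits[self.selected_K]


def class_enumeration(Y: np.ndarray, K_max: int = 7,
                      policy: StartPolicy | None = None, *,
                      bootstrap_B: int = 0) -> EnumerationResult:
    """Fit K = 1..K_max and assemble the fit-index table.

    Stops early (recording the offending fit, flagged non-unique) when
    the best log-likelihood of a candidate is not replicated by at least
    two starts — the operational "unique solution could not be
    determined" rule. The selected model is the smallest-BIC candidate;
    the table also carries BF (K vs K+1), cmP, entropy, the naive LR
    statistic, and optionally the bootstrap LRT p-value (computed when
    ``bootstrap_B > 0``).
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    policy = policy or StartPolicy()
    Y = np.asarray(Y, float)
    N = Y.shape[0]
    fits: dict[int, FitResult] = {}
    stopped_early = False
    for K in range(1, K_max + 1):
        fit = em_fit(Y, K, StartPolicy(policy.n_starts, policy.max_iter,
                                       policy.tol, seed=policy.seed + K))
        fits[K] = fit
        if K > 1 and not fit.unique_solution:
            warnings.warn(
                f"K={K}: best log-likelihood not replicated across starts; "
                "stopping enumeration"
            )
            stopped_early = True
            break

    rows = []
    Ks = sorted(fits)
    for K in Ks:
        fit = fits[K]
        ic = information_criteria(fit.loglik, fit.n_params, N)
        row = {"K": K, "d": fit.n_params, "LL": fit.loglik, **ic,
               "entropy": relative_entropy(fit.posteriors) if K > 1 else np.nan,
               "unique": fit.unique_solution,
               "n_starts_replicating_best": fit.n_starts_replicating_best}
        row["naive_LR"] = (2.0 * (fit.loglik - fits[K - 1].loglik)
                           if K - 1 in fits else np.nan)
        if bootstrap_B > 0 and K > 1:
            res = bootstrap_lrt(Y, K, bootstrap_B, policy,
                                fit_null=fits[K - 1], fit_alt=fit)
            row["blrt_p"] = res["p_value"]
        else:
            row["blrt_p"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("K")

    bf, cmp_ = evidence_weights(table["BIC"].to_numpy())
    table["BF_vs_next"] = np.append(bf, np.nan) if len(bf) else np.nan
    table["cmP"] = cmp_
    selected_K = int(table["BIC"].idxmin())
    table["selected"] = table.index == selected_K
    return EnumerationResult(fits, table, selected_K, stopped_early)
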