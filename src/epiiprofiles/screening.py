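"""Indicator screening for the latent class model.

Two sequential screens select which dichotomized EPII items enter the
measurement model:

1. **Base-rate filter** — items endorsed by fewer than a threshold
   proportion of respondents (default 5%) are set aside; rare events
   carry too little information to support class-specific estimates.
2. **Stress-correlation screen** — among the remaining items, only those
   whose Spearman rank correlation with the Perceived Stress Scale total
   is significantly positive are retained. The default test is one-sided
   (positive), reflecting that the screen seeks *stress-related*
   experiences; a two-sided variant is available.

Spearman p-values use the large-sample t approximation on midranked
data; an exact permutation test is used automatically for small samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def base_rate_filter(binary: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Flag items whose endorsement base rate falls below ``threshold``.

    The comparison is strict (<): an item at exactly the threshold is
    kept. Returns a per-item DataFrame with ``base_rate`` and
    ``excluded_low_base_rate``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if binary.shape[0] == 0 or binary.shape[1] == 0:
        raise ValueError("empty binary matrix")
    rates = binary.mean(axis=0)
    return pd.DataFrame(
        {"base_rate": rates, "excluded_low_base_rate": rates < threshold}
    )


def spearman_item(x: np.ndarray, y: np.ndarray, *,
                  alternative: str = "greater",
                  exact_below: int = 30,
                  rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Spearman correlation of one item with a criterion and its p-value.

    Midranks handle ties (binary items are heavily tied). For
    N < ``exact_below`` the p-value comes from a permutation test
    (9999 resamples); otherwise from the t approximation.
    Returns ``(rho, p)``; a constant column yields ``(nan, nan)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    n = len(x)
    if n < exact_below:
        rng = rng or np.random.default_rng(0)

        def statistic(xp):
            return stats.spearmanr(xp, y).statistic

        res = stats.permutation_test(
            (x,), statistic, permutation_type="pairings",
            alternative=alternative, n_resamples=9999, rng=rng,
        )
        rho = stats.spearmanr(x, y).statistic
        return float(rho), float(res.pvalue)
    res = stats.spearmanr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def spearman_screen(binary: pd.DataFrame, pss: np.ndarray, *,
                    alpha: float = 0.05,
                    alternative: str = "greater",
                    base_rate_threshold: float = 0.05) -> pd.DataFrame:
    """Full screening report: base rates, stress correlations, retention.

    Parameters
    ----------
    binary
        N x J dichotomized item matrix (columns are items).
    pss
        Length-N Perceived Stress Scale totals.
    alpha
        Significance level for the correlation screen.
    alternative
        ``"greater"`` (one-sided positive, default) or ``"two-sided"``.

    Returns a per-item DataFrame with columns ``base_rate``, ``rho``,
    ``p_value``, ``excluded_low_base_rate``, ``retained_indicator``. An
    item is retained iff it survives the base-rate filter and its
    correlation with stress is significantly positive at ``alpha``.
    """
    pss = np.asarray(pss, float)
    if len(pss) != binary.shape[0]:
        raise ValueError("pss length must equal the number of respondents")
    report = base_rate_filter(binary, base_rate_threshold)
    rhos, pvals = [], []
    for col in binary.columns:
        rho, p = spearman_item(binary[col].to_numpy(), pss, alternative=alternative)
        if np.isnan(rho):
            warnings.warn(f"constant item column {col!r}: rho undefined, not retained")
        rhos.append(rho)
        pvals.append(p)
    report["rho"] = rhos
    report["p_value"] = pvals
    significant = (report["p_value"] < alpha) & (report["rho"] > 0)
    report["retained_indicator"] = (
        ~report["excluded_low_base_rate"] & significant.fillna(False)
    )
    return report


def select_indicators(report: pd.DataFrame) -> list:
    """Ordered list of retained indicator ids from a screening report.

    Raises if nothing is retained (the class model cannot proceed).
    """
    retained = report.index[report["retained_indicator"]].tolist()
    if not retained:
        raise ValueError("no indicators retained by screening; cannot fit a class model")
    return sorted(retained)


def screen_from_published(items: pd.DataFrame | None = None, *,
                          base_rate_threshold: float = 0.05) -> pd.DataFrame:
    """Re-derive the indicator screen from published per-item summaries.

    Applies the base-rate filter to the printed base-rate column and the
    retention rule to the printed significance stars and correlation
    signs — an internal-consistency reconstruction that needs no
    respondent-level data.
    """
    from . import tables

    items = items if items is not None else tables.epii_items()
    rate = items["base_rate_pct"] / 100.0
    excluded = rate < base_rate_threshold
    significant = items["sig"].isin(["*", "**"]) & (items["pss_rho"] > 0)
    return pd.DataFrame(
        {
            "base_rate": rate,
            "rho": items["pss_rho"],
            "excluded_low_base_rate": excluded,
            "retained_indicator": ~excluded & significant,
        },
        index=items.index,
    )
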