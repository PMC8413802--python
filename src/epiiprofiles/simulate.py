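"""Synthetic pandemic-experience survey generator.

Emulates the statistical structure the analysis pipeline assumes, with
defaults taken from the published study population:

* a 5-class binary mixture over the 38 stress-related indicators
  (published class proportions and conditional item probabilities);
* the remaining 54 EPII items endorsed class-independently at their
  published base rates;
* class-conditional binary distal outcomes (sociodemographics and
  psychosocial screens) at the published class-specific rates;
* psychosocial scale totals drawn from class-conditional normals and
  allocated to item responses so that items sum to the drawn total.
  Screen-bearing scales (PHQ-9, GAD-7, PC-PTSD-5) invert the normal
  exceedance at the published class-specific screen rates, so scored
  screens approximately reproduce those rates; the perceived-stress and
  social-support means are package choices (high stress / low support
  in the three high-risk classes).

Endorsed EPII items are split into "Yes, me" vs "Yes, person in home"
raw codes (80/20 by default; household-level items 42/43/65 are always
"yes"), and non-endorsed into "No" vs "Not applicable" (85/15). The
analysis collapses these, so the split is cosmetic but exercises the
dichotomization path.

Generation is bit-reproducible: one mandatory master seed spawns
independent streams per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import tables
from .catalog import (NO, NOT_APPLICABLE, YES_ME, YES_OTHER,
                      HOUSEHOLD_LEVEL_ITEMS, epii_column)

#: class-conditional normal means for scales without a published
#: screen profile (package choice, see docs/methods.md): perceived
#: stress high in classes 1-3, social support high in classes 4-5.
DEFAULT_PSS_MEANS = (20.0, 22.0, 19.0, 14.0, 12.0)
DEFAULT_PSS_SD = 6.0
DEFAULT_SSQ_MEANS = (18.0, 15.0, 16.0, 21.0, 22.0)
DEFAULT_SSQ_SD = 4.0


def exceedance_mean(cutoff: float, p: np.ndarray, sd: float) -> np.ndarray:
    """Normal means giving P(X >= cutoff - 0.5) = p at fixed sd.

    Totals are rounded to integers, so the half-point continuity
    correction makes P(round(X) >= cutoff) match p. Rates are clipped
    to [0.002, 0.998] to keep the inversion finite.
    """
    p = np.clip(np.asarray(p, float), 0.002, 0.998)
    return (cutoff - 0.5) - sd * stats.norm.ppf(1.0 - p)


def _default_scale_specs() -> dict:
    rates = tables.distal_rates()
    return {
        "pss": {"means": np.asarray(DEFAULT_PSS_MEANS), "sd": DEFAULT_PSS_SD},
        "phq9": {"means": exceedance_mean(15, rates.loc["phq9_ge15", "p1":"p5"].to_numpy(), 5.0), "sd": 5.0},
        "gad7": {"means": exceedance_mean(15, rates.loc["gad7_ge15", "p1":"p5"].to_numpy(), 5.0), "sd": 5.0},
        "pcptsd": {"means": exceedance_mean(3, rates.loc["pcptsd_ge3", "p1":"p5"].to_numpy(), 1.5), "sd": 1.5},
        "ssq": {"means": np.asarray(DEFAULT_SSQ_MEANS), "sd": DEFAULT_SSQ_SD},
    }


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the published study conditions."""

    n: int = tables.STUDY_N
    seed: int = 0
    pi: np.ndarray = field(default_factory=tables.class_proportions)
    rho: pd.DataFrame | None = None        # items x classes, index = item ids
    nonindicator_rates: pd.Series | None = None
    distal_rates: pd.DataFrame | None = None
    scale_specs: dict | None = None
    yes_me_split: float = 0.8
    na_split: float = 0.15

    def __post_init__(self):
        self.pi = np.asarray(self.pi, float)
        self.pi = self.pi / self.pi.sum()
        if self.rho is None:
            prof = tables.class_profiles().sort_index()
            self.rho = prof.loc[:, "rho1":"rho5"]
        if self.nonindicator_rates is None:
            items = tables.epii_items()
            others = items.index.difference(self.rho.index)
            self.nonindicator_rates = items.loc[others, "base_rate_pct"] / 100.0
        if self.distal_rates is None:
            self.distal_rates = tables.distal_rates()
        if self.scale_specs is None:
            self.scale_specs = _default_scale_specs()
        for arr in (self.pi, self.rho.to_numpy(), self.nonindicator_rates.to_numpy()):
            if np.any(np.asarray(arr) < 0) or np.any(np.asarray(arr) > 1):
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.pi)

    def marginal_prevalence(self, item: int) -> float:
        """Model-implied marginal endorsement rate sum_k pi_k rho_jk."""
        if item in self.rho.index:
            return float(self.rho.loc[item].to_numpy() @ self.pi)
        return float(self.nonindicator_rates.loc[item])


@dataclass
class SyntheticDataset:
    """A generated survey with its ground truth attached."""

    config: SyntheticConfig
    labels: np.ndarray              # (N,), true classes, 1-based
    raw: pd.DataFrame               # wide CSV schema the pipeline consumes
    indicators: pd.DataFrame        # N x 38 binary truth (pre raw-coding)
    distals: pd.DataFrame           # directly drawn binary outcomes


def _raw_code(endorsed: np.ndarray, rng: np.random.Generator,
              yes_me_split: float, na_split: float,
              household: bool) -> np.ndarray:
    """Map a binary endorsement column to 4-level raw codes."""
    n = len(endorsed)
    out = np.empty(n, dtype=np.int64)
    yes = endorsed.astype(bool)
    if household:
        out[yes] = YES_ME
    else:
        me = rng.random(n) < yes_me_split
        out[yes] = np.where(me[yes], YES_ME, YES_OTHER)
    na = rng.random(n) < na_split
    out[~yes] = np.where(na[~yes], NOT_APPLICABLE, NO)
    return out


def _allocate_total(totals: np.ndarray, n_items: int, item_max: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Integer item responses summing exactly to each respondent's total.

    Sequential uniform allocation within the feasible range of each item
    (order is then shuffled per column block so no item is systematically
    larger).
    """
    n = len(totals)
    remaining = totals.astype(np.int64).copy()
    cols = []
    for i in range(n_items):
        slots_left = n_items - i - 1
        lo = np.maximum(0, remaining - slots_left * item_max)
        hi = np.minimum(item_max, remaining)
        vals = rng.integers(lo, hi + 1)
        remaining -= vals
        cols.append(vals)
    mat = np.column_stack(cols)
    # shuffle item order independently per respondent
    perm = rng.permuted(np.tile(np.arange(n_items), (n, 1)), axis=1)
    return np.take_along_axis(mat, perm, axis=1)


def generate_lca_data(config: SyntheticConfig) -> SyntheticDataset:
    """Draw class labels, all 92 raw-coded EPII items, and distal outcomes."""
    ss = np.random.SeedSequence(config.seed)
    r_label, r_ind, r_non, r_code, r_distal, r_scale = (
        np.random.default_rng(s) for s in ss.spawn(6))

    n = config.n
    labels = r_label.choice(config.n_classes, size=n, p=config.pi) + 1

    rho = config.rho.to_numpy(float)            # (J, K)
    ind = (r_ind.random((n, rho.shape[0])) < rho.T[labels - 1]).astype(np.int64)
    indicators = pd.DataFrame(ind, columns=[epii_column(i) for i in config.rho.index])

    non_items = config.nonindicator_rates.index
    non_rates = config.nonindicator_rates.to_numpy(float)
    non = (r_non.random((n, len(non_items))) < non_rates[None, :]).astype(np.int64)
    non_df = pd.DataFrame(non, columns=[epii_column(i) for i in non_items])

    raw = pd.DataFrame({"respondent_id": np.arange(1, n + 1)})
    binary_all = pd.concat([indicators, non_df], axis=1)
    for item in sorted(list(config.rho.index) + list(non_items)):
        col = epii_column(item)
        raw[col] = _raw_code(binary_all[col].to_numpy(), r_code,
                             config.yes_me_split, config.na_split,
                             household=item in HOUSEHOLD_LEVEL_ITEMS)

    distals = generate_distals(labels, config, rng=r_distal)
    scale_items = generate_scale_items(labels, config, rng=r_scale)
    raw = pd.concat([raw, scale_items,
                     distals.filter(regex="^(?!pcptsd|phq9|gad7)")], axis=1)
    return SyntheticDataset(config, labels, raw, indicators, distals)


def generate_distals(labels: np.ndarray, config: SyntheticConfig, *,
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> pd.DataFrame:
    """Binary distal outcomes drawn at the class-conditional rates."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    labels = np.asarray(labels)
    if labels.min() < 1 or labels.max() > config.n_classes:
        raise ValueError("labels must lie in 1..K")
    out = {}
    for outcome, row in config.distal_rates.iterrows():
        p = row.loc["p1":"p5"].to_numpy(float)
        out[outcome] = (rng.random(len(labels)) < p[labels - 1]).astype(np.int64)
    return pd.DataFrame(out)


def generate_scale_items(labels: np.ndarray, config: SyntheticConfig, *,
                         rng: np.random.Generator | None = None,
                         seed: int | None = None) -> pd.DataFrame:
    """Item-level scale responses consistent with class-conditional totals."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    defs = tables.scale_definitions()
    frames = []
    for name, spec in config.scale_specs.items():
        sdef = defs[name]
        m, mx = len(sdef["columns"]), sdef["item_max"]
        means = np.asarray(spec["means"], float)
        totals = rng.normal(means[labels - 1], spec["sd"])
        totals = np.clip(np.round(totals), 0, m * mx)
        items = _allocate_total(totals, m, mx, rng)
        frames.append(pd.DataFrame(items, columns=sdef["columns"]))
    return pd.concat(frames, axis=1)


def truth_table(dataset: SyntheticDataset) -> dict:
    """The exact generator parameters and labels, for recovery scoring."""
    cfg = dataset.config
    return {
        "n": cfg.n,
        "seed": cfg.seed,
        "pi": cfg.pi.copy(),
        "rho": cfg.rho.copy(),
        "nonindicator_rates": cfg.nonindicator_rates.copy(),
        "distal_rates": cfg.distal_rates.copy(),
        "scale_specs": {k: {"means": np.asarray(v["means"]).copy(), "sd": v["sd"]}
                        for k, v in cfg.scale_specs.items()},
        "labels": dataset.labels.copy(),
    }
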