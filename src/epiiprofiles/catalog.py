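"""EPII item catalog, dichotomization, domain counts, and scale scoring.

The Epidemic-Pandemic Impacts Inventory (EPII) is a 92-item checklist of
pandemic-related experiences across five thematic domains: work/employment
(12 items), home life (19), social activities and isolation (18),
emotional/physical health and infection (24), and positive change (19).
Each item is answered "Yes, me" / "Yes, person in home" / "No" /
"Not applicable"; three items (42, 43, 65) are asked at the household
level as a single yes/no. For analysis, both "yes" codes collapse to 1
and "No"/"N/A" collapse to 0, yielding dichotomous indicators.

The psychosocial battery (PSS, PHQ-9, GAD-7, PC-PTSD-5, Duke-UNC SSQ) is
scored as plain item sums after within-scale mean imputation of the rare
nondisclosed responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables

# Raw EPII response codes as they appear in the wide CSV interface.
NO = 0
YES_ME = 1
YES_OTHER = 2
NOT_APPLICABLE = 3
NONDISCLOSED = 9

VALID_CODES = frozenset({NO, YES_ME, YES_OTHER, NOT_APPLICABLE, NONDISCLOSED})

#: raw code -> dichotomous indicator. Both "yes" codes endorse the item;
#: "no" and "not applicable" do not; the rare opt-out is treated as
#: not-endorsed (conservative; counted and reported by the pipeline).
DICHOTOMY = {NO: 0, YES_ME: 1, YES_OTHER: 1, NOT_APPLICABLE: 0, NONDISCLOSED: 0}

DOMAINS = ("work", "home", "social", "health", "positive")
DOMAIN_SIZES = {"work": 12, "home": 19, "social": 18, "health": 24, "positive": 19}
ADVERSE_DOMAINS = ("work", "home", "social", "health")
HOUSEHOLD_LEVEL_ITEMS = (42, 43, 65)


def epii_column(item: int) -> str:
    """Wide-CSV column name for an EPII item id."""
    return f"EPII{item:02d}"


class CodingError(ValueError):
    """An EPII cell carries a code outside the response enumeration."""


@dataclass(frozen=True)
class ItemCatalog:
    """The 92 EPII items with domain membership and wording keys."""

    table: pd.DataFrame = field(default_factory=tables.epii_items)

    def __post_init__(self):
        t = self.table
        if len(t) != 92 or set(t.index) != set(range(1, 93)):
            raise ValueError("catalog must contain exactly items 1..92")
        sizes = t["domain"].value_counts().to_dict()
        if sizes != DOMAIN_SIZES:
            raise ValueError(f"unexpected domain sizes: {sizes}")

    def items_in_domain(self, domain: str) -> list[int]:
        return self.table.index[self.table["domain"] == domain].tolist()

    def domain_of(self, item: int) -> str:
        return self.table.at[item, "domain"]

    @property
    def item_ids(self) -> list[int]:
        return self.table.index.tolist()


def dichotomize_responses(raw: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Collapse 4-level raw EPII codes to 0/1 indicators.

    Parameters
    ----------
    raw
        One row per respondent; EPII columns coded with the raw response
        enumeration (0=No, 1=Yes-me, 2=Yes-other, 3=N/A, 9=nondisclosed).
    columns
        EPII columns to dichotomize; defaults to every column whose name
        starts with ``EPII``.

    Returns
    -------
    DataFrame of the same row order with entries in {0, 1}.

    Raises
    ------
    CodingError
        If any cell carries a code outside the enumeration; the message
        names the offending row and column.
    """
    if columns is None:
        columns = [c for c in raw.columns if c.startswith("EPII")]
    if not columns:
        raise ValueError("no EPII columns to dichotomize")
    sub = raw[columns]
    values = sub.to_numpy()
    bad = ~np.isin(values, list(VALID_CODES))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CodingError(
            f"invalid EPII code {values[i, j]!r} at row {sub.index[i]!r}, "
            f"column {columns[j]!r}"
        )
    out = sub.replace(DICHOTOMY)
    return out.astype(np.int64)


def nondisclosure_count(raw: pd.DataFrame, columns: list[str] | None = None) -> int:
    """Number of EPII cells coded as the opt-out (mapped to 0 downstream)."""
    if columns is None:
        columns = [c for c in raw.columns if c.startswith("EPII")]
    return int((raw[columns].to_numpy() == NONDISCLOSED).sum())


def domain_counts(binary: pd.DataFrame, catalog: ItemCatalog | None = None) -> pd.DataFrame:
    """Per-respondent cumulative counts of endorsed items per domain.

    ``adverse_total`` sums the four non-positive domains; these cumulative
    exposure counts are the continuous outcomes compared across classes.
    """
    catalog = catalog or ItemCatalog()
    item_of_col = {}
    for col in binary.columns:
        if not (col.startswith("EPII") and col[4:].isdigit()):
            raise KeyError(f"column {col!r} has no catalog entry")
        item = int(col[4:])
        if item not in catalog.table.index:
            raise KeyError(f"column {col!r} has no catalog entry")
        item_of_col[col] = item
    out = pd.DataFrame(index=binary.index)
    for domain in DOMAINS:
        cols = [c for c, i in item_of_col.items() if catalog.domain_of(i) == domain]
        out[domain] = binary[cols].sum(axis=1) if cols else 0
    out["adverse_total"] = out[list(ADVERSE_DOMAINS)].sum(axis=1)
    return out


def score_scale(items: pd.DataFrame, item_min: int, item_max: int) -> pd.DataFrame:
    """Sum-score one scale with within-respondent mean imputation.

    Nondisclosed responses (code 9, outside every scale's item range) are
    replaced by the mean of that respondent's disclosed items on the same
    scale, then items are summed. A respondent with no disclosed items
    gets a missing total.

    Returns a DataFrame with ``total`` (float; NaN when undefined),
    ``imputed_fraction`` and ``missing`` columns.
    """
    values = items.to_numpy(dtype=float)
    out_of_range = (values < item_min) | (values > item_max)
    disclosed = np.where(out_of_range, np.nan, values)
    n_items = values.shape[1]
    n_disclosed = np.sum(~np.isnan(disclosed), axis=1)
    sums = np.nansum(disclosed, axis=1)
    row_mean = np.divide(sums, n_disclosed, out=np.zeros_like(sums),
                         where=n_disclosed > 0)
    filled = np.where(np.isnan(disclosed), row_mean[:, None], disclosed)
    total = filled.sum(axis=1)
    total = np.where(n_disclosed == 0, np.nan, total)
    return pd.DataFrame(
        {
            "total": total,
            "imputed_fraction": (n_items - n_disclosed) / n_items,
            "missing": n_disclosed == 0,
        },
        index=items.index,
    )


def score_scales(df: pd.DataFrame, definitions: dict | None = None) -> pd.DataFrame:
    """Score the full psychosocial battery and attach screening flags.

    Returns one row per respondent with ``<scale>_total`` and
    ``<scale>_imputed_fraction`` for each scale plus the boolean screens
    ``phq9_ge15``, ``gad7_ge15``, ``pcptsd_ge3``.
    """
    definitions = definitions or tables.scale_definitions()
    out = pd.DataFrame(index=df.index)
    for name, spec in definitions.items():
        scored = score_scale(df[spec["columns"]], spec["item_min"], spec["item_max"])
        out[f"{name}_total"] = scored["total"]
        out[f"{name}_imputed_fraction"] = scored["imputed_fraction"]
    return pd.concat([out, screen_flags(out, definitions)], axis=1)


def screen_flags(scores: pd.DataFrame, definitions: dict | None = None) -> pd.DataFrame:
    """Boolean screening indicators from scale totals.

    Cutoffs: PHQ-9 >= 15 (moderately severe depression), GAD-7 >= 15
    (severe anxiety), PC-PTSD-5 >= 3 (probable PTSD). A missing total
    yields a missing flag (pandas nullable boolean).
    """
    definitions = definitions or tables.scale_definitions()
    out = pd.DataFrame(index=scores.index)
    for name, spec in definitions.items():
        cutoff = spec.get("cutoff")
        if cutoff is None:
            continue
        total = scores[f"{name}_total"]
        flag = pd.array(total >= cutoff, dtype="boolean")
        flag[total.isna().to_numpy()] = pd.NA
        out[f"{name}_ge{cutoff}"] = flag
    return out


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: m/(m-1) * (1 - sum(item variances)/var(total)).

    Sample variances (ddof=1). Requires at least two items, two
    respondents, and a nonzero total-score variance.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("cronbach_alpha needs an N x m matrix with m >= 2")
    if x.shape[0] < 2:
        raise ValueError("cronbach_alpha needs at least 2 respondents")
    m = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return m / (m - 1) * (1 - item_var / total_var)
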