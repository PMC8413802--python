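"""Packaged reference tables.

The package ships three small CSVs holding published summary statistics for
the 92-item Epidemic-Pandemic Impacts Inventory (EPII) study population:

* ``epii_items.csv`` — the full item catalog with observed base rates (in
  percent), Spearman correlations with perceived stress, and the reported
  significance stars (``*`` for p < .05, ``**`` for p < .01).
* ``class_profiles.csv`` — the 5-class solution: per-indicator univariate
  entropy and conditional endorsement probabilities rho[j, k].
* ``distal_rates.csv`` — class-conditional probabilities of binary
  sociodemographic characteristics and psychosocial screens.

These serve two roles: as the default parameterization of the synthetic
survey generator, and as printed inputs for internal-consistency checks
(e.g., re-deriving the indicator screen from the published base rates).
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml

#: Mixing proportions of the published 5-class solution (sum to 0.999 as
#: printed; renormalize before use as generator weights).
CLASS_PROPORTIONS_PRINTED = (0.181, 0.144, 0.314, 0.173, 0.187)

#: Published fit table for class enumeration K = 1..7 at N = 652:
#: number of free parameters d and maximized log-likelihood per K.
FIT_TABLE_LL = {
    1: (38, -12117.21),
    2: (77, -11376.82),
    3: (116, -11061.00),
    4: (155, -10912.56),
    5: (194, -10785.57),
    6: (233, -10697.33),
    7: (272, -10638.31),
}

#: Published BIC / SABIC columns of the same fit table (for recomputation
#: checks against d, LL and N = 652).
FIT_TABLE_BIC = {
    1: (24480.67, 24360.02),
    2: (23252.61, 23008.13),
    3: (22873.93, 22505.64),
    4: (22829.52, 22337.40),
    5: (22828.27, 22212.32),
    6: (22904.51, 22164.73),
    7: (23039.00, 22175.59),
}

#: Analytic sample size of the published study.
STUDY_N = 652


def _data_path(name: str):
    return importlib.resources.files("epiiprofiles.data").joinpath(name)


@lru_cache(maxsize=None)
def epii_items() -> pd.DataFrame:
    """Item catalog with published base rates and stress correlations.

    Returns a DataFrame indexed by item id (1..92) with columns
    ``domain``, ``label``, ``base_rate_pct``, ``pss_rho``, ``sig``,
    ``household_level``.
    """
    with importlib.resources.as_file(_data_path("epii_items.csv")) as p:
        df = pd.read_csv(p, keep_default_na=False, na_values=[])
    df["sig"] = df["sig"].astype(str)
    df["household_level"] = df["household_level"].astype(bool)
    return df.set_index("item").sort_index()


@lru_cache(maxsize=None)
def class_profiles() -> pd.DataFrame:
    """Published 5-class conditional item probabilities.

    Indexed by item id (38 retained indicators, catalog order is the
    printed order); columns ``univariate_entropy`` and ``rho1``..``rho5``.
    """
    with importlib.resources.as_file(_data_path("class_profiles.csv")) as p:
        return pd.read_csv(p).set_index("item")


@lru_cache(maxsize=None)
def distal_rates() -> pd.DataFrame:
    """Published class-conditional rates of binary distal outcomes."""
    with importlib.resources.as_file(_data_path("distal_rates.csv")) as p:
        return pd.read_csv(p).set_index("outcome")


@lru_cache(maxsize=None)
def scale_definitions() -> dict:
    """Scale battery definitions (item columns, ranges, screening cutoffs)."""
    with importlib.resources.as_file(_data_path("scales.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


def class_proportions() -> np.ndarray:
    """Published class proportions renormalized to sum exactly to 1."""
    pi = np.asarray(CLASS_PROPORTIONS_PRINTED, dtype=float)
    return pi / pi.sum()


def profile_matrix() -> np.ndarray:
    """The published rho as a (38, 5) array in catalog item order."""
    prof = class_profiles().sort_index()
    return prof[["rho1", "rho2", "rho3", "rho4", "rho5"]].to_numpy(float)


def indicator_items() -> list[int]:
    """Item ids of the 38 retained indicators, ascending."""
    return sorted(class_profiles().index.tolist())
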