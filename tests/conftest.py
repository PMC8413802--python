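"""Shared fixtures.

The expensive objects — the n=2000 synthetic survey generated from the
published class structure, its K=5 fit, and the full class enumeration —
are session-scoped so the recovery, diagnostics and distal tests share
one computation.
"""

import numpy as np
import pytest

import epiiprofiles as ep
from epiiprofiles import selection, tables

#: canonical fixed seed for the synthetic-recovery study (the package
#: default seed, declared once for all recovery fixtures)
RECOVERY_SEED = 0
RECOVERY_N = 2000


@pytest.fixture(scope="session")
def reference_params() -> ep.LCAParameters:
    """The published 5-class generator (pi renormalized, rho from print)."""
    return ep.LCAParameters(tables.class_proportions(), tables.profile_matrix())


@pytest.fixture(scope="session")
def synthetic_2000() -> ep.SyntheticDataset:
    return ep.generate_lca_data(ep.SyntheticConfig(n=RECOVERY_N, seed=RECOVERY_SEED))


@pytest.fixture(scope="session")
def enumeration_2000(synthetic_2000) -> selection.EnumerationResult:
    """Class enumeration K=1..7 with 50 starts on the n=2000 dataset."""
    Y = synthetic_2000.indicators.to_numpy(float)
    return selection.class_enumeration(
        Y, 7, ep.StartPolicy(n_starts=50, seed=RECOVERY_SEED))


@pytest.fixture(scope="session")
def fit5_aligned(enumeration_2000, reference_params) -> ep.FitResult:
    """The 5-class fit with labels aligned to the generator."""
    fit = enumeration_2000.fits[5]
    perm = ep.align_labels(fit.params, reference_params)
    return ep.apply_alignment(fit, perm)
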