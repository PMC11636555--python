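"""Shared fixtures.

The calibrated generator profile and the large verification cohort are
expensive (about ten seconds), so they are built once per session.  The
verification cohort uses a different seed than the calibration draws on
purpose: every distributional claim is checked out-of-sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scpi.generator import GeneratorProfile, calibrate_profile, generate_cohort
from scpi.scoring import score_cohort

CALIBRATION_SEED = 101
VERIFICATION_SEED = 424242
VERIFICATION_N = 50_000


@pytest.fixture(scope="session")
def calibrated_profile() -> GeneratorProfile:
    profile, cal = calibrate_profile(seed=CALIBRATION_SEED)
    assert cal.converged, cal.report()
    return profile


@pytest.fixture(scope="session")
def big_cohort(calibrated_profile) -> pd.DataFrame:
    """Scored verification cohort, n=50000, fresh seed."""
    cohort = generate_cohort(calibrated_profile, VERIFICATION_N, seed=VERIFICATION_SEED)
    return score_cohort(cohort)


@pytest.fixture()
def toy_cohort() -> pd.DataFrame:
    """Three complete rows with known patterns plus two outcome columns."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3],
            "item_1a": [1, 0, 0],
            "item_1b": [1, 0, 0],
            "item_1c": [1, 0, 0],
            "item_2a": [0, 0, 0],
            "item_2b": [0, 0, 1],
            "item_2c": [0, 0, 1],
            "hrqol_15d": [0.95, 0.80, 0.70],
            "bdi": [2.0, 6.0, 11.0],
        }
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
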