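"""Shared fixtures: small synthetic samples with known truth."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from spermflow.config import Thresholds
from spermflow.synthdata import (
    CasaTruth,
    KinematicComponent,
    MbbrTruth,
    ScsaTruth,
    simulate_scsa_events,
    simulate_stain_pair_mbbr,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_low_event_warnings():
    # small fixtures routinely acquire < 5000 events; the flag is exercised
    # explicitly in the gating tests
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*gated events.*")
        yield


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture
def scsa_sample(thresholds):
    truth = ScsaTruth()
    return simulate_scsa_events(truth, 5000, seed=101, thresholds=thresholds)


@pytest.fixture
def mbbr_pair(thresholds):
    truth = MbbrTruth()
    return simulate_stain_pair_mbbr(truth, 5000, seed=102, thresholds=thresholds)


@pytest.fixture
def separated_casa_truth() -> CasaTruth:
    """Three well-separated swimming patterns (slow-linear, fast-linear,
    fast-erratic) for clustering recovery tests."""
    comps = (
        KinematicComponent.from_velocities(
            40.0, 12.0, 22.0, alh=1.2, bcf=8.0, vcl_sigma=0.18, ratio_sigma=0.25
        ),
        KinematicComponent.from_velocities(
            150.0, 90.0, 110.0, alh=2.6, bcf=22.0, vcl_sigma=0.18, ratio_sigma=0.25
        ),
        KinematicComponent.from_velocities(
            140.0, 12.0, 65.0, alh=4.5, bcf=12.0, vcl_sigma=0.18, ratio_sigma=0.25
        ),
    )
    return CasaTruth(components=comps, weights=(0.3, 0.5, 0.2), immotile=0.0)


@pytest.fixture
def balanced_study_table() -> pd.DataFrame:
    """Balanced 6 boars x 2 ejaculates x 2 days response table with a known
    day shift and boar/unit random effects."""
    rng = np.random.default_rng(7)
    rows = []
    for b in range(6):
        bb = rng.normal(0, 1.0)
        for e in range(2):
            u = rng.normal(0, 0.5)
            for d, day in enumerate(("D0", "D11")):
                rows.append(
                    {
                        "boar": f"B{b:02d}",
                        "ejaculate": f"E{e}",
                        "day": day,
                        "y": bb + u + 1.5 * d + rng.normal(0, 1.0),
                    }
                )
    return pd.DataFrame(rows)
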