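"""Shared fixtures: acquisition defaults, AIF, phantoms and a large cohort."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gliomet import AcquisitionParams, build_phantom, default_aif, gb_like_phantom_spec
from gliomet.pipeline import RULE_FEATURES
from gliomet.synthetic import CohortSpec, default_cohort_spec, sample_feature_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

COHORT_SEED = 20260928


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def aif(acq):
    return default_aif(acq)


@pytest.fixture(scope="session")
def gb_phantom():
    """Noiseless GB-like phantom at the default 64 mm^3 geometry."""
    return build_phantom(gb_like_phantom_spec())


@pytest.fixture(scope="session")
def large_cohort():
    """2e5 cases per group of the three rule biomarkers (study-derived spec)."""
    full = default_cohort_spec()
    spec = CohortSpec(
        features={k: dict(v) for k, v in full.features.items() if k in RULE_FEATURES},
        n_gb=200_000,
        n_bm=200_000,
    )
    return sample_feature_cohort(spec, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Compact GB-like phantom geometry for faster image-domain tests."""
    import dataclasses

    spec = gb_like_phantom_spec()
    return dataclasses.replace(
        spec,
        grid_shape=(48, 48, 48),
        lesion_radius_mm=8.0,
        necrotic_core_radius_mm=3.0,
        edema_radius_mm=16.0,
    )
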