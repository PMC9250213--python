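import dataclasses

import numpy as np
import pytest

from csfclear.model import AssayErrorModel, DoseEvent, Observation, PKParameters, SubjectRecord
from csfclear.simulate import CohortConfig, default_study_config


@pytest.fixture
def bateman_params() -> PKParameters:
    """One-compartment parameters with an absorption lag of 1 h."""
    return PKParameters(ka=0.2, tlag=1.0, v=15.0, ke=0.462)


@pytest.fixture
def two_cpt_params() -> PKParameters:
    return PKParameters(ka=0.19, tlag=0.6, v=88.0, ke=0.462, kcp=2.8, kpc=0.9)


@pytest.fixture
def dose_500() -> DoseEvent:
    return DoseEvent(amount=500.0)


@pytest.fixture
def error_model() -> AssayErrorModel:
    return AssayErrorModel()


def make_subject(
    params: PKParameters,
    dose: DoseEvent,
    times,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "S1",
    group: str = "REF",
) -> SubjectRecord:
    """Subject whose observations lie on (or near) a known curve."""
    from csfclear.model import solve_profile

    conc = solve_profile(params, dose, np.asarray(times, dtype=float), params.structure)
    if noise_sd > 0:
        assert rng is not None
        conc = np.maximum(conc + rng.normal(0, noise_sd, conc.shape), 0.0)
    obs = tuple(Observation(time=float(t), concentration=float(c)) for t, c in zip(times, conc))
    return SubjectRecord(id=subject_id, group=group, dose=dose, observations=obs)


@pytest.fixture
def make_noisy_subject():
    return make_subject


def ref_only_config(n_subjects: int = 28, seed: int = 0, **overrides) -> CohortConfig:
    """A REF-group-only study configuration at the 0.5 mmol dose."""
    full = default_study_config(seed=seed)
    ref = next(g for g in full.groups if g.name == "REF")
    ref = dataclasses.replace(
        ref,
        n_subjects=n_subjects,
        dose_allocation={0.10: 0, 0.25: 0, 0.50: n_subjects},
    )
    return dataclasses.replace(full, groups=(ref,), seed=seed, **overrides)


@pytest.fixture
def ref_cohort_config():
    return ref_only_config
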