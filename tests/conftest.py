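import numpy as np
import pytest

from comorbmap import (
    ChildRecord,
    CohortTable,
    Education,
    Group,
    ImpairmentMatrix,
    SyntheticConfig,
    calibrate_loadings,
    generate_cohort,
)
from comorbmap.reference import reference_rates
from comorbmap.registry import DEFAULT_REGISTRY


def make_child(child_id="c1", group=Group.EPT, sex="M",
               education=Education.BACHELOR, brain_injury=False,
               morbidity=False, touwen=None, scores=None, aux=None):
    return ChildRecord(
        child_id=child_id, group=group, sex=sex, mother_education=education,
        brain_injury=brain_injury, morbidity=morbidity,
        touwen_domains=touwen, scores=scores or {}, aux_scores=aux or {})


def make_matrix(calls, observed=None, groups=None, domains=None):
    """Small impairment matrix over the first k registry domains."""
    calls = np.asarray(calls, dtype=bool)
    n, k = calls.shape
    if domains is None:
        domains = DEFAULT_REGISTRY.abbreviations[:k]
    if observed is None:
        observed = np.ones_like(calls, dtype=bool)
    if groups is None:
        groups = [Group.EPT] * n
    return ImpairmentMatrix(
        child_ids=[f"c{i}" for i in range(n)],
        domains=tuple(domains),
        calls=calls,
        observed=np.asarray(observed, dtype=bool),
        groups=np.array(groups, dtype=object),
        registry=DEFAULT_REGISTRY,
    )


@pytest.fixture(scope="session")
def calibration():
    """Generator parameters calibrated to the published marginal rates."""
    return calibrate_loadings(reference_rates())


@pytest.fixture(scope="session")
def calibrated_cohort_5000(calibration):
    """Large calibrated cohort for Monte-Carlo rate checks."""
    cfg = calibration.to_config(seed=20_001, n_ept=5000, n_term=5000,
                                missing_rate=0.0)
    return generate_cohort(cfg)


@pytest.fixture()
def small_cohort():
    cfg = SyntheticConfig(seed=42, n_ept=8, n_term=6, missing_rate=0.15)
    return generate_cohort(cfg)
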