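import numpy as np
import pytest

from clonalpgs import (CloneModel, DiagnosisThresholds, SimTruth, TraitSpec,
                       simulate_study)
from scipy.special import logit


@pytest.fixture(scope="session")
def small_truth() -> SimTruth:
    """A small but non-degenerate study: two traits, visible clone selection."""
    return SimTruth(
        m_variants=80, n_individuals=6000, maf_range=(0.1, 0.5),
        ld_block_size=10, ld_rho=0.3,
        traits=[TraitSpec("PCT", 40, 0.4), TraitSpec("HGB", 30, 0.3)],
        clone_model=CloneModel(alpha0=float(logit(0.05)), alpha1=0.5),
        diagnosis_thresholds=DiagnosisThresholds(et_trait="PCT", et_cut=2.2,
                                                 pv_trait="HGB", pv_cut=2.4,
                                                 clone_boost=2.0, mf_frac=0.1),
        seed=11)


@pytest.fixture(scope="session")
def small_study(small_truth):
    return simulate_study(small_truth)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
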