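import numpy as np
import pandas as pd
import pytest

from symclass.syndata import (
    EffectSpec,
    ModalityEffect,
    default_factor_spec,
    generate_cohort,
    generate_symptoms,
)


@pytest.fixture(scope="session")
def spec():
    return default_factor_spec()


@pytest.fixture(scope="session")
def symptoms_large(spec):
    """Big sample for parameter-recovery checks."""
    X, scores = generate_symptoms(spec, 5000, seed=11)
    return X, scores


@pytest.fixture(scope="session")
def symptoms_study(spec):
    """Study-scale sample (n=362) without dominance enforcement."""
    X, scores = generate_symptoms(spec, 362, seed=23)
    return X, scores


@pytest.fixture(scope="session")
def two_class_cohort():
    """200 subjects, 2 classes, strong planted signal on 10 of 100 features."""
    eff = EffectSpec(
        {"m1": ModalityEffect(100, affected_fraction=0.1, effect_size=2.0)},
        n_sites=1,
    )
    return generate_cohort(["A"] * 100 + ["B"] * 100, eff, n_hc=0, seed=31)


@pytest.fixture(scope="session")
def null_cohort():
    """200 subjects, 2 classes, no effect anywhere."""
    eff = EffectSpec(
        {"m1": ModalityEffect(20, affected_fraction=0.0, effect_size=0.0)},
        n_sites=1,
    )
    return generate_cohort(["A"] * 100 + ["B"] * 100, eff, n_hc=0, seed=37)


def rng_matrix(seed, n, p):
    return np.random.default_rng(seed).standard_normal((n, p))
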