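"""Shared fixtures: one small docked peptide-DNA complex (built once per
session) plus its minimized form, and a synthetic feature dataset."""

import numpy as np
import pytest

from dnabind.forcefield import minimize
from dnabind.synthetic import (
    FixtureSpec, build_toy_complex, generate_feature_dataset,
)

TOY_SPEC = FixtureSpec(dna_sequence="GCGATCGC", peptide_sequence="GRKSA",
                       seed=0)


@pytest.fixture(scope="session")
def toy_complex():
    """Protonated docked peptide-DNA complex with partners assigned."""
    return build_toy_complex(TOY_SPEC)


@pytest.fixture(scope="session")
def wild_min(toy_complex):
    """The toy complex after restrained minimization."""
    structure, trace = minimize(toy_complex)
    structure._energy_trace = trace   # stashed for minimization tests
    return structure


@pytest.fixture(scope="session")
def synth_dataset():
    """219-row synthetic feature/ddG table over 49 complexes."""
    return generate_feature_dataset(n=219, noise_sd=0.86, n_complexes=49,
                                    seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
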