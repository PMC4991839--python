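"""Shared fixtures: representative cell, synthetic recordings, basin mask.

Everything is generated programmatically with fixed seeds; session scope is
used for the expensive simulations so many tests can share them.
"""

import numpy as np
import pytest

import isrtools as it


@pytest.fixture(scope="session")
def rep():
    """The representative Purkinje-cell parameter set."""
    return it.representative_cell()


@pytest.fixture(scope="session")
def bundle():
    """Synthetic fixture bundle for the fitting pipeline."""
    return it.fixture_suite(seed=5)


@pytest.fixture(scope="session")
def rep_fit(bundle):
    """Full dynamic-IV fit of the representative synthetic recording."""
    params, report = it.fit_full(bundle["dyniv_noise"], bundle["pulse"])
    return params, report, bundle["spec"].params


@pytest.fixture(scope="session")
def basin150(rep):
    """Rest-state basin of the representative cell at I = -150 pA."""
    return it.rest_basin(rep, -150.0)


@pytest.fixture(scope="session")
def type1_params(rep):
    """A type I variant (weak subthreshold adaptation)."""
    p = rep.with_(a=2.0)
    assert it.classify_excitability(p) == "type_I"
    return p
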