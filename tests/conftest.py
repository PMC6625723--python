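import numpy as np
import pytest

from dediff import DedifferentiationSpec, HierarchyParams, named_fixture


@pytest.fixture
def fig6a_r03():
    """Fig 6a parameter set with r1 = 0.3 (leading compartment 3)."""
    params, spec = named_fixture("fig6a").bind(r1=0.3, kappa=1.0)
    return params, spec


@pytest.fixture
def simple_n3():
    """Three-compartment tissue with diagonal (0.2, -0.2, -1)."""
    return HierarchyParams(n=3, r=(1.0, 1.0), p=(0.6, 0.4), q=(0.4, 0.6), d=1.0)


def all_bound_fixtures():
    """Every named figure fixture, free parameters bound midrange."""
    from dediff import list_fixtures

    out = []
    for name in list_fixtures():
        params, spec = named_fixture(name).bind()
        out.append((name, params, spec))
    return out
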