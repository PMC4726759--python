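import numpy as np
import pytest

from cmekit.fixtures import make_fixture


@pytest.fixture(scope="session")
def birth_death():
    return make_fixture("birth_death")


@pytest.fixture(scope="session")
def dimerization():
    return make_fixture("dimerization")


@pytest.fixture(scope="session")
def three_stage():
    return make_fixture("three_stage_gene_expression")


@pytest.fixture(scope="session")
def timedep_birth():
    return make_fixture("timedep_birth")


@pytest.fixture(scope="session")
def two_compartment_chain():
    return make_fixture("two_compartment_chain")


def bd_exact_mean(t, k=10.0, gamma=1.0):
    """Closed-form mean (= variance) of the birth–death network from x0=0."""
    return k / gamma * (1.0 - np.exp(-gamma * np.asarray(t, dtype=float)))


@pytest.fixture(scope="session")
def three_stage_fsp_reference(three_stage):
    """Session-cached FSP oracle for the gene-expression fixture."""
    from cmekit.fsp import enumerate_states, fsp_moments, solve_fsp

    t_grid = np.linspace(0.0, 100.0, 21)
    space = enumerate_states(three_stage, {"M": 14, "P": 120})
    sol = solve_fsp(three_stage, space, t_grid)
    return sol, fsp_moments(sol, 2)
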