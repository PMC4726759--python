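"""Moment equations, closures, RRE and trajectory statistics."""

import numpy as np
import pytest
import sympy as sp

from cmekit.moments import (
    CLOSURES,
    ClosureError,
    MomentTrajectory,
    apply_closure,
    correlation_maps,
    derive_moment_equations,
    derive_rre,
    mean_symbol,
    moment_indices,
    moment_state_count,
    raw_in_central,
    raw_symbol,
    simulate_moments,
)
from conftest import bd_exact_mean

T_GRID = [0.0, 0.5, 1.0, 5.0, 30.0]
SCHEMES = [s for s in CLOSURES if s != "user"]


# ---------------------------------------------------------------------------
# RRE
# ---------------------------------------------------------------------------

def test_rre_birth_death(birth_death):
    sys = derive_rre(birth_death)
    X, k, gamma = sp.symbols("X k gamma")
    assert sp.simplify(sys.rhs[0] - (k - gamma * X)) == 0


def test_rre_dimerization_macroscopic_limit(dimerization):
    sys = derive_rre(dimerization)
    X, k1, k2 = sp.symbols("X k1 k2")
    assert sp.simplify(sys.rhs[0] - (k1 - 2 * k2 * X ** 2)) == 0


def test_rre_zero_propensity_network():
    from cmekit.network import Reaction, ReactionNetwork, Species

    net = ReactionNetwork([Species("X")], [Reaction({}, {"X": 1}, sp.Integer(0))], {})
    assert derive_rre(net).rhs == [sp.Integer(0)]


# ---------------------------------------------------------------------------
# derivation
# ---------------------------------------------------------------------------

def test_birth_death_raw_m2_equations(birth_death):
    sysm = derive_moment_equations(birth_death, 2)
    k, gamma = sp.symbols("k gamma")
    m1, m2 = raw_symbol((1,)), raw_symbol((2,))
    d1, d2 = sysm.symbolic.rhs
    assert sp.simplify(d1 - (k - gamma * m1)) == 0
    assert sp.simplify(d2 - (k + (2 * k + gamma) * m1 - 2 * gamma * m2)) == 0


def test_birth_death_central_m2_equations(birth_death):
    sysc = derive_moment_equations(birth_death, 2, kind="central_plus_mean")
    k, gamma = sp.symbols("k gamma")
    mu = mean_symbol(0, 1)
    c2 = sp.Symbol("c_2")
    dmu, dc2 = sysc.symbolic.rhs
    assert sp.simplify(dmu - (k - gamma * mu)) == 0
    assert sp.simplify(dc2 - (k + gamma * mu - 2 * gamma * c2)) == 0


@pytest.mark.parametrize("m", [1, 2, 3])
def test_raw_and_central_derivations_interconvert(three_stage, m):
    """Converting the raw system into central variables must reproduce the
    independently derived central system, symbolically."""
    raw = derive_moment_equations(three_stage, m)
    cen = derive_moment_equations(three_stage, m, kind="central_plus_mean")
    n = three_stage.n_species
    # map raw symbols to their central expressions
    conv = {}
    for idx in moment_indices(n, m + 2):
        if sum(idx) >= 2:
            conv[raw_symbol(idx)] = raw_in_central(idx)
    cen_rhs = {str(s): sp.expand(r) for s, r in
               zip(cen.symbolic.state_symbols, cen.symbolic.rhs)}
    # mean equations: convert raw mean RHS and compare
    for i in range(n):
        got = sp.expand(sp.sympify(raw.symbolic.rhs[i]).xreplace(conv))
        want = cen_rhs[str(mean_symbol(i, n))]
        assert sp.simplify(got - want) == 0


def test_linear_network_closes_exactly(birth_death):
    for m in (1, 2, 3, 4):
        sysm = derive_moment_equations(birth_death, m)
        assert sysm.higher_order_symbols == []


def test_moment_state_count_matches_combinatorics():
    for n_s, m in [(1, 2), (2, 3), (4, 2), (4, 4), (8, 2)]:
        assert len(moment_indices(n_s, m)) == moment_state_count(n_s, m)


def test_non_polynomial_propensity_needs_expansion_request():
    from cmekit.network import Reaction, ReactionNetwork, Species

    X, v, K = sp.symbols("X v K")
    net = ReactionNetwork([Species("X")],
                          [Reaction({}, {"X": 1}, v * X / (K + X))],
                          {"v": 1.0, "K": 5.0})
    with pytest.raises(ValueError, match="taylor_order"):
        derive_moment_equations(net, 2)
    sysm = derive_moment_equations(net, 2, taylor_order=2)
    assert sysm.symbolic.n == 2


# ---------------------------------------------------------------------------
# closures
# ---------------------------------------------------------------------------

def test_low_dispersion_m2_dimerization(dimerization):
    closed = apply_closure(derive_moment_equations(dimerization, 2), "low_dispersion")
    m1, m2 = raw_symbol((1,)), raw_symbol((2,))
    got = sp.sympify(closed.closure_map["m_3"])
    assert sp.simplify(got - (3 * m1 * m2 - 2 * m1 ** 3)) == 0


def test_zero_cumulants_gaussian_third_moment(dimerization):
    closed = apply_closure(derive_moment_equations(dimerization, 2), "zero_cumulants")
    m1, m2 = raw_symbol((1,)), raw_symbol((2,))
    # <x^3> = 3 mu sigma^2 + mu^3 = 3 m1 m2 - 2 m1^3
    got = sp.sympify(closed.closure_map["m_3"])
    assert sp.simplify(got - (3 * m1 * m2 - 2 * m1 ** 3)) == 0


def test_mean_field_peels_first_species(dimerization):
    closed = apply_closure(derive_moment_equations(dimerization, 2), "mean_field")
    m1, m2 = raw_symbol((1,)), raw_symbol((2,))
    assert sp.simplify(sp.sympify(closed.closure_map["m_3"]) - m1 * m2) == 0


def test_derivative_matching_exponents(dimerization):
    closed = apply_closure(derive_moment_equations(dimerization, 2),
                           "derivative_matching")
    m1, m2 = raw_symbol((1,)), raw_symbol((2,))
    assert sp.simplify(sp.sympify(closed.closure_map["m_3"]) - m2 ** 3 / m1 ** 3) == 0


def test_user_closure_and_missing_symbol_error(dimerization):
    unclosed = derive_moment_equations(dimerization, 2)
    closed = apply_closure(unclosed, "user", {(3,): raw_symbol((1,)) ** 3})
    assert closed.higher_order_symbols == []
    with pytest.raises(ClosureError, match="unresolved"):
        apply_closure(unclosed, "user", {})


def test_closure_on_linear_network_is_identity(birth_death):
    unclosed = derive_moment_equations(birth_death, 2)
    for scheme in SCHEMES:
        closed = apply_closure(unclosed, scheme)
        assert closed.closure_map == {}
        for a, b in zip(closed.symbolic.rhs, unclosed.symbolic.rhs):
            assert sp.expand(a - b) == 0


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("m", [1, 2, 3, 4])
@pytest.mark.parametrize("scheme", SCHEMES)
def test_linear_exactness_all_orders_and_closures(birth_death, m, scheme):
    closed = apply_closure(derive_moment_equations(birth_death, m), scheme)
    traj = simulate_moments(closed, T_GRID, birth_death.parameters)
    exact = bd_exact_mean(T_GRID)
    assert np.max(np.abs(traj.mean("X")[1:] - exact[1:]) / exact[1:]) < 1e-6
    if m >= 2:
        assert np.max(np.abs(traj.variance("X")[1:] - exact[1:]) / exact[1:]) < 1e-6


def test_zero_rate_zero_state_stays_zero(birth_death):
    closed = apply_closure(derive_moment_equations(birth_death, 2), "low_dispersion")
    traj = simulate_moments(closed, [0.0, 1.0, 10.0], {"k": 0.0, "gamma": 1.0})
    assert np.allclose(traj.means, 0.0) and np.allclose(traj.variance("X"), 0.0)


def test_dimerization_mm2_against_fsp_oracle(dimerization):
    from cmekit.fsp import enumerate_states, fsp_moments, solve_fsp

    closed = apply_closure(derive_moment_equations(dimerization, 2), "low_dispersion")
    traj = simulate_moments(closed, [0.0, 10.0], dimerization.parameters)
    space = enumerate_states(dimerization, {"X": 200})
    ref = fsp_moments(solve_fsp(dimerization, space, [0.0, 10.0]), 2)
    rel = abs(traj.mean("X")[-1] - ref.mean("X")[-1]) / ref.mean("X")[-1]
    assert rel < 0.05


def test_concentration_units_rescale(birth_death):
    from cmekit.network import Compartment, ReactionNetwork

    net = ReactionNetwork(
        species=birth_death.species, reactions=birth_death.reactions,
        parameters=birth_death.parameters,
        compartments=[Compartment("default", 2.0)], name="bd2")
    sysm = derive_moment_equations(net, 2, units="concentrations")
    traj = simulate_moments(sysm, [0.0, 30.0], net.parameters)
    # concentration mean = count mean / volume
    assert traj.mean("X")[-1] == pytest.approx(10.0 / 2.0, rel=1e-6)


# ---------------------------------------------------------------------------
# correlation maps
# ---------------------------------------------------------------------------

def _toy_traj(cov_matrices):
    n = cov_matrices[0].shape[0]
    names = [f"s{i}" for i in range(n)]
    central = {}
    for i in range(n):
        for j in range(i, n):
            idx = [0] * n
            idx[i] += 1
            idx[j] += 1
            central[tuple(idx)] = np.array([C[i, j] for C in cov_matrices])
    return MomentTrajectory(
        times=np.arange(len(cov_matrices), dtype=float), species_names=names,
        means=np.zeros((len(cov_matrices), n)), central=central)


def test_correlation_diagonal_covariance_gives_identity():
    maps = correlation_maps(_toy_traj([np.diag([2.0, 3.0])]))
    assert np.allclose(maps["correlation"][0], np.eye(2))


def test_partial_correlation_two_species_closed_form():
    C = np.array([[2.0, 0.8], [0.8, 1.5]])
    maps = correlation_maps(_toy_traj([C]))
    rho = C[0, 1] / np.sqrt(C[0, 0] * C[1, 1])
    assert maps["correlation"][0][0, 1] == pytest.approx(rho)
    # for two species the partial correlation equals the correlation
    assert maps["partial_correlation"][0][0, 1] == pytest.approx(rho, rel=1e-10)


def test_zero_variance_entries_reported_absent():
    maps = correlation_maps(_toy_traj([np.diag([2.0, 0.0])]))
    assert np.isnan(maps["correlation"][0][0, 1])


def test_three_stage_mrna_protein_positively_correlated(three_stage):
    from cmekit.sse import derive_sse, simulate_sse

    traj = simulate_sse(derive_sse(three_stage, "LNA"), [0.0, 10.0],
                        three_stage.parameters)
    maps = correlation_maps(traj)
    i, j = traj.species_names.index("M"), traj.species_names.index("P")
    assert maps["correlation"][-1][i, j] > 0


def test_trajectory_flags_not_silently_clipped():
    traj = _toy_traj([np.diag([-1.0, 1.0])])
    traj.check_flags()
    assert traj.flags["negative_variance"] == ["s0"]
    assert traj.central[(2, 0)][0] == -1.0  # value left untouched
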