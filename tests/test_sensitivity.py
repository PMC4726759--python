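"""Forward/adjoint sensitivities and least-squares gradients."""

import numpy as np
import pytest
import sympy as sp

from cmekit.moments import (
    apply_closure,
    derive_moment_equations,
    derive_rre,
    mean_symbol,
)
from cmekit.sensitivity import (
    Objective,
    derive_adjoint,
    derive_forward_sensitivities,
    gradient,
    objective_value,
    _eval_objective,
    _observable_fns,
)
from cmekit.symbolic import SymbolicSystem, compile_system, integrate


@pytest.fixture(scope="module")
def bd_rre(birth_death):
    return derive_rre(birth_death)


def _mm2_objective(net, times, theta_data, order=2):
    """Synthetic data generated from the model itself at theta_data."""
    msys = apply_closure(derive_moment_equations(net, order), "low_dispersion")
    n = net.n_species
    mean_subs = {s: mean_symbol(i, n) for i, s in enumerate(net.species_symbols)}
    obs = [sp.sympify(o.expression).subs(mean_subs, simultaneous=True)
           for o in net.observables]
    dummy = Objective(obs, times, np.zeros((len(times), len(obs))))
    _, sol, _, tv = _eval_objective(msys.symbolic, dummy, theta_data)
    fns = _observable_fns(msys.symbolic, obs)
    data = np.array([[fn(t, *sol[k + 1], *tv) for fn in fns]
                     for k, t in enumerate(times)])
    return msys.symbolic, Objective(obs, times, data)


def test_birth_death_sensitivity_closed_form(bd_rre):
    """For x' = k − γx, s_k(t) = (1 − e^{−γt})/γ."""
    sens = derive_forward_sensitivities(bd_rre, ["k"])
    sol = integrate(compile_system(sens.augmented), [0.0, 1.0, 5.0],
                    {"k": 10, "gamma": 1})
    for t, row in zip([1.0, 5.0], sol[1:]):
        assert row[1] == pytest.approx((1 - np.exp(-t)) / 1.0, rel=1e-7)


def test_absent_parameter_zero_sensitivity(bd_rre):
    X, k, gamma, unused = sp.symbols("X k gamma unused")
    sys = SymbolicSystem([X], [k - gamma * X], [sp.Integer(0)], [k, gamma, unused])
    sens = derive_forward_sensitivities(sys, ["unused"])
    sol = integrate(compile_system(sens.augmented), [0.0, 3.0],
                    {"k": 10, "gamma": 1, "unused": 5})
    assert np.allclose(sol[:, 1], 0.0)


def test_augmented_dimension_is_n_times_one_plus_ntheta():
    syms = sp.symbols("x0:5")
    ps = sp.symbols("p0:3")
    sys = SymbolicSystem(list(syms), [p * s for p, s in zip(list(ps) * 2, syms)],
                         [sp.Integer(1)] * 5, list(ps))
    sens = derive_forward_sensitivities(sys, order=1)
    assert sens.augmented.n == 5 * (1 + 3) == 20


def test_second_order_dimension_and_symmetry(bd_rre):
    sens = derive_forward_sensitivities(bd_rre, ["k", "gamma"], order=2)
    # n(1 + nθ + nθ(nθ+1)/2) = 1 * (1 + 2 + 3)
    assert sens.augmented.n == 6
    sol = integrate(compile_system(sens.augmented), [0.0, 2.0], {"k": 10, "gamma": 1})
    # parameter-order symmetry: derive with the reversed parameter list
    rev = derive_forward_sensitivities(bd_rre, ["gamma", "k"], order=2)
    sol_r = integrate(compile_system(rev.augmented), [0.0, 2.0], {"k": 10, "gamma": 1})
    s2_kg = sol[-1, sens.block_index[("s2", 0, 0, 1)]]
    s2_gk = sol_r[-1, rev.block_index[("s2", 0, 0, 1)]]
    assert s2_kg == pytest.approx(s2_gk, rel=1e-7)


def test_second_order_matches_finite_difference_of_first(bd_rre):
    sens2 = derive_forward_sensitivities(bd_rre, ["k", "gamma"], order=2)
    sol = integrate(compile_system(sens2.augmented), [0.0, 2.0], {"k": 10, "gamma": 1})
    got = sol[-1, sens2.block_index[("s2", 0, 0, 1)]]
    # FD oracle on the first-order sensitivity wrt gamma
    sens1 = derive_forward_sensitivities(bd_rre, ["k"], order=1)
    h = 1e-6

    def s_k(gv):
        s = integrate(compile_system(sens1.augmented), [0.0, 2.0],
                      {"k": 10, "gamma": gv}, tol=(1e-12, 1e-14))
        return s[-1, 1]

    fd = (s_k(1 + h) - s_k(1 - h)) / (2 * h)
    assert got == pytest.approx(fd, rel=1e-5)


def test_dae_mass_matrix_propagates_to_blocks():
    x, z, p = sp.symbols("x z p")
    sys = SymbolicSystem([x, z], [p - x, x - z], [sp.Integer(0), sp.Integer(0)],
                         [p], kind="dae", mass_matrix=sp.diag(1, 0))
    sens = derive_forward_sensitivities(sys, ["p"])
    mm = sp.Matrix(sens.augmented.mass_matrix)
    assert [mm[i, i] for i in range(4)] == [1, 0, 1, 0]


def test_adjoint_rejects_dae():
    x, z, p = sp.symbols("x z p")
    sys = SymbolicSystem([x, z], [p - x, x - z], [sp.Integer(0), sp.Integer(0)],
                         [p], kind="dae", mass_matrix=sp.diag(1, 0))
    obj = Objective([x], [1.0], [[0.0]])
    with pytest.raises(ValueError, match="ODE"):
        derive_adjoint(sys, obj)


def test_adjoint_dimension_independent_of_ntheta(bd_rre):
    obj = Objective([sp.Symbol("X")], [1.0], [[5.0]])
    adj = derive_adjoint(bd_rre, obj)
    assert adj.adjoint_dimension == bd_rre.n == 1


def test_adjoint_equals_forward_single_datum(bd_rre):
    obj = Objective([sp.Symbol("X")], [1.0], [[5.0]], weights=2.0)
    gF, vF = gradient(obj, bd_rre, {"k": 10, "gamma": 1}, "forward")
    gA, vA = gradient(obj, bd_rre, {"k": 10, "gamma": 1}, "adjoint")
    assert vF == pytest.approx(vA, rel=1e-9)
    assert np.max(np.abs(gF - gA) / np.abs(gF)) < 1e-8


def test_zero_residual_objective_zero_gradient(bd_rre):
    mu = 10 * (1 - np.exp(-np.array([0.5, 2.0])))
    obj = Objective([sp.Symbol("X")], [0.5, 2.0], mu[:, None])
    for method in ("forward", "adjoint"):
        g, v = gradient(obj, bd_rre, {"k": 10, "gamma": 1}, method)
        assert v < 1e-12
        assert np.linalg.norm(g) < 1e-6


@pytest.mark.parametrize("base", ["rre", "lna", "mm2", "mm3"])
def test_forward_adjoint_duality_across_descriptions(birth_death, base):
    if base == "rre":
        sys = derive_rre(birth_death)
        obs = [sp.Symbol("X")]
    elif base == "lna":
        from cmekit.sse import _OMEGA_FROZEN, derive_sse

        sse = derive_sse(birth_death, "LNA")
        sys = sse.symbolic
        obs = [sp.Symbol("sse_phi_X") + sp.Symbol("sse_S0_0_0")]
    else:
        order = int(base[-1])
        sys = apply_closure(derive_moment_equations(birth_death, order),
                            "low_dispersion").symbolic
        obs = [mean_symbol(0, 1)]
    theta = {str(p): v for p, v in
             zip(sys.parameter_symbols,
                 [10.0, 1.0, 1.0][:len(sys.parameter_symbols)])}
    obj = Objective(obs, [0.5, 1.5], [[3.0], [6.0]])
    gF, _ = gradient(obj, sys, theta, "forward")
    gA, _ = gradient(obj, sys, theta, "adjoint")
    assert np.max(np.abs(gF - gA) / np.maximum(np.abs(gF), 1e-10)) < 1e-6


def test_three_method_agreement_on_chain_mm2(two_compartment_chain):
    times = np.array([5.0, 10.0, 20.0, 30.0])
    sys, obj = _mm2_objective(two_compartment_chain, times,
                              two_compartment_chain.parameters)
    theta = {k: v * 1.15 for k, v in two_compartment_chain.parameters.items()}
    gF, vF = gradient(obj, sys, theta, "forward")
    gA, vA = gradient(obj, sys, theta, "adjoint")
    gD, vD = gradient(obj, sys, theta, "finite_differences")
    assert vF == pytest.approx(vA, rel=1e-8)
    assert np.max(np.abs(gF - gA) / np.abs(gF)) < 1e-6
    assert np.max(np.abs(gF - gD) / np.abs(gF)) < 1e-4


def test_forward_gradient_against_five_point_stencil(bd_rre):
    obj = Objective([sp.Symbol("X")], [1.0, 3.0], [[4.0], [8.0]])
    gF, _ = gradient(obj, bd_rre, {"k": 10, "gamma": 1}, "forward",
                     theta_subset=["k"])

    def f(kv):
        return objective_value(obj, bd_rre, {"k": kv, "gamma": 1},
                               tol=(1e-12, 1e-14))

    h = 1e-3
    stencil = (f(10 - 2 * h) - 8 * f(10 - h) + 8 * f(10 + h)
               - f(10 + 2 * h)) / (12 * h)
    assert gF[0] == pytest.approx(stencil, rel=1e-6)


def test_structural_work_scaling(bd_rre):
    """Adjoint state count stays n as n_θ grows; forward grows affinely."""
    obj = Objective([sp.Symbol("X")], [1.0], [[5.0]])
    adj = derive_adjoint(bd_rre, obj)
    assert adj.adjoint_dimension == 1
    dims = [derive_forward_sensitivities(bd_rre, sub).augmented.n
            for sub in (["k"], ["k", "gamma"])]
    assert dims == [2, 3]
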