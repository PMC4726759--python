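"""Conditional moments: partitioning, derivation, degenerate equivalences."""

import numpy as np
import pytest
import sympy as sp

from cmekit.fixtures import make_fixture
from cmekit.fsp import enumerate_states, marginalize, solve_fsp
from cmekit.mcm import (
    Partition,
    derive_mcm,
    partition_species,
    reconstruct_overall_moments,
    simulate_mcm,
)
from cmekit.moments import apply_closure, derive_moment_equations, simulate_moments
from cmekit.symbolic import compile_system, integrate


@pytest.fixture(scope="module")
def ts_partition(three_stage):
    return partition_species(three_stage, "auto")


def test_auto_partition_three_stage(three_stage, ts_partition):
    assert ts_partition.low_copy == ["G_off", "G_on"]
    assert ts_partition.high_copy == ["M", "P"]


def test_auto_partition_fails_without_finite_range(birth_death):
    with pytest.raises(ValueError, match="manual"):
        partition_species(birth_death, "auto")


def test_manual_partition_with_bound(birth_death):
    part = partition_species(birth_death, "manual",
                             {"low_copy": ["X"], "bounds": {"X": 20}})
    assert part.low_copy == ["X"] and part.bounds["X"] == 20
    sys = derive_mcm(birth_death, part, 0)
    assert sys.n_modes == 21


def test_three_stage_m2_state_count(three_stage, ts_partition):
    sys = derive_mcm(three_stage, ts_partition, 2)
    # 2 modes x (1 probability + 2 conditional means + 3 second moments)
    assert len(sys.symbolic.state_symbols) == 12


def test_probability_subsystem_conserves_mass_symbolically(three_stage, ts_partition):
    sys = derive_mcm(three_stage, ts_partition, 2)
    zero = sys.indices[0]
    total = sum(sp.sympify(sys.symbolic.rhs[sys.state_pos[(r, zero)]])
                for r in range(sys.n_modes))
    assert sp.expand(total) == 0


def test_marginal_probabilities_sum_to_one(three_stage, ts_partition):
    sys = derive_mcm(three_stage, ts_partition, 2)
    res = simulate_mcm(sys, np.linspace(0, 100, 21), three_stage.parameters)
    assert np.abs(res.marginal().sum(axis=1) - 1.0).max() < 1e-6


def test_promoter_marginal_matches_fsp(three_stage, ts_partition,
                                       three_stage_fsp_reference):
    sol, _ = three_stage_fsp_reference
    sys = derive_mcm(three_stage, ts_partition, 3)
    res = simulate_mcm(sys, sol.times, three_stage.parameters)
    states, probs = marginalize(sol, ["G_off", "G_on"])
    fsp_cols = {tuple(s): i for i, s in enumerate(states)}
    for r, mode in enumerate(sys.modes):
        dev = np.abs(res.marginal()[:, r] - probs[:, fsp_cols[mode]]).max()
        assert dev < 0.01


def test_reconstructed_protein_mean_matches_fsp(three_stage, ts_partition,
                                                three_stage_fsp_reference):
    _, ref = three_stage_fsp_reference
    sys = derive_mcm(three_stage, ts_partition, 3)
    res = simulate_mcm(sys, ref.times, three_stage.parameters)
    traj = reconstruct_overall_moments(res)
    rel = np.abs(traj.mean("P")[1:] - ref.mean("P")[1:]) / ref.mean("P")[1:]
    assert rel.max() < 0.02


def test_order_three_at_least_as_accurate_as_order_two(three_stage, ts_partition,
                                                       three_stage_fsp_reference):
    _, ref = three_stage_fsp_reference
    errs = {}
    for m in (2, 3):
        sys = derive_mcm(three_stage, ts_partition, m)
        res = simulate_mcm(sys, ref.times, three_stage.parameters)
        traj = reconstruct_overall_moments(res)
        errs[m] = abs(traj.mean("P")[-1] - ref.mean("P")[-1]) / ref.mean("P")[-1]
    assert errs[3] <= errs[2]


def test_empty_high_copy_reduces_to_fsp():
    """Promoter-only network: the hybrid system IS the mode-space CME."""
    from cmekit.network import Reaction, ReactionNetwork, Species

    g_off, g_on, a, b = sp.symbols("G_off G_on a b")
    net = ReactionNetwork(
        species=[Species("G_off", initial_amount=1), Species("G_on")],
        reactions=[Reaction({"G_off": 1}, {"G_on": 1}, a * g_off),
                   Reaction({"G_on": 1}, {"G_off": 1}, b * g_on)],
        parameters={"a": 0.3, "b": 0.7})
    part = partition_species(net, "auto")
    assert part.high_copy == []
    sys = derive_mcm(net, part, 2)
    res = simulate_mcm(sys, [0.0, 1.0, 5.0], net.parameters)
    sol = solve_fsp(net, enumerate_states(net, {}), [0.0, 1.0, 5.0])
    cols = [sol.space.index[y] for y in sys.modes]
    assert np.abs(res.marginal() - sol.p[:, cols]).max() < 1e-7


@pytest.mark.parametrize("closure", ["low_dispersion", "zero_cumulants"])
def test_empty_low_copy_reduces_to_moment_equations(dimerization, closure):
    part = Partition(low_copy=[], high_copy=["X"], bounds={})
    sys = derive_mcm(dimerization, part, 2, closure)
    res = simulate_mcm(sys, [0.0, 5.0, 10.0], dimerization.parameters)
    traj = reconstruct_overall_moments(res)
    mm = simulate_moments(
        apply_closure(derive_moment_equations(dimerization, 2), closure),
        [0.0, 5.0, 10.0], dimerization.parameters)
    assert np.allclose(traj.mean("X"), mm.mean("X"), rtol=1e-7)
    assert np.allclose(traj.variance("X"), mm.variance("X"), rtol=1e-6, atol=1e-9)


def test_frozen_promoter_conditional_equals_unconditional(three_stage):
    """With switching off and the promoter started on, the single active
    mode's conditional moments are the plain moment equations of the
    reduced network."""
    net = make_fixture("three_stage_gene_expression",
                       {"tau_on": 0.0, "tau_off": 0.0, "tau_fb": 0.0,
                        "G_off_0": 0, "G_on_0": 1})
    part = partition_species(net, "auto")
    sys = derive_mcm(net, part, 2)
    res = simulate_mcm(sys, [0.0, 5.0, 20.0], net.parameters)
    on_row = sys.modes.index((0, 1))
    traj = reconstruct_overall_moments(res)
    assert np.allclose(res.marginal()[:, on_row], 1.0, atol=1e-9)
    assert np.allclose(res.conditional_mean("M", on_row), traj.mean("M"),
                       rtol=1e-8)


def test_initial_condition_point_mass(three_stage, ts_partition):
    sys = derive_mcm(three_stage, ts_partition, 2)
    res = simulate_mcm(sys, [0.0], three_stage.parameters)
    off_row = sys.modes.index((1, 0))
    assert res.marginal()[0, off_row] == 1.0
    assert res.conditional_variance("P", off_row)[0] == 0.0


def test_empty_mode_reported_absent(three_stage, ts_partition):
    sys = derive_mcm(three_stage, ts_partition, 2)
    res = simulate_mcm(sys, [0.0], three_stage.parameters)
    on_row = sys.modes.index((0, 1))
    assert np.isnan(res.conditional_mean("P", on_row)[0])


def test_total_variance_decomposition_degenerate():
    """Two modes with equal conditional means: between-mode variance term
    vanishes, overall mean equals the common conditional mean."""
    # symmetric switching, transcription in both modes at the same rate
    g_off, g_on, m, a, km, gm = sp.symbols("G_off G_on M a k_m gamma_m")
    from cmekit.network import Reaction, ReactionNetwork, Species

    net = ReactionNetwork(
        species=[Species("G_off", initial_amount=1), Species("G_on"), Species("M")],
        reactions=[
            Reaction({"G_off": 1}, {"G_on": 1}, a * g_off),
            Reaction({"G_on": 1}, {"G_off": 1}, a * g_on),
            Reaction({}, {"M": 1}, km * (g_off + g_on)),
            Reaction({"M": 1}, {}, gm * m)],
        parameters={"a": 1.0, "k_m": 5.0, "gamma_m": 1.0})
    part = partition_species(net, "auto")
    sys = derive_mcm(net, part, 2)
    res = simulate_mcm(sys, [0.0, 10.0], net.parameters)
    traj = reconstruct_overall_moments(res)
    rows = range(sys.n_modes)
    cond_means = [res.conditional_mean("M", r)[-1] for r in rows]
    assert cond_means[0] == pytest.approx(cond_means[1], rel=1e-6)
    assert traj.mean("M")[-1] == pytest.approx(cond_means[0], rel=1e-6)
    # M decouples from the promoter: Poisson, total variance = within-mode part
    assert traj.variance("M")[-1] == pytest.approx(traj.mean("M")[-1], rel=1e-6)


def test_normalized_dae_view_matches_weighted_ode(three_stage, ts_partition):
    sys = derive_mcm(three_stage, ts_partition, 2)
    dae = sys.normalized_dae()
    assert dae.kind == "dae"
    sol = integrate(compile_system(dae), [0.0, 1.0, 5.0], three_stage.parameters)
    res = simulate_mcm(sys, [0.0, 1.0, 5.0], three_stage.parameters)
    assert np.abs(sol[:, :sys.n_modes] - res.marginal()).max() < 1e-8
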