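"""Stochastic simulation: exactness, reproducibility, estimators."""

import math

import numpy as np
import pytest
import sympy as sp
from scipy.stats import ks_2samp, poisson

from cmekit.fixtures import make_fixture
from cmekit.network import Reaction, ReactionNetwork, Species
from cmekit.ssa import (
    TimeDependentPropensityError,
    empirical_distribution,
    ensemble_moments,
    first_event_times,
    load_ensemble,
    save_ensemble,
    simulate_direct,
    simulate_modified_next_reaction,
    simulate_next_reaction,
    total_variation,
)
from conftest import bd_exact_mean

N_PATHS = 2000  # desk-scale ensembles; the acceptance checks use 10^4


def test_same_seed_bit_identical(birth_death):
    a = simulate_direct(birth_death, [0.0, 1.0], 100, seed=7)
    b = simulate_direct(birth_death, [0.0, 1.0], 100, seed=7)
    assert np.array_equal(a.paths, b.paths)
    assert a.seeds == b.seeds


def test_different_seed_differs(birth_death):
    a = simulate_direct(birth_death, [0.0, 1.0], 100, seed=1)
    b = simulate_direct(birth_death, [0.0, 1.0], 100, seed=2)
    assert not np.array_equal(a.paths, b.paths)


def test_pure_death_first_jump_exponential():
    net = make_fixture("birth_death", {"k": 0.0, "X_0": 1, "gamma": 2.0})
    times = first_event_times(net, 10_000, seed=5, method="direct")
    se = 0.5 / math.sqrt(10_000)
    assert abs(times.mean() - 0.5) < 4 * se


def test_absorbing_state_constant_paths():
    net = ReactionNetwork([Species("X", initial_amount=0)],
                          [Reaction({"X": 1}, {}, sp.Symbol("g") * sp.Symbol("X"))],
                          {"g": 1.0})
    ens = simulate_direct(net, [0.0, 1.0, 5.0], 50, seed=0)
    assert np.all(ens.paths == 0)


@pytest.mark.parametrize("sampler", [simulate_direct, simulate_next_reaction])
def test_transient_mean_within_four_standard_errors(birth_death, sampler):
    ens = sampler(birth_death, [0.0, 1.0], N_PATHS, seed=11)
    est = ensemble_moments(ens, 2)
    z = (est.means[-1, 0] - bd_exact_mean(1.0)) / est.sem_means[-1, 0]
    assert abs(z) < 4


def test_single_path_is_valid_ensemble(birth_death):
    ens = simulate_next_reaction(birth_death, [0.0, 1.0], 1, seed=3)
    assert ens.paths.shape == (1, 2, 1)
    est = ensemble_moments(ens, 2)
    assert est.sem_means.shape == (2, 1)


def test_homogeneous_methods_agree_in_law(birth_death):
    fa = first_event_times(birth_death, 5000, seed=21, method="direct")
    fb = first_event_times(birth_death, 5000, seed=22, method="next_reaction")
    fc = first_event_times(birth_death, 5000, seed=23,
                           method="modified_next_reaction")
    assert ks_2samp(fa, fb).pvalue > 0.001
    assert ks_2samp(fa, fc).pvalue > 0.001


def test_time_dependent_propensity_redirects(timedep_birth):
    with pytest.raises(TimeDependentPropensityError, match="modified_next_reaction"):
        simulate_direct(timedep_birth, [0.0, 1.0], 10, seed=0)
    with pytest.raises(TimeDependentPropensityError):
        simulate_next_reaction(timedep_birth, [0.0, 1.0], 10, seed=0)


def test_modified_next_reaction_inhomogeneous_poisson(timedep_birth):
    t_end = 2 * np.pi
    ens = simulate_modified_next_reaction(timedep_birth, [0.0, t_end],
                                          N_PATHS, seed=17)
    x = ens.paths[:, -1, 0].astype(float)
    exact = 10 * np.pi  # ∫ 5(1+sin t) dt over one full period
    se = x.std(ddof=1) / math.sqrt(N_PATHS)
    assert abs(x.mean() - exact) < 4 * se


def test_modified_method_reduces_to_homogeneous(birth_death):
    ens_m = simulate_modified_next_reaction(birth_death, [0.0, 1.0], N_PATHS, seed=31)
    ens_d = simulate_direct(birth_death, [0.0, 1.0], N_PATHS, seed=32)
    xa, xb = ens_m.paths[:, -1, 0], ens_d.paths[:, -1, 0]
    pooled_se = math.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb))
    z = (xa.mean() - xb.mean()) / pooled_se
    assert abs(z) < 3.3  # two-sample z-test at alpha = 0.001


def test_delay_semantics():
    net = ReactionNetwork([Species("X")],
                          [Reaction({}, {"X": 1}, sp.Symbol("k"), delay=2.0)],
                          {"k": 5.0})
    ens = simulate_modified_next_reaction(net, [0.0, 1.0, 1.99, 2.5], 200, seed=9)
    assert np.all(ens.paths[:, :3, 0] == 0)   # nothing completes before t = delay
    assert ens.paths[:, 3, 0].mean() > 0


def test_no_negative_counts(three_stage):
    ens = simulate_direct(three_stage, np.linspace(0, 20, 11), 200, seed=4)
    assert ens.paths.min() >= 0
    # promoter conservation holds along every path
    assert np.all(ens.paths[:, :, 0] + ens.paths[:, :, 1] == 1)


def test_ensemble_moment_estimators(birth_death):
    ens = simulate_direct(birth_death, [0.0, 30.0], N_PATHS, seed=13)
    est = ensemble_moments(ens, 4)
    fano = est.central[(2,)][-1] / est.means[-1, 0]
    assert 0.9 < fano < 1.1  # Poisson stationary law
    assert np.all(est.se_central[(2,)] >= 0)
    assert np.all(est.central[(2,)] >= 0)


def test_constant_ensemble_degenerate_moments():
    net = ReactionNetwork([Species("X", initial_amount=7)],
                          [Reaction({}, {"X": 1}, sp.Integer(0))], {})
    ens = simulate_direct(net, [0.0, 1.0], 40, seed=0)
    est = ensemble_moments(ens, 2)
    assert np.all(est.means == 7.0)
    assert np.all(est.central[(2,)] == 0.0) and np.all(est.sem_means == 0.0)


def test_pooled_mean_is_weighted_mean_of_halves(birth_death):
    ens = simulate_direct(birth_death, [0.0, 1.0], 400, seed=8)
    full = ensemble_moments(ens, 1).means[-1, 0]
    half_a = ens.paths[:200, -1, 0].mean()
    half_b = ens.paths[200:, -1, 0].mean()
    assert full == pytest.approx(0.5 * (half_a + half_b), rel=1e-12)


def test_empirical_distribution_normalised_and_marginal_consistent(three_stage):
    ens = simulate_direct(three_stage, [0.0, 5.0], 300, seed=2)
    states, probs = empirical_distribution(ens, 5.0)
    assert probs.sum() == pytest.approx(1.0)
    # marginalising the joint equals the directly computed marginal
    m_states, m_probs = empirical_distribution(ens, 5.0, ["P"])
    joint_marg = {}
    for st, pr in zip(states, probs):
        joint_marg[st[3]] = joint_marg.get(st[3], 0.0) + pr
    for st, pr in zip(m_states, m_probs):
        assert joint_marg[st[0]] == pytest.approx(pr)


def test_empirical_distribution_requires_grid_time(birth_death):
    ens = simulate_direct(birth_death, [0.0, 1.0], 10, seed=0)
    with pytest.raises(ValueError, match="not on the output grid"):
        empirical_distribution(ens, 0.5)


def test_stationary_distribution_close_to_poisson(birth_death):
    ens = simulate_direct(birth_death, [0.0, 30.0], N_PATHS, seed=29)
    states, probs = empirical_distribution(ens, 30.0)
    ref_states = np.arange(0, 41)[:, None]
    tv = total_variation(states, probs, ref_states, poisson.pmf(np.arange(41), 10.0))
    assert tv < 0.08


def test_hdf5_roundtrip(tmp_path, birth_death):
    ens = simulate_direct(birth_death, [0.0, 1.0], 20, seed=5)
    path = tmp_path / "ens.h5"
    save_ensemble(ens, path)
    back = load_ensemble(path)
    assert np.array_equal(back.paths, ens.paths)
    assert back.method == ens.method and back.seeds == ens.seeds
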