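"""Finite state projection of the chemical master equation.

The CME restricted to a finite set of states is a linear ODE
``dp/dt = A(t) p`` whose solution is a pointwise lower bound on the true
probabilities.  Probability flowing out of the truncation is not
re-injected, so the *mass defect* ``1 − Σ_x p(x|t)`` is a certified,
monotonically growing bound on the approximation error.  Within this
package the FSP is the reference oracle against which all mesoscopic
descriptions are judged.

Truncations are hyper-rectangles intersected with the conservation laws
detected from the left null space of the stoichiometry matrix; conserved
species are bounded automatically.  Lost mass is tracked only through the
defect (no explicit sink state), and moments computed from a solution are
renormalised by ``1 − defect`` with the defect reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sps
import sympy as sp

from .network import TIME, ReactionNetwork, stoichiometry_matrix
from .symbolic import DEFAULT_ATOL, DEFAULT_RTOL, IntegrationError
from .moments import MomentTrajectory, moment_indices, _sub_indices, _binom_prod


@dataclass
class StateSpace:
    states: np.ndarray                  # (n_states, n_s) integers
    index: dict                         # tuple(state) -> row
    bounds: dict                        # species name -> inclusive upper bound
    species_names: list

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass
class FSPSolution:
    times: np.ndarray
    p: np.ndarray                       # (n_times, n_states)
    space: StateSpace
    metadata: dict = field(default_factory=dict)

    @property
    def mass_defect(self) -> np.ndarray:
        return 1.0 - self.p.sum(axis=1)


def conservation_laws(net: ReactionNetwork):
    """Integer left-null-space vectors c with cᵀ ν_j = 0 for all reactions."""
    S = sp.Matrix(stoichiometry_matrix(net).tolist())
    laws = []
    for vec in S.T.nullspace():
        denoms = [sp.fraction(sp.nsimplify(v))[1] for v in vec]
        scale = sp.lcm([sp.Integer(d) for d in denoms]) if denoms else sp.Integer(1)
        ivec = [int(v * scale) for v in vec]
        if any(ivec):
            if sum(1 for v in ivec if v < 0) > sum(1 for v in ivec if v > 0):
                ivec = [-v for v in ivec]
            laws.append(np.array(ivec, dtype=np.int64))
    return laws


def enumerate_states(net: ReactionNetwork, bounds: dict | None = None,
                     cap: int = 2_000_000) -> StateSpace:
    """Hyper-rectangle state enumeration intersected with conservation laws.

    ``bounds`` maps species names to inclusive upper bounds.  Species covered
    by a nonnegative conservation law are bounded automatically from the
    conserved total; every other species needs an explicit bound.
    """
    bounds = dict(bounds or {})
    x0 = net.initial_state
    laws = conservation_laws(net)
    auto = {}
    for c in laws:
        if np.all(c >= 0) and np.any(c > 0):
            total = int(c @ x0)
            for i, ci in enumerate(c):
                if ci > 0:
                    name = net.species_names[i]
                    auto[name] = min(auto.get(name, total // ci), total // ci)
    eff = {}
    for s in net.species:
        if s.name in bounds:
            eff[s.name] = int(bounds[s.name])
        elif s.name in auto:
            eff[s.name] = auto[s.name]
        else:
            raise ValueError(f"species '{s.name}' has no bound and no conservation law")
        if eff[s.name] < x0[net.species_names.index(s.name)]:
            raise ValueError(f"bound for '{s.name}' excludes the initial state")

    ranges = [range(eff[name] + 1) for name in net.species_names]
    raw_count = int(np.prod([len(r) for r in ranges], dtype=np.int64))
    if raw_count > 50 * cap:
        raise ValueError(f"candidate state space of {raw_count} states exceeds the cap")

    consts = [int(c @ x0) for c in laws]
    states = []
    for x in itertools.product(*ranges):
        xv = np.array(x, dtype=np.int64)
        if all(int(c @ xv) == k for c, k in zip(laws, consts)):
            states.append(x)
            if len(states) > cap:
                raise ValueError(f"state space exceeds the cap of {cap} states")
    arr = np.array(states, dtype=np.int64).reshape(len(states), net.n_species)
    index = {tuple(s): i for i, s in enumerate(states)}
    return StateSpace(states=arr, index=index, bounds=eff,
                      species_names=list(net.species_names))


def _propensity_evaluator(net: ReactionNetwork, theta: dict):
    """Vectorised evaluator: (t, states) -> array (n_reactions, n_states)."""
    syms = net.species_symbols
    params = net.parameter_symbols
    fns = [sp.lambdify([TIME] + syms + params, a, modules="numpy")
           for a in net.propensities()]
    tvals = [float(theta[str(p)]) for p in params]

    def evaluate(t, states):
        cols = [states[:, i] for i in range(states.shape[1])]
        out = np.empty((len(fns), len(states)))
        for j, fn in enumerate(fns):
            out[j] = np.broadcast_to(fn(t, *cols, *tvals), (len(states),))
        return out

    return evaluate


def build_generator(net: ReactionNetwork, space: StateSpace, theta: dict | None = None):
    """Assemble the truncated CME generator.

    Returns a sparse CSC matrix for time-independent propensities, otherwise
    a callable ``A(t)``.  Column x carries the total outflow −Σ_j a_j(x) on
    the diagonal — including flow leaving the truncation, so column sums are
    ≤ 0 with deficit equal to the outflow rate — and gains ``a_j(x)`` at row
    x+ν_j wherever that state is retained.
    """
    theta = dict(net.parameters if theta is None else theta)
    S = stoichiometry_matrix(net)
    evaluate = _propensity_evaluator(net, theta)
    n = space.n_states
    states = space.states

    patterns = []
    for j in range(net.n_reactions):
        target = states + S[:, j]
        rows = np.fromiter(
            (space.index.get(tuple(x), -1) for x in target), dtype=np.int64, count=n)
        patterns.append(rows)

    def assemble(t):
        prop = evaluate(t, states)
        if np.any(prop < -1e-12):
            j, i = map(int, np.argwhere(prop < -1e-12)[0])
            raise ValueError(
                f"negative propensity for reaction {j} in state {tuple(states[i])} at t={t}")
        data, rows_all, cols_all = [], [], []
        diag = np.zeros(n)
        cols = np.arange(n)
        for j in range(net.n_reactions):
            a = prop[j]
            diag -= a
            keep = patterns[j] >= 0
            rows_all.append(patterns[j][keep])
            cols_all.append(cols[keep])
            data.append(a[keep])
        rows_all.append(cols)
        cols_all.append(cols)
        data.append(diag)
        return sps.csc_matrix(
            (np.concatenate(data), (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(n, n))

    if net.is_time_dependent():
        return assemble
    return assemble(0.0)


def solve_fsp(net: ReactionNetwork, space: StateSpace, t_grid, theta: dict | None = None,
              tol=(DEFAULT_RTOL, DEFAULT_ATOL), p0: np.ndarray | None = None) -> FSPSolution:
    """Integrate dp/dt = A(t) p on the truncated space with a stiff solver."""
    from scipy.integrate import solve_ivp

    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be nonempty and strictly increasing")
    if p0 is None:
        key = tuple(int(v) for v in net.initial_state)
        if key not in space.index:
            raise ValueError(f"initial state {key} is outside the truncated space")
        p0 = np.zeros(space.n_states)
        p0[space.index[key]] = 1.0
    else:
        p0 = np.asarray(p0, dtype=float)
        if abs(p0.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1 on the space")

    A = build_generator(net, space, theta)
    if len(t_grid) == 1:
        return FSPSolution(times=t_grid, p=p0[None, :], space=space,
                           metadata={"method": "FSP", "network": net.name})

    if callable(A):
        rhs = lambda t, p: A(t) @ p
        jac = lambda t, p: A(t)
    else:
        rhs = lambda t, p: A @ p
        jac = lambda t, p: A
    rtol, atol = tol
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), p0, method="BDF",
                    t_eval=t_grid, rtol=rtol, atol=atol, jac=jac)
    if not sol.success:
        raise IntegrationError(f"FSP integration failed: {sol.message}",
                               t_fail=sol.t[-1] if len(sol.t) else t_grid[0])
    return FSPSolution(times=t_grid, p=sol.y.T.copy(), space=space,
                       metadata={"method": "FSP", "network": net.name,
                                 "bounds": dict(space.bounds)})


def fsp_error_bound(sol: FSPSolution) -> np.ndarray:
    """Per-time mass defect 1 − Σ_x p(x|t) (the certified FSP error)."""
    return sol.mass_defect


def marginalize(sol: FSPSolution, species: list[str]):
    """Marginal distribution time course over a subset of species.

    Returns ``(sub_states, probs)`` where ``sub_states`` holds the distinct
    retained sub-states and ``probs`` has one row per time.  Marginal sums
    equal ``1 − mass_defect`` at each time.
    """
    if not species:
        raise ValueError("species subset must be nonempty")
    cols = [sol.space.species_names.index(s) for s in species]
    sub = sol.space.states[:, cols]
    uniq, inv = np.unique(sub, axis=0, return_inverse=True)
    probs = np.zeros((len(sol.times), len(uniq)))
    for k in range(len(sol.times)):
        np.add.at(probs[k], inv, sol.p[k])
    return uniq, probs


def fsp_moments(sol: FSPSolution, order: int) -> MomentTrajectory:
    """Moments of the truncated distribution, renormalised by 1 − defect."""
    if order < 1:
        raise ValueError("order must be >= 1")
    states = sol.space.states.astype(float)
    n = states.shape[1]
    defect = sol.mass_defect
    norm = np.clip(1.0 - defect, 1e-300, None)
    w = sol.p / norm[:, None]

    raw = {}
    for idx in moment_indices(n, order):
        mono = np.prod(states ** np.array(idx), axis=1)
        raw[idx] = w @ mono
    means = np.stack([raw[tuple(1 if k == i else 0 for k in range(n))]
                      for i in range(n)], axis=1)
    central = {}
    for idx in moment_indices(n, order):
        if sum(idx) < 2:
            continue
        acc = np.zeros(len(sol.times))
        for j in _sub_indices(idx):
            coeff = _binom_prod(idx, j)
            mu_pow = np.ones(len(sol.times))
            for i in range(n):
                if idx[i] > j[i]:
                    mu_pow = mu_pow * (-means[:, i]) ** (idx[i] - j[i])
            m_val = np.ones(len(sol.times)) if sum(j) == 0 else raw[j]
            acc = acc + coeff * mu_pow * m_val
        central[idx] = acc
    traj = MomentTrajectory(
        times=sol.times, species_names=list(sol.space.species_names),
        means=means, central=central,
        metadata={"method": "FSP", "order": order},
        flags={"mass_defect_max": float(defect.max())})
    traj.check_flags()
    return traj


def distribution_to_frame(sol: FSPSolution):
    """CSV-ready export: one row per (time, state, probability)."""
    import pandas as pd

    rows = []
    for k, t in enumerate(sol.times):
        for i, x in enumerate(sol.space.states):
            rows.append({"time": t,
                         **{n: int(v) for n, v in zip(sol.space.species_names, x)},
                         "probability": sol.p[k, i]})
    return pd.DataFrame(rows)
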