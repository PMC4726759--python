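"""Method of conditional moments: hybrid marginal/moment description.

Species are partitioned into *low-copy* species ``y`` (e.g. promoter
occupancy states, whose reachable range is finite and tiny) and
*high-copy* species ``z`` (mRNA, protein).  The description tracks

* the exact marginal probability ``p(y|t)`` of every low-copy mode, and
* the moments of ``z`` conditional on each mode, up to a chosen order m,

which together form a differential–algebraic system: the conditional-moment
equations degenerate where ``p(y) = 0``.  Integration therefore uses the
*weighted-moment* form ``w_I^y = p(y)·E[z^I | y]`` whose dynamics are plain
ODEs derived directly from the master equation:

    d w_I^y/dt = Σ_j ( ⟨a_j(y−Δy_j, z) (z+ν_j^z)^I⟩_{y−Δy_j} − ⟨a_j(y, z) z^I⟩_y )

with ⟨·⟩_y the unnormalised conditional expectation (a linear combination
of weighted moments) and Δy_j, ν_j^z the low/high blocks of the
stoichiometry.  Propensities are evaluated exactly in ``y`` (modes are
enumerated) and must be polynomial in ``z``.  Weighted moments above order
m are closed per mode with the same schemes as the plain moment equations;
the conditional normalisation 1/p(y) appearing inside closure expressions
is regularised as p/(p² + ε²), which vanishes smoothly for empty modes
instead of diverging.

The normalised DAE view (states p(y) and conditional moments, with a
p-weighted singular mass matrix) is available via
:meth:`MCMSystem.normalized_dae` and integrates through the DAE path of the
symbolic engine.

Two degenerate partitions tie the derivation to its neighbours and are the
strongest structural checks: with no high-copy species the system is
exactly the finite-state projection on the modes, and with no low-copy
species it is exactly the moment equations of order m.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .network import ReactionNetwork, stoichiometry_matrix
from .symbolic import SymbolicSystem, compile_system, integrate
from .moments import (
    MomentTrajectory,
    moment_indices,
    _closure_expression,
    _sub_indices,
    _binom_prod,
)
from .fsp import conservation_laws

#: regularisation for 1/p(y) inside closure expressions
MCM_EPS = 1e-12
#: conditional moments are reported only where p(y) exceeds this
REPORT_EPS = 1e-10


@dataclass
class Partition:
    low_copy: list                     # species names (modes y)
    high_copy: list                    # species names (z)
    bounds: dict = field(default_factory=dict)  # low-copy name -> upper bound


@dataclass
class MCMSystem:
    modes: list                        # list of y tuples (low-copy states)
    partition: Partition
    order: int
    closure: str
    symbolic: SymbolicSystem           # weighted-moment ODE form
    indices: list                      # z multi-indices incl. the zero index
    state_pos: dict                    # (mode_row, z_index) -> state position
    species_names: list
    net: ReactionNetwork | None = None

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def normalized_dae(self) -> SymbolicSystem:
        """The DAE view: states p(y) and conditional moments M_I^y.

        Probability rows carry unit mass; conditional-moment rows carry the
        state-dependent mass p(y) (from p·dM/dt = dw_I/dt − M_I·dw_0/dt),
        singular wherever a mode is empty.
        """
        n_modes, idxs = self.n_modes, self.indices
        p_syms = [sp.Symbol(f"mcmP_{r}") for r in range(n_modes)]
        M_syms = {(r, I): sp.Symbol(f"mcmM_{r}_" + "_".join(map(str, I)))
                  for r in range(n_modes) for I in idxs if sum(I) > 0}
        subs = {}
        for (r, I), pos in self.state_pos.items():
            wsym = self.symbolic.state_symbols[pos]
            subs[wsym] = p_syms[r] if sum(I) == 0 else p_syms[r] * M_syms[(r, I)]
        w_rhs = {key: sp.sympify(self.symbolic.rhs[pos]).xreplace(subs)
                 for key, pos in self.state_pos.items()}
        states, rhs, mass, ic = [], [], [], []
        x0 = {key: self.symbolic.initial_condition[pos]
              for key, pos in self.state_pos.items()}
        for r in range(n_modes):
            states.append(p_syms[r])
            rhs.append(sp.expand(w_rhs[(r, idxs[0])]))
            mass.append(sp.Integer(1))
            ic.append(x0[(r, idxs[0])])
        for r in range(n_modes):
            p0 = float(x0[(r, idxs[0])])
            for I in idxs:
                if sum(I) == 0:
                    continue
                states.append(M_syms[(r, I)])
                rhs.append(sp.expand(w_rhs[(r, I)]
                                     - M_syms[(r, I)] * w_rhs[(r, idxs[0])]))
                mass.append(p_syms[r])
                ic.append(sp.Float(float(x0[(r, I)]) / p0) if p0 > 0 else sp.Integer(0))
        return SymbolicSystem(
            state_symbols=states, rhs=rhs, initial_condition=ic,
            parameter_symbols=list(self.symbolic.parameter_symbols), kind="dae",
            mass_matrix=sp.diag(*mass),
            metadata={**self.symbolic.metadata, "form": "normalized_dae"})


@dataclass
class MCMResult:
    times: np.ndarray
    system: MCMSystem
    weighted: np.ndarray               # raw solution of the weighted ODE

    def marginal(self) -> np.ndarray:
        """p(y|t): shape (n_times, n_modes)."""
        out = np.empty((len(self.times), self.system.n_modes))
        zero = self.system.indices[0]
        for r in range(self.system.n_modes):
            out[:, r] = self.weighted[:, self.system.state_pos[(r, zero)]]
        return out

    def weighted_moment(self, mode_row: int, z_index: tuple) -> np.ndarray:
        return self.weighted[:, self.system.state_pos[(mode_row, z_index)]]

    def conditional_mean(self, species: str, mode_row: int) -> np.ndarray:
        """E[z | y] over time; NaN where the mode is (numerically) empty."""
        i = self.system.partition.high_copy.index(species)
        nz = len(self.system.partition.high_copy)
        e = tuple(1 if k == i else 0 for k in range(nz))
        p = self.marginal()[:, mode_row]
        with np.errstate(divide="ignore", invalid="ignore"):
            val = self.weighted_moment(mode_row, e) / p
        val[p < REPORT_EPS] = np.nan
        return val

    def conditional_variance(self, species: str, mode_row: int) -> np.ndarray:
        i = self.system.partition.high_copy.index(species)
        nz = len(self.system.partition.high_copy)
        e = tuple(1 if k == i else 0 for k in range(nz))
        e2 = tuple(2 if k == i else 0 for k in range(nz))
        p = self.marginal()[:, mode_row]
        with np.errstate(divide="ignore", invalid="ignore"):
            m1 = self.weighted_moment(mode_row, e) / p
            m2 = self.weighted_moment(mode_row, e2) / p
            val = m2 - m1 ** 2
        val[p < REPORT_EPS] = np.nan
        return val


def partition_species(net: ReactionNetwork, rule: str = "auto",
                      manual_sets: dict | None = None, cap: int = 2) -> Partition:
    """Split species into low-copy modes and high-copy moment species.

    ``auto``: species whose reachable range is provably finite (from a
    nonnegative conservation law) with at most ``cap`` states become
    low-copy.  ``manual``: ``manual_sets`` supplies ``low_copy`` (and
    optionally per-species ``bounds``); everything else is high-copy.
    """
    names = net.species_names
    x0 = net.initial_state
    auto_bounds = {}
    for c in conservation_laws(net):
        if np.all(c >= 0) and np.any(c > 0):
            total = int(c @ x0)
            for i, ci in enumerate(c):
                if ci > 0:
                    b = total // int(ci)
                    auto_bounds[names[i]] = min(auto_bounds.get(names[i], b), b)
    if rule == "auto":
        hints = {s.name: s.abundance_class for s in net.species}
        low = [nm for nm in names
               if nm in auto_bounds and hints.get(nm) != "high_copy"
               and (auto_bounds[nm] + 1 <= cap or hints.get(nm) == "low_copy")]
        if not low:
            raise ValueError(
                "no species has a provably finite range within the cap; "
                "supply a manual partition")
        bounds = {nm: auto_bounds[nm] for nm in low}
    elif rule == "manual":
        manual_sets = manual_sets or {}
        low = list(manual_sets.get("low_copy", []))
        unknown = [nm for nm in low if nm not in names]
        if unknown:
            raise ValueError(f"unknown species in manual partition: {unknown}")
        bounds = {}
        for nm in low:
            if nm in (manual_sets.get("bounds") or {}):
                bounds[nm] = int(manual_sets["bounds"][nm])
            elif nm in auto_bounds:
                bounds[nm] = auto_bounds[nm]
            else:
                raise ValueError(f"low-copy species '{nm}' needs an explicit bound")
    else:
        raise ValueError("rule must be 'auto' or 'manual'")
    high = [nm for nm in names if nm not in low]
    return Partition(low_copy=low, high_copy=high, bounds=bounds)


def _enumerate_modes(net: ReactionNetwork, part: Partition):
    """All low-copy states consistent with conservation laws on low species."""
    names = net.species_names
    low_idx = [names.index(nm) for nm in part.low_copy]
    x0 = net.initial_state
    laws = []
    for c in conservation_laws(net):
        if all(c[i] == 0 for i in range(len(names)) if names[i] not in part.low_copy):
            laws.append((c[low_idx], int(c @ x0)))
    ranges = [range(part.bounds[nm] + 1) for nm in part.low_copy]
    modes = [y for y in itertools.product(*ranges)
             if all(int(np.dot(cl, y)) == k for cl, k in laws)]
    if not modes:
        raise ValueError("mode enumeration produced no states")
    return modes


def derive_mcm(net: ReactionNetwork, partition: Partition, order: int,
               closure: str = "low_dispersion", user_map: dict | None = None
               ) -> MCMSystem:
    """Derive the weighted conditional-moment ODE system."""
    if order < 0:
        raise ValueError("order must be >= 0")
    names = net.species_names
    low_idx = [names.index(nm) for nm in partition.low_copy]
    high_idx = [names.index(nm) for nm in partition.high_copy]
    n_z = len(high_idx)
    S = stoichiometry_matrix(net)
    modes = _enumerate_modes(net, partition)
    mode_row = {y: r for r, y in enumerate(modes)}
    z_syms = [net.species_symbols[i] for i in high_idx]
    low_syms = [net.species_symbols[i] for i in low_idx]

    idxs = [tuple([0] * n_z)] + (moment_indices(n_z, order) if n_z and order else [])

    def wsym(r, I):
        return sp.Symbol(f"w_{r}_" + "_".join(map(str, I)))

    props = net.propensities()

    def prop_at_mode(j, y):
        a = props[j].subs({s: sp.Integer(v) for s, v in zip(low_syms, y)},
                          simultaneous=True)
        if z_syms:
            try:
                sp.Poly(a, *z_syms)
            except sp.PolynomialError:
                raise ValueError(
                    f"propensity of reaction {j} is not polynomial in the "
                    "high-copy species; Taylor-expand it first") from None
        return a

    def unnormalized_expectation(expr_poly, r):
        """⟨poly(z)⟩_y as a linear combination of weighted-moment symbols."""
        if not z_syms:
            return sp.expand(expr_poly) * wsym(r, idxs[0])
        poly = sp.Poly(sp.expand(expr_poly), *z_syms)
        out = sp.Integer(0)
        for powers, coeff in poly.terms():
            out += coeff * wsym(r, tuple(powers))
        return out

    rhs_map = {}
    for y in modes:
        r = mode_row[y]
        for I in idxs:
            acc = sp.Integer(0)
            for j in range(net.n_reactions):
                dy = tuple(int(S[i, j]) for i in low_idx)
                dz = [int(S[i, j]) for i in high_idx]
                mono = math.prod(
                    [sp.Integer(1)] + [z ** p for z, p in zip(z_syms, I) if p])
                acc -= unnormalized_expectation(prop_at_mode(j, y) * mono, r)
                y_pre = tuple(yv - d for yv, d in zip(y, dy))
                if y_pre in mode_row:
                    shifted = sp.expand(math.prod(
                        [sp.Integer(1)] + [(z + d) ** p
                                           for z, d, p in zip(z_syms, dz, I) if p]))
                    acc += unnormalized_expectation(
                        prop_at_mode(j, y_pre) * shifted, mode_row[y_pre])
            rhs_map[(r, I)] = sp.expand(acc)

    # close weighted moments of order > m, per mode
    eps = sp.Float(MCM_EPS)
    closure_subs = {}
    if n_z:
        memo: dict = {}
        needed = set()
        for expr in rhs_map.values():
            for s in expr.free_symbols:
                name = str(s)
                if name.startswith("w_"):
                    parts = name.split("_")
                    I = tuple(int(v) for v in parts[2:])
                    if sum(I) > order:
                        needed.add((int(parts[1]), I))
        for (r, I) in sorted(needed):
            if closure == "user":
                if user_map is None or I not in user_map:
                    raise ValueError(f"user closure missing index {I}")
                raw_expr = sp.sympify(user_map[I])
            else:
                raw_expr = _closure_expression(I, order, n_z, closure, memo)
            w0 = wsym(r, idxs[0])
            reg = w0 / (w0 ** 2 + eps ** 2)   # regularised 1/p(y)
            rsubs = {}
            for s in raw_expr.free_symbols:
                if str(s).startswith("m_"):
                    J = tuple(int(v) for v in str(s)[2:].split("_"))
                    rsubs[s] = wsym(r, J) * reg
            closure_subs[wsym(r, I)] = sp.expand(w0 * raw_expr.xreplace(rsubs))

    states, rhs, ic = [], [], []
    state_pos = {}
    x0 = net.initial_state
    y0 = tuple(int(x0[i]) for i in low_idx)
    z0 = [int(x0[i]) for i in high_idx]
    if y0 not in mode_row:
        raise ValueError("initial low-copy state lies outside the enumerated modes")
    for y in modes:
        r = mode_row[y]
        for I in idxs:
            state_pos[(r, I)] = len(states)
            states.append(wsym(r, I))
            expr = rhs_map[(r, I)]
            if closure_subs:
                expr = sp.sympify(expr).xreplace(closure_subs)
            rhs.append(expr)
            if y == y0:
                ic.append(sp.Integer(math.prod(z ** p for z, p in zip(z0, I))
                                     if sum(I) else 1))
            else:
                ic.append(sp.Integer(0))

    sym_sys = SymbolicSystem(
        state_symbols=states, rhs=rhs, initial_condition=ic,
        parameter_symbols=net.parameter_symbols, kind="ode",
        metadata={"method": "MCM", "order": order, "closure": closure,
                  "network": net.name})
    return MCMSystem(modes=modes, partition=partition, order=order, closure=closure,
                     symbolic=sym_sys, indices=idxs, state_pos=state_pos,
                     species_names=list(names), net=net)


def simulate_mcm(sys: MCMSystem, t_grid, theta, tol=(1e-8, 1e-10)) -> MCMResult:
    """Integrate the weighted-moment ODE form."""
    compiled = compile_system(sys.symbolic)
    sol = integrate(compiled, t_grid, theta, tol=tol)
    return MCMResult(times=np.asarray(t_grid, float), system=sys, weighted=sol)


def reconstruct_overall_moments(result: MCMResult) -> MomentTrajectory:
    """Unconditional moments over all species.

    Uses the laws of total expectation and total variance: the mean of a
    high-copy species is Σ_y w_{e}^y and its variance combines within-mode
    and between-mode contributions automatically through the weighted
    second moments.  Covers orders ≤ 2 (requires m ≥ 2 for variances).
    """
    sys = result.system
    names = sys.species_names
    n = len(names)
    low, high = sys.partition.low_copy, sys.partition.high_copy
    T = len(result.times)
    marg = result.marginal()
    modes = np.array(sys.modes, dtype=float).reshape(len(sys.modes), len(low))

    def raw(full_idx: tuple) -> np.ndarray:
        Jy = [full_idx[names.index(nm)] for nm in low]
        Jz = tuple(full_idx[names.index(nm)] for nm in high)
        if sum(Jz) > sys.order:
            raise KeyError(f"needs conditional moments of order {sum(Jz)}")
        acc = np.zeros(T)
        for r in range(sys.n_modes):
            ypow = math.prod(modes[r, k] ** p for k, p in enumerate(Jy)) if Jy else 1.0
            wvec = result.weighted_moment(r, Jz) if high else marg[:, r]
            acc = acc + ypow * wvec
        return acc

    means = np.empty((T, n))
    for i in range(n):
        means[:, i] = raw(tuple(1 if k == i else 0 for k in range(n)))
    central = {}
    if not high or sys.order >= 2:
        for idx in moment_indices(n, 2):
            if sum(idx) != 2:
                continue
            try:
                raw(idx)
            except KeyError:
                continue
            acc = np.zeros(T)
            for j in _sub_indices(idx):
                coeff = _binom_prod(idx, j)
                mu_pow = np.ones(T)
                for i in range(n):
                    if idx[i] > j[i]:
                        mu_pow = mu_pow * (-means[:, i]) ** (idx[i] - j[i])
                mv = np.ones(T) if sum(j) == 0 else raw(j)
                acc = acc + coeff * mu_pow * mv
            central[idx] = acc
    traj = MomentTrajectory(
        times=result.times, species_names=list(names), means=means, central=central,
        metadata={"method": "MCM", "order": sys.order, "closure": sys.closure})
    traj.check_flags()
    return traj


def conditional_to_frame(result: MCMResult):
    """Per-mode marginal and conditional-moment export (long format)."""
    import pandas as pd

    sys = result.system
    marg = result.marginal()
    rows = []
    for k, t in enumerate(result.times):
        for r, y in enumerate(sys.modes):
            label = ",".join(f"{nm}={v}" for nm, v in zip(sys.partition.low_copy, y))
            rows.append({"time": t, "mode": label, "quantity": "probability",
                         "value": marg[k, r]})
            for nm in sys.partition.high_copy:
                if sys.order >= 1:
                    rows.append({"time": t, "mode": label,
                                 "quantity": f"mean[{nm}]",
                                 "value": result.conditional_mean(nm, r)[k]})
                if sys.order >= 2:
                    rows.append({"time": t, "mode": label,
                                 "quantity": f"var[{nm}]",
                                 "value": result.conditional_variance(nm, r)[k]})
    return pd.DataFrame(rows)
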