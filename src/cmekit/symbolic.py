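"""Symbolic derivation core and numeric lowering.

All mesoscopic and macroscopic descriptions in this package are derived by
applying the generator of the chemical master equation to polynomial test
functions:  for a network with propensities ``a_j(x, t)`` and state-change
vectors ``ν_j``, the time evolution of any polynomial expectation obeys

    d⟨f(X)⟩/dt = ⟨ Σ_j a_j(X, t) · ( f(X + ν_j) − f(X) ) ⟩ .

:func:`apply_generator` produces the inner expression exactly; the moment,
system-size-expansion and conditional-moment engines then take expectations
and truncate in their own ways.  Derived systems are represented as
:class:`SymbolicSystem` objects and lowered to fast numeric callables with
common-subexpression elimination by :func:`compile_system`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .network import TIME, ReactionNetwork, stoichiometry_matrix


class CompilationError(ValueError):
    """Raised when a symbolic system references unresolved symbols."""


class IntegrationError(RuntimeError):
    """Integrator failure; carries the failure time and last valid state."""

    def __init__(self, message, t_fail=None, last_state=None):
        super().__init__(message)
        self.t_fail = t_fail
        self.last_state = last_state


@dataclass
class SymbolicSystem:
    """An ODE or DAE system ``M(x) dx/dt = rhs(x, θ, t)``.

    ``mass_matrix`` is ``None`` for plain ODEs (identity).  A DAE carries a
    singular diagonal mass matrix; rows with a structurally zero mass entry
    are algebraic constraints ``0 = rhs_i``.
    """

    state_symbols: list
    rhs: list
    initial_condition: list
    parameter_symbols: list
    kind: str = "ode"                    # {"ode", "dae"}
    mass_matrix: sp.Matrix | None = None # diagonal; entries may be expressions
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.state_symbols)

    def __post_init__(self):
        if len(self.rhs) != len(self.state_symbols):
            raise ValueError("rhs length must equal state length")
        if len(self.initial_condition) != len(self.state_symbols):
            raise ValueError("initial_condition length must equal state length")
        if self.mass_matrix is not None and self.kind == "ode":
            mm = sp.Matrix(self.mass_matrix)
            if mm != sp.eye(self.n):
                self.kind = "dae"

    def free_unresolved(self):
        allowed = set(self.state_symbols) | set(self.parameter_symbols) | {TIME}
        stray = set()
        for e in list(self.rhs) + list(self.initial_condition):
            stray |= sp.sympify(e).free_symbols - allowed
        return sorted(stray, key=str)

    def write_equations(self, path) -> None:
        """Dump the derived system, one equation per line, for inspection."""
        with open(path, "w") as fh:
            for meta_key, meta_val in sorted(self.metadata.items()):
                fh.write(f"# {meta_key}: {meta_val}\n")
            for s, r, ic in zip(self.state_symbols, self.rhs, self.initial_condition):
                fh.write(f"d({s})/dt = {sp.sstr(sp.expand(r))}    [{s}(0) = {sp.sstr(ic)}]\n")


@dataclass
class CompiledSystem:
    """Numeric lowering of a :class:`SymbolicSystem`."""

    system: SymbolicSystem
    rhs_fn: object          # (t, state, theta) -> dstate
    jac_fn: object          # (t, state, theta) -> n x n
    x0_fn: object           # (theta,) -> state
    mass_diag_fn: object | None = None  # (t, state, theta) -> diagonal, None = identity
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.system.n


# ---------------------------------------------------------------------------
# generator and Taylor expansion
# ---------------------------------------------------------------------------

def apply_generator(f, net: ReactionNetwork):
    """Apply the CME generator to a polynomial ``f`` of the species symbols.

    Returns ``Σ_j a_j(x,t) (f(x+ν_j) − f(x))`` fully expanded.  Taking the
    expectation of the result gives ``d⟨f⟩/dt`` exactly.
    """
    f = sp.sympify(f)
    syms = net.species_symbols
    try:
        sp.Poly(f, *syms)
    except sp.PolynomialError as exc:
        raise ValueError(
            f"generator requires a polynomial in the species symbols, got {f}"
        ) from exc
    S = stoichiometry_matrix(net)
    props = net.propensities()
    total = sp.Integer(0)
    for j, a in enumerate(props):
        shifted = f.subs(
            {s: s + int(S[i, j]) for i, s in enumerate(syms) if S[i, j] != 0},
            simultaneous=True,
        )
        total += a * (shifted - f)
    return sp.expand(total)


def taylor_expand_propensity(prop, center: dict, order: int):
    """Multivariate Taylor polynomial of ``prop`` about ``center``.

    ``center`` maps symbols to expansion-point expressions (which may be
    symbols themselves, e.g. running means).  Truncation is at total degree
    ``order`` across all expanded symbols.
    """
    prop = sp.sympify(prop)
    if order < 0:
        raise ValueError("order must be >= 0")
    eps = sp.Dummy("eps")
    subs = {x: c + eps * (x - c) for x, c in center.items()}
    shifted = prop.subs(subs, simultaneous=True)
    try:
        series = sp.series(shifted, eps, 0, order + 1).removeO()
    except (sp.PoleError, NotImplementedError, ZeroDivisionError) as exc:
        raise ValueError(f"propensity {prop} is not expandable about {center}") from exc
    return sp.expand(series.subs(eps, 1))


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def _lambdify_vector(exprs, states, params, with_time=True):
    """Lambdify a list of expressions with CSE into (t, x, theta) -> array."""
    args = ([TIME] if with_time else []) + [sp.Matrix(states) if states else sp.zeros(0, 1)]
    # use flat argument lists; pack/unpack around the generated function
    flat_args = ([TIME] if with_time else []) + list(states) + list(params)
    fn = sp.lambdify(flat_args, list(exprs), modules="numpy", cse=True)
    n_states = len(states)

    if with_time:
        def wrapper(t, x, theta):
            out = fn(t, *[x[i] for i in range(n_states)], *theta)
            return np.asarray(out, dtype=float)
    else:
        def wrapper(theta):
            out = fn(*([0.0] * n_states), *theta)
            return np.asarray(out, dtype=float)
    return wrapper


def compile_system(system: SymbolicSystem) -> CompiledSystem:
    """Lower a symbolic system to numeric ``rhs``/``jac``/``x0`` callables."""
    stray = system.free_unresolved()
    if stray:
        raise CompilationError(f"unresolved symbols in system: {', '.join(map(str, stray))}")

    states = list(system.state_symbols)
    params = list(system.parameter_symbols)
    rhs = [sp.sympify(e) for e in system.rhs]
    jac_mat = sp.Matrix(rhs).jacobian(states) if states else sp.zeros(0, 0)

    rhs_fn = _lambdify_vector(rhs, states, params)
    jac_flat = _lambdify_vector(list(jac_mat), states, params)
    n = len(states)

    def jac_fn(t, x, theta):
        return jac_flat(t, x, theta).reshape(n, n)

    ic = [sp.sympify(e) for e in system.initial_condition]
    ic_fn = sp.lambdify(params, list(ic), modules="numpy", cse=True)

    def x0_fn(theta):
        return np.asarray(ic_fn(*theta), dtype=float)

    mass_fn = None
    if system.mass_matrix is not None and system.kind == "dae":
        mm = sp.Matrix(system.mass_matrix)
        diag = [mm[i, i] for i in range(system.n)]
        if mm != sp.diag(*diag):
            raise CompilationError("only diagonal mass matrices are supported")
        mass_fn = _lambdify_vector(diag, states, params)

    return CompiledSystem(system, rhs_fn, jac_fn, x0_fn, mass_fn,
                          metadata=dict(system.metadata))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: Regularisation for state-dependent (near-singular) mass entries on the
#: DAE path: 1/m is evaluated as m/(m² + ε²), which vanishes smoothly as the
#: mass entry crosses zero instead of diverging.
MASS_EPS = 1e-12


def theta_vector(system: SymbolicSystem, theta) -> np.ndarray:
    """Accept a dict (by parameter name) or a sequence in declared order."""
    if isinstance(theta, dict):
        return np.array([float(theta[str(p)]) for p in system.parameter_symbols])
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(system.parameter_symbols),):
        raise ValueError("theta length does not match parameter_symbols")
    return theta


def integrate(compiled: CompiledSystem, t_grid, theta, tol=(DEFAULT_RTOL, DEFAULT_ATOL),
              method="LSODA"):
    """Integrate a compiled ODE/DAE on a strictly increasing time grid.

    Returns an array of shape ``(len(t_grid), n)``.  DAEs with structurally
    zero diagonal mass rows are solved in semi-explicit index-1 form (the
    algebraic states are resolved by damped Newton inside the right-hand
    side); state-dependent mass entries are handled by regularised division.
    """
    from scipy.integrate import solve_ivp
    from scipy.optimize import fsolve

    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a nonempty 1-d array")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    rtol, atol = tol
    theta = theta_vector(compiled.system, theta)
    x0 = compiled.x0_fn(theta)
    n = compiled.n

    if len(t_grid) == 1:
        return x0[None, :].copy()

    if compiled.mass_diag_fn is None:
        rhs = lambda t, x: compiled.rhs_fn(t, x, theta)
        jac = lambda t, x: compiled.jac_fn(t, x, theta)
    else:
        system = compiled.system
        diag_exprs = [sp.Matrix(system.mass_matrix)[i, i] for i in range(n)]
        alg = np.array([e == 0 for e in map(sp.sympify, diag_exprs)], dtype=bool)
        if alg.any():
            diff_idx = np.where(~alg)[0]
            alg_idx = np.where(alg)[0]
            const_diff = all(sp.sympify(diag_exprs[i]) == 1 for i in diff_idx)
            if not const_diff:
                raise CompilationError(
                    "mixed algebraic / state-dependent mass rows are not supported")
            state = {"z": x0[alg_idx].copy()}

            def full_state(t, xd):
                x = np.empty(n)
                x[diff_idx] = xd

                def residual(z):
                    x[alg_idx] = z
                    return compiled.rhs_fn(t, x, theta)[alg_idx]

                z, _, ier, _ = fsolve(residual, state["z"], full_output=True)
                if ier == 1:
                    state["z"] = z
                x[alg_idx] = state["z"]
                return x

            def rhs(t, xd):
                x = full_state(t, xd)
                return compiled.rhs_fn(t, x, theta)[diff_idx]

            jac = None
            sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), x0[diff_idx],
                            method="LSODA", t_eval=t_grid, rtol=rtol, atol=atol)
            if not sol.success:
                raise IntegrationError(f"DAE integration failed: {sol.message}",
                                       t_fail=sol.t[-1] if len(sol.t) else t_grid[0])
            out = np.empty((len(t_grid), n))
            for i, (t, xd) in enumerate(zip(sol.t, sol.y.T)):
                out[i] = full_state(t, xd)
            return out
        # state-dependent diagonal mass, no structurally zero rows
        def rhs(t, x):
            m = compiled.mass_diag_fn(t, x, theta)
            return compiled.rhs_fn(t, x, theta) * m / (m * m + MASS_EPS)

        jac = None
        method = "LSODA"

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), x0, method=method,
                    t_eval=t_grid, rtol=rtol, atol=atol,
                    jac=jac if method in ("BDF", "Radau", "LSODA") else None)
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else t_grid[0]
        last = sol.y[:, -1] if sol.y.size else x0
        raise IntegrationError(f"integration failed at t={t_fail}: {sol.message}",
                               t_fail=t_fail, last_state=last)
    return sol.y.T.copy()
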