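"""Forward and adjoint sensitivity analysis for derived ODE/DAE systems.

Forward sensitivities augment a system of ``n`` states with
``s_a = ∂x/∂θ_a`` per parameter, giving ``n(1+n_θ)`` equations at order 1:

    ds_a/dt = J(x, t) s_a + ∂f/∂θ_a ,    s_a(0) = ∂x₀/∂θ_a ,

and, at order 2, the ``n·n_θ(n_θ+1)/2`` symmetric second-order states with
the full chain-rule right-hand side (state Hessian contracted with two
first-order sensitivities plus the mixed parameter terms).

Adjoint sensitivities target a scalar weighted least-squares objective
``J(θ) = Σ_k w_k (g(x(t_k), θ) − d_k)²``: one backward ODE
``dλ/dt = −Jᵀ λ`` of dimension ``n`` — independent of n_θ — with jump
updates ``λ ← λ + ∂(residual term)/∂x`` at each measurement time, and the
gradient assembled as ``∂J/∂θ = ∫ λᵀ ∂f/∂θ dt + λ(0)ᵀ ∂x₀/∂θ`` plus the
explicit parameter dependence of the observables.  The backward sweep
integrates segment-wise between measurement times (no delta smoothing), so
discrete-time data are handled exactly.  The adjoint path supports ODE
systems only; DAE bases are rejected.

Central finite differences (default relative step 1e−6, absolute floor
1e−8) are provided as the reference cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

from .network import TIME
from .symbolic import SymbolicSystem, compile_system, integrate, theta_vector

FD_REL_STEP = 1e-6
FD_ABS_FLOOR = 1e-8


@dataclass
class SensitivitySystem:
    base: SymbolicSystem
    parameters: list                  # θ subset (sympy symbols)
    order: int
    augmented: SymbolicSystem
    block_index: dict                 # ("x", i) | ("s", i, a) | ("s2", i, a, b) -> pos

    @property
    def n_base(self) -> int:
        return self.base.n

    @property
    def n_theta(self) -> int:
        return len(self.parameters)


@dataclass
class Objective:
    """Weighted least-squares objective on observables of a derived system."""

    observables: list                 # sympy expressions in states (and θ)
    times: np.ndarray                 # measurement times, increasing, > t0
    data: np.ndarray                  # (n_times, n_obs)
    weights: np.ndarray | float = 1.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape != (len(self.times), len(self.observables)):
            raise ValueError("data must have shape (n_times, n_observables)")
        w = np.asarray(self.weights, dtype=float)
        self.weights = np.broadcast_to(w, self.data.shape).copy()
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("measurement times must be strictly increasing")


def _sens_symbol(state, param, second=None):
    if second is None:
        return sp.Symbol(f"sens_{state}_{param}")
    return sp.Symbol(f"sens2_{state}_{param}_{second}")


def derive_forward_sensitivities(sys: SymbolicSystem, theta_subset=None,
                                 order: int = 1) -> SensitivitySystem:
    """Augment a symbolic system with forward sensitivity states."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    params = ([sp.Symbol(str(p)) for p in theta_subset]
              if theta_subset is not None else list(sys.parameter_symbols))
    missing = [p for p in params if p not in set(sys.parameter_symbols)]
    if missing:
        raise ValueError(f"parameters not in system: {missing}")
    x = list(sys.state_symbols)
    n = len(x)
    f = [sp.sympify(e) for e in sys.rhs]
    J = sp.Matrix(f).jacobian(x)
    ntheta = len(params)

    s = {(i, a): _sens_symbol(x[i], p) for a, p in enumerate(params) for i in range(n)}
    states = list(x)
    rhs = list(f)
    ic = [sp.sympify(e) for e in sys.initial_condition]
    block_index = {("x", i): i for i in range(n)}

    f_theta = {a: [sp.diff(fi, p) for fi in f] for a, p in enumerate(params)}
    for a, p in enumerate(params):
        for i in range(n):
            block_index[("s", i, a)] = len(states)
            states.append(s[(i, a)])
            rhs.append(sp.expand(
                sum(J[i, k] * s[(k, a)] for k in range(n)) + f_theta[a][i]))
            ic.append(sp.diff(sys.initial_condition[i], p))

    if order == 2:
        Hx = [[[sp.diff(J[i, k], x[l]) for l in range(n)] for k in range(n)]
              for i in range(n)]
        Jtheta = {a: [[sp.diff(J[i, k], params[a]) for k in range(n)]
                      for i in range(n)] for a in range(ntheta)}
        for a in range(ntheta):
            for b in range(a, ntheta):
                for i in range(n):
                    s2 = _sens_symbol(x[i], params[a], params[b])
                    block_index[("s2", i, a, b)] = len(states)
                    states.append(s2)
        for a in range(ntheta):
            for b in range(a, ntheta):
                for i in range(n):
                    expr = sum(
                        J[i, k] * states[block_index[("s2", k, a, b)]]
                        for k in range(n))
                    expr += sum(Hx[i][k][l] * s[(k, a)] * s[(l, b)]
                                for k in range(n) for l in range(n))
                    expr += sum(Jtheta[b][i][k] * s[(k, a)] for k in range(n))
                    expr += sum(Jtheta[a][i][k] * s[(k, b)] for k in range(n))
                    expr += sp.diff(f_theta[a][i], params[b])
                    rhs.append(sp.expand(expr))
                    ic.append(sp.diff(sys.initial_condition[i], params[a], params[b]))

    mass = None
    kind = sys.kind
    if sys.mass_matrix is not None and kind == "dae":
        diag = [sp.Matrix(sys.mass_matrix)[i, i] for i in range(n)]
        reps = 1 + ntheta + (ntheta * (ntheta + 1) // 2 if order == 2 else 0)
        mass = sp.diag(*(diag * reps))
    aug = SymbolicSystem(
        state_symbols=states, rhs=rhs, initial_condition=ic,
        parameter_symbols=list(sys.parameter_symbols), kind=kind, mass_matrix=mass,
        metadata={**sys.metadata, "sensitivity_order": order,
                  "sensitivity_parameters": [str(p) for p in params]})
    return SensitivitySystem(base=sys, parameters=params, order=order,
                             augmented=aug, block_index=block_index)


@dataclass
class AdjointSystem:
    """Backward adjoint machinery for a least-squares objective."""

    base: SymbolicSystem
    objective: Objective
    parameters: list
    neg_JT: sp.Matrix                  # dλ/dt = neg_JT · λ
    f_theta: sp.Matrix                 # (n, n_θ)
    obs_grad_x: list                   # per observable: list of ∂g/∂x_i
    obs_grad_theta: list               # per observable: list of ∂g/∂θ_a

    @property
    def adjoint_dimension(self) -> int:
        return self.base.n


def derive_adjoint(sys: SymbolicSystem, objective: Objective,
                   theta_subset=None) -> AdjointSystem:
    """Adjoint ODE and gradient assembly rule for an ODE base system."""
    if sys.kind != "dae" and sys.mass_matrix is not None:
        pass
    if sys.kind == "dae":
        raise ValueError("adjoint sensitivities support ODE systems only")
    params = ([sp.Symbol(str(p)) for p in theta_subset]
              if theta_subset is not None else list(sys.parameter_symbols))
    x = list(sys.state_symbols)
    f = [sp.sympify(e) for e in sys.rhs]
    J = sp.Matrix(f).jacobian(x)
    f_theta = sp.Matrix([[sp.diff(fi, p) for p in params] for fi in f])
    obs = [sp.sympify(g) for g in objective.observables]
    obs_grad_x = [[sp.diff(g, xi) for xi in x] for g in obs]
    obs_grad_theta = [[sp.diff(g, p) for p in params] for g in obs]
    return AdjointSystem(base=sys, objective=objective, parameters=params,
                         neg_JT=-J.T, f_theta=f_theta,
                         obs_grad_x=obs_grad_x, obs_grad_theta=obs_grad_theta)


# ---------------------------------------------------------------------------
# objective evaluation and gradients
# ---------------------------------------------------------------------------

def _observable_fns(sys: SymbolicSystem, observables):
    args = [TIME] + list(sys.state_symbols) + list(sys.parameter_symbols)
    return [sp.lambdify(args, sp.sympify(g), modules="numpy") for g in observables]


def _eval_objective(sys: SymbolicSystem, objective: Objective, theta,
                    tol=(1e-10, 1e-12)):
    compiled = compile_system(sys)
    tv = theta_vector(sys, theta)
    t0 = 0.0
    grid = np.concatenate([[t0], objective.times])
    sol = integrate(compiled, grid, tv, tol=tol)
    fns = _observable_fns(sys, objective.observables)
    Y = np.empty((len(objective.times), len(fns)))
    for k, t in enumerate(objective.times):
        xk = sol[k + 1]
        for o, fn in enumerate(fns):
            Y[k, o] = fn(t, *xk, *tv)
    R = Y - objective.data
    value = float(np.sum(objective.weights * R ** 2))
    return value, sol, R, tv


def gradient(objective: Objective, sys: SymbolicSystem, theta,
             method: str = "forward", fd_step: float | None = None,
             theta_subset=None, tol=(1e-10, 1e-12)):
    """Gradient of the weighted least-squares objective.

    Returns ``(grad, value)`` with one gradient entry per parameter in
    ``theta_subset`` (default: all system parameters), computed by forward
    sensitivities, the adjoint sweep, or central finite differences.
    """
    if method == "forward":
        return _gradient_forward(objective, sys, theta, theta_subset, tol)
    if method == "adjoint":
        return _gradient_adjoint(objective, sys, theta, theta_subset, tol)
    if method == "finite_differences":
        return _gradient_fd(objective, sys, theta, theta_subset, fd_step, tol)
    raise ValueError("method must be forward, adjoint or finite_differences")


def _gradient_forward(objective, sys, theta, theta_subset, tol):
    sens = derive_forward_sensitivities(sys, theta_subset, order=1)
    params = sens.parameters
    compiled = compile_system(sens.augmented)
    tv = theta_vector(sys, theta)
    grid = np.concatenate([[0.0], objective.times])
    sol = integrate(compiled, grid, tv, tol=tol)
    n = sens.n_base
    fns = _observable_fns(sys, objective.observables)
    gx_fns = [[sp.lambdify([TIME] + list(sys.state_symbols) + list(sys.parameter_symbols),
                           sp.diff(sp.sympify(g), xi), modules="numpy")
               for xi in sys.state_symbols] for g in objective.observables]
    gth_fns = [[sp.lambdify([TIME] + list(sys.state_symbols) + list(sys.parameter_symbols),
                            sp.diff(sp.sympify(g), p), modules="numpy")
                for p in params] for g in objective.observables]
    grad = np.zeros(len(params))
    value = 0.0
    for k, t in enumerate(objective.times):
        row = sol[k + 1]
        xk = row[:n]
        for o in range(len(fns)):
            y = fns[o](t, *xk, *tv)
            r = y - objective.data[k, o]
            w = objective.weights[k, o]
            value += w * r * r
            gx = np.array([g(t, *xk, *tv) for g in gx_fns[o]], dtype=float)
            for a in range(len(params)):
                s_a = np.array([row[sens.block_index[("s", i, a)]] for i in range(n)])
                grad[a] += 2 * w * r * (gx @ s_a + gth_fns[o][a](t, *xk, *tv))
    return grad, float(value)


def _gradient_adjoint(objective, sys, theta, theta_subset, tol):
    from scipy.integrate import solve_ivp

    adj = derive_adjoint(sys, objective, theta_subset)
    params = adj.parameters
    ntheta = len(params)
    n = sys.n
    tv = theta_vector(sys, theta)
    compiled = compile_system(sys)
    t0, tT = 0.0, float(objective.times[-1])
    grid = np.concatenate([[t0], objective.times])
    rtol, atol = tol

    fwd = solve_ivp(lambda t, x: compiled.rhs_fn(t, x, tv), (t0, tT),
                    compiled.x0_fn(tv), method="LSODA", dense_output=True,
                    rtol=rtol, atol=atol,
                    jac=lambda t, x: compiled.jac_fn(t, x, tv))
    if not fwd.success:
        raise RuntimeError(f"forward solve failed in adjoint sweep: {fwd.message}")
    xfun = fwd.sol

    args = [TIME] + list(sys.state_symbols) + list(sys.parameter_symbols)
    negJT_fn = sp.lambdify(args, adj.neg_JT.tolist(), modules="numpy")
    ftheta_fn = sp.lambdify(args, adj.f_theta.tolist(), modules="numpy")
    fns = _observable_fns(sys, objective.observables)
    gx_fns = [sp.lambdify(args, gx, modules="numpy") for gx in
              [sp.Matrix(row).T.tolist()[0] if False else row for row in adj.obs_grad_x]]
    gth_fns = [sp.lambdify(args, row, modules="numpy") for row in adj.obs_grad_theta]

    def back_rhs(t, z):
        lam = z[:n]
        x = xfun(t)
        A = np.asarray(negJT_fn(t, *x, *tv), dtype=float)
        dlam = A @ lam
        F = np.asarray(ftheta_fn(t, *x, *tv), dtype=float).reshape(n, ntheta)
        # quadrature runs backward in t, so negate to accumulate +∫ λᵀ f_θ dt
        dq = -(F.T @ lam)
        return np.concatenate([dlam, dq])

    lam = np.zeros(n)
    quad = np.zeros(ntheta)
    grad = np.zeros(ntheta)
    value = 0.0
    times = list(objective.times)
    # walk measurement times backwards, applying residual jumps
    for k in range(len(times) - 1, -1, -1):
        tk = times[k]
        xk = xfun(tk)
        for o in range(len(fns)):
            y = fns[o](tk, *xk, *tv)
            r = y - objective.data[k, o]
            w = objective.weights[k, o]
            value += w * r * r
            lam = lam + 2 * w * r * np.asarray(gx_fns[o](tk, *xk, *tv), dtype=float)
            grad += 2 * w * r * np.asarray(gth_fns[o](tk, *xk, *tv), dtype=float)
        t_lower = times[k - 1] if k > 0 else t0
        if tk > t_lower:
            z = np.concatenate([lam, quad])
            back = solve_ivp(back_rhs, (tk, t_lower), z, method="LSODA",
                             rtol=rtol, atol=atol)
            if not back.success:
                raise RuntimeError(f"adjoint backward solve failed: {back.message}")
            lam = back.y[:n, -1]
            quad = back.y[n:, -1]
    grad += quad
    # boundary term: λ(0)ᵀ ∂x₀/∂θ
    x0_theta = sp.Matrix([[sp.diff(e, p) for p in params]
                          for e in sys.initial_condition])
    x0th = np.asarray(sp.lambdify(list(sys.parameter_symbols), x0_theta.tolist(),
                                  modules="numpy")(*tv), dtype=float).reshape(n, ntheta)
    grad += x0th.T @ lam
    return grad, float(value)


def _gradient_fd(objective, sys, theta, theta_subset, fd_step, tol):
    params = ([str(p) for p in theta_subset] if theta_subset is not None
              else [str(p) for p in sys.parameter_symbols])
    tv = theta_vector(sys, theta)
    names = [str(p) for p in sys.parameter_symbols]
    value, _, _, _ = _eval_objective(sys, objective, tv, tol)
    grad = np.zeros(len(params))
    for a, pname in enumerate(params):
        i = names.index(pname)
        step = (fd_step if fd_step is not None
                else max(FD_REL_STEP * abs(tv[i]), FD_ABS_FLOOR))
        up, dn = tv.copy(), tv.copy()
        up[i] += step
        dn[i] -= step
        v_up, _, _, _ = _eval_objective(sys, objective, up, tol)
        v_dn, _, _, _ = _eval_objective(sys, objective, dn, tol)
        grad[a] = (v_up - v_dn) / (2 * step)
    return grad, float(value)


def objective_value(objective: Objective, sys: SymbolicSystem, theta,
                    tol=(1e-10, 1e-12)) -> float:
    """The weighted least-squares objective at θ (no gradient)."""
    value, _, _, _ = _eval_objective(sys, objective, theta, tol)
    return value
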