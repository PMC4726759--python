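"""System size expansion: RRE, LNA, EMRE and IOS orders.

The expansion writes the count state as ``x = Ω φ + √Ω ξ`` where ``φ``
solves the macroscopic reaction rate equations and ``ξ`` carries the
fluctuations.  Substituting into the master-equation generator and
collecting powers of ``h = Ω^{−1/2}`` yields, order by order,

* ``RRE``  — dφ/dt = S f(φ, t);
* ``LNA``  — the leading covariance Σ of ξ:
  dΣ/dt = J Σ + Σ Jᵀ + S diag(f) Sᵀ with J the Jacobian of S f;
* ``EMRE`` — the O(h) mean of ξ, driven by the propensity Hessians
  contracted with Σ and by the combinatorial sub-leading propensity terms
  (the −1 in x(x−1)); the corrected mean in counts is Ωφ + ⟨ξ⟩₁;
* ``IOS``  — the next covariance correction, coupling the third and fourth
  ξ-moments at their leading orders.

Rather than transcribing textbook correction formulas, this module performs
the expansion mechanically: the generator applied to ξ-monomials is
expanded symbolically in ``h``, formal expectations replace ξ-monomials by
order-resolved moment symbols (with the parity rule that ⟨ξ^K⟩ has no h^k
component when |K|+k is odd), and the ODEs for each tracked component are
read off.  Exact cancellation of the divergent h^{−1} terms against the
macroscopic drift is asserted during derivation, which catches any
mis-scaled propensity.

Each reaction is brought to macroscopic scaling by splitting the volume
into the expansion parameter and a frozen numeric copy: a propensity of
total degree d is multiplied by (Ω_ref/Ω)^{d−1}, which leaves its value
unchanged at the actual volume while making the h-series start at h⁰.
Higher-order corrections never feed back into lower orders, so an IOS
system contains the EMRE, LNA and RRE systems as closed sub-blocks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import sympy as sp

from .network import ReactionNetwork, stoichiometry_matrix
from .symbolic import SymbolicSystem, compile_system, integrate
from .moments import MomentTrajectory

ORDER_TAGS = ("RRE", "LNA", "EMRE", "IOS")

_OMEGA_FROZEN = sp.Symbol("Omega_ref", positive=True)


class SSEDerivationError(ValueError):
    pass


@dataclass
class SSESystem:
    order_tag: str
    symbolic: SymbolicSystem
    species_names: list
    state_map: dict               # label -> state position, labels like ("phi", i)
    net: ReactionNetwork | None = None

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def block(self, kind: str) -> dict:
        """State positions of one block ('phi', 'S0', 'a1', 'V2', 'T3', 'Q4')."""
        return {lab: pos for lab, pos in self.state_map.items() if lab[0] == kind}


def _sym_indices(n, order):
    """Nondecreasing index tuples (symmetric tensor storage)."""
    return list(itertools.combinations_with_replacement(range(n), order))


def _moment_symbol(kind, key):
    return sp.Symbol(f"sse_{kind}_" + "_".join(map(str, key)))


def derive_sse(net: ReactionNetwork, order_tag: str) -> SSESystem:
    """Derive the expansion ODE system at the requested order."""
    if order_tag not in ORDER_TAGS:
        raise ValueError(f"order_tag must be one of {ORDER_TAGS}")
    n = net.n_species
    syms = net.species_symbols
    S = stoichiometry_matrix(net)
    h = sp.Symbol("h_sse", positive=True)
    phi = [sp.Symbol(f"sse_phi_{name}") for name in net.species_names]
    xi = [sp.Symbol(f"sse_xi_{i}") for i in range(n)]

    # --- per-reaction h-series of the scaled propensity -------------------
    E = []
    for j, a in enumerate(net.propensities()):
        try:
            poly = sp.Poly(a, *syms)
        except sp.PolynomialError:
            raise SSEDerivationError(
                f"reaction {j} ({net.reactions[j].name or a}) has a non-polynomial "
                "propensity; Taylor-expand it before deriving the expansion") from None
        d = max((sum(p) for p, _ in poly.terms()), default=0)
        subs = {s: phi[i] / h ** 2 + xi[i] / h for i, s in enumerate(syms)}
        expr = a.subs(subs, simultaneous=True) * h ** 2 * (_OMEGA_FROZEN * h ** 2) ** (d - 1)
        expr = sp.expand(expr)
        pol = sp.Poly(expr, h)
        if any(k[0] < 0 for k in pol.monoms()):
            raise SSEDerivationError(f"reaction {j} does not admit macroscopic scaling")
        E.append(expr)

    # macroscopic rates: h^0 coefficient at xi = 0
    f = [sp.expand(Ej.subs({x: 0 for x in xi}, simultaneous=True)).coeff(h, 0)
         for Ej in E]
    phidot = [sp.expand(sum(sp.Integer(int(S[i, j])) * f[j] for j in range(len(E))))
              for i in range(n)]

    # --- tracked moment blocks by tag -------------------------------------
    blocks = [("phi", 1)]
    if order_tag in ("LNA", "EMRE", "IOS"):
        blocks.append(("S0", 2))
    if order_tag in ("EMRE", "IOS"):
        blocks.append(("a1", 1))
    if order_tag == "IOS":
        blocks += [("T3", 3), ("Q4", 4), ("V2", 2)]

    kind_of = {("a1", 1): 1, ("S0", 2): 0, ("V2", 2): 2, ("T3", 3): 1, ("Q4", 4): 0}
    tracked: dict = {}
    for kind, order in blocks:
        if kind == "phi":
            continue
        for key in _sym_indices(n, order):
            tracked[(order, kind_of[(kind, order)], key)] = _moment_symbol(kind, key)

    def expect(monom_powers, h_budget):
        """⟨ξ^K⟩ as a truncated h-series of tracked symbols."""
        order = sum(monom_powers)
        if order == 0:
            return sp.Integer(1)
        key = tuple(sorted(itertools.chain.from_iterable(
            [i] * p for i, p in enumerate(monom_powers))))
        out = sp.Integer(0)
        for k in range(0, h_budget + 1):
            if (order + k) % 2 != 0:
                continue
            symb = tracked.get((order, k, key))
            if symb is not None:
                out += h ** k * symb
        return out

    max_h = {1: 1, 2: 2, 3: 1, 4: 0}

    def generator_series(I_powers):
        """h-series of d⟨ξ^I⟩/dt with drift subtraction, as {h_order: expr}."""
        parts = []
        base = math.prod(
            [sp.Integer(1)] + [xi[i] ** p for i, p in enumerate(I_powers) if p])
        for j in range(len(E)):
            shifted = math.prod(
                [sp.Integer(1)] + [(xi[i] + h * int(S[i, j])) ** p
                                   for i, p in enumerate(I_powers) if p])
            parts.append(E[j] * (shifted - base))
        total = sp.expand(sum(parts) / h ** 2)
        for i, p in enumerate(I_powers):
            if p:
                lower = math.prod(
                    [sp.Integer(1)] + [xi[k] ** (I_powers[k] - (1 if k == i else 0))
                                       for k in range(n)
                                       if I_powers[k] - (1 if k == i else 0) > 0])
                total -= p * phidot[i] * lower / h
        total = sp.expand(total * h ** 2)  # polynomial in h iff consistent
        pol = sp.Poly(total, h)
        budget = max_h[sum(I_powers)]
        out = {k: sp.Integer(0) for k in range(budget + 1)}
        for mono in pol.monoms():
            k = mono[0] - 2
            cexpr = pol.coeff_monomial(h ** mono[0])
            if k < 0:
                if sp.expand(cexpr) != 0:
                    raise SSEDerivationError(
                        "divergent terms failed to cancel; propensity scaling inconsistent")
                continue
            if k > budget:
                continue
            poly_xi = sp.Poly(sp.expand(cexpr), *xi) if any(
                x in cexpr.free_symbols for x in xi) else None
            if poly_xi is None:
                out[k] += cexpr
                continue
            acc = sp.Integer(0)
            for powers, coeff in poly_xi.terms():
                acc += coeff * expect(powers, budget - k)
            accp = sp.Poly(sp.expand(acc), h)
            for mono2 in accp.monoms():
                kk = k + mono2[0]
                if kk <= budget:
                    out[kk] += accp.coeff_monomial(h ** mono2[0])
        return {k: sp.expand(v) for k, v in out.items()}

    # --- assemble the ODE system ------------------------------------------
    states, rhs, ic = [], [], []
    state_map = {}
    x0 = net.initial_state
    for i in range(n):
        state_map[("phi", i)] = len(states)
        states.append(phi[i])
        rhs.append(phidot[i])
        ic.append(sp.Integer(int(x0[i])) / _OMEGA_FROZEN)

    moment_eqs: dict = {}
    if order_tag != "RRE":
        orders = {2}
        if order_tag in ("EMRE", "IOS"):
            orders.add(1)
        if order_tag == "IOS":
            orders.update({3, 4})
        for order in sorted(orders):
            for key in _sym_indices(n, order):
                powers = [0] * n
                for i in key:
                    powers[i] += 1
                moment_eqs[(order, key)] = generator_series(tuple(powers))

    for kind, order in blocks:
        if kind == "phi":
            continue
        korder = kind_of[(kind, order)]
        for key in _sym_indices(n, order):
            state_map[(kind,) + key] = len(states)
            states.append(tracked[(order, korder, key)])
            rhs.append(moment_eqs[(order, key)][korder])
            ic.append(sp.Integer(0))

    params = net.parameter_symbols + [_OMEGA_FROZEN]
    sym_sys = SymbolicSystem(
        state_symbols=states, rhs=rhs, initial_condition=ic,
        parameter_symbols=params, kind="ode",
        metadata={"method": "SSE", "order_tag": order_tag, "network": net.name})
    return SSESystem(order_tag=order_tag, symbolic=sym_sys,
                     species_names=list(net.species_names),
                     state_map=state_map, net=net)


def simulate_sse(sys: SSESystem, t_grid, theta, omega: float = 1.0,
                 tol=(1e-8, 1e-10), units: str = "molecule_numbers") -> MomentTrajectory:
    """Integrate an expansion system; report mean/covariance in counts.

    Mean in counts: Ωφ (+ the EMRE correction at EMRE/IOS order).
    Covariance in counts: Ω·Σ (+ the IOS correction at IOS order).
    ``units='concentrations'`` divides the mean by Ω and the covariance
    by Ω².
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if isinstance(theta, dict):
        theta = {**theta, str(_OMEGA_FROZEN): float(omega)}
    else:
        theta = list(theta) + [float(omega)]
    compiled = compile_system(sys.symbolic)
    sol = integrate(compiled, t_grid, theta, tol=tol)
    times = np.asarray(t_grid, float)
    n = sys.n_species
    tag = sys.order_tag

    means = np.empty((len(times), n))
    for i in range(n):
        means[:, i] = omega * sol[:, sys.state_map[("phi", i)]]
    if tag in ("EMRE", "IOS"):
        for i in range(n):
            means[:, i] += sol[:, sys.state_map[("a1", i)]]

    central = {}
    if tag != "RRE":
        for (i, j) in _sym_indices(n, 2):
            cov = omega * sol[:, sys.state_map[("S0", i, j)]]
            if tag == "IOS":
                cov = cov + sol[:, sys.state_map[("V2", i, j)]]
                cov = cov - (sol[:, sys.state_map[("a1", i)]]
                             * sol[:, sys.state_map[("a1", j)]])
            idx = [0] * n
            idx[i] += 1
            idx[j] += 1
            central[tuple(idx)] = cov
    if units == "concentrations":
        means = means / omega
        central = {k: v / omega ** 2 for k, v in central.items()}
    traj = MomentTrajectory(
        times=times, species_names=list(sys.species_names), means=means,
        central=central,
        metadata={"method": tag, "omega": omega, "units": units})
    traj.check_flags()
    return traj
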