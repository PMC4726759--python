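"""Moment equations of arbitrary order with selectable closures.

For a multi-index ``I`` over the species, the raw moment ``⟨x^I⟩`` obeys

    d⟨x^I⟩/dt = ⟨ Σ_j a_j(x,t) ((x+ν_j)^I − x^I) ⟩ ,

which for polynomial propensities is a linear combination of raw moments.
Truncating at total order ``m`` leaves right-hand sides that reference
moments of order up to ``m + (max propensity degree − 1)``; a *closure*
substitutes those by expressions in the retained moments:

``low_dispersion``
    central moments of order > m are set to zero;
``zero_cumulants``
    cumulants of order > m are set to zero and the higher raw moments are
    rebuilt through the moment–cumulant recursion (order 2 gives the
    Gaussian relations, e.g. ⟨x³⟩ = 3μσ² + μ³);
``mean_field``
    a higher raw moment factorises as ⟨x^I⟩ = ⟨x_s⟩·⟨x^{I−e_s}⟩ where ``s``
    is the lexicographically first species present in ``I`` (the canonical
    "peel" rule — the literature leaves the split under-determined, so we
    fix and document this one);
``derivative_matching``
    ⟨x^I⟩ = ∏_{1≤|J|≤m} ⟨x^J⟩^{γ_J} with exponents solving the binomial
    moment-matching linear system, so the substitution is exact for a
    deterministic (point-mass) distribution;
``user``
    a caller-supplied substitution map.

The order-1 system with the combinatorial sub-leading terms of mass-action
propensities dropped is the macroscopic reaction rate equation
(:func:`derive_rre`), exact for networks with at most linear propensities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .network import TIME, ReactionNetwork, stoichiometry_matrix
from .symbolic import (
    SymbolicSystem,
    compile_system,
    integrate,
    taylor_expand_propensity,
)

CLOSURES = ("low_dispersion", "mean_field", "zero_cumulants", "derivative_matching", "user")


# ---------------------------------------------------------------------------
# multi-index bookkeeping
# ---------------------------------------------------------------------------

MomentIndex = tuple  # nonnegative integer multi-index over species


def moment_indices(n_s: int, order: int, min_order: int = 1) -> list[tuple]:
    """All multi-indices with min_order ≤ |I| ≤ order, by total order then lex."""
    out = []
    for total in range(min_order, order + 1):
        out.extend(sorted(_compositions(total, n_s), reverse=True))
    return out


def _compositions(total: int, n: int):
    if n == 1:
        yield (total,)
        return
    for first in range(total, -1, -1):
        for rest in _compositions(total - first, n - 1):
            yield (first,) + rest


def moment_state_count(n_s: int, m: int) -> int:
    """Number of moment state variables up to order m: C(n_s+m, m) − 1."""
    return math.comb(n_s + m, m) - 1


def raw_symbol(idx: tuple) -> sp.Symbol:
    return sp.Symbol("m_" + "_".join(map(str, idx)))


def central_symbol(idx: tuple) -> sp.Symbol:
    return sp.Symbol("c_" + "_".join(map(str, idx)))


def mean_symbol(i: int, n_s: int) -> sp.Symbol:
    e = tuple(1 if k == i else 0 for k in range(n_s))
    return raw_symbol(e)


def _idx_of(symbol) -> tuple:
    return tuple(int(v) for v in str(symbol)[2:].split("_"))


def _binom_prod(a: tuple, b: tuple) -> int:
    return math.prod(math.comb(ai, bi) for ai, bi in zip(a, b))


def _sub_indices(idx: tuple):
    """All J with 0 ≤ J ≤ I componentwise."""
    return itertools.product(*(range(i + 1) for i in idx))


def _monomial_to_moments(expr, species_syms):
    """Replace species monomials in a polynomial by raw-moment symbols."""
    poly = sp.Poly(sp.expand(expr), *species_syms)
    out = sp.Integer(0)
    for powers, coeff in poly.terms():
        if all(p == 0 for p in powers):
            out += coeff
        else:
            out += coeff * raw_symbol(tuple(powers))
    return out


def raw_in_central(idx: tuple):
    """⟨x^I⟩ as a polynomial in means and central moments (C_{e_i} ≡ 0)."""
    n = len(idx)
    mu = [mean_symbol(i, n) for i in range(n)]
    expr = sp.Integer(0)
    for j in _sub_indices(idx):
        order_j = sum(j)
        if order_j == 1:
            continue  # first central moments vanish
        cj = sp.Integer(1) if order_j == 0 else central_symbol(j)
        coeff = _binom_prod(idx, j)
        mu_pow = math.prod(
            [sp.Integer(1)] + [mu[i] ** (idx[i] - j[i]) for i in range(n) if idx[i] > j[i]])
        expr += coeff * mu_pow * cj
    return sp.expand(expr)


def central_in_raw(idx: tuple):
    """Central moment C_I as a polynomial in raw moments (means included)."""
    n = len(idx)
    mu = [mean_symbol(i, n) for i in range(n)]
    expr = sp.Integer(0)
    for j in _sub_indices(idx):
        order_j = sum(j)
        mj = sp.Integer(1) if order_j == 0 else raw_symbol(j)
        coeff = _binom_prod(idx, j)
        sign_pow = math.prod(
            [sp.Integer(1)] + [(-mu[i]) ** (idx[i] - j[i]) for i in range(n) if idx[i] > j[i]])
        expr += coeff * sign_pow * mj
    return sp.expand(expr)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MomentSystem:
    order: int
    kind: str                      # {"raw", "central_plus_mean"}
    units: str                     # {"molecule_numbers", "concentrations"}
    symbolic: SymbolicSystem
    closure: str                   # {"none"} ∪ CLOSURES
    closure_map: dict = field(default_factory=dict)
    species_names: list = field(default_factory=list)
    indices: list = field(default_factory=list)
    net: ReactionNetwork | None = None

    @property
    def higher_order_symbols(self):
        """Moment symbols of order > m still present in the RHS."""
        keep = {raw_symbol(i) for i in self.indices} | {central_symbol(i) for i in self.indices}
        keep |= set(self.symbolic.parameter_symbols) | {TIME}
        stray = set()
        for e in self.symbolic.rhs:
            stray |= sp.sympify(e).free_symbols - keep
        return sorted(stray, key=str)


@dataclass
class MomentTrajectory:
    """Mean and central-moment time courses, engine-agnostic.

    ``means`` has shape (n_times, n_species); ``central`` maps multi-indices
    of order ≥ 2 to per-time arrays.  ``flags`` records diagnostics such as
    negative-variance or non-PSD-covariance detections (violations are
    flagged, never silently clipped).
    """

    times: np.ndarray
    species_names: list
    means: np.ndarray
    central: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def _i(self, name: str) -> int:
        return self.species_names.index(name)

    def mean(self, name: str) -> np.ndarray:
        return self.means[:, self._i(name)]

    def variance(self, name: str) -> np.ndarray:
        i = self._i(name)
        idx = tuple(2 if k == i else 0 for k in range(self.n_species))
        return self.central[idx]

    def covariance(self, name_a: str, name_b: str) -> np.ndarray:
        i, j = self._i(name_a), self._i(name_b)
        if i == j:
            return self.variance(name_a)
        idx = tuple(1 if k in (i, j) else 0 for k in range(self.n_species))
        return self.central[idx]

    def covariance_matrix(self, time_index: int) -> np.ndarray:
        n = self.n_species
        C = np.full((n, n), np.nan)
        names = self.species_names
        for i in range(n):
            for j in range(i, n):
                try:
                    C[i, j] = C[j, i] = self.covariance(names[i], names[j])[time_index]
                except KeyError:
                    pass
        return C

    def check_flags(self, tol: float = 1e-8) -> dict:
        """Populate diagnostics for negative variances / non-PSD covariances."""
        neg = []
        for i, name in enumerate(self.species_names):
            idx = tuple(2 if k == i else 0 for k in range(self.n_species))
            if idx in self.central and np.any(self.central[idx] < -tol):
                neg.append(name)
        self.flags["negative_variance"] = neg
        non_psd = []
        if self.central:
            for k in range(len(self.times)):
                C = self.covariance_matrix(k)
                if not np.any(np.isnan(C)):
                    scale = max(1.0, float(np.abs(C).max()))
                    if np.linalg.eigvalsh(C).min() < -tol * scale:
                        non_psd.append(float(self.times[k]))
        self.flags["non_psd_times"] = non_psd
        return self.flags


# ---------------------------------------------------------------------------
# macroscopic limit (RRE)
# ---------------------------------------------------------------------------

def macroscopic_rate(prop, species_syms):
    """The macroscopic rate function of one propensity.

    For polynomial propensities this is the highest-total-degree homogeneous
    part (``k₂x(x−1) → k₂φ²``), which drops the combinatorial corrections of
    mass-action counting; non-polynomial propensities are used verbatim.
    """
    prop = sp.sympify(prop)
    try:
        poly = sp.Poly(prop, *species_syms)
    except sp.PolynomialError:
        return prop
    deg = max((sum(p) for p, _ in poly.terms()), default=0)
    out = sp.Integer(0)
    for powers, coeff in poly.terms():
        if sum(powers) == deg:
            out += coeff * math.prod(
                [sp.Integer(1)] + [s ** p for s, p in zip(species_syms, powers) if p])
    return out


def derive_rre(net: ReactionNetwork, units: str = "molecule_numbers") -> SymbolicSystem:
    """Reaction rate equations dφ/dt = Σ_j ν_j f_j(φ, t)."""
    syms = net.species_symbols
    S = stoichiometry_matrix(net)
    rates = [macroscopic_rate(a, syms) for a in net.propensities()]
    rhs = [sp.expand(sum(sp.Integer(int(S[i, j])) * rates[j] for j in range(net.n_reactions)))
           for i in range(net.n_species)]
    x0 = [sp.Integer(s.initial_amount) for s in net.species]
    if units == "concentrations":
        vols = [sp.Float(net.volume_of(s.name)) for s in net.species]
        subs = {sym: sym * v for sym, v in zip(syms, vols)}
        rhs = [sp.expand(e.subs(subs, simultaneous=True) / v) for e, v in zip(rhs, vols)]
        x0 = [ic / v for ic, v in zip(x0, vols)]
    return SymbolicSystem(
        state_symbols=list(syms), rhs=rhs, initial_condition=x0,
        parameter_symbols=net.parameter_symbols, kind="ode",
        metadata={"method": "RRE", "units": units, "network": net.name},
    )


# ---------------------------------------------------------------------------
# moment-equation derivation
# ---------------------------------------------------------------------------

def _polynomial_propensities(net: ReactionNetwork, taylor_order: int | None):
    syms = net.species_symbols
    props = []
    n = net.n_species
    for j, a in enumerate(net.propensities()):
        try:
            sp.Poly(a, *syms)
            props.append(a)
        except sp.PolynomialError:
            if taylor_order is None:
                raise ValueError(
                    f"propensity of reaction {j} ({a}) is not polynomial; "
                    "pass taylor_order to expand it about the means") from None
            center = {s: mean_symbol(i, n) for i, s in enumerate(syms)}
            props.append(taylor_expand_propensity(a, center, taylor_order))
    return props


def derive_moment_equations(net: ReactionNetwork, order: int,
                            units: str = "molecule_numbers",
                            kind: str = "raw",
                            taylor_order: int | None = None) -> MomentSystem:
    """Exact (unclosed) moment equations up to total order ``m``.

    Raw representation: states are ⟨x^I⟩ for 1 ≤ |I| ≤ m.  The
    central-plus-mean representation carries the means plus central moments
    of order 2..m and is derived independently (not by converting the raw
    system), so the two routes cross-validate each other symbolically.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    syms = net.species_symbols
    n = net.n_species
    props = _polynomial_propensities(net, taylor_order)
    S = stoichiometry_matrix(net)

    def gen(fpoly):
        total = sp.Integer(0)
        for j, a in enumerate(props):
            shifted = fpoly.subs(
                {s: s + int(S[i, j]) for i, s in enumerate(syms) if S[i, j] != 0},
                simultaneous=True)
            total += a * (shifted - fpoly)
        return sp.expand(total)

    indices = moment_indices(n, order)
    x0 = net.initial_state

    if kind == "raw":
        states = [raw_symbol(i) for i in indices]
        rhs = []
        for idx in indices:
            mono = math.prod([sp.Integer(1)] + [s ** p for s, p in zip(syms, idx) if p])
            rhs.append(_monomial_to_moments(gen(mono), syms))
        ic = [sp.Integer(math.prod(int(x0[i]) ** idx[i] for i in range(n)))
              for idx in indices]
    elif kind == "central_plus_mean":
        states, rhs, ic = _derive_central(order, gen, syms, x0)
    else:
        raise ValueError("kind must be 'raw' or 'central_plus_mean'")

    sym_sys = SymbolicSystem(
        state_symbols=states, rhs=rhs, initial_condition=ic,
        parameter_symbols=net.parameter_symbols, kind="ode",
        metadata={"method": "MM", "order": order, "kind": kind, "units": units,
                  "network": net.name})
    msys = MomentSystem(order=order, kind=kind, units=units, symbolic=sym_sys,
                        closure="none", species_names=net.species_names,
                        indices=indices, net=net)
    if units == "concentrations":
        _to_concentrations(msys)
    return msys


def _derive_central(order, gen, syms, x0):
    """Independent derivation of the central-moment representation.

    Uses d⟨(x−μ)^I⟩/dt = ⟨G (x−μ)^I⟩ − Σ_i I_i ⟨(x−μ)^{I−e_i}⟩ μ̇_i with μ
    held symbolic inside the generator application.
    """
    n = len(syms)
    indices = moment_indices(n, order)
    mu = [mean_symbol(i, n) for i in range(n)]

    def to_central(expr):
        expr = sp.sympify(expr)
        subs = {}
        for s in expr.free_symbols:
            if str(s).startswith("m_"):
                idx = _idx_of(s)
                if sum(idx) >= 2:
                    subs[s] = raw_in_central(idx)
        return sp.expand(expr.xreplace(subs))

    mean_rhs = [to_central(_monomial_to_moments(gen(s), syms)) for s in syms]

    states, rhs, ic = [], [], []
    for i in range(n):
        states.append(mu[i])
        rhs.append(mean_rhs[i])
        ic.append(sp.Integer(int(x0[i])))
    for idx in indices:
        if sum(idx) < 2:
            continue
        shifted = math.prod(
            [sp.Integer(1)] + [(s - m_) ** p for s, m_, p in zip(syms, mu, idx) if p])
        g = gen(sp.expand(shifted))
        expr = to_central(_monomial_to_moments(g, syms))
        for i in range(n):
            if idx[i] > 0:
                lower = tuple(idx[k] - (1 if k == i else 0) for k in range(n))
                if sum(lower) == 1:
                    c_lower = sp.Integer(0)
                elif sum(lower) == 0:
                    c_lower = sp.Integer(1)
                else:
                    c_lower = central_symbol(lower)
                expr -= idx[i] * c_lower * mean_rhs[i]
        states.append(central_symbol(idx))
        rhs.append(sp.expand(expr))
        ic.append(sp.Integer(0))  # deterministic initial state
    return states, rhs, ic


def _to_concentrations(msys: MomentSystem) -> None:
    """Rescale a raw count-moment system to concentration moments in place."""
    if msys.kind != "raw":
        raise ValueError("concentration rescaling operates on the raw representation")
    net = msys.net
    vols = [net.volume_of(name) for name in msys.species_names]

    def scale(idx):
        return math.prod(v ** p for v, p in zip(vols, idx))

    all_syms = {}
    for e in msys.symbolic.rhs:
        for s in sp.sympify(e).free_symbols:
            if str(s).startswith("m_"):
                all_syms[s] = _idx_of(s)
    subs = {s: sp.Float(scale(idx)) * s for s, idx in all_syms.items()}
    new_rhs = []
    for state, e in zip(msys.symbolic.state_symbols, msys.symbolic.rhs):
        idx = _idx_of(state)
        new_rhs.append(sp.expand(sp.sympify(e).xreplace(subs) / scale(idx)))
    msys.symbolic.rhs = new_rhs
    msys.symbolic.initial_condition = [
        ic / scale(idx) for ic, idx in zip(msys.symbolic.initial_condition, msys.indices)]


# ---------------------------------------------------------------------------
# closures
# ---------------------------------------------------------------------------

class ClosureError(ValueError):
    pass


def _closure_expression(idx, m, n_s, scheme, memo):
    """Raw-moment substitution for a single index of order > m."""
    if idx in memo:
        return memo[idx]
    if scheme == "low_dispersion":
        expr = raw_in_central(idx)
        csubs = {}
        for s in expr.free_symbols:
            if str(s).startswith("c_"):
                j = _idx_of(s)
                csubs[s] = sp.Integer(0) if sum(j) > m else central_in_raw(j)
        expr = sp.expand(expr.xreplace(csubs))
    elif scheme == "zero_cumulants":
        expr = _zero_cumulant_moment(idx, m, memo)
    elif scheme == "mean_field":
        s = next(i for i, v in enumerate(idx) if v > 0)
        e_s = tuple(1 if k == s else 0 for k in range(n_s))
        rest = tuple(idx[k] - e_s[k] for k in range(n_s))
        rest_expr = (raw_symbol(rest) if sum(rest) <= m
                     else _closure_expression(rest, m, n_s, scheme, memo))
        expr = sp.expand(raw_symbol(e_s) * rest_expr)
    elif scheme == "derivative_matching":
        expr = _derivative_matching_moment(idx, m, n_s)
    else:
        raise ClosureError(f"unknown closure scheme '{scheme}'")
    memo[idx] = expr
    return expr


def _cumulants_in_raw(n_s, m):
    """κ_J (|J| ≤ m) in terms of raw moments via the multivariate recursion."""
    kappa = {}
    for idx in moment_indices(n_s, m):
        i = next(k for k, v in enumerate(idx) if v > 0)
        e = tuple(1 if k == i else 0 for k in range(n_s))
        rest = tuple(idx[k] - e[k] for k in range(n_s))
        expr = raw_symbol(idx)
        for j in _sub_indices(rest):
            if j == rest:
                continue  # that term is κ_idx itself
            kj = tuple(j[k] + e[k] for k in range(n_s))
            mj = tuple(rest[k] - j[k] for k in range(n_s))
            m_part = sp.Integer(1) if sum(mj) == 0 else raw_symbol(mj)
            expr -= _binom_prod(rest, j) * kappa[kj] * m_part
        kappa[idx] = sp.expand(expr)
    return kappa


_KAPPA_CACHE: dict = {}


def _zero_cumulant_moment(idx, m, memo):
    n_s = len(idx)
    if (n_s, m) not in _KAPPA_CACHE:
        _KAPPA_CACHE[(n_s, m)] = _cumulants_in_raw(n_s, m)
    kappa = _KAPPA_CACHE[(n_s, m)]
    i = next(k for k, v in enumerate(idx) if v > 0)
    e = tuple(1 if k == i else 0 for k in range(n_s))
    rest = tuple(idx[k] - e[k] for k in range(n_s))
    expr = sp.Integer(0)
    for j in _sub_indices(rest):
        kj = tuple(j[k] + e[k] for k in range(n_s))
        if sum(kj) > m:
            continue  # cumulant of order > m set to zero
        mj = tuple(rest[k] - j[k] for k in range(n_s))
        if sum(mj) == 0:
            m_part = sp.Integer(1)
        elif sum(mj) <= m:
            m_part = raw_symbol(mj)
        elif mj in memo:
            m_part = memo[mj]
        else:
            m_part = _zero_cumulant_moment(mj, m, memo)
            memo[mj] = m_part
        expr += _binom_prod(rest, j) * kappa[kj] * m_part
    return sp.expand(expr)


_DM_CACHE: dict = {}


def _derivative_matching_moment(idx, m, n_s):
    """Product form with binomially matched exponents.

    γ solves Σ_{1≤|K|≤m} γ_K · C(K, L) = C(I, L) for all 1 ≤ |L| ≤ m with
    C(A, B) = ∏_i binom(A_i, B_i), making the substitution exact when the
    distribution is a point mass.
    """
    key = (n_s, m, idx)
    if key in _DM_CACHE:
        return _DM_CACHE[key]
    lower = moment_indices(n_s, m)
    A = np.array([[_binom_prod(K, L) for K in lower] for L in lower], dtype=float)
    b = np.array([_binom_prod(idx, L) for L in lower], dtype=float)
    gamma = np.linalg.solve(A, b)
    expr = sp.Integer(1)
    for g, K in zip(gamma, lower):
        if abs(g) < 1e-12:
            continue
        g_exact = sp.nsimplify(g, rational=True, tolerance=1e-9)
        expr *= raw_symbol(K) ** g_exact
    _DM_CACHE[key] = expr
    return expr


def apply_closure(msys: MomentSystem, scheme: str, user_map: dict | None = None) -> MomentSystem:
    """Close a moment system: substitute every moment symbol of order > m."""
    if msys.closure != "none":
        raise ClosureError("system is already closed")
    if msys.kind != "raw":
        raise ClosureError("closures operate on the raw representation; "
                           "derive with kind='raw' (convert afterwards if needed)")
    if scheme not in CLOSURES:
        raise ClosureError(f"unknown closure '{scheme}', choose from {CLOSURES}")
    m, n_s = msys.order, len(msys.species_names)
    higher = {}
    for s in msys.higher_order_symbols:
        name = str(s)
        if not name.startswith("m_"):
            raise ClosureError(f"unexpected symbol '{name}' in unclosed system")
        higher[s] = _idx_of(s)

    memo: dict = {}
    if scheme == "user":
        subs = {
            (raw_symbol(k) if isinstance(k, tuple) else sp.Symbol(str(k))): sp.sympify(v)
            for k, v in (user_map or {}).items()}
        missing = [str(s) for s in higher if s not in subs]
        if missing:
            raise ClosureError(f"user closure leaves unresolved: {', '.join(sorted(missing))}")
    else:
        subs = {s: _closure_expression(idx, m, n_s, scheme, memo)
                for s, idx in higher.items()}

    new_rhs = [sp.expand(sp.sympify(e).xreplace(subs)) for e in msys.symbolic.rhs]
    sym_sys = SymbolicSystem(
        state_symbols=list(msys.symbolic.state_symbols), rhs=new_rhs,
        initial_condition=list(msys.symbolic.initial_condition),
        parameter_symbols=list(msys.symbolic.parameter_symbols), kind="ode",
        metadata={**msys.symbolic.metadata, "closure": scheme})
    closed = MomentSystem(order=m, kind=msys.kind, units=msys.units, symbolic=sym_sys,
                          closure=scheme, closure_map={str(k): v for k, v in subs.items()},
                          species_names=msys.species_names, indices=msys.indices,
                          net=msys.net)
    leftover = closed.higher_order_symbols
    if leftover:
        raise ClosureError(f"closure left unresolved symbols: {leftover}")
    return closed


# ---------------------------------------------------------------------------
# simulation and statistics
# ---------------------------------------------------------------------------

def simulate_moments(msys: MomentSystem, t_grid, theta,
                     tol=(1e-8, 1e-10)) -> MomentTrajectory:
    """Integrate a closed moment system and return mean/central trajectories."""
    if msys.higher_order_symbols:
        raise ClosureError("system is unclosed; apply_closure first")
    compiled = compile_system(msys.symbolic)
    from .symbolic import IntegrationError
    try:
        with np.errstate(all="ignore"):
            sol = integrate(compiled, t_grid, theta, tol=tol)
    except IntegrationError as exc:
        raise IntegrationError(
            f"moment integration failed (method=MM, order={msys.order}, "
            f"closure={msys.closure}): {exc}", t_fail=exc.t_fail,
            last_state=exc.last_state) from exc
    if not np.all(np.isfinite(sol)):
        raise IntegrationError(
            f"moment integration diverged (method=MM, order={msys.order}, "
            f"closure={msys.closure})")
    return moment_trajectory_from_solution(msys, np.asarray(t_grid, float), sol)


def moment_trajectory_from_solution(msys: MomentSystem, times, sol) -> MomentTrajectory:
    n = len(msys.species_names)
    values = {_idx_of(s): sol[:, k] for k, s in enumerate(msys.symbolic.state_symbols)}
    means = np.stack([values[tuple(1 if k == i else 0 for k in range(n))]
                      for i in range(n)], axis=1)
    central = {}
    if msys.kind == "raw":
        for idx in msys.indices:
            if sum(idx) < 2:
                continue
            acc = np.zeros(len(times))
            for j in _sub_indices(idx):
                coeff = _binom_prod(idx, j)
                mu_pow = np.ones(len(times))
                for i in range(n):
                    if idx[i] > j[i]:
                        mu_pow = mu_pow * (-means[:, i]) ** (idx[i] - j[i])
                m_val = np.ones(len(times)) if sum(j) == 0 else values[j]
                acc = acc + coeff * mu_pow * m_val
            central[idx] = acc
    else:  # central_plus_mean: non-mean states are already central
        central = {idx: arr for idx, arr in values.items() if sum(idx) >= 2}
    traj = MomentTrajectory(
        times=np.asarray(times, float), species_names=list(msys.species_names),
        means=means, central=central,
        metadata={"method": "MM", "order": msys.order, "closure": msys.closure,
                  "units": msys.units})
    traj.check_flags()
    return traj


def correlation_maps(traj: MomentTrajectory):
    """Per-time correlation and partial-correlation matrices.

    Entries whose defining variances vanish are reported as NaN (absent,
    not zero).  If the covariance matrix is singular at some time, the
    partial correlations for that time are NaN and a diagnostic is recorded.
    """
    if not traj.central:
        raise ValueError("trajectory carries no second-order moments")
    T, n = len(traj.times), traj.n_species
    corr = np.full((T, n, n), np.nan)
    partial = np.full((T, n, n), np.nan)
    diagnostics = []
    for k in range(T):
        C = traj.covariance_matrix(k)
        if np.any(np.isnan(C)):
            diagnostics.append((float(traj.times[k]), "incomplete covariance"))
            continue
        sd = np.sqrt(np.clip(np.diag(C), 0.0, None))
        ok = sd > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ck = C / np.outer(sd, sd)
        ck[~np.outer(ok, ok)] = np.nan
        np.fill_diagonal(ck, np.where(ok, 1.0, np.nan))
        corr[k] = ck
        sub = np.ix_(ok, ok)
        Csub = C[sub]
        if Csub.size and np.linalg.matrix_rank(Csub) == Csub.shape[0]:
            K = np.linalg.inv(Csub)
            d = np.sqrt(np.abs(np.diag(K)))
            pk = -K / np.outer(d, d)
            np.fill_diagonal(pk, 1.0)
            pview = np.full((n, n), np.nan)
            pview[sub] = pk
            partial[k] = pview
        else:
            diagnostics.append((float(traj.times[k]), "singular covariance"))
    return {"correlation": corr, "partial_correlation": partial,
            "diagnostics": diagnostics}


def trajectory_to_frame(traj: MomentTrajectory):
    """Long-format export: one row per (time, moment index, value)."""
    import pandas as pd

    rows = []
    for k, t in enumerate(traj.times):
        for i, name in enumerate(traj.species_names):
            rows.append({"time": t, "kind": "mean", "index": name,
                         "value": traj.means[k, i]})
        for idx, arr in sorted(traj.central.items()):
            rows.append({"time": t, "kind": "central",
                         "index": "_".join(map(str, idx)), "value": arr[k]})
    return pd.DataFrame(rows)
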