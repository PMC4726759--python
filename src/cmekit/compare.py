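"""Cross-method comparison: run any description and measure relative errors.

The accuracy of an approximate description is quantified against a
reference (FSP or a large SSA ensemble) through the relative errors of the
mean and variance, |μ_method − μ_ref| / μ_ref, per species and time.  The
closure benchmark sweeps truncation orders × closure schemes and reports a
grid of steady-state errors; configurations whose integration diverges
(derivative matching is the usual culprit) are reported as ``failed``
rather than as a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ReactionNetwork
from .symbolic import IntegrationError, compile_system, integrate
from .moments import (
    MomentTrajectory,
    apply_closure,
    derive_moment_equations,
    derive_rre,
    simulate_moments,
)
from .sse import derive_sse, simulate_sse
from .mcm import derive_mcm, partition_species, reconstruct_overall_moments, simulate_mcm
from .fsp import enumerate_states, fsp_moments, solve_fsp
from .ssa import ensemble_moments, simulate_direct, simulate_modified_next_reaction


@dataclass
class MethodSpec:
    """One description to run: method name plus its options."""

    method: str                        # ssa | fsp | rre | lna | emre | ios | mm | mcm
    order: int | None = None           # mm / mcm truncation order
    closure: str | None = None         # mm / mcm closure
    bounds: dict | None = None         # fsp truncation bounds
    n_paths: int | None = None         # ssa ensemble size
    seed: int | None = None            # ssa seed
    partition: object | None = None    # mcm partition (default: auto)

    def label(self) -> str:
        if self.method in ("mm", "mcm"):
            return f"{self.method.upper()}{self.order}({self.closure})"
        return self.method.upper()

    def validate(self) -> list[str]:
        problems = []
        if self.method not in ("ssa", "fsp", "rre", "lna", "emre", "ios", "mm", "mcm"):
            problems.append(f"unknown method '{self.method}'")
        if self.closure is not None and self.method not in ("mm", "mcm"):
            problems.append(f"closure option is invalid for method '{self.method}'")
        if self.order is not None and self.method not in ("mm", "mcm"):
            problems.append(f"order option is invalid for method '{self.method}'")
        if self.method in ("mm", "mcm") and self.order is None:
            problems.append(f"method '{self.method}' requires an order")
        if self.method == "ssa" and self.seed is None:
            problems.append("ssa requires a seed for reproducibility")
        if self.method == "fsp" and not self.bounds:
            problems.append("fsp requires truncation bounds")
        return problems


def run_method(net: ReactionNetwork, spec: MethodSpec, t_grid, theta=None
               ) -> MomentTrajectory:
    """Execute one description and return its moment trajectory (counts)."""
    problems = spec.validate()
    if problems:
        raise ValueError("; ".join(problems))
    theta = dict(net.parameters if theta is None else theta)
    m = spec.method
    if m == "fsp":
        space = enumerate_states(net, spec.bounds)
        sol = solve_fsp(net, space, t_grid, theta)
        return fsp_moments(sol, 2)
    if m == "ssa":
        n_paths = spec.n_paths or 1000
        if net.is_time_dependent() or any(r.delay for r in net.reactions):
            ens = simulate_modified_next_reaction(net, t_grid, n_paths, spec.seed, theta)
        else:
            ens = simulate_direct(net, t_grid, n_paths, spec.seed, theta)
        return ensemble_moments(ens, 2).to_trajectory()
    if m == "rre":
        sys = derive_rre(net)
        sol = integrate(compile_system(sys), t_grid, theta)
        return MomentTrajectory(times=np.asarray(t_grid, float),
                                species_names=net.species_names, means=sol,
                                metadata={"method": "RRE"})
    if m in ("lna", "emre", "ios"):
        return simulate_sse(derive_sse(net, m.upper()), t_grid, theta)
    if m == "mm":
        msys = derive_moment_equations(net, spec.order)
        closed = apply_closure(msys, spec.closure or "low_dispersion")
        return simulate_moments(closed, t_grid, theta)
    if m == "mcm":
        part = spec.partition or partition_species(net, "auto")
        msys = derive_mcm(net, part, spec.order, spec.closure or "low_dispersion")
        return reconstruct_overall_moments(simulate_mcm(msys, t_grid, theta))
    raise ValueError(f"unknown method '{m}'")


def relative_errors(traj: MomentTrajectory, ref: MomentTrajectory,
                    species: list[str] | None = None) -> pd.DataFrame:
    """Per-time relative errors of mean and variance against the reference.

    Errors are always reported relative to the declared reference; the
    comparison never swaps the roles of the two trajectories.
    """
    if not np.allclose(traj.times, ref.times):
        raise ValueError("trajectories must share the time grid")
    species = species or [s for s in traj.species_names if s in ref.species_names]
    rows = []
    for name in species:
        mu, mu_ref = traj.mean(name), ref.mean(name)
        with np.errstate(divide="ignore", invalid="ignore"):
            err_mu = np.abs(mu - mu_ref) / np.abs(mu_ref)
        try:
            v, v_ref = traj.variance(name), ref.variance(name)
            with np.errstate(divide="ignore", invalid="ignore"):
                err_v = np.abs(v - v_ref) / np.abs(v_ref)
        except KeyError:
            err_v = np.full(len(traj.times), np.nan)
        for k, t in enumerate(traj.times):
            rows.append({"time": t, "species": name,
                         "rel_err_mean": err_mu[k], "rel_err_variance": err_v[k]})
    return pd.DataFrame(rows)


def compare(net: ReactionNetwork, specs: list[MethodSpec], reference: MethodSpec,
            t_grid, theta=None, species: list[str] | None = None) -> pd.DataFrame:
    """Run several descriptions against one reference (fsp or ssa).

    Returns a long-format table (method, time, species, relative errors);
    a method whose simulation diverges appears with status ``failed`` and
    no numbers.
    """
    if reference.method not in ("fsp", "ssa"):
        raise ValueError("reference must be fsp or ssa")
    ref = run_method(net, reference, t_grid, theta)
    frames = []
    for spec in specs:
        label = spec.label()
        try:
            traj = run_method(net, spec, t_grid, theta)
        except (IntegrationError, FloatingPointError, OverflowError) as exc:
            frames.append(pd.DataFrame([{
                "method": label, "status": "failed", "detail": str(exc)[:200]}]))
            continue
        df = relative_errors(traj, ref, species)
        df.insert(0, "method", label)
        df["status"] = "ok"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def closure_benchmark(net: ReactionNetwork, orders, closures, t_star: float,
                      reference: MomentTrajectory, species: str,
                      methods=("mm",), theta=None, t_grid=None,
                      partition=None) -> pd.DataFrame:
    """Order × closure grid of steady-state relative errors vs a reference.

    One row per (method, order, closure) with the relative errors of mean
    and variance of ``species`` at ``t_star``; configurations that cannot
    be simulated (divergence) carry status ``failed`` and NaN errors, so
    no approximation error is reported for them.
    """
    if t_grid is None:
        t_grid = [0.0, t_star]
    k_ref = int(np.argmin(np.abs(reference.times - t_star)))
    mu_ref = reference.mean(species)[k_ref]
    var_ref = reference.variance(species)[k_ref]
    rows = []
    for method in methods:
        for order in orders:
            for closure in closures:
                entry = {"method": method.upper(), "order": order, "closure": closure}
                spec = MethodSpec(method=method, order=order, closure=closure,
                                  partition=partition)
                try:
                    with np.errstate(all="ignore"):
                        traj = run_method(net, spec, t_grid, theta)
                    k = int(np.argmin(np.abs(traj.times - t_star)))
                    mu = traj.mean(species)[k]
                    var = traj.variance(species)[k]
                    if not (np.isfinite(mu) and np.isfinite(var)):
                        raise IntegrationError("non-finite moments")
                    entry.update(status="ok",
                                 rel_err_mean=abs(mu - mu_ref) / abs(mu_ref),
                                 rel_err_variance=abs(var - var_ref) / abs(var_ref))
                except (IntegrationError, FloatingPointError, OverflowError,
                        ZeroDivisionError) as exc:
                    entry.update(status="failed", rel_err_mean=np.nan,
                                 rel_err_variance=np.nan, detail=str(exc)[:120])
                rows.append(entry)
    return pd.DataFrame(rows)
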