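"""Built-in benchmark networks.

These fixtures are the study conditions for the whole package: every engine
is validated against them, and the acceptance checks instantiate them with
the defaults documented here.

``birth_death``
    ∅ → X at constant rate k, X → ∅ at rate γ·x.  Linear propensities, so
    the chemical master equation has the closed-form solution
    X(t) ~ Poisson(k/γ·(1−e^{−γt})) from X(0)=0: mean and variance are both
    10(1−e^{−t}) at the defaults k=10, γ=1.

``dimerization``
    ∅ → X at k₁, 2X → ∅ with propensity k₂·x(x−1).  The simplest genuinely
    nonlinear network: moment equations do not close, the reaction rate
    equation is biased, and EMRE corrections are exercised.

``three_stage_gene_expression``
    A gene whose promoter switches between an off- and an on-state,
    transcription in the on-state, translation, degradation of mRNA and
    protein, and a protein-induced promoter activation (positive feedback).
    Species (G_off, G_on, M, P) with the conservation law G_off + G_on = 1.
    The mix of a single-copy promoter with medium-copy mRNA/protein makes
    this the canonical test for the hybrid conditional-moment description.

``timedep_birth``
    ∅ → X with the time-dependent propensity a(t) = b₀(1 + sin ωt) and no
    degradation, so X(t) ~ Poisson(∫₀ᵗ a(s) ds): X(2π) ~ Poisson(2π b₀) at
    the defaults b₀=5, ω=1.

``two_compartment_chain``
    A signalling cascade over a cytoplasmic and a nuclear compartment:
    activation of S driven by the input u(t), dimerization of the activated
    form, nuclear import, a 5-step linear chain of nuclear intermediates
    (modelling delayed export) and export back to the cytoplasm.
"""

from __future__ import annotations

import sympy as sp

from .network import (
    Compartment,
    InputSignal,
    Observable,
    Reaction,
    ReactionNetwork,
    Species,
    mass_action,
)

FIXTURE_NAMES = (
    "birth_death",
    "dimerization",
    "three_stage_gene_expression",
    "timedep_birth",
    "two_compartment_chain",
)

#: Documented fixture parameter defaults.
DEFAULTS = {
    "birth_death": {"k": 10.0, "gamma": 1.0},
    "dimerization": {"k1": 4.0, "k2": 0.01},
    "three_stage_gene_expression": {
        "tau_on": 0.1,     # basal promoter activation G_off -> G_on
        "tau_off": 0.3,    # promoter deactivation G_on -> G_off
        "tau_fb": 0.005,   # feedback activation G_off + P -> G_on + P (per protein)
        "k_m": 4.0,        # transcription in the on-state
        "k_p": 2.0,        # translation per mRNA
        "gamma_m": 1.0,    # mRNA degradation
        "gamma_p": 0.2,    # protein degradation
    },
    "timedep_birth": {"b0": 5.0, "omega": 1.0},
    "two_compartment_chain": {
        "k_act": 0.1,   # input-driven activation S -> Sp
        "k_dim": 0.05,  # dimerization 2 Sp -> Spd
        "k_imp": 0.2,   # nuclear import Spd -> nSp1
        "k_ch": 0.3,    # chain progression / export rate
    },
}

#: Default initial amounts (species not listed start at 0).
INITIALS = {
    "birth_death": {},
    "dimerization": {},
    "three_stage_gene_expression": {"G_off": 1},
    "timedep_birth": {},
    "two_compartment_chain": {"S": 50},
}


def make_fixture(name: str, overrides: dict | None = None) -> ReactionNetwork:
    """Return one of the documented benchmark networks.

    ``overrides`` may replace any parameter value; keys of the form
    ``"<species>_0"`` override an initial amount.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture '{name}'; choose from {FIXTURE_NAMES}")
    overrides = dict(overrides or {})
    params = dict(DEFAULTS[name])
    initials = dict(INITIALS[name])
    for key in list(overrides):
        if key.endswith("_0") and key[:-2] not in params:
            initials[key[:-2]] = overrides.pop(key)
        elif key in params:
            params[key] = overrides.pop(key)
    if overrides:
        raise ValueError(f"unknown override(s) for fixture '{name}': {sorted(overrides)}")
    builder = {
        "birth_death": _birth_death,
        "dimerization": _dimerization,
        "three_stage_gene_expression": _three_stage,
        "timedep_birth": _timedep_birth,
        "two_compartment_chain": _two_compartment_chain,
    }[name]
    return builder(params, initials)


def _birth_death(p, init) -> ReactionNetwork:
    k, gamma, x = sp.symbols("k gamma X")
    return ReactionNetwork(
        species=[Species("X", initial_amount=init.get("X", 0))],
        reactions=[
            Reaction({}, {"X": 1}, k, kinetics="mass_action", name="birth"),
            Reaction({"X": 1}, {}, gamma * x, kinetics="mass_action", name="death"),
        ],
        parameters=dict(p),
        observables=[Observable("X_count", x)],
        name="birth_death",
    )


def _dimerization(p, init) -> ReactionNetwork:
    k1, k2, x = sp.symbols("k1 k2 X")
    return ReactionNetwork(
        species=[Species("X", initial_amount=init.get("X", 0))],
        reactions=[
            Reaction({}, {"X": 1}, k1, kinetics="mass_action", name="birth"),
            # propensity written without the 1/2 convention on purpose: the
            # rate constant k2 multiplies the ordered-pair count x(x-1)
            Reaction({"X": 2}, {}, k2 * x * (x - 1), kinetics="general", name="dimerize"),
        ],
        parameters=dict(p),
        observables=[Observable("X_count", x)],
        name="dimerization",
    )


def _three_stage(p, init) -> ReactionNetwork:
    g_off, g_on, m, prot = sp.symbols("G_off G_on M P")
    tau_on, tau_off, tau_fb, k_m, k_p, gamma_m, gamma_p = sp.symbols(
        "tau_on tau_off tau_fb k_m k_p gamma_m gamma_p")
    return ReactionNetwork(
        species=[
            Species("G_off", initial_amount=init.get("G_off", 1), abundance_class="low_copy"),
            Species("G_on", initial_amount=init.get("G_on", 0), abundance_class="low_copy"),
            Species("M", initial_amount=init.get("M", 0)),
            Species("P", initial_amount=init.get("P", 0)),
        ],
        reactions=[
            Reaction({"G_off": 1}, {"G_on": 1}, tau_on * g_off, kinetics="mass_action", name="activate"),
            Reaction({"G_on": 1}, {"G_off": 1}, tau_off * g_on, kinetics="mass_action", name="deactivate"),
            Reaction({"G_off": 1, "P": 1}, {"G_on": 1, "P": 1}, tau_fb * g_off * prot,
                     kinetics="mass_action", name="feedback_activate"),
            Reaction({"G_on": 1}, {"G_on": 1, "M": 1}, k_m * g_on, kinetics="mass_action", name="transcribe"),
            Reaction({"M": 1}, {"M": 1, "P": 1}, k_p * m, kinetics="mass_action", name="translate"),
            Reaction({"M": 1}, {}, gamma_m * m, kinetics="mass_action", name="mrna_decay"),
            Reaction({"P": 1}, {}, gamma_p * prot, kinetics="mass_action", name="protein_decay"),
        ],
        parameters=dict(p),
        observables=[Observable("protein", prot), Observable("mrna", m)],
        name="three_stage_gene_expression",
    )


def _timedep_birth(p, init) -> ReactionNetwork:
    b0, omega, t = sp.symbols("b0 omega t")
    return ReactionNetwork(
        species=[Species("X", initial_amount=init.get("X", 0))],
        reactions=[
            Reaction({}, {"X": 1}, b0 * (1 + sp.sin(omega * t)), kinetics="general", name="birth"),
        ],
        parameters=dict(p),
        observables=[Observable("X_count", sp.Symbol("X"))],
        name="timedep_birth",
    )


def _two_compartment_chain(p, init) -> ReactionNetwork:
    t = sp.Symbol("t")
    k_act, k_dim, k_imp, k_ch = sp.symbols("k_act k_dim k_imp k_ch")
    s, spho, sd = sp.symbols("S Sp Spd")
    chain = [sp.Symbol(f"nSp{i}") for i in range(1, 6)]
    u = sp.Symbol("u")

    species = [
        Species("S", "cytoplasm", init.get("S", 50)),
        Species("Sp", "cytoplasm", init.get("Sp", 0)),
        Species("Spd", "cytoplasm", init.get("Spd", 0)),
    ] + [Species(f"nSp{i}", "nucleus", init.get(f"nSp{i}", 0)) for i in range(1, 6)]

    reactions = [
        Reaction({"S": 1}, {"Sp": 1}, k_act * u * s, kinetics="general", name="activate"),
        mass_action(k_dim, {"Sp": 2}, {"Spd": 1}, name="dimerize"),
        Reaction({"Spd": 1}, {"nSp1": 1}, k_imp * sd, kinetics="mass_action", name="import"),
    ]
    for i in range(1, 5):
        reactions.append(Reaction({f"nSp{i}": 1}, {f"nSp{i+1}": 1}, k_ch * chain[i - 1],
                                  kinetics="mass_action", name=f"chain_{i}"))
    reactions.append(Reaction({"nSp5": 1}, {"S": 2}, k_ch * chain[4],
                              kinetics="mass_action", name="export"))

    return ReactionNetwork(
        species=species,
        reactions=reactions,
        parameters=dict(p),
        compartments=[Compartment("cytoplasm", 1.0), Compartment("nucleus", 1.0)],
        inputs=[InputSignal("u", sp.exp(-t / 5) * (1 - sp.exp(-t)))],
        observables=[Observable("dimer", sd), Observable("free", s)],
        name="two_compartment_chain",
    )
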