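"""Built-in catalog of full/QSS-reduced model pairs.

Five classic systems in which a fast species is eliminated by a
quasi-steady-state argument, each exposed as a :class:`~qssakit.network.ModelPair`
with its full network, reduced network, QSS map and default parameters:

``genetic_nfl``
    Transcriptional negative feedback: a repressor R binds a single promoter
    (fraction D_A active); standard QSSA gives Hill transcription
    alpha_M*K_D/(K_D+R) with K_D = k_b/k_f.  Concentrations scaled by total
    DNA, so D_A + D_R = 1.  Units h^-1.
``coop_enzyme``
    Cooperative two-step enzyme kinetics; QSSA (valid when Km1 >> Km2) gives
    consumption k_p*S^2/(Km^2+S^2), Km^2 = Km1*Km2.  Scaled by total enzyme
    (E + E_S + E_S2 = 1).  Units s^-1.
``oscillator``
    A three-stage negative-feedback oscillator with repressor-DNA binding.
    Two reductions: total QSSA (tQSSA, in T = R + D_R, fast variable solved
    from a quadratic) and prefactor QSSA (pQSSA, in R, with multiplier
    p(R) = 1 + D_T*K_d/(R+K_d)^2).  K_d = (k_b + beta_R)/k_f.  Units h^-1.
``composite_nfl``
    Negative feedback with enzymatic degradation; three partial reductions:
    ER (enzymatic step reduced to Michaelis-Menten), DR (DNA binding reduced
    to a Hill function) and EDR (both).  Units s^-1.
``linear_cascade``
    Constitutive transcription/translation; eliminating mRNA leaves a birth-
    death process for protein.  The fast variable (mRNA) is unbounded.
    Closed-form stationary variances are available for both models.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .network import (
    DefinitionError,
    ModelPair,
    RateLaw,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
    apply_conservation,
)

__all__ = [
    "CATALOG",
    "CatalogEntry",
    "make_genetic_nfl",
    "make_genetic_nfl_unscaled",
    "make_coop_enzyme",
    "make_oscillator",
    "make_composite_nfl",
    "make_linear_cascade",
    "closed_form_variances",
    "CascadeVariances",
]


def _merge(defaults: dict, overrides: dict) -> dict:
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise DefinitionError(f"unknown parameters {sorted(unknown)}")
    out = dict(defaults)
    out.update(overrides)
    for k, v in out.items():
        if isinstance(v, (int, float)) and v <= 0 and k not in ("M0", "R0", "P0", "S0", "DA0"):
            raise DefinitionError(f"parameter {k} must be positive, got {v}")
    return out


# ---------------------------------------------------------------------------
# genetic negative feedback loop
# ---------------------------------------------------------------------------

GENETIC_DEFAULTS = dict(
    K_D=10.0, alpha_M=300.0, alpha_R=1.0, beta_M=1.0, beta_R=1.0, k_f=10.0,
    M0=100.0, R0=100.0, DA0=0.0,
)


def make_genetic_nfl(**overrides) -> ModelPair:
    """Full (promoter binding explicit) vs standard-QSSA Hill reduction.

    ``k_b`` is derived as ``K_D * k_f``; networks built with different
    ``k_f`` at fixed ``K_D`` share a bit-identical reduction.  ``alpha_R``
    defaults to 1/h (not fixed by the reference parameter set).
    """
    k_b = overrides.pop("k_b", None)
    p = _merge(GENETIC_DEFAULTS, overrides)
    if k_b is not None:
        if "K_D" in overrides and not math.isclose(k_b, p["K_D"] * p["k_f"]):
            raise DefinitionError("inconsistent K_D, k_f, k_b")
        p["K_D"] = k_b / p["k_f"]
    k_b = p["K_D"] * p["k_f"]

    full = ReactionNetwork(
        [
            SpeciesSpec("M", "slow", p["M0"]),
            SpeciesSpec("R", "slow", p["R0"]),
            SpeciesSpec("D_A", "fast", p["DA0"], 0.0, 1.0),
            SpeciesSpec("D_R", "eliminated", 1.0 - p["DA0"], 0.0, 1.0),
        ],
        [
            Reaction("transcription", {}, {"M": 1},
                     RateLaw("closed_form", expression="alpha_M*D_A",
                             parameters={"alpha_M": p["alpha_M"]})),
            Reaction("mRNA_decay", {"M": 1}, {}, RateLaw("mass_action", p["beta_M"])),
            Reaction("translation", {}, {"R": 1},
                     RateLaw("closed_form", expression="alpha_R*M",
                             parameters={"alpha_R": p["alpha_R"]})),
            Reaction("repressor_decay", {"R": 1}, {}, RateLaw("mass_action", p["beta_R"])),
            Reaction("binding", {"R": 1, "D_A": 1}, {"D_R": 1},
                     RateLaw("mass_action", p["k_f"])),
            Reaction("unbinding", {"D_R": 1}, {"R": 1, "D_A": 1},
                     RateLaw("mass_action", k_b)),
        ],
        conservation_laws=[({"D_A": 1, "D_R": 1}, 1.0)],
        name="genetic_nfl_full",
    )
    full = apply_conservation(full)

    reduced = ReactionNetwork(
        [SpeciesSpec("M", "slow", p["M0"]), SpeciesSpec("R", "slow", p["R0"])],
        [
            Reaction("transcription", {}, {"M": 1},
                     RateLaw("closed_form", expression="alpha_M*K_D/(K_D + R)",
                             parameters={"alpha_M": p["alpha_M"], "K_D": p["K_D"]})),
            Reaction("mRNA_decay", {"M": 1}, {}, RateLaw("mass_action", p["beta_M"])),
            Reaction("translation", {}, {"R": 1},
                     RateLaw("closed_form", expression="alpha_R*M",
                             parameters={"alpha_R": p["alpha_R"]})),
            Reaction("repressor_decay", {"R": 1}, {}, RateLaw("mass_action", p["beta_R"])),
        ],
        name="genetic_nfl_reduced",
    )

    K_D = p["K_D"]
    return ModelPair(
        full=full,
        reduced=reduced,
        slow_map={"M": "M", "R": "R"},
        observable="R",
        grid_species=["D_A"],
        qss_map=lambda slow: {"D_A": K_D / (K_D + slow["R"])},
        name="genetic_nfl",
    )


def make_genetic_nfl_unscaled(D_T: int = 1, **overrides) -> ReactionNetwork:
    """The same feedback loop in absolute DNA copy numbers (no D_T scaling).

    The promoter pool has ``D_T`` copies; the binding constant becomes
    ``k_f* = k_f / D_T`` and transcription ``(alpha_M/D_T)*D_A`` so the
    macroscopic dynamics match the scaled model.  Used for copy-number
    scaling experiments: Var(D_A/D_T) shrinks as D_T grows.
    """
    p = _merge(GENETIC_DEFAULTS, overrides)
    k_b = p["K_D"] * p["k_f"]
    net = ReactionNetwork(
        [
            SpeciesSpec("M", "slow", p["M0"]),
            SpeciesSpec("R", "slow", p["R0"]),
            SpeciesSpec("D_A", "fast", p["DA0"] * D_T, 0.0, float(D_T)),
            SpeciesSpec("D_R", "eliminated", (1.0 - p["DA0"]) * D_T, 0.0, float(D_T)),
        ],
        [
            Reaction("transcription", {}, {"M": 1},
                     RateLaw("closed_form", expression="a*D_A",
                             parameters={"a": p["alpha_M"] / D_T})),
            Reaction("mRNA_decay", {"M": 1}, {}, RateLaw("mass_action", p["beta_M"])),
            Reaction("translation", {}, {"R": 1},
                     RateLaw("closed_form", expression="alpha_R*M",
                             parameters={"alpha_R": p["alpha_R"]})),
            Reaction("repressor_decay", {"R": 1}, {}, RateLaw("mass_action", p["beta_R"])),
            Reaction("binding", {"R": 1, "D_A": 1}, {"D_R": 1},
                     RateLaw("mass_action", p["k_f"] / D_T)),
            Reaction("unbinding", {"D_R": 1}, {"R": 1, "D_A": 1},
                     RateLaw("mass_action", k_b)),
        ],
        conservation_laws=[({"D_A": 1, "D_R": 1}, float(D_T))],
        name=f"genetic_nfl_unscaled_DT{D_T}",
    )
    return apply_conservation(net)


# ---------------------------------------------------------------------------
# cooperative enzyme kinetics
# ---------------------------------------------------------------------------

COOP_DEFAULTS = dict(
    k_in=0.5, kr1=100.0, kr2=100.0, k_p=1.0, Km1=2e6, Km2=0.101, S0=0.0,
)


def make_coop_enzyme(**overrides) -> ModelPair:
    """Two-step cooperative enzyme vs its Hill-type QSSA reduction.

    ``k1 = kr1/Km1`` and ``k2 = (kr2+k_p)/Km2`` are derived, so varying the
    unbinding rates at fixed Km1, Km2 leaves the reduced network identical.
    A warning (not an error) is issued when Km1 >> Km2 fails.
    """
    p = _merge(COOP_DEFAULTS, overrides)
    if p["Km1"] < 100 * p["Km2"]:
        warnings.warn(
            f"Km1={p['Km1']:g} is not much larger than Km2={p['Km2']:g}; "
            "the cooperative reduction assumes Km1 >> Km2",
            stacklevel=2,
        )
    k1 = p["kr1"] / p["Km1"]
    k2 = (p["kr2"] + p["k_p"]) / p["Km2"]
    Km_sq = p["Km1"] * p["Km2"]

    full = ReactionNetwork(
        [
            SpeciesSpec("S", "slow", p["S0"]),
            SpeciesSpec("E", "eliminated", 1.0, 0.0, 1.0),
            SpeciesSpec("E_S", "fast", 0.0, 0.0, 1.0),
            SpeciesSpec("E_S2", "fast", 0.0, 0.0, 1.0),
            SpeciesSpec("P", "slow", 0.0),
        ],
        [
            Reaction("inflow", {}, {"S": 1}, RateLaw("mass_action", p["k_in"])),
            Reaction("bind1", {"S": 1, "E": 1}, {"E_S": 1}, RateLaw("mass_action", k1)),
            Reaction("unbind1", {"E_S": 1}, {"S": 1, "E": 1}, RateLaw("mass_action", p["kr1"])),
            Reaction("bind2", {"S": 1, "E_S": 1}, {"E_S2": 1}, RateLaw("mass_action", k2)),
            Reaction("unbind2", {"E_S2": 1}, {"S": 1, "E_S": 1},
                     RateLaw("mass_action", p["kr2"])),
            Reaction("catalysis", {"E_S2": 1}, {"E_S": 1, "P": 1},
                     RateLaw("mass_action", p["k_p"])),
        ],
        conservation_laws=[({"E": 1, "E_S": 1, "E_S2": 1}, 1.0)],
        name="coop_enzyme_full",
    )
    full = apply_conservation(full)

    reduced = ReactionNetwork(
        [SpeciesSpec("S", "slow", p["S0"]), SpeciesSpec("P", "slow", 0.0)],
        [
            Reaction("inflow", {}, {"S": 1}, RateLaw("mass_action", p["k_in"])),
            Reaction("conversion", {"S": 1}, {"P": 1},
                     RateLaw("closed_form", expression="k_p*S**2/(Km_sq + S**2)",
                             parameters={"k_p": p["k_p"], "Km_sq": Km_sq})),
        ],
        name="coop_enzyme_reduced",
    )

    Km1, Km2 = p["Km1"], p["Km2"]

    def qss_map(slow: dict) -> dict:
        s = slow["S"]
        e_free = 1.0 / (1.0 + s / Km1 + s * s / (Km1 * Km2))
        return {"E_S": (s / Km1) * e_free, "E_S2": (s * s / (Km1 * Km2)) * e_free}

    return ModelPair(
        full=full,
        reduced=reduced,
        slow_map={"S": "S", "P": "P"},
        observable="S",
        grid_species=["E_S", "E_S2"],
        qss_map=qss_map,
        fast_constraint=lambda fast, slow: fast["E_S"] + fast["E_S2"] <= 1.0 + 1e-12,
        name="coop_enzyme",
    )


# ---------------------------------------------------------------------------
# negative-feedback oscillator (tQSSA / pQSSA)
# ---------------------------------------------------------------------------

OSC_DEFAULTS = dict(
    alpha_M=15.1745, alpha_P=1.0, alpha_R=1.0, beta_M=1.0, beta_P=1.0, beta_R=1.0,
    k_b=50.0, k_f=200.0, D_T=164.75,
)

_DA_OF_T = "(D_T - T - K_d + sqrt((D_T - T - K_d)**2 + 4*D_T*K_d))/2"


def _oscillator_full(p: dict) -> ReactionNetwork:
    net = ReactionNetwork(
        [
            SpeciesSpec("M", "slow", p["M0"]),
            SpeciesSpec("P", "slow", p["P0"]),
            SpeciesSpec("R", "slow", p["R0"]),
            SpeciesSpec("D_R", "fast", p["DR0"], 0.0, p["D_T"]),
            SpeciesSpec("D_A", "eliminated", p["D_T"] - p["DR0"], 0.0, p["D_T"]),
        ],
        [
            Reaction("transcription", {}, {"M": 1},
                     RateLaw("closed_form", expression="alpha_M*D_A",
                             parameters={"alpha_M": p["alpha_M"]})),
            Reaction("mRNA_decay", {"M": 1}, {}, RateLaw("mass_action", p["beta_M"])),
            Reaction("translation", {}, {"P": 1},
                     RateLaw("closed_form", expression="alpha_P*M",
                             parameters={"alpha_P": p["alpha_P"]})),
            Reaction("protein_decay", {"P": 1}, {}, RateLaw("mass_action", p["beta_P"])),
            Reaction("activation", {}, {"R": 1},
                     RateLaw("closed_form", expression="alpha_R*P",
                             parameters={"alpha_R": p["alpha_R"]})),
            Reaction("repressor_decay", {"R": 1}, {}, RateLaw("mass_action", p["beta_R"])),
            Reaction("binding", {"R": 1, "D_A": 1}, {"D_R": 1},
                     RateLaw("mass_action", p["k_f"])),
            Reaction("unbinding", {"D_R": 1}, {"R": 1, "D_A": 1},
                     RateLaw("mass_action", p["k_b"])),
            Reaction("bound_decay", {"D_R": 1}, {"D_A": 1},
                     RateLaw("mass_action", p["beta_R"])),
        ],
        conservation_laws=[({"D_A": 1, "D_R": 1}, p["D_T"])],
        name="oscillator_full",
    )
    return apply_conservation(net)


@functools.lru_cache(maxsize=8)
def _limit_cycle_state(param_items: tuple) -> tuple:
    """A point on the full model's deterministic limit cycle (past transients)."""
    from .ode import integrate

    p = dict(param_items)
    p.update(M0=10.0, P0=10.0, R0=10.0, DR0=0.0)
    full = _oscillator_full(p)
    final = integrate(full, t_end=200.0, n_out=400, rtol=1e-8, atol=1e-10).final_state()
    return tuple(sorted(final.items()))


def make_oscillator(reduction: str = "tqssa", **overrides) -> ModelPair:
    """Full oscillator vs its total-QSSA or prefactor-QSSA reduction.

    K_d = (k_b + beta_R)/k_f (the constant appearing in the QSS root and the
    prefactor).  Default initial conditions lie on the deterministic limit
    cycle of the full model, located by integrating past transients.
    The pQSSA reduced network carries the prefactor p(R); its stochastic
    counterpart (``reduced.without_prefactor()``) uses the reduced reaction
    rates as propensities on the untransformed variable.
    """
    if reduction not in ("tqssa", "pqssa"):
        raise DefinitionError(f"unknown reduction {reduction!r}")
    p = _merge(OSC_DEFAULTS, overrides)
    K_d = (p["k_b"] + p["beta_R"]) / p["k_f"]
    D_T = p["D_T"]
    lc = dict(_limit_cycle_state(tuple(sorted(p.items()))))
    p = dict(p, M0=lc["M"], P0=lc["P"], R0=lc["R"], DR0=lc["D_R"])
    full = _oscillator_full(p)

    common = {"alpha_M": p["alpha_M"], "K_d": K_d, "D_T": D_T}
    if reduction == "tqssa":
        reduced = ReactionNetwork(
            [
                SpeciesSpec("M", "slow", p["M0"]),
                SpeciesSpec("P", "slow", p["P0"]),
                SpeciesSpec("T", "slow", p["R0"] + p["DR0"]),
            ],
            [
                Reaction("transcription", {}, {"M": 1},
                         RateLaw("closed_form", expression=f"alpha_M*({_DA_OF_T})",
                                 parameters=common)),
                Reaction("mRNA_decay", {"M": 1}, {}, RateLaw("mass_action", p["beta_M"])),
                Reaction("translation", {}, {"P": 1},
                         RateLaw("closed_form", expression="alpha_P*M",
                                 parameters={"alpha_P": p["alpha_P"]})),
                Reaction("protein_decay", {"P": 1}, {}, RateLaw("mass_action", p["beta_P"])),
                Reaction("activation", {}, {"T": 1},
                         RateLaw("closed_form", expression="alpha_R*P",
                                 parameters={"alpha_R": p["alpha_R"]})),
                Reaction("total_decay", {"T": 1}, {}, RateLaw("mass_action", p["beta_R"])),
            ],
            name="oscillator_tqssa",
        )

        def qss_map(slow: dict) -> dict:
            return {"D_R": D_T - qss_DA_of_T(slow["T"], D_T, K_d)}

        def embed(slow: dict, fast: dict) -> dict:
            d_r = fast["D_R"]
            return {"M": slow["M"], "P": slow["P"], "D_R": d_r, "R": slow["T"] - d_r}

        return ModelPair(
            full=full,
            reduced=reduced,
            slow_map={"M": "M", "P": "P", "T": "T"},
            observable="M",
            grid_species=["D_R"],
            qss_map=qss_map,
            embed=embed,
            fast_constraint=lambda fast, slow: fast["D_R"] <= min(D_T, slow["T"]) + 1e-12,
            name="oscillator_tqssa",
        )

    reduced = ReactionNetwork(
        [
            SpeciesSpec("M", "slow", p["M0"]),
            SpeciesSpec("P", "slow", p["P0"]),
            SpeciesSpec("R", "slow", p["R0"]),
        ],
        [
            Reaction("transcription", {}, {"M": 1},
                     RateLaw("closed_form", expression="alpha_M*D_T*K_d/(R + K_d)",
                             parameters=common)),
            Reaction("mRNA_decay", {"M": 1}, {}, RateLaw("mass_action", p["beta_M"])),
            Reaction("translation", {}, {"P": 1},
                     RateLaw("closed_form", expression="alpha_P*M",
                             parameters={"alpha_P": p["alpha_P"]})),
            Reaction("protein_decay", {"P": 1}, {}, RateLaw("mass_action", p["beta_P"])),
            Reaction("activation", {}, {"R": 1},
                     RateLaw("closed_form", expression="alpha_R*P",
                             parameters={"alpha_R": p["alpha_R"]})),
            Reaction("repressor_decay", {"R": 1},
                     {},
                     RateLaw("closed_form",
                             expression="beta_R*(R + D_T*R/(R + K_d))",
                             parameters={"beta_R": p["beta_R"], "D_T": D_T, "K_d": K_d})),
        ],
        prefactors={"R": f"1 + {D_T!r}*{K_d!r}/((R + {K_d!r})**2)"},
        name="oscillator_pqssa",
    )

    return ModelPair(
        full=full,
        reduced=reduced,
        slow_map={"M": "M", "P": "P", "R": "R"},
        observable="M",
        grid_species=["D_R"],
        qss_map=lambda slow: {"D_R": D_T * slow["R"] / (slow["R"] + K_d)},
        fast_constraint=lambda fast, slow: fast["D_R"] <= D_T + 1e-12,
        name="oscillator_pqssa",
    )


def qss_DA_of_T(T: float, D_T: float, K_d: float) -> float:
    """Active-promoter QSS as a function of total repressor (quadratic root)."""
    b = D_T - T - K_d
    return 0.5 * (b + math.sqrt(b * b + 4.0 * D_T * K_d))


# ---------------------------------------------------------------------------
# composite negative feedback (ER / DR / EDR)
# ---------------------------------------------------------------------------

COMPOSITE_DEFAULTS = dict(
    alpha_M=50.0, beta_M=1.0, k_R=1.0, k4=1.0, kr1=10.0, kr2=10.0, kr3=10.0,
    k1=1e-5, k2=100.0, K_M=110.0, D_T=0.01, E_T=1.0,
)

COMPOSITE_VARIANTS = ("full", "ER", "DR", "EDR")


def make_composite_nfl(variant: str = "EDR", **overrides) -> ModelPair:
    """Negative feedback with enzymatic degradation and composite reductions.

    ``k3 = (kr3 + k4)/K_M`` is derived; ``K_D^2 = kr1*kr2/(k1*k2)``.  The
    total enzyme E_T is not part of the reference parameter set; the default
    E_T = 1 scales concentrations by total enzyme (as in the cooperative
    model) and puts the reduced steady state near R ~ 100.  SSA for this
    entry uses volume 100 by default so the DNA total D_T = 0.01 maps to one
    promoter copy.
    """
    if variant not in COMPOSITE_VARIANTS:
        raise DefinitionError(f"unknown variant {variant!r}; pick from {COMPOSITE_VARIANTS}")
    p = _merge(COMPOSITE_DEFAULTS, overrides)
    k3 = (p["kr3"] + p["k4"]) / p["K_M"]
    K_D_sq = p["kr1"] * p["kr2"] / (p["k1"] * p["k2"])
    D_T, E_T = p["D_T"], p["E_T"]
    volume = 1.0 / D_T

    dna_species = [
        SpeciesSpec("D", "fast", D_T, 0.0, D_T),
        SpeciesSpec("D_R", "fast", 0.0, 0.0, D_T),
        SpeciesSpec("D_R2", "eliminated", 0.0, 0.0, D_T),
    ]
    enz_species = [
        SpeciesSpec("E", "eliminated", E_T, 0.0, E_T),
        SpeciesSpec("E_R", "fast", 0.0, 0.0, E_T),
    ]
    slow_species = [SpeciesSpec("M", "slow", 0.0), SpeciesSpec("R", "slow", 0.0)]

    transcription_full = Reaction(
        "transcription", {}, {"M": 1},
        RateLaw("closed_form", expression="alpha_M*(D + D_R)",
                parameters={"alpha_M": p["alpha_M"]}),
    )
    transcription_hill = Reaction(
        "transcription", {}, {"M": 1},
        RateLaw("closed_form", expression="alpha_M*D_T*K_D_sq/(K_D_sq + R**2)",
                parameters={"alpha_M": p["alpha_M"], "D_T": D_T, "K_D_sq": K_D_sq}),
    )
    mrna_decay = Reaction("mRNA_decay", {"M": 1}, {}, RateLaw("mass_action", p["beta_M"]))
    translation = Reaction(
        "translation", {}, {"R": 1},
        RateLaw("closed_form", expression="k_R*M", parameters={"k_R": p["k_R"]}),
    )
    dna_reactions = [
        Reaction("bind1", {"R": 1, "D": 1}, {"D_R": 1}, RateLaw("mass_action", p["k1"])),
        Reaction("unbind1", {"D_R": 1}, {"R": 1, "D": 1}, RateLaw("mass_action", p["kr1"])),
        Reaction("bind2", {"R": 1, "D_R": 1}, {"D_R2": 1}, RateLaw("mass_action", p["k2"])),
        Reaction("unbind2", {"D_R2": 1}, {"R": 1, "D_R": 1}, RateLaw("mass_action", p["kr2"])),
    ]
    enz_reactions = [
        Reaction("bindE", {"R": 1, "E": 1}, {"E_R": 1}, RateLaw("mass_action", k3)),
        Reaction("unbindE", {"E_R": 1}, {"R": 1, "E": 1}, RateLaw("mass_action", p["kr3"])),
        Reaction("enzymatic_decay", {"E_R": 1}, {"E": 1}, RateLaw("mass_action", p["k4"])),
    ]
    mm_degradation = Reaction(
        "degradation", {"R": 1}, {},
        RateLaw("closed_form", expression="k4*E_T*R/(K_M + R)",
                parameters={"k4": p["k4"], "E_T": E_T, "K_M": p["K_M"]}),
    )

    full = apply_conservation(ReactionNetwork(
        slow_species + dna_species + enz_species,
        [transcription_full, mrna_decay, translation] + dna_reactions + enz_reactions,
        conservation_laws=[({"D": 1, "D_R": 1, "D_R2": 1}, D_T), ({"E": 1, "E_R": 1}, E_T)],
        volume=volume,
        name="composite_nfl_full",
    ))

    if variant == "full":
        reduced, grid, constraint = full, [], None
    elif variant == "ER":
        reduced = apply_conservation(ReactionNetwork(
            slow_species + dna_species,
            [transcription_full, mrna_decay, translation] + dna_reactions + [mm_degradation],
            conservation_laws=[({"D": 1, "D_R": 1, "D_R2": 1}, D_T)],
            volume=volume,
            name="composite_nfl_ER",
        ))
        grid, constraint = ["E_R"], None
    elif variant == "DR":
        reduced = apply_conservation(ReactionNetwork(
            slow_species + enz_species,
            [transcription_hill, mrna_decay, translation] + enz_reactions,
            conservation_laws=[({"E": 1, "E_R": 1}, E_T)],
            volume=volume,
            name="composite_nfl_DR",
        ))
        grid = ["D", "D_R"]
        constraint = lambda fast, slow: fast["D"] + fast["D_R"] <= D_T + 1e-12  # noqa: E731
    else:  # EDR
        reduced = ReactionNetwork(
            slow_species,
            [transcription_hill, mrna_decay, translation, mm_degradation],
            volume=volume,
            name="composite_nfl_EDR",
        )
        grid = ["D", "D_R", "E_R"]
        constraint = lambda fast, slow: fast["D"] + fast["D_R"] <= D_T + 1e-12  # noqa: E731

    KD1 = p["kr1"] / p["k1"]
    KD2 = p["kr2"] / p["k2"]
    K_M = p["K_M"]

    def qss_map(slow: dict) -> dict:
        r = slow["R"]
        d_free = D_T / (1.0 + r / KD1 + r * r / (KD1 * KD2))
        return {
            "D": d_free,
            "D_R": (r / KD1) * d_free,
            "E_R": E_T * r / (K_M + r),
        }

    return ModelPair(
        full=full,
        reduced=reduced,
        slow_map={"M": "M", "R": "R"},
        observable="R",
        grid_species=grid,
        qss_map=lambda slow: {k: v for k, v in qss_map(slow).items() if k in grid},
        fast_constraint=constraint,
        name=f"composite_nfl_{variant}",
    )


# ---------------------------------------------------------------------------
# linear transcription/translation cascade
# ---------------------------------------------------------------------------

CASCADE_DEFAULTS = dict(alpha_M=10.0, alpha_P=1.0, k_M=1.0, k_P=0.1)


def make_linear_cascade(**overrides) -> ModelPair:
    """Constitutive expression vs the mRNA-eliminated birth-death reduction.

    The fast species (mRNA) is unbounded; the reduced model's birth rate is
    alpha_M*alpha_P/k_M.  Default initial conditions sit at the rounded
    deterministic steady state (M = alpha_M/k_M, P = alpha_M*alpha_P/(k_M*k_P)).
    """
    p = _merge(CASCADE_DEFAULTS, overrides)
    m_ss = p["alpha_M"] / p["k_M"]
    p_ss = p["alpha_M"] * p["alpha_P"] / (p["k_M"] * p["k_P"])
    full = ReactionNetwork(
        [
            SpeciesSpec("M", "fast", float(round(m_ss))),
            SpeciesSpec("P", "slow", float(round(p_ss))),
        ],
        [
            Reaction("transcription", {}, {"M": 1}, RateLaw("mass_action", p["alpha_M"])),
            Reaction("mRNA_decay", {"M": 1}, {}, RateLaw("mass_action", p["k_M"])),
            Reaction("translation", {}, {"P": 1},
                     RateLaw("closed_form", expression="alpha_P*M",
                             parameters={"alpha_P": p["alpha_P"]})),
            Reaction("protein_decay", {"P": 1}, {}, RateLaw("mass_action", p["k_P"])),
        ],
        name="linear_cascade_full",
    )
    reduced = ReactionNetwork(
        [SpeciesSpec("P", "slow", float(round(p_ss)))],
        [
            Reaction("birth", {}, {"P": 1},
                     RateLaw("mass_action", p["alpha_M"] * p["alpha_P"] / p["k_M"])),
            Reaction("protein_decay", {"P": 1}, {}, RateLaw("mass_action", p["k_P"])),
        ],
        name="linear_cascade_reduced",
    )
    return ModelPair(
        full=full,
        reduced=reduced,
        slow_map={"P": "P"},
        observable="P",
        grid_species=["M"],
        qss_map=lambda slow: {"M": m_ss},
        name="linear_cascade",
    )


@dataclass(frozen=True)
class CascadeVariances:
    """Closed-form stationary statistics of the linear cascade."""

    mean_P: float
    var_full: float
    var_qssa: float
    rel_error: float  # (sigma_full - sigma_qssa)/<P>, exact
    rel_error_approx: float  # (sqrt(alpha_P/k_M+1)-1)/sqrt(alpha_M*alpha_P/(k_P*k_M))


def closed_form_variances(**overrides) -> CascadeVariances:
    """Exact stationary mean/variances of the cascade and the CV-gap scaling.

    var_full/mean exceeds 1 by the translational burst term
    (alpha_P/k_M)/(1+k_P/k_M); the reduced model is Poisson (var = mean).
    The CV gap (sigma_full - sigma_qssa)/<P> scales like sqrt(k_P).
    """
    p = _merge(CASCADE_DEFAULTS, overrides)
    mean_p = p["alpha_M"] * p["alpha_P"] / (p["k_M"] * p["k_P"])
    var_full = mean_p * ((p["alpha_P"] / p["k_M"]) / (1.0 + p["k_P"] / p["k_M"]) + 1.0)
    var_qssa = mean_p
    rel = (math.sqrt(var_full) - math.sqrt(var_qssa)) / mean_p
    rel_approx = (math.sqrt(p["alpha_P"] / p["k_M"] + 1.0) - 1.0) / math.sqrt(mean_p)
    return CascadeVariances(mean_p, var_full, var_qssa, rel, rel_approx)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    variants: tuple
    default_params: dict  # name -> (value, unit)
    default_T: float
    time_unit: str
    observable: str
    region_species: tuple
    factory: object
    default_burn_in: float | None = None  # None: derived from slowest decay
    region_mode: str = "stationary"

    def make(self, variant: str | None = None, **overrides) -> ModelPair:
        if variant is None or len(self.variants) == 1:
            return self.factory(**overrides)
        return self.factory(variant, **overrides)


def _units(params: dict, unit: str, dimless: tuple = ()) -> dict:
    return {k: (v, "-" if k in dimless else unit) for k, v in params.items()}


CATALOG: dict[str, CatalogEntry] = {
    "genetic_nfl": CatalogEntry(
        "genetic_nfl", ("sqssa",),
        _units(GENETIC_DEFAULTS, "1/h", dimless=("K_D", "M0", "R0", "DA0")),
        20.0, "h", "R", ("M", "R"),
        lambda variant="sqssa", **kw: make_genetic_nfl(**kw),
    ),
    "coop_enzyme": CatalogEntry(
        "coop_enzyme", ("sqssa",),
        _units(COOP_DEFAULTS, "1/s", dimless=("Km1", "Km2", "S0")),
        4000.0, "s", "S", ("S",),
        lambda variant="sqssa", **kw: make_coop_enzyme(**kw),
        default_burn_in=6000.0,
    ),
    "oscillator": CatalogEntry(
        "oscillator", ("tqssa", "pqssa"),
        _units(OSC_DEFAULTS, "1/h", dimless=("D_T",)),
        40.0, "h", "M", ("M", "P", "T", "R"),
        lambda variant="tqssa", **kw: make_oscillator(variant, **kw),
        region_mode="oscillatory",
    ),
    "composite_nfl": CatalogEntry(
        "composite_nfl", COMPOSITE_VARIANTS,
        _units(COMPOSITE_DEFAULTS, "1/s", dimless=("K_M", "D_T", "E_T")),
        2000.0, "s", "R", ("M", "R"),
        lambda variant="EDR", **kw: make_composite_nfl(variant, **kw),
        default_burn_in=1500.0,
    ),
    "linear_cascade": CatalogEntry(
        "linear_cascade", ("sqssa",),
        _units(CASCADE_DEFAULTS, "1/time"),
        100.0, "time", "P", ("P",),
        lambda variant="sqssa", **kw: make_linear_cascade(**kw),
    ),
}
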