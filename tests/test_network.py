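"""Network construction, derivatives, propensities and conservation handling."""

import math

import numpy as np
import pytest
from scipy.optimize import fsolve

from qssakit import (
    DefinitionError,
    RateLaw,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
    StateError,
    apply_conservation,
    integrate,
    make_composite_nfl,
    make_genetic_nfl,
)


def test_reduced_rhs_matches_hill_arithmetic(genetic_pair):
    # alpha_M*K_D/(K_D+R) - beta_M*M at (M=100, R=0): 300*1 - 100 = 200
    rhs = genetic_pair.reduced.evaluate_rhs({"M": 100.0, "R": 0.0})
    assert rhs["M"] == pytest.approx(200.0)
    assert rhs["R"] == pytest.approx(100.0)


def test_rhs_vanishes_at_fixed_point(genetic_pair):
    # reduced model fixed point: R^2 + K_D R = alpha_M K_D / beta -> M = R = 50
    rhs = genetic_pair.reduced.evaluate_rhs({"M": 50.0, "R": 50.0})
    assert max(abs(v) for v in rhs.values()) < 1e-12


def test_full_rhs_residual_at_independent_steady_state(genetic_pair):
    """fsolve (independent root-finder) fixed point has rhs residual < 1e-10."""
    net = genetic_pair.full
    order = net.species_order
    f = net.rhs_function()
    x = fsolve(f, np.array([50.0, 50.0, 1.0 / 6.0]), full_output=False, xtol=1e-12)
    assert np.max(np.abs(f(x))) < 1e-10
    rhs = net.evaluate_rhs(dict(zip(order, x)))
    assert max(abs(v) for v in rhs.values()) < 1e-10


class TestPropensities:
    def test_mass_action_at_unit_volume(self, genetic_pair):
        a = genetic_pair.full.propensities({"M": 0, "R": 100, "D_A": 1})
        names = [r.name for r in genetic_pair.full.reactions]
        assert a[names.index("binding")] == pytest.approx(10.0 * 100 * 1)

    def test_hill_propensity_at_unit_volume(self, genetic_pair):
        a = genetic_pair.reduced.propensities({"M": 0, "R": 10})
        names = [r.name for r in genetic_pair.reduced.reactions]
        assert a[names.index("transcription")] == pytest.approx(300.0 * 10 / 20)

    def test_volume_substitution_rule(self):
        # a = Omega * k * (n_X/Omega) * (n_Y/Omega) = 2 * (4/2) * (6/2) = 12
        net = ReactionNetwork(
            [SpeciesSpec("X", initial=2.0), SpeciesSpec("Y", initial=3.0)],
            [Reaction("rxn", {"X": 1, "Y": 1}, {}, RateLaw("mass_action", 1.0))],
            volume=2.0,
        )
        assert net.propensities({"X": 4, "Y": 6})[0] == pytest.approx(12.0)

    def test_negative_count_rejected(self, genetic_pair):
        with pytest.raises(StateError):
            genetic_pair.full.propensities({"M": -1, "R": 0, "D_A": 0})

    def test_unknown_species_rejected(self, genetic_pair):
        with pytest.raises(DefinitionError):
            genetic_pair.full.evaluate_rhs({"M": 1, "R": 1, "bogus": 1})

    def test_microscopic_exact_pair_combinatorics(self):
        # dimerisation 2X -> 0 with the n(n-1)/(2 Omega) convention
        net = ReactionNetwork(
            [SpeciesSpec("X", initial=4.0)],
            [Reaction("dimer", {"X": 2}, {}, RateLaw("mass_action", 1.0))],
            microscopic_exact=True,
        )
        assert net.propensities({"X": 4})[0] == pytest.approx(4 * 3 / 2)


class TestApplyConservation:
    def test_substitutes_eliminated_species(self, genetic_pair):
        # the unbinding rate became k_b*(1 - D_A) after eliminating D_R
        unbind = [r for r in genetic_pair.full.reactions if r.name == "unbinding"][0]
        expr = genetic_pair.full.rate_expression(unbind)
        assert expr.names == {"D_A"}
        f = expr.compile(["D_A"])
        assert f(np.array([0.25])) == pytest.approx(100.0 * 0.75)

    def test_identity_without_conservation_laws(self, cascade_pair):
        assert apply_conservation(cascade_pair.full) is cascade_pair.full

    def test_composite_elimination_matches_brute_force(self):
        """ODE of the eliminated network tracks the unreduced one to < 1e-8."""
        pair = make_composite_nfl("full")
        # the same chemistry with D_R2 and E kept as explicit dynamical species
        p = dict(alpha_M=50.0, beta_M=1.0, k_R=1.0, k4=1.0, kr1=10.0, kr2=10.0,
                 kr3=10.0, k1=1e-5, k2=100.0, D_T=0.01, E_T=1.0)
        k3 = (p["kr3"] + p["k4"]) / 110.0
        unreduced = ReactionNetwork(
            [
                SpeciesSpec("M"), SpeciesSpec("R"),
                SpeciesSpec("D", "fast", p["D_T"], 0, p["D_T"]),
                SpeciesSpec("D_R", "fast", 0, 0, p["D_T"]),
                SpeciesSpec("D_R2", "fast", 0, 0, p["D_T"]),
                SpeciesSpec("E", "fast", p["E_T"], 0, p["E_T"]),
                SpeciesSpec("E_R", "fast", 0, 0, p["E_T"]),
            ],
            [
                Reaction("transcription", {}, {"M": 1},
                         RateLaw("closed_form", expression="a*(D + D_R)",
                                 parameters={"a": p["alpha_M"]})),
                Reaction("mRNA_decay", {"M": 1}, {}, RateLaw("mass_action", p["beta_M"])),
                Reaction("translation", {}, {"R": 1},
                         RateLaw("closed_form", expression="k_R*M",
                                 parameters={"k_R": p["k_R"]})),
                Reaction("bind1", {"R": 1, "D": 1}, {"D_R": 1}, RateLaw("mass_action", p["k1"])),
                Reaction("unbind1", {"D_R": 1}, {"R": 1, "D": 1},
                         RateLaw("mass_action", p["kr1"])),
                Reaction("bind2", {"R": 1, "D_R": 1}, {"D_R2": 1},
                         RateLaw("mass_action", p["k2"])),
                Reaction("unbind2", {"D_R2": 1}, {"R": 1, "D_R": 1},
                         RateLaw("mass_action", p["kr2"])),
                Reaction("bindE", {"R": 1, "E": 1}, {"E_R": 1}, RateLaw("mass_action", k3)),
                Reaction("unbindE", {"E_R": 1}, {"R": 1, "E": 1},
                         RateLaw("mass_action", p["kr3"])),
                Reaction("enzymatic_decay", {"E_R": 1}, {"E": 1}, RateLaw("mass_action", p["k4"])),
            ],
            volume=100.0,
        )
        init = {"M": 0.1, "R": 80.0, "D": 0.005, "D_R": 0.005, "D_R2": 0.0,
                "E": 0.7, "E_R": 0.3}
        t1 = integrate(unreduced, init, 200.0, 500, rtol=1e-11, atol=1e-13)
        t2 = integrate(pair.full, init, 200.0, 500, rtol=1e-11, atol=1e-13)
        for sp in pair.full.species_order:
            scale = max(1.0, float(np.max(np.abs(t1[sp]))))
            assert np.max(np.abs(t1[sp] - t2[sp])) < 1e-8 * scale

    def test_initial_state_must_respect_conservation(self):
        with pytest.raises(DefinitionError, match="conservation"):
            ReactionNetwork(
                [SpeciesSpec("A", initial=1.0), SpeciesSpec("B", "eliminated", 1.0)],
                [],
                conservation_laws=[({"A": 1, "B": 1}, 1.0)],
            )

    def test_reaction_breaking_conserved_total_rejected(self):
        with pytest.raises(DefinitionError, match="conserved"):
            ReactionNetwork(
                [SpeciesSpec("A", initial=1.0), SpeciesSpec("B", initial=0.0)],
                [Reaction("leak", {"A": 1}, {}, RateLaw("mass_action", 1.0))],
                conservation_laws=[({"A": 1, "B": 1}, 1.0)],
            )

    def test_eliminated_species_needs_exactly_one_law(self):
        with pytest.raises(DefinitionError, match="exactly one"):
            ReactionNetwork(
                [SpeciesSpec("A", initial=1.0), SpeciesSpec("B", "eliminated", 0.0)],
                [],
            )


def test_initial_value_outside_physical_range_rejected():
    with pytest.raises(DefinitionError, match="physical range"):
        SpeciesSpec("D_A", "fast", 2.0, 0.0, 1.0)


def test_yaml_round_trip(tmp_path, genetic_pair):
    path = tmp_path / "net.yaml"
    genetic_pair.full.to_yaml(path)
    clone = ReactionNetwork.from_yaml(path)
    state = {"M": 30.0, "R": 70.0, "D_A": 0.3}
    assert clone.evaluate_rhs(state) == genetic_pair.full.evaluate_rhs(state)
    assert clone.species_order == genetic_pair.full.species_order


def test_prefactor_divides_derivative():
    net = ReactionNetwork(
        [SpeciesSpec("X", initial=1.0)],
        [Reaction("in", {}, {"X": 1}, RateLaw("mass_action", 6.0))],
        prefactors={"X": "2 + X"},
    )
    assert net.evaluate_rhs({"X": 1.0})["X"] == pytest.approx(2.0)
    assert math.isclose(
        net.without_prefactor().evaluate_rhs({"X": 1.0})["X"], 6.0
    )
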