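"""The built-in model pairs: defaults, QSS maps, reduction invariance."""

import math

import numpy as np
import pytest

from qssakit import (
    CATALOG,
    DefinitionError,
    closed_form_variances,
    integrate,
    l1_relative_error,
    make_composite_nfl,
    make_coop_enzyme,
    make_genetic_nfl,
    make_linear_cascade,
    make_oscillator,
)
from qssakit.catalog import OSC_DEFAULTS, qss_DA_of_T
from qssakit.metrics import _project_observable


class TestGeneticNFL:
    def test_qss_map_limits(self, genetic_pair):
        assert genetic_pair.qss_map({"R": 0.0})["D_A"] == pytest.approx(1.0)
        assert genetic_pair.qss_map({"R": 10.0})["D_A"] == pytest.approx(0.5)

    def test_qss_root_satisfies_fast_balance(self, genetic_pair):
        # -k_f R D_A + k_b (1 - D_A) at D_A = K_D/(K_D+R) vanishes identically
        for r in np.linspace(0.0, 130.0, 27):
            da = genetic_pair.qss_map({"R": r})["D_A"]
            assert abs(-10.0 * r * da + 100.0 * (1 - da)) < 1e-8

    def test_deterministic_agreement_from_reference_ic(self, genetic_pair):
        tf = integrate(genetic_pair.full, t_end=20.0, n_out=2000)
        tr = integrate(genetic_pair.reduced, t_end=20.0, n_out=2000)
        err = l1_relative_error(_project_observable(genetic_pair, tf), tr, "R", 20.0)
        assert err < 0.05

    def test_reduction_depends_only_on_KD(self):
        a = make_genetic_nfl(k_f=0.3).reduced.to_dict()
        b = make_genetic_nfl(k_f=30.0).reduced.to_dict()
        assert a == b

    def test_inconsistent_rate_triple_rejected(self):
        with pytest.raises(DefinitionError):
            make_genetic_nfl(K_D=10.0, k_f=1.0, k_b=5.0)


class TestCoopEnzyme:
    def test_km_squared_product(self):
        pair = make_coop_enzyme()
        conv = [r for r in pair.reduced.reactions if r.name == "conversion"][0]
        expr = pair.reduced.rate_expression(conv).compile(["P", "S"])
        km_sq = 2e6 * 0.101
        s_half = math.sqrt(km_sq)
        # half-saturation: consumption = k_p/2 when S^2 = Km^2
        assert expr(np.array([0.0, s_half])) == pytest.approx(0.5)

    def test_reduction_invariant_under_unbinding_rates(self):
        a = make_coop_enzyme(kr1=10.0, kr2=40.0).reduced.to_dict()
        b = make_coop_enzyme(kr1=1000.0, kr2=4000.0).reduced.to_dict()
        assert a == b

    def test_warns_when_cooperativity_assumption_fails(self):
        with pytest.warns(UserWarning, match="Km1"):
            make_coop_enzyme(Km1=1.0, Km2=1.0)

    def test_qss_map_is_a_fast_fixed_point(self):
        pair = make_coop_enzyme()
        s = 449.0
        fast = pair.qss_map({"S": s})
        rhs = pair.full.evaluate_rhs({"S": s, "P": 0.0, **fast})
        assert abs(rhs["E_S"]) < 1e-8 and abs(rhs["E_S2"]) < 1e-8


class TestOscillator:
    def test_qss_root_limits(self):
        d_t, k_d = OSC_DEFAULTS["D_T"], 51.0 / 200.0
        assert qss_DA_of_T(0.0, d_t, k_d) == pytest.approx(d_t, rel=1e-9)
        assert qss_DA_of_T(1e9, d_t, k_d) == pytest.approx(0.0, abs=1e-6)

    def test_prefactor_limits(self):
        pair = make_oscillator("pqssa")
        d_t, k_d = OSC_DEFAULTS["D_T"], 51.0 / 200.0
        pf = pair.reduced.prefactors["R"].compile(["R"])
        assert pf(np.array([0.0])) == pytest.approx(1.0 + d_t / k_d)
        assert pf(np.array([1e9])) == pytest.approx(1.0, rel=1e-6)

    def test_qss_root_satisfies_fast_balance(self):
        d_t, k_d = OSC_DEFAULTS["D_T"], 51.0 / 200.0
        k_f, k_b, beta_R = 200.0, 50.0, 1.0
        for t in np.linspace(0.0, 2 * d_t, 41):
            da = qss_DA_of_T(t, d_t, k_d)
            dr = d_t - da
            resid = k_f * (t - dr) * da - (k_b + beta_R) * dr
            assert abs(resid) < 1e-8 * max(1.0, k_f * d_t * d_t)

    def test_tqssa_and_pqssa_are_the_same_reduction(self):
        """Mapped through T = R + D_R(R), the two reduced flows coincide."""
        d_t, k_d = OSC_DEFAULTS["D_T"], 51.0 / 200.0
        pt, pp = make_oscillator("tqssa"), make_oscillator("pqssa")
        init = pt.full.initial_state()
        r0 = init["R"]
        t0 = r0 + d_t * r0 / (r0 + k_d)
        tr_t = integrate(pt.reduced, {"M": init["M"], "P": init["P"], "T": t0},
                         20.0, 2000, rtol=1e-10, atol=1e-12)
        tr_p = integrate(pp.reduced, {"M": init["M"], "P": init["P"], "R": r0},
                         20.0, 2000, rtol=1e-10, atol=1e-12)
        r = tr_p["R"]
        t_of_r = r + d_t * r / (r + k_d)
        assert np.max(np.abs(tr_t["T"] - t_of_r)) / np.max(tr_t["T"]) < 1e-6
        assert np.max(np.abs(tr_t["M"] - tr_p["M"])) / np.max(tr_t["M"]) < 1e-6

    def test_default_ic_is_on_a_limit_cycle(self):
        pair = make_oscillator("tqssa")
        traj = integrate(pair.full, t_end=30.0, n_out=1000)
        m = traj["M"]
        # sustained oscillation: late-time amplitude comparable to early
        assert m[700:].max() - m[700:].min() > 0.5 * (m.max() - m.min())

    def test_unknown_reduction_rejected(self):
        with pytest.raises(DefinitionError):
            make_oscillator("sqssa")


class TestCompositeNFL:
    def test_derived_constants(self):
        pair = make_composite_nfl("EDR")
        hill = [r for r in pair.reduced.reactions if r.name == "transcription"][0]
        expr = pair.reduced.rate_expression(hill).compile(["M", "R"])
        # K_D^2 = kr1*kr2/(k1*k2) = 1e5; at R = sqrt(K_D^2) transcription halves
        assert expr(np.array([0.0, math.sqrt(1e5)])) == pytest.approx(0.25)
        # at R = 0 the Hill factor is 1: alpha_M * D_T = 0.5
        assert expr(np.array([0.0, 0.0])) == pytest.approx(0.5)

    def test_k3_from_KM(self):
        # k3 = (kr3 + k4)/K_M = 11/110; rate at R=1 with all enzyme free is k3*E_T
        pair = make_composite_nfl("DR")
        bind = [r for r in pair.reduced.reactions if r.name == "bindE"][0]
        expr = pair.reduced.rate_expression(bind).compile(pair.reduced.species_order)
        state = {"M": 0.0, "R": 1.0, "E_R": 0.0}
        x = np.array([state[s] for s in pair.reduced.species_order])
        assert expr(x) == pytest.approx((10.0 + 1.0) / 110.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(DefinitionError, match="variant"):
            make_composite_nfl("XX")

    def test_full_variant_is_self_paired(self):
        pair = make_composite_nfl("full")
        assert pair.reduced is pair.full and pair.grid_species == []


class TestLinearCascade:
    def test_reduced_steady_state(self):
        v = closed_form_variances()
        assert v.mean_P == pytest.approx(100.0)

    def test_full_variance_closed_form(self):
        v = closed_form_variances(k_P=0.1)
        assert v.var_full == pytest.approx(100.0 * (1.0 / 1.1 + 1.0))
        assert v.var_qssa == pytest.approx(100.0)

    def test_poisson_limit_as_burst_vanishes(self):
        v = closed_form_variances(alpha_P=1e-9, alpha_M=1e9)
        assert v.var_full / v.mean_P == pytest.approx(1.0, rel=1e-6)

    def test_cv_gap_scaling_approaches_sqrt_kP(self):
        r = closed_form_variances(k_P=1e-4).rel_error / closed_form_variances(
            k_P=1e-5
        ).rel_error
        assert r == pytest.approx(math.sqrt(10.0), rel=1e-3)

    def test_reduction_depends_only_on_rate_product(self):
        a = make_linear_cascade(alpha_M=2.0, alpha_P=5.0).reduced.to_dict()
        b = make_linear_cascade(alpha_M=10.0, alpha_P=1.0).reduced.to_dict()
        assert a == b

    def test_normalized_transient_is_parameter_free(self):
        """M(t)/(alpha_M/k_M) depends only on the normalized initial value."""
        out = []
        for am, ap in ((1.0, 10.0), (10.0, 1.0)):
            pair = make_linear_cascade(alpha_M=am, alpha_P=ap)
            m_ss = am / 1.0
            traj = integrate(pair.full, {"M": 0.5 * m_ss, "P": 100.0}, 5.0, 200)
            out.append(traj["M"] / m_ss)
        np.testing.assert_allclose(out[0], out[1], rtol=1e-7)


def test_catalog_registry_is_complete():
    assert set(CATALOG) == {
        "genetic_nfl", "coop_enzyme", "oscillator", "composite_nfl", "linear_cascade"
    }
    for entry in CATALOG.values():
        pair = entry.make()
        assert pair.observable in pair.reduced.species_order
        shared = set(pair.reduced.species_order) & set(pair.full.species_order)
        assert pair.observable in shared or entry.name == "oscillator"
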