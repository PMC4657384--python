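"""Stochastic engine: exactness, reproducibility, moments and the bootstrap."""

import numpy as np
import pytest
from scipy import stats

from qssakit import (
    RateLaw,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
    block_bootstrap_se,
    gillespie_run,
    integrate,
    make_genetic_nfl_unscaled,
    make_oscillator,
    run_ensemble,
    stationary_moments,
)


def _birth_death(alpha=10.0, beta=10.0, x0=0.0):
    return ReactionNetwork(
        [SpeciesSpec("X", initial=x0)],
        [
            Reaction("birth", {}, {"X": 1}, RateLaw("mass_action", alpha)),
            Reaction("death", {"X": 1}, {}, RateLaw("mass_action", beta)),
        ],
    )


def test_network_without_reactions_stays_constant():
    net = ReactionNetwork([SpeciesSpec("X", initial=5.0)], [])
    traj = gillespie_run(net, t_end=1.0, seed=1)
    assert np.all(traj["X"] == 5)


def test_pure_decay_ensemble_mean_matches_closed_form():
    """Linear death process: <X(1)> = 1000 exp(-1), within 3 standard errors."""
    net = ReactionNetwork(
        [SpeciesSpec("X", initial=1000.0)],
        [Reaction("death", {"X": 1}, {}, RateLaw("mass_action", 1.0))],
    )
    ens = run_ensemble(net, record_times=np.array([1.0]), n_reps=1000, seed_base=7)
    x = ens.species("X").astype(float)
    expected = 1000 * np.exp(-1.0)
    se = x.std(ddof=1) / np.sqrt(len(x))
    assert abs(x.mean() - expected) < 3 * se


def test_birth_death_stationary_distribution_is_poisson():
    """Chi-square goodness of fit against Poisson(alpha/beta) at the 1% level."""
    ens = run_ensemble(
        _birth_death(alpha=10.0, beta=10.0), record_times=np.array([3.0]),
        n_reps=10_000, seed_base=11,
    )
    x = ens.species("X")
    kmax = x.max()
    observed = np.bincount(x, minlength=kmax + 1).astype(float)
    expected = stats.poisson.pmf(np.arange(kmax + 1), 10.0 / 10.0) * len(x)
    # pool low-probability tail bins so every expected count is >= 5
    lo = np.searchsorted(np.cumsum(expected), 5.0) + 1
    hi = kmax - np.searchsorted(np.cumsum(expected[::-1]), 5.0) - 1
    obs = np.concatenate([[observed[:lo].sum()], observed[lo:hi], [observed[hi:].sum()]])
    exp = np.concatenate([[expected[:lo].sum()], expected[lo:hi], [expected[hi:].sum()]])
    exp *= obs.sum() / exp.sum()
    p_value = stats.chisquare(obs, exp).pvalue
    assert p_value > 0.01


def test_gillespie_is_bit_reproducible(cascade_pair):
    times = np.linspace(0.0, 5.0, 11)
    a = gillespie_run(cascade_pair.full, t_end=5.0, seed=42, record_times=times)
    b = gillespie_run(cascade_pair.full, t_end=5.0, seed=42, record_times=times)
    assert np.array_equal(a.states, b.states)


def test_ensemble_moments_deterministic_given_seed(cascade_pair):
    m1 = stationary_moments(cascade_pair.reduced, n_reps=500, seed_base=3)
    m2 = stationary_moments(cascade_pair.reduced, n_reps=500, seed_base=3)
    assert m1.mean == m2.mean and m1.variance == m2.variance


def test_python_and_numba_paths_agree(cascade_pair):
    """Same chemistry, independent implementations: means agree within 3 SE."""
    mom = stationary_moments(cascade_pair.reduced, n_reps=2000, seed_base=5)
    vals = [
        gillespie_run(
            cascade_pair.reduced, t_end=101.0, seed=9000 + i, record_times=np.array([100.5])
        ).states[0, 0]
        for i in range(200)
    ]
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - mom.mean["P"]) < 3 * se + 3 * np.sqrt(
        mom.variance["P"] / mom.n_reps
    )


def test_counts_conserved_exactly_along_ssa():
    net = ReactionNetwork(
        [SpeciesSpec("A", initial=7.0), SpeciesSpec("B", initial=3.0)],
        [
            Reaction("fwd", {"A": 1}, {"B": 1}, RateLaw("mass_action", 2.0)),
            Reaction("rev", {"B": 1}, {"A": 1}, RateLaw("mass_action", 1.0)),
        ],
        conservation_laws=[({"A": 1, "B": 1}, 10.0)],
    )
    ens = run_ensemble(net, record_times=np.linspace(0, 5, 20), n_reps=50, seed_base=1)
    totals = ens.counts.sum(axis=2)
    assert np.all(totals == 10)


def test_mean_converges_to_ode_with_volume():
    """a = Omega f(n/Omega): ensemble mean tracks the ODE at Omega in {1,10,100}."""
    for omega in (1.0, 10.0, 100.0):
        net = ReactionNetwork(
            [SpeciesSpec("X", initial=0.0), SpeciesSpec("Y", initial=4.0)],
            [
                Reaction("in", {}, {"X": 1}, RateLaw("mass_action", 5.0)),
                Reaction("conv", {"X": 1}, {"Y": 1}, RateLaw("mass_action", 1.0)),
                Reaction("out", {"Y": 1}, {}, RateLaw("mass_action", 0.5)),
            ],
            volume=omega,
        )
        ode = integrate(net, t_end=2.0, n_out=10)
        init = {"X": 0, "Y": int(4 * omega)}
        ens = run_ensemble(net, init, np.array([2.0]), n_reps=400, seed_base=13)
        for sp in ("X", "Y"):
            x = ens.concentrations(sp)
            se = x.std(ddof=1) / np.sqrt(len(x))
            assert abs(x.mean() - ode[sp][-1]) < 3.5 * se + 1e-9


def test_promoter_noise_shrinks_with_copy_number():
    """Var(D_A/D_T) decreases as the promoter copy number D_T grows."""
    variances = []
    for d_t in (1, 4, 16):
        net = make_genetic_nfl_unscaled(D_T=d_t)
        mom = stationary_moments(net, burn_in=10.0, n_reps=1500, seed_base=17)
        variances.append(mom.variance["D_A"] / d_t**2)
    assert variances[0] > variances[1] > variances[2]


def test_prefactored_network_rejected_by_ssa():
    pair = make_oscillator("pqssa")
    with pytest.raises(ValueError, match="prefactor"):
        pair.reduced.compiled()
    # the declared stochastic counterpart simulates fine
    run_ensemble(
        pair.reduced.without_prefactor(),
        {"M": 284, "P": 194, "R": 2},
        np.array([0.1]),
        n_reps=2,
        seed_base=1,
    )


class TestBlockBootstrap:
    def test_constant_samples_have_zero_se(self):
        assert block_bootstrap_se(np.full(500, 3.0), statistic=np.mean) == 0.0

    def test_block_length_one_matches_iid_bootstrap(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10.0, 2.0, size=2000)
        se_block = block_bootstrap_se(x, statistic=np.mean, block_length=1, n_boot=400, seed=2)
        se_iid = np.std(
            [np.mean(rng.choice(x, size=len(x))) for _ in range(400)], ddof=1
        )
        assert se_block == pytest.approx(se_iid, rel=0.25)

    def test_gaussian_mean_se_matches_closed_form(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.0, 1.0, size=10_000)
        se = block_bootstrap_se(x, statistic=np.mean, block_length=100, n_boot=300, seed=5)
        assert se == pytest.approx(x.std(ddof=1) / 100.0, rel=0.10)

    def test_block_longer_than_sample_rejected(self):
        with pytest.raises(ValueError):
            block_bootstrap_se(np.ones(10), block_length=11)


def test_absorbing_state_continues_as_constant():
    net = ReactionNetwork(
        [SpeciesSpec("X", initial=3.0)],
        [Reaction("death", {"X": 1}, {}, RateLaw("mass_action", 50.0))],
    )
    traj = gillespie_run(net, t_end=10.0, seed=3, record_times=np.linspace(0, 10, 21))
    assert traj["X"][-1] == 0
    assert np.all(np.diff(traj["X"]) <= 0)
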