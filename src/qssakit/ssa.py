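"""Exact stochastic simulation (Gillespie direct method) and ensemble statistics.

Two execution paths share one network representation:

* :func:`gillespie_run` -- a pure-Python direct method producing a single,
  bit-reproducible trajectory (``numpy.random.PCG64`` seeded directly);
* :func:`run_ensemble` / :func:`stationary_moments` -- a numba-compiled
  kernel over many replicates, with per-replicate seeds derived by the
  counter scheme ``seed_base + replicate`` so ensembles are reproducible
  and order-independent.

Stationary statistics take one sample per replicate at the final time
(avoiding within-trajectory autocorrelation); uncertainty on derived
statistics comes from a moving-block bootstrap (default block length 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._ssa_kernel import ensemble_states
from .network import ReactionNetwork, StateError
from .ode import Trajectory

__all__ = [
    "Ensemble",
    "MomentSummary",
    "gillespie_run",
    "run_ensemble",
    "stationary_moments",
    "block_bootstrap_se",
    "cv",
    "default_burn_in",
]


def cv(samples: np.ndarray) -> float:
    """Coefficient of variation, sd/mean (sample sd, ddof=1)."""
    m = float(np.mean(samples))
    if m == 0.0:
        raise ZeroDivisionError("CV undefined for zero-mean samples")
    return float(np.std(samples, ddof=1)) / m


def _check_counts(network: ReactionNetwork, counts: dict) -> np.ndarray:
    vec = np.array([counts[s] for s in network.species_order], dtype=np.int64)
    if np.any(vec < 0):
        raise StateError("negative initial count")
    for coeffs, total in network.conservation_laws:
        value = sum(c * counts[sp] for sp, c in coeffs.items())
        if abs(value - total * network.volume) > 1e-6:
            raise StateError(f"initial counts violate conservation law {coeffs}")
    return vec


def gillespie_run(
    network: ReactionNetwork,
    initial_counts: dict | None = None,
    t_end: float = 1.0,
    seed: int = 0,
    record_times: np.ndarray | None = None,
) -> Trajectory:
    """One exact direct-method realization, recorded at ``record_times``.

    The recorded state at time ``s`` is the state immediately before the
    first event later than ``s``.  When every propensity vanishes the state
    is absorbing and the trajectory continues as a constant.
    """
    if network.has_prefactor:
        raise ValueError("SSA is defined only for unprefactored networks")
    counts = dict(initial_counts or network.initial_counts())
    vec = _check_counts(network, counts).astype(float)
    if record_times is None:
        record_times = np.linspace(0.0, t_end, 101)
    record_times = np.asarray(record_times, dtype=float)
    rng = np.random.Generator(np.random.PCG64(seed))
    order = network.species_order
    out = np.zeros((record_times.size, len(order)))
    t, ri = 0.0, 0
    stoich = np.array(
        [[rxn.net_change(sp) for sp in order] for rxn in network.reactions], dtype=float
    )
    while ri < record_times.size:
        a = network.propensities(vec)
        a0 = float(a.sum())
        if a0 <= 0.0:
            break
        t_next = t + rng.exponential(1.0) / a0
        while ri < record_times.size and record_times[ri] < t_next:
            out[ri] = vec
            ri += 1
        if ri == record_times.size:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
        vec = vec + stoich[min(j, len(a) - 1)]
        t = t_next
    out[ri:] = vec
    return Trajectory(record_times, out, order)


@dataclass
class Ensemble:
    """Replicate counts at the recorded sample times."""

    sample_times: np.ndarray
    counts: np.ndarray  # (n_reps, n_times, n_species) integer counts
    species_order: list[str]
    seed_base: int
    volume: float = 1.0

    @property
    def n_reps(self) -> int:
        return self.counts.shape[0]

    def species(self, name: str, time_index: int = -1) -> np.ndarray:
        """Counts of one species across replicates at one sample time."""
        return self.counts[:, time_index, self.species_order.index(name)]

    def concentrations(self, name: str, time_index: int = -1) -> np.ndarray:
        return self.species(name, time_index) / self.volume

    def to_csv(self, path) -> None:
        import pandas as pd

        reps, times = np.meshgrid(
            np.arange(self.n_reps), self.sample_times, indexing="ij"
        )
        frame = pd.DataFrame(
            {"rep": reps.ravel(), "time": times.ravel()}
            | {
                sp: self.counts[:, :, i].ravel()
                for i, sp in enumerate(self.species_order)
            }
        )
        frame.to_csv(path, index=False)


@dataclass
class MomentSummary:
    """Stationary moments across replicates (one sample per replicate)."""

    mean: dict
    variance: dict
    cv: dict
    fano: dict
    n_reps: int
    samples: np.ndarray = field(repr=False)  # (n_reps, n_species) counts
    species_order: list[str] = field(default_factory=list)
    volume: float = 1.0

    def species_samples(self, name: str) -> np.ndarray:
        return self.samples[:, self.species_order.index(name)]

    def histogram(self, name: str) -> dict:
        values, freq = np.unique(self.species_samples(name), return_counts=True)
        return dict(zip(values.tolist(), freq.tolist()))

    def histogram_to_csv(self, path, name: str) -> None:
        hist = self.histogram(name)
        with open(path, "w") as fh:
            fh.write("species,count,frequency\n")
            for value, freq in hist.items():
                fh.write(f"{name},{value},{freq}\n")


def run_ensemble(
    network: ReactionNetwork,
    initial_counts: dict | None = None,
    record_times: np.ndarray | None = None,
    n_reps: int = 1000,
    seed_base: int = 0,
) -> Ensemble:
    """Replicated direct-method runs via the compiled kernel."""
    counts = dict(initial_counts or network.initial_counts())
    vec = _check_counts(network, counts)
    record_times = np.asarray(record_times, dtype=float)
    out = ensemble_states(network.compiled(), vec, record_times, n_reps, seed_base)
    return Ensemble(record_times, out, network.species_order, seed_base, network.volume)


def default_burn_in(network: ReactionNetwork, factor: float = 10.0) -> float:
    """``factor`` times the slowest first-order consumption timescale.

    Scans mass-action reactions that consume exactly one unit of a species;
    the smallest such rate constant sets the slowest relaxation time.  Falls
    back to ``factor`` when the network has no first-order decays.
    """
    rates = [
        r.rate_law.rate_constant
        for r in network.reactions
        if r.rate_law.kind == "mass_action" and sum(r.reactants.values()) == 1
        and not r.products
    ]
    if not rates:
        return factor
    return factor / min(rates)


def stationary_moments(
    network: ReactionNetwork,
    initial_counts: dict | None = None,
    burn_in: float | None = None,
    t_end: float | None = None,
    n_reps: int = 10_000,
    seed_base: int = 0,
) -> MomentSummary:
    """Moments from the state at ``t_end`` across independent replicates.

    ``burn_in`` documents the time after which the reduced-model transient
    has decayed; sampling happens at ``t_end`` (default: the burn-in time
    itself), one draw per replicate.
    """
    if burn_in is None:
        burn_in = default_burn_in(network)
    if t_end is None:
        t_end = burn_in * 1.000001
    if not burn_in < t_end:
        raise ValueError("burn_in must be smaller than t_end")
    ens = run_ensemble(
        network, initial_counts, np.array([t_end]), n_reps=n_reps, seed_base=seed_base
    )
    samples = ens.counts[:, -1, :].astype(float)
    mean = samples.mean(axis=0)
    var = samples.var(axis=0, ddof=1)
    order = network.species_order
    cvs, fanos = {}, {}
    for i, sp in enumerate(order):
        if mean[i] > 0:
            cvs[sp] = float(np.sqrt(var[i]) / mean[i])
            fanos[sp] = float(var[i] / mean[i])
        else:
            cvs[sp] = float("nan")
            fanos[sp] = float("nan")
    return MomentSummary(
        mean=dict(zip(order, mean.tolist())),
        variance=dict(zip(order, var.tolist())),
        cv=cvs,
        fano=fanos,
        n_reps=n_reps,
        samples=ens.counts[:, -1, :],
        species_order=order,
        volume=network.volume,
    )


def block_bootstrap_se(
    samples: np.ndarray,
    statistic=cv,
    block_length: int = 100,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Moving-block bootstrap standard error of ``statistic(samples)``.

    Contiguous blocks of ``block_length`` samples are resampled with
    replacement until the original length is reached (the tail block is
    trimmed), and the statistic is recomputed per resample.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if block_length > n:
        raise ValueError(f"block length {block_length} exceeds sample size {n}")
    rng = np.random.Generator(np.random.PCG64(seed))
    n_blocks = -(-n // block_length)
    starts_max = n - block_length + 1
    stats = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, starts_max, size=n_blocks)
        idx = (starts[:, None] + np.arange(block_length)[None, :]).ravel()[:n]
        stats[b] = statistic(samples[idx])
    return float(np.std(stats, ddof=1))
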