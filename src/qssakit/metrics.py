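"""Error metrics and analytic validity estimates for QSS reductions.

The central numerical quantity is the deterministic QSSA error

    max over an initial-condition region of
    int_0^T |X_full - X_QSSA| dt / int_0^T |X_QSSA| dt

where the region spans the slow species' likely stochastic range (mean +/- 3
standard deviations from the reduced-model SSA) crossed with the *entire*
physical range of the fast species.  The stochastic counterpart is the
relative error of the observable's coefficient of variation at steady state
between the full and reduced stochastic models.

Analytic companions: the initial-transient (IT) phase estimate of how much a
slow variable moves while the fast one relaxes, and the two-part validity
condition for the stochastic QSSA (timescale separation, plus a closure term
proportional to the fast species' scaled variance).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .network import ModelPair, ReactionNetwork
from .ode import DEFAULT_ATOL, DEFAULT_N_OUT, DEFAULT_RTOL, integrate, l1_relative_error
from .ssa import cv, stationary_moments

__all__ = [
    "ICRegion",
    "DeterministicErrorReport",
    "StochasticErrorReport",
    "deterministic_qssa_error",
    "stochastic_cv_error",
    "it_phase_change_estimate",
    "measure_it_phase_change",
    "stochastic_validity_terms",
]


@dataclass(frozen=True)
class ICRegion:
    """Initial-condition region: slow intervals x full fast ranges."""

    slow_intervals: dict  # species -> (lo, hi)
    fast_ranges: dict  # species -> (lo, hi)
    grid_points_per_dim: int = 5

    def __post_init__(self):
        for name, (lo, hi) in {**self.slow_intervals, **self.fast_ranges}.items():
            if not lo <= hi:
                raise ValueError(f"empty interval for {name}: [{lo}, {hi}]")
            if not np.isfinite(hi):
                raise ValueError(
                    f"unbounded range for {name}; supply an explicit cap for "
                    "unbounded fast species"
                )

    def grid(self):
        """Cartesian grid over (slow x fast), endpoints included."""
        names = list(self.slow_intervals) + list(self.fast_ranges)
        axes = [
            np.linspace(lo, hi, 1 if hi == lo else self.grid_points_per_dim)
            for lo, hi in [*self.slow_intervals.values(), *self.fast_ranges.values()]
        ]
        n_slow = len(self.slow_intervals)
        for point in itertools.product(*axes):
            slow = dict(zip(names[:n_slow], point[:n_slow]))
            fast = dict(zip(names[n_slow:], point[n_slow:]))
            yield slow, fast


@dataclass
class DeterministicErrorReport:
    max_error: float
    argmax_ic: dict
    per_ic_errors: list  # [(ic dict, error), ...]
    T: float
    observable: str

    def to_frame(self):
        import pandas as pd

        rows = [{**{f"ic_{k}": v for k, v in ic.items()}, "error": e}
                for ic, e in self.per_ic_errors]
        return pd.DataFrame(rows)


@dataclass
class StochasticErrorReport:
    cv_full: float
    cv_reduced: float
    rel_cv_error: float  # |cv_full - cv_reduced| / cv_full
    cv_diff: float  # |cv_full - cv_reduced|  (the sqrt(k_P)-scaling quantity)
    bootstrap_se: float  # SE of rel_cv_error
    cv_diff_se: float
    n_reps: int
    observable: str = ""
    means: dict = field(default_factory=dict)


def deterministic_qssa_error(
    pair: ModelPair,
    region: ICRegion,
    T: float,
    n_out: int = DEFAULT_N_OUT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> DeterministicErrorReport:
    """Max relative L1 error of the observable over the IC region.

    The reduced model starts from the slow coordinates only; the full model
    additionally takes each grid value of the fast species.  Reduced
    trajectories are shared across fast grid points of the same slow point.
    Grid points violating the pair's feasibility constraint (e.g. promoter
    states summing past the DNA total) are skipped.
    """
    per_ic = []
    best = (-1.0, None)
    reduced_cache: dict = {}
    for slow, fast in region.grid():
        if not pair.fast_feasible(fast, slow):
            continue
        key = tuple(sorted(slow.items()))
        if key not in reduced_cache:
            reduced_cache[key] = integrate(
                pair.reduced, pair.reduced_initial(slow), T, n_out, rtol, atol
            )
        red_traj = reduced_cache[key]
        full_traj = integrate(pair.full, pair.full_initial(slow, fast), T, n_out, rtol, atol)
        full_obs = _project_observable(pair, full_traj)
        err = l1_relative_error(full_obs, red_traj, pair.observable, T)
        ic = {**slow, **fast}
        per_ic.append((ic, err))
        if err > best[0]:
            best = (err, ic)
    if not per_ic:
        raise ValueError("empty initial-condition region (all grid points infeasible)")
    return DeterministicErrorReport(best[0], best[1], per_ic, T, pair.observable)


def _project_observable(pair: ModelPair, full_traj):
    """View the full trajectory in the reduced model's coordinates.

    The observable must exist in both models under slow_map; when the
    reduced coordinate is a combination of full species (e.g. total
    repressor T = R + D_R), the pair's slow_map names a full species whose
    column is replaced by the combination via the qss relation.  For the
    catalog pairs the observable is always a shared species, so this is a
    rename at most.
    """
    from .ode import Trajectory

    full_name = pair.slow_map.get(pair.observable, pair.observable)
    if full_name in full_traj.species_order:
        col = full_traj[full_name]
    elif pair.observable == "T" and {"R", "D_R"} <= set(full_traj.species_order):
        col = full_traj["R"] + full_traj["D_R"]
    else:
        raise ValueError(f"cannot project observable {pair.observable!r} onto full model")
    states = np.zeros((full_traj.times.size, 1))
    states[:, 0] = col
    return Trajectory(full_traj.times, states, [pair.observable])


def stochastic_cv_error(
    full: ReactionNetwork,
    reduced: ReactionNetwork,
    observable: str,
    burn_in: float | None = None,
    t_end: float | None = None,
    n_reps: int = 10_000,
    seed_base: int = 0,
    block_length: int = 100,
    n_boot: int = 200,
    initial_full: dict | None = None,
    initial_reduced: dict | None = None,
) -> StochasticErrorReport:
    """Relative CV error of the observable at steady state, full vs reduced.

    Both ensembles share the same seed base (common random streams across
    parameter sweeps).  The bootstrap SE resamples the per-replicate
    stationary samples of both ensembles in blocks and recomputes the error
    statistic per resample.
    """
    if reduced.has_prefactor:
        reduced = reduced.without_prefactor()
    if full.has_prefactor:
        raise ValueError("full network must be unprefactored")
    mom_f = stationary_moments(full, initial_full, burn_in, t_end, n_reps, seed_base)
    mom_r = stationary_moments(reduced, initial_reduced, burn_in, t_end, n_reps, seed_base)
    xf = mom_f.species_samples(observable).astype(float)
    xr = mom_r.species_samples(observable).astype(float)
    cv_f, cv_r = cv(xf), cv(xr)
    if cv_f == 0:
        raise ZeroDivisionError("full-model CV is zero; relative error undefined")
    rel = abs(cv_f - cv_r) / cv_f
    diff = abs(cv_f - cv_r)

    rng = np.random.Generator(np.random.PCG64(seed_base + 101))
    rels = np.empty(n_boot)
    diffs = np.empty(n_boot)
    nf, nr = len(xf), len(xr)
    bf, br = min(block_length, nf), min(block_length, nr)
    for b in range(n_boot):
        f_idx = _block_indices(rng, nf, bf)
        r_idx = _block_indices(rng, nr, br)
        cf, cr = cv(xf[f_idx]), cv(xr[r_idx])
        rels[b] = abs(cf - cr) / cf
        diffs[b] = abs(cf - cr)
    return StochasticErrorReport(
        cv_full=cv_f,
        cv_reduced=cv_r,
        rel_cv_error=rel,
        cv_diff=diff,
        bootstrap_se=float(np.std(rels, ddof=1)),
        cv_diff_se=float(np.std(diffs, ddof=1)),
        n_reps=n_reps,
        observable=observable,
        means={"full": float(np.mean(xf)), "reduced": float(np.mean(xr))},
    )


def _block_indices(rng, n: int, block_length: int) -> np.ndarray:
    n_blocks = -(-n // block_length)
    starts = rng.integers(0, n - block_length + 1, size=n_blocks)
    return (starts[:, None] + np.arange(block_length)[None, :]).ravel()[:n]


def it_phase_change_estimate(
    beta_R: float,
    k_f: float,
    K_D: float,
    R0: float,
    DA_max: float = 1.0,
    k_b: float | None = None,
) -> tuple[float, float]:
    """IT-phase estimate of the slow variable's relative change.

    Returns ``(|dR|/R0 estimate, t_DA)`` where the estimate is
    ``(beta_R/k_f + DA_max)/(R0 + K_D)`` and ``t_DA = 1/(k_f*R0 + k_b)`` is
    the fast species' relaxation timescale during the transient.  ``DA_max``
    defaults to the fast species' upper physical bound (1 in the DNA-scaled
    model), the most conservative choice.
    """
    if R0 + K_D <= 0:
        raise ValueError("R0 + K_D must be positive")
    if k_b is None:
        k_b = K_D * k_f
    estimate = (beta_R / k_f + DA_max) / (R0 + K_D)
    t_da = 1.0 / (k_f * R0 + k_b)
    return estimate, t_da


def measure_it_phase_change(
    pair: ModelPair,
    R0: float,
    k_f: float,
    k_b: float,
    slow_species: str = "R",
    fast_initial: dict | None = None,
    horizon_factor: float = 5.0,
    n_out: int = 400,
) -> float:
    """Observed max |R(t)-R(0)|/R(0) over the IT phase of the full ODE.

    The IT window is ``horizon_factor * t_DA`` where
    ``t_DA = 1/(k_f*R0 + k_b)`` is the fast species' relaxation timescale
    during the transient.
    """
    t_da = 1.0 / (k_f * R0 + k_b)
    init = pair.full.initial_state()
    init[slow_species] = R0
    if fast_initial:
        init.update(fast_initial)
    traj = integrate(pair.full, init, horizon_factor * t_da, n_out)
    r = traj[slow_species]
    return float(np.max(np.abs(r - R0)) / R0)


def stochastic_validity_terms(
    k_f: float,
    beta_R: float,
    K_D: float,
    R: float,
    var_DA_scaled: float,
    D_T: float = 1.0,
) -> tuple[float, float]:
    """The two stochastic-QSSA validity quantities.

    Returns ``(timescale_ratio, closure_term)``: the reduction is trusted
    when ``k_f/beta_R >> 1`` (fast binding) and the closure term
    ``Var(D_A/D_T) * D_T/(R + K_D) << 1`` (deterministic QSS approximates
    the conditional average of the fast species).  With D_T = 1 the closure
    term reduces to Var(D_A)/(R + K_D).
    """
    if R + K_D <= 0:
        raise ValueError("R + K_D must be positive")
    return k_f / beta_R, var_DA_scaled * D_T / (R + K_D)
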