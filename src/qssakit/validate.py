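"""The three-step stochastic-QSSA validation procedure.

Step 1 -- simulate the *reduced* stochastic model (never the full one; the
method's point is that full stochastic simulations are not required).
Step 2 -- from those simulations, take each slow variable's stationary
mean +/- 3 SD as its initial-condition interval; fast variables get their
entire physical range (their distribution is unknown without the full
model).  Step 3 -- measure the deterministic QSSA error over the region; if
it stays below the threshold everywhere, the stochastic QSSA is trusted.

For oscillatory reductions the stationary distribution is not unimodal, so
the slow intervals are taken instead from percentiles of reduced-model SSA
samples pooled over one period of the limit cycle.

Unbounded fast species (an mRNA pool, say) have no "entire physical range";
the caller must either cap them explicitly or permit a short auxiliary SSA
of the full model, from which the cap is set at mean + 5 SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    DeterministicErrorReport,
    ICRegion,
    deterministic_qssa_error,
    stochastic_cv_error,
)
from .network import ModelPair, ReactionNetwork
from .ode import integrate
from .ssa import default_burn_in, run_ensemble, stationary_moments

__all__ = [
    "DEFAULT_THRESHOLD",
    "ValidationReport",
    "estimate_ic_region",
    "validate",
    "sweep",
    "estimate_period",
]

# Pass line on the deterministic QSSA error.  The validated quantity is
# comparative (no universal pass line exists), so this default is a
# convention, calibrated so the catalog systems reproduce their known
# qualitative outcomes; it sits >=3x away from every measured catalog error
# on either side.  Always reported alongside the raw error and overridable.
DEFAULT_THRESHOLD = 0.02


@dataclass
class ValidationReport:
    ic_region: ICRegion
    det_report: DeterministicErrorReport
    threshold: float
    verdict: str  # "valid" | "invalid"
    provenance: dict = field(default_factory=dict)

    @property
    def max_error(self) -> float:
        return self.det_report.max_error

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "threshold": self.threshold,
            "max_error": self.det_report.max_error,
            "argmax_ic": self.det_report.argmax_ic,
            "observable": self.det_report.observable,
            "T": self.det_report.T,
            "slow_intervals": {k: list(v) for k, v in self.ic_region.slow_intervals.items()},
            "fast_ranges": {k: list(v) for k, v in self.ic_region.fast_ranges.items()},
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"stochastic QSSA verdict: {self.verdict.upper()}",
            f"  max deterministic error {self.det_report.max_error:.4g} "
            f"(threshold {self.threshold:g}) over T={self.det_report.T:g}, "
            f"observable {self.det_report.observable}",
            f"  argmax initial condition: "
            + ", ".join(f"{k}={v:.4g}" for k, v in self.det_report.argmax_ic.items()),
            "  slow intervals: "
            + ", ".join(
                f"{k} in [{lo:.4g}, {hi:.4g}]"
                for k, (lo, hi) in self.ic_region.slow_intervals.items()
            ),
        ]
        return "\n".join(lines)


def _rounded_counts(network: ReactionNetwork, state: dict | None = None) -> dict:
    state = state or network.initial_state()
    return {s: int(round(state[s] * network.volume)) for s in network.species_order}


def estimate_period(network: ReactionNetwork, observable: str, t_max: float = 100.0) -> float:
    """Limit-cycle period from deterministic peaks of the observable."""
    from scipy.signal import find_peaks

    traj = integrate(network, t_end=t_max, n_out=4000)
    x = traj[observable]
    peaks, _ = find_peaks(x, prominence=0.05 * (x.max() - x.min()))
    peaks = peaks[traj.times[peaks] > 0.2 * t_max]
    if len(peaks) < 3:
        raise ValueError("could not detect enough oscillation peaks to estimate a period")
    return float(np.mean(np.diff(traj.times[peaks])))


def estimate_ic_region(
    reduced: ReactionNetwork,
    slow_species: list[str],
    pair: ModelPair,
    n_reps: int = 1000,
    seed: int = 0,
    burn_in: float | None = None,
    mode: str = "stationary",
    grid_points_per_dim: int = 5,
    fast_caps: dict | None = None,
    allow_auxiliary_full_ssa: bool = False,
    percentiles: tuple = (1.0, 99.0),
) -> ICRegion:
    """Slow intervals from reduced-model SSA; fast ranges from physical bounds."""
    sim_net = reduced.without_prefactor()
    if burn_in is None:
        burn_in = default_burn_in(sim_net)

    if mode == "stationary":
        mom = stationary_moments(
            sim_net, _rounded_counts(sim_net), burn_in, burn_in * 1.000001, n_reps, seed
        )
        slow_intervals = {}
        for sp in slow_species:
            samples = mom.species_samples(sp) / sim_net.volume
            m, sd = float(np.mean(samples)), float(np.std(samples, ddof=1))
            spec = sim_net.spec(sp)
            slow_intervals[sp] = (max(spec.lo, m - 3 * sd), min(spec.hi, m + 3 * sd))
    elif mode == "oscillatory":
        period = estimate_period(reduced, slow_species[0], t_max=max(10 * burn_in, 100.0))
        times = burn_in + np.linspace(0.0, period, 21)
        ens = run_ensemble(sim_net, _rounded_counts(sim_net), times, n_reps, seed)
        slow_intervals = {}
        for sp in slow_species:
            pooled = ens.counts[:, :, sim_net.species_order.index(sp)].ravel() / sim_net.volume
            lo, hi = np.percentile(pooled, percentiles)
            spec = sim_net.spec(sp)
            slow_intervals[sp] = (max(spec.lo, float(lo)), min(spec.hi, float(hi)))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    fast_ranges = {}
    for sp in pair.grid_species:
        spec = pair.full.spec(sp)
        hi = spec.hi
        if not np.isfinite(hi):
            if fast_caps and sp in fast_caps:
                hi = float(fast_caps[sp])
            elif allow_auxiliary_full_ssa:
                aux = stationary_moments(
                    pair.full,
                    _rounded_counts(pair.full),
                    burn_in,
                    burn_in * 1.000001,
                    max(200, n_reps // 5),
                    seed + 7,
                )
                samples = aux.species_samples(sp) / pair.full.volume
                hi = float(np.mean(samples) + 5 * np.std(samples, ddof=1))
            else:
                raise ValueError(
                    f"fast species {sp!r} is unbounded: supply fast_caps[{sp!r}] or set "
                    "allow_auxiliary_full_ssa=True"
                )
        fast_ranges[sp] = (spec.lo, hi)
    return ICRegion(slow_intervals, fast_ranges, grid_points_per_dim)


def validate(
    pair: ModelPair,
    slow_species: list[str],
    T: float,
    threshold: float = DEFAULT_THRESHOLD,
    n_reps: int = 1000,
    seed: int = 0,
    burn_in: float | None = None,
    mode: str = "stationary",
    grid_points_per_dim: int = 5,
    n_out: int = 2000,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    fast_caps: dict | None = None,
    allow_auxiliary_full_ssa: bool = False,
) -> ValidationReport:
    """Run the full three-step procedure and return the verdict.

    Only the reduced model is ever simulated stochastically; the verdict is
    otherwise a purely deterministic computation.
    """
    region = estimate_ic_region(
        pair.reduced, slow_species, pair, n_reps, seed, burn_in, mode,
        grid_points_per_dim, fast_caps, allow_auxiliary_full_ssa,
    )
    det = deterministic_qssa_error(pair, region, T, n_out, rtol, atol)
    verdict = "valid" if det.max_error <= threshold else "invalid"
    return ValidationReport(
        ic_region=region,
        det_report=det,
        threshold=threshold,
        verdict=verdict,
        provenance={
            "pair": pair.name,
            "seed": seed,
            "n_reps": n_reps,
            "burn_in": burn_in,
            "mode": mode,
            "T": T,
            "grid_points_per_dim": grid_points_per_dim,
            "n_out": n_out,
            "rtol": rtol,
            "atol": atol,
        },
    )


def sweep(
    pair_factory,
    parameter: str,
    grid,
    slow_species: list[str],
    T: float,
    det_n_reps: int = 1000,
    stoch_n_reps: int = 1000,
    seed: int = 0,
    burn_in: float | None = None,
    stoch_burn_in: float | None = None,
    grid_points_per_dim: int = 5,
    n_out: int = 2000,
    include_stochastic: bool = True,
) -> pd.DataFrame:
    """Deterministic and stochastic QSSA errors across a parameter grid.

    All grid points share the same seeds (common random numbers), so trends
    across the grid are not masked by independent sampling noise.  Returns a
    tidy table with one row per parameter value.
    """
    rows = []
    for value in grid:
        pair = pair_factory(**{parameter: value})
        region = estimate_ic_region(
            pair.reduced, slow_species, pair, det_n_reps, seed, burn_in,
            grid_points_per_dim=grid_points_per_dim,
        )
        det = deterministic_qssa_error(pair, region, T, n_out)
        row = {
            "parameter": parameter,
            "value": value,
            "det_error": det.max_error,
        }
        if include_stochastic:
            st = stochastic_cv_error(
                pair.full,
                pair.reduced,
                pair.observable,
                burn_in=stoch_burn_in,
                n_reps=stoch_n_reps,
                seed_base=seed,
                initial_full=_rounded_counts(pair.full),
                initial_reduced=_rounded_counts(pair.reduced),
            )
            row.update(
                stoch_error=st.rel_cv_error,
                cv_full=st.cv_full,
                cv_reduced=st.cv_reduced,
                cv_diff=st.cv_diff,
                bootstrap_se=st.bootstrap_se,
                cv_diff_se=st.cv_diff_se,
            )
        rows.append(row)
    return pd.DataFrame(rows)
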