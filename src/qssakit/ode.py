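"""Deterministic integration, steady states, and the L1 trajectory error.

The relative L1 error

    err = int_0^T |X_full(t) - X_QSSA(t)| dt / int_0^T |X_QSSA(t)| dt

computed on a shared uniform output grid (trapezoidal rule) is the inner
quantity of the initial-condition-sweep validation metric.  Default solver
tolerances are tight (rtol=1e-8, atol=1e-10) because the full models are
stiff when binding/unbinding constants are large and the initial-transient
phase -- timescale 1/(k_f*R + k_b) -- must be resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import ReactionNetwork

__all__ = [
    "Trajectory",
    "IntegrationError",
    "integrate",
    "steady_state",
    "l1_relative_error",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_N_OUT = 2000


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the failing time in ``.time``."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


@dataclass
class Trajectory:
    """A time course sampled on a grid: ``states[k, i]`` = species i at times[k]."""

    times: np.ndarray
    states: np.ndarray
    species_order: list[str]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, len(self.species_order)):
            raise ValueError("states shape does not match times/species")

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, self.species_order.index(species)]

    def final_state(self) -> dict:
        return dict(zip(self.species_order, self.states[-1]))

    def to_csv(self, path) -> None:
        header = "time," + ",".join(self.species_order)
        np.savetxt(
            path,
            np.column_stack([self.times, self.states]),
            delimiter=",",
            header=header,
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        with open(path) as fh:
            names = fh.readline().strip().split(",")
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(data[:, 0], data[:, 1:], names[1:])


def integrate(
    network: ReactionNetwork,
    initial: dict | None = None,
    t_end: float = 1.0,
    n_out: int = DEFAULT_N_OUT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the network on a uniform grid of ``n_out + 1`` points."""
    order = network.species_order
    init = network.initial_state()
    if initial is not None:
        init.update(initial)
    x0 = np.array([init[s] for s in order], dtype=float)
    rhs = network.rhs_function()
    t_eval = np.linspace(0.0, t_end, n_out + 1)
    sol = solve_ivp(
        lambda t, x: rhs(x),
        (0.0, t_end),
        x0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(
            f"integration of {network.name!r} failed at t={t_fail:g}: {sol.message}",
            time=t_fail,
        )
    return Trajectory(sol.t, sol.y.T, order)


def steady_state(
    network: ReactionNetwork,
    guess: dict | None = None,
    t_relax: float = 200.0,
    tol: float = 1e-10,
) -> dict:
    """A state with ``max|rhs| < tol * scale``, via relaxation then root-finding."""
    order = network.species_order
    relaxed = integrate(network, guess, t_end=t_relax, n_out=50).final_state()
    x0 = np.array([relaxed[s] for s in order])
    rhs = network.rhs_function()
    sol = root(rhs, x0, method="hybr", tol=1e-13)
    x = sol.x if sol.success else x0
    scale = max(1.0, float(np.max(np.abs(x))))
    resid = float(np.max(np.abs(rhs(x))))
    if resid > tol * scale:
        raise IntegrationError(
            f"steady-state search for {network.name!r} stalled (residual {resid:.3e})"
        )
    return dict(zip(order, x))


def l1_relative_error(
    full_traj: Trajectory,
    reduced_traj: Trajectory,
    species: str,
    T: float | None = None,
) -> float:
    """Relative L1 distance of one species between two matched trajectories."""
    if full_traj.times.shape != reduced_traj.times.shape or not np.allclose(
        full_traj.times, reduced_traj.times, rtol=1e-9, atol=1e-12
    ):
        raise ValueError("trajectories are not sampled on the same grid")
    times = full_traj.times
    if T is None:
        T = float(times[-1])
    if T > times[-1] * (1 + 1e-9):
        raise ValueError(f"grid covers [0, {times[-1]:g}] but T={T:g} requested")
    mask = times <= T * (1 + 1e-12)
    t = times[mask]
    xf = full_traj[species][mask]
    xr = reduced_traj[species][mask]
    denom = float(np.trapezoid(np.abs(xr), t))
    if denom <= 0.0:
        raise ZeroDivisionError("degenerate reduced trajectory: zero denominator integral")
    return float(np.trapezoid(np.abs(xf - xr), t)) / denom
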