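"""Trajectory integration inside the invariant box and attractor assignment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .atlas import Equilibrium
from .model import ModelParams, State, vector_field

__all__ = [
    "Trajectory",
    "IntegrationError",
    "AttractorConfigError",
    "integrate",
    "assign_attractor",
    "simulate",
]

#: defaults chosen so that the slowest printed feedback coefficients
#: (order 0.1 per time unit) relax well inside the horizon
T_END = 2000.0
RTOL = 1e-9
ATOL = 1e-11
DIST_TOL = 1e-3
RESIDUAL_TOL = 1e-6


class IntegrationError(RuntimeError):
    """Integrator failed; carries the partial trajectory in ``.trajectory``."""

    def __init__(self, message: str, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.trajectory = trajectory


class AttractorConfigError(ValueError):
    """Two stable equilibria closer than the assignment tolerance."""


@dataclass
class Trajectory:
    """A time-indexed solution path with its attractor assignment."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 3)
    terminal_residual: float
    max_box_violation: float
    attractor: str = "unresolved"

    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x": self.states[:, 0], "r": self.states[:, 1], "c": self.states[:, 2]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _box_violation(states: np.ndarray, params: ModelParams) -> float:
    lo = np.array([0.0, 0.0, params.beta])
    hi = np.array([1.0, 1.0, params.alpha])
    return float(max(np.max(lo - states, initial=0.0), np.max(states - hi, initial=0.0)))


def integrate(
    state0: State | np.ndarray,
    params: ModelParams,
    t_end: float = T_END,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "RK45",
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the coupled system from ``state0`` over ``[0, t_end]``.

    The default solver is an adaptive explicit embedded Runge-Kutta pair:
    the vector field is polynomial with eigenvalues of order one (non-stiff),
    and trajectories routinely pass exponentially close to the invariant
    faces, where implicit and stiffness-switching multistep solvers are prone
    to step-size collapse.  Stiff-capable methods remain selectable via
    ``method`` (any ``scipy.integrate.solve_ivp`` method name).

    The faces of the box are exactly invariant, so any numerical excursion is
    an error-control artefact; the stored states are clipped back into the
    box and the largest excursion is recorded as ``max_box_violation``.
    """
    y0 = state0.as_array() if isinstance(state0, State) else np.asarray(state0, dtype=float)
    State(*y0).validate(params)

    sol = solve_ivp(
        lambda t, y: vector_field(y, params),
        (0.0, float(t_end)),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=False,
    )
    states = sol.y.T
    violation = _box_violation(states, params)
    lo = np.array([0.0, 0.0, params.beta])
    hi = np.array([1.0, 1.0, params.alpha])
    states = np.clip(states, lo, hi)
    residual = float(np.linalg.norm(vector_field(states[-1], params)))
    traj = Trajectory(sol.t, states, residual, violation)
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}", trajectory=traj)
    return traj


def assign_attractor(
    traj: Trajectory,
    stable: list[Equilibrium],
    dist_tol: float = DIST_TOL,
    residual_tol: float = RESIDUAL_TOL,
) -> str:
    """Label a trajectory by the unique stable equilibrium it settled on.

    Returns ``"unresolved"`` when the final state is not within ``dist_tol``
    of any stable equilibrium or the vector field there has norm above
    ``residual_tol`` (still in transit, or parked on an unstable set).
    """
    coords = np.array([eq.coords() for eq in stable]) if stable else np.empty((0, 3))
    for i in range(len(stable)):
        for j in range(i + 1, len(stable)):
            if np.linalg.norm(coords[i] - coords[j]) < 2 * dist_tol:
                raise AttractorConfigError(
                    f"stable equilibria {stable[i].label} and {stable[j].label} are closer "
                    f"than 2*dist_tol={2 * dist_tol}; reduce dist_tol"
                )
    if traj.terminal_residual > residual_tol or not len(stable):
        traj.attractor = "unresolved"
        return traj.attractor
    d = np.linalg.norm(coords - traj.final_state(), axis=1)
    k = int(np.argmin(d))
    traj.attractor = stable[k].label if d[k] <= dist_tol else "unresolved"
    return traj.attractor


def simulate(
    state0: State | np.ndarray,
    params: ModelParams,
    stable: list[Equilibrium] | None = None,
    **kwargs,
) -> Trajectory:
    """Integrate and, when a stable set is supplied, assign the attractor."""
    traj = integrate(state0, params, **kwargs)
    if stable is not None:
        assign_attractor(traj, stable)
    return traj
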