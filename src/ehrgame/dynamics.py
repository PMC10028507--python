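"""Numerical integration of the three-population replicator system.

The state (x, y, z) collects the strategy fractions of governments pushing
hard, hospitals participating actively and patients supervising.  Each
coordinate follows ``u' = u (1 - u) g_u`` with the gains of
:mod:`ehrgame.game`, so the unit cube is forward-invariant for the continuous
system and every cube vertex is an exact fixed point.

Two integrators are provided:

* ``fixed-step-euler`` — explicit Euler at a 0.125-year step over a 20-year
  horizon, mirroring a stock-and-flow system-dynamics run.  At realistic
  payoff magnitudes Euler can overshoot the cube within a single step; the
  integrator projects the state back onto [0, 1] after each step and records
  the largest projection on the trajectory.  Setting
  ``clamp_tolerance`` to a number turns a larger projection into a hard
  :class:`StepTooCoarseError` naming the offending time.
* ``adaptive-rk`` — :func:`scipy.integrate.solve_ivp` (LSODA, which switches
  to a stiff method when the gains are large), sampled on the same time grid.
  This is the accuracy reference; for the continuous dynamics the cube is
  invariant, so only roundoff-level projection is ever needed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .params import MixedState, ParameterSet

__all__ = [
    "IntegratorConfig",
    "Trajectory",
    "StepTooCoarseError",
    "rhs",
    "integrate",
    "detect_convergence",
    "time_to_threshold",
    "nudge_interior",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

_COORDS = {"x": 0, "y": 1, "z": 2}


class StepTooCoarseError(RuntimeError):
    """The fixed step produced an out-of-cube excursion beyond tolerance."""

    def __init__(self, time: float, magnitude: float, tolerance: float):
        self.time = time
        self.magnitude = magnitude
        self.tolerance = tolerance
        super().__init__(
            f"integration step too coarse: clamping by {magnitude:.3g} "
            f"(> tolerance {tolerance:.3g}) at t={time:.6g} years"
        )


@dataclasses.dataclass(frozen=True)
class IntegratorConfig:
    """Integration scheme and time grid.

    ``clamp_tolerance=None`` clamps silently (the excursion magnitude is
    still recorded on the trajectory); a numeric value makes a larger
    excursion a diagnostic failure.
    """

    method: Literal["fixed-step-euler", "adaptive-rk"] = "fixed-step-euler"
    step: float = 0.125
    t0: float = 0.0
    t_end: float = 20.0
    clamp_tolerance: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("fixed-step-euler", "adaptive-rk"):
            raise ValueError(f"unknown integrator method {self.method!r}")
        if not self.t_end > self.t0:
            raise ValueError("t_end must exceed t0")
        if not 0 < self.step <= self.t_end - self.t0:
            raise ValueError("step must be positive and at most t_end - t0")
        if self.clamp_tolerance is not None and self.clamp_tolerance < 0:
            raise ValueError("clamp_tolerance must be nonnegative")

    def grid(self) -> np.ndarray:
        n_steps = int(round((self.t_end - self.t0) / self.step))
        return self.t0 + self.step * np.arange(n_steps + 1)


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Time series of states produced by :func:`integrate`."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 3), columns x, y, z
    config: IntegratorConfig
    max_clamp: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if times.ndim != 1 or states.shape != (times.size, 3):
            raise ValueError("times must be 1-D and states (len(times), 3)")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if states.size and (states.min() < 0 or states.max() > 1):
            raise ValueError("states must lie in the closed unit cube")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    def __len__(self) -> int:
        return self.times.size

    @property
    def final_state(self) -> MixedState:
        return MixedState.from_iterable(self.states[-1])

    def coordinate(self, name: str) -> np.ndarray:
        return self.states[:, _COORDS[name]]


def _rates(u: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Replicator right-hand side without cube validation (integrator core)."""
    x, y, z = u
    p = params
    g_x = (p.Rg + p.Fg + p.Mh + p.Kg - p.Cg) - y * (z * p.Fp + p.Fg + p.Fh + p.Mh)
    g_y = (p.Rh + p.Kh - p.Ch) + x * (p.Fh + p.Mh)
    g_z = x * (p.Fp - p.Rp + y * p.Rp) + (1 - y) * p.Rp - p.Cp
    return np.array([x * (1 - x) * g_x, y * (1 - y) * g_y, z * (1 - z) * g_z])


def rhs(state: MixedState, params: ParameterSet) -> tuple[float, float, float]:
    """Per-year rates of change of (x, y, z) at a state in the unit cube."""
    if not isinstance(state, MixedState):
        state = MixedState.from_iterable(state)  # validates the cube
    rates = _rates(np.array(state.as_tuple()), params)
    return (float(rates[0]), float(rates[1]), float(rates[2]))


def nudge_interior(state: MixedState, epsilon_offset: float = 1e-6) -> MixedState:
    """Move exact-boundary coordinates slightly into the open cube.

    Boundary states are invariant under the replicator flow; nudging emulates
    the small strategy perturbations that start an evolution away from a pure
    initial state.
    """
    vals = [min(max(v, epsilon_offset), 1.0 - epsilon_offset) for v in state.as_tuple()]
    return MixedState.from_iterable(vals)


def integrate(
    state0: MixedState,
    params: ParameterSet,
    config: IntegratorConfig | None = None,
) -> Trajectory:
    """Integrate the replicator system from ``state0``; deterministic."""
    if not isinstance(state0, MixedState):
        state0 = MixedState.from_iterable(state0)
    config = config or IntegratorConfig()
    times = config.grid()

    if config.method == "fixed-step-euler":
        states = np.empty((times.size, 3))
        states[0] = state0.as_tuple()
        max_clamp = 0.0
        u = states[0].copy()
        for i in range(1, times.size):
            u = u + config.step * _rates(u, params)
            clamped = np.clip(u, 0.0, 1.0)
            excursion = float(np.max(np.abs(u - clamped)))
            if excursion > max_clamp:
                max_clamp = excursion
            if config.clamp_tolerance is not None and excursion > config.clamp_tolerance:
                raise StepTooCoarseError(times[i], excursion, config.clamp_tolerance)
            u = clamped
            states[i] = u
        return Trajectory(times, states, config, max_clamp)

    # Evaluate the rates on the state projected onto the cube: identical for
    # admissible states, but keeps trial steps of the adaptive solver from
    # wandering into the region outside [0, 1]^3 where the cubic RHS diverges.
    sol = solve_ivp(
        lambda t, u: _rates(np.clip(u, 0.0, 1.0), params),
        (config.t0, config.t_end),
        np.array(state0.as_tuple()),
        method="LSODA",
        t_eval=times,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:  # pragma: no cover - LSODA is robust on this RHS
        raise RuntimeError(f"adaptive integration failed: {sol.message}")
    states = sol.y.T
    clamped = np.clip(states, 0.0, 1.0)
    max_clamp = float(np.max(np.abs(states - clamped))) if states.size else 0.0
    if config.clamp_tolerance is not None and max_clamp > config.clamp_tolerance:
        idx = int(np.argmax(np.max(np.abs(states - clamped), axis=1)))
        raise StepTooCoarseError(times[idx], max_clamp, config.clamp_tolerance)
    return Trajectory(times, clamped, config, max_clamp)


def detect_convergence(
    traj: Trajectory, tol: float = 1e-3
) -> tuple[int, int, int] | None:
    """Vertex the trajectory has settled at, or ``None``.

    A vertex qualifies if the final state is within sup-norm ``tol`` of it
    *and* the sup-distance to it is nonincreasing over the last 10% of the
    samples (so a trajectory merely passing near a vertex does not count).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if tol <= 0:
        raise ValueError("tol must be positive")
    final = traj.states[-1]
    vertex = tuple(int(round(v)) for v in final)
    dist = np.max(np.abs(traj.states - np.array(vertex)), axis=1)
    if dist[-1] > tol:
        return None
    tail = dist[-max(2, len(traj) // 10):]
    if np.any(np.diff(tail) > 1e-12):
        return None
    return vertex


def time_to_threshold(
    traj: Trajectory, coordinate: str | int, threshold: float
) -> float | None:
    """First time a coordinate crosses a threshold, by linear interpolation.

    Returns ``None`` when the coordinate never reaches the threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    idx = _COORDS[coordinate] if isinstance(coordinate, str) else int(coordinate)
    values = traj.states[:, idx] - threshold
    if values[0] == 0.0:
        return float(traj.times[0])
    sign_change = np.nonzero(values[:-1] * values[1:] <= 0)[0]
    if sign_change.size == 0:
        return None
    i = int(sign_change[0])
    v0, v1 = values[i], values[i + 1]
    t0, t1 = traj.times[i], traj.times[i + 1]
    if v1 == v0:  # flat segment sitting exactly on the threshold
        return float(t1)
    return float(t0 - v0 * (t1 - t0) / (v1 - v0))


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write ``t,x,y,z`` rows at full floating precision."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("t,x,y,z\n")
        for t, (x, y, z) in zip(traj.times, traj.states):
            fh.write(f"{float(t)!r},{float(x)!r},{float(y)!r},{float(z)!r}\n")


def read_trajectory_csv(
    path: str | Path, config: IntegratorConfig | None = None
) -> Trajectory:
    """Round-trip reader for :func:`write_trajectory_csv` output."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    times, states = data[:, 0], data[:, 1:4]
    if config is None:
        step = float(times[1] - times[0]) if times.size > 1 else 1.0
        config = IntegratorConfig(step=step, t0=float(times[0]), t_end=float(times[-1]))
    return Trajectory(times, states, config)
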