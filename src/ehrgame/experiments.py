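"""Simulation studies: initial-condition scenarios and sensitivity sweeps.

Three families of experiments mirror the study design of the underlying
analysis:

* :func:`run_fig2_scenarios` — six labelled initial conditions (interior and
  exact-boundary) integrated under the reference fixed-step scheme, with
  convergence verdicts; exact-boundary starts are run both as given (where
  they are invariant) and nudged slightly into the interior.
* :func:`oat_sweep` — one-at-a-time parameter sweeps recording a metric
  (time to a threshold, final state, or converged vertex) per swept value.
* :func:`patient_threshold_experiment` and
  :func:`diminishing_penalty_experiment` — the two targeted designs: the
  knife-edge in the patients' long-run behaviour at ``Fp = Cp``, and the
  diminishing marginal effect of the hospital penalty ``Mh``.

Sweeps default to the adaptive integrator so that metric differences across
swept values reflect the continuous dynamics rather than fixed-step
saturation artefacts.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .dynamics import (
    IntegratorConfig,
    Trajectory,
    detect_convergence,
    integrate,
    nudge_interior,
    time_to_threshold,
)
from .params import BASELINE, PARAM_NAMES, ConstraintError, MixedState, ParameterSet
from .stability import classify_vertex

__all__ = [
    "FIG2_STARTS",
    "ScenarioResult",
    "run_fig2_scenarios",
    "SweepSpec",
    "SweepOutcome",
    "SweepResult",
    "oat_sweep",
    "default_sweep_values",
    "PatientThresholdReport",
    "patient_threshold_experiment",
    "PenaltyMarginalReport",
    "diminishing_penalty_experiment",
]

#: The six labelled initial conditions of the holistic simulation.
FIG2_STARTS: dict[str, tuple[float, float, float]] = {
    "A": (0.01, 0.01, 0.01),
    "B": (0.45, 0.35, 0.4),
    "C": (0.99, 0.01, 0.01),
    "D": (0.0, 0.8, 0.01),
    "E": (0.05, 0.5, 0.01),
    "F": (0.99, 0.0, 0.01),
}

_ADAPTIVE = IntegratorConfig(method="adaptive-rk")


@dataclasses.dataclass(frozen=True)
class ScenarioResult:
    """One labelled scenario: as-given run plus an optional nudged rerun."""

    label: str
    start: tuple[float, float, float]
    trajectory: Trajectory
    verdict: tuple[int, int, int] | None
    nudged_start: tuple[float, float, float] | None = None
    nudged_trajectory: Trajectory | None = None
    nudged_verdict: tuple[int, int, int] | None = None


def run_fig2_scenarios(
    params: ParameterSet = BASELINE,
    config: IntegratorConfig | None = None,
    epsilon_offset: float = 1e-6,
    tol: float = 1e-3,
) -> dict[str, ScenarioResult]:
    """Integrate the six labelled scenarios and attach convergence verdicts.

    Scenarios whose printed start sits exactly on the cube boundary are
    additionally rerun from a start nudged ``epsilon_offset`` into the
    interior, since exact-boundary coordinates are invariant under the
    replicator flow; both verdicts are reported.
    """
    config = config or IntegratorConfig()
    out: dict[str, ScenarioResult] = {}
    for label, start in FIG2_STARTS.items():
        state0 = MixedState(*start)
        traj = integrate(state0, params, config)
        verdict = detect_convergence(traj, tol)
        nudged_start = nudged_traj = nudged_verdict = None
        if any(v in (0.0, 1.0) for v in start):
            nudged = nudge_interior(state0, epsilon_offset)
            nudged_start = nudged.as_tuple()
            nudged_traj = integrate(nudged, params, config)
            nudged_verdict = detect_convergence(nudged_traj, tol)
        out[label] = ScenarioResult(
            label=label,
            start=start,
            trajectory=traj,
            verdict=verdict,
            nudged_start=nudged_start,
            nudged_trajectory=nudged_traj,
            nudged_verdict=nudged_verdict,
        )
    return out


@dataclasses.dataclass(frozen=True)
class SweepSpec:
    """A one-at-a-time sweep of a single parameter.

    ``metric`` is one of ``time-to-threshold`` (years for ``coordinate`` to
    cross ``threshold``), ``final-state`` or ``converged-vertex``.
    """

    parameter: str
    values: tuple[float, ...]
    baseline: ParameterSet = BASELINE
    initial_state: MixedState = MixedState(0.45, 0.35, 0.4)
    metric: str = "time-to-threshold"
    coordinate: str = "x"
    threshold: float = 0.99
    config: IntegratorConfig = _ADAPTIVE
    strict: bool = True

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.metric not in ("time-to-threshold", "final-state", "converged-vertex"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if not self.values:
            raise ValueError("values must be nonempty")


@dataclasses.dataclass(frozen=True)
class SweepOutcome:
    """Metric outcome for one swept value.

    ``flag`` is ``"constraint-violated"`` when the value breaks a strict-mode
    ordering (the run is flagged, never silently dropped).
    """

    value: float
    metric: float | tuple | None
    trajectory: Trajectory | None
    flag: str | None = None


@dataclasses.dataclass(frozen=True)
class SweepResult:
    spec: SweepSpec
    outcomes: tuple[SweepOutcome, ...]

    def metrics(self) -> list[float | tuple | None]:
        return [o.metric for o in self.outcomes]


def default_sweep_values(parameter: str, baseline: ParameterSet = BASELINE) -> tuple[float, ...]:
    """Default sweep grid: half, one and two times the baseline value."""
    base = getattr(baseline, parameter)
    return (0.5 * base, base, 2.0 * base)


def oat_sweep(spec: SweepSpec) -> SweepResult:
    """Run a one-at-a-time sweep; deterministic for a fixed spec."""
    outcomes: list[SweepOutcome] = []
    for value in spec.values:
        try:
            params = spec.baseline.replace(
                **{spec.parameter: float(value), "strict": spec.strict}
            )
        except ConstraintError as err:
            outcomes.append(
                SweepOutcome(float(value), None, None, flag=f"constraint-violated: {err}")
            )
            continue
        traj = integrate(spec.initial_state, params, spec.config)
        if spec.metric == "time-to-threshold":
            metric = time_to_threshold(traj, spec.coordinate, spec.threshold)
        elif spec.metric == "final-state":
            metric = traj.final_state.as_tuple()
        else:
            metric = detect_convergence(traj, tol=1e-3)
        outcomes.append(SweepOutcome(float(value), metric, traj))
    return SweepResult(spec, tuple(outcomes))


@dataclasses.dataclass(frozen=True)
class PatientThresholdReport:
    """Long-run patient behaviour in the three reward-vs-cost regimes.

    The patients' eigenvalue at the all-cooperate vertex (1, 1, 1) is
    ``-(Fp - Cp)``: supervision survives in the long run exactly when the
    supervision reward exceeds its cost, collapses when it falls short, and
    the vertex is non-hyperbolic in z on the knife edge ``Fp = Cp``.
    """

    regimes: tuple[str, str, str]
    params: tuple[ParameterSet, ParameterSet, ParameterSet]
    z_limits: tuple[float, float, float]
    z_eigenvalues: tuple[float, float, float]
    classifications: tuple[str, str, str]


def patient_threshold_experiment(
    params: ParameterSet = BASELINE,
    start: MixedState = MixedState(0.45, 0.35, 0.4),
    config: IntegratorConfig | None = None,
) -> PatientThresholdReport:
    """Compare the three regimes Fp > Cp, Fp = Cp and Fp < Cp.

    All other parameters stay at the supplied baseline; the common interior
    start isolates the effect of the reward/cost difference on the patients'
    limiting behaviour.
    """
    config = config or IntegratorConfig(method="adaptive-rk")
    mid = 0.5 * (params.Fp + params.Cp) or 1.0
    regime_params = (
        params.replace(Fp=max(params.Fp, params.Cp + 1.0)),   # reward dominates
        params.replace(Fp=mid, Cp=mid),                        # knife edge
        params.replace(Fp=max(params.Cp - 1.0, 0.0), Cp=max(params.Cp, params.Fp)),
    )
    # Guarantee the third regime really has Fp < Cp whatever the input values.
    low = regime_params[2]
    if not low.Fp < low.Cp:
        low = low.replace(Cp=low.Fp + 1.0)
        regime_params = (regime_params[0], regime_params[1], low)

    z_limits, z_eigs, classes = [], [], []
    for p in regime_params:
        traj = integrate(start, p, config)
        z_limits.append(float(traj.coordinate("z")[-1]))
        report = classify_vertex((1, 1, 1), p)
        z_eigs.append(report.eigenvalues[2])
        classes.append(report.classification)
    return PatientThresholdReport(
        regimes=("Fp>Cp", "Fp=Cp", "Fp<Cp"),
        params=regime_params,
        z_limits=tuple(z_limits),
        z_eigenvalues=tuple(z_eigs),
        classifications=tuple(classes),
    )


@dataclasses.dataclass(frozen=True)
class PenaltyMarginalReport:
    """Diminishing marginal effect of the hospital penalty Mh.

    ``times`` are the years for the hospital fraction y to cross the
    threshold at each penalty level; ``per_unit_improvements`` are the
    successive time reductions divided by the penalty increments.
    """

    mh_values: tuple[float, ...]
    times: tuple[float | None, ...]
    per_unit_improvements: tuple[float, ...]
    marginal_effect_nonincreasing: bool


def diminishing_penalty_experiment(
    params: ParameterSet = BASELINE,
    mh_values: Sequence[float] = (5.0, 10.0, 20.0, 40.0),
    start: MixedState = MixedState(0.45, 0.35, 0.4),
    threshold: float = 0.99,
    config: IntegratorConfig | None = None,
) -> PenaltyMarginalReport:
    """Sweep the penalty Mh and measure the per-unit speed-up of hospitals."""
    mh_values = tuple(float(v) for v in mh_values)
    if any(b < a for a, b in zip(mh_values, mh_values[1:])):
        raise ValueError("mh_values must be nondecreasing")
    config = config or IntegratorConfig(method="adaptive-rk")
    spec = SweepSpec(
        parameter="Mh",
        values=mh_values,
        baseline=params,
        initial_state=start,
        metric="time-to-threshold",
        coordinate="y",
        threshold=threshold,
        config=config,
    )
    result = oat_sweep(spec)
    times = tuple(result.metrics())
    per_unit: list[float] = []
    for (m0, t0), (m1, t1) in zip(
        zip(mh_values, times), zip(mh_values[1:], times[1:])
    ):
        if t0 is None or t1 is None or m1 == m0:
            per_unit.append(0.0)
        else:
            per_unit.append((t0 - t1) / (m1 - m0))
    nonincreasing = all(b <= a + 1e-12 for a, b in zip(per_unit, per_unit[1:]))
    return PenaltyMarginalReport(
        mh_values=mh_values,
        times=times,
        per_unit_improvements=tuple(per_unit),
        marginal_effect_nonincreasing=nonincreasing,
    )
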