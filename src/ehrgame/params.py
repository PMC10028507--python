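"""Exogenous payoffs and population strategy state for the EHR-integration game.

The model has three boundedly rational populations — local governments,
hospitals inside a medical consortium, and patients — each split between two
strategies.  Twelve exogenous parameters (all in abstract, dimensionless
payoff units) describe rewards, costs, subsidies and penalties:

=======  ==========================================================
symbol   meaning
=======  ==========================================================
Rg       government benefit when it pushes EHR integration hard
Cg       government cost of pushing hard
Kg       government cost when it treats integration negatively
Fg       penalty on a negative government (accountability, reputation)
Rh       hospital revenue under normal operation
Ch       hospital cost of active participation
Kh       hospital cost of passive participation
Fh       subsidy to an actively participating hospital
Mh       penalty on a passively participating hospital (on complaint)
Fp       reward to a patient who actively supervises
Cp       patient cost of supervising
Rp       social damage caused by passive hospital participation
=======  ==========================================================

Two orderings are structural: negligence is cheaper than effort for both the
government (``Cg > Kg``) and the hospital (``Ch > Kh``).  A *strict*
:class:`ParameterSet` enforces them; ``strict=False`` admits degenerate sets
(e.g. all zeros) that are useful as algebraic probes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "PARAM_NAMES",
    "ParameterSet",
    "MixedState",
    "BASELINE",
    "load_parameters",
    "save_parameters",
]

#: Canonical field order, used for serialization and vector views.
PARAM_NAMES: tuple[str, ...] = (
    "Rg", "Cg", "Kg", "Fg",
    "Rh", "Ch", "Kh", "Fh", "Mh",
    "Fp", "Cp", "Rp",
)


class ConstraintError(ValueError):
    """A parameter set or state violates a model constraint."""


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """The twelve exogenous payoff/cost parameters.

    Parameters are nonnegative reals in abstract payoff units.  With
    ``strict=True`` (default) the orderings ``Cg > Kg`` and ``Ch > Kh``
    are enforced.
    """

    Rg: float
    Cg: float
    Kg: float
    Fg: float
    Rh: float
    Ch: float
    Kh: float
    Fh: float
    Mh: float
    Fp: float
    Cp: float
    Rp: float
    strict: bool = dataclasses.field(default=True, compare=False, repr=False)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConstraintError(f"{name} must be a real number, got {value!r}")
            if not math.isfinite(value):
                raise ConstraintError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ConstraintError(f"{name} must be nonnegative, got {value!r}")
            object.__setattr__(self, name, float(value))
        if self.strict:
            if not self.Cg > self.Kg:
                raise ConstraintError(
                    f"strict mode requires Cg > Kg (got Cg={self.Cg}, Kg={self.Kg}): "
                    "negligence must be cheaper than effort for the government"
                )
            if not self.Ch > self.Kh:
                raise ConstraintError(
                    f"strict mode requires Ch > Kh (got Ch={self.Ch}, Kh={self.Kh}): "
                    "passive participation must be cheaper for the hospital"
                )

    @classmethod
    def zeros(cls) -> "ParameterSet":
        """All-zero probe set (test mode; violates the strict orderings)."""
        return cls(**{name: 0.0 for name in PARAM_NAMES}, strict=False)

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, float], *, strict: bool = True
    ) -> "ParameterSet":
        """Build from a flat mapping whose keys are exactly the 12 symbols."""
        unknown = sorted(set(mapping) - set(PARAM_NAMES))
        if unknown:
            raise ConstraintError(f"unknown parameter key(s): {', '.join(unknown)}")
        missing = sorted(set(PARAM_NAMES) - set(mapping))
        if missing:
            raise ConstraintError(f"missing parameter key(s): {', '.join(missing)}")
        return cls(**{k: float(mapping[k]) for k in PARAM_NAMES}, strict=strict)

    def replace(self, **changes: float) -> "ParameterSet":
        """Copy with some fields replaced (used by one-at-a-time sweeps)."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in PARAM_NAMES)


#: Baseline expert-style assignment used throughout the default analyses.
BASELINE = ParameterSet(
    Rg=30.0, Cg=6.0, Kg=3.0, Fg=4.0,
    Rh=50.0, Ch=7.0, Kh=5.0, Fh=8.0, Mh=10.0,
    Fp=2.0, Cp=1.0, Rp=6.0,
)


@dataclasses.dataclass(frozen=True)
class MixedState:
    """Population strategy fractions on the closed unit cube.

    ``x`` is the fraction of governments pushing hard, ``y`` the fraction of
    hospitals participating actively, ``z`` the fraction of patients who
    supervise.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConstraintError(f"{name} must be a real number, got {value!r}")
            if not (0.0 <= value <= 1.0):
                raise ConstraintError(f"{name} must lie in [0, 1], got {value!r}")
            object.__setattr__(self, name, float(value))

    @classmethod
    def from_iterable(cls, values: Iterable[float]) -> "MixedState":
        x, y, z = values
        return cls(x, y, z)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    def is_vertex(self, tol: float = 0.0) -> bool:
        return all(
            min(abs(v), abs(1.0 - v)) <= tol for v in (self.x, self.y, self.z)
        )


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as a flat YAML mapping (JSON-compatible keys)."""
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(params.as_dict(), fh, sort_keys=False)


def load_parameters(path: str | Path, *, strict: bool = True) -> ParameterSet:
    """Read a flat key-value file (YAML or JSON) into a :class:`ParameterSet`."""
    path = Path(path)
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    if not isinstance(data, Mapping):
        raise ConstraintError(f"{path}: expected a flat key-value mapping")
    return ParameterSet.from_mapping(data, strict=strict)
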