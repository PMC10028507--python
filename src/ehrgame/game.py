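"""Payoff matrix, expected payoffs and replicator gains of the tripartite game.

Each population has two pure strategies:

* government — ``PUSH`` (push integration hard) vs ``NEGATIVE`` (treat it
  negatively),
* hospital — ``ACTIVE`` vs ``PASSIVE`` participation,
* patient — ``SUPERVISE`` (complain to the supervisory body) vs ``WAIVE``.

The 2x2x2 payoff matrix is the single source of truth for all algebra in the
package.  Expected payoffs are available both as a brute-force enumeration
over the eight pure profiles (the oracle form) and as audited closed forms;
the two must agree to machine precision, which the test suite enforces.

The replicator gain of a population is the difference between its two
conditional expected payoffs; the system's dynamics are ``x' = x(1-x) g_x``
and likewise for y and z.  The closed forms, re-derived from the payoff
matrix, are::

    g_x = (Rg + Fg + Mh + Kg - Cg) - y (z Fp + Fg + Fh + Mh)
    g_y = (Rh + Kh - Ch) + x (Fh + Mh)
    g_z = x (Fp - Rp + y Rp) + (1 - y) Rp - Cp

:func:`derivation_audit` additionally checks a set of widely reproduced
transcriptions of these equations against the matrix-derived forms and
reports the symbolic residual of every variant that does not match (several
contain sign or symbol slips).
"""

from __future__ import annotations

import dataclasses
import enum
from functools import lru_cache
from types import SimpleNamespace
from typing import Iterator

import sympy as sp

from .params import BASELINE, PARAM_NAMES, MixedState, ParameterSet

__all__ = [
    "GovStrategy",
    "HospitalStrategy",
    "PatientStrategy",
    "PureProfile",
    "PayoffTriple",
    "ExpectedPayoffs",
    "GainVector",
    "all_profiles",
    "payoff_triple",
    "expected_payoffs_enumerated",
    "gains_enumerated",
    "gain_closed_form",
    "gain_parameter_support",
    "derivation_audit",
    "EquationAudit",
]


class GovStrategy(enum.Enum):
    PUSH = "push"
    NEGATIVE = "negative"


class HospitalStrategy(enum.Enum):
    ACTIVE = "active"
    PASSIVE = "passive"


class PatientStrategy(enum.Enum):
    SUPERVISE = "supervise"
    WAIVE = "waive"


@dataclasses.dataclass(frozen=True)
class PureProfile:
    """One of the eight pure strategy combinations."""

    gov: GovStrategy
    hosp: HospitalStrategy
    pat: PatientStrategy

    def __post_init__(self) -> None:
        if not isinstance(self.gov, GovStrategy):
            raise TypeError(f"gov must be a GovStrategy, got {self.gov!r}")
        if not isinstance(self.hosp, HospitalStrategy):
            raise TypeError(f"hosp must be a HospitalStrategy, got {self.hosp!r}")
        if not isinstance(self.pat, PatientStrategy):
            raise TypeError(f"pat must be a PatientStrategy, got {self.pat!r}")


@dataclasses.dataclass(frozen=True)
class PayoffTriple:
    """Per-profile payoffs (government, hospital, patient)."""

    u_g: float
    u_h: float
    u_p: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.u_g, self.u_h, self.u_p)


def all_profiles() -> Iterator[PureProfile]:
    """Iterate over the eight pure profiles in a fixed order."""
    for gov in GovStrategy:
        for hosp in HospitalStrategy:
            for pat in PatientStrategy:
                yield PureProfile(gov, hosp, pat)


def _cell(p, push: bool, active: bool, supervise: bool):
    """Payoff-matrix cell as (u_g, u_h, u_p).

    ``p`` only needs attribute access for the 12 symbols, so the same code
    serves numeric parameter sets and sympy symbol namespaces.
    """
    if push:
        if active:
            u_g = p.Rg - p.Cg - p.Fh - (p.Fp if supervise else 0)
            u_h = p.Rh - p.Ch + p.Fh
            u_p = (p.Fp - p.Cp) if supervise else 0
        else:
            u_g = p.Rg - p.Cg + p.Mh
            u_h = -p.Kh - p.Mh
            u_p = (p.Fp - p.Cp - p.Rp) if supervise else -p.Rp
    else:
        if active:
            u_g = -p.Kg
            u_h = p.Rh - p.Ch
            u_p = -p.Cp if supervise else 0
        else:
            u_g = -p.Kg - p.Fg
            u_h = -p.Kh
            u_p = -p.Cp if supervise else -p.Rp
    return u_g, u_h, u_p


def payoff_triple(profile: PureProfile, params: ParameterSet) -> PayoffTriple:
    """Payoffs of the three players under a pure strategy profile."""
    if not isinstance(profile, PureProfile):
        raise TypeError(f"profile must be a PureProfile, got {profile!r}")
    u_g, u_h, u_p = _cell(
        params,
        profile.gov is GovStrategy.PUSH,
        profile.hosp is HospitalStrategy.ACTIVE,
        profile.pat is PatientStrategy.SUPERVISE,
    )
    return PayoffTriple(float(u_g), float(u_h), float(u_p))


@dataclasses.dataclass(frozen=True)
class ExpectedPayoffs:
    """Conditional and average expected payoffs of the three populations.

    ``Eg1``/``Eg2`` condition on the government pushing / being negative,
    ``Eh1``/``Eh2`` on active / passive hospitals, ``Ep1``/``Ep2`` on
    supervising / waiving patients; ``Eg``, ``Eh``, ``Ep`` are the population
    averages, e.g. ``Eg = x Eg1 + (1 - x) Eg2``.
    """

    Eg1: float
    Eg2: float
    Eg: float
    Eh1: float
    Eh2: float
    Eh: float
    Ep1: float
    Ep2: float
    Ep: float


@dataclasses.dataclass(frozen=True)
class GainVector:
    """Replicator gains (differences of conditional expected payoffs)."""

    g_x: float
    g_y: float
    g_z: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.g_x, self.g_y, self.g_z)


def _expected(p, x, y, z):
    """All nine expectations by enumeration over the 8 matrix cells.

    Works for numbers and sympy expressions alike.
    """
    def u(push, active, sup):
        return _cell(p, push, active, sup)

    def mix(weights_cells, idx):
        return sum(w * cell[idx] for w, cell in weights_cells)

    hp_weights = [
        (y * z, (True, True)), (y * (1 - z), (True, False)),
        ((1 - y) * z, (False, True)), ((1 - y) * (1 - z), (False, False)),
    ]
    Eg1 = sum(w * u(True, a, s)[0] for w, (a, s) in hp_weights)
    Eg2 = sum(w * u(False, a, s)[0] for w, (a, s) in hp_weights)

    gp_weights = [
        (x * z, (True, True)), (x * (1 - z), (True, False)),
        ((1 - x) * z, (False, True)), ((1 - x) * (1 - z), (False, False)),
    ]
    Eh1 = sum(w * u(g, True, s)[1] for w, (g, s) in gp_weights)
    Eh2 = sum(w * u(g, False, s)[1] for w, (g, s) in gp_weights)

    gh_weights = [
        (x * y, (True, True)), (x * (1 - y), (True, False)),
        ((1 - x) * y, (False, True)), ((1 - x) * (1 - y), (False, False)),
    ]
    Ep1 = sum(w * u(g, a, True)[2] for w, (g, a) in gh_weights)
    Ep2 = sum(w * u(g, a, False)[2] for w, (g, a) in gh_weights)

    Eg = x * Eg1 + (1 - x) * Eg2
    Eh = y * Eh1 + (1 - y) * Eh2
    Ep = z * Ep1 + (1 - z) * Ep2
    return Eg1, Eg2, Eg, Eh1, Eh2, Eh, Ep1, Ep2, Ep


def expected_payoffs_enumerated(
    state: MixedState, params: ParameterSet
) -> ExpectedPayoffs:
    """Expected payoffs by probability-weighted enumeration (oracle form)."""
    if not isinstance(state, MixedState):
        state = MixedState.from_iterable(state)
    values = _expected(params, state.x, state.y, state.z)
    return ExpectedPayoffs(*(float(v) for v in values))


def gains_enumerated(state: MixedState, params: ParameterSet) -> GainVector:
    """Replicator gains straight from the enumeration oracle."""
    e = expected_payoffs_enumerated(state, params)
    return GainVector(e.Eg1 - e.Eg2, e.Eh1 - e.Eh2, e.Ep1 - e.Ep2)


def gain_closed_form(state: MixedState, params: ParameterSet) -> GainVector:
    """Audited closed-form replicator gains.

    Must agree with :func:`gains_enumerated` to machine precision; the test
    suite checks this on thousands of random states and parameter sets.
    """
    if not isinstance(state, MixedState):
        state = MixedState.from_iterable(state)
    p, (x, y, z) = params, state.as_tuple()
    g_x = (p.Rg + p.Fg + p.Mh + p.Kg - p.Cg) - y * (z * p.Fp + p.Fg + p.Fh + p.Mh)
    g_y = (p.Rh + p.Kh - p.Ch) + x * (p.Fh + p.Mh)
    g_z = x * (p.Fp - p.Rp + y * p.Rp) + (1 - y) * p.Rp - p.Cp
    return GainVector(g_x, g_y, g_z)


# ---------------------------------------------------------------------------
# Symbolic layer: derived gains, parameter support, and the derivation audit.
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _symbols():
    """Sympy symbols for the 12 parameters and the state, plus a namespace."""
    param_syms = {name: sp.Symbol(name, nonnegative=True) for name in PARAM_NAMES}
    x, y, z = sp.symbols("x y z", nonnegative=True)
    return SimpleNamespace(**param_syms), param_syms, (x, y, z)


@lru_cache(maxsize=1)
def symbolic_gains() -> tuple[sp.Expr, sp.Expr, sp.Expr]:
    """The three gains derived symbolically from the payoff matrix."""
    ns, _, (x, y, z) = _symbols()
    Eg1, Eg2, _, Eh1, Eh2, _, Ep1, Ep2, _ = _expected(ns, x, y, z)
    return (
        sp.expand(Eg1 - Eg2),
        sp.expand(Eh1 - Eh2),
        sp.expand(Ep1 - Ep2),
    )


def gain_parameter_support() -> dict[str, tuple[str, ...]]:
    """Parameters entering each gain with a not-identically-zero coefficient.

    The government gain depends on 7 of the 12 parameters, the hospital gain
    on 5 and the patient gain on 3; these counts drive the one-at-a-time
    sensitivity designs.
    """
    _, param_syms, _ = _symbols()
    gx, gy, gz = symbolic_gains()
    out = {}
    for key, expr in (("x", gx), ("y", gy), ("z", gz)):
        names = [n for n, s in param_syms.items() if s in expr.free_symbols]
        out[key] = tuple(sorted(names))
    return out


@dataclasses.dataclass(frozen=True)
class EquationAudit:
    """Result of comparing one reported equation variant to the derived form.

    ``residual`` is ``derived - reported`` (expanded); ``residual_at_params``
    is the same expression with the numeric parameters substituted, still a
    function of the state (x, y, z).
    """

    equation: str
    matches: bool
    derived: str
    reported: str
    residual: str
    residual_at_params: str


def _reported_forms():
    """Widely reproduced transcriptions of the model's equations.

    Several variants carry sign/symbol slips relative to the payoff-matrix
    derivation; they are kept verbatim so the audit can quantify each slip.
    """
    ns, _, (x, y, z) = _symbols()
    p = ns
    Eg1, Eg2, _, Eh1, Eh2, _, Ep1, Ep2, _ = _expected(ns, x, y, z)
    gx, gy, gz = symbolic_gains()

    rep_Eg1 = (
        y * z * (p.Rg - p.Cg - p.Fh - p.Fg)          # slip: Fg where Fp belongs
        + y * (1 - z) * (p.Rg - p.Cg - p.Fh)
        + z * (1 - y) * (p.Rg - p.Cg + p.Mh)
        + (1 - y) * (1 - z) * (p.Rg - p.Cg + p.Mh)
    )
    rep_Eg2 = (
        y * z * (-p.Kg) + y * (1 - z) * (-p.Kg)
        + z * (1 - y) * (-p.Kg - p.Fg)
        + (1 - y) * (1 - z) * (-p.Kg - p.Fg)
    )
    rep_Eh1 = (
        x * z * (p.Rh - p.Ch + p.Fh) + x * (1 - z) * (p.Rh - p.Ch + p.Fh)
        + z * (1 - x) * (p.Rh - p.Ch) + (1 - x) * (1 - z) * (p.Rh - p.Ch)
    )
    rep_Eh2 = (
        x * z * (-p.Kh - p.Mh) + x * (1 - z) * (-p.Kh - p.Mh)
        + z * (1 - x) * (-p.Kh) + z * (1 - x) * (-p.Kh)  # slip: duplicated term
        + (1 - x) * (1 - z) * (-p.Kh)
    )
    rep_Ep1 = (
        x * y * (p.Fp - p.Cp) + y * (1 - x) * (-p.Cp)
        + x * (1 - y) * (p.Fp - p.Cp - p.Rp) + (1 - x) * (1 - y) * (-p.Cp)
    )
    rep_Ep2 = x * (1 - y) * (-p.Rp) + (1 - x) * (1 - y) * (-p.Rp)

    rep_gx_final = (p.Rg + p.Fg + p.Mh + p.Kg - p.Cg) - y * (
        z * p.Fp + p.Fg + p.Fh + p.Mh
    )
    rep_gy = (p.Rh + p.Kh - p.Ch) - x * (p.Fh + p.Mh)      # slip: x-term sign
    rep_gz = x * (p.Fp - p.Rp - y * p.Rp) + (1 - y) * p.Rp - p.Cp  # slip: yRp sign
    rep_sys_gx = (p.Rg + p.Fg + p.Mh + p.Kg + p.Cg) - y * (  # slip: +Cg
        z * p.Fp + p.Fg + p.Fh + p.Mh
    )
    rep_sys_gy = (p.Rh + p.Kh - p.Ch) + x * (p.Fh + p.Mh)
    rep_sys_gz = x * (p.Fp - p.Rp + y * p.Rp) + (1 - y) * p.Rp - p.Cp

    return [
        ("E_g1 (government, push)", Eg1, rep_Eg1),
        ("E_g2 (government, negative)", Eg2, rep_Eg2),
        ("E_h1 (hospital, active)", Eh1, rep_Eh1),
        ("E_h2 (hospital, passive)", Eh2, rep_Eh2),
        ("E_p1 (patient, supervise)", Ep1, rep_Ep1),
        ("E_p2 (patient, waive)", Ep2, rep_Ep2),
        ("g_x (government gain, reduced)", gx, rep_gx_final),
        ("g_y (hospital gain, reduced)", gy, rep_gy),
        ("g_z (patient gain, reduced)", gz, rep_gz),
        ("g_x (system form)", gx, rep_sys_gx),
        ("g_y (system form)", gy, rep_sys_gy),
        ("g_z (system form)", gz, rep_sys_gz),
    ]


def derivation_audit(params: ParameterSet = BASELINE) -> list[EquationAudit]:
    """Audit reported equation variants against the payoff-matrix derivation.

    For every variant, reports whether it equals the derived form as a
    polynomial identity in the parameters and the state, and the residual
    (derived minus reported) when it does not.
    """
    _, param_syms, _ = _symbols()
    subs = {param_syms[name]: getattr(params, name) for name in PARAM_NAMES}
    out: list[EquationAudit] = []
    for label, derived, reported in _reported_forms():
        residual = sp.expand(derived - reported)
        matches = residual == 0
        out.append(
            EquationAudit(
                equation=label,
                matches=bool(matches),
                derived=str(sp.expand(derived)),
                reported=str(sp.expand(reported)),
                residual=str(residual),
                residual_at_params=str(sp.expand(residual.subs(subs))),
            )
        )
    return out
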