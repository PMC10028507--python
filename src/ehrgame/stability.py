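"""Pure-strategy equilibria, Jacobian analysis and vertex stability.

Setting the three replicator equations to zero over the unit cube yields the
eight cube vertices as pure-strategy equilibria (the interior mixed
equilibrium is out of scope).  Because each equation carries the logistic
factor ``u (1 - u)``, the Jacobian at any vertex is diagonal, its eigenvalues
are simply ``±g_u`` evaluated there, and asymptotic stability is equivalent
to all three eigenvalues being negative.

A widely used shortcut classifies a vertex as stable when ``det(J) > 0`` and
``tr(J) < 0``.  In three dimensions that pair of conditions is necessary but
not sufficient (one negative and two positive eigenvalues also satisfy it),
so this module decides stability from the full eigenvalue sign pattern and
reports the shortcut's verdict alongside for comparison.

A reference table of per-vertex det/tr closed forms circulates with this
model; :func:`table3_audit` evaluates those printed expressions next to the
matrix-derived ones and flags the rows that disagree (two rows carry sign
slips).
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import sympy as sp

from .game import _symbols, symbolic_gains
from .params import BASELINE, MixedState, ParameterSet

__all__ = [
    "VERTICES",
    "enumerate_pure_equilibria",
    "jacobian",
    "classify_vertex",
    "classify_all",
    "EquilibriumReport",
    "table3_audit",
    "Table3Row",
    "write_equilibrium_csv",
]

#: The eight pure-strategy equilibria, in lexicographic order.
VERTICES: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1),
    (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1),
)


def enumerate_pure_equilibria() -> tuple[MixedState, ...]:
    """The eight pure-strategy equilibrium points of the replicator system."""
    return tuple(MixedState(*v) for v in VERTICES)


def _gains(state: Sequence[float], p: ParameterSet) -> tuple[float, float, float]:
    x, y, z = state
    g_x = (p.Rg + p.Fg + p.Mh + p.Kg - p.Cg) - y * (z * p.Fp + p.Fg + p.Fh + p.Mh)
    g_y = (p.Rh + p.Kh - p.Ch) + x * (p.Fh + p.Mh)
    g_z = x * (p.Fp - p.Rp + y * p.Rp) + (1 - y) * p.Rp - p.Cp
    return g_x, g_y, g_z


def jacobian(state: MixedState, params: ParameterSet) -> np.ndarray:
    """Closed-form Jacobian of the replicator right-hand side.

    Entries are analytic partial derivatives of ``(x(1-x)g_x, y(1-y)g_y,
    z(1-z)g_z)``; at any vertex all off-diagonal entries vanish because the
    logistic prefactors do.  The (2,3) entry is identically zero: the
    hospital's gain never depends on the patient fraction z.
    """
    if not isinstance(state, MixedState):
        state = MixedState.from_iterable(state)
    x, y, z = state.as_tuple()
    p = params
    g_x, g_y, g_z = _gains((x, y, z), p)
    J = np.zeros((3, 3))
    J[0, 0] = (1 - 2 * x) * g_x
    J[0, 1] = -x * (1 - x) * (z * p.Fp + p.Fg + p.Fh + p.Mh)
    J[0, 2] = -x * (1 - x) * y * p.Fp
    J[1, 0] = y * (1 - y) * (p.Fh + p.Mh)
    J[1, 1] = (1 - 2 * y) * g_y
    J[1, 2] = 0.0
    J[2, 0] = z * (1 - z) * (p.Fp - p.Rp + y * p.Rp)
    J[2, 1] = -z * (1 - z) * (1 - x) * p.Rp
    J[2, 2] = (1 - 2 * z) * g_z
    return J


@dataclasses.dataclass(frozen=True)
class EquilibriumReport:
    """Stability diagnostics for one cube vertex.

    ``classification`` follows the eigenvalue sign pattern (``stable`` iff
    all negative, ``unstable`` iff all positive, ``non-hyperbolic`` when any
    eigenvalue sits within tolerance of zero, else ``saddle``);
    ``det_tr_criterion`` is the det(J)>0 & tr(J)<0 shortcut's verdict, and
    ``paper_detJ``/``paper_trJ`` evaluate the circulated reference table.
    """

    vertex: tuple[int, int, int]
    diagonal: tuple[float, float, float]
    eigenvalues: tuple[float, float, float]
    detJ: float
    trJ: float
    paper_detJ: float
    paper_trJ: float
    classification: str
    det_tr_criterion: bool
    table3_match: dict[str, bool]


def _classify(eigenvalues: Sequence[float], tol: float) -> str:
    if any(abs(e) <= tol for e in eigenvalues):
        return "non-hyperbolic"
    if all(e < 0 for e in eigenvalues):
        return "stable"
    if all(e > 0 for e in eigenvalues):
        return "unstable"
    return "saddle"


# Printed det/tr reference expressions per vertex, kept verbatim for auditing.
_PRINTED_DET_TR = {
    (0, 0, 0): (
        lambda p: (p.Rp - p.Cp) * (p.Kh + p.Rh - p.Ch)
        * (p.Fg + p.Kg + p.Mh + p.Rg - p.Cg),
        lambda p: p.Fg + p.Kg + p.Kh + p.Mh + p.Rg + p.Rh + p.Rp
        - p.Cg - p.Ch - p.Cp,
    ),
    (0, 0, 1): (
        lambda p: (p.Cp - p.Rp) * (p.Kh + p.Rh - p.Ch)
        * (p.Fg + p.Kg + p.Mh + p.Rg - p.Cg),
        lambda p: p.Cp + p.Fg + p.Kg + p.Kh + p.Mh + p.Rg + p.Rh
        - p.Rp - p.Cg - p.Ch,
    ),
    (0, 1, 0): (
        # printed factor carries +Cg; the matrix derivation yields -Cg
        lambda p: -p.Cp * (p.Ch - p.Kh - p.Rh) * (p.Kg + p.Rg + p.Cg - p.Fh),
        lambda p: p.Ch - p.Cp - p.Fh + p.Kg - p.Kh + p.Rg - p.Rh - p.Cg,
    ),
    (0, 1, 1): (
        lambda p: p.Cp * (p.Ch - p.Kh - p.Rh)
        * (p.Kg + p.Rg - p.Cg - p.Fh - p.Fp),
        lambda p: p.Ch + p.Cp - p.Fh - p.Fp + p.Kg - p.Kh + p.Rg - p.Rh - p.Cg,
    ),
    (1, 0, 0): (
        lambda p: (p.Fp - p.Cp) * (p.Cg - p.Fg - p.Kg - p.Mh - p.Rg)
        * (p.Fh + p.Kh + p.Mh + p.Rh - p.Ch),
        lambda p: p.Cg - p.Ch - p.Cp - p.Fg + p.Fh + p.Fp - p.Kg + p.Kh
        - p.Rg + p.Rh,
    ),
    (1, 0, 1): (
        lambda p: (p.Cp - p.Fp) * (p.Cg - p.Fg - p.Kg - p.Mh - p.Rg)
        * (p.Fh + p.Kh + p.Mh + p.Rh - p.Ch),
        lambda p: p.Cg - p.Ch + p.Cp - p.Fg + p.Fh - p.Fp - p.Kg + p.Kh
        - p.Rg + p.Rh,
    ),
    (1, 1, 0): (
        lambda p: (p.Fp - p.Cp) * (p.Cg + p.Fh - p.Kg - p.Rg)
        * (p.Ch - p.Fh - p.Kh - p.Mh - p.Rh),
        lambda p: p.Cg + p.Ch - p.Cp + p.Fp - p.Kg - p.Kh - p.Mh - p.Rg - p.Rh,
    ),
    (1, 1, 1): (
        # printed det factor has -Fh (derived +Fh); printed tr has +Kh (derived -Kh)
        lambda p: (p.Cp - p.Fp) * (p.Cg - p.Fh + p.Fp - p.Kg - p.Rg)
        * (p.Ch - p.Fh - p.Kh - p.Mh - p.Rh),
        lambda p: p.Cg + p.Ch + p.Cp - p.Kg + p.Kh - p.Mh - p.Rg - p.Rh,
    ),
}


def classify_vertex(
    vertex: MixedState | Sequence[float],
    params: ParameterSet,
    tol: float = 1e-9,
) -> EquilibriumReport:
    """Full stability report for one pure-strategy equilibrium."""
    if isinstance(vertex, MixedState):
        coords = vertex.as_tuple()
    else:
        coords = tuple(float(v) for v in vertex)
    if any(v not in (0.0, 1.0) for v in coords):
        raise ValueError(f"not a cube vertex: {coords}")
    key = tuple(int(v) for v in coords)

    J = jacobian(MixedState(*coords), params)
    diag = tuple(float(J[i, i]) for i in range(3))
    # At a vertex J is (lower) triangular with J23=0, so the eigenvalues are
    # exactly the diagonal; keep them as such rather than calling an
    # eigensolver that would reorder them.
    eigenvalues = diag
    detJ = diag[0] * diag[1] * diag[2]
    trJ = sum(diag)
    det_fn, tr_fn = _PRINTED_DET_TR[key]
    paper_detJ, paper_trJ = float(det_fn(params)), float(tr_fn(params))
    return EquilibriumReport(
        vertex=key,
        diagonal=diag,
        eigenvalues=eigenvalues,
        detJ=detJ,
        trJ=trJ,
        paper_detJ=paper_detJ,
        paper_trJ=paper_trJ,
        classification=_classify(eigenvalues, tol),
        det_tr_criterion=bool(detJ > 0 and trJ < 0),
        table3_match={
            "det": bool(abs(detJ - paper_detJ) <= 1e-9 * max(1.0, abs(detJ))),
            "tr": bool(abs(trJ - paper_trJ) <= 1e-9 * max(1.0, abs(trJ))),
        },
    )


def classify_all(params: ParameterSet, tol: float = 1e-9) -> list[EquilibriumReport]:
    """Stability reports for all eight vertices."""
    return [classify_vertex(v, params, tol) for v in VERTICES]


@dataclasses.dataclass(frozen=True)
class Table3Row:
    """Audit of one row of the circulated det/tr reference table."""

    vertex: tuple[int, int, int]
    derived_det: float
    printed_det: float
    det_matches_symbolically: bool
    det_residual: str
    derived_tr: float
    printed_tr: float
    tr_matches_symbolically: bool
    tr_residual: str


@lru_cache(maxsize=1)
def _symbolic_table3() -> dict[tuple[int, int, int], tuple[bool, str, bool, str]]:
    """Symbolic match flags and residuals per vertex, computed once."""
    ns, _, (x, y, z) = _symbols()
    gx, gy, gz = symbolic_gains()
    out = {}
    for vertex in VERTICES:
        a, b, c = vertex
        sub = {x: a, y: b, z: c}
        diag = (
            (1 - 2 * a) * gx.subs(sub),
            (1 - 2 * b) * gy.subs(sub),
            (1 - 2 * c) * gz.subs(sub),
        )
        derived_det = sp.expand(diag[0] * diag[1] * diag[2])
        derived_tr = sp.expand(diag[0] + diag[1] + diag[2])
        det_fn, tr_fn = _PRINTED_DET_TR[vertex]
        printed_det = sp.expand(det_fn(ns))
        printed_tr = sp.expand(tr_fn(ns))
        det_res = sp.expand(derived_det - printed_det)
        tr_res = sp.expand(derived_tr - printed_tr)
        out[vertex] = (det_res == 0, str(det_res), tr_res == 0, str(tr_res))
    return out


def table3_audit(params: ParameterSet = BASELINE) -> list[Table3Row]:
    """Compare printed and derived det/tr for all eight vertices.

    Rows that disagree are flagged both symbolically (polynomial residual in
    the 12 parameters) and numerically at the supplied parameter values; the
    audit reports both sides without choosing for the user.
    """
    symbolic = _symbolic_table3()
    rows = []
    for vertex in VERTICES:
        report = classify_vertex(vertex, params)
        det_ok, det_res, tr_ok, tr_res = symbolic[vertex]
        rows.append(
            Table3Row(
                vertex=vertex,
                derived_det=report.detJ,
                printed_det=report.paper_detJ,
                det_matches_symbolically=det_ok,
                det_residual=det_res,
                derived_tr=report.trJ,
                printed_tr=report.paper_trJ,
                tr_matches_symbolically=tr_ok,
                tr_residual=tr_res,
            )
        )
    return rows


def write_equilibrium_csv(reports: Sequence[EquilibriumReport], path: str | Path) -> None:
    """Write per-vertex stability reports as CSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "vertex,eig1,eig2,eig3,detJ,trJ,paper_detJ,paper_trJ,"
            "classification,det_tr_criterion,table3_det_match,table3_tr_match\n"
        )
        for r in reports:
            vertex = "".join(str(v) for v in r.vertex)
            fh.write(
                f"({vertex}),{r.eigenvalues[0]!r},{r.eigenvalues[1]!r},"
                f"{r.eigenvalues[2]!r},{r.detJ!r},{r.trJ!r},{r.paper_detJ!r},"
                f"{r.paper_trJ!r},{r.classification},{r.det_tr_criterion},"
                f"{r.table3_match['det']},{r.table3_match['tr']}\n"
            )
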