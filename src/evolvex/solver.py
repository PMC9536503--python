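"""Thin, deterministic LP/MILP layer on top of scipy's HiGHS interface.

Every optimization in the package goes through :class:`LinearProblem`:
add variables with bounds (optionally integer), add linear constraints as
``lb <= a.v <= ub`` rows, set a linear objective, solve.  Any backend
offering those five verbs could replace this one; scipy's ``milp`` wrapper
around HiGHS is used because it is deterministic for a fixed variable and
constraint order (single-threaded, no random restarts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

#: scipy.optimize.milp status codes -> package vocabulary
_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


class SolverError(RuntimeError):
    """Solver returned a status the caller cannot recover from."""


@dataclass
class Solution:
    status: str
    objective: float | None
    x: np.ndarray | None

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class LinearProblem:
    """Incrementally built linear (or mixed-integer linear) program.

    Variables and constraints keep insertion order; the objective may be
    replaced between solves, which is how FVA-style repeated optimization
    reuses one constraint matrix.
    """

    _lb: list[float] = field(default_factory=list)
    _ub: list[float] = field(default_factory=list)
    _integer: list[bool] = field(default_factory=list)
    _rows_i: list[np.ndarray] = field(default_factory=list)
    _rows_c: list[np.ndarray] = field(default_factory=list)
    _row_lb: list[float] = field(default_factory=list)
    _row_ub: list[float] = field(default_factory=list)
    _obj: dict[int, float] = field(default_factory=dict)
    _sense: float = 1.0  # +1 minimize, -1 maximize

    # -- construction ------------------------------------------------------
    def add_var(self, lb: float, ub: float, *, integer: bool = False) -> int:
        if lb > ub:
            raise ValueError(f"variable bounds inverted: [{lb}, {ub}]")
        self._lb.append(float(lb))
        self._ub.append(float(ub))
        self._integer.append(integer)
        return len(self._lb) - 1

    def add_vars(self, lb: np.ndarray, ub: np.ndarray) -> int:
        """Append a block of continuous variables; return index of the first."""
        start = len(self._lb)
        self._lb.extend(np.asarray(lb, dtype=float).tolist())
        self._ub.extend(np.asarray(ub, dtype=float).tolist())
        self._integer.extend([False] * len(lb))
        return start

    def add_constraint(self, coeffs: dict[int, float],
                       lb: float = -np.inf, ub: float = np.inf) -> None:
        idx = np.fromiter(coeffs.keys(), dtype=np.int64, count=len(coeffs))
        val = np.fromiter(coeffs.values(), dtype=float, count=len(coeffs))
        self._rows_i.append(idx)
        self._rows_c.append(val)
        self._row_lb.append(float(lb))
        self._row_ub.append(float(ub))

    def add_matrix_rows(self, A: np.ndarray, var_offset: int = 0,
                        lb: float = 0.0, ub: float = 0.0) -> None:
        """Add one ``lb <= A[i]·v <= ub`` row per matrix row (e.g. S·v = 0)."""
        A = np.asarray(A, dtype=float)
        for row in A:
            (nz,) = np.nonzero(row)
            self._rows_i.append(nz + var_offset)
            self._rows_c.append(row[nz])
            self._row_lb.append(lb)
            self._row_ub.append(ub)

    def set_objective(self, coeffs: dict[int, float], sense: str = "min") -> None:
        if sense not in ("min", "max"):
            raise ValueError(f"unknown sense {sense!r}")
        self._obj = dict(coeffs)
        self._sense = 1.0 if sense == "min" else -1.0

    # -- solving -----------------------------------------------------------
    def solve(self) -> Solution:
        n = len(self._lb)
        c = np.zeros(n)
        for i, v in self._obj.items():
            c[i] = v
        constraints = []
        if self._rows_i:
            indptr = np.zeros(len(self._rows_i) + 1, dtype=np.int64)
            np.cumsum([len(r) for r in self._rows_i], out=indptr[1:])
            A = sparse.csr_matrix(
                (np.concatenate(self._rows_c), np.concatenate(self._rows_i), indptr),
                shape=(len(self._rows_i), n),
            )
            constraints = [LinearConstraint(A, self._row_lb, self._row_ub)]
        res = milp(
            c=self._sense * c,
            constraints=constraints,
            integrality=np.asarray(self._integer, dtype=np.uint8),
            bounds=Bounds(np.asarray(self._lb), np.asarray(self._ub)),
        )
        status = _STATUS.get(res.status)
        if status is None:
            raise SolverError(f"solver failed: {res.message}")
        if status != OPTIMAL:
            return Solution(status, None, None)
        return Solution(OPTIMAL, self._sense * float(res.fun), np.asarray(res.x))
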