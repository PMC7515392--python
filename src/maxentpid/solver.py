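"""The four constrained mutual-information minimizations.

Given the observed joint ``P`` of (T, X, Y, Z), the maximum-entropy
decomposition needs the minima of ``MI_Q(T; X, Y, Z)`` and of the three
pairwise ``MI_Q(T; Xi, Xj)`` over the polytope of joints ``Q`` that preserve
the pairwise marginals (T,X), (T,Y) and (T,Z) of ``P``.  Equivalently each
problem maximizes the conditional entropy ``H_Q(T | scope)``, since the
target marginal — and with it ``H_Q(T)`` — is fixed by the constraints.

:func:`build_problem` poses one minimization, :func:`solve` runs it and
attaches optimality-certificate violations, and :func:`solve_all` runs all
four (optionally as three concurrent phases).  Optimal values are in bits.
"""

from __future__ import annotations

import itertools
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._opt import LN2, EntropyObjective, EntropyProgram, ViolationRecord
from .distributions import (
    JointDistribution,
    MarginalTriple,
    entropy,
    marginal_triple,
    sorted_labels,
    validate,
)

__all__ = [
    "SCOPES",
    "SolverConfig",
    "OptProblemSpec",
    "OptResult",
    "build_problem",
    "solve",
    "certificate_violations",
    "solve_all",
]

#: the four source scopes whose mutual information with T is minimized
SCOPES = ("XYZ", "XY", "XZ", "YZ")


@dataclass(frozen=True)
class SolverConfig:
    """Tolerances and iteration cap governing the interior-point solve.

    The names and defaults follow the conventional exponential-cone solver
    parameters: ``feastol`` bounds the feasibility residuals, ``abstol`` /
    ``reltol`` the duality gap, the ``*_inacc`` variants are the relaxed
    thresholds under which a solution is still reported as *inaccurate*
    rather than failed, and ``max_iter`` caps the interior-point iterations.
    """

    feastol: float = 1e-7
    abstol: float = 1e-6
    reltol: float = 1e-6
    feastol_inacc: float = 1e-3
    abstol_inacc: float = 1e-4
    reltol_inacc: float = 1e-4
    max_iter: int = 100

    def __post_init__(self):
        for name in ("feastol", "abstol", "reltol", "feastol_inacc",
                     "abstol_inacc", "reltol_inacc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def replace(self, **kwargs) -> "SolverConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


class _SupportData:
    """Scope-independent data shared by the four problems of one pmf."""

    def __init__(self, d: JointDistribution):
        d = validate(d)
        self.dist = d
        self.marginals = marginal_triple(d)
        pxt, pyt, pzt = self.marginals.pxt, self.marginals.pyt, self.marginals.pzt
        self.t_labels = sorted_labels(t for t, _ in pxt)
        self.x_labels = sorted_labels(x for _, x in pxt)
        self.y_labels = sorted_labels(y for _, y in pyt)
        self.z_labels = sorted_labels(z for _, z in pzt)
        tix = {t: i for i, t in enumerate(self.t_labels)}
        xix = {x: i for i, x in enumerate(self.x_labels)}
        yix = {y: i for i, y in enumerate(self.y_labels)}
        zix = {z: i for i, z in enumerate(self.z_labels)}

        pos_x: dict = {}
        pos_y: dict = {}
        pos_z: dict = {}
        for (t, x), p in pxt.items():
            if p > 0:
                pos_x.setdefault(t, []).append(x)
        for (t, y), p in pyt.items():
            if p > 0:
                pos_y.setdefault(t, []).append(y)
        for (t, z), p in pzt.items():
            if p > 0:
                pos_z.setdefault(t, []).append(z)

        ti, xi, yi, zi = [], [], [], []
        for t in self.t_labels:
            xs = sorted_labels(pos_x.get(t, ()))
            ys = sorted_labels(pos_y.get(t, ()))
            zs = sorted_labels(pos_z.get(t, ()))
            it = tix[t]
            for x, y, z in itertools.product(xs, ys, zs):
                ti.append(it)
                xi.append(xix[x])
                yi.append(yix[y])
                zi.append(zix[z])
        if not ti:
            raise ValueError("degenerate support: no admissible cell")
        self.ti = np.asarray(ti, dtype=np.int64)
        self.xi = np.asarray(xi, dtype=np.int64)
        self.yi = np.asarray(yi, dtype=np.int64)
        self.zi = np.asarray(zi, dtype=np.int64)
        self.n = self.ti.size

        # constraint rows: one per positive pairwise-marginal cell
        rows, data_b, col_rows = [], [], []
        offset = 0
        self.partition_rows = None
        for six, labels, pm in (
            (self.xi, self.x_labels, pxt),
            (self.yi, self.y_labels, pyt),
            (self.zi, self.z_labels, pzt),
        ):
            codes = self.ti * len(labels) + six
            uniq, inv = np.unique(codes, return_inverse=True)
            bvals = np.empty(uniq.size)
            for k, code in enumerate(uniq):
                t = self.t_labels[code // len(labels)]
                s = labels[code % len(labels)]
                bvals[k] = pm[(t, s)]
            col_rows.append(inv + offset)
            data_b.append(bvals)
            if self.partition_rows is None:
                self.partition_rows = np.arange(offset, offset + uniq.size)
            offset += uniq.size
        row_idx = np.concatenate(col_rows)
        col_idx = np.tile(np.arange(self.n), 3)
        self.A = sp.csr_matrix(
            (np.ones(row_idx.size), (row_idx, col_idx)), shape=(offset, self.n)
        )
        self.b = np.concatenate(data_b)

        q0 = np.zeros(self.n)
        lookup = {
            (int(a), int(b_), int(c), int(e)): i
            for i, (a, b_, c, e) in enumerate(zip(self.ti, self.xi, self.yi, self.zi))
        }
        for (t, x, y, z), p in d.mass.items():
            if p > 0:
                q0[lookup[(tix[t], xix[x], yix[y], zix[z])]] = p
        self.q0 = q0

        self.h_target = entropy(self.marginals.target_marginal())

    def cell_labels(self) -> list[tuple]:
        return [
            (self.t_labels[a], self.x_labels[b], self.y_labels[c], self.z_labels[e])
            for a, b, c, e in zip(self.ti, self.xi, self.yi, self.zi)
        ]

    def objective(self, scope: str) -> EntropyObjective:
        coords = {"X": self.xi, "Y": self.yi, "Z": self.zi}
        src = [coords[s] for s in scope]
        mcode = self.ti.copy()
        for arr in src:
            mcode = mcode * (arr.max() + 1) + arr
        _, Mmap = np.unique(mcode, return_inverse=True)
        nm = int(Mmap.max()) + 1
        gcode = np.zeros_like(self.ti)
        for arr in src:
            gcode = gcode * (arr.max() + 1) + arr
        # group id per m-cell: every cell of an m-cell shares the source config
        gm = np.zeros(nm, dtype=np.int64)
        gm[Mmap] = gcode
        _, Gmap = np.unique(gm, return_inverse=True)
        return EntropyObjective(Mmap=Mmap, Gmap=Gmap, nm=nm, ng=int(Gmap.max()) + 1)

    def program(self, scope: str) -> EntropyProgram:
        return EntropyProgram(
            A=self.A, b=self.b, obj=self.objective(scope), q0=self.q0,
            partition_rows=self.partition_rows,
        )


@dataclass
class OptProblemSpec:
    """One posed minimization of ``MI_Q(T; scope)`` over the marginal polytope."""

    scope: str
    marginals: MarginalTriple
    fixed_target_entropy: float
    _data: _SupportData = field(repr=False)

    @property
    def variable_support(self) -> list[tuple]:
        """Ordered quadruples over which the optimization variable may be
        positive: exactly the cells where all three pairwise marginals are
        positive (a superset of the support of the observed pmf)."""
        return self._data.cell_labels()

    @property
    def n_cells(self) -> int:
        return self._data.n

    def mi_observed(self) -> float:
        """``MI_P(T; scope)`` of the observed pmf — a feasible upper bound."""
        return self._data.h_target + self._data.objective(self.scope).value(
            self._data.q0
        ) / LN2


@dataclass
class OptResult:
    """Outcome of one minimization: value (bits), solution, certificates."""

    scope: str
    optimal_value: float
    solution_vector: np.ndarray | None
    status: str                      # optimal | inaccurate | failed
    violation: ViolationRecord
    message: str = ""
    niter: int = 0
    determined: bool = False
    _spec: OptProblemSpec | None = field(default=None, repr=False)

    @property
    def solution(self) -> dict:
        """The minimizing pmf as an outcome -> mass mapping."""
        if self.solution_vector is None:
            raise ValueError("no solution attached")
        cells = self._spec.variable_support
        return {c: float(v) for c, v in zip(cells, self.solution_vector)}


def build_problem(d: JointDistribution, scope: str,
                  _data: _SupportData | None = None) -> OptProblemSpec:
    """Pose the minimization of ``MI_Q(T; scope)`` over the marginal polytope
    of *d*; ``scope`` is one of ``XYZ``, ``XY``, ``XZ``, ``YZ``."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    data = _data if _data is not None else _SupportData(d)
    return OptProblemSpec(
        scope=scope,
        marginals=data.marginals,
        fixed_target_entropy=data.h_target,
        _data=data,
    )


def _classify(viol: ViolationRecord, value: float, cfg: SolverConfig) -> str:
    rel = viol.duality_gap / abs(value) if abs(value) > 1e-12 else np.inf
    if viol.primal_residual <= cfg.feastol and viol.dual_residual <= cfg.feastol and (
        viol.duality_gap <= cfg.abstol or rel <= cfg.reltol
    ):
        return "optimal"
    if viol.primal_residual <= cfg.feastol_inacc and (
        viol.duality_gap <= cfg.abstol_inacc or rel <= cfg.reltol_inacc
    ):
        return "inaccurate"
    return "failed"


def solve(spec: OptProblemSpec, cfg: SolverConfig | None = None) -> OptResult:
    """Solve one posed problem.  Never raises on non-convergence: the status
    encodes the outcome, and the best feasible iterate found (at worst the
    observed pmf itself, which is always feasible) is returned."""
    cfg = cfg or SolverConfig()
    program = spec._data.program(spec.scope)
    try:
        out = program.solve(max_iter=cfg.max_iter)
        q = out["q"]
        determined = out["determined"]
        message = out["info"].get("message", "")
        niter = out["info"].get("niter", 0)
    except Exception as exc:  # pragma: no cover - defensive
        q = spec._data.q0
        determined = False
        message = f"solver error: {exc}; returning the observed (feasible) pmf"
        niter = 0
    viol = program.certificates(q, determined=determined)
    value = spec.fixed_target_entropy + program.obj.value(q) / LN2
    status = _classify(viol, value, cfg)
    return OptResult(
        scope=spec.scope,
        optimal_value=float(value),
        solution_vector=q,
        status=status,
        violation=viol,
        message=message,
        niter=niter,
        determined=determined,
        _spec=spec,
    )


def certificate_violations(res: OptResult, spec: OptProblemSpec) -> ViolationRecord:
    """Recompute the violation record of a result's solution from scratch."""
    if res.solution_vector is None:
        raise ValueError("no solution attached")
    program = spec._data.program(spec.scope)
    return program.certificates(res.solution_vector, determined=res.determined)


def solve_all(d: JointDistribution, cfg: SolverConfig | None = None,
              parallel: str | bool = "off") -> dict[str, OptResult]:
    """Solve all four problems; returns results keyed XYZ, XY, XZ, YZ.

    ``parallel`` is a scheduling contract only: with ``"on"`` the four
    problems are built, solved, and certified as three concurrent phases;
    with ``"off"`` everything runs sequentially.  The numbers are identical
    either way.
    """
    cfg = cfg or SolverConfig()
    data = _SupportData(d)
    use_parallel = parallel in ("on", True)
    if use_parallel:
        with ThreadPoolExecutor(max_workers=4) as pool:
            specs = list(pool.map(lambda s: build_problem(d, s, _data=data), SCOPES))
            results = list(pool.map(lambda sp_: solve(sp_, cfg), specs))
        return dict(zip(SCOPES, results))
    return {s: solve(build_problem(d, s, _data=data), cfg) for s in SCOPES}
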