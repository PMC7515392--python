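"""Trivariate maximum-entropy partial information decomposition.

The estimator splits ``MI(T; X, Y, Z)`` into eight parts: synergy ``CI``,
shared information ``SI``, three unique informations ``UI(T; Xi \\ Xj, Xk)``
and three pairwise shared-unique informations ``UI(T; Xi, Xj \\ Xk)``.  The
parts are linear combinations of the observed mutual informations and of the
four constrained minima computed by :mod:`maxentpid.solver`:

    CI   = MI(T;X,Y,Z) - m_XYZ
    UI_i = m_XYZ - m_jk                                 (pair jk excludes i)
    SI   = sum_i MI(T;X_i) + sum_i UI_i - 2 m_XYZ
    UI_jk = m_XYZ + UI_i - MI(T;X_i) - sum_i UI_i

which is the unique solution of the decomposition identity system
(conservation of the joint mutual information plus, per source, the
consistency of ``MI(T;X_i)`` with the parts accessible through ``X_i``).
``CI`` and each ``UI_i`` are nonnegative whenever the four minima are exact;
``SI`` and the ``UI_jk`` may be legitimately negative in the presence of
deterministic dependencies.

The module is organized statsmodels-style: :class:`TrivariatePID` is the
model (built from a distribution), its :meth:`~TrivariatePID.fit` returns a
:class:`TrivariatePIDResults` carrying the estimates, the per-problem
optimality-violation records, diagnostics and a :meth:`summary` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._opt import ViolationRecord
from .distributions import (
    JointDistribution,
    EmptyDistributionError,
    mutual_information,
    validate,
)
from .solver import SCOPES, OptResult, SolverConfig, solve_all

__all__ = [
    "PID_KEYS",
    "VIOLATION_KEYS",
    "InfeasibleRepairError",
    "TrivariatePID",
    "TrivariatePIDResults",
    "assemble",
    "needs_repair",
    "qp_repair",
    "prune_small_masses",
    "pid",
]

#: result keys, in reporting order
PID_KEYS = ("UIX", "UIY", "UIZ", "UIXY", "UIXZ", "UIYZ", "CI", "SI")

#: violation-record keys and the problem each one certifies
VIOLATION_KEYS = {"Num_Err_I": "XYZ", "Num_Err_12": "XY",
                  "Num_Err_13": "XZ", "Num_Err_23": "YZ"}

_QUANT_LABELS = {
    "UIX": "UI(T;X\\Y,Z)", "UIY": "UI(T;Y\\X,Z)", "UIZ": "UI(T;Z\\X,Y)",
    "UIXY": "UI(T;X,Y\\Z)", "UIXZ": "UI(T;X,Z\\Y)", "UIYZ": "UI(T;Y,Z\\X)",
    "CI": "CI(T;X,Y,Z)", "SI": "SI(T;X,Y,Z)",
}


class InfeasibleRepairError(RuntimeError):
    """The identity-respecting repair program has an empty feasible set."""


def _mi_profile(d: JointDistribution) -> dict[str, float]:
    return {
        "X": mutual_information(d, {"X"}),
        "Y": mutual_information(d, {"Y"}),
        "Z": mutual_information(d, {"Z"}),
        "XY": mutual_information(d, {"X", "Y"}),
        "XZ": mutual_information(d, {"X", "Z"}),
        "YZ": mutual_information(d, {"Y", "Z"}),
        "XYZ": mutual_information(d, {"X", "Y", "Z"}),
    }


def _assemble_values(mi: Mapping[str, float], optima: Mapping[str, float]) -> dict[str, float]:
    m_xyz, m_xy, m_xz, m_yz = (optima[s] for s in SCOPES)
    ui_x = m_xyz - m_yz
    ui_y = m_xyz - m_xz
    ui_z = m_xyz - m_xy
    ui_sum = ui_x + ui_y + ui_z
    return {
        "CI": mi["XYZ"] - m_xyz,
        "UIX": ui_x,
        "UIY": ui_y,
        "UIZ": ui_z,
        "SI": mi["X"] + mi["Y"] + mi["Z"] + ui_sum - 2.0 * m_xyz,
        "UIYZ": m_xyz + ui_x - mi["X"] - ui_sum,
        "UIXZ": m_xyz + ui_y - mi["Y"] - ui_sum,
        "UIXY": m_xyz + ui_z - mi["Z"] - ui_sum,
    }


def assemble(d: JointDistribution, optima: Mapping[str, float]) -> dict[str, float]:
    """The eight decomposition quantities from the four optimal values.

    ``optima`` maps the scopes XYZ, XY, XZ, YZ to the minima of
    ``MI_Q(T; scope)`` in bits.  The output satisfies the decomposition
    identities exactly by construction.
    """
    for s in SCOPES:
        if not np.isfinite(optima[s]):
            raise ValueError(f"non-finite optimum for scope {s}")
    return _assemble_values(_mi_profile(validate(d)), optima)


def needs_repair(results: Mapping[str, "OptResult | ViolationRecord"],
                 threshold: float = 1e-6) -> tuple[bool, set[str]]:
    """Which of the four problems are errant: any violation component above
    *threshold*, or a failed status."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    errant: set[str] = set()
    for scope in SCOPES:
        res = results[scope]
        viol = res.violation if isinstance(res, OptResult) else res
        failed = isinstance(res, OptResult) and res.status == "failed"
        if failed or viol.max() > threshold:
            errant.add(scope)
    return bool(errant), errant


def qp_repair(raw_optima: Mapping[str, float], errant: set[str],
              mi: Mapping[str, float]) -> dict[str, float]:
    """Least-squares repair of errant optima under the identity constraints.

    The errant minima move as little as possible (in the sum-of-squares
    sense) while the full vector obeys every bound that exact minima must
    satisfy: ``m_scope <= MI(T;scope)`` (the observed pmf is feasible),
    ``m_jk >= max(MI(T;Xj), MI(T;Xk))`` (monotonicity under the preserved
    marginals) and ``m_XYZ >= m_jk`` (nested scopes), which together force
    ``CI >= 0`` and ``UI_i >= 0`` in the assembled decomposition.
    Non-errant values are held fixed.

    Raises :class:`InfeasibleRepairError` if the fixed values already
    contradict the constraint system.
    """
    if not errant:
        return dict(raw_optima)
    free = [s for s in SCOPES if s in errant]
    fixed = {s: float(raw_optima[s]) for s in SCOPES if s not in errant}
    single = {"XY": ("X", "Y"), "XZ": ("X", "Z"), "YZ": ("Y", "Z")}

    def vec_to_m(v: np.ndarray) -> dict[str, float]:
        m = dict(fixed)
        m.update({s: float(v[i]) for i, s in enumerate(free)})
        return m

    cons = []

    def add(fn):
        cons.append({"type": "ineq", "fun": fn})

    slack = 1e-9
    for s in SCOPES:
        if s in errant:
            i = free.index(s)
            add(lambda v, i=i, s=s: mi[s] - v[i] + slack)          # m <= MI(T;scope)
            if s == "XYZ":
                lo = max(mi[k] for k in ("X", "Y", "Z"))
                add(lambda v, i=i, lo=lo: v[i] - lo + slack)
            else:
                lo = max(mi[single[s][0]], mi[single[s][1]])
                add(lambda v, i=i, lo=lo: v[i] - lo + slack)
    for pair in ("XY", "XZ", "YZ"):
        if "XYZ" in errant and pair in errant:
            i, j = free.index("XYZ"), free.index(pair)
            add(lambda v, i=i, j=j: v[i] - v[j] + slack)
        elif "XYZ" in errant:
            i = free.index("XYZ")
            add(lambda v, i=i, p=pair: v[i] - fixed[p] + slack)
        elif pair in errant:
            j = free.index(pair)
            add(lambda v, j=j: fixed["XYZ"] - v[j] + slack)

    raw = np.array([float(raw_optima[s]) for s in free])
    # clip the start into the simple per-variable bounds
    x0 = raw.copy()
    for i, s in enumerate(free):
        if s == "XYZ":
            lo = max(mi[k] for k in ("X", "Y", "Z"))
        else:
            lo = max(mi[single[s][0]], mi[single[s][1]])
        x0[i] = np.clip(x0[i], lo, mi[s])

    obj = lambda v: float(np.sum((v - raw) ** 2))
    grad = lambda v: 2.0 * (v - raw)
    res = minimize(obj, x0, jac=grad, method="SLSQP", constraints=cons,
                   options={"ftol": 1e-16, "maxiter": 300})
    if not res.success:
        viol = max((-c["fun"](res.x) for c in cons), default=0.0)
        if viol > 1e-6:
            raise InfeasibleRepairError(
                f"repair constraints inconsistent (violation {viol:.2e})"
            )
    return vec_to_m(res.x)


def prune_small_masses(d: JointDistribution, floor: float) -> JointDistribution:
    """Drop outcomes with mass below *floor* and renormalize.

    A mitigation for numerically challenging pmfs carrying many almost-null
    masses; off by default in :meth:`TrivariatePID.fit`.
    """
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    if floor == 0:
        return d
    if floor >= max(d.mass.values()):
        raise EmptyDistributionError("floor too large: it would empty the support")
    kept = {k: v for k, v in d.mass.items() if v >= floor}
    total = sum(kept.values())
    return JointDistribution({k: v / total for k, v in kept.items()})


class TrivariatePID:
    """Maximum-entropy PID model for a discrete joint pmf of (T, X, Y, Z).

    Parameters
    ----------
    dist
        A :class:`~maxentpid.distributions.JointDistribution` or an
        outcome -> mass mapping with quadruple keys.
    prune_floor
        If positive, outcomes below this mass are dropped (and the pmf
        renormalized) before fitting.

    Examples
    --------
    >>> from maxentpid import TrivariatePID, datasets
    >>> res = TrivariatePID(datasets.gate("AndDuplicate")).fit()
    >>> round(res.params["CI"], 6)
    0.5
    """

    def __init__(self, dist: JointDistribution | Mapping[tuple, float],
                 prune_floor: float = 0.0):
        d = validate(dist)
        if prune_floor > 0:
            d = prune_small_masses(d, prune_floor)
        self.dist = d
        self.mi = _mi_profile(d)

    @classmethod
    def from_dict(cls, mass: Mapping[tuple, float], **kw) -> "TrivariatePID":
        return cls(mass, **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "TrivariatePID":
        """Build from a DataFrame with columns t, x, y, z, p."""
        cols = [c.lower() for c in df.columns]
        missing = {"t", "x", "y", "z", "p"} - set(cols)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        df = df.rename(columns=dict(zip(df.columns, cols)))
        mass = {
            (r.t, r.x, r.y, r.z): float(r.p) for r in df.itertuples(index=False)
        }
        if len(mass) != len(df):
            raise ValueError("duplicate (t, x, y, z) outcomes in the table")
        return cls(mass, **kw)

    @classmethod
    def from_table(cls, path, format: str = "table", **kw) -> "TrivariatePID":
        from .distributions import read_distribution

        with open(path, "r", encoding="utf-8") as fh:
            return cls(read_distribution(fh, format=format), **kw)

    def fit(self, config: SolverConfig | None = None, parallel: str = "off",
            repair_threshold: float = 1e-6) -> "TrivariatePIDResults":
        """Solve the four minimizations, repair errant values if needed, and
        assemble the decomposition."""
        cfg = config or SolverConfig()
        opt_results = solve_all(self.dist, cfg, parallel=parallel)
        raw_optima = {s: r.optimal_value for s, r in opt_results.items()}
        flag, errant = needs_repair(opt_results, repair_threshold)
        repaired = False
        optima = dict(raw_optima)
        notes: list[str] = []
        if flag:
            try:
                optima = qp_repair(raw_optima, errant, self.mi)
                repaired = True
                notes.append(
                    "repair adjusted problem(s) " + ", ".join(sorted(errant))
                )
            except InfeasibleRepairError as exc:
                warnings.warn(f"repair infeasible, reporting raw optima: {exc}")
                notes.append(f"repair infeasible: {exc}")
        values = _assemble_values(self.mi, optima)
        return TrivariatePIDResults(
            model=self,
            params=pd.Series({k: values[k] for k in PID_KEYS}, name="bits"),
            opt_results=opt_results,
            optima=optima,
            raw_optima=raw_optima,
            repaired=repaired,
            errant=errant,
            config=cfg,
            notes=notes,
        )


@dataclass
class TrivariatePIDResults:
    """Fitted decomposition: estimates, certificates and diagnostics."""

    model: TrivariatePID
    params: pd.Series
    opt_results: dict[str, OptResult]
    optima: dict[str, float]
    raw_optima: dict[str, float]
    repaired: bool
    errant: set[str]
    config: SolverConfig
    notes: list[str] = field(default_factory=list)

    @property
    def violations(self) -> dict[str, ViolationRecord]:
        return {key: self.opt_results[s].violation
                for key, s in VIOLATION_KEYS.items()}

    @property
    def statuses(self) -> dict[str, str]:
        return {s: r.status for s, r in self.opt_results.items()}

    def conservation_error(self) -> float:
        """|sum of the eight parts - MI(T;X,Y,Z)| in bits."""
        return abs(float(self.params.sum()) - self.model.mi["XYZ"])

    def source_identity_errors(self) -> dict[str, float]:
        """Per source i: |SI + UI_i + UI_ij + UI_ik - MI(T;X_i)| in bits."""
        p = self.params
        return {
            "X": abs(p["SI"] + p["UIX"] + p["UIXY"] + p["UIXZ"] - self.model.mi["X"]),
            "Y": abs(p["SI"] + p["UIY"] + p["UIXY"] + p["UIYZ"] - self.model.mi["Y"]),
            "Z": abs(p["SI"] + p["UIZ"] + p["UIXZ"] + p["UIYZ"] - self.model.mi["Z"]),
        }

    def to_dict(self) -> dict:
        """Flat mapping with the canonical result and violation keys."""
        out = {k: float(self.params[k]) for k in PID_KEYS}
        for key, rec in self.violations.items():
            out[key] = list(rec.as_tuple())
        return out

    def finer(self, config: SolverConfig | None = None):
        """Split the synergy into finer parts via the bivariate hierarchy."""
        from .hierarchy import finer_parts

        return finer_parts(self.model.dist, self, config or self.config)

    def summary(self) -> str:
        lines = []
        lines.append("Maximum-entropy trivariate partial information decomposition")
        lines.append("=" * 64)
        mi = self.model.mi
        lines.append(f"MI(T;X,Y,Z) = {mi['XYZ']:.9f} bits   "
                     f"support: {len(self.model.dist)} outcomes")
        lines.append("-" * 64)
        lines.append(f"{'quantity':<16}{'':<16}{'bits':>14}")
        for k in PID_KEYS:
            lines.append(f"{k:<16}{_QUANT_LABELS[k]:<16}{self.params[k]:>14.9f}")
        lines.append("-" * 64)
        lines.append(f"{'problem':<10}{'min MI (bits)':>14}{'status':>12}"
                     f"{'primal':>10}{'dual':>10}{'gap':>10}")
        for key, scope in VIOLATION_KEYS.items():
            r = self.opt_results[scope]
            v = r.violation
            lines.append(
                f"{scope:<10}{self.optima[scope]:>14.9f}{r.status:>12}"
                f"{v.primal_residual:>10.1e}{v.dual_residual:>10.1e}"
                f"{v.duality_gap:>10.1e}"
            )
        lines.append(f"repaired: {self.repaired}"
                     + (f"   ({'; '.join(self.notes)})" if self.notes else ""))
        lines.append(f"conservation error: {self.conservation_error():.2e} bits")
        return "\n".join(lines)


def pid(dist: JointDistribution | Mapping[tuple, float],
        config: SolverConfig | None = None, parallel: str = "off",
        repair_threshold: float = 1e-6) -> TrivariatePIDResults:
    """One-call decomposition: build the model and fit it."""
    return TrivariatePID(dist).fit(config=config, parallel=parallel,
                                   repair_threshold=repair_threshold)
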