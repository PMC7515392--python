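"""Constrained conditional-entropy maximization engine.

Each of the information minimizations solved by this package has the form

    minimize   sum_j m_j ln(m_j / g_s(j))      (= -H_Q(T | S), in nats)
    subject to A q = b,  q >= 0

where ``q`` is a joint pmf supported on an explicit cell list, ``m = M q`` is
its marginal over the target and the conditioning sources ``S``, the groups
``s(j)`` collect the m-cells sharing a source configuration, and the rows of
``A`` fix pairwise (target, source) marginals.  Minimizing the negative
conditional entropy of the target is equivalent to minimizing ``MI(T; S)``
because the target marginal — hence ``H_Q(T)`` — is pinned by the
constraints.

Solution strategy
-----------------
1. *Constraint propagation*: rows touching a single undetermined cell pin that
   cell; iterated to a fixed point.  Structured inputs (copy gates, point
   masses) are fully determined here and need no iterative optimization.
2. *Interior point*: the remaining cells are optimized with
   ``scipy.optimize.minimize(method="trust-constr")`` from a strictly
   feasible start found by linear programming (cells that are zero in every
   feasible point are detected and removed first).
3. *Polish*: an active-set Newton refinement on the equality-constrained
   reduced problem drives the gradient projection to machine precision.

Certificates
------------
The Lagrangian dual of the program has a closed form: for multipliers
``lam`` with ``c = A' lam`` (and, per m-cell, ``c* = max`` over its fiber),
the dual function equals ``lam' b`` whenever every conditioning group ``s``
satisfies ``logsumexp_j(c*_j) <= 0``, and is unbounded below otherwise.
Because one marginal family partitions the cells, any fitted ``lam`` can be
shifted into dual feasibility at a cost of exactly the worst group violation,
giving a valid lower bound and hence a rigorous duality gap.  The reported
violation record is (primal residual, dual feasibility violation, duality
gap in bits).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

LN2 = math.log(2.0)

_DENSE_CAP = 4000        # max free cells for dense polish / rank reduction
_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class ViolationRecord:
    """Optimality-certificate violations of a returned solution."""

    primal_residual: float
    dual_residual: float
    duality_gap: float

    def max(self) -> float:
        return max(self.primal_residual, self.dual_residual, self.duality_gap)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.primal_residual, self.dual_residual, self.duality_gap)


@dataclass
class EntropyObjective:
    """Negative conditional entropy -H(T|S) as a function of the cell masses."""

    Mmap: np.ndarray        # cell -> m-cell (marginal over T and S)
    Gmap: np.ndarray        # m-cell -> conditioning group
    nm: int
    ng: int

    def marginals(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = np.bincount(self.Mmap, weights=q, minlength=self.nm)
        g = np.bincount(self.Gmap, weights=m, minlength=self.ng)
        return m, g

    def value(self, q: np.ndarray) -> float:
        m, g = self.marginals(q)
        pos = m > 0
        return float(np.sum(m[pos] * (np.log(m[pos]) - np.log(g[self.Gmap[pos]]))))

    def grad_m(self, q: np.ndarray) -> np.ndarray:
        m, g = self.marginals(q)
        return np.log(np.maximum(m, _LOG_FLOOR)) - np.log(np.maximum(g[self.Gmap], _LOG_FLOOR))

    def grad(self, q: np.ndarray) -> np.ndarray:
        return self.grad_m(q)[self.Mmap]

    def hess(self, q: np.ndarray) -> sp.csr_matrix:
        n = q.shape[0]
        m, g = self.marginals(q)
        ones = np.ones(n)
        P = sp.csr_matrix((ones, (self.Mmap, np.arange(n))), shape=(self.nm, n))
        S = sp.csr_matrix((ones, (self.Gmap[self.Mmap], np.arange(n))), shape=(self.ng, n))
        dm = 1.0 / np.maximum(m, 1e-250)
        dg = 1.0 / np.maximum(g, 1e-250)
        H = P.T @ sp.diags(dm) @ P - S.T @ sp.diags(dg) @ S
        return H.tocsr()

    def hess_dense(self, q: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """Dense Hessian block over the cells in *idx* (cheap for small blocks)."""
        m, g = self.marginals(q)
        dm = 1.0 / np.maximum(m, 1e-250)
        dg = 1.0 / np.maximum(g, 1e-250)
        Mi = self.Mmap[idx]
        Gi = self.Gmap[self.Mmap][idx]
        H = np.where(Mi[:, None] == Mi[None, :], dm[Mi][:, None], 0.0)
        H -= np.where(Gi[:, None] == Gi[None, :], dg[Gi][:, None], 0.0)
        return H


@dataclass
class EntropyProgram:
    """One minimization instance: objective plus marginal equality constraints."""

    A: sp.csr_matrix
    b: np.ndarray
    obj: EntropyObjective
    q0: np.ndarray                   # feasible point (the observed pmf on the cells)
    partition_rows: np.ndarray       # row indices forming a partition of the cells
    pinned_only: bool = field(default=False, init=False)

    # -- constraint propagation -------------------------------------------
    def propagate(self) -> tuple[np.ndarray, np.ndarray]:
        """Pin cells forced by rows with a single undetermined entry.

        Returns (pinned mask, values); unpinned entries of the value vector
        are zero.
        """
        A = self.A
        n = A.shape[1]
        q = np.zeros(n)
        pinned = np.zeros(n, dtype=bool)
        Abool = A.copy()
        Abool.data = np.ones_like(Abool.data)
        nnz_row = np.diff(A.indptr)

        # vectorized first pass: rows with a single nonzero pin their cell
        single = np.flatnonzero(nnz_row == 1)
        if single.size:
            cols = A.indices[A.indptr[single]]
            vals = self.b[single] / A.data[A.indptr[single]]
            q[cols] = vals
            pinned[cols] = True

        while True:
            free = (~pinned).astype(float)
            cnt = np.rint(Abool @ free).astype(int)
            rows1 = np.flatnonzero(cnt == 1)
            if rows1.size == 0:
                break
            known = A @ np.where(pinned, q, 0.0)
            progress = False
            for r in rows1:
                cols = A.indices[A.indptr[r]:A.indptr[r + 1]]
                data = A.data[A.indptr[r]:A.indptr[r + 1]]
                freecols = cols[~pinned[cols]]
                if freecols.size != 1:
                    continue
                j = freecols[0]
                coef = data[~pinned[cols]][0]
                q[j] = (self.b[r] - known[r]) / coef
                pinned[j] = True
                progress = True
            if not progress:
                break
        return pinned, q

    # -- feasibility helpers ----------------------------------------------
    @staticmethod
    def _interior_point(A: sp.csr_matrix, b: np.ndarray):
        """Max-min-slack LP: a feasible q maximizing its smallest entry."""
        r, n = A.shape
        c = np.zeros(n + 1)
        c[-1] = -1.0
        A_eq = sp.hstack([A, sp.csr_matrix((r, 1))], format="csr")
        A_ub = sp.hstack([-sp.eye(n, format="csr"), sp.csr_matrix(np.ones((n, 1)))],
                         format="csr")
        bounds = [(0.0, None)] * n + [(None, 0.5)]
        res = linprog(c, A_ub=A_ub, b_ub=np.zeros(n), A_eq=A_eq, b_eq=b,
                      bounds=bounds, method="highs")
        if not res.success:
            return None, -np.inf
        return res.x[:n], res.x[-1]

    @staticmethod
    def _forced_zeros(A: sp.csr_matrix, b: np.ndarray, hint: np.ndarray) -> np.ndarray:
        """Cells that are zero in *every* feasible point."""
        n = A.shape[1]
        candidate = hint <= 1e-12
        while candidate.any():
            c = np.zeros(n)
            c[candidate] = -1.0
            res = linprog(c, A_eq=A, b_eq=b, bounds=(0.0, None), method="highs")
            if not res.success:
                break
            reachable = candidate & (res.x > 1e-10)
            if -res.fun < 1e-10 or not reachable.any():
                break
            candidate &= ~reachable
        return candidate if candidate.any() else np.zeros(n, dtype=bool)

    # -- main solve --------------------------------------------------------
    def solve(self, max_iter: int = 100) -> dict:
        n = self.A.shape[1]
        info: dict = {"niter": 0, "message": "", "stages": []}
        pinned, qpin = self.propagate()
        free = np.flatnonzero(~pinned)
        q = np.where(pinned, qpin, self.q0)
        if free.size == 0:
            self.pinned_only = True
            info["stages"].append("propagation")
            info["message"] = "fully determined by the marginal constraints"
            return {"q": np.maximum(qpin, 0.0), "info": info, "lam": None,
                    "determined": True}

        A_red = self.A[:, free].tocsr()
        b_red = self.b - self.A[:, pinned] @ qpin[pinned]
        live = np.flatnonzero(np.diff(A_red.indptr) > 0)
        A_red = A_red[live]
        b_red = b_red[live]

        x0 = self.q0[free]
        dense_path = free.size <= _DENSE_CAP and A_red.shape[0] <= _DENSE_CAP
        if dense_path and np.min(x0) > 1e-12:
            # the observed pmf is already a strictly interior feasible start
            A_red, b_red = _independent_rows(A_red, b_red)
        elif dense_path:
            x_int, slack = self._interior_point(A_red, b_red)
            if x_int is not None and slack <= 1e-11:
                forced = self._forced_zeros(A_red, b_red, x_int)
                if forced.any():
                    keep = ~forced
                    sub = np.zeros(n, dtype=bool)
                    sub[free[forced]] = True
                    pinned = pinned | sub
                    free = free[keep]
                    A_red = A_red[:, keep].tocsr()
                    live = np.flatnonzero(np.diff(A_red.indptr) > 0)
                    A_red = A_red[live]
                    b_red = b_red[live]
                    if free.size == 0:
                        self.pinned_only = True
                        info["message"] = "fully determined by the marginal constraints"
                        return {"q": np.maximum(qpin, 0.0), "info": info,
                                "lam": None, "determined": True}
                    x_int, slack = self._interior_point(A_red, b_red)
            if x_int is not None and slack > 0:
                x0 = x_int
            # drop linearly dependent rows for the equality constraint
            A_red, b_red = _independent_rows(A_red, b_red)

        qfix = np.where(pinned, np.maximum(qpin, 0.0), 0.0)

        def assemble(x: np.ndarray) -> np.ndarray:
            qq = qfix.copy()
            qq[free] = x
            return qq

        fun = lambda x: self.obj.value(assemble(np.maximum(x, 0.0)))
        jac = lambda x: self.obj.grad(assemble(np.maximum(x, _LOG_FLOOR)))[free]
        hess = lambda x: self.obj.hess(assemble(x))[free][:, free]
        hess_d = lambda x: self.obj.hess_dense(assemble(x), free)

        best_x = x0.copy()
        best_f = fun(x0)
        capped = False
        Ad = A_red.toarray() if dense_path else None
        # below this certified gap (bits) further stages cannot improve the
        # reported value materially; the multiplier fit resolves ~1e-8
        gap_target = 1e-8

        def consider(x, stage):
            nonlocal best_x, best_f
            x = np.maximum(x, 0.0)
            f = fun(x)
            if f < best_f - 1e-15 and _primal_residual(A_red, b_red, x) < 1e-7:
                best_x, best_f = x, f
            info["stages"].append(stage)

        def try_polish():
            if not dense_path:
                return
            try:
                x, _lam = _polish(best_x, Ad, b_red, fun, jac, hess_d)
                consider(x, "polish")
            except Exception as exc:  # pragma: no cover - defensive
                info["message"] = (info["message"] + "; " if info["message"] else "") + \
                    f"polish stage failed: {exc}"

        def gap_now():
            rec = self.certificates(assemble(best_x), determined=False)
            return rec.duality_gap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # stage 1: sequential quadratic programming + Newton polish
            if dense_path:
                try:
                    res = minimize(
                        fun, x0, jac=jac, method="SLSQP",
                        constraints=[{"type": "eq",
                                      "fun": lambda x: Ad @ x - b_red,
                                      "jac": lambda x: Ad}],
                        bounds=[(0.0, 1.0)] * free.size,
                        options={"maxiter": max(max_iter, 100), "ftol": 1e-14},
                    )
                    info["niter"] = int(res.get("nit", 0))
                    consider(res.x, "sqp")
                except Exception as exc:  # pragma: no cover - defensive
                    info["message"] = f"sqp stage failed: {exc}"
                try_polish()

            # stage 2: deterministic perturbed restarts along the feasible set
            if dense_path and gap_now() > gap_target:
                from scipy.linalg import null_space

                N = null_space(Ad)
                rng = np.random.default_rng(12345)
                for _trial in range(2):
                    if N.size == 0:
                        break
                    u = rng.normal(size=N.shape[1])
                    step = N @ u
                    pos = best_x > 1e-9
                    scale = 0.25 * (np.min(best_x[pos] / np.maximum(
                        np.abs(step[pos]), 1e-300)) if pos.any() else 0.0)
                    xr = np.maximum(best_x + min(scale, 1.0) * step, 0.0)
                    try:
                        res = minimize(
                            fun, xr, jac=jac, method="SLSQP",
                            constraints=[{"type": "eq",
                                          "fun": lambda x: Ad @ x - b_red,
                                          "jac": lambda x: Ad}],
                            bounds=[(0.0, 1.0)] * free.size,
                            options={"maxiter": max(max_iter, 200), "ftol": 1e-14},
                        )
                        consider(res.x, "restart")
                    except Exception:  # pragma: no cover - defensive
                        continue
                    try_polish()
                    if gap_now() <= gap_target:
                        break

            # stage 3: interior-point fallback when the gap is not certified
            if not dense_path or gap_now() > gap_target:
                try:
                    res = minimize(
                        fun, best_x, jac=jac, hess=hess, method="trust-constr",
                        constraints=LinearConstraint(A_red, b_red, b_red),
                        bounds=Bounds(np.zeros(free.size), np.inf),
                        options={"gtol": 1e-10, "xtol": 1e-13,
                                 "maxiter": max(max_iter, 200), "verbose": 0},
                    )
                    info["niter"] += int(res.niter)
                    capped = res.status == 0
                    consider(res.x, "interior-point")
                except Exception as exc:  # pragma: no cover - defensive
                    info["message"] = (info["message"] + "; " if info["message"] else "") + \
                        f"interior-point stage failed: {exc}"
                try_polish()

            # stage 3: deterministic perturbed restarts along the feasible set
            if dense_path and gap_now() > gap_target:
                from scipy.linalg import null_space

                N = null_space(Ad)
                rng = np.random.default_rng(12345)
                for _trial in range(3):
                    if N.size == 0:
                        break
                    u = rng.normal(size=N.shape[1])
                    step = N @ u
                    pos = best_x > 1e-9
                    scale = 0.25 * (np.min(best_x[pos] / np.maximum(
                        np.abs(step[pos]), 1e-300)) if pos.any() else 0.0)
                    xr = np.maximum(best_x + min(scale, 1.0) * step, 0.0)
                    try:
                        res = minimize(
                            fun, xr, jac=jac, method="SLSQP",
                            constraints=[{"type": "eq",
                                          "fun": lambda x: Ad @ x - b_red,
                                          "jac": lambda x: Ad}],
                            bounds=[(0.0, 1.0)] * free.size,
                            options={"maxiter": max(max_iter, 200), "ftol": 1e-14},
                        )
                        consider(res.x, "restart")
                    except Exception:  # pragma: no cover - defensive
                        continue
                    try_polish()
                    if gap_now() <= gap_target:
                        break

        if capped:
            info["message"] = (info["message"] + "; " if info["message"] else "") + \
                "iteration cap reached in the interior-point stage"
        return {"q": assemble(best_x), "info": info, "lam": None,
                "determined": False}

    # -- certificates ------------------------------------------------------
    def certificates(self, q: np.ndarray, lam: np.ndarray | None = None,
                     determined: bool | None = None) -> ViolationRecord:
        primal = _primal_residual(self.A, self.b, q)
        if determined is None:
            determined = self.pinned_only
        f = self.obj.value(q)
        if determined:
            # the feasible set is a single point, so the value is the minimum
            return ViolationRecord(primal, 0.0, 0.0)
        candidates = []
        for qtol in (1e-12, 1e-9):
            lam_fit = self._fit_multipliers(q, qtol)
            if lam_fit is not None:
                candidates.append(lam_fit)
        if lam is not None:
            candidates.append(lam)
        best = None
        for cand in candidates:
            dres, gap = self._dual_gap(q, f, cand)
            if best is None or gap < best[1]:
                best = (dres, gap)
        if best is None:
            # no multiplier estimate: bound the gap by the feasible objective
            return ViolationRecord(primal, np.inf, np.inf)
        dres, gap = best
        return ViolationRecord(primal, dres, max(gap, 0.0) / LN2)

    def _fit_multipliers(self, q: np.ndarray, qtol: float = 1e-12) -> np.ndarray | None:
        # stationarity grad = A' lam holds only on cells with positive mass;
        # zero cells carry a free nonnegative bound multiplier and would bias
        # the fit
        grad = self.obj.grad(q)
        ok = q > qtol
        if ok.sum() == 0:
            return None
        At = self.A[:, ok].T
        g = grad[ok]
        if At.shape[0] <= _DENSE_CAP * 4 and At.shape[1] <= _DENSE_CAP:
            lam, *_ = np.linalg.lstsq(At.toarray(), g, rcond=None)
        else:
            lam = sp.linalg.lsqr(At, g, atol=1e-14, btol=1e-14, iter_lim=2000)[0]
        return lam

    def _dual_gap(self, q: np.ndarray, f: float, lam: np.ndarray) -> tuple[float, float]:
        """Dual feasibility violation and rigorous duality gap (nats)."""
        c = self.A.T @ lam
        # per m-cell: the best attainable coefficient over its fiber
        cstar = np.full(self.obj.nm, -np.inf)
        np.maximum.at(cstar, self.obj.Mmap, c)
        # per conditioning group: logsumexp over its m-cells must be <= 0
        gmax = np.full(self.obj.ng, -np.inf)
        np.maximum.at(gmax, self.obj.Gmap, cstar)
        sums = np.bincount(self.obj.Gmap, weights=np.exp(cstar - gmax[self.obj.Gmap]),
                           minlength=self.obj.ng)
        delta = gmax + np.log(np.maximum(sums, _LOG_FLOOR))
        viol = float(max(0.0, np.max(delta[np.isfinite(delta)])))
        dual_value = float(lam @ self.b) - viol
        return viol, f - dual_value


def _primal_residual(A, b, q) -> float:
    eq = float(np.max(np.abs(A @ q - b))) if A.shape[0] else 0.0
    neg = float(max(0.0, -np.min(q))) if q.size else 0.0
    return max(eq, neg)


def _independent_rows(A: sp.csr_matrix, b: np.ndarray):
    """Keep a maximal linearly independent subset of constraint rows."""
    from scipy.linalg import qr

    Ad = A.toarray()
    _q, r, piv = qr(Ad.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(Ad.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    return sp.csr_matrix(Ad[keep]), b[keep]


def _polish(x0: np.ndarray, A: np.ndarray, b: np.ndarray, fun, jac, hess,
            act_tol: float = 1e-10, max_outer: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Active-set Newton refinement of the equality-constrained problem.

    ``A`` must have full row rank.  Cells pushed to the boundary are fixed at
    zero; fixed cells whose multiplier sign shows they should re-enter are
    reseeded at a small positive value.  Linear feasibility is restored inside
    each Newton system, so the iterates satisfy ``A x = b`` to round-off.
    """
    n = x0.size
    r = A.shape[0]

    def newton(x, active, max_inner=60):
        x = x.copy()
        lam = np.zeros(r)
        for _inner in range(max_inner):
            F = np.flatnonzero(~active)
            if F.size == 0:
                break
            g = jac(x)
            H = hess(x)
            gF = g[F]
            HFF = H[np.ix_(F, F)]
            AF = A[:, F]
            nF = F.size
            tau = 1e-12 * (1.0 + np.abs(np.diag(HFF)).max())
            KKT = np.zeros((nF + r, nF + r))
            KKT[:nF, :nF] = HFF + tau * np.eye(nF)
            KKT[:nF, nF:] = AF.T
            KKT[nF:, :nF] = AF
            rhs = np.concatenate([-gF, b - A @ x])
            try:
                sol = np.linalg.solve(KKT, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(KKT, rhs, rcond=None)
            dx = sol[:nF]
            lam = sol[nF:]
            neg = dx < 0
            alpha = 1.0
            if neg.any():
                ratio = x[F][neg] / -dx[neg]
                alpha = min(1.0, 0.9995 * float(ratio.min()))
            if alpha <= 0:
                break
            f0 = fun(x)
            slope = float(gF @ dx)
            step = alpha
            accepted = False
            for _ls in range(40):
                xt = x.copy()
                xt[F] = x[F] + step * dx
                if (xt[F] >= 0).all() and fun(xt) <= f0 + 1e-4 * step * min(slope, 0.0) + 1e-15:
                    x = xt
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            newly = (x[F] < act_tol) & (dx < 0)
            if newly.any():
                active[F[newly]] = True
                x[F[newly]] = 0.0
                continue
            if np.abs(dx).max() * step < 1e-13:
                break
        return x, lam, active

    active = x0 < act_tol
    x, lam, active = newton(np.maximum(x0, 0.0), active)
    f = fun(x)
    # release trials: fixed cells with a strictly negative reduced gradient
    # may lower the objective if allowed back in; re-seed them in one batch
    # and keep the move only if the objective actually improves
    for _outer in range(max_outer):
        if not active.any():
            break
        mu = np.where(active, jac(x) - A.T @ lam, np.inf)
        cand = mu < -1e-8
        if not cand.any():
            break
        trial_active = active & ~cand
        xt = x.copy()
        xt[cand] = 1e-8
        xt, lam_t, trial_active = newton(xt, trial_active)
        ft = fun(xt)
        resid = float(np.abs(A @ xt - b).max()) if r else 0.0
        if ft < f - 1e-14 and resid < 1e-9:
            x, lam, active, f = xt, lam_t, trial_active, ft
        else:
            break
    return x, lam
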