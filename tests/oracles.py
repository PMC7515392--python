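"""Independent reference implementations used only by the tests.

Everything here is deliberately naive: plain double-loop summation for the
information functionals and a generic multi-restart constrained nonlinear
minimizer over the *full* outcome grid (no support reduction, no Newton
polish), so that agreement with the package is a genuine cross-check of two
different computational routes.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
from scipy.optimize import minimize

_SOURCE_POS = {"X": 1, "Y": 2, "Z": 3}


def naive_entropy(pmf: dict) -> float:
    h = 0.0
    for p in pmf.values():
        if p > 0:
            h -= p * math.log2(p)
    return h


def naive_marginal(mass: dict, positions: tuple[int, ...]) -> dict:
    out: dict = {}
    for outcome, p in mass.items():
        key = tuple(outcome[i] for i in positions)
        out[key] = out.get(key, 0.0) + p
    return out


def naive_mi(mass: dict, sources: tuple[str, ...]) -> float:
    """MI(T; sources) by direct summation over the joint support."""
    pos = tuple(sorted(_SOURCE_POS[s] for s in sources))
    p_t = naive_marginal(mass, (0,))
    p_s = naive_marginal(mass, pos)
    p_ts = naive_marginal(mass, (0,) + pos)
    mi = 0.0
    for key, p in p_ts.items():
        if p <= 0:
            continue
        t, rest = key[0], key[1:]
        mi += p * math.log2(p / (p_t[(t,)] * p_s[rest]))
    return mi


def _grids(mass: dict):
    alphabets = [sorted({k[i] for k in mass}, key=str) for i in range(4)]
    cells = list(itertools.product(*alphabets))
    return alphabets, cells


def brute_force_min_mi(mass: dict, sources: tuple[str, ...], restarts: int = 6,
                       seed: int = 0) -> float:
    """Multi-restart constrained minimization of MI_Q(T; sources) over all
    joints Q on the full outcome grid preserving the three pairwise
    (target, source) marginals of *mass*.  Returns the best value in bits."""
    alphabets, cells = _grids(mass)
    n = len(cells)
    index = {c: i for i, c in enumerate(cells)}
    pos = tuple(sorted(_SOURCE_POS[s] for s in sources))

    # pairwise marginal equality constraints over the full grid
    rows = []
    rhs = []
    for si in (1, 2, 3):
        target_pairs = naive_marginal(mass, (0, si))
        for t in alphabets[0]:
            for s in alphabets[si]:
                row = np.zeros(n)
                for c in cells:
                    if c[0] == t and c[si] == s:
                        row[index[c]] = 1.0
                rows.append(row)
                rhs.append(target_pairs.get((t, s), 0.0))
    A = np.array(rows)
    b = np.array(rhs)
    # keep an independent subset of rows (SLSQP rejects dependent equalities)
    from scipy.linalg import qr

    _q, r_, piv = qr(A.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r_))
    rank = int(np.sum(diag > max(A.shape) * np.finfo(float).eps * diag[0]))
    keep = np.sort(piv[:rank])
    A, b = A[keep], b[keep]

    group_of = {}
    groups = sorted({tuple(c[i] for i in pos) for c in cells}, key=str)
    gidx = {g: i for i, g in enumerate(groups)}
    tidx = {t: i for i, t in enumerate(alphabets[0])}
    cell_g = np.array([gidx[tuple(c[i] for i in pos)] for c in cells])
    cell_t = np.array([tidx[c[0]] for c in cells])

    def mi_of(q):
        q = np.maximum(q, 0.0)
        pg = np.bincount(cell_g, weights=q, minlength=len(groups))
        pts = {}
        for i, qi in enumerate(q):
            key = (cell_t[i], cell_g[i])
            pts[key] = pts.get(key, 0.0) + qi
        pt = np.bincount(cell_t, weights=q, minlength=len(alphabets[0]))
        val = 0.0
        for (t, g), p in pts.items():
            if p > 1e-15:
                val += p * math.log2(p / max(pt[t] * pg[g], 1e-300))
        return val

    q0 = np.zeros(n)
    for c, p in mass.items():
        q0[index[c]] = p

    rng = np.random.default_rng(seed)
    best = mi_of(q0)
    cons = [{"type": "eq", "fun": lambda q: A @ q - b, "jac": lambda q: A}]
    for trial in range(restarts):
        if trial == 0:
            start = q0
        else:
            start = 0.5 * q0 + 0.5 * rng.dirichlet(np.ones(n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(mi_of, start, method="SLSQP", constraints=cons,
                           bounds=[(0.0, 1.0)] * n,
                           options={"maxiter": 500, "ftol": 1e-13})
        if res.x is not None:
            q = np.maximum(res.x, 0.0)
            if np.abs(A @ q - b).max() < 1e-7:
                best = min(best, mi_of(q))
    return best


def brute_force_pid(mass: dict, restarts: int = 6, seed: int = 0) -> dict:
    """The eight-part decomposition computed entirely through the oracle
    route: naive mutual informations plus brute-force minima, combined by
    the decomposition identities (restated here independently)."""
    m_xyz = brute_force_min_mi(mass, ("X", "Y", "Z"), restarts, seed)
    m_xy = brute_force_min_mi(mass, ("X", "Y"), restarts, seed + 1)
    m_xz = brute_force_min_mi(mass, ("X", "Z"), restarts, seed + 2)
    m_yz = brute_force_min_mi(mass, ("Y", "Z"), restarts, seed + 3)
    mi_x = naive_mi(mass, ("X",))
    mi_y = naive_mi(mass, ("Y",))
    mi_z = naive_mi(mass, ("Z",))
    mi_xyz = naive_mi(mass, ("X", "Y", "Z"))
    ui_x, ui_y, ui_z = m_xyz - m_yz, m_xyz - m_xz, m_xyz - m_xy
    ui_sum = ui_x + ui_y + ui_z
    return {
        "CI": mi_xyz - m_xyz,
        "UIX": ui_x, "UIY": ui_y, "UIZ": ui_z,
        "SI": mi_x + mi_y + mi_z + ui_sum - 2 * m_xyz,
        "UIYZ": m_xyz + ui_x - mi_x - ui_sum,
        "UIXZ": m_xyz + ui_y - mi_y - ui_sum,
        "UIXY": m_xyz + ui_z - mi_z - ui_sum,
        "optima": {"XYZ": m_xyz, "XY": m_xy, "XZ": m_xz, "YZ": m_yz},
    }
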