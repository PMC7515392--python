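"""Bivariate maximum-entropy PID and the bivariate/trivariate hierarchy.

The bivariate decomposition of a target ``T`` with two sources ``A`` and
``B`` needs a single minimization: ``min MI_Q(T; A, B)`` over the joints
``Q(T, A, B)`` preserving the (T,A) and (T,B) marginals.  Writing ``m`` for
the minimum,

    CI2  = MI(T;A,B) - m          (synergy)
    UI2_A = m - MI(T;B)           (unique to A)
    UI2_B = m - MI(T;A)           (unique to B)
    SI2  = MI(T;A) + MI(T;B) - m  (shared)

all of which are nonnegative in the bivariate case.

Because redundancy is invariant to the context in which it is measured, the
bivariate quantities of source pairs and of agglomerated sources are
consistent with the trivariate decomposition — e.g. ``SI2(T; Xi, Xj)``
equals ``SI + UI_ij`` of the trivariate result.  :func:`finer_parts`
exploits this hierarchy to split the trivariate synergy ``CI`` into additive
finer atoms: for each pair coalition ``(Xi, Xj)`` the in-context coalition
synergy

    w_ij = CI - CI2(T; Xk, (Xi, Xj))

measures how much of the total synergy is already available when ``Xi`` and
``Xj`` act jointly (``CI2(T; Xk, (Xi,Xj))`` is the part that still needs
``Xk`` as a separate partner).  Sorting ``w_(1) >= w_(2) >= w_(3)`` yields

    syn only from the strongest pair     w_(1) - w_(2)
    syn shared by two or more pairs      w_(2)
    syn requiring all three sources      CI - w_(1)

which sum to ``CI`` exactly.  Groupings whose solve fails leave their share
in the residual rather than guessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from ._opt import LN2, EntropyObjective, EntropyProgram, ViolationRecord
from .distributions import JointDistribution, entropy, sorted_labels
from .solver import SolverConfig, _classify

__all__ = ["BivariatePID", "FinerSynergy", "bivariate_pid", "finer_parts"]

#: source pairs and, for each, the complementary source
_PAIRS = (("X", "Y", "Z"), ("X", "Z", "Y"), ("Y", "Z", "X"))


@dataclass(frozen=True)
class BivariatePID:
    """Bivariate decomposition of MI(T; A, B); all quantities in bits."""

    SI2: float
    CI2: float
    UI2_A: float
    UI2_B: float
    optimum: float                 # min MI_Q(T; A, B)
    status: str
    violation: ViolationRecord

    @property
    def total(self) -> float:
        return self.SI2 + self.CI2 + self.UI2_A + self.UI2_B


def _bivariate_program(tab: Mapping[tuple, float]):
    """Cells, marginal constraints and objective for min MI(T;A,B)."""
    pat: dict = {}
    pbt: dict = {}
    for (t, a, b), p in tab.items():
        if p <= 0:
            continue
        pat[(t, a)] = pat.get((t, a), 0.0) + p
        pbt[(t, b)] = pbt.get((t, b), 0.0) + p
    t_labels = sorted_labels(t for t, _ in pat)
    a_labels = sorted_labels(a for _, a in pat)
    b_labels = sorted_labels(b for _, b in pbt)
    tix = {t: i for i, t in enumerate(t_labels)}
    aix = {a: i for i, a in enumerate(a_labels)}
    bix = {b: i for i, b in enumerate(b_labels)}
    pos_a: dict = {}
    pos_b: dict = {}
    for (t, a) in pat:
        pos_a.setdefault(t, []).append(a)
    for (t, b) in pbt:
        pos_b.setdefault(t, []).append(b)

    cells = []
    for t in t_labels:
        for a in sorted_labels(pos_a.get(t, ())):
            for b in sorted_labels(pos_b.get(t, ())):
                cells.append((t, a, b))
    n = len(cells)
    ti = np.array([tix[c[0]] for c in cells])
    ai = np.array([aix[c[1]] for c in cells])
    bi = np.array([bix[c[2]] for c in cells])

    rows_a, inv_a = np.unique(ti * len(a_labels) + ai, return_inverse=True)
    rows_b, inv_b = np.unique(ti * len(b_labels) + bi, return_inverse=True)
    b_a = np.array([pat[(t_labels[c // len(a_labels)], a_labels[c % len(a_labels)])]
                    for c in rows_a])
    b_b = np.array([pbt[(t_labels[c // len(b_labels)], b_labels[c % len(b_labels)])]
                    for c in rows_b])
    row_idx = np.concatenate([inv_a, inv_b + rows_a.size])
    col_idx = np.tile(np.arange(n), 2)
    A = sp.csr_matrix((np.ones(row_idx.size), (row_idx, col_idx)),
                      shape=(rows_a.size + rows_b.size, n))
    bvec = np.concatenate([b_a, b_b])

    # objective: -H(T | A, B); m-cells are the cells, groups are (a, b)
    _, Gmap_cells = np.unique(ai * len(b_labels) + bi, return_inverse=True)
    obj = EntropyObjective(Mmap=np.arange(n), Gmap=Gmap_cells, nm=n,
                           ng=int(Gmap_cells.max()) + 1)
    q0 = np.zeros(n)
    lookup = {c: i for i, c in enumerate(cells)}
    for c, p in tab.items():
        if p > 0:
            q0[lookup[c]] = p
    program = EntropyProgram(A=A, b=bvec, obj=obj, q0=q0,
                             partition_rows=np.arange(rows_a.size))
    h_t = entropy({t: sum(p for (tt, _), p in pat.items() if tt == t)
                   for t in t_labels})
    return program, h_t, pat, pbt


def bivariate_pid(tab: Mapping[tuple, float],
                  cfg: SolverConfig | None = None) -> BivariatePID:
    """Bivariate maximum-entropy PID of a (t, a, b) pmf."""
    cfg = cfg or SolverConfig()
    total = math.fsum(tab.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"pmf not normalized (total {total!r})")
    program, h_t, pat, pbt = _bivariate_program(tab)
    out = program.solve(max_iter=cfg.max_iter)
    q = out["q"]
    viol = program.certificates(q, determined=out["determined"])
    m = h_t + program.obj.value(q) / LN2
    status = _classify(viol, m, cfg)

    # mutual informations of the observed pmf
    h_a = entropy(_sum_over(pat, 1))
    h_b = entropy(_sum_over(pbt, 1))
    mi_a = h_t + h_a - entropy(pat)
    mi_b = h_t + h_b - entropy(pbt)
    joint_ab: dict = {}
    for (t, a, b), p in tab.items():
        if p > 0:
            joint_ab[(a, b)] = joint_ab.get((a, b), 0.0) + p
    mi_ab = h_t + entropy(joint_ab) - entropy({k: v for k, v in tab.items() if v > 0})
    return BivariatePID(
        SI2=mi_a + mi_b - m,
        CI2=mi_ab - m,
        UI2_A=m - mi_b,
        UI2_B=m - mi_a,
        optimum=float(m),
        status=status,
        violation=viol,
    )


def _sum_over(pair_pmf: Mapping[tuple, float], keep: int) -> dict:
    out: dict = {}
    for k, p in pair_pmf.items():
        out[k[keep]] = out.get(k[keep], 0.0) + p
    return out


@dataclass
class FinerSynergy:
    """Finer split of the trivariate synergy via the bivariate hierarchy."""

    atoms: dict[str, float]
    residual: float
    pair_synergy: dict[str, float]            # in-context coalition synergy w_ij
    pair_bivariate: dict[str, BivariatePID]   # runs on (T; Xi, Xj)
    agglomerated: dict[str, BivariatePID]     # runs on (T; Xk, (Xi, Xj))
    redundancy_consistency: dict[str, float]  # |SI2(i,j) - (SI + UI_ij)|
    warnings: list[str] = field(default_factory=list)

    def total(self) -> float:
        return math.fsum(v for v in self.atoms.values() if np.isfinite(v)) \
            + self.residual

    def to_dict(self) -> dict:
        return {
            "atoms": dict(self.atoms),
            "residual": self.residual,
            "pair_synergy": dict(self.pair_synergy),
            "redundancy_consistency": dict(self.redundancy_consistency),
            "warnings": list(self.warnings),
        }


def _pair_pmf(d: JointDistribution, i: str, j: str) -> dict:
    """(t, xi, xj) marginal pmf."""
    out: dict = {}
    for (t, x, y, z), p in d.mass.items():
        if p <= 0:
            continue
        vals = {"X": x, "Y": y, "Z": z}
        key = (t, vals[i], vals[j])
        out[key] = out.get(key, 0.0) + p
    return out


def _agglomerated_pmf(d: JointDistribution, k: str) -> dict:
    """(t, xk, (xi, xj)) pmf with the complementary pair as a product symbol."""
    i, j = [v for v in ("X", "Y", "Z") if v != k]
    out: dict = {}
    for (t, x, y, z), p in d.mass.items():
        if p <= 0:
            continue
        vals = {"X": x, "Y": y, "Z": z}
        key = (t, vals[k], (vals[i], vals[j]))
        out[key] = out.get(key, 0.0) + p
    return out


def finer_parts(d: JointDistribution, coarse, cfg: SolverConfig | None = None,
                consistency_tol: float = 2e-6) -> FinerSynergy:
    """Split the trivariate synergy of *coarse* into finer atoms.

    Runs the bivariate solver on the three source pairs and on the three
    agglomerated groupings, checks the context-invariance relations, and
    allocates ``CI`` into pair-coalition atoms plus a triple-only part.
    Failed groupings leave their share in the residual.
    """
    cfg = cfg or SolverConfig()
    ci = float(coarse.params["CI"])
    si = float(coarse.params["SI"])

    pair_biv: dict[str, BivariatePID] = {}
    aggl: dict[str, BivariatePID] = {}
    warnings_: list[str] = []
    for i, j, k in _PAIRS:
        pair_biv[i + j] = bivariate_pid(_pair_pmf(d, i, j), cfg)
        aggl[k] = bivariate_pid(_agglomerated_pmf(d, k), cfg)

    consistency = {}
    for i, j, _k in _PAIRS:
        expected = si + float(coarse.params["UI" + i + j])
        dev = abs(pair_biv[i + j].SI2 - expected)
        consistency[i + j] = dev
        if dev > consistency_tol:
            warnings_.append(
                f"context-invariance deviation {dev:.2e} bits for pair ({i},{j})"
            )

    atom_keys = ["syn_only_XY", "syn_only_XZ", "syn_only_YZ",
                 "syn_shared_pairs", "syn_triple"]
    if ci <= 1e-12:
        # degenerate: zero synergy forces every finer part to zero
        return FinerSynergy(
            atoms={k: 0.0 for k in atom_keys}, residual=0.0,
            pair_synergy={i + j: 0.0 for i, j, _ in _PAIRS},
            pair_bivariate=pair_biv, agglomerated=aggl,
            redundancy_consistency=consistency, warnings=warnings_,
        )

    w: dict[str, float] = {}
    failed = [k for k, r in aggl.items() if r.status == "failed"]
    for i, j, k in _PAIRS:
        if k in failed:
            w[i + j] = np.nan
        else:
            w[i + j] = float(np.clip(ci - aggl[k].CI2, 0.0, ci))

    atoms = {k: np.nan for k in atom_keys}
    if failed:
        warnings_.append(
            "unidentifiable finer split: agglomerated solve failed for "
            + ", ".join(sorted(failed)) + "; remainder attributed to synergy"
        )
        residual = ci
        for key in atom_keys:
            atoms[key] = np.nan
    else:
        order = sorted(w, key=w.get, reverse=True)
        w1, w2 = w[order[0]], w[order[1]]
        for pair in w:
            atoms["syn_only_" + pair] = w1 - w2 if pair == order[0] else 0.0
        atoms["syn_shared_pairs"] = w2
        atoms["syn_triple"] = ci - w1
        residual = ci - math.fsum(atoms.values())
    return FinerSynergy(
        atoms=atoms, residual=residual, pair_synergy=w,
        pair_bivariate=pair_biv, agglomerated=aggl,
        redundancy_consistency=consistency, warnings=warnings_,
    )
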