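import itertools
import math

import numpy as np
import pytest

from maxentpid import datasets
from maxentpid.distributions import JointDistribution, mutual_information
from maxentpid.solver import (
    SCOPES,
    SolverConfig,
    build_problem,
    certificate_violations,
    solve,
    solve_all,
)
from oracles import brute_force_min_mi


def uniform_binary():
    return JointDistribution({k: 1 / 16 for k in itertools.product((0, 1), repeat=4)})


class TestSolverConfig:
    def test_defaults(self):
        cfg = SolverConfig()
        assert cfg.feastol == 1e-7
        assert cfg.abstol == 1e-6
        assert cfg.reltol == 1e-6
        assert cfg.feastol_inacc == 1e-3
        assert cfg.abstol_inacc == 1e-4
        assert cfg.reltol_inacc == 1e-4
        assert cfg.max_iter == 100

    @pytest.mark.parametrize("kw", [{"feastol": 0.0}, {"abstol": -1e-9},
                                    {"max_iter": 0}])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SolverConfig(**kw)


class TestBuildProblem:
    def test_copy_gate_support_is_forced(self):
        spec = build_problem(datasets.copy_gate(2, 2, 2), "XYZ")
        assert spec.n_cells == 8
        for t, x, y, z in spec.variable_support:
            assert t == f"{x},{y},{z}"

    def test_product_pmf_full_support(self):
        spec = build_problem(uniform_binary(), "XY")
        assert spec.n_cells == 16

    def test_scope_changes_objective_not_constraints(self):
        d = uniform_binary()
        s1 = build_problem(d, "XY")
        s2 = build_problem(d, "XZ")
        assert s1.variable_support == s2.variable_support
        assert s1.marginals.pxt == s2.marginals.pxt

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError, match="scope"):
            build_problem(uniform_binary(), "XW")

    def test_support_contains_observed_support(self, gates):
        for d in gates.values():
            spec = build_problem(d, "XYZ")
            assert set(d.support) <= set(spec.variable_support)


class TestSolve:
    def test_xor_duplicate_fully_decouplable(self, gates):
        res = solve(build_problem(gates["XorDuplicate"], "XYZ"))
        assert res.optimal_value == pytest.approx(0.0, abs=1e-9)
        assert res.status == "optimal"

    def test_xor_loses_pinned_by_z_marginal(self, gates):
        res = solve(build_problem(gates["XorLoses"], "XYZ"))
        assert res.optimal_value == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_trivial(self):
        d = JointDistribution({("a", "b", "c", "d"): 1.0})
        for scope in SCOPES:
            res = solve(build_problem(d, scope))
            assert res.optimal_value == pytest.approx(0.0, abs=1e-12)
            assert res.determined

    def test_solution_is_a_feasible_pmf(self, gates, random_binary_dists):
        cfg = SolverConfig()
        for d in list(gates.values()) + random_binary_dists[:3]:
            for scope in SCOPES:
                res = solve(build_problem(d, scope), cfg)
                v = res.solution_vector
                assert v.min() >= -cfg.feastol
                assert abs(v.sum() - 1.0) <= cfg.feastol
                assert res.violation.primal_residual <= cfg.feastol


class TestSolveAll:
    def test_copy_gate_unique_information_structure(self):
        res = solve_all(datasets.copy_gate(2, 2, 2))
        values = {s: r.optimal_value for s, r in res.items()}
        assert values["XYZ"] == pytest.approx(3.0, abs=1e-9)
        for pair in ("XY", "XZ", "YZ"):
            assert values[pair] == pytest.approx(2.0, abs=1e-9)

    def test_and_duplicate_optima(self, gates):
        expected = 2 - 0.75 * math.log2(3) - 0.5
        res = solve_all(gates["AndDuplicate"])
        for r in res.values():
            assert r.optimal_value == pytest.approx(expected, abs=1e-9)

    def test_parallel_flag_is_scheduling_only(self, gates):
        d = gates["AndDuplicate"]
        seq = solve_all(d, parallel="off")
        par = solve_all(d, parallel="on")
        for scope in SCOPES:
            assert seq[scope].optimal_value == par[scope].optimal_value
            np.testing.assert_array_equal(seq[scope].solution_vector,
                                          par[scope].solution_vector)

    def test_objective_ordering_and_feasible_upper_bound(self, random_binary_dists):
        for d in random_binary_dists[:5]:
            res = solve_all(d)
            v = {s: r.optimal_value for s, r in res.items()}
            for pair, srcs in (("XY", {"X", "Y"}), ("XZ", {"X", "Z"}),
                               ("YZ", {"Y", "Z"})):
                assert v["XYZ"] >= v[pair] - 1e-8
                assert v[pair] >= -1e-9
                assert v[pair] <= mutual_information(d, srcs) + 1e-8
            assert v["XYZ"] <= mutual_information(d, {"X", "Y", "Z"}) + 1e-8


class TestCertificates:
    def test_feeding_back_p_reveals_the_gap(self, gates):
        # the observed pmf is feasible but 1 bit above the minimum
        d = gates["XorDuplicate"]
        spec = build_problem(d, "XYZ")
        res = solve(spec)
        res_p = res.__class__(
            scope="XYZ", optimal_value=1.0,
            solution_vector=spec._data.q0, status="failed",
            violation=res.violation, determined=False, _spec=spec,
        )
        viol = certificate_violations(res_p, spec)
        assert viol.primal_residual <= 1e-12
        assert viol.duality_gap == pytest.approx(1.0, abs=1e-6)

    def test_perturbed_solution_shows_primal_residual(self, gates):
        spec = build_problem(gates["XorDuplicate"], "XYZ")
        res = solve(spec)
        bad = res.solution_vector.copy()
        bad[0] += 1e-3
        res_bad = res.__class__(
            scope="XYZ", optimal_value=res.optimal_value, solution_vector=bad,
            status="failed", violation=res.violation, determined=False,
            _spec=spec,
        )
        viol = certificate_violations(res_bad, spec)
        assert viol.primal_residual >= 1e-3 - 1e-12

    def test_exact_optimum_certifies_cleanly(self):
        spec = build_problem(datasets.copy_gate(2, 2, 2), "XYZ")
        res = solve(spec)
        viol = certificate_violations(res, spec)
        assert viol.primal_residual <= 1e-8
        assert viol.dual_residual <= 1e-8
        assert viol.duality_gap <= 1e-8

    def test_missing_solution_rejected(self, gates):
        spec = build_problem(gates["XorLoses"], "XY")
        res = solve(spec)
        res_none = res.__class__(
            scope="XY", optimal_value=0.0, solution_vector=None,
            status="failed", violation=res.violation, _spec=spec,
        )
        with pytest.raises(ValueError, match="no solution"):
            certificate_violations(res_none, spec)


class TestOracleEquivalence:
    def test_optima_match_brute_force(self):
        # a slice of the larger acceptance sweep, kept here as a unit check
        worst = 0.0
        for i in range(8):
            d = datasets.random_joint((2, 2, 2, 2), seed=900 + i)
            res = solve_all(d)
            for scope, srcs in (("XYZ", ("X", "Y", "Z")), ("XY", ("X", "Y")),
                                ("XZ", ("X", "Z")), ("YZ", ("Y", "Z"))):
                ref = brute_force_min_mi(d.mass, srcs, restarts=4, seed=i)
                worst = max(worst, abs(ref - res[scope].optimal_value))
        assert worst <= 1e-5
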