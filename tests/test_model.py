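import itertools
import math

import numpy as np
import pandas as pd
import pytest

from maxentpid import datasets
from maxentpid.distributions import EmptyDistributionError, JointDistribution
from maxentpid.model import (
    PID_KEYS,
    VIOLATION_KEYS,
    TrivariatePID,
    assemble,
    needs_repair,
    pid,
    prune_small_masses,
    qp_repair,
)
from maxentpid._opt import ViolationRecord
from maxentpid.solver import SCOPES, solve_all
from oracles import brute_force_pid

AND_MIN = 2 - 0.75 * math.log2(3) - 0.5     # 0.311278...


def mi_profile(d):
    from maxentpid.model import _mi_profile
    return _mi_profile(d)


class TestAssemble:
    def test_copy_gate_identities(self):
        d = datasets.copy_gate(2, 2, 2)
        out = assemble(d, {"XYZ": 3.0, "XY": 2.0, "XZ": 2.0, "YZ": 2.0})
        for k in ("UIX", "UIY", "UIZ"):
            assert out[k] == pytest.approx(1.0, abs=1e-12)
        for k in ("CI", "SI", "UIXY", "UIXZ", "UIYZ"):
            assert out[k] == pytest.approx(0.0, abs=1e-12)

    def test_xor_duplicate_pure_synergy(self, gates):
        out = assemble(gates["XorDuplicate"], {s: 0.0 for s in SCOPES})
        assert out["CI"] == pytest.approx(1.0, abs=1e-12)
        assert all(abs(out[k]) < 1e-12 for k in PID_KEYS if k != "CI")

    def test_and_duplicate_synergy_and_redundancy(self, gates):
        out = assemble(gates["AndDuplicate"], {s: AND_MIN for s in SCOPES})
        assert out["CI"] == pytest.approx(0.5, abs=1e-12)
        assert out["SI"] == pytest.approx(AND_MIN, abs=1e-12)
        assert all(abs(out[k]) < 1e-12 for k in
                   ("UIX", "UIY", "UIZ", "UIXY", "UIXZ", "UIYZ"))

    def test_non_finite_optimum_rejected(self, gates):
        with pytest.raises(ValueError, match="non-finite"):
            assemble(gates["XorLoses"], {"XYZ": np.nan, "XY": 0, "XZ": 1, "YZ": 1})


class TestNeedsRepair:
    def _records(self, **overrides):
        recs = {s: ViolationRecord(1e-9, 1e-9, 1e-9) for s in SCOPES}
        recs.update(overrides)
        return recs

    def test_clean_run_no_repair(self):
        flag, errant = needs_repair(self._records(), threshold=1e-6)
        assert not flag and errant == set()

    def test_single_large_gap_flagged(self):
        recs = self._records(XY=ViolationRecord(1e-9, 1e-9, 1e-2))
        flag, errant = needs_repair(recs, threshold=1e-6)
        assert flag and errant == {"XY"}

    def test_all_flagged(self):
        recs = {s: ViolationRecord(1.0, 1.0, 1.0) for s in SCOPES}
        flag, errant = needs_repair(recs, threshold=1e-6)
        assert errant == set(SCOPES)


class TestQpRepair:
    def test_spurious_flag_leaves_values(self):
        d = datasets.copy_gate(2, 2, 2)
        mi = mi_profile(d)
        raw = {"XYZ": 3.0, "XY": 2.0, "XZ": 2.0, "YZ": 2.0}
        out = qp_repair(raw, {"XY"}, mi)
        assert out == pytest.approx(raw, abs=1e-7)

    def test_perturbed_copy_pair_projected_back(self):
        d = datasets.copy_gate(2, 2, 2)
        mi = mi_profile(d)
        raw = {"XYZ": 3.0, "XY": 2.05, "XZ": 2.0, "YZ": 2.0}
        out = qp_repair(raw, {"XY"}, mi)
        assert out["XY"] == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("name", datasets.GATE_NAMES)
    def test_all_flagged_gate_recovers_decomposition(self, name, gates):
        d = gates[name]
        mi = mi_profile(d)
        truth = {s: r.optimal_value for s, r in solve_all(d).items()}
        corrupted = {s: v / 100.0 - 0.25 for s, v in truth.items()}
        out = qp_repair(corrupted, set(SCOPES), mi)
        rebuilt = assemble(d, out)
        ref = datasets.analytic_gate_reference(name)
        assert max(abs(rebuilt[k] - ref[k]) for k in PID_KEYS) < 1e-6


class TestPrune:
    def test_zero_floor_is_identity(self, gates):
        d = gates["AndDuplicate"]
        assert prune_small_masses(d, 0.0) is d

    def test_tiny_mass_dropped(self):
        d = JointDistribution({(0, 0, 0, 0): 0.999999999999, (1, 1, 1, 1): 1e-12})
        out = prune_small_masses(d, 1e-9)
        assert len(out) == 1
        assert out.mass[(0, 0, 0, 0)] == pytest.approx(1.0)

    def test_floor_too_large_rejected(self, gates):
        with pytest.raises(EmptyDistributionError, match="floor too large"):
            prune_small_masses(gates["XorLoses"], 0.5)

    def test_pruning_perturbs_decomposition_continuously(self):
        d = datasets.random_joint((2, 2, 2, 14), seed=77)
        pruned = prune_small_masses(d, 1e-8)
        removed = 1.0 - sum(d.mass[k] for k in pruned.mass)
        assert removed < 1e-6
        r0 = TrivariatePID(d).fit()
        r1 = TrivariatePID(pruned).fit()
        assert max(abs(r0.params[k] - r1.params[k]) for k in PID_KEYS) < 1e-4


class TestFit:
    def test_and_duplicate_end_to_end(self, gates):
        res = TrivariatePID(gates["AndDuplicate"]).fit()
        assert res.params["CI"] == pytest.approx(0.5, abs=1e-9)
        assert res.params["SI"] == pytest.approx(AND_MIN, abs=1e-9)
        assert set(res.to_dict()) == set(PID_KEYS) | set(VIOLATION_KEYS)

    def test_uniform_product_all_zero(self):
        d = JointDistribution({k: 1 / 16 for k in itertools.product((0, 1), repeat=4)})
        res = TrivariatePID(d).fit()
        assert max(abs(v) for v in res.params) < 1e-9

    def test_copy_gate_log_dimensions(self):
        res = TrivariatePID(datasets.copy_gate(10, 10, 10)).fit()
        ref = datasets.analytic_copy_reference(10, 10, 10)
        assert datasets.deviation(res, ref) <= 1e-7

    def test_conservation_and_source_identities(self, random_binary_dists):
        for d in random_binary_dists[:5]:
            res = TrivariatePID(d).fit()
            assert res.conservation_error() < 1e-9
            assert max(res.source_identity_errors().values()) < 1e-9

    def test_nonnegativity_of_synergy_and_unique(self, random_binary_dists):
        for d in random_binary_dists:
            res = TrivariatePID(d).fit()
            assert res.params["CI"] >= -1e-9
            for k in ("UIX", "UIY", "UIZ"):
                assert res.params[k] >= -1e-9

    def test_source_relabelling_equivariance(self):
        d = datasets.random_joint((2, 3, 2, 4), seed=4242)
        swapped = JointDistribution(
            {(t, z, y, x): p for (t, x, y, z), p in d.mass.items()}
        )
        r1 = TrivariatePID(d).fit()
        r2 = TrivariatePID(swapped).fit()
        tol = 2e-7
        assert r2.params["UIX"] == pytest.approx(r1.params["UIZ"], abs=tol)
        assert r2.params["UIZ"] == pytest.approx(r1.params["UIX"], abs=tol)
        assert r2.params["UIY"] == pytest.approx(r1.params["UIY"], abs=tol)
        assert r2.params["UIXY"] == pytest.approx(r1.params["UIYZ"], abs=tol)
        assert r2.params["UIYZ"] == pytest.approx(r1.params["UIXY"], abs=tol)
        assert r2.params["CI"] == pytest.approx(r1.params["CI"], abs=tol)
        assert r2.params["SI"] == pytest.approx(r1.params["SI"], abs=tol)

    def test_matches_full_oracle_decomposition(self):
        d = datasets.random_joint((2, 2, 2, 2), seed=1234)
        res = TrivariatePID(d).fit()
        ref = brute_force_pid(d.mass, restarts=5, seed=0)
        assert max(abs(res.params[k] - ref[k]) for k in PID_KEYS) < 1e-5

    def test_from_dataframe_round_trip(self, gates):
        d = gates["AndDuplicate"]
        df = pd.DataFrame(
            [(t, x, y, z, p) for (t, x, y, z), p in d.mass.items()],
            columns=["t", "x", "y", "z", "p"],
        )
        res = TrivariatePID.from_dataframe(df).fit()
        assert res.params["CI"] == pytest.approx(0.5, abs=1e-9)

    def test_summary_mentions_every_quantity(self, gates):
        text = TrivariatePID(gates["XorLoses"]).fit().summary()
        for k in PID_KEYS:
            assert k in text

    def test_pid_wrapper(self, gates):
        res = pid(gates["XorDuplicate"])
        assert res.params["CI"] == pytest.approx(1.0, abs=1e-9)
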