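"""Grid enumeration, condition execution, best-method rule, real-data protocol."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from netdiff.runner import (
    Condition,
    ConditionResult,
    GridSpec,
    best_method_table,
    enumerate_conditions,
    permute_and_split,
    realdata_condition,
    run_condition,
)
from netdiff.simulate import Dataset, random_network, sample_data

SMOKE = GridSpec(
    nv=(10,),
    ne_multipliers=(1.5,),
    nd_fractions=(0.25,),
    n1=(200,),
    n2_ratios=(0.5,),
    repeats=2,
    algorithms=("pc",),
    b=3,
    algorithm_params={"pc": {"max_cond_size": 1}},
)


class TestEnumerateConditions:
    def test_full_grid_counts(self):
        spec = GridSpec()
        conds = enumerate_conditions(spec)
        assert len(conds) == 240
        assert len(conds) * spec.repeats == 12_000
        assert sum(c.rsbs_applicable for c in conds) == 180

    def test_matches_nested_loop_oracle(self):
        spec = GridSpec(nv=(10, 20), ne_multipliers=(1.5,), nd_fractions=(0.1, 0.5),
                        n1=(100,), n2_ratios=(0.5, 1.0), repeats=3)
        expected = []
        for nv in spec.nv:
            for m in spec.ne_multipliers:
                for f in spec.nd_fractions:
                    for n1 in spec.n1:
                        for r in spec.n2_ratios:
                            ne = int(round(m * nv))
                            expected.append(
                                Condition(nv, ne, math.ceil(f * ne), n1, math.ceil(r * n1))
                            )
        assert enumerate_conditions(spec) == expected

    def test_ceil_applied_to_nd_and_n2(self):
        spec = GridSpec(nv=(10,), ne_multipliers=(1.5,), nd_fractions=(0.05,),
                        n1=(500,), n2_ratios=(0.1,))
        (cond,) = enumerate_conditions(spec)
        assert cond.ne == 15 and cond.nd == 1 and cond.n2 == 50

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enumerate_conditions(GridSpec(nv=()))


@pytest.fixture(scope="module")
def smoke_result():
    (cond,) = enumerate_conditions(SMOKE)
    return run_condition(cond, SMOKE, master_seed=3)


class TestRunCondition:
    def test_expected_row_structure(self, smoke_result):
        rows = smoke_result.rows
        # 2 repeats x 3 methods x 2 directions x 2 modes (rsbs applicable: n1 != n2)
        assert len(rows) == 2 * 3 * 2 * 2
        assert set(rows["method"]) == {"naive", "bs", "rsbs"}
        assert set(rows["mode"]) == {"orientation", "skeleton"}

    def test_rsbs_absent_when_equal_sample_sizes(self):
        from dataclasses import replace

        spec = replace(SMOKE, n2_ratios=(1.0,))
        (cond,) = enumerate_conditions(spec)
        res = run_condition(cond, spec, master_seed=3)
        assert "rsbs" not in set(res.rows["method"])

    def test_deterministic_given_master_seed(self, smoke_result):
        (cond,) = enumerate_conditions(SMOKE)
        again = run_condition(cond, SMOKE, master_seed=3)
        pd.testing.assert_frame_equal(smoke_result.rows, again.rows)

    def test_aggregate_has_mean_and_std(self, smoke_result):
        agg = smoke_result.aggregate()
        assert ("aucroc", "mean") in agg.columns


def _fake_result(cond, method_stats, direction="12", mode="orientation"):
    """Two repeats per method with an exact (mean, sample SD) per metric."""
    rows = []
    for method, (mean, sd) in method_stats.items():
        half = sd / math.sqrt(2)  # ddof=1 SD of {m-h, m+h} is h*sqrt(2)
        for r, v in enumerate([mean - half, mean + half]):
            rows.append({"repeat": r, "algorithm": "pc", "method": method,
                         "direction": direction, "mode": mode, "aucroc": v,
                         "aupr": v, "cross_entropy": v, "f1": v})
    return ConditionResult(condition=cond, rows=pd.DataFrame(rows))


class TestBestMethodRule:
    COND = Condition(10, 15, 4, 200, 100)

    def test_identical_means_both_best(self):
        res = _fake_result(self.COND, {"bs": (0.9, 0.0), "naive": (0.9, 0.0)})
        table = best_method_table([res], metric="aucroc")
        assert dict(zip(table["method"], table["percent_best"])) == {
            "bs": 100.0, "naive": 100.0}

    def test_one_sd_rule_hand_computed(self):
        # best mean 0.9, sd 0.05 -> cutoff 0.85; 0.84 is out
        res = _fake_result(self.COND, {"bs": (0.9, 0.05), "naive": (0.84, 0.0)})
        table = best_method_table([res], metric="aucroc")
        marks = dict(zip(table["method"], table["percent_best"]))
        assert marks["bs"] == 100.0 and marks["naive"] == 0.0

    def test_within_one_sd_marked_best(self):
        res = _fake_result(self.COND, {"bs": (0.9, 0.05), "naive": (0.86, 0.0)})
        table = best_method_table([res], metric="aucroc")
        marks = dict(zip(table["method"], table["percent_best"]))
        assert marks["naive"] == 100.0

    def test_lower_is_better_for_cross_entropy(self):
        # smaller cross-entropy wins, in contrast to the ranking metrics
        res = _fake_result(self.COND, {"bs": (0.2, 0.0), "naive": (0.9, 0.0)})
        table = best_method_table([res], metric="cross_entropy")
        marks = dict(zip(table["method"], table["percent_best"]))
        assert marks["bs"] == 100.0 and marks["naive"] == 0.0
        aucroc = best_method_table([res], metric="aucroc")
        marks = dict(zip(aucroc["method"], aucroc["percent_best"]))
        assert marks["naive"] == 100.0 and marks["bs"] == 0.0


@pytest.fixture(scope="module")
def d0():
    net = random_network(8, 12, seed=31)
    return sample_data(net, 4000, seed=32)


class TestPermuteAndSplit:
    def test_marginals_preserved_and_sets_disjoint(self, d0):
        d1f, d2f, (s1, s2) = permute_and_split(d0, 2, seed=33)
        assert not (set(s1) & set(s2))
        idx = {v: i for i, v in enumerate(d0.variables)}
        for name in s1:
            np.testing.assert_array_equal(
                np.sort(d1f.values[:, idx[name]]), np.sort(d0.values[:, idx[name]])
            )

    def test_permuted_column_decorrelated(self, d0):
        d1f, _, (s1, _) = permute_and_split(d0, 2, seed=33)
        idx = {v: i for i, v in enumerate(d0.variables)}
        others = [v for v in d0.variables if v not in s1]
        # 5 SE bound on a sample correlation of independent columns
        bound = 5 / math.sqrt(d0.n)
        for name in s1:
            for other in others:
                r = np.corrcoef(d1f.values[:, idx[name]], d1f.values[:, idx[other]])[0, 1]
                assert abs(r) < bound

    def test_too_many_permuted_variables_rejected(self, d0):
        with pytest.raises(ValueError, match="distinct variables"):
            permute_and_split(d0, 5, seed=0)


class TestRealdataProtocol:
    def test_smoke_run(self):
        net = random_network(8, 12, seed=41)
        d0 = sample_data(net, 300, seed=42)
        d1f, d2f, _ = permute_and_split(d0, 2, seed=43)
        rows = realdata_condition(
            d1f, d2f, seed=44, ratios=(0.5, 1.0), algorithm="ges", b=3,
            modes=("skeleton",),
        )
        # 60% subsample defines N1
        assert set(rows["n1"]) == {math.ceil(0.6 * 300)}
        # rsbs present at ratio 0.5, absent at ratio 1 (equal sizes)
        at_half = rows[rows["ratio"] == 0.5]
        at_one = rows[rows["ratio"] == 1.0]
        assert "rsbs" in set(at_half["method"])
        assert "rsbs" not in set(at_one["method"])
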