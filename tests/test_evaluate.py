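"""Labels, classification metrics, effect sizes and their invariants."""

import numpy as np
import pytest

from netdiff.diff import DiffScoreMap
from netdiff.evaluate import (
    DiffLabels,
    classification_metrics,
    correlate_effectsize_scores,
    effect_size,
    effect_size_table,
    pair_universe,
    true_edge_diff,
)
from netdiff.simulate import (
    DagStructure,
    LinearGaussianNetwork,
    implied_covariance,
    sample_data,
)


def _labels(variables, positives, mode="orientation"):
    return DiffLabels(mode=mode, variables=variables, positives=frozenset(positives))


def _scores(variables, scores, mode="orientation"):
    return DiffScoreMap(
        mode=mode, method="bs", variables=variables, scores=dict(scores)
    )


class TestTrueEdgeDiff:
    def test_identical_graphs_all_zero(self, small_net):
        labels = true_edge_diff(small_net, small_net, "orientation")
        assert labels.positives == frozenset()

    def test_simulated_pair_positives_are_deleted_edges(self, small_pair):
        fwd = true_edge_diff(small_pair.g1, small_pair.g2, "orientation")
        rev = true_edge_diff(small_pair.g2, small_pair.g1, "orientation")
        assert fwd.positives == small_pair.deleted_edges
        assert rev.positives == small_pair.added_edges
        assert not (fwd.positives & rev.positives)

    def test_universe_cardinalities(self, small_net):
        nv = len(small_net.variables)
        assert len(pair_universe(small_net.variables, "orientation")) == nv * (nv - 1)
        assert len(pair_universe(small_net.variables, "skeleton")) == nv * (nv - 1) // 2

    def test_mismatched_variables_rejected(self, small_net):
        dag = DagStructure(variables=("P", "Q"), edges=frozenset(), order=("P", "Q"))
        other = LinearGaussianNetwork(dag=dag, coefficients={}, noise_sd={"P": 1.0, "Q": 1.0})
        with pytest.raises(ValueError):
            true_edge_diff(small_net, other)


class TestClassificationMetrics:
    VARS = ("A", "B", "C")

    def test_perfect_scores(self):
        labels = _labels(self.VARS, {("A", "B")})
        scores = _scores(self.VARS, {("A", "B"): 1.0})
        rep = classification_metrics(labels, scores)
        assert rep.aucroc == 1.0 and rep.aupr == 1.0 and rep.f1 == 1.0

    def test_constant_scores_are_uninformative(self):
        labels = _labels(self.VARS, {("A", "B")})
        scores = _scores(self.VARS, {p: 0.5 for p in pair_universe(self.VARS, "orientation")})
        rep = classification_metrics(labels, scores)
        assert rep.aucroc == 0.5

    def test_hand_enumerated_four_pair_example(self):
        """labels (1,0,0,0), scores (0.9,0.8,0.1,0.1): both ranking areas are 1
        and the F1-optimal threshold separates 0.8 from 0.9."""
        variables = ("A", "B", "C")
        universe = pair_universe(variables, "skeleton")  # 3 pairs -> use 4 ordered
        labels = DiffLabels(
            mode="orientation",
            variables=("A", "B", "C"),
            positives=frozenset({("A", "B")}),
        )
        s = {("A", "B"): 0.9, ("B", "A"): 0.8, ("A", "C"): 0.1, ("C", "A"): 0.1}
        scores = _scores(("A", "B", "C"), s)
        rep = classification_metrics(labels, scores)
        assert rep.aucroc == 1.0
        assert rep.aupr == 1.0
        assert 0.8 < rep.threshold <= 0.9

    def test_degenerate_labels_report_missing_ranking_metrics(self):
        labels = _labels(self.VARS, set())
        scores = _scores(self.VARS, {})
        rep = classification_metrics(labels, scores)
        assert rep.aucroc is None and rep.aupr is None
        assert rep.n_pos == 0

    def test_aucroc_equals_pairwise_comparison_probability(self):
        """Brute-force oracle: AUCROC = P(random positive outscores random
        negative), ties counting one half."""
        rng = np.random.default_rng(12)
        variables = tuple(f"V{c}" for c in "abcdefghijklmn")  # 14 vars, 182 pairs
        universe = pair_universe(variables, "orientation")
        y = rng.random(len(universe)) < 0.3
        s = np.round(rng.random(len(universe)), 1)  # coarse grid forces ties
        labels = DiffLabels(
            mode="orientation",
            variables=variables,
            positives=frozenset(p for p, yi in zip(universe, y) if yi),
        )
        smap = _scores(variables, dict(zip(universe, s)))
        rep = classification_metrics(labels, smap)
        pos, neg = s[y], s[~y]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert rep.aucroc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        universe = pair_universe(self.VARS, "orientation")
        y = rng.random(len(universe)) < 0.5
        s = rng.random(len(universe))
        labels = _labels(self.VARS, {p for p, yi in zip(universe, y) if yi})
        a = classification_metrics(labels, _scores(self.VARS, dict(zip(universe, s))))
        b = classification_metrics(
            labels, _scores(self.VARS, dict(zip(universe, np.tanh(3 * s))))
        )
        assert a.aucroc == pytest.approx(b.aucroc)
        assert a.aupr == pytest.approx(b.aupr)


class TestEffectSize:
    def test_single_parent_closed_form(self):
        dag = DagStructure(("X", "Y"), frozenset({("X", "Y")}), ("X", "Y"))
        net = LinearGaussianNetwork(
            dag=dag, coefficients={("X", "Y"): 0.3}, noise_sd={"X": 1.0, "Y": np.sqrt(0.91)}
        )
        # R^2 = 0.09, f^2 = 0.09/0.91
        assert effect_size(net, ("X", "Y")) == pytest.approx(0.09 / 0.91)

    def test_minimum_coefficient_just_below_small_band(self):
        dag = DagStructure(("X", "Y"), frozenset({("X", "Y")}), ("X", "Y"))
        net = LinearGaussianNetwork(
            dag=dag, coefficients={("X", "Y"): 0.1}, noise_sd={"X": 1.0, "Y": np.sqrt(0.99)}
        )
        f2 = effect_size(net, ("X", "Y"))
        assert f2 == pytest.approx(0.01 / 0.99)
        assert f2 < 0.02

    def test_absent_edge_rejected(self, small_net):
        with pytest.raises(ValueError, match="not in the network"):
            missing = next(
                (a, b)
                for a in small_net.variables
                for b in small_net.variables
                if a != b and (a, b) not in small_net.edges
            )
            effect_size(small_net, missing)

    def test_matches_sample_regression(self, small_net):
        """Monte-Carlo oracle: population f^2 vs OLS R^2 difference on samples."""
        data = sample_data(small_net, 200_000, seed=21).values
        idx = {v: i for i, v in enumerate(small_net.variables)}
        edge = max(effect_size_table(small_net), key=lambda e: effect_size(small_net, e))
        tail, head = edge
        parents = list(small_net.dag.parents(head))

        def r2(cols):
            if not cols:
                return 0.0
            x = data[:, [idx[c] for c in cols]]
            y = data[:, idx[head]]
            beta, *_ = np.linalg.lstsq(
                np.column_stack([x, np.ones(len(x))]), y, rcond=None
            )
            resid = y - np.column_stack([x, np.ones(len(x))]) @ beta
            return 1 - resid.var() / y.var()

        full = r2(parents)
        reduced = r2([p for p in parents if p != tail])
        sample_f2 = (full - reduced) / (1 - full)
        assert effect_size(small_net, edge) == pytest.approx(sample_f2, abs=0.005)


class TestCorrelation:
    def test_monotone_scores_give_rho_one(self):
        table = {("A", "B"): 0.05, ("A", "C"): 0.1, ("B", "C"): 0.2}
        scores = _scores(("A", "B", "C"), {e: i for i, e in enumerate(sorted(table))})
        # scores increase with f2 ordering by construction
        table_sorted = dict(sorted(table.items(), key=lambda kv: kv[1]))
        scores = _scores(
            ("A", "B", "C"), {e: i for i, e in enumerate(table_sorted)}
        )
        res = correlate_effectsize_scores(table_sorted, scores)
        assert res.rho == pytest.approx(1.0)

    def test_constant_scores_flagged(self):
        table = {("A", "B"): 0.05, ("A", "C"): 0.1, ("B", "C"): 0.2}
        scores = _scores(("A", "B", "C"), {e: 0.5 for e in table})
        res = correlate_effectsize_scores(table, scores)
        assert res.rho is None and res.flag == "zero variance"

    def test_fewer_than_three_edges_undefined(self):
        res = correlate_effectsize_scores(
            {("A", "B"): 0.1}, _scores(("A", "B"), {("A", "B"): 0.5})
        )
        assert res.rho is None and "fewer" in res.flag
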