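"""Ranking, greedy selection, protocols, reproducibility and robustness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

import midrw as m
from midrw.activity import ActivityMatrix
from midrw.evaluate import (
    accuracy,
    default_classifier,
    greedy_select,
    hf_subpathways,
)


def _diff_from_t(ts: list[float]) -> m.DifferentialTable:
    table = pd.DataFrame(
        {
            "t": ts,
            "p": [0.01] * len(ts),
            "is_differential": [True] * len(ts),
            "degenerate": [False] * len(ts),
        },
        index=[f"f{i}" for i in range(len(ts))],
    )
    return m.DifferentialTable(table, 0.05)


class TestAuc:
    def test_perfect_separation(self):
        assert m.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_worked_four_point_example(self):
        # 3 of the 4 case/control pairs rank correctly -> 0.75
        assert m.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_all_ties_half(self):
        assert m.auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            m.auc([0.1, 0.2], [1, 1])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_matches_roc_integration_oracle(self, seed):
        """Mann–Whitney estimator vs sklearn's trapezoidal ROC area."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        y = np.zeros(n, dtype=int)
        y[: max(1, n // 3)] = 1
        rng.shuffle(y)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        assert m.auc(scores, y) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


class TestRankCandidates:
    def _activity(self, rows, cols, values):
        return ActivityMatrix(
            pd.DataFrame(values, index=rows, columns=cols), pd.DataFrame()
        )

    def test_sorted_by_p_then_abs_t(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(20)]
        lab = m.PhenotypeLabels(
            pd.Series(["case"] * 10 + ["control"] * 10, index=cols)
        )
        # r1 strong effect, r2 weak, r3 none
        vals = np.vstack(
            [
                np.r_[rng.normal(3, 1, 10), rng.normal(0, 1, 10)],
                np.r_[rng.normal(1, 1, 10), rng.normal(0, 1, 10)],
                rng.normal(0, 1, 20),
            ]
        )
        act = self._activity(["r1", "r2", "r3"], cols, vals)
        ranked = m.rank_candidates(act, lab, top_k=2)
        assert ranked == ["r1", "r2"]

    def test_truncation_when_fewer_available(self):
        cols = ["a", "b", "c", "d"]
        lab = m.PhenotypeLabels(
            pd.Series(["case", "case", "control", "control"], index=cols)
        )
        act = self._activity(["r1"], cols, [[1.0, 2.0, 0.0, 0.1]])
        assert m.rank_candidates(act, lab, top_k=20) == ["r1"]


class TestGreedySelect:
    def _setup(self, seed=0, n_feats=6, n=60):
        rng = np.random.default_rng(seed)
        cols = [f"s{i}" for i in range(n)]
        y = np.r_[np.ones(n // 2, dtype=int), np.zeros(n - n // 2, dtype=int)]
        vals = rng.normal(size=(n_feats, n))
        vals[0] += 1.2 * y  # informative
        vals[1] += 0.8 * y
        ids = [f"f{i}" for i in range(n_feats)]
        act = ActivityMatrix(pd.DataFrame(vals, index=ids, columns=cols), pd.DataFrame())
        half = n // 2
        ret_cols = cols[: half // 2] + cols[half : half + half // 2]
        sel_cols = [c for c in cols if c not in set(ret_cols)]
        ret = ActivityMatrix(act.values[ret_cols], pd.DataFrame())
        sel = ActivityMatrix(act.values[sel_cols], pd.DataFrame())
        y_ret = np.array([1 if c in cols[:half] else 0 for c in ret_cols])
        y_sel = np.array([1 if c in cols[:half] else 0 for c in sel_cols])
        return ids, ret, y_ret, sel, y_sel

    def test_first_candidate_always_kept(self):
        ids, ret, y_ret, sel, y_sel = self._setup()
        res = greedy_select(ids, ret, y_ret, sel, y_sel)
        assert res.selected[0] == ids[0]

    def test_accepted_auc_strictly_increasing(self):
        ids, ret, y_ret, sel, y_sel = self._setup(seed=3)
        res = greedy_select(ids, ret, y_ret, sel, y_sel)
        assert all(b > a for a, b in zip(res.selection_auc, res.selection_auc[1:]))

    def test_matches_exhaustive_replay_oracle(self):
        """Replay the accept/reject rule with an independent AUC routine."""
        ids, ret, y_ret, sel, y_sel = self._setup(seed=5)
        res = greedy_select(ids, ret, y_ret, sel, y_sel)
        selected: list[str] = []
        best = -np.inf
        for cand in ids:
            trial = selected + [cand]
            clf = default_classifier()
            clf.fit(ret.as_features(trial), y_ret)
            a = roc_auc_score(y_sel, clf.predict_proba(sel.as_features(trial))[:, 1])
            if not selected or a > best:
                selected, best = trial, a
        assert res.selected == selected

    def test_equal_auc_candidate_removed(self):
        """A duplicated feature cannot strictly improve AUC: rejected."""
        ids, ret, y_ret, sel, y_sel = self._setup(seed=7, n_feats=2)
        ret.values.loc["f1"] = ret.values.loc["f0"]
        sel.values.loc["f1"] = sel.values.loc["f0"]
        res = greedy_select(["f0", "f1"], ret, y_ret, sel, y_sel)
        assert res.selected == ["f0"]


class TestHfSubpathways:
    def test_strictly_above_median(self):
        assert hf_subpathways({"a": 1, "b": 2, "c": 3}) == {"c"}

    def test_all_equal_empty(self):
        assert hf_subpathways({"a": 4, "b": 4, "c": 4}) == set()

    def test_even_count_median_by_hand(self):
        # counts (0,0,10,10): median 5, the two 10s exceed it
        assert hf_subpathways({"a": 0, "b": 0, "c": 10, "d": 10}) == {"c", "d"}


class TestCScore:
    def test_identical_tables_give_one(self):
        d = _diff_from_t([4.0, -2.0, 1.0])
        for n in (1, 2, 3):
            assert m.c_score(d, d, n) == 1.0

    def test_worked_pair(self):
        train = _diff_from_t([4.0, 2.0])
        valid = _diff_from_t([2.0, 1.0])
        assert m.c_score(train, valid, 2) == pytest.approx(2.0)

    def test_uniform_scaling(self):
        train = _diff_from_t([4.0, 2.0, 1.0])
        valid = _diff_from_t([8.0, 4.0, 2.0])
        assert m.c_score(train, valid, 3) == pytest.approx(0.5)

    def test_rank_pairing_sorts_each_side(self):
        train = _diff_from_t([1.0, -4.0])  # |t| sorted: 4, 1
        valid = _diff_from_t([-2.0, 0.5])  # |t| sorted: 2, 0.5
        assert m.c_score(train, valid, 2) == pytest.approx((4 / 2 + 1 / 0.5) / 2)

    def test_insufficient_coverage_rejected(self):
        with pytest.raises(ValueError, match="at least N"):
            m.c_score(_diff_from_t([1.0]), _diff_from_t([1.0, 2.0]), 2)

    def test_ascending_option_pairs_smallest_first(self):
        train = _diff_from_t([4.0, 2.0, 1.0])
        valid = _diff_from_t([3.0, 0.5, 6.0])
        got = m.c_score(train, valid, 2, descending=False)
        assert got == pytest.approx((1.0 / 0.5 + 2.0 / 3.0) / 2)


class TestOverlapSignificance:
    def test_disjoint_sets(self):
        assert m.overlap_significance({"a"}, {"b"}, 10) == 1.0

    def test_full_overlap_enumeration_oracle(self):
        # |a|=|b|=3, universe 10, overlap 3: exhaustive enumeration
        p = m.overlap_significance({"x", "y", "z"}, {"x", "y", "z"}, 10)
        universe = range(10)
        fixed = {0, 1, 2}
        hits = sum(
            1 for c in itertools.combinations(universe, 3) if len(fixed & set(c)) >= 3
        )
        total = len(list(itertools.combinations(universe, 3)))
        assert p == pytest.approx(hits / total)
        assert p == pytest.approx(1 / 120)

    def test_forced_full_overlap(self):
        s = {"a", "b", "c"}
        assert m.overlap_significance(s, s, 3) == pytest.approx(1.0)


class TestProtocols:
    def test_within_cardinality_and_determinism(self, small_cohort):
        _, bundle, net, _ = small_cohort
        r1 = m.evaluate_within(bundle, net, reps=2, folds=5, seed=9)
        r2 = m.evaluate_within(bundle, net, reps=2, folds=5, seed=9)
        assert len(r1.records) == 2 * 5 * 3
        assert r1.to_dict() == r2.to_dict()

    def test_within_different_seed_differs(self, small_cohort):
        _, bundle, net, _ = small_cohort
        r1 = m.evaluate_within(bundle, net, reps=1, folds=5, seed=1)
        r2 = m.evaluate_within(bundle, net, reps=1, folds=5, seed=2)
        assert r1.to_dict() != r2.to_dict()

    def test_cross_cardinality(self, small_cohort):
        cfg, bundle, net, _ = small_cohort
        import dataclasses

        cfg2 = dataclasses.replace(cfg, seed=cfg.seed + 1, signal_seed=cfg.seed)
        pathways = m.simulate_pathways(cfg)
        ge2, me2, lab2, tg2, _ = m.simulate_cohort(cfg2, pathways)
        test_bundle = m.DataBundle(ge2, me2, lab2, tg2)
        rep = m.evaluate_cross(bundle, test_bundle, net, reps=2, seed=3)
        assert len(rep.records) == 2 * 5

    def test_cross_on_self_behaves_like_within(self, small_cohort):
        _, bundle, net, _ = small_cohort
        rep = m.evaluate_cross(bundle, bundle, net, reps=1, seed=4)
        assert len(rep.records) == 5
        assert rep.mean_auc > 0.9  # training cohort as test: near-perfect

    def test_reproducibility_bookkeeping(self, small_cohort):
        _, bundle, net, _ = small_cohort
        r1 = m.reproducibility_within(
            bundle, net, reps=2, folds=5, n_values=(3, 5), seed=5
        )
        r2 = m.reproducibility_within(
            bundle, net, reps=2, folds=5, n_values=(3, 5), seed=5
        )
        assert r1.n_experiments == 10
        assert r1.c_scores == r2.c_scores
        assert all(v > 0 for v in r1.c_scores.values())

    def test_reproducibility_self_consistency_limit(self, small_cohort):
        """Validation == training data drives C toward 1."""
        _, bundle, net, _ = small_cohort
        model = m.fit_activity_model(
            bundle.gene_expr, bundle.mirna_expr, bundle.labels, bundle.targets, net
        )
        act = model.transform(bundle.gene_expr, bundle.sample_ids)
        diff = m.t_scores(
            m.ExpressionMatrix(act.values, "mirna"), bundle.labels
        )
        assert m.c_score(diff, diff, min(5, len(act.subpathway_ids))) == 1.0


class TestDeletionRobustness:
    def test_fraction_zero_reproduces_baseline(self, small_cohort):
        _, bundle, net, _ = small_cohort
        table = m.deletion_robustness(
            bundle, net, "targets", [0.0], seed=1, eval_seed=6, reps=1, folds=5
        )
        base = m.evaluate_within(bundle, net, reps=1, folds=5, seed=6)
        assert table.mean_auc[0] == base.mean_auc
        assert table.mean_accuracy[0] == base.mean_accuracy

    def test_deterministic_under_seed(self, small_cohort):
        _, bundle, net, _ = small_cohort
        kw = dict(seed=2, eval_seed=3, reps=1, folds=5)
        t1 = m.deletion_robustness(bundle, net, "targets", [0.2], **kw)
        t2 = m.deletion_robustness(bundle, net, "targets", [0.2], **kw)
        pd.testing.assert_frame_equal(t1, t2)

    def test_network_deletion_runs(self, small_cohort):
        _, bundle, net, _ = small_cohort
        table = m.deletion_robustness(
            bundle, net, "network", [0.1], seed=4, eval_seed=5, reps=1, folds=5
        )
        assert len(table) == 1
        assert table.flagged[0] or np.isfinite(table.mean_auc[0])


def test_accuracy_threshold():
    assert accuracy([0.9, 0.4, 0.6, 0.1], [1, 0, 1, 0]) == 1.0
    assert accuracy([0.9, 0.6, 0.4, 0.1], [1, 0, 1, 0]) == 0.5
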