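"""Metrics, cross-validation protocol, and harness-closure properties."""

import math

import numpy as np
import pytest
from sklearn.metrics import precision_score, recall_score

from elscore.aggregate import build_score_report
from elscore.core import ItemResponse, SubtestAdministration
from elscore.evaluation import (
    EvalConfig,
    classification_metrics,
    cross_validate,
    spearman_rho,
    subgroup_report,
    tier_mae,
)
from elscore.synthetic import GeneratorConfig, generate_corpus


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        assert classification_metrics([0, 1, 2], [0, 1, 2], "macro") == (1.0, 1.0, 1.0)

    def test_hand_computed_confusion(self):
        acc, prec, rec = classification_metrics([0, 0, 1, 1], [0, 1, 0, 1], "macro")
        assert (acc, prec, rec) == (0.5, 0.5, 0.5)

    @pytest.mark.parametrize("averaging", ["macro", "weighted"])
    def test_matches_sklearn(self, averaging):
        rng = np.random.default_rng(0)
        for _ in range(10):
            gold = rng.integers(0, 4, size=60)
            pred = rng.integers(0, 4, size=60)
            acc, prec, rec = classification_metrics(gold, pred, averaging)
            assert math.isclose(
                prec, precision_score(gold, pred, average=averaging, zero_division=0)
            )
            assert math.isclose(
                rec, recall_score(gold, pred, average=averaging, zero_division=0)
            )
            assert math.isclose(acc, float(np.mean(gold == pred)))

    def test_weighted_recall_equals_accuracy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            gold = rng.integers(0, 3, size=40)
            pred = rng.integers(0, 3, size=40)
            acc, _, rec = classification_metrics(gold, pred, "weighted")
            assert math.isclose(acc, rec)

    def test_macro_invariant_under_relabeling(self):
        gold = [0, 0, 1, 1, 2, 2]
        pred = [0, 1, 1, 2, 2, 0]
        relabel = {0: 2, 1: 0, 2: 1}
        a1 = classification_metrics(gold, pred, "macro")
        a2 = classification_metrics([relabel[g] for g in gold],
                                    [relabel[p] for p in pred], "macro")
        assert a1 == a2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            classification_metrics([0, 1], [0], "macro")

    def test_degradation_monotone_under_label_noise(self):
        """More label noise means lower accuracy and higher item MAE."""
        rng = np.random.default_rng(5)
        gold = rng.integers(0, 3, size=400)

        def noisy(rate, seed):
            r = np.random.default_rng(seed)
            pred = gold.copy()
            flip = r.random(len(gold)) < rate
            pred[flip] = (pred[flip] + 1 + r.integers(0, 2, flip.sum())) % 3
            return pred

        accs, maes = {}, {}
        for rate in (0.1, 0.3):
            a, m = [], []
            for rep in range(20):
                pred = noisy(rate, 100 + rep)
                a.append(classification_metrics(gold, pred, "weighted")[0])
                m.append(float(np.mean(np.abs(gold - pred))))
            accs[rate], maes[rate] = np.mean(a), np.mean(m)
        assert accs[0.1] > accs[0.3]
        assert maes[0.1] < maes[0.3]


class TestSpearman:
    def test_identity_and_reversal(self):
        assert spearman_rho([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0

    def test_single_swap_hand_value(self):
        # d^2 = (0,1,1,0) -> rho = 1 - 6*2/(4*15) = 0.8
        assert math.isclose(spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]), 0.8)

    def test_zero_variance_gives_nan_sentinel(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman_rho([1, 2], [1, 2])


def _reports(raws, toy_table, scores_per_child=None):
    reports = []
    for cid, raw_scores in raws.items():
        admins, scores = [], {}
        for code, item_scores in raw_scores.items():
            items = [ItemResponse(code, i, f"s{i}", "p", "r") for i in range(len(item_scores))]
            admins.append(SubtestAdministration(cid, code, 72, items))
            scores[code] = item_scores
        reports.append(build_score_report(cid, admins, scores, toy_table))
    return reports


class TestTierMae:
    def test_identical_reports_zero_everywhere(self, toy_norm_table):
        raws = {"a": {"FS": [2, 1, 0], "RS": [3, 2, 1], "WS": [1, 1, 0]},
                "b": {"FS": [0, 0, 1], "RS": [1, 1, 1], "WS": [0, 1, 1]}}
        g = _reports(raws, toy_norm_table)
        p = _reports(raws, toy_norm_table)
        for tier in ("item", "raw", "scaled", "eli"):
            assert tier_mae(g, p, tier) == 0.0

    def test_raw_tier_arithmetic(self, toy_norm_table):
        g = _reports({"a": {"FS": [2] * 5}, "b": {"FS": [2] * 10}}, toy_norm_table)
        p = _reports({"a": {"FS": [2] * 4 + [0]}, "b": {"FS": [2] * 10 + [1]}}, toy_norm_table)
        # raws: gold 10,20 vs predicted 8,21 -> mean(|2|,|1|) = 1.5
        assert tier_mae(g, p, "raw") == 1.5

    def test_item_tier_pools_items(self, toy_norm_table):
        gold_items = {"a": {"FS": [1] * 25}, "b": {"FS": [1] * 25}}
        pred_items = {"a": {"FS": [1] * 24 + [2]}, "b": {"FS": [1] * 25}}
        g = _reports(gold_items, toy_norm_table)
        p = _reports(pred_items, toy_norm_table)
        # one of 50 pooled items off by 1 -> 0.02
        assert tier_mae(g, p, "item") == pytest.approx(0.02)

    def test_misaligned_reports_rejected(self, toy_norm_table):
        g = _reports({"a": {"FS": [1, 1]}}, toy_norm_table)
        p = _reports({"b": {"FS": [1, 1]}}, toy_norm_table)
        with pytest.raises(ValueError, match="no predicted report"):
            tier_mae(g, p, "raw")


@pytest.fixture(scope="module")
def corpus():
    cfg = GeneratorConfig(seed=13, n_children=25,
                          items_per_subtest={"EV": 6, "WS": 6, "RS": 6, "FS": 6})
    clean, _ = generate_corpus(cfg)
    return clean


class TestCrossValidate:
    def test_oracle_scorer_is_perfect_at_every_tier(self, default_norm_table):
        # full-length administrations so every tier (incl. ELI) has variance
        clean, _ = generate_corpus(GeneratorConfig(seed=13, n_children=25))
        cfg = EvalConfig(n_folds=5, n_repetitions=1, seed=0)
        rep = cross_validate(clean, "gold_oracle", eval_config=cfg,
                             norm_table=default_norm_table)
        for code in ("EV", "WS", "RS", "FS"):
            assert rep.metric(code, "accuracy")[0] == 1.0
            assert rep.metric(code, "item_mae")[0] == 0.0
            assert rep.metric(code, "raw_mae")[0] == 0.0
            assert rep.metric(code, "scaled_mae")[0] == 0.0
            assert rep.metric(code, "raw_rho")[0] == pytest.approx(1.0)
        assert rep.metric("ELI", "eli_mae")[0] == 0.0
        assert rep.metric("ELI", "eli_rho")[0] == pytest.approx(1.0)

    def test_same_seed_reproduces_report(self, corpus, default_norm_table):
        cfg = EvalConfig(n_folds=3, n_repetitions=2, seed=4)
        r1 = cross_validate(corpus, "lightweight_ngram", eval_config=cfg,
                            norm_table=default_norm_table)
        r2 = cross_validate(corpus, "lightweight_ngram", eval_config=cfg,
                            norm_table=default_norm_table)
        assert r1.per_repetition.equals(r2.per_repetition)

    def test_child_fold_partition_law(self, corpus):
        cfg = EvalConfig(n_folds=5, n_repetitions=2, seed=1)
        rep = cross_validate(corpus, "gold_oracle", eval_config=cfg)
        preds = rep.item_predictions
        for r, grp in preds.groupby("repetition"):
            counts = grp.groupby(["child_id", "subtest", "item_index"]).size()
            assert (counts == 1).all()  # each item scored exactly once per repetition

    def test_too_few_children_rejected(self, default_norm_table):
        cfg = GeneratorConfig(seed=1, n_children=3,
                              items_per_subtest={"EV": 4, "WS": 4, "RS": 4, "FS": 4})
        clean, _ = generate_corpus(cfg)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(clean, "gold_oracle", eval_config=EvalConfig(n_folds=5))

    def test_item_fold_unit_also_partitions(self, corpus):
        cfg = EvalConfig(n_folds=4, n_repetitions=1, seed=2, fold_unit="item")
        rep = cross_validate(corpus, "gold_oracle", eval_config=cfg)
        counts = rep.item_predictions.groupby(
            ["child_id", "subtest", "item_index"]).size()
        assert (counts == 1).all()

    def test_per_subtest_backend_mapping(self, corpus):
        cfg = EvalConfig(n_folds=3, n_repetitions=1, seed=3)
        backends = {"EV": "lightweight_ngram", "WS": "lightweight_ngram",
                    "FS": "lightweight_ngram", "RS": "svm_edit_features"}
        rep = cross_validate(corpus, backends, eval_config=cfg)
        assert set(rep.item_predictions.subtest.unique()) == {"EV", "WS", "RS", "FS"}


class TestSubgroupReport:
    def test_groups_reported_separately_same_predictions(self, default_norm_table):
        cfg = GeneratorConfig(seed=21, n_children=20,
                              items_per_subtest={"EV": 6, "WS": 6, "RS": 6, "FS": 6})
        clean, _ = generate_corpus(cfg)
        groups = {a.group for a in clean}
        assert groups == {"TD", "non-TD"}
        rep = cross_validate(clean, "gold_oracle",
                             eval_config=EvalConfig(n_folds=4, n_repetitions=1, seed=0),
                             norm_table=default_norm_table)
        sub = subgroup_report(rep)
        assert set(sub) == groups
        for g, frame in sub.items():
            acc = frame[(frame.scope == "EV") & (frame.metric == "accuracy")]["mean"].iloc[0]
            assert acc == 1.0  # oracle is perfect in every subgroup

    def test_single_group_matches_unstratified(self, default_norm_table):
        cfg = GeneratorConfig(seed=22, n_children=15, group_probs={"TD": 1.0},
                              items_per_subtest={"EV": 6, "WS": 6, "RS": 6, "FS": 6})
        clean, _ = generate_corpus(cfg)
        rep = cross_validate(clean, "lightweight_ngram",
                             eval_config=EvalConfig(n_folds=3, n_repetitions=1, seed=0),
                             norm_table=default_norm_table)
        sub = subgroup_report(rep)
        assert set(sub) == {"TD"}
        whole = rep.summary().set_index(["scope", "metric"])["mean"]
        part = sub["TD"].set_index(["scope", "metric"])["mean"]
        for key in part.index:
            assert math.isclose(part[key], whole[key], abs_tol=1e-12) or (
                math.isnan(part[key]) and math.isnan(whole[key])
            )
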