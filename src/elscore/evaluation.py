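"""Repeated cross-validated evaluation of the scoring pipeline.

The harness mirrors the standard protocol for this kind of scoring study:
k-fold cross-validation (default 5 folds) repeated over multiple reshuffles
of the data set (default 20), reporting the mean and standard deviation
over repetitions of

* item-level classification accuracy, precision and recall (weighted or
  macro averaging over score classes);
* mean absolute error (MAE) at the item, raw, scaled and composite (ELI)
  tiers, obtained by pushing predicted item scores through the
  aggregation stage;
* Spearman's rank correlation at the same tiers.

Folds partition *children*, not items, so no child contributes to both the
training and test side of a fold (``fold_unit="item"`` reproduces the
laxer alternative).  Per-repetition shuffles use seeds derived as
``seed + repetition``.  Weighted recall is algebraically identical to
accuracy, which is why published tables for this task often show
precision = recall = accuracy; weighted averaging is therefore the
default, with macro available.

Undefined Spearman correlations (zero-variance vectors) are reported as
NaN sentinels and excluded from repetition means; the exclusion count is
kept in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.model_selection import KFold

from .aggregate import build_score_report
from .classifiers import (
    BaseScorer,
    PairExample,
    ScorerSpec,
    TrainConfig,
    fit_scorer,
)
from .core import ScoreReport, SubtestAdministration
from .corpus_io import NormTable

logger = logging.getLogger(__name__)

__all__ = [
    "EvalConfig",
    "EvalReport",
    "classification_metrics",
    "tier_mae",
    "spearman_rho",
    "cross_validate",
    "subgroup_report",
]


@dataclass(frozen=True)
class EvalConfig:
    """Protocol settings for :func:`cross_validate`."""

    n_folds: int = 5
    n_repetitions: int = 20
    averaging: str = "weighted"
    seed: int = 0
    subgroup_key: Optional[str] = None
    ceiling_on: str = "predicted"  # which score stream triggers discontinuation
    fold_unit: str = "child"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.averaging not in ("macro", "weighted"):
            raise ValueError("averaging must be 'macro' or 'weighted'")
        if self.ceiling_on not in ("predicted", "gold"):
            raise ValueError("ceiling_on must be 'predicted' or 'gold'")
        if self.fold_unit not in ("child", "item"):
            raise ValueError("fold_unit must be 'child' or 'item'")


# ---------------------------------------------------------------------------
# metrics


def classification_metrics(
    gold: Sequence[int], predicted: Sequence[int], averaging: str = "weighted"
) -> tuple[float, float, float]:
    """(accuracy, precision, recall) from a per-class confusion matrix.

    Per-class precision/recall are averaged unweighted (``macro``) or
    weighted by gold support (``weighted``); classes absent from both gold
    and predictions are excluded, and an undefined per-class ratio (zero
    denominator) counts as 0.  Weighted recall equals accuracy by the
    support-weighting identity.
    """
    gold = np.asarray(gold)
    predicted = np.asarray(predicted)
    if len(gold) != len(predicted):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(predicted)} predicted")
    if len(gold) == 0:
        raise ValueError("empty inputs")
    classes = sorted(set(gold) | set(predicted))
    acc = float(np.mean(gold == predicted))
    precs, recs, supports = [], [], []
    for c in classes:
        tp = float(np.sum((gold == c) & (predicted == c)))
        pred_c = float(np.sum(predicted == c))
        gold_c = float(np.sum(gold == c))
        precs.append(tp / pred_c if pred_c else 0.0)
        recs.append(tp / gold_c if gold_c else 0.0)
        supports.append(gold_c)
    if averaging == "macro":
        return acc, float(np.mean(precs)), float(np.mean(recs))
    w = np.asarray(supports) / float(len(gold))
    return acc, float(np.dot(w, precs)), float(np.dot(w, recs))


def spearman_rho(gold: Sequence[float], predicted: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Returns NaN (the undefined-correlation sentinel) when either vector
    has zero variance instead of raising.
    """
    gold = np.asarray(gold, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(gold) != len(predicted):
        raise ValueError("length mismatch")
    if len(gold) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(gold) == 0 or np.ptp(predicted) == 0:
        return float("nan")
    return float(spearmanr(gold, predicted).statistic)


def tier_mae(
    gold_reports: Sequence[ScoreReport],
    pred_reports: Sequence[ScoreReport],
    tier: str,
) -> float:
    """Mean absolute error between aligned score reports at one tier.

    ``tier`` is one of ``item`` (pooling all retained items), ``raw``,
    ``scaled`` or ``eli``.  Reports must align by (child, subtest);
    misalignment raises ``ValueError``.
    """
    if tier not in ("item", "raw", "scaled", "eli"):
        raise ValueError(f"unknown tier {tier!r}")
    by_child = {r.child_id: r for r in pred_reports}
    diffs: list[float] = []
    for g in gold_reports:
        p = by_child.get(g.child_id)
        if p is None:
            raise ValueError(f"no predicted report for child {g.child_id!r}")
        if tier == "eli":
            if (g.eli is None) != (p.eli is None):
                raise ValueError(f"ELI present on one side only for {g.child_id!r}")
            if g.eli is not None:
                diffs.append(abs(g.eli - p.eli))
            continue
        for code, gs in g.per_subtest.items():
            if code not in p.per_subtest:
                raise ValueError(f"subtest {code} missing from predicted report {g.child_id!r}")
            ps = p.per_subtest[code]
            if tier == "item":
                if len(gs.item_scores) != len(ps.item_scores):
                    raise ValueError(
                        f"item lists misaligned for {g.child_id!r}/{code}: "
                        f"{len(gs.item_scores)} vs {len(ps.item_scores)}"
                    )
                diffs.extend(abs(a - b) for a, b in zip(gs.item_scores, ps.item_scores))
            elif tier == "raw":
                diffs.append(abs(gs.raw - ps.raw))
            else:
                if (gs.scaled is None) != (ps.scaled is None):
                    raise ValueError(f"scaled present on one side only for {g.child_id!r}/{code}")
                if gs.scaled is not None:
                    diffs.append(abs(gs.scaled - ps.scaled))
    if not diffs:
        raise ValueError(f"no aligned observations at tier {tier!r}")
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# cross-validation


def _mean_sd(values: Sequence[float]) -> tuple[float, float, int]:
    """(mean, sd over repetitions, n excluded NaN)."""
    arr = np.asarray(values, dtype=float)
    ok = arr[~np.isnan(arr)]
    excluded = int(np.isnan(arr).sum())
    if len(ok) == 0:
        return float("nan"), float("nan"), excluded
    sd = float(np.std(ok, ddof=1)) if len(ok) > 1 else 0.0
    return float(np.mean(ok)), sd, excluded


@dataclass
class EvalReport:
    """Cross-validation results: per-repetition values and their summary.

    ``per_repetition`` holds one row per (repetition, subtest-or-ELI,
    metric); ``item_predictions`` one row per scored test item across all
    repetitions; ``child_tiers`` one row per (repetition, child, subtest)
    with gold/predicted raw and scaled plus per-child ELI.  ``summary()``
    tabulates mean +/- SD over repetitions.
    """

    config: EvalConfig
    per_repetition: pd.DataFrame
    item_predictions: pd.DataFrame
    child_tiers: pd.DataFrame
    eli_rows: pd.DataFrame
    subgroups: dict[str, pd.DataFrame] = field(default_factory=dict)

    def metric(self, scope: str, metric: str) -> tuple[float, float, int]:
        """Mean, SD and NaN-exclusion count of one metric over repetitions."""
        sel = self.per_repetition
        vals = sel[(sel.scope == scope) & (sel.metric == metric)].value
        if vals.empty:
            raise KeyError(f"no metric {metric!r} for scope {scope!r}")
        return _mean_sd(vals.tolist())

    def summary(self) -> pd.DataFrame:
        rows = []
        for (scope, metric), grp in self.per_repetition.groupby(["scope", "metric"]):
            mean, sd, excl = _mean_sd(grp.value.tolist())
            rows.append(
                {"scope": scope, "metric": metric, "mean": mean, "sd": sd,
                 "n_repetitions": len(grp), "n_undefined": excl}
            )
        return pd.DataFrame(rows).sort_values(["scope", "metric"]).reset_index(drop=True)


def _folds(children: list[str], n_folds: int, rng: np.random.Generator) -> list[list[str]]:
    order = [children[i] for i in rng.permutation(len(children))]
    kf = KFold(n_splits=n_folds, shuffle=False)
    return [[order[i] for i in test] for _, test in kf.split(order)]


def _resolve_backend(backend: Union[str, Mapping[str, str]], code: str) -> str:
    if isinstance(backend, str):
        return backend
    return backend[code]


def cross_validate(
    admins: Sequence[SubtestAdministration],
    backend: Union[str, Mapping[str, str]],
    train_config: Optional[TrainConfig] = None,
    eval_config: Optional[EvalConfig] = None,
    norm_table: Optional[NormTable] = None,
) -> EvalReport:
    """Run the repeated k-fold protocol over a gold-scored corpus.

    ``backend`` is a backend name or a subtest->backend mapping.  Item
    scores are predicted per fold by a scorer trained only on the other
    folds, then summarized per child through the aggregation stage
    (discontinuation triggered on the ``ceiling_on`` stream), and compared
    with the gold-derived tiers.  The scaled and ELI tiers require a norm
    table.
    """
    train_config = train_config or TrainConfig()
    cfg = eval_config or EvalConfig()
    by_subtest: dict[str, dict[str, SubtestAdministration]] = {}
    for a in admins:
        by_subtest.setdefault(a.subtest, {})[a.child_id] = a
    children = sorted({a.child_id for a in admins})
    for code, group in by_subtest.items():
        if len(group) < cfg.n_folds:
            raise ValueError(
                f"{code}: {len(group)} children < {cfg.n_folds} folds"
            )

    rep_rows: list[dict] = []
    item_rows: list[dict] = []
    tier_rows: list[dict] = []
    eli_rows: list[dict] = []
    for rep in range(cfg.n_repetitions):
        rng = np.random.default_rng(cfg.seed + rep)
        preds: dict[tuple[str, str], list[int]] = {}
        if cfg.fold_unit == "child":
            folds = _folds(children, cfg.n_folds, rng)
            for test_children in folds:
                test_set = set(test_children)
                for code, group in by_subtest.items():
                    train_pairs, _ = _admin_pairs(
                        [a for cid, a in sorted(group.items()) if cid not in test_set]
                    )
                    test_admins = [group[cid] for cid in sorted(test_set) if cid in group]
                    if not test_admins:
                        continue
                    scorer = _fit(code, backend, train_pairs, train_config, cfg, rep)
                    for a in test_admins:
                        pairs = [_pair(it) for it in a.items]
                        preds[(a.child_id, code)] = scorer.predict(pairs)
        else:  # fold_unit == "item": pool items, ignore child boundaries
            for code, group in by_subtest.items():
                all_items = [
                    (a, it) for _, a in sorted(group.items()) for it in a.items
                ]
                idx = rng.permutation(len(all_items))
                kf = KFold(n_splits=cfg.n_folds, shuffle=False)
                item_preds: dict[tuple[str, int], int] = {}
                for tr, te in kf.split(idx):
                    tr_pairs = [_pair(all_items[idx[i]][1]) for i in tr]
                    scorer = _fit(code, backend, tr_pairs, train_config, cfg, rep)
                    te_pairs = [_pair(all_items[idx[i]][1]) for i in te]
                    for i, s in zip(te, scorer.predict(te_pairs)):
                        a, it = all_items[idx[i]]
                        item_preds[(a.child_id, it.item_index)] = s
                for cid, a in group.items():
                    preds[(cid, code)] = [
                        item_preds[(cid, it.item_index)] for it in a.items
                    ]

        # item-level rows
        for (cid, code), scores in preds.items():
            a = by_subtest[code][cid]
            for it, s in zip(a.items, scores):
                item_rows.append(
                    {"repetition": rep, "child_id": cid, "subtest": code,
                     "item_index": it.item_index, "group": a.group,
                     "gold": it.gold_score, "predicted": s}
                )
        # per-child tiers
        gold_reports, pred_reports = _tier_reports(by_subtest, preds, norm_table, cfg)
        for g in gold_reports:
            p = next(r for r in pred_reports if r.child_id == g.child_id)
            grp = next(
                (a.group for a in admins if a.child_id == g.child_id), None
            )
            for code, gs in g.per_subtest.items():
                ps = p.per_subtest[code]
                tier_rows.append(
                    {"repetition": rep, "child_id": g.child_id, "subtest": code,
                     "group": grp, "gold_raw": gs.raw, "pred_raw": ps.raw,
                     "gold_scaled": gs.scaled, "pred_scaled": ps.scaled}
                )
            if g.eli is not None and p.eli is not None:
                eli_rows.append(
                    {"repetition": rep, "child_id": g.child_id, "group": grp,
                     "gold_eli": g.eli, "pred_eli": p.eli}
                )

        rep_rows.extend(
            _repetition_metrics(
                rep,
                pd.DataFrame([r for r in item_rows if r["repetition"] == rep]),
                pd.DataFrame([r for r in tier_rows if r["repetition"] == rep]),
                pd.DataFrame([r for r in eli_rows if r["repetition"] == rep]),
                cfg.averaging,
            )
        )

    report = EvalReport(
        config=cfg,
        per_repetition=pd.DataFrame(rep_rows),
        item_predictions=pd.DataFrame(item_rows),
        child_tiers=pd.DataFrame(tier_rows),
        eli_rows=pd.DataFrame(eli_rows),
    )
    if cfg.subgroup_key:
        report.subgroups = subgroup_report(report)
    return report


def _pair(it) -> PairExample:
    return PairExample(
        subtest=it.subtest, prompt_text=it.prompt_text,
        response_text=it.response_text, label=it.gold_score,
    )


def _admin_pairs(admins) -> tuple[list[PairExample], list]:
    pairs = [_pair(it) for a in admins for it in a.items]
    return pairs, admins


def _fit(code, backend, train_pairs, train_config, cfg, rep) -> BaseScorer:
    spec = ScorerSpec(backend=_resolve_backend(backend, code), subtest=code)
    tc = TrainConfig(
        validation_fraction=train_config.validation_fraction,
        patience_epochs=train_config.patience_epochs,
        l2_weight=train_config.l2_weight,
        max_epochs=train_config.max_epochs,
        learning_rate=train_config.learning_rate,
        batch_size=train_config.batch_size,
        seed=train_config.seed + 7919 * rep,
    )
    scorer, _ = fit_scorer(spec, train_pairs, tc)
    return scorer


def _tier_reports(by_subtest, preds, norm_table, cfg):
    children = sorted({cid for code in by_subtest for cid in by_subtest[code]})
    gold_reports, pred_reports = [], []
    for cid in children:
        admins = [by_subtest[code][cid] for code in by_subtest if cid in by_subtest[code]]
        gold_scores = {a.subtest: [it.gold_score for it in a.items] for a in admins}
        pred_scores = {a.subtest: preds[(cid, a.subtest)] for a in admins}
        gold_reports.append(
            build_score_report(cid, admins, gold_scores, norm_table, scorer_id="gold")
        )
        if cfg.ceiling_on == "gold":
            # truncate predictions where the *gold* stream discontinues
            pred_reports.append(
                _report_with_gold_ceiling(cid, admins, gold_scores, pred_scores, norm_table)
            )
        else:
            pred_reports.append(
                build_score_report(cid, admins, pred_scores, norm_table, scorer_id="predicted")
            )
    return gold_reports, pred_reports


def _report_with_gold_ceiling(cid, admins, gold_scores, pred_scores, norm_table):
    from .aggregate import apply_discontinuation

    truncated = {}
    for a in admins:
        retained_gold, _ = apply_discontinuation(gold_scores[a.subtest], a.subtest)
        truncated[a.subtest] = pred_scores[a.subtest][: len(retained_gold)]
    return build_score_report(
        cid, admins, truncated, norm_table, scorer_id="predicted", apply_ceiling=False
    )


def _repetition_metrics(rep, items, tiers, elis, averaging) -> list[dict]:
    rows = []

    def add(scope, metric, value):
        rows.append({"repetition": rep, "scope": scope, "metric": metric,
                     "value": float(value)})

    for code, grp in items.groupby("subtest"):
        acc, prec, rec = classification_metrics(grp.gold, grp.predicted, averaging)
        add(code, "accuracy", acc)
        add(code, "precision", prec)
        add(code, "recall", rec)
        add(code, "item_mae", np.mean(np.abs(grp.gold - grp.predicted)))
        add(code, "item_rho", spearman_rho(grp.gold, grp.predicted))
    for code, grp in tiers.groupby("subtest"):
        add(code, "raw_mae", np.mean(np.abs(grp.gold_raw - grp.pred_raw)))
        add(code, "raw_rho", spearman_rho(grp.gold_raw, grp.pred_raw))
        if grp.gold_scaled.notna().all():
            add(code, "scaled_mae", np.mean(np.abs(grp.gold_scaled - grp.pred_scaled)))
            add(code, "scaled_rho", spearman_rho(grp.gold_scaled, grp.pred_scaled))
    if len(elis):
        add("ELI", "eli_mae", np.mean(np.abs(elis.gold_eli - elis.pred_eli)))
        add("ELI", "eli_rho", spearman_rho(elis.gold_eli, elis.pred_eli))
    return rows


def subgroup_report(report: EvalReport, subgroup_key: str = "group") -> dict[str, pd.DataFrame]:
    """Per-group metric summaries over the same predictions (no re-training).

    Groups come from the administrations' group tags carried through the
    report frames.  Groups with zero test items are omitted with a logged
    warning.  Returns ``{group: summary DataFrame}``.
    """
    out: dict[str, pd.DataFrame] = {}
    groups = [g for g in report.item_predictions["group"].dropna().unique()]
    if not groups:
        logger.warning("no subgroup tags present; returning empty subgroup report")
        return out
    for g in groups:
        items = report.item_predictions[report.item_predictions.group == g]
        tiers = report.child_tiers[report.child_tiers.group == g]
        elis = report.eli_rows[report.eli_rows.group == g] if len(report.eli_rows) else report.eli_rows
        if items.empty:
            logger.warning("subgroup %r has no test items; omitted", g)
            continue
        rows = []
        for rep, rep_items in items.groupby("repetition"):
            rep_tiers = tiers[tiers.repetition == rep] if len(tiers) else tiers
            rep_elis = elis[elis.repetition == rep] if len(elis) else elis
            rows.extend(
                _repetition_metrics(rep, rep_items, rep_tiers, rep_elis,
                                    report.config.averaging)
            )
        per_rep = pd.DataFrame(rows)
        summaries = []
        for (scope, metric), grp in per_rep.groupby(["scope", "metric"]):
            mean, sd, excl = _mean_sd(grp.value.tolist())
            summaries.append({"scope": scope, "metric": metric, "mean": mean,
                              "sd": sd, "n_undefined": excl})
        out[g] = pd.DataFrame(summaries).sort_values(["scope", "metric"]).reset_index(drop=True)
    return out
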