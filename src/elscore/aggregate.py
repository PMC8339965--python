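"""Multi-tier score aggregation: item scores -> raw -> scaled -> ELI.

This is the deterministic stage that summarizes item-level scores according
to conventional administration rules:

* a subtest is discontinued at the item completing the first run of
  ``discontinuation_run`` consecutive zero scores (7 for EV, 5 for FS and
  RS; WS has no rule) — items after the run are dropped, not zero-filled;
* the raw score is the sum of retained item scores;
* raw scores convert to age-normed scaled scores (1-19) via a lookup table;
* the FS + RS + WS scaled scores sum into the Expressive Language Index
  (45-155) via a second lookup.  EV never contributes to the composite.

Whether the zero run is detected on predicted scores (fully automatic
scoring) or on gold scores (replicating the manual administration) is a
caller choice (``ceiling_on``); reverse/basal starting rules are not
modelled.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .core import SUBTESTS, ScoreReport, SubtestAdministration, SubtestScores
from .corpus_io import NormTable

__all__ = [
    "apply_discontinuation",
    "raw_score",
    "scaled_score",
    "eli_composite",
    "aggregate_subtest",
    "build_score_report",
]

ELI_SUBTESTS = ("FS", "RS", "WS")


def apply_discontinuation(
    item_scores: Sequence[int], subtest: str
) -> tuple[list[int], Optional[int]]:
    """Truncate an ordered score list at the discontinuation point.

    Returns ``(retained_scores, discontinued_at)`` where ``discontinued_at``
    is the 0-based index of the item completing the first run of the
    subtest's required consecutive zeros, or ``None`` if the rule never
    fires (or the subtest has no rule).
    """
    sub = SUBTESTS[subtest]
    bad = [s for s in item_scores if s not in sub.score_classes]
    if bad:
        raise ValueError(f"{subtest}: scores {bad} outside classes {sub.score_classes}")
    run_needed = sub.discontinuation_run
    if run_needed is None:
        return list(item_scores), None
    run = 0
    for i, s in enumerate(item_scores):
        run = run + 1 if s == 0 else 0
        if run == run_needed:
            return list(item_scores[: i + 1]), i
    return list(item_scores), None


def raw_score(retained_scores: Iterable[int]) -> int:
    """Sum of retained item scores."""
    return int(sum(retained_scores))


def scaled_score(raw: int, age_months: int, subtest: str, table: NormTable) -> int:
    """Age-normed scaled score (1-19) for a raw score via the lookup table.

    Raises :class:`~elscore.corpus_io.NormTableError` naming the gap when
    the table does not cover the (subtest, age, raw) combination.
    """
    return table.scaled_lookup(subtest, age_months, raw)


def eli_composite(scaled_fs: int, scaled_rs: int, scaled_ws: int, table: NormTable) -> int:
    """Expressive Language Index from the FS+RS+WS scaled-score sum."""
    for name, s in (("FS", scaled_fs), ("RS", scaled_rs), ("WS", scaled_ws)):
        if not 1 <= s <= 19:
            raise ValueError(f"{name} scaled score {s} outside 1-19")
    return table.eli_lookup(scaled_fs + scaled_rs + scaled_ws)


def aggregate_subtest(
    item_scores: Sequence[int],
    subtest: str,
    age_months: int,
    table: Optional[NormTable] = None,
    *,
    apply_ceiling: bool = True,
) -> SubtestScores:
    """Item scores -> (retained, raw, scaled) for one child x subtest.

    ``apply_ceiling=False`` scores every administered item (research use);
    the scaled tier is omitted when no norm table is supplied.
    """
    if apply_ceiling:
        retained, disc = apply_discontinuation(item_scores, subtest)
    else:
        retained, disc = list(item_scores), None
    raw = raw_score(retained)
    scaled = None
    if table is not None:
        scaled = scaled_score(raw, age_months, subtest, table)
    return SubtestScores(item_scores=retained, discontinued_at=disc, raw=raw, scaled=scaled)


def build_score_report(
    child_id: str,
    admins: Sequence[SubtestAdministration],
    item_scores: dict[str, Sequence[int]],
    table: Optional[NormTable] = None,
    *,
    scorer_id: str = "gold",
    apply_ceiling: bool = True,
) -> ScoreReport:
    """Assemble the full multi-tier report for one child.

    ``item_scores`` maps subtest code to the ordered item scores to
    aggregate (predicted or gold).  The ELI composite is attached iff
    scaled scores exist for all of FS, RS and WS.
    """
    per: dict[str, SubtestScores] = {}
    for admin in admins:
        if admin.child_id != child_id:
            raise ValueError(f"administration for {admin.child_id!r}, expected {child_id!r}")
        scores = item_scores[admin.subtest]
        per[admin.subtest] = aggregate_subtest(
            scores, admin.subtest, admin.age_months, table, apply_ceiling=apply_ceiling
        )
    eli = None
    if table is not None and all(
        c in per and per[c].scaled is not None for c in ELI_SUBTESTS
    ):
        eli = eli_composite(
            per["FS"].scaled, per["RS"].scaled, per["WS"].scaled, table
        )
    return ScoreReport(child_id=child_id, per_subtest=per, eli=eli, scorer_id=scorer_id)
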