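"""Domain model for expressive-language subtest scoring.

Four subtests are modelled, mirroring the standard clinical battery design:

``EV``
    Expressive Vocabulary — confrontation naming of a pictured object.
    Item scores 0/1/2 (no credit / partial credit, e.g. "fruit" for "lime" /
    full credit).  Administration stops after 7 consecutive zeros.
``WS``
    Word Structure — complete a sentence frame with an inflected form.
    Binary 0/1, no discontinuation rule.
``RS``
    Recalling Sentences — repeat a heard sentence verbatim.  Scored 0–3 from
    the number of errors (omissions, substitutions, additions); repetitions
    are never counted as errors.  Stops after 5 consecutive zeros.
``FS``
    Formulated Sentences — produce a sentence using a target word.  Scored
    0/1/2; stops after 5 consecutive zeros.

Raw scores (sums of item scores) are later converted to age-normed scaled
scores (1–19, mean 10, SD 3); the FS+RS+WS scaled scores feed a composite
Expressive Language Index (45–155, mean 100, SD 15).  Those stages live in
:mod:`elscore.aggregate` and :mod:`elscore.norms`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "Subtest",
    "SUBTESTS",
    "SUBTEST_CODES",
    "ItemResponse",
    "SubtestAdministration",
    "SubtestScores",
    "ScoreReport",
    "Violation",
    "validate_administration",
]


@dataclass(frozen=True)
class Subtest:
    """Static description of one subtest.

    Parameters
    ----------
    code : str
        One of ``EV``, ``WS``, ``RS``, ``FS``.
    score_classes : tuple of int
        Permitted item scores, ascending.
    discontinuation_run : int or None
        Number of consecutive zero item scores that ends the administration
        (``None`` means no discontinuation rule applies).
    max_items : int
        Number of stimuli in a full administration.  The raw-score scale is
        ``0 .. max(score_classes) * max_items``.
    """

    code: str
    score_classes: tuple[int, ...]
    discontinuation_run: Optional[int]
    max_items: int

    @property
    def n_classes(self) -> int:
        return len(self.score_classes)

    @property
    def raw_max(self) -> int:
        return max(self.score_classes) * self.max_items


#: The four subtests with their published scoring structure.  ``max_items``
#: is derived from the raw-score scale divided by the maximum item score
#: (EV 54/2, FS 48/2, RS 96/3, WS 32/1); pass a custom :class:`Subtest` to
#: the generator or aggregator to override item counts.
SUBTESTS: Mapping[str, Subtest] = {
    "EV": Subtest("EV", (0, 1, 2), 7, 27),
    "WS": Subtest("WS", (0, 1), None, 32),
    "RS": Subtest("RS", (0, 1, 2, 3), 5, 32),
    "FS": Subtest("FS", (0, 1, 2), 5, 24),
}

SUBTEST_CODES: tuple[str, ...] = tuple(SUBTESTS)

TRANSCRIPT_KINDS = ("clean", "verbatim")


@dataclass
class ItemResponse:
    """One stimulus/response pair.

    ``prompt_text`` is the target word (EV), sentence frame (WS), target
    sentence (RS) or target word with scene (FS).  ``response_text`` may be
    empty — a non-response is legal and scores 0 under every scorer.
    ``transcript_kind`` distinguishes the examiner's *clean* transcript
    (scored response only) from the *verbatim* transcript (everything the
    child said, including prefatory chatter).
    """

    subtest: str
    item_index: int
    stimulus_id: str
    prompt_text: str
    response_text: str
    transcript_kind: str = "clean"
    gold_score: Optional[int] = None
    extra: dict = field(default_factory=dict)


@dataclass
class SubtestAdministration:
    """Ordered item responses for one child on one subtest.

    Item order is administration order; discontinuation semantics depend on
    it, so order is part of the data model.  ``group`` is an optional
    free-form tag (e.g. "TD" / "non-TD") used only for stratified
    evaluation reporting.
    """

    child_id: str
    subtest: str
    age_months: int
    items: list[ItemResponse]
    group: Optional[str] = None

    def gold_scores(self) -> list[Optional[int]]:
        return [it.gold_score for it in self.items]


@dataclass
class SubtestScores:
    """Scored tiers for one child x subtest."""

    item_scores: list[int]
    discontinued_at: Optional[int]
    raw: int
    scaled: Optional[int] = None


@dataclass
class ScoreReport:
    """Item, raw, scaled and composite scores for one child.

    The Expressive Language Index (``eli``) is present iff scaled scores
    exist for all of FS, RS and WS; EV never contributes to it.
    ``scorer_id`` records which scorer produced the item scores.
    """

    child_id: str
    per_subtest: dict[str, SubtestScores]
    eli: Optional[int] = None
    scorer_id: str = "gold"


@dataclass(frozen=True)
class Violation:
    """One invariant violation, naming the offending field and rule."""

    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


def validate_administration(admin: SubtestAdministration) -> list[Violation]:
    """Check a :class:`SubtestAdministration` against the model invariants.

    Returns an empty list iff the administration is well formed; violations
    are returned, never raised.
    """
    out: list[Violation] = []
    if admin.subtest not in SUBTESTS:
        out.append(Violation("subtest", f"unknown subtest code {admin.subtest!r}"))
        return out
    sub = SUBTESTS[admin.subtest]
    if admin.age_months < 0:
        out.append(Violation("age_months", "must be non-negative"))
    for pos, item in enumerate(admin.items):
        where = f"items[{pos}]"
        if item.subtest != admin.subtest:
            out.append(
                Violation(
                    f"{where}.subtest",
                    f"item subtest {item.subtest!r} differs from "
                    f"administration subtest {admin.subtest!r}",
                )
            )
        if item.item_index != pos:
            out.append(
                Violation(
                    f"{where}.item_index",
                    f"expected consecutive index {pos}, got {item.item_index} "
                    "(indices must run 0..n-1 without gaps)",
                )
            )
        if not item.prompt_text:
            out.append(Violation(f"{where}.prompt_text", "must be non-empty"))
        if item.transcript_kind not in TRANSCRIPT_KINDS:
            out.append(
                Violation(
                    f"{where}.transcript_kind",
                    f"must be one of {TRANSCRIPT_KINDS}, got {item.transcript_kind!r}",
                )
            )
        if item.gold_score is not None and item.gold_score not in sub.score_classes:
            out.append(
                Violation(
                    f"{where}.gold_score",
                    f"{item.gold_score} not in score classes "
                    f"{set(sub.score_classes)} for {sub.code}",
                )
            )
    return out


def validate_corpus(admins: Iterable[SubtestAdministration]) -> list[Violation]:
    """Validate every administration; violations are prefixed by child/subtest."""
    out: list[Violation] = []
    for admin in admins:
        for v in validate_administration(admin):
            out.append(Violation(f"{admin.child_id}/{admin.subtest}.{v.field}", v.rule))
    return out
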