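"""Deterministic scoring of Recalling Sentences responses.

The scored quantity is the number of word-level errors a child makes when
repeating a target sentence: omissions (deleted words), substitutions and
additions (inserted words).  Adjacent repeated words ("the the quick fox")
are disfluencies, not errors, and are collapsed away before alignment.

The alignment is a word-level Levenshtein dynamic programme with unit costs
that reports *operation counts*, not just a distance — the counts are also
the feature vector of the RS baseline classifier, so tie-breaking among
minimum-cost alignments is part of the contract: the backtrace prefers the
diagonal move (match/substitution), then the vertical move (insertion,
consuming a response word), then the horizontal move (deletion, consuming a
target word).

Transpositions are not a primitive edit: a swapped adjacent pair surfaces as
two substitutions under the unit-cost alignment.  An optional swap-cost-1
variant (Damerau-style) can be enabled with ``allow_transpositions=True``
but is off by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "EditOpCounts",
    "RsScoreMap",
    "DEFAULT_RS_SCORE_MAP",
    "normalize_tokens",
    "collapse_repetitions",
    "align",
    "rs_item_score",
    "rs_features",
]

_TOKEN_RE = re.compile(r"[a-z0-9']+")


@dataclass(frozen=True)
class EditOpCounts:
    """Operation counts from a minimum-cost target/response alignment.

    Invariants: ``total_errors == insertions + deletions + substitutions``;
    ``correct + deletions + substitutions`` equals the target length and
    ``correct + insertions + substitutions`` the (repetition-collapsed)
    response length.
    """

    insertions: int
    deletions: int
    substitutions: int
    correct: int

    @property
    def total_errors(self) -> int:
        return self.insertions + self.deletions + self.substitutions

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.insertions, self.deletions, self.substitutions, self.correct)


@dataclass(frozen=True)
class RsScoreMap:
    """Error-count -> item-score mapping for sentence recall.

    ``thresholds`` is an ordered list of ``(max_errors_inclusive, score)``
    pairs, descending in score, with an implicit open-ended final tier
    scoring 0.  The published task states the 0-3 scale but not the
    thresholds; the default follows the standard sentence-recall convention
    (0 errors -> 3, 1 -> 2, 2-3 -> 1, >=4 -> 0) and is user-overridable.
    """

    thresholds: tuple[tuple[int, int], ...] = ((0, 3), (1, 2), (3, 1))

    def __post_init__(self) -> None:
        scores = [s for _, s in self.thresholds] + [0]
        if sorted(scores, reverse=True) != scores or len(set(scores)) != len(scores):
            raise ValueError("score map scores must be strictly descending and end at 0")
        bounds = [t for t, _ in self.thresholds]
        if sorted(bounds) != bounds or len(set(bounds)) != len(bounds):
            raise ValueError("error thresholds must be strictly increasing")

    def score(self, total_errors: int) -> int:
        for max_err, score in self.thresholds:
            if total_errors <= max_err:
                return score
        return 0

    def errors_for_score(self, score: int) -> tuple[int, Optional[int]]:
        """Inclusive error-count interval ``(lo, hi)`` yielding ``score``.

        ``hi`` is ``None`` for the open-ended 0 tier.
        """
        lo = 0
        for max_err, s in self.thresholds:
            if s == score:
                return lo, max_err
            lo = max_err + 1
        if score == 0:
            return lo, None
        raise KeyError(f"score {score} not produced by this map")


DEFAULT_RS_SCORE_MAP = RsScoreMap()


def normalize_tokens(text: str) -> list[str]:
    """Lowercase, strip punctuation, and whitespace-tokenize.

    Internal apostrophes are kept ("I'm" -> "i'm"); leading/trailing
    apostrophes are stripped.
    """
    return [t.strip("'") for t in _TOKEN_RE.findall(text.lower()) if t.strip("'")]


def collapse_repetitions(tokens: Sequence[str]) -> list[str]:
    """Reduce maximal runs of identical adjacent tokens to one token.

    Only adjacent identical tokens collapse; non-adjacent duplicates (which
    may be genuine content, "a b a") are untouched.  Run collapse is
    idempotent, so a single pass reaches the fixpoint.
    """
    out: list[str] = []
    for tok in tokens:
        if not out or out[-1] != tok:
            out.append(tok)
    return out


def align(
    response_tokens: Sequence[str],
    target_tokens: Sequence[str],
    *,
    allow_transpositions: bool = False,
) -> EditOpCounts:
    """Minimum-edit-cost alignment of response against target, with counts.

    Unit costs for insertion (extra response word), deletion (omitted target
    word) and substitution.  With ``allow_transpositions`` an adjacent swap
    costs 1 and is counted as one substitution-pair error (reported as 1
    substitution + 1 correct is *not* done; the swap contributes 1 to
    ``substitutions`` and both words leave the correct count).
    """
    r, t = list(response_tokens), list(target_tokens)
    m, n = len(r), len(t)
    # D[i][j] = min cost aligning r[:i] with t[:j]
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        D[i][0] = i
    for j in range(1, n + 1):
        D[0][j] = j
    for i in range(1, m + 1):
        ri = r[i - 1]
        for j in range(1, n + 1):
            sub = D[i - 1][j - 1] + (0 if ri == t[j - 1] else 1)
            ins = D[i - 1][j] + 1
            dele = D[i][j - 1] + 1
            best = min(sub, ins, dele)
            if (
                allow_transpositions
                and i > 1
                and j > 1
                and ri == t[j - 2]
                and r[i - 2] == t[j - 1]
                and ri != r[i - 2]
            ):
                best = min(best, D[i - 2][j - 2] + 1)
            D[i][j] = best
    # Deterministic backtrace: diagonal, up (insertion), left (deletion).
    i, j = m, n
    ins = dele = subs = corr = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            cost = 0 if r[i - 1] == t[j - 1] else 1
            if D[i][j] == D[i - 1][j - 1] + cost:
                if cost == 0:
                    corr += 1
                else:
                    subs += 1
                i, j = i - 1, j - 1
                continue
        if (
            allow_transpositions
            and i > 1
            and j > 1
            and r[i - 1] == t[j - 2]
            and r[i - 2] == t[j - 1]
            and r[i - 1] != r[i - 2]
            and D[i][j] == D[i - 2][j - 2] + 1
        ):
            subs += 1
            i, j = i - 2, j - 2
            continue
        if i > 0 and D[i][j] == D[i - 1][j] + 1:
            ins += 1
            i -= 1
            continue
        dele += 1
        j -= 1
    return EditOpCounts(insertions=ins, deletions=dele, substitutions=subs, correct=corr)


def _prepare(response_text: str, target_text: str) -> tuple[list[str], list[str]]:
    resp = collapse_repetitions(normalize_tokens(response_text))
    targ = normalize_tokens(target_text)
    return resp, targ


def rs_item_score(
    response_text: str,
    target_text: str,
    score_map: RsScoreMap = DEFAULT_RS_SCORE_MAP,
    *,
    allow_transpositions: bool = False,
) -> int:
    """Rule-based RS item score: normalize, collapse repetitions, align, map.

    An empty response aligns as all-deletions and falls in the open-ended
    0 tier for any target of >= 4 words under the default map.
    """
    resp, targ = _prepare(response_text, target_text)
    counts = align(resp, targ, allow_transpositions=allow_transpositions)
    return score_map.score(counts.total_errors)


def rs_features(response_text: str, target_text: str) -> tuple[int, int, int, int]:
    """Alignment-count feature vector (insertions, deletions, substitutions, correct).

    This is the hand-crafted correctness representation used by the RS
    baseline classifier.
    """
    resp, targ = _prepare(response_text, target_text)
    return align(resp, targ).as_tuple()
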