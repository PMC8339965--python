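"""Synthetic transcript corpora with construction-time gold scores.

No child-speech corpus can be shipped (such data is protected), so this
module generates prompt/response transcripts whose *scoring-relevant*
structure matches the real task, with gold item scores that are correct by
construction:

* EV/WS/FS responses are drawn from stimulus-specific banks of exemplar
  responses pre-labelled with each score class (e.g. the full-credit name,
  a not-specific-enough category word for partial credit, an unrelated
  word for no credit);
* RS responses are built from the target sentence by injecting exactly
  ``k`` scored errors, where ``k`` maps to the gold score under the
  configured error->score map; uncounted adjacent repetitions may be
  injected on top and never change the gold score (the generator
  re-verifies every response against the rule scorer and re-samples on
  accidental collisions);
* each item exists in a *clean* variant (the scored response only) and a
  *verbatim* variant that may add prefatory/trailing chatter ("i think
  that one's a ..."); the two variants always share the gold score;
* with ``zero_run_prob`` > 0 some children enter a terminal all-zero run,
  exercising the discontinuation rules downstream.

Linguistic realism is a non-goal: vocabulary comes from small built-in
word lists, and scorers only ever see token patterns.  Transpositions are
generated as adjacent swaps and count as 2 scored errors under the default
(substitution-pair) alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import SUBTESTS, ItemResponse, SubtestAdministration
from .norms import DEFAULT_SCORE_DISTRIBUTIONS
from .rs_edit import (
    DEFAULT_RS_SCORE_MAP,
    RsScoreMap,
    align,
    collapse_repetitions,
    normalize_tokens,
    rs_item_score,
)

__all__ = [
    "GeneratorConfig",
    "Stimulus",
    "build_stimulus_bank",
    "inject_rs_errors",
    "generate_corpus",
]

# ---------------------------------------------------------------------------
# word material.  The class pools are disjoint by construction so that the
# score classes of a stimulus use disjoint exemplar vocabularies.

_NOUNS = (
    "pirate lime ship garden puppy ladder violin anchor basket candle doctor "
    "engine feather guitar hammer island jacket kitten lantern mirror needle "
    "orange pencil quilt rabbit saddle teapot wagon zebra bridge castle "
    "dragon helmet marble"
).split()

_CATEGORIES = (
    "fruit animal toy tool vehicle instrument plant food building person "
    "machine clothing furniture container liquid insect flower metal game "
    "shape sound color number weather place drink bird fish sport room "
    "street light paper music"
).split()

_UNRELATED = (
    "sky cloud seven yesterday happy blue loud soft maybe never tomorrow "
    "green quiet early eight sunny cold warm round heavy empty slow little "
    "big old new far near high low wrong left right"
).split()

_VERBS = [
    ("fix", "fixed"), ("open", "opened"), ("wash", "washed"), ("climb", "climbed"),
    ("paint", "painted"), ("plant", "planted"), ("pull", "pulled"), ("push", "pushed"),
    ("cook", "cooked"), ("clean", "cleaned"), ("play", "played"), ("jump", "jumped"),
    ("walk", "walked"), ("talk", "talked"), ("kick", "kicked"), ("lift", "lifted"),
    ("carry", "carried"), ("brush", "brushed"), ("fold", "folded"), ("pour", "poured"),
    ("stack", "stacked"), ("mend", "mended"), ("tie", "tied"), ("wrap", "wrapped"),
    ("hug", "hugged"), ("share", "shared"), ("trace", "traced"), ("count", "counted"),
    ("spell", "spelled"), ("draw", "drew"), ("build", "built"), ("ride", "rode"),
    ("drive", "drove"), ("sing", "sang"),
]

_FS_TARGETS = (
    "because safely quickly before after until unless carefully slowly "
    "together finally suddenly outside between during although instead "
    "almost nearly everywhere sometimes always beside behind across toward"
).split()

_RS_ADJ = "small tall sleepy friendly busy hungry tiny gentle brave curious".split()
_RS_NOUN = "boy girl teacher farmer baker nurse sailor painter dancer singer".split()
_RS_VERB = "found washed carried painted opened followed watched helped moved chased".split()
_RS_OBJ = "book ball kite drum wagon basket ladder bucket ribbon bottle".split()
_RS_PLACE = "school kitchen meadow harbor market library attic bakery station bridge".split()

#: Nonword junk tokens for injected insertions/substitutions; guaranteed
#: never to occur in any target sentence.
_JUNK = "zog blick frop quim snerb plof trang wug dax fep gorp lirk mib vop".split()

_CHATTER_PRE = [
    "i think that one's a",
    "um it's a",
    "maybe it's",
    "let me see",
    "i guess it's",
    "that looks like",
    "um i think it was",
]
_CHATTER_POST = ["i think", "or something", "yeah", "right"]


@dataclass(frozen=True)
class Stimulus:
    """One prompt with >=1 exemplar response per score class."""

    stimulus_id: str
    prompt_text: str
    exemplars: Mapping[int, tuple[str, ...]]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic corpus.

    ``score_distributions`` sets the per-subtest probability of each item
    score (before any terminal zero run); ``chatter_prob`` the chance a
    verbatim response gains filler; ``rs_error_mix`` the split of injected
    RS errors over (insertion, deletion, substitution);
    ``rs_repetition_prob`` the chance of an injected uncounted repetition;
    ``zero_run_prob`` the chance a child enters a terminal all-zero run.
    The seed fully determines the output.
    """

    seed: int = 0
    n_children: int = 100
    subtests: tuple[str, ...] = ("EV", "WS", "RS", "FS")
    items_per_subtest: Optional[Mapping[str, int]] = None
    score_distributions: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_DISTRIBUTIONS)
    )
    chatter_prob: float = 0.5
    rs_error_mix: tuple[float, float, float] = (0.30, 0.35, 0.35)
    rs_repetition_prob: float = 0.20
    zero_run_prob: float = 0.15
    age_range_months: tuple[int, int] = (60, 120)
    group_probs: Mapping[str, float] = field(
        default_factory=lambda: {"TD": 0.43, "non-TD": 0.57}
    )
    score_map: RsScoreMap = DEFAULT_RS_SCORE_MAP

    def __post_init__(self) -> None:
        for name, vec in [
            ("rs_error_mix", self.rs_error_mix),
            ("group_probs", tuple(self.group_probs.values())),
        ] + [(f"score_distributions[{c}]", v) for c, v in self.score_distributions.items()]:
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, sums to {sum(vec)}")
        if not 0 <= self.chatter_prob <= 1:
            raise ValueError("chatter_prob must be a probability")

    def n_items(self, code: str) -> int:
        if self.items_per_subtest and code in self.items_per_subtest:
            return int(self.items_per_subtest[code])
        return SUBTESTS[code].max_items


# ---------------------------------------------------------------------------
# stimulus banks


def build_stimulus_bank(subtest: str, n_stimuli: int, seed: int) -> list[Stimulus]:
    """Deterministic bank of stimuli with per-class exemplar responses.

    Exemplars for distinct score classes of one stimulus are distinct
    strings, and the vocabularies of different classes are drawn from
    disjoint pools.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    rng = np.random.default_rng(seed)
    stimuli: list[Stimulus] = []
    if subtest == "EV":
        nouns = _cycle_pick(_NOUNS, n_stimuli, rng)
        cats = _cycle_pick(_CATEGORIES, n_stimuli, rng)
        unrel = _cycle_pick(_UNRELATED, n_stimuli, rng)
        for i in range(n_stimuli):
            target, cat, u = nouns[i], cats[i], unrel[i]
            stimuli.append(
                Stimulus(
                    stimulus_id=f"EV{i:03d}",
                    prompt_text=target,
                    exemplars={
                        2: (target, f"a {target}"),
                        1: (cat, f"some kind of {cat}"),
                        0: (u, f"{u} thing"),
                    },
                )
            )
    elif subtest == "WS":
        verbs = _cycle_pick(_VERBS, n_stimuli, rng)
        nouns = _cycle_pick(_NOUNS, n_stimuli, rng)
        for i in range(n_stimuli):
            stem, past = verbs[i]
            noun = nouns[i]
            prompt = (
                f"the woman is {stem}ing the {noun} ; "
                f"here is the {noun} that the woman"
            )
            stimuli.append(
                Stimulus(
                    stimulus_id=f"WS{i:03d}",
                    prompt_text=prompt,
                    exemplars={1: (past,), 0: (stem, f"{stem}ing")},
                )
            )
    elif subtest == "FS":
        targets = _cycle_pick(_FS_TARGETS, n_stimuli, rng)
        for i in range(n_stimuli):
            t = targets[i]
            stimuli.append(
                Stimulus(
                    stimulus_id=f"FS{i:03d}",
                    prompt_text=t,
                    exemplars={
                        2: (
                            f"the students worked {t} in our classroom",
                            f"my friend smiled {t} at recess",
                        ),
                        1: (f"doing things {t}", f"{t} it happened"),
                        0: ("dunno really", "banana banana banana"),
                    },
                )
            )
    elif subtest == "RS":
        combos = _distinct_tuples(
            (_RS_ADJ, _RS_NOUN, _RS_VERB, _RS_OBJ, _RS_PLACE), n_stimuli, rng
        )
        for i, (adj, noun, verb, obj, place) in enumerate(combos):
            target = f"the {adj} {noun} {verb} the {obj} near the {place}"
            ex: dict[int, tuple[str, ...]] = {}
            toks = normalize_tokens(target)
            score_map = DEFAULT_RS_SCORE_MAP
            for score in SUBTESTS["RS"].score_classes:
                lo, hi = score_map.errors_for_score(score)
                k = lo if hi is None else lo
                resp = inject_rs_errors(toks, k, (0.3, 0.35, 0.35), 0.0, rng)
                ex[score] = (" ".join(resp),)
            stimuli.append(
                Stimulus(stimulus_id=f"RS{i:03d}", prompt_text=target, exemplars=ex)
            )
    else:
        raise ValueError(f"unknown subtest {subtest!r}")
    return stimuli


def _cycle_pick(pool: Sequence, n: int, rng: np.random.Generator) -> list:
    """n items from pool in a seeded order, cycling if n exceeds the pool."""
    reps = -(-n // len(pool))
    out = []
    for _ in range(reps):
        out.extend(pool[int(i)] for i in rng.permutation(len(pool)))
    return out[:n]


def _distinct_tuples(pools: tuple[Sequence, ...], n: int, rng: np.random.Generator) -> list[tuple]:
    seen: set[tuple] = set()
    out: list[tuple] = []
    while len(out) < n:
        combo = tuple(pool[int(rng.integers(len(pool)))] for pool in pools)
        if combo not in seen:
            seen.add(combo)
            out.append(combo)
    return out


# ---------------------------------------------------------------------------
# RS error injection


def inject_rs_errors(
    target_tokens: Sequence[str],
    k_errors: int,
    mix: tuple[float, float, float],
    repetition_prob: float,
    rng: np.random.Generator | int,
) -> list[str]:
    """Build a response containing exactly ``k_errors`` scored errors.

    ``mix`` weights (insertion, deletion, substitution).  Injected junk
    tokens come from a nonword list disjoint from all targets.  After
    injection, uncounted adjacent repetitions are added with
    ``repetition_prob`` per response; the result is re-verified against the
    alignment (post repetition-collapse) and re-sampled on accidental
    collisions (e.g. a deletion that fuses two identical words).  Raises
    ``ValueError`` when ``k_errors`` is unachievable (deletion-only mix
    with more errors than target words).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    target = list(target_tokens)
    if k_errors < 0:
        raise ValueError("k_errors must be >= 0")
    if mix[0] == 0 and mix[2] == 0 and k_errors > len(target):
        raise ValueError(
            f"cannot inject {k_errors} deletions into a {len(target)}-token target"
        )
    ops = ("ins", "del", "sub")
    for _ in range(200):
        resp = list(target)
        for _ in range(k_errors):
            op = ops[int(rng.choice(3, p=mix))]
            if op == "del" and not resp:
                op = "ins" if mix[0] > 0 else "sub"
            if op == "del":
                resp.pop(int(rng.integers(len(resp))))
            elif op == "sub" and resp:
                resp[int(rng.integers(len(resp)))] = _JUNK[int(rng.integers(len(_JUNK)))]
            else:
                pos = int(rng.integers(len(resp) + 1))
                resp.insert(pos, _JUNK[int(rng.integers(len(_JUNK)))])
        if repetition_prob > 0 and resp and rng.random() < repetition_prob:
            pos = int(rng.integers(len(resp)))
            resp.insert(pos, resp[pos])
        counts = align(collapse_repetitions(resp), target)
        if counts.total_errors == k_errors:
            return resp
    raise ValueError(
        f"could not realize {k_errors} scored errors on target {target!r} "
        f"with mix {mix} after 200 attempts"
    )


# ---------------------------------------------------------------------------
# corpus generation


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[SubtestAdministration], list[SubtestAdministration]]:
    """Generate parallel clean and verbatim corpora.

    Returns ``(clean, verbatim)`` administration lists; for every item the
    two variants share stimulus and gold score.  Output is a pure function
    of the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    banks = {
        code: build_stimulus_bank(code, config.n_items(code), seed=config.seed + 1000 + i)
        for i, code in enumerate(config.subtests)
    }
    group_names = list(config.group_probs)
    group_p = np.asarray([config.group_probs[g] for g in group_names], dtype=float)

    clean_admins: list[SubtestAdministration] = []
    verbatim_admins: list[SubtestAdministration] = []
    for c in range(config.n_children):
        child_id = f"c{c:04d}"
        age = int(rng.integers(config.age_range_months[0], config.age_range_months[1]))
        group = group_names[int(rng.choice(len(group_names), p=group_p))]
        for code in config.subtests:
            sub = SUBTESTS[code]
            n_items = config.n_items(code)
            probs = np.asarray(config.score_distributions[code], dtype=float)
            classes = np.asarray(sub.score_classes)

            zero_start: Optional[int] = None
            if config.zero_run_prob > 0 and rng.random() < config.zero_run_prob:
                run = sub.discontinuation_run or 5
                hi = max(1, n_items - run)
                zero_start = int(rng.integers(1, hi + 1))

            clean_items: list[ItemResponse] = []
            verb_items: list[ItemResponse] = []
            for i in range(n_items):
                stim = banks[code][i]
                if zero_start is not None and i >= zero_start:
                    gold = 0
                else:
                    gold = int(classes[int(rng.choice(len(classes), p=probs))])
                if code == "RS":
                    clean_text = _rs_response(stim, gold, config, rng)
                else:
                    options = stim.exemplars[gold]
                    clean_text = options[int(rng.integers(len(options)))]
                verb_text = clean_text
                if rng.random() < config.chatter_prob:
                    pre = _CHATTER_PRE[int(rng.integers(len(_CHATTER_PRE)))]
                    verb_text = f"{pre} {clean_text}".strip()
                    if rng.random() < 0.3:
                        post = _CHATTER_POST[int(rng.integers(len(_CHATTER_POST)))]
                        verb_text = f"{verb_text} {post}"
                common = dict(
                    subtest=code,
                    item_index=i,
                    stimulus_id=stim.stimulus_id,
                    prompt_text=stim.prompt_text,
                    gold_score=gold,
                )
                clean_items.append(
                    ItemResponse(response_text=clean_text, transcript_kind="clean", **common)
                )
                verb_items.append(
                    ItemResponse(response_text=verb_text, transcript_kind="verbatim", **common)
                )
            clean_admins.append(
                SubtestAdministration(child_id, code, age, clean_items, group=group)
            )
            verbatim_admins.append(
                SubtestAdministration(child_id, code, age, verb_items, group=group)
            )
    return clean_admins, verbatim_admins


def _rs_response(
    stim: Stimulus, gold: int, config: GeneratorConfig, rng: np.random.Generator
) -> str:
    """RS response realizing the gold score; verified by the rule scorer."""
    target = normalize_tokens(stim.prompt_text)
    lo, hi = config.score_map.errors_for_score(gold)
    hi_eff = lo + 1 if hi is None else hi  # open-ended zero tier: keep k small
    k = int(rng.integers(lo, hi_eff + 1))
    resp = inject_rs_errors(
        target, k, config.rs_error_mix, config.rs_repetition_prob, rng
    )
    text = " ".join(resp)
    got = rs_item_score(text, stim.prompt_text, config.score_map)
    if got != gold:  # pragma: no cover - inject_rs_errors already verifies
        raise RuntimeError(f"gold-score collision: wanted {gold}, scorer says {got}")
    return text
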