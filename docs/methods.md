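# Methods

## Scope and model

`elscore` scores four expressive-language subtests from transcripts. Each
subtest is a fixed ordered sequence of stimuli; a child's response to each
stimulus receives an integer item score (EV and FS 0–2, WS 0–1, RS 0–3).
Item scores are summed into a raw score, subject to a discontinuation
(ceiling) rule — administration ends at the item completing the first run
of consecutive zeros (7 for EV, 5 for FS and RS; WS has none). Raw scores
convert to age-normed scaled scores (1–19, mean 10, SD 3) through a lookup
table, and the FS+RS+WS scaled-score sum converts to the Expressive
Language Index (ELI, 45–155, mean 100, SD 15) through a second lookup.
Item counts per subtest default to EV 27, WS 32, RS 32, FS 24 — the values
implied by the published raw-score scales (0–54, 0–32, 0–96, 0–48) divided
by the maximum item score — and are configurable.

Two transcript variants are modelled. The *clean* transcript is the scored
response as an examiner would record it; the *verbatim* transcript is
everything the child said, including prefatory chatter ("I think that
one's a pirate" where the clean transcript reads "pirate"). Scorers are
trained and evaluated separately on each variant; verbatim is the harder
condition.

## Sentence-recall rule scoring

RS responses are scored deterministically:

1. normalize: lowercase, strip punctuation (internal apostrophes kept),
   whitespace-tokenize;
2. collapse repetitions: maximal runs of identical adjacent tokens reduce
   to one token. Repetitions are disfluencies and never count as errors.
   Only adjacency matters — non-adjacent duplicates are genuine content,
   and phrase-level restarts are deliberately not detected (a token-level
   rule is deterministic and cheap; run collapse is idempotent);
3. align against the normalized target with a unit-cost word-level
   Levenshtein dynamic programme that reports operation counts
   (insertions, deletions/omissions, substitutions, correct words);
4. map the total error count to a score through a threshold map.

The error→score thresholds are a convention, not a published fact: the
task defines a 0–3 scale "based on number of errors" without printing the
cut-offs. The default (0 → 3, 1 → 2, 2–3 → 1, ≥ 4 → 0) follows standard
sentence-recall practice and is an explicit, overridable config object.

Because the operation counts double as classifier features, tie-breaking
among equal-cost alignments is part of the contract: the backtrace prefers
the diagonal move (match/substitution), then insertion, then deletion.
Substitution is therefore preferred over an insertion+deletion pair of the
same cost, and counts are reproducible. Transpositions are not a primitive
edit; an adjacent swap surfaces as two substitutions (two errors). A
Damerau-style swap-cost-1 variant exists (`allow_transpositions=True`) but
is off by default, and the synthetic generator counts a generated swap as
two scored errors accordingly.

The alignment is verified in the test suite against a brute-force
enumeration oracle — complete agreement over all token-sequence pairs of
length ≤ 4 over a 3-symbol alphabet — plus property tests for the count
identities, role-swap symmetry and the triangle inequality.

## Item classifiers

All learned scorers implement one contract: `fit(pairs, config)` on
labelled (prompt, response) pairs of a single subtest, `predict(pairs)`
returning scores from that subtest's class set, deterministic given the
seed. Training data must contain at least two classes.

Iterative backends share one training protocol: a seeded 10% validation
holdout (falling back to a stratified split with a logged warning if a
plain split would strip a class from the training side), per-epoch
validation loss, early stopping once the loss has failed to improve for 4
consecutive epochs, restoration of the best-validation-loss state, and an
L2 penalty on the trained weights. The early-stopping rule is exact and
unit-tested: the restored epoch is the argmin of validation loss over
completed epochs (first occurrence on ties).

Backends:

* `lightweight_ngram` — 1-nearest-neighbour by cosine similarity over
  sparse profiles of response unigrams/bigrams plus namespaced prompt
  unigrams. Deterministic tie-break toward the earliest training example,
  so exact duplicates of training pairs receive their training label.
  Fast, download-free; the default for tests and pipelines.
* `svm_mean_embedding` — linear SVM on the 300-dimensional arithmetic
  mean of the response's word vectors (the classic baseline for the EV
  and WS tasks). Empty responses and out-of-vocabulary words map to the
  zero vector, so the mean of nothing is defined.
* `svm_edit_features` — linear SVM on the RS alignment counts
  (insertions, deletions, substitutions, correct); RS only.
* `mlp_static_embedding` — one-hidden-layer MLP (64 units) over a static
  sentence embedding of the response (mean word vector; the embedding is
  never fine-tuned, only the MLP trains). The FS baseline family. The
  embedding covers the response only, not the prompt.
* `finetuned_transformer` — a compact self-attention pair classifier.
  The pair is encoded as `[CLS] prompt [SEP] response` with segment flags
  (exactly one separator; over-length input truncates the response tail
  first); a single-block single-head attention encoder (width 32, frozen,
  randomly initialized from the seed) produces CLS + mean-pooled
  features, and a softmax head is trained with minibatch gradient descent
  under the shared protocol, with decoupled weight decay so the update is
  stable for any L2 strength. This configuration keeps the package
  runnable with no model download; a pretrained encoder can be plugged in
  by overriding the feature extractor.
* `gold_oracle` — echoes gold labels; a diagnostic used to validate
  harness closure (a perfect item scorer must produce perfect score
  tiers), never a real scorer.

Word embeddings come from a provider interface. The default provider is a
seeded hash projection: each token's 300-dim vector is drawn from a
generator seeded by a stable hash of the token, giving deterministic,
download-free vectors with unit expected norm. A pretrained word-vector
text file can be substituted (`WordVectorFile`).

Unreported training hyperparameters are conventional defaults, stated as
such: learning rate 0.1 for the softmax head (standardized features),
1e-3 for the MLP, batch size 16, max 50 epochs, L2 weight 0.01, no class
reweighting (a flag could be added; the default mirrors plain training).

## Aggregation

Items after a discontinuation point are *dropped*, not zero-filled: both
give the same raw score, but dropped items are excluded from item-level
evaluation, mirroring real administration where post-ceiling items are
never presented. `apply_ceiling=False` (`--score-past-ceiling`) scores
everything, for research use. When scoring automatically, the zero run
can be detected on the predicted stream (default) or the gold stream
(`ceiling_on="gold"`, replicating manual administration); which stream a
deployed system should use is genuinely open, so both are provided.
Reverse/basal starting rules are not modelled. The ELI requires all of
FS, RS and WS scaled scores; nothing is imputed. Age bands are half-open
`[min, max)` months — a child exactly on a boundary falls in the upper
band.

## Synthetic data

No transcript corpus ships with the package (child speech is protected),
so the generator produces corpora whose *scoring-relevant* structure is
controlled and whose gold scores are correct by construction:

* EV/WS/FS responses are drawn from stimulus-specific exemplar banks with
  one or more pre-labelled exemplars per score class — e.g. full credit
  names the target, partial credit gives a category word ("fruit" for
  "lime"), no credit an unrelated word; WS contrasts the inflected form
  against the bare stem. Distinct classes use disjoint word pools, which
  is what makes the separable-recovery acceptance check meaningful.
* RS responses are built from the target sentence by injecting exactly
  `k` scored errors (insertion/deletion/substitution mix configurable),
  where `k` is drawn from the error interval of the intended gold score
  under the configured score map. Injected junk words come from a nonword
  list disjoint from all targets. Uncounted adjacent repetitions are
  injected on top with probability `rs_repetition_prob` and never change
  the score. Every response is re-verified against the alignment and
  re-sampled on accidental collisions (e.g. a deletion fusing two
  identical words); the rule scorer therefore reproduces the gold score
  on 100% of generated RS items, which the acceptance suite asserts on
  5,000+ items.
* Verbatim variants prepend (and sometimes append) chatter phrases from a
  fixed list with probability `chatter_prob`; chatter is never
  interleaved. Clean and verbatim variants always share the gold score.
* With probability `zero_run_prob` a child enters a terminal all-zero run
  long enough to trigger the subtest's discontinuation rule.

Default per-item score distributions put most mass on creditable
responses (e.g. EV 0.15/0.25/0.60); no per-item distributions are
published, so these are the package's own study conditions, fixed once.
Linguistic realism is a non-goal: vocabulary comes from small built-in
word lists, ages are uniform over 60–119 months, and no age-conditioned
development is modelled. Passing tests on this generator demonstrates the
*pipeline* (alignment, protocol, aggregation, harness) — not performance
on real child speech, where responses are not drawn from closed exemplar
banks and classes are not vocabulary-separable.

## Synthetic norms

Norm tables are external configuration, never hard-coded: the published
tables are proprietary test content. The `norms` module builds internally
consistent synthetic tables by quantile matching. A reference population
of raw scores is simulated per subtest and age band; each child carries a
latent ability `a ~ N(0, ability_sd)` that tilts the class probabilities
(`p_a(k) ∝ p(k)·exp(a·k/k_max)`). Between-child ability variance is what
gives a norm population its raw-score spread; it also keeps the raw
distribution smooth enough (no raw value carrying several percent of the
mass) that integer discretization does not bias the calibration. With iid
item scores and no ability spread, the RS raw distribution is narrow
enough that the scaled mean drifts by ~0.1–0.15 points; `ability_sd=1.0`
is the default.

Each raw value `r` then receives
`scaled(r) = clip(round(10 + 3·Φ⁻¹(q_r)), 1, 19)` with `q_r` the mid-rank
empirical quantile of `r` — equivalently, scaled `s` covers reference
quantiles `Φ((s−10.5)/3)..Φ((s−9.5)/3)`, with ties at boundaries breaking
toward the lower score and a monotone guard against rounding jitter. The
ELI table is built the same way (mean 100, SD 15) over the scaled-sum
distribution the raw→scaled tables themselves induce (per-subtest samples
are independently permuted before pairing into reference children).
Mid-rank quantiles are clipped to `[1/2n, 1−1/2n]` so the normal quantile
stays finite. The acceptance suite verifies, on a fresh 100,000-child
sample, scaled mean 10 ± 0.1 and SD 3 ± 0.3 per subtest and ELI mean
100 ± 1, SD 15 ± 1.5; `scripts/acceptance.py` recomputes the two means.
These tables are calibrated approximations for exercising the pipeline —
they carry no real developmental norms.

## Evaluation harness

Cross-validation partitions *children* into folds (default 5) so no
child's items appear on both sides of a fold; `fold_unit="item"` exposes
the laxer item-level alternative. The whole procedure repeats over
reshuffles (default 20) with repetition seeds derived as
`seed + repetition`; reports give mean and SD (ddof 1) over repetitions.
Item metrics pool all test items of a repetition; raw/scaled/ELI metrics
compare per-child aggregated predictions with gold-derived tiers.

Precision and recall average per class, weighted by gold support by
default: support-weighted recall is algebraically identical to accuracy,
which matches how published tables for this task show
precision = recall = accuracy; macro averaging is available. Per-class
ratios with zero denominators count as 0, and classes absent from both
gold and predictions are excluded. The implementation is confusion-matrix
arithmetic in the package, cross-checked against scikit-learn in tests.
Spearman's ρ uses average ranks; a zero-variance vector yields a NaN
sentinel that is excluded from repetition means with an exclusion count,
never an exception. Subgroup reports (e.g. TD vs non-TD tags) recompute
the same metrics per group over the same predictions, with no
re-training; empty groups are omitted with a warning.

## Problem sizes and numerical choices

The shipped test and acceptance workloads use corpora of 10–200 synthetic
children (up to ~23,000 items), 100,000-child norm references, and
5-fold × 1–3-repetition cross-validation — sizes chosen so the entire
suite runs in well under a minute of CPU apart from the norm-calibration
check (~10 s). Determinism: every stochastic component takes an explicit
seed; repetition and bank seeds are derived additively; SVC is used
without probability calibration so refits reproduce predictions exactly.

## Limitations

* The transformer-style backend trains only its classification head over
  a frozen random encoder by default; results with a pretrained,
  fully fine-tuned encoder will differ substantially.
* Synthetic corpora are vocabulary-separable by construction; accuracy
  numbers on them are upper bounds of plumbing correctness, not estimates
  of real-transcript performance.
* Norm tables are synthetic calibrations, not published norms; scaled and
  composite scores from them are meaningful only relative to the
  configured reference population.
* No ASR, audio, diarization, phonetic or lemma-level matching; no
  reverse/basal rules; no diagnostic logic (the conventional
  clinical-concern threshold of a scaled score below 7 is surfaced only
  as documentation, never computed on).
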