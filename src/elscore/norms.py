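"""Synthetic, internally consistent norm tables.

The published normative tables are proprietary test content, so this module
constructs *synthetic* lookup tables calibrated the way norm tables are
defined: scaled scores have mean 10 / SD 3 and the composite has mean 100 /
SD 15 over a reference population.

Construction is quantile matching (area transformation): for a reference
sample of raw scores, each raw value ``r`` receives the scaled score

    scaled(r) = clip(round(10 + 3 * Phi^-1(q_r)), 1, 19)

where ``q_r`` is the mid-rank empirical quantile of ``r`` (the average of
the CDF just below and at ``r``), and Phi^-1 the standard-normal quantile
function.  Equivalently, scaled ``s`` covers the reference quantiles
``Phi((s-10.5)/3) .. Phi((s-9.5)/3)``, clamped to 1 and 19 in the tails;
ties at quantile boundaries break toward the lower scaled score via the
rounding convention.  The ELI table is built the same way (mean 100, SD 15)
over the scaled-sum distribution that the raw->scaled tables themselves
induce on the reference population.

These tables are calibrated approximations for exercising the scoring
pipeline; they are NOT the published normative tables and carry no
developmental age-norm information beyond what the configured reference
distributions encode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm as _normal

from .core import SUBTESTS
from .corpus_io import NormBandRow, NormTable

__all__ = [
    "NormConfig",
    "DEFAULT_SCORE_DISTRIBUTIONS",
    "reference_population",
    "build_norm_tables",
    "make_default_norm_table",
]

#: Default per-subtest item-score probability vectors for the synthetic
#: reference population (indices are the score classes in ascending order).
#: Chosen to put most mass on creditable responses, as in a typical
#: norm-reference population, while keeping raw-score distributions smooth.
DEFAULT_SCORE_DISTRIBUTIONS: Mapping[str, tuple[float, ...]] = {
    "EV": (0.15, 0.25, 0.60),
    "WS": (0.30, 0.70),
    "RS": (0.15, 0.20, 0.25, 0.40),
    "FS": (0.20, 0.30, 0.50),
}


@dataclass(frozen=True)
class NormConfig:
    """Reference-population settings for synthetic norm construction.

    ``age_bands`` are half-open ``[min_months, max_months)``; the default
    single band spans ages 5-9 years.  ``n_per_band`` reference children
    are drawn per band (>= 10,000 keeps quantile noise well below the
    integer discretization of the scales).  ``ability_sd`` controls the
    between-child ability spread of the reference population (see
    :func:`_raw_samples`).
    """

    age_bands: tuple[tuple[int, int], ...] = ((60, 120),)
    n_per_band: int = 10_000
    ability_sd: float = 1.0
    score_distributions: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_DISTRIBUTIONS)
    )


def _raw_samples(
    code: str,
    probs: Sequence[float],
    n: int,
    rng: np.random.Generator,
    ability_sd: float = 1.0,
) -> np.ndarray:
    """Draw n raw scores as sums of per-item scores for one subtest.

    Each reference child carries a latent ability ``a ~ N(0, ability_sd)``
    that tilts the base class probabilities ``p(k)`` to
    ``p_a(k) \\propto p(k) exp(a k / k_max)`` — higher-ability children earn
    higher item scores more often.  Between-child variation is what gives
    a norm population its raw-score spread; it also keeps the raw
    distribution smooth enough that integer quantile discretization does
    not bias the scaled-score calibration.
    """
    sub = SUBTESTS[code]
    probs = np.asarray(probs, dtype=float)
    if len(probs) != sub.n_classes:
        raise ValueError(f"{code}: need {sub.n_classes} class probabilities, got {len(probs)}")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"{code}: probabilities sum to {probs.sum()}, not 1")
    classes = np.asarray(sub.score_classes, dtype=float)
    a = rng.standard_normal(n) * ability_sd
    logits = np.log(probs)[None, :] + a[:, None] * (classes / classes.max())[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    # Gumbel-max sampling of each child's items from their tilted distribution
    G = rng.gumbel(size=(n, sub.max_items, len(classes)))
    pick = np.argmax(np.log(P)[:, None, :] + G, axis=2)
    return classes[pick].sum(axis=1).astype(int)


def reference_population(
    config: NormConfig, seed: int
) -> dict[str, dict[tuple[int, int], np.ndarray]]:
    """Per-subtest, per-age-band reference raw-score samples.

    Deterministic for a fixed seed.  Samples are bounded by the subtest raw
    scale by construction (sums of per-item scores).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[tuple[int, int], np.ndarray]] = {}
    for code in SUBTESTS:
        probs = config.score_distributions[code]
        out[code] = {
            band: _raw_samples(code, probs, config.n_per_band, rng, config.ability_sd)
            for band in config.age_bands
        }
    return out


def _midrank_quantiles(values: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Mid-rank empirical quantile of each support point under `values`."""
    n = len(values)
    counts = np.array([(values == v).sum() for v in support], dtype=float)
    cum = np.cumsum(counts)
    below = cum - counts
    q = (below + cum) / (2 * n)
    # keep quantiles strictly inside (0, 1) so the normal quantile is finite
    return np.clip(q, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))


def _quantile_map(values: np.ndarray, support: np.ndarray, mean: float, sd: float,
                  lo: int, hi: int) -> np.ndarray:
    """Map each support point to clip(round(mean + sd*z), lo, hi), monotone."""
    z = _normal.ppf(_midrank_quantiles(values, support))
    mapped = np.clip(np.rint(mean + sd * z).astype(int), lo, hi)
    return np.maximum.accumulate(mapped)  # guard against rounding jitter


def _rows_from_mapping(band: tuple[int, int], support: np.ndarray, scaled: np.ndarray) -> list[NormBandRow]:
    rows = []
    start = 0
    for i in range(1, len(support) + 1):
        if i == len(support) or scaled[i] != scaled[start]:
            rows.append(
                NormBandRow(
                    age_min=band[0],
                    age_max=band[1],
                    raw_min=int(support[start]),
                    raw_max=int(support[i - 1]),
                    scaled=int(scaled[start]),
                )
            )
            start = i
    return rows


def build_norm_tables(
    reference: Mapping[str, Mapping[tuple[int, int], np.ndarray]],
    seed: int = 0,
) -> NormTable:
    """Build a validated :class:`NormTable` from reference raw-score samples.

    ``reference`` maps subtest code -> age band -> raw-score sample (as
    produced by :func:`reference_population`).  ``seed`` controls the
    pairing of per-subtest samples into reference children for the ELI
    section.  Raises ``ValueError`` on a degenerate (single-support-point)
    reference distribution.
    """
    subtest_tables: dict[str, list[NormBandRow]] = {}
    scaled_by_band: dict[tuple[int, int], dict[str, np.ndarray]] = {}
    for code, bands in reference.items():
        sub = SUBTESTS[code]
        rows: list[NormBandRow] = []
        for band, sample in bands.items():
            sample = np.asarray(sample)
            if len(np.unique(sample)) < 2:
                raise ValueError(
                    f"{code} band {band}: degenerate reference distribution "
                    "(single support point)"
                )
            support = np.arange(0, sub.raw_max + 1)
            scaled = _quantile_map(sample, support, 10.0, 3.0, 1, 19)
            rows.extend(_rows_from_mapping(band, support, scaled))
            scaled_by_band.setdefault(band, {})[code] = scaled[sample]
        subtest_tables[code] = rows

    # ELI over the induced scaled-sum distribution (FS + RS + WS).  Samples
    # within a band are paired into children after an independent shuffle.
    rng = np.random.default_rng(seed)
    sums = []
    for band, per_code in scaled_by_band.items():
        if not all(c in per_code for c in ("FS", "RS", "WS")):
            continue
        n = min(len(per_code[c]) for c in ("FS", "RS", "WS"))
        total = np.zeros(n, dtype=int)
        for c in ("FS", "RS", "WS"):
            total += rng.permutation(per_code[c][:n])
        sums.append(total)
    eli_table: list[tuple[int, int, int]] = []
    if sums:
        all_sums = np.concatenate(sums)
        support = np.arange(3, 58)
        eli_vals = _quantile_map(all_sums, support, 100.0, 15.0, 45, 155)
        start = 0
        for i in range(1, len(support) + 1):
            if i == len(support) or eli_vals[i] != eli_vals[start]:
                eli_table.append((int(support[start]), int(support[i - 1]), int(eli_vals[start])))
                start = i

    table = NormTable(subtest_tables=subtest_tables, eli_table=eli_table)
    table.validate()
    return table


def make_default_norm_table(seed: int, config: NormConfig | None = None) -> NormTable:
    """Convenience: default reference population -> validated norm table."""
    config = config or NormConfig()
    return build_norm_tables(reference_population(config, seed), seed=seed)
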