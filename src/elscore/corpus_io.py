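"""Read/write transcript corpora, norm tables, and score reports.

Corpora are UTF-8 line-delimited JSON, one object per line with fields
``child_id, age_months, subtest, item_index, stimulus_id, prompt_text,
response_text, transcript_kind, gold_score`` (``gold_score`` and the
optional ``group`` tag are omitted when absent).  Line-delimited records
keep free-text responses (commas, quotes) unambiguous; unknown fields are
preserved on round-trip.  A TSV import shim is provided for convenience.

Norm tables are delimited text in two sections: a raw->scaled section with
columns ``subtest, age_min_months, age_max_months, raw_min, raw_max,
scaled`` and an ELI section (after a ``# ELI`` marker line) with columns
``scaled_sum_min, scaled_sum_max, eli``.  The tables shipped or generated
by this package are synthetic (see :mod:`elscore.norms`): the published
normative tables are proprietary test content and are never bundled.

Age bands are half-open ``[min_months, max_months)``: a child exactly on a
boundary falls in the upper band.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .core import (
    SUBTESTS,
    ItemResponse,
    ScoreReport,
    SubtestAdministration,
    validate_corpus,
)

__all__ = [
    "CorpusFormatError",
    "NormTableError",
    "NormBandRow",
    "NormTable",
    "read_corpus",
    "write_corpus",
    "read_corpus_tsv",
    "read_norm_table",
    "write_norm_table",
    "write_score_reports",
]

_CORE_FIELDS = (
    "child_id",
    "age_months",
    "subtest",
    "item_index",
    "stimulus_id",
    "prompt_text",
    "response_text",
    "transcript_kind",
    "gold_score",
    "group",
)


class CorpusFormatError(ValueError):
    """Malformed corpus file (parse failure or duplicate item)."""


class NormTableError(ValueError):
    """Norm table violates coverage, range, or monotonicity requirements."""


# ---------------------------------------------------------------------------
# corpora


def _record_from_item(admin: SubtestAdministration, item: ItemResponse) -> dict:
    rec = {
        "child_id": admin.child_id,
        "age_months": admin.age_months,
        "subtest": item.subtest,
        "item_index": item.item_index,
        "stimulus_id": item.stimulus_id,
        "prompt_text": item.prompt_text,
        "response_text": item.response_text,
        "transcript_kind": item.transcript_kind,
    }
    if item.gold_score is not None:
        rec["gold_score"] = item.gold_score
    if admin.group is not None:
        rec["group"] = admin.group
    rec.update(item.extra)
    return rec


def write_corpus(
    admins: Sequence[SubtestAdministration], path: Union[str, Path]
) -> None:
    """Write administrations as line-delimited JSON records.

    Raises ``ValueError`` if any administration violates the model
    invariants (the file format must only ever contain valid corpora).
    """
    violations = validate_corpus(admins)
    if violations:
        raise ValueError(
            "refusing to write invalid corpus: " + "; ".join(map(str, violations[:5]))
        )
    with open(path, "w", encoding="utf-8") as fh:
        for admin in admins:
            for item in admin.items:
                fh.write(
                    json.dumps(_record_from_item(admin, item), ensure_ascii=False)
                )
                fh.write("\n")


def read_corpus(path: Union[str, Path, io.TextIOBase]) -> list[SubtestAdministration]:
    """Read a line-delimited corpus, grouping records into administrations.

    ``path`` may also be an open text stream.  Records are grouped by
    ``(child_id, subtest)`` and sorted by ``item_index``.  A malformed line
    or a duplicate ``(child_id, subtest, item_index)`` raises
    :class:`CorpusFormatError` naming the line number.
    """
    groups: dict[tuple[str, str], dict] = {}
    if hasattr(path, "read"):
        fh_ctx = path
        close = False
    else:
        fh_ctx = open(path, encoding="utf-8")
        close = True
    try:
        for lineno, line in enumerate(fh_ctx, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: malformed record: {exc}") from exc
            try:
                key = (str(rec["child_id"]), str(rec["subtest"]))
                item = ItemResponse(
                    subtest=str(rec["subtest"]),
                    item_index=int(rec["item_index"]),
                    stimulus_id=str(rec["stimulus_id"]),
                    prompt_text=str(rec["prompt_text"]),
                    response_text=str(rec.get("response_text", "")),
                    transcript_kind=str(rec.get("transcript_kind", "clean")),
                    gold_score=(
                        int(rec["gold_score"]) if rec.get("gold_score") is not None else None
                    ),
                    extra={k: v for k, v in rec.items() if k not in _CORE_FIELDS},
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise CorpusFormatError(f"line {lineno}: missing/invalid field: {exc}") from exc
            g = groups.setdefault(
                key,
                {
                    "age_months": int(rec["age_months"]),
                    "group": rec.get("group"),
                    "items": {},
                },
            )
            if item.item_index in g["items"]:
                raise CorpusFormatError(
                    f"line {lineno}: duplicate item_index {item.item_index} "
                    f"for child {key[0]!r} subtest {key[1]}"
                )
            g["items"][item.item_index] = item
    finally:
        if close:
            fh_ctx.close()
    admins = []
    for (child_id, subtest), g in groups.items():
        items = [g["items"][i] for i in sorted(g["items"])]
        admins.append(
            SubtestAdministration(
                child_id=child_id,
                subtest=subtest,
                age_months=g["age_months"],
                items=items,
                group=g["group"],
            )
        )
    return admins


def read_corpus_tsv(path: Union[str, Path]) -> list[SubtestAdministration]:
    """Convenience TSV importer (same columns as the JSON records)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    buf = io.StringIO()
    for rec in df.to_dict(orient="records"):
        for k in ("age_months", "item_index"):
            rec[k] = int(rec[k])
        gs = rec.get("gold_score", "")
        if gs == "":
            rec.pop("gold_score", None)
        else:
            rec["gold_score"] = int(gs)
        if rec.get("group", "") == "":
            rec.pop("group", None)
        buf.write(json.dumps(rec, ensure_ascii=False) + "\n")
    buf.seek(0)
    return read_corpus(buf)


# ---------------------------------------------------------------------------
# norm tables


@dataclass(frozen=True)
class NormBandRow:
    """One raw->scaled row: ages [age_min, age_max) months, raws inclusive."""

    age_min: int
    age_max: int
    raw_min: int
    raw_max: int
    scaled: int


@dataclass
class NormTable:
    """Raw->scaled and scaled-sum->ELI lookup structures.

    ``subtest_tables`` maps subtest code to rows; within one age band the
    raw intervals must be disjoint, contiguous and cover the full raw scale,
    with scaled non-decreasing in raw.  ``eli_table`` is a list of
    ``(scaled_sum_min, scaled_sum_max, eli)`` covering sums 3..57 with eli
    non-decreasing.
    """

    subtest_tables: dict[str, list[NormBandRow]]
    eli_table: list[tuple[int, int, int]] = field(default_factory=list)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for code, rows in self.subtest_tables.items():
            if code not in SUBTESTS:
                raise NormTableError(f"unknown subtest {code!r}")
            raw_max = SUBTESTS[code].raw_max
            bands: dict[tuple[int, int], list[NormBandRow]] = {}
            for row in rows:
                if not 1 <= row.scaled <= 19:
                    raise NormTableError(
                        f"{code}: scaled {row.scaled} outside 1-19 "
                        f"(band [{row.age_min},{row.age_max}))"
                    )
                if row.age_min >= row.age_max:
                    raise NormTableError(f"{code}: empty age band [{row.age_min},{row.age_max})")
                bands.setdefault((row.age_min, row.age_max), []).append(row)
            spans = sorted(bands)
            for (a, b), (c, d) in zip(spans, spans[1:]):
                if c < b:
                    raise NormTableError(
                        f"{code}: overlapping age bands [{a},{b}) and [{c},{d})"
                    )
            for span, band_rows in bands.items():
                band_rows = sorted(band_rows, key=lambda r: r.raw_min)
                prev_end = -1
                prev_scaled = 0
                for row in band_rows:
                    if row.raw_min != prev_end + 1:
                        kind = "overlap" if row.raw_min <= prev_end else "gap"
                        raise NormTableError(
                            f"{code} band [{span[0]},{span[1]}): raw {kind} "
                            f"between {prev_end} and {row.raw_min}"
                        )
                    if row.raw_max < row.raw_min:
                        raise NormTableError(f"{code}: empty raw interval {row}")
                    if row.scaled < prev_scaled:
                        raise NormTableError(
                            f"{code} band [{span[0]},{span[1]}): scaled decreases "
                            f"({prev_scaled} -> {row.scaled}) at raw {row.raw_min}"
                        )
                    prev_end = row.raw_max
                    prev_scaled = row.scaled
                if prev_end != raw_max:
                    raise NormTableError(
                        f"{code} band [{span[0]},{span[1]}): raws covered to "
                        f"{prev_end}, scale runs to {raw_max}"
                    )
        if self.eli_table:
            rows = sorted(self.eli_table)
            prev_end = 2
            prev_eli = 0
            for lo, hi, eli in rows:
                if not 45 <= eli <= 155:
                    raise NormTableError(f"ELI {eli} outside 45-155")
                if lo != prev_end + 1:
                    raise NormTableError(f"ELI sum coverage breaks between {prev_end} and {lo}")
                if eli < prev_eli:
                    raise NormTableError(f"ELI decreases ({prev_eli} -> {eli}) at sum {lo}")
                prev_end, prev_eli = hi, eli
            if rows[0][0] != 3 or prev_end != 57:
                raise NormTableError(
                    f"ELI table must cover scaled sums 3-57, covers {rows[0][0]}-{prev_end}"
                )

    # -- lookups ------------------------------------------------------------
    def scaled_lookup(self, subtest: str, age_months: int, raw: int) -> int:
        rows = self.subtest_tables.get(subtest)
        if not rows:
            raise NormTableError(f"no raw->scaled table for subtest {subtest!r}")
        in_band = [r for r in rows if r.age_min <= age_months < r.age_max]
        if not in_band:
            raise NormTableError(
                f"{subtest}: no age band covers {age_months} months"
            )
        for row in in_band:
            if row.raw_min <= raw <= row.raw_max:
                return row.scaled
        raise NormTableError(
            f"{subtest}: raw {raw} outside table coverage for age {age_months} months"
        )

    def eli_lookup(self, scaled_sum: int) -> int:
        for lo, hi, eli in self.eli_table:
            if lo <= scaled_sum <= hi:
                return eli
        raise NormTableError(f"ELI table does not cover scaled sum {scaled_sum}")


_NORM_COLS = ["subtest", "age_min_months", "age_max_months", "raw_min", "raw_max", "scaled"]
_ELI_COLS = ["scaled_sum_min", "scaled_sum_max", "eli"]
_ELI_MARKER = "# ELI"


def write_norm_table(table: NormTable, path: Union[str, Path]) -> None:
    """Write both sections as tab-delimited text (validates first)."""
    table.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_NORM_COLS) + "\n")
        for code, rows in table.subtest_tables.items():
            for r in sorted(rows, key=lambda r: (r.age_min, r.raw_min)):
                fh.write(
                    f"{code}\t{r.age_min}\t{r.age_max}\t{r.raw_min}\t{r.raw_max}\t{r.scaled}\n"
                )
        fh.write("\n" + _ELI_MARKER + "\n")
        fh.write("\t".join(_ELI_COLS) + "\n")
        for lo, hi, eli in sorted(table.eli_table):
            fh.write(f"{lo}\t{hi}\t{eli}\n")


def read_norm_table(path: Union[str, Path]) -> NormTable:
    """Read and validate a two-section norm-table file."""
    text = Path(path).read_text(encoding="utf-8")
    if _ELI_MARKER in text:
        scaled_part, eli_part = text.split(_ELI_MARKER, 1)
    else:
        scaled_part, eli_part = text, ""
    sdf = pd.read_csv(io.StringIO(scaled_part), sep="\t")
    missing = [c for c in _NORM_COLS if c not in sdf.columns]
    if missing:
        raise NormTableError(f"norm table missing columns {missing}")
    subtest_tables: dict[str, list[NormBandRow]] = {}
    for rec in sdf.to_dict(orient="records"):
        subtest_tables.setdefault(str(rec["subtest"]), []).append(
            NormBandRow(
                age_min=int(rec["age_min_months"]),
                age_max=int(rec["age_max_months"]),
                raw_min=int(rec["raw_min"]),
                raw_max=int(rec["raw_max"]),
                scaled=int(rec["scaled"]),
            )
        )
    eli_table: list[tuple[int, int, int]] = []
    if eli_part.strip():
        edf = pd.read_csv(io.StringIO(eli_part), sep="\t")
        for rec in edf.to_dict(orient="records"):
            eli_table.append(
                (int(rec["scaled_sum_min"]), int(rec["scaled_sum_max"]), int(rec["eli"]))
            )
    table = NormTable(subtest_tables=subtest_tables, eli_table=eli_table)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# score reports


def write_score_reports(reports: Iterable[ScoreReport], path: Union[str, Path]) -> None:
    """Tab-delimited report: one row per child x subtest plus one ELI row."""
    rows = []
    for rep in reports:
        for code, ss in rep.per_subtest.items():
            rows.append(
                {
                    "child_id": rep.child_id,
                    "subtest": code,
                    "scorer_id": rep.scorer_id,
                    "raw": ss.raw,
                    "scaled": "" if ss.scaled is None else ss.scaled,
                    "discontinued_at": "" if ss.discontinued_at is None else ss.discontinued_at,
                    "item_scores": ",".join(map(str, ss.item_scores)),
                }
            )
        if rep.eli is not None:
            rows.append(
                {
                    "child_id": rep.child_id,
                    "subtest": "ELI",
                    "scorer_id": rep.scorer_id,
                    "raw": "",
                    "scaled": rep.eli,
                    "discontinued_at": "",
                    "item_scores": "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
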