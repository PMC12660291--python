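"""Core domain types for the AIF extraction pipeline.

A *report* is the free text of one FDG PET-CT study; an *actionable
incidental finding* (AIF) is a finding unrelated to the indication for
the scan that requires clinical action or follow-up.  Gold annotations
list the verbatim sentences of a report that describe AIFs; the binary
document label is derived from them (positive iff at least one AIF
sentence is present).

This module also owns deterministic sentence segmentation and the JSONL
report/annotation file formats shared by every pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence


class AifexError(Exception):
    """Base class for pipeline errors."""


class DatasetError(AifexError):
    """Malformed dataset file or inconsistent dataset contents."""


def collapse_ws(s: str) -> str:
    """Collapse every whitespace run to a single space and strip the ends."""
    return " ".join(s.split())


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

#: Tokens whose trailing period never ends a sentence.  Units and titles
#: common in radiology reports; lower-cased, trailing periods removed.
ABBREVIATIONS = frozenset(
    {"cm", "mm", "dr", "mr", "mrs", "prof", "e.g", "i.e", "vs", "fig", "approx"}
)

_TERMINAL = ".!?"


def _is_list_marker(prefix: str) -> bool:
    """True when the text before a period is a bare list numeral like "1"."""
    stripped = prefix.strip()
    return stripped.isdigit() and len(stripped) <= 3


def segment_sentences(text: str) -> list[str]:
    """Split report text into verbatim sentence strings, deterministically.

    Rule based: a sentence ends at terminal punctuation (``.!?``) followed
    by whitespace and an upper-case letter or digit, unless the token before
    the period is a known abbreviation or a numbered-list marker ("1. ...":
    the numeral stays attached to its sentence).  Newlines are hard
    boundaries, so section headers such as ``Findings:`` become their own
    sentences.  Whitespace-only input yields an empty list.

    Each returned sentence is a stripped verbatim substring of ``text``;
    joining them with single spaces and collapsing whitespace reproduces the
    whitespace-collapsed input.  Segmentation is idempotent: re-segmenting
    any returned sentence returns that sentence alone.
    """
    sentences: list[str] = []
    for line in text.split("\n"):
        start = 0
        i = 0
        n = len(line)
        while i < n:
            ch = line[i]
            if ch in _TERMINAL:
                j = i + 1
                while j < n and line[j].isspace():
                    j += 1
                followed = j > i + 1 and j < n and (line[j].isupper() or line[j].isdigit())
                if followed:
                    prefix = line[start:i]
                    words = prefix.split()
                    last = words[-1].rstrip(".").lower() if words else ""
                    if ch == "." and last in ABBREVIATIONS:
                        pass
                    elif ch == "." and _is_list_marker(prefix):
                        pass
                    else:
                        seg = line[start : i + 1].strip()
                        if seg:
                            sentences.append(seg)
                        start = j
                        i = j
                        continue
            i += 1
        tail = line[start:].strip()
        if tail:
            sentences.append(tail)
    return sentences


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class ParseStatus(str, Enum):
    """Outcome of structured-output parsing for one report.

    ``ok``: first attempt parsed; ``recovered``: a fallback attempt parsed;
    ``fatal_null``: every attempt failed and a parsable null answer was
    emitted (scored incorrect downstream).
    """

    OK = "ok"
    RECOVERED = "recovered"
    FATAL_NULL = "fatal_null"


@dataclass(frozen=True)
class Report:
    """One radiology report.

    ``sentences`` is the deterministic segmentation of ``text`` (computed if
    not supplied); ``sections`` optionally maps a section name (e.g.
    "Findings") to a half-open ``(start, end)`` sentence-index range.
    Sentence identity throughout the pipeline is by verbatim string, not
    character offset.
    """

    report_id: str
    text: str
    sentences: tuple[str, ...] = ()
    sections: Mapping[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.sentences:
            object.__setattr__(self, "sentences", tuple(segment_sentences(self.text)))
        if self.sections is not None:
            self._check_sections()

    def _check_sections(self) -> None:
        n = len(self.sentences)
        prev_end = 0
        for name, (lo, hi) in self.sections.items():  # insertion-ordered
            if not (0 <= lo <= hi <= n):
                raise DatasetError(
                    f"report {self.report_id!r}: section {name!r} range ({lo}, {hi}) "
                    f"out of bounds for {n} sentences"
                )
            if lo < prev_end:
                raise DatasetError(
                    f"report {self.report_id!r}: section {name!r} overlaps the previous section"
                )
            prev_end = hi


@dataclass(frozen=True)
class GoldAnnotation:
    """Gold AIF sentences for one report.

    ``aif_sentences`` behaves as an ordered set: duplicates are removed with
    first-occurrence order preserved, giving deterministic serialisation.
    The document label is derived, never stored: positive iff at least one
    AIF sentence is present.
    """

    report_id: str
    aif_sentences: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for s in self.aif_sentences:
            seen.setdefault(s, None)
        object.__setattr__(self, "aif_sentences", tuple(seen))

    @property
    def doc_label(self) -> bool:
        return bool(self.aif_sentences)


@dataclass(frozen=True)
class ExtractionResult:
    """Model output for one report after the decoding controller ran.

    ``predicted_label`` is ``None`` only for ``fatal_null`` results, which
    also carry no sentences; ``raw_generations`` retains the raw backend
    output of every attempt for audit.
    """

    report_id: str
    predicted_label: bool | None
    predicted_sentences: tuple[str, ...]
    attempts: int
    parse_status: ParseStatus
    raw_generations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.parse_status is ParseStatus.FATAL_NULL:
            if self.predicted_label is not None or self.predicted_sentences:
                raise AifexError(
                    f"report {self.report_id!r}: fatal_null results must carry a null "
                    "label and no sentences"
                )
        if self.attempts < 1:
            raise AifexError(f"report {self.report_id!r}: attempts must be >= 1")


@dataclass
class Dataset:
    """A named collection of reports with (possibly partial) annotations."""

    name: str
    reports: list[Report]
    annotations: dict[str, GoldAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate report_id(s): {dupes}")
        extra = set(self.annotations) - set(ids)
        if extra:
            raise DatasetError(f"annotations for unknown report_id(s): {sorted(extra)}")
        for rid, ann in self.annotations.items():
            if ann.report_id != rid:
                raise DatasetError(f"annotation keyed {rid!r} carries report_id {ann.report_id!r}")

    def __len__(self) -> int:
        return len(self.reports)

    def report(self, report_id: str) -> Report:
        for r in self.reports:
            if r.report_id == report_id:
                return r
        raise DatasetError(f"unknown report_id {report_id!r}")

    def validate_grounding(self) -> None:
        """Check every gold sentence occurs verbatim in its report's text."""
        by_id = {r.report_id: r for r in self.reports}
        for rid, ann in self.annotations.items():
            text = by_id[rid].text
            for s in ann.aif_sentences:
                if s not in text:
                    raise DatasetError(
                        f"report {rid!r}: gold sentence not found verbatim in text: {s!r}"
                    )


# ---------------------------------------------------------------------------
# JSONL I/O
# ---------------------------------------------------------------------------


def _read_jsonl(path: Path) -> Iterable[tuple[int, dict]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise DatasetError(f"{path}:{lineno}: malformed JSON line: {exc}") from exc
            if not isinstance(rec, dict):
                raise DatasetError(f"{path}:{lineno}: record is not a JSON object")
            yield lineno, rec


def read_dataset(
    reports_path: str | Path,
    gold_path: str | Path | None = None,
    name: str | None = None,
) -> Dataset:
    """Read a dataset from report JSONL (and optionally annotation JSONL).

    Report records: ``{"report_id": str, "text": str, "sections": {...}?}``.
    A report record may inline ``"aif_sentences"`` when no separate gold file
    is used.  Annotation records: ``{"report_id": str, "aif_sentences":
    [str, ...]}``; the document label is derived, never stored.  Duplicate
    report ids and malformed lines raise :class:`DatasetError` naming the
    line.
    """
    reports_path = Path(reports_path)
    reports: list[Report] = []
    annotations: dict[str, GoldAnnotation] = {}
    seen: set[str] = set()
    for lineno, rec in _read_jsonl(reports_path):
        try:
            rid = rec["report_id"]
            text = rec["text"]
        except KeyError as exc:
            raise DatasetError(f"{reports_path}:{lineno}: missing field {exc}") from exc
        if rid in seen:
            raise DatasetError(f"{reports_path}:{lineno}: duplicate report_id {rid!r}")
        seen.add(rid)
        sections = rec.get("sections")
        if sections is not None:
            sections = {k: (int(v[0]), int(v[1])) for k, v in sections.items()}
        reports.append(Report(report_id=rid, text=text, sections=sections))
        if "aif_sentences" in rec:
            annotations[rid] = GoldAnnotation(rid, tuple(rec["aif_sentences"]))
    if gold_path is not None:
        for lineno, rec in _read_jsonl(Path(gold_path)):
            try:
                rid = rec["report_id"]
                sents = rec["aif_sentences"]
            except KeyError as exc:
                raise DatasetError(f"{gold_path}:{lineno}: missing field {exc}") from exc
            if rid in annotations:
                raise DatasetError(f"{gold_path}:{lineno}: duplicate annotation for {rid!r}")
            annotations[rid] = GoldAnnotation(rid, tuple(sents))
    return Dataset(name=name or reports_path.stem, reports=reports, annotations=annotations)


def write_dataset(
    dataset: Dataset,
    reports_path: str | Path,
    gold_path: str | Path | None = None,
) -> None:
    """Write a dataset to report JSONL, and annotation JSONL if requested.

    With ``gold_path=None`` annotations are inlined as ``aif_sentences`` on
    the report records; either layout round-trips through
    :func:`read_dataset`.
    """
    with open(reports_path, "w", encoding="utf-8") as fh:
        for r in dataset.reports:
            rec: dict = {"report_id": r.report_id, "text": r.text}
            if r.sections is not None:
                rec["sections"] = {k: list(v) for k, v in r.sections.items()}
            if gold_path is None and r.report_id in dataset.annotations:
                rec["aif_sentences"] = list(dataset.annotations[r.report_id].aif_sentences)
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    if gold_path is not None:
        with open(gold_path, "w", encoding="utf-8") as fh:
            for r in dataset.reports:
                ann = dataset.annotations.get(r.report_id)
                if ann is None:
                    continue
                rec = {"report_id": ann.report_id, "aif_sentences": list(ann.aif_sentences)}
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def write_predictions(results: Sequence[ExtractionResult], path: str | Path) -> None:
    """Write extraction results as predictions JSONL."""
    with open(path, "w", encoding="utf-8") as fh:
        for res in results:
            rec = {
                "report_id": res.report_id,
                "predicted_label": res.predicted_label,
                "predicted_sentences": list(res.predicted_sentences),
                "attempts": res.attempts,
                "parse_status": res.parse_status.value,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_predictions(path: str | Path) -> list[ExtractionResult]:
    """Read predictions JSONL written by :func:`write_predictions`."""
    out: list[ExtractionResult] = []
    for lineno, rec in _read_jsonl(Path(path)):
        try:
            out.append(
                ExtractionResult(
                    report_id=rec["report_id"],
                    predicted_label=rec["predicted_label"],
                    predicted_sentences=tuple(rec["predicted_sentences"]),
                    attempts=int(rec["attempts"]),
                    parse_status=ParseStatus(rec["parse_status"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise DatasetError(f"{path}:{lineno}: bad prediction record: {exc}") from exc
    return out


TokenizerHook = Callable[[str], Sequence[str]]


def whitespace_tokens(text: str) -> list[str]:
    """Default tokenizer hook: whitespace tokens.

    Report-length targets in the dataset profiles are matched in whitespace
    tokens; a subword tokenizer can be substituted through the hook where
    LLM-tokenizer counts are wanted.
    """
    return text.split()
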