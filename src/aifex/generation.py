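"""Decoding control and structured-output parsing.

The generation backend is an abstract interface (prompt + decoding
config + seed -> raw text); this module owns everything around it: the
rule-based artefact stripper that uncovers a JSON payload inside chatty
output, strict schema validation, the lenient whitespace parser for
free-text outputs, and the *hybrid* retry controller — greedy decoding
first, then nucleus-sampling fallbacks (temperature = top_p = 0.5) with
per-attempt derived seeds, stopping at the first valid parse or
returning a parsable null answer when the attempt budget is exhausted so
that malformed output never propagates downstream.
"""

from __future__ import annotations

import abc
import json
from dataclasses import dataclass, field
from typing import Sequence

from .core import AifexError, Dataset, ExtractionResult, ParseStatus, Report
from .evaluation import ParsingErrorTally, tally_parsing_errors
from .prompting import (
    LABEL_PREFIX,
    NEGATIVE_MARKER,
    PromptStrategy,
    PromptTemplate,
    build_prompt,
)

DECODING_METHODS = ("greedy", "nucleus", "beam", "hybrid")


class BackendError(AifexError):
    """A backend failed to generate; carries report context."""


@dataclass(frozen=True)
class DecodingConfig:
    """Decoding strategy and its parameters.

    Method-irrelevant fields are ignored.  Hybrid defaults: one greedy
    attempt plus up to five nucleus fallbacks at temperature = top_p = 0.5
    (``max_attempts=6`` total).
    """

    method: str = "hybrid"
    temperature: float = 0.5
    top_p: float = 0.5
    num_beams: int = 4
    max_attempts: int = 6
    fallback_temperature: float = 0.5
    fallback_top_p: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in DECODING_METHODS:
            raise AifexError(f"unknown decoding method {self.method!r}")
        if self.method == "nucleus" and not (self.temperature > 0 and 0 < self.top_p <= 1):
            raise AifexError("nucleus sampling needs temperature > 0 and top_p in (0, 1]")
        if self.method == "beam" and self.num_beams < 2:
            raise AifexError("beam search needs num_beams >= 2")
        if self.max_attempts < 1:
            raise AifexError("max_attempts must be >= 1")


class GenerationBackend(abc.ABC):
    """Text-generation contract.

    Greedy decoding must be deterministic for a fixed prompt; sampling
    methods must be deterministic for a fixed (prompt, seed).  Chat/
    instruction formatting is the backend's concern, not the caller's.
    """

    @abc.abstractmethod
    def generate(self, prompt: str, config: DecodingConfig, seed: int) -> str:
        """Return the raw generation for one prompt."""


@dataclass
class ParsedAnswer:
    """Validated interpretation of one raw generation."""

    valid: bool
    label: bool | None = None
    sentences: tuple[str, ...] = ()


@dataclass
class StripResult:
    text: str
    found: bool  # False when no brace-balanced span was present


def _balanced_span(text: str) -> tuple[int, int] | None:
    """First outermost brace-balanced span, honouring JSON string quoting."""
    depth = 0
    start = None
    in_str = False
    esc = False
    for i, ch in enumerate(text):
        if in_str:
            if esc:
                esc = False
            elif ch == "\\":
                esc = True
            elif ch == '"':
                in_str = False
            continue
        if depth > 0 and ch == '"':
            in_str = True
        elif ch == "{":
            if depth == 0:
                start = i
            depth += 1
        elif ch == "}" and depth > 0:
            depth -= 1
            if depth == 0:
                assert start is not None
                return start, i + 1
    return None


def strip_artefacts(raw: str) -> StripResult:
    """Remove decoration around a JSON payload.

    Drops code-fence markers, any prose before/after the first outermost
    brace-balanced span, and trailing repetition after the first complete
    object.  When no balanced span exists the input is returned unchanged
    with ``found=False``.  Idempotent: a bare object maps to itself.
    """
    cleaned = raw.replace("```json", " ").replace("```", " ")
    span = _balanced_span(cleaned)
    if span is None:
        return StripResult(text=raw, found=False)
    return StripResult(text=cleaned[span[0] : span[1]], found=True)


def _validate_schema(obj: object, strategy: PromptStrategy) -> ParsedAnswer:
    if not isinstance(obj, dict):
        return ParsedAnswer(valid=False)
    expected_keys = (
        {"actionable_findings_present", "aif_sentences"}
        if strategy.reasoning == "cot"
        else {"aif_sentences"}
    )
    if set(obj) != expected_keys:
        return ParsedAnswer(valid=False)
    sents = obj["aif_sentences"]
    if not isinstance(sents, list) or not all(isinstance(s, str) for s in sents):
        return ParsedAnswer(valid=False)
    if strategy.reasoning == "cot":
        label = obj["actionable_findings_present"]
        if not isinstance(label, bool):
            return ParsedAnswer(valid=False)
    else:
        label = len(sents) > 0  # label derived from whether any AIFs are returned
    return ParsedAnswer(valid=True, label=label, sentences=tuple(sents))


def parse_answer(
    raw: str, strategy: PromptStrategy, negative_marker: str = NEGATIVE_MARKER
) -> ParsedAnswer:
    """Interpret a raw generation under a strategy's output contract.

    JSON formats: strip artefacts, strict ``json.loads``, then schema
    validation — exactly the required keys, boolean label (chain-of-thought
    only), list of strings.  Any violation yields ``valid=False``; retries
    are the controller's job, so nothing raises.

    Free-text formats use the lenient whitespace parser: non-empty lines
    are sentences, the negative marker maps to an empty answer, and a
    leading ``Label:`` line (chain-of-thought) sets the document label;
    otherwise the label derives from sentence presence.
    """
    if strategy.output_format == "json":
        stripped = strip_artefacts(raw)
        if not stripped.found:
            return ParsedAnswer(valid=False)
        try:
            obj = json.loads(stripped.text)
        except json.JSONDecodeError:
            return ParsedAnswer(valid=False)
        return _validate_schema(obj, strategy)

    lines = [ln.strip() for ln in raw.splitlines() if ln.strip()]
    label: bool | None = None
    if lines and lines[0].startswith(LABEL_PREFIX):
        word = lines[0][len(LABEL_PREFIX) :].strip().lower()
        if word in ("positive", "negative"):
            label = word == "positive"
        lines = lines[1:]
    sentences = tuple(ln for ln in lines if ln != negative_marker)
    if label is None:
        label = len(sentences) > 0
    return ParsedAnswer(valid=True, label=label, sentences=sentences)


NULL_ANSWER = "null"  # the JSON-parsable null emitted on attempt exhaustion


def _attempt_config(config: DecodingConfig, attempt: int) -> DecodingConfig:
    """Decoding parameters for one hybrid attempt (1-based)."""
    if config.method != "hybrid":
        return config
    if attempt == 1:
        return DecodingConfig(method="greedy", max_attempts=config.max_attempts)
    return DecodingConfig(
        method="nucleus",
        temperature=config.fallback_temperature,
        top_p=config.fallback_top_p,
        max_attempts=config.max_attempts,
    )


def extract(
    report: Report,
    template: PromptTemplate,
    backend: GenerationBackend,
    config: DecodingConfig,
    seed: int,
) -> ExtractionResult:
    """Run the decoding controller for one report.

    Hybrid: attempt 1 is greedy; attempts 2..max_attempts are nucleus at
    the fallback temperature/top_p with per-attempt seeds ``seed +
    attempt_index``, stopping at the first valid parse (status ``ok`` on
    attempt 1, ``recovered`` later).  Exhaustion returns the parsable null
    answer (status ``fatal_null``), which evaluation scores as incorrect.
    Non-hybrid methods make a single attempt.
    """
    prompt = build_prompt(report, template)
    n_attempts = config.max_attempts if config.method == "hybrid" else 1
    raw_outputs: list[str] = []
    for attempt in range(1, n_attempts + 1):
        attempt_cfg = _attempt_config(config, attempt)
        try:
            raw = backend.generate(prompt, attempt_cfg, seed + attempt - 1)
        except Exception as exc:  # noqa: BLE001 - wrap with report context
            raise BackendError(f"backend failed on report {report.report_id!r}: {exc}") from exc
        raw_outputs.append(raw)
        answer = parse_answer(raw, template.strategy)
        if answer.valid:
            status = ParseStatus.OK if attempt == 1 else ParseStatus.RECOVERED
            return ExtractionResult(
                report_id=report.report_id,
                predicted_label=answer.label,
                predicted_sentences=answer.sentences,
                attempts=attempt,
                parse_status=status,
                raw_generations=tuple(raw_outputs),
            )
    raw_outputs.append(NULL_ANSWER)
    return ExtractionResult(
        report_id=report.report_id,
        predicted_label=None,
        predicted_sentences=(),
        attempts=n_attempts,
        parse_status=ParseStatus.FATAL_NULL,
        raw_generations=tuple(raw_outputs),
    )


@dataclass
class ExtractionRun:
    results: list[ExtractionResult] = field(default_factory=list)
    tally: ParsingErrorTally = field(default_factory=ParsingErrorTally)


def run_extraction(
    dataset: Dataset,
    template: PromptTemplate,
    backend: GenerationBackend,
    config: DecodingConfig,
    seed: int,
) -> ExtractionRun:
    """Extract every report in dataset order and tally parsing errors.

    The tally counts reports that needed at least one retry and, among
    them, the fatal nulls — both readings of a "parsing error" count.
    """
    results = [extract(r, template, backend, config, seed) for r in dataset.reports]
    return ExtractionRun(results=results, tally=tally_parsing_errors(results))
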