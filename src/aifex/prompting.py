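"""Prompt construction for AIF extraction.

Four prompt strategies are supported, crossing the reasoning framing
(standard extraction vs chain-of-thought document classification with
sentence extraction as the intermediate step) with the output format
(JSON vs free text):

    "Standard—JSON", "CoT—JSON", "Standard", "CoT"

The instruction texts live as editable assets under ``templates/`` with
the literal placeholder ``<REPORT TEXT HERE>`` marking where report text
is inserted, verbatim and unescaped.  Chat/instruction-template
application (system/user roles, special tokens) is deliberately left to
the generation backend via a hook, since it differs per model family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable

from .core import AifexError, GoldAnnotation, Report

PLACEHOLDER = "<REPORT TEXT HERE>"

#: Free-text rendering of "no findings" (configurable at the parse site).
NEGATIVE_MARKER = "NONE"

#: Free-text chain-of-thought label line prefix.
LABEL_PREFIX = "Label:"


class TemplateError(AifexError):
    """Instruction text violates the template contract."""


@dataclass(frozen=True)
class PromptStrategy:
    """One of the four reasoning × output-format combinations."""

    reasoning: str  # "standard" | "cot"
    output_format: str  # "json" | "free_text"

    def __post_init__(self) -> None:
        if self.reasoning not in ("standard", "cot"):
            raise TemplateError(f"unknown reasoning {self.reasoning!r}")
        if self.output_format not in ("json", "free_text"):
            raise TemplateError(f"unknown output format {self.output_format!r}")

    @property
    def name(self) -> str:
        base = "CoT" if self.reasoning == "cot" else "Standard"
        return f"{base}—JSON" if self.output_format == "json" else base


#: Registry of the four strategies by display name and by CLI-friendly key.
STRATEGIES: dict[str, PromptStrategy] = {}
for _strategy, _key, _asset in (
    (PromptStrategy("standard", "json"), "standard-json", "standard_json.txt"),
    (PromptStrategy("cot", "json"), "cot-json", "cot_json.txt"),
    (PromptStrategy("standard", "free_text"), "standard", "standard.txt"),
    (PromptStrategy("cot", "free_text"), "cot", "cot.txt"),
):
    STRATEGIES[_strategy.name] = _strategy
    STRATEGIES[_key] = _strategy

_ASSETS = {
    "standard-json": "standard_json.txt",
    "cot-json": "cot_json.txt",
    "standard": "standard.txt",
    "cot": "cot.txt",
}


def strategy_key(strategy: PromptStrategy) -> str:
    base = "cot" if strategy.reasoning == "cot" else "standard"
    return f"{base}-json" if strategy.output_format == "json" else base


def resolve_strategy(name: str | PromptStrategy) -> PromptStrategy:
    """Look up a strategy by display name ("CoT—JSON") or key ("cot-json")."""
    if isinstance(name, PromptStrategy):
        return name
    try:
        return STRATEGIES[name]
    except KeyError:
        raise TemplateError(
            f"unknown prompt strategy {name!r}; choose from {sorted(_ASSETS)}"
        ) from None


@dataclass(frozen=True)
class PromptTemplate:
    """An instruction text with exactly one report placeholder."""

    strategy: PromptStrategy
    instruction_text: str
    target_schema_hint: str = ""

    def __post_init__(self) -> None:
        count = self.instruction_text.count(PLACEHOLDER)
        if count != 1:
            raise TemplateError(
                f"instruction text must contain {PLACEHOLDER!r} exactly once, found {count}"
            )


def load_template(strategy: str | PromptStrategy) -> PromptTemplate:
    """Load the shipped instruction asset for a strategy."""
    strat = resolve_strategy(strategy)
    asset = _ASSETS[strategy_key(strat)]
    text = (resources.files("aifex") / "templates" / asset).read_text(encoding="utf-8")
    if strat.output_format == "json":
        hint = (
            '{"actionable_findings_present": bool, "aif_sentences": [str, ...]}'
            if strat.reasoning == "cot"
            else '{"aif_sentences": [str, ...]}'
        )
    else:
        hint = f"one sentence per line; {NEGATIVE_MARKER} when empty"
    return PromptTemplate(strategy=strat, instruction_text=text, target_schema_hint=hint)


def build_prompt(report: Report, template: PromptTemplate) -> str:
    """Insert the report text into the template, verbatim, exactly once.

    No escaping or other mutation: braces and quotes inside the report
    survive untouched (the parser, not the prompt, owns robustness).
    """
    return template.instruction_text.replace(PLACEHOLDER, report.text)


def canonical_json(obj: dict) -> str:
    """Deterministic JSON rendering: sorted keys, fixed separators."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def render_target(gold: GoldAnnotation, strategy: PromptStrategy) -> str:
    """Render the gold answer in a strategy's output format.

    JSON formats use the canonical output schema serialised
    deterministically; free-text formats newline-join the sentences (with
    ``NONE`` for an empty answer), and the chain-of-thought variant leads
    with the document label line.
    """
    sentences = list(gold.aif_sentences)
    if strategy.output_format == "json":
        if strategy.reasoning == "cot":
            return canonical_json(
                {"actionable_findings_present": gold.doc_label, "aif_sentences": sentences}
            )
        return canonical_json({"aif_sentences": sentences})
    body = "\n".join(sentences) if sentences else NEGATIVE_MARKER
    if strategy.reasoning == "cot":
        label = "positive" if gold.doc_label else "negative"
        return f"{LABEL_PREFIX} {label}\n{body}"
    return body


def build_training_example(
    report: Report, gold: GoldAnnotation, template: PromptTemplate
) -> tuple[str, str]:
    """(input, target) pair for supervised fine-tuning on next-token loss."""
    if gold.report_id != report.report_id:
        raise AifexError(
            f"gold annotation {gold.report_id!r} does not belong to report {report.report_id!r}"
        )
    return build_prompt(report, template), render_target(gold, template.strategy)


#: Hook type for backend-specific chat/instruction formatting; identity here.
ChatTemplateHook = Callable[[str], str]
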