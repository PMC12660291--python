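"""Fixture generation backends.

Two deterministic backends stand behind the :class:`GenerationBackend`
interface for testing the controller and the evaluation stack without a
GPU or model weights:

* :class:`ScriptedBackend` — an explicit prompt -> [outputs] table whose
  entries are consumed one per attempt; exercises the retry controller.
* :class:`OracleBackend` — renders the gold annotation of the report
  embedded in the prompt, optionally perturbed in controlled ways
  (boundary trims, artefact wrapping, dropped duplicate references,
  distractor insertion, label flips, invalid attempts, ungrounded
  sentences), so end-to-end runs have known expected scores.

A real LLM adapter lives in :mod:`aifex.hf` as an optional extra.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import Dataset, GoldAnnotation, Report
from .evaluation import normalize_sentence
from .generation import BackendError, DecodingConfig, GenerationBackend
from .prompting import PromptStrategy, canonical_json


class ScriptedBackend(GenerationBackend):
    """Replays a fixed table of outputs.

    ``script`` maps a prompt to the sequence of raw outputs returned on
    successive calls for that prompt (the last entry repeats once
    exhausted).  A plain sequence applies to every prompt.  Decoding
    config and seed are recorded but do not alter the output, which makes
    controller behaviour fully predictable.
    """

    def __init__(self, script: Mapping[str, Sequence[str]] | Sequence[str]):
        self._script = script
        self._calls: dict[str, int] = {}
        self.call_log: list[tuple[str, str, int]] = []  # (prompt, method, seed)

    def generate(self, prompt: str, config: DecodingConfig, seed: int) -> str:
        if isinstance(self._script, Mapping):
            if prompt not in self._script:
                raise BackendError("no scripted outputs for this prompt")
            outputs = self._script[prompt]
        else:
            outputs = self._script
        idx = self._calls.get(prompt, 0)
        self._calls[prompt] = idx + 1
        self.call_log.append((prompt, config.method, seed))
        return outputs[min(idx, len(outputs) - 1)]


@dataclass(frozen=True)
class OraclePerturbations:
    """Controlled corruption rates for the oracle backend (all default off).

    Probabilities apply per sentence or per report as noted; everything is
    deterministic given the backend seed and report id.

    - ``boundary_trim`` (per sentence): decorate sentence edges with list
      numerals/punctuation only — within the reach of evaluation
      normalization, so metrics should be unaffected.
    - ``boundary_word_drop`` (per sentence): drop the trailing word — a
      boundary disagreement *beyond* normalization, producing a paired
      FP/FN (a soft boundary error).
    - ``duplicate_drop`` (per sentence): drop a later reference to an
      already-emitted finding (soft multiple-reference error).
    - ``distractor_insert`` (per report): add a grounded non-gold sentence
      from the report (hard false positive).
    - ``label_flip`` (per report): answer as if the document label were
      inverted (positive -> empty answer; negative -> one distractor).
    - ``artefact_wrap`` (per report): wrap the JSON payload in code fences
      and prose; the artefact stripper must recover it on attempt 1.
    - ``invalid_attempts``: emit unparsable output on this many leading
      attempts per report, exercising the hybrid fallback.
    - ``hallucinate`` (per report): add a fabricated sentence absent from
      the report text (must trip the grounding audit).
    """

    boundary_trim: float = 0.0
    boundary_word_drop: float = 0.0
    duplicate_drop: float = 0.0
    distractor_insert: float = 0.0
    label_flip: float = 0.0
    artefact_wrap: float = 0.0
    invalid_attempts: int = 0
    hallucinate: float = 0.0


HALLUCINATED_SENTENCE = "A fabricated lesion is described that appears nowhere in the report."


def _token_set(s: str) -> set[str]:
    return {t for t in "".join(c if c.isalpha() else " " for c in s.lower()).split() if t}


def _jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


class OracleBackend(GenerationBackend):
    """Answers from gold annotations, with optional perturbations.

    The backend locates the report whose text is embedded in the prompt
    (prompt construction inserts it verbatim), renders the gold answer in
    the strategy's output format, and applies the configured
    perturbations.  With all perturbations off the rendered answer is the
    gold answer, so a full pipeline run scores 1.0 everywhere.
    """

    def __init__(
        self,
        dataset: Dataset,
        strategy: PromptStrategy,
        perturbations: OraclePerturbations | None = None,
    ):
        self._dataset = dataset
        self._strategy = strategy
        self._perturb = perturbations or OraclePerturbations()
        self._prompt_cache: dict[str, Report] = {}
        self._attempt_counts: dict[str, int] = {}

    def _resolve_report(self, prompt: str) -> Report:
        if prompt in self._prompt_cache:
            return self._prompt_cache[prompt]
        best: Report | None = None
        for rep in self._dataset.reports:
            if rep.text and rep.text in prompt:
                if best is None or len(rep.text) > len(best.text):
                    best = rep
        if best is None:
            raise BackendError("prompt does not embed any known report text")
        self._prompt_cache[prompt] = best
        return best

    def _perturb_sentences(
        self, gold: GoldAnnotation, report: Report, rng: random.Random
    ) -> list[str]:
        p = self._perturb
        out: list[str] = []
        kept_tokens: list[set[str]] = []
        for sent in gold.aif_sentences:
            toks = _token_set(sent)
            if p.duplicate_drop and any(
                _jaccard(toks, prev) >= 0.6 for prev in kept_tokens
            ) and rng.random() < p.duplicate_drop:
                continue
            kept_tokens.append(toks)
            if p.boundary_word_drop and rng.random() < p.boundary_word_drop:
                # drop the trailing word: a boundary disagreement beyond the
                # reach of edge normalization, while the leading measurement
                # keeps same-template findings distinct after normalization
                words = sent.split()
                if len(words) > 2:
                    sent = " ".join(words[:-1])
            if p.boundary_trim and rng.random() < p.boundary_trim:
                sent = f"{rng.randrange(1, 9)}. {sent.rstrip('.')}"
            out.append(sent)
        if p.distractor_insert and rng.random() < p.distractor_insert:
            distractor = self._pick_distractor(gold, report)
            if distractor is not None:
                out.append(distractor)
        if p.hallucinate and rng.random() < p.hallucinate:
            out.append(HALLUCINATED_SENTENCE)
        return out

    def _pick_distractor(self, gold: GoldAnnotation, report: Report) -> str | None:
        gold_norm = {normalize_sentence(s) for s in gold.aif_sentences}
        for sent in report.sentences:
            norm = normalize_sentence(sent)
            if not norm or norm in gold_norm or sent.endswith(":"):
                continue
            # prefer a plausible-looking incidental over pure boilerplate
            if "No " in sent or sent.startswith("No"):
                continue
            if "Clinical details" in sent or "Technique" in sent or "Comparison" in sent:
                continue
            return sent
        return None

    def generate(self, prompt: str, config: DecodingConfig, seed: int) -> str:
        report = self._resolve_report(prompt)
        attempt_idx = self._attempt_counts.get(report.report_id, 0)
        self._attempt_counts[report.report_id] = attempt_idx + 1
        if attempt_idx < self._perturb.invalid_attempts:
            return 'The model rambles and emits broken output {"aif_sentences": ['
        gold = self._dataset.annotations.get(report.report_id) or GoldAnnotation(
            report.report_id, ()
        )
        # Perturbation decisions depend only on (base seed, report), not the
        # attempt index, so retries answer consistently.
        base_seed = seed - attempt_idx
        rng = random.Random(f"{base_seed}:{report.report_id}")
        if self._perturb.label_flip and rng.random() < self._perturb.label_flip:
            if gold.doc_label:
                sentences: list[str] = []
            else:
                distractor = self._pick_distractor(gold, report)
                sentences = [distractor] if distractor else [report.sentences[0]]
        else:
            sentences = self._perturb_sentences(gold, report, rng)
        answer = render_answer(self._strategy, sentences)
        if self._perturb.artefact_wrap and rng.random() < self._perturb.artefact_wrap:
            if self._strategy.output_format == "json":
                answer = f"Here is the answer:\n```json\n{answer}\n```\nHope this helps."
        return answer


def render_answer(strategy: PromptStrategy, sentences: Sequence[str]) -> str:
    """Render a (possibly perturbed) sentence list in a strategy's format."""
    if strategy.output_format == "json":
        if strategy.reasoning == "cot":
            return canonical_json(
                {"actionable_findings_present": bool(sentences), "aif_sentences": list(sentences)}
            )
        return canonical_json({"aif_sentences": list(sentences)})
    from .prompting import LABEL_PREFIX, NEGATIVE_MARKER

    body = "\n".join(sentences) if sentences else NEGATIVE_MARKER
    if strategy.reasoning == "cot":
        label = "positive" if sentences else "negative"
        return f"{LABEL_PREFIX} {label}\n{body}"
    return body
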