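"""Soft/hard error taxonomy for sentence-level mismatches.

Automatic exact-match scoring (even after normalization) penalises some
extractions that a clinician would accept.  This module classifies every
false positive / false negative sentence from a run into a taxonomy of
*soft* errors — mismatches that would not realistically affect clinical
practice — and *hard* errors that would:

soft:
    ``boundary_soft``            sentence-boundary disagreement (one side
                                 is a substring of the other);
    ``text_artefact_soft``       same content modulo case/whitespace
                                 artefacts;
    ``multiple_reference_soft``  a missed *second* reference to a finding
                                 that was otherwise extracted;
hard:
    ``hard_false_positive``      extracted sentence not annotated as an
                                 AIF (covers both contextual
                                 misinterpretation of actionability and
                                 plain non-findings — text alone cannot
                                 separate them);
    ``missed_aif_hard``          gold AIF with no corresponding output;
    ``ungrounded``               extracted sentence not locatable in the
                                 report text (a hallucination).

``summarize_errors`` also recomputes sentence metrics with soft errors
forgiven, giving the "real-world" performance estimate that the strict
automatic metrics lower-bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .core import AifexError, Dataset, ExtractionResult, GoldAnnotation, Report, collapse_ws
from .evaluation import match_sentences, normalize_sentence


class ErrorKind(str, Enum):
    BOUNDARY_SOFT = "boundary_soft"
    MULTIPLE_REFERENCE_SOFT = "multiple_reference_soft"
    TEXT_ARTEFACT_SOFT = "text_artefact_soft"
    HARD_FALSE_POSITIVE = "hard_false_positive"
    MISSED_AIF_HARD = "missed_aif_hard"
    UNGROUNDED = "ungrounded"


SOFT_KINDS = frozenset(
    {ErrorKind.BOUNDARY_SOFT, ErrorKind.MULTIPLE_REFERENCE_SOFT, ErrorKind.TEXT_ARTEFACT_SOFT}
)

#: Kinds whose record covers an (FP, FN) *pair* rather than a single mismatch.
PAIR_KINDS = frozenset({ErrorKind.BOUNDARY_SOFT, ErrorKind.TEXT_ARTEFACT_SOFT})


@dataclass(frozen=True)
class ErrorRecord:
    report_id: str
    kind: ErrorKind
    gold_sentence: str | None = None
    pred_sentence: str | None = None

    def __post_init__(self) -> None:
        if self.kind in PAIR_KINDS and not (self.gold_sentence and self.pred_sentence):
            raise AifexError(f"{self.kind.value} records need both sentences")
        if self.kind is ErrorKind.MISSED_AIF_HARD and self.pred_sentence is not None:
            raise AifexError("missed_aif_hard records carry the gold sentence only")
        if (
            self.kind in (ErrorKind.HARD_FALSE_POSITIVE, ErrorKind.UNGROUNDED)
            and self.gold_sentence is not None
        ):
            raise AifexError(f"{self.kind.value} records carry the predicted sentence only")


def _extended_norm(s: str) -> str:
    """Lowercase + interior-whitespace collapse on top of edge normalization."""
    return collapse_ws(normalize_sentence(s)).lower()


def _alpha_tokens(s: str) -> set[str]:
    return {t for t in "".join(c if c.isalpha() else " " for c in s.lower()).split() if t}


def _jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def classify_errors(
    gold: GoldAnnotation,
    pred: ExtractionResult,
    report: Report,
    jaccard_threshold: float = 0.6,
) -> list[ErrorRecord]:
    """Partition one report's FP/FN sentences into taxonomy kinds.

    Deterministic rule cascade over the normalized FP/FN sets, soft rules
    before hard so that a benign reading wins where one exists:

    (a) boundary: FP/FN pairs where one normalized string contains the
        other, consumed greedily by longest overlap (ties by report
        order); (b) text artefact: FP equal to an FN after lowercasing and
        whitespace collapse; (c) multiple reference: FN whose alphabetic
        token-set Jaccard with a matched (true-positive) gold sentence of
        the same report reaches ``jaccard_threshold``; (d) ungrounded: FP
        not locatable in the report text; (e) everything left is hard.
    """
    if not (gold.report_id == pred.report_id == report.report_id):
        raise AifexError("gold/prediction/report ids do not match")
    match = match_sentences(gold, pred)
    fps = list(match.false_positives)  # normalized forms, prediction order
    fns = list(match.false_negatives)  # normalized forms, gold order
    records: list[ErrorRecord] = []

    # (a) boundary pairs, greedy by longest containment overlap
    pairs: list[tuple[int, int, int]] = []  # (overlap, fp_idx, fn_idx)
    for i, fp in enumerate(fps):
        for j, fn in enumerate(fns):
            if fp in fn or fn in fp:
                pairs.append((min(len(fp), len(fn)), i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_fp: set[int] = set()
    used_fn: set[int] = set()
    for _, i, j in pairs:
        if i in used_fp or j in used_fn:
            continue
        used_fp.add(i)
        used_fn.add(j)
        records.append(
            ErrorRecord(report.report_id, ErrorKind.BOUNDARY_SOFT, fns[j], fps[i])
        )

    # (b) text artefacts among the remainder
    for i, fp in enumerate(fps):
        if i in used_fp:
            continue
        for j, fn in enumerate(fns):
            if j in used_fn:
                continue
            if _extended_norm(fp) == _extended_norm(fn):
                used_fp.add(i)
                used_fn.add(j)
                records.append(
                    ErrorRecord(report.report_id, ErrorKind.TEXT_ARTEFACT_SOFT, fn, fp)
                )
                break

    # (c) multiple-reference misses against matched gold sentences
    tp_tokens = [_alpha_tokens(s) for s in match.true_positives]
    for j, fn in enumerate(fns):
        if j in used_fn:
            continue
        if any(_jaccard(_alpha_tokens(fn), t) >= jaccard_threshold for t in tp_tokens):
            used_fn.add(j)
            records.append(
                ErrorRecord(report.report_id, ErrorKind.MULTIPLE_REFERENCE_SOFT, gold_sentence=fn)
            )

    # (d)/(e) remaining FPs: ungrounded, else hard
    haystack = collapse_ws(report.text)
    for i, fp in enumerate(fps):
        if i in used_fp:
            continue
        kind = (
            ErrorKind.HARD_FALSE_POSITIVE
            if collapse_ws(fp) in haystack
            else ErrorKind.UNGROUNDED
        )
        records.append(ErrorRecord(report.report_id, kind, pred_sentence=fp))

    # (e) remaining FNs are missed AIFs
    for j, fn in enumerate(fns):
        if j in used_fn:
            continue
        records.append(ErrorRecord(report.report_id, ErrorKind.MISSED_AIF_HARD, gold_sentence=fn))

    return records


@dataclass
class ErrorSummary:
    """Corpus-level taxonomy counts and soft-forgiven metrics.

    ``record_counts`` counts records per kind (a boundary/text-artefact
    record covers one FP *and* one FN); ``covered_mismatches`` therefore
    equals total FP + FN when pair kinds are weighted by two.  The
    adjusted metrics treat soft errors as correct: each soft pair converts
    to a true positive, and multiple-reference misses leave recall's
    denominator (their content is already credited).
    """

    record_counts: dict[str, int]
    soft_records: int
    hard_records: int
    covered_mismatches: int
    total_mismatches: int
    unadjusted: dict[str, float]
    adjusted: dict[str, float]


def _prf(tp: int, fp: int, fn: int) -> dict[str, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return {"precision": p, "recall": r, "f1": f}


def summarize_errors(
    dataset: Dataset,
    results: Sequence[ExtractionResult],
    jaccard_threshold: float = 0.6,
) -> tuple[list[ErrorRecord], ErrorSummary]:
    """Classify every mismatch in a run and summarise.

    Returns the per-record list (for review) and the corpus summary with
    both strict and soft-forgiven sentence metrics; the adjusted scores
    can only be at least the unadjusted ones.
    """
    by_id = {r.report_id: r for r in dataset.reports}
    all_records: list[ErrorRecord] = []
    tp = fp = fn = 0
    for res in results:
        ann = dataset.annotations.get(res.report_id)
        if ann is None:
            raise AifexError(f"no gold annotation for report {res.report_id!r}")
        report = by_id[res.report_id]
        m = match_sentences(ann, res)
        tp += m.tp
        fp += m.fp
        fn += m.fn
        all_records.extend(classify_errors(ann, res, report, jaccard_threshold))

    counts = {kind.value: 0 for kind in ErrorKind}
    for rec in all_records:
        counts[rec.kind.value] += 1
    n_pair = counts[ErrorKind.BOUNDARY_SOFT.value] + counts[ErrorKind.TEXT_ARTEFACT_SOFT.value]
    n_multiref = counts[ErrorKind.MULTIPLE_REFERENCE_SOFT.value]
    soft = sum(counts[k.value] for k in SOFT_KINDS)
    hard = sum(counts[k.value] for k in ErrorKind if k not in SOFT_KINDS)
    covered = sum(
        counts[k.value] * (2 if k in PAIR_KINDS else 1) for k in ErrorKind
    )

    adj_tp = tp + n_pair
    adj_fp = fp - n_pair
    adj_fn = fn - n_pair - n_multiref
    summary = ErrorSummary(
        record_counts=counts,
        soft_records=soft,
        hard_records=hard,
        covered_mismatches=covered,
        total_mismatches=fp + fn,
        unadjusted=_prf(tp, fp, fn),
        adjusted=_prf(adj_tp, adj_fp, adj_fn),
    )
    return all_records, summary
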