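"""Two-tier evaluation of AIF extraction.

Document level: binary classification of each report (AIF present /
absent), scored with accuracy plus macro-averaged precision, recall and
F1 — both classes matter clinically, so neither dominates the average.

Sentence level: extracted sentences are compared to gold sentences by
exact string match after *normalization* — stripping whitespace,
punctuation and digits from both ends — which forgives benign sentence-
boundary disagreements such as a dropped numbered-list numeral while
still guaranteeing that anything scored correct is semantically exact.
Sentence scores are micro (corpus-pooled), with no macro-averaging.

Also here: multi-seed aggregation (mean and t-based 95% CI across runs)
and Cohen's kappa for two-rater agreement on binary labels.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Mapping, Sequence

from scipy import stats as _stats

from .core import (
    AifexError,
    Dataset,
    ExtractionResult,
    GoldAnnotation,
    ParseStatus,
    collapse_ws,
)

#: Characters stripped from sentence edges: ASCII punctuation plus the
#: unicode dashes/quotes/ellipsis that word processors substitute.
#: Frozen here; the whole normalization contract depends on this one set.
EDGE_PUNCTUATION = string.punctuation + "–—‘’“”…«»°"

_EDGE_CHARS = frozenset(string.whitespace + string.digits + EDGE_PUNCTUATION)


def normalize_sentence(s: str) -> str:
    """Strip leading/trailing whitespace, punctuation and digits.

    Interior content (including interior digits such as a "2.1 cm"
    measurement) is untouched; case is preserved.  Idempotent.
    """
    lo, hi = 0, len(s)
    while lo < hi and s[lo] in _EDGE_CHARS:
        lo += 1
    while hi > lo and s[hi - 1] in _EDGE_CHARS:
        hi -= 1
    return s[lo:hi]


def normalized_set(sentences: Sequence[str]) -> dict[str, str]:
    """Map normalized form -> first original, dropping empty normalizations."""
    out: dict[str, str] = {}
    for s in sentences:
        norm = normalize_sentence(s)
        if norm and norm not in out:
            out[norm] = s
    return out


@dataclass
class SentenceMatchResult:
    """Per-report sentence match outcome (normalized, deduplicated)."""

    report_id: str
    true_positives: list[str]
    false_positives: list[str]
    false_negatives: list[str]

    @property
    def tp(self) -> int:
        return len(self.true_positives)

    @property
    def fp(self) -> int:
        return len(self.false_positives)

    @property
    def fn(self) -> int:
        return len(self.false_negatives)


def match_sentences(gold: GoldAnnotation, pred: ExtractionResult) -> SentenceMatchResult:
    """Match predicted sentences against gold by normalized exact equality.

    Both sides are normalized then deduplicated per report (set semantics:
    no double credit for repeated sentences).  A ``fatal_null`` prediction
    contributes no TP/FP and every gold sentence as FN.  The stored
    sentence lists are in gold order (TP/FN) and prediction order (FP),
    using normalized forms.
    """
    if gold.report_id != pred.report_id:
        raise AifexError(
            f"report_id mismatch: gold {gold.report_id!r} vs prediction {pred.report_id!r}"
        )
    gold_norm = normalized_set(gold.aif_sentences)
    pred_norm = normalized_set(pred.predicted_sentences)
    tp = [g for g in gold_norm if g in pred_norm]
    fn = [g for g in gold_norm if g not in pred_norm]
    fp = [p for p in pred_norm if p not in gold_norm]
    return SentenceMatchResult(gold.report_id, tp, fp, fn)


def derive_doc_label(sentences: Sequence[str]) -> bool:
    """Document label from a sentence list: positive iff non-empty."""
    return bool(list(sentences))


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision/recall/F1 with zero-denominator convention P=R=F1=0."""
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


@dataclass
class ParsingErrorTally:
    """Reports that needed at least one retry, and fatal nulls among them."""

    reports_retried: int = 0
    fatal_nulls: int = 0

    def as_tuple(self) -> tuple[int, int]:
        return (self.reports_retried, self.fatal_nulls)


def tally_parsing_errors(results: Sequence[ExtractionResult]) -> ParsingErrorTally:
    retried = sum(1 for r in results if r.parse_status is not ParseStatus.OK)
    fatal = sum(1 for r in results if r.parse_status is ParseStatus.FATAL_NULL)
    return ParsingErrorTally(reports_retried=retried, fatal_nulls=fatal)


@dataclass
class MetricsReport:
    """Document-level (macro) and sentence-level (micro) scores for one run."""

    doc_precision_macro: float
    doc_recall_macro: float
    doc_f1_macro: float
    doc_accuracy: float
    doc_confusion: dict[str, int]  # keys tp, fp, tn, fn (positive = AIF present)
    sent_precision: float
    sent_recall: float
    sent_f1: float
    sent_counts: dict[str, int]  # keys tp, fp, fn
    parsing_errors: ParsingErrorTally = field(default_factory=ParsingErrorTally)

    def as_flat_dict(self) -> dict[str, float]:
        return {
            "doc_precision_macro": self.doc_precision_macro,
            "doc_recall_macro": self.doc_recall_macro,
            "doc_f1_macro": self.doc_f1_macro,
            "doc_accuracy": self.doc_accuracy,
            "sent_precision": self.sent_precision,
            "sent_recall": self.sent_recall,
            "sent_f1": self.sent_f1,
        }

    def as_dict(self) -> dict:
        out: dict = dict(self.as_flat_dict())
        out["doc_confusion"] = dict(self.doc_confusion)
        out["sent_counts"] = dict(self.sent_counts)
        out["parsing_errors"] = {
            "reports_retried": self.parsing_errors.reports_retried,
            "fatal_nulls": self.parsing_errors.fatal_nulls,
        }
        return out


def effective_doc_label(gold_label: bool, result: ExtractionResult) -> bool:
    """Predicted document label as scored.

    A fatal-null answer carries no label and is scored incorrect against
    either gold label, realised as the complement of the gold label so the
    confusion matrix still sums to the number of reports.
    """
    if result.parse_status is ParseStatus.FATAL_NULL or result.predicted_label is None:
        return not gold_label
    return result.predicted_label


def compute_metrics(dataset: Dataset, results: Sequence[ExtractionResult]) -> MetricsReport:
    """Score one extraction run against a dataset's gold annotations.

    Document macro metrics are the unweighted mean of per-class (positive,
    negative) precision/recall/F1; sentence metrics pool TP/FP/FN over the
    corpus.  Every result's report must be annotated.
    """
    conf = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    stp = sfp = sfn = 0
    for res in results:
        ann = dataset.annotations.get(res.report_id)
        if ann is None:
            raise AifexError(f"no gold annotation for report {res.report_id!r}")
        gold_label = ann.doc_label
        pred_label = effective_doc_label(gold_label, res)
        if gold_label and pred_label:
            conf["tp"] += 1
        elif gold_label and not pred_label:
            conf["fn"] += 1
        elif not gold_label and pred_label:
            conf["fp"] += 1
        else:
            conf["tn"] += 1
        m = match_sentences(ann, res)
        stp += m.tp
        sfp += m.fp
        sfn += m.fn

    n = len(results)
    acc = (conf["tp"] + conf["tn"]) / n if n else 0.0
    # per-class P/R/F1: positive class, then negative class (swap roles)
    p_pos, r_pos, f_pos = _prf(conf["tp"], conf["fp"], conf["fn"])
    p_neg, r_neg, f_neg = _prf(conf["tn"], conf["fn"], conf["fp"])
    sp, sr, sf = _prf(stp, sfp, sfn)
    return MetricsReport(
        doc_precision_macro=(p_pos + p_neg) / 2,
        doc_recall_macro=(r_pos + r_neg) / 2,
        doc_f1_macro=(f_pos + f_neg) / 2,
        doc_accuracy=acc,
        doc_confusion=conf,
        sent_precision=sp,
        sent_recall=sr,
        sent_f1=sf,
        sent_counts={"tp": stp, "fp": sfp, "fn": sfn},
        parsing_errors=tally_parsing_errors(results),
    )


# ---------------------------------------------------------------------------
# Multi-run aggregation
# ---------------------------------------------------------------------------


@dataclass
class AggregateReport:
    """Per-metric mean and 95% CI half-width over k >= 2 runs."""

    k: int
    means: dict[str, float]
    ci_half_widths: dict[str, float]


def aggregate_values(values: Sequence[float], confidence: float = 0.95) -> tuple[float, float]:
    """Mean and t-based CI half-width of independent run values.

    Half-width = t(1-(1-confidence)/2, k-1) * sd / sqrt(k) with the sample
    standard deviation; the t distribution is the right reference for the
    small run counts (k = 3) typical of seed-replicated training.
    """
    k = len(values)
    if k < 2:
        raise AifexError("aggregation needs at least 2 runs")
    m = mean(values)
    sd = stdev(values)
    tcrit = float(_stats.t.ppf(0.5 + confidence / 2, df=k - 1))
    return m, tcrit * sd / math.sqrt(k)


def aggregate_runs(reports: Sequence[MetricsReport | Mapping[str, float]]) -> AggregateReport:
    """Aggregate the scalar metrics of k >= 2 runs (mean ± 95% CI)."""
    if len(reports) < 2:
        raise AifexError("aggregation needs at least 2 runs")
    flats = [r.as_flat_dict() if isinstance(r, MetricsReport) else dict(r) for r in reports]
    keys = [k for k in flats[0] if all(k in f for f in flats)]
    means: dict[str, float] = {}
    hws: dict[str, float] = {}
    for key in keys:
        means[key], hws[key] = aggregate_values([f[key] for f in flats])
    return AggregateReport(k=len(flats), means=means, ci_half_widths=hws)


# ---------------------------------------------------------------------------
# Inter-annotator agreement
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    kappa: float
    observed_agreement: float
    expected_agreement: float


def cohens_kappa(labels_a: Sequence[bool], labels_b: Sequence[bool]) -> AgreementReport:
    """Two-rater Cohen's kappa on binary labels.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    raters' marginals.  Degenerate case p_e = 1 (both raters constant):
    kappa is 1 when the raters agree everywhere, else 0.
    """
    if len(labels_a) != len(labels_b):
        raise AifexError("label vectors must have equal length")
    n = len(labels_a)
    if n == 0:
        raise AifexError("label vectors must be non-empty")
    a = [bool(x) for x in labels_a]
    b = [bool(x) for x in labels_b]
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    pa = sum(a) / n
    pb = sum(b) / n
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return AgreementReport(kappa=kappa, observed_agreement=p_o, expected_agreement=p_e)


# ---------------------------------------------------------------------------
# Grounding audit
# ---------------------------------------------------------------------------


def audit_grounding(dataset: Dataset, results: Sequence[ExtractionResult]) -> list[tuple[str, str]]:
    """Flag predicted sentences not locatable in their report's text.

    A prediction is *grounded* when its normalized form occurs as a
    substring of the whitespace-collapsed report text — hallucinated
    content fails this check, benign boundary trims do not.  Returns
    ``(report_id, sentence)`` pairs for every ungrounded prediction.
    """
    by_id = {r.report_id: r for r in dataset.reports}
    flags: list[tuple[str, str]] = []
    for res in results:
        rep = by_id.get(res.report_id)
        if rep is None:
            raise AifexError(f"unknown report_id {res.report_id!r} in results")
        haystack = collapse_ws(rep.text)
        for s in res.predicted_sentences:
            norm = collapse_ws(normalize_sentence(s))
            if norm and norm not in haystack:
                flags.append((res.report_id, s))
    return flags
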