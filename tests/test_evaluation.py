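"""Normalization, matching, metrics, aggregation and agreement."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from aifex.core import Dataset, ExtractionResult, GoldAnnotation, ParseStatus, Report
from aifex.evaluation import (
    aggregate_runs,
    aggregate_values,
    cohens_kappa,
    compute_metrics,
    match_sentences,
    derive_doc_label,
    normalize_sentence,
)


def _result(rid, sentences, label=None, status=ParseStatus.OK):
    if status is ParseStatus.FATAL_NULL:
        return ExtractionResult(rid, None, (), 6, status)
    if label is None:
        label = bool(sentences)
    return ExtractionResult(rid, label, tuple(sentences), 1, status)


class TestNormalization:
    def test_numbered_list_prefix_and_terminal_punctuation_stripped(self):
        got = normalize_sentence("1. Incidental 2.1 cm left adrenal nodule.")
        assert got == "Incidental 2.1 cm left adrenal nodule"

    def test_all_edge_input_collapses_to_empty(self):
        assert normalize_sentence("   ...123  ") == ""

    def test_case_and_interior_preserved(self):
        assert normalize_sentence('  "Severe Emphysema, Noted."  ') == "Severe Emphysema, Noted"

    @given(st.text(max_size=60))
    @settings(max_examples=300, derandomize=True)
    def test_idempotent(self, s):
        assert normalize_sentence(normalize_sentence(s)) == normalize_sentence(s)


class TestMatchSentences:
    def test_normalized_match_counts(self):
        gold = GoldAnnotation("r", ("A.", "B."))
        pred = _result("r", ["1. A."])
        m = match_sentences(gold, pred)
        assert (m.tp, m.fp, m.fn) == (1, 0, 1)

    def test_pure_false_positive(self):
        m = match_sentences(GoldAnnotation("r", ()), _result("r", ["X"]))
        assert (m.tp, m.fp, m.fn) == (0, 1, 0)

    def test_fatal_null_counts_all_gold_as_fn(self):
        gold = GoldAnnotation("r", ("A.", "B."))
        m = match_sentences(gold, _result("r", [], status=ParseStatus.FATAL_NULL))
        assert (m.tp, m.fp, m.fn) == (0, 0, 2)

    def test_duplicates_deduplicated_no_double_credit(self):
        gold = GoldAnnotation("r", ("A.",))
        m = match_sentences(gold, _result("r", ["A.", "1. A.", "A."]))
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_report_id_mismatch_rejected(self):
        with pytest.raises(Exception):
            match_sentences(GoldAnnotation("a", ()), _result("b", []))

    def test_counts_equal_quadratic_brute_force_on_random_sets(self):
        rng = random.Random(17)
        vocab = [f"Sentence number {i}." for i in range(12)]
        for _ in range(50):
            gold_s = rng.sample(vocab, rng.randrange(0, 6))
            pred_s = [
                (f"{rng.randrange(1,9)}. " + s) if rng.random() < 0.5 else s
                for s in rng.sample(vocab, rng.randrange(0, 6))
            ]
            m = match_sentences(GoldAnnotation("r", tuple(gold_s)), _result("r", pred_s))
            # brute force: all-pairs normalized comparison on deduped sets
            gn = list(dict.fromkeys(normalize_sentence(s) for s in gold_s if normalize_sentence(s)))
            pn = list(dict.fromkeys(normalize_sentence(s) for s in pred_s if normalize_sentence(s)))
            tp = sum(1 for g in gn for p in pn if g == p)
            assert (m.tp, m.fp, m.fn) == (tp, len(pn) - tp, len(gn) - tp)
            assert m.tp + m.fn == len(gn)
            assert m.tp + m.fp == len(pn)


def test_derive_doc_label():
    assert derive_doc_label([]) is False
    assert derive_doc_label(["x"]) is True


class TestComputeMetrics:
    def _dataset(self, gold_labels):
        reports, annotations = [], {}
        for i, pos in enumerate(gold_labels):
            rid = f"r{i}"
            text = "Severe emphysema is seen.\nAll else clear."
            reports.append(Report(rid, text))
            annotations[rid] = GoldAnnotation(
                rid, ("Severe emphysema is seen.",) if pos else ()
            )
        return Dataset("d", reports, annotations)

    def test_symmetric_confusion_gives_half_everywhere(self):
        ds = self._dataset([True, True, False, False])
        results = [
            _result("r0", ["Severe emphysema is seen."]),  # doc TP
            _result("r1", []),  # doc FN
            _result("r2", ["All else clear."]),  # doc FP
            _result("r3", []),  # doc TN
        ]
        m = compute_metrics(ds, results)
        assert m.doc_confusion == {"tp": 1, "fp": 1, "tn": 1, "fn": 1}
        assert m.doc_accuracy == pytest.approx(0.5)
        assert m.doc_precision_macro == pytest.approx(0.5)
        assert m.doc_recall_macro == pytest.approx(0.5)
        assert m.doc_f1_macro == pytest.approx(0.5)

    def test_sentence_micro_arithmetic(self):
        # totals TP=3, FP=1, FN=2 -> P=0.75, R=0.6, F1=0.6667
        ds = self._dataset([True, True, True, True, True])
        results = [
            _result("r0", ["Severe emphysema is seen."]),
            _result("r1", ["Severe emphysema is seen."]),
            _result("r2", ["Severe emphysema is seen.", "All else clear."]),
            _result("r3", [], label=False),
            _result("r4", [], label=False),
        ]
        m = compute_metrics(ds, results)
        assert m.sent_counts == {"tp": 3, "fp": 1, "fn": 2}
        assert m.sent_precision == pytest.approx(0.75)
        assert m.sent_recall == pytest.approx(0.6)
        assert m.sent_f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_fatal_null_scored_incorrect_for_either_gold_label(self):
        ds = self._dataset([True, False])
        results = [
            _result("r0", [], status=ParseStatus.FATAL_NULL),
            _result("r1", [], status=ParseStatus.FATAL_NULL),
        ]
        m = compute_metrics(ds, results)
        assert m.doc_accuracy == 0.0
        assert m.doc_confusion["fn"] == 1 and m.doc_confusion["fp"] == 1

    def test_missing_annotation_names_report(self):
        ds = Dataset("d", [Report("r0", "x.")], {})
        with pytest.raises(Exception, match="r0"):
            compute_metrics(ds, [_result("r0", [])])

    def test_macro_metrics_match_sklearn_on_random_labelings(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = random.Random(23)
        for trial in range(20):
            n = 30
            gold = [rng.random() < 0.5 for _ in range(n)]
            pred = [g if rng.random() < 0.7 else not g for g in gold]
            ds = self._dataset(gold)
            results = [
                _result(f"r{i}", ["Severe emphysema is seen."] if p else [], label=p)
                for i, p in enumerate(pred)
            ]
            m = compute_metrics(ds, results)
            p, r, f, _ = precision_recall_fscore_support(
                gold, pred, average="macro", zero_division=0
            )
            assert m.doc_precision_macro == pytest.approx(p)
            assert m.doc_recall_macro == pytest.approx(r)
            assert m.doc_f1_macro == pytest.approx(f)

    def test_label_flip_rate_never_increases_expected_accuracy(self):
        """Document accuracy decreases (stochastically) in the oracle's
        label-flip rate."""
        from statistics import mean

        from aifex.backends import OracleBackend, OraclePerturbations
        from aifex.generation import DecodingConfig, run_extraction
        from aifex.prompting import load_template
        from aifex.synth import generate_dataset, internal_profile

        ds = generate_dataset(internal_profile(60, seed=13))
        tpl = load_template("cot-json")
        means = []
        for rate in (0.0, 0.4, 0.8):
            accs = []
            for seed in range(3):
                be = OracleBackend(ds, tpl.strategy, OraclePerturbations(label_flip=rate))
                run = run_extraction(ds, tpl, be, DecodingConfig(), seed=seed)
                accs.append(compute_metrics(ds, run.results).doc_accuracy)
            means.append(mean(accs))
        assert means[0] >= means[1] >= means[2]

    def test_exhaustive_recount_on_small_fixtures(self):
        """Every count matches a brute-force recount on <=10-report fixtures."""
        rng = random.Random(29)
        sentences = [f"Finding {i} is noted." for i in range(8)]
        for _ in range(10):
            n = rng.randrange(2, 10)
            reports, annotations, results = [], {}, []
            for i in range(n):
                rid = f"r{i}"
                text = "\n".join(sentences)
                gold_s = tuple(rng.sample(sentences, rng.randrange(0, 4)))
                pred_s = rng.sample(sentences, rng.randrange(0, 4))
                reports.append(Report(rid, text))
                annotations[rid] = GoldAnnotation(rid, gold_s)
                results.append(_result(rid, pred_s))
            ds = Dataset("d", reports, annotations)
            m = compute_metrics(ds, results)
            # brute force recount
            conf = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
            tp = fp = fn = 0
            for res in results:
                g = annotations[res.report_id].doc_label
                p = res.predicted_label
                conf["tp" if g and p else "fn" if g else "fp" if p else "tn"] += 1
                gn = {normalize_sentence(s) for s in annotations[res.report_id].aif_sentences}
                pn = {normalize_sentence(s) for s in res.predicted_sentences}
                tp += len(gn & pn)
                fp += len(pn - gn)
                fn += len(gn - pn)
            assert m.doc_confusion == conf
            assert m.sent_counts == {"tp": tp, "fp": fp, "fn": fn}
            assert sum(conf.values()) == n


class TestAggregation:
    def test_zero_variance(self):
        mean_, hw = aggregate_values([0.9, 0.9, 0.9])
        assert mean_ == pytest.approx(0.9)
        assert hw == pytest.approx(0.0)

    def test_three_run_t_interval_against_frozen_t_table(self):
        # sd([0.90, 0.91, 0.92]) = 0.01; t_(0.975, df=2) = 4.302653 (t table)
        mean_, hw = aggregate_values([0.90, 0.91, 0.92])
        assert mean_ == pytest.approx(0.91)
        assert hw == pytest.approx(4.302653 * 0.01 / math.sqrt(3), rel=1e-5)
        assert hw == pytest.approx(0.0248, abs=5e-4)

    def test_single_run_rejected(self):
        with pytest.raises(Exception):
            aggregate_values([0.9])

    def test_aggregate_runs_mean_within_run_range(self):
        runs = [{"doc_f1_macro": v, "sent_f1": v / 2} for v in (0.8, 0.85, 0.9)]
        agg = aggregate_runs(runs)
        assert agg.k == 3
        for key, m in agg.means.items():
            vals = [r[key] for r in runs]
            assert min(vals) <= m <= max(vals)
            assert agg.ci_half_widths[key] >= 0


class TestCohensKappa:
    def test_perfect_agreement(self):
        rep = cohens_kappa([True, False, True], [True, False, True])
        assert rep.kappa == pytest.approx(1.0)
        assert rep.observed_agreement == 1.0

    def test_hand_computed_table(self):
        # 2x2 table with p_o = 0.9 and p_e = 0.5 -> kappa = 0.8
        a = [True] * 45 + [True] * 5 + [False] * 5 + [False] * 45
        b = [True] * 45 + [False] * 5 + [True] * 5 + [False] * 45
        rep = cohens_kappa(a, b)
        assert rep.observed_agreement == pytest.approx(0.9)
        assert rep.expected_agreement == pytest.approx(0.5)
        assert rep.kappa == pytest.approx(0.8)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = random.Random(31)
        for _ in range(10):
            a = [rng.random() < 0.6 for _ in range(80)]
            b = [x if rng.random() < 0.75 else not x for x in a]
            assert cohens_kappa(a, b).kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_independent_random_null_is_near_zero(self):
        rng = random.Random(7)
        n = 10_000
        a = [rng.random() < 0.5 for _ in range(n)]
        b = [rng.random() < 0.5 for _ in range(n)]
        assert abs(cohens_kappa(a, b).kappa) < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(Exception):
            cohens_kappa([True], [True, False])


def test_all_metric_values_in_unit_interval(internal_dataset):
    from aifex.backends import OracleBackend, OraclePerturbations
    from aifex.generation import DecodingConfig, run_extraction
    from aifex.prompting import load_template

    tpl = load_template("cot-json")
    be = OracleBackend(
        internal_dataset, tpl.strategy,
        OraclePerturbations(boundary_word_drop=0.3, label_flip=0.2, distractor_insert=0.3),
    )
    run = run_extraction(internal_dataset, tpl, be, DecodingConfig(), seed=2)
    m = compute_metrics(internal_dataset, run.results)
    for v in m.as_flat_dict().values():
        assert 0.0 <= v <= 1.0
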