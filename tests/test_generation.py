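"""Artefact stripping, schema parsing and the hybrid retry controller."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from aifex.backends import OracleBackend, OraclePerturbations, ScriptedBackend
from aifex.core import ParseStatus, Report
from aifex.evaluation import tally_parsing_errors
from aifex.generation import (
    DecodingConfig,
    extract,
    parse_answer,
    run_extraction,
    strip_artefacts,
)
from aifex.prompting import PromptStrategy, load_template
from aifex.synth import generate_dataset, internal_profile

COT_JSON = PromptStrategy("cot", "json")
STD_JSON = PromptStrategy("standard", "json")

VALID = '{"actionable_findings_present":false,"aif_sentences":[]}'
INVALID = "so sorry, no JSON today {"


class TestStripArtefacts:
    def test_code_fence_removed(self):
        assert strip_artefacts('```json\n{"a":1}\n```').text == '{"a":1}'

    def test_surrounding_prose_removed(self):
        got = strip_artefacts('Here is the answer: {"a":1} Hope this helps')
        assert got.text == '{"a":1}'
        assert got.found

    def test_trailing_repetition_dropped(self):
        got = strip_artefacts('{"a":1} {"a":1} {"a":1}')
        assert got.text == '{"a":1}'

    def test_no_balanced_span_flagged(self):
        got = strip_artefacts("no json here")
        assert got.text == "no json here"
        assert not got.found

    def test_braces_inside_json_strings_ignored(self):
        payload = '{"aif_sentences":["a } b { c"]}'
        assert strip_artefacts(f"prefix {payload} suffix").text == payload

    @given(st.text(max_size=80))
    @settings(max_examples=200, derandomize=True)
    def test_idempotent_on_fuzzed_input(self, s):
        decorated = f"```json\n{s}\n```"
        once = strip_artefacts(decorated).text
        assert strip_artefacts(once).text == once


class TestParseAnswer:
    def test_cot_json_valid_exemplar(self):
        raw = '{"actionable_findings_present": true, "aif_sentences": ["Severe emphysema."]}'
        ans = parse_answer(raw, COT_JSON)
        assert ans.valid and ans.label is True
        assert ans.sentences == ("Severe emphysema.",)

    def test_standard_json_label_derived_from_sentences(self):
        assert parse_answer('{"aif_sentences": []}', STD_JSON).label is False
        assert parse_answer('{"aif_sentences": ["x"]}', STD_JSON).label is True

    @pytest.mark.parametrize(
        "raw",
        [
            '{"actionable_findings_present": "yes"}',  # type violation, missing key
            '{"actionable_findings_present": "yes", "aif_sentences": []}',
            '{"aif_sentences": [1, 2]}',
            '{"aif_sentences": []}',  # wrong schema for CoT (missing label key)
            '{"actionable_findings_present": true, "aif_sentences": [], "extra": 1}',
            "not json at all",
        ],
    )
    def test_cot_json_schema_violations(self, raw):
        assert not parse_answer(raw, COT_JSON).valid

    def test_free_text_whitespace_parser(self):
        strat = PromptStrategy("standard", "free_text")
        ans = parse_answer("A.\n\nB.\n", strat)
        assert ans.valid and ans.sentences == ("A.", "B.") and ans.label is True
        neg = parse_answer("NONE", strat)
        assert neg.valid and neg.sentences == () and neg.label is False

    def test_free_text_cot_label_line(self):
        strat = PromptStrategy("cot", "free_text")
        ans = parse_answer("Label: negative\nNONE", strat)
        assert ans.valid and ans.label is False and ans.sentences == ()
        ans = parse_answer("Label: positive\nSevere emphysema.", strat)
        assert ans.label is True and ans.sentences == ("Severe emphysema.",)


@pytest.fixture
def report_and_template():
    return Report("r1", "Severe emphysema is noted."), load_template("cot-json")


class TestHybridController:
    def test_first_attempt_valid(self, report_and_template):
        report, tpl = report_and_template
        backend = ScriptedBackend([VALID])
        res = extract(report, tpl, backend, DecodingConfig(), seed=0)
        assert res.attempts == 1 and res.parse_status is ParseStatus.OK
        assert tally_parsing_errors([res]).as_tuple() == (0, 0)

    def test_recovery_on_second_attempt(self, report_and_template):
        report, tpl = report_and_template
        backend = ScriptedBackend([INVALID, VALID])
        res = extract(report, tpl, backend, DecodingConfig(), seed=0)
        assert res.attempts == 2 and res.parse_status is ParseStatus.RECOVERED
        assert len(res.raw_generations) == 2
        assert tally_parsing_errors([res]).as_tuple() == (1, 0)

    @pytest.mark.parametrize("k", [2, 4])
    def test_recovery_after_k_failures(self, report_and_template, k):
        report, tpl = report_and_template
        backend = ScriptedBackend([INVALID] * k + [VALID])
        res = extract(report, tpl, backend, DecodingConfig(), seed=0)
        assert res.attempts == k + 1 and res.parse_status is ParseStatus.RECOVERED

    def test_exhaustion_yields_fatal_null(self, report_and_template):
        report, tpl = report_and_template
        backend = ScriptedBackend([INVALID])
        cfg = DecodingConfig()
        res = extract(report, tpl, backend, cfg, seed=0)
        assert res.parse_status is ParseStatus.FATAL_NULL
        assert res.predicted_label is None and res.predicted_sentences == ()
        assert res.attempts == cfg.max_attempts
        # the null answer itself is JSON-parsable
        assert json.loads(res.raw_generations[-1]) is None
        assert tally_parsing_errors([res]).as_tuple() == (1, 1)

    def test_greedy_used_exactly_once_then_nucleus_fallbacks(self, report_and_template):
        report, tpl = report_and_template
        backend = ScriptedBackend([INVALID] * 3 + [VALID])
        extract(report, tpl, backend, DecodingConfig(), seed=10)
        methods = [m for _, m, _ in backend.call_log]
        seeds = [s for _, _, s in backend.call_log]
        assert methods == ["greedy", "nucleus", "nucleus", "nucleus"]
        assert seeds == [10, 11, 12, 13]  # per-attempt derived seeds

    def test_attempt_cap_respected(self, report_and_template):
        report, tpl = report_and_template
        backend = ScriptedBackend([INVALID])
        res = extract(report, tpl, backend, DecodingConfig(max_attempts=3), seed=0)
        assert res.attempts == 3 and len(backend.call_log) == 3

    def test_non_hybrid_methods_single_attempt(self, report_and_template):
        report, tpl = report_and_template
        backend = ScriptedBackend([INVALID, VALID])
        res = extract(report, tpl, backend, DecodingConfig(method="greedy"), seed=0)
        assert res.parse_status is ParseStatus.FATAL_NULL
        assert len(backend.call_log) == 1


class TestRunExtraction:
    def test_tally_matches_recount(self, small_dataset, cot_json_template):
        # script per prompt: r1 recovers, r2 ok, r3 fatal
        from aifex.prompting import build_prompt

        script = {}
        for rep in small_dataset.reports:
            prompt = build_prompt(rep, cot_json_template)
            if rep.report_id == "r1":
                script[prompt] = [INVALID, VALID]
            elif rep.report_id == "r2":
                script[prompt] = [VALID]
            else:
                script[prompt] = [INVALID]
        run = run_extraction(
            small_dataset, cot_json_template, ScriptedBackend(script), DecodingConfig(), 0
        )
        assert run.tally.as_tuple() == (2, 1)
        assert run.tally.as_tuple() == tally_parsing_errors(run.results).as_tuple()
        assert [r.report_id for r in run.results] == ["r1", "r2", "r3"]

    def test_deterministic_given_seed(self):
        ds = generate_dataset(internal_profile(20, seed=5))
        tpl = load_template("cot-json")
        runs = []
        for _ in range(2):
            backend = OracleBackend(ds, tpl.strategy, OraclePerturbations(boundary_trim=0.5))
            runs.append(run_extraction(ds, tpl, backend, DecodingConfig(), seed=3))
        assert [
            (r.report_id, r.predicted_sentences, r.raw_generations) for r in runs[0].results
        ] == [(r.report_id, r.predicted_sentences, r.raw_generations) for r in runs[1].results]


def test_grounding_audit_detects_planted_hallucination():
    from aifex.evaluation import audit_grounding

    ds = generate_dataset(internal_profile(10, seed=6))
    tpl = load_template("cot-json")
    clean = OracleBackend(ds, tpl.strategy)
    run = run_extraction(ds, tpl, clean, DecodingConfig(), seed=0)
    assert audit_grounding(ds, run.results) == []
    tainted = OracleBackend(ds, tpl.strategy, OraclePerturbations(hallucinate=1.0))
    run = run_extraction(ds, tpl, tainted, DecodingConfig(), seed=0)
    flags = audit_grounding(ds, run.results)
    assert len(flags) == len(ds.reports)
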