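# Methods

## Task and model of the data

A PET-CT report is free text; its gold annotation is the set of verbatim
sentences describing actionable incidental findings (AIFs). The document
label is *derived*: positive iff at least one AIF sentence is annotated.
Sentence identity is by verbatim string, not character offset — this
matches string-match evaluation and keeps every artefact (reports,
annotations, predictions) a plain JSONL file.

Actionability is contextual to a lung-cancer population: a finding with
an intensifying qualifier ("severe emphysema") is actionable; the same
finding with a diminishing or neutral qualifier ("mild", "moderate") is
not. The synthetic sentence banks encode this convention directly —
actionable and non-actionable template sets are disjoint by
construction.

## Sentence segmentation

Segmentation is rule-based and deterministic: a sentence ends at
terminal punctuation followed by whitespace and an upper-case letter or
digit; newlines are hard boundaries (section headers such as
`Findings:` become their own segments). Two guards prevent spurious
splits: an abbreviation stop-list (`cm`, `mm`, `Dr`, `e.g.`, `vs`, …)
and a numbered-list rule that keeps a leading numeral (`1. …`) attached
to its sentence. A learned sentence tokenizer was deliberately not used:
reproducible evaluation requires byte-identical segmentation across
runs and machines, and the evaluation normalization (below) already
absorbs the boundary ambiguity that motivates statistical tokenizers.
The cost is conservative behaviour around abbreviation-final sentences
("… measuring 1.5 cm. The …" does not split); the synthetic templates
avoid ending sentences on stop-list tokens.

## Decoding control

The hybrid controller makes one greedy attempt, then up to
`max_attempts − 1` nucleus-sampling attempts at temperature = top-p =
0.5 (defaults; `max_attempts = 6`, i.e. five fallback retries after the
greedy attempt — the retry budget is configurable because either reading
of a "five-attempt limit" is defensible). Per-attempt seeds derive as
`seed + attempt_index`, so fallbacks differ deterministically. On
exhaustion the controller emits the JSON-parsable `null` answer with a
null label and no sentences; evaluation scores it as incorrect against
either gold label (realised as the complement of the gold label so the
confusion matrix still sums to n).

JSON outputs pass through an artefact stripper (code fences and
prose outside the first outermost brace-balanced span, honouring JSON
string quoting; idempotent) and then strict schema validation: exactly
the required keys, boolean label (chain-of-thought only), list of
strings. Free-text outputs use a lenient line parser: non-empty lines
are sentences, `NONE` means no findings, and a leading `Label:` line
carries the chain-of-thought document label. For standard strategies
the label is always derived from whether any sentences were returned.

## Evaluation

**Normalization** strips a leading/trailing run of whitespace, digits
and punctuation (ASCII punctuation plus unicode dashes/quotes/ellipsis,
frozen in one constant) from each sentence; interior content and case
are untouched, so "1. Incidental 2.1 cm adrenal nodule." and
"Incidental 2.1 cm adrenal nodule" normalize identically while the
interior measurement survives. The operation is idempotent.

**Sentence matching** deduplicates normalized sentences per report (set
semantics — repeated generations earn no double credit; duplicate
handling is not otherwise forced by the task definition) and counts
exact normalized equality as a true positive. Sentence metrics are
micro: precision/recall/F1 from corpus-summed TP/FP/FN, with the
zero-denominator convention P = R = F1 = 0 so empty-prediction runs
remain scoreable.

**Document metrics** are accuracy plus macro-averaged P/R/F1 — the
unweighted mean over the positive and negative classes, since both
classes matter clinically and the class balance differs sharply between
report styles.

**Aggregation** over k seed-replicated runs reports the mean and a
t-based 95% CI half-width, `t(0.975, k−1)·sd/√k` with sample sd — the
right small-sample reference for k = 3. **Cohen's kappa** implements
the standard two-rater statistic; the degenerate case p_e = 1 (both
raters constant) is defined as 1 when observed agreement is 1, else 0.

## Error taxonomy

Residual mismatches are partitioned by a deterministic cascade, soft
rules first so a benign reading wins where one exists: (a) boundary
errors — FP/FN pairs where one normalized string contains the other,
consumed greedily by longest overlap; (b) text artefacts — FP equal to
an FN after additionally lowercasing and collapsing interior
whitespace; (c) multiple-reference misses — an FN whose alphabetic
token-set Jaccard with any matched gold sentence of the same report
reaches 0.6 (default, configurable; there is no quantitative ground
truth to calibrate against, so the threshold is a declared default);
(d) ungrounded FPs — not locatable in the whitespace-collapsed report
text; (e) the remainder is hard (missed AIF / non-actionable
extraction, which cannot be separated from contextual misinterpretation
without clinical judgement). Soft-forgiven metrics convert each
boundary/artefact pair into a true positive and remove
multiple-reference misses from recall's denominator; they can only be
at least the strict metrics.

## Synthetic report generator

The generator emulates two reporting styles at their published corpus
statistics: *internal* (priority-ordered findings, positive/negative
ratio 0.64, mean 392 whitespace tokens, 0.781 gold sentences/report)
and *external* (anatomical head-to-legs ordering, ratio 1.64, 570.3
tokens, 1.697 gold sentences/report). Mechanics:

- The positive count is fixed at `round(n·ratio/(1+ratio))`, so the
  realised class ratio tracks the target tightly at any n.
- Per-report token targets are drawn from a normal distribution at the
  profile mean (8% relative sd) and met by padding with negative filler
  sentences; token counts use whitespace tokens by default, with a
  tokenizer hook for substituting a subword tokenizer (avoids any model
  download in tests; published counts use an LLM tokenizer, so absolute
  token means are comparable only through the hook).
- The number of distinct findings per positive report is 1 + Poisson,
  with the rate back-solved from the profile's AIF-sentence mean and
  the multi-reference probability.
- Each planted finding is restated in the Interpretation section with
  probability 0.3 (default) as "<finding clause>, as above." — the
  clause verbatim, the carrier distinct — and both references enter the
  gold set, exercising the multiple-reference error path. Restating
  verbatim-identical strings would collapse in a sentence *set*, hence
  the carrier.
- Findings sections render as numbered lists with probability 0.5
  (default), exercising boundary normalization. Both defaults are
  unconstrained by any published value; they are chosen so the
  normalization and taxonomy paths appear in any moderately sized
  corpus.
- Priority style orders primary disease, then AIFs, then distractors
  and filler; anatomical style sorts all findings head-to-legs by a
  region tag on each template.

What the generator does **not** emulate: clinically realistic language,
patient-level report duplication, per-section length structure beyond
fixed headers, and the full actionability guideline taxonomy — the
banks carry only named exemplar findings. Passing tests therefore
demonstrate the pipeline's *mechanics* (parsing, retry control,
normalization, metric arithmetic, taxonomy partitioning, grounding),
not clinical extraction quality on real reports, which requires the
private data and a trained model.

## Fixture backends

The scripted backend replays an explicit prompt → outputs table and
exists to pin down controller behaviour. The oracle backend locates the
report embedded in each prompt and renders its gold annotation, with
independent perturbation channels whose expected effect on each metric
is known: edge-numeral trims (normalization-invisible), trailing-word
drops (soft boundary errors), duplicate-reference drops (soft
multiple-reference errors), grounded distractor insertion (hard false
positives), label flips (document-level errors, monotone in rate),
artefact wrapping (stripper work, no metric effect), leading invalid
attempts (retry tally), and fabricated sentences (grounding-audit
flags). All perturbation decisions derive from the run seed and report
id, so runs are reproducible byte-for-byte.

## Fine-tuning recipe

The QLoRA configuration is data, not code: rank 16, alpha 64, 4-bit
quantisation, learning rate 2e-4 with linear decay, three epochs, 8-bit
AdamW, eight gradient-accumulation steps of micro-batch one (effective
batch 8). Validation rejects quantisation widths outside {4, 8, 16} and
non-positive hyperparameters. LoRA dropout (0.0) and target modules
(all attention projections) are not pinned by any published value and
are overridable. Training execution itself sits behind the optional
Hugging Face adapter (`aifex[hf]`) and is excluded from the test
surface: the package's contract is the recipe plus the emitted
(input, target) corpus, both fully testable on CPU.

## Problem sizes

The test suite and the acceptance script run on synthetic corpora of
60–500 reports (500 for profile recovery, 200 for the identity run,
100 for perturbation studies), sizes at which realised corpus
statistics sit comfortably inside the stated tolerances (class ratio
±10%, means ±15%) while the whole suite completes in seconds on one
CPU.
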