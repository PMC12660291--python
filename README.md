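# aifex

Extraction of **actionable incidental findings (AIFs)** from FDG PET-CT
radiology reports with open large language models — the full pipeline
around the model: prompt construction, decoding control with structured
output, two-tier evaluation, error taxonomy, a QLoRA fine-tuning recipe,
and a synthetic report generator so everything is testable without
confidential clinical data or a GPU.

## The problem

PET-CT scans performed for cancer staging frequently reveal findings
unrelated to the indication for the scan — an abdominal aortic aneurysm,
a suspicious renal or thyroid nodule, severe emphysema — that require
clinical action or follow-up. Whether an incidental finding is
*actionable* is contextual: in a lung-cancer population, emphysema is
actionable only with an intensifying qualifier ("severe"), not with
diminishing or neutral ones ("mild", "moderate"). An extraction system
must therefore both classify each report (AIF present / absent) and
return the verbatim sentences describing each AIF, in a structured
format downstream applications can consume.

## What the package implements

- **Prompting** (`aifex.prompting`): four prompt strategies crossing
  reasoning style — *standard* (extract AIF sentences only; the document
  label follows from whether any are returned) vs *chain-of-thought*
  (classify the document, with sentence extraction as the intermediate
  step) — with output format, JSON vs free text: `Standard—JSON`,
  `CoT—JSON`, `Standard`, `CoT`. Instruction texts are editable assets
  with a literal `<REPORT TEXT HERE>` placeholder.
- **Decoding control** (`aifex.generation`): a backend-agnostic
  interface with greedy, nucleus, beam and *hybrid* decoding. Hybrid
  decoding runs greedy first; if the output fails artefact stripping +
  strict JSON schema validation, it retries with nucleus sampling
  (temperature = top-p = 0.5) up to a five-retry limit, then returns a
  JSON-parsable `null` answer that is scored as incorrect — parse
  failures never propagate downstream.
- **Evaluation** (`aifex.evaluation`): document-level accuracy and
  macro-averaged precision/recall/F1 over the positive and negative
  classes, plus micro (corpus-pooled) sentence-level P/R/F1 under exact
  string match after *normalization* — stripping whitespace, punctuation
  and digits from sentence edges, which forgives numbered-list numerals
  and similar boundary artefacts while guaranteeing semantic exactness.
  Multi-seed aggregation (mean ± t-based 95% CI) and Cohen's kappa for
  two-rater agreement are included.
- **Error taxonomy** (`aifex.errors`): every residual mismatch is
  classified as *soft* (sentence-boundary, multiple-reference, text
  artefact — harmless in practice) or *hard* (missed AIF, non-actionable
  extraction, ungrounded/hallucinated), and sentence metrics are
  recomputed with soft errors forgiven, estimating real-world
  performance above the strict lower bound.
- **Synthetic reports** (`aifex.synth`): labelled lung-cancer PET-CT
  reports in two styles — *priority-ordered* findings (internal profile:
  positive/negative ratio 0.64, ~392 tokens/report, ~0.78 AIF
  sentences/report) and *anatomically ordered* head-to-legs (external
  profile: ratio 1.64, ~570 tokens, ~1.70 AIF sentences) — with gold
  annotations grounded in the text by construction.
- **Fine-tuning recipe** (`aifex.finetune`): the QLoRA configuration
  (4-bit quantisation, LoRA rank 16 / alpha 64, lr 2e-4 with linear
  decay, 3 epochs, 8-bit AdamW, effective batch size 8) as a validated,
  serialisable config, plus emission of the supervised (input, target)
  corpus for next-token training.

Two deterministic fixture backends (`aifex.backends`) — a scripted
prompt→outputs table and a gold-annotation oracle with controlled
perturbations — drive the test suite; a real Hugging Face causal-LM
adapter is available as the optional `aifex[hf]` extra.

## Worked example

```sh
aifex synth --profile internal --n 50 --seed 7 --out reports.jsonl --gold gold.jsonl
# synth internal: n=50 pos=20 neg=30 ratio=0.667 mean_tokens=394.8 mean_aif=0.740
aifex extract --reports reports.jsonl --gold gold.jsonl --strategy cot-json \
              --backend oracle --decoding hybrid --seed 1 --out preds.jsonl
# extract: 50 reports, parsing errors (retried=0, fatal=0)
aifex evaluate --reports reports.jsonl --gold gold.jsonl --preds preds.jsonl --out metrics.json
# doc macro F1=1.000 acc=1.000 | sent F1=1.000 | ungrounded=0
```

The first command writes a 50-report labelled corpus whose realised
statistics (20 positives, 30 negatives, mean 394.8 whitespace tokens,
0.74 gold AIF sentences per report) track the internal profile. The
oracle backend answers each prompt from the gold annotation, so the
evaluation reports perfect document-level macro F1 and sentence-level
F1 with zero parsing errors and zero ungrounded sentences — the
end-to-end identity check that validates every pipeline stage at once.
Adding perturbations (see `OraclePerturbations`) degrades these scores
in controlled, predictable ways; `aifex errors` then splits the induced
mismatches into soft and hard kinds and reports both strict and
soft-forgiven sentence metrics.

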