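"""QLoRA fine-tuning recipe and training-corpus emission.

The training recipe — 4-bit base-model quantisation with low-rank
adapters (rank 16, alpha 64), learning rate 2e-4 with linear decay over
three epochs, 8-bit AdamW, and eight gradient-accumulation steps of
mini-batch one (effective batch size eight) — is encoded as a validated,
serialisable configuration.  The training objective is next-token
prediction over prompt + report + rendered target, so the corpus emitted
here is exactly the (input, target) pairs a trainer consumes.  Running
the training itself needs a GPU and model weights and lives behind the
optional :mod:`aifex.hf` adapter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .core import AifexError, Dataset
from .prompting import PromptTemplate, build_training_example


@dataclass(frozen=True)
class FineTuneConfig:
    """QLoRA hyperparameters; defaults are the validated recipe."""

    lora_rank: int = 16
    lora_alpha: int = 64
    quantisation_bits: int = 4
    learning_rate: float = 2e-4
    lr_schedule: str = "linear_decay"
    epochs: int = 3
    optimiser: str = "adamw_8bit"
    gradient_accumulation_steps: int = 8
    micro_batch_size: int = 1
    base_model_id: str = "meta-llama/Llama-3.1-8B-Instruct"
    prompt_strategy: str = "cot-json"
    seed: int = 0
    # LoRA dropout and target modules are free choices in the recipe;
    # default targets all attention projections.
    lora_dropout: float = 0.0
    target_modules: tuple[str, ...] = ("q_proj", "k_proj", "v_proj", "o_proj")

    def __post_init__(self) -> None:
        if self.quantisation_bits not in (4, 8, 16):
            raise AifexError("quantisation_bits must be 4, 8 or 16")
        for name in (
            "lora_rank",
            "lora_alpha",
            "learning_rate",
            "epochs",
            "gradient_accumulation_steps",
            "micro_batch_size",
        ):
            if getattr(self, name) <= 0:
                raise AifexError(f"{name} must be positive")
        if self.lr_schedule != "linear_decay":
            raise AifexError("only the linear_decay schedule is supported")
        if not 0 <= self.lora_dropout < 1:
            raise AifexError("lora_dropout must be in [0, 1)")

    @property
    def effective_batch_size(self) -> int:
        return self.gradient_accumulation_steps * self.micro_batch_size

    def to_json(self) -> str:
        obj = asdict(self)
        obj["target_modules"] = list(self.target_modules)
        return json.dumps(obj, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, payload: str) -> "FineTuneConfig":
        obj = json.loads(payload)
        obj["target_modules"] = tuple(obj.get("target_modules", ()))
        return cls(**obj)


def default_config() -> FineTuneConfig:
    """The recipe defaults (see class docstring)."""
    return FineTuneConfig()


def emit_training_corpus(
    dataset: Dataset,
    template: PromptTemplate,
    out_path: str | Path,
) -> int:
    """Write the supervised corpus JSONL ({"input", "target"} per report).

    One record per report in dataset order; every report must be
    annotated.  Returns the number of records written.
    """
    if not dataset.reports:
        raise AifexError("cannot emit a training corpus from an empty dataset")
    n = 0
    with open(out_path, "w", encoding="utf-8") as fh:
        for rep in dataset.reports:
            ann = dataset.annotations.get(rep.report_id)
            if ann is None:
                raise AifexError(f"report {rep.report_id!r} has no annotation")
            inp, target = build_training_example(rep, ann, template)
            fh.write(json.dumps({"input": inp, "target": target}, ensure_ascii=False) + "\n")
            n += 1
    return n
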