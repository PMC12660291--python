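"""Optional Hugging Face backend adapter (install extra ``aifex[hf]``).

Thin adapter putting a causal LM behind the :class:`GenerationBackend`
interface: the chat template is applied via the model tokenizer, and the
decoding config maps onto ``model.generate`` arguments (greedy, nucleus
with temperature/top_p, beam with ``num_beams``).  Imported lazily so the
core pipeline never requires torch/transformers.
"""

from __future__ import annotations

from .generation import BackendError, DecodingConfig, GenerationBackend


class HFBackend(GenerationBackend):
    """Causal-LM backend; requires the ``hf`` extra and model weights."""

    def __init__(self, model_id: str, device: str = "cuda", max_new_tokens: int = 512):
        try:
            import torch  # noqa: F401
            from transformers import AutoModelForCausalLM, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional extra
            raise BackendError(
                "the Hugging Face backend requires `pip install aifex[hf]`"
            ) from exc
        self._tokenizer = AutoTokenizer.from_pretrained(model_id)
        self._model = AutoModelForCausalLM.from_pretrained(model_id, device_map=device)
        self._max_new_tokens = max_new_tokens

    def generate(self, prompt: str, config: DecodingConfig, seed: int) -> str:  # pragma: no cover
        import torch
        from transformers import set_seed

        set_seed(seed % (2**31))
        messages = [{"role": "user", "content": prompt}]
        inputs = self._tokenizer.apply_chat_template(
            messages, add_generation_prompt=True, return_tensors="pt"
        ).to(self._model.device)
        kwargs: dict = {"max_new_tokens": self._max_new_tokens}
        if config.method in ("greedy", "hybrid"):
            kwargs["do_sample"] = False
        elif config.method == "nucleus":
            kwargs.update(do_sample=True, temperature=config.temperature, top_p=config.top_p)
        elif config.method == "beam":
            kwargs.update(do_sample=False, num_beams=config.num_beams)
        with torch.no_grad():
            out = self._model.generate(inputs, **kwargs)
        return self._tokenizer.decode(out[0, inputs.shape[1] :], skip_special_tokens=True)
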