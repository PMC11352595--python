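"""A tiny trainable contextual encoder.

The pipeline is encoder-agnostic: any object honouring :class:`EncoderContract`
(deterministic per-token final-layer vectors, a token vocabulary that can grow
special tokens, and gradients that propagate back to the input embeddings) can
be plugged in. :class:`TinyEncoder` is the bundled implementation — a small
pre-norm transformer (single-head self-attention with a learned relative
position bias, position-wise feed-forward blocks) over a word-level vocabulary.
It is sized to train from scratch on a CPU in minutes, which is what the
synthetic corpora are designed for.

Gradient access for adversarial training: :meth:`TinyEncoder.forward` returns
the embedding-lookup node ``X`` alongside the final hidden states; callers may
re-run :meth:`forward_from` on ``X + delta`` to obtain gradients with respect
to the perturbation ``delta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax
from .tokenization import Vocabulary

MAX_LEN = 512  # hard cap on tokens per encoded sequence
_REL_WINDOW = 16  # relative position bias is clipped to +/- this offset


@dataclass
class TinyEncoderSpec:
    """Seeded parameters for constructing a :class:`TinyEncoder`."""

    dim: int = 32
    n_layers: int = 2
    ffn_dim: int = 64
    max_len: int = MAX_LEN
    seed: int = 0


class EncoderContract:
    """Duck-typed interface every pluggable encoder must honour.

    Required attributes/methods::

        dim: int                    # width of per-token vectors
        max_len: int                # maximum tokens per sequence (512)
        vocab: Vocabulary           # supports add_special()
        parameters() -> [Tensor]
        add_special_tokens([str])
        forward(ids) -> (X, H)      # embedding node and (T, dim) states
        forward_from(X) -> H        # states from (possibly perturbed) embeddings
    """


def _layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps) ** 0.5 * gain + bias


class TinyEncoder(EncoderContract):
    """Word-level transformer encoder, deterministic given its seed."""

    def __init__(self, vocab: Vocabulary, spec: TinyEncoderSpec | None = None):
        spec = spec or TinyEncoderSpec()
        self.spec = spec
        self.dim = spec.dim
        self.max_len = spec.max_len
        self.n_layers = spec.n_layers
        self.vocab = vocab
        self._rng = np.random.default_rng(spec.seed)
        d, h = spec.dim, spec.ffn_dim

        self.tok_emb = self._param((len(vocab), d), scale=0.1)
        self.layers = []
        for _ in range(spec.n_layers):
            layer = {
                "ln1_g": Tensor(np.ones(d)), "ln1_b": Tensor(np.zeros(d)),
                "wq": self._xavier(d, d), "wk": self._xavier(d, d),
                "wv": self._xavier(d, d), "wo": self._xavier(d, d),
                # locality-decay init (ALiBi-style): nearby tokens start with
                # higher attention, which the bias can unlearn if unhelpful
                "rel_bias": Tensor(-0.3 * np.abs(np.arange(-_REL_WINDOW, _REL_WINDOW + 1))),
                "ln2_g": Tensor(np.ones(d)), "ln2_b": Tensor(np.zeros(d)),
                "w1": self._xavier(d, h), "b1": Tensor(np.zeros(h)),
                "w2": self._xavier(h, d), "b2": Tensor(np.zeros(d)),
            }
            self.layers.append(layer)
        self.lnf_g = Tensor(np.ones(d))
        self.lnf_b = Tensor(np.zeros(d))

    # ------------------------------------------------------------------
    def _param(self, shape, scale):
        return Tensor(self._rng.normal(0.0, scale, size=shape))

    def _xavier(self, fan_in, fan_out):
        std = np.sqrt(2.0 / (fan_in + fan_out))
        return Tensor(self._rng.normal(0.0, std, size=(fan_in, fan_out)))

    def parameters(self) -> list[Tensor]:
        params = [self.tok_emb, self.lnf_g, self.lnf_b]
        for layer in self.layers:
            params.extend(layer.values())
        return params

    def add_special_tokens(self, tokens: list[str]) -> None:
        """Register new special tokens, growing the embedding table."""
        new = [t for t in tokens if t not in self.vocab]
        for t in new:
            self.vocab.add_special(t)
        if new:
            extra = self._rng.normal(0.0, 0.1, size=(len(new), self.dim))
            self.tok_emb.data = np.concatenate([self.tok_emb.data, extra], axis=0)

    # ------------------------------------------------------------------
    def encode_ids(self, tokens: list[str]) -> np.ndarray:
        ids = self.vocab.encode(tokens)
        return np.asarray(ids[: self.max_len], dtype=np.intp)

    def embed(self, ids: np.ndarray) -> Tensor:
        return self.tok_emb[np.asarray(ids, dtype=np.intp)]

    def forward(self, ids: np.ndarray) -> tuple[Tensor, Tensor]:
        """Return ``(X, H)``: the embedding node and the final hidden states."""
        X = self.embed(ids)
        return X, self.forward_from(X)

    def forward_from(self, X: Tensor) -> Tensor:
        T = X.shape[0]
        offsets = np.clip(
            np.arange(T)[None, :] - np.arange(T)[:, None], -_REL_WINDOW, _REL_WINDOW
        ) + _REL_WINDOW
        h = X
        inv_sqrt_d = 1.0 / np.sqrt(self.dim)
        for layer in self.layers:
            a = _layer_norm(h, layer["ln1_g"], layer["ln1_b"])
            q = a @ layer["wq"]
            k = a @ layer["wk"]
            v = a @ layer["wv"]
            scores = (q @ k.T) * inv_sqrt_d + layer["rel_bias"][offsets]
            h = h + (softmax(scores, axis=-1) @ v) @ layer["wo"]
            f = _layer_norm(h, layer["ln2_g"], layer["ln2_b"])
            h = h + (f @ layer["w1"] + layer["b1"]).relu() @ layer["w2"] + layer["b2"]
        return _layer_norm(h, self.lnf_g, self.lnf_b)

    def states(self, tokens: list[str]) -> np.ndarray:
        """Convenience: final hidden states as a plain array (no grad)."""
        _, h = self.forward(self.encode_ids(tokens))
        return h.data


def make_tiny_encoder(texts: list[str], spec: TinyEncoderSpec | None = None) -> TinyEncoder:
    """Build a :class:`TinyEncoder` whose vocabulary covers ``texts``."""
    return TinyEncoder(Vocabulary.from_texts(texts), spec)
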