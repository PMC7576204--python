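"""Multi-scale layer-wise attention network for trajectory classification.

The network runs eight parallel stacks over the standardized feature series:
four 1D-convolutional stacks whose kernels span 3%, 6%, 9% and 12% of the
maximum sequence length (short- to mid-range shape detectors) and four LSTM
stacks (long-range dependencies).  Every layer of every stack (default four
layers of 16 units, dropout 0.5) feeds one attention neuron

    a = softmax(tanh(W_a Z^T + b_a)),

where Z is the layer's output sequence, W_a is a 1xN weight vector and b_a a
per-time-step bias.  The tanh bounds the pre-softmax logits to [-1, 1], which
smooths the attention (max/min ratio at most e^2), and the softmax is taken
over valid (unpadded) time steps only so that padding can never absorb
attention mass.  Each layer's output is weighted by its attention, all
weighted outputs are concatenated channel-wise, mean-pooled over valid steps
and classified by a dense softmax head over the two classes.

Padded time steps are zeroed at the input and after every layer, making
predictions and attentions exactly independent of the amount of trailing
padding.  The sentinel -1.0 used in stored feature tensors is canonicalized
away internally.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .errors import ValidationError
from .features import FeatureTensor

__all__ = ["ModelConfig", "DeepHLNet", "layer_attention", "ForwardResult", "batch_tensors"]


@dataclass(frozen=True)
class ModelConfig:
    l_max: int
    n_features: int
    n_stacks_conv: int = 4
    n_stacks_recurrent: int = 4
    layers_per_stack: int = 4
    units: int = 16
    conv_kernel_fractions: tuple = (0.03, 0.06, 0.09, 0.12)
    dropout_rate: float = 0.5

    def kernel_sizes(self) -> list[int]:
        sizes = [int(round(f * self.l_max)) for f in self.conv_kernel_fractions]
        if any(k < 1 for k in sizes):
            raise ValidationError(
                f"kernel fraction times l_max={self.l_max} rounds to 0: {sizes}")
        return sizes

    def validate(self) -> None:
        if self.units < 1 or self.layers_per_stack < 1:
            raise ValidationError("units and layers_per_stack must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if len(self.conv_kernel_fractions) != self.n_stacks_conv:
            raise ValidationError("one kernel fraction per convolutional stack required")
        self.kernel_sizes()


@dataclass
class ForwardResult:
    probabilities: np.ndarray  # (B, 2)
    attentions: dict  # layer_id -> (B, T)
    logits: "nn.Tensor"


def layer_attention(Z: np.ndarray, W_a: np.ndarray, b_a: np.ndarray,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Attention of one layer output: softmax(tanh(W_a Z^T + b_a)) over valid steps.

    Z: (T, N) or (B, T, N); W_a: (N,) or (1, N); b_a: (T,) or (1, T);
    mask: bool over time (default all valid).  Padded steps get attention 0.
    """
    Z = np.asarray(Z, dtype=float)
    squeeze = Z.ndim == 2
    if squeeze:
        Z = Z[None]
    B, T, N = Z.shape
    W_a = np.asarray(W_a, dtype=float).reshape(N)
    b_a = np.asarray(b_a, dtype=float).reshape(-1)[:T]
    if mask is None:
        mask = np.ones((B, T), dtype=bool)
    else:
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), (B, T) if mask.ndim > 1 else (T,))
        if mask.ndim == 1:
            mask = np.broadcast_to(mask, (B, T))
    if not mask.any(axis=1).all():
        raise ValidationError("attention over an all-masked sequence is undefined")
    scores = np.tanh(Z @ W_a + b_a)
    scores = np.where(mask, scores, -np.inf)
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.where(mask, np.exp(scores), 0.0)
    a = e / e.sum(axis=1, keepdims=True)
    return a[0] if squeeze else a


#: the network trains in float32 (memory-bandwidth bound on CPU)
DTYPE = np.float32


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(DTYPE)


class DeepHLNet:
    """The trajectory classifier; parameters live in ``self.params``."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.params: dict[str, nn.Tensor] = {}
        rng = np.random.default_rng([int(seed), 0x9E3779B9])
        C = config.units
        kernels = config.kernel_sizes()
        self.layer_ids: list[str] = []
        for s, K in enumerate(kernels):
            for l in range(config.layers_per_stack):
                cin = config.n_features if l == 0 else C
                lid = f"conv{s + 1}_l{l + 1}"
                self._add(f"{lid}.w", _glorot(rng, (K, cin, C), K * cin, K * C))
                self._add(f"{lid}.b", np.zeros(C))
                self._add_attention(rng, lid)
        for s in range(config.n_stacks_recurrent):
            for l in range(config.layers_per_stack):
                cin = config.n_features if l == 0 else C
                lid = f"lstm{s + 1}_l{l + 1}"
                self._add(f"{lid}.wx", _glorot(rng, (cin, 4 * C), cin, 4 * C))
                self._add(f"{lid}.wh", _glorot(rng, (C, 4 * C), C, 4 * C))
                b = np.zeros(4 * C)
                b[C:2 * C] = 1.0  # forget-gate bias
                self._add(f"{lid}.b", b)
                self._add_attention(rng, lid)
        n_layers = (config.n_stacks_conv + config.n_stacks_recurrent) * config.layers_per_stack
        self._add("head.w", _glorot(rng, (n_layers * C, 2), n_layers * C, 2))
        self._add("head.b", np.zeros(2))
        self.class_labels: tuple = ("A", "B")

    def _add(self, name: str, data: np.ndarray) -> None:
        self.params[name] = nn.Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)

    def _add_attention(self, rng: np.random.Generator, lid: str) -> None:
        C = self.config.units
        self._add(f"{lid}.att_w", _glorot(rng, (C, 1), C, 1))
        self._add(f"{lid}.att_b", np.zeros(self.config.l_max))
        self.layer_ids.append(lid)

    def parameters(self) -> list:
        return list(self.params.values())

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray, mask: np.ndarray,
                training: bool = False, rng: np.random.Generator | None = None) -> ForwardResult:
        """Run the network on a batch.

        X: (B, T, n_features) with arbitrary values at padded steps;
        mask: (B, T) validity.  Returns class probabilities, one attention
        vector per layer (zero at padded steps) and the logits tensor for
        loss computation.
        """
        cfg = self.config
        if X.ndim != 3 or X.shape[2] != cfg.n_features or X.shape[1] > cfg.l_max:
            raise ValidationError(f"input shape {X.shape} incompatible with model "
                                  f"(l_max={cfg.l_max}, n_features={cfg.n_features})")
        if not mask.any(axis=1).all():
            raise ValidationError("a fully padded sequence cannot be classified")
        if training and rng is None:
            rng = np.random.default_rng()
        B, T, _ = X.shape
        maskf = mask.astype(DTYPE)[:, :, None]
        x_in = nn.Tensor(np.where(mask[:, :, None], X, 0.0).astype(DTYPE))
        weighted, attentions = [], {}
        for s_kind, n_stacks in (("conv", cfg.n_stacks_conv), ("lstm", cfg.n_stacks_recurrent)):
            for s in range(n_stacks):
                h = x_in
                for l in range(cfg.layers_per_stack):
                    lid = f"{s_kind}{s + 1}_l{l + 1}"
                    if s_kind == "conv":
                        z = nn.conv1d_same(h, self.params[f"{lid}.w"], self.params[f"{lid}.b"])
                        z = nn.tanh(z)
                    else:
                        z = nn.lstm(h, self.params[f"{lid}.wx"], self.params[f"{lid}.wh"],
                                    self.params[f"{lid}.b"])
                    z = nn.mul(z, maskf)
                    z = nn.dropout(z, cfg.dropout_rate, rng, training)
                    scores = nn.reshape(nn.matmul(z, self.params[f"{lid}.att_w"]), (B, T))
                    scores = nn.add(scores, nn.slice_(self.params[f"{lid}.att_b"], slice(0, T)))
                    att = nn.masked_softmax(nn.tanh(scores), mask)
                    attentions[lid] = att.data
                    weighted.append(nn.mul(z, nn.reshape(att, (B, T, 1))))
                    h = z
        # mean over valid steps, then channel-wise concatenation (equivalent to
        # concatenating the weighted sequences first, but far smaller buffers)
        pooled = nn.concat([nn.masked_mean(w, mask) for w in weighted], axis=-1)
        logits = nn.add(nn.matmul(pooled, self.params["head.w"]), self.params["head.b"])
        zl = logits.data - logits.data.max(axis=1, keepdims=True)
        probs = np.exp(zl)
        probs /= probs.sum(axis=1, keepdims=True)
        return ForwardResult(probabilities=probs, attentions=attentions, logits=logits)

    def predict(self, tensors: list[FeatureTensor]) -> ForwardResult:
        """Evaluation-mode forward pass on a list of feature tensors."""
        X, mask = batch_tensors(tensors)
        with nn.no_grad():
            return self.forward(X, mask, training=False)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path, extra_meta: dict | None = None) -> None:
        """Binary checkpoint: one npz with parameters + JSON-encoded config."""
        meta = {"config": asdict(self.config), "class_labels": list(self.class_labels)}
        meta.update(extra_meta or {})
        arrays = {name.replace("/", "_"): p.data for name, p in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["DeepHLNet", dict]:
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            cfg_d = meta["config"]
            cfg_d["conv_kernel_fractions"] = tuple(cfg_d["conv_kernel_fractions"])
            config = ModelConfig(**cfg_d)
            model = cls(config, seed=0)
            for name in model.params:
                model.params[name].data = npz[name].astype(DTYPE)
        model.class_labels = tuple(meta["class_labels"])
        return model, meta


def batch_tensors(tensors: list[FeatureTensor]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([ft.values for ft in tensors])
    mask = np.stack([ft.mask for ft in tensors])
    return X, mask
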