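"""Stacked autoencoder for nonlinear dimensionality reduction.

Five layers l1..l5 (l1 = the 277 input features) connected by weight
matrices W1..W4 with strictly decreasing widths, sigmoid hidden
activations.  Training follows the classic two-step recipe: greedy
unsupervised pretraining (each autoencoder reconstructs the code of the
previous one, linear decoder, MSE loss), then supervised fine-tuning of
the whole stack with a 2-unit softmax label layer appended to l5.  The
label layer exists only during fine-tuning; the encoder up to l5 is the
dimensionality reducer handed to the SVM, and the retained weight
matrices are the input to the backward contribution analysis.

Implemented in numpy with a full-batch Adam optimizer: the cohorts are
small (tens of subjects, hundreds of features), so explicit matrix
gradients are both transparent and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_HIDDEN_SIZES = (128, 64, 32, 10)
DEFAULT_PRETRAIN_EPOCHS = 30
DEFAULT_FINETUNE_EPOCHS = 100
DEFAULT_LEARNING_RATE = 1e-2


@dataclass(frozen=True)
class SaeConfig:
    hidden_sizes: tuple[int, ...] = DEFAULT_HIDDEN_SIZES
    pretrain_epochs: int = DEFAULT_PRETRAIN_EPOCHS
    finetune_epochs: int = DEFAULT_FINETUNE_EPOCHS
    learning_rate: float = DEFAULT_LEARNING_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if any(b >= a for a, b in zip(self.hidden_sizes, self.hidden_sizes[1:])):
            raise ValueError("hidden sizes must be strictly decreasing")
        if self.pretrain_epochs < 0 or self.finetune_epochs < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class SaeModel:
    """Encoder weights W1..Wk (each shaped out x in), biases, label layer."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    label_weight: np.ndarray | None = None
    label_bias: np.ndarray | None = None
    pretrain_losses: list[list[float]] = field(default_factory=list)
    finetune_losses: list[float] = field(default_factory=list)
    config: SaeConfig | None = None

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[1],) + tuple(w.shape[0] for w in self.weights)

    def validate(self) -> None:
        sizes = self.layer_sizes
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("layer sizes must be strictly decreasing")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape[0] != b.shape[0]:
                raise ValueError(f"bias {i} does not match weight {i}")
        if self.label_weight is not None and self.label_weight.shape[0] != 2:
            raise ValueError("label layer must have width 2 (binary)")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _init_layer(rng: np.random.Generator, n_out: int, n_in: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
    return rng.uniform(-scale, scale, (n_out, n_in))


def pretrain_autoencoders(
    x: np.ndarray, config: SaeConfig = SaeConfig()
) -> tuple[list[np.ndarray], list[np.ndarray], list[list[float]]]:
    """Greedy layer-wise pretraining.

    Autoencoder i encodes the previous layer's code with a sigmoid unit
    and reconstructs it with a linear decoder under MSE; only the
    encoder half is kept.  Returns (weights, biases, per-AE loss logs).
    Zero epochs returns the seeded random initialization untouched.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be 2-D (subjects x features)")
    rng = np.random.default_rng(config.seed)
    sizes = (x.shape[1],) + tuple(config.hidden_sizes)
    weights: list[np.ndarray] = []
    biases: list[np.ndarray] = []
    logs: list[list[float]] = []
    current = x
    n = x.shape[0]
    for i in range(len(sizes) - 1):
        n_in, n_out = sizes[i], sizes[i + 1]
        w_enc = _init_layer(rng, n_out, n_in)
        b_enc = np.zeros(n_out)
        w_dec = _init_layer(rng, n_in, n_out)
        b_dec = np.zeros(n_in)
        opt = _Adam([w_enc, b_enc, w_dec, b_dec], config.learning_rate)
        losses: list[float] = []
        for _ in range(config.pretrain_epochs):
            h = _sigmoid(current @ w_enc.T + b_enc)
            recon = h @ w_dec.T + b_dec
            err = recon - current
            loss = float((err**2).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite pretraining loss in autoencoder {i + 1}; "
                    f"reduce learning rate (currently {config.learning_rate})"
                )
            losses.append(loss)
            scale = 2.0 / err.size
            g_wdec = scale * err.T @ h
            g_bdec = scale * err.sum(axis=0)
            dh = scale * err @ w_dec
            dz = dh * h * (1 - h)
            g_wenc = dz.T @ current
            g_benc = dz.sum(axis=0)
            opt.step([g_wenc, g_benc, g_wdec, g_bdec])
        weights.append(w_enc)
        biases.append(b_enc)
        logs.append(losses)
        current = _sigmoid(current @ w_enc.T + b_enc)
        assert current.shape == (n, n_out)
    return weights, biases, logs


def fine_tune_supervised(
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    x: np.ndarray,
    y: np.ndarray,
    config: SaeConfig = SaeConfig(),
    pretrain_losses: list[list[float]] | None = None,
) -> SaeModel:
    """End-to-end supervised training with a 2-unit softmax label layer.

    Cross-entropy on the binary labels; all encoder weights and the
    label layer are updated together.  The label layer is retained on
    the returned model for the attribution pass.
    """
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("fine-tuning needs both classes present")
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(config.seed + 1)
    weights = [w.copy() for w in weights]
    biases = [b.copy() for b in biases]
    w_lab = _init_layer(rng, 2, weights[-1].shape[0])
    b_lab = np.zeros(2)
    params = [*weights, *biases, w_lab, b_lab]
    opt = _Adam(params, config.learning_rate)
    onehot = np.eye(2)[y]
    losses: list[float] = []
    for _ in range(config.finetune_epochs):
        acts = [x]
        for w, b in zip(weights, biases):
            acts.append(_sigmoid(acts[-1] @ w.T + b))
        logits = acts[-1] @ w_lab.T + b_lab
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        loss = float(-(onehot * np.log(probs + 1e-12)).sum(axis=1).mean())
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite fine-tuning loss; reduce learning rate "
                f"(currently {config.learning_rate})"
            )
        losses.append(loss)
        dlogits = (probs - onehot) / x.shape[0]
        g_wlab = dlogits.T @ acts[-1]
        g_blab = dlogits.sum(axis=0)
        upstream = dlogits @ w_lab
        g_w: list[np.ndarray] = []
        g_b: list[np.ndarray] = []
        for i in range(len(weights) - 1, -1, -1):
            dz = upstream * acts[i + 1] * (1 - acts[i + 1])
            g_w.append(dz.T @ acts[i])
            g_b.append(dz.sum(axis=0))
            upstream = dz @ weights[i]
        g_w.reverse()
        g_b.reverse()
        opt.step([*g_w, *g_b, g_wlab, g_blab])
    model = SaeModel(
        weights=weights,
        biases=biases,
        label_weight=w_lab,
        label_bias=b_lab,
        pretrain_losses=pretrain_losses or [],
        finetune_losses=losses,
        config=config,
    )
    model.validate()
    return model


def train_sae(x: np.ndarray, y: np.ndarray, config: SaeConfig = SaeConfig()) -> SaeModel:
    """Pretrain then fine-tune on (x, y)."""
    weights, biases, logs = pretrain_autoencoders(x, config)
    return fine_tune_supervised(weights, biases, x, y, config, pretrain_losses=logs)


def encode(model: SaeModel, x: np.ndarray) -> np.ndarray:
    """Deterministic forward pass to the bottleneck layer l5."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.weights[0].shape[1]:
        raise ValueError(
            f"x must have {model.weights[0].shape[1]} columns, got {x.shape}"
        )
    h = x
    for w, b in zip(model.weights, model.biases):
        h = _sigmoid(h @ w.T + b)
    return h
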