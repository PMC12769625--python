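"""A compact NumPy convolutional-network engine.

Implements exactly what the desk-scale experiments need: 3x3 same-padding
convolutions (im2col), ReLU, 2x2 max-pooling, nearest-neighbour upsampling with
skip connections, a global-average-pool classifier head, Adam, softmax
cross-entropy, and a Dice + binary-cross-entropy segmentation loss.  Everything
is float64-free (float32 throughout), seeded, and single-threaded-deterministic.

Two models are provided on a shared encoder:

* :class:`FractalClassifier` — encoder + GAP + linear head for the category
  pretext task;
* :class:`SegNet` — encoder + skip-connected decoder + 1x1 head producing a
  single foreground logit map.

The encoder weights transfer between them by name, which is the mechanism of
the pretraining -> fine-tuning handoff (the classification head is dropped on
export).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["SegNet", "FractalClassifier", "Adam", "softmax_cross_entropy",
           "dice_bce_loss", "sigmoid", "save_checkpoint", "load_checkpoint",
           "DEFAULT_WIDTHS"]

DEFAULT_WIDTHS = (4, 8, 16, 32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# layers


class Conv3x3:
    """3x3 convolution, stride 1, zero same-padding."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str):
        scale = np.sqrt(2.0 / (cin * 9))  # He init for ReLU nets
        self.W = (rng.standard_normal((cout, cin * 9)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.name = name
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * Wd, C * 9)
        out = cols @ self.W.T + self.b
        if train:
            self._cols = cols
            self._shape = (B, C, H, Wd)
        return out.reshape(B, H, Wd, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, Wd = self._shape
        dyc = dy.transpose(0, 2, 3, 1).reshape(B * H * Wd, -1)
        self.dW = (dyc.T @ self._cols).astype(np.float32)
        self.db = dyc.sum(axis=0).astype(np.float32)
        dcols = (dyc @ self.W).reshape(B, H, Wd, C, 3, 3).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, H + 2, Wd + 2), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + H, j : j + Wd] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, :, 1 : H + 1, 1 : Wd + 1]

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}


class Conv1x1:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str):
        self.W = (rng.standard_normal((cout, cin)) * np.sqrt(2.0 / cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.name = name

    def params(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def forward(self, x, train=True):
        if train:
            self._x = x
        return np.einsum("oc,bchw->bohw", self.W, x) + self.b[None, :, None, None]

    def backward(self, dy):
        self.dW = np.einsum("bohw,bchw->oc", dy, self._x).astype(np.float32)
        self.db = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        dx = np.einsum("oc,bohw->bchw", self.W, dy)
        self._x = None
        return dx

    def grads(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}


class ReLU:
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2:
    def forward(self, x, train=True):
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            self._mask = xr == out[:, :, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, dy):
        B, C, H, W = self._shape
        dx = (self._mask * dy[:, :, :, None, :, None]).reshape(B, C, H, W)
        self._mask = None
        return dx.astype(np.float32)


class Upsample2:
    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        B, C, H, W = dy.shape
        return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5)).astype(np.float32)


class Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str):
        self.W = (rng.standard_normal((cout, cin)) * np.sqrt(1.0 / cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.name = name

    def params(self):
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = (dy.T @ self._x).astype(np.float32)
        self.db = dy.sum(axis=0).astype(np.float32)
        dx = dy @ self.W
        self._x = None
        return dx

    def grads(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}


# ---------------------------------------------------------------------------
# models


class _Encoder:
    """Four conv+ReLU levels separated by 2x2 max-pools."""

    def __init__(self, in_channels: int, widths: tuple[int, ...],
                 rng: np.random.Generator):
        self.convs = []
        cin = in_channels
        for lvl, w in enumerate(widths):
            self.convs.append(Conv3x3(cin, w, rng, name=f"enc{lvl}"))
            cin = w
        self.relus = [ReLU() for _ in widths]
        self.pools = [MaxPool2() for _ in range(len(widths) - 1)]
        self.widths = widths

    def forward(self, x, train=True):
        feats = []
        for lvl, (conv, relu) in enumerate(zip(self.convs, self.relus)):
            x = relu.forward(conv.forward(x, train), train)
            feats.append(x)
            if lvl < len(self.pools):
                x = self.pools[lvl].forward(x, train)
        return feats  # feats[-1] is the deepest (post-pool applied before next conv)

    def backward_from(self, dfeats):
        """dfeats: list of gradients w.r.t. each level's feature map."""
        dx = None
        for lvl in reversed(range(len(self.convs))):
            d = dfeats[lvl]
            if dx is not None:
                d = d + self.pools[lvl].backward(dx)
            dx = self.convs[lvl].backward(self.relus[lvl].backward(d))
        return dx

    def params(self):
        out = {}
        for c in self.convs:
            out.update(c.params())
        return out

    def grads(self):
        out = {}
        for c in self.convs:
            out.update(c.grads())
        return out


class FractalClassifier:
    """Encoder + flattened deep features + linear head for the pretext task.

    The flatten head (rather than global average pooling) keeps the spatial
    layout of the deepest feature map, which carries most of the information
    distinguishing fractal categories; it is discarded on encoder export.
    """

    def __init__(self, n_classes: int, in_channels: int = 1,
                 widths: tuple[int, ...] = DEFAULT_WIDTHS, seed: int = 0,
                 input_side: int = 64):
        rng = np.random.default_rng(seed)
        self.encoder = _Encoder(in_channels, widths, rng)
        deep_side = input_side // 2 ** (len(widths) - 1)
        self.head = Linear(widths[-1] * deep_side**2, n_classes, rng, name="head")
        self.n_classes = n_classes

    def forward(self, x, train=True):
        feats = self.encoder.forward(x.astype(np.float32), train)
        self._feat_shapes = [f.shape for f in feats]
        deep = feats[-1]
        flat = deep.reshape(deep.shape[0], -1)
        return self.head.forward(flat, train)

    def backward(self, dlogits):
        ddeep = self.head.backward(dlogits).reshape(self._feat_shapes[-1])
        dfeats = [np.zeros(s, dtype=np.float32) for s in self._feat_shapes[:-1]]
        dfeats.append(ddeep.astype(np.float32))
        self.encoder.backward_from(dfeats)

    def params(self):
        return {**self.encoder.params(), **self.head.params()}

    def grads(self):
        return {**self.encoder.grads(), **self.head.grads()}

    def encoder_state(self) -> dict[str, np.ndarray]:
        """Encoder weights only — the classification head is dropped on export."""
        return {k: v.copy() for k, v in self.encoder.params().items()}


class SegNet:
    """Skip-connected encoder-decoder emitting one foreground logit per pixel."""

    def __init__(self, in_channels: int = 1, widths: tuple[int, ...] = DEFAULT_WIDTHS,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = _Encoder(in_channels, widths, rng)
        self.ups = [Upsample2() for _ in range(len(widths) - 1)]
        self.dec_convs = []
        self.dec_relus = []
        cin = widths[-1]
        for lvl in reversed(range(len(widths) - 1)):
            conv = Conv3x3(cin + widths[lvl], widths[lvl], rng, name=f"dec{lvl}")
            self.dec_convs.append(conv)
            self.dec_relus.append(ReLU())
            cin = widths[lvl]
        self.out_head = Conv1x1(widths[0], 1, rng, name="seghead")
        self.widths = widths

    def forward(self, x, train=True):
        feats = self.encoder.forward(x.astype(np.float32), train)
        self._feat_shapes = [f.shape for f in feats]
        y = feats[-1]
        for k, lvl in enumerate(reversed(range(len(self.widths) - 1))):
            y = self.ups[k].forward(y, train)
            y = np.concatenate([y, feats[lvl]], axis=1)
            y = self.dec_relus[k].forward(self.dec_convs[k].forward(y, train), train)
        return self.out_head.forward(y, train)

    def backward(self, dlogits):
        dy = self.out_head.backward(dlogits)
        dfeats = [np.zeros(s, dtype=np.float32) for s in self._feat_shapes]
        for k in reversed(range(len(self.dec_convs))):
            lvl = len(self.widths) - 2 - k
            d = self.dec_convs[k].backward(self.dec_relus[k].backward(dy))
            skip_c = self._feat_shapes[lvl][1]
            dfeats[lvl] += d[:, -skip_c:]
            dy = self.ups[k].backward(d[:, :-skip_c])
        dfeats[-1] = dfeats[-1] + dy
        self.encoder.backward_from(dfeats)

    def params(self):
        out = self.encoder.params()
        for c in self.dec_convs:
            out.update(c.params())
        out.update(self.out_head.params())
        return out

    def grads(self):
        out = self.encoder.grads()
        for c in self.dec_convs:
            out.update(c.grads())
        out.update(self.out_head.grads())
        return out

    def load_encoder_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.encoder.params()
        for k, v in state.items():
            if k not in own:
                raise KeyError(f"unknown encoder weight {k}")
            if own[k].shape != v.shape:
                raise ValueError(f"shape mismatch for {k}: {own[k].shape} vs {v.shape}")
            own[k][...] = v

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.params()
        for k, v in state.items():
            own[k][...] = v

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params().items()}


# ---------------------------------------------------------------------------
# losses and optimizer


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


def dice_bce_loss(logits: np.ndarray, target: np.ndarray,
                  eps: float = 1.0) -> tuple[float, np.ndarray]:
    """Equal-weight sum of soft-Dice loss and BCE, with gradient w.r.t. logits.

    The soft Dice is batch-aggregated: D = (2*sum(p*g)+eps) / (sum(p)+sum(g)+eps),
    which is the stable choice under severe foreground/background imbalance.
    """
    p = sigmoid(logits)
    g = target.astype(np.float32)
    nel = logits.size
    bce = float(np.mean(np.clip(-np.log(np.where(g > 0.5, p, 1.0 - p) + 1e-7), 0, 50)))
    inter = float((p * g).sum())
    sums = float(p.sum() + g.sum())
    dice = (2.0 * inter + eps) / (sums + eps)
    loss = bce + (1.0 - dice)
    dbce_dp = (p - g) / nel  # gradient of BCE-with-logits w.r.t. logits
    ddice_dp = (2.0 * g * (sums + eps) - (2.0 * inter + eps)) / (sums + eps) ** 2
    ddice_dz = -ddice_dp * p * (1.0 - p)
    grad = (dbce_dp + ddice_dz).astype(np.float32)
    return float(loss), grad


class Adam:
    def __init__(self, params: dict[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# checkpoints: single-file NPZ weight archive with a JSON metadata block


def save_checkpoint(path: str | Path, state: dict[str, np.ndarray],
                    metadata: dict) -> None:
    buf = {k.replace(".", "__"): v for k, v in state.items()}
    buf["__metadata__"] = np.frombuffer(
        json.dumps(metadata).encode(), dtype=np.uint8
    )
    np.savez(path, **buf)


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__metadata__"]).decode()) if "__metadata__" in z else {}
        state = {k.replace("__", "."): z[k] for k in z.files if k != "__metadata__"}
    return state, meta
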