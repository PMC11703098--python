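"""Reduced-Xception CNN: 5-class border-morphology classifier whose global
average pooling layer doubles as a 32-dimensional patch embedding.

The classification task is a proxy: its only purpose is to shape convolution
filters that distinguish junction morphologies, after which the activation of
the global-average-pooling layer is used as the embedding of a patch.
Architecture: a stem of two plain convolutions (widths 16 and 32, stride-2
entry), three residual blocks of depthwise-separable convolutions (default
widths 32, 64, 64) each downsampled by 2x2 max pooling with a strided 1x1
convolution on the skip path, one separable convolution to exactly
``embedding_dim`` channels, global average pooling, and a softmax head of 5
units.  Global pooling destroys the position of the border inside the patch
while retaining morphology and its extent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from .roi import CLASS_NAMES, ROISet, augment_batch

N_CLASSES = 5


@dataclass
class ModelConfig:
    input_size: tuple[int, int, int] = (64, 64, 1)
    n_classes: int = N_CLASSES
    embedding_dim: int = 32
    stem_widths: tuple[int, int] = (16, 32)
    block_widths: tuple[int, ...] = (32, 64, 64)
    final_width: int = 32
    learning_rate: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 100
    patience: int | None = None  # early stop after this many non-improving epochs
    target_val_acc: float | None = None  # stop once validation accuracy reaches this
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes != N_CLASSES:
            raise ValueError("the morphology proxy task has exactly 5 classes")
        if self.final_width != self.embedding_dim:
            raise ValueError("final separable-conv width must equal embedding_dim")
        if self.input_size[0] != self.input_size[1] or self.input_size[0] % 16:
            raise ValueError("input must be square with side divisible by 16")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("invalid training hyperparameters")


class _Block:
    """Residual depthwise-separable block with stride-2 pooling."""

    def __init__(self, cin, cout, rng, dtype):
        self.r1 = _nn.ReLU()
        self.sep1 = _nn.SeparableConv2D(cin, cout, rng, dtype)
        self.bn1 = _nn.BatchNorm(cout, dtype=dtype)
        self.r2 = _nn.ReLU()
        self.sep2 = _nn.SeparableConv2D(cout, cout, rng, dtype)
        self.bn2 = _nn.BatchNorm(cout, dtype=dtype)
        self.pool = _nn.MaxPool2()
        self.skip = _nn.Conv2D(cin, cout, k=1, stride=2, rng=rng, dtype=dtype)
        self.bn_skip = _nn.BatchNorm(cout, dtype=dtype)

    def params(self):
        return (self.sep1.params() + self.bn1.params() + self.sep2.params()
                + self.bn2.params() + self.skip.params() + self.bn_skip.params())

    def bns(self):
        return [self.bn1, self.bn2, self.bn_skip]

    def forward(self, x, train=False):
        h = self.sep1.forward(self.r1.forward(x))
        h = self.r2.forward(self.bn1.forward(h, train))
        h = self.bn2.forward(self.sep2.forward(h), train)
        h = self.pool.forward(h)
        return h + self.bn_skip.forward(self.skip.forward(x), train)

    def backward(self, dout):
        dx = self.skip.backward(self.bn_skip.backward(dout))
        d = self.pool.backward(dout)
        d = self.sep2.backward(self.bn2.backward(d))
        d = self.bn1.backward(self.r2.backward(d))
        d = self.r1.backward(self.sep1.backward(d))
        return dx + d


class MorphologyCNN:
    """The network. ``forward`` returns (logits, embedding)."""

    def __init__(self, config: ModelConfig | None = None, dtype=np.float32):
        self.config = config or ModelConfig()
        self.config.validate()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.dtype = dtype
        s1, s2 = cfg.stem_widths
        self.conv1 = _nn.Conv2D(cfg.input_size[2], s1, k=3, stride=2, rng=rng, dtype=dtype)
        self.bn1 = _nn.BatchNorm(s1, dtype=dtype)
        self.r1 = _nn.ReLU()
        self.conv2 = _nn.Conv2D(s1, s2, k=3, stride=1, rng=rng, dtype=dtype)
        self.bn2 = _nn.BatchNorm(s2, dtype=dtype)
        self.r2 = _nn.ReLU()
        self.blocks = []
        cin = s2
        for w in cfg.block_widths:
            self.blocks.append(_Block(cin, w, rng, dtype))
            cin = w
        self.final_sep = _nn.SeparableConv2D(cin, cfg.embedding_dim, rng, dtype)
        self.bn3 = _nn.BatchNorm(cfg.embedding_dim, dtype=dtype)
        self.r3 = _nn.ReLU()
        self.gap = _nn.GlobalAvgPool()
        self.head = _nn.Dense(cfg.embedding_dim, cfg.n_classes, rng, dtype)

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[_nn.Param]:
        ps = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        for b in self.blocks:
            ps += b.params()
        return ps + self.final_sep.params() + self.bn3.params() + self.head.params()

    def _bns(self) -> list[_nn.BatchNorm]:
        out = [self.bn1, self.bn2]
        for b in self.blocks:
            out += b.bns()
        return out + [self.bn3]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_weights(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        for bn in self._bns():
            arrays += [bn.running_mean.copy(), bn.running_var.copy()]
        return arrays

    def set_weights(self, weights: list[np.ndarray]) -> None:
        n = len(self.params())
        stats = weights[n:]
        for p, w in zip(self.params(), weights[:n], strict=True):
            p.value[...] = w
        bns = self._bns()
        if stats:
            assert len(stats) == 2 * len(bns)
            for i, bn in enumerate(bns):
                bn.running_mean = stats[2 * i].copy()
                bn.running_var = stats[2 * i + 1].copy()

    # -- computation -------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:3] != self.config.input_size[:2]:
            raise ValueError(f"expected {self.config.input_size[:2]} patches, got {x.shape[1:3]}")
        h = self.r1.forward(self.bn1.forward(self.conv1.forward(x.astype(self.dtype, copy=False)), train))
        h = self.r2.forward(self.bn2.forward(self.conv2.forward(h), train))
        for b in self.blocks:
            h = b.forward(h, train)
        self._feat = self.r3.forward(self.bn3.forward(self.final_sep.forward(h), train))
        emb = self.gap.forward(self._feat)
        logits = self.head.forward(emb)
        return logits, emb

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.gap.backward(self.head.backward(dlogits))
        d = self.final_sep.backward(self.bn3.backward(self.r3.backward(d)))
        for b in reversed(self.blocks):
            d = b.backward(d)
        d = self.bn2.backward(self.r2.backward(d))
        d = self.conv2.backward(d)
        d = self.conv1.backward(self.bn1.backward(self.r1.backward(d)))

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {f"param_{i}": a for i, a in enumerate(self.get_weights())}
        np.savez_compressed(path, **arrays)
        cfg = self.config.__dict__.copy()
        with open(str(path) + ".json", "w") as fh:
            json.dump({"config": cfg, "classes": {str(k): v for k, v in CLASS_NAMES.items()}}, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "MorphologyCNN":
        with open(str(path) + ".json") as fh:
            raw = json.load(fh)["config"]
        for k in ("input_size", "stem_widths", "block_widths"):
            raw[k] = tuple(raw[k])
        model = cls(ModelConfig(**raw))
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        model.set_weights([data[f"param_{i}"] for i in range(len(data.files))])
        return model


def build_model(config: ModelConfig | None = None) -> MorphologyCNN:
    return MorphologyCNN(config)


def _as_xy(rois: ROISet) -> tuple[np.ndarray, np.ndarray]:
    y = rois.labels
    if y is None:
        raise ValueError("ROISet carries no morphology labels")
    if np.any((y < 1) | (y > N_CLASSES)):
        raise ValueError("labels must be class codes 1..5")
    return rois.patches, y - 1


def _eval(model: MorphologyCNN, x: np.ndarray, y: np.ndarray, batch: int) -> tuple[float, float]:
    losses, hits, n = 0.0, 0, len(x)
    for i in range(0, n, batch):
        logits, _ = model.forward(x[i : i + batch])
        loss, _ = _nn.softmax_cross_entropy(logits, y[i : i + batch])
        losses += loss * len(logits)
        hits += int((logits.argmax(axis=1) == y[i : i + batch]).sum())
    return losses / n, hits / n


def train(
    model: MorphologyCNN,
    train_set: ROISet,
    val_set: ROISet,
    config: ModelConfig | None = None,
) -> tuple[MorphologyCNN, pd.DataFrame]:
    """Train the proxy classifier with on-the-fly augmentation.

    Categorical cross-entropy, Adam at the configured learning rate, mirror/
    brightness/contrast augmentation applied to training patches only.  The
    checkpoint with the best validation loss (accuracy as tie-break) is
    restored into the returned model; history records per-epoch train/val
    loss and accuracy.
    """
    config = config or model.config
    config.validate()
    if len(train_set) == 0:
        raise ValueError("empty training set")
    xtr, ytr = _as_xy(train_set)
    xva, yva = _as_xy(val_set)
    rng = np.random.default_rng(config.seed + 1)
    opt = _nn.Adam(model.params(), lr=config.learning_rate)
    rows = []
    best = (np.inf, -np.inf, None)  # (val_loss, -val_acc ordering handled below)
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(xtr))
        ep_loss, ep_hits = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = augment_batch(xtr[idx], rng)
            logits, _ = model.forward(xb, train=True)
            loss, dlogits = _nn.softmax_cross_entropy(logits, ytr[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
            ep_hits += int((logits.argmax(axis=1) == ytr[idx]).sum())
        val_loss, val_acc = _eval(model, xva, yva, config.batch_size)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": ep_loss / len(xtr),
                "train_acc": ep_hits / len(xtr),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        improved = (val_loss, -val_acc) < (best[0], best[1])
        if improved:
            best = (val_loss, -val_acc, model.get_weights())
            stale = 0
        else:
            stale += 1
        if config.patience is not None and stale > config.patience:
            break
        if config.target_val_acc is not None and val_acc >= config.target_val_acc:
            break
    if best[2] is not None:
        model.set_weights(best[2])
    return model, pd.DataFrame(rows)


def classify(model: MorphologyCNN, rois: ROISet, batch: int = 256) -> np.ndarray:
    """Row-wise softmax class probabilities, shape (n, 5). Argmax = prediction."""
    probs = []
    for i in range(0, len(rois), batch):
        logits, _ = model.forward(rois.patches[i : i + batch])
        probs.append(_nn.softmax(logits))
    return np.concatenate(probs) if probs else np.zeros((0, N_CLASSES))


def embed(model: MorphologyCNN, rois: ROISet, batch: int = 256) -> np.ndarray:
    """Global-average-pool embeddings, shape (n, embedding_dim)."""
    out = []
    for i in range(0, len(rois), batch):
        _, emb = model.forward(rois.patches[i : i + batch])
        out.append(emb)
    return np.concatenate(out) if out else np.zeros((0, model.config.embedding_dim))
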