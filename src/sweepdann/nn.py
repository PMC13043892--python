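"""Convolutional classifiers with optional domain-adversarial training.

A small, fully seeded convolutional network implemented directly in numpy
(forward and backward passes are written out by hand; the finite-difference
tests in the suite check the gradients).  Two variants share one feature
extractor:

* a plain CNN: convolution blocks -> global average pooling -> label head,
  trained by cross-entropy on labeled source images;
* a DANN: the same feature extractor plus a domain head connected through a
  gradient-reversal layer.  Training minimizes label cross-entropy on the
  source while *maximizing* the domain classifier's error on source+target,
  which aligns the feature distributions of the two domains.  The reversal
  strength follows the standard warm-up schedule
  lambda(p) = 2/(1+exp(-gamma*p)) - 1 with p = training progress in [0, 1].

Everything is deterministic given (spec, TrainConfig.seed): initialization,
shuffling and target resampling each draw from their own seeded stream, so a
DANN trained with lambda identically zero reproduces the source-only CNN's
label path exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "ConvBlock",
    "ArchitectureSpec",
    "TrainConfig",
    "Classifier",
    "GradientReversal",
    "grl_lambda",
    "build_cnn",
    "build_dann",
    "train_source_only",
    "train_dann",
    "predict_scores",
    "save_classifier",
    "load_classifier",
]


# ----------------------------------------------------------------------
# Architecture


@dataclass(frozen=True)
class ConvBlock:
    """One convolution block: same-padding conv (odd kernel, stride 1),
    ReLU, then max-pooling."""

    channels: int
    kernel: Tuple[int, int] = (3, 3)
    pool: Tuple[int, int] = (1, 2)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Feature extractor + dense heads over an n_sample x W input image.

    The label head and (optional) domain head both consume the same feature
    vector (flattened or globally averaged final activations);
    ``domain_hidden=None`` defines the plain CNN.
    """

    input_shape: Tuple[int, int]
    blocks: Tuple[ConvBlock, ...] = (ConvBlock(16), ConvBlock(32), ConvBlock(64))
    label_hidden: Tuple[int, ...] = (64,)
    domain_hidden: Optional[Tuple[int, ...]] = (64,)
    # "flatten" keeps the window coordinate (sweeps are positional signals);
    # "gap" is the location-free global-average-pooling alternative.
    feature_pooling: str = "flatten"
    # per-channel batch normalization after each convolution (standard in
    # domain-adversarial training; stabilizes the minimax game)
    batch_norm: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "blocks",
            tuple(b if isinstance(b, ConvBlock) else ConvBlock(**b) for b in self.blocks),
        )
        self.validate()

    def validate(self) -> None:
        h, w = self.input_shape
        if h < 1 or w < 1:
            raise ValueError("input_shape must be positive")
        for i, b in enumerate(self.blocks):
            kh, kw = b.kernel
            if kh % 2 == 0 or kw % 2 == 0:
                raise ValueError(f"block {i}: kernels must be odd, got {b.kernel}")
            if b.channels < 1:
                raise ValueError(f"block {i}: channels must be >= 1")
            ph, pw = b.pool
            if h % ph or w % pw:
                raise ValueError(
                    f"block {i}: pool {b.pool} does not divide activation {h}x{w}"
                )
            h, w = h // ph, w // pw
        if self.feature_pooling not in ("gap", "flatten"):
            raise ValueError("feature_pooling must be 'gap' or 'flatten'")

    def block_shapes(self) -> List[Tuple[int, int, int]]:
        """(channels, H, W) after each block."""
        h, w = self.input_shape
        shapes = []
        for b in self.blocks:
            h, w = h // b.pool[0], w // b.pool[1]
            shapes.append((b.channels, h, w))
        return shapes

    @property
    def feature_dim(self) -> int:
        shapes = self.block_shapes()
        c, h, w = shapes[-1] if shapes else (1, *self.input_shape)
        return c if self.feature_pooling == "gap" else c * h * w

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        d["input_shape"] = tuple(d["input_shape"])
        d["blocks"] = tuple(
            ConvBlock(b["channels"], tuple(b["kernel"]), tuple(b["pool"]))
            for b in d["blocks"]
        )
        d["label_hidden"] = tuple(d["label_hidden"])
        if d.get("domain_hidden") is not None:
            d["domain_hidden"] = tuple(d["domain_hidden"])
        return cls(**d)


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 64
    optimizer: str = "adam"
    lr: float = 1e-3
    gamma: float = 10.0  # gradient-reversal warm-up sharpness
    domain_loss_weight: float = 1.0
    seed: int = 0
    deterministic: bool = True  # kept for the contract; numpy path is always deterministic

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 0 or self.batch_size == 0:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.lr <= 0 or self.gamma < 0:
            raise ValueError("lr must be > 0 and gamma >= 0")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


def grl_lambda(p: float, gamma: float) -> float:
    """Reversal strength schedule: 0 at p=0, saturating towards 1."""
    return 2.0 / (1.0 + math.exp(-gamma * p)) - 1.0


class GradientReversal:
    """Identity in the forward pass; multiplies gradients by -lambda in the
    backward pass (the adversarial sign flip of domain-adversarial training)."""

    def __init__(self, lam: float = 1.0):
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        self.lam = lam

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return -self.lam * dy


# ----------------------------------------------------------------------
# Layer primitives (float64, minibatch-first)


def _conv_same(x: np.ndarray, w: np.ndarray, b: Optional[np.ndarray]):
    """Same-padding stride-1 convolution via im2col.

    x: (B, Cin, H, W); w: (Cout, Cin, kh, kw).  Returns (out, cols) where
    cols is kept for the weight-gradient computation.
    """
    B, Cin, H, W = x.shape
    Cout, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # (B, Cin, H, W, kh, kw) -> (B, H*W, Cin*kh*kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, Cin * kh * kw)
    out = cols @ w.reshape(Cout, -1).T
    if b is not None:
        out += b
    return out.transpose(0, 2, 1).reshape(B, Cout, H, W), cols


def _conv_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray, x_shape):
    """Gradients of a same-padding conv.  dx is itself a convolution of dy
    with the spatially flipped, channel-transposed kernel."""
    B, Cin, H, W = x_shape
    Cout = w.shape[0]
    dy2 = dy.reshape(B, Cout, H * W).transpose(0, 2, 1)  # (B, P, Cout)
    dw = (dy2.reshape(-1, Cout).T @ cols.reshape(-1, cols.shape[-1])).reshape(w.shape)
    db = dy2.sum(axis=(0, 1))
    w_flip = w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
    dx, _ = _conv_same(dy, np.ascontiguousarray(w_flip), None)
    return dx, dw, db


def _maxpool(x: np.ndarray, pool: Tuple[int, int]):
    ph, pw = pool
    B, C, H, W = x.shape
    xr = x.reshape(B, C, H // ph, ph, W // pw, pw).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(B, C, H // ph, W // pw, ph * pw)
    am = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, am[..., None], axis=-1)[..., 0]
    return out, am


def _maxpool_backward(dy: np.ndarray, am: np.ndarray, pool, x_shape):
    ph, pw = pool
    B, C, H, W = x_shape
    dxr = np.zeros((B, C, H // ph, W // pw, ph * pw))
    np.put_along_axis(dxr, am[..., None], dy[..., None], axis=-1)
    dxr = dxr.reshape(B, C, H // ph, W // pw, ph, pw).transpose(0, 1, 2, 4, 3, 5)
    return dxr.reshape(B, C, H, W)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean CE loss and gradient w.r.t. logits."""
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    n = len(y)
    loss = -float(logp[np.arange(n), y].mean())
    grad = softmax(logits)
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


# ----------------------------------------------------------------------
# Classifier


class Classifier:
    """CNN / DANN with explicit parameter dict and hand-written backprop.

    Parameter names: ``conv{i}/W|b`` for the feature extractor,
    ``label{i}/W|b`` and ``label_out/W|b`` for the label head, and the
    analogous ``domain*`` names when a domain head exists.
    """

    def __init__(self, spec: ArchitectureSpec, kind: str, seed: int = 0):
        if kind not in ("cnn", "dann"):
            raise ValueError("kind must be 'cnn' or 'dann'")
        if kind == "dann" and spec.domain_hidden is None:
            raise ValueError("a DANN spec needs a domain head")
        self.spec = spec
        self.kind = kind
        self.seed = seed
        self.history: List[dict] = []
        # affine input standardization, fit on the training source set
        self.input_mean: float = 0.0
        self.input_std: float = 1.0
        # batch-norm running (mean, var) per block, for inference mode
        self.bn_running: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        self.bn_momentum = 0.1
        self.params: Dict[str, np.ndarray] = {}
        self._init_params()

    def fit_input_scaling(self, x: np.ndarray) -> None:
        self.input_mean = float(np.mean(x))
        self.input_std = float(max(np.std(x), 1e-8))

    # -- initialization -------------------------------------------------
    def _init_params(self) -> None:
        spec = self.spec
        cin = 1
        for i, blk in enumerate(spec.blocks):
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0, i]))
            fan_in = cin * blk.kernel[0] * blk.kernel[1]
            self.params[f"conv{i}/W"] = rng.normal(
                0.0, math.sqrt(2.0 / fan_in), size=(blk.channels, cin, *blk.kernel)
            )
            self.params[f"conv{i}/b"] = np.zeros(blk.channels)
            if spec.batch_norm:
                self.params[f"bn{i}/gamma"] = np.ones(blk.channels)
                self.params[f"bn{i}/beta"] = np.zeros(blk.channels)
                self.bn_running[f"bn{i}"] = (np.zeros(blk.channels), np.ones(blk.channels))
            cin = blk.channels
        self._init_head("label", spec.label_hidden, group=0, offset=100)
        if self.kind == "dann":
            self._init_head("domain", spec.domain_hidden, group=1, offset=100)

    def _init_head(self, name: str, hidden: Sequence[int], group: int, offset: int):
        dim = self.spec.feature_dim
        for i, width in enumerate(hidden):
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, group, offset + i]))
            self.params[f"{name}{i}/W"] = rng.normal(0.0, math.sqrt(2.0 / dim), size=(width, dim))
            self.params[f"{name}{i}/b"] = np.zeros(width)
            dim = width
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, group, offset + 99]))
        self.params[f"{name}_out/W"] = rng.normal(0.0, math.sqrt(1.0 / dim), size=(2, dim))
        self.params[f"{name}_out/b"] = np.zeros(2)

    # -- bookkeeping -----------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def label_path_names(self) -> List[str]:
        return sorted(k for k in self.params if not k.startswith("domain"))

    def domain_path_names(self) -> List[str]:
        return sorted(k for k in self.params if k.startswith("domain"))

    # -- batch normalization ----------------------------------------------
    def _bn_forward(self, name: str, a: np.ndarray, train: bool, update_stats: bool):
        gamma = self.params[f"{name}/gamma"][None, :, None, None]
        beta = self.params[f"{name}/beta"][None, :, None, None]
        eps = 1e-5
        if train:
            mu = a.mean(axis=(0, 2, 3))
            var = a.var(axis=(0, 2, 3))
            if update_stats:
                rm, rv = self.bn_running[name]
                m = self.bn_momentum
                self.bn_running[name] = ((1 - m) * rm + m * mu, (1 - m) * rv + m * var)
        else:
            mu, var = self.bn_running[name]
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (a - mu[None, :, None, None]) * inv[None, :, None, None]
        return gamma * xhat + beta, (xhat, inv, train)

    def _bn_backward(self, name: str, dy: np.ndarray, bn_cache, grads):
        xhat, inv, train = bn_cache
        gamma = self.params[f"{name}/gamma"]
        grads[f"{name}/gamma"] = grads.get(f"{name}/gamma", 0.0) + (dy * xhat).sum(
            axis=(0, 2, 3)
        )
        grads[f"{name}/beta"] = grads.get(f"{name}/beta", 0.0) + dy.sum(axis=(0, 2, 3))
        dxhat = dy * gamma[None, :, None, None]
        if not train:  # running statistics are constants w.r.t. the batch
            return dxhat * inv[None, :, None, None]
        B, C, H, W = dy.shape
        n = B * H * W
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)

    # -- forward / backward ----------------------------------------------
    def feature_forward(self, x: np.ndarray, train: bool = False,
                        update_stats: Optional[bool] = None):
        """x: (B, H, W) image batch -> (features (B, F), cache).

        ``train`` selects batch statistics for batch norm (vs running
        statistics); ``update_stats`` controls whether this pass refreshes
        the running statistics (defaults to ``train``).
        """
        if update_stats is None:
            update_stats = train
        a = (x[:, None, :, :].astype(np.float64) - self.input_mean) / self.input_std
        cache = {"x_shapes": [], "cols": [], "relu": [], "am": [], "bn": []}
        for i, blk in enumerate(self.spec.blocks):
            cache["x_shapes"].append(a.shape)
            a, cols = _conv_same(a, self.params[f"conv{i}/W"], self.params[f"conv{i}/b"])
            cache["cols"].append(cols)
            if self.spec.batch_norm:
                a, bn_cache = self._bn_forward(f"bn{i}", a, train, update_stats)
                cache["bn"].append(bn_cache)
            mask = a > 0
            a = a * mask
            cache["relu"].append(mask)
            a, am = _maxpool(a, blk.pool)
            cache["am"].append(am)
        cache["pre_gap_shape"] = a.shape
        cache["block_out"] = a
        if self.spec.feature_pooling == "gap":
            feat = a.mean(axis=(2, 3))
        else:
            feat = a.reshape(a.shape[0], -1)
        return feat, cache

    def feature_backward(self, dfeat: np.ndarray, cache, grads: Dict[str, np.ndarray]):
        B, C, H, W = cache["pre_gap_shape"]
        if self.spec.feature_pooling == "gap":
            da = np.broadcast_to(dfeat[:, :, None, None], (B, C, H, W)) / (H * W)
        else:
            da = dfeat.reshape(B, C, H, W)
        for i in reversed(range(len(self.spec.blocks))):
            blk = self.spec.blocks[i]
            pooled_in_shape = cache["relu"][i].shape
            da = _maxpool_backward(da, cache["am"][i], blk.pool, pooled_in_shape)
            da = da * cache["relu"][i]
            if self.spec.batch_norm:
                da = self._bn_backward(f"bn{i}", da, cache["bn"][i], grads)
            da, dw, db = _conv_backward(
                da, cache["cols"][i], self.params[f"conv{i}/W"], cache["x_shapes"][i]
            )
            grads[f"conv{i}/W"] = grads.get(f"conv{i}/W", 0.0) + dw
            grads[f"conv{i}/b"] = grads.get(f"conv{i}/b", 0.0) + db
        return da

    def head_forward(self, feat: np.ndarray, name: str):
        hidden = self.spec.label_hidden if name == "label" else self.spec.domain_hidden
        a = feat
        cache = []
        for i in range(len(hidden)):
            w, b = self.params[f"{name}{i}/W"], self.params[f"{name}{i}/b"]
            z = a @ w.T + b
            mask = z > 0
            cache.append((a, mask))
            a = z * mask
        logits = a @ self.params[f"{name}_out/W"].T + self.params[f"{name}_out/b"]
        return logits, (cache, a)

    def head_backward(self, dlogits: np.ndarray, hcache, name: str, grads):
        cache, a_last = hcache
        grads[f"{name}_out/W"] = grads.get(f"{name}_out/W", 0.0) + dlogits.T @ a_last
        grads[f"{name}_out/b"] = grads.get(f"{name}_out/b", 0.0) + dlogits.sum(axis=0)
        da = dlogits @ self.params[f"{name}_out/W"]
        for i in reversed(range(len(cache))):
            a_in, mask = cache[i]
            dz = da * mask
            grads[f"{name}{i}/W"] = grads.get(f"{name}{i}/W", 0.0) + dz.T @ a_in
            grads[f"{name}{i}/b"] = grads.get(f"{name}{i}/b", 0.0) + dz.sum(axis=0)
            da = dz @ self.params[f"{name}{i}/W"]
        return da

    def label_logits(self, x: np.ndarray) -> np.ndarray:
        feat, _ = self.feature_forward(x)
        logits, _ = self.head_forward(feat, "label")
        return logits

    # -- Grad-CAM hooks ----------------------------------------------------
    def gradcam_components(self, x: np.ndarray, class_index: int):
        """Last-block activations A and d(class logit)/dA for a batch.

        Returns (A, dA), both (B, C, H', W').  The label head sits directly
        on the global average pool of A, so the chain is short and exact.
        """
        if class_index not in (0, 1):
            raise ValueError("class_index must be 0 or 1")
        feat, cache = self.feature_forward(x)
        logits, hcache = self.head_forward(feat, "label")
        dlogits = np.zeros_like(logits)
        dlogits[:, class_index] = 1.0
        grads: Dict[str, np.ndarray] = {}
        dfeat = self.head_backward(dlogits, hcache, "label", grads)
        A = cache["block_out"]
        B, C, H, W = A.shape
        if self.spec.feature_pooling == "gap":
            dA = np.broadcast_to(dfeat[:, :, None, None], (B, C, H, W)) / (H * W)
        else:
            dA = dfeat.reshape(B, C, H, W)
        return A, np.ascontiguousarray(dA)


def build_cnn(spec: ArchitectureSpec, seed: int = 0) -> Classifier:
    """Untrained source-only convolutional classifier."""
    return Classifier(spec, "cnn", seed=seed)


def build_dann(spec: ArchitectureSpec, seed: int = 0) -> Classifier:
    """Untrained domain-adversarial classifier sharing the CNN's feature and
    label initialization for the same seed."""
    return Classifier(spec, "dann", seed=seed)


# ----------------------------------------------------------------------
# Optimizer


class Adam:
    def __init__(self, names: Sequence[str], lr: float):
        self.names = list(names)
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in self.names:
            if k not in grads:
                continue
            g = grads[k]
            m = self.m.get(k)
            if m is None:
                m = np.zeros_like(params[k])
                self.m[k] = m
                self.v[k] = np.zeros_like(params[k])
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ----------------------------------------------------------------------
# Training


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if not np.isin(classes, [0, 1]).all() or classes.size < 2:
        raise ValueError("training labels must contain both classes 0 and 1")
    return labels.astype(np.int64)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield perm[lo : lo + batch_size]


def train_source_only(model: Classifier, images, labels=None, config: Optional[TrainConfig] = None) -> Classifier:
    """Minimize label cross-entropy on labeled source images.

    ``images`` may be an ImageSet (labels taken from it) or a raw
    (n, H, W) array plus explicit ``labels``.
    """
    cfg = config or TrainConfig()
    x, y = _unpack(images, labels)
    y = _check_labels(y)
    model.fit_input_scaling(x)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 100]))
    opt = Adam(model.label_path_names(), cfg.lr)
    for _ in range(cfg.epochs):
        losses = []
        for idx in _batches(len(y), cfg.batch_size, shuffle_rng):
            grads: Dict[str, np.ndarray] = {}
            feat, cache = model.feature_forward(x[idx], train=True)
            logits, hcache = model.head_forward(feat, "label")
            loss, dlogits = cross_entropy(logits, y[idx])
            dfeat = model.head_backward(dlogits, hcache, "label", grads)
            model.feature_backward(dfeat, cache, grads)
            opt.step(model.params, grads)
            losses.append(loss)
        model.history.append({"label_loss": float(np.mean(losses))})
    return model


def train_dann(
    model: Classifier,
    source_images,
    target_images,
    source_labels=None,
    config: Optional[TrainConfig] = None,
) -> Classifier:
    """Adversarial training: label CE on source plus domain CE on
    source+target routed through gradient reversal.

    Target images are unlabeled; any labels they carry are ignored.  Target
    batches are drawn with replacement to match the source batch count.
    """
    if model.kind != "dann":
        raise ValueError("model has no domain head; build it with build_dann")
    cfg = config or TrainConfig()
    xs, ys = _unpack(source_images, source_labels)
    ys = _check_labels(ys)
    xt, _ = _unpack(target_images, allow_unlabeled=True)
    if len(xt) == 0:
        raise ValueError(
            "target set is empty: use train_source_only for source-only training"
        )
    model.fit_input_scaling(xs)  # source statistics only, shared with the CNN
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 100]))
    target_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    diag_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 102]))
    opt = Adam(model.label_path_names() + model.domain_path_names(), cfg.lr)
    n = len(ys)
    batches_per_epoch = math.ceil(n / cfg.batch_size)
    total = max(cfg.epochs * batches_per_epoch, 1)
    step = 0
    for _ in range(cfg.epochs):
        label_losses, domain_losses = [], []
        for idx in _batches(n, cfg.batch_size, shuffle_rng):
            lam = grl_lambda(step / total, cfg.gamma)
            step += 1
            tgt_idx = target_rng.integers(0, len(xt), size=len(idx))
            grads: Dict[str, np.ndarray] = {}

            feat_s, cache_s = model.feature_forward(xs[idx], train=True)
            logits, hcache = model.head_forward(feat_s, "label")
            label_loss, dlogits = cross_entropy(logits, ys[idx])
            dfeat_s = model.head_backward(dlogits, hcache, "label", grads)

            # the target pass normalizes by its own batch statistics but
            # leaves the (source-defined) running statistics untouched
            feat_t, cache_t = model.feature_forward(xt[tgt_idx], train=True,
                                                    update_stats=False)
            feat_all = np.concatenate([feat_s, feat_t])
            dom_y = np.concatenate(
                [np.zeros(len(idx), dtype=np.int64), np.ones(len(tgt_idx), dtype=np.int64)]
            )
            dom_logits, dom_cache = model.head_forward(feat_all, "domain")
            domain_loss, ddom = cross_entropy(dom_logits, dom_y)
            ddom = ddom * cfg.domain_loss_weight
            dfeat_dom = model.head_backward(ddom, dom_cache, "domain", grads)

            if lam > 0.0:
                grl = GradientReversal(lam)
                dfeat_s = dfeat_s + grl.backward(dfeat_dom[: len(idx)])
                model.feature_backward(dfeat_s, cache_s, grads)
                model.feature_backward(grl.backward(dfeat_dom[len(idx):]), cache_t, grads)
            else:
                model.feature_backward(dfeat_s, cache_s, grads)
            opt.step(model.params, grads)
            label_losses.append(label_loss)
            domain_losses.append(domain_loss)
        model.history.append(
            {
                "label_loss": float(np.mean(label_losses)),
                "domain_loss": float(np.mean(domain_losses)),
                "domain_acc": _domain_accuracy(model, xs, xt, diag_rng),
            }
        )
    return model


def _domain_accuracy(model, xs, xt, rng, max_per_domain: int = 128) -> float:
    """Diagnostic: domain-head accuracy on a random source/target mix
    (values near 0.5 indicate aligned features)."""
    ks = rng.choice(len(xs), size=min(max_per_domain, len(xs)), replace=False)
    kt = rng.choice(len(xt), size=min(max_per_domain, len(xt)), replace=False)
    x = np.concatenate([xs[ks], xt[kt]])
    y = np.concatenate([np.zeros(len(ks)), np.ones(len(kt))])
    feat, _ = model.feature_forward(x)
    logits, _ = model.head_forward(feat, "domain")
    return float((logits.argmax(axis=1) == y).mean())


def _unpack(images, labels=None, allow_unlabeled: bool = False):
    """Accept an ImageSet-like object or a raw pixel array."""
    if hasattr(images, "pixels"):
        x = np.asarray(images.pixels, dtype=np.float64)
        y = np.asarray(images.labels) if labels is None else np.asarray(labels)
    else:
        x = np.asarray(images, dtype=np.float64)
        y = None if labels is None else np.asarray(labels)
    if y is None:
        if not allow_unlabeled:
            raise ValueError("labels are required")
        y = np.full(len(x), -1)
    return x, y


def predict_scores(model: Classifier, images, batch_size: int = 256) -> np.ndarray:
    """Per-image sweep probability from the label head (class index 1)."""
    x, _ = _unpack(images, allow_unlabeled=True)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1:] != tuple(model.spec.input_shape):
        raise ValueError(
            f"image shape {x.shape[1:]} does not match spec {model.spec.input_shape}"
        )
    out = []
    for lo in range(0, len(x), batch_size):
        logits = model.label_logits(x[lo : lo + batch_size])
        out.append(softmax(logits)[:, 1])
    return np.concatenate(out)


# ----------------------------------------------------------------------
# Serialization


def save_classifier(model: Classifier, path: Union[str, Path]) -> None:
    """Checkpoint = architecture/metadata JSON + parameter arrays (.npz)."""
    meta = {
        "kind": model.kind,
        "seed": model.seed,
        "spec": model.spec.to_json(),
        "history": model.history,
        "input_mean": model.input_mean,
        "input_std": model.input_std,
    }
    arrays = dict(model.params)
    for name, (rm, rv) in model.bn_running.items():
        arrays[f"{name}/running_mean"] = rm
        arrays[f"{name}/running_var"] = rv
    np.savez(Path(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_classifier(path: Union[str, Path]) -> Classifier:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        model = Classifier(ArchitectureSpec.from_json(meta["spec"]), meta["kind"],
                           seed=meta["seed"])
        for k in model.params:
            model.params[k] = z[k]
        for name in list(model.bn_running):
            model.bn_running[name] = (z[f"{name}/running_mean"],
                                      z[f"{name}/running_var"])
        model.history = meta["history"]
        model.input_mean = meta.get("input_mean", 0.0)
        model.input_std = meta.get("input_std", 1.0)
    return model
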