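"""Patch-wise convolutional classifier for tissue labelling.

Each pixel of a head slice is classified by running a small convolutional
network on the intensity patch centred on it.  Layer semantics:

* convolution layer ``x_j = f( sum_{i in M_j} x_i * k_ij + b_j )`` — valid
  convolution, stride 1, with an optional connection table ``M_j`` choosing
  which upstream feature maps feed map ``j``;
* pooling layer ``x_j = f( beta_j * down(x_j) + b_j )`` — ``down`` sums each
  non-overlapping ``s x s`` window, ``beta_j`` and ``b_j`` are a trainable
  per-map gain and bias; the map count is unchanged, the map side shrinks by
  the pool factor;
* ``f`` is the logistic sigmoid throughout.

Two architectures are provided.  ``LENET`` (the production default) follows
the classic LeNet-5 geometry on 32x32 patches: C1 six 5x5 maps -> S2 2x2
pool -> C3 sixteen 5x5 maps with the classic partial-connection table -> S4
2x2 pool -> C5 120 maps (5x5 kernels on 5x5 input, i.e. fully connected) ->
F6 84 units -> 4-way affine output trained with softmax cross-entropy.
``SMALL`` is a minimal variant on 4x4 patches: six 3x3 convolutions then a
2x2 down-sampling stage yielding six single-pixel features, read out by an
affine head.

Everything is implemented in numpy (im2col convolutions, hand-written
backprop, Adam with a configurable first-moment decay).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import TISSUE_CLASSES, Tissue

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# architecture arithmetic
# ---------------------------------------------------------------------------

def conv_output_dim(input_side: int, kernel_side: int) -> int:
    """Side of a valid, stride-1, unpadded convolution output."""
    if kernel_side < 1:
        raise ValueError("kernel_side must be >= 1")
    if kernel_side > input_side:
        raise ValueError(
            f"kernel side {kernel_side} exceeds input side {input_side}"
        )
    return input_side - kernel_side + 1


def pool_output_dim(input_side: int, pool_side: int) -> int:
    """Side after non-overlapping pooling; the pool must tile the input."""
    if pool_side < 1:
        raise ValueError("pool_side must be >= 1")
    if input_side % pool_side != 0:
        raise ValueError(
            f"pool side {pool_side} does not divide input side {input_side} "
            "(windows must not overlap)"
        )
    return input_side // pool_side


#: Classic LeNet-5 S2 -> C3 partial-connection table: entry j lists the S2
#: maps feeding C3 map j.
LENET_C3_TABLE: tuple[tuple[int, ...], ...] = (
    (0, 1, 2), (1, 2, 3), (2, 3, 4), (3, 4, 5), (0, 4, 5), (0, 1, 5),
    (0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 5), (0, 3, 4, 5), (0, 1, 4, 5),
    (0, 1, 2, 5), (0, 1, 3, 4), (1, 2, 4, 5), (0, 2, 3, 5),
    (0, 1, 2, 3, 4, 5),
)


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the patch classifier."""

    kind: str  # convolution | pooling | fully_connected | output
    n_maps: int
    kernel: int = 1
    connections: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("convolution", "pooling", "fully_connected", "output"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kernel < 1 or self.n_maps < 1:
            raise ValueError("kernel and n_maps must be >= 1")


def _lenet_layers(n_classes: int) -> tuple[LayerSpec, ...]:
    return (
        LayerSpec("convolution", n_maps=6, kernel=5),
        LayerSpec("pooling", n_maps=6, kernel=2),
        LayerSpec("convolution", n_maps=16, kernel=5, connections=LENET_C3_TABLE),
        LayerSpec("pooling", n_maps=16, kernel=2),
        LayerSpec("convolution", n_maps=120, kernel=5),
        LayerSpec("fully_connected", n_maps=84),
        LayerSpec("output", n_maps=n_classes),
    )


def _small_layers(n_classes: int) -> tuple[LayerSpec, ...]:
    return (
        LayerSpec("convolution", n_maps=6, kernel=3),
        LayerSpec("pooling", n_maps=6, kernel=2),
        LayerSpec("output", n_maps=n_classes),
    )


@dataclass(frozen=True)
class CnnSpec:
    """Network architecture: variant, ordered layers, class count."""

    variant: str = "LENET"
    n_classes: int = 4
    layers: tuple[LayerSpec, ...] = ()
    input_side: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("LENET", "SMALL"):
            raise ValueError("variant must be 'LENET' or 'SMALL'")
        if not self.layers:
            builder = _lenet_layers if self.variant == "LENET" else _small_layers
            object.__setattr__(self, "layers", builder(self.n_classes))
        if not self.input_side:
            object.__setattr__(self, "input_side", 32 if self.variant == "LENET" else 4)
        self.validate()

    def validate(self) -> None:
        """Check the layer shapes chain; names the first failing layer."""
        side = self.input_side
        for i, layer in enumerate(self.layers):
            try:
                if layer.kind == "convolution":
                    side = conv_output_dim(side, layer.kernel)
                elif layer.kind == "pooling":
                    side = pool_output_dim(side, layer.kernel)
                else:
                    side = 1  # dense layers consume the flattened maps
            except ValueError as exc:
                raise ValueError(f"layer {i} ({layer.kind}): {exc}") from exc
        if self.layers[-1].kind != "output":
            raise ValueError("last layer must be an output layer")

    def feature_sides(self) -> list[int]:
        """Map side after each conv/pool layer (the dimension chain)."""
        sides = []
        side = self.input_side
        for layer in self.layers:
            if layer.kind == "convolution":
                side = conv_output_dim(side, layer.kernel)
                sides.append(side)
            elif layer.kind == "pooling":
                side = pool_output_dim(side, layer.kernel)
                sides.append(side)
        return sides


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe for the patch classifier (Adam, cross-entropy).

    ``batch_size`` counts *images*: one optimisation step averages gradients
    over up to ``patches_per_image`` patches sampled from each of
    ``batch_size`` slices.  A subepoch is one pass over the training images
    in such groups; an epoch consists of ``subepochs_per_epoch`` subepochs,
    with a validation checkpoint at the end of every subepoch.
    """

    learning_rate: float = 0.001
    momentum_beta1: float = 0.5
    loss: str = "cross_entropy"
    epochs: int = 50
    subepochs_per_epoch: int = 20
    batch_size: int = 5
    patches_per_image: int = 50
    split: tuple[int, int, int] | None = (600, 100, 100)
    seed: int = 0
    max_majority_ratio: float = 4.0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1 or self.subepochs_per_epoch < 1:
            raise ValueError("epochs and subepochs_per_epoch must be >= 1")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is supported")


# ---------------------------------------------------------------------------
# layers (numpy forward/backward)
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _ConvLayer:
    """Valid convolution + per-map bias + sigmoid, optional connection table."""

    def __init__(self, n_in: int, n_out: int, k: int,
                 connections: Sequence[Sequence[int]] | None,
                 rng: np.random.Generator):
        self.n_in, self.n_out, self.k = n_in, n_out, k
        mask = np.zeros((n_out, n_in, k, k))
        if connections is None:
            mask[:] = 1.0
            fan_in = n_in * k * k
        else:
            if len(connections) != n_out:
                raise ValueError("connection table length must equal n_maps")
            for j, srcs in enumerate(connections):
                mask[j, list(srcs)] = 1.0
            fan_in = max(len(s) for s in connections) * k * k
        self.mask = mask
        limit = np.sqrt(6.0 / (fan_in + n_out * k * k))
        self.W = rng.uniform(-limit, limit, size=(n_out, n_in, k, k)) * mask
        self.b = np.zeros(n_out)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        k = self.k
        cols = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # (B, C, oh, ow, k, k) -> (B, oh*ow, C*k*k)
        oh, ow = cols.shape[2], cols.shape[3]
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(B, oh * ow, C * k * k)
        Wm = (self.W * self.mask).reshape(self.n_out, -1)
        z = cols @ Wm.T + self.b
        y = _sigmoid(z)
        self._cache = (x.shape, cols, y, oh, ow)
        return y.reshape(B, oh, ow, self.n_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray):
        x_shape, cols, y, oh, ow = self._cache
        B, C, H, Wd = x_shape
        k = self.k
        dy = dy.transpose(0, 2, 3, 1).reshape(B, oh * ow, self.n_out)
        dz = dy * y * (1.0 - y)
        Wm = (self.W * self.mask).reshape(self.n_out, -1)
        dW = np.einsum("bpo,bpi->oi", dz, cols).reshape(self.W.shape) * self.mask
        db = dz.sum(axis=(0, 1))
        dcols = dz @ Wm  # (B, oh*ow, C*k*k)
        dx = np.zeros(x_shape)
        dcols = dcols.reshape(B, oh, ow, C, k, k)
        for di in range(k):
            for dj in range(k):
                dx[:, :, di:di + oh, dj:dj + ow] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self.grads = [dW, db]
        return dx


class _PoolLayer:
    """Non-overlapping sum pooling with trainable per-map gain and bias."""

    def __init__(self, n_maps: int, s: int, rng: np.random.Generator):
        self.n_maps, self.s = n_maps, s
        self.beta = rng.uniform(0.5, 1.5, size=n_maps) / (s * s)
        self.b = np.zeros(n_maps)
        self._cache = None

    @property
    def params(self):
        return [self.beta, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        s = self.s
        d = x.reshape(B, C, H // s, s, Wd // s, s).sum(axis=(3, 5))
        y = _sigmoid(self.beta[None, :, None, None] * d + self.b[None, :, None, None])
        self._cache = (x.shape, d, y)
        return y

    def backward(self, dy: np.ndarray):
        x_shape, d, y = self._cache
        dz = dy * y * (1.0 - y)
        dbeta = (dz * d).sum(axis=(0, 2, 3))
        db = dz.sum(axis=(0, 2, 3))
        dd = dz * self.beta[None, :, None, None]
        s = self.s
        dx = np.repeat(np.repeat(dd, s, axis=2), s, axis=3).reshape(x_shape)
        self.grads = [dbeta, db]
        return dx


class _DenseLayer:
    """Affine map on flattened features, optional sigmoid."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: bool):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.activation = activation
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B = x.shape[0]
        flat = x.reshape(B, -1)
        z = flat @ self.W.T + self.b
        y = _sigmoid(z) if self.activation else z
        self._cache = (x.shape, flat, y)
        return y

    def backward(self, dy: np.ndarray):
        x_shape, flat, y = self._cache
        dz = dy * y * (1.0 - y) if self.activation else dy
        self.grads = [dz.T @ flat, dz.sum(axis=0)]
        return (dz @ self.W).reshape(x_shape)


class PatchClassifier:
    """Sigmoid CNN over intensity patches; softmax cross-entropy readout."""

    def __init__(self, spec: CnnSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.trained = False
        # input standardisation constants (grey/255 scale); refreshed from
        # the training patches by train() and persisted in checkpoints.
        # centred inputs keep the sigmoid stack out of its flat region.
        self.input_mean = 0.35
        self.input_std = 0.30
        rng = np.random.default_rng(seed)
        self.layers: list = []
        side = spec.input_side
        n_maps = 1
        for ls in spec.layers:
            if ls.kind == "convolution":
                self.layers.append(_ConvLayer(n_maps, ls.n_maps, ls.kernel,
                                              ls.connections, rng))
                side = conv_output_dim(side, ls.kernel)
                n_maps = ls.n_maps
            elif ls.kind == "pooling":
                if ls.n_maps != n_maps:
                    raise ValueError("pooling must preserve the map count")
                self.layers.append(_PoolLayer(n_maps, ls.kernel, rng))
                side = pool_output_dim(side, ls.kernel)
            else:
                n_in = n_maps * side * side
                self.layers.append(
                    _DenseLayer(n_in, ls.n_maps, rng,
                                activation=(ls.kind == "fully_connected"))
                )
                n_maps, side = ls.n_maps, 1

    # -- plumbing ----------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def _prepare(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float64) / 255.0
        x = (x - self.input_mean) / self.input_std
        if x.ndim == 3:
            x = x[:, None, :, :]
        return x

    def forward(self, patches: np.ndarray, return_activations: bool = False):
        """Class scores (logits) for a batch of patches; optionally the
        per-layer activations (feature maps) as well."""
        x = self._prepare(patches)
        acts = []
        for layer in self.layers:
            x = layer.forward(x)
            acts.append(x)
        return (x, acts) if return_activations else x

    def loss_and_grads(self, patches: np.ndarray, targets: np.ndarray):
        """Mean softmax cross-entropy and parameter gradients."""
        logits = self.forward(patches)
        B = logits.shape[0]
        shifted = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(shifted)
        probs = expz / expz.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(probs[np.arange(B), targets] + 1e-300))
        dlogits = probs.copy()
        dlogits[np.arange(B), targets] -= 1.0
        dlogits /= B
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        grads = [g for layer in self.layers for g in layer.grads]
        return loss, grads

    def predict_proba(self, patches: np.ndarray, batch: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(patches), batch):
            logits = self.forward(patches[i:i + batch])
            shifted = logits - logits.max(axis=1, keepdims=True)
            expz = np.exp(shifted)
            out.append(expz / expz.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def predict(self, patches: np.ndarray, batch: int = 512) -> np.ndarray:
        return self.predict_proba(patches, batch=batch).argmax(axis=1)

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


def build_model(spec: CnnSpec, seed: int = 0) -> PatchClassifier:
    """Construct a seeded, untrained patch classifier from a spec."""
    return PatchClassifier(spec, seed=seed)


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

@dataclass
class PatchSet:
    """Intensity patches with centre-pixel tissue labels."""

    patches: np.ndarray  # (N, side, side) uint8
    labels: np.ndarray  # (N,) tissue codes
    image_ids: np.ndarray  # (N,) source image index
    patch_side: int
    stride: int

    def __len__(self) -> int:
        return len(self.patches)


def extract_patches(
    img: np.ndarray,
    lm: np.ndarray,
    patch_side: int,
    stride: int = 1,
    image_id: int = 0,
) -> PatchSet:
    """Extract patches centred on tissue-labelled pixels, in raster order.

    The centre of a patch with top-left corner (i, j) is the pixel at
    (i + side//2, j + side//2).  Only centres whose label is one of the four
    tissue classes yield a patch; the patch label is that centre label.
    """
    img = np.asarray(img, dtype=np.uint8)
    lm = np.asarray(lm, dtype=np.uint8)
    if img.shape != lm.shape:
        raise ValueError("image and label map shapes differ")
    H, W = img.shape
    if patch_side > min(H, W):
        raise ValueError("patch does not fit inside the image")
    c = patch_side // 2
    patches, labels = [], []
    tissue_codes = {int(t) for t in TISSUE_CLASSES}
    for i in range(0, H - patch_side + 1, stride):
        for j in range(0, W - patch_side + 1, stride):
            lab = int(lm[i + c, j + c])
            if lab in tissue_codes:
                patches.append(img[i:i + patch_side, j:j + patch_side])
                labels.append(lab)
    if not patches:
        log.warning("extract_patches: no tissue-labelled centres found")
        return PatchSet(
            patches=np.zeros((0, patch_side, patch_side), dtype=np.uint8),
            labels=np.zeros(0, dtype=np.uint8),
            image_ids=np.zeros(0, dtype=np.int64),
            patch_side=patch_side, stride=stride,
        )
    return PatchSet(
        patches=np.stack(patches),
        labels=np.asarray(labels, dtype=np.uint8),
        image_ids=np.full(len(patches), image_id, dtype=np.int64),
        patch_side=patch_side, stride=stride,
    )


def merge_patchsets(sets: Sequence[PatchSet]) -> PatchSet:
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("no non-empty patch sets to merge")
    side, stride = sets[0].patch_side, sets[0].stride
    return PatchSet(
        patches=np.concatenate([s.patches for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        image_ids=np.concatenate([s.image_ids for s in sets]),
        patch_side=side, stride=stride,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

#: tissue code -> class index (and back) for the 4-way softmax
CLASS_OF_TISSUE = {int(t): i for i, t in enumerate(TISSUE_CLASSES)}
TISSUE_OF_CLASS = {i: int(t) for i, t in enumerate(TISSUE_CLASSES)}


class _Adam:
    def __init__(self, params, lr: float, beta1: float, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    model: PatchClassifier
    history: list[dict]
    best_val_accuracy: float
    split_image_ids: dict[str, np.ndarray]


def _balanced_indices(labels: np.ndarray, max_ratio: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Cap the per-class count at max_ratio x the rarest class's count."""
    counts = {c: int((labels == c).sum()) for c in np.unique(labels)}
    cap = int(np.ceil(max_ratio * min(counts.values())))
    keep = []
    for c in counts:
        idx = np.nonzero(labels == c)[0]
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def train(model: PatchClassifier, patches: PatchSet, cfg: TrainConfig) -> TrainResult:
    """Train the classifier with Adam on softmax cross-entropy.

    The train/validation(/test) split is by source image, never by patch, so
    patches from one slice cannot leak across the split.  Each subepoch
    passes once over the training images in groups of ``cfg.batch_size``
    slices, taking one Adam step per group on a patch sample from those
    slices; validation accuracy is checkpointed at every subepoch and the
    best-validation parameters are restored at the end.  Fully
    deterministic given ``cfg.seed``.
    """
    if len(patches) == 0:
        raise ValueError("cannot train on an empty patch set")
    rng = np.random.default_rng(cfg.seed)

    images = np.unique(patches.image_ids)
    n_img = len(images)
    if cfg.split is not None:
        if sum(cfg.split) != n_img:
            raise ValueError(
                f"split {cfg.split} must sum to the number of images ({n_img})"
            )
        n_tr, n_val, _ = cfg.split
    else:
        n_tr = max(1, int(round(0.8 * n_img)))
        n_val = max(0, n_img - n_tr)
    perm = rng.permutation(images)
    tr_imgs = perm[:n_tr]
    val_imgs = perm[n_tr:n_tr + n_val]
    te_imgs = perm[n_tr + n_val:]

    tr_mask = np.isin(patches.image_ids, tr_imgs)
    val_mask = np.isin(patches.image_ids, val_imgs)
    X_tr, y_tr = patches.patches[tr_mask], patches.labels[tr_mask]
    X_val, y_val = patches.patches[val_mask], patches.labels[val_mask]
    if len(X_val) == 0:  # fall back to training patches for checkpointing
        X_val, y_val = X_tr, y_tr

    missing = [Tissue(t).name for t in sorted({int(t) for t in TISSUE_CLASSES}
                                              - set(np.unique(y_tr).tolist()))]
    if missing:
        raise ValueError(f"training patches missing tissue classes: {missing}")

    t_tr = np.array([CLASS_OF_TISSUE[int(t)] for t in y_tr])
    t_val = np.array([CLASS_OF_TISSUE[int(t)] for t in y_val])

    img_of_tr = patches.image_ids[tr_mask]

    # standardise inputs with training-set statistics
    model.input_mean = float(X_tr.mean() / 255.0)
    model.input_std = float(max(X_tr.std() / 255.0, 1e-3))

    # fixed validation subset keeps checkpointing cheap and deterministic
    if len(X_val) > 512:
        vsub = np.sort(rng.choice(len(X_val), 512, replace=False))
        X_val, t_val = X_val[vsub], t_val[vsub]

    opt = _Adam(model.params, cfg.learning_rate, cfg.momentum_beta1)
    init_loss, _ = model.loss_and_grads(X_tr[: min(len(X_tr), 256)],
                                        t_tr[: min(len(t_tr), 256)])
    history: list[dict] = [
        {"epoch": 0, "loss": float(init_loss),
         "val_accuracy": float(np.mean(model.predict(X_val) == t_val))}
    ]
    best_acc = history[0]["val_accuracy"]
    best_state = model.get_state()

    for epoch in range(1, cfg.epochs + 1):
        keep = _balanced_indices(t_tr, cfg.max_majority_ratio, rng)
        by_image = {int(im): keep[img_of_tr[keep] == im]
                    for im in np.unique(img_of_tr[keep])}
        img_list = np.array(sorted(by_image))
        losses = []
        for _ in range(cfg.subepochs_per_epoch):
            order = rng.permutation(img_list)
            for g in range(0, len(order), cfg.batch_size):
                group = order[g:g + cfg.batch_size]
                idx = []
                for im in group:
                    pool = by_image[int(im)]
                    if len(pool) > cfg.patches_per_image:
                        pool = rng.choice(pool, cfg.patches_per_image,
                                          replace=False)
                    idx.append(pool)
                idx = np.concatenate(idx)
                loss, grads = model.loss_and_grads(X_tr[idx], t_tr[idx])
                opt.step(model.params, grads)
                losses.append(loss)
            acc = float(np.mean(model.predict(X_val) == t_val))
            if acc > best_acc:
                best_acc = acc
                best_state = model.get_state()
        history.append({"epoch": epoch,
                        "loss": float(np.mean(losses)) if losses else float("nan"),
                        "val_accuracy": acc})
        log.info("epoch %d: loss %.4f val_acc %.4f", epoch, history[-1]["loss"], acc)

    model.set_state(best_state)
    model.trained = True
    return TrainResult(model=model, history=history, best_val_accuracy=best_acc,
                       split_image_ids={"train": tr_imgs, "val": val_imgs,
                                        "test": te_imgs})


# ---------------------------------------------------------------------------
# dense prediction
# ---------------------------------------------------------------------------

def predict_labelmap(model: PatchClassifier, img: np.ndarray, stride: int = 1,
                     return_confidence: bool = False):
    """Classify every foreground pixel of a (suppressed) image.

    Patches are evaluated on a stride grid of centres; each pixel in the
    valid region takes the class of the nearest evaluated centre.  Border
    pixels (where no full patch fits) and suppressed pixels (grey level 0)
    are BACKGROUND.  With ``return_confidence`` the winning softmax
    probability per pixel is returned alongside (0 where BACKGROUND).
    """
    if not model.trained:
        raise ValueError("predict_labelmap requires a trained model")
    img = np.asarray(img, dtype=np.uint8)
    H, W = img.shape
    p = model.spec.input_side
    c = p // 2
    out = np.full((H, W), Tissue.BACKGROUND, dtype=np.uint8)
    conf = np.zeros((H, W))
    rows = np.arange(c, H - p + 1 + c, stride)
    cols = np.arange(c, W - p + 1 + c, stride)
    if rows.size == 0 or cols.size == 0:
        return (out, conf) if return_confidence else out
    grid = np.full((rows.size, cols.size), Tissue.BACKGROUND, dtype=np.uint8)
    grid_conf = np.zeros((rows.size, cols.size))
    centres = [(ri, ci) for ri, r in enumerate(rows) for ci, cc in enumerate(cols)
               if img[r, cc] != 0]
    if centres:
        batch_patches = np.stack([
            img[rows[ri] - c: rows[ri] - c + p, cols[ci] - c: cols[ci] - c + p]
            for ri, ci in centres
        ])
        probs = model.predict_proba(batch_patches)
        classes = probs.argmax(axis=1)
        winners = probs[np.arange(len(classes)), classes]
        for (ri, ci), cls, w in zip(centres, classes, winners):
            grid[ri, ci] = TISSUE_OF_CLASS[int(cls)]
            grid_conf[ri, ci] = w
    # each valid-region pixel inherits the nearest evaluated centre's label
    yy = np.arange(c, H - p + 1 + c)
    xx = np.arange(c, W - p + 1 + c)
    gi = np.clip(np.rint((yy - c) / stride).astype(int), 0, rows.size - 1)
    gj = np.clip(np.rint((xx - c) / stride).astype(int), 0, cols.size - 1)
    out[c:H - p + 1 + c, c:W - p + 1 + c] = grid[np.ix_(gi, gj)]
    conf[c:H - p + 1 + c, c:W - p + 1 + c] = grid_conf[np.ix_(gi, gj)]
    out[img == 0] = Tissue.BACKGROUND
    conf[img == 0] = 0.0
    return (out, conf) if return_confidence else out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: PatchClassifier, path, cfg: TrainConfig | None = None) -> None:
    """Single-file npz archive plus a JSON sidecar (spec, config, seed)."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.params)}
    np.savez(path, **arrays)
    spec = model.spec
    meta = {
        "variant": spec.variant,
        "n_classes": spec.n_classes,
        "input_side": spec.input_side,
        "seed": model.seed,
        "trained": model.trained,
        "input_mean": model.input_mean,
        "input_std": model.input_std,
        "train_config": None if cfg is None else {
            "learning_rate": cfg.learning_rate,
            "momentum_beta1": cfg.momentum_beta1,
            "epochs": cfg.epochs,
            "subepochs_per_epoch": cfg.subepochs_per_epoch,
            "batch_size": cfg.batch_size,
            "seed": cfg.seed,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path) -> PatchClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = CnnSpec(variant=meta["variant"], n_classes=meta["n_classes"])
    model = PatchClassifier(spec, seed=meta["seed"])
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.set_state([data[f"p{i}"] for i in range(len(model.params))])
    model.trained = bool(meta["trained"])
    model.input_mean = float(meta.get("input_mean", model.input_mean))
    model.input_std = float(meta.get("input_std", model.input_std))
    return model


def save_history_csv(history: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch,loss,val_accuracy\n")
        for row in history:
            fh.write(f"{row['epoch']},{row['loss']},{row['val_accuracy']}\n")
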