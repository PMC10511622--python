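"""Binary BAC classifier: VGG16-style backbone with a compact dense head.

The classifier is a stack of 3x3 convolution blocks with 2x2 max pooling
(13 conv layers / 5 pools in the full profile), followed by two 256-unit
dense layers with leaky-ReLU activations (slope 0.3) and dropout 0.3, and a
single sigmoid output.  Transfer-learning style partial fine-tuning is
expressed by freezing all but the deepest ``n_finetune_conv_layers``
convolutions; the head is always trainable.

Training minimises class-weighted binary cross-entropy with Adam under a
cosine-annealed learning rate, applies online augmentation (geometric
transforms then pixel noise), monitors validation AUC-PR after every epoch,
and returns the weights of the best epoch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.metrics import average_precision_score

from .nn import (Adam, Conv2d, Dense, Dropout, Flatten, LeakyReLU, MaxPool2d,
                 Sequential, Sigmoid)

__all__ = [
    "FULL_BACKBONE", "REDUCED_BACKBONE",
    "ModelConfig", "AugmentConfig", "TrainConfig", "TrainedModel",
    "build_model", "class_weights", "lr_schedule", "augment",
    "train", "predict",
]

# (widths of the conv layers in each block); a 2x2 pool follows each block
FULL_BACKBONE = ((64, 64), (128, 128), (256, 256, 256),
                 (512, 512, 512), (512, 512, 512))
REDUCED_BACKBONE = tuple(tuple(wd // 8 for wd in blk) for blk in FULL_BACKBONE)


@dataclass(frozen=True)
class ModelConfig:
    input_size: tuple[int, int] = (1536, 768)
    backbone_widths: tuple[tuple[int, ...], ...] = FULL_BACKBONE
    n_finetune_conv_layers: int = 5
    head_units: int = 256
    leaky_alpha: float = 0.3
    dropout_rate: float = 0.3
    dtype: type = np.float32

    @property
    def n_conv_layers(self) -> int:
        return sum(len(b) for b in self.backbone_widths)

    def validate(self) -> None:
        h, w = self.input_size
        n_pools = len(self.backbone_widths)
        if h % (2 ** n_pools) or w % (2 ** n_pools):
            raise ValueError("input_size must be divisible by 2**n_blocks")
        if not 0 <= self.n_finetune_conv_layers <= self.n_conv_layers:
            raise ValueError("n_finetune_conv_layers exceeds the number of "
                             "convolutional layers")
        if self.leaky_alpha <= 0:
            raise ValueError("leaky_alpha must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class AugmentConfig:
    rotation_deg: float = 10.0
    shift_frac: float = 0.05
    hflip: bool = True
    vflip: bool = True
    zoom_frac: float = 0.10
    gaussian_sd_frac: float = 0.01      # fraction of the image dynamic range
    salt_pepper_frac: float = 0.005

    def validate(self) -> None:
        for name in ("rotation_deg", "shift_frac", "zoom_frac",
                     "gaussian_sd_frac", "salt_pepper_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def is_identity(self) -> bool:
        return (self.rotation_deg == 0 and self.shift_frac == 0
                and self.zoom_frac == 0 and not self.hflip and not self.vflip
                and self.gaussian_sd_frac == 0 and self.salt_pepper_frac == 0)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 25
    batch_size: int = 8
    lr0: float = 1e-6
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        self.augmentation.validate()


@dataclass
class TrainedModel:
    weights: list[np.ndarray]
    history: list[dict]                 # per-epoch: epoch, lr, train_loss, val_auc_pr
    selected_epoch: int


def build_model(config: ModelConfig, rng: np.random.Generator | None = None,
                pretrained_weights: list[np.ndarray] | None = None) -> Sequential:
    """Assemble the classifier; freeze all but the deepest n conv layers."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(0)
    h, w = config.input_size
    layers: list = []
    c_in = 3
    conv_count = config.n_conv_layers
    first_trainable = conv_count - config.n_finetune_conv_layers
    # He gain corrected for the leaky slope so activations neither grow nor
    # shrink through the 13-layer stack
    gain = 2.0 / (1.0 + config.leaky_alpha ** 2)
    seen = 0
    for block in config.backbone_widths:
        for width in block:
            layers.append(Conv2d(c_in, width, rng, dtype=config.dtype,
                                 trainable=seen >= first_trainable, gain=gain))
            layers.append(LeakyReLU(config.leaky_alpha))
            c_in = width
            seen += 1
        layers.append(MaxPool2d())
        h //= 2
        w //= 2
    layers.append(Flatten())
    d = h * w * c_in
    for _ in range(2):
        layers.append(Dense(d, config.head_units, rng, dtype=config.dtype,
                            gain=gain))
        layers.append(LeakyReLU(config.leaky_alpha))
        layers.append(Dropout(config.dropout_rate))
        d = config.head_units
    # near-zero initial logits: start from p ~ 0.5 regardless of depth
    layers.append(Dense(d, 1, rng, dtype=config.dtype, gain=0.01))
    layers.append(Sigmoid())
    model = Sequential(layers)
    if pretrained_weights is not None:
        model.set_weights(pretrained_weights)
    return model


def class_weights(labels) -> tuple[float, float]:
    """Per-class loss weights w_c = N / (2 * N_c), inverse to class frequency."""
    y = np.asarray(labels)
    n_pos = int((y > 0).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute class weights")
    n = n_pos + n_neg
    return n / (2.0 * n_neg), n / (2.0 * n_pos)


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Cosine annealing from lr0 at epoch 0 to 0 at the last epoch."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    if config.epochs == 1:
        return config.lr0
    return config.lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / (config.epochs - 1)))


def augment(image: np.ndarray, config: AugmentConfig,
            rng: np.random.Generator) -> np.ndarray:
    """One random augmentation draw: geometric transforms, then noise.

    Flips are exact (array reversal); rotation/shift/zoom are composed into a
    single bilinear resampling.  A zero-magnitude config is a bitwise
    identity.
    """
    config.validate()
    if config.is_identity:
        return image
    img = image
    squeeze = False
    if img.ndim == 2:
        img = img[:, :, None]
        squeeze = True
    h, w, _ = img.shape

    if config.hflip and rng.random() < 0.5:
        img = img[:, ::-1, :]
    if config.vflip and rng.random() < 0.5:
        img = img[::-1, :, :]

    theta = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg)) \
        if config.rotation_deg else 0.0
    zoom = 1.0 + (rng.uniform(-config.zoom_frac, config.zoom_frac)
                  if config.zoom_frac else 0.0)
    dr = rng.uniform(-config.shift_frac, config.shift_frac) * h \
        if config.shift_frac else 0.0
    dc = rng.uniform(-config.shift_frac, config.shift_frac) * w \
        if config.shift_frac else 0.0
    if theta != 0.0 or zoom != 1.0 or dr != 0.0 or dc != 0.0:
        # output coords -> input coords: rotate/scale about the centre, shift
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        mat = np.array([[cos_t, -sin_t], [sin_t, cos_t]]) / zoom
        centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        offset = centre - mat @ centre + np.array([dr, dc])
        fill = float(img.min())
        out = np.empty_like(img)
        for ch in range(img.shape[2]):
            out[:, :, ch] = ndimage.affine_transform(
                img[:, :, ch], mat, offset=offset, order=1,
                mode="constant", cval=fill)
        img = out
    else:
        img = np.ascontiguousarray(img)

    dyn = float(img.max() - img.min())
    if config.gaussian_sd_frac and dyn > 0:
        img = img + (config.gaussian_sd_frac * dyn
                     * rng.standard_normal(img.shape[:2])[:, :, None]
                     ).astype(img.dtype)
    if config.salt_pepper_frac:
        lo, hi = float(img.min()), float(img.max())
        hits = rng.random((h, w)) < config.salt_pepper_frac
        salt = rng.random((h, w)) < 0.5
        img = img.copy()
        img[hits & salt, :] = hi
        img[hits & ~salt, :] = lo
    if squeeze:
        img = img[:, :, 0]
    return img


def _as_batch3(x: np.ndarray) -> np.ndarray:
    """(n, H, W) single-channel stack -> (n, H, W, 3) replicated channels."""
    if x.ndim == 4:
        return x
    return np.repeat(x[:, :, :, None], 3, axis=3)


def _weighted_bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p.astype(np.float64), eps, 1 - eps)
    return float(np.mean(w * -(y * np.log(p) + (1 - y) * np.log(1 - p))))


def train(model: Sequential, train_set, val_set, config: TrainConfig) -> TrainedModel:
    """Train the classifier and return the best-epoch weights.

    ``train_set`` / ``val_set`` are (X, y) with X of shape (n, H, W) (single
    channel; replicated to 3 on the fly) and y in {0, 1}.  Validation AUC-PR
    is computed on un-augmented views after each epoch; the returned weights
    are those of the first epoch attaining the maximum.  Fully reproducible
    for a fixed seed: data order, augmentation and dropout all derive from
    per-epoch substreams.
    """
    config.validate()
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    y_tr = np.asarray(y_tr, dtype=np.float64)
    y_va = np.asarray(y_va, dtype=np.float64)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be non-empty")
    w_neg, w_pos = class_weights(y_tr)
    if len(np.unique(y_va)) < 2:
        raise ValueError("validation set must contain both classes")

    opt = Adam(model.trainable_params(), lr=config.lr0)
    cache_from = model.first_trainable_index()
    logit_index = len(model.layers) - 2      # layer before the sigmoid
    dropouts = [l for l in model.layers if isinstance(l, Dropout)]

    # the frozen prefix never changes, so validation views are pushed
    # through it once and only the trainable suffix is re-evaluated per epoch
    if cache_from > 0:
        feats = [model.forward(_as_batch3(np.stack([x_va[i] for i in
                                                    range(s, min(s + 16, len(x_va)))])),
                               train=False, upto=cache_from)
                 for s in range(0, len(x_va), 16)]
        val_feats = np.concatenate(feats)

        def val_scores_fn():
            out = []
            for s in range(0, len(val_feats), 16):
                out.append(model.forward(val_feats[s:s + 16], train=False,
                                         start=cache_from).reshape(-1))
            return np.concatenate(out)
    else:
        def val_scores_fn():
            return predict(model, x_va)

    history: list[dict] = []
    best_auc, best_epoch, best_weights = -np.inf, -1, None
    n = len(x_tr)
    root = np.random.SeedSequence(config.seed)

    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        opt.lr = lr
        order_ss, aug_ss, drop_ss = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(epoch,)).spawn(3)
        order = np.random.default_rng(order_ss).permutation(n)
        aug_rng = np.random.default_rng(aug_ss)
        drop_rng = np.random.default_rng(drop_ss)
        for d in dropouts:
            d.rng = drop_rng

        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = np.stack([augment(x_tr[i], config.augmentation, aug_rng)
                           for i in idx])
            yb = y_tr[idx]
            wb = np.where(yb > 0, w_pos, w_neg)
            model.zero_grad()
            z = model.forward(_as_batch3(xb), train=True, cache_from=cache_from,
                              upto=logit_index + 1).reshape(-1)
            p = 1.0 / (1.0 + np.exp(-z))
            loss = _weighted_bce(p, yb, wb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}")
            losses.append(loss)
            dz = (wb * (p - yb) / len(idx)).astype(z.dtype)
            model.backward(dz.reshape(-1, 1), from_index=logit_index,
                           to_index=cache_from)
            opt.step()

        for d in dropouts:
            d.rng = None
        val_auc = float(average_precision_score(y_va, val_scores_fn()))
        history.append({"epoch": epoch, "lr": float(lr),
                        "train_loss": float(np.mean(losses)),
                        "val_auc_pr": val_auc})
        if val_auc > best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    return TrainedModel(weights=copy.deepcopy(best_weights), history=history,
                        selected_epoch=best_epoch)


def predict(model: Sequential, inputs, batch_size: int = 16) -> np.ndarray:
    """Deterministic inference scores in (0, 1), order-preserving."""
    out = []
    n = len(inputs)
    for start in range(0, n, batch_size):
        xb = np.stack([np.asarray(inputs[i]) for i in range(start, min(start + batch_size, n))])
        p = model.forward(_as_batch3(xb), train=False)
        out.append(p.reshape(-1))
    return np.concatenate(out) if out else np.empty(0)
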