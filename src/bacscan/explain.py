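"""Grad-CAM++ relevance heatmaps over a convolutional layer.

For a binary classifier with pre-sigmoid logit S, attribution is computed for
Y = exp(S) at a chosen convolutional feature map A^k (post-activation).  With
piecewise-linear networks (conv / leaky-ReLU / max-pool / dense), higher-order
derivatives of Y reduce to powers of the first-order gradient g = dS/dA:

    d2Y/dA^2 = exp(S) * g^2,    d3Y/dA^3 = exp(S) * g^3,

so the Grad-CAM++ pixel weights have the closed form

    alpha_ij^k = g_ij^2 / (2 g_ij^2 + (sum_ab A_ab^k) g_ij^3),

with alpha = 0 where the denominator vanishes.  The channel weights are
w_k = sum_ij alpha_ij^k relu(dY/dA_ij^k) and the raw map is
relu(sum_k w_k A^k), which is non-negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Sequential

__all__ = ["Heatmap", "gradcampp_raw", "to_heatmap", "deepest_conv_index"]

_EPS = 1e-8
_EXP_CLIP = 80.0  # logit cap inside exp(); avoids overflow, cancels on normalisation


@dataclass
class Heatmap:
    values: np.ndarray          # (H, W) in [0, 1], model-input resolution
    layer_index: int            # index of the attributed conv layer
    score: float                # sigmoid output of the model for this input
    all_zero: bool              # raw map was identically zero


def deepest_conv_index(model: Sequential) -> int:
    convs = model.conv_indices()
    if not convs:
        raise ValueError("model has no convolutional layer")
    return convs[-1]


def gradcampp_raw(model: Sequential, x: np.ndarray,
                  layer_index: int | None = None) -> tuple[np.ndarray, float]:
    """Raw (low-resolution) Grad-CAM++ map for a single input.

    ``x`` is one model input of shape (H, W, 3).  ``layer_index`` selects the
    convolutional layer to attribute (default: the deepest); the feature map
    used is the output of the activation that follows it.  Returns
    (raw map (h, w), sigmoid score).
    """
    if layer_index is None:
        layer_index = deepest_conv_index(model)
    if not isinstance(model.layers[layer_index], Conv2d):
        raise TypeError(f"layer {layer_index} is not a convolutional layer")
    act_index = layer_index + 1          # the activation following the conv
    if x.ndim != 3:
        raise ValueError("expected a single (H, W, 3) input")
    xb = x[None]

    # forward up to the attributed activation (no caching below it) ...
    h = xb
    for i in range(act_index + 1):
        h = model.layers[i].forward(h, train=False, cache=False)
    activ = h                             # A, shape (1, h, w, C)
    # ... then through the rest with caches so we can backpropagate to A
    logit_index = len(model.layers) - 2
    for i in range(act_index + 1, logit_index + 1):
        h = model.layers[i].forward(h, train=False, cache=True)
    s = float(h.reshape(-1)[0])
    score = float(1.0 / (1.0 + np.exp(-s)))

    g = model.backward(np.ones((1, 1), dtype=h.dtype),
                       from_index=logit_index, to_index=act_index + 1)
    g = g[0].astype(np.float64)           # dS/dA, (h, w, C)
    a = activ[0].astype(np.float64)

    if not np.any(a):
        return np.zeros(a.shape[:2]), score

    exp_s = np.exp(min(s, _EXP_CLIP))
    g2 = g * g
    denom = 2.0 * g2 + a.sum(axis=(0, 1), keepdims=True) * g2 * g
    alpha = np.where(np.abs(denom) > _EPS, g2 / np.where(denom == 0, 1.0, denom), 0.0)
    w = (alpha * np.maximum(exp_s * g, 0.0)).sum(axis=(0, 1))   # (C,)
    raw = np.maximum((a * w).sum(axis=2), 0.0)
    return raw, score


def _bilinear_upsample(raw: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Pixel-centre-aligned bilinear resampling with edge clamping."""
    h, w = raw.shape
    th, tw = out_shape
    r = np.clip((np.arange(th) + 0.5) * h / th - 0.5, 0, h - 1)
    c = np.clip((np.arange(tw) + 0.5) * w / tw - 0.5, 0, w - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = (r - r0)[:, None]
    fc = (c - c0)[None, :]
    top = raw[np.ix_(r0, c0)] * (1 - fc) + raw[np.ix_(r0, c1)] * fc
    bot = raw[np.ix_(r1, c0)] * (1 - fc) + raw[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr


def to_heatmap(raw: np.ndarray, target_size: tuple[int, int],
               layer_index: int = -1, score: float = float("nan"),
               norm: str = "p99",
               region: np.ndarray | None = None) -> Heatmap:
    """Upsample a raw map to model-input resolution and normalise to [0, 1].

    ``region`` optionally restricts relevance to a boolean mask at target
    resolution (e.g. the breast tissue) before normalisation.  ``norm``
    selects the scale: ``"p99"`` (default) divides by the 99th percentile —
    robust to a single dominant cell, so downstream thresholding reflects
    the spatial extent of the relevant region rather than the sharpness of
    its peak — while ``"max"`` divides by the maximum.  Values are clipped
    to [0, 1]; all-zero raw maps pass through as all-zero heatmaps, flagged.
    """
    up = _bilinear_upsample(raw.astype(np.float64), target_size)
    up = np.maximum(up, 0.0)
    if region is not None:
        up = up * region
    if norm == "max":
        scale = float(up.max())
    elif norm == "p99":
        scale = float(np.percentile(up, 99))
        if scale <= 0:
            scale = float(up.max())
    else:
        raise ValueError(f"unknown norm {norm!r}")
    if scale > 0:
        up = np.clip(up / scale, 0.0, 1.0)
        zero = False
    else:
        zero = True
    return Heatmap(values=up, layer_index=layer_index, score=score,
                   all_zero=zero)
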