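"""Sequential container with partial-depth caching and weight snapshots."""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, Layer, Param, Sigmoid

__all__ = ["Sequential"]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    # -- introspection -------------------------------------------------
    def conv_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.layers) if isinstance(l, Conv2d)]

    def first_trainable_index(self) -> int:
        for i, l in enumerate(self.layers):
            if l.trainable and l.params():
                return i
        return len(self.layers)

    def trainable_params(self) -> list[Param]:
        return [p for l in self.layers if l.trainable for p in l.params()]

    def all_params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    # -- execution -----------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                cache_from: int | None = None, upto: int | None = None,
                start: int = 0) -> np.ndarray:
        """Run layers [start, upto); cache backward state from ``cache_from``."""
        stop = len(self.layers) if upto is None else upto
        cf = stop if cache_from is None else cache_from
        for i in range(start, stop):
            x = self.layers[i].forward(x, train=train, cache=i >= cf)
        return x

    def backward(self, dy: np.ndarray, from_index: int | None = None,
                 to_index: int = 0) -> np.ndarray:
        """Backpropagate from layer ``from_index`` (inclusive, default last)
        down to ``to_index`` (inclusive); returns the gradient at the input of
        layer ``to_index``."""
        start = len(self.layers) - 1 if from_index is None else from_index
        for i in range(start, to_index - 1, -1):
            dy = self.layers[i].backward(dy)
        return dy

    def logit(self, x: np.ndarray, train: bool = False,
              cache_from: int | None = None) -> np.ndarray:
        """Pre-sigmoid score; requires the last layer to be a Sigmoid."""
        if not isinstance(self.layers[-1], Sigmoid):
            raise TypeError("model does not end in a Sigmoid output layer")
        z = self.forward(x, train=train, cache_from=cache_from,
                         upto=len(self.layers) - 1)
        return z.reshape(-1)

    def zero_grad(self) -> None:
        for p in self.all_params():
            p.grad[...] = 0.0

    # -- weight snapshots ----------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.all_params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.all_params()
        if len(params) != len(weights):
            raise ValueError("weight list does not match model parameters")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"shape mismatch: {p.value.shape} vs {w.shape}")
            p.value[...] = w
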