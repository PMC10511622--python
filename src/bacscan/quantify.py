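"""Calcified-area estimation from thresholded heatmaps.

For a positive prediction, the estimated BAC area is

    BAC_area = P * sum_i 1[G(i) > Th]

where G is the normalised heatmap, Th the binarisation threshold (default
0.3) and P the per-pixel area in mm^2 in the model frame.  "Pixel size" is
deliberately interpreted as an area (product of the per-axis mm/pixel sizes
after the crop/resize geometry) so the result carries area units; the
downstream correlation with measured lengths is rank-based, so this
interpretation does not affect the correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .explain import Heatmap

__all__ = ["QuantConfig", "QuantResult", "bac_mask", "bac_area",
           "quantify_view", "area_length_correlation"]


@dataclass(frozen=True)
class QuantConfig:
    th: float = 0.3
    pixel_area_mm2: float = 1.0

    def validate(self) -> None:
        if not 0.0 < self.th < 1.0:
            raise ValueError("th must be in (0, 1)")
        if self.pixel_area_mm2 <= 0:
            raise ValueError("pixel_area_mm2 must be positive")


@dataclass
class QuantResult:
    view_id: str
    n_above: int
    bac_area_mm2: float
    mask: np.ndarray


def _values(heatmap) -> np.ndarray:
    return heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)


def bac_mask(heatmap, config: QuantConfig) -> np.ndarray:
    """Binary BAC region: pixels with G(i) strictly above Th."""
    config.validate()
    return _values(heatmap) > config.th


def bac_area(heatmap, config: QuantConfig) -> float:
    """Estimated calcified area in mm^2: P times the suprathreshold count."""
    return config.pixel_area_mm2 * int(bac_mask(heatmap, config).sum())


def quantify_view(heatmap, config: QuantConfig, view_id: str = "") -> QuantResult:
    mask = bac_mask(heatmap, config)
    n = int(mask.sum())
    return QuantResult(view_id=view_id, n_above=n,
                       bac_area_mm2=config.pixel_area_mm2 * n, mask=mask)


def area_length_correlation(areas_mm2, truth_lengths_mm) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties) with two-sided p."""
    a = np.asarray(areas_mm2, dtype=float)
    b = np.asarray(truth_lengths_mm, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
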