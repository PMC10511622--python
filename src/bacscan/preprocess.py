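"""Breast-region extraction and model-input preparation.

Mammograms carry large dark background areas (and occasionally bright view
markers).  The tissue region is isolated by Otsu thresholding of the intensity
histogram, keeping the largest 4-connected foreground component; the tightest
bounding box of that component is cropped, resampled to the fixed network
input size, replicated to three identical channels, and z-score normalised
over breast pixels only (background pixels are set to the minimum normalised
value).  The affine crop+scale geometry is retained so model-frame coordinates
— and heatmap pixel areas — can be mapped back to the source frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "BreastMask",
    "ModelInput",
    "Geometry",
    "otsu_threshold",
    "segment_breast",
    "crop_resize_normalize",
    "DegenerateImageError",
    "SegmentationError",
    "NormalizationError",
    "load_image",
]


class DegenerateImageError(ValueError):
    """Histogram has a single occupied gray level; no threshold exists."""


class SegmentationError(RuntimeError):
    """No foreground component found."""


class NormalizationError(RuntimeError):
    """Breast region has zero intensity variance."""


@dataclass
class BreastMask:
    mask: np.ndarray                       # bool, aligned to the source image
    bbox: tuple[int, int, int, int]        # (row_min, row_max, col_min, col_max), half-open
    threshold_used: float


@dataclass
class Geometry:
    """Affine map between model coordinates and source pixel coordinates.

    Model pixel centre (r, c) maps to source (row_min + (r + .5) * sr - .5,
    col_min + (c + .5) * sc - .5) with per-axis scales sr, sc (source pixels
    per model pixel).
    """

    bbox: tuple[int, int, int, int]
    target_size: tuple[int, int]
    source_pixel_size: float               # mm per source pixel side

    @property
    def scale(self) -> tuple[float, float]:
        r0, r1, c0, c1 = self.bbox
        th, tw = self.target_size
        return ((r1 - r0) / th, (c1 - c0) / tw)

    def model_to_source(self, rc: np.ndarray) -> np.ndarray:
        rc = np.asarray(rc, dtype=float)
        sr, sc = self.scale
        r0, _, c0, _ = self.bbox
        out = np.empty_like(rc)
        out[..., 0] = r0 + (rc[..., 0] + 0.5) * sr - 0.5
        out[..., 1] = c0 + (rc[..., 1] + 0.5) * sc - 0.5
        return out

    def source_to_model(self, rc: np.ndarray) -> np.ndarray:
        rc = np.asarray(rc, dtype=float)
        sr, sc = self.scale
        r0, _, c0, _ = self.bbox
        out = np.empty_like(rc)
        out[..., 0] = (rc[..., 0] - r0 + 0.5) / sr - 0.5
        out[..., 1] = (rc[..., 1] - c0 + 0.5) / sc - 0.5
        return out

    def model_pixel_size(self) -> tuple[float, float]:
        """mm per model pixel along (rows, cols)."""
        sr, sc = self.scale
        return (sr * self.source_pixel_size, sc * self.source_pixel_size)

    def model_pixel_area_mm2(self) -> float:
        pr, pc = self.model_pixel_size()
        return pr * pc


@dataclass
class ModelInput:
    tensor: np.ndarray                     # (H, W, 3), channels identical
    geometry: Geometry
    source_pixel_size: float
    breast_mask_model: np.ndarray          # bool (H, W), breast pixels in model frame


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold on a gray-level histogram of counts.

    Returns the level t maximising between-class variance for the split
    levels <= t vs levels > t; ties are broken by the lowest qualifying
    level.  Raises :class:`DegenerateImageError` if fewer than two gray
    levels are occupied.
    """
    counts = np.asarray(histogram, dtype=np.float64)
    if counts.ndim != 1:
        raise ValueError("histogram must be 1-D")
    if (counts < 0).any():
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(counts) < 2:
        raise DegenerateImageError("histogram has fewer than two occupied levels")

    levels = np.arange(counts.size, dtype=np.float64)
    total = counts.sum()
    w0 = np.cumsum(counts)                 # class-0 mass for t = 0..L-1
    m0 = np.cumsum(counts * levels)        # class-0 first moment
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)            # both classes non-empty
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (m0[-1] - m0) / w1
    between = np.where(valid, w0 * w1 * (mean0 - mean1) ** 2, -np.inf)
    # argmax returns the first (lowest) maximiser
    t = int(np.argmax(between))
    if not np.isfinite(between[t]):
        raise DegenerateImageError("no valid two-class split")
    return t


def _image_histogram(image: np.ndarray, n_bins: int = 256):
    """Quantise an arbitrary-range image to a histogram plus bin centres."""
    img = np.asarray(image, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise DegenerateImageError("constant image")
    if np.issubdtype(np.asarray(image).dtype, np.integer) and hi - lo < n_bins:
        # small integer range: one bin per level, exact
        offsets = np.arange(lo, hi + 1)
        counts = np.bincount((img - lo).astype(np.int64).ravel(),
                             minlength=offsets.size)
        return counts, offsets
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(img.ravel(), bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return counts, centers


def segment_breast(image: np.ndarray) -> BreastMask:
    """Largest 4-connected component above the Otsu threshold, plus its bbox."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    counts, values = _image_histogram(img)
    t_idx = otsu_threshold(counts)
    threshold = float(values[t_idx])
    fg = img > threshold
    if not fg.any():
        raise SegmentationError("empty foreground after thresholding")
    labels, n = ndimage.label(fg)  # default structure = 4-connectivity
    if n == 0:
        raise SegmentationError("no connected component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    bbox = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    return BreastMask(mask=mask, bbox=bbox, threshold_used=threshold)


def crop_resize_normalize(image: np.ndarray, mask: BreastMask,
                          target_size: tuple[int, int],
                          source_pixel_size: float = 1.0) -> ModelInput:
    """Crop to the breast bbox, resample, replicate to 3 channels, z-score.

    Breast pixels are standardised with the mean/SD computed over the breast
    region only; background is set to the minimum normalised breast value.
    Resampling is bilinear with anti-aliasing on downscale.
    """
    th, tw = target_size
    if th <= 0 or tw <= 0:
        raise ValueError("target_size must be positive")
    r0, r1, c0, c1 = mask.bbox
    crop = np.asarray(image, dtype=np.float64)[r0:r1, c0:c1]
    mcrop = mask.mask[r0:r1, c0:c1]

    downscale = th < crop.shape[0] or tw < crop.shape[1]
    resized = resize(crop, (th, tw), order=1, anti_aliasing=downscale,
                     preserve_range=True)
    mresized = resize(mcrop.astype(np.float64), (th, tw), order=0,
                      anti_aliasing=False, preserve_range=True) >= 0.5
    if not mresized.any():
        raise SegmentationError("breast mask vanished after resampling")

    vals = resized[mresized]
    mu, sd = float(vals.mean()), float(vals.std())
    if sd == 0.0:
        raise NormalizationError("zero intensity SD over the breast region")
    out = np.empty_like(resized)
    out[mresized] = (vals - mu) / sd
    out[~mresized] = out[mresized].min()

    geometry = Geometry(bbox=mask.bbox, target_size=(th, tw),
                        source_pixel_size=source_pixel_size)
    tensor = np.repeat(out.astype(np.float32)[:, :, None], 3, axis=2)
    return ModelInput(tensor=tensor, geometry=geometry,
                      source_pixel_size=source_pixel_size,
                      breast_mask_model=mresized)


def load_image(path: str) -> tuple[np.ndarray, float | None]:
    """Read PNG/TIFF or DICOM; returns (image, pixel size in mm or None).

    For DICOM the pixel size is taken from Imager Pixel Spacing (or Pixel
    Spacing) when present.
    """
    lower = path.lower()
    if lower.endswith((".dcm", ".dicom")):
        import pydicom

        ds = pydicom.dcmread(path)
        img = ds.pixel_array.astype(np.float64)
        spacing = getattr(ds, "ImagerPixelSpacing", None) or \
            getattr(ds, "PixelSpacing", None)
        px = float(spacing[0]) if spacing else None
        return img, px
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)), None
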