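"""Synthetic mammogram-like phantom cohorts with ground-truth calcifications.

Real mammographic cohorts with breast arterial calcification (BAC) labels are
not publicly depositable, so every downstream stage of the pipeline is
exercised on phantoms: a half-elliptical "breast" of textured tissue on a dark
background, optionally carrying one or more curved arterial tracks rendered as
dashed bright segments (the parallel/punctate linear opacities a radiologist
reads as BAC), plus label-independent confounders — benign round
calcifications and skin-fold-like linear structures.

Each rendered view records a pixel-exact truth mask of the calcified track and
the total centerline arc length of the rendered dashes in millimetres; this is
the stand-in for manual length measurements against which heatmap-derived
areas are correlated.

A screening exam is four views per patient (left/right x CC/MLO).  The
patient label is positive iff at least one view is positive, and the
probability of being a BAC+ patient follows a step function over the four age
classes of the cohort (age-quartile classes), with rates that rise steeply
with age as observed in screening populations (defaults 6.3%, 11.6%, 34.3%,
38.2%).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "PhantomImage",
    "CohortRecord",
    "PhantomCohort",
    "PatientState",
    "generate_cohort",
    "render_view",
    "write_cohort",
    "PlacementError",
]

VIEWS = ("L-CC", "L-MLO", "R-CC", "R-MLO")

# intensity layout (fraction of dynamic range); calcifications must sit
# strictly above the tissue texture ceiling so a learnable signal exists
_BACKGROUND = 0.02
_TISSUE_LO, _TISSUE_HI = 0.20, 0.72
_CALC_LO, _CALC_HI = 0.85, 0.98
_FOLD_BOOST = 0.12


class PlacementError(RuntimeError):
    """A calcified track could not be placed inside the tissue region."""


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic cohort."""

    n_patients: int
    image_height: int = 384
    image_width: int = 192
    pixel_size: float = 0.2            # mm per pixel side
    age_range: tuple[float, float] = (45.0, 87.0)
    prevalence_by_age_class: tuple[float, float, float, float] = (
        0.063, 0.116, 0.343, 0.382)
    track_length_range: tuple[float, float] = (8.0, 45.0)  # mm per track
    confounder_rate_round: float = 0.25   # benign round calcifications / view
    confounder_rate_fold: float = 0.20    # skin-fold structure / view
    view_positive_rate: float = 0.75      # P(view shows BAC | patient BAC+)
    noise_level: float = 0.02             # relative intensity SD
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image_height/image_width must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be ordered (min < max)")
        for name in ("confounder_rate_round", "confounder_rate_fold",
                     "view_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.prevalence_by_age_class):
            raise ValueError("prevalence_by_age_class entries must be in [0, 1]")
        if len(self.prevalence_by_age_class) != 4:
            raise ValueError("prevalence_by_age_class must have 4 entries")
        lo, hi = self.track_length_range
        if not 0 < lo <= hi:
            raise ValueError("track_length_range must be positive and ordered")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")


@dataclass
class PhantomImage:
    pixels: np.ndarray          # float32 (H, W) in [0, 1]
    truth_mask: np.ndarray      # bool (H, W), calcified track pixels
    truth_length: float         # mm, total centerline length of track dashes
    label: bool                 # view-level BAC label
    pixel_size: float           # mm


@dataclass
class CohortRecord:
    patient_id: str
    age: float
    view: str                   # CC / MLO
    laterality: str             # L / R
    label: bool                 # view-level BAC label
    pixel_size_mm: float
    truth_length_mm: float
    path: str | None = None


@dataclass
class PatientState:
    patient_id: str
    age: float
    age_class: int
    bac_positive: bool
    n_tracks: int
    track_lengths_mm: tuple[float, ...]
    view_positive: dict[str, bool]


@dataclass
class PhantomCohort:
    spec: PhantomSpec
    patients: list[PatientState]
    records: list[CohortRecord]
    images: dict[tuple[str, str], PhantomImage] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "age": [r.age for r in self.records],
                "view": [r.view for r in self.records],
                "laterality": [r.laterality for r in self.records],
                "label": [int(r.label) for r in self.records],
                "pixel_size_mm": [r.pixel_size_mm for r in self.records],
                "truth_length_mm": [r.truth_length_mm for r in self.records],
                "path": [r.path for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# patient sampling
# ---------------------------------------------------------------------------

def _age_class_of(age: float, qs: np.ndarray) -> int:
    return int(np.searchsorted(qs, age, side="left"))


def _sample_patient(pid: str, age: float, age_class: int, prevalence: float,
                    spec: PhantomSpec, rng: np.random.Generator) -> PatientState:
    positive = bool(rng.random() < prevalence)
    n_tracks = 0
    lengths: tuple[float, ...] = ()
    view_pos = {v: False for v in VIEWS}
    if positive:
        n_tracks = int(rng.integers(1, 4))
        lo, hi = spec.track_length_range
        # log-uniform severity: many low-burden, few high-burden patients
        lengths = tuple(float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                        for _ in range(n_tracks))
        while True:
            flags = rng.random(4) < spec.view_positive_rate
            if flags.any():
                break
        view_pos = dict(zip(VIEWS, (bool(f) for f in flags)))
    return PatientState(pid, age, age_class, positive, n_tracks, lengths, view_pos)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _tissue_mask(h: int, w: int, mirrored: bool, view: str,
                 rng: np.random.Generator) -> np.ndarray:
    """Half-ellipse breast shape, chest-wall side flush with one image edge."""
    cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    a = h * rng.uniform(0.42, 0.48)          # vertical semi-axis
    b = w * rng.uniform(0.78, 0.92)          # horizontal semi-axis
    if view == "MLO":                        # MLO projections run taller
        a *= rng.uniform(1.02, 1.08)
        b *= rng.uniform(0.92, 1.0)
    rr, cc = np.mgrid[0:h, 0:w]
    mask = ((rr - cy) / a) ** 2 + (cc / b) ** 2 <= 1.0
    if mirrored:
        mask = mask[:, ::-1]
    return mask


def _bezier(p0, p1, p2, ts):
    """Quadratic Bezier points for parameters ts, shape (len(ts), 2)."""
    t = ts[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def _draw_disc(img, mask_out, r0, c0, radius, value):
    h, w = img.shape
    rr, cc = np.mgrid[max(0, int(r0 - radius)):min(h, int(r0 + radius + 2)),
                      max(0, int(c0 - radius)):min(w, int(c0 + radius + 2))]
    sel = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    img[rr[sel], cc[sel]] = value
    if mask_out is not None:
        mask_out[rr[sel], cc[sel]] = True


def _render_track(img: np.ndarray, truth: np.ndarray, interior: np.ndarray,
                  target_mm: float, pixel_size: float,
                  rng: np.random.Generator, max_tries: int = 60) -> float:
    """Place one dashed calcified track along a quadratic Bezier path.

    Returns the rendered centerline length in mm.  Control points are drawn
    from the eroded tissue interior so the whole curve (convex hull of the
    control points) stays inside tissue.
    """
    h, w = img.shape
    idx = np.flatnonzero(interior.ravel())
    if idx.size == 0:
        raise PlacementError("no tissue interior to place a track in")
    coords = np.column_stack(np.unravel_index(idx, (h, w))).astype(float)
    target_px = target_mm / pixel_size

    for _ in range(max_tries):
        p0 = coords[rng.integers(coords.shape[0])]
        theta = rng.uniform(0, 2 * np.pi)
        chord = target_px * rng.uniform(0.70, 0.95)
        p2 = p0 + chord * np.array([np.sin(theta), np.cos(theta)])
        if not (0 <= p2[0] < h and 0 <= p2[1] < w):
            continue
        if not interior[int(p2[0]), int(p2[1])]:
            continue
        mid = (p0 + p2) / 2.0
        perp = np.array([np.cos(theta), -np.sin(theta)])
        p1 = mid + perp * chord * rng.uniform(-0.35, 0.35)
        p1 = np.clip(p1, 0, [h - 1, w - 1])
        if not interior[int(p1[0]), int(p1[1])]:
            continue

        ts = np.linspace(0.0, 1.0, 2048)
        pts = _bezier(p0, p1, p2, ts)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])  # arc length in px
        total_px = s[-1]
        if total_px < 0.5 * target_px:
            continue
        end_px = min(total_px, target_px)

        # dash pattern along arc length: linear dashes with punctate dots mixed
        rendered_mm = 0.0
        pos = 0.0
        thick = rng.integers(1, 3)  # 1-2 px half-width behaviour below
        while pos < end_px:
            if rng.random() < 0.25:        # punctate dot
                dash_mm = rng.uniform(0.3, 0.8)
            else:                          # linear dash
                dash_mm = rng.uniform(0.8, 2.0)
            dash_px = min(dash_mm / pixel_size, end_px - pos)
            i0, i1 = np.searchsorted(s, [pos, pos + dash_px])
            i1 = min(max(i1, i0 + 1), len(ts) - 1)
            dash_pts = pts[i0:i1 + 1]
            rr = np.clip(np.round(dash_pts[:, 0]).astype(int), 0, h - 1)
            cc = np.clip(np.round(dash_pts[:, 1]).astype(int), 0, w - 1)
            val = rng.uniform(_CALC_LO, _CALC_HI)
            img[rr, cc] = val
            truth[rr, cc] = True
            if thick > 1:
                rr2 = np.clip(rr + 1, 0, h - 1)
                img[rr2, cc] = val
                truth[rr2, cc] = True
            rendered_mm += (s[i1] - s[i0]) * pixel_size
            pos += dash_px + rng.uniform(0.4, 1.2) / pixel_size  # gap in mm
        return rendered_mm
    raise PlacementError(
        f"could not place a {target_mm:.1f} mm track after {max_tries} tries")


def _render_confounders(img: np.ndarray, tissue: np.ndarray, interior: np.ndarray,
                        spec: PhantomSpec, rng: np.random.Generator) -> None:
    h, w = img.shape
    if rng.random() < spec.confounder_rate_round:
        coords = np.column_stack(np.nonzero(interior))
        if coords.size:
            for _ in range(int(rng.integers(2, 9))):
                r0, c0 = coords[rng.integers(coords.shape[0])]
                _draw_disc(img, None, float(r0), float(c0),
                           rng.uniform(1.0, 3.0),
                           rng.uniform(_CALC_LO, _CALC_HI))
    if rng.random() < spec.confounder_rate_fold:
        # skin-fold: a long, faint bright ridge near the tissue boundary with
        # a few tiny cutaneous calcifications lined up on it
        edge = tissue & ~ndimage.binary_erosion(tissue, iterations=6)
        coords = np.column_stack(np.nonzero(edge))
        if coords.size >= 2:
            p0 = coords[rng.integers(coords.shape[0])].astype(float)
            p2 = coords[rng.integers(coords.shape[0])].astype(float)
            p1 = (p0 + p2) / 2 + rng.uniform(-8, 8, size=2)
            pts = _bezier(p0, p1, p2, np.linspace(0, 1, 1024))
            rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
            cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
            on = tissue[rr, cc]
            img[rr[on], cc[on]] = np.minimum(
                img[rr[on], cc[on]] + _FOLD_BOOST, _TISSUE_HI + _FOLD_BOOST)
            for _ in range(int(rng.integers(2, 5))):
                k = rng.integers(len(rr))
                if tissue[rr[k], cc[k]]:
                    _draw_disc(img, None, float(rr[k]), float(cc[k]),
                               rng.uniform(0.8, 1.6),
                               rng.uniform(_CALC_LO, _CALC_HI))


def render_view(patient: PatientState, view_code: str, spec: PhantomSpec,
                rng: np.random.Generator) -> PhantomImage:
    """Render one mammographic view of a phantom patient."""
    if view_code not in VIEWS:
        raise ValueError(f"unknown view code {view_code!r}")
    laterality, view = view_code.split("-")
    h, w = spec.image_height, spec.image_width
    mirrored = laterality == "R"

    tissue = _tissue_mask(h, w, mirrored, view, rng)
    img = np.full((h, w), _BACKGROUND, dtype=np.float64)
    # smooth texture: low-frequency fibroglandular-like pattern
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
    texture = texture / (np.abs(texture).max() + 1e-12)
    base = rng.uniform(0.38, 0.5)
    tis = base + 0.16 * texture[tissue]
    img[tissue] = np.clip(tis, _TISSUE_LO, _TISSUE_HI)

    interior = ndimage.binary_erosion(tissue, iterations=10)
    _render_confounders(img, tissue, interior, spec, rng)

    truth = np.zeros((h, w), dtype=bool)
    truth_length = 0.0
    positive = patient.view_positive.get(view_code, False)
    if positive:
        for target_mm in patient.track_lengths_mm:
            truth_length += _render_track(img, truth, interior, target_mm,
                                          spec.pixel_size, rng)

    if spec.noise_level > 0:
        img = img + spec.noise_level * rng.standard_normal((h, w))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    # noise must not erase truth pixels' brightness ordering
    if truth.any():
        img[truth] = np.maximum(img[truth], _CALC_LO)

    return PhantomImage(pixels=img, truth_mask=truth,
                        truth_length=float(truth_length),
                        label=bool(positive), pixel_size=spec.pixel_size)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(spec: PhantomSpec, render: bool = True) -> PhantomCohort:
    """Generate a phantom cohort; deterministic for a given spec (incl. seed).

    Each patient draws from an independent substream spawned from the spec
    seed, so cohorts are stable under patient reordering.  With
    ``render=False`` only patient/view metadata are produced; truth lengths
    are only known after rendering, so unrendered cohorts carry NaN there.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    age_ss, *patient_ss = root.spawn(spec.n_patients + 1)

    age_rng = np.random.default_rng(age_ss)
    ages = age_rng.uniform(spec.age_range[0], spec.age_range[1],
                           size=spec.n_patients)
    qs = np.percentile(ages, [25, 50, 75])

    width = len(str(max(spec.n_patients - 1, 1)))
    patients: list[PatientState] = []
    records: list[CohortRecord] = []
    images: dict[tuple[str, str], PhantomImage] = {}

    for i in range(spec.n_patients):
        rng = np.random.default_rng(patient_ss[i])
        pid = f"P{i:0{width}d}"
        age = float(ages[i])
        cls = _age_class_of(age, qs)
        state = _sample_patient(pid, age, cls,
                                spec.prevalence_by_age_class[cls], spec, rng)
        patients.append(state)
        for view_code in VIEWS:
            lat, view = view_code.split("-")
            if render:
                im = render_view(state, view_code, spec, rng)
                images[(pid, view_code)] = im
                tl = im.truth_length
                lab = im.label
            else:
                tl = float("nan")
                lab = state.view_positive.get(view_code, False)
            records.append(CohortRecord(
                patient_id=pid, age=age, view=view, laterality=lat,
                label=bool(lab), pixel_size_mm=spec.pixel_size,
                truth_length_mm=tl))

    return PhantomCohort(spec=spec, patients=patients, records=records,
                         images=images)


def write_cohort(cohort: PhantomCohort, outdir: str) -> str:
    """Write images (16-bit PNG), truth masks (PNG) and the cohort CSV."""
    import imageio.v3 as iio

    os.makedirs(outdir, exist_ok=True)
    img_dir = os.path.join(outdir, "images")
    mask_dir = os.path.join(outdir, "masks")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(mask_dir, exist_ok=True)
    for rec in cohort.records:
        key = (rec.patient_id, f"{rec.laterality}-{rec.view}")
        im = cohort.images.get(key)
        if im is None:
            continue
        name = f"{rec.patient_id}_{rec.laterality}-{rec.view}.png"
        iio.imwrite(os.path.join(img_dir, name),
                    np.round(im.pixels * 65535).astype(np.uint16))
        iio.imwrite(os.path.join(mask_dir, name),
                    (im.truth_mask * 255).astype(np.uint8))
        rec.path = os.path.join("images", name)
    csv_path = os.path.join(outdir, "cohort.csv")
    cohort.to_frame().to_csv(csv_path, index=False)
    return csv_path
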