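"""Synthetic narrow-band-imaging-like polyp images and whole synthetic studies.

Real CADx systems for colorectal polyps are trained on endoscopic NBI stills.
This module emulates the *structure* of such data so the rest of the pipeline
(localization, quality gating, BoVW characterization, the three-image protocol
and the study statistics) can be trained and exercised without any download:

* one textured elliptical "polyp" on a procedurally textured mucosa-like
  background, with a class-specific surface pattern —

  - ``adenoma``      tubular pattern: warped oriented stripes (NBI shows
                     brownish tubulo-gyral pits on adenomas);
  - ``ssl``          open-pit pattern: dense dark rounded pits;
  - ``hyperplastic`` sparse faint dots on a pale, smooth surface;

* degraded variants (Gaussian blur, overexposed specular patch, or no polyp
  at all) reproducing the failure modes the quality gate and localizer must
  reject;
* whole studies: patients with negative-binomial polyp counts (mean 0.74,
  SD 1.23 per colonoscopy), class mix 73 % adenoma / 10 % SSL / 17 %
  hyperplastic, rectosigmoid vs proximal location, and three independently
  degraded captures per polyp.

All intensity computations use Rec. 601 luminance; images are 8-bit RGB.
Identical spec + seed yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .localization import BoundingBox

CLASSES = ("adenoma", "ssl", "hyperplastic")

#: default degradation rates per capture in a synthetic study; most captures
#: are clean, mirroring the near-perfect first-image success seen clinically
DEFAULT_P_BLUR = 0.08
DEFAULT_P_OVEREXPOSED = 0.05
DEFAULT_P_ABSENT = 0.02


@dataclass(frozen=True)
class TextureParams:
    """Per-class texture descriptors; amplitudes are 8-bit luminance units."""

    stripe_wavelength: float = 9.0       # adenoma tubular pattern period (px)
    stripe_amplitude: float = 26.0
    stripe_warp: float = 3.0             # orientation dispersion (phase warp, px)
    blob_density: float = 3.0e-3         # SSL pits per px^2
    blob_sigma: float = 2.6              # SSL pit radius scale (px)
    blob_amplitude: float = 45.0
    dot_spacing: float = 15.0            # hyperplastic dot grid spacing (px)
    dot_sigma: float = 1.4
    dot_amplitude: float = 30.0
    contrast: float = 1.0                # global multiplier: texture difficulty dial


@dataclass(frozen=True)
class Degradation:
    blur_sigma: float = 0.0              # whole-image Gaussian blur (px)
    overexposed_fraction: float = 0.0    # target fraction of the box at >=250


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic capture; identical spec+seed => identical pixels."""

    image_size: tuple[int, int] = (512, 512)   # (H, W)
    polyp_class: str = "adenoma"               # adenoma | ssl | hyperplastic | none
    polyp_radius: float = 80.0                 # semi-major axis (px)
    texture: TextureParams = field(default_factory=TextureParams)
    degradation: Degradation = field(default_factory=Degradation)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.polyp_class not in CLASSES + ("none",):
            raise ValueError(f"unknown polyp_class {self.polyp_class!r}")
        if self.polyp_class != "none" and not 0 < self.polyp_radius < min(h, w) / 2:
            raise ValueError("polyp_radius must lie in (0, min(H, W)/2)")
        if not 0.0 <= self.degradation.overexposed_fraction <= 1.0:
            raise ValueError("overexposed_fraction must be in [0, 1]")
        if self.degradation.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


@dataclass(frozen=True)
class PolypTruth:
    """Generator ground truth: tight box (None when no polyp) and class label."""

    box: BoundingBox | None
    label: str


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float, scale: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    s = f.std()
    return f * (scale / s) if s > 0 else f


def _impulse_field(mask: np.ndarray, points: np.ndarray, sigma: float,
                   amplitude: float) -> np.ndarray:
    """Sum of Gaussian pits at integer points, peak height ~= amplitude."""
    fld = np.zeros(mask.shape)
    if len(points):
        ys = np.clip(points[:, 0].astype(int), 0, mask.shape[0] - 1)
        xs = np.clip(points[:, 1].astype(int), 0, mask.shape[1] - 1)
        np.add.at(fld, (ys, xs), 1.0)
        fld = ndimage.gaussian_filter(fld, sigma) * (2 * np.pi * sigma**2)
    return amplitude * fld


def _class_texture(cls: str, tex: TextureParams, mask: np.ndarray,
                   yy: np.ndarray, xx: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Signed luminance modulation inside the polyp mask."""
    h, w = mask.shape
    if cls == "adenoma":
        theta = rng.uniform(0, np.pi)
        u = np.cos(theta) * xx + np.sin(theta) * yy
        u = u + _smooth_noise(rng, (h, w), 12.0, tex.stripe_warp * tex.stripe_wavelength / 3.0)
        return tex.stripe_amplitude * np.sin(2 * np.pi * u / tex.stripe_wavelength)
    if cls == "ssl":
        area = float(mask.sum())
        n = rng.poisson(tex.blob_density * area)
        idx = np.flatnonzero(mask.ravel())
        pts = np.column_stack(np.unravel_index(rng.choice(idx, size=min(n, idx.size)), mask.shape)) \
            if n and idx.size else np.empty((0, 2))
        return -_impulse_field(mask, pts, tex.blob_sigma, tex.blob_amplitude)
    if cls == "hyperplastic":
        s = tex.dot_spacing
        gy = np.arange(0, h, s)
        gx = np.arange(0, w, s)
        cy, cx = np.meshgrid(gy, gx, indexing="ij")
        jitter = rng.uniform(-s / 3, s / 3, size=(2,) + cy.shape)
        pts = np.column_stack([(cy + jitter[0]).ravel(), (cx + jitter[1]).ravel()])
        inside = mask[np.clip(pts[:, 0].astype(int), 0, h - 1),
                      np.clip(pts[:, 1].astype(int), 0, w - 1)]
        return -_impulse_field(mask, pts[inside], tex.dot_sigma, tex.dot_amplitude)
    raise ValueError(cls)


# class-specific mean color shift of the polyp surface (R, G, B); adenomas
# appear browner under NBI, serrated lesions paler
_CLASS_SHIFT = {
    "adenoma": np.array([28.0, -4.0, -14.0]),
    "ssl": np.array([16.0, 6.0, -6.0]),
    "hyperplastic": np.array([20.0, 14.0, 10.0]),
}


def generate_polyp_image(spec: SyntheticSpec) -> tuple[np.ndarray, PolypTruth]:
    """Render one capture.

    Returns the 8-bit RGB image and the ground truth (tight bounding box of the
    polyp mask, or an empty box when ``polyp_class == "none"``).
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # mucosa-like background: teal base, low-frequency mottle, fine grain, vignette
    base = np.array([108.0, 132.0, 122.0])
    lowf = _smooth_noise(rng, (h, w), 40.0, 14.0)
    grain = _smooth_noise(rng, (h, w), 1.5, 4.0)
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    lum = lowf + grain - 22.0 * r2
    img = base[None, None, :] + lum[..., None] * np.array([1.0, 1.0, 0.95])

    truth_box: BoundingBox | None = None
    mask = None
    if spec.polyp_class != "none":
        r = spec.polyp_radius
        cy = rng.uniform(r + 8, h - r - 8)
        cx = rng.uniform(r + 8, w - r - 8)
        b = r * rng.uniform(0.7, 1.0)
        ang = rng.uniform(0, np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        d = np.sqrt((u / r) ** 2 + (v / b) ** 2)
        mask = d <= 1.0
        edge = np.clip((1.0 - d) / 0.12, 0.0, 1.0)  # soft rim

        dome = 16.0 * np.clip(1.0 - d**2, 0.0, 1.0)
        tex = _class_texture(spec.polyp_class, spec.texture, mask, yy, xx, rng)
        modulation = (dome + spec.texture.contrast * tex) * edge
        img += edge[..., None] * _CLASS_SHIFT[spec.polyp_class][None, None, :]
        img += modulation[..., None] * np.array([1.0, 1.0, 0.92])

        ys, xs = np.nonzero(mask)
        truth_box = BoundingBox(x=int(xs.min()), y=int(ys.min()),
                                w=int(xs.max() - xs.min() + 1),
                                h=int(ys.max() - ys.min() + 1))

    f = spec.degradation.overexposed_fraction
    if f > 0:
        # specular highlight: a saturated disk covering ~f of the box (or of a
        # central region when there is no polyp)
        if truth_box is not None:
            bx, by, bw, bh = truth_box.x, truth_box.y, truth_box.w, truth_box.h
        else:
            bw, bh = w // 2, h // 2
            bx, by = w // 4, h // 4
        rad = float(np.sqrt(f * bw * bh / np.pi))
        hy = rng.uniform(by + 0.3 * bh, by + 0.7 * bh)
        hx = rng.uniform(bx + 0.3 * bw, bx + 0.7 * bw)
        disk = (yy - hy) ** 2 + (xx - hx) ** 2 <= rad**2
        img[disk] = 255.0

    # blur last: the specular highlight is part of the scene, so defocus/motion
    # blur smears it too (its saturated core keeps counting as overexposed)
    if spec.degradation.blur_sigma > 0:
        for c in range(3):
            img[..., c] = ndimage.gaussian_filter(img[..., c], spec.degradation.blur_sigma)

    return np.clip(img, 0, 255).astype(np.uint8), PolypTruth(truth_box, spec.polyp_class)


# ---------------------------------------------------------------------------
# whole-study synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySpec:
    """Conditions of a synthetic validation study."""

    n_patients: int = 292
    mean_polyps_per_colonoscopy: float = 0.74
    sd_polyps_per_colonoscopy: float = 1.23
    class_mix: tuple[float, float, float] = (0.73, 0.10, 0.17)
    rectosigmoid_fraction: float = 0.29
    image_size: tuple[int, int] = (512, 512)
    polyp_radius_range: tuple[float, float] = (55.0, 95.0)
    p_blur: float = DEFAULT_P_BLUR
    blur_sigma_range: tuple[float, float] = (2.5, 4.5)
    p_overexposed: float = DEFAULT_P_OVEREXPOSED
    overexposed_range: tuple[float, float] = (0.3, 0.7)
    p_absent: float = DEFAULT_P_ABSENT
    texture: TextureParams = field(default_factory=TextureParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.mean_polyps_per_colonoscopy <= 0:
            raise ValueError("mean_polyps_per_colonoscopy must be positive")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix entries must be nonnegative")


@dataclass(frozen=True)
class SyntheticPolyp:
    """One study polyp: identity, ground-truth histology, and three capture
    recipes with independently drawn degradations (rendered on demand)."""

    polyp_id: str
    patient_id: str
    size_mm: int
    segment: str                      # rectosigmoid | proximal
    histology: str
    capture_specs: tuple[SyntheticSpec, ...]

    def render(self, k: int) -> tuple[np.ndarray, PolypTruth]:
        """Render capture ``k`` (0-based, < 3)."""
        return generate_polyp_image(self.capture_specs[k])


@dataclass(frozen=True)
class StudyDataset:
    spec: StudySpec
    polyps: tuple[SyntheticPolyp, ...]
    polyps_per_patient: tuple[int, ...]

    def __iter__(self) -> Iterator[SyntheticPolyp]:
        return iter(self.polyps)

    def __len__(self) -> int:
        return len(self.polyps)


_SIZE_MM_P = (0.25, 0.30, 0.20, 0.15, 0.10)  # 1..5 mm, skewed small


def _draw_counts(rng: np.random.Generator, spec: StudySpec) -> np.ndarray:
    """Per-colonoscopy polyp counts: negative binomial matching mean and SD
    (overdispersed, variance > mean); Poisson fallback if not overdispersed."""
    mu = spec.mean_polyps_per_colonoscopy
    var = spec.sd_polyps_per_colonoscopy**2
    if var > mu:
        size = mu**2 / (var - mu)
        p = size / (size + mu)
        return rng.negative_binomial(size, p, spec.n_patients)
    return rng.poisson(mu, spec.n_patients)


def generate_study(spec: StudySpec) -> StudyDataset:
    """Draw a whole study: patients, per-patient polyp counts, histologies,
    segments and per-capture degradation recipes.

    Images are *not* rasterized here; call :meth:`SyntheticPolyp.render` (or
    :func:`write_study`) to materialize pixels. This keeps large draws (used to
    check the count distribution) cheap.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _draw_counts(rng, spec)
    polyps: list[SyntheticPolyp] = []
    for i, n in enumerate(counts):
        patient_id = f"S{i + 1:05d}"
        for _ in range(int(n)):
            cls = CLASSES[rng.choice(3, p=np.asarray(spec.class_mix))]
            segment = "rectosigmoid" if rng.random() < spec.rectosigmoid_fraction else "proximal"
            size_mm = 1 + int(rng.choice(5, p=_SIZE_MM_P))
            radius = rng.uniform(*spec.polyp_radius_range)
            caps = []
            for _k in range(3):
                absent = rng.random() < spec.p_absent
                blur = rng.uniform(*spec.blur_sigma_range) if rng.random() < spec.p_blur else 0.0
                over = rng.uniform(*spec.overexposed_range) if rng.random() < spec.p_overexposed else 0.0
                caps.append(SyntheticSpec(
                    image_size=spec.image_size,
                    polyp_class="none" if absent else cls,
                    polyp_radius=radius,
                    texture=spec.texture,
                    degradation=Degradation(blur_sigma=blur, overexposed_fraction=over),
                    seed=int(rng.integers(0, 2**31 - 1)),
                ))
            polyps.append(SyntheticPolyp(
                polyp_id=f"P{len(polyps) + 1:05d}", patient_id=patient_id,
                size_mm=size_mm, segment=segment, histology=cls,
                capture_specs=tuple(caps)))
    return StudyDataset(spec=spec, polyps=tuple(polyps),
                        polyps_per_patient=tuple(int(c) for c in counts))


def write_study(dataset: StudyDataset, outdir: str, captures: int = 3) -> dict:
    """Materialize a study to disk: PNG captures, COCO-style annotations, and a
    study table CSV. Returns the COCO dictionary."""
    import os

    from . import io as _io

    os.makedirs(outdir, exist_ok=True)
    images, annotations, rows = [], [], []
    img_id = ann_id = 0
    for p in dataset:
        for k in range(min(captures, len(p.capture_specs))):
            img, truth = p.render(k)
            fname = f"{p.polyp_id}_c{k + 1}.png"
            _io.write_png(os.path.join(outdir, fname), img)
            img_id += 1
            images.append({"id": img_id, "file_name": fname,
                           "width": img.shape[1], "height": img.shape[0],
                           "polyp_id": p.polyp_id, "capture_index": k + 1})
            if truth.box is not None:
                ann_id += 1
                annotations.append({
                    "id": ann_id, "image_id": img_id,
                    "category_id": CLASSES.index(truth.label) + 1,
                    "bbox": [truth.box.x, truth.box.y, truth.box.w, truth.box.h],
                    "area": truth.box.w * truth.box.h, "iscrowd": 0})
        rows.append({"polyp_id": p.polyp_id, "patient_id": p.patient_id,
                     "size_mm": p.size_mm, "segment": p.segment,
                     "histology": p.histology})
    coco = {"images": images, "annotations": annotations,
            "categories": [{"id": i + 1, "name": c} for i, c in enumerate(CLASSES)]}
    _io.write_coco(os.path.join(outdir, "annotations.json"), coco)
    _io.write_table(os.path.join(outdir, "polyps.csv"), rows)
    return coco
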