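"""Synthetic contrast-CT-like slices and circumferential stress profiles.

The generator emulates the geometry that matters to the localisation
pipeline: one or two bright stent-graft (SG) branch cross-sections (filled
discs or annuli with a darker lumen), a smaller bright endoleak blob placed
at a controlled angle and radial offset from one branch's centre, mild
Gaussian blur and additive Gaussian pixel noise clipped to the dynamic range.
Every scene carries a ground-truth sidecar (centroids and the requested
angle) so every downstream stage can be scored without any external data.

Pixels are isotropic; no pixel spacing accompanies the angular measurements
this package reproduces, and angles are spacing-free under isotropy.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import angle_to_centroid

__all__ = [
    "BranchSpec",
    "EndoleakSpec",
    "SyntheticSceneSpec",
    "GroundTruth",
    "StressProfileSpec",
    "generate_scene",
    "generate_stress_profile",
    "write_scene",
    "write_stress_profile",
]


@dataclass(frozen=True)
class BranchSpec:
    """One SG branch cross-section: a filled disc, or an annulus when
    ``lumen_radius > 0`` (bright wall, darker lumen)."""

    center_row: float
    center_col: float
    outer_radius: float
    lumen_radius: float = 0.0
    intensity: float = 200.0
    lumen_intensity: float = 90.0

    def __post_init__(self) -> None:
        if self.outer_radius <= 0:
            raise ValueError("branch outer_radius must be > 0")
        if not 0 <= self.lumen_radius < self.outer_radius:
            raise ValueError("lumen_radius must be in [0, outer_radius)")


@dataclass(frozen=True)
class EndoleakSpec:
    """A filled bright disc at (angle_deg, radial_offset) from the anchor
    branch centre, under the package angle convention (0 deg rightward,
    counterclockwise, rows downward)."""

    anchor_branch_index: int = 0
    angle_deg: float = 265.0
    radial_offset: float = 60.0
    radius: float = 12.0
    intensity: float = 180.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("endoleak radius must be > 0")
        if not 0.0 <= self.angle_deg < 360.0:
            raise ValueError("endoleak angle_deg must lie in [0, 360)")


@dataclass(frozen=True)
class SyntheticSceneSpec:
    image_height: int = 256
    image_width: int = 256
    branches: tuple[BranchSpec, ...] = (
        BranchSpec(center_row=128.0, center_col=128.0, outer_radius=40.0),
    )
    endoleak: EndoleakSpec | None = field(default_factory=EndoleakSpec)
    background_level: float = 30.0
    noise_sd: float = 5.0
    blur_sigma: float = 1.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not self.branches:
            raise ValueError("at least one branch is required")


@dataclass(frozen=True)
class GroundTruth:
    """Placement truth recorded before blur and noise are applied.

    ``sg_centroid`` is the area-weighted centroid of all rendered branch
    pixels; ``anchor_centroid`` is the centroid of the anchor branch alone.
    ``endoleak_centroid`` is the pixel-mask centroid of the rendered blob
    (sub-pixel, so it can differ from the requested placement by a fraction
    of a pixel at small radii).
    """

    sg_centroid: tuple[float, float]
    anchor_centroid: tuple[float, float] | None = None
    endoleak_centroid: tuple[float, float] | None = None
    true_endoleak_angle_deg: float | None = None
    true_stress_peak_angle_deg: float | None = None

    def __post_init__(self) -> None:
        for a in (self.true_endoleak_angle_deg, self.true_stress_peak_angle_deg):
            if a is not None and not 0.0 <= a < 360.0:
                raise ValueError("ground-truth angles must lie in [0, 360)")


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _endoleak_center(spec: SyntheticSceneSpec) -> tuple[float, float]:
    el = spec.endoleak
    anchor = spec.branches[el.anchor_branch_index]
    theta = math.radians(el.angle_deg)
    # +x is increasing column; +y (counterclockwise) is decreasing row
    row = anchor.center_row - el.radial_offset * math.sin(theta)
    col = anchor.center_col + el.radial_offset * math.cos(theta)
    return row, col


def _validate_placement(spec: SyntheticSceneSpec) -> None:
    h, w = spec.image_height, spec.image_width
    for i, br in enumerate(spec.branches):
        if (
            br.center_row - br.outer_radius < 0
            or br.center_row + br.outer_radius > h - 1
            or br.center_col - br.outer_radius < 0
            or br.center_col + br.outer_radius > w - 1
        ):
            raise ValueError(f"branch {i} extends outside the image frame")
    if spec.endoleak is None:
        return
    el = spec.endoleak
    if not 0 <= el.anchor_branch_index < len(spec.branches):
        raise ValueError("anchor_branch_index out of range")
    er, ec = _endoleak_center(spec)
    if (
        er - el.radius < 0
        or er + el.radius > h - 1
        or ec - el.radius < 0
        or ec + el.radius > w - 1
    ):
        raise ValueError("endoleak extends outside the image frame")
    for i, br in enumerate(spec.branches):
        lumen = br.lumen_radius if br.lumen_radius > 0 else br.outer_radius
        d = math.hypot(er - br.center_row, ec - br.center_col)
        if d < lumen + el.radius:
            raise ValueError(
                f"endoleak overlaps the lumen of branch {i} "
                f"(centre distance {d:.1f} px < {lumen + el.radius:.1f} px)"
            )


def generate_scene(spec: SyntheticSceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene and its ground truth.

    Returns the image as ``uint8``/``uint16`` per ``spec.bit_depth``.
    Rendering order: background, branch discs/annuli, endoleak disc; then
    Gaussian blur (``blur_sigma``), then additive Gaussian noise
    (``noise_sd``) clipped to the dynamic range.  Identical specs (including
    seed) produce bit-identical images.
    """
    _validate_placement(spec)
    shape = (spec.image_height, spec.image_width)
    img = np.full(shape, float(spec.background_level))

    branch_mask_total = np.zeros(shape, dtype=bool)
    anchor_centroid = None
    centroids = []
    areas = []
    for i, br in enumerate(spec.branches):
        outer = _disc_mask(shape, (br.center_row, br.center_col), br.outer_radius)
        img[outer] = br.intensity
        if br.lumen_radius > 0:
            lumen = _disc_mask(shape, (br.center_row, br.center_col), br.lumen_radius)
            img[lumen] = br.lumen_intensity
        branch_mask_total |= outer
        rr, cc = np.nonzero(outer)
        centroids.append((rr.mean(), cc.mean()))
        areas.append(rr.size)

    areas_arr = np.asarray(areas, dtype=float)
    cents = np.asarray(centroids)
    sg_centroid = tuple(np.average(cents, axis=0, weights=areas_arr))

    endoleak_centroid = None
    true_angle = None
    if spec.endoleak is not None:
        el_center = _endoleak_center(spec)
        el_mask = _disc_mask(shape, el_center, spec.endoleak.radius)
        img[el_mask] = spec.endoleak.intensity
        rr, cc = np.nonzero(el_mask)
        endoleak_centroid = (rr.mean(), cc.mean())
        anchor_centroid = centroids[spec.endoleak.anchor_branch_index]
        true_angle = spec.endoleak.angle_deg

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)

    vmax = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    img = np.clip(np.rint(img), 0, vmax).astype(dtype)

    truth = GroundTruth(
        sg_centroid=sg_centroid,
        anchor_centroid=anchor_centroid,
        endoleak_centroid=endoleak_centroid,
        true_endoleak_angle_deg=true_angle,
    )
    return img, truth


@dataclass(frozen=True)
class StressProfileSpec:
    """A circumferential wall-stress profile: baseline plus wrapped-Gaussian
    bumps, sampled at uniform angles, with optional additive noise.

    Units are MPa.  Defaults place stresses in the sub-MPa range typical of
    stent-graft walls (baseline 0.2 MPa, peak ~0.8 MPa).  ``peak_width_deg``
    is the Gaussian sigma of the bump.
    """

    peak_angle_deg: float = 230.9
    peak_width_deg: float = 25.0
    peak_amplitude: float = 0.6
    baseline: float = 0.2
    secondary_peaks: tuple[tuple[float, float, float], ...] = ()  # (angle, width, amplitude)
    noise_sd: float = 0.01
    n_samples: int = 360
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")
        if self.peak_width_deg <= 0:
            raise ValueError("peak_width_deg must be > 0")
        if self.peak_amplitude < 0 or self.baseline < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for ang, width, amp in self.secondary_peaks:
            if width <= 0 or amp < 0:
                raise ValueError("secondary peak widths must be > 0, amplitudes >= 0")
            if amp >= self.peak_amplitude:
                raise ValueError(
                    "secondary peak amplitude must be < primary amplitude "
                    "(the ground-truth peak would be ambiguous)"
                )


def _wrapped_gaussian(angles_deg: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Gaussian bump on the circle: sum over the three nearest period images.

    Exact to machine precision for sigma well below 120 deg.
    """
    out = np.zeros_like(angles_deg, dtype=float)
    for k in (-360.0, 0.0, 360.0):
        out += np.exp(-0.5 * ((angles_deg - mu + k) / sigma) ** 2)
    return out


def generate_stress_profile(spec: StressProfileSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample a stress profile at ``n_samples`` uniform angles.

    Returns a DataFrame with columns ``angle_deg`` and ``stress_mpa`` (the
    on-disk CSV schema) and a :class:`GroundTruth` carrying the noiseless
    global-peak angle.  Stresses are clipped at 0 after noise.
    """
    angles = np.linspace(0.0, 360.0, spec.n_samples, endpoint=False)
    stress = spec.baseline + spec.peak_amplitude * _wrapped_gaussian(
        angles, spec.peak_angle_deg % 360.0, spec.peak_width_deg
    )
    for ang, width, amp in spec.secondary_peaks:
        stress += amp * _wrapped_gaussian(angles, ang % 360.0, width)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        stress = stress + rng.normal(0.0, spec.noise_sd, size=stress.shape)
    stress = np.clip(stress, 0.0, None)
    df = pd.DataFrame({"angle_deg": angles, "stress_mpa": stress})
    truth = GroundTruth(
        sg_centroid=(math.nan, math.nan),
        true_stress_peak_angle_deg=spec.peak_angle_deg % 360.0,
    )
    return df, truth


def write_scene(image: np.ndarray, truth: GroundTruth, path: str) -> None:
    """Write the image (16/8-bit grayscale TIFF or PNG by extension) and a
    ``<basename>.truth.json`` ground-truth sidecar."""
    iio.imwrite(path, image)
    base = path.rsplit(".", 1)[0]
    payload = dataclasses.asdict(truth)
    with open(base + ".truth.json", "w") as fh:
        json.dump(payload, fh, indent=2)


def write_stress_profile(df: pd.DataFrame, truth: GroundTruth, path: str) -> None:
    """Write a 2-column ``angle_deg,stress_mpa`` CSV plus a truth sidecar."""
    df.to_csv(path, index=False)
    base = path.rsplit(".", 1)[0]
    with open(base + ".truth.json", "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)
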