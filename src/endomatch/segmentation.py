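"""Slice segmentation: isolate the endoleak and stent-graft cross-sections.

The chain mirrors a standard contrast-CT blob-isolation recipe: optional ROI
crop, square-window mean denoising, intensity binarization (Otsu by default),
Canny edge detection, morphological closing with a disc element, interior
hole-filling, and connected-component extraction with sub-pixel centroids.

Role assignment (which region is a branch, which the endoleak) is this
module's own rule — in clinical use the endoleak is identified by a
radiologist, so a seed-point override is provided.  By default the largest
region is a stent-graft branch, the second-largest is too when its area is a
configurable fraction of the largest, and the endoleak is the largest
remaining region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage
from skimage import feature, filters, measure, morphology

__all__ = [
    "GrayImage",
    "ROISpec",
    "SegmentedRegion",
    "SegmentationConfig",
    "NoEndoleakCandidate",
    "SegmentationResult",
    "crop_roi",
    "denoise_mean",
    "binarize",
    "canny_edges",
    "morphological_close",
    "fill_interior",
    "extract_regions",
    "segment_endoleak",
    "midpoint_of_contact",
    "read_image",
]


@dataclass
class GrayImage:
    """A 2-D grayscale raster with bit depth and optional pixel spacing.

    ``offset`` records the (row, col) of this image's origin in the
    full-frame coordinate system, so centroids measured after an ROI crop can
    be mapped back by simple addition.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_spacing: float = 1.0
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        vmax = 2**self.bit_depth - 1
        if self.pixels.min() < 0 or self.pixels.max() > vmax:
            raise ValueError(f"intensities outside [0, {vmax}] for bit depth {self.bit_depth}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROISpec:
    top_row: int
    left_col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI height and width must be > 0")


@dataclass(frozen=True)
class SegmentedRegion:
    """A labelled 8-connected pixel region with sub-pixel centroid.

    ``centroid`` is the mean of member pixel coordinates in full-frame
    (row, col); ``boundary`` is an ordered closed contour around the region.
    """

    label: int
    pixel_count: int
    centroid: tuple[float, float]
    boundary: np.ndarray  # (n, 2) ordered (row, col), full-frame coordinates
    role_tag: str = "unknown"


@dataclass
class SegmentationConfig:
    """Every knob of the chain, with the package defaults.

    ``n_branches=None`` enables the area-ratio rule: the second-largest
    region is also tagged ``sg_branch`` when its area is at least
    ``branch_area_ratio`` times the largest.  ``endoleak_seed`` switches the
    endoleak choice from largest-remaining to nearest-centroid-to-seed.
    """

    roi: ROISpec | None = None
    denoise_window: int = 3
    threshold_method: str = "otsu"  # or "fixed"
    threshold: float | None = None
    canny_sigma: float = 1.0
    canny_low_frac: float = 0.1
    canny_high_frac: float = 0.2
    closing_radius: int = 3
    min_region_area: int = 20
    n_branches: int | None = None
    branch_area_ratio: float = 0.5
    endoleak_seed: tuple[float, float] | None = None

    def to_yaml(self) -> str:
        d = asdict(self)
        if self.roi is not None:
            d["roi"] = asdict(self.roi)
        if self.endoleak_seed is not None:
            d["endoleak_seed"] = list(self.endoleak_seed)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SegmentationConfig":
        d = yaml.safe_load(text) or {}
        if d.get("roi"):
            d["roi"] = ROISpec(**d["roi"])
        if d.get("endoleak_seed"):
            d["endoleak_seed"] = tuple(d["endoleak_seed"])
        return cls(**d)


class NoEndoleakCandidate:
    """Structured non-error outcome: the chain found branches but no region
    qualifying as an endoleak.  Screening slices without an endoleak is the
    intended negative case, so this is not an exception."""

    def __init__(self, branches: list[SegmentedRegion]):
        self.branches = branches

    def __repr__(self) -> str:  # pragma: no cover
        return f"NoEndoleakCandidate(branches={len(self.branches)})"


@dataclass
class SegmentationResult:
    endoleak: SegmentedRegion | None
    branches: list[SegmentedRegion]

    @property
    def found_endoleak(self) -> bool:
        return self.endoleak is not None


def crop_roi(image: GrayImage, roi: ROISpec) -> GrayImage:
    """Crop, recording the offset so centroids map back to full-frame."""
    h, w = image.shape
    if roi.top_row < 0:
        raise ValueError("ROI exceeds image bounds at the top edge")
    if roi.left_col < 0:
        raise ValueError("ROI exceeds image bounds at the left edge")
    if roi.top_row + roi.height > h:
        raise ValueError("ROI exceeds image bounds at the bottom edge")
    if roi.left_col + roi.width > w:
        raise ValueError("ROI exceeds image bounds at the right edge")
    sub = image.pixels[
        roi.top_row : roi.top_row + roi.height,
        roi.left_col : roi.left_col + roi.width,
    ]
    return GrayImage(
        pixels=sub.copy(),
        bit_depth=image.bit_depth,
        pixel_spacing=image.pixel_spacing,
        offset=(image.offset[0] + roi.top_row, image.offset[1] + roi.left_col),
    )


def denoise_mean(image: GrayImage, window: int = 3) -> GrayImage:
    """Square-window mean filter; each pixel becomes the arithmetic mean of
    the ``window x window`` neighbourhood centred on it, with edge
    replication at the border."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1; got {window}")
    out = ndimage.uniform_filter(
        image.pixels.astype(np.float64), size=window, mode="nearest"
    )
    vmax = 2**image.bit_depth - 1
    return GrayImage(
        pixels=np.clip(out, 0, vmax),
        bit_depth=image.bit_depth,
        pixel_spacing=image.pixel_spacing,
        offset=image.offset,
    )


def binarize(
    image: GrayImage, method: str = "otsu", threshold: float | None = None
) -> np.ndarray:
    """Foreground mask: true where intensity >= threshold.

    ``otsu`` picks the threshold automatically; a constant image has no
    defined Otsu threshold and raises.
    """
    px = image.pixels
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        t = threshold
    elif method == "otsu":
        if np.ptp(px) == 0:
            raise ValueError("Otsu threshold undefined for a constant image")
        t = filters.threshold_otsu(px)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return px >= t


def canny_edges(
    image: GrayImage,
    sigma: float = 1.0,
    low_frac: float = 0.1,
    high_frac: float = 0.2,
) -> np.ndarray:
    """Canny edge mask: Gaussian smoothing at ``sigma``, gradient magnitude,
    non-maximum suppression, double-threshold hysteresis with thresholds as
    fractions of the maximum gradient."""
    if not 0 <= low_frac < high_frac <= 1:
        raise ValueError("require 0 <= low_frac < high_frac <= 1")
    px = image.pixels.astype(np.float64)
    if np.ptp(px) == 0:
        return np.zeros(image.shape, dtype=bool)
    return _canny_frac(px, sigma, low_frac, high_frac)


def _canny_frac(px: np.ndarray, sigma: float, low_frac: float, high_frac: float) -> np.ndarray:
    # skimage's absolute thresholds apply to the smoothed gradient magnitude;
    # scale them to its maximum so low/high behave as fractions of max gradient.
    smoothed = ndimage.gaussian_filter(px, sigma, mode="nearest")
    gr = ndimage.sobel(smoothed, axis=0, mode="nearest")
    gc = ndimage.sobel(smoothed, axis=1, mode="nearest")
    gmax = float(np.hypot(gr, gc).max())
    if gmax == 0:
        return np.zeros(px.shape, dtype=bool)
    return feature.canny(
        px, sigma=sigma, low_threshold=low_frac * gmax, high_threshold=high_frac * gmax
    )


def morphological_close(mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Binary closing (dilation then erosion) with a disc structuring element."""
    if radius < 1:
        raise ValueError("closing radius must be >= 1")
    return morphology.closing(mask.astype(bool), morphology.disk(radius)).astype(bool)


def fill_interior(mask: np.ndarray) -> np.ndarray:
    """Fill holes enclosed by foreground — closing seals the boundary but
    does not fill large interiors, and centroid correctness needs solid
    regions."""
    return ndimage.binary_fill_holes(mask)


def _ordered_boundary(region_mask: np.ndarray) -> np.ndarray:
    """Ordered closed contour of the largest outline of a binary region, as
    (row, col) sub-pixel coordinates."""
    padded = np.pad(region_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.zeros((0, 2))
    longest = max(contours, key=len)
    return longest - 1.0  # undo padding


def extract_regions(mask: np.ndarray, min_region_area: int = 20,
                    offset: tuple[int, int] = (0, 0)) -> list[SegmentedRegion]:
    """8-connected components of area >= ``min_region_area``, sorted by
    descending area, each with centroid = mean of member pixel coordinates
    (full-frame via ``offset``)."""
    labels = measure.label(mask, connectivity=2)
    regions = []
    for props in measure.regionprops(labels):
        if props.area < min_region_area:
            continue
        boundary = _ordered_boundary(labels == props.label)
        boundary = boundary + np.asarray(offset, dtype=float)
        regions.append(
            SegmentedRegion(
                label=props.label,
                pixel_count=int(props.area),
                centroid=(
                    props.centroid[0] + offset[0],
                    props.centroid[1] + offset[1],
                ),
                boundary=boundary,
            )
        )
    regions.sort(key=lambda r: (-r.pixel_count, r.label))
    return regions


def _tag_roles(
    regions: list[SegmentedRegion], config: SegmentationConfig
) -> SegmentationResult | NoEndoleakCandidate:
    if not regions:
        return NoEndoleakCandidate(branches=[])
    if config.n_branches is not None:
        n_branch = min(config.n_branches, len(regions))
    else:
        n_branch = 1
        if (
            len(regions) >= 2
            and regions[1].pixel_count >= config.branch_area_ratio * regions[0].pixel_count
        ):
            n_branch = 2
    branches = [
        SegmentedRegion(**{**asdict_region(r), "role_tag": "sg_branch"})
        for r in regions[:n_branch]
    ]
    rest = regions[n_branch:]
    if not rest:
        return NoEndoleakCandidate(branches=branches)
    if config.endoleak_seed is not None:
        sr, sc = config.endoleak_seed
        chosen = min(
            rest, key=lambda r: (r.centroid[0] - sr) ** 2 + (r.centroid[1] - sc) ** 2
        )
    else:
        chosen = rest[0]  # largest remaining
    endoleak = SegmentedRegion(**{**asdict_region(chosen), "role_tag": "endoleak"})
    return SegmentationResult(endoleak=endoleak, branches=branches)


def asdict_region(r: SegmentedRegion) -> dict:
    return {
        "label": r.label,
        "pixel_count": r.pixel_count,
        "centroid": r.centroid,
        "boundary": r.boundary,
        "role_tag": r.role_tag,
    }


def segment_endoleak(
    image: GrayImage, config: SegmentationConfig | None = None
) -> SegmentationResult | NoEndoleakCandidate:
    """Run the full chain and tag roles.

    crop -> mean denoise -> binarize -> Canny -> close -> fill -> regions.
    Returns a :class:`SegmentationResult` or, when no region qualifies as an
    endoleak, a :class:`NoEndoleakCandidate` (a structured outcome, not an
    exception — slices without endoleak are the intended negative case).
    """
    config = config or SegmentationConfig()
    img = crop_roi(image, config.roi) if config.roi is not None else image
    img = denoise_mean(img, config.denoise_window)
    fg = binarize(img, config.threshold_method, config.threshold)
    edges = canny_edges(
        GrayImage(fg.astype(np.float64) * (2**img.bit_depth - 1), img.bit_depth,
                  img.pixel_spacing, img.offset),
        config.canny_sigma,
        config.canny_low_frac,
        config.canny_high_frac,
    )
    closed = morphological_close(edges, config.closing_radius)
    solid = fill_interior(closed)
    regions = extract_regions(solid, config.min_region_area, offset=img.offset)
    return _tag_roles(regions, config)


def midpoint_of_contact(
    endoleak: SegmentedRegion,
    branch_a: SegmentedRegion,
    branch_b: SegmentedRegion,
    contact_tol: float = 3.0,
) -> tuple[float, float]:
    """Leak-site locator for an endoleak spanning both daughter branches.

    Walks the endoleak's ordered boundary, marks points within
    ``contact_tol`` pixels of either branch boundary, and returns the middle
    point of the contact arc.  Preferred arc: a contiguous circular run of
    contact points touching both branches; failing that, the midpoint of the
    shortest boundary arc between a contact with branch A and one with
    branch B.

    Raises
    ------
    ValueError
        If the endoleak boundary contacts fewer than two branches — use the
        centroid rule instead.
    """
    eb = endoleak.boundary
    if len(eb) == 0:
        raise ValueError("endoleak region has an empty boundary")

    def near(other: SegmentedRegion) -> np.ndarray:
        ob = other.boundary
        if len(ob) == 0:
            return np.zeros(len(eb), dtype=bool)
        d2 = ((eb[:, None, :] - ob[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        return d2 <= contact_tol**2

    near_a = near(branch_a)
    near_b = near(branch_b)
    if not near_a.any() or not near_b.any():
        missing = [] if near_a.any() else ["first"]
        if not near_b.any():
            missing.append("second")
        raise ValueError(
            f"endoleak boundary has no contact with the {' and '.join(missing)} "
            "branch within tolerance; use the centroid rule"
        )

    contact = near_a | near_b
    n = len(eb)
    runs = _circular_runs(contact)
    both = [r for r in runs if near_a[r].any() and near_b[r].any()]
    if both:
        run = max(both, key=len)
        mid = run[len(run) // 2]
        return tuple(eb[mid])
    # no single run touches both: take the shortest circular arc from an
    # A-contact to a B-contact and return its middle point
    ia = np.nonzero(near_a)[0]
    ib = np.nonzero(near_b)[0]
    diff = (ia[:, None] - ib[None, :]) % n
    arc = np.minimum(diff, n - diff)
    k = np.unravel_index(np.argmin(arc), arc.shape)
    a_idx, b_idx = ia[k[0]], ib[k[1]]
    fwd = (b_idx - a_idx) % n
    if fwd <= n - fwd:
        mid = (a_idx + fwd // 2) % n
    else:
        back = n - fwd
        mid = (b_idx + back // 2) % n
    return tuple(eb[mid])


def _circular_runs(flags: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of True in a circular boolean array, as index arrays in
    boundary order."""
    n = len(flags)
    if flags.all():
        return [np.arange(n)]
    if not flags.any():
        return []
    # rotate so position 0 is False, then split linear runs
    start = int(np.argmin(flags))
    rolled = np.roll(flags, -start)
    runs = []
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            runs.append((np.arange(i, j) + start) % n)
            i = j
        else:
            i += 1
    return runs


def read_image(path: str, pixel_spacing: float = 1.0) -> GrayImage:
    """Read an 8/16-bit grayscale TIFF/PNG, or a DICOM file (``.dcm``) with
    rescale slope/intercept applied and intensities shifted to a
    non-negative range."""
    if str(path).lower().endswith(".dcm"):
        import pydicom

        ds = pydicom.dcmread(path)
        px = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        px = px * slope + intercept
        px = px - px.min()  # CT values can be negative (HU); shift to >= 0
        spacing = pixel_spacing
        if getattr(ds, "PixelSpacing", None):
            spacing = float(ds.PixelSpacing[0])
        depth = 16 if px.max() > 255 else 8
        return GrayImage(px, bit_depth=depth, pixel_spacing=spacing)
    import imageio.v3 as iio

    px = iio.imread(path)
    if px.ndim == 3:
        px = px[..., 0]
    depth = 16 if px.dtype.itemsize > 1 else 8
    return GrayImage(px.astype(np.float64), bit_depth=depth, pixel_spacing=pixel_spacing)
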