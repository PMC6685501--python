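"""Brightfield sperm-head morphometry.

Segments the head from a contrast-enhanced brightfield image and measures
the morphological parameters used for DFI prediction: head area ``A``,
perimeter ``P``, width ``HW`` and length ``L``, midpiece width ``MW``,
acrosome area ``AA`` (the anterior region where the axial gray profile
sharply increases), acrosomal vacuole area ``VA``, and head circularity
``C = 4 pi A / P^2``.

Conventions: rasters are row-major with 0-based pixel-center coordinates;
the head's principal axis is oriented from the posterior (midpiece) end to
the anterior tip; every reported length/area is converted to micrometres
before leaving the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu

from .errors import DomainError, MeasurementError, NoCellFound

logger = logging.getLogger(__name__)

#: Default brightfield opening radius used to detach the thin midpiece/tail
#: from the head during segmentation.  Chosen between the midpiece
#: half-width (~0.66 um) and the head half-width (~1.7 um).
DEFAULT_OPENING_RADIUS_UM = 0.9


@dataclass
class CellImageSet:
    """Registered brightfield + green + red rasters for one field of view."""

    brightfield: np.ndarray
    green: np.ndarray
    red: np.ndarray
    pixel_size_um: float
    cell_id: str | None = None
    donor: int | None = None

    def __post_init__(self) -> None:
        shapes = {self.brightfield.shape, self.green.shape, self.red.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class HeadMask:
    """Segmented head: boolean raster, centroid and oriented principal axis.

    ``axis`` is a unit vector in (row, col) coordinates pointing from the
    posterior (midpiece) end toward the anterior tip.
    """

    mask: np.ndarray
    centroid: tuple[float, float]
    axis: tuple[float, float]

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def projections(self) -> tuple[np.ndarray, np.ndarray]:
        """(along-axis, perpendicular) pixel-center projections, in pixels."""
        coords = np.argwhere(self.mask).astype(float)
        rel = coords - np.asarray(self.centroid)
        v = np.asarray(self.axis)
        perp = np.array([-v[1], v[0]])
        return rel @ v, rel @ perp


class HeadDimensions(NamedTuple):
    A: float
    P: float
    HW: float
    L: float


@dataclass
class AxialProfile:
    """Mean gray value in 1-pixel slabs along the major axis, tail to tip."""

    positions_um: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AcrosomeMeasurement:
    aa_um2: float
    detected: bool
    boundary_um: float | None
    region: np.ndarray | None  # boolean raster of the acrosomal head region


@dataclass
class VacuoleMeasurement:
    va_um2: float
    count: int


@dataclass
class MidpieceMeasurement:
    mw_um: float
    found: bool


@dataclass
class MorphometryResult:
    """The six model features plus raw head area/perimeter and flags."""

    A: float
    P: float
    HW: float
    L: float
    MW: float
    AA: float
    VA: float
    C: float
    no_acrosome_detected: bool = False
    no_midpiece_found: bool = False


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def as_float_image(img: np.ndarray) -> np.ndarray:
    """Normalize an image to float gray in [0, 1] (integer dtypes by full range)."""
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(float) / float(np.iinfo(img.dtype).max)
    return img.astype(float)


def contrast_stretch(img: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    """Linear percentile stretch (the brightfield contrast adjustment)."""
    lo, hi = np.percentile(img, [p_lo, p_hi])
    if hi <= lo:
        return img.copy()
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def _binary_open_edt(fg: np.ndarray, radius_px: float) -> np.ndarray:
    """Morphological opening with a disk, via two distance transforms."""
    if radius_px <= 0:
        return fg.copy()
    core = ndimage.distance_transform_edt(fg) > radius_px
    if not core.any():
        return core
    return ndimage.distance_transform_edt(~core) <= radius_px


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def segment_head(brightfield: np.ndarray, pixel_size_um: float,
                 opening_radius_um: float = DEFAULT_OPENING_RADIUS_UM,
                 contrast_enhance: bool = False,
                 min_area_um2: float = 1.0) -> HeadMask:
    """Segment the sperm head from a brightfield raster.

    The image is thresholded (Otsu) and holes are filled.  A morphological
    opening at ``opening_radius_um`` (adapted down for small heads)
    suppresses thin structures — midpiece, tail, noise specks — so the
    largest opened component reliably marks the head; the returned mask is
    the original un-opened component containing that marker, which keeps
    the fine boundary structure that the perimeter (hence circularity)
    measurement depends on.  If two or more markers exceed
    ``min_area_um2`` a warning is logged and the largest is kept.  The
    principal axis comes from the mask's second moments and is oriented
    away from residual foreground (the midpiece).

    A midpiece imaged in full contact with the head at full contrast ends
    up inside the returned component and extends the mask posteriorly; in
    practice the low-contrast neck separates the two in the thresholded
    foreground.
    """
    img = np.asarray(brightfield)
    if img.size == 0:
        raise NoCellFound("empty raster")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    g = as_float_image(img)
    if contrast_enhance:
        g = contrast_stretch(g)
    if g.max() - g.min() < 0.05:
        raise NoCellFound("no contrast in brightfield image")
    fg = g > threshold_otsu(g)
    fg = ndimage.binary_fill_holes(fg)

    # the opening radius adapts down for small heads so the low-curvature
    # tips of elongated heads are not clipped (the half-width of the widest
    # structure, i.e. the head, is the max of the distance transform)
    edt = ndimage.distance_transform_edt(fg)
    radius_px = min(opening_radius_um / pixel_size_um, 0.5 * float(edt.max()))
    opened = _binary_open_edt(fg, radius_px)
    if not opened.any():
        raise NoCellFound("no foreground after opening")
    marker_labels, _ = ndimage.label(opened)
    marker_areas = np.bincount(marker_labels.ravel())[1:]
    min_px = min_area_um2 / pixel_size_um ** 2
    qualifying = np.flatnonzero(marker_areas >= min_px)
    if qualifying.size == 0:
        raise NoCellFound(f"no component of area >= {min_area_um2} um^2")
    if qualifying.size > 1:
        logger.warning("segment_head: %d candidate heads; keeping the largest",
                       qualifying.size)
    # rank candidate markers by the area of their full (un-opened)
    # thresholded component and return that component: the head is the
    # largest solid structure even when a wide midpiece erodes well
    fg_labels, _ = ndimage.label(fg)
    fg_areas = np.bincount(fg_labels.ravel())
    best_area, head_label = -1, 0
    for q in qualifying:
        marker = marker_labels == (q + 1)
        parent = int(np.bincount(fg_labels[marker]).argmax())
        if fg_areas[parent] > best_area:
            best_area, head_label = int(fg_areas[parent]), parent
    mask = fg_labels == head_label

    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    # canonical sign before orientation by the midpiece
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v

    # orient: the posterior end is the one with residual foreground (the
    # midpiece/tail removed by the opening) beyond it
    extra = fg & ~mask
    if extra.any():
        ec = np.argwhere(extra).astype(float) - centroid
        proj_mask = (coords - centroid) @ v
        proj_extra = ec @ v
        ahead = int((proj_extra > proj_mask.max()).sum())
        behind = int((proj_extra < proj_mask.min()).sum())
        if ahead > behind:
            v = -v
    return HeadMask(mask=mask, centroid=(float(centroid[0]), float(centroid[1])),
                    axis=(float(v[0]), float(v[1])))


def measure_head(head: HeadMask, pixel_size_um: float) -> HeadDimensions:
    """Head area, perimeter, width and length in micrometre units.

    ``A`` is the pixel count times the pixel area.  ``P`` is a sub-pixel
    estimate: the mask is smoothed with a small Gaussian and the length of
    the 0.5-level marching-squares contour is measured (naive
    boundary-pixel counting biases circularity low by up to ~20%).
    ``L``/``HW`` are the full extents of the mask along/perpendicular to
    the principal axis, plus one pixel for the pixel footprint.
    """
    if head.n_pixels <= 1:
        raise MeasurementError("degenerate (<= 1 pixel) head mask")
    px = pixel_size_um
    A = head.n_pixels * px ** 2

    # smoothing scale adapts to the mask size: heavy enough to suppress the
    # staircase bias, light enough not to shrink small high-curvature shapes
    r_eq = np.sqrt(head.n_pixels / np.pi)
    sigma = float(np.clip(0.12 * r_eq, 0.8, 1.5))
    sm = ndimage.gaussian_filter(head.mask.astype(float), sigma=sigma)
    contours = skmeasure.find_contours(sm, 0.5)
    if not contours:
        raise MeasurementError("no contour found for head mask")
    contour = max(contours, key=len)
    P = float(np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1))) * px

    along, perp = head.projections()
    L = (along.max() - along.min() + 1.0) * px
    HW = (perp.max() - perp.min() + 1.0) * px
    return HeadDimensions(A=float(A), P=P, HW=float(HW), L=float(L))


def circularity(A: float, P: float) -> float:
    """Head circularity ``C = 4 pi A / P^2`` (1 for a perfect circle)."""
    if A <= 0 or P <= 0:
        raise DomainError(f"area and perimeter must be positive, got A={A}, P={P}")
    return 4.0 * np.pi * A / P ** 2


def axial_gray_profile(brightfield: np.ndarray, head: HeadMask) -> AxialProfile:
    """Mean gray of head pixels in 1-pixel slabs perpendicular to the axis.

    Slabs are ordered from the posterior (tail) end to the anterior tip.
    Positions are slab centers in pixels from the posterior end; callers
    multiply by the pixel size for micrometre units (the profile is used
    relative to the mask, so pixel units are kept here).
    """
    g = as_float_image(brightfield)
    along, _ = head.projections()
    rel = along - along.min()
    idx = np.floor(rel).astype(int)
    n_slabs = idx.max() + 1
    vals = g[head.mask]
    sums = np.bincount(idx, weights=vals, minlength=n_slabs)
    counts = np.bincount(idx, minlength=n_slabs)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    positions = np.arange(n_slabs) + 0.5
    keep = counts > 0
    return AxialProfile(positions_um=positions[keep], values=means[keep])


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v.copy()
    half = window // 2
    padded = np.pad(v, half, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def measure_acrosome(profile: AxialProfile, head: HeadMask,
                     brightfield: np.ndarray, pixel_size_um: float,
                     k: float = 3.0, window: int = 3,
                     min_step: float = 0.02) -> AcrosomeMeasurement:
    """Acrosome area from the sharp rise of the axial gray profile.

    The boundary is the position of the maximum of the smoothed profile's
    first derivative; the step is accepted when its height exceeds both
    ``k`` times the profile's noise standard deviation (estimated from the
    median absolute successive difference) and ``min_step`` normalized
    gray units (partial boundary pixels give the tip slabs a small real
    gradient that is not an acrosome).  ``AA`` is the head area anterior
    to the boundary.  When no step is accepted the area is zero and the
    result is flagged ``detected=False``.
    """
    v = np.asarray(profile.values, dtype=float)
    trim = 3  # end slabs mix in partial boundary pixels; keep them out
    if len(v) < 2 * trim + 4:
        return AcrosomeMeasurement(0.0, False, None, None)
    sm = _moving_average(v, window)
    d = np.diff(sm)
    window_idx = np.arange(trim, len(d) - trim)
    i = int(window_idx[np.argmax(d[window_idx])])
    after = sm[i + 1: i + 1 + window]
    before = sm[max(0, i - window + 1): i + 1]
    step = float(after.mean() - before.mean())

    diffs = np.diff(v)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    if step <= max(k * sigma, min_step):
        return AcrosomeMeasurement(0.0, False, None, None)

    # slab j covers along-axis interval [j, j+1); the step sits between
    # slabs i and i+1, i.e. at relative position i+1 (pixels)
    boundary_rel = float(i + 1)
    along, _ = head.projections()
    rel = along - along.min()
    anterior = rel >= boundary_rel
    aa = float(anterior.sum()) * pixel_size_um ** 2
    region = np.zeros_like(head.mask)
    coords = np.argwhere(head.mask)
    region[tuple(coords[anterior].T)] = True
    return AcrosomeMeasurement(aa_um2=aa, detected=True,
                               boundary_um=boundary_rel * pixel_size_um,
                               region=region)


def measure_vacuoles(brightfield: np.ndarray, head: HeadMask,
                     acrosome_region: np.ndarray | None,
                     pixel_size_um: float,
                     contrast_threshold: float = 0.06,
                     min_area_um2: float = 0.05) -> VacuoleMeasurement:
    """Total vacuole area inside the acrosomal region.

    Vacuoles are connected regions whose gray deviates from the region's
    median by more than ``contrast_threshold`` (normalized gray units) and
    whose area is at least ``min_area_um2``.  The region is eroded by two
    pixels first so that partial-coverage pixels on the head's outer
    boundary are not mistaken for vacuole contrast.
    """
    if acrosome_region is None or not np.asarray(acrosome_region).any():
        return VacuoleMeasurement(0.0, 0)
    region = ndimage.binary_erosion(np.asarray(acrosome_region, dtype=bool),
                                    iterations=2)
    if not region.any():
        return VacuoleMeasurement(0.0, 0)
    g = as_float_image(brightfield)
    level = float(np.median(g[region]))
    candidate = region & (np.abs(g - level) > contrast_threshold)
    labels, n = ndimage.label(candidate)
    if n == 0:
        return VacuoleMeasurement(0.0, 0)
    areas_px = np.bincount(labels.ravel())[1:]
    min_px = min_area_um2 / pixel_size_um ** 2
    keep = areas_px >= min_px
    total = float(areas_px[keep].sum()) * pixel_size_um ** 2
    return VacuoleMeasurement(va_um2=total, count=int(keep.sum()))


def measure_midpiece(brightfield: np.ndarray, head: HeadMask,
                     pixel_size_um: float, band_um: float = 1.0,
                     gap_tolerance_um: float = 0.3,
                     contrast_enhance: bool = False) -> MidpieceMeasurement:
    """Median midpiece width over the first micrometre behind the head.

    The midpiece is foreground (Otsu threshold) outside the head mask and
    within ``gap_tolerance_um`` of it (the low-contrast neck may leave a
    small gap in the thresholded foreground); its width is the foreground
    count in 1-pixel slabs along the head axis, and the reported ``MW`` is
    the median width over the band.  If no adjoining structure exists the
    result is flagged.
    """
    g = as_float_image(brightfield)
    if contrast_enhance:
        g = contrast_stretch(g)
    if g.max() - g.min() < 0.05:
        return MidpieceMeasurement(np.nan, False)
    fg = ndimage.binary_fill_holes(g > threshold_otsu(g))
    extra = fg & ~head.mask
    if not extra.any():
        return MidpieceMeasurement(np.nan, False)
    # keep only components within the gap tolerance of the head
    labels, _ = ndimage.label(extra)
    reach = max(1, int(np.ceil(gap_tolerance_um / pixel_size_um)))
    ring = ndimage.binary_dilation(head.mask, iterations=reach) & extra
    touching = np.unique(labels[ring])
    touching = touching[touching > 0]
    if touching.size == 0:
        return MidpieceMeasurement(np.nan, False)
    keep = np.isin(labels, touching)

    v = np.asarray(head.axis)
    centroid = np.asarray(head.centroid)
    along_mask, _ = head.projections()
    posterior_end = along_mask.min()
    coords = np.argwhere(keep).astype(float)
    proj = (coords - centroid) @ v - posterior_end
    band_px = band_um / pixel_size_um
    in_band = (proj >= -band_px) & (proj < 0)
    if in_band.sum() < 3:
        return MidpieceMeasurement(np.nan, False)
    slab = np.floor(proj[in_band] + band_px).astype(int)
    counts = np.bincount(slab)
    widths = counts[counts > 0] * pixel_size_um
    if widths.size < 3:
        return MidpieceMeasurement(np.nan, False)
    return MidpieceMeasurement(float(np.median(widths)), True)


def measure_cell(images: CellImageSet,
                 opening_radius_um: float = DEFAULT_OPENING_RADIUS_UM,
                 contrast_enhance: bool = False) -> MorphometryResult:
    """Run the full morphometry chain on one brightfield image."""
    px = images.pixel_size_um
    head = segment_head(images.brightfield, px,
                        opening_radius_um=opening_radius_um,
                        contrast_enhance=contrast_enhance)
    dims = measure_head(head, px)
    C = circularity(dims.A, dims.P)
    profile = axial_gray_profile(images.brightfield, head)
    acro = measure_acrosome(profile, head, images.brightfield, px)
    vac = measure_vacuoles(images.brightfield, head, acro.region, px)
    mid = measure_midpiece(images.brightfield, head, px)
    return MorphometryResult(
        A=dims.A, P=dims.P, HW=dims.HW, L=dims.L,
        MW=mid.mw_um, AA=acro.aa_um2, VA=vac.va_um2, C=C,
        no_acrosome_detected=not acro.detected,
        no_midpiece_found=not mid.found,
    )
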