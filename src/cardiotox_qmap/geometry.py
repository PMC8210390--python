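"""LV short-axis geometry: wall masks, segments, blood ROI, volumes and function.

Contours are closed polygons in mm in the slice plane.  The myocardial wall
is the annular region between the endocardial and epicardial borders.  For
tissue characterization the wall is trimmed by a fractional offset (15% of
local wall thickness from each border, measured along radial rays from the
wall centroid) to avoid partial-volume contamination, then divided into four
angular segments (anterior, inferior, septal, lateral).  LV volumes use
summation of discs over the short-axis stack; mass assumes a myocardial
density of 1.05 g/ml.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import InputError

__all__ = [
    "PlanarContour",
    "SliceGeometry",
    "PixelGrid",
    "SegmentModel",
    "BloodROI",
    "LVFunctionResult",
    "wall_mask",
    "apply_offset",
    "divide_segments",
    "lv_volumes",
    "lv_function",
    "SEGMENT_NAMES",
]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05

#: Segment order by angular quadrant relative to the septal direction:
#: septal at 0 deg, anterior +90, lateral +180, inferior +270.
SEGMENT_NAMES = ("septal", "anterior", "lateral", "inferior")


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed polygon area (shoelace formula); positive for CCW order."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class PlanarContour:
    """Ordered closed polygon (mm) delineating a border on one slice."""

    vertices: np.ndarray
    slice_index: int = 0
    phase: str = "ED"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InputError("contour needs >=3 (x, y) vertices")
        # drop a duplicated closing vertex
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise InputError("contour needs >=3 distinct vertices")
        if not ShapelyPolygon(v).is_valid:
            raise InputError("contour polygon is self-intersecting or degenerate")
        if shoelace_area(v) < 0:  # normalize to CCW
            v = v[::-1]
        if shoelace_area(v) <= 0:
            raise InputError("contour must enclose positive area")
        self.vertices = v

    @property
    def area(self) -> float:
        return shoelace_area(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid of the enclosed polygon."""
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * np.sum(cross)
        cx = np.sum((x + xn) * cross) / (6 * a)
        cy = np.sum((y + yn) * cross) / (6 * a)
        return np.array([cx, cy])

    def contains(self, points: np.ndarray, radius: float = 0.0) -> np.ndarray:
        return MplPath(self.vertices).contains_points(
            np.atleast_2d(points), radius=radius
        )


@dataclass
class SliceGeometry:
    """Endocardial/epicardial contour pair for one short-axis slice."""

    endo: PlanarContour
    epi: PlanarContour
    thickness: float = 2.0  # mm
    gap: float = 0.0  # mm

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InputError("slice thickness must be positive")
        if self.epi.area <= self.endo.area:
            raise InputError("epicardial area must exceed endocardial area")


@dataclass
class PixelGrid:
    """Raster on which mm-space contours are rasterized.

    ``origin`` is the mm coordinate of pixel (row=0, col=0)'s center; x maps
    to columns and y to rows.
    """

    shape: tuple
    pixel_spacing: float  # mm/pixel
    origin: tuple = (0.0, 0.0)

    def centers(self) -> np.ndarray:
        """(n_pixels, 2) array of pixel-center mm coordinates (x, y)."""
        rows, cols = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        x = self.origin[0] + cols * self.pixel_spacing
        y = self.origin[1] + rows * self.pixel_spacing
        return np.column_stack([x.ravel(), y.ravel()])

    def pixel_area(self) -> float:
        return self.pixel_spacing**2


@dataclass
class SegmentModel:
    """Per-pixel 4-segment labeling of the offset LV wall.

    ``labels`` holds segment names from :data:`SEGMENT_NAMES` or ``"none"``
    outside the retained wall.
    """

    labels: np.ndarray
    offset_fraction: float = 0.15

    def segment_mask(self, name: str) -> np.ndarray:
        return self.labels == name


@dataclass
class BloodROI:
    """Small round ROI in the LV cavity, away from papillary muscle."""

    region: np.ndarray
    area: float

    @classmethod
    def validate(
        cls,
        region: np.ndarray,
        grid: PixelGrid,
        endo: PlanarContour,
        papillary_mask: np.ndarray | None = None,
    ) -> "BloodROI":
        region = np.asarray(region, dtype=bool)
        area = float(region.sum() * grid.pixel_area())
        if area >= 5.0:
            raise InputError(f"blood ROI area {area:.2f} mm^2 must be < 5 mm^2")
        centers = grid.centers()[region.ravel()]
        if centers.size and not endo.contains(centers).all():
            raise InputError("blood ROI crosses the endocardial border")
        if papillary_mask is not None and np.any(region & papillary_mask):
            raise InputError("blood ROI overlaps the papillary-muscle exclusion mask")
        return cls(region=region, area=area)


@dataclass
class LVFunctionResult:
    LVEDV: float  # ml
    LVESV: float  # ml
    LVSV: float  # ml
    LVEF: float  # %
    CO: float  # l/min
    LVmass: float  # g
    HR: float  # beats/min


def wall_mask(geometry: SliceGeometry, grid: PixelGrid) -> np.ndarray:
    """Rasterize the annular myocardial wall: inside epi, outside endo.

    Membership is decided at pixel centers.  A degenerate geometry whose
    borders coincide yields an empty mask with a warning.
    """
    centers = grid.centers()
    inside_epi = geometry.epi.contains(centers)
    inside_endo = geometry.endo.contains(centers)
    mask = (inside_epi & ~inside_endo).reshape(grid.shape)
    if not mask.any():
        warnings.warn("wall mask is empty (degenerate contours?)", stacklevel=2)
    return mask


def _ray_radii(contour: PlanarContour, center: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Distance from ``center`` to the contour along each ray angle.

    Assumes the contour is star-shaped about ``center`` (true for LV
    short-axis borders); takes the largest positive intersection.
    """
    v = contour.vertices - center
    p0 = v
    p1 = np.roll(v, -1, axis=0)
    d = p1 - p0  # edge direction, (m, 2)
    radii = np.empty(angles.size)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    for i, u in enumerate(dirs):
        # solve p0 + s*d = t*u for each edge; keep s in [0,1], t > 0
        denom = d[:, 0] * (-u[1]) - d[:, 1] * (-u[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (-(p0[:, 0]) * (-u[1]) + p0[:, 1] * (-u[0])) / denom
            t = (d[:, 0] * p0[:, 1] - d[:, 1] * p0[:, 0]) / denom
        ok = np.isfinite(t) & (s >= -1e-12) & (s <= 1 + 1e-12) & (t > 0)
        if not ok.any():
            raise InputError("contour is not star-shaped about the wall centroid")
        radii[i] = t[ok].max()
    return radii


def apply_offset(
    geometry: SliceGeometry, offset_fraction: float = 0.15, n_rays: int = 720
) -> SliceGeometry:
    """Trim both wall borders toward mid-wall by a fraction of local thickness.

    Along each radial ray from the wall centroid, the endocardial border
    moves outward and the epicardial border inward by ``offset_fraction`` of
    the local wall thickness, so the retained wall has thickness
    ``1 - 2*offset_fraction`` of the original along every ray.
    """
    if not 0 <= offset_fraction < 0.5:
        raise InputError("offset_fraction must be in [0, 0.5)")
    if offset_fraction == 0:
        return geometry
    center = geometry.epi.centroid
    angles = np.linspace(0, 2 * np.pi, n_rays, endpoint=False)
    r_endo = _ray_radii(geometry.endo, center, angles)
    r_epi = _ray_radii(geometry.epi, center, angles)
    wall = r_epi - r_endo
    if np.any(wall <= 0):
        raise InputError("endocardial border is not inside the epicardial border")
    new_endo = r_endo + offset_fraction * wall
    new_epi = r_epi - offset_fraction * wall
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    endo = PlanarContour(
        center + new_endo[:, None] * dirs,
        slice_index=geometry.endo.slice_index,
        phase=geometry.endo.phase,
    )
    epi = PlanarContour(
        center + new_epi[:, None] * dirs,
        slice_index=geometry.epi.slice_index,
        phase=geometry.epi.phase,
    )
    return SliceGeometry(endo=endo, epi=epi, thickness=geometry.thickness, gap=geometry.gap)


def divide_segments(
    wall: np.ndarray,
    centroid_mm: np.ndarray,
    septal_direction_deg: float,
    grid: PixelGrid,
    offset_fraction: float = 0.15,
) -> SegmentModel:
    """Assign wall pixels to four 90-degree quadrants.

    Quadrants are centered on the septal direction and its rotations:
    septal at ``septal_direction_deg``, anterior at +90, lateral at +180,
    inferior at +270 (angles measured CCW from +x in mm space).
    """
    wall = np.asarray(wall, dtype=bool)
    if not wall.any():
        raise InputError("wall mask is empty")
    centers = grid.centers().reshape(grid.shape + (2,))
    rel = centers - np.asarray(centroid_mm, dtype=float)
    theta = np.degrees(np.arctan2(rel[..., 1], rel[..., 0]))
    quad = np.floor(((theta - septal_direction_deg + 45.0) % 360.0) / 90.0).astype(int)
    labels = np.full(grid.shape, "none", dtype=object)
    for idx, name in enumerate(SEGMENT_NAMES):
        labels[wall & (quad == idx)] = name
    return SegmentModel(labels=labels, offset_fraction=offset_fraction)


def lv_volumes(slices: list[SliceGeometry]) -> float:
    """Summation-of-discs LV cavity volume in ml.

    Each slice contributes its endocardial area times its effective section
    spacing (thickness + gap); mm^3 are converted to ml.
    """
    if not slices:
        raise InputError("need at least one slice")
    vol_mm3 = sum(s.endo.area * (s.thickness + s.gap) for s in slices)
    return vol_mm3 / 1000.0


def wall_volume(slices: list[SliceGeometry]) -> float:
    """Myocardial wall volume (ml) by summation of annular discs."""
    if not slices:
        raise InputError("need at least one slice")
    vol_mm3 = sum((s.epi.area - s.endo.area) * (s.thickness + s.gap) for s in slices)
    return vol_mm3 / 1000.0


def lv_function(
    EDV: float, ESV: float, HR: float, wall_volume_ml: float = 0.0
) -> LVFunctionResult:
    """Derive stroke volume, ejection fraction, cardiac output and mass.

    ``SV = EDV - ESV``; ``EF = 100*SV/EDV``; ``CO = SV*HR/1000`` (l/min);
    ``mass = wall_volume * 1.05`` (g).
    """
    if EDV <= 0:
        raise InputError("EDV must be positive")
    if ESV < 0 or ESV > EDV:
        raise InputError("ESV must lie in [0, EDV]")
    sv = EDV - ESV
    ef = 100.0 * sv / EDV
    co = sv * HR / 1000.0
    return LVFunctionResult(
        LVEDV=EDV,
        LVESV=ESV,
        LVSV=sv,
        LVEF=ef,
        CO=co,
        LVmass=wall_volume_ml * MYOCARDIAL_DENSITY_G_PER_ML,
        HR=HR,
    )


def select_phases(slices: list[SliceGeometry]) -> tuple[list, list]:
    """Pick ED/ES slice sets when phases are unlabeled.

    ED is the phase with maximal total endocardial area, ES the minimal.
    """
    phases: dict[str, list[SliceGeometry]] = {}
    for s in slices:
        phases.setdefault(s.endo.phase, []).append(s)
    if len(phases) < 2:
        raise InputError("need at least two phases to select ED/ES")
    areas = {p: sum(s.endo.area for s in ss) for p, ss in phases.items()}
    ed = max(areas, key=areas.get)
    es = min(areas, key=areas.get)
    return phases[ed], phases[es]
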