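"""Parametric geometry of the graded micro-ruler scaffold.

The scaffold is a planar array of tall, thin walls extruded in Z.  A *unit
wall* is a 210 µm segment divided by short perpendicular *cross walls* into
seven niche sections (three of 10 µm, two of 30 µm, one of 50 and one of
70 µm).  Four units joined end to end — the last two mirror images of the
first two — give an 840 µm long wall, replicated 16 times in four sets of
four with wall separations of 20, 25, 35 and 55 µm.  The volume between two
adjacent walls is a *chamber*; the pockets bounded by cross walls are
*niches*.  All dimensions are measured from traced-line centers.

This module provides the exact closed forms used throughout the analysis
(chamber footprints, opening sizes, isotropic niche-occupancy ratios,
bounding volume) and a rasterizer that turns the vector model into a pixel
label mask (wall material / niche zone / open space) for image-based
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScaffoldParamError",
    "ScaffoldParams",
    "Wall",
    "CrossWall",
    "Chamber",
    "ScaffoldModel",
    "LabelMask",
    "build_scaffold",
    "chamber_footprint",
    "chamber_opening",
    "isotropic_niche_ratio",
    "scaffold_volume",
    "rasterize",
]

# raster labels
LABEL_BACKGROUND = 0
LABEL_WALL = 1
LABEL_NICHE = 2


class ScaffoldParamError(ValueError):
    """A scaffold parameter set violates one of its invariants."""


@dataclass(frozen=True)
class ScaffoldParams:
    """Design parameters of the scaffold, in µm unless noted.

    ``total_depth`` is the overall Y extent of the wall array.  The in-set
    wall gaps are fixed by ``wall_separations``; any remainder is split
    equally over the gaps between sets.  ``total_depth=None`` means "no
    inter-set spacing" (depth equals the sum of in-set gaps), which is the
    natural choice for reduced test configurations.
    """

    unit_wall_length: float = 210.0
    wall_height: float = 24.0
    niche_sections: tuple[float, ...] = (10.0, 10.0, 10.0, 30.0, 30.0, 50.0, 70.0)
    cross_wall_length: float = 15.0
    cross_wall_half: float = 7.5
    wall_separations: tuple[float, ...] = (20.0, 25.0, 35.0, 55.0)
    walls_per_set: int = 4
    n_sets: int = 4
    units_per_wall: int = 4
    line_thickness: float = 2.0
    z_slice: float = 4.0  # fabrication layer pitch, metadata only
    niche_depth: float = 7.5
    total_depth: float | None = 520.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.niche_sections) - self.unit_wall_length) > 1e-9:
            raise ScaffoldParamError(
                "sum(niche_sections) must equal unit_wall_length: "
                f"{sum(self.niche_sections)} != {self.unit_wall_length}"
            )
        if abs(self.cross_wall_length - 2.0 * self.cross_wall_half) > 1e-9:
            raise ScaffoldParamError(
                "cross_wall_length must equal 2 * cross_wall_half: "
                f"{self.cross_wall_length} != 2*{self.cross_wall_half}"
            )
        if any(s <= 0 for s in self.wall_separations):
            raise ScaffoldParamError("all wall separations must be > 0")
        if any(s <= 0 for s in self.niche_sections):
            raise ScaffoldParamError("all niche sections must be > 0")
        if self.line_thickness < 0:
            raise ScaffoldParamError("line_thickness must be >= 0")
        if self.n_sets < 1 or self.walls_per_set < 2 or self.units_per_wall < 1:
            raise ScaffoldParamError(
                "need n_sets >= 1, walls_per_set >= 2, units_per_wall >= 1"
            )
        if len(self.wall_separations) < self.n_sets:
            raise ScaffoldParamError(
                f"need at least n_sets={self.n_sets} wall separations, "
                f"got {len(self.wall_separations)}"
            )
        if self.niche_depth <= 0 or self.wall_height <= 0:
            raise ScaffoldParamError("niche_depth and wall_height must be > 0")
        if self.total_depth is not None:
            inset = self._in_set_depth()
            if self.n_sets == 1:
                if abs(self.total_depth - inset) > 1e-9:
                    raise ScaffoldParamError(
                        "with a single set, total_depth must equal the in-set "
                        f"gap sum {inset} (or be None); got {self.total_depth}"
                    )
            elif self.total_depth < inset - 1e-9:
                raise ScaffoldParamError(
                    f"total_depth {self.total_depth} smaller than the in-set "
                    f"gap sum {inset}"
                )

    def _in_set_depth(self) -> float:
        return sum(
            (self.walls_per_set - 1) * self.wall_separations[i]
            for i in range(self.n_sets)
        )

    @property
    def wall_length(self) -> float:
        return self.units_per_wall * self.unit_wall_length

    @property
    def depth(self) -> float:
        """Overall Y extent (center-of-line convention)."""
        if self.total_depth is None:
            return self._in_set_depth()
        return self.total_depth

    @property
    def inter_set_gap(self) -> float:
        if self.n_sets == 1:
            return 0.0
        return (self.depth - self._in_set_depth()) / (self.n_sets - 1)

    def section_boundaries(self) -> np.ndarray:
        """Cross-wall X positions along a full wall (unit 3-4 mirrored)."""
        unit = np.concatenate([[0.0], np.cumsum(self.niche_sections)])
        mirrored = self.unit_wall_length - unit[::-1]
        bounds = [0.0]
        for u in range(self.units_per_wall):
            pattern = unit if u < (self.units_per_wall + 1) // 2 else mirrored
            offset = u * self.unit_wall_length
            bounds.extend((offset + pattern[1:]).tolist())
        return np.unique(np.round(np.asarray(bounds), 9))


@dataclass(frozen=True)
class Wall:
    """A long wall: a thick segment along X at fixed Y (centerline)."""

    y: float
    x0: float
    x1: float
    thickness: float
    set_index: int


@dataclass(frozen=True)
class CrossWall:
    """A short wall along Y at fixed X, spanning ±cross_wall_half around a wall."""

    x: float
    y0: float
    y1: float
    thickness: float


@dataclass(frozen=True)
class Chamber:
    """One compartment between two adjacent walls, one niche section wide.

    The rectangle (x0, x1) x (y0, y1) is bounded by wall centerlines; the
    design footprint is niche_size * wall_separation.
    """

    id: int
    niche_size: float
    wall_separation: float
    x0: float
    x1: float
    y0: float
    y1: float
    opening_size: float
    line_thickness: float = 2.0

    @property
    def footprint_area(self) -> float:
        return self.niche_size * self.wall_separation

    @property
    def effective_niche_size(self) -> float:
        """Niche size reduced by the traced-line thickness."""
        return max(0.0, self.niche_size - self.line_thickness)

    @property
    def effective_separation(self) -> float:
        return max(0.0, self.wall_separation - self.line_thickness)

    @property
    def polygon(self) -> list[tuple[float, float]]:
        return [
            (self.x0, self.y0),
            (self.x1, self.y0),
            (self.x1, self.y1),
            (self.x0, self.y1),
        ]

    def niche_zone_rects(self, niche_depth: float) -> list[tuple[float, float, float, float]]:
        """Axis-aligned (x0, x1, y0, y1) strips within niche_depth of a bounding wall."""
        d = min(niche_depth, (self.y1 - self.y0) / 2.0)
        return [
            (self.x0, self.x1, self.y0, self.y0 + d),
            (self.x0, self.x1, self.y1 - d, self.y1),
        ]

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class ScaffoldModel:
    """Vector geometry of the full scaffold."""

    params: ScaffoldParams
    walls: list[Wall]
    cross_walls: list[CrossWall]
    chambers: list[Chamber]

    @property
    def bounding_box(self) -> tuple[float, float, float]:
        p = self.params
        return (p.wall_length, p.depth, p.wall_height)

    def set_y_ranges(self) -> list[tuple[float, float, float]]:
        """Per wall set: (wall_separation, y_first, y_last)."""
        out = []
        for i in range(self.params.n_sets):
            ws = [w for w in self.walls if w.set_index == i]
            out.append((self.params.wall_separations[i], ws[0].y, ws[-1].y))
        return out


def chamber_footprint(niche_size: float, wall_separation: float) -> float:
    """Design footprint of a chamber, µm² (center-of-line, no thickness correction)."""
    if niche_size <= 0 or wall_separation <= 0:
        raise ValueError("niche_size and wall_separation must be > 0")
    return niche_size * wall_separation


def chamber_opening(wall_separation: float, cross_wall_length: float = 15.0) -> float:
    """Gap between opposing cross-wall tips at a chamber end, µm (floored at 0)."""
    if wall_separation <= 0:
        raise ValueError("wall_separation must be > 0")
    if cross_wall_length < 0:
        raise ValueError("cross_wall_length must be >= 0")
    return max(0.0, wall_separation - cross_wall_length)


def isotropic_niche_ratio(wall_separation: float, niche_depth: float = 7.5) -> float:
    """Expected niche-zone fraction for spatially uniform material.

    Under a uniform distribution between two walls a distance ``wall_separation``
    apart, the fraction lying within ``niche_depth`` of either wall is
    ``2 * niche_depth / wall_separation``, capped at 1 when the two bands cover
    the whole gap.
    """
    if wall_separation <= 0 or niche_depth <= 0:
        raise ValueError("wall_separation and niche_depth must be > 0")
    return min(1.0, 2.0 * niche_depth / wall_separation)


def scaffold_volume(model: ScaffoldModel) -> float:
    """Bounding volume width x depth x height, µm³."""
    w, d, h = model.bounding_box
    return w * d * h


def build_scaffold(params: ScaffoldParams | None = None) -> ScaffoldModel:
    """Assemble the vector model: walls, cross walls and enumerated chambers.

    Chambers are enumerated per inter-wall gap over the seven niche sections of
    the canonical unit wall (unit 1); the remaining units along a wall repeat or
    mirror the same (niche size, separation) classes.
    """
    p = params if params is not None else ScaffoldParams()
    p.validate()

    walls: list[Wall] = []
    y = 0.0
    for s in range(p.n_sets):
        sep = p.wall_separations[s]
        for w in range(p.walls_per_set):
            walls.append(Wall(y=y, x0=0.0, x1=p.wall_length, thickness=p.line_thickness, set_index=s))
            if w < p.walls_per_set - 1:
                y += sep
        if s < p.n_sets - 1:
            y += p.inter_set_gap

    bounds = ScaffoldParams.section_boundaries(p)
    cross_walls = [
        CrossWall(x=float(x), y0=w.y - p.cross_wall_half, y1=w.y + p.cross_wall_half,
                  thickness=p.line_thickness)
        for w in walls
        for x in bounds
    ]

    unit = np.concatenate([[0.0], np.cumsum(p.niche_sections)])
    chambers: list[Chamber] = []
    cid = 0
    for s in range(p.n_sets):
        sep = p.wall_separations[s]
        set_walls = [w for w in walls if w.set_index == s]
        for w0, w1 in zip(set_walls[:-1], set_walls[1:]):
            for k, niche in enumerate(p.niche_sections):
                chambers.append(
                    Chamber(
                        id=cid,
                        niche_size=float(niche),
                        wall_separation=float(sep),
                        x0=float(unit[k]),
                        x1=float(unit[k + 1]),
                        y0=w0.y,
                        y1=w1.y,
                        opening_size=chamber_opening(sep, p.cross_wall_length),
                        line_thickness=p.line_thickness,
                    )
                )
                cid += 1

    return ScaffoldModel(params=p, walls=walls, cross_walls=cross_walls, chambers=chambers)


@dataclass
class LabelMask:
    """Pixel raster of the scaffold plane.

    ``grid`` holds integer labels (0 background / chamber interior, 1 wall
    material, 2 niche zone); ``wall_coverage`` holds the exact area fraction of
    each pixel covered by wall material (axis-aligned overlap, so
    ``wall_coverage.sum() * pixel_size**2`` equals the true material footprint
    to machine precision).  Pixel (0, 0) is top-left with its center at
    ``0.5 * pixel_size``.
    """

    grid: np.ndarray
    pixel_size: float
    wall_coverage: np.ndarray
    niche_depth: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # (ny, nx)

    def wall_area(self) -> float:
        """Exact rasterized material footprint in µm²."""
        return float(self.wall_coverage.sum()) * self.pixel_size**2

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.grid.shape
        yc = (np.arange(ny) + 0.5) * self.pixel_size
        xc = (np.arange(nx) + 0.5) * self.pixel_size
        return yc, xc


def _band_overlap(edges: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-pixel-interval overlap fraction with the band [lo, hi]."""
    left = np.maximum(edges[:-1], lo)
    right = np.minimum(edges[1:], hi)
    return np.clip(right - left, 0.0, None) / (edges[1] - edges[0])


def rasterize(
    model: ScaffoldModel,
    pixel_size: float,
    fov: tuple[float, float] | None = None,
) -> LabelMask:
    """Rasterize the model to a label mask.

    ``fov`` is the imaged (width, height) in µm; default is the model bounding
    box.  Wall material is labelled where the exact pixel coverage is >= 0.5;
    niche zones are pixels whose center lies within ``niche_depth`` of a long
    wall centerline (along the wall span) and that are not material.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    p = model.params
    if pixel_size > p.line_thickness > 0:
        warnings.warn(
            f"pixel_size {pixel_size} exceeds line thickness {p.line_thickness}; "
            "walls may vanish from the raster",
            stacklevel=2,
        )
    width, height = fov if fov is not None else (p.wall_length, p.depth)
    nx = max(1, int(round(width / pixel_size)))
    ny = max(1, int(round(height / pixel_size)))
    xe = np.arange(nx + 1) * pixel_size
    ye = np.arange(ny + 1) * pixel_size

    coverage = np.zeros((ny, nx), dtype=np.float64)
    half_t = p.line_thickness / 2.0
    for w in model.walls:
        oy = _band_overlap(ye, w.y - half_t, w.y + half_t)
        if not oy.any():
            continue
        ox = _band_overlap(xe, w.x0, w.x1)
        coverage += oy[:, None] * ox[None, :]
    for cw in model.cross_walls:
        ox = _band_overlap(xe, cw.x - half_t, cw.x + half_t)
        if not ox.any():
            continue
        oy = _band_overlap(ye, cw.y0, cw.y1)
        coverage += oy[:, None] * ox[None, :]
    np.clip(coverage, 0.0, 1.0, out=coverage)

    yc = (np.arange(ny) + 0.5) * pixel_size
    xc = (np.arange(nx) + 0.5) * pixel_size
    niche = np.zeros((ny, nx), dtype=bool)
    for w in model.walls:
        rows = np.abs(yc - w.y) <= p.niche_depth
        if not rows.any():
            continue
        cols = (xc >= w.x0) & (xc < w.x1)
        niche[np.ix_(rows, cols)] = True

    grid = np.zeros((ny, nx), dtype=np.int8)
    material = coverage >= 0.5
    grid[niche] = LABEL_NICHE
    grid[material] = LABEL_WALL
    return LabelMask(
        grid=grid,
        pixel_size=pixel_size,
        wall_coverage=coverage.astype(np.float32),
        niche_depth=p.niche_depth,
    )
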