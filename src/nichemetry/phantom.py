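"""Synthetic hyperspectral confocal phantom with known ground truth.

Renders the scaffold plus stained A549-like cells into lambda-mode Z-stacks
that emulate the study acquisition: 12 slices at 2 µm step over the 24 µm
scaffold height, 1.66 µm/pixel over a 630 x 520 µm field of view, 32 (or 23)
emission channels.  Cells are spheres (15 µm default) with concentric
nuclei (8 µm); walls are extruded from the rasterized geometry and their
autofluorescence brightness follows the UV-quench model.  Per-voxel expected
photon counts get Poisson shot noise plus Gaussian read noise.

Every output is reproducible from a single numpy Generator; ground-truth cell
positions, per-voxel abundances and motion tracks are returned alongside the
rendered data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import LabelMask, ScaffoldModel, rasterize
from .spectra import (
    DEFAULT_QUENCH_K,
    LAMBDA_405,
    EndmemberSpectrum,
    QuenchModel,
    SpectralConfig,
    quench_intensity,
)

__all__ = [
    "ImagingConfig",
    "SyntheticCell",
    "HyperspectralStack",
    "MotionSpec",
    "PlacementError",
    "place_cells",
    "render_stack",
    "render_nuclei_stack",
    "simulate_timelapse",
    "TimelapseResult",
    "DEFAULT_BRIGHTNESS",
]

# Per-voxel photon amplitudes at full occupancy.  The scaffold value is the
# pre-quench autofluorescence; after the default 150 min UV treatment it is
# ~5x the cell stain brightness (the walls remain clearly the brightest
# feature, as in the real acquisitions).
DEFAULT_BRIGHTNESS = {
    "scaffold": 5000.0 / 0.22,
    "nuclei": 1000.0,
    "cytoplasm": 800.0,
    "background": 50.0,
}


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry and noise settings."""

    pixel_size: float = 1.66           # µm/px
    fov: tuple[float, float] = (630.0, 520.0)  # (width, height) µm
    n_slices: int = 12
    z_step: float = 2.0                # µm
    spectral: SpectralConfig = LAMBDA_405
    gaussian_sd: float = 2.0           # read noise, photons
    poisson: bool = True
    clip_max: float | None = None      # optional full-well saturation

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.n_slices < 1 or self.z_step <= 0:
            raise ValueError("pixel_size, n_slices and z_step must be positive")

    @property
    def height(self) -> float:
        return self.n_slices * self.z_step

    @property
    def shape_yx(self) -> tuple[int, int]:
        return (
            max(1, int(round(self.fov[1] / self.pixel_size))),
            max(1, int(round(self.fov[0] / self.pixel_size))),
        )


@dataclass
class SyntheticCell:
    """A spherical cell with a concentric spherical nucleus (µm)."""

    x: float
    y: float
    z: float
    diameter: float = 15.0
    nucleus_diameter: float = 8.0
    contact: bool = False  # ground truth: placed as a wall-contact cell

    def __post_init__(self) -> None:
        if not self.nucleus_diameter < self.diameter:
            raise ValueError("nucleus_diameter must be smaller than diameter")


@dataclass
class HyperspectralStack:
    """A lambda-mode Z-stack: data is (Z, C, Y, X) non-negative intensities."""

    data: np.ndarray
    imaging: ImagingConfig

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (Z, C, Y, X)")
        z, c, _, _ = self.data.shape
        if c != self.imaging.spectral.n_channels:
            raise ValueError(
                f"channel axis {c} does not match spectral config "
                f"({self.imaging.spectral.n_channels} channels)"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("stack intensities must be finite")

    @property
    def excitation_nm(self) -> float:
        return self.imaging.spectral.excitation_nm


class PlacementError(RuntimeError):
    """Could not place the requested number of cells without overlap."""


def _in_material(model: ScaffoldModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized test whether planar points fall on wall material."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    half = model.params.line_thickness / 2.0
    hit = np.zeros(x.shape, dtype=bool)
    for w in model.walls:
        hit |= (np.abs(y - w.y) <= half) & (x >= w.x0) & (x <= w.x1)
    bounds = model.params.section_boundaries()
    # cross walls share x positions across walls; test per wall y-extent
    ch = model.params.cross_wall_half
    ys = np.array([w.y for w in model.walls])
    near_cross_x = np.min(np.abs(x[:, None] - bounds[None, :]), axis=1) <= half
    near_wall_y = np.min(np.abs(y[:, None] - ys[None, :]), axis=1) <= ch
    hit |= near_cross_x & near_wall_y
    return hit


def place_cells(
    model: ScaffoldModel,
    n: int,
    niche_bias: float,
    rng: np.random.Generator | int,
    diameter: float = 15.0,
    nucleus_diameter: float = 8.0,
    min_separation: float = 8.0,
    max_tries: int = 500,
) -> list[SyntheticCell]:
    """Place non-overlapping cells inside the chambers.

    Each cell first draws its chamber with probability proportional to the
    chamber footprint, then is a *contact* cell with probability
    ``niche_bias``: its center is drawn uniformly from that chamber's niche
    zone eroded by the nucleus radius, so the nucleus (the compact marker
    scored by the packing and tracking analyses) lies wholly within the
    7.5 µm contact zone.  Otherwise the center is drawn uniformly over the
    full chamber.  Drawing the chamber first keeps the expected contact
    fraction equal to ``niche_bias`` within every chamber class.  Centers are
    rejected on wall material or within ``min_separation`` (a 3-D distance:
    nuclei at different heights may share a planar position) of an existing
    cell.
    """
    if not 0.0 <= niche_bias <= 1.0:
        raise ValueError("niche_bias must be in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = model.params
    half_t = p.line_thickness / 2.0
    r_nuc = nucleus_diameter / 2.0

    chambers = model.chambers
    interior_w = np.array([c.footprint_area for c in chambers])
    interior_w = interior_w / interior_w.sum()
    band = max(0.0, p.niche_depth - r_nuc - half_t)
    if niche_bias > 0 and band <= 0:
        raise PlacementError(
            "niche zone too shallow to hold a nucleus: "
            f"niche_depth={p.niche_depth}, nucleus radius={r_nuc}"
        )
    zlo = r_nuc
    zhi = max(zlo, p.wall_height - r_nuc)
    cells: list[SyntheticCell] = []
    inner_tries = 50
    for _ in range(n):
        placed = False
        # contact/interior and the chamber are drawn once per cell and kept
        # across position retries, so collisions cannot skew the contact
        # fraction or its distribution over chamber classes; only a chamber
        # whose region is effectively full is redrawn
        contact = rng.random() < niche_bias
        ci = rng.choice(len(chambers), p=interior_w)
        for _try in range(max_tries):
            if _try and _try % inner_tries == 0:
                ci = rng.choice(len(chambers), p=interior_w)
            c = chambers[ci]
            if contact:
                side = rng.random() < 0.5
                u = half_t + rng.random() * band  # distance from wall centerline
                y = c.y0 + u if side else c.y1 - u
            else:
                y = c.y0 + half_t + rng.random() * max(1e-9, (c.y1 - c.y0) - 2 * half_t)
            x = c.x0 + rng.random() * (c.x1 - c.x0)
            if _in_material(model, x, y)[0]:
                continue
            z = zlo + rng.random() * (zhi - zlo)
            # nuclei must not overlap in 3D (cells deform, nuclei do not)
            if any(
                (x - o.x) ** 2 + (y - o.y) ** 2 + (z - o.z) ** 2 < min_separation**2
                for o in cells
            ):
                continue
            cells.append(
                SyntheticCell(x=float(x), y=float(y), z=float(z),
                              diameter=diameter, nucleus_diameter=nucleus_diameter,
                              contact=contact)
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {len(cells) + 1}/{n} after {max_tries} tries"
            )
    return cells


def _deposit_sphere(
    target: np.ndarray,
    cx: float,
    cy: float,
    cz: float,
    radius: float,
    amplitude: float,
    pixel_size: float,
    z_edges: np.ndarray,
) -> None:
    """Add slab-integrated sphere occupancy x amplitude into (Z, Y, X) target."""
    nz, ny, nx = target.shape
    i0 = max(0, int((cx - radius) / pixel_size) - 1)
    i1 = min(nx, int((cx + radius) / pixel_size) + 2)
    j0 = max(0, int((cy - radius) / pixel_size) - 1)
    j1 = min(ny, int((cy + radius) / pixel_size) + 2)
    if i0 >= i1 or j0 >= j1:
        return
    xc = (np.arange(i0, i1) + 0.5) * pixel_size
    yc = (np.arange(j0, j1) + 0.5) * pixel_size
    rho2 = (xc[None, :] - cx) ** 2 + (yc[:, None] - cy) ** 2
    h = np.sqrt(np.clip(radius**2 - rho2, 0.0, None))  # half chord in z
    z_step = z_edges[1] - z_edges[0]
    lo = cz - h
    hi = cz + h
    overlap = (
        np.minimum(z_edges[1:, None, None], hi[None])
        - np.maximum(z_edges[:-1, None, None], lo[None])
    )
    occ = np.clip(overlap, 0.0, None) / z_step
    target[:, j0:j1, i0:i1] += amplitude * occ


def _expected_abundances(
    model: ScaffoldModel,
    cells: list[SyntheticCell],
    imaging: ImagingConfig,
    quench_time: float,
    brightness: dict[str, float],
    quench: QuenchModel | None,
    mask: LabelMask | None,
) -> tuple[dict[str, np.ndarray], LabelMask]:
    ny, nx = imaging.shape_yx
    nz = imaging.n_slices
    if mask is None:
        mask = rasterize(model, imaging.pixel_size, fov=imaging.fov)
    if mask.shape != (ny, nx):
        raise ValueError("label mask shape does not match imaging config")
    z_edges = np.arange(nz + 1) * imaging.z_step

    if quench is None:
        quench = QuenchModel(I0=brightness["scaffold"], k=DEFAULT_QUENCH_K)
    scaffold_amp = quench_intensity(quench, quench_time)

    ab = {name: np.zeros((nz, ny, nx), dtype=np.float64)
          for name in ("scaffold", "nuclei", "cytoplasm", "background")}
    # walls span the full height of the stack
    wall_height_slices = model.params.wall_height / imaging.z_step
    for k in range(nz):
        frac = np.clip(wall_height_slices - k, 0.0, 1.0)
        if frac > 0:
            ab["scaffold"][k] = scaffold_amp * frac * mask.wall_coverage
    ab["background"][:] = brightness["background"]
    for cell in cells:
        _deposit_sphere(ab["cytoplasm"], cell.x, cell.y, cell.z,
                        cell.diameter / 2.0, brightness["cytoplasm"],
                        imaging.pixel_size, z_edges)
        _deposit_sphere(ab["nuclei"], cell.x, cell.y, cell.z,
                        cell.nucleus_diameter / 2.0, brightness["nuclei"],
                        imaging.pixel_size, z_edges)
    return ab, mask


def _apply_noise(
    expected: np.ndarray, imaging: ImagingConfig, rng: np.random.Generator | None
) -> np.ndarray:
    if rng is None:
        data = expected.copy()
    else:
        data = expected
        if imaging.poisson:
            data = rng.poisson(np.clip(data, 0.0, None)).astype(np.float64)
        if imaging.gaussian_sd > 0:
            data = data + rng.normal(0.0, imaging.gaussian_sd, size=data.shape)
        data = np.clip(data, 0.0, None)
    if imaging.clip_max is not None:
        data = np.minimum(data, imaging.clip_max)
    return data.astype(np.float32)


def render_stack(
    model: ScaffoldModel,
    cells: list[SyntheticCell],
    endmembers: dict[str, EndmemberSpectrum],
    imaging: ImagingConfig,
    quench_time: float = 150.0,
    brightness: dict[str, float] | None = None,
    quench: QuenchModel | None = None,
    rng: np.random.Generator | int | None = None,
    mask: LabelMask | None = None,
) -> tuple[HyperspectralStack, dict[str, np.ndarray]]:
    """Render a lambda-mode stack; returns (stack, ground-truth abundances).

    Per-voxel intensity is the sum over sources of geometric occupancy x
    brightness x endmember spectrum; the scaffold amplitude is attenuated by
    the UV-quench model at ``quench_time`` minutes.  ``rng=None`` disables
    noise (expected counts are returned).
    """
    required = {"scaffold", "nuclei", "cytoplasm", "background"}
    if not required <= set(endmembers):
        raise ValueError(f"endmember set must cover {sorted(required)}")
    for em in endmembers.values():
        if em.config.n_channels != imaging.spectral.n_channels:
            raise ValueError(
                f"endmember {em.name!r} is on a {em.config.n_channels}-channel "
                f"grid; imaging uses {imaging.spectral.n_channels}"
            )
    brightness = dict(DEFAULT_BRIGHTNESS if brightness is None else brightness)
    ab, _ = _expected_abundances(model, cells, imaging, quench_time, brightness,
                                 quench, mask)
    C = imaging.spectral.n_channels
    names = sorted(ab)
    A = np.stack([ab[n] for n in names])  # (E, Z, Y, X)
    S = np.stack([endmembers[n].weights for n in names])  # (E, C)
    expected = np.einsum("ezyx,ec->zcyx", A, S, optimize=True)
    if rng is not None and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    data = _apply_noise(expected, imaging, rng)
    truth = {n: ab[n].astype(np.float32) for n in names}
    return HyperspectralStack(data=data, imaging=imaging), truth


def render_nuclei_stack(
    model: ScaffoldModel,
    cells: list[SyntheticCell],
    imaging: ImagingConfig,
    brightness: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
    mask: LabelMask | None = None,
) -> np.ndarray:
    """Render a single-channel (Z, Y, X) nucleus-stain intensity stack.

    This is the unmixed-nuclei view the tracker consumes: nuclei plus flat
    background, no scaffold signal.
    """
    brightness = dict(DEFAULT_BRIGHTNESS if brightness is None else brightness)
    ab, _ = _expected_abundances(model, cells, imaging, 0.0, brightness, None, mask)
    expected = ab["nuclei"] + brightness["background"]
    return _apply_noise(expected, imaging, rng)


@dataclass(frozen=True)
class MotionSpec:
    """Confined random walk between timepoints.

    ``step_scale`` is the per-interval displacement in µm — a scalar, or a
    mapping from wall separation (and the key ``"control"``) to scale for
    region-dependent motility.  Cells never cross wall material when
    ``wall_blocking`` is on.
    """

    step_scale: float | dict = 5.0
    n_timepoints: int = 6
    interval_min: float = 65.0
    wall_blocking: bool = True
    max_tries: int = 25

    def scale_at(self, model: ScaffoldModel, y: float) -> float:
        if not isinstance(self.step_scale, dict):
            return float(self.step_scale)
        for sep, y0, y1 in model.set_y_ranges():
            if y0 - 1e-9 <= y <= y1 + 1e-9:
                return float(self.step_scale.get(sep, self.step_scale.get("control", 0.0)))
        return float(self.step_scale.get("control", 0.0))


@dataclass
class TimelapseResult:
    stacks: list[np.ndarray]          # per timepoint (Z, Y, X) nuclei intensity
    tracks: pd.DataFrame              # ground truth: cell, t, x_um, y_um, z_um
    cells_per_timepoint: list[list[SyntheticCell]]

    def total_distances(self) -> pd.Series:
        """Ground-truth total path length per cell, µm."""
        def path(g: pd.DataFrame) -> float:
            dx = np.diff(g["x_um"].to_numpy())
            dy = np.diff(g["y_um"].to_numpy())
            return float(np.sqrt(dx**2 + dy**2).sum())
        return self.tracks.sort_values("t").groupby("cell").apply(path, include_groups=False)


def _segment_blocked(model: ScaffoldModel, x0, y0, x1, y1) -> bool:
    """True if the straight step from (x0,y0) to (x1,y1) touches material."""
    length = float(np.hypot(x1 - x0, y1 - y0))
    n = max(2, int(length / 0.5) + 1)
    ts = np.linspace(0.0, 1.0, n)
    xs = x0 + ts * (x1 - x0)
    ys = y0 + ts * (y1 - y0)
    return bool(_in_material(model, xs, ys).any())


def simulate_timelapse(
    model: ScaffoldModel,
    cells: list[SyntheticCell],
    motion: MotionSpec,
    imaging: ImagingConfig,
    rng: np.random.Generator | int,
    render: bool = True,
) -> TimelapseResult:
    """Random-walk the cells over the timepoints and render nuclei stacks.

    Each interval a cell attempts a step of its region's ``step_scale`` in a
    uniformly random direction; steps that would cross wall material or leave
    the scaffold footprint are re-drawn (up to ``max_tries``, then the cell
    stays put — full confinement).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = model.params
    width, depth = p.wall_length, p.depth
    mask = rasterize(model, imaging.pixel_size, fov=imaging.fov) if render else None

    current = [replace(c) for c in cells]
    per_t: list[list[SyntheticCell]] = [[replace(c) for c in current]]
    for _t in range(1, motion.n_timepoints):
        moved: list[SyntheticCell] = []
        for c in current:
            s = motion.scale_at(model, c.y)
            nx_, ny_ = c.x, c.y
            if s > 0:
                for _try in range(motion.max_tries):
                    ang = rng.random() * 2.0 * np.pi
                    px_, py_ = c.x + s * np.cos(ang), c.y + s * np.sin(ang)
                    if not (0.0 <= px_ <= width and 0.0 <= py_ <= depth):
                        continue
                    if motion.wall_blocking and _segment_blocked(model, c.x, c.y, px_, py_):
                        continue
                    nx_, ny_ = px_, py_
                    break
            moved.append(replace(c, x=float(nx_), y=float(ny_)))
        current = moved
        per_t.append([replace(c) for c in current])

    rows = [
        {"cell": i, "t": t, "x_um": c.x, "y_um": c.y, "z_um": c.z}
        for t, snapshot in enumerate(per_t)
        for i, c in enumerate(snapshot)
    ]
    tracks = pd.DataFrame(rows)

    stacks = []
    if render:
        for snapshot in per_t:
            stacks.append(render_nuclei_stack(model, snapshot, imaging, rng=rng, mask=mask))
    return TimelapseResult(stacks=stacks, tracks=tracks, cells_per_timepoint=per_t)
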