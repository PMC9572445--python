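"""Nucleus detection, radius-N greedy linking, and motility gradient maps.

The time-lapse analysis splits each 12-slice stack into a bottom partition
(first 7 slices, 14 µm — one average cell height above the glass) and a top
partition (last 5 slices, 10 µm), projects each partition to a single image,
detects nucleus centroids, and links them across the 6 timepoints with a
single-parameter greedy tracker: a cell's next position is the nearest
unclaimed detection within a radius of N pixels (16.6 µm at N=10 and
1.66 µm/px); if none is found the track ends.  After a first pass seeded
from t=0, a second pass re-seeds from the earliest detections left
unclaimed.  Tracks shorter than five timepoints are discarded.  Each kept
track reports its total path length, which the gradient map renders as a
blue-to-red field clipped at a display maximum (30 µm by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure
from skimage.registration import phase_cross_correlation

from .geometry import LABEL_NICHE, LABEL_WALL, LabelMask, ScaffoldModel

__all__ = [
    "ZPartition",
    "TrackingConfig",
    "Track",
    "GradientMap",
    "z_partition",
    "detect_nuclei",
    "link_tracks",
    "kernel_to_um",
    "render_gradient_map",
    "summarize_motility",
    "estimate_shift",
    "apply_shift",
]


@dataclass
class ZPartition:
    """Bottom/top split of a Z-stack with per-partition 2-D projections."""

    bottom: np.ndarray
    top: np.ndarray
    bottom_slices: int
    top_slices: int


def z_partition(stack: np.ndarray, bottom_slices: int = 7,
                projection: str = "max") -> ZPartition:
    """Split (Z, Y, X) into bottom/top partitions and project each to 2-D.

    Defaults follow the study convention: bottom = first 7 slices (14 µm at a
    2 µm step), top = remaining 5 slices (10 µm); maximum-intensity
    projection (``projection='mean'`` available).
    """
    if stack.ndim != 3:
        raise ValueError("stack must be (Z, Y, X)")
    nz = stack.shape[0]
    if not 0 < bottom_slices < nz:
        raise ValueError(f"bottom_slices must split the {nz}-slice stack")
    op = {"max": np.max, "mean": np.mean}.get(projection)
    if op is None:
        raise ValueError("projection must be 'max' or 'mean'")
    return ZPartition(
        bottom=op(stack[:bottom_slices], axis=0),
        top=op(stack[bottom_slices:], axis=0),
        bottom_slices=bottom_slices,
        top_slices=nz - bottom_slices,
    )


@dataclass(frozen=True)
class TrackingConfig:
    """Tracker parameters.

    ``N`` is the movement kernel radius in pixels: the next position of a
    tracked nucleus must lie within this radius.  With the default
    1.66 µm/px, N=10 corresponds to 16.6 µm, about one cell diameter.
    """

    N: float = 10.0
    pixel_size: float = 1.66
    n_passes: int = 2
    min_track_points: int = 5
    n_timepoints: int = 6

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1 pixel")
        if self.min_track_points > self.n_timepoints:
            raise ValueError("min_track_points cannot exceed n_timepoints")


def kernel_to_um(N: float, pixel_size: float) -> float:
    """Movement kernel radius in µm."""
    if N <= 0 or pixel_size <= 0:
        raise ValueError("N and pixel_size must be > 0")
    return N * pixel_size


@dataclass
class Track:
    """One linked nucleus trajectory over consecutive timepoints."""

    id: int
    positions: list[tuple[int, float, float]]  # (t, x_px, y_px)
    pass_index: int
    pixel_size: float
    partition: str = ""

    @property
    def t0(self) -> int:
        return self.positions[0][0]

    @property
    def n_points(self) -> int:
        return len(self.positions)

    @property
    def step_lengths_px(self) -> np.ndarray:
        p = np.array([(x, y) for _, x, y in self.positions])
        return np.sqrt((np.diff(p, axis=0) ** 2).sum(axis=1)) if len(p) > 1 else np.zeros(0)

    @property
    def total_distance_px(self) -> float:
        return float(self.step_lengths_px.sum())

    @property
    def total_distance_um(self) -> float:
        return self.total_distance_px * self.pixel_size


def detect_nuclei(
    projection: np.ndarray,
    nucleus_diameter_px: float = 8.0 / 1.66,
    smooth_sigma: float = 1.0,
    threshold: float | None = None,
    area_factors: tuple[float, float] = (0.25, 4.0),
) -> np.ndarray:
    """Detect nucleus centroids in a partition projection.

    Gaussian smoothing, Otsu threshold (unless an explicit threshold is
    given), connected components filtered to a plausible area window around
    the nominal nucleus cross-section, intensity-weighted centroids.
    Returns an (n, 2) array of (x, y) pixel coordinates in raster-scan
    component order; an empty array for blank images.
    """
    img = np.asarray(projection, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        return np.zeros((0, 2))
    sm = ndimage.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    thr = filters.threshold_otsu(sm) if threshold is None else threshold
    fg = sm > thr
    if not fg.any():
        return np.zeros((0, 2))
    nominal = np.pi * (nucleus_diameter_px / 2.0) ** 2
    lo, hi = area_factors[0] * nominal, area_factors[1] * nominal
    labels = measure.label(fg)
    out = []
    for region in measure.regionprops(labels, intensity_image=sm):
        if lo <= region.area <= hi:
            cy, cx = region.centroid_weighted
            out.append((float(cx), float(cy)))
    return np.asarray(out) if out else np.zeros((0, 2))


def _advance_tracks(
    active: list[Track],
    detections: list[np.ndarray],
    claimed: list[np.ndarray],
    t_start: int,
    config: TrackingConfig,
) -> None:
    """Advance tracks timepoint-major in seeding order, claiming exclusively."""
    T = len(detections)
    alive = list(active)
    for t in range(t_start, T):
        nxt: list[Track] = []
        for tr in alive:
            dets = detections[t]
            free = ~claimed[t]
            if dets.shape[0] == 0 or not free.any():
                continue
            _, x, y = tr.positions[-1]
            d = np.hypot(dets[:, 0] - x, dets[:, 1] - y)
            d[~free] = np.inf
            j = int(np.argmin(d))  # ties broken by lowest detection index
            if d[j] <= config.N:
                tr.positions.append((t, float(dets[j, 0]), float(dets[j, 1])))
                claimed[t][j] = True
                nxt.append(tr)
            # else: track terminates
        alive = nxt
        if not alive:
            break


def link_tracks(
    detections: list[np.ndarray], config: TrackingConfig | None = None
) -> list[Track]:
    """Greedy radius-N nearest-neighbour linking across timepoints.

    Pass 1 seeds one track per t=0 detection, in input order; each timepoint
    the tracks advance in seeding order, each claiming the nearest unclaimed
    detection within N pixels (a detection feeds at most one track).  A track
    with no candidate terminates.  Subsequent passes re-seed from the earliest
    detections left unclaimed.  Tracks shorter than ``min_track_points``
    consecutive timepoints are discarded.
    """
    config = config or TrackingConfig()
    detections = [
        np.asarray(d, dtype=float).reshape(-1, 2) for d in detections
    ]
    T = len(detections)
    if T < 2:
        raise ValueError("need at least 2 timepoints")
    claimed = [np.zeros(len(d), dtype=bool) for d in detections]
    all_tracks: list[Track] = []
    next_id = 0

    for pass_index in range(1, config.n_passes + 1):
        seed_times = [0] if pass_index == 1 else list(range(T - 1))
        for t0 in seed_times:
            seeds: list[Track] = []
            for j in range(len(detections[t0])):
                if claimed[t0][j]:
                    continue
                tr = Track(
                    id=next_id,
                    positions=[(t0, float(detections[t0][j, 0]), float(detections[t0][j, 1]))],
                    pass_index=pass_index,
                    pixel_size=config.pixel_size,
                )
                next_id += 1
                claimed[t0][j] = True
                seeds.append(tr)
            if seeds:
                _advance_tracks(seeds, detections, claimed, t0 + 1, config)
                all_tracks.extend(seeds)

    kept = [tr for tr in all_tracks if tr.n_points >= config.min_track_points]
    for i, tr in enumerate(kept):
        tr.id = i
    return kept


@dataclass
class GradientMap:
    """2-D motility field (µm of total movement), clipped at display_max."""

    field: np.ndarray
    display_max: float
    pixel_size: float


def render_gradient_map(
    tracks: list[Track],
    shape: tuple[int, int],
    display_max: float = 30.0,
    kernel_sigma_px: float = 5.0,
) -> GradientMap:
    """Deposit each track's total distance as Gaussian bumps around its positions.

    Overlapping deposits combine by maximum (the map shows the most motile
    cell at each location, not a density); the field is clipped at
    ``display_max`` µm and is exactly zero beyond 3 sigma of any track
    position.
    """
    ny, nx = shape
    field = np.zeros((ny, nx))
    if not tracks:
        return GradientMap(field=field, display_max=display_max,
                           pixel_size=1.66)
    cut = 3.0 * kernel_sigma_px
    for tr in tracks:
        amp = min(tr.total_distance_um, display_max)
        for _, x, y in tr.positions:
            i0, i1 = max(0, int(x - cut)), min(nx, int(x + cut) + 2)
            j0, j1 = max(0, int(y - cut)), min(ny, int(y + cut) + 2)
            if i0 >= i1 or j0 >= j1:
                continue
            xs = np.arange(i0, i1)
            ys = np.arange(j0, j1)
            d2 = (xs[None, :] - x) ** 2 + (ys[:, None] - y) ** 2
            bump = amp * np.exp(-d2 / (2.0 * kernel_sigma_px**2))
            bump[d2 > cut**2] = 0.0
            np.maximum(field[j0:j1, i0:i1], bump, out=field[j0:j1, i0:i1])
    return GradientMap(field=np.minimum(field, display_max),
                       display_max=display_max,
                       pixel_size=tracks[0].pixel_size)


def summarize_motility(
    tracks: list[Track],
    model: ScaffoldModel,
    mask: LabelMask,
) -> pd.DataFrame:
    """Per-region motility table keyed by (wall_separation | control, partition).

    Tracks are assigned to the wall-set region containing their t=0 position
    (the planar area outside all sets is the control region); niche membership
    uses the label-mask value at the t=0 pixel, with wall pixels counted as
    contact.
    """
    regions = model.set_y_ranges()
    rows = []
    for tr in tracks:
        _, x, y = tr.positions[0]
        xu, yu = x * mask.pixel_size, y * mask.pixel_size
        region = "control"
        for sep, y0, y1 in regions:
            if y0 - 1e-9 <= yu <= y1 + 1e-9:
                region = sep
                break
        iy = min(mask.grid.shape[0] - 1, max(0, int(y)))
        ix = min(mask.grid.shape[1] - 1, max(0, int(x)))
        in_niche = mask.grid[iy, ix] in (LABEL_NICHE, LABEL_WALL)
        rows.append(
            {
                "region": region,
                "partition": tr.partition or "all",
                "total_um": tr.total_distance_um,
                "in_niche": in_niche,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["region", "partition", "n_tracks", "mean_total_um",
                     "max_total_um", "niche_fraction"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["region", "partition"])
        .agg(
            n_tracks=("total_um", "size"),
            mean_total_um=("total_um", "mean"),
            max_total_um=("total_um", "max"),
            niche_fraction=("in_niche", "mean"),
        )
        .reset_index()
    )
    return out


def estimate_shift(image: np.ndarray, reference: np.ndarray) -> tuple[int, int]:
    """Integer-pixel (dy, dx) translation of image relative to reference.

    Cross-correlation registration against the scaffold channel; apply the
    negated shift to bring the image into the reference frame.
    """
    shift, _, _ = phase_cross_correlation(reference, image, upsample_factor=1)
    # phase_cross_correlation returns the correction; negate for displacement
    return -int(round(shift[0])), -int(round(shift[1]))


def apply_shift(image: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate by integer pixels with zero fill."""
    return ndimage.shift(image, shift, order=0, mode="constant", cval=0.0)
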