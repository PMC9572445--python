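"""End-to-end experiment chains over the synthetic phantom.

These functions wire the stages together the way the analysis drivers run
them: place cells -> render a lambda-mode stack -> unmix -> per-chamber
packing, and place cells -> time-lapse -> detect -> link -> motility summary.
Each chain consumes one integer seed and is fully reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import LabelMask, ScaffoldModel, build_scaffold, rasterize
from .packing import aggregate_by_class, sum_per_chamber
from .phantom import (
    ImagingConfig,
    MotionSpec,
    place_cells,
    simulate_timelapse,
)
from .spectra import LAMBDA_405, default_endmembers
from .tracking import (
    Track,
    TrackingConfig,
    detect_nuclei,
    link_tracks,
    summarize_motility,
    z_partition,
)
from .unmixing import unmix
from .phantom import render_stack

__all__ = [
    "unit1_imaging",
    "run_packing_experiment",
    "run_motility_experiment",
]


def unit1_imaging(pixel_size: float = 1.66) -> ImagingConfig:
    """Field of view cropped to the canonical unit wall (210 x 520 µm).

    The enumerated chambers all lie in x in [0, 210] µm, so this crop covers
    every chamber class at the native pixel size while keeping stacks small.
    """
    return ImagingConfig(pixel_size=pixel_size, fov=(210.0, 520.0))


def run_packing_experiment(
    n_cells: int,
    niche_bias: float,
    seed: int,
    model: ScaffoldModel | None = None,
    imaging: ImagingConfig | None = None,
    mask: LabelMask | None = None,
    mode: str = "nnls",
    threshold="auto",
) -> pd.DataFrame:
    """One packing run: place -> render -> unmix -> per-chamber sums.

    Returns the per-chamber packing table (both cell endmembers) with the
    wall-separation class aggregate attached via ``aggregate_by_class``.
    """
    model = model or build_scaffold()
    imaging = imaging or unit1_imaging()
    if mask is None:
        mask = rasterize(model, imaging.pixel_size, fov=imaging.fov)
    rng = np.random.default_rng(seed)
    endmembers = default_endmembers(imaging.spectral)
    cells = place_cells(model, n_cells, niche_bias, rng=rng)
    stack, _ = render_stack(model, cells, endmembers, imaging, rng=rng, mask=mask)
    abundances = unmix(stack, endmembers, mode=mode)
    table = sum_per_chamber(abundances, model, mask, threshold=threshold)
    table["seed"] = seed
    table["niche_bias"] = niche_bias
    return table


def class_niche_ratios(tables: list[pd.DataFrame], endmember: str = "nuclei") -> pd.DataFrame:
    """Pool per-chamber tables over seeds into per-separation niche ratios."""
    table = pd.concat(tables, ignore_index=True)
    agg = aggregate_by_class(table[table["endmember"] == endmember])
    return agg.set_index("wall_separation")


def run_motility_experiment(
    n_cells: int,
    seed: int,
    model: ScaffoldModel | None = None,
    imaging: ImagingConfig | None = None,
    mask: LabelMask | None = None,
    motion: MotionSpec | None = None,
    niche_bias: float = 0.0,
    tracking: TrackingConfig | None = None,
) -> tuple[list[Track], pd.DataFrame, pd.DataFrame]:
    """One time-lapse run: place -> walk -> render -> detect -> link -> summarize.

    Returns (tracks, per-region summary, ground-truth track table).  Tracks
    are linked separately in the bottom (7-slice) and top (5-slice)
    partitions.
    """
    model = model or build_scaffold()
    imaging = imaging or unit1_imaging()
    if mask is None:
        mask = rasterize(model, imaging.pixel_size, fov=imaging.fov)
    motion = motion or MotionSpec()
    tracking = tracking or TrackingConfig(pixel_size=imaging.pixel_size)
    rng = np.random.default_rng(seed)
    cells = place_cells(model, n_cells, niche_bias, rng=rng)
    res = simulate_timelapse(model, cells, motion, imaging, rng=rng)

    tracks: list[Track] = []
    for partition in ("bottom", "top"):
        dets = []
        for stack in res.stacks:
            zp = z_partition(stack)
            proj = zp.bottom if partition == "bottom" else zp.top
            dets.append(detect_nuclei(proj))
        for tr in link_tracks(dets, tracking):
            tr.partition = partition
            tracks.append(tr)
    summary = summarize_motility(tracks, model, mask)
    return tracks, summary, res.tracks
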