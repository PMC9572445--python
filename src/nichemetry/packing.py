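"""Per-chamber cell-packing statistics against the isotropic expectation.

For each chamber the unmixed cellular abundance (nuclei, cytoplasm) is summed
over the full stack height, normalized to the 200 µm² reference chamber area,
and split into contact material — abundance within the 7.5 µm niche zone of
either bounding wall — versus the free mid-chamber space.  The measured
niche-contact ratio is compared with the geometric expectation for spatially
uniform material, 2 * niche_depth / separation (0.75, 0.6, 0.43, 0.27 for the
20/25/35/55 µm separations): a positive excess means wall-contact enrichment
beyond what chamber geometry alone would produce.

Signal on wall pixels is counted as contact material (it is material pressed
against the polymer), so the niche zone here is the full band within
``niche_depth`` of a wall centerline including the traced line itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import LabelMask, ScaffoldModel, isotropic_niche_ratio
from .unmixing import AbundanceStack

__all__ = [
    "UNIT_AREA",
    "sum_per_chamber",
    "density_per_unit_area",
    "compare_to_isotropic",
    "aggregate_by_class",
    "conservation_check",
]

UNIT_AREA = 200.0  # µm², the 10 x 20 reference chamber footprint

CELL_ENDMEMBERS = ("nuclei", "cytoplasm")


def density_per_unit_area(total: float, footprint_area: float,
                          unit_area: float = UNIT_AREA) -> float:
    """Abundance normalized to the reference chamber area."""
    if footprint_area <= 0:
        raise ValueError("footprint_area must be > 0")
    return total * unit_area / footprint_area


def _as_abundance_dict(abundances) -> dict[str, np.ndarray]:
    if isinstance(abundances, AbundanceStack):
        return abundances.abundances
    return abundances


def noise_floor(volume: np.ndarray, n_mad: float = 5.0) -> float:
    """Robust per-voxel abundance noise floor for non-negative unmixing output.

    NNLS zeroes most empty voxels exactly and leaves zero-truncated noise on
    the rest, so the floor is estimated from the *positive* values: their
    median plus ``n_mad`` times their median absolute deviation.  Signal
    voxels are assumed to be a minority of the positive population (true for
    sparse cells in a large field); for noiseless data use a threshold of 0
    instead.
    """
    v = np.asarray(volume, dtype=np.float64).ravel()
    pos = v[v > 0]
    if pos.size == 0:
        return 0.0
    med = float(np.median(pos))
    mad = float(np.median(np.abs(pos - med)))
    return med + n_mad * mad


def sum_per_chamber(
    abundances: AbundanceStack | dict[str, np.ndarray],
    model: ScaffoldModel,
    mask: LabelMask,
    endmembers: tuple[str, ...] = CELL_ENDMEMBERS,
    threshold: float | dict[str, float] | str = 0.0,
) -> pd.DataFrame:
    """Per-chamber totals and niche sums over the full stack height.

    Pixels are assigned to a chamber when their center lies inside the chamber
    rectangle; the niche sum additionally requires the pixel center to be
    within ``niche_depth`` of a bounding wall centerline (wall pixels count as
    contact).  Chambers that rasterize to zero pixels are flagged, not
    dropped.

    ``threshold`` suppresses the residual abundance that non-negative
    unmixing leaves on empty voxels before summation: voxels below the level
    are zeroed.  The default 0 sums raw abundances (exact, right for
    noiseless or ground-truth input); ``"auto"`` estimates a per-endmember
    :func:`noise_floor`, which is what the noisy unmixing pipeline should
    use; a number or per-endmember dict gives an explicit level.
    """
    ab = _as_abundance_dict(abundances)
    some = next(iter(ab.values()))
    if mask.grid.shape != some.shape[1:]:
        raise ValueError("mask not congruent with abundance XY shape")
    yc, xc = mask.pixel_centers()
    d = model.params.niche_depth

    planar: dict[str, np.ndarray] = {}
    for name in endmembers:
        vol = np.asarray(ab[name], dtype=np.float64)
        if threshold == "auto":
            th = noise_floor(vol)
        elif isinstance(threshold, dict):
            th = float(threshold.get(name, 0.0))
        else:
            th = float(threshold)
        if th > 0:
            vol = np.where(vol >= th, vol, 0.0)
        planar[name] = vol.sum(axis=0)

    rows = []
    for ch in model.chambers:
        cols = (xc >= ch.x0) & (xc < ch.x1)
        rws = (yc >= ch.y0) & (yc < ch.y1)
        n_pix = int(cols.sum()) * int(rws.sum())
        niche_rows = rws & (
            (np.abs(yc - ch.y0) <= d) | (np.abs(yc - ch.y1) <= d)
        )
        iso = isotropic_niche_ratio(ch.wall_separation, d)
        for name in endmembers:
            img = planar[name]
            total = float(img[np.ix_(rws, cols)].sum()) if n_pix else 0.0
            niche = float(img[np.ix_(niche_rows, cols)].sum()) if n_pix else 0.0
            rows.append(
                {
                    "chamber_id": ch.id,
                    "endmember": name,
                    "niche_size": ch.niche_size,
                    "wall_separation": ch.wall_separation,
                    "footprint_area": ch.footprint_area,
                    "opening_size": ch.opening_size,
                    "n_pixels": n_pix,
                    "total_abundance": total,
                    "niche_abundance": niche,
                    "niche_ratio": niche / total if total > 0 else np.nan,
                    "density_per_unit_area": density_per_unit_area(total, ch.footprint_area),
                    "isotropic_ratio": iso,
                    "flagged": n_pix == 0,
                }
            )
    return pd.DataFrame(rows)


def compare_to_isotropic(table: pd.DataFrame) -> pd.DataFrame:
    """Add the signed excess niche_ratio - isotropic_ratio per row.

    Positive excess means wall-contact enrichment beyond uniform packing.
    Rows with zero total abundance keep NaN excess and are flagged.
    """
    out = table.copy()
    out["excess"] = out["niche_ratio"] - out["isotropic_ratio"]
    out.loc[out["total_abundance"] <= 0, "excess"] = np.nan
    out.loc[out["total_abundance"] <= 0, "flagged"] = True
    return out


def aggregate_by_class(
    table: pd.DataFrame, by: tuple[str, ...] = ("wall_separation",)
) -> pd.DataFrame:
    """Abundance-weighted summary over replicate chambers of one class.

    The class niche ratio is sum(niche) / sum(total) so chambers contribute in
    proportion to their material, matching a pooled per-class measurement.
    """
    def agg(g: pd.DataFrame) -> pd.Series:
        total = g["total_abundance"].sum()
        niche = g["niche_abundance"].sum()
        return pd.Series(
            {
                "total_abundance": total,
                "niche_abundance": niche,
                "niche_ratio": niche / total if total > 0 else np.nan,
                "mean_density": g["density_per_unit_area"].mean(),
                "isotropic_ratio": g["isotropic_ratio"].iloc[0]
                if g["isotropic_ratio"].nunique() == 1
                else np.nan,
                "n_chambers": len(g),
            }
        )

    keys = ["endmember", *by]
    return table.groupby(keys).apply(agg, include_groups=False).reset_index()


def conservation_check(
    abundances: AbundanceStack | dict[str, np.ndarray],
    table: pd.DataFrame,
    endmember: str,
) -> tuple[float, float, float]:
    """(sum over chambers, out-of-chamber remainder, image total) for one endmember.

    Chamber rectangles are disjoint, so chamber sums plus the remainder equal
    the total image abundance exactly when the table was built with
    ``threshold=0``.
    """
    ab = _as_abundance_dict(abundances)
    total_image = float(np.asarray(ab[endmember], dtype=np.float64).sum())
    in_chambers = float(
        table.loc[table["endmember"] == endmember, "total_abundance"].sum()
    )
    return in_chambers, total_image - in_chambers, total_image
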