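"""Stack and configuration I/O.

Stacks travel as TIFF with a JSON metadata block (axes string plus spatial
calibration) written by tifffile; ``read_stack`` normalizes any subset of the
Z/C/Y/X axes back to a 4-D (Z, C, Y, X) array, broadcasting missing axes to
length 1.  Run configuration is a flat YAML document mirroring the parameter
dataclasses, round-tripping unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .geometry import ScaffoldParams
from .phantom import ImagingConfig
from .spectra import SpectralConfig
from .tracking import TrackingConfig

__all__ = [
    "write_stack",
    "read_stack",
    "StackMeta",
    "RunConfig",
    "save_config",
    "load_config",
]

_CANONICAL_AXES = "ZCYX"


@dataclass
class StackMeta:
    pixel_size_um: float | None = None
    z_step_um: float | None = None
    axes: str = _CANONICAL_AXES


def write_stack(
    path: str | Path,
    data: np.ndarray,
    axes: str | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> None:
    """Write an array as TIFF with axes and calibration metadata."""
    data = np.asarray(data)
    if axes is None:
        axes = _CANONICAL_AXES[-data.ndim:]
    if len(axes) != data.ndim:
        raise ValueError(f"axes {axes!r} does not match array ndim {data.ndim}")
    tifffile.imwrite(
        Path(path),
        data,
        metadata={
            "axes": axes,
            "pixel_size_um": pixel_size_um,
            "z_step_um": z_step_um,
        },
    )


def read_stack(
    path: str | Path,
    axes: str | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> tuple[np.ndarray, StackMeta]:
    """Read a TIFF and normalize to (Z, C, Y, X).

    Axes come from the file metadata, or from the ``axes`` override, or — for
    plain 2-D/3-D files without metadata — default to the trailing letters of
    Z/C/Y/X.  Unrecognized axis letters without an override raise an error
    naming the detected axes.  Missing axes broadcast to length 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = series.axes
        meta: dict = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
    detected = axes or meta.get("axes") or file_axes
    detected = str(detected).upper()
    if len(detected) != data.ndim or any(
        a not in _CANONICAL_AXES + "QS" for a in detected
    ):
        # shaped TIFFs report unknown dims as Q; fall back to positional default
        if axes is None and data.ndim <= 4 and all(a in "QSZCYX" for a in detected):
            detected = _CANONICAL_AXES[-data.ndim:]
        else:
            raise ValueError(
                f"cannot interpret axes {detected!r} for {path.name}; "
                "pass axes= explicitly"
            )
    # replace placeholder letters positionally
    if any(a in "QS" for a in detected):
        detected = _CANONICAL_AXES[-data.ndim:]

    for i, a in enumerate(_CANONICAL_AXES):
        if a not in detected:
            data = np.expand_dims(data, axis=0)
            detected = a + detected
    order = [detected.index(a) for a in _CANONICAL_AXES]
    data = np.transpose(data, order)
    out_meta = StackMeta(
        pixel_size_um=pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um"),
        z_step_um=z_step_um if z_step_um is not None else meta.get("z_step_um"),
        axes=_CANONICAL_AXES,
    )
    return data, out_meta


@dataclass
class RunConfig:
    """One seed governs the whole run; config round-trips through YAML."""

    scaffold: ScaffoldParams
    imaging: ImagingConfig
    tracking: TrackingConfig
    seed: int = 0
    log_level: str = "INFO"


def save_config(config: RunConfig, path: str | Path) -> None:
    doc = {
        "scaffold": asdict(config.scaffold),
        "imaging": asdict(config.imaging),
        "tracking": asdict(config.tracking),
        "seed": config.seed,
        "log_level": config.log_level,
    }
    # YAML-friendly containers
    doc["scaffold"]["niche_sections"] = list(config.scaffold.niche_sections)
    doc["scaffold"]["wall_separations"] = list(config.scaffold.wall_separations)
    doc["imaging"]["fov"] = list(config.imaging.fov)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    sc = dict(doc["scaffold"])
    sc["niche_sections"] = tuple(sc["niche_sections"])
    sc["wall_separations"] = tuple(sc["wall_separations"])
    im = dict(doc["imaging"])
    im["fov"] = tuple(im["fov"])
    im["spectral"] = SpectralConfig(**im["spectral"])
    return RunConfig(
        scaffold=ScaffoldParams(**sc),
        imaging=ImagingConfig(**im),
        tracking=TrackingConfig(**doc["tracking"]),
        seed=int(doc.get("seed", 0)),
        log_level=str(doc.get("log_level", "INFO")),
    )
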