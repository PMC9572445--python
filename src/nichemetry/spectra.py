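"""Emission spectra and photobleaching models shared by generator and unmixer.

Lambda-mode confocal acquisition records one image per emission wavelength
bin.  The two instrument grids modelled here follow the acquisition used for
the scaffold studies: 32 channels spanning 416-687 nm under 405 nm excitation
and 23 channels spanning 494-687 nm under 488 nm excitation (nominally 9 nm
bins; the exact bin width is derived from the range and channel count).

Endmember spectra are unit-sum weight vectors on a channel grid: a broad
scaffold autofluorescence profile, Hoechst-like and CF488-like stain peaks,
and a flat background.  UV quenching of the scaffold autofluorescence is a
single exponential I(t) = I0 * exp(-k t), fitted in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SpectralConfig",
    "LAMBDA_405",
    "LAMBDA_488",
    "EndmemberSpectrum",
    "make_endmember",
    "default_endmembers",
    "QuenchModel",
    "QuenchFit",
    "quench_intensity",
    "fit_quench",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SpectralConfig:
    """One excitation line's detection grid."""

    excitation_nm: float
    range_start_nm: float
    range_end_nm: float
    n_channels: int
    nominal_bin_width_nm: float = 9.0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.range_end_nm <= self.range_start_nm:
            raise ValueError("need n_channels >= 1 and a positive spectral range")

    @property
    def bin_width_nm(self) -> float:
        return (self.range_end_nm - self.range_start_nm) / self.n_channels

    @property
    def bin_edges_nm(self) -> np.ndarray:
        return np.linspace(self.range_start_nm, self.range_end_nm, self.n_channels + 1)

    @property
    def channel_centers_nm(self) -> np.ndarray:
        e = self.bin_edges_nm
        return 0.5 * (e[:-1] + e[1:])


LAMBDA_405 = SpectralConfig(excitation_nm=405.0, range_start_nm=416.0,
                            range_end_nm=687.0, n_channels=32)
LAMBDA_488 = SpectralConfig(excitation_nm=488.0, range_start_nm=494.0,
                            range_end_nm=687.0, n_channels=23)


@dataclass(frozen=True)
class EndmemberSpectrum:
    """Unit-sum emission weights of one source on a channel grid."""

    name: str
    weights: np.ndarray
    config: SpectralConfig

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(w) != self.config.n_channels:
            raise ValueError(
                f"weights must have {self.config.n_channels} entries, got {w.shape}"
            )
        if (w < -1e-12).any():
            raise ValueError("endmember weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("endmember weights must sum to 1")
        object.__setattr__(self, "weights", w)


def make_endmember(
    name: str,
    config: SpectralConfig,
    peak_nm: float | None = None,
    fwhm_nm: float | None = None,
    shape: str = "gaussian",
) -> EndmemberSpectrum:
    """Build an endmember on a channel grid.

    ``shape='gaussian'`` integrates a Gaussian line (peak, FWHM) over each
    bin.  ``shape='broad'`` is a very wide Gaussian (peak 480 nm, FWHM 220 nm
    unless overridden) spanning all channels — the scaffold autofluorescence
    convention.  ``shape='flat'`` gives equal weights (background).
    """
    edges = config.bin_edges_nm
    if shape == "flat":
        w = np.ones(config.n_channels)
    else:
        if shape == "broad":
            peak_nm = 480.0 if peak_nm is None else peak_nm
            fwhm_nm = 220.0 if fwhm_nm is None else fwhm_nm
        elif shape != "gaussian":
            raise ValueError(f"unknown shape {shape!r}")
        if peak_nm is None or fwhm_nm is None:
            raise ValueError("gaussian endmembers need peak_nm and fwhm_nm")
        if fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be > 0")
        sigma = fwhm_nm * _FWHM_TO_SIGMA
        cdf = stats.norm.cdf(edges, loc=peak_nm, scale=sigma)
        w = np.diff(cdf)
    total = w.sum()
    if total <= 0:
        raise ValueError("endmember has no weight inside the detection range")
    return EndmemberSpectrum(name=name, weights=w / total, config=config)


def default_endmembers(config: SpectralConfig) -> dict[str, EndmemberSpectrum]:
    """The four-source endmember set used by the synthetic generator.

    Stain line shapes are generator conventions with known ground truth:
    nuclei stain peak 461 nm / FWHM 50 nm (Hoechst-like), cytoplasm stain
    peak 515 nm / FWHM 40 nm (CF488-like), broad scaffold autofluorescence,
    flat low-level background.
    """
    return {
        "scaffold": make_endmember("scaffold", config, shape="broad"),
        "nuclei": make_endmember("nuclei", config, peak_nm=461.0, fwhm_nm=50.0),
        "cytoplasm": make_endmember("cytoplasm", config, peak_nm=515.0, fwhm_nm=40.0),
        "background": make_endmember("background", config, shape="flat"),
    }


@dataclass(frozen=True)
class QuenchModel:
    """Single-exponential UV quench of autofluorescence: I(t) = I0 exp(-k t)."""

    I0: float
    k: float  # per minute

    def __post_init__(self) -> None:
        if self.I0 <= 0:
            raise ValueError("I0 must be > 0")
        if self.k < 0:
            raise ValueError("k must be >= 0")


# decay rate that maps 100% -> 22% over 150 min of UV treatment
DEFAULT_QUENCH_K = float(np.log(1.0 / 0.22) / 150.0)


def quench_intensity(model: QuenchModel, t: float | np.ndarray) -> float | np.ndarray:
    """Scaffold autofluorescence intensity after t minutes of UV treatment."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    out = model.I0 * np.exp(-model.k * t)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class QuenchFit:
    model: QuenchModel
    r_squared: float | None  # None when the fit is degenerate (k == 0 exactly)


def fit_quench(t: np.ndarray, intensity: np.ndarray) -> QuenchFit:
    """Least-squares line fit of log-intensity vs time.

    The quench trend is linear on a log scale, so the exponential parameters
    come from ordinary linear regression on (t, log I): slope -> -k,
    intercept -> log I0.  R² is reported on the log scale and flagged None
    for constant data (zero variance).
    """
    t = np.asarray(t, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if t.ndim != 1 or t.shape != intensity.shape:
        raise ValueError("t and intensity must be 1-D arrays of equal length")
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    if len(np.unique(t)) != len(t):
        raise ValueError("time points must be distinct")
    if (intensity <= 0).any():
        raise ValueError("intensities must be > 0 (log fit)")

    logi = np.log(intensity)
    if np.ptp(logi) == 0.0:
        return QuenchFit(model=QuenchModel(I0=float(intensity[0]), k=0.0), r_squared=None)
    res = stats.linregress(t, logi)
    k = max(0.0, -res.slope)
    return QuenchFit(
        model=QuenchModel(I0=float(np.exp(res.intercept)), k=float(k)),
        r_squared=float(res.rvalue**2),
    )
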