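"""ROI-based endmember estimation and per-voxel linear spectral unmixing.

Each voxel of a lambda-mode stack carries a measured emission spectrum y that
is modelled as a non-negative combination of endmember spectra, y = E a + ε.
``estimate_endmembers`` extracts the endmember matrix E from user-chosen
regions of interest (mean ROI spectrum, unit-sum normalized, as in standard
lambda-mode unmixing workflows); ``unmix`` solves the per-voxel least-squares
problem, either unconstrained (OLS) or with non-negative abundances (NNLS).

The NNLS solver exploits the small, fixed endmember count: for k endmembers
the optimal active set is one of 2^k - 1 supports, so all candidate
restricted OLS solutions are computed as dense matrix products over every
voxel at once and the support satisfying the KKT conditions is selected.
This is exact (it matches scipy.optimize.nnls voxel by voxel) and fully
vectorized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.optimize

from .geometry import LABEL_WALL, LabelMask
from .phantom import HyperspectralStack
from .spectra import EndmemberSpectrum

__all__ = [
    "RoiSet",
    "AbundanceStack",
    "estimate_endmembers",
    "unmix",
    "masked_views",
    "nnls_batch",
]

CONDITION_WARN_THRESHOLD = 1e3


@dataclass
class RoiSet:
    """Named planar regions, one per endmember: name -> (slice_index, 2-D bool mask)."""

    rois: dict[str, tuple[int, np.ndarray]]

    def __post_init__(self) -> None:
        union: np.ndarray | None = None
        for name, (z, m) in self.rois.items():
            m = np.asarray(m, dtype=bool)
            if m.ndim != 2:
                raise ValueError(f"ROI {name!r} mask must be 2-D")
            if not m.any():
                raise ValueError(f"ROI {name!r} is empty")
            self.rois[name] = (int(z), m)
            if union is None:
                union = np.zeros_like(m, dtype=np.int8)
            union = union + m.astype(np.int8)
        if union is not None and (union > 1).any():
            raise ValueError("ROIs must be pairwise disjoint")


@dataclass
class AbundanceStack:
    """Per-endmember (Z, Y, X) abundance volumes plus per-voxel RMS residual."""

    abundances: dict[str, np.ndarray]
    residual: np.ndarray
    mode: str

    @property
    def names(self) -> list[str]:
        return list(self.abundances)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.residual.shape


def estimate_endmembers(
    stack: HyperspectralStack, rois: RoiSet
) -> list[EndmemberSpectrum]:
    """Mean ROI spectrum per endmember, unit-sum normalized.

    A pair of near-identical ROI spectra (or a generally ill-conditioned
    endmember matrix) triggers a warning: unmixing will not be able to
    separate those sources reliably.
    """
    nz, _, ny, nx = stack.data.shape
    out: list[EndmemberSpectrum] = []
    for name, (z, m) in rois.rois.items():
        if not 0 <= z < nz:
            raise ValueError(f"ROI {name!r} slice {z} outside stack (nz={nz})")
        if m.shape != (ny, nx):
            raise ValueError(f"ROI {name!r} mask shape {m.shape} != image {(ny, nx)}")
        spec = stack.data[z][:, m].astype(np.float64).mean(axis=1)
        total = spec.sum()
        if total <= 0:
            raise ValueError(f"ROI {name!r} has zero total intensity")
        out.append(
            EndmemberSpectrum(name=name, weights=spec / total, config=stack.imaging.spectral)
        )
    E = np.stack([em.weights for em in out], axis=1)
    cond = np.linalg.cond(E)
    if cond > CONDITION_WARN_THRESHOLD:
        warnings.warn(
            f"endmember matrix is ill-conditioned (cond={cond:.3g}); "
            "ROI spectra may describe mixed or duplicate sources",
            stacklevel=2,
        )
    return out


def nnls_batch(E: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact NNLS min ||E x - y||, x >= 0, for many right-hand sides.

    E is (C, k) with k small; Y is (C, V).  Enumerates candidate supports by
    decreasing size and accepts, per column, the first support whose
    restricted OLS solution satisfies primal (x >= 0) and dual (gradient of
    excluded coefficients <= 0) feasibility.  Columns left unresolved by
    numerical ties fall back to scipy.optimize.nnls.
    """
    C, k = E.shape
    if k > 12:
        raise ValueError("exhaustive active-set solver is for small endmember counts")
    V = Y.shape[1]
    X = np.zeros((k, V))
    solved = np.zeros(V, dtype=bool)
    scale = float(np.abs(Y).max()) if Y.size else 0.0
    tol = 1e-9 * (1.0 + scale)

    # normal-equation form: restricted solutions and KKT duals only need the
    # Gram matrix G = E'E (k x k) and b = E'Y (k x V), so per-support work is
    # O(k^2 V) regardless of the channel count
    G = E.T @ E
    b = E.T @ Y

    supports = [
        list(S)
        for size in range(k, 0, -1)
        for S in combinations(range(k), size)
    ]
    for S in supports:
        idx = np.flatnonzero(~solved)
        if idx.size == 0:
            break
        bS = b[np.ix_(S, idx)]
        Xs = np.linalg.solve(G[np.ix_(S, S)], bS)
        primal = (Xs >= -tol).all(axis=0)
        comp = [j for j in range(k) if j not in S]
        if comp:
            w = b[np.ix_(comp, idx)] - G[np.ix_(comp, S)] @ Xs
            dual = (w <= tol).all(axis=0)
        else:
            dual = np.ones(idx.size, dtype=bool)
        ok = primal & dual
        if ok.any():
            sel = idx[ok]
            X[np.ix_(S, sel)] = np.clip(Xs[:, ok], 0.0, None)
            solved[sel] = True
    # empty support: zero is optimal when all gradients are non-positive
    idx = np.flatnonzero(~solved)
    if idx.size:
        ok = (b[:, idx] <= tol).all(axis=0)
        solved[idx[ok]] = True
        idx = idx[~ok]
    for j in idx:  # numerically degenerate leftovers, if any
        X[:, j], _ = scipy.optimize.nnls(E, Y[:, j])
    return X


def unmix(
    stack: HyperspectralStack,
    endmembers: list[EndmemberSpectrum] | dict[str, EndmemberSpectrum],
    mode: str = "nnls",
) -> AbundanceStack:
    """Per-voxel linear unmixing into endmember abundance volumes.

    ``mode='ols'`` solves the unconstrained least-squares problem (exact on
    noiseless mixtures, abundances may go negative under noise);
    ``mode='nnls'`` enforces physical non-negativity.  The endmember matrix
    must be full column rank; the per-voxel RMS spectral misfit is returned
    alongside the abundances.
    """
    if isinstance(endmembers, dict):
        endmembers = list(endmembers.values())
    if mode not in ("ols", "nnls"):
        raise ValueError(f"mode must be 'ols' or 'nnls', got {mode!r}")
    names = [em.name for em in endmembers]
    E = np.stack([em.weights for em in endmembers], axis=1)  # (C, k)
    C, k = E.shape
    if np.linalg.matrix_rank(E) < k:
        # name the collinear pair for the error message
        worst = None
        for i in range(k):
            for j in range(i + 1, k):
                c = abs(
                    np.dot(E[:, i], E[:, j])
                    / (np.linalg.norm(E[:, i]) * np.linalg.norm(E[:, j]))
                )
                if worst is None or c > worst[0]:
                    worst = (c, names[i], names[j])
        raise ValueError(
            "endmember matrix is rank deficient; most collinear pair: "
            f"{worst[1]!r} vs {worst[2]!r}"
        )

    nz, c_axis, ny, nx = stack.data.shape
    if c_axis != C:
        raise ValueError(f"stack has {c_axis} channels, endmembers have {C}")
    Y = stack.data.reshape(nz, C, ny * nx).transpose(1, 0, 2).reshape(C, nz * ny * nx)
    Y = np.ascontiguousarray(Y, dtype=np.float64)

    if mode == "ols":
        X = np.linalg.pinv(E) @ Y
    else:
        X = nnls_batch(E, Y)

    resid = Y - E @ X
    rms = np.sqrt(np.mean(resid**2, axis=0))

    Xz = X.reshape(k, nz, ny, nx)
    abundances = {names[i]: Xz[i] for i in range(k)}
    return AbundanceStack(abundances=abundances,
                          residual=rms.reshape(nz, ny, nx).astype(np.float32),
                          mode=mode)


def masked_views(
    abundances: AbundanceStack, mask: LabelMask
) -> dict[str, np.ndarray]:
    """Zero the cell-endmember maps on scaffold pixels.

    Returns per-endmember copies where wall-labelled pixels are removed from
    the nuclei/cytoplasm maps; the scaffold abundance is passed through
    untouched as a position marker.
    """
    some = next(iter(abundances.abundances.values()))
    if mask.grid.shape != some.shape[1:]:
        raise ValueError(
            f"mask shape {mask.grid.shape} does not match stack XY {some.shape[1:]}"
        )
    wall = mask.grid == LABEL_WALL
    out: dict[str, np.ndarray] = {}
    for name, vol in abundances.abundances.items():
        if name in ("scaffold", "background"):
            out[name] = vol.copy()
        else:
            v = vol.copy()
            v[:, wall] = 0.0
            out[name] = v
    return out
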