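"""Regional homogeneity (ReHo) mapping via Kendall's coefficient of concordance.

ReHo measures the local temporal synchrony of a voxel with its immediate
neighborhood: Kendall's W among the K time series formed by the voxel and
its stencil neighbors (26 for the full 3x3x3 cube).  W is 1 for perfect
rank agreement and has expectation ~1/K under independence.  Maps are
normalized by the whole-mask mean W and Gaussian-smoothed last ("smReHo"
ordering), with the kernel renormalized inside the mask so that edge
voxels are not attenuated by out-of-mask zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .preprocess import Bold4D, BrainMask

#: neighborhood stencils: face (7), face+edge (19), face+edge+corner (27)
_STENCILS = {
    7: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 1],
    19: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if abs(dx) + abs(dy) + abs(dz) <= 2],
    27: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)],
}


@dataclass
class ReHoMap:
    """3D map of Kendall's W values with provenance of the computation.

    ``stage`` tracks the processing state: ``raw`` W values in [0, 1],
    ``normalized`` after division by the in-mask mean (mean 1), and
    ``smoothed`` after the Gaussian kernel.  ``k_map`` records the
    effective neighborhood size actually used at each voxel (smaller than
    ``neighborhood_k`` at mask boundaries).
    """

    data: np.ndarray
    stage: str  # {"raw", "normalized", "smoothed"}
    neighborhood_k: int
    n_timepoints_used: int
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    k_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ReHoMap must be 3D")
        if self.stage not in ("raw", "normalized", "smoothed"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)


def kendalls_w(series_block: np.ndarray, tie_correction: bool = False) -> float:
    """Kendall's coefficient of concordance among K series of length n.

    Each row is one series; values are converted to midranks over time.
    W = 12*S / (K^2 (n^3 - n) - K * sum_T) where S is the sum of squared
    deviations of the per-timepoint rank sums from their mean, and sum_T
    is the usual tie-correction term (included only when
    ``tie_correction`` is on; the uncorrected form matches the classic
    ReHo toolbox formula and is the default).

    Invariant to any strictly monotone transform of a single series.
    Returns 0 with a warning when the denominator degenerates (all series
    constant under tie correction).
    """
    block = np.asarray(series_block, dtype=np.float64)
    if block.ndim != 2:
        raise ValueError("series_block must be 2D (K series x n timepoints)")
    k, n = block.shape
    if k < 2 or n < 2:
        raise ValueError(f"need K >= 2 and n >= 2, got K={k}, n={n}")

    ranks = rankdata(block, axis=1)  # midranks
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())

    denom = k * k * (n ** 3 - n)
    if tie_correction:
        denom -= k * _tie_term(block)
    if denom <= 0:
        warnings.warn("degenerate Kendall's W denominator; returning 0", RuntimeWarning)
        return 0.0
    return 12.0 * s / denom


def _tie_term(block: np.ndarray) -> float:
    """Sum over series of sum(t^3 - t) over tie groups of size t."""
    total = 0.0
    for row in block:
        _, counts = np.unique(row, return_counts=True)
        total += float((counts.astype(np.float64) ** 3 - counts).sum())
    return total


def _shift3(arr: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Shift a 3D/4D array by an integer 3D offset, zero-filling the border.

    out[i] = arr[i - offset] where defined; the leading three axes are
    spatial.
    """
    out = np.zeros_like(arr)
    src = []
    dst = []
    for ax, d in enumerate(offset):
        n = arr.shape[ax]
        if abs(d) >= n:
            return out
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def reho_map(
    bold: Bold4D,
    mask: BrainMask,
    neighborhood_k: int = 27,
    tie_correction: bool = False,
) -> ReHoMap:
    """Raw ReHo map: Kendall's W of each in-mask voxel with its neighbors.

    At mask boundaries the W is computed over the available in-mask
    neighbors with the effective K recorded in ``k_map`` (toolbox
    behavior: the whole mask gets a value rather than discarding edge
    voxels).  Voxels with fewer than 2 in-mask series get 0 and a
    warning.  The computation is fully vectorized: per-voxel time ranks
    are accumulated over shifted copies of the rank volume.
    """
    if neighborhood_k not in _STENCILS:
        raise ValueError("neighborhood_k must be one of 7, 19, 27")
    if mask.data.shape != bold.grid_shape:
        raise ValueError("mask shape does not match bold grid")
    n = bold.n_timepoints
    if n < 2:
        raise ValueError("need at least 2 timepoints")

    m = mask.data
    # midranks over time for every voxel; out-of-mask contributions are
    # masked out during accumulation below
    ranks = rankdata(bold.data, axis=3).astype(np.float64)
    ranks_masked = ranks * m[..., None]

    rank_sum = np.zeros_like(ranks)
    k_eff = np.zeros(bold.grid_shape, dtype=np.float64)
    tie_sum = None
    if tie_correction:
        tie_vox = np.zeros(bold.grid_shape)
        flat = bold.data[m]
        tie_vals = np.empty(flat.shape[0])
        for i, row in enumerate(flat):
            _, counts = np.unique(row, return_counts=True)
            tie_vals[i] = (counts.astype(np.float64) ** 3 - counts).sum()
        tie_vox[m] = tie_vals
        tie_sum = np.zeros(bold.grid_shape)

    mask_f = m.astype(np.float64)
    for offset in _STENCILS[neighborhood_k]:
        rank_sum += _shift3(ranks_masked, offset)
        k_eff += _shift3(mask_f, offset)
        if tie_correction:
            tie_sum += _shift3(tie_vox, offset)

    w = np.zeros(bold.grid_shape)
    valid = m & (k_eff >= 2)
    if (m & ~valid).any():
        warnings.warn(
            f"{int((m & ~valid).sum())} in-mask voxel(s) have no in-mask "
            "neighbor; set to 0",
            RuntimeWarning,
        )
    kv = k_eff[valid]
    rs = rank_sum[valid]  # (n_valid, n)
    s = ((rs - rs.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    denom = kv * kv * (n ** 3 - n)
    if tie_correction:
        denom = denom - kv * tie_sum[valid]
    good = denom > 0
    if not good.all():
        warnings.warn(
            f"{int((~good).sum())} voxel(s) with degenerate W denominator; set to 0",
            RuntimeWarning,
        )
    wvals = np.zeros(kv.shape)
    wvals[good] = 12.0 * s[good] / denom[good]
    w[valid] = wvals

    k_map = np.where(m, k_eff, 0.0)
    return ReHoMap(
        data=w,
        stage="raw",
        neighborhood_k=neighborhood_k,
        n_timepoints_used=n,
        voxel_size_mm=bold.voxel_size_mm,
        affine=bold.affine,
        k_map=k_map,
    )


def normalize_and_smooth(
    rmap: ReHoMap,
    mask: BrainMask,
    fwhm_mm: float = 4.0,
) -> ReHoMap:
    """Divide by the in-mask mean W, then Gaussian-smooth within the mask.

    Normalization makes the in-mask mean exactly 1 (removing between-
    subject global differences in overall synchrony); the subsequent
    Gaussian kernel (FWHM in mm, converted per-axis to voxel sigmas) is
    renormalized within the mask — smoothed values are divided by the
    smoothed mask — so that out-of-mask zeros do not bleed in and edge
    voxels keep their scale.  ``fwhm_mm = 0`` leaves the map unsmoothed.
    """
    if rmap.stage != "raw":
        raise ValueError("normalize_and_smooth expects a raw-stage map")
    if mask.data.shape != rmap.data.shape:
        raise ValueError("mask shape does not match map")
    m = mask.data
    mean_w = rmap.data[m].mean()
    if mean_w <= 0:
        raise ValueError("in-mask mean W is not positive; cannot normalize")
    normalized = np.where(m, rmap.data / mean_w, 0.0)

    if fwhm_mm == 0:
        data, stage = normalized, "normalized"
    else:
        sigma_vox = [
            fwhm_mm / (np.sqrt(8.0 * np.log(2.0)) * v) for v in rmap.voxel_size_mm
        ]
        num = ndimage.gaussian_filter(normalized * m, sigma=sigma_vox)
        den = ndimage.gaussian_filter(m.astype(np.float64), sigma=sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = np.where(m & (den > 0), num / np.maximum(den, 1e-300), 0.0)
        data, stage = smoothed, "smoothed"

    return ReHoMap(
        data=data,
        stage=stage,
        neighborhood_k=rmap.neighborhood_k,
        n_timepoints_used=rmap.n_timepoints_used,
        voxel_size_mm=rmap.voxel_size_mm,
        affine=rmap.affine,
        k_map=rmap.k_map,
    )
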