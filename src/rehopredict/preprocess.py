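"""Temporal cleaning and motion quality control for resting-state BOLD series.

The operations here cover the post-realignment part of a standard
resting-state pipeline: discarding initial equilibration volumes, linear
detrending with an ideal (brick-wall) band-pass filter in the 0.01-0.1 Hz
band, Power-style framewise displacement, and threshold-based motion
screening.  Slice-timing correction, realignment estimation and spatial
normalization are assumed to have happened upstream; motion parameters are
consumed, never estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

MIN_FILTER_LENGTH = 32  # volumes; shorter series give the DFT too few in-band bins


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Bold4D:
    """A subject's 4D BOLD grid with voxel-size and timing metadata.

    ``data`` is indexed (x, y, z, t); ``voxel_size_mm`` is the spatial
    sampling in mm per axis and ``tr_seconds`` the repetition time.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_seconds: float = 2.0
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Bold4D needs a 4D array, got shape {self.data.shape}")
        if self.data.shape[3] < 1:
            raise ValueError("Bold4D needs at least one volume")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(tuple(self.voxel_size_mm) + (self.tr_seconds,))
        return img

    @classmethod
    def from_nifti(cls, path_or_img) -> "Bold4D":
        img = path_or_img if isinstance(path_or_img, nib.Nifti1Image) else nib.load(str(path_or_img))
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
        return cls(
            data=np.asanyarray(img.dataobj, dtype=np.float64),
            voxel_size_mm=tuple(float(z) for z in zooms[:3]),
            tr_seconds=tr,
            affine=np.asarray(img.affine),
        )


@dataclass
class BrainMask:
    """Binary 3D mask sharing grid and affine with its companion volumes."""

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("BrainMask must be 3D")
        if not self.data.any():
            raise ValueError("BrainMask has no in-mask voxel")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    @classmethod
    def from_nifti(cls, path_or_img) -> "BrainMask":
        img = path_or_img if isinstance(path_or_img, nib.Nifti1Image) else nib.load(str(path_or_img))
        return cls(data=np.asanyarray(img.dataobj) > 0, affine=np.asarray(img.affine))


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: translations (mm) then rotations (rad).

    One row per volume, six columns: x/y/z translation in millimetres
    followed by rotations about x/y/z in radians (the realignment-toolbox
    file convention).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=np.float64))
        if self.params.shape[1] != 6:
            raise ValueError("MotionTrace needs 6 columns (3 trans mm, 3 rot rad)")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]

    def save(self, path) -> None:
        np.savetxt(path, self.params, fmt="%.10g")

    @classmethod
    def load(cls, path) -> "MotionTrace":
        return cls(np.loadtxt(path, ndmin=2))


@dataclass
class SubjectQC:
    """Motion quality-control summary for one subject."""

    max_abs_translation_mm: float
    max_abs_rotation_deg: float
    fd_series: np.ndarray
    mean_fd: float
    excluded: bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def drop_initial_volumes(bold: Bold4D, k: int = 10) -> Bold4D:
    """Discard the first ``k`` volumes (signal-equilibration scrubbing).

    The default of 10 matches common practice for a TR-2 s acquisition.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k >= bold.n_timepoints:
        raise ValueError(
            f"cannot drop {k} volumes from a series of {bold.n_timepoints}"
        )
    return Bold4D(
        data=bold.data[..., k:],
        voxel_size_mm=bold.voxel_size_mm,
        tr_seconds=bold.tr_seconds,
        affine=bold.affine,
    )


def detrend_and_bandpass(
    bold: Bold4D,
    mask: BrainMask,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> Bold4D:
    """Linear detrend then ideal band-pass each in-mask voxel series.

    The filter is a zero-phase brick wall on the real DFT: frequency bins
    within [low_hz, high_hz] are retained, everything else (including DC)
    is zeroed, mirroring the "ideal filter" of the classic resting-state
    toolboxes.  Out-of-mask voxels are zeroed.
    """
    t = bold.n_timepoints
    nyquist = 1.0 / (2.0 * bold.tr_seconds)
    if not (0.0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(f"high_hz {high_hz} exceeds Nyquist {nyquist}")
    if t < MIN_FILTER_LENGTH:
        raise ValueError(f"series too short to filter: {t} < {MIN_FILTER_LENGTH}")
    if mask.data.shape != bold.grid_shape:
        raise ValueError("mask shape does not match bold grid")

    series = bold.data[mask.data]  # (n_vox, t)

    # least-squares linear trend removal
    x = np.arange(t, dtype=np.float64)
    x = x - x.mean()
    slope = series @ x / (x @ x)
    series = series - series.mean(axis=1, keepdims=True) - slope[:, None] * x[None, :]

    freqs = np.fft.rfftfreq(t, d=bold.tr_seconds)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spec = np.fft.rfft(series, axis=1)
    spec[:, ~keep] = 0.0
    filtered = np.fft.irfft(spec, n=t, axis=1)

    out = np.zeros_like(bold.data)
    out[mask.data] = filtered
    return Bold4D(
        data=out,
        voxel_size_mm=bold.voxel_size_mm,
        tr_seconds=bold.tr_seconds,
        affine=bold.affine,
    )


def framewise_displacement(motion: MotionTrace, head_radius_mm: float = 50.0) -> SubjectQC:
    """Power-style framewise displacement from a motion trace.

    FD_i = sum of absolute backward differences of the three translations
    plus ``head_radius_mm`` times those of the three rotations (radians
    approximated as arc length on a sphere of that radius).  Returns a QC
    record with the FD series and summary motion extrema; the exclusion
    flag is left False (see :func:`motion_screen`).
    """
    if motion.n_volumes < 2:
        raise ValueError("framewise displacement needs at least 2 volumes")
    d = np.diff(motion.params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return SubjectQC(
        max_abs_translation_mm=float(np.abs(motion.translations_mm).max()),
        max_abs_rotation_deg=float(np.degrees(np.abs(motion.rotations_rad)).max()),
        fd_series=fd,
        mean_fd=float(fd.mean()),
        excluded=False,
    )


def motion_screen(
    motion: MotionTrace,
    trans_mm: float = 2.0,
    rot_deg: float = 2.0,
    head_radius_mm: float = 50.0,
) -> SubjectQC:
    """Flag a subject whose motion exceeds the translation/rotation limits.

    Exclusion is strict ("more than"): a parameter exactly at the threshold
    does not exclude.  Rotations are stored in radians and converted to
    degrees only here.
    """
    qc = framewise_displacement(motion, head_radius_mm=head_radius_mm)
    qc.excluded = bool(
        qc.max_abs_translation_mm > trans_mm or qc.max_abs_rotation_deg > rot_deg
    )
    return qc


def qc_table(qcs: dict[str, SubjectQC]):
    """Assemble per-subject QC records into a tidy table (TSV-ready)."""
    import pandas as pd

    rows = [
        {
            "subject_id": sid,
            "max_abs_translation_mm": qc.max_abs_translation_mm,
            "max_abs_rotation_deg": qc.max_abs_rotation_deg,
            "mean_fd": qc.mean_fd,
            "excluded": qc.excluded,
        }
        for sid, qc in qcs.items()
    ]
    return pd.DataFrame(rows)
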