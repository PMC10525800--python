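"""Synthetic resting-state cohorts with known local-synchrony ground truth.

Real patient scans for this kind of study are rarely deposited, so every
downstream stage is exercised on cohorts generated here.  The generator
emulates a two-group resting-state design: per-subject 4D BOLD grids in
which selected regions of interest carry a planted level of local temporal
coherence, six-parameter motion traces, demographic covariates, and
clinical outcomes in which the treatment-response reduction rate is a
stated noisy linear function of the subject's ROI-mean regional
homogeneity.

Coherence is implemented with a shared latent factor: inside an ROI with
coherence c, every voxel's series is sqrt(1-c) * iid Gaussian noise plus
sqrt(c) * one latent series shared across the ROI, so the expected
pairwise correlation between ROI voxels is exactly c — an analytic handle
that spatial smoothing would not give.  Group 2 uses c + group_delta,
planting a known between-group ReHo difference.  Kendall's W is monotone
in c, so recovery of the planted regions is a well-defined target.

The generator makes no attempt at hemodynamic response shapes,
physiological (cardiac/respiratory) noise, scanner drift fields or
susceptibility artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Bold4D, BrainMask, MotionTrace, drop_initial_volumes, detrend_and_bandpass
from .reho import reho_map

# stage tags for the seed-derivation scheme (global seed -> per-stage,
# per-subject SeedSequence entropy); documented so any subject can be
# regenerated in isolation
STAGE_BOLD = 1
STAGE_MOTION = 2
STAGE_CLINICAL = 3

# covariate / baseline-score sampling ranges (integer-valued scales);
# chosen to match a typical adult outpatient anxiety cohort
AGE_RANGE = (18, 52)
EDUCATION_RANGE = (7, 19)
HAMA_BASELINE_RANGE = (10, 25)
HAMD_BASELINE_RANGE = (7, 21)


@dataclass
class RoiSpec:
    """A planted region: voxel set, coherence level, and group offset."""

    name: str
    voxels: np.ndarray  # (m, 3) integer indices
    coherence: float
    group_delta: float = 0.0

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=np.int64))
        if self.voxels.shape[0] == 0 or self.voxels.shape[1] != 3:
            raise ValueError("voxel set must be a nonempty (m, 3) index array")
        for c in (self.coherence, self.coherence + self.group_delta):
            if not (0.0 <= c < 1.0):
                raise ValueError("coherence and coherence+group_delta must lie in [0, 1)")

    def coherence_for_group(self, group: int) -> float:
        return self.coherence + (self.group_delta if group == 2 else 0.0)

    @staticmethod
    def box(name: str, lo: tuple[int, int, int], hi: tuple[int, int, int],
            coherence: float, group_delta: float = 0.0) -> "RoiSpec":
        """Convenience: an axis-aligned box ROI with corners lo..hi inclusive."""
        xs, ys, zs = (np.arange(lo[i], hi[i] + 1) for i in range(3))
        grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
        return RoiSpec(name=name, voxels=grid, coherence=coherence, group_delta=group_delta)


@dataclass
class OutcomeModel:
    """Linear map from ROI-mean ReHo features to the reduction rate."""

    coefficients: np.ndarray
    intercept: float = 0.5
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=np.float64))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def mean_rr(self, features: np.ndarray) -> np.ndarray:
        feats = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if feats.shape[1] != self.coefficients.shape[0]:
            raise ValueError("feature count does not match coefficients")
        return self.intercept + feats @ self.coefficients


@dataclass
class CohortConfig:
    """Everything needed to regenerate a cohort bit-for-bit.

    Defaults favor fast experimentation (24^3 grid, 120 volumes); the
    acquisition being emulated uses 240 volumes at TR 2 s, available by
    setting ``n_timepoints=240``.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    n_per_group: int = 10
    rois: list[RoiSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    motion_amplitude: float = 0.3
    outcome_model: OutcomeModel | None = None
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    drop_volumes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.n_timepoints <= 10:
            raise ValueError("n_timepoints must exceed 10 (survives volume dropping)")
        if self.tr_seconds <= 0 or self.n_per_group <= 0 or self.noise_sd <= 0:
            raise ValueError("tr_seconds, n_per_group, noise_sd must be positive")
        if self.motion_amplitude < 0:
            raise ValueError("motion_amplitude must be nonnegative")
        for roi in self.rois:
            if (roi.voxels < 0).any() or (roi.voxels >= np.array(self.grid_shape)).any():
                raise ValueError(f"ROI {roi.name!r} extends outside the grid")
        if self.outcome_model is None:
            self.outcome_model = OutcomeModel(
                coefficients=np.zeros(len(self.rois)), intercept=0.5, noise_sd=0.05
            )
        if self.outcome_model.coefficients.shape[0] != len(self.rois):
            raise ValueError("outcome_model coefficient count must equal ROI count")


@dataclass
class SubjectRecord:
    """Group label, covariates and clinical scores for one subject."""

    subject_id: str
    group: int
    age: int
    sex: int  # 0/1
    education: int
    hama_baseline: int
    hama_week4: int
    hamd_baseline: int
    hamd_week4: int
    mean_fd: float = float("nan")


@dataclass
class SyntheticCohort:
    """Generated subjects plus the ground truth used to make them."""

    subjects: list[tuple[SubjectRecord, Bold4D, MotionTrace]]
    mask: BrainMask
    truth: dict
    config: CohortConfig

    @property
    def clinical_table(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(rec) for rec, _, _ in self.subjects])


def subject_seed(config_seed: int, stage: int, group: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-stage, per-subject seed derivation."""
    return np.random.SeedSequence([config_seed, stage, group, index])


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence([int(seed)])


def _child_seedseq(seq: np.random.SeedSequence, tag: int) -> np.random.SeedSequence:
    ent = seq.entropy if isinstance(seq.entropy, (list, tuple)) else [seq.entropy]
    return np.random.SeedSequence(list(ent) + [tag])


def interior_mask(grid_shape: tuple[int, int, int],
                  voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)) -> BrainMask:
    """Grid interior (1-voxel border excluded), so every in-mask voxel has
    a full 27-voxel neighborhood on the default fixture."""
    m = np.zeros(grid_shape, dtype=bool)
    m[1:-1, 1:-1, 1:-1] = True
    return BrainMask(data=m, affine=np.diag(list(voxel_size_mm) + [1.0]))


def generate_bold_subject(
    config: CohortConfig, group: int, subject_seed_seq,
) -> tuple[Bold4D, MotionTrace]:
    """One subject's 4D series and motion trace.

    Each voxel's series is sqrt(1-c) * iid noise + sqrt(c) * the ROI's
    shared latent series (c = 0 outside ROIs), scaled by ``noise_sd``.
    The motion trace is a bounded Gaussian random walk: translations
    clipped to +/- motion_amplitude mm, rotations to the radian
    equivalent on a 50 mm sphere.  Identical seeds give identical output.
    """
    if group not in (1, 2):
        raise ValueError("group must be 1 or 2")
    seq = _as_seedseq(subject_seed_seq)
    rng = np.random.default_rng(seq)
    T = config.n_timepoints
    shape = config.grid_shape

    data = rng.standard_normal(size=shape + (T,))
    for roi in config.rois:
        c = roi.coherence_for_group(group)
        latent = rng.standard_normal(size=T)
        ix = tuple(roi.voxels.T)
        data[ix] = np.sqrt(1.0 - c) * data[ix] + np.sqrt(c) * latent
    data *= config.noise_sd

    mrng = np.random.default_rng(_child_seedseq(seq, STAGE_MOTION))
    amp = config.motion_amplitude
    steps = mrng.standard_normal(size=(T, 6)) * (amp / 20.0)
    walk = np.cumsum(steps, axis=0)
    walk[:, :3] = np.clip(walk[:, :3], -amp, amp)
    walk[:, 3:] = np.clip(walk[:, 3:] / 50.0, -amp / 50.0, amp / 50.0)
    motion = MotionTrace(params=walk)

    bold = Bold4D(
        data=data,
        voxel_size_mm=config.voxel_size_mm,
        tr_seconds=config.tr_seconds,
    )
    return bold, motion


def generate_clinical_outcomes(
    config: CohortConfig,
    reho_features: np.ndarray,
    subject_seed_seqs: list,
    groups: list[int] | None = None,
) -> pd.DataFrame:
    """Covariates and clinical scores whose reduction rate follows the
    outcome model.

    Baseline HAMA/HAMD are uniform integers from the stated ranges; the
    exact (pre-rounding) reduction rate is the linear outcome model on
    ``reho_features`` plus Gaussian noise, and the integer week-4 score
    is back-computed from it and clipped at 0.  Exact RRs are returned in
    ``rr_hama_exact`` / ``rr_hamd_exact`` so tests need not fight the
    rounding of integer-valued scales.
    """
    feats = np.atleast_2d(np.asarray(reho_features, dtype=np.float64))
    n = feats.shape[0]
    if len(subject_seed_seqs) != n:
        raise ValueError("feature rows and subject seeds disagree")
    model = config.outcome_model
    assert model is not None
    mean_rr = model.mean_rr(feats)

    rows = []
    for i, seq in enumerate(subject_seed_seqs):
        rng = np.random.default_rng(_child_seedseq(_as_seedseq(seq), STAGE_CLINICAL))
        age = int(rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1))
        sex = int(rng.integers(0, 2))
        edu = int(rng.integers(EDUCATION_RANGE[0], EDUCATION_RANGE[1] + 1))
        hama0 = int(rng.integers(HAMA_BASELINE_RANGE[0], HAMA_BASELINE_RANGE[1] + 1))
        hamd0 = int(rng.integers(HAMD_BASELINE_RANGE[0], HAMD_BASELINE_RANGE[1] + 1))
        rr_hama = float(mean_rr[i] + rng.normal(0.0, model.noise_sd))
        rr_hamd = float(mean_rr[i] + rng.normal(0.0, model.noise_sd))
        hama4 = max(0, int(round(hama0 * (1.0 - rr_hama))))
        hamd4 = max(0, int(round(hamd0 * (1.0 - rr_hamd))))
        rows.append(
            {
                "age": age, "sex": sex, "education": edu,
                "hama_baseline": hama0, "hama_week4": hama4,
                "hamd_baseline": hamd0, "hamd_week4": hamd4,
                "rr_hama_exact": rr_hama, "rr_hamd_exact": rr_hamd,
                "group": (groups[i] if groups else 1),
            }
        )
    return pd.DataFrame(rows)


def roi_mean_reho_features(
    bold: Bold4D, mask: BrainMask, config: CohortConfig,
) -> np.ndarray:
    """ROI-mean raw Kendall's W after the standard temporal cleaning."""
    b = drop_initial_volumes(bold, config.drop_volumes)
    b = detrend_and_bandpass(b, mask)
    rmap = reho_map(b, mask)
    return np.array([rmap.data[tuple(roi.voxels.T)].mean() for roi in config.rois])


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full two-group cohort with ground truth.

    Group 2 uses coherence + group_delta in every ROI.  Outcome features
    are each subject's ROI-mean raw ReHo computed by actually running the
    temporal cleaning and ReHo mapping on the generated volumes, so the
    planted outcome structure survives the real pipeline.  The ``truth``
    block records per-group ROI coherences, the outcome model, the
    feature matrix and the exact reduction rates.
    """
    mask = interior_mask(config.grid_shape, config.voxel_size_mm)
    entries = []
    seed_seqs = []
    groups = []
    bolds = []
    motions = []
    for group in (1, 2):
        for i in range(config.n_per_group):
            seq = subject_seed(config.seed, STAGE_BOLD, group, i)
            bold, motion = generate_bold_subject(config, group, seq)
            seed_seqs.append(seq)
            groups.append(group)
            bolds.append(bold)
            motions.append(motion)

    if config.rois:
        features = np.stack(
            [roi_mean_reho_features(b, mask, config) for b in bolds]
        )
    else:
        features = np.zeros((len(bolds), 0))
    clin = generate_clinical_outcomes(config, features, seed_seqs, groups)

    for j, (group, bold, motion) in enumerate(zip(groups, bolds, motions)):
        row = clin.iloc[j]
        rec = SubjectRecord(
            subject_id=f"sub-{group}{j % config.n_per_group:03d}",
            group=group,
            age=int(row.age), sex=int(row.sex), education=int(row.education),
            hama_baseline=int(row.hama_baseline), hama_week4=int(row.hama_week4),
            hamd_baseline=int(row.hamd_baseline), hamd_week4=int(row.hamd_week4),
        )
        entries.append((rec, bold, motion))

    truth = {
        "roi_coherence": {
            roi.name: {"group1": roi.coherence, "group2": roi.coherence_for_group(2)}
            for roi in config.rois
        },
        "outcome_coefficients": config.outcome_model.coefficients.tolist(),  # type: ignore[union-attr]
        "outcome_intercept": config.outcome_model.intercept,  # type: ignore[union-attr]
        "outcome_noise_sd": config.outcome_model.noise_sd,  # type: ignore[union-attr]
        "features": features.tolist(),
        "rr_hama_exact": clin["rr_hama_exact"].tolist(),
        "rr_hamd_exact": clin["rr_hamd_exact"].tolist(),
        "groups": groups,
    }
    return SyntheticCohort(subjects=entries, mask=mask, truth=truth, config=config)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the cohort as NIfTI volumes, motion text files and a TSV table.

    Returns a manifest of the paths written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"subjects": []}
    mask_path = out / "mask.nii.gz"
    cohort.mask.to_nifti().to_filename(str(mask_path))
    paths["mask"] = str(mask_path)
    for rec, bold, motion in cohort.subjects:
        bp = out / f"{rec.subject_id}_bold.nii.gz"
        mp = out / f"{rec.subject_id}_motion.txt"
        bold.to_nifti().to_filename(str(bp))
        motion.save(mp)
        paths["subjects"].append(
            {"subject_id": rec.subject_id, "bold": str(bp), "motion": str(mp)}
        )
    clin_path = out / "clinical.tsv"
    cohort.clinical_table.to_csv(clin_path, sep="\t", index=False)
    paths["clinical"] = str(clin_path)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(cohort.truth, indent=1))
    paths["truth"] = str(truth_path)
    return paths
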