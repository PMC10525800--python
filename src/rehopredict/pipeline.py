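"""End-to-end orchestration: simulate -> QC -> ReHo -> group stats -> predict.

A single :class:`RunConfig` (YAML-serializable) drives the whole analysis;
every stage writes its artifacts under the output directory and records
content hashes in a manifest, so a rerun over a completed directory skips
stages whose parameters and outputs are unchanged, and two runs with the
same seed produce identical hashes.  One global seed expands into
per-stage, per-subject seeds through the counter scheme in
:mod:`rehopredict.synth`, so any subject's data can be regenerated in
isolation.

Group convention: group 1 is the control group, group 2 the patient group
(the one carrying the planted coherence offsets and whose reduction rates
are predicted).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import predict as pred
from . import stats as st
from .preprocess import (
    Bold4D,
    BrainMask,
    MotionTrace,
    detrend_and_bandpass,
    drop_initial_volumes,
    framewise_displacement,
    motion_screen,
)
from .reho import ReHoMap, normalize_and_smooth, reho_map
from .synth import CohortConfig, OutcomeModel, RoiSpec, generate_cohort, write_cohort

STAGES = ["simulate", "preprocess", "reho", "group_stats", "predict"]


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Small two-ROI cohort with strong planted group differences."""
    rois = [
        RoiSpec.box("roi_a", (4, 4, 4), (8, 8, 8), coherence=0.6, group_delta=-0.45),
        RoiSpec.box("roi_b", (14, 14, 14), (18, 18, 18), coherence=0.1, group_delta=0.5),
    ]
    return CohortConfig(
        rois=rois,
        n_per_group=12,
        outcome_model=OutcomeModel(
            coefficients=np.array([6.0, -4.0]), intercept=0.4, noise_sd=0.05
        ),
        seed=seed,
    )


@dataclass
class RunConfig:
    """Parameters for one reproducible end-to-end run."""

    out_dir: str = "run_output"
    seed: int = 0
    # synthetic-cohort stage (ignored when data_dir points at existing files)
    data_dir: str | None = None
    n_per_group: int = 12
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    # preprocessing
    drop_volumes: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.1
    trans_mm: float = 2.0
    rot_deg: float = 2.0
    head_radius_mm: float = 50.0
    # ReHo
    neighborhood_k: int = 27
    fwhm_mm: float = 4.0
    tie_correction: bool = False
    # group statistics
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    two_tailed: bool = True
    connectivity: int = 26
    correlation_n_tests: int = 9
    # prediction
    svr_mode: str = "paper"
    svr_c_exponents: tuple[int, ...] = tuple(range(-10, 11, 2))
    svr_gamma_exponents: tuple[int, ...] = tuple(range(-10, 11, 2))
    svr_epsilon: float = 0.1
    svr_n_folds: int = 5
    svr_standardize: bool = True
    n_perm: int = 100

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.grid_shape = tuple(cfg.grid_shape)
        cfg.svr_c_exponents = tuple(cfg.svr_c_exponents)
        cfg.svr_gamma_exponents = tuple(cfg.svr_gamma_exponents)
        return cfg

    def svr_config(self) -> pred.SvrConfig:
        return pred.SvrConfig(
            c_exponents=self.svr_c_exponents,
            gamma_exponents=self.svr_gamma_exponents,
            epsilon=self.svr_epsilon,
            n_folds=self.svr_n_folds,
            mode=self.svr_mode,
            standardize=self.svr_standardize,
            seed=self.seed,
        )


def validate_config(config: RunConfig) -> list[str]:
    """All invariant violations in the config; empty list means valid."""
    v = []
    if not (0 < config.voxel_p < 1):
        v.append(f"voxel_p must be in (0, 1), got {config.voxel_p}")
    if not (0 < config.cluster_p < 1):
        v.append(f"cluster_p must be in (0, 1), got {config.cluster_p}")
    if config.svr_n_folds < 2:
        v.append(f"svr_n_folds must be >= 2, got {config.svr_n_folds}")
    if config.n_perm < 1:
        v.append(f"n_perm must be >= 1, got {config.n_perm}")
    if config.neighborhood_k not in (7, 19, 27):
        v.append(f"neighborhood_k must be 7, 19 or 27, got {config.neighborhood_k}")
    if config.connectivity not in (6, 18, 26):
        v.append(f"connectivity must be 6, 18 or 26, got {config.connectivity}")
    if not (0 < config.low_hz < config.high_hz):
        v.append("need 0 < low_hz < high_hz")
    if config.high_hz > 1.0 / (2.0 * config.tr_seconds) + 1e-12:
        v.append("high_hz exceeds the Nyquist frequency for tr_seconds")
    if config.drop_volumes < 0 or config.drop_volumes >= config.n_timepoints:
        v.append("drop_volumes must be in [0, n_timepoints)")
    if config.fwhm_mm < 0:
        v.append("fwhm_mm must be nonnegative")
    if config.svr_mode not in ("paper", "nested"):
        v.append(f"svr_mode must be 'paper' or 'nested', got {config.svr_mode}")
    if config.data_dir is not None and not Path(config.data_dir).exists():
        v.append(f"data_dir does not exist: {config.data_dir}")
    if config.n_per_group < 1:
        v.append("n_per_group must be positive")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Manifest:
    """Per-stage record of parameters, output hashes and warnings."""

    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data: dict = {"stages": {}, "warnings": [], "excluded_subjects": []}
        if self.path.exists():
            try:
                self.data = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                pass

    def stage_fresh(self, name: str, params_hash: str) -> bool:
        """True when the stage's recorded outputs exist unchanged."""
        entry = self.data["stages"].get(name)
        if not entry or entry.get("params_hash") != params_hash:
            return False
        for p, digest in entry.get("outputs", {}).items():
            path = Path(p)
            if not path.exists() or _sha256(path) != digest:
                return False
        return True

    def record(self, name: str, params_hash: str, outputs: list[Path],
               skipped: bool, t0: float, warnings_: list[str]) -> None:
        self.data["stages"][name] = {
            "params_hash": params_hash,
            "outputs": {str(p): _sha256(p) for p in outputs},
            "skipped": skipped,
            "wall_seconds": round(time.time() - t0, 3),
            "stamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "warnings": warnings_,
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


@dataclass
class RunManifest:
    """Returned summary of an end-to-end run."""

    out_dir: str
    stages: dict
    excluded_subjects: list[str]
    cluster_table: pd.DataFrame | None = None
    correlation_table: pd.DataFrame | None = None
    svr_report: dict | None = None


def _load_subjects(data_dir: Path):
    clin = pd.read_csv(data_dir / "clinical.tsv", sep="\t")
    mask = BrainMask.from_nifti(data_dir / "mask.nii.gz")
    subjects = []
    for _, row in clin.iterrows():
        sid = row["subject_id"]
        subjects.append(
            {
                "subject_id": sid,
                "group": int(row["group"]),
                "record": row,
                "bold_path": data_dir / f"{sid}_bold.nii.gz",
                "motion_path": data_dir / f"{sid}_motion.txt",
            }
        )
    return subjects, mask, clin


def run_end_to_end(config: RunConfig) -> RunManifest:
    """Execute all stages in order, skipping up-to-date ones.

    Subjects failing motion screening are excluded from every downstream
    stage; the exclusion list is logged in the manifest.  Any stage
    failure aborts with the stage name attached.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    caught: list[str] = []

    def run_stage(name, params, produce):
        ph = _params_hash(params)
        t0 = time.time()
        entry = manifest.data["stages"].get(name, {})
        if manifest.stage_fresh(name, ph):
            manifest.data["stages"][name]["skipped"] = True
            manifest.save()
            return [Path(p) for p in entry.get("outputs", {})]
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                outputs = produce()
            msgs = [str(w.message) for w in wlist]
        except Exception as exc:  # noqa: BLE001 - reraise with stage context
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, ph, outputs, False, t0, msgs)
        caught.extend(msgs)
        return outputs

    # ---- stage 1: simulate (or point at existing data) -------------------
    data_dir = Path(config.data_dir) if config.data_dir else out / "data"

    def _simulate():
        ccfg = default_cohort_config(config.seed)
        ccfg.n_per_group = config.n_per_group
        ccfg.grid_shape = config.grid_shape
        ccfg.n_timepoints = config.n_timepoints
        ccfg.tr_seconds = config.tr_seconds
        ccfg.drop_volumes = config.drop_volumes
        cohort = generate_cohort(ccfg)
        paths = write_cohort(cohort, data_dir)
        files = [Path(paths["mask"]), Path(paths["clinical"]), Path(paths["truth"])]
        for s in paths["subjects"]:
            files += [Path(s["bold"]), Path(s["motion"])]
        return files

    if config.data_dir is None:
        run_stage(
            "simulate",
            {"seed": config.seed, "n_per_group": config.n_per_group,
             "grid": config.grid_shape, "t": config.n_timepoints,
             "tr": config.tr_seconds},
            _simulate,
        )
    subjects, mask, clin = _load_subjects(data_dir)

    # ---- stage 2: preprocess QC ------------------------------------------
    qc_path = out / "qc.tsv"

    def _preprocess():
        rows = []
        for s in subjects:
            motion = MotionTrace.load(s["motion_path"])
            qc = motion_screen(
                motion, config.trans_mm, config.rot_deg, config.head_radius_mm
            )
            rows.append(
                {
                    "subject_id": s["subject_id"],
                    "max_abs_translation_mm": qc.max_abs_translation_mm,
                    "max_abs_rotation_deg": qc.max_abs_rotation_deg,
                    "mean_fd": qc.mean_fd,
                    "excluded": qc.excluded,
                }
            )
        pd.DataFrame(rows).to_csv(qc_path, sep="\t", index=False)
        return [qc_path]

    run_stage(
        "preprocess",
        {"trans": config.trans_mm, "rot": config.rot_deg,
         "radius": config.head_radius_mm, "subjects": [s["subject_id"] for s in subjects]},
        _preprocess,
    )
    qc = pd.read_csv(qc_path, sep="\t").set_index("subject_id")
    excluded = sorted(qc.index[qc["excluded"]].tolist())
    manifest.data["excluded_subjects"] = excluded
    manifest.save()
    kept = [s for s in subjects if s["subject_id"] not in excluded]

    # ---- stage 3: ReHo maps ----------------------------------------------
    reho_dir = out / "reho"

    def _reho():
        reho_dir.mkdir(exist_ok=True)
        files = []
        for s in kept:
            bold = Bold4D.from_nifti(s["bold_path"])
            bold = drop_initial_volumes(bold, config.drop_volumes)
            bold = detrend_and_bandpass(bold, mask, config.low_hz, config.high_hz)
            rmap = reho_map(bold, mask, config.neighborhood_k, config.tie_correction)
            smap = normalize_and_smooth(rmap, mask, config.fwhm_mm)
            p = reho_dir / f"{s['subject_id']}_reho.nii.gz"
            smap.to_nifti().to_filename(str(p))
            files.append(p)
        return files

    run_stage(
        "reho",
        {"k": config.neighborhood_k, "fwhm": config.fwhm_mm,
         "tie": config.tie_correction, "band": [config.low_hz, config.high_hz],
         "drop": config.drop_volumes, "subjects": [s["subject_id"] for s in kept]},
        _reho,
    )

    def _load_map(sid) -> ReHoMap:
        import nibabel as nib

        img = nib.load(str(reho_dir / f"{sid}_reho.nii.gz"))
        return ReHoMap(
            data=np.asanyarray(img.dataobj, dtype=np.float64),
            stage="smoothed",
            neighborhood_k=config.neighborhood_k,
            n_timepoints_used=config.n_timepoints - config.drop_volumes,
            voxel_size_mm=tuple(float(z) for z in img.header.get_zooms()[:3]),
            affine=np.asarray(img.affine),
        )

    maps = [_load_map(s["subject_id"]) for s in kept]
    groups = np.array([s["group"] for s in kept])
    covs = np.column_stack(
        [
            [float(s["record"]["age"]) for s in kept],
            [float(s["record"]["sex"]) for s in kept],
            [float(s["record"]["education"]) for s in kept],
            [float(qc.loc[s["subject_id"], "mean_fd"]) for s in kept],
        ]
    )

    # ---- stage 4: group statistics ---------------------------------------
    clusters_path = out / "clusters.tsv"
    corr_path = out / "correlations.tsv"
    voxels_path = out / "cluster_voxels.json"

    def _group_stats():
        design = st.DesignMatrix.two_sample(
            groups, covs, ["age", "sex", "education", "mean_fd"]
        )
        tmap = st.voxelwise_glm_contrast(maps, design, mask)
        smooth = st.estimate_smoothness_fwhm(
            tmap.residuals, mask, maps[0].voxel_size_mm
        )
        n1 = int((groups == groups.min()).sum())
        n2 = int((groups == groups.max()).sum())
        table = st.grf_cluster_table(
            tmap, smooth, mask,
            voxel_p=config.voxel_p, cluster_p=config.cluster_p,
            two_tailed=config.two_tailed, connectivity=config.connectivity,
            n1=n1, n2=n2, kind="two_sample", keep_voxel_lists=True,
        )
        vox = {str(i): r["_voxels"].tolist() for i, r in table.iterrows()}
        voxels_path.write_text(json.dumps(vox))
        table.drop(columns=["_voxels"]).to_csv(clusters_path, sep="\t", index=False)

        # symptom correlations among patients (group 2): cluster means vs
        # baseline severity
        pat = groups == 2
        if len(table) and pat.sum() >= 3:
            feats = _cluster_features(maps, table, pat)
            scores = pd.DataFrame(
                {
                    "hama_baseline": [float(s["record"]["hama_baseline"]) for s in kept],
                    "hamd_baseline": [float(s["record"]["hamd_baseline"]) for s in kept],
                }
            ).loc[pat]
            corr = st.correlate_with_symptoms(
                feats, scores.reset_index(drop=True),
                method="auto", n_tests=config.correlation_n_tests,
            )
        else:
            corr = pd.DataFrame(
                columns=["feature", "score", "method", "r", "p", "significant_bonferroni"]
            )
        corr.to_csv(corr_path, sep="\t", index=False)
        return [clusters_path, corr_path, voxels_path]

    def _cluster_features(all_maps, table, subject_sel) -> pd.DataFrame:
        vox = json.loads(voxels_path.read_text()) if voxels_path.exists() else None
        cols = {}
        for i, row in table.reset_index(drop=True).iterrows():
            if "_voxels" in table.columns and row.get("_voxels") is not None:
                idx = np.asarray(row["_voxels"])
            else:
                idx = np.asarray(vox[str(i)])
            sel = tuple(idx.T)
            cols[f"cluster_{i}_{row['sign']}"] = [
                float(m.data[sel].mean())
                for m, keep_flag in zip(all_maps, subject_sel)
                if keep_flag
            ]
        return pd.DataFrame(cols)

    run_stage(
        "group_stats",
        {"voxel_p": config.voxel_p, "cluster_p": config.cluster_p,
         "two_tailed": config.two_tailed, "conn": config.connectivity,
         "subjects": [s["subject_id"] for s in kept]},
        _group_stats,
    )
    cluster_table = pd.read_csv(clusters_path, sep="\t")
    corr_table = pd.read_csv(corr_path, sep="\t")

    # ---- stage 5: prediction ---------------------------------------------
    svr_path = out / "svr_run.json"

    def _predict():
        pat = groups == 2
        report: dict = {"n_patients": int(pat.sum())}
        if len(cluster_table) == 0:
            report["status"] = "skipped: no significant clusters to use as features"
        elif pat.sum() < 10:
            report["status"] = "skipped: fewer than 10 patients"
        else:
            vox = json.loads(voxels_path.read_text())
            feats = np.column_stack(
                [
                    [m.data[tuple(np.asarray(vox[str(i)]).T)].mean()
                     for m, k in zip(maps, pat) if k]
                    for i in range(len(cluster_table))
                ]
            )
            report["status"] = "ok"
            scfg = config.svr_config()
            for scale in ("hama", "hamd"):
                rr = np.array(
                    [
                        pred.reduction_rate(
                            float(s["record"][f"{scale}_baseline"]),
                            float(s["record"][f"{scale}_week4"]),
                        )
                        for s, k in zip(kept, pat)
                        if k
                    ]
                )
                run = pred.permutation_significance(feats, rr, scfg, n_perm=config.n_perm)
                report[scale] = run.to_dict()
        svr_path.write_text(json.dumps(report, indent=1))
        return [svr_path]

    run_stage(
        "predict",
        {"svr": asdict(config)["svr_mode"], "grid_c": config.svr_c_exponents,
         "grid_g": config.svr_gamma_exponents, "n_perm": config.n_perm,
         "seed": config.seed, "clusters": len(cluster_table)},
        _predict,
    )
    svr_report = json.loads(svr_path.read_text())

    _write_summary(out, manifest, cluster_table, corr_table, svr_report)
    return RunManifest(
        out_dir=str(out),
        stages=manifest.data["stages"],
        excluded_subjects=excluded,
        cluster_table=cluster_table,
        correlation_table=corr_table,
        svr_report=svr_report,
    )


def _write_summary(out: Path, manifest: _Manifest, clusters: pd.DataFrame,
                   corr: pd.DataFrame, svr: dict) -> None:
    lines = ["# Run summary", ""]
    for name, entry in manifest.data["stages"].items():
        tag = "skipped" if entry.get("skipped") else f"{entry['wall_seconds']}s"
        lines.append(f"- stage `{name}`: {tag}, {len(entry['outputs'])} output(s)")
    if manifest.data.get("excluded_subjects"):
        lines.append(f"- excluded subjects: {manifest.data['excluded_subjects']}")
    lines += ["", f"## Clusters ({len(clusters)})", "", clusters.to_string(), ""]
    if len(corr):
        lines += ["## Symptom correlations", "", corr.to_string(), ""]
    lines += ["## Prediction", "", "```json", json.dumps(
        {k: (v if not isinstance(v, dict) else {kk: v[kk] for kk in
             ("mse", "pearson_r", "p_r", "p_mse") if kk in v})
         for k, v in svr.items()}, indent=1), "```"]
    (out / "summary.md").write_text("\n".join(lines))
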