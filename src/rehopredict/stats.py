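"""Voxelwise group inference with Gaussian-random-field cluster correction.

The pipeline stage this module implements: per-voxel ordinary-least-squares
contrasts (two-sample with nuisance covariates, or paired), residual-based
smoothness (FWHM / RESEL) estimation, cluster-extent correction using the
classic Gaussian-field results (expected Euler characteristic for the
number of clusters, a stretched-exponential tail for cluster size), a
label/sign permutation oracle as an assumption-free cross-check, Cohen's d
effect sizes, and the small-table utilities used for cohort matching and
symptom correlations.

Cluster-extent corrected p, for a cluster of k voxels at z threshold u:

    E[m]   = R * (4 ln 2)^{3/2} (u^2 - 1) exp(-u^2/2) / (2 pi)^2
    nbar   = V * P(Z > u) / E[m]
    beta   = (Gamma(5/2) / nbar)^{2/3}
    P(n>=k)= exp(-beta * k^{2/3})
    p_corr = 1 - exp(-E[m] * P(n >= k))

with R the RESEL count, V the mask volume in voxels, and nbar the expected
cluster size.  "Two-tailed" follows the toolbox convention: each tail is
thresholded at voxel_p/2 and tested at cluster_p/2, positive and negative
clusters reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from scipy.special import gamma as gamma_fn

from .preprocess import BrainMask
from .reho import ReHoMap

_CONNECTIVITY = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Subjects-by-regressors design with the contrast of interest.

    Columns are intercept, the group/condition contrast column, then any
    nuisance covariates (age, sex, education, mean FD).  ``contrast``
    selects the tested combination.
    """

    X: np.ndarray
    contrast: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        if self.contrast.shape != (self.X.shape[1],):
            raise ValueError("contrast length must equal the number of columns")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if not self.column_names:
            self.column_names = [f"x{i}" for i in range(self.X.shape[1])]

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @classmethod
    def two_sample(
        cls,
        group: np.ndarray,
        covariates: np.ndarray | None = None,
        covariate_names: list[str] | None = None,
    ) -> "DesignMatrix":
        """Intercept + group indicator (+ centered covariates); contrast on
        the group column (group 2 minus group 1 for labels {1, 2})."""
        group = np.asarray(group)
        levels = np.unique(group)
        if len(levels) != 2:
            raise ValueError("two_sample design needs exactly 2 group levels")
        ind = (group == levels[1]).astype(np.float64)
        cols = [np.ones(len(group)), ind]
        names = ["intercept", "group"]
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
            if cov.shape[0] != len(group):
                cov = cov.T
            cov = cov - cov.mean(axis=0)
            cols.extend(cov.T)
            names.extend(
                covariate_names
                or [f"cov{i}" for i in range(cov.shape[1])]
            )
        X = np.column_stack(cols)
        contrast = np.zeros(X.shape[1])
        contrast[1] = 1.0
        return cls(X=X, contrast=contrast, column_names=names)


@dataclass
class TStatMap:
    """Voxelwise t statistics with degrees of freedom and standardized residuals."""

    data: np.ndarray
    df: int
    design_summary: str = ""
    residuals: np.ndarray | None = None  # (n_subjects, x, y, z) standardized
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])


@dataclass
class SmoothnessEstimate:
    """Per-axis FWHM of the residual field and the implied RESEL count."""

    fwhm_mm: tuple[float, float, float]
    fwhm_vox: tuple[float, float, float]
    resel_count: float
    method: str = "residual first-differences"

    def __post_init__(self) -> None:
        if any(not np.isfinite(f) or f <= 0 for f in self.fwhm_mm):
            raise ValueError("smoothness FWHM must be finite and positive")
        if not np.isfinite(self.resel_count) or self.resel_count <= 0:
            raise ValueError("resel count must be finite and positive")


#: ClusterTable columns, mirroring the usual published cluster-report shape
CLUSTER_COLUMNS = [
    "sign", "peak_x_mm", "peak_y_mm", "peak_z_mm",
    "n_voxels", "peak_t", "p_corrected", "df", "cohens_d",
]


def _empty_cluster_table() -> pd.DataFrame:
    return pd.DataFrame(columns=CLUSTER_COLUMNS)


# ---------------------------------------------------------------------------
# voxelwise GLM
# ---------------------------------------------------------------------------

def _stack_maps(maps) -> np.ndarray:
    arrs = [m.data if isinstance(m, ReHoMap) else np.asarray(m, dtype=np.float64) for m in maps]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError("all maps must share one grid shape")
    return np.stack(arrs, axis=0)


def voxelwise_glm_contrast(
    maps,
    design: DesignMatrix,
    mask: BrainMask,
) -> TStatMap:
    """Per-voxel OLS contrast t map over a stack of subject maps.

    t = c'beta / sqrt(sigma2 * c'(X'X)^{-1}c) with df = n - rank(X);
    voxels with zero residual variance get t = 0 with a warning.
    Standardized residual images are retained on the returned map for
    smoothness estimation.
    """
    Y4 = _stack_maps(maps)
    if Y4.shape[0] != design.n_subjects:
        raise ValueError("one map per design row required")
    if Y4.shape[1:] != mask.data.shape:
        raise ValueError("map grid does not match mask")
    m = mask.data
    Y = Y4[:, m]  # (n, v)

    X = design.X
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("nonpositive degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    rss = (resid ** 2).sum(axis=0)
    sigma2 = rss / df
    c = design.contrast
    cvar = float(c @ xtx_inv @ c)
    se = np.sqrt(sigma2 * cvar)

    tvals = np.zeros(Y.shape[1])
    # residual SS that is zero up to float roundoff counts as degenerate
    scale = (Y ** 2).sum(axis=0)
    ok = rss > scale * 1e-24
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} voxel(s) with zero residual variance; t set to 0",
            RuntimeWarning,
        )
    tvals[ok] = (c @ beta)[ok] / se[ok]

    with np.errstate(invalid="ignore", divide="ignore"):
        std_resid = np.where(ok, resid / np.sqrt(np.maximum(sigma2, 1e-300)), 0.0)

    tmap = np.zeros(mask.data.shape)
    tmap[m] = tvals
    res4 = np.zeros((n,) + mask.data.shape)
    res4[:, m] = std_resid

    first = maps[0]
    vsize = first.voxel_size_mm if isinstance(first, ReHoMap) else (3.0, 3.0, 3.0)
    aff = first.affine if isinstance(first, ReHoMap) else None
    return TStatMap(
        data=tmap,
        df=df,
        design_summary=f"OLS contrast over columns {design.column_names}",
        residuals=res4,
        voxel_size_mm=tuple(vsize),
        affine=aff,
    )


def paired_t_map(pre_maps, post_maps, mask: BrainMask) -> TStatMap:
    """One-sample t on per-subject (post - pre) differences; df = n - 1.

    Voxels where every subject shows an identical difference (sd = 0) get
    t = 0 with a warning rather than +/-inf.
    """
    pre = _stack_maps(pre_maps)
    post = _stack_maps(post_maps)
    if pre.shape != post.shape:
        raise ValueError("pre and post stacks must match in subjects and grid")
    n = pre.shape[0]
    if n < 2:
        raise ValueError("paired t needs at least 2 subjects")
    diff4 = post - pre
    m = mask.data
    D = diff4[:, m]
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    tvals = np.zeros(D.shape[1])
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} voxel(s) with zero difference sd; t set to 0",
            RuntimeWarning,
        )
    tvals[ok] = mean[ok] / (sd[ok] / np.sqrt(n))

    with np.errstate(invalid="ignore", divide="ignore"):
        std_resid = np.where(ok, (D - mean) / np.maximum(sd, 1e-300), 0.0)

    tmap = np.zeros(mask.data.shape)
    tmap[m] = tvals
    res4 = np.zeros((n,) + mask.data.shape)
    res4[:, m] = std_resid

    first = pre_maps[0]
    vsize = first.voxel_size_mm if isinstance(first, ReHoMap) else (3.0, 3.0, 3.0)
    aff = first.affine if isinstance(first, ReHoMap) else None
    return TStatMap(
        data=tmap,
        df=n - 1,
        design_summary="paired one-sample t on post-pre differences",
        residuals=res4,
        voxel_size_mm=tuple(vsize),
        affine=aff,
    )


# ---------------------------------------------------------------------------
# smoothness and GRF cluster correction
# ---------------------------------------------------------------------------

def estimate_smoothness_fwhm(
    residual_maps: np.ndarray,
    mask: BrainMask,
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> SmoothnessEstimate:
    """FWHM of the residual field from spatial first differences.

    The classic derivative-based estimator: for a unit-variance Gaussian
    field the roughness along an axis is approximated by v, the variance
    of first differences, and FWHM = sqrt(4 ln 2 / v) voxels.  Residual
    images are rescaled to unit in-mask variance, v pooled over images,
    and the RESEL count is mask volume divided by the product of
    per-axis voxel FWHMs.  (For unsmoothed white noise v = 2, giving
    ~1.18 voxels; the estimator is meant for the smooth fields GRF
    theory assumes.)
    """
    res = np.asarray(residual_maps, dtype=np.float64)
    if res.ndim == 3:
        res = res[None]
    if res.shape[0] < 3:
        raise ValueError("need at least 3 residual maps")
    m = mask.data
    if res.shape[1:] != m.shape:
        raise ValueError("residual grid does not match mask")

    sd = res[:, m].std(axis=1, ddof=1)
    keep = sd > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 non-degenerate residual maps")
    res = res[keep] / sd[keep][:, None, None, None]

    fwhm_vox = []
    for ax in range(3):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(0, -1)
        pair = m[tuple(sl_hi)] & m[tuple(sl_lo)]
        if not pair.any():
            raise ValueError(f"mask has no neighbor pairs along axis {ax}")
        d = res[(slice(None),) + tuple(sl_hi)] - res[(slice(None),) + tuple(sl_lo)]
        v = max(float((d[:, pair] ** 2).mean()), 1e-12)
        fwhm_vox.append(float(np.sqrt(4.0 * np.log(2.0) / v)))

    fwhm_mm = tuple(f * s for f, s in zip(fwhm_vox, voxel_size_mm))
    resels = mask.n_voxels / float(np.prod(fwhm_vox))
    return SmoothnessEstimate(
        fwhm_mm=fwhm_mm, fwhm_vox=tuple(fwhm_vox), resel_count=resels
    )


def _grf_cluster_p(extent: int, z_thr: float, resels: float, n_mask: int) -> float:
    """Corrected p for one cluster of ``extent`` voxels at z threshold."""
    u = z_thr
    # expected number of clusters: 3D Euler-characteristic density x resels
    rho3 = (4.0 * np.log(2.0)) ** 1.5 * (u * u - 1.0) * np.exp(-u * u / 2.0) / (2.0 * np.pi) ** 2
    e_m = max(resels * rho3, 1e-300)
    nbar = max(n_mask * sps.norm.sf(u) / e_m, 1e-300)  # expected cluster size, voxels
    beta = (gamma_fn(2.5) / nbar) ** (2.0 / 3.0)
    p_ext = np.exp(-beta * extent ** (2.0 / 3.0))
    # -expm1 keeps tiny probabilities positive instead of rounding to 0
    return float(max(-np.expm1(-e_m * p_ext), 1e-300))


def _extract_clusters(
    tmap: TStatMap,
    mask: BrainMask,
    t_thr: float,
    z_thr: float,
    cluster_alpha: float,
    smoothness: SmoothnessEstimate | None,
    connectivity: int,
    n1: int | None,
    n2: int | None,
    kind: str,
    paired_d_formula: str,
    all_clusters: bool = False,
) -> list[dict]:
    """Threshold both tails, label components, score each cluster."""
    rows = []
    structure = _CONNECTIVITY[connectivity]
    for sign, signed in (("+", tmap.data), ("-", -tmap.data)):
        supra = (signed > t_thr) & mask.data
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            idx = np.argwhere(labels == lab)
            extent = idx.shape[0]
            vals = signed[labels == lab]
            peak_local = idx[np.argmax(vals)]
            peak_t = float(tmap.data[tuple(peak_local)])
            if smoothness is not None:
                p_corr = _grf_cluster_p(
                    extent, z_thr, smoothness.resel_count, mask.n_voxels
                )
            else:
                p_corr = np.nan
            if not all_clusters and np.isfinite(p_corr) and p_corr > cluster_alpha:
                continue
            world = tmap.affine @ np.append(peak_local, 1.0)
            d = cohens_d_from_t(
                peak_t, kind=kind, n1=n1 or 0, n2=n2,
                paired_formula=paired_d_formula,
            ) if n1 else np.nan
            rows.append(
                {
                    "sign": sign,
                    "peak_x_mm": float(world[0]),
                    "peak_y_mm": float(world[1]),
                    "peak_z_mm": float(world[2]),
                    "n_voxels": int(extent),
                    "peak_t": peak_t,
                    "p_corrected": p_corr,
                    "df": tmap.df,
                    "cohens_d": d,
                    "_voxels": idx,
                }
            )
    rows.sort(key=lambda r: -r["n_voxels"])
    return rows


def grf_cluster_table(
    tmap: TStatMap,
    smoothness: SmoothnessEstimate,
    mask: BrainMask,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    two_tailed: bool = True,
    connectivity: int = 26,
    n1: int | None = None,
    n2: int | None = None,
    kind: str = "two_sample",
    paired_d_formula: str = "t_over_sqrt_n",
    keep_voxel_lists: bool = False,
) -> pd.DataFrame:
    """GRF cluster-extent corrected cluster table at the given thresholds.

    Two-tailed inference splits both the voxel threshold and the cluster
    alpha across the tails (voxel_p/2 and cluster_p/2 per tail); set
    ``two_tailed=False`` for a single positive-tail test at the full
    levels.  The t threshold is the Student quantile at the per-tail
    voxel p; the matching Gaussian quantile enters the GRF formulas.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("voxel_p and cluster_p must be in (0, 1)")
    if tmap.df < 1:
        raise ValueError("df must be >= 1")
    tail_p = voxel_p / 2.0 if two_tailed else voxel_p
    tail_alpha = cluster_p / 2.0 if two_tailed else cluster_p
    t_thr = float(sps.t.isf(tail_p, tmap.df))
    z_thr = float(sps.norm.isf(tail_p))

    rows = _extract_clusters(
        tmap, mask, t_thr, z_thr, tail_alpha, smoothness, connectivity,
        n1, n2, kind, paired_d_formula,
    )
    if not two_tailed:
        rows = [r for r in rows if r["sign"] == "+"]
    if not keep_voxel_lists:
        for r in rows:
            r.pop("_voxels")
    cols = CLUSTER_COLUMNS + (["_voxels"] if keep_voxel_lists else [])
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def permutation_cluster_oracle(
    maps,
    design: DesignMatrix | None,
    mask: BrainMask,
    voxel_p: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    two_tailed: bool = True,
    connectivity: int = 26,
    paired_diffs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Max-cluster-extent permutation test, the distribution-free cross-check.

    Two-sample designs permute the group column of the design; paired
    designs (pass the per-subject difference stack via ``paired_diffs``)
    flip difference signs.  Corrected p for an observed cluster of extent
    k is (1 + #{null max extent >= k}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p", RuntimeWarning)
    rng = np.random.default_rng(seed)
    tail_p = voxel_p / 2.0 if two_tailed else voxel_p

    if paired_diffs is not None:
        diffs = np.asarray(paired_diffs, dtype=np.float64)
        n = diffs.shape[0]
        zeros = np.zeros_like(diffs)

        def observed_tmap() -> TStatMap:
            return paired_t_map(zeros, diffs, mask)

        def null_tmap() -> TStatMap:
            signs = rng.choice([-1.0, 1.0], size=n)
            return paired_t_map(zeros, diffs * signs[:, None, None, None], mask)
    else:
        if design is None:
            raise ValueError("need a design (or paired_diffs)")
        gcol = design.X[:, 1]
        if np.unique(gcol).size < 2:
            raise ValueError("nothing to permute: all subjects in one group")

        def observed_tmap() -> TStatMap:
            return voxelwise_glm_contrast(maps, design, mask)

        def null_tmap() -> TStatMap:
            perm = rng.permutation(len(gcol))
            Xp = design.X.copy()
            Xp[:, 1] = gcol[perm]
            dperm = DesignMatrix(Xp, design.contrast, list(design.column_names))
            return voxelwise_glm_contrast(maps, dperm, mask)

    def max_extent(tm: TStatMap) -> tuple[int, list[dict]]:
        t_thr = float(sps.t.isf(tail_p, tm.df))
        rows = _extract_clusters(
            tm, mask, t_thr, z_thr=sps.norm.isf(tail_p), cluster_alpha=1.0,
            smoothness=None, connectivity=connectivity,
            n1=None, n2=None, kind="two_sample",
            paired_d_formula="t_over_sqrt_n", all_clusters=True,
        )
        return (max((r["n_voxels"] for r in rows), default=0), rows)

    obs_t = observed_tmap()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, obs_rows = max_extent(obs_t)
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            null_max[i], _ = max_extent(null_tmap())

    for r in obs_rows:
        r["p_corrected"] = float(
            (1 + (null_max >= r["n_voxels"]).sum()) / (n_perm + 1)
        )
        r.pop("_voxels")
    obs_rows.sort(key=lambda r: -r["n_voxels"])
    return pd.DataFrame(obs_rows, columns=CLUSTER_COLUMNS) if obs_rows else _empty_cluster_table()


# ---------------------------------------------------------------------------
# effect sizes, matching, correlations
# ---------------------------------------------------------------------------

def cohens_d_from_t(
    t: float,
    kind: str,
    n1: int,
    n2: int | None = None,
    paired_formula: str = "t_over_sqrt_n",
) -> float:
    """Cohen's d recovered from a t statistic and the group sizes.

    two_sample: d = t * sqrt(1/n1 + 1/n2).  paired: d = t / sqrt(n) by
    default; ``paired_formula="t_times_2_over_sqrt_df"`` selects the
    repeated-measures variant d = 2t / sqrt(df).  The paired conversion
    is configurable because published tables are not consistent about it.
    """
    if kind == "two_sample":
        if n1 <= 0 or n2 is None or n2 <= 0:
            raise ValueError("two_sample d needs positive n1 and n2")
        return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))
    if kind == "paired":
        if n1 <= 0:
            raise ValueError("paired d needs positive n")
        if paired_formula == "t_over_sqrt_n":
            return float(t / np.sqrt(n1))
        if paired_formula == "t_times_2_over_sqrt_df":
            return float(2.0 * t / np.sqrt(n1 - 1))
        raise ValueError(f"unknown paired_formula {paired_formula!r}")
    raise ValueError(f"unknown kind {kind!r}")


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table.

    Returns (statistic, df=1, Cramer's V).  This is the cohort-matching
    check applied to e.g. a sex-by-group table.
    """
    tab = np.asarray(table, dtype=np.float64).reshape(2, 2)
    if (tab < 0).any():
        raise ValueError("counts must be nonnegative")
    n = tab.sum()
    row = tab.sum(axis=1)
    col = tab.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    expected = np.outer(row, col) / n
    chi2 = float(((tab - expected) ** 2 / expected).sum())
    return chi2, 1, float(np.sqrt(chi2 / n))


def correlate_with_symptoms(
    cluster_features: pd.DataFrame,
    scores: pd.DataFrame,
    method: str = "auto",
    n_tests: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate per-cluster imaging features with clinical scores.

    ``method="auto"`` uses Pearson only when both columns pass a
    Shapiro-Wilk normality test at 0.05 and Spearman otherwise; the
    significance flag applies a Bonferroni-corrected threshold
    alpha / n_tests (n_tests defaults to the number of pairs computed).
    """
    if method not in ("pearson", "spearman", "auto"):
        raise ValueError("method must be pearson, spearman or auto")
    pairs = [(f, s) for f in cluster_features.columns for s in scores.columns]
    if n_tests is None:
        n_tests = len(pairs)
    rows = []
    for feat, score in pairs:
        x = np.asarray(cluster_features[feat], dtype=np.float64)
        y = np.asarray(scores[score], dtype=np.float64)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 complete pairs for ({feat}, {score})")
        x, y = x[ok], y[ok]
        use = method
        if method == "auto":
            normal = (
                sps.shapiro(x).pvalue > 0.05 and sps.shapiro(y).pvalue > 0.05
            )
            use = "pearson" if normal else "spearman"
        if use == "pearson":
            r, p = sps.pearsonr(x, y)
        else:
            r, p = sps.spearmanr(x, y)
        rows.append(
            {
                "feature": feat,
                "score": score,
                "method": use,
                "r": float(r),
                "p": float(p),
                "significant_bonferroni": bool(p < alpha / n_tests),
            }
        )
    return pd.DataFrame(rows)
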