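# Methods

This note documents the models, numerical choices and limitations behind
`rehopredict`, in the order the pipeline runs.

## Synthetic cohorts

The generator emulates a two-group resting-state study: per subject a 4D
BOLD grid (default 24×24×24 voxels of 3 mm, 120 volumes at TR = 2 s; the
emulated acquisition uses 240 volumes and is available by setting
`n_timepoints=240` — the shorter default exists purely for run time), a
six-parameter motion trace, demographic covariates, and clinical scores at
baseline and week 4.

**Coherence model.** Local synchrony is planted with a shared latent
factor rather than spatial smoothing: inside an ROI with coherence
c ∈ [0, 1), each voxel's series is √(1−c)·iid N(0,1) + √c·one latent
N(0,1) series shared by the ROI.  The expected pairwise correlation
between ROI voxels is then exactly c, giving an analytic handle for tests;
Kendall's W is monotone in c, so planted group differences (group 2 uses
c + `group_delta`) translate into well-defined ReHo effects.  What this
construction does **not** emulate: hemodynamic response shapes,
physiological (cardiac/respiratory) noise, scanner drift fields,
susceptibility artifacts, or spatial autocorrelation outside the ROIs.
Passing tests therefore demonstrate correctness of the algorithms under
the stated statistical model, not performance on real scanner data.

**Motion.** A bounded Gaussian random walk: per-volume steps of
sd = amplitude/20, translations clipped to ±amplitude mm and rotations to
the radian equivalent on a 50 mm sphere.  Amplitude 0 gives an exactly
zero trace.  The default amplitude (0.3 mm) never triggers the 2 mm/2°
exclusion screen; tests that exercise exclusion plant larger jumps.

**Outcomes.** Baseline HAMA and HAMD are uniform integers on 10–25 and
7–21 (means ≈ 17.5 and 14, matching a typical outpatient anxiety cohort);
age 18–52, education 7–19 years, sex Bernoulli(½).  The reduction rate is
RR = intercept + β·(ROI-mean ReHo) + N(0, σ²), with the ROI-mean ReHo
computed by actually running the cleaning and ReHo stages on the generated
volumes.  The integer week-4 score is round(baseline·(1−RR)) clipped at 0;
because integer scales quantize RR, the exact pre-rounding RR is stored in
the cohort's truth block, and with σ = 0 ordinary least squares on the
true features recovers β to machine precision.  Default σ = 0.05 — small
against the planted signal range (roughly 0.3–0.5 in RR units), standing
in for the strong brain–outcome coupling the design assumes.

**Seeding.** One global seed expands into per-stage, per-subject
`SeedSequence([seed, stage, group, index])` streams, so any subject can be
regenerated in isolation and identical configs give bit-identical cohorts.

## Temporal preprocessing and motion QC

The first 10 volumes are dropped (scanner equilibration), then each
in-mask series is linearly detrended and band-passed to 0.01–0.1 Hz with a
zero-phase brick-wall mask on the real DFT — the "ideal filter" of the
classic resting-state toolboxes.  A minimum of 32 volumes is required;
shorter series leave the DFT too few in-band bins.  Framewise displacement
follows the Power convention, Σ|Δtranslation| + 50 mm·Σ|Δrotation(rad)|,
chosen because the toolbox family being emulated defaults to it (the
alternative Jenkinson definition is not implemented).  Motion screening
excludes subjects with any |translation| > 2 mm or |rotation| > 2°;
"more than" is strict, so values exactly at threshold survive.  Screening
is applied to the full trace as stored (one row per acquired volume).

## ReHo

Kendall's W is computed over each in-mask voxel and its stencil neighbors
(27, 19 or 7; default 27).  Ranks are midranks; the denominator uses the
uncorrected K²(n³−n) by default, matching the classic ReHo formula and
toolbox behavior, with the tie-correction term −K·ΣT available by flag.
Degenerate denominators (all-constant blocks under tie correction) return
0 with a warning.  At mask boundaries W is computed over the available
in-mask neighbors with the effective K recorded in a companion map —
toolbox behavior, which values the whole mask — so on pure noise the
in-mask mean W sits slightly above 1/27 (≈ 0.042 on the default interior
mask; exactly ≈ 1/27 over full-neighborhood voxels).

Maps are divided by the in-mask mean (making the mask mean exactly 1, the
normalization applied per subject) and then smoothed with a 4 mm FWHM
Gaussian.  Smoothing comes last ("smReHo" order).  The kernel is
renormalized within the mask — smoothed map divided by smoothed mask — so
edge voxels are not attenuated toward zero; on the small synthetic grids
this matters materially.  Normalization uses the subject's own mask (a
whole-brain template mask would be the alternative on real data; the
synthetic masks are identical across subjects, so the choice is moot
here).  One consequence worth knowing: because of the global division, a
strong planted *increase* in one ROI produces genuine small *decreases*
everywhere else in the normalized maps — visible in the fixtures as small
opposite-sign background clusters.

## Group statistics

Per-voxel OLS with contrast t = c′β̂ / √(σ̂²·c′(X′X)⁻¹c), df = n − rank(X);
covariates are mean-centered.  Voxels whose residual sum of squares is
zero up to float roundoff (possible on synthetic data) get t = 0 with a
warning, as do zero-sd voxels in the paired test.

**Smoothness.**  Estimated from the standardized GLM residual images by
the classic derivative-based formula: per axis, FWHM = √(4 ln 2 / v)
voxels with v the pooled variance of first differences of the
unit-variance residual field.  RESELs = mask voxels / Π FWHM.  For
unsmoothed white noise this returns ≈ 1.18 voxels; it is meant for the
smooth fields random-field theory assumes.  (Whether the original
toolchain used a residual-based or statistic-map-based estimator is not
documentable; residuals are the better-behaved choice.)

**Cluster correction.**  The t map is thresholded per tail at the Student
quantile of voxel_p/2 (two-tailed default), components labeled with
26-connectivity, and each cluster of extent k assigned the classic
Gaussian-field cluster-extent p:

    E[m]    = R · (4 ln 2)^{3/2} (u² − 1) e^{−u²/2} / (2π)²
    n̄      = V · Φ̄(u) / E[m]
    β       = (Γ(5/2)/n̄)^{2/3}
    p_corr  = 1 − exp(−E[m] · exp(−β k^{2/3}))

with u the Gaussian quantile matching the tail probability, R the RESEL
count and V the mask volume.  Clusters pass at p_corr ≤ cluster_p/2 per
tail; positive and negative clusters are reported separately with sign.
`expm1` keeps extremely small p values positive.  Measured calibration at
19³/n = 20+20: familywise error ≈ 0.035–0.045 at nominal 0.05 for fields
of 5–6 voxel FWHM, but only 0.005–0.01 at 2–3 voxel FWHM — the
stretched-exponential size tail overstates large-cluster probability on
small, barely-smooth discrete fields, making the correction conservative
there.  The null-calibration suite therefore simulates at 5-voxel FWHM,
the regime the asymptotic theory addresses (rule of thumb: smoothness at
least 3× voxel size); the low-smoothness conservatism is a known
limitation, not corrected for.

**Permutation oracle.**  A max-cluster-extent permutation test (group
labels shuffled, or difference signs flipped for paired designs) provides
an assumption-free cross-check, with corrected
p = (1 + #{null max ≥ k})/(n_perm + 1).  On well-separated planted effects
it confirms the GRF decisions; clusters sitting exactly at the alpha
boundary can legitimately differ between the two corrections.

**Effect sizes.**  Two-sample d = t·√(1/n₁ + 1/n₂).  For paired designs
the default is d = t/√n, with d = 2t/√df selectable — published tables are
inconsistent about the paired conversion (a documented example prints a
paired d of 1.08 where t/√n gives 0.76 and 2t/√df gives 1.54), so the
formula is configuration, not inference, and no attempt is made to
reconcile such rows.  The 2×2 chi-square is Pearson's without continuity
correction, with Cramér's V = √(χ²/N).

**Symptom correlations.**  Pearson or Spearman per pair; "auto" picks
Pearson only when both columns pass Shapiro–Wilk at 0.05.  Significance is
flagged at the Bonferroni-corrected threshold α/n_tests, with n_tests = 9
in the pipeline default (the number of simultaneous scale tests in the
emulated design, i.e. p < 0.005 at α = 0.05).

## Prediction

RR = (baseline − week4)/baseline, rejected (with a logged reason) when the
baseline is nonpositive; negative RR (worsening) is legitimate.

The SVR uses an RBF kernel with ε = 0.1 (the common library default) and
integer power-of-two grids for C and γ spanning 2⁻¹⁰…2¹⁰.  Features are
standardized by training-fold statistics (kernel methods are
scale-sensitive; applying test-fold statistics would leak).  Folds come
from a seeded shuffle followed by a contiguous split, unstratified.

Two grid-search protocols are first-class.  **paper** mode scores each
(C, γ) by the aggregated out-of-fold MSE of a full 5-fold CV and reports
the winning pair's aggregated predictions — the protocol widespread in the
applied literature, optimistically biased because test folds inform the
selection.  **nested** mode repeats the grid search inside each training
fold and is the sound choice for new data.  On pure-noise targets the
nested protocol's mean r stays near zero (slightly negative, the usual
small-sample CV artifact) while paper mode is allowed to drift optimistic;
the package measures this gap in its tests rather than hiding it.  Ties in
the grid search break toward the smallest exponents.

The permutation test reruns the identical CV procedure on shuffled
targets; p_r = #{null r ≥ observed}/N and p_mse = #{null MSE ≤ observed}/N.
This plain k/N convention can return exactly 0 on strong signals; the
(k+1)/(N+1) variant, never smaller and never zero, is always computed
alongside and selectable as the primary.  The full 5000-permutation run is
the library default; tests and the acceptance script use 50–200
permutations with a coarser grid purely for run time.  The Bonferroni
threshold sometimes quoted for such correlations (0.05/36 ≈ 0.001) is
exposed as a plain configuration value; its divisor is not derived by this
package.

## Pipeline

`run_end_to_end` executes simulate → motion QC → ReHo → group statistics →
prediction.  Each stage hashes its parameters and outputs into a manifest;
a rerun over a completed directory skips stages whose parameters and
output hashes are unchanged, and two runs with the same seed produce
byte-identical artifacts (NIfTI gzip output is deterministic).  Subjects
failing the motion screen are dropped from every downstream stage and
listed in the manifest.  Prediction features are the per-cluster means of
baseline smoothed-normalized ReHo within the significant between-group
clusters, for the patient group only; voxelwise features are deliberately
out of scope.  If no cluster survives correction the prediction stage
records that and skips, rather than inventing features.

Default sizes (24³ grid, 120 volumes, 12 subjects/group, 100 permutations,
exponent grids in steps of 2) are chosen so a full run completes in about
1–2 minutes on one CPU; all are configurable upward to the emulated
study's scale (240 volumes, 54/group, 5000 permutations, unit-step grids).

## Known limitations

- The synthetic data's noise model is white in space and time outside the
  planted ROIs; real BOLD autocorrelation would change the ReHo null level
  and the GRF smoothness estimates.
- GRF cluster p values are conservative below ~3 voxel FWHM smoothness
  (measured above); the permutation oracle is the fallback there.
- The paired Cohen's d convention is configurable, not resolved.
- No slice-timing, realignment, spatial normalization, nuisance
  regression, scrubbing, atlas labeling, TFCE, or BIDS ingestion.
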