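# Methods

## Model

All calibrations share the Beer–Lambert forward model `A = C K + E`: each
observed spectrum (row of `A`, L×P) is a linear mixture of per-component
spectra (rows of `K`, M×P) weighted by component quantities (row of `C`,
L×M). Spectra and component quantities are mean-centered around the
calibration set before fitting, and the stored means are re-applied
identically at prediction; metrics are always reported on the original
(un-centered) concentration scale. Centering can be disabled for exact
noiseless algebra.

The textbook normal-equation forms `K̂ = (CᵀC)⁻¹CᵀA` and
`C̃ = AK̃ᵀ(K̃K̃ᵀ)⁻¹` are numerically fragile once augmentation introduces
near-dependent columns, so both solves use rank-revealing minimum-norm
least squares (`numpy.linalg.lstsq`), with a singular-value cutoff of
`max(dim) · ε · σ_max` for rank decisions. A rank-deficient component
matrix at fit time is an error naming the dependent columns (found by
pivoted QR); a rank-deficient `K̃` at prediction time degrades gracefully
to the minimum-norm solution with a warning — this is what makes
augmentation columns orthogonal to every concentration column provably
harmless (their fitted spectra are numerically zero and the cutoff removes
them), instead of a hard singularity. Only a numerically zero `K̃` raises.

## Augmentation (ACLS)

The unmodeled-variance rescue runs in five steps, each exposed separately:

1. **Channel correlation.** `r²_j` = squared Pearson correlation of channel
   j's intensity with the target concentration across calibration samples;
   constant channels get 0 by convention.
2. **Candidate ranking.** Channels with `r² < r2_threshold` (default 0.2)
   are sorted by ascending r² and greedily filtered to pairwise wavenumber
   spacing ≥ `min_spacing` (default 100 cm⁻¹). The spacing rule is our
   reproducible reading of "pick from different spectral regions":
   neighbouring channels in smooth spectra are nearly collinear, so
   unconstrained picks would be redundant.
3. **RMSECV curve.** For m = 0..m_max (default cap 30, further capped so
   every leave-one-out fold keeps ≥ 2 spare samples), exhaustive
   leave-one-out RMSECV of the target from CLS on `C` plus the first m
   candidates. The candidate list is fixed; only the CLS fit is redone per
   fold. Rank-deficient folds record NaN with a warning.
4. **Elbow.** The m maximizing the perpendicular distance *below* the
   chord joining the first and last finite curve points (Kneedle-style);
   ties break toward smaller m, a straight-line curve yields m = 0, and if
   the elbow's RMSECV exceeds the unaugmented value the choice falls back
   to m = 0 — a guard against the unstable low-m region, where a single
   appended channel can inject correlated noise. An explicit `m_override`
   replicates a visually chosen size and skips the sweep (the curve is then
   evaluated at that m only).
5. **Final fit.** CLS on the augmented matrix. Channels that are
   numerically linear combinations of columns already present are dropped
   with a warning, not an error. Predicted pseudo-component "concentrations"
   are retained in the full prediction but flagged; they are regression
   bookkeeping, never chemistry.

## Baselines

- **CLS1 / CLS2**: CLS on the target column only / on all analyte columns.
- **CRACLS**: starting from all analyte columns, iteratively append the
  calibration target residual (predicted − reference) as a pseudo column
  and refit, stopping on relative improvement < 1e-8, a numerically zero
  residual, a rank-deficient append, or 10 iterations. The source
  description of this algorithm is a one-liner, so iteration count and
  tolerance are this package's choices; per-iteration calibration residual
  norms are recorded and are non-increasing by construction.
- **PCR**: target regressed on the leading principal-component scores of
  the centered spectra (SVD-based, in-package).
- **PLS**: univariate-target NIPALS with deflation via scikit-learn's
  `PLSRegression(scale=False)`, re-expressed as an affine map of the raw
  spectrum; a zero-covariance direction stops extraction early with a
  warning.
- **Latent-dimension choice**: leave-one-out RMSECV for k = 1..k_max
  (default 10); the smallest k within 2% (relative) of the curve minimum
  wins — the parsimony rule standing in for a selection reference that is
  not specified in detail.

All fitters return the same `CalibrationModel` contract: `predict(spectra)`
gives target concentrations in original units.

## Evaluation protocol

`venetian_blinds_split` assigns fold `i mod n_folds` in acquisition order
(0-based); for smoothly varying batch processes this preserves
concentration ranges and correlations across folds. The comparison table
fits every method on fold 0, scores RMSEP and R² (squared Pearson) on fold
1, reports leave-one-out RMSECV on the calibration fold, sorts worst-first
by RMSEP, and attaches to each row the two-group one-way ANOVA p value on
absolute validation errors against the previous row. No multiple-testing
correction is applied across these pairwise tests, matching standard
practice for this table layout. For two groups the ANOVA F equals the
squared pooled t statistic; all-identical groups return F = 0, p = 1.

## Synthetic data generator

The generator emulates in-line Raman monitoring of the sequential
hydrogenation phenylacetylene (PA) → styrene (ST) → ethylbenzene (EB),
providing a fully specified, seeded stand-in for batch-reaction
calibration data.

- **Axis**: 230–3500 cm⁻¹ at 2 cm⁻¹ → 1636 channels.
- **Kinetics**: first-order consecutive reaction; defaults c0 = 0.4598
  concentration units, k1 = 1, k2 = 0.07 per unit time, batch duration 35,
  geometric time grid (ratio 1.35, dense early where the reaction is
  fast). These defaults were set so the 7-batch, 110-sample layout
  (16,16,16,16,16,15,15) reproduces the descriptive statistics of the
  emulated process: analyte ranges ≈ 0–0.46 / 0–0.38 / 0–0.42 and
  target-vs-other concentration R² ≈ 0.24 (ST) and 0.44 (EB). PA is
  monotone decreasing, EB monotone increasing, ST unimodal, and the three
  sum to the batch's c0 exactly (mass conservation; reference
  concentrations are never noised — they stand for chromatographic ground
  truth).
- **Batch variability**: per batch, c0, k1 and k2 are jittered by a
  log-normal factor (σ = 0.05). The c0 jitter matters structurally:
  identical initial charges would close the mass balance to the same
  constant in every batch and make the centered three-analyte matrix rank
  deficient.
- **Pure spectra**: Gaussian/Lorentzian bands at literature-typical
  positions (PA's 2110 cm⁻¹ alkyne marker; shared ring modes near
  1000/1600 cm⁻¹; aromatic and aliphatic C–H around 2870–3062 cm⁻¹), so
  the analyte spectra genuinely overlap — omitting ST/EB must corrupt a
  target-only CLS fit.
- **Perturbations**, applied in a fixed, documented order: extra spectral
  components → baseline drift (random per-sample polynomial) → per-sample
  wavelength shift (sub-channel linear interpolation) → intensity
  nonlinearity (quadratic saturation `x − βx²`) → i.i.d. Gaussian noise.
  Spectral-component amplitudes are either i.i.d. uniform or a smooth
  sinusoid over batch time (random phase per batch), the latter emulating
  slow instrumental drift.
- **Registered scenarios**: `paperlike` (one spectral interferent of
  magnitude 0.05 with bands at 450/1080/3360 cm⁻¹, β = 0.02, noise sd
  1e-3), `clean` (no interferents, no noise), and `two_interferents` (two
  independent spectral components, low noise). The paperlike interferent
  magnitude and β were calibrated during generator development to the
  stated design point — CLS2 clearly degraded but functional, CLS1 failing
  visibly — with the interferent bands kept mostly in analyte-quiet
  regions so its proxy channels have low target correlation. Because the
  interferent amplitudes are random, their sample correlation with the
  analytes (and hence the exact CLS2 error) varies with seed; the
  qualitative ordering CLS1 ≫ CLS2 > ACLS ≈ PLS/PCR is stable.

What the generator does **not** emulate: solvent background (generated
solvent-free), physically calibrated Raman cross-sections, detector
spikes/cosmic rays, or heteroscedastic shot noise. Passing tests therefore
demonstrate the algorithmic claims (information-loss degradation and its
augmentation rescue) under controlled linear-plus-perturbation conditions,
not instrument-grade robustness.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 110 × 1636 benchmark; the
oracle-equivalence checks use 200 random 20 × 3 × 30 problems. Exhaustive
leave-one-out underlies every RMSECV (no shortcut formulas), which keeps
the augmentation sweep O(L · m_max) CLS fits — about ten seconds for the
benchmark. Tolerances: exact-algebra assertions at 1e-8–1e-12;
rank decisions at the SVD cutoff above. Degenerate inputs (constant
target, single sample, no channel under the r² threshold, all-NaN curve)
raise typed errors rather than propagating NaNs.

## Known limitations

- The elbow rule is geometric; on curves that decline smoothly without a
  knee it picks a small m and relies on the fallback, and a visually
  chosen size must be supplied via `m_override`.
- CRACLS is reconstructed from a one-line description; variants that
  append multiple residual columns per iteration or recompute earlier
  columns would differ.
- Channel selection assumes the unmodeled variance is visible in channels
  weakly correlated with the target; an interferent whose spectrum lies
  entirely under strong target bands would evade it.
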