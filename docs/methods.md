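# Methods

This note documents the models, estimators, numerical choices and the
synthetic study design implemented in `ivimpipe`, in the spirit of the model
documentation that simulation and statistics packages ship alongside their
code. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Signal model

The voxel-wise forward model is the bi-exponential intravoxel-incoherent-
motion (IVIM) decay of the fractional signal,

    S(b)/S(0) = (1 − v_bw)·exp(−b·D) + v_bw·exp(−b·(D + D*)),

with tissue diffusivity `D`, pseudo-diffusivity `D*`, blood-water fraction
`v_bw`, and the derived flow index `D*·v_bw`. Two conventions for the fast
compartment's decay rate circulate in the IVIM literature: `D + D*` (used
here by default, `fast_rate_convention="sum"`) and `D*` alone
(`"dstar_only"`). They are related by a constant shift of the reported `D*`
by exactly `D`; the option exists so maps can be compared against either
convention. The default 15-point b schedule is
0, 5, 10, 20, 30, 40, 60, 80, 120, 160, 200, 300, 500, 750, 1000 s/mm²,
densely sampled at low b where the perfusion compartment decays.

## 2. Estimation

**Segmented fit.** The classical two-stage estimator: a log-linear least
squares fit over `b ≥ b_cut` (default 200 s/mm²) gives `D` and the tissue
amplitude; with `D` fixed, `(v_bw, D*)` are then estimated by bounded least
squares on the full curve. At `b_cut = 200` and `D* ≥ 10·10⁻³ mm²/s` the
perfusion compartment has decayed by at least `e⁻²`, so its residual
contamination biases the tail `D` upward by under 2% at typical brain
parameters (asserted in the tests). That small bias is truth-dependent,
which is why the segmented estimator is the initializer rather than the
default production fitter.

**Full NLS.** Simultaneous bounded least squares on `(v_bw, D, D*)`,
started from the segmented solution (or from bound midpoints when the
segmented stage is undefined). The per-voxel path uses
`scipy.optimize.least_squares` (trust-region reflective) followed by an
unconstrained Levenberg–Marquardt polish that is accepted only if it stays
inside the bounds and lowers the cost — trf alone can stall ~10⁻⁶ short of
optima that sit on a box bound. The volume path is a vectorized damped
Gauss–Newton on all voxels at once, also started from the segmented
solution, accepting steps per voxel only when they reduce the residual;
this guarantees the documented invariant that the full-NLS residual never
exceeds the segmented residual, and makes whole-cohort fitting take seconds
rather than hours.

**Bounds and constraints.** `v_bw ∈ [0, 0.3]`, `D ∈ [0, 3·10⁻³]`,
`D* ≤ 0.1 mm²/s` — physiological brain ranges that also prevent the two
compartments from swapping roles. The physical ordering `D* ≥ D` is imposed
by parameterizing the gap `D* − D ∈ [0, 0.1]`; as a consequence the
effective ceiling on `D*` is `D + 0.1` (at most 0.103) rather than exactly
0.1, a deliberate simplification that keeps the constraint a box bound.
Fits with `v_bw < 0.005` are flagged unidentifiable (the perfusion
compartment carries no signal there and `D*` is arbitrary); the noiseless
round-trip guarantees exclude that corner.

**Tolerances.** `ftol = xtol = gtol = 10⁻¹⁴`, at most 200 function
evaluations per voxel; the batch Gauss–Newton stops when no voxel improves
its sum of squares by more than 10⁻¹² relative. These are tight because the
package promises noiseless forward/inverse consistency to 10⁻⁶ relative
error across the parameter box.

**Noise behaviour.** Magnitude (Rician) noise biases small `v_bw` upward:
at noise scale 0.02·S0 and the canonical brain operating point
(v_bw = 0.05, D = 0.8·10⁻³, D* = 10·10⁻³), the median bias over 200 voxels
is within ±5% for `D` and within ±30% for `v_bw` (both asserted); `D*` is
the noisiest parameter and is reported without a bound. At smaller v_bw or
higher D* the v_bw bias can exceed that band — regional medians and group
contrasts, not absolute voxel values, are the intended readout.

## 3. Pre-processing

Raw series are reduced in the order: average the gradient directions →
smooth each volume with a spatial Gaussian kernel (default FWHM 8 mm) →
divide by the voxel's own b=0 signal. Averaging first matches the usual
acquisition-side practice; an alternative path (`fit_then_smooth`) fits the
raw series and instead smooths the resulting parameter maps with a
normalized convolution that respects the validity mask, for sensitivity
analyses. Anisotropic voxels (default 3.75 × 3.75 × 5 mm) get per-axis
kernel widths; convolution uses nearest-neighbour boundary replication so
constant fields pass through unchanged and edges are not darkened.
Averaging and normalization commute only on noiseless data (the tests
assert exactly that), which is one reason the order is fixed.

## 4. Group inference

**t maps.** Pooled-variance two-sample t per voxel,
`df = n_A + n_B − 2`; voxels with any non-finite subject value or zero
pooled variance leave the analysis mask. Both one-sided contrasts run
separately at the same forming threshold.

**Smoothness.** Residuals of the two-group means model are standardized
voxel-wise; the lag-1 spatial autocorrelation ρ of the standardized
residuals gives the per-axis Gaussian kernel width via
`σ² = −1/(4·ln ρ)` (exact for a Gaussian autocorrelation — the
finite-difference derivative-variance estimator systematically
overestimates FWHM by 8–14% at the default smoothness, which would bias
the resel count). For rough fields (ρ < 0.1) the derivative-variance
formula `FWHM = √(4·ln2 / var(Δu))` is used instead; on white noise it
yields ≈1.18 voxels. The resel count is the mask volume divided by the
product of per-axis FWHMs. The estimator recovers 8-mm smoothing within
15% on the default grid (asserted over 50 simulations).

**Cluster-extent RFT.** The forming t threshold is converted to an
equal-tail Gaussian score at the model's df, then Gaussian-field theory
gives the expected cluster count `E[m] = R·(4 ln2)^{3/2} (2π)^{-2}
(z²−1) e^{−z²/2}` (R = resels), the expected cluster size from the
expected suprathreshold volume, an exponential extent tail
`P(n ≥ k) = exp(−β k^{2/3})` with `β = (Γ(5/2)/E[n])^{2/3}`, and the
corrected `p = 1 − exp(−E[m]·P(n ≥ k))` (Poisson clumping). This is an
approximation on three counts — Gaussianized t field, desk-scale search
volume, estimated smoothness — so its family-wise error is only required
to fall in [0.02, 0.10] at nominal 0.05 on null phantoms (asserted over
500 simulations); thresholds below 1.5 attach an explicit warning.

**Permutation test.** The exact nonparametric route: the null is the
maximum supra-threshold cluster size over group-label rearrangements
(exhaustive when the arrangement count is small, otherwise sampled), and
each observed cluster gets `p = (1 + #{null max ≥ size})/(1 + #null)`.
With 3 + 3 subjects the exhaustive null has C(6,3) = 20 arrangements and
the smallest attainable p is 1/20. t statistics for all permutations are
computed by matrix products, so hundreds of permutations on the default
grid cost well under a second. Its null FWE is required in [0.03, 0.07].
RFT and permutation p-values must agree in cluster rank order.

**Connectivity** defaults to 18-neighbour (the SPM convention); 6 and 26
are selectable and all three are checked against an independent
flood-fill oracle. Cluster peaks are reported in mm through a diagonal
affine with the origin at the grid centre — synthetic grids carry no
atlas coordinates.

**Intersection.** The voxel-wise AND of the per-parameter significant
cluster masks defines the region that all four parameters implicate; it
feeds the association stage and is fixed before any covariate is seen.

## 5. Association

Per subject, the median of each parameter map inside the region (invalid
voxels excluded); per parameter × covariate pair, Pearson r with the
two-sided t-transform p on n−2 df plus the regression line (Spearman
optional). Missing covariates are dropped pairwise with a logged count; at
least 3 complete pairs are required and zero variance is an explicit
error. By default only the patient group enters, matching the case-only
clinical-correlation design. Unadjusted p-values are primary, flagged at
0.05 and 0.1 ("trend"); a Benjamini–Hochberg column is always emitted
alongside for modern practice.

## 6. The synthetic study

The phantom emulates a small case/control brain-DWI study on a
24 × 24 × 12 grid of 3.75 × 3.75 × 5 mm voxels, 11 subjects per group,
three orthogonal gradient directions, Rician noise at 2% of S0
(magnitude of the noiseless signal plus complex Gaussian noise; a Gaussian
noise option exists for oracle tests). Baseline parameters
(v_bw = 0.05, D = 0.8·10⁻³, D* = 10·10⁻³ mm²/s) are literature-typical
brain values, not fitted to any dataset. Per subject, each true parameter
field is the group mean plus a global offset (30% of the between-subject
SD) plus a smooth Gaussian random field (FWHM 10 mm, the remaining
variance); the split matters because a purely global offset is infinitely
smooth and, for low-noise parameters like D, produces whole-map t shifts
that bridge true and null clusters. Between-subject SDs default to
0.005 (v_bw), 0.05·10⁻³ (D) and 1·10⁻³ (D*).

"Patients" receive additive shifts inside a posterior ellipsoid
(radii 28 × 22 × 18 mm, centred at fractional grid position
(0.5, 0.72, 0.5)): v_bw −0.018, D +0.15·10⁻³, D* +16·10⁻³. The signs
reproduce the qualitative clinical pattern (lower blood-water fraction,
higher diffusivities and flow product in patients); the magnitudes were
chosen once so that each parameter's fitted-map effect is ~2–3
between-subject SDs — the large D* shift is required because the flow
product `v_bw·D*` must rise despite the v_bw drop partially cancelling
it. Covariates are linear in each subject's true regional parameter mean:
two cognitive Z-scores couple negatively to regional flow, a
disease-activity score couples negatively to regional v_bw, and two
Z-scores are pure noise (null covariates for calibration).

What the phantom does **not** emulate: anatomy (no tissue classes, no CSF
compartment or suppression, no atlas space), motion or eddy-current
artifacts, registration error (subjects are born aligned), coil or
multi-shell effects, and any covariance between parameters beyond the
flow product's definition. Passing tests therefore demonstrate the
correctness and calibration of the estimators and inference under the
stated noise model — not robustness to acquisition artifacts.

All randomness derives from a single integer seed through spawned
`SeedSequence` streams; identical specs give byte-identical cohorts,
and the pipeline manifest checksums every artifact.

## 7. Problem sizes used in the checks

The self-checks run at the study's native design (24 × 24 × 12 grid, 11
per group): noiseless recovery on a 5³ parameter grid; noisy calibration
at 200 voxels per operating point; cluster-oracle comparison on 100 random
maps × 3 connectivities; FWE calibration on 500 null cohorts per
correction (199 permutations each); end-to-end effect recovery on 20
cohort seeds; association power on 100 seeds (region-restricted fits).
`scripts/acceptance.py` recomputes the same quantities at moderately
reduced replicate counts (300/200 null cohorts, 10 recovery seeds, 60
association seeds) and reports each with the problem size used.

## 8. Known limitations

- Cluster-extent RFT here uses Gaussian-field formulas with a
  df-Gaussianized threshold rather than t-field EC densities; at df = 20
  and the default grid this stays within the calibration band, but for
  much smaller df or rougher fields the permutation route is the one to
  trust.
- The segmented fitter's truth-dependent D bias (tail contamination)
  propagates into v_bw and D* on noiseless data; it is retained because it
  is the field's standard initializer, but production maps use the full
  fit.
- Rician bias at low v_bw is not corrected; a noise-floor correction would
  be needed for absolute quantification at higher noise scales.
- The permutation test permutes group labels only; it assumes
  exchangeability under the null and offers no covariate adjustment
  (matching the two-sample design it implements).
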