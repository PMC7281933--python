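# ivimpipe

Intravoxel-incoherent-motion (IVIM) analysis of multi-b diffusion-weighted
brain MRI, built as a fully testable pipeline: synthetic two-group cohort
simulation, bi-exponential parameter mapping, cluster-level family-wise-error
group inference, and regional association with clinical covariates.

## Who this is for

Researchers studying microvascular and microstructural brain changes with
diffusion MRI — e.g., case/control perfusion studies in small clinical
cohorts — who need every stage of the classical analysis chain (voxel-wise
model fitting → SPM-style cluster inference → region-of-interest
correlations) reproducible end to end on data with known ground truth.
Because clinical DWI is rarely shareable, the package ships a phantom
generator that emulates the study design, so the whole chain is verifiable
without any download.

## The model

The fractional DWI signal at diffusion weighting `b` (s/mm²) is modelled as
two compartments:

    S(b)/S(0) = (1 − v_bw)·exp(−b·D) + v_bw·exp(−b·(D + D*))

- `D` — diffusion coefficient of water in bulk tissue (mm²/s),
- `D*` — effective (pseudo-)diffusion coefficient of blood water in randomly
  oriented microvessels (mm²/s),
- `v_bw` — fraction of voxel water in blood,
- `D*·v_bw` — derived flow-related product.

Per voxel, parameters are estimated either by the classical *segmented* fit
(`D` from the log-linear high-b tail at `b ≥ 200 s/mm²`, then `v_bw, D*` by
bounded least squares) or by *full* bounded nonlinear least squares started
from the segmented solution. Group differences are tested with a
pooled-variance two-sample t statistic per voxel; contiguous voxels above a
nominal T-score threshold form clusters, whose family-wise-error-corrected
p-values come from Gaussian random-field cluster-extent theory (with
residual-based smoothness estimation) or from a max-cluster-size permutation
test. Medians of the parameter maps inside the intersection of significant
clusters are then correlated (Pearson) with per-subject covariates.

## Worked example

```python
import numpy as np
import ivimpipe as ip

spec = ip.PhantomSpec(seed=1)            # 24x24x12 grid, 11 subjects per group
cohort = ip.generate_cohort(spec)

fitted = {}
for subj, dwi in zip(cohort.truth.subjects, cohort.dwi):
    series = ip.preprocess_series(dwi, fwhm_mm=8.0)   # average, smooth, normalize
    fitted[subj.subject_id] = ip.fit_ivim_volume(series, method="full_nls")

patients = [fitted[s.subject_id]["flow"] for s in cohort.truth.subjects if s.group == "patient"]
controls = [fitted[s.subject_id]["flow"] for s in cohort.truth.subjects if s.group == "control"]
tmap, clusters = ip.compare_groups(patients, controls, forming_threshold=1.7,
                                   voxel_size_mm=spec.voxel_size_mm)
top = clusters[0]
print(f"flow cluster: {top.size_voxels} voxels, peak t={top.peak_t:.2f} at "
      f"{tuple(round(x, 1) for x in top.peak_mm)} mm, p_fwe={top.p_fwe:.4f}")
print(f"overlap with true effect region: Dice={ip.dice(top.mask, cohort.truth.region_mask):.2f}")

med = [ip.regional_median(fitted[s.subject_id]["flow"], cohort.truth.region_mask)
       for s in cohort.truth.subjects if s.group == "patient"]
vca = [s.covariates["vca_z"] for s in cohort.truth.subjects if s.group == "patient"]
res = ip.correlate(np.array(med), np.array(vca))
print(f"median flow vs VCA Z-score (patients): r={res.r:.2f}, p={res.p:.4f}, slope={res.slope:.0f}")
```

prints (about half a minute on one CPU):

```
flow cluster: 949 voxels, peak t=11.64 at (-9.4, 24.4, 7.5) mm, p_fwe=0.0000
overlap with true effect region: Dice=0.80
median flow vs VCA Z-score (patients): r=-0.85, p=0.0009, slope=-7535
```

The phantom plants a posterior effect region in which "patients" have lower
blood-water fraction and higher `D`, `D*` and flow product. The comparison
finds one dominant supra-threshold cluster for the flow product
(patients > controls) that is significant after family-wise-error
correction and overlaps the true region at Dice 0.80; the patients' median
regional flow correlates negatively with the simulated visuoconstructional
Z-score, as generated.

## Command line

The same pipeline runs from a shell via the `ivim` entry point, driven by a
single YAML config (see `ivimpipe.pipeline` for the schema):

```
ivim run-all --out-dir run --seed 1
ivim simulate --config study.yaml     # or stage by stage:
ivim preprocess --config study.yaml
ivim fit --config study.yaml --method full_nls
ivim compare --config study.yaml --correction perm
ivim associate --config study.yaml
```

Each stage writes NIfTI volumes, plain-text b-value files and TSV tables
into its own subdirectory of the run folder; `manifest.json` records the
package version, config hash, seeds and a checksum for every artifact, and
identical configs reproduce identical checksums.

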