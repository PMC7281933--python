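"""Synthetic two-group multi-b DWI cohorts with known IVIM ground truth.

The phantom emulates a case/control brain-DWI study on a small common voxel
grid: every subject gets spatially smooth true parameter fields (Gaussian
random fields around group means), the patient group receives additive
shifts inside a posterior ellipsoidal "effect region" (lower blood-water
fraction; higher D, D* and flow product), magnitude images are produced by
the bi-exponential forward model with Rician noise, and clinical covariates
are linearly coupled to each subject's true regional parameter mean.

Defaults are desk-scale but keep genuine 3-D cluster topology; IVIM
baselines are literature-typical brain values.  There is no anatomical
realism: no tissue classes, no CSF compartment, no motion or eddy
artifacts, and subjects are born co-registered.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .ivim import IVIMParams, _fast_rate
from .preprocess import FWHM_TO_SIGMA, DWISeries, validate_b_values

#: 15-point diffusion-weighting schedule (s/mm^2) used throughout
DEFAULT_B_VALUES = (0, 5, 10, 20, 30, 40, 60, 80, 120, 160, 200, 300, 500, 750, 1000)

FIELD_PARAMS = ("vbw", "d", "dstar")


@dataclass(frozen=True)
class EllipsoidRegion:
    """Axis-aligned ellipsoid described by fractional center and mm radii."""

    center_frac: tuple[float, float, float] = (0.5, 0.72, 0.5)
    radii_mm: tuple[float, float, float] = (28.0, 22.0, 18.0)

    def mask(self, grid_shape, voxel_size_mm) -> np.ndarray:
        coords = np.indices(grid_shape, dtype=float)
        out = np.zeros(grid_shape, dtype=float)
        for ax in range(3):
            c = self.center_frac[ax] * (grid_shape[ax] - 1)
            out += ((coords[ax] - c) * voxel_size_mm[ax] / self.radii_mm[ax]) ** 2
        return out <= 1.0


@dataclass(frozen=True)
class CovariateModel:
    """Linear coupling of a clinical covariate to a regional parameter mean.

    ``covariate = intercept + slope * regional_mean(parameter) + N(0, noise_sd)``.
    ``parameter=None`` (or slope 0) gives a null covariate: noise around the
    intercept, independent of the imaging.
    """

    parameter: str | None
    slope: float
    intercept: float
    noise_sd: float


def _default_covariates() -> dict[str, CovariateModel]:
    # Names mirror a pediatric-lupus-style covariate battery: four cognitive
    # domain Z-scores plus a disease-activity score.  The visuoconstructional
    # and psychomotor Z-scores couple negatively to regional flow, disease
    # activity couples negatively to regional v_bw; working memory and
    # attention are null covariates.
    return {
        "vca_z": CovariateModel("flow", -8000.0, 7.1, 0.1),
        "pms_z": CovariateModel("flow", -8000.0, 6.8, 0.1),
        "wm_z": CovariateModel(None, 0.0, 0.0, 0.7),
        "attention_z": CovariateModel(None, 0.0, 0.0, 0.8),
        "sledai": CovariateModel("vbw", -1500.0, 54.0, 2.0),
    }


@dataclass
class PhantomSpec:
    """Complete description of a synthetic cohort; fully determines outputs."""

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (3.75, 3.75, 5.0)
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    n_per_group: int = 11
    effect_region: EllipsoidRegion | np.ndarray = field(default_factory=EllipsoidRegion)
    baseline: IVIMParams = field(default_factory=lambda: IVIMParams(0.05, 0.8e-3, 10e-3))
    effect_deltas: dict[str, float] = field(
        default_factory=lambda: {"vbw": -0.018, "d": 0.15e-3, "dstar": 16e-3}
    )
    between_subject_sd: dict[str, float] = field(
        default_factory=lambda: {"vbw": 0.005, "d": 0.05e-3, "dstar": 1.0e-3}
    )
    noise_sigma: float = 0.02          # Rician scale, relative to S0
    s0: float = 1000.0                 # b=0 magnitude signal
    field_smooth_fwhm_mm: float = 10.0  # smoothness of the true parameter fields
    offset_frac: float = 0.3           # share of between-subject SD that is a
                                       # spatially constant per-subject offset
    n_directions: int = 3
    noise_model: str = "rician"        # "rician" | "gaussian"
    covariates: dict[str, CovariateModel] = field(default_factory=_default_covariates)
    seed: int = 0

    def validate(self) -> None:
        validate_b_values(np.asarray(self.b_values, dtype=float))
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        self.baseline.validate()
        shifted = self.shifted_params()
        if not 0.0 <= shifted.vbw <= 1.0:
            raise ValueError("effect delta drives v_bw outside [0, 1]")
        if shifted.d < 0:
            raise ValueError("effect delta drives D below 0")
        if shifted.dstar < shifted.d:
            raise ValueError("effect delta drives D* below D")
        for p in FIELD_PARAMS:
            if self.between_subject_sd.get(p, 0.0) < 0:
                raise ValueError(f"between_subject_sd[{p!r}] must be non-negative")

    def shifted_params(self) -> IVIMParams:
        """Baseline plus the patient-group effect deltas."""
        d = self.effect_deltas
        return IVIMParams(
            self.baseline.vbw + d.get("vbw", 0.0),
            self.baseline.d + d.get("d", 0.0),
            self.baseline.dstar + d.get("dstar", 0.0),
        )

    def region_mask(self) -> np.ndarray:
        if isinstance(self.effect_region, np.ndarray):
            m = np.asarray(self.effect_region, dtype=bool)
            if m.shape != tuple(self.grid_shape):
                raise ValueError("effect_region mask shape does not match grid_shape")
            return m
        return self.effect_region.mask(self.grid_shape, self.voxel_size_mm)

    def brain_mask(self) -> np.ndarray:
        return np.ones(self.grid_shape, dtype=bool)


@dataclass
class SubjectTruth:
    """Per-subject ground truth: smooth parameter fields and covariates."""

    subject_id: str
    group: str
    fields: dict[str, np.ndarray]  # vbw, d, dstar, flow
    covariates: dict[str, float] = field(default_factory=dict)

    def regional_mean(self, parameter: str, region: np.ndarray) -> float:
        return float(self.fields[parameter][region].mean())


@dataclass
class GroundTruth:
    subjects: list[SubjectTruth]
    region_mask: np.ndarray
    spec: PhantomSpec


def _unit_random_field(shape, voxel_size_mm, fwhm_mm, rng) -> np.ndarray:
    """Stationary Gaussian random field with unit pointwise variance.

    White noise is convolved with a Gaussian kernel (periodic boundaries keep
    the field stationary) and rescaled by the exact discrete kernel norm.
    """
    white = rng.standard_normal(shape)
    if fwhm_mm <= 0:
        return white
    sigma = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm]
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma=sigma, mode="wrap")
    norm = float(np.sqrt(np.sum(kernel**2)))
    return smooth / norm


def build_true_fields(spec: PhantomSpec, group: str, subject_seed: int) -> SubjectTruth:
    """Draw one subject's smooth true parameter fields.

    Each parameter field is (group mean) + (subject offset) + (smooth
    zero-mean random field); patients get the effect deltas added inside the
    effect region only.  Physical bounds are enforced voxel-wise.
    """
    spec.validate()
    if group not in ("patient", "control"):
        raise ValueError(f"group must be 'patient' or 'control', got {group!r}")
    rng = np.random.default_rng(subject_seed)
    region = spec.region_mask()
    base = {p: getattr(spec.baseline, p) for p in FIELD_PARAMS}
    fields: dict[str, np.ndarray] = {}
    for p in FIELD_PARAMS:
        sd = spec.between_subject_sd.get(p, 0.0)
        f = np.full(spec.grid_shape, base[p], dtype=float)
        if group == "patient":
            f += spec.effect_deltas.get(p, 0.0) * region
        f += rng.normal(0.0, spec.offset_frac * sd)  # global subject offset
        field_sd = sd * math.sqrt(max(1.0 - spec.offset_frac**2, 0.0))
        if field_sd > 0:
            f += field_sd * _unit_random_field(
                spec.grid_shape, spec.voxel_size_mm, spec.field_smooth_fwhm_mm, rng
            )
        fields[p] = f
    fields["vbw"] = np.clip(fields["vbw"], 0.0, 1.0)
    fields["d"] = np.maximum(fields["d"], 0.0)
    fields["dstar"] = np.maximum(fields["dstar"], fields["d"])
    fields["flow"] = fields["dstar"] * fields["vbw"]
    return SubjectTruth(subject_id="", group=group, fields=fields)


def simulate_dwi(
    truth: SubjectTruth,
    spec: PhantomSpec,
    n_directions: int | None = None,
    seed: int = 0,
) -> DWISeries:
    """Forward-simulate a magnitude multi-b acquisition from true fields.

    Noiseless signal per voxel and b value follows the bi-exponential model
    scaled by S0; Rician noise takes the magnitude of the signal plus a
    complex Gaussian perturbation (sd ``noise_sigma * S0`` per channel), one
    independent realization per gradient direction.
    """
    spec.validate()
    ndir = spec.n_directions if n_directions is None else n_directions
    if ndir < 1:
        raise ValueError("n_directions must be >= 1")
    v, d, dstar = (truth.fields[p] for p in FIELD_PARAMS)
    if v.shape != tuple(spec.grid_shape):
        raise ValueError("truth fields do not match spec grid_shape")
    b = np.asarray(spec.b_values, dtype=float)
    fast = _fast_rate(d, dstar, "sum")
    clean = spec.s0 * (
        (1.0 - v)[..., None] * np.exp(-d[..., None] * b)
        + v[..., None] * np.exp(-fast[..., None] * b)
    )  # (X, Y, Z, B)
    rng = np.random.default_rng(seed)
    sig = spec.noise_sigma * spec.s0
    shape = clean.shape + (ndir,)
    if sig == 0:
        noisy = np.repeat(clean[..., None], ndir, axis=-1)
    elif spec.noise_model == "rician":
        g1 = rng.normal(0.0, sig, size=shape)
        g2 = rng.normal(0.0, sig, size=shape)
        noisy = np.hypot(clean[..., None] + g1, g2)
    else:  # gaussian, for oracle tests; clipped to keep magnitude semantics
        noisy = np.maximum(clean[..., None] + rng.normal(0.0, sig, size=shape), 0.0)
    return DWISeries(
        signal=noisy,
        b_values=b,
        voxel_size_mm=spec.voxel_size_mm,
        brain_mask=spec.brain_mask(),
    )


@dataclass
class Cohort:
    dwi: list[DWISeries]
    table: pd.DataFrame
    truth: GroundTruth


def _subject_seeds(spec: PhantomSpec, n_subjects: int) -> np.ndarray:
    root = np.random.SeedSequence(spec.seed)
    state = root.generate_state(3 * n_subjects, dtype=np.uint32)
    return (state & 0x7FFFFFFF).reshape(n_subjects, 3)


def generate_cohort(spec: PhantomSpec) -> Cohort:
    """Generate the full two-group cohort: DWI, cohort table, ground truth.

    Covariates are drawn per subject from the spec's linear covariate models
    evaluated on the subject's *true* regional parameter mean.  Outputs are
    byte-identical for identical specs (including the seed).
    """
    spec.validate()
    region = spec.region_mask()
    n_total = 2 * spec.n_per_group
    seeds = _subject_seeds(spec, n_total)
    groups = ["patient"] * spec.n_per_group + ["control"] * spec.n_per_group

    subjects: list[SubjectTruth] = []
    dwis: list[DWISeries] = []
    rows = []
    for i, group in enumerate(groups):
        field_seed, dwi_seed, cov_seed = (int(s) for s in seeds[i])
        truth = build_true_fields(spec, group, field_seed)
        truth.subject_id = f"sub-{i + 1:02d}"
        cov_rng = np.random.default_rng(cov_seed)
        for name, model in spec.covariates.items():
            if model.parameter is None:
                value = model.intercept + cov_rng.normal(0.0, model.noise_sd)
            else:
                mean = truth.regional_mean(model.parameter, region)
                value = (
                    model.intercept
                    + model.slope * mean
                    + (cov_rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0)
                )
            truth.covariates[name] = float(value)
        subjects.append(truth)
        dwis.append(simulate_dwi(truth, spec, seed=dwi_seed))
        rows.append(
            {"subject_id": truth.subject_id, "group": group, **truth.covariates}
        )
    table = pd.DataFrame(rows)
    return Cohort(dwi=dwis, table=table, truth=GroundTruth(subjects, region, spec))
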