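"""Synthetic CT/dose/outcome cohorts with known ground truth.

The real study population (77 radiotherapy patients with planning CT,
3D dose and recurrence follow-up) is not publicly available, so this
module generates a stand-in cohort in which every prognostic signal is
known by construction:

* an ellipsoidal tumour VOI in a uniform soft-tissue background, filled
  with a Gaussian-random-field texture whose correlation length is set
  by a two-level latent *texture class*;
* a simultaneous-integrated-boost style dose map delivering the
  prescription to the VOI plus a 5 mm margin (D95 >= prescription by
  construction), with a smooth heterogeneity field whose amplitude is
  set by a latent *dose class*;
* clinical covariates drawn to match the published cohort marginals
  (~92% male, ~61% age >= 58, ~71% peripheral invasion, ~29% stage IVB);
* survival times from a Weibull proportional-hazards model on the two
  latent classes, with exponential + administrative censoring.

Because the latent classes drive both the images and the hazard, the
radiomic and dosiomic ends of the pipeline each carry real prognostic
information that downstream models can (and should) recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import ImageVolume, VOIMask

__all__ = [
    "PhantomSpec",
    "HazardSpec",
    "SyntheticPatient",
    "generate_images",
    "generate_survival",
    "generate_cohort",
]

#: Clinical covariate marginals of the published 77-patient cohort.
CLINICAL_MARGINALS = {
    "male": 0.922,
    "age_ge_58": 0.610,
    "peripheral_invasion": 0.714,
    "stage_ivb": 0.286,
}

# Age model: Normal(mu, sd) with P(age >= 58) matching the cohort split.
_AGE_MEAN, _AGE_SD = 60.2, 8.0

#: VOI -> boost-region expansion margin (mm), SIB-style.
BOOST_MARGIN_MM = 5.0

#: Multipliers applied to the base texture correlation length / dose
#: heterogeneity amplitude for latent class 1 (coarse texture / hot plan).
TEXTURE_CLASS_FACTOR = 3.0
TEXTURE_CLASS_AMPLITUDE_FACTOR = 1.4
DOSE_CLASS_FACTOR = 3.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one synthetic patient volume."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_radius_range: tuple[float, float] = (8.0, 14.0)  # mm
    background_hu: float = 40.0
    tumor_mean_hu: float = 60.0
    tumor_hu_sd: float = 15.0  # between-patient spread of the tumor mean
    texture_correlation_length: float = 4.0  # mm
    texture_amplitude: float = 40.0  # HU (std of the texture field)
    texture_amplitude_jitter: float = 0.15  # relative per-patient spread
    image_noise_sigma: float = 10.0  # HU
    prescription_dose: float = 70.0  # Gy
    penumbra_sigma: float = 5.0  # mm
    dose_heterogeneity_amplitude: float = 2.0  # Gy (std of the field)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes of at least 16 voxels")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValueError("tumor_radius_range must satisfy 0 < lo <= hi")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")
        if self.penumbra_sigma <= 0 or self.texture_correlation_length <= 0:
            raise ValueError("length scales must be positive")
        for name in (
            "texture_amplitude",
            "image_noise_sigma",
            "dose_heterogeneity_amplitude",
            "tumor_hu_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.texture_amplitude_jitter < 1:
            raise ValueError("texture_amplitude_jitter must be in [0, 1)")


@dataclass(frozen=True)
class HazardSpec:
    """Weibull proportional-hazards generator for the synthetic outcomes.

    Event times follow a Weibull baseline (shape/scale in months) scaled
    multiplicatively by exp(beta . x) on the latent covariates; censoring
    is the minimum of an exponential time and an administrative horizon
    near the published cohort's maximum follow-up.
    """

    beta: tuple[float, ...] = (0.8, 0.8)
    baseline_shape: float = 1.3
    baseline_scale: float = 60.0  # months
    censoring_rate: float = 0.45
    admin_horizon: float = 81.4  # months
    #: logit shift of P(stage IVB) per unit of centered latent risk; 0 keeps
    #: clinical covariates independent of outcome (the default)
    stage_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull baseline shape and scale must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.admin_horizon <= 0:
            raise ValueError("admin_horizon must be positive")
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))


@dataclass
class SyntheticPatient:
    """One simulated patient: volumes, clinical record and outcome."""

    patient_id: str
    ct: ImageVolume
    dose: ImageVolume
    voi: VOIMask
    clinical: dict
    latent: dict
    latent_risk: float
    time: float  # months
    event: int


def _smooth_field(rng: np.random.Generator, shape, spacing, corr_length_mm: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    sigma_vox = [corr_length_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    if sd == 0:  # pragma: no cover - degenerate only for pathological grids
        return np.zeros(shape)
    return smooth / sd


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip((xx, yy, zz), center_mm, radii_mm))
    return q <= 1.0


def generate_images(
    spec: PhantomSpec, patient_seed: int
) -> tuple[ImageVolume, ImageVolume, VOIMask]:
    """Generate one (CT, dose, VOI) triple.

    The VOI is an ellipsoid with radii drawn uniformly from
    ``tumor_radius_range``; if it (plus the boost margin) touches the
    grid boundary the radii are shrunk and the draw repeated.
    """
    rng = np.random.default_rng(patient_seed)
    shape, spacing = spec.grid_shape, spec.voxel_spacing
    extent = [n * s for n, s in zip(shape, spacing)]

    margin = BOOST_MARGIN_MM + max(spacing)
    lo, hi = spec.tumor_radius_range
    radii = rng.uniform(lo, hi, size=3)
    center = [e / 2 + rng.uniform(-1, 1) * sp for e, sp in zip(extent, spacing)]
    for _ in range(20):
        fits = all(
            c - r - margin > 0 and c + r + margin < e
            for c, r, e in zip(center, radii, extent)
        )
        if fits:
            break
        radii = radii * 0.8
        if radii.min() < 1.0:
            raise ValueError(
                f"tumor of radius range {spec.tumor_radius_range} mm plus "
                f"{margin:.1f} mm margin cannot fit in a grid of extent "
                f"{extent} mm: increase grid_shape or reduce tumor_radius_range"
            )
    mask_arr = _ellipsoid_mask(shape, spacing, center, radii)
    if not mask_arr.any():  # pragma: no cover - radii >= 1 mm always cover a voxel
        raise ValueError("generated VOI is empty; radii too small for voxel spacing")

    # CT: uniform background, textured tumor, global acquisition noise.
    # Tumor mean HU and texture amplitude carry per-patient spread so the
    # cohort has genuine between-patient feature variance.
    ct = np.full(shape, spec.background_hu, dtype=np.float64)
    tumor_mean = spec.tumor_mean_hu + (
        rng.normal(0.0, spec.tumor_hu_sd) if spec.tumor_hu_sd > 0 else 0.0
    )
    ct[mask_arr] = tumor_mean
    if spec.texture_amplitude > 0:
        amp = spec.texture_amplitude * rng.uniform(
            1 - spec.texture_amplitude_jitter, 1 + spec.texture_amplitude_jitter
        )
        texture = _smooth_field(rng, shape, spacing, spec.texture_correlation_length)
        ct[mask_arr] += amp * texture[mask_arr]
    if spec.image_noise_sigma > 0:
        ct += rng.normal(0.0, spec.image_noise_sigma, size=shape)

    # Dose: prescription plateau on the VOI + margin, Gaussian penumbra
    # outside, non-negative heterogeneity (hot spots) inside.
    dist_out = ndimage.distance_transform_edt(~mask_arr, sampling=spacing)
    boost = dist_out <= BOOST_MARGIN_MM  # VOI voxels have dist_out == 0
    dose = np.zeros(shape, dtype=np.float64)
    fall = ndimage.distance_transform_edt(~boost, sampling=spacing)
    dose[~boost] = spec.prescription_dose * np.exp(
        -(fall[~boost] ** 2) / (2 * spec.penumbra_sigma**2)
    )
    dose[boost] = spec.prescription_dose
    if spec.dose_heterogeneity_amplitude > 0:
        het = _smooth_field(rng, shape, spacing, 2 * BOOST_MARGIN_MM)
        het = spec.dose_heterogeneity_amplitude * het
        dose[boost] += het[boost] - het[boost].min()

    ct_vol = ImageVolume(ct, spacing)
    dose_vol = ImageVolume(dose, spacing)
    voi = VOIMask(mask_arr, spacing)
    return ct_vol, dose_vol, voi


def generate_survival(
    latent_covariates: np.ndarray,
    hz: HazardSpec,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """Draw one (time, event) pair under the proportional-hazards model.

    The event time is Weibull(shape, scale) accelerated by
    ``exp(beta . x)``; the observation is censored at the minimum of an
    exponential censoring time and the administrative horizon.
    """
    x = np.atleast_1d(np.asarray(latent_covariates, dtype=float))
    beta = np.asarray(hz.beta, dtype=float)
    if x.shape != beta.shape:
        raise ValueError(f"covariate length {x.shape} does not match beta {beta.shape}")
    if rng is None:
        rng = np.random.default_rng(hz.seed)
    u = rng.uniform()
    hr = float(np.exp(beta @ x))
    t_event = hz.baseline_scale * (-np.log(u) / hr) ** (1.0 / hz.baseline_shape)
    c = hz.admin_horizon
    if hz.censoring_rate > 0:
        cens_scale = hz.baseline_scale * (1 - hz.censoring_rate) / hz.censoring_rate
        c = min(c, rng.exponential(cens_scale))
    time = max(min(t_event, c), 1e-6)
    event = int(t_event <= c)
    return float(time), event


def _draw_clinical(rng: np.random.Generator) -> dict:
    age = rng.normal(_AGE_MEAN, _AGE_SD)
    return {
        "gender": int(rng.uniform() < CLINICAL_MARGINALS["male"]),  # 1 = male
        "age": float(np.clip(age, 18.0, 95.0)),
        "stage_ivb": int(rng.uniform() < CLINICAL_MARGINALS["stage_ivb"]),
        "peripheral_invasion": int(rng.uniform() < CLINICAL_MARGINALS["peripheral_invasion"]),
    }


def generate_cohort(
    n: int, spec: PhantomSpec, hz: HazardSpec
) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Generate a full cohort plus its clinical/outcome table.

    Each patient carries two latent binary classes: a texture class that
    multiplies the CT texture correlation length by
    ``TEXTURE_CLASS_FACTOR`` and a dose class that multiplies the dose
    heterogeneity amplitude by ``DOSE_CLASS_FACTOR``. The hazard acts on
    ``(texture_class, dose_class)`` through ``hz.beta``, so both image
    modalities carry prognostic signal.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2 patients")
    if len(hz.beta) != 2:
        raise ValueError("cohort generation uses 2 latent classes; beta must have length 2")
    seeds = np.random.SeedSequence(spec.seed).spawn(n)
    patients: list[SyntheticPatient] = []
    rows = []
    for i, ss in enumerate(seeds):
        child = ss.generate_state(2)
        rng = np.random.default_rng(ss)
        tex_class = int(rng.uniform() < 0.5)
        dose_class = int(rng.uniform() < 0.5)
        # class 1 = coarse, high-amplitude texture (necrotic-like pattern);
        # class 1 dose = hot, heterogeneous boost
        pspec = dataclasses.replace(
            spec,
            texture_correlation_length=spec.texture_correlation_length
            * (TEXTURE_CLASS_FACTOR if tex_class else 1.0),
            texture_amplitude=spec.texture_amplitude
            * (TEXTURE_CLASS_AMPLITUDE_FACTOR if tex_class else 1.0),
            dose_heterogeneity_amplitude=spec.dose_heterogeneity_amplitude
            * (DOSE_CLASS_FACTOR if dose_class else 1.0),
        )
        ct, dose, voi = generate_images(pspec, int(child[0] % (2**31)))
        clinical = _draw_clinical(rng)
        x = np.array([tex_class, dose_class], dtype=float)
        if hz.stage_coupling != 0.0:
            # tie stage IVB to the latent risk (marginal preserved by centering)
            risk_centered = float(np.asarray(hz.beta) @ (x - 0.5))
            base_logit = np.log(
                CLINICAL_MARGINALS["stage_ivb"] / (1 - CLINICAL_MARGINALS["stage_ivb"])
            )
            p_stage = 1.0 / (1.0 + np.exp(-(base_logit + hz.stage_coupling * risk_centered)))
            clinical["stage_ivb"] = int(rng.uniform() < p_stage)
        time, event = generate_survival(x, hz, rng=rng)
        pid = f"P{i:03d}"
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                ct=ct,
                dose=dose,
                voi=voi,
                clinical=clinical,
                latent={"texture_class": tex_class, "dose_class": dose_class},
                latent_risk=float(np.asarray(hz.beta) @ x),
                time=time,
                event=event,
            )
        )
        rows.append(
            {
                "patient_id": pid,
                "gender": clinical["gender"],
                "age": clinical["age"],
                "stage_ivb": clinical["stage_ivb"],
                "peripheral_invasion": clinical["peripheral_invasion"],
                "time_months": time,
                "event": event,
                "texture_class": tex_class,
                "dose_class": dose_class,
                "latent_risk": float(np.asarray(hz.beta) @ x),
            }
        )
    return patients, pd.DataFrame(rows)
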