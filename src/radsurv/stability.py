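"""Perturbation-based feature stability filtering.

Features are recomputed after perturbing the inputs — additive Gaussian
image noise (10/50/100 HU by default) and random VOI boundary
deformation (0.5/1.0 pixel-pitch RMS) — and judged by two intraclass
correlation coefficients from a one-way ANOVA decomposition over a
patients x raters matrix (raters = original + perturbed recomputations):

    ICC1 = (MSR - MSW) / (MSR + (k + 1) * MSW)      (as printed)
    ICC2 = (MSR - MSW) / MSR

where MSR is the between-patient (row) mean square, MSW the residual
mean square and k the number of raters. The printed ICC1 denominator
differs from the textbook ICC(1,1) weight (k - 1); both are available
via the ``formula`` switch and agree whenever MSW = 0.

A feature is reproducible iff ICC1 > 0.7 and ICC2 > 0.95 across every
perturbation condition of its modality; dose features are tested under
boundary perturbation only, since image noise is a CT acquisition
artifact and the planned dose is noise-free.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import DiscretizationSpec, FilterBank, extract_all
from .volume import ImageVolume, VOIMask

__all__ = [
    "PerturbationSpec",
    "add_gaussian_noise",
    "perturb_mask",
    "icc1",
    "icc2",
    "stability_filter",
    "stability_report",
]

#: smoothing length (voxels) of the random boundary displacement field
DISPLACEMENT_SMOOTHING_VOX = 4.0


@dataclass(frozen=True)
class PerturbationSpec:
    """Perturbation conditions of the stability test."""

    noise_sigmas_hu: tuple[float, ...] = (10.0, 50.0, 100.0)
    boundary_levels_pixels: tuple[float, ...] = (0.5, 1.0)
    realizations_per_level: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.noise_sigmas_hu):
            raise ValueError("noise sigmas must be non-negative")
        if any(a < 0 for a in self.boundary_levels_pixels):
            raise ValueError("boundary levels must be non-negative")
        if self.realizations_per_level < 1:
            raise ValueError("realizations_per_level must be >= 1")
        object.__setattr__(self, "noise_sigmas_hu", tuple(float(s) for s in self.noise_sigmas_hu))
        object.__setattr__(
            self, "boundary_levels_pixels", tuple(float(a) for a in self.boundary_levels_pixels)
        )

    def conditions(self, modality: str) -> list[str]:
        """Condition labels applied to a modality."""
        bound = [f"boundary_{a:g}px" for a in self.boundary_levels_pixels]
        if modality == "dosiomic":
            return bound
        return [f"noise_{s:g}HU" for s in self.noise_sigmas_hu] + bound


def add_gaussian_noise(vol: ImageVolume, sigma: float, seed: int) -> ImageVolume:
    """Add i.i.d. zero-mean Gaussian noise of the given sigma."""
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if sigma == 0:
        return vol
    rng = np.random.default_rng(seed)
    return vol.with_values(vol.values + rng.normal(0.0, sigma, size=vol.shape))


def perturb_mask(mask: VOIMask, amplitude: float, seed: int) -> VOIMask:
    """Deform the VOI boundary by a smooth random displacement field.

    Three independent white-noise fields are Gaussian-smoothed
    (``DISPLACEMENT_SMOOTHING_VOX`` voxels) and rescaled so the RMS
    displacement magnitude equals ``amplitude`` voxel pitches; the mask
    is pulled back through the field with nearest-neighbor sampling.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude == 0:
        return mask
    rng = np.random.default_rng(seed)
    shape = mask.shape
    disp = np.stack(
        [
            ndimage.gaussian_filter(
                rng.standard_normal(shape), DISPLACEMENT_SMOOTHING_VOX, mode="wrap"
            )
            for _ in range(3)
        ]
    )
    rms = float(np.sqrt((disp**2).sum(0).mean()))
    disp *= amplitude / rms
    grid = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    coords = [g + d for g, d in zip(grid, disp)]
    warped = ndimage.map_coordinates(
        mask.values.astype(np.float32), coords, order=0, mode="nearest"
    )
    out = warped > 0.5
    if not out.any():
        raise ValueError(f"boundary perturbation of {amplitude} px emptied the mask")
    return VOIMask(out, mask.spacing, mask.origin)


def _anova(m: np.ndarray) -> tuple[float, float, int]:
    """One-way ANOVA mean squares of a patients x raters matrix."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("rating matrix must be n>=2 patients by k>=2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("rating matrix must be finite")
    n, k = m.shape
    row_means = m.mean(axis=1)
    grand = m.mean()
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((m - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    return float(msr), float(msw), k


def icc1(m: np.ndarray, formula: str = "as_printed") -> float:
    """ICC(1,1): inter-rater reliability under one-way ANOVA.

    ``as_printed`` uses denominator MSR + (k+1)*MSW; ``standard`` the
    textbook MSR + (k-1)*MSW. An all-constant matrix is defined as 1.
    """
    if formula not in ("as_printed", "standard"):
        raise ValueError(f"unknown ICC1 formula {formula!r}")
    msr, msw, k = _anova(m)
    if msr == 0 and msw == 0:
        warnings.warn("constant rating matrix: ICC1 defined as 1", stacklevel=2)
        return 1.0
    weight = k + 1 if formula == "as_printed" else k - 1
    return (msr - msw) / (msr + weight * msw)


def icc2(m: np.ndarray) -> float:
    """ICC(2): non-independence index, (MSR - MSW) / MSR."""
    msr, msw, _ = _anova(m)
    if msr == 0:
        warnings.warn("zero between-patient variance: ICC2 defined as 0", stacklevel=2)
        return 0.0
    return (msr - msw) / msr


def _perturbed_features(
    patients: list[tuple[str, ImageVolume, VOIMask]],
    condition: str,
    spec: PerturbationSpec,
    disc: DiscretizationSpec,
    bank: FilterBank | None,
) -> list[pd.DataFrame]:
    """One feature table per perturbed realization under a condition."""
    kind, value = condition.split("_")
    level = float(value.rstrip("pxHU"))
    tables = []
    for r in range(spec.realizations_per_level):
        rows = {}
        for idx, (pid, vol, mask) in enumerate(patients):
            seed = np.random.SeedSequence(
                [spec.seed, zlib.crc32(condition.encode()), r, idx]
            ).generate_state(1)[0] % (2**31)
            if kind == "noise":
                rows[pid] = extract_all(
                    add_gaussian_noise(vol, level, int(seed)), mask, disc, bank
                )
            else:
                rows[pid] = extract_all(
                    vol, perturb_mask(mask, level, int(seed)), disc, bank
                )
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "patient_id"
        tables.append(df)
    return tables


def stability_report(
    patients: list[tuple[str, ImageVolume, VOIMask]],
    base_features: pd.DataFrame,
    modality: str,
    spec: PerturbationSpec,
    disc: DiscretizationSpec,
    bank: FilterBank | None,
    icc1_formula: str = "as_printed",
) -> pd.DataFrame:
    """Per-feature, per-condition ICCs over a cohort.

    The rating matrix of a feature under a condition has one column for
    the unperturbed computation and one per perturbed realization.
    """
    if modality not in ("radiomic", "dosiomic"):
        raise ValueError(f"unknown modality {modality!r}")
    records = []
    for condition in spec.conditions(modality):
        perturbed = _perturbed_features(patients, condition, spec, disc, bank)
        for feat in base_features.columns:
            cols = [base_features[feat].to_numpy()] + [t[feat].to_numpy() for t in perturbed]
            m = np.column_stack(cols)
            if not np.all(np.isfinite(m)):
                v1, v2 = -np.inf, -np.inf  # degenerate feature: never reproducible
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    v1 = icc1(m, icc1_formula)
                    v2 = icc2(m)
            records.append(
                {"feature": feat, "condition": condition, "icc1": v1, "icc2": v2}
            )
    report = pd.DataFrame.from_records(records)
    report.attrs["icc1_formula"] = icc1_formula
    report.attrs["modality"] = modality
    return report


def stability_filter(
    report: pd.DataFrame,
    modality: str,
    spec: PerturbationSpec | None = None,
    thresholds: tuple[float, float] = (0.7, 0.95),
) -> list[str]:
    """Features whose worst-condition ICC1 > t1 and ICC2 > t2 (strict).

    When a :class:`PerturbationSpec` is given, the report must cover all
    of the modality's configured conditions.
    """
    if spec is not None:
        expected = set(spec.conditions(modality))
        missing = expected - set(report["condition"])
        if missing:
            raise ValueError(f"stability report missing conditions: {sorted(missing)}")
    t1, t2 = thresholds
    worst = report.groupby("feature")[["icc1", "icc2"]].min()
    passing = worst[(worst["icc1"] > t1) & (worst["icc2"] > t2)]
    return [f for f in report["feature"].unique() if f in passing.index]
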