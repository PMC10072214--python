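"""Image filter bank: Laplacian-of-Gaussian and 3D wavelet sub-bands.

Both filters return images on the original grid so the same VOI mask
applies: LoG is spacing-aware (sigma given in mm), and the wavelet
decomposition is single-level undecimated (stationary), applying the
bior6.8 analysis low/high-pass pair along each axis with symmetric
boundary handling, yielding the 8 sub-bands LLL..HHH.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pywt
from scipy import ndimage

from ..volume import ImageVolume

__all__ = ["FilterBank", "apply_log", "apply_wavelet"]


@dataclass(frozen=True)
class FilterBank:
    """Which derived images to add to the feature pool."""

    log_sigmas: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)  # mm
    wavelet_name: str = "bior6.8"
    wavelet_level: int = 1
    include_wavelet: bool = True

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.log_sigmas):
            raise ValueError("LoG sigmas must be positive")
        if self.wavelet_level < 1:
            raise ValueError("wavelet_level must be >= 1")
        object.__setattr__(self, "log_sigmas", tuple(float(s) for s in self.log_sigmas))

    @property
    def n_images(self) -> int:
        """Number of derived images: one per sigma plus 8 sub-bands."""
        return len(self.log_sigmas) + (8 if self.include_wavelet else 0)

    def image_labels(self) -> list[str]:
        labels = [f"log-sigma-{s:g}mm" for s in self.log_sigmas]
        if self.include_wavelet:
            labels += [f"wavelet-{b}" for b in _SUBBANDS]
        return labels


_SUBBANDS = ["".join(b) for b in product("LH", repeat=3)]  # LLL, LLH, ... HHH


def apply_log(vol: ImageVolume, sigma: float) -> ImageVolume:
    """Laplacian-of-Gaussian response with sigma in physical mm."""
    if sigma <= 0:
        raise ValueError("LoG sigma must be positive")
    sigma_vox = [sigma / s for s in vol.spacing]
    out = ndimage.gaussian_laplace(vol.values, sigma=sigma_vox, mode="reflect")
    # the truncated discrete kernel has a small nonzero DC gain; remove it
    # so the operator is exactly band-pass (constant input -> 0)
    dc = ndimage.gaussian_laplace(np.ones((1, 1, 1)), sigma=sigma_vox, mode="reflect")[0, 0, 0]
    if dc != 0:
        out = out - dc * ndimage.gaussian_filter(vol.values, sigma=sigma_vox, mode="reflect")
    return vol.with_values(out)


def _min_grid(wavelet: pywt.Wavelet) -> int:
    return len(wavelet.dec_lo)


def apply_wavelet(vol: ImageVolume, bank: FilterBank) -> dict[str, ImageVolume]:
    """Single-level stationary 3D wavelet decomposition (8 sub-bands).

    Each sub-band applies the analysis low-pass (L) or high-pass (H)
    filter along the corresponding axis; no downsampling, so the
    sub-bands stay aligned with the VOI grid.
    """
    wavelet = pywt.Wavelet(bank.wavelet_name)
    need = _min_grid(wavelet)
    if min(vol.shape) < need:
        raise ValueError(
            f"grid {vol.shape} too small for {bank.wavelet_name}: "
            f"every axis must have at least {need} voxels"
        )
    # correlate1d with the reversed decomposition filter == convolution
    lo = np.asarray(wavelet.dec_lo)[::-1]
    hi = np.asarray(wavelet.dec_hi)[::-1]
    out: dict[str, ImageVolume] = {}
    for band in _SUBBANDS:
        arr = vol.values
        for axis, ch in enumerate(band):
            kernel = lo if ch == "L" else hi
            arr = ndimage.correlate1d(arr, kernel, axis=axis, mode="reflect")
        out[band] = vol.with_values(arr)
    return out
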