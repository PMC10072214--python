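"""Gray-level discretization of a masked intensity region."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizationSpec", "discretize"]


@dataclass(frozen=True)
class DiscretizationSpec:
    """How region intensities are binned before histogram/texture features.

    ``fixed_bin_width`` bins at absolute intensity edges that are
    multiples of ``bin_width`` (comparable across patients);
    ``fixed_bin_count`` uses ``bin_count`` equal-width bins spanning the
    region's own min..max.
    """

    mode: str = "fixed_bin_width"
    bin_width: float | None = 25.0
    bin_count: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_bin_width", "fixed_bin_count"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed_bin_width":
            if self.bin_width is None or self.bin_width <= 0:
                raise ValueError("fixed_bin_width requires bin_width > 0")
        else:
            if self.bin_count is None or self.bin_count < 2:
                raise ValueError("fixed_bin_count requires bin_count >= 2")


def discretize(values: np.ndarray, disc: DiscretizationSpec) -> np.ndarray:
    """Map region intensities to integer gray levels 1..Ng."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot discretize an empty region")
    if disc.mode == "fixed_bin_width":
        bw = float(disc.bin_width)
        levels = np.floor(values / bw).astype(np.int64)
        return levels - levels.min() + 1
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.int64)
    nb = int(disc.bin_count)
    levels = np.floor((values - vmin) / (vmax - vmin) * nb).astype(np.int64) + 1
    return np.minimum(levels, nb)
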