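"""The 75 texture features from the five gray-level matrix families.

Families and counts: co-occurrence (GLCM, 24), run length (GLRLM, 16),
size zone (GLSZM, 16), neighborhood gray-tone difference (NGTDM, 5) and
dependence (GLDM, 14). All matrices are built on the discretized region
in 3D: GLCM/GLRLM use the 13 unique distance-1 directions (symmetric
accumulation, features averaged over directions); GLSZM zones and
GLDM/NGTDM neighborhoods are 26-connected.

Degenerate regions (a single gray level) do not raise: each family's
conventions for that case are noted in the feature docstrings below
(e.g. GLCM Correlation -> 1, NGTDM Coarseness -> 1e6).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..volume import ImageVolume, VOIMask
from .discretize import DiscretizationSpec, discretize

__all__ = [
    "TEXTURE_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "GLDM_NAMES",
    "compute_texture",
]

#: largest finite stand-in for 1/0-type degeneracies (NGTDM coarseness)
COARSENESS_CAP = 1e6

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

TEXTURE_NAMES = tuple(
    [f"glcm_{n}" for n in GLCM_NAMES]
    + [f"glrlm_{n}" for n in GLRLM_NAMES]
    + [f"glszm_{n}" for n in GLSZM_NAMES]
    + [f"ngtdm_{n}" for n in NGTDM_NAMES]
    + [f"gldm_{n}" for n in GLDM_NAMES]
)

# 13 unique distance-1 directions in 3D (half of the 26-neighborhood)
DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

_EPS = np.finfo(float).eps


def _crop_levels(vol: ImageVolume, mask: VOIMask, disc: DiscretizationSpec):
    """Discretized levels (0 outside mask) cropped to the mask bbox."""
    mask.check_aligned(vol)
    m = mask.values
    if not m.any():
        raise ValueError("empty mask: no voxels for texture features")
    idx = np.argwhere(m)
    lo, hi = idx.min(0), idx.max(0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    mc = m[sl]
    levels = np.zeros(mc.shape, dtype=np.int64)
    levels[mc] = discretize(vol.values[sl][mc], disc)
    return levels, mc


def _shift(arr: np.ndarray, off, fill=0) -> np.ndarray:
    """Array of neighbor values at +off, aligned with arr; fill outside."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, o in zip(arr.shape, off):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------- GLCM


def _glcm_features(
    P: np.ndarray, vals: np.ndarray, n_levels: int, idx=None
) -> dict[str, float]:
    """Features of one normalized symmetric co-occurrence matrix."""
    i = vals[:, None].astype(float)
    j = vals[None, :].astype(float)
    px = P.sum(1)
    py = P.sum(0)
    ux = float((vals * px).sum())
    uy = float((vals * py).sum())
    sx = float(np.sqrt(((vals - ux) ** 2 * px).sum()))
    sy = float(np.sqrt(((vals - uy) ** 2 * py).sum()))

    # sum / difference distributions (bincount over precomputed cell codes)
    if idx is None:
        idx = _glcm_index(vals)
    sum_vals, sum_code, diff_vals, diff_code, ksum, kdiff = idx
    p_sum = np.bincount(sum_code, weights=P.ravel(), minlength=len(sum_vals))
    p_diff = np.bincount(diff_code, weights=P.ravel(), minlength=len(diff_vals))

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    diff_avg = float((diff_vals * p_diff).sum())
    hxy = ent(P)
    px_py = px[:, None] * py[None, :]
    nz = P > 0
    hxy1 = float(-(P[nz] * np.log2(px_py[nz] + _EPS)).sum())
    nz2 = px_py > 0
    hxy2 = float(-(px_py[nz2] * np.log2(px_py[nz2])).sum())
    hx = ent(px)
    hy = ent(py)
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    if n_levels > 1:
        Q = (P / np.maximum(px[:, None] * py[None, :], _EPS)) @ P.T
        eig = np.sort(np.linalg.eigvals(Q).real)
        mcc = float(np.sqrt(max(0.0, eig[-2]))) if len(eig) > 1 else 1.0
    else:
        mcc = 1.0

    offdiag = kdiff > 0
    return {
        "Autocorrelation": float((P * i * j).sum()),
        "ClusterProminence": float((P * (i + j - ux - uy) ** 4).sum()),
        "ClusterShade": float((P * (i + j - ux - uy) ** 3).sum()),
        "ClusterTendency": float((P * (i + j - ux - uy) ** 2).sum()),
        "Contrast": float((P * (i - j) ** 2).sum()),
        "Correlation": float(((P * i * j).sum() - ux * uy) / (sx * sy)) if sx > 0 and sy > 0 else 1.0,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((diff_vals - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((P / (1.0 + kdiff)).sum()),
        "Idm": float((P / (1.0 + kdiff**2)).sum()),
        "Idmn": float((P / (1.0 + (kdiff / n_levels) ** 2)).sum()),
        "Idn": float((P / (1.0 + kdiff / n_levels)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((P[offdiag] / kdiff[offdiag] ** 2).sum()),
        "JointAverage": ux,
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((sum_vals * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float((P * (i - ux) ** 2).sum()),
    }


def _glcm_index(vals: np.ndarray):
    """Precomputed sum/difference cell codes shared by all directions."""
    ksum = vals[:, None] + vals[None, :]
    kdiff = np.abs(vals[:, None] - vals[None, :])
    sum_vals, sum_code = np.unique(ksum, return_inverse=True)
    diff_vals, diff_code = np.unique(kdiff, return_inverse=True)
    return sum_vals, sum_code.ravel(), diff_vals, diff_code.ravel(), ksum, kdiff


def _glcm(levels: np.ndarray) -> dict[str, float]:
    vals = np.unique(levels[levels > 0])
    lut = np.zeros(levels.max() + 1, dtype=np.int64)
    lut[vals] = np.arange(len(vals))
    idx = _glcm_index(vals)
    n = len(vals)
    per_dir = []
    for d in DIRECTIONS_13:
        nb = _shift(levels, d)
        ok = (levels > 0) & (nb > 0)
        if not ok.any():
            continue
        a = lut[levels[ok]]
        b = lut[nb[ok]]
        P = np.bincount(a * n + b, minlength=n * n).reshape(n, n).astype(float)
        P = P + P.T  # symmetric accumulation
        per_dir.append(_glcm_features(P / P.sum(), vals, n, idx))
    if not per_dir:  # single-voxel region: no pairs in any direction
        per_dir = [_glcm_features(np.ones((1, 1)), vals[:1], 1)]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


# --------------------------------------------------------------- GLRLM


def _run_matrix(levels: np.ndarray, d) -> np.ndarray:
    """Run-length counts P[level, length] for one direction."""
    inm = levels > 0
    nxt = _shift(levels, d)
    prev = _shift(levels, tuple(-x for x in d))
    cont = inm & (nxt == levels) & (nxt > 0)  # run continues at +d
    start = inm & ~((prev == levels) & (prev > 0))
    # tail[v] = number of consecutive continuations starting at v
    tail = np.zeros(levels.shape, dtype=np.int64)
    while True:
        new = np.where(cont, 1 + _shift(tail, d), 0)
        if (new == tail).all():
            break
        tail = new
    lengths = 1 + tail[start]
    lv = levels[start]
    P = np.zeros((levels.max() + 1, lengths.max() + 1))
    np.add.at(P, (lv, lengths), 1.0)
    return P


def _rl_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    iv = np.arange(P.shape[0], dtype=float)[:, None]
    jv = np.arange(P.shape[1], dtype=float)[None, :]
    iv[0, 0] = jv[0, 0] = 1.0  # level/length 0 rows are empty; avoid 0-div
    Nr = P.sum()
    p = P / Nr
    mu_i = (iv * p).sum()
    mu_j = (jv * p).sum()
    pnz = p[p > 0]
    return {
        "GrayLevelNonUniformity": float((P.sum(1) ** 2).sum() / Nr),
        "GrayLevelNonUniformityNormalized": float((P.sum(1) ** 2).sum() / Nr**2),
        "GrayLevelVariance": float((p * (iv - mu_i) ** 2).sum()),
        "HighGrayLevelRunEmphasis": float((P * iv**2).sum() / Nr),
        "LongRunEmphasis": float((P * jv**2).sum() / Nr),
        "LongRunHighGrayLevelEmphasis": float((P * iv**2 * jv**2).sum() / Nr),
        "LongRunLowGrayLevelEmphasis": float((P * jv**2 / iv**2).sum() / Nr),
        "LowGrayLevelRunEmphasis": float((P / iv**2).sum() / Nr),
        "RunEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "RunLengthNonUniformity": float((P.sum(0) ** 2).sum() / Nr),
        "RunLengthNonUniformityNormalized": float((P.sum(0) ** 2).sum() / Nr**2),
        "RunPercentage": float(Nr / n_voxels),
        "RunVariance": float((p * (jv - mu_j) ** 2).sum()),
        "ShortRunEmphasis": float((P / jv**2).sum() / Nr),
        "ShortRunHighGrayLevelEmphasis": float((P * iv**2 / jv**2).sum() / Nr),
        "ShortRunLowGrayLevelEmphasis": float((P / (iv**2 * jv**2)).sum() / Nr),
    }


def _glrlm(levels: np.ndarray) -> dict[str, float]:
    n_vox = int((levels > 0).sum())
    per_dir = [_rl_features(_run_matrix(levels, d), n_vox) for d in DIRECTIONS_13]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


# --------------------------------------------------------------- GLSZM


def _glszm(levels: np.ndarray) -> dict[str, float]:
    structure = np.ones((3, 3, 3), dtype=int)
    zone_levels = []
    zone_sizes = []
    for g in np.unique(levels[levels > 0]):
        lab, nlab = ndimage.label(levels == g, structure=structure)
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            zone_levels.extend([g] * nlab)
            zone_sizes.extend(sizes.tolist())
    iv = np.asarray(zone_levels, dtype=float)
    jv = np.asarray(zone_sizes, dtype=float)
    Nz = len(iv)
    Np = int((levels > 0).sum())
    p = np.full(Nz, 1.0 / Nz)
    mu_i = (iv * p).sum()
    mu_j = (jv * p).sum()
    # marginals over distinct levels / sizes for the non-uniformities
    lvl_counts = np.array([(iv == g).sum() for g in np.unique(iv)], dtype=float)
    size_counts = np.array([(jv == s).sum() for s in np.unique(jv)], dtype=float)
    # zone-probability entropy over (level, size) cells
    cells: dict[tuple[float, float], int] = {}
    for g, s in zip(iv, jv):
        cells[(g, s)] = cells.get((g, s), 0) + 1
    pc = np.array(list(cells.values()), dtype=float) / Nz
    return {
        "GrayLevelNonUniformity": float((lvl_counts**2).sum() / Nz),
        "GrayLevelNonUniformityNormalized": float((lvl_counts**2).sum() / Nz**2),
        "GrayLevelVariance": float((p * (iv - mu_i) ** 2).sum()),
        "HighGrayLevelZoneEmphasis": float((iv**2).mean()),
        "LargeAreaEmphasis": float((jv**2).mean()),
        "LargeAreaHighGrayLevelEmphasis": float((iv**2 * jv**2).mean()),
        "LargeAreaLowGrayLevelEmphasis": float((jv**2 / iv**2).mean()),
        "LowGrayLevelZoneEmphasis": float((1.0 / iv**2).mean()),
        "SizeZoneNonUniformity": float((size_counts**2).sum() / Nz),
        "SizeZoneNonUniformityNormalized": float((size_counts**2).sum() / Nz**2),
        "SmallAreaEmphasis": float((1.0 / jv**2).mean()),
        "SmallAreaHighGrayLevelEmphasis": float((iv**2 / jv**2).mean()),
        "SmallAreaLowGrayLevelEmphasis": float((1.0 / (iv**2 * jv**2)).mean()),
        "ZoneEntropy": float(-(pc * np.log2(pc)).sum()),
        "ZonePercentage": float(Nz / Np),
        "ZoneVariance": float((p * (jv - mu_j) ** 2).sum()),
    }


# --------------------------------------------------------------- NGTDM


def _neighbor_stats(levels: np.ndarray):
    """Per-voxel sum and count of in-mask 26-neighbor levels."""
    inm = levels > 0
    nsum = np.zeros(levels.shape, dtype=float)
    ncnt = np.zeros(levels.shape, dtype=float)
    for off in OFFSETS_26:
        nb = _shift(levels, off)
        ok = nb > 0
        nsum += np.where(ok, nb, 0)
        ncnt += ok
    return inm, nsum, ncnt


def _ngtdm(levels: np.ndarray) -> dict[str, float]:
    inm, nsum, ncnt = _neighbor_stats(levels)
    valid = inm & (ncnt > 0)
    Nv = int(valid.sum())
    if Nv == 0:  # single voxel with no neighbors
        return {k: (COARSENESS_CAP if k == "Coarseness" else 0.0) for k in NGTDM_NAMES}
    diff = np.abs(levels - nsum / np.maximum(ncnt, 1))
    lv = levels[valid]
    dv = diff[valid]
    gmax = int(lv.max())
    s = np.zeros(gmax + 1)
    n = np.zeros(gmax + 1)
    np.add.at(s, lv, dv)
    np.add.at(n, lv, 1.0)
    present = np.flatnonzero(n > 0)
    p = n / Nv
    pi = p[present]
    si = s[present]
    gi = present.astype(float)
    ngp = len(present)

    sum_ps = float((pi * si).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else COARSENESS_CAP

    if ngp > 1:
        dij2 = (gi[:, None] - gi[None, :]) ** 2
        contrast = float(
            (pi[:, None] * pi[None, :] * dij2).sum() / (ngp * (ngp - 1)) * (si.sum() / Nv)
        )
        denom_busy = float(np.abs(gi[:, None] * pi[:, None] - gi[None, :] * pi[None, :]).sum())
        busyness = sum_ps / denom_busy if denom_busy > 0 else 0.0
        complexity = float(
            (
                np.abs(gi[:, None] - gi[None, :])
                * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                / (pi[:, None] + pi[None, :])
            ).sum()
            / Nv
        )
        strength = (
            float(((pi[:, None] + pi[None, :]) * dij2).sum()) / si.sum()
            if si.sum() > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": float(min(coarseness, COARSENESS_CAP)),
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ---------------------------------------------------------------- GLDM


def _gldm(levels: np.ndarray, alpha: int = 0) -> dict[str, float]:
    inm = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        nb = _shift(levels, off)
        dep += (nb > 0) & (np.abs(nb - levels) <= alpha)
    lv = levels[inm]
    jv_vox = dep[inm] + 1  # dependence size counts the voxel itself
    P = np.zeros((levels.max() + 1, jv_vox.max() + 1))
    np.add.at(P, (lv, jv_vox), 1.0)
    Nz = P.sum()
    p = P / Nz
    iv = np.arange(P.shape[0], dtype=float)[:, None]
    jv = np.arange(P.shape[1], dtype=float)[None, :]
    iv[0, 0] = jv[0, 0] = 1.0
    mu_i = (iv * p).sum()
    mu_j = (jv * p).sum()
    pnz = p[p > 0]
    return {
        "DependenceEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "DependenceNonUniformity": float((P.sum(0) ** 2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((P.sum(0) ** 2).sum() / Nz**2),
        "DependenceVariance": float((p * (jv - mu_j) ** 2).sum()),
        "GrayLevelNonUniformity": float((P.sum(1) ** 2).sum() / Nz),
        "GrayLevelVariance": float((p * (iv - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((P * iv**2).sum() / Nz),
        "LargeDependenceEmphasis": float((P * jv**2).sum() / Nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * iv**2 * jv**2).sum() / Nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * jv**2 / iv**2).sum() / Nz),
        "LowGrayLevelEmphasis": float((P / iv**2).sum() / Nz),
        "SmallDependenceEmphasis": float((P / jv**2).sum() / Nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * iv**2 / jv**2).sum() / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (iv**2 * jv**2)).sum() / Nz),
    }


def compute_texture(
    vol: ImageVolume, mask: VOIMask, disc: DiscretizationSpec
) -> dict[str, float]:
    """All 75 texture features of the masked, discretized region."""
    levels, _ = _crop_levels(vol, mask, disc)
    out: dict[str, float] = {}
    out.update({f"glcm_{k}": v for k, v in _glcm(levels).items()})
    out.update({f"glrlm_{k}": v for k, v in _glrlm(levels).items()})
    out.update({f"glszm_{k}": v for k, v in _glszm(levels).items()})
    out.update({f"ngtdm_{k}": v for k, v in _ngtdm(levels).items()})
    out.update({f"gldm_{k}": v for k, v in _gldm(levels).items()})
    return out
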