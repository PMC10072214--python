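"""Independent brute-force oracles used only by the test suite.

Everything here is written with plain Python loops and dictionaries —
no shared code with the package implementations — so agreement between
the two routes checks both the matrix construction and the feature
formulas.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

DIRS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
NEIGH_26 = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def _voxels(levels):
    return [tuple(p) for p in np.argwhere(levels > 0)]


def _entropy2(probs):
    return -sum(p * math.log2(p) for p in probs if p > 0)


# ------------------------------------------------------------- GLCM


def glcm_oracle(levels: np.ndarray) -> dict[str, float]:
    shape = levels.shape
    grays = sorted({int(levels[p]) for p in _voxels(levels)})
    ng = len(grays)
    per_dir = []
    for d in DIRS_13:
        counts: dict[tuple[int, int], float] = {}
        for p in _voxels(levels):
            q = tuple(a + b for a, b in zip(p, d))
            if _inside(shape, q) and levels[q] > 0:
                a, b = int(levels[p]), int(levels[q])
                counts[(a, b)] = counts.get((a, b), 0) + 1
                counts[(b, a)] = counts.get((b, a), 0) + 1
        if not counts:
            continue
        total = sum(counts.values())
        p_ij = {k: v / total for k, v in counts.items()}
        per_dir.append(_glcm_formulas(p_ij, grays, ng))
    if not per_dir:
        per_dir = [_glcm_formulas({(grays[0], grays[0]): 1.0}, grays[:1], 1)]
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in per_dir[0]}


def _glcm_formulas(p_ij, grays, ng):
    px = {i: sum(p_ij.get((i, j), 0) for j in grays) for i in grays}
    py = {j: sum(p_ij.get((i, j), 0) for i in grays) for j in grays}
    ux = sum(i * px[i] for i in grays)
    uy = sum(j * py[j] for j in grays)
    sx = math.sqrt(sum((i - ux) ** 2 * px[i] for i in grays))
    sy = math.sqrt(sum((j - uy) ** 2 * py[j] for j in grays))
    psum: dict[int, float] = {}
    pdiff: dict[int, float] = {}
    for (i, j), v in p_ij.items():
        psum[i + j] = psum.get(i + j, 0) + v
        pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0) + v
    da = sum(k * v for k, v in pdiff.items())
    hxy = _entropy2(p_ij.values())
    hx = _entropy2(px.values())
    hy = _entropy2(py.values())
    eps = np.finfo(float).eps
    hxy1 = -sum(v * math.log2(px[i] * py[j] + eps) for (i, j), v in p_ij.items())
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in grays
        for j in grays
        if px[i] * py[j] > 0
    )
    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0
    if ng > 1:
        Q = np.zeros((ng, ng))
        gi = {g: n for n, g in enumerate(grays)}
        for i in grays:
            for j in grays:
                Q[gi[i], gi[j]] = sum(
                    p_ij.get((i, k), 0) * p_ij.get((j, k), 0) / max(px[i] * py[k], eps)
                    for k in grays
                )
        eig = sorted(np.linalg.eigvals(Q).real)
        mcc = math.sqrt(max(0.0, eig[-2]))
    else:
        mcc = 1.0
    corr = (
        (sum(i * j * v for (i, j), v in p_ij.items()) - ux * uy) / (sx * sy)
        if sx > 0 and sy > 0
        else 1.0
    )
    return {
        "Autocorrelation": sum(i * j * v for (i, j), v in p_ij.items()),
        "ClusterProminence": sum((i + j - ux - uy) ** 4 * v for (i, j), v in p_ij.items()),
        "ClusterShade": sum((i + j - ux - uy) ** 3 * v for (i, j), v in p_ij.items()),
        "ClusterTendency": sum((i + j - ux - uy) ** 2 * v for (i, j), v in p_ij.items()),
        "Contrast": sum((i - j) ** 2 * v for (i, j), v in p_ij.items()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(pdiff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "Id": sum(v / (1 + abs(i - j)) for (i, j), v in p_ij.items()),
        "Idm": sum(v / (1 + (i - j) ** 2) for (i, j), v in p_ij.items()),
        "Idmn": sum(v / (1 + ((i - j) / ng) ** 2) for (i, j), v in p_ij.items()),
        "Idn": sum(v / (1 + abs(i - j) / ng) for (i, j), v in p_ij.items()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": sum(v / (i - j) ** 2 for (i, j), v in p_ij.items() if i != j),
        "JointAverage": ux,
        "JointEnergy": sum(v**2 for v in p_ij.values()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": max(p_ij.values()),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": _entropy2(psum.values()),
        "SumSquares": sum((i - ux) ** 2 * v for (i, j), v in p_ij.items()),
    }


# ------------------------------------------------------------ GLRLM


def _runs(levels, d):
    """All runs (level, length) along direction d, walking every line."""
    shape = levels.shape
    runs = []
    for p in _voxels(levels):
        prev = tuple(a - b for a, b in zip(p, d))
        if _inside(shape, prev) and levels[prev] == levels[p] and levels[prev] > 0:
            continue  # not a run start
        length = 1
        cur = p
        while True:
            nxt = tuple(a + b for a, b in zip(cur, d))
            if _inside(shape, nxt) and levels[nxt] == levels[cur] and levels[nxt] > 0:
                length += 1
                cur = nxt
            else:
                break
        runs.append((int(levels[p]), length))
    return runs


def _rl_formulas(runs, n_vox):
    nr = len(runs)
    counts: dict[tuple[int, int], int] = {}
    for r in runs:
        counts[r] = counts.get(r, 0) + 1
    p = {k: v / nr for k, v in counts.items()}
    mu_i = sum(i * v for (i, _), v in p.items())
    mu_j = sum(j * v for (_, j), v in p.items())
    by_level: dict[int, int] = {}
    by_len: dict[int, int] = {}
    for (i, j), v in counts.items():
        by_level[i] = by_level.get(i, 0) + v
        by_len[j] = by_len.get(j, 0) + v
    return {
        "GrayLevelNonUniformity": sum(v**2 for v in by_level.values()) / nr,
        "GrayLevelNonUniformityNormalized": sum(v**2 for v in by_level.values()) / nr**2,
        "GrayLevelVariance": sum((i - mu_i) ** 2 * v for (i, _), v in p.items()),
        "HighGrayLevelRunEmphasis": sum(i**2 * v for (i, _), v in counts.items()) / nr,
        "LongRunEmphasis": sum(j**2 * v for (_, j), v in counts.items()) / nr,
        "LongRunHighGrayLevelEmphasis": sum(i**2 * j**2 * v for (i, j), v in counts.items()) / nr,
        "LongRunLowGrayLevelEmphasis": sum(j**2 / i**2 * v for (i, j), v in counts.items()) / nr,
        "LowGrayLevelRunEmphasis": sum(v / i**2 for (i, _), v in counts.items()) / nr,
        "RunEntropy": _entropy2(p.values()),
        "RunLengthNonUniformity": sum(v**2 for v in by_len.values()) / nr,
        "RunLengthNonUniformityNormalized": sum(v**2 for v in by_len.values()) / nr**2,
        "RunPercentage": nr / n_vox,
        "RunVariance": sum((j - mu_j) ** 2 * v for (_, j), v in p.items()),
        "ShortRunEmphasis": sum(v / j**2 for (_, j), v in counts.items()) / nr,
        "ShortRunHighGrayLevelEmphasis": sum(i**2 / j**2 * v for (i, j), v in counts.items()) / nr,
        "ShortRunLowGrayLevelEmphasis": sum(v / (i**2 * j**2) for (i, j), v in counts.items()) / nr,
    }


def glrlm_oracle(levels: np.ndarray) -> dict[str, float]:
    n_vox = len(_voxels(levels))
    per_dir = [_rl_formulas(_runs(levels, d), n_vox) for d in DIRS_13]
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in per_dir[0]}


# ------------------------------------------------------------ GLSZM


def glszm_oracle(levels: np.ndarray) -> dict[str, float]:
    shape = levels.shape
    seen: set[tuple[int, int, int]] = set()
    zones = []  # (level, size)
    for p in _voxels(levels):
        if p in seen:
            continue
        g = int(levels[p])
        stack, zone = [p], set()
        seen.add(p)
        while stack:
            cur = stack.pop()
            zone.add(cur)
            for off in NEIGH_26:
                q = tuple(a + b for a, b in zip(cur, off))
                if _inside(shape, q) and q not in seen and levels[q] == g:
                    seen.add(q)
                    stack.append(q)
        zones.append((g, len(zone)))
    nz = len(zones)
    n_vox = len(_voxels(levels))
    counts: dict[tuple[int, int], int] = {}
    for z in zones:
        counts[z] = counts.get(z, 0) + 1
    p = {k: v / nz for k, v in counts.items()}
    mu_i = sum(i * v for (i, _), v in p.items())
    mu_j = sum(s * v for (_, s), v in p.items())
    by_level: dict[int, int] = {}
    by_size: dict[int, int] = {}
    for (i, s), v in counts.items():
        by_level[i] = by_level.get(i, 0) + v
        by_size[s] = by_size.get(s, 0) + v
    return {
        "GrayLevelNonUniformity": sum(v**2 for v in by_level.values()) / nz,
        "GrayLevelNonUniformityNormalized": sum(v**2 for v in by_level.values()) / nz**2,
        "GrayLevelVariance": sum((i - mu_i) ** 2 * v for (i, _), v in p.items()),
        "HighGrayLevelZoneEmphasis": sum(i**2 * v for (i, _), v in counts.items()) / nz,
        "LargeAreaEmphasis": sum(s**2 * v for (_, s), v in counts.items()) / nz,
        "LargeAreaHighGrayLevelEmphasis": sum(i**2 * s**2 * v for (i, s), v in counts.items()) / nz,
        "LargeAreaLowGrayLevelEmphasis": sum(s**2 / i**2 * v for (i, s), v in counts.items()) / nz,
        "LowGrayLevelZoneEmphasis": sum(v / i**2 for (i, _), v in counts.items()) / nz,
        "SizeZoneNonUniformity": sum(v**2 for v in by_size.values()) / nz,
        "SizeZoneNonUniformityNormalized": sum(v**2 for v in by_size.values()) / nz**2,
        "SmallAreaEmphasis": sum(v / s**2 for (_, s), v in counts.items()) / nz,
        "SmallAreaHighGrayLevelEmphasis": sum(i**2 / s**2 * v for (i, s), v in counts.items()) / nz,
        "SmallAreaLowGrayLevelEmphasis": sum(v / (i**2 * s**2) for (i, s), v in counts.items()) / nz,
        "ZoneEntropy": _entropy2(p.values()),
        "ZonePercentage": nz / n_vox,
        "ZoneVariance": sum((s - mu_j) ** 2 * v for (_, s), v in p.items()),
    }


# ------------------------------------------------------------ NGTDM


def ngtdm_oracle(levels: np.ndarray) -> dict[str, float]:
    shape = levels.shape
    s: dict[int, float] = {}
    n: dict[int, int] = {}
    nv = 0
    for p in _voxels(levels):
        nbrs = []
        for off in NEIGH_26:
            q = tuple(a + b for a, b in zip(p, off))
            if _inside(shape, q) and levels[q] > 0:
                nbrs.append(int(levels[q]))
        if not nbrs:
            continue
        nv += 1
        g = int(levels[p])
        diff = abs(g - sum(nbrs) / len(nbrs))
        s[g] = s.get(g, 0.0) + diff
        n[g] = n.get(g, 0) + 1
    if nv == 0:
        return {"Busyness": 0.0, "Coarseness": 1e6, "Complexity": 0.0,
                "Contrast": 0.0, "Strength": 0.0}
    grays = sorted(n)
    ngp = len(grays)
    p = {g: n[g] / nv for g in grays}
    sum_ps = sum(p[g] * s[g] for g in grays)
    coarseness = min(1.0 / sum_ps, 1e6) if sum_ps > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in grays for j in grays)
            / (ngp * (ngp - 1))
            * (sum(s.values()) / nv)
        )
        denom = sum(abs(i * p[i] - j * p[j]) for i in grays for j in grays)
        busyness = sum_ps / denom if denom > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in grays
                for j in grays
            )
            / nv
        )
        stot = sum(s.values())
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in grays for j in grays) / stot
            if stot > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ------------------------------------------------------------- GLDM


def gldm_oracle(levels: np.ndarray, alpha: int = 0) -> dict[str, float]:
    shape = levels.shape
    counts: dict[tuple[int, int], int] = {}
    for p in _voxels(levels):
        g = int(levels[p])
        dep = 1
        for off in NEIGH_26:
            q = tuple(a + b for a, b in zip(p, off))
            if _inside(shape, q) and levels[q] > 0 and abs(int(levels[q]) - g) <= alpha:
                dep += 1
        counts[(g, dep)] = counts.get((g, dep), 0) + 1
    nz = sum(counts.values())
    p = {k: v / nz for k, v in counts.items()}
    mu_i = sum(i * v for (i, _), v in p.items())
    mu_j = sum(j * v for (_, j), v in p.items())
    by_level: dict[int, int] = {}
    by_dep: dict[int, int] = {}
    for (i, j), v in counts.items():
        by_level[i] = by_level.get(i, 0) + v
        by_dep[j] = by_dep.get(j, 0) + v
    return {
        "DependenceEntropy": _entropy2(p.values()),
        "DependenceNonUniformity": sum(v**2 for v in by_dep.values()) / nz,
        "DependenceNonUniformityNormalized": sum(v**2 for v in by_dep.values()) / nz**2,
        "DependenceVariance": sum((j - mu_j) ** 2 * v for (_, j), v in p.items()),
        "GrayLevelNonUniformity": sum(v**2 for v in by_level.values()) / nz,
        "GrayLevelVariance": sum((i - mu_i) ** 2 * v for (i, _), v in p.items()),
        "HighGrayLevelEmphasis": sum(i**2 * v for (i, _), v in counts.items()) / nz,
        "LargeDependenceEmphasis": sum(j**2 * v for (_, j), v in counts.items()) / nz,
        "LargeDependenceHighGrayLevelEmphasis": sum(i**2 * j**2 * v for (i, j), v in counts.items()) / nz,
        "LargeDependenceLowGrayLevelEmphasis": sum(j**2 / i**2 * v for (i, j), v in counts.items()) / nz,
        "LowGrayLevelEmphasis": sum(v / i**2 for (i, _), v in counts.items()) / nz,
        "SmallDependenceEmphasis": sum(v / j**2 for (_, j), v in counts.items()) / nz,
        "SmallDependenceHighGrayLevelEmphasis": sum(i**2 / j**2 * v for (i, j), v in counts.items()) / nz,
        "SmallDependenceLowGrayLevelEmphasis": sum(v / (i**2 * j**2) for (i, j), v in counts.items()) / nz,
    }


def texture_oracle(levels: np.ndarray) -> dict[str, float]:
    """All 75 features, keyed the same way as compute_texture."""
    out = {}
    out.update({f"glcm_{k}": v for k, v in glcm_oracle(levels).items()})
    out.update({f"glrlm_{k}": v for k, v in glrlm_oracle(levels).items()})
    out.update({f"glszm_{k}": v for k, v in glszm_oracle(levels).items()})
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_oracle(levels).items()})
    out.update({f"gldm_{k}": v for k, v in gldm_oracle(levels).items()})
    return out


# ---------------------------------------------------- ANOVA / ICC


def anova_icc_oracle(m: np.ndarray, k_weight: int) -> tuple[float, float]:
    """(ICC1 with given denominator weight on MSW, ICC2) by explicit sums."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_rows = k * sum((m[i].mean() - grand) ** 2 for i in range(n))
    ss_within = sum((m[i, j] - m[i].mean()) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msw = ss_within / (n * (k - 1))
    icc1 = (msr - msw) / (msr + k_weight * msw)
    icc2 = (msr - msw) / msr
    return icc1, icc2


# ------------------------------------------------- survival oracles


def c_index_oracle(time, event, risk, tie_mode) -> float:
    """Exhaustive pair enumeration of the concordance index."""
    num = den = 0.0
    n = len(time)
    for j in range(n):
        for i in range(n):
            if time[j] < time[i] and event[j] == 1:
                den += 1
                if risk[j] > risk[i]:
                    num += 1
                elif risk[j] == risk[i] and tie_mode == "half":
                    num += 0.5
    return num / den


def km_oracle(time, event):
    """Hand product-limit estimate at each distinct event time."""
    times = sorted(set(time))
    s = 1.0
    out = []
    for t in times:
        at_risk = sum(1 for x in time if x >= t)
        deaths = sum(1 for x, e in zip(time, event) if x == t and e == 1)
        if deaths:
            s *= 1 - deaths / at_risk
        out.append((t, s))
    return out


def logrank_oracle(time_a, event_a, time_b, event_b) -> float:
    """Chi-square from the hand-tabulated O/E/V risk table."""
    times = sorted({t for t, e in zip(list(time_a) + list(time_b),
                                      list(event_a) + list(event_b)) if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n_a = sum(1 for x in time_a if x >= t)
        n_b = sum(1 for x in time_b if x >= t)
        d_a = sum(1 for x, e in zip(time_a, event_a) if x == t and e == 1)
        d_b = sum(1 for x, e in zip(time_b, event_b) if x == t and e == 1)
        n = n_a + n_b
        d = d_a + d_b
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def cox_loglik_oracle(beta, time, event, x):
    """Breslow log partial likelihood for a single covariate, no ties."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk_set = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk_set))
    return ll
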