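"""Gray-level matrix engines and first-order/shape descriptors.

Implements the standard radiomic feature classes on a discretized image
restricted to a mask: first-order statistics (18), gray-level co-occurrence
(22), run-length (16), size-zone (16), neighborhood gray-tone difference (5),
gray-level dependence (14), and mesh-based shape descriptors (14).

Conventions: gray levels are 1..Ng from fixed-bin-width discretization
anchored at zero; co-occurrence/run-length use the 13 unique 3-D directions
at voxel distance 1 with features averaged over directions; zones and
dependence use 26-connectivity; all logs are base 2 with 0·log(0) := 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

_EPS = np.finfo(np.float64).tiny

# 13 unique direction offsets covering the 26-neighborhood up to sign
DIRECTIONS = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=int,
)


def discretize(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Fixed-bin-width discretization to integer levels 1..Ng, bins anchored at 0."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    g = np.floor(values / bin_width) - np.floor(values.min() / bin_width) + 1
    g = g.astype(np.int64)
    return g, int(g.max())


def _xlog2(p: np.ndarray) -> np.ndarray:
    return p * np.log2(p + _EPS)


def _shift_view(arr: np.ndarray, off: np.ndarray):
    """Source/destination slice pair for shifting ``arr`` by ``off``."""
    src, dst = [], []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    return tuple(src), tuple(dst)


# --------------------------------------------------------------------------
# First order
# --------------------------------------------------------------------------

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]


def firstorder_features(
    values: np.ndarray, voxel_volume: float, bin_width: float
) -> dict[str, float]:
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    g, ng = discretize(x, bin_width)
    p = np.bincount(g)[1:] / n
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if sd > 0:
        m = x - mean
        skew = np.mean(m**3) / sd**3
        kurt = np.mean(m**4) / var**2  # Pearson (not excess) kurtosis
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume * np.sum(x**2)),
        "Entropy": float(-np.sum(_xlog2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(med),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }


# --------------------------------------------------------------------------
# GLCM (22 features)
# --------------------------------------------------------------------------

GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "SumEntropy", "SumSquares",
]


def glcm_features(G: np.ndarray, mask: np.ndarray, ng: int) -> dict[str, float]:
    mats = []
    for off in DIRECTIONS:
        src, dst = _shift_view(G, off)
        valid = mask[dst] & mask[src]
        gi = G[dst][valid]
        gj = G[src][valid]
        if gi.size == 0:
            continue
        cnt = np.bincount((gi - 1) * ng + (gj - 1), minlength=ng * ng).reshape(ng, ng)
        cnt = cnt + cnt.T  # symmetric
        mats.append(cnt / cnt.sum())
    if not mats:
        return {k: np.nan for k in GLCM_NAMES}
    P = np.stack(mats)  # (D, Ng, Ng)
    i = np.arange(1, ng + 1)
    I = i[None, :, None].astype(float)
    J = i[None, None, :].astype(float)
    px = P.sum(axis=2)  # (D, Ng)
    mu = (i * px).sum(axis=1)  # == mu_x == mu_y by symmetry
    sig2 = ((i - mu[:, None]) ** 2 * px).sum(axis=1)
    sig = np.sqrt(sig2)

    k_diff = np.arange(ng)
    k_sum = np.arange(2, 2 * ng + 1)
    D = P.shape[0]
    pxmy = np.zeros((D, ng))
    pxpy = np.zeros((D, 2 * ng - 1))
    absdiff = np.abs(I - J).astype(int)[0]
    sums = (I + J).astype(int)[0]
    for d in range(D):
        pxmy[d] = np.bincount(absdiff.ravel(), weights=P[d].ravel(), minlength=ng)
        pxpy[d] = np.bincount(
            sums.ravel() - 2, weights=P[d].ravel(), minlength=2 * ng - 1
        )

    da = (k_diff * pxmy).sum(axis=1)
    hxy = -(_xlog2(P)).sum(axis=(1, 2))
    hx = -(_xlog2(px)).sum(axis=1)
    pxy_outer = px[:, :, None] * px[:, None, :]
    hxy1 = -(P * np.log2(pxy_outer + _EPS)).sum(axis=(1, 2))
    hxy2 = -(_xlog2(pxy_outer)).sum(axis=(1, 2))
    denom = np.maximum(hx, _EPS)
    imc1 = np.where(hx > 0, (hxy - hxy1) / denom, 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))

    with np.errstate(divide="ignore", invalid="ignore"):
        corr = ((I * J * P).sum(axis=(1, 2)) - mu * mu) / (sig * sig)
    corr = np.where(sig > 0, corr, 1.0)
    offdiag = absdiff > 0
    inv_var = np.array(
        [(P[d][offdiag] / (absdiff[offdiag] ** 2)).sum() for d in range(D)]
    )

    feats = {
        "Autocorrelation": (I * J * P).sum(axis=(1, 2)),
        "ClusterProminence": (((I + J - 2 * mu[:, None, None]) ** 4) * P).sum(axis=(1, 2)),
        "ClusterShade": (((I + J - 2 * mu[:, None, None]) ** 3) * P).sum(axis=(1, 2)),
        "ClusterTendency": (((I + J - 2 * mu[:, None, None]) ** 2) * P).sum(axis=(1, 2)),
        "Contrast": (((I - J) ** 2) * P).sum(axis=(1, 2)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -(_xlog2(pxmy)).sum(axis=1),
        "DifferenceVariance": (((k_diff - da[:, None]) ** 2) * pxmy).sum(axis=1),
        "Id": (pxmy / (1.0 + k_diff)).sum(axis=1),
        "Idm": (pxmy / (1.0 + k_diff**2)).sum(axis=1),
        "Idmn": (pxmy / (1.0 + (k_diff / ng) ** 2)).sum(axis=1),
        "Idn": (pxmy / (1.0 + k_diff / ng)).sum(axis=1),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": (P**2).sum(axis=(1, 2)),
        "JointEntropy": hxy,
        "MaximumProbability": P.max(axis=(1, 2)),
        "SumEntropy": -(_xlog2(pxpy)).sum(axis=1),
        "SumSquares": (((I - mu[:, None, None]) ** 2) * P).sum(axis=(1, 2)),
    }
    return {k: float(np.mean(v)) for k, v in feats.items()}


# --------------------------------------------------------------------------
# GLRLM (16 features)
# --------------------------------------------------------------------------

GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]


def _run_matrix(G: np.ndarray, mask: np.ndarray, off: np.ndarray, ng: int) -> np.ndarray:
    """Run-length matrix P(g, l) for one direction via uniform-window counts.

    A_l(g) counts length-l uniform in-mask windows; maximal runs of length m
    contribute (m-l+1) to A_l, so R(m) = A_m - 2 A_{m+1} + A_{m+2}.
    """
    max_len = max(G.shape)
    A = [np.bincount(G[mask], minlength=ng + 1)]
    U = mask.copy()
    for l in range(2, max_len + 1):
        step = (l - 1) * off
        if any(abs(s) >= n for s, n in zip(step, G.shape)):
            break
        src, dst = _shift_view(G, step)
        ok = np.zeros_like(mask)
        ok[dst] = U[dst] & mask[src] & (G[dst] == G[src])
        U = ok
        cnt = np.bincount(G[U], minlength=ng + 1)
        A.append(cnt)
        if cnt.sum() == 0:
            break
    A = np.array(A + [np.zeros(ng + 1, dtype=int)] * 2)
    L = len(A) - 2
    R = A[:L] - 2 * A[1 : L + 1] + A[2 : L + 2]
    return np.clip(R[:, 1:].T, 0, None).astype(float)  # (Ng, L)


def _rl_style_features(P: np.ndarray, n_voxels: int, prefix: tuple[str, ...]) -> dict[str, float]:
    """Shared GLRLM/GLSZM/GLDM feature formulas on a (Ng, L) matrix."""
    (sre, lre, gln, glnn, rln, rlnn, rp, glv, rv, re,
     lgl, hgl, srlgl, srhgl, lrlgl, lrhgl) = prefix
    ns = P.sum()
    if ns == 0:
        return {k: np.nan for k in prefix}
    g = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / ns
    pg = P.sum(axis=1)
    pl = P.sum(axis=0)
    mu_g = (g[:, 0] * pg / ns).sum()
    mu_l = (l[0] * pl / ns).sum()
    return {
        sre: float((P / l**2).sum() / ns),
        lre: float((P * l**2).sum() / ns),
        gln: float((pg**2).sum() / ns),
        glnn: float((pg**2).sum() / ns**2),
        rln: float((pl**2).sum() / ns),
        rlnn: float((pl**2).sum() / ns**2),
        rp: float(ns / n_voxels),
        glv: float((p * (g - mu_g) ** 2).sum()),
        rv: float((p * (l - mu_l) ** 2).sum()),
        re: float(-(_xlog2(p)).sum()),
        lgl: float((P / g**2).sum() / ns),
        hgl: float((P * g**2).sum() / ns),
        srlgl: float((P / (g**2 * l**2)).sum() / ns),
        srhgl: float((P * g**2 / l**2).sum() / ns),
        lrlgl: float((P * l**2 / g**2).sum() / ns),
        lrhgl: float((P * g**2 * l**2).sum() / ns),
    }


def glrlm_features(G: np.ndarray, mask: np.ndarray, ng: int) -> dict[str, float]:
    n_voxels = int(mask.sum())
    per_dir = []
    for off in DIRECTIONS:
        P = _run_matrix(G, mask, off, ng)
        per_dir.append(_rl_style_features(P, n_voxels, tuple(GLRLM_NAMES)))
    return {k: float(np.nanmean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


# --------------------------------------------------------------------------
# GLSZM (16 features)
# --------------------------------------------------------------------------

GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_features(G: np.ndarray, mask: np.ndarray, ng: int) -> dict[str, float]:
    zones: dict[tuple[int, int], int] = {}
    max_size = 0
    coords = np.argwhere(mask)
    levels_at = G[mask]
    order = np.argsort(levels_at, kind="stable")
    coords = coords[order]
    levels_sorted = levels_at[order]
    boundaries = np.searchsorted(levels_sorted, np.arange(1, ng + 2))
    for level in range(1, ng + 1):
        pts = coords[boundaries[level - 1] : boundaries[level]]
        if len(pts) == 0:
            continue
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        binmap = np.zeros(tuple(hi - lo + 1), dtype=bool)
        binmap[tuple((pts - lo).T)] = True
        lab, nlab = ndimage.label(binmap, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones[(level, int(s))] = zones.get((level, int(s)), 0) + 1
            max_size = max(max_size, int(s))
    P = np.zeros((ng, max_size))
    for (g, s), c in zones.items():
        P[g - 1, s - 1] += c
    return _rl_style_features(P, int(mask.sum()), tuple(GLSZM_NAMES))


# --------------------------------------------------------------------------
# NGTDM (5 features)
# --------------------------------------------------------------------------

NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def ngtdm_features(G: np.ndarray, mask: np.ndarray, ng: int) -> dict[str, float]:
    kernel = np.ones((3, 3, 3))
    gm = np.where(mask, G, 0).astype(np.float64)
    msk = mask.astype(np.float64)
    ssum = ndimage.correlate(gm, kernel, mode="constant") - gm
    cnt = ndimage.correlate(msk, kernel, mode="constant") - msk
    valid = mask & (cnt > 0)
    levels = G[valid]
    abar = ssum[valid] / cnt[valid]
    diffs = np.abs(levels - abar)

    nvp = levels.size
    if nvp == 0:
        return {k: np.nan for k in NGTDM_NAMES}
    n_i = np.bincount(levels, minlength=ng + 1)[1:].astype(float)
    s_i = np.bincount(levels, weights=diffs, minlength=ng + 1)[1:]
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    iv = np.arange(1, ng + 1, dtype=float)

    sum_ps = float((p_i * s_i).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6

    if ngp > 1:
        pi_, pj_ = p_i[present][:, None], p_i[present][None, :]
        ii, jj = iv[present][:, None], iv[present][None, :]
        contrast = (
            (pi_ * pj_ * (ii - jj) ** 2).sum() / (ngp * (ngp - 1))
        ) * (diffs.sum() / nvp)
        busy_den = np.abs(ii * pi_ - jj * pj_).sum()
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        si_, sj_ = s_i[present][:, None], s_i[present][None, :]
        complexity = (
            np.abs(ii - jj) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)
        ).sum() / nvp
        s_total = s_i.sum()
        strength = (
            ((pi_ + pj_) * (ii - jj) ** 2).sum() / s_total if s_total > 0 else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# --------------------------------------------------------------------------
# GLDM (14 features)
# --------------------------------------------------------------------------

GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]

_OFFSETS26 = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=int,
)


def gldm_features(
    G: np.ndarray, mask: np.ndarray, ng: int, alpha: int = 0
) -> dict[str, float]:
    dep = np.zeros(G.shape, dtype=np.int64)
    for off in _OFFSETS26:
        src, dst = _shift_view(G, off)
        ok = mask[dst] & mask[src] & (np.abs(G[dst] - G[src]) <= alpha)
        dep[dst] += ok
    dep = dep + 1  # dependence size counts the centre voxel
    levels = G[mask]
    sizes = dep[mask]
    nd = int(sizes.max())
    P = np.zeros((ng, nd))
    np.add.at(P, (levels - 1, sizes - 1), 1.0)
    # reuse the run-length formula kernel; GLDM has no normalized-GLN or
    # percentage analogue (every voxel has a dependence), so two slots are dropped
    slots = (
        "SmallDependenceEmphasis", "LargeDependenceEmphasis",
        "GrayLevelNonUniformity", "_drop_glnn", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "_drop_pct", "GrayLevelVariance",
        "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
        "SmallDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
    )
    vals = _rl_style_features(P, int(mask.sum()), slots)
    return {k: vals[k] for k in GLDM_NAMES}


# --------------------------------------------------------------------------
# Shape (14 features)
# --------------------------------------------------------------------------

SHAPE_NAMES = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "MaximumDiameter3D", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
]


def _pairwise_max_sq(pts: np.ndarray) -> float:
    # ||a-b||^2 = |a|^2 + |b|^2 - 2 a.b via BLAS; cheap even for ~2k points
    sq = (pts * pts).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (pts @ pts.T)
    return float(max(d2.max(), 0.0))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass
    return float(np.sqrt(_pairwise_max_sq(pts)))


def _max_pairwise_direct(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return 0.0
    return float(np.sqrt(_pairwise_max_sq(np.asarray(pts, dtype=np.float64))))


def _max_2d_diameter(coords: np.ndarray, plane_axis: int) -> float:
    """Largest in-plane diameter over slices perpendicular to ``plane_axis``."""
    other = [a for a in range(3) if a != plane_axis]
    best = 0.0
    for v in np.unique(coords[:, plane_axis]):
        pts = coords[coords[:, plane_axis] == v][:, other]
        if len(pts) > 400:
            best = max(best, _max_pairwise(pts))
        else:
            best = max(best, _max_pairwise_direct(pts))
    return best


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    spacing = np.asarray(spacing, dtype=float)
    n = int(mask.sum())
    if n == 0:
        return {k: np.nan for k in SHAPE_NAMES}
    voxel_volume = float(np.prod(spacing))
    # slight pre-smoothing anti-aliases the binary surface so the mesh does
    # not carry staircase area (a voxelized sphere would otherwise read ~0.92
    # sphericity); sigma is in voxels and small enough to keep volume within
    # a few percent
    padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float64), 1), 0.7)
    verts, faces, *_ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    surface_area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(
        abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0
    )

    idx = np.argwhere(mask).astype(np.float64)
    phys = idx * spacing
    centered = phys - phys.mean(axis=0)
    if n > 3:
        cov = np.cov(centered, rowvar=False)
        eig = np.sort(np.clip(np.linalg.eigvalsh(cov), 0, None))[::-1]
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": n * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "MaximumDiameter3D": _max_pairwise(verts),
        "Maximum2DDiameterSlice": _max_2d_diameter(phys, 2),
        "Maximum2DDiameterColumn": _max_2d_diameter(phys, 1),
        "Maximum2DDiameterRow": _max_2d_diameter(phys, 0),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
    }


TEXTURE_CLASS_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}


def intensity_features(
    image: np.ndarray,
    mask: np.ndarray,
    voxel_volume: float,
    bin_width: float,
) -> dict[str, dict[str, float]]:
    """All 91 intensity-derived features (first-order + 5 texture classes)."""
    values = image[mask]
    g_vals, ng = discretize(values, bin_width)
    G = np.zeros(mask.shape, dtype=np.int64)
    G[mask] = g_vals
    return {
        "firstorder": firstorder_features(values, voxel_volume, bin_width),
        "glcm": glcm_features(G, mask, ng),
        "glrlm": glrlm_features(G, mask, ng),
        "glszm": glszm_features(G, mask, ng),
        "ngtdm": ngtdm_features(G, mask, ng),
        "gldm": gldm_features(G, mask, ng),
    }
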