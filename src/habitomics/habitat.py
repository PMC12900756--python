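"""Voxel-wise local features and cohort-level K-means habitat segmentation.

Intratumoral heterogeneity is quantified by sliding a 5x5x5 window over the
tumor VOI and computing 19 first-order statistics per voxel (window clipped
to the mask).  Voxel feature vectors are pooled across training patients,
z-scored, and clustered with K-means; the cluster count is chosen by
maximizing the Calinski-Harabasz index over k = 2..10.  One model is fitted
on the pooled training voxels and applied cohort-wide so habitat labels
H1..Hk are comparable across patients; clusters are ordered by descending
windowed-mean-intensity center (H1 = most enhancing, H2 = least).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from sklearn.cluster import KMeans

from .imaging import RegionMask, Volume

#: the 19 local first-order statistic channels, in fixed order
LOCAL_CHANNELS = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "StandardDeviation", "Skewness", "Kurtosis",
    "Variance", "Uniformity",
)

MEAN_CHANNEL = LOCAL_CHANNELS.index("Mean")


@dataclass
class LocalFeatureMap:
    """Per-voxel local statistics over a tumor crop.

    ``array`` is (19, cx, cy, cz) over the crop ``crop`` of the original
    grid; ``valid_mask`` flags in-mask voxels with enough in-window support.
    """

    array: np.ndarray
    valid_mask: np.ndarray
    in_mask: np.ndarray
    crop: tuple[slice, slice, slice]
    full_shape: tuple[int, int, int]
    channel_names: tuple[str, ...] = LOCAL_CHANNELS

    def voxel_features(self, valid_only: bool = True) -> np.ndarray:
        """(n_voxels, 19) matrix of per-voxel features."""
        sel = self.valid_mask if valid_only else self.in_mask
        return self.array[:, sel].T


def _row_percentile(sorted_vals: np.ndarray, counts: np.ndarray, q: float) -> np.ndarray:
    """Row-wise percentile (linear interpolation) on row-sorted data."""
    pos = (q / 100.0) * (counts - 1)
    lo = np.floor(pos).astype(int)
    hi = np.ceil(pos).astype(int)
    frac = pos - lo
    vlo = np.take_along_axis(sorted_vals, lo[:, None], axis=1)[:, 0]
    vhi = np.take_along_axis(sorted_vals, hi[:, None], axis=1)[:, 0]
    return vlo + frac * (vhi - vlo)


def local_feature_maps(
    volume: Volume,
    tumor_mask: RegionMask,
    window: int = 5,
    min_support: int = 8,
    bin_width: float = 0.25,
) -> LocalFeatureMap:
    """Compute the 19-channel local feature map over the tumor VOI.

    Statistics use only in-window, in-mask neighbours (the window is clipped
    at the tumor boundary).  Voxels with fewer than ``min_support`` in-mask
    window members are flagged invalid.  ``bin_width`` discretizes intensities
    for the entropy/uniformity channels; the default suits unit-variance
    normalized images.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if tumor_mask.voxel_count == 0:
        raise ValueError("tumor mask is empty")
    if not volume.same_grid(tumor_mask):
        raise ValueError("mask grid does not match volume grid")

    half = window // 2
    idx = np.argwhere(tumor_mask.array)
    crop = tuple(
        slice(int(lo), int(hi) + 1) for lo, hi in zip(idx.min(axis=0), idx.max(axis=0))
    )
    arr = volume.array[crop]
    msk = tumor_mask.array[crop]
    # float32 halves the cost of the dominant row-sort with ample precision
    # for cluster features
    pad_vals = np.pad(
        np.where(msk, arr, np.nan).astype(np.float32), half, constant_values=np.nan
    )

    win_shape = (window,) * 3
    windows = sliding_window_view(pad_vals, win_shape)  # (cx,cy,cz,w,w,w)
    vox = np.argwhere(msk)
    V = windows[vox[:, 0], vox[:, 1], vox[:, 2]].reshape(len(vox), -1)

    finite = np.isfinite(V)
    m = finite.sum(axis=1)
    Vz = np.where(finite, V, 0.0)
    Vs = np.sort(V, axis=1)  # NaNs sort last

    mf = m.astype(float)
    mean = Vz.sum(axis=1) / mf
    energy = (Vz**2).sum(axis=1)
    var = energy / mf - mean**2
    var = np.clip(var, 0.0, None)
    sd = np.sqrt(var)
    mn = Vs[:, 0]
    mx = np.take_along_axis(Vs, (m - 1)[:, None], axis=1)[:, 0]
    p10 = _row_percentile(Vs, m, 10)
    p25 = _row_percentile(Vs, m, 25)
    p50 = _row_percentile(Vs, m, 50)
    p75 = _row_percentile(Vs, m, 75)
    p90 = _row_percentile(Vs, m, 90)
    dev = np.where(finite, V - mean[:, None], 0.0)
    mad = np.abs(dev).sum(axis=1) / mf
    robust_sel = finite & (V >= p10[:, None]) & (V <= p90[:, None])
    mr = np.maximum(robust_sel.sum(axis=1), 1).astype(float)
    mu_r = np.where(robust_sel, V, 0.0).sum(axis=1) / mr
    rmad = np.where(robust_sel, np.abs(V - mu_r[:, None]), 0.0).sum(axis=1) / mr
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = (dev**3).sum(axis=1) / mf / sd**3
        kurt = (dev**4).sum(axis=1) / mf / var**2
    skew = np.where(sd > 0, skew, 0.0)
    kurt = np.where(sd > 0, kurt, 0.0)

    # entropy / uniformity on fixed-width bins (zero-anchored)
    g = np.where(finite, np.floor(V / bin_width), 0).astype(np.int64)
    gmin = g[finite].min() if finite.any() else 0
    g = g - gmin
    nbins = int(g[finite].max()) + 1 if finite.any() else 1
    rows = np.repeat(np.arange(len(vox)), V.shape[1])
    flat = (rows * nbins + g.ravel())[finite.ravel()]
    hist = np.bincount(flat, minlength=len(vox) * nbins).reshape(len(vox), nbins)
    p = hist / mf[:, None]
    tiny = np.finfo(float).tiny
    entropy = -(p * np.log2(p + tiny)).sum(axis=1)
    uniformity = (p**2).sum(axis=1)

    voxvol = volume.voxel_volume_mm3
    stats = np.stack(
        [
            energy, voxvol * energy, entropy, mn, p10, p90, mx, mean, p50,
            p75 - p25, mx - mn, mad, rmad, np.sqrt(energy / mf), sd, skew,
            kurt, var, uniformity,
        ]
    )

    array = np.zeros((len(LOCAL_CHANNELS),) + msk.shape)
    array[:, vox[:, 0], vox[:, 1], vox[:, 2]] = stats
    valid = np.zeros(msk.shape, dtype=bool)
    valid[vox[:, 0], vox[:, 1], vox[:, 2]] = m >= min_support
    return LocalFeatureMap(
        array=array,
        valid_mask=valid,
        in_mask=msk,
        crop=crop,
        full_shape=volume.shape,
    )


# --------------------------------------------------------------------------
# Calinski-Harabasz index
# --------------------------------------------------------------------------

def calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """CH = [B/(k-1)] / [W/(n-k)] with B/W between/within-cluster squared deviations."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = len(uniq), len(X)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if n <= k:
        raise ValueError("need more points than clusters")
    grand = X.mean(axis=0)
    W = 0.0
    B = 0.0
    for u in uniq:
        sub = X[labels == u]
        c = sub.mean(axis=0)
        W += ((sub - c) ** 2).sum()
        B += len(sub) * ((c - grand) ** 2).sum()
    if W == 0:
        return np.inf
    return float((B / (k - 1)) / (W / (n - k)))


# --------------------------------------------------------------------------
# Habitat model
# --------------------------------------------------------------------------

@dataclass
class HabitatModel:
    """Cohort-level voxel-cluster model applied to every patient.

    ``centers`` live in standardized channel space and are ordered H1..Hk by
    descending windowed-mean-intensity; ``scaler`` holds the pooled training
    per-channel mean/SD.
    """

    k: int
    centers: np.ndarray
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    ch_scores: dict[int, float]
    seed: int
    channel_names: tuple[str, ...] = LOCAL_CHANNELS

    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (features - self.scaler_mean) / self.scaler_sd


@dataclass
class HabitatMap:
    """Integer habitat labels (0 background, 1..k inside the tumor)."""

    labels: np.ndarray
    per_label_voxel_counts: dict[int, int]
    per_label_fractions: dict[int, float]


def fit_habitat_model(
    maps: list[LocalFeatureMap],
    k_range: tuple[int, int] = (2, 10),
    voxel_subsample: int = 100_000,
    n_init: int = 10,
    seed: int = 0,
) -> HabitatModel:
    """Fit K-means per candidate k on pooled standardized training voxels.

    k is selected by maximizing the CH index on a seeded voxel subsample;
    clusters are then relabeled H1..Hk by descending mean-intensity center.
    """
    lo, hi = k_range
    if not (2 <= lo <= hi <= 10):
        raise ValueError("k_range must lie within [2, 10]")
    pooled = np.concatenate([m.voxel_features() for m in maps], axis=0)
    if len(pooled) < hi * 50:
        raise ValueError(
            f"insufficient valid voxels ({len(pooled)}) for k up to {hi}"
        )
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (pooled - mu) / sd

    rng = np.random.default_rng(seed)
    if len(Z) > voxel_subsample:
        sel = rng.choice(len(Z), size=voxel_subsample, replace=False)
        Z = Z[sel]
    Z = np.ascontiguousarray(Z, dtype=np.float32)  # halves K-means cost

    ch_scores: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, init="k-means++")
        labels = km.fit_predict(Z)
        ch_scores[k] = calinski_harabasz(Z, labels)
        fits[k] = km
    best_k = max(ch_scores, key=lambda k: (ch_scores[k], -k))
    km = fits[best_k]
    # order clusters by descending raw mean-intensity center
    raw_mean = km.cluster_centers_[:, MEAN_CHANNEL] * sd[MEAN_CHANNEL] + mu[MEAN_CHANNEL]
    order = np.argsort(-raw_mean)
    centers = km.cluster_centers_[order]
    return HabitatModel(
        k=best_k,
        centers=centers,
        scaler_mean=mu,
        scaler_sd=sd,
        ch_scores=ch_scores,
        seed=seed,
    )


def assign_habitats(
    model: HabitatModel,
    feature_map: LocalFeatureMap,
    tumor_mask: RegionMask,
) -> HabitatMap:
    """Assign every tumor voxel to its nearest habitat center.

    Valid voxels take the nearest center in standardized space; invalid ones
    inherit the label of their nearest valid neighbour, so the habitat map
    partitions the tumor mask exactly.
    """
    if tumor_mask.voxel_count == 0:
        raise ValueError("tumor mask is empty")
    if feature_map.array.shape[0] != model.centers.shape[1]:
        raise ValueError("channel count does not match the fitted model")
    msk = feature_map.in_mask
    valid = feature_map.valid_mask
    feats = model.standardize(feature_map.array[:, valid].T)
    d2 = ((feats[:, None, :] - model.centers[None, :, :]) ** 2).sum(axis=2)
    lab_valid = d2.argmin(axis=1) + 1

    crop_labels = np.zeros(msk.shape, dtype=np.int16)
    crop_labels[valid] = lab_valid
    holes = msk & ~valid
    if holes.any():
        if not valid.any():
            raise ValueError("no valid voxels to assign from")
        _, (ix, iy, iz) = ndimage.distance_transform_edt(
            ~valid, return_indices=True
        )
        crop_labels[holes] = crop_labels[ix[holes], iy[holes], iz[holes]]

    labels = np.zeros(feature_map.full_shape, dtype=np.int16)
    labels[feature_map.crop] = np.where(msk, crop_labels, 0)
    counts = {
        h: int((labels == h).sum()) for h in range(1, model.k + 1)
    }
    total = sum(counts.values())
    fractions = {h: (c / total if total else 0.0) for h, c in counts.items()}
    return HabitatMap(labels, counts, fractions)


def habitat_masks(
    habitat_map: HabitatMap, like: RegionMask, k: int
) -> dict[str, RegionMask]:
    """Per-habitat RegionMasks (roles ``h1..hk``) on the original grid."""
    return {
        f"h{h}": RegionMask(
            habitat_map.labels == h, like.spacing_mm, like.origin_mm, role=f"h{h}"
        )
        for h in range(1, k + 1)
    }
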