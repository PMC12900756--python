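"""Region-wise radiomic feature extraction, imputation, and ICC filtering.

Each region yields 1,015 features: 14 shape descriptors from the original
geometry plus 91 intensity features (18 first-order, 22 GLCM, 16 GLRLM,
16 GLSZM, 5 NGTDM, 14 GLDM) computed on each of 11 image types — the
original image, the 8 level-1 stationary 3-D wavelet sub-bands, and
Laplacian-of-Gaussian at two sigma values.  The integrated habitat region
concatenates the three per-habitat vectors (3 x 1,015 = 3,045 features).

Feature names carry full provenance as ``region|filter|class|name`` and
round-trip through :class:`FeatureName`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from sklearn.impute import KNNImputer

from . import _texture
from .imaging import RegionMask, Volume

SHAPE_CLASS = "shape"
INTENSITY_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")
FEATURE_CLASSES = (SHAPE_CLASS,) + INTENSITY_CLASSES

WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

HABITAT_REGIONS = ("h1", "h2", "h3", "habitat_integrated")


@dataclass(frozen=True)
class FeatureName:
    """Structured feature identifier: (region, image filter, class, base name)."""

    region: str
    image_filter: str
    feature_class: str
    base_name: str

    def __post_init__(self) -> None:
        if self.feature_class == SHAPE_CLASS and self.image_filter != "original":
            raise ValueError("shape features exist only under the original filter")

    def __str__(self) -> str:
        return f"{self.region}|{self.image_filter}|{self.feature_class}|{self.base_name}"

    @classmethod
    def parse(cls, name: str) -> "FeatureName":
        region, image_filter, feature_class, base = name.split("|")
        return cls(region, image_filter, feature_class, base)


@dataclass(frozen=True)
class ExtractionConfig:
    """Feature-extraction settings.

    Discretization uses the conventional fixed bin width of 25 on intensities
    scaled by ``intensity_scale`` (so z-scored inputs are binned at an
    effective width of 0.25); statistics themselves are computed on the raw
    intensity scale.
    """

    bin_width: float = 25.0
    intensity_scale: float = 100.0

    @property
    def effective_bin_width(self) -> float:
        return self.bin_width / self.intensity_scale
    wavelet: str = "coif1"
    log_sigmas_mm: tuple[float, ...] = (2.0, 3.0)
    min_voxels: int = 10
    crop_margin: int = 8

    @property
    def image_filters(self) -> tuple[str, ...]:
        return (
            ("original",)
            + tuple(f"wavelet-{b}" for b in WAVELET_BANDS)
            + tuple(f"log-sigma-{s:g}-mm" for s in self.log_sigmas_mm)
        )


def feature_names(region: str, config: ExtractionConfig | None = None) -> list[str]:
    """The full ordered feature-name list for one region (1,015 by default)."""
    config = config or ExtractionConfig()
    names = [
        str(FeatureName(region, "original", SHAPE_CLASS, n))
        for n in _texture.SHAPE_NAMES
    ]
    for filt in config.image_filters:
        for klass in INTENSITY_CLASSES:
            names.extend(
                str(FeatureName(region, filt, klass, n))
                for n in _texture.TEXTURE_CLASS_NAMES[klass]
            )
    return names


# --------------------------------------------------------------------------
# Filter bank
# --------------------------------------------------------------------------

class FilterBank:
    """The 11 derived images for one volume, computed once on a crop.

    The crop covers ``bounds`` (a bounding-box slice triple) plus a margin so
    filters see context; all masks extracted against this bank must lie
    within ``bounds``.
    """

    def __init__(
        self,
        volume: Volume,
        config: ExtractionConfig,
        bounds: tuple[slice, slice, slice] | None = None,
    ) -> None:
        self.config = config
        self.spacing = volume.spacing_mm
        arr = volume.array
        if bounds is None:
            bounds = tuple(slice(0, n) for n in arr.shape)
        margin = config.crop_margin
        self.crop = tuple(
            slice(max(0, b.start - margin), min(n, b.stop + margin))
            for b, n in zip(bounds, arr.shape)
        )
        sub = arr[self.crop]
        self.images: dict[str, np.ndarray] = {"original": sub}
        self.images.update(self._wavelet_bands(sub, config.wavelet))
        for s in config.log_sigmas_mm:
            sig = [s / sp for sp in self.spacing]
            self.images[f"log-sigma-{s:g}-mm"] = ndimage.gaussian_laplace(sub, sigma=sig)

    @staticmethod
    def _wavelet_bands(arr: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
        # level-1 undecimated (stationary) transform; pad to even dims
        pads = [(0, n % 2) for n in arr.shape]
        padded = np.pad(arr, pads, mode="edge")
        coeffs = pywt.swtn(padded, wavelet, level=1)[0]
        out = {}
        trim = tuple(slice(0, n) for n in arr.shape)
        for key, band in coeffs.items():
            name = "wavelet-" + key.replace("a", "L").replace("d", "H")
            out[name] = band[trim]
        return out

    def mask_in_crop(self, mask: RegionMask) -> np.ndarray:
        return mask.array[self.crop]


# --------------------------------------------------------------------------
# Extraction
# --------------------------------------------------------------------------

def extract_features(
    volume: Volume,
    region_mask: RegionMask,
    config: ExtractionConfig | None = None,
    bank: FilterBank | None = None,
) -> pd.Series:
    """All 1,015 features for one region; a too-small region returns NaNs.

    Empty or sub-minimum masks yield a fully missing-flagged vector (so absent
    habitats flow into KNN imputation rather than raising).
    """
    config = config or ExtractionConfig()
    region = region_mask.role
    names = feature_names(region, config)
    if region_mask.voxel_count < config.min_voxels:
        return pd.Series(np.nan, index=names, name=region)
    if not volume.same_grid(region_mask):
        raise ValueError("region mask grid does not match the volume")

    if bank is None:
        idx = np.argwhere(region_mask.array)
        bounds = tuple(
            slice(int(lo), int(hi) + 1)
            for lo, hi in zip(idx.min(axis=0), idx.max(axis=0))
        )
        bank = FilterBank(volume, config, bounds)

    mask = bank.mask_in_crop(region_mask)
    # tighten to the region's own bounding box (plus 0-voxel pad is fine for
    # matrix engines, which never look outside the mask)
    idx = np.argwhere(mask)
    sub = tuple(
        slice(int(lo), int(hi) + 1) for lo, hi in zip(idx.min(axis=0), idx.max(axis=0))
    )
    mask_c = mask[sub]
    voxvol = float(np.prod(bank.spacing))

    values: dict[str, float] = {}
    shp = _texture.shape_features(mask_c, bank.spacing)
    for n, v in shp.items():
        values[str(FeatureName(region, "original", SHAPE_CLASS, n))] = v
    for filt in config.image_filters:
        img_c = bank.images[filt][sub]
        by_class = _texture.intensity_features(
            img_c, mask_c, voxvol, config.effective_bin_width
        )
        for klass, feats in by_class.items():
            for n, v in feats.items():
                values[str(FeatureName(region, filt, klass, n))] = v
    return pd.Series([values[n] for n in names], index=names, name=region)


def extract_region_table(
    volume: Volume,
    masks: dict[str, RegionMask],
    config: ExtractionConfig | None = None,
) -> pd.Series:
    """Extract several regions of one patient sharing a single filter bank."""
    config = config or ExtractionConfig()
    union = np.zeros(volume.shape, dtype=bool)
    any_used = False
    for m in masks.values():
        if m.voxel_count >= config.min_voxels:
            union |= m.array
            any_used = True
    if any_used:
        idx = np.argwhere(union)
        bounds = tuple(
            slice(int(lo), int(hi) + 1)
            for lo, hi in zip(idx.min(axis=0), idx.max(axis=0))
        )
        bank = FilterBank(volume, config, bounds)
    else:
        bank = None
    parts = [
        extract_features(volume, m.with_role(region), config, bank=bank)
        for region, m in masks.items()
    ]
    return pd.concat(parts)


def integrated_habitat_features(
    h1_vec: pd.Series, h2_vec: pd.Series, h3_vec: pd.Series
) -> pd.Series:
    """Concatenate the three habitat vectors into the integrated-region vector.

    Names become ``habitat_integrated|filter|class|name_hX`` (3,045 entries);
    missing habitats propagate as NaN blocks.
    """
    parts = []
    for vec, tag in ((h1_vec, "h1"), (h2_vec, "h2"), (h3_vec, "h3")):
        renamed = {}
        for name, value in vec.items():
            fn = FeatureName.parse(name)
            renamed[
                str(
                    FeatureName(
                        "habitat_integrated",
                        fn.image_filter,
                        fn.feature_class,
                        f"{fn.base_name}_{tag}",
                    )
                )
            ] = value
        parts.append(pd.Series(renamed))
    return pd.concat(parts)


# --------------------------------------------------------------------------
# KNN imputation
# --------------------------------------------------------------------------

def knn_impute(
    table: pd.DataFrame,
    k_neighbors: int = 5,
    train_index: pd.Index | None = None,
) -> pd.DataFrame:
    """Impute missing cells with a KNN imputer fitted on training rows only.

    Distances are computed on standardized observed features (training
    mean/SD); observed entries are returned unchanged.
    """
    train_index = table.index if train_index is None else train_index
    train = table.loc[train_index]
    dead = train.columns[train.isna().all(axis=0)]
    if len(dead):
        raise ValueError(
            f"columns with no observed training values: {list(map(str, dead[:5]))}"
            + ("..." if len(dead) > 5 else "")
        )
    if not table.isna().any().any():
        return table.copy()
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0).replace(0.0, 1.0)
    imputer = KNNImputer(n_neighbors=min(k_neighbors, len(train)))
    imputer.fit((train - mu) / sd)
    filled = imputer.transform((table - mu) / sd)
    out = pd.DataFrame(filled, index=table.index, columns=table.columns) * sd + mu
    out[~table.isna()] = table  # observed cells are authoritative
    return out


# --------------------------------------------------------------------------
# ICC(2,1) and reliability filtering
# --------------------------------------------------------------------------

def icc_two_way(reader1: np.ndarray, reader2: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    return float(icc_two_way_table(
        pd.DataFrame({"f": np.asarray(reader1, dtype=float)}),
        pd.DataFrame({"f": np.asarray(reader2, dtype=float)}),
    )["f"])


def icc_two_way_table(
    table1: pd.DataFrame, table2: pd.DataFrame, strict: bool = True
) -> pd.Series:
    """Column-wise ICC(2,1) from the two-way ANOVA decomposition (k = 2 raters).

    Zero-total-variance columns raise when ``strict``, else come back NaN.
    """
    if list(table1.columns) != list(table2.columns):
        raise ValueError("reader tables must share columns")
    n = len(table1)
    if n < 3 or len(table2) != n:
        raise ValueError("ICC needs >=3 matched subjects per reader")
    k = 2
    y1 = table1.to_numpy(dtype=float)
    y2 = table2.to_numpy(dtype=float)
    y = np.stack([y1, y2])  # (k, n, p)
    grand = y.mean(axis=(0, 1))
    row_mean = y.mean(axis=0)  # per subject
    col_mean = y.mean(axis=1)  # per rater
    ss_total = ((y - grand) ** 2).sum(axis=(0, 1))
    degenerate = ss_total == 0
    if np.any(degenerate) and strict:
        raise ValueError("zero total variance in at least one feature")
    ss_rows = k * ((row_mean - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_mean - grand) ** 2).sum(axis=0)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc = np.where(degenerate, np.nan, icc)
    return pd.Series(icc, index=table1.columns)


def filter_by_icc(
    table: pd.DataFrame,
    reader2_table: pd.DataFrame,
    threshold: float = 0.75,
    exempt_regions: tuple[str, ...] = HABITAT_REGIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop non-reproducible features (ICC < threshold) outside exempt regions.

    Habitat-region columns come from unsupervised clustering with no second
    reading, so they are always retained.  Returns the filtered table and a
    per-feature report (icc, exempt flag, kept flag).
    """
    exempt = {c for c in table.columns if FeatureName.parse(c).region in exempt_regions}
    checked = [c for c in table.columns if c not in exempt]
    missing = [c for c in checked if c not in reader2_table.columns]
    if missing:
        raise ValueError(
            f"reader-2 values missing for non-exempt features, e.g. {missing[:3]}"
        )
    icc = (
        icc_two_way_table(table[checked], reader2_table[checked], strict=False)
        if checked
        else pd.Series(dtype=float)
    )
    report = pd.DataFrame(
        {
            "icc": [icc.get(c, np.nan) for c in table.columns],
            "exempt": [c in exempt for c in table.columns],
        },
        index=table.columns,
    )
    report["kept"] = report["exempt"] | (report["icc"] >= threshold)
    kept_cols = [c for c in table.columns if report.loc[c, "kept"]]
    return table[kept_cols], report
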