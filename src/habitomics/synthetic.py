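"""Seeded synthetic cohorts of 3-D kidney-tumor images with planted habitats.

Each patient is a smoothed, randomly deformed ellipsoidal tumor embedded in a
noisy parenchyma slab on a contrast-enhanced-T1-like intensity scale (arbitrary
units, parenchyma at 100).  The tumor carries ``k_true`` planted subregions
laid out along a random intratumoral axis, emulating the eccentric necrosis
typical of large renal tumors: an enhancing viable zone (habitat 1, bright and
relatively homogeneous), a necrotic zone (habitat 2, dark), and a transitional
zone between them (habitat 3, intermediate intensity with strong fine-scale
speckle from mixed viable/necrotic microregions).  The three zones therefore
separate along two feature axes (windowed mean and windowed texture), which is
what makes the planted cluster count recoverable by windowed-statistic
clustering.

Planted grade effects: high-grade tumors are drawn with larger radii, higher
necrosis fraction, and a higher probability of low corticomedullary
enhancement (which attenuates the enhancing zone).  A second reader's mask is
the first reader's with smooth boundary jitter so inter-reader reliability
filtering is exercised without being saturated.

Not emulated: MRI physics and artefacts, k-space sampling, multi-sequence
output, organ anatomy beyond the parenchyma slab.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import RegionMask, Volume


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Geometry is in millimetres on an isotropic grid; intensities are arbitrary
    units with parenchyma at 100.
    """

    n_patients: int = 154
    high_grade_prevalence: float = 0.27
    k_true: int = 3
    #: mean intensity per planted habitat: H1 enhancing, H2 necrotic, H3 transitional
    subregion_means: tuple[float, ...] = (160.0, 80.0, 120.0)
    #: intensity SD per planted habitat; H3's high value is spatially
    #: correlated speckle (mixed-tissue texture), the discriminating axis
    subregion_noise_sd: tuple[float, ...] = (15.0, 20.0, 45.0)
    #: correlation length (voxels) of the H3 speckle field
    speckle_correlation_vox: float = 0.8
    #: (low, high) tumor radius range in mm per grade [low-grade, high-grade]
    tumor_radius_range_mm: tuple[tuple[float, float], tuple[float, float]] = (
        (16.0, 20.0),
        (18.0, 24.0),
    )
    #: necrotic-zone volume fraction range per grade
    necrosis_fraction_range: tuple[tuple[float, float], tuple[float, float]] = (
        (0.15, 0.28),
        (0.25, 0.42),
    )
    #: transitional-zone volume fraction
    transition_fraction: float = 0.35
    reader2_perturbation_mm: float = 1.0
    bias_field_amplitude: float = 0.15
    #: P(low corticomedullary enhancement | grade) for grade 0 and 1
    enhancement_effect: tuple[float, float] = (0.27, 0.69)
    #: intensity drop of the enhancing/transitional zones under low enhancement
    low_enhancement_shift: float = 12.0
    parenchyma_mean: float = 100.0
    parenchyma_sd: float = 25.0
    grid_shape: tuple[int, int, int] = (72, 72, 72)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: amplitude of the smooth radial boundary deformation (fraction of radius)
    deformation_amplitude: float = 0.12
    #: amplitude of the habitat-axis deformation (fraction of radius)
    habitat_deformation: float = 0.06
    smoothing_sigma_mm: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if not 0.0 <= self.high_grade_prevalence <= 1.0:
            raise ConfigurationError("high_grade_prevalence must be in [0, 1]")
        if self.k_true < 1:
            raise ConfigurationError("k_true must be >= 1")
        for lo, hi in self.tumor_radius_range_mm:
            if lo <= 0 or hi < lo:
                raise ConfigurationError("radius ranges must be positive and ordered")
        for p in self.enhancement_effect:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("enhancement_effect entries are probabilities")
        if len(self.subregion_means) < self.k_true:
            raise ConfigurationError("need one subregion mean per planted habitat")


@dataclass
class SyntheticPatient:
    """One simulated case: image, dual-reader masks, truth and covariates."""

    patient_id: str
    volume: Volume
    mask_reader1: RegionMask
    mask_reader2: RegionMask
    habitat_truth: np.ndarray  # 0 background, 1..k_true on reader-1 foreground
    body_mask: RegionMask
    grade: int
    clinical: dict

    def __post_init__(self) -> None:
        if self.grade not in (0, 1):
            raise ConfigurationError("grade must be 0 or 1")


# --------------------------------------------------------------------------
# Field helpers
# --------------------------------------------------------------------------

def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int, int], coarse: int = 6
) -> np.ndarray:
    """Perlin-style smooth random field scaled to [-1, 1].

    Coarse white noise upsampled trilinearly: piecewise-linear but smooth on
    the scale of a coarse cell, at a fraction of a spline-interpolation cost.
    """
    noise = rng.standard_normal((coarse,) * 3)
    fld = ndimage.zoom(noise, [s / coarse for s in shape], order=1)
    fld = fld[: shape[0], : shape[1], : shape[2]]
    m = np.abs(fld).max()
    return fld / m if m > 0 else fld


def _radial_coordinate(
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    center_mm: np.ndarray,
    semiaxes_mm: np.ndarray,
    deformation: np.ndarray,
    amplitude: float,
) -> np.ndarray:
    """Normalized, smoothly deformed ellipsoidal radius (1 = tumor surface)."""
    axes = [
        (np.arange(n) * s).reshape([-1 if i == j else 1 for j in range(3)])
        for i, (n, s) in enumerate(zip(shape, spacing))
    ]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(axes, center_mm, semiaxes_mm))
    return np.sqrt(q) * (1.0 + amplitude * deformation)


# --------------------------------------------------------------------------
# Patient simulation
# --------------------------------------------------------------------------

def _plant_habitats(
    config: CohortConfig,
    rng: np.random.Generator,
    tumor: np.ndarray,
    center: np.ndarray,
    radius: float,
    necro_frac: float,
) -> np.ndarray:
    """Habitat truth labels along a random intratumoral axis (eccentric
    necrosis): H2 at one pole, H3 transitional band, H1 the remainder."""
    shape, spacing = config.grid_shape, config.spacing_mm
    truth = np.zeros(shape, dtype=np.int16)
    if config.k_true == 1:
        truth[tumor] = 1
        return truth
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    axes = [
        (np.arange(n) * s).reshape([-1 if i == j else 1 for j in range(3)])
        for i, (n, s) in enumerate(zip(shape, spacing))
    ]
    w = sum((g - c) * a for g, c, a in zip(axes, center, axis)) / radius
    w = w + config.habitat_deformation * _smooth_field(rng, shape, coarse=4)
    wt = w[tumor]
    if config.k_true == 2:
        q1 = np.quantile(wt, necro_frac)
        lab = np.where(wt <= q1, 2, 1).astype(np.int16)
    else:
        q1, q2 = np.quantile(wt, [necro_frac, necro_frac + config.transition_fraction])
        lab = np.full(wt.size, 1, dtype=np.int16)
        lab[wt <= q2] = 3
        lab[wt <= q1] = 2
    truth[tumor] = lab
    return truth


def _simulate_patient(
    config: CohortConfig, rng: np.random.Generator, index: int
) -> SyntheticPatient:
    shape, spacing = config.grid_shape, config.spacing_mm
    extent = np.array([n * s for n, s in zip(shape, spacing)])

    grade = int(rng.random() < config.high_grade_prevalence)
    lo, hi = config.tumor_radius_range_mm[grade]
    radius = rng.uniform(lo, hi)
    semiaxes = radius * rng.uniform(0.88, 1.12, size=3)
    center = extent / 2 + rng.uniform(-2.0, 2.0, size=3)

    deform = _smooth_field(rng, shape, coarse=6)
    r = _radial_coordinate(
        shape, spacing, center, semiaxes, deform, config.deformation_amplitude
    )
    tumor = r <= 1.0

    nlo, nhi = config.necrosis_fraction_range[grade]
    necro_frac = rng.uniform(nlo, nhi)
    truth = _plant_habitats(config, rng, tumor, center, radius, necro_frac)

    # clinical covariates; low enhancement is the planted strong grade effect
    p_low = config.enhancement_effect[grade]
    low_enh = int(rng.random() < p_low)
    age = float(np.clip(rng.normal(60.0 + 3.5 * grade, 11.0), 25, 90))
    sex = int(rng.random() < 0.68)  # 1 = male
    hypertension = int(rng.random() < 0.4)  # planted noise covariate
    cystic_necrosis = int(necro_frac > 0.28 or rng.random() < 0.15)

    # intensities
    means = np.array(config.subregion_means[: config.k_true], dtype=float)
    if low_enh:
        means = means.copy()
        means[0] -= config.low_enhancement_shift
        if config.k_true >= 3:
            means[2] -= config.low_enhancement_shift / 2.0
    img = rng.normal(config.parenchyma_mean, config.parenchyma_sd, size=shape)
    speckle = ndimage.gaussian_filter(
        rng.standard_normal(shape), config.speckle_correlation_vox
    )
    speckle /= speckle.std()
    for h in range(1, config.k_true + 1):
        sel = truth == h
        n_sel = int(sel.sum())
        sd = config.subregion_noise_sd[h - 1]
        if h == 3:  # transitional zone: correlated mixed-tissue speckle
            img[sel] = means[h - 1] + sd * speckle[sel]
        else:
            img[sel] = means[h - 1] + sd * rng.standard_normal(n_sel)

    sigma_vox = [config.smoothing_sigma_mm / s for s in spacing]
    img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if config.bias_field_amplitude > 0:
        img = img * (
            1.0 + config.bias_field_amplitude * _smooth_field(rng, shape, coarse=3)
        )
    img = np.clip(img, 0.0, None)

    # reader-2 mask: smooth boundary jitter up to reader2_perturbation_mm
    jitter = _smooth_field(rng, shape, coarse=6)
    rel = config.reader2_perturbation_mm / max(radius, 1e-6)
    mask2 = r * (1.0 + rel * jitter) <= 1.0

    clinical = {
        "age": round(age, 1),
        "sex_male": sex,
        "max_diameter_mm": round(2.0 * float(semiaxes.max()), 2),
        "low_enhancement": low_enh,
        "cystic_necrosis": cystic_necrosis,
        "hypertension": hypertension,
    }
    return SyntheticPatient(
        patient_id=f"P{index:04d}",
        volume=Volume(img, spacing),
        mask_reader1=RegionMask(tumor, spacing, role="tumor"),
        mask_reader2=RegionMask(mask2, spacing, role="tumor"),
        habitat_truth=truth,
        body_mask=RegionMask(np.ones(shape, dtype=bool), spacing, role="body"),
        grade=grade,
        clinical=clinical,
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate a seeded cohort; same config + seed gives bit-identical output."""
    rng = np.random.default_rng(config.seed)
    streams = rng.spawn(config.n_patients) if config.n_patients else []
    return [_simulate_patient(config, s, i) for i, s in enumerate(streams)]


def clinical_table(patients: Sequence[SyntheticPatient]) -> pd.DataFrame:
    """Per-patient covariate table (id index, grade + covariates columns)."""
    rows = [
        {"patient_id": p.patient_id, "grade": p.grade, **p.clinical}
        for p in patients
    ]
    return pd.DataFrame(rows).set_index("patient_id")


# --------------------------------------------------------------------------
# Train/test split
# --------------------------------------------------------------------------

def split_cohort(
    patients: Sequence[SyntheticPatient] | Sequence[str],
    ratio: float = 0.7,
    stratified: bool = False,
    seed: int = 0,
    labels: Sequence[int] | None = None,
) -> tuple[list[str], list[str]]:
    """Random split into (training ids, test ids).

    Sizes follow ``round``: 154 patients at ratio 0.7 give a 108/46 split.
    Stratified mode preserves class fractions to within rounding and requires
    at least two members per class.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ConfigurationError("ratio must be in [0, 1]")
    if patients and isinstance(patients[0], SyntheticPatient):
        ids = [p.patient_id for p in patients]
        labs = [p.grade for p in patients]
    else:
        ids = [str(p) for p in patients]
        labs = list(labels) if labels is not None else None
    rng = np.random.default_rng(seed)
    n = len(ids)
    if not stratified:
        order = rng.permutation(n)
        n_train = int(round(ratio * n))
        train = sorted(ids[i] for i in order[:n_train])
        test = sorted(ids[i] for i in order[n_train:])
        return train, test
    if labs is None:
        raise ConfigurationError("stratified split needs labels")
    train, test = [], []
    for cls in sorted(set(labs)):
        members = [i for i, l in enumerate(labs) if l == cls]
        if len(members) < 2:
            raise ConfigurationError(
                f"stratified split needs >=2 patients in class {cls}"
            )
        order = rng.permutation(len(members))
        n_test = int(round((1.0 - ratio) * len(members)))
        test.extend(ids[members[i]] for i in order[:n_test])
        train.extend(ids[members[i]] for i in order[n_test:])
    return sorted(train), sorted(test)


def write_cohort(patients: Sequence[SyntheticPatient], out_dir) -> pd.DataFrame:
    """Write NIfTI volume/mask pairs and the cohort CSV; returns the table."""
    from pathlib import Path

    from .imaging import save_labelmap, save_mask, save_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        vpath = out / f"{p.patient_id}_image.nii.gz"
        m1 = out / f"{p.patient_id}_mask_r1.nii.gz"
        m2 = out / f"{p.patient_id}_mask_r2.nii.gz"
        tpath = out / f"{p.patient_id}_habitat_truth.nii.gz"
        save_volume(p.volume, vpath)
        save_mask(p.mask_reader1, m1)
        save_mask(p.mask_reader2, m2)
        save_labelmap(p.habitat_truth, p.volume, tpath)
        rows.append(
            {
                "patient_id": p.patient_id,
                "grade": p.grade,
                **p.clinical,
                "image": vpath.name,
                "mask_reader1": m1.name,
                "mask_reader2": m2.name,
                "habitat_truth": tpath.name,
            }
        )
    table = pd.DataFrame(rows).set_index("patient_id")
    table.to_csv(out / "cohort.csv")
    return table
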