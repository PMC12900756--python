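"""Config-driven orchestration: simulate -> preprocess -> rings -> habitat ->
extract -> select -> train -> evaluate, with provenance and determinism.

Every stage seed is derived from the master seed, so a rerun with the same
config reproduces the run bit-for-bit (manifest hash and report included).
The final report always contains the 12 models Clinic, Intra, Peri1-5mm,
HabitatH1-H3, Habitat (integrated) and Combined (nomogram).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import features as ft
from . import habitat as hb
from . import imaging as im
from . import modeling as md
from . import selection as sel
from . import synthetic as syn

log = logging.getLogger("habitomics")

MODEL_NAMES = [
    "Clinic", "Intra", "Peri1mm", "Peri2mm", "Peri3mm", "Peri4mm", "Peri5mm",
    "HabitatH1", "HabitatH2", "HabitatH3", "Habitat", "Combined",
]

REGION_TO_MODEL = {
    "intra": "Intra",
    "ring_1mm": "Peri1mm",
    "ring_2mm": "Peri2mm",
    "ring_3mm": "Peri3mm",
    "ring_4mm": "Peri4mm",
    "ring_5mm": "Peri5mm",
    "h1": "HabitatH1",
    "h2": "HabitatH2",
    "h3": "HabitatH3",
    "habitat_integrated": "Habitat",
}


@dataclass
class RunConfig:
    """Full-pipeline configuration; thresholds default to the study settings
    (ICC >= 0.75, |r| <= 0.9, alpha 0.05, ten-fold LASSO CV, five-fold model
    CV, habitat k searched over 2-10)."""

    cohort: syn.CohortConfig = field(default_factory=syn.CohortConfig)
    split_ratio: float = 0.7
    stratified_split: bool = True
    ring_distances_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    k_range: tuple[int, int] = (2, 10)
    voxel_subsample: int = 100_000
    kmeans_n_init: int = 10
    extraction: ft.ExtractionConfig = field(default_factory=ft.ExtractionConfig)
    icc_threshold: float = 0.75
    r_threshold: float = 0.9
    alpha: float = 0.05
    lasso_folds: int = 10
    model_cv_folds: int = 5
    selection_policy: str = "cv"  # or "paper_faithful"
    threshold_policy: str = "train_youden"  # or "per_cohort"
    target_spacing_mm: float = 1.0
    seed: int = 0
    save_images: bool = False
    attribution_permutations: int = 6
    attribution_max_samples: int = 8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = syn.CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("cohort", {}).items()
        })
        extraction = ft.ExtractionConfig(**raw.pop("extraction", {}))
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(cohort=cohort, extraction=extraction, **raw)

    def canonical_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, sort_keys=True, default=list))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical_dict(), sort_keys=True).encode()
        ).hexdigest()


def _stage_seed(master: int, offset: int) -> int:
    return int((master * 997 + offset * 7919) % (2**31 - 1))


def demo_config(seed: int = 0, n_patients: int = 40) -> RunConfig:
    """Desk-scale demo: 40 patients on a 48-cube grid with smaller tumors."""
    cohort = syn.CohortConfig(
        n_patients=n_patients,
        grid_shape=(48, 48, 48),
        tumor_radius_range_mm=((10.0, 13.0), (12.0, 16.0)),
        seed=_stage_seed(seed, 1),
    )
    return RunConfig(cohort=cohort, seed=seed)


# --------------------------------------------------------------------------
# Stage implementations
# --------------------------------------------------------------------------

def _preprocess_patient(
    p: syn.SyntheticPatient, config: RunConfig
) -> tuple[im.Volume, dict[str, im.RegionMask]]:
    vol = im.correct_bias(p.volume, p.body_mask, seed=_stage_seed(config.seed, 11))
    masks = [p.mask_reader1, p.mask_reader2, p.body_mask]
    vol, masks = im.resample_isotropic(vol, masks, config.target_spacing_mm)
    m1, m2, body = masks
    vol = im.normalize_intensity(vol, body)
    return vol, {"reader1": m1, "reader2": m2, "body": body}


STAGES = ("simulate", "preprocess", "habitat", "extract", "select", "train",
          "evaluate")


def run_pipeline(config: RunConfig, out_dir, until: str | None = None) -> dict:
    """Execute the stages in order; write per-stage artifacts; return the report.

    ``until`` stops after the named stage (one of ``simulate``,
    ``preprocess``, ``habitat``, ``extract``, ``select``, ``train``,
    ``evaluate``), returning the artifacts produced so far.
    """
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage: {until}")
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_master = config.seed

    # -- simulate -----------------------------------------------------------
    log.info("stage simulate: n=%d", config.cohort.n_patients)
    patients = syn.generate_cohort(config.cohort)
    clin = syn.clinical_table(patients)
    clin.to_csv(out / "cohort.csv")
    if config.save_images:
        syn.write_cohort(patients, out / "images")
    train_ids, test_ids = syn.split_cohort(
        patients,
        ratio=config.split_ratio,
        stratified=config.stratified_split,
        seed=_stage_seed(rng_master, 2),
    )
    json.dump(
        {"train": train_ids, "test": test_ids},
        open(out / "split.json", "w"),
        indent=1,
    )
    labels = clin["grade"]
    if until == "simulate":
        return {"stage": "simulate", "n_patients": len(patients)}

    # -- preprocess + rings + local feature maps ---------------------------
    log.info("stage preprocess/rings/local-features")
    vols: dict[str, im.Volume] = {}
    masks: dict[str, dict[str, im.RegionMask]] = {}
    rings1: dict[str, dict[float, im.RegionMask]] = {}
    rings2: dict[str, dict[float, im.RegionMask]] = {}
    maps: dict[str, hb.LocalFeatureMap] = {}
    for p in patients:
        vol, mk = _preprocess_patient(p, config)
        vols[p.patient_id] = vol
        masks[p.patient_id] = mk
        rings1[p.patient_id] = im.peritumoral_rings(
            mk["reader1"], config.ring_distances_mm
        )
        rings2[p.patient_id] = im.peritumoral_rings(
            mk["reader2"], config.ring_distances_mm
        )
        maps[p.patient_id] = hb.local_feature_maps(vol, mk["reader1"])
    if until == "preprocess":
        return {"stage": "preprocess", "n_patients": len(patients)}

    # -- habitat ------------------------------------------------------------
    log.info("stage habitat: fit on %d training patients", len(train_ids))
    model = hb.fit_habitat_model(
        [maps[i] for i in train_ids],
        k_range=config.k_range,
        voxel_subsample=config.voxel_subsample,
        n_init=config.kmeans_n_init,
        seed=_stage_seed(rng_master, 3),
    )
    habitat_maps = {
        pid: hb.assign_habitats(model, maps[pid], masks[pid]["reader1"])
        for pid in clin.index
    }
    frac_rows = []
    for pid, hm in habitat_maps.items():
        row = {"patient_id": pid}
        row.update({f"h{h}_count": c for h, c in hm.per_label_voxel_counts.items()})
        row.update({f"h{h}_fraction": f for h, f in hm.per_label_fractions.items()})
        frac_rows.append(row)
    pd.DataFrame(frac_rows).set_index("patient_id").to_csv(out / "habitat_fractions.csv")
    json.dump(
        {"k": model.k, "ch_scores": {str(k): v for k, v in model.ch_scores.items()}},
        open(out / "habitat_model.json", "w"),
        indent=1,
    )
    if until == "habitat":
        return {"stage": "habitat", "k": model.k, "ch_scores": model.ch_scores}

    # -- extract ------------------------------------------------------------
    log.info("stage extract: %d patients x %d regions", len(patients), 9)
    rows1, rows2 = {}, {}
    for p in patients:
        pid = p.patient_id
        vol = vols[pid]
        region_masks = {"intra": masks[pid]["reader1"].with_role("intra")}
        for d, rm in rings1[pid].items():
            region_masks[f"ring_{d:g}mm"] = rm
        hmasks = hb.habitat_masks(habitat_maps[pid], masks[pid]["reader1"], model.k)
        region_masks.update(hmasks)
        vec = ft.extract_region_table(vol, region_masks, config.extraction)
        hvecs = {
            tag: vec[[c for c in vec.index if c.startswith(f"{tag}|")]]
            for tag in ("h1", "h2", "h3")
        }
        integ = ft.integrated_habitat_features(hvecs["h1"], hvecs["h2"], hvecs["h3"])
        rows1[pid] = pd.concat([vec, integ])
        if pid in train_ids:  # reader-2 extraction feeds the ICC filter
            r2 = {"intra": masks[pid]["reader2"].with_role("intra")}
            for d, rm in rings2[pid].items():
                r2[f"ring_{d:g}mm"] = rm
            rows2[pid] = ft.extract_region_table(vol, r2, config.extraction)
    table = pd.DataFrame(rows1).T.loc[clin.index]
    table_r2 = pd.DataFrame(rows2).T.loc[[i for i in clin.index if i in rows2]]
    table.to_csv(out / "features_reader1.csv")

    # -- impute + ICC filter ------------------------------------------------
    log.info("stage impute/icc")
    table = ft.knn_impute(table, train_index=pd.Index(train_ids))
    filtered_train, icc_report = ft.filter_by_icc(
        table.loc[train_ids], table_r2.loc[train_ids], threshold=config.icc_threshold
    )
    icc_report.to_csv(out / "icc_report.csv")
    table = table[filtered_train.columns]
    if until == "extract":
        return {"stage": "extract", "n_features": table.shape[1]}

    # -- selection per region ------------------------------------------------
    log.info("stage select")
    y_train = labels.loc[train_ids].to_numpy()
    y_test = labels.loc[test_ids].to_numpy()
    selections: dict[str, tuple] = {}
    for region in REGION_TO_MODEL:
        cols = [c for c in table.columns if ft.FeatureName.parse(c).region == region]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result, tr_z, te_z = sel.select_features(
                table.loc[train_ids, cols],
                y_train,
                table.loc[test_ids, cols],
                alpha=config.alpha,
                r_threshold=config.r_threshold,
                n_folds=config.lasso_folds,
                seed=_stage_seed(rng_master, 5),
            )
        result.to_json(out / f"selection_{region}.json")
        selections[region] = (result, tr_z, te_z)
    if until == "select":
        return {
            "stage": "select",
            "n_selected": {r: len(s[0].selected) for r, s in selections.items()},
        }

    # -- modeling per region --------------------------------------------------
    log.info("stage train")
    radscores_train = pd.DataFrame(index=pd.Index(train_ids))
    radscores_test = pd.DataFrame(index=pd.Index(test_ids))
    chosen: dict[str, dict] = {}
    region_models: dict[str, md.TrainedModel] = {}
    selected_train_z: dict[str, pd.DataFrame] = {}
    for region, model_name in REGION_TO_MODEL.items():
        result, tr_z, te_z = selections[region]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidates = md.train_all_algorithms(
                tr_z, y_train, region,
                cv_folds=config.model_cv_folds,
                seed=_stage_seed(rng_master, 6),
            )
            test_aucs = {
                a: ev.roc_auc(m.predict_probability(te_z), y_test)
                for a, m in candidates.items()
            }
            algo, best = md.select_best_algorithm(
                candidates,
                evaluation_scores=test_aucs,
                policy=config.selection_policy,
            )
        region_models[region] = best
        selected_train_z[region] = tr_z
        chosen[model_name] = {
            "region": region,
            "algorithm": algo,
            "n_selected_features": len(result.selected),
            "lasso_lambda": result.lasso_lambda,
            "cv_auc": best.cv_auc,
        }
        radscores_train[model_name] = best.predict_probability(tr_z)
        radscores_test[model_name] = best.predict_probability(te_z)

    # -- clinical model ------------------------------------------------------
    log.info("stage clinic/nomogram")
    covariates = clin.drop(columns=["grade"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        independent, or_table = md.screen_clinical(
            covariates.loc[train_ids], y_train, entry_alpha=config.alpha
        )
    or_table.to_csv(out / "clinical_screening.csv")
    if not independent:
        uni = or_table[or_table["stage"] == "univariate"]
        independent = [uni["p"].idxmin()]
        log.warning("no independent clinical predictor; using %s", independent)
    clinic_model = md.build_nomogram(
        covariates.loc[train_ids, independent], y_train
    )
    radscores_train["Clinic"] = clinic_model.predict_probability(
        covariates.loc[train_ids, independent]
    )
    radscores_test["Clinic"] = clinic_model.predict_probability(
        covariates.loc[test_ids, independent]
    )

    # -- nomogram (Combined) -------------------------------------------------
    nomo_inputs_train = pd.concat(
        [
            covariates.loc[train_ids, independent],
            radscores_train[["Intra", "Peri2mm", "Habitat"]],
        ],
        axis=1,
    )
    nomo_inputs_test = pd.concat(
        [
            covariates.loc[test_ids, independent],
            radscores_test[["Intra", "Peri2mm", "Habitat"]],
        ],
        axis=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nomogram = md.build_nomogram(nomo_inputs_train, y_train)
    radscores_train["Combined"] = nomogram.predict_probability(nomo_inputs_train)
    radscores_test["Combined"] = nomogram.predict_probability(nomo_inputs_test)
    nomogram.points_table().to_csv(out / "nomogram_points.csv")
    radscores_train.to_csv(out / "scores_train.csv")
    radscores_test.to_csv(out / "scores_test.csv")
    if until == "train":
        return {"stage": "train", "models": chosen}

    # -- evaluate ------------------------------------------------------------
    log.info("stage evaluate")
    report = build_report(
        radscores_train, radscores_test, y_train, y_test,
        threshold_policy=config.threshold_policy,
    )
    report["models"] = chosen
    report["habitat"] = {
        "k": model.k,
        "ch_scores": {str(k): v for k, v in model.ch_scores.items()},
        "mean_fractions": {
            f"h{h}": float(
                np.mean([habitat_maps[pid].per_label_fractions[h] for pid in clin.index])
            )
            for h in range(1, model.k + 1)
        },
    }
    report["clinical_independent_predictors"] = independent

    # attribution of the integrated-habitat model (global importance)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bg = selected_train_z["habitat_integrated"]
        sub = bg.iloc[: config.attribution_max_samples]
        attr, ranking, base = ev.attribution_summary(
            region_models["habitat_integrated"],
            sub,
            bg,
            n_permutations=config.attribution_permutations,
            seed=_stage_seed(rng_master, 8),
        )
    ranking.to_csv(out / "habitat_attribution_ranking.csv", header=["mean_abs_attribution"])

    manifest = {
        "config_hash": config.config_hash(),
        "config": config.canonical_dict(),
        "stage_seeds": {
            name: _stage_seed(rng_master, off)
            for name, off in [
                ("cohort", 1), ("split", 2), ("habitat", 3), ("selection", 5),
                ("modeling", 6), ("attribution", 8), ("bias", 11),
            ]
        },
        "n_train": len(train_ids),
        "n_test": len(test_ids),
    }
    json.dump(manifest, open(out / "manifest.json", "w"), indent=1, sort_keys=True)
    json.dump(report, open(out / "report.json", "w"), indent=1, sort_keys=True,
              default=float)
    _report_to_csv(report, out / "report_models.csv")
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return report


# --------------------------------------------------------------------------
# Report assembly
# --------------------------------------------------------------------------

def build_report(
    scores_train: pd.DataFrame,
    scores_test: pd.DataFrame,
    y_train: np.ndarray,
    y_test: np.ndarray,
    threshold_policy: str = "train_youden",
) -> dict:
    """Per-model AUC/CI/threshold metrics, DeLong matrices, calibration, DCA."""
    report: dict = {"metrics": {}, "delong_p": {}, "calibration": {}, "dca": {}}
    names = [m for m in MODEL_NAMES if m in scores_train.columns]
    for cohort, scores, y in (
        ("train", scores_train, y_train),
        ("test", scores_test, y_test),
    ):
        block = {}
        for name in names:
            s = scores[name].to_numpy()
            auc, lo, hi = ev.delong_ci(s, y)
            if threshold_policy == "per_cohort":
                thr = ev.youden_threshold(s, y)
            else:
                thr = ev.youden_threshold(scores_train[name].to_numpy(), y_train)
            block[name] = {
                "auc": auc, "ci_low": lo, "ci_high": hi,
                **ev.threshold_metrics(s, y, thr),
            }
        report["metrics"][cohort] = block
        pmat = {
            a: {
                b: (1.0 if a == b else ev.delong_test(
                    scores[a].to_numpy(), scores[b].to_numpy(), y)[1])
                for b in names
            }
            for a in names
        }
        report["delong_p"][cohort] = pmat
        bins, brier = ev.calibration_curve(
            np.clip(scores["Combined"].to_numpy(), 0, 1), y
        )
        report["calibration"][cohort] = {
            "bins": bins.to_dict(orient="list"), "brier": brier,
        }
        dca = {
            name: ev.decision_curve(
                np.clip(scores[name].to_numpy(), 0, 1), y
            )["net_benefit"].tolist()
            for name in ("Clinic", "Combined")
        }
        dca["thresholds"] = ev.decision_curve(
            np.clip(scores["Combined"].to_numpy(), 0, 1), y
        )["threshold"].tolist()
        report["dca"][cohort] = dca
    return report


def _report_to_csv(report: dict, path) -> None:
    rows = []
    for cohort, block in report["metrics"].items():
        for name, m in block.items():
            rows.append(
                {
                    "model": name, "cohort": cohort, "AUC": m["auc"],
                    "CI": f"{m['ci_low']:.4f} - {m['ci_high']:.4f}",
                    "Accuracy": m["accuracy"], "Sensitivity": m["sensitivity"],
                    "Specificity": m["specificity"], "PPV": m["ppv"],
                    "NPV": m["npv"],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
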