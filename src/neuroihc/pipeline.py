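"""End-to-end desk-scale pipeline: simulate -> plan -> quantify -> score ->
classify -> stats, with config serialisation, provenance manifest and a
summary report.

A run is reproducible from its config + seed alone: the global seed is
fanned out to per-stage child streams so stages can be rerun
independently, and the manifest records a checksum per output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from neuroihc import clinstats
from neuroihc.cells import segment_cells
from neuroihc.classifier import (
    ClassifierConfig,
    assemble_features,
    cross_validate,
    evaluate,
    leave_one_out,
    split_train_test,
    top_k_group_composition,
    train_forest,
)
from neuroihc.cohort import (
    generate_cohort_table,
    generate_manual_grades,
    generate_qpcr_plate,
)
from neuroihc.constants import stage_seed
from neuroihc.effects import EffectConfig, null_effects, study_effects
from neuroihc.render import render_roi
from neuroihc.sampling import enumerate_plan, specs_from_plan
from neuroihc.stain_quant import (
    DEFAULT_INTENSITY_THRESHOLDS,
    count_detections,
    digital_allred,
    positive_area_fraction,
    segment_superpixels,
    separate_hd,
    superpixel_features,
)

EFFECT_PRESETS = {"study": study_effects, "null": null_effects}


@dataclass
class RunConfig:
    """Serialisable configuration of one pipeline run."""

    seed: int = 0
    # cohort + design
    n_disease: int = 4
    n_control: int = 4
    stains: tuple = ("Iba1", "FUS")
    regions: tuple = ("BA4",)
    n_replicates: int = 3
    # effects / noise
    effect_preset: str = "study"  # study | null
    case_sd: float = 0.02
    roi_sd: float = 0.15
    od_noise_sd: float = 0.015
    # quantification
    um_per_px: float = 2.0
    superpixel_area_um2: float = 400.0
    compactness: float = 0.2
    intensity_thresholds: tuple = DEFAULT_INTENSITY_THRESHOLDS
    kappa_noise: float = 0.0
    # classifier
    n_trees: int = 50
    train_fraction: float = 0.66
    cv_folds: int = 3
    split_unit: str = "roi"
    # qPCR
    qpcr_n_control: int = 8
    qpcr_n_disease: int = 8
    qpcr_true_log2_fc: float = 0.0
    qpcr_ct_sd: float = 0.3
    # io
    save_images: int = 4  # how many example ROIs to write as TIFF

    def effects(self) -> EffectConfig:
        if self.effect_preset not in EFFECT_PRESETS:
            raise ValueError(f"unknown effect preset {self.effect_preset!r}")
        return EFFECT_PRESETS[self.effect_preset](
            seed=stage_seed(self.seed, "effects"),
            case_sd=self.case_sd,
            roi_sd=self.roi_sd,
            od_noise_sd=self.od_noise_sd,
        )

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            n_trees=self.n_trees,
            train_fraction=self.train_fraction,
            cv_folds=self.cv_folds,
            seed=stage_seed(self.seed, "classifier"),
            split_unit=self.split_unit,
        )

    def to_yaml(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        payload = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def quantify_roi(img, spec, config: RunConfig, vessel_mask=None):
    """One ROI through the quantification stack.

    Returns (superpixel records, cell records or None, allred score,
    counts dict).  Cells are segmented for the nuclear/cytoplasmic
    localisation stain (FUS).
    """
    hema, dab = separate_hd(img)
    labels = segment_superpixels(
        dab,
        config.superpixel_area_um2,
        config.um_per_px,
        compactness=config.compactness,
    )
    sp = superpixel_features(
        labels,
        dab,
        vessel_mask,
        config.um_per_px,
        roi_id=spec.roi_id,
        thresholds=config.intensity_thresholds,
    )
    cells = None
    if spec.stain == "FUS":
        cells = segment_cells(hema, dab, config.um_per_px, roi_id=spec.roi_id)
    score = digital_allred(sp)
    counts = count_detections(sp, cells)
    counts["positive_area_fraction"] = positive_area_fraction(sp)
    return sp, cells, score, counts


def run_pipeline(config: RunConfig, out_dir: Path) -> dict:
    """Execute the full pipeline and write its outputs under ``out_dir``.

    Stages: cohort simulation, ROI plan, render + quantify, digital
    Allred + synthetic manual grades, random-forest classification
    (hierarchical report, cross-validation, feature-group leave-one-out),
    statistics (concordance, stain correlations, group test, ddCt), and a
    provenance manifest.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)
        return p

    stage = {}
    try:
        stage["name"] = "cohort"
        cohort = generate_cohort_table(
            config.n_disease, config.n_control, stage_seed(config.seed, "cohort")
        )
        save_csv(cohort, "cohort.csv")

        stage["name"] = "plan"
        plan = enumerate_plan(cohort, config.stains, config.regions, config.n_replicates)
        save_csv(plan, "plan.csv")

        stage["name"] = "quantify"
        effects = config.effects()
        group_of = dict(zip(cohort["case_id"], cohort["group"]))
        sp_frames, cell_frames, roi_rows, allred_rows = [], [], [], []
        n_saved = 0
        for i, spec in enumerate(specs_from_plan(plan)):
            img, truth = render_roi(
                spec,
                effects,
                stage_seed(config.seed, f"roi|{spec.roi_id}"),
                group=group_of[spec.case_id],
                um_per_px=config.um_per_px,
            )
            if n_saved < config.save_images:
                tifffile.imwrite(out / "images" / f"{i:04d}.tif", img)
                n_saved += 1
            sp, cells, score, counts = quantify_roi(
                img, spec, config, vessel_mask=truth.vessel_mask
            )
            sp_frames.append(sp)
            if cells is not None and len(cells):
                cell_frames.append(cells)
            allred_rows.append(
                {
                    "roi_id": spec.roi_id,
                    "proportion_score": score.proportion_score,
                    "intensity_score": score.intensity_score,
                    "allred_total": score.total,
                }
            )
            roi_rows.append(
                {
                    "roi_id": spec.roi_id,
                    "case_id": spec.case_id,
                    "stain": spec.stain,
                    "region": spec.region,
                    "matter": spec.matter,
                    "adjacency": spec.adjacency,
                    "replicate": spec.replicate,
                    "group": group_of[spec.case_id],
                    "true_positive_fraction": truth.positive_fraction,
                    "true_mean_class": truth.mean_intensity_class,
                    "n_objects": truth.n_objects,
                }
                | counts
            )
        superpixels = pd.concat(sp_frames, ignore_index=True)
        cells_all = (
            pd.concat(cell_frames, ignore_index=True)
            if cell_frames
            else pd.DataFrame(columns=["roi_id", "cell_id", "cell_type"])
        )
        roi_summary = pd.DataFrame(roi_rows)
        allred = pd.DataFrame(allred_rows)
        save_csv(superpixels, "superpixels.csv")
        save_csv(cells_all, "cells.csv")
        save_csv(roi_summary, "roi_summary.csv")
        save_csv(allred, "allred.csv")

        stage["name"] = "grades"
        # FUS is excluded from severity grading: localisation, not
        # intensity, is its relevant readout
        truth_df = roi_summary.loc[
            roi_summary["stain"] != "FUS"
        ].rename(columns={"true_positive_fraction": "positive_fraction"})
        grades = generate_manual_grades(
            truth_df, config.kappa_noise, stage_seed(config.seed, "grades")
        )
        grades = grades.merge(truth_df[["roi_id", "stain"]], on="roi_id")
        save_csv(grades, "manual_grades.csv")

        stage["name"] = "classify"
        detections = _detection_table(superpixels, cells_all)
        fm = assemble_features(detections, plan, cohort)
        cc = config.classifier_config()
        train, test = split_train_test(
            fm, cc.train_fraction, unit=cc.split_unit, seed=cc.seed
        )
        model = train_forest(train, cc)
        report = evaluate(model, test)
        strata = report.strata.copy()
        strata.insert(0, "scope", "stratum")
        overall_row = {"scope": "overall", "depth": 0, "n": len(test)}
        overall_row.update(
            {
                k: getattr(report.overall, k)
                for k in ("tp", "fn", "tn", "fp", "sensitivity", "specificity", "chi2_stat", "chi2_p", "tested")
            }
        )
        strata = pd.concat([pd.DataFrame([overall_row]), strata], ignore_index=True)
        save_csv(strata, "classifier_report.csv")
        folds, cv_summary = cross_validate(fm, cc)
        save_csv(folds, "cross_validation.csv")
        loo, importances = leave_one_out(fm, cc, unit="feature_group")
        save_csv(loo, "leave_one_out.csv")
        save_csv(importances, "feature_ranking.csv")

        stage["name"] = "stats"
        stats_out = {}
        merged = allred.merge(grades, on="roi_id")
        concordance = {}
        for stain, sub in merged.groupby("stain", observed=True):
            if len(sub) >= 3:
                rho, p = clinstats.grade_concordance(sub["allred_total"], sub["grade"])
                concordance[stain] = {"rho": rho, "p_value": p, "n": len(sub)}
        stats_out["allred_grade_concordance"] = concordance
        summaries = clinstats.triplicate_average(
            roi_summary,
            ["n_positive_superpixels", "positive_area_fraction"],
        )
        labels = cohort[["case_id", "group"]]
        wide = (
            summaries.pivot_table(
                index=["case_id", "region", "matter", "adjacency"],
                columns="stain",
                values="n_positive_superpixels",
                observed=True,
            )
            .reset_index()
            .merge(labels, on="case_id")
        )
        stain_cols = [s for s in config.stains if s in wide.columns]
        if len(stain_cols) >= 2:
            corr = clinstats.spearman_matrix(wide, stain_cols)
            save_csv(corr, "stain_correlations.csv")
        per_case = clinstats.case_average(
            summaries, ["n_positive_superpixels", "positive_area_fraction"]
        ).merge(labels, on="case_id")
        save_csv(per_case, "case_summaries.csv")
        group_tests = []
        for stain in config.stains:
            sub = per_case[per_case["stain"] == stain]
            res = clinstats.choose_and_run_test(
                {
                    g: sub.loc[sub["group"] == g, "n_positive_superpixels"].to_numpy()
                    for g in ("disease", "control")
                }
            )
            group_tests.append(
                {
                    "stain": stain,
                    "tested": res.tested,
                    "branch": res.branch,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
        save_csv(pd.DataFrame(group_tests), "group_tests.csv")

        stage["name"] = "qpcr"
        plate = generate_qpcr_plate(
            config.qpcr_n_control,
            config.qpcr_n_disease,
            config.qpcr_true_log2_fc,
            config.qpcr_ct_sd,
            stage_seed(config.seed, "qpcr"),
        )
        save_csv(plate, "qpcr_plate.csv")
        qres = clinstats.ddct_analysis(plate)
        save_csv(qres.per_sample, "qpcr_fold_changes.csv")
        stats_out["qpcr"] = {
            "mean_log2_fc_disease": qres.mean_log2_fc_disease,
            "t_p_value": qres.p_value,
            "levene_p": qres.levene_p,
            "n_excluded": len(qres.excluded),
        }
        stats_out["cross_validation"] = cv_summary
        stats_out["top50_feature_groups"] = {
            k: int(v) for k, v in top_k_group_composition(importances, 50).items()
        }
        p_stats = out / "stats_summary.json"
        p_stats.write_text(json.dumps(stats_out, indent=2, default=float))
        written.append(p_stats)

        stage["name"] = "config"
        config.to_yaml(out / "config.yaml")
        written.append(out / "config.yaml")
    except Exception as err:
        partial = {
            "failed_stage": stage.get("name", "unknown"),
            "error": repr(err),
            "outputs": [str(p.relative_to(out)) for p in written],
        }
        (out / "manifest.json").write_text(json.dumps(partial, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage.get('name')!r}: {err}") from err

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _detection_table(superpixels: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    sp = superpixels.drop(columns=["label"], errors="ignore").copy()
    sp["detection_type"] = "superpixel"
    if len(cells):
        c = cells.drop(columns=["cell_id"], errors="ignore").copy()
        c = c.rename(columns={})
        c["detection_type"] = "cell"
        c = c.drop(columns=["cell_type"], errors="ignore")
        return pd.concat([sp, c], ignore_index=True)
    return sp


def make_report(run_dir: Path) -> dict:
    """Summarise a completed run directory.

    Returns the hierarchy table of per-stratum sensitivity/specificity/
    chi-square, the top-k feature-group composition, correlation and
    group-test tables, and cross-checks the strata against the plan.
    """
    run_dir = Path(run_dir)
    needed = ["classifier_report.csv", "plan.csv", "stats_summary.json", "feature_ranking.csv"]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"run directory incomplete; missing {missing}")
    strata = pd.read_csv(run_dir / "classifier_report.csv")
    plan = pd.read_csv(run_dir / "plan.csv")
    stats_summary = json.loads((run_dir / "stats_summary.json").read_text())
    ranking = pd.read_csv(run_dir / "feature_ranking.csv")
    report = {
        "hierarchy_depths": sorted(int(d) for d in strata["depth"].unique() if d > 0),
        "overall": strata[strata["scope"] == "overall"].iloc[0].to_dict(),
        "strata": strata,
        "top50_feature_groups": stats_summary.get("top50_feature_groups", {}),
        "cross_validation": stats_summary.get("cross_validation", {}),
        "stats": stats_summary,
        "n_planned_rois": len(plan),
        "plan_strata": plan.groupby(
            ["stain", "region", "matter", "adjacency"], observed=True
        )
        .size()
        .reset_index(name="n_rois"),
        "feature_ranking": ranking,
    }
    deepest = strata[strata["depth"] == 4]
    report["deepest_strata_match_plan"] = set(
        map(tuple, deepest[["stain", "region", "matter", "adjacency"]].dropna().to_numpy())
    ) <= set(map(tuple, report["plan_strata"][["stain", "region", "matter", "adjacency"]].to_numpy()))
    return report
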