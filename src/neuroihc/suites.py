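"""Canonical synthetic experiment recipes.

Each function runs one self-contained study-condition experiment —
concordance of digital Allred vs manual grading, classifier type-I
calibration on null cohorts, single-stain planted-effect power,
regression-coefficient recovery, ddCt fold-change recovery, and
leave-one-out feature attribution — and returns plain numbers.  The test
suite and the acceptance script both call these, so the measured
quantities are computed in exactly one place.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from neuroihc.clinstats import compare_regressions, ddct_analysis, grade_concordance
from neuroihc.cohort import generate_cohort_table, generate_manual_grades, generate_qpcr_plate
from neuroihc.classifier import (
    ClassifierConfig,
    assemble_features,
    split_train_test,
    train_forest,
    evaluate,
    leave_one_out,
)
from neuroihc.constants import STAINS, stage_seed
from neuroihc.effects import StainEffect, null_effects, single_stain_effects, with_baseline
from neuroihc.featuresim import informative_noise_detections, sample_detections
from neuroihc.render import render_roi
from neuroihc.sampling import ROISpec, enumerate_plan
from neuroihc.stain_quant import (
    digital_allred,
    positive_area_fraction,
    segment_superpixels,
    separate_hd,
    superpixel_features,
)


def quantify_rendered(img, um_per_px, *, target_area_um2=400.0, vessel_mask=None):
    """Render-side quantification used across the suites."""
    _, dab = separate_hd(img)
    labels = segment_superpixels(dab, target_area_um2, um_per_px)
    return superpixel_features(labels, dab, vessel_mask, um_per_px)


def concordance_suite(
    seed: int,
    *,
    n_levels: int = 12,
    n_replicates: int = 3,
    um_per_px: float = 2.0,
    kappa_noise: float = 0.0,
    max_fraction: float = 0.5,
) -> dict:
    """Digital Allred vs synthetic manual grading across burden levels.

    Renders ROIs over a grid of planted positive fractions with stain
    intensity deepening alongside burden (severe tissue stains darker),
    scores each digitally, grades each from the true burden with the
    requested label noise, and returns the Spearman concordance plus the
    worst planted-vs-measured fraction error.
    """
    rows = []
    for i, pf in enumerate(np.linspace(0.0, max_fraction, n_levels)):
        mean_class = 1.0 + 3.0 * pf
        cfg = with_baseline(
            null_effects(seed=0, roi_sd=0.0, case_sd=0.0),
            "Iba1",
            positive_fraction=float(pf),
            mean_class=float(mean_class),
        )
        for rep in range(n_replicates):
            spec = ROISpec(f"lvl{i:02d}-r{rep}", "SYN", "Iba1", "BA4", "GM", "NVA", rep + 1)
            img, truth = render_roi(
                spec, cfg, stage_seed(seed, spec.roi_id), um_per_px=um_per_px
            )
            sp = quantify_rendered(img, um_per_px)
            rows.append(
                {
                    "roi_id": spec.roi_id,
                    "positive_fraction": truth.positive_fraction,
                    "measured_fraction": positive_area_fraction(sp),
                    "allred_total": digital_allred(sp).total,
                }
            )
    df = pd.DataFrame(rows)
    grades = generate_manual_grades(df, kappa_noise, stage_seed(seed, "grades"))
    rho, p = grade_concordance(df["allred_total"], grades["grade"])
    return {
        "rho": rho,
        "p_value": p,
        "n": len(df),
        "max_fraction_error": float((df["measured_fraction"] - df["positive_fraction"]).abs().max()),
        "table": df.assign(grade=grades["grade"]),
    }


# ---------------------------------------------------------------------------
# classifier suites


def stain_panel_report(
    seed: int,
    effects,
    *,
    n_cases: int = 6,
    regions=("BA4",),
    n_replicates: int = 2,
    n_superpixels: int = 12,
    n_cells: int = 4,
    n_trees: int = 30,
    split_unit: str = "roi",
    drop_extent: bool = False,
):
    cohort = generate_cohort_table(n_cases, n_cases, stage_seed(seed, "cohort"))
    plan = enumerate_plan(cohort, STAINS, regions, n_replicates)
    det = sample_detections(
        plan,
        cohort,
        effects,
        stage_seed(seed, "detections"),
        n_superpixels_per_roi=n_superpixels,
        n_cells_per_roi=n_cells,
    )
    fm = assemble_features(det, plan, cohort)
    if drop_extent:
        fm = fm.drop_features(["roi_positive_fraction", "roi_n_positive"])
    cc = ClassifierConfig(n_trees=n_trees, seed=stage_seed(seed, "split"), split_unit=split_unit)
    train, test = split_train_test(fm, cc.train_fraction, unit=split_unit, seed=cc.seed)
    return evaluate(train_forest(train, cc), test)


def type_one_calibration(seed: int, n_cohorts: int = 200, alpha: float = 0.05) -> dict:
    """Per-stratum chi-square rejection rate over null cohorts.

    The null here is fully exchangeable at the detection level (all
    disease deltas zero AND no case/ROI-level noise, with ROI-broadcast
    extent features excluded), because the Pearson test on pooled
    detections assumes independent observations; cluster-level noise or
    shared within-ROI covariates would make detections pseudoreplicates
    and the test anticonservative by design, not by defect.
    """
    ps: list[float] = []
    for i in range(n_cohorts):
        rep = stain_panel_report(
            stage_seed(seed, f"null{i}"),
            null_effects(seed=stage_seed(seed, f"eff{i}"), case_sd=0.0, roi_sd=0.0),
            drop_extent=True,
        )
        d1 = rep.strata[(rep.strata["depth"] == 1) & (rep.strata["tested"])]
        ps.extend(d1["chi2_p"].tolist())
    ps_arr = np.asarray(ps)
    return {
        "n_strata": len(ps_arr),
        "rejection_rate": float((ps_arr < alpha).mean()),
        "alpha": alpha,
        "p_values": ps_arr,
    }


def single_stain_power(
    seed: int,
    n_seeds: int = 50,
    *,
    stain: str = "Iba1",
    od_shift_sigma: float = 2.0,
) -> dict:
    """How often the planted stain ranks first in sensitivity+specificity.

    Plants a detection-level mean-OD shift (in marginal-sd units) in one
    stain of an otherwise null panel, then asks whether that stain's
    stratum tops the per-stain ranking.
    """
    wins = 0
    for i in range(n_seeds):
        eff = single_stain_effects(
            stain,
            StainEffect(od_shift_sigma=od_shift_sigma),
            seed=stage_seed(seed, f"peff{i}"),
        )
        rep = stain_panel_report(stage_seed(seed, f"power{i}"), eff)
        d1 = rep.strata[rep.strata["depth"] == 1].set_index("stain")
        wins += (d1["sensitivity"] + d1["specificity"]).idxmax() == stain
    return {"n_seeds": n_seeds, "wins": wins, "win_rate": wins / n_seeds, "stain": stain}


def loo_attribution(seed: int, *, n_rois: int = 200, n_noise: int = 8, shift: float = 2.0) -> dict:
    """Leave-one-out deltas with one informative feature among pure noise.

    Dropping the informative feature should collapse accuracy to chance;
    dropping any noise feature should barely move it.
    """
    det = informative_noise_detections(n_rois, n_noise, shift, stage_seed(seed, "loo"), rows_per_roi=20)
    plan = det[["roi_id", "case_id", "stain", "region", "matter", "adjacency"]].drop_duplicates()
    plan = plan.assign(replicate=1)
    cohort = pd.DataFrame(
        {
            "case_id": det["case_id"].unique(),
            "group": [
                "disease" if c.startswith("ALS") else "control"
                for c in det["case_id"].unique()
            ],
        }
    )
    fm = assemble_features(det.drop(columns=["label"]), plan, cohort)
    cc = ClassifierConfig(n_trees=120, seed=stage_seed(seed, "loo-split"))
    loo, ranking = leave_one_out(fm, cc, unit="feature")
    loo = loo.set_index("unit")
    sig = loo.loc["signal"]
    noise_rows = loo.drop(index="signal")
    return {
        "baseline_accuracy": float(
            (loo["baseline_sensitivity"].iloc[0] + loo["baseline_specificity"].iloc[0]) / 2
        ),
        "signal_dropped_accuracy": float((sig["sensitivity"] + sig["specificity"]) / 2),
        "max_noise_delta": float(
            noise_rows[["delta_sensitivity", "delta_specificity"]].abs().to_numpy().max()
        ),
        "top_feature": ranking.iloc[0]["feature"],
        "loo": loo,
    }


# ---------------------------------------------------------------------------
# statistics suites


def regression_recovery(
    seed: int,
    n_seeds: int = 30,
    *,
    intercept_shift: float = 8.0,
    slope: float = 2.0,
    noise_sd: float = 2.0,
    n_per_group: int = 100,
) -> dict:
    """Planted intercept-only group shift: how often the interaction model
    flags the intercept (p < 0.001) but not the slope (p > 0.05)."""
    hits_intercept = hits_slope = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(stage_seed(seed, f"reg{i}"))
        x = rng.uniform(0, 10, 2 * n_per_group)
        g = np.array(["control"] * n_per_group + ["disease"] * n_per_group)
        y = slope * x + np.where(g == "disease", intercept_shift, 0.0) + rng.normal(
            0, noise_sd, 2 * n_per_group
        )
        rc = compare_regressions(x, y, g, reference="control")
        hits_intercept += rc.intercept_diff_p["disease"] < 0.001
        hits_slope += rc.slope_diff_p["disease"] > 0.05
    return {
        "n_seeds": n_seeds,
        "intercept_hit_rate": hits_intercept / n_seeds,
        "slope_pass_rate": hits_slope / n_seeds,
    }


def ddct_recovery(
    seed: int,
    true_log2_fc: float,
    *,
    ct_sd: float = 0.3,
    n_seeds: int = 10,
    n_control: int = 8,
    n_disease: int = 8,
) -> dict:
    """Mean recovered log2 fold change over replicate simulated plates."""
    recovered = []
    for i in range(n_seeds):
        plate = generate_qpcr_plate(
            n_control, n_disease, true_log2_fc, ct_sd, stage_seed(seed, f"qpcr{i}")
        )
        recovered.append(ddct_analysis(plate).mean_log2_fc_disease)
    rec = np.asarray(recovered)
    return {
        "true_log2_fc": true_log2_fc,
        "mean_recovered": float(rec.mean()),
        "sd_recovered": float(rec.std(ddof=1)),
        "abs_error": float(abs(rec.mean() - true_log2_fc)),
        "n_seeds": n_seeds,
    }
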