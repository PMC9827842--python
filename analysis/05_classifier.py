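"""Random-forest disease classification of the synthetic stain panel.

Trains the forest on detection-level features sampled under the study
effect model, reports the hierarchical sensitivity/specificity table,
3-fold cross-validation, leave-one-out feature-group deltas and the
top-feature ranking, then runs the calibration (null cohorts) and power
(single-stain planted effect) suites.
"""

import argparse
from pathlib import Path

import numpy as np

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
from neuroihc.cohort import generate_cohort_table
from neuroihc.constants import REGIONS, STAINS, stage_seed
from neuroihc.effects import study_effects
from neuroihc.featuresim import sample_detections
from neuroihc.sampling import enumerate_plan
from neuroihc.suites import single_stain_power, type_one_calibration


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/05_classifier"))
    ap.add_argument("--null-cohorts", type=int, default=100)
    ap.add_argument("--power-seeds", type=int, default=25)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort_table(10, 10, stage_seed(args.seed, "cohort"))
    plan = enumerate_plan(cohort, STAINS, REGIONS, n_replicates=2)
    det = sample_detections(
        plan, cohort, study_effects(seed=stage_seed(args.seed, "effects")),
        stage_seed(args.seed, "detections"), n_superpixels_per_roi=12, n_cells_per_roi=4,
    )
    fm = assemble_features(det, plan, cohort)
    print(f"feature pool: {len(fm)} detections x {len(fm.features)} features "
          f"over {plan.roi_id.nunique()} ROIs")

    cc = ClassifierConfig(n_trees=100, seed=stage_seed(args.seed, "clf"))
    train, test = split_train_test(fm, cc.train_fraction, unit=cc.split_unit, seed=cc.seed)
    model = train_forest(train, cc)
    report = evaluate(model, test)
    report.strata.to_csv(args.out / "hierarchy.csv", index=False)
    ov = report.overall
    print(f"overall: sensitivity {ov.sensitivity:.1f}%, specificity {ov.specificity:.1f}% "
          f"(chi2 p={ov.chi2_p:.2e})")
    d1 = report.strata[report.strata["depth"] == 1].sort_values(
        "sensitivity", ascending=False
    )
    for r in d1.itertuples(index=False):
        print(f"  {r.stain:7s} sens {r.sensitivity:5.1f}  spec {r.specificity:5.1f}  "
              f"chi2 p {r.chi2_p:.2e}")

    folds, summary = cross_validate(fm, cc)
    folds.to_csv(args.out / "cross_validation.csv", index=False)
    print(f"3-fold CV: sensitivity {summary['sensitivity_mean']:.1f} "
          f"+/- {summary['sensitivity_sd']:.1f}, specificity "
          f"{summary['specificity_mean']:.1f} +/- {summary['specificity_sd']:.1f}")

    loo, ranking = leave_one_out(fm, cc, unit="feature_group")
    loo.to_csv(args.out / "leave_one_out.csv", index=False)
    ranking.to_csv(args.out / "feature_ranking.csv", index=False)
    worst = loo.loc[np.abs(loo[["delta_sensitivity", "delta_specificity"]]).max(axis=1).idxmax()]
    print(f"leave-one-out: largest group effect = {worst.unit} "
          f"(d-sens {worst.delta_sensitivity:+.1f}, d-spec {worst.delta_specificity:+.1f})")
    comp = top_k_group_composition(ranking, 50)
    print("top-50 feature groups:", dict(comp))

    cal = type_one_calibration(stage_seed(args.seed, "cal"), n_cohorts=args.null_cohorts)
    print(f"null calibration: chi2 rejects {cal['rejection_rate']:.3f} of "
          f"{cal['n_strata']} strata at alpha=0.05")
    pw = single_stain_power(stage_seed(args.seed, "pow"), n_seeds=args.power_seeds)
    print(f"power: planted stain ({pw['stain']}) ranked first in "
          f"{pw['wins']}/{pw['n_seeds']} seeds")
    print(f"outputs in {args.out}")


if __name__ == "__main__":
    main()
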