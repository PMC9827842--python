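"""Simulate the synthetic cohort inputs: clinical sheet, qPCR plate and
example brightfield ROIs.

Writes the generated tables under --out and prints what was planted so
the downstream analyses can be read against known ground truth.
"""

import argparse
from pathlib import Path

import tifffile

from neuroihc.cohort import generate_cohort_table, generate_qpcr_plate, study_cohort
from neuroihc.constants import stage_seed
from neuroihc.effects import study_effects
from neuroihc.render import render_roi
from neuroihc.sampling import ROISpec


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/01_simulate"))
    args = ap.parse_args()
    out = args.out
    (out / "images").mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort_table(10, 10, stage_seed(args.seed, "cohort"))
    cohort.to_csv(out / "synthetic_cohort.csv", index=False)
    study_cohort().to_csv(out / "study_cohort.csv", index=False)
    print(f"synthetic cohort: {len(cohort)} cases "
          f"({(cohort.group == 'disease').sum()} disease / {(cohort.group == 'control').sum()} control)")

    plate = generate_qpcr_plate(8, 8, true_log2_fc=0.0, ct_sd=0.3, seed=stage_seed(args.seed, "qpcr"))
    plate.to_csv(out / "qpcr_plate.csv", index=False)
    print(f"qPCR plate: {plate.sample_id.nunique()} samples x 2 genes x triplicates (null planted FC)")

    effects = study_effects(seed=stage_seed(args.seed, "effects"))
    for stain in ("Iba1", "CD68", "GFAP", "pTDP43", "FUS"):
        for adjacency in ("VA", "NVA"):
            spec = ROISpec(f"demo|{stain}|{adjacency}", "ALS-01", stain, "BA4", "GM", adjacency, 1)
            img, truth = render_roi(
                spec, effects, stage_seed(args.seed, spec.roi_id), group="disease", um_per_px=1.0
            )
            tifffile.imwrite(out / "images" / f"{stain}_{adjacency}.tif", img)
            print(f"  rendered {stain:7s} {adjacency:3s}: planted positive fraction "
                  f"{truth.positive_fraction:.3f}, {truth.n_nuclei} nuclei")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
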