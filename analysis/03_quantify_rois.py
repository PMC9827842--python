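"""Render and quantify a burden grid: generator/measurement self-consistency.

For a ladder of planted positive-area fractions, renders noise-free ROIs,
runs colour deconvolution + superpixel quantification, and tabulates the
planted vs measured burden and intensity class.
"""

import argparse
from pathlib import Path

import pandas as pd

from neuroihc.constants import stage_seed
from neuroihc.effects import null_effects, with_baseline
from neuroihc.render import render_roi
from neuroihc.sampling import ROISpec
from neuroihc.stain_quant import (
    digital_allred,
    positive_area_fraction,
    segment_superpixels,
    separate_hd,
    superpixel_features,
)

UM_PER_PX = 1.0


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/03_quantify"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for pf in (0.05, 0.10, 0.20, 0.30, 0.45):
        for mc in (1.2, 2.0, 2.8):
            cfg = with_baseline(
                null_effects(seed=0, roi_sd=0.0, case_sd=0.0),
                "Iba1",
                positive_fraction=pf,
                mean_class=mc,
            )
            spec = ROISpec(f"grid|{pf}|{mc}", "SYN", "Iba1", "BA4", "GM", "NVA", 1)
            img, truth = render_roi(spec, cfg, stage_seed(args.seed, spec.roi_id), um_per_px=UM_PER_PX)
            _, dab = separate_hd(img)
            sp = superpixel_features(segment_superpixels(dab, 400.0, UM_PER_PX), dab, None, UM_PER_PX)
            pos = sp[sp["intensity_class"] >= 1]
            rows.append(
                {
                    "planted_fraction": truth.positive_fraction,
                    "measured_fraction": positive_area_fraction(sp),
                    "planted_mean_class": truth.mean_intensity_class,
                    "measured_mean_class": pos["intensity_class"].mean() if len(pos) else 0.0,
                    "allred_total": digital_allred(sp).total,
                    "n_superpixels": len(sp),
                }
            )
    df = pd.DataFrame(rows)
    df["fraction_error"] = df["measured_fraction"] - df["planted_fraction"]
    df.to_csv(args.out / "self_consistency.csv", index=False)
    print(df.round(3).to_string(index=False))
    print(f"\nmax |fraction error| = {df['fraction_error'].abs().max():.3f} "
          f"(declared tolerance 0.05); outputs in {args.out}")


if __name__ == "__main__":
    main()
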