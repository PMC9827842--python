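"""Enumerate the ROI sampling plan and the clinical strata.

Reproduces the design arithmetic (240 fields per case, 4,800 for the
20-case cohort) and the cognitive/survival groupings of the published
cohort sheet.
"""

import argparse
from pathlib import Path

import pandas as pd

from neuroihc.cohort import study_cohort
from neuroihc.sampling import enumerate_plan, stratify_cases


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)  # design is deterministic
    ap.add_argument("--out", type=Path, default=Path("results/02_plan"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = study_cohort()
    plan = enumerate_plan(cohort)
    plan.to_csv(args.out / "roi_plan.csv", index=False)
    per_case = plan.groupby("case_id").size()
    print(f"plan: {len(plan)} ROIs total, {per_case.iloc[0]} per case "
          f"(5 stains x 4 regions x GM/WM x VA/NVA x 3 replicates)")

    rows = []
    for domain in ("language", "fluency", "executive"):
        g = stratify_cases(cohort, domain)
        rows.append(
            {
                "domain": domain,
                "impaired_n": len(g.impaired),
                "unimpaired_n": len(g.unimpaired),
                "no_ecas_n": len(g.no_ecas),
                "impaired": ";".join(g.impaired),
                "testable": g.testable()["impaired"] and g.testable()["unimpaired"],
            }
        )
        print(f"{domain:10s}: impaired n={len(g.impaired)} ({', '.join(g.impaired) or '-'}), "
              f"unimpaired n={len(g.unimpaired)}, no ECAS n={len(g.no_ecas)}")
    g = stratify_cases(cohort, "language")
    print(f"survival  : long (>48 m) n={len(g.long_survivors)} ({', '.join(g.long_survivors)}), "
          f"short n={len(g.short_survivors)}")
    pd.DataFrame(rows).to_csv(args.out / "clinical_strata.csv", index=False)
    print(f"outputs in {args.out}")


if __name__ == "__main__":
    main()
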