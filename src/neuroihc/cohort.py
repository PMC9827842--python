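"""Synthetic clinical cohorts, manual-grade sheets and qPCR plates.

The cohort table mirrors a brain-bank clinical sheet for a C9orf72-ALS
case/control series: sex, age at death, disease duration (months, disease
cases only), region of onset, ECAS availability and per-domain cognitive
impairment, and ALSFRS data-point counts.  ``study_cohort`` returns the
published 10 + 10 demographics of the deeply phenotyped C9-ALS cohort this
pipeline emulates, used as the fixed input for clinical stratification.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from neuroihc.constants import ECAS_DOMAINS

ONSET_REGIONS = ("bulbar", "upper_limb", "lower_limb", "mixed")

#: Default per-domain ECAS impairment prevalence among disease cases with
#: ECAS data, approximating the observed cohort mix (language dysfunction
#: the most common impairment).
DEFAULT_ECAS_PREVALENCE: Mapping[str, float] = {
    "language": 0.45,
    "fluency": 0.10,
    "executive": 0.15,
    "memory": 0.10,
    "visuospatial": 0.05,
}

COHORT_COLUMNS = [
    "case_id",
    "group",
    "sex",
    "age_years",
    "duration_months",
    "onset_region",
    "ecas_available",
    "ecas_domains_impaired",
    "alsfrs_points",
]


def _domains_to_str(domains: Sequence[str]) -> str:
    return "|".join(d for d in ECAS_DOMAINS if d in set(domains))


def domains_from_str(value: str) -> frozenset:
    """Parse the pipe-joined ECAS-domain cell back into a set."""
    if not isinstance(value, str) or not value:
        return frozenset()
    return frozenset(value.split("|"))


def generate_cohort_table(
    n_disease: int,
    n_control: int,
    seed: int,
    *,
    ecas_prevalence: Mapping[str, float] = DEFAULT_ECAS_PREVALENCE,
    ecas_availability: float = 0.7,
) -> pd.DataFrame:
    """Generate a seeded synthetic case/control clinical sheet.

    Controls are age- and sex-matched to disease cases: where group sizes
    permit, each control reuses the age/sex of one disease case so the
    marginals agree exactly.  Controls carry no disease duration and no
    ECAS impairments.
    """
    if n_disease < 0 or n_control < 0:
        raise ValueError("n_disease and n_control must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    dis_age, dis_sex = [], []
    for i in range(n_disease):
        age = int(np.clip(rng.normal(60, 8), 40, 85))
        sex = "M" if rng.random() < 0.5 else "F"
        dis_age.append(age)
        dis_sex.append(sex)
        duration = max(1, int(rng.lognormal(mean=np.log(48.0), sigma=0.45)))
        has_ecas = rng.random() < ecas_availability
        domains: list[str] = []
        if has_ecas:
            domains = [d for d in ECAS_DOMAINS if rng.random() < ecas_prevalence.get(d, 0.0)]
        rows.append(
            {
                "case_id": f"ALS-{i + 1:02d}",
                "group": "disease",
                "sex": sex,
                "age_years": age,
                "duration_months": duration,
                "onset_region": ONSET_REGIONS[rng.integers(len(ONSET_REGIONS))],
                "ecas_available": has_ecas,
                "ecas_domains_impaired": _domains_to_str(domains),
                "alsfrs_points": int(rng.poisson(2.5)),
            }
        )
    # age/sex matching: recycle the disease marginals (permuted) for controls
    order = rng.permutation(n_disease) if n_disease else np.array([], dtype=int)
    for j in range(n_control):
        if n_disease:
            k = order[j % n_disease]
            age, sex = dis_age[k], dis_sex[k]
        else:
            age = int(np.clip(rng.normal(60, 8), 40, 85))
            sex = "M" if rng.random() < 0.5 else "F"
        rows.append(
            {
                "case_id": f"CTL-{j + 1:02d}",
                "group": "control",
                "sex": sex,
                "age_years": age,
                "duration_months": pd.NA,
                "onset_region": pd.NA,
                "ecas_available": False,
                "ecas_domains_impaired": "",
                "alsfrs_points": 0,
            }
        )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df["duration_months"] = df["duration_months"].astype("Int64")
    return df


def study_cohort() -> pd.DataFrame:
    """The published 10 C9-ALS + 10 matched-control cohort demographics.

    Fixed input data (not simulated) used for the clinical stratification
    analyses: disease durations span 25-119 months; seven disease cases
    have ECAS data (three with language dysfunction, one with executive
    dysfunction, one FTD case impaired in all three ALS-specific domains,
    two unimpaired).
    """
    disease = [
        # case, sex, age, duration_m, onset, ecas?, impaired domains, alsfrs points
        ("Case 1", "F", 63, 25, "lower_limb", True, (), 0),
        ("Case 2", "M", 50, 29, "bulbar", True, ("language",), 4),
        ("Case 3", "F", 63, 30, "upper_limb", False, (), 3),
        ("Case 4", "F", 62, 37, "mixed", True, (), 6),
        ("Case 5", "F", 65, 44, "lower_limb", False, (), 2),
        ("Case 6", "M", 65, 50, "upper_limb", False, (), 1),
        ("Case 7", "M", 62, 50, "lower_limb", True, ("executive",), 2),
        ("Case 8", "M", 43, 57, "bulbar", True, ("language",), 0),
        ("Case 9", "M", 58, 87, "lower_limb", True, ("language",), 3),
        # FTD case impaired across the three ALS-specific cognitive domains
        ("Case 10", "F", 63, 119, "upper_limb", True, ("language", "fluency", "executive"), 0),
    ]
    controls = [
        ("Control 1", "F", 65),
        ("Control 2", "M", 50),
        ("Control 3", "F", 57),
        ("Control 4", "F", 57),
        ("Control 5", "F", 71),
        ("Control 6", "M", 58),
        ("Control 7", "F", 59),
        ("Control 8", "M", 44),
        ("Control 9", "M", 63),
        ("Control 10", "F", 61),
    ]
    rows = [
        {
            "case_id": cid,
            "group": "disease",
            "sex": sex,
            "age_years": age,
            "duration_months": dur,
            "onset_region": onset,
            "ecas_available": ecas,
            "ecas_domains_impaired": _domains_to_str(domains),
            "alsfrs_points": alsfrs,
        }
        for cid, sex, age, dur, onset, ecas, domains, alsfrs in disease
    ] + [
        {
            "case_id": cid,
            "group": "control",
            "sex": sex,
            "age_years": age,
            "duration_months": pd.NA,
            "onset_region": pd.NA,
            "ecas_available": False,
            "ecas_domains_impaired": "",
            "alsfrs_points": 0,
        }
        for cid, sex, age in controls
    ]
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df["duration_months"] = df["duration_months"].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# manual ordinal grading


#: Positive-area-fraction bin edges mapping true stain burden onto the
#: ordinal severity scale none (0) / mild (1) / moderate (2) / severe (3).
GRADE_EDGES = (0.02, 0.10, 0.25)


def burden_to_grade(burden, edges: Sequence[float] = GRADE_EDGES) -> np.ndarray:
    """Monotone map from true positive-area fraction to ordinal grade 0-3."""
    return np.digitize(np.asarray(burden, dtype=float), np.asarray(edges))


def generate_manual_grades(
    truth: pd.DataFrame,
    kappa_noise: float,
    seed: int,
    *,
    burden_col: str = "positive_fraction",
    edges: Sequence[float] = GRADE_EDGES,
) -> pd.DataFrame:
    """Emulate ordinal manual grading (0-3) of each ROI's true burden.

    ``truth`` needs a ``roi_id`` column and one burden column per graded
    compartment (the default single column yields one ``grade``; columns
    named ``neuronal_burden``/``glial_burden`` additionally yield separate
    neuronal and glial grades).  With probability ``kappa_noise`` a grade
    is perturbed by +/-1 (clipped to 0-3), emulating inter-rater slack.
    """
    if not 0 <= kappa_noise < 1:
        raise ValueError("kappa_noise must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame({"roi_id": truth["roi_id"].to_numpy()})

    def _grade(col_in: str, col_out: str) -> None:
        g = burden_to_grade(truth[col_in].to_numpy(), edges)
        flip = rng.random(len(g)) < kappa_noise
        step = rng.choice([-1, 1], size=len(g))
        g = np.clip(g + flip * step, 0, 3)
        out[col_out] = g.astype(int)

    if burden_col in truth.columns:
        _grade(burden_col, "grade")
    for comp in ("neuronal", "glial"):
        col = f"{comp}_burden"
        if col in truth.columns:
            _grade(col, f"{comp}_grade")
    return out


# ---------------------------------------------------------------------------
# qPCR plate simulation


def generate_qpcr_plate(
    n_control: int,
    n_disease: int,
    true_log2_fc: float,
    ct_sd: float,
    seed: int,
    *,
    target_gene: str = "FUS",
    reference_gene: str = "18S",
    n_replicates: int = 3,
    sample_sd: float = 0.5,
    base_ct_reference: float = 12.0,
    base_dct: float = 12.0,
) -> pd.DataFrame:
    """Simulate a Ct table (target + reference gene, technical triplicates).

    Each sample carries a shared RNA-input offset on both genes, so the
    within-sample dCt = Ct_target - Ct_reference isolates expression.
    Disease samples have dCt lowered by ``true_log2_fc`` (fold change
    2**true_log2_fc relative to the control mean).  ``ct_sd`` is the
    technical replicate noise; at 0 the planted fold change is exact.
    """
    if ct_sd < 0:
        raise ValueError("ct_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    samples = [(f"CTL-{i + 1:02d}", "control") for i in range(n_control)] + [
        (f"ALS-{i + 1:02d}", "disease") for i in range(n_disease)
    ]
    for sample_id, group in samples:
        offset = rng.normal(0.0, sample_sd)
        dct = base_dct - (true_log2_fc if group == "disease" else 0.0)
        for gene, base in ((reference_gene, base_ct_reference), (target_gene, base_ct_reference + dct)):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "gene": gene,
                        "replicate": rep,
                        "ct": base + offset + (rng.normal(0.0, ct_sd) if ct_sd else 0.0),
                    }
                )
    return pd.DataFrame(rows)
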