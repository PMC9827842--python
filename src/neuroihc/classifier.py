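"""Random-forest disease/control classification of detection-level features.

The feature pool (superpixel + cell records) is split group-wise into
train/test sets, a forest of information-gain trees is fitted, and
performance is reported hierarchically — overall, per stain, per
stain x region, x matter, x vascular adjacency — as 2x2 predicted-vs-true
cross-tables with sensitivity (100*TP/total disease), specificity
(100*TN/total control) and a Pearson chi-square association test.
Three-fold group-aware cross-validation and leave-one-out feature /
feature-group analyses assess model validity and feature contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

META_COLUMNS = ("roi_id", "case_id", "stain", "region", "matter", "adjacency", "label")
LABELS = ("disease", "control")

#: The six feature themes.
FEATURE_GROUPS = (
    "staining-intensity",
    "staining-extent",
    "morphology-area",
    "morphology-shape",
    "spatial-vessel",
    "spatial-position",
)

#: Default column -> feature-group tags.
FEATURE_GROUP_OF = {
    "mean_dab_od": "staining-intensity",
    "intensity_class": "staining-intensity",
    "nuclear_mean_od": "staining-intensity",
    "cytoplasmic_mean_od": "staining-intensity",
    "nc_ratio": "staining-intensity",
    "roi_positive_fraction": "staining-extent",
    "roi_n_positive": "staining-extent",
    "area_um2": "morphology-area",
    "perimeter_um": "morphology-area",
    "nucleus_area_um2": "morphology-area",
    "circularity": "morphology-shape",
    "dist_to_vessel_um": "spatial-vessel",
    "dist_to_vessel_missing": "spatial-vessel",
    "centroid_x_um": "spatial-position",
    "centroid_y_um": "spatial-position",
}

#: Sentinel for structurally missing values (e.g. vessel distance in NVA
#: fields, cell-only features on superpixel rows); always paired with a
#: missingness indicator column.
MISSING_SENTINEL = -1.0


@dataclass
class FeatureMatrix:
    """Detection-level feature table with metadata and group tags."""

    data: pd.DataFrame
    feature_groups: dict  # feature column -> group name

    def __post_init__(self):
        missing_meta = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing_meta:
            raise ValueError(f"missing metadata columns: {missing_meta}")
        if self.data["label"].isna().any():
            raise ValueError("labels must not be missing")
        untagged = [
            c
            for c in self.data.columns
            if c not in META_COLUMNS and c not in self.feature_groups
        ]
        if untagged:
            raise ValueError(f"feature columns without a group tag: {untagged}")

    @property
    def features(self) -> list:
        return [c for c in self.data.columns if c in self.feature_groups]

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[mask].reset_index(drop=True), self.feature_groups)

    def drop_features(self, columns: Sequence[str]) -> "FeatureMatrix":
        cols = set(columns)
        return FeatureMatrix(
            self.data.drop(columns=[c for c in cols if c in self.data.columns]),
            {c: g for c, g in self.feature_groups.items() if c not in cols},
        )


def assemble_features(
    detections: pd.DataFrame,
    plan: pd.DataFrame,
    cohort: pd.DataFrame,
    *,
    feature_group_of: dict = FEATURE_GROUP_OF,
) -> FeatureMatrix:
    """Join detection records to the plan and cohort into a FeatureMatrix.

    ``detections`` needs ``roi_id`` plus feature columns; plan metadata
    and the case-level disease/control label are joined in, ROI-level
    staining-extent features are derived, and structural missingness is
    sentinel-encoded with indicator columns.
    """
    if len(detections) == 0:
        return FeatureMatrix(
            pd.DataFrame(columns=list(META_COLUMNS)), feature_groups={}
        )
    plan_meta = plan[["roi_id", "case_id", "stain", "region", "matter", "adjacency"]]
    orphans = sorted(set(detections["roi_id"]) - set(plan_meta["roi_id"]))
    if orphans:
        raise ValueError(f"detections reference roi_ids absent from the plan: {orphans[:10]}")
    df = detections.copy()
    drop = [c for c in plan_meta.columns if c != "roi_id" and c in df.columns]
    df = df.drop(columns=drop).merge(plan_meta, on="roi_id", how="left")
    label_of = dict(zip(cohort["case_id"], cohort["group"]))
    df["label"] = df["case_id"].map(label_of)
    if df["label"].isna().any():
        bad = sorted(df.loc[df["label"].isna(), "case_id"].unique())
        raise ValueError(f"cases absent from the cohort sheet: {bad}")

    # ROI-level staining-extent features broadcast onto detections
    if "intensity_class" in df.columns:
        sp = df[df.get("detection_type", "superpixel") == "superpixel"]
        per_roi = sp.groupby("roi_id")["intensity_class"].agg(
            roi_positive_fraction=lambda c: float((c >= 1).mean()),
            roi_n_positive=lambda c: float((c >= 1).sum()),
        )
        df = df.merge(per_roi, on="roi_id", how="left")

    feature_cols = [
        c
        for c in df.columns
        if c not in META_COLUMNS and c not in ("detection_type",)
    ]
    groups = {}
    for c in feature_cols:
        groups[c] = feature_group_of.get(c, "staining-intensity")
    # sentinel-encode structural missingness
    for c in list(feature_cols):
        if df[c].isna().any():
            ind = f"{c}_missing"
            if ind not in df.columns:
                df[ind] = df[c].isna().astype(float)
                groups[ind] = groups[c]
            df[c] = df[c].fillna(MISSING_SENTINEL)
    if "detection_type" in df.columns:
        df["is_cell"] = (df["detection_type"] == "cell").astype(float)
        groups["is_cell"] = "staining-extent"
        df = df.drop(columns=["detection_type"])
    return FeatureMatrix(df.reset_index(drop=True), groups)


# ---------------------------------------------------------------------------
# configuration, splitting


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 1000
    split_criterion: str = "entropy"  # information gain
    train_fraction: float = 0.66
    cv_folds: int = 3
    seed: int = 0
    split_unit: str = "roi"  # detection | roi | case
    top_k: int = 50

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def _group_ids(fm: FeatureMatrix, unit: str) -> pd.Series:
    if unit == "detection":
        return pd.Series(np.arange(len(fm)), index=fm.data.index).astype(str)
    if unit in ("roi", "case"):
        return fm.data[f"{unit}_id"]
    raise ValueError(f"unknown split unit {unit!r}")


def split_train_test(
    fm: FeatureMatrix,
    train_fraction: float = 0.66,
    *,
    unit: str = "roi",
    seed: int = 0,
):
    """Label-stratified, group-wise train/test split.

    All detections of one grouping unit (ROI by default) land on the same
    side; within each label the units are shuffled and split at
    ``train_fraction``.
    """
    labels_present = set(fm.data["label"].unique())
    if labels_present != set(LABELS):
        raise ValueError(f"both labels required before splitting; got {labels_present}")
    rng = np.random.default_rng(seed)
    gids = _group_ids(fm, unit)
    train_mask = pd.Series(False, index=fm.data.index)
    for label in LABELS:
        units = gids[fm.data["label"] == label].unique()
        if len(units) < 2:
            raise ValueError(
                f"cannot group-split: label {label!r} has {len(units)} {unit} unit(s)"
            )
        units = rng.permutation(units)
        n_train = int(round(train_fraction * len(units)))
        n_train = min(max(n_train, 1), len(units) - 1)
        train_units = set(units[:n_train])
        train_mask |= gids.isin(train_units) & (fm.data["label"] == label)
    return fm.subset(train_mask), fm.subset(~train_mask)


# ---------------------------------------------------------------------------
# the forest


@dataclass
class ForestModel:
    clf: RandomForestClassifier
    feature_cols: list
    means: np.ndarray
    sds: np.ndarray
    config: ClassifierConfig
    feature_groups: dict = field(default_factory=dict)

    def transform(self, fm: FeatureMatrix) -> np.ndarray:
        x = fm.data[self.feature_cols].to_numpy(dtype=float)
        return (x - self.means) / self.sds

    def predict(self, fm: FeatureMatrix) -> np.ndarray:
        return self.clf.predict(self.transform(fm))

    @property
    def importances(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_cols,
                "feature_group": [self.feature_groups.get(c, "") for c in self.feature_cols],
                "importance": self.clf.feature_importances_,
            }
        ).sort_values("importance", ascending=False, ignore_index=True)


def train_forest(train: FeatureMatrix, config: ClassifierConfig) -> ForestModel:
    """Fit the forest (entropy/information-gain splits, majority vote).

    Features are z-scored with train-split statistics only.
    """
    y = train.data["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    cols = train.features
    x = train.data[cols].to_numpy(dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    sds[sds == 0] = 1.0
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion=config.split_criterion,
        random_state=config.seed,
        n_jobs=1,
    )
    clf.fit((x - means) / sds, y)
    return ForestModel(clf, cols, means, sds, config, dict(train.feature_groups))


# ---------------------------------------------------------------------------
# cross-tables and hierarchical evaluation


@dataclass(frozen=True)
class CrossTable:
    """2x2 predicted-vs-true disease table."""

    tp: int
    fn: int
    tn: int
    fp: int
    chi2_stat: float = np.nan
    chi2_p: float = np.nan
    tested: bool = False

    @property
    def sensitivity(self) -> float:
        total_disease = self.tp + self.fn
        return 100.0 * self.tp / total_disease if total_disease else np.nan

    @property
    def specificity(self) -> float:
        total_control = self.tn + self.fp
        return 100.0 * self.tn / total_control if total_control else np.nan


def make_crosstable(tp: int, fn: int, tn: int, fp: int, *, correction: bool = False) -> CrossTable:
    """Build a CrossTable and run the Pearson chi-square test (df=1).

    Strata with an empty margin are flagged untested (p = NaN) rather
    than tested.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("cross-table cells must be >= 0")
    table = np.array([[tp, fn], [fp, tn]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return CrossTable(tp, fn, tn, fp)
    res = stats.chi2_contingency(table, correction=correction)
    return CrossTable(tp, fn, tn, fp, float(res.statistic), float(res.pvalue), True)


def crosstable_from_predictions(y_true, y_pred) -> CrossTable:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return make_crosstable(
        tp=int(((y_true == "disease") & (y_pred == "disease")).sum()),
        fn=int(((y_true == "disease") & (y_pred == "control")).sum()),
        tn=int(((y_true == "control") & (y_pred == "control")).sum()),
        fp=int(((y_true == "control") & (y_pred == "disease")).sum()),
    )


HIERARCHY = ("stain", "region", "matter", "adjacency")


@dataclass
class ClassifierReport:
    overall: CrossTable
    strata: pd.DataFrame  # one row per stratum at every hierarchy depth
    config: ClassifierConfig


def _ct_row(ct: CrossTable) -> dict:
    return {
        "tp": ct.tp,
        "fn": ct.fn,
        "tn": ct.tn,
        "fp": ct.fp,
        "sensitivity": ct.sensitivity,
        "specificity": ct.specificity,
        "chi2_stat": ct.chi2_stat,
        "chi2_p": ct.chi2_p,
        "tested": ct.tested,
    }


def evaluate(
    model: ForestModel,
    test: FeatureMatrix,
    *,
    hierarchy: Sequence[str] = HIERARCHY,
) -> ClassifierReport:
    """Hierarchical test-set evaluation.

    Produces the overall cross-table plus one stratum per combination of
    the first d hierarchy levels, for every depth d (stain; stain x
    region; x matter; x vascular adjacency).
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    y_true = test.data["label"].to_numpy()
    y_pred = model.predict(test)
    overall = crosstable_from_predictions(y_true, y_pred)
    rows = []
    for depth in range(1, len(hierarchy) + 1):
        keys = list(hierarchy[:depth])
        grouped = test.data.groupby(keys, observed=True, sort=True).indices
        for key, idx in grouped.items():
            key = (key,) if depth == 1 else key
            ct = crosstable_from_predictions(y_true[idx], y_pred[idx])
            row = {"depth": depth}
            row.update(dict(zip(keys, key)))
            row.update(_ct_row(ct))
            row["n"] = len(idx)
            rows.append(row)
    strata = pd.DataFrame(rows)
    for col in hierarchy:
        if col not in strata.columns:
            strata[col] = pd.NA
    return ClassifierReport(overall, strata, model.config)


# ---------------------------------------------------------------------------
# cross-validation


def _group_folds(fm: FeatureMatrix, k: int, unit: str, seed: int) -> np.ndarray:
    """Label-stratified, group-aware fold assignment per row."""
    rng = np.random.default_rng(seed)
    gids = _group_ids(fm, unit)
    fold_of: dict = {}
    for label in LABELS:
        units = gids[fm.data["label"] == label].unique()
        if len(units) < k:
            raise ValueError(
                f"cv folds ({k}) exceed {unit} units for label {label!r} ({len(units)})"
            )
        units = rng.permutation(units)
        for i, u in enumerate(units):
            fold_of[u] = i % k
    return gids.map(fold_of).to_numpy()


def cross_validate(fm: FeatureMatrix, config: ClassifierConfig):
    """k-fold group-aware cross-validation.

    Returns (per-fold frame with sensitivity/specificity, summary dict
    with their means and sds).
    """
    if config.cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    folds = _group_folds(fm, config.cv_folds, config.split_unit, config.seed)
    rows = []
    for f in range(config.cv_folds):
        train = fm.subset(folds != f)
        test = fm.subset(folds == f)
        model = train_forest(train, config)
        ct = crosstable_from_predictions(test.data["label"].to_numpy(), model.predict(test))
        rows.append({"fold": f, "n_test": len(test)} | _ct_row(ct))
    per_fold = pd.DataFrame(rows)
    summary = {
        "sensitivity_mean": float(per_fold["sensitivity"].mean()),
        "sensitivity_sd": float(per_fold["sensitivity"].std(ddof=1)),
        "specificity_mean": float(per_fold["specificity"].mean()),
        "specificity_sd": float(per_fold["specificity"].std(ddof=1)),
    }
    return per_fold, summary


# ---------------------------------------------------------------------------
# leave-one-out feature analysis


def leave_one_out(
    fm: FeatureMatrix,
    config: ClassifierConfig,
    *,
    unit: str = "feature",
):
    """Retrain without each feature (or feature group) and record deltas.

    Returns (loo frame with baseline-relative sensitivity/specificity
    deltas per unit, importance ranking of the baseline model).  The
    ranking statistic is mean impurity-decrease importance; the top-k
    group composition summarises which feature themes dominate.
    """
    if unit not in ("feature", "feature_group"):
        raise ValueError("unit must be 'feature' or 'feature_group'")
    if len(fm.features) < 2:
        raise ValueError("need >= 2 features for leave-one-out analysis")
    train, test = split_train_test(
        fm, config.train_fraction, unit=config.split_unit, seed=config.seed
    )
    base_model = train_forest(train, config)
    base_ct = crosstable_from_predictions(
        test.data["label"].to_numpy(), base_model.predict(test)
    )
    if unit == "feature":
        units = [(c, [c]) for c in fm.features]
    else:
        groups: dict[str, list] = {}
        for c, g in fm.feature_groups.items():
            groups.setdefault(g, []).append(c)
        units = sorted(groups.items())
    rows = []
    for name, cols in units:
        if len(cols) >= len(fm.features):
            continue  # dropping everything leaves no model
        model = train_forest(train.drop_features(cols), config)
        ct = crosstable_from_predictions(
            test.data["label"].to_numpy(), model.predict(test.drop_features(cols))
        )
        rows.append(
            {
                "unit": name,
                "n_features_dropped": len(cols),
                "sensitivity": ct.sensitivity,
                "specificity": ct.specificity,
                "delta_sensitivity": ct.sensitivity - base_ct.sensitivity,
                "delta_specificity": ct.specificity - base_ct.specificity,
            }
        )
    loo = pd.DataFrame(rows)
    loo["baseline_sensitivity"] = base_ct.sensitivity
    loo["baseline_specificity"] = base_ct.specificity
    return loo, base_model.importances


def top_k_group_composition(importances: pd.DataFrame, k: int = 50) -> pd.Series:
    """Feature-group counts among the top-k ranked features."""
    return importances.head(k)["feature_group"].value_counts()


def with_seed(config: ClassifierConfig, seed: int) -> ClassifierConfig:
    return replace(config, seed=seed)
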