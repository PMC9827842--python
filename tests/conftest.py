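import numpy as np
import pandas as pd
import pytest

from neuroihc.cohort import generate_cohort_table, study_cohort
from neuroihc.effects import null_effects, with_baseline
from neuroihc.render import render_roi
from neuroihc.sampling import ROISpec, enumerate_plan


@pytest.fixture(scope="session")
def cohort_table():
    return study_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort_table(4, 4, seed=11)


@pytest.fixture(scope="session")
def small_plan(small_cohort):
    return enumerate_plan(small_cohort, stains=("Iba1", "FUS"), regions=("BA4",), n_replicates=2)


@pytest.fixture(scope="session")
def rendered_iba1_va():
    """One vascular-adjacent microglial ROI with a planted 30% burden."""
    cfg = with_baseline(
        null_effects(seed=0, roi_sd=0.0, case_sd=0.0), "Iba1", positive_fraction=0.30
    )
    spec = ROISpec("fix-va", "SYN-01", "Iba1", "BA4", "GM", "VA", 1)
    img, truth = render_roi(spec, cfg, seed=202, um_per_px=1.0)
    return spec, img, truth


@pytest.fixture(scope="session")
def rendered_fus():
    """One FUS ROI (cellular nuclear/cytoplasmic staining)."""
    cfg = null_effects(seed=0, roi_sd=0.0, case_sd=0.0)
    spec = ROISpec("fix-fus", "SYN-01", "FUS", "BA4", "GM", "NVA", 1)
    img, truth = render_roi(spec, cfg, seed=303, um_per_px=1.0)
    return spec, img, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_superpixel_records(classes, areas=None):
    """Minimal superpixel record table for Allred/count tests."""
    classes = np.asarray(classes)
    if areas is None:
        areas = np.full(len(classes), 400.0)
    return pd.DataFrame(
        {
            "roi_id": "t",
            "label": np.arange(1, len(classes) + 1),
            "mean_dab_od": classes * 0.25,
            "intensity_class": classes,
            "area_um2": areas,
            "perimeter_um": 80.0,
            "circularity": 0.8,
            "centroid_x_um": 0.0,
            "centroid_y_um": 0.0,
            "dist_to_vessel_um": np.nan,
        }
    )
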