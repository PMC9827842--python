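"""Cell segmentation by nuclear-area thresholding.

Nuclei are the connected components of the thresholded haematoxylin
density, split by a distance-transform watershed and filtered on minimum
area.  Cells are typed neuron vs glia on nuclear area (neurons have large
nuclei), and a cytoplasmic ring is grown by bounded morphological
expansion clipped at neighbouring cells, from which nuclear and
cytoplasmic mean DAB ODs and their ratio (N/C) are measured — the readout
used for nuclear/cytoplasmic stain localisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import expand_labels, watershed

#: Nuclei smaller than a glial nucleus cross-section are debris.
DEFAULT_MIN_NUCLEUS_AREA_UM2 = 8.0

#: Nuclear area separating neuron-like from glia-like nuclei.
DEFAULT_NEURON_AREA_UM2 = 70.0

#: Cytoplasmic mean-OD floor below which the N/C ratio is undefined.
NC_OD_FLOOR = 1e-3


def segment_cells(
    hema_density: np.ndarray,
    dab_density: np.ndarray,
    um_per_px: float,
    *,
    nucleus_od_threshold: float = 0.15,
    neuron_area_threshold_um2: float = DEFAULT_NEURON_AREA_UM2,
    expansion_um: float = 3.0,
    min_nucleus_area_um2: float = DEFAULT_MIN_NUCLEUS_AREA_UM2,
    roi_id: str = "roi",
) -> pd.DataFrame:
    """Segment cells from haematoxylin density and measure DAB compartments.

    Returns one row per cell: nucleus area (um^2), cell type (neuron if
    nucleus area exceeds ``neuron_area_threshold_um2``, else glia),
    nuclear and cytoplasmic mean DAB OD, and ``nc_ratio`` (NaN where the
    cytoplasmic mean OD is below the floor).  An image without nuclei
    yields an empty frame.
    """
    if nucleus_od_threshold <= 0 or neuron_area_threshold_um2 <= 0:
        raise ValueError("thresholds must be > 0")
    hema = np.asarray(hema_density, dtype=float)
    dab = np.asarray(dab_density, dtype=float)
    if hema.shape != dab.shape:
        raise ValueError("hema_density and dab_density must share a shape")

    mask = hema > nucleus_od_threshold
    cols = [
        "roi_id",
        "cell_id",
        "nucleus_area_um2",
        "cell_type",
        "nuclear_mean_od",
        "cytoplasmic_mean_od",
        "nc_ratio",
    ]
    if not mask.any():
        return pd.DataFrame(columns=cols)

    # watershed split of touching nuclei seeded at distance-transform peaks
    distance = ndi.distance_transform_edt(mask)
    min_sep_px = max(2, int(round(np.sqrt(min_nucleus_area_um2) / um_per_px)))
    peaks = peak_local_max(distance, min_distance=min_sep_px, labels=mask, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        markers, _ = ndi.label(mask)
    nuclei = watershed(-distance, markers, mask=mask)

    # minimum-area filter
    min_px = min_nucleus_area_um2 / um_per_px**2
    labels, areas = np.unique(nuclei[nuclei > 0], return_counts=True)
    keep = labels[areas >= min_px]
    nuclei = np.where(np.isin(nuclei, keep), nuclei, 0)

    # cytoplasm ring: bounded expansion clipped at neighbouring cells
    expanded = expand_labels(nuclei, distance=expansion_um / um_per_px)

    rows = []
    for lab in np.unique(nuclei[nuclei > 0]):
        nuc = nuclei == lab
        ring = (expanded == lab) & ~nuc
        area_um2 = float(nuc.sum()) * um_per_px**2
        nuc_od = float(dab[nuc].mean())
        cyto_od = float(dab[ring].mean()) if ring.any() else np.nan
        nc = (
            nuc_od / cyto_od
            if np.isfinite(cyto_od) and cyto_od > NC_OD_FLOOR
            else np.nan
        )
        rows.append(
            {
                "roi_id": roi_id,
                "cell_id": int(lab),
                "nucleus_area_um2": area_um2,
                "cell_type": "neuron" if area_um2 > neuron_area_threshold_um2 else "glia",
                "nuclear_mean_od": nuc_od,
                "cytoplasmic_mean_od": cyto_od,
                "nc_ratio": nc,
            }
        )
    return pd.DataFrame(rows, columns=cols)
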