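"""Shared study-design constants and seed plumbing."""

from __future__ import annotations

import zlib

#: IHC panel: microglia (Iba1), macrophage lysosomal activation (CD68),
#: astrocyte activation (GFAP), phosphorylated TDP-43 aggregates, and the
#: RNA-binding protein FUS (nuclear/cytoplasmic localisation marker).
STAINS = ("Iba1", "CD68", "GFAP", "pTDP43", "FUS")

#: Brodmann areas sampled: motor cortex (BA4) and the three ECAS-linked
#: cognitive regions: BA39 (language), BA44 (fluency), BA46 (executive).
REGIONS = ("BA4", "BA39", "BA44", "BA46")

MATTERS = ("GM", "WM")
ADJACENCIES = ("VA", "NVA")

#: ECAS cognitive domains used for clinical stratification.
ECAS_DOMAINS = ("language", "fluency", "executive", "memory", "visuospatial")

#: ROI side length in micrometres (square fields).
ROI_SIZE_UM = 500.0

#: Smallest vessel calibre (lumen diameter, um) that counts as "larger than
#: a small capillary" for vascular-adjacency classification.
MIN_VESSEL_DIAMETER_UM = 10.0

#: Minimum clearance (um) between an NVA ROI and any qualifying vessel.
NVA_CLEARANCE_UM = 250.0

#: Long- vs short-survivor cutoff on disease duration (months).
SURVIVAL_CUTOFF_MONTHS = 48


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage child seed from a global seed.

    Counter-free scheme: mix the stage name's CRC32 into the seed so each
    pipeline stage can be rerun independently with a stable stream.
    Result is always in [0, 2**31).
    """
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def case_stream(seed: int, case_id: str) -> int:
    """Deterministic per-case child seed (stable across plan orderings)."""
    return (int(seed) * 31 + zlib.crc32(case_id.encode())) % (2**31)
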