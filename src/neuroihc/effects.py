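"""Planted disease-effect model shared by the image renderer and the
detection-level feature sampler.

Per-stain baselines describe control tissue; ``StainEffect`` deltas are
the group-level disease shifts (added for disease cases).  Between-case
heterogeneity enters as a case-level random intercept on the latent
burden, and per-ROI multiplicative noise on top — the nested
ROI-within-case structure the statistics layer assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from neuroihc.constants import STAINS, case_stream


@dataclass(frozen=True)
class StainBaseline:
    """Control-tissue staining parameters for one IHC marker."""

    positive_fraction: float  # fraction of ROI area DAB-positive
    mean_class: float  # mean intensity class of positive material (1-3)
    texture: str  # blob | fibrillar | punctate | cellular
    blob_radius_um: tuple = (4.0, 10.0)  # stained-object radius range
    elongation_steps: int = 3  # random-walk steps per object (shape irregularity)
    vessel_proximity_mean_um: float = 120.0  # mean object distance to vessel (VA)
    nc_ratio: float = 1.15  # nuclear/cytoplasmic OD ratio (cellular texture)
    circularity: float = 0.65  # typical object circularity (feature sampler)


#: Control baselines: microglia are moderately abundant, activated
#: macrophage staining sparser, astrocyte staining fibrillar and diffuse,
#: pTDP-43 aggregates sparse puncta, FUS predominantly nuclear in cells.
BASELINES: dict[str, StainBaseline] = {
    "Iba1": StainBaseline(0.12, 1.4, "blob", (4.0, 11.0), 4),
    "CD68": StainBaseline(0.06, 1.5, "blob", (3.0, 8.0), 2),
    "GFAP": StainBaseline(0.15, 1.6, "fibrillar", (1.0, 2.0), 6),
    "pTDP43": StainBaseline(0.015, 2.0, "punctate", (1.0, 2.5), 1),
    "FUS": StainBaseline(0.10, 1.5, "cellular", (3.0, 6.0), 1),
}


@dataclass(frozen=True)
class StainEffect:
    """Disease-vs-control shifts planted for one stain."""

    positive_density_delta: float = 0.0  # added positive area fraction
    intensity_class_shift: float = 0.0  # expected class increment
    circularity_delta: float = 0.0  # shift in object circularity
    vessel_proximity_delta_um: float = 0.0  # shift in mean distance to vessel
    glial_nc_ratio_delta: float = 0.0  # shift in glial N/C stain ratio
    #: detection-level mean-OD shift in units of the marginal OD sd
    #: (sharp per-detection signal, as opposed to the ROI-level burden
    #: deltas above which detections only reflect in aggregate)
    od_shift_sigma: float = 0.0


#: Disease effect directions mirrored from the study findings: raised
#: microglial (Iba1) burden/intensity with less circular, more
#: vessel-proximal objects; raised CD68 and GFAP burden; sparse extra
#: pTDP-43 aggregates; raised glial nuclear/cytoplasmic FUS ratio.
STUDY_EFFECTS: dict[str, StainEffect] = {
    "Iba1": StainEffect(0.06, 0.30, -0.08, -30.0, 0.0),
    "CD68": StainEffect(0.05, 0.20, -0.04, -15.0, 0.0),
    "GFAP": StainEffect(0.04, 0.10, 0.0, 0.0, 0.0),
    "pTDP43": StainEffect(0.020, 0.30, 0.0, 0.0, 0.0),
    "FUS": StainEffect(0.0, 0.0, 0.0, 0.0, 0.30),
}


@dataclass(frozen=True)
class EffectConfig:
    """Planted effects + noise model for a synthetic cohort."""

    effects: dict = field(default_factory=dict)  # stain -> StainEffect
    baselines: dict = field(default_factory=lambda: dict(BASELINES))
    case_sd: float = 0.02  # sd of case-level additive intercept on burden
    roi_sd: float = 0.15  # sd of per-ROI multiplicative noise
    od_noise_sd: float = 0.015  # Gaussian photon noise on OD (renderer)
    seed: int = 0  # stream for the case-level intercepts

    def __post_init__(self):
        if self.case_sd < 0 or self.roi_sd < 0 or self.od_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        for b in self.baselines.values():
            if not 0 <= b.positive_fraction <= 1:
                raise ValueError("baseline positive fractions must be in [0, 1]")

    def effect(self, stain: str) -> StainEffect:
        return self.effects.get(stain, StainEffect())

    def baseline(self, stain: str) -> StainBaseline:
        try:
            return self.baselines[stain]
        except KeyError:
            raise KeyError(
                f"unknown stain {stain!r}; valid stains: {sorted(self.baselines)}"
            ) from None

    def case_intercept(self, case_id: str, stain: str) -> float:
        """Deterministic case-level additive intercept on the latent burden."""
        if self.case_sd == 0:
            return 0.0
        rng = np.random.default_rng(case_stream(self.seed, f"{case_id}|{stain}"))
        return float(rng.normal(0.0, self.case_sd))


def null_effects(seed: int = 0, **noise) -> EffectConfig:
    """All-zero disease deltas (baseline + noise only): the null cohort."""
    return EffectConfig(effects={}, seed=seed, **noise)


def study_effects(seed: int = 0, **noise) -> EffectConfig:
    """The default planted study conditions."""
    return EffectConfig(effects=dict(STUDY_EFFECTS), seed=seed, **noise)


def single_stain_effects(
    stain: str, effect: StainEffect, seed: int = 0, **noise
) -> EffectConfig:
    """Plant an effect in one stain only (all others null)."""
    if stain not in STAINS:
        raise KeyError(f"unknown stain {stain!r}; valid stains: {list(STAINS)}")
    return EffectConfig(effects={stain: effect}, seed=seed, **noise)


def with_baseline(config: EffectConfig, stain: str, **changes) -> EffectConfig:
    """Copy of ``config`` with one stain's baseline fields replaced."""
    baselines = dict(config.baselines)
    baselines[stain] = replace(baselines[stain], **changes)
    return replace(config, baselines=baselines)
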