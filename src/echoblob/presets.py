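"""Frozen simulation presets.

The ``paper`` preset was tuned once against the pipeline's own blob
metrics (see scripts/tune_preset.py) so that default seeded cohorts of
n = 34 + 34 approximate the calibration targets: healthy echointensity
~72 vs FM ~78.5, a clearly positive FM excess in total blob size, and
positive blob-size-vs-symptom correlations through the latent-severity
cross-link.  Frame-to-frame (within-subject) variation comes only from
fresh speckle and inclusion draws; no target for it exists, which is a
free modelling choice recorded here.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .synth import CovariateModel, CovariateSpec, GroupParams

#: default isotropic pixel spacing for synthetic data (mm); real cohorts
#: must supply spacings in the manifest.
DEFAULT_SPACING = (0.4, 0.4)
#: rows x cols of the synthetic frames at full (acquisition-like) scale
DEFAULT_SIZE = (125, 580)

_FM_COVS = {
    "age": CovariateSpec(45.0, 9.0, 0.0, 18, 60),
    "bmi": CovariateSpec(28.2, 4.5, 0.8, 16, 45),
    "weight": CovariateSpec(74.0, 11.0, 2.0, 45, 120),
    "pain_vas": CovariateSpec(7.4, 1.5, 1.0, 0, 10),
    "fatigue_vas": CovariateSpec(7.6, 1.4, 0.9, 0, 10),
    "sleep_vas": CovariateSpec(6.0, 2.0, 1.2, 0, 10),
    "csi_total": CovariateSpec(50.0, 16.0, 12.0, 0, 100),
    "bdi": CovariateSpec(18.0, 9.0, 6.0, 0, 63),
    "bai": CovariateSpec(21.0, 12.0, 8.0, 0, 63),
    "fiq": CovariateSpec(64.0, 15.0, 10.0, 0, 100),
    "wpi": CovariateSpec(15.0, 3.5, 2.0, 3, 19),
    "sss": CovariateSpec(9.5, 2.5, 1.5, 0, 12),
    "complaint_months": CovariateSpec(96.0, 80.0, 35.0, 1, 360),
    "diagnosis_months": CovariateSpec(45.0, 50.0, 18.0, 1, 240),
    "sf36_physical_functioning": CovariateSpec(48.0, 25.0, -15.0, 0, 100),
    "sf36_physical_role": CovariateSpec(25.0, 32.0, -18.0, 0, 100),
    "sf36_bodily_pain": CovariateSpec(35.0, 20.0, -12.0, 0, 100),
    "sf36_general_health": CovariateSpec(30.0, 18.0, -10.0, 0, 100),
    "sf36_vitality": CovariateSpec(30.0, 20.0, -12.0, 0, 100),
    "sf36_social_functioning": CovariateSpec(48.0, 25.0, -14.0, 0, 100),
    "sf36_emotional_role": CovariateSpec(30.0, 35.0, -18.0, 0, 100),
    "sf36_mental_health": CovariateSpec(45.0, 20.0, -12.0, 0, 100),
}

_HEALTHY_COVS = {
    "age": CovariateSpec(40.0, 9.0, 0.0, 18, 60),
    "bmi": CovariateSpec(25.8, 4.0, 0.0, 16, 45),
    "weight": CovariateSpec(68.0, 10.0, 0.0, 45, 120),
    "pain_vas": CovariateSpec(1.2, 1.2, 0.0, 0, 10),
    "fatigue_vas": CovariateSpec(2.0, 1.5, 0.0, 0, 10),
    "sleep_vas": CovariateSpec(1.5, 1.5, 0.0, 0, 10),
    "csi_total": CovariateSpec(27.0, 10.0, 0.0, 0, 100),
    "bdi": CovariateSpec(7.0, 4.0, 0.0, 0, 63),
    "bai": CovariateSpec(9.0, 5.0, 0.0, 0, 63),
    "sf36_physical_functioning": CovariateSpec(90.0, 10.0, 0.0, 0, 100),
    "sf36_physical_role": CovariateSpec(85.0, 25.0, 0.0, 0, 100),
    "sf36_bodily_pain": CovariateSpec(75.0, 15.0, 0.0, 0, 100),
    "sf36_general_health": CovariateSpec(68.0, 15.0, 0.0, 0, 100),
    "sf36_vitality": CovariateSpec(55.0, 15.0, 0.0, 0, 100),
    "sf36_social_functioning": CovariateSpec(80.0, 15.0, 0.0, 0, 100),
    "sf36_emotional_role": CovariateSpec(85.0, 25.0, 0.0, 0, 100),
    "sf36_mental_health": CovariateSpec(65.0, 12.0, 0.0, 0, 100),
}

PAPER_PRESET = {
    "healthy": GroupParams(
        mean_echointensity_target=71.3,
        inclusion_rate=0.25,
        inclusion_brightness_gain=2.2,
        between_subject_sd=8.0,
    ),
    "fm": GroupParams(
        mean_echointensity_target=75.0,
        inclusion_rate=1.0,
        inclusion_brightness_gain=2.8,
        between_subject_sd=8.0,
    ),
    "covariates": CovariateModel(
        fm=_FM_COVS,
        healthy=_HEALTHY_COVS,
        severity_inclusion_coeff=0.6,
        severity_echo_coeff=4.0,
        drug_classes=("none", "duloxetine", "duloxetine+pregabalin", "pregabalin", "amitriptyline"),
        drug_probs=(0.56, 0.235, 0.088, 0.088, 0.029),
    ),
}

PRESETS = {"paper": PAPER_PRESET}


def get_preset(name: str) -> dict:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def preset_to_json(preset: dict, path: str | Path) -> None:
    """Dump a preset to JSON (GroupParams / CovariateModel flattened)."""
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(type(obj))

    Path(path).write_text(json.dumps(preset, default=enc, indent=2))
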