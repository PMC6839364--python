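"""Loaders for the packaged reference tables.

The package ships, as plain TSV/YAML under ``cbctrisk/data``:

* the cohort-mean organ dose table for the two patient cohorts (lung and
  liver cancer) under the three acquisition modes (``thorax``, ``pelvis``,
  ``fourd``), with organ volumes;
* the per-organ BEIR VII EAR parameters (with the other-solid-cancer values
  marked as such);
* the published cohort effective doses and EAR tables, used as cross-check
  references by the test-suite and reporting fixture mode;
* ICRP-103 tissue weighting schemes (full, and the contoured-organ subset);
* the shipped acquisition protocols;
* the two cohorts' patient characteristics (sex, height, weight, BMI).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .risk import BEIRParameterSet, OrganDoseTable, TissueWeightingScheme

__all__ = [
    "data_path",
    "load_organ_dose_frame",
    "load_organ_doses",
    "load_beir_parameters",
    "load_weighting_scheme",
    "load_reference_effective_doses",
    "load_reference_ear",
    "load_patient_characteristics",
]

COHORTS = ("lung", "liver")
MODES = ("thorax", "pelvis", "fourd")


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("cbctrisk.data") / name)


def load_organ_dose_frame() -> pd.DataFrame:
    """Long-format cohort-mean organ doses for every cohort and mode."""
    return pd.read_csv(data_path("organ_doses.tsv"), sep="\t")


def load_organ_doses(cohort: str, mode: str) -> OrganDoseTable:
    """Cohort-mean organ dose table for one cohort and acquisition mode."""
    if cohort not in COHORTS:
        raise ValueError(f"cohort must be one of {COHORTS}, got {cohort!r}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    frame = load_organ_dose_frame()
    sel = frame[(frame["cohort"] == cohort) & (frame["mode"] == mode)]
    return OrganDoseTable(
        sel[["organ_id", "mean_dose_mGy", "volume_cm3"]].reset_index(drop=True)
    )


def load_beir_parameters() -> BEIRParameterSet:
    """Packaged per-organ BEIR VII EAR parameters (A0 = 60 y)."""
    return BEIRParameterSet.read(data_path("beir_parameters.tsv"))


def load_weighting_scheme(scheme: str = "study_subset") -> TissueWeightingScheme:
    """Packaged ICRP-103 weighting scheme (``full`` or ``study_subset``)."""
    return TissueWeightingScheme.from_yaml(data_path("icrp103_weights.yaml"), scheme)


def load_reference_effective_doses() -> pd.DataFrame:
    """Published cohort effective doses (mSv) per cohort and mode."""
    return pd.read_csv(data_path("reference_effective_dose.tsv"), sep="\t")


def load_reference_ear() -> pd.DataFrame:
    """Published EAR table (cases per 10^6 person-years; e=30 y, A=70 y)."""
    return pd.read_csv(data_path("reference_ear.tsv"), sep="\t")


def load_patient_characteristics(cohort: str | None = None) -> pd.DataFrame:
    """Patient characteristics of the two cohorts (height/weight rows with
    missing measurements keep NaN)."""
    frame = pd.read_csv(data_path("patients.tsv"), sep="\t")
    if cohort is not None:
        frame = frame[frame["cohort"] == cohort].reset_index(drop=True)
    return frame
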