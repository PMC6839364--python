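"""Equivalent dose, ICRP-103 effective dose, and BEIR VII excess absolute risk.

This module turns per-organ mean absorbed doses (mGy) into

* equivalent doses ``H_T = w_R * D_T`` (mSv; ``w_R = 1`` for photons),
* the effective dose ``E = sum_T w_T H_T`` with the ICRP-103 remainder rule
  (the remainder tissues share a collective weight of 0.12 applied to their
  arithmetic mean dose over the 13 designated remainder organs), and
* the BEIR VII excess absolute risk (EAR) of radiation-induced cancer
  incidence,

      EAR = beta_{M/F} * D * exp(gamma * (e - 30) / 10) * (A / A0)^eta

  with ``D`` in Gy, ``e`` the age at exposure, ``A`` the attained age and
  ``A0 = 60`` the reference attained age.  ``beta`` is tabulated per organ and
  sex in units of cases per 10^4 person-years per Gy; results are reported in
  cases per 10^6 person-years.

Organ-dose tables live in :class:`OrganDoseTable` (a thin pandas wrapper),
weighting schemes in :class:`TissueWeightingScheme`, and the per-organ EAR
parameters in :class:`BEIRParameterSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ORGAN_REGISTRY",
    "OrganDoseTable",
    "TissueWeightingScheme",
    "BEIRParameters",
    "BEIRParameterSet",
    "EARQuery",
    "EARResult",
    "equivalent_dose",
    "effective_dose",
    "excess_absolute_risk",
    "ear_time_series",
]

#: Controlled vocabulary of organ identifiers: the 15 contoured
#: thoraco-abdominal organs plus the additional ICRP-103 tissues needed for
#: the full weighting scheme.  Identifiers starting with ``other`` are also
#: accepted in dose tables (unweighted bookkeeping entries).
ORGAN_REGISTRY = frozenset(
    {
        # contoured in the study
        "lung",
        "stomach",
        "bone_marrow",
        "esophagus",
        "liver",
        "thyroid",
        "bone_surface",
        "skin",
        "adrenal_glands",
        "gallbladder",
        "heart",
        "intestine",
        "kidney",
        "pancreas",
        "spleen",
        # remaining ICRP-103 tissues
        "gonads",
        "colon",
        "breast",
        "bladder",
        "brain",
        "salivary_glands",
        "extrathoracic_region",
        "lymphatic_nodes",
        "muscle",
        "oral_mucosa",
        "prostate_uterus",
        "small_intestine",
        "thymus",
    }
)


def _check_organ_id(organ_id: str) -> str:
    if organ_id not in ORGAN_REGISTRY and not organ_id.startswith("other"):
        raise ValueError(
            f"unknown organ_id {organ_id!r}; expected one of the organ "
            f"registry or an 'other*' entry"
        )
    return organ_id


class OrganDoseTable:
    """Per-organ mean absorbed dose table (mGy), optionally with volumes (cm^3).

    Parameters
    ----------
    frame:
        DataFrame with columns ``organ_id`` and ``mean_dose_mGy`` and
        optionally ``volume_cm3``.  Organ ids must be unique, registry-valid,
        and doses non-negative.
    """

    REQUIRED = ("organ_id", "mean_dose_mGy")

    def __init__(self, frame: pd.DataFrame):
        frame = pd.DataFrame(frame).reset_index(drop=True)
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"organ dose table lacks column {col!r}")
        if frame["organ_id"].duplicated().any():
            dupes = frame.loc[frame["organ_id"].duplicated(), "organ_id"].tolist()
            raise ValueError(f"duplicate organ_id entries: {dupes}")
        for organ in frame["organ_id"]:
            _check_organ_id(organ)
        doses = frame["mean_dose_mGy"].to_numpy(dtype=float)
        if not np.all(np.isfinite(doses)) or (doses < 0).any():
            raise ValueError("mean_dose_mGy must be finite and >= 0")
        self._frame = frame

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, float] | tuple[str, float, float]]
    ) -> "OrganDoseTable":
        records = list(records)
        rows = []
        for rec in records:
            row = {"organ_id": rec[0], "mean_dose_mGy": float(rec[1])}
            if len(rec) > 2:
                row["volume_cm3"] = float(rec[2])
            rows.append(row)
        cols = ["organ_id", "mean_dose_mGy"]
        if any(len(r) > 2 for r in records):
            cols.append("volume_cm3")
        return cls(pd.DataFrame(rows, columns=cols))

    @classmethod
    def from_mapping(cls, doses: Mapping[str, float]) -> "OrganDoseTable":
        return cls(
            pd.DataFrame(
                {"organ_id": list(doses), "mean_dose_mGy": list(doses.values())}
            )
        )

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "OrganDoseTable":
        return cls(pd.read_csv(path, sep=sep))

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self._frame.to_csv(path, sep=sep, index=False)

    # -- access ------------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def organs(self) -> list[str]:
        return self._frame["organ_id"].tolist()

    def dose(self, organ_id: str) -> float:
        sel = self._frame.loc[self._frame["organ_id"] == organ_id, "mean_dose_mGy"]
        if sel.empty:
            raise KeyError(organ_id)
        return float(sel.iloc[0])

    def to_mapping(self) -> dict[str, float]:
        return dict(
            zip(self._frame["organ_id"], self._frame["mean_dose_mGy"].astype(float))
        )

    def scaled(self, factor: float) -> "OrganDoseTable":
        """Return a new table with every dose multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        frame = self._frame.copy()
        frame["mean_dose_mGy"] = frame["mean_dose_mGy"] * factor
        return OrganDoseTable(frame)

    def subset(self, organs: Sequence[str]) -> "OrganDoseTable":
        frame = self._frame[self._frame["organ_id"].isin(organs)]
        return OrganDoseTable(frame)

    def __len__(self) -> int:
        return len(self._frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OrganDoseTable({len(self)} organs)"


@dataclass(frozen=True)
class TissueWeightingScheme:
    """ICRP-103 tissue weighting factors with the remainder-organ rule.

    ``explicit_weights`` maps organ ids to their individual ``w_T``; organs in
    ``remainder_organs`` share ``remainder_weight`` applied to their arithmetic
    mean dose over ``remainder_divisor`` organs.  The divisor stays at the full
    ICRP count (13) even when fewer remainder organs were measured: unmeasured
    remainder organs are treated as receiving zero dose.
    """

    explicit_weights: Mapping[str, float]
    remainder_organs: tuple[str, ...]
    remainder_weight: float = 0.12
    remainder_divisor: int = 13
    radiation_weight: float = 1.0

    def __post_init__(self):
        for organ, w in self.explicit_weights.items():
            _check_organ_id(organ)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight for {organ!r} outside [0, 1]: {w}")
        if not 0.0 <= self.remainder_weight <= 1.0:
            raise ValueError("remainder_weight outside [0, 1]")
        if self.remainder_divisor < len(self.remainder_organs):
            raise ValueError(
                "remainder_divisor smaller than the number of remainder organs"
            )
        overlap = set(self.explicit_weights) & set(self.remainder_organs)
        if overlap:
            raise ValueError(f"organs both explicit and remainder: {sorted(overlap)}")

    @property
    def total_weight(self) -> float:
        return float(sum(self.explicit_weights.values())) + self.remainder_weight

    @classmethod
    def _from_config_dict(cls, cfg: Mapping, radiation_weight: float = 1.0):
        return cls(
            explicit_weights=dict(cfg["explicit_weights"]),
            remainder_organs=tuple(cfg["remainder_organs"]),
            remainder_weight=float(cfg["remainder_weight"]),
            remainder_divisor=int(cfg["remainder_divisor"]),
            radiation_weight=radiation_weight,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, scheme: str = "study_subset"):
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls._from_config_dict(
            cfg[scheme], radiation_weight=float(cfg.get("radiation_weight_photon", 1.0))
        )

    @classmethod
    def icrp103_full(cls) -> "TissueWeightingScheme":
        """The complete ICRP-103 scheme (weights sum to 1.0)."""
        from . import datasets

        return datasets.load_weighting_scheme("full")

    @classmethod
    def study_subset(cls) -> "TissueWeightingScheme":
        """The scheme for the 15 contoured organs (8 explicit + 7 remainder)."""
        from . import datasets

        return datasets.load_weighting_scheme("study_subset")


def equivalent_dose(mean_dose: float | np.ndarray, radiation_weight: float = 1.0):
    """Equivalent dose ``H_T = w_R * D_T`` (mSv for ``D_T`` in mGy).

    For photons ``w_R = 1.0`` and the operation relabels mGy as mSv.
    """
    dose = np.asarray(mean_dose, dtype=float)
    if (dose < 0).any():
        raise ValueError("mean dose must be >= 0")
    out = dose * float(radiation_weight)
    return float(out) if np.isscalar(mean_dose) or out.ndim == 0 else out


def effective_dose(doses: OrganDoseTable, scheme: TissueWeightingScheme) -> float:
    """Effective dose ``E`` (mSv) from an organ mean-dose table (mGy).

    ``E = sum_explicit w_T H_T
         + remainder_weight * sum_remainder H_T / remainder_divisor``
    where ``H_T`` is the equivalent dose.  Organs of the scheme that are
    absent from the table contribute zero; organs in the table that the
    scheme does not know are an error.
    """
    explicit = 0.0
    remainder_sum = 0.0
    remainder = set(scheme.remainder_organs)
    for organ, dose_mgy in doses.to_mapping().items():
        h_t = equivalent_dose(dose_mgy, scheme.radiation_weight)
        if organ in scheme.explicit_weights:
            explicit += scheme.explicit_weights[organ] * h_t
        elif organ in remainder:
            remainder_sum += h_t
        else:
            raise ValueError(
                f"organ {organ!r} is neither an explicitly weighted tissue nor "
                f"a remainder organ of this weighting scheme"
            )
    return explicit + scheme.remainder_weight * remainder_sum / scheme.remainder_divisor


@dataclass(frozen=True)
class BEIRParameters:
    """One organ's EAR parameter tuple.

    ``beta_m``/``beta_f`` are in cases per 10^4 person-years per Gy; ``gamma``
    is per decade of exposure age; ``eta`` is the attained-age power.
    """

    beta_m: float
    beta_f: float
    gamma: float
    eta: float
    source: str = "specific"

    def __post_init__(self):
        if self.beta_m < 0 or self.beta_f < 0:
            raise ValueError("beta must be >= 0")

    def beta(self, sex: str) -> float:
        if sex == "male":
            return self.beta_m
        if sex == "female":
            return self.beta_f
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


#: The EAR parameter tuple applied to organs without organ-specific incidence
#: parameters ("other solid cancer" values).
OTHER_SOLID = BEIRParameters(beta_m=5.1, beta_f=4.2, gamma=-0.39, eta=1.9,
                             source="other_solid")


@dataclass(frozen=True)
class BEIRParameterSet:
    """Per-organ EAR parameters with an other-solid-cancer fallback.

    Every organ resolves to exactly one tuple: its own entry if present,
    otherwise ``other_solid_fallback``.  ``reference_attained_age`` is the
    age ``A0`` at which the attained-age modifier equals one.
    """

    parameters: Mapping[str, BEIRParameters]
    other_solid_fallback: BEIRParameters = OTHER_SOLID
    reference_attained_age: float = 60.0

    def __post_init__(self):
        if self.reference_attained_age <= 0:
            raise ValueError("reference attained age must be > 0")
        for organ in self.parameters:
            _check_organ_id(organ)

    @property
    def organs(self) -> list[str]:
        """Organs with a tabulated (non-fallback-by-default) entry."""
        return list(self.parameters)

    def get(self, organ_id: str) -> BEIRParameters:
        _check_organ_id(organ_id)
        return self.parameters.get(organ_id, self.other_solid_fallback)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, a0: float = 60.0) -> "BEIRParameterSet":
        params = {
            row.organ_id: BEIRParameters(
                beta_m=float(row.beta_m),
                beta_f=float(row.beta_f),
                gamma=float(row.gamma),
                eta=float(row.eta),
                source=getattr(row, "source", "specific"),
            )
            for row in frame.itertuples()
        }
        return cls(parameters=params, reference_attained_age=a0)

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t", a0: float = 60.0):
        return cls.from_frame(pd.read_csv(path, sep=sep), a0=a0)

    @classmethod
    def default(cls) -> "BEIRParameterSet":
        from . import datasets

        return datasets.load_beir_parameters()


@dataclass(frozen=True)
class EARQuery:
    """Who/when of an EAR evaluation: organ, sex, exposure and attained age."""

    organ_id: str
    sex: str
    exposure_age: float
    attained_age: float

    def __post_init__(self):
        _check_organ_id(self.organ_id)
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.exposure_age < 0:
            raise ValueError("exposure age must be >= 0")
        if self.attained_age < self.exposure_age:
            raise ValueError("attained age must be >= exposure age")


@dataclass(frozen=True)
class EARResult:
    """EAR in cases per 10^6 person-years for one organ/sex/age combination."""

    organ_id: str
    sex: str
    value: float
    exposure_age: float
    attained_age: float

    @property
    def time_since_exposure(self) -> float:
        return self.attained_age - self.exposure_age


def _ear_formula(
    dose_gy: float, beta: float, gamma: float, eta: float, a0: float,
    exposure_age: float, attained_age: float,
) -> float:
    # beta is per 10^4 person-years per Gy; report per 10^6 person-years.
    modifier = math.exp(gamma * (exposure_age - 30.0) / 10.0)
    return 100.0 * beta * dose_gy * modifier * (attained_age / a0) ** eta


def excess_absolute_risk(
    dose_msv: float, params: BEIRParameterSet, query: EARQuery
) -> EARResult:
    """BEIR VII excess absolute risk for one organ.

    ``dose_msv`` is the organ equivalent dose in mSv (converted internally to
    Gy); the exposure-age modifier ``exp(gamma (e - 30)/10)`` is applied as
    written for all ``e`` without clamping ``e`` at 30.  Returns cases per
    10^6 person-years.
    """
    if dose_msv < 0:
        raise ValueError("dose must be >= 0")
    p = params.get(query.organ_id)
    value = _ear_formula(
        dose_msv / 1000.0,
        p.beta(query.sex),
        p.gamma,
        p.eta,
        params.reference_attained_age,
        query.exposure_age,
        query.attained_age,
    )
    return EARResult(
        organ_id=query.organ_id,
        sex=query.sex,
        value=value,
        exposure_age=query.exposure_age,
        attained_age=query.attained_age,
    )


def ear_time_series(
    doses: OrganDoseTable,
    params: BEIRParameterSet,
    sex: str,
    attained_age: float,
    exposure_ages: Sequence[float],
    organs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """EAR per organ per exposure age at a fixed attained age.

    Returns a tidy DataFrame with one row per (organ, exposure age) and a
    ``time_since_exposure`` column (= attained age - exposure age).  By
    default only organs present in both the dose table and the tabulated
    parameter set are evaluated; pass ``organs`` to override.
    """
    if len(exposure_ages) == 0:
        raise ValueError("exposure_ages must be non-empty")
    for e in exposure_ages:
        if e > attained_age:
            raise ValueError(f"exposure age {e} exceeds attained age {attained_age}")
    if organs is None:
        tabulated = set(params.organs)
        organs = [o for o in doses.organs if o in tabulated]
    rows = []
    for organ in organs:
        dose = doses.dose(organ)
        for e in exposure_ages:
            res = excess_absolute_risk(
                dose, params, EARQuery(organ, sex, float(e), float(attained_age))
            )
            rows.append(
                {
                    "organ_id": organ,
                    "sex": sex,
                    "exposure_age": float(e),
                    "attained_age": float(attained_age),
                    "time_since_exposure": float(attained_age) - float(e),
                    "ear_per_1e6_py": res.value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "organ_id",
            "sex",
            "exposure_age",
            "attained_age",
            "time_since_exposure",
            "ear_per_1e6_py",
        ],
    )
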