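"""Synthetic body phantoms, a rotational kV dose simulator, and cohort sampling.

This module replaces two things a dose-to-risk study would normally take from
the clinic: planning-CT-derived patient anatomy and Monte Carlo dose
transport.

* :func:`generate_phantom` voxelises an elliptic-cylinder trunk with
  ellipsoidal organs into a four-material phantom plus organ masks.
* :func:`simulate_rotational_dose` is a primary-photon analytic model: for
  each gantry angle it casts parallel rays through the field aperture,
  attenuates the fluence exponentially through the traversed materials
  (with an inverse-square factor along the beam axis), and deposits dose
  proportional to local fluence times the material's mass-absorption weight.
  A half-bowtie transmission profile (monotone across the lateral field
  axis) and an anode heel gradient (monotone along the patient axis)
  reproduce the beam asymmetries of a linac-mounted kV imager.  The model's
  contract is linearity in mAs, geometry and asymmetry — not dosimetric
  accuracy: there is no scatter, no buildup, no spectrum.
* :func:`sample_cohort` draws a reproducible synthetic patient cohort whose
  sex, height and body-mass-index distributions emulate the lung and liver
  radiotherapy cohorts the defaults were derived from, spanning all three
  WHO BMI classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .acquisition import AcquisitionProtocol
from .grids import (
    MATERIAL_DENSITY_G_CM3,
    MATERIALS,
    DoseGrid,
    MaterialPhantom,
    StructureSet,
)

__all__ = [
    "OrganSpec",
    "PhantomSpec",
    "BeamModel",
    "CohortSpec",
    "Patient",
    "BMIResult",
    "generate_phantom",
    "simulate_rotational_dose",
    "sample_cohort",
    "bmi_class",
    "default_organ_layout",
]


# ---------------------------------------------------------------------------
# phantom specification and voxelisation

@dataclass(frozen=True)
class OrganSpec:
    """One ellipsoidal organ component: centre/radii in cm, body-centred
    coordinates (+x right, +y posterior, +z superior).  Several components
    may share an ``organ_id`` (e.g. two lungs) and merge into one mask."""

    organ_id: str
    center_cm: tuple[float, float, float]
    radii_cm: tuple[float, float, float]
    material: str = "tissue"

    def __post_init__(self):
        if any(r <= 0 for r in self.radii_cm):
            raise ValueError(f"organ {self.organ_id!r} radii must be > 0")
        if self.material not in MATERIALS:
            raise ValueError(f"unknown material {self.material!r}")

    @property
    def analytic_volume_cm3(self) -> float:
        a, b, c = self.radii_cm
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class PhantomSpec:
    """Elliptic-cylinder trunk (lateral radius ``body_a_cm``, antero-posterior
    radius ``body_b_cm``, length ``length_cm``) with a list of organs."""

    body_a_cm: float
    body_b_cm: float
    length_cm: float
    organs: tuple[OrganSpec, ...] = ()
    sex: str = "female"
    height_cm: float = 160.0
    weight_kg: float = 55.0
    include_skin: bool = True

    def __post_init__(self):
        if min(self.body_a_cm, self.body_b_cm, self.length_cm) <= 0:
            raise ValueError("body radii and length must be > 0")


def default_organ_layout(
    body_a_cm: float, body_b_cm: float, length_cm: float,
    organ_scale: float = 1.0,
) -> tuple[OrganSpec, ...]:
    """A thoraco-abdominal organ layout scaled to the trunk dimensions.

    Positions and radii are fractions of the body half-axes, chosen so every
    organ sits inside the trunk; ``organ_scale`` scales all organ radii to
    sweep organ-volume ranges.
    """
    a, b, L = body_a_cm, body_b_cm, length_cm
    s = organ_scale

    def organ(organ_id, cx, cy, cz, rx, ry, rz, material="tissue"):
        return OrganSpec(
            organ_id,
            (cx * a, cy * b, cz * L),
            (s * rx * a, s * ry * b, s * rz * L),
            material,
        )

    return (
        organ("lung", -0.45, -0.15, 0.15, 0.28, 0.50, 0.20, "lung"),
        organ("lung", +0.45, -0.15, 0.15, 0.28, 0.50, 0.20, "lung"),
        organ("heart", -0.05, -0.15, 0.08, 0.20, 0.25, 0.10),
        organ("esophagus", 0.0, 0.20, 0.10, 0.04, 0.06, 0.25),
        organ("thyroid", 0.0, -0.05, 0.42, 0.06, 0.06, 0.04),
        organ("bone_marrow", 0.0, 0.60, 0.0, 0.10, 0.12, 0.45, "bone"),
        organ("liver", +0.35, 0.0, -0.10, 0.30, 0.40, 0.15),
        organ("stomach", -0.30, 0.05, -0.12, 0.18, 0.22, 0.08),
        organ("spleen", -0.42, 0.25, -0.14, 0.10, 0.15, 0.07),
        organ("pancreas", -0.08, 0.18, -0.20, 0.15, 0.08, 0.05),
        organ("gallbladder", +0.15, 0.15, -0.16, 0.06, 0.08, 0.04),
        organ("kidney", -0.28, 0.45, -0.28, 0.09, 0.12, 0.09),
        organ("kidney", +0.28, 0.45, -0.28, 0.09, 0.12, 0.09),
        organ("adrenal_glands", -0.20, 0.40, -0.20, 0.04, 0.05, 0.03),
        organ("adrenal_glands", +0.20, 0.40, -0.20, 0.04, 0.05, 0.03),
        organ("intestine", 0.0, 0.10, -0.38, 0.40, 0.40, 0.10),
    )


def generate_phantom(
    spec: PhantomSpec, voxel_size_mm: float = 2.5, margin_mm: float = 10.0
) -> tuple[MaterialPhantom, StructureSet]:
    """Voxelise a phantom spec into a material phantom and organ masks.

    Organ masks record geometry (they may overlap); material labels are
    painted body-first then organ-by-organ in list order.  An organ whose
    ellipsoid sticks out of the trunk raises.  If ``include_skin`` is set, a
    one-voxel surface shell of the trunk becomes the ``skin`` mask.
    """
    v = float(voxel_size_mm)
    a_mm, b_mm = spec.body_a_cm * 10.0, spec.body_b_cm * 10.0
    half_l_mm = spec.length_cm * 10.0 / 2.0

    def n_half(extent_mm):
        return int(math.ceil((extent_mm + margin_mm) / v))

    nx, ny, nz = (2 * n_half(a_mm) + 1, 2 * n_half(b_mm) + 1,
                  2 * n_half(half_l_mm) + 1)
    x = (np.arange(nx) - (nx - 1) / 2) * v
    y = (np.arange(ny) - (ny - 1) / 2) * v
    z = (np.arange(nz) - (nz - 1) / 2) * v
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    body = ((X / a_mm) ** 2 + (Y / b_mm) ** 2 <= 1.0) & (np.abs(Z) <= half_l_mm)
    labels = np.where(body, MATERIALS.index("tissue"), MATERIALS.index("air")).astype(
        np.uint8
    )

    masks: dict[str, np.ndarray] = {}
    for organ in spec.organs:
        cx, cy, cz = (c * 10.0 for c in organ.center_cm)
        rx, ry, rz = (r * 10.0 for r in organ.radii_cm)
        mask = (
            ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2
        ) <= 1.0
        if not mask.any():
            raise ValueError(
                f"organ {organ.organ_id!r} is smaller than one voxel at "
                f"{v} mm resolution"
            )
        if (mask & ~body).any():
            raise ValueError(f"organ {organ.organ_id!r} extends outside the body")
        labels[mask] = MATERIALS.index(organ.material)
        if organ.organ_id in masks:
            masks[organ.organ_id] |= mask
        else:
            masks[organ.organ_id] = mask

    if spec.include_skin:
        shell = body & ~ndimage.binary_erosion(body)
        masks.setdefault("skin", shell)

    density = np.empty(labels.shape, dtype=float)
    for idx, mat in enumerate(MATERIALS):
        density[labels == idx] = MATERIAL_DENSITY_G_CM3[mat]
    phantom = MaterialPhantom(labels, density, voxel_size_mm=(v, v, v))
    structures = StructureSet(phantom.shape, masks)
    return phantom, structures


# ---------------------------------------------------------------------------
# beam model and rotational dose simulation

@dataclass(frozen=True)
class BeamModel:
    """Geometry and transmission model of the kV imaging beam.

    The field at the isocenter is 26.5 x 19.8 cm^2 with asymmetric lateral
    offsets (x1 = 23.9 cm on the +x side, x2 = 2.6 cm on the -x side; the
    half-fan geometry that lets a full rotation cover the body) and
    symmetric longitudinal offsets (y1 = y2 = 9.9 cm along the patient
    axis).  ``bowtie_strength`` sets the monotone lateral transmission drop
    of the half-bowtie filter across the field; ``heel_strength`` the
    monotone longitudinal drop from the anode heel effect.  Setting either
    to zero disables that asymmetry.  ``mu_per_mm`` are effective linear
    attenuation coefficients per material (configuration defaults for a
    ~125 kV beam, not measured values); ``reference_dose_rate_mgy_per_mas``
    converts the normalised deposition to mGy per mAs.
    """

    sad_cm: float = 100.0
    field_x1_cm: float = 23.9
    field_x2_cm: float = 2.6
    field_y1_cm: float = 9.9
    field_y2_cm: float = 9.9
    bowtie_strength: float = 0.4
    heel_strength: float = 0.15
    mu_per_mm: tuple[float, float, float, float] = (2.5e-5, 0.0055, 0.021, 0.048)
    reference_dose_rate_mgy_per_mas: float = 5.0

    def __post_init__(self):
        if any(m <= 0 for m in self.mu_per_mm):
            raise ValueError("attenuation coefficients must be > 0")
        if not 0.0 <= self.bowtie_strength < 1.0:
            raise ValueError("bowtie_strength must be in [0, 1)")
        if not 0.0 <= self.heel_strength < 1.0:
            raise ValueError("heel_strength must be in [0, 1)")

    def mu_volume(self, phantom: MaterialPhantom) -> np.ndarray:
        lut = np.asarray(self.mu_per_mm, dtype=float)
        return lut[phantom.labels]

    def lateral_transmission(self, x_mm: np.ndarray) -> np.ndarray:
        """Half-bowtie transmission across the beam-frame lateral axis:
        monotone decrease from the thin (-x) to the thick (+x) side,
        zero outside the aperture."""
        lo, hi = -self.field_x2_cm * 10.0, self.field_x1_cm * 10.0
        frac = np.clip((x_mm - lo) / (hi - lo), 0.0, 1.0)
        trans = 1.0 - self.bowtie_strength * frac
        trans[(x_mm < lo) | (x_mm > hi)] = 0.0
        return trans

    def longitudinal_transmission(self, z_mm: np.ndarray) -> np.ndarray:
        """Anode heel transmission along the patient axis: monotone decrease
        toward +z (the anode end), zero outside the aperture."""
        lo, hi = -self.field_y1_cm * 10.0, self.field_y2_cm * 10.0
        frac = np.clip((z_mm - lo) / (hi - lo), 0.0, 1.0)
        trans = 1.0 - self.heel_strength * frac
        trans[(z_mm < lo) | (z_mm > hi)] = 0.0
        return trans


def simulate_rotational_dose(
    phantom: MaterialPhantom,
    beam: BeamModel,
    protocol: AcquisitionProtocol,
    angles_deg: Sequence[float] | None = None,
) -> DoseGrid:
    """Primary-photon analytic dose for a rotational kV acquisition.

    For each gantry angle (0 deg = source anterior, beam travelling +y) the
    phantom is resampled into the beam frame, the ray path integral of the
    attenuation coefficient is accumulated along the beam axis, and dose is
    deposited as ``transmission * invsq * exp(-path) * mu/rho``.  The
    per-angle contributions share the protocol's total mAs equally; the
    output is normalised by the beam's reference dose rate and by
    ``N * total_mas`` of the protocol (deterministic, and exactly linear in
    both).
    """
    if angles_deg is None:
        angles_deg = np.arange(
            protocol.gantry_start_deg, protocol.gantry_stop_deg,
            protocol.gantry_step_deg,
        )
    angles = np.asarray(list(angles_deg), dtype=float)
    if angles.size == 0:
        raise ValueError("angle list must be non-empty")
    if (angles < -180.0).any() or (angles > 180.0).any():
        raise ValueError("gantry angles must lie in [-180, 180] degrees")

    vx, vy, vz = phantom.voxel_size_mm
    nx, ny, nz = phantom.shape
    mu = beam.mu_volume(phantom)
    dep_weight = mu / phantom.density_g_cm3  # ~ mass energy-absorption weight

    x_mm = (np.arange(nx) - (nx - 1) / 2) * vx
    z_mm = (np.arange(nz) - (nz - 1) / 2) * vz
    y_index = np.arange(ny) - (ny - 1) / 2
    sad_mm = beam.sad_cm * 10.0
    # distance from source along the beam axis; isocenter at grid centre
    dist_mm = sad_mm + y_index * vy
    invsq = (sad_mm / dist_mm) ** 2

    trans_xz = np.outer(
        beam.lateral_transmission(x_mm), beam.longitudinal_transmission(z_mm)
    )  # (nx, nz), fixed in the beam frame
    fluence_shape = trans_xz[:, None, :] * invsq[None, :, None]

    mu_air = beam.mu_per_mm[MATERIALS.index("air")]
    dep_air = mu_air / MATERIAL_DENSITY_G_CM3["air"]
    accum = np.zeros(phantom.shape, dtype=float)
    for theta in angles:
        if theta == 0.0:
            mu_r, dep_r = mu, dep_weight
        else:
            mu_r = ndimage.rotate(mu, theta, axes=(0, 1), reshape=False,
                                  order=1, mode="constant", cval=mu_air)
            dep_r = ndimage.rotate(dep_weight, theta, axes=(0, 1), reshape=False,
                                   order=1, mode="constant", cval=dep_air)
            mu_r = np.clip(mu_r, 0.0, None)
            dep_r = np.clip(dep_r, 0.0, None)
        # path integral to the voxel centre (half credit for the own voxel)
        path = (np.cumsum(mu_r, axis=1) - 0.5 * mu_r) * vy
        deposition = fluence_shape * np.exp(-path) * dep_r
        if theta == 0.0:
            accum += deposition
        else:
            back = ndimage.rotate(deposition, -theta, axes=(0, 1), reshape=False,
                                  order=1, mode="constant", cval=0.0)
            accum += np.clip(back, 0.0, None)
    accum /= angles.size

    dose = (
        accum
        * beam.reference_dose_rate_mgy_per_mas
        * protocol.n_acquisitions
        * protocol.total_mas
    )
    return DoseGrid(
        dose,
        voxel_size_mm=phantom.voxel_size_mm,
        origin_mm=phantom.origin_mm,
        unit="mGy",
    )


# ---------------------------------------------------------------------------
# BMI and cohort sampling

class BMIResult(NamedTuple):
    value: float  # kg/m^2
    category: str  # underweight / normal / overweight


def bmi_class(height_cm: float, weight_kg: float) -> BMIResult:
    """BMI = weight / (height in m)^2 with the WHO class cut points
    (underweight < 18.50, normal 18.50-24.99, overweight >= 25.00 kg/m^2;
    each class floor is inclusive).

    The class is assigned at the one-decimal reporting precision of clinical
    BMI tables, so a patient whose BMI prints as 18.5 falls in the normal
    class even if the unrounded value is 18.4997.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be > 0")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    reported = round(bmi, 1)
    if reported < 18.50:
        category = "underweight"
    elif reported < 25.00:
        category = "normal"
    else:
        category = "overweight"
    return BMIResult(bmi, category)


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic-cohort sampling parameters.

    Heights are normal, truncated to ``height_range_cm``; BMI is sampled
    (normal, truncated) and weight derived as ``BMI * (height/100)^2`` so the
    joint height/weight distribution has a realistic BMI spread.  The seed is
    mandatory: sampling is fully reproducible.
    """

    n_patients: int = 15
    site: str = "lung"
    seed: int = 0
    female_fraction: float = 0.5
    height_mean_cm: float = 154.6
    height_sd_cm: float = 10.3
    height_range_cm: tuple[float, float] = (130.0, 185.0)
    bmi_mean: float = 21.6
    bmi_sd: float = 3.1
    bmi_range: tuple[float, float] = (14.0, 35.0)
    organ_scale: float = 1.0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.height_sd_cm < 0 or self.bmi_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.height_range_cm[0] <= 0 or self.height_range_cm[0] >= self.height_range_cm[1]:
            raise ValueError("height_range_cm must be an increasing positive range")
        if self.bmi_range[0] <= 0 or self.bmi_range[0] >= self.bmi_range[1]:
            raise ValueError("bmi_range must be an increasing positive range")

    @classmethod
    def for_site(cls, site: str, n_patients: int = 15, seed: int = 0, **overrides):
        """Defaults emulating the lung / liver radiotherapy cohorts."""
        presets = {
            "lung": dict(female_fraction=8 / 15, height_mean_cm=154.6,
                         height_sd_cm=10.3, bmi_mean=21.6, bmi_sd=3.1),
            "liver": dict(female_fraction=3 / 15, height_mean_cm=159.0,
                          height_sd_cm=7.7, bmi_mean=22.5, bmi_sd=4.3),
        }
        if site not in presets:
            raise ValueError(f"site must be 'lung' or 'liver', got {site!r}")
        kwargs = {**presets[site], **overrides}
        return cls(n_patients=n_patients, site=site, seed=seed, **kwargs)


@dataclass(frozen=True)
class Patient:
    patient_id: int
    sex: str
    height_cm: float
    weight_kg: float
    bmi: float
    bmi_category: str
    phantom: PhantomSpec


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate distribution outside truncation range")
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError(
        f"truncated normal ({mean}, {sd}) almost never falls in [{lo}, {hi}]"
    )


def body_radii_from_anthropometry(
    height_cm: float, weight_kg: float,
    trunk_volume_fraction: float = 0.45,
    trunk_length_fraction: float = 0.30,
    aspect_ratio: float = 1.5,
) -> tuple[float, float, float]:
    """Elliptic-trunk half-axes (cm) from height and weight.

    Body volume is weight at unit density; a fixed fraction sits in a trunk
    of length proportional to height, and the elliptic cross-section has a
    fixed lateral:antero-posterior aspect ratio.
    """
    volume_cm3 = weight_kg * 1000.0 * trunk_volume_fraction
    length_cm = height_cm * trunk_length_fraction
    area_cm2 = volume_cm3 / length_cm
    b = math.sqrt(area_cm2 / (math.pi * aspect_ratio))
    return aspect_ratio * b, b, length_cm


def sample_cohort(spec: CohortSpec) -> list[Patient]:
    """Draw a reproducible synthetic cohort with phantom specs attached."""
    rng = np.random.default_rng(spec.seed)
    patients = []
    for i in range(spec.n_patients):
        sex = "female" if rng.random() < spec.female_fraction else "male"
        height = _truncated_normal(
            rng, spec.height_mean_cm, spec.height_sd_cm, *spec.height_range_cm
        )
        bmi = _truncated_normal(rng, spec.bmi_mean, spec.bmi_sd, *spec.bmi_range)
        weight = bmi * (height / 100.0) ** 2
        a, b, length = body_radii_from_anthropometry(height, weight)
        phantom = PhantomSpec(
            body_a_cm=a,
            body_b_cm=b,
            length_cm=length,
            organs=default_organ_layout(a, b, length, spec.organ_scale),
            sex=sex,
            height_cm=height,
            weight_kg=weight,
        )
        result = bmi_class(height, weight)
        patients.append(
            Patient(
                patient_id=i + 1,
                sex=sex,
                height_cm=height,
                weight_kg=weight,
                bmi=result.value,
                bmi_category=result.category,
                phantom=phantom,
            )
        )
    return patients


def cohort_manifest(patients: Sequence[Patient], site: str = ""):
    """Cohort table mirroring the study's patient-characteristics layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "patient": [p.patient_id for p in patients],
            "sex": ["F" if p.sex == "female" else "M" for p in patients],
            "height_cm": [round(p.height_cm, 1) for p in patients],
            "weight_kg": [round(p.weight_kg, 1) for p in patients],
            "bmi": [round(p.bmi, 1) for p in patients],
            "bmi_category": [p.bmi_category for p in patients],
            "site": site or None,
        }
    )
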