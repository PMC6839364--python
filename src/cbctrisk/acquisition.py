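"""Beam-output calibration and acquisition-protocol dose arithmetic.

A Monte-Carlo (or synthetic) dose field comes out normalised per simulated
fluence unit; the conversion to an absolute patient dose is

    D_abs = D_MC * f_cal * N * A * T_acq * F * T_pulse

where ``f_cal`` is a measured calibration factor, ``N`` the number of CBCT
acquisitions and ``A * T_acq * F * T_pulse`` the protocol's total tube
current-time product (mAs) for a pulsed kV beam.  The calibration factor is
obtained from an ionisation-chamber measurement ``D_w`` and a matched
simulation ``D_MC`` at reference tube settings:

    f_cal = D_w / (D_MC * A_cal * T_cal)

The three shipped protocols (thorax and pelvis 3D-CBCT, 4D-CBCT) total
360, 1440 and 672 mAs per acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "BeamCalibration",
    "calibration_factor",
    "total_mas",
    "absolute_dose",
    "load_protocols",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Pulsed kV CBCT acquisition settings.

    Attributes
    ----------
    mode:
        ``thorax``, ``pelvis``, ``fourd`` or ``custom``.
    n_acquisitions:
        Number of CBCT acquisitions ``N``.
    tube_current_ma, acquisition_time_s, frame_rate_fps, pulse_duration_s:
        ``A`` (mA), ``T_acq`` (s), ``F`` (frames/s) and ``T_pulse`` (s per
        frame); their product is the total mAs per acquisition.
    tube_voltage_kv, gantry_*:
        Metadata describing the beam quality and the rotational sampling.
    """

    mode: str
    n_acquisitions: int
    tube_current_ma: float
    acquisition_time_s: float
    frame_rate_fps: float
    pulse_duration_s: float
    tube_voltage_kv: float = 125.0
    gantry_start_deg: float = -180.0
    gantry_stop_deg: float = 180.0
    gantry_step_deg: float = 2.0

    def __post_init__(self):
        if self.n_acquisitions < 1 or self.n_acquisitions != int(self.n_acquisitions):
            raise ValueError("n_acquisitions must be an integer >= 1")
        for name in (
            "tube_current_ma",
            "acquisition_time_s",
            "frame_rate_fps",
            "pulse_duration_s",
            "tube_voltage_kv",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def total_mas(self) -> float:
        """Total tube current-time product per acquisition (mAs)."""
        return (
            self.tube_current_ma
            * self.acquisition_time_s
            * self.frame_rate_fps
            * self.pulse_duration_s
        )

    def replace(self, **kwargs) -> "AcquisitionProtocol":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)

    # shipped protocols ----------------------------------------------------
    @classmethod
    def thorax(cls, **overrides) -> "AcquisitionProtocol":
        return load_protocols()["thorax"].replace(**overrides)

    @classmethod
    def pelvis(cls, **overrides) -> "AcquisitionProtocol":
        return load_protocols()["pelvis"].replace(**overrides)

    @classmethod
    def fourd(cls, **overrides) -> "AcquisitionProtocol":
        return load_protocols()["fourd"].replace(**overrides)


def load_protocols(path: str | Path | None = None) -> dict[str, AcquisitionProtocol]:
    """Load acquisition protocols from YAML (default: the packaged set)."""
    import yaml

    if path is None:
        path = Path(__file__).parent / "data" / "protocols.yaml"
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return {
        mode: AcquisitionProtocol(mode=mode, **params) for mode, params in cfg.items()
    }


def total_mas(protocol: AcquisitionProtocol) -> float:
    """Total mAs per acquisition: ``A * T_acq * F * T_pulse``."""
    return protocol.total_mas


@dataclass(frozen=True)
class BeamCalibration:
    """Conversion constant from simulated dose units to absolute dose.

    ``f_cal`` carries units of absolute dose per (simulated dose unit * mAs);
    its magnitude depends on the simulator's per-history normalisation, so it
    is carried as configuration rather than recomputed.  ``sim_unit`` tags
    the simulated-dose unit the factor applies to.
    """

    f_cal: float
    reference_current_ma: float = 257.0
    reference_time_s: float = 0.777
    reference_depth_cm: float = 2.0
    reference_ssd_cm: float = 100.0
    sim_unit: str = "per_history"

    def __post_init__(self):
        if self.f_cal <= 0:
            raise ValueError("f_cal must be > 0")


def calibration_factor(
    measured_dose: float,
    simulated_dose: float,
    reference_current_ma: float = 257.0,
    reference_time_s: float = 0.777,
    sim_unit: str = "per_history",
    **geometry,
) -> BeamCalibration:
    """Calibration factor ``f_cal = D_w / (D_MC * A_cal * T_cal)``.

    ``reference_time_s`` is in seconds (the reference exposure time of 777 ms
    enters as 0.777 s).
    """
    for name, value in (
        ("measured_dose", measured_dose),
        ("simulated_dose", simulated_dose),
        ("reference_current_ma", reference_current_ma),
        ("reference_time_s", reference_time_s),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be > 0")
    f_cal = measured_dose / (simulated_dose * reference_current_ma * reference_time_s)
    return BeamCalibration(
        f_cal=f_cal,
        reference_current_ma=reference_current_ma,
        reference_time_s=reference_time_s,
        sim_unit=sim_unit,
        **geometry,
    )


def absolute_dose(
    simulated_dose,
    calibration: BeamCalibration,
    protocol: AcquisitionProtocol,
    sim_unit: str | None = None,
):
    """Absolute dose ``D_abs = D_MC * f_cal * N * A * T_acq * F * T_pulse``.

    ``simulated_dose`` may be a scalar, an ndarray, or a
    :class:`~cbctrisk.grids.DoseGrid` (whose ``unit`` must match the
    calibration's ``sim_unit``); the output is in the calibration's absolute
    dose unit (mGy for the shipped configuration) and elementwise linear in
    every factor.
    """
    from .grids import DoseGrid  # local import to avoid a cycle

    factor = float(
        calibration.f_cal * protocol.n_acquisitions * protocol.total_mas
    )
    if isinstance(simulated_dose, DoseGrid):
        if simulated_dose.unit != calibration.sim_unit:
            raise ValueError(
                f"unit mismatch: grid carries {simulated_dose.unit!r} but the "
                f"calibration applies to {calibration.sim_unit!r}"
            )
        return simulated_dose.with_values(simulated_dose.values * factor, unit="mGy")
    if sim_unit is not None and sim_unit != calibration.sim_unit:
        raise ValueError(
            f"unit mismatch: dose given in {sim_unit!r} but the calibration "
            f"applies to {calibration.sim_unit!r}"
        )
    out = np.asarray(simulated_dose, dtype=float) * factor
    return float(out) if out.ndim == 0 else out
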