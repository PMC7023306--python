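"""Mobility <-> CCS conversion and linear TIMS calibration.

TIMS does not measure a drift time over a known length, so collision cross
sections are obtained by calibration: tune-mix ions with community-agreed
reference CCS values define a linear map from the raw instrument mobility
reading to inverse reduced mobility (1/K0), and 1/K0 is converted to CCS
with the Mason-Schamp relation

    Omega = (3 z e) / (16 N0) * sqrt(2 pi / (mu k_B T)) * (1 / K0)

where z is the charge number, e the elementary charge, N0 the gas number
density at standard conditions, mu the ion-gas reduced mass, k_B the
Boltzmann constant and T the gas temperature.  At fixed m/z, z and gas,
CCS is strictly proportional to 1/K0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ELEMENTARY_CHARGE",
    "BOLTZMANN",
    "LOSCHMIDT",
    "DALTON",
    "MobilityPhysicsContext",
    "ReferenceCalibrantTable",
    "CalibrationModel",
    "CalibratedMobility",
    "CalibrationError",
    "ccs_from_inverse_k0",
    "inverse_k0_from_ccs",
    "fit_calibration",
    "apply_calibration",
    "dual_reference_ccs",
]

ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
#: Gas number density at 273.15 K and 101.325 kPa (Loschmidt constant), m^-3.
LOSCHMIDT = 2.686780111e25
DALTON = 1.66053906660e-27  # kg

# 1/K0 is conventionally quoted in V*s/cm^2; SI wants V*s/m^2.
_INV_K0_SI = 1.0e4
_M2_TO_A2 = 1.0e20


class CalibrationError(ValueError):
    """Raised when a TIMS calibration cannot be fitted."""


@dataclass(frozen=True)
class MobilityPhysicsContext:
    """Physical conditions entering the Mason-Schamp conversion.

    ``temperature`` defaults to 305 K; reduced-mobility conventions differ
    between vendors and the effective value is exposed rather than hidden.
    The drift gas is N2 (molar mass 28.0134 Da); trace O2 in the concurrent
    gas belongs in :class:`~timsccs.core.InstrumentMetadata`, not in the
    reduced mass, because reference CCS values are defined for pure N2.
    """

    drift_gas_molar_mass: float = 28.0134  # Da
    temperature: float = 305.0  # K
    charge_number: int = 1
    elementary_charge: float = ELEMENTARY_CHARGE
    boltzmann: float = BOLTZMANN
    gas_number_density: float = LOSCHMIDT

    def __post_init__(self) -> None:
        for name in (
            "drift_gas_molar_mass",
            "temperature",
            "charge_number",
            "elementary_charge",
            "boltzmann",
            "gas_number_density",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def _conversion_factor(self, mz: float) -> float:
        """CCS (A^2) per unit 1/K0 (V*s/cm^2) at the given m/z."""
        z = self.charge_number
        ion_mass = mz * z * DALTON
        gas_mass = self.drift_gas_molar_mass * DALTON
        mu = ion_mass * gas_mass / (ion_mass + gas_mass)
        prefactor = 3.0 * z * self.elementary_charge / (16.0 * self.gas_number_density)
        thermal = math.sqrt(2.0 * math.pi / (mu * self.boltzmann * self.temperature))
        return prefactor * thermal * _INV_K0_SI * _M2_TO_A2


def ccs_from_inverse_k0(
    inv_k0: float, mz: float, ctx: MobilityPhysicsContext | None = None
) -> float:
    """Convert inverse reduced mobility (V*s/cm^2) to CCS (A^2)."""
    ctx = ctx or MobilityPhysicsContext()
    if inv_k0 <= 0 or mz <= 0:
        raise ValueError("inv_k0 and mz must be > 0")
    return ctx._conversion_factor(mz) * inv_k0


def inverse_k0_from_ccs(
    ccs: float, mz: float, ctx: MobilityPhysicsContext | None = None
) -> float:
    """Exact algebraic inverse of :func:`ccs_from_inverse_k0`."""
    ctx = ctx or MobilityPhysicsContext()
    if ccs <= 0 or mz <= 0:
        raise ValueError("ccs and mz must be > 0")
    return ccs / ctx._conversion_factor(mz)


@dataclass(frozen=True)
class ReferenceCalibrantTable:
    """Tune-mix calibrant ions with their agreed reference CCS values."""

    table_id: str
    rows: tuple[tuple[float, int, float], ...]  # (mz, charge, reference_ccs)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(tuple(r) for r in self.rows))
        for mz, charge, ccs in self.rows:
            if mz <= 0 or charge == 0 or ccs <= 0:
                raise ValueError(f"bad calibrant row ({mz}, {charge}, {ccs})")

    @property
    def usable(self) -> bool:
        return len(self.rows) >= 3

    def reference_inverse_k0(self, ctx: MobilityPhysicsContext | None = None) -> np.ndarray:
        """Reference 1/K0 of each calibrant, from its reference CCS."""
        ctx = ctx or MobilityPhysicsContext()
        out = []
        for mz, charge, ccs in self.rows:
            row_ctx = (
                ctx
                if abs(charge) == ctx.charge_number
                else MobilityPhysicsContext(
                    drift_gas_molar_mass=ctx.drift_gas_molar_mass,
                    temperature=ctx.temperature,
                    charge_number=abs(charge),
                    elementary_charge=ctx.elementary_charge,
                    boltzmann=ctx.boltzmann,
                    gas_number_density=ctx.gas_number_density,
                )
            )
            out.append(inverse_k0_from_ccs(ccs, mz, row_ctx))
        return np.asarray(out)


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map raw reading -> 1/K0, fitted against one reference table."""

    slope: float
    intercept: float
    n_points: int
    max_abs_residual: float
    reference_table_id: str
    raw_span: tuple[float, float] = (-math.inf, math.inf)
    residuals: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise CalibrationError("calibration needs at least 3 points")
        if self.slope == 0:
            raise CalibrationError("calibration slope must be nonzero")


class CalibratedMobility(NamedTuple):
    """A calibrated 1/K0 value plus an extrapolation flag."""

    inv_k0: float
    extrapolated: bool


def fit_calibration(
    measured_raw: Sequence[float],
    table: ReferenceCalibrantTable,
    ctx: MobilityPhysicsContext | None = None,
) -> CalibrationModel:
    """Ordinary least squares fit of reference 1/K0 against raw readings.

    Readings are paired with calibrant rows by index.  The reference 1/K0
    of each calibrant comes from its reference CCS via the Mason-Schamp
    inverse, so the fitted model directly maps raw readings into 1/K0 and
    analyte values are obtained by interpolation.
    """
    ctx = ctx or MobilityPhysicsContext()
    raw = np.asarray(measured_raw, dtype=float)
    if len(raw) != len(table.rows):
        raise CalibrationError(
            f"{len(raw)} readings paired with {len(table.rows)} calibrants"
        )
    if len(raw) < 3:
        raise CalibrationError("at least 3 calibration points are required")
    if np.ptp(raw) == 0 or np.var(raw) == 0:
        raise CalibrationError("degenerate calibrant readings (zero variance)")
    ref = table.reference_inverse_k0(ctx)
    slope, intercept = np.polyfit(raw, ref, 1)
    residuals = ref - (slope * raw + intercept)
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        n_points=len(raw),
        max_abs_residual=float(np.max(np.abs(residuals))),
        reference_table_id=table.table_id,
        raw_span=(float(raw.min()), float(raw.max())),
        residuals=tuple(float(r) for r in residuals),
    )


def apply_calibration(model: CalibrationModel, raw: float) -> CalibratedMobility:
    """Evaluate the affine calibration; flag values outside the calibrant span."""
    inv_k0 = model.slope * raw + model.intercept
    lo, hi = model.raw_span
    return CalibratedMobility(float(inv_k0), not lo <= raw <= hi)


def dual_reference_ccs(
    raw: float,
    mz: float,
    tables: Sequence[ReferenceCalibrantTable],
    calibrant_raw: Sequence[float] | Mapping[str, Sequence[float]],
    ctx: MobilityPhysicsContext | None = None,
) -> dict[str, float]:
    """CCS of one raw reading under independently fitted calibrations.

    Multiple reference CCS lists coexist for the common tune-mix ions, so a
    library records a CCS under each.  ``calibrant_raw`` holds the measured
    raw readings of the calibrants, either shared between tables or as a
    map from table id to per-table readings.
    """
    ctx = ctx or MobilityPhysicsContext()
    out: dict[str, float] = {}
    for table in tables:
        readings = (
            calibrant_raw[table.table_id]
            if isinstance(calibrant_raw, Mapping)
            else calibrant_raw
        )
        model = fit_calibration(readings, table, ctx)
        inv_k0, _ = apply_calibration(model, raw)
        out[table.table_id] = ccs_from_inverse_k0(inv_k0, mz, ctx)
    return out
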