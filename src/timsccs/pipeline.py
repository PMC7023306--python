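"""End-to-end processing chains built from the module primitives.

These helpers wire the standard workflow together: measure calibrant
apexes from a tune-mix run and fit the linear TIMS calibration; extract,
smooth and pick the mobilogram of a compound's ion species and report its
calibrated CCS from the highest-purity peak; run a replicate batch
through that chain into library replicate sets.
"""

from __future__ import annotations

from typing import Sequence

from .adducts import species_mz
from .core import CompoundRecord
from .librarybuild import ReplicateSet
from .mobilogram import (
    FrameStack,
    MobilityPeak,
    apex_ccs,
    extract_eim,
    peak_purity,
    pick_peaks,
    smooth,
)
from .physics import (
    CalibrationModel,
    MobilityPhysicsContext,
    ReferenceCalibrantTable,
    fit_calibration,
)

__all__ = [
    "measure_calibrant_raw",
    "calibrate_run",
    "measure_species_ccs",
    "process_replicate_batch",
]


def _strongest_apex(frames: FrameStack, mz: float, tol: float) -> float:
    eim = extract_eim(frames, mz, tol=tol)
    try:
        eim = smooth(eim)
    except ValueError:
        pass  # axis too short/coarse for the default window; pick raw
    peaks = pick_peaks(eim)
    if not peaks:
        raise ValueError(f"no mobility peak found for m/z {mz}")
    return max(peaks, key=lambda p: p.height).apex_inv_k0


def measure_calibrant_raw(
    frames: FrameStack, table: ReferenceCalibrantTable, tol: float = 0.05
) -> list[float]:
    """Apex raw readings of each calibrant ion, in table row order."""
    return [_strongest_apex(frames, mz, tol) for mz, _, _ in table.rows]


def calibrate_run(
    frames: FrameStack,
    table: ReferenceCalibrantTable,
    ctx: MobilityPhysicsContext | None = None,
    tol: float = 0.05,
) -> CalibrationModel:
    """Fit the linear TIMS calibration from a tune-mix frame stack."""
    return fit_calibration(measure_calibrant_raw(frames, table, tol), table, ctx)


def measure_species_ccs(
    frames: FrameStack,
    compound: CompoundRecord,
    species: str,
    model: CalibrationModel | None,
    ctx: MobilityPhysicsContext | None = None,
    tol: float = 0.01,
    smooth_first: bool = True,
) -> tuple[float, MobilityPeak]:
    """CCS of one ion species via EIM -> smooth -> pick -> purity -> apex.

    Among the picked mobility peaks the one with the highest purity (the
    cleanest single-ion-species peak) is selected, matching how a CCS is
    read off a complex mobilogram.
    """
    mz = species_mz(compound.monoisotopic_mass, species)
    eim = extract_eim(frames, mz, tol=tol)
    if smooth_first:
        try:
            eim = smooth(eim)
        except ValueError:
            pass
    peaks = pick_peaks(eim)
    if not peaks:
        raise ValueError(f"no mobility peak for {compound.name} {species}")
    for p in peaks:
        p.purity = peak_purity(frames, p, mz, tol=tol)
    best = max(peaks, key=lambda p: (p.purity, p.height))
    ccs = apex_ccs(best, model, mz, ctx)
    return ccs, best


def process_replicate_batch(
    runs: Sequence[FrameStack],
    compounds: Sequence[tuple[CompoundRecord, Sequence[str]]],
    model: CalibrationModel | None = None,
    ctx: MobilityPhysicsContext | None = None,
    reference_table_id: str | None = None,
    tol: float = 0.01,
) -> list[ReplicateSet]:
    """Measure every (compound, species) in every run into replicate sets."""
    ref_id = reference_table_id or (
        model.reference_table_id if model is not None else "identity"
    )
    sets: list[ReplicateSet] = []
    for compound, species_list in compounds:
        for species in species_list:
            values = []
            for frames in runs:
                ccs, _ = measure_species_ccs(
                    frames, compound, species, model, ctx, tol=tol
                )
                values.append(ccs)
            sets.append(
                ReplicateSet(
                    compound=compound,
                    species=species,
                    ccs_values=values,
                    reference_table_id=ref_id,
                    retention_time=compound.retention_time,
                )
            )
    return sets
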