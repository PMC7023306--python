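"""Synthetic ion-mobility data with machine-readable ground truth.

Every generator emulates one experimental design from the acquisition
workflow: frame stacks with Gaussian mobility peaks for known species at
known CCS (single-compound infusions), tune-mix calibrant runs under an
affine raw-axis distortion, replicate batches with controlled relative
CCS jitter (the triplicate reproducibility design), and a dense random
matrix background (the spike-into-plant-extract design).  Truth tables
carry the planted m/z, 1/K0 and CCS so recovery can be scored exactly;
all generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .adducts import species_mz, theoretical_isotope_pattern
from .core import CompoundRecord
from .mobilogram import FrameStack
from .physics import MobilityPhysicsContext, ReferenceCalibrantTable, inverse_k0_from_ccs

__all__ = [
    "SimulatedSpecies",
    "SimulatedCompound",
    "SimulationSpec",
    "simulate_frames",
    "simulate_calibrant_run",
    "simulate_replicate_batch",
    "overlay_matrix_background",
]


@dataclass(frozen=True)
class SimulatedSpecies:
    """One planted ion species: its true CCS and relative abundance."""

    species: str
    true_ccs: float  # A^2
    abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.true_ccs <= 0 or self.abundance <= 0:
            raise ValueError("true_ccs and abundance must be > 0")


@dataclass(frozen=True)
class SimulatedCompound:
    compound: CompoundRecord
    ions: tuple[SimulatedSpecies, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ions", tuple(self.ions))


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of a simulated acquisition.

    The mobility axis spans 0.4-1.8 1/K0 over 1000 bins by default, the
    acquisition range of the survey experiments.  ``peak_sigma`` is the
    Gaussian mobility peak sigma in 1/K0 units; the 0.012 default puts a
    mid-range peak near resolving power 40, the broad survey regime.
    ``calibration_distortion`` (slope, intercept) defines the affine map
    raw -> 1/K0 that a calibration should recover; species are planted at
    the raw position that maps onto their true 1/K0.
    """

    compounds: tuple[SimulatedCompound, ...]
    mobility_axis: tuple[float, float, int] = (0.4, 1.8, 1000)
    peak_sigma: float = 0.012  # 1/K0 units
    noise_fraction: float = 0.0  # additive, as a fraction of each peak height
    calibration_distortion: tuple[float, float] = (1.0, 0.0)
    seed: int = 0
    base_intensity: float = 1.0e4
    n_isotopologues: int = 4
    mass_range: tuple[float, float] = (100.0, 1500.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", tuple(self.compounds))
        lo, hi, n_bins = self.mobility_axis
        if not lo < hi:
            raise ValueError("mobility axis min must be < max")
        if n_bins < 50:
            raise ValueError("mobility axis needs at least 50 bins")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be > 0")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.calibration_distortion[0] == 0:
            raise ValueError("distortion slope must be nonzero")


def _raw_axis(spec_axis: tuple[float, float, int]) -> np.ndarray:
    lo, hi, n_bins = spec_axis
    return np.linspace(lo, hi, n_bins)


def _plant_gaussian(
    bins: list[list[tuple[float, float]]],
    axis: np.ndarray,
    center: float,
    sigma: float,
    mz_list: Sequence[float],
    heights: Sequence[float],
    rng: np.random.Generator | None,
    noise_scale: float,
) -> None:
    lo = np.searchsorted(axis, center - 5.0 * sigma)
    hi = np.searchsorted(axis, center + 5.0 * sigma, side="right")
    for i in range(lo, hi):
        amp = np.exp(-0.5 * ((axis[i] - center) / sigma) ** 2)
        for mz, height in zip(mz_list, heights):
            intensity = height * amp
            if rng is not None and noise_scale > 0:
                intensity += rng.uniform(0.0, noise_scale * height)
            if intensity > 1e-9:
                bins[i].append((mz, intensity))


def _to_frames(axis: np.ndarray, bins: list[list[tuple[float, float]]]) -> FrameStack:
    spectra = []
    for centroids in bins:
        if centroids:
            mz = np.array([c[0] for c in centroids])
            inten = np.array([c[1] for c in centroids])
            order = np.argsort(mz)
            spectra.append((mz[order], inten[order]))
        else:
            spectra.append((np.empty(0), np.empty(0)))
    return FrameStack(raw_axis=axis, spectra=spectra)


def simulate_frames(
    spec: SimulationSpec, ctx: MobilityPhysicsContext | None = None
) -> tuple[FrameStack, pd.DataFrame]:
    """Generate one frame stack plus its truth table.

    Each (compound, species) contributes a Gaussian mobility profile at
    the raw position implied by its true CCS and the inverse of the
    calibration distortion, carrying centroids at the species m/z with
    the compound's theoretical isotopologue pattern.
    """
    ctx = ctx or MobilityPhysicsContext()
    axis = _raw_axis(spec.mobility_axis)
    slope, intercept = spec.calibration_distortion
    rng = np.random.default_rng(spec.seed) if spec.noise_fraction > 0 else None
    bins: list[list[tuple[float, float]]] = [[] for _ in axis]
    truth_rows = []
    for sim in spec.compounds:
        pattern = (
            theoretical_isotope_pattern(
                sim.compound.molecular_formula, spec.n_isotopologues
            )
            if sim.compound.molecular_formula
            else None
        )
        for ion in sim.ions:
            mz0 = species_mz(sim.compound.monoisotopic_mass, ion.species)
            if not spec.mass_range[0] <= mz0 <= spec.mass_range[1]:
                raise ValueError(
                    f"{sim.compound.name} {ion.species} m/z {mz0:.4f} outside "
                    f"mass range {spec.mass_range}"
                )
            inv_k0 = inverse_k0_from_ccs(ion.true_ccs, mz0, ctx)
            raw_center = (inv_k0 - intercept) / slope
            if pattern is not None:
                mz_list = [mz0 + (m - pattern.masses[0]) for m in pattern.masses]
                heights = [
                    spec.base_intensity * ion.abundance * rel
                    for rel in pattern.intensities
                ]
            else:
                mz_list = [mz0]
                heights = [spec.base_intensity * ion.abundance]
            _plant_gaussian(
                bins,
                axis,
                raw_center,
                spec.peak_sigma / abs(slope),
                mz_list,
                heights,
                rng,
                spec.noise_fraction,
            )
            truth_rows.append(
                {
                    "compound": sim.compound.name,
                    "species": ion.species,
                    "mz": mz0,
                    "true_ccs": ion.true_ccs,
                    "true_inv_k0": inv_k0,
                    "raw_center": raw_center,
                    "abundance": ion.abundance,
                }
            )
    return _to_frames(axis, bins), pd.DataFrame(truth_rows)


def simulate_calibrant_run(
    table: ReferenceCalibrantTable,
    distortion: tuple[float, float] = (1.0, 0.0),
    ctx: MobilityPhysicsContext | None = None,
    seed: int = 0,
    mobility_axis: tuple[float, float, int] = (0.4, 1.8, 1000),
    peak_sigma: float = 0.012,
    noise_fraction: float = 0.0,
    base_intensity: float = 1.0e4,
) -> FrameStack:
    """Tune-mix run: calibrant ions planted at distorted raw positions.

    The planted positions satisfy 1/K0 = slope*raw + intercept, so fitting
    a calibration against the table recovers exactly ``distortion``.
    """
    if not table.usable:
        raise ValueError("reference table needs at least 3 calibrants")
    ctx = ctx or MobilityPhysicsContext()
    axis = _raw_axis(mobility_axis)
    slope, intercept = distortion
    rng = np.random.default_rng(seed) if noise_fraction > 0 else None
    bins: list[list[tuple[float, float]]] = [[] for _ in axis]
    for (mz, charge, _), inv_k0 in zip(table.rows, table.reference_inverse_k0(ctx)):
        raw_center = (inv_k0 - intercept) / slope
        _plant_gaussian(
            bins,
            axis,
            raw_center,
            peak_sigma / abs(slope),
            [mz],
            [base_intensity],
            rng,
            noise_fraction,
        )
    return _to_frames(axis, bins)


def simulate_replicate_batch(
    spec: SimulationSpec,
    n_replicates: int = 3,
    ccs_jitter_rsd: float = 0.1,
    seed: int = 0,
) -> tuple[list[FrameStack], pd.DataFrame]:
    """Replicate runs with true CCS jittered at a controlled relative SD.

    ``ccs_jitter_rsd`` is in percent (0.1 = 0.1% relative SD), emulating
    day-to-day triplicate variability; a pipeline run over the batch
    should recover per-compound RSDs near this value.  Returns the runs
    plus a concatenated truth table with a ``replicate`` column.
    """
    if ccs_jitter_rsd < 0:
        raise ValueError("ccs_jitter_rsd must be >= 0")
    rng = np.random.default_rng(seed)
    runs: list[FrameStack] = []
    truths = []
    for r in range(n_replicates):
        jittered_compounds = []
        for sim in spec.compounds:
            ions = tuple(
                dataclasses.replace(
                    ion,
                    true_ccs=ion.true_ccs
                    * (1.0 + rng.normal(0.0, ccs_jitter_rsd / 100.0)),
                )
                for ion in sim.ions
            )
            jittered_compounds.append(dataclasses.replace(sim, ions=ions))
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_spec = dataclasses.replace(
            spec, compounds=tuple(jittered_compounds), seed=rep_seed
        )
        frames, truth = simulate_frames(rep_spec)
        truth["replicate"] = r
        runs.append(frames)
        truths.append(truth)
    return runs, pd.concat(truths, ignore_index=True)


def overlay_matrix_background(
    frames: FrameStack,
    density: float,
    seed: int = 0,
    mz_range: tuple[float, float] = (100.0, 1500.0),
    intensity_range: tuple[float, float] = (1.0e2, 1.0e4),
    peak_sigma: float = 0.012,
) -> FrameStack:
    """Overlay a random dense matrix of background mobility features.

    ``density`` is the expected feature count per 1/K0 unit; positions are
    uniform in mobility and m/z, intensities log-uniform.  The planted
    centroids of the input are preserved unchanged — this emulates spiking
    authentic standards into a complex plant extract.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if density == 0:
        return frames
    rng = np.random.default_rng(seed)
    axis = frames.raw_axis.copy()
    span = float(abs(axis[-1] - axis[0]))
    n_features = int(rng.poisson(density * span))
    bins: list[list[tuple[float, float]]] = [
        list(zip(mz.tolist(), inten.tolist())) for mz, inten in frames.spectra
    ]
    log_lo, log_hi = np.log(intensity_range[0]), np.log(intensity_range[1])
    for _ in range(n_features):
        center = rng.uniform(axis.min(), axis.max())
        mz = rng.uniform(*mz_range)
        height = float(np.exp(rng.uniform(log_lo, log_hi)))
        _plant_gaussian(bins, axis, center, peak_sigma, [mz], [height], None, 0.0)
    return _to_frames(axis, bins)
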