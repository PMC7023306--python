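"""Negative-mode ion species m/z, theoretical isotope patterns and
annotation of mobility peaks.

Plant natural products in negative electrospray form a small, recurring
set of singly charged species: the deprotonated molecule [M-H]-, its
dimer [2M-H]-, the oxidized [M-3H]- (loss of two hydrogens, e.g. catechol
to quinone, then deprotonation), the formic acid adduct [M-H+HCO2H]- and
the sodium formate adduct [M-H+Na+HCO2]-.  Deprotonation removes a proton
(the electron stays), which is what puts deprotonated rutin at nominal
m/z 609 and its companions at 607 and 677.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    ATOMIC_MASS,
    NEGATIVE_MODE_SPECIES,
    PROTON_MASS,
    CompoundRecord,
    IonSpeciesAnnotation,
    parse_formula,
)
from .mobilogram import FrameStack, MobilityPeak, peak_purity, _oriented, _mz_window

__all__ = [
    "ISOTOPES",
    "SPECIES_MZ_RULES",
    "IsotopePattern",
    "species_mz",
    "theoretical_isotope_pattern",
    "pattern_deviation",
    "annotate_peaks",
]

_H = ATOMIC_MASS["H"]
# Neutral adduct masses from the same atomic mass table.
_HCOOH = ATOMIC_MASS["C"] + 2 * _H + 2 * ATOMIC_MASS["O"]  # 46.0054793
_NAHCO2 = ATOMIC_MASS["Na"] + ATOMIC_MASS["C"] + _H + 2 * ATOMIC_MASS["O"]  # 67.9874251

#: m/z of each species as (multiplier of M, constant offset); charge -1.
SPECIES_MZ_RULES: dict[str, tuple[float, float]] = {
    "[M-H]-": (1.0, -PROTON_MASS),
    "[2M-H]-": (2.0, -PROTON_MASS),
    "[M-3H]-": (1.0, -2.0 * _H - PROTON_MASS),
    "[M-H+HCO2H]-": (1.0, -PROTON_MASS + _HCOOH),
    "[M-H+Na+HCO2]-": (1.0, -PROTON_MASS + _NAHCO2),
}

# Isotope (mass Da, abundance) per element, lightest first.
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.0078250319, 0.999885), (2.0141017781, 0.000115)),
    "C": ((12.0, 0.9893), (13.0033548378, 0.0107)),
    "N": ((14.0030740052, 0.99636), (15.0001088984, 0.00364)),
    "O": ((15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)),
    "S": ((31.97207069, 0.9499), (32.97145850, 0.0075), (33.96786683, 0.0425), (35.96708088, 0.0001)),
    "Na": ((22.98976928, 1.0),),
    "P": ((30.97376151, 1.0),),
}


@dataclass(frozen=True)
class IsotopePattern:
    """Unit-mass-aggregated isotopologue pattern, base peak normalized to 1."""

    masses: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.masses or len(self.masses) != len(self.intensities):
            raise ValueError("pattern needs matching, nonempty mass/intensity lists")
        if any(b <= a for a, b in zip(self.masses, self.masses[1:])):
            raise ValueError("pattern masses must be strictly increasing")
        if abs(max(self.intensities) - 1.0) > 1e-9:
            raise ValueError("base peak intensity must be 1.0")
        if any(not 0 < i <= 1 for i in self.intensities):
            raise ValueError("intensities must lie in (0, 1]")


def species_mz(monoisotopic_mass: float, species: str) -> float:
    """Theoretical m/z of a negative-mode species of neutral mass M (Da)."""
    if monoisotopic_mass <= 0:
        raise ValueError("monoisotopic mass must be > 0")
    try:
        mult, offset = SPECIES_MZ_RULES[species]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}; supported: {sorted(SPECIES_MZ_RULES)}"
        ) from None
    return mult * monoisotopic_mass + offset


# A distribution over "extra neutron" counts: offset -> (probability,
# probability-weighted mass sum).  Convolution adds offsets and masses.
_Dist = dict[int, tuple[float, float]]


def _single_atom(element: str) -> _Dist:
    isotopes = ISOTOPES[element]
    mono = isotopes[0][0]
    dist: _Dist = {}
    for mass, abundance in isotopes:
        offset = round(mass - mono)
        p, ms = dist.get(offset, (0.0, 0.0))
        dist[offset] = (p + abundance, ms + abundance * mass)
    return dist


def _convolve(a: _Dist, b: _Dist, max_offset: int) -> _Dist:
    out: _Dist = {}
    for oa, (pa, ma) in a.items():
        for ob, (pb, mb) in b.items():
            o = oa + ob
            if o > max_offset:
                continue
            # mean masses add under convolution; keep probability-weighted sums
            p, ms = out.get(o, (0.0, 0.0))
            mean = (ma / pa) + (mb / pb)
            out[o] = (p + pa * pb, ms + pa * pb * mean)
    return out


def _element_power(element: str, n: int, max_offset: int) -> _Dist:
    """Distribution of n atoms of one element (exponentiation by squaring)."""
    result: _Dist = {0: (1.0, 0.0)}
    base = _single_atom(element)
    while n:
        if n & 1:
            result = _convolve(result, base, max_offset)
        n >>= 1
        if n:
            base = _convolve(base, base, max_offset)
    return result


def theoretical_isotope_pattern(
    formula: str | Mapping[str, int], n_isotopologues: int = 4
) -> IsotopePattern:
    """Isotopologue pattern of a formula by per-element convolution.

    Isotopologues are aggregated on a unit-mass grid (extra-neutron count),
    the scale a TOF observes for these analytes, truncated to
    ``n_isotopologues`` and normalized so the base peak is 1.
    """
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    if not counts:
        raise ValueError("empty formula")
    for element in counts:
        if element not in ISOTOPES:
            raise ValueError(f"unsupported element {element!r}")
    if n_isotopologues < 1:
        raise ValueError("n_isotopologues must be >= 1")
    max_offset = n_isotopologues - 1 + 2  # slack so truncation cannot bias bins
    dist: _Dist = {0: (1.0, 0.0)}
    for element, n in counts.items():
        dist = _convolve(dist, _element_power(element, n, max_offset), max_offset)
    offsets = sorted(o for o in dist if o < n_isotopologues and dist[o][0] > 0)
    probs = np.array([dist[o][0] for o in offsets])
    masses = np.array([dist[o][1] / dist[o][0] for o in offsets])
    probs /= probs.max()
    keep = probs > 1e-12
    return IsotopePattern(
        masses=tuple(float(m) for m in masses[keep]),
        intensities=tuple(float(p) for p in probs[keep]),
    )


def pattern_deviation(observed: IsotopePattern, theoretical: IsotopePattern) -> float:
    """Root-mean-square intensity mismatch, scaled by 1000 (0 = perfect).

    An open analog of vendor pattern-match scores: both patterns are base
    normalized and compared over their first min(n) isotopologues.
    """
    n = min(len(observed.intensities), len(theoretical.intensities))
    if n == 0:
        raise ValueError("empty isotope pattern")
    obs = np.array(observed.intensities[:n])
    theo = np.array(theoretical.intensities[:n])
    return 1000.0 * float(np.sqrt(np.mean((obs - theo) ** 2)))


def _observed_pattern(
    frames: FrameStack,
    peak: MobilityPeak,
    base_mz: float,
    theoretical: IsotopePattern,
    tol: float,
) -> IsotopePattern | None:
    """Sum centroid intensity at each isotopologue m/z over the peak extent."""
    axis, spectra = _oriented(frames)
    lo = peak.apex_inv_k0 - peak.base_width_inv_k0 / 2.0
    hi = peak.apex_inv_k0 + peak.base_width_inv_k0 / 2.0
    offsets = [m - theoretical.masses[0] for m in theoretical.masses]
    sums = np.zeros(len(offsets))
    for pos, (mz, inten) in zip(axis, spectra):
        if lo <= pos <= hi and mz.size:
            for k, off in enumerate(offsets):
                sums[k] += inten[np.abs(mz - (base_mz + off)) <= tol].sum()
    if sums.max() <= 0:
        return None
    sums /= sums.max()
    keep = [k for k in range(len(offsets)) if sums[k] > 0]
    return IsotopePattern(
        masses=tuple(base_mz + offsets[k] for k in keep),
        intensities=tuple(float(sums[k]) for k in keep),
    )


def annotate_peaks(
    peaks: Sequence[MobilityPeak],
    frames: FrameStack,
    compound: CompoundRecord,
    tol: float = 0.01,
    pattern_ceiling: float = 50.0,
    min_purity: float = 0.5,
    candidate_species: Sequence[str] = NEGATIVE_MODE_SPECIES,
) -> list[tuple[MobilityPeak, IonSpeciesAnnotation]]:
    """Assign ion species to mobility peaks by m/z dominance + pattern.

    A peak earns a species when (a) centroids at the species m/z dominate
    its mobility extent (purity >= ``min_purity``), and (b) the observed
    isotopologue pattern deviates from the theoretical one by at most
    ``pattern_ceiling``.  When several peaks qualify for the same species,
    the highest-purity peak wins — CCS values are only trustworthy for the
    peak that actually carries a single ion species.  Each species is
    assigned to at most one peak; leftovers are labeled ``unknown``.
    """
    if compound.molecular_formula is None:
        raise ValueError("annotation requires a molecular formula")
    candidates: list[tuple[float, int, str, float]] = []  # purity, peak idx, species, mz
    theo = theoretical_isotope_pattern(compound.molecular_formula)
    for sp in candidate_species:
        mz_s = species_mz(compound.monoisotopic_mass, sp)
        for pi, peak in enumerate(peaks):
            purity = peak_purity(frames, peak, mz_s, tol=tol)
            if purity < min_purity:
                continue
            observed = _observed_pattern(frames, peak, mz_s, theo, tol)
            if observed is None or pattern_deviation(observed, theo) > pattern_ceiling:
                continue
            candidates.append((purity, pi, sp, mz_s))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    assigned_peaks: dict[int, IonSpeciesAnnotation] = {}
    assigned_species: set[str] = set()
    for purity, pi, sp, mz_s in candidates:
        if pi in assigned_peaks or sp in assigned_species:
            continue
        assigned_peaks[pi] = IonSpeciesAnnotation(
            species=sp, charge=-1, mz=mz_s, purity=purity
        )
        assigned_species.add(sp)

    out: list[tuple[MobilityPeak, IonSpeciesAnnotation]] = []
    for pi, peak in enumerate(peaks):
        if pi in assigned_peaks:
            annotation = assigned_peaks[pi]
            peak.purity = annotation.purity
        else:
            annotation = IonSpeciesAnnotation(
                species="unknown", charge=-1, mz=math.nan, purity=0.0
            )
        out.append((peak, annotation))
    return out
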