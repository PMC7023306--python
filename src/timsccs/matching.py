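"""Multi-criterion query-to-library matching with tiered annotation quality.

Each supplied criterion — accurate mass (ppm), retention time (min),
isotope pattern score, MS/MS cosine similarity, and CCS percent delta —
is evaluated against a (wide, narrow) threshold pair, mirroring the
two-square annotation-quality display: meeting the wide threshold is a
moderate match, the narrow one a strong match.  CCS carries an extra
high-confidence flag at 0.3% alongside its 5%/2% tiers, since the
community quotes both a <=2.0% moderate and a <=0.3% high-confidence
matching convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .core import CCSLibraryEntry
from .adducts import IsotopePattern, pattern_deviation, theoretical_isotope_pattern

__all__ = [
    "QueryFeature",
    "AQTiers",
    "AQResult",
    "CRITERIA",
    "ccs_delta",
    "msms_cosine",
    "aq_score",
    "match_features",
]

CRITERIA = ("mass_ppm", "rt_min", "pattern_score", "msms_cosine", "ccs_percent")

#: criteria where larger is better (similarity scales).
_HIGHER_IS_BETTER = {"msms_cosine"}


@dataclass
class QueryFeature:
    """One feature from a profiling run, with whatever evidence it has."""

    mz: float
    feature_id: str = ""
    rt: float | None = None  # minutes
    ccs: float | None = None  # A^2
    isotope_pattern: IsotopePattern | None = None
    msms: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("feature m/z must be > 0")
        if self.msms is not None and not self.msms:
            raise ValueError("empty MS/MS peak list; omit it instead")


@dataclass(frozen=True)
class AQTiers:
    """(wide, narrow) thresholds per criterion.

    Deltas are 'smaller is better' except the MS/MS cosine, where narrow
    means a *higher* similarity.  ``high_confidence_ccs_percent`` is the
    separate high-confidence CCS flag threshold.
    """

    mass_ppm: tuple[float, float] = (5.0, 2.0)
    rt_min: tuple[float, float] = (0.3, 0.1)
    pattern_score: tuple[float, float] = (50.0, 20.0)
    msms_cosine: tuple[float, float] = (0.6, 0.8)
    ccs_percent: tuple[float, float] = (5.0, 2.0)
    high_confidence_ccs_percent: float = 0.3

    def __post_init__(self) -> None:
        for name in CRITERIA:
            wide, narrow = getattr(self, name)
            if wide <= 0 or narrow <= 0:
                raise ValueError(f"{name} thresholds must be > 0")
            if name in _HIGHER_IS_BETTER:
                if narrow <= wide:
                    raise ValueError(f"{name}: narrow must exceed wide (similarity)")
            elif narrow >= wide:
                raise ValueError(f"{name}: narrow must be stricter than wide")


@dataclass
class AQResult:
    """Tier assignment of one query feature against one library entry."""

    entry_id: str
    deltas: dict[str, float | None] = field(default_factory=dict)
    tiers: dict[str, str] = field(default_factory=dict)  # none|wide|narrow
    high_confidence_ccs: bool = False

    @property
    def n_narrow(self) -> int:
        return sum(1 for t in self.tiers.values() if t == "narrow")

    @property
    def n_wide(self) -> int:
        # narrow implies the wide condition, so count both.
        return sum(1 for t in self.tiers.values() if t in ("wide", "narrow"))

    def rank_key(self) -> tuple:
        mass = self.deltas.get("mass_ppm")
        ccs = self.deltas.get("ccs_percent")
        return (
            -self.n_narrow,
            -self.n_wide,
            math.inf if mass is None else mass,
            math.inf if ccs is None else ccs,
            self.entry_id,
        )


def ccs_delta(query_ccs: float, library_ccs: float) -> float:
    """Percent CCS deviation relative to the library value."""
    if query_ccs <= 0 or library_ccs <= 0:
        raise ValueError("CCS values must be > 0")
    return 100.0 * abs(query_ccs - library_ccs) / library_ccs


def msms_cosine(
    a: Sequence[tuple[float, float]],
    b: Sequence[tuple[float, float]],
    bin_width: float = 0.01,
) -> float:
    """Cosine similarity of two MS/MS peak lists on a shared m/z binning."""
    if not a or not b:
        raise ValueError("MS/MS peak lists must be nonempty")

    def binned(peaks: Sequence[tuple[float, float]]) -> dict[int, float]:
        out: dict[int, float] = {}
        for mz, inten in peaks:
            out[round(mz / bin_width)] = out.get(round(mz / bin_width), 0.0) + inten
        return out

    va, vb = binned(a), binned(b)
    na = math.sqrt(sum(v * v for v in va.values()))
    nb = math.sqrt(sum(v * v for v in vb.values()))
    if na == 0 or nb == 0:
        raise ValueError("all-zero MS/MS intensities")
    dot = sum(v * vb.get(k, 0.0) for k, v in va.items())
    return dot / (na * nb)


def _tier(delta: float, thresholds: tuple[float, float], higher_better: bool) -> str:
    wide, narrow = thresholds
    if higher_better:
        if delta >= narrow:
            return "narrow"
        if delta >= wide:
            return "wide"
    else:
        if delta <= narrow:
            return "narrow"
        if delta <= wide:
            return "wide"
    return "none"


def aq_score(
    f: QueryFeature,
    e: CCSLibraryEntry,
    tiers: AQTiers | None = None,
    reference_table_id: str | None = None,
    library_msms: Sequence[tuple[float, float]] | None = None,
) -> AQResult:
    """Evaluate every criterion the feature supplies against one entry.

    Criteria the feature does not carry are marked not-evaluated (delta
    ``None``, no tier) rather than counted against the match.
    """
    tiers = tiers or AQTiers()
    result = AQResult(entry_id=e.entry_id)

    lib_mz = e.species.mz
    result.deltas["mass_ppm"] = abs(f.mz - lib_mz) / lib_mz * 1e6
    result.tiers["mass_ppm"] = _tier(result.deltas["mass_ppm"], tiers.mass_ppm, False)

    if f.rt is not None and e.retention_time is not None:
        result.deltas["rt_min"] = abs(f.rt - e.retention_time)
        result.tiers["rt_min"] = _tier(result.deltas["rt_min"], tiers.rt_min, False)
    else:
        result.deltas["rt_min"] = None

    if f.isotope_pattern is not None and e.compound.molecular_formula is not None:
        theo = theoretical_isotope_pattern(e.compound.molecular_formula)
        result.deltas["pattern_score"] = pattern_deviation(f.isotope_pattern, theo)
        result.tiers["pattern_score"] = _tier(
            result.deltas["pattern_score"], tiers.pattern_score, False
        )
    else:
        result.deltas["pattern_score"] = None

    if f.msms is not None and library_msms:
        result.deltas["msms_cosine"] = msms_cosine(f.msms, library_msms)
        result.tiers["msms_cosine"] = _tier(
            result.deltas["msms_cosine"], tiers.msms_cosine, True
        )
    else:
        result.deltas["msms_cosine"] = None

    if f.ccs is not None and e.ccs_by_reference:
        ref = reference_table_id or sorted(e.ccs_by_reference)[0]
        if ref not in e.ccs_by_reference:
            raise KeyError(f"entry {e.entry_id} has no CCS under reference {ref!r}")
        delta = ccs_delta(f.ccs, e.ccs_by_reference[ref].mean)
        result.deltas["ccs_percent"] = delta
        result.tiers["ccs_percent"] = _tier(delta, tiers.ccs_percent, False)
        result.high_confidence_ccs = delta <= tiers.high_confidence_ccs_percent
    else:
        result.deltas["ccs_percent"] = None

    return result


def match_features(
    features: Sequence[QueryFeature],
    library: Sequence[CCSLibraryEntry],
    tiers: AQTiers | None = None,
    reference_table_id: str | None = None,
    top_k: int = 3,
) -> list[list[AQResult]]:
    """Rank library candidates for each feature.

    Candidates are pre-filtered by the wide accurate-mass tier, then
    ranked by narrow-tier count, wide-tier count, ascending mass ppm,
    ascending CCS delta, and finally entry id — a deterministic ordinal
    key, since the annotation-quality display reports tiers, not a fused
    score.
    """
    if not library:
        raise ValueError("library is empty")
    tiers = tiers or AQTiers()
    out: list[list[AQResult]] = []
    for f in features:
        results = []
        for e in library:
            ppm = abs(f.mz - e.species.mz) / e.species.mz * 1e6
            if ppm > tiers.mass_ppm[0]:
                continue
            results.append(aq_score(f, e, tiers, reference_table_id))
        results.sort(key=lambda r: r.rank_key())
        out.append(results[:top_k])
    return out
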