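"""Replicate aggregation into a CCS library and library comparison.

Triplicate (or more) analyses of each authentic standard are collapsed to
mean / sample SD / relative SD per (compound, ion species, calibration
reference).  Libraries or measurement sets are compared compound-by-
compound as percent differences, the reproducibility currency of CCS
work: well-behaved [M-H]- replicates stay below ~0.35% RSD, and matrix or
infusion effects show up as sub-percent shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import (
    AggregateStats,
    CCSLibraryEntry,
    CompoundRecord,
    InstrumentMetadata,
    IonSpeciesAnnotation,
)
from .adducts import species_mz

__all__ = [
    "ReplicateSet",
    "ComparisonReport",
    "aggregate_replicates",
    "percent_difference",
    "build_library",
    "compare_measurement_sets",
    "DEFAULT_QC_RSD_PERCENT",
]

#: QC ceiling for [M-H]- replicate RSD; the well-behaved regime tops out
#: near 0.35%, so anything above it deserves a flag.
DEFAULT_QC_RSD_PERCENT = 0.35


@dataclass
class ReplicateSet:
    """CCS values of one ion species of one compound across analyses."""

    compound: CompoundRecord
    species: str
    ccs_values: list[float]
    reference_table_id: str = "default"
    retention_time: float | None = None

    def __post_init__(self) -> None:
        if not self.ccs_values:
            raise ValueError("a replicate set needs at least one value")
        if any(v <= 0 for v in self.ccs_values):
            raise ValueError("CCS values must be > 0")


@dataclass
class ComparisonReport:
    """Per-item percent differences between two measurement sets."""

    per_item: list[tuple[str, float, float, float]]  # id, a, b, % difference
    summary: AggregateStats
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)

    def mean_percent_difference(self) -> float:
        return self.summary.mean


def aggregate_replicates(r: ReplicateSet) -> AggregateStats:
    """Mean, sample (n-1) SD and RSD% of a replicate set.

    A single replicate yields a defined mean with SD/RSD flagged undefined
    (NaN) rather than a fake zero.
    """
    return AggregateStats.from_values(r.ccs_values)


def percent_difference(a: float, b: float, denominator: str = "first") -> float:
    """Unsigned percent difference 100*|a-b|/d.

    ``denominator`` picks d: the first value (reference/library,
    the default), the second, or the mean of both (symmetric).
    """
    if a <= 0 or b <= 0:
        raise ValueError("values must be > 0")
    if denominator == "first":
        d = a
    elif denominator == "second":
        d = b
    elif denominator == "mean":
        d = (a + b) / 2.0
    else:
        raise ValueError(f"denominator {denominator!r}; use first|second|mean")
    return 100.0 * abs(a - b) / d


def build_library(
    sets: Sequence[ReplicateSet],
    rt_map: Mapping[str, float] | None = None,
    metadata: InstrumentMetadata | None = None,
    qc_rsd_percent: float = DEFAULT_QC_RSD_PERCENT,
) -> list[CCSLibraryEntry]:
    """Aggregate replicate sets into one entry per (compound, species).

    Sets for the same (compound, species) under different calibration
    reference tables merge into one entry carrying one
    :class:`AggregateStats` per reference.  An entry whose [M-H]- RSD
    exceeds ``qc_rsd_percent`` is flagged rather than dropped.
    """
    grouped: dict[tuple[str, str], list[ReplicateSet]] = {}
    for s in sets:
        grouped.setdefault((s.compound.name, s.species), []).append(s)

    entries: list[CCSLibraryEntry] = []
    for (name, species), group in grouped.items():
        compound = group[0].compound
        for other in group[1:]:
            if (
                other.compound.monoisotopic_mass != compound.monoisotopic_mass
                or other.compound.molecular_formula != compound.molecular_formula
            ):
                raise ValueError(f"conflicting compound metadata for {name!r}")
        by_ref: dict[str, AggregateStats] = {}
        for s in group:
            if s.reference_table_id in by_ref:
                raise ValueError(
                    f"duplicate replicate set for {name!r}/{species}/"
                    f"{s.reference_table_id}"
                )
            by_ref[s.reference_table_id] = aggregate_replicates(s)
        rt = group[0].retention_time
        if rt is None and rt_map is not None:
            rt = rt_map.get(name)
        qc_flags = []
        if species == "[M-H]-" and any(
            st.sd_defined and st.rsd_percent > qc_rsd_percent for st in by_ref.values()
        ):
            qc_flags.append(f"rsd_above_{qc_rsd_percent}pct")
        entries.append(
            CCSLibraryEntry(
                compound=compound,
                species=IonSpeciesAnnotation(
                    species=species,
                    charge=-1,
                    mz=species_mz(compound.monoisotopic_mass, species)
                    if species != "unknown"
                    else math.nan,
                ),
                ccs_by_reference=by_ref,
                retention_time=rt,
                n_replicates=max(len(s.ccs_values) for s in group),
                metadata=metadata,
                qc_flags=qc_flags,
            )
        )
    return entries


def compare_measurement_sets(
    a: Mapping[str, float] | Sequence[tuple[str, float]],
    b: Mapping[str, float] | Sequence[tuple[str, float]],
    denominator: str = "first",
) -> ComparisonReport:
    """Compare two keyed CCS measurement sets by percent difference.

    Keys (typically compound names) must be unique per side; unmatched
    keys are listed, not silently dropped.  The summary aggregates the
    per-item percent differences with the plain mean and sample SD.
    """
    da = dict(a)
    db = dict(b)
    if len(da) != len(list(a)) or len(db) != len(list(b)):
        raise ValueError("join keys must be unique per side")
    common = [k for k in da if k in db]
    if not common:
        raise ValueError("no common keys between the two sets")
    per_item = [
        (k, da[k], db[k], percent_difference(da[k], db[k], denominator))
        for k in common
    ]
    diffs = [d for _, _, _, d in per_item]
    if len(diffs) == 1:
        summary = AggregateStats(mean=diffs[0], sd=math.nan, rsd_percent=math.nan, n=1)
    else:
        n = len(diffs)
        mean = math.fsum(diffs) / n
        sd = math.sqrt(math.fsum((d - mean) ** 2 for d in diffs) / (n - 1))
        rsd = 100.0 * sd / mean if mean > 0 else math.nan
        summary = AggregateStats(mean=mean, sd=sd, rsd_percent=rsd, n=n)
    return ComparisonReport(
        per_item=per_item,
        summary=summary,
        unmatched_a=[k for k in da if k not in db],
        unmatched_b=[k for k in db if k not in da],
    )
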