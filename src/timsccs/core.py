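"""Shared domain types and the CCS library file format.

The library is a flat tab-separated file with a ``#key=value`` metadata
header recording the instrument conditions that a collision cross section
depends on (drift-gas composition, temperature, pressures, mobility range,
ramp time, calibration reference tables), following the ion-mobility
community's metadata reporting recommendations.  One data row corresponds
to one (compound, ion species, calibration reference table) triple.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence, TextIO

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "NEGATIVE_MODE_SPECIES",
    "AggregateStats",
    "CompoundRecord",
    "IonSpeciesAnnotation",
    "InstrumentMetadata",
    "CCSLibraryEntry",
    "LibraryValidationError",
    "LibraryParseError",
    "Violation",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "write_library",
    "read_library",
    "validate_library",
]

# CODATA/IUPAC monoisotopic atomic masses (Da).
ATOMIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "P": 30.97376151,
    "S": 31.97207069,
}

#: Proton mass in Da; deprotonation removes a proton, the electron stays.
PROTON_MASS = 1.00727646688

#: Negative-mode ion species observed for plant natural products.
NEGATIVE_MODE_SPECIES = (
    "[M-H]-",
    "[2M-H]-",
    "[M-3H]-",
    "[M-H+HCO2H]-",
    "[M-H+Na+HCO2]-",
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class LibraryValidationError(ValueError):
    """An entry violates a library invariant; message names the field."""


class LibraryParseError(ValueError):
    """A library file cannot be parsed; message cites column or row."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula such as ``C27H30O16``."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in ATOMIC_MASS:
            raise ValueError(f"unsupported element {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(count) if count else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"malformed formula {formula!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Render an element-count map in Hill order (C, H, then alphabetic)."""
    ordered = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in ordered)


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic (lowest-isotope) mass of a formula, in Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ATOMIC_MASS[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class AggregateStats:
    """Mean / sample SD / relative SD of a set of replicate measurements.

    ``sd`` uses the n-1 denominator (replicates are a sample of the
    measurement population).  ``rsd_percent`` is ``100 * sd / mean``.  A
    single replicate leaves the dispersion undefined (``sd`` is NaN).
    """

    mean: float
    sd: float
    rsd_percent: float
    n: int = 0

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "AggregateStats":
        if not values:
            raise ValueError("no values to aggregate")
        if any(v <= 0 for v in values):
            raise ValueError("aggregated values must be positive")
        n = len(values)
        mean = math.fsum(values) / n
        if n == 1:
            return cls(mean=mean, sd=math.nan, rsd_percent=math.nan, n=1)
        var = math.fsum((v - mean) ** 2 for v in values) / (n - 1)
        sd = math.sqrt(var)
        return cls(mean=mean, sd=sd, rsd_percent=100.0 * sd / mean, n=n)

    @property
    def sd_defined(self) -> bool:
        return not math.isnan(self.sd)

    def is_consistent(self, rel_tol: float = 1e-9) -> bool:
        """Check ``rsd_percent == 100 * sd / mean`` to relative tolerance."""
        if not self.sd_defined:
            return math.isnan(self.rsd_percent)
        expected = 100.0 * self.sd / self.mean
        return math.isclose(self.rsd_percent, expected, rel_tol=rel_tol, abs_tol=1e-12)


@dataclass
class CompoundRecord:
    """An authentic standard: name, formula, neutral monoisotopic mass."""

    name: str
    molecular_formula: dict[str, int] | None = None
    monoisotopic_mass: float = 0.0
    compound_class: str = ""
    retention_time: float | None = None  # minutes

    def __post_init__(self) -> None:
        if isinstance(self.molecular_formula, str):
            self.molecular_formula = parse_formula(self.molecular_formula)
        if self.molecular_formula and not self.monoisotopic_mass:
            self.monoisotopic_mass = monoisotopic_mass(self.molecular_formula)
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.name}: monoisotopic_mass must be > 0")
        if self.molecular_formula is not None:
            computed = monoisotopic_mass(self.molecular_formula)
            if abs(computed - self.monoisotopic_mass) > 1e-3:
                raise ValueError(
                    f"{self.name}: monoisotopic_mass {self.monoisotopic_mass} "
                    f"disagrees with formula mass {computed:.5f} by > 0.001 Da"
                )


@dataclass
class IonSpeciesAnnotation:
    """Assignment of an ion species (adduct/aggregate) to an observed ion."""

    species: str
    charge: int
    mz: float
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.species != "unknown" and self.species not in NEGATIVE_MODE_SPECIES:
            raise ValueError(f"unknown ion species label {self.species!r}")
        if self.charge == 0:
            raise ValueError("charge must be nonzero")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity {self.purity} outside [0, 1]")


@dataclass
class InstrumentMetadata:
    """User-controllable TIMS acquisition parameters that condition a CCS."""

    drift_gas_composition: dict[str, float] = field(
        default_factory=lambda: {"N2": 0.994, "O2": 0.006}
    )
    gas_temperature: float = 305.0  # K
    tunnel_in_pressure: float = 2.50  # mbar
    tunnel_out_pressure: float = 0.74  # mbar
    mobility_range: tuple[float, float] = (0.4, 1.8)  # 1/K0, V*s/cm^2
    ramp_time: float = 90.0  # ms
    icc_target: float = 5e6  # ion count target (charge control)
    polarity: str = "negative"
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.drift_gas_composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"gas composition fractions sum to {total}, not 1")
        lo, hi = self.mobility_range
        if not lo < hi:
            raise ValueError("mobility_range min must be < max")
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"polarity {self.polarity!r}")


@dataclass
class CCSLibraryEntry:
    """Aggregated CCS of one ion species of one compound.

    ``ccs_by_reference`` maps a calibration-reference-table id (e.g. the
    vendor default vs. the community consensus tune-mix values) to the
    replicate-aggregated CCS statistics obtained under that calibration.
    """

    compound: CompoundRecord
    species: IonSpeciesAnnotation
    ccs_by_reference: dict[str, AggregateStats]
    retention_time: float | None = None
    n_replicates: int = 1
    metadata: InstrumentMetadata | None = None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def entry_id(self) -> str:
        return f"{self.compound.name}|{self.species.species}"

    def ccs(self, reference_table_id: str) -> float:
        return self.ccs_by_reference[reference_table_id].mean


@dataclass(frozen=True)
class Violation:
    entry_index: int
    field: str
    message: str


def _check_entry(i: int, entry: CCSLibraryEntry) -> list[Violation]:
    out: list[Violation] = []
    if entry.n_replicates < 1:
        out.append(Violation(i, "n_replicates", "n_replicates must be >= 1"))
    if not entry.ccs_by_reference:
        out.append(Violation(i, "ccs_by_reference", "no CCS values recorded"))
    for ref, stats in entry.ccs_by_reference.items():
        if not stats.mean > 0:
            out.append(Violation(i, "ccs_mean", f"[{ref}] mean CCS {stats.mean} <= 0"))
        if stats.sd_defined and stats.sd < 0:
            out.append(Violation(i, "ccs_sd", f"[{ref}] sd {stats.sd} < 0"))
        if not stats.is_consistent():
            out.append(
                Violation(
                    i,
                    "ccs_rsd_percent",
                    f"[{ref}] rsd {stats.rsd_percent} != 100*sd/mean",
                )
            )
    return out


def validate_library(entries: Sequence[CCSLibraryEntry]) -> list[Violation]:
    """Report invariant violations; an empty report means a valid library.

    Also flags duplicate (compound, species, reference-table) rows, which
    would make a lookup ambiguous.
    """
    report: list[Violation] = []
    for i, entry in enumerate(entries):
        report.extend(_check_entry(i, entry))
    seen: dict[tuple[str, str, str], int] = {}
    for i, entry in enumerate(entries):
        for ref in entry.ccs_by_reference:
            key = (entry.compound.name, entry.species.species, ref)
            if key in seen:
                report.append(
                    Violation(
                        i,
                        "duplicate",
                        f"duplicate row {key} (first seen at entry {seen[key]})",
                    )
                )
            else:
                seen[key] = i
    return report


_COLUMNS = [
    "compound",
    "formula",
    "monoisotopic_mass",
    "compound_class",
    "species",
    "charge",
    "mz",
    "purity",
    "retention_time_min",
    "reference_table",
    "ccs_mean",
    "ccs_sd",
    "ccs_rsd_percent",
    "n_replicates",
    "qc_flags",
]

_META_KEYS = {
    "gas_composition",
    "gas_temperature_K",
    "tunnel_in_pressure_mbar",
    "tunnel_out_pressure_mbar",
    "mobility_range",
    "ramp_time_ms",
    "icc_target",
    "polarity",
    "reference_tables",
    "library_format",
}


def _fmt(x: float | None) -> str:
    # Shortest representation that reparses to the identical float, so a
    # write -> read cycle is the identity on every numeric field.
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return repr(float(x))


def write_library(
    entries: Sequence[CCSLibraryEntry],
    metadata: InstrumentMetadata,
    fh: TextIO,
) -> None:
    """Serialize entries as '#key=value' header lines plus a TSV table.

    Raises :class:`LibraryValidationError` naming the offending field if any
    entry violates an invariant.  CCS and percent values are written with 5
    decimal places.
    """
    report = validate_library(entries)
    if report:
        v = report[0]
        raise LibraryValidationError(
            f"entry {v.entry_index}: field '{v.field}': {v.message}"
        )
    refs = sorted({ref for e in entries for ref in e.ccs_by_reference})
    gas = ",".join(f"{k}:{v:g}" for k, v in metadata.drift_gas_composition.items())
    fh.write("#library_format=timsccs-1\n")
    fh.write(f"#gas_composition={gas}\n")
    fh.write(f"#gas_temperature_K={metadata.gas_temperature:g}\n")
    fh.write(f"#tunnel_in_pressure_mbar={metadata.tunnel_in_pressure:g}\n")
    fh.write(f"#tunnel_out_pressure_mbar={metadata.tunnel_out_pressure:g}\n")
    fh.write(f"#mobility_range={metadata.mobility_range[0]:g},{metadata.mobility_range[1]:g}\n")
    fh.write(f"#ramp_time_ms={metadata.ramp_time:g}\n")
    fh.write(f"#icc_target={metadata.icc_target:g}\n")
    fh.write(f"#polarity={metadata.polarity}\n")
    fh.write(f"#reference_tables={','.join(refs)}\n")
    for key, value in metadata.extra.items():
        fh.write(f"#{key}={value}\n")
    fh.write("\t".join(_COLUMNS) + "\n")
    for entry in entries:
        comp = entry.compound
        formula = format_formula(comp.molecular_formula) if comp.molecular_formula else "NA"
        for ref in sorted(entry.ccs_by_reference):
            stats = entry.ccs_by_reference[ref]
            row = [
                comp.name,
                formula,
                _fmt(comp.monoisotopic_mass),
                comp.compound_class or "NA",
                entry.species.species,
                str(entry.species.charge),
                _fmt(entry.species.mz),
                _fmt(entry.species.purity),
                _fmt(entry.retention_time),
                ref,
                _fmt(stats.mean),
                _fmt(stats.sd),
                _fmt(stats.rsd_percent),
                str(entry.n_replicates),
                ";".join(entry.qc_flags) or "NA",
            ]
            fh.write("\t".join(row) + "\n")


def _parse_float(text: str, row: int, column: str) -> float:
    if text == "NA":
        return math.nan
    try:
        return float(text)
    except ValueError:
        raise LibraryParseError(
            f"row {row}: malformed numeric {text!r} in column '{column}'"
        ) from None


def read_library(fh: TextIO) -> tuple[list[CCSLibraryEntry], InstrumentMetadata]:
    """Read a library file produced by :func:`write_library`.

    Unknown ``#key=value`` header lines are preserved in ``metadata.extra``.
    Rows for the same (compound, species) under different reference tables
    are merged back into a single entry.
    """
    header: dict[str, str] = {}
    columns: list[str] | None = None
    rows: list[dict[str, str]] = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            header[key] = value
            continue
        cells = line.split("\t")
        if columns is None:
            columns = cells
            missing = [c for c in _COLUMNS if c not in columns]
            if missing:
                raise LibraryParseError(f"missing mandatory column '{missing[0]}'")
            continue
        if len(cells) != len(columns):
            raise LibraryParseError(f"row {lineno}: expected {len(columns)} cells")
        rows.append(dict(zip(columns, cells)))

    if columns is None and not header:
        raise LibraryParseError("empty file")

    def meta_float(key: str, default: float) -> float:
        return float(header[key]) if key in header else default

    gas = {"N2": 1.0}
    if "gas_composition" in header and header["gas_composition"]:
        gas = {}
        for part in header["gas_composition"].split(","):
            name, _, frac = part.partition(":")
            gas[name] = float(frac)
    mob = (0.4, 1.8)
    if "mobility_range" in header:
        lo, hi = header["mobility_range"].split(",")
        mob = (float(lo), float(hi))
    metadata = InstrumentMetadata(
        drift_gas_composition=gas,
        gas_temperature=meta_float("gas_temperature_K", 305.0),
        tunnel_in_pressure=meta_float("tunnel_in_pressure_mbar", 2.50),
        tunnel_out_pressure=meta_float("tunnel_out_pressure_mbar", 0.74),
        mobility_range=mob,
        ramp_time=meta_float("ramp_time_ms", 90.0),
        icc_target=meta_float("icc_target", 5e6),
        polarity=header.get("polarity", "negative"),
        extra={k: v for k, v in header.items() if k not in _META_KEYS},
    )

    entries: dict[tuple[str, str], CCSLibraryEntry] = {}
    for i, row in enumerate(rows, start=1):
        formula = row["formula"] if row["formula"] != "NA" else None
        compound = CompoundRecord(
            name=row["compound"],
            molecular_formula=parse_formula(formula) if formula else None,
            monoisotopic_mass=_parse_float(row["monoisotopic_mass"], i, "monoisotopic_mass"),
            compound_class="" if row["compound_class"] == "NA" else row["compound_class"],
        )
        rt = _parse_float(row["retention_time_min"], i, "retention_time_min")
        compound.retention_time = None if math.isnan(rt) else rt
        try:
            charge = int(row["charge"])
        except ValueError:
            raise LibraryParseError(
                f"row {i}: malformed numeric {row['charge']!r} in column 'charge'"
            ) from None
        stats = AggregateStats(
            mean=_parse_float(row["ccs_mean"], i, "ccs_mean"),
            sd=_parse_float(row["ccs_sd"], i, "ccs_sd"),
            rsd_percent=_parse_float(row["ccs_rsd_percent"], i, "ccs_rsd_percent"),
            n=int(row["n_replicates"]),
        )
        key = (compound.name, row["species"])
        if key not in entries:
            entries[key] = CCSLibraryEntry(
                compound=compound,
                species=IonSpeciesAnnotation(
                    species=row["species"],
                    charge=charge,
                    mz=_parse_float(row["mz"], i, "mz"),
                    purity=_parse_float(row["purity"], i, "purity"),
                ),
                ccs_by_reference={},
                retention_time=compound.retention_time,
                n_replicates=int(row["n_replicates"]),
                metadata=metadata,
                qc_flags=[] if row["qc_flags"] == "NA" else row["qc_flags"].split(";"),
            )
        entries[key].ccs_by_reference[row["reference_table"]] = stats

    result = list(entries.values())
    for v in (x for e in result for x in _check_entry(0, e) if x.field == "ccs_rsd_percent"):
        raise LibraryParseError(f"inconsistent aggregate statistics on read: {v.message}")
    return result, metadata
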