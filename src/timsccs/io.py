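"""Frame-stack and reference-table file I/O.

The native frame-stack format is JSON lines: one frame per line with the
raw mobility reading and parallel centroid arrays, plus an optional
leading header object.  mzML files whose spectra carry an inverse reduced
ion mobility value can be ingested through pyteomics.
"""

from __future__ import annotations

import json
from typing import TextIO

import numpy as np

from .mobilogram import FrameStack
from .physics import ReferenceCalibrantTable

__all__ = [
    "write_frames_jsonl",
    "read_frames_jsonl",
    "read_frames_mzml",
    "read_reference_table",
    "write_reference_table",
]


def write_frames_jsonl(frames: FrameStack, fh: TextIO) -> None:
    """One JSON object per frame: {"raw": x, "mz": [...], "intensity": [...]}."""
    header = {"format": "timsccs-frames-1", "calibrated": frames.axis_is_calibrated}
    fh.write(json.dumps(header) + "\n")
    for raw, (mz, inten) in zip(frames.raw_axis, frames.spectra):
        fh.write(
            json.dumps(
                {
                    "raw": float(raw),
                    "mz": [float(x) for x in mz],
                    "intensity": [float(x) for x in inten],
                }
            )
            + "\n"
        )


def read_frames_jsonl(fh: TextIO) -> FrameStack:
    axis: list[float] = []
    spectra: list[tuple[np.ndarray, np.ndarray]] = []
    calibrated = False
    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"line {lineno}: invalid JSON ({exc.msg})") from None
        if "format" in obj:
            calibrated = bool(obj.get("calibrated", False))
            continue
        if "raw" not in obj:
            raise ValueError(f"line {lineno}: frame object missing 'raw'")
        axis.append(float(obj["raw"]))
        mz = np.asarray(obj.get("mz", []), dtype=float)
        inten = np.asarray(obj.get("intensity", []), dtype=float)
        if mz.size != inten.size:
            raise ValueError(f"line {lineno}: mz/intensity length mismatch")
        spectra.append((mz, inten))
    return FrameStack(
        raw_axis=np.asarray(axis), spectra=spectra, axis_is_calibrated=calibrated
    )


def _decode_binary_array(elem) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, zlib or plain)."""
    import base64
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"
    accessions = {
        cv.get("accession") for cv in elem.iter(f"{ns}cvParam")
    } | {cv.get("accession") for cv in elem.iter("cvParam")}
    binary = elem.find(f"{ns}binary")
    if binary is None:
        binary = elem.find("binary")
    data = base64.b64decode((binary.text or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        data = zlib.decompress(data)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(data, dtype=dtype).astype(float)


def read_frames_mzml(path: str) -> FrameStack:
    """Ingest an mzML file whose spectra carry ion-mobility values.

    Each spectrum with an ``inverse reduced ion mobility`` cvParam
    (MS:1002815) becomes one frame; the axis is sorted into increasing
    mobility and flagged calibrated, since mzML stores physical 1/K0.
    Only the spectrum list is read (centroid arrays, 32/64-bit float,
    plain or zlib), which is the subset ion-mobility exports use.
    """
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    frames: list[tuple[float, np.ndarray, np.ndarray]] = []
    for _, spectrum in etree.iterparse(path, tag=(f"{ns}spectrum", "spectrum")):
        mobility = None
        for cv in spectrum.iter(f"{ns}cvParam", "cvParam"):
            if cv.get("accession") == "MS:1002815":
                mobility = float(cv.get("value"))
                break
        if mobility is not None:
            arrays: dict[str, np.ndarray] = {}
            for bda in spectrum.iter(f"{ns}binaryDataArray", "binaryDataArray"):
                accs = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam", "cvParam")}
                if "MS:1000514" in accs:
                    arrays["mz"] = _decode_binary_array(bda)
                elif "MS:1000515" in accs:
                    arrays["intensity"] = _decode_binary_array(bda)
            if "mz" in arrays and "intensity" in arrays:
                frames.append((mobility, arrays["mz"], arrays["intensity"]))
        spectrum.clear()
    if not frames:
        raise ValueError("no ion-mobility spectra found in mzML file")
    frames.sort(key=lambda f: f[0])
    return FrameStack(
        raw_axis=np.array([f[0] for f in frames]),
        spectra=[(f[1], f[2]) for f in frames],
        axis_is_calibrated=True,
    )


def read_reference_table(fh: TextIO, table_id: str | None = None) -> ReferenceCalibrantTable:
    """TSV with columns table_id, mz, charge, reference_ccs (header row)."""
    rows = []
    file_table_id = table_id
    header: list[str] | None = None
    for line in fh:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
            for col in ("table_id", "mz", "charge", "reference_ccs"):
                if col not in header:
                    raise ValueError(f"reference table missing column '{col}'")
            continue
        record = dict(zip(header, cells))
        file_table_id = file_table_id or record["table_id"]
        rows.append(
            (float(record["mz"]), int(record["charge"]), float(record["reference_ccs"]))
        )
    if header is None or not rows:
        raise ValueError("empty reference table")
    return ReferenceCalibrantTable(table_id=file_table_id or "default", rows=tuple(rows))


def write_reference_table(table: ReferenceCalibrantTable, fh: TextIO) -> None:
    fh.write("table_id\tmz\tcharge\treference_ccs\n")
    for mz, charge, ccs in table.rows:
        fh.write(f"{table.table_id}\t{mz!r}\t{charge}\t{ccs!r}\n")
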