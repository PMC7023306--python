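"""Ion mobilogram construction, smoothing, peak picking and purity.

A :class:`FrameStack` holds one centroided mass spectrum per mobility bin.
From it we derive an extracted ion mobilogram (EIM: summed intensity of
centroids near one target m/z per bin) or a base peak mobilogram (BPM:
maximum centroid intensity per bin), smooth with a single-cycle
Savitzky-Golay filter over a 0.005 V*s/cm^2 window, and pick mobility
peaks with vendor-style parameters: sensitivity 97 (detection floor at 3%
of the base peak), relative intensity threshold 15% and minimum peak
valley 10%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .physics import CalibrationModel, MobilityPhysicsContext, apply_calibration, ccs_from_inverse_k0

__all__ = [
    "FrameStack",
    "Mobilogram",
    "MobilityPeak",
    "extract_eim",
    "extract_bpm",
    "smooth",
    "pick_peaks",
    "peak_purity",
    "apex_ccs",
    "tims_resolving_power",
]

# FWHM of a Gaussian is 2*sqrt(2*ln 2) sigma; base width uses the 4 sigma
# convention, so base = FWHM * 4 / 2.35482.
_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class FrameStack:
    """Per-mobility-bin centroided spectra from one ion-mobility ramp."""

    raw_axis: np.ndarray  # strictly monotonic mobility readings, one per bin
    spectra: list[tuple[np.ndarray, np.ndarray]]  # per bin: (mz, intensity)
    axis_is_calibrated: bool = False  # True when raw_axis is already 1/K0

    def __post_init__(self) -> None:
        self.raw_axis = np.asarray(self.raw_axis, dtype=float)
        if len(self.spectra) != self.raw_axis.size:
            raise ValueError("one spectrum per axis bin required")
        diffs = np.diff(self.raw_axis)
        if self.raw_axis.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("mobility axis must be strictly monotonic")
        self.spectra = [
            (np.asarray(mz, dtype=float), np.asarray(inten, dtype=float))
            for mz, inten in self.spectra
        ]
        for _, inten in self.spectra:
            if inten.size and inten.min() < 0:
                raise ValueError("centroid intensities must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(self.raw_axis.size)


@dataclass
class Mobilogram:
    """Intensity versus mobility trace (EIM or BPM)."""

    axis: np.ndarray
    intensity: np.ndarray
    kind: str = "EIM"  # "EIM" or "BPM"
    target_mz: float | None = None
    tolerance: float | None = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.size != self.intensity.size:
            raise ValueError("axis and intensity lengths differ")
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("mobilogram axis must be strictly increasing")
        if self.kind not in ("EIM", "BPM"):
            raise ValueError(f"kind {self.kind!r}")

    @property
    def bin_spacing(self) -> float:
        if self.axis.size < 2:
            raise ValueError("axis too short to define a spacing")
        return float(np.median(np.diff(self.axis)))


@dataclass
class MobilityPeak:
    """One picked mobility peak.

    Position and widths are stored in the source mobilogram's axis units
    (raw readings, or 1/K0 for a calibrated axis).  The CCS-domain fields
    are filled by :func:`apex_ccs` once a calibration is available.
    """

    apex_inv_k0: float
    height: float
    fwhm_inv_k0: float
    base_width_inv_k0: float
    area: float
    purity: float | None = None
    apex_ccs: float | None = None
    fwhm_ccs: float | None = None
    base_width_ccs: float | None = None
    apex_index: int = field(default=-1, repr=False)


def _oriented(frames: FrameStack) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """Return axis/spectra sorted by increasing mobility reading."""
    if frames.n_bins > 1 and frames.raw_axis[1] < frames.raw_axis[0]:
        return frames.raw_axis[::-1].copy(), frames.spectra[::-1]
    return frames.raw_axis.copy(), list(frames.spectra)


def _mz_window(target_mz: float, tol: float, ppm: bool) -> float:
    return target_mz * tol * 1e-6 if ppm else tol


def extract_eim(
    frames: FrameStack, target_mz: float, tol: float = 0.01, ppm: bool = False
) -> Mobilogram:
    """Extracted ion mobilogram: summed centroid intensity near target m/z."""
    if tol <= 0:
        raise ValueError("tolerance must be > 0")
    axis, spectra = _oriented(frames)
    window = _mz_window(target_mz, tol, ppm)
    intensity = np.zeros(len(spectra))
    for i, (mz, inten) in enumerate(spectra):
        if mz.size:
            intensity[i] = inten[np.abs(mz - target_mz) <= window].sum()
    return Mobilogram(axis, intensity, kind="EIM", target_mz=target_mz, tolerance=tol)


def extract_bpm(frames: FrameStack) -> Mobilogram:
    """Base peak mobilogram: maximum centroid intensity per bin."""
    axis, spectra = _oriented(frames)
    intensity = np.array([inten.max() if inten.size else 0.0 for _, inten in spectra])
    return Mobilogram(axis, intensity, kind="BPM")


def smooth(
    m: Mobilogram,
    window_mobility: float = 0.005,
    cycles: int = 1,
    poly_order: int = 2,
) -> Mobilogram:
    """Savitzky-Golay smoothing over a mobility-width window.

    The window is the nearest odd point count >= window_mobility divided by
    the bin spacing (the filter needs an odd window), with reflect padding
    at the edges.  ``cycles`` repeats the filter.
    """
    n_points = int(math.ceil(window_mobility / m.bin_spacing))
    if n_points % 2 == 0:
        n_points += 1
    if n_points < 5:
        raise ValueError(
            f"smoothing window of {n_points} points (< 5) at this bin spacing"
        )
    if n_points > m.intensity.size:
        raise ValueError("smoothing window exceeds mobilogram length")
    y = m.intensity
    for _ in range(cycles):
        y = savgol_filter(y, n_points, poly_order, mode="mirror")
    return replace(m, intensity=np.clip(y, 0.0, None))


def _half_crossing(axis: np.ndarray, y: np.ndarray, apex: int, level: float, step: int) -> float:
    """Axis position where y crosses ``level`` walking from apex by ``step``."""
    i = apex
    while 0 <= i + step < y.size and y[i + step] > level:
        i += step
    j = i + step
    if not 0 <= j < y.size:  # ran off the edge: use the edge position
        return float(axis[i])
    if y[i] == y[j]:
        return float(axis[j])
    frac = (y[i] - level) / (y[i] - y[j])
    return float(axis[i] + frac * (axis[j] - axis[i]))


def pick_peaks(
    m: Mobilogram,
    sensitivity: float = 97.0,
    rel_intensity_threshold: float = 15.0,
    min_valley: float = 10.0,
) -> list[MobilityPeak]:
    """Detect mobility peaks with vendor-style picking parameters.

    Local maxima above the detection floor ((100 - sensitivity)% of the
    base intensity) are candidates.  Adjacent candidates are merged unless
    the valley between them drops by at least ``min_valley`` percent of
    the lower apex.  Surviving peaks below ``rel_intensity_threshold``
    percent of the base peak are discarded.  FWHM is measured by linear
    interpolation at half height; the 4-sigma base width assumes a locally
    Gaussian shape (FWHM * 4 / 2.3548).
    """
    for name, value in (
        ("sensitivity", sensitivity),
        ("rel_intensity_threshold", rel_intensity_threshold),
        ("min_valley", min_valley),
    ):
        if not 0 < value <= 100:
            raise ValueError(f"{name} must be in (0, 100]")
    y = m.intensity
    if y.size == 0 or y.max() <= 0:
        return []
    base = float(y.max())
    floor = (100.0 - sensitivity) / 100.0 * base
    idx, _ = find_peaks(y, height=max(floor, 0.0) or None)
    candidates = list(idx)
    if not candidates:  # e.g. maximum sits on an edge bin
        candidates = [int(np.argmax(y))]

    merged = True
    while merged and len(candidates) > 1:
        merged = False
        for i in range(len(candidates) - 1):
            a, b = candidates[i], candidates[i + 1]
            valley = float(y[a : b + 1].min())
            lower = min(y[a], y[b])
            if valley > (1.0 - min_valley / 100.0) * lower:
                drop = i + 1 if y[a] >= y[b] else i
                candidates.pop(drop)
                merged = True
                break

    threshold = rel_intensity_threshold / 100.0 * base
    kept = [i for i in candidates if y[i] >= threshold]

    peaks: list[MobilityPeak] = []
    for i in kept:
        apex_x = float(m.axis[i])
        # Sub-bin apex via a three-point parabola; on log intensity a
        # sampled Gaussian has an exactly quadratic apex, so the vertex is
        # recovered far below the bin spacing.
        if 0 < i < y.size - 1 and y[i - 1] > 0 and y[i + 1] > 0 and y[i] > 0:
            ym, y0, yp = (
                (math.log(y[i - 1]), math.log(y[i]), math.log(y[i + 1]))
                if min(y[i - 1 : i + 2]) > 0
                else (y[i - 1], y[i], y[i + 1])
            )
            denom = ym - 2.0 * y0 + yp
            if denom < 0:
                shift = 0.5 * (ym - yp) / denom
                if abs(shift) <= 0.5:
                    apex_x = float(m.axis[i] + shift * m.bin_spacing)
        half = y[i] / 2.0
        left = _half_crossing(m.axis, y, i, half, -1)
        right = _half_crossing(m.axis, y, i, half, +1)
        fwhm = max(right - left, m.bin_spacing * 1e-6)
        base_width = fwhm * 4.0 / _FWHM_PER_SIGMA
        lo = np.searchsorted(m.axis, m.axis[i] - base_width / 2.0)
        hi = np.searchsorted(m.axis, m.axis[i] + base_width / 2.0, side="right")
        area = float(np.trapezoid(y[lo:hi], m.axis[lo:hi])) if hi - lo > 1 else 0.0
        peaks.append(
            MobilityPeak(
                apex_inv_k0=apex_x,
                height=float(y[i]),
                fwhm_inv_k0=float(fwhm),
                base_width_inv_k0=float(base_width),
                area=area,
                apex_index=int(i),
            )
        )
    return peaks


def peak_purity(
    frames: FrameStack,
    peak: MobilityPeak,
    target_mz: float,
    tol: float = 0.01,
    ppm: bool = False,
) -> float:
    """Fraction of total centroid intensity near target m/z over the peak.

    The peak extent is its 4-sigma base width around the apex.  A zero
    total intensity in the extent yields purity 0 (degenerate window).
    """
    axis, spectra = _oriented(frames)
    lo = peak.apex_inv_k0 - peak.base_width_inv_k0 / 2.0
    hi = peak.apex_inv_k0 + peak.base_width_inv_k0 / 2.0
    window = _mz_window(target_mz, tol, ppm)
    target = total = 0.0
    for pos, (mz, inten) in zip(axis, spectra):
        if lo <= pos <= hi and inten.size:
            total += float(inten.sum())
            target += float(inten[np.abs(mz - target_mz) <= window].sum())
    if total == 0.0:
        return 0.0
    return target / total


def apex_ccs(
    peak: MobilityPeak,
    model: CalibrationModel | None,
    mz: float,
    ctx: MobilityPhysicsContext | None = None,
) -> float:
    """Convert a peak apex to CCS and fill the peak's CCS-domain fields.

    The apex raw reading goes through the calibration into 1/K0 and then
    through the Mason-Schamp relation.  Widths convert with the same
    (linear) chain, so resolving power is identical in both domains.
    ``model=None`` treats the axis as already calibrated (identity).
    """
    ctx = ctx or MobilityPhysicsContext()
    if model is None:
        inv_k0 = peak.apex_inv_k0
        slope = 1.0
    else:
        inv_k0, _ = apply_calibration(model, peak.apex_inv_k0)
        slope = abs(model.slope)
    if inv_k0 <= 0:
        raise ValueError("calibrated apex mobility is nonpositive")
    ccs = ccs_from_inverse_k0(inv_k0, mz, ctx)
    scale = ccs / inv_k0 * slope  # A^2 per raw-axis unit
    peak.apex_ccs = ccs
    peak.fwhm_ccs = peak.fwhm_inv_k0 * scale
    peak.base_width_ccs = peak.base_width_inv_k0 * scale
    return ccs


def tims_resolving_power(peak: MobilityPeak) -> float:
    """Single-peak resolving power R = apex / FWHM.

    Uses CCS-domain values when present, else the mobility domain; the two
    agree because CCS is proportional to 1/K0 at fixed m/z.
    """
    if peak.apex_ccs is not None and peak.fwhm_ccs:
        return peak.apex_ccs / peak.fwhm_ccs
    if peak.fwhm_inv_k0 <= 0:
        raise ValueError("peak FWHM must be > 0")
    return peak.apex_inv_k0 / peak.fwhm_inv_k0
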