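"""Peak capacity and pairwise isomer resolution analysis.

Peak capacity P = 1 + t_g / mean(w) estimates how many components a
gradient of length t_g can resolve given 4-sigma base peak widths w; for
a multi-dimensional platform the capacities of orthogonal dimensions
multiply.  Pairwise resolution Rpp = |delta CCS| / mean(W_CCS) (equal to
the same ratio in 1/K0 units) quantifies isomer separability: Rpp = 1 is
baseline separation at 4 sigma, 0.5 roughly half-height separation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PeakCapacityRequest",
    "ResolutionMatrix",
    "peak_capacity",
    "multidim_peak_capacity",
    "rpp",
    "isomer_matrix",
    "rpp_color",
]


@dataclass(frozen=True)
class PeakCapacityRequest:
    """Gradient time plus the 4-sigma base widths of representative peaks."""

    gradient_time: float  # minutes
    peak_widths: tuple[float, ...]  # minutes, 4-sigma base widths

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_widths", tuple(self.peak_widths))
        if self.gradient_time <= 0:
            raise ValueError("gradient_time must be > 0")
        if not self.peak_widths or any(w <= 0 for w in self.peak_widths):
            raise ValueError("all peak widths must be > 0")

    @property
    def n(self) -> int:
        return len(self.peak_widths)


@dataclass
class ResolutionMatrix:
    """All pairwise resolutions within an isomer group."""

    group_id: str
    members: list[tuple[str, float, float]]  # name, apex_ccs, base_width_ccs
    rpp: np.ndarray  # symmetric, zero diagonal
    counts: dict[float, int]  # threshold -> pairs with Rpp >= threshold

    @property
    def n_pairs(self) -> int:
        n = len(self.members)
        return n * (n - 1) // 2


def peak_capacity(req: PeakCapacityRequest) -> float:
    """P = 1 + gradient time / average 4-sigma base width."""
    mean_width = math.fsum(req.peak_widths) / req.n
    if mean_width <= 0:
        raise ValueError("mean peak width must be > 0")
    return 1.0 + req.gradient_time / mean_width


def multidim_peak_capacity(capacities: Sequence[float]) -> float:
    """Total capacity of orthogonal dimensions: the product, not the sum."""
    if not capacities:
        raise ValueError("need at least one dimension")
    if any(c <= 0 for c in capacities):
        raise ValueError("capacities must be > 0")
    return float(math.prod(capacities))


def rpp(
    peak_a: tuple[float, float], peak_b: tuple[float, float]
) -> float:
    """Pairwise resolution |delta apex| / mean(base widths).

    Peaks are (apex, 4-sigma base width) in CCS units; because CCS is
    proportional to 1/K0 at fixed m/z, computing in mobility units gives
    the identical number.
    """
    apex_a, width_a = peak_a
    apex_b, width_b = peak_b
    if width_a <= 0 or width_b <= 0:
        raise ValueError("peak widths must be > 0")
    return abs(apex_a - apex_b) / ((width_a + width_b) / 2.0)


def rpp_color(r: float) -> str:
    """Heat-map class for a pairwise resolution value."""
    if r > 1.0:
        return "green"
    if r > 0.5:
        return "yellow"
    if r > 0.25:
        return "white"
    return "red"


def isomer_matrix(
    members: Sequence[tuple[str, float, float]],
    thresholds: Sequence[float] = (0.25, 0.5, 1.0),
    group_id: str = "",
) -> ResolutionMatrix:
    """Pairwise resolution matrix over an isomer group with threshold counts.

    ``members`` are (name, apex_ccs, base_width_ccs).  ``counts`` reports,
    per threshold, how many of the n(n-1)/2 unordered pairs reach at least
    that resolution — the quantity that grows as TIMS resolving power
    increases.
    """
    if len(members) < 2:
        raise ValueError("an isomer group needs at least 2 members")
    n = len(members)
    matrix = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        r = rpp(members[i][1:], members[j][1:])
        matrix[i, j] = matrix[j, i] = r
    pair_values = [matrix[i, j] for i, j in itertools.combinations(range(n), 2)]
    counts = {float(t): sum(1 for v in pair_values if v >= t) for t in thresholds}
    return ResolutionMatrix(
        group_id=group_id, members=list(members), rpp=matrix, counts=counts
    )
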