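"""Distance binning and the three-class side-chain orientation classifier.

An ordered residue pair (i -> j) is characterised by three vectors:

* ``a`` — Calpha->Cbeta of residue i,
* ``b`` — Calpha->Cbeta of residue j,
* ``c`` — Calpha_i -> Calpha_j.

The pair is PARALLEL when ``a . b > 0``; otherwise it is ANTIPARALLEL_FACING
when ``a . c > 0`` and ANTIPARALLEL_AWAY when both products are non-positive.

Distances fall into half-open bins: the first bin covers [0, first_bin_upper)
(default 4 A) and each subsequent bin spans ``bin_width`` (default 1 A) up to
``max_distance``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "OrientationClass",
    "DistanceBinning",
    "OUT_OF_RANGE",
    "orientation_class",
    "orientation_classes",
    "distance_bin",
    "distance_bins",
    "DegenerateGeometryError",
]

#: Sentinel bin index for distances at or beyond ``max_distance``.
OUT_OF_RANGE: int = -1

_DOT_EPS = 0.0  # ties (dot == 0) go to the "non-positive" branch exactly as defined


class DegenerateGeometryError(ValueError):
    """Raised when orientation vectors have zero length or backbone is degenerate."""


class OrientationClass(IntEnum):
    PARALLEL = 0
    ANTIPARALLEL_FACING = 1
    ANTIPARALLEL_AWAY = 2


@dataclass(frozen=True)
class DistanceBinning:
    """Half-open distance bins: [0, 4), [4, 5), ... [max-1, max)."""

    first_bin_upper: float = 4.0
    bin_width: float = 1.0
    max_distance: float = 20.0

    def __post_init__(self) -> None:
        if self.first_bin_upper <= 0 or self.bin_width <= 0:
            raise ValueError("bin parameters must be positive")
        span = self.max_distance - self.first_bin_upper
        n = span / self.bin_width
        if span < 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                "max_distance - first_bin_upper must be a whole number of bin widths"
            )

    @property
    def n_bins(self) -> int:
        return 1 + int(round((self.max_distance - self.first_bin_upper) / self.bin_width))

    def edges(self) -> np.ndarray:
        """Bin edges, length n_bins + 1, starting at 0."""
        upper = self.first_bin_upper + self.bin_width * np.arange(self.n_bins)
        return np.concatenate([[0.0], upper])

    def to_header(self) -> dict[str, float]:
        return {
            "first_bin_upper": self.first_bin_upper,
            "bin_width": self.bin_width,
            "max_distance": self.max_distance,
        }


def distance_bin(d: float, binning: DistanceBinning) -> int:
    """Bin index for distance ``d`` (A), or ``OUT_OF_RANGE`` if d >= max_distance."""
    if d < 0:
        raise ValueError(f"negative distance: {d}")
    if d >= binning.max_distance:
        return OUT_OF_RANGE
    if d < binning.first_bin_upper:
        return 0
    return 1 + int((d - binning.first_bin_upper) / binning.bin_width)


def distance_bins(d: np.ndarray, binning: DistanceBinning) -> np.ndarray:
    """Vectorised :func:`distance_bin`; returns int array with OUT_OF_RANGE sentinels."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative distance")
    out = np.where(
        d < binning.first_bin_upper,
        0,
        1 + np.floor((d - binning.first_bin_upper) / binning.bin_width).astype(int),
    )
    out = np.where(d >= binning.max_distance, OUT_OF_RANGE, out)
    return out.astype(int)


def orientation_class(ca_i, cb_i, ca_j, cb_j) -> OrientationClass:
    """Classify the ordered pair i -> j from the four atom positions."""
    ca_i = np.asarray(ca_i, dtype=float)
    cb_i = np.asarray(cb_i, dtype=float)
    ca_j = np.asarray(ca_j, dtype=float)
    cb_j = np.asarray(cb_j, dtype=float)
    a = cb_i - ca_i
    b = cb_j - ca_j
    c = ca_j - ca_i
    if not (np.dot(a, a) > 0 and np.dot(b, b) > 0 and np.dot(c, c) > 0):
        raise DegenerateGeometryError("degenerate orientation geometry")
    if np.dot(a, b) > _DOT_EPS:
        return OrientationClass.PARALLEL
    if np.dot(a, c) > _DOT_EPS:
        return OrientationClass.ANTIPARALLEL_FACING
    return OrientationClass.ANTIPARALLEL_AWAY


def orientation_classes(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """Orientation class of every ordered pair in a chain.

    Parameters
    ----------
    ca, cb : (n, 3) arrays of Calpha and Cbeta coordinates.

    Returns
    -------
    (n, n) int array; entry [i, j] is the class of i -> j. The diagonal is
    meaningless and set to -1.
    """
    a = cb - ca  # (n, 3)
    dot_ab = a @ a.T
    # dot_ac[i, j] = a_i . (ca_j - ca_i)
    dot_ac = a @ ca.T - np.sum(a * ca, axis=1)[:, None]
    out = np.where(
        dot_ab > 0,
        int(OrientationClass.PARALLEL),
        np.where(
            dot_ac > 0,
            int(OrientationClass.ANTIPARALLEL_FACING),
            int(OrientationClass.ANTIPARALLEL_AWAY),
        ),
    )
    np.fill_diagonal(out, -1)
    return out
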