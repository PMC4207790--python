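"""Three-phase segmentation of colony growth curves and mask-based area.

Adapting colonies show an exponential micro-colony phase, a long division
arrest, and a slow resumption of growth.  ``segment_phases`` fits a
continuous three-segment piecewise-linear model to log(area) by exhaustive
search over changepoint pairs on the observation grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

DEFAULT_S_FLAT = 0.005  # |slope| below this (per hour, log scale) counts as arrest
DEFAULT_S_MIN = 0.02  # slope above this counts as visible growth


@dataclass(frozen=True)
class AreaTimeSeries:
    """Colony area (pixels) sampled at strictly increasing times (hours)."""

    t: np.ndarray
    area: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        area = np.asarray(self.area, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "area", area)
        if t.ndim != 1 or area.shape != t.shape:
            raise ValueError("t and area must be 1-D arrays of equal length")
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(area <= 0):
            raise ValueError("areas must be positive (log-transformable)")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class PhaseSegmentation:
    t1: float
    t2: float
    s1: float
    s2: float
    s3: float
    sse: float
    valid_three_phase: bool

    @property
    def slopes(self) -> tuple[float, float, float]:
        return (self.s1, self.s2, self.s3)


def segment_phases(
    series: AreaTimeSeries,
    min_segment_points: int = 4,
    *,
    s_flat: float = DEFAULT_S_FLAT,
    s_min: float = DEFAULT_S_MIN,
) -> PhaseSegmentation:
    """Segment a growth curve into three phases.

    Fits ``log(area) ~ continuous piecewise-linear`` with two changepoints
    restricted to observation times, minimising the residual sum of squares
    over all admissible changepoint pairs (each segment keeps at least
    ``min_segment_points`` observations).  Ties are broken towards the
    earliest ``(t1, t2)`` pair.
    """
    n = len(series)
    if n < 3 * min_segment_points:
        raise ValueError(
            f"need at least {3 * min_segment_points} observations, got {n}"
        )
    t = series.t
    y = np.log(series.area)
    ones = np.ones(n)

    best = None  # (sse, i, j, coef)
    for i in range(min_segment_points - 1, n - 2 * min_segment_points):
        h1 = np.maximum(t - t[i], 0.0)
        for j in range(i + min_segment_points, n - min_segment_points):
            h2 = np.maximum(t - t[j], 0.0)
            X = np.column_stack((ones, t, h1, h2))
            coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(res[0]) if res.size else float(
                np.sum((y - X @ coef) ** 2)
            )
            if best is None or sse < best[0]:
                best = (sse, i, j, coef)

    sse, i, j, coef = best
    s1 = float(coef[1])
    s2 = float(coef[1] + coef[2])
    s3 = float(coef[1] + coef[2] + coef[3])
    valid = (s1 > s_min) and (abs(s2) < s_flat) and (s3 > s_min)
    return PhaseSegmentation(
        t1=float(t[i]), t2=float(t[j]), s1=s1, s2=s2, s3=s3,
        sse=sse, valid_three_phase=valid,
    )


def colony_area(mask) -> int:
    """Area in pixels of the largest 4-connected component of a binary mask.

    Detached debris (smaller components) is ignored.  An empty mask yields
    area 0 with a warning.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be a 2-D grid")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    if not arr.any():
        warnings.warn("empty mask: colony area is 0", stacklevel=2)
        return 0
    # default structure is 4-connectivity
    labels, n = ndimage.label(arr)
    sizes = ndimage.sum_labels(arr, labels, index=np.arange(1, n + 1))
    return int(sizes.max())
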