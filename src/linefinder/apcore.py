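"""Arithmetic-progression identities and the min–max–sum (MMS) statistic.

A straight line ``y = m*x + c`` sampled on a unit index grid is a finite
arithmetic progression (AP).  For any AP the classical sum identity gives

    (a_1 + a_n) / S_n = 2/n,

independently of the terms themselves, so ``2/n`` acts as a global indicator
of agreement with a line.  The statistic used throughout this package is the
pair of MMS ratios

    MMS_max = (a_max - a_min) / (S_n - a_min * n)
    MMS_min = (a_max - a_min) / (a_max * n - S_n)

For a series that agrees with the constant form ``y = c`` both ratios equal
``2/n`` exactly; a ratio exceeding the threshold ``R = 2/n + w`` flags the
maximum (respectively minimum) element as disagreeing with the fit.  The
ratios satisfy the reciprocal identity ``1/MMS_max + 1/MMS_min = n`` and are
both bounded by 1, which bounds the admissible weight ``0 <= w <= 1 - 2/n``.

These primitives make no distributional assumption whatsoever; they only use
order statistics and the sum.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger("linefinder")

#: Relative scale of the "equal to zero" tolerance: comparisons against zero
#: use ``DEFAULT_EPS_SCALE * max|a|`` of the series under consideration.
DEFAULT_EPS_SCALE = 1e-9


class DegenerateSeriesError(ValueError):
    """The series admits no meaningful statistic (e.g. zero sum, all equal)."""


def zero_tolerance(values: np.ndarray, eps_scale: float = DEFAULT_EPS_SCALE) -> float:
    """Absolute tolerance for treating a value of *values*' scale as zero."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return 0.0
    return eps_scale * float(np.max(np.abs(values)))


@dataclass(frozen=True)
class SeriesPoint:
    """A single observation: ordinal index ``x`` and measured value ``a``."""

    x: float
    a: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.a)):
            raise ValueError(f"non-finite point ({self.x}, {self.a})")


class TimeSeries:
    """An ordered series of (x, a) points with strictly increasing x.

    Gaps in x are allowed and meaningful: the method never re-indexes after a
    removal, which is what makes it free of missing-data imputation.
    """

    __slots__ = ("_x", "_a")

    def __init__(self, x: Iterable[float], a: Iterable[float]) -> None:
        x_arr = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
        a_arr = np.asarray(list(a) if not isinstance(a, np.ndarray) else a, dtype=float)
        if x_arr.ndim != 1 or a_arr.ndim != 1 or x_arr.size != a_arr.size:
            raise ValueError("x and a must be one-dimensional and equally long")
        if not (np.all(np.isfinite(x_arr)) and np.all(np.isfinite(a_arr))):
            raise ValueError("series contains non-finite values")
        if x_arr.size >= 2 and not np.all(np.diff(x_arr) > 0):
            raise ValueError("x values must be strictly increasing")
        x_arr.setflags(write=False)
        a_arr.setflags(write=False)
        self._x = x_arr
        self._a = a_arr

    @classmethod
    def from_points(cls, points: Iterable[SeriesPoint | tuple]) -> "TimeSeries":
        pts = [(p.x, p.a) if isinstance(p, SeriesPoint) else tuple(p) for p in points]
        return cls([p[0] for p in pts], [p[1] for p in pts])

    # -- raw access -------------------------------------------------------
    @property
    def x(self) -> np.ndarray:
        return self._x

    @property
    def a(self) -> np.ndarray:
        return self._a

    # -- derived quantities -----------------------------------------------
    @property
    def n(self) -> int:
        return int(self._x.size)

    @property
    def s_n(self) -> float:
        return float(self._a.sum())

    @property
    def a_first(self) -> float:
        return float(self._a[0])

    @property
    def a_last(self) -> float:
        return float(self._a[-1])

    @property
    def a_max(self) -> float:
        return float(self._a.max())

    @property
    def a_min(self) -> float:
        return float(self._a.min())

    @property
    def points(self) -> tuple[SeriesPoint, ...]:
        return tuple(SeriesPoint(float(xi), float(ai)) for xi, ai in zip(self._x, self._a))

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[SeriesPoint]:
        return iter(self.points)

    def __getitem__(self, i: int) -> SeriesPoint:
        return SeriesPoint(float(self._x[i]), float(self._a[i]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeSeries):
            return NotImplemented
        return self._x.size == other._x.size and bool(
            np.array_equal(self._x, other._x) and np.array_equal(self._a, other._a)
        )

    def __repr__(self) -> str:
        return f"TimeSeries(n={self.n}, x=[{self._x[0] if self.n else ''}..{self._x[-1] if self.n else ''}])"

    def subset(self, indices: Sequence[int] | np.ndarray) -> "TimeSeries":
        """A new series restricted to *indices* (kept in x order)."""
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = np.sort(idx)
        return TimeSeries(self._x[idx], self._a[idx])

    def without(self, index: int) -> "TimeSeries":
        keep = np.ones(self.n, dtype=bool)
        keep[index] = False
        return TimeSeries(self._x[keep], self._a[keep])


class Verdict(str, enum.Enum):
    """Outcome of one MMS test."""

    MAX_FLAGGED = "max-flagged"
    MIN_FLAGGED = "min-flagged"
    NONE = "none"
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class MmsResult:
    """The paired MMS ratios, the active threshold and the verdict.

    ``arg_max``/``arg_min`` are positions (into the tested value vector) of
    the extreme elements, so callers can map a verdict back to a point.
    """

    mms_max: float
    mms_min: float
    threshold: float
    n: int
    verdict: Verdict
    arg_max: int = -1
    arg_min: int = -1

    @property
    def flagged(self) -> int | None:
        """Position of the flagged element, or None if nothing was flagged."""
        if self.verdict is Verdict.MAX_FLAGGED:
            return self.arg_max
        if self.verdict is Verdict.MIN_FLAGGED:
            return self.arg_min
        return None


# ---------------------------------------------------------------------------
# Arithmetic-progression identities
# ---------------------------------------------------------------------------

def ap_sum(a_first: float, a_last: float, n: int) -> float:
    """Sum of a finite AP with *n* terms, first term *a_first*, last *a_last*."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return (n / 2.0) * (a_first + a_last)


def ap_nth_term(a_first: float, d: float, n: int) -> float:
    """n-th term of an AP with first term *a_first* and common difference *d*."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return d * (n - 1) + a_first


def ap_indicator(series: TimeSeries) -> float:
    """The ratio ``(a_first + a_last) / S_n``; equals ``2/n`` for any exact AP.

    Inequality with ``2/n`` proves the series is not an AP; equality does NOT
    prove the converse (symmetric perturbations can cancel in the sum), which
    is why the full iterative test exists.
    """
    if series.n < 2:
        raise ValueError("series must have at least 2 points")
    s_n = series.s_n
    if abs(s_n) <= zero_tolerance(series.a):
        raise DegenerateSeriesError("sum of series is (numerically) zero")
    return (series.a_first + series.a_last) / s_n


# ---------------------------------------------------------------------------
# MMS statistic
# ---------------------------------------------------------------------------

def mms_from_values(
    values: np.ndarray, threshold: float, eps: float
) -> MmsResult:
    """Apply the MMS test to a raw value vector with an explicit threshold.

    Degenerate when max and min agree within *eps* (constant vector: both
    denominators vanish algebraically).  When both ratios exceed the
    threshold the larger one wins; an exact tie flags the maximum.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("MMS needs at least 2 values")
    i_max = int(np.argmax(v))
    i_min = int(np.argmin(v))
    v_max = float(v[i_max])
    v_min = float(v[i_min])
    spread = v_max - v_min
    if spread <= eps:
        return MmsResult(float("nan"), float("nan"), threshold, n,
                         Verdict.DEGENERATE, i_max, i_min)
    s = float(v.sum())
    den_max = s - v_min * n          # = sum(v - v_min) >= spread > 0
    den_min = v_max * n - s          # = sum(v_max - v) >= spread > 0
    if den_max <= eps or den_min <= eps:
        # Algebraically impossible for a non-constant vector; only numeric
        # cancellation can get here — report degenerate rather than divide.
        return MmsResult(float("nan"), float("nan"), threshold, n,
                         Verdict.DEGENERATE, i_max, i_min)
    mms_max = spread / den_max
    mms_min = spread / den_min
    exceed_max = mms_max > threshold
    exceed_min = mms_min > threshold
    if exceed_max and exceed_min:
        verdict = Verdict.MAX_FLAGGED if mms_max >= mms_min else Verdict.MIN_FLAGGED
    elif exceed_max:
        verdict = Verdict.MAX_FLAGGED
    elif exceed_min:
        verdict = Verdict.MIN_FLAGGED
    else:
        verdict = Verdict.NONE
    return MmsResult(mms_max, mms_min, threshold, n, verdict, i_max, i_min)


def mms_raw(
    series: TimeSeries,
    w: float = 0.0,
    *,
    k: float | None = None,
    eps_scale: float = DEFAULT_EPS_SCALE,
) -> MmsResult:
    """MMS test on a raw series expected to follow the ``y = c`` form.

    The threshold is ``R_w = 2/n + w`` with ``0 <= w <= 1 - 2/n``.  The
    weight may equivalently be given as ``k`` via the substitution
    ``w = 2k/n`` (so ``R = 2/n * (1 + k)``).
    """
    n = series.n
    if n < 2:
        raise ValueError("series must have at least 2 points")
    if k is not None:
        w = 2.0 * k / n
    if not (0.0 <= w <= 1.0 - 2.0 / n + 1e-12):
        raise ValueError(f"w={w} outside [0, 1 - 2/n] for n={n}")
    threshold = 2.0 / n + w
    eps = zero_tolerance(series.a, eps_scale)
    return mms_from_values(series.a, threshold, eps)
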