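"""Reference-point transformation of a sloped series to ``y = c`` form.

The MMS statistic only applies to series expected to be constant.  To test a
general line, each point is re-expressed relative to a chosen reference
point ``(x_r, a_r)``:

    aT_k = a_k - a_r,   xT_k = x_k - x_r,
    slope estimate  s = G_aT / G_xT   (sums over the current window)
    aTT_k = aT_k - xT_k * s           for x_k >= x_r
    aTT_k = -(aT_k - xT_k * s)        for x_k <  x_r

An exactly collinear series maps to all zeros for every reference; the sign
flip left of the reference makes the detection symmetric about it.  The
transformation uses x values as given, so gaps (missing records) need no
imputation.

The legacy single-reference variant (first point as reference, absolute
values, raw x in the slope denominator) is kept for comparison only; it is
known to fail when the first point itself is an outlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .apcore import SeriesPoint, TimeSeries, zero_tolerance


class DegenerateGeometryError(ValueError):
    """The x offsets sum to zero: the slope estimate is undefined."""


@dataclass(frozen=True)
class TransformedSeries:
    """A series transformed relative to one reference point.

    Carries the source series so detection verdicts can be mapped back to
    original points.
    """

    source: TimeSeries
    reference_index: int
    xT: np.ndarray
    aT: np.ndarray
    aTT: np.ndarray
    ga_t: float
    gx_t: float

    @property
    def reference_point(self) -> SeriesPoint:
        return self.source[self.reference_index]

    @property
    def slope_estimate(self) -> float:
        return self.ga_t / self.gx_t

    @property
    def n(self) -> int:
        return int(self.aTT.size)

    @property
    def s_n_tt(self) -> float:
        return float(self.aTT.sum())


def transform_multi_ref(series: TimeSeries, r: int) -> TransformedSeries:
    """Transform *series* to ``y = c`` form relative to its r-th point.

    Raises
    ------
    DegenerateGeometryError
        If the x offsets sum to (numerically) zero, e.g. when the reference
        sits exactly in the middle of a symmetric x grid.  Callers recover
        via the one-point-exclusion remedy in :mod:`linefinder.detect`.
    """
    n = series.n
    if n < 2:
        raise ValueError("series must have at least 2 points")
    if not (0 <= r < n):
        raise ValueError(f"reference index {r} out of range for n={n}")
    x = series.x
    a = series.a
    xt = x - x[r]
    at = a - a[r]
    gx = float(xt.sum())
    ga = float(at.sum())
    if abs(gx) <= zero_tolerance(xt):
        raise DegenerateGeometryError(
            f"sum of x offsets is zero for reference index {r}"
        )
    att = at - xt * (ga / gx)
    att = np.where(xt >= 0, att, -att)
    att.setflags(write=False)
    return TransformedSeries(series, r, xt, at, att, ga, gx)


def transform_emms(series: TimeSeries) -> np.ndarray:
    """Legacy single-reference transform: ``|aT_k - x_k * (G_aT / G_x)|``.

    The first point is the fixed reference (``aT_k = a_k - a_0``) and the
    slope denominator is the sum of the raw x values, exactly as in the
    predecessor method.  Returned values are absolute.
    """
    n = series.n
    if n < 2:
        raise ValueError("series must have at least 2 points")
    x = series.x
    at = series.a - series.a[0]
    gx = float(x.sum())
    if abs(gx) <= zero_tolerance(x):
        raise DegenerateGeometryError("sum of x values is zero")
    ga = float(at.sum())
    return np.abs(at - x * (ga / gx))
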