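"""One full detection cycle for a single reference point.

Each iteration re-transforms the live working set against the reference,
applies the MMS test to the transformed values with threshold
``R_k = 2/n * (1 + k)`` (n = live point count), removes the flagged point,
and repeats.  Termination happens when (1) every transformed value is zero
(the survivors agree exactly with one line), (2) the reference point itself
would be flagged (the candidate is then invalid), (3) nothing exceeds the
threshold, or — with an expected-number-of-non-outliers (ENNOL) stopping
rule — when the working set has shrunk to that count.

Two degenerate situations have explicit remedies:

* the x offsets sum to zero (slope estimate undefined): one suspected
  extreme point is excluded for that iteration only and re-examined later;
* MMS_max equals MMS_min with non-zero transformed values present, which
  mimics a termination: a non-suspected non-zero point is temporarily
  excluded to decide whether the termination is real.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .apcore import (
    DEFAULT_EPS_SCALE,
    MmsResult,
    SeriesPoint,
    TimeSeries,
    Verdict,
    mms_from_values,
)
from .transform import DegenerateGeometryError, TransformedSeries, transform_multi_ref

logger = logging.getLogger("linefinder")


class ReferenceUnusableError(ValueError):
    """No transformation exists for this reference even after the remedy."""


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of one detection cycle.

    k
        Threshold weight; the active threshold is ``2/n * (1 + k)`` at the
        CURRENT point count.  ``k = 0`` is the strictest setting (pure
        ``2/n``); larger k tolerates larger residuals.
    min_points
        Minimum size of an acceptable fit.  At least 3: any 2-point set has
        |r_xy| = 1 and would always win selection.
    ennol
        Expected number of non-outliers.  When set, removal stops as soon as
        the working set is this small (or a natural termination fires first).
    eps_scale
        Scale of the zero tolerance: values within ``eps_scale * max|a|`` of
        zero count as zero.
    """

    k: float = 0.0
    min_points: int = 5
    ennol: Optional[int] = None
    eps_scale: float = DEFAULT_EPS_SCALE
    max_iterations: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")
        if self.ennol is not None and self.ennol < 1:
            raise ValueError("ennol must be positive")
        if self.eps_scale <= 0:
            raise ValueError("eps_scale must be positive")


@dataclass(frozen=True)
class IterationRecord:
    """Mirror of one iteration: threshold, both ratios, and the action."""

    iteration: int
    n: int
    threshold: float
    mms_max: float
    mms_min: float
    action: str  # "removed-max" | "removed-min" | "terminated"
    removed_point: Optional[SeriesPoint] = None
    termination_reason: Optional[str] = None


@dataclass(frozen=True)
class CandidateFit:
    """Outcome of a detection cycle for one reference point."""

    reference_index: int
    reference_point: SeriesPoint
    surviving: TimeSeries
    removed: tuple[tuple[SeriesPoint, int, float], ...]  # (point, iteration, k)
    trace: tuple[IterationRecord, ...]
    r_xy: float
    valid: bool
    invalid_reason: Optional[str] = None


def _threshold(n: int, k: float) -> float:
    # Both MMS ratios are algebraically <= 1, so a threshold above 1 simply
    # means no detection is possible; clamp to keep the invariant R in (0,1].
    return min(1.0, (2.0 / n) * (1.0 + k))


def detect_once(ts: TransformedSeries, k: float,
                eps_scale: float = DEFAULT_EPS_SCALE) -> MmsResult:
    """Apply the MMS test to a transformed series with threshold 2/n*(1+k).

    The zero tolerance is scaled by the ORIGINAL series values (not the
    transformed ones) so that near-line residuals from a well-estimated
    slope register as zero.
    """
    n = ts.n
    if n < 2:
        raise ValueError("transformed series must have at least 2 values")
    eps = eps_scale * float(np.max(np.abs(ts.source.a))) if ts.source.n else 0.0
    return mms_from_values(ts.aTT, _threshold(n, k), eps)


def handle_gx_zero(series: TimeSeries, r: int) -> TimeSeries:
    """Remedy for a zero x-offset sum: exclude one suspected extreme point.

    The suspected point is the non-reference point with the largest
    ``|a - a_r|``.  It is excluded from the returned working copy only; the
    caller re-examines it in later iterations.  Raises
    :class:`ReferenceUnusableError` if no exclusion can restore a usable
    geometry.
    """
    try:
        transform_multi_ref(series, r)
    except DegenerateGeometryError:
        pass
    else:
        return series
    if series.n < 3:
        raise ReferenceUnusableError("too few points to exclude one")
    dev = np.abs(series.a - series.a[r])
    dev[r] = -np.inf
    excl = int(np.argmax(dev))
    reduced = series.without(excl)
    new_r = r - 1 if excl < r else r
    try:
        transform_multi_ref(reduced, new_r)
    except DegenerateGeometryError as exc:  # pragma: no cover - unreachable
        raise ReferenceUnusableError(str(exc)) from exc
    return reduced


def resolve_ambiguous_termination(ts: TransformedSeries, k: float,
                                  eps_scale: float = DEFAULT_EPS_SCALE) -> str:
    """Decide whether MMS_max == MMS_min (non-zero values present) really
    terminates the cycle.

    Returns one of ``"real-termination"``, ``"continue"`` or
    ``"all-nonzero-flagged"``.  A non-suspected (value strictly between min
    and max), non-zero point is temporarily excluded, lowest x first:

    * equality breaks on the reduced set -> ``"continue"`` (detection goes
      on; the excluded point returns next iteration);
    * equality persists -> ``"real-termination"``;
    * no eligible point exists (every non-zero value ties an extreme) ->
      ``"all-nonzero-flagged"``.
    """
    eps = eps_scale * float(np.max(np.abs(ts.source.a)))
    outcome, _, _ = _resolve_ambiguous(np.asarray(ts.aTT, dtype=float), k, eps)
    return outcome


def _mms_pair(v: np.ndarray) -> tuple[float, float]:
    n = v.size
    v_max = float(v.max())
    v_min = float(v.min())
    s = float(v.sum())
    return (v_max - v_min) / (s - v_min * n), (v_max - v_min) / (v_max * n - s)


def _resolve_ambiguous(att: np.ndarray, k: float, eps: float
                       ) -> tuple[str, Optional[int], Optional[str]]:
    """Implementation of the ambiguity remedy on a raw aTT vector.

    Returns (outcome, flagged_position, side); the position refers to *att*
    and is only set for outcome ``"continue"``, with side "max" or "min".
    """
    v_max = float(att.max())
    v_min = float(att.min())
    near_max = np.abs(att - v_max) <= eps
    near_min = np.abs(att - v_min) <= eps
    nonzero = np.abs(att) > eps
    eligible = np.flatnonzero(nonzero & ~near_max & ~near_min)
    if eligible.size == 0:
        return "all-nonzero-flagged", None, None
    excl = int(eligible[0])  # lowest x first (aTT is stored in x order)
    keep = np.ones(att.size, dtype=bool)
    keep[excl] = False
    red = att[keep]
    if float(red.max()) - float(red.min()) <= eps:
        return "real-termination", None, None
    mms_max, mms_min = _mms_pair(red)
    tol = 1e-9 * max(1.0, abs(mms_max), abs(mms_min))
    if abs(mms_max - mms_min) <= tol:
        return "real-termination", None, None
    res = mms_from_values(red, _threshold(red.size, k), eps)
    if res.flagged is None:
        return "real-termination", None, None
    pos = int(np.flatnonzero(keep)[res.flagged])
    side = "max" if res.verdict is Verdict.MAX_FLAGGED else "min"
    return "continue", pos, side


def run_reference(series: TimeSeries, r: int, config: DetectionConfig
                  ) -> CandidateFit:
    """Run the full transform → test → remove cycle for reference index *r*.

    The reference is tracked as a point, not a position: removals shrink the
    working set around it.  Returns a :class:`CandidateFit` with the
    surviving series, the removal sequence and a complete per-iteration
    trace.  The candidate is invalid if the reference would be flagged, the
    reference geometry is unusable, or too few points survive.
    """
    n0 = series.n
    if not (0 <= r < n0):
        raise ValueError(f"reference index {r} out of range")
    if n0 < config.min_points:
        raise ValueError("series smaller than min_points")
    x = series.x
    a = series.a
    eps = config.eps_scale * float(np.max(np.abs(a)))
    xtol = config.eps_scale * float(np.max(np.abs(x - x[r])))
    alive = np.ones(n0, dtype=bool)
    trace: list[IterationRecord] = []
    removed: list[tuple[SeriesPoint, int, float]] = []
    valid = True
    invalid_reason: Optional[str] = None
    max_iter = config.max_iterations or (n0 + 2)

    def terminate(it: int, n: int, thr: float, mx: float, mn: float,
                  reason: str) -> None:
        trace.append(IterationRecord(it, n, thr, mx, mn, "terminated",
                                     None, reason))

    it = 0
    while True:
        it += 1
        if it > max_iter:  # pragma: no cover - n strictly decreases
            raise RuntimeError("detection failed to terminate")
        idx = np.flatnonzero(alive)
        m = idx.size
        if config.ennol is not None and m <= config.ennol:
            terminate(it, m, float("nan"), float("nan"), float("nan"),
                      "ennol-reached")
            break
        if m < 2:
            terminate(it, m, float("nan"), float("nan"), float("nan"),
                      "too-few-points")
            break

        # ---- transform (with the zero-geometry remedy) -------------------
        use = idx
        xt = x[use] - x[r]
        gx = float(xt.sum())
        excluded: Optional[int] = None
        if abs(gx) <= xtol:
            cand = use[use != r]
            if cand.size < 2:
                valid = False
                invalid_reason = "reference-unusable"
                terminate(it, m, float("nan"), float("nan"), float("nan"),
                          "reference-unusable")
                break
            excluded = int(cand[np.argmax(np.abs(a[cand] - a[r]))])
            use = use[use != excluded]
            xt = x[use] - x[r]
            gx = float(xt.sum())
            if abs(gx) <= xtol:  # pragma: no cover - excluding a non-ref
                valid = False    # point always shifts the offset sum
                invalid_reason = "reference-unusable"
                terminate(it, m, float("nan"), float("nan"), float("nan"),
                          "reference-unusable")
                break
        at = a[use] - a[r]
        slope = float(at.sum()) / gx
        att = at - xt * slope
        np.negative(att, out=att, where=xt < 0)
        m_eff = use.size
        thr = _threshold(m_eff, config.k)

        # ---- all-zero termination ---------------------------------------
        if float(np.max(np.abs(att))) <= eps:
            if excluded is not None:
                # The remainder agrees with a line; check whether the
                # temporarily excluded suspect does too.
                att_exc = (a[excluded] - a[r]) - (x[excluded] - x[r]) * slope
                if x[excluded] < x[r]:
                    att_exc = -att_exc
                if abs(att_exc) > eps:
                    alive[excluded] = False
                    pt = SeriesPoint(float(x[excluded]), float(a[excluded]))
                    removed.append((pt, it, config.k))
                    action = "removed-max" if att_exc > 0 else "removed-min"
                    trace.append(IterationRecord(it, m, thr, float("nan"),
                                                 float("nan"), action, pt))
                    continue
            terminate(it, m_eff, thr, float("nan"), float("nan"), "all-zero")
            break

        # ---- MMS test ----------------------------------------------------
        res = mms_from_values(att, thr, eps)
        if res.verdict is Verdict.DEGENERATE:
            terminate(it, m_eff, thr, res.mms_max, res.mms_min, "no-detection")
            break
        flagged_use_pos: Optional[int] = res.flagged
        side = "max" if res.verdict is Verdict.MAX_FLAGGED else "min"
        if flagged_use_pos is None:
            tol = 1e-9 * max(1.0, res.mms_max, res.mms_min)
            if abs(res.mms_max - res.mms_min) <= tol:
                outcome, pos, amb_side = _resolve_ambiguous(att, config.k, eps)
                if outcome == "real-termination":
                    terminate(it, m_eff, thr, res.mms_max, res.mms_min,
                              "no-detection")
                    break
                if outcome == "all-nonzero-flagged":
                    for p in np.flatnonzero(np.abs(att) > eps):
                        gp = int(use[p])
                        alive[gp] = False
                        pt = SeriesPoint(float(x[gp]), float(a[gp]))
                        removed.append((pt, it, config.k))
                    terminate(it, m_eff, thr, res.mms_max, res.mms_min,
                              "ambiguous-resolved")
                    break
                flagged_use_pos = pos  # "continue": flagged on reduced set
                side = amb_side or "max"
                logger.debug("ambiguous MMS equality resolved by exclusion "
                             "at iteration %d (ref %d)", it, r)
            else:
                terminate(it, m_eff, thr, res.mms_max, res.mms_min,
                          "no-detection")
                break

        flagged = int(use[flagged_use_pos])
        if flagged == r:
            # Exact-value tie with another point rescues the reference.
            ties = np.flatnonzero((att == att[flagged_use_pos]) & (use != r))
            if ties.size:
                flagged = int(use[ties[0]])
            else:
                valid = False
                invalid_reason = "reference-flagged"
                terminate(it, m_eff, thr, res.mms_max, res.mms_min,
                          "reference-flagged")
                logger.debug("reference point %d flagged as disagreeing "
                             "with the fit; candidate invalid", r)
                break
        alive[flagged] = False
        pt = SeriesPoint(float(x[flagged]), float(a[flagged]))
        removed.append((pt, it, config.k))
        trace.append(IterationRecord(it, m_eff, thr, res.mms_max, res.mms_min,
                                     f"removed-{side}", pt))

    surviving = series.subset(alive)
    if surviving.n < config.min_points:
        valid = False
        invalid_reason = invalid_reason or "too-few-points"
    from .search import pearson_special  # local import: avoid cycle
    r_xy = pearson_special(surviving) if surviving.n >= 2 else float("nan")
    return CandidateFit(
        reference_index=r,
        reference_point=series[r],
        surviving=surviving,
        removed=tuple(removed),
        trace=tuple(trace),
        r_xy=r_xy,
        valid=valid,
        invalid_reason=invalid_reason,
    )
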