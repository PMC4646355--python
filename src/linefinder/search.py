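"""Search across reference points and selection of the best linear fit.

Every point of the series may serve as the reference for one detection
cycle; each cycle yields a candidate fit (its surviving points).  Candidates
are scored by the product-moment correlation of their surviving points, with
one special case: a constant-valued series (the line ``y = c``) makes the
correlation undefined, and is stipulated to score ``r_xy = 1`` so that
horizontal fits are identifiable.

Selection: maximum ``|r_xy|`` first, then the larger surviving set (a
50-point perfect line beats a 3-point one), then the smallest reference
index for determinism.  A minimum fit size guards against trivially perfect
tiny candidates.

The multi-step variant runs the same search with a strictly decreasing
schedule of threshold weights ``k``: the widest stage removes gross
outliers, later (stricter) stages remove noise, and every removal is
labelled with the stage at which it fell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .apcore import SeriesPoint, TimeSeries, zero_tolerance
from .detect import CandidateFit, DetectionConfig, run_reference

logger = logging.getLogger("linefinder")


class NoFitFoundError(RuntimeError):
    """No reference point produced a valid candidate fit."""

    def __init__(self, message: str, groups: Optional[dict] = None) -> None:
        super().__init__(message)
        self.groups = groups or {}


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of a full search.

    method
        ``"best-correlation"`` ranks candidates by |r_xy| then size;
        ``"ennol"`` additionally stops each cycle once the expected number
        of non-outliers remain and ranks by |r_xy|.
    k_schedule
        Strictly decreasing thresholds for the multi-step variant; a single
        element reproduces the plain search.  Defaults to ``(detection.k,)``.
    reference_set
        Indices to try as reference points; default all.
    """

    method: str = "best-correlation"
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    k_schedule: Optional[tuple[float, ...]] = None
    reference_set: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.method not in ("best-correlation", "ennol"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "ennol" and self.detection.ennol is None:
            raise ValueError("method 'ennol' requires detection.ennol")
        ks = self.schedule
        if any(k2 >= k1 for k1, k2 in zip(ks, ks[1:])):
            raise ValueError("k_schedule must be strictly decreasing")
        if any(k < 0 for k in ks):
            raise ValueError("k values must be >= 0")

    @property
    def schedule(self) -> tuple[float, ...]:
        return self.k_schedule if self.k_schedule else (self.detection.k,)


@dataclass(frozen=True)
class FitResult:
    """The selected fit, all candidates, and removals grouped by k stage."""

    best: CandidateFit
    candidates: tuple[CandidateFit, ...]
    groups: dict[SeriesPoint, float]

    @property
    def surviving(self) -> TimeSeries:
        return self.best.surviving


def pearson_special(points: TimeSeries) -> float:
    """Product-moment correlation of (x, a), with the ``y = c`` stipulation.

    A constant-valued series has zero a-variance and an undefined
    correlation; it is a perfect horizontal line, so the correlation is
    stipulated to be exactly 1.
    """
    if points.n < 2:
        raise ValueError("correlation needs at least 2 points")
    a = points.a
    if float(np.max(a)) - float(np.min(a)) <= 1e-3 * zero_tolerance(a):
        return 1.0
    x = points.x
    # An exactly collinear set (up to the working zero tolerance) is a
    # perfect fit by definition; snap to +-1 so floating-point noise in the
    # correlation cannot rank a perfect subset above a perfect superset.
    xc = x - x.mean()
    slope = float(np.dot(xc, a)) / float(np.dot(xc, xc))
    resid = a - (a.mean() + slope * xc)
    if float(np.max(np.abs(resid))) <= zero_tolerance(a):
        return 1.0 if slope >= 0 else -1.0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, a)[0, 1]
    if not np.isfinite(r):
        return 1.0  # zero variance at machine scale
    return float(np.clip(r, -1.0, 1.0))


def _rank_key(cand: CandidateFit) -> tuple[float, int, int]:
    return (abs(cand.r_xy), cand.surviving.n, -cand.reference_index)


def best_fit(series: TimeSeries, config: Optional[SearchConfig] = None
             ) -> FitResult:
    """Try every configured reference point and select the best candidate.

    Raises :class:`NoFitFoundError` when no reference yields a valid
    candidate of at least ``min_points`` surviving points.
    """
    config = config or SearchConfig()
    det = config.detection
    if config.k_schedule:
        if len(config.k_schedule) > 1:
            return multi_step_fit(series, config)
        det = replace(det, k=config.k_schedule[0])
    n = series.n
    if n < det.min_points:
        raise ValueError("series smaller than min_points")
    refs: Sequence[int] = (config.reference_set
                           if config.reference_set is not None else range(n))
    if len(refs) == 0:
        raise ValueError("reference_set is empty")
    candidates = [run_reference(series, int(r), det) for r in refs]
    valid = [c for c in candidates if c.valid]
    if not valid:
        raise NoFitFoundError("no reference point produced a valid fit")
    best = max(valid, key=_rank_key)
    k_level = det.k
    groups = {pt: k_level for pt, _, _ in best.removed}
    return FitResult(best=best, candidates=tuple(candidates), groups=groups)


def multi_step_fit(series: TimeSeries, config: SearchConfig) -> FitResult:
    """Graded removal: one search per k of the schedule, widest first.

    Each stage's surviving set is the next stage's input, so the stages are
    monotonically nested; removals are labelled with their stage's k (the
    largest k catches outliers, smaller k catches noise).
    """
    schedule = config.schedule
    groups: dict[SeriesPoint, float] = {}
    current = series
    result: Optional[FitResult] = None
    for k_level in schedule:
        stage_cfg = replace(config, k_schedule=(k_level,),
                            detection=replace(config.detection, k=k_level))
        try:
            result = best_fit(current, stage_cfg)
        except NoFitFoundError as exc:
            raise NoFitFoundError(
                f"no valid candidate at k={k_level}", groups=groups
            ) from exc
        groups.update(result.groups)
        current = result.best.surviving
    assert result is not None
    return FitResult(best=result.best, candidates=result.candidates,
                     groups=groups)
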