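"""Reading delimited series files and writing the JSON run report."""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np

from .apcore import TimeSeries
from .detect import CandidateFit, IterationRecord
from .search import FitResult, SearchConfig

logger = logging.getLogger("linefinder")


class SeriesFormatError(ValueError):
    """The input file cannot be parsed into a valid series."""


def _split(line: str, delimiter: Optional[str]) -> list[str]:
    if delimiter is not None:
        return [f.strip() for f in line.split(delimiter)]
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def read_series(
    path: Union[str, Path],
    *,
    delimiter: Optional[str] = None,
    columns: tuple[int, int] = (0, 1),
) -> TimeSeries:
    """Read a two-column (x, value) series from a delimited text file.

    Blank lines and ``#`` comments are skipped; a single non-numeric header
    row is tolerated.  The delimiter is auto-detected (tab, then comma, then
    whitespace) unless given.  Errors carry the offending line number.
    """
    path = Path(path)
    cx, ca = columns
    xs: list[float] = []
    vals: list[float] = []
    lines: list[int] = []
    header_skipped = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split(line, delimiter)
            if max(cx, ca) >= len(fields):
                raise SeriesFormatError(
                    f"{path}:{lineno}: expected at least "
                    f"{max(cx, ca) + 1} columns, got {len(fields)}")
            try:
                xv = float(fields[cx])
                av = float(fields[ca])
            except ValueError:
                if not header_skipped and not xs:
                    header_skipped = True
                    continue
                raise SeriesFormatError(
                    f"{path}:{lineno}: non-numeric value in "
                    f"{fields[cx]!r}/{fields[ca]!r}") from None
            xs.append(xv)
            vals.append(av)
            lines.append(lineno)
    if len(xs) < 2:
        raise SeriesFormatError(f"{path}: fewer than 2 data rows")
    for i in range(1, len(xs)):
        if xs[i] == xs[i - 1]:
            raise SeriesFormatError(
                f"{path}:{lines[i]}: duplicate x value {xs[i]}")
        if xs[i] < xs[i - 1]:
            raise SeriesFormatError(
                f"{path}:{lines[i]}: x values not increasing "
                f"({xs[i]} after {xs[i - 1]})")
    return TimeSeries(xs, vals)


def write_series(series: TimeSeries, path: Union[str, Path],
                 mask: Optional[np.ndarray] = None,
                 delimiter: str = "\t") -> None:
    """Write a series (optionally with an inlier-mask column) as text."""
    path = Path(path)
    with path.open("w") as fh:
        header = ["x", "value"] + (["inlier"] if mask is not None else [])
        fh.write("# " + delimiter.join(header) + "\n")
        for i in range(series.n):
            row = [repr(float(series.x[i])), repr(float(series.a[i]))]
            if mask is not None:
                row.append(str(int(mask[i])))
            fh.write(delimiter.join(row) + "\n")


# ---------------------------------------------------------------------------
# JSON run report
# ---------------------------------------------------------------------------

def _gap_summary(series: TimeSeries) -> list[dict]:
    if series.n < 3:
        return []
    diffs = np.diff(series.x)
    step = float(np.median(diffs))
    gaps = []
    for i, d in enumerate(diffs):
        if d > 1.5 * step:
            gaps.append({"after_x": float(series.x[i]),
                         "width": float(d),
                         "missing_steps": int(round(d / step)) - 1})
    return gaps


def _record_to_dict(rec: IterationRecord) -> dict:
    return {
        "iteration": rec.iteration,
        "n": rec.n,
        "threshold": _num(rec.threshold),
        "mms_max": _num(rec.mms_max),
        "mms_min": _num(rec.mms_min),
        "action": rec.action,
        "removed_point": ([rec.removed_point.x, rec.removed_point.a]
                          if rec.removed_point else None),
        "termination_reason": rec.termination_reason,
    }


def _num(v: float) -> Optional[float]:
    return None if v is None or not np.isfinite(v) else float(v)


def _candidate_to_dict(c: CandidateFit, full_trace: bool) -> dict:
    d = {
        "reference_index": c.reference_index,
        "reference_point": [c.reference_point.x, c.reference_point.a],
        "valid": c.valid,
        "invalid_reason": c.invalid_reason,
        "r_xy": _num(c.r_xy),
        "n_surviving": c.surviving.n,
    }
    if full_trace:
        d["trace"] = [_record_to_dict(r) for r in c.trace]
    return d


def build_report(series: TimeSeries, result: FitResult,
                 config: SearchConfig, *, full_traces: bool = True,
                 warnings: Sequence[str] = ()) -> dict:
    """Assemble the machine-readable run report as a JSON-serialisable dict."""
    best = result.best
    return {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "input": {
            "n": series.n,
            "x_range": [float(series.x[0]), float(series.x[-1])],
            "gaps": _gap_summary(series),
        },
        "config": {
            "method": config.method,
            "k_schedule": list(config.schedule),
            "min_points": config.detection.min_points,
            "ennol": config.detection.ennol,
            "eps_scale": config.detection.eps_scale,
            "reference_set": (list(config.reference_set)
                              if config.reference_set is not None else None),
        },
        "best": {
            "reference_index": best.reference_index,
            "reference_point": [best.reference_point.x,
                                best.reference_point.a],
            "r_xy": _num(best.r_xy),
            "surviving": [[float(x), float(a)]
                          for x, a in zip(best.surviving.x,
                                          best.surviving.a)],
        },
        "groups": [{"x": p.x, "a": p.a, "k": k}
                   for p, k in sorted(result.groups.items(),
                                      key=lambda kv: kv[0].x)],
        "candidates": [_candidate_to_dict(c, full_traces)
                       for c in result.candidates],
        "warnings": list(warnings),
    }


def write_report(report: dict, dest: Union[str, Path, TextIO]) -> None:
    if hasattr(dest, "write"):
        json.dump(report, dest, indent=2)
        dest.write("\n")
    else:
        with Path(dest).open("w") as fh:
            json.dump(report, fh, indent=2)
            fh.write("\n")
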