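"""Planted-line fixture generation.

Produces series in which a known subset of points lies exactly on a line
``a = m*x + c`` (the inliers) while the rest deviate by known magnitudes,
optionally one-sided (non-Gaussian) and with whole blocks of indices
missing.  The ground-truth inlier mask is returned alongside the series so
recovery can be scored for masking (a deviant kept) and swapping (an inlier
removed).

Deviation magnitudes are sampled log-uniformly over the configured range by
default: the experimental designs this emulates span several decades (from
deviations barely above working precision up to 1e4), and a log-uniform draw
exercises every decade instead of almost surely drawing from the top one.
Plain uniform sampling is available via ``magnitude_distribution``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dataclass_replace
from typing import Optional

import numpy as np

from .apcore import TimeSeries

#: Smallest number of inliers a spec must plant (a usable fit needs >= 3).
MIN_FIT_SIZE = 3


@dataclass(frozen=True)
class PlantedSpec:
    """Recipe for one synthetic series.

    n_total
        Number of x indices before missing regions are cut out.
    gradient, intercept
        The planted line ``a = gradient * x + intercept``.
    x_start
        First x index; spacing is 1.
    inlier_fraction
        Fraction of the surviving (non-missing) points placed exactly on the
        line; ignored when ``inlier_indices`` is given.
    inlier_indices
        Explicit zero-based x-grid indices (before missing-region removal)
        that must lie on the line.
    deviation_range
        (low, high) absolute deviation magnitudes for non-inliers; (0, 0)
        makes every point an inlier.
    deviation_sides
        "two-sided", "one-sided-positive" or "one-sided-negative".
    magnitude_distribution
        "log-uniform" (default) or "uniform" sampling of magnitudes.
    missing_regions
        Sequence of (start_index, length) blocks removed from the grid
        entirely — no placeholder records remain.
    seed
        Seed of the generator; identical spec + seed reproduces the series.
    """

    n_total: int = 1000
    gradient: float = 1.0
    intercept: float = 0.0
    x_start: float = 0.0
    inlier_fraction: float = 0.45
    inlier_indices: Optional[tuple[int, ...]] = None
    deviation_range: tuple[float, float] = (1e-2, 1e4)
    deviation_sides: str = "two-sided"
    magnitude_distribution: str = "log-uniform"
    missing_regions: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < MIN_FIT_SIZE:
            raise ValueError("n_total too small")
        if self.inlier_indices is None and not (0 < self.inlier_fraction <= 1):
            raise ValueError("inlier_fraction must be in (0, 1]")
        low, high = self.deviation_range
        if low < 0 or high < low:
            raise ValueError("deviation_range must satisfy 0 <= low <= high")
        if (low, high) != (0.0, 0.0) and low <= 0:
            raise ValueError("deviation lower bound must be positive "
                             "(zero would plant an accidental inlier)")
        if self.deviation_sides not in (
            "two-sided", "one-sided-positive", "one-sided-negative"
        ):
            raise ValueError(f"unknown deviation_sides {self.deviation_sides!r}")
        if self.magnitude_distribution not in ("log-uniform", "uniform"):
            raise ValueError("magnitude_distribution must be "
                             "'log-uniform' or 'uniform'")
        for start, length in self.missing_regions:
            if start < 0 or length < 1 or start + length > self.n_total:
                raise ValueError(f"missing region ({start},{length}) outside "
                                 f"grid of {self.n_total}")


def planted_line(spec: PlantedSpec) -> tuple[TimeSeries, np.ndarray]:
    """Generate a series per *spec*; returns (series, boolean inlier mask).

    The mask is aligned with the returned series (missing indices are gone).
    Raises ``ValueError`` if the spec leaves fewer than three inliers.
    """
    rng = np.random.default_rng(spec.seed)
    keep = np.ones(spec.n_total, dtype=bool)
    for start, length in spec.missing_regions:
        keep[start:start + length] = False
    grid = np.flatnonzero(keep)
    n = grid.size
    if n < MIN_FIT_SIZE:
        raise ValueError("missing regions leave too few points")
    x = spec.x_start + grid.astype(float)
    a = spec.gradient * x + spec.intercept
    mask = np.zeros(n, dtype=bool)

    low, high = spec.deviation_range
    if (low, high) == (0.0, 0.0):
        mask[:] = True
        return TimeSeries(x, a), mask

    if spec.inlier_indices is not None:
        wanted = set(spec.inlier_indices)
        inl = np.flatnonzero(np.isin(grid, list(wanted)))
        if inl.size < MIN_FIT_SIZE:
            raise ValueError("missing regions overlap the planted inliers; "
                             f"only {inl.size} remain")
    else:
        n_in = int(round(spec.inlier_fraction * n))
        n_in = max(n_in, MIN_FIT_SIZE)
        inl = rng.choice(n, size=n_in, replace=False)
    mask[inl] = True

    dev_idx = np.flatnonzero(~mask)
    nd = dev_idx.size
    if nd:
        if spec.magnitude_distribution == "log-uniform":
            mag = np.exp(rng.uniform(math.log(low), math.log(high), size=nd))
        else:
            mag = rng.uniform(low, high, size=nd)
        mag = np.clip(mag, low, high)
        if spec.deviation_sides == "one-sided-positive":
            sign = np.ones(nd)
        elif spec.deviation_sides == "one-sided-negative":
            sign = -np.ones(nd)
        else:
            sign = rng.choice([-1.0, 1.0], size=nd)
        a = a.copy()
        a[dev_idx] += sign * mag
    return TimeSeries(x, a), mask


def worked_example_series() -> TimeSeries:
    """The six-point worked example: x = 6..11, one gross and one mild
    deviant around the line ``a = 10x - 40``."""
    return TimeSeries([6, 7, 8, 9, 10, 11],
                      [22.0, 30.0, 41.81, 50.001, 60.0, 70.0])


# Named presets mirroring the synthetic experimental designs: planted lines
# with <50% inliers, deviations over many decades, one- or two-sided, and
# blocks of initially missing records.
PRESETS: dict[str, PlantedSpec] = {
    "small-onesided": PlantedSpec(
        n_total=10, gradient=2.0, intercept=5.0, inlier_fraction=0.4,
        deviation_range=(1e-4, 1e4), deviation_sides="one-sided-positive",
    ),
    "small-twosided": PlantedSpec(
        n_total=10, gradient=-1.5, intercept=100.0, inlier_fraction=0.4,
        deviation_range=(1e-4, 1e4), deviation_sides="two-sided",
    ),
    "small-constant": PlantedSpec(
        n_total=10, gradient=0.0, intercept=42.0, inlier_fraction=0.4,
        deviation_range=(1e-4, 1e4), deviation_sides="two-sided",
    ),
    "large-twosided-gaps": PlantedSpec(
        n_total=1000, gradient=0.8, intercept=10.0, inlier_fraction=0.45,
        deviation_range=(1e-2, 1e4), deviation_sides="two-sided",
        missing_regions=((100, 50), (300, 100), (550, 100), (800, 50)),
    ),
    "large-onesided-gaps": PlantedSpec(
        n_total=1000, gradient=1.2, intercept=-5.0, inlier_fraction=0.45,
        deviation_range=(1e-2, 1e4), deviation_sides="one-sided-positive",
        missing_regions=((150, 100), (600, 150)),
    ),
}


def preset(name: str, seed: Optional[int] = None) -> PlantedSpec:
    """Look up a named preset, optionally re-seeded."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(PRESETS)}") from None
    if seed is not None:
        spec = dataclass_replace(spec, seed=seed)
    return spec
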