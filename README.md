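# linefinder

Non-parametric identification of the points of a time series that agree
with a single linear fit — robust to >50% contamination, one-sided
(non-Gaussian) deviations, and missing records, with no imputation and no
distributional assumptions.

## The problem

Sensor streams (the motivating case is process data from biogas plants,
recorded every other hour for months) are expected to drift linearly during
stable operation, but the raw series mixes three populations: clean points
on the trend, noise close to it, and gross outliers far from it. Classical
regression is pulled off the trend by the contamination; outlier tests that
assume a noise distribution fail when the assumption is wrong; and both
struggle once fewer than half the points are clean. This package answers a
different question than least squares: *which exact subset of points lies on
one line?*

## The method

A line sampled on an index grid is a finite arithmetic progression, and for
any AP the classical sum identity gives

    (a_1 + a_n) / S_n = 2/n ,

independent of the terms. For a series expected to be constant (`y = c`),
the pair of min–max–sum (MMS) ratios

    MMS_max = (a_max − a_min) / (S_n − a_min·n)
    MMS_min = (a_max − a_min) / (a_max·n − S_n)

both equal `2/n` exactly; `MMS_max > 2/n·(1+k)` flags the maximum as
disagreeing with the fit (resp. the minimum for `MMS_min`), with `k ≥ 0` a
tolerance weight. To test a general line, the series is transformed relative
to a reference point `(x_r, a_r)`:

    aTT_k = ± [ (a_k − a_r) − (x_k − x_r) · Σ(a − a_r)/Σ(x − x_r) ] ,

with the sign flipped left of the reference. Any exactly collinear series
maps to all zeros for every reference, so the MMS test applies; one point is
removed per iteration and the transform is recomputed until the survivors
agree exactly. Every point is tried as the reference, and the best candidate
maximizes the absolute correlation `|r_xy|` of its survivors (a constant
series is stipulated `r_xy = 1` so horizontal fits are identifiable), then
the surviving count, subject to a minimum fit size. Because x values are
used as given, gaps from missing or removed records need no imputation.
A strictly decreasing schedule of `k` values grades the removals: the
tolerant stage catches outliers, stricter stages catch noise.

## Worked example

The six-point series `x = 6..11`, `a = 22, 30, 41.81, 50.001, 60, 70`
contains a three-point line `a = 10x − 40`, one gross deviant and one mild
one:

```
$ printf '6\t22\n7\t30\n8\t41.81\n9\t50.001\n10\t60\n11\t70\n' > series.tsv
$ linefinder fit series.tsv --k 0 --min-points 3
n_input=6 n_fit=3 r_xy=1.000000 reference=(7,30)
  7	30
  10	60
  11	70
removed (point -> k level):
  (6,22) -> k=0
  (8,41.81) -> k=0
  (9,50.001) -> k=0
```

The detection cycle with reference `(7, 30)` and `k = 0` first transforms
all six points (`aTT = −2.42, 0.00, 1.39, −0.85, −1.27, −1.69`), finds
`MMS_max = 0.39 > 2/6` and removes `(8, 41.81)`; the recomputed second
iteration finds `MMS_min = 0.50 > 2/5` and removes `(6, 22)`; then
`(9, 50.001)` falls, and the remaining three points transform to exactly
zero — the surviving line, with `r_xy = 1`.

The same API is available in Python:

```python
from linefinder import best_fit, SearchConfig, DetectionConfig, worked_example_series

result = best_fit(worked_example_series(),
                  SearchConfig(detection=DetectionConfig(k=0, min_points=3)))
print(list(result.surviving.x))   # [7.0, 10.0, 11.0]
print(result.best.r_xy)           # 1.0
```

Synthetic contaminated fixtures (planted lines with known inlier masks,
deviations spanning decades, missing blocks) come from
`linefinder simulate` or `linefinder.planted_line`.

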