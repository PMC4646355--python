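# Methods

## Model and procedure

The package treats "agrees with a linear fit" as an exact, combinatorial
property: a point belongs to the fit if it lies on the line defined by the
other members, not merely near a trend. The procedure rests on two facts.

1. **AP indicator.** A line sampled at indices `x_k` is an arithmetic
   progression, and every AP satisfies `(a_1 + a_n)/S_n = 2/n`. Inequality
   proves contamination; equality proves nothing (symmetric perturbations
   cancel in the sum), which is why the indicator is never used alone.
2. **MMS ratios.** For a series expected to be constant, the ratios
   `MMS_max = (a_max − a_min)/(S_n − a_min·n)` and
   `MMS_min = (a_max − a_min)/(a_max·n − S_n)` both equal `2/n` exactly.
   They obey the reciprocal identity `1/MMS_max + 1/MMS_min = n`, are
   bounded by 1, and `MMS_max > 2/n·(1+k)` flags the maximum element as
   disagreeing (resp. `MMS_min`, the minimum). A useful corollary of the
   identity: both ratios can never exceed the threshold simultaneously
   (for `k ≥ 0`), so each test flags at most one point.

To test a sloped line, the working set is transformed against a reference
point `r`: offsets `aT = a − a_r`, `xT = x − x_r`, slope estimate
`s = ΣaT / ΣxT`, and `aTT = aT − xT·s`, negated where `xT < 0`. The sign
flip puts the residuals of a wrongly-estimated slope on one side of zero
(a "fan" proportional to `|xT|`), which keeps the detection symmetric about
the reference. One point is removed per iteration (the flagged extreme of
`aTT`), and the transform, the threshold `2/n·(1+k)` and both ratios are
recomputed from the live set each time. Termination: all `aTT` zero (the
survivors are exactly collinear), no ratio above threshold, the reference
itself flagged (the candidate is then invalid), or — optionally — the
working set reaching an expected number of non-outliers (ENNOL).

Every point (or any chosen subset) serves as reference once; each cycle
yields a candidate surviving set. Candidates are ranked by `|r_xy|`
(product-moment correlation of the survivors), then by surviving count
descending, then by reference index for determinism, subject to
`min_points`. Since inlier references recover the true line and deviant
references produce smaller or imperfect candidates, the cross-reference
selection is what makes the method resistant to a bad reference — the known
failure mode of the legacy single-reference (EMMS) variant, which is kept
only as a comparison utility.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 0 | threshold weight; active threshold `2/n·(1+k)` (dimensionless). 0 = strictest; the admissible range at size n is `0 ≤ k ≤ n/2 − 1`. |
| `min_points` | 5 | smallest acceptable fit. Must be ≥ 3: any 2-point set has `r_xy = ±1` and would always win. 5 matches the reference experiments. |
| `ennol` | off | optional stop at an expected number of non-outliers. |
| `eps_scale` | 1e−9 | zero tolerance is `eps_scale × max|a|` of the input series; matches double-precision head-room on the data's own scale. |
| `k_schedule` | `(k,)` | strictly decreasing stages; removals are labelled by stage, separating outliers (large k) from noise (small k). |
| `reference_set` | all points | any subset may be used; results are independent of evaluation order. |

## Numerical choices

* **Thresholds above 1.** When the working set shrinks below `2(1+k)`
  points, `2/n·(1+k)` would exceed 1, which no ratio can; the threshold is
  clamped at 1 and the cycle simply terminates with "no detection".
* **Tie-breaks.** Ambiguous arg-max ties that would flag the reference are
  resolved toward a non-reference point of equal value; otherwise the
  candidate is invalidated rather than silently continuing.
* **Equal ratios with non-zero residuals.** `MMS_max = MMS_min` mimics
  termination. The remedy excludes one non-suspected (value strictly
  between the extremes), non-zero point, lowest x first: if the equality
  breaks, detection continues on the reduced set and the excluded point
  returns next iteration; if it persists, the termination is real; if no
  eligible point exists (every non-zero value ties an extreme, e.g.
  `1.1, 1.1, 0, 0, 0, −1.1, −1.1`), all non-zero terms are flagged.
* **Zero offset sum.** A reference in the middle of a symmetric x grid
  makes `ΣxT = 0` and the slope estimate undefined; the point with the
  largest `|a − a_r|` is excluded for that iteration only (excluding any
  non-reference point restores `ΣxT ≠ 0`), and is re-examined afterwards —
  including a final check of the excluded point against the fitted line
  when the remainder is already clean.
* **Correlation snapping.** `r_xy` of a surviving set that is collinear
  within the zero tolerance is snapped to exactly ±1. Floating-point noise
  in the textbook formula is of order 1e−16 and would otherwise rank a
  perfect 3-point subset above a perfect 50-point line. A constant-valued
  set (zero a-variance, the formula is 0/0) is stipulated `r_xy = 1`, so
  horizontal fits are identifiable.
* **Worked-example bookkeeping.** `n` is always the live point count; the
  published third-iteration intermediates of the six-point example use the
  pre-removal count, so our recomputed ratios there differ (0.69 vs 0.55)
  while the flagged point, removal order and final fit are identical.

## The synthetic generator

`planted_line` emulates the reference experimental designs: a line
`a = m·x + c` sampled on a unit grid, a chosen fraction (typically
0.40–0.49) of points placed on it exactly, the rest displaced by magnitudes
drawn from a configured range with one-sided or two-sided signs, and whole
index blocks deleted (missing records, no placeholders). Magnitudes are
sampled log-uniformly by default because the emulated designs span many
decades (±10⁻⁴ or ±10⁻² up to ±10⁴) and a uniform draw over such a range
almost never produces the small deviations that stress the method;
uniform sampling is available as an option. One explicit seed controls all
randomness.

What the generator does *not* emulate: measurement noise on the inliers
themselves (inliers are exact, which is what makes "zero masking, zero
swapping" a well-defined score), autocorrelated sensor drift, or multiple
co-existing linear regimes. Passing the recovery tests therefore shows the
combinatorial machinery is correct under extreme contamination, not that
the method tolerates inliers that are themselves noisy — on real data one
grades tolerance with the `k` schedule instead.

## Problem sizes and test design

The recovery suite runs 100 deterministic replicates: 40 at n = 10 (one
missing index, 4 planted inliers, `min_points = 4`), 40 at n = 100 (three
missing blocks of 5–10), and 20 at n = 1000 (four missing blocks of 50–100,
i.e. 700 live points), cycling positive, negative and zero gradients,
one- and two-sided deviations in ±10⁻²..±10⁴ and inlier fractions
0.40–0.49. For the n = 1000 replicates the search uses ~64 evenly spaced
reference points rather than all 700 — the method admits any reference
subset, recovery needs only one clean reference, and spread references keep
the cost proportional to what the extra references would add in redundancy.
Small-series oracle checks enumerate the maximum exactly-collinear subset
over all point pairs (O(n³)) and require byte-exact agreement.

## Known limitations

* Exactness is the contract: points near but not on the line are removed at
  `k = 0`. Tolerance must be expressed through `k`, and the right `k` for a
  given noise level depends on n and the contamination structure.
* Balanced two-sided gross outliers suppress each other's MMS ratios
  (flagging compares the midrange to the mean), so a tolerant stage may
  pass over contamination that a stricter stage then removes; the k-graded
  magnitude separation is cleanest when gross deviants are not symmetric.
* Deviations at or below ~1e−9 of the data scale fall inside the zero
  tolerance and are treated as agreeing with the fit, by design.
* One line per window: segmenting multiple co-existing linear regimes is
  out of scope.
* The legacy EMMS path assumes zero-based contiguous indices; with shifted
  or gapped grids its slope estimate is biased. It is retained only to
  demonstrate the failure mode the multi-reference method fixes.
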