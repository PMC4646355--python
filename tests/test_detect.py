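"""The per-reference detection cycle: transform, test, remove, terminate."""

import numpy as np
import pytest

from linefinder import (
    DetectionConfig,
    ReferenceUnusableError,
    TimeSeries,
    TransformedSeries,
    Verdict,
    detect_once,
    handle_gx_zero,
    planted_line,
    PlantedSpec,
    resolve_ambiguous_termination,
    run_reference,
    transform_multi_ref,
)
from conftest import make_collinear


def _ts_from_att(att, source=None):
    """Build a TransformedSeries carrying given aTT values (for testing the
    ambiguity remedy on literature vectors)."""
    att = np.asarray(att, dtype=float)
    n = att.size
    src = source or TimeSeries(np.arange(n, dtype=float), att)
    xt = src.x - src.x[0]
    return TransformedSeries(src, 0, xt, att.copy(), att, float(att.sum()),
                             float(xt.sum()))


class TestDetectOnce:
    def test_worked_example_iteration_one(self, worked_example):
        ts = transform_multi_ref(worked_example, 1)
        res = detect_once(ts, k=0.0)
        assert round(res.mms_max, 2) == 0.39
        assert round(res.mms_min, 2) == 0.29
        assert res.threshold == pytest.approx(2 / 6)
        assert res.verdict is Verdict.MAX_FLAGGED
        flagged = worked_example[res.flagged]
        assert (flagged.x, flagged.a) == (8.0, 41.81)

    def test_worked_example_iteration_two(self, worked_example):
        reduced = worked_example.without(2)  # (8, 41.81) already removed
        ts = transform_multi_ref(reduced, 1)
        assert ts.s_n_tt == pytest.approx(-4.50, abs=5e-3)
        assert round(float(ts.aTT.min()), 2) == -2.25
        res = detect_once(ts, k=0.0)
        assert round(res.mms_min, 2) == 0.50
        assert res.verdict is Verdict.MIN_FLAGGED
        flagged = reduced[res.flagged]
        assert (flagged.x, flagged.a) == (6.0, 22.0)

    def test_all_zero_transform_is_degenerate(self):
        ts = transform_multi_ref(make_collinear(6, 2.0, 1.0), 2)
        assert detect_once(ts, k=0.0).verdict is Verdict.DEGENERATE


class TestRunReference:
    def test_worked_example_full_cycle(self, worked_example):
        cand = run_reference(worked_example, 1,
                             DetectionConfig(k=0.0, min_points=3))
        removed_pts = [(p.x, p.a) for p, _, _ in cand.removed]
        assert removed_pts == [(8.0, 41.81), (6.0, 22.0), (9.0, 50.001)]
        assert list(zip(cand.surviving.x, cand.surviving.a)) == [
            (7.0, 30.0), (10.0, 60.0), (11.0, 70.0)]
        assert cand.valid
        assert cand.trace[-1].termination_reason == "all-zero"
        assert cand.r_xy == pytest.approx(1.0)

    def test_threshold_tracks_live_point_count(self, worked_example):
        cand = run_reference(worked_example, 1,
                             DetectionConfig(k=0.0, min_points=3))
        removals = [t for t in cand.trace if t.action != "terminated"]
        assert [t.n for t in removals] == [6, 5, 4]
        assert [round(t.threshold, 2) for t in removals] == [0.33, 0.40, 0.50]

    def test_collinear_series_terminates_immediately(self):
        s = make_collinear(8, -3.0, 12.0)
        cand = run_reference(s, 5, DetectionConfig(min_points=3))
        assert cand.removed == ()
        assert cand.surviving.n == 8
        assert cand.trace[-1].termination_reason == "all-zero"

    def test_partition_preserved(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 25))
            s = TimeSeries(np.arange(n, dtype=float),
                           rng.normal(size=n) * 10)
            r = int(rng.integers(0, n))
            cand = run_reference(s, r, DetectionConfig(min_points=3))
            removed_x = {p.x for p, _, _ in cand.removed}
            surviving_x = set(cand.surviving.x)
            assert removed_x | surviving_x == set(s.x)
            assert removed_x & surviving_x == set()

    def test_deterministic_trace(self, rng):
        s = TimeSeries(np.arange(15, dtype=float), rng.normal(size=15))
        c1 = run_reference(s, 4, DetectionConfig(min_points=3))
        c2 = run_reference(s, 4, DetectionConfig(min_points=3))
        assert c1.trace == c2.trace
        assert c1.removed == c2.removed

    def test_planted_line_recovered_from_inlier_reference(self):
        spec = PlantedSpec(n_total=20, gradient=1.5, intercept=2.0,
                           inlier_fraction=0.45, deviation_range=(1.0, 50.0),
                           seed=7)
        s, mask = planted_line(spec)
        ref = int(np.flatnonzero(mask)[0])
        cand = run_reference(s, ref, DetectionConfig(k=0.0, min_points=3))
        assert set(cand.surviving.x) == set(s.x[mask])

    def test_missing_data_indifference(self):
        # deleting a deviant record before the run does not change which
        # inliers survive: the method needs no imputation
        spec = PlantedSpec(n_total=18, gradient=2.0, intercept=-3.0,
                           inlier_fraction=0.5, deviation_range=(1.0, 100.0),
                           seed=3)
        s, mask = planted_line(spec)
        ref = int(np.flatnonzero(mask)[0])
        cfg = DetectionConfig(k=0.0, min_points=3)
        full = run_reference(s, ref, cfg)
        drop = int(np.flatnonzero(~mask)[2])
        reduced_series = s.without(drop)
        new_ref = ref - 1 if drop < ref else ref
        reduced = run_reference(reduced_series, new_ref, cfg)
        assert set(full.surviving.x) == set(reduced.surviving.x)

    def test_ennol_stops_removal_early(self):
        spec = PlantedSpec(n_total=10, gradient=1.0, intercept=0.0,
                           inlier_fraction=0.4, deviation_range=(1.0, 100.0),
                           seed=11)
        s, mask = planted_line(spec)
        ref = int(np.flatnonzero(mask)[0])
        cand = run_reference(s, ref,
                             DetectionConfig(k=0.0, min_points=3, ennol=6))
        assert cand.surviving.n == 6
        assert cand.trace[-1].termination_reason == "ennol-reached"

    def test_natural_termination_beats_ennol(self):
        s = make_collinear(10, 1.0, 0.0)
        cand = run_reference(s, 0, DetectionConfig(min_points=3, ennol=4))
        assert cand.surviving.n == 10
        assert cand.trace[-1].termination_reason == "all-zero"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectionConfig(k=-1.0)
        with pytest.raises(ValueError):
            DetectionConfig(min_points=2)


class TestGxZeroRemedy:
    def test_symmetric_x_triggers_exclusion(self):
        s = TimeSeries([1, 2, 3], [5.0, 1.0, 7.0])
        reduced = handle_gx_zero(s, 1)
        assert reduced.n == 2  # the extreme |a - a_r| point was excluded
        assert 3.0 not in list(reduced.x)  # (3,7) deviates most from a_r=1

    def test_non_degenerate_input_returned_unchanged(self):
        s = TimeSeries([0, 1, 2], [1.0, 2.0, 3.0])
        assert handle_gx_zero(s, 0) is s

    def test_exclusion_restores_usable_geometry(self):
        s = TimeSeries([1, 2, 3], [5.0, 1.0, 7.0])
        reduced = handle_gx_zero(s, 1)
        # the reduced series transforms without error (ref now at index 1)
        ts = transform_multi_ref(reduced, 1)
        assert ts.gx_t != 0.0

    def test_detection_survives_symmetric_geometry(self):
        # x symmetric about the reference: the cycle must still run and
        # remove the outlier rather than fail
        s = TimeSeries([1, 2, 3, 4, 5], [10.0, 20.0, 30.0, 40.0, 500.0])
        cand = run_reference(s, 2, DetectionConfig(k=0.0, min_points=3))
        assert 5.0 not in set(cand.surviving.x)
        assert set(cand.surviving.x) >= {1.0, 2.0, 3.0, 4.0}


class TestAmbiguousTermination:
    def test_equal_ratios_with_structure_continue(self):
        # literature example: MMS_max = MMS_min = 0.33 yet the series does
        # not agree with a line; exclusion breaks the equality
        ts = _ts_from_att([0.0, -1.1, -2.1, 2.2, 1.0, 0.3])
        assert resolve_ambiguous_termination(ts, k=0.0) == "continue"

    def test_paired_extremes_flag_all_nonzero(self):
        # every non-zero value ties an extreme: no eligible exclusion, so
        # all non-zero terms disagree with the fit
        ts = _ts_from_att([1.1, 1.1, 0.0, 0.0, 0.0, -1.1, -1.1])
        assert resolve_ambiguous_termination(ts, k=0.0) == \
            "all-nonzero-flagged"

    def test_ambiguity_resolved_inside_cycle(self):
        # construct a raw series whose first transform (ref = first point)
        # has MMS_max = MMS_min = 2/n exactly (residual sum 0, max = -min)
        # yet clearly disagrees with a line; the cycle must not stop there
        # but remove the true extreme via the exclusion remedy
        x = np.arange(6, dtype=float)
        att = np.array([0.0, 2.2, -2.2, 1.1, -1.1, 0.0])
        a = 10.0 + att + 2.0 * x
        cand = run_reference(TimeSeries(x, a), 0,
                             DetectionConfig(k=0.0, min_points=3))
        assert cand.removed  # detection continued past the tied state
        first = cand.removed[0][0]
        assert (first.x, first.a) == (1.0, a[1])  # the +2.2 deviant
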