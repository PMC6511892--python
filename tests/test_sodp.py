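"""Second-order-difference-plot construction and the four ClassA metrics.

The independent oracle used throughout is a naive per-point loop: each SODP
point's angle is computed with math.atan2 and its quadrant read off the
coordinate signs, one point at a time.
"""

import math

import numpy as np
import pytest

from classa.preprocess import UniformHRV, coarse_grain
from classa.sodp import (
    build_sodp,
    classa_batch,
    classa_window,
    q3_proportion_batch,
    quadrant_proportions,
    real_angle_sum,
    three_point_forward_diff,
)


def oracle_sodp(values):
    """Brute-force SODP: per-point angles/quadrants via math.atan2."""
    v = list(map(float, values))
    d = [(4 * v[i + 1] - 3 * v[i] - v[i + 2]) / 2 for i in range(len(v) - 2)]
    pts, angs, quads = [], [], []
    for i in range(len(d) - 1):
        px, py = d[i], d[i + 1]
        pts.append((px, py))
        if px == 0 and py == 0:
            angs.append(None)
            quads.append("BOUNDARY")
            continue
        a = math.degrees(math.atan2(py, px))
        angs.append(a + 360.0 if a < 0 else a)
        if px > 0 and py > 0:
            quads.append("Q1")
        elif px < 0 and py > 0:
            quads.append("Q2")
        elif px < 0 and py < 0:
            quads.append("Q3")
        elif px > 0 and py < 0:
            quads.append("Q4")
        else:
            quads.append("BOUNDARY")
    return pts, angs, quads


class TestDifferenceSeries:
    def test_linear_sequence_gives_constant_slope(self, make_hrv):
        d = three_point_forward_diff(make_hrv(np.arange(1, 21, dtype=float)))
        np.testing.assert_allclose(d.d, 1.0)
        assert len(d) == 18

    def test_alternating_sequence(self, make_hrv):
        d = three_point_forward_diff(make_hrv([0, 1, 0, 1, 0, 1]))
        np.testing.assert_allclose(d.d, [2, -2, 2, -2])

    def test_constant_gives_zero(self, make_hrv):
        d = three_point_forward_diff(make_hrv([0.8] * 10))
        np.testing.assert_allclose(d.d, 0.0)

    def test_short_input_rejected(self, make_hrv):
        with pytest.raises(ValueError):
            three_point_forward_diff(make_hrv([1.0, 2.0, 3.0]))


class TestBuildSODP:
    def test_linear_up_all_q1_at_45deg(self, make_hrv):
        s = build_sodp(make_hrv(np.arange(40, dtype=float)))
        assert len(s) == 37
        np.testing.assert_allclose(s.points, 1.0)
        np.testing.assert_allclose(s.angles, 45.0)
        assert set(s.quadrants) == {"Q1"}

    def test_linear_down_all_q3_at_225deg(self, make_hrv):
        s = build_sodp(make_hrv(-np.arange(40, dtype=float)))
        np.testing.assert_allclose(s.angles, 225.0)
        assert set(s.quadrants) == {"Q3"}

    def test_alternating_q2_q4(self, make_hrv):
        s = build_sodp(make_hrv([0, 1, 0, 1, 0, 1]))
        np.testing.assert_allclose(s.points, [(2, -2), (-2, 2), (2, -2)])
        np.testing.assert_allclose(s.angles, [315.0, 135.0, 315.0])
        assert list(s.quadrants) == ["Q4", "Q2", "Q4"]

    def test_constant_is_degenerate(self, make_hrv):
        s = build_sodp(make_hrv([0.8] * 10))
        assert s.is_degenerate
        assert set(s.quadrants) == {"BOUNDARY"}


class TestRealAngleSum:
    def test_increasing_ramp(self, make_hrv):
        s = build_sodp(make_hrv(np.arange(40, dtype=float)))
        assert real_angle_sum(s) == pytest.approx(37 * 45 / 40)  # 41.625
        assert 0 < real_angle_sum(s) < 90

    def test_decreasing_ramp(self, make_hrv):
        s = build_sodp(make_hrv(-np.arange(40, dtype=float)))
        assert real_angle_sum(s) == pytest.approx(37 * 225 / 40)  # 208.125
        assert 180 < real_angle_sum(s) < 270

    def test_constant_degenerate_zero(self, make_hrv):
        s = build_sodp(make_hrv([1.0] * 12))
        assert real_angle_sum(s) == 0.0 and s.is_degenerate

    def test_points_denominator(self, make_hrv):
        s = build_sodp(make_hrv(np.arange(40, dtype=float)))
        assert real_angle_sum(s, denominator="points") == pytest.approx(45.0)


class TestQuadrantProportions:
    def test_ramp_proportions(self, make_hrv):
        s = build_sodp(make_hrv(np.arange(40, dtype=float)))
        pq1, pq24, q3 = quadrant_proportions(s)
        assert (pq1, pq24, q3) == (37 / 40, 0.0, 0.0)

    def test_alternating_proportions(self, make_hrv):
        v = np.where(np.arange(40) % 2 == 0, 0.0, 1.0)
        pq1, pq24, q3 = quadrant_proportions(build_sodp(make_hrv(v)))
        assert (pq1, pq24, q3) == (0.0, 37 / 40, 0.0)

    def test_constant_all_zero(self, make_hrv):
        assert quadrant_proportions(build_sodp(make_hrv([2.0] * 10))) == (0, 0, 0)

    def test_partition_sums_to_point_fraction(self, rng, make_hrv):
        # quadrants + boundary exhaust the N-3 points exactly
        for _ in range(20):
            n = int(rng.integers(10, 60))
            s = build_sodp(make_hrv(rng.normal(0.8, 0.1, n)))
            total = (
                s.quadrant_count("Q1")
                + s.quadrant_count("Q2")
                + s.quadrant_count("Q3")
                + s.quadrant_count("Q4")
                + s.quadrant_count("BOUNDARY")
            )
            assert total == n - 3


class TestClassAWindow:
    def test_published_sample_counts(self, make_hrv):
        res = classa_window(
            make_hrv(np.random.default_rng(0).normal(0.8, 0.05, 40)),
            make_hrv(np.random.default_rng(1).normal(0.8, 0.05, 240)),
            tau=7,
        )
        assert res.n_scale1 == 40 and res.n_scale_tau == 34

    def test_decreasing_long_window_pq3(self, make_hrv):
        # coarse-graining preserves strict decrease -> all points in Q3
        res = classa_window(
            make_hrv(np.arange(40, dtype=float)),
            make_hrv(-np.arange(240, dtype=float)),
            tau=7,
        )
        assert res.pq3 == pytest.approx((34 - 3) / 34)

    def test_too_short_after_coarse_graining_rejected(self, make_hrv):
        with pytest.raises(ValueError):
            classa_window(
                make_hrv(np.arange(40.0)), make_hrv(np.arange(20.0)), tau=7
            )


class TestInvariances:
    def _metrics(self, values):
        s = build_sodp(UniformHRV(np.asarray(values, float), 4.0))
        return real_angle_sum(s), *quadrant_proportions(s)

    def test_shift_invariance(self, rng):
        # exact algebraically; floating-point rounding leaves ulp-level noise
        for _ in range(30):
            v = rng.normal(0.8, 0.1, int(rng.integers(10, 50)))
            np.testing.assert_allclose(
                self._metrics(v), self._metrics(v + 5.0), atol=1e-9
            )

    def test_positive_scaling_invariance(self, rng):
        for _ in range(30):
            v = rng.normal(0.0, 1.0, int(rng.integers(10, 50)))
            m1, m2 = self._metrics(v), self._metrics(v * 3.5)
            np.testing.assert_allclose(m1, m2, atol=1e-9)

    def test_negation_reflects_through_origin(self, rng):
        for _ in range(30):
            v = rng.normal(0.0, 1.0, int(rng.integers(10, 50)))
            s, sn = build_sodp(UniformHRV(v, 4.0)), build_sodp(UniformHRV(-v, 4.0))
            np.testing.assert_allclose(sn.points, -s.points, atol=1e-12)
            assert s.quadrant_count("Q1") == sn.quadrant_count("Q3")
            assert s.quadrant_count("Q2") == sn.quadrant_count("Q4")

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            v = rng.normal(0.8, 0.1, int(rng.integers(10, 51)))
            s = build_sodp(UniformHRV(v, 4.0))
            pts, angs, quads = oracle_sodp(v)
            np.testing.assert_allclose(s.points, pts, atol=1e-12)
            assert list(s.quadrants) == quads
            for a_prod, a_oracle in zip(s.angles, angs):
                if a_oracle is not None:
                    assert abs(a_prod - a_oracle) < 1e-9


class TestBatchPath:
    def test_batch_equals_per_window(self, rng):
        W = rng.normal(0.8, 0.1, (50, 40))
        ras, pq1, pq24, q3 = classa_batch(W)
        for i in range(50):
            s = build_sodp(UniformHRV(W[i], 4.0))
            assert ras[i] == pytest.approx(real_angle_sum(s), abs=1e-12)
            p1, p24, p3 = quadrant_proportions(s)
            assert (pq1[i], pq24[i], q3[i]) == (p1, p24, p3)

    def test_q3_batch_equals_coarse_per_window(self, rng):
        W = rng.normal(0.8, 0.1, (20, 240))
        q3 = q3_proportion_batch(W, tau=7)
        for i in range(20):
            xc = coarse_grain(UniformHRV(W[i], 4.0), 7)
            assert q3[i] == quadrant_proportions(build_sodp(xc))[2]
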