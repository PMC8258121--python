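"""Non-local PG depletion and its coupled FCD / hydration updates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cared.pg_depletion import (NonlocalParams, element_average, fcd_from_pg,
                                gauss_weight, hydration_from_pg,
                                nonlocal_field, update_pg)


class TestGaussWeight:
    def test_peak_value(self):
        l = 0.18
        peak = gauss_weight(np.zeros(3), np.zeros(3), l)
        assert peak == pytest.approx((2 * np.pi) ** -1.5 * l ** -3)

    def test_exponent_scale(self):
        l = 0.2
        d = l * np.sqrt(2)
        w = gauss_weight(np.zeros(3), np.array([d, 0, 0]), l)
        peak = gauss_weight(np.zeros(3), np.zeros(3), l)
        assert w / peak == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_far_field_vanishes(self):
        assert gauss_weight(np.zeros(3), np.array([50.0, 0, 0]), 0.2) < 1e-30


def brute_force_nonlocal(values, points, l):
    """O(N²) double-loop oracle with the explicit Gauss weight."""
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            w = gauss_weight(points[i], points[j], l)
            num += w * values[j]
            den += w
        out[i] = num / den
    return out


class TestNonlocalField:
    def test_constant_field_preserved(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, (50, 3))
        out = nonlocal_field(np.full(50, 0.37), pts, NonlocalParams(l=0.3))
        np.testing.assert_allclose(out, 0.37, rtol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1.5, (120, 3))
        vals = rng.uniform(0, 0.6, 120)
        p = NonlocalParams(l=0.18)
        got = nonlocal_field(vals, pts, p)
        np.testing.assert_allclose(got, brute_force_nonlocal(vals, pts, p.l),
                                   atol=1e-12)

    def test_spike_smoothed_below_peak(self):
        pts = np.stack([np.linspace(0, 1.5, 40), np.zeros(40),
                        np.zeros(40)], axis=1)
        vals = np.zeros(40)
        vals[20] = 1.0
        out = nonlocal_field(vals, pts, NonlocalParams(l=0.18))
        assert out.max() < 1.0
        assert out.min() >= 0.0
        assert np.argmax(out) == 20

    def test_max_principle_and_linearity(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, (80, 3))
        a = rng.uniform(0, 1, 80)
        b = rng.uniform(0, 1, 80)
        p = NonlocalParams(l=0.25)
        na, nb = nonlocal_field(a, pts, p), nonlocal_field(b, pts, p)
        assert na.min() >= a.min() - 1e-12 and na.max() <= a.max() + 1e-12
        np.testing.assert_allclose(nonlocal_field(2 * a + 3 * b, pts, p),
                                   2 * na + 3 * nb, atol=1e-10)

    def test_small_length_approaches_local_field(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1.5, (60, 3))
        vals = rng.uniform(0, 1, 60)
        out = nonlocal_field(vals, pts, NonlocalParams(l=1e-3))
        np.testing.assert_allclose(out, vals, atol=1e-8)

    def test_kdtree_truncation_matches_dense(self):
        """Above the dense-size cutoff the truncated sum stays exact to 1e-6."""
        rng = np.random.default_rng(4)
        n = 2500
        pts = rng.uniform(0, 1.5, (n, 3))
        vals = rng.uniform(0, 1, n)
        p = NonlocalParams(l=0.12)
        got = nonlocal_field(vals, pts, p)   # kd-tree path (n > 2000)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        W = np.exp(-d2 / (2 * p.l ** 2))
        dense = (W @ vals) / W.sum(1)
        assert np.abs(got - dense).max() / np.abs(dense).max() < 1e-6

    def test_element_average(self):
        vals = np.array([1.0, 3.0, 10.0, 20.0])
        el = np.array([0, 0, 1, 1])
        np.testing.assert_allclose(element_average(vals, el, 2), [2.0, 15.0])


class TestUpdatePG:
    def test_at_threshold_unchanged(self):
        assert update_pg(0.8, 0.30, 0.30) == 0.8
        assert update_pg(0.8, 0.10, 0.30) == 0.8

    def test_depletion_value(self):
        assert update_pg(1.0, 0.45, 0.30) == pytest.approx(0.95)

    def test_factor_clamped_at_zero(self):
        # stimulus far above threshold cannot make PG negative
        assert update_pg(0.5, 4.0, 0.30) == 0.0

    @given(st.floats(0, 1), st.floats(0, 2))
    @settings(max_examples=80, deadline=None)
    def test_bounded_and_monotone(self, pg, eps):
        out = update_pg(pg, eps, 0.30)
        assert 0.0 <= out <= pg + 1e-15


class TestCoupledUpdates:
    def test_fcd_proportionality(self):
        assert fcd_from_pg(0.18, 0.5) == pytest.approx(0.09)
        assert fcd_from_pg(0.18, 1.0) == 0.18
        assert fcd_from_pg(0.18, 0.0) == 0.0

    def test_fcd_exact_proportionality_array(self):
        rng = np.random.default_rng(5)
        FCD0 = rng.uniform(0.05, 0.3, 40)
        PG = rng.uniform(0, 1, 40)
        np.testing.assert_array_equal(fcd_from_pg(FCD0, PG), FCD0 * PG)

    def test_hydration_endpoints(self):
        assert hydration_from_pg(0.8, 1.0) == pytest.approx(0.8)
        assert hydration_from_pg(0.8, 0.0) == pytest.approx(1.0)
        assert hydration_from_pg(0.8, 0.5) == pytest.approx(0.9)

    def test_hydration_printed_variant_flagged_behaviour(self):
        # audit-only form exceeds 1 and does not recover n_f0
        assert hydration_from_pg(0.8, 1.0, printed_variant=True) == \
            pytest.approx(1.2)

    @given(st.floats(0.5, 0.95), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=80, deadline=None)
    def test_hydration_monotone_in_depletion(self, nf0, pg1, pg2):
        lo, hi = min(pg1, pg2), max(pg1, pg2)
        n_lo = hydration_from_pg(nf0, hi)   # less depleted
        n_hi = hydration_from_pg(nf0, lo)   # more depleted
        assert nf0 - 1e-12 <= n_lo <= n_hi <= 1.0 + 1e-12
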