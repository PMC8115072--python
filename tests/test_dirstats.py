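"""Circular statistics: binning, smoothing, modality, uniformity tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gridwave as gw
from gridwave.dirstats import _smooth_circular


def vonmises_deg(rng, mu_deg, kappa, n):
    return np.rad2deg(rng.vonmises(np.deg2rad(mu_deg), kappa, n)) % 360.0


def circ_diff(a, b):
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


class TestBuildDistribution:
    def test_vonmises_mixture_classified_bidirectional(self):
        """0.7/0.3 mixture at 30/210 deg, kappa=4: bidirectional with modes
        within one bin of the planted directions (Monte Carlo, 10 seeds)."""
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            d = np.r_[vonmises_deg(rng, 30.0, 4.0, 1400),
                      vonmises_deg(rng, 210.0, 4.0, 600)]
            dist = gw.build_distribution(d)
            good = (
                dist.modality == "bidirectional"
                and circ_diff(dist.modes[0], 30.0) <= 10.0
                and circ_diff(dist.modes[1], 210.0) <= 10.0
                and dist.test_name == "hodges_ajne"
            )
            ok += good
        assert ok >= 9

    def test_single_vonmises_unidirectional(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            dist = gw.build_distribution(vonmises_deg(rng, 90.0, 4.0, 2000))
            ok += (dist.modality == "unidirectional"
                   and circ_diff(dist.modes[0], 90.0) <= 10.0
                   and dist.test_name == "rayleigh")
        assert ok >= 9

    def test_tiny_secondary_weight_stays_unidirectional(self):
        rng = np.random.default_rng(3)
        d = np.r_[vonmises_deg(rng, 30.0, 8.0, 1960),
                  vonmises_deg(rng, 210.0, 8.0, 40)]
        dist = gw.build_distribution(d)
        assert dist.modality == "unidirectional"

    def test_counts_conserved_and_sum_matches_n(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 360, 500)
        dist = gw.build_distribution(d)
        assert dist.counts.sum() == 500
        assert dist.smoothed.sum() == pytest.approx(500.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gw.build_distribution(np.array([]))

    @given(shift=st.floats(min_value=0.0, max_value=350.0))
    @settings(max_examples=20, deadline=None)
    def test_modes_rotate_with_global_shift(self, shift):
        """Rotating every direction by a multiple of the bin width shifts
        the modes by exactly that amount."""
        shift = round(shift / 10.0) * 10.0
        rng = np.random.default_rng(7)
        d = np.r_[vonmises_deg(rng, 25.0, 6.0, 700),
                  vonmises_deg(rng, 205.0, 6.0, 500)]
        base = gw.build_distribution(d)
        moved = gw.build_distribution((d + shift) % 360.0)
        expected = sorted((np.array(base.modes) + shift) % 360.0)
        assert np.allclose(circ_diff(sorted(moved.modes), expected), 0.0,
                           atol=1e-6)

    def test_smoothing_mass_preserving(self):
        rng = np.random.default_rng(9)
        c = rng.integers(0, 50, 36).astype(float)
        assert _smooth_circular(c).sum() == pytest.approx(c.sum())


def brute_force_hodges_ajne_m(deg):
    """Oracle: sweep every half-plane boundary; m = min count in a closed
    half-circle."""
    rad = np.deg2rad(np.asarray(deg) % 360.0)
    m = len(rad)
    for a in np.r_[rad, rad + np.pi, rad - 1e-9, rad + np.pi - 1e-9]:
        d = (rad - a) % (2 * np.pi)
        inside = np.sum(d <= np.pi)
        m = min(m, inside, len(rad) - inside)
    return int(m)


class TestHodgesAjne:
    def test_half_circle_cluster_exact_p(self):
        """All 10 points in one half-circle: m = 0 and the exact tail
        probability is 10/512."""
        d = np.linspace(10, 120, 10)
        m, p = gw.hodges_ajne_test(d)
        assert m == 0
        assert p == pytest.approx(10 / 512)

    def test_uniform_fan_balanced(self):
        d = np.arange(0, 360, 10.0)
        m, p = gw.hodges_ajne_test(d)
        assert m == 18 and p == 1.0

    def test_matches_brute_force_small_n(self):
        rng = np.random.default_rng(21)
        for n in range(4, 13):
            for _ in range(30):
                d = rng.uniform(0, 360, n)
                m, p = gw.hodges_ajne_test(d)
                assert m == brute_force_hodges_ajne_m(d)
                if 2 * m < n:
                    from math import comb
                    assert p == pytest.approx(
                        min(1.0, (n - 2 * m) * comb(n, m) / 2 ** (n - 1))
                    )

    def test_antipodal_clusters_small_m_not_guaranteed(self):
        """Tight antipodal clusters: the best half-circle isolates the
        lighter lobe, so m equals its weight. An unbalanced 30/10 pair is
        detected only at moderate significance, and a perfectly balanced
        20/20 pair is invisible to the statistic (m = n/2, p = 1) — the
        test detects non-uniformity, not bimodality per se."""
        rng = np.random.default_rng(22)
        unbal = np.r_[vonmises_deg(rng, 30.0, 50.0, 30),
                      vonmises_deg(rng, 210.0, 50.0, 10)]
        m_u, p_u = gw.hodges_ajne_test(unbal)
        assert 8 <= m_u <= 10 and 0.001 < p_u < 0.1
        bal = np.r_[vonmises_deg(rng, 30.0, 50.0, 20),
                    vonmises_deg(rng, 210.0, 50.0, 20)]
        m_b, p_b = gw.hodges_ajne_test(bal)
        assert m_b >= 14 and p_b > 0.3

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            gw.hodges_ajne_test(np.array([0.0, 10.0, 20.0]))


class TestRayleigh:
    def test_identical_angles_maximal_concentration(self):
        rbar, z, p = gw.rayleigh_test(np.full(43, 77.0))
        assert rbar == pytest.approx(1.0)
        assert z == pytest.approx(43.0)
        assert 0.0 <= p < 1e-15  # underflow-safe extreme significance

    def test_equally_spaced_angles_cancel(self):
        rbar, z, p = gw.rayleigh_test(np.arange(0, 360, 30.0))
        assert rbar == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(33)
        for n in (10, 50, 200):
            d = vonmises_deg(rng, 120.0, 1.0, n)
            _, z, p = gw.rayleigh_test(d)
            z_pg, p_pg = pg.circ_rayleigh(np.deg2rad(d))
            assert z == pytest.approx(z_pg, rel=1e-9)
            assert p == pytest.approx(p_pg, rel=1e-6)

    def test_null_calibration(self):
        """Uniform samples reject at ~5% at alpha = 0.05."""
        rng = np.random.default_rng(44)
        rejections = sum(
            gw.rayleigh_test(rng.uniform(0, 360, 50))[2] < 0.05
            for _ in range(2000)
        )
        assert 60 <= rejections <= 140  # binomial(2000, .05): mean 100, sd 9.7


class TestCommonMedian:
    def test_identical_groups_no_separation(self):
        d = np.linspace(0, 359, 40)
        stat, p = gw.common_median_test([d, d.copy()])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_null_calibration(self):
        """Two groups from the same von Mises: false-positive rate near
        alpha (400 replicates)."""
        rng = np.random.default_rng(55)
        rejections = 0
        for _ in range(400):
            a = vonmises_deg(rng, 100.0, 2.0, 60)
            b = vonmises_deg(rng, 100.0, 2.0, 60)
            rejections += gw.common_median_test([a, b])[1] < 0.05
        assert 6 <= rejections <= 44  # binomial(400, .05): mean 20, sd 4.4

    def test_power_against_32_degree_rotation(self):
        """Groups offset by 32 degrees (kappa=8, n=200) separate at
        p < 0.001 in >= 95% of replicates — the scale of the
        physical-rotation control experiment."""
        rng = np.random.default_rng(66)
        hits = sum(
            gw.common_median_test(
                [vonmises_deg(rng, 100.0, 8.0, 200),
                 vonmises_deg(rng, 132.0, 8.0, 200)]
            )[1] < 0.001
            for _ in range(40)
        )
        assert hits >= 38

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            gw.common_median_test([np.arange(5.0), np.arange(20.0)])


class TestAngleSplit:
    def test_wedge_membership(self):
        idx0, idx1 = gw.angle_split(np.array([50.0]), (30.0, 210.0))
        assert list(idx0) == [0] and list(idx1) == []

    def test_outside_both_wedges_dropped(self):
        idx0, idx1 = gw.angle_split(np.array([120.0]), (30.0, 210.0))
        assert idx0.size == 0 and idx1.size == 0

    def test_planted_regime_ratio_recovered(self):
        rng = np.random.default_rng(77)
        d = np.r_[vonmises_deg(rng, 30.0, 6.0, 600),
                  vonmises_deg(rng, 210.0, 6.0, 400)]
        idx0, idx1 = gw.angle_split(d, (30.0, 210.0))
        ratio = idx0.size / (idx0.size + idx1.size)
        assert ratio == pytest.approx(0.6, abs=0.04)

    def test_overlapping_wedges_rejected(self):
        with pytest.raises(ValueError):
            gw.angle_split(np.array([0.0]), (30.0, 100.0), half_width=45.0)

    def test_disjoint_sets(self):
        rng = np.random.default_rng(88)
        d = rng.uniform(0, 360, 1000)
        idx0, idx1 = gw.angle_split(d, (0.0, 180.0))
        assert not set(idx0) & set(idx1)
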