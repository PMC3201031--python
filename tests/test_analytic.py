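"""Closed-form model checks: survival/transit kernels, the two- and
one-factor reinitiation probabilities, conversions and sweeps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from gcn4sim.analytic import (
    ReinitPrediction,
    distance_sweep,
    factorx_sensitivity,
    model1_gcn4_construct_d_pct,
    model1_gcn4_with_uorf4_pct,
    model1_p1,
    model1_p2,
    model1_p3,
    model1_uorf4_pct,
    model2_gcn4_pct,
    model2_uorf4_pct,
    observed_gcn4_pct,
    observed_uorf4_pct,
    survival_probability,
    tc_dependence_curve,
    transit_density,
)
from gcn4sim.layout import ReporterActivities, RateSet


class TestSurvival:
    @pytest.mark.parametrize(
        "a_s,a_d,n,expected",
        [
            (30.0, 0.0, 1000, 1.0),
            (30.0, 30.0, 1, 0.5),
            (30.0, 1.35, 32, 0.2445),  # direct evaluation of (30/31.35)**32
        ],
    )
    def test_values(self, a_s, a_d, n, expected):
        assert survival_probability(a_s, a_d, n) == pytest.approx(
            expected, rel=1e-3
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            survival_probability(30.0, -1.0, 5)
        with pytest.raises(ValueError):
            survival_probability(30.0, 1.0, -5)

    def test_large_n_underflows_gracefully(self):
        assert survival_probability(30.0, 1.0, 10**6) == pytest.approx(0.0)


class TestTransitDensity:
    def test_origin(self):
        assert transit_density(30.0, 1.35, 0, 0.0) == 1.0
        assert transit_density(30.0, 1.35, 5, 0.0) == 0.0

    def test_time_integral_matches_survival(self):
        # integrating the joint density over all arrival times gives the
        # positional marginal: survival / total rate
        a_s, a_d, n = 30.0, 1.35, 32
        integral, _ = quad(
            lambda t: transit_density(a_s, a_d, n, t), 0, 60, limit=200
        )
        assert integral == pytest.approx(
            survival_probability(a_s, a_d, n) / (a_s + a_d), rel=1e-8
        )

    def test_mode_at_n_over_total_rate(self):
        a_s, a_d, n = 30.0, 1.35, 32
        t_star = n / (a_s + a_d)
        peak = transit_density(a_s, a_d, n, t_star)
        for dt in (-0.05, 0.05):
            assert transit_density(a_s, a_d, n, t_star + dt) < peak


class TestModel1:
    def test_no_factors_never_assembles(self):
        bare = RateSet(30.0, 0.0, 0.0)
        for n in (0, 10, 500):
            assert model1_p1(bare, n) == 0.0
        assert model1_p1(RateSet(30.0, 1.0, 0.0), 100) == 0.0  # one factor only

    def test_empty_scan_gives_zero(self, derepressing):
        assert model1_p1(derepressing, 0) == 0.0

    def test_p2_trivial_zeros(self, derepressing):
        no_x = RateSet(30.0, 1.35, 0.0)
        assert model1_p2(no_x, 32, 151) == 0.0
        assert model1_p2(derepressing, 32, 0) == 0.0

    def test_p3_vanishes_for_long_n1(self, derepressing):
        assert model1_p3(derepressing, 10**4, 151) < 1e-12

    @pytest.mark.parametrize(
        "fn,args,expected",
        [
            (model1_p2, (32, 151), 0.39480),  # frozen from direct summation,
            (model1_p3, (32, 151), 0.09005),  # cross-checked by the MC oracle
        ],
    )
    def test_frozen_derepressing_values(self, derepressing, fn, args, expected):
        assert fn(derepressing, *args) == pytest.approx(expected, rel=1e-4)

    def test_uorf4_pct_undefined_when_p1_zero(self):
        with pytest.raises(ZeroDivisionError):
            model1_uorf4_pct(RateSet(30.0, 0.0, 0.0), 32, 151)

    def test_construct_d_limits(self, derepressing):
        assert model1_gcn4_construct_d_pct(derepressing, 0) == 0.0
        saturating = RateSet(1.0, 1e4, 1e4)
        assert model1_gcn4_construct_d_pct(saturating, 100) == pytest.approx(
            100.0, abs=1e-6
        )

    @given(
        log_tc=st.floats(-4, 0),
        log_x=st.floats(-4, 0),
        n1=st.integers(0, 300),
        n2=st.integers(0, 300),
    )
    @settings(max_examples=50, deadline=None)
    def test_probability_ordering_invariant(self, log_tc, log_x, n1, n2):
        """The two main-ORF paths, minus the boundary term they share (an
        extra-factor binding exactly at the uORF4 position belongs to both
        summations), are a sub-event of full two-factor assembly:
        0 <= P2 + P3 - shared <= P1(n1+n2) <= 1."""
        rates = RateSet(30.0, 30.0 * 10**log_tc, 30.0 * 10**log_x)
        p1 = model1_p1(rates, n1 + n2)
        p2 = model1_p2(rates, n1, n2)
        p3 = model1_p3(rates, n1, n2)
        shared = (
            rates.p_s1**n1
            * rates.p_x1
            * (1.0 - rates.p_s3**n2)
        )
        assert 0.0 <= p2 + p3
        assert p2 + p3 - shared <= p1 + 1e-9
        assert p1 <= 1.0 + 1e-12

    def test_bundle_consistency(self, repressing):
        pred = ReinitPrediction.compute(repressing, 32, 151)
        assert pred.p_gcn4_with_uorf4_pct == pytest.approx(
            100 * (pred.p2 + pred.p3)
        )
        assert pred.p_uorf4_pct == pytest.approx(
            100 * (pred.p1 - pred.p2 - pred.p3) / pred.p1
        )


class TestModel2:
    def test_trivial_limits(self):
        assert model2_uorf4_pct(30.0, 0.0, 500) == 0.0
        assert model2_uorf4_pct(30.0, 1.35, 10**5) == pytest.approx(100.0)
        assert model2_gcn4_pct(30.0, 1.35, 32, 0) == 0.0
        assert model2_gcn4_pct(30.0, 0.0, 32, 151) == 0.0

    def test_most_ribosomes_commit_after_short_scan_when_replete(self):
        # ~3/4 of scanners translate the inhibitory uORF after only 32 nt
        # at the replete-condition TC binding rate
        assert model2_uorf4_pct(30.0, 1.35, 32) == pytest.approx(75.55, rel=1e-3)

    def test_two_algebraic_forms_identical(self):
        for a_tc in (0.17, 1.35):
            for n1, n2 in ((32, 151), (200, 150), (7, 3)):
                ps = 30.0 / (30.0 + a_tc)
                direct = 100.0 * (ps**n1) * (1.0 - ps**n2)
                expanded = 100.0 * (ps**n1 - ps ** (n1 + n2))
                assert model2_gcn4_pct(30.0, a_tc, n1, n2) == pytest.approx(
                    direct, abs=1e-12
                )
                assert direct == pytest.approx(expanded, abs=1e-10)

    def test_model1_reduces_to_model2_at_saturating_extra_factor(self):
        """With the extra factor binding instantaneously the two-factor
        model collapses onto the one-factor form (< 0.1 pp everywhere)."""
        a_s = 30.0
        for n1 in (10, 50, 100, 200, 350):
            for n2 in (10, 100, 151, 300, 500):
                for a_tc in (0.17, 1.35, 4.0):
                    m1 = model1_gcn4_with_uorf4_pct(
                        RateSet(a_s, a_tc, 1e6 * a_s), n1, n2
                    )
                    m2 = model2_gcn4_pct(a_s, a_tc, n1, n2)
                    assert abs(m1 - m2) < 0.1


class TestObservedConversions:
    def test_uorf4_arithmetic(self):
        assert observed_uorf4_pct(ReporterActivities(a1=20, a2=100)) == 80.0
        assert observed_uorf4_pct(ReporterActivities(a1=100, a2=100)) == 0.0
        assert observed_uorf4_pct(ReporterActivities(a1=0, a2=100)) == 100.0
        with pytest.raises(ValueError):
            observed_uorf4_pct(ReporterActivities(a1=1, a2=0))

    def test_gcn4_normalisation(self):
        act = ReporterActivities(a2=2, a3=4, a2_ref=1, a3_ref=1)
        assert observed_gcn4_pct(act) == 50.0
        ref_equal = ReporterActivities(a2=3, a3=6, a2_ref=1, a3_ref=2)
        assert observed_gcn4_pct(ref_equal) == 100.0
        assert observed_gcn4_pct(ReporterActivities(a2=0, a3=1)) == 0.0


class TestSweeps:
    def test_single_point_grid_is_its_own_optimum(self, derepressing):
        df, (a_opt, p_opt) = tc_dependence_curve(derepressing, 200, 151, [0.5])
        assert len(df) == 1 and a_opt == 0.5

    def test_tc_curve_unimodal_on_log_grid(self, derepressing):
        grid = np.geomspace(1e-4, 0.1, 120) * 30.0
        df, _ = tc_dependence_curve(derepressing, 200, 151, grid)
        y = df["gcn4_pct"].to_numpy()
        signs = np.sign(np.diff(y))
        changes = np.sum(np.diff(signs[signs != 0]) != 0)
        assert changes == 1  # rises then falls: one interior optimum

    def test_models_nearly_superimposable_at_natural_distances(self, derepressing):
        """At natural spacings the extra factor is always acquired, so the
        one- and two-factor TC-dependence curves coincide (< 5 pp gap)."""
        grid = np.geomspace(1e-4, 0.1, 60) * 30.0
        df1, _ = tc_dependence_curve(derepressing, 200, 151, grid, model="model1")
        gap = np.abs(
            df1["gcn4_pct"].to_numpy()
            - np.array([model2_gcn4_pct(30.0, g, 200, 151) for g in grid])
        )
        assert gap.max() < 5.0

    def test_factorx_reductions(self, derepressing):
        df = factorx_sensitivity(derepressing, 200, 151, [1, 5, 10])
        base, five, ten = df["optimum_pct"].to_numpy()
        assert np.all(np.diff(df["optimum_pct"].to_numpy()) <= 1e-12)
        # five-fold depletion barely detectable; ten-fold costs roughly a fifth
        assert abs(five - base) / base < 0.05
        assert 0.05 < (base - ten) / base < 0.30

    def test_distance_sweep_shapes(self, repressing, derepressing):
        one = distance_sweep(derepressing, "n1", 151, [100])
        assert len(one) == 1
        # shortening n1 promotes main-ORF reinitiation monotonically when
        # amino acids are replete; by natural spacing it has collapsed
        rep = distance_sweep(repressing, "n1", 151, list(range(0, 201, 10)))
        y = rep["gcn4_pct"].to_numpy()
        assert np.all(np.diff(y) < 0)
        assert y[0] / y[-1] > 100
        # lengthening n2 from natural to 600 nt raises starved-cell
        # reinitiation by at least half
        der = distance_sweep(derepressing, "n2", 200, [150, 600])
        assert der["gcn4_pct"].iloc[1] / der["gcn4_pct"].iloc[0] > 1.5
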