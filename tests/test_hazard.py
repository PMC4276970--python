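import numpy as np
import pytest

import relapsim as rs
from relapsim.hazard import hazard_to_rate


class TestDiscreteHazard:
    def test_hand_counted_life_table(self, hand_dataset):
        """Life table for times [2,5,8,8,11], events [1,1,1,0,1], width 3."""
        b = rs.discrete_hazard(hand_dataset, 3.0)
        assert np.array_equal(b.n_at_risk, [5, 4, 3, 1])
        assert np.array_equal(b.n_events, [1, 1, 1, 1])
        assert b.hazard == pytest.approx([0.2, 0.25, 1 / 3, 1.0])

    def test_no_events_gives_zero_hazard(self):
        data = rs.SurvivalDataset(np.array([3.0, 7.0, 12.0]),
                                  np.zeros(3, bool))
        b = rs.discrete_hazard(data, 3.0)
        assert np.all(b.hazard[b.defined] == 0.0)

    def test_risk_sets_non_increasing_and_cover_max_time(self):
        data = rs.SurvivalDataset(np.array([1.0, 2.0, 14.0]),
                                  np.array([True, True, True]))
        b = rs.discrete_hazard(data, 3.0)
        assert b.edges[-1] > 14.0  # bins cover the largest observed time
        assert np.all(np.diff(b.n_at_risk) <= 0)
        assert np.all(b.defined)  # risk set nonempty up to max(time)
        assert b.hazard[-1] == 1.0  # last subject relapses in the last bin

    def test_empty_risk_set_is_nan_flagged(self):
        # a hand-built life table with an emptied risk set: undefined, not 0
        edges = np.arange(0.0, 9.1, 3.0)
        h = np.where(np.array([10.0, 0.0, 0.0]) > 0, 0.1, np.nan)
        b = rs.BinnedHazard(3.0, edges, np.array([10.0, 0.0, 0.0]),
                            np.array([1, 0, 0]), h)
        assert not b.defined[1] and np.isnan(b.hazard[1])

    def test_actuarial_option_half_weights_in_bin_censorings(self, hand_dataset):
        b = rs.discrete_hazard(hand_dataset, 3.0, actuarial=True)
        assert b.n_at_risk[2] == pytest.approx(2.5)

    def test_censoring_before_first_bin_end_changes_risk_not_events(self):
        base = rs.SurvivalDataset(np.array([2.0, 5.0, 8.0]),
                                  np.array([True, True, True]))
        padded = rs.SurvivalDataset(
            np.array([2.0, 5.0, 8.0, 1.0, 1.5]),
            np.array([True, True, True, False, False]),
        )
        b0, b1 = rs.discrete_hazard(base, 3.0), rs.discrete_hazard(padded, 3.0)
        assert np.array_equal(b0.n_events, b1.n_events)
        assert b1.n_at_risk[0] == b0.n_at_risk[0] + 2
        assert np.array_equal(b0.n_at_risk[1:], b1.n_at_risk[1:])

    def test_constant_hazard_consistency(self, constant_hazard_dataset):
        """Mean binned hazard on memoryless data matches 1 - exp(-lam*w)
        within Monte-Carlo error."""
        lam, w = 0.01, 3.0
        b = rs.discrete_hazard(constant_hazard_dataset, w)
        expected = 1.0 - np.exp(-lam * w)
        sel = b.n_at_risk > 500
        se = np.sqrt(expected * (1 - expected) / b.n_at_risk[sel].sum() * sel.sum())
        assert np.mean(b.hazard[sel]) == pytest.approx(expected, abs=3 * se)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self, hand_dataset):
        km = rs.km_curve(hand_dataset)
        assert km(2.0) == pytest.approx(0.8)
        assert km(5.0) == pytest.approx(0.6)
        assert km(8.0) == pytest.approx(0.4)  # event before censoring at the tie
        assert km(11.0) == pytest.approx(0.0)
        assert km(0.0) == pytest.approx(1.0)

    def test_all_censored_is_flat_one(self):
        data = rs.SurvivalDataset(np.array([4.0, 9.0]), np.zeros(2, bool))
        km = rs.km_curve(data)
        assert km(120.0) == pytest.approx(1.0)

    def test_km_hazard_duality(self, default_cohort):
        """Product of (1 - h_j) over bins tracks the KM curve at bin edges:
        the hazard is the per-bin slope information of the KM curve."""
        b = rs.discrete_hazard(default_cohort, 3.0)
        km = rs.km_curve(default_cohort)
        surv = np.cumprod(1.0 - np.nan_to_num(b.hazard))
        km_at_edges = km(b.edges[1:] - 1e-9)
        assert np.allclose(surv, km_at_edges, atol=1.0 / len(default_cohort) + 1e-9)

    def test_plateau_between_36_and_60_months(self, default_cohort):
        """Under the untreated default the KM curve flattens between the
        early relapse wave and the late natural-history wave."""
        km = rs.km_curve(default_cohort)
        starts = np.arange(0.0, 37.0, 12.0)
        drops = km(starts) - km(starts + 12.0)
        # the 36-48 month window is the flattest of the first four years
        assert np.argmin(drops) == 3
        assert drops[3] < 0.5 * (km(6.0) - km(18.0))


class TestKernelSmooth:
    def test_constant_preserved_exactly_everywhere(self):
        edges = np.arange(0.0, 123.0, 3.0)
        n = edges.size - 1
        b = rs.BinnedHazard(3.0, edges, np.full(n, 100.0), np.full(n, 10),
                            np.full(n, 0.1))
        sm = rs.kernel_smooth(b, 9.0)
        assert np.allclose(sm.values, 0.1, atol=1e-12)

    def test_spike_mass_conserved_and_spread(self):
        edges = np.arange(0.0, 123.0, 3.0)
        n = edges.size - 1
        h = np.zeros(n)
        h[20] = 0.3
        b = rs.BinnedHazard(3.0, edges, np.full(n, 100.0),
                            np.zeros(n, int), h)
        sm = rs.kernel_smooth(b, 9.0)
        assert np.sum(sm.values) * 3.0 == pytest.approx(0.3 * 3.0, rel=1e-9)
        support = np.flatnonzero(sm.values > 0)
        assert np.all(np.abs(b.centers[support] - b.centers[20]) < 9.0)
        # Epanechnikov profile: symmetric, peaked at the spike bin
        assert np.argmax(sm.values) == 20
        assert sm.values[18] == pytest.approx(sm.values[22], rel=1e-9)

    def test_direct_convolution_oracle(self):
        """Interior smoothing equals a directly computed normalized
        Epanechnikov weighted average."""
        rng = np.random.default_rng(2)
        edges = np.arange(0.0, 63.0, 3.0)
        n = edges.size - 1
        h = rng.uniform(0.0, 0.2, n)
        b = rs.BinnedHazard(3.0, edges, np.full(n, 50.0), np.zeros(n, int), h)
        bw = 7.5
        sm = rs.kernel_smooth(b, bw)
        centers = b.centers
        for i in range(3, n - 3):
            u = (centers - centers[i]) / bw
            w = np.where(np.abs(u) < 1, 0.75 * (1 - u**2), 0.0)
            assert sm.values[i] == pytest.approx(np.sum(w * h) / np.sum(w))

    def test_small_bandwidth_warns_and_passes_through(self):
        edges = np.arange(0.0, 33.0, 3.0)
        n = edges.size - 1
        b = rs.BinnedHazard(3.0, edges, np.full(n, 10.0), np.zeros(n, int),
                            np.linspace(0, 0.1, n))
        with pytest.warns(UserWarning):
            sm = rs.kernel_smooth(b, 1.0)
        assert np.allclose(sm.values, b.hazard)


class TestPiecewiseExponential:
    def test_single_segment_is_exponential_mle(self, hand_dataset):
        fit = rs.piecewise_exp_fit(hand_dataset, [])
        assert fit.rates[0] == pytest.approx(4.0 / 34.0)

    def test_rate_recovery_on_exponential_data(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(20.0, 5000)
        data = rs.SurvivalDataset(t, np.ones(5000, bool))
        fit = rs.piecewise_exp_fit(data, [])
        assert fit.rates[0] == pytest.approx(0.05, rel=0.05)

    def test_no_events_all_rates_zero(self):
        data = rs.SurvivalDataset(np.array([5.0, 15.0, 25.0]),
                                  np.zeros(3, bool))
        fit = rs.piecewise_exp_fit(data, [10.0])
        assert np.all(fit.rates == 0.0)

    def test_matches_lifelines_piecewise_fitter(self):
        """Independent cross-check of rates against the regression fitter
        from lifelines on the same breakpoints."""
        from lifelines import PiecewiseExponentialFitter

        rng = np.random.default_rng(12)
        t = np.concatenate([rng.exponential(10.0, 2000),
                            20.0 + rng.exponential(40.0, 2000)])
        e = t <= 120.0
        data = rs.SurvivalDataset(np.minimum(t, 120.0), e)
        knots = [20.0, 60.0]
        fit = rs.piecewise_exp_fit(data, knots)
        pwf = PiecewiseExponentialFitter(breakpoints=knots)
        pwf.fit(data.times, data.events)
        theirs = 1.0 / pwf.params_.to_numpy()  # lambda_ params are scales
        assert np.allclose(fit.rates, theirs, rtol=1e-3)

    def test_zero_person_time_segment_rejected(self, hand_dataset):
        with pytest.raises(ValueError):
            rs.piecewise_exp_fit(hand_dataset, [20.0])


def test_hazard_to_rate_inverts_interval_probability():
    edges = np.arange(0.0, 12.0, 3.0)
    b = rs.BinnedHazard(3.0, edges, np.full(3, 10.0), np.zeros(3, int),
                        np.array([0.0, 1 - np.exp(-0.3), 0.5]))
    rates = hazard_to_rate(b)
    assert rates[0] == 0.0
    assert rates[1] == pytest.approx(0.1)
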