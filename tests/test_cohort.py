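from dataclasses import replace

import numpy as np
import pytest

import relapsim as rs
from relapsim.cohort import (
    DEFAULT_MEDIAN_A,
    Deposit,
    DepositState,
    GroupConfig,
    GroupLabel,
    conditional_relapse_times,
)
from relapsim.growth import GompertzParams, GrowthRateDistribution, time_to_size


def _config(groups, sigma_log=0.3, **kw):
    return rs.SimConfig(
        n_patients=kw.pop("n_patients", 1000),
        groups=groups,
        growth=GrowthRateDistribution(DEFAULT_MEDIAN_A, sigma_log),
        **kw,
    )


def test_deposit_state_transitions_are_one_way():
    d = Deposit(DepositState.DORMANT_SINGLE, 1.0, 0.08)
    d.advance(DepositState.AVASCULAR_DORMANT)
    d.advance(DepositState.VASCULAR_GROWING)
    with pytest.raises(ValueError):
        Deposit(DepositState.DORMANT_SINGLE, 1.0, 0.08).advance(
            DepositState.VASCULAR_GROWING
        )


def test_cured_patients_always_censored_at_horizon():
    cfg = _config((GroupConfig(GroupLabel.CURED, 1.0),))
    for r in rs.simulate_cohort(cfg):
        assert r.time == 120.0 and not r.event


def test_triggered_avascular_is_deterministic_without_heterogeneity():
    """With zero rate spread every triggered-avascular relapse is at
    exactly the avascular->detection transit time (10 months)."""
    cfg = _config(
        (GroupConfig(GroupLabel.TRIGGERED_AVASCULAR, 1.0),), sigma_log=0.0
    )
    times = [r.time for r in rs.simulate_cohort(cfg)]
    assert np.allclose(times, 10.0)


def test_triggered_single_instant_switch_collapses_to_growth_times():
    """An infinitely fast angiogenic switch leaves only deterministic
    growth: t = t(1 cell -> avascular limit) + t(avascular -> detection)."""
    cfg = _config(
        (GroupConfig(GroupLabel.TRIGGERED_SINGLE, 1.0, rate_switch=np.inf),),
        sigma_log=0.0,
        n_patients=50,
    )
    expected = time_to_size(
        GompertzParams(1.0, 1e12, DEFAULT_MEDIAN_A), 1e5
    ) + time_to_size(GompertzParams(1e5, 1e12, DEFAULT_MEDIAN_A), 1e9)
    times = [r.time for r in rs.simulate_cohort(cfg)]
    assert np.allclose(times, expected)
    assert expected == pytest.approx(6.361357982 + 10.0, rel=1e-6)


def test_cohort_reproducible_from_seed():
    cfg = rs.default_config(5000, seed=11)
    assert rs.simulate_cohort(cfg) == rs.simulate_cohort(cfg)


def test_group_assignment_matches_weights():
    cfg = rs.default_config(20000, seed=1)
    records = rs.simulate_cohort(cfg)
    counts = {g.label: 0 for g in cfg.groups}
    for r in records:
        counts[r.group] += 1
    for g in cfg.groups:
        assert counts[g.label] / len(records) == pytest.approx(g.weight, abs=0.015)


def test_weights_must_sum_to_one():
    with pytest.raises(ValueError):
        _config((GroupConfig(GroupLabel.CURED, 0.5),))


def test_triggered_avascular_mode_near_ten_months():
    """Relapse-time histogram of the triggered-avascular group is unimodal
    with its mode in the bin containing 10 months."""
    cfg = _config(
        (GroupConfig(GroupLabel.TRIGGERED_AVASCULAR, 1.0),), n_patients=10000
    )
    times = np.array([r.time for r in rs.simulate_cohort(cfg) if r.event])
    hist, edges = np.histogram(times, bins=np.arange(0, 123, 3.0))
    mode_bin = edges[np.argmax(hist)]
    assert mode_bin == 9.0  # bin [9, 12) contains 10 months


def test_simulate_patient_matches_group_semantics():
    cfg = rs.default_config(10)
    rng = np.random.default_rng(0)
    rec = rs.simulate_patient(cfg.group(GroupLabel.CURED), cfg, rng)
    assert rec.time == 120.0 and not rec.event
    rec = rs.simulate_patient(cfg.group(GroupLabel.TRIGGERED_AVASCULAR), cfg, rng)
    assert rec.event and 3.0 < rec.time < 30.0


class TestNsaidScenario:
    def test_identity_at_zero_suppression(self):
        cfg = rs.default_config(100)
        assert rs.nsaid_scenario(cfg, 0.0) == cfg

    def test_full_suppression_moves_triggered_mass_to_cured(self):
        cfg = rs.default_config(100)
        out = rs.nsaid_scenario(cfg, 1.0)
        assert out.group(GroupLabel.TRIGGERED_AVASCULAR).weight == 0.0
        assert out.group(GroupLabel.TRIGGERED_SINGLE).weight == 0.0
        assert out.group(GroupLabel.CURED).weight == pytest.approx(0.83)
        assert sum(g.weight for g in out.groups) == pytest.approx(1.0)

    def test_suppression_lowers_early_hazard(self):
        """80% suppression of the surgery-triggered groups lowers the mean
        binned hazard over months 9-18 severalfold."""
        control = rs.default_config(20000, seed=21)
        treated = rs.nsaid_scenario(control, 0.8)

        def early_hazard(cfg):
            data = rs.SurvivalDataset.from_records(rs.simulate_cohort(cfg))
            b = rs.discrete_hazard(data, 3.0)
            sel = (b.edges[:-1] >= 9.0) & (b.edges[:-1] < 18.0)
            return np.nanmean(b.hazard[sel])

        ratio = early_hazard(control) / early_hazard(treated)
        assert ratio > 2.0

    def test_invalid_suppression(self):
        with pytest.raises(ValueError):
            rs.nsaid_scenario(rs.default_config(10), 1.5)


def test_natural_history_times_shrink_with_faster_switch():
    """Raising the angiogenic-switch rate stochastically shortens
    natural-history relapse times."""
    cfg = rs.default_config(10)
    slow = cfg.group(GroupLabel.NATURAL_HISTORY)
    fast = replace(slow, rate_switch=slow.rate_switch * 4)
    t_slow = conditional_relapse_times(slow, cfg, np.random.default_rng(5), 20000)
    t_fast = conditional_relapse_times(fast, cfg, np.random.default_rng(5), 20000)
    for q in (0.25, 0.5, 0.75):
        assert np.quantile(t_fast, q) < np.quantile(t_slow, q)


def test_mixture_hazard_is_weighted_sum_of_group_subhazards():
    """The mixed cohort's binned event density equals the weight-scaled sum
    of per-group event densities up to Monte-Carlo error."""
    cfg = rs.default_config(50000, seed=3)
    mixed = rs.SurvivalDataset.from_records(rs.simulate_cohort(cfg))
    edges = np.arange(0.0, 123.0, 3.0)
    mix_density = np.histogram(mixed.times[mixed.events], bins=edges)[0] / len(mixed)

    expected = np.zeros(edges.size - 1)
    for g in cfg.groups:
        if g.label == GroupLabel.CURED:
            continue
        t = conditional_relapse_times(g, cfg, np.random.default_rng(100), 50000)
        t = t[t <= 120.0]
        expected += g.weight * np.histogram(t, bins=edges)[0] / 50000

    se = np.sqrt(np.maximum(expected, 1e-6) / len(mixed))
    assert np.all(np.abs(mix_density - expected) < 4 * se + 2e-4)


def test_triggered_peak_sharper_than_natural_history():
    """The surgery-synchronized avascular mode is far narrower than the
    stochastic natural-history mode."""
    cfg = rs.default_config(10)
    ta = conditional_relapse_times(
        cfg.group(GroupLabel.TRIGGERED_AVASCULAR), cfg,
        np.random.default_rng(8), 20000
    )
    nh = conditional_relapse_times(
        cfg.group(GroupLabel.NATURAL_HISTORY), cfg,
        np.random.default_rng(9), 20000
    )
    iqr = lambda x: np.subtract(*np.percentile(x, [75, 25]))
    assert iqr(ta) < 0.5 * iqr(nh)
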