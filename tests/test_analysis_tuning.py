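"""Tuning curves (discrete, 1D, 2D, continuous) and Bayesian decoding."""

import numpy as np
import pandas as pd
import pytest

from spiketime import (EpochSet, EventGroup, MultiValuedSeries,
                       TimestampSeries, ValuedSeries, circular_distance,
                       decode_bayes_1d, preferred_direction, tuning_1d,
                       tuning_2d, tuning_continuous, tuning_discrete)
from spiketime.analysis import TuningCurve


def _group_one_unit(times, support):
    return EventGroup({0: TimestampSeries(times, time_support=support)},
                      time_support=support)


class TestTuningDiscrete:
    def test_on_off_rates(self):
        sup = EpochSet([0], [10])
        g = _group_one_unit(np.linspace(0, 4.9, 10), sup)
        out = tuning_discrete(g, {"ON": EpochSet([0], [5]),
                                  "OFF": EpochSet([5], [10])})
        assert out.loc["ON", 0] == 2.0
        assert out.loc["OFF", 0] == pytest.approx(0.0)

    def test_full_support_matches_metadata_rate(self):
        sup = EpochSet([0], [10])
        g = _group_one_unit(np.linspace(0.1, 9.9, 37), sup)
        out = tuning_discrete(g, {"all": sup})
        assert out.loc["all", 0] == g.metadata.loc[0, "rate"]

    def test_zero_duration_condition_rejected(self):
        g = _group_one_unit([1.0], EpochSet([0], [10]))
        with pytest.raises(ValueError):
            tuning_discrete(g, {"bad": EpochSet([20], [20])})

    def test_matches_restrict_then_rate_oracle(self):
        rng = np.random.default_rng(4)
        sup = EpochSet([0], [60])
        g = _group_one_unit(np.sort(rng.uniform(0, 60, 120)), sup)
        ep = EpochSet([5, 30], [20, 50])
        out = tuning_discrete(g, {"c": ep})
        assert out.loc["c", 0] == g[0].restrict(ep).rate()


class TestTuning1D:
    def test_occupancy_formula_single_bin(self):
        # 100 feature samples at dt=0.1 all in one bin; 20 spikes -> 2 Hz
        sup = EpochSet([0], [10])
        feat = ValuedSeries(np.arange(100) * 0.1, np.full(100, 0.55),
                            time_support=sup)
        g = _group_one_unit(np.linspace(0.05, 9.5, 20), sup)
        tc = tuning_1d(g, feat, nb_bins=10, range=(0, 1))
        occupied = int(np.digitize(0.55, np.linspace(0, 1, 11))) - 1
        assert tc.rates[0].iloc[occupied] == pytest.approx(2.0)
        undefined = np.delete(np.arange(10), occupied)
        assert np.isnan(tc.rates[0].to_numpy()[undefined]).all()

    def test_unvisited_bins_are_nan_not_zero(self):
        sup = EpochSet([0], [1])
        feat = ValuedSeries(np.arange(0, 1, 0.01), np.full(100, 0.1),
                            time_support=sup)
        g = _group_one_unit([0.5], sup)
        tc = tuning_1d(g, feat, nb_bins=4, range=(0, 1))
        assert np.isnan(tc.rates[0].to_numpy()[1:]).all()

    def test_occupancy_conserved_when_doubling_bins(self, hd_session_small):
        g, traj, _ = hd_session_small
        t1 = tuning_1d(g, traj, 12, circular=True)
        t2 = tuning_1d(g, traj, 24, circular=True)
        assert t1.occupancy.sum() == pytest.approx(t2.occupancy.sum())
        # sums to the analyzed duration within one feature sample
        assert t1.occupancy.sum() == pytest.approx(
            traj.time_support.total_duration, abs=0.05)

    def test_flat_curve_for_uniform_feature_homogeneous_unit(self):
        rng = np.random.default_rng(12)
        dur, lam = 400.0, 8.0
        sup = EpochSet([0], [dur])
        feat = ValuedSeries(np.arange(0, dur, 0.05),
                            rng.uniform(0, 1, int(dur / 0.05)),
                            time_support=sup)
        spikes = np.sort(rng.uniform(0, dur, rng.poisson(lam * dur)))
        g = _group_one_unit(spikes, sup)
        tc = tuning_1d(g, feat, nb_bins=5, range=(0, 1))
        se = np.sqrt(lam / tc.occupancy)  # Poisson SE of a rate estimate
        assert np.all(np.abs(tc.rates[0].to_numpy() - lam) < 3 * se)


class TestTuning2D:
    def test_single_cell_rate(self):
        sup = EpochSet([0], [10])
        feat = MultiValuedSeries(np.arange(100) * 0.1,
                                 np.column_stack([np.full(100, 0.5),
                                                  np.full(100, 0.5)]),
                                 column_names=["x", "y"], time_support=sup)
        g = _group_one_unit(np.linspace(0.05, 9.5, 20), sup)
        tc = tuning_2d(g, feat, nb_bins=3, ranges=((0, 1), (0, 1)))
        assert tc.rates[0][1, 1] == pytest.approx(2.0)
        assert np.isnan(np.delete(tc.rates[0].ravel(), 4)).all()

    def test_marginal_matches_1d_within_sampling(self):
        rng = np.random.default_rng(21)
        dur = 200.0
        sup = EpochSet([0], [dur])
        t = np.arange(0, dur, 0.05)
        x = rng.uniform(0, 1, t.size)
        y = rng.uniform(0, 1, t.size)
        feat2 = MultiValuedSeries(t, np.column_stack([x, y]),
                                  column_names=["x", "y"], time_support=sup)
        feat1 = ValuedSeries(t, x, time_support=sup)
        spikes = np.sort(rng.uniform(0, dur, 1200))
        g = _group_one_unit(spikes, sup)
        tc2 = tuning_2d(g, feat2, nb_bins=4, ranges=((0, 1), (0, 1)))
        tc1 = tuning_1d(g, feat1, nb_bins=4, range=(0, 1))
        # occupancy-weighted marginal of the 2-D map equals the 1-D curve
        occ2 = tc2.occupancy
        marg = np.nansum(tc2.rates[0] * occ2, axis=1) / occ2.sum(axis=1)
        np.testing.assert_allclose(marg, tc1.rates[0].to_numpy(), rtol=1e-9)

    def test_requires_two_columns(self):
        sup = EpochSet([0], [1])
        feat = MultiValuedSeries([0.0, 0.5], [[1.0], [2.0]], time_support=sup)
        with pytest.raises(ValueError):
            tuning_2d(_group_one_unit([0.5], sup), feat, 2)


class TestTuningContinuous:
    def test_constant_signal_gives_constant_curve(self):
        sup = EpochSet([0], [10])
        t = np.arange(0, 10, 0.1)
        vals = ValuedSeries(t, np.ones(t.size), time_support=sup)
        feat = ValuedSeries(t, np.sin(t) * 0.5 + 0.5, time_support=sup)
        tc = tuning_continuous(vals, feat, nb_bins=5, range=(0, 1))
        got = tc.rates.to_numpy().ravel()
        assert np.allclose(got[~np.isnan(got)], 1.0)

    def test_identity_binning_recovers_bin_centers(self):
        sup = EpochSet([0], [10])
        t = np.arange(0, 10, 0.01)
        f = np.linspace(0, 1, t.size)
        vals = ValuedSeries(t, f, time_support=sup)
        feat = ValuedSeries(t, f, time_support=sup)
        tc = tuning_continuous(vals, feat, nb_bins=10, range=(0, 1))
        got = tc.rates.to_numpy().ravel()
        assert np.all(np.abs(got - tc.bin_centers) <= 0.05 + 1e-9)

    def test_no_overlap_rejected(self):
        vals = ValuedSeries([0.0, 1.0], [1.0, 2.0])
        feat = ValuedSeries([10.0, 11.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            tuning_continuous(vals, feat, nb_bins=2)


class TestDecoder:
    @staticmethod
    def _two_state_tc():
        return TuningCurve(
            bin_centers=np.array([0.0, 1.0]),
            rates=pd.DataFrame({0: [10.0, 1.0]}, index=[0.0, 1.0]),
            occupancy=np.array([1.0, 1.0]), unit_ids=[0])

    def test_closed_form_two_state_map(self):
        """One unit, states at 10 and 1 Hz, tau=1 s: 8 spikes favor the
        10 Hz state (10^8 e^-10 >> e^-1); 0 spikes favor the 1 Hz state."""
        tc = self._two_state_tc()
        sup = EpochSet([0], [2])
        g = EventGroup({0: TimestampSeries(np.linspace(0.05, 0.95, 8),
                                           time_support=sup)},
                       time_support=sup)
        dec = decode_bayes_1d(tc, g, bin_size=1.0, ep=sup)
        np.testing.assert_array_equal(dec.map_estimate, [0.0, 1.0])
        # exact posterior from the closed form
        l1 = 8 * np.log(10) - 10
        l2 = 0 - 1.0
        want = np.exp(l1) / (np.exp(l1) + np.exp(l2))
        assert dec.posterior.iloc[0, 0] == pytest.approx(want, rel=1e-12)

    def test_identical_rates_give_uniform_posterior(self):
        tc = TuningCurve(np.array([0.0, 1.0]),
                         pd.DataFrame({0: [5.0, 5.0]}, index=[0.0, 1.0]),
                         np.array([1.0, 1.0]), [0])
        sup = EpochSet([0], [1])
        g = EventGroup({0: TimestampSeries([0.2, 0.4], time_support=sup)},
                       time_support=sup)
        dec = decode_bayes_1d(tc, g, 1.0, sup)
        np.testing.assert_allclose(dec.posterior.to_numpy(), 0.5)

    def test_posterior_rows_sum_to_one(self, hd_session_small):
        g, traj, _ = hd_session_small
        tc = tuning_1d(g, traj, 12, circular=True)
        dec = decode_bayes_1d(tc, g, 0.5, traj.time_support)
        np.testing.assert_allclose(dec.posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_single_state_map_is_constant(self):
        tc = TuningCurve(np.array([0.3]),
                         pd.DataFrame({0: [5.0]}, index=[0.3]),
                         np.array([1.0]), [0])
        sup = EpochSet([0], [2])
        g = EventGroup({0: TimestampSeries([0.5, 1.5], time_support=sup)},
                       time_support=sup)
        dec = decode_bayes_1d(tc, g, 1.0, sup)
        assert np.all(dec.map_estimate == 0.3)

    def test_unit_mismatch_rejected(self):
        tc = self._two_state_tc()
        sup = EpochSet([0], [1])
        g = EventGroup({7: TimestampSeries([0.5], time_support=sup)},
                       time_support=sup)
        with pytest.raises(ValueError, match="missing"):
            decode_bayes_1d(tc, g, 1.0, sup)

    def test_occupancy_prior_shifts_posterior(self):
        tc = TuningCurve(np.array([0.0, 1.0]),
                         pd.DataFrame({0: [5.0, 5.0]}, index=[0.0, 1.0]),
                         np.array([3.0, 1.0]), [0])
        sup = EpochSet([0], [1])
        g = EventGroup({0: TimestampSeries([0.5], time_support=sup)},
                       time_support=sup)
        dec = decode_bayes_1d(tc, g, 1.0, sup, prior="occupancy")
        assert dec.posterior.iloc[0, 0] == pytest.approx(0.75)


class TestRecovery:
    def test_preferred_direction_recovery(self, hd_session_small):
        g, traj, tunings = hd_session_small
        tc = tuning_1d(g, traj, 24, circular=True)
        pref = preferred_direction(tc)
        bin_width = 2 * np.pi / 24
        for i, tun in enumerate(tunings):
            if np.nanmax(tc.rates[i].to_numpy()) >= 5.0:
                assert circular_distance(pref[i], tun.mu) <= bin_width

    def test_decoding_beats_chance(self, hd_session_small):
        g, traj, _ = hd_session_small
        tc = tuning_1d(g, traj, 24, circular=True)
        dec = decode_bayes_1d(tc, g, 0.2, traj.time_support)
        truth = TimestampSeries(dec.times, time_support=traj.time_support) \
            .value_from(traj).values
        med = np.median(circular_distance(dec.map_estimate, truth))
        assert med < 2 * (2 * np.pi / 24)  # << 90 deg chance
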