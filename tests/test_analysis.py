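import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phispike import (
    GeneratorSpec,
    PeriodRecord,
    PhiRunConfig,
    PhiSpikeError,
    bonferroni_alpha,
    correlate_phi_rewards,
    day_average,
    gen_session_with_rewards,
    period_phi,
    spearman_correlation,
)


@pytest.fixture(scope="module")
def linked_session():
    spec = GeneratorSpec(n_neurons=10, duration_s=960.0, bin_size=0.03,
                         base_rate=0.15, coupling=0.5, delay_bins=1, seed=21)
    return gen_session_with_rewards(spec, phi_reward_link=2.0,
                                    base_reward_rate=0.3)


@pytest.fixture(scope="module")
def linked_records(linked_session):
    config = PhiRunConfig(method="atomic", lag_bins=1, n_periods=8)
    return period_phi(linked_session, config, session_id="s0")


class TestPeriodPhi:
    def test_sixteen_minute_session_gives_8_records(self, linked_records):
        assert len(linked_records) == 8
        for record in linked_records:
            assert record.duration_s == pytest.approx(120.0, abs=0.05)
            assert record.phi_normalized is not None
            assert record.n_neurons_used >= 2

    def test_reward_rate_definition(self, linked_session, linked_records):
        for record in linked_records:
            lo = record.period_index * record.duration_s
            n_rewards = len(linked_session.events_in(
                lo, lo + record.duration_s, "reward"))
            assert record.reward_rate == pytest.approx(
                n_rewards / record.duration_s)

    def test_phi_normalized_by_neuron_count(self, linked_records):
        # re-deriving the division is definitional: phi_normalized * n = phi
        for record in linked_records:
            assert np.isfinite(record.phi_normalized * record.n_neurons_used)

    def test_failed_period_emits_missing_record(self):
        from phispike import SessionData, SpikeTrain

        # spikes only in the first half: later periods are all-constant
        trains = tuple(
            SpikeTrain(f"n{i}", np.sort(np.random.default_rng(i).random(200)) * 30.0)
            for i in range(5))
        session = SessionData(trains=trains, t_start=0.0, t_end=120.0)
        config = PhiRunConfig(method="atomic", bin_size=0.03, n_periods=4)
        records = period_phi(session, config)
        assert len(records) == 4
        assert records[0].phi_normalized is not None
        assert any(r.phi_normalized is None for r in records[2:])

    def test_bad_method_rejected(self, linked_session):
        with pytest.raises(ValueError):
            period_phi(linked_session, PhiRunConfig(method="spectral"))


class TestDayAverage:
    @staticmethod
    def _record(session, day, period, phi, rate=0.1):
        return PeriodRecord(session_id=session, period_index=period,
                            phi_normalized=phi, n_neurons_used=5,
                            reward_rate=rate, duration_s=120.0, day=day)

    def test_two_session_mean(self):
        records = [self._record("s1", "d1", 0, 0.2),
                   self._record("s2", "d1", 0, 0.4)]
        table = day_average(records)
        assert table.loc[0, "phi_normalized"] == pytest.approx(0.3)
        assert table.loc[0, "n_sessions"] == 2

    def test_single_session_identity(self):
        table = day_average([self._record("s1", "d1", 0, 0.7)])
        assert table.loc[0, "phi_normalized"] == pytest.approx(0.7)

    def test_missing_values_ignored(self):
        records = [self._record("s1", "d1", 0, None),
                   self._record("s2", "d1", 0, 0.4)]
        table = day_average(records)
        assert table.loc[0, "phi_normalized"] == pytest.approx(0.4)

    def test_requires_day_labels(self):
        with pytest.raises(ValueError):
            day_average([self._record("s1", None, 0, 0.2)])


class TestSpearman:
    def test_perfect_monotone(self):
        # minimum pair count is 4
        report = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert report.rho == pytest.approx(1.0)
        assert report.p_value == pytest.approx(0.0, abs=1e-12)

    def test_reversed(self):
        report = spearman_correlation([1, 2, 3, 4], [40, 30, 20, 10])
        assert report.rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        report = spearman_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert report.rho == pytest.approx(0.8)
        # two-sided t p-value with n-2 = 2 d.f.
        t = 0.8 * math.sqrt(2 / (1 - 0.64))
        from scipy import stats
        assert report.p_value == pytest.approx(2 * stats.t.sf(t, 2), abs=1e-12)

    def test_matches_scipy(self, rng):
        from scipy import stats
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        report = spearman_correlation(x, y)
        rho, p = stats.spearmanr(x, y)
        assert report.rho == pytest.approx(rho, abs=1e-12)
        assert report.p_value == pytest.approx(p, abs=1e-9)

    def test_missing_pairs_dropped(self):
        report = spearman_correlation([1, None, 2, 3, 4], [1, 5, 2, 3, 4])
        assert report.n == 4
        assert report.rho == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(PhiSpikeError, match="undefined"):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs(self):
        with pytest.raises(PhiSpikeError):
            spearman_correlation([1, 2, 3], [1, 2, 3])

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=5,
                    max_size=30, unique=True),
           st.integers(min_value=0, max_value=10 ** 6))
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, xs, seed):
        ys = np.random.default_rng(seed).normal(size=len(xs))
        if np.ptp(ys) == 0:
            return
        base = spearman_correlation(xs, ys)
        transformed = spearman_correlation(
            [3.0 * x for x in xs], ys)  # strictly monotone, exact in floats
        assert transformed.rho == pytest.approx(base.rho, abs=1e-9)


class TestBonferroni:
    def test_fifteen_hypotheses(self):
        value = bonferroni_alpha(0.05, 15)
        assert value == pytest.approx(0.05 / 15)
        # the printed threshold 0.0034 corresponds to ceiling at 4 d.p.
        assert math.ceil(value * 1e4) / 1e4 == pytest.approx(0.0034)

    def test_single_hypothesis_identity(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_stricter_family_level(self):
        assert bonferroni_alpha(0.01, 15) == pytest.approx(6.667e-4, rel=1e-3)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestCorrelatePhiRewards:
    def test_positive_link_detected(self, linked_records):
        # one 16-min session gives only 8 points; check sign and report shape
        report = correlate_phi_rewards(linked_records, n_hypotheses=15)
        assert report.rho > 0
        assert report.n == len([r for r in linked_records
                                if r.phi_normalized is not None])
        assert report.alpha_corrected == pytest.approx(0.05 / 15)
        assert report.significant == (report.p_value < 0.05 / 15)

    def test_record_order_invariance(self, linked_records):
        fwd = correlate_phi_rewards(linked_records)
        rev = correlate_phi_rewards(list(reversed(linked_records)))
        assert fwd.rho == pytest.approx(rev.rho, abs=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)

    def test_shuffled_rewards_mostly_not_significant(self, rng):
        # permutation null on 64 synthetic period records
        phi = np.linspace(0.1, 0.9, 64) + rng.normal(0, 0.01, 64)
        rates = np.linspace(0.05, 0.4, 64)
        n_sig = 0
        n_shuffles = 40
        for _ in range(n_shuffles):
            shuffled = rng.permutation(rates)
            records = [PeriodRecord(session_id="s", period_index=i,
                                    phi_normalized=float(phi[i]),
                                    n_neurons_used=5,
                                    reward_rate=float(shuffled[i]),
                                    duration_s=120.0)
                       for i in range(64)]
            if correlate_phi_rewards(records, n_hypotheses=15).significant:
                n_sig += 1
        assert n_sig <= 0.05 * n_shuffles

    def test_all_equal_phi_propagates_error(self):
        records = [PeriodRecord(session_id="s", period_index=i,
                                phi_normalized=0.5, n_neurons_used=5,
                                reward_rate=0.1 * i, duration_s=120.0)
                   for i in range(8)]
        with pytest.raises(PhiSpikeError):
            correlate_phi_rewards(records)

    def test_stars_convention(self):
        from phispike import CorrelationReport
        strong = CorrelationReport(rho=0.9, p_value=1e-5, n=64,
                                   alpha_corrected=0.05 / 15, significant=True)
        weak = CorrelationReport(rho=0.3, p_value=0.002, n=64,
                                 alpha_corrected=0.05 / 15, significant=True)
        null = CorrelationReport(rho=0.1, p_value=0.2, n=64,
                                 alpha_corrected=0.05 / 15, significant=False)
        assert strong.stars(15) == "**"
        assert weak.stars(15) == "*"
        assert null.stars(15) == "ns"
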