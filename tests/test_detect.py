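"""Burst detector rules, stimulus association, descriptive statistics."""

import numpy as np
import pytest

from burstclust import (
    Burst,
    DetectorParams,
    SpikeTrain,
    StimulusEvent,
    associate_stimuli,
    detect_bursts,
    generate_poisson_train,
    interburst_histogram,
    joint_isi,
    psth,
    rate_correlation,
    rate_series,
)


def train(times, duration=None, id=""):
    t = np.asarray(times, dtype=float)
    if duration is None:
        duration = float(t[-1]) + 1.0 if t.size else 1.0
    return SpikeTrain(times=t, duration=duration, id=id)


class TestDetectBursts:
    def test_six_spike_burst(self):
        """Six rapid spikes preceded by 200 ms silence form one burst."""
        t = train([0.200, 0.210, 0.222, 0.235, 0.245, 0.258], duration=1.0)
        bursts = detect_bursts(t)
        assert len(bursts) == 1
        b = bursts[0]
        assert b.onset == pytest.approx(0.200)
        assert b.n_spikes == 6
        assert b.span == pytest.approx(0.058)

    def test_min_spikes_enforced(self):
        # 4 spikes at 10 ms spacing: high rate but below the count threshold
        t = train([0.2, 0.21, 0.22, 0.23], duration=1.0)
        assert detect_bursts(t) == []

    def test_pre_silence_enforced(self):
        # candidate first spike only 50 ms after the previous spike
        t = train([0.150, 0.200, 0.210, 0.222, 0.235, 0.245, 0.258], duration=1.0)
        assert detect_bursts(t) == []

    def test_recording_start_counts_as_silence(self):
        t = train([0.001, 0.010, 0.020, 0.030, 0.041], duration=1.0)
        bursts = detect_bursts(t)
        assert len(bursts) == 1 and bursts[0].onset == pytest.approx(0.001)

    def test_second_spike_rule(self):
        # first ISI of 20 ms > 15 ms: no candidate can open
        t = train([0.2, 0.220, 0.225, 0.230, 0.235, 0.240], duration=1.0)
        assert detect_bursts(t) == []

    def test_end_isi_terminates(self):
        # a 30 ms interval ends the burst before the gap
        t = train([0.2, 0.21, 0.22, 0.23, 0.24, 0.270, 0.272], duration=1.0)
        bursts = detect_bursts(t)
        assert len(bursts) == 1
        assert bursts[0].n_spikes == 5
        assert bursts[0].span == pytest.approx(0.04)

    def test_pair_sum_rule_ends_before_first_interval(self):
        # ISIs: 10,10,10,10,25,21 ms; pair 25+21=46 > 45 ends the burst at
        # the spike before the 25 ms interval
        t = train([0.2, 0.21, 0.22, 0.23, 0.24, 0.265, 0.286], duration=1.0)
        bursts = detect_bursts(t)
        assert len(bursts) == 1
        assert bursts[0].n_spikes == 5
        assert bursts[0].rel_times[-1] == pytest.approx(0.04)

    def test_min_duration_strict(self):
        # 5 spikes spanning exactly 8 ms: not longer than 8 ms, rejected
        t = train([0.2, 0.202, 0.204, 0.206, 0.208], duration=1.0)
        assert detect_bursts(t) == []
        # 5 spikes spanning 8.4 ms pass
        t = train([0.2, 0.202, 0.204, 0.206, 0.2084], duration=1.0)
        assert len(detect_bursts(t)) == 1

    def test_rejected_candidate_spikes_still_block_presilence(self):
        # a 3-spike rejected candidate 30 ms before a would-be burst start
        t = train([0.2, 0.205, 0.210, 0.250, 0.255, 0.262, 0.270, 0.278],
                  duration=1.0)
        assert detect_bursts(t) == []

    def test_detected_bursts_satisfy_invariants(self):
        rng = np.random.default_rng(3)
        p = DetectorParams()
        for _ in range(20):
            t = np.sort(rng.uniform(0, 30, size=rng.integers(50, 400)))
            t = t[np.concatenate([[True], np.diff(t) > 1e-4])]
            bursts = detect_bursts(train(t, duration=31.0))
            last_end = -np.inf
            for b in bursts:
                isis = np.diff(b.rel_times)
                assert b.onset >= last_end  # non-overlapping, sorted
                last_end = b.onset + b.span
                assert b.n_spikes >= p.min_spikes
                assert b.span > p.min_duration
                assert np.all(isis < p.end_isi)
                if isis.size >= 2:
                    assert np.all(isis[:-1] + isis[1:] <= p.end_pair_sum)

    def test_poisson_train_rarely_bursts(self):
        """A homogeneous 5 Hz Poisson train essentially never satisfies the
        burst rules: mean count << 1, zero bursts in >= 95% of seeds."""
        n_bursts = []
        for seed in range(200):
            t = generate_poisson_train(5.0, duration=60.0, seed=seed)
            t = t[np.concatenate([[True], np.diff(t) > 0])]
            n_bursts.append(len(detect_bursts(train(t, duration=61.0))))
        n_bursts = np.array(n_bursts)
        assert n_bursts.mean() < 0.2
        assert np.mean(n_bursts == 0) >= 0.95

    def test_concatenation_idempotence(self):
        """Detection on two recordings separated by > pre_silence equals
        the union of separate detections."""
        rng = np.random.default_rng(5)

        def mk(offset):
            out = []
            t = offset
            for _ in range(4):
                t += rng.uniform(0.3, 1.0)
                burst = t + np.cumsum(rng.uniform(0.002, 0.01, size=8))
                out.extend([t, *burst])
                t = out[-1]
            return np.array(out)

        a = mk(0.1)
        b = mk(10.0)
        sep = [detect_bursts(train(a, 9.0)), detect_bursts(train(b, 20.0))]
        joint = detect_bursts(train(np.concatenate([a, b]), 20.0))
        onsets_sep = [x.onset for bl in sep for x in bl]
        assert [x.onset for x in joint] == pytest.approx(onsets_sep)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SpikeTrain(times=np.array([0.2, 0.1]), duration=1.0)


class TestAssociateStimuli:
    events = [StimulusEvent(1.0, 4), StimulusEvent(2.0, 1)]

    def burst(self, onset):
        return Burst(onset=onset, rel_times=np.array([0.0, 0.005, 0.01, 0.015, 0.02]))

    def test_short_latency_burst_gets_class(self):
        out = associate_stimuli([self.burst(1.010)], self.events)
        assert out[0].label == "4"
        assert out[0].trigger_onset == pytest.approx(1.0)

    def test_outside_window_is_noise(self):
        out = associate_stimuli([self.burst(1.060)], self.events)
        assert out[0].label == "N"

    def test_burst_before_trigger_allowed(self):
        out = associate_stimuli([self.burst(0.960)], self.events)
        assert out[0].label == "4"

    def test_only_nearest_burst_wins_the_event(self):
        out = associate_stimuli([self.burst(0.990), self.burst(1.005)], self.events)
        assert [b.label for b in out] == ["N", "4"]

    def test_nearest_event_claims_shared_burst(self):
        events = [StimulusEvent(1.0, 4), StimulusEvent(1.06, 2)]
        out = associate_stimuli([self.burst(1.045)], events)
        assert out[0].label == "2"

    def test_equidistant_tie_goes_to_earlier_event(self):
        events = [StimulusEvent(1.0, 4), StimulusEvent(1.08, 2)]
        out = associate_stimuli([self.burst(1.04)], events)
        assert out[0].label == "4"

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            associate_stimuli([self.burst(1.0)], self.events, window=-0.01)


class TestStatistics:
    def test_joint_isi_pairs(self):
        pairs = joint_isi(np.array([0.0, 0.01, 0.02, 0.5]))
        assert pairs == pytest.approx([(0.01, 0.01), (0.01, 0.48)])

    def test_joint_isi_regular_train(self):
        pairs = joint_isi(np.arange(0, 0.1, 0.01))
        assert all(p == pytest.approx((0.01, 0.01)) for p in pairs)

    def test_joint_isi_degenerate(self):
        assert joint_isi(np.array([0.0, 1.0])) == []

    def test_interburst_histogram_binning(self):
        bursts = [Burst(onset=o, rel_times=np.array([0.0])) for o in (0.0, 1.0, 2.0)]
        counts, edges = interburst_histogram(bursts, bin=0.5)
        k = np.searchsorted(edges, 1.0, side="right") - 1
        assert counts[k] == 2 and counts.sum() == 2

    def test_interburst_histogram_degenerate(self):
        counts, edges = interburst_histogram(
            [Burst(onset=0.0, rel_times=np.array([0.0]))]
        )
        assert counts.size == 0

    def test_interburst_constant_gaps(self):
        bursts = [Burst(onset=10.0 * k, rel_times=np.array([0.0])) for k in range(5)]
        counts, edges = interburst_histogram(bursts, bin=0.5)
        occupied = np.flatnonzero(counts)
        assert occupied.size == 1
        assert edges[occupied[0]] == pytest.approx(10.0)
        assert counts[occupied[0]] == 4

    def test_rate_series_uniform(self):
        rs = rate_series(np.arange(10) + 0.5, bin=1.0, duration=10.0)
        assert np.allclose(rs.values, 1.0)

    def test_rate_series_empty(self):
        rs = rate_series([], bin=1.0, duration=10.0)
        assert np.allclose(rs.values, 0.0) and rs.values.size == 10

    def test_rate_series_concentrated(self):
        rs = rate_series(np.linspace(0.01, 0.9, 100), bin=1.0, duration=10.0)
        assert rs.values[0] == pytest.approx(100.0)
        assert np.allclose(rs.values[1:], 0.0)

    def test_rate_series_partial_final_bin(self):
        rs = rate_series([10.25], bin=1.0, duration=10.5)
        assert rs.values[-1] == pytest.approx(1 / 0.5)

    def test_rate_correlation_identity_and_negation(self):
        rs = rate_series(np.sort(np.random.default_rng(0).uniform(0, 10, 50)),
                         1.0, 10.0)
        assert rate_correlation(rs, rs) == pytest.approx(1.0)
        neg = rate_series([], 1.0, 10.0)
        neg.values = -rs.values
        assert rate_correlation(rs, neg) == pytest.approx(-1.0)

    def test_rate_correlation_independent_noise(self):
        rng = np.random.default_rng(1)
        a = rate_series([], 1.0, 10.0)
        b = rate_series([], 1.0, 10.0)
        a.values = rng.normal(size=10_000)
        b.values = rng.normal(size=10_000)
        a.bin_start_times = b.bin_start_times = np.arange(10_000.0)
        assert abs(rate_correlation(a, b)) < 0.05

    def test_rate_correlation_zero_variance_warns_nan(self):
        a = rate_series([], 1.0, 10.0)
        b = rate_series([0.5], 1.0, 10.0)
        with pytest.warns(RuntimeWarning):
            assert np.isnan(rate_correlation(a, a))
        with pytest.warns(RuntimeWarning):
            assert np.isnan(rate_correlation(a, b))

    def test_psth_single_spike_bin(self):
        b = Burst(onset=1.005, rel_times=np.array([0.0]), trigger_onset=1.0)
        counts, edges = psth([b], bin=0.002, window=(-0.01, 0.02))
        k = np.flatnonzero(counts)
        assert k.size == 1
        assert edges[k[0]] == pytest.approx(0.004)

    def test_psth_additive(self):
        b = Burst(onset=1.002, rel_times=np.array([0.0, 0.004, 0.009]),
                  trigger_onset=1.0)
        c1, _ = psth([b])
        c2, _ = psth([b, b])
        assert np.array_equal(c2, 2 * c1)

    def test_psth_empty(self):
        counts, _ = psth([], bin=0.002, window=(0, 0.01))
        assert np.all(counts == 0)

    def test_psth_requires_trigger(self):
        b = Burst(onset=1.0, rel_times=np.array([0.0]))
        with pytest.raises(ValueError, match="trigger"):
            psth([b])
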