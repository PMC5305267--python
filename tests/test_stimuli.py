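"""Stimulus fields: graded gradient, local random patches, switching schedules."""

import numpy as np
import pytest
from scipy import stats

from polartension.stimuli import (StimulusProtocol, StimulusEvent,
                                  graded_field, local_random_field,
                                  make_ks_function, switching_schedule,
                                  count_direction_changes, AXIS_DIRECTIONS)


class TestGraded:
    def test_zero_after_duration(self, params_small, disk_small):
        proto = StimulusProtocol(kind="graded", ks_amp=0.01, ks_dur=10.0,
                                 direction=0, R=params_small.R)
        assert graded_field(proto, disk_small, 11.0).max() == 0.0
        assert graded_field(proto, disk_small, 5.0).max() > 0.0

    def test_pole_values(self, params_small, disk_small):
        """k_s spans [0, 2R·amp]: 0 at the rear pole, 0.2 at the front pole
        for R=10, amp=0.01."""
        p = params_small
        proto = StimulusProtocol(kind="graded", ks_amp=0.01, ks_dur=10.0,
                                 direction=0, R=p.R)
        ks = graded_field(proto, disk_small, 1.0)
        X, Y = disk_small.meshgrid()
        mask = disk_small.interior_mask()
        front = mask & (X > p.R - 1.5) & (np.abs(Y) < 1.0)
        rear = mask & (X < -p.R + 1.5) & (np.abs(Y) < 1.0)
        assert ks[front].max() == pytest.approx(0.2, rel=0.1)
        assert ks[rear].min() < 0.02
        assert ks.max() <= 2 * p.R * 0.01 + 1e-12

    def test_direction_mirror_symmetry(self, params_small, disk_small):
        proto_pos = StimulusProtocol(kind="graded", ks_amp=0.01, ks_dur=10.0,
                                     direction=0, R=params_small.R)
        proto_neg = StimulusProtocol(kind="graded", ks_amp=0.01, ks_dur=10.0,
                                     direction=180, R=params_small.R)
        a = graded_field(proto_pos, disk_small, 1.0)
        b = graded_field(proto_neg, disk_small, 1.0)
        # mirroring the +x field in x gives the −x field (even grid: roll
        # to keep the cell-centered pixel alignment)
        mirrored = np.roll(a[::-1, :], 1, axis=0)
        assert np.allclose(mirrored, b, atol=1e-12)

    def test_non_axis_direction_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(kind="graded", ks_amp=0.01, ks_dur=1.0,
                             direction=45)


class TestLocalRandom:
    def test_zero_outside_band(self, params_small, disk_small):
        p = params_small
        proto = StimulusProtocol(kind="local_random", ks_amp=0.1, ks_dur=10.0,
                                 direction=0, seed=1, R=p.R)
        ks = local_random_field(proto, disk_small, 1.0)
        X, _ = disk_small.meshgrid()
        outside = (X < -0.01) | (X > 0.25 * p.R + 0.01)
        assert np.all(ks[outside] == 0.0)
        assert ks.max() <= 0.1

    def test_uniform_mean_over_band(self, params_small, disk_small):
        p = params_small
        vals = []
        for seed in range(30):
            proto = StimulusProtocol(kind="local_random", ks_amp=1.0,
                                     ks_dur=10.0, direction=0, seed=seed,
                                     R=p.R)
            ks = local_random_field(proto, disk_small, 1.0)
            vals.append(ks[ks > 0].mean())
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_seed_determinism(self, params_small, disk_small):
        mk = lambda s: local_random_field(
            StimulusProtocol(kind="local_random", ks_amp=0.1, ks_dur=10.0,
                             direction=0, seed=s, R=params_small.R),
            disk_small, 1.0)
        assert np.array_equal(mk(5), mk(5))
        assert not np.array_equal(mk(5), mk(6))

    def test_pattern_frozen_during_event(self, params_small, disk_small):
        proto = StimulusProtocol(kind="local_random", ks_amp=0.1, ks_dur=10.0,
                                 direction=0, seed=3, R=params_small.R)
        ks = make_ks_function(proto, disk_small)
        assert np.array_equal(ks(2.0), ks(9.0))


class TestSwitchingSchedule:
    def test_sequential_non_overlapping(self):
        sched = switching_schedule(0, 10, (0.005, 0.02), (10, 40), gap=30.0)
        for a, b in zip(sched, sched[1:]):
            assert b.onset >= a.offset + 29.99

    def test_direction_distribution_uniform(self):
        sched = switching_schedule(123, 4000, (0.01, 0.02), (5, 10), gap=1.0)
        counts = [sum(1 for e in sched if e.direction == d)
                  for d in AXIS_DIRECTIONS]
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 1e-4

    def test_ns_counting_conventions(self):
        evs = [StimulusEvent(0, 0.01, 5, d) for d in (0, 0, 90, 90, 180)]
        # without an initial direction the first event never counts
        assert count_direction_changes(evs) == 2
        # with initial polarity along 0°, the first event matches it
        assert count_direction_changes(evs, initial_direction=0) == 2
        # initial polarity along 90°: the first event (0°) differs
        assert count_direction_changes(evs, initial_direction=90) == 3
        # all events in one direction: only the first redirection counts
        same = [StimulusEvent(0, 0.01, 5, 90) for _ in range(4)]
        assert count_direction_changes(same, initial_direction=0) == 1

    def test_amplitude_duration_ranges(self):
        sched = switching_schedule(7, 200, (0.004, 0.02), (15, 50), gap=10)
        amps = [e.ks_amp for e in sched]
        durs = [e.ks_dur for e in sched]
        assert 0.004 <= min(amps) and max(amps) <= 0.02
        assert 15 <= min(durs) and max(durs) <= 50

    def test_every_field_nonneg_and_expires(self, params_small, disk_small):
        proto = StimulusProtocol(
            kind="switching_sequence", R=params_small.R,
            schedule=switching_schedule(1, 3, (0.01, 0.02), (5, 8), gap=5))
        ks = make_ks_function(proto, disk_small)
        last_off = proto.schedule[-1].offset
        for t in np.linspace(0.1, last_off + 5, 40):
            field = ks(t)
            if isinstance(field, np.ndarray):
                assert field.min() >= 0.0
        assert ks(last_off + 1.0) == 0.0
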