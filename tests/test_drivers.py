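"""Driver policies, lapse schedules and synthetic cohort generation."""

import numpy as np
import pytest

from lanelapse import (
    CarState,
    CohortSpec,
    DriverProfile,
    DynamicsConfig,
    InvalidParameterError,
    LapseSchedule,
    attentive_policy,
    generate_archetype_group,
    generate_cohort,
    lapsed_policy,
    make_lapse_schedule,
    profile_for_age,
    simulate_session,
    write_session,
)


class TestAttentivePolicy:
    def test_inside_deadband_presses_nothing(self):
        prof = DriverProfile(reaction_delay=0.0, deadband=0.1, miskey_prob=0.0)
        assert attentive_policy(CarState(0, 0.0), prof, []) == "none"

    def test_corrective_direction(self):
        prof = DriverProfile(reaction_delay=0.0, deadband=0.1, miskey_prob=0.0)
        assert attentive_policy(CarState(0, 1.0), prof, []) == "left"
        assert attentive_policy(CarState(0, -1.0), prof, []) == "right"

    def test_uses_delayed_observation(self):
        prof = DriverProfile(reaction_delay=0.1, deadband=0.1, miskey_prob=0.0)
        # position 5 samples ago was -1.0 even though the car is now at +1.0
        history = [-1.0, 0.0, 0.0, 0.0, 0.0]
        assert attentive_policy(CarState(0, 1.0), prof, history, 50.0) == "right"

    def test_miskey_matches_seeded_replay_oracle(self):
        """With miskey 1 the output equals an independent replay of the
        documented rng consumption: one random(), one integers(0,3)."""
        prof = DriverProfile(reaction_delay=0.0, deadband=0.1, miskey_prob=1.0)
        names = ["none", "left", "right"]
        for seed in range(20):
            oracle_rng = np.random.default_rng(seed)
            oracle_rng.random()
            expected = names[int(oracle_rng.integers(0, 3))]
            got = attentive_policy(
                CarState(0, 1.0), prof, [], rng=np.random.default_rng(seed)
            )
            assert got == expected

    def test_lapsed_policy_is_no_input(self):
        assert lapsed_policy() == "none"


class TestLapseSchedule:
    def test_rejects_overlapping_or_unsorted_intervals(self):
        with pytest.raises(InvalidParameterError):
            LapseSchedule(((0.0, 10.0), (5.0, 15.0)))
        with pytest.raises(InvalidParameterError):
            LapseSchedule(((10.0, 5.0),))

    def test_tick_mask_half_open(self):
        sched = LapseSchedule(((1.0, 2.0),))
        mask = sched.tick_mask(200, 50.0)
        assert not mask[49] and mask[50] and mask[99] and not mask[100]

    @pytest.mark.parametrize("archetype,expected", [
        ("uniform_good", ()),
        ("uniform_poor", ((0.0, 690.0),)),
    ])
    def test_constant_archetypes(self, archetype, expected):
        sched = make_lapse_schedule(archetype, 690.0, seed=1)
        assert sched.intervals == expected

    def test_onset_loss_with_planted_onset(self):
        sched = make_lapse_schedule("onset_loss", 690.0, {"onset_s": 210.0}, seed=1)
        assert sched.intervals == ((210.0, 690.0),)

    def test_alternating_structure_over_many_seeds(self):
        for seed in range(100):
            sched = make_lapse_schedule(
                "alternating", 690.0, {"mean_on_s": 120, "mean_off_s": 90}, seed=seed
            )
            iv = sched.intervals
            assert len(iv) >= 2  # bounded draws guarantee repetition
            assert all(0 <= a < b <= 690.0 for a, b in iv)
            assert all(iv[i][1] < iv[i + 1][0] for i in range(len(iv) - 1))

    def test_unknown_archetype_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_lapse_schedule("sleepy", 690.0)


class TestSimulateSession:
    def test_default_session_has_exactly_34496_samples(self, default_cfg):
        from lanelapse import default_track

        rec = simulate_session(default_track(0, default_cfg),
                               profile_for_age(11), default_cfg, seed=0)
        assert rec.n_samples == 34_496

    def test_track_shorter_than_session_rejected(self, short_cfg):
        from lanelapse import build_track

        tiny = build_track(1, 1, 5.0, 0)  # 10 s < 40 s session
        with pytest.raises(InvalidParameterError):
            simulate_session(tiny, profile_for_age(11), short_cfg, seed=0)

    def test_zero_delay_driver_stays_within_one_tick_bound(self, short_track, short_cfg):
        """deadband 0.05, no delay, no noise: |error| can exceed the
        deadband by at most one tick of combined key+drift velocity."""
        prof = DriverProfile(reaction_delay=0.0, deadband=0.05, miskey_prob=0.0)
        rec = simulate_session(short_track, prof, short_cfg, seed=0)
        bound = 0.05 + (0.45 * 10 + 10) / 50
        assert np.max(np.abs(rec.positions)) <= bound + 1e-12

    def test_deterministic_given_seed(self, short_track, short_cfg, tmp_path):
        a = simulate_session(short_track, profile_for_age(9), short_cfg, seed=5,
                             participant_id="9-1", age=9)
        b = simulate_session(short_track, profile_for_age(9), short_cfg, seed=5,
                             participant_id="9-1", age=9)
        np.testing.assert_array_equal(a.positions, b.positions)
        write_session(a, tmp_path / "a.csv")
        write_session(b, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_lapsed_driver_pins_to_an_edge_on_curves(self, default_cfg):
        """With no input the outward drift pins the car to the road edge
        within half_width / (0.45*speed) s of each curve's start."""
        from lanelapse import default_track, SegmentKind

        tr = default_track(2, default_cfg)
        prof = DriverProfile(
            lapse_schedule=LapseSchedule(((0.0, default_cfg.session_duration),))
        )
        rec = simulate_session(tr, prof, default_cfg, seed=2)
        drift_time = default_cfg.half_width / (0.45 * default_cfg.lateral_speed)
        t0 = 0.0
        for seg in tr.segments:
            if seg.kind is not SegmentKind.STRAIGHT:
                i = int(np.ceil((t0 + drift_time + 0.1) * default_cfg.sample_rate))
                if i < rec.n_samples:
                    window = np.abs(
                        rec.positions[i: i + int(default_cfg.sample_rate)]
                    )
                    assert window.max() == pytest.approx(default_cfg.half_width)
            t0 += seg.duration

    def test_lapsed_worse_than_attentive_over_seeds(self, short_track, short_cfg):
        att = DriverProfile(reaction_delay=0.2, deadband=0.1, miskey_prob=0.01)
        lap = DriverProfile(
            lapse_schedule=LapseSchedule(((0.0, short_cfg.session_duration),))
        )
        for seed in range(5):
            m_att = np.abs(
                simulate_session(short_track, att, short_cfg, seed).positions
            ).mean()
            m_lap = np.abs(
                simulate_session(short_track, lap, short_cfg, seed).positions
            ).mean()
            assert m_lap > m_att

    def test_enlarging_a_lapse_never_reduces_mean_error(self, short_track, short_cfg):
        for seed in range(20):
            small = DriverProfile(lapse_schedule=LapseSchedule(((10.0, 15.0),)))
            large = DriverProfile(lapse_schedule=LapseSchedule(((10.0, 25.0),)))
            m_small = np.abs(
                simulate_session(short_track, small, short_cfg, seed).positions
            ).mean()
            m_large = np.abs(
                simulate_session(short_track, large, short_cfg, seed).positions
            ).mean()
            assert m_large >= m_small


class TestCohortSpec:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            CohortSpec(archetype_mix={"uniform_good": 0.5, "uniform_poor": 0.4})

    def test_negative_proportion_rejected(self):
        with pytest.raises(InvalidParameterError):
            CohortSpec(archetype_mix={"uniform_good": 1.5, "uniform_poor": -0.5,
                                      "onset_loss": 0.0, "alternating": 0.0})

    def test_unknown_archetype_rejected(self):
        with pytest.raises(InvalidParameterError):
            CohortSpec(archetype_mix={"bored": 1.0})


class TestGenerateCohort:
    def test_empty_cohort(self, short_cfg, short_track):
        cohort = generate_cohort(CohortSpec(n_participants=0, seed=0),
                                 short_track, short_cfg)
        assert len(cohort) == 0

    def test_ids_follow_age_dash_counter_convention(self, short_cfg, short_track):
        cohort = generate_cohort(CohortSpec(n_participants=12, seed=3),
                                 short_track, short_cfg)
        for s in cohort.sessions:
            age, k = s.participant_id.split("-")
            assert int(age) == s.age
            assert int(k) >= 1
        assert len(set(cohort.participant_ids)) == 12

    def test_reproducible_from_seed(self, short_cfg, short_track):
        a = generate_cohort(CohortSpec(n_participants=5, seed=8), short_track, short_cfg)
        b = generate_cohort(CohortSpec(n_participants=5, seed=8), short_track, short_cfg)
        assert a.participant_ids == b.participant_ids
        for sa, sb in zip(a.sessions, b.sessions):
            np.testing.assert_array_equal(sa.positions, sb.positions)

    def test_good_cohort_beats_poor_cohort_participantwise(self, short_cfg, short_track):
        good = generate_cohort(
            CohortSpec(n_participants=6, seed=4,
                       archetype_mix={"uniform_good": 1.0}),
            short_track, short_cfg,
        )
        poor = generate_cohort(
            CohortSpec(n_participants=6, seed=4,
                       archetype_mix={"uniform_poor": 1.0}),
            short_track, short_cfg,
        )
        for g, p in zip(good.sessions, poor.sessions):
            assert np.abs(p.positions).mean() > np.abs(g.positions).mean()

    def test_age_gradient_on_attentive_cohort(self, short_cfg, short_track):
        """Median |error| by age is non-increasing for >= 80% of adjacent
        age pairs on an attentive-only cohort."""
        cohort = generate_cohort(
            CohortSpec(n_participants=55, seed=6,
                       archetype_mix={"uniform_good": 1.0}),
            short_track, short_cfg,
        )
        medians = {}
        for age in cohort.ages():
            pooled = np.concatenate(
                [np.abs(s.positions) for s in cohort.by_age(age)]
            )
            medians[age] = np.median(pooled)
        ages = sorted(medians)
        pairs = [(medians[a], medians[b]) for a, b in zip(ages, ages[1:])]
        frac = sum(1 for lo, hi in pairs if hi <= lo + 1e-12) / len(pairs)
        assert frac >= 0.8

    def test_onset_loss_sessions_worse_after_onset(self, short_cfg, short_track):
        """Out-of-band error rate before a planted onset is lower than
        after it, within each session."""
        hits = 0
        for seed in range(20):
            sched = make_lapse_schedule("onset_loss", 40.0, {"onset_s": 20.0})
            prof = profile_for_age(11, lapse_schedule=sched)
            rec = simulate_session(short_track, prof, short_cfg, seed)
            i = 20 * 50
            thresh = 1.5
            before = np.mean(np.abs(rec.positions[:i]) > thresh)
            after = np.mean(np.abs(rec.positions[i:]) > thresh)
            hits += after > before
        assert hits >= 19  # >= 95% of seeds
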