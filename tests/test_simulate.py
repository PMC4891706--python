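"""Agent-based simulator: random walk, ring experiments, catwalk sessions."""

import io as stdio
from dataclasses import replace

import numpy as np
import pytest

from ringgap import (
    ArenaGeometry,
    CatwalkSetup,
    ConfigurationError,
    SimConfig,
    get_profile,
    random_walk_step,
    simulate_catwalk_session,
    simulate_ring_experiment,
)
from ringgap.io import write_approach_log, write_track_table


class TestRandomWalkStep:
    def test_straight_line_without_turning_or_speed_noise(self, geometry, control):
        prof = replace(control, speed_sd=0.0, turn_rate_initial=0.0)
        state = (0.0, 0.0, 0.0, 0)
        for _ in range(3):
            state = random_walk_step(state, prof, geometry, np.random.default_rng(0))
        x, y, heading, t = state
        assert x == pytest.approx(3 * prof.speed_mean)
        assert y == pytest.approx(0.0)
        assert heading == 0.0 and t == 3

    def test_infinite_persistence_gives_constant_turn_rate(self, geometry, control):
        prof = replace(control, turn_rate_initial=0.3, persistence_timescale=1e12)
        rng = np.random.default_rng(42)
        turns = 0
        n = 4000
        for t in (0, n):   # early and late time behave identically
            count = 0
            for _ in range(n // 2):
                _, _, heading, _ = random_walk_step((0, 0, 0.0, t), prof, geometry, rng)
                count += heading != 0.0
            turns = count / (n // 2)
            assert turns == pytest.approx(0.3, abs=0.04)

    def test_fixed_seed_reproduces_trajectory(self, geometry, control):
        def run():
            rng = np.random.default_rng(11)
            state = (5.0, -3.0, 1.0, 0)
            return [state := random_walk_step(state, control, geometry, rng) for _ in range(10)]

        assert run() == run()

    def test_reflects_inside_disk(self, geometry, control):
        rng = np.random.default_rng(3)
        state = (geometry.disk_radius - 1.0, 0.0, 0.0, 0)
        for _ in range(50):
            state = random_walk_step(state, control, geometry, rng)
            assert np.hypot(state[0], state[1]) <= geometry.disk_radius + 1e-9


class TestRingExperiment:
    def test_record_invariants_hold(self, geometry):
        rec = simulate_ring_experiment(SimConfig(seed=0), geometry)
        rec.validate()
        assert len(rec.tracks) == 15
        for tr in rec.tracks:
            assert np.array_equal(tr.t, np.arange(600))
            r = np.hypot(tr.x, tr.y)
            assert np.all(r <= geometry.disk_radius + 1e-9)

    def test_conservation_alive_plus_dead_is_15(self, geometry):
        for seed in range(5):
            rec = simulate_ring_experiment(SimConfig(seed=seed, profile="clumsy"), geometry)
            n_alive = sum(not tr.dead[-1] for tr in rec.tracks)
            assert n_alive + rec.n_dead == 15

    def test_never_attempting_flies_stay_inside_first_groove(self, geometry, control):
        timid = replace(control, attempt_curve=((2.5, 0.0), (6.0, 0.0)),
                        success_curve=((2.5, 0.0),))
        rec = simulate_ring_experiment(SimConfig(seed=1, profile=timid), geometry)
        assert rec.n_dead == 0
        for tr in rec.tracks:
            assert np.hypot(tr.x, tr.y).max() < geometry.groove_inner_radii[0]

    def test_perfect_climbers_reach_the_rim_without_losses(self, geometry, control):
        ace = replace(
            control,
            attempt_curve=((2.5, 1.0), (6.0, 1.0)),
            success_curve=((2.5, 1.0), (6.0, 1.0)),
            fall_given_attempt=0.0,
            approach_refractory=0.0,
        )
        rec = simulate_ring_experiment(SimConfig(seed=2, profile=ace), geometry)
        assert rec.n_dead == 0
        outer_edge = geometry.groove_outer_radii[-1]
        assert any(np.hypot(tr.x, tr.y).max() > outer_edge for tr in rec.tracks)

    def test_dead_flies_frozen_at_groove_midline(self, geometry):
        rec = simulate_ring_experiment(SimConfig(seed=3, profile="clumsy"), geometry)
        assert rec.n_dead > 0
        for tr in rec.tracks:
            if not tr.dead[-1]:
                continue
            i = tr.death_time
            r = np.hypot(tr.x[i:], tr.y[i:])
            assert np.all(r == r[0])
            assert r[0] == pytest.approx(geometry.groove_midline(tr.death_groove))

    def test_alive_flies_never_rest_inside_a_groove(self, geometry):
        rec = simulate_ring_experiment(SimConfig(seed=4), geometry)
        for tr in rec.tracks:
            r = np.hypot(tr.x, tr.y)
            alive = ~tr.dead
            for radius in r[alive]:
                assert geometry.groove_at_radius(float(radius)) is None

    def test_dead_count_within_monte_carlo_envelope(self, geometry):
        # the same profile's 200-replicate distribution brackets one run
        counts = [
            simulate_ring_experiment(SimConfig(seed=1000 + s), geometry).n_dead
            for s in range(200)
        ]
        observed = simulate_ring_experiment(SimConfig(seed=1), geometry).n_dead
        assert min(counts) <= observed <= max(counts)

    def test_ring_assay_requires_15_flies(self, geometry):
        with pytest.raises(ConfigurationError):
            simulate_ring_experiment(SimConfig(seed=0, n_flies=10), geometry)

    def test_identical_config_is_byte_identical(self, geometry):
        def dump():
            buf = stdio.StringIO()
            write_track_table(simulate_ring_experiment(SimConfig(seed=9), geometry), buf)
            return buf.getvalue()

        assert dump() == dump()


class TestCatwalkSession:
    def test_each_fly_contributes_exactly_ten_approaches(self):
        log = simulate_catwalk_session("control", CatwalkSetup(gap_width=3.0), 8, seed=0)
        by_fly = log.by_fly()
        assert len(by_fly) == 8
        assert all(len(v) == 10 for v in by_fly.values())
        for evs in by_fly.values():
            assert [e.approach_index for e in evs] == list(range(1, 11))

    def test_zero_attempt_probability_yields_no_events(self, control):
        timid = replace(control, attempt_curve=((2.5, 0.0), (6.0, 0.0)),
                        success_curve=((2.5, 0.0),))
        log = simulate_catwalk_session(timid, CatwalkSetup(gap_width=3.0), 20, seed=1)
        assert not any(ev.attempted or ev.fell or ev.crossed for ev in log.events)

    def test_certain_success_crosses_ten_out_of_ten(self, control):
        ace = replace(
            control,
            attempt_curve=((2.5, 1.0), (6.0, 1.0)),
            success_curve=((2.5, 1.0), (6.0, 1.0)),
            fall_given_attempt=0.0,
        )
        log = simulate_catwalk_session(ace, CatwalkSetup(gap_width=4.0), 10, seed=2)
        assert all(ev.crossed for ev in log.events)

    def test_event_outcome_flags_are_consistent(self):
        log = simulate_catwalk_session(
            "tarsi_clumsy", CatwalkSetup(gap_width=3.5), 40, seed=3
        )
        for ev in log.events:
            if ev.fell or ev.crossed:
                assert ev.attempted
            assert not (ev.fell and ev.crossed)

    def test_identical_seed_is_byte_identical(self):
        def dump():
            buf = stdio.StringIO()
            write_approach_log(
                simulate_catwalk_session("control", CatwalkSetup(gap_width=2.5), 12, seed=5),
                buf,
            )
            return buf.getvalue()

        assert dump() == dump()

    def test_super_climber_median_matches_printed_aggregate_rate(self):
        # 40 crossings in 300 approaches -> per-fly median 1 crossing in 10
        from scipy.stats import binom

        from ringgap import per_fly_fractions

        log = simulate_catwalk_session(
            "super_climber", CatwalkSetup(gap_width=4.0), 101, seed=6
        )
        med = float(np.median([f.frac_cross for f in per_fly_fractions(log)]))
        assert med == binom.ppf(0.5, 10, 40 / 300) / 10 == pytest.approx(0.1)
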