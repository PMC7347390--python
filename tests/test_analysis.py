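"""Eigenworms, binned behavior, state summaries, dispersal, circular stats."""

import numpy as np
import pytest

from wormstates.analysis import (
    bend_phase,
    egg_rate_by_state_and_velocity,
    eigenworm_pca,
    event_triggered_average,
    grid_dispersal,
    knn_egg_distance,
    phase_event_histogram,
    rayleigh_test,
    reversal_runs,
    state_behavior_summary,
    trace_correlates,
    velocity_binned_behavior,
)
from wormstates.record import EventTrain
from wormstates.states import StatePath

FR = 20.0


def simple_record(n, seed=0):
    from tests.test_record import make_record

    return make_record(n, seed=seed)


class TestEigenwormPCA:
    def test_two_mode_data_fully_explained_by_two_components(self):
        rng = np.random.default_rng(0)
        m1 = np.sin(np.linspace(0, 2 * np.pi, 14))
        m2 = np.cos(np.linspace(0, 2 * np.pi, 14))
        X = np.outer(rng.normal(0, 1, 500), m1) + np.outer(rng.normal(0, 1, 500), m2)
        with pytest.warns(UserWarning, match="rank-deficient"):
            basis, proj = eigenworm_pca(X, n_components=4)
        assert basis.components.shape[0] == 2
        assert basis.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_spreads_evenly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (20_000, 14))
        basis, _ = eigenworm_pca(X)
        # each fraction concentrates near 1/14 for isotropic input
        assert np.abs(basis.explained_fraction - 1 / 14).max() < 0.01

    def test_components_orthonormal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (500, 14)) * np.linspace(1, 3, 14)
        basis, _ = eigenworm_pca(X)
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(basis.components.shape[0]),
                                   atol=1e-9)

    def test_projection_variance_identity(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (2000, 14)) * np.linspace(1, 3, 14)
        basis, proj = eigenworm_pca(X)
        total = (X - X.mean(axis=0)).var(axis=0).sum()
        got = proj.var(axis=0).sum() / total
        np.testing.assert_allclose(got, basis.explained_fraction.sum(), atol=1e-6)


class TestVelocityBinned:
    def test_events_absent_from_unvisited_velocity_bins(self):
        rec = simple_record(4000)
        rng = np.random.default_rng(0)
        velocity = rng.uniform(0.15, 0.35, 4000)
        events = {"egg": EventTrain("egg", rec.timestamps[np.arange(50, 4000, 400)])}
        out = velocity_binned_behavior(rec, velocity, events=events)
        prof = out["egg"]
        neg = prof.bin_edges[:-1] < 0
        assert np.all(np.isnan(prof.statistic[neg]))
        assert prof.excluded[neg].all()

    def test_homogeneous_poisson_rate_flat(self):
        rec = simple_record(40_000, seed=1)
        rng = np.random.default_rng(2)
        velocity = rng.uniform(-0.2, 0.4, 40_000)
        rate_per_min = 30.0
        event_frames = np.flatnonzero(rng.random(40_000) < rate_per_min / 60 / FR)
        events = {"egg": EventTrain("egg", rec.timestamps[event_frames])}
        out = velocity_binned_behavior(rec, velocity, events=events)
        prof = out["egg"]
        ok = ~prof.excluded
        t_min = prof.time_in_bin[ok] / 60
        se = np.sqrt(rate_per_min / t_min)
        assert (np.abs(prof.statistic[ok] - rate_per_min) < 4 * se).all()

    def test_shuffled_null_profile_flat(self):
        rec = simple_record(40_000, seed=3)
        rng = np.random.default_rng(4)
        velocity = rng.uniform(-0.2, 0.4, 40_000)
        fast = np.flatnonzero(velocity > 0.2)
        events = {"egg": EventTrain("egg", np.sort(rec.timestamps[
            rng.choice(fast, 120, replace=False)]))}
        out = velocity_binned_behavior(rec, velocity, events=events,
                                       shuffle_null=True, seed=5)
        null = out["egg_null"]
        ok = ~null.excluded
        rates = null.statistic[ok]
        t_min = null.time_in_bin[ok] / 60
        overall = 120 / t_min.sum()
        se = np.sqrt(overall / t_min)
        assert (np.abs(rates - overall) < 4 * se).all()


class TestStateSummary:
    def _path(self, n_bins, states, velocity_state):
        labels = {s: ("roam" if s == velocity_state else f"dwell{s}")
                  for s in np.unique(states)}
        return StatePath(states=np.asarray(states), labels=labels)

    def test_frozen_posture_has_zero_average_motion(self):
        rec = simple_record(1200)
        rec.posture[:] = rec.posture[0]
        states = np.zeros(20, int)
        path = self._path(20, states, velocity_state=0)
        out = state_behavior_summary(rec, np.full(1200, 0.1), path)
        assert out[0]["average_motion"] == pytest.approx(0.0, abs=1e-12)

    def test_reversal_duration_classification(self):
        velocity = np.full(1200, 0.1)
        velocity[100:140] = -0.1  # 2 s
        velocity[400:520] = -0.1  # 6 s
        short, long_ = reversal_runs(velocity, FR)
        assert len(short) == 1 and len(long_) == 1
        assert short[0] == (100, 140) and long_[0] == (400, 520)

    def test_state_egg_rates_recovered(self, hour_record, model):
        rec, truth = hour_record
        states = truth.state_path
        path = self._path(states.size, states, velocity_state=model.roaming_state)
        velocity = np.full(rec.n_frames, 0.1)
        out = state_behavior_summary(
            rec, velocity, path, events={"egg": truth.events["egg"]}
        )
        # roaming rate within 3 SE (Poisson, SE from the generator rate)
        roam = out[model.roaming_state]
        se = np.sqrt(0.5 / roam["occupancy_min"])
        assert abs(roam["egg_rate_per_min"] - 0.5) < 3 * se


class TestEventTriggered:
    def test_constant_signal_flat_average(self):
        rec = simple_record(2000)
        sig = np.full(2000, 3.3)
        out = event_triggered_average(
            rec, {"v": sig}, rec.timestamps[[500, 1000, 1500]], window_s=5.0
        )
        lag, mean, sem = out["v"]
        np.testing.assert_allclose(mean, 3.3)
        np.testing.assert_allclose(sem, 0.0, atol=1e-12)

    def test_step_at_events_reproduced(self):
        rec = simple_record(6000)
        sig = np.zeros(6000)
        events = [1000, 2500, 4000]
        for f in events:
            sig[f:] += 1.0
        out = event_triggered_average(
            rec, {"v": sig}, rec.timestamps[events], window_s=5.0
        )
        lag, mean, _ = out["v"]
        assert mean[lag < -0.1].std() < 1e-9
        assert (mean[lag > 0.1] - mean[lag < -0.1].mean()
                == pytest.approx(1.0, abs=1e-9))

    def test_sem_shrinks_with_sqrt_n(self):
        rng = np.random.default_rng(0)
        rec = simple_record(42_000)
        sig = rng.normal(0, 1, 42_000)
        frames4 = np.arange(1000, 5000, 1000)
        frames16 = np.arange(1000, 17_000, 1000)
        sem4 = event_triggered_average(
            rec, {"v": sig}, rec.timestamps[frames4], window_s=2.0)["v"][2]
        sem16 = event_triggered_average(
            rec, {"v": sig}, rec.timestamps[frames16], window_s=2.0)["v"][2]
        ratio = sem4.mean() / sem16.mean()
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_truncated_windows_excluded(self):
        rec = simple_record(200)
        with pytest.raises(ValueError, match="window"):
            event_triggered_average(rec, {"v": np.zeros(200)},
                                    np.array([0.1]), window_s=30.0)


class TestEggRateByState:
    def _inputs(self, n_animals=4, rate_roam=0.5, rate_dwell=0.5, seed=0,
                n_frames=96_000):
        rng = np.random.default_rng(seed)
        records, velocities, eggs, paths = [], [], [], []
        for a in range(n_animals):
            rec = simple_record(n_frames, seed=seed + a)
            n_bins = n_frames // 60
            states = (rng.random(n_bins) < 0.4).astype(int)  # 1 = roam
            labels = {0: "dwell1", 1: "roam"}
            frame_state = np.repeat(states, 60)[:n_frames]
            velocity = np.where(frame_state == 1,
                                rng.uniform(0.0, 0.3, n_frames),
                                rng.uniform(-0.05, 0.25, n_frames))
            rate = np.where(frame_state == 1, rate_roam, rate_dwell)
            ev = np.flatnonzero(rng.random(n_frames) < rate / 60 / 20.0)
            records.append(rec)
            velocities.append(velocity)
            eggs.append(EventTrain("egg", rec.timestamps[ev]))
            paths.append(StatePath(states=states, labels=labels))
        return records, velocities, eggs, paths

    def test_six_fold_ratio_recovered_and_significant(self):
        recs, vels, eggs, paths = self._inputs(rate_roam=6.0, rate_dwell=1.0,
                                               seed=1)
        out = egg_rate_by_state_and_velocity(
            recs, vels, eggs, paths, n_boot=200, n_perm=500, seed=0
        )
        ok = ~np.isnan(out["rate"][0]) & ~np.isnan(out["rate"][1]) & \
            (out["rate"][1] > 0)
        ratios = out["rate"][0][ok] / out["rate"][1][ok]
        assert np.median(ratios) == pytest.approx(6.0, rel=0.5)
        assert (out["p_bin_bonferroni"][ok] < 0.05).mean() > 0.5

    def test_null_rates_rarely_significant(self):
        recs, vels, eggs, paths = self._inputs(rate_roam=1.0, rate_dwell=1.0,
                                               seed=2)
        out = egg_rate_by_state_and_velocity(
            recs, vels, eggs, paths, n_boot=100, n_perm=1000, seed=3
        )
        p = out["p_bin_bonferroni"]
        tested = np.isfinite(p)
        assert (p[tested] < 0.05).mean() <= 0.05 + 1e-9

    def test_underfilled_bins_excluded(self):
        recs, vels, eggs, paths = self._inputs(n_frames=2400, seed=4)  # 2 min
        out = egg_rate_by_state_and_velocity(recs, vels, eggs, paths,
                                             n_boot=50, n_perm=100, seed=0)
        assert out["excluded"].all()  # no bin reaches 4 min per animal
        assert np.isnan(out["rate"]).all()


class TestEggDispersal:
    def test_knn_hand_computed(self):
        eggs = np.array([[0.0, 0], [1000.0, 0], [2000.0, 0]])
        out = knn_egg_distance(eggs, k_range=range(1, 3))
        assert out[1] == pytest.approx(1000.0)
        assert out[2] == pytest.approx((1500 + 1000 + 1500) / 3)

    def test_knn_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        eggs = rng.uniform(0, 5000, (20, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = eggs @ R.T + np.array([123.0, -456.0])
        a = knn_egg_distance(eggs)
        b = knn_egg_distance(moved)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9)

    def test_knn_truncates_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            out = knn_egg_distance(np.zeros((3, 2)), k_range=range(1, 10))
        assert set(out) == {1, 2}

    def test_grid_fraction_hand_computed(self):
        path = np.array([[i * 500.0 + 250, 250.0] for i in range(10)])
        eggs = np.array([[250.0, 250], [750.0, 250], [1250.0, 250],
                         [1750.0, 250]])
        assert grid_dispersal(path, eggs) == pytest.approx(0.4)

    def test_no_eggs_zero(self):
        path = np.array([[250.0, 250]])
        assert grid_dispersal(path, np.zeros((0, 2))) == 0.0

    def test_every_cell_occupied_gives_one(self):
        path = np.array([[i * 500.0 + 250, 250.0] for i in range(5)])
        assert grid_dispersal(path, path.copy()) == 1.0

    def test_whole_cell_translation_invariance(self):
        rng = np.random.default_rng(1)
        path = rng.uniform(0, 5000, (200, 2))
        eggs = rng.uniform(0, 5000, (15, 2))
        base = grid_dispersal(path, eggs)
        shifted = grid_dispersal(path + 1000.0, eggs + 1000.0)
        assert base == shifted


class TestBendPhase:
    def _wave(self, omega=2 * np.pi * 0.5, n=2000, A=0.4):
        t = np.arange(n) / FR
        s = np.linspace(0, 1, 14)
        angles = A * np.sin(omega * t[:, None] - 2 * np.pi * 1.5 * s[None, :])
        return t, angles - angles.mean(axis=1, keepdims=True)

    def _projections(self, angles):
        basis, proj = eigenworm_pca(angles, n_components=2)
        return proj

    def test_traveling_wave_phase_rate(self):
        omega = 2 * np.pi * 0.5
        t, angles = self._wave(omega)
        proj = self._projections(angles)
        prof = bend_phase(proj, angles)
        good = np.isfinite(prof.phase)
        unwrapped = np.unwrap(prof.phase[good])
        # mean advance over the full trace (elliptic orbits modulate the
        # instantaneous rate, but whole cycles average to omega)
        rate = (unwrapped[-1] - unwrapped[0]) / ((good.sum() - 1) / FR)
        assert rate == pytest.approx(omega, rel=0.02)
        assert rate > 0  # phase advances forward

    def test_depth_scales_with_amplitude(self):
        _, a1 = self._wave(A=0.4)
        _, a2 = self._wave(A=0.8)
        p1 = bend_phase(self._projections(a1), a1)
        p2 = bend_phase(self._projections(a2), a2)
        np.testing.assert_allclose(p2.depth, 2 * p1.depth, rtol=1e-6)

    def test_static_posture_has_no_phase(self):
        angles = np.tile(np.linspace(-0.5, 0.5, 14), (100, 1))
        proj = np.zeros((100, 2))
        prof = bend_phase(proj, angles)
        assert np.isnan(prof.phase).all()


class TestRayleigh:
    def test_identical_phases_give_z_equal_n(self):
        z, p = rayleigh_test(np.full(10, 1.2))
        assert z == pytest.approx(10.0)
        assert p < 1e-3

    def test_antipodal_pairs_cancel(self):
        z, _ = rayleigh_test(np.array([0.0, np.pi, 0.5, 0.5 + np.pi]))
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_uniform_null_calibration(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(100)          :
            phases = rng.uniform(-np.pi, np.pi, 1000)
            _, p = rayleigh_test(phases)
            rejections += p < 0.05
        assert rejections <= 10

    def test_matches_pingouin(self):
        from pingouin import circ_rayleigh

        rng = np.random.default_rng(1)
        phases = rng.vonmises(0.5, 1.0, 200)
        z, p = rayleigh_test(phases)
        z_ref, p_ref = circ_rayleigh(phases)
        assert z == pytest.approx(z_ref, rel=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-6, abs=1e-12)

    def test_phase_histogram_counts_sum_to_events(self):
        rng = np.random.default_rng(2)
        n = 500
        t = np.arange(n) / FR
        prof = bend_phase(
            np.stack([np.cos(2 * t), np.sin(2 * t)], axis=1),
            rng.normal(0, 0.3, (n, 14)),
        )
        ev = t[rng.choice(n, 40, replace=False)]
        out = phase_event_histogram(np.sort(ev), t, prof)
        assert out["counts"].sum() == out["n"] == 40


class TestTraceCorrelates:
    def test_trace_equal_to_angle_nine_correlates_perfectly(self):
        rec = simple_record(2000, seed=5)
        trace = rec.posture[:, 9].copy()
        out = trace_correlates(trace, rec, speed=np.full(2000, 0.1))
        assert out["angle_correlations"][9] == pytest.approx(1.0)

    def test_white_noise_uncorrelated(self):
        rec = simple_record(5000, seed=6)
        rng = np.random.default_rng(7)
        out = trace_correlates(rng.normal(0, 1, 5000), rec,
                               speed=np.full(5000, 0.1))
        assert np.abs(out["angle_correlations"]).max() < 3 / np.sqrt(5000) * 1.5

    def test_derivative_increases_with_speed_by_construction(self):
        n = 20_000
        rec = simple_record(n, seed=8)
        rng = np.random.default_rng(9)
        speed = rng.uniform(0.0, 0.3, n)
        trace = np.cumsum(speed) / FR  # derivative = speed
        out = trace_correlates(trace, rec, speed=speed)
        binned = out["abs_derivative_by_speed"]
        good = ~np.isnan(binned)
        assert (np.diff(binned[good]) > 0).all()

    def test_too_few_frames_rejected(self):
        rec = simple_record(50)
        with pytest.raises(ValueError, match="100"):
            trace_correlates(np.zeros(50), rec, speed=np.zeros(50))
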