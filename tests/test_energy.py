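"""Static and snapshot-switching minimum control energy."""

import warnings

import numpy as np
import pytest
from scipy.linalg import expm

from funcontrol import (
    ConnectivityMatrix,
    NormalizedInteraction,
    TemporalSystem,
    TimeSeriesData,
    TransitionSpec,
    build_temporal_system,
    control_matrix,
    extract_states,
    segment_windows,
    shuffle_null,
    static_min_energy,
    tau_sweep,
    temporal_min_energy,
    transition_experiment,
)
from oracles import least_norm_energy, random_stable


def _wrap(A):
    return NormalizedInteraction(A, A, -A, 1.0, 0.0, "window_correlation")


class TestStaticEnergy:
    def test_free_evolution_costs_nothing(self, rng):
        A = random_stable(rng, 4)
        x0 = rng.normal(0, 1, 4)
        xf = expm(A * 3.0) @ x0
        res = static_min_energy(A, np.eye(4), TransitionSpec(x0, xf, 3.0))
        assert res.energy == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.d, 0.0, atol=1e-10)

    def test_zero_dynamics_closed_form(self, rng):
        x0, xf = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        res = static_min_energy(
            np.zeros((5, 5)), np.eye(5), TransitionSpec(x0, xf, 10.0)
        )
        assert res.energy == pytest.approx(np.sum((xf - x0) ** 2) / 20.0, abs=1e-10)

    def test_matches_least_norm_discretization(self, rng):
        A = random_stable(rng, 6)
        x0, xf = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
        res = static_min_energy(A, np.eye(6), TransitionSpec(x0, xf, 2.0))
        oracle = least_norm_energy([A], [2.0], np.eye(6), x0, xf, dt=1e-3)
        assert 2.0 * res.energy == pytest.approx(oracle, rel=0.01)

    def test_restricted_control_set_unreachable(self, rng):
        # with a decoupled system and control only on region 0, region 1
        # cannot be moved
        A = np.diag([-0.5, -0.5])
        B = control_matrix(2, [0])
        spec = TransitionSpec(np.zeros(2), np.array([0.0, 1.0]), 2.0)
        with pytest.raises(ValueError, match="unreachable"):
            static_min_energy(A, B, spec)

    def test_enlarging_control_set_never_costs_more(self, rng):
        A = random_stable(rng, 6)
        x0, xf = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
        spec = TransitionSpec(x0, xf, 4.0)
        full = static_min_energy(A, np.eye(6), spec).energy
        for k in (3, 4, 5):
            B = control_matrix(6, np.arange(k))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                try:
                    sub = static_min_energy(A, B, spec).energy
                except ValueError:
                    continue  # genuinely unreachable with this subset
            assert full <= sub * (1 + 1e-8)


class TestTemporalEnergy:
    def test_single_snapshot_reduces_to_static(self, rng):
        A = random_stable(rng, 5)
        x0, xf = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        system = TemporalSystem([_wrap(A)], [3.0], np.eye(5))
        spec = TransitionSpec(x0, xf, 3.0)
        E_d = temporal_min_energy(system, spec).energy
        E_s = static_min_energy(A, np.eye(5), spec).energy
        assert E_d == pytest.approx(E_s, rel=1e-12)

    def test_identical_snapshots_reduce_to_static_on_summed_horizon(self, rng):
        A = random_stable(rng, 6)
        x0, xf = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
        durations = [1.5, 2.5, 1.0, 3.0]
        system = TemporalSystem([_wrap(A)] * 4, durations, np.eye(6))
        spec = TransitionSpec(x0, xf, sum(durations))
        E_d = temporal_min_energy(system, spec).energy
        E_s = static_min_energy(A, np.eye(6), spec).energy
        assert E_d == pytest.approx(E_s, rel=1e-8)

    def test_zero_dynamics_closed_form(self, rng):
        x0, xf = rng.normal(0, 1, 4), rng.normal(0, 1, 4)
        Z = np.zeros((4, 4))
        system = TemporalSystem([_wrap(Z)] * 3, [2.0, 3.0, 5.0], np.eye(4))
        spec = TransitionSpec(x0, xf, 10.0)
        expected = np.sum((xf - x0) ** 2) / (2.0 * 10.0)
        assert temporal_min_energy(system, spec).energy == pytest.approx(
            expected, abs=1e-10
        )

    def test_matches_least_norm_discretization(self, rng):
        mats = [random_stable(rng, 6) for _ in range(3)]
        durations = [0.8, 1.0, 0.7]
        x0, xf = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
        system = TemporalSystem([_wrap(A) for A in mats], durations, np.eye(6))
        spec = TransitionSpec(x0, xf, sum(durations))
        E_d = temporal_min_energy(system, spec).energy
        oracle = least_norm_energy(mats, durations, np.eye(6), x0, xf, dt=1e-3)
        assert 2.0 * E_d == pytest.approx(oracle, rel=0.01)

    def test_energy_nonnegative_zero_iff_zero_drift(self, rng):
        mats = [random_stable(rng, 4) for _ in range(2)]
        system = TemporalSystem([_wrap(A) for A in mats], [1.0, 1.0], np.eye(4))
        x0 = rng.normal(0, 1, 4)
        xf = expm(mats[1] * 1.0) @ expm(mats[0] * 1.0) @ x0
        res = temporal_min_energy(system, TransitionSpec(x0, xf, 2.0))
        assert res.energy == pytest.approx(0.0, abs=1e-10)
        res2 = temporal_min_energy(
            system, TransitionSpec(x0, xf + 0.5, 2.0)
        )
        assert res2.energy > 0


class TestBuildTemporalSystem:
    def _windows(self, rng, m, n=5):
        return [
            ConnectivityMatrix(
                np.corrcoef(rng.normal(0, 1, (n, 60))),
                "window_correlation",
                window_span=(60 * i, 60 * (i + 1)),
            )
            for i in range(m)
        ]

    def test_duration_scheme_m5(self, rng):
        system = build_temporal_system(self._windows(rng, 5), np.eye(5))
        np.testing.assert_allclose(system.durations, [30, 60, 60, 60, 30])
        assert system.total_horizon == pytest.approx(240.0)

    def test_duration_scheme_m2(self, rng):
        system = build_temporal_system(self._windows(rng, 2), np.eye(5))
        np.testing.assert_allclose(system.durations, [30, 30])
        assert system.total_horizon == pytest.approx(60.0)

    def test_single_window_warns(self, rng):
        with pytest.warns(RuntimeWarning, match="single-snapshot"):
            system = build_temporal_system(self._windows(rng, 1), np.eye(5))
        np.testing.assert_allclose(system.durations, [30.0])

    def test_snapshots_are_stabilized(self, rng):
        system = build_temporal_system(self._windows(rng, 3), np.eye(5))
        for snap in system.snapshots:
            assert np.max(np.linalg.eigvals(snap.A).real) < 0


class TestStateExtraction:
    def test_central_ten_frames_of_sixty(self):
        vals = np.arange(120, dtype=float)[None, :]
        ts = TimeSeriesData(vals)
        x0, xf = extract_states(ts, (0, 60), (60, 120))
        # frames 25..34 of each window
        assert x0[0] == pytest.approx(np.mean(np.arange(25, 35)))
        assert xf[0] == pytest.approx(np.mean(np.arange(85, 95)))

    def test_endpoint_mode(self):
        vals = np.arange(120, dtype=float)[None, :]
        ts = TimeSeriesData(vals)
        x0, xf = extract_states(ts, (0, 60), (60, 120), mode="endpoint_value")
        assert x0[0] == 0.0 and xf[0] == 119.0

    def test_constant_series_gives_constant_states(self):
        ts = TimeSeriesData(np.full((3, 120), 2.5))
        x0, xf = extract_states(ts, (0, 60), (60, 120))
        np.testing.assert_allclose(x0, 2.5)
        np.testing.assert_allclose(xf, 2.5)

    def test_window_too_short_for_mean10(self):
        ts = TimeSeriesData(np.zeros((2, 20)))
        with pytest.raises(ValueError):
            extract_states(ts, (0, 8), (12, 20))

    def test_segment_windows_tiling(self):
        spans = segment_windows(200, window=60)
        assert spans == [(0, 60), (60, 120), (120, 180)]
        with pytest.raises(ValueError):
            segment_windows(59, window=60)


class TestShuffleNull:
    def test_time_invariant_system_has_zero_inflation(self, rng):
        A = random_stable(rng, 4)
        system = TemporalSystem([_wrap(A)] * 4, [30, 60, 60, 30], np.eye(4))
        spec = TransitionSpec(rng.normal(0, 1, 4), rng.normal(0, 1, 4), 180.0)
        res = shuffle_null(system, spec, n_perm=10, seed=0)
        assert abs(res.log_inflation) < 1e-10

    def test_two_snapshots_enumerable_null(self, rng):
        mats = [random_stable(rng, 3), random_stable(rng, 3)]
        system = TemporalSystem([_wrap(A) for A in mats], [1.0, 2.0], np.eye(3))
        spec = TransitionSpec(rng.normal(0, 1, 3), rng.normal(0, 1, 3), 3.0)
        res = shuffle_null(system, spec, n_perm=40, seed=1)
        # permutations of 2 snapshots: identity or swap only
        assert len(np.unique(np.round(res.null_energies, 12))) <= 2
        identity_E = temporal_min_energy(system, spec).energy
        assert np.any(np.isclose(res.null_energies, identity_E, rtol=1e-10))

    def test_durations_stay_attached_to_positions(self, rng):
        # all-equal durations: permuting order with position-locked durations
        # must keep total horizon; check via the M=2 asymmetric case instead
        mats = [random_stable(rng, 3), random_stable(rng, 3)]
        system = TemporalSystem([_wrap(A) for A in mats], [1.0, 5.0], np.eye(3))
        spec = TransitionSpec(rng.normal(0, 1, 3), rng.normal(0, 1, 3), 6.0)
        swapped = TemporalSystem(
            [system.snapshots[1], system.snapshots[0]], [1.0, 5.0], np.eye(3)
        )
        E_swap = temporal_min_energy(swapped, spec).energy
        res = shuffle_null(system, spec, n_perm=50, seed=2)
        others = res.null_energies[
            ~np.isclose(res.null_energies, res.observed_energy, rtol=1e-10)
        ]
        if others.size:
            assert np.allclose(others, E_swap, rtol=1e-10)

    def test_seed_reproducibility(self, rng):
        mats = [random_stable(rng, 3) for _ in range(3)]
        system = TemporalSystem([_wrap(A) for A in mats], [1, 1, 1], np.eye(3))
        spec = TransitionSpec(rng.normal(0, 1, 3), rng.normal(0, 1, 3), 3.0)
        a = shuffle_null(system, spec, n_perm=8, seed=3)
        b = shuffle_null(system, spec, n_perm=8, seed=3)
        np.testing.assert_array_equal(a.null_energies, b.null_energies)

    def test_requires_two_snapshots(self, rng):
        system = TemporalSystem([_wrap(random_stable(rng, 3))], [1.0], np.eye(3))
        spec = TransitionSpec(np.zeros(3), np.ones(3), 1.0)
        with pytest.raises(ValueError):
            shuffle_null(system, spec)


class TestTauSweep:
    def test_zero_dynamics_closed_form_decreasing(self, rng):
        Z = np.zeros((3, 3))
        system = TemporalSystem([_wrap(Z)] * 3, [1, 1, 1], np.eye(3))
        x0, xf = rng.normal(0, 1, 3), rng.normal(0, 1, 3)
        taus = [1.0, 2.0, 5.0, 10.0]
        rows = tau_sweep(system, Z, x0, xf, taus)
        norm2 = np.sum((xf - x0) ** 2)
        for row in rows:
            assert row["E_s"] == pytest.approx(norm2 / (2 * row["tau_s"]), rel=1e-8)
            assert row["E_d"] == pytest.approx(row["E_s"], rel=1e-8)
        energies = [r["E_s"] for r in rows]
        assert all(a > b for a, b in zip(energies, energies[1:]))

    def test_single_value(self, rng):
        A = random_stable(rng, 3)
        system = TemporalSystem([_wrap(A)] * 2, [1, 1], np.eye(3))
        rows = tau_sweep(system, A, rng.normal(0, 1, 3), rng.normal(0, 1, 3), [4.0])
        assert len(rows) == 1

    def test_time_invariant_snapshots_agree(self, rng):
        A = random_stable(rng, 4)
        system = TemporalSystem([_wrap(A)] * 3, [1, 1, 1], np.eye(4))
        rows = tau_sweep(
            system, A, rng.normal(0, 1, 4), rng.normal(0, 1, 4), [2.0, 6.0, 12.0]
        )
        for row in rows:
            assert row["E_d"] == pytest.approx(row["E_s"], rel=1e-8)


class TestTransitionExperiment:
    def test_builds_paired_systems(self, small_cohort):
        subjects, _ = small_cohort
        from funcontrol import preprocess_series

        ts = preprocess_series(subjects[0], n_discard=0)
        B = np.eye(ts.n_regions)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            system, spec, static_A = transition_experiment(ts, (0, 300), B)
        assert system.M == 5
        np.testing.assert_allclose(system.durations, [30, 60, 60, 60, 30])
        assert spec.tau_s == pytest.approx(system.total_horizon)
        assert static_A.shape == (ts.n_regions, ts.n_regions)

    def test_segment_too_short(self, small_cohort):
        subjects, _ = small_cohort
        with pytest.raises(ValueError):
            transition_experiment(subjects[0], (0, 100), np.eye(subjects[0].n_regions))
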