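"""Event-driven DMD engine: event algebra, conservation laws, thermostat."""

import math

import numpy as np
import pytest

from cldmd.engine import (
    ghost_collision,
    initial_state,
    kinetic_energy,
    predict_boundary_time,
    random_coil,
    resolve_crossing,
    run_md,
)
from cldmd.forcefield import total_potential_energy


class TestPredictBoundaryTime:
    def test_head_on_closing(self):
        assert predict_boundary_time((10, 0, 0), (-1, 0, 0), 8.0) == pytest.approx(2.0)

    def test_receding_from_inner_boundary(self):
        assert predict_boundary_time((10, 0, 0), (1, 0, 0), 8.0) is None

    def test_outward_crossing_from_inside(self):
        assert predict_boundary_time((5, 0, 0), (1, 0, 0), 8.0) == pytest.approx(3.0)

    def test_zero_relative_velocity(self):
        assert predict_boundary_time((10, 0, 0), (0, 0, 0), 8.0) is None

    def test_matches_dense_time_scan(self, rng):
        for _ in range(50):
            r = rng.normal(0, 8, 3)
            v = rng.normal(0, 1, 3)
            d = float(rng.uniform(2, 12))
            if abs(np.linalg.norm(r) - d) < 1e-3:
                continue
            t_pred = predict_boundary_time(r, v, d)
            # brute-force scan: bracket sign changes of |r + tv| - d
            ts = np.linspace(0, 50, 2_000_001)
            f = np.linalg.norm(r[None, :] + ts[:, None] * v[None, :], axis=1) - d
            crossings = np.where(np.sign(f[:-1]) != np.sign(f[1:]))[0]
            if t_pred is None:
                assert len(crossings) == 0 or ts[crossings[0]] > 49
            else:
                lo, hi = ts[crossings[0]], ts[crossings[0] + 1]
                for _ in range(80):  # bisect to 1e-9
                    mid = 0.5 * (lo + hi)
                    fm = np.linalg.norm(r + mid * v) - d
                    if np.sign(fm) == np.sign(np.linalg.norm(r + lo * v) - d):
                        lo = mid
                    else:
                        hi = mid
                assert t_pred == pytest.approx(0.5 * (lo + hi), abs=1e-9)


class TestResolveCrossing:
    def test_no_step_transmits_unchanged(self):
        assert resolve_crossing(1.0, -2.0, 0.0) == (-2.0, True)

    def test_falling_into_well_accelerates(self):
        v, ok = resolve_crossing(1.0, -2.0, -1.0)
        assert ok and v == pytest.approx(-math.sqrt(6.0))

    def test_insufficient_energy_reflects(self):
        assert resolve_crossing(1.0, -1.0, 1.0) == (1.0, False)

    def test_energy_balance_exact(self, rng):
        for _ in range(200):
            mu = float(rng.uniform(0.2, 3.0))
            vr = float(rng.normal(0, 2))
            dU = float(rng.normal(0, 1))
            v_new, ok = resolve_crossing(mu, vr, dU)
            if ok:
                assert 0.5 * mu * v_new**2 == pytest.approx(
                    0.5 * mu * vr**2 - dU, abs=1e-12
                )
            else:
                assert v_new == -vr

    def test_bad_reduced_mass(self):
        with pytest.raises(ValueError):
            resolve_crossing(0.0, 1.0, 0.0)


class TestTwoBodyDynamics:
    def test_bond_oscillation_period_matches_closed_form(self, small_model):
        """Head-on bounce in the bond well has period 2·width/|v_rel|."""
        from cldmd.forcefield import build_chain

        model = build_chain("GG")
        st = initial_state(model, T=0.5, seed=0)
        st.positions = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]])
        st.velocities = np.array([[0.25, 0.0, 0.0], [-0.25, 0.0, 0.0]])
        st.shells = None
        st2, traj = run_md(st, 0.5, 8, sample_every=1, seed=0, ghost_rate=0.0)
        times = traj.times
        lo, hi = 3.8 * 0.98, 3.8 * 1.02
        half_period = (hi - lo) / 0.5  # relative speed 0.5
        gaps = np.diff(times)
        # first gap is a partial traversal; all later gaps are full wall-to-wall
        assert np.allclose(gaps[1:], half_period, atol=1e-8)

    def test_single_pair_beyond_cutoff_never_collides(self):
        from cldmd.forcefield import build_chain

        model = build_chain("GG")
        st = initial_state(model, T=0.5, seed=0)
        st.positions = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]])
        st.velocities = np.zeros((2, 3))
        st.shells = None
        with pytest.raises(RuntimeError, match="no events"):
            run_md(st, 0.5, 10, sample_every=1, seed=0, ghost_rate=0.0)


class TestConservation:
    def test_energy_conserved_without_thermostat(self, small_model):
        st = initial_state(small_model, T=0.5, seed=3)
        e0 = kinetic_energy(st.velocities, small_model.masses) + \
            total_potential_energy(st.positions, small_model)
        st2, traj = run_md(st, 0.5, 1000, sample_every=1, seed=4,
                           ghost_rate=0.0, audit_every=100)
        total = traj.kinetic + traj.energies
        assert np.max(np.abs(total - e0)) / max(1.0, abs(e0)) < 1e-8
        assert traj.max_audit_error < 1e-6

    def test_momentum_conserved_exactly(self, small_model):
        st = initial_state(small_model, T=0.5, seed=5)
        p0 = st.velocities.sum(axis=0)
        st2, _ = run_md(st, 0.5, 2000, sample_every=0, seed=6, ghost_rate=0.0)
        p1 = st2.velocities.sum(axis=0)
        assert np.allclose(p0, p1, atol=1e-12)

    def test_no_tunneling_through_hard_cores(self, small_model):
        st = initial_state(small_model, T=0.6, seed=7)
        st2, traj = run_md(st, 0.6, 20_000, sample_every=500, seed=8)
        for frame in traj.positions:
            d = np.linalg.norm(frame[:, None] - frame[None, :], axis=2)
            n = len(frame)
            for i in range(n):
                for j in range(i + 3, n):
                    assert d[i, j] > 4.0 - 1e-9

    def test_incremental_energy_matches_recompute(self, small_model):
        st = initial_state(small_model, T=0.5, seed=9)
        _, traj = run_md(st, 0.5, 5000, sample_every=100, seed=10,
                         audit_every=100)
        assert traj.max_audit_error < 1e-6
        # frame energies agree with from-scratch recomputation
        k = len(traj) // 2
        e = total_potential_energy(traj.positions[k], small_model)
        assert traj.energies[k] == pytest.approx(e, abs=1e-6)


class TestDeterminismAndThermostat:
    def test_same_seed_bitwise_identical(self, small_model):
        runs = []
        for _ in range(2):
            st = initial_state(small_model, T=0.5, seed=11)
            _, traj = run_md(st, 0.5, 3000, sample_every=50, seed=12)
            runs.append(traj)
        assert np.array_equal(runs[0].positions, runs[1].positions)
        assert np.array_equal(runs[0].energies, runs[1].energies)

    def test_ghost_collision_distribution(self):
        rng = np.random.default_rng(99)
        draws = np.array(
            [ghost_collision(None, 0.5, 1.0, rng) for _ in range(35_000)]
        )
        # component mean ~ 0 within 4 sigma of the mean estimator
        sigma = math.sqrt(0.5)
        assert np.all(
            np.abs(draws.mean(axis=0)) < 4 * sigma / math.sqrt(len(draws))
        )
        assert draws.var() == pytest.approx(0.5, rel=0.02)

    def test_ghost_collision_zero_temperature(self):
        rng = np.random.default_rng(0)
        assert np.allclose(ghost_collision(None, 0.0, 1.0, rng), 0.0)

    def test_long_run_kinetic_energy_thermalizes(self, small_model):
        """Canonical contract: time-averaged <KE>/bead -> (3/2) T.

        Kinetic energy is constant between events, so with one frame per
        event the duration-weighted frame average is the exact time
        average (event-count averages would overweight fast states).
        """
        T = 0.5
        st = initial_state(small_model, T=T, seed=13)
        st, traj = run_md(st, T, 80_000, sample_every=1, seed=13,
                          ghost_rate=0.5)
        dt = np.diff(traj.times)
        ke_mean = float(np.sum(traj.kinetic[:-1] * dt) / np.sum(dt)) / 10
        assert ke_mean == pytest.approx(1.5 * T, rel=0.02)

    def test_hydrophobic_homopolymer_collapses(self, hydrophobic_model):
        from cldmd.ensemble import radius_of_gyration

        st = initial_state(hydrophobic_model, T=0.3, seed=14)
        rg0 = radius_of_gyration(st.positions)
        st2, _ = run_md(st, 0.3, 40_000, sample_every=0, seed=15)
        assert radius_of_gyration(st2.positions) < rg0

    def test_overlapping_initial_state_rejected(self, small_model):
        st = initial_state(small_model, T=0.5, seed=16)
        st.positions[5] = st.positions[0] + np.array([1.0, 0.0, 0.0])
        st.shells = None
        with pytest.raises(ValueError, match="overlap"):
            run_md(st, 0.5, 100, seed=17)


class TestRandomCoil:
    def test_geometry_contract(self):
        coords = random_coil(30, seed=21)
        bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        assert np.allclose(bonds, 3.8, atol=1e-9)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        for i in range(30):
            for j in range(i + 3, 30):
                assert d[i, j] >= 4.0

    def test_seeded_determinism(self):
        assert np.array_equal(random_coil(25, seed=2), random_coil(25, seed=2))
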