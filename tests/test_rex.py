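"""Replica exchange, WHAM density of states and heat capacity."""

import math

import numpy as np
import pytest

from cldmd.rex import (
    DensityOfStates,
    ExchangeLog,
    heat_capacity,
    make_ladder,
    metropolis_swap,
    mixing_report,
    run_rex,
    wham,
)


class TestLadder:
    def test_production_ladder_spacing(self):
        ladder = make_ladder(0.375, 0.605, 24)
        assert len(ladder) == 24
        assert np.allclose(np.diff(ladder), 0.01)
        assert ladder[0] == 0.375 and ladder[-1] == 0.605

    def test_two_rungs(self):
        assert make_ladder(1.0, 2.0, 2).tolist() == [1.0, 2.0]

    def test_single_rung_rejected(self):
        with pytest.raises(ValueError):
            make_ladder(1.0, 2.0, 1)


class TestMetropolis:
    def test_equal_energies_always_accept(self):
        assert metropolis_swap(-5.0, 0.4, -5.0, 0.5, u=0.999999)

    def test_downhill_always_accept(self):
        # the colder rung holds the higher energy: swapping restores the
        # energy-temperature ordering, so the move is always accepted
        assert metropolis_swap(-2.0, 0.4, -10.0, 0.5, u=0.999999)

    def test_equal_temperatures_rejected(self):
        with pytest.raises(ValueError):
            metropolis_swap(0.0, 0.5, 1.0, 0.5, 0.5)

    def test_empirical_rate_matches_closed_form(self):
        """Already-ordered case (cold rung holds the lower energy):
        acceptance equals the exponential factor."""
        rng = np.random.default_rng(42)
        E_a, T_a, E_b, T_b = -6.0, 0.4, -4.0, 0.5
        arg = (1 / T_a - 1 / T_b) * (E_a - E_b)
        expected = math.exp(arg)
        assert arg < 0
        n = 100_000
        hits = sum(
            metropolis_swap(E_a, T_a, E_b, T_b, u)
            for u in rng.random(n)
        )
        rate = hits / n
        sigma = math.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) < 3 * sigma


class TestRunRex:
    def test_fixed_seed_identical_logs(self, small_model):
        logs = []
        for _ in range(2):
            res = run_rex(small_model, [], make_ladder(0.4, 0.5, 3),
                          n_steps=3000, exchange_every=500, seed=5,
                          sample_every=250)
            logs.append(res.log.to_frame())
        assert logs[0].equals(logs[1])

    def test_exchange_period_beyond_run_logs_nothing(self, small_model):
        res = run_rex(small_model, [], make_ladder(0.4, 0.5, 2),
                      n_steps=500, exchange_every=1000, seed=5,
                      sample_every=100)
        assert len(res.log.to_frame()) == 0

    def test_adjacent_replicas_mix(self, small_model):
        res = run_rex(small_model, [], make_ladder(0.45, 0.46, 2),
                      n_steps=20_000, exchange_every=500, seed=6,
                      sample_every=500)
        # nearly equal temperatures: swaps accept readily, both replicas
        # must visit both rungs
        occ = res.rung_of_replica
        for rep in range(2):
            assert set(occ[:, rep]) == {0, 1}

    def test_acceptance_rates_in_open_interval(self, small_model):
        res = run_rex(small_model, [], make_ladder(0.4, 0.6, 4),
                      n_steps=20_000, exchange_every=500, seed=7,
                      sample_every=500)
        rep = mixing_report(res.log, n_replicas=4)
        rates = rep["acceptance"]["acceptance"]
        assert ((rates > 0) & (rates < 1)).all()

    def test_production_frames_drop_equilibration(self, small_model):
        res = run_rex(small_model, [], make_ladder(0.4, 0.5, 2),
                      n_steps=6000, exchange_every=1000, seed=8,
                      sample_every=500)
        per_replica = len(res.trajectories[0])
        expected = 2 * (per_replica - per_replica // 3)
        assert len(res.production_frames()) == expected


def _two_level_counts(rng, temps, n_samples, g1=100.0, gap=2.0):
    """Exact Boltzmann sampling of a two-level system (E = 0 or gap)."""
    centers = np.array([0.0, gap])
    counts = np.zeros((len(temps), 2))
    for k, T in enumerate(temps):
        p1 = g1 * math.exp(-gap / T)
        p1 = p1 / (1.0 + p1)
        counts[k, 1] = rng.binomial(n_samples, p1)
        counts[k, 0] = n_samples - counts[k, 1]
    return centers, counts


class TestWham:
    def test_single_temperature_limit(self):
        # with one histogram, rho(E) ∝ n(E) exp(E/T)
        centers = np.array([0.0, 1.0, 2.0])
        counts = np.array([[100.0, 50.0, 10.0]])
        dos = wham(centers, counts, [0.5])
        expected = np.log(counts[0]) + centers / 0.5
        expected -= expected[0]
        assert np.allclose(dos.log_density, expected, atol=1e-6)

    def test_two_level_recovers_degeneracy_ratio(self, rng):
        centers, counts = _two_level_counts(rng, [0.5, 1.0, 2.0], 100_000)
        dos = wham(centers, counts, [0.5, 1.0, 2.0])
        ratio = dos.log_density[1] - dos.log_density[0]
        assert abs(ratio - math.log(100.0)) < 0.05

    def test_zero_tolerance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            wham(np.array([0.0]), np.array([[5.0]]), [0.5], tol=0.0)

    def test_disjoint_histograms_rejected(self):
        centers = np.array([0.0, 1.0, 5.0, 6.0])
        counts = np.array([[10.0, 5.0, 0.0, 0.0],
                           [0.0, 0.0, 5.0, 10.0]])
        with pytest.raises(ValueError, match="rungs 0 and 1"):
            wham(centers, counts, [0.4, 0.6])


class TestHeatCapacity:
    def test_schottky_peak_position(self, rng):
        """Cv peak of the recovered two-level system sits at the analytic
        Schottky temperature (within the evaluation grid resolution)."""
        g1, gap = 100.0, 2.0
        T_grid = np.linspace(0.1, 3.0, 581)

        def analytic_cv(T):
            w = g1 * np.exp(-gap / T)
            p = w / (1 + w)
            return (gap / T) ** 2 * p * (1 - p)

        t_star = T_grid[np.argmax(analytic_cv(T_grid))]
        centers, counts = _two_level_counts(rng, [0.2, 0.4, 0.8], 200_000,
                                            g1, gap)
        dos = wham(centers, counts, [0.2, 0.4, 0.8])
        cv = heat_capacity(dos, T_grid)
        t_peak = float(cv.loc[cv["Cv"].idxmax(), "T"])
        grid_step = T_grid[1] - T_grid[0]
        assert abs(t_peak - t_star) <= 3 * grid_step

    def test_single_energy_level_gives_zero(self):
        dos = DensityOfStates(np.array([1.0]), np.array([0.0]),
                              np.zeros(1), np.array([0.5]))
        cv = heat_capacity(dos, [0.3, 0.5, 1.0])
        assert np.allclose(cv["Cv"], 0.0)

    def test_nonnegative_everywhere(self, rng):
        centers = np.linspace(-3, 3, 13)
        log_rho = rng.normal(0, 1, 13)
        dos = DensityOfStates(centers, log_rho, np.zeros(1), np.array([0.5]))
        cv = heat_capacity(dos, np.linspace(0.2, 2.0, 19))
        assert (cv["Cv"] >= 0).all()


class TestMixingReport:
    def test_zero_accepts_single_rung_each(self):
        log = ExchangeLog()
        for t in range(10):
            log.add(t, 0, 1, 0, 1, -1.0, -2.0, 0.4, 0.5, False)
        rep = mixing_report(log, n_replicas=2)
        visits = rep["rung_visits"]
        assert visits[0, 1] == 0 and visits[1, 0] == 0

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            mixing_report(ExchangeLog())

    def test_low_acceptance_flagged(self):
        log = ExchangeLog()
        for t in range(100):
            log.add(t, 0, 1, 0, 1, -1.0, -2.0, 0.4, 0.5, t == 0)
        rep = mixing_report(log, n_replicas=2)
        assert (0, 1) in rep["low_acceptance_pairs"]
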