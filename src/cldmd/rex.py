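"""Temperature replica exchange around the DMD engine, plus WHAM.

Replicas run independently at the rungs of a temperature ladder and
periodically attempt Metropolis swaps between adjacent rungs, letting cold
replicas borrow barrier-crossing ability from hot ones.  Swaps exchange
*temperatures* (with velocity rescaling), which is bookkeeping-equivalent
to exchanging configurations.  The energy histograms accumulated across
rungs are combined by the Weighted Histogram Analysis Method into a single
density of states, from which the heat-capacity curve — the convergence
diagnostic — follows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SystemState, Trajectory, build_pair_tables, run_md


def make_ladder(t_min: float, t_max: float, n: int) -> np.ndarray:
    """Arithmetic temperature ladder, endpoints included.

    The default production ladder is 24 rungs equally spaced on
    [0.375, 0.605] kcal/(mol·k_B).
    """
    if n < 2:
        raise ValueError("a ladder needs at least 2 rungs")
    if not t_min < t_max:
        raise ValueError("require t_min < t_max")
    return np.linspace(t_min, t_max, n)


DEFAULT_LADDER = make_ladder(0.375, 0.605, 24)


def metropolis_swap(
    E_a: float, T_a: float, E_b: float, T_b: float, u: float
) -> bool:
    """Accept a temperature swap iff u < min(1, exp[(1/T_a − 1/T_b)(E_a − E_b)])."""
    if T_a == T_b:
        raise ValueError("swap partners must differ in temperature")
    arg = (1.0 / T_a - 1.0 / T_b) * (E_a - E_b)
    return u < min(1.0, math.exp(min(arg, 0.0)) if arg < 0 else 1.0)


@dataclass
class ExchangeLog:
    """Record of every swap attempt between adjacent ladder rungs."""

    attempts: list = field(default_factory=list)

    def add(self, time, rung_a, rung_b, rep_a, rep_b, E_a, E_b, T_a, T_b,
            accepted):
        self.attempts.append(
            dict(time=time, rung_a=rung_a, rung_b=rung_b,
                 replica_a=rep_a, replica_b=rep_b,
                 E_a=E_a, E_b=E_b, T_a=T_a, T_b=T_b, accepted=accepted)
        )

    def to_frame(self) -> pd.DataFrame:
        cols = ["time", "rung_a", "rung_b", "replica_a", "replica_b",
                "E_a", "E_b", "T_a", "T_b", "accepted"]
        return pd.DataFrame(self.attempts, columns=cols)


@dataclass
class RexResult:
    trajectories: list[Trajectory]     # per replica, concatenated segments
    rung_of_replica: np.ndarray        # (rounds+1, n_replicas) rung indices
    log: ExchangeLog
    ladder: np.ndarray
    equilibration_fraction: float = 1.0 / 3.0

    def production_frames(self) -> list[tuple[np.ndarray, float, float]]:
        """(coords, energy, temperature) for post-equilibration frames."""
        out = []
        for traj in self.trajectories:
            n = len(traj)
            start = int(math.floor(self.equilibration_fraction * n))
            for k in range(start, n):
                out.append(
                    (traj.positions[k], float(traj.energies[k]),
                     traj.temperature)
                )
        return out


def _segment_seed(seed: int, replica: int, segment: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(replica), int(segment)])
    return int(ss.generate_state(1)[0] % 2**31)


def run_rex(
    model,
    wells,
    ladder=None,
    n_steps: int = 60_000,
    exchange_every: int = 1_000,
    seed: int = 0,
    sample_every: int = 200,
    ghost_rate: float = 0.1,
    start_coords: np.ndarray | None = None,
    equilibration_fraction: float = 1.0 / 3.0,
) -> RexResult:
    """Replica-exchange DMD from an unfolded start.

    Each replica runs ``n_steps`` events total, attempting swaps every
    ``exchange_every`` events between alternating even/odd adjacent rung
    pairs.  On acceptance the two replicas trade temperatures and rescale
    velocities by sqrt(T_new/T_old).  Fully reproducible under ``seed``.

    Per-replica trajectories are tagged per frame with the replica's rung
    temperature at sampling time; the first ``equilibration_fraction`` of
    frames is flagged as equilibration by :meth:`RexResult.production_frames`.
    """
    ladder = DEFAULT_LADDER if ladder is None else np.asarray(ladder, float)
    n_rep = len(ladder)
    tables = build_pair_tables(model, wells)
    swap_rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 0xE5C4A9])
    )

    # replica r starts on rung r; with no start structure given, each
    # replica begins from its own unfolded random coil so the ladder
    # carries independent folding attempts
    from .engine import initial_state, random_coil

    rung = np.arange(n_rep)
    states = []
    for r in range(n_rep):
        coords = (
            random_coil(model.n_residues, seed=_segment_seed(seed, r, 777))
            if start_coords is None
            else start_coords
        )
        st = initial_state(
            model, wells, T=float(ladder[rung[r]]),
            seed=_segment_seed(seed, r, 0), coords=coords,
        )
        states.append(st)

    n_rounds = n_steps // exchange_every
    # a final partial segment (or the whole run, if shorter than one
    # exchange period) propagates without a swap attempt afterwards
    segments = [exchange_every] * n_rounds
    if n_steps - n_rounds * exchange_every > 0:
        segments.append(n_steps - n_rounds * exchange_every)
    trajs: list[Trajectory | None] = [None] * n_rep
    occupancy = np.empty((len(segments) + 1, n_rep), dtype=int)
    occupancy[0] = rung
    log = ExchangeLog()
    energies = np.zeros(n_rep)

    for seg, seg_steps in enumerate(segments):
        for r in range(n_rep):
            states[r], traj = run_md(
                states[r], float(ladder[rung[r]]), seg_steps,
                sample_every=sample_every,
                seed=_segment_seed(seed, r, seg + 1),
                ghost_rate=ghost_rate, _tables=tables,
            )
            trajs[r] = traj if trajs[r] is None else trajs[r].concat(traj)
            energies[r] = traj.energies[-1] if len(traj) else np.nan
        if math.isnan(energies[0]):
            # sample_every > exchange_every: fall back to a fresh energy
            from .forcefield import total_potential_energy

            for r in range(n_rep):
                energies[r] = total_potential_energy(
                    states[r].positions, model, wells
                )
        if seg >= n_rounds:
            occupancy[seg + 1] = rung
            continue  # partial tail segment: no swap attempt
        # alternate even/odd adjacent rung pairs
        start = 0 if seg % 2 == 0 else 1
        rep_on_rung = np.argsort(rung)
        for k in range(start, n_rep - 1, 2):
            ra, rb = int(rep_on_rung[k]), int(rep_on_rung[k + 1])
            Ta, Tb = float(ladder[k]), float(ladder[k + 1])
            Ea, Eb = float(energies[ra]), float(energies[rb])
            u = float(swap_rng.random())
            acc = metropolis_swap(Ea, Ta, Eb, Tb, u)
            log.add(states[ra].time, k, k + 1, ra, rb, Ea, Eb, Ta, Tb, acc)
            if acc:
                rung[ra], rung[rb] = k + 1, k
                states[ra].velocities *= math.sqrt(Tb / Ta)
                states[rb].velocities *= math.sqrt(Ta / Tb)
        occupancy[seg + 1] = rung

    return RexResult(
        [t for t in trajs if t is not None],
        occupancy, log, ladder, equilibration_fraction,
    )


# ---------------------------------------------------------------------------
# WHAM

@dataclass
class DensityOfStates:
    """log density of states on an energy grid, anchored at its minimum bin."""

    energies: np.ndarray        # bin centers
    log_density: np.ndarray
    free_energies: np.ndarray   # per-temperature shifts f_k at convergence
    temperatures: np.ndarray


def energy_histograms(
    frames_energy_T: list[tuple[float, float]],
    ladder,
    bin_width: float | None = None,
):
    """Per-rung energy histograms on a common grid (Freedman–Diaconis)."""
    ladder = np.asarray(ladder, float)
    E = np.array([e for e, _ in frames_energy_T])
    T = np.array([t for _, t in frames_energy_T])
    if bin_width is None:
        q75, q25 = np.percentile(E, [75, 25])
        iqr = q75 - q25
        bin_width = 2 * iqr / max(1.0, len(E) ** (1 / 3))
        if bin_width <= 0:
            bin_width = max(1e-6, (E.max() - E.min()) / 50 or 1e-6)
    lo, hi = E.min() - 0.5 * bin_width, E.max() + 0.5 * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts = np.zeros((len(ladder), len(edges) - 1))
    for k, Tk in enumerate(ladder):
        counts[k] = np.histogram(E[np.isclose(T, Tk)], bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def wham(
    centers: np.ndarray,
    counts: np.ndarray,
    ladder,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> DensityOfStates:
    """Self-consistent WHAM solution for the density of states.

        ρ(E) = Σ_k n_k(E) / Σ_k N_k exp[(f_k − E)/T_k]
        f_k  = −T_k ln Σ_E ρ(E) exp(−E/T_k)

    Iterated in log space until max |Δf_k| < tol.  Requires overlapping
    histogram support between adjacent rungs; a support gap is rejected
    with the offending rung pair named.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    ladder = np.asarray(ladder, float)
    counts = np.asarray(counts, float)
    centers = np.asarray(centers, float)
    if counts.shape != (len(ladder), len(centers)):
        raise ValueError("counts must be (n_temperatures, n_bins)")
    occupied = counts > 0
    if len(ladder) > 1:
        for k in range(len(ladder) - 1):
            if not np.any(occupied[k] & occupied[k + 1]):
                raise ValueError(
                    f"energy histograms of rungs {k} and {k + 1} share no "
                    "support; WHAM cannot bridge the gap"
                )
    N_k = counts.sum(axis=1)
    n_E = counts.sum(axis=0)
    support = n_E > 0
    beta = 1.0 / ladder

    f = np.zeros(len(ladder))
    log_nE = np.where(support, np.log(np.maximum(n_E, 1e-300)), -np.inf)
    for _ in range(max_iter):
        # log ρ(E) = log Σ_k n_k(E) − logsumexp_k[ log N_k + (f_k − E)/T_k ]
        with np.errstate(divide="ignore"):
            log_den = _logsumexp(
                np.log(np.maximum(N_k, 1e-300))[:, None]
                + (f[:, None] - centers[None, :]) * beta[:, None],
                axis=0,
            )
        log_rho = np.where(support, log_nE - log_den, -np.inf)
        new_f = -ladder * _logsumexp(
            log_rho[None, :] - centers[None, :] * beta[:, None], axis=1
        )
        new_f -= new_f[0]
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta < tol:
            break
    log_rho = log_rho - log_rho[support].max()
    anchor = np.argmax(support)  # lowest occupied bin
    log_rho = log_rho - log_rho[anchor]
    return DensityOfStates(centers[support], log_rho[support], f, ladder)


def _logsumexp(a, axis):
    amax = np.max(a, axis=axis, keepdims=True)
    amax = np.where(np.isfinite(amax), amax, 0.0)
    out = np.log(np.sum(np.exp(a - amax), axis=axis)) + np.squeeze(amax, axis)
    return out


def heat_capacity(dos: DensityOfStates, T_grid) -> pd.DataFrame:
    """Cv(T) = (⟨E²⟩ − ⟨E⟩²)/T² with moments under ρ(E)e^{−E/T}."""
    T_grid = np.asarray(T_grid, float)
    rows = []
    for T in T_grid:
        logw = dos.log_density - dos.energies / T
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        e1 = float(w @ dos.energies)
        e2 = float(w @ dos.energies**2)
        rows.append({"T": T, "Cv": max(0.0, (e2 - e1 * e1)) / (T * T)})
    return pd.DataFrame(rows)


def mixing_report(log: ExchangeLog, n_replicas: int | None = None) -> dict:
    """Rung-occupancy histogram per replica and per-pair acceptance rates.

    Flags adjacent rung pairs whose swap acceptance is below 5% — the sign
    of a ladder too sparse for its energy distributions to overlap.
    """
    df = log.to_frame()
    if len(df) == 0:
        raise ValueError("empty exchange log")
    pair_stats = (
        df.groupby(["rung_a", "rung_b"])["accepted"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "acceptance"})
    )
    flagged = [
        tuple(map(int, idx))
        for idx, row in pair_stats.iterrows()
        if row["acceptance"] < 0.05
    ]
    # reconstruct rung visits per replica from the attempt stream
    n_rep = n_replicas or int(
        max(df["replica_a"].max(), df["replica_b"].max()) + 1
    )
    rung = np.arange(n_rep)
    visits = np.zeros((n_rep, n_rep), dtype=int)
    for row in df.itertuples(index=False):
        if row.accepted:
            ra, rb = int(row.replica_a), int(row.replica_b)
            rung[ra], rung[rb] = rung[rb], rung[ra]
        visits[np.arange(n_rep), rung] += 1
    return {
        "acceptance": pair_stats,
        "low_acceptance_pairs": flagged,
        "rung_visits": visits,
    }
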