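"""Event-driven discrete molecular dynamics for step-potential chains.

Between events every bead flies ballistically; at an event a single pair
exchanges momentum along its line of centers according to energy and
momentum conservation (transmission over, or reflection off, a potential
step).  An Andersen-style thermostat ("ghost collisions") resamples a
random bead's velocity from the Maxwell–Boltzmann distribution at Poisson
times, making long runs canonical at the requested temperature.

Units: Å, kcal/mol, bead masses of 1, k_B = 1 — temperatures are in
kcal/(mol·k_B), velocities in Å per DMD time unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .constraints import ConstraintWell
from .forcefield import ChainModel

DEFAULT_GHOST_RATE = 0.1  # thermostat collisions per bead per time unit


# ---------------------------------------------------------------------------
# elementary event algebra (pure-python mirrors of the kernel logic)

def predict_boundary_time(rel_pos, rel_vel, d: float) -> float | None:
    """Earliest positive time at which |rel_pos + t rel_vel| = d, else None.

    Roots of the quadratic a t² + 2 b t + c = 0 with a = v·v, b = r·v,
    c = r·r − d².  The pair must not sit exactly on the boundary.
    """
    r = np.asarray(rel_pos, dtype=float)
    v = np.asarray(rel_vel, dtype=float)
    a = float(v @ v)
    if a == 0.0:
        return None
    b = float(r @ v)
    c = float(r @ r) - d * d
    disc = b * b - a * c
    if disc < 0.0:
        return None
    sq = math.sqrt(disc)
    roots = sorted(((-b - sq) / a, (-b + sq) / a))
    for t in roots:
        if t > 0.0:
            return t
    return None


def resolve_crossing(mu: float, v_r: float, dU: float) -> tuple[float, bool]:
    """Radial relative speed after meeting an energy step of height dU.

    Transmits (sign preserved, speed from the energy balance
    ½ μ v_r'² = ½ μ v_r² − ΔU) when the radial kinetic energy exceeds the
    step, otherwise reflects elastically.  Returns ``(v_r', transmitted)``.
    """
    if mu <= 0:
        raise ValueError("reduced mass must be positive")
    ke = 0.5 * mu * v_r * v_r
    if math.isinf(dU) or ke <= dU:
        return -v_r, False
    v_new = math.sqrt(v_r * v_r - 2.0 * dU / mu)
    return math.copysign(v_new, v_r) if v_r != 0 else v_new, True


def ghost_collision(vel, T: float, m: float, rng: np.random.Generator):
    """Resample a bead velocity from Maxwell–Boltzmann at temperature T."""
    if T < 0:
        raise ValueError("temperature must be non-negative")
    if T == 0:
        return np.zeros(3)
    return rng.normal(0.0, math.sqrt(T / m), size=3)


# ---------------------------------------------------------------------------
# pair-table compilation

def build_pair_tables(model: ChainModel, wells: list[ConstraintWell] | None):
    """Flatten the per-pair step potentials into padded kernel arrays.

    A crosslinked nonbonded pair is governed by the *sum* of its nonbonded
    potential and its constraint well; the boundaries are merged and the
    region energies added.
    """
    n = model.n_residues
    well_map: dict[tuple[int, int], list[ConstraintWell]] = {}
    for w in wells or []:
        well_map.setdefault((w.res_i - 1, w.res_j - 1), []).append(w)

    pair_pots = []
    for i in range(n):
        for j in range(i + 1, n):
            pot = model.pair_potential(i, j)
            radii = list(pot.radii)
            energies = list(pot.energies)
            for w in well_map.get((i, j), ()):
                radii, energies = _merge_step(radii, energies, w)
            pair_pots.append((radii, energies))

    maxb = max(len(r) for r, _ in pair_pots)
    npairs = len(pair_pots)
    radii2d = np.full((npairs, maxb), np.inf)
    U2d = np.zeros((npairs, maxb + 1))
    nb = np.zeros(npairs, dtype=np.int64)
    for p, (radii, energies) in enumerate(pair_pots):
        nb[p] = len(radii)
        radii2d[p, : len(radii)] = radii
        U2d[p, : len(energies)] = energies
    return radii2d, U2d, nb


def _merge_step(radii, energies, well: ConstraintWell):
    """Add a flat-bottom well (0 inside r_hi, penalty outside) to a step fn."""
    new_radii = sorted(set(radii) | {well.r_hi})
    new_energies = []
    bounds = [0.0, *new_radii]
    for k in range(len(new_radii) + 1):
        lo = bounds[k]
        mid = lo + 1e-9 if k == len(new_radii) else 0.5 * (lo + bounds[k + 1])
        base_idx = int(np.searchsorted(radii, mid, side="right"))
        base = energies[base_idx]
        extra = well.penalty if mid > well.r_hi else 0.0
        new_energies.append(base + extra)
    return new_radii, new_energies


# ---------------------------------------------------------------------------
# system state and trajectories

@dataclass
class SystemState:
    """Positions, velocities and bookkeeping for one replica."""

    positions: np.ndarray
    velocities: np.ndarray
    model: ChainModel
    wells: list[ConstraintWell] = field(default_factory=list)
    temperature: float = 0.45
    time: float = 0.0
    #: tracked per-pair shell indices; carried across engine calls so that
    #: pairs resting numerically on a boundary are never misclassified
    shells: np.ndarray | None = None

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            self.model,
            list(self.wells),
            self.temperature,
            self.time,
            None if self.shells is None else self.shells.copy(),
        )


@dataclass
class Trajectory:
    """Frame snapshots at a fixed event-sampling interval."""

    positions: np.ndarray        # (frames, n, 3)
    energies: np.ndarray         # potential energy per frame
    times: np.ndarray
    temperature: float
    kinetic: np.ndarray | None = None
    max_audit_error: float = 0.0

    def __len__(self) -> int:
        return self.positions.shape[0]

    def concat(self, other: "Trajectory") -> "Trajectory":
        return Trajectory(
            np.concatenate([self.positions, other.positions]),
            np.concatenate([self.energies, other.energies]),
            np.concatenate([self.times, other.times]),
            other.temperature,
            (None if self.kinetic is None or other.kinetic is None
             else np.concatenate([self.kinetic, other.kinetic])),
            max(self.max_audit_error, other.max_audit_error),
        )


def extended_conformation(n: int, bond: float = 3.8) -> np.ndarray:
    """A planar zig-zag Cα trace: the maximally extended valid chain.

    Geometry keeps d(i,i+1) = bond and d(i,i+2) = 6.0 Å, inside the
    pseudo-angle window, with all longer-range pairs clear of the 4 Å core.
    """
    a = 3.0
    h = math.sqrt(bond * bond - a * a)
    coords = np.zeros((n, 3))
    coords[:, 0] = a * np.arange(n)
    coords[1::2, 1] = h
    return coords


def random_coil(n: int, seed: int = 0, bond: float = 3.8) -> np.ndarray:
    """A seeded self-avoiding random coil: the "completely unfolded" start.

    Turn angles are drawn uniformly inside the pseudo-angle window and
    nonbonded pairs keep ≥ 4.2 Å clearance (backtracking on dead ends),
    so the coil is a valid unfolded configuration carrying no information
    about any particular fold.
    """
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    pos[1] = (bond, 0.0, 0.0)
    i = 2
    backtracks = 0
    while i < n:
        prev = pos[i - 1] - pos[i - 2]
        prev /= np.linalg.norm(prev)
        a = np.array([1.0, 0.0, 0.0])
        if abs(prev @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(prev, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(prev, e1)
        ok = False
        for _ in range(30):
            theta = rng.uniform(math.radians(40.0), math.radians(102.0))
            phi = rng.uniform(0.0, 2.0 * math.pi)
            step = bond * (
                math.cos(theta) * prev
                + math.sin(theta) * (math.cos(phi) * e1 + math.sin(phi) * e2)
            )
            cand = pos[i - 1] + step
            d2 = np.linalg.norm(cand - pos[i - 2])
            if not 4.6 <= d2 <= 7.2:
                continue
            if i >= 3 and np.linalg.norm(
                cand - pos[: i - 2], axis=1
            ).min() < 4.2:
                continue
            pos[i] = cand
            ok = True
            break
        if ok:
            i += 1
        else:
            i = max(2, i - 1)
            backtracks += 1
            if backtracks > 10_000:
                raise RuntimeError("random coil generation stalled")
    return pos


def maxwell_velocities(
    n: int, T: float, masses: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Maxwell–Boltzmann draw with the center-of-mass drift removed."""
    v = rng.normal(0.0, 1.0, size=(n, 3)) * np.sqrt(T / masses)[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v


def initial_state(
    model: ChainModel,
    wells: list[ConstraintWell] | None = None,
    T: float = 0.45,
    seed: int = 0,
    coords: np.ndarray | None = None,
) -> SystemState:
    rng = np.random.default_rng(seed)
    n = model.n_residues
    pos = (
        extended_conformation(n, model.params.bond_length)
        if coords is None
        else np.array(coords, dtype=float)
    )
    vel = maxwell_velocities(n, T, model.masses, rng)
    return SystemState(pos, vel, model, list(wells or []), T)


def run_md(
    state: SystemState,
    T: float,
    n_steps: int,
    sample_every: int = 100,
    seed: int = 0,
    ghost_rate: float = DEFAULT_GHOST_RATE,
    audit_every: int = 0,
    _tables=None,
) -> tuple[SystemState, Trajectory]:
    """Propagate ``n_steps`` events at temperature ``T``.

    Returns the advanced state plus the sampled trajectory.  Reproducible:
    the same seed and inputs give bitwise-identical trajectories.  Raises
    on hard-core overlaps in the initial state and on an event-less,
    thermostat-less system that cannot advance.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    state = state.copy()
    state.temperature = T
    radii2d, U2d, nb = (
        _tables
        if _tables is not None
        else build_pair_tables(state.model, state.wells)
    )
    pos = np.ascontiguousarray(state.positions, dtype=float)
    vel = np.ascontiguousarray(state.velocities, dtype=float)
    masses = state.model.masses.astype(float)

    if state.shells is not None and len(state.shells) == nb.shape[0]:
        shell = state.shells
        U0 = _kernel.potential_from_shells(shell, U2d)
    else:
        shell = _kernel.compute_shells(pos, radii2d, nb)
        U0 = _kernel.potential_from_shells(shell, U2d)
        if math.isinf(U0):
            bad = np.where(
                ~np.isfinite(U2d[np.arange(len(shell)), shell])
            )[0]
            raise ValueError(
                f"initial state has hard-core overlaps (pair index {bad[:3]})"
            )

    n_frames = n_steps // sample_every if sample_every > 0 else 0
    frames_pos = np.empty((n_frames, pos.shape[0], 3))
    frames_U = np.empty(n_frames)
    frames_t = np.empty(n_frames)
    frames_K = np.empty(n_frames)

    t_now, U_tot, got, max_audit, status = _kernel.run_segment(
        pos, vel, masses, radii2d, U2d, nb, shell,
        float(T), float(ghost_rate),
        int(n_steps), int(sample_every), int(audit_every),
        int(seed) % 2**31, float(state.time), U0,
        frames_pos, frames_U, frames_t, frames_K,
    )
    if status == _kernel.STALLED:
        raise RuntimeError(
            "no events can be scheduled (free system without thermostat)"
        )
    state.positions = pos
    state.velocities = vel
    state.time = t_now
    state.shells = shell
    traj = Trajectory(
        frames_pos[:got], frames_U[:got], frames_t[:got], T,
        frames_K[:got], max_audit,
    )
    return state, traj


def kinetic_energy(vel: np.ndarray, masses: np.ndarray) -> float:
    return float(0.5 * (masses[:, None] * vel * vel).sum())
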