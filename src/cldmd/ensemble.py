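"""Post-simulation ensemble analysis.

Implements the standard pipeline applied to the replica-exchange output:
rank all production frames by potential energy and keep the lowest 10%,
compute the pairwise Cα RMSD matrix, pick the clustering cutoff at the
peak of the pairwise-RMSD distribution, cluster with the greedy
neighbour-counting (Daura/GROMOS) algorithm, and characterize each
cluster by centroid, population, per-residue RMSF, contact and
contact-frequency maps and radius of gyration.  The unconstrained
relaxation run probes whether a constrained model is overfit: a structure
held together only by the crosslink wells expands once they are removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


# ---------------------------------------------------------------------------
# snapshot selection

@dataclass
class SnapshotSet:
    """Cα coordinate frames with per-frame potential energies."""

    coords: np.ndarray      # (m, n, 3)
    energies: np.ndarray    # (m,)
    sources: list = field(default_factory=list)  # provenance labels

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] != len(self.energies):
            raise ValueError("coords (m, n, 3) must match energies (m,)")
        if not self.sources:
            self.sources = list(range(len(self.energies)))

    def __len__(self) -> int:
        return self.coords.shape[0]


def select_low_energy(snapshots: SnapshotSet, fraction: float = 0.10
                      ) -> SnapshotSet:
    """Keep the floor(fraction · N) lowest-energy frames, stable in ties."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = max(1, math.floor(fraction * len(snapshots)))
    order = np.argsort(snapshots.energies, kind="stable")[:n_keep]
    order = np.sort(order)  # preserve frame order among the kept
    return SnapshotSet(
        snapshots.coords[order],
        snapshots.energies[order],
        [snapshots.sources[k] for k in order],
    )


# ---------------------------------------------------------------------------
# superposition & RMSD

def kabsch_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimal RMSD between conformations over proper rigid motions."""
    _, rmsd = kabsch_superpose(A, B)
    return rmsd


def kabsch_superpose(A: np.ndarray, B: np.ndarray):
    """Superpose ``A`` onto ``B``; returns (A aligned, RMSD).

    SVD-based Kabsch with the determinant sign correction, so only proper
    rotations are used (no reflections).
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("conformations must share shape (n, 3)")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    A_rot = A0 @ R.T
    rmsd = float(np.sqrt(((A_rot - B0) ** 2).sum() / A.shape[0]))
    return A_rot + cb, rmsd


def rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """Symmetric pairwise Kabsch RMSD matrix for a frame stack."""
    m = coords.shape[0]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = kabsch_rmsd(coords[i], coords[j])
    return out


def choose_cutoff(matrix: np.ndarray) -> float:
    """Clustering cutoff = mode of the pairwise-RMSD distribution.

    Histogram with Freedman–Diaconis bins over the upper triangle; ties
    resolve to the smallest modal bin center.  With exactly 2 structures
    the single pairwise RMSD is returned.
    """
    matrix = np.asarray(matrix, float)
    m = matrix.shape[0]
    if m < 2:
        raise ValueError("need at least 2 structures")
    vals = matrix[np.triu_indices(m, k=1)]
    if m == 2:
        return float(vals[0])
    if np.allclose(vals, vals[0]):
        return float(vals[0])
    q75, q25 = np.percentile(vals, [75, 25])
    width = 2 * (q75 - q25) / len(vals) ** (1 / 3)
    if width <= 0:
        return float(np.median(vals))
    n_bins = max(1, int(np.ceil((vals.max() - vals.min()) / width)))
    counts, edges = np.histogram(vals, bins=n_bins)
    mode_bin = int(np.argmax(counts))  # argmax takes the first (smallest) tie
    return float(0.5 * (edges[mode_bin] + edges[mode_bin + 1]))


# ---------------------------------------------------------------------------
# Daura (GROMOS) clustering

@dataclass
class Clustering:
    """Disjoint clusters ordered by size; populations relative to input."""

    clusters: list[list[int]]
    centroids: list[int]
    populations: list[float]
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def daura_cluster(matrix: np.ndarray, cutoff: float) -> Clustering:
    """Greedy neighbour-counting clustering on an RMSD matrix.

    Repeatedly take the structure with the most neighbours within
    ``cutoff`` (ties to the lowest index) as a centroid, remove it and its
    neighbours as one cluster, and recurse on the rest.  Clusters are
    reported largest-first; populations are fractions of the *input* size.
    """
    matrix = np.asarray(matrix, float)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    m = matrix.shape[0]
    if matrix.shape != (m, m):
        raise ValueError("matrix must be square")
    remaining = list(range(m))
    clusters, centroids = [], []
    while remaining:
        sub = matrix[np.ix_(remaining, remaining)]
        neigh_counts = (sub <= cutoff).sum(axis=1)  # includes self
        best = int(np.argmax(neigh_counts))         # first max = lowest index
        members_local = np.where(sub[best] <= cutoff)[0]
        members = [remaining[k] for k in members_local]
        clusters.append(sorted(members))
        centroids.append(remaining[best])
        remaining = [k for k in remaining if k not in set(members)]
    order = sorted(
        range(len(clusters)),
        key=lambda c: (-len(clusters[c]), clusters[c][0]),
    )
    clusters = [clusters[c] for c in order]
    centroids = [centroids[c] for c in order]
    pops = [len(c) / m for c in clusters]
    return Clustering(clusters, centroids, pops, float(cutoff))


# ---------------------------------------------------------------------------
# per-cluster descriptors

def rmsf(member_coords: np.ndarray, centroid_coords: np.ndarray) -> np.ndarray:
    """Per-residue RMS displacement about the centroid after superposition."""
    member_coords = np.asarray(member_coords, float)
    if member_coords.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 members")
    sq = np.zeros(centroid_coords.shape[0])
    for frame in member_coords:
        aligned, _ = kabsch_superpose(frame, centroid_coords)
        sq += ((aligned - centroid_coords) ** 2).sum(axis=1)
    return np.sqrt(sq / member_coords.shape[0])


def contact_map(coords: np.ndarray, cutoff: float = 8.0,
                min_separation: int = 3) -> np.ndarray:
    """Binary Cα contact map: d ≤ cutoff (inclusive), |i−j| ≥ min_separation.

    The near-diagonal band is excluded — consecutive beads of a Cα trace
    are trivially within 8 Å.
    """
    coords = np.asarray(coords, float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    cmap = (d <= cutoff).astype(float)
    n = coords.shape[0]
    idx = np.arange(n)
    band = np.abs(idx[:, None] - idx[None, :]) < min_separation
    cmap[band] = 0.0
    return cmap


def contact_frequency(member_coords: np.ndarray, cutoff: float = 8.0
                      ) -> np.ndarray:
    """Mean of member binary contact maps — how often each contact forms."""
    member_coords = np.asarray(member_coords, float)
    maps = [contact_map(c, cutoff) for c in member_coords]
    return np.mean(maps, axis=0)


def fraction_native_contacts(coords: np.ndarray, native: np.ndarray,
                             cutoff: float = 8.0) -> float:
    """Q: fraction of the native map's contacts present in ``coords``."""
    nat = contact_map(native, cutoff)
    got = contact_map(coords, cutoff)
    n_native = nat.sum()
    if n_native == 0:
        return float("nan")
    return float((nat * got).sum() / n_native)


def radius_of_gyration(coords: np.ndarray) -> float:
    """RMS distance of beads from their centroid (uniform masses)."""
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one point")
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c * c).sum() / coords.shape[0]))


# ---------------------------------------------------------------------------
# overfit probe: unconstrained relaxation

def relax_unconstrained(
    centroid_coords: np.ndarray,
    model,
    T: float = 0.45,
    n_steps: int = 20_000,
    discard: int = 5_000,
    sample_every: int = 100,
    seed: int = 0,
):
    """Relax a constrained model with all crosslink wells removed.

    Runs plain DMD at the stated temperature, discards the first
    ``discard`` events as equilibration and reports the Rg trace of the
    remainder plus the expansion ratio mean(Rg)/Rg(start).  A model that
    was held together only by the constraint wells balloons here.
    """
    if discard >= n_steps:
        raise ValueError("discard must be smaller than n_steps")
    from .engine import initial_state, run_md

    st = initial_state(model, wells=None, T=T, seed=seed,
                       coords=centroid_coords)
    rg0 = radius_of_gyration(centroid_coords)
    _, traj = run_md(st, T, n_steps, sample_every=sample_every, seed=seed)
    n_discard = discard // sample_every
    rg_trace = np.array(
        [radius_of_gyration(c) for c in traj.positions[n_discard:]]
    )
    return {
        "rg_initial": rg0,
        "rg_trace": rg_trace,
        "rg_mean": float(rg_trace.mean()),
        "rg_std": float(rg_trace.std()),
        "expansion_ratio": float(rg_trace.mean() / rg0),
    }
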