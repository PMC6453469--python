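"""End-to-end orchestration: fold → select → cluster → characterize → validate.

This is the programmatic surface the command line wraps: each function
takes and returns plain package objects so the stages compose in scripts
and tests without touching disk.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import constraints as xl
from . import ensemble as ens
from . import validation as val
from .forcefield import ChainModel
from .io import RunConfig
from .rex import RexResult, make_ladder, run_rex

logger = logging.getLogger(__name__)


@dataclass
class ClusterSummary:
    members: list[int]
    centroid_index: int
    centroid_coords: np.ndarray
    population: float
    rg: float
    rmsf: np.ndarray | None
    contact_frequency: np.ndarray


@dataclass
class EnsembleReport:
    """Clusters, maps and scalar descriptors of a folded ensemble."""

    clusters: list[ClusterSummary]
    cutoff: float
    n_selected: int
    n_total: int
    rg_values: np.ndarray              # Rg of every selected frame
    selected_energies: np.ndarray

    @property
    def populations(self) -> list[float]:
        return [c.population for c in self.clusters]

    def major_clusters(self, min_population: float = 0.05):
        return [c for c in self.clusters if c.population >= min_population]

    def member_weights(self):
        """(stacked member coords, population-proportional weights)."""
        coords, weights = [], []
        for c in self.clusters:
            coords.append(c.centroid_coords)
            weights.append(c.population)
        return np.stack(coords), np.array(weights) / np.sum(weights)


def fold(
    model: ChainModel,
    records: list[xl.CrosslinkRecord],
    config: RunConfig | None = None,
    seed: int | None = None,
    start_coords: np.ndarray | None = None,
) -> RexResult:
    """Replica-exchange CL-DMD run from an unfolded chain.

    Only constraint-role records become wells; validation records are
    kept away from the physics entirely.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    xl.check_indices(records, model.n_residues)
    wells = xl.build_constraint_wells(
        records, penalty=config.constraint_penalty
    )
    ladder = make_ladder(config.t_min, config.t_max, config.n_replicas)
    t0 = time.perf_counter()
    result = run_rex(
        model,
        wells,
        ladder,
        n_steps=config.n_steps,
        exchange_every=config.exchange_every,
        seed=seed,
        sample_every=config.sample_every,
        ghost_rate=config.ghost_rate,
        start_coords=start_coords,
        equilibration_fraction=config.equilibration_fraction,
    )
    logger.info(
        "REX: %d replicas x %d events in %.1f s",
        config.n_replicas, config.n_steps, time.perf_counter() - t0,
    )
    return result


def collect_snapshots(result: RexResult) -> ens.SnapshotSet:
    """Pool post-equilibration frames from all replicas."""
    frames = result.production_frames()
    coords = np.stack([f[0] for f in frames])
    energies = np.array([f[1] for f in frames])
    sources = [f[2] for f in frames]
    return ens.SnapshotSet(coords, energies, sources)


def analyze(
    snapshots: ens.SnapshotSet, config: RunConfig | None = None
) -> EnsembleReport:
    """Low-energy selection, data-driven cutoff, clustering, descriptors."""
    config = config or RunConfig()
    selected = ens.select_low_energy(snapshots, config.selection_fraction)
    if len(selected) == 1:
        c = selected.coords[0]
        cluster = ClusterSummary(
            [0], 0, c, 1.0, ens.radius_of_gyration(c), None,
            ens.contact_map(c, config.contact_cutoff),
        )
        return EnsembleReport(
            [cluster], 0.0, 1, len(snapshots),
            np.array([cluster.rg]), selected.energies,
        )
    matrix = ens.rmsd_matrix(selected.coords)
    cutoff = ens.choose_cutoff(matrix)
    clustering = ens.daura_cluster(matrix, cutoff)
    clusters = []
    for members, centroid, pop in zip(
        clustering.clusters, clustering.centroids, clustering.populations
    ):
        cen = selected.coords[centroid]
        member_coords = selected.coords[members]
        clusters.append(
            ClusterSummary(
                members=members,
                centroid_index=centroid,
                centroid_coords=cen,
                population=pop,
                rg=ens.radius_of_gyration(cen),
                rmsf=(ens.rmsf(member_coords, cen)
                      if len(members) >= 2 else None),
                contact_frequency=ens.contact_frequency(
                    member_coords, config.contact_cutoff
                ),
            )
        )
    rg_values = np.array(
        [ens.radius_of_gyration(c) for c in selected.coords]
    )
    return EnsembleReport(
        clusters, cutoff, len(selected), len(snapshots),
        rg_values, selected.energies,
    )


def validate(
    report: EnsembleReport,
    records: list[xl.CrosslinkRecord],
    sm_records: list[val.SMRecord] | None = None,
    hdx_profile: val.HDXProfile | None = None,
) -> dict:
    """Score the ensemble against the held-out observables."""
    coords, weights = report.member_weights()
    out: dict = {}
    constraint_records = [r for r in records if r.role == "constraint"]
    if constraint_records:
        per = [
            xl.satisfaction_summary(
                xl.satisfaction_report(c, constraint_records)
            )["fraction"]
            for c in coords
        ]
        out["constraint_satisfaction"] = {
            "per_centroid": per,
            "weighted": float(np.dot(weights, per)),
            "top_cluster": per[0],
        }
    out["long_distance"] = val.ld_crosslink_check(coords, records, weights)
    if sm_records:
        sm = val.sm_consistency(coords, sm_records, weights)
        out["surface_modification"] = {"agreement": sm["agreement"]}
    if hdx_profile is not None:
        hdx = val.hdx_protection_estimate(coords, weights, hdx_profile)
        out["hdx"] = {
            "expected_protected_count": hdx["expected_protected_count"],
            "measured_protected_count": hdx.get("measured_protected_count"),
            "agreement": hdx.get("agreement"),
        }
    return out


def relaxation_test(
    report: EnsembleReport,
    model: ChainModel,
    config: RunConfig | None = None,
    seed: int = 0,
) -> dict:
    """Unconstrained relaxation of the top-cluster centroid (overfit probe)."""
    config = config or RunConfig()
    top = report.clusters[0]
    return ens.relax_unconstrained(
        top.centroid_coords,
        model,
        T=config.relax_temperature,
        n_steps=config.relax_n_steps,
        discard=config.relax_n_discard,
        sample_every=config.sample_every,
        seed=seed,
    )
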