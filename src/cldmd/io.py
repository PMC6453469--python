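"""Readers/writers for the formats the pipeline touches, plus run config.

Conventions: residues are numbered from 1 everywhere, distances are Å.
All tables share one CSV dialect — comma separated, ``#`` comment lines,
header required.  Ensembles and trajectories travel as Cα-only
multi-model PDB (MODEL/ENDMDL), read back with Biopython.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import SnapshotSet
from .validation import HDXProfile, SMRecord


def read_fasta(path) -> str:
    """First sequence of a FASTA file as a plain string."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        return str(rec.seq)
    raise ValueError(f"no sequences in {path}")


# ---------------------------------------------------------------------------
# multi-model Cα PDB

def write_pdb_ensemble(snapshots, path, sequence: str | None = None) -> None:
    """Write coordinate frames as a Cα-only multi-model PDB file.

    ``snapshots`` may be a SnapshotSet or a plain (m, n, 3) array.
    """
    coords = (
        snapshots.coords if isinstance(snapshots, SnapshotSet)
        else np.asarray(snapshots, float)
    )
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[0] == 0:
        raise ValueError("refusing to write an empty ensemble")
    with open(path, "w") as fh:
        for m, frame in enumerate(coords, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for r, (x, y, z) in enumerate(frame, start=1):
                aa3 = "ALA"
                if sequence is not None:
                    aa3 = _THREE.get(sequence[r - 1], "UNK")
                fh.write(
                    f"ATOM  {r:5d}  CA  {aa3} A{r:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb_ensemble(path) -> SnapshotSet:
    """Read a Cα multi-model PDB back into a SnapshotSet.

    Rejects files with no models and files whose models differ in residue
    count (naming the offending model).  Energies are zero-filled: PDB
    carries no energy.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("ens", str(path))
    frames = []
    for model in structure:
        cas = [
            atom.coord
            for chain in model
            for res in chain
            for atom in res
            if atom.get_name() == "CA"
        ]
        if not cas:
            continue
        frames.append(np.array(cas, dtype=float))
    if not frames:
        raise ValueError(f"{path} contains no models with Cα atoms")
    n0 = frames[0].shape[0]
    for k, f in enumerate(frames):
        if f.shape[0] != n0:
            raise ValueError(
                f"model {k + 1} has {f.shape[0]} residues, expected {n0}"
            )
    coords = np.stack(frames)
    return SnapshotSet(coords, np.zeros(len(frames)))


_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


# ---------------------------------------------------------------------------
# tables

def write_crosslink_csv(records, path) -> None:
    pd.DataFrame(
        [
            {"res_i": r.res_i, "res_j": r.res_j, "reagent": r.reagent,
             "role": r.role}
            for r in records
        ]
    ).to_csv(path, index=False)


def read_sm_table(source) -> list[SMRecord]:
    """CSV with columns ``residue,hl_ratio``."""
    df = pd.read_csv(source, comment="#")
    if not {"residue", "hl_ratio"}.issubset(df.columns):
        raise ValueError("SM table needs columns residue,hl_ratio")
    return [
        SMRecord(int(r.residue), float(r.hl_ratio))
        for r in df.itertuples(index=False)
    ]


def write_sm_table(records, path) -> None:
    pd.DataFrame(
        [{"residue": r.residue, "hl_ratio": round(r.hl_ratio, 4)}
         for r in records]
    ).to_csv(path, index=False)


def read_hdx_table(source) -> HDXProfile:
    """CSV with columns ``residue,deuteration``; rows must cover 1..n."""
    df = pd.read_csv(source, comment="#").sort_values("residue")
    if not {"residue", "deuteration"}.issubset(df.columns):
        raise ValueError("HDX table needs columns residue,deuteration")
    return HDXProfile(df["deuteration"].to_numpy())


def write_hdx_table(profile: HDXProfile, path) -> None:
    pd.DataFrame(
        {
            "residue": np.arange(1, len(profile.deuteration) + 1),
            "deuteration": np.round(profile.deuteration, 4),
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Every protocol constant of a run, with production defaults.

    Defaults mirror the reference protocol: a 24-rung ladder on
    [0.375, 0.605] kcal/(mol·k_B), 6×10⁶ DMD steps scaled down by
    ``scale_factor``, the first third discarded, the lowest 10% of
    energies selected, 8 Å contacts and the per-reagent satisfaction
    thresholds.  Each run writes its resolved config next to its outputs
    so any result can be replayed exactly.
    """

    n_replicas: int = 24
    t_min: float = 0.375
    t_max: float = 0.605
    total_steps: int = 6_000_000
    scale_factor: int = 100
    exchange_every: int = 1_000
    sample_every: int = 200
    ghost_rate: float = 0.1
    equilibration_fraction: float = 1.0 / 3.0
    selection_fraction: float = 0.10
    contact_cutoff: float = 8.0
    constraint_penalty: float = 2.0
    min_population: float = 0.05
    relax_temperature: float = 0.45
    relax_steps: int = 2_000_000
    relax_discard: int = 500_000
    seed: int = 0
    reagent_thresholds: dict = field(
        default_factory=lambda: {
            "ABAS": 17.0, "EDC": 10.0, "SDA": 15.0, "TATA": 14.0,
            "CBDPS": 25.0,
        }
    )

    @property
    def n_steps(self) -> int:
        return self.total_steps // self.scale_factor

    @property
    def relax_n_steps(self) -> int:
        return self.relax_steps // self.scale_factor

    @property
    def relax_n_discard(self) -> int:
        return self.relax_discard // self.scale_factor

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def write_matrix_csv(matrix: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(matrix)).to_csv(path, index=False, header=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
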