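"""Coarse-grained chain topology and discretized (step) interaction potentials.

The model is a one-bead-per-residue Cα trace.  Every interaction in the
system — virtual bonds, pseudo-angle wells, nonbonded contacts and
crosslink constraint wells — is a :class:`StepPotential`: a piecewise
constant function of the pair distance.  Because potentials are piecewise
constant, the dynamics reduce to ballistic flight punctuated by
instantaneous "collisions" at shell boundaries (see :mod:`cldmd.engine`).

Units: distances in Å, energies in kcal/mol, masses in bead units (1.0 per
residue by default), k_B = 1 so temperatures are in kcal/(mol·k_B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence as TSequence

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Residue classes used by the nonbonded table.  Histidine is grouped with
#: the positives (protonatable imidazole); tyrosine with the polars.
HYDROPHOBIC = set("AVLIMFWC")
POSITIVE = set("KRH")
NEGATIVE = set("DE")
POLAR = set("GSTNQYP")

#: The 140-residue human α-synuclein chain (UniProt P37840), the default
#: modelling target.
ALPHA_SYNUCLEIN = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVATVAEKTK"
    "EQVTNVGGAVVTGVTAVAQKTVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDP"
    "DNEAYEMPSEEGYQDYEPEA"
)


def residue_class(aa: str) -> str:
    """Map a one-letter code onto {hydrophobic, polar, positive, negative}."""
    if aa in HYDROPHOBIC:
        return "hydrophobic"
    if aa in POSITIVE:
        return "positive"
    if aa in NEGATIVE:
        return "negative"
    if aa in POLAR:
        return "polar"
    raise ValueError(f"unknown residue code {aa!r}")


@dataclass(frozen=True)
class Sequence:
    """An ordered amino-acid chain, 1-based residue numbering.

    Raises ``ValueError`` naming the first offending position if any code is
    outside the 20-letter alphabet, or if the chain is shorter than 2.
    """

    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("sequence must contain at least 2 residues")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in AA_ALPHABET:
                raise ValueError(
                    f"unknown residue code {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        return self.residues[i]

    @property
    def classes(self) -> list[str]:
        return [residue_class(aa) for aa in self.residues]


# Sentinel energy for an impenetrable (hard) wall.
INF = math.inf


@dataclass(frozen=True)
class StepPotential:
    """A piecewise-constant pair potential.

    ``radii`` are the strictly increasing shell boundaries (Å); ``energies``
    has one entry per region bounded by them, i.e. ``len(radii) + 1``
    values: ``energies[0]`` is the region below ``radii[0]`` (``inf`` for a
    hard core), ``energies[-1]`` the region beyond ``radii[-1]`` (0 for an
    ordinary interaction that vanishes at the cutoff, a finite penalty for a
    constraint well, ``inf`` for the outer wall of a covalent bond).
    """

    radii: tuple[float, ...]
    energies: tuple[float, ...]

    def __post_init__(self) -> None:
        r = self.radii
        if len(r) < 1:
            raise ValueError("at least one shell boundary required")
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("radii must be strictly increasing")
        if r[0] <= 0:
            raise ValueError("innermost radius must be positive")
        if len(self.energies) != len(r) + 1:
            raise ValueError(
                f"need {len(r) + 1} region energies for {len(r)} radii"
            )
        for e in self.energies[1:-1]:
            if not math.isfinite(e):
                raise ValueError("interior shell energies must be finite")

    @property
    def cutoff(self) -> float:
        return self.radii[-1]

    def energy_at(self, r: float) -> float:
        """Energy of the shell containing distance ``r`` (may be ``inf``)."""
        if r <= 0:
            raise ValueError("distance must be positive")
        # np.searchsorted convention: region index = #boundaries below r
        idx = int(np.searchsorted(self.radii, r, side="right"))
        return self.energies[idx]


def potential_energy_at(pot: StepPotential, r: float) -> float:
    """Shell lookup; ``inf`` signals a hard-core violation."""
    return pot.energy_at(r)


def hard_sphere(core: float) -> StepPotential:
    return StepPotential((core,), (INF, 0.0))


def square_well(
    lo: float, hi: float, depth: float, core: float | None = None
) -> StepPotential:
    """An attractive/repulsive single-step well between ``lo`` and ``hi``."""
    if core is None:
        return StepPotential((lo, hi), (INF, depth, 0.0))
    return StepPotential((core, lo, hi), (INF, 0.0, depth, 0.0))


@dataclass
class ForceFieldParams:
    """Tunable constants of the coarse-grained potential.

    Defaults give a minimal physics that produces compact globules:
    a two-step hydrophobic well, screened-Coulomb-like single steps for
    charge pairs, a universal 4 Å Cα hard core, stiff 3.8 Å virtual bonds
    and a pseudo-angle well keeping Cα(i)–Cα(i+2) in standard trace
    geometry.  Implicit solvation is absorbed into the hydrophobic step
    energies rather than modelled separately.
    """

    bond_length: float = 3.8
    bond_delta: float = 0.02          # fractional half-width of the bond well
    angle_lo: float = 4.5             # (i, i+2) pseudo-angle window, Å
    angle_hi: float = 7.3
    angle_penalty: float = 4.0        # kcal/mol outside the window
    angle_core: float = 3.0
    hard_core: float = 4.0            # nonbonded Cα–Cα exclusion, Å
    hh_shells: tuple[float, float] = (6.5, 8.0)
    hh_energies: tuple[float, float] = (-1.0, -0.4)
    charge_cutoff: float = 12.0
    charge_energy: float = 0.6        # magnitude of the electrostatic step
    bead_mass: float = 1.0

    def bond_well(self) -> StepPotential:
        lo = self.bond_length * (1.0 - self.bond_delta)
        hi = self.bond_length * (1.0 + self.bond_delta)
        return StepPotential((lo, hi), (INF, 0.0, INF))

    def angle_well(self) -> StepPotential:
        return StepPotential(
            (self.angle_core, self.angle_lo, self.angle_hi),
            (INF, self.angle_penalty, 0.0, self.angle_penalty),
        )

    def nonbonded(self, class_a: str, class_b: str) -> StepPotential:
        key = frozenset((class_a, class_b))
        if key == {"hydrophobic"}:
            return StepPotential(
                (self.hard_core, *self.hh_shells),
                (INF, *self.hh_energies, 0.0),
            )
        if key == {"positive", "negative"}:
            return StepPotential(
                (self.hard_core, self.charge_cutoff),
                (INF, -self.charge_energy, 0.0),
            )
        if key in ({"positive"}, {"negative"}):
            return StepPotential(
                (self.hard_core, self.charge_cutoff),
                (INF, +self.charge_energy, 0.0),
            )
        return hard_sphere(self.hard_core)


_CLASSES = ("hydrophobic", "polar", "positive", "negative")


@dataclass
class ChainModel:
    """United-residue topology: which StepPotential governs each pair.

    Pairs with ``|i - j| <= 2`` are governed exclusively by the bond /
    pseudo-angle wells; every other pair resolves to the nonbonded table
    entry for its residue-class pair.
    """

    sequence: Sequence
    params: ForceFieldParams
    bond: StepPotential = field(init=False)
    angle: StepPotential = field(init=False)
    nonbonded_table: dict[frozenset, StepPotential] = field(init=False)

    def __post_init__(self) -> None:
        self.bond = self.params.bond_well()
        self.angle = self.params.angle_well()
        self.nonbonded_table = {}
        for a in _CLASSES:
            for b in _CLASSES:
                self.nonbonded_table[frozenset((a, b))] = (
                    self.params.nonbonded(a, b)
                )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def masses(self) -> np.ndarray:
        return np.full(self.n_residues, self.params.bead_mass)

    def pair_potential(self, i: int, j: int) -> StepPotential:
        """Governing potential for 0-based bead indices ``i < j``."""
        if not 0 <= i < j < self.n_residues:
            raise ValueError(f"invalid pair ({i}, {j})")
        sep = j - i
        if sep == 1:
            return self.bond
        if sep == 2:
            return self.angle
        key = frozenset(
            (residue_class(self.sequence[i]), residue_class(self.sequence[j]))
        )
        return self.nonbonded_table[key]


def build_chain(
    sequence: Sequence | str, params: ForceFieldParams | None = None
) -> ChainModel:
    """Assemble the chain topology for one sequence.

    Accepts either a validated :class:`Sequence` or a raw string (validated
    here, rejecting unknown codes with the offending position).
    """
    if isinstance(sequence, str):
        sequence = Sequence(sequence)
    return ChainModel(sequence, params or ForceFieldParams())


def pair_distances(coords: np.ndarray) -> np.ndarray:
    """Condensed upper-triangle distance vector, scipy pdist ordering."""
    from scipy.spatial.distance import pdist

    return pdist(np.asarray(coords, dtype=float))


def total_potential_energy(
    coords: np.ndarray,
    model: ChainModel,
    wells: TSequence | None = None,
) -> float:
    """Sum of all governed pair energies plus constraint-well penalties.

    Deterministic given positions.  A pair inside its hard core makes the
    state invalid: raises ``ValueError`` identifying the pair (1-based).
    """
    coords = np.asarray(coords, dtype=float)
    n = model.n_residues
    if coords.shape != (n, 3):
        raise ValueError(f"expected coordinates of shape ({n}, 3)")
    total = 0.0
    d = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((d * d).sum(axis=2))
    for i in range(n):
        for j in range(i + 1, n):
            e = model.pair_potential(i, j).energy_at(dist[i, j])
            if math.isinf(e):
                raise ValueError(
                    f"hard-core overlap between residues {i + 1} and {j + 1}"
                )
            total += e
    if wells:
        for w in wells:
            i, j = w.res_i - 1, w.res_j - 1
            total += w.energy_at(dist[i, j])
    return total
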