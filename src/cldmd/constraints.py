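"""Crosslink tables and their conversion into flat-bottom constraint wells.

A crosslinking reagent of a given spacer length can only bridge residues
whose Cα atoms sit within a reagent-specific maximum distance.  Each
observed crosslink therefore becomes a soft, flat-bottom penalty: zero
energy anywhere below the reagent's maximum Cα–Cα span, a finite penalty
beyond it.  Penalties are finite on purpose — with conflicting constraints
(as expected for a disordered, multi-conformation protein) the simulation
resolves the conflict energetically by satisfying an optimal subset rather
than being trapped by an infeasible restraint.

Short-range reagents (ABAS, SDA, TATA, EDC) drive the folding; the
long-spacer CBDPS reagent is reserved for post-hoc validation.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReagentSpec:
    """A crosslinking reagent: maximum Cα–Cα span and reactive chemistry."""

    name: str
    max_ca_distance: float
    #: residue selectors for synthetic sampling: "amine" targets lysines and
    #: the N-terminus, "carboxyl" aspartate/glutamate and the C-terminus,
    #: "photo" inserts anywhere.
    chemistry: tuple[str, str]
    role: str = "constraint"


#: Cα–Cα satisfaction thresholds per reagent (Å).  A crosslink is satisfied
#: iff the distance is strictly below the threshold.
REAGENTS: dict[str, ReagentSpec] = {
    "ABAS": ReagentSpec("ABAS", 17.0, ("amine", "photo")),
    "EDC": ReagentSpec("EDC", 10.0, ("amine", "carboxyl")),
    "SDA": ReagentSpec("SDA", 15.0, ("amine", "photo")),
    "TATA": ReagentSpec("TATA", 14.0, ("photo", "photo")),
    "CBDPS": ReagentSpec("CBDPS", 25.0, ("amine", "amine"), role="validation"),
}


@dataclass(frozen=True)
class CrosslinkRecord:
    """One observed crosslink: an unordered residue pair plus its reagent.

    ``role`` is ``"constraint"`` for the short-range reagents that bias the
    folding simulation and ``"validation"`` for long-distance (CBDPS)
    records used only for scoring.
    """

    res_i: int
    res_j: int
    reagent: str
    role: str = ""

    def __post_init__(self) -> None:
        if self.res_i == self.res_j:
            raise ValueError(f"self-crosslink at residue {self.res_i}")
        if self.reagent not in REAGENTS:
            raise ValueError(f"unknown reagent {self.reagent!r}")
        if not self.role:
            object.__setattr__(self, "role", REAGENTS[self.reagent].role)
        if self.role not in ("constraint", "validation"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def pair(self) -> tuple[int, int]:
        return tuple(sorted((self.res_i, self.res_j)))

    @property
    def max_distance(self) -> float:
        return REAGENTS[self.reagent].max_ca_distance


@dataclass(frozen=True)
class ConstraintWell:
    """Flat-bottom penalty for one crosslinked pair.

    Zero energy for distances in ``[r_lo, r_hi]``, finite ``penalty``
    beyond ``r_hi`` (single outward step — no force at the bottom).  The
    region below ``r_lo`` is governed by the chain's own hard core.
    """

    res_i: int
    res_j: int
    r_lo: float
    r_hi: float
    penalty: float

    def __post_init__(self) -> None:
        if self.r_lo >= self.r_hi:
            raise ValueError("well bottom must have r_lo < r_hi")
        if not (self.penalty > 0 and np.isfinite(self.penalty)):
            raise ValueError(
                "constraint penalty must be positive and finite "
                "(constraints stay escapable)"
            )

    def energy_at(self, r: float) -> float:
        return self.penalty if r > self.r_hi else 0.0


def parse_crosslink_table(source) -> list[CrosslinkRecord]:
    """Read a crosslink CSV into records.

    Dialect: comma-separated, ``#`` comment lines, required header with
    columns ``res_i,res_j,reagent`` and an optional ``role`` column.  CBDPS
    rows are tagged ``role=validation`` regardless; duplicates (same
    unordered pair + reagent) collapse to one record with a warning.

    ``source`` may be a path, file object, or CSV text.  ``n_residues``
    range checking is the caller's concern via :func:`check_indices`.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, comment="#")
    required = {"res_i", "res_j", "reagent"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"crosslink table must name columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    records: list[CrosslinkRecord] = []
    seen: set[tuple] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            i, j = int(row.res_i), int(row.res_j)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {row_no}: non-integer residue index") from exc
        if i < 1 or j < 1:
            raise ValueError(f"row {row_no}: residue indices are 1-based")
        reagent = str(row.reagent).strip().upper()
        if reagent not in REAGENTS:
            raise ValueError(f"row {row_no}: unknown reagent {row.reagent!r}")
        role = REAGENTS[reagent].role
        rec = CrosslinkRecord(i, j, reagent, role)
        key = (rec.pair, reagent)
        if key in seen:
            msg = (
                f"duplicate crosslink {rec.pair} ({reagent}) at row "
                f"{row_no}; keeping first occurrence"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        seen.add(key)
        records.append(rec)
    return records


def check_indices(records: list[CrosslinkRecord], n_residues: int) -> None:
    """Reject records indexing outside the chain."""
    for k, rec in enumerate(records):
        if rec.res_i > n_residues or rec.res_j > n_residues:
            raise ValueError(
                f"record {k}: residue pair {rec.pair} exceeds chain "
                f"length {n_residues}"
            )


def build_constraint_wells(
    records: list[CrosslinkRecord],
    penalty: float = 2.0,
    r_lo: float = 4.0,
) -> list[ConstraintWell]:
    """One flat-bottom well per constraint record.

    The bottom spans hard-core contact (4.0 Å) to the reagent's maximum
    Cα–Cα span; the default 2.0 kcal/mol penalty is large enough to bias
    folding yet small enough that mutually conflicting constraints resolve
    by partial satisfaction.
    """
    wells = []
    for rec in records:
        if rec.role != "constraint":
            continue
        wells.append(
            ConstraintWell(*rec.pair, r_lo, rec.max_distance, penalty)
        )
    return wells


def satisfaction_report(
    coords: np.ndarray, records: list[CrosslinkRecord]
) -> pd.DataFrame:
    """Per-record satisfaction of reagent distance thresholds.

    A record is satisfied iff its Cα–Cα distance is *strictly* below the
    reagent maximum.  Returns a DataFrame with one row per record
    (``res_i, res_j, reagent, distance, threshold, satisfied``); aggregate
    with :func:`satisfaction_summary`.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    rows = []
    for rec in records:
        i, j = rec.pair
        if j > n:
            raise ValueError(
                f"residue {j} missing from conformation of length {n}"
            )
        d = float(np.linalg.norm(coords[i - 1] - coords[j - 1]))
        rows.append(
            {
                "res_i": i,
                "res_j": j,
                "reagent": rec.reagent,
                "role": rec.role,
                "distance": d,
                "threshold": rec.max_distance,
                "satisfied": d < rec.max_distance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "res_i", "res_j", "reagent", "role",
            "distance", "threshold", "satisfied",
        ],
    )


def satisfaction_summary(report: pd.DataFrame) -> dict:
    """Overall and per-reagent satisfied counts from a report frame."""
    if len(report) == 0:
        return {"n_records": 0, "n_satisfied": 0, "fraction": float("nan"),
                "per_reagent": {}}
    per = {
        reagent: {
            "n": int(len(grp)),
            "satisfied": int(grp["satisfied"].sum()),
        }
        for reagent, grp in report.groupby("reagent")
    }
    n_sat = int(report["satisfied"].sum())
    return {
        "n_records": int(len(report)),
        "n_satisfied": n_sat,
        "fraction": n_sat / len(report),
        "per_reagent": per,
    }
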