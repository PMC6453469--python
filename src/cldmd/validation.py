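"""Cross-validation of a predicted ensemble against orthogonal experiments.

Three observables, none of which entered the folding simulation:

* **Long-distance crosslinks** (CBDPS, 25 Å Cα–Cα maximum): a good model
  keeps the linked pairs within the reagent span.
* **Differential surface modification** (SM): a residue whose
  heavy/light modification ratio exceeds 1.5 is somewhat protected in the
  native state, i.e. buried; the model's burial labels should agree.
* **Hydrogen/deuterium exchange** (HDX): backbone amides engaged in
  secondary structure exchange slowly.  The proxy used here equates
  protection with residing in an assigned helix/strand element — a
  deliberate simplification that ignores tertiary solvent shielding.

All ensemble-level scores are population-weighted means in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constraints import CrosslinkRecord, satisfaction_report

SM_PROTECTED_RATIO = 1.5  # heavy/light ratio above which a residue is buried


@dataclass(frozen=True)
class SMRecord:
    """Surface-modification readout for one residue."""

    residue: int
    hl_ratio: float

    def __post_init__(self) -> None:
        if self.hl_ratio <= 0:
            raise ValueError("heavy/light ratio must be positive")

    @property
    def protected(self) -> bool:
        return self.hl_ratio > SM_PROTECTED_RATIO


@dataclass
class HDXProfile:
    """Per-residue deuteration fractions; 1 means fully unprotected."""

    deuteration: np.ndarray

    def __post_init__(self) -> None:
        self.deuteration = np.asarray(self.deuteration, float)
        if np.any((self.deuteration < 0) | (self.deuteration > 1)):
            raise ValueError("deuteration fractions must lie in [0, 1]")

    @property
    def protected_count(self) -> int:
        return int((self.deuteration < 0.5).sum())


# ---------------------------------------------------------------------------
# burial

def burial_proxy(
    coords: np.ndarray,
    probe_radius: float = 10.0,
    quantile: float = 0.75,
):
    """Neighbour-count burial estimate for a Cα trace.

    A residue's burial score is the number of residues more than 2 apart
    in sequence within ``probe_radius``; residues above the ensemble's
    upper-quartile count are labelled buried.  Returns
    ``(counts, buried_mask)``.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    idx = np.arange(n)
    mask = (np.abs(idx[:, None] - idx[None, :]) > 2) & (d <= probe_radius)
    counts = mask.sum(axis=1)
    threshold = np.quantile(counts, quantile)
    return counts, counts > threshold


def ensemble_burial(
    member_coords: np.ndarray,
    weights=None,
    probe_radius: float = 10.0,
    quantile: float = 0.75,
) -> np.ndarray:
    """Majority (population-weighted) burial label per residue."""
    member_coords = np.asarray(member_coords, float)
    m = member_coords.shape[0]
    weights = np.full(m, 1.0 / m) if weights is None else np.asarray(weights)
    weights = weights / weights.sum()
    frac = np.zeros(member_coords.shape[1])
    for w, c in zip(weights, member_coords):
        _, buried = burial_proxy(c, probe_radius, quantile)
        frac += w * buried
    return frac > 0.5


def sm_consistency(
    member_coords: np.ndarray,
    sm_records: list[SMRecord],
    weights=None,
    probe_radius: float = 10.0,
) -> dict:
    """Agreement between SM protection labels and model burial labels.

    For each residue in the table: protected (ratio > 1.5) should be
    buried in the ensemble majority, unprotected exposed.  Returns the
    agreement fraction and the per-residue comparison table.
    """
    if not sm_records:
        raise ValueError("empty surface-modification table")
    buried = ensemble_burial(member_coords, weights, probe_radius)
    rows = []
    for rec in sm_records:
        if not 1 <= rec.residue <= len(buried):
            raise ValueError(f"residue {rec.residue} outside the chain")
        model_buried = bool(buried[rec.residue - 1])
        rows.append(
            {
                "residue": rec.residue,
                "hl_ratio": rec.hl_ratio,
                "sm_protected": rec.protected,
                "model_buried": model_buried,
                "agrees": rec.protected == model_buried,
            }
        )
    table = pd.DataFrame(rows)
    return {
        "agreement": float(table["agrees"].mean()),
        "table": table,
    }


# ---------------------------------------------------------------------------
# secondary structure from the Cα trace

# Cα(i)–Cα(i+3) and Cα(i)–Cα(i+4) distance windows of an ideal α-helix.
HELIX_D3 = (4.8, 5.6)
HELIX_D4 = (5.8, 6.6)
STRAND_PAIR_CUTOFF = 5.5


def ss_assign(coords: np.ndarray) -> str:
    """Per-residue secondary-structure string over {H, E, C}.

    Helix: (i, i+3) and (i, i+4) distances inside the helical windows,
    sustained over a run of four consecutive residues.  Strand: two
    consecutive cross-strand Cα pairings ≤ 5.5 Å with |i−j| > 4 in
    parallel or antiparallel register.  Everything else is coil.
    Invariant under rigid motion (distances only).
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if n < 5:
        raise ValueError("chain too short for secondary-structure assignment")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)

    helical_step = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        ok3 = HELIX_D3[0] <= d[i, i + 3] <= HELIX_D3[1]
        ok4 = HELIX_D4[0] <= d[i, i + 4] <= HELIX_D4[1]
        helical_step[i] = ok3 and ok4
    labels = np.full(n, "C", dtype="<U1")
    run = 0
    for i in range(n - 4):
        run = run + 1 if helical_step[i] else 0
        if run >= 4:
            labels[i - run + 1 : i + 5] = "H"

    # strand pairing: consecutive cross-strand contacts in register
    for i in range(n - 1):
        for j in range(i + 5, n - 1):
            anti = d[i, j] <= STRAND_PAIR_CUTOFF and \
                d[i + 1, j - 1] <= STRAND_PAIR_CUTOFF and j - 1 > i + 1 + 4
            para = d[i, j] <= STRAND_PAIR_CUTOFF and \
                d[i + 1, j + 1] <= STRAND_PAIR_CUTOFF
            if anti:
                for k in (i, i + 1, j - 1, j):
                    if labels[k] == "C":
                        labels[k] = "E"
            elif para:
                for k in (i, i + 1, j, j + 1):
                    if labels[k] == "C":
                        labels[k] = "E"
    return "".join(labels)


def hdx_protection_estimate(
    member_coords: np.ndarray,
    weights=None,
    profile: HDXProfile | None = None,
) -> dict:
    """Expected protected-amide count from ensemble H/E occupancy.

    Residue protection probability = population-weighted frequency of an
    H or E assignment across members; the expected protected count is the
    sum of those probabilities.  If an experimental ``profile`` is given,
    the report includes agreement = fraction of residues whose predicted
    protection (probability > 0.5) matches the measured one
    (deuteration < 0.5).
    """
    member_coords = np.asarray(member_coords, float)
    if member_coords.ndim != 3 or member_coords.shape[0] == 0:
        raise ValueError("nonempty (m, n, 3) ensemble required")
    m, n, _ = member_coords.shape
    weights = np.full(m, 1.0 / m) if weights is None else np.asarray(weights)
    weights = weights / weights.sum()
    prob = np.zeros(n)
    for w, c in zip(weights, member_coords):
        labels = np.array(list(ss_assign(c)))
        prob += w * (labels != "C")
    out = {
        "protection_probability": prob,
        "expected_protected_count": float(prob.sum()),
    }
    if profile is not None:
        measured = profile.deuteration < 0.5
        predicted = prob > 0.5
        out["agreement"] = float((measured == predicted).mean())
        out["measured_protected_count"] = int(measured.sum())
    return out


# ---------------------------------------------------------------------------
# long-distance crosslinks

def ld_crosslink_check(
    member_coords: np.ndarray,
    records: list[CrosslinkRecord],
    weights=None,
) -> dict:
    """Population-weighted satisfaction of validation-role crosslinks.

    Satisfaction follows the strict `< threshold` rule (25 Å for CBDPS).
    With no validation records the report flags the absence rather than
    failing.
    """
    val_records = [r for r in records if r.role == "validation"]
    member_coords = np.asarray(member_coords, float)
    m = member_coords.shape[0]
    weights = np.full(m, 1.0 / m) if weights is None else np.asarray(weights)
    weights = weights / weights.sum()
    if not val_records:
        return {"no_validation_data": True, "weighted_fraction": math.nan,
                "per_structure": []}
    fracs = []
    for c in member_coords:
        rep = satisfaction_report(c, val_records)
        fracs.append(float(rep["satisfied"].mean()))
    return {
        "no_validation_data": False,
        "per_structure": fracs,
        "weighted_fraction": float(np.dot(weights, fracs)),
        "n_records": len(val_records),
    }
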