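"""Structure- and profile-space evaluation metrics.

CA-RMSD after optimal rigid superposition (Kabsch), the three-tier accuracy
labelling of baseline predictions, ensemble diversity, and the correlation
between input P(r) divergence and output structural diversity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidParameterError
from .structures import AtomicStructure

TIER_HIGH_MAX = 1.0   # Angstrom, inclusive upper bound of the high-accuracy tier
TIER_MID_MAX = 5.0    # Angstrom, inclusive upper bound of the mid-accuracy tier


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD between two matched point sets over proper rotations and
    translations.

    Both sets are centered, the optimal rotation comes from the SVD of the
    covariance matrix with the usual determinant sign correction (reflections
    are not allowed), and the RMSD of the superposed sets is returned.
    """
    a = np.asarray(coords_a, dtype=np.float64)
    b = np.asarray(coords_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InvalidParameterError("coordinate sets must be matched (n, 3) arrays")
    if len(a) < 1:
        raise DegenerateInputError("empty coordinate sets")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    diff = ac @ rot.T - bc
    return float(np.sqrt((diff ** 2).sum() / len(a)))


def ca_rmsd(a: AtomicStructure, b: AtomicStructure) -> float:
    """Kabsch CA-RMSD over residues present in both structures.

    Residues are matched by (chain, residue index); superposition uses all
    shared CA atoms.
    """
    ca_a = _ca_by_residue(a)
    ca_b = _ca_by_residue(b)
    shared = [k for k in ca_a if k in ca_b]
    if not shared:
        raise DegenerateInputError("no shared residues with CA atoms")
    xa = np.array([ca_a[k] for k in shared])
    xb = np.array([ca_b[k] for k in shared])
    return kabsch_rmsd(xa, xb)


def _ca_by_residue(s: AtomicStructure) -> dict:
    out = {}
    for i, name in enumerate(s.atom_names):
        if name == "CA":
            out[(s.chain_ids[i], int(s.res_indices[i]))] = s.coords[i]
    return out


def accuracy_tier(rmsd: float) -> str:
    """Tier label of a baseline prediction RMSD.

    high: rmsd <= 1.0 A; mid: 1.0 < rmsd <= 5.0 A; low: rmsd > 5.0 A.
    """
    if rmsd < 0:
        raise InvalidParameterError("RMSD cannot be negative")
    if rmsd <= TIER_HIGH_MAX:
        return "high"
    if rmsd <= TIER_MID_MAX:
        return "mid"
    return "low"


def intra_ensemble_rmsd(ensemble: list[AtomicStructure] | list[np.ndarray]) -> float:
    """Mean pairwise Kabsch CA-RMSD over all unordered conformer pairs."""
    coords = [
        m.ca_coords() if isinstance(m, AtomicStructure) else np.asarray(m)
        for m in ensemble
    ]
    if len(coords) < 2:
        return 0.0
    vals = [kabsch_rmsd(x, y) for x, y in combinations(coords, 2)]
    return float(np.mean(vals))


def divergence_diversity_correlation(pairs: np.ndarray) -> float:
    """Pearson r between input P(r) divergence and output structural diversity.

    ``pairs`` is an (n, 2) array of (P(r) L1 distance, structure RMSD)
    observations; requires n >= 3 and nonzero variance in both coordinates.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidParameterError("pairs must be an (n, 2) array")
    if len(arr) < 3:
        raise DegenerateInputError("need at least three observation pairs")
    if np.isclose(arr[:, 0].std(), 0) or np.isclose(arr[:, 1].std(), 0):
        raise DegenerateInputError("zero variance in one coordinate")
    return float(stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)


@dataclass
class UnfavouredResult:
    rmsd: float
    label: str       # which reference is the unfavoured (farther) state
    rmsd_apo: float
    rmsd_holo: float
    tie: bool


def unfavoured_conformer_rmsd(
    prediction: AtomicStructure,
    apo_ref: AtomicStructure,
    holo_ref: AtomicStructure,
) -> UnfavouredResult:
    """RMSD to the conformational state the prediction sits farther from.

    A prediction close to one state "favours" it; the other reference is the
    unfavoured conformer, whose RMSD measures how much of the transition the
    prediction missed.  Exact ties break to the first-listed (apo) reference
    and are flagged.
    """
    r_apo = ca_rmsd(prediction, apo_ref)
    r_holo = ca_rmsd(prediction, holo_ref)
    tie = bool(np.isclose(r_apo, r_holo, rtol=0, atol=1e-12))
    if tie or r_apo >= r_holo:
        return UnfavouredResult(r_apo, "apo", r_apo, r_holo, tie)
    return UnfavouredResult(r_holo, "holo", r_apo, r_holo, tie)


@dataclass
class EvaluationReport:
    """Per-target evaluation summary."""

    rmsd_to_refs: dict[str, float]
    best_of_ensemble_rmsd: float | None
    intra_ensemble_rmsd: float | None
    rg_delta: float | None
    saxs_l1: float | None
    tier: str

    def to_dict(self) -> dict:
        return {
            "rmsd_to_refs": self.rmsd_to_refs,
            "best_of_ensemble_rmsd": self.best_of_ensemble_rmsd,
            "intra_ensemble_rmsd": self.intra_ensemble_rmsd,
            "rg_delta": self.rg_delta,
            "saxs_l1": self.saxs_l1,
            "tier": self.tier,
        }
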