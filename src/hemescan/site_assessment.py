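"""Post-hoc assessment of predicted heme sites.

Automates the checks a structural biologist makes on a transferred heme
pose before trusting it:

* **axial-ligand candidates** — which His/Cys/Tyr/Met/Lys donor atoms
  lie near the placed iron, and whether the donor-iron distance is in
  coordination-bond range (roughly 1.9-2.6 A for Fe-N/O/S), merely
  *near* (a plausible ligand after local rearrangement), or too far;
* **steric feasibility** — a soft van-der-Waals overlap sum between the
  placed heme and all protein atoms, plus a burial fraction
  distinguishing pocket placements from surface ones.  This is triage,
  not an energy function: docking/refinement is deliberately out of
  scope;
* **model confidence** — for predicted (AlphaFold-style) models, the
  mean pLDDT over the site residues, flagged with AlphaFold's published
  bands (< 50 very low, < 70 low, otherwise high).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Residue, Structure

__all__ = [
    "AssessmentParams",
    "LigandCandidate",
    "SiteAssessment",
    "DONOR_ATOMS",
    "VDW_RADII",
    "find_ligand_candidates",
    "clash_score",
    "annotate_confidence",
    "assess_site",
]

#: Side-chain donor atoms screened as potential axial ligands to the iron.
#: His contributes both ring nitrogens (they are distinct candidates).
DONOR_ATOMS: dict[str, tuple[str, ...]] = {
    "HIS": ("ND1", "NE2"),
    "CYS": ("SG",),
    "TYR": ("OH",),
    "MET": ("SD",),
    "LYS": ("NZ",),
}

#: Fixed van-der-Waals radii (A) for the clash triage.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "FE": 1.40}
_VDW_DEFAULT = 1.70


@dataclass(frozen=True)
class AssessmentParams:
    report_max: float = 8.0       # A; donors beyond this are not reported
    bonding_max: float = 3.0      # A; donor-Fe distance for "bonding"
    near_max: float = 6.0         # A; "near" band upper edge
    overlap_factor: float = 0.7   # clash threshold = overlap_factor * vdW sum
    burial_radius: float = 5.0    # A; heme atom "buried" if protein atom this close
    plddt_low: float = 70.0
    plddt_very_low: float = 50.0


@dataclass
class LigandCandidate:
    residue_id: tuple[str, int, str]
    res_name: str
    donor_atom: str
    distance_to_fe: float
    plausibility: str   # bonding | near | far

    def __post_init__(self) -> None:
        if self.distance_to_fe < 0:
            raise ValueError("distance cannot be negative")


@dataclass
class SiteAssessment:
    ligand_candidates: list[LigandCandidate] = field(default_factory=list)
    clash_score: float = 0.0       # A of summed vdW overlap
    burial_fraction: float = 0.0   # heme atoms with protein within burial_radius
    confidence_flag: str = "n/a"   # high | low | very_low | n/a


def _band(d: float, params: AssessmentParams) -> str:
    if d <= params.bonding_max:
        return "bonding"
    if d <= params.near_max:
        return "near"
    return "far"


def find_ligand_candidates(
    query: Structure,
    placed_fe: np.ndarray,
    params: AssessmentParams = AssessmentParams(),
) -> list[LigandCandidate]:
    """Donor atoms within ``report_max`` of the placed iron, nearest first."""
    fe = np.asarray(placed_fe, dtype=float).reshape(3)
    if not np.all(np.isfinite(fe)):
        raise ValueError("placed_fe must be finite")
    out: list[LigandCandidate] = []
    for res in query.polymer_residues():
        donors = DONOR_ATOMS.get(res.name)
        if not donors:
            continue
        for name in donors:
            atom = res.get_atom(name)
            if atom is None:
                continue
            d = float(np.linalg.norm(atom.coord - fe))
            if d <= params.report_max:
                out.append(
                    LigandCandidate(
                        residue_id=res.rid,
                        res_name=res.name,
                        donor_atom=name,
                        distance_to_fe=d,
                        plausibility=_band(d, params),
                    )
                )
    out.sort(key=lambda c: (c.distance_to_fe, c.residue_id, c.donor_atom))
    return out


def clash_score(
    query: Structure,
    placed_heme_names: Sequence[str],
    placed_heme_coords: np.ndarray,
    params: AssessmentParams = AssessmentParams(),
) -> tuple[float, float]:
    """Soft steric overlap of the placed heme against all protein atoms.

    Returns ``(clash, burial_fraction)`` where clash is the sum over all
    heme-atom/protein-atom pairs of ``max(0, overlap_factor * (r1 + r2)
    - d)`` in Angstrom, and burial_fraction is the fraction of heme
    heavy atoms with at least one protein heavy atom within
    ``burial_radius``.  Hetero groups in the query (including an already
    bound heme) are not counted as protein.
    """
    heme_xyz = np.asarray(placed_heme_coords, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(heme_xyz)):
        raise ValueError("placed heme coordinates must be finite")

    prot_atoms = [a for r in query.polymer_residues() for a in r.atoms]
    if not prot_atoms:
        return 0.0, 0.0
    prot_xyz = np.array([a.coord for a in prot_atoms])
    prot_r = np.array([VDW_RADII.get(a.element, _VDW_DEFAULT) for a in prot_atoms])
    heme_r = np.array(
        [VDW_RADII.get(_element_of(nm), _VDW_DEFAULT) for nm in placed_heme_names]
    )

    d = cdist(heme_xyz, prot_xyz)
    thresh = params.overlap_factor * (heme_r[:, None] + prot_r[None, :])
    clash = float(np.maximum(0.0, thresh - d).sum())
    burial = float(np.mean(d.min(axis=1) <= params.burial_radius))
    return clash, burial


def _element_of(atom_name: str) -> str:
    name = atom_name.strip().upper()
    if name.startswith("FE"):
        return "FE"
    for ch in name:
        if ch.isalpha():
            return ch
    return "C"


def annotate_confidence(
    query: Structure,
    site_residue_ids: Sequence[tuple[str, int, str]],
    params: AssessmentParams = AssessmentParams(),
) -> str:
    """Confidence flag from the mean pLDDT of the site residues.

    Only meaningful for predicted models, where the B-factor column
    holds pLDDT; experimental and synthetic structures return ``n/a``.
    The flag depends only on the mean, so it is invariant to residue
    order.
    """
    if query.source_kind != "predicted_model":
        return "n/a"
    values = []
    for rid in site_residue_ids:
        res = query.find_residue(rid)
        if res is None or not res.atoms:
            continue
        values.append(res.mean_bfactor())
    if not values:
        warnings.warn("no B-factor values available for site residues; confidence n/a")
        return "n/a"
    mean = float(np.mean(values))
    if mean < params.plddt_very_low:
        return "very_low"
    if mean < params.plddt_low:
        return "low"
    return "high"


def assess_site(
    query: Structure,
    placed_heme_names: Sequence[str],
    placed_heme_coords: np.ndarray,
    placed_fe: np.ndarray,
    matched_residue_ids: Sequence[tuple[str, int, str]],
    params: AssessmentParams = AssessmentParams(),
) -> SiteAssessment:
    """Full assessment of one predicted site."""
    candidates = find_ligand_candidates(query, placed_fe, params)
    clash, burial = clash_score(query, placed_heme_names, placed_heme_coords, params)
    site_ids = list(matched_residue_ids) + [c.residue_id for c in candidates]
    seen: set[tuple[str, int, str]] = set()
    unique_ids = [rid for rid in site_ids if not (rid in seen or seen.add(rid))]
    flag = annotate_confidence(query, unique_ids, params)
    return SiteAssessment(
        ligand_candidates=candidates,
        clash_score=clash,
        burial_fraction=burial,
        confidence_flag=flag,
    )
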