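"""Geometric template matching.

Scans a query structure against a template library: for every template,
enumerate compatible residue triplets (type identity, plus a complete
pairwise Calpha-distance prune), superpose the template's nine match
atoms onto the query triplet with a Kabsch least-squares fit, filter by
RMSD, and transfer the source heme into the query frame through the
fitted transform.

Everything here is deterministic: no randomness, ties broken
lexicographically, output fully ordered.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structure_io import Residue, Structure
from .template_library import MATCH_ATOMS, HemeTemplate, TemplateLibrary

__all__ = [
    "MatcherParams",
    "RigidTransform",
    "TemplateMatch",
    "ScanResult",
    "DegenerateGeometryError",
    "SIMILARITY_GROUPS",
    "similarity_group",
    "kabsch_superpose",
    "enumerate_candidate_triplets",
    "scan",
]

#: Residue similarity groups shared by triplet typing (optional) and
#: environment scoring: acidic, basic, aromatic, aliphatic/thioether,
#: hydroxyl, amide, small; Cys and Pro stand alone.
SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset({"ASP", "GLU"}),
    frozenset({"LYS", "ARG", "HIS"}),
    frozenset({"PHE", "TYR", "TRP"}),
    frozenset({"ILE", "LEU", "VAL", "MET"}),
    frozenset({"SER", "THR"}),
    frozenset({"ASN", "GLN"}),
    frozenset({"ALA", "GLY"}),
    frozenset({"CYS"}),
    frozenset({"PRO"}),
)

_GROUP_OF: dict[str, frozenset[str]] = {
    name: grp for grp in SIMILARITY_GROUPS for name in grp
}


def similarity_group(res_name: str) -> Optional[frozenset[str]]:
    """The similarity group containing ``res_name``, or None for
    non-standard residues."""
    return _GROUP_OF.get(res_name)


class DegenerateGeometryError(ValueError):
    """Raised when a point set is too degenerate (collinear) to superpose."""


@dataclass(frozen=True)
class MatcherParams:
    rmsd_max: float = 2.0           # A over the 9 match atoms
    pair_tol: float = 1.5           # A tolerance on Calpha-Calpha distances
    allow_similar_triplets: bool = False  # identity required by default


@dataclass
class RigidTransform:
    """A proper rigid-body transform x -> R x + t (rotation + translation)."""

    rotation: np.ndarray     # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def validate(self, tol: float = 1e-9) -> None:
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=tol):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > tol:
            raise ValueError("rotation has det != +1 (reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> R_s (R_o x + t_o) + t_s."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid superposition of ``moving`` onto ``fixed``.

    Classic Kabsch: centre both point sets, take the SVD of the
    covariance, and correct the sign of the smallest singular direction
    so that a reflection is never returned.  Returns the transform and
    the RMSD of the transformed moving set against the fixed set.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 points are given or either set is (near-)
        collinear, in which case the rotation is not fully determined.
    """
    moving = np.asarray(moving, dtype=float).reshape(-1, 3)
    fixed = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if moving.shape != fixed.shape:
        raise ValueError("point sets differ in size")
    n = len(moving)
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")

    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    a = moving - cm
    b = fixed - cf

    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    scale = max(float(np.linalg.norm(a)), float(np.linalg.norm(b)), 1e-12)
    if s[1] <= 1e-8 * scale:
        # rank < 2: both sets collinear, rotation about the line undetermined
        raise DegenerateGeometryError("collinear point set: superposition underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cf - rotation @ cm
    transform = RigidTransform(rotation, translation)
    diff = transform.apply(moving) - fixed
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return transform, rmsd


@dataclass
class TemplateMatch:
    """A template matched onto a query residue triplet."""

    template_id: str
    source_structure_id: str
    query_residues: tuple[tuple[str, int, str], ...]  # ordered as template residues
    query_res_names: tuple[str, str, str]
    transform: RigidTransform
    rmsd: float
    placed_heme_names: list[str]
    placed_heme_coords: np.ndarray   # (M, 3), query frame
    fe_index: int

    @property
    def placed_fe(self) -> np.ndarray:
        return self.placed_heme_coords[self.fe_index]

    def sort_key(self) -> tuple:
        return (self.rmsd, self.template_id, self.query_residues)


@dataclass
class ScanResult:
    matches: list[TemplateMatch] = field(default_factory=list)
    skips: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.matches)

    def __len__(self) -> int:
        return len(self.matches)


def _types_compatible(query_name: str, template_name: str, allow_similar: bool) -> bool:
    if query_name == template_name:
        return True
    if not allow_similar:
        return False
    grp = similarity_group(template_name)
    return grp is not None and query_name in grp


def _eligible_residues(query: Structure) -> list[tuple[Residue, np.ndarray]]:
    """Standard residues usable as triplet members: have all own match atoms.

    Returns (residue, match-atom coords (3,3)) pairs; residues missing a
    match atom are excluded (callers count them as skips).
    """
    out = []
    for res in query.standard_residues():
        names = MATCH_ATOMS.get(res.name)
        if names is None:
            continue
        atoms = [res.get_atom(nm) for nm in names]
        if any(a is None for a in atoms):
            continue
        out.append((res, np.array([a.coord for a in atoms])))  # type: ignore[union-attr]
    return out


def enumerate_candidate_triplets(
    query: Structure, t: HemeTemplate, params: MatcherParams = MatcherParams()
) -> list[tuple[Residue, Residue, Residue]]:
    """All ordered triples of distinct query residues compatible with ``t``.

    A triple qualifies iff (i) each residue's type is identical to the
    corresponding template residue (or in its similarity group when
    ``allow_similar_triplets`` is on), and (ii) each pairwise
    Calpha-Calpha distance agrees with the template's within
    ``pair_tol``.  The enumeration is complete with respect to these two
    rules and deterministically ordered.
    """
    eligible = _eligible_residues(query)
    # Calpha positions for the distance prune
    cas = {}
    for res, _ in eligible:
        ca = res.ca
        if ca is None:
            continue
        cas[res.rid] = ca.coord
    candidates: list[list[Residue]] = []
    for tr in t.residues:
        cset = [
            res for res, _ in eligible
            if res.rid in cas
            and _types_compatible(res.name, tr.res_name, params.allow_similar_triplets)
        ]
        if not cset:
            return []
        candidates.append(cset)

    tca = []
    for tr in t.residues:
        try:
            i = tr.atom_names.index("CA")
        except ValueError:
            i = 1
        tca.append(tr.coords[i])
    d01 = float(np.linalg.norm(tca[0] - tca[1]))
    d02 = float(np.linalg.norm(tca[0] - tca[2]))
    d12 = float(np.linalg.norm(tca[1] - tca[2]))

    tol = params.pair_tol
    out: list[tuple[Residue, Residue, Residue]] = []
    for r0 in candidates[0]:
        c0 = cas[r0.rid]
        for r1 in candidates[1]:
            if r1.rid == r0.rid:
                continue
            c1 = cas[r1.rid]
            if abs(float(np.linalg.norm(c0 - c1)) - d01) > tol:
                continue
            for r2 in candidates[2]:
                if r2.rid == r0.rid or r2.rid == r1.rid:
                    continue
                c2 = cas[r2.rid]
                if abs(float(np.linalg.norm(c0 - c2)) - d02) > tol:
                    continue
                if abs(float(np.linalg.norm(c1 - c2)) - d12) > tol:
                    continue
                out.append((r0, r1, r2))
    out.sort(key=lambda trip: tuple(r.rid for r in trip))
    return out


def _match_atom_coords(res: Residue) -> Optional[np.ndarray]:
    names = MATCH_ATOMS.get(res.name)
    if names is None:
        return None
    atoms = [res.get_atom(nm) for nm in names]
    if any(a is None for a in atoms):
        return None
    return np.array([a.coord for a in atoms])


def match_template_to_triplet(
    t: HemeTemplate, triplet: Sequence[Residue], params: MatcherParams = MatcherParams()
) -> Optional[TemplateMatch]:
    """Superpose ``t`` onto a specific query triplet; None if over rmsd_max.

    The transform maps the template frame into the query frame; the
    placed heme and its iron are the template's heme pushed through that
    transform (the iron coordinate is taken from the same transformed
    array, so the two can never disagree).
    """
    fixed = []
    for res in triplet:
        xyz = _match_atom_coords(res)
        if xyz is None:
            return None
        fixed.append(xyz)
    fixed_arr = np.vstack(fixed)
    moving = t.match_atom_coords()
    try:
        transform, rmsd = kabsch_superpose(moving, fixed_arr)
    except DegenerateGeometryError:
        return None
    if rmsd > params.rmsd_max:
        return None
    placed = transform.apply(t.heme_coords)
    return TemplateMatch(
        template_id=t.template_id,
        source_structure_id=t.source_structure_id,
        query_residues=tuple(r.rid for r in triplet),
        query_res_names=tuple(r.name for r in triplet),  # type: ignore[arg-type]
        transform=transform,
        rmsd=rmsd,
        placed_heme_names=list(t.heme_atom_names),
        placed_heme_coords=placed,
        fe_index=t.fe_index,
    )


def scan(
    query: Structure, lib: TemplateLibrary, params: MatcherParams = MatcherParams()
) -> ScanResult:
    """Scan every library template against the query structure.

    For each candidate triplet the template's nine match atoms are
    superposed onto the query triplet's corresponding atoms; matches
    with RMSD <= ``rmsd_max`` are kept and carry the transferred heme
    pose.  Output is sorted by (rmsd, template_id, residue ids) and the
    result records counts of skipped candidates (missing atoms,
    degenerate geometry).
    """
    result = ScanResult()
    templates = sorted(lib.templates, key=lambda t: t.template_id)
    for t in templates:
        for triplet in enumerate_candidate_triplets(query, t, params):
            fixed = []
            bad = False
            for res in triplet:
                xyz = _match_atom_coords(res)
                if xyz is None:
                    result.skips["missing_match_atom"] += 1
                    bad = True
                    break
                fixed.append(xyz)
            if bad:
                continue
            moving = t.match_atom_coords()
            try:
                transform, rmsd = kabsch_superpose(moving, np.vstack(fixed))
            except DegenerateGeometryError:
                result.skips["degenerate_triplet"] += 1
                continue
            if rmsd > params.rmsd_max:
                result.skips["over_rmsd_max"] += 1
                continue
            placed = transform.apply(t.heme_coords)
            result.matches.append(
                TemplateMatch(
                    template_id=t.template_id,
                    source_structure_id=t.source_structure_id,
                    query_residues=tuple(r.rid for r in triplet),
                    query_res_names=tuple(r.name for r in triplet),  # type: ignore[arg-type]
                    transform=transform,
                    rmsd=rmsd,
                    placed_heme_names=list(t.heme_atom_names),
                    placed_heme_coords=placed,
                    fe_index=t.fe_index,
                )
            )
    result.matches.sort(key=TemplateMatch.sort_key)
    return result


def brute_force_scan(
    query: Structure, lib: TemplateLibrary, params: MatcherParams = MatcherParams()
) -> ScanResult:
    """Exhaustive reference scan without the pairwise-distance prune.

    Enumerates *every* ordered triple of type-compatible residues and
    applies only the Kabsch RMSD filter.  Quadratically slower than
    :func:`scan`; exists as the independent completeness oracle for
    small structures.
    """
    result = ScanResult()
    templates = sorted(lib.templates, key=lambda t: t.template_id)
    eligible = _eligible_residues(query)
    for t in templates:
        csets = []
        for tr in t.residues:
            csets.append(
                [res for res, _ in eligible
                 if _types_compatible(res.name, tr.res_name, params.allow_similar_triplets)]
            )
        for trip in itertools.product(*csets):
            if len({r.rid for r in trip}) != 3:
                continue
            m = match_template_to_triplet(t, trip, params)
            if m is not None:
                result.matches.append(m)
    result.matches.sort(key=TemplateMatch.sort_key)
    return result
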