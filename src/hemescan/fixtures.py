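"""Synthetic heme-protein fixtures with planted, fully known binding sites.

Real heme-bound structures cannot be bundled with the package, so this
module builds small artificial ones: an idealized planar heme (a
porphine-style core of 24 heavy atoms plus the iron, from a built-in
synthetic coordinate table — not taken from any PDB entry), ligating
residues whose donor atoms sit at caller-requested distances from the
iron, an environment shell of chosen residue types within the 10 A
scoring radius, and a decoy helix far from the site.  Every placement is
deterministic given the seed, and the returned ground truth records the
heme pose, the site residues and the environment labels, so expected
outcomes of every downstream operation can be computed without
re-deriving geometry.

These fixtures are geometric, not physical: no torsion angles, no
energetics, side chains reduced to the atoms the search actually uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .structure_io import Atom, Residue, Structure
from .template_library import MATCH_ATOMS
from .matcher import SIMILARITY_GROUPS, similarity_group

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "GeometryError",
    "IDEAL_HEME",
    "make_toy_heme_protein",
    "perturb_structure",
    "mutate_environment",
    "CANONICAL_SPECS",
]


class GeometryError(ValueError):
    """Raised when requested fixture geometry cannot be realised."""


def _ideal_heme_table() -> list[tuple[str, str, np.ndarray]]:
    """Synthetic idealized heme: Fe + 4 pyrrole N + 20 ring carbons, planar.

    Radii and angles approximate a porphyrin macrocycle; the values are
    invented for testing, deliberately not copied from any database
    entry.
    """
    atoms: list[tuple[str, str, np.ndarray]] = [("FE", "FE", np.zeros(3))]
    for sub, theta0 in zip("ABCD", (0.0, 90.0, 180.0, 270.0)):
        def pol(r: float, deg: float) -> np.ndarray:
            t = math.radians(deg)
            return np.array([r * math.cos(t), r * math.sin(t), 0.0])

        atoms.append((f"N{sub}", "N", pol(2.05, theta0)))
        atoms.append((f"C1{sub}", "C", pol(3.05, theta0 - 18.0)))
        atoms.append((f"C2{sub}", "C", pol(4.25, theta0 - 11.0)))
        atoms.append((f"C3{sub}", "C", pol(4.25, theta0 + 11.0)))
        atoms.append((f"C4{sub}", "C", pol(3.05, theta0 + 18.0)))
        atoms.append((f"CH{sub}", "C", pol(3.42, theta0 + 45.0)))
    return atoms


IDEAL_HEME = _ideal_heme_table()   # 25 entries: Fe + 24 heavy atoms


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for one synthetic heme protein.

    ``ligating_residues`` lists (residue type, donor-to-Fe distance in
    A); the donor is the residue's functional match atom.  The first two
    entries are placed on the axial (+z/-z) directions, further ones on
    45-degree tilted directions around the ring.  ``env_composition``
    maps residue type to the number of copies planted in the 10 A
    environment shell.  ``noise_sigma`` adds isotropic Gaussian noise to
    every heavy atom after construction.
    """

    seed: int = 0
    n_scaffold_residues: int = 20
    ligating_residues: tuple[tuple[str, float], ...] = (
        ("HIS", 2.1), ("TYR", 2.5), ("LEU", 3.8),
    )
    env_composition: tuple[tuple[str, int], ...] = (
        ("PHE", 2), ("SER", 1), ("VAL", 1), ("ASN", 1),
        ("GLU", 1), ("TRP", 1), ("THR", 1),
    )
    noise_sigma: float = 0.0
    plddt_profile: Optional[float] = None   # constant pLDDT; tags a predicted model


@dataclass
class GroundTruth:
    """Everything known about a generated fixture."""

    spec: FixtureSpec
    fe_coord: np.ndarray
    heme_names: list[str]
    heme_coords: np.ndarray
    heme_rid: tuple[str, int, str]
    site_residues: list[tuple[tuple[str, int, str], str, str, float]]
    # (rid, res_name, donor atom, requested donor-Fe distance)
    environment: list[tuple[tuple[str, int, str], str]]   # (rid, res_name)

    @property
    def site_rids(self) -> list[tuple[str, int, str]]:
        return [rid for rid, *_ in self.site_residues]


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise GeometryError("zero-length direction")
    return v / n


def _perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(u, ref))


def _element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch
    return "C"


def _mk_atoms(pos: dict[str, np.ndarray], bfactor: float) -> list[Atom]:
    return [
        Atom(name=n, element=_element(n), coord=c, occupancy=1.0, bfactor=bfactor)
        for n, c in pos.items()
    ]


def _ligating_residue(
    name: str, donor: np.ndarray, u: np.ndarray, bfactor: float,
    chain: str, seq: int,
) -> tuple[Residue, str]:
    """Residue with its functional match atom exactly at ``donor``.

    ``u`` points away from the iron; all backbone atoms are placed
    further out along u so the residue never pierces the heme plane.
    Returns the residue and the donor atom name.
    """
    if name not in MATCH_ATOMS:
        raise GeometryError(f"unknown residue type {name}")
    p = _perp(u)
    t = np.cross(u, p)
    match = MATCH_ATOMS[name]
    pos: dict[str, np.ndarray] = {}
    if name == "GLY":
        pos["C"] = donor
        pos["CA"] = pos["C"] + 1.52 * _unit(0.8 * u + 0.6 * p)
        pos["N"] = pos["CA"] + 1.46 * _unit(0.8 * u - 0.6 * p)
        pos["O"] = pos["C"] + 1.23 * t
        donor_name = "C"
    elif name == "ALA":
        pos["CB"] = donor
        pos["CA"] = pos["CB"] + 1.53 * _unit(0.8 * u + 0.6 * p)
        pos["N"] = pos["CA"] + 1.46 * _unit(0.8 * u - 0.6 * p)
        pos["C"] = pos["CA"] + 1.52 * _unit(0.6 * u + 0.8 * t)
        pos["O"] = pos["C"] + 1.23 * u
        donor_name = "CB"
    else:
        func = match[2]
        pos[func] = donor
        pos["CB"] = donor + 1.50 * _unit(0.8 * u + 0.6 * p)
        pos["CA"] = pos["CB"] + 1.53 * _unit(0.8 * u - 0.6 * p)
        pos["N"] = pos["CA"] + 1.46 * _unit(0.6 * u + 0.8 * t)
        pos["C"] = pos["CA"] + 1.52 * _unit(0.6 * u - 0.8 * t)
        pos["O"] = pos["C"] + 1.23 * u
        donor_name = func
    res = Residue(chain_id=chain, name=name, seq_num=seq, atoms=_mk_atoms(pos, bfactor))
    return res, donor_name


def _shell_residue(
    name: str, ca: np.ndarray, u: np.ndarray, bfactor: float, chain: str, seq: int
) -> Residue:
    """Residue anchored by its Calpha, side chain pointing outward along u."""
    p = _perp(u)
    t = np.cross(u, p)
    pos: dict[str, np.ndarray] = {"CA": ca}
    pos["N"] = ca + 1.46 * _unit(0.5 * u + 0.866 * p)
    pos["C"] = ca + 1.52 * _unit(0.5 * u - 0.866 * p)
    pos["O"] = pos["C"] + 1.23 * _unit(0.7 * u + 0.714 * t)
    if name != "GLY":
        pos["CB"] = ca + 1.53 * u
        match = MATCH_ATOMS[name]
        if name != "ALA":
            pos[match[2]] = pos["CB"] + 1.50 * _unit(0.9 * u + 0.436 * t)
    return Residue(chain_id=chain, name=name, seq_num=seq, atoms=_mk_atoms(pos, bfactor))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_LIGAND_DIRECTIONS = [
    np.array([0.0, 0.0, 1.0]),
    np.array([0.0, 0.0, -1.0]),
] + [
    np.array(
        [math.cos(math.radians(az)) * math.sqrt(0.5),
         math.sin(math.radians(az)) * math.sqrt(0.5),
         sz * math.sqrt(0.5)]
    )
    for az, sz in ((0, 1), (60, -1), (120, 1), (180, -1), (240, 1), (300, -1))
]

_MIN_ENV_HEME_DIST = 7.0    # keeps every env atom outside the 4 A contact shell
_ENV_MATCH_MAX = 9.8        # env Calpha must sit within the 10 A rule with margin
_OVERLAP_FACTOR = 0.55      # placements closer than this x vdW-sum are infeasible

_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "FE": 1.40}


def _check_no_overlap(residues: Sequence[Residue], heme: Sequence[tuple[str, str, np.ndarray]]) -> None:
    entries: list[tuple[str, np.ndarray, int]] = []
    for i, r in enumerate(residues):
        for a in r.atoms:
            entries.append((a.element, a.coord, i))
    for name, el, c in heme:
        entries.append((el, c, -1))
    xyz = np.array([c for _, c, _ in entries])
    owner = np.array([o for _, _, o in entries])
    radii = np.array([_VDW.get(e, 1.70) for e, _, _ in entries])
    from scipy.spatial.distance import cdist

    d = cdist(xyz, xyz)
    thresh = _OVERLAP_FACTOR * (radii[:, None] + radii[None, :])
    same = owner[:, None] == owner[None, :]
    np.fill_diagonal(same, True)
    bad = (d < thresh) & ~same
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GeometryError(
            f"overlapping placements: atoms {i} and {j} at {d[i, j]:.2f} A"
        )


def make_toy_heme_protein(spec: FixtureSpec) -> tuple[Structure, GroundTruth]:
    """Build a synthetic heme protein with a planted binding site.

    Raises :class:`GeometryError` when the requested composition cannot
    be placed without steric overlap or outside the environment rule.
    """
    if len(spec.ligating_residues) > len(_LIGAND_DIRECTIONS):
        raise GeometryError(
            f"at most {len(_LIGAND_DIRECTIONS)} ligating residues supported"
        )
    bfac = spec.plddt_profile if spec.plddt_profile is not None else 20.0
    chain = "A"

    residues: list[Residue] = []
    site_records = []
    for i, (name, dist) in enumerate(spec.ligating_residues):
        if dist <= 0:
            raise GeometryError("donor distance must be positive")
        u = _LIGAND_DIRECTIONS[i]
        donor = dist * u
        res, donor_name = _ligating_residue(name, donor, u, bfac, chain, 101 + i)
        residues.append(res)
        site_records.append((res.rid, name, donor_name, dist))

    # match atoms the environment rule is measured against
    match_pts = []
    for res in residues:
        for nm in MATCH_ATOMS[res.name]:
            a = res.get_atom(nm)
            if a is not None:
                match_pts.append(a.coord)
    match_xyz = np.array(match_pts)
    heme_xyz = np.array([c for _, _, c in IDEAL_HEME])

    env_records = []
    wanted = [nm for nm, count in spec.env_composition for _ in range(count)]
    dirs = _fibonacci_sphere(128)
    placed_xyz = [a.coord for r in residues for a in r.atoms]
    slot = 0
    seq = 201
    for di in range(len(dirs)):
        if slot >= len(wanted):
            break
        d = dirs[di]
        for radius in (8.8, 9.4, 10.0):
            ca = radius * d
            if np.linalg.norm(ca - heme_xyz, axis=1).min() < _MIN_ENV_HEME_DIST:
                continue
            if np.linalg.norm(ca - match_xyz, axis=1).min() > _ENV_MATCH_MAX:
                continue
            if placed_xyz and np.linalg.norm(ca - np.array(placed_xyz), axis=1).min() < 3.8:
                continue
            name = wanted[slot]
            res = _shell_residue(name, ca, d.copy(), bfac, chain, seq)
            residues.append(res)
            env_records.append((res.rid, name))
            placed_xyz.extend(a.coord for a in res.atoms)
            slot += 1
            seq += 1
            break
    if slot < len(wanted):
        raise GeometryError(
            f"could only place {slot} of {len(wanted)} environment residues"
        )

    # decoy helix, >= 15 A from the site
    palette = ["LEU", "SER", "HIS", "ALA", "VAL", "TYR", "THR", "GLY"]
    axis_x = 26.0
    for i in range(spec.n_scaffold_residues):
        ang = math.radians(100.0 * i)
        ca = np.array(
            [axis_x + 2.3 * math.cos(ang), 1.5 * i - 15.0, 2.3 * math.sin(ang)]
        )
        u = _unit(np.array([math.cos(ang), 0.0, math.sin(ang)]))
        res = _shell_residue(palette[i % len(palette)], ca, u, bfac, chain, 301 + i)
        residues.append(res)

    heme_res = Residue(
        chain_id=chain,
        name="HEM",
        seq_num=501,
        atoms=[
            Atom(name=nm, element=el, coord=c.copy(), occupancy=1.0, bfactor=bfac)
            for nm, el, c in IDEAL_HEME
        ],
        is_hetero=True,
    )
    _check_no_overlap(residues, IDEAL_HEME)
    residues.append(heme_res)
    residues.sort(key=lambda r: (r.chain_id, r.seq_num, r.icode))

    kind = "predicted_model" if spec.plddt_profile is not None else "synthetic"
    s = Structure(id=f"toy-{spec.seed}", residues=residues, source_kind=kind)

    gt = GroundTruth(
        spec=spec,
        fe_coord=np.zeros(3),
        heme_names=[nm for nm, _, _ in IDEAL_HEME],
        heme_coords=heme_xyz.copy(),
        heme_rid=heme_res.rid,
        site_residues=site_records,
        environment=env_records,
    )

    if spec.noise_sigma > 0:
        s = perturb_structure(s, spec.noise_sigma, seed=spec.seed)
        heme = s.find_residue(gt.heme_rid)
        assert heme is not None
        gt.heme_coords = np.array([a.coord for a in heme.atoms])
        fe = heme.get_atom("FE")
        assert fe is not None
        gt.fe_coord = fe.coord.copy()
    return s, gt


def perturb_structure(s: Structure, sigma: float, seed: int = 0) -> Structure:
    """Isotropic Gaussian coordinate noise on every heavy atom; seeded."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = s.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for res in out.residues:
        for atom in res.atoms:
            atom.coord = atom.coord + rng.normal(0.0, sigma, size=3)
    return out


_DISSIMILAR_PREFERENCE = ["TRP", "ASP", "LYS", "ASN", "SER", "PHE", "CYS"]
# residues whose similar-mutation would change the match-atom scheme
_NO_SIMILAR = {"CYS", "PRO", "ALA", "GLY"}


def _similar_to(name: str) -> Optional[str]:
    grp = similarity_group(name)
    if grp is None or len(grp) < 2 or name in _NO_SIMILAR:
        return None
    members = sorted(grp)
    i = members.index(name)
    return members[(i + 1) % len(members)]


def _dissimilar_to(name: str) -> str:
    grp = similarity_group(name) or frozenset({name})
    for cand in _DISSIMILAR_PREFERENCE:
        if cand != name and cand not in grp:
            return cand
    raise GeometryError(f"no dissimilar replacement for {name}")


def mutate_environment(
    s: Structure,
    gt: GroundTruth,
    k: int,
    mode: str,
    seed: int = 0,
) -> tuple[Structure, GroundTruth]:
    """Rename ``k`` environment residues within (similar) or outside
    (dissimilar) their similarity group.

    Geometry is untouched (the Calpha the scoring rule reads stays
    put); the residue name and its functional-atom label are rewritten
    so the structure stays self-consistent.  Returns a new structure and
    updated ground truth.
    """
    if mode not in ("similar", "dissimilar"):
        raise ValueError(f"mode must be similar|dissimilar, got {mode!r}")
    env = list(gt.environment)
    if mode == "similar":
        mutable = [(rid, nm) for rid, nm in env if _similar_to(nm) is not None]
    else:
        mutable = env
    if k > len(mutable):
        raise ValueError(f"k={k} exceeds mutable environment size {len(mutable)}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(mutable))
    chosen = [mutable[i] for i in order[:k]]

    out = s.copy()
    new_env = dict(env)
    for rid, old_name in chosen:
        res = out.find_residue(rid)
        if res is None:
            raise ValueError(f"environment residue {rid} not found")
        new_name = _similar_to(old_name) if mode == "similar" else _dissimilar_to(old_name)
        assert new_name is not None
        old_func = MATCH_ATOMS[old_name][2]
        new_func = MATCH_ATOMS[new_name][2]
        func_atom = res.get_atom(old_func)
        if func_atom is not None and old_func not in ("C", "CB"):
            func_atom.name = new_func
            func_atom.element = _element(new_func)
        res.name = new_name
        new_env[rid] = new_name

    new_gt = replace(
        gt,
        environment=[(rid, new_env[rid]) for rid, _ in env],
        heme_coords=gt.heme_coords.copy(),
        fe_coord=gt.fe_coord.copy(),
    )
    return out, new_gt


#: The canonical fixture set exercised by the test suite and written by
#: ``hemescan fixtures generate``: a His/Tyr-ligated site (globin-like
#: axial histidine plus the tyrosine ligation seen in heme-scavenging
#: proteins), a bis-His site (cytochrome-b-like), and a Cys-ligated site
#: (P450-like thiolate), each with a mixed 10 A environment shell.
CANONICAL_SPECS: tuple[FixtureSpec, ...] = (
    FixtureSpec(seed=11),
    FixtureSpec(
        seed=22,
        ligating_residues=(("HIS", 2.1), ("HIS", 2.2), ("MET", 4.0)),
        env_composition=(
            ("GLU", 2), ("PHE", 1), ("LEU", 2), ("GLN", 1), ("SER", 1), ("TRP", 1),
        ),
    ),
    FixtureSpec(
        seed=33,
        ligating_residues=(("CYS", 2.3), ("LYS", 3.9), ("PHE", 3.6)),
        env_composition=(
            ("VAL", 1), ("THR", 1), ("ASN", 1), ("TYR", 1), ("ILE", 1),
        ),
    ),
)
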