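"""Macromolecular structure input/output.

Reads PDB and mmCIF files (via gemmi) into a small internal model —
chains of residues of atoms — that the rest of the package operates on,
detects bound heme groups, and writes predicted-site PDB files that can
be opened directly in PyMOL.

Conventions:

* only the first model of a multi-model file is kept (NMR ensembles are
  not averaged);
* alternate locations are resolved to the highest-occupancy conformer
  (ties broken by altloc letter, ``A`` first);
* hydrogens and waters are dropped — all downstream geometry is
  heavy-atom only;
* the B-factor column is preserved verbatim; for AlphaFold models it
  holds the per-residue confidence (pLDDT, 0-100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "HemeGroup",
    "StructureParseError",
    "NoPolymerError",
    "DEFAULT_HEME_CODES",
    "STANDARD_AMINO_ACIDS",
    "read_structure",
    "detect_heme_groups",
    "write_site_pdb",
    "write_pml_script",
]

#: b-, c-, a- and o-type heme hetero codes recognised by default.
DEFAULT_HEME_CODES = frozenset({"HEM", "HEC", "HEA", "HEB"})

STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class NoPolymerError(StructureParseError):
    """Raised when a parsed file contains no protein residues."""


@dataclass
class Atom:
    """A heavy atom with Cartesian coordinates in Angstrom.

    ``bfactor`` carries the crystallographic B-factor for experimental
    structures and the pLDDT confidence (0-100) for AlphaFold models.
    """

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            warnings.warn(
                f"atom {self.name}: occupancy {self.occupancy} outside [0,1]; clamped"
            )
            self.occupancy = min(max(self.occupancy, 0.0), 1.0)

    def copy(self) -> "Atom":
        return replace(self, coord=self.coord.copy())


@dataclass
class Residue:
    """One residue, identified by (chain_id, seq_num, icode) in author numbering."""

    chain_id: str
    name: str
    seq_num: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def rid(self) -> tuple[str, int, str]:
        """Hashable residue identifier (chain, author seq number, insertion code)."""
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.seq_num}{self.icode}"

    def get_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.get_atom("CA")

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    def mean_bfactor(self) -> float:
        return float(np.mean([a.bfactor for a in self.atoms]))

    @property
    def is_standard_aa(self) -> bool:
        return not self.is_hetero and self.name in STANDARD_AMINO_ACIDS

    def copy(self) -> "Residue":
        return replace(self, atoms=[a.copy() for a in self.atoms])


@dataclass
class Structure:
    """A single-model macromolecular structure.

    ``source_kind`` distinguishes experimental structures, predicted
    (AlphaFold-style) models whose B-factor column holds pLDDT, and
    synthetic fixtures produced by :mod:`hemescan.fixtures`.
    """

    id: str
    residues: list[Residue] = field(default_factory=list)
    source_kind: str = "experimental"

    def __post_init__(self) -> None:
        if self.source_kind not in ("experimental", "predicted_model", "synthetic"):
            raise ValueError(f"unknown source_kind {self.source_kind!r}")

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def polymer_residues(self) -> list[Residue]:
        """Protein residues (standard and non-standard), heteros excluded."""
        return [r for r in self.residues if not r.is_hetero]

    def standard_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_standard_aa]

    def hetero_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_hetero]

    def find_residue(self, rid: tuple[str, int, str]) -> Optional[Residue]:
        for r in self.residues:
            if r.rid == rid:
                return r
        return None

    def protein_atom_coords(self) -> np.ndarray:
        """(N, 3) array of all polymer heavy-atom coordinates."""
        coords = [a.coord for r in self.polymer_residues() for a in r.atoms]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def copy(self) -> "Structure":
        return Structure(
            id=self.id,
            residues=[r.copy() for r in self.residues],
            source_kind=self.source_kind,
        )


@dataclass
class HemeGroup:
    """A bound heme: its hetero residue, its iron atom, and the matched code."""

    residue: Residue
    fe_atom: Atom
    code: str

    @property
    def fe_coord(self) -> np.ndarray:
        return self.fe_atom.coord

    def heavy_atoms(self) -> list[Atom]:
        return list(self.residue.atoms)


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(atoms: Sequence[Atom], residue_label: str) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties broken by altloc letter."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    resolved = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            chosen = group[0]
        else:
            chosen = sorted(group, key=lambda a: (-a.occupancy, a.altloc or "~"))[0]
        resolved.append(replace(chosen, altloc="", coord=chosen.coord.copy()))
    return resolved


def read_structure(
    path: str | Path,
    format_hint: Optional[str] = None,
    source_kind: Optional[str] = None,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path
        File to read.  The format is taken from ``format_hint``
        (``"pdb"`` or ``"mmcif"``) when given, otherwise inferred from
        the file by gemmi.
    source_kind
        Force the structure kind.  When omitted, files whose title
        mentions AlphaFold are tagged ``predicted_model``, everything
        else ``experimental``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"{path}: file not found")
    fmt = {None: gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}.get(format_hint)
    if fmt is None:
        raise ValueError(f"unknown format_hint {format_hint!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no coordinate model")

    st.setup_entities()
    model = st[0]  # first model only; ensembles are not averaged

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            atoms: list[Atom] = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name.upper(),
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=float(at.occ),
                        bfactor=float(at.b_iso),
                        altloc=at.altloc if at.altloc != "\0" else "",
                    )
                )
            if not atoms:
                continue
            is_het = res.het_flag == "H" if res.het_flag in ("A", "H") else (
                res.name not in STANDARD_AMINO_ACIDS
            )
            r = Residue(
                chain_id=chain.name,
                name=res.name,
                seq_num=res.seqid.num,
                icode=res.seqid.icode.strip(),
                atoms=[],
                is_hetero=is_het,
            )
            r.atoms = _resolve_altlocs(atoms, r.label)
            residues.append(r)

    if not residues:
        raise StructureParseError(f"{path}: no atoms parsed")
    if not any(r.is_standard_aa for r in residues):
        raise NoPolymerError(f"{path}: no polymer (protein) residues found")

    if source_kind is None:
        title = st.name or ""
        if "_struct.title" in st.info:
            title += " " + st.info["_struct.title"]
        source_kind = "predicted_model" if "ALPHAFOLD" in title.upper() else "experimental"

    return Structure(id=st.name or path.stem, residues=residues, source_kind=source_kind)


# ---------------------------------------------------------------------------
# heme detection


def detect_heme_groups(
    s: Structure, heme_codes: Iterable[str] = DEFAULT_HEME_CODES
) -> list[HemeGroup]:
    """Find bound hemes: hetero residues with a recognised code and an Fe atom.

    Residues matching a heme code but lacking iron are skipped with a
    warning (a stripped or partially modelled cofactor is not a usable
    template source).  Output order is deterministic: (chain, seq_num).
    """
    codes = {c.upper() for c in heme_codes}
    groups: list[HemeGroup] = []
    for res in s.hetero_residues():
        if res.name.upper() not in codes:
            continue
        fe = next((a for a in res.atoms if a.element == "FE" or a.name == "FE"), None)
        if fe is None:
            warnings.warn(f"{s.id} {res.label}: heme residue without Fe atom; skipped")
            continue
        groups.append(HemeGroup(residue=res, fe_atom=fe, code=res.name.upper()))
    groups.sort(key=lambda g: (g.residue.chain_id, g.residue.seq_num, g.residue.icode))
    return groups


# ---------------------------------------------------------------------------
# writing


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14 for 1-letter elements
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _pdb_atom_line(
    serial: int,
    atom: Atom,
    res_name: str,
    chain_id: str,
    seq_num: int,
    icode: str,
    hetero: bool,
) -> str:
    record = "HETATM" if hetero else "ATOM  "
    x, y, z = atom.coord
    return (
        f"{record}{serial:5d} {_format_atom_name(atom.name, atom.element)} "
        f"{res_name:>3s} {chain_id:1s}{seq_num:4d}{icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
        f"          {atom.element:>2s}"
    )


def _free_chain_id(s: Structure) -> str:
    used = {r.chain_id for r in s.residues}
    for c in "ZYXWVUTSRQPONMLKJIHGFEDCBA0123456789":
        if c not in used:
            return c
    return "z"


def structure_to_pdb_string(s: Structure, remarks: Sequence[str] = ()) -> str:
    """Serialize a Structure as PDB text (coordinates at 3-decimal precision)."""
    lines = [f"REMARK 999 {r}"[:80] for r in remarks]
    serial = 0
    last_chain = None
    for res in s.residues:
        if last_chain is not None and res.chain_id != last_chain and not res.is_hetero:
            pass
        last_chain = res.chain_id
        for atom in res.atoms:
            serial += 1
            lines.append(
                _pdb_atom_line(
                    serial, atom, res.name, res.chain_id, res.seq_num, res.icode,
                    res.is_hetero,
                )
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure_pdb(s: Structure, path: str | Path, remarks: Sequence[str] = ()) -> None:
    Path(path).write_text(structure_to_pdb_string(s, remarks))


def write_site_pdb(
    query: Structure,
    placed_heme: Sequence[Atom],
    matched_residues: Sequence[Residue],
    path: str | Path,
    scores: Optional[dict] = None,
) -> None:
    """Write a predicted-site PDB: query + placed heme + a remark block.

    The query coordinates are written unchanged; the transferred heme is
    appended as HETATM records (residue ``HEM``) on a chain id unused by
    the query.  The remark block lists the matched template residues and
    any scores supplied, so the file is self-describing when opened in
    PyMOL.
    """
    for a in placed_heme:
        if not np.all(np.isfinite(a.coord)):
            raise ValueError("placed heme contains non-finite coordinates")
    remarks = ["HEMESCAN PREDICTED HEME BINDING SITE"]
    for r in matched_residues:
        remarks.append(f"MATCHED RESIDUE {r.chain_id} {r.name} {r.seq_num}{r.icode}")
    for key, val in (scores or {}).items():
        remarks.append(f"SCORE {key.upper()} {val}")

    heme_chain = _free_chain_id(query)
    out = query.copy()
    out.residues.append(
        Residue(
            chain_id=heme_chain,
            name="HEM",
            seq_num=1,
            atoms=[a.copy() for a in placed_heme],
            is_hetero=True,
        )
    )
    write_structure_pdb(out, path, remarks=remarks)


def write_pml_script(site_pdb_path: str | Path, matched_residues: Sequence[Residue],
                     path: str | Path) -> None:
    """Write a cosmetic PyMOL script that loads a site file and colours the match."""
    lines = [
        f"load {Path(site_pdb_path).name}",
        "hide everything",
        "show cartoon, polymer",
        "show sticks, resn HEM",
        "color grey80, polymer",
        "color orange, resn HEM",
    ]
    for r in matched_residues:
        sel = f"chain {r.chain_id} and resi {r.seq_num}{r.icode}"
        lines.append(f"show sticks, ({sel})")
        lines.append(f"color red, ({sel})")
    lines.append("zoom resn HEM, 8")
    Path(path).write_text("\n".join(lines) + "\n")
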