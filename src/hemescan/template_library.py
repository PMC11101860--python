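"""Extraction and storage of 3-residue heme-binding templates.

A template is the 3D conformation of a residue triplet observed in
contact with a bound heme in a source structure.  Each template records:

* three template residues, each represented by three named *match
  atoms* (Calpha, Cbeta and one residue-specific functional atom; Gly
  and Ala, which lack the full set, fall back to backbone atoms);
* every heavy atom of the source heme, in the same coordinate frame,
  with the iron flagged — so a geometric match can transfer the whole
  heme pose into a query structure;
* the local environment: all residues whose Calpha lies within the
  environment radius (10 A by default) of any of the nine match atoms.
  The environment is what the scoring module compares between source
  and query.

Libraries serialize to a versioned JSON document so that a build is
diffable and reproducible; the extraction parameters travel with the
library.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import HemeGroup, Residue, Structure

__all__ = [
    "MATCH_ATOMS",
    "LibraryParams",
    "TemplateResidue",
    "EnvironmentResidue",
    "HemeTemplate",
    "TemplateLibrary",
    "LibraryFormatError",
    "extract_contact_residues",
    "build_templates",
    "save_library",
    "load_library",
]

LIBRARY_FORMAT_VERSION = "1"

#: Match atoms per residue type: (Calpha, Cbeta, functional atom), except
#: Gly (no side chain) which uses N/CA/C and Ala (functional atom would
#: duplicate Cbeta) which uses N/CA/CB.
MATCH_ATOMS: dict[str, tuple[str, str, str]] = {
    "GLY": ("N", "CA", "C"),
    "ALA": ("N", "CA", "CB"),
    "HIS": ("CA", "CB", "NE2"),
    "CYS": ("CA", "CB", "SG"),
    "TYR": ("CA", "CB", "OH"),
    "MET": ("CA", "CB", "SD"),
    "LYS": ("CA", "CB", "NZ"),
    "ARG": ("CA", "CB", "CZ"),
    "ASP": ("CA", "CB", "CG"),
    "GLU": ("CA", "CB", "CD"),
    "SER": ("CA", "CB", "OG"),
    "THR": ("CA", "CB", "OG1"),
    "ASN": ("CA", "CB", "CG"),
    "GLN": ("CA", "CB", "CD"),
    "TRP": ("CA", "CB", "NE1"),
    "PHE": ("CA", "CB", "CZ"),
    "LEU": ("CA", "CB", "CG"),
    "ILE": ("CA", "CB", "CG1"),
    "VAL": ("CA", "CB", "CG1"),
    "PRO": ("CA", "CB", "CG"),
}

_MIN_PAIR_DIST = 0.5   # A; match atoms closer than this are degenerate
_MIN_TRIANGLE_AREA = 0.1  # A^2


class LibraryFormatError(ValueError):
    """Raised on library files with a wrong version or broken schema."""


@dataclass(frozen=True)
class LibraryParams:
    """Extraction parameters; stored with the library for reproducibility."""

    contact_cutoff: float = 4.0     # A, heavy-atom to heavy-atom
    env_radius: float = 10.0        # A, Calpha to any match atom
    max_contacts: int = 8           # nearest contact residues considered
    max_triplets: int = 56          # cap on templates per heme
    match_atom_scheme: str = "ca-cb-functional"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LibraryParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise LibraryFormatError(f"unknown library params: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TemplateResidue:
    """One template residue: its type and its three named match atoms."""

    res_name: str
    atom_names: tuple[str, str, str]
    coords: np.ndarray          # (3, 3)
    source_id: tuple[str, int, str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3, 3)
        d = cdist(self.coords, self.coords)
        if d[np.triu_indices(3, 1)].min() <= _MIN_PAIR_DIST:
            raise ValueError(f"{self.res_name} {self.source_id}: match atoms nearly coincident")
        area = 0.5 * np.linalg.norm(
            np.cross(self.coords[1] - self.coords[0], self.coords[2] - self.coords[0])
        )
        if area <= _MIN_TRIANGLE_AREA:
            raise ValueError(f"{self.res_name} {self.source_id}: match atoms collinear")


@dataclass
class EnvironmentResidue:
    """An environment residue, represented by its Calpha position."""

    res_name: str
    rep_coord: np.ndarray
    source_id: tuple[str, int, str]

    def __post_init__(self) -> None:
        self.rep_coord = np.asarray(self.rep_coord, dtype=float).reshape(3)


@dataclass
class HemeTemplate:
    """A 3-residue heme-binding template with heme pose and environment."""

    template_id: str
    source_structure_id: str
    residues: tuple[TemplateResidue, TemplateResidue, TemplateResidue]
    heme_atom_names: list[str]
    heme_coords: np.ndarray      # (M, 3), same frame as residue coords
    fe_index: int                # row of heme_coords holding the iron
    environment: list[EnvironmentResidue] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.heme_coords = np.asarray(self.heme_coords, dtype=float).reshape(-1, 3)
        if len(self.heme_atom_names) != len(self.heme_coords):
            raise ValueError("heme atom names and coordinates disagree in length")
        if not 0 <= self.fe_index < len(self.heme_coords):
            raise ValueError("fe_index out of range: iron missing from heme atoms")

    @property
    def type_key(self) -> tuple[str, str, str]:
        return tuple(sorted(r.res_name for r in self.residues))  # type: ignore[return-value]

    @property
    def fe_coord(self) -> np.ndarray:
        return self.heme_coords[self.fe_index]

    def match_atom_coords(self) -> np.ndarray:
        """The 9 match-atom coordinates, residue-major order. Shape (9, 3)."""
        return np.vstack([r.coords for r in self.residues])

    def environment_ids(self) -> set[tuple[str, int, str]]:
        return {e.source_id for e in self.environment}


@dataclass
class TemplateLibrary:
    templates: list[HemeTemplate]
    params: LibraryParams = field(default_factory=LibraryParams)

    @property
    def index(self) -> dict[tuple[str, str, str], list[str]]:
        """type_key -> template ids, in library order."""
        idx: dict[tuple[str, str, str], list[str]] = {}
        for t in self.templates:
            idx.setdefault(t.type_key, []).append(t.template_id)
        return idx

    def __len__(self) -> int:
        return len(self.templates)


# ---------------------------------------------------------------------------
# extraction


def extract_contact_residues(
    s: Structure, h: HemeGroup, contact_cutoff: float = 4.0
) -> list[Residue]:
    """Standard amino acids with >= 1 heavy atom within ``contact_cutoff``
    of any heme heavy atom, sorted by minimum distance (ascending, ties by
    residue id)."""
    heme_xyz = np.array([a.coord for a in h.heavy_atoms()]).reshape(-1, 3)
    hits: list[tuple[float, Residue]] = []
    for res in s.standard_residues():
        xyz = res.heavy_coords()
        if xyz.size == 0:
            continue
        dmin = float(cdist(xyz, heme_xyz).min())
        if dmin <= contact_cutoff:
            hits.append((dmin, res))
    hits.sort(key=lambda t: (t[0], t[1].rid))
    return [r for _, r in hits]


def _template_residue(res: Residue) -> Optional[TemplateResidue]:
    names = MATCH_ATOMS.get(res.name)
    if names is None:
        return None
    atoms = [res.get_atom(n) for n in names]
    if any(a is None for a in atoms):
        return None   # missing side-chain atoms disqualify the residue
    try:
        return TemplateResidue(
            res_name=res.name,
            atom_names=names,
            coords=np.array([a.coord for a in atoms]),  # type: ignore[union-attr]
            source_id=res.rid,
        )
    except ValueError:
        return None   # degenerate geometry disqualifies too


def _environment_for(
    s: Structure,
    match_xyz: np.ndarray,
    template_ids: set[tuple[str, int, str]],
    env_radius: float,
) -> list[EnvironmentResidue]:
    env: list[EnvironmentResidue] = []
    for res in s.polymer_residues():
        if res.rid in template_ids:
            continue
        ca = res.ca
        if ca is None:
            continue
        if cdist(ca.coord.reshape(1, 3), match_xyz).min() <= env_radius:
            env.append(EnvironmentResidue(res.name, ca.coord.copy(), res.rid))
    env.sort(key=lambda e: e.source_id)
    return env


def build_templates(
    s: Structure, h: HemeGroup, params: LibraryParams = LibraryParams()
) -> list[HemeTemplate]:
    """Build templates from all triplets of the nearest contact residues.

    Contact residues missing any of their match atoms are disqualified.
    Triplets are formed from the nearest ``max_contacts`` residues,
    nearest-first, capped at ``max_triplets`` per heme.  With fewer than
    three usable contacts an empty list is returned with a warning.
    """
    contacts = extract_contact_residues(s, h, params.contact_cutoff)
    usable: list[tuple[Residue, TemplateResidue]] = []
    for res in contacts:
        tr = _template_residue(res)
        if tr is not None:
            usable.append((res, tr))
    if len(usable) < 3:
        warnings.warn(
            f"{s.id} {h.residue.label}: only {len(usable)} usable contact residues; "
            "no templates built"
        )
        return []
    usable = usable[: params.max_contacts]

    heme_atoms = h.heavy_atoms()
    heme_names = [a.name for a in heme_atoms]
    heme_xyz = np.array([a.coord for a in heme_atoms]).reshape(-1, 3)
    fe_index = next(
        i for i, a in enumerate(heme_atoms) if a is h.fe_atom or a.name == h.fe_atom.name
    )

    templates: list[HemeTemplate] = []
    heme_tag = f"{h.residue.chain_id}{h.residue.seq_num}"
    for k, combo in enumerate(itertools.combinations(usable, 3)):
        if k >= params.max_triplets:
            break
        trs = tuple(tr for _, tr in combo)
        template_ids = {tr.source_id for tr in trs}
        t = HemeTemplate(
            template_id=f"{s.id}|{heme_tag}|t{k:03d}",
            source_structure_id=s.id,
            residues=trs,  # type: ignore[arg-type]
            heme_atom_names=list(heme_names),
            heme_coords=heme_xyz.copy(),
            fe_index=fe_index,
        )
        t.environment = _environment_for(
            s, t.match_atom_coords(), template_ids, params.env_radius
        )
        templates.append(t)
    return templates


def build_library(
    structures: Sequence[Structure],
    heme_codes,
    params: LibraryParams = LibraryParams(),
) -> tuple[TemplateLibrary, list[dict]]:
    """Build a library from heme-bound structures; returns (library, build log)."""
    from .structure_io import detect_heme_groups

    templates: list[HemeTemplate] = []
    log: list[dict] = []
    for s in structures:
        groups = detect_heme_groups(s, heme_codes)
        n_before = len(templates)
        for h in groups:
            templates.extend(build_templates(s, h, params))
        log.append(
            {"structure": s.id, "hemes": len(groups), "templates": len(templates) - n_before}
        )
    return TemplateLibrary(templates=templates, params=params), log


# ---------------------------------------------------------------------------
# serialization


def _template_to_dict(t: HemeTemplate) -> dict:
    return {
        "template_id": t.template_id,
        "source_structure_id": t.source_structure_id,
        "residues": [
            {
                "res_name": r.res_name,
                "atom_names": list(r.atom_names),
                "coords": r.coords.tolist(),
                "source_id": list(r.source_id),
            }
            for r in t.residues
        ],
        "heme_atom_names": list(t.heme_atom_names),
        "heme_coords": t.heme_coords.tolist(),
        "fe_index": t.fe_index,
        "environment": [
            {
                "res_name": e.res_name,
                "rep_coord": e.rep_coord.tolist(),
                "source_id": list(e.source_id),
            }
            for e in t.environment
        ],
    }


def _template_from_dict(d: dict) -> HemeTemplate:
    residues = tuple(
        TemplateResidue(
            res_name=r["res_name"],
            atom_names=tuple(r["atom_names"]),
            coords=np.array(r["coords"]),
            source_id=(r["source_id"][0], int(r["source_id"][1]), r["source_id"][2]),
        )
        for r in d["residues"]
    )
    t = HemeTemplate(
        template_id=d["template_id"],
        source_structure_id=d["source_structure_id"],
        residues=residues,  # type: ignore[arg-type]
        heme_atom_names=list(d["heme_atom_names"]),
        heme_coords=np.array(d["heme_coords"]),
        fe_index=int(d["fe_index"]),
    )
    t.environment = [
        EnvironmentResidue(
            res_name=e["res_name"],
            rep_coord=np.array(e["rep_coord"]),
            source_id=(e["source_id"][0], int(e["source_id"][1]), e["source_id"][2]),
        )
        for e in d["environment"]
    ]
    return t


def save_library(lib: TemplateLibrary, path: str | Path) -> None:
    doc = {
        "format_version": LIBRARY_FORMAT_VERSION,
        "params": lib.params.to_dict(),
        "templates": [_template_to_dict(t) for t in lib.templates],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_library(path: str | Path) -> TemplateLibrary:
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise LibraryFormatError(f"{path}: cannot parse library file: {exc}") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise LibraryFormatError(f"{path}: not a template library file")
    version = doc["format_version"]
    if version != LIBRARY_FORMAT_VERSION:
        raise LibraryFormatError(
            f"{path}: library format version {version!r}; "
            f"this build reads version {LIBRARY_FORMAT_VERSION!r}"
        )
    params = LibraryParams.from_dict(doc["params"])
    templates = [_template_from_dict(d) for d in doc["templates"]]
    return TemplateLibrary(templates=templates, params=params)
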