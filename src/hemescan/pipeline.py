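"""End-to-end prediction pipeline: scan, score, cluster, assess, report.

Glue between the stage modules, used by both the CLI and the tests.
Reports are plain dictionaries/TSV rows with the full configuration and
library parameters embedded, and are byte-identical across repeat runs
with equal inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .config import RunConfig
from .matcher import ScanResult, scan
from .scoring import ScoredMatch, SiteCluster, cluster_sites, score_matches
from .site_assessment import SiteAssessment, assess_site
from .structure_io import Atom, Residue, Structure, write_site_pdb, write_pml_script
from .template_library import TemplateLibrary

__all__ = ["SiteReport", "PredictionReport", "predict_sites", "write_reports"]

TSV_COLUMNS = [
    "rank", "template_id", "source_structure_id",
    "q_res1", "q_res2", "q_res3", "rmsd",
    "fe_x", "fe_y", "fe_z",
    "n_env", "n_identical", "n_similar", "n_unmatched", "score",
    "fraction_matched", "bias_applied", "n_members",
    "clash_score", "burial_fraction", "confidence_flag", "ligand_candidates",
]


@dataclass
class SiteReport:
    cluster: SiteCluster
    assessment: SiteAssessment

    @property
    def representative(self) -> ScoredMatch:
        return self.cluster.representative

    def to_row(self) -> dict:
        rep = self.representative
        m = rep.match
        fe = self.cluster.fe_centroid
        ligands = ";".join(
            f"{c.res_name}{c.residue_id[1]}.{c.donor_atom}:{c.distance_to_fe:.2f}:{c.plausibility}"
            for c in self.assessment.ligand_candidates
        )
        return {
            "rank": self.cluster.rank,
            "template_id": m.template_id,
            "source_structure_id": m.source_structure_id,
            "q_res1": _rid_str(m.query_residues[0], m.query_res_names[0]),
            "q_res2": _rid_str(m.query_residues[1], m.query_res_names[1]),
            "q_res3": _rid_str(m.query_residues[2], m.query_res_names[2]),
            "rmsd": f"{m.rmsd:.6f}",
            "fe_x": f"{fe[0]:.4f}",
            "fe_y": f"{fe[1]:.4f}",
            "fe_z": f"{fe[2]:.4f}",
            "n_env": rep.env.n_env,
            "n_identical": rep.env.n_identical,
            "n_similar": rep.env.n_similar,
            "n_unmatched": rep.env.n_unmatched,
            "score": _num(rep.env.score),
            "fraction_matched": f"{rep.env.fraction_matched:.4f}",
            "bias_applied": str(rep.env.bias_applied).lower(),
            "n_members": len(self.cluster.members),
            "clash_score": f"{self.assessment.clash_score:.4f}",
            "burial_fraction": f"{self.assessment.burial_fraction:.4f}",
            "confidence_flag": self.assessment.confidence_flag,
            "ligand_candidates": ligands,
        }

    def to_json_dict(self) -> dict:
        row = self.to_row()
        row["ligand_candidates"] = [
            {
                "chain": c.residue_id[0],
                "seq_num": c.residue_id[1],
                "icode": c.residue_id[2],
                "res_name": c.res_name,
                "donor_atom": c.donor_atom,
                "distance_to_fe": round(c.distance_to_fe, 4),
                "plausibility": c.plausibility,
            }
            for c in self.assessment.ligand_candidates
        ]
        return row


def _rid_str(rid: tuple[str, int, str], name: str) -> str:
    return f"{rid[0]}/{name}{rid[1]}{rid[2]}"


def _num(x: float) -> str:
    return f"{x:.4f}".rstrip("0").rstrip(".") if x != int(x) else str(int(x))


@dataclass
class PredictionReport:
    query_id: str
    config: RunConfig
    library_params: dict
    n_templates: int
    n_matches: int
    skips: dict
    sites: list[SiteReport] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "config": self.config.to_dict(),
            "library_params": self.library_params,
            "n_templates": self.n_templates,
            "n_matches": self.n_matches,
            "n_sites": len(self.sites),
            "skips": dict(sorted(self.skips.items())),
            "sites": [s.to_json_dict() for s in self.sites],
        }

    def to_tsv(self) -> str:
        lines = ["\t".join(TSV_COLUMNS)]
        for s in self.sites:
            row = s.to_row()
            lines.append("\t".join(str(row[c]) for c in TSV_COLUMNS))
        return "\n".join(lines) + "\n"


def predict_sites(
    query: Structure,
    lib: TemplateLibrary,
    config: RunConfig = RunConfig(),
) -> PredictionReport:
    """Run the full search on one query structure.

    Scans every template, scores every geometric match by environment
    similarity, clusters matches into sites by placed-iron proximity,
    and assesses each site (ligand candidates, sterics, confidence).
    """
    result: ScanResult = scan(query, lib, config.matcher)
    scored = score_matches(result.matches, lib, query, config.scoring)
    clusters = cluster_sites(scored, config.scoring.cluster_radius)
    sites: list[SiteReport] = []
    for cl in clusters:
        rep = cl.representative.match
        assessment = assess_site(
            query,
            rep.placed_heme_names,
            rep.placed_heme_coords,
            rep.placed_fe,
            rep.query_residues,
            config.assessment,
        )
        sites.append(SiteReport(cluster=cl, assessment=assessment))
    return PredictionReport(
        query_id=query.id,
        config=config,
        library_params=lib.params.to_dict(),
        n_templates=len(lib),
        n_matches=len(result.matches),
        skips=dict(result.skips),
        sites=sites,
    )


def write_reports(
    report: PredictionReport,
    query: Structure,
    out_prefix: str | Path,
    top_n_pdb: Optional[int] = None,
    pml: bool = False,
) -> list[Path]:
    """Write TSV + JSON reports and top-N predicted-site PDB files.

    Returns the list of files written.  TSV and JSON contain the same
    numbers; site PDBs carry the query unchanged plus the placed heme.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tsv_path = out_prefix.with_suffix(".tsv")
    tsv_path.write_text(report.to_tsv())
    written.append(tsv_path)

    json_path = out_prefix.with_suffix(".json")
    json_path.write_text(json.dumps(report.to_json_dict(), indent=1, sort_keys=True))
    written.append(json_path)

    n = len(report.sites) if top_n_pdb is None else min(top_n_pdb, len(report.sites))
    for site in report.sites[:n]:
        rep = site.representative.match
        heme_atoms = [
            Atom(name=nm, element=_heme_element(nm), coord=c)
            for nm, c in zip(rep.placed_heme_names, rep.placed_heme_coords)
        ]
        matched: list[Residue] = []
        for rid in rep.query_residues:
            res = query.find_residue(rid)
            if res is not None:
                matched.append(res)
        pdb_path = out_prefix.parent / f"{out_prefix.name}_site{site.cluster.rank}.pdb"
        write_site_pdb(
            query, heme_atoms, matched, pdb_path,
            scores={"rank": site.cluster.rank, "score": site.representative.score,
                    "rmsd": round(rep.rmsd, 6)},
        )
        written.append(pdb_path)
        if pml:
            pml_path = pdb_path.with_suffix(".pml")
            write_pml_script(pdb_path, matched, pml_path)
            written.append(pml_path)
    return written


def _heme_element(atom_name: str) -> str:
    nm = atom_name.strip().upper()
    if nm.startswith("FE"):
        return "FE"
    for ch in nm:
        if ch.isalpha():
            return ch
    return "C"
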