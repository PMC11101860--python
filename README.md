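# hemescan

Template-based search for heme-binding sites in protein structures.

Heme (iron-protoporphyrin IX) is not only the tightly bound cofactor of
globins, cytochromes and heme enzymes — it also binds *transiently* to
regulatory proteins (transcription factors, circadian-clock proteins, ion
channels), usually with lower affinity, looser ligation and without a
classical buried heme pocket. Those regulatory sites are hard to find
experimentally, and sequence-only predictors give residue lists that are hard
to interpret structurally. `hemescan` is for structural biologists and
bioinformaticians who have a structure — a crystal structure or an AlphaFold
model — and want concrete, visualizable candidate heme poses in it.

## Method

The search follows the reverse-template idea used for ligand-binding-site
annotation:

1. **Template extraction.** From each heme-bound source structure, take the
   residues in heavy-atom contact (≤ 4 Å) with the heme and form 3-residue
   templates. Each template residue is reduced to three *match atoms*
   (Cα, Cβ and one residue-specific functional atom, e.g. His → NE2,
   Cys → SG, Tyr → OH); the template also stores the full heme pose and its
   10 Å *environment* (every residue whose Cα lies within 10 Å of the nine
   match atoms).
2. **Scanning.** Every template is scanned against the query: all residue
   triplets of matching types (pre-filtered by pairwise Cα–Cα distances) are
   superposed onto the template's match atoms with a Kabsch least-squares
   fit; matches with RMSD ≤ 2 Å are kept, and the source heme is transferred
   into the query frame through the fitted transform — giving a concrete
   predicted pose, not just a residue list.
3. **Environment scoring.** Each match is scored by how many of the
   template's environment residues occur in equivalent 3D positions in the
   query: `score = w_id·n_identical + w_sim·n_similar` (defaults 2 and 1),
   where *identical* means the same residue type and *similar* the same
   physicochemical group. The homology enhancement such servers normally
   apply is **off by default** — for heme searching it hides analogous sites
   in non-homologous proteins — but remains available as a toggle.
4. **Sites and assessment.** Matches are clustered by the position of the
   placed iron (5 Å radius) into ranked sites, and each site is assessed:
   axial-ligand candidates (His/Cys/Tyr/Met/Lys donor atoms near the Fe,
   banded as bonding ≤ 3 Å / near ≤ 6 Å / far), a soft van-der-Waals clash
   score and burial fraction for the pose, and, for AlphaFold models, a
   confidence flag from the mean pLDDT of the site residues (< 50 very low,
   < 70 low).

Docking-based pose refinement and building a full-PDB template sweep are out
of scope; libraries are built from the heme-bound structures you provide.

## Worked example

The package ships a generator for synthetic heme proteins with planted,
fully known binding sites:

```sh
hemescan fixtures generate -d fx
hemescan build-library fx/toy-11.pdb -o heme_lib.json
hemescan scan fx/toy-11.pdb heme_lib.json -o out/toy11
```

which prints

```
wrote 1 templates to heme_lib.json
1 site(s); rank 1: score 16, Fe at (-0.00, -0.00, 0.00)
```

and writes `out/toy11.tsv`, `out/toy11.json` and `out/toy11_site1.pdb` (the
query plus the placed heme, ready for PyMOL). Selected TSV columns:

```
rank  rmsd      n_identical  n_similar  fraction_matched  burial_fraction  ligand_candidates
1     0.000000  8            0          1.0000            1.0000           HIS101.NE2:2.10:bonding;TYR102.OH:2.50:bonding
```

This is a self-scan, so the numbers are the exact ceiling: the triplet
superposes at RMSD 0, all 8 environment residues are identical
(score = 2 × 8 = 16), the pose is fully buried, and the planted axial
ligands (His NE2 at 2.10 Å, Tyr OH at 2.50 Å from the iron) are reported in
the bonding band. On a real query the same columns tell you how geometrically
close the match is, how much of the source environment is conserved, and
whether the pose is sterically and chemically plausible.

Scanning a query against a library built from *other* structures works the
same way: `hemescan scan query.pdb library.json -o out/query`
(add `--source-kind predicted_model` for AlphaFold inputs so pLDDT flags are
reported). `hemescan assess` runs the assessment alone on any heme pose.

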