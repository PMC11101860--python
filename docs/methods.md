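# Methods

## Model and assumptions

`hemescan` treats heme binding as a *local geometric* recognition problem: a
binding site is characterised by the 3D arrangement of a small number of
contacting side chains, and a site in a new structure is found by rigidly
superposing observed arrangements (templates) onto candidate residue
triplets. The underlying assumptions are:

* heme recognition is dominated by a few contacting residues whose relative
  geometry is conserved enough to survive a rigid-body comparison;
* the rest of the pocket can be summarised by residue *identity* within
  10 Å, compared in 3D rather than in sequence — so analogous sites in
  non-homologous proteins can still score;
* side-chain flexibility, protonation and binding energetics are ignored.
  A transferred pose is a hypothesis to be inspected (and, if needed,
  refined by docking elsewhere), not a minimised complex.

Consequences worth keeping in mind: a site whose contacting residues moved
more than the RMSD cutoff apart (apo-form rearrangement, poor model
geometry) is invisible to the search, as is any binding mode absent from the
template library. Both failure modes are intrinsic to template matching, not
implementation accidents.

## Pipeline stages and parameters

All parameters live in `RunConfig` and are embedded verbatim in every
report. Units are Angstrom unless stated.

**Template extraction** (`template_library`)

| parameter | default | role |
|---|---|---|
| `contact_cutoff` | 4.0 | heavy-atom contact defining site residues; the standard ligand-contact distance |
| `env_radius` | 10.0 | Cα-to-match-atom radius of the scored environment |
| `max_contacts` | 8 | nearest contacts considered for triplets |
| `max_triplets` | 56 | cap per heme (= C(8,3)); bounds library size deterministically |

Each template residue contributes three match atoms: Cα, Cβ and one
residue-specific functional atom (His NE2, Cys SG, Tyr OH, Met SD, Lys NZ,
Arg CZ, Asp CG, Glu CD, Ser OG, Thr OG1, Asn CG, Gln CD, Trp NE1, Phe CZ,
Leu CG, Ile CG1, Val CG1, Pro CG). Gly has no side chain and uses N/CA/C;
Ala's functional atom would duplicate Cβ, so it uses N/CA/CB. Residues
missing a match atom, or with (near-)collinear match atoms (pairwise
distance ≤ 0.5 Å or triangle area ≤ 0.1 Å²), are disqualified rather than
patched. Hemes are recognised by hetero code ({HEM, HEC, HEA, HEB} by
default, configurable) and must contain an iron atom.

**Matching** (`matcher`)

| parameter | default | role |
|---|---|---|
| `rmsd_max` | 2.0 | cutoff over the 9 superposed match atoms |
| `pair_tol` | 1.5 | Cα–Cα distance prune on candidate triplets |
| `allow_similar_triplets` | off | identity required for triplet typing |

Superposition is the classic Kabsch SVD fit with the determinant
correction, so a reflection is never returned; (near-)collinear point sets
raise an explicit degeneracy error instead of returning an arbitrary
rotation. Triplet correspondence is ordered — a single geometric site can
match in up to 3! correspondences, which later collapse into one cluster —
because this is the simplest scheme that is provably complete.

The pairwise-distance prune never discards a candidate whose per-atom
displacements stay below about `pair_tol`/2, which covers the noise regime
the package is validated in (σ = 0.3 Å); in an adversarial worst case a
match at the RMSD cutoff could concentrate its error in one residue and
evade the prune. `matcher.brute_force_scan` is the exhaustive reference
without the prune; the test suite verifies exact agreement between the two
on every fixture, and it remains available for desk-scale queries where
certainty matters more than speed.

**Scoring** (`scoring`)

| parameter | default | role |
|---|---|---|
| `w_id`, `w_sim` | 2.0, 1.0 | weights of identical / similar environment residues |
| `env_tol` | 3.0 | mapped-Cα to query-Cα tolerance for "equivalent position" |
| `bias_enabled`, `bias_beta` | off, 1.0 | homology enhancement toggle |
| `cluster_radius` | 5.0 | placed-iron radius merging matches into sites |

The 2:1 weight ratio encodes only the ordering identical > similar > absent
without pretending more precision exists. Environment residues are assigned
one-to-one to query Cαs greedily by ascending distance (deterministic
tie-breaks), so one query residue cannot satisfy two template residues.
Similarity groups: {D,E}, {K,R,H}, {F,Y,W}, {I,L,V,M}, {S,T}, {N,Q}, {A,G},
{C}, {P}. Non-standard polymer residues may occupy a position but always
count as dissimilar. The homology bias multiplies the score by
`1 + β·n_identical/n_env`; this functional form is a stand-in — the point of
carrying it is that "bias removed" (the default, appropriate for heme
searches across non-homologs) is a testable toggle, not an absence.
Clustering is greedy best-first on placed-iron positions with centroid
updates; 5 Å is about half a heme's width, enough to separate adjacent but
distinct sites. Ranking is by raw representative score; no E-value is
computed.

**Assessment** (`site_assessment`)

Donor atoms screened: His ND1 *and* NE2 (reported separately — the two ring
nitrogens are chemically distinct ligation options), Cys SG, Tyr OH, Met SD,
Lys NZ, within 8 Å of the placed iron. Plausibility bands: bonding ≤ 3.0 Å
(Fe–N/O/S coordination bonds are ~1.9–2.6 Å), near ≤ 6.0 Å (compatible with
ligation after modest rearrangement), far beyond. The clash score sums
`max(0, 0.7·(r₁+r₂) − d)` over heme/protein atom pairs with fixed vdW radii
(C 1.70, N 1.55, O 1.52, S 1.80, Fe 1.40); the 0.7 overlap factor makes it
a triage for gross steric impossibility, deliberately blind to normal
contact distances. Burial fraction is the share of heme atoms with a
protein atom within 5 Å — reported, not thresholded, since no quantitative
surface-site feasibility criterion is established. Confidence flags apply
AlphaFold's published pLDDT bands (< 50 very low, < 70 low) to the mean
over the matched triplet plus the ligand candidates, and only for
structures tagged as predicted models.

**I/O conventions** (`structure_io`): first model only; altlocs resolved to
highest occupancy (ties → letter A); hydrogens and waters dropped; residues
identified by author numbering throughout; B-factors preserved verbatim.
Output PDBs round-trip at the format's 3-decimal precision.

## The synthetic fixture generator

`fixtures.make_toy_heme_protein` builds test structures from an idealized
planar heme (a synthetic porphine-style table of 24 heavy atoms + Fe —
invented coordinates, taken from no database entry), ligating residues whose
donor atoms are placed at exactly the requested Fe distances (axial first,
then 45°-tilted directions), an environment shell of chosen residue types
with Cαs inside the 10 Å rule but outside the 4 Å contact shell, and a decoy
helix ≥ 15 Å away containing triplet-type look-alikes. Placement is fully
deterministic per seed; infeasible requests (e.g. a ligand driven into the
porphyrin ring) raise an error rather than emitting a broken structure.
`perturb_structure` adds seeded isotropic Gaussian noise;
`mutate_environment` renames environment residues within or outside their
similarity group while leaving geometry untouched, so expected score changes
are exact multiples of the weights.

What the fixtures emulate: the *geometry* the algorithm consumes — contact
distances, a populated 10 Å shell, decoy triplets, coordinate error, pLDDT
columns. What they do not emulate: real side-chain rotamers and packing,
realistic folds, heme propionates/vinyls, partial occupancy, or the
redundancy structure of a real template library. Passing tests therefore
demonstrate algorithmic correctness (the right matches found, scored and
ranked, exactly as specified), not predictive accuracy on real proteins —
the one real-data check (Tyr161–Fe ≤ 2.7 Å in heme-bound human serum
albumin, PDB 1N5U) runs when that file is supplied by the user, since real
crystallographic data is not bundled.

Validation problem sizes were chosen to keep the whole suite near-instant
while exercising every code path: three canonical fixtures of ~30 residues
(His/Tyr-, bis-His- and Cys-ligated sites), 100 noise trials at σ = 0.3 Å,
and 20 × 1000 random-transform comparisons for the superposition.

## Known limitations

* Template libraries are only as good as their inputs; no redundancy
  clustering across homologous sources is performed.
* The score is not normalised across templates with different environment
  sizes (the matched fraction is reported alongside the raw score).
* No flexibility: rigid templates, rigid query, no rotamer search.
* Cys-Pro (CP) motif sites, under-represented among heme-bound structures
  and often in low-confidence model regions, are expected to be missed —
  the pLDDT flag exists precisely to make the second half of that problem
  visible.
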