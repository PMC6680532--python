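# Methods

## The model

A druggable binding site (DBS) is an equivalence class of ligand-proximity
pockets observed across homologous protein chains.  The pipeline's stages
and their assumptions:

**Ligand space.**  Ligands are parsed from SMILES (RDKit).  Validity
excludes covalent binders, additives/salts/metals/solvents (editable
exclusion list in `src/promisite/data/exclusions.csv`), peptides of ≥ 11
residues and oligonucleotides of ≥ 4 nucleotides.  Drug-likeness is a
data-driven rule set defaulting to Rings ≤ 6, RotatableB ≤ 11 and
0.1 ≤ ratioH/C ≤ 1.11 (bounds inclusive); Lipinski bounds (MW ≤ 500,
logP ≤ 5, HBD ≤ 5, HBA ≤ 10) are available but off by default.  The
21-slot descriptor vector has twelve core slots (Rings, RigidB, RotatableB,
MW, logP, logD, ratioH/C, HBD, HBA, tPSA, carbon frequency, heavy atoms)
and nine reconstructed slots (charged atoms, halogens, O count, N count,
ring systems, max ring size, stereocenters, MW of largest fragment, formal
charge) labeled as such in `RECONSTRUCTED_DESCRIPTORS`.  logD is
approximated by logP — no pKa model is shipped; an external predictor can
overwrite the slot.  Fingerprints are 166-bit MACCS keys; the backend is a
single function (`MACCS_fingerprint`) so an alternative key set can be
swapped in, which matters because Tanimoto values are key-set dependent.

**Ligand clustering.**  Butina leader clustering at Tanimoto ≥ 0.8:
candidates ranked by neighbor count (ties by id), the densest unassigned
ligand becomes a centroid and absorbs its unassigned neighbors.  Every
member is within the threshold of its centroid; member–member similarity
may be lower (documented Butina property).  An agglomerative Ward
alternative (`method="ward"`) is kept for comparison because both
aggregation criteria are plausible readings of the protocol; Butina is the
default since its threshold semantics match the 0.8 cutoff directly.  The
cluster representative minimizes the inverse-variance-weighted Euclidean
distance to the cluster's mean descriptor vector (variances over the whole
dataset; zero-variance descriptors carry no weight; ties break on id).

**Chain space.**  Sequence identity uses a deterministic unit-scored global
alignment (match +1, mismatch 0, affine gaps −10/−0.5) via Biopython's
`PairwiseAligner`; the identity denominator is the shorter sequence length
(CD-HIT convention, default) or the alignment column count (strict,
configurable).  Clustering is greedy and two-pass — families at > t1 = 0.90
joining longest-first, then a second greedy pass over family representatives
at > t2 = 0.80 merging families.  Greedy clustering is not transitive in
general; planted-family recovery is exact on separable inputs, which is the
regime the tests assert.  Superposition is a Kabsch least-squares fit over
sequence-aligned CA pairs onto the cluster's longest chain (ties by id);
collinear point sets and < 3 aligned pairs are hard errors.  Import hooks
(`load_cluster_file`, `load_transform_file`) accept memberships/transforms
from external clustering or structure-alignment tools in the package's CSV/
JSON formats, for users who prefer those tools' alignments.

**Pockets.**  Heavy atoms only, on both sides: at crystallographic
resolutions hydrogens are rarely resolved.  The proximity threshold
defaults to 5.5 Å with an inclusive boundary (d ≤ 5.5); close contact in
the literature spans 4–6 Å, and the threshold is a config value.  A ligand
contacting two or more chains of a complex marks an interface pocket and is
omitted (logged with the chains involved); a ligand contacting none is
rejected as empty.  Pocket coordinates are mapped into the chain-cluster
reference frame before any cross-chain comparison.

**Pocket descriptors (72 slots).**  Core slots: residue/atom counts,
element frequencies, Tyr-hydroxyl-oxygen and Trp-indole-nitrogen
frequencies, side-chain atom proportion, Kyte–Doolittle mean hydrophobicity,
residue-class frequencies (aliphatic A/V/L/I, aromatic F/W/Y/H, charged
D/E/K/R/H, polar S/T/N/Q/C/Y/W/H, tiny G/A/S/C), the 20 per-residue
frequencies (computed over standard residues, summing to 1; non-standard
residues counted separately), convex-hull volume and the convexity index.
The convexity index (PCI) is a reconstruction: hull volume over the volume
of the smallest enclosing sphere (trimesh's minimum bounding sphere), in
(0, 1], larger = more compact/convex.  Whether its orientation matches
other published convexity indices is recorded as an open assumption and not
asserted in tests.  Volume is the convex hull of pocket atoms — a
deterministic, dependency-light choice; a solvent-excluded-surface volume
can be plugged in.  Fewer than 4 non-coplanar atoms leaves volume/PCI as
NaN while frequencies are still computed.  Slots beyond the documented core
are reconstructed fillers (gyration-tensor shape, residue-class counts,
net side-chain charge, ...) listed in `RECONSTRUCTED_POCKET_DESCRIPTORS`
and excluded from cross-study claims.  Druggability scoring is a stub
(`druggability_score`) returning NaN unless a plug-in is supplied.

**DBS clustering.**  Per chain cluster, C = D − k·σ with k = 2 and σ the
population standard deviation (divisor p; configurable to sample).  Pockets
whose barycenter distance is strictly below C are linked; DBS are connected
components, so transitivity holds for any k by construction, and pairs
joined only transitively (within-cluster SO = 0) are logged.  C ≤ 0 (when
D < k·σ) falls back to all-singleton clusters with a warning.  Atom
correspondence for the score of overlap: two atoms are common when they
share (aligned reference residue position, atom name); on a single chain
this reduces to identical atom records.  Atoms at unaligned positions get
chain-private keys so they never match across chains.

**Promiscuity.**  L = distinct Ligand-Clusters bound: S (1), MP (2–3),
HP (≥ 4).  A single-pocket DBS is UNDETERMINED — one observation cannot
witness promiscuity — and is reported separately from S.  Statistics are
computed on the DBS4 subset (≥ 4 member pockets, configurable).

**Statistics.**  One-way ANOVA across classes, pairwise t-tests with a
Bonferroni correction, χ² for categoricals.  The Bonferroni denominator
defaults to the number of tests actually performed (descriptors × class
pairs): correcting over descriptors alone does not control the family-wise
error once three classes are compared (simulation puts it near 0.14 at a
nominal 0.05).  Degenerate inputs (all-identical values, classes with < 2
rows) are skipped with a reason.  A Welch option is deliberately not the
default; ANOVA assumes homoscedastic normal groups and the caller can
pre-transform.  CART: Gini impurity, minimum leaf size 5, cost-complexity
pruning with the alpha chosen on an internal group-aware holdout; classes
balanced 1:1 by random undersampling of majority *groups*; cross-validation
assigns whole groups (Pocket-Clusters, or Ligand-Clusters for ligand rows)
to folds so near-duplicate rows never straddle train and test.  Performance
is mean ± sd over folds × repeats (500 by default; tests and the bundled
pipeline use fewer repeats to keep runs short).  Both the standard accuracy
(TP+TN)/total and the verbatim published formula TP/(TP+FP) — which is a
precision, kept under the name `precision_eq5` — are reported.

**Network.**  Strictly bipartite, unweighted, deduplicated; ligand-cluster
promiscuity is degree-based (selective = 1 DBS, promiscuous ≥ 2).  Summary
tables give (i) DBS/pocket shares per promiscuity level, (ii) ligand
clusters dedicated to one level vs "mixed" with a combination breakdown,
(iii) per-level ligand-cluster promiscuity where the "All DBS" row uses
distinct counts, not column sums, because one cluster can bind several
levels.  Protein class is a free-text per-DBS annotation supplied by the
caller.  Multi-edges carry no weight — the edge definition is existential.
Exports are GraphML and edge-list CSV; rendering is out of scope.

## The synthetic generator

The generator emulates the *statistical* structure the pipeline consumes,
not protein physics.  Chains are 110-residue backbones on a smooth helix
(radius 10 Å, 0.35 rad and 1.5 Å rise per residue, giving the physical
~3.8 Å CA–CA virtual bond), with N/CA/C/O plus up to five side-chain
pseudo-atoms per residue chosen by residue type (characteristic heteroatoms
— Tyr OH, Trp NE1, Cys SG — are kept so element-specific descriptors are
exercised; Gly has none).  Family identity is tuned by substituting
floor(L·(1−t)/2) positions per chain so any pair differs in at most twice
that and pairwise identity stays ≥ t.  Sites are residue windows whose
anchors sit 4 Å inside the helix; site separation is enforced on anchor
coordinates and unsatisfiable layouts fail before any file is written.
Ligand families are chemotype pools (carbazoles, flavones, quinoline
sulfonamides, acridine diamines, anthraquinones, biphenyl nitriles,
phenothiazines, nitroquinoxalines, pyrenols, benzothiadiazole amines) whose
members are ring-position isomers and short homologs of a decorated core;
MACCS keys are largely position-insensitive, so within-family Tanimoto is
high while chemotypes stay well apart.  Members are admitted by
acceptance–rejection against the within-family band and the drug-likeness
rules, and cross-family overlap at the clustering threshold is a hard
generation error.  Ligand 3D "poses" are random heavy-atom blobs (sd 1.1 Å,
clipped at 2.2 Å) at the site anchor — pocket extraction needs plausible
contact geometry, not chemistry.  Each complex gets a random rigid
transform and isotropic Gaussian coordinate noise (default sd 0.25 Å,
crystal-variation scale).  Defaults: 3 chain families × 4 chains at
identity 0.92, 2 sites per family 25 Å apart, 5 pockets per site, 4 ligand
families × 3 ligands at Tanimoto ≥ 0.8.

What the generator does *not* emulate — real fold geometry, induced fit,
partial occupancy, alternate conformers, gapped homology, covalent
ligands, crystal-contact interfaces — bounds what passing tests show: they
verify the algorithmic contracts (exact recovery on separable instances,
oracle equivalence of the geometric primitives, calibration of the
statistics), not performance on noisy real structure data.

## Numerical choices

- Boundary conditions: pocket membership inclusive (d ≤ threshold); DBS
  edge strict (d < C); clustering threshold inclusive (Tanimoto ≥ 0.8);
  identity thresholds strict (> 0.90 / > 0.80); occurrence filter ≥ 4.
- Tie-breaks are lexicographic on ids everywhere (cluster numbering by
  smallest member id, representatives, reference chains at equal length).
- σ in the cutoff is population (divisor p); a single-pocket population has
  σ = 0 and C = d_max.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the same seed and inputs give byte-identical
  outputs (fixed PDB float formatting, sorted iteration).
- The reference study used by the acceptance script: 5 chain families ×
  (1, 2, 3, 2, 1) planted sites with labels covering S/MP/HP, 5 pockets per
  site, 25 Å separation — 45 complexes, small enough to run in seconds while
  exercising every stage.

## Known limitations

- The convexity index and the filler descriptor slots are reconstructions;
  only the documented core slots are comparable across studies.
- Greedy identity clustering can split borderline families near the
  thresholds; exactness claims hold for well-separated inputs.
- logD equals logP (no protonation model); χ² support is limited to
  categorical descriptor columns the caller marks as such.
- The pipeline's built-in CART step is skipped (with a manifest note) when
  a study has fewer than five groups per class, as any cross-validated
  estimate below that is noise.
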