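# Methods

`agelascreen` implements a ligand-centric virtual-screening platform for
agelastatin-class ribosomal inhibitors: volume-overlap shape screening over
conformer ensembles, scaffold-based de novo enumeration, a voxelized
field-based 3D-QSAR, and geometric ligand–RNA interaction fingerprinting.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Ligand library

The packaged library holds agelastatin A (AA) and seven analogues (CAA,
CEAA, DCEAA, EAA, PAA, DeBAA, DeBEAA) as SMILES transcribed by hand from
the published 2D structures: a bromopyrrole A-ring fused to a six-membered
B-ring lactam, a cyclopentane C-ring, and an N-methyl imidazolidinone
D-ring carrying a hemiaminal hydroxyl (AA: C12H13BrN4O3). The analogues
vary three positions — the two pyrrole carbons (H/Cl/Br) and the D-ring
imide nitrogen (H/ethyl/phenyl). Transcription is validated by a
substituent-pattern test (which compounds carry Br, Cl, N-ethyl), not by an
external database. Stereocenters are omitted: printed wedges are not
machine-readable, and every computation here (volume overlap, voxel fields,
geometric fingerprints) is insensitive to absolute configuration at the
ensemble level. Halogen placement on the pyrrole follows the prose
description of the series and carries naming weight only.

The packaged activity table holds the published predicted affinities for
the series: CSM affinity (−log10 Kd|Ki), a docking score, and two MM-GBSA
binding energies (ΔG, kcal/mol, two alternative pose conformations). These
columns are consumed as data — the package does not recompute docking or
MM-GBSA, which is out of scope.

## Conformer ensembles

Conformers are generated with RDKit's ETKDGv3 distance-geometry embedder
(seeded; package default seed 2020), relaxed with MMFF94 (UFF fallback),
energy-sorted, and greedily deduplicated at a 0.5 Å heavy-atom best-RMSD
threshold. The retention policy is a global cap of 500 and a budget of 20
conformers per rotatable bond; rotatable bonds are non-ring single bonds
between two heavy atoms that each carry a further heavy neighbor, and
amide C–N bonds are counted (so amide-containing linkers contribute
sampling budget). Rigid molecules (zero rotatable bonds) still receive one
20-conformer budget so ring pucker is represented. Energies are relative
force-field strains used only for ordering; their absolute values carry no
contract.

## Shape similarity

Similarity between superposed molecules A and B is the hard-sphere volume
Tanimoto Sim(A,B) = V(A∩B)/V(A∪B) ∈ [0,1]. Volumes are measured on a
boolean occupancy lattice (0.5 Å spacing, shared with the QSAR stage) over
heavy atoms with Bondi van der Waals radii; hydrogens are ignored. Because
a plain voxel-center count has an offset-dependent error of several
percent, volumes are counted on a 3×-subsampled refinement of the lattice
(27 sub-centers per voxel), which keeps the error of a single-atom sphere
below ~1% at 0.5 Å spacing and makes the estimate stable under grid
refinement. Two caveats follow from the lattice model: joint *translation*
of both molecules is exactly invariant (the lattice is anchored to the
coordinates), while joint *rotation* perturbs Sim at the 10⁻²–10⁻³ level
through discretization anisotropy; tests budget for this.

The alignment search works per conformer pair. Each pair is seeded by
centroid superposition plus principal axes with the four proper axis-flip
hypotheses. Because the boolean-overlap objective is rugged and the seeds
can sit far from the optimum when substituents reorder the principal
moments (the phenyl analogue is the hard case), optimization runs on a
smooth surrogate: atoms as spherical Gaussians (amplitude 2.7, width set so
each Gaussian reproduces its sphere volume) and the Gaussian Tanimoto as
objective, maximized by Nelder–Mead from the seeds plus six seeded random
restarts (σ = 0.8 rad / Å) per pair. The best pairs (default 6) are then
polished against the voxel objective and finally re-scored with the
subsampled hard-sphere estimator, which is the reported similarity. The
whole search is deterministic for a fixed seed; ties break
lexicographically on conformer indices. Screening keeps at most 4
alignments per ligand, drops hits below Sim 0.7, and ranks ligands by best
similarity. Typed similarities re-rasterize atom subsets per class —
pharmacophore classes (donor, acceptor, hydrophobic, aromatic, halogen) or
element symbols — at a fixed alignment.

## De novo generation

Core separation cuts every exocyclic single bond from a ring atom to a
non-ring substituent, leaving the ring-system core with mapped attachment
slots (labels cycle Core1/Core2/Core3) and the severed fragments;
reassembly is the exact inverse, which is property-tested. Enumeration
takes the Cartesian product of fragment choices over slots (hydrogen = bare
slot), so the pre-filtration pool size equals the product of slot
cardinalities. The filter cascade is, in order: chemical filtration
(sanitization, seeded 3D embedding, MMFF minimization — survivors carry one
minimized conformer), state enumeration (a packaged rule table of
pKa-annotated ionization transforms and tautomer transforms applied over a
pH window; the parent is always retained; transforms are written against
the kekulized graph), a reactive-group SMARTS blocklist (acyl halides,
acrylate Michael acceptors, epoxides, aldehydes, α-halo sp³ carbons,
azides, peroxides — aryl halides are deliberately allowed, since the parent
scaffold is an aryl bromide), and a physicochemical Z-score filter: a
7-descriptor vector (MW, heavy atoms, H-bond donors/acceptors, ring count,
halogen count, cLogP) z-scored against the active set, dropping candidates
whose max |z| exceeds the threshold (default 3; the published protocol
names no value). All filters are idempotent and pool manifests are
deterministic. The pH rule table is a small packaged lookup, not a pKa
predictor; pool routing is by core provenance.

## Pharmacophore perception and hypotheses

Feature typing is rule-based SMARTS on the molecular graph: donors are N/O
bearing hydrogen, acceptors are N/O with an available lone pair (aromatic
pyrrole-type N and amide N excluded), halogens F/Cl/Br/I, aromatic features
at ring centroids, hydrophobic features at centroids of connected
nonpolar-carbon clusters, plus formal-charge features. A common hypothesis
across pre-aligned molecules keeps feature clusters represented in every
molecule within a distance tolerance (default 1.5 Å) and of one kind;
cluster centroids become hypothesis features, and at least three must
survive. One structural caveat: N-ethylation of the D-ring nitrogen
removes that N–H, so the ethylated analogues have one fewer graph-level
donor than AA; the published narrative of "added donors" for CEAA refers to
its receptor-bound feature map, which a ligand-only perception cannot
reproduce and which is not asserted.

## Voxel-field QSAR

All training molecules are shape-aligned into one frame: each ligand's best
alignment to the AA ensemble, composed with the rigid map from its matched
AA conformer onto AA conformer 0 (so alignments that matched different
reference conformers still land in a single frame). Fields live on a
shared 0.5 Å lattice padded 3 Å beyond the training set, with three blocks
per molecule: electrostatic (Gasteiger partial charges, hydrogens folded
into heavy atoms, each atom's charge spread uniformly over the voxels
inside its van der Waals radius, so the block integrates to the net
charge), hydrophobic (occupancy by nonpolar carbons), and donor (occupancy
within 1.0 Å of an idealized donor-H tip, placed 1.0 Å from the donor
heavy atom along the direction away from its neighbors).

The regression is single-response NIPALS partial least squares on the
unfolded descriptors: zero-variance columns dropped, mean-centering on,
unit-variance scaling off (field magnitudes are physically scaled).
"PLS with 2 latent variables" is the default reading; the component count
is configurable, and the worked study chooses it at the training-R²
plateau (components added while R² gains ≥ 0.01, capped at 7 = n−1).
The regression vector back-projects into per-class signed coefficient
lattices exportable as OpenDX grids, with a JSON summary of the
top-|coefficient| voxels. Reported statistics: R² = 1 − SSres/SStot,
residual SD (n−1 denominator), RMSE = √(SSres/n), and Pearson r between
fitted and actual activity. With mean-centered training, residuals sum to
zero and SD ≥ RMSE — an internal-consistency relation the tests check.
The activity column for the worked 8-compound study is the packaged CSM
affinity, the one printed activity scale identifiable for that fit; this
is a documented assumption. The worked fit reaches R² ≥ 0.97 and
Pearson ≥ 0.987 under these conditions; the spread statistics (SD, RMSE)
depend on the latent-variable count and field conventions and are reported
but not targeted.

PLS is authored in-package; scikit-learn's PLSRegression serves only as an
independent cross-check in tests, and PLS at full rank is verified against
ordinary least squares.

## Interaction fingerprints

Detection is purely geometric on PDB coordinates, with every threshold a
parameter: hydrogen bonds (donor–acceptor heavy-atom distance ≤ 3.5 Å and
D–H…A angle ≥ 120°, both directions; explicit hydrogens trusted when
present, otherwise idealized H placed on plausible donors — a C–O bond
under 1.32 Å marks a carbonyl, which gets none), halogen–π (halogen within
4.0 Å of an aromatic-ring centroid and within 45° of the ring normal),
linear halogen bonds (C–X…A ≥ 150°, X…A ≤ 3.6 Å), π stacking (parallel:
centroids ≤ 4.5 Å, planes within 30°; T-shaped: 60–90° at ≤ 5.0 Å), and
the van der Waals contact shell (residues with any heavy atom within
4.5 Å, sorted by residue number). Nucleobase donors, acceptors, and ring
systems come from residue-name templates (A/U/G/C, plus backbone oxygens);
unknown residue names fall back to distance-graph ring detection. Residue
numbering is taken verbatim from the input file; no renumbering between
prokaryotic and eukaryotic conventions is attempted.

The buried fraction is 1 − SASA(ligand in complex)/SASA(ligand alone) with
a 1.4 Å probe. SASA uses deterministic Shrake–Rupley sampling (256
golden-spiral points per atom) rather than a lattice count: point sampling
is the field-standard estimator, frame-orientation independent, and
directly tied to the probe-sphere definition. All detections are invariant
under rigid transformation of the complex and monotone in their distance
cutoffs.

Because reproducing the published docked poses would require a commercial
docking engine and the ribosome structure — both out of scope — the
detectors are validated on synthetic complexes built by the pose-fixture
generator: a rigid chlorobenzamide-like template ligand with idealized
uracil-like bases (or single-carbon contact markers, which can trigger only
the contact-shell detector) placed to realize each requested interaction at
an exact geometry, including a 9-residue contact shell mirroring the
published nucleotide enumeration, a two-shell carbon cage for the
fully-buried case, and a planar wall for partial burial. Passing these
tests shows the geometry is detected correctly; it does not validate any
claim about real ribosome poses.

## Orchestration and reproducibility

A validated configuration (pydantic models over YAML) carries the protocol
defaults — seed 2020, cutoff 0.7, 4 alignments, cap 500, 20 per rotatable
bond, 0.5 Å spacing — and the full run executes conformers → shape screen
→ QSAR → ranked report, writing a manifest with a config digest and
SHA-256 digests of every stage output; identical config + seed reproduces
identical digests. The ranking report ranks every affinity-like column
(more negative = stronger) and flags rank disagreements between columns
without resolving them — the published series itself is ranked differently
by different energy columns. The biological-validation arm of the original
workflow is represented only by the report; no assay modeling.

## Problem sizes and known limitations

The default test run uses the full 8-analogue ensembles (10–20 conformers
each) for the worked QSAR and screen-bookkeeping checks, 10 molecules for
the conformer-dedup property, and 100 generated drug-like molecules for
the separate/reassemble identity; the orchestrated-run test uses a reduced
3-ligand library with 4-conformer ensembles. These sizes are the package's
choice of a thorough-but-quick default; all scale up through parameters.

Limitations: the shape model has no electrostatic-field term and no
chirality penalty beyond what 3D overlap induces; the alignment search is
stochastic-but-seeded, so borderline ligands (PAA sits almost exactly at
the 0.7 cutoff against AA) can cross the cutoff in either direction under
different seeds; partial charges are Gasteiger-level; the state enumerator
is a rule table, not a pKa predictor; and interaction detection has no
water-mediated bridges and no energetics.
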