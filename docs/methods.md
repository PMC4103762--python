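# Methods

This note documents the models and procedures `polopharm` implements, the
parameters that matter, what the synthetic fixtures do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Structure handling

Complexes are read from PDB with gemmi. Coordinates are in Å and author
residue numbering is kept verbatim — binding-site residues of the Plk1
polo-box domain are conventionally cited by their deposited numbers
(Trp414, Asp416, His538, Lys540, Leu491, with His489 and Arg516 as optional
extras), and renumbering would break every such lookup. Only the first model
of multi-model files is used (with a warning) and altLoc `A` is preferred,
so parsing is deterministic. Waters (HOH/WAT/DOD) are removed during
preparation. The ligand is selected by HETATM residue name, or by
`chain:<id>` for polymer ligands such as phosphopeptides; every other
non-water atom becomes receptor, so the partition is complete by
construction.

Crystal HETATM blocks carry no reliable bond orders, and most X-ray entries
lack hydrogens. Ligand connectivity therefore comes from a SMILES template
when one is supplied, and otherwise from distance-based perception (bond iff
d ≤ r_i + r_j + 0.45 Å on Cordero covalent radii). All downstream geometry
is designed to work on heavy atoms only; hydrogen counts are implied from
default valences minus the bond-order sum.

Receptor superposition is a Kabsch least-squares fit on Cα atoms shared by
(chain, residue-number) key, requiring at least three; the consensus step
assumes all models sit in one receptor frame.

## Interaction perception

Feature typing on the ligand graph follows standard perception rules:
donors are N/O bearing ≥1 hydrogen (explicit or valence-implied); acceptors
are N/O with an available lone pair, excluding quaternary nitrogen and amide
nitrogen (order-dependent rules deactivate gracefully when orders are
unknown); hydrophobic groups are maximal connected sets of carbons/halogens
with no attached polar atom, of size ≥ 3; positive-ionizable groups are
amines, amidines and guanidines; negative-ionizable groups are carboxylate,
phosphate/phosphonate, sulfate/sulfonate and tetrazole. Histidine's
donor/acceptor duality is fixed by convention (ND1 donor, NE2 acceptor)
rather than pKa prediction, so typing is deterministic.

Geometric windows (all exposed in `PerceptionConfig`):

| interaction  | criterion                                        | default |
|--------------|--------------------------------------------------|---------|
| hydrogen bond| heavy donor–acceptor distance                     | 2.5–3.5 Å |
|              | D–H···A angle, only when an explicit H exists     | ≥ 120°  |
| hydrophobic  | apolar group centroid → hydrophobic side-chain C/S| ≤ 5.0 Å |
| ionic        | ionizable group centroid → charged receptor center| ≤ 5.6 Å |

These are conventional structure-based perception defaults; the commercial
tools in this space do not publish their cutoffs, so ours are explicit and
configurable. Each contact becomes one feature at the ligand-side centroid
(tolerance 1.5 Å for every kind by default — a single radius keeps fit
values comparable across kinds); H-bond features carry a unit direction
toward the receptor partner, and same-kind contacts whose centroids
coincide within 0.5 Å merge into one feature that retains every direction.
Excluded volumes are 1.3 Å spheres on receptor heavy atoms within 5 Å of
the ligand.

## Consensus

Features of identical kind across superposed models are single-linkage
clustered (connected components of the ≤ 2.0 Å proximity graph), with the
extra rule that directional features pointing more than 90° apart never
merge — an acceptor aimed at Trp414 and one aimed at His538 are different
interactions even if their centroids coincide. Clusters supported by at
least `min_support` distinct models (default: all of them) become consensus
features with mean centroid, maximum member tolerance and normalized mean
direction; everything else is discarded. Connected components make the
result independent of input order, and features are sorted (kind, centroid)
for a canonical output. The consensus inherits the reference model's
excluded volumes (union semantics — conservative sterics) and rebuilds all
pairwise distance constraints with tolerance = sum of the two feature
radii. An empty consensus raises an error carrying the per-support
histogram rather than returning a silent empty model. The cluster radius is
exposed because "common" is not a published quantity; values in
1.5–2.5 Å behave equivalently on well-separated feature sets.

## Drug-likeness gate

Descriptors come from RDKit's standard contribution schemes: average
molecular weight, Crippen logP, Ertl TPSA, rotatable bonds, Lipinski counts
(HBD = OH+NH hydrogens, HBA = N+O atoms — the classic convention), and a
Delaney-style ESOL solubility estimate
`logS = 0.16 − 0.63·logP − 0.0062·MW + 0.066·RB − 0.74·AP`.

The Rule-of-5 gate is hard and strict (`MW < 500`, `logP < 5`, `HBD < 5`,
`HBA < 10`; one violation fails). The ADMET stage is a **surrogate**: the
proprietary QSAR categories of commercial suites are not reproducible, so
`polopharm` ships a transparent descriptor-based classifier with the same
categorical interface — absorption 0–3 from an Egan-style TPSA/logP ellipse
(semi-axes 131.6 Å² / 5.88; level 0 inside, levels 1–2 in inflated shells,
3 outside), solubility 0–5 by binning logS at −8/−6/−4/−2/0 (3 = the
classic "good" band), BBB 0–4 by binning TPSA at 40/60/90/140 Å² (3 = low
brain penetration, the desirable class for a non-CNS target). Level
semantics are the surrogate's own, documented here rather than guessed from
any vendor tool; absolute filtered counts from proprietary libraries are
consequently out of scope. The filter applies ADMET first, then Ro5, and
reports per-stage survivor counts.

## Pharmacophore matching and fit values

Matching uses the correspondence-graph formulation: nodes are
kind-compatible (model feature, ligand point) pairs; an edge joins two pairs
whose model-side and ligand-side distances agree within the summed feature
tolerances; cliques of size ≥ n_features − max_omitted are geometrically
consistent assignments. All cliques (not only maximal ones) are enumerated
in deterministic order, because with re-alignment a sub-assignment can
outscore its superset; a guard aborts a molecule after 10⁶ expansions and
flags it in the report instead of hanging.

Each assignment is scored `fit = Σ w_f · max(0, 1 − (d_f/tol_f)²)` over
matched features, with unit weights. A feature whose residual reaches its
tolerance contributes zero and is re-marked as omitted (counting against
`max_omitted`); a match whose atoms penetrate an excluded-volume sphere is
flagged as a clash and rejected. This fit function is this package's own
definition — the commercial "fit value" is not published — chosen to
reproduce its observable properties: the maximum equals the feature count,
reached only at zero displacement everywhere, and a ≥3-of-5 match can pass
fit ≥ 3 only with small displacements. `max_omitted` defaults to 2 on a
five-feature model (3–5 features matched), matching the usual screening
setup.

Two scoring frames exist, and the distinction matters. With `refit=True`
(default for conformer screening) the matched points are Kabsch-aligned
onto the model centroids first, so the fit is invariant under any rigid
motion of the input pose; fewer than three or collinear points fall back to
a centroid translation. With `refit=False` the pose is taken as already
being in the model frame — the right mode for docked poses or
receptor-frame fitting — and displacements are measured in place. The
closed-form reference values (fit 5.0 for a perfect 5-feature match, 4.75
with one feature displaced by tol/2, 4.0 with one feature at exactly its
tolerance) are exact in the in-place frame; re-alignment can only shrink
the residual sum, so the refit fit is always ≥ the in-place value. Screening
runs per molecule over all conformers and assignments, keeps the best
non-clashing match with enough features, gates at `min_fit` (default 3.0,
inclusive), and ranks by fit with molecule id as the deterministic
tie-break.

## Pose analysis

Redocking RMSD is computed in place (no realignment — pose and reference
share the receptor frame) over heavy atoms matched by canonical order, with
an optional symmetry-aware mode that minimizes over element-preserving graph
automorphisms so a flipped aromatic ring is not penalized; < 2 Å is the
conventional redocking success bar. Key-residue analysis reuses the H-bond
perception restricted to the listed residues and emits one boolean per
residue — the machine-readable row of a key-residue conservation table.
The pose gate keeps poses with ≥ `min_key_hbonds` key-residue H-bonds
(default 3, mirroring the 3-of-5 logic of the screening stage; the source
workflows state "good interactions" without a count) and dock score
strictly above `min_score` (default 60). Scores are opaque tags parsed from
the pose file (`dock_score` by default); pose generation and scoring
functions are deliberately out of scope, and poses without a parseable
score are excluded and counted rather than crashing the run.

## Fluorescence-polarization analytics

`mP = (I∥ − I⊥)/(I∥ + I⊥) × G × 1000` with instrument G-factor 0.998
(configurable; implemented verbatim as printed on plate-reader protocols).
Percent inhibition uses two-point normalization
`100·(mP_DMSO − mP)/(mP_DMSO − mP_free)` when free-peptide controls exist —
without the free anchor, "100%" is undefined — and falls back to the
single-point DMSO form `100·(1 − mP/mP_DMSO)` otherwise; control replicates
are averaged.

IC50s come from the four-parameter logistic
`y = bottom + (top − bottom)/(1 + (IC50/x)^hill)` (hill > 0 ⇒ inhibition
rises with dose), fit by bounded least squares from a multi-start grid
(IC50 geometric over the dose range × hill ∈ {0.5, 1, 2}); the best local
optimum wins and the convergence flag is honest — degenerate data (flat
responses, fewer than five distinct doses, no converging start) returns
`converged=False` with a message, never a silent number. Because
control-normalized percent inhibition defines 0% and 100% by the plate
controls, the constrained variant with `fix_bottom=0, fix_top=100` is the
appropriate model for such data and is markedly more stable when the
titration does not reach its plateau (a 100 µM top dose against a ~37 µM
IC50 samples only ~73% inhibition, leaving a free top ill-determined); the
free fit remains the default. An optional residual-resampling bootstrap
(seeded, 200 replicates by default) yields a 95% CI on the IC50. All
stochastic routines take explicit seeds (package default 20140718).

## Synthetic fixtures: what they emulate, and what they do not

The generators produce deterministic, byte-identical artifacts per seed,
each with a truth record sufficient for assertions without re-deriving
geometry:

* **Toy complexes** place template residues (anchor atom exposed at the
  local origin, all other atoms ≥ 0.8 Å behind it) 15 Å apart with ligand
  fragments at designed distances, so only same-index interactions can fall
  inside any cutoff. Derived incidental contacts (e.g. a phosphate oxygen
  also hydrogen-bonding the lysine it salt-bridges) are computed into the
  truth by plain distance arithmetic on the designed coordinates.
* **Feature-set families** share a jittered five-feature core; per-model
  decoys sit on shells of radius 16 + 3·m Å, so decoys from different models
  are ≥ 3 Å apart and can never form a cross-model cluster — consensus
  recovery has an exact combinatorial answer.
* **Pseudo-ligands** are minimal chemically valid fragments (carbonyl for
  acceptor, hydroxyl for donor, cyclopropane for hydrophobic, amine/
  carboxylate for ionizable) whose feature points land exactly on model
  centroids, with optional exact displacements; their fit values are known
  in closed form. A hydroxyl donor is unavoidably also an acceptor point —
  harmless for matching, since geometry excludes it from wrong assignments.
* **Screening decoys** are the same fragments with the core geometry scaled
  so every pairwise distance exceeds every model distance plus summed
  tolerances: no correspondence edge can exist, so decoys are unmatchable by
  construction for any seed, not just observed ones.
* **FP plates** simulate mP between a bound-tracer level (300 mP) and a
  free-tracer floor (50 mP) via the 4PL displacement model, convert mP back
  to parallel/perpendicular intensities at fixed total intensity, and add
  seeded Gaussian noise (σ expressed as a fraction of the 250 mP window) to
  test wells only, keeping the normalization anchors exact.

These fixtures are chemically minimal, not realistic: no conformational
strain, no partial occupancy, no tautomers, no plate-position effects, no
correlated noise. Passing tests therefore demonstrate the correctness of
the geometric, combinatorial and statistical machinery against known
ground truth — they do not demonstrate recovery rates on real crystal
structures or real screening libraries. Applying the identical pipeline to
deposited complexes (the `read_complex` → `superpose_receptors` →
`build_structure_pharmacophore` → `build_consensus` chain, exposed through
the CLI) requires downloading those entries and is exercised only in the
network-dependent end-to-end test.

## Problem sizes and determinism

The default verification sizes are chosen to be exhaustively checkable:
consensus on 9 models of ≤ 9 features; matcher equivalence against full
enumeration on 100 random cases with ≤ 6 features and ≤ 8 points;
screening on 20 matchers + 80 decoys; IC50 recovery on 12-dose ladders with
50 noisy replicates; a 93-compound single-dose screen with 28 designed
actives. The matcher itself has no RNG; all iteration orders are sorted and
ties broken lexicographically, so screening output is reproducible
bit-for-bit.

## Known limitations

* No π-stacking, halogen-bond or water-bridged features; no protonation or
  tautomer enumeration (His convention is fixed).
* Amide-nitrogen exclusion needs bond orders; distance-perceived ligands
  (bare PDB HETATM) type amide N as a donor/acceptor like any other N–H.
* Conformers are consumed, never generated; flexible (torsion-optimizing)
  fitting is out of scope.
* The ADMET surrogate shares only its categorical interface with
  proprietary QSAR models; absolute level agreement is not expected.
* The excluded-volume clash test uses the matched conformer rigidly; no
  relaxation is attempted.
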