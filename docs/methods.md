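# Methods

## Model

A consensus pharmacophore summarises the recurrent receptor–ligand
interactions of an ensemble of `N` co-crystal structures sharing one
reference frame. Each complex contributes a set of typed feature points
(HBD, HBA, HYD, POS, NEG); pooled same-kind features are clustered in
Cartesian space, and a cluster's *statistical frequency* is
`round-half-up(100·count/N)` where `count` is the number of **distinct**
complexes among its members (a complex contributing two coincident features
counts once). Clusters with frequency strictly above a threshold (default
60 %) become model features; receptor-occupied space near any ligand becomes
excluded-volume spheres. The assumption is the usual one for this model
class: interactions conserved across many independent complexes are the
ones required for binding, while singletons reflect ligand-specific or
crystallographic accidents.

## Perception rules

Feature typing is deliberately explicit rather than bit-compatible with any
commercial perception engine (whose definitions are proprietary); every
cutoff lives in `PerceptionRules` and is serialised with the model.

| rule | default | role |
|---|---|---|
| `max_da` | 3.5 Å | donor–acceptor heavy-atom ceiling for H-bonds |
| `min_angle` | 120° | D–H⋯A floor, applied only when the H is explicit |
| `hyd_contact` | 4.5 Å | apolar receptor carbon → hydrophobic centroid |
| `ion_contact` | 5.5 Å | counter-charged receptor group → ionizable point |
| `tolerance` | 1.6 Å | feature sphere radius used in the fit value |
| `ev_contact` | 5.0 Å | receptor atom → ligand distance for excluded volumes |
| `ev_radius` | 1.2 Å | excluded-volume sphere radius |
| `ev_merge` | 1.0 Å | coincident-candidate merge radius |
| `cluster_radius` | 2.0 Å | same-kind feature clustering radius |

Chemistry-only candidates (before the interaction filter): donors are
N/O/S bearing a hydrogen; acceptors are oxygens, or hydrogen-free nitrogens
with a multiple bond that are not amide nitrogens; hydrophobes are centroids
of all-carbon rings and of acyclic chains of ≥3 contiguous apolar carbons;
positive-ionizable points are protonatable amines, guanidines, quaternary
and formally positive atoms (functional-group lookup at physiological pH —
no pKa computation); negative-ionizable points are carboxylate-like groups
(a C/S/P centre with ≥2 terminal oxygens, feature at the group centroid
including the central atom) and lone formally negative atoms. Hydrogen
counts are valence-implied when not explicit (default valences C4/N3/O2/S2,
charge-adjusted), so hydrogen-free crystallographic ligands and explicit-H
molecules behave consistently. Features sit on heavy atoms (no projected
points); donor/acceptor directions are stored but do not enter the fit.

The interaction filter retains a candidate only when the receptor engages
it: donors/acceptors need a geometric H-bond (distance-only when the
structure carries no hydrogens, the normal X-ray situation — polar hydrogens
are never added), hydrophobes need an apolar receptor carbon within
`hyd_contact` (backbone carbonyl carbons and side-chain carbons bonded to
heteroatoms are excluded by a per-residue table), and charged features need
an acidic oxygen (Asp/Glu/OXT) or basic nitrogen (Lys/Arg/His) within
`ion_contact`. Every retained feature records its contacting residues.

## Clustering and labels

Clustering is greedy agglomerative, same-kind only: the pair of clusters
with the smallest centroid distance is merged while that distance is at most
`cluster_radius`; centroids are unweighted member means. Determinism and
permutation-invariance come from canonical pre-sorting and a lexicographic
centroid tie-break. Labels are assigned per kind in descending count order
(H1, H2, …, D1, …, Pos1, …; ties again by centroid order). The retention
rule is strictly `frequency > threshold`, so with 14 complexes a 64 %
(9-of-14) cluster passes a 60 % threshold but a 60 % cluster would not.

## Mapping and screening

All injective kind-compatible assignments of a conformer's candidate points
onto **all** model features are enumerated (partial matching exists as a
flag but defaults off); with ≤6 model features exhaustion is cheap and
exact, so no heuristic search is needed. Each assignment is scored after
closed-form Kabsch superposition of the matched point sets (centroid
translation when fewer than three features); an assignment is rejected if
any displacement exceeds its feature tolerance or any ligand heavy atom
falls strictly inside an excluded volume (van der Waals radii are not
added — documented simplification). The quadratic-falloff fit value is the
de-facto standard for sphere-tolerance pharmacophores; weights default
to 1, so a perfect 6-feature map scores 6.0. Molecules are ranked by
best-over-conformers fit, ties by molecule id, with either a rank cutoff
(`top_k`) or a fit floor (`min_fit`); conformer generation itself is out of
scope — conformers are consumed from multi-conformer SDF.

## Superposition

The ensemble alignment is pairwise CA-based Kabsch superposition onto a
designated reference complex with an explicit residue pairing, rather than
a sequence–structure multiple alignment: deterministic, dependency-free and
sufficient once a pairing is known. The reference complex is a required
configuration choice. Waters and monatomic ions (HOH/WAT, Na, K, Mg, Zn,
Cl, Ca-as-het, Mn) are stripped on reading; altlocs keep the
highest-occupancy copy; residue numbering is taken verbatim from the file.
Distance boundaries are closed (≤) throughout.

## Synthetic data: what it emulates and what it does not

`sbpharm.fixtures` generates download-free ensembles in which every feature
is planted: a site of a given kind gets a minimal ligand fragment (amine,
carbonyl, propyl chain, carboxylate) and the matching receptor residue at
geometries safely inside one rule's capture radius and outside all others.
The stock ensemble plants 19 sites over 14 complexes with the multiplicity
pattern of the MetRS crystal ensemble (counts 12, 11, 10, 9, 9, 9, 5,
2, 2, 2 and nine singletons), sites ≥12 Å apart on a grid, ligand pose
noise of expected magnitude 0.3 Å (receptor fixed — a rigid-receptor
idealisation), and three far anchor residues for superposition tests.
Screening libraries contain actives whose compact probe groups sit on the
model centres (per-fragment jitter ≤0.3 Å, conformers hidden among
fragment-scrambled poses) and decoys formed by deleting every fragment able
to supply one required feature kind — which is why full enrichment is a
construction guarantee, not an empirical claim.

Passing tests on these fixtures therefore demonstrates the correctness of
the geometry, clustering, statistics and ranking machinery — not perception
accuracy on real crystal structures, where protonation, tautomers, water
networks, altloc ambiguity and genuinely folded binding sites make feature
assignment far noisier. Quantities that depend on real perception (absolute
feature positions, the exact number of excluded volumes, sub-ångström
bound-pose RMSDs against crystallographic conformers) are reported by the
pipeline but are fixture-dependent.

## Numerical choices

Rounding of frequencies is half-up (`floor(x+0.5)`), matching the published
integer percentages. Comparisons use closed boundaries with 1e-12…1e-9
slack where float noise could flip a boundary case. Kabsch uses SVD with a
determinant guard so reflections are never returned. PDB output encodes
ligand bond orders by repeating CONECT pairs and formal charges in columns
79–80, so generated complexes round-trip through text files without losing
perception-relevant chemistry; bond orders for ligands lacking CONECT come
from covalent-radius distance perception (all single). Problem sizes in the
test suite and acceptance script (14 complexes, 19 sites, 100-molecule
libraries) mirror the study conditions and run in seconds.

## Known limitations

- No aromatic ring-normal features, projected donor/acceptor points or
  metal-coordination features.
- Ionization by functional-group lookup only; no pKa or tautomer models.
- Hydrophobic receptor contacts rely on a per-residue polar-carbon table
  covering the 20 standard residues; exotic residues default to apolar.
- The external docking-score column of the final report is ingested, never
  computed: docking engines and their scoring functions are out of scope.
- Scaffold novelty and purchasability of hits are human judgements and are
  not modelled.
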