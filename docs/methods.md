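# Methods

## The model

Zn(II) in a (pseudo)tetrahedral N/O/S coordination environment exposes
σ-holes — regions of positive electrostatic potential on the extensions of
its four Zn–Y coordination bonds. A spodium bond (SpB) is the resulting
directional noncovalent attraction between the Zn center and an
electron-rich atom A approaching roughly *trans* to one coordination bond.
This package operationalizes the SpB survey purely geometrically; all
electronic-structure quantities (interaction energies, electron-density
topology, potential surfaces) are explicitly out of scope.

### Site definition

A tetrahedral Zn site is a Zn atom with **exactly four** N/O/S heavy atoms
strictly within the coordination cutoff (default 2.5 Å). The cutoff sits
above the Zn+N/O/S covalent-radius sums (Zn 1.22, N 0.71, O 0.66, S 1.05 Å),
so genuine covalent bonding is never mistaken for coordination. The
definition is deliberately count-and-distance only — no angular quality
filter — because that is the criterion the survey is built on; a
tetrahedrality score (maximum deviation of the six Y–Zn–Y angles from
109.47°) is computed and reported for inspection but never filters.
Zn atoms with three or five near ligands are logged and skipped. In di-Zn
centers each Zn is evaluated independently; a bridging atom may belong to
both sites. Carbon or halogen atoms near the Zn neither count as ligands
nor disqualify a site.

The formal charge is +2 minus the number of anionic ligand groups:
ASP/GLU side-chain carboxylate O, CYS thiolate S, and configurable het
donors (e.g. a deprotonated sulfonamide N). Anionicity is assigned from
residue identity since surveyed crystal structures carry no reliable
protonation; case-specific footnote curation (protonation fixes, capping
notes for particular reference entries) ships as a small JSON override
table rather than hard-coded logic. Unknown het donors contribute 0 and
flag the site's charge as uncertain.

### Contact criteria

A Zn···A contact (A = N/O/S heavy atom, not one of the site's four
coordinating atoms, outside the coordination shell) is a SpB when

* 2.5 Å ≤ d(Zn···A) < 5 Å — lower bound inclusive, upper exclusive;
* 140° ≤ θ ≤ 180°, where θ is the **maximum** of the four ∠Y–Zn···A
  angles. The σ-hole lies on the extension of a Zn–Y bond, so the most
  nearly linear angle is the physically relevant one; the Y achieving it
  is reported as the trans ligand.

Acceptors belonging to a coordinating *residue* (but not the coordinating
atoms themselves) are kept, since only coordination bonds are excluded; a
flag can exclude whole coordinating residues. Each contact records
r̂ = d/(r_vdW(Zn)+r_vdW(A)) with Bondi radii (Zn 1.39, N 1.55, O 1.52,
S 1.80 Å) by default; the Alvarez Zn radius (2.39 Å) is selectable because
Bondi's Zn value is widely considered underestimated — with it, most
contacts fall inside the van der Waals sum.

Phase-1 selection (the input to model building) keeps contacts with
θ ≥ 160° and O/S acceptors and returns the single shortest one per
structure; distance ties within 0.001 Å go to the larger θ.

### Survey statistics

`summarize` produces: the element × donor-class count matrix with
marginals; percentage fractions over four partner categories
(CYS/HIS/ASP/GLU residues, other amino acids, water, nonprotein ligands);
a 2-D (r̂, θ) histogram, default bins 0.05 × 5°, fine enough to resolve a
density maximum a few tenths of an Å beyond the van der Waals sum; and the
(φ, ψ) list of protein-residue acceptors.

Secondary structure is assigned from rectangular φ/ψ boxes
(αR: φ∈[−100,−30], ψ∈[−67,−7]; αL: φ∈[30,100], ψ∈[7,67]; collagen/PPII:
φ∈[−90,−45], ψ∈[120,180]; β: φ∈[−180,−45] with ψ∈[90,180]∪[−180,−150];
otherwise "other", checked in that priority order). This is an
approximation standing in for a hydrogen-bond-pattern assigner: it
reproduces the canonical Ramachandran clusters but will mislabel residues
near box edges. Users who run an external assigner can ingest its labels
via the per-residue TSV hook.

### Truncated coordination models

From the Phase-1 contact, `build_model` assembles a QM-ready cluster:

* Zn fragment — the Zn plus its coordinating residues truncated to donor
  groups: HIS → imidazole ring (CG, ND1, CD2, CE1, NE2; the severed CB
  position is recorded as a cap-hydrogen site), ASP/GLU → acetate (4 heavy
  atoms, the chain-side carbon re-read as a methyl), CYS → thiomethyl
  (2 heavy atoms), coordinated water → its O. Bidentate residues are
  truncated once.
* Partner fragment by scheme — A: the interacting residue with backbone
  amino/carboxyl ends replaced by methyl carbons at the backbone N/C
  positions (carbonyl O dropped with its C); B: the backbone N/CA/C/O
  fragment with side chain and chain continuations capped; C: the complete
  het ligand verbatim; D: the water O with two template hydrogens
  (O–H 0.96 Å, 104.5°) when the crystal has none.

Heavy-atom coordinates are copied bitwise from the source structure and
never moved. Hydrogens, when emitted, are ideal-template placements
flagged `unoptimized` in the XYZ comment and sidecar — the expectation is
an external H-only relaxation with all heavy atoms frozen. Net charge is
site formal charge + partner charge (capped partners are neutral unless
the acceptor group itself is anionic), plus any per-structure override.

## Synthetic data

The generator emulates exactly the features the criteria quantify:

* Zn centers on a 20 Å lattice (pairwise ≥ 15 Å, so sites never
  interact), four ligands at 2.0 Å along exact tetrahedral directions in
  a random (seeded) orientation;
* acceptors placed in the Zn–Y plane at prescribed (d, θ) opposite a
  chosen ligand — the construction is exact, so for zero jitter the
  detector recovers planted values to ≤ 1e-6 (Å, °);
* embeddings that make each acceptor chemically plausible (water as HOH,
  het ligand, side-chain atom with its companion carbons, backbone
  carbonyl inside an ideal tripeptide oriented so the carbonyl faces the
  metal and the chain sits behind it);
* decoy families: 3-coordinate and 5-coordinate Zn, acceptor below 2.5 Å
  (which necessarily enters the coordination shell and voids the site),
  beyond 5 Å, and along a two-ligand bisector where every ∠Y–Zn···A stays
  near 125°, below the window;
* ideal poly-alanine backbones (N–CA 1.458, CA–C 1.525, C–N 1.329 Å,
  angles 111/117/121°, ω = 180°) realizing requested (φ, ψ) exactly via
  the NeRF internal-coordinate construction.

After assembly the generator audits itself with an independent brute-force
scan: every planted contact, and nothing else, must satisfy the criteria.
Acceptor embeddings get a bounded number of seeded re-orientations before
the generator refuses the plan, so ground truth is exact by construction —
recall and precision against it are meaningful at 1.0/1.0. Coordinate
jitter (`noise_sd`) shifts realized geometry; the ground truth records the
realized, not the planned, values.

In minimal mode (the default, used for detection corpora) coordinating
HIS/ASP/GLU/CYS are emitted as their donor atom only, so no uncontrolled
ring/carboxylate atom can enter the contact window; `full_residues=True`
(used for model-builder fixtures) emits complete truncatable groups built
radially away from the Zn, which keeps their companion N/O atoms ≥ 15°
below the angular window by construction.

What the synthetic data does **not** emulate: real side-chain rotamers and
sterics, crystal packing and symmetry mates, disorder/altlocs, solvent
shells, or realistic B-factors. Passing tests therefore demonstrate the
correctness of the criteria's implementation, not the biological
statistics of a real PDB release; survey numbers on real data come from
running `spodium survey` on locally provided PDB files.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_resolution` | 2.0 Å | entries kept only if resolution strictly below; absent resolution rejected |
| `coord_cutoff` | 2.5 Å | Zn–Y coordination shell (strict <) |
| `d_min`, `d_max` | 2.5, 5.0 Å | contact window, [d_min, d_max) |
| `angle_min` | 140° | directionality window lower bound (inclusive) |
| `directional_min` | 160° | Phase-1 high-directionality bound |
| `phase1_elements` | {O, S} | Phase-1 acceptor elements |
| radii | Bondi / Alvarez-Zn | normalization of r̂ |
| histogram bins | 0.05 × 5° | (r̂, θ) density resolution |

## Numerical choices and degenerate inputs

* Angles use a clamped arccos; torsions use the atan2 two-normal
  construction, stable at 0/180°, with the (−180, 180] convention.
* Altloc resolution keeps the highest-occupancy conformer, ties to
  blank/'A'; only the first model of multi-model entries is read.
* φ/ψ at chain termini yield only the defined member; a C(i−1)–N distance
  above 1.8 Å is a chain break and treated as a terminus on both sides.
* Distance ties in Phase-1 selection (< 0.001 Å) break toward larger θ.
* Site detection is rigid-motion invariant to ~1e-9 Å (verified by test).
* Symmetry mates are not generated; only deposited coordinates are
  searched. Hydrogens are parsed but excluded from all detection geometry.

## Problem sizes

The test suite and the acceptance script run on a 50-structure synthetic
corpus (125 planted contacts, 125 decoys spanning all five violation
families), 1000-torsion round-trip sweeps, and single-site fixtures for
the model builder — sizes chosen to exercise every code path with exact
ground truth while keeping the whole suite in the low seconds.

## Known limitations

* φ/ψ-box secondary structure is a coarse stand-in (see above).
* The count-only tetrahedrality criterion admits strongly distorted
  4-coordinate sites; use the reported tetrahedrality score to filter if
  desired.
* Charge assignment is residue-identity-based; unusual protonation states
  need the override table.
* Whether acceptors shared by two Zn sites should be deduplicated is
  genuinely ambiguous; they are kept per site (sites are independent by
  construction). Backbone-N acceptors are counted like any other N even
  though amide delocalization makes those contacts weak.
* Cap-hydrogen orientations in exported models are templates, not
  optimized positions.
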