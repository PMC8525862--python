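# spodium

Survey of **spodium bonds** at tetrahedral Zn(II) sites in protein
structures.

A spodium bond (SpB) is the attractive, directional noncovalent interaction
between a group-12 metal — here Zn(II) in its common (pseudo)tetrahedral
coordination — and an electron-rich atom. The tetrahedral coordination
leaves regions of positive electrostatic potential (σ-holes) on the
extensions of the four Zn–Y coordination bonds, so a lone-pair N, O or S
atom sitting roughly *trans* to a coordination bond can bind the metal
noncovalently, well outside its coordination shell. This package is for
structural bioinformaticians and computational chemists who want to mine
such contacts from the PDB and prepare cluster models for quantum-chemistry
follow-up.

## What it computes

For each structure the pipeline:

1. **Finds tetrahedral Zn sites** — a Zn with *exactly four* N/O/S heavy
   atoms at d(Zn–Y) < 2.5 Å (above the Zn–Y covalent-radius sums:
   Zn 1.22, N 0.71, O 0.66, S 1.05 Å, so coordination is never confused
   with covalent bonding), and assigns a formal charge
   (+2 minus the number of anionic ligands: ASP/GLU carboxylate,
   CYS thiolate, configurable het groups).
2. **Detects SpB contacts** Zn···A (A = N/O/S) by the geometric criteria

       2.5 Å ≤ d(Zn···A) < 5 Å    and    140° ≤ θ(∠Y–Zn···A) ≤ 180°

   where θ is the maximum over the four ligands Y (the σ-hole lies on the
   extension of a Zn–Y bond, so the most nearly linear angle is the
   relevant one). Each contact carries the normalized distance
   r̂ = d / (r_vdW(Zn) + r_vdW(A)) (Bondi radii Zn 1.39, N 1.55, O 1.52,
   S 1.80 Å; the Alvarez Zn radius 2.39 Å is selectable), the donor class
   (backbone / side chain / het ligand / water) and, for protein residues,
   the backbone (φ, ψ) and a coarse secondary-structure class.
3. **Aggregates survey statistics** — the element × donor-class count
   matrix with marginals, pie-chart fractions over residue categories,
   the (r̂, θ) radial/angular histogram and a Ramachandran point list.
4. **Builds truncated coordination models** from the most directional
   contact per structure (Phase-1 selection: θ ≥ 160°, O/S acceptor,
   shortest d): Zn plus its coordinating residues truncated to their donor
   groups (HIS → imidazole, ASP/GLU → acetate, CYS → thiomethyl) and the
   capped interacting partner (scheme A: amino-acid side chain, B:
   backbone carbonyl, C: het ligand, D: water), exported as XYZ with net
   charge — heavy atoms verbatim from the crystal, template hydrogens
   flagged unoptimized.

A fully tested synthetic-structure generator (`spodium.synthetic`) builds
labelled PDB fixtures — planted contacts with exact (d, θ), decoy sites
violating one criterion each, ideal peptides with prescribed torsions — so
the whole pipeline is verifiable without downloading anything.

## Worked example

```sh
$ spodium synth plan.json --seed 7 --out structures
DEMO: 58 atoms, 2 planted contacts
$ spodium survey 'structures/*.pdb' --out survey_out
{
 "n_inputs": 1, "n_skipped": 0, "skipped": {},
 "n_sites": 2, "n_contacts": 2, "out_dir": "survey_out"
}
$ cat survey_out/DEMO_contacts.tsv
structure_id  zn_serial ... trans_ligand  acceptor ... d      theta  r_hat
DEMO          1         ... HIS20:A/NE2   HOH O water  3.193  177.2  1.0973
DEMO          1         ... HIS30:A/NE2   MET SD ...   4.200  150.0  1.3166
```

The plan planted a water O at 3.193 Å / 177.2° opposite the first HIS and
a MET sulfur at 4.2 Å / 150°; both are recovered exactly. The site is
3 HIS + 1 ASP, hence formal charge +1. r̂ = 3.193/2.91 = 1.0973 for the
water O: the contact sits ~0.3 Å beyond the Bondi van der Waals sum, the
regime where most surveyed SpBs live. Model preparation then keeps only
the highly directional water contact and builds the scheme D cluster:

```sh
$ spodium modelprep structures/DEMO.pdb --out models
models/DEMO_modelD.xyz
$ head -2 models/DEMO_modelD.xyz
23
DEMO site=DEMO:A1 partner=HOH60:A scheme=D charge=+1 hydrogens=unoptimized
```

23 atoms = Zn + 3 imidazoles (5 each) + acetate (4) + water O + 2 template
H; net charge +1 = site charge +1 plus a neutral water.

`plan.json` used above:

```json
{
  "sites": [["HIS-N", "HIS-N", "HIS-N", "ASP-O"]],
  "acceptors": [
    {"element": "O", "donor_class": "water", "d": 3.193, "theta": 177.2, "trans_index": 0},
    {"element": "S", "donor_class": "side_chain", "d": 4.2, "theta": 150.0, "trans_index": 1}
  ],
  "decoys": ["theta_below"],
  "structure_id": "DEMO",
  "full_residues": true
}
```

## Library use

```python
from spodium import parse_structure, find_zn_sites, detect_contacts, summarize

model = parse_structure("structure.pdb")
sites = find_zn_sites(model)                 # tetrahedral Zn sites
contacts = detect_contacts(model, sites)     # SpB contacts
summary = summarize(contacts)                # Table-style counts, histograms
```

See `docs/methods.md` for the model, parameter choices and limitations.
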