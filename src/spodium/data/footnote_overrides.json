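{
  "_comment": "Per-structure curation applied when building truncated coordination models: case-specific protonation and capping notes for the reference entries. Fields: partner_charge (int), site_charge_delta (int), notes (free text). Notes marked 'cap' are informational; schemes A/B already apply the capping.",
  "4P4F": {
    "site_charge_delta": 0,
    "notes": "an O atom of the coordinating phosphorus amide is recorded as protonated so the Zn center stays neutral"
  },
  "2O6E": {
    "notes": "cap: protein chain from the interacting MET replaced by a methyl group"
  },
  "2ZNR": {
    "notes": "cap: side chain of the interacting residue replaced by a methyl group"
  },
  "3F1A": {
    "notes": "cap: side chain of the interacting residue replaced by a methyl group"
  },
  "1F18": {
    "notes": "cap: side chain of the interacting residue replaced by a methyl group"
  },
  "2VR7": {
    "notes": "cap: residue group of the interacting LYS replaced by a methyl group to avoid ancillary hydrogen bonds"
  },
  "5LE1": {
    "partner_charge": 0,
    "notes": "inhibitor carboxylate treated as protonated; only one Zn center of the di-Zn site considered; coordinating imidazole dihedral rotated 90 deg in the reference model"
  },
  "6SJ4": {
    "partner_charge": 0,
    "notes": "inhibitor carboxylate treated as protonated"
  },
  "6R6F": {
    "site_charge_delta": -1,
    "notes": "coordinating sulfonamide N treated as deprotonated"
  }
}
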