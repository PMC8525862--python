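"""Truncated Zn-coordination models for quantum-chemistry input.

From a selected spodium-bond contact, assemble a small cluster model of the
Zn center and its interacting electron-rich partner, following four
building schemes keyed to the partner type:

  A  interacting amino-acid side chain (backbone capped with methyls)
  B  backbone carbonyl fragment (side chain / chain continuation capped)
  C  complete het-ligand molecule
  D  a single water molecule

Coordinating residues are truncated to their donor groups: HIS to the
imidazole ring, ASP/GLU to acetate, CYS to thiomethyl.  Heavy-atom
coordinates are always taken verbatim from the crystal structure and never
moved; the only constructed positions are optional template hydrogens,
which are flagged unoptimized (a downstream H-only relaxation is expected
before any energy calculation).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Tuple

import numpy as np

from .spb_detect import SpBContact
from .structure_io import AtomRecord, ResidueKey, StructureModel
from .zn_sites import ligand_charge

SCHEMES = ("A", "B", "C", "D")

#: heavy atoms retained per truncatable coordinating residue; the first
#: entry is re-labelled as the methyl/cap carbon where applicable
TRUNCATION_ATOMS: Dict[str, Tuple[str, ...]] = {
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),  # imidazole ring
    "ASP": ("CB", "CG", "OD1", "OD2"),          # acetate (CB as methyl C)
    "GLU": ("CG", "CD", "OE1", "OE2"),          # acetate (CG as methyl C)
    "CYS": ("CB", "SG"),                        # thiomethyl
}

#: where the severed chain continues, per truncation — the position is kept
#: as a cap-hydrogen site
_CAP_NEIGHBOR: Dict[str, str] = {"HIS": "CB", "ASP": "CA", "GLU": "CB", "CYS": "CA"}


class TruncationError(ValueError):
    """A residue cannot be truncated by the supported schemes."""


class CappingError(ValueError):
    """An interacting partner cannot be capped (e.g. atoms missing)."""


class Fragment(NamedTuple):
    atoms: List[AtomRecord]
    cap_sites: List[np.ndarray]


@dataclass
class TruncatedModel:
    """A scheme A-D cluster model ready for QM-input export."""

    scheme: str
    zn_fragment: List[AtomRecord]
    partner_fragment: List[AtomRecord]
    net_charge: int
    provenance: str
    cap_sites: List[np.ndarray] = field(default_factory=list)
    hydrogens_unoptimized: bool = True

    @property
    def atoms(self) -> List[AtomRecord]:
        return list(self.zn_fragment) + list(self.partner_fragment)


def _relabel_methyl(atom: AtomRecord, name: str = "CM") -> AtomRecord:
    """Turn an atom into a methyl cap carbon at the same position."""
    cap = atom.copy()
    cap.atom_name = name
    cap.element = "C"
    return cap


def truncate_residue(model: StructureModel, residue: ResidueKey) -> Fragment:
    """Truncate one coordinating residue to its donor group.

    HIS keeps the five imidazole ring atoms (the severed CB position is
    recorded as a cap-hydrogen site); ASP/GLU keep four heavy atoms forming
    an acetate; CYS keeps two forming a thiomethyl.  Waters keep their O.
    Coordinates are copied verbatim.
    """
    residue = tuple(residue)
    atoms = model.residue_atoms(residue)
    if not atoms:
        raise TruncationError(f"residue {residue!r} not found")
    resname = atoms[0].residue_name
    if atoms[0].is_water:
        kept = [a.copy() for a in atoms if a.element == "O"]
        return Fragment(kept, [])
    if resname not in TRUNCATION_ATOMS:
        raise TruncationError(
            f"no truncation scheme for residue {resname} {residue!r}"
        )
    wanted = TRUNCATION_ATOMS[resname]
    by_name = {a.atom_name: a for a in atoms}
    missing = [n for n in wanted if n not in by_name]
    if missing:
        raise TruncationError(
            f"{resname} {residue!r} is missing atoms {missing} needed for truncation"
        )
    kept = [by_name[n].copy() for n in wanted]
    cap_sites = []
    cap_name = _CAP_NEIGHBOR[resname]
    if cap_name in by_name:
        cap_sites.append(by_name[cap_name].coords.copy())
    return Fragment(kept, cap_sites)


def _water_hydrogens(o_atom: AtomRecord, serial_base: int) -> List[AtomRecord]:
    """Two template H at 0.96 A / 104.5 deg in an arbitrary plane."""
    o = o_atom.coords
    # arbitrary but deterministic orientation
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([np.cos(np.deg2rad(104.5)), np.sin(np.deg2rad(104.5)), 0.0])
    out = []
    for i, d in enumerate((u, v)):
        h = AtomRecord(
            serial=serial_base + i,
            atom_name=f"H{i + 1}",
            element="H",
            residue_name=o_atom.residue_name,
            residue_seq=o_atom.residue_seq,
            chain_id=o_atom.chain_id,
            coords=o + 0.96 * d,
            insertion_code=o_atom.insertion_code,
            is_het=o_atom.is_het,
        )
        out.append(h)
    return out


def cap_partner(
    model: StructureModel,
    contact: SpBContact,
    scheme: str,
    overrides: Optional[dict] = None,
    water_hydrogens: bool = True,
) -> Fragment:
    """Extract and cap the interacting electron-rich partner.

    Scheme A keeps the full interacting residue with the backbone amino and
    carboxyl ends replaced by methyl carbons (at the positions of the
    backbone N and C; the carbonyl O is dropped with its C).  Scheme B
    keeps the backbone fragment N/CA/C/O with the side chain and the chain
    continuations replaced by methyls.  Scheme C keeps the complete het
    ligand verbatim.  Scheme D keeps the single water O, with template H
    added when the crystal provides none.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    acc = contact.acceptor
    atoms = model.residue_atoms(acc.residue_key)
    if not atoms:
        raise CappingError(f"partner residue {acc.residue_id} not found")
    by_name = {a.atom_name: a for a in atoms if not a.is_hydrogen}

    if scheme == "D":
        kept = [a.copy() for a in atoms if a.element == "O"]
        if not kept:
            raise CappingError(f"water {acc.residue_id} has no O atom")
        frag = Fragment(kept, [])
        if water_hydrogens and not any(a.is_hydrogen for a in atoms):
            frag.atoms.extend(_water_hydrogens(kept[0], serial_base=90001))
        return frag

    if scheme == "C":
        return Fragment([a.copy() for a in atoms if not a.is_hydrogen], [])

    missing = [n for n in ("N", "CA", "C") if n not in by_name]
    if missing:
        raise CappingError(
            f"partner {acc.residue_id} is missing backbone atoms {missing}"
        )

    if scheme == "A":
        # side chain + CA; amino and carboxyl ends become methyl carbons
        kept, caps = [], []
        for a in atoms:
            if a.is_hydrogen:
                continue
            if a.atom_name == "N":
                kept.append(_relabel_methyl(a, "CMN"))
                caps.append(a.coords.copy())
            elif a.atom_name == "C":
                kept.append(_relabel_methyl(a, "CMC"))
                caps.append(a.coords.copy())
            elif a.atom_name in ("O", "OXT"):
                continue  # carbonyl goes with the capped C
            else:
                kept.append(a.copy())
        return Fragment(kept, caps)

    # scheme B: backbone carbonyl fragment
    kept = [by_name[n].copy() for n in ("N", "CA", "C", "O") if n in by_name]
    if "O" not in by_name:
        raise CappingError(f"partner {acc.residue_id} has no backbone O")
    caps = []
    if "CB" in by_name:  # side chain replaced by methyl
        kept.append(_relabel_methyl(by_name["CB"], "CMB"))
        caps.append(by_name["CB"].coords.copy())
    return Fragment(kept, caps)


def partner_charge(contact: SpBContact, scheme: str,
                   overrides: Optional[dict] = None) -> int:
    """Formal charge of the capped partner fragment.

    Capped amino-acid and water partners are neutral except anionic side
    chains acting as the acceptor (ASP/GLU carboxylate, CYS thiolate).
    Het-ligand charges default to 0 and can be set per structure via
    ``overrides`` (e.g. an inhibitor carboxylate recorded as protonated).
    """
    overrides = overrides or {}
    if "partner_charge" in overrides:
        return int(overrides["partner_charge"])
    acc = contact.acceptor
    if scheme == "A":
        charge, _ = ligand_charge(acc)
        return charge
    return 0


def infer_scheme(contact: SpBContact) -> str:
    """Map an acceptor's donor class to the building scheme."""
    return {
        "side_chain": "A",
        "backbone": "B",
        "ligand": "C",
        "water": "D",
    }[contact.donor_class]


def build_model(
    contact: SpBContact,
    model: StructureModel,
    scheme: Optional[str] = None,
    overrides: Optional[dict] = None,
) -> TruncatedModel:
    """Assemble the full cluster model for one selected contact.

    The Zn fragment contains the Zn and the truncations of its (up to four)
    coordinating residues; the partner fragment is the capped interacting
    species.  The net charge is the site's formal charge plus the partner
    charge, with per-structure footnote overrides applied on top
    (``overrides = {"site_charge_delta": int, "partner_charge": int}``).
    """
    overrides = overrides or {}
    if scheme is None:
        scheme = infer_scheme(contact)
    site = contact.site
    zn_fragment: List[AtomRecord] = [site.zn.copy()]
    cap_sites: List[np.ndarray] = []
    partner_key = contact.acceptor.residue_key
    seen: set = set()
    for lig in site.ligands:
        key = lig.residue_key
        if key in seen:
            continue  # bidentate residue truncated once
        seen.add(key)
        atoms = model.residue_atoms(key)
        resname = atoms[0].residue_name if atoms else "?"
        if atoms and atoms[0].is_het and not atoms[0].is_water:
            # het coordinating group kept whole (e.g. a sulfonamide)
            zn_fragment.extend(a.copy() for a in atoms if not a.is_hydrogen)
            continue
        try:
            frag = truncate_residue(model, key)
        except TruncationError as exc:
            raise TruncationError(
                f"cannot build Zn fragment: coordinating residue "
                f"{resname}{key[1]}:{key[0]} is unsupported ({exc})"
            ) from exc
        zn_fragment.extend(frag.atoms)
        cap_sites.extend(frag.cap_sites)

    pfrag = cap_partner(model, contact, scheme, overrides)
    cap_sites.extend(pfrag.cap_sites)

    net = (
        site.formal_charge
        + int(overrides.get("site_charge_delta", 0))
        + partner_charge(contact, scheme, overrides)
    )
    return TruncatedModel(
        scheme=scheme,
        zn_fragment=zn_fragment,
        partner_fragment=pfrag.atoms,
        net_charge=net,
        provenance=(
            f"{contact.structure_id} site={site.site_label} "
            f"partner={contact.acceptor.residue_id}"
        ),
        cap_sites=cap_sites,
    )


def default_overrides() -> Dict[str, dict]:
    """Per-structure footnote curation shipped with the package.

    Keys are structure ids; values carry ``partner_charge``,
    ``site_charge_delta`` and free-text ``notes`` for the reference
    entries whose protonation or capping needs case-specific handling.
    """
    from importlib.resources import files

    payload = json.loads(
        files("spodium").joinpath("data/footnote_overrides.json").read_text()
    )
    payload.pop("_comment", None)
    return payload


def write_xyz(tm: TruncatedModel, path) -> None:
    """Write a standard XYZ file plus a JSON sidecar with fragment info.

    The comment line carries the provenance, scheme and net charge
    (``charge=+1`` style); coordinates are at 6-decimal precision.
    """
    atoms = tm.atoms
    lines = [str(len(atoms))]
    lines.append(
        f"{tm.provenance} scheme={tm.scheme} charge={tm.net_charge:+d}"
        + (" hydrogens=unoptimized" if tm.hydrogens_unoptimized else "")
    )
    for a in atoms:
        x, y, z = a.coords
        lines.append(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write XYZ to {path}: {exc}") from exc
    sidecar = {
        "provenance": tm.provenance,
        "scheme": tm.scheme,
        "net_charge": tm.net_charge,
        "n_atoms": len(atoms),
        "zn_fragment": list(range(len(tm.zn_fragment))),
        "partner_fragment": list(
            range(len(tm.zn_fragment), len(atoms))
        ),
        "cap_sites": [list(map(float, c)) for c in tm.cap_sites],
        "hydrogens": "unoptimized" if tm.hydrogens_unoptimized else "crystal",
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_xyz(path) -> Tuple[List[str], np.ndarray, str]:
    """Minimal XYZ reader for round-trip checks: (elements, coords, comment)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0])
    comment = lines[1]
    elements, coords = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.array(coords), comment
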