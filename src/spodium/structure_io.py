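"""Read and write protein structures (PDB, optionally mmCIF) into a flat
atom-record model.

The survey only needs atom identities, coordinates and a couple of header
fields, so the in-memory model is a plain list of :class:`AtomRecord` plus
the crystallographic resolution.  Parsing goes through gemmi; alternate
locations are resolved to a single conformer and only the first model of
multi-model (NMR) entries is kept.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

import gemmi

#: the 20 standard amino-acid 3-letter codes
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: residue names recognized as water
WATER_NAMES = frozenset({"HOH", "DOD", "WAT"})

ResidueKey = Tuple[str, int, str]  # (chain_id, residue_seq, insertion_code)


class ParseError(ValueError):
    """A structure file could not be read."""


class EmptyStructureError(ParseError):
    """A structure file contained no atoms."""


@dataclass
class AtomRecord:
    """One atom of a structure (post altloc/model resolution)."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: np.ndarray
    insertion_code: str = ""
    occupancy: float = 1.0
    altloc: str = ""
    is_het: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be 3 finite numbers")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element")
        self.element = self.element.strip().capitalize()
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.serial}: occupancy {self.occupancy} outside [0,1]")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def residue_id(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.residue_name}{self.residue_seq}{icode}:{self.chain_id}"

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    @property
    def is_standard_aa(self) -> bool:
        return self.residue_name in STANDARD_AA

    def copy(self) -> "AtomRecord":
        return AtomRecord(
            serial=self.serial,
            atom_name=self.atom_name,
            element=self.element,
            residue_name=self.residue_name,
            residue_seq=self.residue_seq,
            chain_id=self.chain_id,
            coords=self.coords.copy(),
            insertion_code=self.insertion_code,
            occupancy=self.occupancy,
            altloc=self.altloc,
            is_het=self.is_het,
        )


@dataclass
class StructureModel:
    """A parsed structure: one model's atoms plus header metadata."""

    structure_id: str
    atoms: List[AtomRecord] = field(default_factory=list)
    resolution: Optional[float] = None
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        """(n_atoms, 3) coordinate matrix in atom order."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.vstack([a.coords for a in self.atoms])

    def heavy_atoms(self) -> List[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def residue_keys(self) -> List[ResidueKey]:
        """Residue keys in order of first appearance."""
        seen: Dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def residue_atoms(self, key: ResidueKey) -> List[AtomRecord]:
        key = tuple(key)
        return [a for a in self.atoms if a.residue_key == key]

    def find_atom(self, key: ResidueKey, atom_name: str) -> Optional[AtomRecord]:
        key = tuple(key)
        for a in self.atoms:
            if a.residue_key == key and a.atom_name == atom_name:
                return a
        return None


def _altloc_sort_key(atom: gemmi.Atom):
    # highest occupancy wins; ties prefer blank then 'A' then later letters
    alt = atom.altloc if atom.altloc not in ("\x00", "") else ""
    return (-atom.occ, alt)


def parse_structure(
    path,
    altloc_policy: str = "highest_occupancy",
    model_policy: str = "first",
) -> StructureModel:
    """Parse a PDB (or mmCIF) file into a :class:`StructureModel`.

    Hydrogens are retained (downstream geometry ignores them).  Only the
    first model is kept by default; for alternate locations the conformer
    with the highest occupancy is kept, ties broken in favour of blank/'A'.
    """
    if altloc_policy not in ("highest_occupancy", "all"):
        raise ValueError(f"unknown altloc_policy {altloc_policy!r}")
    if model_policy != "first":
        raise ValueError(f"unknown model_policy {model_policy!r}")
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot parse structure file {path}: {exc}") from exc

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    atoms: List[AtomRecord] = []
    if len(st) == 0:
        raise EmptyStructureError(f"no models in {path}")
    model = st[0]
    for chain in model:
        for res in chain:
            # group altlocs per atom name
            by_name: Dict[str, List[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                if altloc_policy == "highest_occupancy":
                    chosen = [min(group, key=_altloc_sort_key)]
                else:
                    chosen = group
                for at in chosen:
                    atoms.append(
                        AtomRecord(
                            serial=at.serial,
                            atom_name=name,
                            element=at.element.name,
                            residue_name=res.name,
                            residue_seq=res.seqid.num,
                            insertion_code=res.seqid.icode.strip(),
                            chain_id=chain.name,
                            coords=(at.pos.x, at.pos.y, at.pos.z),
                            occupancy=min(max(at.occ, 0.0), 1.0),
                            altloc=at.altloc if at.altloc != "\x00" else "",
                            is_het=res.het_flag == "H",
                        )
                    )
    if not atoms:
        raise EmptyStructureError(f"no atoms in {path}")
    structure_id = st.name.strip() if st.name.strip() else path.stem
    return StructureModel(
        structure_id=structure_id,
        atoms=atoms,
        resolution=resolution,
        source_path=str(path),
    )


def write_structure(model: StructureModel, path) -> None:
    """Write a :class:`StructureModel` as a PDB file.

    Coordinates are written at the format's 3-decimal precision; waters and
    het groups come out as HETATM records.
    """
    if not model.atoms:
        raise ValueError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = model.structure_id
    if model.resolution is not None:
        st.resolution = model.resolution
    gm = gemmi.Model("1")
    # gemmi's add_residue/add_chain copy their argument, so each container
    # must be fully populated before insertion into its parent
    grouped: Dict[str, Dict[ResidueKey, List[AtomRecord]]] = {}
    for a in model.atoms:
        grouped.setdefault(a.chain_id, {}).setdefault(a.residue_key, []).append(a)
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for key, recs in residues.items():
            res = gemmi.Residue()
            res.name = recs[0].residue_name
            res.seqid = gemmi.SeqId(recs[0].residue_seq,
                                    recs[0].insertion_code or " ")
            res.het_flag = "H" if (recs[0].is_het or recs[0].is_water) else "A"
            for a in recs:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.coords)
                at.occ = a.occupancy
                at.serial = a.serial
                if a.altloc:
                    at.altloc = a.altloc
                res.add_atom(at)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write PDB to {path}: {exc}") from exc


def passes_resolution(model: StructureModel, max_res: float = 2.0) -> bool:
    """True iff the resolution is present and strictly below ``max_res``.

    Entries without a recorded resolution (e.g. NMR) are rejected, matching
    a survey restricted to well-resolved crystal structures.
    """
    if model.resolution is None or not math.isfinite(model.resolution):
        return False
    return model.resolution < max_res
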