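"""Labelled synthetic structures for exercising the survey end to end.

The generator emulates exactly the situations the detection criteria are
written for: a Zn atom with four N/O/S donors in a tetrahedral shell within
the coordination cutoff, acceptor atoms planted at a prescribed distance d
and directionality angle theta opposite a chosen Zn-Y bond, decoy sites
violating one criterion each, and short ideal-geometry peptide backbones
with known phi/psi.  Every structure comes with a ground-truth table; after
assembly the generator audits itself with an independent brute-force scan
and re-orients embedding atoms (or raises) so that no unplanned atom falls
inside the contact window — the ground truth is exact by construction.

It is not a physically realistic protein generator: there is no sterics
beyond a minimum-separation/audit check, no side-chain rotamer logic and no
crystal packing.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import geometry
from .structure_io import AtomRecord, StructureModel
from .zn_sites import YOS_ELEMENTS

#: exact tetrahedral unit directions
TETRA_DIRS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / math.sqrt(3.0)

#: ligand codes understood by the generator -> (residue, donor atom, element)
LIGAND_CODES: Dict[str, Tuple[str, str, str]] = {
    "HIS-N": ("HIS", "NE2", "N"),
    "ASP-O": ("ASP", "OD1", "O"),
    "GLU-O": ("GLU", "OE1", "O"),
    "CYS-S": ("CYS", "SG", "S"),
    "HOH-O": ("HOH", "O", "O"),
}

DECOY_KINDS = ("coord3", "coord5", "d_below", "d_above", "theta_below")

#: ideal backbone internal coordinates (Angstrom / degrees)
BB_N_CA, BB_CA_C, BB_C_N, BB_C_O = 1.458, 1.525, 1.329, 1.231
ANG_N_CA_C, ANG_CA_C_N, ANG_C_N_CA, ANG_CA_C_O = 111.0, 117.0, 121.0, 121.0


class GenerationError(RuntimeError):
    """A synthetic plan could not be realized cleanly."""


@dataclass
class PlannedAcceptor:
    """One acceptor to plant opposite a chosen Zn-Y bond."""

    element: str
    donor_class: str  # backbone / side_chain / ligand / water
    d: float
    theta: float
    trans_index: int = 0
    site_index: int = 0

    def __post_init__(self):
        self.element = self.element.capitalize()
        if self.element not in YOS_ELEMENTS:
            raise ValueError(f"acceptor element must be N/O/S, got {self.element}")
        if not 0.0 < self.d < 10.0:
            raise ValueError("planned d must lie in (0, 10) A")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("planned theta must lie in [0, 180] deg")


@dataclass
class SyntheticSpec:
    """Full plan for one synthetic structure."""

    sites: List[List[str]] = field(default_factory=lambda: [["HIS-N"] * 4])
    acceptors: List[PlannedAcceptor] = field(default_factory=list)
    decoys: List[str] = field(default_factory=list)
    zn_ligand_distance: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0
    full_residues: bool = False
    structure_id: str = "SYN1"
    resolution: float = 1.5

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticSpec":
        acceptors = [PlannedAcceptor(**a) for a in payload.pop("acceptors", [])]
        return cls(acceptors=acceptors, **payload)


# --- low-level builders ------------------------------------------------------


class _Builder:
    """Accumulates AtomRecords with running serial/residue numbering."""

    def __init__(self):
        self.atoms: List[AtomRecord] = []
        self._serial = 0
        self._resseq = 0

    def next_residue(self) -> int:
        self._resseq += 10  # gaps guarantee residues never read as bonded
        return self._resseq

    def add(self, atom_name, element, resname, resseq, coords,
            het=False, chain="A") -> AtomRecord:
        self._serial += 1
        rec = AtomRecord(
            serial=self._serial,
            atom_name=atom_name,
            element=element,
            residue_name=resname,
            residue_seq=resseq,
            chain_id=chain,
            coords=np.asarray(coords, dtype=float),
            is_het=het,
        )
        self.atoms.append(rec)
        return rec


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A unit vector perpendicular to u, direction drawn from rng."""
    while True:
        v = rng.normal(size=3)
        v -= u * np.dot(v, u)
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _rotation_about(axis: np.ndarray, ang_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(ang_deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR-based uniform-ish rotation; determinism is all that matters here
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _acceptor_direction(trans_dir: np.ndarray, theta: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit direction making angle theta with the trans ligand direction.

    The acceptor is placed in a plane containing Zn and Y, offset by
    (180 - theta) from the exact anti position.
    """
    beta = math.radians(180.0 - theta)
    p = _perpendicular(trans_dir, rng)
    return -trans_dir * math.cos(beta) + p * math.sin(beta)


# --- residue embeddings ------------------------------------------------------


def _embed_ligand_residue(b: _Builder, code: str, donor_pos, away: np.ndarray,
                          rng: np.random.Generator, full: bool) -> AtomRecord:
    """Emit a coordinating residue whose donor atom sits at donor_pos.

    In minimal mode only the donor atom is emitted.  In full mode the
    truncation-relevant side-chain group is built with ideal geometry
    extending radially away from Zn, which keeps every companion N/O atom
    well below the directionality window (max Y-Zn-A angle < 125 deg).
    """
    resname, donor_name, element = LIGAND_CODES[code]
    seq = b.next_residue()
    het = resname == "HOH"
    donor = b.add(donor_name, element, resname, seq, donor_pos, het=het)
    if not full or het:
        return donor
    donor_pos = np.asarray(donor_pos, dtype=float)
    w = _perpendicular(away, rng)
    if resname == "HIS":
        # regular pentagon of side 1.37, NE2 nearest Zn, ring extending away
        r_ring = 1.37 / (2.0 * math.sin(math.pi / 5.0))
        center = donor_pos + r_ring * away
        to_ne2 = -away
        ring = {}
        for name, ang in (("CE1", 72.0), ("CD2", -72.0),
                          ("ND1", 144.0), ("CG", -144.0)):
            d = math.cos(math.radians(ang)) * to_ne2 + \
                math.sin(math.radians(ang)) * w
            ring[name] = center + r_ring * d
        b.add("ND1", "N", resname, seq, ring["ND1"])
        b.add("CE1", "C", resname, seq, ring["CE1"])
        b.add("CD2", "C", resname, seq, ring["CD2"])
        cg = b.add("CG", "C", resname, seq, ring["CG"])
        cb_dir = ring["CG"] - center
        cb_dir /= np.linalg.norm(cb_dir)
        b.add("CB", "C", resname, seq, ring["CG"] + 1.50 * cb_dir)
    elif resname in ("ASP", "GLU"):
        names = {"ASP": ("CG", "OD2", "CB", "CA"),
                 "GLU": ("CD", "OE2", "CG", "CB")}[resname]
        c_carbox = donor_pos + 1.25 * away
        b.add(names[0], "C", resname, seq, c_carbox)
        o2_dir = math.cos(math.radians(54.0)) * away + \
            math.sin(math.radians(54.0)) * w
        b.add(names[1], "O", resname, seq, c_carbox + 1.25 * o2_dir)
        cb_dir = math.cos(math.radians(54.0)) * away - \
            math.sin(math.radians(54.0)) * w
        cb = c_carbox + 1.52 * cb_dir
        b.add(names[2], "C", resname, seq, cb)
        b.add(names[3], "C", resname, seq, cb + 1.53 * away)
    elif resname == "CYS":
        cb = donor_pos + 1.81 * away
        b.add("CB", "C", resname, seq, cb)
        b.add("CA", "C", resname, seq, cb + 1.53 * (
            math.cos(math.radians(30.0)) * away + math.sin(math.radians(30.0)) * w))
    return donor


def _embed_acceptor(
    b: _Builder,
    plan: PlannedAcceptor,
    pos: np.ndarray,
    u_acc: np.ndarray,
    rng: np.random.Generator,
    full: bool = False,
) -> Tuple[AtomRecord, List[int]]:
    """Emit the acceptor atom inside a chemically plausible residue.

    Returns the acceptor record and the indices (into ``b.atoms``) of the
    companion atoms added with it (used for audit/retry re-orientation).
    """
    start = len(b.atoms)
    seq = b.next_residue()
    if plan.donor_class == "water":
        acc = b.add("O", "O", "HOH", seq, pos, het=True)
    elif plan.donor_class == "ligand":
        name = {"O": "O1", "N": "N1", "S": "S1"}[plan.element]
        acc = b.add(name, plan.element, "LIG", seq, pos, het=True)
        b.add("C1", "C", "LIG", seq, pos + 1.40 * u_acc, het=True)
    elif plan.donor_class == "side_chain":
        resname, aname, companions = {
            "O": ("SER", "OG", (("CB", 1.41),)),
            "N": ("LYS", "NZ", (("CE", 1.49),)),
            "S": ("MET", "SD", (("CG", 1.80), ("CE", 1.79))),
        }[plan.element]
        acc = b.add(aname, plan.element, resname, seq, pos)
        w = _perpendicular(u_acc, rng)
        for i, (cname, bond) in enumerate(companions):
            d = math.cos(math.radians(25.0 * i)) * u_acc + \
                math.sin(math.radians(25.0 * i)) * w
            b.add(cname, "C", resname, seq, pos + bond * d)
        if full:
            # approximate backbone behind the side chain (away from Zn),
            # far enough that its N/O never enter the contact window
            base = pos + 3.8 * u_acc
            b.add("CA", "C", resname, seq, base)
            b.add("N", "N", resname, seq, base + 1.46 * (
                math.cos(math.radians(40.0)) * u_acc
                + math.sin(math.radians(40.0)) * w))
            c_pos = base + 1.53 * (
                math.cos(math.radians(40.0)) * u_acc
                - math.sin(math.radians(40.0)) * w)
            b.add("C", "C", resname, seq, c_pos)
            b.add("O", "O", resname, seq, c_pos + 1.23 * u_acc)
    elif plan.donor_class == "backbone":
        acc = _embed_backbone_acceptor(b, plan, pos, u_acc, rng, seq)
    else:
        raise ValueError(f"unknown donor class {plan.donor_class!r}")
    companions = [i for i in range(start, len(b.atoms)) if b.atoms[i] is not acc]
    return acc, companions


def _embed_backbone_acceptor(b, plan, pos, u_acc, rng, seq) -> AtomRecord:
    """Place a tripeptide so its middle-residue O (or N) lands on ``pos``.

    The peptide is first built in a local frame, then rigidly moved; the
    caller's audit/retry loop rotates it until no other peptide atom
    intrudes on the contact window.
    """
    pep = generate_peptide([(-57.0, -47.0)] * 3)
    target_name = "O" if plan.element == "O" else "N"
    mid_key = pep.residue_keys()[1]
    anchor = pep.find_atom(mid_key, target_name)
    coords = pep.coords_array() - anchor.coords  # anchor at origin
    # point the acceptor's covalent bond(s) away from Zn, so the acceptor
    # lone pair faces the sigma-hole and the chain sits behind the acceptor
    neighbors = [
        xyz for xyz in coords
        if 0.0 < np.linalg.norm(xyz) < 1.6
    ]
    bond_dir = _normalize(np.mean(neighbors, axis=0))
    R = _align_rotation(bond_dir, u_acc)
    coords = coords @ R.T
    # a fresh azimuth each attempt; rotation about u_acc keeps the pose
    spin = _rotation_about(u_acc, float(rng.uniform(0.0, 360.0)))
    coords = coords @ spin.T + pos
    acc = None
    for at, xyz in zip(pep.atoms, coords):
        rec = b.add(at.atom_name, at.element, at.residue_name,
                    seq + at.residue_seq, xyz)
        if at.residue_key == mid_key and at.atom_name == target_name:
            acc = rec
    return acc


def _align_rotation(a: np.ndarray, bvec: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    bvec = bvec / np.linalg.norm(bvec)
    v = np.cross(a, bvec)
    c = float(np.dot(a, bvec))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


# --- audit -------------------------------------------------------------------


def _qualifying_atoms(zn_pos, ligand_pos, atoms: Sequence[AtomRecord],
                      skip_ids, d_min=2.5, d_max=5.0, angle_min=140.0):
    """Brute-force scan: indices of atoms inside the contact window."""
    hits = []
    for i, a in enumerate(atoms):
        if id(a) in skip_ids or a.is_hydrogen or a.element not in YOS_ELEMENTS:
            continue
        d = geometry.distance(zn_pos, a.coords)
        if not (d_min <= d < d_max):
            continue
        theta = max(geometry.angle(lp, zn_pos, a.coords) for lp in ligand_pos)
        if angle_min <= theta <= 180.0:
            hits.append(i)
    return hits


# --- main entry points -------------------------------------------------------


def generate_structure(
    spec: SyntheticSpec,
) -> Tuple[StructureModel, pd.DataFrame]:
    """Realize a :class:`SyntheticSpec` into a structure plus ground truth.

    Zn centers are placed on a 20 A lattice (pairwise separation >= 15 A so
    sites never interact).  The ground-truth table lists every planted
    acceptor with its realized (d, theta, donor_class) — recomputed from
    the final coordinates, so it is exact even under coordinate jitter —
    and every decoy with its violation reason.
    """
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    truth_rows: List[dict] = []

    n_centers = len(spec.sites) + len(spec.decoys)
    centers = [
        20.0 * np.array([i % 4, (i // 4) % 4, i // 16], dtype=float)
        for i in range(n_centers)
    ]

    def jitter():
        if spec.noise_sd <= 0:
            return np.zeros(3)
        return rng.normal(0.0, spec.noise_sd, size=3)

    def build_site(center, codes, site_idx, label):
        R = _random_rotation(rng)
        dirs = TETRA_DIRS @ R.T
        zn = b.add("ZN", "Zn", "ZN", b.next_residue(), center + jitter(), het=True)
        ligands = []
        for k, code in enumerate(codes):
            pos = center + spec.zn_ligand_distance * dirs[k] + jitter()
            ligands.append(
                _embed_ligand_residue(b, code, pos, dirs[k], rng,
                                      spec.full_residues)
            )
        return zn, ligands, dirs

    # planted sites + acceptors
    site_records = []
    for s_idx, codes in enumerate(spec.sites):
        if len(codes) != 4:
            raise GenerationError(f"site {s_idx}: need exactly 4 ligand codes")
        zn, ligands, dirs = build_site(centers[s_idx], codes, s_idx, f"site{s_idx}")
        site_records.append((zn, ligands, dirs))

    for plan in spec.acceptors:
        if not 0 <= plan.site_index < len(site_records):
            raise GenerationError(f"acceptor references missing site {plan.site_index}")
        zn, ligands, dirs = site_records[plan.site_index]
        trans_dir = dirs[plan.trans_index]
        ligand_pos = [l.coords for l in ligands]
        placed = False
        for attempt in range(24):
            u_acc = _acceptor_direction(trans_dir, plan.theta, rng)
            pos = zn.coords + plan.d * u_acc + jitter()
            mark = len(b.atoms)
            acc, companions = _embed_acceptor(b, plan, pos, u_acc, rng,
                                              full=spec.full_residues)
            skip = {id(l) for l in ligands} | {id(zn)}
            hits = _qualifying_atoms(zn.coords, ligand_pos, b.atoms[mark:], skip)
            hit_atoms = [b.atoms[mark + i] for i in hits]
            # no embedding atom may intrude into the coordination shell,
            # which would turn the planted 4-coordinate site 5-coordinate
            intruders = [
                a for a in b.atoms[mark:]
                if not a.is_hydrogen and a.element in YOS_ELEMENTS
                and geometry.distance(zn.coords, a.coords) < 2.5
            ]
            if hit_atoms == [acc] and not intruders:
                placed = True
                break
            del b.atoms[mark:]  # retry with a fresh orientation
        if not placed:
            raise GenerationError(
                f"cannot embed acceptor {plan} without stray in-window atoms; "
                f"reduce noise_sd or relax the plan"
            )
        d_real = geometry.distance(zn.coords, acc.coords)
        theta_real = max(
            geometry.angle(lp, zn.coords, acc.coords) for lp in ligand_pos
        )
        truth_rows.append(
            {
                "kind": "contact",
                "site_index": plan.site_index,
                "zn_serial": zn.serial,
                "acceptor_serial": acc.serial,
                "element": plan.element,
                "donor_class": plan.donor_class,
                "d": d_real,
                "theta": theta_real,
                "is_decoy": False,
                "violation": "",
            }
        )

    # decoy sites
    for d_idx, kind in enumerate(spec.decoys):
        if kind not in DECOY_KINDS:
            raise GenerationError(f"unknown decoy kind {kind!r}")
        center = centers[len(spec.sites) + d_idx]
        codes = ["HIS-N"] * (3 if kind == "coord3" else 4)
        zn, ligands, dirs = build_site(center, codes, -1, kind)
        acc_serial = None
        if kind == "coord5":
            fifth = center + 2.3 * _normalize(dirs[0] + dirs[1]) + jitter()
            acc_serial = b.add("O", "O", "HOH", b.next_residue(), fifth,
                               het=True).serial
        elif kind == "d_below":
            # inside the coordination shell: the Zn becomes 5-coordinate
            pos = center + 2.45 * (-dirs[0]) + jitter()
            acc_serial = b.add("O", "O", "HOH", b.next_residue(), pos,
                               het=True).serial
        elif kind == "d_above":
            u = _acceptor_direction(dirs[0], 170.0, rng)
            pos = center + 5.2 * u + jitter()
            acc_serial = b.add("O", "O", "HOH", b.next_residue(), pos,
                               het=True).serial
        elif kind == "theta_below":
            # the bisector of two ligand directions caps every Y-Zn-A
            # angle at ~125 deg, below the 140 deg window
            pos = center + 3.5 * _normalize(dirs[0] + dirs[1]) + jitter()
            acc_serial = b.add("O", "O", "HOH", b.next_residue(), pos,
                               het=True).serial
        truth_rows.append(
            {
                "kind": "decoy",
                "site_index": -1,
                "zn_serial": zn.serial,
                "acceptor_serial": acc_serial,
                "element": "O" if acc_serial else "",
                "donor_class": "",
                "d": float("nan"),
                "theta": float("nan"),
                "is_decoy": True,
                "violation": kind,
            }
        )

    model = StructureModel(
        structure_id=spec.structure_id,
        atoms=b.atoms,
        resolution=spec.resolution,
        source_path="<synthetic>",
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "kind", "site_index", "zn_serial", "acceptor_serial", "element",
            "donor_class", "d", "theta", "is_decoy", "violation",
        ],
    )
    _global_audit(model, spec, truth)
    return model, truth


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _global_audit(model: StructureModel, spec: SyntheticSpec,
                  truth: pd.DataFrame) -> None:
    """Verify the ground truth with an independent whole-structure scan."""
    zn_atoms = [a for a in model.atoms if a.element == "Zn"]
    expected = {
        (int(r.zn_serial), int(r.acceptor_serial))
        for r in truth.itertuples()
        if r.kind == "contact"
    }
    found = set()
    for zn in zn_atoms:
        shell = [
            a for a in model.heavy_atoms()
            if a.element in YOS_ELEMENTS
            and np.linalg.norm(a.coords - zn.coords) < 2.5
        ]
        if len(shell) != 4:
            continue
        skip = {id(a) for a in shell} | {id(zn)}
        lig_pos = [a.coords for a in shell]
        for i in _qualifying_atoms(zn.coords, lig_pos, model.atoms, skip):
            found.add((zn.serial, model.atoms[i].serial))
    if found != expected:
        raise GenerationError(
            f"self-audit failed: planted {sorted(expected)} but the criteria "
            f"select {sorted(found)}; reduce noise_sd or adjust the plan"
        )


def generate_peptide(
    phi_psi_list: Sequence[Tuple[float, float]], seed: int = 0
) -> StructureModel:
    """Ideal poly-alanine backbone realizing the requested (phi, psi) list.

    Bond lengths N-CA 1.458, CA-C 1.525, C-N 1.329 A; backbone angles
    111/117/121 deg; omega fixed at 180.  phi of the first residue and psi
    of the last are unrealizable (no flanking atoms) and are ignored.
    """
    if len(phi_psi_list) < 1:
        raise ValueError("need at least one residue")
    n_res = len(phi_psi_list)
    b = _Builder()
    # residue 1 in a canonical frame
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BB_N_CA, 0.0, 0.0])
    ang = math.radians(ANG_N_CA_C)
    C = CA + BB_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone = [(N, CA, C)]
    for i in range(1, n_res):
        N_prev, CA_prev, C_prev = backbone[-1]
        psi_prev = phi_psi_list[i - 1][1]
        N_next = geometry.place_atom(N_prev, CA_prev, C_prev,
                                     BB_C_N, ANG_CA_C_N, psi_prev)
        CA_next = geometry.place_atom(CA_prev, C_prev, N_next,
                                      BB_N_CA, ANG_C_N_CA, 180.0)
        C_next = geometry.place_atom(C_prev, N_next, CA_next,
                                     BB_CA_C, ANG_N_CA_C, phi_psi_list[i][0])
        backbone.append((N_next, CA_next, C_next))

    for i, (N_i, CA_i, C_i) in enumerate(backbone):
        seq = i + 1
        b.add("N", "N", "ALA", seq, N_i)
        b.add("CA", "C", "ALA", seq, CA_i)
        b.add("C", "C", "ALA", seq, C_i)
        # carbonyl O anti to the next amide N (or at psi+180 for the C-term)
        psi = phi_psi_list[i][1]
        O_i = geometry.place_atom(N_i, CA_i, C_i, BB_C_O, ANG_CA_C_O,
                                  psi + 180.0)
        b.add("O", "O", "ALA", seq, O_i)
    return StructureModel(
        structure_id=f"PEP{n_res}", atoms=b.atoms, resolution=None,
        source_path="<synthetic>",
    )


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# --- corpus ------------------------------------------------------------------

_CORPUS_COMPOSITIONS = (
    ["HIS-N"] * 4,
    ["HIS-N", "HIS-N", "HIS-N", "ASP-O"],
    ["HIS-N", "HIS-N", "ASP-O", "GLU-O"],
    ["HIS-N", "HIS-N", "HIS-N", "CYS-S"],
    ["HIS-N", "HIS-N", "CYS-S", "HOH-O"],
)

_CORPUS_ACCEPTORS = (
    ("O", "water", 3.2, 170.0),
    ("O", "side_chain", 3.6, 162.0),
    ("S", "side_chain", 4.2, 150.0),
    ("N", "ligand", 3.9, 176.0),
    ("O", "backbone", 3.4, 168.0),
    ("O", "ligand", 2.9, 144.0),
    ("N", "side_chain", 4.6, 155.0),
)


def generate_corpus(
    n_structures: int = 50,
    seed: int = 0,
    noise_sd: float = 0.0,
    full_residues: bool = False,
) -> List[Tuple[StructureModel, pd.DataFrame]]:
    """A seed-fixed corpus cycling compositions, acceptors and decoys.

    Each structure carries one planted site with 2-3 acceptors on distinct
    trans ligands and 2-3 decoy sites, so a 50-structure corpus holds well
    over 100 planted contacts and 100 decoys spanning every violation
    family.
    """
    base = np.random.default_rng(seed)
    child_seeds = base.integers(0, 2**31 - 1, size=n_structures)
    out = []
    for k in range(n_structures):
        comp = list(_CORPUS_COMPOSITIONS[k % len(_CORPUS_COMPOSITIONS)])
        n_acc = 2 + (k % 2)
        acceptors = []
        for j in range(n_acc):
            el, cls, d, theta = _CORPUS_ACCEPTORS[(k + 3 * j) % len(_CORPUS_ACCEPTORS)]
            acceptors.append(
                PlannedAcceptor(element=el, donor_class=cls, d=d + 0.07 * j,
                                theta=theta, trans_index=j % 4, site_index=0)
            )
        decoys = [DECOY_KINDS[(k + j) % len(DECOY_KINDS)] for j in range(2 + k % 2)]
        spec = SyntheticSpec(
            sites=[comp],
            acceptors=acceptors,
            decoys=decoys,
            noise_sd=noise_sd,
            seed=int(child_seeds[k]),
            full_residues=full_residues,
            structure_id=f"SYN{k:03d}",
        )
        out.append(generate_structure(spec))
    return out
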