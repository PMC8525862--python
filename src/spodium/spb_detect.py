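"""Spodium-bond contact detection, classification and Phase-1 selection.

A spodium bond (SpB) is the attractive noncovalent interaction between a
tetrahedrally coordinated Zn(II) center — acting as an electrophile through
the sigma-hole on the extension of one of its Zn-Y coordination bonds — and
an electron-rich acceptor atom A (a lone-pair N, O or S).  A Zn...A contact
qualifies when

    d_min <= d(Zn...A) < d_max        (2.5 A <= d < 5 A by default)
    angle_min <= theta <= 180         (140 deg by default)

where theta is the *maximum* of the four Y-Zn...A angles: the sigma-hole
sits opposite a Zn-Y bond, so the relevant angle is the most nearly linear
one, and the Y achieving it is reported as the trans ligand.

Phase-1 selection restricts to highly directional contacts (theta >= 160
degrees, O/S acceptors) and keeps the single shortest contact per
structure — the subset used to build truncated coordination models.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import geometry
from .structure_io import AtomRecord, StructureModel
from .zn_sites import RadiiTable, ZnSite

logger = logging.getLogger(__name__)

DONOR_CLASSES = ("backbone", "side_chain", "ligand", "water")

#: backbone atom names of a standard amino acid (only N and O can accept)
_BACKBONE_NAMES = frozenset({"N", "O", "C", "CA", "OXT"})


@dataclass
class ContactCriteria:
    """Geometric windows defining a spodium-bond contact."""

    d_min: float = 2.5
    d_max: float = 5.0
    angle_min: float = 140.0
    coord_cutoff: float = 2.5
    acceptor_elements: frozenset = frozenset({"N", "O", "S"})
    exclude_coordinating_residues: bool = False

    def __post_init__(self):
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be below d_max")
        if not 0.0 <= self.angle_min <= 180.0:
            raise ValueError("angle_min must lie in [0, 180]")
        self.acceptor_elements = frozenset(
            e.capitalize() for e in self.acceptor_elements
        )


@dataclass
class SpBContact:
    """One Zn...A spodium-bond contact."""

    site: ZnSite
    acceptor: AtomRecord
    d: float
    theta: float
    trans_ligand: AtomRecord
    r_hat: float
    donor_class: str
    phi: Optional[float] = None
    psi: Optional[float] = None
    ss: Optional[str] = None
    structure_id: str = ""

    @property
    def acceptor_residue(self) -> str:
        return self.acceptor.residue_id


def classify_donor(acceptor: AtomRecord) -> str:
    """Provenance class of an acceptor atom.

    water < het ligand < backbone < side chain, checked in that order:
    waters by residue name, any other HETATM as ligand, standard-residue
    atoms named N/O/C/CA/OXT as backbone, everything else as side chain.
    """
    if acceptor.is_water:
        return "water"
    if acceptor.is_het:
        return "ligand"
    if acceptor.is_standard_aa:
        if acceptor.atom_name in _BACKBONE_NAMES:
            return "backbone"
        return "side_chain"
    logger.warning(
        "nonstandard residue %s with ATOM record: classified side_chain",
        acceptor.residue_name,
    )
    return "side_chain"


def _contact_from_geometry(
    site: ZnSite,
    acceptor: AtomRecord,
    d: float,
    criteria: ContactCriteria,
    radii: RadiiTable,
    model: StructureModel,
    phi_psi_cache: Dict,
) -> Optional[SpBContact]:
    angles = [
        geometry.angle(lig.coords, site.zn.coords, acceptor.coords)
        for lig in site.ligands
    ]
    theta = max(angles)
    if not (criteria.angle_min <= theta <= 180.0):
        return None
    trans = site.ligands[int(np.argmax(angles))]
    r_hat = geometry.normalized_distance(d, acceptor.element, radii)
    phi = psi = ss = None
    if acceptor.is_standard_aa and not acceptor.is_het:
        key = acceptor.residue_key
        if key not in phi_psi_cache:
            phi_psi_cache[key] = geometry.phi_psi(model, key)
        phi, psi = phi_psi_cache[key]
        if phi is not None and psi is not None:
            ss = geometry.ss_class(phi, psi)
    return SpBContact(
        site=site,
        acceptor=acceptor,
        d=d,
        theta=theta,
        trans_ligand=trans,
        r_hat=r_hat,
        donor_class=classify_donor(acceptor),
        phi=phi,
        psi=psi,
        ss=ss,
        structure_id=model.structure_id,
    )


def detect_contacts(
    model: StructureModel,
    sites: Sequence[ZnSite],
    criteria: Optional[ContactCriteria] = None,
    radii: Optional[RadiiTable] = None,
    method: str = "kdtree",
) -> List[SpBContact]:
    """All qualifying Zn...A contacts for the given sites.

    For every N/O/S heavy atom A that is not one of a site's four
    coordinating atoms (and lies beyond the coordination cutoff), the
    distance and the four Y-Zn...A angles are computed; one
    :class:`SpBContact` is emitted per (site, A) pair inside the windows.
    Acceptors belonging to a coordinating *residue* are kept unless
    ``criteria.exclude_coordinating_residues`` is set — only coordination
    bonds themselves are excluded.

    ``method="kdtree"`` uses a spatial index for the radial query;
    ``method="bruteforce"`` scans every (site, atom) pair and is retained
    as the slow reference path.
    """
    criteria = criteria or ContactCriteria()
    radii = radii or RadiiTable()
    candidates = [
        a for a in model.heavy_atoms() if a.element in criteria.acceptor_elements
    ]
    if not candidates or not sites:
        return []
    if method == "kdtree":
        tree = cKDTree(np.vstack([a.coords for a in candidates]))
    elif method != "bruteforce":
        raise ValueError(f"unknown method {method!r}")

    phi_psi_cache: Dict = {}
    contacts: List[SpBContact] = []
    for site in sites:
        coord_ids = {id(lig) for lig in site.ligands}
        coord_res = {lig.residue_key for lig in site.ligands}
        if method == "kdtree":
            idx = tree.query_ball_point(site.zn.coords, criteria.d_max)
            pool = [candidates[i] for i in idx]
        else:
            pool = candidates
        for acc in pool:
            if id(acc) in coord_ids or acc is site.zn:
                continue
            if criteria.exclude_coordinating_residues and acc.residue_key in coord_res:
                continue
            d = float(np.linalg.norm(acc.coords - site.zn.coords))
            # lower bound inclusive, upper bound exclusive; anything inside
            # the coordination shell (d < cutoff) can never be an acceptor
            if d < criteria.d_min or d >= criteria.d_max or d < criteria.coord_cutoff:
                continue
            contact = _contact_from_geometry(
                site, acc, d, criteria, radii, model, phi_psi_cache
            )
            if contact is not None:
                contacts.append(contact)
    contacts.sort(key=lambda c: (c.site.zn.serial, c.acceptor.serial))
    return contacts


def select_directional(
    contacts: Sequence[SpBContact],
    angle_min_hi: float = 160.0,
    elements: Set[str] = frozenset({"O", "S"}),
    d_tie: float = 0.001,
) -> Optional[SpBContact]:
    """Phase-1 selection: the shortest highly directional O/S contact.

    Filters one structure's contacts to theta in [``angle_min_hi``, 180]
    and acceptor element in ``elements``, then returns the contact of
    minimum d; ties within ``d_tie`` A are broken by the larger theta.
    Returns None when nothing qualifies.
    """
    elements = {e.capitalize() for e in elements}
    pool = [
        c for c in contacts
        if angle_min_hi <= c.theta <= 180.0 and c.acceptor.element in elements
    ]
    if not pool:
        return None
    best = pool[0]
    for c in pool[1:]:
        if c.d < best.d - d_tie:
            best = c
        elif abs(c.d - best.d) <= d_tie and c.theta > best.theta:
            best = c
    return best


def contacts_to_table(contacts: Sequence[SpBContact]) -> pd.DataFrame:
    """One row per contact, in the survey's TSV column layout."""
    rows = []
    for c in contacts:
        rows.append(
            {
                "structure_id": c.structure_id,
                "zn_serial": c.site.zn.serial,
                "zn_chain": c.site.zn.chain_id,
                "site_charge": c.site.formal_charge,
                "trans_ligand": f"{c.trans_ligand.residue_id}/{c.trans_ligand.atom_name}",
                "acceptor_residue_name": c.acceptor.residue_name,
                "acceptor_residue_seq": c.acceptor.residue_seq,
                "acceptor_chain": c.acceptor.chain_id,
                "acceptor_atom_name": c.acceptor.atom_name,
                "acceptor_element": c.acceptor.element,
                "donor_class": c.donor_class,
                "d": round(c.d, 3),
                "theta": round(c.theta, 1),
                "r_hat": round(c.r_hat, 4),
                "phi": None if c.phi is None else round(c.phi, 1),
                "psi": None if c.psi is None else round(c.psi, 1),
                "ss_class": c.ss,
            }
        )
    columns = [
        "structure_id", "zn_serial", "zn_chain", "site_charge", "trans_ligand",
        "acceptor_residue_name", "acceptor_residue_seq", "acceptor_chain",
        "acceptor_atom_name", "acceptor_element", "donor_class",
        "d", "theta", "r_hat", "phi", "psi", "ss_class",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_contacts_tsv(contacts: Sequence[SpBContact], path) -> None:
    contacts_to_table(contacts).to_csv(path, sep="\t", index=False)
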