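"""Vector geometry: distances, angles, torsions, backbone dihedrals.

All angles are in degrees. Coordinates are 3-vectors in Angstroms
(anything array-like of length 3 is accepted).
"""
from __future__ import annotations

import math
from typing import TYPE_CHECKING, Optional, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .structure_io import StructureModel
    from .zn_sites import RadiiTable

#: peptide-bond C(i-1)-N distance above which two consecutive residues are
#: treated as a chain break (Angstrom)
CHAIN_BREAK_CN = 1.8


class UndefinedAngleError(ValueError):
    """Raised when an angle or dihedral is geometrically undefined."""


def distance(p, q) -> float:
    """Euclidean distance between two points."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.linalg.norm(p - q))


def angle(a, vertex, c) -> float:
    """Angle a-vertex-c in degrees, in [0, 180].

    The cosine is clamped to [-1, 1] so that nearly collinear arms never
    produce a domain error.
    """
    a = np.asarray(a, dtype=float)
    v = np.asarray(vertex, dtype=float)
    c = np.asarray(c, dtype=float)
    u1 = a - v
    u2 = c - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise UndefinedAngleError("zero-length arm at angle vertex")
    cosang = float(np.dot(u1, u2) / (n1 * n2))
    cosang = max(-1.0, min(1.0, cosang))
    return math.degrees(math.acos(cosang))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion p1-p2-p3-p4 in degrees, in (-180, 180].

    Uses the atan2 construction on the two plane normals, which is stable
    near 0 and 180 degrees.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) == 0.0:
        raise UndefinedAngleError("coincident central atoms in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise UndefinedAngleError("collinear atoms make the dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    # convention: (-180, 180], planar trans maps to +180
    if ang <= -180.0:
        ang += 360.0
    if ang == -180.0:  # pragma: no cover - guarded above
        ang = 180.0
    return ang


def place_atom(a, b, c, bond: float, ang: float, torsion: float) -> np.ndarray:
    """Place a new atom d with given internal coordinates relative to a-b-c.

    ``bond`` = |c-d|, ``ang`` = angle(b, c, d), ``torsion`` =
    dihedral(a, b, c, d); angles in degrees.  This is the standard NeRF
    (natural extension reference frame) construction used by backbone
    builders.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(ang)
    chi = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            -bond * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def phi_psi(
    model: "StructureModel", residue
) -> Tuple[Optional[float], Optional[float]]:
    """Backbone torsions (phi, psi) of one residue, either may be None.

    ``residue`` is a residue key ``(chain_id, residue_seq, insertion_code)``.
    phi = C(i-1)-N-CA-C and psi = N-CA-C-N(i+1).  Chain termini yield only
    the defined member; a peptide-bond C-N distance above
    :data:`CHAIN_BREAK_CN` is treated as a terminus on both sides.
    """
    chain_id = residue[0]
    chain = [key for key in model.residue_keys() if key[0] == chain_id]
    try:
        idx = chain.index(tuple(residue))
    except ValueError:
        raise KeyError(f"residue {residue!r} not found in model")

    def bb(key, name):
        atom = model.find_atom(key, name)
        return None if atom is None else atom.coords

    n = bb(chain[idx], "N")
    ca = bb(chain[idx], "CA")
    c = bb(chain[idx], "C")
    if n is None or ca is None or c is None:
        return None, None

    phi = psi = None
    if idx > 0:
        c_prev = bb(chain[idx - 1], "C")
        if c_prev is not None and distance(c_prev, n) <= CHAIN_BREAK_CN:
            phi = dihedral(c_prev, n, ca, c)
    if idx + 1 < len(chain):
        n_next = bb(chain[idx + 1], "N")
        if n_next is not None and distance(c, n_next) <= CHAIN_BREAK_CN:
            psi = dihedral(n, ca, c, n_next)
    return phi, psi


# phi/psi boxes for the secondary-structure classes, checked in priority
# order; values in degrees.
_SS_BOXES = (
    ("alpha_R", (-100.0, -30.0), (-67.0, -7.0)),
    ("alpha_L", (30.0, 100.0), (7.0, 67.0)),
    ("collagen_PPII", (-90.0, -45.0), (120.0, 180.0)),
)


def ss_class(phi: float, psi: float) -> str:
    """Coarse secondary-structure class from one (phi, psi) pair.

    Rectangular boxes approximate the classic Ramachandran clusters:
    right-handed alpha helix, left-handed alpha helix, collagen/polyproline
    II, and beta sheet; anything else is ``other``.  This is a deliberate
    stand-in for a full hydrogen-bond-pattern assigner and is only as good
    as the boxes.
    """
    for name, (plo, phi_hi), (slo, shi) in _SS_BOXES:
        if plo <= phi <= phi_hi and slo <= psi <= shi:
            return name
    if -180.0 <= phi <= -45.0 and (90.0 <= psi <= 180.0 or -180.0 <= psi <= -150.0):
        return "beta"
    return "other"


def normalized_distance(d: float, element: str, radii: "RadiiTable" = None,
                        zn_radius: str = "bondi") -> float:
    """Zn...A distance divided by the sum of Zn and A van der Waals radii.

    ``element`` is the acceptor element (N, O or S).  Bondi radii by
    default; ``zn_radius="alvarez"`` substitutes the longer Alvarez Zn
    radius (2.39 A).
    """
    from .zn_sites import RadiiTable

    if radii is None:
        radii = RadiiTable()
    element = element.capitalize()
    if element not in radii.vdw:
        raise KeyError(f"no van der Waals radius for element {element!r}")
    if zn_radius == "alvarez":
        zn = radii.vdw_alvarez_zn
    elif zn_radius == "bondi":
        zn = radii.vdw["Zn"]
    else:
        raise ValueError(f"unknown zn_radius source {zn_radius!r}")
    return d / (zn + radii.vdw[element])
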