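"""Spodium-bond contact detection, donor classes, Phase-1 selection."""
import copy
import math

import numpy as np
import pytest

from spodium import zn_sites
from spodium.spb_detect import (
    classify_donor,
    contacts_to_table,
    detect_contacts,
    select_directional,
)
from spodium.structure_io import AtomRecord, StructureModel
from spodium.synthetic import TETRA_DIRS

from conftest import oracle_angle, oracle_contact_scan, oracle_distance, rigid_transform


def site_with_acceptor(d, theta, element="O", resname="HOH", aname="O"):
    """Zn at origin, 4 HIS N ligands, one acceptor at (d, theta) vs ligand 0."""
    atoms = [AtomRecord(1, "ZN", "Zn", "ZN", 1, "A", (0, 0, 0), is_het=True)]
    for i in range(4):
        atoms.append(
            AtomRecord(i + 2, "NE2", "N", "HIS", i + 2, "A", 2.0 * TETRA_DIRS[i])
        )
    u = TETRA_DIRS[0]
    p = np.cross(u, [0.0, 0.0, 1.0])
    p /= np.linalg.norm(p)
    beta = math.radians(180.0 - theta)
    direction = -u * math.cos(beta) + p * math.sin(beta)
    atoms.append(
        AtomRecord(6, aname, element, resname, 10, "A", d * direction,
                   is_het=resname in ("HOH", "LIG"))
    )
    model = StructureModel("T", atoms=atoms, resolution=1.5)
    sites = zn_sites.find_zn_sites(model)
    assert len(sites) == 1
    return model, sites


class TestDetection:
    def test_collinear_acceptor(self):
        model, sites = site_with_acceptor(3.5, 180.0)
        (c,) = detect_contacts(model, sites)
        assert c.d == pytest.approx(3.5, abs=1e-9)
        assert c.theta == pytest.approx(180.0, abs=1e-6)
        assert c.trans_ligand.serial == 2

    def test_distance_window_upper_exclusive(self):
        model, sites = site_with_acceptor(5.2, 180.0)
        assert detect_contacts(model, sites) == []
        model, sites = site_with_acceptor(5.0, 180.0)
        assert detect_contacts(model, sites) == []
        model, sites = site_with_acceptor(4.999, 180.0)
        assert len(detect_contacts(model, sites)) == 1

    def test_distance_window_lower_inclusive(self):
        model, sites = site_with_acceptor(2.5, 180.0)
        (c,) = detect_contacts(model, sites)
        assert c.d == pytest.approx(2.5, abs=1e-12)

    def test_angle_window(self):
        model, sites = site_with_acceptor(3.5, 139.0)
        assert detect_contacts(model, sites) == []
        model, sites = site_with_acceptor(3.5, 140.0)
        assert len(detect_contacts(model, sites)) == 1

    def test_all_angles_below_window(self):
        # along the bisector of two ligand directions every Y-Zn-A angle
        # stays near 125 deg (verified by brute force below)
        atoms = [AtomRecord(1, "ZN", "Zn", "ZN", 1, "A", (0, 0, 0), is_het=True)]
        for i in range(4):
            atoms.append(
                AtomRecord(i + 2, "NE2", "N", "HIS", i + 2, "A",
                           2.0 * TETRA_DIRS[i])
            )
        u = (TETRA_DIRS[0] + TETRA_DIRS[1])
        u /= np.linalg.norm(u)
        atoms.append(AtomRecord(6, "O", "O", "HOH", 10, "A", 3.5 * u, is_het=True))
        model = StructureModel("T", atoms=atoms, resolution=1.5)
        sites = zn_sites.find_zn_sites(model)
        max_angle = max(
            oracle_angle(2.0 * TETRA_DIRS[i], (0, 0, 0), 3.5 * u) for i in range(4)
        )
        assert max_angle < 140.0
        assert detect_contacts(model, sites) == []

    def test_theta_is_max_over_ligands(self):
        model, sites = site_with_acceptor(3.5, 165.0)
        (c,) = detect_contacts(model, sites)
        angles = [
            oracle_angle(lig.coords, c.site.zn.coords, c.acceptor.coords)
            for lig in c.site.ligands
        ]
        assert c.theta == pytest.approx(max(angles), abs=1e-9)

    def test_coordinating_atoms_never_acceptors(self):
        model, sites = site_with_acceptor(3.5, 180.0)
        contacts = detect_contacts(model, sites)
        coord_serials = {lig.serial for lig in sites[0].ligands}
        assert all(c.acceptor.serial not in coord_serials for c in contacts)

    def test_posthoc_audit_on_corpus(self, corpus):
        """Every emitted contact satisfies the windows when recomputed
        with an independent scalar implementation."""
        for model, _ in corpus[:10]:
            sites = zn_sites.find_zn_sites(model)
            for c in detect_contacts(model, sites):
                d = oracle_distance(c.acceptor.coords, c.site.zn.coords)
                assert 2.5 <= d < 5.0
                assert d == pytest.approx(c.d, abs=1e-9)
                theta = max(
                    oracle_angle(l.coords, c.site.zn.coords, c.acceptor.coords)
                    for l in c.site.ligands
                )
                assert 140.0 <= theta <= 180.0
                assert theta == pytest.approx(c.theta, abs=1e-9)

    def test_oracle_equivalence_on_corpus(self, corpus):
        """KD-tree detection equals the O(N^2) scan, contact for contact."""
        for model, _ in corpus:
            sites = zn_sites.find_zn_sites(model)
            fast = detect_contacts(model, sites, method="kdtree")
            slow = detect_contacts(model, sites, method="bruteforce")
            key = lambda c: (c.site.zn.serial, c.acceptor.serial, c.d, c.theta)
            assert [key(c) for c in fast] == [key(c) for c in slow]

    def test_rigid_motion_invariance(self, corpus):
        model, _ = corpus[1]
        ref = detect_contacts(model, zn_sites.find_zn_sites(model))
        moved = copy.deepcopy(model)
        rigid_transform(moved, seed=3)
        new = detect_contacts(moved, zn_sites.find_zn_sites(moved))
        assert [(c.site.zn.serial, c.acceptor.serial) for c in new] == [
            (c.site.zn.serial, c.acceptor.serial) for c in ref
        ]
        for a, b in zip(new, ref):
            assert a.d == pytest.approx(b.d, abs=1e-9)
            assert a.theta == pytest.approx(b.theta, abs=1e-7)

    def test_r_hat_monotone_in_d(self):
        ds = [2.6, 3.0, 3.7, 4.4, 4.9]
        r_hats = []
        for d in ds:
            model, sites = site_with_acceptor(d, 175.0)
            (c,) = detect_contacts(model, sites)
            r_hats.append(c.r_hat)
        assert all(a < b for a, b in zip(r_hats, r_hats[1:]))


class TestDonorClass:
    @pytest.mark.parametrize(
        "resname,aname,het,expected",
        [
            ("HOH", "O", True, "water"),
            ("DOD", "O", True, "water"),
            ("LYS", "O", False, "backbone"),
            ("LYS", "N", False, "backbone"),
            ("MET", "SD", False, "side_chain"),
            ("SER", "OG", False, "side_chain"),
            ("LIG", "O1", True, "ligand"),
            ("ALA", "OXT", False, "backbone"),
        ],
    )
    def test_classes(self, resname, aname, het, expected):
        atom = AtomRecord(1, aname, aname[0], resname, 1, "A", (0, 0, 0),
                          is_het=het)
        assert classify_donor(atom) == expected

    def test_nonstandard_atom_record_is_side_chain(self):
        atom = AtomRecord(1, "NX", "N", "XYZ", 1, "A", (0, 0, 0))
        assert classify_donor(atom) == "side_chain"


def _mock_contacts(specs):
    """Build lightweight contacts with given (d, theta, element)."""
    out = []
    for d, theta, element in specs:
        model, sites = site_with_acceptor(d, theta, element=element,
                                          resname="HOH", aname="O")
        cs = detect_contacts(model, sites)
        if cs:
            out.extend(cs)
    return out


class TestPhase1Selection:
    def test_directionality_filter(self):
        contacts = _mock_contacts([(3.2, 165.0, "O"), (2.9, 150.0, "O")])
        chosen = select_directional(contacts)
        assert chosen.d == pytest.approx(3.2, abs=1e-9)

    def test_singleton(self):
        contacts = _mock_contacts([(4.0, 179.0, "O")])
        assert select_directional(contacts) is contacts[0]

    def test_shortest_wins(self):
        contacts = _mock_contacts([(3.0, 162.0, "O"), (3.4, 178.0, "O")])
        assert select_directional(contacts).d == pytest.approx(3.0, abs=1e-9)

    def test_element_restriction(self):
        model, sites = site_with_acceptor(3.0, 170.0, element="N",
                                          resname="LIG", aname="N1")
        contacts = detect_contacts(model, sites)
        assert contacts and select_directional(contacts) is None
        assert select_directional(contacts, elements={"N"}) is contacts[0]

    def test_tie_broken_by_theta(self):
        contacts = _mock_contacts([(3.2, 165.0, "O"), (3.2004, 171.0, "O")])
        assert select_directional(contacts).theta == pytest.approx(171.0, abs=0.01)

    def test_empty(self):
        assert select_directional([]) is None


class TestPlantedRecovery:
    def test_recall_and_precision_are_perfect(self, corpus):
        """Ground-truth contacts are all found and nothing else is."""
        tp = fp = fn = 0
        for model, truth in corpus:
            sites = zn_sites.find_zn_sites(model)
            got = {
                (c.site.zn.serial, c.acceptor.serial)
                for c in detect_contacts(model, sites)
            }
            exp = {
                (int(r.zn_serial), int(r.acceptor_serial))
                for r in truth.itertuples()
                if r.kind == "contact"
            }
            tp += len(got & exp)
            fp += len(got - exp)
            fn += len(exp - got)
        assert fp == 0 and fn == 0 and tp > 0

    def test_decoys_yield_nothing(self, corpus):
        """Each violation family is represented and produces no contact."""
        seen = set()
        for model, truth in corpus:
            seen.update(truth.loc[truth.is_decoy, "violation"])
            got = oracle_contact_scan(model)
            decoy_zn = {
                int(r.zn_serial) for r in truth.itertuples() if r.is_decoy
            }
            assert not {pair for pair in got if pair[0] in decoy_zn}
        assert seen == {"coord3", "coord5", "d_below", "d_above", "theta_below"}


class TestTable:
    def test_column_layout_and_rounding(self):
        model, sites = site_with_acceptor(3.45678, 171.234)
        contacts = detect_contacts(model, sites)
        df = contacts_to_table(contacts)
        assert list(df.columns[:5]) == [
            "structure_id", "zn_serial", "zn_chain", "site_charge", "trans_ligand",
        ]
        assert df.loc[0, "d"] == pytest.approx(3.457, abs=1e-9)
        assert df.loc[0, "donor_class"] == "water"
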