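"""Truncated coordination models: atom counts, frozen coordinates, charges."""
import numpy as np
import pytest

from spodium import spb_detect, synthetic, zn_sites
from spodium.model_builder import (
    TruncationError,
    build_model,
    cap_partner,
    default_overrides,
    infer_scheme,
    read_xyz,
    truncate_residue,
    write_xyz,
)
from spodium.synthetic import PlannedAcceptor, SyntheticSpec


def full_site(composition, acceptor, seed=5):
    spec = SyntheticSpec(
        sites=[composition],
        acceptors=[acceptor],
        seed=seed,
        full_residues=True,
    )
    model, _ = synthetic.generate_structure(spec)
    sites = zn_sites.find_zn_sites(model)
    assert len(sites) == 1
    contacts = spb_detect.detect_contacts(model, sites)
    chosen = spb_detect.select_directional(
        contacts, elements={"N", "O", "S"}
    )
    assert chosen is not None
    return model, chosen


WATER = PlannedAcceptor("O", "water", 3.2, 175.0, 0, 0)


class TestTruncation:
    @pytest.mark.parametrize(
        "code,n_heavy",
        [("HIS-N", 5), ("ASP-O", 4), ("GLU-O", 4), ("CYS-S", 2)],
    )
    def test_retained_heavy_atom_counts(self, code, n_heavy):
        comp = [code] + ["HIS-N"] * 3
        model, contact = full_site(comp, WATER)
        key = contact.site.ligands[0].residue_key
        # ligand order is serial-sorted; find the residue of interest
        resname = code.split("-")[0]
        keys = {
            l.residue_key for l in contact.site.ligands
            if l.residue_name == resname
        }
        frag = truncate_residue(model, next(iter(keys)))
        assert len(frag.atoms) == n_heavy

    def test_his_ring_atom_names(self):
        model, contact = full_site(["HIS-N"] * 4, WATER)
        frag = truncate_residue(model, contact.site.ligands[0].residue_key)
        assert {a.atom_name for a in frag.atoms} == {
            "CG", "ND1", "CD2", "CE1", "NE2"
        }
        assert len(frag.cap_sites) == 1  # severed CB position

    def test_unsupported_residue(self):
        pep = synthetic.generate_peptide([(-57.0, -47.0)] * 2)
        with pytest.raises(TruncationError):
            truncate_residue(pep, pep.residue_keys()[0])

    def test_coordinates_frozen(self):
        model, contact = full_site(["ASP-O"] + ["HIS-N"] * 3, WATER)
        for lig in contact.site.ligands:
            frag = truncate_residue(model, lig.residue_key)
            for atom in frag.atoms:
                src = model.find_atom(atom.residue_key, atom.atom_name)
                assert np.array_equal(atom.coords, src.coords)


class TestCapping:
    def test_scheme_b_backbone_fragment(self):
        model, contact = full_site(
            ["HIS-N"] * 4,
            PlannedAcceptor("O", "backbone", 3.5, 172.0, 0, 0),
        )
        frag = cap_partner(model, contact, "B")
        names = {a.atom_name for a in frag.atoms}
        assert {"N", "CA", "C", "O"} <= names

    def test_scheme_d_water_with_template_h(self):
        model, contact = full_site(["HIS-N"] * 4, WATER)
        frag = cap_partner(model, contact, "D")
        elements = sorted(a.element for a in frag.atoms)
        assert elements == ["H", "H", "O"]
        o = next(a for a in frag.atoms if a.element == "O")
        for h in (a for a in frag.atoms if a.element == "H"):
            assert np.linalg.norm(h.coords - o.coords) == pytest.approx(0.96)

    def test_scheme_a_methyl_caps_side_chain_kept(self):
        model, contact = full_site(
            ["HIS-N"] * 4,
            PlannedAcceptor("S", "side_chain", 4.0, 170.0, 0, 0),
        )
        frag = cap_partner(model, contact, "A")
        names = {a.atom_name for a in frag.atoms}
        assert "SD" in names  # the acceptor side chain survives
        assert all(a.element != "O" or a.atom_name != "O" for a in frag.atoms)

    def test_scheme_c_ligand_kept_whole(self):
        model, contact = full_site(
            ["HIS-N"] * 4,
            PlannedAcceptor("N", "ligand", 3.8, 170.0, 0, 0),
        )
        frag = cap_partner(model, contact, "C")
        assert len(frag.atoms) == len(model.residue_atoms(
            contact.acceptor.residue_key
        ))


class TestBuildModel:
    def test_scheme_inference(self):
        model, contact = full_site(["HIS-N"] * 4, WATER)
        assert infer_scheme(contact) == "D"

    def test_his3_asp_site_with_sidechain_partner(self):
        model, contact = full_site(
        ["HIS-N", "HIS-N", "HIS-N", "ASP-O"],
            PlannedAcceptor("O", "side_chain", 3.0, 176.0, 1, 0),
        )
        tm = build_model(contact, model)
        assert tm.scheme == "A"
        # Zn + 3x imidazole(5) + acetate(4)
        assert len(tm.zn_fragment) == 1 + 15 + 4
        assert tm.net_charge == 1  # site +1, neutral hydroxyl partner

    def test_his4_water_net_charge(self):
        model, contact = full_site(["HIS-N"] * 4, WATER)
        tm = build_model(contact, model)
        assert tm.scheme == "D" and tm.net_charge == 2

    def test_his2asp2_water_net_charge(self):
        model, contact = full_site(
            ["HIS-N", "HIS-N", "ASP-O", "ASP-O"], WATER
        )
        tm = build_model(contact, model)
        assert tm.net_charge == 0

    def test_charge_additivity(self):
        """net = site charge + partner charge across compositions/partners."""
        cases = [
            (["HIS-N"] * 4, WATER, 0),
            (["HIS-N", "HIS-N", "HIS-N", "CYS-S"], WATER, 0),
            (["HIS-N", "HIS-N", "ASP-O", "CYS-S"],
             PlannedAcceptor("O", "side_chain", 3.1, 174.0, 0, 0), 0),
        ]
        for comp, acceptor, pcharge in cases:
            model, contact = full_site(comp, acceptor)
            tm = build_model(contact, model)
            assert tm.net_charge == contact.site.formal_charge + pcharge

    def test_heavy_atoms_bitwise_frozen(self):
        model, contact = full_site(
            ["HIS-N", "HIS-N", "CYS-S", "ASP-O"], WATER
        )
        tm = build_model(contact, model)
        by_identity = {
            (a.residue_key, a.atom_name): a for a in model.atoms
        }
        for atom in tm.atoms:
            if atom.element == "H":
                continue
            src = by_identity[(atom.residue_key, atom.atom_name)]
            assert atom.coords.tobytes() == src.coords.tobytes()

    def test_overrides_shift_charges(self):
        model, contact = full_site(["HIS-N"] * 4, WATER)
        tm = build_model(contact, model,
                         overrides={"site_charge_delta": -1})
        assert tm.net_charge == 1

    def test_shipped_override_table_loads(self):
        table = default_overrides()
        assert table["6R6F"]["site_charge_delta"] == -1
        assert table["5LE1"]["partner_charge"] == 0


class TestXYZ:
    def test_round_trip(self, tmp_path):
        model, contact = full_site(["HIS-N"] * 4, WATER)
        tm = build_model(contact, model)
        path = tmp_path / "m.xyz"
        write_xyz(tm, path)
        elements, coords, comment = read_xyz(path)
        assert elements == [a.element for a in tm.atoms]
        assert np.allclose(coords, np.vstack([a.coords for a in tm.atoms]),
                           atol=1e-6)
        assert "charge=+2" in comment
        sidecar = (tmp_path / "m.xyz.json")
        assert sidecar.exists()

    def test_single_atom_model_is_three_lines(self, tmp_path):
        from spodium.model_builder import TruncatedModel
        from spodium.structure_io import AtomRecord

        tm = TruncatedModel(
            scheme="D",
            zn_fragment=[AtomRecord(1, "ZN", "Zn", "ZN", 1, "A", (0, 0, 0),
                                    is_het=True)],
            partner_fragment=[],
            net_charge=2,
            provenance="unit",
        )
        path = tmp_path / "one.xyz"
        write_xyz(tm, path)
        assert len(path.read_text().rstrip("\n").split("\n")) == 3
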