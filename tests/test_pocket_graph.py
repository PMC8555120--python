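import numpy as np
import pytest

from pocketgnn.pocket_graph import (
    Residue, PocketError, NonStandardResidue, STANDARD_AA3,
    bin_ca_distance, residue_one_hot, parse_pdb_complex,
    extract_contact_residues, build_pocket_graph, extract_pocket,
    write_pocket, read_pocket,
)
from pocketgnn.synthetic_data import generate_toy_complex_pdb

from _oracles import bin_distance_literal, pocket_edges_bruteforce


def _residue(idx, aa3, ca):
    ca = np.asarray(ca, dtype=float)
    return Residue(chain_id="A", seq_number=idx, aa3=aa3, ca_coord=ca,
                   heavy_atom_coords=[ca])


class TestDistanceBinning:
    @pytest.mark.parametrize("d,cls", [
        (3.0, "I"), (8.0, "III"), (12.0, "V"),
        (4.8, "II"),          # shared endpoint goes to the upper bin
        (1.0, "I"), (13.5999, "V"),
        (14.0, None), (0.5, None), (13.6, None), (0.0, None),
    ])
    def test_printed_intervals_half_open(self, d, cls):
        assert bin_ca_distance(d) == cls

    def test_negative_distance_is_an_error(self):
        with pytest.raises(ValueError):
            bin_ca_distance(-0.1)


class TestOneHot:
    def test_alphabetical_extremes(self):
        ala = residue_one_hot("ALA")
        val = residue_one_hot("VAL")
        assert ala[0] == 1 and ala.sum() == 1
        assert val[19] == 1 and val.sum() == 1

    def test_every_standard_code_hits_a_distinct_index(self):
        idx = {np.argmax(residue_one_hot(aa)) for aa in STANDARD_AA3}
        assert idx == set(range(20))

    def test_non_standard_residue_signalled(self):
        with pytest.raises(NonStandardResidue):
            residue_one_hot("MSE")


class TestParsePdbComplex:
    def test_toy_fixture_round_trip(self):
        toy = generate_toy_complex_pdb(3, 2, [2.0, 4.0, 6.0], seed=0)
        protein, ligand = parse_pdb_complex(toy.pdb_text, "LIG")
        assert len(protein) == 3
        assert len(ligand) == 2
        assert all(r.ca_coord.shape == (3,) for r in protein)

    def test_missing_ligand_code_is_an_error(self):
        toy = generate_toy_complex_pdb(3, 2, [2.0, 4.0, 6.0], seed=0)
        with pytest.raises(PocketError):
            parse_pdb_complex(toy.pdb_text, "XYZ")

    def test_water_never_accepted_as_ligand(self):
        toy = generate_toy_complex_pdb(3, 1, [2.0, 4.0, 6.0], seed=0)
        with pytest.raises(PocketError):
            parse_pdb_complex(toy.pdb_text, "HOH")

    def test_residue_without_ca_dropped_with_warning(self):
        toy = generate_toy_complex_pdb(3, 1, [2.0, 4.0, 6.0], seed=0)
        # strip the CA of residue 2
        kept = [ln for ln in toy.pdb_text.splitlines()
                if not (ln.startswith("ATOM") and " CA " in ln and " A   2" in ln)]
        with pytest.warns(UserWarning, match="no CA"):
            protein, _ = parse_pdb_complex("\n".join(kept) + "\n", "LIG")
        assert len(protein) == 2


class TestContactExtraction:
    def test_planted_distances_select_exactly_within_cutoff(self):
        toy = generate_toy_complex_pdb(4, 2, [2.0, 4.0, 5.0, 8.0], seed=3)
        protein, ligand = parse_pdb_complex(toy.pdb_text, "LIG")
        contacts = extract_contact_residues(protein, ligand, 4.5)
        assert [r.seq_number - 1 for r in contacts] == sorted(toy.contact_set(4.5))
        assert toy.contact_set(4.5) == {0, 1}

    def test_increasing_cutoff_never_removes_a_contact(self):
        toy = generate_toy_complex_pdb(6, 2, [1.5, 3.0, 4.4, 5.5, 7.0, 10.0],
                                       seed=5)
        protein, ligand = parse_pdb_complex(toy.pdb_text, "LIG")
        previous: set[int] = set()
        for cutoff in (2.0, 4.0, 6.0, 8.0, 12.0):
            got = {r.seq_number for r in
                   extract_contact_residues(protein, ligand, cutoff)}
            assert previous <= got
            previous = got

    def test_empty_ligand_is_an_error_empty_result_warns(self):
        res = [_residue(1, "ALA", [0, 0, 0])]
        with pytest.raises(PocketError):
            extract_contact_residues(res, [], 4.5)
        far = [_residue(1, "ALA", [50, 0, 0])]
        with pytest.warns(UserWarning, match="empty pocket"):
            assert extract_contact_residues(far, [np.zeros(3)], 4.5) == []


class TestBuildPocketGraph:
    def test_two_residues_at_3_8_angstroms_get_class_I_edge(self):
        g = build_pocket_graph([_residue(1, "ALA", [0, 0, 0]),
                                _residue(2, "GLY", [3.8, 0, 0])])
        assert g.edges == [(0, 1, "I")]

    def test_distant_residues_get_no_edge(self):
        g = build_pocket_graph([_residue(1, "ALA", [0, 0, 0]),
                                _residue(2, "GLY", [20.0, 0, 0])])
        assert g.edges == []

    def test_collinear_residues_match_hand_computed_bins(self):
        # Cα at 0, 5, 10, 15 Å: pair distances 5,10,15,5,10,5
        g = build_pocket_graph([
            _residue(i + 1, "ALA", [5.0 * i, 0, 0]) for i in range(4)
        ])
        assert set(g.edges) == {(0, 1, "II"), (0, 2, "IV"), (1, 2, "II"),
                                (1, 3, "IV"), (2, 3, "II")}

    def test_one_hot_rows_are_valid_indicators(self):
        g = build_pocket_graph([_residue(1, "TRP", [0, 0, 0]),
                                _residue(2, "VAL", [4.0, 0, 0])])
        assert g.vertex_onehots.shape == (2, 20)
        assert (g.vertex_onehots.sum(axis=1) == 1).all()
        assert g.vertex_onehots[0][17] == 1  # TRP alphabetical index

    def test_non_standard_residues_dropped_empty_pocket_is_error(self):
        with pytest.warns(UserWarning, match="non-standard"):
            g = build_pocket_graph([_residue(1, "MSE", [0, 0, 0]),
                                    _residue(2, "ALA", [3.0, 0, 0])])
        assert g.vertex_labels == ["ALA"]
        with pytest.raises(PocketError):
            build_pocket_graph([_residue(1, "MSE", [0, 0, 0])])

    def test_edges_match_bruteforce_double_loop(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(2, 20))
            coords = rng.uniform(0, 15, size=(n, 3))
            residues = [_residue(i + 1, "LEU", coords[i]) for i in range(n)]
            g = build_pocket_graph(residues)
            assert set(g.edges) == pocket_edges_bruteforce(coords)

    def test_rigid_motion_leaves_the_graph_unchanged(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 12, size=(12, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q.T + np.array([100.0, -50.0, 3.0])
        g1 = build_pocket_graph([_residue(i, "SER", c)
                                 for i, c in enumerate(coords, 1)])
        g2 = build_pocket_graph([_residue(i, "SER", c)
                                 for i, c in enumerate(moved, 1)])
        assert g1.edges == g2.edges


class TestPocketTextFormat:
    def test_write_read_round_trip(self):
        toy = generate_toy_complex_pdb(5, 2, [2.0, 3.0, 4.0, 4.4, 9.0], seed=9)
        pocket = extract_pocket(toy.pdb_text, "LIG", 4.5)
        again = read_pocket(write_pocket(pocket))
        assert again.vertex_labels == pocket.vertex_labels
        assert again.edges == pocket.edges
        assert np.allclose(again.vertex_onehots, pocket.vertex_onehots)

    def test_rejects_other_formats(self):
        with pytest.raises(ValueError):
            read_pocket("#something-else v9\n")
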