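import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipsite.errors import AmbiguousMappingError
from lipsite.quant_io import Atom, Residue, StructureModel
from lipsite.structure_mapping import (
    center_of_mass,
    compare_peptide_sets,
    map_peptide_to_structure,
    predict_binding_site,
    selection_string,
)
from lipsite.synthetic import write_toy_structure

_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def _atom(x, y, z, element="C", name="CA"):
    return Atom(name, element, _MASS[element], x, y, z)


def _single_atom_structure(positions, letters="ACD"):
    """Chain of 1-atom residues at the given positions."""
    from lipsite.quant_io import ONE_TO_THREE

    model = StructureModel()
    model.chains["A"] = [
        Residue(
            name=ONE_TO_THREE[letters[i]], number=i + 1,
            atoms=(_atom(*positions[i]),),
        )
        for i in range(len(positions))
    ]
    return model


class TestMapping:
    def test_full_chain_match_covers_all_residues(self):
        model = write_toy_structure("MKTAYIAK", "helix")
        m = map_peptide_to_structure("MKTAYIAK", model, "A")
        assert (m.start, m.end) == (1, 8)
        assert m.matched_residues == 8

    def test_peptide_planted_at_offset_17(self):
        # string-search oracle: residue numbering starts at 1, so a peptide
        # at 0-based offset 17 starts at author residue 18
        background = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        pep = "WWHHWW"
        seq = background[:17] + pep + background[17:30]
        assert seq.find(pep) == 17
        model = write_toy_structure(seq, "helix")
        m = map_peptide_to_structure(pep, model, "A")
        assert m.start == 18
        assert m.end == 18 + len(pep) - 1

    def test_absent_peptide_is_unmapped_not_fatal(self):
        model = write_toy_structure("MKTAYIAK", "helix")
        m = map_peptide_to_structure("WWWW", model, "A")
        assert not m.mapped and not m.usable

    def test_multiple_matches_raise_with_positions(self):
        model = write_toy_structure("AKCAKC", "helix")
        with pytest.raises(AmbiguousMappingError) as exc:
            map_peptide_to_structure("AKC", model, "A")
        assert exc.value.positions == [0, 3]

    def test_il_equivalence_flag(self):
        model = write_toy_structure("MKTAYLAK", "helix")
        assert not map_peptide_to_structure("TAYIAK", model, "A").mapped
        m = map_peptide_to_structure("TAYIAK", model, "A", il_equivalent=True)
        assert m.mapped

    def test_mapping_independent_of_other_chains(self):
        model = write_toy_structure("MKTAYIAK", "helix")
        model.chains["B"] = list(write_toy_structure("GGGG", "helix").chains["A"])
        m = map_peptide_to_structure("MKTAYIAK", model, "A")
        assert m.chain_id == "A" and m.matched_residues == 8

    def test_unknown_chain_raises(self):
        model = write_toy_structure("MKTA", "helix")
        with pytest.raises(KeyError):
            map_peptide_to_structure("MKTA", model, "Q")


class TestCenterOfMass:
    def test_single_atom(self):
        com = center_of_mass([_atom(1.0, 2.0, 3.0)])
        np.testing.assert_allclose(com, [1, 2, 3])
        np.testing.assert_allclose(
            center_of_mass([_atom(1.0, 2.0, 3.0)], weighting="geometric"), [1, 2, 3]
        )

    def test_two_same_element_atoms_symmetric(self):
        com = center_of_mass([_atom(0, 0, 0), _atom(2, 0, 0)])
        np.testing.assert_allclose(com, [1, 0, 0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            center_of_mass([])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 100))
        elements = rng.choice(list(_MASS), size=n)
        coords = rng.uniform(-50, 50, size=(n, 3))
        atoms = [_atom(*coords[i], element=elements[i]) for i in range(n)]
        for weighting in ("mass", "geometric"):
            # independent accumulation, scalar loop
            sw, acc = 0.0, np.zeros(3)
            for a in atoms:
                w = a.mass if weighting == "mass" else 1.0
                sw += w
                acc += w * np.array([a.x, a.y, a.z])
            np.testing.assert_allclose(
                center_of_mass(atoms, weighting), acc / sw, atol=1e-9
            )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_translation_and_rotation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        atoms = [
            _atom(*rng.uniform(-20, 20, 3), element=rng.choice(list(_MASS)))
            for _ in range(n)
        ]
        com = center_of_mass(atoms)
        shift = rng.uniform(-5, 5, 3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = [
            Atom(a.name, a.element, a.mass, *(q @ (a.coord + shift))) for a in atoms
        ]
        np.testing.assert_allclose(center_of_mass(moved), q @ (com + shift), atol=1e-9)


class TestPredictBindingSite:
    def test_single_atom_site(self):
        model = _single_atom_structure([(1.0, 2.0, 3.0)], "A")
        m = map_peptide_to_structure("A", model, "A")
        pred = predict_binding_site([m], model)
        np.testing.assert_allclose(pred.com, [1, 2, 3])
        assert pred.atom_count == 1

    def test_symmetric_peptides_triangulate_symmetry_center(self):
        """Three identical single-residue 'peptides' at 120-degree rotations
        about the z-axis through (5, 5, 0): the pooled CoM is the center."""
        center = np.array([5.0, 5.0, 0.0])
        positions = []
        for k in range(3):
            theta = 2 * np.pi * k / 3
            rot = np.array(
                [
                    [np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1],
                ]
            )
            positions.append(center + rot @ np.array([7.0, 0.0, 0.0]))
        model = _single_atom_structure(positions, "ACD")
        mappings = [map_peptide_to_structure(p, model, "A") for p in "ACD"]
        pred = predict_binding_site(mappings, model)
        np.testing.assert_allclose(pred.com, center, atol=1e-6)

    def test_overlapping_peptides_deduplicated_by_default(self):
        model = write_toy_structure("MKTAYIAKQRWS", "helix")
        m1 = map_peptide_to_structure("MKTAYIAK", model, "A")
        m2 = map_peptide_to_structure("AYIAKQRWS", model, "A")
        dedup = predict_binding_site([m1, m2], model)
        multi = predict_binding_site([m1, m2], model, deduplicate=False)
        union_atoms = sum(
            len(r.atoms) for r in model.chains["A"]
        )  # the two peptides jointly cover the whole chain
        assert dedup.atom_count == union_atoms
        assert multi.atom_count == len(m1.atoms) + len(m2.atoms)
        assert multi.atom_count > dedup.atom_count

    def test_all_unusable_is_error(self):
        model = write_toy_structure("MKTA", "helix")
        bad = map_peptide_to_structure("WWW", model, "A")
        with pytest.raises(ValueError, match="usable"):
            predict_binding_site([bad], model)

    def test_nearby_residues_sorted_by_distance(self):
        model = write_toy_structure("MKTAYIAKQRWS", "helix")
        m = map_peptide_to_structure("MKTAYIAKQRWS", model, "A")
        pred = predict_binding_site([m], model, neighbor_radius=15.0)
        dists = [d for _, _, d in pred.nearby_residues]
        assert dists == sorted(dists)
        assert all(d <= 15.0 for d in dists)

    def test_end_to_end_com_near_planted_pocket(self, noisy_experiment):
        from lipsite.dose_response import fit_peptide, rank_peptides, select_top

        centered, structure, truth = noisy_experiment
        fits = [fit_peptide(centered, p) for p in truth.responsive_peptides]
        top = select_top(rank_peptides(fits), k=3)
        mappings = [
            map_peptide_to_structure(p, structure, "A") for p in top.peptides
        ]
        pred = predict_binding_site(mappings, structure)
        assert np.linalg.norm(pred.com - truth.pocket_center) < 10.0


class TestCompareSets:
    @staticmethod
    def _mapped(model, peps):
        return [map_peptide_to_structure(p, model, "A") for p in peps]

    def test_identical_sets_fully_overlap(self):
        model = write_toy_structure("MKTAYIAKQRWSDEFGHCNP", "helix")
        maps = self._mapped(model, ["MKTAY", "AKQRW", "FGHCN"])
        report = compare_peptide_sets(maps, maps)
        assert report.n_overlapping_pairs == 3

    def test_touching_ranges_overlap_inclusively(self):
        # ranges 1-5 and 5-9 share residue 5
        model = write_toy_structure("MKTAYIAKQ", "helix")
        a = self._mapped(model, ["MKTAY"])
        b = self._mapped(model, ["YIAKQ"])
        assert compare_peptide_sets(a, b).n_overlapping_pairs == 1

    def test_planted_two_of_three_overlaps(self):
        model = write_toy_structure("MKTAYIAKQRWSDEFGHCNPLV", "helix")
        set_a = self._mapped(model, ["MKTAY", "WSDEF", "NPLV"])
        set_b = self._mapped(model, ["TAYIA", "EFGHC"])  # overlaps 1st and 2nd of A
        report = compare_peptide_sets(set_a, set_b)
        assert report.n_overlapping_pairs == 2
        assert report.peptides_a_overlapping == ("MKTAY", "WSDEF")


def test_selection_string_lists_ranges():
    model = write_toy_structure("MKTAYIAKQ", "helix")
    maps = [map_peptide_to_structure("MKTAY", model, "A")]
    assert selection_string(maps) == "A/1-5"
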