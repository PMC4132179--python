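"""C-alpha geometry: PDB parsing, allele mapping and configuration distances."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chiscreen.matrix import AlleleAnnotation, Substitution, reverse_weights
from chiscreen.structure import (
    FilamentTopology,
    StructureError,
    StructureModel,
    UnresolvedAlleleError,
    distance_table,
    export_residue_attributes,
    map_allele_residues,
    min_ca_distance,
    pair_distance,
    read_pdb_calpha,
    write_calpha_pdb,
)
from chiscreen.synthetic import SyntheticConfig, generate_filament, subunit_center


def _ann(allele_id, positions):
    return AlleleAnnotation(
        allele_id,
        tuple(Substitution("D", p, "A") for p in positions),
        "other",
        "side",
    )


class TestPdbIO:
    def test_filament_round_trip(self, synthetic_default, tmp_path):
        """Writing the synthetic filament to PDB and re-reading preserves
        coordinates to the fixed-width precision of the format."""
        _, model, _, _, _, _ = synthetic_default
        path = tmp_path / "filament.pdb"
        write_calpha_pdb(model, path)
        back = read_pdb_calpha(path)
        assert back.subunit_ids == model.subunit_ids
        for chain in model.subunit_ids:
            for resnum, xyz in model.subunits[chain].items():
                assert np.allclose(back.subunits[chain][resnum], xyz, atol=1.5e-3)

    def test_chain_filter(self, synthetic_default, tmp_path):
        _, model, _, _, _, _ = synthetic_default
        path = tmp_path / "filament.pdb"
        write_calpha_pdb(model, path)
        only_a = read_pdb_calpha(path, chains={"A"})
        assert only_a.subunit_ids == ("A",)

    def test_small_handwritten_file(self, tmp_path):
        path = tmp_path / "three.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.000   4.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  ALA A   3       0.000   0.000   5.000  1.00  0.00           C\n"
            "END\n"
        )
        model = read_pdb_calpha(path)
        assert model.subunit_ids == ("A",)
        assert sorted(model.subunits["A"]) == [1, 2, 3]

    def test_no_ca_atoms_is_an_error(self, tmp_path):
        path = tmp_path / "cb.pdb"
        path.write_text(
            "ATOM      1  CB  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(StructureError):
            read_pdb_calpha(path)

    def test_insertion_codes_rejected(self, tmp_path):
        path = tmp_path / "icode.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1A      0.000   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(StructureError, match="insertion"):
            read_pdb_calpha(path)


class TestMinCaDistance:
    def test_three_four_five_triangle(self):
        assert min_ca_distance([[0, 0, 0]], [[3, 4, 0]]) == pytest.approx(5.0)

    def test_shared_point_gives_zero(self):
        a = [[1, 2, 3], [4, 5, 6]]
        assert min_ca_distance(a, [[4, 5, 6]]) == pytest.approx(0.0)

    def test_matches_exhaustive_search(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = rng.uniform(-30, 30, size=(5, 3))
            b = rng.uniform(-30, 30, size=(7, 3))
            oracle = min(
                math.dist(p, q) for p in a.tolist() for q in b.tolist()
            )
            assert min_ca_distance(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            min_ca_distance(np.empty((0, 3)), [[0, 0, 0]])


class TestAlleleMapping:
    @pytest.fixture
    def model(self):
        return StructureModel(
            subunits={
                "A": {1: np.zeros(3), 5: np.array([1.0, 0, 0]), 9: np.array([0, 2.0, 0])}
            }
        )

    def test_full_resolution(self, model):
        coords, unresolved = map_allele_residues(_ann("x", [1, 5]), model, "A")
        assert coords.shape == (2, 3) and unresolved == ()

    def test_partial_resolution_warns(self, model):
        with pytest.warns(UserWarning, match="unresolved"):
            coords, unresolved = map_allele_residues(_ann("x", [5, 99]), model, "A")
        assert coords.shape == (1, 3) and unresolved == (99,)

    def test_fully_unresolved_allele_flagged(self, model):
        with pytest.raises(UnresolvedAlleleError):
            map_allele_residues(_ann("x", [42]), model, "A")


class TestPairDistance:
    @pytest.fixture
    def filament(self):
        cfg = SyntheticConfig(seed=3, n_subunits=4, residues_per_subunit=60)
        return cfg, *generate_filament(cfg)

    def test_symmetry_and_self_distance(self, filament):
        _, model, topo = filament
        a1, a2 = _ann("p", [3, 7]), _ann("q", [20, 31])
        for config in ("monomer", "stacked", "backed"):
            assert pair_distance(a1, a2, config, model, topo) == pytest.approx(
                pair_distance(a2, a1, config, model, topo)
            )
        assert pair_distance(a1, a1, "monomer", model) == pytest.approx(0.0)

    def test_matches_exhaustive_orientation_search(self, filament):
        """Stacked/backed distances equal brute force over every declared
        subunit pair and both residue-set assignments."""
        _, model, topo = filament
        rng = np.random.default_rng(0)
        for _ in range(25):
            pos1 = sorted(rng.choice(60, size=3, replace=False) + 1)
            pos2 = sorted(rng.choice(60, size=2, replace=False) + 1)
            a1, a2 = _ann("p", pos1), _ann("q", pos2)
            for kind in ("stacked", "backed"):
                oracle = min(
                    math.dist(model.subunits[u][i], model.subunits[v][j])
                    for (u, v) in topo.pairs(kind)
                    for (pa, pb) in ((pos1, pos2), (pos2, pos1))
                    for i in pa
                    for j in pb
                )
                assert pair_distance(a1, a2, kind, model, topo) == pytest.approx(oracle)

    def test_minimisation_beats_any_fixed_orientation(self, filament):
        _, model, topo = filament
        a1, a2 = _ann("p", [3, 7]), _ann("q", [20, 31])
        best = pair_distance(a1, a2, "stacked", model, topo)
        u, v = topo.stacked_pairs[0]
        fixed = min_ca_distance(
            model.coords(u, a1.positions), model.coords(v, a2.positions)
        )
        assert best <= fixed + 1e-9

    def test_rigid_motion_invariance(self, filament):
        _, model, topo = filament
        rng = np.random.default_rng(1)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.uniform(-50, 50, size=3)
        moved = StructureModel(
            subunits={
                c: {r: q @ xyz + shift for r, xyz in residues.items()}
                for c, residues in model.subunits.items()
            }
        )
        a1, a2 = _ann("p", [3, 7, 11]), _ann("q", [20, 31])
        for config in ("monomer", "stacked", "backed"):
            assert pair_distance(a1, a2, config, model, topo) == pytest.approx(
                pair_distance(a1, a2, config, moved, topo), abs=1e-9
            )

    def test_missing_topology_kind_is_configuration_error(self, filament):
        _, model, _ = filament
        empty = FilamentTopology()
        with pytest.raises(StructureError):
            pair_distance(_ann("p", [3]), _ann("q", [5]), "stacked", model, empty)


class TestPolePatchGeometry:
    def test_stacked_contact_closer_than_monomer_for_opposite_poles(
        self, synthetic_default
    ):
        """Patches on opposite subunit poles are nearer across the stacked
        interface than within one subunit, while any intra-subunit patch
        pair stays within the subunit diameter."""
        cfg, model, topo, _, _, truth = synthetic_default
        diam = 2 * cfg.subunit_radius
        local_center = subunit_center(cfg, 0)
        chain = model.subunit_ids[0]
        crossing = 0
        for allele_a, pos_a in truth.allele_positions.items():
            for allele_b, pos_b in truth.allele_positions.items():
                if allele_a >= allele_b:
                    continue
                if truth.allele_cluster[allele_a] != truth.allele_cluster[allele_b]:
                    continue
                a1, a2 = _ann(allele_a, list(pos_a)), _ann(allele_b, list(pos_b))
                d_mono = pair_distance(a1, a2, "monomer", model)
                assert d_mono <= diam + 1e-6
                # opposite-pole pairs: monomer-far but stacked-near
                za = np.mean([model.subunits[chain][p][2] for p in pos_a])
                zb = np.mean([model.subunits[chain][p][2] for p in pos_b])
                if abs(za - zb) > cfg.subunit_radius:
                    d_stack = pair_distance(a1, a2, "stacked", model, topo)
                    assert d_stack < d_mono
                    crossing += 1
        assert crossing >= 5  # the planted motif actually occurs


class TestDistanceTable:
    def test_pair_count_and_similarity_consistency(self, synthetic_default):
        from chiscreen.cluster import uncentered_pearson

        cfg, model, topo, matrix, annotations, _ = synthetic_default
        weighted = reverse_weights(matrix)
        result = distance_table(annotations, weighted, model, topo)
        n = len(annotations) - len(result.excluded)
        assert len(result.table) == n * (n - 1) // 2
        sample = result.table.sample(10, random_state=0)
        for row in sample.itertuples():
            expected = uncentered_pearson(
                weighted.weights.loc[row.allele_a].to_numpy(dtype=float),
                weighted.weights.loc[row.allele_b].to_numpy(dtype=float),
            )
            assert row.similarity == pytest.approx(expected, abs=1e-12)

    def test_unresolved_alleles_excluded_and_listed(self, synthetic_default):
        cfg, model, topo, matrix, annotations, _ = synthetic_default
        ghost = _ann("ghost", [9999])
        weighted = reverse_weights(matrix)
        before = distance_table(annotations, weighted, model, topo)
        with_ghost = distance_table(annotations + [ghost], weighted, model, topo)
        assert "ghost" in with_ghost.excluded
        assert len(with_ghost.table) == len(before.table)

    def test_too_few_usable_alleles(self, synthetic_default):
        cfg, model, topo, matrix, annotations, _ = synthetic_default
        with pytest.raises(StructureError):
            distance_table(annotations[:2], reverse_weights(matrix), model, topo)


class TestResidueAttributes:
    def test_per_residue_lines(self, tmp_path):
        anns = [_ann("act1-105", [311, 312]), _ann("act1-135", [4])]
        path = tmp_path / "attrs.txt"
        export_residue_attributes({"act1-105": 113, "act1-135": 9}, anns, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("attribute:")
        assert "\t:311\t113" in lines and "\t:312\t113" in lines
        assert "\t:4\t9" in lines
        assert len(lines) == 1 + 3

    def test_empty_degrees_header_only(self, tmp_path):
        path = tmp_path / "attrs.txt"
        export_residue_attributes({}, [_ann("x", [5])], path)
        assert path.read_text().splitlines() == ["attribute: chi_interactions"]

    def test_line_count_equals_substitution_count(self, table1, tmp_path):
        annotations, degrees = table1
        path = tmp_path / "attrs.txt"
        export_residue_attributes(degrees.to_dict(), annotations, path)
        total = sum(len(a.substitutions) for a in annotations)
        assert len(path.read_text().splitlines()) == 1 + total

    def test_conflicting_residue_claim_rejected(self, tmp_path):
        anns = [_ann("x", [5]), _ann("y", [5])]
        with pytest.raises(ValueError, match="claimed"):
            export_residue_attributes({"x": 1, "y": 2}, anns, tmp_path / "a.txt")
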