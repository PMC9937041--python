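"""Structure parsing, ASA, exposure, mapping, clustering permutation test."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from ponevo.phylo_engine import Alignment
from ponevo.structure_cluster import (
    MAX_ASA,
    classify_exposed,
    clustering_permutation_test,
    compute_asa,
    map_alignment_to_structure,
    parse_structure,
)
from ponevo.synthetic_data.structures import StructureSpec, simulate_structure


def _atom_line(serial, name, resname, resnum, x, y, z, element="C", occ=1.0,
               altloc=" "):
    return (
        f"ATOM  {serial:>5} {name:^4}{altloc}{resname} A{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2}"
    )


class TestParseStructure:
    def test_simulated_pseudo_pdb_round_trips(self):
        pdb, _ = simulate_structure(StructureSpec(n_residues=100, seed=1))
        residues = parse_structure(pdb)
        assert len(residues) == 100
        assert all(r.ca is not None for r in residues)
        assert all(len(r.coords) == 1 for r in residues)

    def test_hetatm_only_input_is_an_error(self):
        text = (
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00"
            "           O\nEND\n"
        )
        with pytest.raises(ValueError, match="no ATOM records"):
            parse_structure(text)

    def test_altloc_resolves_to_highest_occupancy(self):
        text = "\n".join(
            [
                _atom_line(1, "CA", "ALA", 1, 0.0, 0.0, 0.0, occ=0.6, altloc="A"),
                _atom_line(2, "CA", "ALA", 1, 9.0, 9.0, 9.0, occ=0.4, altloc="B"),
                "END",
            ]
        )
        residues = parse_structure(text)
        assert len(residues) == 1
        assert np.allclose(residues[0].ca, [0.0, 0.0, 0.0])

    def test_missing_calpha_is_kept_but_marked(self):
        text = "\n".join(
            [
                _atom_line(1, "CB", "ALA", 1, 0.0, 0.0, 0.0),
                _atom_line(2, "CA", "GLY", 2, 5.0, 0.0, 0.0),
                "END",
            ]
        )
        residues = parse_structure(text)
        assert residues[0].ca is None and residues[1].ca is not None


class TestComputeAsa:
    def test_isolated_atom_matches_analytic_sphere(self):
        text = _atom_line(1, "CA", "ALA", 1, 0.0, 0.0, 0.0) + "\nEND\n"
        res = compute_asa(parse_structure(text))
        expected = 4 * math.pi * (1.70 + 1.4) ** 2
        assert res[0].asa == pytest.approx(expected, rel=0.01)

    def test_two_distant_atoms_each_keep_a_full_sphere(self):
        text = "\n".join(
            [
                _atom_line(1, "CA", "ALA", 1, 0.0, 0.0, 0.0),
                _atom_line(2, "CA", "ALA", 2, 50.0, 0.0, 0.0),
                "END",
            ]
        )
        res = compute_asa(parse_structure(text))
        expected = 4 * math.pi * (1.70 + 1.4) ** 2
        for r in res:
            assert r.asa == pytest.approx(expected, rel=0.01)

    def test_coincident_atoms_share_one_sphere(self):
        text = "\n".join(
            [
                _atom_line(1, "CA", "ALA", 1, 0.0, 0.0, 0.0),
                _atom_line(2, "CA", "ALA", 2, 0.0, 0.0, 0.0),
                "END",
            ]
        )
        res = compute_asa(parse_structure(text))
        total = res[0].asa + res[1].asa
        expected = 4 * math.pi * (1.70 + 1.4) ** 2
        assert total == pytest.approx(expected, rel=0.02)

    def test_rotation_and_translation_invariance(self):
        pdb, _ = simulate_structure(StructureSpec(n_residues=40, seed=2))
        res = compute_asa(parse_structure(pdb), n_points=5000)
        base = np.array([r.asa for r in res])
        # rigid-body motion applied to the raw coordinates
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        moved = parse_structure(pdb)
        for r in moved:
            r.coords = r.coords @ Q.T + np.array([11.0, -3.0, 7.0])
        compute_asa(moved, n_points=5000)
        rotated = np.array([r.asa for r in moved])
        assert np.abs(rotated - base).max() / base.max() < 0.005

    def test_too_few_points_rejected(self):
        pdb, _ = simulate_structure(StructureSpec(n_residues=5, seed=3))
        with pytest.raises(ValueError, match="n_points"):
            compute_asa(parse_structure(pdb), n_points=5)


class TestClassifyExposed:
    def test_isolated_residue_is_exposed(self):
        text = _atom_line(1, "CA", "ALA", 1, 0.0, 0.0, 0.0) + "\nEND\n"
        res = classify_exposed(compute_asa(parse_structure(text)))
        assert res[0].exposed is True

    def test_threshold_is_inclusive_and_matches_direct_ratio(self):
        pdb, _ = simulate_structure(StructureSpec(n_residues=60, seed=4))
        res = classify_exposed(compute_asa(parse_structure(pdb)), 0.2)
        for r in res:
            assert r.exposed == ((r.asa / MAX_ASA[r.resname]) >= 0.2)

    def test_dense_ball_buries_interior_residues(self):
        # a packed cube of C-alpha atoms: the central one must be buried
        lines, serial = [], 1
        for ix in range(3):
            for iy in range(3):
                for iz in range(3):
                    lines.append(
                        _atom_line(
                            serial, "CA", "ALA", serial,
                            4.0 * ix, 4.0 * iy, 4.0 * iz,
                        )
                    )
                    serial += 1
        res = classify_exposed(compute_asa(parse_structure("\n".join(lines))))
        center = [r for r in res if np.allclose(r.ca, [4.0, 4.0, 4.0])][0]
        corner = [r for r in res if np.allclose(r.ca, [0.0, 0.0, 0.0])][0]
        assert center.exposed is False
        assert corner.exposed is True


class TestMapAlignmentToStructure:
    def test_identity_map_for_ungapped_matching_query(self):
        msa = Alignment(["rabbit", "possum"], ["ARNDC", "ARNEC"])
        mapping = map_alignment_to_structure(msa, "rabbit", "ARNDC")
        assert mapping == {0: 1, 1: 2, 2: 3, 3: 4, 4: 5}

    def test_gap_column_maps_to_nothing_without_shifting_the_rest(self):
        msa = Alignment(["rabbit", "possum"], ["AR-DC", "ARNEC"])
        mapping = map_alignment_to_structure(msa, "rabbit", "ARDC")
        assert mapping == {0: 1, 1: 2, 3: 3, 4: 4}
        assert 2 not in mapping

    def test_planted_offsets_recovered_on_random_alignments(self):
        rng = np.random.default_rng(6)
        aas = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(20):
            n = int(rng.integers(10, 60))
            residues = "".join(rng.choice(list(aas), n))
            gap_cols = set(rng.choice(2 * n, size=n, replace=False))
            row, expected, ri = [], {}, 0
            for col in range(2 * n):
                if col in gap_cols and ri < n:
                    row.append(residues[ri])
                    expected[col] = ri + 1
                    ri += 1
                else:
                    row.append("-")
            msa = Alignment(["q"], ["".join(row)])
            got = map_alignment_to_structure(msa, "q", residues[:ri])
            assert got == expected

    def test_excessive_mismatch_rejected(self):
        msa = Alignment(["q"], ["AAAAAAAAAA"])
        with pytest.raises(ValueError, match="mismatch"):
            map_alignment_to_structure(msa, "q", "RRRRRRRRRR")

    def test_absent_query_rejected(self):
        msa = Alignment(["a"], ["AR"])
        with pytest.raises(ValueError, match="not in alignment"):
            map_alignment_to_structure(msa, "missing", "AR")


class TestClusteringPermutationTest:
    def test_selecting_the_whole_pool_gives_p_one(self):
        pdb, _ = simulate_structure(StructureSpec(n_residues=30, seed=7))
        res = parse_structure(pdb)
        selected = {r.resnum for r in res}
        out = clustering_permutation_test(
            selected, res, restrict_to_exposed=False, n_permutations=500, seed=1
        )
        assert out.p_value == 1.0

    def test_planted_cluster_is_detected(self):
        pdb, truth = simulate_structure(
            StructureSpec(n_residues=150, cluster=(8, 6.0), seed=8)
        )
        res = parse_structure(pdb)
        out = clustering_permutation_test(
            truth, res, restrict_to_exposed=False, n_permutations=10_000, seed=2
        )
        assert out.p_value <= 0.01

    def test_p_value_never_below_add_one_floor(self):
        pdb, truth = simulate_structure(
            StructureSpec(n_residues=80, cluster=(6, 5.0), seed=9)
        )
        res = parse_structure(pdb)
        out = clustering_permutation_test(
            truth, res, restrict_to_exposed=False, n_permutations=200, seed=3
        )
        assert out.p_value >= 1 / 201

    def test_null_draws_give_approximately_uniform_p(self):
        pdb, _ = simulate_structure(StructureSpec(n_residues=80, seed=10))
        res = parse_structure(pdb)
        pool = [r.resnum for r in res]
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(100):
            selected = set(rng.choice(pool, size=6, replace=False).tolist())
            out = clustering_permutation_test(
                selected, res, restrict_to_exposed=False,
                n_permutations=2_000, seed=int(rng.integers(2**31)),
            )
            pvals.append(out.p_value)
        stat, p = kstest(pvals, "uniform")
        assert p > 0.01

    def test_relabeling_and_rigid_motion_leave_p_unchanged(self):
        pdb, truth = simulate_structure(
            StructureSpec(n_residues=60, cluster=(5, 6.0), seed=12)
        )
        res = parse_structure(pdb)
        out1 = clustering_permutation_test(
            truth, res, restrict_to_exposed=False, n_permutations=2_000, seed=4
        )
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = parse_structure(pdb)
        for r in moved:
            r.coords = r.coords @ Q.T + 5.0
            r.ca = r.ca @ Q.T + 5.0
        out2 = clustering_permutation_test(
            truth, moved, restrict_to_exposed=False, n_permutations=2_000, seed=4
        )
        assert out1.p_value == out2.p_value
        assert out1.observed == pytest.approx(out2.observed, abs=1e-9)

    def test_tiny_selected_set_rejected(self):
        pdb, _ = simulate_structure(StructureSpec(n_residues=20, seed=13))
        res = parse_structure(pdb)
        with pytest.raises(ValueError, match=">= 2 selected"):
            clustering_permutation_test(
                {1}, res, restrict_to_exposed=False, n_permutations=100, seed=5
            )


class TestSimulatedStructures:
    def test_no_cluster_means_empty_truth_set(self):
        _, truth = simulate_structure(StructureSpec(n_residues=50, seed=14))
        assert truth == set()

    def test_same_seed_reproduces_coordinates_exactly(self):
        s1, _ = simulate_structure(StructureSpec(60, cluster=(5, 7.0), seed=15))
        s2, _ = simulate_structure(StructureSpec(60, cluster=(5, 7.0), seed=15))
        assert s1 == s2

    def test_infeasible_cluster_geometry_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            StructureSpec(n_residues=100, cluster=(50, 2.0), seed=0)

    def test_planted_cluster_is_tighter_than_random_sets(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            pdb, truth = simulate_structure(
                StructureSpec(n_residues=100, cluster=(10, 8.0), seed=seed)
            )
            res = parse_structure(pdb)
            coords = {r.resnum: r.ca for r in res}

            def mean_pairwise(nums):
                pts = np.array([coords[n] for n in nums])
                D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
                return D[np.triu_indices(len(nums), 1)].mean()

            rng = np.random.default_rng(1000 + seed)
            random_set = rng.choice(
                [r.resnum for r in res], size=10, replace=False
            )
            if mean_pairwise(sorted(truth)) < mean_pairwise(random_set):
                hits += 1
        assert hits >= 95
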