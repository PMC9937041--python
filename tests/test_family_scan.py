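"""Family-scan rules: parsing, filters, naming, loss, retro, duplication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ponevo.family_scan import (
    BlastHit,
    DomainHit,
    GeneLocus,
    assign_names,
    filter_blast_hits,
    filter_hits,
    flag_retroduplication,
    infer_loss,
    label_duplication_nodes,
    parse_domtblout,
)
from ponevo.phylo_engine.trees import PhyloTree
from ponevo.synthetic_data.loci import LocusTableSpec, PlantedArray, simulate_locus_table


def _locus(gene, scaffold, start, end, species="sp", exons=5):
    return GeneLocus(species, gene, scaffold, start, end, "+", exons)


class TestParseDomtblout:
    def test_comment_only_file_yields_nothing(self):
        assert parse_domtblout("# a comment\n#another\n") == []

    def test_two_domain_lines_aggregate_to_one_record(self):
        line = (
            "sp|g1 - 400 ary PF01731.21 330 {full} 55 0.1 {d} 2 {e} {e} "
            "50 0.1 5 320 10 380 5 390 0.95 -"
        )
        text = (
            line.format(full="1e-10", d=1, e="1e-8")
            + "\n"
            + line.format(full="1e-10", d=2, e="1e-3")
            + "\n"
        )
        hits = parse_domtblout(text)
        assert len(hits) == 1
        h = hits[0]
        assert h.species == "sp" and h.gene_id == "g1"
        assert h.full_seq_evalue == 1e-10
        assert h.best_domain_evalue == 1e-8
        assert h.n_domains == 2

    def test_malformed_line_reports_its_number(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_domtblout("# ok\nbad line with few columns\n")

    def test_simulator_roundtrip_preserves_planted_hit_count(self):
        rng = np.random.default_rng(0)
        for seed in range(30):
            n_arrays = int(rng.integers(1, 5))
            spec = LocusTableSpec(
                species=["s1", "s2"],
                arrays=[
                    PlantedArray(
                        species=["s1", "s2"][int(rng.integers(2))],
                        scaffold=f"sc{rng.integers(3)}",
                        n_genes=int(rng.integers(1, 5)),
                        gap_bp=int(rng.integers(0, 200_000)),
                    )
                    for _ in range(n_arrays)
                ],
                straddle_evalues=bool(seed % 2),
                seed=seed,
            )
            loci, text, truth = simulate_locus_table(spec)
            hits = parse_domtblout(text)
            assert len(hits) == truth["n_hit_genes"] == len(loci)


class TestFilterHits:
    def test_both_evalues_must_pass(self):
        h = DomainHit("sp", "g", 1e-7, 1e-5, 1)
        assert filter_hits([h]) == []

    def test_boundary_is_inclusive(self):
        h = DomainHit("sp", "g", 1e-6, 1e-6, 3)
        assert filter_hits([h]) == [h]

    def test_matches_brute_force_on_straddling_hits(self):
        rng = np.random.default_rng(1)
        hits = [
            DomainHit(
                "sp", f"g{i}",
                10.0 ** rng.uniform(-9, -3),
                10.0 ** rng.uniform(-9, -3),
                int(rng.integers(1, 4)),
            )
            for i in range(500)
        ]
        expected = [
            h for h in hits
            if h.full_seq_evalue <= 1e-6 and h.best_domain_evalue <= 1e-6
        ]
        assert filter_hits(hits) == expected

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(2)
        hits = [
            DomainHit("sp", f"g{i}", 10.0 ** rng.uniform(-8, -4),
                      10.0 ** rng.uniform(-8, -4), 1)
            for i in range(100)
        ]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        ids = [h.gene_id for h in once]
        assert ids == sorted(ids, key=lambda g: int(g[1:]))


class TestAssignNames:
    def test_fifty_kb_gap_makes_a_numbered_array(self):
        loci = [_locus("g1", "chr1", 1, 2_000), _locus("g2", "chr1", 52_000, 54_000)]
        assert assign_names(loci) == {"g1": "A1", "g2": "A2"}

    def test_different_scaffolds_get_different_letters(self):
        loci = [_locus("g1", "chr1", 1, 2_000), _locus("g2", "chr2", 1, 2_000)]
        assert assign_names(loci) == {"g1": "A", "g2": "B"}

    def test_gap_beyond_window_splits_arrays(self):
        loci = [_locus("g1", "chr1", 1, 2_000), _locus("g2", "chr1", 150_000, 152_000)]
        assert assign_names(loci) == {"g1": "A", "g2": "B"}

    def test_single_linkage_chains_beyond_the_window(self):
        # consecutive gaps of 90 kb; ends span > 180 kb but stay one array
        loci = [
            _locus("g1", "chr1", 1, 1_000),
            _locus("g2", "chr1", 91_001, 92_000),
            _locus("g3", "chr1", 182_001, 183_000),
        ]
        names = assign_names(loci)
        assert names == {"g1": "A1", "g2": "A2", "g3": "A3"}
        # brute-force connected components under the pairwise link predicate
        def gap(a, b):
            if a.scaffold != b.scaffold:
                return None
            lo, hi = sorted([a, b], key=lambda l: l.start)
            return max(0, hi.start - lo.end - 1)

        adj = {
            (a.gene_id, b.gene_id)
            for a in loci
            for b in loci
            if a is not b and gap(a, b) is not None and gap(a, b) <= 100_000
        }
        assert ("g1", "g2") in adj and ("g2", "g3") in adj
        assert ("g1", "g3") not in adj  # linked only transitively

    def test_overlapping_loci_count_as_gap_zero(self):
        loci = [_locus("g1", "chr1", 1, 5_000), _locus("g2", "chr1", 4_000, 9_000)]
        assert assign_names(loci) == {"g1": "A1", "g2": "A2"}

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        loci = []
        pos = 1
        for i in range(12):
            scaffold = f"chr{int(rng.integers(3))}"
            start = int(rng.integers(1, 5_000_000))
            loci.append(_locus(f"g{i}", scaffold, start, start + 1_000))
        base = assign_names(loci)
        for _ in range(5):
            rng.shuffle(loci)
            assert assign_names(loci) == base

    def test_duplicate_gene_id_rejected(self):
        loci = [_locus("g1", "chr1", 1, 10), _locus("g1", "chr1", 100, 200)]
        with pytest.raises(ValueError, match="duplicate"):
            assign_names(loci)


class TestInferLoss:
    def test_absent_in_all_group_members_claims_loss(self):
        presence = pd.DataFrame(
            {"fam": [False, False, False]}, index=["s1", "s2", "s3"]
        )
        groups = {"s1": "G", "s2": "G", "s3": "G"}
        assert infer_loss(presence, groups) == [("G", "fam")]

    def test_one_present_species_blocks_the_claim(self):
        presence = pd.DataFrame(
            {"fam": [False, True, False]}, index=["s1", "s2", "s3"]
        )
        groups = {"s1": "G", "s2": "G", "s3": "G"}
        assert infer_loss(presence, groups) == []

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            species = [f"s{i}" for i in range(50)]
            fams = [f"f{j}" for j in range(6)]
            presence = pd.DataFrame(
                rng.random((50, 6)) < 0.15, index=species, columns=fams
            )
            groups = {sp: f"G{int(rng.integers(8))}" for sp in species}
            expected = sorted(
                (g, fam)
                for g in set(groups.values())
                for fam in fams
                if not any(
                    presence.loc[sp, fam] for sp in species if groups[sp] == g
                )
            )
            assert infer_loss(presence, groups) == expected

    def test_unmapped_species_rejected(self):
        presence = pd.DataFrame({"fam": [True]}, index=["s1"])
        with pytest.raises(ValueError, match="without a group"):
            infer_loss(presence, {})


class TestFlagRetroduplication:
    def test_single_exon_gene_among_intron_rich_siblings_is_flagged(self):
        loci = [
            _locus("g1", "c", 1, 10, exons=9),
            _locus("g2", "c", 20, 30, exons=9),
            _locus("g3", "c", 40, 50, exons=9),
            _locus("g4", "c", 60, 70, exons=1),
        ]
        assert flag_retroduplication(loci) == ["g4"]

    def test_all_single_exon_clade_flags_nothing(self):
        loci = [_locus(f"g{i}", "c", i * 100, i * 100 + 10, exons=1) for i in range(4)]
        assert flag_retroduplication(loci) == []

    def test_all_multi_exon_clade_flags_nothing(self):
        loci = [_locus(f"g{i}", "c", i * 100, i * 100 + 10, exons=7) for i in range(4)]
        assert flag_retroduplication(loci) == []


class TestFilterBlastHits:
    def test_coverage_below_threshold_rejected(self):
        h = BlastHit("q", "s", 49.0, 95.0)
        assert filter_blast_hits([h]) == []

    def test_inclusive_boundary_retained(self):
        h = BlastHit("q", "s", 50.0, 90.0)
        assert filter_blast_hits([h]) == [h]

    def test_longest_isoform_wins(self):
        short = BlastHit("q", "iso1", 80.0, 95.0, subject_length=300,
                         subject_locus="locusX")
        long = BlastHit("q", "iso2", 80.0, 95.0, subject_length=355,
                        subject_locus="locusX")
        assert filter_blast_hits([short, long]) == [long]

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=100),
                st.floats(min_value=0, max_value=100),
            ),
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_thresholding(self, rows):
        hits = [
            BlastHit("q", f"s{i}", pid, qcov) for i, (pid, qcov) in enumerate(rows)
        ]
        expected = [
            h for h in hits if h.query_coverage >= 90 and h.percent_identity >= 50
        ]
        assert filter_blast_hits(hits) == expected


class TestLabelDuplicationNodes:
    def test_mixed_tree_labels_root_duplication_children_speciation(self):
        tree = PhyloTree.from_newick("((spA_1:1,spB_1:1):1,(spA_2:1,spB_2:1):1);")
        species = {n: n.split("_")[0] for n in tree.leaf_names}
        labels = label_duplication_nodes(tree, species)
        resolved = tree.resolved_binary()
        assert labels[resolved.root] == "duplication"
        internal = [i for i in labels if i != resolved.root]
        assert all(labels[i] == "speciation" for i in internal)

    def test_one_gene_per_species_has_no_duplications(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        labels = label_duplication_nodes(tree, {n: n for n in "abcd"})
        assert set(labels.values()) == {"speciation"}

    def test_two_same_species_leaves_mark_a_duplication(self):
        tree = PhyloTree.from_newick("(spA_x:1,spA_y:1);")
        labels = label_duplication_nodes(tree, {"spA_x": "spA", "spA_y": "spA"})
        assert list(labels.values()) == ["duplication"]

    def test_multifurcation_is_resolved_deterministically(self):
        tree = PhyloTree.from_newick("(spA_1:1,spA_2:1,spB_1:1);")
        species = {n: n.split("_")[0] for n in tree.leaf_names}
        l1 = label_duplication_nodes(tree, species)
        l2 = label_duplication_nodes(tree, species)
        assert l1 == l2
        assert "duplication" in l1.values()


class TestPlantedTruthRecovery:
    def test_arrays_absences_and_retro_flags_recovered_exactly(self):
        rng = np.random.default_rng(8)
        for seed in range(25):
            species = ["s1", "s2", "s3", "s4"]
            arrays, absent = [], {}
            for ai in range(int(rng.integers(1, 4))):
                sp = species[int(rng.integers(3))]  # s4 stays family-free
                n_genes = int(rng.integers(1, 5))
                retro = (
                    tuple(int(x) for x in rng.choice(n_genes, 1))
                    if n_genes >= 2 and rng.random() < 0.4
                    else ()
                )
                arrays.append(
                    PlantedArray(
                        species=sp,
                        scaffold=f"sc{int(rng.integers(2))}",
                        n_genes=n_genes,
                        gap_bp=int(rng.integers(0, 90_000)),
                        retro_indices=retro,
                    )
                )
            absent["fam1"] = {"s4"}
            spec = LocusTableSpec(
                species=species, arrays=arrays, absences=absent, seed=seed
            )
            loci, text, truth = simulate_locus_table(spec)
            hits = parse_domtblout(text)
            kept = filter_hits(hits)
            assert len(kept) == len(loci)  # no straddling: all pass
            assert not any(h.species == "s4" for h in kept)
            # planted array sizes match recovered name groups per species
            truth_genes = pd.DataFrame(truth["genes"])
            for sp, block in loci.groupby("species"):
                sp_loci = [GeneLocus(**r) for r in block.to_dict("records")]
                names = assign_names(sp_loci)
                by_array = truth_genes[truth_genes.species == sp].groupby(
                    "array_index"
                )["gene_id"]
                recovered = {}
                for gid, name in names.items():
                    letter = name.rstrip("0123456789")
                    recovered.setdefault(letter, set()).add(gid)
                planted_sets = {frozenset(v) for _, v in by_array}
                assert {frozenset(v) for v in recovered.values()} == planted_sets
            # retro flags recovered within each planted multi-gene array
            for ai, arr in enumerate(arrays):
                members = truth_genes[truth_genes.array_index == ai]
                if len(members) < 2:
                    continue
                sub = [
                    GeneLocus(**r)
                    for r in loci[loci.gene_id.isin(members.gene_id)].to_dict(
                        "records"
                    )
                ]
                expected = sorted(members[members.retro].gene_id)
                assert sorted(flag_retroduplication(sub)) == expected
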