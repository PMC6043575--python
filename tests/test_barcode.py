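"""K2P distances, barcode-gap summaries, neighbor joining and assignment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from garcinia_auth.barcode import (DistanceMatrix, SequenceRecord,
                                   assign_query, count_parsimony_informative,
                                   distance_matrix, distance_summaries,
                                   evaluate_markers, k2p_distance, nj_tree,
                                   read_fasta, write_fasta, write_newick)
from garcinia_auth.errors import (AlignmentError, FastaParseError,
                                  InsufficientDataError, TreeError)


def rec(rid, seq, species=None, marker="its"):
    return SequenceRecord(rid, seq, species, marker)


class TestFasta:
    def test_read_parses_header_dialect(self, tmp_path):
        path = tmp_path / "lib.fasta"
        path.write_text(">s1|Garcinia indica|its\nACGT\n"
                        ">s2|Garcinia gummi-gutta|its\nACGA\n")
        records = read_fasta(path)
        assert len(records) == 2
        assert records[0].species == "Garcinia indica"
        assert records[1].marker == "its"

    def test_round_trip(self, tmp_path):
        records = [rec("a", "ACGT-RN", "sp1"), rec("b", "acgtacg", None)]
        path = tmp_path / "out.fasta"
        write_fasta(records, path)
        assert read_fasta(path) == [rec("a", "ACGT-RN", "sp1"),
                                    rec("b", "ACGTACG", None)]

    def test_query_header_without_species(self, tmp_path):
        path = tmp_path / "q.fasta"
        path.write_text(">query1\nACGT\n")
        (q,) = read_fasta(path)
        assert q.species is None and q.marker is None

    def test_errors_name_offender(self, tmp_path):
        dup = tmp_path / "dup.fasta"
        dup.write_text(">a|x\nACGT\n>a|y\nACGT\n")
        with pytest.raises(FastaParseError, match="'a'"):
            read_fasta(dup)
        bad = tmp_path / "bad.fasta"
        bad.write_text(">z\nACGQ\n")
        with pytest.raises(FastaParseError, match="'z'"):
            read_fasta(bad)
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(FastaParseError):
            read_fasta(empty)


class TestK2P:
    def test_identical_sequences(self):
        d = k2p_distance("ACGTACGT", "ACGTACGT")
        assert (d.p, d.q, d.d) == (0.0, 0.0, 0.0)

    def test_worked_example_one_ts_one_tv(self):
        # 10 comparable sites, 1 transition (A->G), 1 transversion (A->C)
        a = "AAAAAAAAAA"
        b = "GCAAAAAAAA"
        d = k2p_distance(a, b)
        assert (d.p, d.q) == (0.1, 0.1)
        assert d.d == pytest.approx(0.23412, abs=5e-6)

    def test_saturation_flagged(self):
        # P = 0.5, Q = 0 -> 1 - 2P - Q = 0 -> undefined
        a = "AAGGAAGGAAGG"
        b = "GAGGGAGGGAGG"  # hand-tuned: 6 transitions in 12 sites
        d = k2p_distance("AAAAAAAAAAAA", "GGGGGGAAAAAA")
        assert d.p == 0.5 and d.q == 0.0
        assert d.d is None and "saturation" in d.undefined_reason

    def test_pairwise_deletion_of_gaps_and_ambiguities(self):
        d = k2p_distance("AC-GTN", "ACTGTA")
        assert d.sites_compared == 4  # gap and N columns dropped

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            k2p_distance("ACGT", "ACG")

    def test_no_comparable_sites_undefined(self):
        d = k2p_distance("NN--", "AC-G")
        assert d.sites_compared == 0 and d.d is None

    def test_matches_bruteforce_formula_on_pq_grid(self):
        """Count-based distances equal direct formula evaluation to 1e-12."""
        length = 200
        for n_ts, n_tv in itertools.product(range(0, 30, 3), range(0, 30, 3)):
            a = "A" * length
            # transitions A->G, transversions A->T, disjoint site blocks
            b = ("G" * n_ts) + ("T" * n_tv) + "A" * (length - n_ts - n_tv)
            got = k2p_distance(a, b)
            p, q = n_ts / length, n_tv / length
            expected = (-0.5 * math.log(1 - 2 * p - q)
                        - 0.25 * math.log(1 - 2 * q))
            assert got.d == pytest.approx(expected, abs=1e-12)

    def test_reduces_to_jukes_cantor_at_equal_rates(self):
        """With transitions:transversions at 1:2 (kappa=1), K2P equals JC."""
        length = 300
        for n_sub in range(3, 60, 9):
            n_ts = n_sub // 3
            n_tv = 2 * (n_sub // 3)
            a = "A" * length
            b = ("G" * n_ts) + ("T" * n_tv) + "A" * (length - n_ts - n_tv)
            d = k2p_distance(a, b)
            total = (n_ts + n_tv) / length
            jc = -0.75 * math.log(1 - 4 * total / 3)
            assert d.d == pytest.approx(jc, abs=1e-12)

    def test_monotone_in_p_and_q(self):
        def dist(p, q, n=1000):
            a = "A" * n
            b = ("G" * int(p * n)) + ("T" * int(q * n)) \
                + "A" * (n - int(p * n) - int(q * n))
            return k2p_distance(a, b).d
        assert dist(0.10, 0.05) < dist(0.15, 0.05) < dist(0.20, 0.05)
        assert dist(0.10, 0.05) < dist(0.10, 0.10) < dist(0.10, 0.15)


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        records = [rec(f"s{i}", "ACGTACGTAA") for i in range(3)]
        m = distance_matrix(records)
        assert np.all(m.values == 0.0)

    def test_symmetry_and_elementwise_agreement(self, rng):
        bases = np.array(list("ACGT"))
        records = [rec(f"s{i}", "".join(bases[rng.integers(0, 4, 60)]))
                   for i in range(6)]
        m = distance_matrix(records)
        np.testing.assert_array_equal(m.values, m.values.T)
        for i, j in itertools.combinations(range(6), 2):
            direct = k2p_distance(records[i], records[j])
            cell = m.values[i, j]
            if direct.d is None:
                assert np.isnan(cell)
            else:
                assert cell == pytest.approx(direct.d, abs=1e-15)

    def test_undefined_cells_do_not_abort(self):
        records = [rec("a", "AAAAAAAAAA"), rec("b", "GGGGGGAAAA"),
                   rec("c", "AAAAAAAAAC")]
        m = distance_matrix(records)  # a~b saturated
        assert np.isnan(m.values[0, 1]) and not np.isnan(m.values[0, 2])
        assert not m.complete

    def test_mixed_markers_rejected(self):
        with pytest.raises(AlignmentError):
            distance_matrix([rec("a", "ACGT", marker="its"),
                             rec("b", "ACGT", marker="rbcL")])


class TestDistanceSummaries:
    def test_two_species_two_identical_individuals(self):
        # intra pairs identical (d=0); inter distance > 0
        records = [rec("a1", "A" * 100, "sp1"), rec("a2", "A" * 100, "sp1"),
                   rec("b1", "A" * 88 + "G" * 6 + "T" * 6, "sp2"),
                   rec("b2", "A" * 88 + "G" * 6 + "T" * 6, "sp2")]
        m = distance_matrix(records)
        s = distance_summaries(m, marker="toy")
        assert (s.intra_mean, s.intra_sd) == (0.0, 0.0)
        assert s.inter_sd == 0.0 and s.inter_mean > 0
        assert s.suitable

    def test_inverted_gap_flagged_unsuitable(self):
        """A marker with inter mean below intra mean has no barcode gap."""
        # two species; within-species variation larger than between
        far = "G" * 10 + "T" * 10 + "A" * 180
        records = [rec("a1", "A" * 200, "sp1"), rec("a2", far, "sp1"),
                   rec("b1", "A" * 199 + "G", "sp2"),
                   rec("b2", far[:-1] + "C", "sp2")]
        m = distance_matrix(records)
        s = distance_summaries(m, marker="rbcL-like")
        assert s.inter_mean < s.intra_mean
        assert not s.suitable and "no_barcode_gap" in s.flags

    def test_agrees_with_bruteforce_enumeration(self, rng):
        bases = np.array(list("ACGT"))
        species = ["sp1"] * 3 + ["sp2"] * 3 + ["sp3"] * 4
        root = bases[rng.integers(0, 4, 150)]
        records = []
        for i, sp in enumerate(species):
            seq = root.copy()
            idx = rng.choice(150, size=rng.integers(1, 12), replace=False)
            seq[idx] = bases[rng.integers(0, 4, idx.size)]
            records.append(rec(f"s{i}", "".join(seq), sp))
        m = distance_matrix(records)
        s = distance_summaries(m)
        intra, inter = [], []
        for a, b in itertools.combinations(records, 2):
            d = k2p_distance(a, b).d
            if d is None:
                continue
            (intra if a.species == b.species else inter).append(d)
        assert s.intra_mean == pytest.approx(np.mean(intra), abs=1e-12)
        assert s.intra_sd == pytest.approx(np.std(intra), abs=1e-12)
        assert s.inter_mean == pytest.approx(np.mean(inter), abs=1e-12)
        assert (s.n_intra_pairs, s.n_inter_pairs) == (len(intra), len(inter))


class TestParsimonyInformative:
    def test_identical_alignment_has_none(self):
        assert count_parsimony_informative(
            [rec(f"s{i}", "ACGTACGT") for i in range(4)]) == 0

    def test_definition_by_enumeration(self):
        # columns: {A,A,T,T} informative; {A,A,A,T} not; {A,T,G,C} not
        seqs = ["AAA", "AAT", "TAG", "TTC"]
        records = [rec(f"s{i}", s) for i, s in enumerate(seqs)]
        assert count_parsimony_informative(records) == 1

    def test_gap_only_column_ignored(self):
        base = ["AAT", "AAT", "TAA", "TTA"]
        with_gap = [s + "-" for s in base]
        a = count_parsimony_informative([rec(f"s{i}", s)
                                         for i, s in enumerate(base)])
        b = count_parsimony_informative([rec(f"s{i}", s)
                                         for i, s in enumerate(with_gap)])
        assert a == b

    def test_too_few_sequences(self):
        with pytest.raises(InsufficientDataError):
            count_parsimony_informative([rec("a", "ACGT")] )


def additive_frame():
    """Distances generated by the tree ((A:1,B:2):1,(C:3,D:4))."""
    d = {("A", "B"): 3.0, ("A", "C"): 5.0, ("A", "D"): 6.0,
         ("B", "C"): 6.0, ("B", "D"): 7.0, ("C", "D"): 7.0}
    labels = list("ABCD")
    m = np.zeros((4, 4))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                m[i, j] = m[j, i] = d[(a, b)]
    return pd.DataFrame(m, index=labels, columns=labels)


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        tree = nj_tree(additive_frame())
        # exact path-length matrix recovery
        pl = tree.path_length_matrix()
        np.testing.assert_allclose(pl.values, additive_frame().values,
                                   atol=1e-9)
        # topology: A+B form a cherry (their path avoids C/D side)
        (attach_a,) = tree.neighbors("A")
        assert "B" in tree.leaves_beyond(attach_a, "A") or \
            tree.path_length("A", "B") == pytest.approx(3.0, abs=1e-9)

    def test_three_taxa_closed_form(self):
        labels = list("ABC")
        d = pd.DataFrame([[0, 2, 3], [2, 0, 4], [3, 4, 0]],
                         index=labels, columns=labels, dtype=float)
        tree = nj_tree(d)
        # star branch lengths: lA = (dAB + dAC - dBC)/2 etc.
        (center,) = tree.neighbors("A").keys()
        assert tree.neighbors("A")[center] == pytest.approx(0.5)
        assert tree.neighbors("B")[center] == pytest.approx(1.5)
        assert tree.neighbors("C")[center] == pytest.approx(2.5)

    def test_all_zero_matrix(self):
        labels = list("ABCD")
        tree = nj_tree(pd.DataFrame(np.zeros((4, 4)), index=labels,
                                    columns=labels))
        assert all(length == 0.0
                   for nbrs in tree.adjacency.values()
                   for length in nbrs.values())

    def test_undefined_cells_rejected_with_pairs(self):
        records = [rec("a", "AAAAAAAAAA"), rec("b", "GGGGGGAAAA"),
                   rec("c", "AAAAAAAAAC"), rec("d", "AAAAAAAAGC")]
        m = distance_matrix(records)
        with pytest.raises(TreeError, match="a~b"):
            nj_tree(m)

    def test_matches_scikit_bio_on_random_matrix(self, rng):
        """Cross-check path lengths against an independent NJ implementation."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        n = 7
        coords = rng.uniform(0, 1, size=(n, 4))
        m = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(m, 0.0)
        labels = [f"t{i}" for i in range(n)]
        ours = nj_tree(pd.DataFrame(m, index=labels, columns=labels))
        theirs = skbio_nj(SkbioDM(m, ids=labels))
        for a, b in itertools.combinations(labels, 2):
            expected = theirs.find(a).distance(theirs.find(b))
            assert ours.path_length(a, b) == pytest.approx(expected, abs=1e-6)

    def test_additive_matrices_from_random_trees(self, rng):
        """NJ reproduces the generating tree's path lengths on additive input."""
        import dendropy
        for _ in range(5):
            taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(6)])
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
                num_extant_tips=6, rng=__import__("random").Random(
                    int(rng.integers(2 ** 31))))
            for edge in tree.preorder_edge_iter():
                if edge.length is None:
                    edge.length = 0.0
            pdm = tree.phylogenetic_distance_matrix()
            labels = [t.label for t in taxa]
            m = np.array([[pdm.distance(taxa.get_taxon(a), taxa.get_taxon(b))
                           for b in labels] for a in labels])
            ours = nj_tree(pd.DataFrame(m, index=labels, columns=labels))
            for i, j in itertools.combinations(range(len(labels)), 2):
                assert ours.path_length(labels[i], labels[j]) == pytest.approx(
                    m[i, j], abs=1e-9)


class TestNewick:
    def test_round_trip_parseable(self, tmp_path):
        import dendropy
        tree = nj_tree(additive_frame())
        path = tmp_path / "tree.nwk"
        text = write_newick(tree, path)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == \
            ["A", "B", "C", "D"]
        pdm = parsed.phylogenetic_distance_matrix()
        tns = parsed.taxon_namespace
        assert pdm.distance(tns.get_taxon("A"),
                            tns.get_taxon("B")) == pytest.approx(3.0, abs=1e-9)

    def test_leaf_permutation_gives_isomorphic_tree(self):
        import dendropy
        frame = additive_frame()
        perm = frame.loc[list("DCBA"), list("DCBA")]
        t1 = dendropy.Tree.get(data=nj_tree(frame).to_newick(),
                               schema="newick",
                               taxon_namespace=dendropy.TaxonNamespace())
        tns = t1.taxon_namespace
        t2 = dendropy.Tree.get(data=nj_tree(perm).to_newick(),
                               schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_empty_tree_rejected(self):
        from garcinia_auth.barcode import PhyloTree
        with pytest.raises(TreeError):
            PhyloTree(adjacency={}, leaves=[]).to_newick()


class TestAssignQuery:
    @staticmethod
    def toy_library():
        # two species, 100 bp, clearly separated
        sp1 = "A" * 100
        sp2 = "A" * 80 + "G" * 10 + "T" * 10
        return [
            rec("r1", sp1, "sp1"), rec("r2", sp1[:-1] + "G", "sp1"),
            rec("r3", sp2, "sp2"), rec("r4", sp2[:-1] + "C", "sp2"),
        ]

    def test_identical_to_reference_assigned(self):
        res = assign_query(rec("q", "A" * 100), self.toy_library())
        assert res.assigned_species == "sp1"
        assert res.nearest_distance == 0.0
        assert res.clade_support

    def test_equidistant_tie_is_ambiguous(self):
        refs = [rec("r1", "A" * 100, "sp1"),
                rec("r2", "A" * 96 + "TTTT", "sp2")]
        # two transversions from each reference -> exactly equal distances
        q = rec("q", "A" * 98 + "TT")
        res = assign_query(q, refs)
        assert res.assigned_species == "ambiguous"

    def test_distant_query_is_no_match(self):
        res = assign_query(rec("q", "G" * 50 + "C" * 50),
                           self.toy_library(), distance_ceiling=0.2)
        assert res.assigned_species == "no-match"

    def test_assignment_implies_both_criteria(self):
        res = assign_query(rec("q", "A" * 99 + "G"), self.toy_library())
        assert res.assigned and res.clade_support


class TestEvaluateMarkers:
    def test_single_marker_single_row(self):
        table = evaluate_markers(
            {"its": TestAssignQuery.toy_library()})
        assert len(table) == 1
        assert bool(table.loc[0, "suitable"])

    def test_engineered_unsuitable_marker_flagged(self):
        good = TestAssignQuery.toy_library()
        far = "G" * 10 + "T" * 10 + "A" * 180
        bad = [rec("a1", "A" * 200, "sp1"), rec("a2", far, "sp1"),
               rec("b1", "A" * 199 + "G", "sp2"),
               rec("b2", far[:-1] + "C", "sp2")]
        table = evaluate_markers({"its": good, "rbcL": bad}).set_index("marker")
        assert bool(table.loc["its", "suitable"])
        assert not bool(table.loc["rbcL", "suitable"])
        # ranked by interspecific mean, descending
        assert table["inter_mean"].is_monotonic_decreasing

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            evaluate_markers({})
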