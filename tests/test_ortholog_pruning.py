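"""Homolog-tree pruning: outlier filter, same-taxon masking, long-branch
cutting and maximum-inclusion ortholog extraction."""

import random

import numpy as np
import pandas as pd
import pytest

from conftest import graft_paralogs, mi_oracle, random_homolog_newick
from phylodisc import msc_sim
from phylodisc.core_io import read_newick
from phylodisc.ortholog_pruning import (cut_long_internal_branches,
                                        extract_mi_orthologs,
                                        filter_orthogroups,
                                        mask_same_taxon_tips,
                                        prune_homolog_tree,
                                        remove_outlier_tips, trim_columns)
from phylodisc.core_io import Alignment
from phylodisc.splits import taxon_index, unrooted_split_set


def _og_table(rows):
    return pd.DataFrame(rows, columns=["orthogroup", "taxon", "sequence",
                                       "chars"])


class TestFilterOrthogroups:
    def test_missing_taxon_excluded(self):
        table = _og_table([
            ("OG1", "A", "s1", 10), ("OG1", "B", "s2", 10),
            ("OG1", "C", "s3", 10),
            ("OG2", "A", "s4", 10), ("OG2", "B", "s5", 10),
            ("OG3", "A", "s6", 10), ("OG3", "B", "s7", 10),
            ("OG3", "C", "s8", 10),
        ])
        assert filter_orthogroups(table, {"A", "B", "C"}) == ["OG1", "OG3"]

    def test_full_occupancy_keeps_all_in_order(self):
        table = _og_table([("OG2", "A", "s1", 1), ("OG2", "B", "s2", 1),
                           ("OG1", "A", "s3", 1), ("OG1", "B", "s4", 1)])
        assert filter_orthogroups(table, {"A", "B"}) == ["OG2", "OG1"]

    def test_empty_table(self):
        assert filter_orthogroups(_og_table([]), {"A"}) == []


class TestOutlierTips:
    def test_equal_tips_untouched(self):
        t = read_newick("((a:0.1,b:0.1):0.1,(c:0.1,(d:0.1,e:0.1):0.1):0.1);")
        out, removed = remove_outlier_tips(t, factor=10)
        assert removed == [] and out.n_tips == 5

    def test_single_outlier_removed(self):
        t = read_newick("((a:0.1,b:5.0):0.1,(c:0.1,(d:0.1,e:0.1):0.1):0.1);")
        out, removed = remove_outlier_tips(t, factor=10)
        assert removed == ["b"] and out.n_tips == 4

    def test_two_outliers_removed_iteratively(self):
        t = read_newick(
            "((a:0.1,b:5.0):0.1,((c:0.1,f:0.1):0.1,(d:3.0,e:0.1):0.1):0.1);")
        out, removed = remove_outlier_tips(t, factor=10)
        assert set(removed) == {"b", "d"}
        assert removed[0] == "b"  # worst first

    def test_never_below_four_tips(self):
        t = read_newick("((a:0.1,b:9.0):0.1,(c:0.1,d:9.0):0.1);")
        out, removed = remove_outlier_tips(t, factor=10)
        assert out.n_tips == 4 and removed == []

    def test_missing_lengths_rejected(self):
        t = read_newick("((a,b),(c,(d,e)));")
        with pytest.raises(ValueError):
            remove_outlier_tips(t)


class TestMasking:
    def test_monophyletic_pair_keeps_best_covered(self):
        t = read_newick("((a1:0.1,a2:0.1):0.2,b:0.3);", homolog_ok=True)
        out, masked = mask_same_taxon_tips(
            t, {"a1": 500, "a2": 300, "b": 100},
            taxon_of={"a1": "A", "a2": "A", "b": "B"})
        assert masked == ["a2"]
        assert sorted(out.tip_labels) == ["a1", "b"]

    def test_ladder_keeps_single_best(self):
        t = read_newick("(a1:0.1,(a2:0.1,(a3:0.1,b:0.1):0.1):0.1);",
                        homolog_ok=True)
        out, masked = mask_same_taxon_tips(
            t, {"a1": 100, "a2": 200, "a3": 900, "b": 50},
            taxon_of={"a1": "A", "a2": "A", "a3": "A", "b": "B"})
        assert sorted(out.tip_labels) == ["a3", "b"]
        assert set(masked) == {"a1", "a2"}

    def test_separated_tips_untouched(self):
        t = read_newick("(a1:0.1,(b:0.1,(a2:0.1,c:0.1):0.1):0.1);",
                        homolog_ok=True)
        out, masked = mask_same_taxon_tips(
            t, {"a1": 1, "b": 1, "a2": 1, "c": 1},
            taxon_of={"a1": "A", "a2": "A", "b": "B", "c": "C"})
        assert masked == [] and out.n_tips == 4

    def test_missing_char_count_rejected(self):
        t = read_newick("((a1:0.1,a2:0.1):0.2,b:0.3);", homolog_ok=True)
        with pytest.raises(ValueError, match="character count"):
            mask_same_taxon_tips(t, {"a1": 10},
                                 taxon_of={"a1": "A", "a2": "A", "b": "B"})

    def test_last_tip_of_taxon_survives(self):
        """Masking only ever removes a tip when a same-taxon tip is
        retained."""
        rng = random.Random(77)
        for _ in range(50):
            nwk, taxon_of, counts = random_homolog_newick(
                rng, ["A", "B", "C"], rng.randrange(4, 10))
            t = read_newick(nwk, homolog_ok=True)
            before = {taxon_of[l] for l in t.tip_labels}
            out, _ = mask_same_taxon_tips(t, counts, taxon_of=taxon_of)
            after = {taxon_of[l] for l in out.tip_labels}
            assert before == after


class TestLongBranchCutting:
    def test_no_long_branch_is_identity(self):
        t = read_newick("((a:0.1,b:0.1):0.2,(c:0.1,d:0.1):0.2);")
        pieces = cut_long_internal_branches(t, cutoff=0.6)
        assert len(pieces) == 1 and pieces[0].n_tips == 4

    def test_single_cut_partitions_bipartition(self):
        t = read_newick("((a:0.1,b:0.1):0.9,(c:0.1,d:0.1):0.2);")
        pieces = cut_long_internal_branches(t, cutoff=0.6)
        assert sorted(sorted(p.tip_labels) for p in pieces) == [
            ["a", "b"], ["c", "d"]]

    def test_chain_of_two_long_branches(self):
        t = read_newick(
            "((a:0.1,b:0.1):0.9,((c:0.1,d:0.1):0.9,(e:0.1,f:0.1):0.1):0.1);")
        pieces = cut_long_internal_branches(t, cutoff=0.6)
        assert sorted(sorted(p.tip_labels) for p in pieces) == [
            ["a", "b"], ["c", "d"], ["e", "f"]]


class TestMaximumInclusion:
    def test_duplication_free_tree_passes_through(self):
        net = msc_sim.make_scenario("ils_only")
        gt = msc_sim.simulate_gene_trees(net, 1, 17).trees[0]
        t = read_newick(gt.newick(), homolog_ok=True, units="subs/site")
        orthos = extract_mi_orthologs(t, cutoff=1e9)
        assert len(orthos) == 1 and orthos[0].n_tips == 11

    def test_deep_duplicate_takes_larger_side(self):
        t = read_newick("((A1:0.1,B:0.1):0.1,(A2:0.1,C:0.1):0.1);",
                        homolog_ok=True)
        orthos = extract_mi_orthologs(
            t, cutoff=1e9, min_taxa=3,
            taxon_of={"A1": "A", "A2": "A", "B": "B", "C": "C"})
        assert len(orthos) == 1
        assert len(orthos[0].tip_labels) == 3

    def test_oracle_equivalence_random_homologs(self):
        """Greedy MI equals exhaustive edge-cut search on 200 random
        homolog trees of <= 8 tips."""
        rng = random.Random(99)
        for _ in range(200):
            nwk, taxon_of, counts = random_homolog_newick(
                rng, ["A", "B", "C", "D"], rng.randrange(4, 9))
            t = read_newick(nwk, homolog_ok=True, units="subs/site")
            got = [frozenset(o.tip_labels)
                   for o in extract_mi_orthologs(
                       t, cutoff=0.6, min_taxa=3, char_counts=counts,
                       taxon_of=taxon_of)]
            exp = mi_oracle(t, 0.6, 3, taxon_of, counts)
            assert sorted(got, key=sorted) == sorted(exp, key=sorted)

    def test_outputs_are_one_to_one(self):
        rng = random.Random(13)
        for _ in range(30):
            nwk, taxon_of, counts = random_homolog_newick(
                rng, ["A", "B", "C"], rng.randrange(4, 12))
            t = read_newick(nwk, homolog_ok=True)
            for o in extract_mi_orthologs(t, cutoff=0.6, min_taxa=2,
                                          char_counts=counts,
                                          taxon_of=taxon_of):
                taxa = [taxon_of[l] for l in o.tip_labels]
                assert len(set(taxa)) == len(taxa)


class TestFullPipeline:
    def test_recovers_generating_topology(self):
        """Grafted per-taxon duplicates are pruned away: the extracted
        ortholog matches the generating gene tree in >= 95% of loci."""
        net = msc_sim.make_scenario("ils_only")
        gts = msc_sim.simulate_gene_trees(net, 60, 301)
        rng = random.Random(301)
        idx = taxon_index(sorted(net.tree.tip_labels))
        hits = total = 0
        for gt in gts:
            nwk, taxon_of, counts = graft_paralogs(gt, rng)
            ht = read_newick(nwk, homolog_ok=True, units="subs/site")
            orthos, report = prune_homolog_tree(
                ht, counts, taxon_of=taxon_of, outlier_factor=None,
                cutoff=1e9, min_taxa=11)
            total += 1
            if len(orthos) == 1:
                relabelled = {l: taxon_of[l] for l in orthos[0].tip_labels}
                o = orthos[0].copy()
                for lf in o.dtree.leaf_node_iter():
                    lf.taxon.label = relabelled[lf.taxon.label]
                if unrooted_split_set(o, idx) == unrooted_split_set(gt, idx):
                    hits += 1
        assert hits / total >= 0.95


class TestTrimColumns:
    def test_low_occupancy_dropped(self):
        seqs = [("t%d" % i, "A-" if i else "AA") for i in range(10)]
        aln = Alignment.from_sequences(seqs)
        out = trim_columns(aln, 0.2)
        assert out.n_sites == 1

    def test_exact_threshold_kept(self):
        rows = [("t%d" % i, "AA" if i < 2 else "A-") for i in range(10)]
        aln = Alignment.from_sequences(rows)
        out = trim_columns(aln, 0.2)  # occupancy exactly 0.2
        assert out.n_sites == 2

    def test_ungapped_unchanged(self):
        aln = Alignment.from_sequences([("a", "ACGT"), ("b", "ACGT")])
        assert trim_columns(aln, 0.2).n_sites == 4

    def test_all_columns_removed_warns(self):
        aln = Alignment.from_sequences(
            [("t%d" % i, "--") for i in range(9)] + [("t9", "AA")])
        with pytest.warns(UserWarning):
            out = trim_columns(aln, 0.5)
        assert out.n_sites == 0
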