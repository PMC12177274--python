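"""Tree/alignment plumbing and the cleaning operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylotraits import synthgen, treekit
from phylotraits.treekit import Alignment, CleaningParams

from conftest import random_homolog_newick, unrooted_splits


class TestNewickIO:
    def test_two_tip_parse(self):
        tree = treekit.parse_newick("(A:0.1,B:0.2);")
        labels = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert labels == {"A": 0.1, "B": 0.2}

    def test_roundtrip_random_50_tip_tree(self, rng):
        text = random_homolog_newick(rng, n_tips=50)
        tree = treekit.parse_newick(text)
        back = treekit.parse_newick(treekit.write_newick(tree))
        assert unrooted_splits(back) == unrooted_splits(tree)
        lengths = sorted(l.edge.length for l in tree.leaf_node_iter())
        lengths_back = sorted(l.edge.length for l in back.leaf_node_iter())
        assert np.allclose(lengths, lengths_back, atol=1e-9)

    def test_malformed_input_reports_position(self):
        with pytest.raises(Exception) as exc:
            treekit.parse_newick("(A:0.1,")
        assert "column" in str(exc.value) or "line" in str(exc.value)


class TestAlignmentOps:
    def test_clean_columns_examples(self):
        aln = Alignment({f"s{i}": row for i, row in enumerate([
            "A-AA", "C-C-", "G-G-", "T-T-", "A-A-",
            "C-C-", "G-G-", "T-T-", "A-A-", "C-C-",
        ])})
        cleaned, report = treekit.clean_columns(aln, 0.1)
        # col 1 all gaps -> dropped; col 3 has exactly 1/10 occupancy -> kept
        assert cleaned.n_columns == 3
        assert cleaned.rows["s0"] == "AAA"
        assert not report["empty"]

    def test_clean_columns_ungapped_unchanged_and_idempotent(self):
        aln = Alignment({"x": "ACGTACGT", "y": "TGCATGCA"})
        cleaned, _ = treekit.clean_columns(aln, 0.1)
        assert cleaned.rows == aln.rows
        twice, _ = treekit.clean_columns(cleaned, 0.1)
        assert twice.rows == cleaned.rows

    def test_clean_columns_all_removed_flagged(self):
        aln = Alignment({"x": "---", "y": "NNN"})
        cleaned, report = treekit.clean_columns(aln, 0.1)
        assert cleaned is None and report["empty"]

    @given(st.integers(min_value=1, max_value=30), st.integers(min_value=2, max_value=6))
    @settings(max_examples=25, deadline=None)
    def test_clean_columns_idempotence_property(self, n_cols, n_rows):
        rng = np.random.default_rng(n_cols * 31 + n_rows)
        chars = np.array(list("ACGT-N"))
        rows = {
            f"r{i}": "".join(rng.choice(chars, size=n_cols)) for i in range(n_rows)
        }
        cleaned, _ = treekit.clean_columns(Alignment(rows), 0.3)
        if cleaned is not None:
            twice, _ = treekit.clean_columns(cleaned, 0.3)
            assert twice.rows == cleaned.rows

    @pytest.mark.parametrize(
        "row,expected", [("----", 0), ("ACGT--", 4), ("ANNN", 1)]
    )
    def test_informative_chars(self, row, expected):
        aln = Alignment({"x": row, "y": "A" * len(row)})
        assert treekit.informative_chars(aln, "x") == expected

    def test_informative_chars_unknown_id(self):
        with pytest.raises(KeyError):
            treekit.informative_chars(Alignment({"x": "ACGT"}), "nope")


class TestJCDistance:
    def test_identical_and_frozen_value(self):
        # 10% mismatches over 100 sites -> d = -0.75 ln(1 - 0.4/3)
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        dist = treekit.jc_distance(Alignment({"a": a, "b": b, "c": a}))
        assert dist.loc["a", "c"] == 0.0
        assert dist.loc["a", "b"] == pytest.approx(0.1073256, abs=1e-6)
        assert np.allclose(dist.to_numpy(), dist.to_numpy().T)
        assert np.diag(dist.to_numpy()).sum() == 0.0

    def test_saturation_ceiling_and_disjoint_rows(self):
        sat = treekit.jc_distance(Alignment({"a": "A" * 100, "b": "C" * 100}))
        assert sat.loc["a", "b"] == treekit.JC_CEILING
        with pytest.raises(ValueError):
            treekit.jc_distance(Alignment({"a": "AC--", "b": "--GT"}))


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        """Distances additive on ((A,B),(C,D)) with internal branch 0.3:
        NJ must return that topology (four-point condition holds)."""
        import pandas as pd

        # pendant: A=.1 B=.2 C=.15 D=.25, internal .3
        d = {
            ("A", "B"): 0.3, ("A", "C"): 0.55, ("A", "D"): 0.65,
            ("B", "C"): 0.65, ("B", "D"): 0.75, ("C", "D"): 0.4,
        }
        labels = ["A", "B", "C", "D"]
        mat = pd.DataFrame(0.0, index=labels, columns=labels)
        for (x, y), v in d.items():
            mat.loc[x, y] = mat.loc[y, x] = v
        # four-point oracle: AB|CD iff d(AB)+d(CD) < min of the other sums
        assert d[("A", "B")] + d[("C", "D")] < d[("A", "C")] + d[("B", "D")]
        tree = treekit.neighbor_joining(mat)
        assert unrooted_splits(tree) == {frozenset({"A", "B"})} or unrooted_splits(
            tree
        ) == {frozenset({"C", "D"})}
        # path lengths reproduced exactly on additive input
        pdm = tree.phylogenetic_distance_matrix()
        tns = tree.taxon_namespace
        for (x, y), v in d.items():
            assert pdm.distance(tns.get_taxon(x), tns.get_taxon(y)) == pytest.approx(v)

    def test_three_taxon_closed_form(self):
        import pandas as pd

        mat = pd.DataFrame(
            [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = treekit.neighbor_joining(mat)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.2)
        assert lengths["C"] == pytest.approx(0.4)

    def test_matches_scikit_bio_on_random_matrices(self, rng):
        """Independent oracle: scikit-bio's NJ yields the same unrooted
        topology on random tree-derived (additive + jittered) matrices."""
        import pandas as pd
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        for rep in range(10):
            text = random_homolog_newick(rng, n_tips=8)
            tree = treekit.parse_newick(text)
            pdm = tree.phylogenetic_distance_matrix()
            taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
            labels = [t.label for t in taxa]
            mat = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
            mine = treekit.neighbor_joining(pd.DataFrame(mat, index=labels, columns=labels))
            theirs_nwk = skbio_nj(DistanceMatrix(mat, ids=labels)).__str__()
            theirs = treekit.parse_newick(theirs_nwk)
            assert unrooted_splits(mine) == unrooted_splits(theirs)

    def test_order_invariance(self, rng):
        import pandas as pd

        text = random_homolog_newick(rng, n_tips=7)
        tree = treekit.parse_newick(text)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa]
        mat = pd.DataFrame(
            [[pdm.distance(a, b) for b in taxa] for a in taxa],
            index=labels, columns=labels,
        )
        perm = list(np.random.default_rng(1).permutation(labels))
        t1 = treekit.neighbor_joining(mat)
        t2 = treekit.neighbor_joining(mat.loc[perm, perm])
        assert unrooted_splits(t1) == unrooted_splits(t2)

    def test_nan_rejected(self):
        import pandas as pd

        mat = pd.DataFrame(np.full((3, 3), np.nan), index=list("ABC"), columns=list("ABC"))
        with pytest.raises(ValueError):
            treekit.neighbor_joining(mat)


class TestTrimLongTips:
    def test_absolute_rule(self):
        tree = treekit.parse_newick("(A@1:0.5,(B@1:0.01,C@1:0.01):0.01);")
        out, report = treekit.trim_long_tips(tree)
        assert report.removed == [("A@1", "absolute")]
        assert sorted(treekit.tip_labels(out)) == ["B@1", "C@1"]

    def test_neither_rule_fires(self):
        tree = treekit.parse_newick("((A@1:0.35,B@1:0.30):0.1,(C@1:0.1,D@1:0.1):0.1);")
        out, report = treekit.trim_long_tips(tree)
        assert report.removed == []
        assert len(treekit.tip_labels(out)) == 4

    def test_unary_collapse_sums_lengths(self):
        # removing A@1 (0.45 > 0.4) leaves B@1's pendant as 0.05 + 0.02
        tree = treekit.parse_newick("((A@1:0.45,B@1:0.05):0.02,(C@1:0.1,D@1:0.1):0.1);")
        out, report = treekit.trim_long_tips(tree)
        assert ("A@1", "absolute") in report.removed
        pend = {l.taxon.label: l.edge.length for l in out.leaf_node_iter()}
        assert pend["B@1"] == pytest.approx(0.07)

    def test_relative_rule_needs_both_conditions(self):
        params = CleaningParams(abs_cutoff=5.0)  # disable absolute rule
        fires = treekit.parse_newick("((A@1:0.7,B@1:0.05):0.1,(C@1:0.1,D@1:0.1):0.1);")
        out, report = treekit.trim_long_tips(fires, params)
        assert ("A@1", "relative") in report.removed
        # long but sister is comparably long: kept
        quiet = treekit.parse_newick("((A@1:0.7,B@1:0.5):0.1,(C@1:0.1,D@1:0.1):0.1);")
        _, report2 = treekit.trim_long_tips(quiet, params)
        assert report2.removed == []

    def test_all_tips_removed_degenerate(self):
        tree = treekit.parse_newick("(A@1:0.9,B@1:0.8);")
        out, report = treekit.trim_long_tips(tree)
        assert report.degenerate
        assert out is None

    def test_path_lengths_preserved_between_survivors(self, rng):
        """Collapse conserves pairwise path lengths among surviving tips."""
        for _ in range(5):
            text = random_homolog_newick(rng, n_tips=10, max_len=0.5)
            tree = treekit.parse_newick(text)
            before = tree.phylogenetic_distance_matrix()
            out, report = treekit.trim_long_tips(tree)
            if out is None or not report.removed:
                continue
            after = out.phylogenetic_distance_matrix()
            survivors = treekit.tip_labels(out)
            for i, x in enumerate(survivors):
                for y in survivors[i + 1:]:
                    tx_b = tree.taxon_namespace.get_taxon(x)
                    ty_b = tree.taxon_namespace.get_taxon(y)
                    tx_a = out.taxon_namespace.get_taxon(x)
                    ty_a = out.taxon_namespace.get_taxon(y)
                    assert after.distance(tx_a, ty_a) == pytest.approx(
                        before.distance(tx_b, ty_b), abs=1e-9
                    )

    def test_contaminant_removal_rate(self):
        """>= 95% of injected long-branch contaminants are trimmed."""
        sp = synthgen.default_species_tree()
        cfg = synthgen.GeneFamilyConfig(
            n_families=120, dup_rate=0.05, loss_rate=0.0,
            contaminant_prob=0.15, contaminant_length=1.5, seed=42,
        )
        injected = removed = 0
        for fam in synthgen.simulate_gene_families(sp, cfg):
            if fam.tree is None or not fam.contaminant_tips:
                continue
            out, report = treekit.trim_long_tips(fam.tree)
            gone = {tip for tip, _ in report.removed}
            injected += len(fam.contaminant_tips)
            removed += len(set(fam.contaminant_tips) & gone)
        assert injected > 50
        assert removed / injected >= 0.95


class TestMaskMonophyleticDuplicates:
    def _aln(self, counts):
        # informative count encoded as that many A's padded with gaps
        width = max(counts.values())
        return Alignment({k: "A" * v + "-" * (width - v) for k, v in counts.items()})

    def test_sister_pair_keeps_most_informative(self):
        tree = treekit.parse_newick("((A@1:0.1,A@2:0.1):0.1,B@1:0.1);")
        aln = self._aln({"A@1": 100, "A@2": 80, "B@1": 50})
        out = treekit.mask_monophyletic_duplicates(tree, aln)
        assert sorted(treekit.tip_labels(out)) == ["A@1", "B@1"]

    def test_non_sister_duplicates_kept(self):
        tree = treekit.parse_newick("((A@1:0.1,B@1:0.1):0.1,(A@2:0.1,C@1:0.1):0.1);")
        aln = self._aln({"A@1": 10, "B@1": 10, "A@2": 10, "C@1": 10})
        out = treekit.mask_monophyletic_duplicates(tree, aln)
        assert sorted(treekit.tip_labels(out)) == ["A@1", "A@2", "B@1", "C@1"]

    def test_nested_clade_iterates_to_fixed_point(self):
        tree = treekit.parse_newick(
            "((A@1:0.1,(A@2:0.1,A@3:0.1):0.1):0.1,B@1:0.1);"
        )
        aln = self._aln({"A@1": 50, "A@2": 90, "A@3": 70, "B@1": 10})
        out = treekit.mask_monophyletic_duplicates(tree, aln)
        assert sorted(treekit.tip_labels(out)) == ["A@2", "B@1"]

    def test_missing_alignment_row_rejected(self):
        tree = treekit.parse_newick("(A@1:0.1,B@1:0.1);")
        with pytest.raises(KeyError):
            treekit.mask_monophyletic_duplicates(tree, Alignment({"A@1": "ACGT"}))


class TestCutDeepParalogs:
    def test_central_deep_edge_splits_two_four_taxon_trees(self):
        tree = treekit.parse_newick(
            "(((A@1:.1,B@1:.1):.1,(C@1:.1,D@1:.1):.1):1.2,"
            "((E@1:.1,F@1:.1):.1,(G@1:.1,H@1:.1):.1):0.1);"
        )
        frags, report = treekit.cut_deep_paralogs(tree)
        assert report.n_cut_edges == 1
        assert sorted(sorted(treekit.taxon_of(l) for l in treekit.tip_labels(f)) for f in frags) == [
            ["A", "B", "C", "D"], ["E", "F", "G", "H"],
        ]

    def test_small_fragment_discarded(self):
        tree = treekit.parse_newick(
            "((A@1:.1,(B@1:.1,C@1:.1):.1):1.2,"
            "((E@1:.1,F@1:.1):.1,(G@1:.1,H@1:.1):.1):0.1);"
        )
        frags, report = treekit.cut_deep_paralogs(tree)
        assert len(frags) == 1
        assert sorted(treekit.taxon_of(l) for l in treekit.tip_labels(frags[0])) == [
            "E", "F", "G", "H",
        ]
        assert report.discarded == [["A@1", "B@1", "C@1"]]

    def test_no_deep_edge_passthrough(self):
        text = "((A@1:.1,B@1:.1):.2,(C@1:.1,D@1:.1):.2);"
        frags, report = treekit.cut_deep_paralogs(treekit.parse_newick(text))
        assert len(frags) == 1 and report.n_cut_edges == 0
        assert sorted(treekit.tip_labels(frags[0])) == ["A@1", "B@1", "C@1", "D@1"]

    def test_output_tips_subset_of_input(self, rng):
        for _ in range(5):
            tree = treekit.parse_newick(random_homolog_newick(rng, n_tips=14, max_len=1.4))
            before = set(treekit.tip_labels(tree))
            frags, report = treekit.cut_deep_paralogs(tree)
            after = set()
            for f in frags:
                after |= set(treekit.tip_labels(f))
            for d in report.discarded:
                after |= set(d)
            assert after == before
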