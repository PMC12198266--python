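"""Distance computation, neighbor joining, rooting and monophyly."""

import io
import itertools
import math

import numpy as np
import pytest
from Bio import Phylo

from aaokit import phylo, synthetic
from aaokit.alignment import Msa
from conftest import random_rooted_tree


def tree_bipartition_lengths(tree) -> dict[frozenset, float]:
    """Unrooted edge map: frozenset(smaller leaf side) -> branch length.

    The two edges of a rooted tree's root describe the same unrooted edge;
    their lengths are summed.
    """
    leaves = frozenset(l.taxon.label for l in tree.seed_node.leaf_iter())
    out: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = min(below, leaves - below, key=lambda s: (len(s), sorted(s)))
        out[side] = out.get(side, 0.0) + (node.edge.length or 0.0)
    return out


class TestPDistance:
    def test_identical_rows_are_zero(self):
        msa = Msa(["a", "b", "c"], ["ACDE"] * 3)
        assert np.allclose(phylo.p_distance_matrix(msa).values, 0.0)

    def test_worked_value_with_poisson_correction(self):
        row_a = "A" * 100
        row_b = "C" * 5 + "A" * 95
        msa = Msa(["a", "b", "c"], [row_a, row_b, row_a])
        plain = phylo.p_distance_matrix(msa, "none")
        assert plain.values[0, 1] == pytest.approx(0.05)
        corrected = phylo.p_distance_matrix(msa, "poisson")
        assert corrected.values[0, 1] == pytest.approx(-math.log(0.95), abs=1e-6)

    def test_gapped_columns_excluded_from_denominator(self):
        msa = Msa(["a", "b", "c"], ["AC-E", "ACD-", "ACDE"])
        D = phylo.p_distance_matrix(msa)
        assert D.values[0, 1] == 0.0  # only 'AC' shared

    def test_disjoint_gap_patterns_rejected(self):
        msa = Msa(["a", "b", "c"], ["A--", "-C-", "AC-"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            phylo.p_distance_matrix(msa)

    def test_saturated_pair_rejects_poisson(self):
        msa = Msa(["a", "b", "c"], ["AAAA", "CCCC", "AACC"])
        with pytest.raises(ValueError, match="Poisson"):
            phylo.p_distance_matrix(msa, "poisson")


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))

    def test_tsv_output(self, tmp_path):
        D = phylo.DistanceMatrix(["a", "b"], np.array([[0.0, 2.5], [2.5, 0.0]]))
        D.write_tsv(tmp_path / "d.tsv")
        lines = (tmp_path / "d.tsv").read_text().splitlines()
        assert lines[0] == "\ta\tb" and lines[1] == "a\t0\t2.5"


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        D = synthetic.generate_additive_matrix("((A:1,B:2):1,(C:3,D:4):0);")
        tree = phylo.neighbor_joining(D)
        lengths = tree_bipartition_lengths(tree)
        assert lengths[frozenset({"A"})] == pytest.approx(1.0, abs=1e-9)
        assert lengths[frozenset({"B"})] == pytest.approx(2.0, abs=1e-9)
        assert lengths[frozenset({"C"})] == pytest.approx(3.0, abs=1e-9)
        assert lengths[frozenset({"D"})] == pytest.approx(4.0, abs=1e-9)
        assert lengths[frozenset({"A", "B"})] == pytest.approx(1.0, abs=1e-9)

    def test_three_taxon_closed_form(self):
        D = phylo.DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
        )
        tree = phylo.neighbor_joining(D)
        lengths = tree_bipartition_lengths(tree)
        assert lengths[frozenset({"a"})] == pytest.approx(1.0)
        assert lengths[frozenset({"b"})] == pytest.approx(2.0)
        assert lengths[frozenset({"c"})] == pytest.approx(3.0)

    def test_tie_break_is_deterministic(self):
        values = np.full((4, 4), 1.0)
        np.fill_diagonal(values, 0.0)
        D = phylo.DistanceMatrix(list("abcd"), values)
        first = phylo.to_newick(phylo.neighbor_joining(D))
        assert first == phylo.to_newick(phylo.neighbor_joining(D))
        # lowest (row, column) pair joins first: a with b
        assert frozenset({"a", "b"}) in tree_bipartition_lengths(
            phylo.neighbor_joining(D)
        )

    def test_exact_recovery_on_random_additive_matrices(self):
        """Topology and branch lengths recovered to 1e-9 on >= 50 random
        trees of 4-12 taxa."""
        rng = np.random.default_rng(17)
        for trial in range(55):
            newick = random_rooted_tree(rng, int(rng.integers(4, 13)))
            source = synthetic.generate_additive_matrix(newick)
            recovered = phylo.neighbor_joining(source)
            expected = tree_bipartition_lengths(phylo.from_newick(newick))
            got = tree_bipartition_lengths(recovered)
            assert set(got) == set(expected), f"topology differs on trial {trial}"
            for side, length in expected.items():
                assert got[side] == pytest.approx(length, abs=1e-9)

    def test_topology_matches_scikit_bio_on_noisy_matrices(self):
        """Independent-implementation cross-check on non-additive input."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            M = rng.uniform(0.1, 1.0, size=(n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            labels = [f"t{i}" for i in range(n)]
            mine = set(tree_bipartition_lengths(
                phylo.neighbor_joining(phylo.DistanceMatrix(labels, M))
            ))
            ref = sk_nj(SkDM(M, labels))
            leaves = frozenset(labels)
            theirs = set()
            for node in ref.traverse(include_self=False):
                below = frozenset(t.name for t in node.tips()) or frozenset([node.name])
                theirs.add(min(below, leaves - below,
                               key=lambda s: (len(s), sorted(s))))
            assert mine == theirs

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(
                phylo.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
            )


def test_newick_round_trip_lossless():
    rng = np.random.default_rng(23)
    for _ in range(10):
        newick = random_rooted_tree(rng, int(rng.integers(4, 10)))
        tree = phylo.from_newick(newick)
        again = phylo.from_newick(phylo.to_newick(tree))
        assert tree_bipartition_lengths(tree) == tree_bipartition_lengths(again)


class TestOutgroupRooting:
    def _quartet(self):
        return phylo.neighbor_joining(
            synthetic.generate_additive_matrix("((A:1,B:2):1,(C:3,D:4):0);")
        )

    def test_single_leaf_outgroup_splits_pendant_edge(self):
        rooted = phylo.root_with_outgroup(self._quartet(), ["D"])
        assert rooted.is_rooted
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        assert sorted(c.edge.length for c in children) == pytest.approx([2.0, 2.0])

    def test_outgroup_pair_roots_on_internal_edge(self):
        rooted = phylo.root_with_outgroup(self._quartet(), ["C", "D"])
        sides = [
            frozenset(l.taxon.label for l in c.leaf_iter())
            for c in rooted.seed_node.child_nodes()
        ]
        assert frozenset({"C", "D"}) in sides and frozenset({"A", "B"}) in sides

    def test_non_separable_outgroup_rejected(self):
        with pytest.raises(ValueError, match="not monophyletic"):
            phylo.root_with_outgroup(self._quartet(), ["A", "C"])

    def test_unknown_outgroup_rejected(self):
        with pytest.raises(ValueError):
            phylo.root_with_outgroup(self._quartet(), ["Z"])


class TestMonophyly:
    def test_clean_split(self):
        tree = phylo.from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        tree.is_rooted = True
        report = phylo.monophyly_report(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert all(r.is_monophyletic and r.clade_purity == 1.0 for r in report.values())

    def test_interleaved_labels(self):
        tree = phylo.from_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        tree.is_rooted = True
        report = phylo.monophyly_report(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        for r in report.values():
            assert not r.is_monophyletic
            assert r.clade_purity == pytest.approx(0.5)
            assert r.clade_size == 4

    def test_singleton_label_is_monophyletic_by_convention(self):
        tree = phylo.from_newick("((a1:1,a2:1):1,c:1);")
        tree.is_rooted = True
        report = phylo.monophyly_report(tree, {"a1": "A", "a2": "A", "c": "C"})
        assert report["C"].is_monophyletic and report["C"].clade_size == 1

    def test_unlabeled_leaf_rejected(self):
        tree = phylo.from_newick("((a1:1,a2:1):1,c:1);")
        tree.is_rooted = True
        with pytest.raises(ValueError, match="unlabeled"):
            phylo.monophyly_report(tree, {"a1": "A", "a2": "A"})

    def test_against_brute_force_mrca_oracle(self):
        """Random labelled 4-6 leaf trees versus an independent Bio.Phylo
        smallest-containing-clade search."""
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(4, 7))
            newick = random_rooted_tree(rng, n)
            labels = {f"T{i}": str(rng.choice(["A", "B"])) for i in range(n)}
            tree = phylo.from_newick(newick)
            tree.is_rooted = True
            report = phylo.monophyly_report(tree, labels)

            ref = Phylo.read(io.StringIO(newick), "newick")
            all_clades = [ref.root] + list(ref.root.find_clades())
            for lab in set(labels.values()):
                members = {l for l, v in labels.items() if v == lab}
                best = None
                for clade in all_clades:
                    leafset = {t.name for t in clade.get_terminals()}
                    if members <= leafset and (best is None or len(leafset) < len(best)):
                        best = leafset
                assert report[lab].clade_size == len(best)
                assert report[lab].is_monophyletic == (best == members)
                assert report[lab].clade_purity == pytest.approx(len(members) / len(best))


def test_bootstrap_support_saturates_on_clean_signal():
    rows = ["AAAAAAAAAA" + "CCCCCCCCCC", "AAAAAAAAAA" + "CCCCCCCCCG",
            "TTTTTTTTTT" + "CCCCCCCCCC", "TTTTTTTTTT" + "GCCCCCCCCC"]
    msa = Msa(["a1", "a2", "b1", "b2"], rows)
    tree = phylo.neighbor_joining(phylo.p_distance_matrix(msa))
    support = phylo.bootstrap_support(msa, tree, n_replicates=50, seed=4)
    assert support and all(v > 0.9 for v in support.values())


def test_end_to_end_synthetic_types_form_clades(study_bundle):
    """Families generated per type cluster into monophyletic type clades."""
    config, records, truths = study_bundle
    non_decoys = [r for r, t in zip(records, truths) if not t.is_decoy]
    truth_by_id = {t.seq_id: t for t in truths}
    rng = np.random.default_rng(1)
    subset = [r for r in non_decoys if int(r.id.rsplit("_", 1)[1]) < 4]
    from aaokit.alignment import progressive_msa

    msa = progressive_msa(subset + synthetic.generate_outgroup(config))
    D = phylo.p_distance_matrix(msa)
    tree = phylo.neighbor_joining(D)
    rooted = phylo.root_with_outgroup(tree, ["outgroup_1", "outgroup_2"])
    labels = {
        r.id: f"{truth_by_id[r.id].kingdom}:{truth_by_id[r.id].true_type}"
        for r in subset
    }
    labels["outgroup_1"] = labels["outgroup_2"] = "outgroup"
    report = phylo.monophyly_report(rooted, labels)
    for lab, res in report.items():
        assert res.is_monophyletic, f"{lab} not monophyletic"
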