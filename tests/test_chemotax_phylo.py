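"""Matrix scaling, clustering, PCA, VIP, neighbor joining, concordance."""

import io

import numpy as np
import pandas as pd
import pytest

from halolip.chemotax_phylo import (
    LINKAGES,
    bootstrap_support,
    concordance,
    hcluster,
    nj_tree,
    p_distance,
    pca,
    plsda_vip,
    prepare_matrix,
    read_alignment,
    robinson_foulds,
    tree_bipartitions,
)


@pytest.fixture
def abundances():
    rng = np.random.default_rng(3)
    return pd.DataFrame(
        rng.uniform(1.0, 1e5, size=(12, 5)),
        index=[f"L{i}" for i in range(12)],
        columns=list("abcde"),
    )


class TestPrepareMatrix:
    def test_cluster_mode_columns_standardized(self, abundances):
        out = prepare_matrix(abundances, "cluster")
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(out.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_ordination_columns_sum_to_one_before_log(self, abundances):
        out = prepare_matrix(abundances, "ordination")
        assert np.allclose((10.0**out).sum(axis=0), 1.0, atol=1e-12)

    def test_ordination_invariant_to_sample_scaling(self, abundances):
        ref = prepare_matrix(abundances, "ordination")
        scaled = abundances.copy()
        scaled["c"] = scaled["c"] * 2.0
        out = prepare_matrix(scaled, "ordination")
        assert np.allclose(out["c"], ref["c"])

    def test_zeros_replaced_by_half_minimum(self):
        x = pd.DataFrame({"a": [0.0, 10.0], "b": [4.0, 2.0]})
        out = prepare_matrix(x, "ordination")
        assert np.isfinite(out.values).all()

    def test_all_zero_column_rejected(self):
        x = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="all-zero"):
            prepare_matrix(x, "cluster")

    def test_constant_column_falls_back_with_warning(self):
        x = pd.DataFrame({"a": [5.0, 5.0], "b": [1.0, 9.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = prepare_matrix(x, "cluster")
        assert np.isfinite(out.values).all()


class TestHcluster:
    def test_identical_columns_merge_at_zero(self):
        x = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 0.0]})
        d = hcluster(x, "complete")
        assert d.linkage_matrix[0, 2] == pytest.approx(0.0)

    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_three_points_on_a_line(self, linkage):
        x = pd.DataFrame({"A": [0.0], "B": [1.0], "C": [10.0]})
        d = hcluster(x, linkage)
        cut = d.cut(2)
        assert cut["A"] == cut["B"] != cut["C"]

    def test_newick_contains_all_labels(self):
        x = pd.DataFrame(np.eye(4), columns=list("wxyz"))
        nwk = hcluster(x, "average").to_newick()
        for label in "wxyz":
            assert label in nwk
        assert nwk.endswith(";")

    def test_nan_rejected(self):
        x = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            hcluster(x, "complete")


class TestPca:
    def test_duplicate_rows_full_variance_on_pc1(self):
        base = np.linspace(0, 1, 6)
        x = pd.DataFrame([base, 2 * base, -base],
                         columns=list("abcdef"))
        _, _, explained = pca(x, 1)
        assert explained[0] == pytest.approx(1.0)

    def test_two_group_separation_in_pc1_sign(self):
        x = pd.DataFrame(
            {"a": [10.0, 0.0], "b": [11.0, 0.5], "c": [0.0, 10.0],
             "d": [0.3, 11.0]},
        )
        scores, _, _ = pca(x, 1)
        assert np.sign(scores.loc["a", "PC1"]) == np.sign(scores.loc["b", "PC1"])
        assert np.sign(scores.loc["a", "PC1"]) != np.sign(scores.loc["c", "PC1"])

    def test_full_rank_reconstruction(self, abundances):
        k = min(abundances.shape[1] - 1, np.linalg.matrix_rank(
            abundances.T - abundances.T.mean()))
        scores, loadings, _ = pca(abundances, k)
        x = abundances.T.values - abundances.T.values.mean(axis=0)
        assert np.allclose(scores.values @ loadings.values.T, x, atol=1e-8)

    def test_components_beyond_rank_rejected(self):
        x = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 4.0]})
        with pytest.raises(ValueError):
            pca(x, 5)


class TestVip:
    def _matrix(self):
        rng = np.random.default_rng(11)
        cols = [f"s{i}" for i in range(8)]
        labels = {c: ("X" if i < 4 else "Y") for i, c in enumerate(cols)}
        noise = rng.normal(0, 1, size=(10, 8))
        data = pd.DataFrame(noise, index=[f"f{i}" for i in range(10)],
                            columns=cols)
        # one perfectly discriminant feature
        data.loc["f0"] = [5.0] * 4 + [-5.0] * 4
        return data, labels

    def test_discriminant_feature_ranks_first(self):
        data, labels = self._matrix()
        vip = plsda_vip(data, labels)
        assert vip.index[0] == "f0"

    def test_mean_squared_vip_is_one(self):
        data, labels = self._matrix()
        vip = plsda_vip(data, labels)
        assert float((vip**2).mean()) == pytest.approx(1.0, abs=1e-6)

    def test_constant_feature_scores_low(self):
        data, labels = self._matrix()
        data.loc["f9"] = 1.0
        vip = plsda_vip(data, labels)
        assert vip["f9"] < 0.5 * vip["f0"]

    def test_single_class_rejected(self):
        data, labels = self._matrix()
        with pytest.raises(ValueError):
            plsda_vip(data, {k: "X" for k in labels})


ALIGNED = """>A
ACGTACGTAC
>B
ACGTACGTAC
>C
ACGTTTTTAC
>D
ACG-TTTTAC
"""


class TestPDistance:
    def test_identical_sequences_distance_zero(self):
        seqs = read_alignment(io.StringIO(ALIGNED))
        d = p_distance(seqs)
        assert d.loc["A", "B"] == 0.0

    def test_pairwise_deletion_ignores_gap_sites(self):
        seqs = read_alignment(io.StringIO(ALIGNED))
        d = p_distance(seqs)
        # C vs D: one gap site ignored, 9 comparable, 0 differences
        assert d.loc["C", "D"] == 0.0
        # A vs D: gap site ignored -> 9 sites, 3 differ
        assert d.loc["A", "D"] == pytest.approx(3 / 9)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            read_alignment(io.StringIO(">A\nACGT\n>B\nACG\n"))


def _parse_branch_lengths(newick):
    import re
    return {
        m.group(1): float(m.group(2))
        for m in re.finditer(r"([A-Za-z]\w*):([\d.]+)", newick)
    }


class TestNeighborJoining:
    def test_additive_four_taxon_exact_recovery(self):
        """NJ recovers the generating topology and exact branch lengths of
        an additive matrix; the true split is certified independently by
        the four-point condition."""
        # tree: ((A:1,B:2):1,C:3,D:4) with internal edge 1
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        # four-point condition: AB|CD is the additive split
        assert d.loc["A", "B"] + d.loc["C", "D"] < \
            d.loc["A", "C"] + d.loc["B", "D"]
        nwk = nj_tree(d)
        assert tree_bipartitions(nwk) == {frozenset({"A", "B"})}
        lengths = _parse_branch_lengths(nwk)
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_additive_six_taxon_topology_recovery(self):
        """Random additive 6-taxon distances: NJ recovers the generating
        topology (RF = 0) and agrees with an independent implementation."""
        # caterpillar tree (((A,B),(C,D)),(E,F)) with known branch lengths
        true_nwk = "(((A:1,B:2):1,(C:1.5,D:0.5):2):1,E:1,F:3);"
        import dendropy
        tree = dendropy.Tree.get(data=true_nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa]
        d = pd.DataFrame(
            [[pdm.distance(a, b) for b in taxa] for a in taxa],
            index=labels, columns=labels,
        )
        mine = nj_tree(d)
        assert robinson_foulds(mine, true_nwk) == 0
        skbio = pytest.importorskip("skbio")
        dm = skbio.DistanceMatrix(d.values, ids=labels)
        theirs = skbio.tree.nj(dm)
        assert tree_bipartitions(mine) == tree_bipartitions(
            str(theirs).strip()
        )

    def test_fewer_than_three_taxa_rejected(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"),
                         columns=list("AB"), dtype=float)
        with pytest.raises(ValueError):
            nj_tree(d)


class TestBootstrap:
    def _congruent_seqs(self):
        # A,B identical; C,D identical; 40% of sites separate the pairs
        a = "ACGT" * 10 + "AAAA" * 5
        c = "ACGT" * 10 + "TTTT" * 5
        return {"A": a, "B": a, "C": c, "D": c}

    def test_congruent_sites_give_full_support(self):
        support = bootstrap_support(self._congruent_seqs(),
                                    n_replicates=100, seed=5)
        assert support  # the AB|CD split exists
        assert all(v == pytest.approx(1.0) for v in support.values())

    def test_invariant_to_taxon_input_order(self):
        seqs = self._congruent_seqs()
        reordered = {k: seqs[k] for k in ["D", "B", "C", "A"]}
        s1 = bootstrap_support(seqs, n_replicates=25, seed=9)
        s2 = bootstrap_support(reordered, n_replicates=25, seed=9)
        assert s1 == s2


class TestConcordance:
    ORDERS = {
        "Ha": "Halobacteriales",
        "Hf1": "Haloferacales", "Hf2": "Haloferacales", "Hf3": "Haloferacales",
        "Nt1": "Natrialbales", "Nt2": "Natrialbales", "Nt3": "Natrialbales",
    }

    def _matrix(self, swap=False):
        # three well-separated order blocks in a 2-D trait space
        coords = {
            "Ha": (0.0, 0.0), "Hf1": (10.0, 0.1), "Hf2": (10.2, 0.0),
            "Hf3": (9.9, -0.1), "Nt1": (0.0, 10.0), "Nt2": (0.1, 10.2),
            "Nt3": (-0.1, 9.9),
        }
        if swap:  # drag one Natrialbales strain into the Ha corner
            coords["Nt3"] = (0.05, 0.05)
        return pd.DataFrame(coords)

    def test_perfect_agreement(self):
        d = hcluster(self._matrix(), "complete")
        res = concordance(d, self.ORDERS, k=3)
        assert res["ari"] == pytest.approx(1.0)

    def test_one_strain_swapped_matches_closed_form(self):
        """One Natrialbales strain clustering with Halobacteriales gives
        the closed-form ARI 12/19 on the 7-leaf label vector."""
        d = hcluster(self._matrix(swap=True), "complete")
        res = concordance(d, self.ORDERS, k=3)
        assert res["ari"] == pytest.approx(12.0 / 19.0)

    def test_k1_is_zero_by_convention(self):
        d = hcluster(self._matrix(), "complete")
        assert concordance(d, self.ORDERS, k=1)["ari"] == 0.0

    def test_leaf_set_mismatch_rejected(self):
        d = hcluster(self._matrix(), "complete")
        with pytest.raises(ValueError):
            concordance(d, {"X": "o"}, k=2)

    def test_rf_zero_for_identical_topology(self):
        d = hcluster(self._matrix(), "complete")
        nwk = d.to_newick()
        res = concordance(d, self.ORDERS, k=3, reference_newick=nwk)
        assert res["rf"] == 0
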