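"""Kinship recursion, inbreeding, the gene-drop oracle, and matrix I/O."""

import numpy as np
import pytest

from cppherit import (
    Individual,
    Pedigree,
    UnknownIdError,
    gene_drop_kinship,
    inbreeding_coefficient,
    kinship_matrix,
    read_kinship_csv,
)


class TestClosedForms:
    def test_distinct_inbred_founders(self, inbred_cross_pedigree):
        K = kinship_matrix(inbred_cross_pedigree, ["A", "B"])
        assert K.phi("A", "B") == 0.0
        assert K.phi("A", "A") == 1.0 and K.phi("B", "B") == 1.0

    def test_noninbred_founder_self_kinship(self, outbred_sib_pedigree):
        K = kinship_matrix(outbred_sib_pedigree, ["p1"])
        assert K.values[0, 0] == 0.5

    def test_f1_sibs_of_inbred_cross(self, inbred_cross_pedigree):
        assert kinship_matrix(inbred_cross_pedigree).phi("f1a", "f1b") == 0.5

    def test_outbred_full_sibs(self, outbred_sib_pedigree):
        assert kinship_matrix(outbred_sib_pedigree).phi("s1", "s2") == 0.25

    def test_inbreeding_coefficients(self, inbred_cross_pedigree):
        # F1 of a cross between unrelated inbred founders is non-inbred
        assert inbreeding_coefficient(inbred_cross_pedigree, "f1a") == 0.0
        assert inbreeding_coefficient(inbred_cross_pedigree, "A") == 1.0
        # F2 from mating two F1 sibs: F = Phi(F1, F1') = 0.5
        assert inbreeding_coefficient(inbred_cross_pedigree, "f2") == 0.5

    def test_unknown_id(self, inbred_cross_pedigree):
        with pytest.raises(UnknownIdError):
            inbreeding_coefficient(inbred_cross_pedigree, "nope")


class TestGeneDrop:
    def test_unrelated_founders_exactly_zero(self, outbred_sib_pedigree):
        G = gene_drop_kinship(outbred_sib_pedigree, ["p1", "p2"], n_reps=50, seed=0)
        assert G.phi("p1", "p2") == 0.0
        assert G.phi("p1", "p1") == 0.5  # two distinct labels

    def test_f1_sib_pair_matches_recursion(self, inbred_cross_pedigree):
        G = gene_drop_kinship(inbred_cross_pedigree, ["f1a", "f1b"], n_reps=10_000, seed=1)
        assert abs(G.phi("f1a", "f1b") - 0.5) <= 0.01

    def test_deterministic_given_seed(self, outbred_sib_pedigree):
        a = gene_drop_kinship(outbred_sib_pedigree, n_reps=500, seed=7)
        b = gene_drop_kinship(outbred_sib_pedigree, n_reps=500, seed=7)
        np.testing.assert_array_equal(a.values, b.values)


class TestMatrixProperties:
    def test_symmetric_and_psd_on_ail(self, small_ail):
        ids = small_ail.generation_ids(small_ail.max_generation)
        K = kinship_matrix(small_ail, list(ids))
        np.testing.assert_allclose(K.values, K.values.T)
        assert K.min_additive_eigenvalue() >= -1e-8
        off = K.values[~np.eye(len(K), dtype=bool)]
        assert ((off >= 0) & (off <= 1)).all()
        diag = np.diag(K.values)
        assert ((diag >= 0.5) & (diag <= 1.0)).all()

    def test_recursion_matches_gene_drop_on_ail(self, small_ail):
        ids = list(small_ail.generation_ids(small_ail.max_generation))[:25]
        K = kinship_matrix(small_ail, ids)
        G = gene_drop_kinship(small_ail, ids, n_reps=10_000, seed=3)
        # 3 Monte-Carlo SEs, bounding the per-entry SE by 0.5/sqrt(reps)
        assert np.max(np.abs(K.values - G.values)) <= 3 * 0.5 / np.sqrt(10_000)

    def test_pruning_irrelevant_branches_leaves_kinship_unchanged(self, small_ail):
        ids = list(small_ail.generation_ids(small_ail.max_generation))[:10]
        full = kinship_matrix(small_ail, ids)
        pruned_ped = small_ail.subset(ids)  # drops all non-ancestors
        assert len(pruned_ped) < len(small_ail)
        pruned = kinship_matrix(pruned_ped, ids)
        np.testing.assert_allclose(full.values, pruned.values)

    def test_subset_order_follows_request(self, inbred_cross_pedigree):
        K = kinship_matrix(inbred_cross_pedigree, ["f1b", "A"])
        assert K.ids == ("f1b", "A")
        assert K.values[1, 1] == 1.0


def test_square_and_triplet_io_roundtrip(tmp_path, inbred_cross_pedigree):
    K = kinship_matrix(inbred_cross_pedigree)
    sq = tmp_path / "k.csv"
    K.write_csv(sq)
    back = read_kinship_csv(sq)
    assert back.ids == K.ids
    np.testing.assert_allclose(back.values, K.values)
    trip = K.to_triplets()
    n = len(K)
    assert len(trip) == n * (n + 1) // 2
    assert trip.loc[(trip.id1 == "f1a") & (trip.id2 == "f1b"), "phi"].iloc[0] == 0.5
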