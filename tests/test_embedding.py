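import numpy as np
import pytest
import scipy.sparse as sp

import citescreen as cs
from citescreen.embedding import DegenerateRowError


def norm_from_dense(A, sqrt_dialect=True):
    return cs.row_normalize(sp.csr_matrix(np.asarray(A, dtype=float)), sqrt_dialect)


class TestRowNormalize:
    def test_hand_case_square_root_dialect(self):
        norm = norm_from_dense([[3.0, 1.0]])
        row = norm.R.toarray()[0]
        np.testing.assert_allclose(row, [np.sqrt(0.75), 0.5], atol=1e-12)
        assert abs(row @ row - 1.0) < 1e-10

    def test_plain_dialect_gives_l1_shares(self):
        norm = norm_from_dense([[3.0, 1.0]], sqrt_dialect=False)
        np.testing.assert_allclose(norm.R.toarray()[0], [0.75, 0.25], atol=1e-12)

    def test_zero_row_flagged_degenerate(self):
        norm = norm_from_dense([[0.0, 0.0], [1.0, 1.0]])
        assert list(norm.valid) == [False, True]
        assert norm.R[0].nnz == 0

    def test_all_valid_rows_have_unit_self_inner_product(self, small_features):
        _, norm = small_features
        sq = np.asarray(norm.R.multiply(norm.R).sum(axis=1)).ravel()
        np.testing.assert_allclose(sq[norm.valid], 1.0, atol=1e-10)


class TestPairwiseSimilarity:
    def test_identical_rows_similarity_one(self):
        norm = norm_from_dense([[3.0, 1.0], [3.0, 1.0]])
        assert cs.pairwise_similarity(norm, 0, 1) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_vocabularies_similarity_zero(self):
        norm = norm_from_dense([[1.0, 0.0], [0.0, 1.0]])
        assert cs.pairwise_similarity(norm, 0, 1) == 0.0

    def test_bhattacharyya_by_hand(self):
        # shares (0.75, 0.25) vs (0.25, 0.75)
        norm = norm_from_dense([[3.0, 1.0], [1.0, 3.0]])
        expected = np.sqrt(0.75 * 0.25) + np.sqrt(0.25 * 0.75)
        assert cs.pairwise_similarity(norm, 0, 1) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_row_raises(self):
        norm = norm_from_dense([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(DegenerateRowError):
            cs.pairwise_similarity(norm, 0, 1)


class TestDegreeVector:
    def test_two_row_degree_by_hand(self):
        norm = norm_from_dense([[3.0, 1.0], [1.0, 3.0]])
        expected = 1.0 + np.sqrt(0.75 * 0.25) * 2
        np.testing.assert_allclose(cs.degree_vector(norm), [expected, expected], atol=1e-12)

    def test_orthogonal_rows_give_identity_degree(self):
        norm = norm_from_dense(np.eye(4))
        np.testing.assert_allclose(cs.degree_vector(norm), np.ones(4), atol=1e-12)

    def test_single_row(self):
        norm = norm_from_dense([[2.0, 5.0]])
        np.testing.assert_allclose(cs.degree_vector(norm), [1.0], atol=1e-12)

    def test_matches_materialised_similarity_rowsums(self, small_features):
        _, norm = small_features
        C = cs.similarity_matrix(norm)
        np.testing.assert_allclose(cs.degree_vector(norm), C.sum(axis=1), atol=1e-8)


class TestSpectralEmbed:
    def test_two_by_two_closed_form(self):
        # C = [[1, s], [s, 1]] with s = 0.8660; eigenvalues of C~ = C / (1+s)
        # are (1+s)/(1+s) = 1 and (1-s)/(1+s).
        norm = norm_from_dense([[3.0, 1.0], [1.0, 3.0]])
        s = 2 * np.sqrt(0.75 * 0.25)
        emb = cs.spectral_embed(norm, p=2)
        np.testing.assert_allclose(
            emb.eigenvalues, [1.0, (1 - s) / (1 + s)], atol=1e-10
        )
        C_tilde = cs.normalised_similarity_dense(norm)
        np.testing.assert_allclose(emb.Z @ emb.Z.T, C_tilde, atol=1e-8)

    def test_orthogonal_documents_identity_operator(self):
        norm = norm_from_dense(np.eye(5))
        emb = cs.spectral_embed(norm, p=5)
        np.testing.assert_allclose(emb.eigenvalues, np.ones(5), atol=1e-10)
        np.testing.assert_allclose(emb.Z @ emb.Z.T, np.eye(5), atol=1e-8)

    def test_top_eigenvector_is_scaled_degree_fixed_point(self, small_features):
        # C~ (D^{1/2} 1) = D^{-1/2} C 1 = D^{-1/2} deg = D^{1/2} 1
        _, norm = small_features
        v = np.sqrt(cs.degree_vector(norm))
        C_tilde = cs.normalised_similarity_dense(norm)
        np.testing.assert_allclose(C_tilde @ v, v, atol=1e-8)

    def test_eigenvalue_invariants(self, small_embedding):
        lam = small_embedding.eigenvalues
        assert abs(lam[0] - 1.0) < 1e-8
        assert np.all(np.diff(lam) <= 1e-12)
        assert lam.min() >= -1e-8 and lam.max() <= 1 + 1e-8

    def test_implicit_operator_matches_dense_oracle(self, small_features):
        _, norm = small_features
        p = 20
        implicit = cs.spectral_embed(norm, p=p, seed=3, dense_threshold=0)
        C_tilde = cs.normalised_similarity_dense(norm)
        vals = np.sort(np.linalg.eigvalsh(C_tilde))[::-1][:p]
        np.testing.assert_allclose(implicit.eigenvalues, vals, atol=1e-6)

    def test_full_rank_embedding_reconstructs_operator(self, small_features):
        _, norm = small_features
        n = norm.n
        emb = cs.spectral_embed(norm, p=n)
        C_tilde = cs.normalised_similarity_dense(norm)
        assert np.abs(emb.Z @ emb.Z.T - C_tilde).max() <= 1e-6
        # inner products of embedding rows reproduce the normalised similarity
        d, dp = 3, 11
        assert emb.Z[d] @ emb.Z[dp] == pytest.approx(C_tilde[d, dp], abs=1e-6)

    def test_p_larger_than_corpus_rejected(self, small_features):
        _, norm = small_features
        with pytest.raises(ValueError, match="exceeds corpus size"):
            cs.spectral_embed(norm, p=norm.n + 1)

    def test_degenerate_rows_get_zero_coordinates(self):
        A = np.vstack([np.zeros(3), np.eye(3)])
        norm = norm_from_dense(A)
        emb = cs.spectral_embed(norm, p=2)
        assert np.all(emb.Z[0] == 0.0)
        assert not emb.valid[0]

    def test_zero_fill_warns_when_p_exceeds_rank(self):
        norm = norm_from_dense(np.eye(3))
        A = np.vstack([np.eye(3), np.zeros(3)])
        norm = norm_from_dense(A)
        with pytest.warns(RuntimeWarning, match="zero-filled"):
            emb = cs.spectral_embed(norm, p=4)
        assert np.all(emb.Z[:, 3] == 0.0)

    def test_deterministic_given_seed(self, small_features):
        _, norm = small_features
        a = cs.spectral_embed(norm, p=10, seed=5, dense_threshold=0)
        b = cs.spectral_embed(norm, p=10, seed=5, dense_threshold=0)
        np.testing.assert_array_equal(a.Z, b.Z)
        np.testing.assert_array_equal(a.eigenvalues, b.eigenvalues)

    def test_class_structure_is_tighter_in_embedding(self, small_synth, small_embedding):
        report = cs.structure_report(small_synth.labels, small_embedding.Z, rng_seed=0)
        assert report["eligible_eligible_mean"] < report["mixed_mean"]
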