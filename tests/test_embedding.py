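import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import freeassoc as fa
from freeassoc.errors import ConfigurationError, UsageError


def snowball(rows):
    frame = pd.DataFrame(rows, columns=["participant_id", "cue", "response"])
    return fa.set_targets(fa.import_study(frame), "cues")


def ppmi_reference(counts: np.ndarray) -> np.ndarray:
    """Independent cell-by-cell evaluation of the PPMI definition."""
    total = counts.sum()
    out = np.zeros_like(counts, dtype=float)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            n = counts[i, j]
            if n > 0:
                pmi = np.log(n * total / (counts[i].sum() * counts[:, j].sum()))
                out[i, j] = max(0.0, pmi)
    return out


class TestCountMatrix:
    def test_tabulates_response_distribution_per_cue(self):
        study = snowball(
            [("p1", "a", "x"), ("p1", "a", "x"), ("p1", "a", "y")]
        )
        cm = fa.build_count_matrix(study)
        assert cm.to_frame().loc["a"].to_dict() == {"x": 2.0, "y": 1.0}

    def test_disjoint_response_sets_give_block_diagonal(self):
        study = snowball(
            [("p1", "a", "x"), ("p1", "a", "y"), ("p1", "b", "u"), ("p1", "b", "v")]
        )
        frame = fa.build_count_matrix(study).to_frame()
        assert frame.loc["a", ["u", "v"]].sum() == 0
        assert frame.loc["b", ["x", "y"]].sum() == 0

    def test_margins_cached_consistently(self):
        study = snowball([("p1", "a", "x"), ("p1", "b", "x"), ("p1", "b", "y")])
        cm = fa.build_count_matrix(study)
        assert cm.row_totals.sum() == cm.grand_total == cm.col_totals.sum() == 3

    def test_targets_including_responses_are_infeasible(self, toy_study):
        study = fa.set_targets(toy_study, "both")
        with pytest.raises(UsageError, match="cues only"):
            fa.build_count_matrix(study)

    def test_target_never_used_as_cue_is_an_error(self):
        study = snowball([("p1", "a", "x")])
        study.targets = pd.DataFrame({"target": ["a", "ghost"]})
        with pytest.raises(UsageError, match="ghost"):
            fa.build_count_matrix(study)

    def test_locality_of_tabulation(self):
        """Removing one cue's rows does not change other rows' counts."""
        rows = [("p1", "a", "x"), ("p1", "a", "y"), ("p1", "b", "x")]
        full = fa.build_count_matrix(snowball(rows)).to_frame()
        reduced = fa.build_count_matrix(snowball(rows[:2])).to_frame()
        assert full.loc["a", ["x", "y"]].equals(reduced.loc["a", ["x", "y"]])


class TestPPMI:
    def test_uniform_counts_give_all_zero(self):
        assert fa.ppmi(np.full((3, 4), 5.0)) == pytest.approx(np.zeros((3, 4)))

    def test_diagonal_two_by_two(self):
        out = fa.ppmi(np.array([[2.0, 0.0], [0.0, 2.0]]))
        assert out == pytest.approx(np.log(2) * np.eye(2))

    def test_zero_total_rejected(self):
        with pytest.raises(UsageError):
            fa.ppmi(np.zeros((2, 2)))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(1, 8), st.integers(1, 8)),
            elements=st.integers(0, 9).map(float),
        ).filter(lambda a: a.sum() > 0)
    )
    def test_matches_cellwise_formula_oracle(self, counts):
        assert fa.ppmi(counts) == pytest.approx(
            ppmi_reference(counts), abs=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(1, 6), st.integers(1, 6)),
            elements=st.integers(0, 9).map(float),
        ).filter(lambda a: a.sum() > 0)
    )
    def test_outputs_non_negative_and_zero_preserving(self, counts):
        out = fa.ppmi(counts)
        assert (out >= 0).all()
        assert (out[counts == 0] == 0).all()


def cosine(m):
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = m / norms
    return unit @ unit.T


class TestSVDEmbed:
    def test_rank_one_matrix_reconstructed_at_n_dim_one(self):
        m = np.outer([1.0, 2.0, 3.0], [4.0, 5.0])
        emb = fa.svd_embed(m, 1)
        assert emb.vectors.shape == (3, 1)
        # U1*s1 times the right singular vector reconstructs a rank-1 input
        _, _, vt = np.linalg.svd(m, full_matrices=False)
        v1 = vt[0] * np.sign(vt[0][np.abs(vt[0]).argmax()])
        assert np.outer(emb.vectors[:, 0], v1) == pytest.approx(m, abs=1e-10)

    def test_full_rank_preserves_dot_products(self):
        rng = np.random.default_rng(3)
        m = rng.random((5, 7))
        emb = fa.svd_embed(m, 5)
        assert emb.vectors @ emb.vectors.T == pytest.approx(m @ m.T, abs=1e-8)

    def test_full_rank_preserves_cosine_similarities(self):
        rng = np.random.default_rng(4)
        m = fa.ppmi(rng.integers(0, 9, size=(6, 10)).astype(float))
        emb = fa.svd_embed(m, 6)
        assert cosine(emb.vectors) == pytest.approx(cosine(m), abs=1e-8)

    def test_zero_matrix_gives_zero_embedding(self):
        emb = fa.svd_embed(np.zeros((3, 3)), 2)
        assert emb.vectors == pytest.approx(np.zeros((3, 2)))

    def test_excess_n_dim_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            emb = fa.svd_embed(np.eye(3), 10)
        assert emb.n_dim == 3

    def test_repeated_runs_identical_including_signs(self):
        rng = np.random.default_rng(5)
        m = rng.random((6, 6))
        a = fa.svd_embed(m, 4).vectors
        b = fa.svd_embed(m, 4).vectors
        assert (a == b).all()


class TestEmbedTargets:
    def test_ppmi_svd_shape_contract(self, small_study):
        study = fa.embed_targets(small_study, n_dim=2)
        assert study.embedding.vectors.shape == (len(study.embedding.labels), 2)
        assert study.embedding.method == "ppmi-svd"

    def test_infeasible_with_response_targets(self, toy_study):
        study = fa.set_targets(toy_study, "both")
        with pytest.raises(UsageError):
            fa.embed_targets(study, method="ppmi-svd")

    def test_external_provider_reproducible(self, small_study):
        provider = fa.HashEmbeddingProvider(n_dim=8)
        a = fa.embed_targets(small_study, method="external", provider=provider)
        b = fa.embed_targets(small_study, method="external", provider=provider)
        assert (a.embedding.vectors == b.embedding.vectors).all()
        assert a.embedding.provider == provider.identifier

    def test_missing_provider_is_configuration_error(self, small_study):
        with pytest.raises(ConfigurationError, match="(?i)provider"):
            fa.embed_targets(small_study, method="external")

    def test_provider_failure_names_the_string(self, small_study):
        class Broken:
            identifier = "broken"

            def embed(self, texts):
                raise RuntimeError("no backend")

        first_target = small_study.target_list()[0]
        with pytest.raises(ConfigurationError, match=first_target):
            fa.embed_targets(small_study, method="external", provider=Broken())


class TestProjection:
    def test_pca_of_2d_embedding_preserves_pairwise_distances(self):
        rng = np.random.default_rng(6)
        emb = fa.EmbeddingMatrix(
            labels=[f"t{i}" for i in range(10)], vectors=rng.random((10, 2))
        )
        proj = fa.project_embedding(emb, "pca", n_dim=2)
        from scipy.spatial.distance import pdist

        assert pdist(proj.vectors) == pytest.approx(pdist(emb.vectors), abs=1e-9)

    def test_mds_maps_identical_vectors_to_identical_points(self):
        base = np.array([[1.0, 2.0, 3.0]])
        vectors = np.vstack([base, base, np.array([[3.0, -1.0, 0.5]]),
                             np.array([[0.2, 5.0, 1.0]])])
        emb = fa.EmbeddingMatrix(labels=list("abcd"), vectors=vectors)
        proj = fa.project_embedding(emb, "mds", n_dim=2)
        assert proj.vectors[0] == pytest.approx(proj.vectors[1], abs=1e-6)

    def test_umap_same_seed_identical_coordinates(self, embedded_study):
        a = fa.project_study(embedded_study, "umap", seed=9)
        b = fa.project_study(embedded_study, "umap", seed=9)
        assert a.embedding.vectors == pytest.approx(b.embedding.vectors)
        assert a.embedding.n_dim == 2

    def test_unknown_method_rejected(self, embedded_study):
        with pytest.raises(UsageError):
            fa.project_study(embedded_study, "pacmap")
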