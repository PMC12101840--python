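import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import lexalign as lx
from lexalign.alignment import UndefinedAlignmentError
from lexalign.metrics import centroids


def sim_from_upper(upper, n):
    """Build a symmetric unit-diagonal matrix from its strict upper triangle."""
    m = np.eye(n)
    iu = np.triu_indices(n, 1)
    m[iu] = upper
    m[(iu[1], iu[0])] = upper
    return lx.SimilarityMatrix(values=m, words=tuple(str(i) for i in range(n)))


class TestCosineSimilarityMatrix:
    def test_orthogonal_vectors_give_identity(self):
        s = lx.cosine_similarity_matrix(np.eye(4))
        np.testing.assert_allclose(s.values, np.eye(4), atol=1e-12)

    def test_scale_invariance(self):
        reps = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        scaled = reps * np.array([[2.0], [5.0], [0.3]])
        np.testing.assert_allclose(
            lx.cosine_similarity_matrix(reps).values,
            lx.cosine_similarity_matrix(scaled).values,
            atol=1e-12,
        )

    def test_matches_pairwise_loop(self, rng):
        reps = rng.normal(size=(4, 6))
        s = lx.cosine_similarity_matrix(reps)
        for i, j in itertools.combinations(range(4), 2):
            expected = reps[i] @ reps[j] / (
                np.linalg.norm(reps[i]) * np.linalg.norm(reps[j])
            )
            assert s.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError):
            lx.cosine_similarity_matrix(np.eye(2))


class TestAlignmentStrength:
    def test_identical_matrices_give_one(self, rng):
        s = lx.cosine_similarity_matrix(rng.normal(size=(5, 4)))
        assert lx.alignment_strength(s, s) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        upper = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        a = sim_from_upper(upper, 4)
        b = sim_from_upper(upper[::-1], 4)
        assert lx.alignment_strength(a, b) == pytest.approx(-1.0)

    def test_textbook_rank_difference_formula(self):
        upper = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        swapped = upper.copy()
        swapped[[4, 5]] = swapped[[5, 4]]
        a, b = sim_from_upper(upper, 4), sim_from_upper(swapped, 4)
        # one adjacent transposition: rho = 1 - 6*2 / (6*(36-1))
        assert lx.alignment_strength(a, b) == pytest.approx(1 - 12 / 210, abs=1e-12)

    def test_constant_triangle_undefined(self):
        a = sim_from_upper(np.full(6, 0.5), 4)
        b = sim_from_upper(np.arange(6) / 10, 4)
        with pytest.raises(UndefinedAlignmentError):
            lx.alignment_strength(a, b)

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = lx.cosine_similarity_matrix(rng.normal(size=(5, 4)))
        b = lx.cosine_similarity_matrix(rng.normal(size=(5, 4)))
        # strictly increasing transform of one matrix's entries
        transformed = sim_from_upper(np.tanh(2.0 * a.upper_triangle()) * 0.99, 5)
        base = lx.alignment_strength(a, b)
        assert lx.alignment_strength(transformed, b) == pytest.approx(base, abs=1e-12)


class TestWordAlignmentProfile:
    def test_identical_matrices_give_ones(self, rng):
        s = lx.cosine_similarity_matrix(rng.normal(size=(6, 5)))
        np.testing.assert_allclose(lx.word_alignment_profile(s, s), 1.0)

    def test_null_profile_centered_near_zero(self):
        means = []
        for rep in range(50):
            rng = np.random.default_rng(rep)
            a = lx.cosine_similarity_matrix(rng.normal(size=(40, 20)))
            b = lx.cosine_similarity_matrix(rng.normal(size=(40, 20)))
            means.append(lx.word_alignment_profile(a, b).mean())
        assert abs(np.mean(means)) < 0.1

    def test_shuffled_word_drops_below_others(self):
        rng = np.random.default_rng(4)
        reps = rng.normal(size=(20, 12))
        s_l = lx.cosine_similarity_matrix(reps)
        vis = reps.copy()
        vis[0] = rng.normal(size=12)  # break word 0's visual similarity structure
        s_v = lx.cosine_similarity_matrix(vis)
        profile = lx.word_alignment_profile(s_v, s_l)
        assert profile[0] < np.min(profile[1:])


class TestSamplePermutations:
    def test_n2_always_the_swap(self, rng):
        perms = lx.sample_permutations(2, 20, rng)
        assert np.all(perms == [1, 0])

    def test_identity_never_returned(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            perms = lx.sample_permutations(3, 200, rng)
            assert not np.any(np.all(perms == [0, 1, 2], axis=1))

    def test_uniform_over_non_identity_permutations(self):
        """N=3: each of the 5 non-identity permutations at frequency 1/5."""
        rng = np.random.default_rng(99)
        perms = lx.sample_permutations(3, 50_000, rng)
        codes = perms[:, 0] * 9 + perms[:, 1] * 3 + perms[:, 2]
        _, counts = np.unique(codes, return_counts=True)
        assert counts.size == 5
        chi2 = ((counts - 10_000.0) ** 2 / 10_000.0).sum()
        assert stats.chi2.sf(chi2, df=4) > 0.001


class TestPermutedStrengths:
    def test_identity_recovers_true_strength(self, rng):
        a = lx.cosine_similarity_matrix(rng.normal(size=(6, 5)))
        b = lx.cosine_similarity_matrix(rng.normal(size=(6, 5)))
        true = lx.alignment_strength(a, b)
        out = lx.permuted_strengths(a, b, np.arange(6))
        assert out[0] == pytest.approx(true, abs=1e-12)

    def test_reindexing_equals_recomputation(self, rng):
        """Reindexed-matrix strength equals recomputing cosines on permuted vectors."""
        vis = rng.normal(size=(6, 5))
        ling = rng.normal(size=(6, 5))
        s_v = lx.cosine_similarity_matrix(vis)
        s_l = lx.cosine_similarity_matrix(ling)
        perm = np.array([2, 0, 5, 1, 4, 3])
        via_reindex = lx.permuted_strengths(s_v, s_l, perm)[0]
        s_v_re = lx.cosine_similarity_matrix(vis[perm])
        via_recompute = lx.alignment_strength(s_v_re, lx.cosine_similarity_matrix(ling))
        assert via_reindex == pytest.approx(via_recompute, abs=1e-12)

    def test_joint_relabeling_invariance(self, rng):
        vis = rng.normal(size=(6, 5))
        ling = rng.normal(size=(6, 5))
        s_v = lx.cosine_similarity_matrix(vis)
        s_l = lx.cosine_similarity_matrix(ling)
        perm = np.array([3, 1, 0, 5, 2, 4])
        true = lx.alignment_strength(s_v, s_l)
        both = lx.alignment_strength(
            lx.cosine_similarity_matrix(vis[perm]),
            lx.cosine_similarity_matrix(ling[perm]),
        )
        assert both == pytest.approx(true, abs=1e-12)

    def test_matches_scipy_spearman_per_permutation(self, rng):
        s_v = lx.cosine_similarity_matrix(rng.normal(size=(7, 4)))
        s_l = lx.cosine_similarity_matrix(rng.normal(size=(7, 4)))
        perms = lx.sample_permutations(7, 10, rng)
        fast = lx.permuted_strengths(s_v, s_l, perms)
        iu = np.triu_indices(7, 1)
        for p, val in zip(perms, fast):
            ref = stats.spearmanr(
                s_v.values[np.ix_(p, p)][iu], s_l.values[iu]
            ).statistic
            assert val == pytest.approx(ref, abs=1e-12)

    def test_invalid_permutation_rejected(self, rng):
        s = lx.cosine_similarity_matrix(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError, match="permutation"):
            lx.permuted_strengths(s, s, np.array([0, 0, 1, 2]))


class TestRelativeAlignmentStrength:
    def test_all_below_gives_one(self):
        assert lx.relative_alignment_strength(0.9, np.full(1000, 0.5)) == 1.0

    def test_counting(self):
        assert lx.relative_alignment_strength(0.5, [0.1, 0.2, 0.6, 0.7]) == 0.5

    def test_ties_count_as_not_lower(self):
        assert lx.relative_alignment_strength(0.4, [0.4, 0.4, 0.4]) == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            lx.relative_alignment_strength(0.5, [])


class TestSingleExemplarAnalysis:
    def test_df_matches_pooled_counts(self):
        """Pooled t df = n_systems + n_systems * n_permutations - 2."""
        params = lx.SyntheticSystemParams(
            n_words=8, exemplars_visual=4, exemplars_linguistic=4, seed=0
        )
        system, _ = lx.generate_bimodal_system(params)
        cfg = lx.RunConfig(n_permutations=20, seed=0)
        result = lx.single_exemplar_analysis(
            system, n_systems=5, config=cfg, rng=np.random.default_rng(0)
        )
        assert result.comparison.degrees_of_freedom == 5 + 5 * 20 - 2
        assert result.relative_strengths.shape == (5,)
        # study-scale count check without a full run
        assert lx.pooled_df(1000, 1000 * 1000) == 1_000_998

    def test_perfect_alignment_limit(self):
        """Shared latent, zero dispersion: every sampled system has strength 1."""
        params = lx.SyntheticSystemParams(
            n_words=8, alignment=1.0, dispersion_visual=0.0,
            dispersion_linguistic=0.0, exemplars_visual=3,
            exemplars_linguistic=3, seed=1,
        )
        system, _ = lx.generate_bimodal_system(params)
        cfg = lx.RunConfig(n_permutations=10, seed=1)
        result = lx.single_exemplar_analysis(
            system, n_systems=5, config=cfg, rng=np.random.default_rng(1)
        )
        np.testing.assert_allclose(result.true_strengths, 1.0, atol=1e-10)


def test_alignment_report_relative_strength_definition(rng):
    s_v = lx.cosine_similarity_matrix(rng.normal(size=(8, 6)))
    s_l = lx.cosine_similarity_matrix(rng.normal(size=(8, 6)))
    report = lx.alignment_report(s_v, s_l, 100, np.random.default_rng(0))
    assert report.n_permutations == 100
    expected = np.mean(report.permuted_strengths < report.true_strength)
    assert report.relative_strength == pytest.approx(expected)
    assert 0.0 <= report.relative_strength <= 1.0
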