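"""Rank RSMs, the ideal observer, judgment RSMs, and correspondence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sizeaxis import (ResponseMatrix, assign_size_ranks, generate_pairwise_judgments,
                      ideal_observer_rsm, judgment_rsm, rank_rsm, rsm_correspondence)
from sizeaxis.errors import BinningError, DimensionError, UndefinedStatisticError
from sizeaxis.rsa import RankRSM
from sizeaxis._utils import rng_from


class TestIdealObserver:
    def test_matches_brute_force_enumeration(self):
        """Independent oracle: loop over all 64 rank pairs."""
        rsm = ideal_observer_rsm(8)
        for i in range(1, 9):
            for j in range(1, 9):
                assert rsm.values[i - 1, j - 1] == 1.0 - abs(i - j) / 8.0

    def test_extreme_entries(self):
        rsm = ideal_observer_rsm(8)
        assert rsm.values[0, 0] == 1.0
        assert rsm.values[0, 7] == pytest.approx(0.125)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(2, 20))
    def test_symmetric_toeplitz_unit_diagonal(self, k):
        v = ideal_observer_rsm(k).values
        assert np.array_equal(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        for d in range(1, k):
            band = np.diagonal(v, offset=d)
            assert np.allclose(band, band[0])


class TestAssignRanks:
    def test_matched_design_counts(self):
        rng = rng_from(0, "sizes")
        sizes = np.concatenate([
            10 ** rng.uniform(lo, lo + 0.5, 6) for lo in np.arange(0, 4, 0.5)])
        ranks = assign_size_ranks(sizes, 8, min_per_rank=6, size_range=(1, 1e4))
        assert list(np.bincount(ranks)[1:]) == [6] * 8

    def test_monotone_sizes_give_nondecreasing_ranks(self):
        ranks = assign_size_ranks(np.logspace(0, 3, 30), 5)
        assert np.all(np.diff(ranks) >= 0)

    def test_identical_sizes_error_names_empty_ranks(self):
        with pytest.raises(BinningError, match="7 empty"):
            assign_size_ranks(np.full(10, 5.0), 8)

    def test_under_occupied_rank_is_named(self):
        with pytest.raises(BinningError, match="rank"):
            assign_size_ranks([1.0, 1.1, 1000.0], 4, min_per_rank=2,
                              size_range=(1, 1e4))


class TestRankRSM:
    def test_identical_responses_give_unit_matrix(self):
        X = np.tile(np.arange(5.0), (16, 1))
        ranks = np.repeat(np.arange(1, 5), 4)
        rsm = rank_rsm(ResponseMatrix(values=X), ranks)
        assert np.allclose(rsm.values, 1.0)

    def test_orthogonal_rank_means_give_zero_offdiagonal(self):
        """Zero-sum mutually orthogonal rank means are exactly uncorrelated."""
        from scipy.linalg import hadamard
        base = hadamard(8)[1:5].astype(float)  # 4 zero-sum orthogonal patterns
        X = np.repeat(base, 3, axis=0)         # 3 stimuli per rank
        ranks = np.repeat(np.arange(1, 5), 3)
        rsm = rank_rsm(ResponseMatrix(values=X), ranks)
        off = rsm.values[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-10)

    def test_planted_noiseless_similarity_decays_with_rank_distance(self, stimuli32):
        """Brute force on a generated matrix: mean similarity at rank
        distance d strictly decreases in d.  (Per-row strict decrease cannot
        hold for a correlation RSM of a 1-D planted signal: correlation is
        scale-free, so similarity rises again toward the far extreme.)"""
        from sizeaxis import generate_planted_activations
        from sizeaxis.synthetic import PlantedGroundTruth
        truth = PlantedGroundTruth.default(64, 10, seed=0, beta=2.0, noise_sd=0.0)
        resp = generate_planted_activations(stimuli32, 64, truth, seed=1)
        rsm = rank_rsm(resp, stimuli32.ranks).values
        dist = np.abs(np.subtract.outer(np.arange(8), np.arange(8)))
        by_d = [rsm[dist == d].mean() for d in range(1, 8)]
        assert np.all(np.diff(by_d) < 0)

    def test_empty_rank_raises(self):
        with pytest.raises(BinningError):
            rank_rsm(ResponseMatrix(values=np.random.default_rng(0).random((6, 4))),
                     [1, 1, 1, 3, 3, 3])

    def test_invariance_to_channel_permutation_and_relabeling(self, encoded32, stimuli32):
        rsm = rank_rsm(encoded32, stimuli32.ranks)
        perm = np.random.default_rng(1).permutation(encoded32.channel_count)
        rsm_p = rank_rsm(ResponseMatrix(values=encoded32.values[:, perm]),
                         stimuli32.ranks)
        np.testing.assert_allclose(rsm.values, rsm_p.values, atol=1e-12)
        # swapping two stimuli within a rank changes nothing
        i, j = np.nonzero(stimuli32.ranks == 3)[0][:2]
        X = encoded32.values.copy()
        X[[i, j]] = X[[j, i]]
        rsm_s = rank_rsm(ResponseMatrix(values=X), stimuli32.ranks)
        np.testing.assert_allclose(rsm.values, rsm_s.values, atol=1e-12)


class TestJudgmentRSM:
    def test_equal_proportions_give_all_ones(self):
        # two objects per rank, each winning exactly once within its pair
        ind = np.zeros((8, 8), int)
        for a in range(0, 8, 2):
            ind[a, a + 1] = 1
        for a in range(8):
            for b in range(8):
                if a != b and ind[a, b] == 0 and ind[b, a] == 0:
                    ind[min(a, b), max(a, b)] = 1
        from sizeaxis.synthetic import JudgmentMatrix
        j = JudgmentMatrix(indicator=ind, n_objects=8)
        # use one rank so the rank proportion is a single mean
        rsm = judgment_rsm(j, np.ones(8, int) * 1, denom=8)
        assert np.allclose(rsm.values, 1.0)

    def test_noiseless_rank_proportions_increase(self, stimuli48):
        j = generate_pairwise_judgments(stimuli48.sizes_cm, weber_noise=0.0, seed=0)
        from sizeaxis.rsa import proportional_values
        prop = proportional_values(j)
        rank_prop = [prop[stimuli48.ranks == r].mean() for r in range(1, 9)]
        assert np.all(np.diff(rank_prop) > 0)

    def test_entry_formula_direct_substitution(self):
        """Prop difference 0.8 with denominator 8 gives 1 - 0.1 = 0.9."""
        from sizeaxis.synthetic import JudgmentMatrix
        n = 10
        sizes = np.concatenate([np.ones(5), np.full(5, 100.0)])
        j = generate_pairwise_judgments(sizes, 0.0, seed=0)
        ranks = np.concatenate([np.ones(5, int), np.full(5, 2, int)])
        rsm = judgment_rsm(j, ranks, denom=8)
        prop_small = j.indicator[:5].sum() / (5 * n)
        prop_big = j.indicator[5:].sum() / (5 * n)
        expected = 1 - abs(prop_big - prop_small) / 8
        assert rsm.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_range_denominator_variant(self, stimuli48):
        j = generate_pairwise_judgments(stimuli48.sizes_cm, 0.0, seed=0)
        rsm = judgment_rsm(j, stimuli48.ranks, denom="range")
        assert rsm.values.min() == pytest.approx(0.0, abs=1e-12)


class TestCorrespondence:
    def test_self_correlation_is_one(self, encoded32, stimuli32):
        rsm = rank_rsm(encoded32, stimuli32.ranks)
        assert rsm_correspondence(rsm, rsm) == pytest.approx(1.0)

    def test_affine_reversal_is_minus_one(self):
        ideal = ideal_observer_rsm(8)
        rev = RankRSM(values=2.0 - ideal.values, n_ranks=8, kind="response")
        assert rsm_correspondence(rev, ideal) == pytest.approx(-1.0)

    def test_matches_manual_pearson_to_1e12(self):
        rng = rng_from(3, "rsm")
        a = rng.random((8, 8))
        a = (a + a.T) / 2
        b = rng.random((8, 8))
        b = (b + b.T) / 2
        ra = RankRSM(values=a, n_ranks=8, kind="response")
        rb = RankRSM(values=b, n_ranks=8, kind="response")
        iu = np.triu_indices(8, 1)
        x, y = a[iu], b[iu]
        manual = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert rsm_correspondence(ra, rb) == pytest.approx(manual, abs=1e-12)
        assert len(x) == 28

    def test_constant_triangle_is_undefined(self):
        const = RankRSM(values=np.ones((4, 4)), n_ranks=4, kind="response")
        with pytest.raises(UndefinedStatisticError):
            rsm_correspondence(const, ideal_observer_rsm(4))

    def test_rank_count_mismatch(self):
        with pytest.raises(DimensionError):
            rsm_correspondence(ideal_observer_rsm(4), ideal_observer_rsm(5))


class TestPlantedAndNullCorrespondence:
    def test_noiseless_planted_correspondence_is_high(self):
        """Strong noiseless planted axis: R > 0.6 in all of 20 seeds.  (A
        Pearson-RSM of a 1-D code saturates near 0.8 — similarity becomes
        sign-like at large gain — so the ceiling is structural.)"""
        from sizeaxis import generate_planted_activations, generate_size_stimuli
        from sizeaxis.synthetic import PlantedGroundTruth
        from sizeaxis._utils import child_seed
        ideal = ideal_observer_rsm(8)
        for seed in range(20):
            stim = generate_size_stimuli(seed=child_seed(seed, "ns"), image_px=32)
            truth = PlantedGroundTruth.default(64, 10, seed=child_seed(seed, "nt"),
                                               beta=2.0, noise_sd=0.0)
            resp = generate_planted_activations(stim, 64, truth,
                                                seed=child_seed(seed, "na"))
            assert rsm_correspondence(rank_rsm(resp, stim.ranks), ideal) > 0.6

    def test_shuffled_images_sit_inside_permutation_band(self):
        """Responses to pixel-shuffled stimuli carry no size information:
        the observed correspondence falls inside the rank-permutation 95%
        band in at least 8 of 10 seeds."""
        from sizeaxis import build_encoder, encode, generate_size_stimuli
        from sizeaxis.transforms import transform_stimuli
        from sizeaxis._utils import rng_from
        ideal = ideal_observer_rsm(8)
        inside = 0
        for seed in range(10):
            stim = generate_size_stimuli(seed=seed, image_px=32)
            enc = build_encoder(image_px=32, seed=500 + seed)
            resp = encode(enc, transform_stimuli(stim, "shuffle", seed=seed))
            obs = rsm_correspondence(rank_rsm(resp, stim.ranks), ideal)
            rng = rng_from(seed, "band")
            null = [rsm_correspondence(rank_rsm(resp, rng.permutation(stim.ranks)),
                                       ideal) for _ in range(200)]
            lo, hi = np.quantile(null, [0.025, 0.975])
            inside += (lo <= obs <= hi)
        assert inside >= 8
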