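"""RDM construction against brute-force oracles, the RDM-RDM correlation
map, and Mantel permutation inference."""

import numpy as np
import pandas as pd
import pytest

from svamech.alff import ALFFMaps
from svamech.isrsa import (
    RDM,
    behavioral_rdm,
    isrsa_map,
    lower_triangle,
    mantel_permutation,
    neural_rdm,
    _pattern_corr_rdm,
)


def _maps_from_patterns(patterns_by_parcel, subject_ids=None):
    """Stack (subjects x voxels) pattern matrices into an ALFFMaps stand-in."""
    arr = np.stack(patterns_by_parcel, axis=1)
    sids = subject_ids or list(range(arr.shape[0]))
    return ALFFMaps(values=arr.astype(float), band=(0.01, 0.1),
                    subject_ids=list(sids))


class TestBehavioralRDM:
    def test_identical_vectors_distance_zero(self):
        items = np.tile([1, 4, 2, 6], (3, 1))
        rdm = behavioral_rdm(items)
        assert np.allclose(rdm.matrix, 0)

    def test_unit_shift_over_ten_items_gives_sqrt_ten(self):
        items = np.vstack([np.ones(10), np.full(10, 2)])
        rdm = behavioral_rdm(items)
        assert rdm.matrix[1, 0] == pytest.approx(np.sqrt(10))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        items = rng.integers(1, 7, size=(20, 10)).astype(float)
        rdm = behavioral_rdm(items)
        for i in range(20):
            for j in range(20):
                d = np.sqrt(((items[i] - items[j]) ** 2).sum())
                assert rdm.matrix[i, j] == pytest.approx(d, abs=1e-12)

    def test_missing_items_exclude_subject_with_warning(self):
        items = pd.DataFrame(np.ones((4, 5)))
        items.iloc[2, 3] = np.nan
        with pytest.warns(UserWarning, match="excluding"):
            rdm = behavioral_rdm(items)
        assert rdm.n == 3 and 2 not in rdm.subject_ids


class TestNeuralRDM:
    def test_self_dissimilarity_zero_and_negation_two(self):
        rng = np.random.default_rng(1)
        pat = rng.standard_normal(30)
        maps = _maps_from_patterns([np.vstack([pat, pat, -pat])])
        rdm = neural_rdm(maps, 0)
        assert rdm.matrix[1, 0] == pytest.approx(0, abs=1e-12)
        assert rdm.matrix[2, 0] == pytest.approx(2, abs=1e-12)

    def test_matches_pairwise_correlation_oracle(self):
        rng = np.random.default_rng(2)
        patterns = rng.standard_normal((15, 30))
        rdm = neural_rdm(_maps_from_patterns([patterns]), 0)
        for i in range(15):
            for j in range(15):
                expected = 0 if i == j else 1 - np.corrcoef(patterns[i], patterns[j])[0, 1]
                assert rdm.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_entries_within_zero_two(self, alff_small):
        maps, _, _ = alff_small
        for parcel in range(maps.n_parcels):
            m = neural_rdm(maps, parcel).matrix
            assert (m >= -1e-12).all() and (m <= 2 + 1e-12).all()

    def test_zero_variance_pattern_signalled(self):
        patterns = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            neural_rdm(_maps_from_patterns([patterns]), 0)


class TestRDMContainer:
    def test_lower_triangle_length_and_diagonal_exclusion(self):
        n = 9
        m = np.abs(np.random.default_rng(3).standard_normal((n, n)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        v = lower_triangle(m)
        assert len(v) == n * (n - 1) // 2
        i, j = np.tril_indices(n, k=-1)
        assert not np.any(i == j)  # diagonal never enters the vector
        rdm = RDM(matrix=m, metric="euclidean", subject_ids=list(range(n)))
        assert rdm.n == n

    def test_asymmetric_or_nonzero_diagonal_rejected(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            RDM(matrix=bad, metric="euclidean", subject_ids=[0, 1])
        bad2 = np.array([[1.0, 0], [0, 0]])
        with pytest.raises(ValueError, match="diagonal"):
            RDM(matrix=bad2, metric="euclidean", subject_ids=[0, 1])


class TestISRSAMap:
    def test_neural_equal_behavioral_gives_r_one(self):
        rng = np.random.default_rng(4)
        patterns = rng.standard_normal((12, 20))
        maps = _maps_from_patterns([patterns])
        behav = RDM(matrix=_pattern_corr_rdm(patterns), metric="one_minus_pearson",
                    subject_ids=maps.subject_ids)
        res = isrsa_map(behav, maps)
        assert res["r"].iloc[0] == pytest.approx(1.0)
        assert res["p_bonferroni"].iloc[0] == pytest.approx(res["p_raw"].iloc[0])

    def test_subject_order_mismatch_is_hard_error(self):
        rng = np.random.default_rng(5)
        patterns = rng.standard_normal((8, 10))
        maps = _maps_from_patterns([patterns], subject_ids=list("abcdefgh"))
        behav = behavioral_rdm(rng.integers(1, 7, (8, 10)).astype(float),
                               subject_ids=list("abcdefgH"))
        with pytest.raises(ValueError, match="subject order"):
            isrsa_map(behav, maps)

    def test_consistent_subject_permutation_leaves_r_unchanged(self):
        rng = np.random.default_rng(6)
        items = rng.integers(1, 7, (15, 10)).astype(float)
        patterns = [rng.standard_normal((15, 12)) for _ in range(3)]
        maps = _maps_from_patterns(patterns)
        res = isrsa_map(behavioral_rdm(items), maps)
        perm = rng.permutation(15)
        maps_p = _maps_from_patterns([p[perm] for p in patterns])
        res_p = isrsa_map(behavioral_rdm(items[perm]), maps_p)
        np.testing.assert_allclose(res["r"], res_p["r"], atol=1e-12)

    def test_planted_pattern_coupling_ranks_top(self, alff_small):
        maps, _, profile = alff_small
        behav = behavioral_rdm(profile, subject_ids=maps.subject_ids)
        res = isrsa_map(behav, maps)
        top2 = set(res.sort_values("r", ascending=False)["parcel"].head(2))
        assert top2 == {2, 9}

    def test_bonferroni_is_capped_product(self, alff_small):
        maps, _, profile = alff_small
        behav = behavioral_rdm(profile, subject_ids=maps.subject_ids)
        res = isrsa_map(behav, maps)
        np.testing.assert_allclose(
            res["p_bonferroni"], np.minimum(1, maps.n_parcels * res["p_raw"]))


class TestMantel:
    @staticmethod
    def _two_rdms(seed, n=20):
        rng = np.random.default_rng(seed)
        a = behavioral_rdm(rng.standard_normal((n, 8)))
        b = behavioral_rdm(rng.standard_normal((n, 8)))
        return a, b

    def test_identical_rdms_give_minimal_p(self):
        a, _ = self._two_rdms(0)
        r, p = mantel_permutation(a, a, n_perm=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_fixed_seed_reproducible(self):
        a, b = self._two_rdms(1)
        out1 = mantel_permutation(a, b, n_perm=199, seed=2)
        out2 = mantel_permutation(a, b, n_perm=199, seed=2)
        assert out1 == out2

    def test_observed_statistic_matches_pearson_on_triangles(self):
        a, b = self._two_rdms(2)
        r, _ = mantel_permutation(a, b, n_perm=99, seed=3)
        expected = np.corrcoef(lower_triangle(a.matrix), lower_triangle(b.matrix))[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_too_few_permutations_rejected(self):
        a, b = self._two_rdms(3)
        with pytest.raises(ValueError, match="99"):
            mantel_permutation(a, b, n_perm=50)

    def test_small_n_warns_about_permutation_space(self):
        rng = np.random.default_rng(4)
        a = behavioral_rdm(rng.standard_normal((4, 5)))
        b = behavioral_rdm(rng.standard_normal((4, 5)))
        with pytest.warns(UserWarning, match="distinct permutations"):
            mantel_permutation(a, b, n_perm=100, seed=0)
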