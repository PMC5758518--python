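"""PCA, VARIMAX, sparsity, similarity, pairing, cross-validated VAF."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from beamwalk import (ComponentSet, SegmentalDecomposition, covariance_pca,
                      crossfit_vaf, greedy_pair, group_vaf, hoyer_sparsity,
                      retain_components, similarity, varimax)
from beamwalk.anthropometry import SEGMENTS
from beamwalk.decomposition import DecompositionError


def _planted_matrix(rng, n_frames=4000, variances=(9.0, 4.0, 1.0), noise=0.0):
    """Data with orthonormal planted vectors weighted by orthogonal sinusoids."""
    t = np.arange(n_frames) / 100.0
    k = len(variances)
    freqs = 0.5 + 0.45 * np.arange(k)
    weights = np.sqrt(2.0 * np.asarray(variances)) * np.sin(
        2 * np.pi * freqs * t[:, None])
    basis, _ = np.linalg.qr(rng.normal(size=(14, k)))
    data = weights @ basis.T + rng.normal(0.0, noise, size=(n_frames, 14))
    return data, basis, np.asarray(variances)


class TestCovariancePCA:
    def test_rank_one_data(self, rng):
        u = rng.normal(size=14)
        u /= np.linalg.norm(u)
        amp = rng.normal(size=300)
        cs = covariance_pca(amp[:, None] * u)
        assert cs.vaf[0] == pytest.approx(100.0)
        assert abs(similarity(cs.loadings[:, 0], u)) == pytest.approx(1.0)

    def test_isotropic_noise_flat_spectrum(self, rng):
        cs = covariance_pca(rng.normal(size=(40000, 14)))
        np.testing.assert_allclose(cs.vaf, 100.0 / 14.0, atol=0.6)

    def test_planted_synergies_recovered(self, rng):
        data, basis, variances = _planted_matrix(rng, noise=0.05)
        cs = covariance_pca(data)
        pairing = greedy_pair(cs.loadings[:, :3], basis)
        assert all(s > 0.99 for _, _, s in pairing.pairs)
        expected = 100.0 * variances.sum() / (variances.sum() + 14 * 0.05**2)
        assert cs.cumulative_vaf[2] == pytest.approx(expected, abs=2.0)

    def test_insufficient_data_rejected(self):
        with pytest.raises(DecompositionError):
            covariance_pca(np.ones((1, 14)))

    def test_orthonormal_components_and_full_vaf(self, rng):
        cs = covariance_pca(rng.normal(size=(200, 14)))
        units = cs.unit_loadings()
        np.testing.assert_allclose(units.T @ units, np.eye(14), atol=1e-8)
        assert cs.vaf.sum() == pytest.approx(100.0)
        assert np.all(np.diff(cs.cumulative_vaf) >= -1e-12)


class TestRetainComponents:
    def _cs(self, vaf):
        vaf = np.asarray(vaf, dtype=float)
        loadings = np.zeros((14, vaf.size))
        loadings[:vaf.size, :] = np.eye(vaf.size) * np.sqrt(vaf)
        return ComponentSet(loadings=loadings, vaf=vaf, total_variance=100.0)

    def test_cumulative_crossing(self):
        cs = self._cs([90, 6, 2, 2])
        assert retain_components(cs, 95.0).n_components == 2

    def test_rank_one(self):
        assert retain_components(self._cs([100.0]), 95.0).n_components == 1

    def test_threshold_100_keeps_rank(self):
        cs = self._cs([50, 30, 20])
        assert retain_components(cs, 100.0).n_components == 3

    def test_bad_threshold(self):
        with pytest.raises(DecompositionError):
            retain_components(self._cs([100.0]), 0.0)


def _varimax_criterion(loadings):
    sq = loadings**2
    return float(np.sum(sq**2) / loadings.shape[0]
                 - np.sum((sq.sum(axis=0) / loadings.shape[0])**2))


class TestVarimax:
    def test_single_component_unchanged_up_to_sign(self, rng):
        cs = covariance_pca(rng.normal(size=(100, 14)))
        one = retain_components(cs, 1e-6)  # keeps K = 1
        rotated = varimax(one)
        np.testing.assert_allclose(np.abs(rotated.loadings),
                                   np.abs(one.loadings), atol=1e-12)

    def test_sparse_loadings_are_fixed_point(self):
        loadings = np.zeros((14, 2))
        loadings[2, 0] = 1.5
        loadings[7, 1] = 1.0
        cs = ComponentSet(loadings=loadings, vaf=np.array([60.0, 40.0]),
                          total_variance=(1.5**2 + 1.0) / 0.9)
        rotated = varimax(cs)
        pairing = greedy_pair(rotated, cs)
        assert all(s == pytest.approx(1.0, abs=1e-8) for _, _, s in pairing.pairs)

    def test_recovers_axis_aligned_pair_vs_angle_scan(self):
        sparse = np.zeros((6, 2))
        sparse[0, 0] = sparse[1, 0] = 1.0
        sparse[2, 1] = 1.0
        sparse[3, 1] = -1.0
        mix = np.array([[1.0, 1.0], [1.0, -1.0]]) / np.sqrt(2)
        mixed = sparse @ mix
        cs = ComponentSet(loadings=mixed, vaf=np.array([50.0, 50.0]),
                          total_variance=4.0, channel_names=tuple("abcdef"))
        rotated = varimax(cs)
        # independent oracle: brute-force scan of the planar rotation angle
        best_angle, best_value = None, -np.inf
        for phi in np.linspace(0, np.pi / 2, 20001):
            c, s = np.cos(phi), np.sin(phi)
            value = _varimax_criterion(mixed @ np.array([[c, -s], [s, c]]))
            if value > best_value:
                best_angle, best_value = phi, value
        assert _varimax_criterion(rotated.loadings) == pytest.approx(
            best_value, abs=1e-6)
        pairing = greedy_pair(rotated, sparse)
        assert all(s == pytest.approx(1.0, abs=1e-6) for _, _, s in pairing.pairs)
        assert rotated.sparsity().mean() > cs.sparsity().mean()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_subspace_and_vaf_conserved_sparsity_nondecreasing(self, seed):
        r = np.random.default_rng(seed)
        data, *_ = _planted_matrix(r, n_frames=1500,
                                   variances=(9.0, 4.0, 1.0), noise=0.2)
        retained = retain_components(covariance_pca(data), 95.0)
        rotated = varimax(retained)

        def projector(loadings):
            q, _ = np.linalg.qr(loadings)
            return q @ q.T

        np.testing.assert_allclose(projector(retained.loadings),
                                   projector(rotated.loadings), atol=1e-8)
        assert rotated.vaf.sum() == pytest.approx(retained.vaf.sum(), abs=1e-8)
        assert rotated.sparsity().mean() >= retained.sparsity().mean() - 1e-12


class TestHoyerSparsity:
    def test_single_nonzero_is_one(self):
        v = np.zeros(14)
        v[4] = 3.7
        assert hoyer_sparsity(v) == pytest.approx(1.0)

    def test_uniform_vector_is_zero(self):
        assert hoyer_sparsity(np.full(14, 0.25)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_n4(self):
        # l1 = 2, l2 = sqrt(2), N = 4 -> (2 - sqrt(2)) / 1
        assert hoyer_sparsity(np.array([1.0, 1.0, 0.0, 0.0])) == pytest.approx(
            2.0 - np.sqrt(2.0))

    def test_zero_vector_rejected(self):
        with pytest.raises(DecompositionError):
            hoyer_sparsity(np.zeros(14))

    @settings(max_examples=50, deadline=None)
    @given(hnp.arrays(np.float64, 14, elements=st.floats(-5, 5)))
    def test_bounded_and_scale_invariant(self, v):
        if np.linalg.norm(v) < 1e-6:
            return
        s = hoyer_sparsity(v)
        assert -1e-9 <= s <= 1.0 + 1e-9
        assert hoyer_sparsity(3.7 * v) == pytest.approx(s, abs=1e-9)


class TestSimilarity:
    def test_proportional_vectors(self):
        u = np.arange(1.0, 15.0)
        assert similarity(u, 2.5 * u) == pytest.approx(1.0)

    def test_orthogonal_unit_vectors(self):
        e1, e2 = np.eye(14)[:, 0], np.eye(14)[:, 1]
        assert similarity(e1, e2) == pytest.approx(0.0, abs=1e-15)

    def test_cos_45(self):
        assert similarity(np.array([1.0, 1.0]), np.array([1.0, 0.0])) == \
            pytest.approx(1.0 / np.sqrt(2.0))

    def test_zero_vector_rejected(self):
        with pytest.raises(DecompositionError):
            similarity(np.zeros(3), np.ones(3))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    def test_symmetric_bounded_scale_invariant(self, seed, scale):
        r = np.random.default_rng(seed)
        u, v = r.normal(size=14), r.normal(size=14)
        s = similarity(u, v)
        assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12
        assert similarity(v, u) == pytest.approx(s)
        assert similarity(scale * u, v) == pytest.approx(s)


def _exhaustive_assignment(a, b):
    """Best-sum assignment of |S| over all permutations (oracle)."""
    ka, kb = a.shape[1], b.shape[1]
    sim = np.array([[abs(similarity(a[:, i], b[:, j])) for j in range(kb)]
                    for i in range(ka)])
    small, large = (range(ka), range(kb)) if ka <= kb else (range(kb), range(ka))
    best, best_sum = None, -np.inf
    for perm in itertools.permutations(large, len(list(small))):
        total = sum(sim[i, j] if ka <= kb else sim[j, i]
                    for i, j in zip(small, perm))
        if total > best_sum:
            best_sum, best = total, set(
                (i, j) if ka <= kb else (j, i) for i, j in zip(small, perm))
    return best


class TestGreedyPair:
    def test_identical_sets(self, rng):
        a = rng.normal(size=(14, 4))
        pairing = greedy_pair(a, a.copy())
        assert pairing.mean == pytest.approx(1.0)
        assert all(i == j for i, j, _ in pairing.pairs)

    def test_permutation_and_sign_invariance(self, rng):
        a = rng.normal(size=(14, 4))
        perm = [2, 0, 3, 1]
        b = a[:, perm] * np.array([1, -1, 1, -1])
        pairing = greedy_pair(a, b)
        assert pairing.mean == pytest.approx(1.0)
        matched = {(i, j) for i, j, _ in pairing.pairs}
        assert matched == {(p, k) for k, p in enumerate(perm)}

    def test_rotated_basis_pair_cos30(self):
        a = np.eye(2)
        phi = np.pi / 6
        b = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        pairing = greedy_pair(a, b)
        assert all(s == pytest.approx(np.cos(phi)) for _, _, s in pairing.pairs)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_exhaustive_assignment_on_near_matched_sets(self, seed):
        r = np.random.default_rng(seed)
        k = int(r.integers(2, 6))
        a, _ = np.linalg.qr(r.normal(size=(14, k)))
        # b: same set, permuted, sign-flipped and mildly perturbed
        perm = r.permutation(k)
        b = a[:, perm] * r.choice([-1.0, 1.0], size=k)
        b = b + 0.1 * r.normal(size=b.shape)
        greedy = {(i, j) for i, j, _ in greedy_pair(a, b).pairs}
        assert greedy == _exhaustive_assignment(a, b)


class TestCrossfitVaf:
    def test_own_full_rank_components_give_100(self, rng):
        data = rng.normal(size=(300, 14))
        cs = covariance_pca(data)
        assert crossfit_vaf(cs, data) == pytest.approx(100.0, abs=1e-9)

    def test_orthogonal_components_give_0(self, rng):
        data = np.zeros((100, 14))
        data[:, 0] = rng.normal(size=100)
        components = np.zeros((14, 2))
        components[1, 0] = 1.0
        components[2, 1] = 1.0
        assert crossfit_vaf(components, data) == pytest.approx(0.0, abs=1e-9)

    def test_retained_components_match_cumulative_eigen_vaf(self, rng):
        data, *_ = _planted_matrix(rng, n_frames=2000, noise=0.3)
        cs = covariance_pca(data)
        retained = retain_components(cs, 95.0)
        k = retained.n_components
        assert crossfit_vaf(retained, data) == pytest.approx(
            float(cs.cumulative_vaf[k - 1]), abs=1e-9)


class TestGroupVaf:
    def test_all_variance_in_trunk(self):
        data = np.zeros((200, 14))
        data[:, SEGMENTS.index("Tr")] = np.sin(np.linspace(0, 20, 200))
        gv = group_vaf(data)
        assert gv["trunk"] == pytest.approx(100.0)
        for grp in ("head", "arms", "legs"):
            assert gv[grp] == pytest.approx(0.0, abs=1e-9)

    def test_independent_channels_split_by_count(self, rng):
        data = rng.normal(size=(60000, 14))
        gv = group_vaf(data)
        for grp, count in (("head", 1), ("trunk", 1), ("arms", 6), ("legs", 6)):
            assert gv[grp] == pytest.approx(100.0 * count / 14.0, abs=1.0)

    def test_variance_share_sums_to_100(self, rng):
        data = rng.normal(size=(500, 14)) * np.linspace(0.5, 2.0, 14)
        gv = group_vaf(data, method="variance_share")
        assert sum(gv.values()) == pytest.approx(100.0)

    def test_non_partition_rejected(self):
        with pytest.raises(DecompositionError, match="partition"):
            group_vaf(np.ones((10, 14)), groups={"all": SEGMENTS[:10]})


class TestModelObject:
    def test_fit_results_surface(self, rng):
        data, basis, _ = _planted_matrix(rng, noise=0.1)
        results = SegmentalDecomposition(data, SEGMENTS, label="demo").fit()
        assert results.n_components == 3
        scores = results.scores()
        recon = scores.scores @ results.components.loadings.T
        centered = data - data.mean(axis=0)
        vaf = 100 * (1 - ((centered - recon)**2).sum() / (centered**2).sum())
        assert vaf == pytest.approx(results.retained.vaf.sum(), abs=1e-6)
        text = results.summary()
        assert "retained K = 3" in text and "VARIMAX" in text
        assert results.crossfit(data) > 95.0

    def test_component_set_json_roundtrip(self, rng, tmp_path):
        data, *_ = _planted_matrix(rng, n_frames=500)
        cs = SegmentalDecomposition(data, SEGMENTS).fit().components
        path = tmp_path / "components.json"
        cs.to_json(path)
        back = ComponentSet.from_json(path)
        np.testing.assert_allclose(back.loadings, cs.loadings, atol=1e-12)
        np.testing.assert_allclose(back.vaf, cs.vaf, atol=1e-12)
        assert back.rotated == cs.rotated
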