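"""Habitat clustering: K-means, CH score, K selection, canonical parts."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from ivim_habitat.habitat import (VoxelVectorSet, assign_habitats,
                                  canonical_parts, ch_score, collect_vectors,
                                  habitat_summary, kmeans_fit, select_k,
                                  standardize)
from ivim_habitat.phantom import sample_vector_mixture

WELL_SEPARATED = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0], [4.0, 4.0]])


def _vector_set(x):
    return VoxelVectorSet(values=x, coords=np.zeros((x.shape[0], 3), dtype=int))


class TestCollectAndStandardize:
    def test_one_vector_per_mask_voxel(self, noiseless_phantom):
        _, _, mask, _, maps = noiseless_phantom
        vs = collect_vectors(maps, mask)
        assert vs.n == mask.n_voxels and vs.n_dropped == 0

    def test_nan_voxels_dropped_with_count(self, noiseless_phantom):
        _, _, mask, _, maps = noiseless_phantom
        d = maps.d.copy()
        coords = np.argwhere(mask.data)[:2]
        for c in coords:
            d[tuple(c)] = np.nan
        from dataclasses import replace
        maps2 = replace(maps, d=d)
        vs = collect_vectors(maps2, mask)
        assert vs.n == mask.n_voxels - 2 and vs.n_dropped == 2

    def test_values_match_map_lookup(self, noiseless_phantom):
        _, _, mask, _, maps = noiseless_phantom
        vs = collect_vectors(maps, mask)
        for i in (0, vs.n // 2, vs.n - 1):
            x, y, z = vs.coords[i]
            assert vs.values[i, 0] == maps.d[x, y, z]
            assert vs.values[i, 1] == maps.f[x, y, z]

    def test_standardize_population_convention(self):
        vs = _vector_set(np.array([[0.0, 0.0], [2.0, 2.0]]))
        z = standardize(vs)
        assert np.allclose(z.values, [[-1, -1], [1, 1]])

    def test_standardize_round_trip(self, rng):
        x = rng.normal(size=(50, 2))
        z = standardize(_vector_set(x))
        assert np.allclose(z.values * z.sd + z.mean, x, atol=1e-12)

    def test_zero_variance_rejected(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError):
            standardize(_vector_set(x))


class TestKmeans:
    def test_two_blob_identity(self, rng):
        x, lab = sample_vector_mixture(np.array([[0, 0], [10, 10]]), 0.1, 50, 1)
        _, pred, _ = kmeans_fit(x, 2, seed=0)
        assert adjusted_rand_score(lab, pred) == 1.0

    def test_exhaustive_partition_oracle(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 0.0]])
        centroids, labels, inertia = kmeans_fit(x, 2, seed=0)
        assert inertia == pytest.approx(1.0)
        got = {tuple(np.round(c, 6)) for c in centroids}
        assert got == {(0.5, 0.0), (10.5, 0.0)}

    def test_seed_determinism(self, rng):
        x = rng.normal(size=(200, 2))
        c1, l1, i1 = kmeans_fit(x, 3, seed=5)
        c2, l2, i2 = kmeans_fit(x, 3, seed=5)
        assert np.array_equal(c1, c2) and np.array_equal(l1, l2) and i1 == i2

    def test_k_exceeding_distinct_vectors_rejected(self):
        x = np.tile([[0.0, 0.0], [1.0, 1.0]], (5, 1))
        with pytest.raises(ValueError):
            kmeans_fit(x, 3, seed=0)


class TestChScore:
    def test_hand_computed_sums_of_squares(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 0.0]])
        labels = np.array([1, 1, 2, 2])
        # BSS = 2*(5^2) + 2*(5^2) = 100, WSS = 4*(0.5^2) = 1 -> (100/1)/(1/2)
        assert ch_score(x, labels) == pytest.approx(200.0)

    def test_point_mass_clusters_give_infinity(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        assert ch_score(x, np.array([1, 1, 2, 2])) == np.inf

    def test_true_labels_beat_random_labels(self, rng):
        x, lab = sample_vector_mixture(np.array([[0, 0], [6, 0]]), 1.0, 100, 2)
        random_labels = rng.integers(1, 3, size=x.shape[0])
        while np.unique(random_labels).size < 2:
            random_labels = rng.integers(1, 3, size=x.shape[0])
        assert ch_score(x, lab) > ch_score(x, random_labels)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        x, _ = sample_vector_mixture(WELL_SEPARATED, 1.0, 50, seed)
        _, labels, _ = kmeans_fit(x, 3, seed=seed)
        mine = ch_score(x, labels)
        ref = calinski_harabasz_score(x, labels)
        assert mine == pytest.approx(ref, rel=1e-10)


class TestSelectK:
    def test_recovers_planted_four_components(self):
        hits = 0
        for seed in range(20):
            x, _ = sample_vector_mixture(WELL_SEPARATED, 1.0, 200, seed)
            vs = standardize(_vector_set(x))
            model = select_k(vs, range(2, 9), seed=seed)
            hits += model.k == 4
        assert hits >= 18

    def test_planted_structure_produces_a_sharp_ch_peak(self, rng):
        """A 4-component mixture peaks sharply at K = 4; an unstructured
        Gaussian blob yields a flat CH curve with no comparable peak."""
        centers = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0], [5.0, 5.0]])
        x, _ = sample_vector_mixture(centers, 1.0, 100, 0)
        planted = select_k(standardize(_vector_set(x)), range(2, 7), seed=0)
        blob = select_k(standardize(_vector_set(rng.normal(size=(400, 2)))),
                        range(2, 7), seed=0)
        peak = max(planted.ch_curve.values()) / min(planted.ch_curve.values())
        flat = max(blob.ch_curve.values()) / min(blob.ch_curve.values())
        assert planted.k == 4
        assert peak > 2.0 > flat

    def test_score_curve_has_one_entry_per_k(self):
        x, _ = sample_vector_mixture(WELL_SEPARATED, 1.0, 50, 0)
        vs = standardize(_vector_set(x))
        model = select_k(vs, range(2, 7), seed=0)
        assert sorted(model.ch_curve) == [2, 3, 4, 5, 6]


class TestCanonicalParts:
    def test_reference_pattern(self):
        # low D / mid f, high D, high f, low D + low f (standardized units)
        centroids = np.array([
            [-0.5, 0.0],   # part 1
            [1.5, -0.5],   # part 2: max D
            [0.0, 1.5],    # part 3: max f
            [-1.0, -1.0],  # part 4: min D + f
        ])
        assert list(canonical_parts(centroids)) == [1, 2, 3, 4]

    def test_order_invariance(self, rng):
        centroids = np.array([[-0.5, 0.0], [1.5, -0.5], [0.0, 1.5], [-1.0, -1.0]])
        perm = rng.permutation(4)
        base = canonical_parts(centroids)
        shuffled = canonical_parts(centroids[perm])
        assert np.array_equal(shuffled, base[perm])

    def test_k3_lexicographic_fallback(self):
        centroids = np.array([[1.0, 0.0], [-1.0, 0.5], [0.0, -0.5]])
        assert list(canonical_parts(centroids)) == [3, 1, 2]


class TestAssignAndSummary:
    def test_assignment_matches_bruteforce_nearest_centroid(self, snr50_phantom):
        _, _, mask, _, maps = snr50_phantom
        vs = standardize(collect_vectors(maps, mask))
        model = select_k(vs, [4], seed=0)
        label_map = assign_habitats(maps, mask, model)
        z = (collect_vectors(maps, mask).values - model.mean) / model.sd
        d2 = ((z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
        expected = model.part_of_cluster[np.argmin(d2, axis=1)]
        assert np.array_equal(label_map[mask.data], expected)
        assert np.array_equal(label_map > 0, mask.data)

    def test_label_recovery_on_planted_mixture(self):
        centers = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0], [5.0, 5.0]])
        x, lab = sample_vector_mixture(centers, 1.0, 300, 3)
        _, pred, _ = kmeans_fit(x, 4, seed=0)
        assert adjusted_rand_score(lab, pred) >= 0.9

    def test_noiseless_pipeline_recovers_layout_exactly(self, noiseless_phantom):
        _, _, mask, truth, maps = noiseless_phantom
        vs = standardize(collect_vectors(maps, mask))
        _, pred, _ = kmeans_fit(vs.values, 4, seed=0)
        assert adjusted_rand_score(truth.labels[mask.data], pred) == 1.0

    def test_summary_fractions(self):
        label_map = np.zeros((10, 10, 1), dtype=int)
        label_map[:5, :5, 0] = 1
        label_map[5:, :5, 0] = 2
        label_map[:5, 5:, 0] = 3
        label_map[5:, 5:, 0] = 4
        s = habitat_summary(label_map, (1.0, 1.0, 1.0))
        assert np.allclose(s["volume_fraction"], 0.25)
        assert s["volume_mm3"].sum() == 100.0

    def test_missing_part_retained_with_zero(self):
        label_map = np.zeros((4, 4, 1), dtype=int)
        label_map[:2, :, 0] = 1
        label_map[2:, :, 0] = 3
        s = habitat_summary(label_map, (1.0, 1.0, 1.0), k=4)
        row = s[s["part"] == 2].iloc[0]
        assert row["volume_mm3"] == 0.0 and row["volume_fraction"] == 0.0
        assert s["volume_fraction"].sum() == pytest.approx(1.0, abs=1e-12)
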