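import warnings

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from habitomics.habitat import (
    EntropyMap,
    SuperpixelRecord,
    build_partition,
    ch_index,
    compare_subregions,
    local_entropy,
    patient_superpixels,
    population_clustering,
    select_k,
)
from habitomics.phantom import generate_cohort

from oracles import oracle_ch


class TestLocalEntropy:
    def test_constant_image_entropy_zero(self):
        img = np.full((20, 20), 7.0)
        em = local_entropy(img, np.ones((20, 20)))
        assert np.allclose(em.values, 0.0)

    def test_checkerboard_interior_value(self):
        # 9x9 window on a two-valued checkerboard: 41/81 vs 40/81 occupancy
        n = 17
        img = (np.indices((n, n)).sum(axis=0) % 2).astype(float)
        em = local_entropy(img, np.ones((n, n)), window=9, n_bins=2)
        expected = -(41 / 81 * np.log2(41 / 81) + 40 / 81 * np.log2(40 / 81))
        assert em.values[8, 8] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.99990, abs=1e-5)

    def test_entropy_bounded_by_log2_bins(self):
        rng = np.random.default_rng(0)
        img = rng.random((30, 30)) * 100
        for n_bins in (2, 8, 32):
            em = local_entropy(img, np.ones((30, 30)), n_bins=n_bins)
            assert em.values.max() <= np.log2(n_bins) + 1e-12

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            local_entropy(np.ones((5, 5)), np.ones((5, 5)), window=8)


def _records_from_points(points, case_id="c", n_pixels=10):
    return [
        SuperpixelRecord(
            case_id=case_id,
            slice_index=0,
            pixel_coords=np.zeros((n_pixels, 2), dtype=int),
            mean_intensity=float(p[0]),
            mean_entropy=float(p[1]),
        )
        for p in points
    ]


class TestPatientSuperpixels:
    @staticmethod
    def _blob_slice():
        rng = np.random.default_rng(0)
        img = np.zeros((20, 20))
        img[:10] = 10 + rng.normal(0, 0.1, (10, 20))
        img[10:] = 50 + rng.normal(0, 0.1, (10, 20))
        ent = np.zeros((20, 20))
        ent[:10] = 0.5
        ent[10:] = 3.0
        mask = np.ones((20, 20))
        return img, EntropyMap(values=ent, mask=mask.astype(bool), n_bins=32), mask

    def test_separable_blobs_recovered(self):
        img, em, mask = self._blob_slice()
        recs = patient_superpixels(img, em, mask, n_superpixels=2, seed=0)
        assert len(recs) == 2
        sizes = sorted(r.n_pixels for r in recs)
        assert sizes == [200, 200]
        means = sorted(r.mean_intensity for r in recs)
        assert means[0] == pytest.approx(10, abs=0.5)
        assert means[1] == pytest.approx(50, abs=0.5)

    def test_deterministic_given_seed(self):
        img, em, mask = self._blob_slice()
        a = patient_superpixels(img, em, mask, 4, seed=3)
        b = patient_superpixels(img, em, mask, 4, seed=3)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.pixel_coords, rb.pixel_coords)
            assert ra.mean_intensity == rb.mean_intensity

    def test_single_superpixel_mean_equals_roi_mean(self):
        img, em, mask = self._blob_slice()
        recs = patient_superpixels(img, em, mask, 1, seed=0)
        assert len(recs) == 1
        assert recs[0].mean_intensity == pytest.approx(img[mask == 1].mean())

    def test_more_clusters_than_pixels_rejected(self):
        img, em, mask = self._blob_slice()
        with pytest.raises(ValueError):
            patient_superpixels(img, em, mask, 500, seed=0)


class TestPopulationClustering:
    def test_separable_groups(self):
        recs = _records_from_points([(0, 0)] * 10 + [(10, 10)] * 10)
        labels = population_clustering(recs, 2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_k_equal_to_record_count(self):
        recs = _records_from_points([(i, i % 3) for i in range(6)])
        labels = population_clustering(recs, 6)
        assert len(set(labels.tolist())) == 6

    def test_duplication_invariance(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 0.3, (8, 2)), rng.normal(5, 0.3, (8, 2))])
        base = population_clustering(_records_from_points(pts), 2)
        doubled = population_clustering(_records_from_points(np.vstack([pts, pts])), 2)
        assert adjusted_rand_score(base, doubled[: len(pts)]) == 1.0
        assert adjusted_rand_score(doubled[: len(pts)], doubled[len(pts):]) == 1.0

    def test_k_exceeding_records_rejected(self):
        with pytest.raises(ValueError):
            population_clustering(_records_from_points([(0, 0), (1, 1)]), 3)


class TestChIndex:
    def test_hand_worked_1d_example(self):
        # B = 100, W = 1 -> CH = (100/1) / (1/2) = 200
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        labels = np.array([0, 0, 1, 1])
        assert ch_index(pts, labels) == pytest.approx(200.0, abs=1e-12)

    def test_zero_within_variance_returns_inf(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0], [5.0, 5.0], [9.0, 9.0]])
        labels = np.array([0, 0, 1, 1, 2])
        assert ch_index(pts, labels) == np.inf

    def test_true_labels_beat_random_labels(self):
        rng = np.random.default_rng(1)
        blob_a = rng.normal(0, 1, (25, 2))
        blob_b = rng.normal(8, 1, (25, 2))
        pts = np.vstack([blob_a, blob_b])
        true = np.repeat([0, 1], 25)
        rand = rng.permutation(true)
        assert ch_index(pts, true) > ch_index(pts, rand)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pts = rng.normal(0, 1, (30, 2))
            labels = rng.integers(0, 3, 30)
            if len(set(labels.tolist())) < 2:
                continue
            assert ch_index(pts, labels) == pytest.approx(
                oracle_ch(pts, labels), rel=1e-9
            )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            ch_index(np.arange(5.0), np.zeros(5, dtype=int))


class TestSelectK:
    @staticmethod
    def _blob_records(k_true, n_per, seed, spread=0.3):
        rng = np.random.default_rng(seed)
        centers = [(0, 0), (4, 4), (8, 0)][:k_true]
        pts = np.vstack(
            [rng.normal(c, spread, (n_per, 2)) for c in centers]
        )
        return _records_from_points(pts)

    @pytest.mark.parametrize("k_true", [2, 3])
    def test_recovers_planted_k_in_most_seeds(self, k_true):
        hits = 0
        for seed in range(20):
            recs = self._blob_records(k_true, 30, seed)
            k_star, _ = select_k(recs)
            hits += k_star == k_true
        assert hits >= 18  # >= 90% of seeds

    def test_ch_table_bookkeeping(self):
        recs = self._blob_records(2, 12, 0)
        _, ch_by_k = select_k(recs, k_min=2, k_max=10)
        assert sorted(ch_by_k) == list(range(2, 11))

    def test_few_records_lowers_k_max_with_warning(self):
        recs = self._blob_records(2, 4, 0)  # 8 records <= k_max
        with pytest.warns(UserWarning, match="lowering k_max"):
            k_star, ch_by_k = select_k(recs)
        assert max(ch_by_k) == len(recs) - 1
        assert k_star == 2


class TestBuildPartition:
    def test_zero_noise_separable_limit_perfect_recovery(self, flat_zero_noise_cases):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part = build_partition(flat_zero_noise_cases, seed=0)
        assert part.k == 2
        for case in flat_zero_noise_cases:
            m = case.mask.data.astype(bool)
            ari = adjusted_rand_score(case.truth_labels[m], part.labels[case.case_id][m])
            assert ari == 1.0

    def test_noisy_cohort_high_agreement_with_planted_habitats(self, small_cohort, small_partition):
        assert small_partition.k == 2
        aris = []
        for case in small_cohort.cases:
            m = case.mask.data.astype(bool)
            aris.append(
                adjusted_rand_score(
                    case.truth_labels[m], small_partition.labels[case.case_id][m]
                )
            )
        assert np.mean(aris) >= 0.8

    def test_s1_is_highest_entropy_subregion(self, small_cohort, small_partition):
        ent_means = {}
        for rank in range(1, small_partition.k + 1):
            vals = []
            for case in small_cohort.cases:
                sel = small_partition.labels[case.case_id] == rank
                if sel.any():
                    vals.append(small_partition.entropy_maps[case.case_id][sel].mean())
            ent_means[rank] = np.mean(vals)
        assert ent_means[1] == max(ent_means.values())

    def test_affine_rescaling_invariance(self, small_cohort):
        import copy

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = build_partition(small_cohort.cases, seed=5)
            rescaled_cases = copy.deepcopy(small_cohort.cases)
            for case in rescaled_cases:
                case.volume.data = case.volume.data * 3.7 + 55.0
            rescaled = build_partition(rescaled_cases, seed=5)
        assert base.k == rescaled.k
        for case in small_cohort.cases:
            m = case.mask.data.astype(bool)
            ari = adjusted_rand_score(
                base.labels[case.case_id][m], rescaled.labels[case.case_id][m]
            )
            assert ari == 1.0

    def test_single_case_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            build_partition(small_cohort.cases[:1])


class TestCompareSubregions:
    def test_planted_phantoms_s1_exceeds_s2(self):
        cohort = generate_cohort(20, effect_size=0.0, seed=21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part = build_partition(cohort.cases, seed=2)
        res = compare_subregions(part, cohort.cases)
        per = res["per_case"]
        assert per["S1_intensity"].mean() > per["S2_intensity"].mean()
        assert per["S1_entropy"].mean() > per["S2_entropy"].mean()
        assert res["intensity_p"] < 0.01
        assert res["entropy_p"] < 0.01

    def test_t_statistic_antisymmetric_under_label_swap(self, small_cohort, small_partition):
        a = compare_subregions(small_partition, small_cohort.cases, "S1", "S2")
        b = compare_subregions(small_partition, small_cohort.cases, "S2", "S1")
        assert a["intensity_t"] == pytest.approx(-b["intensity_t"], rel=1e-12)
        assert a["entropy_t"] == pytest.approx(-b["entropy_t"], rel=1e-12)
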