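"""RDMs, noise ceilings, RDM comparison, MDS, and the distance ratio."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from layerprobe.rsa import (
    BIN_DURATION_MS,
    NeuralRecording,
    NeuralUnit,
    RDM,
    compare_rdms,
    compute_rdm,
    embed_distances,
    load_recording_csv,
    load_recording_h5,
    mds_embed,
    neural_response_matrix,
    noise_ceiling,
    normalized_similarity,
    rdm_distance_ratio,
    rdm_from_csv,
    rdm_to_csv,
    save_recording_csv,
    save_recording_h5,
)


def _recording(n_units=5, n_bins=12, n_reps=4, noise=0.0, seed=0, latencies=None, pad=0):
    rng = np.random.default_rng(seed)
    signal = rng.uniform(1, 10, size=(n_units, n_bins))
    rates = np.repeat(signal[:, :, None], n_reps, axis=2)
    if pad:
        rates = np.concatenate([np.ones((n_units, pad, n_reps)), rates], axis=1)
    if noise:
        rates = rates + rng.normal(0, noise, rates.shape)
    lat = latencies if latencies is not None else [0.0] * n_units
    units = [NeuralUnit(id=f"u{i}", area="V1", latency_ms=lat[i]) for i in range(n_units)]
    return NeuralRecording(units=units, rates=rates, bin_labels=[f"b{i}" for i in range(n_bins)])


class TestResponseMatrix:
    def test_shape_is_bins_by_units(self):
        M = neural_response_matrix(_recording())
        assert M.shape == (12, 5)

    def test_columns_are_standardized(self):
        M = neural_response_matrix(_recording(noise=0.3, seed=2))
        assert np.abs(M.mean(axis=0)).max() < 1e-12
        assert np.allclose(M.std(axis=0), 1.0)

    def test_constant_unit_becomes_zero_column(self):
        rec = _recording()
        rec.rates[2] = 4.2
        M = neural_response_matrix(rec)
        assert np.all(M[:, 2] == 0.0)

    def test_zero_latency_prealigned_rates_equal_plain_bin_means(self):
        rec = _recording(noise=0.0)
        M = neural_response_matrix(rec)
        means = rec.rates.mean(axis=2).T
        expected = (means - means.mean(axis=0)) / means.std(axis=0)
        assert np.allclose(M, expected)

    def test_one_bin_latency_shifts_the_window(self):
        # the same signal padded by one leading bin, read with a one-bin
        # latency, reproduces the unshifted response matrix
        plain = neural_response_matrix(_recording(seed=5))
        lagged = _recording(seed=5, pad=1, latencies=[BIN_DURATION_MS] * 5)
        assert np.allclose(neural_response_matrix(lagged), plain)

    def test_latency_beyond_time_axis_rejected(self):
        rec = _recording(latencies=[3 * BIN_DURATION_MS] * 5)
        with pytest.raises(ValueError, match="latency"):
            neural_response_matrix(rec)


class TestComputeRDM:
    def test_hand_computed_three_row_example(self):
        M = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [1.0, 3.0, 2.0]])
        rdm = compute_rdm(M, labels=["r1", "r2", "r3"])
        assert rdm.values[0, 1] == pytest.approx(2.0)
        assert rdm.values[0, 2] == pytest.approx(0.5)
        assert rdm.values[1, 2] == pytest.approx(1.5)
        assert np.all(np.diag(rdm.values) == 0.0)

    def test_duplicate_rows_have_zero_dissimilarity(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(10)
        rdm = compute_rdm(np.vstack([row, row, rng.standard_normal(10)]))
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_row_has_dissimilarity_two(self):
        rng = np.random.default_rng(1)
        row = rng.standard_normal(10)
        rdm = compute_rdm(np.vstack([row, -row, rng.standard_normal(10)]))
        assert rdm.values[0, 1] == pytest.approx(2.0)

    def test_row_affine_transform_with_positive_slope_is_invisible(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((6, 20))
        M2 = M * rng.uniform(0.5, 3.0, size=(6, 1)) + rng.uniform(-2, 2, size=(6, 1))
        assert np.allclose(compute_rdm(M).values, compute_rdm(M2).values, atol=1e-12)

    def test_constant_row_error_names_the_row(self):
        M = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        with pytest.raises(ValueError, match="row0"):
            compute_rdm(M, labels=["row0", "row1", "row2"])


class TestCompareRDMs:
    def _rdm(self, seed=0, n=8):
        return compute_rdm(np.random.default_rng(seed).standard_normal((n, 15)))

    def test_self_comparison_is_one(self):
        r = self._rdm()
        assert compare_rdms(r, r) == pytest.approx(1.0)

    def test_monotone_transform_of_entries_keeps_rho_one(self):
        r = self._rdm()
        transformed = RDM(values=np.exp(r.values) - 1.0, labels=r.labels)
        assert compare_rdms(r, transformed) == pytest.approx(1.0)

    def test_matches_brute_force_rank_correlation(self):
        a, b = self._rdm(1), self._rdm(2)
        iu = np.triu_indices(8, k=1)
        expected = spearmanr(a.values[iu], b.values[iu]).statistic
        assert abs(compare_rdms(a, b) - expected) < 1e-12

    def test_label_mismatch_rejected(self):
        a = compute_rdm(np.random.default_rng(0).standard_normal((4, 6)), labels=list("abcd"))
        b = compute_rdm(np.random.default_rng(1).standard_normal((4, 6)), labels=list("abce"))
        with pytest.raises(ValueError, match="labels"):
            compare_rdms(a, b)


class TestNoiseCeiling:
    def test_noiseless_repetitions_give_ceiling_exactly_one(self):
        nc = noise_ceiling(_recording(noise=0.0), n_splits=20, seed=0)
        assert nc.value == pytest.approx(1.0)

    def test_spearman_brown_closed_form(self):
        # mean split-half r of 0.5 must become 2*0.5/1.5 = 2/3
        assert 2 * 0.5 / (1 + 0.5) == pytest.approx(2 / 3)
        # construct a population whose empirical mean split-half r is then
        # mapped through the same closed form
        rec = _recording(noise=2.0, seed=3, n_reps=6)
        nc = noise_ceiling(rec, n_splits=50, seed=1)
        # recompute expected from the same split stream
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(50):
            perm = rng.permutation(6)
            a = compute_rdm(neural_response_matrix(rec, perm[:3]), rec.bin_labels)
            b = compute_rdm(neural_response_matrix(rec, perm[3:]), rec.bin_labels)
            rs.append(spearmanr(a.upper, b.upper).statistic)
        r = np.mean(rs)
        assert nc.value == pytest.approx(2 * r / (1 + r), abs=1e-12)

    def test_ceiling_decreases_with_trial_noise(self):
        means = []
        for noise in (0.5, 2.0, 6.0):
            vals = [noise_ceiling(_recording(noise=noise, seed=s, n_reps=6),
                                  n_splits=30, seed=s).value for s in range(20)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_single_repetition_rejected(self):
        with pytest.raises(ValueError):
            noise_ceiling(_recording(n_reps=1))


class TestNormalizedSimilarity:
    def test_divides_by_the_ceiling(self):
        a = compute_rdm(np.random.default_rng(0).standard_normal((6, 9)))
        assert normalized_similarity(a, a, 0.8) == pytest.approx(1.0 / 0.8)

    def test_noiseless_neural_rdm_from_model_features_scores_one(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((10, 8))
        model = compute_rdm(M)
        neural = compute_rdm(M.copy())
        assert normalized_similarity(model, neural, 1.0) == pytest.approx(1.0)

    def test_nonpositive_ceiling_rejected(self):
        a = compute_rdm(np.random.default_rng(0).standard_normal((4, 9)))
        with pytest.raises(ValueError):
            normalized_similarity(a, a, 0.0)


class TestMDS:
    def test_equal_distances_embed_as_an_equilateral_triangle(self):
        D = np.full((3, 3), 0.5)
        np.fill_diagonal(D, 0.0)
        X = embed_distances(D, dims=2, seed=0)
        d = sorted(np.linalg.norm(X[i] - X[j]) for i, j in ((0, 1), (0, 2), (1, 2)))
        assert d[2] / d[0] == pytest.approx(1.0, abs=1e-3)

    def test_duplicate_rdms_land_on_coincident_points(self):
        rng = np.random.default_rng(0)
        base = [compute_rdm(rng.standard_normal((8, 30))) for _ in range(3)]
        X = mds_embed([base[0], base[0], base[1], base[2]], dims=2, seed=0)
        scale = np.abs(X).max()
        assert np.linalg.norm(X[0] - X[1]) < 1e-6 * max(scale, 1.0) + 1e-6

    def test_one_row_of_coordinates_per_rdm(self):
        rng = np.random.default_rng(1)
        rdms = [compute_rdm(rng.standard_normal((6, 12))) for _ in range(5)]
        assert mds_embed(rdms, dims=2, seed=0).shape == (5, 2)

    def test_fewer_than_three_rdms_rejected(self):
        rng = np.random.default_rng(2)
        rdms = [compute_rdm(rng.standard_normal((6, 12))) for _ in range(2)]
        with pytest.raises(ValueError):
            mds_embed(rdms, dims=2, seed=0)


class TestDistanceRatio:
    def _rdms(self, seeds, n=10):
        return [compute_rdm(np.random.default_rng(s).standard_normal((n, 12))) for s in seeds]

    def test_neural_identical_to_one_model_gives_ratio_below_one(self):
        m1 = self._rdms([1, 2])
        m2 = self._rdms([3, 4])
        neural = [m1[0]]
        ratio = rdm_distance_ratio(neural, {"m1": m1, "m2": m2})
        assert ratio < 1.0

    def test_matches_brute_force_recomputation(self):
        neural = self._rdms([0])
        groups = {"a": self._rdms([1, 2]), "b": self._rdms([3]), "c": self._rdms([4])}
        ratio = rdm_distance_ratio(neural, groups)
        num = np.mean([1 - compare_rdms(neural[0], m)
                       for g in groups.values() for m in g])
        den = np.mean([1 - compare_rdms(a, b)
                       for ga, gb in (("a", "b"), ("a", "c"), ("b", "c"))
                       for a in groups[ga] for b in groups[gb]])
        assert abs(ratio - num / den) < 1e-12

    def test_identical_rdms_everywhere_is_undefined(self):
        r = self._rdms([5])[0]
        with pytest.raises(ValueError, match="undefined|zero"):
            rdm_distance_ratio([r], {"a": [r], "b": [r]})

    def test_single_model_group_rejected(self):
        r = self._rdms([5])[0]
        with pytest.raises(ValueError):
            rdm_distance_ratio([r], {"a": [r]})


class TestRecordingIO:
    def test_hdf5_round_trip(self, tmp_path):
        rec = _recording(noise=0.4, seed=7, latencies=[0.0, 50.0, 100.0, 0.0, 25.0])
        save_recording_h5(rec, tmp_path / "rec.h5")
        back = load_recording_h5(tmp_path / "rec.h5")
        assert back.bin_labels == rec.bin_labels
        order = {u.id: i for i, u in enumerate(rec.units)}
        for i, u in enumerate(back.units):
            j = order[u.id]
            assert u.latency_ms == rec.units[j].latency_ms
            assert np.array_equal(back.rates[i], rec.rates[j])

    def test_csv_round_trip(self, tmp_path):
        rec = _recording(noise=0.4, seed=8)
        save_recording_csv(rec, tmp_path / "rec.csv")
        back = load_recording_csv(tmp_path / "rec.csv")
        assert back.bin_labels == rec.bin_labels
        assert np.allclose(back.rates, rec.rates)

    def test_rdm_csv_round_trip(self, tmp_path):
        rdm = compute_rdm(np.random.default_rng(0).standard_normal((5, 9)),
                          labels=[f"s{i}" for i in range(5)])
        rdm_to_csv(rdm, tmp_path / "rdm.csv")
        back = rdm_from_csv(tmp_path / "rdm.csv")
        assert back.labels == rdm.labels
        assert np.allclose(back.values, rdm.values)
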