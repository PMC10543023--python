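"""Grid projection, R-map fitting, fingerprint selection, LOO validation."""

import numpy as np
import pytest
import scipy.stats

from nstream.spatial import (
    ChannelPerformanceRecord,
    GridSpec,
    VoxelVolume,
    default_sensorimotor_grid,
    fit_decoding_network_map,
    leave_one_out_map_validation,
    project_to_grid,
    select_channel_by_fingerprint,
)
from nstream.synthetic import gen_fingerprint_cohort


def _point_grid(*points, max_dist=20.0):
    return GridSpec(points=np.array(points, dtype=float), max_dist_mm=max_dist)


class TestProjectToGrid:
    def test_single_channel_in_range_copies_value(self):
        grid = _point_grid([0, 0, 0])
        out = project_to_grid([7.0], [[5.0, 0, 0]], grid)
        assert out[0] == pytest.approx(7.0, abs=1e-12)

    def test_equidistant_pair_averages(self):
        grid = _point_grid([0, 0, 0])
        out = project_to_grid([0.0, 4.0], [[3, 0, 0], [-3, 0, 0]], grid)
        assert out[0] == pytest.approx(2.0, abs=1e-12)

    def test_inverse_distance_weights(self):
        # distances 1 mm and 3 mm -> weights 0.75 / 0.25 -> value 1.0
        grid = _point_grid([0, 0, 0])
        out = project_to_grid([0.0, 4.0], [[1, 0, 0], [3, 0, 0]], grid)
        assert out[0] == pytest.approx(1.0, abs=1e-12)

    def test_channel_exactly_at_grid_point(self):
        grid = _point_grid([0, 0, 0])
        out = project_to_grid([5.0, 9.0], [[0, 0, 0], [2, 0, 0]], grid)
        assert out[0] == 5.0

    def test_out_of_range_point_is_nan(self):
        grid = _point_grid([0, 0, 0], [100, 100, 100])
        out = project_to_grid([1.0], [[0, 0, 5]], grid)
        assert np.isfinite(out[0]) and np.isnan(out[1])

    def test_weights_sum_to_one_linearity_and_permutation(self, rng):
        grid = default_sensorimotor_grid()
        locs = grid.points[:10] + rng.normal(0, 5, size=(10, 3))
        v1 = rng.normal(size=10)
        v2 = rng.normal(size=10)
        p1 = project_to_grid(v1, locs, grid)
        p2 = project_to_grid(v2, locs, grid)
        p_sum = project_to_grid(v1 + v2, locs, grid)
        np.testing.assert_allclose(p_sum, p1 + p2, atol=1e-12, equal_nan=True)
        # constant input -> constant output wherever defined (weights sum to 1)
        p_const = project_to_grid(np.full(10, 3.3), locs, grid)
        finite = np.isfinite(p_const)
        np.testing.assert_allclose(p_const[finite], 3.3, atol=1e-12)
        perm = rng.permutation(10)
        p_perm = project_to_grid(v1[perm], locs[perm], grid)
        np.testing.assert_allclose(p_perm, p1, atol=1e-12, equal_nan=True)

    def test_default_grid_has_38_distinct_points(self):
        grid = default_sensorimotor_grid()
        assert grid.points.shape == (38, 3)


def _records_from(fps, perfs):
    return [
        ChannelPerformanceRecord(
            name=f"ch{i}",
            performance=None if p is None else float(p),
            fingerprint=VoxelVolume(data=fp),
        )
        for i, (fp, p) in enumerate(zip(fps, perfs))
    ]


class TestFitDecodingNetworkMap:
    def test_planted_voxel_recovered_with_perfect_correlation(self, rng):
        # oracle: direct per-voxel Spearman via scipy
        shape = (5, 5, 5)
        n = 12
        fps = rng.normal(size=(n, *shape))
        perfs = fps[:, 2, 2, 2].copy()
        records = _records_from(fps, perfs)
        rmap = fit_decoding_network_map(records)
        assert rmap.data[2, 2, 2] == pytest.approx(1.0)
        assert np.unravel_index(np.nanargmax(rmap.data), shape) == (2, 2, 2)
        for idx in [(0, 0, 0), (4, 1, 3), (2, 2, 2)]:
            expected = scipy.stats.spearmanr(fps[:, *idx], perfs).statistic
            assert rmap.data[idx] == pytest.approx(expected, abs=1e-12)

    def test_identical_performances_give_all_nan_map(self, rng):
        fps = rng.normal(size=(5, 3, 3, 3))
        rmap = fit_decoding_network_map(_records_from(fps, np.full(5, 0.7)))
        assert np.isnan(rmap.data).all()

    def test_negating_performances_negates_map(self, rng):
        fps = rng.normal(size=(8, 3, 3, 3))
        perfs = rng.normal(size=8)
        pos = fit_decoding_network_map(_records_from(fps, perfs), method="pearson")
        neg = fit_decoding_network_map(_records_from(fps, -perfs), method="pearson")
        np.testing.assert_allclose(neg.data, -pos.data, atol=1e-12)

    def test_spearman_invariant_to_monotone_performance_transform(self, rng):
        fps = rng.normal(size=(9, 3, 3, 3))
        perfs = rng.uniform(0.4, 0.9, size=9)
        base = fit_decoding_network_map(_records_from(fps, perfs))
        warped = fit_decoding_network_map(_records_from(fps, np.exp(5 * perfs)))
        np.testing.assert_allclose(warped.data, base.data, atol=1e-12)

    def test_too_few_records_or_mismatched_geometry_rejected(self, rng):
        fps = rng.normal(size=(2, 3, 3, 3))
        with pytest.raises(ValueError, match="3 records"):
            fit_decoding_network_map(_records_from(fps, [0.5, 0.6]))
        records = _records_from(rng.normal(size=(3, 3, 3, 3)), [0.5, 0.6, 0.7])
        records[2].fingerprint = VoxelVolume(data=rng.normal(size=(4, 4, 4)))
        with pytest.raises(ValueError, match="shape"):
            fit_decoding_network_map(records)


class TestSelectChannelByFingerprint:
    def test_exact_match_wins_with_similarity_one(self, rng):
        template = VoxelVolume(data=rng.normal(size=(4, 4, 4)))
        cands = _records_from(
            [rng.normal(size=(4, 4, 4)), template.data.copy()], [None, None]
        )
        chosen, scores = select_channel_by_fingerprint(template, cands)
        assert chosen.name == "ch1"
        assert scores["ch1"] == pytest.approx(1.0)

    def test_negated_template_never_beats_positive_candidate(self, rng):
        template = VoxelVolume(data=rng.normal(size=(4, 4, 4)))
        cands = _records_from(
            [-template.data, 0.5 * template.data + 0.1 * rng.normal(size=(4, 4, 4))],
            [None, None],
        )
        chosen, scores = select_channel_by_fingerprint(template, cands)
        assert chosen.name == "ch1"
        assert scores["ch0"] == pytest.approx(-1.0)

    def test_planted_best_channel_selected_in_95_percent_of_draws(self):
        hits = 0
        for seed in range(100):
            records, truth = gen_fingerprint_cohort(
                n_channels=8, snr=5.0, distinct_best=True, seed=seed
            )
            template = VoxelVolume(data=truth["planted_map"])
            chosen, _ = select_channel_by_fingerprint(template, records)
            hits += chosen.name == f"ch{truth['best_channel']:02d}"
        assert hits >= 95


class TestLeaveOneOutValidation:
    def test_deterministic_monotone_cohort_validates_strongly(self):
        records, _ = gen_fingerprint_cohort(
            n_channels=20, snr=10.0, perf_noise_sd=0.0,
            seed=11,
        )
        frame = leave_one_out_map_validation(records, unit="channel")
        assert frame.attrs["rho"] > 0.9

    def test_subject_unit_groups_channels(self):
        records, _ = gen_fingerprint_cohort(
            n_channels=16, channels_per_subject=4, snr=10.0, seed=2
        )
        frame = leave_one_out_map_validation(records, unit="subject")
        assert frame["unit"].nunique() == 4
        assert frame.attrs["rho"] > 0.8

    def test_shuffled_performances_collapse_to_chance(self):
        # a 20-subject (40-channel) null: the permutation distribution of a
        # rank correlation at this n has sd ~ 1/sqrt(39) ~ 0.16, so |rho|
        # stays small in the typical draw and near zero on average
        rhos = []
        n_seeds = 20
        for seed in range(n_seeds):
            records, _ = gen_fingerprint_cohort(
                n_channels=40, channels_per_subject=2, snr=5.0, seed=seed
            )
            rng = np.random.default_rng(seed + 500)
            perfs = rng.permutation([r.performance for r in records])
            for r, p in zip(records, perfs):
                r.performance = float(p)
            frame = leave_one_out_map_validation(records, unit="channel")
            rhos.append(frame.attrs["rho"])
        rhos = np.abs(rhos)
        assert np.mean(rhos < 0.3) >= 0.85
        assert np.median(rhos) < 0.2

    def test_template_never_sees_held_out_unit(self, rng):
        # leakage audit: perturbing the held-out fingerprint must leave the
        # template fitted on the others bit-identical
        records, _ = gen_fingerprint_cohort(n_channels=6, snr=5.0, seed=4)
        train = records[1:]
        before = fit_decoding_network_map(train).data.copy()
        records[0].fingerprint.data += 1e6
        after = fit_decoding_network_map(train).data
        np.testing.assert_array_equal(before, after)

    def test_three_units_rejected(self):
        records, _ = gen_fingerprint_cohort(n_channels=3, seed=0)
        with pytest.raises(ValueError, match="4 units"):
            leave_one_out_map_validation(records)

    def test_missing_subject_labels_rejected(self):
        records, _ = gen_fingerprint_cohort(n_channels=6, seed=0)
        records[0].subject = None
        with pytest.raises(ValueError, match="subject"):
            leave_one_out_map_validation(records, unit="subject")


class TestVoxelVolumeIO:
    def test_nifti_round_trip(self, tmp_path, rng):
        vol = VoxelVolume(data=rng.normal(size=(4, 5, 6)),
                          affine=np.diag([2.0, 2.0, 2.0, 1.0]))
        path = str(tmp_path / "vol.nii")
        vol.to_nifti(path)
        back = VoxelVolume.from_nifti(path)
        np.testing.assert_allclose(back.data, vol.data, atol=1e-12)
        np.testing.assert_allclose(back.affine, vol.affine)
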