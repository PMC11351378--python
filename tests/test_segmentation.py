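"""ROI cropping, local thresholding, object separation and metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from ligafib import (
    LabeledVolume,
    PhantomConfig,
    VoxelVolume,
    compute_metrics,
    crop_roi,
    filter_artifacts,
    generate_phantom,
    match_labels,
    niblack_threshold,
    orientation_sampler,
    read_volume,
    remove_speckle,
    separate_objects,
    truth_label_volume,
    write_volume,
)

VS = 0.009


def cylinder_mask(shape, centre, direction, radius, length, voxel=1.0):
    """Independent cylinder rasteriser for constructing binary inputs."""
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    pts = (np.stack(grids, -1) + 0.5) * voxel - np.asarray(centre)
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    t = pts @ d
    perp2 = np.einsum("...i,...i", pts, pts) - t * t
    return (perp2 <= radius**2) & (np.abs(t) <= length / 2)


class TestCropRoi:
    def test_protocol_roi_arithmetic(self):
        """A 4 mm ROI offset 1 mm in 9 um voxels spans round(4/0.009)=444
        slices starting at slice 111."""
        n_slices = int(round(24.0 / VS))
        vol = VoxelVolume(np.zeros((n_slices, 4, 4)), VS)
        out = crop_roi(vol, roi_length_mm=4.0, offset_mm=1.0)
        assert out.shape[0] == 444
        assert out.shape[1:] == (4, 4)

    def test_identity_crop(self):
        data = np.arange(5 * 3 * 3, dtype=float).reshape(5, 3, 3)
        vol = VoxelVolume(data, 1.0)
        out = crop_roi(vol, roi_length_mm=5.0, offset_mm=0.0)
        np.testing.assert_array_equal(out.data, data)

    def test_roi_exceeding_extent_rejected(self):
        vol = VoxelVolume(np.zeros((int(round(24 / VS)), 4, 4)), VS)
        with pytest.raises(ValueError):
            crop_roi(vol, roi_length_mm=30.0)
        with pytest.raises(ValueError):
            crop_roi(vol, roi_length_mm=4.0, offset_mm=21.0)


class TestNiblack:
    def test_constant_volume_all_background(self):
        vol = VoxelVolume(np.full((10, 10, 10), 37.0), VS)
        out = niblack_threshold(vol, window_radius=2, k=0.2)
        assert not out.data.any()

    def test_matches_per_voxel_oracle(self, rng):
        """5x5x5 volume, window covering everything: compare against a
        brute-force loop that recomputes mean + k*sd per voxel."""
        data = rng.uniform(0, 255, (5, 5, 5))
        vol = VoxelVolume(data, VS)
        k = 0.2
        got = niblack_threshold(vol, window_radius=4, k=k).data
        expected = np.zeros_like(data, dtype=bool)
        for i in range(5):
            for j in range(5):
                for l in range(5):
                    w = data  # window radius 4 covers the whole 5^3 volume
                    expected[i, j, l] = data[i, j, l] > w.mean() + k * w.std()
        np.testing.assert_array_equal(got, expected)

    def test_clipped_window_oracle_at_borders(self, rng):
        """Window radius 1: border statistics use only in-volume voxels."""
        data = rng.uniform(0, 255, (4, 4, 4))
        got = niblack_threshold(VoxelVolume(data, VS), window_radius=1, k=0.5).data
        expected = np.zeros_like(data, dtype=bool)
        for idx in np.ndindex(4, 4, 4):
            sl = tuple(slice(max(0, i - 1), min(4, i + 2)) for i in idx)
            w = data[sl]
            expected[idx] = data[idx] > w.mean() + 0.5 * w.std()
        np.testing.assert_array_equal(got, expected)

    def test_detects_phantom_fibers(self):
        """On the stated phantom contrast (fiber 200 / matrix 120 /
        background 5, noise 5), at least 95 % of true fiber voxels are
        foreground."""
        config = PhantomConfig(
            shape=(96, 96, 96),
            n_fibers=4,
            radius_range_mm=(0.035, 0.05),
            length_range_mm=(0.5, 0.7),
            intensity_matrix=120.0,
            noise_sd=5.0,
            matrix_radius_fraction=0.8,
            avoid_overlap=True,
            min_separation_mm=0.02,
            seed=21,
        )
        volume, truth = generate_phantom(config)
        fg = niblack_threshold(volume, window_radius=15, k=0.2).data
        truth_mask = truth_label_volume(truth, config.shape, VS) > 0
        assert fg[truth_mask].mean() >= 0.95

    def test_non_finite_rejected(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            niblack_threshold(VoxelVolume(data, VS))


class TestSeparateObjects:
    def test_two_disjoint_cylinders(self):
        mask = cylinder_mask((60, 40, 40), (30, 10, 10), (1, 0, 0), 5, 50)
        mask |= cylinder_mask((60, 40, 40), (30, 28, 28), (1, 0, 0), 5, 50)
        out = separate_objects(VoxelVolume(mask, VS), h=2.0)
        assert out.n_objects == 2

    def test_empty_foreground(self):
        out = separate_objects(VoxelVolume(np.zeros((8, 8, 8), bool), VS), h=2.0)
        assert out.n_objects == 0

    def test_fused_cylinders_split_at_neck(self):
        """Two parallel radius-6 cylinders with axes 11 voxels apart are
        fused along a thin neck (the distance-map saddle sits ~2 below the
        axis ridges); h = 3 must split the union into exactly 2 labels."""
        shape = (60, 34, 44)
        m1 = cylinder_mask(shape, (30, 16.5, 15.5), (1, 0, 0), 6, 50)
        m2 = cylinder_mask(shape, (30, 16.5, 26.5), (1, 0, 0), 6, 50)
        mask = m1 | m2
        # the union is a single connected component
        _, n_cc = ndi.label(mask, structure=np.ones((3, 3, 3)))
        assert n_cc == 1
        out = separate_objects(VoxelVolume(mask, VS), h=3.0, smooth_sigma=0.0)
        assert out.n_objects == 2

    def test_label_count_bounded_by_components(self, rng):
        blob = ndi.gaussian_filter(rng.standard_normal((40, 40, 40)), 3) > 0.05
        n_cc = ndi.label(blob, structure=np.ones((3, 3, 3)))[1]
        few = separate_objects(VoxelVolume(blob, VS), h=0.2, smooth_sigma=0.0)
        assert few.n_objects >= n_cc
        # h above the maximal distance value: pure connected components
        capped = separate_objects(VoxelVolume(blob, VS), h=1e3, smooth_sigma=0.0)
        assert capped.n_objects == n_cc

    def test_every_foreground_voxel_labeled(self, rng):
        blob = ndi.gaussian_filter(rng.standard_normal((30, 30, 30)), 2) > 0.1
        out = separate_objects(VoxelVolume(blob, VS), h=2.0)
        assert (out.labels > 0).sum() == blob.sum()
        labels = np.unique(out.labels)
        np.testing.assert_array_equal(labels, np.arange(out.n_objects + 1))

    def test_negative_h_rejected(self):
        with pytest.raises(ValueError):
            separate_objects(VoxelVolume(np.ones((4, 4, 4), bool), VS), h=-1.0)

    def test_remove_speckle(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[2:12, 2:7, 2:7] = True  # 250 voxels
        mask[15, 15, 15] = True  # speck
        out = remove_speckle(VoxelVolume(mask, VS), min_voxels=10)
        assert out.data.sum() == 250


class TestComputeMetrics:
    def make_labeled(self, mask):
        return LabeledVolume(mask.astype(np.int32), VS)

    def test_axis_aligned_cylinder(self):
        mask = cylinder_mask((210, 40, 40), (105.0, 20.2, 19.7), (1, 0, 0), 5, 200)
        rec = compute_metrics(self.make_labeled(mask)).iloc[0]
        assert rec.theta_deg <= 1.0
        assert rec.volume_mm3 == pytest.approx(mask.sum() * VS**3)
        assert rec.mean_cross_area_mm2 == pytest.approx(np.pi * (5 * VS) ** 2, rel=0.15)
        assert not rec.is_artifact

    def test_oblique_cylinder_angles(self):
        d = (np.cos(np.radians(45)), 0.0, np.sin(np.radians(45)))  # phi = 0 plane
        mask = cylinder_mask((80, 30, 80), (40.1, 15.2, 40.3), d, 4, 70)
        rec = compute_metrics(self.make_labeled(mask)).iloc[0]
        assert rec.theta_deg == pytest.approx(45.0, abs=2.0)
        phi_dist = min(rec.phi_deg, 180 - rec.phi_deg)
        assert phi_dist == pytest.approx(0.0, abs=2.0)

    def test_single_voxel_is_artifact(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        rec = compute_metrics(self.make_labeled(mask)).iloc[0]
        assert rec.is_artifact
        assert np.isnan(rec.theta_deg)

    def test_volume_conservation_across_objects(self, rng):
        blob = ndi.gaussian_filter(rng.standard_normal((40, 40, 40)), 2) > 0.1
        labeled = separate_objects(VoxelVolume(blob, VS), h=1.0)
        records = compute_metrics(labeled)
        assert records["n_voxels"].sum() == blob.sum()
        assert records["volume_mm3"].sum() == pytest.approx(blob.sum() * VS**3)

    def test_orientation_invariant_under_quarter_turn(self):
        d = (np.cos(np.radians(30)),
             np.sin(np.radians(30)) * np.sin(np.radians(40)),
             np.sin(np.radians(30)) * np.cos(np.radians(40)))
        mask = cylinder_mask((80, 80, 80), (40.3, 40.1, 39.8), d, 4, 60)
        rec = compute_metrics(self.make_labeled(mask)).iloc[0]
        rotated = np.rot90(mask, k=1, axes=(1, 2))
        rec_rot = compute_metrics(self.make_labeled(rotated)).iloc[0]
        assert rec_rot.theta_deg == pytest.approx(rec.theta_deg, abs=1.0)
        shift = abs(rec_rot.phi_deg - rec.phi_deg) % 180
        assert min(shift, 180 - shift) == pytest.approx(90.0, abs=1.0)


class TestFilterArtifacts:
    def records(self, rows):
        rows = [dict({"is_artifact": False}, **row) for row in rows]
        return pd.DataFrame(rows)

    def test_collapsed_rule_requires_both_angles(self):
        df = self.records(
            [
                dict(label=1, volume_mm3=1e-5, theta_deg=90.0, phi_deg=0.0),
                dict(label=2, volume_mm3=1e-5, theta_deg=90.0, phi_deg=45.0),
                dict(label=3, volume_mm3=1e-5, theta_deg=89.5, phi_deg=179.6),
                dict(label=4, volume_mm3=1e-5, theta_deg=45.0, phi_deg=0.0),
            ]
        )
        fibers, artifacts = filter_artifacts(df, angle_tol=1.0)
        assert sorted(artifacts["label"]) == [1, 3]  # phi near 0 mod 180
        assert sorted(fibers["label"]) == [2, 4]

    def test_fiber_fraction_reported(self, rng):
        rows = [
            dict(label=i, volume_mm3=1e-5, theta_deg=90.0, phi_deg=0.0)
            for i in range(25)
        ] + [
            dict(label=25 + i, volume_mm3=1e-5, theta_deg=30.0, phi_deg=60.0)
            for i in range(75)
        ]
        fibers, artifacts = filter_artifacts(self.records(rows))
        assert len(fibers) == 75 and len(artifacts) == 25
        assert fibers.attrs["fiber_fraction"] == pytest.approx(0.75)

    def test_flagged_and_zero_volume_excluded(self):
        df = self.records(
            [
                dict(label=1, volume_mm3=0.0, theta_deg=10.0, phi_deg=10.0),
                dict(label=2, volume_mm3=1e-5, theta_deg=np.nan, phi_deg=np.nan,
                     is_artifact=True),
                dict(label=3, volume_mm3=1e-5, theta_deg=10.0, phi_deg=10.0),
            ]
        )
        fibers, artifacts = filter_artifacts(df)
        assert list(fibers["label"]) == [3]


class TestEndToEnd:
    def test_small_phantom_chain_recovers_fibers(self):
        """Eight non-overlapping fibers at 128^3: at least 90 % matched
        one-to-one with theta error within 5 degrees."""
        config = PhantomConfig(
            shape=(128, 128, 128),
            n_fibers=8,
            radius_range_mm=(0.035, 0.05),
            length_range_mm=(0.7, 0.95),
            matrix_radius_fraction=0.8,  # ROI inside the specimen
            avoid_overlap=True,
            min_separation_mm=0.027,
            seed=13,
        )
        volume, truth = generate_phantom(config)
        binary = niblack_threshold(volume, window_radius=15, k=1.5)
        binary = remove_speckle(binary, 50)
        labeled = separate_objects(binary, h=2.0, smooth_sigma=1.0)
        records = compute_metrics(labeled)
        truth_labels = truth_label_volume(truth, config.shape, VS)
        matches = match_labels(truth_labels, labeled.labels)
        merged = matches.merge(
            truth, on="fiber_id"
        ).merge(records, left_on="matched_label", right_on="label")
        ok = 0
        seen = set()
        for row in merged.itertuples():
            if row.matched_label in seen or row.matched_label == 0:
                continue
            if abs(row.theta_deg - row.theta_true_deg) <= 5.0:
                ok += 1
                seen.add(row.matched_label)
        assert ok >= 0.9 * len(truth)


class TestTiffIO:
    def test_volume_round_trip(self, tmp_path, rng):
        data = rng.uniform(0, 255, (6, 5, 4))
        vol = VoxelVolume(data, VS)
        path = tmp_path / "vol.tif"
        write_volume(path, vol, seed=3)
        back = read_volume(path)
        np.testing.assert_allclose(back.data, data)
        assert back.voxel_size_mm == VS
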