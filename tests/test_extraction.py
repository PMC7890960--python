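import numpy as np
import pytest

from roikit.core import BinaryMask, Image, LabelMap, Spacing
from roikit.extraction import (
    connected_components,
    double_threshold_extract,
    fuzzy_distance_transform,
    gaussian_prefilter,
    multiscale_opening,
    size_filter,
    threshold_extract,
    watershed_flood,
)
from roikit.phantom import bridged_blobs_phantom, gradient_blobs_phantom

from conftest import best_match_jaccard
from oracles import fdt_oracle, flood_fill_components


class TestGaussianPrefilter:
    def test_sigma_zero_is_identity(self, rng, unit_spacing):
        values = rng.random((4, 4, 4))
        out = gaussian_prefilter(values, 0.0, unit_spacing)
        np.testing.assert_array_equal(out, values)

    def test_constant_image_unchanged(self, unit_spacing):
        out = gaussian_prefilter(np.full((6, 6, 6), 3.0), 2.0, unit_spacing)
        np.testing.assert_allclose(out, 3.0, rtol=1e-12)

    def test_impulse_matches_separable_gaussian(self, confocal_spacing):
        n = 15
        data = np.zeros((n, n, n))
        data[n // 2, n // 2, n // 2] = 1.0
        sigma_nm = 70.0  # 4-sigma support stays inside the grid
        out = gaussian_prefilter(data, sigma_nm, confocal_spacing)
        sigmas = sigma_nm / confocal_spacing.as_array()
        kernels = []
        for s in sigmas:
            radius = int(4.0 * s + 0.5)  # 4-sigma support, renormalized
            ax = np.arange(n) - n // 2
            k = np.where(np.abs(ax) <= radius, np.exp(-(ax**2) / (2 * s**2)), 0.0)
            kernels.append(k / k.sum())
        expected = np.einsum("i,j,k->ijk", *kernels)
        np.testing.assert_allclose(out, expected, atol=1e-6)


class TestConnectedComponents:
    def test_corner_touching_depends_on_connectivity(self, unit_spacing):
        member = np.zeros((2, 2, 2), bool)
        member[0, 0, 0] = member[1, 1, 1] = True
        mask = BinaryMask(member, unit_spacing)
        assert connected_components(mask, 26).component_count == 1
        assert connected_components(mask, 6).component_count == 2

    def test_size_then_index_label_order(self, unit_spacing):
        member = np.zeros((3, 6, 6), bool)
        member[0, 0, 3:6] = True  # size 3, later in linear order than...
        member[0, 0, 0] = True  # size 1, smallest linear index
        member[2, 4, 0:3] = True  # size 3, larger linear index
        lm = connected_components(BinaryMask(member, unit_spacing), 6)
        assert lm.component_count == 3
        # largest-first; equal sizes -> smaller first linear index wins
        assert lm.labels[0, 0, 3] == 1
        assert lm.labels[2, 4, 0] == 2
        assert lm.labels[0, 0, 0] == 3

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_partition_matches_flood_fill_oracle(self, rng, unit_spacing, connectivity):
        for _ in range(10):
            member = rng.random((6, 6, 6)) < 0.3
            lm = connected_components(BinaryMask(member, unit_spacing), connectivity)
            ours = {
                frozenset(map(tuple, np.argwhere(lm.labels == l)))
                for l in range(1, lm.component_count + 1)
            }
            assert ours == flood_fill_components(member, connectivity)

    def test_empty_mask(self, unit_spacing):
        lm = connected_components(BinaryMask(np.zeros((3, 3, 3), bool), unit_spacing))
        assert lm.component_count == 0


class TestSizeFilter:
    def _labels(self, unit_spacing):
        member = np.zeros((4, 10, 10), bool)
        member[0, :5, :10] = True  # 50
        member[2, 0, :10] = True  # 10
        member[3, 5, :3] = True  # 3
        return connected_components(BinaryMask(member, unit_spacing), 6)

    def test_min_zero_unchanged(self, unit_spacing):
        lm = self._labels(unit_spacing)
        out = size_filter(lm, 0)
        np.testing.assert_array_equal(out.labels, lm.labels)

    def test_threshold_filters_and_relabels(self, unit_spacing):
        lm = self._labels(unit_spacing)
        out = size_filter(lm, 10)
        assert out.component_count == 2
        np.testing.assert_array_equal(np.sort(out.sizes())[::-1], [50, 10])

    def test_all_removed(self, unit_spacing):
        out = size_filter(self._labels(unit_spacing), 1000)
        assert out.component_count == 0 and not (out.labels > 0).any()


class TestThresholdExtract:
    def test_bright_blob_manual_threshold(self, unit_spacing):
        data = np.zeros((5, 5, 5))
        data[2, 2, :5] = 9.0
        image = Image(data, unit_spacing)
        out = threshold_extract(image, threshold=1.0, min_size_voxels=1)
        assert out.labels.component_count == 1
        assert out.labels.sizes()[0] == 5
        assert out.provenance["realized_threshold"] == 1.0
        empty = threshold_extract(image, threshold=1.0, min_size_voxels=6)
        assert empty.labels.component_count == 0

    def test_two_blob_phantom_with_otsu_matches_truth(self, unit_spacing):
        data = np.zeros((8, 8, 16))
        data[2:5, 2:5, 2:5] = 100.0
        data[2:5, 2:5, 10:14] = 100.0
        image = Image(data, unit_spacing)
        out = threshold_extract(image, method="otsu", n_bins=64)
        assert out.labels.component_count == 2
        np.testing.assert_array_equal(out.labels.labels > 0, data > 0)


class TestFuzzyDistanceTransform:
    def test_constant_membership_background_mode_is_geodesic(self, confocal_spacing):
        mu = np.ones((4, 5, 6))
        region = np.ones((4, 5, 6), bool)
        seeds = np.zeros((4, 5, 6), bool)
        seeds[0, 0, 0] = True
        d = fuzzy_distance_transform(mu, seeds, region, "background", confocal_spacing).d
        # w = 1 (+eps): plain anisotropic geodesic distance via oracle
        expected = fdt_oracle(mu, seeds, region, "background", confocal_spacing.as_array())
        np.testing.assert_allclose(d, expected, atol=1e-9)
        assert d[0, 0, 1] == pytest.approx(70.0 * (1 + 1e-6))

    def test_constant_membership_object_mode_near_zero(self, unit_spacing):
        mu = np.ones((3, 3, 3))
        region = np.ones((3, 3, 3), bool)
        seeds = np.zeros((3, 3, 3), bool)
        seeds[1, 1, 1] = True
        d = fuzzy_distance_transform(mu, seeds, region, "object", unit_spacing).d
        assert np.isfinite(d).all()
        assert d.max() < 1e-4  # epsilon-scaled lengths only

    def test_matches_graph_oracle_on_random_grids(self, rng, confocal_spacing):
        for _ in range(30):
            mu = rng.random((6, 6, 4))
            region = rng.random((6, 6, 4)) < 0.85
            seeds = region & (rng.random((6, 6, 4)) < 0.15)
            if not seeds.any():
                continue
            for mode in ("object", "background"):
                d = fuzzy_distance_transform(mu, seeds, region, mode, confocal_spacing).d
                expected = fdt_oracle(mu, seeds, region, mode, confocal_spacing.as_array())
                both_inf = np.isinf(d) & np.isinf(expected)
                np.testing.assert_allclose(d[~both_inf], expected[~both_inf], atol=1e-9)

    def test_seed_and_region_validation(self, unit_spacing):
        mu = np.ones((3, 3, 3))
        seeds = np.zeros((3, 3, 3), bool)
        seeds[0, 0, 0] = True
        with pytest.raises(ValueError, match="empty region"):
            fuzzy_distance_transform(mu, seeds, np.zeros((3, 3, 3), bool), "object", unit_spacing)
        region = np.ones((3, 3, 3), bool)
        region[0, 0, 0] = False
        with pytest.raises(ValueError, match="seeds outside region"):
            fuzzy_distance_transform(mu, seeds, region, "object", unit_spacing)


class TestMultiscaleOpening:
    def test_line_example_labels_match_graph_reasoning(self, unit_spacing):
        """Bright ends are separated; the dim middle (closer to the
        background than to either object under the fuzzy costs) stays
        unlabeled."""
        data = np.array([10, 10, 2, 1, 2, 10, 10], float).reshape(1, 1, 7)
        lm = multiscale_opening(data, 8.0, 2.0, unit_spacing)
        np.testing.assert_array_equal(lm.labels.ravel(), [1, 1, 0, 0, 0, 2, 2])

    def test_single_core_yields_one_label(self, unit_spacing):
        data = np.zeros((7, 7, 7))
        data[2:5, 2:5, 2:5] = 80.0  # bright envelope around a brighter core
        data[3, 3, 3] = 100.0
        lm = multiscale_opening(data, 90.0, 5.0, unit_spacing)
        assert lm.component_count == 1
        assert lm.labels[3, 3, 3] == 1
        # high-membership envelope voxels join the single object
        assert (lm.labels[2:5, 2:5, 2:5] == 1).all()
        assert not ((lm.labels > 0) & (data < 5.0)).any()

    def test_threshold_order_and_no_core_errors(self, unit_spacing):
        data = np.ones((3, 3, 3))
        with pytest.raises(ValueError, match="threshold order"):
            multiscale_opening(data, 1.0, 5.0, unit_spacing)
        with pytest.raises(ValueError, match="no core objects"):
            multiscale_opening(data, 50.0, 0.5, unit_spacing)

    def test_bridged_blobs_separation_with_noise(self):
        ph = bridged_blobs_phantom(noise_sd=5.0, seed=7)
        lm, diag = multiscale_opening(
            ph.image.channel(0), 60.0, 15.0, ph.image.spacing, return_diagnostics=True
        )
        assert lm.component_count == 2
        for truth_label in (1, 2):
            assert best_match_jaccard(lm.labels, ph.truth_labels.labels, truth_label) >= 0.9

    def test_labeled_voxels_strictly_closer_to_object(self):
        """The defining rule: every labeled voxel is closer to its object
        than to the background."""
        ph = bridged_blobs_phantom(noise_sd=5.0, seed=7)
        ch = ph.image.channel(0)
        lm, diag = multiscale_opening(ch, 60.0, 15.0, ph.image.spacing, return_diagnostics=True)
        from roikit.extraction import membership_ramp
        import scipy.ndimage as ndi

        mu = membership_ramp(ch, 60.0, 15.0)
        env = diag["envelope"]
        region = ndi.binary_dilation(env, ndi.generate_binary_structure(3, 3))
        labeled = lm.labels > 0
        d_obj = fuzzy_distance_transform(
            mu, labeled, region, "object", ph.image.spacing
        ).d
        # seeds have d_obj = 0 < d_bg wherever background exists
        assert (d_obj[labeled] < diag["d_background"][labeled]).all()

    def test_monotone_growth_and_termination(self, unit_spacing):
        ph = bridged_blobs_phantom(noise_sd=0.0)
        lm1 = multiscale_opening(ph.image.channel(0), 60.0, 15.0, ph.image.spacing, max_iterations=1)
        lm_full, diag = multiscale_opening(
            ph.image.channel(0), 60.0, 15.0, ph.image.spacing, return_diagnostics=True
        )
        assert diag["iterations"] <= 100
        # labeled set grows monotonically: everything labeled at iter 1 stays labeled
        assert ((lm1.labels > 0) <= (lm_full.labels > 0)).all()
        assert (lm_full.labels > 0).sum() <= diag["envelope"].sum()

    def test_labels_subset_of_envelope(self):
        ph = bridged_blobs_phantom(noise_sd=5.0, seed=11)
        lm, diag = multiscale_opening(
            ph.image.channel(0), 60.0, 15.0, ph.image.spacing, return_diagnostics=True
        )
        assert not ((lm.labels > 0) & ~diag["envelope"]).any()


class TestWatershedFlood:
    def test_single_core_floods_whole_envelope(self, unit_spacing):
        member = np.zeros((3, 5, 5), bool)
        member[1, 1:4, 1:4] = True
        cores_arr = np.zeros((3, 5, 5), np.int32)
        cores_arr[1, 2, 2] = 1
        lm = watershed_flood(
            np.zeros((3, 5, 5)),
            LabelMap(cores_arr, unit_spacing),
            BinaryMask(member, unit_spacing),
            variant="distance",
        )
        np.testing.assert_array_equal(lm.labels > 0, member)
        assert lm.component_count == 1

    def test_two_point_cores_in_uniform_bar_split_at_midplane(self, unit_spacing):
        member = np.zeros((5, 5, 21), bool)
        member[1:4, 1:4, :] = True  # bar surrounded by background laterally
        cores_arr = np.zeros((5, 5, 21), np.int32)
        cores_arr[2, 2, 2] = 1
        cores_arr[2, 2, 18] = 2
        lm = watershed_flood(
            np.zeros((5, 5, 21)),
            LabelMap(cores_arr, unit_spacing),
            BinaryMask(member, unit_spacing),
            variant="distance",
        )
        # symmetric bar: left half -> 1, right half -> 2 (mid plane may tie)
        assert (lm.labels[1:4, 1:4, :10] == 1).all()
        assert (lm.labels[1:4, 1:4, 11:] == 2).all()
        np.testing.assert_array_equal(lm.labels > 0, member)

    def test_cores_outside_envelope_rejected(self, unit_spacing):
        cores_arr = np.zeros((3, 3, 3), np.int32)
        cores_arr[0, 0, 0] = 1
        member = np.zeros((3, 3, 3), bool)
        member[2, 2, 2] = True
        with pytest.raises(ValueError, match="cores outside envelope"):
            watershed_flood(
                np.zeros((3, 3, 3)),
                LabelMap(cores_arr, unit_spacing),
                BinaryMask(member, unit_spacing),
            )

    def test_intensity_watershed_oversplits_gradient_object_but_mso_does_not(self):
        """An elongated object with three internal brightness maxima:
        watershed seeded at the maxima fragments it; MSO with two-stage
        cores recovers the true two objects."""
        ph = gradient_blobs_phantom(noise_sd=5.0, seed=3)
        ch = ph.image.channel(0)
        markers = np.zeros(ch.shape, np.int32)
        seeds = ph.parameters["maxima_voxels"] + [ph.parameters["ball_maximum_voxel"]]
        for i, v in enumerate(seeds, 1):
            markers[tuple(v)] = i
        ws = watershed_flood(
            ch,
            LabelMap(markers, ph.image.spacing),
            BinaryMask(ch >= 15.0, ph.image.spacing),
            variant="intensity",
        )
        assert ws.component_count > 2
        mso = multiscale_opening(ch, 120.0, 15.0, ph.image.spacing)
        assert mso.component_count == 2
        for truth_label in (1, 2):
            assert best_match_jaccard(mso.labels, ph.truth_labels.labels, truth_label) >= 0.9


class TestDoubleThresholdExtract:
    def test_mso_dispatch_on_bridge_phantom(self):
        ph = bridged_blobs_phantom(noise_sd=5.0, seed=5)
        out = double_threshold_extract(
            ph.image, core_threshold=60.0, envelope_threshold=15.0, flood_method="mso"
        )
        assert out.labels.component_count == 2
        assert out.provenance["realized_core_threshold"] == 60.0

    def test_watershed_single_core_fills_envelope(self, unit_spacing):
        data = np.zeros((5, 7, 7))
        data[1:4, 1:6, 1:6] = 10.0
        data[2, 3, 3] = 100.0
        image = Image(data, unit_spacing)
        out = double_threshold_extract(
            image, core_threshold=50.0, envelope_threshold=5.0, flood_method="watershed_distance"
        )
        np.testing.assert_array_equal(out.labels.labels > 0, data >= 5.0)

    def test_cores_equal_envelope_returns_cores(self, unit_spacing):
        data = np.zeros((4, 4, 8))
        data[1:3, 1:3, 1:3] = 100.0
        data[1:3, 1:3, 5:7] = 100.0
        image = Image(data, unit_spacing)
        for flood in ("mso", "watershed_distance", "watershed_intensity"):
            out = double_threshold_extract(
                image, core_threshold=90.0, envelope_threshold=50.0, flood_method=flood
            )
            assert out.labels.component_count == 2
            np.testing.assert_array_equal(out.labels.labels > 0, data > 0)

    def test_automated_threshold_specs(self):
        ph = bridged_blobs_phantom(noise_sd=2.0, seed=9)
        out = double_threshold_extract(
            ph.image,
            core_threshold={"method": "otsu"},
            envelope_threshold=15.0,
            flood_method="mso",
            n_bins=128,
        )
        assert out.labels.component_count >= 1
        assert 15.0 < out.provenance["realized_core_threshold"] <= 100.0

    def test_threshold_order_error(self, unit_spacing):
        image = Image(np.ones((3, 3, 3)), unit_spacing)
        with pytest.raises(ValueError, match="threshold order"):
            double_threshold_extract(
                image, core_threshold=1.0, envelope_threshold=2.0, flood_method="mso"
            )
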