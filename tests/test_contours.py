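"""Peri-cellular contour pipeline: preprocessing, segmentation, rings."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import morphology

import flimfret as ff
from conftest import segment_scene

from _oracles import brute_force_white_tophat, exact_ring_bands


def disk_mask(shape, center, radius):
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestInvertNormalize:
    def test_constant_image_maps_to_zero(self):
        out = ff.invert_normalize(np.full((6, 6), 37.0))
        assert np.all(out == 0.0)

    def test_extremes_swap(self):
        img = np.array([[0.0, 200.0]])
        out = ff.invert_normalize(img)
        assert out[0, 0] == 1.0 and out[0, 1] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(1, 50, size=(9, 9))
        assert np.allclose(ff.invert_normalize(img), ff.invert_normalize(2 * img))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ff.invert_normalize(np.zeros((4, 4)))


class TestTophat:
    def test_flat_image_gives_zeros(self):
        assert np.allclose(ff.tophat_enhance(np.full((15, 15), 3.0), 3), 0.0)

    def test_small_blob_preserved(self):
        img = np.zeros((21, 21))
        img[10, 10] = 5.0  # single-pixel blob, far narrower than the element
        out = ff.tophat_enhance(img, 5)
        assert out[10, 10] == pytest.approx(5.0)

    def test_matches_brute_force_oracle_on_small_fixture(self):
        """Implementation equals input minus min-then-max sliding-window
        opening on an 11x11 image."""
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 10, size=(11, 11))
        footprint = morphology.disk(2)
        expected = brute_force_white_tophat(img, footprint)
        got = img - morphology.opening(img, footprint=footprint)
        assert np.allclose(got, expected)
        # and tophat_enhance is exactly that white top-hat
        assert np.allclose(ff.tophat_enhance(img, 2), got)


class TestCanny:
    def test_blank_image_no_edges(self):
        assert ff.canny_edges(np.zeros((16, 16))).sum() == 0

    def test_disk_edge_within_one_pixel(self):
        """Edges of a high-contrast disk trace the true circle radius."""
        img = disk_mask((64, 64), (32, 32), 15).astype(float)
        edges = ff.canny_edges(img, sigma=1.0, low_frac=0.1, high_frac=0.2)
        assert edges.sum() > 40
        yy, xx = np.nonzero(edges)
        r = np.hypot(yy - 32, xx - 32)
        assert np.all(np.abs(r - 15) <= 1.5)

    def test_noise_below_low_threshold_silent(self):
        """Weak uniform noise next to a strong edge stays below the
        hysteresis band: no edge pixels away from the disk."""
        rng = np.random.default_rng(5)
        img = rng.uniform(0.0, 0.01, size=(64, 64))
        img[disk_mask((64, 64), (32, 32), 12)] += 1.0
        edges = ff.canny_edges(img, sigma=1.0, low_frac=0.1, high_frac=0.2)
        yy, xx = np.nonzero(edges)
        r = np.hypot(yy - 32, xx - 32)
        assert edges.sum() > 0
        assert np.all(np.abs(r - 12) <= 2.0)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            ff.canny_edges(np.zeros((8, 8)), low_frac=0.3, high_frac=0.2)


class TestPrimaryContour:
    def test_clean_disk_area_within_five_percent(self):
        # large enough that the half-pixel edge envelope stays under 5%
        img = disk_mask((80, 80), (40, 40), 25).astype(float)
        edges = ff.canny_edges(img, sigma=1.0, low_frac=0.1, high_frac=0.2)
        mask = ff.extract_primary_contour(edges)
        assert mask.area == pytest.approx(np.pi * 25**2, rel=0.05)
        assert mask.boundary.shape[1] == 2

    def test_larger_of_two_blobs_selected(self):
        edges = np.zeros((60, 60), dtype=bool)
        big = disk_mask((60, 60), (20, 20), 10)
        small = disk_mask((60, 60), (45, 45), 5)
        for blob in (big, small):
            edges |= blob & ~morphology.erosion(blob)
        mask = ff.extract_primary_contour(edges)
        assert (mask.mask & big).sum() > 0
        assert (mask.mask & small).sum() == 0

    def test_gap_bridged_by_closing(self):
        """A 3-px gap in the edge ring still yields a closed mask with
        closing radius 2."""
        ring = disk_mask((40, 40), (20, 20), 10) & ~disk_mask((40, 40), (20, 20), 9)
        ring[9:12, 19:22] = False  # cut a gap at the top
        mask = ff.extract_primary_contour(ring, closing_radius=2)
        assert mask.area > 200  # interior filled, not just the ring

    def test_empty_edges_is_an_error(self):
        with pytest.raises(ValueError):
            ff.extract_primary_contour(np.zeros((20, 20), dtype=bool))


class TestRingPropagation:
    def test_single_contour_is_dilation_shell(self):
        mask = ff.CellMask(
            mask=disk_mask((40, 40), (20, 20), 8),
            boundary=np.zeros((1, 2)),
        )
        rings = ff.propagate_rings(mask, 1)
        shell = morphology.dilation(mask.mask, footprint=morphology.disk(1)) & ~mask.mask
        assert np.array_equal(rings.labels == 1, shell)

    def test_annulus_pixel_counts_match_geometry(self):
        """Ring k around a radius-10 disk holds ~2*pi*(10+k-1/2) pixels."""
        mask = ff.CellMask(mask=disk_mask((60, 60), (30, 30), 10), boundary=np.zeros((1, 2)))
        rings = ff.propagate_rings(mask, 8)
        for k in range(1, 9):
            count = (rings.labels == k).sum()
            # the digital disk's effective radius wobbles ~0.5 px, so allow
            # a generous but bounded tolerance around the annulus area
            expected = 2 * np.pi * (10 + k - 0.5)
            assert count == pytest.approx(expected, rel=0.25)

    @pytest.mark.parametrize("shape", ["disk", "ellipse", "crescent", "noisy"])
    def test_bands_match_exact_edt_oracle(self, shape):
        """Distance-transform banding equals the brute-force exact
        Euclidean oracle on convex and concave masks."""
        base = np.zeros((48, 48), dtype=bool)
        if shape == "disk":
            base = disk_mask((48, 48), (24, 24), 9)
        elif shape == "ellipse":
            yy, xx = np.indices((48, 48))
            base = ((yy - 24) / 11.0) ** 2 + ((xx - 24) / 6.0) ** 2 <= 1.0
        elif shape == "crescent":
            # open bite from the right leaves a connected, hole-free moon
            base = disk_mask((48, 48), (24, 24), 10) & ~disk_mask((48, 48), (24, 33), 6)
        else:
            rng = np.random.default_rng(8)
            blob = disk_mask((48, 48), (24, 24), 8)
            noise = rng.random((48, 48)) < 0.03
            base = ndimage.binary_fill_holes(
                ndimage.binary_dilation(blob) | (noise & ndimage.binary_dilation(blob, iterations=3))
            )
            base = ndimage.label(base)[0] == 1
        mask = ff.CellMask(mask=base, boundary=np.zeros((1, 2)))
        rings = ff.propagate_rings(mask, 10)
        oracle = exact_ring_bands(base, 10)
        assert np.array_equal(rings.labels, oracle)

    def test_border_touching_mask_warns(self):
        base = disk_mask((30, 30), (4, 15), 6)
        mask = ff.CellMask(mask=base, boundary=np.zeros((1, 2)))
        with pytest.warns(UserWarning):
            ff.propagate_rings(mask, 5)


class TestRingBinning:
    @staticmethod
    def _rings(n_contours):
        mask = ff.CellMask(mask=disk_mask((140, 140), (70, 70), 8), boundary=np.zeros((1, 2)))
        return ff.propagate_rings(mask, n_contours)

    def test_forty_contours_group_four_gives_ten_bins(self):
        binned = ff.bin_rings(self._rings(40), 4)
        assert binned.n_rings == 10
        assert binned.labels.max() == 10

    def test_group_one_is_identity(self):
        rings = self._rings(12)
        binned = ff.bin_rings(rings, 1)
        assert np.array_equal(binned.labels, rings.labels)

    def test_trailing_partial_group_dropped(self):
        rings = self._rings(42)
        binned = ff.bin_rings(rings, 4)
        assert binned.n_rings == 10
        # contours 41-42 become unset
        dropped = (rings.labels >= 41) & (rings.labels <= 42)
        assert np.all(binned.labels[dropped] == -1)

    def test_ring_bin_pools_consecutive_contours(self):
        rings = self._rings(8)
        binned = ff.bin_rings(rings, 4)
        for j in (1, 2):
            members = set(np.unique(rings.labels[binned.labels == j]))
            assert members == set(range((j - 1) * 4 + 1, j * 4 + 1))


class TestRingProfile:
    def test_constant_scene_flat_profile(self, flat_scene):
        image, truth = flat_scene
        mask = segment_scene(image)
        binned = ff.bin_rings(ff.propagate_rings(mask, 40), 4)
        profile = ff.ring_profile(image, binned, threshold=10_000)
        tau = profile.tau[profile.valid]
        assert tau.size >= 8
        assert np.all(np.abs(tau - 2.0) / 2.0 < 0.02)

    def test_gradient_scene_monotone_profile(self, gradient_scene):
        image, truth = gradient_scene
        mask = segment_scene(image)
        binned = ff.bin_rings(ff.propagate_rings(mask, 40), 4)
        profile = ff.ring_profile(image, binned, threshold=10_000)
        tau = profile.tau[profile.valid]
        assert np.corrcoef(np.arange(tau.size), tau)[0, 1] > 0.9

    def test_under_gate_ring_invalid(self, flat_scene):
        image, _ = flat_scene
        mask = segment_scene(image)
        binned = ff.bin_rings(ff.propagate_rings(mask, 40), 4)
        profile = ff.ring_profile(image, binned, threshold=10**9)
        assert not profile.valid.any()
        assert np.all(np.isnan(profile.tau))

    def test_photon_conservation_across_partition(self, flat_scene):
        """Ring bins + mask interior + beyond-range pixels account for every
        photon in the image."""
        image, _ = flat_scene
        mask = segment_scene(image)
        binned = ff.bin_rings(ff.propagate_rings(mask, 40), 4)
        profile = ff.ring_profile(image, binned, threshold=10_000)
        intensity = image.intensity()
        in_rings = profile.n_photons.sum()
        in_mask = intensity[binned.labels == 0].sum()
        beyond = intensity[binned.labels == -1].sum()
        assert in_rings + in_mask + beyond == intensity.sum()


class TestCellMeanTau:
    def test_constant_scene_pooled_tau(self, flat_scene):
        image, _ = flat_scene
        mask = segment_scene(image)
        binned = ff.bin_rings(ff.propagate_rings(mask, 40), 4)
        profile = ff.ring_profile(image, binned, threshold=10_000)
        pooled = ff.cell_mean_tau(profile, 40)
        assert pooled == pytest.approx(2.0, rel=0.01)

    def test_equals_fit_of_summed_ring_histograms(self, gradient_scene):
        """Pooling is associative: one fit of the summed member-ring
        histograms equals cell_mean_tau."""
        image, _ = gradient_scene
        mask = segment_scene(image)
        binned = ff.bin_rings(ff.propagate_rings(mask, 40), 4)
        profile = ff.ring_profile(image, binned, threshold=10_000)
        pooled_counts = profile.pooled_counts[:10].sum(axis=0)
        direct = ff.fit_monoexponential(
            ff.PhotonHistogram(profile.bin_edges, pooled_counts)
        ).tau
        assert ff.cell_mean_tau(profile, 40) == pytest.approx(direct, abs=1e-12)

    def test_gradient_scene_pooled_between_extremes(self, gradient_scene):
        image, _ = gradient_scene
        mask = segment_scene(image)
        binned = ff.bin_rings(ff.propagate_rings(mask, 40), 4)
        profile = ff.ring_profile(image, binned, threshold=10_000)
        pooled = ff.cell_mean_tau(profile, 40)
        tau = profile.tau[profile.valid]
        assert tau.min() < pooled < tau.max()

    def test_gate_violation_is_error(self, flat_scene):
        image, _ = flat_scene
        mask = segment_scene(image)
        binned = ff.bin_rings(ff.propagate_rings(mask, 40), 4)
        profile = ff.ring_profile(image, binned, threshold=10_000)
        with pytest.raises(ValueError):
            ff.cell_mean_tau(profile, 40, threshold=10**9)


class TestProfileStability:
    def test_boundary_traversal_direction_irrelevant(self, flat_scene):
        """Ring lifetimes depend only on the mask geometry, not on how the
        boundary polyline is ordered."""
        image, _ = flat_scene
        mask = segment_scene(image)
        reversed_mask = ff.CellMask(mask=mask.mask, boundary=mask.boundary[::-1])
        p1 = ff.ring_profile(image, ff.bin_rings(ff.propagate_rings(mask, 20), 4))
        p2 = ff.ring_profile(image, ff.bin_rings(ff.propagate_rings(reversed_mask, 20), 4))
        assert np.array_equal(p1.n_photons, p2.n_photons)
        assert np.allclose(p1.tau, p2.tau, equal_nan=True)
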