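"""Segmentation: Otsu oracle equivalence, the three masks, domain assignment."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from microcap import phantom, segmentation
from microcap.exceptions import CouponNotFoundError, DegenerateHistogramError, NoHydrogelError
from microcap.segmentation import SegmentationParams, otsu_threshold


def brute_force_otsu(values, bins=256):
    """Independent oracle: scan every interior bin edge, computing the
    between-class variance of the binned histogram directly."""
    x = np.asarray(values, dtype=float).ravel()
    lo, hi = x.min(), x.max()
    counts, _ = np.histogram((x - lo) / (hi - lo), bins=bins, range=(0.0, 1.0))
    centers = (np.arange(bins) + 0.5) / bins
    best_k, best_var = None, -1.0
    n = counts.sum()
    for k in range(1, bins):
        n0 = counts[:k].sum()
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / n0
        mu1 = (counts[k:] * centers[k:]).sum() / n1
        var = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
        if var > best_var + 1e-15:
            best_var, best_k = var, k
    return lo + (best_k / bins) * (hi - lo)


class TestOtsu:
    def test_two_level_image(self):
        values = np.array([10.0] * 500 + [200.0] * 500)
        thr = otsu_threshold(values)
        assert 10.0 < thr < 200.0
        assert (values > thr).sum() == 500

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full(100, 7.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1000, allow_nan=False), min_size=5, max_size=200),
           st.integers(min_value=2, max_value=64))
    def test_matches_bruteforce_on_fuzzed_inputs(self, values, bins):
        x = np.asarray(values)
        if x.max() == x.min():
            return
        assert otsu_threshold(x, bins) == pytest.approx(brute_force_otsu(x, bins), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 50), st.floats(-100, 100))
    def test_affine_intensity_invariance(self, seed, scale, offset):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(20, 3, 300), rng.normal(80, 5, 200)])
        thr = otsu_threshold(x)
        thr2 = otsu_threshold(scale * x + offset)
        assert thr2 == pytest.approx(scale * thr + offset, rel=1e-9, abs=1e-9)

    def test_agrees_with_skimage_within_one_bin(self):
        from skimage.filters import threshold_otsu
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(30, 4, 4000), rng.normal(150, 10, 1000)])
        ours = otsu_threshold(x, 256)
        ref = threshold_otsu(x, nbins=256)
        assert abs(ours - ref) <= (x.max() - x.min()) / 256

    def test_threshold_separates_noisefree_phantom_spheres(self, clean_stack, truth):
        labels, _ = truth
        mask = segmentation.segment_microspheres(clean_stack)
        agreement = (mask == labels.mask("microsphere")).mean()
        assert agreement >= 0.999


class TestSegmentMicrospheres:
    def test_dark_channel_gives_empty_mask(self):
        z = np.zeros((8, 8, 8))
        stack = phantom.ChannelStack(z, z, np.ones_like(z))
        assert not segmentation.segment_microspheres(stack).any()

    def test_noise_only_channel_gives_empty_mask(self):
        # no genuine sphere class: threshold would split the background noise
        rng = np.random.default_rng(4)
        z = np.zeros((16, 16, 16))
        stack = phantom.ChannelStack(z, rng.random((16, 16, 16)), np.ones_like(z))
        assert not segmentation.segment_microspheres(stack).any()

    @pytest.fixture(scope="class")
    def sphere_scene(self):
        geometry = phantom.make_geometry(cap_radius=8.0, coupon_z=1.0, n_spheres=20,
                                         cw_penetration_depth=3.0, seed=3,
                                         cap_center_xy=(10.0, 10.0))
        field = phantom.ConcentrationField()
        return geometry, field

    def test_connected_component_count_under_noise(self, sphere_scene):
        geometry, field = sphere_scene
        cfg = phantom.ImagingConfig(voxel_size_xyz=(0.2, 0.2, 0.2),
                                    stack_shape=(60, 100, 100),
                                    noise_model=phantom.GaussianNoise(0.05 * field.af594_sphere),
                                    seed=5)
        stack = phantom.render_stack(geometry, field, cfg)
        mask = segmentation.segment_microspheres(stack)
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
        assert n == 20

    def test_recovered_volume_matches_analytic(self, sphere_scene):
        geometry, field = sphere_scene
        cfg = phantom.ImagingConfig(voxel_size_xyz=(0.2, 0.2, 0.2),
                                    stack_shape=(60, 100, 100))
        stack = phantom.render_stack(geometry, field, cfg)
        mask = segmentation.segment_microspheres(stack)
        recovered = mask.sum() * 0.2**3
        analytic = sum(4.0 / 3.0 * np.pi * r**3 for _, r in geometry.spheres)
        assert recovered == pytest.approx(analytic, rel=0.20)


class TestSegmentHydrogel:
    def test_solid_stained_cap_needs_no_filling(self):
        # penetration >= radius: the whole cap is stained, filling is a no-op
        g = phantom.make_geometry(cap_radius=10.0, coupon_z=1.5, n_spheres=0,
                                  cw_penetration_depth=20.0, seed=0,
                                  cap_center_xy=(13.0, 13.0))
        cfg = phantom.ImagingConfig(stack_shape=(14, 26, 26))
        stack = phantom.render_stack(g, phantom.ConcentrationField(), cfg)
        labels, _ = phantom.ground_truth(g, cfg, phantom.ConcentrationField())
        mask = segmentation.segment_hydrogel(stack)
        assert np.array_equal(mask, labels.mask("hydrogel"))

    def test_fill_recovers_unstained_core(self):
        # 10 um shell on a 100 um-diameter cap: the core is unstained
        g = phantom.make_geometry(cap_radius=50.0, coupon_z=3.0, n_spheres=0,
                                  cw_penetration_depth=10.0, seed=0,
                                  cap_center_xy=(60.0, 60.0))
        cfg = phantom.ImagingConfig(voxel_size_xyz=(1, 1, 1), stack_shape=(60, 120, 120))
        stack = phantom.render_stack(g, phantom.ConcentrationField(), cfg)
        labels, _ = phantom.ground_truth(g, cfg, phantom.ConcentrationField())
        gt = labels.mask("hydrogel")
        shell_only = stack.cw > 0
        mask = segmentation.segment_hydrogel(stack)
        assert shell_only.sum() < 0.6 * gt.sum()  # the fill has real work to do
        assert (mask & gt).sum() >= 0.95 * gt.sum()

    def test_small_noise_blobs_are_discarded(self, clean_stack):
        mask_ref = segmentation.segment_hydrogel(clean_stack)
        cw = clean_stack.cw.copy()
        rng = np.random.default_rng(8)
        for _ in range(5):  # isolated bright blobs well below min_region_voxels
            z, y, x = rng.integers(2, 60, 3)
            cw[z:z + 2, y:y + 2, x:x + 2] = clean_stack.cw.max()
        noisy = phantom.ChannelStack(cw, clean_stack.af594, clean_stack.fitc,
                                     clean_stack.voxel_size_xyz)
        mask = segmentation.segment_hydrogel(noisy)
        assert np.array_equal(mask, mask_ref)

    def test_degenerate_cw_raises(self):
        z = np.zeros((8, 8, 8))
        stack = phantom.ChannelStack(z, z, np.ones_like(z))
        with pytest.raises(NoHydrogelError):
            segmentation.segment_hydrogel(stack)


class TestSegmentCoupon:
    def test_noisefree_plane_exact_in_every_column(self, small_scene, clean_stack):
        geometry, _, config = small_scene
        k = phantom.reflection_layer_index(geometry, config)
        planes = segmentation.detect_coupon_planes(clean_stack)
        assert (planes == k).all()

    def test_bias_mask_is_strict_superset(self, clean_stack):
        m0 = segmentation.segment_coupon(clean_stack, SegmentationParams(coupon_bias_layers=0))
        m2 = segmentation.segment_coupon(clean_stack, SegmentationParams(coupon_bias_layers=2))
        assert (m0 & ~m2).sum() == 0
        assert m2.sum() > m0.sum()

    def test_noisy_detection_within_one_layer(self, small_scene):
        geometry, field, _ = small_scene
        cfg = phantom.ImagingConfig(
            voxel_size_xyz=(0.5, 0.5, 0.5), stack_shape=(64, 64, 64),
            noise_model=phantom.GaussianNoise(0.10 * field.coupon_reflection), seed=11)
        stack = phantom.render_stack(geometry, field, cfg)
        k = phantom.reflection_layer_index(geometry, cfg)
        planes = segmentation.detect_coupon_planes(stack)
        assert (np.abs(planes - k) <= 1).mean() >= 0.95

    def test_no_edge_raises(self):
        # monotonically increasing along z: no positive-to-negative transition
        ramp = np.arange(16, dtype=float)[:, None, None] * np.ones((16, 8, 8))
        stack = phantom.ChannelStack(np.zeros_like(ramp) + ramp, ramp, ramp)
        with pytest.raises(CouponNotFoundError):
            segmentation.detect_coupon_planes(stack)


class TestAssignDomains:
    def test_all_empty_masks_give_all_water(self):
        e = np.zeros((4, 4, 4), dtype=bool)
        labels = segmentation.assign_domains(e, e, e)
        assert labels.counts() == {"water": 64, "hydrogel": 0, "microsphere": 0, "coupon": 0}

    def test_precedence_coupon_over_sphere_over_hydrogel(self):
        full = np.ones((2, 2, 2), dtype=bool)
        labels = segmentation.assign_domains(full, full, full)
        assert (labels.labels == 3).all()
        labels = segmentation.assign_domains(full, full, ~full)
        assert (labels.labels == 2).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            segmentation.assign_domains(np.zeros((2, 2, 2), bool),
                                        np.zeros((3, 2, 2), bool),
                                        np.zeros((2, 2, 2), bool))

    def test_output_is_a_partition(self, clean_stack):
        labels = segmentation.segment_stack(clean_stack)
        assert sum(labels.counts().values()) == labels.labels.size

    def test_end_to_end_noisefree_accuracy(self, clean_stack, truth):
        gt, _ = truth
        labels = segmentation.segment_stack(clean_stack)
        assert (labels.labels == gt.labels).mean() >= 0.98

    def test_accuracy_degrades_gracefully_with_noise(self, small_scene, truth):
        geometry, field, _ = small_scene
        gt, _ = truth
        mean_acc = []
        for sigma in (2.0, 20.0):
            accs = []
            for seed in range(3):
                cfg = phantom.ImagingConfig(
                    voxel_size_xyz=(0.5, 0.5, 0.5), stack_shape=(64, 64, 64),
                    noise_model=phantom.GaussianNoise(sigma), seed=seed)
                stack = phantom.render_stack(geometry, field, cfg)
                labels = segmentation.segment_stack(stack)
                accs.append((labels.labels == gt.labels).mean())
            mean_acc.append(np.mean(accs))
        assert mean_acc[1] <= mean_acc[0]
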