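"""Recovery-coefficient metrics and the background-noise figure."""
import numpy as np
import pytest

import gatedqa as g
from gatedqa.imaging import F18_HALF_LIFE_S, Mask
from gatedqa.segmentation import SegmentationResult

from conftest import make_volume


def seg_result(vol, mask_voxels, failed=False, reason="none"):
    return SegmentationResult(
        mask=Mask(mask_voxels, vol.spacing, vol.origin),
        threshold_value=0.4, max_value=1.0, failed=failed, failure_reason=reason,
    )


class TestMaskVolume:
    def test_count_times_voxel_volume(self):
        vol = make_volume((10, 10, 10), spacing=4.0)
        m = np.zeros(vol.shape, dtype=bool)
        m.ravel()[:100] = True
        assert g.mask_volume(Mask(m, vol.spacing, vol.origin)) == pytest.approx(6.4)

    def test_empty_mask_is_zero(self):
        vol = make_volume((5, 5, 5))
        assert g.mask_volume(Mask(np.zeros(vol.shape, bool), vol.spacing, vol.origin)) == 0.0


class TestVolumeRc:
    def test_identical_segmentations_give_unity(self):
        vol = make_volume((10, 10, 10))
        m = np.zeros(vol.shape, bool)
        m[2:5, 2:5, 2:5] = True
        rec = g.volume_rc(seg_result(vol, m), seg_result(vol, m))
        assert rec.rc == 1.0 and not rec.failed

    def test_failed_moving_gets_sentinel_five(self):
        vol = make_volume((10, 10, 10))
        m = np.zeros(vol.shape, bool)
        m[2:5, 2:5, 2:5] = True
        moving = seg_result(vol, np.zeros(vol.shape, bool), failed=True, reason="empty")
        rec = g.volume_rc(moving, seg_result(vol, m))
        assert rec.rc == 5.0 and rec.failed

    def test_ratio_arithmetic(self):
        vol = make_volume((20, 20, 20), spacing=1.0)
        m1 = np.zeros(vol.shape, bool); m1.ravel()[:1150] = True   # 1.15 ml
        m2 = np.zeros(vol.shape, bool); m2.ravel()[:2300] = True   # 2.30 ml
        rec = g.volume_rc(seg_result(vol, m2), seg_result(vol, m1))
        assert rec.rc == pytest.approx(2.0)

    def test_failed_static_is_an_error(self):
        vol = make_volume((10, 10, 10))
        bad = seg_result(vol, np.zeros(vol.shape, bool), failed=True, reason="empty")
        good = seg_result(vol, np.ones(vol.shape, bool))
        with pytest.raises(ValueError, match="static"):
            g.volume_rc(good, bad)


class TestConcentration:
    def test_mean_of_constant_region(self):
        vol = make_volume((10, 10, 10), value=900000.0)
        m = np.zeros(vol.shape, bool); m[2:6, 2:6, 2:6] = True
        assert g.mean_concentration(vol, Mask(m, vol.spacing, vol.origin)) == 900000.0

    def test_mean_of_mixed_region(self):
        vol = make_volume((10, 10, 10), value=0.0)
        vol.voxels[0:5] = 2.0
        m = np.ones(vol.shape, bool)
        assert g.mean_concentration(vol, Mask(m, vol.spacing, vol.origin)) == pytest.approx(1.0)

    def test_empty_mask_errors(self):
        vol = make_volume((5, 5, 5))
        with pytest.raises(ValueError, match="empty"):
            g.mean_concentration(vol, Mask(np.zeros(vol.shape, bool), vol.spacing, vol.origin))

    @pytest.mark.parametrize(
        "c_mov,c_stat,dt,expected",
        [
            (15000.0, 15000.0, 0.0, 1.0),
            (7500.0, 15000.0, F18_HALF_LIFE_S, 1.0),  # perfect decay compensation
            (12000.0, 15000.0, 0.0, 0.8),
        ],
    )
    def test_decay_compensated_rc(self, c_mov, c_stat, dt, expected):
        rec = g.concentration_rc(c_mov, c_stat, dt)
        assert rec.rc == pytest.approx(expected, rel=1e-9)

    def test_invariant_under_matched_decay_rescale(self):
        for dt in (100.0, 1500.0, 6000.0):
            base = g.concentration_rc(12000.0, 15000.0, 0.0).rc
            scaled = g.concentration_rc(
                12000.0 * 2 ** (-dt / F18_HALF_LIFE_S), 15000.0, dt
            ).rc
            assert scaled == pytest.approx(base, rel=1e-9)

    def test_nonpositive_static_errors(self):
        with pytest.raises(ValueError):
            g.concentration_rc(1.0, 0.0)


class TestCountRods:
    def make_sector(self, counts_per_slice):
        """Triangle over 3 slices, n well-separated cold disks per slice."""
        vol = make_volume((40, 40, 9), value=10.0)
        tri = np.zeros(vol.shape, bool)
        for k, n in enumerate(counts_per_slice):
            iz = 3 + k
            tri[2:38, 2:38, iz] = True
            xs, ys = np.ogrid[:40, :40]
            centers = [(6 + 8 * (i % 4), 6 + 8 * (i // 4)) for i in range(n)]
            for cx, cy in centers:
                vol.voxels[:, :, iz][(xs - cx) ** 2 + (ys - cy) ** 2 <= 4] = 0.5
        return vol, Mask(tri, vol.spacing, vol.origin)

    def test_eight_disks_on_each_slice(self):
        vol, tri = self.make_sector([8, 8, 8])
        assert g.count_rods(vol, tri) == 8

    def test_median_over_slices_rounds_half_up(self):
        vol, tri = self.make_sector([7, 8, 8])
        assert g.count_rods(vol, tri) == 8
        vol, tri = self.make_sector([7, 8, 7, 8])  # even count: median 7.5 -> 8
        assert g.count_rods(vol, tri) == 8

    def test_uniform_slices_count_zero(self):
        vol, tri = self.make_sector([0, 0, 0])
        assert g.count_rods(vol, tri) == 0

    def test_speckle_suppression_via_min_component(self):
        vol, tri = self.make_sector([5, 5, 5])
        vol.voxels[30, 30, 3] = 0.0  # single-voxel speckle
        assert g.count_rods(vol, tri, min_component_voxels=2) == 5
        assert g.count_rods(vol, tri, min_component_voxels=1) >= 5


class TestClassifySector:
    @pytest.mark.parametrize("detected,total,expected", [
        (6, 8, True),    # exactly 75%
        (5, 8, False),
        (8, 8, True),
        (0, 8, False),
    ])
    def test_75_percent_boundary(self, detected, total, expected):
        assert g.classify_sector(detected, total) is expected

    def test_monotone_in_detected(self):
        flags = [g.classify_sector(k, 12) for k in range(13)]
        assert flags == sorted(flags)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            g.classify_sector(1, 0)


class TestSectorContrast:
    def test_two_level_sector(self):
        vol = make_volume((20, 20, 5), value=10.0)
        tri = np.zeros(vol.shape, bool)
        tri[2:18, 2:18, 2] = True
        vol.voxels[5:8, 5:8, 2] = 2.0
        c = g.sector_contrast(vol, Mask(tri, vol.spacing, vol.origin))
        assert c == pytest.approx(5.0)

    def test_uniform_sector_is_undefined(self):
        vol = make_volume((20, 20, 5), value=10.0)
        tri = np.zeros(vol.shape, bool)
        tri[2:18, 2:18, 2] = True
        with pytest.raises(ValueError, match="undefined"):
            g.sector_contrast(vol, Mask(tri, vol.spacing, vol.origin))


class TestBackgroundNoise:
    def voi(self):
        # radius for a 30 ml sphere
        r = (3 * 30.0 * 1000.0 / (4 * np.pi)) ** (1 / 3)
        return g.RoiSpec("sphere", {"center": (0, 0, 0), "radius": r})

    def test_constant_background_is_noiseless(self):
        vol = make_volume((20, 20, 20), spacing=4.0, value=15000.0)
        assert g.background_noise(vol, self.voi()) == 0.0

    def test_recovers_injected_sigma(self):
        rng = np.random.default_rng(11)
        vol = make_volume((20, 20, 20), spacing=4.0, value=15000.0)
        vol.voxels += rng.normal(0.0, 500.0, vol.shape)
        sd = g.background_noise(vol, self.voi())
        assert abs(sd - 500.0) < 50.0

    def test_wrong_voi_size_rejected(self):
        vol = make_volume((30, 30, 30), spacing=4.0, value=1.0)
        small = g.RoiSpec("sphere", {"center": (0, 0, 0), "radius": 10.0})
        with pytest.raises(ValueError, match="10%"):
            g.background_noise(vol, small)


class TestCollapsePhases:
    def test_phase_mean_including_sentinels(self):
        recs = [
            g.RcRecord("volume", "4_phases", "sin", "s1", 1.0, v, v, failed=(v == 5.0), phase=i)
            for i, v in enumerate([0.9, 1.1, 5.0, 1.0])
        ]
        out = g.collapse_phases(recs)
        assert len(out) == 1
        assert out[0].rc == pytest.approx(2.0)
        assert not out[0].failed  # only all-failed collapses to failed

    def test_single_records_pass_through(self):
        rec = g.RcRecord("volume", "exhale_30", "sin", "s1", 1.0, 1.2, 1.2)
        assert g.collapse_phases([rec]) == [rec]
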