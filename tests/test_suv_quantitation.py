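"""SUV computation, MTV segmentation, TLG and MTD."""

import numpy as np
import pytest

import petdlbcl as p
from conftest import random_suv_volume


def cuboid_volume(lesion_suv=4.0, background=1.0, spacing=(2.0, 2.0, 2.0)):
    """20^3 grid with a 10x10x10 uniform lesion block."""
    values = np.full((20, 20, 20), background)
    values[5:15, 5:15, 5:15] = lesion_suv
    return p.SuvVolume(values, spacing)


class TestComputeSuv:
    def test_body_weight_formula(self):
        vol = p.compute_suv(np.full((2, 2, 2), 10.0), dose_mbq=350.0, weight_kg=70.0)
        assert vol.values == pytest.approx(2.0)

    def test_zero_activity_gives_zero_suv(self):
        vol = p.compute_suv(np.zeros((3, 3, 3)), dose_mbq=370.0, weight_kg=80.0)
        assert np.all(vol.values == 0)

    def test_matches_elementwise_oracle(self, rng):
        act = rng.uniform(0, 50, size=(6, 5, 4))
        vol = p.compute_suv(act, dose_mbq=370.0, weight_kg=82.5)
        oracle = np.empty_like(act)
        for idx in np.ndindex(act.shape):
            oracle[idx] = act[idx] * 82.5 / 370.0
        np.testing.assert_allclose(vol.values, oracle)

    @pytest.mark.parametrize("dose,weight", [(0.0, 70.0), (-1.0, 70.0), (370.0, 0.0)])
    def test_nonpositive_dose_or_weight_rejected(self, dose, weight):
        with pytest.raises(ValueError):
            p.compute_suv(np.ones((2, 2, 2)), dose_mbq=dose, weight_kg=weight)


class TestSegmentMtv:
    def test_uniform_cuboid_lesion_totals(self):
        seg = p.segment_mtv(cuboid_volume(), threshold=2.5)
        assert seg.n_lesions == 1
        assert seg.mtv_total == pytest.approx(8.0)       # 1000 voxels x 0.008 cm3
        assert seg.suv_mean_total == pytest.approx(4.0)
        assert seg.tlg_total == pytest.approx(32.0)

    def test_threshold_is_inclusive(self):
        values = np.ones((5, 5, 5))
        values[2, 2, 2] = 2.5
        seg = p.segment_mtv(p.SuvVolume(values, (1, 1, 1)), threshold=2.5)
        assert seg.n_lesions == 1
        assert seg.lesions[0].voxel_count == 1

    def test_edit_mask_excluded_matches_brute_force(self, rng):
        """Two lesions plus a masked hot region: totals equal a voxel scan."""
        values = np.ones((16, 16, 16))
        values[2:5, 2:5, 2:5] = 6.0
        values[10:13, 10:13, 10:13] = 4.0
        values[2:6, 10:14, 2:6] = 8.0  # myocardium-like, masked out
        mask = np.zeros_like(values, dtype=bool)
        mask[2:6, 10:14, 2:6] = True
        vol = p.SuvVolume(values, (2.0, 2.0, 2.0), edit_mask=mask)
        seg = p.segment_mtv(vol, threshold=2.5)
        count = sum(
            1
            for idx in np.ndindex(values.shape)
            if values[idx] >= 2.5 and not mask[idx]
        )
        assert seg.mtv_total == pytest.approx(count * vol.voxel_volume_cm3)
        assert not np.any((seg.label_map > 0) & mask)

    def test_random_volumes_match_voxel_scan_oracle(self, rng):
        for _ in range(5):
            vol = random_suv_volume(rng)
            seg = p.segment_mtv(vol, threshold=2.5)
            above = (vol.values >= 2.5) & ~vol.edit_mask
            assert seg.mtv_total == pytest.approx(above.sum() * vol.voxel_volume_cm3)
            if above.any():
                assert seg.suv_max_total == pytest.approx(vol.values[above].max())
                assert seg.suv_mean_total == pytest.approx(vol.values[above].mean())

    def test_empty_volume_errors(self):
        with pytest.raises(ValueError, match="empty"):
            p.segment_mtv(p.SuvVolume(np.empty((0, 0, 0)), (1, 1, 1)))

    def test_fully_excluded_volume_gives_zero_mtv(self):
        vol = p.SuvVolume(np.full((4, 4, 4), 5.0), (1, 1, 1),
                          edit_mask=np.ones((4, 4, 4), bool))
        seg = p.segment_mtv(vol)
        assert seg.mtv_total == 0.0
        assert seg.tlg_total == 0.0
        assert seg.n_lesions == 0

    def test_mtv_monotone_in_threshold(self, rng):
        vol = random_suv_volume(rng, with_mask=False)
        mtvs = [p.segment_mtv(vol, threshold=t).mtv_total for t in np.linspace(0.5, 6.0, 12)]
        assert all(a >= b for a, b in zip(mtvs, mtvs[1:]))

    def test_additive_over_disjoint_lesions(self):
        values = np.ones((20, 10, 10))
        values[1:4, 1:4, 1:4] = 5.0
        values[15:19, 5:9, 5:9] = 3.0
        vol = p.SuvVolume(values, (1.0, 1.0, 1.0))
        seg = p.segment_mtv(vol)
        assert seg.n_lesions == 2
        assert seg.mtv_total == pytest.approx(sum(l.volume_cm3 for l in seg.lesions))
        # totals are invariant to which lesion carries which label
        assert seg.suv_max_total == pytest.approx(max(l.suv_max for l in seg.lesions))

    def test_tlg_formulations_agree(self, rng):
        """mtv*mean over all voxels == sum of per-lesion volume*mean."""
        for _ in range(5):
            vol = random_suv_volume(rng)
            seg = p.segment_mtv(vol, threshold=2.0)
            per_lesion = sum(l.volume_cm3 * l.suv_mean for l in seg.lesions)
            assert seg.tlg_total == pytest.approx(per_lesion, rel=1e-9)
            assert seg.tlg_total == seg.mtv_total * seg.suv_mean_total

    def test_min_voxels_filter(self):
        values = np.ones((10, 10, 10))
        values[1, 1, 1] = 5.0           # single voxel
        values[5:8, 5:8, 5:8] = 5.0     # 27 voxels
        seg = p.segment_mtv(p.SuvVolume(values, (1, 1, 1)), min_voxels=2)
        assert seg.n_lesions == 1
        assert seg.lesions[0].voxel_count == 27


class TestSegmentMtvPct:
    def test_uniform_lesion_identical_to_fixed_mode(self):
        vol = cuboid_volume()
        fixed = p.segment_mtv(vol, threshold=2.5)
        for fraction in (0.2, 0.41, 0.9):
            pct = p.segment_mtv_pct(vol, fraction=fraction)
            assert pct.mtv_total == pytest.approx(fixed.mtv_total)

    def test_fraction_41_brute_force(self):
        values = np.ones((12, 12, 12))
        values[3:9, 3:9, 3:9] = 5.0
        values[5:7, 5:7, 5:7] = 10.0  # peak inside the lesion
        vol = p.SuvVolume(values, (2.0, 2.0, 2.0))
        seg = p.segment_mtv_pct(vol, fraction=0.41)
        # the single lesion has SUVmax 10 -> per-lesion threshold 4.1
        count = int(np.sum(values >= 4.1))
        assert seg.mtv_total == pytest.approx(count * vol.voxel_volume_cm3)

    def test_volume_monotone_nonincreasing_in_fraction(self, rng):
        vol = random_suv_volume(rng, with_mask=False)
        fractions = np.linspace(0.05, 0.99, 10)
        mtvs = [p.segment_mtv_pct(vol, fraction=f).mtv_total for f in fractions]
        assert all(a >= b for a, b in zip(mtvs, mtvs[1:]))


class TestMaxTumourDimension:
    def test_single_voxel_lesion_is_zero(self):
        values = np.ones((5, 5, 5))
        values[2, 2, 2] = 5.0
        seg = p.segment_mtv(p.SuvVolume(values, (2, 2, 2)))
        assert p.max_tumour_dimension(seg) == 0.0

    def test_straight_line_51_voxels_at_2mm_is_10cm(self):
        values = np.ones((60, 3, 3))
        values[4:55, 1, 1] = 5.0  # 51 voxels along axis 0
        seg = p.segment_mtv(p.SuvVolume(values, (2.0, 2.0, 2.0)))
        assert p.max_tumour_dimension(seg) == pytest.approx(10.0)

    def test_random_blob_matches_all_pairs_oracle(self, rng):
        values = np.ones((12, 12, 12))
        blob = rng.random((12, 12, 12)) < 0.08
        blob[6, 6, 6] = True
        values[blob] = 5.0
        spacing = (2.0, 3.0, 2.5)
        seg = p.segment_mtv(p.SuvVolume(values, spacing))
        best = 0.0
        for lesion in seg.lesions:
            pts = np.argwhere(seg.label_map == lesion.label) * np.array(spacing)
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    best = max(best, float(np.linalg.norm(pts[i] - pts[j])))
        assert p.max_tumour_dimension(seg) == pytest.approx(best / 10.0)

    def test_no_lesions_signalled_distinctly(self):
        seg = p.segment_mtv(p.SuvVolume(np.ones((4, 4, 4)), (1, 1, 1)))
        with pytest.raises(p.NoLesionsError):
            p.max_tumour_dimension(seg)
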