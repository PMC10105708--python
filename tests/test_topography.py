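import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from absp.image import LabelMask
from absp.topography import (
    ProbabilisticMap,
    asymmetry_table,
    fit_quadrants,
    probabilistic_map,
    quadrant_profile,
    render_map,
    select_reference,
)


def _ellipsoid_mask(semi=(8.0, 4.0, 3.0), spacing=(0.5, 0.5, 0.5), rot=None):
    # cubic field of view sized to the largest semi-axis so a rotated
    # ellipsoid is never clipped; even dimensions keep voxel centres off
    # the exact symmetry planes
    half = 1.2 * max(semi)
    n = np.ceil(2 * half / np.array(spacing)).astype(int)
    n += n % 2
    A = np.diag([*spacing, 1.0])
    A[:3, 3] = -(n - 1) * np.array(spacing) / 2
    idx = np.stack(np.meshgrid(*(np.arange(k) for k in n), indexing="ij"), axis=-1)
    pts = idx @ A[:3, :3].T + A[:3, 3]
    if rot is not None:
        pts = pts @ rot.T
    data = ((pts / np.array(semi)) ** 2).sum(axis=-1) <= 1.0
    return LabelMask(data, A, "SNc", "R")


class TestQuadrantFit:
    def test_axis_aligned_ellipsoid_gives_equal_quadrants(self):
        mask = _ellipsoid_mask()
        part = fit_quadrants(mask)
        counts = np.array([(part.labels == q).sum() for q in (1, 2, 3, 4)])
        assert counts.max() / counts.min() - 1 < 0.02

    def test_partition_is_exact(self, hc_subject):
        for side in ("L", "R"):
            mask = hc_subject.truth_masks[("NM", "SNc", side)]
            part = fit_quadrants(mask)
            union = part.labels > 0
            assert np.array_equal(union, mask.data)
            assert set(np.unique(part.labels[mask.data])) == {1, 2, 3, 4}

    def test_axis_rotates_with_the_mask(self):
        theta = np.deg2rad(25)
        R = np.array(
            [
                [np.cos(theta), 0, np.sin(theta)],
                [0, 1, 0],
                [-np.sin(theta), 0, np.cos(theta)],
            ]
        )
        a1 = fit_quadrants(_ellipsoid_mask()).axis
        a2 = fit_quadrants(_ellipsoid_mask(rot=R)).axis
        # sampling the rotated ellipsoid: axis should be R^T applied to a1
        expected = R.T @ a1
        angle = np.rad2deg(np.arccos(np.clip(abs(expected @ a2), -1, 1)))
        assert angle < 2.0

    def test_degenerate_mask_rejected(self):
        flat = np.zeros((10, 10, 10), bool)
        flat[:, :, 5] = True  # a plane has no third principal direction
        with pytest.raises(ValueError):
            fit_quadrants(LabelMask(flat, np.eye(4), "SNc", "L"))
        with pytest.raises(ValueError):
            fit_quadrants(LabelMask(np.zeros((4, 4, 4), bool), np.eye(4), "SNc", "L"))

    def test_labels_stable_under_one_voxel_erosion(self):
        """Eroding a well-resolved structure by one voxel neither flips the
        quadrant centroids' labels nor relabels the interior."""
        mask = _ellipsoid_mask()
        part = fit_quadrants(mask)
        eroded = mask.with_data(ndimage.binary_erosion(mask.data))
        part2 = fit_quadrants(eroded)
        core = eroded.data
        agree = (part.labels[core] == part2.labels[core]).mean()
        assert agree > 0.9
        for q in (1, 2, 3, 4):
            sel = np.argwhere((part.labels == q) & core)
            centroid = sel.mean(axis=0)
            nearest = sel[np.argmin(((sel - centroid) ** 2).sum(axis=1))]
            assert part2.labels[tuple(nearest)] == q


class TestQuadrantProfile:
    def test_quadrant_nvols_sum_to_whole_structure(self, hc_subject):
        from absp import quantify

        side = "L"
        snc = hc_subject.truth_masks[("NM", "SNc", side)]
        bs = hc_subject.truth_masks[("NM", "brainstem", "both")]
        part = fit_quadrants(snc)
        prof = quadrant_profile(
            {"NM": hc_subject.nm_volume},
            {side: snc},
            {side: part},
            {"NM": bs},
            hc_subject.gm_volume,
        )
        quads = prof[(prof.quadrant != "all") & (prof.sequence == "NM")]
        thr, _ = quantify.threshold_structure(
            hc_subject.nm_volume, snc, bs, "hyper", reference_exclude=[snc]
        )
        whole = quantify.normalized_volume(thr, hc_subject.gm_volume)
        assert quads["nvol"].sum() == pytest.approx(whole, rel=1e-9)

    def test_uniform_structure_has_equal_quadrant_crs(self, hc_subject):
        side = "R"
        snc = hc_subject.truth_masks[("NM", "SNc", side)]
        bs = hc_subject.truth_masks[("NM", "brainstem", "both")]
        part = fit_quadrants(snc)
        prof = quadrant_profile(
            {"NM": hc_subject.nm_volume},
            {side: snc},
            {side: part},
            {"NM": bs},
            hc_subject.gm_volume,
        )
        crs = prof[(prof.quadrant != "all") & (prof.sequence == "NM")]["cr"]
        assert crs.std() == pytest.approx(0.0, abs=1e-6)

    def test_slice_nvols_also_sum_to_whole(self, hc_subject):
        side = "L"
        snc = hc_subject.truth_masks[("NM", "SNc", side)]
        bs = hc_subject.truth_masks[("NM", "brainstem", "both")]
        prof = quadrant_profile(
            {"NM": hc_subject.nm_volume},
            {side: snc},
            {side: fit_quadrants(snc)},
            {"NM": bs},
            hc_subject.gm_volume,
        )
        by_quadrant = prof[(prof.quadrant != "all")]["nvol"].sum()
        by_slice = prof[(prof.slice != "all")]["nvol"].sum()
        assert by_slice == pytest.approx(by_quadrant, rel=1e-9)


class TestProbabilisticMaps:
    def _mask(self, data):
        return LabelMask(data, np.eye(4))

    def test_single_subject_map_is_binary(self, rng):
        m = self._mask(rng.random((5, 5, 5)) > 0.5)
        pm = probabilistic_map([m])
        assert set(np.unique(pm.data)) <= {0.0, 1.0}

    def test_two_half_overlapping_masks(self):
        a = np.zeros((8, 4, 4), bool)
        b = np.zeros((8, 4, 4), bool)
        a[0:4] = True
        b[2:6] = True
        pm = probabilistic_map([self._mask(a), self._mask(b)])
        assert np.all(pm.data[2:4] == 1.0)
        assert np.all(pm.data[0:2] == 0.5)
        assert np.all(pm.data[4:6] == 0.5)
        assert pm.data.max() <= 1.0

    def test_map_conserves_mean_structure_volume(self, rng):
        masks = [self._mask(rng.random((6, 6, 6)) > 0.6) for _ in range(5)]
        pm = probabilistic_map(masks)
        mean_vol = np.mean([m.n_voxels for m in masks])
        assert pm.data.sum() == pytest.approx(mean_vol)

    def test_grid_mismatch_rejected(self):
        a = self._mask(np.ones((4, 4, 4), bool))
        b = LabelMask(np.ones((4, 4, 4), bool), np.diag([2.0, 1, 1, 1]))
        with pytest.raises(ValueError):
            probabilistic_map([a, b])

    def test_render_upsample_identity_and_factor4(self, rng):
        pm = ProbabilisticMap(
            rng.random((6, 6, 4)).astype(np.float32), np.eye(4), "SNc", "NM", "HC", 5
        )
        same = render_map(pm, upsample=1)
        np.testing.assert_array_equal(same.data, pm.data)
        up = render_map(pm, upsample=4)
        assert up.data.shape == (24, 24, 4)
        assert up.data.min() >= 0.0 and up.data.max() <= 1.0


class TestCommonSpaceAndAsymmetry:
    def test_identical_cohort_maps_through_near_identity(self, hc_subject):
        from absp.topography import build_common_space

        vols = {"s0": hc_subject.nm_volume, "s1": hc_subject.nm_volume}
        cs = build_common_space(vols, {"s0": 0.9, "s1": 0.8}, stages=("rigid",))
        assert cs.reference_id == "s0"
        assert cs.transforms["s0"].rotation_angle_deg == 0.0
        # identical anatomy: the estimated transform is near identity
        assert cs.transforms["s1"].rotation_angle_deg < 0.5
        assert np.linalg.norm(cs.transforms["s1"].matrix[:3, 3]) < 0.5
        mask = hc_subject.truth_masks[("NM", "SNc", "L")]
        moved = cs.to_reference("s1", mask)
        from absp.image import dice_coefficient

        assert dice_coefficient(moved, mask) >= 0.95

    def test_reference_selection_tie_break(self):
        assert select_reference({"b": 0.9, "a": 0.9, "c": 0.8}) == "a"
        assert select_reference({"x": 0.95, "y": 0.90}) == "x"

    def test_asymmetry_pairs_and_ratio(self):
        rows = []
        for i in range(10):
            for side, nvol in (("L", 1.1), ("R", 1.0)):
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "group": "HC",
                        "structure": "SNc",
                        "sequence": "NM",
                        "side": side,
                        "cr": 0.2,
                        "nvol": nvol,
                    }
                )
        out = asymmetry_table(pd.DataFrame(rows))
        assert len(out) == 10
        assert out["nvol_lr_ratio"].mean() == pytest.approx(1.1)

    def test_missing_side_dropped(self):
        rows = [
            {"subject_id": "s0", "group": "HC", "structure": "SNc",
             "sequence": "NM", "side": "L", "cr": 0.2, "nvol": 1.0},
            {"subject_id": "s1", "group": "HC", "structure": "SNc",
             "sequence": "NM", "side": "L", "cr": 0.2, "nvol": 1.0},
            {"subject_id": "s1", "group": "HC", "structure": "SNc",
             "sequence": "NM", "side": "R", "cr": 0.2, "nvol": 0.9},
        ]
        out = asymmetry_table(pd.DataFrame(rows))
        assert list(out["subject_id"]) == ["s1"]
        assert out.attrs["n_dropped"] == 1
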