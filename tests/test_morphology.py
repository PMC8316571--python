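"""Hit-miss transform, seeds, contours, thickening, and segmentation."""

import numpy as np
import pytest

from otolithct.classify import get_material
from otolithct.morphology import (
    StructuringElementPair,
    border_growth_pairs,
    extract_contour,
    hit_miss,
    identify_seeds,
    segment_aggregates,
    thicken,
)
from otolithct.phantom import default_config, generate_phantom, silence
from otolithct.volume_io import Mask

SPACING = (0.5, 0.18, 0.18)


def mask_of(data):
    return Mask(np.asarray(data, dtype=bool), SPACING)


def brute_force_hmt(x: np.ndarray, b1, b2) -> np.ndarray:
    """Independent oracle: explicit double loop over positions and offsets;
    out-of-bounds probes count as background."""
    out = np.zeros_like(x, dtype=bool)
    shape = x.shape
    for pos in np.ndindex(shape):
        ok = True
        for off in b1:
            q = tuple(p + o for p, o in zip(pos, off))
            inside = all(0 <= qi < ni for qi, ni in zip(q, shape))
            if not (inside and x[q]):
                ok = False
                break
        if ok:
            for off in b2:
                q = tuple(p + o for p, o in zip(pos, off))
                inside = all(0 <= qi < ni for qi, ni in zip(q, shape))
                if inside and x[q]:
                    ok = False
                    break
        out[pos] = ok
    return out


class TestHitMiss:
    def test_identity_probe(self):
        rng = np.random.default_rng(1)
        x = mask_of(rng.random((4, 5, 6)) > 0.5)
        se = StructuringElementPair(b1=[(0, 0, 0)], b2=[])
        np.testing.assert_array_equal(hit_miss(x, se).data, x.data)

    def test_single_voxel_with_background_neighbor(self):
        x = np.zeros((1, 3, 3), dtype=bool)
        x[0, 1, 1] = True
        se = StructuringElementPair(b1=[(0, 0, 0)], b2=[(0, 0, 1)])
        out = hit_miss(mask_of(x), se)
        np.testing.assert_array_equal(out.data, x)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            StructuringElementPair(b1=[(0, 0, 0)], b2=[(0, 0, 0)])

    @pytest.mark.parametrize("case", range(20))
    def test_matches_brute_force_oracle(self, case):
        rng = np.random.default_rng(100 + case)
        x = rng.random((6, 6, 1 if case % 2 else 6)) > 0.4
        n1, n2 = rng.integers(0, 4, size=2)
        offs = [tuple(int(v) for v in rng.integers(-2, 3, size=3)) for _ in range(n1 + n2 + 1)]
        b1, b2 = offs[: n1 + 1], [o for o in offs[n1 + 1 :] if o not in offs[: n1 + 1]]
        se = StructuringElementPair(b1=b1, b2=b2)
        expected = brute_force_hmt(x, se.b1, se.b2)
        np.testing.assert_array_equal(hit_miss(mask_of(x), se).data, expected)

    def test_erosion_identity(self):
        """HMT(X) == erode(X, B1) & erode(~X, B2) -- cross-check against
        scipy's erosion with matching border handling."""
        from scipy import ndimage

        rng = np.random.default_rng(5)
        x = rng.random((7, 7, 7)) > 0.5
        fp1 = np.zeros((3, 3, 3), dtype=bool)
        fp1[1, 1, 1] = fp1[1, 1, 2] = True
        fp2 = np.zeros((3, 3, 3), dtype=bool)
        fp2[1, 0, 1] = True
        se = StructuringElementPair(b1=[(0, 0, 0), (0, 0, 1)], b2=[(0, -1, 0)])
        expected = ndimage.binary_erosion(x, fp1, border_value=0) & ndimage.binary_erosion(
            ~x, fp2, border_value=1
        )
        np.testing.assert_array_equal(hit_miss(mask_of(x), se).data, expected)


class TestSeeds:
    def test_two_disjoint_blobs(self):
        x = np.zeros((3, 8, 8), dtype=bool)
        x[1, 1:3, 1:3] = True
        x[1, 5:7, 5:7] = True
        assert len(identify_seeds(mask_of(x))) == 2

    def test_empty_mask(self):
        assert identify_seeds(mask_of(np.zeros((2, 2, 2)))) == []

    def test_diagonal_touch_depends_on_connectivity(self):
        x = np.zeros((1, 4, 4), dtype=bool)
        x[0, 1, 1] = True
        x[0, 2, 2] = True
        assert len(identify_seeds(mask_of(x), connectivity=26)) == 1
        assert len(identify_seeds(mask_of(x), connectivity=6)) == 2

    def test_seed_is_lexicographically_smallest(self):
        x = np.zeros((2, 3, 3), dtype=bool)
        x[1, 2, 0] = x[1, 2, 1] = x[0, 2, 2] = True
        seeds = identify_seeds(mask_of(x), connectivity=26)
        assert seeds == [(0, 2, 2)]


class TestContour:
    def test_solid_cube_becomes_shell(self):
        x = np.zeros((7, 7, 7), dtype=bool)
        x[1:6, 1:6, 1:6] = True
        contour = extract_contour(mask_of(x), connectivity=6)
        assert contour.count() == 5**3 - 3**3  # 98

    def test_single_voxel_is_its_own_contour(self):
        x = np.zeros((3, 3, 3), dtype=bool)
        x[1, 1, 1] = True
        np.testing.assert_array_equal(extract_contour(mask_of(x)).data, x)

    def test_empty_mask(self):
        assert extract_contour(mask_of(np.zeros((2, 2, 2)))).count() == 0

    def test_never_adds_voxels(self):
        rng = np.random.default_rng(3)
        x = rng.random((5, 6, 7)) > 0.5
        contour = extract_contour(mask_of(x))
        assert not np.any(contour.data & ~x)


class TestThicken:
    def test_grows_one_layer_on_matched_side(self):
        # B1 = left in-plane neighbor foreground, B2 = origin background:
        # matches background voxels directly right of foreground.
        x = np.zeros((1, 4, 4), dtype=bool)
        x[0, 1:3, 1] = True
        se = StructuringElementPair(b1=[(0, 0, -1)], b2=[(0, 0, 0)])
        out = thicken(mask_of(x), se)
        expected = x.copy()
        expected[0, 1:3, 2] = True
        np.testing.assert_array_equal(out.data, expected)

    def test_empty_input_stays_empty(self):
        x = mask_of(np.zeros((2, 3, 3)))
        se = StructuringElementPair(b1=[(0, 0, 1)], b2=[(0, 0, 0)])
        assert thicken(x, se).count() == 0

    def test_non_matching_se_is_identity(self):
        x = np.zeros((1, 3, 3), dtype=bool)
        x[0, 1, 1] = True
        # requires a foreground pair that never occurs
        se = StructuringElementPair(b1=[(0, 0, -1), (0, 0, 1)], b2=[(0, 0, 0)])
        out = thicken(mask_of(x), se)
        np.testing.assert_array_equal(out.data, x)
        again = thicken(out, se)
        np.testing.assert_array_equal(again.data, x)

    def test_never_removes_voxels(self):
        rng = np.random.default_rng(9)
        x = rng.random((4, 6, 6)) > 0.6
        for se in border_growth_pairs():
            out = thicken(mask_of(x), se)
            assert np.all(out.data[x])


class TestSegmentAggregates:
    def test_quiet_phantom_gives_two_regions(self, quiet_phantom):
        vol, truth = quiet_phantom
        regions = segment_aggregates(vol, get_material("CaCO3"))
        assert len(regions) == 2

    def test_no_blobs_gives_empty_result_with_warning(self):
        cfg = silence(default_config(0))
        cfg = cfg.model_copy(update={"maculae": []})
        vol, _ = generate_phantom(cfg)
        with pytest.warns(UserWarning, match="no CaCO3"):
            assert segment_aggregates(vol, get_material("CaCO3")) == []

    def test_noisy_phantom_same_two_labels_with_min_size_filter(self, quiet_phantom, noisy_phantom):
        vol_q, _ = quiet_phantom
        vol_n, truth = noisy_phantom
        quiet_regions = segment_aggregates(vol_q, get_material("CaCO3"))
        noisy_regions = segment_aggregates(vol_n, get_material("CaCO3"), min_voxels=10)
        assert len(noisy_regions) == len(quiet_regions) == 2
        for region in noisy_regions:
            overlaps = [
                2 * (region.mask.data & b.mask.data).sum() / (region.mask.count() + b.mask.count())
                for b in truth.blobs
            ]
            assert max(overlaps) > 0.8  # Dice against the matching truth blob

    def test_labels_partition_filtered_mask(self, noisy_phantom):
        vol, _ = noisy_phantom
        regions = segment_aggregates(vol, get_material("CaCO3"), min_voxels=10)
        union = np.zeros(vol.shape, dtype=int)
        for r in regions:
            union[r.mask.data] += 1
        assert union.max() == 1  # regions are disjoint

    def test_roi_restricts_segmentation(self, quiet_phantom):
        vol, truth = quiet_phantom
        roi = truth.blobs[0].mask  # only the utricle region admitted
        regions = segment_aggregates(vol, get_material("CaCO3"), roi=roi)
        assert len(regions) == 1

    def test_regions_carry_seed_contour_thickened(self, quiet_phantom):
        vol, _ = quiet_phantom
        for r in segment_aggregates(vol, get_material("CaCO3")):
            assert r.mask.data[r.seed]
            assert not np.any(r.contour.data & ~r.mask.data)
            assert np.all(r.thickened.data[r.contour.data])
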