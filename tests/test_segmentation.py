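"""Segmentation chain operators against brute-force oracles and ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from endomatch.geometry import angle_to_centroid, circular_difference
from endomatch.segmentation import (
    GrayImage,
    NoEndoleakCandidate,
    ROISpec,
    SegmentationConfig,
    binarize,
    canny_edges,
    crop_roi,
    denoise_mean,
    extract_regions,
    fill_interior,
    midpoint_of_contact,
    morphological_close,
    segment_endoleak,
)

from conftest import disc_mask


def brute_mean_filter(px: np.ndarray, window: int) -> np.ndarray:
    """Oracle: explicit loop with edge replication."""
    h, w = px.shape
    half = window // 2
    out = np.empty_like(px, dtype=float)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    acc += px[rr, cc]
            out[r, c] = acc / window**2
    return out


class TestCropRoi:
    def test_identity_crop(self):
        img = GrayImage(np.arange(36.0).reshape(6, 6), bit_depth=8)
        out = crop_roi(img, ROISpec(0, 0, 6, 6))
        assert np.array_equal(out.pixels, img.pixels)
        assert out.offset == (0, 0)

    def test_constant_crop(self):
        img = GrayImage(np.full((30, 30), 7.0), bit_depth=8)
        out = crop_roi(img, ROISpec(5, 8, 10, 10))
        assert out.shape == (10, 10)
        assert np.all(out.pixels == 7.0)
        assert out.offset == (5, 8)

    @pytest.mark.parametrize(
        "roi, edge",
        [
            (ROISpec(-1, 0, 5, 5), "top"),
            (ROISpec(0, -2, 5, 5), "left"),
            (ROISpec(16, 0, 5, 5), "bottom"),
            (ROISpec(0, 16, 5, 5), "right"),
        ],
    )
    def test_out_of_bounds_names_edge(self, roi, edge):
        img = GrayImage(np.zeros((20, 20)), bit_depth=8)
        with pytest.raises(ValueError, match=edge):
            crop_roi(img, roi)

    def test_crop_centroid_commutes_with_offset(self):
        """Centroid after crop + offset-add equals centroid on the full frame."""
        full = np.zeros((80, 80))
        full[disc_mask((80, 80), (42.0, 55.0), 9.0)] = 200.0
        img = GrayImage(full, bit_depth=8)
        whole = extract_regions(img.pixels > 100, 1)[0]
        cropped = crop_roi(img, ROISpec(30, 40, 30, 30))
        part = extract_regions(cropped.pixels > 100, 1, offset=cropped.offset)[0]
        assert part.centroid[0] == pytest.approx(whole.centroid[0], abs=1e-9)
        assert part.centroid[1] == pytest.approx(whole.centroid[1], abs=1e-9)


class TestDenoiseMean:
    def test_window_one_is_identity(self):
        img = GrayImage(np.random.default_rng(0).uniform(0, 255, (12, 12)), bit_depth=8)
        assert np.array_equal(denoise_mean(img, 1).pixels, img.pixels)

    def test_constant_unchanged(self):
        img = GrayImage(np.full((9, 9), 42.0), bit_depth=8)
        for w in (3, 5, 7):
            assert np.allclose(denoise_mean(img, w).pixels, 42.0)

    def test_even_window_rejected(self):
        img = GrayImage(np.zeros((5, 5)), bit_depth=8)
        with pytest.raises(ValueError, match="odd"):
            denoise_mean(img, 4)

    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_brute_force_loop(self, window):
        rng = np.random.default_rng(7)
        px = rng.uniform(0, 255, (9, 11))
        img = GrayImage(px, bit_depth=8)
        out = denoise_mean(img, window).pixels
        assert np.allclose(out, brute_mean_filter(px, window), atol=1e-9)

    def test_single_bright_pixel_interior(self):
        px = np.zeros((5, 5))
        px[2, 2] = 90.0
        out = denoise_mean(GrayImage(px, bit_depth=8), 3).pixels
        assert out[2, 2] == pytest.approx(10.0)
        assert out[1, 1] == pytest.approx(10.0)
        assert out[0, 0] == pytest.approx(0.0)


class TestBinarize:
    def test_fixed_threshold_zero_all_true(self):
        img = GrayImage(np.random.default_rng(1).uniform(0, 255, (8, 8)), bit_depth=8)
        assert binarize(img, "fixed", 0).all()

    def test_otsu_separates_bimodal(self):
        px = np.full((20, 20), 10.0)
        px[5:15, 5:15] = 200.0
        mask = binarize(GrayImage(px, bit_depth=8), "otsu")
        assert np.array_equal(mask, px == 200.0)

    def test_otsu_on_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            binarize(GrayImage(np.full((8, 8), 5.0), bit_depth=8), "otsu")

    def test_dice_against_ground_truth(self, default_scene):
        img, truth, spec = default_scene
        mask = binarize(denoise_mean(img, 3), "otsu")
        gt = np.zeros(img.shape, dtype=bool)
        br = spec.branches[0]
        gt |= disc_mask(img.shape, (br.center_row, br.center_col), br.outer_radius)
        gt |= disc_mask(img.shape, truth.endoleak_centroid, spec.endoleak.radius)
        dice = 2 * (mask & gt).sum() / (mask.sum() + gt.sum())
        assert dice >= 0.9


class TestCannyEdges:
    def test_constant_image_empty(self):
        img = GrayImage(np.full((16, 16), 99.0), bit_depth=8)
        assert not canny_edges(img).any()

    def test_disc_edge_is_a_ring_near_true_radius(self):
        shape, center, radius = (120, 120), (60.0, 60.0), 25.0
        px = np.where(disc_mask(shape, center, radius), 200.0, 20.0)
        edges = canny_edges(GrayImage(px, bit_depth=8), sigma=1.0)
        rr, cc = np.nonzero(edges)
        assert len(rr) > 0
        dist = np.hypot(rr - center[0], cc - center[1])
        assert np.all(np.abs(dist - radius) <= 1.5)
        # the ring surrounds the centre: edge pixels span all four quadrants
        assert (rr < 60).any() and (rr > 60).any()
        assert (cc < 60).any() and (cc > 60).any()

    def test_boundary_recall_on_scene(self, default_scene):
        img, truth, spec = default_scene
        edges = canny_edges(denoise_mean(img, 3))
        er, ec = np.nonzero(edges)
        edge_pts = np.stack([er, ec], axis=1)
        br = spec.branches[0]
        for center, radius in [
            ((br.center_row, br.center_col), br.outer_radius),
            (truth.endoleak_centroid, spec.endoleak.radius),
        ]:
            theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
            bound = np.stack(
                [center[0] + radius * np.sin(theta), center[1] + radius * np.cos(theta)],
                axis=1,
            )
            d = np.sqrt(((bound[:, None, :] - edge_pts[None, :, :]) ** 2).sum(-1)).min(1)
            assert (d <= 2.0).mean() >= 0.9


class TestMorphologicalClose:
    def test_solid_disc_unchanged(self):
        m = disc_mask((60, 60), (30.0, 30.0), 15.0)
        assert np.array_equal(morphological_close(m, 3), m)

    def test_bridges_one_pixel_gap_in_ring(self):
        m = disc_mask((60, 60), (30.0, 30.0), 15.5) & ~disc_mask(
            (60, 60), (30.0, 30.0), 14.5
        )
        m[30, 44:46] = False  # cut the ring
        from skimage import measure

        assert measure.label(m, connectivity=2).max() >= 1
        closed = morphological_close(m, 2)
        assert measure.label(closed, connectivity=2).max() == 1
        assert (closed & m).sum() == m.sum()  # extensive: output contains input

    @settings(max_examples=30, deadline=None)
    @given(
        m=hnp.arrays(bool, (24, 24), elements=st.booleans()),
        radius=st.integers(1, 4),
    )
    def test_idempotent_on_random_masks(self, m, radius):
        once = morphological_close(m, radius)
        assert np.array_equal(morphological_close(once, radius), once)
        assert (once & m).sum() == m.sum()  # extensivity


class TestExtractRegions:
    def test_symmetric_block_centroid(self):
        m = np.zeros((10, 10), dtype=bool)
        m[0:3, 0:3] = True
        regions = extract_regions(m, 1)
        assert len(regions) == 1
        assert regions[0].centroid == (1.0, 1.0)
        assert regions[0].pixel_count == 9

    def test_two_discs_centroids_match_analytic(self):
        m = disc_mask((100, 100), (30.0, 30.0), 10.0) | disc_mask(
            (100, 100), (70.0, 60.0), 14.0
        )
        regions = extract_regions(m, 1)
        assert len(regions) == 2
        # sorted by descending area: big disc first
        assert regions[0].centroid[0] == pytest.approx(70.0, abs=0.5)
        assert regions[0].centroid[1] == pytest.approx(60.0, abs=0.5)
        assert regions[1].centroid[0] == pytest.approx(30.0, abs=0.5)

    def test_centroid_matches_pixel_enumeration(self):
        rng = np.random.default_rng(5)
        m = fill_interior(disc_mask((50, 50), (25.0, 20.0), 11.0))
        region = extract_regions(m, 1)[0]
        rr, cc = np.nonzero(m)
        assert region.centroid[0] == pytest.approx(rr.mean(), abs=1e-12)
        assert region.centroid[1] == pytest.approx(cc.mean(), abs=1e-12)

    def test_min_area_filter(self):
        m = np.zeros((10, 10), dtype=bool)
        m[0:3, 0:3] = True
        assert extract_regions(m, 10) == []
        assert extract_regions(np.zeros((5, 5), bool), 1) == []


class TestSegmentEndoleak:
    def test_recovers_scene_within_two_pixels(self, default_scene):
        img, truth, spec = default_scene
        result = segment_endoleak(img)
        assert result.found_endoleak
        ce, ct = result.endoleak.centroid, truth.endoleak_centroid
        assert np.hypot(ce[0] - ct[0], ce[1] - ct[1]) <= 2.0
        assert len(result.branches) == 1
        assert result.branches[0].role_tag == "sg_branch"

    def test_no_endoleak_is_structured_outcome(self):
        from endomatch.synthetic_ct import SyntheticSceneSpec, generate_scene

        img, _ = generate_scene(SyntheticSceneSpec(endoleak=None, seed=2))
        result = segment_endoleak(GrayImage(img.astype(float), bit_depth=8))
        assert isinstance(result, NoEndoleakCandidate)
        assert len(result.branches) == 1

    def test_two_branch_scene_roles(self, two_branch_scene):
        img, truth, spec = two_branch_scene
        result = segment_endoleak(img)
        assert [b.role_tag for b in result.branches] == ["sg_branch", "sg_branch"]
        assert result.endoleak.role_tag == "endoleak"
        ce, ct = result.endoleak.centroid, truth.endoleak_centroid
        assert np.hypot(ce[0] - ct[0], ce[1] - ct[1]) <= 2.0

    def test_translation_equivariance(self):
        from endomatch.synthetic_ct import (
            BranchSpec,
            EndoleakSpec,
            SyntheticSceneSpec,
            generate_scene,
        )

        def scene(dr, dc):
            spec = SyntheticSceneSpec(
                branches=(
                    BranchSpec(
                        center_row=110.0 + dr, center_col=110.0 + dc, outer_radius=35.0
                    ),
                ),
                endoleak=EndoleakSpec(angle_deg=45.0, radial_offset=55.0, radius=10.0),
                noise_sd=0.0,
                blur_sigma=1.0,
            )
            img, _ = generate_scene(spec)
            return segment_endoleak(GrayImage(img.astype(float), bit_depth=8))

        a, b = scene(0, 0), scene(7, -9)
        for ra, rb in [(a.endoleak, b.endoleak), (a.branches[0], b.branches[0])]:
            assert rb.centroid[0] - ra.centroid[0] == pytest.approx(7.0, abs=0.1)
            assert rb.centroid[1] - ra.centroid[1] == pytest.approx(-9.0, abs=0.1)

    def test_seed_point_override(self, two_branch_scene):
        img, truth, spec = two_branch_scene
        cfg = SegmentationConfig(endoleak_seed=truth.endoleak_centroid)
        result = segment_endoleak(img, cfg)
        ce, ct = result.endoleak.centroid, truth.endoleak_centroid
        assert np.hypot(ce[0] - ct[0], ce[1] - ct[1]) <= 2.0

    def test_dice_at_ten_percent_noise(self):
        """Recovered endoleak mask overlaps truth (Dice >= 0.8) at 10% noise."""
        from endomatch.synthetic_ct import EndoleakSpec, SyntheticSceneSpec, generate_scene

        spec = SyntheticSceneSpec(
            endoleak=EndoleakSpec(angle_deg=200.0), noise_sd=15.0, seed=12
        )
        img, truth = generate_scene(spec)
        g = GrayImage(img.astype(float), bit_depth=8)
        result = segment_endoleak(g)
        assert result.found_endoleak
        # rerun the chain to a labelled mask and score the endoleak component
        from skimage import measure

        fg = binarize(denoise_mean(g, 3), "otsu")
        edges = canny_edges(GrayImage(fg.astype(float) * 255, 8))
        solid = fill_interior(morphological_close(edges, 3))
        labels = measure.label(solid, connectivity=2)
        cr, cc_ = result.endoleak.centroid
        lab = labels[int(round(cr)), int(round(cc_))]
        recovered = labels == lab
        gt = disc_mask(img.shape, truth.endoleak_centroid, spec.endoleak.radius)
        dice = 2 * (recovered & gt).sum() / (recovered.sum() + gt.sum())
        assert dice >= 0.8


class TestMidpointOfContact:
    @staticmethod
    def _regions():
        # two branch discs close together with an endoleak bar carved to hug
        # their upper edges: the bar's bottom boundary stays within the
        # contact tolerance of one disc or the other over one contiguous arc
        shape = (200, 200)
        a = disc_mask(shape, (100.0, 85.0), 30.0)
        b = disc_mask(shape, (100.0, 115.0), 30.0)
        e = np.zeros(shape, dtype=bool)
        e[55:80, 50:150] = True
        e &= ~(a | b)
        return (
            extract_regions(e, 1)[0],
            extract_regions(a, 1)[0],
            extract_regions(b, 1)[0],
        )

    def test_symmetric_scene_midpoint_on_axis(self):
        re, ra, rb = self._regions()
        mp = midpoint_of_contact(re, ra, rb, contact_tol=3.0)
        assert mp[1] == pytest.approx(100.0, abs=1.0)  # vertical symmetry axis

    def test_single_arc_midpoint_matches_brute_force(self):
        re, ra, rb = self._regions()
        mp = midpoint_of_contact(re, ra, rb, contact_tol=3.0)
        # oracle: enumerate boundary points in contact with either branch,
        # find the contiguous circular arc containing contacts with both, and
        # take its middle element
        eb = re.boundary
        def near(other):
            d2 = ((eb[:, None, :] - other.boundary[None, :, :]) ** 2).sum(2).min(1)
            return d2 <= 9.0
        na, nb = near(ra), near(rb)
        contact = na | nb
        n = len(eb)
        # rotate to start at a non-contact point, then scan runs
        start = int(np.argmin(contact))
        order = [(i + start) % n for i in range(n)]
        runs, cur = [], []
        for i in order:
            if contact[i]:
                cur.append(i)
            elif cur:
                runs.append(cur)
                cur = []
        if cur:
            runs.append(cur)
        both = [r for r in runs if any(na[i] for i in r) and any(nb[i] for i in r)]
        expected = eb[max(both, key=len)[len(max(both, key=len)) // 2]]
        assert mp[0] == pytest.approx(expected[0], abs=1e-9)
        assert mp[1] == pytest.approx(expected[1], abs=1e-9)

    def test_single_branch_contact_errors(self):
        shape = (200, 200)
        a = disc_mask(shape, (100.0, 60.0), 30.0)
        b = disc_mask(shape, (100.0, 140.0), 30.0)
        e = np.zeros(shape, dtype=bool)
        e[60:75, 20:70] = True
        e &= ~(a | b)
        re = extract_regions(e, 1)[0]
        ra = extract_regions(a, 1)[0]
        rb = extract_regions(b, 1)[0]
        with pytest.raises(ValueError, match="centroid rule"):
            midpoint_of_contact(re, ra, rb, contact_tol=3.0)
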