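"""Slide container, foreground detection, tiling, multi-scale fusion."""

import numpy as np
import pytest

from resmtunet.synthetic import OracleModel, SynthSpec, make_slide
from resmtunet.wsi import (PatchPlan, SlidePyramid, extract_context,
                           fuse_multiscale, infer_slide, otsu_foreground,
                           plan_tiles, resize_bilinear)


def _flat_slide(value=255, size=1024, levels=2):
    lvls = [np.full((size >> i, size >> i, 3), value, dtype=np.uint8)
            for i in range(levels)]
    return SlidePyramid(levels=lvls)


class TestOtsu:
    def test_two_level_image_threshold_between_modes(self):
        """Otsu on a 50/200 mixture: exhaustive between-class-variance search
        as the oracle."""
        rng = np.random.default_rng(0)
        vals = np.where(rng.random((64, 64)) < 0.4, 50, 200).astype(np.uint8)
        img = np.repeat(vals[:, :, None], 3, axis=2)
        slide = SlidePyramid(levels=[img, img[::2, ::2]])
        fg = otsu_foreground(slide)

        gray = vals[::2, ::2] / 255.0
        best_t, best_v = None, -1.0
        for t in np.unique(gray)[:-1]:
            w0 = (gray <= t).mean()
            w1 = 1 - w0
            if w0 == 0 or w1 == 0:
                continue
            m0, m1 = gray[gray <= t].mean(), gray[gray > t].mean()
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best_v:
                best_v, best_t = v, t
        assert 50 / 255 < fg.threshold <= 200 / 255
        assert best_t <= fg.threshold            # same separating interval
        assert np.array_equal(fg.mask, gray < fg.threshold)
        assert fg.mask.any() and (~fg.mask).any()

    def test_all_white_thumbnail_plans_no_tiles(self):
        slide = _flat_slide(255)
        with pytest.warns(UserWarning, match="constant"):
            fg = otsu_foreground(slide)
        assert not fg.mask.any()
        assert plan_tiles(fg, slide) == []

    def test_foreground_area_matches_planted_fraction(self, small_slide):
        fg = otsu_foreground(small_slide.pyramid)
        planted = small_slide.tissue.mean()
        measured = fg.level0(small_slide.mask.shape).mean()
        assert abs(measured - planted) < 0.1 * planted


class TestPlanTiles:
    def test_full_tissue_slide_has_four_tiles(self):
        """1024x1024 all-tissue slide -> exactly four 512px tiles."""
        img = np.full((1024, 1024, 3), 120, dtype=np.uint8)
        img[0, 0] = 255                     # one bright pixel keeps Otsu defined
        slide = SlidePyramid(levels=[img, img[::4, ::4]])
        plans = plan_tiles(otsu_foreground(slide), slide)
        assert len(plans) == 4
        assert {p.origin for p in plans} == {(0, 0), (512, 0), (0, 512),
                                             (512, 512)}

    def test_tiles_never_overlap(self, small_slide):
        plans = plan_tiles(otsu_foreground(small_slide.pyramid),
                           small_slide.pyramid)
        seen = np.zeros(small_slide.pyramid.dimensions, dtype=int)
        for p in plans:
            x, y = p.origin
            seen[y:y + 512, x:x + 512] += 1
        assert seen.max() <= 1

    def test_edge_tile_windows_resolved_by_padding(self):
        """A corner tile's 768/1024 windows extend past the slide but are
        still well-defined 512px images after reflect padding."""
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (1024, 1024, 3)).astype(np.uint8)
        slide = SlidePyramid(levels=[img, img[::4, ::4]])
        plan = PatchPlan(origin=(0, 0))
        windows = extract_context(slide, plan)
        assert all(w.shape == (512, 512, 3) for w in windows)
        assert all(np.isfinite(w).all() for w in windows)


class TestExtractContext:
    def test_constant_slide_gives_equal_constant_windows(self):
        slide = _flat_slide(140)
        windows = extract_context(slide, PatchPlan(origin=(256, 256)))
        for w in windows:
            assert np.allclose(w, 140 / 255.0, atol=1e-9)

    def test_windows_are_concentric(self):
        plan = PatchPlan(origin=(512, 512))
        for size in plan.context_sizes:
            x, y = plan.window_origin(size)
            assert (x + size / 2, y + size / 2) == plan.center

    def test_checkerboard_window_matches_resize_oracle(self):
        rng = np.random.default_rng(0)
        base = np.kron(rng.integers(0, 2, (64, 64)), np.ones((32, 32)))
        img = (base[:, :, None] * 200 + 30).astype(np.uint8).repeat(3, axis=2)
        slide = SlidePyramid(levels=[img, img[::4, ::4]])
        plan = PatchPlan(origin=(512, 512))
        w3 = extract_context(slide, plan)[2]
        x, y = plan.window_origin(1024)
        crop = img[y:y + 1024, x:x + 1024].astype(float) / 255.0
        oracle = _bilinear_oracle(crop, 512, 512)
        assert np.abs(w3 - oracle).max() < 1e-9


def _bilinear_oracle(img, ho, wo):
    """Independent align_corners=False bilinear resampler (vectorized)."""
    h, w = img.shape[:2]
    ys = np.clip((np.arange(ho) + 0.5) * h / ho - 0.5, 0, h - 1)
    xs = np.clip((np.arange(wo) + 0.5) * w / wo - 0.5, 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = (ys - y0)[:, None, None]
    fx = (xs - x0)[None, :, None]
    return (img[np.ix_(y0, x0)] * (1 - fy) * (1 - fx)
            + img[np.ix_(y0, x1)] * (1 - fy) * fx
            + img[np.ix_(y1, x0)] * fy * (1 - fx)
            + img[np.ix_(y1, x1)] * fy * fx)


class TestFuseMultiscale:
    def test_constant_distribution_is_fixed_point(self):
        p = np.array([0.6, 0.25, 0.15])
        maps = [np.broadcast_to(p, (512, 512, 3)).copy() for _ in range(3)]
        fused = fuse_multiscale(maps, PatchPlan(origin=(0, 0)))
        assert np.allclose(fused, p, atol=1e-12)

    def test_three_distinct_constants_average_exactly(self):
        ps = [np.array([0.7, 0.3]), np.array([0.5, 0.5]), np.array([0.2, 0.8])]
        maps = [np.broadcast_to(p, (512, 512, 2)).copy() for p in ps]
        fused = fuse_multiscale(maps, PatchPlan(origin=(0, 0)))
        assert np.allclose(fused, np.mean(ps, axis=0), atol=1e-12)

    def test_spatially_varying_maps_match_geometry_oracle(self):
        """Resize-back + center-crop + average against an independent
        implementation, to 1e-5."""
        rng = np.random.default_rng(1)
        maps = []
        for _ in range(3):
            raw = rng.random((512, 512, 3))
            maps.append(raw / raw.sum(axis=-1, keepdims=True))
        plan = PatchPlan(origin=(0, 0))
        fused = fuse_multiscale(maps, plan)

        acc = np.array(maps[0])
        for m, size in zip(maps[1:], (768, 1024)):
            full = _bilinear_oracle(m, size, size)
            off = (size - 512) // 2
            acc += full[off:off + 512, off:off + 512]
        acc /= 3
        acc /= acc.sum(axis=-1, keepdims=True)
        assert np.abs(fused - acc).max() < 1e-5

    def test_output_stays_on_simplex(self):
        rng = np.random.default_rng(2)
        maps = [rng.dirichlet(np.ones(4), size=(512, 512)) for _ in range(3)]
        fused = fuse_multiscale(maps, PatchPlan(origin=(0, 0)))
        assert np.allclose(fused.sum(axis=-1), 1.0, atol=1e-9)
        assert (fused >= 0).all()


class TestSlidePyramid:
    def test_tiff_roundtrip_with_magnification(self, tmp_path, small_slide):
        path = tmp_path / "slide.tiff"
        small_slide.pyramid.save(path)
        loaded = SlidePyramid.load(path)
        assert loaded.base_magnification == 20.0
        assert len(loaded.levels) == len(small_slide.pyramid.levels)
        assert np.array_equal(loaded.levels[0], small_slide.pyramid.levels[0])

    def test_missing_magnification_requires_override(self, tmp_path):
        import tifffile
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        tifffile.imwrite(tmp_path / "bare.tiff", img)
        with pytest.raises(ValueError, match="magnification"):
            SlidePyramid.load(tmp_path / "bare.tiff")
        loaded = SlidePyramid.load(tmp_path / "bare.tiff", magnification=20)
        assert loaded.base_magnification == 20

    def test_read_region_reflect_padding(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
        slide = SlidePyramid(levels=[img, img[::2, ::2]])
        crop = slide.read_region(-8, -8, 32)
        assert crop.shape == (32, 32, 3)
        assert np.array_equal(crop[8:, 8:], img[:24, :24])


class TestInferSlide:
    def test_oracle_pipeline_identity_small(self, small_slide):
        result = infer_slide(small_slide.pyramid, OracleModel(small_slide),
                             n_labels=5)
        fg = result.foreground.level0(small_slide.mask.shape)
        tile_area = np.zeros_like(fg)
        for p in result.plans:
            x, y = p.origin
            tile_area[y:y + 512, x:x + 512] = True
        sel = fg & tile_area
        assert sel.sum() > 0
        assert (result.labels[sel] == small_slide.mask[sel]).all()

    def test_probabilities_on_simplex(self, small_slide):
        result = infer_slide(small_slide.pyramid,
                             OracleModel(small_slide, temperature=0.7),
                             n_labels=5)
        sums = result.prob_map.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-5)

    def test_output_stride(self, small_slide):
        result = infer_slide(small_slide.pyramid, OracleModel(small_slide),
                             n_labels=5, stride=4)
        assert result.labels.shape == (256, 256)
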