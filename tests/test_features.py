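"""Feature vocabulary: masks, geometry, photometry, GLCM textures, BDS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipogate.events import Mask
from lipogate.features import (
    EmptyMaskError,
    FeatureConfig,
    GLCM_OFFSETS,
    bright_detail_similarity_r3,
    build_feature_table,
    extract_features,
    geometry_features,
    haralick_features,
    intensity_features,
    molecules_in_sphere,
    object_mask,
    quantize,
)
from lipogate.synthetic import DEFAULT_OPTICS, PhenotypeSpec, render_event

from conftest import make_event


def disk_mask(shape, center, radius):
    ys, xs = np.indices(shape)
    return np.hypot(ys - center[0], xs - center[1]) <= radius


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


class TestObjectMask:
    def test_sphere_mask_covers_ground_truth_disk(self, clean_sphere_event,
                                                  optics):
        mask = object_mask(clean_sphere_event)
        n0, n1 = mask.region.shape
        cfg = FeatureConfig()
        # design target: the object disk plus the PSF spread and the
        # configured mask dilation
        r_px = (4.0 + optics.psf_sigma_infocus) / optics.pixel_size \
            + cfg.dilation_radius
        truth = disk_mask((n0, n1), ((n0 - 1) / 2, (n1 - 1) / 2), r_px)
        inter = (mask.region & truth).sum()
        union = (mask.region | truth).sum()
        assert inter / union >= 0.85
        # lumen included despite the dark interior of the ring
        assert mask.region[n0 // 2, n1 // 2]

    def test_background_only_tile_raises(self):
        rng = np.random.default_rng(0)
        ev = make_event({"membrane": rng.normal(10, 1, (60, 60)).clip(0)})
        with pytest.raises(EmptyMaskError):
            object_mask(ev)

    def test_doublet_mask_is_single_component(self, optics):
        from scipy import ndimage

        ev = render_event(
            PhenotypeSpec(shape_class="doublet", diameter=7.0), optics, 3,
            noise=False,
        )
        mask = object_mask(ev)
        _, n = ndimage.label(mask.region)
        assert n == 1


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


class TestGeometryFeatures:
    def test_disk_area_matches_pixel_count_oracle(self):
        region = disk_mask((64, 64), (31.5, 31.5), 15.0)
        feats = geometry_features(Mask(region, "m"), pixel_size=0.5)
        assert feats["area"] == pytest.approx(region.sum() * 0.25)
        # and the discrete disk is close to pi r^2
        assert feats["area"] == pytest.approx(math.pi * 7.5**2, rel=0.03)
        assert feats["aspect_ratio"] > 0.97

    def test_ellipse_aspect_ratio(self):
        ys, xs = np.indices((80, 80))
        region = ((xs - 40) / 20.0) ** 2 + ((ys - 40) / 10.0) ** 2 <= 1.0
        feats = geometry_features(Mask(region, "m"), pixel_size=1.0)
        assert feats["aspect_ratio"] == pytest.approx(0.50, abs=0.02)

    def test_circularity_orders_disk_above_capsule(self):
        disk = disk_mask((80, 80), (39.5, 39.5), 14.0)
        # 3:1 capsule of roughly equal area
        ys, xs = np.indices((80, 80))
        half, r = 16.0, 8.0
        d = np.hypot(np.clip(np.abs(xs - 39.5) - half, 0, None), ys - 39.5)
        capsule = d <= r
        c_disk = geometry_features(Mask(disk, "m"), 1.0)["circularity"]
        c_cap = geometry_features(Mask(capsule, "m"), 1.0)["circularity"]
        assert c_disk > c_cap > 0

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            geometry_features(Mask(np.zeros((8, 8), bool), "m"), 1.0)


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------


class TestIntensityFeatures:
    def test_constant_image_gives_zero_texture(self):
        ev = make_event({"m": np.full((40, 40), 55.0)})
        mask = Mask(disk_mask((40, 40), (19.5, 19.5), 10), "m")
        feats = intensity_features(ev, mask, "m")
        assert feats["intensity"] == 0.0
        assert feats["std_dev"] == 0.0
        assert feats["gradient_rms"] == 0.0
        assert feats["contrast"] == 0.0

    def test_compactness_ranks_blob_above_uniform(self):
        shape = (60, 60)
        mask = Mask(disk_mask(shape, (29.5, 29.5), 14), "m")
        ys, xs = np.indices(shape)
        blob = 1000.0 * np.exp(-((ys - 29.5) ** 2 + (xs - 29.5) ** 2) / 8.0)
        uniform = np.where(mask.region, blob.sum() / mask.n_pixels, 0.0)
        f_blob = intensity_features(make_event({"m": blob}), mask, "m")
        f_uni = intensity_features(make_event({"m": uniform}), mask, "m")
        assert f_blob["compactness"] > f_uni["compactness"]
        # radius-of-gyration oracle for the uniform disk: r_gyr = R/sqrt(2)
        r_eq = math.sqrt(mask.n_pixels / math.pi)
        ys, xs = np.nonzero(mask.region)
        r2 = ((ys - ys.mean()) ** 2 + (xs - xs.mean()) ** 2).mean()
        assert f_uni["compactness"] == pytest.approx(r_eq / math.sqrt(r2),
                                                     rel=1e-6)

    def test_intensity_linearity_and_scale_invariance(self, sphere_event):
        mask = object_mask(sphere_event)
        base = intensity_features(sphere_event, mask, "membrane")
        scaled_ev = make_event(
            {"membrane": 3.0 * sphere_event.channels["membrane"]},
            pixel_size=sphere_event.pixel_size,
        )
        scaled = intensity_features(scaled_ev, mask, "membrane")
        assert scaled["intensity"] == pytest.approx(3 * base["intensity"], rel=1e-9)
        assert scaled["max_pixel"] == pytest.approx(3 * base["max_pixel"], rel=1e-9)
        assert scaled["gradient_rms"] == pytest.approx(base["gradient_rms"], rel=1e-9)
        assert scaled["contrast"] == pytest.approx(base["contrast"], rel=1e-9)
        h_base = haralick_features(sphere_event, mask, "membrane")
        h_scaled = haralick_features(scaled_ev, mask, "membrane")
        for k in h_base:
            assert h_scaled[k] == pytest.approx(h_base[k], abs=1e-9)

    def test_gradient_rms_strictly_decreasing_in_blur(self, optics):
        values = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            ev = render_event(
                PhenotypeSpec(diameter=8.0, defocus_sigma=sigma), optics, 9,
                noise=False,
            )
            mask = object_mask(ev)
            values.append(intensity_features(ev, mask, "membrane")["gradient_rms"])
        assert all(a > b for a, b in zip(values, values[1:]))


# ---------------------------------------------------------------------------
# GLCM / Haralick
# ---------------------------------------------------------------------------


def glcm_oracle(img, mask, offset, levels):
    """Brute-force pair enumeration: the independent GLCM reference."""
    q = quantize(np.asarray(img, float), mask, levels)
    dr, dc = offset
    counts = np.zeros((levels, levels))
    n0, n1 = q.shape
    for r in range(n0):
        for c in range(n1):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < n0 and 0 <= c2 < n1 and mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def oracle_stats(p):
    levels = p.shape[0]
    i = np.arange(levels)
    homog = corr = ent = con = 0.0
    mu = sum(i[a] * p[a].sum() for a in range(levels))
    var = sum((a - mu) ** 2 * p[a].sum() for a in range(levels))
    for a in range(levels):
        for b in range(levels):
            homog += p[a, b] / (1 + abs(a - b))
            con += p[a, b] * (a - b) ** 2
            if p[a, b] > 0:
                ent -= p[a, b] * math.log(p[a, b])
            if var > 0:
                corr += (a - mu) * (b - mu) * p[a, b] / var
    return {"homogeneity": homog, "correlation": corr, "entropy": ent,
            "contrast": con}


class TestHaralick:
    def test_constant_image_conventions(self):
        ev = make_event({"m": np.full((20, 20), 7.0)})
        mask = Mask(np.ones((20, 20), bool), "m")
        h = haralick_features(ev, mask, "m", levels=32, granularity=1)
        assert h["h_homogeneity_mean"] == pytest.approx(1.0)
        assert h["h_contrast_mean"] == pytest.approx(0.0)
        assert h["h_entropy_mean"] == pytest.approx(0.0)
        assert h["h_correlation_mean"] == pytest.approx(0.0)  # sigma = 0

    def test_checkerboard_contrast_is_one(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 100.0
        ev = make_event({"m": board})
        mask = Mask(np.ones((4, 4), bool), "m")
        # horizontal-offset oracle: every pair differs by one level
        p = glcm_oracle(board, mask.region, (0, 1), 2)
        assert oracle_stats(p)["contrast"] == pytest.approx(1.0)
        h = haralick_features(ev, mask, "m", levels=2, granularity=1)
        # all 4 offsets of a checkerboard: ->, v see (0,1); diagonals see equal
        assert h["h_contrast_mean"] == pytest.approx(
            np.mean([1.0, 1.0, 0.0, 0.0]))

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        n0=st.integers(2, 8),
        n1=st.integers(2, 8),
        levels=st.integers(2, 8),
        data=st.data(),
    )
    def test_matches_bruteforce_oracle_on_small_images(self, n0, n1, levels,
                                                       data):
        img = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, 20), min_size=n1, max_size=n1),
                    min_size=n0, max_size=n0,
                )
            ),
            dtype=float,
        )
        mask_bits = np.array(
            data.draw(
                st.lists(
                    st.lists(st.booleans(), min_size=n1, max_size=n1),
                    min_size=n0, max_size=n0,
                )
            )
        )
        mask_bits[0, :2] = True  # guarantee at least one horizontal pair
        ev = make_event({"m": img})
        ours = haralick_features(ev, Mask(mask_bits, "m"), "m",
                                 levels=levels, granularity=1)
        per_offset = {k: [] for k in ("homogeneity", "correlation", "entropy",
                                      "contrast")}
        for off in GLCM_OFFSETS:
            p = glcm_oracle(img, mask_bits, off, levels)
            if p is None:
                continue
            for k, v in oracle_stats(p).items():
                per_offset[k].append(v)
        for k, vals in per_offset.items():
            assert ours[f"h_{k}_mean"] == pytest.approx(np.mean(vals), abs=1e-9)
            assert ours[f"h_{k}_std"] == pytest.approx(np.std(vals), abs=1e-9)

    def test_homogeneity_bounds(self, sphere_event):
        mask = object_mask(sphere_event)
        h = haralick_features(sphere_event, mask, "membrane")
        assert 0 < h["h_homogeneity_mean"] <= 1


# ---------------------------------------------------------------------------
# bright-detail similarity
# ---------------------------------------------------------------------------


class TestBrightDetailSimilarity:
    def test_identical_channels_score_capped_max(self):
        rng = np.random.default_rng(1)
        img = rng.poisson(50, (60, 60)).astype(float)
        ev = make_event({"a": img, "b": img.copy()})
        mask = Mask(np.ones((60, 60), bool), "a")
        score = bright_detail_similarity_r3(ev, mask, "a", "b")
        assert score == pytest.approx(6.0, abs=1e-6)

    def test_independent_noise_scores_near_zero(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(50, (110, 110)).astype(float)
        b = rng.poisson(50, (110, 110)).astype(float)
        ev = make_event({"a": a, "b": b})
        mask = Mask(np.ones((110, 110), bool), "a")
        assert abs(bright_detail_similarity_r3(ev, mask, "a", "b")) < 0.1

    def test_zero_variance_detail_scores_zero(self):
        ev = make_event({"a": np.full((30, 30), 9.0),
                         "b": np.full((30, 30), 4.0)})
        mask = Mask(np.ones((30, 30), bool), "a")
        assert bright_detail_similarity_r3(ev, mask, "a", "b") == 0.0

    def test_membrane_reporter_colocalizes_more_than_lumen(self, optics):
        mem_spec = PhenotypeSpec(diameter=8.0, reporter_pattern="membrane",
                                 reporter_brightness=150.0)
        lum_spec = PhenotypeSpec(diameter=8.0, reporter_pattern="lumen",
                                 reporter_brightness=150.0)
        scores = {}
        for name, spec in (("mem", mem_spec), ("lum", lum_spec)):
            ev = render_event(spec, optics, 21)
            mask = object_mask(ev)
            scores[name] = bright_detail_similarity_r3(ev, mask, "membrane",
                                                       "reporter")
        assert scores["mem"] > scores["lum"]


# ---------------------------------------------------------------------------
# molecule count + composition
# ---------------------------------------------------------------------------


class TestMoleculesInSphere:
    def test_detection_limit_worked_example(self):
        n = molecules_in_sphere(500e-9, 4.0)
        assert n == pytest.approx(1.0e4, rel=0.02)

    def test_zero_concentration(self):
        assert molecules_in_sphere(0.0, 5.0) == 0.0

    def test_hand_unit_analysis(self):
        # 1 M in a 1 um sphere: (pi/6)*1e-15 L * 6.022e23 / L
        assert molecules_in_sphere(1.0, 1.0) == pytest.approx(3.153e8, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            molecules_in_sphere(-1e-9, 4.0)
        with pytest.raises(ValueError):
            molecules_in_sphere(1e-9, 0.0)


class TestExtractFeatures:
    def test_feature_vector_invariants_on_render(self, sphere_event):
        row = extract_features(sphere_event)
        assert row["mask_ok"] == 1.0
        assert row["area"] > 0
        assert 0 < row["aspect_ratio"] <= 1
        assert 0 < row["h_homogeneity_mean_membrane"] <= 1
        assert all(np.isfinite(v) for v in row.values())

    def test_translation_invariance(self, sphere_event):
        rolled = make_event(
            {k: np.roll(v, (4, -3), axis=(0, 1))
             for k, v in sphere_event.channels.items()},
            pixel_size=sphere_event.pixel_size,
        )
        a = extract_features(sphere_event)
        b = extract_features(rolled)
        for k in a:
            assert b[k] == pytest.approx(a[k], abs=1e-9)

    def test_table_stable_columns_and_determinism(self, optics):
        events = [
            render_event(PhenotypeSpec(diameter=5 + i), optics, i,
                         event_id=f"e{i}")
            for i in range(4)
        ]
        t1 = build_feature_table(events)
        t2 = build_feature_table(events)
        assert list(t1.columns) == list(t2.columns)
        assert t1.equals(t2)
        assert len(t1) == 4

    def test_missing_channel_is_configuration_error(self, sphere_event):
        cfg = FeatureConfig(channels=("membrane", "nonexistent"))
        with pytest.raises(KeyError):
            extract_features(sphere_event, cfg)

    def test_empty_mask_flagged_not_dropped(self):
        rng = np.random.default_rng(3)
        ev = make_event({"membrane": rng.normal(10, 1, (60, 60)).clip(0),
                         "reporter": np.zeros((60, 60))})
        row = extract_features(ev)
        assert row["mask_ok"] == 0.0
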