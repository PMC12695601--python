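"""Connected components, per-region geometry, skeleton length, refinement."""

from collections import deque
from dataclasses import replace

import numpy as np
import pytest
from skimage import draw, morphology

from ciliascope import (
    CiliumRecord,
    RGBImage,
    RefinementThresholds,
    SceneSpec,
    detect_cilia,
    label_components,
    refine_candidates,
    region_features,
    skeleton_length,
)
from ciliascope.synthetic import fixture_detection_config


def flood_fill_labels(mask, connectivity=8):
    """Brute-force BFS connected-component labeling oracle."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            nxt += 1
            queue = deque([(r0, c0)])
            labels[r0, c0] = nxt
            while queue:
                r, c = queue.popleft()
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not labels[rr, cc]
                    ):
                        labels[rr, cc] = nxt
                        queue.append((rr, cc))
    return labels


def moment_ellipse_oracle(coords):
    """Direct-summation second-central-moment ellipse of a pixel set."""
    coords = np.asarray(coords, dtype=float)
    center = coords.mean(axis=0)
    d = coords - center
    cov = np.array(
        [
            [(d[:, 0] ** 2).mean(), (d[:, 0] * d[:, 1]).mean()],
            [(d[:, 0] * d[:, 1]).mean(), (d[:, 1] ** 2).mean()],
        ]
    )
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    major = 4.0 * np.sqrt(max(eigvals[0], 0.0))
    minor = 4.0 * np.sqrt(max(eigvals[1], 0.0))
    ecc = np.sqrt(1.0 - eigvals[1] / eigvals[0]) if eigvals[0] > 0 else 0.0
    return center, major, minor, ecc


class TestLabelComponents:
    def test_disjoint_blobs(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        mask[6:8, 6:8] = True
        assert label_components(mask).max() == 2

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert label_components(mask, connectivity=8).max() == 1
        assert label_components(mask, connectivity=4).max() == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(20):
            mask = rng.uniform(size=(16, 16)) < 0.4
            ours = label_components(mask, connectivity)
            oracle = flood_fill_labels(mask, connectivity)
            assert ours.max() == oracle.max()
            # identical partitions up to label permutation
            for k in range(1, oracle.max() + 1):
                assert len(np.unique(ours[oracle == k])) == 1


class TestRegionFeatures:
    def test_symmetric_disk_eccentricity_zero(self):
        labels = np.zeros((40, 40), dtype=int)
        rr, cc = draw.disk((20, 20), 12)
        labels[rr, cc] = 1
        rec = region_features(labels, 1)
        assert rec.eccentricity == 0.0
        assert rec.area == len(rr)

    def test_one_pixel_wide_segment_eccentricity_one(self):
        labels = np.zeros((10, 40), dtype=int)
        labels[5, 5:35] = 1
        rec = region_features(labels, 1)
        assert rec.eccentricity == 1.0
        assert rec.axis_minor_length == 0.0
        assert rec.bounding_box == (5, 5, 6, 35)

    def test_moments_match_direct_summation_oracle(self, rng):
        for _ in range(15):
            labels = np.zeros((24, 24), dtype=int)
            mask = rng.uniform(size=(24, 24)) < 0.3
            if not mask.any():
                continue
            comp = label_components(mask) == 1
            labels[comp] = 7
            rec = region_features(labels, 7, compute_skeleton=False)
            center, major, minor, ecc = moment_ellipse_oracle(np.argwhere(comp))
            assert rec.centroid == pytest.approx(tuple(center))
            assert rec.axis_major_length == pytest.approx(major, abs=1e-8)
            assert rec.axis_minor_length == pytest.approx(minor, abs=1e-8)
            assert rec.eccentricity == pytest.approx(ecc, abs=1e-8)

    def test_form_factor_of_large_disk_near_one(self):
        labels = np.zeros((120, 120), dtype=int)
        rr, cc = draw.disk((60, 60), 50)
        labels[rr, cc] = 1
        rec = region_features(labels, 1, compute_skeleton=False)
        assert rec.form_factor == pytest.approx(1.0, rel=0.10)

    def test_missing_id_raises(self):
        with pytest.raises(KeyError):
            region_features(np.zeros((5, 5), dtype=int), 3)

    def test_single_pixel_degenerate(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[2, 2] = 1
        rec = region_features(labels, 1)
        assert rec.eccentricity == 0.0
        assert rec.axis_major_length == 0.0
        assert rec.skeleton_length == 0.0


class TestSkeletonLength:
    def test_straight_line_of_n_pixels(self):
        mask = np.zeros((5, 30), dtype=bool)
        mask[2, 3:27] = True  # 24 pixels
        assert skeleton_length(mask) == pytest.approx(23.0)

    def test_diagonal_line_uses_sqrt2_weights(self):
        n = 20
        mask = np.eye(n, dtype=bool)
        assert skeleton_length(mask) == pytest.approx((n - 1) * np.sqrt(2.0))

    def test_bent_filament_tracks_arc_length(self):
        # quarter-circle arc of radius 40: arc length = 20*pi
        radius, width = 40.0, 3
        thetas = np.linspace(0.0, np.pi / 2, 200)
        pts = np.stack([10 + radius * np.sin(thetas), 10 + radius * np.cos(thetas)], axis=1)
        mask = np.zeros((64, 64), dtype=bool)
        idx = np.round(pts).astype(int)
        mask[idx[:, 0], idx[:, 1]] = True
        mask = morphology.dilation(mask, morphology.disk(width // 2))
        arc = radius * np.pi / 2
        assert skeleton_length(mask) == pytest.approx(arc, rel=0.10)

    def test_empty_and_single_pixel(self):
        with pytest.raises(ValueError):
            skeleton_length(np.zeros((4, 4), dtype=bool))
        single = np.zeros((4, 4), dtype=bool)
        single[2, 2] = True
        assert skeleton_length(single) == 0.0

    def test_skeleton_tracks_major_axis_for_straight_thin_ellipses(self):
        # continuum relation for an ellipse: centerline = major - 2*b^2/a,
        # so the skeleton trails the major axis by at most ~the minor axis
        for a, b in [(25, 2.5), (25, 4.0), (30, 2.0), (30, 5.0)]:
            labels = np.zeros((80, 80), dtype=int)
            rr, cc = draw.ellipse(40, 40, b, a)
            labels[rr, cc] = 1
            rec = region_features(labels, 1)
            assert rec.skeleton_length >= rec.axis_major_length - rec.axis_minor_length - 2.0

    def test_bent_filament_skeleton_exceeds_major_axis(self):
        # the ellipse proxy under-measures curved filaments; the skeleton does not
        radius = 40.0
        thetas = np.linspace(0.0, np.pi, 300)  # half circle
        pts = np.stack([50 + radius * np.sin(thetas), 50 + radius * np.cos(thetas)], axis=1)
        mask = np.zeros((100, 100), dtype=bool)
        idx = np.round(pts).astype(int)
        mask[idx[:, 0], idx[:, 1]] = True
        mask = morphology.dilation(mask, morphology.disk(1))
        labels = mask.astype(int)
        rec = region_features(labels, 1)
        assert rec.skeleton_length > rec.axis_major_length


class TestRefinement:
    def _records(self, **overrides):
        base = dict(
            instance_id=1, area=300.0, perimeter=80.0, centroid=(0.0, 0.0),
            eccentricity=0.9, form_factor=0.4, axis_minor_length=4.0,
            axis_major_length=40.0, skeleton_length=38.0,
            bounding_box=(1, 1, 5, 5), touches_edge=False,
        )
        base.update(overrides)
        return CiliumRecord(**base)

    def test_circular_blob_removed_by_default_eccentricity(self):
        circle = self._records(eccentricity=0.0)
        assert refine_candidates([circle], RefinementThresholds()) == []

    def test_thresholds_are_inclusive(self):
        exact = self._records(
            skeleton_length=14.0, area=256.0, eccentricity=0.46, perimeter=67.0
        )
        assert refine_candidates([exact], RefinementThresholds()) == [exact]

    def test_edge_exclusion_flag(self):
        edge = self._records(touches_edge=True)
        assert refine_candidates([edge], RefinementThresholds(exclude_edge=True)) == []
        assert refine_candidates([edge], RefinementThresholds()) == [edge]

    @pytest.mark.parametrize(
        "field", ["min_length", "min_area", "min_eccentricity", "min_perimeter"]
    )
    def test_tightening_any_threshold_is_monotone(self, rng, field):
        records = [
            self._records(
                instance_id=i,
                area=rng.uniform(0, 600),
                perimeter=rng.uniform(0, 150),
                eccentricity=rng.uniform(0, 1),
                skeleton_length=rng.uniform(0, 60),
            )
            for i in range(40)
        ]
        base = RefinementThresholds(
            min_length=0, min_area=0, min_eccentricity=0, min_perimeter=0
        )
        counts = []
        for value in np.linspace(0, 1, 11):
            scale = {"min_length": 60, "min_area": 600, "min_eccentricity": 1, "min_perimeter": 150}
            thr = replace(base, **{field: value * scale[field]})
            counts.append(len(refine_candidates(records, thr)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_refinement_is_a_sublist_filter(self, rng):
        records = [self._records(instance_id=i, eccentricity=rng.uniform(0, 1)) for i in range(10)]
        kept = refine_candidates(records, RefinementThresholds())
        ids = [r.instance_id for r in records]
        assert [r.instance_id for r in kept] == [i for i in ids if records[i].eccentricity >= 0.46]


class TestDetectCilia:
    def test_blank_image_gives_no_records(self):
        img = RGBImage(np.zeros((128, 128, 3)))
        assert detect_cilia(img, fixture_detection_config(SceneSpec(image_size=128))) == []

    def test_filaments_detected_dots_rejected(self):
        # 5 bright bars above all scaled thresholds, 3 compact dots below
        spec = SceneSpec()
        pixels = np.zeros((512, 512, 3))
        bars = [
            ((60, 60), (60, 130)),
            ((150, 400), (220, 400)),
            ((300, 60), (350, 110)),
            ((430, 200), (430, 270)),
            ((80, 300), (140, 340)),
        ]
        stroke = np.zeros((512, 512), dtype=bool)
        for (r0, c0), (r1, c1) in bars:
            rr, cc = draw.line(r0, c0, r1, c1)
            stroke[rr, cc] = True
        stroke = morphology.dilation(stroke, morphology.disk(1))
        pixels[:, :, 1][stroke] = 0.9
        for center in [(250, 250), (400, 80), (480, 480)]:
            rr, cc = draw.disk(center, 2, shape=(512, 512))
            pixels[rr, cc, 1] = 0.9
        records = detect_cilia(RGBImage(pixels), fixture_detection_config(spec))
        assert len(records) == 5

    def test_detection_is_deterministic(self, default_scene):
        _, image, _, config = default_scene
        first = detect_cilia(image, config)
        second = detect_cilia(image, config)
        assert len(first) == len(second)
        for a, b in zip(first, second):
            assert a.skeleton_length == b.skeleton_length
            assert a.area == b.area
            np.testing.assert_array_equal(a.pixel_coords, b.pixel_coords)

    def test_length_um_reported_when_pixel_size_configured(self, default_scene):
        _, image, _, config = default_scene
        config_um = replace(config, pixel_size=0.2)
        records = detect_cilia(image, config_um)
        assert records
        for rec in records:
            assert rec.length_um == pytest.approx(rec.skeleton_length * 0.2)
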