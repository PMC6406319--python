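"""Nucleus extraction, circularity and box-counting fractal dimension."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from skimage.transform import rotate

from histoflux import (SectionImage, SyntheticSpec, box_counts,
                       circularity_from_mask, distance_field, extract_nuclei,
                       fractal_dimension, generate_section, proximal_filter,
                       render_nucleus)

from conftest import disk_mask, square_mask, koch_prefractal


def _nuclei_section(img, px=1.0):
    z = np.zeros_like(img, dtype=float)
    return SectionImage(img.astype(float), z, z, px)


class TestCircularity:
    def test_disk_is_one(self):
        assert circularity_from_mask(disk_mask(50)) == pytest.approx(1.0, abs=0.02)

    def test_square_is_pi_over_four(self):
        assert circularity_from_mask(square_mask(80)) \
            == pytest.approx(np.pi / 4, abs=0.02)

    def test_capped_near_one(self):
        for r in (10, 20, 35):
            assert circularity_from_mask(disk_mask(r)) <= 1.05

    def test_degenerate_object_rejected(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        with pytest.raises(ValueError, match="degenerate"):
            circularity_from_mask(m)

    @pytest.mark.parametrize("angle", [20, 45, 70])
    def test_rotation_invariance(self, angle):
        base = square_mask(60, pad=40).astype(float)
        rot = rotate(base, angle, order=0) > 0.5
        c0 = circularity_from_mask(square_mask(60))
        assert circularity_from_mask(rot) == pytest.approx(c0, rel=0.02)

    def test_scale_invariance(self):
        c1 = circularity_from_mask(disk_mask(25))
        c2 = circularity_from_mask(disk_mask(50))
        assert c1 == pytest.approx(c2, rel=0.02)


class TestFractalDimension:
    def test_straight_line_is_one(self):
        pts = np.column_stack([np.linspace(0, 1000, 2000),
                               np.linspace(0, 400, 2000)])
        fd, r2 = fractal_dimension(pts)
        assert fd == pytest.approx(1.0, abs=0.05)
        assert r2 > 0.99

    def test_koch_prefractal_matches_theory(self):
        fd, r2 = fractal_dimension(koch_prefractal())
        assert fd == pytest.approx(np.log(4) / np.log(3), abs=0.05)
        assert r2 > 0.99

    def test_smooth_closed_curve_is_one(self):
        th = np.linspace(0, 2 * np.pi, 1500, endpoint=False)
        pts = np.column_stack([200 * np.cos(th), 200 * np.sin(th)])
        fd, _ = fractal_dimension(pts)
        assert fd == pytest.approx(1.0, abs=0.05)

    def test_point_order_irrelevant(self):
        pts = koch_prefractal()
        rng = np.random.default_rng(0)
        shuffled = pts[rng.permutation(len(pts))]
        assert fractal_dimension(pts)[0] == pytest.approx(
            fractal_dimension(shuffled)[0], abs=1e-12)

    def test_stable_under_grid_offsets(self):
        pts = koch_prefractal()
        vals = [fractal_dimension(pts, seed=s)[0] for s in range(4)]
        assert max(vals) - min(vals) <= 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="points"):
            fractal_dimension(np.zeros((5, 2)))

    def test_box_counts_match_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.integers(0, 64, size=(200, 2)).astype(float)
        sizes = np.array([2.0, 4.0, 8.0, 16.0])
        counts = box_counts(pts, sizes, n_offsets=1)
        lo = pts.min(axis=0)
        for eps, n in zip(sizes, counts):
            occupied = set()
            for p in pts:  # exhaustive O(N) per point, zero-offset grid
                occupied.add((int((p[0] - lo[0]) // eps),
                              int((p[1] - lo[1]) // eps)))
            assert n == len(occupied)


class TestExtractNuclei:
    def test_recovers_all_intact_nuclei(self):
        spec = SyntheticSpec(rng_seed=2, n_nuclei=50, frac_fragmented=0.0)
        section, truth = generate_section(spec)
        objects = extract_nuclei(section)
        assert len(objects) == len(truth.nuclei) == 50

    def test_blank_image_gives_empty_list(self):
        sec = _nuclei_section(np.zeros((64, 64)))
        assert extract_nuclei(sec) == []

    def test_fragmented_nucleus_splits_unless_merged(self):
        img = np.zeros((90, 90))
        mask = render_nucleus("fragmented", 2.0, 4, radius_px=22)
        from scipy import ndimage
        lab, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, lab, range(1, n + 1))
        n_lobes = int(np.sum(sizes >= 5))  # lobes the size filter keeps
        assert n_lobes >= 2
        img[10:10 + mask.shape[0], 10:10 + mask.shape[1]] = mask * 2000.0
        sec = _nuclei_section(img)
        split = extract_nuclei(sec, min_size_px=5)
        assert len(split) == n_lobes
        merged = extract_nuclei(sec, min_size_px=5, merge_radius_px=30.0)
        assert len(merged) == 1
        assert merged[0].n_components == n_lobes
        # joint measurement: fragmentation lowers circularity
        assert merged[0].circularity < 0.7

    def test_min_size_filter_discards_specks(self):
        img = np.zeros((80, 80))
        img[30:50, 30:50] = 1000.0   # 20x20 object
        img[5:7, 5:7] = 1000.0       # 2x2 speck
        sec = _nuclei_section(img)
        # min_size applies to the LoG interior; a 2x2 speck blurs to ~30 px
        both = extract_nuclei(sec, min_size_px=12)
        assert len(both) == 2
        objects = extract_nuclei(sec, min_size_px=100)
        assert len(objects) == 1
        assert objects[0].area_px > 300

    def test_fragmented_cohort_contrasts(self):
        """Fragmented nuclei: lower circularity, higher fractal dimension."""
        base = dict(image_shape=(512, 512), n_nuclei=120, nucleus_radius_um=8.0,
                    fragmentation_severity=2.0)
        intact_sec, _ = generate_section(SyntheticSpec(rng_seed=21,
                                                       frac_fragmented=0.0, **base))
        frag_sec, _ = generate_section(SyntheticSpec(rng_seed=21,
                                                     frac_fragmented=1.0, **base))
        merge_px = 8.0  # above the inter-fragment gap, below nucleus spacing
        intact = extract_nuclei(intact_sec, merge_radius_px=merge_px)
        frag = extract_nuclei(frag_sec, merge_radius_px=merge_px)
        assert np.nanmean([o.circularity for o in frag]) \
            < np.nanmean([o.circularity for o in intact])
        assert np.nanmean([o.fractal_dimension for o in frag]) \
            > np.nanmean([o.fractal_dimension for o in intact])


class TestSeverityMonotonicity:
    def test_circularity_down_fd_up_with_severity(self):
        grid = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
        mean_circ, mean_fd = [], []
        for sev in grid:
            circs, fds = [], []
            for seed in range(40):
                mask = render_nucleus("fragmented", sev, 1000 + seed,
                                      radius_px=20)
                circs.append(circularity_from_mask(mask))
                from histoflux.radiomics import mask_contours
                pts = np.vstack([c for c in mask_contours(np.pad(mask, 2))
                                 if len(c) >= 2])
                fds.append(fractal_dimension(pts, seed=seed)[0])
            mean_circ.append(np.mean(circs))
            mean_fd.append(np.mean(fds))
        assert spearmanr(grid, mean_circ).statistic <= -0.9
        assert spearmanr(grid, mean_fd).statistic >= 0.9


class TestProximalFilter:
    def test_boundary_inclusion(self):
        from histoflux.radiomics import NucleusObject

        def obj(row):
            return NucleusObject(label=1, contour=np.zeros((16, 2)),
                                 area_px=10, perimeter_px=10, circularity=1.0,
                                 fractal_dimension=1.0, fd_r2=1.0,
                                 centroid_rc=(row, 0.0))

        dist = np.tile(np.arange(100.0)[:, None], (1, 4))  # 1 um per row
        near, far = obj(79.0), obj(81.0)
        kept = proximal_filter([near, far], dist, max_dist_um=80.0)
        assert kept == [near]
        assert far.distance_to_vessel_um == pytest.approx(81.0)

    def test_infinite_radius_is_identity(self, clean_section):
        section, truth = clean_section
        objects = extract_nuclei(section)
        dist = distance_field(truth.vessel_mask, section.pixel_size_um)
        kept = proximal_filter(list(objects), dist, max_dist_um=np.inf)
        assert kept == objects

    def test_ground_truth_band_membership(self, clean_section):
        section, truth = clean_section
        objects = extract_nuclei(section)
        dist = distance_field(truth.vessel_mask, section.pixel_size_um)
        kept = proximal_filter(list(objects), dist, max_dist_um=80.0)
        # oracle: count ground-truth nuclei whose centroid lies in the band
        n_expected = sum(
            dist[int(round(n.centroid_rc[0])), int(round(n.centroid_rc[1]))] <= 80.0
            for n in truth.nuclei)
        assert len(kept) == n_expected
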