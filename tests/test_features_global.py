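"""Unit and oracle tests for the modality-independent feature extractors.

The oracles here deliberately use the slowest, most literal computation
available — per-pixel loops, explicit flood fill — so that a bug in the
vectorized implementation cannot hide in a shared code path.
"""

from collections import deque

import numpy as np
import pytest

from dicomcbir import ImageRecord, extract_global
from dicomcbir.dicom_io import GrayImage
from dicomcbir.errors import ContractError
from dicomcbir.features_global import (
    Histogram,
    edge_histogram,
    entropy,
    intensity_histogram,
    moments,
    segment,
)


def _hist(weights, normalized=True):
    w = np.asarray(weights, dtype=float)
    return Histogram(w, np.arange(len(w) + 1, dtype=float), normalized=normalized)


class TestIntensityHistogram:
    def test_constant_image_all_mass_first_bin(self):
        h = intensity_histogram(GrayImage(np.zeros((8, 8))), 8)
        np.testing.assert_allclose(h.weights, [1, 0, 0, 0, 0, 0, 0, 0])

    def test_half_and_half(self):
        v = np.zeros((4, 4))
        v[:, 2:] = 1.0
        h = intensity_histogram(GrayImage(v), 2)
        np.testing.assert_allclose(h.weights, [0.5, 0.5])

    def test_matches_per_pixel_counting_oracle(self, rng):
        v = rng.random((32, 32))
        h = intensity_histogram(GrayImage(v), 16)
        counts = np.zeros(16)
        for x in v.ravel():  # right-closed last bin
            counts[min(int(x * 16), 15)] += 1
        np.testing.assert_allclose(h.weights, counts / 1024, atol=1e-12)

    def test_value_one_counted_in_last_bin(self):
        h = intensity_histogram(GrayImage(np.ones((2, 2))), 4)
        np.testing.assert_allclose(h.weights, [0, 0, 0, 1])


class TestEntropy:
    @pytest.mark.parametrize(
        "weights, expected",
        [([1, 0, 0, 0], 0.0),
         ([0.125] * 8, 3.0),
         ([0.5, 0.25, 0.25], 1.5)],
    )
    def test_known_values(self, weights, expected):
        assert entropy(_hist(weights)) == pytest.approx(expected, abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ContractError):
            entropy(_hist([0.5, 0.2]))

    def test_bounded_by_log2_bins(self, rng):
        for _ in range(20):
            w = rng.random(16)
            h = _hist(w / w.sum())
            assert 0.0 <= entropy(h) <= np.log2(16) + 1e-12


def _sobel_orientation_oracle(v, bins):
    """Literal per-pixel 3x3 Sobel with replicate borders."""
    n, m = v.shape
    p = np.pad(v, 1, mode="edge")
    weights = np.zeros(bins)
    for r in range(n):
        for c in range(m):
            win = p[r : r + 3, c : c + 3]
            gx = (win[0, 2] + 2 * win[1, 2] + win[2, 2]
                  - win[0, 0] - 2 * win[1, 0] - win[2, 0])
            gy = (win[2, 0] + 2 * win[2, 1] + win[2, 2]
                  - win[0, 0] - 2 * win[0, 1] - win[0, 2])
            mag = np.hypot(gx, gy)
            theta = np.degrees(np.arctan2(gy, gx)) % 180.0
            if theta >= 180.0:
                theta -= 180.0
            weights[min(int(theta / 180.0 * bins), bins - 1)] += mag
    return weights


class TestEdgeHistogram:
    def test_constant_image_zero_flag(self):
        h = edge_histogram(GrayImage(np.full((8, 8), 0.3)), 4)
        assert not h.normalized
        np.testing.assert_array_equal(h.weights, np.zeros(4))

    def test_vertical_step_edge_mass_at_zero_degrees(self):
        v = np.zeros((16, 16))
        v[:, 8:] = 1.0
        h = edge_histogram(GrayImage(v), 4)
        assert h.normalized
        assert h.weights[0] == pytest.approx(1.0)

    def test_matches_per_pixel_sobel_oracle(self, rng):
        v = rng.random((12, 15))
        h = edge_histogram(GrayImage(v), 8)
        expected = _sobel_orientation_oracle(v, 8)
        np.testing.assert_allclose(h.weights, expected / expected.sum(), atol=1e-12)


def _flood_fill_oracle(mask):
    """BFS 8-connected labeling returning (area, centroid) per component."""
    n, m = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r0 in range(n):
        for c0 in range(m):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            q, pixels = deque([(r0, c0)]), []
            seen[r0, c0] = True
            while q:
                r, c = q.popleft()
                pixels.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < n and 0 <= cc < m and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            q.append((rr, cc))
            arr = np.array(pixels)
            comps.append((len(pixels), float(arr[:, 0].mean()), float(arr[:, 1].mean())))
    return sorted(comps, key=lambda t: -t[0])


class TestSegment:
    def test_square_on_black(self):
        v = np.zeros((32, 32))
        v[5:15, 8:18] = 1.0
        segs = segment(GrayImage(v), "fixed", 0.5)
        assert len(segs) == 1
        assert segs[0].area_px == 100
        assert segs[0].centroid == (9.5, 12.5)

    def test_ordering_by_area_descending(self):
        v = np.zeros((64, 64))
        v[(np.indices((64, 64))[0] - 16) ** 2 + (np.indices((64, 64))[1] - 16) ** 2 <= 64] = 1.0
        v[40:45, 40:50] = 1.0  # area 50 rectangle
        segs = segment(GrayImage(v), "fixed", 0.5)
        areas = [s.area_px for s in segs]
        assert areas == sorted(areas, reverse=True)
        assert len(segs) == 2

    def test_no_foreground_empty_list(self):
        assert segment(GrayImage(np.zeros((8, 8))), "fixed", 0.5) == []

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(25):
            mask = rng.random((32, 32)) < 0.35
            segs = segment(GrayImage(mask.astype(float)), "fixed", 0.5)
            expected = _flood_fill_oracle(mask)
            assert [s.area_px for s in segs] == [a for a, _, _ in expected]
            got = sorted((s.area_px, *s.centroid) for s in segs)
            assert got == pytest.approx(sorted(expected))


class TestMoments:
    def _square(self, r0=10, c0=10, size=10, shape=(64, 64)):
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r0 + size, c0:c0 + size] = True
        return mask

    def test_m00_equals_area(self):
        assert moments(self._square()).raw[(0, 0)] == 100.0

    def test_central_first_moments_vanish(self, rng):
        mask = rng.random((20, 20)) < 0.4
        if not mask.any():
            mask[3, 3] = True
        ms = moments(mask)
        assert abs(ms.central[(1, 0)]) < 1e-9
        assert abs(ms.central[(0, 1)]) < 1e-9

    def test_hu_translation_invariance(self):
        a = moments(self._square(5, 5)).hu
        b = moments(self._square(25, 22)).hu  # translated by (20, 17)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_hu_scale_stability(self):
        # asymmetric L-shape so all leading Hu values are meaningfully nonzero
        def ell(size, shape=(200, 200)):
            m = np.zeros(shape, dtype=bool)
            m[4:4 + 2 * size, 4:4 + size] = True
            m[4:4 + size, 4:4 + 2 * size] = True
            return m

        a, b = moments(ell(20)).hu, moments(ell(40)).hu
        nonzero = np.abs(a) > 1e-12
        assert nonzero.sum() >= 4
        assert np.all(np.abs((b[nonzero] - a[nonzero]) / a[nonzero]) <= 1e-3)

    def test_empty_mask_rejected(self):
        with pytest.raises(ContractError):
            moments(np.zeros((4, 4), dtype=bool))


class TestExtractGlobal:
    def test_constant_phantom_degenerate_composition(self):
        rec = ImageRecord(uid="1.1", modality="CT",
                          pixels=np.full((16, 16), 100), bits_stored=8)
        gf = extract_global(rec)
        assert gf.entropy_bits == 0.0
        assert gf.segments == []
        assert gf.moments is None
        assert not gf.edge_hist.normalized

    def test_square_phantom_segment_matches_ground_truth(self, square_phantom):
        rec, truth = square_phantom
        gf = extract_global(rec)
        assert gf.segments[0].area_px == truth.object_areas[0]
        assert gf.segments[0].centroid == pytest.approx(truth.object_centroids[0])

    def test_deterministic(self, mammo_phantom):
        rec, _ = mammo_phantom
        a, b = extract_global(rec), extract_global(rec)
        np.testing.assert_array_equal(a.intensity_hist.weights, b.intensity_hist.weights)
        np.testing.assert_array_equal(a.moments.hu, b.moments.hu)
        assert [s.area_px for s in a.segments] == [s.area_px for s in b.segments]
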