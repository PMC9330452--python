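"""Thresholding operators vs brute-force oracles; morphological chain."""

import numpy as np
import pytest
from scipy import ndimage

import tuberelax as tx
from tuberelax.segmentation import (DegenerateHistogramError, SegmentationParams,
                                    delineate_cortex, delineate_pith_and_flesh,
                                    entropy_threshold, otsu_threshold,
                                    segment_tubers, threshold_image)

from conftest import dice


# ---------------------------------------------------------------- oracles

def _lowest_tied_argmax(objectives):
    """Lowest split index whose objective ties the maximum (1e-9 relative)."""
    obj = np.asarray(objectives, dtype=float)
    best = np.nanmax(obj)
    tol = 1e-9 * max(abs(best), 1.0)
    return int(np.flatnonzero(obj >= best - tol)[0])


def otsu_bruteforce_index(hist):
    """Exhaustive search of the between-class-variance split index."""
    p = np.asarray(hist, float) / np.sum(hist)
    centers = np.arange(len(p), dtype=float)
    objs = []
    for t in range(len(p) - 1):
        w0 = p[: t + 1].sum()
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            objs.append(-np.inf)
            continue
        mu0 = (p[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (p[t + 1:] * centers[t + 1:]).sum() / w1
        objs.append(w0 * w1 * (mu0 - mu1) ** 2)
    return _lowest_tied_argmax(objs)


def kapur_bruteforce_index(hist):
    """Exhaustive search of the Kapur two-class entropy split index."""
    p = np.asarray(hist, float) / np.sum(hist)
    objs = []
    for t in range(len(p) - 1):
        p0, p1 = p[: t + 1], p[t + 1:]
        P0, P1 = p0.sum(), p1.sum()
        if P0 <= 0 or P1 <= 0:
            objs.append(-np.inf)
            continue
        q0 = p0[p0 > 0] / P0
        q1 = p1[p1 > 0] / P1
        objs.append(-(q0 * np.log(q0)).sum() - (q1 * np.log(q1)).sum())
    return _lowest_tied_argmax(objs)


def erode_bruteforce(mask, kernel_half):
    """Pixelwise erosion: keep p iff the full square around p is inside."""
    m = np.asarray(mask, bool)
    out = np.zeros_like(m)
    k = kernel_half
    padded = np.pad(m, k, constant_values=False)
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            out[i, j] = padded[i: i + 2 * k + 1, j: j + 2 * k + 1].all()
    return out


def threshold_to_index(value):
    # implementation returns midpoint between integer bin centers t, t+1
    return int(np.floor(value))


# ----------------------------------------------------------- thresholding

class TestOtsu:
    def test_two_spikes_split(self):
        h = np.zeros(256)
        h[10] = 100
        h[200] = 100
        thr = otsu_threshold(h)
        assert 10 < thr < 200

    def test_matches_bruteforce_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            h = rng.integers(0, 50, size=256)
            if (h > 0).sum() < 2:
                continue
            assert threshold_to_index(otsu_threshold(h)) == otsu_bruteforce_index(h)

    def test_matches_skimage_reference(self):
        """Independent cross-check against an established implementation."""
        from skimage.filters import threshold_otsu
        rng = np.random.default_rng(3)
        img = np.concatenate([rng.normal(40, 6, 4000), rng.normal(160, 12, 3000)])
        img = np.clip(img, 0, 255).astype(np.uint8)
        hist = np.bincount(img, minlength=256)
        ours = otsu_threshold(hist)
        ref = threshold_otsu(img)
        assert abs(ours - ref) <= 1.0

    def test_degenerate_histogram_rejected(self):
        h = np.zeros(256)
        h[7] = 50
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(h)

    def test_foreground_covers_ground_truth(self, default_phantom):
        spec, img, truth = default_phantom  # sigma = 2 % of peak
        thr = threshold_image(img.data[0], "otsu")
        fg = img.data[0] > thr
        tuber = truth.tuber_ids > 0
        assert (fg & tuber).sum() / tuber.sum() >= 0.99


class TestKapur:
    def test_two_spikes_split(self):
        h = np.zeros(256)
        h[50] = 80
        h[250] = 120
        thr = entropy_threshold(h)
        assert 50 < thr < 250

    def test_matches_bruteforce_on_random_histograms(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            h = rng.integers(0, 50, size=256)
            if (h > 0).sum() < 2:
                continue
            assert threshold_to_index(entropy_threshold(h)) == kapur_bruteforce_index(h)

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            entropy_threshold(np.array([0.0, 5.0, 0.0]))

    def test_late_echo_recovers_pith(self, default_phantom):
        spec, img, truth = default_phantom
        params = SegmentationParams()
        labels = tx.segment_tissues(img, params)
        assert dice(labels.tissue_mask("pith"), truth.tissue_mask("pith")) >= 0.85


# ------------------------------------------------------------- morphology

class TestSegmentTubers:
    def test_eight_tubers_reading_order(self, default_phantom):
        spec, img, truth = default_phantom
        labels = segment_tubers(img, SegmentationParams())
        assert list(labels.tuber_numbers) == list(range(1, 9))
        # reading order: centroids sorted band by band
        cents = [ndimage.center_of_mass(labels.tuber_ids == i) for i in range(1, 9)]
        rows = [c[0] for c in cents]
        cols = [c[1] for c in cents]
        assert max(rows[:4]) < min(rows[4:])          # top band first
        assert cols[:4] == sorted(cols[:4])           # left to right
        assert cols[4:] == sorted(cols[4:])

    def test_reading_order_matches_ground_truth_ids(self, default_phantom):
        spec, img, truth = default_phantom
        labels = segment_tubers(img, SegmentationParams())
        for tid in range(1, 9):
            pred = labels.tuber_ids == tid
            overlap = np.bincount(truth.tuber_ids[pred], minlength=9).argmax()
            assert overlap == tid

    def test_skin_erosion_matches_bruteforce(self):
        """Eroding a disk with the 5x5 kernel equals pixelwise erosion."""
        rr, cc = np.mgrid[0:50, 0:50]
        disk = (rr - 25) ** 2 + (cc - 25) ** 2 <= 20 ** 2
        ours = ndimage.binary_erosion(disk, np.ones((5, 5), bool))
        assert np.array_equal(ours, erode_bruteforce(disk, 2))

    def test_tuber_masks_match_ground_truth(self, default_phantom):
        spec, img, truth = default_phantom
        labels = segment_tubers(img, SegmentationParams())
        for tid in range(1, 9):
            d = dice(labels.tuber_ids == tid, truth.tuber_ids == tid)
            assert d >= 0.98

    def test_no_tubers_found(self):
        rng = np.random.default_rng(0)
        data = np.abs(rng.normal(0, 1, (4, 64, 64)))
        img = tx.MultiEchoImage(data=data, te_ms=6.5)
        with pytest.raises(ValueError, match="no tubers"):
            segment_tubers(img, SegmentationParams(min_tuber_area_px=5000))


class TestDelineateCortex:
    def test_disk_ring_matches_bruteforce_strip(self):
        """Cortex of a radius-20 disk with strip 3 equals the eroded-strip oracle."""
        rr, cc = np.mgrid[0:50, 0:50]
        disk = (rr - 25) ** 2 + (cc - 25) ** 2 <= 20 ** 2
        ours = delineate_cortex(disk, SegmentationParams(cortex_strip_px=3))
        inner = disk.copy()
        for _ in range(3):
            inner = erode_bruteforce(inner, 1)
        assert np.array_equal(ours, disk & ~inner)

    def test_strip_zero_is_empty(self):
        disk = np.zeros((20, 20), bool)
        disk[5:15, 5:15] = True
        ring = delineate_cortex(disk, SegmentationParams(cortex_strip_px=0))
        assert not ring.any()

    def test_thin_mask_degenerates_to_whole_mask(self):
        m = np.zeros((10, 10), bool)
        m[4:6, 2:8] = True  # 2 px thick < 3 px strip
        ring = delineate_cortex(m, SegmentationParams(cortex_strip_px=3))
        assert np.array_equal(ring, m)

    def test_cortex_dice_on_phantom(self, segmented_phantom):
        spec, img, truth, labels = segmented_phantom
        assert dice(labels.tissue_mask("cortex"), truth.tissue_mask("cortex")) >= 0.85


class TestPithAndFlesh:
    def test_partition_is_exact(self, segmented_phantom):
        """cortex + flesh + pith tile the skinless mask with no overlap."""
        spec, img, truth, labels = segmented_phantom
        eroded = (labels.tuber_ids > 0) & (labels.labels != tx.LABEL_CODE["skin"])
        union = (labels.tissue_mask("cortex") | labels.tissue_mask("flesh")
                 | labels.tissue_mask("pith"))
        assert np.array_equal(union, eroded)
        total = (labels.tissue_mask("cortex").sum() + labels.tissue_mask("flesh").sum()
                 + labels.tissue_mask("pith").sum())
        assert total == eroded.sum()

    def test_vascular_ring_discarded(self):
        """Bright ring objects at the cortex-flesh interface are not pith."""
        spec = tx.default_phantom_spec(noise_sigma=2.0, seed=2, vascular=True)
        img, truth = tx.generate_phantom(spec)
        labels = tx.segment_tissues(img)
        ring = truth.tissue_mask("vascular")
        pith = labels.tissue_mask("pith")
        assert (ring & pith).sum() / ring.sum() < 0.2
        assert dice(pith, truth.tissue_mask("pith")) >= 0.8

    def test_flesh_dice_on_phantom(self, segmented_phantom):
        spec, img, truth, labels = segmented_phantom
        assert dice(labels.tissue_mask("flesh"), truth.tissue_mask("flesh")) >= 0.85


class TestChainProperties:
    def test_idempotent(self, default_phantom):
        spec, img, truth = default_phantom
        a = tx.segment_tissues(img)
        b = tx.segment_tissues(img)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.tuber_ids, b.tuber_ids)

    def test_dice_degrades_with_noise(self):
        """Mean per-tissue Dice falls as sigma rises through the SNR floor."""
        scores = []
        for sigma in (2.0, 6.0, 12.0):
            spec = tx.default_phantom_spec(noise_sigma=sigma, seed=5)
            img, truth = tx.generate_phantom(spec)
            labels = tx.segment_tissues(img)
            scores.append(np.mean([
                dice(labels.tissue_mask(t), truth.tissue_mask(t))
                for t in ("cortex", "flesh", "pith")]))
        assert scores[0] > scores[1] > scores[2]
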