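"""Automatic tissue segmentation of multi-echo tuber images.

The chain mirrors a classical morphological protocol: tubers are split
from the background by Otsu thresholding of an early echo, the skin is
removed by one erosion with a square kernel, the cortex is the strip of
a fixed number of single-pixel erosion layers inside the skinless mask,
the pith is the bright central region found by a maximum-entropy (Kapur)
threshold on a late echo, and the flesh is whatever remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import LABEL_CODE, MultiEchoImage, TissueLabelMap

__all__ = [
    "SegmentationParams",
    "otsu_threshold",
    "entropy_threshold",
    "threshold_image",
    "segment_tubers",
    "delineate_cortex",
    "delineate_pith_and_flesh",
    "segment_tissues",
]

_S3 = np.ones((3, 3), dtype=bool)
_REL_TOL = 1e-9  # objective tie tolerance for threshold selection


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two populated bins."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the segmentation chain.

    ``bg_echo_index`` is the frame used for the background/tuber split
    (an early echo, maximum SNR); ``seg_echo_index`` the frame used for
    the pith threshold (default echo 20, TE = 130 ms, where the long-T2
    pith is visibly brighter).  ``erosion_kernel`` is the side of the
    square kernel of the skin-removal erosion; ``cortex_strip_px`` the
    number of single-pixel erosion layers making up the cortex.
    """

    seg_echo_index: int = 19          # 0-based; echo 20 -> TE = 130 ms
    bg_echo_index: int = 0
    erosion_kernel: int = 5
    cortex_strip_px: int = 3
    min_tuber_area_px: int = 200
    entropy_method: str = "kapur"
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.erosion_kernel < 3 or self.erosion_kernel % 2 == 0:
            raise ValueError("erosion_kernel must be odd and >= 3")
        if self.cortex_strip_px < 0:
            raise ValueError("cortex_strip_px must be >= 0")


def _select_threshold(objective: np.ndarray, valid: np.ndarray) -> int:
    """Lowest split index whose objective ties the maximum (1e-9 relative)."""
    if not valid.any():
        raise DegenerateHistogramError("degenerate histogram")
    obj = np.where(valid, objective, -np.inf)
    best = obj.max()
    tol = _REL_TOL * max(abs(best), 1.0)
    return int(np.flatnonzero(obj >= best - tol)[0])


def _as_hist(histogram: np.ndarray) -> np.ndarray:
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or len(h) < 2:
        raise ValueError("histogram must be a 1D array of >= 2 bins")
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    if (h > 0).sum() < 2:
        raise DegenerateHistogramError("degenerate histogram")
    return h


def _threshold_value(bin_centers: np.ndarray, t: int) -> float:
    # midpoint between the last background bin and the first foreground bin
    return float((bin_centers[t] + bin_centers[t + 1]) / 2.0)


def otsu_threshold(histogram: np.ndarray, bin_centers: np.ndarray | None = None) -> float:
    """Otsu threshold of an intensity histogram.

    Maximises the between-class variance over all splits
    ``background = bins[:t+1]``, ``foreground = bins[t+1:]`` and returns
    the intensity midway between the two bins flanking the best split
    (ties resolved towards the lowest split).  Pixels classify as
    foreground when strictly above the returned value.
    """
    h = _as_hist(histogram)
    if bin_centers is None:
        bin_centers = np.arange(len(h), dtype=float)
    p = h / h.sum()
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    cum_mu = np.cumsum(p * bin_centers)[:-1]
    mu = cum_mu[-1] + p[-1] * bin_centers[-1]
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mu / w0
        mu1 = (mu - cum_mu) / w1
        objective = w0 * w1 * (mu0 - mu1) ** 2
    objective = np.where(valid, objective, -np.inf)
    t = _select_threshold(objective, valid)
    return _threshold_value(np.asarray(bin_centers, dtype=float), t)


def entropy_threshold(histogram: np.ndarray, bin_centers: np.ndarray | None = None) -> float:
    """Kapur maximum-entropy threshold of an intensity histogram.

    Maximises the sum of the Shannon entropies of the normalised
    background and foreground class histograms; same split and
    tie-break conventions as :func:`otsu_threshold`.
    """
    h = _as_hist(histogram)
    if bin_centers is None:
        bin_centers = np.arange(len(h), dtype=float)
    p = h / h.sum()
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    P0 = np.cumsum(p)[:-1]
    P1 = 1.0 - P0
    S0 = np.cumsum(plogp)[:-1]
    S1 = plogp.sum() - S0
    valid = (P0 > 0) & (P1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(P0) - S0 / P0
        h1 = np.log(P1) - S1 / P1
    objective = np.where(valid, h0 + h1, -np.inf)
    t = _select_threshold(objective, valid)
    return _threshold_value(np.asarray(bin_centers, dtype=float), t)


def threshold_image(frame: np.ndarray, method: str = "otsu",
                    mask: np.ndarray | None = None, n_bins: int = 256) -> float:
    """Histogram a frame (optionally inside a mask) and apply a threshold.

    Uses ``n_bins`` equal-width bins over the in-mask intensity range.
    """
    vals = frame[mask] if mask is not None else frame.ravel()
    if vals.size == 0:
        raise ValueError("empty mask")
    if vals.max() == vals.min():
        raise DegenerateHistogramError("degenerate histogram: single-valued image")
    hist, edges = np.histogram(vals, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    fn = {"otsu": otsu_threshold, "kapur": entropy_threshold}[method]
    return fn(hist, centers)


def _reading_order(centroids: list[tuple[float, float]],
                   heights: list[float]) -> list[int]:
    """Order component indices top-to-bottom, then left-to-right.

    Components are grouped into horizontal bands (a new band starts when
    the next centroid row exceeds the running band anchor by more than
    70 % of the median component height), then sorted by column inside
    each band.
    """
    order = sorted(range(len(centroids)), key=lambda i: centroids[i][0])
    band_gap = 0.7 * float(np.median(heights)) if heights else 1.0
    bands: list[list[int]] = []
    anchor = None
    for i in order:
        r = centroids[i][0]
        if anchor is None or r - anchor > band_gap:
            bands.append([])
            anchor = r
        bands[-1].append(i)
    out: list[int] = []
    for band in bands:
        out.extend(sorted(band, key=lambda i: centroids[i][1]))
    return out


def segment_tubers(img: MultiEchoImage, params: SegmentationParams) -> TissueLabelMap:
    """Split tubers from the background and remove the skin.

    Otsu's threshold on the early echo defines the foreground; connected
    components above the area filter become tubers, numbered in reading
    order of their centroids.  Each tuber mask is eroded once with the
    square kernel to strip peripheral (skin) pixels.  The returned map
    labels the eroded interior as flesh and the stripped ring as skin;
    cortex and pith are refined by the later stages.
    """
    frame = img.data[params.bg_echo_index]
    thr = threshold_image(frame, "otsu", n_bins=params.n_bins)
    fg = frame > thr
    comp, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no tubers found")
    areas = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    keep = [i + 1 for i in range(n) if areas[i] >= params.min_tuber_area_px]
    if not keep:
        raise ValueError("no tubers found")
    cents = ndimage.center_of_mass(fg, comp, keep)
    objs = ndimage.find_objects(comp)
    heights = [objs[k - 1][0].stop - objs[k - 1][0].start for k in keep]
    order = _reading_order(list(cents), heights)

    shape = frame.shape
    labels = np.zeros(shape, dtype=np.uint8)
    tuber_ids = np.zeros(shape, dtype=np.int32)
    kern = np.ones((params.erosion_kernel, params.erosion_kernel), dtype=bool)
    for new_id, idx in enumerate(order, start=1):
        m = comp == keep[idx]
        core = ndimage.binary_erosion(m, kern)
        labels[m & ~core] = LABEL_CODE["skin"]
        labels[core] = LABEL_CODE["flesh"]
        tuber_ids[m] = new_id
    return TissueLabelMap(labels=labels, tuber_ids=tuber_ids)


def delineate_cortex(tuber_mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Cortex ring: the outer ``cortex_strip_px`` erosion layers of a mask.

    The strip is computed by iterated single-pixel (3 x 3) erosions.  If
    the mask is thinner than the strip the whole mask is returned (the
    degenerate case is the caller's to flag).
    """
    m = np.asarray(tuber_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty tuber mask")
    inner = m.copy()
    for _ in range(params.cortex_strip_px):
        inner = ndimage.binary_erosion(inner, _S3)
    return m & ~inner


def delineate_pith_and_flesh(img: MultiEchoImage, tuber_mask: np.ndarray,
                             cortex: np.ndarray, params: SegmentationParams,
                             ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Split the sub-cortical region into pith and flesh.

    A maximum-entropy threshold of the late-echo intensities inside the
    skinless tuber mask marks bright pixels; the bright connected
    component at the tuber centre is the pith (peripheral bright
    objects, e.g. a vascular ring, are discarded).  One binary opening
    cuts thin bright bridges before the central component is picked; the
    component is then restored by dilation within the thresholded mask.
    Flesh is the remainder.  Returns ``(pith, flesh, flagged)`` where
    ``flagged`` marks an empty pith.
    """
    m = np.asarray(tuber_mask, dtype=bool)
    cortex = np.asarray(cortex, dtype=bool)
    if (cortex & ~m).any():
        raise ValueError("cortex must lie inside the tuber mask")
    interior = m & ~cortex
    frame = img.data[params.seg_echo_index]
    try:
        thr = threshold_image(frame, params.entropy_method, mask=interior,
                              n_bins=params.n_bins)
    except DegenerateHistogramError:
        return np.zeros_like(m), interior, True
    above = (frame > thr) & interior
    opened = ndimage.binary_opening(above, _S3)
    comp, n = ndimage.label(opened if opened.any() else above)
    if n == 0:
        return np.zeros_like(m), interior, True
    # component containing (or nearest to) the tuber centroid
    cent = ndimage.center_of_mass(m)
    ci, cj = int(round(cent[0])), int(round(cent[1]))
    label_at_c = comp[ci, cj] if comp[ci, cj] > 0 else 0
    if label_at_c == 0:
        cents = ndimage.center_of_mass(comp > 0, comp, np.arange(1, n + 1))
        d2 = [(r - cent[0]) ** 2 + (c - cent[1]) ** 2 for r, c in cents]
        label_at_c = int(np.argmin(d2)) + 1
    pith = comp == label_at_c
    if opened.any():
        pith = ndimage.binary_dilation(pith, _S3) & above
    flesh = interior & ~pith
    return pith, flesh, False


def segment_tissues(img: MultiEchoImage, params: SegmentationParams | None = None,
                    ) -> TissueLabelMap:
    """Full chain: tubers -> skin removal -> cortex -> pith -> flesh.

    Cortex, flesh and pith partition each skinless tuber mask exactly.
    Tubers whose pith could not be found are recorded in ``flags``.
    """
    params = params or SegmentationParams()
    lab = segment_tubers(img, params)
    labels = lab.labels
    for tid in lab.tuber_numbers:
        tuber = lab.tuber_ids == tid
        interior = tuber & (labels != LABEL_CODE["skin"])
        cortex = delineate_cortex(interior, params)
        if not (interior & ~cortex).any():
            lab.flags[int(tid)] = "degenerate: mask thinner than cortex strip"
            labels[cortex] = LABEL_CODE["cortex"]
            continue
        pith, flesh, flagged = delineate_pith_and_flesh(img, interior, cortex, params)
        if flagged:
            lab.flags[int(tid)] = "empty pith"
        labels[cortex] = LABEL_CODE["cortex"]
        labels[flesh] = LABEL_CODE["flesh"]
        labels[pith] = LABEL_CODE["pith"]
    return lab
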