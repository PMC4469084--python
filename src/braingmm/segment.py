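"""Multilevel Otsu thresholding and morphological tumor isolation.

The segmentation chain: intensity histogram -> m optimal thresholds
(exhaustive maximization of the between-class variance, Otsu's criterion)
-> quantized label raster -> skull stripping (border clearing + erosion)
-> tumor mask (bright band, opening, small-object removal, largest
component).  Thresholds are gray levels (histogram bin centers); quantized
classes follow the half-open band convention [0..t1], (t1..t2], ...,
(tm..max].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation

__all__ = [
    "IntensityHistogram",
    "NoTumorDetectedError",
    "histogram",
    "otsu_multithreshold",
    "between_class_variance",
    "quantize",
    "skull_strip",
    "extract_tumor_mask",
    "dice",
]


class NoTumorDetectedError(RuntimeError):
    """Raised when no pixels survive the tumor-band extraction."""


@dataclass
class IntensityHistogram:
    """Uniform-bin intensity histogram: n+1 edges, n non-negative counts."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("need one more edge than counts")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @classmethod
    def integer_bins(cls, counts) -> "IntensityHistogram":
        """Histogram whose bin centers are the integers 0..n-1 (handy for tests)."""
        counts = np.asarray(counts, dtype=float)
        edges = np.arange(counts.size + 1, dtype=float) - 0.5
        return cls(bin_edges=edges, counts=counts)


def histogram(image, mask=None, n_bins: int = 256, value_range=(0.0, 255.0)) -> IntensityHistogram:
    """Histogram of (optionally masked) pixel intensities; counts sum to the pixel count."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    arr = np.asarray(image, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape:
            raise ValueError("mask shape must match image")
        if not mask.any():
            raise ValueError("empty mask")
        values = arr[mask]
    else:
        values = arr.ravel()
    counts, edges = np.histogram(values, bins=n_bins, range=value_range)
    return IntensityHistogram(bin_edges=edges, counts=counts.astype(float))


_combo_cache: dict = {}


def _candidate_blocks(n_candidates: int, m: int, chunk: int):
    """Yield lexicographically ordered m-combinations of range(n_candidates).

    The full table is cached for the common 256-bin configurations so the
    per-image cost of repeated exhaustive searches is a single argmax.
    """
    key = (n_candidates, m)
    if key not in _combo_cache and n_candidates <= 256 and m <= 3:
        _combo_cache[key] = np.array(
            list(itertools.combinations(range(n_candidates), m)), dtype=np.int64
        )
    if key in _combo_cache:
        table = _combo_cache[key]
        for start in range(0, table.shape[0], chunk):
            yield table[start : start + chunk]
        return
    combo_iter = itertools.combinations(range(n_candidates), m)
    while True:
        block = np.array(list(itertools.islice(combo_iter, chunk)), dtype=np.int64)
        if block.size == 0:
            return
        yield block


def _prefix_sums(hist: IntensityHistogram):
    p = hist.counts / hist.counts.sum()
    centers = hist.centers
    cp = np.concatenate([[0.0], np.cumsum(p)])
    cs = np.concatenate([[0.0], np.cumsum(p * centers)])
    return cp, cs


def between_class_variance(hist: IntensityHistogram, thresholds) -> float:
    """Otsu's criterion sum_k S_k^2 / P_k (minus the constant global term).

    ``thresholds`` are gray levels; bins whose center is <= t_k (and > the
    previous threshold) form class k.
    """
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    cp, cs = _prefix_sums(hist)
    centers = hist.centers
    # index of the last bin in each class
    cut = np.searchsorted(centers, thresholds, side="right")
    bounds = np.concatenate([[0], cut, [centers.size]]).astype(int)
    score = 0.0
    for k in range(bounds.size - 1):
        w = cp[bounds[k + 1]] - cp[bounds[k]]
        s = cs[bounds[k + 1]] - cs[bounds[k]]
        if w > 0:
            score += s * s / w
    mu = cs[-1]
    return float(score - mu * mu)


def otsu_multithreshold(hist: IntensityHistogram, m: int, chunk: int = 500_000):
    """Exhaustively optimal m-threshold Otsu on a binned histogram.

    Evaluates every strictly increasing m-tuple of candidate thresholds (bin
    centers of all bins but the last) and returns the tuple maximizing the
    between-class variance; ties break toward the lexicographically smallest
    tuple.  Exhaustive search is exact and affordable for m <= 3 on 256 bins.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    total = hist.counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    occupied = int(np.count_nonzero(hist.counts))
    if occupied < m + 1:
        raise ValueError(f"need at least {m + 1} occupied bins for {m} thresholds, got {occupied}")
    n = hist.n_bins
    cp, cs = _prefix_sums(hist)
    centers = hist.centers

    best_score = -np.inf
    best_combo: Optional[np.ndarray] = None
    for block in _candidate_blocks(n - 1, m, chunk):
        nb = block.shape[0]
        bounds = np.empty((nb, m + 2), dtype=np.int64)
        bounds[:, 0] = 0
        bounds[:, 1:-1] = block + 1  # class k ends after bin index t_k
        bounds[:, -1] = n
        score = np.zeros(nb)
        for k in range(m + 1):
            w = cp[bounds[:, k + 1]] - cp[bounds[:, k]]
            s = cs[bounds[:, k + 1]] - cs[bounds[:, k]]
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)
            score += term
        # scores equal up to float accumulation error count as ties and
        # resolve toward the lexicographically smallest tuple
        bmax = float(score.max())
        tol = 1e-10 * max(abs(bmax), 1.0)
        i = int(np.flatnonzero(score >= bmax - tol)[0])
        if score[i] > best_score + tol:
            best_score = float(score[i])
            best_combo = block[i].copy()
    assert best_combo is not None
    return centers[best_combo]


def quantize(image, thresholds) -> np.ndarray:
    """Label raster with m+1 classes: label k iff t_k < x <= t_{k+1}."""
    arr = np.asarray(image, dtype=float)
    thresholds = np.sort(np.asarray(thresholds, dtype=float).ravel())
    if thresholds.size == 0:
        return np.zeros(arr.shape, dtype=np.int64)
    return np.searchsorted(thresholds, arr, side="left").astype(np.int64)


def skull_strip(
    labels,
    erosion_radius: int = 5,
    background_label: int = 0,
) -> np.ndarray:
    """Brain-material mask from a quantized label raster.

    Takes the largest 8-connected component of non-background labels after
    discarding components touching the image border, then peels the bright
    skull ring by binary erosion with a disk of the given radius.
    """
    lab = np.asarray(labels)
    fg = lab != background_label
    cc = measure.label(fg, connectivity=2)
    cc = segmentation.clear_border(cc)
    if cc.max() == 0:
        raise ValueError("no interior foreground component found")
    sizes = np.bincount(cc.ravel())
    sizes[0] = 0
    biggest = int(np.argmax(sizes))
    mask = cc == biggest
    if erosion_radius > 0:
        mask = morphology.erosion(mask, morphology.disk(erosion_radius))
    if not mask.any():
        raise ValueError("erosion removed the entire brain component")
    return mask


def extract_tumor_mask(
    labels,
    brain,
    band: Optional[int] = None,
    opening_radius: int = 2,
    min_area: int = 30,
) -> np.ndarray:
    """Tumor mask: bright band inside the brain, cleaned by morphology.

    Keeps pixels of the requested label band (default: the highest band
    present, since the tumor appears bright) within the brain mask, applies
    a disk opening, drops components below ``min_area`` pixels, and returns
    the largest surviving 8-connected component.
    """
    lab = np.asarray(labels)
    brain = np.asarray(brain, dtype=bool)
    if not brain.any():
        raise ValueError("brain mask is empty")
    if band is None:
        band = int(lab.max())
    mask = (lab == band) & brain
    if not mask.any():
        raise NoTumorDetectedError("no pixels in the tumor intensity band")
    if opening_radius > 0:
        mask = morphology.opening(mask, morphology.disk(opening_radius))
    if min_area > 0:
        cc = measure.label(mask, connectivity=2)
        sizes = np.bincount(cc.ravel())
        sizes[0] = 0
        keep = np.flatnonzero(sizes >= min_area)
        mask = np.isin(cc, keep)
    if not mask.any():
        raise NoTumorDetectedError("no component survived morphological cleanup")
    cc = measure.label(mask, connectivity=2)
    sizes = np.bincount(cc.ravel())
    sizes[0] = 0
    return cc == int(np.argmax(sizes))


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
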