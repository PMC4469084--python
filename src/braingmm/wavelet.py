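"""Wavelet comparison features: db1 / coif1 subband mean, std and entropy.

A level-1 separable 2-D DWT (orthonormal filters, periodized extension so
coefficient energy exactly matches image energy on even-sized inputs)
splits a region patch into LL, LH, HL, HH subbands; each subband is
summarized by its arithmetic mean, population standard deviation and the
Shannon entropy (bits) of the histogram of absolute coefficient values.
At level 1 this yields a 12-element feature vector per region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "SUBBANDS",
    "WaveletFeatures",
    "dwt2",
    "shannon_entropy_bits",
    "wavelet_feature_vector",
    "region_patch",
    "extract_wavelet_features",
]

SUBBANDS = ("LL", "LH", "HL", "HH")
SUPPORTED_WAVELETS = ("db1", "coif1")


def _pad_to_multiple(arr: np.ndarray, mult: int, fill: float = 0.0) -> np.ndarray:
    pr = (-arr.shape[0]) % mult
    pc = (-arr.shape[1]) % mult
    if pr or pc:
        arr = np.pad(arr, ((0, pr), (0, pc)), mode="constant", constant_values=fill)
    return arr


def dwt2(image_patch, wavelet_name: str = "db1", level: int = 1) -> dict:
    """Level-``level`` 2-D DWT; returns the deepest {LL, LH, HL, HH} subbands.

    Uses orthonormal filters with periodized signal extension, so for
    even-sided inputs the transform is an orthonormal change of basis
    (Parseval holds exactly).  Odd-sided inputs are zero-padded to the
    required multiple of 2**level.
    """
    if wavelet_name not in SUPPORTED_WAVELETS:
        raise ValueError(f"wavelet must be one of {SUPPORTED_WAVELETS}")
    if level < 1:
        raise ValueError("level must be >= 1")
    arr = np.asarray(image_patch, dtype=float)
    if arr.ndim != 2:
        raise ValueError("patch must be 2-D")
    if min(arr.shape) < 2**level:
        raise ValueError(f"patch of shape {arr.shape} too small for level {level}")
    arr = _pad_to_multiple(arr, 2**level)
    ll = arr
    for _ in range(level):
        ll, (lh, hl, hh) = pywt.dwt2(ll, wavelet_name, mode="periodization")
    return {"LL": ll, "LH": lh, "HL": hl, "HH": hh}


def shannon_entropy_bits(coefficients, n_bins: int = 64) -> float:
    """Entropy (bits) of the normalized histogram of |coefficients|, 0·log0 = 0."""
    c = np.abs(np.asarray(coefficients, dtype=float).ravel())
    # a numerically constant subband carries no information; without this
    # guard float residue of order 1e-13 would spread across the bins
    if c.max() - c.min() <= 1e-12 * max(1.0, c.max()):
        return 0.0
    counts, _ = np.histogram(c, bins=n_bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


@dataclass
class WaveletFeatures:
    wavelet_name: str
    level: int
    records: list  # (subband, mean, std, entropy)
    names: list
    vector: np.ndarray


def wavelet_feature_vector(subbands: dict, wavelet_name: str = "db1", level: int = 1,
                           n_entropy_bins: int = 64) -> WaveletFeatures:
    """Per-subband mean, population std and entropy, flattened in LL,LH,HL,HH order."""
    if not subbands:
        raise ValueError("no subbands given")
    records, names, vals = [], [], []
    for band in SUBBANDS:
        c = np.asarray(subbands[band], dtype=float)
        mean = float(c.mean())
        std = float(c.std())  # denominator n
        ent = shannon_entropy_bits(c, n_bins=n_entropy_bins)
        records.append((band, mean, std, ent))
        for stat, val in (("mean", mean), ("std", std), ("entropy", ent)):
            names.append(f"{wavelet_name}_{band}_{stat}")
            vals.append(val)
    return WaveletFeatures(
        wavelet_name=wavelet_name,
        level=level,
        records=records,
        names=names,
        vector=np.asarray(vals),
    )


def region_patch(image, mask, pad_to_even: bool = True) -> np.ndarray:
    """Bounding-box patch of a region: out-of-mask pixels get the region mean.

    The box is zero-padded to even side lengths so a level-1 DWT sees a
    dyadic-friendly support.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    box = image[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].copy()
    sub = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    box[~sub] = image[mask].mean()
    if pad_to_even:
        box = _pad_to_multiple(box, 2)
    return box


def extract_wavelet_features(image, mask, wavelet_name: str = "db1", level: int = 1,
                             n_entropy_bins: int = 64) -> WaveletFeatures:
    """Full region pipeline: patch -> DWT -> 12-element summary vector."""
    patch = region_patch(image, mask)
    bands = dwt2(patch, wavelet_name=wavelet_name, level=level)
    return wavelet_feature_vector(bands, wavelet_name=wavelet_name, level=level,
                                  n_entropy_bins=n_entropy_bins)
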