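"""Intensity-domain preprocessing for T1-weighted head slices.

The pipeline's front end: wavelet-domain denoising, optional histogram
equalization, pooled grey-level histograms, and suppression of pixels whose
grey level belongs to no tissue band.

Tissue intensity model
----------------------
On the T1-weighted data this package targets, the pooled grey-level histogram
of a head dataset shows four peaks, one per tissue compartment, occupying
disjoint intensity bands:

===========  ==============  =================
tissue       band (grey)     convention
===========  ==============  =================
CSF          [40, 57)        half-open
grey matter  [61, 79.8)      half-open
white matter [86, 110)       half-open
skull        [110, 130]      closed
===========  ==============  =================

Grey levels below 35 are image background.  Levels falling between bands
(35-40, 57-61, 79.8-86, above 130) belong to no tissue and are suppressed to
zero before classification.  The shared boundary 110 is resolved to SKULL so
the four bands are pairwise disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pywt

log = logging.getLogger(__name__)


class Tissue(IntEnum):
    """Per-pixel label codes used throughout the package.

    The integer codes are the on-disk legend for coded label-map PNGs.
    """

    BACKGROUND = 0
    CSF = 1
    GM = 2
    WM = 3
    SKULL = 4
    UNASSIGNED = 5


#: The four anatomical compartments the segmentation targets.
TISSUE_CLASSES: tuple[Tissue, ...] = (Tissue.CSF, Tissue.GM, Tissue.WM, Tissue.SKULL)


@dataclass(frozen=True)
class TissueRanges:
    """Per-tissue grey-level intervals driving thresholding and synthesis.

    Each interval is half-open ``[low, high)`` except the topmost (SKULL),
    which is closed ``[low, high]``.  Intervals must be pairwise disjoint and
    ``background_cutoff`` must lie below the lowest interval.
    """

    csf: tuple[float, float] = (40.0, 57.0)
    gm: tuple[float, float] = (61.0, 79.8)
    wm: tuple[float, float] = (86.0, 110.0)
    skull: tuple[float, float] = (110.0, 130.0)
    background_cutoff: float = 35.0

    def __post_init__(self) -> None:
        ivs = self.intervals()
        los = [lo for lo, _ in ivs.values()]
        his = [hi for _, hi in ivs.values()]
        if any(lo >= hi for lo, hi in ivs.values()):
            raise ValueError("each tissue interval needs low < high")
        order = sorted(range(4), key=lambda i: los[i])
        for a, b in zip(order, order[1:]):
            # half-open convention: sharing a boundary is fine, overlap is not
            if his[a] > los[b]:
                raise ValueError("tissue intervals overlap")
        if self.background_cutoff >= min(los):
            raise ValueError("background_cutoff must lie below every interval")

    def intervals(self) -> dict[Tissue, tuple[float, float]]:
        return {
            Tissue.CSF: self.csf,
            Tissue.GM: self.gm,
            Tissue.WM: self.wm,
            Tissue.SKULL: self.skull,
        }

    def classify_value(self, value: float) -> Tissue:
        """Label a single grey level (BACKGROUND / tissue / UNASSIGNED)."""
        if value < self.background_cutoff:
            return Tissue.BACKGROUND
        if self.skull[0] <= value <= self.skull[1]:
            return Tissue.SKULL
        for tissue in (Tissue.CSF, Tissue.GM, Tissue.WM):
            lo, hi = self.intervals()[tissue]
            if lo <= value < hi:
                return tissue
        return Tissue.UNASSIGNED

    def label_lut(self) -> np.ndarray:
        """256-entry lookup table mapping integer grey level -> label code."""
        return np.array([self.classify_value(v) for v in range(256)], dtype=np.uint8)

    def tissue_mask(self, img: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels whose grey level lies in some tissue band."""
        lut = self.label_lut()
        lab = lut[np.asarray(img, dtype=np.uint8)]
        return (lab >= Tissue.CSF) & (lab <= Tissue.SKULL)


@dataclass(frozen=True)
class WaveletSpec:
    """Configuration of the wavelet shrinkage denoiser.

    family
        PyWavelets wavelet name (default Daubechies-4).
    levels
        decomposition depth (>= 1).
    threshold_rule
        ``"soft"`` or ``"hard"`` coefficient shrinkage.
    threshold_scale
        multiplier on the universal threshold sigma * sqrt(2 ln N), where
        sigma is estimated from the median absolute deviation of the finest
        diagonal-detail coefficients.
    """

    family: str = "db4"
    levels: int = 3
    threshold_rule: str = "soft"
    threshold_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold_rule not in ("soft", "hard"):
            raise ValueError("threshold_rule must be 'soft' or 'hard'")
        if self.threshold_scale <= 0:
            raise ValueError("threshold_scale must be positive")


def _as_grey(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D grey image, got {a.ndim}-D")
    return a


def wavelet_denoise(img: np.ndarray, spec: WaveletSpec | None = None) -> np.ndarray:
    """Denoise by multiscale wavelet shrinkage.

    The image is decomposed with ``spec.family`` to ``spec.levels`` scales,
    detail coefficients at every scale are shrunk (soft or hard) at the
    universal threshold, and the image is reconstructed, rounded and clipped
    back to [0, 255].
    """
    spec = spec or WaveletSpec()
    a = _as_grey(img).astype(np.float64)
    wavelet = pywt.Wavelet(spec.family)
    max_lev = pywt.dwtn_max_level(a.shape, wavelet)
    if spec.levels > max_lev:
        raise ValueError(
            f"decomposition depth {spec.levels} too deep for image "
            f"{a.shape}; maximum depth is {max_lev}"
        )
    coeffs = pywt.wavedec2(a, wavelet, level=spec.levels)
    # noise scale from the finest diagonal detail band (MAD estimator)
    hh = coeffs[-1][2]
    sigma = np.median(np.abs(hh)) / 0.6745
    thr = spec.threshold_scale * sigma * np.sqrt(2.0 * np.log(a.size))
    if thr <= 0:  # noise-free input: nothing to shrink
        return np.clip(np.rint(a), 0, 255).astype(np.uint8)
    new = [coeffs[0]]
    for detail in coeffs[1:]:
        new.append(
            tuple(pywt.threshold(d, thr, mode=spec.threshold_rule) for d in detail)
        )
    rec = pywt.waverec2(new, wavelet)
    rec = rec[: a.shape[0], : a.shape[1]]
    return np.clip(np.rint(rec), 0, 255).astype(np.uint8)


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Contrast enhancement by the classic CDF remap.

    ``out = round((cdf(v) - cdf_min) / (N - cdf_min) * 255)`` — a monotone
    map, so the relative ordering of pixel intensities is preserved.  A
    constant image (or one whose histogram is already uniform over 0..255)
    is a fixed point.
    """
    a = _as_grey(img).astype(np.uint8)
    counts = np.bincount(a.ravel(), minlength=256)
    cdf = np.cumsum(counts)
    nonzero = np.nonzero(counts)[0]
    if nonzero.size <= 1:
        return a.copy()
    cdf_min = cdf[nonzero[0]]
    denom = cdf[-1] - cdf_min
    if denom == 0:  # pragma: no cover - implies single level, handled above
        return a.copy()
    lut = np.rint((cdf - cdf_min) / denom * 255.0).clip(0, 255).astype(np.uint8)
    return lut[a]


def grey_histogram(imgs: Iterable[np.ndarray]) -> np.ndarray:
    """Pooled 256-bin grey-level histogram over a collection of images."""
    counts = np.zeros(256, dtype=np.int64)
    n = 0
    for img in imgs:
        a = _as_grey(img).astype(np.uint8)
        counts += np.bincount(a.ravel(), minlength=256)
        n += 1
    if n == 0:
        raise ValueError("grey_histogram needs at least one image")
    return counts


def suppress_out_of_range(img: np.ndarray, ranges: TissueRanges | None = None) -> np.ndarray:
    """Zero every pixel whose grey level belongs to no tissue band.

    Background, inter-band gaps and levels above the skull band are all
    converted to level 0; pixels inside a band pass through unchanged.
    Idempotent (0 is itself out of every band).
    """
    ranges = ranges or TissueRanges()
    a = _as_grey(img).astype(np.uint8)
    out = a.copy()
    out[~ranges.tissue_mask(a)] = 0
    return out


def save_histogram_tsv(counts: Sequence[int], path) -> None:
    """Write a histogram as two-column TSV (grey_level, count)."""
    arr = np.asarray(counts, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("grey_level\tcount\n")
        for level, c in enumerate(arr):
            fh.write(f"{level}\t{int(c)}\n")
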