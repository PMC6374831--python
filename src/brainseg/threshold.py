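"""Histogram-peak analysis and range-based first-pass segmentation.

Intensity thresholding is the pipeline's early stage: the pooled grey-level
histogram of a head dataset shows one peak per tissue, each pixel is labelled
by the band containing its grey level, and two spatial corrections follow —
skull stripping (the skull is a ring enclosing the brain, so labelled pixels
outside that ring are extracranial clutter) and small-component morphological
cleanup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks as _scipy_find_peaks
from skimage import measure, morphology

from .preprocess import TISSUE_CLASSES, Tissue, TissueRanges

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    level: int
    count: int
    tissue: Tissue | None


@dataclass(frozen=True)
class PeakSet:
    """Histogram local maxima, strictly increasing in grey level."""

    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        levels = [p.level for p in self.peaks]
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("peak levels must be strictly increasing")
        if any(p.count <= 0 for p in self.peaks):
            raise ValueError("peak counts must be positive")

    def __len__(self) -> int:
        return len(self.peaks)


def find_peaks(
    hist: np.ndarray,
    min_separation: int = 5,
    smoothing_window: int = 5,
    ranges: TissueRanges | None = None,
    min_height_frac: float = 0.08,
) -> PeakSet:
    """Locate tissue peaks in a pooled grey-level histogram.

    The histogram is smoothed with a moving average, local maxima above the
    background cutoff and at least ``min_separation`` grey levels apart are
    kept, and each is tagged with the tissue whose band contains it (or
    ``None`` if it falls in a gap).  A maximum must reach
    ``min_height_frac`` of the tallest peak to count — this suppresses the
    faint plateau contributed by heterogeneous non-tissue head content.
    """
    ranges = ranges or TissueRanges()
    counts = np.asarray(hist, dtype=np.float64)
    if counts.ndim != 1 or counts.size != 256:
        raise ValueError("expected a 256-bin histogram")
    w = max(1, int(smoothing_window))
    kernel = np.ones(w) / w
    # edge-padded smoothing: a flat histogram stays flat (no boundary dips
    # that would masquerade as peaks)
    padded = np.pad(counts, (w // 2, w - 1 - w // 2), mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    idx, _ = _scipy_find_peaks(smoothed, distance=max(1, int(min_separation)))
    # only levels above background can host a tissue peak
    cutoff = int(np.ceil(ranges.background_cutoff))
    idx = idx[idx >= cutoff]
    if idx.size:
        floor = max(min_height_frac * smoothed[cutoff:].max(), 1e-12)
        idx = idx[smoothed[idx] >= floor]
    peaks = tuple(
        Peak(
            level=int(i),
            count=int(max(counts[i], 1)),
            tissue=(t if (t := ranges.classify_value(float(i))) in TISSUE_CLASSES else None),
        )
        for i in idx
    )
    return PeakSet(peaks=peaks)


def classify_by_range(img: np.ndarray, ranges: TissueRanges | None = None) -> np.ndarray:
    """Label every pixel by the tissue band containing its grey level.

    Below the background cutoff -> BACKGROUND; inside an inter-band gap ->
    UNASSIGNED.  Every pixel receives exactly one of the six labels.
    """
    ranges = ranges or TissueRanges()
    a = np.asarray(img, dtype=np.uint8)
    return ranges.label_lut()[a]


def skull_strip(lm: np.ndarray) -> np.ndarray:
    """Restrict labels to the skull ring and its interior.

    The skull is a ring structure covering the brain, so the stripper keeps
    the largest connected SKULL component whose filled interior holds at
    least half of all CSF+GM+WM pixels and sets every labelled pixel outside
    that filled ring to BACKGROUND (removing facial structures, ears, and
    other extracranial clutter).  With no SKULL pixels the map is returned
    unchanged with a warning.
    """
    lm = np.asarray(lm, dtype=np.uint8)
    skull = lm == Tissue.SKULL
    if not skull.any():
        log.warning("skull_strip: no SKULL pixels found; map left unchanged")
        return lm.copy()
    brain = (lm == Tissue.CSF) | (lm == Tissue.GM) | (lm == Tissue.WM)
    n_brain = int(brain.sum())
    # noise opens pixel gaps in the ring; close it so the interior fills
    disk = morphology.disk(5)
    closed = ndimage.binary_closing(skull, disk)
    comp = measure.label(ndimage.binary_fill_holes(closed), connectivity=2)
    best_filled = None
    best_size = -1
    for region in measure.regionprops(comp):
        filled = comp == region.label
        inside = int((filled & brain).sum())
        if n_brain == 0 or inside >= 0.5 * n_brain:
            if region.area > best_size:
                best_size = region.area
                best_filled = filled
    out = lm.copy()
    if best_filled is None:
        log.warning("skull_strip: no skull ring encloses the brain; stripping by "
                    "largest component only")
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        best_filled = comp == int(sizes.argmax())
    out[~best_filled] = Tissue.BACKGROUND
    # skull label outside the chosen ring but inside nothing -> already gone;
    # spurious SKULL-coded pixels inside the ring are left to morph_cleanup
    return out


def morph_cleanup(lm: np.ndarray, min_component: int = 10) -> np.ndarray:
    """Per-tissue binary opening+closing and small-component removal.

    Each tissue mask is opened then closed with a 3x3 square (the square,
    unlike the cross, leaves solid rectangles untouched); pixels a tissue
    loses become UNASSIGNED, pixels it gains are claimed only from UNASSIGNED.
    Connected components smaller than ``min_component`` pixels are reassigned
    to UNASSIGNED.
    """
    lm = np.asarray(lm, dtype=np.uint8)
    out = lm.copy()
    selem = ndimage.generate_binary_structure(2, 2)  # 3x3 square
    for tissue in TISSUE_CLASSES:
        mask = lm == tissue
        if not mask.any():
            continue
        cleaned = ndimage.binary_closing(ndimage.binary_opening(mask, selem), selem)
        lost = mask & ~cleaned
        gained = cleaned & ~mask & (out == Tissue.UNASSIGNED)
        out[lost] = Tissue.UNASSIGNED
        out[gained] = tissue
    if min_component > 1:
        for tissue in TISSUE_CLASSES:
            comp = measure.label(out == tissue, connectivity=1)
            if comp.max() == 0:
                continue
            sizes = np.bincount(comp.ravel())
            small = np.nonzero(sizes < min_component)[0]
            small = small[small != 0]
            if small.size:
                out[np.isin(comp, small)] = Tissue.UNASSIGNED
    return out
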