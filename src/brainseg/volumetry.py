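"""Volumetry and evaluation: tissue percentages, GM/WM ratio, Jaccard.

Segmented label maps are reduced to per-tissue pixel counts and percentages
of the non-background head area, the grey-matter/white-matter ratio is
compared against the Visible Chinese Human (VCH) head reference, and mask
overlap is scored with the Jaccard index.

The percentage denominator is all non-background pixels, not the four
tissues alone: reference head percentages sum to under 100% because a head
contains non-tissue content (scalp, muscle, residual structures), and the
same convention here keeps phantom volumetry directly comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .preprocess import TISSUE_CLASSES, Tissue


@dataclass(frozen=True)
class VCHReference:
    """Published head-model reference values (immutable constants)."""

    percentages: dict[str, float]
    gm_wm_ratio: float
    literature_ratios: dict[str, float]


def load_vch_reference() -> VCHReference:
    """Load the packaged VCH reference table."""
    text = resources.files("brainseg.data").joinpath("vch_reference.json").read_text()
    raw = json.loads(text)
    return VCHReference(
        percentages=raw["percentages"],
        gm_wm_ratio=raw["gm_wm_ratio"],
        literature_ratios=raw["literature_ratios"],
    )


@dataclass(frozen=True)
class TissueStats:
    """Per-tissue pixel counts and percentages of non-background pixels."""

    counts: dict[str, int]
    percentages: dict[str, float]
    n_foreground: int

    @property
    def gm_wm_ratio(self) -> float:
        return gm_wm_ratio(self)


def tissue_percentages(lm: np.ndarray) -> TissueStats:
    """Count tissues and express each as a percentage of non-background.

    UNASSIGNED pixels count toward the denominator (they are head content),
    so the four tissue percentages may sum to less than 100.
    """
    lm = np.asarray(lm)
    fg = int((lm != Tissue.BACKGROUND).sum())
    if fg == 0:
        raise ValueError("label map has no non-background pixels")
    counts = {t.name: int((lm == t).sum()) for t in TISSUE_CLASSES}
    counts["UNASSIGNED"] = int((lm == Tissue.UNASSIGNED).sum())
    percentages = {t.name: 100.0 * counts[t.name] / fg for t in TISSUE_CLASSES}
    return TissueStats(counts=counts, percentages=percentages, n_foreground=fg)


def aggregate_stats(maps: list[np.ndarray]) -> TissueStats:
    """Pooled tissue statistics over a collection of label maps."""
    if not maps:
        raise ValueError("no label maps to aggregate")
    stacked = np.concatenate([np.asarray(m).ravel() for m in maps])
    return tissue_percentages(stacked.reshape(1, -1))


def gm_wm_ratio(stats: TissueStats) -> float:
    """Grey-matter to white-matter pixel-count ratio."""
    wm = stats.counts["WM"]
    if wm == 0:
        raise ValueError("GM/WM ratio undefined: no white-matter pixels")
    return stats.counts["GM"] / wm


def ratio_accuracy(predicted: float, reference: float) -> int:
    """Relative agreement of two ratios as a whole percentage.

    ``100 * (1 - |predicted - reference| / reference)``, floored at 0 and
    rounded to the nearest integer percent.
    """
    if reference <= 0:
        raise ValueError("reference ratio must be positive")
    acc = 100.0 * (1.0 - abs(predicted - reference) / reference)
    return int(round(max(acc, 0.0)))


def jaccard(pred: np.ndarray, truth: np.ndarray, tissue: Tissue) -> float:
    """Intersection-over-union of one tissue's binary masks.

    1.0 when both masks are empty (nothing to segment, nothing wrong).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    a = pred == tissue
    b = truth == tissue
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


@dataclass(frozen=True)
class EvalReport:
    """Segmentation quality report against ground truth and the reference."""

    jaccard: dict[str, float]
    deviation_points: dict[str, float]  # |percentage - reference| per tissue
    percentages: dict[str, float]
    gm_wm_ratio: float
    ratio_accuracy: int

    def to_dict(self) -> dict:
        return {
            "jaccard": self.jaccard,
            "deviation_points": self.deviation_points,
            "percentages": self.percentages,
            "gm_wm_ratio": self.gm_wm_ratio,
            "ratio_accuracy": self.ratio_accuracy,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tissue\tpercentage\tdeviation_points\tjaccard\n")
            for t in TISSUE_CLASSES:
                fh.write(
                    f"{t.name}\t{self.percentages[t.name]:.4f}\t"
                    f"{self.deviation_points[t.name]:.4f}\t"
                    f"{self.jaccard.get(t.name, float('nan')):.4f}\n"
                )
            fh.write(f"gm_wm_ratio\t{self.gm_wm_ratio:.4f}\t\t\n")
            fh.write(f"ratio_accuracy\t{self.ratio_accuracy}\t\t\n")


def compare_to_vch(
    stats: TissueStats,
    ref: VCHReference | None = None,
    jaccard_by_tissue: dict[str, float] | None = None,
) -> EvalReport:
    """Per-tissue percentage deviation and ratio accuracy vs the reference."""
    ref = ref or load_vch_reference()
    deviations = {
        t.name: abs(stats.percentages[t.name] - ref.percentages[t.name])
        for t in TISSUE_CLASSES
    }
    ratio = gm_wm_ratio(stats)
    return EvalReport(
        jaccard=jaccard_by_tissue or {},
        deviation_points=deviations,
        percentages=dict(stats.percentages),
        gm_wm_ratio=ratio,
        ratio_accuracy=ratio_accuracy(ratio, ref.gm_wm_ratio),
    )
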