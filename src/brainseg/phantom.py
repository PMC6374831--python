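"""Synthetic head-slice phantoms with ground truth, and image/label I/O.

The generator emulates the kind of data the segmentation pipeline targets:
2-D, 256 x 256, 8-bit T1-weighted head slices in which four tissue
compartments occupy concentric bands — skull outermost, then cerebrospinal
fluid, grey matter, and white matter innermost — each with grey levels drawn
inside its tissue band (see :class:`brainseg.preprocess.TissueRanges`).

Two deliberate nuisance features mimic real head MRI:

* an "other soft tissue" ring (scalp/dura surrogate) between the skull and
  the CSF, labelled UNASSIGNED in the truth and given grey levels outside
  every tissue band.  Reference head models report the four tissues summing
  to ~90% of the head, and this ring supplies the residual so volumetry over
  non-background pixels is directly comparable;
* optional extracranial "facial" blobs (nose/eyes/ears surrogates) whose
  grey levels overlap the grey-matter band but whose true label is
  BACKGROUND — the failure mode that skull stripping must remove.

Default tissue proportions are the Visible Chinese Human head percentages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .preprocess import TISSUE_CLASSES, Tissue, TissueRanges

log = logging.getLogger(__name__)

#: Default per-tissue area fractions of the head (non-background pixels),
#: from the Visible Chinese Human reference percentages.
DEFAULT_PROPORTIONS: dict[Tissue, float] = {
    Tissue.CSF: 0.3765,
    Tissue.GM: 0.2708,
    Tissue.WM: 0.1235,
    Tissue.SKULL: 0.1281,
}

#: Grey-level interval (half-open) for the non-tissue "other soft tissue"
#: ring; sits above the skull band so it is suppressed, never classified.
#: Deliberately broad and flat (heterogeneous content), so it contributes a
#: faint plateau to the histogram rather than a fifth tissue-like peak.
OTHER_INTENSITY: tuple[int, int] = (140, 191)

LEGEND = {int(t): t.name for t in Tissue}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic head-slice generator."""

    size: int = 256
    tissue_proportions: dict[Tissue, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    intensity_ranges: TissueRanges = field(default_factory=TissueRanges)
    noise_sigma: float = 5.0
    noise_model: str = "gaussian"
    facial_structures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("size must be >= 32")
        props = self.tissue_proportions
        if set(props) != set(TISSUE_CLASSES):
            raise ValueError("tissue_proportions must cover CSF, GM, WM, SKULL")
        if any(not (0.0 < p < 1.0) for p in props.values()):
            raise ValueError("each tissue proportion must be in (0, 1)")
        if sum(props.values()) > 1.0 + 1e-12:
            raise ValueError("tissue proportions must sum to <= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class PhantomPair:
    """A synthetic grey image and its aligned ground-truth label map."""

    image: np.ndarray
    truth: np.ndarray
    subject: int = 0
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.image.shape != self.truth.shape:
            raise ValueError("image and truth shapes differ")


def _integer_band(lo: float, hi: float, *, closed: bool) -> tuple[int, int]:
    """Integer grey levels representable inside a band (inclusive ends)."""
    lo_i = int(np.ceil(lo))
    hi_i = int(np.floor(hi)) if closed else int(np.ceil(hi)) - 1
    return lo_i, hi_i


def _geometry(rng: np.random.Generator, size: int) -> dict:
    """Per-subject ellipse parameters (semi-axes, rotation, centre)."""
    scale = size / 256.0
    return {
        "a": rng.uniform(88.0, 102.0) * scale,
        "b": rng.uniform(76.0, 90.0) * scale,
        "theta": rng.uniform(0.0, np.pi),
        "cy": size / 2.0 + rng.uniform(-6.0, 6.0) * scale,
        "cx": size / 2.0 + rng.uniform(-6.0, 6.0) * scale,
    }


def _radius_grid(size: int, geom: dict, slice_scale: float) -> np.ndarray:
    """Normalised elliptical radius of every pixel (1.0 = head boundary)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy = yy - geom["cy"]
    dx = xx - geom["cx"]
    ct, st = np.cos(geom["theta"]), np.sin(geom["theta"])
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    a = geom["a"] * slice_scale
    b = geom["b"] * slice_scale
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def _truth_from_radius(r: np.ndarray, props: dict[Tissue, float]) -> np.ndarray:
    """Concentric truth labels.  Order outside-in: SKULL, other, CSF, GM, WM."""
    p_other = 1.0 - sum(props.values())
    cum_wm = props[Tissue.WM]
    cum_gm = cum_wm + props[Tissue.GM]
    cum_csf = cum_gm + props[Tissue.CSF]
    cum_other = cum_csf + p_other
    truth = np.full(r.shape, Tissue.BACKGROUND, dtype=np.uint8)
    truth[r <= 1.0] = Tissue.SKULL
    truth[r <= np.sqrt(cum_other)] = Tissue.UNASSIGNED
    truth[r <= np.sqrt(cum_csf)] = Tissue.CSF
    truth[r <= np.sqrt(cum_gm)] = Tissue.GM
    truth[r <= np.sqrt(cum_wm)] = Tissue.WM
    return truth


def _paint_intensities(
    truth: np.ndarray, ranges: TissueRanges, rng: np.random.Generator
) -> np.ndarray:
    """Per-tissue grey levels: truncated normal centred mid-band.

    A unimodal in-band distribution (sd = band width / 6, clipped to the
    band; at three sigmas the clipped tail mass is negligible, so no edge
    pile-up) gives the pooled histogram one peak per tissue, as tissue
    histograms show in practice; the non-tissue ring draws uniformly from
    its broad band.
    """
    img = np.zeros(truth.shape, dtype=np.float64)
    bands = {t: _integer_band(*iv, closed=(t is Tissue.SKULL))
             for t, iv in ranges.intervals().items()}
    for tissue, (lo, hi) in bands.items():
        mask = truth == tissue
        n = int(mask.sum())
        mid = (lo + hi) / 2.0
        sd = (hi - lo + 1) / 6.0
        img[mask] = np.clip(np.rint(rng.normal(mid, sd, size=n)), lo, hi)
    other = truth == Tissue.UNASSIGNED
    img[other] = rng.integers(OTHER_INTENSITY[0], OTHER_INTENSITY[1],
                              size=int(other.sum()))
    return img


def _add_facial_blobs(
    img: np.ndarray,
    truth: np.ndarray,
    r: np.ndarray,
    ranges: TissueRanges,
    rng: np.random.Generator,
) -> None:
    """1-3 extracranial blobs with grey-matter-like intensities (truth stays
    BACKGROUND): the structures preprocessing and skull stripping must kill."""
    size = img.shape[0]
    gm_lo, gm_hi = _integer_band(*ranges.gm, closed=False)
    outside = (r > 1.12) & (r < 1.45)
    ys, xs = np.nonzero(outside)
    if ys.size == 0:
        return
    n_blobs = int(rng.integers(1, 4))
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    for _ in range(n_blobs):
        i = int(rng.integers(0, ys.size))
        cy, cx = float(ys[i]), float(xs[i])
        ry = rng.uniform(4.0, 10.0)
        rx = rng.uniform(4.0, 10.0)
        blob = (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0) & (r > 1.05)
        img[blob] = rng.integers(gm_lo, gm_hi + 1, size=int(blob.sum()))


def _apply_noise(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        else:  # rician: magnitude of a complex signal with iid gaussian parts
            n1 = rng.normal(0.0, spec.noise_sigma, size=img.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, size=img.shape)
            img = np.sqrt((img + n1) ** 2 + n2**2)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_phantom(
    spec: PhantomSpec,
    *,
    _rng: np.random.Generator | None = None,
    _geom: dict | None = None,
    _slice_scale: float = 1.0,
) -> PhantomPair:
    """Generate one synthetic head slice with its ground-truth label map.

    Deterministic in ``spec.seed``: equal specs produce bit-identical pairs.
    Before noise, every pixel's grey level lies inside the band of its true
    label (background, and the range-less UNASSIGNED ring, excepted by
    construction of their own bands).
    """
    rng = _rng if _rng is not None else np.random.default_rng(spec.seed)
    geom = _geom if _geom is not None else _geometry(rng, spec.size)
    r = _radius_grid(spec.size, geom, _slice_scale)
    truth = _truth_from_radius(r, spec.tissue_proportions)
    img = _paint_intensities(truth, spec.intensity_ranges, rng)
    if spec.facial_structures:
        _add_facial_blobs(img, truth, r, spec.intensity_ranges, rng)
    return PhantomPair(image=_apply_noise(img, spec, rng), truth=truth)


def generate_dataset(
    spec: PhantomSpec, n_subjects: int, slices_per_subject: int
) -> list[PhantomPair]:
    """Generate ``n_subjects x slices_per_subject`` phantom pairs.

    Each subject gets its own head geometry; slices within a subject share
    the geometry but vary in apparent head size (slice position surrogate)
    and noise realisation.  Subject seeds derive deterministically from
    ``spec.seed``.
    """
    if n_subjects < 1 or slices_per_subject < 1:
        raise ValueError("n_subjects and slices_per_subject must be >= 1")
    pairs: list[PhantomPair] = []
    children = np.random.SeedSequence(spec.seed).spawn(n_subjects)
    for subj, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        geom = _geometry(rng, spec.size)
        for sl in range(slices_per_subject):
            scale = float(rng.uniform(0.88, 1.0)) if slices_per_subject > 1 else 1.0
            pair = generate_phantom(spec, _rng=rng, _geom=geom, _slice_scale=scale)
            pair.subject, pair.slice_index = subj, sl
            pairs.append(pair)
    return pairs


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def _check_grey(arr: np.ndarray, origin: str) -> np.ndarray:
    if arr.ndim != 2:
        raise ValueError(
            f"{origin}: expected a single-channel 2-D image, got {arr.ndim}-D "
            f"data of shape {arr.shape}"
        )
    return arr


def read_image(path, *, slice_index: int | None = None) -> np.ndarray:
    """Read a grey image from 8-bit PNG or single-slice NIfTI.

    NIfTI data are cast/rescaled to integer [0, 255] when necessary (the
    cast is logged); a 3-D volume requires ``slice_index`` (axial, last
    axis).
    """
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        vol = np.asanyarray(nib.load(path).dataobj)
        if vol.ndim == 3:
            if slice_index is None:
                raise ValueError(
                    f"{path}: 3-D NIfTI volume of shape {vol.shape} needs a "
                    "slice_index to select a single slice"
                )
            vol = vol[:, :, slice_index]
        arr = _check_grey(np.asarray(vol), str(path))
        if arr.dtype.kind == "f" or arr.min() < 0 or arr.max() > 255:
            lo, hi = float(arr.min()), float(arr.max())
            if hi > lo:
                arr = (arr - lo) / (hi - lo) * 255.0
            else:
                arr = np.zeros_like(arr, dtype=np.float64)
            log.info("%s: rescaled NIfTI intensities [%g, %g] -> [0, 255]", path, lo, hi)
        return np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    arr = iio.imread(path)
    return _check_grey(np.asarray(arr), str(path)).astype(np.uint8)


def write_image(img: np.ndarray, path) -> None:
    """Write a grey image as 8-bit PNG or single-slice NIfTI (by suffix)."""
    path = Path(path)
    arr = _check_grey(np.asarray(img), str(path))
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("image values must lie in [0, 255]")
    arr = arr.astype(np.uint8)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), path)
    else:
        iio.imwrite(path, arr, extension=".png" if path.suffix == "" else None)


def write_labelmap(lm: np.ndarray, path) -> None:
    """Write a label map: coded PNG + JSON legend + one binary mask per tissue.

    Each tissue mask follows the convention tissue = 255, everything else = 0.
    ``path`` is the coded-map PNG path; masks are written alongside as
    ``<stem>_<tissue>.png`` and the legend as ``<stem>.json``.
    """
    path = Path(path)
    lm = np.asarray(lm, dtype=np.uint8)
    if lm.max() > max(Tissue):
        raise ValueError("label map contains codes outside the legend")
    iio.imwrite(path, lm)
    path.with_suffix(".json").write_text(json.dumps(LEGEND, indent=1))
    for tissue in TISSUE_CLASSES:
        mask = np.where(lm == tissue, 255, 0).astype(np.uint8)
        iio.imwrite(path.with_name(f"{path.stem}_{tissue.name}.png"), mask)


def read_labelmap(path) -> np.ndarray:
    """Read an integer-coded label map PNG, validating the codes."""
    lm = np.asarray(iio.imread(Path(path)))
    lm = _check_grey(lm, str(path))
    if lm.max() > max(Tissue):
        bad = int(lm.max())
        raise ValueError(f"{path}: unknown label code {bad}")
    return lm.astype(np.uint8)
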