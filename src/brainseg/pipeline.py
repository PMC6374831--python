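"""Stage orchestration: phantom -> preprocess -> threshold -> CNN -> cluster
refinement -> evaluation, with on-disk artifacts and per-stage manifests.

Each stage reads the previous stage's files, writes its own under the output
directory, and records a manifest (stage name, config hash, seed, inputs),
so any stage can be re-run in isolation and identical configs yield
identical manifests.

Final per-slice segmentation is assembled as: the range-threshold map (after
skull stripping) provides the head mask and the non-tissue content; CNN
patch predictions overwrite the labels of in-band foreground pixels where
the network is confident; partitioned k-means then resolves UNASSIGNED gap
pixels and non-core disagreements; a single morphological cleanup at the
end removes speckle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cluster as cl
from . import cnn as cnn_mod
from . import phantom as ph
from . import preprocess as pp
from . import threshold as th
from . import volumetry as vol
from .preprocess import TISSUE_CLASSES, Tissue

log = logging.getLogger(__name__)

STAGES = (
    "phantom",
    "preprocess",
    "segment-threshold",
    "train",
    "segment-cnn",
    "cluster-refine",
    "evaluate",
)

_PREVIOUS = {s: STAGES[i - 1] for i, s in enumerate(STAGES) if i}


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, YAML-serialisable.

    The slice split (``n_train``/``n_val``/``n_test``) partitions the
    generated slices; training sees only train+val slices.  Epochs default
    to a reduced desk-scale schedule; the full-scale recipe (50 epochs, 800
    slices, 600/100/100) is expressible through the same fields.
    """

    # phantom
    size: int = 256
    n_subjects: int = 1
    slices_per_subject: int = 16
    noise_sigma: float = 5.0
    facial_structures: bool = True
    # preprocess
    wavelet_family: str = "db4"
    wavelet_levels: int = 3
    wavelet_rule: str = "soft"
    # fraction of the universal threshold; the full universal threshold
    # over-smooths thin structures (skull ring) more than it removes noise
    # at the default noise level, so the pipeline shrinks less aggressively
    wavelet_scale: float = 0.25
    equalize: bool = False
    # threshold
    min_separation: int = 5
    smoothing_window: int = 5
    min_component: int = 10
    # cnn
    cnn_variant: str = "LENET"
    epochs: int = 10
    subepochs_per_epoch: int = 20
    batch_size: int = 5
    learning_rate: float = 0.001
    momentum_beta1: float = 0.5
    train_patch_stride: int = 5
    max_train_patches: int = 4000
    predict_stride: int = 2
    cnn_override_confidence: float = 0.9
    # split (slices)
    n_train: int = 10
    n_val: int = 2
    n_test: int = 4
    # cluster
    k: int = 4
    delta: float = 0.5
    n_workers: int = 1
    spatial_weight: float = 0.01
    # global
    seed: int = 0
    out_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        total = self.n_subjects * self.slices_per_subject
        if self.n_train + self.n_val + self.n_test != total:
            raise ValueError(
                f"slice split {self.n_train}+{self.n_val}+{self.n_test} must "
                f"sum to the dataset size {total}"
            )
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("need at least one training and one test slice")

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def phantom_spec(self) -> ph.PhantomSpec:
        return ph.PhantomSpec(
            size=self.size, noise_sigma=self.noise_sigma,
            facial_structures=self.facial_structures, seed=self.seed,
        )

    def wavelet_spec(self) -> pp.WaveletSpec:
        return pp.WaveletSpec(
            family=self.wavelet_family, levels=self.wavelet_levels,
            threshold_rule=self.wavelet_rule, threshold_scale=self.wavelet_scale,
        )

    def _derived_seed(self, k: int) -> int:
        return (self.seed * 1_000_003 + k) % (2**31 - 1)


def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    d = Path(cfg.out_dir) / stage.replace("-", "_")
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_manifest(cfg: PipelineConfig, stage: str, inputs: list[str],
                    extra: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": sorted(inputs),
    }
    if extra:
        manifest.update(extra)
    (_stage_dir(cfg, stage) / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )


def _require(cfg: PipelineConfig, stage: str) -> Path:
    d = Path(cfg.out_dir) / stage.replace("-", "_")
    if not (d / "manifest.json").exists():
        raise FileNotFoundError(
            f"missing artifacts of prior stage '{stage}'; run it first"
        )
    return d


def _slice_name(i: int) -> str:
    return f"slice_{i:04d}"


def _n_slices(cfg: PipelineConfig) -> int:
    return cfg.n_subjects * cfg.slices_per_subject


def _split_indices(cfg: PipelineConfig) -> dict[str, list[int]]:
    rng = np.random.default_rng(cfg._derived_seed(1))
    perm = rng.permutation(_n_slices(cfg))
    return {
        "train": sorted(int(i) for i in perm[: cfg.n_train + cfg.n_val]),
        "test": sorted(int(i) for i in perm[cfg.n_train + cfg.n_val:]),
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_phantom(cfg: PipelineConfig) -> None:
    d = _stage_dir(cfg, "phantom")
    pairs = ph.generate_dataset(cfg.phantom_spec(), cfg.n_subjects,
                                cfg.slices_per_subject)
    written = []
    for i, pair in enumerate(pairs):
        ph.write_image(pair.image, d / f"{_slice_name(i)}.png")
        ph.write_image(pair.truth, d / f"{_slice_name(i)}_truth.png")
        written.append(_slice_name(i))
    _write_manifest(cfg, "phantom", written, {"n_slices": len(pairs)})


def _load_phantoms(cfg: PipelineConfig):
    d = _require(cfg, "phantom")
    n = _n_slices(cfg)
    imgs = [ph.read_image(d / f"{_slice_name(i)}.png") for i in range(n)]
    truths = [ph.read_labelmap(d / f"{_slice_name(i)}_truth.png") for i in range(n)]
    return imgs, truths


def _stage_preprocess(cfg: PipelineConfig) -> None:
    imgs, _ = _load_phantoms(cfg)
    d = _stage_dir(cfg, "preprocess")
    wspec = cfg.wavelet_spec()
    denoised = []
    for i, img in enumerate(imgs):
        den = pp.wavelet_denoise(img, wspec)
        if cfg.equalize:
            den = pp.equalize_histogram(den)
        sup = pp.suppress_out_of_range(den)
        ph.write_image(den, d / f"{_slice_name(i)}_denoised.png")
        ph.write_image(sup, d / f"{_slice_name(i)}_suppressed.png")
        denoised.append(den)
    pp.save_histogram_tsv(pp.grey_histogram(denoised), d / "histogram.tsv")
    _write_manifest(cfg, "preprocess", [_slice_name(i) for i in range(len(imgs))])


def _load_preprocessed(cfg: PipelineConfig):
    d = _require(cfg, "preprocess")
    n = _n_slices(cfg)
    den = [ph.read_image(d / f"{_slice_name(i)}_denoised.png") for i in range(n)]
    sup = [ph.read_image(d / f"{_slice_name(i)}_suppressed.png") for i in range(n)]
    return den, sup


def _stage_threshold(cfg: PipelineConfig) -> None:
    den, _ = _load_preprocessed(cfg)
    d = _stage_dir(cfg, "segment-threshold")
    for i, img in enumerate(den):
        # no morphological cleanup here: the threshold map must stay exact
        # on clean data; cleanup happens once, after cluster refinement
        lm = th.skull_strip(th.classify_by_range(img))
        ph.write_image(lm, d / f"{_slice_name(i)}_threshold.png")
    _write_manifest(cfg, "segment-threshold",
                    [_slice_name(i) for i in range(len(den))])


def _load_threshold(cfg: PipelineConfig):
    d = _require(cfg, "segment-threshold")
    n = _n_slices(cfg)
    return [ph.read_labelmap(d / f"{_slice_name(i)}_threshold.png") for i in range(n)]


def _stage_train(cfg: PipelineConfig) -> None:
    _, sup = _load_preprocessed(cfg)
    _, truths = _load_phantoms(cfg)
    d = _stage_dir(cfg, "train")
    split = _split_indices(cfg)
    spec = cnn_mod.CnnSpec(variant=cfg.cnn_variant)
    sets = [
        cnn_mod.extract_patches(sup[i], truths[i], spec.input_side,
                                stride=cfg.train_patch_stride, image_id=i)
        for i in split["train"]
    ]
    patches = cnn_mod.merge_patchsets(sets)
    if len(patches) > cfg.max_train_patches:
        rng = np.random.default_rng(cfg._derived_seed(2))
        keep = np.sort(rng.choice(len(patches), cfg.max_train_patches,
                                  replace=False))
        patches = cnn_mod.PatchSet(
            patches=patches.patches[keep], labels=patches.labels[keep],
            image_ids=patches.image_ids[keep],
            patch_side=patches.patch_side, stride=patches.stride,
        )
    tcfg = cnn_mod.TrainConfig(
        learning_rate=cfg.learning_rate, momentum_beta1=cfg.momentum_beta1,
        epochs=cfg.epochs, subepochs_per_epoch=cfg.subepochs_per_epoch,
        batch_size=cfg.batch_size, split=(cfg.n_train, cfg.n_val, 0),
        seed=cfg._derived_seed(3),
    )
    model = cnn_mod.build_model(spec, seed=cfg._derived_seed(4))
    result = cnn_mod.train(model, patches, tcfg)
    cnn_mod.save_checkpoint(result.model, d / "model.npz", tcfg)
    cnn_mod.save_history_csv(result.history, d / "history.csv")
    (d / "split.json").write_text(json.dumps(split, indent=1))
    _write_manifest(cfg, "train", [_slice_name(i) for i in split["train"]],
                    {"n_patches": len(patches),
                     "best_val_accuracy": result.best_val_accuracy})


def _stage_segment_cnn(cfg: PipelineConfig) -> None:
    train_dir = _require(cfg, "train")
    _, sup = _load_preprocessed(cfg)
    thr = _load_threshold(cfg)
    d = _stage_dir(cfg, "segment-cnn")
    model = cnn_mod.load_checkpoint(train_dir / "model.npz")
    split = json.loads((train_dir / "split.json").read_text())
    tissue_codes = np.array([int(t) for t in TISSUE_CLASSES])
    for i in split["test"]:
        cnn_map, conf = cnn_mod.predict_labelmap(
            model, sup[i], stride=cfg.predict_stride, return_confidence=True
        )
        # the intensity rule is the prior; the CNN overrides it only where
        # it is confident, so a weakly trained network cannot degrade the map
        fused = thr[i].copy()
        override = (
            np.isin(cnn_map, tissue_codes)
            & (fused != Tissue.BACKGROUND)
            & (conf >= cfg.cnn_override_confidence)
        )
        fused[override] = cnn_map[override]
        ph.write_image(cnn_map, d / f"{_slice_name(i)}_cnn.png")
        ph.write_image(fused, d / f"{_slice_name(i)}_fused.png")
    _write_manifest(cfg, "segment-cnn", [_slice_name(i) for i in split["test"]])


def _stage_cluster_refine(cfg: PipelineConfig) -> None:
    seg_dir = _require(cfg, "segment-cnn")
    train_dir = _require(cfg, "train")
    den, _ = _load_preprocessed(cfg)
    d = _stage_dir(cfg, "cluster-refine")
    split = json.loads((train_dir / "split.json").read_text())
    ranges = pp.TissueRanges()
    for i in split["test"]:
        fused = ph.read_labelmap(seg_dir / f"{_slice_name(i)}_fused.png")
        feats, idx = cl.pixel_features(den[i], spatial_weight=cfg.spatial_weight)
        # seed one centre per tissue from the current labels (band midpoint
        # fallback), so the clusters land on the tissue bands, not on an
        # arbitrary spatial split
        labels_at = fused[idx[:, 0], idx[:, 1]]
        init = []
        for t in TISSUE_CLASSES:
            member = labels_at == t
            if member.sum() >= 10:
                init.append(feats[member].mean(axis=0))
            else:
                lo, hi = ranges.intervals()[t]
                init.append(np.array([
                    cfg.spatial_weight * den[i].shape[0] / 2,
                    cfg.spatial_weight * den[i].shape[1] / 2,
                    (lo + hi) / 2,
                ]))
        state = cl.kmeans_run(feats, k=cfg.k, delta=cfg.delta,
                              n_workers=cfg.n_workers,
                              seed=cfg._derived_seed(5), pixel_index=idx,
                              init_centers=np.asarray(init))
        refined = cl.refine_labels(fused, den[i], state)
        refined = th.morph_cleanup(refined, min_component=cfg.min_component)
        ph.write_labelmap(refined, d / f"{_slice_name(i)}_final.png")
    _write_manifest(cfg, "cluster-refine", [_slice_name(i) for i in split["test"]])


def _stage_evaluate(cfg: PipelineConfig) -> vol.EvalReport:
    ref_dir = _require(cfg, "cluster-refine")
    train_dir = _require(cfg, "train")
    _, truths = _load_phantoms(cfg)
    d = _stage_dir(cfg, "evaluate")
    split = json.loads((train_dir / "split.json").read_text())
    finals, jac_lists = [], {t.name: [] for t in TISSUE_CLASSES}
    for i in split["test"]:
        final = ph.read_labelmap(ref_dir / f"{_slice_name(i)}_final.png")
        finals.append(final)
        for t in TISSUE_CLASSES:
            jac_lists[t.name].append(vol.jaccard(final, truths[i], t))
    stats = vol.aggregate_stats(finals)
    jac_mean = {name: float(np.mean(v)) for name, v in jac_lists.items()}
    report = vol.compare_to_vch(stats, jaccard_by_tissue=jac_mean)
    report.to_json(d / "report.json")
    report.to_tsv(d / "report.tsv")
    _write_manifest(cfg, "evaluate", [_slice_name(i) for i in split["test"]])
    return report


_STAGE_FUNCS = {
    "phantom": _stage_phantom,
    "preprocess": _stage_preprocess,
    "segment-threshold": _stage_threshold,
    "train": _stage_train,
    "segment-cnn": _stage_segment_cnn,
    "cluster-refine": _stage_cluster_refine,
    "evaluate": _stage_evaluate,
}


def run_stage(name: str, cfg: PipelineConfig):
    """Run one named stage; upstream artifacts must already exist."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    log.info("stage %s: starting (config %s)", name, cfg.config_hash())
    out = _STAGE_FUNCS[name](cfg)
    log.info("stage %s: done", name)
    return out


def run_all(cfg: PipelineConfig) -> vol.EvalReport:
    """Run the full pipeline and return the final evaluation report."""
    report = None
    for name in STAGES:
        report = run_stage(name, cfg)
    return report
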