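"""Master-worker partitioned k-means over pixel feature points.

The refinement stage of the pipeline: foreground pixels become feature
points (spatially down-weighted row/column plus grey level), a k-means with
k = 4 is run under a master-worker contract — the master partitions the
points, workers compute nearest-centre assignments and partial per-cluster
sums, the master reduces and updates centres — until the summed Euclidean
point-to-centre distance stops changing.  After convergence a core-point
filter keeps, per cluster, the fraction ``delta`` of points nearest the
centre (default 0.5); core points characterise the cluster and are protected
during label refinement.

Determinism contract: worker partial results are reduced over fixed-size
chunks folded in chunk order, so the final state is bit-identical for any
worker count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import TISSUE_CLASSES, Tissue, TissueRanges

log = logging.getLogger(__name__)

#: fixed reduction granularity guaranteeing worker-count invariance
_CHUNK = 4096


@dataclass
class ClusterState:
    """Converged k-means state over a point set."""

    k: int
    centers: np.ndarray  # (k, d)
    assignments: np.ndarray  # (n,)
    objective: float  # sum of point-to-centre Euclidean distances
    core_fraction: float
    iteration: int
    objective_history: list[float] = field(default_factory=list)
    core_mask: np.ndarray | None = None  # (n,) bool, set post-convergence
    pixel_index: np.ndarray | None = None  # (n, 2) source pixel rows/cols

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be >= 0")
        if self.assignments.size and (
            self.assignments.min() < 0 or self.assignments.max() >= self.k
        ):
            raise ValueError("assignments out of range")


def partition_points(points: np.ndarray, n_workers: int) -> list[np.ndarray]:
    """Contiguous, disjoint, covering blocks with sizes differing by <= 1."""
    points = np.asarray(points)
    if len(points) == 0:
        raise ValueError("cannot partition zero points")
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    return np.array_split(points, min(n_workers, len(points)))


def assign_and_score(block: np.ndarray, centers: np.ndarray):
    """Nearest-centre assignment and per-cluster distance sums for a block.

    Ties go to the lowest centre index.
    """
    block = np.atleast_2d(np.asarray(block, dtype=np.float64))
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    d2 = ((block[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assignments = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(len(block)), assignments])
    sums = np.bincount(assignments, weights=dist, minlength=len(centers))
    return assignments, sums


def update_centers(points: np.ndarray, assignments: np.ndarray, k: int,
                   prev_centers: np.ndarray | None = None) -> np.ndarray:
    """Arithmetic-mean centres; an empty cluster keeps its previous centre."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    counts = np.bincount(assignments, minlength=k).astype(np.float64)
    sums = np.zeros((k, points.shape[1]))
    np.add.at(sums, assignments, points)
    centers = np.zeros_like(sums)
    nonempty = counts > 0
    centers[nonempty] = sums[nonempty] / counts[nonempty, None]
    if (~nonempty).any():
        if prev_centers is None:
            raise ValueError("empty cluster with no previous centres to keep")
        centers[~nonempty] = np.asarray(prev_centers)[~nonempty]
    return centers


def core_filter(points: np.ndarray, center: np.ndarray, delta: float) -> np.ndarray:
    """The ceil(delta * n) points nearest ``center`` (ties by point index)."""
    if not (0.0 < delta <= 1.0):
        raise ValueError("delta must be in (0, 1]")
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    n = len(points)
    m = int(np.ceil(delta * n))
    dist = np.sqrt(((points - np.asarray(center)) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")  # stable: ties broken by index
    return points[np.sort(order[:m])]


def _core_indices(dist: np.ndarray, delta: float) -> np.ndarray:
    m = int(np.ceil(delta * len(dist)))
    return np.sort(np.argsort(dist, kind="stable")[:m])


def _kmeans_pp(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(points)
    centers = [points[int(rng.integers(n))]]
    d2 = ((points - centers[0]) ** 2).sum(axis=1)
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers.append(points[idx])
        d2 = np.minimum(d2, ((points - centers[-1]) ** 2).sum(axis=1))
    return np.asarray(centers, dtype=np.float64)


def _chunked_pass(points: np.ndarray, centers: np.ndarray, n_workers: int):
    """One assignment pass: per-chunk partial results reduced in chunk order."""
    k, d = centers.shape
    chunks = [points[i:i + _CHUNK] for i in range(0, len(points), _CHUNK)]

    def work(chunk):
        a, dist_sums = assign_and_score(chunk, centers)
        counts = np.bincount(a, minlength=k).astype(np.float64)
        sums = np.zeros((k, d))
        np.add.at(sums, a, chunk)
        return a, dist_sums, counts, sums

    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(work, chunks))
    else:
        results = [work(c) for c in chunks]

    assignments = np.concatenate([r[0] for r in results])
    dist_sums = np.zeros(k)
    counts = np.zeros(k)
    coord_sums = np.zeros((k, d))
    for _, ds, cn, cs in results:  # fold in chunk order: worker-invariant
        dist_sums += ds
        counts += cn
        coord_sums += cs
    return assignments, dist_sums, counts, coord_sums


def kmeans_run(
    points: np.ndarray,
    k: int = 4,
    delta: float = 0.5,
    n_workers: int = 1,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-9,
    pixel_index: np.ndarray | None = None,
    init_centers: np.ndarray | None = None,
) -> ClusterState:
    """Run partitioned k-means to a constant summed-distance objective.

    Iterates assignment -> centre update until the objective (sum over all
    points of Euclidean distance to the assigned centre) changes by less
    than ``tol`` or ``max_iter`` is reached.  Initialisation is seeded
    k-means++ unless explicit ``init_centers`` are given (one per cluster;
    useful when prior labels suggest where the clusters are).  The result
    is bit-identical for any ``n_workers``.  The core filter flags, per
    cluster, the ``delta`` fraction of points nearest the final centre.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    n = len(points)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")
    rng = np.random.default_rng(seed)
    if init_centers is not None:
        centers = np.atleast_2d(np.asarray(init_centers, dtype=np.float64)).copy()
        if centers.shape != (k, points.shape[1]):
            raise ValueError("init_centers must have shape (k, n_features)")
    else:
        centers = _kmeans_pp(points, k, rng)
    history: list[float] = []
    prev_obj = np.inf
    assignments = np.zeros(n, dtype=int)
    prev_state = None  # last accepted (assignments, centers)
    it = 0
    for it in range(1, max_iter + 1):
        assignments, dist_sums, counts, coord_sums = _chunked_pass(
            points, centers, n_workers
        )
        obj = float(dist_sums.sum())
        if obj > prev_obj + tol:
            # plain-distance objective is not formally guaranteed monotone
            # under mean updates; reject the increase and stop at the last
            # accepted state
            log.warning("kmeans: objective rose (%g -> %g); stopping", prev_obj, obj)
            assignments, centers = prev_state
            break
        history.append(obj)
        prev_state = (assignments, centers)
        new_centers = centers.copy()
        nonempty = counts > 0
        new_centers[nonempty] = coord_sums[nonempty] / counts[nonempty, None]
        if abs(prev_obj - obj) < tol:
            prev_obj = obj
            break
        prev_obj = obj
        centers = new_centers
    # per-cluster core flags on the final assignment
    dist = np.sqrt(((points - centers[assignments]) ** 2).sum(axis=1))
    core = np.zeros(n, dtype=bool)
    for c in range(k):
        idx = np.nonzero(assignments == c)[0]
        if idx.size:
            core[idx[_core_indices(dist[idx], delta)]] = True
    return ClusterState(
        k=k, centers=centers, assignments=assignments,
        objective=history[-1] if history else float(dist.sum()),
        core_fraction=delta, iteration=it, objective_history=history,
        core_mask=core, pixel_index=pixel_index,
    )


# ---------------------------------------------------------------------------
# pixel features and label refinement
# ---------------------------------------------------------------------------

def pixel_features(
    img: np.ndarray,
    ranges: TissueRanges | None = None,
    spatial_weight: float = 0.01,
    upper_margin: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature points (w*row, w*col, grey) for pixels in the tissue band.

    The band spans from the background cutoff to the top of the skull band
    plus ``upper_margin`` grey levels (denoising smooths some edge pixels
    slightly out of the top band; the margin lets clustering reclaim them),
    so inter-band gap pixels (candidates for refinement) are included while
    background and far-out-of-band structures are not.  The spatial weight
    keeps grey level dominant: cluster centres are meant to stand for
    tissues, which spatial coordinates alone cannot separate in concentric
    anatomy.
    """
    ranges = ranges or TissueRanges()
    img = np.asarray(img, dtype=np.float64)
    lo = ranges.background_cutoff
    hi = ranges.skull[1] + upper_margin
    mask = (img >= lo) & (img <= hi)
    rows, cols = np.nonzero(mask)
    feats = np.column_stack([
        spatial_weight * rows, spatial_weight * cols, img[rows, cols]
    ])
    return feats, np.column_stack([rows, cols])


def refine_labels(
    lm: np.ndarray,
    img: np.ndarray,
    state: ClusterState,
    ranges: TissueRanges | None = None,
) -> np.ndarray:
    """Refine a label map with a converged cluster state.

    Each cluster maps to the tissue whose band contains its mean grey level
    (clusters whose mean falls in a gap stay unmapped, with a warning).
    UNASSIGNED pixels inherit their cluster's tissue; already-labelled
    pixels keep their label unless they are non-core, disagree with their
    cluster's tissue, *and* their own grey level falls outside their current
    label's band.  The last guard keeps refinement from overriding
    intensity-consistent labels when a cluster happens to straddle two
    bands, and makes refinement a no-op on clean in-band data.
    """
    ranges = ranges or TissueRanges()
    if state.pixel_index is None:
        raise ValueError("state carries no pixel index; build it with pixel_features")
    lm = np.asarray(lm, dtype=np.uint8)
    img = np.asarray(img, dtype=np.float64)
    out = lm.copy()
    rows, cols = state.pixel_index[:, 0], state.pixel_index[:, 1]
    grey = img[rows, cols]
    tissue_of_cluster: dict[int, int | None] = {}
    for c in range(state.k):
        member = state.assignments == c
        if not member.any():
            tissue_of_cluster[c] = None
            continue
        mean_grey = float(grey[member].mean())
        lab = ranges.classify_value(mean_grey)
        if lab in TISSUE_CLASSES:
            tissue_of_cluster[c] = int(lab)
        else:
            tissue_of_cluster[c] = None
            log.warning(
                "refine_labels: cluster %d mean grey %.1f is in no tissue band; "
                "its pixels are left unchanged", c, mean_grey,
            )
    lut = ranges.label_lut()
    for c, tissue in tissue_of_cluster.items():
        if tissue is None:
            continue
        member = state.assignments == c
        r, cc = rows[member], cols[member]
        cur = out[r, cc]
        core = state.core_mask[member] if state.core_mask is not None else np.ones(
            member.sum(), dtype=bool)
        own_band = lut[np.clip(grey[member], 0, 255).astype(np.uint8)] == cur
        take = (cur == Tissue.UNASSIGNED) | (
            (~core) & (cur != tissue) & ~own_band
            & np.isin(cur, [int(t) for t in TISSUE_CLASSES])
        )
        out[r[take], cc[take]] = tissue
    return out


# ---------------------------------------------------------------------------
# flattened dataset matrix dialect
# ---------------------------------------------------------------------------

def write_flat_matrix(images: list[np.ndarray], path, fmt: str = "tsv") -> None:
    """Write a dataset as one matrix: one row per image, first entry the
    image index, the rest the row-major pixels."""
    rows = [np.concatenate([[i], np.asarray(im, dtype=np.int64).ravel()])
            for i, im in enumerate(images)]
    mat = np.stack(rows)
    path = Path(path)
    if fmt == "tsv":
        np.savetxt(path, mat, fmt="%d", delimiter="\t")
    elif fmt == "npy":
        np.save(path, mat)
    else:
        raise ValueError("fmt must be 'tsv' or 'npy'")


def read_flat_matrix(path, size: int | None = None) -> list[tuple[int, np.ndarray]]:
    """Read the flattened matrix dialect back into (index, image) pairs."""
    path = Path(path)
    if path.suffix == ".npy":
        mat = np.load(path)
    else:
        mat = np.loadtxt(path, delimiter="\t", dtype=np.int64, ndmin=2)
    out = []
    for row in mat:
        idx, pixels = int(row[0]), row[1:]
        side = size or int(round(np.sqrt(pixels.size)))
        out.append((idx, pixels.reshape(side, -1).astype(np.uint8)))
    return out
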