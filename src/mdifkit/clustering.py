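"""Functional grouping of voxel time-activity curves.

Voxel TACs inside a tissue mask are partitioned by k-medoids under
Euclidean distance. For clustering only, frames are first denoised with a
HYPR-style composite-guided spatial filter; cluster summary TACs are always
taken from the original, unfiltered image so that no denoising bias reaches
quantification. Cluster selection keeps the largest clusters per tissue
class; an optional rule drops the earliest-peaking cluster as a vascular /
non-brain signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .kinetics import TAC, TimeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicImage",
    "ClusterSet",
    "hypr_denoise",
    "cluster_tacs",
    "select_clusters",
    "drop_vascular_cluster",
]

#: Division guard in the HYPR ratio image.
HYPR_EPS = 1e-12


@dataclass
class DynamicImage:
    """A 4D dynamic volume (x, y, z, frame) with named binary masks."""

    data: np.ndarray
    grid: TimeGrid
    voxel_size: tuple = (1.0, 1.0, 1.0)
    masks: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.data, float)
        if d.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if d.shape[3] != len(self.grid):
            raise ValueError(
                f"{d.shape[3]} frames in image but {len(self.grid)} in the schedule"
            )
        for name, m in self.masks.items():
            if m.shape != d.shape[:3]:
                raise ValueError(f"mask {name!r} shape {m.shape} != image {d.shape[:3]}")
        self.data = d

    @property
    def shape(self):
        return self.data.shape[:3]

    def mask(self, name: str) -> np.ndarray:
        try:
            return self.masks[name].astype(bool)
        except KeyError:
            raise KeyError(f"no mask named {name!r}; have {sorted(self.masks)}") from None

    def voxel_tacs(self, mask_name: str):
        """(n_voxels, T) matrix of in-mask TACs plus the voxel index array."""
        m = self.mask(mask_name)
        idx = np.argwhere(m)
        return self.data[m], idx


def hypr_denoise(img: DynamicImage, sigma_voxels: float = 3.0) -> DynamicImage:
    """Composite-guided (HYPR-style) spatial denoising of each frame.

    out_f = C * G(img_f) / (G(C) + eps), with C the duration-weighted sum
    over frames and G a Gaussian kernel of ``sigma_voxels``. The composite
    carries the spatial detail; each frame contributes only its smooth
    temporal modulation, so noise drops while region-scale dynamics are
    preserved. Intended only to stabilize clustering — never use the output
    for quantification.
    """
    if sigma_voxels <= 0:
        raise ValueError("sigma must be > 0")
    dur = img.grid.frame_duration
    composite = np.tensordot(img.data, dur, axes=([3], [0]))
    if not np.any(composite != 0):
        raise ValueError("all-zero composite image; nothing to denoise")
    smooth_comp = gaussian_filter(composite, sigma_voxels)
    out = np.empty_like(img.data)
    ratio_denom = smooth_comp + HYPR_EPS
    for f in range(img.data.shape[3]):
        out[..., f] = composite * gaussian_filter(img.data[..., f], sigma_voxels) / ratio_denom
    return DynamicImage(out, img.grid, img.voxel_size, dict(img.masks))


@dataclass
class ClusterSet:
    """A k-medoids partition of in-mask voxels.

    ``labels`` maps each voxel to 1..k (0 = outside the mask). Medoid TACs
    and cluster mean TACs are extracted from the original image.
    """

    labels: np.ndarray
    medoid_tacs: list
    mean_tacs: list
    sizes: np.ndarray
    tissue_class: list
    cost: float = 0.0
    cost_histories: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.medoid_tacs)


def _kmedoids_once(X, k, rng, max_iter):
    """Voronoi-style k-medoids: assign to nearest medoid, recompute each
    medoid as the in-cluster point minimizing summed distance. The total
    cost is non-increasing across iterations."""
    n = X.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    history = []
    for _ in range(max_iter):
        d = cdist(X, X[medoids])
        assign = np.argmin(d, axis=1)
        history.append(float(d[np.arange(n), assign].sum()))
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            sub = X[members]
            dd = cdist(sub, sub).sum(axis=0)
            new_medoids[c] = members[np.argmin(dd)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            medoids = new_medoids
            break
        medoids = new_medoids
    d = cdist(X, X[medoids])
    assign = np.argmin(d, axis=1)
    cost = float(d[np.arange(n), assign].sum())
    history.append(cost)
    return medoids, assign, cost, np.array(history)


def cluster_tacs(
    img: DynamicImage,
    mask_name: str,
    k: int,
    seed: int = 0,
    n_replicates: int = 10,
    max_iter: int = 500,
    denoise: bool = True,
    sigma_voxels: float = 3.0,
) -> ClusterSet:
    """k-medoids partition of in-mask voxel TACs (Euclidean distance).

    Feature vectors are the (optionally HYPR-denoised) raw frame values.
    The best of ``n_replicates`` random restarts (lowest within-cluster
    cost) wins; the run is deterministic for a given ``seed``. Cluster mean
    and medoid TACs are computed from the original image.
    """
    source = hypr_denoise(img, sigma_voxels) if denoise else img
    X, idx = source.voxel_tacs(mask_name)
    orig, _ = img.voxel_tacs(mask_name)
    if X.shape[0] == 0:
        raise ValueError(f"mask {mask_name!r} is empty")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k = {k} exceeds the {n_distinct} distinct TACs in the mask")
    rng = np.random.default_rng(seed)
    best = None
    histories = []
    for _ in range(n_replicates):
        medoids, assign, cost, hist = _kmedoids_once(X, k, rng, max_iter)
        histories.append(hist)
        if best is None or cost < best[2]:
            best = (medoids, assign, cost)
    medoids, assign, cost = best
    labels = np.zeros(img.shape, dtype=int)
    labels[tuple(idx.T)] = assign + 1
    sizes = np.bincount(assign, minlength=k)
    medoid_tacs = [
        TAC(img.grid, orig[m], label=f"{mask_name}-medoid-{c + 1}")
        for c, m in enumerate(medoids)
    ]
    mean_tacs = [
        TAC(
            img.grid,
            orig[assign == c].mean(axis=0) if sizes[c] else np.zeros(len(img.grid)),
            label=f"{mask_name}-cluster-{c + 1}",
        )
        for c in range(k)
    ]
    return ClusterSet(
        labels=labels,
        medoid_tacs=medoid_tacs,
        mean_tacs=mean_tacs,
        sizes=sizes,
        tissue_class=[mask_name] * k,
        cost=cost,
        cost_histories=histories,
    )


def select_clusters(cs_gm: ClusterSet, cs_wm: ClusterSet, n_per_class: int = 3) -> list:
    """The ``n_per_class`` largest clusters of each tissue class, as mean TACs.

    Ordered grey-matter first then white-matter, size-descending within a
    class; ties broken by lower cluster index.
    """
    out = []
    for cs in (cs_gm, cs_wm):
        order = sorted(range(cs.k), key=lambda c: (-cs.sizes[c], c))
        out.extend(cs.mean_tacs[c] for c in order[:n_per_class])
    return out


def drop_vascular_cluster(cs: ClusterSet) -> ClusterSet:
    """Remove the cluster whose mean TAC peaks earliest.

    A very early peak is the signature of blood-dominated (non-brain)
    voxels. This is a heuristic stand-in for a qualitative exclusion rule
    and is logged when applied.
    """
    peaks = [tac.t[int(np.argmax(tac.values))] for tac in cs.mean_tacs]
    drop = int(np.argmin(peaks))
    logger.info(
        "excluding cluster %d (earliest mean-TAC peak at %.2f min) as non-brain",
        drop + 1,
        peaks[drop],
    )
    keep = [c for c in range(cs.k) if c != drop]
    labels = cs.labels.copy()
    labels[labels == drop + 1] = 0
    remap = {old + 1: new + 1 for new, old in enumerate(keep)}
    for old, new in remap.items():
        labels[cs.labels == old] = new
    return ClusterSet(
        labels=labels,
        medoid_tacs=[cs.medoid_tacs[c] for c in keep],
        mean_tacs=[cs.mean_tacs[c] for c in keep],
        sizes=cs.sizes[keep],
        tissue_class=[cs.tissue_class[c] for c in keep],
        cost=cs.cost,
        cost_histories=cs.cost_histories,
    )
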