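"""Tumor habitat subregioning by K-means on per-voxel (D, f) vectors.

Every in-mask voxel contributes a two-dimensional vector (D, f).  Vectors are
pooled (by default across lesions), z-scored per dimension — raw D (~1e-3
mm^2/s) and f (~0.1) differ by two orders of magnitude, so unstandardized
Euclidean K-means would ignore D — and clustered with K-means.  The number of
clusters is chosen by the Calinski-Harabasz criterion over a candidate range,
and the K = 4 solution is mapped onto a canonical part ordering:

* part 2 — highest-D centroid (necrotic/edematous),
* part 3 — highest-f centroid among the rest (hypervascular),
* part 4 — lowest D + f among the rest (dense, hypoperfused),
* part 1 — the remaining centroid (low D, intermediate f).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .dwi import VoiMask
from .ivim import IvimMaps

__all__ = [
    "VoxelVectorSet",
    "HabitatModel",
    "collect_vectors",
    "standardize",
    "kmeans_fit",
    "ch_score",
    "select_k",
    "canonical_parts",
    "assign_habitats",
    "habitat_summary",
]


@dataclass
class VoxelVectorSet:
    """Per-voxel (D, f) vectors with their source coordinates."""

    values: np.ndarray               # (n, 2)
    coords: np.ndarray               # (n, 3) integer voxel coordinates
    n_dropped: int = 0               # non-finite voxels removed
    mean: np.ndarray | None = None   # standardization parameters, if applied
    sd: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class HabitatModel:
    """Fitted pooled clustering: centroids in standardized (D, f) space,
    the standardization parameters, the canonical part permutation, and the
    Calinski-Harabasz curve over candidate K."""

    k: int
    centroids: np.ndarray            # (k, 2), standardized space
    mean: np.ndarray                 # (2,)
    sd: np.ndarray                   # (2,)
    part_of_cluster: np.ndarray      # cluster index -> part label in 1..k
    ch_curve: dict[int, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "part_of_cluster": self.part_of_cluster.tolist(),
            "ch_curve": {str(k): v for k, v in self.ch_curve.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HabitatModel":
        p = json.loads(Path(path).read_text())
        return cls(k=p["k"], centroids=np.asarray(p["centroids"]),
                   mean=np.asarray(p["mean"]), sd=np.asarray(p["sd"]),
                   part_of_cluster=np.asarray(p["part_of_cluster"], dtype=int),
                   ch_curve={int(k): v for k, v in p["ch_curve"].items()},
                   seed=p["seed"])


def collect_vectors(maps: IvimMaps, mask: VoiMask) -> VoxelVectorSet:
    """One (D, f) vector per in-mask voxel; non-finite voxels are dropped."""
    coords = np.argwhere(mask.data)
    d = maps.d[mask.data]
    f = maps.f[mask.data]
    values = np.column_stack([d, f])
    finite = np.isfinite(values).all(axis=1)
    n_dropped = int((~finite).sum())
    values, coords = values[finite], coords[finite]
    if values.shape[0] == 0:
        raise ValueError("no finite voxel vectors in the mask")
    return VoxelVectorSet(values=values, coords=coords, n_dropped=n_dropped)


def standardize(vectors: VoxelVectorSet) -> VoxelVectorSet:
    """Z-score each dimension over the pooled set (population SD)."""
    if vectors.n < 2:
        raise ValueError("need at least 2 vectors to standardize")
    mean = vectors.values.mean(axis=0)
    sd = vectors.values.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance dimension cannot be standardized")
    return VoxelVectorSet(values=(vectors.values - mean) / sd,
                          coords=vectors.coords, n_dropped=vectors.n_dropped,
                          mean=mean, sd=sd)


def kmeans_fit(x: np.ndarray, k: int, seed: int = 0,
               n_init: int = 10) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's algorithm with k-means++ seeding and restarts.

    Returns (centroids, labels, inertia); deterministic under *seed*.
    """
    x = np.asarray(x, dtype=float)
    if k < 2:
        raise ValueError("K must be at least 2")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError("K exceeds the number of distinct vectors")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(x)
    return km.cluster_centers_, labels, float(km.inertia_)


def ch_score(x: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz criterion [BSS/(K-1)] / [WSS/(n-K)].

    BSS is the between-cluster sum of squared distances of cluster centroids
    to the overall mean (weighted by cluster size), WSS the within-cluster sum
    of squared distances to cluster centroids.  Returns ``inf`` when WSS = 0
    (all clusters are point masses).
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = uniq.size, x.shape[0]
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if n <= k:
        raise ValueError("need more points than clusters")
    grand = x.mean(axis=0)
    bss = 0.0
    wss = 0.0
    for lab in uniq:
        xi = x[labels == lab]
        ci = xi.mean(axis=0)
        bss += xi.shape[0] * float(np.sum((ci - grand) ** 2))
        wss += float(np.sum((xi - ci) ** 2))
    if wss == 0.0:
        return float("inf")
    return (bss / (k - 1)) / (wss / (n - k))


def select_k(vectors: VoxelVectorSet, k_range: range | list[int] = range(2, 9),
             seed: int = 0, n_init: int = 10) -> HabitatModel:
    """Fit K-means per candidate K and keep the Calinski-Harabasz argmax.

    Vectors must already be standardized (parameters stored).  Ties resolve
    to the smallest K (parsimony).
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("empty K range")
    if vectors.mean is None or vectors.sd is None:
        raise ValueError("vectors must be standardized before clustering")
    curve: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in ks:
        centroids, labels, _ = kmeans_fit(vectors.values, k, seed=seed, n_init=n_init)
        curve[k] = ch_score(vectors.values, labels)
        fits[k] = centroids
    best = max(ks, key=lambda k: (curve[k], -k))
    centroids = fits[best]
    perm = canonical_parts(centroids)
    return HabitatModel(k=best, centroids=centroids, mean=vectors.mean,
                        sd=vectors.sd, part_of_cluster=perm, ch_curve=curve,
                        seed=seed)


def canonical_parts(centroids: np.ndarray) -> np.ndarray:
    """Map cluster indices to canonical part labels.

    For K = 4 (the study's structure): part 2 = max centroid D; part 3 = max
    centroid f among the remaining; part 4 = min (D + f) among the remaining;
    part 1 = the last centroid.  Comparisons are made in the (standardized)
    clustering space; ties break by centroid f then D.  For K != 4 the
    fallback is lexicographic (D, f) order.
    """
    centroids = np.asarray(centroids, dtype=float)
    k = centroids.shape[0]
    part = np.zeros(k, dtype=int)
    if k != 4:
        order = np.lexsort((centroids[:, 1], centroids[:, 0]))
        for rank, idx in enumerate(order, start=1):
            part[idx] = rank
        return part

    remaining = list(range(4))

    def pick(key):
        best = max(remaining, key=key)
        remaining.remove(best)
        return best

    i2 = pick(lambda i: (centroids[i, 0], centroids[i, 1]))
    i3 = pick(lambda i: (centroids[i, 1], centroids[i, 0]))
    i4 = pick(lambda i: (-(centroids[i, 0] + centroids[i, 1]),
                         -centroids[i, 1], -centroids[i, 0]))
    i1 = remaining[0]
    part[i2], part[i3], part[i4], part[i1] = 2, 3, 4, 1
    return part


def assign_habitats(maps: IvimMaps, mask: VoiMask,
                    model: HabitatModel) -> np.ndarray:
    """Label each in-mask voxel with the canonical part of its nearest
    centroid in standardized (D, f) space.  Returns a 3D integer label map,
    0 outside the mask."""
    vectors = collect_vectors(maps, mask)
    z = (vectors.values - model.mean) / model.sd
    d2 = ((z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    label_map = np.zeros(mask.data.shape, dtype=np.int32)
    ix, iy, iz = vectors.coords.T
    label_map[ix, iy, iz] = model.part_of_cluster[nearest]
    return label_map


def habitat_summary(label_map: np.ndarray, spacing: tuple[float, float, float],
                    k: int | None = None) -> pd.DataFrame:
    """Per-part volume (mm^3) and volume fraction of the lesion."""
    label_map = np.asarray(label_map)
    if not (label_map > 0).any():
        raise ValueError("empty label map")
    voxel_volume = float(np.prod(spacing))
    total = int((label_map > 0).sum())
    k = k if k is not None else int(label_map.max())
    rows = []
    for part in range(1, k + 1):
        count = int((label_map == part).sum())
        rows.append({"part": part, "volume_mm3": count * voxel_volume,
                     "volume_fraction": count / total})
    return pd.DataFrame(rows)
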