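"""IBSI-style radiomic feature extraction on IVIM parameter maps.

Three families are implemented:

* first-order histogram statistics (raw intensities, plus entropy and
  uniformity on equal-frequency-discretized intensities);
* 3D shape descriptors of the lesion mask;
* gray-level co-occurrence matrix (GLCM) texture at distance 1, symmetric,
  aggregated over the 13 unique 3D directions.

Whole-tumor extraction z-scores each map over the VOI before the histogram
and texture steps; habitat extraction keeps raw D / f intensities per part so
that part-level statistics (e.g. the median D of a subregion) remain
physically interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area

from .dwi import VoiMask
from .habitat import habitat_summary
from .ivim import IvimMaps

__all__ = [
    "DiscretizationSpec",
    "FeatureVector",
    "FeatureTable",
    "znormalize_region",
    "discretize_equal_frequency",
    "first_order_features",
    "shape_features",
    "glcm_features",
    "extract_whole_tumor",
    "extract_habitat_features",
]

FIRST_ORDER_NAMES = (
    "mean", "median", "p10", "p90", "minimum", "maximum", "range", "variance",
    "skewness", "kurtosis", "iqr", "mad", "rmad", "rms", "entropy", "uniformity",
)

GLCM_NAMES = (
    "joint_energy", "joint_entropy", "contrast", "correlation", "dissimilarity",
    "inverse_difference", "idm", "cluster_shade", "cluster_prominence",
    "max_probability", "sum_average", "sum_entropy", "difference_entropy",
)

#: the 13 unique 3D neighbor directions (one per +/- pair of the 26 neighbors)
GLCM_OFFSETS = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(GLCM_OFFSETS) == 13


@dataclass(frozen=True)
class DiscretizationSpec:
    """Equal-frequency intensity discretization into *bins* gray levels."""

    bins: int = 32

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bin count must be at least 2")


@dataclass
class FeatureVector:
    """Named scalar features with (source, region, family) provenance tags."""

    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)

    def add(self, name: str, value: float, source: str, region: str,
            family: str) -> None:
        if name in self.values:
            raise ValueError(f"duplicate feature name {name!r}")
        self.values[name] = float(value)
        self.provenance[name] = {"source": source, "region": region,
                                 "family": family}

    def update(self, other: "FeatureVector") -> None:
        for name, value in other.values.items():
            prov = other.provenance[name]
            self.add(name, value, prov["source"], prov["region"], prov["family"])


@dataclass
class FeatureTable:
    """Lesion x feature matrix with column provenance and optional labels."""

    data: pd.DataFrame
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)
    labels: pd.DataFrame | None = None

    @classmethod
    def from_vectors(cls, vectors: dict[str, FeatureVector],
                     labels: pd.DataFrame | None = None) -> "FeatureTable":
        rows = {lid: fv.values for lid, fv in vectors.items()}
        prov = next(iter(vectors.values())).provenance if vectors else {}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "lesion"
        return cls(data=df, provenance=prov, labels=labels)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path)
        sidecar = path.with_suffix(".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2))

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        sidecar = path.with_suffix(".provenance.json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(data=df, provenance=prov)


# ---------------------------------------------------------------------------
# preprocessing

def znormalize_region(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Z-score voxel intensities over a region (population SD).

    Returns (normalized values, constant-region flag); a constant region maps
    to all zeros with the flag set.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values), True
    return (values - values.mean()) / sd, False


def discretize_equal_frequency(values: np.ndarray,
                               spec: DiscretizationSpec) -> np.ndarray:
    """Assign integer gray levels 1..B with bin edges at empirical quantiles.

    Values equal to an edge fall in the lower bin; with distinct values each
    bin holds n/B values up to rounding.
    """
    values = np.asarray(values, dtype=float)
    b = spec.bins
    if values.size < b:
        raise ValueError("need at least as many values as bins")
    edges = np.quantile(values, [i / b for i in range(1, b)])
    return np.searchsorted(edges, values, side="left") + 1


# ---------------------------------------------------------------------------
# first-order

def first_order_features(values: np.ndarray,
                         discretized: np.ndarray | None = None,
                         spec: DiscretizationSpec | None = None) -> dict[str, float]:
    """First-order histogram statistics.

    Continuous statistics use the raw *values*; entropy (log2) and uniformity
    use the discretized gray levels (computed here from *spec* when not
    supplied).  Percentiles interpolate linearly between order statistics;
    variance is the population variance; kurtosis is the non-excess
    (Pearson) convention.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty region")
    out: dict[str, float] = {}
    out["mean"] = float(values.mean())
    out["median"] = float(np.median(values))
    out["p10"] = float(np.percentile(values, 10))
    out["p90"] = float(np.percentile(values, 90))
    out["minimum"] = float(values.min())
    out["maximum"] = float(values.max())
    out["range"] = out["maximum"] - out["minimum"]
    centered = values - values.mean()
    m2 = float(np.mean(centered ** 2))
    if values.size < 2 or m2 == 0:
        out["variance"] = 0.0
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    else:
        out["variance"] = m2
        out["skewness"] = float(np.mean(centered ** 3)) / m2 ** 1.5
        out["kurtosis"] = float(np.mean(centered ** 4)) / m2 ** 2
    out["iqr"] = float(np.percentile(values, 75) - np.percentile(values, 25))
    out["mad"] = float(np.abs(values - values.mean()).mean())
    inner = values[(values >= out["p10"]) & (values <= out["p90"])]
    out["rmad"] = float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0
    out["rms"] = float(np.sqrt(np.mean(values ** 2)))

    if discretized is None:
        if spec is not None and values.size >= spec.bins:
            discretized = discretize_equal_frequency(values, spec)
        else:
            discretized = np.ones(values.size, dtype=int)
    counts = np.bincount(np.asarray(discretized, dtype=int))[1:]
    p = counts[counts > 0] / counts.sum()
    out["entropy"] = float(-(p * np.log2(p)).sum())
    out["uniformity"] = float((p ** 2).sum())
    return out


# ---------------------------------------------------------------------------
# shape

def shape_features(mask: VoiMask,
                   spacing: tuple[float, float, float] | None = None) -> dict[str, float]:
    """3D shape descriptors: volume, mesh surface area, sphericity,
    maximum 3D diameter, and principal-axis elongation/flatness."""
    spacing = spacing if spacing is not None else mask.spacing
    m = mask.data
    voxel_volume = float(np.prod(spacing))
    volume = mask.n_voxels * voxel_volume

    # surface area from a triangulated boundary mesh (marching cubes), the
    # IBSI convention; a raw voxel-face count overstates curved surfaces
    padded = np.pad(m.astype(float), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(mesh_surface_area(verts, faces))

    sphericity = (np.pi ** (1 / 3) * (6 * volume) ** (2 / 3)) / area

    # the maximum pairwise distance is attained between boundary voxels
    interior = ndimage.binary_erosion(m)
    boundary = m & ~interior
    bcoords = np.argwhere(boundary).astype(float) * np.asarray(spacing)
    max_diameter = float(pdist(bcoords).max()) if bcoords.shape[0] >= 2 else 0.0

    coords = np.argwhere(m).astype(float) * np.asarray(spacing)
    if coords.shape[0] < 2:
        elongation, flatness = 1.0, 1.0
    else:
        cov = np.cov(coords, rowvar=False, bias=True)
        eig = np.maximum(np.sort(np.linalg.eigvalsh(cov))[::-1], 0.0)
        if eig[0] == 0:
            elongation, flatness = 1.0, 1.0
        else:
            elongation = float(np.sqrt(eig[1] / eig[0]))
            flatness = float(np.sqrt(eig[2] / eig[0]))

    return {"volume": volume, "surface_area": area, "sphericity": sphericity,
            "max_diameter": max_diameter, "elongation": elongation,
            "flatness": flatness}


# ---------------------------------------------------------------------------
# GLCM

def _pair_slices(shape: tuple[int, ...], off: tuple[int, ...]):
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def _glcm_matrix(levels: np.ndarray, region: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix at distance 1 over the 13
    unique 3D directions; both voxels of a pair must lie in the region."""
    p = np.zeros((n_levels, n_levels), dtype=float)
    for off in GLCM_OFFSETS:
        src, dst = _pair_slices(levels.shape, off)
        valid = region[src] & region[dst]
        ai = levels[src][valid] - 1
        bi = levels[dst][valid] - 1
        np.add.at(p, (ai, bi), 1.0)
        np.add.at(p, (bi, ai), 1.0)
    total = p.sum()
    if total > 0:
        p /= total
    return p


def glcm_features(levels_3d: np.ndarray, region: np.ndarray,
                  n_levels: int | None = None) -> dict[str, float]:
    """Standard GLCM texture statistics from a discretized (1..B) volume.

    A region whose voxels all share one gray level yields the degenerate
    matrix: joint energy 1, contrast 0, joint entropy 0.
    """
    region = np.asarray(region).astype(bool)
    if region.sum() < 2:
        raise ValueError("GLCM needs a region of at least 2 voxels")
    levels_3d = np.asarray(levels_3d, dtype=int)
    if n_levels is None:
        n_levels = int(levels_3d[region].max())
    p = _glcm_matrix(levels_3d, region, n_levels)
    if p.sum() == 0:  # no adjacent in-region pairs: degenerate delta matrix
        lev = int(round(float(np.median(levels_3d[region])))) - 1
        p[lev, lev] = 1.0

    i = np.arange(1, n_levels + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric matrix: both marginals coincide
    mu_x = float((i * px).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    nz = p > 0

    out: dict[str, float] = {}
    out["joint_energy"] = float((p ** 2).sum())
    out["joint_entropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    out["contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sigma_x == 0:
        out["correlation"] = 1.0
    else:
        out["correlation"] = float(
            (((ii - mu_x) * (jj - mu_x) * p).sum()) / (sigma_x * sigma_x))
    out["dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    out["inverse_difference"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    out["idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    out["cluster_shade"] = float((((ii + jj - 2 * mu_x) ** 3) * p).sum())
    out["cluster_prominence"] = float((((ii + jj - 2 * mu_x) ** 4) * p).sum())
    out["max_probability"] = float(p.max())

    k_sum = np.arange(2, 2 * n_levels + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    out["sum_average"] = float((k_sum * p_sum).sum())
    nz_s = p_sum > 0
    out["sum_entropy"] = float(-(p_sum[nz_s] * np.log2(p_sum[nz_s])).sum())
    k_diff = np.arange(0, n_levels, dtype=float)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    nz_d = p_diff > 0
    out["difference_entropy"] = float(-(p_diff[nz_d] * np.log2(p_diff[nz_d])).sum())
    return out


# ---------------------------------------------------------------------------
# extraction drivers

_SMALL_REGION = 10  # parts below this voxel count are flagged as unstable


def extract_whole_tumor(maps: IvimMaps, mask: VoiMask,
                        spec: DiscretizationSpec = DiscretizationSpec(),
                        sources: tuple[str, ...] = ("D", "f")) -> FeatureVector:
    """Shape features of the VOI plus, per source map, first-order and GLCM
    features after within-VOI z-normalization and equal-frequency
    discretization."""
    fv = FeatureVector()
    for name, value in shape_features(mask).items():
        fv.add(f"shape_whole_{name}", value, "mask", "whole", "shape")

    source_maps = {"D": maps.d, "f": maps.f, "Dstar": maps.dstar, "S0": maps.s0}
    for src in sources:
        vol = source_maps[src]
        vals = vol[mask.data]
        z, _ = znormalize_region(vals)
        if z.size >= spec.bins:
            disc = discretize_equal_frequency(z, spec)
        else:
            disc = np.ones(z.size, dtype=int)
        for name, value in first_order_features(z, disc).items():
            fv.add(f"{src}_whole_firstorder_{name}", value, src, "whole",
                   "first-order")
        levels = np.zeros(mask.data.shape, dtype=int)
        levels[mask.data] = disc
        for name, value in glcm_features(levels, mask.data, spec.bins).items():
            fv.add(f"{src}_whole_glcm_{name}", value, src, "whole", "GLCM")
    return fv


def extract_habitat_features(maps: IvimMaps, label_map: np.ndarray,
                             mask: VoiMask, k: int,
                             spec: DiscretizationSpec = DiscretizationSpec()
                             ) -> FeatureVector:
    """Per canonical part: volume, volume fraction, and first-order features
    of the raw D and f intensities restricted to the part.  Absent parts
    yield zeros plus an absence flag; parts below 10 voxels are flagged as
    unstable but still computed."""
    fv = FeatureVector()
    summary = habitat_summary(label_map, mask.spacing, k)
    source_maps = {"D": maps.d, "f": maps.f}
    for part in range(1, k + 1):
        region = label_map == part
        count = int(region.sum())
        row = summary[summary["part"] == part].iloc[0]
        pname = f"part{part}"
        fv.add(f"{pname}_volume", row["volume_mm3"], "mask", pname,
               "habitat-geometry")
        fv.add(f"{pname}_volume_fraction", row["volume_fraction"], "mask",
               pname, "habitat-geometry")
        fv.add(f"{pname}_absent", float(count == 0), "mask", pname,
               "habitat-geometry")
        fv.add(f"{pname}_unstable", float(0 < count < _SMALL_REGION), "mask",
               pname, "habitat-geometry")
        for src, vol in source_maps.items():
            if count == 0:
                feats = {name: 0.0 for name in FIRST_ORDER_NAMES}
            else:
                feats = first_order_features(vol[region], spec=spec)
            for name, value in feats.items():
                fv.add(f"{src}_{pname}_firstorder_{name}", value, src, pname,
                       "first-order")
    return fv
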