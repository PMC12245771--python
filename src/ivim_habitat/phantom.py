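"""Synthetic inputs for the habitat-imaging pipeline.

Three generators cover everything downstream stages consume:

* :func:`make_ivim_phantom` — a 4D multi-b-value DWI volume whose lesion is a
  union of disjoint habitat geometries, each with its own (S0, D, D*, f),
  degraded by Rician noise (magnitude MR data);
* :func:`sample_vector_mixture` — pooled (D, f) voxel vectors from a planted
  Gaussian mixture, for cluster-number and label-recovery studies;
* :func:`make_synthetic_cohort` — lesion-by-feature tables with planted
  class-conditional effects, binary endpoint labels, and a paired
  re-segmentation replicate table for ICC robustness testing.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dwi import BValueProtocol, DwiStack, VoiMask, DEFAULT_PROTOCOL
from .ivim import forward_signal

__all__ = [
    "Ellipsoid",
    "Box",
    "HabitatSpec",
    "PhantomConfig",
    "PhantomTruth",
    "default_phantom_config",
    "add_rician_noise",
    "make_ivim_phantom",
    "sample_vector_mixture",
    "CohortFeature",
    "CohortSpec",
    "default_cohort_spec",
    "make_synthetic_cohort",
]


# ---------------------------------------------------------------------------
# geometry primitives

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def rasterize(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
        q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, self.center, self.radii))
        return q <= 1.0


@dataclass(frozen=True)
class Box:
    lo: tuple[int, int, int]
    hi: tuple[int, int, int]  # exclusive

    def rasterize(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        sl = tuple(slice(lo, hi) for lo, hi in zip(self.lo, self.hi))
        out[sl] = True
        return out


@dataclass(frozen=True)
class HabitatSpec:
    """One habitat: a geometry plus its IVIM tissue parameters."""

    geometry: Ellipsoid | Box
    s0: float
    d: float        # mm^2/s
    dstar: float    # mm^2/s
    f: float

    def __post_init__(self) -> None:
        if not (0 <= self.f < 1):
            raise ValueError("f must lie in [0, 1)")
        if not (0 < self.d < self.dstar):
            raise ValueError("require 0 < D < D*")
        if self.s0 <= 0:
            raise ValueError("S0 must be positive")


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    habitats: list[HabitatSpec]
    sigma: float
    seed: int

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")
        if self.sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if not self.habitats:
            raise ValueError("need at least one habitat")


@dataclass
class PhantomTruth:
    d: np.ndarray
    dstar: np.ndarray
    f: np.ndarray
    s0: np.ndarray
    labels: np.ndarray  # 0 background, 1..K habitats, layout order
    mask: VoiMask


def default_phantom_config(sigma: float = 0.0, seed: int = 0) -> PhantomConfig:
    """Four-habitat block phantom on a 32^3, 1 mm grid.

    The habitat parameters mirror the canonical four-part tumor structure:
    part 1 low D / intermediate f, part 2 high D (necrotic/edematous core),
    part 3 high f (hypervascular front), part 4 low D / low f (dense hypoxic
    niche).  Blocks tile a 16^3-voxel lesion so the four geometries are
    contiguous and trivially disjoint.
    """
    blocks = [
        (Box((8, 8, 8), (16, 16, 24)), 1000.0, 0.8e-3, 20e-3, 0.15),   # part 1
        (Box((16, 8, 8), (24, 16, 24)), 1000.0, 2.0e-3, 15e-3, 0.10),  # part 2
        (Box((16, 16, 8), (24, 24, 24)), 1000.0, 1.2e-3, 60e-3, 0.30), # part 3
        (Box((8, 16, 8), (16, 24, 24)), 1000.0, 0.7e-3, 8e-3, 0.04),   # part 4
    ]
    habitats = [HabitatSpec(g, s0, d, ds, f) for g, s0, d, ds, f in blocks]
    return PhantomConfig(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0),
                         habitats=habitats, sigma=sigma, seed=seed)


def add_rician_noise(signal: np.ndarray, sigma: float,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Rician-degrade a nonnegative magnitude signal.

    The output is ``sqrt((S + n1)^2 + n2^2)`` with n1, n2 i.i.d. zero-mean
    Gaussians of standard deviation *sigma* — the magnitude of a complex
    Gaussian perturbation, as measured by an MR magnitude reconstruction.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def make_ivim_phantom(
    config: PhantomConfig,
    protocol: BValueProtocol = DEFAULT_PROTOCOL,
) -> tuple[DwiStack, VoiMask, PhantomTruth]:
    """Rasterize the habitat layout and synthesize its noisy DWI stack."""
    shape = config.shape
    labels = np.zeros(shape, dtype=np.int32)
    d = np.zeros(shape)
    dstar = np.zeros(shape)
    f = np.zeros(shape)
    s0 = np.zeros(shape)
    occupied = np.zeros(shape, dtype=bool)
    for k, hab in enumerate(config.habitats, start=1):
        region = hab.geometry.rasterize(shape)
        if not region.any():
            raise ValueError(f"habitat {k} rasterizes to an empty region")
        if (region & occupied).any():
            raise ValueError(f"habitat {k} overlaps an earlier geometry")
        occupied |= region
        labels[region] = k
        d[region], dstar[region], f[region], s0[region] = hab.d, hab.dstar, hab.f, hab.s0

    mask = VoiMask(occupied, config.spacing)
    b = protocol.array
    signal = np.zeros((*shape, len(protocol)))
    for k, hab in enumerate(config.habitats, start=1):
        region = labels == k
        signal[region] = forward_signal(hab.s0, hab.d, hab.dstar, hab.f, b)
    rng = np.random.default_rng(config.seed)
    signal = add_rician_noise(signal, config.sigma, rng)

    truth = PhantomTruth(d=d, dstar=dstar, f=f, s0=s0, labels=labels, mask=mask)
    return DwiStack(signal, protocol, config.spacing), mask, truth


def sample_vector_mixture(
    centers: np.ndarray,
    sds: float | np.ndarray,
    n_per_component: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw pooled (D, f)-style vectors from an isotropic Gaussian mixture.

    Returns (vectors, component labels 1..K).  Used for planted-model
    cluster-number and label-recovery studies.
    """
    centers = np.asarray(centers, dtype=float)
    k, dim = centers.shape
    sds = np.broadcast_to(np.asarray(sds, dtype=float), (k,))
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for j in range(k):
        xs.append(rng.normal(centers[j], sds[j], size=(n_per_component, dim)))
        ys.append(np.full(n_per_component, j + 1))
    return np.vstack(xs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# tabular cohorts

@dataclass(frozen=True)
class CohortFeature:
    """A named cohort feature with planted per-endpoint effects.

    For continuous features *effects* are standardized mean shifts between
    classes; for binary features they are odds ratios applied on the logit
    scale to a baseline positivity rate.
    """

    name: str
    family: str  # "whole" | "habitat" | "cf"
    kind: str = "continuous"  # or "binary"
    effects: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = 0.3  # binary features only


@dataclass
class CohortSpec:
    n: int
    prevalence: dict[str, float]
    features: list[CohortFeature]
    rater_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValueError("cohort needs n >= 20")
        for name, p in self.prevalence.items():
            if not (0 < p < 1):
                raise ValueError(f"prevalence of {name} must be in (0, 1)")


def default_cohort_spec(n: int = 299, seed: int = 0) -> CohortSpec:
    """Cohort emulating the study population: four IHC endpoints at their
    observed prevalences, with radiomic and conventional-feature effects of
    moderate size planted per endpoint, plus uninformative filler features."""
    prevalence = {"HER2": 0.32, "Ki67": 0.45, "HR": 0.69, "LNM": 0.57}
    feats: list[CohortFeature] = []
    # whole-tumor radiomics: a handful of weakly informative + noise columns
    feats += [
        CohortFeature("D_whole_firstorder_mean", "whole", effects={"Ki67": -0.5}),
        CohortFeature("D_whole_glcm_entropy", "whole", effects={"LNM": 0.4}),
        CohortFeature("f_whole_firstorder_p90", "whole", effects={"HER2": 0.4}),
        CohortFeature("shape_whole_sphericity", "whole", effects={"HR": 0.3}),
    ]
    feats += [CohortFeature(f"whole_noise_{i:02d}", "whole") for i in range(16)]
    # habitat features: stronger planted structure (the study's premise)
    feats += [
        CohortFeature("D_part2_firstorder_p10", "habitat", effects={"HER2": 0.8}),
        CohortFeature("D_part2_firstorder_median", "habitat", effects={"Ki67": 0.7}),
        CohortFeature("part4_volume_fraction", "habitat", effects={"HR": 0.7}),
        CohortFeature("D_part4_firstorder_entropy", "habitat", effects={"LNM": 0.8}),
        CohortFeature("f_part4_firstorder_uniformity", "habitat", effects={"LNM": 0.5}),
    ]
    feats += [CohortFeature(f"habitat_noise_{i:02d}", "habitat") for i in range(10)]
    # conventional MRI features, binary-collapsed as reported
    feats += [
        CohortFeature("cf_rim_enhancement", "cf", kind="binary",
                      effects={"Ki67": 2.5, "HR": 0.5}, baseline_rate=0.5),
        CohortFeature("cf_architectural_distortion", "cf", kind="binary",
                      effects={"LNM": 1.8}, baseline_rate=0.2),
        CohortFeature("cf_high_t2_signal", "cf", kind="binary",
                      effects={}, baseline_rate=0.27),
        CohortFeature("cf_irregular_shape", "cf", kind="binary",
                      effects={"Ki67": 1.6}, baseline_rate=0.75),
        CohortFeature("cf_spiculated_margin", "cf", kind="binary",
                      effects={"HR": 1.7}, baseline_rate=0.5),
        CohortFeature("cf_washout_curve", "cf", kind="binary",
                      effects={"HER2": 1.6}, baseline_rate=0.73),
    ]
    return CohortSpec(n=n, prevalence=prevalence, features=feats, seed=seed)


def make_synthetic_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (features, labels, replicate features) for a cohort.

    Labels are balanced to the stated prevalence exactly (up to rounding).
    Continuous features are standard normal plus the planted standardized
    shift for each positive endpoint; binary features are Bernoulli with the
    planted odds ratios applied to the baseline odds.  The replicate table
    re-draws continuous features with additive rater noise of scale
    ``rater_sigma`` (binary reads are unchanged), emulating feature
    re-extraction from an independent re-segmentation.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    labels = {}
    for name, p in spec.prevalence.items():
        y = np.zeros(n, dtype=int)
        y[: int(round(n * p))] = 1
        labels[name] = rng.permutation(y)
    labels_df = pd.DataFrame(labels, index=pd.RangeIndex(n, name="lesion"))

    cols = {}
    for feat in spec.features:
        if feat.kind == "continuous":
            x = rng.normal(0.0, 1.0, n)
            for endpoint, shift in feat.effects.items():
                x = x + shift * labels_df[endpoint].to_numpy()
            cols[feat.name] = x
        elif feat.kind == "binary":
            logit = np.log(feat.baseline_rate / (1 - feat.baseline_rate))
            eta = np.full(n, logit)
            for endpoint, odds_ratio in feat.effects.items():
                eta = eta + np.log(odds_ratio) * labels_df[endpoint].to_numpy()
            cols[feat.name] = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        else:
            raise ValueError(f"unknown feature kind {feat.kind!r}")
    table = pd.DataFrame(cols, index=labels_df.index)

    replicate = table.copy()
    if spec.rater_sigma > 0:
        for feat in spec.features:
            if feat.kind == "continuous":
                replicate[feat.name] += rng.normal(0.0, spec.rater_sigma, n)
    return table, labels_df, replicate


def feature_families(spec: CohortSpec) -> dict[str, list[str]]:
    """Column names grouped by feature family, in table order."""
    out: dict[str, list[str]] = {}
    for feat in spec.features:
        out.setdefault(feat.family, []).append(feat.name)
    return out
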