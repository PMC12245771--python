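"""Segmented biexponential IVIM fitting.

The intravoxel incoherent motion model describes the DWI signal decay as

    S(b) = S0 * [(1 - f) * exp(-b * D) + f * exp(-b * D*)]

with D the apparent pure diffusion coefficient (mm^2/s), D* the
pseudo-diffusion coefficient of the capillary compartment (mm^2/s), and f the
perfusion fraction.  Because D* >> D, the pseudo-diffusion signal is
negligible above a b-value threshold (default 200 s/mm^2), which motivates
the standard two-step ("segmented") estimator:

1. D from the ordinary least-squares slope of ln S over b > threshold;
2. with D fixed, (S0, f, D*) by bounded nonlinear least squares on all b.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.optimize import least_squares

from .dwi import BValueProtocol, DwiStack, VoiMask

__all__ = [
    "IvimBounds",
    "IvimVoxelFit",
    "IvimMaps",
    "forward_signal",
    "fit_highb_linear",
    "fit_segmented",
    "fit_volume",
]


@dataclass(frozen=True)
class IvimBounds:
    """Breast-tissue-plausible parameter box for the segmented fit.

    The D and D* ranges are kept separated (D* lower bound above the D upper
    bound is *not* enforced globally; instead the per-voxel D* lower bound is
    raised to the fitted D so the fast compartment never decays slower than
    the slow one).
    """

    d_min: float = 1e-5
    d_max: float = 5e-3
    dstar_min: float = 3e-3
    dstar_max: float = 0.5
    f_min: float = 0.0
    f_max: float = 0.5


DEFAULT_BOUNDS = IvimBounds()


@dataclass
class IvimVoxelFit:
    d: float
    dstar: float
    f: float
    s0: float
    highb_intercept: float
    residual_norm: float
    converged: bool


@dataclass
class IvimMaps:
    """Per-voxel IVIM parameter maps defined on a lesion mask (NaN outside)."""

    d: np.ndarray
    dstar: np.ndarray
    f: np.ndarray
    s0: np.ndarray
    converged: np.ndarray  # bool, False outside mask
    mask: VoiMask

    @property
    def convergence_fraction(self) -> float:
        return float(self.converged[self.mask.data].mean())

    def save(self, outdir: str | Path, prefix: str = "ivim") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        affine = np.diag([*self.mask.spacing, 1.0])
        for name, arr in (("D", self.d), ("Dstar", self.dstar),
                          ("f", self.f), ("S0", self.s0)):
            nib.save(nib.Nifti1Image(arr.astype(np.float32), affine),
                     str(outdir / f"{prefix}_{name}.nii.gz"))
        summary = {
            "n_voxels": self.mask.n_voxels,
            "convergence_fraction": self.convergence_fraction,
            "median_D": float(np.nanmedian(self.d)),
            "median_Dstar": float(np.nanmedian(self.dstar)),
            "median_f": float(np.nanmedian(self.f)),
        }
        (outdir / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2))


def forward_signal(s0: float, d: float, dstar: float, f: float,
                   b: float | np.ndarray) -> np.ndarray | float:
    """Evaluate the biexponential IVIM model at diffusion weighting *b*."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be nonnegative")
    out = s0 * ((1.0 - f) * np.exp(-b * d) + f * np.exp(-b * dstar))
    return float(out) if out.ndim == 0 else out


def fit_highb_linear(signal: np.ndarray, protocol: BValueProtocol,
                     threshold: float = 200.0,
                     bounds: IvimBounds = DEFAULT_BOUNDS) -> tuple[float, float, bool]:
    """Step 1: D from the log-linear decay above the b-value threshold.

    Returns ``(D, intercept, floored)`` where *intercept* is the extrapolated
    high-b signal at b = 0 (used to seed f) and *floored* flags that
    nonpositive signals were clamped to the noise floor before the log.
    """
    signal = np.asarray(signal, dtype=float)
    idx = protocol.high_b_indices(threshold)
    if idx.size < 2:
        raise ValueError("need at least 2 b-values above the threshold")
    s = signal[idx]
    if np.all(s <= 0):
        raise ValueError("all high-b signals are nonpositive")
    floor = 1e-6 * max(signal[0], np.max(s))
    floored = bool(np.any(s < floor))
    s = np.maximum(s, floor)
    b = protocol.array[idx]
    slope, log_intercept = np.polyfit(b, np.log(s), 1)
    d = float(np.clip(-slope, bounds.d_min, bounds.d_max))
    return d, float(np.exp(log_intercept)), floored


def fit_segmented(signal: np.ndarray, protocol: BValueProtocol,
                  threshold: float = 200.0,
                  bounds: IvimBounds = DEFAULT_BOUNDS) -> IvimVoxelFit:
    """Two-step segmented fit of a single voxel's per-b signal vector."""
    signal = np.asarray(signal, dtype=float)
    if signal.size != len(protocol):
        raise ValueError("signal length must match protocol")
    if signal.size == 0 or np.any(~np.isfinite(signal)):
        raise ValueError("signal must be finite and nonempty")

    d, intercept, _ = fit_highb_linear(signal, protocol, threshold, bounds)
    b = protocol.array
    s_max = float(np.max(signal))
    s0_hi = 2.0 * max(s_max, 1e-12)
    dstar_lo = max(bounds.dstar_min, d)  # keeps D <= D* per voxel

    s0_seed = float(np.clip(max(signal[0], 1e-12), 1e-12, s0_hi))
    f_seed = float(np.clip(1.0 - intercept / s0_seed, bounds.f_min, bounds.f_max))
    dstar_seed = float(np.clip(10.0 * d, dstar_lo, bounds.dstar_max))

    def residuals(theta: np.ndarray) -> np.ndarray:
        s0, f, dstar = theta
        return forward_signal(s0, d, dstar, f, b) - signal

    try:
        res = least_squares(
            residuals,
            x0=[s0_seed, f_seed, dstar_seed],
            bounds=([1e-12, bounds.f_min, dstar_lo],
                    [s0_hi, bounds.f_max, bounds.dstar_max]),
            method="trf",
        )
        converged = bool(res.success)
    except Exception:
        converged = False

    if converged:
        s0, f, dstar = (float(v) for v in res.x)
        resid = float(np.linalg.norm(res.fun))
    else:
        # monoexponential fallback: keep the lesion map complete, flag the voxel
        s0, f, dstar = float(intercept), 0.0, float(dstar_lo)
        resid = float(np.linalg.norm(forward_signal(s0, d, dstar, f, b) - signal))

    return IvimVoxelFit(d=d, dstar=dstar, f=f, s0=s0, highb_intercept=intercept,
                        residual_norm=resid, converged=converged)


def fit_volume(dwi: DwiStack, mask: VoiMask, threshold: float = 200.0,
               bounds: IvimBounds = DEFAULT_BOUNDS) -> IvimMaps:
    """Apply the segmented fit voxel-wise over the lesion mask."""
    if dwi.shape3d != mask.data.shape:
        raise ValueError("DWI stack and mask shapes disagree")
    shape = mask.data.shape
    d = np.full(shape, np.nan)
    dstar = np.full(shape, np.nan)
    f = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    for ix, iy, iz in np.argwhere(mask.data):
        fit = fit_segmented(dwi.data[ix, iy, iz], dwi.protocol, threshold, bounds)
        d[ix, iy, iz] = fit.d
        dstar[ix, iy, iz] = fit.dstar
        f[ix, iy, iz] = fit.f
        s0[ix, iy, iz] = fit.s0
        conv[ix, iy, iz] = fit.converged
    return IvimMaps(d=d, dstar=dstar, f=f, s0=s0, converged=conv, mask=mask)
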