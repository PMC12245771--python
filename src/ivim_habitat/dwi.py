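"""Core diffusion-MRI containers: b-value protocols, 4D DWI stacks, lesion masks.

Signal volumes are plain float arrays bound to a :class:`BValueProtocol` and a
voxel spacing; NIfTI round trips go through nibabel, and b-values use the
whitespace-separated ``.bval`` convention of FSL/dcm2niix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BValueProtocol",
    "DwiStack",
    "VoiMask",
    "DEFAULT_PROTOCOL",
]


@dataclass(frozen=True)
class BValueProtocol:
    """A multi-b-value diffusion acquisition protocol.

    The protocol must bracket both the perfusion-sensitive regime
    (b <= 200 s/mm^2, at least four values, starting at b = 0) and the
    diffusion regime (b > 200 s/mm^2, at least three values) so that a
    segmented biexponential fit is well posed.
    """

    bvalues: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        if b.ndim != 1 or b.size < 7:
            raise ValueError("protocol needs at least 7 b-values")
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        if b[0] != 0:
            raise ValueError("first b-value must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b-values must be strictly ascending")
        if np.sum(b <= 200) < 4:
            raise ValueError("need at least 4 b-values <= 200 s/mm^2")
        if np.sum(b > 200) < 3:
            raise ValueError("need at least 3 b-values > 200 s/mm^2")
        object.__setattr__(self, "bvalues", tuple(float(x) for x in b))

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.bvalues, dtype=float)

    def high_b_indices(self, threshold: float = 200.0) -> np.ndarray:
        """Indices of b-values strictly above *threshold* (s/mm^2)."""
        return np.flatnonzero(self.array > threshold)

    def to_bval(self, path: str | Path) -> None:
        Path(path).write_text(" ".join(f"{b:g}" for b in self.bvalues) + "\n")

    @classmethod
    def from_bval(cls, path: str | Path) -> "BValueProtocol":
        return cls(tuple(float(x) for x in Path(path).read_text().split()))


#: Eleven-point protocol spanning 0-1000 s/mm^2 with dense low-b sampling.
DEFAULT_PROTOCOL = BValueProtocol((0, 20, 50, 80, 100, 150, 200, 400, 600, 800, 1000))


@dataclass
class DwiStack:
    """4D DWI signal volume, (x, y, z, b-index), bound to protocol and spacing."""

    data: np.ndarray
    protocol: BValueProtocol
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI stack must be 4D (x, y, z, b)")
        if self.data.shape[3] != len(self.protocol):
            raise ValueError(
                f"4th axis ({self.data.shape[3]}) must match protocol length "
                f"({len(self.protocol)})"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude DWI signal must be nonnegative")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def save(self, path: str | Path, bval_path: str | Path | None = None) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))
        if bval_path is not None:
            self.protocol.to_bval(bval_path)

    @classmethod
    def load(cls, path: str | Path, bval_path: str | Path) -> "DwiStack":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float),
                   BValueProtocol.from_bval(bval_path), spacing)


@dataclass
class VoiMask:
    """Binary 3D lesion mask (volume of interest) on the DWI grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask must contain at least one voxel")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def save(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VoiMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj) > 0, spacing)
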