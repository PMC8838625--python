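"""In-memory containers for 3D image volumes.

Axis order is (z, y, x) throughout, with slice index z ascending.  Voxels
are assumed isotropic; the physical coordinate of a voxel index ``i`` along
any axis is ``(i + 0.5) * voxel_size_um`` (voxel-center convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GrayscaleVolume", "BinaryVolume"]

_ALLOWED_INT_DTYPES = ("uint8", "int8", "uint16", "int16")


def _check_voxel_size(voxel_size_um) -> float:
    if np.ndim(voxel_size_um) != 0:
        raise ValueError(
            "anisotropic voxel sizes are not supported; pass a single "
            "isotropic edge length in um"
        )
    v = float(voxel_size_um)
    if not np.isfinite(v) or v <= 0:
        raise ValueError(f"voxel_size_um must be positive, got {voxel_size_um!r}")
    return v


@dataclass
class GrayscaleVolume:
    """A 3D grayscale intensity field, e.g. a reconstructed micro-CT scan.

    Parameters
    ----------
    data
        3D array of shape ``(nz, ny, nx)``.  Integer 8/16-bit or real-valued.
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    provenance
        Free-text record of where the volume came from.
    """

    data: np.ndarray
    voxel_size_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        kind = self.data.dtype.kind
        if kind in "iu":
            if self.data.dtype.name not in _ALLOWED_INT_DTYPES:
                raise ValueError(
                    f"unsupported integer bit depth {self.data.dtype}; "
                    "use 8- or 16-bit integers"
                )
        elif kind == "f":
            if not np.all(np.isfinite(self.data)):
                raise ValueError("volume intensities must be finite")
        elif kind == "b":
            raise TypeError("boolean data belongs in a BinaryVolume")
        else:
            raise ValueError(f"unsupported dtype {self.data.dtype}")
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class BinaryVolume:
    """A segmented void mask: ``True`` marks void voxels."""

    mask: np.ndarray
    voxel_size_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.mask.ndim}")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    @property
    def void_voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))
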