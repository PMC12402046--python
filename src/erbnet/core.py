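"""Core containers shared by every pipeline stage.

Conventions used throughout the package:

* Volumes are 3D numpy arrays indexed ``(x, y, z)`` with 0-based voxel
  coordinates; axial slices lie along the last axis.
* Intensities are Hounsfield Units (water = 0, air = -1000), clipped to
  the 12-bit CT range [-1024, 3071] on reconstruction.
* Voxel spacing is millimetres per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0
HU_AIR = -1000.0

__all__ = ["CTVolume", "HU_MIN", "HU_MAX", "HU_AIR"]


@dataclass
class CTVolume:
    """A 3D scalar field in Hounsfield Units with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU grid; axial slices along the last axis.
    spacing_mm : tuple of float
        Voxel edge length per axis in millimetres; all positive.
    volume_id : str
        Free-form identifier carried through annotations and manifests.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    volume_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be three positive floats, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def copy(self) -> "CTVolume":
        return replace(self, voxels=self.voxels.copy())
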