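"""Isotropic resampling, intensity normalization and patch extraction.

The classifier consumes cubic patches of normalized intensity.  CT volumes
are first resampled to an isotropic grid (clinical chest CT is typically
anisotropic along z), then mapped linearly from a fixed HU window to
[0, 1], and finally cropped to fixed-size cubes centred on lesion
candidates.  A fixed window — rather than per-image min/max — keeps
intensities comparable across dose levels, which matters when the same
lesion is classified at several simulated doses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CTVolume, HU_AIR

DEFAULT_WINDOW = (-1000.0, 400.0)

__all__ = ["Patch", "DEFAULT_WINDOW", "resample_isotropic", "normalize_intensity", "extract_patch"]


@dataclass
class Patch:
    """A cubic block of normalized intensities with its binary label."""

    values: np.ndarray
    label: int = 0
    source_id: str = ""
    center: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or len(set(v.shape)) != 1:
            raise ValueError(f"patch must be a cube, got shape {v.shape}")
        self.values = v


def resample_isotropic(vol: CTVolume, target_mm: float = 1.0) -> CTVolume:
    """Resample a volume to isotropic spacing by trilinear interpolation.

    Parameters
    ----------
    vol : CTVolume
        Input volume with known positive spacing.
    target_mm : float
        Desired isotropic voxel edge length in millimetres.

    Returns
    -------
    CTVolume
        Volume with spacing ``(target_mm,) * 3``; physical extent is
        preserved to within one voxel.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    factors = tuple(s / target_mm for s in vol.spacing_mm)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        out = vol.voxels.copy()
    else:
        # order=1 == trilinear; grid-constant keeps the border finite
        out = ndimage.zoom(vol.voxels.astype(np.float64), factors, order=1,
                           mode="grid-constant", cval=float(vol.voxels.min()),
                           grid_mode=True)
    return CTVolume(out, (target_mm, target_mm, target_mm), vol.volume_id)


def normalize_intensity(voxels: np.ndarray, window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    """Map an HU window linearly onto [0, 1], clipping outside it."""
    lo, hi = float(window[0]), float(window[1])
    if not hi > lo:
        raise ValueError(f"degenerate window {window}")
    x = np.asarray(voxels, dtype=np.float64)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def normalized_air_value(window: tuple[float, float] = DEFAULT_WINDOW) -> float:
    """The padding value used for out-of-volume voxels (air under the window)."""
    return float(normalize_intensity(np.array(HU_AIR), window))


def extract_patch(
    volume: np.ndarray,
    center: tuple[int, int, int],
    side: int = 64,
    *,
    pad_value: float | None = None,
    label: int = 0,
    source_id: str = "",
) -> Patch:
    """Extract a ``side``-cubed patch centred on a voxel coordinate.

    The centre voxel maps to index ``side // 2`` in the patch (a 64-cube
    spans ``center - 32 .. center + 31`` along each axis).  Regions falling
    outside the volume are filled with ``pad_value`` (defaults to the
    normalized air value 0.0) so the lesion is never shifted off-centre.
    """
    vol = np.asarray(volume)
    cx, cy, cz = (int(c) for c in center)
    if not (0 <= cx < vol.shape[0] and 0 <= cy < vol.shape[1] and 0 <= cz < vol.shape[2]):
        raise ValueError(f"center {center} outside volume of shape {vol.shape}")
    if pad_value is None:
        pad_value = 0.0
    half = side // 2
    out = np.full((side, side, side), pad_value, dtype=vol.dtype)
    lo = [c - half for c in (cx, cy, cz)]
    for axis in range(3):
        if side > vol.shape[axis] + side:  # unreachable guard; kept for clarity
            raise ValueError("patch larger than padded volume")
    src = []
    dst = []
    for axis, l in enumerate(lo):
        s0 = max(l, 0)
        s1 = min(l + side, vol.shape[axis])
        if s1 <= s0:
            # patch entirely outside along this axis: return pure padding
            return Patch(out, label=label, source_id=source_id, center=(cx, cy, cz))
        src.append(slice(s0, s1))
        dst.append(slice(s0 - l, s1 - l))
    out[tuple(dst)] = vol[tuple(src)]
    return Patch(out, label=label, source_id=source_id, center=(cx, cy, cz))
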