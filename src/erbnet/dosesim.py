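"""Reduced-dose CT simulation in projection space.

Photon noise in CT is Poisson and arises during acquisition, so a
faithful low-dose simulation injects it into the sinogram and
reconstructs, rather than adding noise in image space.  Each axial slice
of a full-dose HU volume is processed as:

1. HU -> linear attenuation mu via the water-anchored map
   ``mu = mu_water * (1 + HU / 1000)`` (air at -1000 HU maps to mu = 0);
2. parallel-beam Radon transform -> line integrals ``p`` (dimensionless,
   mu in 1/mm times path length in mm);
3. Beer-Lambert transmission ``T_fd = exp(-p)``;
4. Poisson detector counts with mean ``I0 * T_fd``, where the incident
   photon count ``I0`` scales linearly with dose fraction
   (reference 10000; 1000 at 10% dose);
5. noisy projection ``P_ld = ln(I0 / counts)`` with counts clipped to
   ``[min_counts, I0]`` so the log stays finite and nonnegative;
6. ramp-filtered backprojection -> mu map -> HU, clipped to
   [-1024, 3071].

The projector/reconstructor pair wraps ``skimage.transform.radon`` /
``iradon`` (parallel beam, Ram-Lak filter, linear-interpolation
backprojection) with explicit physical units: sinogram values carry the
pixel spacing, so ``p`` really is mu times millimetres.  Slices are
implicitly padded with air (mu = 0) to cover the detector diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import radon as _radon, iradon as _iradon

from .core import CTVolume, HU_AIR, HU_MAX, HU_MIN

__all__ = [
    "DoseConfig", "Sinogram", "raw_to_hu", "hu_to_mu", "mu_to_hu",
    "dose_to_photon_count", "forward_project", "transmission_from_projection",
    "apply_poisson_noise", "projection_from_counts", "reconstruct_fbp",
    "simulate_low_dose_volume",
]

#: linear attenuation of water in 1/mm at ~120 kVp
MU_WATER_DEFAULT = 0.0195

DOSE_FRACTIONS = (1.0, 0.6, 0.4, 0.2, 0.1)


@dataclass
class DoseConfig:
    """Parameters of the low-dose acquisition model."""

    fraction: float = 1.0
    I0_ref: int = 10_000
    mu_water: float = MU_WATER_DEFAULT
    n_angles: int = 180
    min_counts: int = 1
    seed: int = 0
    #: pass the 100%-dose volume through the projector/reconstructor too
    reprocess_full_dose: bool = False
    #: disable Poisson sampling (deterministic projector round trip)
    apply_noise: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"dose fraction must be in (0, 1], got {self.fraction}")
        if self.I0_ref < 1:
            raise ValueError("I0_ref must be >= 1")
        if self.mu_water <= 0:
            raise ValueError("mu_water must be positive")
        if self.n_angles < 2:
            raise ValueError("n_angles must be >= 2")


@dataclass
class Sinogram:
    """Parallel-beam projection data, angles x detector bins, in mu*mm."""

    values: np.ndarray
    angles_deg: np.ndarray
    detector_spacing_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.angles_deg):
            raise ValueError("values must be (n_angles, n_bins) matching angles_deg")
        if self.detector_spacing_mm <= 0:
            raise ValueError("detector_spacing_mm must be positive")


def raw_to_hu(raw, slope: float = 1.0, intercept: float = 0.0):
    """Rescale stored pixel values to HU: ``HU = raw * slope + intercept``."""
    return np.asarray(raw, dtype=np.float64) * slope + intercept


def hu_to_mu(hu, mu_water: float = MU_WATER_DEFAULT):
    """HU to linear attenuation (1/mm), clipped below at 0.

    Water (0 HU) maps to ``mu_water``, air (-1000 HU) to 0.
    """
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    mu = (np.asarray(hu, dtype=np.float64) * mu_water / 1000.0) + mu_water
    return np.maximum(mu, 0.0)


def mu_to_hu(mu, mu_water: float = MU_WATER_DEFAULT):
    """Exact algebraic inverse of :func:`hu_to_mu` on its unclipped range."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return (np.asarray(mu, dtype=np.float64) - mu_water) * 1000.0 / mu_water


def dose_to_photon_count(fraction: float, I0_ref: int = 10_000) -> int:
    """Incident photons at a dose fraction: ``round(fraction * I0_ref)``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"dose fraction must be in (0, 1], got {fraction}")
    return int(round(fraction * I0_ref))


def forward_project(mu_slice: np.ndarray, spacing_mm: float, angles_deg=None) -> Sinogram:
    """Parallel-beam Radon transform of a 2D attenuation map.

    Returns line integrals in mu*mm (discrete sum times pixel spacing);
    the detector covers the padded slice diagonal, bins spaced at the
    pixel spacing.
    """
    mu = np.asarray(mu_slice, dtype=np.float64)
    if mu.ndim != 2 or mu.size == 0:
        raise ValueError(f"mu_slice must be a nonempty 2D array, got shape {mu.shape}")
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    if angles_deg is None:
        angles_deg = np.arange(0.0, 180.0, 1.0)
    angles_deg = np.asarray(angles_deg, dtype=np.float64)
    sino = _radon(mu, theta=angles_deg, circle=False) * float(spacing_mm)
    return Sinogram(sino.T, angles_deg, float(spacing_mm))


def transmission_from_projection(sino: Sinogram | np.ndarray) -> np.ndarray:
    """Beer-Lambert full-dose transmission ``T_fd = exp(-p)`` in (0, 1]."""
    p = sino.values if isinstance(sino, Sinogram) else np.asarray(sino)
    return np.exp(-p)


def apply_poisson_noise(T_fd: np.ndarray, I0: int, seed=None) -> np.ndarray:
    """Sample detector counts ~ Poisson(I0 * T_fd).

    ``seed`` may be an int or an existing ``numpy.random.Generator``.
    """
    if I0 < 1:
        raise ValueError("I0 must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(I0 * np.asarray(T_fd, dtype=np.float64))


def projection_from_counts(T_ld: np.ndarray, I0: int, min_counts: int = 1) -> np.ndarray:
    """Noisy projection ``P_ld = ln(I0 / counts)``.

    Counts are clipped to ``[min_counts, I0]`` first: the lower floor
    keeps the log finite when a detector bin records zero photons, the
    upper cap keeps the projection nonnegative.
    """
    if I0 < 1:
        raise ValueError("I0 must be >= 1")
    counts = np.clip(np.asarray(T_ld, dtype=np.float64), float(min_counts), float(I0))
    return np.log(I0 / counts)


def reconstruct_fbp(sino: Sinogram, out_shape: tuple[int, int], spacing_mm: float | None = None) -> np.ndarray:
    """Ramp-filtered backprojection; returns a mu map in 1/mm."""
    if len(sino.angles_deg) < 2:
        raise ValueError("need at least 2 projection angles for FBP")
    spacing = float(spacing_mm if spacing_mm is not None else sino.detector_spacing_mm)
    if out_shape[0] != out_shape[1]:
        raise ValueError("FBP output must be square; pad the slice first")
    recon = _iradon(sino.values.T, theta=sino.angles_deg, circle=False,
                    filter_name="ramp", interpolation="linear",
                    output_size=int(out_shape[0]))
    return recon / spacing


def _pad_to_square(slice2d: np.ndarray, fill: float) -> tuple[np.ndarray, tuple[slice, slice]]:
    nx, ny = slice2d.shape
    n = max(nx, ny)
    px, py = n - nx, n - ny
    pads = ((px // 2, px - px // 2), (py // 2, py - py // 2))
    out = np.pad(slice2d, pads, mode="constant", constant_values=fill)
    crop = (slice(pads[0][0], pads[0][0] + nx), slice(pads[1][0], pads[1][0] + ny))
    return out, crop


def simulate_low_dose_volume(vol: CTVolume, cfg: DoseConfig) -> CTVolume:
    """Simulate a reduced-dose version of a full-dose HU volume.

    Each axial slice runs the full projection-space chain independently
    with its own RNG stream (``cfg.seed + slice_index``), so results are
    reproducible under parallel slice processing.  At ``fraction == 1.0``
    the input is returned untouched (originals are the 100% reference)
    unless ``reprocess_full_dose`` is set.
    """
    sx, sy, sz = vol.spacing_mm
    if cfg.fraction == 1.0 and not cfg.reprocess_full_dose:
        out = vol.copy()
        out.volume_id = f"{vol.volume_id}_fd100"
        return out
    if abs(sx - sy) > 1e-9:
        raise ValueError(
            f"in-plane spacing must be isotropic (got {sx} x {sy} mm); "
            "resample with preprocess.resample_isotropic first")
    I0 = dose_to_photon_count(cfg.fraction, cfg.I0_ref)
    angles = np.arange(cfg.n_angles) * (180.0 / cfg.n_angles)
    hu = np.clip(vol.voxels.astype(np.float64), HU_MIN, HU_MAX)
    out = np.empty_like(hu)
    for iz in range(hu.shape[2]):
        sl, crop = _pad_to_square(hu[:, :, iz], HU_AIR)
        mu = hu_to_mu(sl, cfg.mu_water)
        sino = forward_project(mu, sx, angles)
        if cfg.apply_noise:
            T_fd = transmission_from_projection(sino)
            counts = apply_poisson_noise(T_fd, I0, seed=cfg.seed + iz)
            p_ld = projection_from_counts(counts, I0, cfg.min_counts)
        else:
            p_ld = sino.values
        noisy = Sinogram(p_ld, angles, sx)
        n = sl.shape[0]
        mu_rec = reconstruct_fbp(noisy, (n, n), sx)
        out[:, :, iz] = np.clip(mu_to_hu(mu_rec, cfg.mu_water), HU_MIN, HU_MAX)[crop]
    pct = int(round(cfg.fraction * 100))
    return CTVolume(out, vol.spacing_mm, f"{vol.volume_id}_ld{pct}")
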