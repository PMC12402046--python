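"""Synthetic lung phantom generation.

Every downstream stage (dose simulation, patch extraction, classifier
training, ensembling) is exercised on seeded synthetic volumes that mimic
the gross intensity structure of chest CT: an air background at -1000 HU,
a soft-tissue body ellipsoid near 0 HU, two low-density lung regions, and
two classes of focal lesions inside the lungs —

* **nodules**: soft-tissue spheres, optionally lobulated by a
  low-frequency radial perturbation;
* **non-nodule confounders**: tubular vessel segments and bifurcations
  (1-4 mm radius) and small calcified granulomas (high HU), i.e. the
  structures that mimic nodules in real screening data.

The generator is a pure function of its config (including the seed), the
class balance is exact, and nodule/lung mean intensities are separable by
construction, so classifier tests have a well-posed learning problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CTVolume
from .preprocess import DEFAULT_WINDOW, extract_patch, normalize_intensity

__all__ = ["PhantomConfig", "LesionAnnotation", "generate_volume", "generate_patch_dataset"]

_MAX_PLACEMENT_TRIES = 500


@dataclass
class PhantomConfig:
    """Geometry, intensity ranges and counts for one synthetic volume.

    HU ranges are ``(low, high)`` pairs sampled uniformly per lesion or
    region.  ``noise_sigma_hu`` is the std of Gaussian texture noise added
    inside the body; 0 disables it (dose-dependent noise comes only from
    the dose simulator).
    """

    volume_shape: tuple[int, int, int] = (128, 128, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_nodules: int = 5
    n_non_nodules: int = 5
    nodule_diameter_mm: tuple[float, float] = (4.0, 20.0)
    nodule_hu: tuple[float, float] = (-100.0, 100.0)
    vessel_hu: tuple[float, float] = (0.0, 100.0)
    vessel_radius_mm: tuple[float, float] = (1.0, 4.0)
    vessel_length_mm: tuple[float, float] = (10.0, 25.0)
    granuloma_hu: tuple[float, float] = (300.0, 800.0)
    granuloma_diameter_mm: tuple[float, float] = (2.0, 6.0)
    lung_hu: tuple[float, float] = (-900.0, -700.0)
    body_hu: tuple[float, float] = (-50.0, 50.0)
    background_hu: float = -1000.0
    noise_sigma_hu: float = 20.0
    #: minimum Euclidean distance (mm) between a nodule centre and every
    #: other lesion centre, so lesion-centred patches are label-clean
    #: (a negative patch must not have a nodule near its centre); half
    #: the patch side is a good value
    min_nodule_separation_mm: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nodule_diameter_mm", "nodule_hu", "vessel_hu", "vessel_radius_mm", "vessel_length_mm",
                     "granuloma_hu", "granuloma_diameter_mm", "lung_hu", "body_hu"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} range must be ordered low <= high, got {(lo, hi)}")
        if self.n_nodules < 0 or self.n_non_nodules < 0:
            raise ValueError("lesion counts must be >= 0")
        if min(self.volume_shape) < 8:
            raise ValueError(f"volume_shape {self.volume_shape} too small")


@dataclass
class LesionAnnotation:
    """One labeled lesion: 0-based x/y/z voxel centre, size and class."""

    volume_id: str
    center: tuple[int, int, int]
    diameter_mm: float
    label: int  # 1 = nodule, 0 = non-nodule

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _local_box(shape, center, half):
    lo = [max(int(np.floor(c - h)), 0) for c, h in zip(center, half)]
    hi = [min(int(np.ceil(c + h)) + 1, n) for c, h, n in zip(center, half, shape)]
    return tuple(slice(l, h) for l, h in zip(lo, hi))


def _offset_grids(box, center, spacing):
    return [
        (np.arange(s.start, s.stop) - c)[sl] * sp
        for s, c, sp, sl in zip(
            box, center, spacing,
            (np.s_[:, None, None], np.s_[None, :, None], np.s_[None, None, :]),
        )
    ]


def _sphere_mask(box, center, radius_mm, spacing, rng=None, lobulate=False):
    dx, dy, dz = _offset_grids(box, center, spacing)
    dist = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    if not lobulate:
        return dist <= radius_mm
    # low-frequency radial displacement: r(u) = r * (1 + a cos(k.u + phi))
    amp = rng.uniform(0.05, 0.15)
    k = rng.normal(size=3)
    k = k / np.linalg.norm(k) * rng.uniform(2.0, 4.0)
    phi = rng.uniform(0, 2 * np.pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux, uy, uz = dx / dist, dy / dist, dz / dist
    arg = np.nan_to_num(k[0] * ux + k[1] * uy + k[2] * uz)
    return dist <= radius_mm * (1.0 + amp * np.cos(arg + phi))


def _cylinder_mask(box, p0, direction, length_mm, radius_mm, spacing):
    dx, dy, dz = _offset_grids(box, p0, spacing)
    # distance to the segment [0, L] along `direction` (unit, mm space)
    t = dx * direction[0] + dy * direction[1] + dz * direction[2]
    t_cl = np.clip(t, -length_mm / 2, length_mm / 2)
    d2 = (dx - t_cl * direction[0]) ** 2 + (dy - t_cl * direction[1]) ** 2 + (dz - t_cl * direction[2]) ** 2
    return d2 <= radius_mm ** 2


def _sample_center(rng, candidates):
    idx = rng.integers(len(candidates[0]))
    return tuple(int(ax[idx]) for ax in candidates)


def generate_volume(config: PhantomConfig) -> tuple[CTVolume, list[LesionAnnotation]]:
    """Generate one phantom volume and its lesion annotations.

    Raises
    ------
    RuntimeError
        If a lesion cannot be placed without overlap after bounded
        retries; the message names the failing lesion index.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.volume_shape)
    spacing = np.asarray(config.spacing_mm, dtype=np.float64)
    nx, ny, nz = shape

    vol = np.full(shape, float(config.background_hu), dtype=np.float64)
    body = _ellipsoid_mask(shape, (nx / 2, ny / 2, nz / 2), (0.46 * nx, 0.44 * ny, 0.65 * nz))
    vol[body] = rng.uniform(*config.body_hu)

    lung_semi = (0.16 * nx, 0.30 * ny, 0.45 * nz)
    lungs = np.zeros(shape, dtype=bool)
    for sx in (-1.0, 1.0):
        lungs |= _ellipsoid_mask(shape, (nx / 2 + sx * 0.22 * nx, ny / 2, nz / 2), lung_semi)
    lungs &= body
    lung_base = rng.uniform(*config.lung_hu)
    vol[lungs] = lung_base

    # mm distance to lung boundary, for margin-aware lesion placement
    edt = ndimage.distance_transform_edt(lungs, sampling=spacing)
    occupied = np.zeros(shape, dtype=bool)
    volume_id = f"phantom-{config.seed}"
    annotations: list[LesionAnnotation] = []
    nodule_centers: list[np.ndarray] = []

    def far_from_nodules(center) -> bool:
        c_mm = np.asarray(center) * spacing
        return all(np.linalg.norm(c_mm - n) >= config.min_nodule_separation_mm
                   for n in nodule_centers)

    def place(lesion_index: int, radius_mm: float, make_mask, hu: float, diameter_mm: float, label: int):
        margin = radius_mm + float(spacing.max())
        cand = np.nonzero(edt >= margin)
        if len(cand[0]) == 0:
            raise RuntimeError(f"no room in lung mask for lesion {lesion_index} (radius {radius_mm:.1f} mm)")
        for _ in range(_MAX_PLACEMENT_TRIES):
            center = _sample_center(rng, cand)
            if label == 0 and not far_from_nodules(center):
                continue
            half = np.ceil((radius_mm * 1.3) / spacing) + 1
            box = _local_box(shape, center, half)
            mask = make_mask(box, center) & lungs[box]
            if not mask.any() or (mask & occupied[box]).any():
                continue
            vol[box][mask] = hu
            occupied[box][mask] = True
            if label == 1:
                nodule_centers.append(np.asarray(center) * spacing)
            annotations.append(LesionAnnotation(volume_id, center, float(diameter_mm), label))
            return
        raise RuntimeError(f"failed to place lesion {lesion_index} after {_MAX_PLACEMENT_TRIES} tries")

    lesion_index = 0
    for _ in range(config.n_nodules):
        d = rng.uniform(*config.nodule_diameter_mm)
        hu = rng.uniform(*config.nodule_hu)
        lob = bool(rng.random() < 0.5)
        place(lesion_index, d / 2,
              lambda box, c, r=d / 2, lob=lob: _sphere_mask(box, c, r, spacing, rng, lobulate=lob),
              hu, d, label=1)
        lesion_index += 1

    kinds = ["vessel", "granuloma", "bifurcation"]
    for i in range(config.n_non_nodules):
        kind = kinds[i % len(kinds)]
        if kind == "granuloma":
            d = rng.uniform(*config.granuloma_diameter_mm)
            hu = rng.uniform(*config.granuloma_hu)
            place(lesion_index, d / 2,
                  lambda box, c, r=d / 2: _sphere_mask(box, c, r, spacing),
                  hu, d, label=0)
        else:
            r = rng.uniform(*config.vessel_radius_mm)
            hu = rng.uniform(*config.vessel_hu)
            length = rng.uniform(*config.vessel_length_mm)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)

            if kind == "vessel":
                def make(box, c, u=u, length=length, r=r):
                    return _cylinder_mask(box, c, u, length, r, spacing)
            else:
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)

                def make(box, c, u=u, v=v, length=length, r=r):
                    m = _cylinder_mask(box, c, u, length, r, spacing)
                    dxg = _offset_grids(box, c, spacing)
                    # branch from the segment centre
                    t = sum(d * ui for d, ui in zip(dxg, u))
                    tb = np.clip(sum(d * vi for d, vi in zip(dxg, v)), 0, length / 2)
                    d2 = sum((d - tb * vi) ** 2 for d, vi in zip(dxg, v))
                    return m | (d2 <= r ** 2)

            # local box must cover the whole segment
            def place_cyl(make=make, r=r, length=length, hu=hu):
                margin = r + float(spacing.max())
                cand = np.nonzero(edt >= margin)
                if len(cand[0]) == 0:
                    raise RuntimeError(f"no room in lung mask for lesion {lesion_index}")
                for _ in range(_MAX_PLACEMENT_TRIES):
                    center = _sample_center(rng, cand)
                    if not far_from_nodules(center):
                        continue
                    half = np.ceil((length / 2 + r) / spacing) + 1
                    box = _local_box(shape, center, half)
                    mask = make(box, center) & lungs[box]
                    if not mask.any() or (mask & occupied[box]).any():
                        continue
                    vol[box][mask] = hu
                    occupied[box][mask] = True
                    annotations.append(LesionAnnotation(volume_id, center, float(2 * r), 0))
                    return
                raise RuntimeError(
                    f"failed to place lesion {lesion_index} after {_MAX_PLACEMENT_TRIES} tries")

            place_cyl()
        lesion_index += 1

    if config.noise_sigma_hu > 0:
        vol[body] += rng.normal(0.0, config.noise_sigma_hu, size=int(body.sum()))

    return CTVolume(vol, tuple(spacing), volume_id), annotations


def generate_patch_dataset(
    config: PhantomConfig,
    n_per_class: int,
    patch_size: int = 64,
    seed: int = 0,
    *,
    window: tuple[float, float] = DEFAULT_WINDOW,
    random_non_nodules: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[LesionAnnotation]]:
    """Build a class-balanced, shuffled stack of lesion-centred patches.

    Volumes are generated (with seeds derived from ``seed``) until
    ``n_per_class`` patches of each class have been collected.  With
    ``random_non_nodules`` the negative class is sampled at random lung
    locations instead of at confounder lesions.

    Returns
    -------
    patches : ndarray, shape (2 * n_per_class, side, side, side), float32
        Normalized intensities in [0, 1].
    labels : ndarray of {0, 1}
    annotations : list of LesionAnnotation, aligned with ``patches``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if patch_size > min(config.volume_shape):
        raise ValueError(
            f"patch_size {patch_size} exceeds smallest volume dimension {min(config.volume_shape)}")
    rng = np.random.default_rng(seed)
    pos: list[tuple[np.ndarray, LesionAnnotation]] = []
    neg: list[tuple[np.ndarray, LesionAnnotation]] = []
    vol_counter = 0
    while len(pos) < n_per_class or len(neg) < n_per_class:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub = PhantomConfig(**{**config.__dict__, "seed": sub_seed})
        vol, anns = generate_volume(sub)
        norm = normalize_intensity(vol.voxels, window)
        for ann in anns:
            patch = extract_patch(norm, ann.center, patch_size,
                                  label=ann.label, source_id=ann.volume_id)
            target = pos if ann.label == 1 else neg
            if ann.label == 0 and random_non_nodules:
                continue
            if len(target) < n_per_class:
                target.append((patch.values.astype(np.float32), ann))
        if random_non_nodules:
            lungs_edt = None
            while len(neg) < n_per_class and vol_counter < 1_000:
                c = tuple(int(rng.integers(8, s - 8)) for s in vol.shape)
                if vol.voxels[c] > -950:  # stay off pure background
                    patch = extract_patch(norm, c, patch_size, label=0, source_id=vol.volume_id)
                    neg.append((patch.values.astype(np.float32),
                                LesionAnnotation(vol.volume_id, c, 1.0, 0)))
        vol_counter += 1
        if vol_counter > 1_000:
            raise RuntimeError("could not collect the requested patches")
    items = pos[:n_per_class] + neg[:n_per_class]
    order = rng.permutation(len(items))
    patches = np.stack([items[i][0] for i in order])
    labels = np.array([items[i][1].label for i in order], dtype=np.int64)
    annotations = [items[i][1] for i in order]
    return patches, labels, annotations
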