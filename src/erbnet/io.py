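"""Readers and writers for the standard on-disk formats.

Volumes travel as NIfTI with the voxel spacing encoded in the affine;
annotations, patch manifests and probability/label vectors as CSV;
configs, reports and ensemble weights as JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CTVolume
from .ensemble import EnsembleWeights
from .phantom import LesionAnnotation

__all__ = ["read_volume", "write_volume", "read_annotations", "write_annotations",
           "write_weights", "read_weights", "write_json", "config_hash"]

ANNOTATION_COLUMNS = ["volume_id", "x", "y", "z", "diameter_mm", "label"]


def write_volume(vol: CTVolume, path) -> Path:
    """Write a volume as NIfTI; the affine diagonal carries the spacing."""
    path = Path(path)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, path)
    return path


def read_volume(path, volume_id: str | None = None) -> CTVolume:
    """Read a NIfTI volume into HU.

    Per-axis spacing comes from the affine; any scl_slope/scl_inter
    rescaling in the header is applied by nibabel's ``get_fdata``, which
    is exactly the raw-value to HU map ``HU = raw * slope + intercept``
    (see :func:`erbnet.dosesim.raw_to_hu`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(path)
        data = np.asarray(img.get_fdata(dtype=np.float64))
    except Exception as exc:  # corrupt file
        raise OSError(f"could not read NIfTI volume {path}: {exc}") from exc
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(data, spacing, volume_id or path.stem.split(".")[0])


def write_annotations(annotations: list[LesionAnnotation], path) -> Path:
    rows = [{"volume_id": a.volume_id, "x": a.center[0], "y": a.center[1],
             "z": a.center[2], "diameter_mm": a.diameter_mm, "label": a.label}
            for a in annotations]
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_annotations(path) -> list[LesionAnnotation]:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV {path} missing columns {sorted(missing)}")
    return [LesionAnnotation(str(r.volume_id), (int(r.x), int(r.y), int(r.z)),
                             float(r.diameter_mm), int(r.label))
            for r in df.itertuples()]


def write_weights(w: EnsembleWeights, path) -> Path:
    payload = {
        "weights": {str(k): float(v) for k, v in zip(
            w.model_keys or range(len(w.weights)), w.weights)},
        "tuning_score": w.tuning_score,
        "n_candidates": w.n_candidates,
        "seed": w.seed,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_weights(path) -> EnsembleWeights:
    payload = json.loads(Path(path).read_text())
    keys = tuple(payload["weights"])
    return EnsembleWeights(np.array([payload["weights"][k] for k in keys]),
                           tuning_score=payload.get("tuning_score", float("nan")),
                           n_candidates=payload.get("n_candidates", 0),
                           seed=payload.get("seed"),
                           model_keys=tuple(float(k) for k in keys))


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, cls=_Encoder))
    return path


def config_hash(obj) -> str:
    """Stable short hash of a (nested, JSON-serializable) configuration."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, cls=_Encoder).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
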