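"""NIfTI / CSV / JSON reading and writing for the analysis pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def save_nifti(path, data: np.ndarray, affine: np.ndarray, dtype=None) -> None:
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, float)), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_cest_stack(path, stack4d: np.ndarray, offsets_ppm, affine) -> None:
    """4-D CEST stack with a JSON sidecar listing the offset axis in ppm."""
    save_nifti(path, stack4d, affine)
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps({"offsets_ppm": list(map(float, offsets_ppm))}, indent=2))


def load_cest_stack(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    data, affine = load_nifti(path)
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    offsets = np.asarray(json.loads(sidecar.read_text())["offsets_ppm"], float)
    return data, offsets, affine


def save_mask(path, mask: np.ndarray, affine) -> None:
    save_nifti(path, mask.astype(np.uint8), affine)


def load_mask(path) -> tuple[np.ndarray, np.ndarray]:
    data, affine = load_nifti(path)
    return data > 0.5, affine


def save_biopsy_csv(path, samples: pd.DataFrame) -> None:
    samples.to_csv(path, index=False)


def load_biopsy_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(str(path)).write_text(json.dumps(obj, indent=2, default=_default))
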