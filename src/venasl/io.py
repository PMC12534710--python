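"""NIfTI + JSON-sidecar reading/writing via nibabel.

Volumes are written as NIfTI with a diagonal affine from the voxel size;
acquisition metadata travels in a BIDS-style JSON sidecar with keys
``LabelingDuration`` (s), ``PostLabelingDelays`` (s list), ``RepetitionTime``
(s), and ``VENC`` (cm/s) where applicable.  Masks are stored as uint8.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .kinetics import AcquisitionTiming

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_sidecar",
    "load_sidecar",
    "timing_to_sidecar",
    "timing_from_sidecar",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_nifti(path, data: np.ndarray, voxel_size=(3.0, 3.0, 3.0)) -> Path:
    path = Path(path)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, _affine(voxel_size))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def timing_to_sidecar(timing: AcquisitionTiming, **extra) -> dict:
    d = {
        "LabelingDuration": timing.labeling_duration,
        "PostLabelingDelays": list(timing.plds),
        "RepetitionTime": timing.tr,
        "NumberOfLabelControlPairs": timing.n_pairs,
    }
    d.update(extra)
    return d


def timing_from_sidecar(sidecar: dict) -> AcquisitionTiming:
    return AcquisitionTiming(
        labeling_duration=float(sidecar["LabelingDuration"]),
        plds=tuple(float(p) for p in sidecar["PostLabelingDelays"]),
        tr=float(sidecar.get("RepetitionTime", 4.0)),
        n_pairs=int(sidecar.get("NumberOfLabelControlPairs", 1)),
    )


def save_sidecar(path, sidecar: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
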