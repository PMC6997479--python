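"""Reading and writing the package's on-disk formats.

* Curves: CSV with header ``time_s,duration_s,value`` (UTF-8, '.'
  decimal); ``time_s`` is the frame midpoint.
* Region masks: JSON with label, grid shape, member indices and element
  size, or NIfTI label maps.
* Phantom specs / truth / analysis results: JSON sidecars.
* Dynamic volumes: NIfTI-1 (x, y, z, t axis order).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import ContingencyTable3x3
from .curves import RegionMask, TimeActivityCurve
from .exceptions import InputError
from .phantom import PhantomSpec, PhantomTruth

__all__ = [
    "read_curve_csv", "write_curve_csv",
    "read_mask_json", "write_mask_json",
    "read_spec_json", "write_spec_json", "write_truth_json",
    "read_table_csv", "write_nifti",
]


def write_curve_csv(curve: TimeActivityCurve, path) -> None:
    pd.DataFrame({"time_s": curve.times, "duration_s": curve.durations,
                  "value": curve.values}).to_csv(path, index=False)


def read_curve_csv(path, region_label: str | None = None,
                   modality: str | None = None) -> TimeActivityCurve:
    df = pd.read_csv(path)
    missing = {"time_s", "duration_s", "value"} - set(df.columns)
    if missing:
        raise InputError(f"curve CSV missing columns: {sorted(missing)}")
    return TimeActivityCurve(times=df["time_s"].to_numpy(),
                             durations=df["duration_s"].to_numpy(),
                             values=df["value"].to_numpy(),
                             region_label=region_label, modality=modality)


def write_mask_json(mask: RegionMask, path) -> None:
    payload = {"label": mask.label, "shape": list(mask.mask.shape),
               "element_size": mask.element_size,
               "indices": [idx.tolist() for idx in mask.indices]}
    Path(path).write_text(json.dumps(payload))


def read_mask_json(path) -> RegionMask:
    payload = json.loads(Path(path).read_text())
    arr = np.zeros(tuple(payload["shape"]), dtype=bool)
    arr[tuple(np.asarray(i) for i in payload["indices"])] = True
    return RegionMask(payload["label"], arr, payload["element_size"])


def write_spec_json(spec: PhantomSpec, path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2))


def read_spec_json(path) -> PhantomSpec:
    payload = json.loads(Path(path).read_text())
    payload.pop("true_srf_left", None)  # derived, not a constructor field
    return PhantomSpec(**payload)


def write_truth_json(truth: PhantomTruth, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=2))


def read_table_csv(path) -> ContingencyTable3x3:
    """3×3 contingency table CSV with category labels as header row/column."""
    df = pd.read_csv(path, index_col=0)
    if df.shape != (3, 3):
        raise InputError("contingency table CSV must be 3x3 with labels")
    return ContingencyTable3x3(df.to_numpy(), tuple(df.columns))


def write_nifti(frames: np.ndarray, voxel_size, path) -> None:
    """Write a dynamic series as NIfTI-1, moving time to the last axis."""
    import nibabel as nib

    data = np.moveaxis(np.asarray(frames), 0, -1)
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
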