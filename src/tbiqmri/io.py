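"""Reading and writing the on-disk layout: NIfTI images, YAML sidecars,
JSON ROI name tables, CSV tables.

Each subject/timepoint directory holds one NIfTI per sequence with the
acquisition conditions stacked along the 4th axis, plus a YAML sidecar
recording the protocol, per-sequence condition values, and the
hemisphere convention (ipsilateral = left = low column indices). The
same reader accepts real data laid out this way.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .protocol import AcquisitionProtocol
from .qmap import ParameterMap, RawStack
from .roi import ROISet
from .cohort import SubjectImageSet

SIDECAR_NAME = "acquisition.yaml"


def _affine(protocol: AcquisitionProtocol) -> np.ndarray:
    v = protocol.voxel_size_mm
    aff = np.diag([v, v, protocol.slice_thickness_mm, 1.0])
    return aff


def write_subject(subject: SubjectImageSet, out_dir: str | Path) -> Path:
    """Write one subject/timepoint image set; returns its directory."""
    d = Path(out_dir) / subject.subject_id / subject.timepoint
    d.mkdir(parents=True, exist_ok=True)
    aff = _affine(subject.protocol)
    conditions = {}
    for name, stack in subject.stacks.items():
        img = nib.Nifti1Image(stack.data[:, :, None, :].astype(np.float32), aff)
        img.header["descrip"] = f"{stack.sequence_kind} [{stack.condition_units}]".encode()
        nib.save(img, d / f"{name}.nii")
        conditions[name] = {
            "sequence_kind": stack.sequence_kind,
            "condition_values": [float(v) for v in stack.condition_values],
            "condition_units": stack.condition_units,
        }
    sidecar = {
        "subject_id": subject.subject_id,
        "timepoint": subject.timepoint,
        "ipsilateral_side": "left (columns < matrix/2)",
        "protocol": subject.protocol.to_dict(),
        "sequences": conditions,
    }
    with open(d / SIDECAR_NAME, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return d


def read_subject(subject_dir: str | Path) -> SubjectImageSet:
    d = Path(subject_dir)
    sidecar_path = d / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no {SIDECAR_NAME} in {d}")
    with open(sidecar_path) as fh:
        sidecar = yaml.safe_load(fh)
    protocol = AcquisitionProtocol.from_dict(sidecar["protocol"])
    stacks = {}
    for name, meta in sidecar["sequences"].items():
        path = d / f"{name}.nii"
        if not path.exists():
            raise FileNotFoundError(f"sequence file missing: {path}")
        data = np.asanyarray(nib.load(path).dataobj, dtype=float)
        if data.ndim != 4 or data.shape[2] != 1:
            raise ValueError(f"{path}: expected (ny, nx, 1, ncond) layout")
        stacks[name] = RawStack(data[:, :, 0, :], np.array(meta["condition_values"]),
                                meta["sequence_kind"], meta.get("condition_units", ""))
    return SubjectImageSet(sidecar["subject_id"], sidecar["timepoint"], protocol, stacks)


def write_parameter_map(pmap: ParameterMap, path: str | Path,
                        protocol: AcquisitionProtocol | None = None) -> None:
    """Map values to <path>.nii with units in the header; the validity
    mask goes to a companion <stem>_valid.nii."""
    path = Path(path)
    aff = _affine(protocol) if protocol else np.eye(4)
    vals = np.where(pmap.valid_mask, pmap.values, np.nan).astype(np.float32)
    img = nib.Nifti1Image(vals[:, :, None], aff)
    img.header["descrip"] = f"units={pmap.units}".encode()
    nib.save(img, path)
    mask_img = nib.Nifti1Image(pmap.valid_mask.astype(np.uint8)[:, :, None], aff)
    nib.save(mask_img, path.with_name(path.stem + "_valid.nii"))


def read_parameter_map(path: str | Path) -> ParameterMap:
    path = Path(path)
    img = nib.load(path)
    vals = np.asanyarray(img.dataobj, dtype=float)[:, :, 0]
    units = img.header["descrip"].tobytes().decode(errors="ignore")
    units = units.split("units=", 1)[-1].strip("\x00 ")
    mask_path = path.with_name(path.stem + "_valid.nii")
    if mask_path.exists():
        valid = np.asanyarray(nib.load(mask_path).dataobj)[:, :, 0].astype(bool)
    else:
        valid = np.isfinite(vals)
    return ParameterMap(vals, units, valid)


def write_roiset(roiset: ROISet, path: str | Path,
                 protocol: AcquisitionProtocol | None = None) -> None:
    path = Path(path)
    aff = _affine(protocol) if protocol else np.eye(4)
    nib.save(nib.Nifti1Image(roiset.label_map.astype(np.int16)[:, :, None], aff), path)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"names": roiset.names, "provenance": roiset.provenance}, fh, indent=1)


def read_roiset(path: str | Path) -> ROISet:
    path = Path(path)
    lm = np.asanyarray(nib.load(path).dataobj)[:, :, 0].astype(np.int16)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return ROISet(lm, {k: int(v) for k, v in meta["names"].items()},
                  meta.get("provenance", "file"))


def write_csv(df, path: str | Path) -> None:
    """Deterministic CSV output (fixed float formatting, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
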