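"""ROI definition/propagation, per-ROI statistics, and contusion volumetry.

The seven-region scheme follows the standard focal-TBI layout: injury
core (C), ipsi-/contralateral perilesion cortex (IC, CC), hippocampus
(IH, CH), and thalamus (IT, CT). ROIs live on the acquisition grid and
are transferred unchanged (or by integer nearest-neighbor scaling) to
every coregistered map; registration itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .protocol import ROI_NAMES
from .qmap import ParameterMap


@dataclass
class ROISet:
    """Integer label map plus a name -> label-id table.

    Labels are pairwise disjoint by construction of the label map; every
    named ROI must be nonempty.
    """

    label_map: np.ndarray
    names: dict[str, int]
    provenance: str = "phantom"

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if not np.issubdtype(self.label_map.dtype, np.integer):
            raise ValueError("ROI label map must be integer-typed")
        for name, lab in self.names.items():
            if not np.any(self.label_map == lab):
                raise ValueError(f"ROI {name!r} (label {lab}) is empty")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_map.shape

    def mask(self, roi_name: str) -> np.ndarray:
        if roi_name not in self.names:
            raise KeyError(f"unknown ROI {roi_name!r}; have {sorted(self.names)}")
        return self.label_map == self.names[roi_name]

    def scaled(self, factor: int) -> "ROISet":
        """Nearest-neighbor upscaling by an integer factor (voxel count x factor^2)."""
        if factor == 1:
            return self
        if factor < 1 or int(factor) != factor:
            raise ValueError("ROI scaling factor must be a positive integer")
        lm = np.kron(self.label_map, np.ones((factor, factor), dtype=self.label_map.dtype))
        return ROISet(lm, dict(self.names), self.provenance)


@dataclass
class ROIStat:
    subject_id: str
    timepoint: str
    roi_name: str
    metric_name: str
    mean: float
    sd: float
    n_valid_voxels: int

    def __post_init__(self) -> None:
        if self.n_valid_voxels < 1:
            raise ValueError("ROIStat requires at least one valid voxel")


@dataclass
class LesionVolumeResult:
    volume_mm3: float
    threshold_used: float
    n_voxels: int
    voxel_size_mm: float
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        expected = self.n_voxels * self.voxel_size_mm**2 * self.slice_thickness_mm
        if abs(self.volume_mm3 - expected) > 1e-12 * max(1.0, expected):
            raise ValueError("volume inconsistent with voxel count x voxel volume")


def propagate_rois(roiset: ROISet, maps: list[ParameterMap]) -> list[tuple[ParameterMap, ROISet]]:
    """Pair every map with the ROI set on its own grid.

    Maps must share the reference grid or be its integer-factor
    interpolation (the 2x / 384-grid case); the ROI labels are then scaled
    by nearest-neighbor. Any other grid is an error — resampling across
    unregistered grids is deliberately not attempted.
    """
    ref = roiset.shape[0]
    out = []
    for m in maps:
        ny, nx = m.shape[0], m.shape[1]
        if ny != nx:
            raise ValueError("maps must be square")
        if ny % ref != 0 or ny // ref not in (1, 2):
            raise ValueError(
                f"map grid {ny}x{nx} does not match ROI grid {ref}x{ref} "
                "or its 2x interpolation; coregistration is out of scope"
            )
        out.append((m, roiset.scaled(ny // ref)))
    return out


def roi_mean(pmap: ParameterMap, roiset: ROISet, roi_name: str,
             subject_id: str = "", timepoint: str = "",
             metric_name: str = "") -> ROIStat:
    """Mean/SD of a map over one ROI, restricted to valid voxels."""
    if pmap.shape != roiset.shape:
        raise ValueError("map and ROI set are on different grids (use propagate_rois)")
    sel = roiset.mask(roi_name) & pmap.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"ROI {roi_name!r} has no valid voxels for metric {metric_name!r}")
    vals = pmap.values[sel]
    return ROIStat(subject_id, timepoint, roi_name, metric_name,
                   float(vals.mean()), float(vals.std(ddof=0)), n)


def roi_table(maps: dict[str, ParameterMap], roiset: ROISet,
              subject_id: str = "", timepoint: str = "") -> pd.DataFrame:
    """All-ROI x all-metric summary for one subject/timepoint."""
    rows = []
    for metric, pmap in maps.items():
        for name in roiset.names:
            s = roi_mean(pmap, roiset, name, subject_id, timepoint, metric)
            rows.append(vars(s))
    return pd.DataFrame(rows)


@dataclass
class LesionConfig:
    """Hyperintensity segmentation settings for contusion volumetry."""

    k_sd: float = 2.0               # threshold = mean(CC) + k_sd * SD(CC)
    reference_roi: str = "contra_cortex"
    connectivity: np.ndarray = field(default_factory=lambda: np.ones((3, 3), int))


def lesion_volume(t2w_map: ParameterMap, roiset: ROISet,
                  voxel_size_mm: float, slice_thickness_mm: float,
                  cfg: LesionConfig | None = None) -> LesionVolumeResult:
    """Contusion volume from hyperintensity on a T2w-like map.

    Threshold is mean + k*SD of the contralateral-cortex reference ROI;
    8-connected in-plane components are kept only when they intersect the
    ipsilateral (left, low-column) half-grid, which discards mirror-side
    artifacts. Data may be a single slice (2-D) or a slice stack
    (ny, nx, nslices) sharing the in-plane ROI map; volumes sum over
    slices. Returns 0.0 mm^3 when nothing is hyperintense.
    """
    cfg = cfg or LesionConfig()
    data = t2w_map.values
    valid = t2w_map.valid_mask
    if data.ndim == 2:
        data = data[:, :, None]
        valid = valid[:, :, None]
    if data.shape[:2] != roiset.shape:
        raise ValueError("t2w map and ROI set are on different grids")
    ref_sel = roiset.mask(cfg.reference_roi)[:, :, None] & valid
    ref_vals = data[ref_sel]
    if ref_vals.size == 0:
        raise ValueError(f"reference ROI {cfg.reference_roi!r} is empty on this map")
    thr = float(ref_vals.mean() + cfg.k_sd * ref_vals.std(ddof=0))

    nx = roiset.shape[1]
    ipsi_half = np.zeros(roiset.shape, bool)
    ipsi_half[:, : nx // 2] = True

    n_vox = 0
    for s in range(data.shape[2]):
        hyper = (data[:, :, s] > thr) & valid[:, :, s]
        if not hyper.any():
            continue
        labels, nlab = ndimage.label(hyper, structure=cfg.connectivity)
        for lab in range(1, nlab + 1):
            comp = labels == lab
            if (comp & ipsi_half).any():
                n_vox += int(comp.sum())
    vol = n_vox * voxel_size_mm**2 * slice_thickness_mm
    return LesionVolumeResult(vol, thr, n_vox, voxel_size_mm, slice_thickness_mm)


def build_cohort_table(roi_stats: pd.DataFrame, manifest: pd.DataFrame,
                       outcomes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join per-ROI imaging metrics with the cohort manifest and outcomes.

    ``roi_stats``: long table (subject_id, timepoint, roi_name, metric_name,
    mean, sd, n_valid_voxels). ``manifest``: one row per subject
    (subject_id, sex, group). ``outcomes``: per-subject outcome columns;
    subjects without outcomes (e.g. early-sacrifice animals) keep their
    imaging rows with missing outcome values.
    """
    required = {"subject_id", "timepoint", "roi_name", "metric_name", "mean"}
    missing = required - set(roi_stats.columns)
    if missing:
        raise ValueError(f"roi_stats missing columns: {sorted(missing)}")
    key = ["subject_id", "timepoint", "roi_name", "metric_name"]
    dup = roi_stats.duplicated(subset=key)
    if dup.any():
        first = roi_stats.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"duplicate (subject, timepoint, roi, metric) record: {first}")
    if "subject_id" not in manifest.columns:
        raise ValueError("manifest must carry subject_id")
    table = roi_stats.merge(manifest, on="subject_id", how="left", validate="m:1")
    if outcomes is not None:
        table = table.merge(outcomes, on="subject_id", how="left", validate="m:1")
    return table


__all__ = [
    "ROISet", "ROIStat", "LesionVolumeResult", "LesionConfig", "ROI_NAMES",
    "propagate_rois", "roi_mean", "roi_table", "lesion_volume",
    "build_cohort_table",
]
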