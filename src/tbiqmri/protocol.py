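"""Acquisition protocol and tissue parameter tables.

The default protocol mirrors a single-slice multiparametric rodent brain
session at 4.7 T: a multi-echo T2 train, an inversion-recovery T1 series,
a multi-b diffusion series, a label/control arterial-spin-labeling pair,
and saturation-transfer images at +/-3.5 ppm (APTw) and 2 kHz (MTR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Condition lists and geometry for one imaging session.

    Units: echo times in ms, inversion times in s, b-values in s/mm^2,
    saturation offsets in ppm, saturation power in uT, saturation time in s.
    ``na_per_sequence`` maps sequence name -> number of signal averages.
    """

    te_list_ms: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
    ti_list_s: tuple[float, ...] = (0.05, 0.3, 0.6, 1.2, 1.8, 2.5, 3.5)
    b_list_s_per_mm2: tuple[float, ...] = (0.0, 166.7, 333.3, 500.0, 666.7, 833.3, 1000.0)
    sat_offsets_ppm: tuple[float, float] = (3.5, -3.5)
    mt_offset_khz: float = 2.0
    sat_power_uT: float = 1.3
    sat_time_s: float = 4.0
    na_per_sequence: dict = field(
        default_factory=lambda: {"t2": 4, "t1_ir": 4, "dwi": 8, "asl": 1, "aptw": 16, "mtr": 16}
    )
    matrix: int = 192
    fov_mm: float = 32.0
    slice_thickness_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.matrix < 8:
            raise ValueError(f"matrix must be >= 8, got {self.matrix}")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        if len(self.te_list_ms) == 0 or any(t <= 0 for t in self.te_list_ms):
            raise ValueError("te_list_ms must be nonempty and strictly positive")
        if len(self.ti_list_s) == 0 or any(t <= 0 for t in self.ti_list_s):
            raise ValueError("ti_list_s must be nonempty and strictly positive")
        if list(self.te_list_ms) != sorted(self.te_list_ms):
            raise ValueError("te_list_ms must be sorted ascending")
        if any(b < 0 for b in self.b_list_s_per_mm2):
            raise ValueError("b-values must be non-negative")
        if self.sat_time_s <= 0 or self.sat_power_uT <= 0:
            raise ValueError("saturation power and time must be positive")

    @property
    def voxel_size_mm(self) -> float:
        return self.fov_mm / self.matrix

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**2 * self.slice_thickness_mm

    def to_dict(self) -> dict:
        d = asdict(self)
        d["te_list_ms"] = list(self.te_list_ms)
        d["ti_list_s"] = list(self.ti_list_s)
        d["b_list_s_per_mm2"] = list(self.b_list_s_per_mm2)
        d["sat_offsets_ppm"] = list(self.sat_offsets_ppm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        d = dict(d)
        for k in ("te_list_ms", "ti_list_s", "b_list_s_per_mm2", "sat_offsets_ppm"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


#: Canonical region names. "ipsi" is the impacted (left) hemisphere.
ROI_NAMES = (
    "core",
    "ipsi_cortex",
    "contra_cortex",
    "ipsi_hippocampus",
    "contra_hippocampus",
    "ipsi_thalamus",
    "contra_thalamus",
)

#: Short labels used in figures/tables: C, IC, CC, IH, CH, IT, CT.
ROI_SHORT = {
    "core": "C",
    "ipsi_cortex": "IC",
    "contra_cortex": "CC",
    "ipsi_hippocampus": "IH",
    "contra_hippocampus": "CH",
    "ipsi_thalamus": "IT",
    "contra_thalamus": "CT",
}

TISSUE_NAMES = ROI_NAMES + ("other_brain", "background")


@dataclass(frozen=True)
class TissueClass:
    """Ground-truth MR parameters for one tissue/region class.

    t1_s in seconds, t2_ms in milliseconds, adc_m2_per_s in m^2/s,
    cbf_ml_per_100g_min in mL/100 g/min, aptw_truth_pct and mtr_truth_pct
    in percent of the unsaturated water signal.
    """

    label_id: int
    name: str
    t1_s: float
    t2_ms: float
    adc_m2_per_s: float
    cbf_ml_per_100g_min: float
    aptw_truth_pct: float
    mtr_truth_pct: float

    def __post_init__(self) -> None:
        if self.name not in TISSUE_NAMES:
            raise ValueError(f"unknown tissue name {self.name!r}")
        if self.name == "background":
            return
        if self.t1_s <= self.t2_ms / 1000.0:
            raise ValueError(f"{self.name}: T1 ({self.t1_s} s) must exceed T2 ({self.t2_ms} ms)")
        if not (0.0 <= self.adc_m2_per_s <= 4e-9):
            raise ValueError(f"{self.name}: ADC {self.adc_m2_per_s} outside [0, 4e-9] m^2/s")
        if self.cbf_ml_per_100g_min < 0:
            raise ValueError(f"{self.name}: CBF must be non-negative")
        if not (-6.0 < self.aptw_truth_pct < 6.0):
            raise ValueError(f"{self.name}: APTw truth outside the (-6, 6)% display window")
        if not (0.0 < self.mtr_truth_pct < 50.0):
            raise ValueError(f"{self.name}: MTR truth outside (0, 50)%")

    def shifted(self, **deltas: float) -> "TissueClass":
        """Return a copy with additive shifts applied to the named fields."""
        d = asdict(self)
        for k, dv in deltas.items():
            if k not in d or k in ("label_id", "name"):
                raise KeyError(f"cannot shift field {k!r}")
            d[k] = d[k] + dv
        return TissueClass(**d)


PARAM_FIELDS = {
    "t1": "t1_s",
    "t2": "t2_ms",
    "adc": "adc_m2_per_s",
    "cbf": "cbf_ml_per_100g_min",
    "aptw": "aptw_truth_pct",
    "mtr": "mtr_truth_pct",
}


def default_tissue_table() -> dict[str, TissueClass]:
    """Baseline (uninjured) tissue values typical of rat brain at 4.7 T.

    The lesion core starts at cortical baseline; injury is applied as
    additive shifts by the effect table. Normal tissue carries a small
    negative APTw value, the expected sign for healthy brain under the
    asymmetry convention used here.
    """
    rows = [
        TissueClass(1, "core", 1.50, 60.0, 0.75e-9, 100.0, -2.0, 30.0),
        TissueClass(2, "ipsi_cortex", 1.50, 60.0, 0.75e-9, 100.0, -2.0, 30.0),
        TissueClass(3, "contra_cortex", 1.50, 60.0, 0.75e-9, 100.0, -2.0, 30.0),
        TissueClass(4, "ipsi_hippocampus", 1.60, 65.0, 0.80e-9, 90.0, -2.2, 28.0),
        TissueClass(5, "contra_hippocampus", 1.60, 65.0, 0.80e-9, 90.0, -2.2, 28.0),
        TissueClass(6, "ipsi_thalamus", 1.45, 55.0, 0.72e-9, 110.0, -1.8, 32.0),
        TissueClass(7, "contra_thalamus", 1.45, 55.0, 0.72e-9, 110.0, -1.8, 32.0),
        TissueClass(8, "other_brain", 1.40, 55.0, 0.70e-9, 80.0, -2.0, 30.0),
        TissueClass(0, "background", 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    ]
    return {t.name: t for t in rows}
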