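"""Digital rat-brain phantom: ground-truth maps and forward simulation.

A single coronal slice is modelled as an elliptical brain on a square
grid. A focal contusion sits in the left (ipsilateral) parietal cortex:
a circular injury core surrounded by an annular perilesion band, with
mirrored contralateral regions and paired hippocampal/thalamic disks.
Injury severity scales the core radius and the additive parameter shifts
applied per (severity, timepoint, region).

Forward models generate the raw image stacks that the reconstruction
module inverts; noiseless, they are exact algebraic inverses of the map
formulas, which is the backbone of the round-trip test strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import (AcquisitionProtocol, TissueClass, PARAM_FIELDS,
                       ROI_NAMES, default_tissue_table)
from .qmap import RawStack
from .roi import ROISet


SEVERITIES = ("sham", "mild", "moderate", "severe")
TIMEPOINTS = ("1h", "1d", "3d")

#: Core (contusion) radius per severity, mm. Mirrors graded impactor
#: depths of a 3-mm-diameter tip; zero for shams.
LESION_RADIUS_MM = {"sham": 0.0, "mild": 1.2, "moderate": 2.4, "severe": 3.0}

#: Z-value of the symmetric saturation baseline used by the saturation
#: forward model (fraction of S0 remaining at +/-3.5 ppm with zero asymmetry).
Z_BASE_DEFAULT = 0.5


@dataclass
class PhantomSpec:
    """Everything needed to realize one subject/timepoint phantom."""

    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    tissue_table: dict[str, TissueClass] = field(default_factory=default_tissue_table)
    severity: str = "sham"
    timepoint: str = "1d"
    lesion_radius_mm: dict[str, float] = field(default_factory=lambda: dict(LESION_RADIUS_MM))
    lesion_center_vox: tuple[int, int] | None = None  # (row, col); default anatomical site
    core_roi_min_radius_mm: float = 1.5   # core ROI size when the lesion is smaller (shams)
    perilesion_width_mm: float = 2.5
    snr_s0: float = 40.0
    m0: float = 100.0
    z_base: float = Z_BASE_DEFAULT
    effect_scale: float = 1.0             # per-subject severity multiplier (cohort layer)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(f"severity must be one of {SEVERITIES}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if self.snr_s0 <= 0:
            raise ValueError("snr_s0 must be positive")
        radii = [self.lesion_radius_mm[s] for s in SEVERITIES]
        if self.lesion_radius_mm["sham"] != 0.0:
            raise ValueError("sham lesion radius must be 0")
        if any(b < a for a, b in zip(radii, radii[1:])):
            raise ValueError("lesion radius must be non-decreasing with severity")


class EffectTable:
    """Additive truth-parameter shifts per (severity, timepoint, region).

    ``shifts[(severity, timepoint, roi_name)] = {param_field: delta}``
    with param fields as in TissueClass (t1_s, t2_ms, adc_m2_per_s,
    cbf_ml_per_100g_min, aptw_truth_pct, mtr_truth_pct). Unlisted keys
    mean "no change". Shifted values must still satisfy the tissue
    invariants; that is checked when the phantom is built.
    """

    def __init__(self, shifts: dict[tuple[str, str, str], dict[str, float]] | None = None):
        self.shifts = dict(shifts or {})
        for (sev, tp, roi), d in self.shifts.items():
            if sev not in SEVERITIES or tp not in TIMEPOINTS:
                raise ValueError(f"bad effect key ({sev}, {tp}, {roi})")
            if roi not in ROI_NAMES:
                raise ValueError(f"bad effect ROI {roi!r}")
            unknown = set(d) - set(PARAM_FIELDS.values())
            if unknown:
                raise ValueError(f"unknown effect fields {sorted(unknown)}")

    def get(self, severity: str, timepoint: str, roi: str) -> dict[str, float]:
        return self.shifts.get((severity, timepoint, roi), {})


def default_effect_table() -> EffectTable:
    """Severity-graded injury pattern over the first three days.

    Qualitative structure: core CBF and APTw depressed acutely (1 h, 1 d)
    in moderate/severe injury with ADC also down early; by day 3 the core
    T2 rises (vasogenic edema) while the perilesion cortex shows elevated
    APTw (moderate/severe) and elevated CBF (severe); severe injury adds
    T1 increases and MTR decreases across ipsilateral sites; hippocampal
    APTw starts slightly low and rises through day 3.
    """
    e: dict[tuple[str, str, str], dict[str, float]] = {}

    # mild: little change; MTR dip in the core at 1 d, small bilateral
    # hippocampal ADC rise
    e[("mild", "1d", "core")] = {"mtr_truth_pct": -3.0, "aptw_truth_pct": -0.5}
    e[("mild", "1d", "ipsi_hippocampus")] = {"adc_m2_per_s": 0.05e-9}
    e[("mild", "1d", "contra_hippocampus")] = {"adc_m2_per_s": 0.05e-9}

    # moderate
    e[("moderate", "1h", "core")] = {"cbf_ml_per_100g_min": -50.0, "aptw_truth_pct": -1.5}
    e[("moderate", "1h", "ipsi_cortex")] = {"cbf_ml_per_100g_min": -30.0}
    e[("moderate", "1d", "core")] = {"cbf_ml_per_100g_min": -45.0, "aptw_truth_pct": -1.5,
                                     "adc_m2_per_s": -0.12e-9, "t1_s": 0.25}
    e[("moderate", "1d", "ipsi_hippocampus")] = {"t2_ms": 8.0, "aptw_truth_pct": -0.3}
    e[("moderate", "3d", "core")] = {"cbf_ml_per_100g_min": -40.0, "t2_ms": 15.0}
    e[("moderate", "3d", "ipsi_cortex")] = {"aptw_truth_pct": 1.8, "cbf_ml_per_100g_min": 8.0}
    e[("moderate", "3d", "ipsi_thalamus")] = {"aptw_truth_pct": 0.4}

    # severe
    e[("severe", "1h", "core")] = {"cbf_ml_per_100g_min": -60.0, "aptw_truth_pct": -2.0,
                                   "adc_m2_per_s": -0.15e-9}
    for roi in ("ipsi_cortex", "ipsi_hippocampus", "ipsi_thalamus"):
        e[("severe", "1h", roi)] = {"cbf_ml_per_100g_min": -25.0, "mtr_truth_pct": -3.0}
    e[("severe", "1h", "contra_cortex")] = {"mtr_truth_pct": -3.0}
    e[("severe", "1h", "ipsi_hippocampus")]["aptw_truth_pct"] = -1.0

    e[("severe", "1d", "core")] = {"cbf_ml_per_100g_min": -55.0, "aptw_truth_pct": -2.0,
                                   "t1_s": 0.3, "mtr_truth_pct": -4.0}
    for roi in ("ipsi_cortex", "ipsi_hippocampus", "ipsi_thalamus"):
        e[("severe", "1d", roi)] = {"t1_s": 0.3, "mtr_truth_pct": -4.0}
    e[("severe", "1d", "ipsi_hippocampus")]["aptw_truth_pct"] = -0.6

    e[("severe", "3d", "core")] = {"t2_ms": 20.0, "cbf_ml_per_100g_min": -35.0,
                                   "t1_s": 0.25, "mtr_truth_pct": -4.0}
    e[("severe", "3d", "ipsi_cortex")] = {"aptw_truth_pct": 2.5, "cbf_ml_per_100g_min": 25.0,
                                          "t1_s": 0.25, "mtr_truth_pct": -4.0}
    e[("severe", "3d", "ipsi_hippocampus")] = {"aptw_truth_pct": 1.0, "mtr_truth_pct": -4.0}
    e[("severe", "3d", "ipsi_thalamus")] = {"t1_s": 0.25, "mtr_truth_pct": -4.0,
                                            "aptw_truth_pct": 0.8}
    return EffectTable(e)


@dataclass
class PhantomTruth:
    """Ground-truth parameter maps plus the label geometry that made them."""

    maps: dict[str, np.ndarray]        # keys: t1, t2, adc, cbf, aptw, mtr, m0
    label_map: np.ndarray
    spec: PhantomSpec
    roi_truth: dict[str, dict[str, float]]  # roi -> param -> truth value

    @property
    def brain(self) -> np.ndarray:
        return self.label_map > 0


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

#: Brain ellipse semi-axes (column, row) in mm.
BRAIN_SEMI_MM = (13.0, 10.0)
#: Normalized (fraction of semi-axis) centers of the fixed ROI disks,
#: as (col_frac, row_frac); rows increase downward, ipsi = left = negative col.
GEOM = {
    "core_center": (-0.52, -0.50),     # dorsal-left parietal cortex
    "hippocampus": (0.4615, 0.32),     # mirrored in col for ipsi/contra
    "thalamus": (0.169, 0.64),         # deep/ventral, near midline
    "hippocampus_radius_mm": 1.8,
    "thalamus_radius_mm": 1.8,
}


def _grid_mm(n: int, fov_mm: float):
    c = (np.arange(n) + 0.5) * fov_mm / n - fov_mm / 2.0
    rows, cols = np.meshgrid(c, c, indexing="ij")
    return rows, cols


def build_phantom(spec: PhantomSpec,
                  effects: EffectTable | None = None) -> tuple[PhantomTruth, ROISet]:
    """Realize truth maps and the seven-ROI label set for one phantom.

    Deterministic given the spec (the seed governs only noise and cohort
    draws, not geometry). Raises if the lesion pokes outside the brain or
    if any shifted tissue value violates its physical range.
    """
    effects = effects if effects is not None else default_effect_table()
    prot = spec.protocol
    n = prot.matrix
    rows, cols = _grid_mm(n, prot.fov_mm)
    a, b = BRAIN_SEMI_MM
    rho2 = (cols / a) ** 2 + (rows / b) ** 2
    brain = rho2 <= 1.0

    if spec.lesion_center_vox is not None:
        r0, c0 = spec.lesion_center_vox
        core_r_mm = rows[r0, c0]
        core_c_mm = cols[r0, c0]
    else:
        core_c_mm = GEOM["core_center"][0] * a
        core_r_mm = GEOM["core_center"][1] * b

    lesion_radius = spec.lesion_radius_mm[spec.severity]
    core_radius = max(lesion_radius, spec.core_roi_min_radius_mm)

    def disk(cc, rr, radius):
        return (cols - cc) ** 2 + (rows - rr) ** 2 <= radius**2

    core = disk(core_c_mm, core_r_mm, core_radius) & brain
    core_full = disk(core_c_mm, core_r_mm, core_radius)
    if np.any(core_full & ~brain):
        raise ValueError("lesion/core ROI extends outside the brain mask")

    annulus_out = disk(core_c_mm, core_r_mm, core_radius + spec.perilesion_width_mm)
    ic = annulus_out & ~core_full & brain
    cc_mirror_core = disk(-core_c_mm, core_r_mm, core_radius)
    cc_ring = disk(-core_c_mm, core_r_mm, core_radius + spec.perilesion_width_mm)
    ccx = cc_ring & ~cc_mirror_core & brain

    hx, hy = GEOM["hippocampus"]
    ih = disk(-abs(hx) * a, hy * b, GEOM["hippocampus_radius_mm"]) & brain
    ch = disk(abs(hx) * a, hy * b, GEOM["hippocampus_radius_mm"]) & brain
    tx, ty = GEOM["thalamus"]
    it_ = disk(-abs(tx) * a, ty * b, GEOM["thalamus_radius_mm"]) & brain
    ct = disk(abs(tx) * a, ty * b, GEOM["thalamus_radius_mm"]) & brain

    regions = {
        "core": core, "ipsi_cortex": ic, "contra_cortex": ccx,
        "ipsi_hippocampus": ih, "contra_hippocampus": ch,
        "ipsi_thalamus": it_, "contra_thalamus": ct,
    }
    names = list(regions)
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            if np.any(regions[ni] & regions[nj]):
                raise ValueError(f"overlapping ROI definitions: {ni} and {nj}")

    tissue = spec.tissue_table
    label_map = np.zeros((n, n), dtype=np.int16)
    label_map[brain] = tissue["other_brain"].label_id
    name_to_label = {}
    for name, mask in regions.items():
        lab = tissue[name].label_id
        label_map[mask] = lab
        name_to_label[name] = lab

    # apply severity/timepoint shifts, scaled by the per-subject multiplier
    roi_truth: dict[str, dict[str, float]] = {}
    shifted_tissue: dict[str, TissueClass] = {}
    for name in list(regions) + ["other_brain"]:
        base = tissue[name]
        deltas = effects.get(spec.severity, spec.timepoint, name) if name in ROI_NAMES else {}
        scaled = {k: v * spec.effect_scale for k, v in deltas.items()}
        t = base.shifted(**scaled) if scaled else base  # validates invariants
        shifted_tissue[name] = t
        roi_truth[name] = {p: getattr(t, f) for p, f in PARAM_FIELDS.items()}

    maps = {p: np.zeros((n, n)) for p in PARAM_FIELDS}
    maps["m0"] = np.where(brain, spec.m0, 0.0)
    for name in list(regions) + ["other_brain"]:
        sel = label_map == tissue[name].label_id
        for p, f in PARAM_FIELDS.items():
            maps[p][sel] = getattr(shifted_tissue[name], f)

    truth = PhantomTruth(maps, label_map, spec, roi_truth)
    roiset = ROISet(label_map * np.isin(label_map, list(name_to_label.values())),
                    name_to_label, provenance="phantom")
    return truth, roiset


# ---------------------------------------------------------------------------
# forward models (noiseless; exact inverses of the qmap reconstructions)
# ---------------------------------------------------------------------------

def forward_ir(truth: PhantomTruth, protocol: AcquisitionProtocol | None = None) -> RawStack:
    """Magnitude inversion-recovery stack: |A + B exp(-TI/T1)| with A = M0,
    B = -2 M0 (ideal inversion). Magnitude output deliberately discards
    polarity so the reconstruction must restore it."""
    prot = protocol or truth.spec.protocol
    ti = np.asarray(prot.ti_list_s)
    if ti.size == 0:
        raise ValueError("ti_list is empty")
    t1 = truth.maps["t1"]
    brain = truth.brain
    if np.any(t1[brain] <= 0):
        raise ValueError("nonpositive T1 inside the brain")
    m0 = truth.maps["m0"]
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-ti[None, None, :] / np.where(t1 > 0, t1, np.inf)[:, :, None])
    sig = np.abs(m0[:, :, None] * (1.0 - 2.0 * decay))
    sig[~brain] = 0.0
    return RawStack(sig, ti, "t1_ir", "s")


def forward_t2(truth: PhantomTruth, protocol: AcquisitionProtocol | None = None) -> RawStack:
    """Mono-exponential multi-echo stack I0 exp(-TE/T2) with I0 = M0."""
    prot = protocol or truth.spec.protocol
    te = np.asarray(prot.te_list_ms)
    t2 = truth.maps["t2"]
    brain = truth.brain
    if np.any(t2[brain] <= 0):
        raise ValueError("nonpositive T2 inside the brain")
    with np.errstate(divide="ignore"):
        sig = truth.maps["m0"][:, :, None] * np.exp(
            -te[None, None, :] / np.where(t2 > 0, t2, np.inf)[:, :, None])
    sig[~brain] = 0.0
    return RawStack(sig, te, "t2", "ms")


def forward_dwi(truth: PhantomTruth, protocol: AcquisitionProtocol | None = None) -> RawStack:
    """Mono-exponential diffusion stack I0 exp(-b ADC); b in s/mm^2, ADC in
    m^2/s (the unit mismatch carries the usual 1e6 mm^2/m^2 factor)."""
    prot = protocol or truth.spec.protocol
    b = np.asarray(prot.b_list_s_per_mm2)
    adc = truth.maps["adc"]
    if np.any(adc[truth.brain] < 0):
        raise ValueError("negative ADC inside the brain")
    sig = truth.maps["m0"][:, :, None] * np.exp(-b[None, None, :] * adc[:, :, None] * 1e6)
    sig[~truth.brain] = 0.0
    return RawStack(sig, b, "dwi", "s/mm^2")


def asl_delta_m_fraction(cbf, t1, lam_ml_per_g=0.9, alpha=0.8):
    """Fractional label/control difference for the single-compartment CASL
    model shared with the CBF reconstruction: dM/S = CBF * 2 alpha T1 / (6000 lambda)."""
    return np.asarray(cbf) * 2.0 * alpha * np.asarray(t1) / (6000.0 * lam_ml_per_g)


def forward_asl(truth: PhantomTruth, protocol: AcquisitionProtocol | None = None,
                lam_ml_per_g: float = 0.9, alpha: float = 0.8) -> RawStack:
    """Control/label ASL pair; condition axis is (control, label)."""
    cbf = truth.maps["cbf"]
    if np.any(cbf[truth.brain] < 0):
        raise ValueError("negative CBF truth")
    control = truth.maps["m0"].copy()
    frac = asl_delta_m_fraction(cbf, truth.maps["t1"], lam_ml_per_g, alpha)
    label = control * (1.0 - frac)
    data = np.stack([control, label], axis=2)
    data[~truth.brain] = 0.0
    return RawStack(data, np.array([0.0, 1.0]), "asl", "control/label")


def forward_sat(truth: PhantomTruth, protocol: AcquisitionProtocol | None = None) -> RawStack:
    """Saturation-image quartet (S0, S+3.5ppm, S-3.5ppm, S_2kHz).

    Built from a symmetric baseline saturation level Z_base plus the
    asymmetry term so the APTw/MTR formulas invert it exactly:
    S+/- = S0 (Z_base -/+ APTw/200), S_2kHz = S0 (1 - MTR/100).
    """
    spec = truth.spec
    s0 = truth.maps["m0"].copy()
    aptw = truth.maps["aptw"]
    mtr = truth.maps["mtr"]
    s_pos = s0 * (spec.z_base - aptw / 200.0)
    s_neg = s0 * (spec.z_base + aptw / 200.0)
    s_mt = s0 * (1.0 - mtr / 100.0)
    brain = truth.brain
    for img, nm in ((s_pos, "S(+3.5 ppm)"), (s_neg, "S(-3.5 ppm)"), (s_mt, "S(2 kHz)")):
        if np.any(img[brain] < 0) or np.any(img[brain] > s0[brain]):
            raise ValueError(f"{nm} outside [0, S0]: truth not representable at this Z_base")
    data = np.stack([s0, s_pos, s_neg, s_mt], axis=2)
    data[~brain] = 0.0
    # offsets in ppm; 2 kHz at 4.7 T ~ 10 ppm
    return RawStack(data, np.array([0.0, 3.5, -3.5, 10.0]), "sat", "ppm")


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def add_noise(stack: RawStack, snr: float, na: int = 1,
              seed: int | np.random.Generator = 0,
              ref_signal: float | None = None) -> RawStack:
    """Rician noise (magnitude of complex Gaussian), averaged over ``na``
    repeats, deterministic per seed.

    Per-average sigma = ref_signal / snr, where ref_signal defaults to the
    mean over nonzero voxels of the stack's brightest condition plane (its
    acquired S0-equivalent). In the high-SNR regime the averaged noise SD
    approaches sigma / sqrt(na).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if na < 1:
        raise ValueError("na must be >= 1")
    if np.isinf(snr):
        return RawStack(stack.data.copy(), stack.condition_values.copy(),
                        stack.sequence_kind, stack.condition_units)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if ref_signal is None:
        ref_plane = stack.data[:, :, int(np.argmax(stack.data.mean(axis=(0, 1))))]
        nz = ref_plane[ref_plane > 0]
        ref_signal = float(nz.mean()) if nz.size else 1.0
    sigma = ref_signal / snr
    shape = stack.data.shape + (na,)
    re = stack.data[..., None] + rng.normal(0.0, sigma, shape)
    im = rng.normal(0.0, sigma, shape)
    noisy = np.sqrt(re**2 + im**2).mean(axis=-1)
    return RawStack(noisy, stack.condition_values.copy(),
                    stack.sequence_kind, stack.condition_units)


def simulate_subject_stacks(truth: PhantomTruth,
                            rng: np.random.Generator) -> dict[str, RawStack]:
    """All six raw stacks for one subject/timepoint, with protocol noise."""
    spec = truth.spec
    prot = spec.protocol
    na = prot.na_per_sequence
    out: dict[str, RawStack] = {}
    out["t2"] = add_noise(forward_t2(truth, prot), spec.snr_s0, na.get("t2", 1), rng)
    out["t1_ir"] = add_noise(forward_ir(truth, prot), spec.snr_s0, na.get("t1_ir", 1), rng)
    out["dwi"] = add_noise(forward_dwi(truth, prot), spec.snr_s0, na.get("dwi", 1), rng)
    out["asl"] = add_noise(forward_asl(truth, prot), spec.snr_s0, na.get("asl", 1), rng)
    out["sat"] = add_noise(forward_sat(truth, prot), spec.snr_s0, na.get("aptw", 1), rng)
    return out


__all__ = [
    "SEVERITIES", "TIMEPOINTS", "LESION_RADIUS_MM", "Z_BASE_DEFAULT",
    "PhantomSpec", "EffectTable", "default_effect_table", "PhantomTruth",
    "build_phantom", "forward_ir", "forward_t2", "forward_dwi",
    "forward_asl", "forward_sat", "asl_delta_m_fraction", "add_noise",
    "simulate_subject_stacks",
]
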