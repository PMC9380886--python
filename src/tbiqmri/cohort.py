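"""Synthetic cohorts: subjects, image sets, and correlated outcomes.

Each subject carries a latent effect multiplier that scales the
severity-graded truth shifts, so regional APTw truth varies within
groups. Behavioral/histology outcomes are linear in the subject's
regional APTw truth plus Gaussian noise, then clamped (and rounded for
integer scales). The noise SD of each outcome is *calibrated* — by a
deterministic internal large-sample simulation — so that the correlation
between outcome and predictor, after clamping and rounding, equals the
configured r. That makes "configured r is realized" a property of the
model by construction rather than an approximation.

Group sizes default to a 7/16/17/16 sham/mild/moderate/severe design
(n = 56). A configurable early-sacrifice subset per group receives
histology (Iba1 counts) instead of 28-day behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import AcquisitionProtocol, TissueClass, default_tissue_table
from .phantom import (SEVERITIES, TIMEPOINTS, EffectTable, PhantomSpec,
                      PhantomTruth, build_phantom, default_effect_table,
                      simulate_subject_stacks)
from .qmap import RawStack


BEHAVIOR_OUTCOMES = ("mnss", "spr", "barnes_escape_s", "fst_immobile_s")
HISTOLOGY_OUTCOMES = ("iba1_core", "iba1_ic", "iba1_it")


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome variable tied to a regional-APTw predictor.

    ``target_r`` is the signed correlation the generated outcome must show
    against the predictor (regional APTw truth at the stated timepoint).
    ``sham_value``/``severe_value`` anchor the linear link at the group
    means; clamping to [lo, hi] and integer rounding are applied after
    noise.
    """

    name: str
    predictor_roi: str
    predictor_timepoint: str
    target_r: float
    sham_value: float
    severe_value: float
    lo: float
    hi: float
    integer: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < abs(self.target_r) < 1.0):
            raise ValueError(f"{self.name}: |target_r| must be in (0, 1)")
        if self.predictor_timepoint not in TIMEPOINTS:
            raise ValueError(f"{self.name}: bad predictor timepoint")


@dataclass
class OutcomeModel:
    outcomes: tuple[OutcomeSpec, ...]
    subject_effect_sd: float = 0.2      # SD of the per-subject effect multiplier
    effect_clip: tuple[float, float] = (0.5, 1.5)
    #: extra (roi, timepoint, outcome, sign) relations expected to emerge
    #: through the shared severity axis (not separately calibrated)
    induced_signs: tuple[tuple[str, str, str, int], ...] = ()


def default_outcome_model() -> OutcomeModel:
    """Outcome battery with the directionality reported for focal TBI:
    depressed core APTw at day 1 predicts worse sensorimotor score,
    anhedonia and slower maze escape; elevated perilesion/thalamic APTw at
    day 3 tracks microglial density; day-1 hippocampal APTw relates
    inversely to forced-swim immobility."""
    outcomes = (
        OutcomeSpec("mnss", "core", "1d", -0.60, 0.5, 11.0, 0.0, 18.0, integer=True),
        OutcomeSpec("spr", "core", "1d", +0.50, 0.85, 0.55, 0.0, 1.0),
        OutcomeSpec("barnes_escape_s", "core", "1d", -0.55, 40.0, 180.0, 0.0, 240.0),
        OutcomeSpec("fst_immobile_s", "ipsi_hippocampus", "1d", -0.45, 60.0, 160.0, 0.0, 240.0),
        OutcomeSpec("iba1_core", "core", "1d", -0.45, 25.0, 90.0, 0.0, np.inf, integer=True),
        OutcomeSpec("iba1_ic", "ipsi_cortex", "3d", +0.60, 20.0, 80.0, 0.0, np.inf, integer=True),
        OutcomeSpec("iba1_it", "ipsi_thalamus", "3d", +0.50, 20.0, 60.0, 0.0, np.inf, integer=True),
    )
    induced = (
        ("ipsi_cortex", "3d", "mnss", +1),
        ("ipsi_cortex", "3d", "spr", -1),
    )
    return OutcomeModel(outcomes, induced_signs=induced)


@dataclass
class CohortSpec:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"sham": 7, "mild": 16, "moderate": 17, "severe": 16})
    #: per-group count euthanized at day 3 for histology (no 28-day behavior)
    early_sacrifice: dict[str, int] = field(
        default_factory=lambda: {"sham": 0, "mild": 7, "moderate": 6, "severe": 6})
    timepoints: tuple[str, ...] = TIMEPOINTS
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    tissue_table: dict[str, TissueClass] = field(default_factory=default_tissue_table)
    effects: EffectTable = field(default_factory=default_effect_table)
    outcome_model: OutcomeModel = field(default_factory=default_outcome_model)
    snr_s0: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.group_sizes:
            if g not in SEVERITIES:
                raise ValueError(f"unknown group {g!r}")
            if self.group_sizes[g] < 0:
                raise ValueError("group sizes must be >= 0")
        if sum(self.group_sizes.values()) == 0:
            raise ValueError("cohort has zero subjects")
        for g, k in self.early_sacrifice.items():
            if k > self.group_sizes.get(g, 0):
                raise ValueError(f"early_sacrifice for {g!r} exceeds group size")


@dataclass
class SubjectRecord:
    subject_id: str
    sex: str
    group: str
    effect_scale: float


@dataclass
class SubjectImageSet:
    subject_id: str
    timepoint: str
    protocol: AcquisitionProtocol
    stacks: dict[str, RawStack]


# ---------------------------------------------------------------------------
# predictor truth and noise-SD calibration
# ---------------------------------------------------------------------------

def _predictor_params(spec: CohortSpec, roi: str, tp: str):
    """(baseline, per-group shift) of regional APTw truth at unit effect scale."""
    base = spec.tissue_table[roi].aptw_truth_pct
    shifts = {g: spec.effects.get(g, tp, roi).get("aptw_truth_pct", 0.0) for g in SEVERITIES}
    return base, shifts


def _finish(y, o: OutcomeSpec):
    y = np.clip(y, o.lo, o.hi)
    if o.integer:
        y = np.rint(y)
    return y


_CAL_CACHE: dict[tuple, float] = {}
_CAL_N = 200_000
_CAL_SEED = 20260927  # internal constant: calibration is part of the model definition


def _link_coeffs(o: OutcomeSpec, base: float, shifts: dict[str, float]):
    if shifts["severe"] == shifts["sham"]:
        raise ValueError(
            f"outcome {o.name!r}: predictor ({o.predictor_roi}@{o.predictor_timepoint}) "
            "has no severity contrast")
    c1 = (o.severe_value - o.sham_value) / (shifts["severe"] - shifts["sham"])
    c0 = o.sham_value - c1 * (base + shifts["sham"])
    return c0, c1


def _calibrate_sigma(o: OutcomeSpec, base: float, shifts: dict[str, float],
                     fracs: dict[str, float], m_sd: float,
                     m_clip: tuple[float, float]) -> tuple[float, float, float]:
    """Noise SD such that corr(predictor, finished outcome) = target_r.

    Returns (c0, c1, sigma). Uses a deterministic large-sample draw with
    common random numbers and bisection; |r|(sigma) is monotone decreasing,
    so the root is unique. Raises if the target is unreachable (predictor
    without severity contrast, or |r| above the zero-noise ceiling).
    """
    c0, c1 = _link_coeffs(o, base, shifts)

    key = (o, base, tuple(sorted(shifts.items())), tuple(sorted(fracs.items())),
           m_sd, m_clip)
    if key in _CAL_CACHE:
        return c0, c1, _CAL_CACHE[key]

    rng = np.random.default_rng(_CAL_SEED)
    groups = rng.choice(list(fracs), size=_CAL_N, p=[fracs[g] for g in fracs])
    m = np.clip(1.0 + m_sd * rng.normal(size=_CAL_N), *m_clip)
    shift_arr = np.array([shifts[g] for g in groups])
    x = base + shift_arr * m
    y0 = c0 + c1 * x
    eps = rng.normal(size=_CAL_N)

    def realized_r(sigma):
        y = _finish(y0 + sigma * eps, o)
        sy = y.std()
        if sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    target = o.target_r
    r0 = realized_r(0.0)
    if abs(r0) < abs(target) or np.sign(r0) != np.sign(target):
        raise ValueError(
            f"outcome {o.name!r}: configured r={target} unreachable "
            f"(zero-noise ceiling r={r0:.3f})")
    lo_s, hi_s = 0.0, abs(c1) * x.std() * 5.0
    while abs(realized_r(hi_s)) > abs(target):
        hi_s *= 2.0
        if hi_s > 1e8:
            raise RuntimeError("calibration failed to bracket")
    for _ in range(60):
        mid = 0.5 * (lo_s + hi_s)
        if abs(realized_r(mid)) > abs(target):
            lo_s = mid
        else:
            hi_s = mid
    sigma = 0.5 * (lo_s + hi_s)
    _CAL_CACHE[key] = sigma
    return c0, c1, sigma


# ---------------------------------------------------------------------------
# cohort draws
# ---------------------------------------------------------------------------

def draw_cohort_outcomes(spec: CohortSpec, rng: np.random.Generator | None = None):
    """Fast path: subjects, manifest, truth predictors, and outcomes — no images.

    Returns (subjects, manifest_df, outcomes_df, expectations_df,
    predictors) where ``predictors`` maps (roi, timepoint) -> per-subject
    APTw truth array aligned with the subject list.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        spec.seed if rng is None else rng)
    model = spec.outcome_model

    subjects: list[SubjectRecord] = []
    early_flags: list[bool] = []
    for g in SEVERITIES:
        n_g = spec.group_sizes.get(g, 0)
        n_early = spec.early_sacrifice.get(g, 0)
        for i in range(n_g):
            sid = f"{g[:2].upper()}{i + 1:02d}"
            m_i = float(np.clip(1.0 + model.subject_effect_sd * rng.normal(),
                                *model.effect_clip))
            subjects.append(SubjectRecord(sid, "", g, m_i))
            early_flags.append(i < n_early)
    n = len(subjects)
    sexes = np.array(["M"] * ((n + 1) // 2) + ["F"] * (n // 2))
    rng.shuffle(sexes)
    for s, sx in zip(subjects, sexes):
        s.sex = str(sx)

    groups = np.array([s.group for s in subjects])
    mvec = np.array([s.effect_scale for s in subjects])
    early = np.array(early_flags)

    predictors: dict[tuple[str, str], np.ndarray] = {}
    for o in model.outcomes:
        key = (o.predictor_roi, o.predictor_timepoint)
        if key not in predictors:
            base, shifts = _predictor_params(spec, *key)
            shift_arr = np.array([shifts[g] for g in groups])
            predictors[key] = base + shift_arr * mvec

    out_vals: dict[str, np.ndarray] = {}
    expect_vals: dict[str, np.ndarray] = {}
    for o in model.outcomes:
        base, shifts = _predictor_params(spec, o.predictor_roi, o.predictor_timepoint)
        has_outcome = early if o.name in HISTOLOGY_OUTCOMES else ~early
        fr = {g: float(np.mean(groups[has_outcome] == g)) for g in SEVERITIES}
        fr = {g: f for g, f in fr.items() if f > 0}
        if not fr:
            out_vals[o.name] = np.full(n, np.nan)
            expect_vals[o.name] = np.full(n, np.nan)
            continue
        contrast = max(shifts[g] for g in fr) - min(shifts[g] for g in fr)
        if contrast == 0.0:
            # degenerate sub-cohort (e.g. sham-only): no correlation to
            # realize; use anchor-scale noise so outcomes still scatter
            c0, c1 = _link_coeffs(o, base, shifts)
            sigma = 0.1 * abs(o.severe_value - o.sham_value)
        else:
            c0, c1, sigma = _calibrate_sigma(o, base, shifts, fr,
                                             model.subject_effect_sd, model.effect_clip)
        x = predictors[(o.predictor_roi, o.predictor_timepoint)]
        y0 = c0 + c1 * x
        y = _finish(y0 + sigma * rng.normal(size=n), o)
        y = np.where(has_outcome, y, np.nan)
        out_vals[o.name] = y
        expect_vals[o.name] = np.where(has_outcome, y0, np.nan)

    manifest = pd.DataFrame({
        "subject_id": [s.subject_id for s in subjects],
        "sex": [s.sex for s in subjects],
        "group": groups,
        "early_sacrifice": early,
    })
    outcomes = pd.DataFrame({"subject_id": manifest["subject_id"], **out_vals})
    expectations = pd.DataFrame({"subject_id": manifest["subject_id"], **expect_vals})
    return subjects, manifest, outcomes, expectations, predictors


def simulate_cohort(spec: CohortSpec, with_images: bool = True):
    """Full cohort simulation.

    Returns (image_sets, cohort, truths):
    ``image_sets`` — list of SubjectImageSet (one per subject x timepoint,
    empty when with_images=False); ``cohort`` — dict with 'manifest',
    'outcomes', 'expectations' DataFrames; ``truths`` — dict
    (subject_id, timepoint) -> PhantomTruth.
    """
    master = np.random.SeedSequence(spec.seed)
    s_outcomes, s_images = master.spawn(2)
    rng_out = np.random.default_rng(s_outcomes)
    subjects, manifest, outcomes, expectations, _ = draw_cohort_outcomes(spec, rng_out)

    image_sets: list[SubjectImageSet] = []
    truths: dict[tuple[str, str], PhantomTruth] = {}
    if with_images:
        child_seeds = s_images.spawn(len(subjects) * len(spec.timepoints))
        k = 0
        for subj in subjects:
            for tp in spec.timepoints:
                pspec = PhantomSpec(protocol=spec.protocol,
                                    tissue_table=spec.tissue_table,
                                    severity=subj.group, timepoint=tp,
                                    snr_s0=spec.snr_s0,
                                    effect_scale=subj.effect_scale,
                                    seed=spec.seed)
                truth, _rois = build_phantom(pspec, spec.effects)
                rng_img = np.random.default_rng(child_seeds[k])
                k += 1
                stacks = simulate_subject_stacks(truth, rng_img)
                image_sets.append(SubjectImageSet(subj.subject_id, tp,
                                                  spec.protocol, stacks))
                truths[(subj.subject_id, tp)] = truth
    cohort = {"manifest": manifest, "outcomes": outcomes, "expectations": expectations}
    return image_sets, cohort, truths


__all__ = [
    "BEHAVIOR_OUTCOMES", "HISTOLOGY_OUTCOMES", "OutcomeSpec", "OutcomeModel",
    "default_outcome_model", "CohortSpec", "SubjectRecord", "SubjectImageSet",
    "draw_cohort_outcomes", "simulate_cohort",
]
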