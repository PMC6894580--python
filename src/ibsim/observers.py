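"""Generative observer models for synthetic subject cohorts.

Each cohort is produced under one of four candidate accounts of how an
unexpected object reaches awareness:

* ``onset_window`` — noticing is triggered by the object's appearance;
  a Bernoulli detection with probability ``p_detect`` (plus an optional
  ``edge_boost`` when the object onsets at a display edge), with the
  latent noticing time uniform in a short window after onset.
* ``offset_window`` — the mirror case, anchored at the disappearance.
* ``fixation_cross`` — anchored at the moment the object passes behind
  fixation; never fires on paths that do not reach fixation.
* ``constant_hazard`` — detection is a Poisson arrival while the object
  is visible, so P(notice) = 1 - exp(-lambda * T) grows with exposure T.

Noticers report the object's location near its position at the latent
noticing time (optionally shifted back along the motion path, emulating
velocity extrapolation), its hue concentrated on the true hue, and its
shape correctly with high probability. Non-noticers place the object
diffusely near the display centre and answer the feature questions at
chance. Reports are emitted on the two-thirds-scale response panel used
for localisation, and every subject carries bounce-count reports and the
screening covariates, so the downstream exclusion and analysis stages are
exercised end to end without human data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import display
from .display import ConditionSpec, DisplayGeometry, MotionParams
from .d15 import identity_arrangement, random_deficient_arrangement

__all__ = [
    "MODEL_VARIANTS",
    "NoticingModel",
    "ReportNoise",
    "ExclusionProbs",
    "SubjectRecord",
    "SHAPE_MENU",
    "COLOUR_MENU",
    "PANEL_SCALE",
    "sample_noticing",
    "sample_location_report",
    "sample_feature_reports",
    "sample_covariates_and_counts",
    "make_count_pool",
    "generate_cohort",
    "cohort_to_csv",
]

MODEL_VARIANTS = ("onset_window", "offset_window", "fixation_cross", "constant_hazard")

#: Nine-option forced-choice menus (chance level 1/9 = 11.1%). The true
#: shape of the unexpected object is always the cross; in E1/E2 its true
#: colour is the grey menu entry.
SHAPE_MENU = (
    "cross", "square", "triangle", "diamond", "circle",
    "star", "pentagon", "hexagon", "heart",
)
COLOUR_MENU = (
    "grey", "red", "orange", "yellow", "green",
    "cyan", "blue", "purple", "pink",
)
TRUE_SHAPE = "cross"
TRUE_COLOUR_LABEL = "grey"

#: The localisation widget shows a two-thirds-scale image of the display.
PANEL_SCALE = 2.0 / 3.0


@dataclass(frozen=True)
class NoticingModel:
    """One candidate noticing process and its parameters."""

    variant: str
    p_detect: float = 0.45
    hazard_per_s: float = 0.2
    window_s: float = 1.0
    edge_boost: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in MODEL_VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")
        if not 0.0 <= self.p_detect <= 1.0:
            raise ValueError("p_detect must lie in [0, 1]")
        if not 0.0 <= self.p_detect + self.edge_boost <= 1.0:
            raise ValueError("p_detect + edge_boost must lie in [0, 1]")
        if self.hazard_per_s < 0.0:
            raise ValueError("hazard_per_s must be >= 0")
        if self.window_s < 0.0:
            raise ValueError("window_s must be >= 0")


@dataclass(frozen=True)
class ReportNoise:
    """Report-noise model shared by all noticing variants.

    ``loc_sigma_px`` is the isotropic placement noise of noticers (full
    display scale); ``extrapolation_px`` shifts the reported point back
    along the motion path toward the motion's origin; ``colour_kappa`` is
    the von Mises concentration of noticers' hue reports; ``q_shape`` and
    ``q_colour`` are the probabilities that a noticer answers the 9-option
    menus correctly; non-noticers place the object near the display centre
    with dispersion ``nonnoticer_loc_sigma_px`` and answer the feature
    questions at chance. Bounce reports are the true count perturbed by a
    relative Gaussian error with sd ``count_error_sd``.
    """

    loc_sigma_px: float = 70.0
    extrapolation_px: float = 20.0
    colour_kappa: float = 4.5
    q_shape: float = 0.88
    q_colour: float | None = None
    nonnoticer_loc_sigma_px: float = 140.0
    count_error_sd: float = 0.15

    def __post_init__(self) -> None:
        for name in ("loc_sigma_px", "colour_kappa", "nonnoticer_loc_sigma_px",
                     "count_error_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 1.0 / len(SHAPE_MENU) <= self.q_shape <= 1.0:
            raise ValueError("q_shape must lie in [1/9, 1]")

    @property
    def q_colour_eff(self) -> float:
        return self.q_shape if self.q_colour is None else self.q_colour


@dataclass(frozen=True)
class ExclusionProbs:
    """Base rates of the screening covariates in a synthetic cohort."""

    p_underage: float = 0.002
    p_vision_uncorrected: float = 0.06
    p_technical: float = 0.05
    p_prior_ib: float = 0.045
    p_d15_deficient: float = 0.08
    d15_severity: int = 4  # random cap swaps applied to deficient arrangements


CLEAN_COVARIATES = ExclusionProbs(0.0, 0.0, 0.0, 0.0, 0.0, 0)


@dataclass
class SubjectRecord:
    """One synthetic participant (row-level view of a cohort frame)."""

    subject_id: str
    experiment: str
    condition_id: str
    direction: str | None
    attended_colour: str
    reported_bounces: tuple[int, int, int]
    true_bounces: tuple[int, int, int]
    reported_noticed: bool
    shape_report: str
    colour_report_label: str | None
    hue_report_deg: float | None
    true_hue_deg: float | None
    location_report: tuple[float, float]
    vision_corrected_ok: bool
    technical_problem: bool
    prior_ib_experience: bool
    age_ok: bool
    d15_arrangement: tuple[int, ...] | None
    t_notice_s: float | None


# ---------------------------------------------------------------------------
# Noticing
# ---------------------------------------------------------------------------

def _noticing_vec(
    model: NoticingModel,
    condition: ConditionSpec,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (noticed, t_notice) for ``n`` subjects of one condition.

    Noticing timing is direction-independent (the path geometry is mirror
    symmetric), so directions are sampled separately.
    """
    t_notice = np.full(n, np.nan)
    if not condition.has_uo:
        return np.zeros(n, dtype=bool), t_notice
    cond = condition if condition.direction else condition.with_direction("LtoR")
    t0, t1 = cond.motion_start_s, cond.uo_offset_time_s

    if model.variant == "constant_hazard":
        if model.hazard_per_s == 0.0:
            return np.zeros(n, dtype=bool), t_notice
        arrival = t0 + rng.exponential(1.0 / model.hazard_per_s, size=n)
        noticed = arrival <= t1
        t_notice[noticed] = arrival[noticed]
        return noticed, t_notice

    p = model.p_detect
    if model.variant == "onset_window" and cond.onset_type == "edge":
        p = p + model.edge_boost
    if model.variant == "onset_window":
        anchor = cond.onset_time_s
    elif model.variant == "offset_window":
        anchor = None  # handled below: window ends at offset
    else:  # fixation_cross
        anchor = cond.fixation_cross_time_s
        if anchor is None:  # path never reaches fixation
            return np.zeros(n, dtype=bool), t_notice
    noticed = rng.random(n) < p
    k = int(noticed.sum())
    if model.variant == "offset_window":
        draws = t1 - rng.uniform(0.0, model.window_s, size=k)
    else:
        draws = anchor + rng.uniform(0.0, model.window_s, size=k)
    t_notice[noticed] = np.clip(draws, t0, t1)
    return noticed, t_notice


def sample_noticing(
    model: NoticingModel,
    condition: ConditionSpec,
    rng: np.random.Generator,
) -> tuple[bool, float | None]:
    """Draw one subject's noticing outcome and latent noticing time."""
    noticed, t = _noticing_vec(model, condition, 1, rng)
    return bool(noticed[0]), (None if np.isnan(t[0]) else float(t[0]))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _panel_clip(xy: np.ndarray, geometry: DisplayGeometry) -> np.ndarray:
    xy[..., 0] = np.clip(xy[..., 0], 0.0, geometry.width_px * PANEL_SCALE)
    xy[..., 1] = np.clip(xy[..., 1], 0.0, geometry.height_px * PANEL_SCALE)
    return xy


def _location_vec(
    noticed: np.ndarray,
    t_notice: np.ndarray,
    directions: np.ndarray,
    condition: ConditionSpec,
    noise: ReportNoise,
    rng: np.random.Generator,
    geometry: DisplayGeometry,
) -> np.ndarray:
    n = len(noticed)
    if noticed.any() and not condition.has_uo:
        raise ValueError("no-object condition cannot have noticers")
    xy = np.empty((n, 2))
    non = ~noticed
    xy[non, 0] = geometry.fixation_x + rng.normal(0, noise.nonnoticer_loc_sigma_px, non.sum())
    xy[non, 1] = geometry.fixation_y + rng.normal(0, noise.nonnoticer_loc_sigma_px, non.sum())
    if noticed.any() and condition.has_uo:
        cond = condition if condition.direction else condition.with_direction("LtoR")
        # canonical left-to-right x, mirrored afterwards for RtoL subjects
        x = display.uo_centre_x_at(cond.with_direction("LtoR"), t_notice[noticed])
        x = x - noise.extrapolation_px  # toward the motion's origin
        rtl = directions[noticed] == "RtoL"
        x = np.where(rtl, geometry.width_px - x, x)
        xy[noticed, 0] = x + rng.normal(0, noise.loc_sigma_px, noticed.sum())
        xy[noticed, 1] = geometry.fixation_y + rng.normal(0, noise.loc_sigma_px, noticed.sum())
    return _panel_clip(xy * PANEL_SCALE, geometry)


def sample_location_report(
    noticed: bool,
    t_notice: float | None,
    condition: ConditionSpec,
    noise: ReportNoise,
    rng: np.random.Generator,
    geometry: DisplayGeometry | None = None,
) -> tuple[float, float]:
    """One subject's placement on the two-thirds-scale panel.

    Noticers place the object at its position at the noticing time,
    shifted ``extrapolation_px`` toward the motion's origin, plus
    isotropic noise; non-noticers place it diffusely about the display
    centre. The result is scaled by 2/3 and clipped to the panel.
    """
    geometry = geometry or DisplayGeometry()
    if noticed and t_notice is None:
        raise ValueError("noticed subject requires a noticing time")
    direction = condition.direction if condition.has_uo else "LtoR"
    xy = _location_vec(
        np.array([noticed]),
        np.array([np.nan if t_notice is None else t_notice]),
        np.array([direction or "LtoR"]),
        condition,
        noise,
        rng,
        geometry,
    )
    return float(xy[0, 0]), float(xy[0, 1])


def _feature_vec(
    noticed: np.ndarray,
    true_hues: np.ndarray | None,
    experiment: str,
    noise: ReportNoise,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """(shape_report, colour_label_report, hue_report_deg)."""
    n = len(noticed)
    other_shapes = [s for s in SHAPE_MENU if s != TRUE_SHAPE]
    shape = np.array(rng.choice(SHAPE_MENU, size=n))
    correct = noticed & (rng.random(n) < noise.q_shape)
    shape[correct] = TRUE_SHAPE
    wrong = noticed & ~correct
    shape[wrong] = rng.choice(other_shapes, size=int(wrong.sum()))

    if experiment == "E3":
        hue = rng.uniform(0.0, 360.0, size=n)
        k = int(noticed.sum())
        if k and noise.colour_kappa > 0:
            err = np.degrees(rng.vonmises(0.0, noise.colour_kappa, size=k))
            hue[noticed] = np.mod(true_hues[noticed] + err, 360.0)
        return shape, None, hue

    other_colours = [c for c in COLOUR_MENU if c != TRUE_COLOUR_LABEL]
    colour = np.array(rng.choice(COLOUR_MENU, size=n))
    correct = noticed & (rng.random(n) < noise.q_colour_eff)
    colour[correct] = TRUE_COLOUR_LABEL
    wrong = noticed & ~correct
    colour[wrong] = rng.choice(other_colours, size=int(wrong.sum()))
    return shape, colour, None


def sample_feature_reports(
    noticed: bool,
    condition: ConditionSpec,
    noise: ReportNoise,
    rng: np.random.Generator,
) -> tuple[str, str | float]:
    """One subject's shape and colour report.

    Returns ``(shape_label, colour)`` where colour is a menu label in
    E1/E2 and a hue in degrees in E3.
    """
    hues = None
    if condition.experiment == "E3":
        hue = condition.uo_hue_deg if condition.uo_hue_deg is not None else 0.0
        hues = np.array([hue])
    shape, label, hue = _feature_vec(
        np.array([noticed]), hues, condition.experiment, noise, rng
    )
    return str(shape[0]), (float(hue[0]) if label is None else str(label[0]))


def sample_covariates_and_counts(
    true_counts: Sequence[int],
    noise: ReportNoise,
    exclusion_probs: ExclusionProbs,
    rng: np.random.Generator,
    experiment: str = "E1",
) -> dict:
    """Bounce-count reports plus screening covariates for one subject.

    Reported counts are ``round(true * (1 + eps))`` with eps ~
    Normal(0, count_error_sd); covariates are independent Bernoulli draws;
    in E3 a D-15 arrangement is attached (identity unless the subject is
    drawn colour-deficient, in which case the arrangement is corrupted by
    ``d15_severity`` random cap swaps).
    """
    true = np.asarray(true_counts, dtype=float)
    eps = rng.normal(0.0, noise.count_error_sd, size=len(true))
    reported = np.maximum(0, np.rint(true * (1.0 + eps))).astype(int)
    out = {
        "true_bounces": tuple(int(t) for t in true),
        "reported_bounces": tuple(int(r) for r in reported),
        "age_ok": bool(rng.random() >= exclusion_probs.p_underage),
        "vision_corrected_ok": bool(rng.random() >= exclusion_probs.p_vision_uncorrected),
        "technical_problem": bool(rng.random() < exclusion_probs.p_technical),
        "prior_ib_experience": bool(rng.random() < exclusion_probs.p_prior_ib),
        "d15_arrangement": None,
    }
    if experiment == "E3":
        if rng.random() < exclusion_probs.p_d15_deficient:
            arr = random_deficient_arrangement(exclusion_probs.d15_severity, rng)
        else:
            arr = identity_arrangement()
        out["d15_arrangement"] = arr
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def make_count_pool(
    n_traces: int = 6,
    seed: int | np.random.Generator = 0,
    geometry: DisplayGeometry | None = None,
    motion: MotionParams | None = None,
) -> np.ndarray:
    """Ground-truth (white, black) bounce counts from simulated trials.

    Subjects in a cohort draw their three per-trial true counts from this
    pool; the unexpected object does not alter object motion, so a single
    pool serves every condition.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cond = ConditionSpec("E1", "pool-none", None, "none", 0.0, 350.0, 350.0)
    counts = np.empty((n_traces, 2), dtype=int)
    for i in range(n_traces):
        trace = display.simulate_trial(
            cond, geometry, motion, seed=rng, store_frames=False
        )
        counts[i] = (trace.true_bounces_white, trace.true_bounces_black)
    return counts


def generate_cohort(
    experiment: str,
    model: NoticingModel,
    noise: ReportNoise | None = None,
    n_per_condition: int = 100,
    seed: int = 0,
    exclusion_probs: ExclusionProbs | None = None,
    count_pool: np.ndarray | None = None,
    geometry: DisplayGeometry | None = None,
) -> pd.DataFrame:
    """Generate a full synthetic cohort as a tidy DataFrame (one row per
    subject; see the column dictionary in the package documentation).

    Subjects are assigned to conditions with the experiment's assignment
    odds (E1 gives the no-object condition a 1-in-5 share; E2 and E3 are
    uniform) with total size ``n_per_condition * n_conditions``, and
    motion direction is drawn per subject. Fully reproducible from the
    seed. ``count_pool`` (from :func:`make_count_pool`) may be supplied to
    reuse simulated bounce-count ground truth across cohorts; otherwise a
    small pool is simulated from the same seed stream.
    """
    noise = noise or ReportNoise()
    exclusion_probs = exclusion_probs or ExclusionProbs()
    geometry = geometry or DisplayGeometry()
    rng = np.random.default_rng(seed)
    catalog = display.condition_catalog(experiment)
    weights = display.assignment_weights(experiment)
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    n_total = n_per_condition * len(catalog)
    if count_pool is None:
        count_pool = make_count_pool(n_traces=6, seed=rng, geometry=geometry)

    cond_idx = rng.choice(len(catalog), size=n_total, p=weights)
    directions = np.where(rng.random(n_total) < 0.5, "LtoR", "RtoL")
    attended = np.where(rng.random(n_total) < 0.5, "white", "black")

    frames: list[pd.DataFrame] = []
    for ci, cond in enumerate(catalog):
        mask = cond_idx == ci
        n = int(mask.sum())
        if n == 0:
            continue
        dirs = directions[mask]
        true_hue = np.full(n, np.nan)
        if experiment == "E3":
            true_hue = rng.choice(np.array(display.E3_HUES_DEG), size=n)
        noticed, t_notice = _noticing_vec(model, cond, n, rng)
        xy = _location_vec(noticed, t_notice, dirs, cond, noise, rng, geometry)
        shape, colour_label, hue_rep = _feature_vec(
            noticed, true_hue, experiment, noise, rng
        )
        # bounce counts: three trials drawn from the ground-truth pool
        pool_idx = rng.integers(0, len(count_pool), size=(n, 3))
        col = (attended[mask] == "black").astype(int)
        true_counts = count_pool[pool_idx, col[:, None]]
        eps = rng.normal(0.0, noise.count_error_sd, size=(n, 3))
        reported = np.maximum(0, np.rint(true_counts * (1.0 + eps))).astype(int)
        # covariates
        age_ok = rng.random(n) >= exclusion_probs.p_underage
        vision_ok = rng.random(n) >= exclusion_probs.p_vision_uncorrected
        technical = rng.random(n) < exclusion_probs.p_technical
        prior = rng.random(n) < exclusion_probs.p_prior_ib
        d15 = np.array([None] * n, dtype=object)
        if experiment == "E3":
            deficient = rng.random(n) < exclusion_probs.p_d15_deficient
            d15 = np.array(
                [
                    "-".join(
                        str(c)
                        for c in (
                            random_deficient_arrangement(
                                exclusion_probs.d15_severity, rng
                            )
                            if bad
                            else identity_arrangement()
                        )
                    )
                    for bad in deficient
                ],
                dtype=object,
            )
        frames.append(
            pd.DataFrame(
                {
                    "condition_id": cond.condition_id,
                    "experiment": experiment,
                    "exposure_label_s": (
                        np.nan if cond.exposure_label_s is None else cond.exposure_label_s
                    ),
                    "onset_type": cond.onset_type,
                    "travel_px": cond.travel_px,
                    "visible_s": cond.visible_duration_s if cond.has_uo else np.nan,
                    "direction": dirs,
                    "attended_colour": attended[mask],
                    "true_bounces_1": true_counts[:, 0],
                    "true_bounces_2": true_counts[:, 1],
                    "true_bounces_3": true_counts[:, 2],
                    "reported_bounces_1": reported[:, 0],
                    "reported_bounces_2": reported[:, 1],
                    "reported_bounces_3": reported[:, 2],
                    "reported_noticed": noticed,
                    "true_shape": TRUE_SHAPE,
                    "shape_report": shape,
                    "true_colour_label": np.array(
                        [TRUE_COLOUR_LABEL if experiment != "E3" else None] * n,
                        dtype=object,
                    ),
                    "colour_report_label": (
                        colour_label.astype(object)
                        if colour_label is not None
                        else np.array([None] * n, dtype=object)
                    ),
                    "true_hue_deg": true_hue,
                    "hue_report_deg": hue_rep if hue_rep is not None else np.nan,
                    "loc_x_panel": xy[:, 0],
                    "loc_y_panel": xy[:, 1],
                    "age_ok": age_ok,
                    "vision_corrected_ok": vision_ok,
                    "technical_problem": technical,
                    "prior_ib_experience": prior,
                    "d15_arrangement": d15,
                    "t_notice_s": t_notice,
                }
            )
        )
    cohort = pd.concat(frames, ignore_index=True)
    # restore the original (randomised) subject order: concatenated row j
    # holds subject perm[j], where perm stably sorts subjects by condition
    perm = np.argsort(cond_idx, kind="stable")
    cohort = cohort.iloc[np.argsort(perm, kind="stable")].reset_index(drop=True)
    cohort.insert(0, "subject_id", [f"S{i:06d}" for i in range(len(cohort))])
    return cohort


def cohort_to_csv(cohort: pd.DataFrame, path: str, diagnostics_path: str | None = None):
    """Write a cohort CSV; the latent noticing time goes to a separate
    diagnostics CSV when requested (it is not observable data)."""
    public = cohort.drop(columns=["t_notice_s"])
    public.to_csv(path, index=False)
    if diagnostics_path:
        cohort[["subject_id", "condition_id", "t_notice_s"]].to_csv(
            diagnostics_path, index=False
        )
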