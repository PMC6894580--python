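"""Multiple-object-tracking display simulator.

Simulates the bounce-counting display used in sustained inattentional
blindness experiments: eight objects (four white, four black; one square,
triangle, diamond and circle per colour) drift along 45-degree diagonals
inside a 700 x 600 px window, bouncing off the edges, while on the critical
trial an unexpected cross traverses the display horizontally at the
vertical midpoint, emerging from and disappearing behind invisible
occluders.

Coordinate convention: origin at the top-left corner, x rightward,
y downward, positions are object centres in continuous (float) pixels.
The display is 700 px wide by 600 px tall with fixation at (350, 300);
under this reading the occluder and travel distances of every condition
sum exactly to the display width.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "DisplayGeometry",
    "ShapeSpec",
    "MotionParams",
    "ObjectState",
    "ConditionSpec",
    "BounceEvent",
    "TrialTrace",
    "SHAPES",
    "condition_catalog",
    "assignment_weights",
    "init_trial",
    "step_objects",
    "reflect_at_edges",
    "uo_kinematics",
    "simulate_trial",
    "simulate_speed_process",
    "export_trace_jsonl",
    "export_bounce_csv",
]

SQRT2 = math.sqrt(2.0)
FRAME_DT = 1.0 / 60.0

#: Half-width of the unexpected cross (40 px wide); governs gradual
#: emergence from behind the occluders.
UO_HALF_WIDTH_PX = 20.0
UO_SPEED_PX_S = 132.0
TRIAL_LENGTH_S = 15.0
UO_OFFSET_TIME_S = 13.0  # the cross always offsets with 2 s remaining

E3_HUES_DEG = tuple(float(h) for h in range(0, 360, 30))


@dataclass(frozen=True)
class DisplayGeometry:
    """Geometry of the display window (px)."""

    width_px: float = 700.0
    height_px: float = 600.0
    fixation_x: float = 350.0
    fixation_y: float = 300.0
    fixation_size_px: float = 10.0


@dataclass(frozen=True)
class ShapeSpec:
    """One display object's shape and bounding box."""

    shape_id: str
    width_px: float
    height_px: float

    @property
    def half_extent_px(self) -> float:
        return max(self.width_px, self.height_px) / 2.0


#: The four tracked shapes plus the unexpected cross (40 x 40, 14 px arms).
SHAPES: dict[str, ShapeSpec] = {
    "square": ShapeSpec("square", 40.0, 40.0),
    "triangle": ShapeSpec("triangle", 50.0, 50.0),
    "diamond": ShapeSpec("diamond", 56.0, 56.0),
    "circle": ShapeSpec("circle", 46.0, 46.0),
    "cross": ShapeSpec("cross", 40.0, 40.0),
}

TRACKED_SHAPES = ("square", "triangle", "diamond", "circle")


@dataclass(frozen=True)
class MotionParams:
    """Parameters of the random speed walk of the tracked objects.

    Speeds live on {66, 132, 198} px/s along a diagonal heading and jump
    by +-66 at change times drawn uniformly from 300-1000 ms; the walk
    reflects at the bounds (at 66 only +66 is possible, at 198 only -66).
    """

    speed_min: float = 66.0
    speed_max: float = 198.0
    speed_step: float = 66.0
    change_interval_min_ms: float = 300.0
    change_interval_max_ms: float = 1000.0

    @property
    def speed_levels(self) -> tuple[float, ...]:
        n = int(round((self.speed_max - self.speed_min) / self.speed_step)) + 1
        return tuple(self.speed_min + i * self.speed_step for i in range(n))


@dataclass
class ObjectState:
    """State of one tracked object; heading components are +-1 signs."""

    x: float
    y: float
    heading_x: int
    heading_y: int
    speed: float
    next_change_time_s: float
    shape: str = "square"
    colour: str = "white"

    @property
    def half_extent_px(self) -> float:
        return SHAPES[self.shape].half_extent_px


@dataclass(frozen=True)
class ConditionSpec:
    """Full geometry and timing of one experimental condition.

    ``onset_occluder_px`` / ``offset_occluder_px`` are the widths of the
    invisible occluders measured from the onset and offset edges of the
    display; together with ``travel_px`` (visible travel of the cross
    centre between the occluder boundaries) they sum to the display width.
    The cross always moves at 132 px/s along y = 300 and disappears
    completely at t = 13 s (2 s before the trial ends); all motion timing
    is anchored to that offset, so the nominal exposure (1.5 / 2.67 / 5 s)
    is carried as a label only.
    """

    experiment: str
    condition_id: str
    exposure_label_s: float | None
    onset_type: str  # edge | mid_display | centred | none
    travel_px: float
    onset_occluder_px: float
    offset_occluder_px: float
    direction: str | None = None  # LtoR | RtoL | None (sample per subject)
    uo_speed: float = UO_SPEED_PX_S
    uo_hue_deg: float | None = None  # None = achromatic grey (E1/E2)
    trial_length_s: float = TRIAL_LENGTH_S
    uo_offset_time_s: float = UO_OFFSET_TIME_S
    width_px: float = 700.0

    def __post_init__(self) -> None:
        if self.onset_type not in ("edge", "mid_display", "centred", "none"):
            raise ValueError(f"unknown onset_type {self.onset_type!r}")
        if self.has_uo:
            total = self.onset_occluder_px + self.travel_px + self.offset_occluder_px
            if not math.isclose(total, self.width_px):
                raise ValueError(
                    f"occluders + travel = {total} != display width {self.width_px}"
                )

    @property
    def has_uo(self) -> bool:
        return self.onset_type != "none"

    # ---- timing (direction-independent by symmetry) -------------------
    @property
    def motion_start_s(self) -> float:
        """Time the (fully hidden) cross starts moving; first partial
        visibility follows immediately after."""
        path = self.travel_px + 2.0 * UO_HALF_WIDTH_PX
        return self.uo_offset_time_s - path / self.uo_speed

    @property
    def onset_time_s(self) -> float:
        """Time the cross centre clears the onset occluder boundary."""
        return self.uo_offset_time_s - (self.travel_px + UO_HALF_WIDTH_PX) / self.uo_speed

    @property
    def visible_duration_s(self) -> float:
        """Length of the interval with a nonzero visible fraction."""
        return self.uo_offset_time_s - self.motion_start_s

    # ---- geometry (for a concrete direction) --------------------------
    def require_direction(self) -> str:
        if self.direction not in ("LtoR", "RtoL"):
            raise ValueError("condition has no concrete direction; use with_direction()")
        return self.direction

    def with_direction(self, direction: str) -> "ConditionSpec":
        if direction not in ("LtoR", "RtoL"):
            raise ValueError(f"unknown direction {direction!r}")
        return replace(self, direction=direction)

    @property
    def onset_boundary_x(self) -> float:
        """x of the inner edge of the onset occluder."""
        if self.require_direction() == "LtoR":
            return self.onset_occluder_px
        return self.width_px - self.onset_occluder_px

    @property
    def offset_boundary_x(self) -> float:
        if self.require_direction() == "LtoR":
            return self.width_px - self.offset_occluder_px
        return self.offset_occluder_px

    @property
    def uncovered_interval(self) -> tuple[float, float]:
        """Horizontal interval not hidden by either occluder."""
        lo, hi = sorted((self.onset_boundary_x, self.offset_boundary_x))
        return max(lo, 0.0), min(hi, self.width_px)

    @property
    def onset_point(self) -> tuple[float, float]:
        return self.onset_boundary_x, 300.0

    @property
    def offset_point(self) -> tuple[float, float]:
        return self.offset_boundary_x, 300.0

    @property
    def fixation_cross_time_s(self) -> float | None:
        """Time the cross centre passes the fixation column (x = 350),
        or None when the path never reaches it."""
        if not self.has_uo:
            return None
        direction = self.require_direction()
        sign = 1.0 if direction == "LtoR" else -1.0
        start_x = self.onset_boundary_x - sign * UO_HALF_WIDTH_PX
        end_x = self.offset_boundary_x + sign * UO_HALF_WIDTH_PX
        fx = 350.0
        if min(start_x, end_x) <= fx <= max(start_x, end_x):
            return self.motion_start_s + abs(fx - start_x) / self.uo_speed
        return None


class BounceEvent(NamedTuple):
    time_s: float
    object_id: int
    colour: str
    edge: str  # left | right | top | bottom


@dataclass
class TrialTrace:
    """Frame-by-frame record of one simulated trial."""

    condition: ConditionSpec
    timestep_s: float
    n_frames: int
    times_s: np.ndarray  # (n_frames,)
    positions: np.ndarray | None  # (n_frames, 8, 2) when store_frames
    speeds: np.ndarray | None  # (n_frames, 8)
    uo_centre: np.ndarray | None  # (n_frames, 2), NaN when absent
    uo_visible_fraction: np.ndarray | None  # (n_frames,)
    bounce_events: list[BounceEvent]
    true_bounces_white: int
    true_bounces_black: int
    object_shapes: tuple[str, ...] = ()
    object_colours: tuple[str, ...] = ()

    def true_bounces(self, colour: str) -> int:
        return self.true_bounces_white if colour == "white" else self.true_bounces_black


# ---------------------------------------------------------------------------
# Condition catalog
# ---------------------------------------------------------------------------

def condition_catalog(experiment: str) -> list[ConditionSpec]:
    """All unexpected-object conditions of one experiment.

    Conditions are returned with ``direction=None`` (a per-subject
    sampling flag); use :meth:`ConditionSpec.with_direction` to fix one.

    * E1: centred paths, exposures 2.67 s (occluders 210/210, travel 280)
      and 5 s (70/70, travel 560), plus a no-unexpected-object condition.
    * E2: exposures 1.5/2.67/5 s (travel 140/280/560) fully crossed with
      edge vs mid-display onset.
    * E3: centred paths, exposures 1.5 s (travel 140) and 5 s (travel 560)
      with a randomly coloured cross.
    """
    if experiment == "E1":
        return [
            ConditionSpec("E1", "E1-2.67s", 2.67, "centred", 280.0, 210.0, 210.0),
            ConditionSpec("E1", "E1-5s", 5.0, "centred", 560.0, 70.0, 70.0),
            ConditionSpec("E1", "E1-none", None, "none", 0.0, 350.0, 350.0),
        ]
    if experiment == "E2":
        out = []
        for label, travel in ((1.5, 140.0), (2.67, 280.0), (5.0, 560.0)):
            out.append(
                ConditionSpec(
                    "E2", f"E2-{label:g}s-edge", label, "edge",
                    travel, 0.0, 700.0 - travel,
                )
            )
            out.append(
                ConditionSpec(
                    "E2", f"E2-{label:g}s-mid", label, "mid_display",
                    travel, 700.0 - travel, 0.0,
                )
            )
        return out
    if experiment == "E3":
        return [
            ConditionSpec("E3", "E3-1.5s", 1.5, "centred", 140.0, 280.0, 280.0),
            ConditionSpec("E3", "E3-5s", 5.0, "centred", 560.0, 70.0, 70.0),
        ]
    raise ValueError(f"unknown experiment {experiment!r}; expected E1, E2 or E3")


def assignment_weights(experiment: str) -> np.ndarray:
    """Condition assignment odds, aligned with :func:`condition_catalog`.

    E1 subjects had a 2 in 5 chance of either unexpected-object condition
    and a 1 in 5 chance of the no-object condition; E2 and E3 assigned
    uniformly.
    """
    n = len(condition_catalog(experiment))
    if experiment == "E1":
        w = np.array([2.0, 2.0, 1.0])
    else:
        w = np.ones(n)
    return w / w.sum()


def catalog_by_id(experiment: str) -> dict[str, ConditionSpec]:
    return {c.condition_id: c for c in condition_catalog(experiment)}


# ---------------------------------------------------------------------------
# Object motion
# ---------------------------------------------------------------------------

def _draw_change_interval(motion: MotionParams, rng: np.random.Generator, size=None):
    return rng.uniform(
        motion.change_interval_min_ms / 1000.0,
        motion.change_interval_max_ms / 1000.0,
        size=size,
    )


def init_trial(
    geometry: DisplayGeometry,
    motion: MotionParams,
    seed: int | np.random.Generator,
) -> list[ObjectState]:
    """Random starting states for the eight tracked objects.

    Positions are uniform over the display with each object fully inside
    the bounds; initial speed is uniform over the speed levels, heading
    uniform over the four diagonals, first change time uniform over the
    change-interval range. Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states: list[ObjectState] = []
    for colour in ("white", "black"):
        for shape in TRACKED_SHAPES:
            half = SHAPES[shape].half_extent_px
            x = rng.uniform(half, geometry.width_px - half)
            y = rng.uniform(half, geometry.height_px - half)
            hx, hy = rng.choice([-1, 1]), rng.choice([-1, 1])
            speed = float(rng.choice(motion.speed_levels))
            states.append(
                ObjectState(
                    x=float(x), y=float(y), heading_x=int(hx), heading_y=int(hy),
                    speed=speed,
                    next_change_time_s=float(_draw_change_interval(motion, rng)),
                    shape=shape, colour=colour,
                )
            )
    return states


def _update_speed(speed: float, motion: MotionParams, rng: np.random.Generator) -> float:
    # Reflecting +-step walk: forced up at the floor, forced down at the cap.
    if speed <= motion.speed_min:
        return speed + motion.speed_step
    if speed >= motion.speed_max:
        return speed - motion.speed_step
    return speed + motion.speed_step * (1 if rng.random() < 0.5 else -1)


def step_objects(
    states: Sequence[ObjectState],
    motion: MotionParams,
    dt: float,
    rng: np.random.Generator,
    t_now: float = 0.0,
) -> list[ObjectState]:
    """Advance object states by ``dt`` seconds (no edge handling).

    Speed changes fire for objects whose scheduled change time has been
    reached at the start of the step; positions then advance along the
    diagonal heading (velocity components are speed / sqrt(2)).
    """
    out = []
    for s in states:
        speed, next_change = s.speed, s.next_change_time_s
        if dt > 0 and t_now >= next_change:
            speed = _update_speed(speed, motion, rng)
            next_change = t_now + float(_draw_change_interval(motion, rng))
        v = speed / SQRT2
        out.append(
            replace(
                s,
                x=s.x + s.heading_x * v * dt,
                y=s.y + s.heading_y * v * dt,
                speed=speed,
                next_change_time_s=next_change,
            )
        )
    return out


def reflect_at_edges(
    state: ObjectState,
    geometry: DisplayGeometry,
    time_s: float = 0.0,
    object_id: int = 0,
) -> tuple[ObjectState, list[BounceEvent]]:
    """Reflect a candidate position off any display edge it has crossed.

    Horizontal heading reverses on left/right contact and vertical heading
    on top/bottom contact; speed is preserved. A corner contact reverses
    both components and emits two bounce events.
    """
    half = state.half_extent_px
    x, y, hx, hy = state.x, state.y, state.heading_x, state.heading_y
    events: list[BounceEvent] = []
    lo_x, hi_x = half, geometry.width_px - half
    lo_y, hi_y = half, geometry.height_px - half
    if x < lo_x:
        x, hx = 2 * lo_x - x, -hx
        events.append(BounceEvent(time_s, object_id, state.colour, "left"))
    elif x > hi_x:
        x, hx = 2 * hi_x - x, -hx
        events.append(BounceEvent(time_s, object_id, state.colour, "right"))
    if y < lo_y:
        y, hy = 2 * lo_y - y, -hy
        events.append(BounceEvent(time_s, object_id, state.colour, "top"))
    elif y > hi_y:
        y, hy = 2 * hi_y - y, -hy
        events.append(BounceEvent(time_s, object_id, state.colour, "bottom"))
    return replace(state, x=x, y=y, heading_x=hx, heading_y=hy), events


# ---------------------------------------------------------------------------
# Unexpected-object kinematics
# ---------------------------------------------------------------------------

def uo_kinematics(
    condition: ConditionSpec, t: float
) -> tuple[float | None, float | None, float]:
    """Centre and visible fraction of the unexpected cross at time ``t``.

    The cross centre moves at 132 px/s along y = 300 from fully hidden
    behind the onset occluder to fully hidden behind the offset occluder,
    reaching the latter exactly at the offset time (13 s). The visible
    fraction is the share of the 40 px cross width inside the uncovered
    window (and inside the display); it ramps up as the cross emerges
    gradually and back down as it disappears. Returns ``(None, None, 0.0)``
    outside the motion interval or for a no-object condition.
    """
    if t < 0.0 or t > condition.trial_length_s:
        raise ValueError(f"t={t} outside trial [0, {condition.trial_length_s}]")
    if not condition.has_uo:
        return None, None, 0.0
    direction = condition.require_direction()
    t0, t1 = condition.motion_start_s, condition.uo_offset_time_s
    if t < t0 or t >= t1:
        return None, None, 0.0
    sign = 1.0 if direction == "LtoR" else -1.0
    start_x = condition.onset_boundary_x - sign * UO_HALF_WIDTH_PX
    cx = start_x + sign * condition.uo_speed * (t - t0)
    lo, hi = condition.uncovered_interval
    left, right = cx - UO_HALF_WIDTH_PX, cx + UO_HALF_WIDTH_PX
    overlap = max(0.0, min(right, hi) - max(left, lo))
    return cx, 300.0, overlap / (2.0 * UO_HALF_WIDTH_PX)


def uo_centre_x_at(condition: ConditionSpec, t: np.ndarray | float) -> np.ndarray:
    """Vectorised cross-centre x at times within the motion interval."""
    direction = condition.require_direction()
    sign = 1.0 if direction == "LtoR" else -1.0
    start_x = condition.onset_boundary_x - sign * UO_HALF_WIDTH_PX
    return start_x + sign * condition.uo_speed * (np.asarray(t) - condition.motion_start_s)


# ---------------------------------------------------------------------------
# Full trial simulation
# ---------------------------------------------------------------------------

def simulate_trial(
    condition: ConditionSpec,
    geometry: DisplayGeometry | None = None,
    motion: MotionParams | None = None,
    seed: int | np.random.Generator = 0,
    store_frames: bool = True,
    dt: float = FRAME_DT,
) -> TrialTrace:
    """Simulate one 15 s trial at a fixed timestep (default 1/60 s).

    Produces the frame-by-frame object states, the unexpected object's
    centre and visible fraction (absent for no-object conditions), the
    bounce-event log and the per-colour ground-truth bounce counts. All
    randomness flows from a single seed, so traces are replayable; if the
    condition carries no concrete direction one is drawn from the same
    stream.
    """
    geometry = geometry or DisplayGeometry()
    motion = motion or MotionParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cond = condition
    if cond.has_uo and cond.direction is None:
        cond = cond.with_direction("LtoR" if rng.random() < 0.5 else "RtoL")

    states = init_trial(geometry, motion, rng)
    n_frames = int(round(cond.trial_length_s / dt)) + 1
    times = np.arange(n_frames) * dt

    positions = np.empty((n_frames, 8, 2)) if store_frames else None
    speeds = np.empty((n_frames, 8)) if store_frames else None
    uo_centre = np.full((n_frames, 2), np.nan) if store_frames else None
    uo_frac = np.zeros(n_frames) if store_frames else None

    events: list[BounceEvent] = []
    bounces = {"white": 0, "black": 0}
    for k, t in enumerate(times):
        if k > 0:
            states = step_objects(states, motion, dt, rng, t_now=float(t) - dt)
            new_states = []
            for i, s in enumerate(states):
                s, ev = reflect_at_edges(s, geometry, time_s=float(t), object_id=i)
                for e in ev:
                    bounces[e.colour] += 1
                events.extend(ev)
                new_states.append(s)
            states = new_states
        if store_frames:
            for i, s in enumerate(states):
                positions[k, i] = (s.x, s.y)
                speeds[k, i] = s.speed
            if cond.has_uo:
                cx, cy, frac = uo_kinematics(cond, float(t))
                if cx is not None:
                    uo_centre[k] = (cx, cy)
                    uo_frac[k] = frac

    return TrialTrace(
        condition=cond,
        timestep_s=dt,
        n_frames=n_frames,
        times_s=times,
        positions=positions,
        speeds=speeds,
        uo_centre=uo_centre,
        uo_visible_fraction=uo_frac,
        bounce_events=events,
        true_bounces_white=bounces["white"],
        true_bounces_black=bounces["black"],
        object_shapes=tuple(s.shape for s in states),
        object_colours=tuple(s.colour for s in states),
    )


def simulate_speed_process(
    total_s: float,
    motion: MotionParams | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """Time-averaged speed of one object's speed walk over ``total_s``
    seconds of simulated time (event-driven, no positions).

    The reflecting +-66 walk on {66, 132, 198} has stationary weights
    (1/4, 1/2, 1/4), so the long-run average is 132 px/s.
    """
    motion = motion or MotionParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = 0.0
    speed = float(rng.choice(motion.speed_levels))
    acc = 0.0
    while t < total_s:
        dur = float(_draw_change_interval(motion, rng))
        dur = min(dur, total_s - t)
        acc += speed * dur
        t += dur
        speed = _update_speed(speed, motion, rng)
    return acc / total_s


# ---------------------------------------------------------------------------
# Trace export
# ---------------------------------------------------------------------------

def export_trace_jsonl(trace: TrialTrace, path: str) -> None:
    """One JSON record per frame: time, object states, cross state."""
    if trace.positions is None:
        raise ValueError("trace was simulated with store_frames=False")
    with open(path, "w") as fh:
        for k in range(trace.n_frames):
            uo = None
            if trace.uo_centre is not None and not math.isnan(trace.uo_centre[k, 0]):
                uo = {
                    "x": round(float(trace.uo_centre[k, 0]), 3),
                    "y": float(trace.uo_centre[k, 1]),
                    "visible_fraction": round(float(trace.uo_visible_fraction[k]), 4),
                }
            rec = {
                "t_s": round(float(trace.times_s[k]), 6),
                "objects": [
                    {
                        "id": i,
                        "shape": trace.object_shapes[i],
                        "colour": trace.object_colours[i],
                        "x": round(float(trace.positions[k, i, 0]), 3),
                        "y": round(float(trace.positions[k, i, 1]), 3),
                        "speed": float(trace.speeds[k, i]),
                    }
                    for i in range(8)
                ],
                "uo": uo,
            }
            fh.write(json.dumps(rec) + "\n")


def export_bounce_csv(trace: TrialTrace, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "object_id", "colour", "edge"])
        for e in trace.bounce_events:
            writer.writerow([f"{e.time_s:.6f}", e.object_id, e.colour, e.edge])


def condition_to_dict(c: ConditionSpec) -> dict:
    return {
        "experiment": c.experiment,
        "condition_id": c.condition_id,
        "exposure_label_s": c.exposure_label_s,
        "onset_type": c.onset_type,
        "travel_px": c.travel_px,
        "onset_occluder_px": c.onset_occluder_px,
        "offset_occluder_px": c.offset_occluder_px,
        "direction": c.direction,
        "uo_speed_px_s": c.uo_speed,
        "uo_hue_deg": c.uo_hue_deg,
        "trial_length_s": c.trial_length_s,
        "uo_offset_time_s": c.uo_offset_time_s,
    }
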