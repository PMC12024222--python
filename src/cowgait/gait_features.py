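"""Kinematic lameness features from side-view keypoint trajectories.

A walking cow is described by eight keypoints tracked in a calibrated
side-view camera plane (x = walking direction in cm, y = height above
ground in cm, time = frame / fps).  Six features with established links to
lameness are extracted:

back arch
    Reciprocal circumradius k = 1/R of the circle through the withers,
    mid-back and tailhead keypoints (cm^-1).  A sound cow walks with a
    level back (k near 0); severe lameness produces a visibly arched back.
head bob
    Maximum peak-to-trough vertical head excursion over the head's
    oscillation cycles (cm).  Lame cows nod the head to unload a limb.
speed
    Net forward displacement of the withers over the clip divided by
    elapsed time (m/s).
step overlap (tracking-up)
    Signed distance between a front-hoof print and the subsequent
    same-side hind-hoof placement (cm); positive when the hind hoof lands
    short of the front print, as under-tracking lame cows do.
supporting phase
    Maximum contralateral asymmetry of mean stance durations (ms); a cow
    avoiding load on a painful limb shortens that limb's stance.
hoof step time
    Duration of two consecutive stride cycles of a hoof (touch-down to
    next touch-down, summed over two cycles), maximised over hooves (ms).

The temporal features rest on gait-event detection: a hoof is in stance
while it is low *and* horizontally still; touch-down (T_Land) and lift-off
(T_Lift) times are quantised to the frame grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

KEYPOINTS: tuple[str, ...] = (
    "head",
    "withers",
    "mid_back",
    "tailhead",
    "hoof_FL",
    "hoof_FR",
    "hoof_HL",
    "hoof_HR",
)
HOOVES: tuple[str, ...] = ("hoof_FL", "hoof_FR", "hoof_HL", "hoof_HR")

#: Canonical feature order (matches the feature-table column order).
FEATURE_NAMES: tuple[str, ...] = (
    "back_arch",
    "head_bob_cm",
    "speed_mps",
    "step_overlap_cm",
    "supporting_phase_ms",
    "hoof_step_time_ms",
)

#: Contralateral pairs for the supporting-phase asymmetry.
CONTRALATERAL_PAIRS = (("hoof_FL", "hoof_FR"), ("hoof_HL", "hoof_HR"))
#: Same-side (front, hind) pairs for step overlap.
SIDE_PAIRS = {"left": ("hoof_FL", "hoof_HL"), "right": ("hoof_FR", "hoof_HR")}


class GaitFeatureError(ValueError):
    """Invalid input to a feature operator."""


class MissingKeypointError(GaitFeatureError):
    """A keypoint cannot be recovered from the clip."""


class GaitEventError(GaitFeatureError):
    """The clip does not contain the gait events a feature needs."""


class FeatureExtractionError(RuntimeError):
    """A named feature failed during composite extraction."""

    def __init__(self, feature: str, cause: Exception):
        super().__init__(f"feature '{feature}' failed: {cause}")
        self.feature = feature
        self.cause = cause


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

def _columns() -> list[str]:
    return [f"{kp}_{ax}" for kp in KEYPOINTS for ax in ("x", "y")]


@dataclass
class Trajectory:
    """Per-frame keypoint coordinates of one cow.

    ``data`` is a wide frame-indexed DataFrame with columns ``<keypoint>_x``
    and ``<keypoint>_y`` in cm; missing observations are NaN.  The frame
    index is made contiguous on construction (absent frames become NaN rows).
    """

    cow_id: str
    fps: float
    data: pd.DataFrame

    def __post_init__(self):
        if not self.fps > 0:
            raise GaitFeatureError(f"fps must be positive, got {self.fps}")
        missing_cols = [c for c in _columns() if c not in self.data.columns]
        if missing_cols:
            raise GaitFeatureError(f"trajectory missing columns: {missing_cols}")
        if len(self.data) == 0:
            raise GaitFeatureError("trajectory has no frames")
        idx = self.data.index
        full = pd.RangeIndex(int(idx.min()), int(idx.max()) + 1)
        if not idx.equals(full):
            self.data = self.data.reindex(full)
        self.data = self.data[_columns()].astype(float)
        self.data.index.name = None

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) / self.fps

    @property
    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def xy(self, keypoint: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.data[f"{keypoint}_x"].to_numpy(),
            self.data[f"{keypoint}_y"].to_numpy(),
        )

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class StanceInterval:
    """One weight-bearing interval of a hoof, on the frame grid.

    An interval touching the first (last) frame of the clip is left-
    (right-)censored: the true touch-down (lift-off) was not observed, so
    duration- and stride-based features treat it with care while the
    touch-down position remains valid.
    """

    hoof: str
    t_land_ms: float   # hoof fully loaded
    t_lift_ms: float   # toe completely lifted
    x_cm: float        # touch-down position
    left_censored: bool = False
    right_censored: bool = False

    def __post_init__(self):
        if not self.t_lift_ms > self.t_land_ms:
            raise GaitFeatureError(
                f"stance interval must have t_lift > t_land "
                f"({self.t_lift_ms} <= {self.t_land_ms})"
            )

    @property
    def duration_ms(self) -> float:
        return self.t_lift_ms - self.t_land_ms


@dataclass(frozen=True)
class FeatureVector:
    """The six kinematic features of one cow, in field-standard units."""

    back_arch: float          # cm^-1
    head_bob_cm: float
    speed_mps: float
    step_overlap_cm: float
    supporting_phase_ms: float
    hoof_step_time_ms: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


@dataclass(frozen=True)
class ExtractionConfig:
    """Gait-event detection thresholds (defaults suit 50-fps cm-calibrated clips)."""

    height_thresh_cm: float = 1.5
    motion_thresh_cm: float = 0.5     # per-frame horizontal displacement
    min_duration_ms: float = 100.0
    hysteresis_frames: int = 2


# ---------------------------------------------------------------------------
# interpolation of obscured frames
# ---------------------------------------------------------------------------

def interpolate_missing(traj: Trajectory) -> Trajectory:
    """Fill missing keypoint observations linearly from adjacent frames.

    Interior gaps are linearly interpolated; leading/trailing gaps take the
    nearest observed value.  Present entries are unchanged.  A keypoint with
    fewer than two observed frames raises :class:`MissingKeypointError`.
    """
    data = traj.data.copy()
    for kp in KEYPOINTS:
        cols = [f"{kp}_x", f"{kp}_y"]
        n_obs = data[cols].notna().all(axis=1).sum()
        if n_obs < 2:
            raise MissingKeypointError(
                f"keypoint '{kp}' observed in {n_obs} frame(s); "
                "at least 2 required to interpolate"
            )
    filled = data.interpolate(method="linear", limit_area="inside")
    filled = filled.ffill().bfill()
    return replace(traj, data=filled)


# ---------------------------------------------------------------------------
# geometric features
# ---------------------------------------------------------------------------

def back_arch_curvature(p_withers, p_mid_back, p_tailhead) -> float:
    """Curvature k = 1/R of the circle through three back keypoints.

    Uses k = 4*Area / (a*b*c); collinear points give exactly 0.  Coincident
    points are rejected.
    """
    p1 = np.asarray(p_withers, dtype=float)
    p2 = np.asarray(p_mid_back, dtype=float)
    p3 = np.asarray(p_tailhead, dtype=float)
    a = float(np.hypot(*(p2 - p3)))
    b = float(np.hypot(*(p1 - p3)))
    c = float(np.hypot(*(p1 - p2)))
    if min(a, b, c) == 0.0:
        raise GaitFeatureError("back keypoints must be pairwise distinct")
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    return 4.0 * (0.5 * abs(cross)) / (a * b * c)


def _curvature_series(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Vectorised per-frame curvature; degenerate frames yield NaN."""
    a = np.hypot(p2[:, 0] - p3[:, 0], p2[:, 1] - p3[:, 1])
    b = np.hypot(p1[:, 0] - p3[:, 0], p1[:, 1] - p3[:, 1])
    c = np.hypot(p1[:, 0] - p2[:, 0], p1[:, 1] - p2[:, 1])
    cross = (p2[:, 0] - p1[:, 0]) * (p3[:, 1] - p1[:, 1]) - (
        p2[:, 1] - p1[:, 1]
    ) * (p3[:, 0] - p1[:, 0])
    denom = a * b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        k = 4.0 * (0.5 * np.abs(cross)) / denom
    k[denom == 0] = np.nan
    return k


def head_bob_amplitude(traj: Trajectory) -> float:
    """Maximum peak-to-trough head-height excursion across oscillation cycles.

    The head-height series is linearly detrended; one "swing" spans
    successive upward zero-crossings of the detrended series (a full cycle,
    containing one peak and one trough), and the feature is the maximum of
    (highest - lowest) over swings.  Returns 0 if no complete swing exists.
    """
    _, y = traj.xy("head")
    if np.isnan(y).any():
        raise MissingKeypointError("head keypoint has missing frames; interpolate first")
    t = traj.times_s()
    if len(y) < 2:
        return 0.0
    trend = np.polyval(np.polyfit(t, y, 1), t)
    s = y - trend

    def refined(idx: int) -> float:
        # parabolic refinement of a sampled extremum (the frame grid
        # otherwise clips peaks of short-period oscillations)
        if 0 < idx < len(s) - 1:
            y0, y1, y2 = s[idx - 1], s[idx], s[idx + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                return float(y1 - (y0 - y2) ** 2 / (8 * denom))
        return float(s[idx])

    up = np.flatnonzero((s[:-1] < 0) & (s[1:] >= 0)) + 1
    if len(up) < 2:
        return 0.0
    amp = 0.0
    for a, b in zip(up[:-1], up[1:]):
        seg = s[a : b + 1]
        hi = refined(a + int(np.argmax(seg)))
        lo = refined(a + int(np.argmin(seg)))
        amp = max(amp, hi - lo)
    return amp


def walking_speed(traj: Trajectory) -> float:
    """Net withers displacement over elapsed time, in m/s."""
    x, _ = traj.xy("withers")
    if np.isnan(x).any():
        raise MissingKeypointError("withers keypoint has missing frames; interpolate first")
    if traj.n_frames < 2:
        raise GaitFeatureError("speed needs at least two frames")
    elapsed = traj.duration_s
    if elapsed <= 0:
        raise GaitFeatureError("zero elapsed time")
    return float(x[-1] - x[0]) / 100.0 / elapsed


# ---------------------------------------------------------------------------
# gait-event detection and temporal features
# ---------------------------------------------------------------------------

def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_stance_intervals(
    traj: Trajectory,
    config: ExtractionConfig = ExtractionConfig(),
) -> dict[str, list[StanceInterval]]:
    """Detect per-hoof stance intervals.

    A frame is a stance candidate when the hoof is below
    ``height_thresh_cm`` *and* its per-frame horizontal displacement (the
    smaller of the backward and forward frame-to-frame differences, so a
    single boundary frame cannot break a run) is below ``motion_thresh_cm``.
    False gaps shorter than ``hysteresis_frames`` inside a stance are
    bridged; runs shorter than ``min_duration_ms`` are discarded.  Event
    times are quantised to the frame grid: T_Land is the first stance
    frame's time, T_Lift the time of the frame after the last stance frame.
    """
    dt_ms = 1000.0 / traj.fps
    out: dict[str, list[StanceInterval]] = {}
    for hoof in HOOVES:
        x, y = traj.xy(hoof)
        if np.isnan(x).any() or np.isnan(y).any():
            raise MissingKeypointError(
                f"hoof '{hoof}' has missing frames; interpolate first"
            )
        if len(x) < 2:
            raise GaitFeatureError("stance detection needs at least two frames")
        dx = np.abs(np.diff(x))
        back = np.concatenate([[dx[0]], dx])
        fwd = np.concatenate([dx, [dx[-1]]])
        motion = np.minimum(back, fwd)
        stance = (y < config.height_thresh_cm) & (motion < config.motion_thresh_cm)

        # hysteresis: bridge short dropouts between stance runs
        runs = _bool_runs(stance)
        merged: list[list[int]] = []
        for start, end in runs:
            if merged and start - merged[-1][1] - 1 < config.hysteresis_frames:
                merged[-1][1] = end
            else:
                merged.append([start, end])

        intervals = []
        for start, end in merged:
            duration = (end - start + 1) * dt_ms
            if duration < config.min_duration_ms:
                continue
            intervals.append(
                StanceInterval(
                    hoof=hoof,
                    t_land_ms=start * dt_ms,
                    t_lift_ms=(end + 1) * dt_ms,
                    # median over the run: the hoof is still while loaded,
                    # so this is the touch-down position, robust to a
                    # boundary frame caught at the very end of the swing
                    x_cm=float(np.median(x[start : end + 1])),
                    left_censored=start == 0,
                    right_censored=end == len(x) - 1,
                )
            )
        out[hoof] = intervals
    if all(len(v) == 0 for v in out.values()):
        raise GaitEventError("no stance interval found for any hoof")
    return out


def step_overlap(stances: dict[str, list[StanceInterval]]) -> float:
    """Tracking-up feature: max over sides of the mean front-minus-hind print distance.

    For each hind touch-down, the overlap is (x of the most recent same-side
    front touch-down) - (x of this hind touch-down); per-side values are
    averaged over cycles and the signed maximum of the two sides returned.
    """
    side_means = {}
    for side, (front, hind) in SIDE_PAIRS.items():
        fronts = sorted(stances.get(front, []), key=lambda s: s.t_land_ms)
        deltas = []
        for h in stances.get(hind, []):
            prev = [f for f in fronts if f.t_land_ms < h.t_land_ms]
            if prev:
                deltas.append(prev[-1].x_cm - h.x_cm)
        if deltas:
            side_means[side] = float(np.mean(deltas))
    if not side_means:
        raise GaitEventError("no hind placement with a preceding same-side front placement")
    return max(side_means.values())


def supporting_phase_feature(stances: dict[str, list[StanceInterval]]) -> float:
    """Maximum contralateral difference of mean stance durations (ms).

    Boundary-censored intervals (whose true duration is unobserved) are
    excluded when a hoof has at least one complete stance.
    """
    mean_dur = {}
    for hoof in HOOVES:
        ivals = stances.get(hoof, [])
        complete = [s for s in ivals if not (s.left_censored or s.right_censored)]
        use = complete or ivals
        if not use:
            raise GaitEventError(f"hoof '{hoof}' has no complete stance")
        mean_dur[hoof] = float(np.mean([s.duration_ms for s in use]))
    return max(
        abs(mean_dur[left] - mean_dur[right]) for left, right in CONTRALATERAL_PAIRS
    )


def hoof_step_time_feature(stances: dict[str, list[StanceInterval]]) -> float:
    """Two-stride duration, maximised over hooves (ms).

    Per hoof, stride cycles are the intervals between consecutive
    touch-downs; each pair of consecutive cycles sums to a two-stride
    duration, and the per-hoof value is the mean of those pair sums.
    Requires at least one hoof with >= 3 touch-downs.
    """
    per_hoof = []
    for hoof in HOOVES:
        # a left-censored interval's "touch-down" is the clip start, not a
        # real gait event, so it cannot anchor a stride
        lands = sorted(
            s.t_land_ms for s in stances.get(hoof, []) if not s.left_censored
        )
        if len(lands) < 3:
            continue
        strides = np.diff(lands)
        pair_sums = strides[:-1] + strides[1:]
        per_hoof.append(float(np.mean(pair_sums)))
    if not per_hoof:
        raise GaitEventError("no hoof with >= 3 touch-downs")
    return max(per_hoof)


# ---------------------------------------------------------------------------
# composite extraction
# ---------------------------------------------------------------------------

def _stance_frame_mask(
    stances: dict[str, list[StanceInterval]], n_frames: int, fps: float
) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    dt_ms = 1000.0 / fps
    for ivals in stances.values():
        for s in ivals:
            a = int(round(s.t_land_ms / dt_ms))
            b = int(round(s.t_lift_ms / dt_ms))
            mask[a : min(b, n_frames)] = True
    return mask


def extract_features(
    traj: Trajectory, config: ExtractionConfig = ExtractionConfig()
) -> FeatureVector:
    """Extract the six kinematic features from one trajectory.

    Missing frames are interpolated first.  Back arch is the per-frame
    curvature of (withers, mid-back, tailhead) averaged over frames in
    which at least one hoof is in stance.  Component failures are re-raised
    as :class:`FeatureExtractionError` naming the failing feature.
    """

    def step(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - named propagation is the contract
            raise FeatureExtractionError(name, exc) from exc

    if traj.has_missing:
        traj = step("interpolation", interpolate_missing, traj)

    speed = step("speed_mps", walking_speed, traj)
    head_bob = step("head_bob_cm", head_bob_amplitude, traj)
    stances = step("gait_events", detect_stance_intervals, traj, config)
    overlap = step("step_overlap_cm", step_overlap, stances)
    supporting = step("supporting_phase_ms", supporting_phase_feature, stances)
    step_time = step("hoof_step_time_ms", hoof_step_time_feature, stances)

    def back_arch_fn():
        p1 = np.column_stack(traj.xy("withers"))
        p2 = np.column_stack(traj.xy("mid_back"))
        p3 = np.column_stack(traj.xy("tailhead"))
        k = _curvature_series(p1, p2, p3)
        mask = _stance_frame_mask(stances, traj.n_frames, traj.fps)
        vals = k[mask & ~np.isnan(k)]
        if vals.size == 0:
            raise GaitEventError("no valid stance-phase frames for back arch")
        return float(vals.mean())

    back_arch = step("back_arch", back_arch_fn)

    return FeatureVector(
        back_arch=back_arch,
        head_bob_cm=head_bob,
        speed_mps=speed,
        step_overlap_cm=overlap,
        supporting_phase_ms=supporting,
        hoof_step_time_ms=step_time,
    )
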