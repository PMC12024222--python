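"""Synthetic cow-gait data with known ground truth.

Two levels of synthesis are provided:

* **Feature cohorts** — per-cow draws of the six kinematic features plus a
  locomotion score (1 sound / 2 mildly lame / 3 severely lame).  Class-
  conditional distributions are lognormal (strictly positive features)
  around published per-score population means, with a per-cow shared
  "expressiveness" effect and cross-feature correlation; step overlap is
  normal because sound cows straddle zero (over- vs under-tracking).
* **Keypoint trajectories** — a deterministic 2-D side-view kinematic
  model (x = walking direction, y = height, cm, frames at a fixed rate)
  whose implied feature vector is known in closed form, for exercising the
  feature extractors end to end.

The kinematic model: the withers advance at constant speed; the head
oscillates vertically at stride frequency with a configurable
peak-to-trough amplitude; withers, mid-back and tailhead lie on a circular
arc of configurable curvature; each hoof alternates stance (fixed x,
height 0) and swing (smooth advance by one stride, height > 0) following
the bovine walking footfall sequence LH-LF-RH-RF, with per-hoof stance
durations and touch-down positions realising the configured asymmetry and
step overlaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gait_features import FEATURE_NAMES, HOOVES, FeatureVector, Trajectory, _columns

SCORES = (1, 2, 3)

#: Published per-score population means, rows = score 1/2/3, columns in
#: FEATURE_NAMES order (back arch cm^-1, head bob cm, speed m/s,
#: step overlap cm, supporting phase ms, hoof step time ms).
TABLE_MEANS = np.array(
    [
        [2.7e-4, 9.0, 2.2, 0.8, 93.1, 821.6],
        [5.4e-4, 10.1, 2.0, 11.3, 225.4, 941.8],
        [9.5e-4, 15.8, 1.9, 17.3, 318.0, 1576.9],
    ]
)

#: Default per-score coefficients of variation for the five lognormal
#: features (step-overlap column is NaN: that feature uses an absolute SD).
#: Calibrated once to the published distributional structure: "separated"
#: score pairs have disjoint interquartile ranges while "overlapping" pairs
#: share central mass (back arch & head bob: scores 1-2 overlap, 3
#: separated; supporting phase: score 1 separated, 2-3 overlap; speed and
#: hoof step time overlap throughout).  Back-arch spreads additionally
#: follow the reported quartiles (score-3 IQR approx. 0.0009-0.0011,
#: i.e. CV approx. 0.15).
DEFAULT_CV = np.array(
    [
        [0.30, 0.30, 0.25, np.nan, 0.30, 0.55],
        [0.30, 0.30, 0.25, np.nan, 0.30, 0.55],
        [0.15, 0.30, 0.25, np.nan, 0.30, 0.55],
    ]
)

#: Per-score SD of the (normal) step-overlap feature, cm.
DEFAULT_STEP_OVERLAP_SD = (3.0, 4.0, 6.0)

_STEP_OVERLAP_COL = FEATURE_NAMES.index("step_overlap_cm")


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the reference cohort: 175 cows split 80/66/29 across
    locomotion scores, feature means from the published per-score table,
    50 fps side-view recordings of 5-10 s over a 6 m alley.
    """

    n_per_score: tuple[int, int, int] = (80, 66, 29)
    feature_means: np.ndarray = field(default_factory=lambda: TABLE_MEANS.copy())
    feature_cv: np.ndarray = field(default_factory=lambda: DEFAULT_CV.copy())
    step_overlap_sd_cm: tuple[float, float, float] = DEFAULT_STEP_OVERLAP_SD
    cow_effect_sd: float = 0.5        # fraction of class SD shared per cow
    cross_feature_corr: float = 0.3   # latent correlation among features
    seed: int = 0
    fps: float = 50.0
    alley_length_m: float = 6.0
    clip_duration_s: tuple[float, float] = (5.0, 10.0)
    dropout_rate: float = 0.02        # keypoint occlusion rate in trajectories

    def __post_init__(self):
        self._normalise_arrays()

    def _normalise_arrays(self) -> None:
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        cv = np.asarray(self.feature_cv, dtype=float)
        if cv.ndim == 0:  # scalar CV broadcast to the 3x6 table
            cv = np.full((3, 6), float(cv))
            cv[:, _STEP_OVERLAP_COL] = np.nan
        self.feature_cv = cv

    def validate(self) -> None:
        self._normalise_arrays()
        if len(self.n_per_score) != 3 or any(n < 1 for n in self.n_per_score):
            raise ConfigError(f"n_per_score must be three counts >= 1: {self.n_per_score}")
        if self.feature_means.shape != (3, 6):
            raise ConfigError(f"feature_means must be 3x6, got {self.feature_means.shape}")
        means = self.feature_means.copy()
        means[:, _STEP_OVERLAP_COL] = 1.0  # step overlap may be near 0
        if np.any(means <= 0):
            raise ConfigError("feature means must be strictly positive (except step overlap)")
        if self.feature_cv.shape != (3, 6):
            raise ConfigError(f"feature_cv must be 3x6, got {self.feature_cv.shape}")
        lognormal_cv = np.delete(self.feature_cv, _STEP_OVERLAP_COL, axis=1)
        if np.any(np.isnan(lognormal_cv)) or np.any(lognormal_cv < 0):
            raise ConfigError("feature_cv entries must be >= 0")
        if any(sd < 0 for sd in self.step_overlap_sd_cm):
            raise ConfigError("step_overlap_sd_cm must be >= 0")
        if not 0 <= self.cow_effect_sd < 1:
            raise ConfigError("cow_effect_sd must lie in [0, 1)")
        if not abs(self.cross_feature_corr) < 1:
            raise ConfigError("|cross_feature_corr| must be < 1")
        a2 = self.cow_effect_sd**2
        rho_u = (self.cross_feature_corr - a2) / (1 - a2)
        if rho_u < -1.0 / (len(FEATURE_NAMES) - 1) or rho_u >= 1.0:
            raise ConfigError(
                "cross_feature_corr incompatible with cow_effect_sd "
                f"(residual correlation {rho_u:.3f} not attainable for 6 features)"
            )
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        lo, hi = self.clip_duration_s
        if not (0 < lo <= hi):
            raise ConfigError("clip_duration_s must be an increasing positive range")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must lie in [0, 1)")


def default_paper_config() -> GeneratorConfig:
    """Config reproducing the reference study conditions (80/66/29 cows etc.)."""
    return GeneratorConfig()


# ---------------------------------------------------------------------------
# feature-level cohort sampling
# ---------------------------------------------------------------------------

def _latent_draws(n: int, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """n x 6 standard-normal latents with per-cow effect and equicorrelation."""
    m = len(FEATURE_NAMES)
    a = config.cow_effect_sd
    a2 = a**2
    rho_u = (config.cross_feature_corr - a2) / (1 - a2) if a2 < 1 else 0.0
    cow = rng.standard_normal((n, 1))
    # exact equicorrelated residuals: u = b*eps + ((sqrt(1+(m-1)rho)-b)/m)*sum(eps)
    # with b = sqrt(1-rho); valid for rho in [-1/(m-1), 1)
    eps = rng.standard_normal((n, m))
    b = math.sqrt(1 - rho_u)
    s = eps.sum(axis=1, keepdims=True)
    u = b * eps + (math.sqrt(1 + (m - 1) * rho_u) - b) / m * s
    return a * cow + math.sqrt(1 - a2) * u


def _features_from_latent(
    z: np.ndarray, score: int, config: GeneratorConfig
) -> np.ndarray:
    """Map latent normals to feature values for one score class."""
    si = SCORES.index(score)
    means = config.feature_means[si]
    out = np.empty_like(z)
    for j, _name in enumerate(FEATURE_NAMES):
        if j == _STEP_OVERLAP_COL:
            out[:, j] = means[j] + config.step_overlap_sd_cm[si] * z[:, j]
        else:
            cv = config.feature_cv[si, j]
            sigma = math.sqrt(math.log1p(cv**2))
            out[:, j] = means[j] * np.exp(sigma * z[:, j] - 0.5 * sigma**2)
    return out


def sample_feature_cohort(
    config: GeneratorConfig | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a feature cohort: one row per cow, six features + ``score``.

    Deterministic given ``config.seed`` (or an explicit ``rng``); per-score
    sample means converge to ``config.feature_means`` as n grows.
    """
    config = config or default_paper_config()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for score, n in zip(SCORES, config.n_per_score):
        z = _latent_draws(n, config, rng)
        feats = _features_from_latent(z, score, config)
        block = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
        block["score"] = score
        rows.append(block)
    cohort = pd.concat(rows, ignore_index=True)
    cohort.insert(0, "cow_id", [f"cow_{i:04d}" for i in range(len(cohort))])
    return cohort


# ---------------------------------------------------------------------------
# mechanistic gait parameters
# ---------------------------------------------------------------------------

#: Footfall phases of the bovine walk LH-LF-RH-RF (fractions of a stride).
FOOTFALL_PHASE = {"hoof_HL": 0.0, "hoof_FL": 0.25, "hoof_HR": 0.5, "hoof_FR": 0.75}

_WITHERS_HEIGHT_CM = 140.0
_HEAD_HEIGHT_CM = 110.0
_HEAD_FORWARD_CM = 80.0
_BACK_CHORD_CM = 90.0
_SWING_HEIGHT_CM = 8.0
_SWING_CLEARANCE_CM = 2.0  # the toe clears the ground throughout the swing
_FRONT_HOOF_OFFSET_CM = -10.0


@dataclass
class GaitParams:
    """Mechanistic ground truth for one synthetic walking bout.

    The implied six-feature vector is computable in closed form via
    :meth:`implied_features`; ``step_time_ms`` is the stride period shared
    by all four hooves (sustained per-hoof period differences would make
    the hooves drift apart, so the two-stride hoof-step-time feature equals
    ``2 * step_time_ms``).
    """

    speed_mps: float
    stride_length_cm: float
    stance_fraction: dict[str, float]          # per hoof, (0, 1)
    stance_asymmetry_ms: float                 # hind contralateral difference
    step_overlap_cm: tuple[float, float]       # (left, right)
    back_arch_curvature: float                 # cm^-1
    head_bob_amplitude_cm: float               # peak-to-trough
    step_time_ms: float                        # stride period

    def validate(self) -> None:
        if self.speed_mps <= 0:
            raise ConfigError("speed must be positive")
        if self.stride_length_cm <= 0:
            raise ConfigError("stride length must be positive")
        if self.step_time_ms <= 0:
            raise ConfigError("step time must be positive")
        for hoof in HOOVES:
            frac = self.stance_fraction.get(hoof)
            if frac is None or not 0 < frac < 1:
                raise ConfigError(f"stance fraction for {hoof} must lie in (0, 1)")
        if self.back_arch_curvature < 0:
            raise ConfigError("curvature must be non-negative")
        if self.head_bob_amplitude_cm < 0:
            raise ConfigError("head-bob amplitude must be non-negative")

    def stance_duration_ms(self, hoof: str) -> float:
        return self.stance_fraction[hoof] * self.step_time_ms

    def implied_features(self) -> FeatureVector:
        d = {h: self.stance_duration_ms(h) for h in HOOVES}
        supporting = max(
            abs(d["hoof_FL"] - d["hoof_FR"]), abs(d["hoof_HL"] - d["hoof_HR"])
        )
        return FeatureVector(
            back_arch=self.back_arch_curvature,
            head_bob_cm=self.head_bob_amplitude_cm,
            speed_mps=self.speed_mps,
            step_overlap_cm=max(self.step_overlap_cm),
            supporting_phase_ms=supporting,
            hoof_step_time_ms=2.0 * self.step_time_ms,
        )


def sample_gait_parameters(
    score: int, config: GeneratorConfig | None = None, rng: np.random.Generator | None = None
) -> GaitParams:
    """Draw mechanistic gait parameters for one cow of a given score.

    The class-conditional feature draw is mapped to :class:`GaitParams` so
    that ``implied_features()`` reproduces the draw exactly, after clipping
    to mechanically realisable ranges (stride period 250-1500 ms so a
    5-10 s clip covers >= 3 cycles, stance asymmetry bounded by available
    stance time, speed 0.5-5 m/s, |step overlap| <= 40 cm).
    """
    if score not in SCORES:
        raise ConfigError(f"score must be one of {SCORES}, got {score}")
    config = config or default_paper_config()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    z = _latent_draws(1, config, rng)
    draw = _features_from_latent(z, score, config)[0]
    feats = dict(zip(FEATURE_NAMES, draw))
    return gait_params_from_features(feats)


def gait_params_from_features(feats: dict[str, float]) -> GaitParams:
    """Closed-form map from a six-feature draw to realisable gait parameters."""
    # stride period bounded so that a 5-10 s clip always covers >= 3 cycles
    step_time = min(max(feats["hoof_step_time_ms"], 500.0), 3000.0) / 2.0
    speed = min(max(feats["speed_mps"], 0.5), 5.0)
    stride = speed * step_time / 10.0  # cm: m/s * ms -> cm

    base_frac = 0.6
    d_min = 120.0  # shortest realisable stance, safely detectable at 50 fps
    d_max = step_time - max(100.0, 0.15 * step_time)
    asym = min(max(feats["supporting_phase_ms"], 0.0), d_max - d_min)
    d_hl = min(base_frac * step_time + asym / 2.0, d_max)
    if d_hl - asym < d_min:
        d_hl = d_min + asym
    d_hr = d_hl - asym
    d_front = min(base_frac * step_time, d_max)
    fractions = {
        "hoof_FL": d_front / step_time,
        "hoof_FR": d_front / step_time,
        "hoof_HL": d_hl / step_time,
        "hoof_HR": d_hr / step_time,
    }

    overlap = min(max(feats["step_overlap_cm"], -40.0), 40.0)
    return GaitParams(
        speed_mps=speed,
        stride_length_cm=stride,
        stance_fraction=fractions,
        stance_asymmetry_ms=asym,
        step_overlap_cm=(overlap, overlap - 3.0),
        back_arch_curvature=max(feats["back_arch"], 0.0),
        head_bob_amplitude_cm=max(feats["head_bob_cm"], 0.0),
        step_time_ms=step_time,
    )


# ---------------------------------------------------------------------------
# trajectory synthesis
# ---------------------------------------------------------------------------

@dataclass
class SynthesisResult:
    """A synthetic trajectory with its ground truth."""

    trajectory: Trajectory
    events: dict[str, list[tuple[float, float, float]]]  # (t_land_ms, t_lift_ms, x_cm)
    features: FeatureVector
    params: GaitParams


def _sagitta(curvature: float, chord: float) -> float:
    if curvature == 0:
        return 0.0
    radius = 1.0 / curvature
    half = chord / 2.0
    if radius <= half:
        raise ConfigError(
            f"curvature {curvature} too large for a {chord} cm back chord"
        )
    return radius - math.sqrt(radius**2 - half**2)


def synthesize_trajectory(
    params: GaitParams,
    duration_s: float,
    fps: float = 50.0,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    cow_id: str = "synthetic",
) -> SynthesisResult:
    """Render a keypoint trajectory realising ``params``.

    Frames are produced at exactly ``fps`` with all eight keypoints present
    (unless ``dropout_rate`` blanks some to exercise interpolation).
    Ground-truth stance events (complete stances within the clip) and the
    closed-form implied feature vector are returned alongside.
    """
    params.validate()
    T = params.step_time_ms / 1000.0
    if duration_s < T:
        raise ConfigError(
            f"duration {duration_s} s shorter than one stride cycle ({T:.3f} s)"
        )
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps
    v_cm = params.speed_mps * 100.0
    S = params.stride_length_cm

    data = pd.DataFrame(index=pd.RangeIndex(n_frames), columns=_columns(), dtype=float)

    # body line: withers advance at constant speed; back keypoints ride along
    x_withers = v_cm * t
    sag = _sagitta(params.back_arch_curvature, _BACK_CHORD_CM)
    data["withers_x"] = x_withers
    data["withers_y"] = _WITHERS_HEIGHT_CM
    data["tailhead_x"] = x_withers - _BACK_CHORD_CM
    data["tailhead_y"] = _WITHERS_HEIGHT_CM
    data["mid_back_x"] = x_withers - _BACK_CHORD_CM / 2.0
    data["mid_back_y"] = _WITHERS_HEIGHT_CM + sag

    # head: forward of the withers, bobbing at stride frequency
    data["head_x"] = x_withers + _HEAD_FORWARD_CM
    data["head_y"] = _HEAD_HEIGHT_CM + (
        params.head_bob_amplitude_cm / 2.0
    ) * np.sin(2.0 * math.pi * t / T)

    # hooves: footprint sequences tied to the front prints via step overlap
    dl, dr = params.step_overlap_cm
    x0 = {
        "hoof_FL": v_cm * 0.25 * T + _FRONT_HOOF_OFFSET_CM,
        "hoof_FR": v_cm * 0.75 * T + _FRONT_HOOF_OFFSET_CM,
    }
    x0["hoof_HL"] = x0["hoof_FL"] - S - dl
    x0["hoof_HR"] = x0["hoof_FR"] - S - dr

    events: dict[str, list[tuple[float, float, float]]] = {}
    for hoof in HOOVES:
        phase = FOOTFALL_PHASE[hoof]
        d_s = params.stance_duration_ms(hoof) / 1000.0
        rel = t / T - phase
        n_cyc = np.floor(rel)
        tau = (rel - n_cyc) * T
        footprint = x0[hoof] + n_cyc * S
        in_stance = tau < d_s
        p = np.clip((tau - d_s) / (T - d_s), 0.0, 1.0)
        smooth = p * p * (3.0 - 2.0 * p)
        data[f"{hoof}_x"] = np.where(in_stance, footprint, footprint + S * smooth)
        # swing height: clears the ground immediately at lift-off (real
        # hooves snap off the ground once the toe unloads) and peaks mid-swing
        swing_y = _SWING_CLEARANCE_CM + (
            _SWING_HEIGHT_CM - _SWING_CLEARANCE_CM
        ) * np.sin(math.pi * p)
        data[f"{hoof}_y"] = np.where(in_stance, 0.0, swing_y)

        hoof_events = []
        n_lo = int(math.floor(-phase)) - 1
        n_hi = int(math.ceil(duration_s / T - phase)) + 1
        for n in range(n_lo, n_hi + 1):
            t_land = (n + phase) * T
            t_lift = t_land + d_s
            if t_land >= 0.0 and t_lift <= duration_s:
                hoof_events.append(
                    (t_land * 1000.0, t_lift * 1000.0, x0[hoof] + n * S)
                )
        events[hoof] = hoof_events

    if dropout_rate > 0:
        if rng is None:
            rng = np.random.default_rng()
        from .gait_features import KEYPOINTS

        mask = rng.random((n_frames, len(KEYPOINTS))) < dropout_rate
        for j, kp in enumerate(KEYPOINTS):
            rows = np.flatnonzero(mask[:, j])
            data.loc[rows, [f"{kp}_x", f"{kp}_y"]] = np.nan

    traj = Trajectory(cow_id=cow_id, fps=fps, data=data)
    return SynthesisResult(
        trajectory=traj,
        events=events,
        features=params.implied_features(),
        params=params,
    )
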