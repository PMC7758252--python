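"""Random-dot stereogram sequences isolating the two binocular cues to motion in depth.

Three stimulus classes are generated as per-frame, per-eye dot tables:

* **CD** (changing disparity): binocularly paired dots, refreshed at every
  frame so that no monocular motion signal survives; the pair disparity
  follows a single linear ramp between ``+peak`` and ``-peak`` arcmin.
* **IOVD** (interocular velocity difference): unpaired dot fields per eye,
  drifting coherently with equal and opposite horizontal velocity in the two
  eyes; dots live for a fixed lifetime and are reborn at random positions.
  Each eye's dots are confined to alternating horizontal strips so that no
  spurious binocular matches arise.
* **STATIC**: disparity-fixed versions of the CD stimulus pinned at the near
  or far extreme (zero stereomotion velocity).

Disparity sign convention: positive = uncrossed (far), negative = crossed
(near).  TOWARD motion ramps far-to-near (``+peak`` to ``-peak``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "CueType",
    "Direction",
    "StimulusSpec",
    "StereoFrame",
    "StimulusSequence",
    "StimulusStats",
    "make_cd_sequence",
    "make_iovd_sequence",
    "make_static_sequence",
    "make_sequence",
    "sequence_stats",
    "write_sequence",
]

DOT_COLUMNS = ["dot_id", "x_deg", "y_deg", "polarity", "age", "contrast_weight"]


class CueType(str, Enum):
    CD = "CD"
    IOVD = "IOVD"
    STATIC = "STATIC"


class Direction(str, Enum):
    TOWARD = "TOWARD"
    AWAY = "AWAY"
    NEAR = "NEAR"
    FAR = "FAR"


_VALID_DIRECTIONS = {
    CueType.CD: {Direction.TOWARD, Direction.AWAY},
    CueType.IOVD: {Direction.TOWARD, Direction.AWAY},
    CueType.STATIC: {Direction.NEAR, Direction.FAR},
}


@dataclass
class StimulusSpec:
    """Geometry and dynamics of one stereomotion trial.

    Defaults: 250 ms probe at 60 frames/s per eye (15 frames), dots with a
    Gaussian profile (sigma 0.05 deg) at one dot per square degree inside a
    1-6 deg annulus, +/-32 arcmin peak disparity (CD/STATIC), +/-128 arcmin
    peak monocular displacement and 50 ms dot lifetime (IOVD).
    """

    cue_type: CueType
    direction: Direction
    duration_ms: float = 250.0
    eye_frame_rate_hz: float = 60.0
    annulus_inner_deg: float = 1.0
    annulus_outer_deg: float = 6.0
    dot_density_per_deg2: float = 1.0
    dot_sigma_deg: float = 0.05
    peak_disparity_arcmin: float = 32.0
    max_monocular_shift_arcmin: float = 128.0
    dot_lifetime_ms: float = 50.0
    strip_height_deg: float = 0.5
    contrast_ramp_deg: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.cue_type = CueType(self.cue_type)
        self.direction = Direction(self.direction)
        if self.annulus_inner_deg >= self.annulus_outer_deg:
            raise ConfigurationError("annulus_inner_deg must be < annulus_outer_deg")
        if self.duration_ms < 0 or self.eye_frame_rate_hz <= 0:
            raise ConfigurationError("duration and frame rate must be non-negative")
        nf = self.duration_ms * self.eye_frame_rate_hz / 1000.0
        if abs(nf - round(nf)) > 1e-9:
            raise ConfigurationError(
                f"duration_ms x eye_frame_rate_hz / 1000 = {nf} is not an integer frame count"
            )
        if self.direction not in _VALID_DIRECTIONS[self.cue_type]:
            raise ConfigurationError(
                f"direction {self.direction.value} invalid for cue {self.cue_type.value}"
            )
        if self.cue_type is CueType.IOVD and self.strip_height_deg <= 0:
            raise ConfigurationError("strip_height_deg must be > 0 for IOVD stimuli")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ms * self.eye_frame_rate_hz / 1000.0))

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.eye_frame_rate_hz

    @property
    def annulus_area_deg2(self) -> float:
        return math.pi * (self.annulus_outer_deg**2 - self.annulus_inner_deg**2)

    @property
    def n_dots(self) -> int:
        """Dots per eye per frame; fixed (not Poisson) so invariants are exact."""
        return int(round(self.dot_density_per_deg2 * self.annulus_area_deg2))

    @property
    def dot_width_deg(self) -> float:
        """Operational dot width: 4 sigma of the Gaussian profile."""
        return 4.0 * self.dot_sigma_deg

    @property
    def lifetime_frames(self) -> int:
        return max(1, int(round(self.dot_lifetime_ms / self.frame_period_ms)))


@dataclass
class StereoFrame:
    """One per-eye refresh: dot tables plus the frame's depth/velocity state."""

    frame_index: int
    left_dots: pd.DataFrame
    right_dots: pd.DataFrame
    disparity_arcmin: Optional[float] = None
    monocular_shift_arcmin: Optional[float] = None  # left-eye shift; right = -this


@dataclass
class StimulusSequence:
    spec: StimulusSpec
    frames: list[StereoFrame] = field(default_factory=list)
    ground_truth_ramp: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class StimulusStats:
    mean_disparity_arcmin: float
    peak_abs_disparity_arcmin: float
    max_monocular_shift_arcmin: float
    max_dot_age_ms: float
    dots_per_frame: int
    empirical_density: float
    strip_overlap_count: int


# ---------------------------------------------------------------------------
# geometry helpers


def _contrast_weight(r: np.ndarray, spec: StimulusSpec) -> np.ndarray:
    """Cosine contrast ramp over ``contrast_ramp_deg`` at both annulus edges."""
    ramp = spec.contrast_ramp_deg
    if ramp <= 0:
        return np.ones_like(r)
    inner, outer = spec.annulus_inner_deg, spec.annulus_outer_deg
    lo = np.clip((r - inner) / ramp, 0.0, 1.0)
    hi = np.clip((outer - r) / ramp, 0.0, 1.0)
    return 0.25 * (1 - np.cos(np.pi * lo)) * (1 - np.cos(np.pi * hi))


def _sample_annulus(rng: np.random.Generator, n: int, spec: StimulusSpec):
    """Uniform points in the annulus (area-uniform radial inversion)."""
    ri2, ro2 = spec.annulus_inner_deg**2, spec.annulus_outer_deg**2
    r = np.sqrt(rng.uniform(ri2, ro2, size=n))
    th = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return r * np.cos(th), r * np.sin(th)


def _in_annulus(x: np.ndarray, y: np.ndarray, spec: StimulusSpec) -> np.ndarray:
    r2 = x * x + y * y
    return (r2 >= spec.annulus_inner_deg**2 - 1e-12) & (
        r2 <= spec.annulus_outer_deg**2 + 1e-12
    )


def _balanced_polarity(rng: np.random.Generator, n: int) -> np.ndarray:
    pol = np.ones(n, dtype=np.int64)
    pol[n // 2 :] = -1
    rng.shuffle(pol)
    return pol


def _dot_frame(dot_id, x, y, polarity, age, spec) -> pd.DataFrame:
    r = np.hypot(x, y)
    return pd.DataFrame(
        {
            "dot_id": np.asarray(dot_id, dtype=np.int64),
            "x_deg": x,
            "y_deg": y,
            "polarity": np.asarray(polarity, dtype=np.int64),
            "age": np.asarray(age, dtype=np.int64),
            "contrast_weight": _contrast_weight(r, spec),
        }
    )


def _linear_ramp(start: float, end: float, n: int) -> np.ndarray:
    """Inclusive-endpoint linear ramp; antisymmetric values cancel exactly."""
    if n == 0:
        return np.zeros(0)
    if n == 1:
        return np.array([start])
    k = np.arange(n, dtype=float)
    if end == -start:
        # integer numerators so antisymmetric pairs cancel exactly (mean == 0)
        return start * (n - 1 - 2 * k) / (n - 1)
    return start + (end - start) * k / (n - 1)


# ---------------------------------------------------------------------------
# CD / STATIC


def _paired_frame(rng, spec: StimulusSpec, frame_index: int,
                  disparity_arcmin: float) -> StereoFrame:
    """Binocularly paired dots, fresh random positions, split disparity shift.

    Base positions are rejection-sampled so that *both* shifted monocular
    copies stay inside the annulus.
    """
    n = spec.n_dots
    dx = disparity_arcmin / 60.0 / 2.0  # per-eye shift in degrees
    xs = np.empty(0)
    ys = np.empty(0)
    while xs.size < n:
        m = max(2 * (n - xs.size), 16)
        x, y = _sample_annulus(rng, m, spec)
        ok = _in_annulus(x - dx, y, spec) & _in_annulus(x + dx, y, spec)
        xs = np.concatenate([xs, x[ok]])
        ys = np.concatenate([ys, y[ok]])
    xs, ys = xs[:n], ys[:n]
    pol = _balanced_polarity(rng, n)
    ids = np.arange(n)
    age = np.ones(n, dtype=np.int64)  # dots refresh every frame
    # right eye built as left + full disparity so undoing the shift is exact
    x_left = xs - dx
    x_right = x_left + disparity_arcmin / 60.0
    left = _dot_frame(ids, x_left, ys, pol, age, spec)
    right = _dot_frame(ids, x_right, ys, pol, age, spec)
    return StereoFrame(frame_index, left, right, disparity_arcmin=disparity_arcmin)


def make_cd_sequence(spec: StimulusSpec) -> StimulusSequence:
    """Changing-disparity stimulus: one full linear disparity ramp.

    TOWARD ramps +peak -> -peak (far to near); AWAY the reverse.  The
    stimulus-averaged disparity is exactly zero.
    """
    if spec.cue_type is not CueType.CD:
        raise ConfigurationError("make_cd_sequence requires cue_type=CD")
    rng = np.random.default_rng(spec.seed)
    peak = spec.peak_disparity_arcmin
    start, end = (peak, -peak) if spec.direction is Direction.TOWARD else (-peak, peak)
    ramp = _linear_ramp(start, end, spec.n_frames)
    frames = [_paired_frame(rng, spec, f, ramp[f]) for f in range(spec.n_frames)]
    return StimulusSequence(spec=spec, frames=frames, ground_truth_ramp=ramp)


def make_static_sequence(spec: StimulusSpec) -> StimulusSequence:
    """Dynamically refreshed dots pinned at the near (-peak) or far (+peak) extreme."""
    if spec.cue_type is not CueType.STATIC:
        raise ConfigurationError("make_static_sequence requires cue_type=STATIC")
    rng = np.random.default_rng(spec.seed)
    d = spec.peak_disparity_arcmin * (1.0 if spec.direction is Direction.FAR else -1.0)
    ramp = np.full(spec.n_frames, d)
    frames = [_paired_frame(rng, spec, f, d) for f in range(spec.n_frames)]
    return StimulusSequence(spec=spec, frames=frames, ground_truth_ramp=ramp)


# ---------------------------------------------------------------------------
# IOVD


def _strip_index(y: np.ndarray, spec: StimulusSpec) -> np.ndarray:
    """Horizontal strip index counted from the annulus bottom (-outer radius)."""
    return np.floor((y + spec.annulus_outer_deg) / spec.strip_height_deg).astype(np.int64)


def _eye_parity(eye: str) -> int:
    # left eye occupies even strips, right eye odd strips
    return 0 if eye == "left" else 1


def _sample_iovd_births(rng, n: int, spec: StimulusSpec, eye: str,
                        future_offsets: list[np.ndarray]):
    """Random birth positions within the eye's strips, inside the annulus,
    such that the dot's whole remaining trajectory stays inside the annulus.

    ``future_offsets[i]`` is the array of horizontal offsets (deg) that dot i
    will accumulate over each remaining frame of its lifetime.  All dots in a
    call share the same remaining-lifetime length, so a single offsets array
    is expected.
    """
    offs = future_offsets
    xs = np.empty(0)
    ys = np.empty(0)
    parity = _eye_parity(eye)
    while xs.size < n:
        m = max(4 * (n - xs.size), 32)
        x, y = _sample_annulus(rng, m, spec)
        ok = (_strip_index(y, spec) % 2) == parity
        for d in offs:
            ok &= _in_annulus(x + d, y, spec)
        xs = np.concatenate([xs, x[ok]])
        ys = np.concatenate([ys, y[ok]])
    return xs[:n], ys[:n]


def _apply_polarity_conflicts(left: pd.DataFrame, right: pd.DataFrame,
                              spec: StimulusSpec) -> int:
    """Disrupt spurious binocular matches near shared strip borders.

    When a left-eye dot and a right-eye dot both lie within one dot width of
    the same strip border and within one dot width of each other
    horizontally, the right-eye dot's polarity is flipped to be opposite the
    left-eye dot's (deterministic rule).  Returns the number of flips.
    """
    w = spec.dot_width_deg
    borders_l = np.round((left["y_deg"].to_numpy() + spec.annulus_outer_deg)
                         / spec.strip_height_deg)
    borders_r = np.round((right["y_deg"].to_numpy() + spec.annulus_outer_deg)
                         / spec.strip_height_deg)
    dist_l = np.abs(left["y_deg"].to_numpy() + spec.annulus_outer_deg
                    - borders_l * spec.strip_height_deg)
    dist_r = np.abs(right["y_deg"].to_numpy() + spec.annulus_outer_deg
                    - borders_r * spec.strip_height_deg)
    near_l = np.flatnonzero(dist_l < w)
    near_r = np.flatnonzero(dist_r < w)
    n_flips = 0
    pol_r = right["polarity"].to_numpy().copy()
    xl = left["x_deg"].to_numpy()
    xr = right["x_deg"].to_numpy()
    pol_l = left["polarity"].to_numpy()
    for i in near_l:
        for j in near_r:
            if borders_l[i] == borders_r[j] and abs(xl[i] - xr[j]) < w:
                if pol_r[j] != -pol_l[i]:
                    pol_r[j] = -pol_l[i]
                    n_flips += 1
    right["polarity"] = pol_r
    return n_flips


def make_iovd_sequence(spec: StimulusSpec) -> StimulusSequence:
    """Interocular-velocity-difference stimulus.

    Each eye sees an independent dot field drifting coherently; the monocular
    lateral shift follows a linear ramp from ``-max`` to ``+max`` arcmin for
    the left eye under TOWARD motion (mirrored in the right eye and for AWAY).
    Dots die in staggered cohorts after ``dot_lifetime_ms`` and are reborn at
    random positions within the eye's alternating horizontal strips.
    """
    if spec.cue_type is not CueType.IOVD:
        raise ConfigurationError("make_iovd_sequence requires cue_type=IOVD")
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    n = spec.n_dots
    life = spec.lifetime_frames
    mx = spec.max_monocular_shift_arcmin
    sgn = 1.0 if spec.direction is Direction.TOWARD else -1.0
    # left-eye coherent shift in arcmin per frame; right eye is the negative
    shift_l = sgn * _linear_ramp(-mx, mx, n_frames)
    shift_deg = shift_l / 60.0

    frames: list[StereoFrame] = []
    state: dict[str, dict[str, np.ndarray]] = {}
    for eye in ("left", "right"):
        eye_sgn = 1.0 if eye == "left" else -1.0
        if n_frames == 0:
            continue
        ages = (np.arange(n) % life) + 1  # staggered cohorts
        # remaining-lifetime horizontal offsets differ per age; sample per cohort
        xs = np.empty(n)
        ys = np.empty(n)
        for a in range(1, life + 1):
            idx = np.flatnonzero(ages == a)
            remain = min(life - a, n_frames - 1)
            offs = [eye_sgn * (shift_deg[g] - shift_deg[0]) for g in range(remain + 1)]
            x, y = _sample_iovd_births(rng, idx.size, spec, eye, offs)
            xs[idx], ys[idx] = x, y
        state[eye] = {
            "x": xs, "y": ys, "age": ages,
            "pol": _balanced_polarity(rng, n), "ids": np.arange(n),
        }

    for f in range(n_frames):
        frame_dots = {}
        for eye in ("left", "right"):
            st = state[eye]
            eye_sgn = 1.0 if eye == "left" else -1.0
            if f > 0:
                delta = eye_sgn * (shift_deg[f] - shift_deg[f - 1])
                st["age"] = st["age"] + 1
                st["x"] = st["x"] + delta
                dead = np.flatnonzero(st["age"] > life)
                if dead.size:
                    remain = min(life - 1, n_frames - 1 - f)
                    offs = [eye_sgn * (shift_deg[g] - shift_deg[f])
                            for g in range(f, f + remain + 1)]
                    x, y = _sample_iovd_births(rng, dead.size, spec, eye, offs)
                    st["x"][dead], st["y"][dead] = x, y
                    st["age"][dead] = 1
            frame_dots[eye] = _dot_frame(
                st["ids"], st["x"].copy(), st["y"].copy(), st["pol"].copy(),
                st["age"].copy(), spec,
            )
        _apply_polarity_conflicts(frame_dots["left"], frame_dots["right"], spec)
        frames.append(
            StereoFrame(
                f, frame_dots["left"], frame_dots["right"],
                monocular_shift_arcmin=shift_l[f],
            )
        )
    return StimulusSequence(spec=spec, frames=frames, ground_truth_ramp=shift_l)


_MAKERS = {
    CueType.CD: make_cd_sequence,
    CueType.IOVD: make_iovd_sequence,
    CueType.STATIC: make_static_sequence,
}


def make_sequence(spec: StimulusSpec) -> StimulusSequence:
    """Dispatch to the maker for ``spec.cue_type``."""
    return _MAKERS[spec.cue_type](spec)


# ---------------------------------------------------------------------------
# validation / IO


def sequence_stats(seq: StimulusSequence) -> StimulusStats:
    """Summary statistics surfacing the sequence's defining constants."""
    if len(seq) == 0:
        raise ValidationError("sequence_stats requires a non-empty sequence")
    spec = seq.spec
    disparities = np.array([f.disparity_arcmin for f in seq.frames
                            if f.disparity_arcmin is not None], dtype=float)
    if disparities.size:
        # compensated summation: exactly-antisymmetric ramps average to 0.0
        mean_disp = math.fsum(disparities) / disparities.size
        peak_disp = float(np.abs(disparities).max())
        max_shift = peak_disp / 2.0  # per-eye half-shift of the pair
    else:
        mean_disp = math.nan
        peak_disp = math.nan
        max_shift = float(max(abs(f.monocular_shift_arcmin) for f in seq.frames))
    max_age = max(
        int(max(f.left_dots["age"].max(), f.right_dots["age"].max()))
        for f in seq.frames
    )
    overlap = 0
    if spec.cue_type is CueType.IOVD:
        for f in seq.frames:
            sl = set(_strip_index(f.left_dots["y_deg"].to_numpy(), spec).tolist())
            sr = set(_strip_index(f.right_dots["y_deg"].to_numpy(), spec).tolist())
            overlap += len(sl & sr)
    n_dots = int(len(seq.frames[0].left_dots))
    return StimulusStats(
        mean_disparity_arcmin=mean_disp,
        peak_abs_disparity_arcmin=peak_disp,
        max_monocular_shift_arcmin=max_shift,
        max_dot_age_ms=max_age * spec.frame_period_ms,
        dots_per_frame=n_dots,
        empirical_density=n_dots / spec.annulus_area_deg2,
        strip_overlap_count=overlap,
    )


def sequence_to_table(seq: StimulusSequence) -> pd.DataFrame:
    rows = []
    for fr in seq.frames:
        for eye, dots in (("left", fr.left_dots), ("right", fr.right_dots)):
            d = dots.copy()
            d.insert(0, "eye", eye)
            d.insert(0, "frame", fr.frame_index)
            rows.append(d)
    if not rows:
        return pd.DataFrame(columns=["frame", "eye"] + DOT_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def write_sequence(seq: StimulusSequence, out_dir: str | Path, stem: str = "stimulus") -> Path:
    """Write one CSV of dot tables plus a JSON sidecar echoing the StimulusSpec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    sequence_to_table(seq).to_csv(csv_path, index=False)
    spec_dict = asdict(seq.spec)
    spec_dict["cue_type"] = seq.spec.cue_type.value
    spec_dict["direction"] = seq.spec.direction.value
    sidecar = {
        "spec": spec_dict,
        "ground_truth_ramp": np.asarray(seq.ground_truth_ramp).tolist(),
        "n_frames": len(seq),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return csv_path
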