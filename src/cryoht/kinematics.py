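"""CASA-style kinematics: velocities, straightness, motility classes.

A track is a uniformly sampled 2D position sequence (µm, frames/s).  The
standard velocity triple is

* VCL — curvilinear velocity: summed step lengths over duration;
* VSL — straight-line velocity: first-to-last displacement over duration;
* VAP — average-path velocity: length of the smoothed path over duration.

Path smoothing uses a centred moving average (default 5 frames) whose
half-width shrinks symmetrically at the ends, so the smoothed path keeps the
original endpoints and VSL ≤ VAP holds exactly; VAP ≤ VCL holds because
averaging contracts the path.  STR = VSL/VAP × 100.

Motility classes follow the standard thresholds: tracks with an average
(path) velocity below 10 µm/s are immotile; progressive tracks need VAP
above 30 µm/s and straightness above 80%.  Which velocity stands in for the
"average velocity" of the immotile rule is a configuration knob (VAP by
default, the SCA convention).

:func:`simulate_tracks` provides a persistent-random-walk population
simulator with a three-class mixture, emitting ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "SpermTrack",
    "KinematicSummary",
    "MotilityThresholds",
    "TrackClassParams",
    "TrackMixture",
    "vcl",
    "vsl",
    "vap",
    "straightness",
    "classify_track",
    "summarize",
    "simulate_tracks",
]

MotilityClass = Literal["immotile", "motile", "progressive"]


@dataclass
class SpermTrack:
    """A time-ordered 2D position sequence at a uniform frame interval."""

    positions: np.ndarray  # (n, 2) in µm
    fps: float
    track_id: object = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError("positions must be an (n, 2) array of µm coordinates")
        if len(self.positions) < 2:
            raise ValidationError("a track needs at least 2 points")
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")

    @property
    def duration(self) -> float:
        """Track duration in seconds ((n−1) frame intervals)."""
        return (len(self.positions) - 1) / self.fps


@dataclass(frozen=True)
class MotilityThresholds:
    """Classification thresholds; defaults are the standard CASA settings."""

    immotile_velocity: float = 10.0     # µm/s, below → immotile
    progressive_velocity: float = 30.0  # µm/s VAP, above → progressive (with STR)
    progressive_str: float = 80.0       # %, above → progressive
    immotile_measure: Literal["vap", "vcl"] = "vap"


@dataclass(frozen=True)
class KinematicSummary:
    """Population-level motility statistics."""

    tm: float        # total motility, %
    pm: float        # progressive motility, %
    mean_vcl: float  # µm/s, over motile tracks
    mean_vsl: float
    mean_vap: float
    n_tracks: int


def _path_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def vcl(track: SpermTrack) -> float:
    """Curvilinear velocity (µm/s): total step length / duration."""
    return _path_length(track.positions) / track.duration


def vsl(track: SpermTrack) -> float:
    """Straight-line velocity (µm/s): net displacement / duration."""
    return float(np.linalg.norm(track.positions[-1] - track.positions[0])) / track.duration


def _smooth_path(points: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with a symmetrically shrinking window.

    At index i the half-width is min(window//2, i, n−1−i), so the endpoints
    are untouched and the average stays centred everywhere.
    """
    n = len(points)
    half = window // 2
    out = np.empty_like(points)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = points[i - h: i + h + 1].mean(axis=0)
    return out


def vap(track: SpermTrack, window: int = 5) -> float:
    """Average-path velocity (µm/s): smoothed path length / duration."""
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"smoothing window must be an odd integer >= 1, got {window}")
    return _path_length(_smooth_path(track.positions, window)) / track.duration


def straightness(track: SpermTrack, window: int = 5) -> float:
    """STR = VSL/VAP × 100 (%).  Raises if VAP is zero (degenerate path)."""
    v_ap = vap(track, window)
    if v_ap == 0:
        raise ValidationError("straightness undefined: VAP is zero")
    return vsl(track) / v_ap * 100.0


def classify_track(track: SpermTrack,
                   thresholds: MotilityThresholds | None = None,
                   window: int = 5) -> MotilityClass:
    """Assign immotile / motile / progressive by the threshold rule.

    A track whose average velocity (VAP by default) is below the immotile
    threshold — or whose VAP is exactly zero, leaving STR undefined — is
    immotile.  Progressive requires VAP above the progressive velocity
    threshold and STR above the straightness threshold; everything else is
    motile but non-progressive.
    """
    thresholds = thresholds or MotilityThresholds()
    v_ap = vap(track, window)
    avg = vcl(track) if thresholds.immotile_measure == "vcl" else v_ap
    if avg < thresholds.immotile_velocity or v_ap == 0:
        return "immotile"
    str_pct = vsl(track) / v_ap * 100.0
    if v_ap > thresholds.progressive_velocity and str_pct > thresholds.progressive_str:
        return "progressive"
    return "motile"


def summarize(tracks: Sequence[SpermTrack],
              thresholds: MotilityThresholds | None = None,
              window: int = 5) -> KinematicSummary:
    """Population summary: TM/PM percentages and velocity means.

    TM is the percentage of non-immotile tracks, PM the percentage of
    progressive ones; velocity means are taken over motile (non-immotile)
    tracks, as CASA reports them.  With no motile track the means are 0.
    """
    if len(tracks) == 0:
        raise ValidationError("cannot summarize an empty track collection")
    thresholds = thresholds or MotilityThresholds()
    classes = [classify_track(t, thresholds, window) for t in tracks]
    motile = [t for t, c in zip(tracks, classes) if c != "immotile"]
    n = len(tracks)
    if motile:
        means = (
            float(np.mean([vcl(t) for t in motile])),
            float(np.mean([vsl(t) for t in motile])),
            float(np.mean([vap(t, window) for t in motile])),
        )
    else:
        means = (0.0, 0.0, 0.0)
    return KinematicSummary(
        tm=100.0 * len(motile) / n,
        pm=100.0 * sum(c == "progressive" for c in classes) / n,
        mean_vcl=means[0], mean_vsl=means[1], mean_vap=means[2],
        n_tracks=n,
    )


# ---------------------------------------------------------------------------
# track simulation


@dataclass(frozen=True)
class TrackClassParams:
    """Per-class persistent-random-walk parameters.

    ``speed_mean``/``speed_sd`` (µm/s) set the per-track swimming speed;
    ``turn_sd`` (radians/frame) sets heading diffusion; ``jitter_sd`` (µm)
    adds positional noise per frame.
    """

    speed_mean: float
    speed_sd: float = 0.0
    turn_sd: float = 0.0
    jitter_sd: float = 0.0


#: Default, well-separated class mixture: mostly progressive swimmers, some
#: erratic (motile non-progressive) cells, some immotile cells that only
#: jitter in place.
DEFAULT_CLASSES: dict[str, TrackClassParams] = {
    "progressive": TrackClassParams(speed_mean=45.0, speed_sd=8.0, turn_sd=0.12,
                                    jitter_sd=0.05),
    "motile": TrackClassParams(speed_mean=30.0, speed_sd=4.0, turn_sd=0.9,
                               jitter_sd=0.05),
    "immotile": TrackClassParams(speed_mean=0.0, speed_sd=0.0, turn_sd=0.0,
                                 jitter_sd=0.08),
}


@dataclass(frozen=True)
class TrackMixture:
    """Class mixture weights plus per-class walk parameters."""

    weights: dict[str, float] = field(
        default_factory=lambda: {"progressive": 0.25, "motile": 0.60, "immotile": 0.15}
    )
    classes: dict[str, TrackClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"mixture weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("mixture weights must be non-negative")
        missing = set(self.weights) - set(self.classes)
        if missing:
            raise ValidationError(f"no walk parameters for classes {sorted(missing)}")


@dataclass(frozen=True)
class TrackSimResult:
    tracks: list[SpermTrack]
    labels: list[str]  # generative ground-truth class per track


def simulate_tracks(mixture: TrackMixture | None = None, n: int = 1000,
                    fps: float = 25.0, duration: float = 1.0,
                    seed: int = 0) -> TrackSimResult:
    """Simulate a track population as persistent random walks.

    Each track draws a class from the mixture, a speed from the class
    distribution (truncated at 0), and evolves a heading by Gaussian turning
    noise per frame; immotile cells only jitter around their origin.
    Deterministic for a fixed seed.
    """
    mixture = mixture or TrackMixture()
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = sorted(mixture.weights)
    probs = np.array([mixture.weights[k] for k in names])
    n_frames = max(2, int(round(duration * fps)) + 1)
    dt = 1.0 / fps

    tracks, labels = [], []
    for i in range(n):
        label = names[rng.choice(len(names), p=probs)]
        p = mixture.classes[label]
        speed = max(0.0, rng.normal(p.speed_mean, p.speed_sd)) if p.speed_sd > 0 else p.speed_mean
        pos = np.zeros((n_frames, 2))
        if speed > 0:
            theta = rng.uniform(0, 2 * np.pi)
            turns = rng.normal(0.0, p.turn_sd, n_frames - 1) if p.turn_sd > 0 else np.zeros(n_frames - 1)
            headings = theta + np.concatenate(([0.0], np.cumsum(turns[:-1])))
            steps = speed * dt * np.column_stack([np.cos(headings), np.sin(headings)])
            pos[1:] = np.cumsum(steps, axis=0)
        if p.jitter_sd > 0:
            pos = pos + rng.normal(0.0, p.jitter_sd, pos.shape)
        tracks.append(SpermTrack(positions=pos, fps=fps, track_id=i))
        labels.append(label)
    return TrackSimResult(tracks=tracks, labels=labels)
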