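"""Trial and session assembly for the cueing experiments.

Two stimulus geometries are supported:

* an eccentricity design — circular noise field, signal placed at a given
  radial distance from fixation with a uniformly random polar angle, with or
  without a preceding colour cue at the signal location;
* a horizontal-position design — a short, wide rectangular noise field with
  the signal at one of several fixed horizontal offsets, optionally with
  task-irrelevant ring outlines ("frames") overlaid on the field.

A session is a fully seeded, balanced crossing of the randomized factors
(condition x location x filter width x tilt); every trial is reproducible
from its own seed, and the whole session from the master seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dynamics import (
    FrameSequence,
    KeyframeStream,
    build_dynamic_stimulus,
    seconds_to_frames,
)
from .embedding import WindowSpec
from .orientation import OrientationFilterSpec

__all__ = [
    "ConfigError",
    "SessionConfig",
    "TrialSpec",
    "place_signal",
    "build_trial",
    "generate_session",
    "build_frames_overlay",
    "apply_overlay",
    "CUE_RGB",
]

#: Pink cue colour (RGB, 8 bit) used by the export layer.
CUE_RGB = (204, 0, 102)


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid session config:\n  - " + "\n  - ".join(self.problems))


@dataclasses.dataclass
class SessionConfig:
    """Everything needed to build a session of trials.

    Geometry is in degrees of visual angle; ``ppd`` (pixels per degree) maps
    it onto the pixel grid.  Noise frames update at ``update_rate_hz`` while
    the display refreshes at ``refresh_rate_hz``; each unique frame is shown
    ``repeat_factor`` times.  Exactly one of ``eccentricities`` /
    ``positions`` selects the placement mode.
    """

    ppd: float
    field_shape: str  # "circular" | "rectangular"
    window_r_deg: float
    window_w_deg: float
    sigmas: Sequence[float]
    trials_per_cell: int
    master_seed: int
    schema_version: int = 1
    refresh_rate_hz: float = 120.0
    update_rate_hz: float = 60.0
    n_steps: int = 4
    field_radius_deg: Optional[float] = None
    field_ramp_deg: float = 0.0
    field_height_deg: Optional[float] = None
    field_width_deg: Optional[float] = None
    mean_luminance: float = 0.5
    contrast: float = 0.2
    fixation_range_ms: Tuple[float, float] = (400.0, 800.0)
    cue_frames: int = 4
    cue_delay_ms: float = 100.0
    signal_frames: Optional[int] = None
    signal_ms: Optional[float] = 50.0
    mask_range_ms: Tuple[float, float] = (500.0, 500.0)
    tilts: Sequence[float] = (40.0, -40.0)
    conditions: Sequence[str] = ("cued", "uncued")
    eccentricities: Optional[Sequence[float]] = None
    positions: Optional[Sequence[float]] = None
    frames_overlay: Optional[dict] = None

    # -- derived geometry ---------------------------------------------------

    @property
    def repeat_factor(self) -> int:
        return int(round(self.refresh_rate_hz / self.update_rate_hz))

    def frame_shape(self) -> Tuple[int, int]:
        """Noise-array dimensions (rows, cols) in pixels; sides kept even."""

        def even(v: float) -> int:
            return max(2, int(math.ceil(v / 2.0)) * 2)

        if self.field_shape == "circular":
            side = even(2 * self.field_radius_deg * self.ppd)
            return side, side
        return (
            even(self.field_height_deg * self.ppd),
            even(self.field_width_deg * self.ppd),
        )

    def signal_n_frames(self) -> int:
        if self.signal_frames is not None:
            return self.signal_frames
        return seconds_to_frames(
            self.signal_ms / 1000.0, self.update_rate_hz, "signal duration"
        )

    # -- validation ---------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "SessionConfig":
        """Validated construction; collects *all* problems before raising."""
        problems: List[str] = []
        known = {f.name for f in dataclasses.fields(cls)}
        ms_aliases = {"cue_ms": "cue_frames"}
        data = dict(data)
        for key in sorted(set(data) - known - set(ms_aliases)):
            problems.append(f"unknown field: {key}")
            data.pop(key)
        if data.get("schema_version", 1) != 1:
            problems.append(
                f"unsupported schema_version {data['schema_version']} (supported: 1)"
            )
        # millisecond alias for the cue, quantized against the update rate
        if "cue_ms" in data:
            try:
                data["cue_frames"] = seconds_to_frames(
                    data.pop("cue_ms") / 1000.0,
                    data.get("update_rate_hz", 60.0),
                    "cue duration",
                )
            except ValueError as exc:
                problems.append(str(exc))
        missing = [
            f.name
            for f in dataclasses.fields(cls)
            if f.default is dataclasses.MISSING
            and f.default_factory is dataclasses.MISSING
            and f.name not in data
        ]
        problems.extend(f"missing required field: {name}" for name in missing)
        if problems and missing:
            raise ConfigError(problems)
        config = cls(**data)
        problems.extend(config.validate())
        if problems:
            raise ConfigError(problems)
        return config

    def validate(self) -> List[str]:
        problems: List[str] = []
        if self.ppd <= 0:
            problems.append("ppd must be positive")
        if self.field_shape not in ("circular", "rectangular"):
            problems.append(
                f"field_shape must be 'circular' or 'rectangular', got {self.field_shape!r}"
            )
        elif self.field_shape == "circular":
            if not self.field_radius_deg or self.field_radius_deg <= 0:
                problems.append("circular fields need field_radius_deg > 0")
        else:
            if not self.field_height_deg or not self.field_width_deg:
                problems.append(
                    "rectangular fields need field_height_deg and field_width_deg"
                )
        ratio = self.refresh_rate_hz / self.update_rate_hz
        if abs(ratio - round(ratio)) > 1e-9:
            problems.append(
                "refresh_rate_hz must be an integer multiple of update_rate_hz"
            )
        if (self.eccentricities is None) == (self.positions is None):
            problems.append("exactly one of eccentricities / positions must be given")
        if list(self.sigmas) != sorted(set(self.sigmas)) and list(self.sigmas) != sorted(
            set(self.sigmas), reverse=True
        ):
            problems.append("sigma ladder must be strictly monotone")
        for name in ("cue_delay_ms",):
            try:
                seconds_to_frames(getattr(self, name) / 1000.0, self.update_rate_hz, name)
            except ValueError as exc:
                problems.append(str(exc))
        if self.signal_frames is None and self.signal_ms is not None:
            try:
                seconds_to_frames(
                    self.signal_ms / 1000.0, self.update_rate_hz, "signal duration"
                )
            except ValueError as exc:
                problems.append(str(exc))
        elif self.signal_frames is None:
            problems.append("one of signal_frames / signal_ms is required")
        for lo, hi, name in (
            (*self.fixation_range_ms, "fixation_range_ms"),
            (*self.mask_range_ms, "mask_range_ms"),
        ):
            if lo > hi or lo < 0:
                problems.append(f"{name} must be a valid (lo, hi) range")
        if self.trials_per_cell < 1:
            problems.append("trials_per_cell must be >= 1")
        return problems


@dataclasses.dataclass(frozen=True)
class TrialSpec:
    """One trial of the session: condition, location, signal, and seed."""

    condition: str
    sigma: float
    tilt: float
    seed: int
    eccentricity: Optional[float] = None
    position: Optional[float] = None

    def __post_init__(self):
        if self.condition not in ("cued", "uncued"):
            raise ValueError(f"condition must be cued/uncued, got {self.condition!r}")
        if (self.eccentricity is None) == (self.position is None):
            raise ValueError("exactly one of eccentricity / position per trial")


def _trial_rngs(seed: int):
    """Named per-trial RNG substreams: noise, placement, timing jitter."""
    noise, placement, jitter = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(noise),
        np.random.default_rng(placement),
        np.random.default_rng(jitter),
    )


def place_signal(trial: TrialSpec, config: SessionConfig) -> WindowSpec:
    """Window centre for a trial, in degrees relative to the field centre.

    Eccentricity mode draws a uniform polar angle under the trial seed;
    position mode places the centre on the horizontal midline.  Placements
    whose window would not fit the field are an error.
    """
    r, w = config.window_r_deg, config.window_w_deg
    if trial.eccentricity is not None:
        ecc = trial.eccentricity
        if config.field_shape != "circular":
            raise ValueError("eccentricity placement needs a circular field")
        if ecc + r + w > config.field_radius_deg + 1e-9:
            raise ValueError(
                f"eccentricity {ecc} deg pushes the window support "
                f"({ecc + r + w:.3f} deg) outside the {config.field_radius_deg} deg field"
            )
        if ecc == 0:
            cx = cy = 0.0
        else:
            _, placement, _ = _trial_rngs(trial.seed)
            theta = placement.uniform(0.0, 2.0 * np.pi)
            cx, cy = ecc * np.cos(theta), ecc * np.sin(theta)
    else:
        pos = trial.position
        if config.field_shape != "rectangular":
            raise ValueError("position placement needs a rectangular field")
        if abs(pos) + r + w > config.field_width_deg / 2 + 1e-9:
            raise ValueError(
                f"position {pos} deg pushes the window support outside the "
                f"{config.field_width_deg} deg wide field"
            )
        cx, cy = float(pos), 0.0
    return WindowSpec(r=r, w=w, center_x=cx, center_y=cy)


def _quantize_ms(ms: float, rate: float, minimum: int = 1) -> int:
    return max(minimum, int(round(ms / 1000.0 * rate)))


def build_trial(trial: TrialSpec, config: SessionConfig):
    """Build one trial's movie and its ground-truth record.

    Timeline (in update frames): fixation (jittered, quantized) -> cue
    period (annotated only on cued trials; uncued trials simply wait) ->
    delay -> signal -> mask.  Cued and uncued trials with the same seed share
    identical grayscale frames; the cue is an export-layer overlay.
    """
    rate = config.update_rate_hz
    noise_rng, _, jitter_rng = _trial_rngs(trial.seed)
    fixation_ms = jitter_rng.uniform(*config.fixation_range_ms)
    mask_ms = jitter_rng.uniform(*config.mask_range_ms)
    fix_f = _quantize_ms(fixation_ms, rate)
    cue_f = config.cue_frames
    delay_f = seconds_to_frames(config.cue_delay_ms / 1000.0, rate, "cue delay")
    sig_f = config.signal_n_frames()
    mask_f = _quantize_ms(mask_ms, rate)
    total = fix_f + cue_f + delay_f + sig_f + mask_f
    height, width = config.frame_shape()
    n_keyframes = math.ceil((total - 1) / config.n_steps) + 1
    stream = KeyframeStream.generate(
        n_keyframes,
        height,
        width,
        seed=int(noise_rng.integers(2**31)),
        mean_luminance=config.mean_luminance,
        contrast=config.contrast,
        n_steps=config.n_steps,
        update_rate=rate,
    )
    window = place_signal(trial, config)
    spec = OrientationFilterSpec(phi0=trial.tilt, sigma=trial.sigma)
    onset_f = fix_f + cue_f + delay_f
    cue_kwargs = {}
    if trial.condition == "cued":
        cue_kwargs = {"cue_onset": fix_f / rate, "cue_duration": cue_f / rate}
    seq = build_dynamic_stimulus(
        stream,
        signal_spec=spec,
        window=window,
        signal_onset=onset_f / rate,
        signal_duration=sig_f / rate,
        ppd=config.ppd,
        require_support=config.field_shape == "circular",
        **cue_kwargs,
    )
    seq.frames = seq.frames[:total]
    seq.meta.update(
        repeat_factor=config.repeat_factor,
        condition=trial.condition,
        cue_rgb=CUE_RGB,
        cue_window=window if trial.condition == "cued" else None,
        field_shape=config.field_shape,
    )
    record = {
        "condition": trial.condition,
        "tilt": trial.tilt,
        "sigma": trial.sigma,
        "eccentricity": trial.eccentricity,
        "position": trial.position,
        "center_x_deg": window.center_x,
        "center_y_deg": window.center_y,
        "fixation_ms": fix_f / rate * 1000.0,
        "signal_on_frame": onset_f,
        "signal_off_frame": onset_f + sig_f,
        "seed": trial.seed,
    }
    return seq, record


def generate_session(config: SessionConfig) -> List[TrialSpec]:
    """Balanced, shuffled, seeded trial list for a whole session.

    The full crossing of condition x location x sigma x tilt appears exactly
    ``trials_per_cell`` times; order and per-trial seeds come from the
    master seed.
    """
    locations = (
        [("eccentricity", e) for e in config.eccentricities]
        if config.eccentricities is not None
        else [("position", p) for p in config.positions]
    )
    cells = list(
        itertools.product(config.conditions, locations, config.sigmas, config.tilts)
    )
    cells = cells * config.trials_per_cell
    rng = np.random.default_rng(config.master_seed)
    rng.shuffle(cells)
    seeds = rng.integers(2**31, size=len(cells))
    trials = []
    for (condition, (mode, value), sigma, tilt), seed in zip(cells, seeds):
        trials.append(
            TrialSpec(
                condition=condition,
                sigma=float(sigma),
                tilt=float(tilt),
                seed=int(seed),
                **{mode: float(value)},
            )
        )
    return trials


def build_frames_overlay(
    positions: Sequence[float],
    radius: float,
    ppd: float,
    shape: Tuple[int, int],
    stroke_px: float = 1.0,
) -> np.ndarray:
    """Boolean mask of ring outlines on the horizontal midline.

    Rings of the given radius (degrees) centred at the stated horizontal
    offsets; stroke width in pixels.  Pixels strictly outside the strokes are
    untouched when the overlay is applied.
    """
    height, width = shape
    y = np.arange(height, dtype=float)[:, None]
    x = np.arange(width, dtype=float)[None, :]
    cy = (height - 1) / 2.0
    mask = np.zeros(shape, dtype=bool)
    r_px = radius * ppd
    for pos in positions:
        cx = (width - 1) / 2.0 + pos * ppd
        if cx - r_px < 0 or cx + r_px > width - 1:
            raise ValueError(f"ring at {pos} deg does not fit the field")
        d = np.hypot(x - cx, y - cy)
        mask |= np.abs(d - r_px) <= stroke_px / 2.0
    return mask


def apply_overlay(pixels: np.ndarray, mask: np.ndarray, luminance: float = 0.0) -> np.ndarray:
    """Paint the overlay mask at a fixed luminance (dark outlines by default)."""
    out = pixels.copy()
    out[mask] = luminance
    return out
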