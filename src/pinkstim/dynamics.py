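"""Dynamic stimulus movies: keyframes, hybrid frames, and signal intervals.

The movie changes gradually from one pink-noise keyframe to the next through
"hybrid" frames — pixelwise mixtures whose image statistics (mean luminance,
RMS contrast) are re-adjusted to the keyframe targets, so no frame flickers
in brightness or contrast.  A transition of ``n_steps`` from keyframe A to B
emits mixtures with B-weights k/n for k = 1..n (the last frame being B
itself); the classical three hybrids of a four-step transition are the
AAB / AB / ABB mixtures.

During the signal interval the orientation filter is applied to *each*
underlying frame independently (keyframes and hybrids alike), the filtered
image is amplitude-matched to that frame, embedded through the raised-cosine
window, and the composite is re-normalized.  The local signal therefore
updates together with the background and its onset and offset are concealed
by the ongoing full-field changes.

Timing is frame-quantized: onsets and durations given in seconds must be
integer multiples of the frame period, otherwise a hard error reports the
nearest valid values (no silent rounding).
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional

import numpy as np

from .embedding import WindowSpec, embed_signal
from .noise import NoiseField, normalize_pixels, rms_contrast
from .orientation import (
    OrientationFilterSpec,
    apply_orientation_filter,
    match_amplitude_range,
)

__all__ = [
    "KeyframeStream",
    "FrameSequence",
    "hybrid_weights",
    "interpolate_keyframes",
    "adjust_image_statistics",
    "seconds_to_frames",
    "build_dynamic_stimulus",
    "concealment_ratio",
    "frame_statistics",
]


def hybrid_weights(n_steps: int) -> np.ndarray:
    """B-weights of the frames emitted for one keyframe transition.

    Linear mixing proportions k/n for k = 1..n; strictly increasing and
    ending at exactly 1 (pure B). Pure A belongs to the previous transition
    and is not re-emitted.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return np.arange(1, n_steps + 1) / n_steps


def adjust_image_statistics(
    pixels: np.ndarray, reference_mean: float, reference_contrast: float
) -> np.ndarray:
    """Affinely re-impose a reference mean and RMS contrast on an image.

    Mixing two independent noise images lowers the contrast (by ~1/sqrt(2)
    for an equal mix); this restores the keyframe statistics exactly.
    Idempotent, and errors on a constant image.
    """
    return normalize_pixels(pixels, reference_mean, reference_contrast)


def interpolate_keyframes(a: NoiseField, b: NoiseField, n_steps: int) -> List[NoiseField]:
    """Hybrid frames carrying the transition from keyframe ``a`` to ``b``.

    Each mixture is statistics-adjusted to the targets of ``a``.
    """
    if a.shape != b.shape:
        raise ValueError("keyframes must share dimensions")
    frames = []
    for w_b in hybrid_weights(n_steps):
        mix = (1.0 - w_b) * a.pixels + w_b * b.pixels
        adjusted = adjust_image_statistics(mix, a.mean_luminance, a.contrast)
        frames.append(dataclasses.replace(a, pixels=adjusted, seed=None))
    return frames


@dataclasses.dataclass
class KeyframeStream:
    """Ordered pink-noise keyframes plus the transition parameters.

    ``n_steps`` hybrid steps connect successive keyframes; frames are shown
    at ``update_rate`` Hz.
    """

    keyframes: List[NoiseField]
    n_steps: int = 4
    update_rate: float = 60.0

    def __post_init__(self):
        if len(self.keyframes) < 2:
            raise ValueError("need at least two keyframes")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.update_rate <= 0:
            raise ValueError("update_rate must be positive")
        first = self.keyframes[0]
        for kf in self.keyframes[1:]:
            if kf.shape != first.shape:
                raise ValueError("keyframes must share dimensions")
            if (kf.mean_luminance, kf.contrast) != (first.mean_luminance, first.contrast):
                raise ValueError("keyframes must share target statistics")

    @classmethod
    def generate(
        cls,
        n_keyframes: int,
        height: int,
        width: int,
        seed: int,
        mean_luminance: float = 0.5,
        contrast: float = 0.2,
        n_steps: int = 4,
        update_rate: float = 60.0,
    ) -> "KeyframeStream":
        """Generate ``n_keyframes`` independent seeded keyframes."""
        from .noise import generate_pink_noise

        children = np.random.SeedSequence(seed).spawn(n_keyframes)
        keyframes = [
            generate_pink_noise(
                height,
                width,
                mean_luminance=mean_luminance,
                contrast=contrast,
                rng=np.random.default_rng(child),
            )
            for child in children
        ]
        return cls(keyframes=keyframes, n_steps=n_steps, update_rate=update_rate)

    @property
    def n_frames(self) -> int:
        return 1 + self.n_steps * (len(self.keyframes) - 1)

    def background_frames(self) -> np.ndarray:
        """All movie frames as an (n, h, w) array: A, hybrids, B, hybrids, C..."""
        frames = [self.keyframes[0].pixels]
        for a, b in zip(self.keyframes[:-1], self.keyframes[1:]):
            frames.extend(f.pixels for f in interpolate_keyframes(a, b, self.n_steps))
        return np.stack(frames)


@dataclasses.dataclass
class FrameSequence:
    """An ordered stimulus movie with per-frame event annotations.

    ``events`` maps event names to frame indices; ``*_off`` indices are
    exclusive (the first frame after the event).  ``meta`` carries target
    statistics and, when present, the window/filter/cue geometry and the
    display repeat factor (frames shown more than once on a faster display).
    """

    frames: np.ndarray
    frame_period: float
    events: dict = dataclasses.field(default_factory=dict)
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        n = len(self.frames)
        for name, idx in self.events.items():
            if not 0 <= idx <= n:
                raise ValueError(f"event {name} index {idx} outside 0..{n}")
        if "signal_on" in self.events:
            if self.events["signal_on"] >= self.events["signal_off"]:
                raise ValueError("signal_on must precede signal_off")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def time_ms(self, index: int) -> float:
        return index * self.frame_period * 1000.0

    def signal_frame_indices(self) -> np.ndarray:
        if "signal_on" not in self.events:
            return np.array([], dtype=int)
        return np.arange(self.events["signal_on"], self.events["signal_off"])

    def labels(self, index: int) -> List[str]:
        """Active event labels for one frame (e.g. ["signal"])."""
        out = []
        for name in ("cue", "signal", "mask"):
            on, off = self.events.get(f"{name}_on"), self.events.get(f"{name}_off")
            if on is not None and off is not None and on <= index < off:
                out.append(name)
        return out

    def to_sidecar(self) -> List[dict]:
        """Event annotations in the export schema: frame_index, t_ms, labels."""
        return [
            {"frame_index": i, "t_ms": self.time_ms(i), "labels": self.labels(i)}
            for i in range(self.n_frames)
        ]


def seconds_to_frames(duration: float, update_rate: float, what: str = "duration") -> int:
    """Convert seconds to a whole number of frames, or fail loudly.

    Durations that are not integer multiples of the frame period are a hard
    error naming the nearest frame-aligned values in milliseconds.
    """
    exact = duration * update_rate
    frames = round(exact)
    if abs(exact - frames) > 1e-6:
        lo = np.floor(exact) / update_rate * 1000.0
        hi = np.ceil(exact) / update_rate * 1000.0
        raise ValueError(
            f"{what} {duration * 1000:g} ms is not a whole number of frames at "
            f"{update_rate:g} Hz; nearest frame-aligned values are {lo:.2f} ms "
            f"and {hi:.2f} ms"
        )
    return int(frames)


def build_dynamic_stimulus(
    stream: KeyframeStream,
    signal_spec: Optional[OrientationFilterSpec] = None,
    window: Optional[WindowSpec] = None,
    signal_onset: float = 0.0,
    signal_duration: float = 0.0,
    ppd: float = 1.0,
    cue_onset: Optional[float] = None,
    cue_duration: Optional[float] = None,
    require_support: bool = True,
) -> FrameSequence:
    """Render the movie, inserting the orientation signal for its interval.

    With ``signal_spec=None`` the sequence is pure background.  Signal frames
    carry the orientation-filtered version of *that* frame's noise, embedded
    through ``window`` and re-normalized to the target statistics.  Cue
    timing, when given, is annotated in the events (the cue overlay itself is
    rendered at export).
    """
    rate = stream.update_rate
    frames = stream.background_frames()
    target = stream.keyframes[0]
    events: dict = {}
    meta = {
        "mean_luminance": target.mean_luminance,
        "contrast": target.contrast,
        "ppd": ppd,
        "update_rate": rate,
    }
    if cue_onset is not None:
        c0 = seconds_to_frames(cue_onset, rate, "cue onset")
        c1 = c0 + seconds_to_frames(cue_duration or 0.0, rate, "cue duration")
        events["cue_on"], events["cue_off"] = c0, c1
    if signal_spec is not None:
        if window is None:
            raise ValueError("a WindowSpec is required to embed a signal")
        i0 = seconds_to_frames(signal_onset, rate, "signal onset")
        i1 = i0 + seconds_to_frames(signal_duration, rate, "signal duration")
        if not (0 <= i0 < i1 <= len(frames)):
            raise ValueError(
                f"signal interval frames [{i0}, {i1}) outside movie of "
                f"{len(frames)} frames"
            )
        for i in range(i0, i1):
            bg = dataclasses.replace(target, pixels=frames[i], seed=None)
            filtered = apply_orientation_filter(bg, signal_spec)
            matched = match_amplitude_range(filtered, bg)
            composite = embed_signal(bg, matched, window, ppd, require_support)
            frames[i] = adjust_image_statistics(
                composite.pixels, target.mean_luminance, target.contrast
            )
        events["signal_on"], events["signal_off"] = i0, i1
        meta["window"] = window
        meta["signal_spec"] = signal_spec
    return FrameSequence(
        frames=frames, frame_period=1.0 / rate, events=events, meta=meta
    )


def concealment_ratio(seq: FrameSequence) -> float:
    """Temporal-concealment diagnostic: RMS frame-difference ratio.

    Ratio of the mean RMS difference between consecutive frames for steps
    touching the signal interval (including the onset and offset transitions)
    to the mean over purely-background steps.  Values near 1 mean signal
    onset/offset are hidden in the ongoing full-field changes; the protocol
    aims for [0.5, 2].
    """
    idx = seq.signal_frame_indices()
    if idx.size == 0:
        raise ValueError("sequence has no signal interval")
    diffs = np.sqrt(np.mean(np.diff(seq.frames, axis=0) ** 2, axis=(1, 2)))
    in_signal = np.zeros(seq.n_frames, dtype=bool)
    in_signal[idx] = True
    touches = in_signal[:-1] | in_signal[1:]
    if touches.all() or not touches.any():
        raise ValueError("need both signal-interval and background-only steps")
    return float(diffs[touches].mean() / diffs[~touches].mean())


def frame_statistics(seq: FrameSequence):
    """Per-frame (mean luminance, RMS contrast) arrays for diagnostics."""
    means = seq.frames.mean(axis=(1, 2))
    contrasts = np.array([rms_contrast(f) for f in seq.frames])
    return means, contrasts
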