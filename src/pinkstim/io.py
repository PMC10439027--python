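"""Configuration files, frame export, and run manifests.

Movies export as zero-padded numbered grayscale PNGs (16-bit by default,
8-bit optional) with an ``events.json`` sidecar of per-frame annotations.
Luminance quantization: pixels are clipped to the normalized [0, 1] range and
rounded half-even to the bit depth, so a write/read round trip reproduces the
quantized values exactly.  A run manifest records the config hash, package
version, master seed and output list — enough to reproduce every output bit
for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from importlib import resources
from pathlib import Path
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import yaml

from .dynamics import FrameSequence
from .protocol import ConfigError, SessionConfig

__all__ = [
    "load_config",
    "builtin_config",
    "quantize",
    "write_frames",
    "read_frames",
    "write_weight_map_png",
    "RunManifest",
    "config_hash",
]


def load_config(path) -> SessionConfig:
    """Load and validate a YAML session config.

    Raises :class:`~pinkstim.protocol.ConfigError` listing every offending
    field at once.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError([f"{path} does not contain a mapping"])
    return SessionConfig.from_dict(data)


def builtin_config(name: str) -> SessionConfig:
    """Load a shipped config by name (e.g. ``"exp1a"`` or ``"exp2"``)."""
    ref = resources.files("pinkstim").joinpath(f"configs/{name}.yaml")
    with resources.as_file(ref) as path:
        return load_config(path)


def quantize(pixels: np.ndarray, bit_depth: int = 16) -> np.ndarray:
    """Clip to [0, 1] and round half-even to ``bit_depth`` grayscale levels."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    levels = 2**bit_depth - 1
    scaled = np.round(np.clip(pixels, 0.0, 1.0) * levels)  # numpy rounds half-even
    return scaled.astype(np.uint8 if bit_depth == 8 else np.uint16)


def write_frames(
    seq: FrameSequence,
    out_dir,
    bit_depth: int = 16,
    prefix: str = "frame",
) -> Tuple[List[Path], dict]:
    """Write a movie as numbered PNGs plus the events.json sidecar.

    Returns the file list and a manifest entry describing the export.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pad = max(4, len(str(seq.n_frames - 1)))
    paths = []
    for i, frame in enumerate(seq.frames):
        path = out_dir / f"{prefix}_{i:0{pad}d}.png"
        try:
            iio.imwrite(path, quantize(frame, bit_depth))
        except OSError as exc:
            raise OSError(f"failed writing frame {i} to {path}: {exc}") from exc
    paths = sorted(out_dir.glob(f"{prefix}_*.png"))
    sidecar = out_dir / "events.json"
    with open(sidecar, "w") as fh:
        json.dump(seq.to_sidecar(), fh, indent=1)
    paths.append(sidecar)
    entry = {
        "directory": str(out_dir),
        "n_frames": seq.n_frames,
        "bit_depth": bit_depth,
        "frame_period_s": seq.frame_period,
        "files": [p.name for p in paths],
    }
    return paths, entry


def read_frames(out_dir, prefix: str = "frame"):
    """Read back an exported movie: (uint frame stack, sidecar events)."""
    out_dir = Path(out_dir)
    frame_paths = sorted(out_dir.glob(f"{prefix}_*.png"))
    if not frame_paths:
        raise FileNotFoundError(f"no '{prefix}_*.png' frames under {out_dir}")
    frames = np.stack([iio.imread(p) for p in frame_paths])
    with open(out_dir / "events.json") as fh:
        events = json.load(fh)
    return frames, events


def write_weight_map_png(weights: np.ndarray, path, bit_depth: int = 8):
    """Export a filter or aperture weight map (values in [0, 1]) for figures."""
    iio.imwrite(Path(path), quantize(np.fft.fftshift(weights), bit_depth))


def config_hash(config: SessionConfig) -> str:
    """SHA-256 over the canonical JSON form of the config."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for one run of the pipeline."""

    config_hash: str
    master_seed: int
    package_version: str = ""
    stage_seeds: dict = dataclasses.field(default_factory=dict)
    outputs: List[dict] = dataclasses.field(default_factory=list)
    timestamp: float = dataclasses.field(default_factory=time.time)

    @classmethod
    def for_run(cls, config: SessionConfig, master_seed: int) -> "RunManifest":
        from . import __version__

        noise, placement, observer, permutation = np.random.SeedSequence(
            master_seed
        ).spawn(4)
        stage_seeds = {
            name: int(ss.generate_state(1)[0] % 2**31)
            for name, ss in zip(
                ("noise", "placement", "observer", "permutation"),
                (noise, placement, observer, permutation),
            )
        }
        return cls(
            config_hash=config_hash(config),
            master_seed=master_seed,
            package_version=__version__,
            stage_seeds=stage_seeds,
        )

    def add_output(self, entry: dict):
        self.outputs.append(entry)

    def write(self, path):
        with open(Path(path), "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(Path(path)) as fh:
            return cls(**json.load(fh))
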