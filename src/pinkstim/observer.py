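"""Synthetic observers: response simulation and an image-computable decoder.

Two complementary stand-ins close the loop without human data:

* ``ObserverModel`` + ``simulate_responses`` — a phenomenological 2AFC
  observer whose probability correct follows the cumulative-Gaussian
  psychometric function of filter width.  Attended trials (cued, or foveal /
  fixed-position presentations) follow the curve; unattended peripheral
  trials respond at chance, emulating the empirical pattern that the signal
  is not discriminable outside the focus of attention.  This observer tests
  the analysis pipeline, not vision: no acuity fall-off is modelled.

* ``decode_tilt`` — a fixed orientation-energy model that reads rendered
  frames: within the analysis window of the signal frames it compares
  spectral energy in the clockwise versus counterclockwise orientation bands
  and reports the sign.  It is deterministic and auditable (no training),
  and serves as the stimulus-level oracle that narrower filter widths carry
  stronger signals, that the signal does not leak outside its window, and
  that discriminability is invariant across positions in the stationary
  noise field.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .dynamics import FrameSequence, KeyframeStream, build_dynamic_stimulus
from .embedding import WindowSpec
from .noise import fold_orientation, make_frequency_grid
from .orientation import OrientationFilterSpec
from .protocol import SessionConfig, TrialSpec, generate_session
from .psychometrics import PsychometricFitResults, fit_cumulative_gaussian

__all__ = [
    "ObserverModel",
    "simulate_responses",
    "decode_tilt",
    "decoder_trial",
    "decoder_accuracy",
    "run_closed_loop",
]


@dataclasses.dataclass(frozen=True)
class ObserverModel:
    """Ground-truth psychometric observer for 2AFC filter-width trials.

    ``mu_true`` is the sigma threshold (deg) where accuracy is 75%,
    ``slope_true`` the spread (deg); ``lapse`` in [0, 0.1];
    ``attention_gain`` scales the effective signal when cued (> 1 narrows
    the effective filter width sigma/gain — a phenomenological knob, 1 by
    default).
    """

    mu_true: float
    slope_true: float
    lapse: float = 0.0
    attention_gain: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.slope_true > 0:
            raise ValueError("slope_true must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")

    def p_correct(self, sigma: float, attended: bool) -> float:
        """Probability correct for one trial."""
        from scipy.stats import norm

        if not attended:
            return 0.5
        eff = sigma / self.attention_gain if self.attention_gain != 1.0 else sigma
        z = -(eff - self.mu_true) / self.slope_true
        return 0.5 + (0.5 - self.lapse) * norm.cdf(z)


def _attended(trial: TrialSpec) -> bool:
    # Cued trials and fixed-position designs are attended; uncued peripheral
    # presentations are not (and uncued foveal ones sit at the gaze centre).
    if trial.position is not None:
        return True
    if trial.condition == "cued":
        return True
    return trial.eccentricity == 0


def simulate_responses(
    trials: List[TrialSpec],
    model: ObserverModel,
    observer: str = "obs1",
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate a response table (one row per trial) under the model."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    rows = []
    for trial in trials:
        p = model.p_correct(trial.sigma, _attended(trial))
        rows.append(
            {
                "observer": observer,
                "condition": trial.condition,
                "eccentricity": trial.eccentricity,
                "position": trial.position,
                "sigma": trial.sigma,
                "tilt": trial.tilt,
                "p_true": p,
                "correct": int(rng.random() < p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# image-computable decoder


def _band_masks(shape, band_center: float, band_halfwidth: float):
    grid = make_frequency_grid(*shape)
    d_cw = np.abs(fold_orientation(grid.phi - band_center))
    d_ccw = np.abs(fold_orientation(grid.phi + band_center))
    ok = ~grid.dc_mask
    return (d_cw <= band_halfwidth) & ok, (d_ccw <= band_halfwidth) & ok


def decode_tilt(
    seq: FrameSequence,
    analysis_window: WindowSpec,
    ppd: Optional[float] = None,
    truth: Optional[dict] = None,
    band_center: float = 40.0,
    band_halfwidth: float = 15.0,
    require_support: bool = True,
) -> Dict:
    """Decode the embedded tilt from a movie's signal frames.

    The decision statistic is the difference of spectral energies in the
    +band_center and -band_center orientation bands (half-width
    ``band_halfwidth`` deg), computed on the mean-subtracted, window-weighted
    signal frames and summed over the interval.  Decoded tilt is the sign of
    the statistic.  Errors if the sequence has no signal frames.
    """
    from .embedding import raised_cosine_window

    idx = seq.signal_frame_indices()
    if idx.size == 0:
        raise ValueError("sequence carries no signal frames to decode")
    if ppd is None:
        ppd = seq.meta.get("ppd", 1.0)
    weights = raised_cosine_window(
        seq.frames.shape[1:], analysis_window, ppd, require_support
    )
    cw_mask, ccw_mask = _band_masks(seq.frames.shape[1:], band_center, band_halfwidth)
    stat = 0.0
    for i in idx:
        frame = seq.frames[i]
        windowed = (frame - frame.mean()) * weights
        power = np.abs(np.fft.fft2(windowed)) ** 2
        stat += float(power[cw_mask].sum() - power[ccw_mask].sum())
    decoded = band_center if stat > 0 else -band_center
    entry = {"statistic": stat, "decoded_tilt": decoded}
    if truth is not None:
        entry["true_tilt"] = truth["tilt"]
        entry["correct"] = int(np.sign(stat) == np.sign(truth["tilt"])) if stat != 0 else 0
    return entry


def decoder_trial(
    sigma: float,
    tilt: float,
    seed: int,
    field_px: int = 256,
    ppd: float = 9.0,
    window: Optional[WindowSpec] = None,
    signal: bool = True,
) -> FrameSequence:
    """Minimal two-frame movie for decoder Monte-Carlo runs.

    One keyframe transition (n_steps=1) with the signal embedded on the
    second frame; with ``signal=False`` the movie is background-only but the
    signal interval is still annotated, so the decoder statistic can be
    evaluated on signal-absent frames.
    """
    if window is None:
        window = WindowSpec(r=1.75, w=0.875)
    stream = KeyframeStream.generate(2, field_px, field_px, seed=seed, n_steps=1)
    seq = build_dynamic_stimulus(
        stream,
        signal_spec=OrientationFilterSpec(phi0=tilt, sigma=sigma) if signal else None,
        window=window if signal else None,
        signal_onset=1.0 / stream.update_rate,
        signal_duration=1.0 / stream.update_rate,
        ppd=ppd,
    )
    if not signal:
        seq.events["signal_on"], seq.events["signal_off"] = 1, 2
        seq.meta["window"] = window
    return seq


def decoder_accuracy(
    sigma: float,
    n_trials: int,
    seed: int,
    field_px: int = 256,
    ppd: float = 9.0,
    window: Optional[WindowSpec] = None,
    analysis_window: Optional[WindowSpec] = None,
    band_halfwidth: float = 15.0,
) -> float:
    """Monte-Carlo decoder accuracy at one filter width.

    Random tilt (+-40) per trial; the analysis window defaults to the
    embedding window (displace it to probe spatial specificity).
    """
    if window is None:
        window = WindowSpec(r=1.75, w=0.875)
    if analysis_window is None:
        analysis_window = window
    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(2**31, size=n_trials)
    correct = 0
    for t_seed in trial_seeds:
        tilt = 40.0 if rng.random() < 0.5 else -40.0
        seq = decoder_trial(
            sigma, tilt, int(t_seed), field_px=field_px, ppd=ppd, window=window
        )
        entry = decode_tilt(
            seq,
            analysis_window,
            ppd=ppd,
            truth={"tilt": tilt},
            band_halfwidth=band_halfwidth,
        )
        correct += entry["correct"]
    return correct / n_trials


def run_closed_loop(
    config: SessionConfig,
    model: ObserverModel,
    by: Optional[str] = "eccentricity",
) -> Dict:
    """Generate trials, simulate responses, and fit the psychometric model.

    Fits the pooled cued data and, when ``by`` is a column with several
    levels, one fit per level.  Returns the fits together with the Th75
    recovery error against the generating ``mu_true``.
    """
    trials = generate_session(config)
    table = simulate_responses(trials, model)
    cued = table[table["condition"] == "cued"]
    if len(cued) == 0:  # designs without a cue factor: everything is attended
        cued = table
    pooled = fit_cumulative_gaussian(cued, abscissa="sigma", orientation="decreasing")
    per_level: Dict[float, PsychometricFitResults] = {}
    if by is not None and by in cued and cued[by].nunique() > 1:
        for level, sub in cued.groupby(by):
            per_level[level] = fit_cumulative_gaussian(
                sub, abscissa="sigma", orientation="decreasing"
            )
    return {
        "responses": table,
        "fit": pooled,
        "per_level": per_level,
        "th75_error": abs(pooled.th75 - model.mu_true),
    }
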