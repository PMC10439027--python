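# Methods

This note documents the models, conventions, and numerical choices behind
`pinkstim`, the way they are implemented, and what the shipped tests do and
do not establish.

## Noise synthesis

A pink-noise field is generated in the frequency domain: a seeded white
Gaussian image is Fourier transformed (yielding complex-Gaussian
coefficients with uniformly random phases and exact Hermitian symmetry), the
amplitudes are scaled by `1/f_r`, and the inverse transform is renormalized.
Equivalent constructions (explicit phase randomization) would pass the same
spectral tests; this one is chosen because it is seeded, vectorized, and
exactly symmetric by construction.

Conventions that hold everywhere in the package:

* **Frequency units** are cycles/pixel on the unshifted `numpy.fft` grid
  (Nyquist 0.5 in both directions). This keeps the radial frequency
  isotropic for non-square fields such as the 2.5° × 20° strip. Conversion
  to cycles/degree (`f · ppd`) happens only at the reporting layer, so the
  core stays display-independent.
* **Orientation** `φ = arctan(fy/fx)` is axial and folded to [−90°, +90°);
  it is undefined (NaN) at DC. `fx` runs along image x (axis 1), `fy` along
  image y (axis 0, downwards).
* **DC handling.** `1/f_r` is singular at DC; the DC amplitude is whatever
  the mean-luminance normalization imposes. The mean is a free parameter of
  the display, not of the spectrum.
* **Normalization.** Fields are affinely rescaled to an exact sample mean
  (`mean_luminance`, default 0.5 in normalized luminance units) and RMS
  contrast (std/mean, default 0.2). The operation is idempotent and fails
  loudly on constant images.

Diagnostics: the radially averaged amplitude profile uses log-spaced bins
over (0, Nyquist]; slope fits exclude the lowest and highest half-octave,
where annulus discretization (few modes per bin at low f, anisotropic corner
coverage near Nyquist) biases the estimate. Band energies are sums of
squared amplitudes over `f_lo ≤ f_r < f_hi` within the Nyquist disk; for a
1/f spectrum adjacent octaves carry equal energy, the scale-invariance that
motivates using this stimulus across retinal eccentricities.

## Orientation filter

The signal filter is the Gaussian orientation weighting
`W = exp(−(Δφ/σ)²)` with `Δφ` the minimal axial distance between the grid
orientation and the preferred orientation φ₀. Choices worth recording:

* **Sign of the exponent.** The weighting is a *decaying* Gaussian: narrower
  σ must concentrate energy around φ₀ (and empirically make the task
  easier). The implementation fixes the sign accordingly.
* **Folding.** Δφ is folded to [−90°, +90°); without folding the filter
  would treat the two half-planes of the spectrum asymmetrically.
* **No wrapped Gaussian.** For σ ≤ 70° the tail that wraps past the 90°
  fold is `exp(−(90/70)²) ≈ 0.19` — not negligible, but the single-Gaussian
  form is the filter's definition, and the tail is part of it.
* **Nyquist bins.** On even-sized grids the Nyquist rows/columns are their
  own conjugate partners and their orientation is sign-ambiguous; the raw
  weight map is therefore not exactly Hermitian-symmetric there. Before
  filtering, the map is averaged with its point reflection
  (`hermitian_symmetrize`), which assigns those bins the mean of the two
  candidate orientations' weights and guarantees a real output (imaginary
  residue below 1e−10 of the RMS). `orientation_weight_map` itself returns
  the raw per-pixel definition, which is what the brute-force oracle in the
  tests recomputes.
* **DC weight is 1**, leaving the mean untouched; the mean is re-imposed
  downstream anyway.

After filtering, the image is affinely rescaled to the min/max range of the
unfiltered original (`match_amplitude_range`) — a monotone map, so pixel
ordering is preserved — before embedding.

## Embedding window

The aperture is a raised cosine: weight 1 out to the plateau radius `r`,
`0.5·(1 + cos(π(d − r)/w))` over the ramp, 0 beyond `r + w`. The ramp lies
*outside* `r`, so "radius" names the full-strength region; this placement is
a package convention (the alternative, ramp inside `r`, is equally
defensible). Windows are evaluated at real-valued distances — centres are
never snapped to the pixel grid — and the composite is computed as
`bg + W·(signal − bg)` with plateau pixels overwritten, so the background is
reproduced bit-exactly outside the support and the signal bit-exactly on the
plateau; every other pixel is a convex combination.

By default the full support must fit inside the array. Narrow fields are the
exception: the 2.5°-high strip of the position design cannot contain the
1.875° support radius vertically, so its trial builder permits ramp clipping
at the field edge while still requiring the plateau to fit
(`require_support=False`).

## Dynamics

Keyframe transitions emit `n_steps` mixtures with B-weights `k/n`
(k = 1..n); the three interior hybrids of a four-step transition are the
classical AAB/AB/ABB mixtures, and pure A is not re-emitted (it ended the
previous transition). Mixing two independent noise images lowers contrast
(≈1/√2 for the equal mix), so every hybrid is affinely re-adjusted to the
keyframe mean/contrast — no frame of the movie flickers in luminance or
contrast (deviations are at rounding level, orders below the 1e−6 the tests
require).

During the signal interval the filter is applied to each underlying frame
independently and the composite is re-normalized; the signal patch therefore
updates with the background rather than being a static pasted patch. The
`concealment_ratio` diagnostic — mean RMS frame-to-frame difference for
steps touching the signal interval over the mean for background-only steps —
sits near 1 for the reference geometry (window r = 1.75° in a 14.32° field),
i.e. signal onset is not a transient.

Timing is strictly frame-quantized: onsets/durations in milliseconds that
are not whole frame counts raise an error naming the nearest valid values.
The shipped eccentricity config encodes the 75 ms cue as 4 frames (66.7 ms)
at the 60 Hz update rate, and the position design encodes its ~42 ms signal
as 5 frames at 120 Hz. The display may refresh faster than the noise
updates; the sequence stores unique frames plus a `repeat_factor`.

## Protocol and configs

Sessions are balanced full crossings of condition × location × σ × tilt,
shuffled and seeded from a master seed; each trial derives named RNG
substreams (noise, placement, timing jitter) from its own seed, so a session
is bit-reproducible and stages do not perturb each other's draws. Placement
draws a uniform polar angle at the requested eccentricity (circular design)
or sits on the horizontal midline (position design); placements whose
support leaves the field are errors. Fixation and mask jitters are
uniform-continuous, then quantized to frame counts.

The pink colour cue is annotated in the event stream and rendered only at
the export layer (RGB [204, 0, 102] at the signal location and dimensions);
the stored grayscale frames of cued and uncued trials are identical, which
is also what makes the "same seed ⇒ same frames" property testable. The ring
outlines of the position design are drawn dark (near 0 luminance) — outlines
at background luminance would be invisible — with a 1-pixel stroke by
default. Pixels-per-degree is a required config input; the shipped configs
use a nominal 26.8 px/deg (a 14.32° field radius spanning half of a 768-px
screen height).

## Psychometrics

Accuracy is modelled as `Ψ(x) = γ + (1 − γ − λ)·Φ(s(x − μ)/σ_slope)` with
guess rate γ = 0.5 (2AFC) and lapse λ = 0 by default (λ is exposed as a
fixed optional parameter; the asymptotes of the data this protocol produces
sit at 0.5 and 1). `s = −1` for filter width (accuracy falls as the filter
widens), `s = +1` for tilt angle. With the defaults, Th75 = μ exactly.

Estimation maximizes the Bernoulli likelihood (aggregated to levels) over
(μ, log σ_slope) with L-BFGS-B from a coarse multi-start grid, ftol 1e−10.
Box bounds span the tested levels ± 2 ranges; estimates at a bound are
flagged `converged=False` rather than returned silently. Data at chance
everywhere either hit a bound or converge to a μ far outside the tested
range — the latter is surfaced via the `extrapolated` flag. Standard errors
come from the finite-difference observed information at the optimum.

The permutation test permutes condition labels within observer (equivalently
sign-flips each observer's paired difference), recomputes the difference of
group means per resample, and reports the two-sided p-value with the
`(1 + hits)/(iterations + 1)` small-sample convention (the raw proportion is
available behind `plus_one=False`); Bonferroni is `min(1, m·p)`. Spatial
summaries report the across-observer mean ± SEM per location with a
piecewise-linear interpolant.

## Synthetic observers

The response simulator draws Bernoulli responses from Ψ with ground-truth
parameters; cued trials, fixed-position trials, and uncued foveal trials are
"attended", uncued peripheral trials respond at chance — emulating the
empirical pattern that the embedded signal is only discriminable inside the
focus of attention. An `attention_gain` multiplier (default 1) scales the
effective signal on attended trials. Deliberately *not* modelled: acuity
fall-off with eccentricity, temporal attention dynamics. Passing
recovery tests therefore validates the stimulus/analysis pipeline, not any
claim about human vision.

The image-computable decoder is a fixed orientation-energy model: on each
signal frame it mean-subtracts, multiplies by the analysis window, and
compares spectral power in the ±40° orientation bands (half-width ±15°,
chosen a priori and exposed as a parameter rather than optimized); the
decoded tilt is the sign of the summed difference. With a matched analysis
window the decoder is close to ideal and sits at ceiling across the σ range
used by the task — accuracy is monotone non-increasing in σ, collapses to
chance when the analysis window is displaced by more than twice the window
support (the stimulus-level "no pop-out" property), and is indistinguishable
across eccentricities at matched σ (the noise field is statistically
stationary, the stimulus-level basis of eccentricity invariance).

## Problem sizes and seeds

Simulation sizes are chosen so the full validation runs comfortably on one
CPU: spectral checks at 512² (10 seeds) and octave checks at 256² (20
seeds); decoder Monte-Carlo on 256-px fields at 9 px/deg with one embedded
signal frame per trial, 150–200 trials per condition; the concealment movie
at the full eccentricity-design geometry scaled to 8 px/deg (230-px field,
45 frames); threshold recovery from 1728 attended trials (the per-observer
scale of a full session; 9 σ levels from 30° to 70°, generating μ = 50°,
slope = 10°); permutation calibration over 1000 simulated null datasets of
12 observers × 20 trials × 2 conditions at 500 resamples each. All
randomness descends from explicit seeds (in `scripts/acceptance.py`, from
the single `--seed` through named substreams), so every number in the
README and the acceptance output is reproducible.

## Known limitations

* The Gaussian orientation filter is unwrapped; at σ = 70° the fold-over
  tail is ≈ 0.19, so very wide filters are slightly less orientation-pure
  than the nominal Gaussian.
* The raised-cosine ramp placement (outside the plateau radius) and the DC
  conventions are package choices; other implementations of the same
  protocol may differ in these details.
* `1/f_r` amplitude scaling on the discrete grid is exact per FFT bin, not
  an average over the annulus a bin represents; at the sizes used this
  shifts slope fits by far less than the tested tolerance.
* The synthetic observers validate the pipeline only; empirical claims about
  human attention and eccentricity invariance require human data collected
  with a calibrated display (gamma linearization, true pixels-per-degree),
  neither of which this package models.
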