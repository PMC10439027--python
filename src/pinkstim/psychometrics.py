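"""Psychometric modelling and resampling statistics for 2AFC data.

The accuracy model is a cumulative Gaussian with the guess rate fixed at the
2AFC chance level:

    Psi(x) = gamma + (1 - gamma - lambda) * Phi(s * (x - mu) / sd),

with gamma = 0.5, lapse rate lambda = 0 by default, ``s = -1`` when accuracy
falls as the abscissa grows (orientation-filter width sigma) and ``s = +1``
when it rises (tilt angle).  Parameters are estimated by maximizing the
Bernoulli likelihood of the per-trial responses; with the defaults the 75%
threshold Th75 equals the fitted ``mu`` analytically, since Psi = 0.75 iff
Phi = 0.5 iff x = mu.

``CumulativeGaussianModel`` / ``PsychometricFitResults`` follow the familiar
model-object pattern: build the model from data, call ``fit()``, read
estimates, standard errors and ``summary()`` off the results.

Also here: a within-observer label-permutation test for condition contrasts
(two-sided on the absolute mean difference, with the small-sample
``(1 + hits) / (iterations + 1)`` convention and Bonferroni correction) and
per-location accuracy summaries with a linear spatial interpolant.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import interp1d

__all__ = [
    "CumulativeGaussianModel",
    "PsychometricFitResults",
    "fit_cumulative_gaussian",
    "threshold_at",
    "PermutationResult",
    "permutation_test",
    "summarize_by_location",
]

_ORIENTATION_SIGN = {"decreasing": -1.0, "increasing": 1.0}


class CumulativeGaussianModel:
    """Maximum-likelihood cumulative-Gaussian psychometric model.

    Parameters
    ----------
    x : array-like
        Per-trial stimulus level (filter width sigma in degrees, or tilt
        angle in degrees).
    correct : array-like of {0, 1}
        Per-trial response correctness.
    orientation : {"decreasing", "increasing"}
        Whether accuracy falls ("decreasing", the sigma case) or rises
        ("increasing", the tilt case) with the abscissa.
    guess, lapse : float
        Lower asymptote (0.5 for 2AFC) and lapse rate (fixed, default 0).
    """

    def __init__(self, x, correct, orientation: str = "decreasing",
                 guess: float = 0.5, lapse: float = 0.0):
        if orientation not in _ORIENTATION_SIGN:
            raise ValueError("orientation must be 'decreasing' or 'increasing'")
        if not 0.0 <= lapse <= 0.5 - 1e-9:
            raise ValueError("lapse must lie in [0, 0.5)")
        x = np.asarray(x, dtype=float)
        correct = np.asarray(correct)
        if x.shape != correct.shape:
            raise ValueError("x and correct must have the same length")
        if not np.isin(correct, (0, 1, False, True)).all():
            raise ValueError("correct must be binary")
        self.orientation = orientation
        self.sign = _ORIENTATION_SIGN[orientation]
        self.guess = float(guess)
        self.lapse = float(lapse)
        # aggregate to levels: sufficient statistics for the Bernoulli likelihood
        levels, inverse = np.unique(x, return_inverse=True)
        if levels.size < 2:
            raise ValueError("need responses at >= 2 distinct abscissa levels")
        self.levels = levels
        self.n_per_level = np.bincount(inverse, minlength=levels.size).astype(float)
        self.k_per_level = np.bincount(
            inverse, weights=correct.astype(float), minlength=levels.size
        )
        self.n_trials = int(self.n_per_level.sum())

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        abscissa: str = "sigma",
        response: str = "correct",
        **kwargs,
    ) -> "CumulativeGaussianModel":
        return cls(table[abscissa].to_numpy(), table[response].to_numpy(), **kwargs)

    # -- likelihood ---------------------------------------------------------

    def predict(self, mu: float, sd: float, x=None) -> np.ndarray:
        """Predicted proportion correct Psi(x)."""
        x = self.levels if x is None else np.asarray(x, dtype=float)
        z = self.sign * (x - mu) / sd
        return self.guess + (1.0 - self.guess - self.lapse) * stats.norm.cdf(z)

    def loglike(self, mu: float, sd: float) -> float:
        p = np.clip(self.predict(mu, sd), 1e-12, 1.0 - 1e-12)
        return float(
            np.sum(self.k_per_level * np.log(p)
                   + (self.n_per_level - self.k_per_level) * np.log(1.0 - p))
        )

    # -- estimation ---------------------------------------------------------

    def fit(self, n_starts: int = 5) -> "PsychometricFitResults":
        """Maximize the likelihood with multi-started bounded quasi-Newton.

        Starts cover a coarse grid over (mu, log sd) spanning the tested
        levels.  Degenerate data (at chance or at ceiling everywhere) push
        ``mu`` to a box bound and are flagged ``converged=False`` rather
        than silently returning an estimate.
        """
        span = float(self.levels.max() - self.levels.min())
        lo, hi = float(self.levels.min()), float(self.levels.max())
        bounds = [(lo - 2 * span, hi + 2 * span), (np.log(span * 1e-3), np.log(span * 50))]

        def nll(params):
            return -self.loglike(params[0], np.exp(params[1]))

        mu_starts = np.linspace(lo, hi, n_starts)
        sd_starts = np.exp(np.linspace(np.log(span / 8), np.log(span), n_starts))
        best = None
        for mu0, sd0 in zip(mu_starts, sd_starts[np.argsort(sd_starts)]):
            for sd_try in (sd0, span / 2):
                res = optimize.minimize(
                    nll,
                    x0=[mu0, np.log(sd_try)],
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"ftol": 1e-10, "gtol": 1e-8},
                )
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
        mu_hat, sd_hat = best.x[0], float(np.exp(best.x[1]))
        at_bound = any(
            abs(best.x[i] - b) < 1e-6 * max(1.0, abs(b))
            for i, (blo, bhi) in enumerate(bounds)
            for b in (blo, bhi)
        )
        converged = bool(best.success) and not at_bound and np.isfinite(best.fun)
        bse = self._standard_errors(mu_hat, sd_hat) if converged else (np.nan, np.nan)
        return PsychometricFitResults(
            model=self,
            mu=float(mu_hat),
            slope_sd=sd_hat,
            se_mu=bse[0],
            se_sd=bse[1],
            loglik=-float(best.fun),
            n_trials=self.n_trials,
            converged=converged,
        )

    def _standard_errors(self, mu: float, sd: float):
        """Observed-information standard errors via central finite differences."""
        h_mu = max(1e-5, 1e-4 * abs(mu) + 1e-5)
        h_sd = max(1e-5, 1e-4 * sd)
        hess = np.empty((2, 2))

        def f(m, s):
            return -self.loglike(m, s)

        hess[0, 0] = (f(mu + h_mu, sd) - 2 * f(mu, sd) + f(mu - h_mu, sd)) / h_mu**2
        hess[1, 1] = (f(mu, sd + h_sd) - 2 * f(mu, sd) + f(mu, sd - h_sd)) / h_sd**2
        hess[0, 1] = hess[1, 0] = (
            f(mu + h_mu, sd + h_sd) - f(mu + h_mu, sd - h_sd)
            - f(mu - h_mu, sd + h_sd) + f(mu - h_mu, sd - h_sd)
        ) / (4 * h_mu * h_sd)
        try:
            cov = np.linalg.inv(hess)
            if cov[0, 0] <= 0 or cov[1, 1] <= 0:
                raise np.linalg.LinAlgError
            return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            return np.nan, np.nan


@dataclasses.dataclass
class PsychometricFitResults:
    """Fitted parameters, uncertainties and diagnostics of one psychometric fit."""

    model: CumulativeGaussianModel
    mu: float
    slope_sd: float
    se_mu: float
    se_sd: float
    loglik: float
    n_trials: int
    converged: bool

    @property
    def th75(self) -> float:
        """75% discrimination threshold; equals mu when guess=0.5, lapse=0."""
        return self.threshold(0.75)

    @property
    def extrapolated(self) -> bool:
        """True when Th75 lies outside the tested stimulus levels.

        Data at chance (or at ceiling) everywhere can produce a formally
        converged fit whose threshold extrapolates beyond the measured
        range; such estimates deserve a caveat.
        """
        return not (self.model.levels.min() <= self.mu <= self.model.levels.max())

    def threshold(self, criterion: float) -> float:
        """Abscissa value where the fitted Psi reaches ``criterion``."""
        m = self.model
        upper = 1.0 - m.lapse
        if not m.guess < criterion < upper:
            raise ValueError(
                f"criterion must lie in ({m.guess}, {upper}), got {criterion}"
            )
        z = stats.norm.ppf((criterion - m.guess) / (1.0 - m.guess - m.lapse))
        return float(self.mu + m.sign * self.slope_sd * z)

    def predict(self, x) -> np.ndarray:
        return self.model.predict(self.mu, self.slope_sd, x)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Cumulative Gaussian psychometric fit (2AFC)",
            "=" * 47,
            f"{'orientation':<22}{m.orientation:>25}",
            f"{'n trials':<22}{self.n_trials:>25d}",
            f"{'n levels':<22}{m.levels.size:>25d}",
            f"{'log-likelihood':<22}{self.loglik:>25.3f}",
            f"{'converged':<22}{str(self.converged):>25}",
            "-" * 47,
            f"{'':<12}{'estimate':>12}{'std err':>12}",
            f"{'mu':<12}{self.mu:>12.4f}{self.se_mu:>12.4f}",
            f"{'slope_sd':<12}{self.slope_sd:>12.4f}{self.se_sd:>12.4f}",
            f"{'Th75':<12}{self.th75:>12.4f}",
            "=" * 47,
        ]
        return "\n".join(lines)

    def plot(self, ax=None, n_points: int = 200):
        """Observed proportions per level with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.plot(m.levels, m.k_per_level / m.n_per_level, "o", label="observed")
        grid = np.linspace(m.levels.min(), m.levels.max(), n_points)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.axhline(0.75, color="gray", lw=0.5)
        ax.set_xlabel("stimulus level (deg)")
        ax.set_ylabel("proportion correct")
        ax.set_ylim(0.4, 1.02)
        ax.legend()
        return ax


def fit_cumulative_gaussian(
    table: pd.DataFrame,
    abscissa: str = "sigma",
    orientation: str = "decreasing",
    **kwargs,
) -> PsychometricFitResults:
    """Convenience wrapper: fit the model straight from a response table."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("n_starts",) if k in kwargs}
    model = CumulativeGaussianModel.from_dataframe(
        table, abscissa=abscissa, orientation=orientation, **kwargs
    )
    return model.fit(**fit_kwargs)


def threshold_at(fit: PsychometricFitResults, criterion: float) -> float:
    """Inverse of the fitted psychometric function at ``criterion``."""
    if not fit.converged:
        raise ValueError("threshold requested from a non-converged fit")
    return fit.threshold(criterion)


@dataclasses.dataclass
class PermutationResult:
    """Observed difference, permutation null, and (corrected) p-values."""

    observed_diff: float
    null_diffs: np.ndarray
    p_raw: float
    p_bonferroni: float
    iterations: int
    seed: Optional[int]

    def __post_init__(self):
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValueError("p_raw outside [0, 1]")


def permutation_test(
    table: pd.DataFrame,
    group_key: str,
    value: str = "correct",
    observer_key: str = "observer",
    groups: Optional[Sequence] = None,
    iterations: int = 1000,
    seed: Optional[int] = None,
    n_comparisons: int = 1,
    plus_one: bool = True,
) -> PermutationResult:
    """Within-observer label-permutation test of a two-group mean difference.

    Per observer, the group labels of the two conditions are randomly
    rearranged on each resample and the difference in group sample means is
    recomputed; the two-sided p-value is the proportion of resampled
    |differences| at least as large as the observed one.  ``plus_one``
    applies the (1 + hits)/(iterations + 1) small-sample convention so p is
    never exactly 0; Bonferroni multiplies by ``n_comparisons`` and caps at 1.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    means = table.groupby([observer_key, group_key], sort=True)[value].mean().unstack()
    if groups is not None:
        missing = [g for g in groups if g not in means.columns]
        if missing:
            raise ValueError(f"group(s) {missing} absent from {group_key}")
        means = means[list(groups)]
    if means.shape[1] != 2:
        raise ValueError(
            f"need exactly two groups in {group_key!r}, got {list(means.columns)}"
        )
    if means.isna().any().any():
        empty = means.columns[means.isna().any()].tolist()
        raise ValueError(f"group(s) {empty} empty for some observer")
    paired = means.iloc[:, 0].to_numpy() - means.iloc[:, 1].to_numpy()
    observed = float(paired.mean())
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(iterations, paired.size)) * 2 - 1
    null = (signs * paired).mean(axis=1)
    hits = int(np.sum(np.abs(null) >= abs(observed)))
    if plus_one:
        p_raw = (1 + hits) / (iterations + 1)
    else:
        p_raw = hits / iterations
    return PermutationResult(
        observed_diff=observed,
        null_diffs=null,
        p_raw=float(p_raw),
        p_bonferroni=float(min(1.0, n_comparisons * p_raw)),
        iterations=iterations,
        seed=seed,
    )


def summarize_by_location(
    table: pd.DataFrame,
    location_key: str = "position",
    value: str = "correct",
    observer_key: str = "observer",
):
    """Group mean accuracy +- SEM per location, plus a linear interpolant.

    Per location, each observer contributes one mean; the group mean and the
    SEM across observers are reported (SEM is 0 for a single observer).  The
    returned interpolant is piecewise linear across locations, the form used
    to visualize accuracy across space.
    """
    per_obs = table.groupby([location_key, observer_key], sort=True)[value].mean()
    grouped = per_obs.groupby(level=0)
    summary = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "sem": grouped.std(ddof=1).fillna(0.0)
            / np.sqrt(grouped.count()),
            "n_observers": grouped.count(),
        }
    ).reset_index()
    interpolant = interp1d(
        summary[location_key].to_numpy(dtype=float),
        summary["mean"].to_numpy(dtype=float),
        kind="linear",
    )
    return summary, interpolant
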