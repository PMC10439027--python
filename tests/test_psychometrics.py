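"""Psychometric fitting, thresholds, permutation tests, spatial summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from pinkstim.psychometrics import (
    CumulativeGaussianModel,
    fit_cumulative_gaussian,
    permutation_test,
    summarize_by_location,
    threshold_at,
)

LEVELS = np.linspace(30.0, 70.0, 9)


def simulate_table(mu, sd, n_per_level, rng, levels=LEVELS):
    x = np.repeat(levels, n_per_level)
    p = 0.5 + 0.5 * stats.norm.cdf(-(x - mu) / sd)
    return x, (rng.random(x.size) < p).astype(int)


@pytest.fixture(scope="module")
def reference_fit():
    rng = np.random.default_rng(2024)
    x, correct = simulate_table(50.0, 10.0, 200, rng)
    return CumulativeGaussianModel(x, correct).fit()


class TestThresholds:
    def test_th75_equals_mu(self, reference_fit):
        # Psi = 0.75 iff Phi = 0.5 iff x = mu
        assert reference_fit.th75 == reference_fit.mu

    def test_one_sd_criterion_increasing(self):
        rng = np.random.default_rng(7)
        x = np.repeat(np.linspace(1.0, 25.0, 9), 150)
        p = 0.5 + 0.5 * stats.norm.cdf((x - 10.0) / 5.0)
        fit = CumulativeGaussianModel(
            x, (rng.random(x.size) < p).astype(int), orientation="increasing"
        ).fit()
        criterion = 0.5 + 0.5 * stats.norm.cdf(1.0)  # ~0.9207
        assert fit.threshold(criterion) == pytest.approx(fit.mu + fit.slope_sd)

    def test_matches_numerical_inversion(self, reference_fit):
        for criterion in (0.6, 0.75, 0.9):
            analytic = reference_fit.threshold(criterion)
            numeric = optimize.brentq(
                lambda x: float(reference_fit.predict(x)) - criterion,
                -200.0,
                300.0,
                xtol=1e-12,
            )
            assert analytic == pytest.approx(numeric, abs=1e-9)

    def test_criterion_validation(self, reference_fit):
        for bad in (0.5, 1.0, 0.2):
            with pytest.raises(ValueError):
                reference_fit.threshold(bad)
        with pytest.raises(ValueError):
            threshold_at(reference_fit, 1.2)


class TestFitting:
    def test_parameter_recovery_replicates(self):
        # 500 replicate experiments at the generating (mu, sd) = (50, 10)
        rng = np.random.default_rng(11)
        mus = []
        for _ in range(500):
            k = rng.binomial(200, 0.5 + 0.5 * stats.norm.cdf(-(LEVELS - 50.0) / 10.0))
            x = np.repeat(LEVELS, 200)
            correct = np.concatenate(
                [np.r_[np.ones(ki), np.zeros(200 - ki)] for ki in k]
            )
            mus.append(CumulativeGaussianModel(x, correct).fit(n_starts=3).mu)
        mus = np.array(mus)
        assert abs(mus.mean() - 50.0) < 1.0
        assert np.sqrt(np.mean((mus - 50.0) ** 2)) < 2.0

    def test_recovery_error_shrinks_with_trials(self):
        rng = np.random.default_rng(13)

        def rmse(n_per_level, reps=120):
            errs = []
            for _ in range(reps):
                k = rng.binomial(
                    n_per_level, 0.5 + 0.5 * stats.norm.cdf(-(LEVELS - 50.0) / 10.0)
                )
                x = np.repeat(LEVELS, n_per_level)
                correct = np.concatenate(
                    [np.r_[np.ones(ki), np.zeros(n_per_level - ki)] for ki in k]
                )
                errs.append(CumulativeGaussianModel(x, correct).fit(n_starts=3).mu - 50.0)
            return float(np.sqrt(np.mean(np.square(errs))))

        errors = [rmse(n) for n in (25, 100, 400)]
        assert errors[0] > errors[1] > errors[2]

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_chance_data_flagged_not_silently_estimated(self, seed):
        # at-chance data must either fail convergence or carry the
        # out-of-range caveat — never look like a clean threshold
        rng = np.random.default_rng(seed)
        x = np.repeat(LEVELS, 50)
        fit = CumulativeGaussianModel(x, (rng.random(x.size) < 0.5).astype(int)).fit()
        assert (not fit.converged) or fit.extrapolated
        if not fit.converged:
            with pytest.raises(ValueError):
                threshold_at(fit, 0.75)

    def test_optimum_at_least_as_likely_as_truth(self):
        rng = np.random.default_rng(21)
        x, correct = simulate_table(50.0, 10.0, 60, rng)
        model = CumulativeGaussianModel(x, correct)
        fit = model.fit()
        assert fit.loglik >= model.loglike(50.0, 10.0) - 1e-9

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            CumulativeGaussianModel(np.full(10, 40.0), np.ones(10))

    def test_dataframe_entry_point_and_summary(self):
        rng = np.random.default_rng(5)
        x, correct = simulate_table(50.0, 10.0, 80, rng)
        table = pd.DataFrame({"sigma": x, "correct": correct})
        fit = fit_cumulative_gaussian(table)
        assert fit.converged
        text = fit.summary()
        assert "mu" in text and "Th75" in text and str(fit.n_trials) in text
        assert fit.se_mu > 0


def paired_table(rng, n_obs=12, n_trials=20, p_a=0.6, p_b=0.6):
    rows = []
    for obs in range(n_obs):
        for cond, p in (("a", p_a), ("b", p_b)):
            for v in rng.random(n_trials) < p:
                rows.append({"observer": obs, "condition": cond, "correct": int(v)})
    return pd.DataFrame(rows)


class TestPermutationTest:
    def test_boundary_p_under_plus_one_convention(self, rng):
        # an observed difference larger than every resample
        rows = []
        for obs in range(20):
            rows.append({"observer": obs, "condition": "a", "correct": 1})
            rows.append({"observer": obs, "condition": "b", "correct": 0})
        table = pd.DataFrame(rows)
        result = permutation_test(table, "condition", iterations=400, seed=1)
        assert result.p_raw == pytest.approx(1 / 401)
        raw = permutation_test(
            table, "condition", iterations=400, seed=1, plus_one=False
        )
        assert raw.p_raw == 0.0

    def test_bonferroni_arithmetic(self, rng):
        table = paired_table(rng)
        result = permutation_test(
            table, "condition", iterations=200, seed=2, n_comparisons=3
        )
        assert result.p_bonferroni == min(1.0, 3 * result.p_raw)

    def test_two_sided_label_symmetry(self, rng):
        table = paired_table(rng, p_a=0.7, p_b=0.55)
        ab = permutation_test(table, "condition", groups=("a", "b"),
                              iterations=300, seed=9)
        ba = permutation_test(table, "condition", groups=("b", "a"),
                              iterations=300, seed=9)
        assert ab.observed_diff == pytest.approx(-ba.observed_diff)
        assert ab.p_raw == ba.p_raw

    def test_empty_group_rejected(self, rng):
        table = paired_table(rng)
        table = table[~((table.observer == 3) & (table.condition == "b"))]
        with pytest.raises(ValueError):
            permutation_test(table, "condition", iterations=100, seed=0)
        with pytest.raises(ValueError):
            permutation_test(
                table[table.condition == "a"], "condition", iterations=100, seed=0
            )


class TestSummarizeByLocation:
    def test_linear_midpoint_interpolation(self):
        table = pd.DataFrame(
            {
                "observer": ["o1"] * 4,
                "position": [0.0, 0.0, 4.0, 4.0],
                "correct": [1, 0.2, 1, 0.6],  # means 0.6 and 0.8
            }
        )
        summary, interp = summarize_by_location(table)
        assert interp(2.0) == pytest.approx(0.7)
        assert np.all(summary["sem"] == 0.0)  # single observer

    def test_matches_groupby_oracle(self, rng):
        table = pd.DataFrame(
            {
                "observer": rng.integers(0, 5, 400),
                "position": rng.choice([-4.0, 0.0, 4.0], 400),
                "correct": rng.integers(0, 2, 400),
            }
        )
        summary, _ = summarize_by_location(table)
        for _, row in summary.iterrows():
            per_obs = []
            for obs in np.unique(table.observer):
                sel = (table.position == row.position) & (table.observer == obs)
                if sel.any():
                    per_obs.append(table.correct[sel].mean())
            assert row["mean"] == pytest.approx(np.mean(per_obs))
            expected_sem = np.std(per_obs, ddof=1) / np.sqrt(len(per_obs))
            assert row["sem"] == pytest.approx(expected_sem)
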