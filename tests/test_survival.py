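"""Cox regression, stepwise selection, KM/log-rank, Fisher and the Relapse Score."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from immunohex import CohortParams, cox_fit, fisher_exact_2x2, generate_cohort, \
    km_logrank, relapse_score, score_stratification, stepwise_lr
from immunohex.survival import score_table


def breslow_log_partial_likelihood(beta, t, e, x):
    """Explicit Breslow partial log-likelihood for one covariate (oracle)."""
    beta = np.atleast_1d(beta)
    order = np.argsort(t)
    t, e, x = t[order], e[order], x[order]
    ll = np.zeros(beta.shape)
    for ut in np.unique(t[e == 1]):
        deaths = (t == ut) & (e == 1)
        risk = t >= ut
        ll += beta * x[deaths].sum() - deaths.sum() * np.log(
            np.exp(np.outer(beta, x[risk])).sum(axis=1))
    return ll


def simulate_two_arm(n, log_hr, seed, baseline=1 / 500.0, censor=2000.0,
                     p_treat=0.5):
    rng = np.random.default_rng(seed)
    x = (rng.uniform(size=n) < p_treat).astype(float)
    t = rng.exponential(1.0 / (baseline * np.exp(log_hr * x)))
    return pd.DataFrame({"x": x, "rfs_days": np.minimum(t, censor),
                         "event": (t <= censor).astype(int)})


class TestCoxFit:
    def test_constant_covariate_rejected(self):
        tab = simulate_two_arm(50, 0.0, 0)
        tab["z"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(tab, ["z"])

    def test_matches_grid_search_oracle_n40(self):
        """Estimate equals brute-force grid maximization of the written-out
        Breslow partial likelihood to 1e-4."""
        tab = simulate_two_arm(40, math.log(3.0), seed=21)
        fit = cox_fit(tab, ["x"], ties="breslow")
        grid = np.arange(-4.0, 4.0, 1e-4)
        ll = breslow_log_partial_likelihood(
            grid, tab["rfs_days"].to_numpy(), tab["event"].to_numpy(),
            tab["x"].to_numpy())
        beta_star = grid[ll.argmax()]
        assert fit.estimates[0] == pytest.approx(beta_star, abs=1e-4)
        # and the fit's log-likelihood equals the oracle at the maximizer
        assert fit.log_likelihood == pytest.approx(
            float(breslow_log_partial_likelihood(fit.estimates[0],
                                                 tab["rfs_days"].to_numpy(),
                                                 tab["event"].to_numpy(),
                                                 tab["x"].to_numpy())[0]))

    def test_hr_ci_consistency(self):
        tab = simulate_two_arm(200, 1.0, 3)
        fit = cox_fit(tab, ["x"])
        assert fit.hr[0] == pytest.approx(math.exp(fit.estimates[0]))
        assert fit.ci_low[0] == pytest.approx(
            math.exp(fit.estimates[0] - 1.959963984540054 * fit.se[0]))

    def test_consistency_bias_shrinks_with_n(self):
        """Two-group exponential simulation: log-HR bias → 0 as n grows."""
        true = math.log(3.0)
        bias = {}
        for n in (100, 500, 2000):
            est = [cox_fit(simulate_two_arm(n, true, seed=100 * n + s), ["x"])
                   .estimates[0] for s in range(10)]
            bias[n] = abs(np.mean(est) - true)
        assert bias[2000] < bias[100]
        assert bias[2000] < 0.1

    def test_paper_effect_sizes_recovered(self):
        """Cohort generated at the reported effect sizes (HR 7.162 for R1,
        0.246 for high edge-SD): both recovered within 15% at n=2000."""
        tab = generate_cohort(CohortParams(n_patients=2000, seed=5))
        tab["high_sd"] = 1 - tab["low_sd"]
        fit = cox_fit(tab, ["r1", "high_sd"])
        hr_r1, hr_sd = fit.hr
        assert abs(hr_r1 - 7.162) / 7.162 < 0.15
        assert abs(hr_sd - 0.246) / 0.246 < 0.15

    def test_monotone_likelihood_flagged_not_crash(self):
        # binary covariate perfectly ordered with event times -> beta diverges
        n = 20
        tab = pd.DataFrame({
            "rfs_days": np.arange(1, n + 1, dtype=float),
            "event": np.ones(n, dtype=int),
            "x": np.r_[np.ones(10), np.zeros(10)],
        })
        fit = cox_fit(tab, ["x"])
        assert fit.converged is False

    def test_no_events_rejected(self):
        tab = simulate_two_arm(30, 0.0, 1)
        tab["event"] = 0
        with pytest.raises(ValueError, match="event"):
            cox_fit(tab, ["x"])


class TestStepwise:
    def test_selects_single_true_predictor(self):
        """One strong binary predictor among 5 noise covariates at n=500:
        the true predictor enters first in ≥90% of 50 seeds, and extra noise
        inclusions stay below the α-driven bound (< 25% of seeds — at
        α=0.05 forward selection admits some noise covariate with
        probability ≈ 1 − 0.95⁵)."""
        true_first = 0
        contaminated = 0
        for seed in range(50):
            rng = np.random.default_rng(10_000 + seed)
            tab = simulate_two_arm(500, math.log(7.0), seed=20_000 + seed)
            for j in range(5):
                tab[f"noise{j}"] = rng.normal(size=500)
            res = stepwise_lr(tab, ["x"] + [f"noise{j}" for j in range(5)])
            if res.selected and res.selected[0] == "x":
                true_first += 1
            if any(c != "x" for c in res.selected):
                contaminated += 1
        assert true_first >= 45
        assert contaminated < 13

    def test_all_noise_rarely_selects(self):
        """Null cohorts: any covariate enters in < 25% of 100 seeds."""
        false_pos = 0
        for seed in range(100):
            rng = np.random.default_rng(30_000 + seed)
            tab = simulate_two_arm(500, 0.0, seed=40_000 + seed)
            tab = tab.drop(columns=["x"])
            for j in range(5):
                tab[f"noise{j}"] = rng.normal(size=500)
            res = stepwise_lr(tab, [f"noise{j}" for j in range(5)])
            if res.selected:
                false_pos += 1
        assert false_pos < 25

    def test_duplicate_covariate_enters_once(self):
        tab = simulate_two_arm(300, math.log(5.0), seed=9)
        tab["x_copy"] = tab["x"]
        res = stepwise_lr(tab, ["x", "x_copy"])
        assert len(res.selected) == 1

    def test_no_candidate_passes_screen_returns_null_model(self):
        tab = simulate_two_arm(100, 0.0, seed=77)
        rng = np.random.default_rng(78)
        tab["z"] = rng.normal(size=100)
        res = stepwise_lr(tab, ["z"])
        if not res.selected:  # overwhelmingly likely under the null
            assert res.fit is None
            assert "no candidate" in res.status or "no covariate" in res.status

    def test_selection_path_recorded(self):
        tab = generate_cohort(CohortParams(n_patients=400, seed=2))
        res = stepwise_lr(tab, ["r1", "low_sd"])
        steps = [p["step"] for p in res.path]
        assert steps[0] == "screen"
        assert "add" in steps


class TestKMLogrank:
    def test_product_limit_by_hand(self):
        # group A: times {1,2,3} all events -> S = 2/3, 1/3, 0
        times = [1, 2, 3, 10, 10, 10]
        events = [1, 1, 1, 0, 0, 0]
        groups = ["a", "a", "a", "b", "b", "b"]
        res = km_logrank(times, events, groups)
        curve = res.curves["a"].set_index("time")["survival"]
        assert curve[1] == pytest.approx(2 / 3)
        assert curve[2] == pytest.approx(1 / 3)
        assert curve[3] == pytest.approx(0.0)

    def test_km_without_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(100, 80)
        res = km_logrank(np.r_[t, t], np.ones(160, int),
                         np.r_[np.zeros(80), np.ones(80)])
        curve = res.curves[0.0]
        emp = 1.0 - np.searchsorted(np.sort(t), curve["time"], side="right") / 80
        assert curve["survival"].to_numpy() == pytest.approx(emp)

    def test_identical_groups_null_statistic(self):
        t = [5, 10, 15, 20]
        e = [1, 1, 0, 1]
        res = km_logrank(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_effect_power(self):
        """HR 7 at n=500: log-rank p < 0.001 in ≥95% of 100 seeds."""
        hits = 0
        for seed in range(100):
            tab = simulate_two_arm(500, math.log(7.0), seed=50_000 + seed)
            res = km_logrank(tab["rfs_days"], tab["event"], tab["x"])
            if res.p_value < 0.001:
                hits += 1
        assert hits >= 95

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3], [1, 1, 1], ["a", "a", "a"])


def enumerate_fisher_p(a, b, c, d):
    """Full hypergeometric enumeration over tables with fixed margins."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, col1, row1)
    ks = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(ks)
    p_obs = rv.pmf(a)
    return probs[probs <= p_obs * (1 + 1e-9)].sum()


class TestFisher:
    def test_reconstructed_margin_table(self):
        """R1 7/8 relapsed vs R0 11/33: two-sided p ≈ 0.0133."""
        oratio, p = fisher_exact_2x2(7, 1, 11, 22)
        assert p == pytest.approx(0.0133, abs=0.0005)
        assert oratio == pytest.approx(7 * 22 / 11)

    def test_n2_table_p_one(self):
        _, p = fisher_exact_2x2(1, 0, 0, 1)
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 25, 4)
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(enumerate_fisher_p(a, b, c, d), abs=1e-9)

    def test_symmetric_under_row_and_column_swap(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(0, 20, 4))
            if a + b + c + d == 0:
                continue
            _, p1 = fisher_exact_2x2(a, b, c, d)
            _, p2 = fisher_exact_2x2(d, c, b, a)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_undefined_odds_ratio_flagged(self):
        oratio, _ = fisher_exact_2x2(3, 0, 2, 5)
        assert np.isnan(oratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestRelapseScore:
    @pytest.mark.parametrize("margin,sd,expected", [
        ("R0", 10.0, 0),
        ("R1", 1.0, 2),
        ("R0", 1.0, 1),
        ("R1", 10.0, 1),
    ])
    def test_score_values(self, margin, sd, expected):
        assert relapse_score(margin, sd).score == expected

    def test_cutoff_boundary_not_low(self):
        assert relapse_score("R0", 5.8).score == 0  # strict '<' rule

    def test_missing_sd_gives_missing_score(self):
        assert relapse_score("R0", float("nan")) is None

    def test_invalid_margin_rejected(self):
        with pytest.raises(ValueError):
            relapse_score("RX", 3.0)

    def test_score_monotone_in_risk(self):
        """Simulated median RFS is ordered score 0 > 1 > 2."""
        tab = generate_cohort(CohortParams(n_patients=6000, seed=8,
                                           censor_time_days=1e9))
        tab["score"] = tab["r1"] + tab["low_sd"]
        med = tab.groupby("score")["rfs_days"].median()
        assert med[0] > med[1] > med[2]


class TestScoreStratification:
    def test_all_zero_scores_skips_both_contrasts(self):
        tab = pd.DataFrame({"score": [0, 0, 0], "rfs_days": [1, 2, 3],
                            "event": [1, 1, 0]})
        res = score_stratification(tab)
        assert res["0_vs_12"] is None and res["01_vs_2"] is None

    def test_contrast_depends_only_on_partition(self):
        tab = generate_cohort(CohortParams(n_patients=300, seed=12))
        tab["score"] = tab["r1"] + tab["low_sd"]
        swapped = tab.copy()
        ones = swapped["score"] == 1
        twos = swapped["score"] == 2
        # shuffling rows between the score-1 and score-2 labels inside the
        # {1,2} side cannot change the {0} vs {1,2} contrast
        res_a = score_stratification(tab)["0_vs_12"]
        swapped.loc[ones | twos, "score"] = np.random.default_rng(0).permutation(
            swapped.loc[ones | twos, "score"].to_numpy())
        res_b = score_stratification(swapped)["0_vs_12"]
        assert res_a.chi2 == pytest.approx(res_b.chi2)

    def test_both_contrasts_powered_at_n500(self):
        """At the reported effect sizes, both contrasts reach p < 0.01 in
        ≥90% of 50 seeds at n=500."""
        hits = 0
        for seed in range(50):
            tab = generate_cohort(CohortParams(n_patients=500, seed=60_000 + seed))
            tab["score"] = tab["r1"] + tab["low_sd"]
            res = score_stratification(tab)
            if (res["0_vs_12"] is not None and res["01_vs_2"] is not None
                    and res["0_vs_12"].p_value < 0.01
                    and res["01_vs_2"].p_value < 0.01):
                hits += 1
        assert hits >= 45

    def test_score_table_from_margin_and_sd(self):
        tab = pd.DataFrame({"margin": ["R0", "R1", "R1"],
                            "edge_sd": [10.0, 2.0, np.nan]})
        out = score_table(tab)
        assert out["score"].tolist()[:2] == [0, 2]
        assert np.isnan(out["score"].iloc[2])
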