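"""Exclusion filters and the exact-test statistics, each checked against an
independent brute-force oracle where one exists."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from blockmaze.analysis import (
    ExclusionCriteria,
    apply_exclusions,
    adjust_p,
    binomial_two_sided,
    bonferroni,
    compare_groups,
    correlate_better_solves,
    fisher_exact_2x2,
    power_min_n,
    proportion_ci,
    spearman,
    summarize_conditions,
)


def make_responses(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "task",
            "trial_index",
            "pair_id",
            "condition",
            "both_outcome",
            "chose_predicted",
            "predicted_on_left",
            "response_time",
            "total_time",
            "eval_correct",
            "attention_pass",
        ],
    )


def participant_rows(pid, n_trials=5, task="Better", condition="AE",
                     outcome="success", chose=True, rt=20.0, total=1500.0,
                     eval_correct=5, attention=True, pair0=0):
    return [
        (pid, task, t, pair0 + t, condition, outcome, chose, True, rt, total,
         eval_correct, attention)
        for t in range(n_trials)
    ]


class TestExclusions:
    def test_short_total_time_excluded(self):
        df = make_responses(
            participant_rows(0, total=540.0) + participant_rows(1)
        )
        filtered, log = apply_exclusions(df, ExclusionCriteria())
        assert set(filtered["participant"]) == {1}
        assert log.iloc[0]["rules"] == "min_total_time"

    def test_two_eval_errors_excluded(self):
        df = make_responses(
            participant_rows(0, eval_correct=3) + participant_rows(1)
        )
        filtered, log = apply_exclusions(df, ExclusionCriteria())
        assert set(filtered["participant"]) == {1}
        assert "max_eval_errors" in log.iloc[0]["rules"]

    def test_fast_median_and_floor_rules(self):
        df = make_responses(
            participant_rows(0, rt=8.0) + participant_rows(1, rt=2.0)
        )
        filtered, log = apply_exclusions(df, ExclusionCriteria())
        assert filtered.empty
        rules = dict(zip(log["participant"], log["rules"]))
        assert "min_median_trial_rt" in rules[0]
        assert "min_trial_rt_floor" in rules[1]

    def test_attention_check(self):
        df = make_responses(participant_rows(0, attention=False))
        filtered, _ = apply_exclusions(df, ExclusionCriteria())
        assert filtered.empty

    def test_compliant_table_unchanged_and_idempotent(self):
        df = make_responses(participant_rows(0) + participant_rows(1))
        once, log = apply_exclusions(df, ExclusionCriteria())
        twice, _ = apply_exclusions(once, ExclusionCriteria())
        assert once.equals(df.reset_index(drop=True))
        assert twice.equals(once)
        assert log.empty


class TestBinomial:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (5, 5, 0.0625),  # 2 * (1/32)
            (8, 10, 0.109375),  # 2 * (45 + 10 + 1) / 1024
            (5, 10, 1.0),
            (0, 5, 0.0625),
        ],
    )
    def test_frozen_values(self, k, n, expected):
        assert binomial_two_sided(k, n, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_minlike_matches_enumeration_oracle(self):
        # oracle: sum pmf over all outcomes no more likely than observed
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(1, 15))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.choice([0.3, 0.5, 0.7]))
            pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
            oracle = sum(q for q in pmf if q <= pmf[k] * (1 + 1e-12))
            assert binomial_two_sided(k, n, p0) == pytest.approx(oracle, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_two_sided(6, 5)


class TestProportionCI:
    def test_half_at_hundred(self):
        lo, hi, degenerate = proportion_ci(50, 100)
        assert lo == pytest.approx(0.402, abs=5e-4)
        assert hi == pytest.approx(0.598, abs=5e-4)
        assert not degenerate

    def test_boundary_degenerate(self):
        lo, hi, degenerate = proportion_ci(0, 20)
        assert (lo, hi) == (0.0, 0.0) and degenerate

    def test_empirical_coverage(self):
        # n=200, p=0.6: normal-approximation interval should cover ~95%
        rng = np.random.default_rng(42)
        n, p, reps = 200, 0.6, 10_000
        ks = rng.binomial(n, p, size=reps)
        mu = ks / n
        half = 1.959963984540054 * np.sqrt(mu * (1 - mu) / n)
        covered = np.mean((mu - half <= p) & (p <= mu + half))
        assert 0.93 <= covered <= 0.97


class TestBonferroni:
    def test_family_threshold(self):
        assert bonferroni(0.005, 6) == pytest.approx(0.005 / 6)

    def test_identity_at_one(self):
        assert bonferroni(0.05, 1) == 0.05
        assert adjust_p(0.03, 1) == 0.03

    def test_adjusted_p_clips(self):
        assert adjust_p(0.3, 6) == 1.0


def _fisher_oracle(table):
    """Hypergeometric enumeration over all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        q = prob(x)
        if q <= p_obs * (1 + 1e-12):
            total += q
    return total


class TestFisher:
    def test_perfect_independence(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_separation_frozen_value(self):
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9
        )

    def test_matches_enumeration_oracle_on_small_tables(self):
        for total in range(1, 13):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        table = [[a, b], [c, d]]
                        assert fisher_exact_2x2(table) == pytest.approx(
                            _fisher_oracle(table), rel=1e-9
                        ), table

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestSpearman:
    def test_monotone_extremes(self):
        rho, _ = spearman([1, 2, 3, 5], [10, 20, 21, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 5], [9, 7, 3, 1])
        assert rho == pytest.approx(-1.0)

    def test_exact_permutation_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for n in (4, 5, 6):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, p = spearman(x, y)
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            obs = abs(np.corrcoef(rx, ry)[0, 1])
            hits = total = 0
            for perm in itertools.permutations(ry):
                total += 1
                hits += abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
            assert p == pytest.approx(hits / total, rel=1e-9)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestSummarize:
    def test_unanimous_table(self):
        df = make_responses(
            participant_rows(0, condition="RE") + participant_rows(1, condition="RE")
        )
        (summary,) = summarize_conditions(df)
        assert summary.mu == 1.0
        assert summary.p_value == pytest.approx(2 * 0.5**summary.n)
        assert summary.k == summary.n == 10

    def test_drop_ae_failures_touches_only_ae(self):
        rows = (
            participant_rows(0, condition="AE", outcome="failure")
            + participant_rows(1, condition="AE", outcome="success", pair0=10)
            + participant_rows(2, condition="RE", outcome="failure", pair0=20)
            + participant_rows(3, condition="GEN", outcome="success", pair0=30)
        )
        df = make_responses(rows)
        with_drop = {s.condition: s.n for s in summarize_conditions(df, True)}
        without = {s.condition: s.n for s in summarize_conditions(df, False)}
        assert with_drop["AE"] == 5 and without["AE"] == 10
        assert with_drop["RE"] == without["RE"] == 5
        assert with_drop["GEN"] == without["GEN"] == 5

    def test_per_trial_multiplicity(self):
        rows = []
        for pid in range(4):
            rows += participant_rows(pid, n_trials=3, condition="GEN")
        df = make_responses(rows)
        summaries = summarize_conditions(df, per_trial=True)
        assert len(summaries) == 3  # one per stimulus pair
        assert all(s.n_tests == 3 for s in summaries)


class TestGroupAnalyses:
    @staticmethod
    def _two_task_table(rng, p_better, p_solves, n_pairs=20, reps=25,
                        condition="GEN", outcome="success"):
        rows = []
        pid = 0
        for task, p_choose in (("Better", p_better), ("Solves", p_solves)):
            for _ in range(reps):
                for pair in range(n_pairs):
                    rows.append(
                        (pid, task, pair, pair, condition, outcome,
                         bool(rng.random() < p_choose), True, 20.0, 1500.0, 5, True)
                    )
                pid += 1
        return make_responses(rows)

    def test_identical_behavior_correlates_perfectly(self):
        # duplicate one task's responses into the other: per-pair choice
        # fractions then agree exactly, so ranks match and rho = 1
        df = self._two_task_table(np.random.default_rng(0), 0.6, 0.6)
        frames = []
        for task in ("Better", "Solves"):
            sub = df[df.task == "Better"].copy()
            sub["task"] = task
            frames.append(sub)
        identical = pd.concat(frames, ignore_index=True)
        (corr,) = correlate_better_solves(identical)
        assert corr.rho == pytest.approx(1.0)

    def test_independent_behavior_has_null_correlation(self):
        rng = np.random.default_rng(11)
        rhos = []
        for _ in range(1000):
            frac_better = rng.random(15)
            frac_solves = rng.random(15)
            rx = stats.rankdata(frac_better)
            ry = stats.rankdata(frac_solves)
            rhos.append(np.corrcoef(rx, ry)[0, 1])
        se = np.std(rhos, ddof=1) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) <= 3 * se

    def test_ae_correlation_omits_failure_pairs(self):
        rng = np.random.default_rng(5)
        success = self._two_task_table(rng, 0.7, 0.6, n_pairs=6, condition="AE")
        failure = self._two_task_table(rng, 0.7, 0.6, n_pairs=4, condition="AE",
                                       outcome="failure")
        failure["pair_id"] += 6
        df = pd.concat([success, failure], ignore_index=True)
        (corr,) = correlate_better_solves(df)
        assert corr.n_pairs == 6
        assert corr.failure_handling == "omitted"

    def test_fisher_contrast_detects_group_shift(self):
        rng = np.random.default_rng(9)
        df = self._two_task_table(rng, 0.9, 0.55, reps=40)
        (comp,) = compare_groups(df)
        assert comp.fisher_p < 1e-6
        chose_better = comp.contingency[0][0]
        assert chose_better == int(
            df[(df.task == "Better")]["chose_predicted"].sum()
        )


class TestPower:
    def test_certain_effect_needs_six_trials(self):
        # k=n first rejects at n=6 (two-sided p = 2/64 < .05)
        assert power_min_n(1.0, alpha=0.05, target_power=0.95) == 6

    def test_zero_target_is_immediate(self):
        assert power_min_n(0.7, alpha=0.05, target_power=0.0) == 1

    def test_exact_power_matches_monte_carlo(self):
        mu, alpha = 0.6, 0.001
        n = power_min_n(mu, alpha=alpha, target_power=0.95)
        # rebuild the rejection region and estimate power by simulation
        k = np.arange(n + 1)
        pmf0 = stats.binom.pmf(k, n, 0.5)
        order = np.argsort(pmf0, kind="stable")
        csum = np.cumsum(pmf0[order])
        j = np.searchsorted(pmf0[order], pmf0 + 1e-15, side="right") - 1
        region = csum[j] <= alpha
        rng = np.random.default_rng(8)
        draws = rng.binomial(n, mu, size=100_000)
        mc_power = np.mean(region[draws])
        exact_power = float(stats.binom.pmf(k[region], n, mu).sum())
        se = math.sqrt(mc_power * (1 - mc_power) / 100_000)
        assert abs(mc_power - exact_power) <= 3 * se
        assert exact_power >= 0.95

    def test_invalid_mu(self):
        with pytest.raises(ValueError):
            power_min_n(0.5)
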