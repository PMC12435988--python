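"""Exclusion filtering and the two-alternative forced-choice statistics.

Per condition (and task group) the fraction μ of trials choosing the
predicted program is tested against the chance baseline P = .5 with an exact
two-sided binomial test (minimal-likelihood convention), Bonferroni-corrected
across the condition×task family; 95% intervals use the normal approximation
for a binomial proportion.  Group contrasts use Fisher's exact test on the
2×2 task×choice table, and cross-task consistency uses Spearman correlations
of per-pair choice fractions.  Trials where both programs *fail* are dropped
from the action-efficiency condition before summarizing (a more efficient
failure is not a better behavior), but kept in representation efficiency,
whose metric does not depend on behavior.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExclusionCriteria",
    "ConditionSummary",
    "GroupComparison",
    "TrialCorrelation",
    "apply_exclusions",
    "binomial_two_sided",
    "proportion_ci",
    "bonferroni",
    "adjust_p",
    "fisher_exact_2x2",
    "spearman",
    "summarize_conditions",
    "compare_groups",
    "correlate_better_solves",
    "power_min_n",
]


@dataclass(frozen=True)
class ExclusionCriteria:
    """Participant-level exclusion thresholds.

    Defaults mirror a pre-registered online-study protocol: drop participants
    whose whole session took under 10 minutes, whose median trial response
    time is under 10 seconds (the stimuli are ~23-second videos), who missed
    two or more of the five comprehension questions, or who failed the
    explicit attention check; ``min_trial_rt_floor`` additionally drops
    anyone with an implausibly fast (< 3 s) single response."""

    min_total_time: float = 600.0
    min_median_trial_rt: float = 10.0
    max_eval_errors: int = 1
    require_attention_pass: bool = True
    min_trial_rt_floor: Optional[float] = 3.0

    def __post_init__(self) -> None:
        if self.min_total_time < 0 or self.min_median_trial_rt < 0:
            raise ValueError("time thresholds must be non-negative")
        if self.max_eval_errors < 0:
            raise ValueError("max_eval_errors must be non-negative")


def apply_exclusions(
    responses: pd.DataFrame, criteria: ExclusionCriteria = ExclusionCriteria()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove whole participants violating any criterion.

    Returns (filtered table, exclusion log); the log has one row per excluded
    participant listing every rule that fired.  Idempotent by construction."""
    log_rows = []
    excluded: set = set()
    for pid, grp in responses.groupby("participant"):
        fired = []
        if float(grp["total_time"].iloc[0]) < criteria.min_total_time:
            fired.append("min_total_time")
        if float(grp["response_time"].median()) < criteria.min_median_trial_rt:
            fired.append("min_median_trial_rt")
        if int(5 - grp["eval_correct"].iloc[0]) > criteria.max_eval_errors:
            fired.append("max_eval_errors")
        if criteria.require_attention_pass and not bool(grp["attention_pass"].iloc[0]):
            fired.append("attention_check")
        if (
            criteria.min_trial_rt_floor is not None
            and float(grp["response_time"].min()) < criteria.min_trial_rt_floor
        ):
            fired.append("min_trial_rt_floor")
        if fired:
            excluded.add(pid)
            log_rows.append({"participant": pid, "rules": ";".join(fired)})
    filtered = responses[~responses["participant"].isin(excluded)].reset_index(drop=True)
    return filtered, pd.DataFrame(log_rows, columns=["participant", "rules"])


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (minimal-likelihood convention: sum
    the probabilities of all outcomes no more likely than the observed)."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    return float(stats.binomtest(k, n, p0).pvalue)


def proportion_ci(
    k: int, n: int, level: float = 0.95
) -> tuple[float, float, bool]:
    """Normal-approximation interval mu ± z·sqrt(mu(1-mu)/n), clipped to
    [0, 1].  The third element flags the degenerate boundary cases k=0, k=n
    where the interval collapses to a point."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mu = k / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(mu * (1.0 - mu) / n)
    return max(0.0, mu - half), min(1.0, mu + half), k in (0, n)


def bonferroni(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def adjust_p(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value min(1, m·p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2×2 count table (hypergeometric
    enumeration over tables with fixed margins)."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with its p-value: exact permutation null for
    n ≤ 8, the t-approximation otherwise.  Constant input is an error (the
    correlation is undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rho = _spearman_rho(x, y)
    if n <= 8:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    res = stats.spearmanr(x, y)
    return rho, float(res.pvalue)


@dataclass
class ConditionSummary:
    condition: str
    task: Optional[str]
    pair_id: Optional[int]  # set for per-trial summaries
    n: int
    k: int
    mu: float
    ci_low: float
    ci_high: float
    p_value: float
    baseline_p: float
    alpha: float
    n_tests: int
    significant: bool


def summarize_conditions(
    responses: pd.DataFrame,
    drop_ae_failures: bool = True,
    per_trial: bool = False,
    alpha: float = 0.05,
    baseline_p: float = 0.5,
) -> list[ConditionSummary]:
    """Per condition (× task when present, × stimulus pair when
    ``per_trial``): trials choosing the predicted program, the exact binomial
    test against the chance baseline, the 95% proportion interval, and the
    Bonferroni verdict with multiplicity equal to the number of summaries in
    the family."""
    df = responses
    if drop_ae_failures:
        df = df[~((df["condition"] == "AE") & (df["both_outcome"] == "failure"))]
    group_cols = ["condition"]
    if "task" in df.columns and df["task"].nunique() > 0:
        group_cols.append("task")
    if per_trial:
        group_cols.append("pair_id")
    grouped = df.groupby(group_cols, sort=True)
    cells = list(grouped)
    m = len(cells)
    if m == 0:
        raise ValueError("no data to summarize")
    out = []
    for key, grp in cells:
        if not isinstance(key, tuple):
            key = (key,)
        lut = dict(zip(group_cols, key))
        n = len(grp)
        k = int(grp["chose_predicted"].sum())
        p = binomial_two_sided(k, n, baseline_p)
        lo, hi, _ = proportion_ci(k, n)
        out.append(
            ConditionSummary(
                condition=str(lut["condition"]),
                task=str(lut["task"]) if "task" in lut else None,
                pair_id=int(lut["pair_id"]) if "pair_id" in lut else None,
                n=n,
                k=k,
                mu=k / n,
                ci_low=lo,
                ci_high=hi,
                p_value=p,
                baseline_p=baseline_p,
                alpha=alpha,
                n_tests=m,
                significant=p <= bonferroni(alpha, m),
            )
        )
    return out


@dataclass
class GroupComparison:
    condition: str
    contingency: tuple[tuple[int, int], tuple[int, int]]  # (task × chose_predicted)
    fisher_p: float
    tasks: tuple[str, str]


def compare_groups(
    responses: pd.DataFrame, drop_ae_failures: bool = True
) -> list[GroupComparison]:
    """Fisher exact contrast of the two task groups' choice counts, one 2×2
    table per condition."""
    tasks = sorted(responses["task"].unique())
    if len(tasks) != 2:
        raise ValueError("need exactly two task groups")
    df = responses
    if drop_ae_failures:
        df = df[~((df["condition"] == "AE") & (df["both_outcome"] == "failure"))]
    out = []
    for cond, grp in df.groupby("condition", sort=True):
        table = []
        for t in tasks:
            sub = grp[grp["task"] == t]
            chose = int(sub["chose_predicted"].sum())
            table.append((chose, int(len(sub) - chose)))
        out.append(
            GroupComparison(
                condition=str(cond),
                contingency=(tuple(table[0]), tuple(table[1])),
                fisher_p=fisher_exact_2x2(table),
                tasks=(tasks[0], tasks[1]),
            )
        )
    return out


@dataclass
class TrialCorrelation:
    condition: str
    rho: float
    p_value: float
    n_pairs: int
    points: pd.DataFrame  # per-pair choice fractions in each task
    failure_handling: str  # "omitted" | "included" | "n/a"


def correlate_better_solves(
    responses: pd.DataFrame, min_pairs: int = 3
) -> list[TrialCorrelation]:
    """Spearman correlation, per condition, between each stimulus pair's
    choice fraction in the two task groups (one point per pair).

    Both-fail pairs are omitted from the action-efficiency correlation but
    included in representation efficiency; generalization pairs are all
    both-success by construction.  Pairs missing a task are dropped."""
    tasks = sorted(responses["task"].unique())
    if len(tasks) != 2:
        raise ValueError("need exactly two task groups")
    t1, t2 = tasks
    out = []
    for cond, grp in responses.groupby("condition", sort=True):
        handling = "n/a"
        if cond == "AE":
            grp = grp[grp["both_outcome"] != "failure"]
            handling = "omitted"
        elif cond == "RE":
            handling = "included"
        frac = (
            grp.groupby(["pair_id", "task"])["chose_predicted"]
            .mean()
            .unstack("task")
        )
        frac = frac.dropna()
        if len(frac) < min_pairs:
            import logging

            logging.getLogger(__name__).warning(
                "condition %s: only %d complete pairs (need %d); skipping "
                "its correlation",
                cond,
                len(frac),
                min_pairs,
            )
            continue
        rho, p = spearman(frac[t1].to_numpy(), frac[t2].to_numpy())
        out.append(
            TrialCorrelation(
                condition=str(cond),
                rho=rho,
                p_value=p,
                n_pairs=len(frac),
                points=frac.reset_index(),
                failure_handling=handling,
            )
        )
    return out


def power_min_n(
    true_mu: float,
    alpha: float = 0.001,
    target_power: float = 0.95,
    two_sided: bool = True,
    p0: float = 0.5,
    n_max: int = 20000,
) -> int:
    """Smallest n at which the exact binomial test against ``p0`` rejects
    with probability ≥ ``target_power`` when the true proportion is
    ``true_mu`` (rejection region built from exact minimal-likelihood
    p-values; power summed exactly under the alternative)."""
    if not p0 < true_mu <= 1.0:
        raise ValueError("true_mu must exceed p0 (and be at most 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for n in range(1, n_max + 1):
        k = np.arange(n + 1)
        pmf0 = stats.binom.pmf(k, n, p0)
        if two_sided:
            # minlike p-value of k sums all outcomes whose pmf does not
            # exceed pmf[k]; vectorized via sorted cumulative sums
            order = np.argsort(pmf0, kind="stable")
            sorted_pmf = pmf0[order]
            csum = np.cumsum(sorted_pmf)
            j = np.searchsorted(sorted_pmf, pmf0 + 1e-15, side="right") - 1
            pvals = csum[j]
        else:
            pvals = stats.binom.sf(k - 1, n, p0)
        region = pvals <= alpha
        power = float(stats.binom.pmf(k[region], n, true_mu).sum())
        if power >= target_power:
            return n
    raise ValueError(f"target power not reached by n = {n_max}")
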