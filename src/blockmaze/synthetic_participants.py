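"""Synthetic observers and response-table simulation.

This is the package's stand-in for human two-alternative choice data.  An
observer weighs the standardized metric differences of a stimulus pair
(predicted program minus the other) and chooses the predicted program with
probability

    lapse/2 + (1 - lapse) * logistic(beta * (w_ae*Δ̃ae + w_re*Δ̃re + w_gen*Δ̃gen))

Standardizers are the pooled standard deviations of metric differences
across the stimulus set, putting actions, blocks, and solved fractions on a
common scale so weights are comparable.  Three presets contrast evaluation
styles: a *behaviorist* weighs only the behavioral metric, a *cognitivist*
weighs all three, and a *solves-instructed* observer is dominated by the
generalization weight (modeling the instruction "choose the program that
solves more mazes" as a weight change).

None of these parameters are claims about human data; they exist to give the
analysis layer inputs with a realistic statistical structure, including
low-effort participants that the exclusion filters should catch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .stimuli import StimulusPair, StimulusSet

__all__ = [
    "ObserverModel",
    "Participant",
    "WeightFit",
    "OBSERVER_PRESETS",
    "standardizers_from_set",
    "metric_differences",
    "choice_probability",
    "choice_probability_from_diffs",
    "make_population",
    "simulate_experiment",
    "recover_weights",
    "RESPONSE_COLUMNS",
]

RESPONSE_COLUMNS = [
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
]


@dataclass(frozen=True)
class ObserverModel:
    w_ae: float
    w_re: float
    w_gen: float
    beta: float = 1.0
    lapse: float = 0.0
    standardizers: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")
        if min(self.w_ae, self.w_re, self.w_gen) < 0:
            raise ValueError("weights must be non-negative")
        if any(s <= 0 for s in self.standardizers):
            raise ValueError("standardizers must be positive")


#: Preset weights (w_ae, w_re, w_gen, lapse).  The solves-instructed preset
#: shares the cognitivist generalization weight but sharply reduced
#: efficiency weights, so group differences appear in the AE/RE conditions
#: and not in GEN.
OBSERVER_PRESETS: dict[str, dict] = {
    "behaviorist": {"w_ae": 2.0, "w_re": 0.0, "w_gen": 0.0, "lapse": 0.05},
    "cognitivist": {"w_ae": 2.0, "w_re": 1.0, "w_gen": 0.6, "lapse": 0.05},
    "solves": {"w_ae": 0.3, "w_re": 0.1, "w_gen": 0.6, "lapse": 0.05},
}


@dataclass(frozen=True)
class Participant:
    id: int
    task: str  # "Better" | "Solves"
    observer: ObserverModel
    rt_location: float  # log-seconds, per-trial response-time distribution
    rt_scale: float
    attention_pass_prob: float = 0.98
    eval_error_prob: float = 0.05


def metric_differences(pair: StimulusPair) -> tuple[float, float, float]:
    """Raw metric differences, predicted program minus the other."""
    m1, m2 = pair.metrics_1, pair.metrics_2
    if pair.predicted == 2:
        m1, m2 = m2, m1
    return (
        float(m1.action_efficiency - m2.action_efficiency),
        float(m1.representation_efficiency - m2.representation_efficiency),
        float(m1.generalization - m2.generalization),
    )


def standardizers_from_set(stimulus_set: StimulusSet) -> tuple[float, float, float]:
    """Pooled standard deviations of metric differences across all pairs
    (zero-variance columns fall back to 1 so degenerate sets stay usable)."""
    diffs = np.array([metric_differences(p) for p in stimulus_set.pairs], dtype=float)
    sds = diffs.std(axis=0, ddof=0)
    return tuple(float(s) if s > 1e-12 else 1.0 for s in sds)


def choice_probability_from_diffs(
    obs: ObserverModel, d_ae: float, d_re: float, d_gen: float
) -> float:
    s_ae, s_re, s_gen = obs.standardizers
    z = obs.beta * (
        obs.w_ae * d_ae / s_ae + obs.w_re * d_re / s_re + obs.w_gen * d_gen / s_gen
    )
    p = 1.0 / (1.0 + math.exp(-z))
    return obs.lapse / 2.0 + (1.0 - obs.lapse) * p


def choice_probability(obs: ObserverModel, pair: StimulusPair) -> float:
    """Probability that the observer chooses the predicted program."""
    return choice_probability_from_diffs(obs, *metric_differences(pair))


def make_population(
    n: int,
    task: str,
    preset: str | ObserverModel,
    stimulus_set: StimulusSet,
    seed: int = 0,
    rt_location_mean: float = math.log(23.0),
    rt_location_sd: float = 0.3,
    rt_scale: float = 0.5,
) -> list[Participant]:
    """Build ``n`` participants for one task group.

    Response-time locations vary across participants around a 23-second
    median trial time; together with the attention and evaluation-question
    error rates, roughly 5% of a default population lands below one of the
    exclusion thresholds — enough to exercise the filters."""
    if task not in ("Better", "Solves"):
        raise ValueError("task must be 'Better' or 'Solves'")
    rng = np.random.default_rng(seed)
    std = standardizers_from_set(stimulus_set)
    if isinstance(preset, ObserverModel):
        obs = replace(preset, standardizers=std)
    else:
        obs = ObserverModel(standardizers=std, **OBSERVER_PRESETS[preset])
    out = []
    for i in range(n):
        out.append(
            Participant(
                id=i,
                task=task,
                observer=obs,
                rt_location=float(rng.normal(rt_location_mean, rt_location_sd)),
                rt_scale=rt_scale,
            )
        )
    return out


def simulate_experiment(
    design: pd.DataFrame,
    participants: Sequence[Participant],
    stimulus_set: StimulusSet,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one task group over an assignment table.

    Each design row yields one response row: the choice is Bernoulli with the
    observer's choice probability, trial response times are log-normal, and
    total time, evaluation-question score, and the attention flag are drawn
    per participant.  Fully reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    by_id = {p.id: p for p in participants}
    missing = set(design["participant"]) - set(by_id)
    if missing:
        raise ValueError(f"design references unknown participants: {sorted(missing)[:5]}")
    pairs = stimulus_set.pairs

    # participant-level draws
    part_rows: dict[int, dict] = {}
    for pid in sorted(set(design["participant"])):
        p = by_id[pid]
        n_trials = int((design["participant"] == pid).sum())
        rts = np.exp(rng.normal(p.rt_location, p.rt_scale, size=n_trials))
        # total time = instruction/training overhead plus the trial times
        overhead = float(np.exp(rng.normal(math.log(900.0), 0.35)))
        part_rows[pid] = {
            "rts": list(rts),
            "total_time": overhead + float(rts.sum()),
            "eval_correct": int(5 - rng.binomial(5, p.eval_error_prob)),
            "attention_pass": bool(rng.random() < p.attention_pass_prob),
        }

    rows = []
    for rec in design.itertuples(index=False):
        p = by_id[rec.participant]
        pair = pairs[rec.pair_id]
        prob = choice_probability(p.observer, pair)
        info = part_rows[rec.participant]
        rows.append(
            {
                "participant": p.id,
                "task": p.task,
                "trial_index": int(rec.trial_index),
                "pair_id": int(rec.pair_id),
                "condition": pair.condition,
                "both_outcome": pair.both_outcome,
                "chose_predicted": bool(rng.random() < prob),
                "predicted_on_left": bool(rec.predicted_on_left),
                "response_time": float(info["rts"].pop()),
                "total_time": float(info["total_time"]),
                "eval_correct": int(info["eval_correct"]),
                "attention_pass": bool(info["attention_pass"]),
            }
        )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


@dataclass
class WeightFit:
    estimates: dict[str, float]
    std_errors: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    converged: bool
    degenerate: bool
    message: str = ""


def recover_weights(
    responses: pd.DataFrame,
    stimulus_set: StimulusSet,
    lapse: float = 0.0,
) -> WeightFit:
    """Maximum-likelihood refit of the choice model on a response table.

    Fits logistic coefficients on the standardized metric differences with
    the inverse temperature absorbed (beta ≡ 1, lapse fixed), reporting Wald
    95% intervals.  Degenerate data — constant choices or perfect
    separation — are flagged, not silently fit."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if responses.empty:
        raise ValueError("empty response table")
    if lapse != 0.0:
        raise NotImplementedError("only the lapse-free fit is implemented")
    std = standardizers_from_set(stimulus_set)
    diffs = np.array(
        [metric_differences(p) for p in stimulus_set.pairs], dtype=float
    ) / np.array(std)
    X = diffs[responses["pair_id"].to_numpy()]
    y = responses["chose_predicted"].to_numpy(dtype=float)

    names = ["w_ae", "w_re", "w_gen"]
    if y.min() == y.max():
        return WeightFit({}, {}, {}, False, True, "all choices identical")
    try:
        model = sm.Logit(y, X)
        res = model.fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return WeightFit({}, {}, {}, False, True, f"degenerate fit: {exc}")
    ci = res.conf_int(alpha=0.05)
    return WeightFit(
        estimates=dict(zip(names, map(float, res.params))),
        std_errors=dict(zip(names, map(float, res.bse))),
        conf_int={n: (float(ci[i][0]), float(ci[i][1])) for i, n in enumerate(names)},
        converged=bool(res.mle_retvals.get("converged", False)),
        degenerate=bool(np.any(~np.isfinite(res.bse)) or np.any(res.bse > 1e3)),
    )
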