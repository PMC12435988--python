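"""Automatic stimulus generation.

Programs are sampled from a probabilistic context-free grammar over the block
language, filtered to at most ``max_blocks`` blocks (not counting the default
Repeat wrapper), and deduplicated by canonical serialization.  Matched
stimulus pairs are then found by searching program×maze combinations for
pairs that are equal (or nearly equal, for generalization) in two metrics and
substantially different in the third, with both programs sharing the same
run outcome on the displayed maze.  Generalization pairs are restricted to
both-success at generation time: efficiently *failing* is not a difference
the choice model is meant to explain, and the search space contains
essentially no both-fail pairs with an order-of-magnitude solved-fraction gap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .blockdsl import (
    ATOMIC_KINDS,
    CONDITIONAL_KINDS,
    Block,
    BlockKind,
    Program,
    program_length,
    serialize_program,
)
from .interpreter import run_program, default_step_cap
from .mazegen import Maze, MazeGenParams, MazeSample
from .metrics import MetricTriple, generalization_mc, representation_efficiency

__all__ = [
    "GrammarConfig",
    "PairTolerances",
    "StimulusPair",
    "StimulusSet",
    "CONDITIONS",
    "sample_programs",
    "find_matched_pairs",
    "verify_pair",
    "assign_trials",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("AE", "RE", "GEN")

_SAMPLED_KINDS = tuple(sorted(ATOMIC_KINDS | CONDITIONAL_KINDS, key=lambda k: k.value))
_SAMPLED_ATOMICS = tuple(sorted(ATOMIC_KINDS, key=lambda k: k.value))


@dataclass(frozen=True)
class GrammarConfig:
    """PCFG over program bodies.

    Statement lists continue with probability ``p_continue`` (geometric
    length); block kinds are drawn uniformly from the six movement/conditional
    kinds at nesting depth < ``max_depth`` and from the three atomic kinds at
    the depth limit; conditionals carry an Else socket with probability
    ``p_else``.  Sampled bodies are wrapped in the default Repeat; an inner
    Repeat is never produced (it would only exit on goal, leaving any
    following code dead)."""

    max_blocks: int = 8  # excludes the default Repeat wrapper
    p_continue: float = 0.5
    p_else: float = 0.5
    max_depth: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_continue < 1.0:
            raise ValueError("p_continue must be in (0, 1)")
        if not 0.0 <= self.p_else <= 1.0:
            raise ValueError("p_else must be in [0, 1]")
        if self.max_blocks < 1:
            raise ValueError("max_blocks must be >= 1")


@dataclass(frozen=True)
class PairTolerances:
    """Margins defining 'equal in two metrics, substantially different in the
    third'.  The generalization gap is a ratio because the solved fractions
    of interest differ by orders of magnitude."""

    ae_margin: int = 5  # min action-count difference
    re_margin: int = 2  # min block-count difference
    gen_margin_ratio: float = 10.0
    gen_equal_tol: float = 0.02  # max |Δgeneralization| counted as equal

    def __post_init__(self) -> None:
        if self.ae_margin <= 0 or self.re_margin <= 0:
            raise ValueError("margins must be positive")
        if self.gen_margin_ratio <= 1.0:
            raise ValueError("gen_margin_ratio must exceed 1")
        if self.gen_equal_tol < 0:
            raise ValueError("gen_equal_tol must be non-negative")


@dataclass
class StimulusPair:
    maze: Maze
    program_1: Program  # the program the condition metric favors
    program_2: Program
    condition: str  # AE | RE | GEN
    both_outcome: str  # success | failure
    metrics_1: MetricTriple
    metrics_2: MetricTriple
    predicted: int = 1


@dataclass
class StimulusSet:
    pairs: list[StimulusPair]
    gen_params: MazeGenParams  # maze distribution behind the generalization estimates
    gen_M: int

    @property
    def per_condition_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for p in self.pairs:
            counts[p.condition] += 1
        return counts


# --- PCFG sampling ---------------------------------------------------------

def _sample_body(
    rng: np.random.Generator, cfg: GrammarConfig, depth: int
) -> tuple[Block, ...]:
    blocks = [_sample_block(rng, cfg, depth)]
    while rng.random() < cfg.p_continue:
        blocks.append(_sample_block(rng, cfg, depth))
    return tuple(blocks)


def _sample_block(rng: np.random.Generator, cfg: GrammarConfig, depth: int) -> Block:
    kinds = _SAMPLED_KINDS if depth < cfg.max_depth else _SAMPLED_ATOMICS
    kind = kinds[int(rng.integers(len(kinds)))]
    if kind in ATOMIC_KINDS:
        return Block(kind)
    then = _sample_body(rng, cfg, depth + 1)
    els = _sample_body(rng, cfg, depth + 1) if rng.random() < cfg.p_else else None
    return Block(kind, then, els)


def sample_programs(
    cfg: GrammarConfig, n: int, max_attempts_per_program: int = 2000
) -> list[Program]:
    """Rejection-sample ``n`` unique programs, each with at most
    ``cfg.max_blocks`` blocks (the Repeat wrapper excluded) and wrapped in the
    default Repeat."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    seen: set[str] = set()
    out: list[Program] = []
    attempts = 0
    budget = max(1000, max_attempts_per_program * max(n, 1))
    while len(out) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"grammar yielded only {len(out)} unique programs "
                f"within {budget} attempts (requested {n})"
            )
        attempts += 1
        body = _sample_body(rng, cfg, depth=0)
        prog = Program(body, default_repeat=True)
        if program_length(prog, count_default_repeat=False) > cfg.max_blocks:
            continue
        key = serialize_program(prog)
        if key in seen:
            continue
        seen.add(key)
        out.append(prog)
    return out


# --- matched-pair search ---------------------------------------------------

def _gen_ratio(g_hi: float, g_lo: float, M: int) -> float:
    # a Monte-Carlo zero cannot enter a ratio: floor the denominator at 1/M
    return g_hi / max(g_lo, 1.0 / M)


def _pair_ok(
    condition: str,
    len1: int,
    len2: int,
    act1: int,
    act2: int,
    gen1: float,
    gen2: float,
    out1: str,
    out2: str,
    success1: bool,
    success2: bool,
    tol: PairTolerances,
    M: int,
) -> bool:
    """Check the condition's equality/margin constraints for an ordered pair
    where program 1 is the one its condition metric favors."""
    if condition == "AE":
        return (
            out1 == out2
            and len1 == len2
            and abs(gen1 - gen2) <= tol.gen_equal_tol
            and act2 - act1 >= tol.ae_margin
        )
    if condition == "RE":
        return (
            out1 == out2
            and act1 == act2
            and abs(gen1 - gen2) <= tol.gen_equal_tol
            and len2 - len1 >= tol.re_margin
        )
    if condition == "GEN":
        return (
            success1
            and success2
            and len1 == len2
            and act1 == act2
            and _gen_ratio(gen1, gen2, M) >= tol.gen_margin_ratio
        )
    raise ValueError(f"unknown condition {condition!r}")


def find_matched_pairs(
    programs: Sequence[Program],
    mazes: Sequence[Maze],
    condition: str,
    tol: PairTolerances,
    quota: int,
    gen_sample: MazeSample,
    max_steps: Optional[int] = None,
    seed: int = 0,
    used: Optional[set[str]] = None,
    require_outcome: Optional[str] = None,
    _gen_cache: Optional[dict[str, tuple[float, float]]] = None,
) -> list[StimulusPair]:
    """Search program×maze combinations for matched pairs of one condition.

    Each program is used in at most one pair (``used`` — a set of canonical
    serializations shared across calls — enforces this across conditions).
    Generalization is estimated lazily and cached: only programs whose
    discrete keys (block count, action count, outcome) already admit a match
    are ever evaluated on the generalization sample.  ``require_outcome``
    ("success" or "failure") restricts the search to pairs with that shared
    outcome, letting callers balance the mix.  The search stops at ``quota``
    pairs or pool exhaustion; a shortfall is logged, not raised."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if require_outcome not in (None, "success", "failure"):
        raise ValueError("require_outcome must be None, 'success', or 'failure'")
    if used is None:
        used = set()
    rng = np.random.default_rng(seed)

    keys = [serialize_program(p) for p in programs]
    lengths = [program_length(p) for p in programs]
    gens: dict[str, tuple[float, float]] = _gen_cache if _gen_cache is not None else {}

    def gen_of(idx: int) -> float:
        k = keys[idx]
        if k not in gens:
            gens[k] = generalization_mc(programs[idx], gen_sample, max_steps)
        return gens[k][0]

    pairs: list[StimulusPair] = []
    maze_order = list(rng.permutation(len(mazes)))
    for mi in maze_order:
        if len(pairs) >= quota:
            break
        maze = mazes[mi]
        cap = max_steps if max_steps is not None else default_step_cap(maze)
        runs: dict[int, tuple[int, str, bool]] = {}
        groups: dict[tuple, list[int]] = {}
        for idx, (p, k) in enumerate(zip(programs, keys)):
            if k in used:
                continue
            res = run_program(p, maze, cap, record_trace=False, detect_cycles=True)
            runs[idx] = (res.n_actions, res.outcome, res.success)
            if require_outcome == "success" and not res.success:
                continue
            if require_outcome == "failure" and res.success:
                continue
            if condition == "AE":
                gkey = (lengths[idx], res.outcome)
            elif condition == "RE":
                gkey = (res.n_actions, res.outcome)
            else:  # GEN: only successes can pair
                if not res.success:
                    continue
                gkey = (lengths[idx], res.n_actions)
            groups.setdefault(gkey, []).append(idx)

        group_keys = [groups_k for groups_k in groups if len(groups[groups_k]) >= 2]
        for gk in [group_keys[i] for i in rng.permutation(len(group_keys))]:
            if len(pairs) >= quota:
                break
            members = groups[gk]
            order = [members[i] for i in rng.permutation(len(members))]
            for a in range(len(order)):
                if len(pairs) >= quota:
                    break
                i = order[a]
                if keys[i] in used:
                    continue
                for b in range(a + 1, len(order)):
                    j = order[b]
                    if keys[j] in used or keys[i] in used:
                        continue
                    acti, outi, suci = runs[i]
                    actj, outj, sucj = runs[j]
                    cand = _orient_pair(
                        condition,
                        (i, acti, outi, suci),
                        (j, actj, outj, sucj),
                        lengths,
                        gen_of,
                        tol,
                        gen_sample.M,
                    )
                    if cand is None:
                        continue
                    (wi, actw, outw, sucw), (li, actl, outl, sucl) = cand
                    m1 = MetricTriple(
                        -actw, sucw, representation_efficiency(programs[wi]),
                        gens[keys[wi]][0], gens[keys[wi]][1], gen_sample.M,
                    )
                    m2 = MetricTriple(
                        -actl, sucl, representation_efficiency(programs[li]),
                        gens[keys[li]][0], gens[keys[li]][1], gen_sample.M,
                    )
                    pairs.append(
                        StimulusPair(
                            maze=maze,
                            program_1=programs[wi],
                            program_2=programs[li],
                            condition=condition,
                            both_outcome="success" if sucw else "failure",
                            metrics_1=m1,
                            metrics_2=m2,
                        )
                    )
                    used.add(keys[wi])
                    used.add(keys[li])
                    break
    if len(pairs) < quota:
        logger.warning(
            "condition %s: found %d of %d requested pairs", condition, len(pairs), quota
        )
    return pairs


def _orient_pair(condition, rec1, rec2, lengths, gen_of, tol, M):
    """Return (favored, other) run records if they form a valid pair, else
    None.  Discrete constraints are checked before generalization is
    estimated, so the expensive metric is only computed for near-matches."""
    for a, b in ((rec1, rec2), (rec2, rec1)):
        (i1, act1, out1, suc1) = a
        (i2, act2, out2, suc2) = b
        len1, len2 = lengths[i1], lengths[i2]
        if condition == "AE" and not (
            out1 == out2 and len1 == len2 and act2 - act1 >= tol.ae_margin
        ):
            continue
        if condition == "RE" and not (
            out1 == out2 and act1 == act2 and len2 - len1 >= tol.re_margin
        ):
            continue
        if condition == "GEN" and not (
            suc1 and suc2 and len1 == len2 and act1 == act2
        ):
            continue
        g1, g2 = gen_of(i1), gen_of(i2)
        if _pair_ok(
            condition, len1, len2, act1, act2, g1, g2, out1, out2, suc1, suc2, tol, M
        ):
            return a, b
    return None


def verify_pair(
    pair: StimulusPair,
    tol: PairTolerances,
    gen_sample: MazeSample,
    max_steps: Optional[int] = None,
) -> bool:
    """Recompute both programs' metrics from scratch and re-check the pair's
    condition constraints (the audit used by tests and the pipeline)."""
    cap = max_steps if max_steps is not None else default_step_cap(pair.maze)
    r1 = run_program(pair.program_1, pair.maze, cap, record_trace=False, detect_cycles=True)
    r2 = run_program(pair.program_2, pair.maze, cap, record_trace=False, detect_cycles=True)
    g1, _ = generalization_mc(pair.program_1, gen_sample, max_steps)
    g2, _ = generalization_mc(pair.program_2, gen_sample, max_steps)
    stored_ok = (
        pair.metrics_1.action_efficiency == -r1.n_actions
        and pair.metrics_2.action_efficiency == -r2.n_actions
        and pair.metrics_1.representation_efficiency
        == representation_efficiency(pair.program_1)
        and pair.metrics_2.representation_efficiency
        == representation_efficiency(pair.program_2)
        and math.isclose(pair.metrics_1.generalization, g1)
        and math.isclose(pair.metrics_2.generalization, g2)
    )
    outcome_ok = pair.both_outcome == ("success" if r1.success else "failure")
    constraints_ok = _pair_ok(
        pair.condition,
        program_length(pair.program_1),
        program_length(pair.program_2),
        r1.n_actions,
        r2.n_actions,
        g1,
        g2,
        r1.outcome,
        r2.outcome,
        r1.success,
        r2.success,
        tol,
        gen_sample.M,
    )
    return stored_ok and outcome_ok and constraints_ok


# --- serialization ---------------------------------------------------------

def _metrics_to_obj(m: MetricTriple) -> dict:
    return {
        "action_efficiency": m.action_efficiency,
        "ae_success": m.ae_success,
        "representation_efficiency": m.representation_efficiency,
        "generalization": m.generalization,
        "generalization_se": m.generalization_se,
        "M": m.M,
    }


def stimulus_set_to_json(stimulus_set: StimulusSet) -> str:
    """Serialize a stimulus set (mazes as grid text, programs in both the
    canonical notation and the JSON mirror) deterministically."""
    import json

    from .blockdsl import program_to_json
    from .mazegen import maze_to_text

    obj = {
        "gen_params": {
            "width": stimulus_set.gen_params.width,
            "height": stimulus_set.gen_params.height,
            "loop_fraction": stimulus_set.gen_params.loop_fraction,
            "min_start_goal_distance": stimulus_set.gen_params.min_start_goal_distance,
            "seed": stimulus_set.gen_params.seed,
        },
        "gen_M": stimulus_set.gen_M,
        "pairs": [
            {
                "condition": p.condition,
                "both_outcome": p.both_outcome,
                "predicted": p.predicted,
                "maze": maze_to_text(p.maze),
                "program_1": serialize_program(p.program_1),
                "program_1_default_repeat": p.program_1.default_repeat,
                "program_2": serialize_program(p.program_2),
                "program_2_default_repeat": p.program_2.default_repeat,
                "metrics_1": _metrics_to_obj(p.metrics_1),
                "metrics_2": _metrics_to_obj(p.metrics_2),
            }
            for p in stimulus_set.pairs
        ],
    }
    return json.dumps(obj, indent=1, sort_keys=True)


def stimulus_set_from_json(text: str) -> StimulusSet:
    import json

    from .blockdsl import parse_program
    from .mazegen import maze_from_text

    obj = json.loads(text)
    gp = obj["gen_params"]
    params = MazeGenParams(
        width=gp["width"],
        height=gp["height"],
        loop_fraction=gp["loop_fraction"],
        min_start_goal_distance=gp["min_start_goal_distance"],
        seed=gp["seed"],
    )
    pairs = []
    for po in obj["pairs"]:
        pairs.append(
            StimulusPair(
                maze=maze_from_text(po["maze"]),
                program_1=parse_program(po["program_1"], po["program_1_default_repeat"]),
                program_2=parse_program(po["program_2"], po["program_2_default_repeat"]),
                condition=po["condition"],
                both_outcome=po["both_outcome"],
                metrics_1=MetricTriple(**po["metrics_1"]),
                metrics_2=MetricTriple(**po["metrics_2"]),
                predicted=po["predicted"],
            )
        )
    return StimulusSet(pairs, params, obj["gen_M"])


# --- trial assignment ------------------------------------------------------

def assign_trials(
    stimulus_set: StimulusSet | int,
    n_participants: int,
    trials_each: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each participant a random subset of ``trials_each`` distinct
    pairs, balanced so every pair's assignment count deviates from the mean
    by at most one, with left/right presentation randomized per trial.

    Returns a design table with columns participant, trial_index, pair_id,
    predicted_on_left."""
    n_pairs = (
        len(stimulus_set.pairs) if isinstance(stimulus_set, StimulusSet) else stimulus_set
    )
    if trials_each > n_pairs:
        raise ValueError("trials_each cannot exceed the number of pairs")
    if n_participants < 1 or trials_each < 1:
        raise ValueError("need at least one participant and one trial")
    rng = np.random.default_rng(seed)

    assignments = _balanced_assignment(rng, n_pairs, n_participants, trials_each)
    rows = []
    for pid, pair_ids in enumerate(assignments):
        for t, pair_id in enumerate(pair_ids):
            rows.append(
                {
                    "participant": pid,
                    "trial_index": t,
                    "pair_id": int(pair_id),
                    "predicted_on_left": bool(rng.integers(2)),
                }
            )
    return pd.DataFrame(rows)


def _balanced_assignment(
    rng: np.random.Generator, n_pairs: int, n_participants: int, trials_each: int
) -> list[list[int]]:
    total = n_participants * trials_each
    # card-dealing: concatenate independent shuffles of the full pair list and
    # slice per participant — global counts then deviate from the mean by at
    # most one; within-participant duplicates (possible only when a slice
    # straddles a shuffle boundary) are repaired by count-preserving swaps
    stream: list[int] = []
    while len(stream) < total:
        stream.extend(int(i) for i in rng.permutation(n_pairs))
    stream = stream[:total]
    slices = [
        stream[i * trials_each : (i + 1) * trials_each] for i in range(n_participants)
    ]
    for _ in range(10 * n_participants + 100):
        bad = next(
            (i for i, s in enumerate(slices) if len(set(s)) != trials_each), None
        )
        if bad is None:
            return slices
        s = slices[bad]
        dup_pos = next(i for i in range(len(s)) if s[i] in s[:i])
        for _try in range(500):
            other = int(rng.integers(n_participants))
            pos = int(rng.integers(trials_each))
            if other == bad:
                continue
            cand = slices[other][pos]
            if cand not in s and s[dup_pos] not in slices[other]:
                slices[other][pos], s[dup_pos] = s[dup_pos], cand
                break
        else:
            raise RuntimeError("balanced assignment repair failed")
    raise RuntimeError("could not construct a balanced assignment")
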