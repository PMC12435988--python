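"""PCFG program sampling, matched-pair search, and trial assignment."""

import numpy as np
import pytest

from blockmaze.blockdsl import (
    ATOMIC_KINDS,
    BlockKind,
    enumerate_programs,
    parse_program,
    program_length,
    serialize_program,
)
from blockmaze.mazegen import MazeGenParams, maze_from_text, sample_mazes
from blockmaze.programs import wall_follower
from blockmaze.stimuli import (
    GrammarConfig,
    PairTolerances,
    assign_trials,
    find_matched_pairs,
    sample_programs,
    stimulus_set_from_json,
    stimulus_set_to_json,
    verify_pair,
)

# hand-built maze on which the left-wall follower and a rigid
# forward/left-only program both succeed with identical action counts
HAND_MAZE = """\
9 9 1 4 S 3 2
#########
#.....#.#
##.G###.#
#.#.#.#.#
#S#.#.#.#
#.......#
#.#.#...#
#...#.#.#
#########
"""
RIGID_PROGRAM = "Repeat[IfPathForward{MoveForward} Else{IfPathLeft{TurnLeft}}]"


class TestSampleprograms:
    def test_zero_requested(self):
        assert sample_programs(GrammarConfig(seed=0), 0) == []

    def test_cap_uniqueness_and_wrapper(self):
        progs = sample_programs(GrammarConfig(seed=1), 2000)
        keys = [serialize_program(p) for p in progs]
        assert len(set(keys)) == 2000
        for p in progs:
            assert p.default_repeat
            assert program_length(p, count_default_repeat=False) <= 8
            # the sampler never emits an inner Repeat
            assert "Repeat" not in serialize_program(p)

    def test_atomic_grammar_matches_enumeration(self):
        cfg = GrammarConfig(max_blocks=2, max_depth=0, seed=3)
        sampled = {serialize_program(p) for p in sample_programs(cfg, 12)}
        atomics = sorted(ATOMIC_KINDS, key=lambda k: k.value)
        enumerated = {
            serialize_program(p) for p in enumerate_programs(2, atomics)
        }
        assert sampled == enumerated

    def test_unreachable_request_raises(self):
        cfg = GrammarConfig(max_blocks=1, max_depth=0, seed=0)
        with pytest.raises(RuntimeError):
            sample_programs(cfg, 4, max_attempts_per_program=100)  # only 3 exist


@pytest.fixture(scope="module")
def small_gen_sample():
    return sample_mazes(MazeGenParams(seed=99), 300)


class TestFindMatchedPairs:
    def test_empty_pool(self, small_gen_sample):
        maze_pool = sample_mazes(MazeGenParams(seed=12), 3).mazes
        assert (
            find_matched_pairs([], maze_pool, "AE", PairTolerances(), 5, small_gen_sample)
            == []
        )

    def test_hand_built_gen_pair_prefers_wall_follower(self, small_gen_sample):
        maze = maze_from_text(HAND_MAZE)
        pool = [parse_program(RIGID_PROGRAM), wall_follower()]
        pairs = find_matched_pairs(
            pool, [maze], "GEN", PairTolerances(), 1, small_gen_sample, seed=0
        )
        assert len(pairs) == 1
        pair = pairs[0]
        assert serialize_program(pair.program_1) == serialize_program(wall_follower())
        assert pair.both_outcome == "success"
        assert pair.metrics_1.generalization > pair.metrics_2.generalization
        assert verify_pair(pair, PairTolerances(), small_gen_sample)

    def test_gen_condition_rejects_failure_only_pools(self, small_gen_sample):
        # spinners never reach the goal, so no generalization pair can form
        pool = [
            parse_program("Repeat[TurnLeft]"),
            parse_program("Repeat[TurnRight]"),
            parse_program("Repeat[TurnLeft, TurnLeft]"),
        ]
        maze_pool = sample_mazes(MazeGenParams(seed=12), 5).mazes
        pairs = find_matched_pairs(
            pool, maze_pool, "GEN", PairTolerances(), 5, small_gen_sample
        )
        assert pairs == []

    def test_unknown_condition(self, small_gen_sample):
        with pytest.raises(ValueError):
            find_matched_pairs([], [], "XX", PairTolerances(), 1, small_gen_sample)


class TestStimulusSetAudit:
    def test_every_generated_pair_reverifies(self, exp2_stimuli):
        tol = PairTolerances()
        gen_sample = sample_mazes(exp2_stimuli.gen_params, exp2_stimuli.gen_M)
        for pair in exp2_stimuli.pairs:
            assert verify_pair(pair, tol, gen_sample)

    def test_gen_pairs_are_all_success(self, exp2_stimuli):
        assert all(
            p.both_outcome == "success"
            for p in exp2_stimuli.pairs
            if p.condition == "GEN"
        )

    def test_programs_never_reused_across_pairs(self, exp2_stimuli):
        seen = []
        for p in exp2_stimuli.pairs:
            seen.append(serialize_program(p.program_1))
            seen.append(serialize_program(p.program_2))
        assert len(seen) == len(set(seen))

    def test_json_round_trip(self, exp2_stimuli):
        text = stimulus_set_to_json(exp2_stimuli)
        back = stimulus_set_from_json(text)
        assert len(back.pairs) == len(exp2_stimuli.pairs)
        for a, b in zip(back.pairs, exp2_stimuli.pairs):
            assert a.condition == b.condition
            assert a.maze == b.maze
            assert serialize_program(a.program_1) == serialize_program(b.program_1)
            assert a.metrics_1 == b.metrics_1
        assert stimulus_set_to_json(back) == text


class TestAssignTrials:
    def test_exact_balance_when_divisible(self):
        design = assign_trials(60, 400, 15, seed=0)
        counts = design["pair_id"].value_counts()
        assert len(counts) == 60
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == 400 * 15
        # each participant sees distinct pairs
        per = design.groupby("participant")["pair_id"].nunique()
        assert (per == 15).all()

    def test_full_deck_shows_everything(self):
        design = assign_trials(10, 7, 10, seed=1)
        per = design.groupby("participant")["pair_id"].nunique()
        assert (per == 10).all()

    def test_seed_reproducibility(self):
        a = assign_trials(20, 50, 5, seed=3)
        b = assign_trials(20, 50, 5, seed=3)
        assert a.equals(b)

    def test_left_right_counterbalanced(self):
        design = assign_trials(60, 400, 15, seed=2)
        frac = design["predicted_on_left"].mean()
        assert abs(frac - 0.5) <= 0.05

    def test_too_many_trials_rejected(self):
        with pytest.raises(ValueError):
            assign_trials(10, 5, 11, seed=0)

    def test_indivisible_sizes_stay_balanced(self):
        design = assign_trials(7, 13, 3, seed=5)
        counts = design["pair_id"].value_counts().reindex(range(7), fill_value=0)
        assert counts.max() - counts.min() <= 1
        per = design.groupby("participant")["pair_id"].nunique()
        assert (per == 3).all()
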