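"""Canonical example programs used throughout the package and its docs."""

from .blockdsl import parse_program

#: Left-wall follower: keeps a hand on the left wall, systematically exploring
#: every corridor of a loop-free maze, so it solves any simply connected maze
#: (5 blocks, counting the wrapping Repeat).
WALL_FOLLOWER_TEXT = "Repeat [IfPathLeft{TurnLeft, MoveForward} Else{TurnRight}]"

#: Straight-line mover: advances only while the way ahead is open, then turns
#: left forever; it solves essentially only mazes with a straight (or
#: left-bending) corridor to the goal.
STRAIGHT_MOVER_TEXT = "Repeat[IfPathForward{MoveForward} Else{TurnLeft}]"


def wall_follower():
    return parse_program(WALL_FOLLOWER_TEXT)


def straight_mover():
    return parse_program(STRAIGHT_MOVER_TEXT)
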