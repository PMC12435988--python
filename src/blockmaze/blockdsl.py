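"""Block-program DSL: AST types, parser, serializer, counting, enumeration.

The language has seven block kinds. Three are atomic movement commands
(``MoveForward``, ``TurnLeft``, ``TurnRight``); three are orientation-relative
path sensors with an optional ``Else`` socket (``IfPathForward``,
``IfPathLeft``, ``IfPathRight``); ``Repeat`` re-runs its body until the agent
reaches the goal.  ``Else`` is a socket of its conditional, never a block of
its own, so the canonical left-wall follower

    Repeat[IfPathLeft{TurnLeft, MoveForward} Else{TurnRight}]

counts as exactly 5 blocks.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "BlockKind",
    "Block",
    "Program",
    "ProgramSyntaxError",
    "ATOMIC_KINDS",
    "CONDITIONAL_KINDS",
    "CONTAINER_KINDS",
    "parse_program",
    "serialize_program",
    "program_length",
    "enumerate_programs",
    "program_to_json",
    "program_from_json",
]


class BlockKind(Enum):
    MOVE_FORWARD = "MoveForward"
    TURN_LEFT = "TurnLeft"
    TURN_RIGHT = "TurnRight"
    IF_PATH_FORWARD = "IfPathForward"
    IF_PATH_LEFT = "IfPathLeft"
    IF_PATH_RIGHT = "IfPathRight"
    REPEAT = "Repeat"

    def __repr__(self) -> str:  # keep test output readable
        return f"BlockKind.{self.name}"


ATOMIC_KINDS = frozenset(
    {BlockKind.MOVE_FORWARD, BlockKind.TURN_LEFT, BlockKind.TURN_RIGHT}
)
CONDITIONAL_KINDS = frozenset(
    {BlockKind.IF_PATH_FORWARD, BlockKind.IF_PATH_LEFT, BlockKind.IF_PATH_RIGHT}
)
CONTAINER_KINDS = CONDITIONAL_KINDS | {BlockKind.REPEAT}


@dataclass(frozen=True)
class Block:
    """One AST node.  Containers hold a non-empty ``then_body``; conditionals
    may additionally carry a non-empty ``else_body``."""

    kind: BlockKind
    then_body: tuple["Block", ...] = ()
    else_body: Optional[tuple["Block", ...]] = None

    def __post_init__(self) -> None:
        if self.kind in ATOMIC_KINDS:
            if self.then_body or self.else_body is not None:
                raise ValueError(f"{self.kind.value} is atomic and takes no body")
        else:
            if not self.then_body:
                raise ValueError(f"{self.kind.value} requires a non-empty body")
        if self.else_body is not None:
            if self.kind not in CONDITIONAL_KINDS:
                raise ValueError("Else socket is only legal on IfPath* blocks")
            if not self.else_body:
                raise ValueError("Else socket, if present, must be non-empty")

    @property
    def n_blocks(self) -> int:
        """Number of AST nodes rooted here (Else contributes its blocks only)."""
        n = 1 + sum(b.n_blocks for b in self.then_body)
        if self.else_body is not None:
            n += sum(b.n_blocks for b in self.else_body)
        return n


@dataclass(frozen=True)
class Program:
    """A program: an ordered block sequence, optionally wrapped in an implicit
    top-level Repeat (the stimulus convention)."""

    body: tuple[Block, ...]
    default_repeat: bool = False

    def __post_init__(self) -> None:
        if not self.body:
            raise ValueError("program body must be non-empty")
        if self.default_repeat and any(
            b.kind is BlockKind.REPEAT for b in self.body
        ):
            raise ValueError(
                "default_repeat programs may not also contain a top-level Repeat"
            )


class ProgramSyntaxError(ValueError):
    """Parse error carrying the character position where it was detected."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


# --- parsing ---------------------------------------------------------------

_KEYWORDS = {k.value.lower(): k for k in BlockKind}
_OPENERS = {"{": "}", "[": "]"}
_TOKEN_RE = re.compile(r"[A-Za-z_]+|[{}\[\],]|\S")


def _tokenize(text: str) -> list[tuple[str, int]]:
    toks = []
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0)
        if tok.isalpha() or "_" in tok or tok in "{}[],":
            toks.append((tok, m.start()))
        else:
            raise ProgramSyntaxError(f"unexpected character {tok!r}", m.start())
    return toks


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.toks = _tokenize(text)
        self.i = 0

    def peek(self) -> Optional[tuple[str, int]]:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise ProgramSyntaxError("unexpected end of input", len(self.text))
        self.i += 1
        return tok

    def parse_body(self) -> tuple[Block, ...]:
        """A braced/bracketed statement list: '{' Stmts '}' or '[' Stmts ']'."""
        tok, pos = self.next()
        if tok not in _OPENERS:
            raise ProgramSyntaxError(f"expected '{{' or '[', found {tok!r}", pos)
        closer = _OPENERS[tok]
        stmts = self.parse_stmts(stop={closer})
        ctok = self.peek()
        if ctok is None:
            raise ProgramSyntaxError(f"missing closing {closer!r}", len(self.text))
        if ctok[0] != closer:
            raise ProgramSyntaxError(
                f"mismatched delimiter: expected {closer!r}, found {ctok[0]!r}",
                ctok[1],
            )
        if not stmts:
            raise ProgramSyntaxError("empty container body", ctok[1])
        self.next()
        return stmts

    def parse_stmts(self, stop: set[str]) -> tuple[Block, ...]:
        blocks: list[Block] = []
        while True:
            tok = self.peek()
            if tok is None or tok[0] in stop:
                return tuple(blocks)
            if tok[0] == ",":
                self.next()
                continue
            blocks.append(self.parse_stmt())

    def parse_stmt(self) -> Block:
        tok, pos = self.next()
        low = tok.lower()
        if low == "else":
            raise ProgramSyntaxError("Else without a preceding conditional", pos)
        kind = _KEYWORDS.get(low)
        if kind is None:
            raise ProgramSyntaxError(f"unknown block name {tok!r}", pos)
        nxt = self.peek()
        if kind in ATOMIC_KINDS:
            if nxt is not None and nxt[0] in _OPENERS:
                raise ProgramSyntaxError(
                    f"{kind.value} is atomic and takes no body", nxt[1]
                )
            return Block(kind)
        if nxt is None or nxt[0] not in _OPENERS:
            raise ProgramSyntaxError(
                f"{kind.value} requires a bracketed body", nxt[1] if nxt else pos
            )
        then_body = self.parse_body()
        else_body = None
        nxt = self.peek()
        if nxt is not None and nxt[0].lower() == "else":
            epos = nxt[1]
            if kind not in CONDITIONAL_KINDS:
                raise ProgramSyntaxError("Else is only legal on IfPath* blocks", epos)
            self.next()
            else_body = self.parse_body()
        return Block(kind, then_body, else_body)


def parse_program(text: str, default_repeat: bool = False) -> Program:
    """Parse canonical program notation into a :class:`Program`.

    Keywords are case-insensitive; statement lists may be separated by commas
    or whitespace; ``[]`` and ``{}`` are interchangeable container delimiters
    (each opener must be closed by its own kind).
    """
    if not text or not text.strip():
        raise ProgramSyntaxError("empty program text", 0)
    p = _Parser(text)
    body = p.parse_stmts(stop=set())
    tok = p.peek()
    if tok is not None:
        raise ProgramSyntaxError(f"unbalanced closing delimiter {tok[0]!r}", tok[1])
    if not body:
        raise ProgramSyntaxError("program body must be non-empty", 0)
    return Program(body, default_repeat=default_repeat)


# --- serialization ---------------------------------------------------------

def _serialize_block(b: Block) -> str:
    if b.kind in ATOMIC_KINDS:
        return b.kind.value
    # canonical style: Repeat uses square brackets, conditionals use braces
    op, cl = ("[", "]") if b.kind is BlockKind.REPEAT else ("{", "}")
    s = f"{b.kind.value}{op}{_serialize_seq(b.then_body)}{cl}"
    if b.else_body is not None:
        s += f" Else{{{_serialize_seq(b.else_body)}}}"
    return s


def _serialize_seq(blocks: Sequence[Block]) -> str:
    return ", ".join(_serialize_block(b) for b in blocks)


def serialize_program(p: Program) -> str:
    """Canonical text form.  ``parse_program(serialize_program(p),
    p.default_repeat)`` reproduces ``p`` exactly; an implicit top-level Repeat
    is carried out-of-band (text holds only the body)."""
    return _serialize_seq(p.body)


# --- counting --------------------------------------------------------------

def program_length(p: Program, count_default_repeat: bool = True) -> int:
    """Total number of blocks in ``p``.

    An implicit top-level Repeat counts as one block under inclusive counting.
    With ``count_default_repeat=False`` a top-level Repeat — implicit, or an
    explicit sole wrapping Repeat — is excluded (the stimulus-filter
    convention)."""
    n = sum(b.n_blocks for b in p.body)
    if p.default_repeat:
        n += 1
    if not count_default_repeat:
        if p.default_repeat:
            n -= 1
        elif len(p.body) == 1 and p.body[0].kind is BlockKind.REPEAT:
            n -= 1
    return n


# --- enumeration -----------------------------------------------------------

def _enum_seqs(
    budget: int, kinds: tuple[BlockKind, ...]
) -> Iterator[tuple[tuple[Block, ...], int]]:
    """All non-empty block sequences with total node count ≤ budget."""
    if budget < 1:
        return
    for blk, size in _enum_blocks(budget, kinds):
        yield (blk,), size
        for rest, rsize in _enum_seqs(budget - size, kinds):
            yield (blk,) + rest, size + rsize


def _enum_blocks(
    budget: int, kinds: tuple[BlockKind, ...]
) -> Iterator[tuple[Block, int]]:
    for k in kinds:
        if k in ATOMIC_KINDS:
            yield Block(k), 1
    if budget < 2:
        return
    for k in kinds:
        if k not in CONTAINER_KINDS:
            continue
        for then, tsize in _enum_seqs(budget - 1, kinds):
            yield Block(k, then), 1 + tsize
            if k in CONDITIONAL_KINDS:
                for els, esize in _enum_seqs(budget - 1 - tsize, kinds):
                    yield Block(k, then, els), 1 + tsize + esize


def enumerate_programs(
    max_blocks: int, kinds: Optional[Iterable[BlockKind]] = None
) -> Iterator[Program]:
    """Yield every structurally valid program with ≤ ``max_blocks`` blocks over
    the given kinds, each exactly once (``default_repeat`` unset)."""
    if max_blocks < 1:
        raise ValueError("max_blocks must be >= 1")
    ks = tuple(kinds) if kinds is not None else tuple(BlockKind)
    for seq, _ in _enum_seqs(max_blocks, ks):
        yield Program(seq)


# --- JSON mirror -----------------------------------------------------------

def _block_to_obj(b: Block) -> dict:
    obj: dict = {"kind": b.kind.value}
    if b.kind in CONTAINER_KINDS:
        obj["then"] = [_block_to_obj(x) for x in b.then_body]
    if b.else_body is not None:
        obj["else"] = [_block_to_obj(x) for x in b.else_body]
    return obj


def _block_from_obj(obj: dict) -> Block:
    kind = BlockKind(obj["kind"])
    then = tuple(_block_from_obj(x) for x in obj.get("then", []))
    els = obj.get("else")
    return Block(kind, then, tuple(_block_from_obj(x) for x in els) if els else None)


def program_to_json(p: Program) -> str:
    return json.dumps(
        {
            "default_repeat": p.default_repeat,
            "body": [_block_to_obj(b) for b in p.body],
        },
        indent=None,
    )


def program_from_json(text: str) -> Program:
    obj = json.loads(text)
    return Program(
        tuple(_block_from_obj(b) for b in obj["body"]),
        default_repeat=bool(obj.get("default_repeat", False)),
    )
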