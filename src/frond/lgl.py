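"""Lexer and parser for LGL, a tiny text language for declaring graphs.

LGL source is ordinary text whose layout visually resembles the graph it
encodes.  The fundamental objects are *items* (graph nodes, or whole named
graphs), *item sets* (comma-separated items) and *arrows* (``->`` / ``<-``)
that connect them; the comma binds tighter than the arrow.  A statement is
terminated by ``;`` and may be preceded by ``label:`` to produce a named
graph.  Tree-shaped structure can be written with the fork operator: ``<``
opens a split after an operand, each branch starts with ``/`` except the
last, which starts with ``\\``; the void item ``.`` is a placeholder branch
head whose children attach directly to the fork parent.  ``@name``
references a previously named graph in place instead of pasting a copy.
Single-letter flags attach to an item with ``[..]`` (e.g. ``B[F]``).

Pipe characters ``|`` and newlines are whitespace, so ASCII-art layouts can
be drawn around the code; ``#`` starts a comment running to end of line.

This module only builds the abstract syntax (:class:`Statement` lists);
graph construction lives in :mod:`frond.graphs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

__all__ = [
    "Token",
    "Item",
    "ItemSet",
    "Fork",
    "Chain",
    "Statement",
    "LglError",
    "LglSyntaxError",
    "tokenize",
    "parse",
    "parse_file",
    "render",
]


class LglError(Exception):
    """Base class for LGL language errors; carries a 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class LglSyntaxError(LglError):
    """Lexical or grammatical error in LGL source."""


# ---------------------------------------------------------------------------
# Tokens
# ---------------------------------------------------------------------------

#: token kinds
ID = "identifier"
ARROW_R = "arrow-right"
ARROW_L = "arrow-left"
COMMA = "comma"
COLON = "colon"
SEMI = "semicolon"
AT = "at"
FORK = "fork-open"
SLASH = "slash"
BSLASH = "backslash"
LBRACK = "lbracket"
RBRACK = "rbracket"
VOID = "dot-void"


@dataclass(frozen=True)
class Token:
    kind: str
    text: str
    line: int


_PUNCT = {
    ",": COMMA,
    ":": COLON,
    ";": SEMI,
    "@": AT,
    "/": SLASH,
    "\\": BSLASH,
    "[": LBRACK,
    "]": RBRACK,
    ".": VOID,
}


def _is_ident_start(ch: str) -> bool:
    return ch.isalpha() or ch == "_"


def _is_ident(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def tokenize(text: str) -> list[Token]:
    """Lex LGL source into a token list.

    ``|`` and newline are whitespace (newlines still advance the line
    counter used for diagnostics), ``#`` comments run to end of line.
    Raises :class:`LglSyntaxError` on an illegal character.
    """
    tokens: list[Token] = []
    line = 1
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            line += 1
            i += 1
            continue
        if ch in " \t\r\f\v|":
            i += 1
            continue
        if ch == "#":
            while i < n and text[i] != "\n":
                i += 1
            continue
        if ch == "-":
            if i + 1 < n and text[i + 1] == ">":
                tokens.append(Token(ARROW_R, "->", line))
                i += 2
                continue
            raise LglSyntaxError("illegal character '-' (expected '->')", line)
        if ch == "<":
            if i + 1 < n and text[i + 1] == "-":
                tokens.append(Token(ARROW_L, "<-", line))
                i += 2
                continue
            tokens.append(Token(FORK, "<", line))
            i += 1
            continue
        if ch in _PUNCT:
            tokens.append(Token(_PUNCT[ch], ch, line))
            i += 1
            continue
        if _is_ident_start(ch):
            j = i + 1
            while j < n and _is_ident(text[j]):
                j += 1
            tokens.append(Token(ID, text[i:j], line))
            i = j
            continue
        raise LglSyntaxError(f"illegal character {ch!r}", line)
    return tokens


# ---------------------------------------------------------------------------
# Abstract syntax
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Item:
    """A single item: node label, named-graph use, ``@`` reference or void."""

    name: str
    flags: frozenset = frozenset()
    ref: bool = False
    line: int = field(default=0, compare=False, repr=False)

    @property
    def is_void(self) -> bool:
        return self.name == "."


@dataclass(frozen=True)
class ItemSet:
    """A comma-separated group of items acting as one operand."""

    items: tuple  # of Item


@dataclass(frozen=True)
class Fork:
    """``parent < /branch ... \\branch`` — a visually tree-shaped split."""

    parent: "Operand"
    branches: tuple  # of Operand


Operand = Union[ItemSet, Fork]


@dataclass(frozen=True)
class Chain:
    """Operands joined pairwise by arrows; a bare operand is a 0-arrow chain."""

    operands: tuple  # of Operand
    arrows: tuple  # of "->" / "<-", len == len(operands) - 1


@dataclass(frozen=True)
class Statement:
    label: str | None
    expr: Chain
    line: int = field(default=0, compare=False, repr=False)


# ---------------------------------------------------------------------------
# Parser (recursive descent)
# ---------------------------------------------------------------------------


class _Parser:
    def __init__(self, tokens: list[Token], last_line: int):
        self.tokens = tokens
        self.pos = 0
        self.last_line = last_line

    def peek(self, offset: int = 0) -> Token | None:
        i = self.pos + offset
        return self.tokens[i] if i < len(self.tokens) else None

    def next(self) -> Token:
        tok = self.peek()
        if tok is None:
            raise LglSyntaxError("unexpected end of input", self.last_line)
        self.pos += 1
        return tok

    def expect(self, kind: str) -> Token:
        tok = self.peek()
        if tok is None:
            raise LglSyntaxError(
                f"unexpected end of input (expected {kind})", self.last_line
            )
        if tok.kind != kind:
            raise LglSyntaxError(
                f"expected {kind}, found {tok.text!r}", tok.line
            )
        self.pos += 1
        return tok

    # program := statement* EOF
    def program(self) -> list[Statement]:
        out = []
        while self.peek() is not None:
            out.append(self.statement())
        return out

    # statement := [ID ':'] chain ';'
    def statement(self) -> Statement:
        label = None
        first = self.peek()
        assert first is not None
        if (
            first.kind == ID
            and self.peek(1) is not None
            and self.peek(1).kind == COLON
        ):
            label = self.next().text
            self.next()  # colon
        expr = self.chain()
        self.expect(SEMI)
        return Statement(label, expr, line=first.line)

    # chain := operand (arrow operand)*
    def chain(self) -> Chain:
        operands = [self.operand()]
        arrows: list[str] = []
        while True:
            tok = self.peek()
            if tok is not None and tok.kind in (ARROW_R, ARROW_L):
                self.next()
                arrows.append(tok.text)
                operands.append(self.operand())
            else:
                return Chain(tuple(operands), tuple(arrows))

    # operand := itemset [fork_tail]
    def operand(self) -> Operand:
        base: Operand = self.itemset()
        tok = self.peek()
        if tok is not None and tok.kind == FORK:
            self.next()
            return Fork(base, self.branches())
        return base

    # branches := ('/' operand)+ '\' operand
    def branches(self) -> tuple:
        out = []
        tok = self.peek()
        if tok is None or tok.kind != SLASH:
            at = tok.line if tok else self.last_line
            raise LglSyntaxError("fork must open with a '/' branch", at)
        while self.peek() is not None and self.peek().kind == SLASH:
            self.next()
            out.append(self.operand())
        self.expect(BSLASH)
        out.append(self.operand())
        return tuple(out)

    # itemset := item (',' item)*
    def itemset(self) -> ItemSet:
        items = [self.item()]
        while self.peek() is not None and self.peek().kind == COMMA:
            self.next()
            items.append(self.item())
        return ItemSet(tuple(items))

    # item := ['@'] (ID | '.') ['[' ID+ ']']
    def item(self) -> Item:
        tok = self.peek()
        if tok is None:
            raise LglSyntaxError(
                "unexpected end of input (expected item)", self.last_line
            )
        ref = False
        if tok.kind == AT:
            self.next()
            ref = True
            tok = self.peek()
            if tok is None or tok.kind != ID:
                at = tok.line if tok else self.last_line
                raise LglSyntaxError("'@' must be followed by a name", at)
        if tok.kind == VOID:
            if ref:
                raise LglSyntaxError("'@' cannot reference the void item", tok.line)
            self.next()
            return Item(".", line=tok.line)
        if tok.kind != ID:
            raise LglSyntaxError(f"expected item, found {tok.text!r}", tok.line)
        self.next()
        flags: set[str] = set()
        nxt = self.peek()
        if nxt is not None and nxt.kind == LBRACK:
            self.next()
            while self.peek() is not None and self.peek().kind == ID:
                word = self.next()
                for ch in word.text:
                    if not ch.isalpha():
                        raise LglSyntaxError(
                            f"flags must be letters, found {ch!r}", word.line
                        )
                    flags.add(ch)
            close = self.expect(RBRACK)
            if not flags:
                raise LglSyntaxError("empty flag list", close.line)
        return Item(tok.text, frozenset(flags), ref, line=tok.line)


def parse(text: str) -> list[Statement]:
    """Parse LGL source into one :class:`Statement` per ``;``-terminated
    statement, in source order.  Raises :class:`LglSyntaxError` with the
    1-based line of the offending token."""
    last_line = text.count("\n") + 1
    parser = _Parser(tokenize(text), last_line)
    return parser.program()


def parse_file(path: str | Path) -> list[Statement]:
    return parse(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Canonical pretty-printer
# ---------------------------------------------------------------------------


def render(node) -> str:
    """Render AST back to canonical LGL text; ``parse(render(x)) == x``."""
    if isinstance(node, list):
        return "\n".join(render(s) for s in node)
    if isinstance(node, Statement):
        head = f"{node.label}: " if node.label else ""
        return f"{head}{render(node.expr)};"
    if isinstance(node, Chain):
        parts = [render(node.operands[0])]
        for arrow, op in zip(node.arrows, node.operands[1:]):
            parts.append(arrow)
            parts.append(render(op))
        return " ".join(parts)
    if isinstance(node, Fork):
        bits = [render(node.parent), "<"]
        for branch in node.branches[:-1]:
            bits.append("/" + render(branch))
        bits.append("\\" + render(node.branches[-1]))
        return " ".join(bits)
    if isinstance(node, ItemSet):
        return ", ".join(render(i) for i in node.items)
    if isinstance(node, Item):
        text = ("@" if node.ref else "") + node.name
        if node.flags:
            text += "[" + "".join(sorted(node.flags)) + "]"
        return text
    raise TypeError(f"cannot render {type(node).__name__}")
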