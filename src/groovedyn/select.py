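"""A small atom-selection query language.

Grammar (case-insensitive keywords)::

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := "not" factor | "(" expr ")" | primary
    primary := "name" IDENT+ | "chain" IDENT+ | "resname" IDENT+
             | "resseq" RANGE+ | "all"
    RANGE   := INT | INT ":" INT        (inclusive)

Examples: ``name CA``, ``chain A and resseq 1:9 and name CA``,
``not chain P``.  Multiple values after a keyword are an implicit OR.
"""

from __future__ import annotations

import re

import numpy as np

from .model import GrooveDynError, Selection, Topology

__all__ = ["select", "SelectionSyntaxError", "EmptySelectionError"]


class SelectionSyntaxError(GrooveDynError):
    """Malformed query; the message carries the character position."""


class EmptySelectionError(GrooveDynError):
    """Query matched no atoms and ``allow_empty`` was not set."""


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")

_KEYWORDS = {"and", "or", "not", "name", "chain", "resname", "resseq", "all"}


def _tokenize(query: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(query):
        m = _TOKEN_RE.match(query, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, query: str, topology: Topology):
        self.query = query
        self.tokens = _tokenize(query)
        self.i = 0
        self.top = topology
        self.n = topology.n_atoms

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.query)

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise SelectionSyntaxError(
                f"unexpected end of query at position {len(self.query)}: {self.query!r}"
            )
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionSyntaxError("empty query")
        mask = self._expr()
        if self.i < len(self.tokens):
            raise SelectionSyntaxError(
                f"unexpected token {self._peek()!r} at position {self._pos()}"
            )
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek() is not None and self._peek().lower() == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while self._peek() is not None and self._peek().lower() == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok = self._peek()
        if tok is None:
            raise SelectionSyntaxError(
                f"unexpected end of query at position {len(self.query)}"
            )
        if tok.lower() == "not":
            self._next()
            return ~self._factor()
        if tok == "(":
            self._next()
            mask = self._expr()
            if self._peek() != ")":
                raise SelectionSyntaxError(
                    f"expected ')' at position {self._pos()} in {self.query!r}"
                )
            self._next()
            return mask
        return self._primary()

    def _values(self) -> list[str]:
        values = []
        while True:
            tok = self._peek()
            if tok is None or tok in ("(", ")") or tok.lower() in _KEYWORDS:
                break
            values.append(self._next())
        if not values:
            raise SelectionSyntaxError(
                f"expected at least one value at position {self._pos()} in {self.query!r}"
            )
        return values

    def _primary(self) -> np.ndarray:
        pos = self._pos()
        tok = self._next().lower()
        if tok == "all":
            return np.ones(self.n, dtype=bool)
        if tok == "name":
            names = {v.upper() for v in self._values()}
            return np.array([a.name.upper() in names for a in self.top.atoms])
        if tok == "chain":
            chains = set(self._values())
            return np.array([a.chain_id in chains for a in self.top.atoms])
        if tok == "resname":
            names = {v.upper() for v in self._values()}
            return np.array([a.residue_name.upper() in names for a in self.top.atoms])
        if tok == "resseq":
            mask = np.zeros(self.n, dtype=bool)
            for value in self._values():
                m = re.fullmatch(r"(-?\d+)(?::(-?\d+))?", value)
                if m is None:
                    raise SelectionSyntaxError(
                        f"bad resseq range {value!r} at position {pos}"
                    )
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                mask |= np.array(
                    [lo <= a.residue_seq <= hi for a in self.top.atoms]
                )
            return mask
        raise SelectionSyntaxError(
            f"unknown selection keyword {tok!r} at position {pos} in {self.query!r}"
        )


def select(topology: Topology, query: str, allow_empty: bool = False) -> Selection:
    """Evaluate a selection query against a topology.

    Returns a :class:`~groovedyn.model.Selection` with deterministic,
    sorted atom indices.  An empty result raises
    :class:`EmptySelectionError` unless ``allow_empty`` is set.
    """
    mask = _Parser(query, topology).parse()
    indices = np.nonzero(mask)[0]
    if indices.size == 0 and not allow_empty:
        raise EmptySelectionError(f"query {query!r} selected no atoms")
    return Selection.from_indices(topology, indices)
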