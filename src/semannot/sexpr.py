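"""A small s-expression reader with source positions.

The domain dialect is a parenthesised Lisp-style syntax; this module only
tokenises and nests it.  All dialect-level interpretation (``:types``,
``:action`` ...) happens in :mod:`semannot.domain`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainSyntaxError

__all__ = ["Atom", "parse_sexprs"]


@dataclass(frozen=True)
class Atom:
    """A bare token or quoted string, with its 1-based source position."""

    value: str
    line: int
    column: int
    is_string: bool = False

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.value


def _tokenize(text: str):
    line, col = 1, 1
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            line += 1
            col = 1
            i += 1
        elif ch in " \t\r":
            i += 1
            col += 1
        elif ch == ";":  # comment to end of line
            while i < n and text[i] != "\n":
                i += 1
        elif ch in "()":
            yield (ch, line, col)
            i += 1
            col += 1
        elif ch == '"':
            start_line, start_col = line, col
            j = i + 1
            while j < n and text[j] != '"':
                if text[j] == "\n":
                    raise DomainSyntaxError("unterminated string", start_line, start_col)
                j += 1
            if j >= n:
                raise DomainSyntaxError("unterminated string", start_line, start_col)
            yield (Atom(text[i + 1 : j], start_line, start_col, is_string=True), line, col)
            col += j - i + 1
            i = j + 1
        else:
            start_line, start_col = line, col
            j = i
            while j < n and text[j] not in ' \t\r\n();"':
                j += 1
            yield (Atom(text[i:j], start_line, start_col), line, col)
            col += j - i
            i = j


def parse_sexprs(text: str) -> list:
    """Parse ``text`` into a list of nested lists of :class:`Atom`."""
    stack: list[list] = [[]]
    last_line, last_col = 1, 1
    for tok, line, col in _tokenize(text):
        last_line, last_col = line, col
        if tok == "(":
            new: list = []
            stack[-1].append(new)
            stack.append(new)
        elif tok == ")":
            if len(stack) == 1:
                raise DomainSyntaxError("unbalanced ')'", line, col)
            stack.pop()
        else:
            stack[-1].append(tok)
    if len(stack) != 1:
        raise DomainSyntaxError("unbalanced '(': expression never closed", last_line, last_col)
    return stack[0]
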