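"""Half-space descriptions ``Ax <= b`` and the cdd-style ``.ine`` text format.

A polytope is described by ``m`` half-spaces ``H_i = {x : a_i . x <= b_i}``
in dimension ``n``; the constraint vectors ``a_i`` are the rows of ``A`` and
row indices run over ``I = {0, ..., m-1}``.  All entries are exact rationals
(:class:`fractions.Fraction`); nothing in this package ever rounds.

The on-disk dialect is the classical polyhedral ``.ine`` convention: each data
row stores ``(b_i, -a_i)``, i.e. the inequality written as ``b_i - a_i.x >= 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from os import PathLike
from typing import Iterable, Sequence, Union

__all__ = ["HRepresentation", "HRepError", "IneParseError", "read_hrep", "write_hrep"]

Scalar = Union[int, str, Fraction, Rational]


class HRepError(ValueError):
    """Invalid half-space description (shape, type or boundedness contract)."""


class IneParseError(HRepError):
    """Malformed ``.ine`` file; the message names the offending line."""


def _as_fraction(x: Scalar) -> Fraction:
    if isinstance(x, float):
        raise HRepError(
            f"float {x!r} rejected: entries must be exact rationals "
            "(int, Fraction or a string such as '1/3' or '0.25')"
        )
    return Fraction(x)


@dataclass(frozen=True)
class HRepresentation:
    """Exact rational system ``Ax <= b`` with ``m`` half-spaces in dimension ``n``.

    Invariants enforced at construction: ``m > n`` (a bounded full-dimensional
    polytope needs more half-spaces than dimensions), every row has length
    ``n``, and every entry is an exact rational.
    """

    A: tuple[tuple[Fraction, ...], ...]
    b: tuple[Fraction, ...]
    _A_int: tuple[tuple[int, ...], ...] = field(init=False, repr=False, compare=False)

    def __init__(self, A: Iterable[Sequence[Scalar]], b: Iterable[Scalar]):
        rows = tuple(tuple(_as_fraction(x) for x in row) for row in A)
        rhs = tuple(_as_fraction(x) for x in b)
        if not rows:
            raise HRepError("empty constraint system (m = 0)")
        n = len(rows[0])
        if any(len(r) != n for r in rows):
            raise HRepError("ragged constraint matrix: rows differ in length")
        if len(rhs) != len(rows):
            raise HRepError(f"length of b ({len(rhs)}) != number of rows ({len(rows)})")
        if n == 0:
            raise HRepError("ambient dimension n = 0")
        if len(rows) <= n:
            raise HRepError(
                f"m = {len(rows)} <= n = {n}: a bounded full-dimensional "
                "polytope requires m > n"
            )
        object.__setattr__(self, "A", rows)
        object.__setattr__(self, "b", rhs)
        # Integer-scaled rows (positive per-row scaling clears denominators);
        # sign work on rays only ever needs these.
        scaled = []
        for row in rows:
            lcm = math.lcm(*(f.denominator for f in row)) if row else 1
            scaled.append(tuple(int(f * lcm) for f in row))
        object.__setattr__(self, "_A_int", tuple(scaled))

    @property
    def m(self) -> int:
        """Number of half-spaces."""
        return len(self.A)

    @property
    def n(self) -> int:
        """Ambient dimension."""
        return len(self.A[0])

    @property
    def indices(self) -> range:
        """Row index set ``I = {0, ..., m-1}``."""
        return range(self.m)

    def row(self, i: int) -> tuple[Fraction, ...]:
        return self.A[i]

    def row_int(self, i: int) -> tuple[int, ...]:
        """Row ``a_i`` rescaled by a positive rational to primitive-ish integers."""
        return self._A_int[i]


def _parse_number(tok: str, path, lineno: int) -> Fraction:
    try:
        return Fraction(tok)
    except (ValueError, ZeroDivisionError) as exc:
        raise IneParseError(f"{path}:{lineno}: non-numeric token {tok!r}") from exc


def read_hrep(path: Union[str, PathLike]) -> HRepresentation:
    """Read an ``.ine`` file into an exact :class:`HRepresentation`.

    Accepted number tokens are integers, ``p/q`` rationals and decimal
    literals (converted exactly, ``0.5`` -> ``1/2``).  ``linearity``
    (equality-constraint) blocks are rejected: this reader handles pure
    inequality systems only.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()

    it = iter(enumerate(lines, start=1))
    # --- header: skip comments until "begin" ---
    m = n1 = None
    header_line = None
    for lineno, raw in it:
        s = raw.strip()
        if not s or s.startswith("*") or s.lower() == "h-representation":
            continue
        if s.lower().startswith("linearity"):
            raise IneParseError(
                f"{path}:{lineno}: 'linearity' (equality) blocks are not supported"
            )
        if s.lower() == "begin":
            header_line = lineno
            break
        raise IneParseError(f"{path}:{lineno}: unexpected line {s!r} before 'begin'")
    if header_line is None:
        raise IneParseError(f"{path}: no 'begin' section found")

    try:
        lineno, raw = next(it)
    except StopIteration:
        raise IneParseError(f"{path}: truncated after 'begin'") from None
    fields = raw.split()
    if len(fields) < 2:
        raise IneParseError(f"{path}:{lineno}: expected 'm n+1 numbertype' header")
    try:
        m, n1 = int(fields[0]), int(fields[1])
    except ValueError:
        raise IneParseError(f"{path}:{lineno}: bad size header {raw.strip()!r}") from None
    if m < 1 or n1 < 2:
        raise IneParseError(f"{path}:{lineno}: degenerate sizes m={m}, n+1={n1}")

    rows_b: list[Fraction] = []
    rows_a: list[list[Fraction]] = []
    for lineno, raw in it:
        s = raw.strip()
        if not s:
            continue
        if s.lower() == "end":
            break
        if s.lower().startswith("linearity"):
            raise IneParseError(
                f"{path}:{lineno}: 'linearity' (equality) blocks are not supported"
            )
        toks = s.split()
        if len(toks) != n1:
            raise IneParseError(
                f"{path}:{lineno}: expected {n1} fields, found {len(toks)}"
            )
        vals = [_parse_number(t, path, lineno) for t in toks]
        rows_b.append(vals[0])
        rows_a.append([-v for v in vals[1:]])  # stored as (b_i, -a_i)
    else:
        raise IneParseError(f"{path}: missing 'end' line")

    if len(rows_b) != m:
        raise IneParseError(
            f"{path}: declared m={m} but found {len(rows_b)} data rows"
        )
    return HRepresentation(rows_a, rows_b)


def write_hrep(H: HRepresentation, path: Union[str, PathLike]) -> None:
    """Write ``H`` in the ``.ine`` dialect; ``read_hrep`` round-trips exactly."""

    def fmt(x: Fraction) -> str:
        return str(x.numerator) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"

    all_int = all(
        v.denominator == 1 for row in H.A for v in row
    ) and all(v.denominator == 1 for v in H.b)
    numbertype = "integer" if all_int else "rational"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("H-representation\n")
        fh.write("begin\n")
        fh.write(f" {H.m} {H.n + 1} {numbertype}\n")
        for i in range(H.m):
            cells = [fmt(H.b[i])] + [fmt(-a) for a in H.A[i]]
            fh.write(" " + " ".join(cells) + "\n")
        fh.write("end\n")
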