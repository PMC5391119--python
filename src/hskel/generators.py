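"""Built-in half-space families: the worked no-signaling example, Birkhoff
polytopes, random regular polytopes, and classical fixtures with known
skeletons.

Each generator returns a :class:`FixtureSpec` bundling the exact system, a
usable start (or interior) point, and whatever ground-truth graph facts are
known, so test suites and benchmarks never need external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Any, Sequence

import numpy as np

from .hrep import HRepresentation, HRepError

__all__ = [
    "FixtureSpec",
    "gen_ns_example",
    "gen_birkhoff",
    "birkhoff_lift",
    "gen_random_regular",
    "gen_classic",
]


@dataclass
class FixtureSpec:
    """A generated input system with provenance and known graph facts."""

    name: str
    params: dict[str, Any]
    hrep: HRepresentation
    start: tuple[Fraction, ...] | None = None       # a known extreme point
    interior: tuple[Fraction, ...] | None = None    # a feasible interior point
    known_facts: dict[str, Any] = field(default_factory=dict)


def _unit(n: int, i: int, sign: int = 1) -> list[int]:
    v = [0] * n
    v[i] = sign
    return v


def gen_ns_example() -> FixtureSpec:
    """The bipartite no-signaling correlation system used as the running
    example: two parties with binary inputs and 3 x 2 outcomes, giving
    ``m = 24`` half-spaces in dimension ``n = 14``.

    The origin is a 6-degenerate vertex of the feasible polytope; the full
    skeleton has 108 vertices and 1548 edges with degrees 16 (72 vertices)
    and 54 (36 vertices).
    """
    n = 14
    A: list[list[int]] = [_unit(n, i, -1) for i in range(14)]

    def combo(*terms: tuple[int, int]) -> list[int]:
        v = [0] * n
        for idx, c in terms:
            v[idx] += c
        return v

    A.append(combo((0, -1), (1, -1), (2, -1), (5, 1), (6, 1)))      # a14
    A.append(combo((9, -1), (10, -1), (11, -1), (12, 1), (13, 1)))  # a15
    A.append(combo((0, -1), (3, -1), (9, 1)))                        # a16
    A.append(combo((1, -1), (4, -1), (10, 1)))                       # a17
    A.append(combo((5, -1), (7, -1), (12, 1)))                       # a18
    A.append(combo((6, -1), (8, -1), (13, 1)))                       # a19
    A.append(combo((0, 1), (1, 1), (2, 1), (3, 1), (4, 1)))          # a20
    A.append(combo((0, 1), (1, 1), (2, 1), (7, 1), (8, 1)))          # a21
    A.append(combo((0, 1), (1, 1), (3, 1), (4, 1), (11, 1)))         # a22
    A.append(combo((5, 1), (6, 1), (7, 1), (8, 1), (9, 1), (10, 1),
                   (11, 1), (12, -1), (13, -1)))                     # a23
    b = [0] * 20 + [1] * 4
    H = HRepresentation(A, b)
    return FixtureSpec(
        name="ns-example",
        params={"n": n, "m": 24},
        hrep=H,
        start=tuple(Fraction(0) for _ in range(n)),
        known_facts={
            "n_vertices": 108,
            "n_edges": 1548,
            "degree_histogram": {16: 72, 54: 36},
            "origin_sigma": 6,
            "origin_rays": 54,
        },
    )


def gen_birkhoff(ell: int) -> FixtureSpec:
    """Birkhoff polytope of ``ell x ell`` doubly-stochastic matrices, in the
    reduced coordinates obtained by eliminating the last row and column.

    Variables are ``x_ij`` for ``i, j < ell - 1`` (dimension
    ``n = (ell-1)^2``); the ``m = ell^2`` inequalities are the
    non-negativity of every entry of the completed matrix.  The vertices are
    the ``ell!`` permutation matrices and the skeleton has diameter 2 for
    ``ell >= 4``.
    """
    if ell < 2:
        raise HRepError("Birkhoff polytope requires ell >= 2")
    r = ell - 1
    n = r * r

    def var(i: int, j: int) -> int:
        return i * r + j

    A: list[list[int]] = []
    b: list[int] = []
    for i in range(r):            # x_ij >= 0
        for j in range(r):
            A.append(_unit(n, var(i, j), -1))
            b.append(0)
    for i in range(r):            # last column: sum_j x_ij <= 1
        row = [0] * n
        for j in range(r):
            row[var(i, j)] = 1
        A.append(row)
        b.append(1)
    for j in range(r):            # last row: sum_i x_ij <= 1
        row = [0] * n
        for i in range(r):
            row[var(i, j)] = 1
        A.append(row)
        b.append(1)
    A.append([-1] * n)            # corner entry: sum_ij x_ij >= ell - 2
    b.append(-(ell - 2))
    H = HRepresentation(A, b)
    uniform = tuple(Fraction(1, ell) for _ in range(n))
    facts: dict[str, Any] = {"n_vertices": math.factorial(ell),
                             "vertices_are_permutations": True}
    if ell >= 4:
        facts["diameter"] = 2
    return FixtureSpec(
        name=f"birkhoff-{ell}",
        params={"ell": ell, "n": n, "m": ell * ell},
        hrep=H,
        interior=uniform,
        known_facts=facts,
    )


def birkhoff_lift(ell: int, x: Sequence[Fraction]) -> list[list[Fraction]]:
    """Complete a reduced Birkhoff point to the full ``ell x ell`` matrix."""
    r = ell - 1
    M = [[Fraction(0)] * ell for _ in range(ell)]
    for i in range(r):
        for j in range(r):
            M[i][j] = Fraction(x[i * r + j])
    for i in range(r):
        M[i][r] = 1 - sum(M[i][:r])
    for j in range(r):
        M[r][j] = 1 - sum(M[i][j] for i in range(r))
    M[r][r] = 1 - sum(M[r][:r])
    return M


def gen_random_regular(n: int, m: int, seed: int, *,
                       precision: int = 10 ** 6, max_retries: int = 64) -> FixtureSpec:
    """Random polytope with ``m`` facet hyperplanes tangent to the unit
    ``(n-1)``-sphere.

    Tangency points are drawn uniformly over the whole sphere and rationalized
    at denominator ``precision`` so the exact kernel can process them;
    sampling repeats until the resulting polytope is bounded.  Almost surely
    every vertex is regular (``sigma = 0``), so the skeleton is ``n``-regular.
    """
    if not (m > n >= 2):
        raise HRepError(f"need m > n >= 2, got n={n}, m={m}")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        U = rng.standard_normal((m, n))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        A = [[Fraction(round(float(u) * precision), precision) for u in row]
             for row in U]
        if any(all(x == 0 for x in row) for row in A):
            continue
        if _bounded(A, n):
            H = HRepresentation(A, [1] * m)
            return FixtureSpec(
                name=f"random-regular-{n}x{m}-s{seed}",
                params={"n": n, "m": m, "seed": seed, "precision": precision},
                hrep=H,
                interior=tuple(Fraction(0) for _ in range(n)),
                known_facts={"regular_degree": n, "all_sigma_zero": True},
            )
    raise HRepError(f"no bounded system found in {max_retries} draws")


def _bounded(A: list[list[Fraction]], n: int) -> bool:
    # Bounded iff every coordinate direction has a finite LP maximum.
    from scipy.optimize import linprog

    Af = np.array([[float(x) for x in row] for row in A])
    bf = np.ones(len(A))
    for j in range(n):
        for sgn in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = -sgn  # maximize sgn * x_j
            res = linprog(c, A_ub=Af, b_ub=bf, bounds=[(None, None)] * n,
                          method="highs")
            if res.status == 3:  # unbounded
                return False
    return True


def gen_classic(family: str, n: int) -> FixtureSpec:
    """Classical oracle fixtures: ``cube``, ``simplex`` or ``crosspolytope``.

    The unit hypercube (regular vertices), the standard simplex (complete
    skeleton) and the cross-polytope (degenerate vertices with
    ``sigma = 2^(n-1) - n``) together exercise every vertex regime.
    """
    if n < 2:
        raise HRepError("classical fixtures require n >= 2")
    if family == "cube":
        A = [_unit(n, i, -1) for i in range(n)] + [_unit(n, i, 1) for i in range(n)]
        b = [0] * n + [1] * n
        facts = {"n_vertices": 2 ** n, "n_edges": n * 2 ** (n - 1),
                 "regular_degree": n, "all_sigma_zero": True}
        interior = tuple(Fraction(1, 2) for _ in range(n))
    elif family == "simplex":
        A = [_unit(n, i, -1) for i in range(n)] + [[1] * n]
        b = [0] * n + [1]
        facts = {"n_vertices": n + 1, "n_edges": n * (n + 1) // 2,
                 "complete": True, "regular_degree": n, "all_sigma_zero": True}
        interior = tuple(Fraction(1, 2 * n) for _ in range(n))
    elif family == "crosspolytope":
        A = [list(signs) for signs in product((1, -1), repeat=n)]
        b = [1] * (2 ** n)
        facts = {"n_vertices": 2 * n, "n_edges": 2 * n * (n - 1),
                 "vertex_sigma": 2 ** (n - 1) - n}
        interior = tuple(Fraction(0) for _ in range(n))
    else:
        raise HRepError(f"unknown family {family!r}")
    H = HRepresentation(A, b)
    start = tuple(Fraction(0) for _ in range(n)) if family in ("cube", "simplex") else None
    return FixtureSpec(name=f"{family}-{n}", params={"n": n, "m": H.m},
                       hrep=H, start=start, interior=interior, known_facts=facts)
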