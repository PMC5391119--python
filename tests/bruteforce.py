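"""Independent skeleton-graph oracle by exhaustive subset enumeration.

Solves every C(m, n) square subsystem with sympy (an independent linear
algebra route from the package's own kernel), keeps the feasible solutions as
vertices, and declares two vertices adjacent when their common active rows
have rank n - 1 (the minimal face containing both is then a segment).  Only
usable for small m; the tests apply it to fixtures with m <= 12.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import sympy as sp


def skeleton_by_enumeration(A, b):
    """Return (vertex set, edge set) of {x : Ax <= b} by brute force."""
    m, n = len(A), len(A[0])
    M = sp.Matrix([[sp.Rational(x) for x in row] for row in A])
    bv = [sp.Rational(x) for x in b]
    verts: dict[tuple[Fraction, ...], tuple[int, ...]] = {}
    for S in combinations(range(m), n):
        sub = M[list(S), :]
        if sub.rank() != n:
            continue
        sol = sub.solve(sp.Matrix([bv[i] for i in S]))
        residual = [bv[i] - (M[i, :] * sol)[0] for i in range(m)]
        if any(r < 0 for r in residual):
            continue
        p = tuple(Fraction(int(x.p), int(x.q)) for x in sol)
        if p not in verts:
            verts[p] = tuple(i for i, r in enumerate(residual) if r == 0)
    keys = sorted(verts)
    edges = set()
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            common = sorted(set(verts[keys[i]]) & set(verts[keys[j]]))
            if common and M[common, :].rank() == n - 1:
                edges.add((keys[i], keys[j]))
    return set(keys), edges
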