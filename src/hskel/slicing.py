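"""Incremental double-description slicing of the cone at a (degenerate) vertex.

At an extreme point ``p`` with active set ``Z(p)`` the feasibility cone,
translated to the origin, is ``D = {x : a_i . x <= 0, i in Z(p)}``.  Its
extreme rays are built incrementally: start from the ``n`` biorthogonal rays
of a basis ``B`` of ``Z(p)`` (a regular cone containing ``D``), then insert
the remaining half-spaces ``B' = Z(p) \\ B`` one at a time.  Each insertion of
``a_k`` keeps the rays on the feasible side, drops the infeasible ones, and
creates one new ray on the cutting hyperplane for every 2-face the hyperplane
slashes — i.e. for every *colaminar* pair ``(rho', rho)`` with ``rho'``
infeasible and ``rho`` feasible:

    phi_k(rho', rho) = (a_k . rho') rho - (a_k . rho) rho'

Whether a pair of extreme rays spans a 2-face is decided either algebraically
(``rank(J|(rho, rho')) = n - 2``) or combinatorially (no third extreme ray is
tight on all of the pair's joint active subset).  The improved slicer keeps a
record ``L`` of pairs already known colaminar — in a regular cone *every*
pair is colaminar, which seeds the record — and rejects outright any pair
whose joint active subset is too small (``|J|(rho, rho')| < n - 2``), so most
pairs never reach a rank computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .hrep import HRepresentation, HRepError
from .linalg import Ray, biorthogonal_rays, primitive, rank_of_rows

__all__ = [
    "DDState",
    "StepTrace",
    "partition_rays",
    "joint_active_set",
    "rejection_precheck",
    "colaminar_algebraic",
    "colaminar_combinatorial",
    "combine_rays",
    "insert_halfspace",
    "slice_cone",
    "audit_state",
]

TestName = Literal["algebraic", "combinatorial"]
Dir = tuple[int, ...]


def _dot(a: Sequence[int], v: Sequence[int]) -> int:
    return sum(x * y for x, y in zip(a, v) if x)


@dataclass
class Counters:
    """Work counters accumulated while slicing one cone."""

    tests: int = 0
    record_hits: int = 0
    rejections: int = 0
    duplicates_merged: int = 0
    ray_counts: list[int] = field(default_factory=list)  # |X| after each insertion

    @property
    def peak_rays(self) -> int:
        return max(self.ray_counts, default=0)


@dataclass
class StepTrace:
    """Everything one insertion step did (kept only when tracing)."""

    k: int
    plus: list[Dir]
    zero: list[Dir]
    minus: list[Dir]
    colaminar_pairs: list[tuple[Dir, Dir]]  # (rho_minus, rho_plus)
    new: list[Dir]


@dataclass
class DDState:
    """A double description ``(J, X_J)`` of the cone being sculpted.

    ``J`` is the set of processed constraint indices (always containing the
    starting basis, hence of rank ``n``); ``rays`` holds the current extreme
    rays keyed by their primitive direction; ``record`` is the set of
    unordered direction pairs known to span a 2-face of the current cone.
    """

    H: HRepresentation
    J: set[int]
    rays: dict[Dir, Ray]
    record: set[frozenset[Dir]] = field(default_factory=set)
    counters: Counters = field(default_factory=Counters)
    trace: list[StepTrace] | None = None

    @classmethod
    def from_basis(cls, H: HRepresentation, basis: Iterable[int], *,
                   keep_trace: bool = False) -> "DDState":
        base = biorthogonal_rays(H, basis)
        rays = {r.direction: r for r in base}
        # In a regular cone every pair of extreme rays is colaminar.
        dirs = list(rays)
        record = {
            frozenset((dirs[i], dirs[j]))
            for i in range(len(dirs)) for j in range(i + 1, len(dirs))
        }
        return cls(H=H, J=set(basis), rays=rays, record=record,
                   trace=[] if keep_trace else None)

    def ray_set(self) -> frozenset[Dir]:
        """Canonical (order-free) view of the current extreme rays."""
        return frozenset(self.rays)


def partition_rays(rays: Iterable[Ray], a_k: Sequence[int]):
    """Split rays by the exact sign of ``a_k . rho``.

    Returns ``(X_plus, X_zero, X_minus)``: rays strictly inside the feasible
    half-space (``a_k . rho < 0``), on its hyperplane, and strictly outside.
    """
    plus, zero, minus = [], [], []
    for r in rays:
        d = _dot(a_k, r.direction)
        (plus if d < 0 else zero if d == 0 else minus).append(r)
    return plus, zero, minus


def joint_active_set(rho: Ray, rho2: Ray) -> frozenset[int]:
    """``J|(rho, rho') = J|rho  ∩  J|rho'`` within the owning cone."""
    return rho.active & rho2.active


def rejection_precheck(joint: frozenset[int], n: int) -> bool:
    """Necessary condition for colaminarity: ``|J|(rho, rho')| >= n - 2``.

    Returns ``True`` when the pair must still be tested (kept), ``False``
    when it can never be colaminar (rejected).
    """
    return len(joint) >= n - 2


def colaminar_algebraic(H: HRepresentation, joint: Iterable[int], n: int) -> bool:
    """Algebraic 2-face test: ``rank {a_i : i in J|(rho, rho')} = n - 2``."""
    return rank_of_rows(H, joint) == n - 2


def colaminar_combinatorial(rays: Iterable[Ray], rho: Ray, rho2: Ray) -> bool:
    """Combinatorial 2-face test: no third extreme ray of the cone is tight
    on the whole joint active subset of the pair."""
    joint = rho.active & rho2.active
    for phi in rays:
        if phi is rho or phi is rho2:
            continue
        if joint <= phi.active:
            return False
    return True


def combine_rays(H: HRepresentation, J_new: Iterable[int], k: int,
                 rho_minus: Ray, rho_plus: Ray) -> Ray:
    """New extreme ray on the cutting hyperplane of ``a_k``.

    ``phi = (a_k . rho') rho - (a_k . rho) rho'`` for ``rho'`` outside
    (``a_k . rho' > 0``) and ``rho`` inside (``a_k . rho < 0``); ``phi`` is a
    positive combination of the pair, lies on the hyperplane, and is returned
    in primitive form.  Its active subset is recomputed by direct dot
    products over ``J ∪ {k}`` — not by set union — so coincidental
    incidences in highly degenerate systems are captured.
    """
    a = H.row_int(k)
    dm = _dot(a, rho_minus.direction)
    dp = _dot(a, rho_plus.direction)
    if not (dm > 0 and dp < 0):
        raise HRepError(
            f"combine_rays precondition violated: a_{k}.rho'={dm} (need >0), "
            f"a_{k}.rho={dp} (need <0)"
        )
    phi = primitive([dm * x - dp * y
                     for x, y in zip(rho_plus.direction, rho_minus.direction)])
    active = frozenset(i for i in J_new if _dot(H.row_int(i), phi) == 0)
    return Ray(direction=phi, active=active)


def insert_halfspace(state: DDState, k: int, *, test: TestName = "algebraic",
                     use_record: bool = True) -> DDState:
    """Insert half-space ``k`` into the cone, updating ``state`` in place.

    With ``use_record=False`` this is the standard insertion: every pair in
    ``X_minus x X_plus`` is submitted to the colaminarity test.  With
    ``use_record=True`` the improved insertion applies the rejection
    pre-test, then consults the 2-face record before testing; record entries
    whose outside ray dies are replaced by the freshly created ray.
    """
    H, n = state.H, state.H.n
    if k in state.J:
        raise HRepError(f"half-space {k} already processed")
    a = H.row_int(k)
    plus, zero, minus = partition_rays(state.rays.values(), a)
    J_new = state.J | {k}

    survivors: dict[Dir, Ray] = {}
    for r in plus:
        survivors[r.direction] = r
    for r in zero:
        survivors[r.direction] = Ray(direction=r.direction, active=r.active | {k})

    pairs_done: list[tuple[Dir, Dir]] = []
    new_dirs: list[Dir] = []
    for rm in minus:
        for rp in plus:
            joint = rm.active & rp.active
            if use_record:
                if not rejection_precheck(joint, n):
                    state.counters.rejections += 1
                    continue
                pair = frozenset((rm.direction, rp.direction))
                if pair in state.record:
                    state.counters.record_hits += 1
                    phi = combine_rays(H, J_new, k, rm, rp)
                    state.record.discard(pair)
                    state.record.add(frozenset((rp.direction, phi.direction)))
                    if phi.direction in survivors:
                        state.counters.duplicates_merged += 1
                    else:
                        survivors[phi.direction] = phi
                        new_dirs.append(phi.direction)
                    pairs_done.append((rm.direction, rp.direction))
                    continue
            state.counters.tests += 1
            if test == "algebraic":
                ok = colaminar_algebraic(H, joint, n)
            else:
                ok = colaminar_combinatorial(state.rays.values(), rm, rp)
            if ok:
                phi = combine_rays(H, J_new, k, rm, rp)
                if use_record:
                    state.record.add(frozenset((rp.direction, phi.direction)))
                if phi.direction in survivors:
                    state.counters.duplicates_merged += 1
                else:
                    survivors[phi.direction] = phi
                    new_dirs.append(phi.direction)
                pairs_done.append((rm.direction, rp.direction))

    if state.trace is not None:
        state.trace.append(StepTrace(
            k=k,
            plus=[r.direction for r in plus],
            zero=[r.direction for r in zero],
            minus=[r.direction for r in minus],
            colaminar_pairs=pairs_done,
            new=new_dirs,
        ))

    state.J = J_new
    state.rays = survivors
    if use_record:
        # entries naming a ray that just died are unreachable; drop them so
        # the record stays auditable against the current cone
        alive = survivors.keys()
        state.record = {pr for pr in state.record
                        if all(d in alive for d in pr)}
    state.counters.ray_counts.append(len(survivors))
    return state


def slice_cone(H: HRepresentation, basis: Iterable[int], order: Sequence[int], *,
               test: TestName = "algebraic", use_record: bool = True,
               keep_trace: bool = False) -> DDState:
    """Sculpt the cone of an active set by inserting ``order`` one at a time.

    ``basis`` must be a rank-``n`` subset of the active set and ``order`` the
    remaining indices (any order; the final ray set does not depend on it).
    Returns the final :class:`DDState`; its ``rays`` are the extreme rays of
    the vertex cone.
    """
    B = set(basis)
    if B & set(order):
        raise HRepError("basis and insertion order overlap")
    state = DDState.from_basis(H, B, keep_trace=keep_trace)
    for k in order:
        insert_halfspace(state, k, test=test, use_record=use_record)
    return state


def audit_state(state: DDState) -> None:
    """Assert the double-description invariants of a state (used in tests).

    Checks that every ray satisfies all processed constraints with equality
    exactly on its recorded active subset, carries the extreme-ray rank
    certificate ``rank(J|rho) = n - 1``, and that every pair in the record is
    genuinely colaminar in the current cone.
    """
    H, n = state.H, state.H.n
    for r in state.rays.values():
        for i in state.J:
            d = _dot(H.row_int(i), r.direction)
            if d > 0:
                raise AssertionError(f"ray {r.direction} violates constraint {i}")
            if (d == 0) != (i in r.active):
                raise AssertionError(
                    f"active subset of ray {r.direction} wrong at constraint {i}")
        if rank_of_rows(H, r.active) != n - 1:
            raise AssertionError(
                f"ray {r.direction} lacks the rank n-1 extremality certificate")
    for pair in state.record:
        rays = [state.rays[d] for d in pair]
        if len(rays) != 2:
            continue  # self-pair cannot arise; degenerate frozenset guard
        if not colaminar_algebraic(H, rays[0].active & rays[1].active, n):
            raise AssertionError(f"record contains non-colaminar pair {pair}")
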