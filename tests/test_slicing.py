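import random
from itertools import combinations, permutations

import pytest

import hskel as hk
from hskel.hrep import HRepError
from hskel.slicing import DDState, insert_halfspace


def e(i, n=14, c=1):
    v = [0] * n
    v[i] = c
    return tuple(v)


def esum(*idx):
    v = [0] * 14
    for i in idx:
        v[i] = 1
    return tuple(v)


# ------------------------------------------------------------- partition

def test_first_insertion_partition(ns):
    """Inserting the first degeneracy half-space splits the 14 base rays
    into 3 feasible, 9 on the hyperplane, 2 infeasible."""
    rays = hk.biorthogonal_rays(ns.hrep, range(14))
    plus, zero, minus = hk.partition_rays(rays, ns.hrep.row_int(14))
    assert {r.direction for r in plus} == {e(0), e(1), e(2)}
    assert {r.direction for r in minus} == {e(5), e(6)}
    assert len(zero) == 9
    assert len(plus) + len(zero) + len(minus) == 14


def test_partition_orthogonal_and_sign_flip(ns):
    rays = hk.biorthogonal_rays(ns.hrep, range(14))
    plus, zero, minus = hk.partition_rays(rays, (0,) * 14)
    assert not plus and not minus and len(zero) == 14
    # negating the constraint swaps the strict sides
    p2, z2, m2 = hk.partition_rays(rays, tuple(-x for x in ns.hrep.row_int(14)))
    assert {r.direction for r in p2} == {e(5), e(6)}
    assert {r.direction for r in m2} == {e(0), e(1), e(2)}


# ------------------------------------------------------------- joint active sets

def test_joint_active_set_of_base_pairs(ns):
    rays = {r.direction: r for r in hk.biorthogonal_rays(ns.hrep, range(14))}
    j = hk.joint_active_set(rays[e(0)], rays[e(1)])
    assert j == frozenset(range(14)) - {0, 1}
    assert len(j) == 12  # n - 2
    assert hk.joint_active_set(rays[e(0)], rays[e(0)]) == rays[e(0)].active
    for a, b in combinations(rays.values(), 2):
        assert len(hk.joint_active_set(a, b)) == 12


@pytest.mark.parametrize("size,keep", [(11, False), (12, True), (13, True)])
def test_rejection_precheck_boundary(size, keep):
    joint = frozenset(range(size))
    assert hk.rejection_precheck(joint, 14) is keep


# ------------------------------------------------------------- colaminarity tests

def test_base_cone_pairs_pass_both_tests(ns):
    H = ns.hrep
    rays = hk.biorthogonal_rays(H, range(14))
    for a, b in combinations(rays, 2):
        joint = hk.joint_active_set(a, b)
        assert hk.colaminar_algebraic(H, joint, 14)
        assert hk.colaminar_combinatorial(rays, a, b)


def test_algebraic_test_sees_through_duplicated_rows():
    # joint of full size n-2 whose rows are rank-deficient (a repeated
    # constraint) must fail the algebraic test
    A = [[-1, 0, 0, 0], [0, -1, 0, 0], [0, 0, -1, 0], [0, 0, 0, -1],
         [-1, 0, 0, 0],  # duplicate of row 0
         [1, 1, 1, 1]]
    H = hk.HRepresentation(A, [0, 0, 0, 0, 0, 1])
    assert not hk.colaminar_algebraic(H, [0, 4], 4)   # rank 1 != 2
    assert hk.colaminar_algebraic(H, [0, 1], 4)


def test_both_tests_agree_on_every_pair_during_slicing(ns):
    """Paired-oracle replay: at every insertion step of the origin cone, the
    algebraic and combinatorial tests give the same verdict on every
    candidate pair in X- x X+."""
    H = ns.hrep
    state = DDState.from_basis(H, range(14))
    for k in range(14, 20):
        plus, zero, minus = hk.partition_rays(state.rays.values(), H.row_int(k))
        for rm in minus:
            for rp in plus:
                joint = hk.joint_active_set(rm, rp)
                assert (hk.colaminar_algebraic(H, joint, 14)
                        == hk.colaminar_combinatorial(state.rays.values(), rm, rp))
        insert_halfspace(state, k, use_record=False)


# ------------------------------------------------------------- new rays

def test_combine_rays_reproduces_first_insertion_table(ns):
    H = ns.hrep
    rays = {r.direction: r for r in hk.biorthogonal_rays(H, range(14))}
    J = set(range(15))
    phi = hk.combine_rays(H, J, 14, rays[e(5)], rays[e(0)])
    assert phi.direction == esum(0, 5)
    phi2 = hk.combine_rays(H, J, 14, rays[e(6)], rays[e(2)])
    assert phi2.direction == esum(2, 6)
    for rm in (e(5), e(6)):
        for rp in (e(0), e(1), e(2)):
            out = hk.combine_rays(H, J, 14, rays[rm], rays[rp])
            a = H.row_int(14)
            assert sum(x * y for x, y in zip(a, out.direction)) == 0
            assert 14 in out.active
    with pytest.raises(HRepError):
        hk.combine_rays(H, J, 14, rays[e(0)], rays[e(5)])  # sides swapped


def test_first_insertion_gains_six_loses_two(ns):
    state = DDState.from_basis(ns.hrep, range(14))
    insert_halfspace(state, 14)
    assert len(state.rays) == 18
    new = set(state.rays) - {e(i) for i in range(14)}
    assert new == {esum(0, 5), esum(1, 5), esum(2, 5),
                   esum(0, 6), esum(1, 6), esum(2, 6)}


def test_insertion_with_empty_minus_side_only_bookkeeps():
    A = [[-1, 0], [0, -1], [-1, -1], [1, 1]]
    H2 = hk.HRepresentation(A, [0, 0, 0, 1])
    st2 = DDState.from_basis(H2, [0, 1])
    before = st2.ray_set()
    insert_halfspace(st2, 2)  # -x-y <= 0 holds on the whole positive cone
    assert st2.ray_set() == before
    assert 2 in st2.J


# ------------------------------------------------------------- full slicing

def test_origin_cone_has_54_rays_and_hump_trajectory(ns):
    state = hk.slice_cone(ns.hrep, range(14), range(14, 20))
    assert len(state.rays) == 54
    # per-step counts follow from each step's gains and losses:
    # 14-2+6, +6-2, +12-3, +12-3, +14-7, +14-7
    assert state.counters.ray_counts == [18, 22, 31, 40, 47, 54]
    hk.audit_state(state)


def test_regular_vertex_slicing_returns_base_rays():
    H = hk.gen_classic("cube", 3).hrep
    state = hk.slice_cone(H, [0, 1, 2], [])
    assert state.ray_set() == {r.direction for r in hk.biorthogonal_rays(H, [0, 1, 2])}


def test_h18_step_reproduces_the_sparse_2face_pattern(ns):
    """The insertion of the sixth-to-last half-space slashes exactly 14
    2-faces, with the sparse incidence pattern of the worked example."""
    state = hk.slice_cone(ns.hrep, range(14), range(14, 20), keep_trace=True)
    step = next(t for t in state.trace if t.k == 18)
    assert (len(step.plus), len(step.zero), len(step.minus)) == (8, 25, 7)
    assert len(step.colaminar_pairs) == 14
    row_marg = sorted(sum(1 for rm, _ in step.colaminar_pairs if rm == d)
                      for d in step.minus)
    col_marg = sorted(sum(1 for _, rp in step.colaminar_pairs if rp == d)
                      for d in step.plus)
    assert row_marg == [1, 1, 1, 1, 3, 3, 4]
    assert col_marg == [0, 0, 0, 0, 2, 2, 3, 7]
    # the surviving base ray e7 spans a 2-face with every dying ray
    assert sum(1 for _, rp in step.colaminar_pairs if rp == e(7)) == 7


def test_standard_and_recording_slicers_agree_stepwise(ns):
    """The standard insertion (test every pair) and the improved insertion
    (record + rejection pre-test) produce identical ray sets at every step,
    for either colaminarity test."""
    H = ns.hrep
    states = {
        (test, rec): DDState.from_basis(H, range(14))
        for test in ("algebraic", "combinatorial") for rec in (True, False)
    }
    ref = None
    for k in range(14, 20):
        sets = []
        for (test, rec), st in states.items():
            insert_halfspace(st, k, test=test, use_record=rec)
            sets.append(st.ray_set())
        assert all(s == sets[0] for s in sets), f"divergence at step {k}"
    # the record saves work: improved slicer runs strictly fewer tests
    assert (states[("algebraic", True)].counters.tests
            < states[("algebraic", False)].counters.tests)
    assert states[("algebraic", True)].counters.record_hits > 0


def test_no_duplicate_rays_in_exact_mode(ns):
    state = hk.slice_cone(ns.hrep, range(14), range(14, 20))
    assert state.counters.duplicates_merged == 0


def test_order_invariance_sampled(ns):
    base = hk.slice_cone(ns.hrep, range(14), range(14, 20)).ray_set()
    rng = random.Random(5)
    orders = [tuple(rng.sample(range(14, 20), 6)) for _ in range(12)]
    orders.append(tuple(reversed(range(14, 20))))
    for o in orders:
        assert hk.slice_cone(ns.hrep, range(14), o).ray_set() == base


def test_basis_invariance_sampled(ns):
    H = ns.hrep
    Z = list(range(20))
    base = hk.slice_cone(H, range(14), range(14, 20)).ray_set()
    rng = random.Random(11)
    found = 0
    while found < 4:
        B = sorted(rng.sample(Z, 14))
        if hk.matrix_rank([H.A[i] for i in B]) < 14:
            continue
        found += 1
        Bp = [i for i in Z if i not in B]
        assert hk.slice_cone(H, B, Bp).ray_set() == base


def test_full_basis_and_order_sweep_on_birkhoff3():
    """On a small degenerate cone, *every* basis and *every* insertion order
    yield the same extreme-ray set."""
    fix = hk.gen_birkhoff(3)
    H = fix.hrep
    v = hk.tighten_to_vertex(H, fix.interior)
    ref = None
    for B in combinations(v.active, H.n):
        if hk.matrix_rank([H.A[i] for i in B]) < H.n:
            continue
        Bp = [i for i in v.active if i not in B]
        for order in permutations(Bp):
            rs = hk.slice_cone(H, B, order).ray_set()
            if ref is None:
                ref = rs
            assert rs == ref


def test_audit_after_every_insertion(ns):
    state = DDState.from_basis(ns.hrep, range(14))
    for k in range(14, 20):
        insert_halfspace(state, k)
        hk.audit_state(state)


def test_overlapping_basis_and_order_rejected(ns):
    with pytest.raises(HRepError):
        hk.slice_cone(ns.hrep, range(14), [13, 14])
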