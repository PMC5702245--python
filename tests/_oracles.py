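"""Independent exact-arithmetic LP oracle for tiny flux networks.

Enumerates all basic feasible solutions (vertices) of the flux polytope
{S v = 0, l <= v <= u} with rational arithmetic and returns the exact
optimum.  Deliberately brute force and solver-free so it can arbitrate the
FBA implementation on networks of up to ~8 reactions.
"""

from fractions import Fraction
from itertools import combinations, product
from typing import List, Optional, Sequence, Tuple


def _rref(rows: List[List[Fraction]]) -> List[List[Fraction]]:
    """Reduced row echelon form; returns the nonzero rows."""
    rows = [list(r) for r in rows]
    n_cols = len(rows[0]) if rows else 0
    pivot_row = 0
    for col in range(n_cols):
        pivot = next(
            (r for r in range(pivot_row, len(rows)) if rows[r][col] != 0), None
        )
        if pivot is None:
            continue
        rows[pivot_row], rows[pivot] = rows[pivot], rows[pivot_row]
        factor = rows[pivot_row][col]
        rows[pivot_row] = [x / factor for x in rows[pivot_row]]
        for r in range(len(rows)):
            if r != pivot_row and rows[r][col] != 0:
                scale = rows[r][col]
                rows[r] = [a - scale * b for a, b in zip(rows[r], rows[pivot_row])]
        pivot_row += 1
        if pivot_row == len(rows):
            break
    return [r for r in rows if any(x != 0 for x in r)]


def _solve_square(A: List[List[Fraction]], b: List[Fraction]) -> Optional[List[Fraction]]:
    """Exact solve of a square system; None when singular."""
    n = len(A)
    M = [list(A[i]) + [b[i]] for i in range(n)]
    for col in range(n):
        pivot = next((r for r in range(col, n) if M[r][col] != 0), None)
        if pivot is None:
            return None
        M[col], M[pivot] = M[pivot], M[col]
        factor = M[col][col]
        M[col] = [x / factor for x in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                scale = M[r][col]
                M[r] = [a - scale * b_ for a, b_ in zip(M[r], M[col])]
    return [M[i][n] for i in range(n)]


def brute_force_lp_max(
    S: Sequence[Sequence[float]],
    lb: Sequence[float],
    ub: Sequence[float],
    c: Sequence[float],
) -> Optional[Fraction]:
    """Exact maximum of c.v over {S v = 0, lb <= v <= ub}, None if infeasible.

    Every vertex of the (bounded) polytope is a basic solution: a set of
    basis columns solving the equality system while the remaining variables
    sit at a bound.  All such candidates are enumerated.
    """
    S = [[Fraction(x).limit_denominator(10**9) for x in row] for row in S]
    lb = [Fraction(x).limit_denominator(10**9) for x in lb]
    ub = [Fraction(x).limit_denominator(10**9) for x in ub]
    c = [Fraction(x).limit_denominator(10**9) for x in c]
    n = len(lb)
    rows = _rref(S) if S else []
    r = len(rows)
    best: Optional[Fraction] = None

    def consider(v: List[Fraction]) -> None:
        nonlocal best
        if any(not (lb[j] <= v[j] <= ub[j]) for j in range(n)):
            return
        value = sum(ci * vi for ci, vi in zip(c, v))
        if best is None or value > best:
            best = value

    if r == 0:
        # no coupling: optimum at a bound of each variable independently
        v = [ub[j] if c[j] > 0 else lb[j] for j in range(n)]
        consider(v)
        return best

    for basis in combinations(range(n), r):
        A = [[rows[i][j] for j in basis] for i in range(r)]
        nonbasic = [j for j in range(n) if j not in basis]
        for corner in product(*[(lb[j], ub[j]) for j in nonbasic]):
            b = [
                -sum(rows[i][j] * val for j, val in zip(nonbasic, corner))
                for i in range(r)
            ]
            sol = _solve_square(A, b)
            if sol is None:
                break  # singular basis: no corner of this basis exists
            v = [Fraction(0)] * n
            for j, val in zip(nonbasic, corner):
                v[j] = val
            for j, val in zip(basis, sol):
                v[j] = val
            consider(v)
    return best
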