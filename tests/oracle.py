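"""Independent LP oracles for the test suite.

Deliberately avoids scipy/HiGHS (the backend under test): a dense
textbook two-phase tableau simplex with Bland's rule for general
fixtures, and exhaustive basic-feasible-solution enumeration for tiny
networks. Slow but transparent.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

TOL = 1e-9


def _tableau_simplex(c: np.ndarray, A: np.ndarray, b: np.ndarray,
                     max_iter: int = 20000) -> Tuple[str, Optional[np.ndarray]]:
    """Minimise c.y subject to A y = b, y >= 0 (b >= 0 required)."""
    m, n = A.shape

    def run_phase(T: np.ndarray, basis: List[int], ncols: int) -> str:
        for _ in range(max_iter):
            # Bland: entering = smallest index with negative reduced cost
            enter = -1
            for j in range(ncols):
                if T[-1, j] < -TOL:
                    enter = j
                    break
            if enter < 0:
                return "optimal"
            ratios = []
            for i in range(m):
                if T[i, enter] > TOL:
                    ratios.append((T[i, -1] / T[i, enter], basis[i], i))
            if not ratios:
                return "unbounded"
            _, _, leave = min(ratios)
            piv = T[leave, enter]
            T[leave, :] /= piv
            for i in range(m + 1):
                if i != leave and abs(T[i, enter]) > 0:
                    T[i, :] -= T[i, enter] * T[leave, :]
            basis[leave] = enter
        raise RuntimeError("simplex iteration limit")

    # phase 1
    T = np.zeros((m + 1, n + m + 1))
    T[:m, :n] = A
    T[:m, n:n + m] = np.eye(m)
    T[:m, -1] = b
    basis = list(range(n, n + m))
    T[-1, :n] = -A.sum(axis=0)
    T[-1, -1] = -b.sum()
    status = run_phase(T, basis, n + m)
    if status != "optimal" or T[-1, -1] < -1e-7:
        return "infeasible", None
    # drive artificials out of the basis where possible
    for i in range(m):
        if basis[i] >= n:
            for j in range(n):
                if abs(T[i, j]) > TOL:
                    piv = T[i, j]
                    T[i, :] /= piv
                    for k in range(m + 1):
                        if k != i and abs(T[k, j]) > 0:
                            T[k, :] -= T[k, j] * T[i, :]
                    basis[i] = j
                    break
    # phase 2
    T2 = np.zeros((m + 1, n + 1))
    T2[:m, :n] = T[:m, :n]
    T2[:m, -1] = T[:m, -1]
    T2[-1, :n] = c
    for i in range(m):
        if basis[i] < n:
            T2[-1, :] -= c[basis[i]] * T2[i, :]
    status = run_phase(T2, basis, n)
    if status == "unbounded":
        return "unbounded", None
    y = np.zeros(n)
    for i in range(m):
        if basis[i] < n:
            y[basis[i]] = T2[i, -1]
    return "optimal", y


def solve_bounded_lp(
    c: Sequence[float],
    A_eq: np.ndarray,
    b_eq: Sequence[float],
    lb: Sequence[float],
    ub: Sequence[float],
    maximize: bool = True,
) -> Tuple[str, Optional[np.ndarray], Optional[float]]:
    """Optimise c.x subject to A_eq x = b_eq and l <= x <= u."""
    c = np.asarray(c, dtype=float)
    A = np.asarray(A_eq, dtype=float)
    b = np.asarray(b_eq, dtype=float)
    lo = np.asarray(lb, dtype=float)
    hi = np.asarray(ub, dtype=float)
    n = len(c)
    d = hi - lo
    # x = w + lo, 0 <= w <= d; slack s: w + s = d
    A1 = np.hstack([A, np.zeros((A.shape[0], n))])
    b1 = b - A @ lo
    A2 = np.hstack([np.eye(n), np.eye(n)])
    big_A = np.vstack([A1, A2])
    big_b = np.concatenate([b1, d])
    neg = big_b < 0
    big_A[neg, :] *= -1
    big_b[neg] *= -1
    obj = np.concatenate([-c if maximize else c, np.zeros(n)])
    status, y = _tableau_simplex(obj, big_A, big_b)
    if status != "optimal":
        return status, None, None
    x = y[:n] + lo
    return "optimal", x, float(c @ x)


def _model_arrays(model):
    S = model.stoichiometric_matrix().toarray()
    lb, ub = model.bounds_arrays()
    rids = model.reaction_ids()
    c = np.zeros(len(rids))
    c[rids.index(model.objective)] = 1.0
    return S, lb, ub, rids, c


def fba_oracle(model) -> Tuple[str, Optional[float]]:
    """Independent growth maximisation via the tableau simplex."""
    S, lb, ub, _, c = _model_arrays(model)
    status, _, obj = solve_bounded_lp(c, S, np.zeros(S.shape[0]), lb, ub)
    return status, obj


def fva_oracle(
    model, fraction_of_optimum: float = 1.0, reactions: Optional[Sequence[str]] = None
) -> Dict[str, Tuple[float, float]]:
    """Independent per-reaction min/max at a fraction of the optimum.

    The objective floor is encoded by an auxiliary variable z with
    lower bound fraction*optimum and the row c.v - z = 0.
    """
    S, lb, ub, rids, c = _model_arrays(model)
    status, opt = fba_oracle(model)
    assert status == "optimal", status
    n = len(rids)
    A = np.hstack([S, np.zeros((S.shape[0], 1))])
    A = np.vstack([A, np.concatenate([c, [-1.0]])])
    b = np.zeros(A.shape[0])
    lo = np.concatenate([lb, [fraction_of_optimum * opt - 1e-9 * max(1.0, abs(opt))]])
    hi = np.concatenate([ub, [max(abs(opt) * 2, 1.0) + abs(opt)]])
    wanted = list(reactions) if reactions is not None else rids
    out: Dict[str, Tuple[float, float]] = {}
    for rid in wanted:
        j = rids.index(rid)
        e = np.zeros(n + 1)
        e[j] = 1.0
        st1, _, vmin = solve_bounded_lp(e, A, b, lo, hi, maximize=False)
        st2, _, vmax = solve_bounded_lp(e, A, b, lo, hi, maximize=True)
        assert st1 == st2 == "optimal", (rid, st1, st2)
        out[rid] = (vmin, vmax)
    return out


def enumerate_vertex_optimum(model) -> Optional[float]:
    """Exhaustive basic-feasible-solution enumeration (tiny models only).

    Every vertex of {v : S v = 0, l <= v <= u} has at least n - rank(S)
    coordinates at a bound; enumerate all such fixings and keep the
    feasible completions.
    """
    S, lb, ub, rids, c = _model_arrays(model)
    n = len(rids)
    rank = np.linalg.matrix_rank(S, tol=1e-10)
    n_fixed = n - rank
    if n_fixed < 0:
        return None
    best = None
    scale = np.maximum(1.0, np.abs(S).max())
    for fixed_tuple in itertools.combinations(range(n), n_fixed):
        fixed = list(fixed_tuple)
        free = [j for j in range(n) if j not in fixed_tuple]
        S_B = S[:, free]
        for choice in itertools.product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for idx, j in enumerate(fixed):
                v[j] = ub[j] if choice[idx] else lb[j]
            rhs = -S[:, fixed] @ v[fixed]
            sol, residual, *_ = np.linalg.lstsq(S_B, rhs, rcond=None)
            v[free] = sol
            if np.linalg.norm(S @ v) > 1e-7 * scale:
                continue
            if np.any(v < lb - 1e-8) or np.any(v > ub + 1e-8):
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best
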