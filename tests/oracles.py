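"""Independent oracles used by the test suite.

These deliberately avoid the code paths of the package:

* ``barcode_by_rank`` derives barcodes from persistent Betti numbers
  computed by GF(2) rank computations and inclusion-exclusion over the
  critical-value grid -- pure linear algebra, no pairing algorithm.
* ``bottleneck_bruteforce`` / ``wasserstein_bruteforce`` enumerate every
  augmented matching with itertools.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- GF(2) rank


def gf2_rank(columns: list[int]) -> int:
    """Rank of a GF(2) matrix whose columns are given as bitsets."""
    basis: dict[int, int] = {}
    rank = 0
    for c in columns:
        while c:
            b = c.bit_length() - 1
            if b in basis:
                c ^= basis[b]
            else:
                basis[b] = c
                rank += 1
                break
    return rank


def barcode_by_rank(fc, max_k: int = 2) -> dict[int, list[tuple[float, float]]]:
    """Barcode of a filtered complex from persistent Betti numbers.

    beta_k(s, t) = dim Z_k(K_s) - dim(B_k(K_t) ∩ C_k(K_s)); the multiplicity
    of the interval (u_i, u_j) follows by inclusion-exclusion on the grid of
    critical values u_1 < ... < u_c (with u_{c+1} = +inf for essential
    classes).  Exact but O(c^2) rank computations: small complexes only.
    """
    order = fc.sorted_simplices()
    values = sorted({v for _, v in order})
    c = len(values)
    # simplices per dimension with their values, indexed per dimension
    by_dim: dict[int, list[tuple[tuple[int, ...], float]]] = {}
    for s, v in order:
        by_dim.setdefault(len(s) - 1, []).append((s, v))

    out: dict[int, list[tuple[float, float]]] = {}
    for k in range(max_k + 1):
        k_simp = by_dim.get(k, [])
        km1 = {s: i for i, (s, _) in enumerate(by_dim.get(k - 1, []))}
        kp1 = by_dim.get(k + 1, [])
        k_index = {s: i for i, (s, _) in enumerate(k_simp)}
        k_values = np.array([v for _, v in k_simp])

        # columns of the boundary of k-simplices (rows: (k-1)-simplices)
        def bd_col(s):
            col = 0
            if k > 0:
                for f in itertools.combinations(s, k):
                    col |= 1 << km1[f]
            return col

        def bd_col_kp1(s):
            col = 0
            for f in itertools.combinations(s, k + 1):
                col |= 1 << k_index[f]
            return col

        k_cols = [bd_col(s) for s, _ in k_simp]
        kp1_cols = [(bd_col_kp1(s), v) for s, v in kp1]

        def beta(si: int, ti: int) -> int:
            """Persistent Betti number for K_{u_si} -> K_{u_ti} (1-based; 0 = empty)."""
            if si == 0:
                return 0
            us, ut = values[si - 1], values[ti - 1]
            sel = k_values <= us
            n_k = int(sel.sum())
            rank_bd = gf2_rank([k_cols[i] for i in range(len(k_cols)) if sel[i]])
            z = n_k - rank_bd
            cols_t = [col for col, v in kp1_cols if v <= ut]
            mask = 0
            for i in range(len(k_simp)):
                if sel[i]:
                    mask |= 1 << i
            b_in_s = gf2_rank(cols_t) - gf2_rank([col & ~mask for col in cols_t])
            return z - b_in_s

        intervals = []
        # cache betas on the (c+1) x c grid
        B = {}
        for si in range(c + 1):
            for ti in range(max(si, 1), c + 1):
                B[(si, ti)] = beta(si, ti)
        for i in range(1, c + 1):
            for j in range(i + 1, c + 1):
                mult = (
                    B[(i, j - 1)] - B[(i, j)] - B[(i - 1, j - 1)] + B[(i - 1, j)]
                )
                intervals.extend([(values[i - 1], values[j - 1])] * mult)
            ess = B[(i, c)] - B[(i - 1, c)]
            intervals.extend([(values[i - 1], math.inf)] * ess)
        out[k] = sorted(intervals)
    return out


# ----------------------------------------------------- matching enumerations


def _l2(a, b) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def _linf(a, b) -> float:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def _diag_linf(a) -> float:
    return (a[1] - a[0]) / 2.0


def _diag_l2(a) -> float:
    return (a[1] - a[0]) / math.sqrt(2.0)


def _augmented_matchings(n: int, m: int):
    """Yield all augmented matchings as lists of (i, j); unmatched -> diagonal."""
    for size in range(0, min(n, m) + 1):
        for ps in itertools.combinations(range(n), size):
            for qs in itertools.permutations(range(m), size):
                yield list(zip(ps, qs))


def bottleneck_bruteforce(P: np.ndarray, Q: np.ndarray) -> float:
    best = math.inf
    for matching in _augmented_matchings(len(P), len(Q)):
        used_p = {i for i, _ in matching}
        used_q = {j for _, j in matching}
        cost = 0.0
        for i, j in matching:
            cost = max(cost, _linf(P[i], Q[j]))
        for i in range(len(P)):
            if i not in used_p:
                cost = max(cost, _diag_linf(P[i]))
        for j in range(len(Q)):
            if j not in used_q:
                cost = max(cost, _diag_linf(Q[j]))
        best = min(best, cost)
    return best if best < math.inf else 0.0


def wasserstein_bruteforce(P: np.ndarray, Q: np.ndarray, q: float = 2.0) -> float:
    best = math.inf
    for matching in _augmented_matchings(len(P), len(Q)):
        used_p = {i for i, _ in matching}
        used_q = {j for _, j in matching}
        cost = sum(_l2(P[i], Q[j]) ** q for i, j in matching)
        cost += sum(_diag_l2(P[i]) ** q for i in range(len(P)) if i not in used_p)
        cost += sum(_diag_l2(Q[j]) ** q for j in range(len(Q)) if j not in used_q)
        best = min(best, cost)
    if best is math.inf:
        return 0.0
    return best ** (1.0 / q)


# ------------------------------------------------------------ misc helpers


def random_barcode(rng: np.random.Generator, max_intervals: int = 6) -> np.ndarray:
    n = int(rng.integers(0, max_intervals + 1))
    b = rng.uniform(0, 5, size=n)
    p = rng.uniform(0.05, 3, size=n)
    return np.column_stack([b, b + p]) if n else np.zeros((0, 2))


def match_barcodes(a: np.ndarray, b: np.ndarray, tol: float = 1e-9) -> bool:
    """Multiset equality of interval lists within tolerance."""
    a = np.asarray(sorted(map(tuple, np.asarray(a).reshape(-1, 2))))
    b = np.asarray(sorted(map(tuple, np.asarray(b).reshape(-1, 2))))
    if a.shape != b.shape:
        return False
    if len(a) == 0:
        return True
    finite = np.isfinite(a) & np.isfinite(b)
    if not (np.isfinite(a) == np.isfinite(b)).all():
        return False
    return bool(np.allclose(a[finite], b[finite], atol=tol, rtol=0))
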