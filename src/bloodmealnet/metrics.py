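"""Weighted bipartite network metrics: interaction evenness and H2'.

Interaction evenness (IE) is the Shannon entropy of the link-weight
distribution scaled by its maximum, ``IE = H / ln L``.  Two denominators are
in circulation: the number of realized links L (the printed formula) and the
number of matrix cells (rows x columns, the convention of the widely used R
implementation).  Both are provided; realized links is the default and the
mode used is recorded with every result.

H2' standardises the observed two-dimensional entropy H2 between the
minimum and maximum entropies achievable by any nonnegative *integer*
matrix sharing the observed row and column totals:

    H2' = (H2max - H2) / (H2max - H2min)

so 0 means interaction frequencies match the random expectation given the
marginals (maximal generalisation) and 1 means maximal specialisation.
The extrema are found by combinatorial search:

* ``H2max`` — minimise sum n*ln(n) over the transportation polytope of the
  marginals: proportional fill (floor of expected counts) completed greedily,
  then unit pushes along alternating cycles until no push improves.  For
  matrices whose smaller dimension is <= 3 every residual cycle has length
  <= 6, all of which are searched, so the result is exactly optimal there
  (this covers the brute-force-verifiable scale).
* ``H2min`` — maximise the same convex objective, attained at a vertex of
  the polytope: greedy largest-remaining-marginal packing from every
  feasible first pairing (multi-start), then maximal pushes along cycles.

Because both extrema are achievable arrangements, a heuristic shortfall can
only place H2max below or H2min above the observed H2; such values are
clamped to H2 and the event is reported through a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from bloodmealnet.networks import InteractionMatrix, dominant_family

__all__ = [
    "UndefinedMetricError", "NetworkMetrics", "shannon_entropy",
    "interaction_evenness", "h2_extrema", "h2_prime", "network_summary",
]


class UndefinedMetricError(ValueError):
    """The metric has no defined value for this matrix geometry."""


@dataclass
class NetworkMetrics:
    """Per-network metric bundle used by the statistical stage."""

    network_id: tuple[str, str]
    habitat: str
    abs_latitude: float
    dominant_family: str
    S: int
    n_diptera: int
    n_hosts: int
    m: int
    L: int
    IE: float
    ie_mode: str
    H2: float
    H2min: float
    H2max: float
    H2prime: float
    n_bloodmeals: int
    flags: list[str] = field(default_factory=list)


def _as_counts(matrix) -> np.ndarray:
    if isinstance(matrix, InteractionMatrix):
        arr = matrix.values
    else:
        arr = np.asarray(matrix)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError("interaction matrix must be two-dimensional")
    if (arr < 0).any():
        raise ValueError("negative weights")
    return arr


def shannon_entropy(matrix) -> float:
    """Shannon entropy H = -sum p ln p over positive cells, p = cell / m."""
    arr = _as_counts(matrix)
    m = arr.sum()
    if m <= 0:
        raise UndefinedMetricError("entropy of an all-zero matrix")
    pos = arr[arr > 0]
    if np.all(pos == pos[0]):
        # exact value for equal link weights (keeps IE at exactly 1.0)
        return float(np.log(pos.size))
    p = pos / m
    return float(-(p * np.log(p)).sum())


def interaction_evenness(matrix, mode: str = "realized_links") -> float:
    """IE = H / ln(denominator).

    ``mode="realized_links"`` uses the number of nonzero cells L;
    ``mode="all_cells"`` uses rows x columns.  Undefined when the
    denominator count is 1 (ln 1 = 0).
    """
    arr = _as_counts(matrix)
    if mode == "realized_links":
        denom = int((arr > 0).sum())
    elif mode == "all_cells":
        denom = arr.shape[0] * arr.shape[1]
    else:
        raise ValueError(f"unknown IE mode {mode!r}")
    if denom < 2:
        raise UndefinedMetricError(
            f"IE undefined: denominator count {denom} (ln 1 = 0)")
    return shannon_entropy(arr) / float(np.log(denom))


# --------------------------------------------------------------------------
# H2 extrema machinery.  All searches operate on integer count matrices with
# fixed row sums r and column sums c; the objective is sum n ln n (minimise
# for H2max, maximise for H2min), with entropy recovered as
# H = ln m - (sum n ln n)/m.

def _nlogn(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def _obj(n: np.ndarray) -> float:
    return float(_nlogn(n).sum())


def _entropy_from_obj(obj: float, m: float) -> float:
    return float(np.log(m) - obj / m)


def _proportional_fill(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Floor of the expected table r_i c_j / m, completed greedily so every
    marginal is met, choosing at each step the cell with the smallest
    increment of n ln n."""
    m = r.sum()
    n = np.floor(np.outer(r, c) / m).astype(np.int64)
    # floors can overshoot nothing but may undershoot; add units one by one
    while True:
        rdef = r - n.sum(axis=1)
        cdef = c - n.sum(axis=0)
        if rdef.sum() == 0:
            break
        inc = _nlogn(n + 1) - _nlogn(n)
        inc[rdef <= 0, :] = np.inf
        inc[:, cdef <= 0] = np.inf
        i, j = np.unravel_index(np.argmin(inc), inc.shape)
        n[i, j] += 1
    return n


def _cycle6_moves(shape: tuple[int, int]):
    """All length-6 alternating cycles for a small matrix: +1 on three cells
    (i_k, j_k), -1 on the three staggered cells (i_k, j_{k+1})."""
    nr, nc = shape
    for rows in itertools.combinations(range(nr), 3):
        for cols in itertools.combinations(range(nc), 3):
            for perm in itertools.permutations(cols):
                plus = tuple(zip(rows, perm))
                # both orientations of the cycle through (rows, perm)
                yield plus, tuple(zip(rows, perm[1:] + perm[:1]))
                yield plus, tuple(zip(rows, perm[-1:] + perm[:-1]))


def _f(x: int) -> float:
    return x * np.log(x) if x > 0 else 0.0


_INF = float("inf")


def _improve_min(n: np.ndarray, max_moves: int = 20000) -> np.ndarray:
    """Unit-push local search minimising sum n ln n (for H2max).

    Searches all 2x2 alternating cycles and, once those are exhausted, all
    length-6 cycles when the matrix is small enough to enumerate them.  For
    matrices with min(rows, cols) <= 3 no residual cycle is longer than 6,
    so local optimality here is global optimality of the convex programme.
    """
    grid = [[int(v) for v in row] for row in n]
    nr, nc = n.shape
    small = nr <= 6 and nc <= 6 and min(nr, nc) >= 3
    for _ in range(max_moves):
        add = [[_f(v + 1) - _f(v) for v in row] for row in grid]
        rem = [[_f(v - 1) - _f(v) if v > 0 else _INF for v in row]
               for row in grid]
        best, move = -1e-12, None
        for i1 in range(nr):
            for i2 in range(nr):
                if i1 == i2:
                    continue
                # +1 at (i1,j1) & (i2,j2), -1 at (i1,j2) & (i2,j1)
                g1 = [add[i1][j] + rem[i2][j] for j in range(nc)]
                g2 = [add[i2][j] + rem[i1][j] for j in range(nc)]
                a1, a2 = _two_smallest(g1)
                b1, b2 = _two_smallest(g2)
                if a1 is None or b1 is None:
                    continue
                if a1 != b1:
                    cands = [(a1, b1)]
                else:
                    cands = []
                    if b2 is not None:
                        cands.append((a1, b2))
                    if a2 is not None:
                        cands.append((a2, b1))
                for j1, j2 in cands:
                    d = g1[j1] + g2[j2]
                    if d < best:
                        best = d
                        move = ((i1, j1), (i2, j2), (i1, j2), (i2, j1))
        if move is None and small:
            for plus, minus in _cycle6_moves((nr, nc)):
                if all(grid[i][j] >= 1 for i, j in minus):
                    d = (sum(add[i][j] for i, j in plus)
                         + sum(rem[i][j] for i, j in minus))
                    if d < best:
                        best, move = d, plus + minus
        if move is None:
            break
        for i, j in move[:len(move) // 2]:
            grid[i][j] += 1
        for i, j in move[len(move) // 2:]:
            grid[i][j] -= 1
    return np.array(grid, dtype=np.int64)


def _two_smallest(g: list[float]) -> tuple[int | None, int | None]:
    """Indices of the two smallest finite entries of g (None when absent)."""
    j1 = j2 = None
    for j, v in enumerate(g):
        if v == _INF:
            continue
        if j1 is None or v < g[j1]:
            j1, j2 = j, j1
        elif j2 is None or v < g[j2]:
            j2 = j
    return j1, j2


def _greedy_pack(r: np.ndarray, c: np.ndarray,
                 first: tuple[int, int] | None = None) -> np.ndarray:
    """Greedy most-specialised packing: repeatedly pair the largest
    remaining row marginal with the largest remaining column marginal."""
    r = r.astype(np.int64).copy()
    c = c.astype(np.int64).copy()
    n = np.zeros((len(r), len(c)), dtype=np.int64)
    if first is not None:
        i, j = first
        t = min(r[i], c[j])
        n[i, j] += t
        r[i] -= t
        c[j] -= t
    while r.sum() > 0:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        t = min(r[i], c[j])
        n[i, j] += t
        r[i] -= t
        c[j] -= t
    return n


def _improve_max(n: np.ndarray, max_moves: int = 5000) -> np.ndarray:
    """Maximal-push local search maximising sum n ln n (for H2min).

    The objective is convex along any cycle direction, so the best step on
    each cycle is a full push to the boundary; 2x2 cycles always, length-6
    cycles (full push) once the 2x2 neighbourhood is exhausted and the
    matrix is small enough to enumerate them.
    """
    grid = [[int(v) for v in row] for row in n]
    nr, nc = n.shape
    small = nr <= 6 and nc <= 6 and min(nr, nc) >= 3
    for _ in range(max_moves):
        best, move = 1e-12, None
        for i1, i2 in itertools.combinations(range(nr), 2):
            row1, row2 = grid[i1], grid[i2]
            for j1, j2 in itertools.combinations(range(nc), 2):
                a, b, c, d = row1[j1], row1[j2], row2[j1], row2[j2]
                # push along the cycle (i1,j1)-(i1,j2)-(i2,j2)-(i2,j1)
                for t in (min(b, c), -min(a, d)):
                    if t == 0:
                        continue
                    delta = (_f(a + t) + _f(d + t) + _f(b - t) + _f(c - t)
                             - _f(a) - _f(b) - _f(c) - _f(d))
                    if delta > best:
                        best, move = delta, ((i1, j1), (i2, j2),
                                             (i1, j2), (i2, j1), t)
        if move is None and small:
            for plus, minus in _cycle6_moves((nr, nc)):
                t = min(grid[i][j] for i, j in minus)
                if t < 1:
                    continue
                delta = (sum(_f(grid[i][j] + t) - _f(grid[i][j])
                             for i, j in plus)
                         + sum(_f(grid[i][j] - t) - _f(grid[i][j])
                               for i, j in minus))
                if delta > best:
                    best, move = delta, plus + minus + (t,)
        if move is None:
            break
        t = move[-1]
        cells = move[:-1]
        half = len(cells) // 2
        for i, j in cells[:half]:
            grid[i][j] += t
        for i, j in cells[half:]:
            grid[i][j] -= t
    return np.array(grid, dtype=np.int64)


def h2_extrema(matrix) -> tuple[float, float]:
    """(H2min, H2max): entropy extrema over integer matrices with the
    observed marginals.

    Heuristic results are achievable arrangements, so they bound the truth
    from inside; if the observed entropy escapes the computed interval the
    offending bound is clamped to it and a warning is issued.
    """
    arr = _as_counts(matrix)
    n_obs = np.round(arr).astype(np.int64)
    if not np.allclose(arr, n_obs):
        raise ValueError("H2 extrema require integer blood-meal counts")
    r = n_obs.sum(axis=1)
    c = n_obs.sum(axis=0)
    m = int(n_obs.sum())
    if m <= 0:
        raise UndefinedMetricError("all-zero matrix")
    h_obs = shannon_entropy(arr)

    # H2max: minimise sum n ln n
    n_max = _improve_min(_proportional_fill(r, c))
    h2max = _entropy_from_obj(_obj(n_max), m)

    # H2min: maximise sum n ln n, multi-start greedy + cycle pushes
    starts: list[np.ndarray] = [_greedy_pack(r, c)]
    if len(r) * len(c) <= 144:
        for i in range(len(r)):
            for j in range(len(c)):
                if r[i] > 0 and c[j] > 0:
                    starts.append(_greedy_pack(r, c, first=(i, j)))
    best_obj, best_n = -np.inf, None
    for s in starts:
        o = _obj(s)
        if o > best_obj:
            best_obj, best_n = o, s
    n_min = _improve_max(best_n)
    h2min = _entropy_from_obj(_obj(n_min), m)

    if h2max < h_obs - 1e-12:
        warnings.warn(
            f"H2max heuristic ({h2max:.6f}) below observed entropy "
            f"({h_obs:.6f}); clamping", stacklevel=2)
        h2max = h_obs
    if h2min > h_obs + 1e-12:
        warnings.warn(
            f"H2min heuristic ({h2min:.6f}) above observed entropy "
            f"({h_obs:.6f}); clamping", stacklevel=2)
        h2min = h_obs
    return min(h2min, h_obs), max(h2max, h_obs)


def h2_prime(matrix, with_flag: bool = False):
    """Standardised specialisation H2' = (H2max - H2) / (H2max - H2min).

    Degenerate geometries (H2max == H2min, e.g. single-row matrices whose
    marginals fix every cell) return 0 with a degeneracy flag rather than
    NaN, so batch tables stay rectangular; such rows are excluded from the
    modelling stage by default.
    """
    h2 = shannon_entropy(matrix)
    h2min, h2max = h2_extrema(matrix)
    if h2max - h2min <= 1e-12:
        return (0.0, True) if with_flag else 0.0
    val = (h2max - h2) / (h2max - h2min)
    val = float(min(max(val, 0.0), 1.0))
    return (val, False) if with_flag else val


def network_summary(matrix: InteractionMatrix,
                    ie_mode: str = "realized_links",
                    compute_h2: bool = True) -> NetworkMetrics:
    """Assemble the full per-network metric row.

    Metric failures are recorded as flags (IE set to NaN when undefined)
    rather than raised, so a batch over many networks always completes.
    """
    flags: list[str] = []
    try:
        ie = interaction_evenness(matrix, mode=ie_mode)
    except UndefinedMetricError:
        ie = float("nan")
        flags.append("ie_undefined")

    if compute_h2:
        h2 = shannon_entropy(matrix)
        h2min, h2max = h2_extrema(matrix)
        if h2max - h2min <= 1e-12:
            h2p = 0.0
            flags.append("h2_degenerate")
        else:
            h2p = float(min(max((h2max - h2) / (h2max - h2min), 0.0), 1.0))
    else:
        h2 = h2min = h2max = h2p = float("nan")
        flags.append("h2_not_computed")

    fam, tie = dominant_family(matrix)
    if tie:
        flags.append("family_tie")

    return NetworkMetrics(
        network_id=matrix.network_id, habitat=matrix.habitat,
        abs_latitude=abs(float(matrix.latitude)), dominant_family=fam,
        S=matrix.richness, n_diptera=matrix.n_diptera,
        n_hosts=matrix.n_hosts, m=matrix.m, L=matrix.links,
        IE=ie, ie_mode=ie_mode, H2=h2 if compute_h2 else float("nan"),
        H2min=h2min, H2max=h2max, H2prime=h2p,
        n_bloodmeals=matrix.m, flags=flags)
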