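"""Independent brute-force oracles used to pin expected values.

These are deliberately naive: exhaustive enumeration and direct evaluation
only, sharing no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def compositions(total: int, parts: int):
    """All nonnegative integer tuples of length `parts` summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            yield (first,) + rest


def matrices_with_marginals(row_sums, col_sums):
    """Enumerate every nonnegative integer matrix with the given marginals."""
    row_sums = list(row_sums)
    col_sums = list(col_sums)

    def rec(rows_left, cols_remaining):
        if not rows_left:
            if all(c == 0 for c in cols_remaining):
                yield []
            return
        r = rows_left[0]
        for row in compositions(r, len(cols_remaining)):
            if any(v > c for v, c in zip(row, cols_remaining)):
                continue
            new_cols = [c - v for c, v in zip(cols_remaining, row)]
            for rest in rec(rows_left[1:], new_cols):
                yield [list(row)] + rest

    for mat in rec(row_sums, col_sums):
        yield np.array(mat, dtype=int)


def entropy(mat) -> float:
    mat = np.asarray(mat, dtype=float)
    m = mat.sum()
    p = mat[mat > 0] / m
    return float(-(p * np.log(p)).sum())


def exact_h2_extrema(mat) -> tuple[float, float]:
    """(min, max) entropy over all integer matrices sharing the marginals."""
    mat = np.asarray(mat, dtype=int)
    r = mat.sum(axis=1)
    c = mat.sum(axis=0)
    ents = [entropy(x) for x in matrices_with_marginals(r, c)]
    return min(ents), max(ents)


def rarefied_richness_by_enumeration(Y, T: int, t: int) -> float:
    """Mean number of detected taxa over all size-t subsets of T units.

    Unit u detects taxon i iff u is one of the Y_i units where it occurs;
    occurrences are assigned to concrete unit sets in the canonical
    hypergeometric sense (each taxon independently occupies an arbitrary
    fixed set of Y_i units; the expectation depends only on Y_i).
    """
    total = 0.0
    nsub = math.comb(T, t)
    for y in Y:
        # P(taxon detected) = 1 - C(T-y, t)/C(T, t), computed by enumeration
        miss = 0
        for subset in itertools.combinations(range(T), t):
            if all(u >= y for u in subset):  # occupies units 0..y-1
                miss += 1
        total += 1.0 - miss / nsub
    return total
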