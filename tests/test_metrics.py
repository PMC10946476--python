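import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodmealnet.metrics import (
    UndefinedMetricError, h2_extrema, h2_prime, interaction_evenness,
    network_summary, shannon_entropy,
)
from conftest import mk_matrix
from oracles import exact_h2_extrema, entropy as oracle_entropy

LN2 = float(np.log(2))


def _random_small_matrix(rng):
    """Random integer matrix, <= 3x3, m <= 12, no empty rows/columns."""
    while True:
        nr, nc = rng.integers(1, 4, size=2)
        m = int(rng.integers(1, 13))
        cells = rng.multinomial(m, rng.dirichlet(np.ones(nr * nc)))
        cells = cells.reshape(nr, nc)
        cells = cells[cells.sum(axis=1) > 0]
        if cells.size == 0:
            continue
        cells = cells[:, cells.sum(axis=0) > 0]
        if cells.size and cells.sum() > 0:
            return cells


class TestShannonEntropy:
    @pytest.mark.parametrize("cells,expected", [
        ([[4, 0], [0, 4]], LN2),                       # two equal links
        ([[5]], 0.0),                                  # single link
        ([[2, 1], [1, 0]], 1.0397207708399179),        # 0.5ln2 + 0.5ln4
    ])
    def test_known_values(self, cells, expected):
        assert shannon_entropy(np.array(cells)) == pytest.approx(expected,
                                                                 abs=1e-12)

    def test_all_zero_matrix_is_error(self):
        with pytest.raises(UndefinedMetricError):
            shannon_entropy(np.zeros((2, 2)))


class TestInteractionEvenness:
    def test_uniform_weights_give_one_in_both_modes(self):
        uniform = np.ones((2, 2))
        assert interaction_evenness(uniform, "realized_links") == pytest.approx(1.0)
        assert interaction_evenness(uniform, "all_cells") == pytest.approx(1.0)

    def test_denominator_modes_differ_on_sparse_matrix(self):
        cells = np.array([[4, 0], [0, 4]])
        assert interaction_evenness(cells, "realized_links") == pytest.approx(1.0)
        assert interaction_evenness(cells, "all_cells") == pytest.approx(0.5)

    def test_derived_value_realized_links(self):
        cells = np.array([[2, 1], [1, 0]])
        expected = 1.0397207708399179 / np.log(3)
        assert interaction_evenness(cells) == pytest.approx(expected, abs=1e-12)

    def test_single_link_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            interaction_evenness(np.array([[7]]), "realized_links")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_evenness_is_one_iff_links_equal(self, seed):
        rng = np.random.default_rng(seed)
        cells = _random_small_matrix(rng)
        if (cells > 0).sum() < 2:
            return
        ie = interaction_evenness(cells, "realized_links")
        positive = cells[cells > 0]
        if np.all(positive == positive[0]):
            assert ie == pytest.approx(1.0, abs=1e-12)
        else:
            assert ie < 1.0 - 1e-12


class TestH2Extrema:
    def test_diagonal_equal_marginals_is_minimal(self):
        lo, hi = h2_extrema(np.array([[5, 0], [0, 5]]))
        assert lo == pytest.approx(LN2, abs=1e-12)

    def test_proportional_matrix_attains_maximum(self):
        cells = np.array([[4, 4], [4, 4]])
        lo, hi = h2_extrema(cells)
        assert hi == pytest.approx(shannon_entropy(cells), abs=1e-12)
        assert hi == pytest.approx(np.log(4), abs=1e-12)

    def test_extrema_bracket_observed_entropy(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            cells = _random_small_matrix(rng)
            lo, hi = h2_extrema(cells)
            h = shannon_entropy(cells)
            assert lo - 1e-12 <= h <= hi + 1e-12

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_exhaustive_enumeration(self, seed):
        """Heuristic extrema equal brute-force enumeration at oracle scale."""
        cells = _random_small_matrix(np.random.default_rng(seed))
        lo, hi = h2_extrema(cells)
        exact_lo, exact_hi = exact_h2_extrema(cells)
        assert lo == pytest.approx(exact_lo, abs=1e-9)
        assert hi == pytest.approx(exact_hi, abs=1e-9)


class TestH2Prime:
    def test_specialised_extreme_is_one(self):
        assert h2_prime(np.array([[5, 0], [0, 5]])) == pytest.approx(1.0)

    def test_random_expectation_extreme_is_zero(self):
        assert h2_prime(np.array([[4, 4], [4, 4]])) == pytest.approx(0.0)

    def test_degenerate_geometry_returns_zero_with_flag(self):
        val, degenerate = h2_prime(np.array([[3, 2, 1]]), with_flag=True)
        assert val == 0.0
        assert degenerate

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_agrees_with_enumeration_derived_value(self, seed):
        cells = _random_small_matrix(np.random.default_rng(seed))
        lo, hi = exact_h2_extrema(cells)
        if hi - lo <= 1e-12:
            assert h2_prime(cells) == 0.0
            return
        expected = (hi - oracle_entropy(cells)) / (hi - lo)
        assert h2_prime(cells) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_invariant_under_permutation_and_transpose(self, seed):
        rng = np.random.default_rng(seed)
        cells = _random_small_matrix(rng)
        base = h2_prime(cells)
        perm = cells[rng.permutation(cells.shape[0])][:,
                                                      rng.permutation(cells.shape[1])]
        assert h2_prime(perm) == pytest.approx(base, abs=1e-9)
        assert h2_prime(cells.T) == pytest.approx(base, abs=1e-9)


class TestNetworkSummary:
    def test_southern_latitude_reported_absolute(self):
        nm = network_summary(mk_matrix([[1, 1], [1, 1]], latitude=-23.5))
        assert nm.abs_latitude == pytest.approx(23.5)

    def test_uniform_two_by_two(self):
        nm = network_summary(mk_matrix([[1, 1], [1, 1]]))
        assert nm.IE == pytest.approx(1.0)
        assert nm.S == 4
        assert nm.m == 4 and nm.L == 4

    def test_one_by_one_flags_instead_of_crashing(self):
        nm = network_summary(mk_matrix([[5]]))
        assert np.isnan(nm.IE)
        assert "ie_undefined" in nm.flags
        assert nm.H2prime == 0.0
        assert "h2_degenerate" in nm.flags
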