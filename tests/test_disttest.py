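from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from winotherm.disttest import (
    DEFAULT_EDGES,
    bin_differences,
    mwu_binned,
    mwu_raw,
)
from winotherm.errors import ConfigurationError


def exact_mwu_p_two_sided(a, b):
    """Brute-force two-sided Mann-Whitney p by enumerating rank assignments.

    For tie-free samples, enumerates every way the combined order statistics
    could be split between the groups, computes the U statistic of group a
    for each, and doubles the smaller tail probability at the observed U.
    """
    a, b = list(a), list(b)
    m, n = len(a), len(b)
    combined = sorted(a + b)
    assert len(set(combined)) == m + n, "oracle requires tie-free samples"
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in combinations(range(m + n), m):
        grp = [combined[i] for i in idx]
        rest = [combined[i] for i in range(m + n) if i not in idx]
        us.append(sum(1 for x in grp for y in rest if x > y))
    us = np.array(us)
    total = len(us)
    p = 2 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / total
    return min(p, 1.0)


class TestBinning:
    def test_hand_binned_examples(self):
        b = bin_differences([-0.005, 0.004, 0.012])
        nonzero = np.nonzero(b.frequencies)[0]
        assert list(nonzero) == [99, 100, 101]  # [-0.01,0), [0,0.01), [0.01,0.02)
        assert np.allclose(b.frequencies[nonzero], 1 / 3)

    def test_all_zero_samples_fill_one_bin(self):
        b = bin_differences([0.0] * 10)
        assert b.frequencies[100] == 1.0
        assert b.frequencies.sum() == 1.0

    def test_out_of_range_kept_in_denominator(self):
        b = bin_differences([0.0, 1.5])
        assert b.n_outside == 1
        assert b.frequencies[100] == pytest.approx(0.5)
        assert b.frequencies.sum() + b.n_outside / b.n_total == pytest.approx(1.0)

    def test_left_closed_boundaries(self):
        b = bin_differences([-1.0, 0.01, 0.999])
        assert b.n_outside == 0
        assert b.frequencies[0] > 0  # -1.0 belongs to the first bin
        assert b.frequencies[101] > 0  # 0.01 opens its own bin
        assert b.frequencies[199] > 0
        # +1.0 is the open right edge and falls outside
        assert bin_differences([0.0, 1.0]).n_outside == 1

    def test_count_bookkeeping_is_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.7, size=5000)
        b = bin_differences(x)
        counts = np.round(b.frequencies * b.n_total).astype(int)
        assert counts.sum() + b.n_outside == b.n_total == 5000

    @settings(derandomize=True, max_examples=20)
    @given(st.permutations(list(np.linspace(-0.9, 0.9, 13))))
    def test_permutation_invariance(self, perm):
        ref = bin_differences(np.linspace(-0.9, 0.9, 13))
        assert np.array_equal(bin_differences(perm).frequencies, ref.frequencies)

    def test_all_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bin_differences([5.0, -3.0])


class TestMannWhitney:
    def test_toy_case_matches_enumeration(self):
        res = mwu_raw([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)
        assert exact_mwu_p_two_sided([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_small_sample_p_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(3, 8, size=2)
        vals = rng.permutation(np.arange(1.0, m + n + 1.0))
        a, b = vals[:m], vals[m:]
        res = mwu_raw(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_mwu_p_two_sided(a, b), abs=1e-12)

    def test_symmetry_in_arguments(self):
        a, b = [0.1, 0.5, 0.9, 1.3], [0.2, 0.4, 1.7]
        assert mwu_raw(a, b).p_value == pytest.approx(mwu_raw(b, a).p_value)

    def test_identical_samples_not_significant(self):
        x = list(np.linspace(0, 1, 30))
        res = mwu_raw(x, x)
        assert res.U == pytest.approx(len(x) ** 2 / 2)
        assert res.p_value > 0.9

    def test_clear_shift_detected_at_small_n(self):
        res = mwu_raw(list(range(8)), [v + 100 for v in range(8)])
        assert res.p_value < 0.05

    def test_binned_test_on_identical_distributions(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.2, 2000)
        a = bin_differences(x)
        res = mwu_binned(a, a)
        assert res.n1 == res.n2 == 200
        assert res.p_value > 0.9

    def test_binned_test_argument_symmetry(self):
        rng = np.random.default_rng(2)
        a = bin_differences(rng.normal(0.1, 0.2, 2000))
        b = bin_differences(rng.normal(-0.1, 0.3, 2000))
        assert mwu_binned(a, b).p_value == pytest.approx(mwu_binned(b, a).p_value)

    def test_binned_edge_mismatch_rejected(self):
        a = bin_differences([0.0])
        b = bin_differences([0.0], edges=np.linspace(-2, 2, 201))
        with pytest.raises(ConfigurationError):
            mwu_binned(a, b)

    def test_binned_test_is_location_blind_but_shape_sensitive(self):
        """The binned procedure compares the *values* of the frequency
        vectors, so a pure location shift (identical histogram shape,
        translated) is invisible to it while the raw rank test sees it
        immediately; a spread difference changes the frequency values and is
        detected.  This documented divergence is why the raw test exists as
        a diagnostic companion."""
        rng = np.random.default_rng(3)
        a = rng.normal(-0.4, 0.05, 3000)
        b = rng.normal(0.4, 0.05, 3000)
        assert mwu_raw(a, b).p_value < 1e-6
        assert mwu_binned(bin_differences(a), bin_differences(b)).p_value > 0.05

        narrow = rng.normal(0.0, 0.05, 3000)
        wide = rng.normal(0.0, 0.3, 3000)
        assert mwu_binned(bin_differences(narrow), bin_differences(wide)).p_value < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            mwu_raw([], [1.0])
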