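"""Divergence machinery vs independent oracles.

The p-distance/distance-matrix implementation is checked against a naive
character-by-character double loop, the Kruskal-Wallis statistic against
the rank-sum formula computed by hand, and bootstrap SEs against the
closed-form binomial SE.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lwiscape import (
    SequenceRecord,
    SequenceSet,
    bootstrap_distance,
    column_information_content,
    distance_matrix,
    divergence_summary,
    kruskal_wallis,
    p_distance,
    position_frequency_matrix,
)
from lwiscape.conservation import ConservationError

COUNTED = set("ACDEFGHIKLMNPQRSTVWY")


def oracle_p_distance(a, b):
    """Independent site-by-site pairwise-deletion loop."""
    n = diff = 0
    for x, y in zip(a, b):
        if x in COUNTED and y in COUNTED:
            n += 1
            diff += x != y
    return (diff / n, n) if n else None


def aln_from(strings):
    return SequenceSet(
        records=tuple(
            SequenceRecord(id=f"s{i}", residues=s) for i, s in enumerate(strings)
        ),
        aligned=True,
    )


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ("ACDE", "ACDE", (0.0, 4)),
            ("ACDE", "ACDF", (0.25, 4)),
            ("AC-E", "ACDE", (0.0, 3)),  # pairwise deletion skips gap column
            ("XCDE", "ACDE", (0.0, 3)),  # 'X' treated like a gap
        ],
    )
    def test_hand_cases(self, a, b, expect):
        assert p_distance(a, b) == expect

    def test_zero_comparable_sites_is_an_error_not_zero(self):
        with pytest.raises(ConservationError):
            p_distance("--A", "AX-")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ConservationError):
            p_distance("ACD", "AC")

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ARN-X", min_size=5, max_size=30),
            min_size=2, max_size=6,
        ).filter(lambda ss: len({len(s) for s in ss}) == 1)
    )
    def test_matrix_equals_double_loop_oracle(self, strings):
        expected = {}
        defined = True
        for i in range(len(strings)):
            for j in range(i + 1, len(strings)):
                got = oracle_p_distance(strings[i], strings[j])
                if got is None:
                    defined = False
                expected[(i, j)] = got
        aln = aln_from(strings)
        if not defined:
            with pytest.raises(ConservationError):
                distance_matrix(aln)
            return
        dm = distance_matrix(aln)
        for (i, j), (d, n) in expected.items():
            assert dm.d[i, j] == pytest.approx(d)
            assert dm.d[j, i] == pytest.approx(d)
            assert dm.n_compared[i, j] == n
        assert np.allclose(np.diag(dm.d), 0)

    def test_symmetry_and_joint_gap_invariance(self):
        a, b = "ARNDC", "ARNEC"
        d1 = p_distance(a, b)
        assert d1 == p_distance(b, a)
        assert p_distance(a + "--", b + "--") == d1


class TestBootstrap:
    def test_identical_sequences_have_zero_variance(self):
        aln = aln_from(["ACDEACDE"] * 3)
        bs = bootstrap_distance(aln, reps=20, seed=1)
        assert np.all(bs.variance == 0)

    def test_same_seed_bit_reproducible(self):
        aln = aln_from(["ARNDCEQGH", "ARNECGQGH", "TRNDCEQWH"])
        b1 = bootstrap_distance(aln, reps=50, seed=7)
        b2 = bootstrap_distance(aln, reps=50, seed=7)
        assert np.array_equal(b1.variance, b2.variance)

    def test_se_close_to_binomial_closed_form(self):
        # two sequences differing at half their sites: resampled distance is
        # Binomial(L, 0.5)/L, so SE should be near sqrt(p(1-p)/L)
        L, p = 100, 0.5
        a = "A" * L
        b = "R" * (L // 2) + "A" * (L // 2)
        bs = bootstrap_distance(aln_from([a, b]), reps=2000, seed=3)
        theo = math.sqrt(p * (1 - p) / L)
        assert bs.std_error[0, 1] == pytest.approx(theo, rel=0.15)
        assert bs.std_error[0, 1] < 3 * theo


class TestDivergenceSummary:
    def test_median_of_three(self):
        s = divergence_summary(np.array([0.1, 0.2, 0.3]))
        assert s.median == pytest.approx(0.2)
        assert s.outliers.size == 0

    def test_iqr_rule_flags_far_point(self):
        # by hand: nine 0.1's -> Q1=Q3=0.1 once 0.9 barely shifts quartiles;
        # numpy linear quantiles give Q1=0.1, Q3=0.1, IQR=0 -> 0.9 outlying
        values = np.array([0.1] * 9 + [0.9])
        s = divergence_summary(values)
        assert 0.9 in s.outliers
        assert s.whisker_high == pytest.approx(0.1)

    def test_single_pair(self):
        s = divergence_summary(np.array([0.42]))
        assert s.median == pytest.approx(0.42)
        assert s.n_pairs == 1
        assert s.outliers.size == 0

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = divergence_summary(rng.random(rng.integers(1, 50)))
            assert s.q1 <= s.median <= s.q3
            lo, hi = s.q1 - 1.5 * (s.q3 - s.q1), s.q3 + 1.5 * (s.q3 - s.q1)
            assert all(v < lo or v > hi for v in s.outliers)


class TestPFMAndIC:
    def test_uniform_column_has_zero_bits(self):
        pfm = position_frequency_matrix(list("ACDEFGHIKLMNPQRSTVWY"))
        ic = column_information_content(pfm)
        assert ic[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_residue_column_is_log2_20(self):
        pfm = position_frequency_matrix(["R"] * 10)
        ic = column_information_content(pfm)
        assert ic[0] == pytest.approx(math.log2(20))

    def test_half_half_column(self):
        pfm = position_frequency_matrix(["R"] * 5 + ["K"] * 5)
        assert pfm.freqs[0, list("ACDEFGHIKLMNPQRSTVWY").index("R")] == 0.5
        ic = column_information_content(pfm)
        assert ic[0] == pytest.approx(math.log2(20) - 1.0)

    def test_gap_excluded_from_denominator(self):
        pfm = position_frequency_matrix(["R"] * 9 + ["-"])
        r_idx = "ACDEFGHIKLMNPQRSTVWY".index("R")
        assert pfm.freqs[0, r_idx] == pytest.approx(1.0)
        assert pfm.counts[0] == 9
        assert pfm.gap_counts[0] == 1

    def test_empty_column_flagged_nan(self):
        pfm = position_frequency_matrix(["-X", "AX"])
        ic = column_information_content(pfm)
        assert math.isnan(ic[1])
        assert pfm.empty_columns[1]

    def test_rows_sum_to_one_over_counted(self):
        rng = np.random.default_rng(5)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY-X"))
        rows = ["".join(rng.choice(aas, size=12)) for _ in range(8)]
        pfm = position_frequency_matrix(rows)
        sums = pfm.freqs.sum(axis=1)
        for j, s in enumerate(sums):
            if pfm.counts[j] > 0:
                assert s == pytest.approx(1.0)
            else:
                assert s == 0.0


def oracle_kruskal_h(groups):
    """Rank-sum H with tie correction, straight from the formula."""
    all_vals = sorted(v for g in groups for v in g)
    n = len(all_vals)
    # average ranks for ties
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and all_vals[j] == all_vals[i]:
            j += 1
        avg = (i + 1 + j) / 2  # mean of ranks i+1..j
        ranks[all_vals[i]] = avg
        i = j
    h = 0.0
    for g in groups:
        r = sum(ranks[v] for v in g)
        h += r * r / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and all_vals[j] == all_vals[i]:
            j += 1
        t = j - i
        ties += t**3 - t
        i = j
    c = 1 - ties / (n**3 - n) if n > 1 else 1.0
    return h / c if c > 0 else 0.0


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_rank_formula(self):
        groups = [[1, 2, 3], [4, 5, 6]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(oracle_kruskal_h(groups))

    def test_all_tied_observations_give_zero(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=9), min_size=1,
                     max_size=7),
            min_size=2, max_size=4,
        ).filter(lambda gs: sum(len(g) for g in gs) >= 3
                 and len({v for g in gs for v in g}) > 1)
    )
    def test_random_inputs_match_oracle(self, groups):
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(oracle_kruskal_h(groups), abs=1e-9)
        assert 0.0 <= res.p_value <= 1.0

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ConservationError):
            kruskal_wallis([[1, 2, 3]])
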