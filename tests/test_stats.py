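import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mpsurvey import (
    ContingencyTable,
    dunn_posthoc,
    kruskal_wallis,
    pearson_chi_square,
    pearson_correlation,
    welch_t,
    wilcoxon_rank_sum,
)
from mpsurvey.stats import LowExpectedCountWarning


def chi_square_oracle(counts: np.ndarray) -> float:
    """Direct Σ (O−E)²/E with E = row·col/total, written independently."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            expected = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - expected) ** 2 / expected
    return stat


def kruskal_oracle(samples) -> float:
    """H from pooled midranks with tie correction, written independently."""
    pooled = np.concatenate(samples)
    order = np.argsort(pooled, kind="mergesort")
    n = len(pooled)
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start:start + len(s)]
        h += len(s) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(s)
    h *= 12.0 / (n * (n + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    return h / correction


def _table(counts):
    counts = np.asarray(counts)
    return ContingencyTable(
        tuple(f"r{i}" for i in range(counts.shape[0])),
        tuple(f"c{j}" for j in range(counts.shape[1])),
        counts,
    )


class TestPearsonChiSquare:
    def test_hand_computed_2x2(self):
        # E = [[1.2,1.8],[2.8,4.2]] → Σ(O−E)²/E = 0.0794
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", LowExpectedCountWarning)
            result = pearson_chi_square(_table([[1, 2], [3, 4]]))
        assert result.statistic == pytest.approx(0.0794, abs=1e-4)
        assert result.df == 1

    def test_proportional_rows_give_zero(self):
        result = pearson_chi_square(_table([[10, 20], [20, 40]]))
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi_square(_table([[1, 0], [3, 0]]))

    def test_needs_two_rows_and_columns(self):
        with pytest.raises(ValueError):
            pearson_chi_square(_table([[1, 2]]))

    def test_low_expected_counts_warn_not_fail(self):
        with pytest.warns(LowExpectedCountWarning):
            pearson_chi_square(_table([[1, 2], [3, 4]]))

    @settings(deadline=None, max_examples=60)
    @given(
        st.integers(min_value=2, max_value=4),
        st.integers(min_value=2, max_value=4),
        st.data(),
    )
    def test_matches_direct_oracle_on_random_small_tables(self, n_rows, n_cols, data):
        counts = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(min_value=0, max_value=30), min_size=n_cols, max_size=n_cols),
                    min_size=n_rows,
                    max_size=n_rows,
                )
            )
        )
        counts[:, 0] += 1  # keep margins positive
        counts[0, :] += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", LowExpectedCountWarning)
            result = pearson_chi_square(_table(counts))
        assert result.statistic == pytest.approx(chi_square_oracle(counts))
        assert result.df == (n_rows - 1) * (n_cols - 1)

    def test_invariant_to_permutation_and_transposition(self):
        counts = np.array([[5, 9, 2], [7, 1, 11]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", LowExpectedCountWarning)
            base = pearson_chi_square(_table(counts)).statistic
            permuted = pearson_chi_square(_table(counts[::-1, ::-1])).statistic
            transposed = pearson_chi_square(_table(counts.T)).statistic
        assert permuted == pytest.approx(base)
        assert transposed == pytest.approx(base)


class TestKruskalWallis:
    def test_matches_independent_oracle_without_ties(self):
        samples = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])]
        values = np.concatenate(samples)
        groups = ["a"] * 3 + ["b"] * 3
        result = kruskal_wallis(values, groups)
        assert result.statistic == pytest.approx(kruskal_oracle(samples))
        assert result.df == 1

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        values = rng.integers(0, 5, 40).astype(float)  # heavy ties
        groups = rng.choice(list("abc"), 40)
        samples = [values[groups == g] for g in "abc"]
        result = kruskal_wallis(values, groups)
        assert result.statistic == pytest.approx(kruskal_oracle(samples))
        assert result.df == 2

    def test_identical_values_give_zero_statistic(self):
        result = kruskal_wallis([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])


class TestDunn:
    def test_two_group_reduction_equals_rank_sum_normal_approx(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        values = np.concatenate([x, y])
        groups = ["a"] * 12 + ["b"] * 9
        dunn = dunn_posthoc(values, groups, adjust="none")
        ranksum = wilcoxon_rank_sum(x, y)
        assert dunn.loc[0, "p_value"] == pytest.approx(ranksum.p_value, rel=1e-9)

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, 30)
        groups = np.repeat(list("abc"), 10)
        raw = dunn_posthoc(values, groups, adjust="none")
        adj = dunn_posthoc(values, groups, adjust="bonferroni")
        np.testing.assert_allclose(adj["p_adjusted"], np.minimum(raw["p_value"] * 3, 1.0))

    def test_detects_injected_shifts(self):
        """Size-by-color style data: shifted groups show up as significant pairs."""
        rng = np.random.default_rng(2024)
        colors = ["black", "navy blue", "pink", "red"]
        frames = []
        for color in colors:
            shift = 3.0 if color in ("pink", "red") else 1.0
            frames.append((color, rng.lognormal(np.log(150 * shift), 0.4, 40)))
        values = np.concatenate([v for _, v in frames])
        groups = np.concatenate([[c] * 40 for c, _ in frames])
        result = dunn_posthoc(values, groups, adjust="holm")
        significant = {
            tuple(sorted((row.group_1, row.group_2)))
            for row in result.itertuples()
            if row.p_adjusted < 0.05
        }
        assert ("black", "pink") in significant
        assert ("navy blue", "red") in significant
        assert ("pink", "red") not in significant

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc([1.0, 2.0], ["a", "a"])


class TestRankSumAndFriends:
    def test_statistic_matches_pair_count_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        # brute force U: count (x_i > y_j) pairs + half ties
        u = sum(0.5 if a == b else float(a > b) for a, b in itertools.product(x, y))
        assert wilcoxon_rank_sum(x, y).statistic == u == 0.0
        assert wilcoxon_rank_sum(y, x).statistic == 9.0

    def test_identical_samples_sit_at_null_mean(self):
        x = [1.0, 2.0, 3.0, 4.0]
        result = wilcoxon_rank_sum(x, x)
        assert result.statistic == len(x) ** 2 / 2  # U at its null expectation
        assert result.p_value == pytest.approx(1.0)

    def test_welch_t_fractional_df_matches_satterthwaite(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 8), rng.normal(0, 3, 20)
        result = welch_t(x, y)
        vx, vy = np.var(x, ddof=1) / len(x), np.var(y, ddof=1) / len(y)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        assert result.df == pytest.approx(df)
        assert result.df != int(result.df)  # genuinely fractional
        assert result.method == "Welch t"

    def test_welch_t_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [1.0, 1.0])

    def test_perfectly_linear_correlation_is_one(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 3 * x + 2).statistic == pytest.approx(1.0)

    def test_constant_input_correlation_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_correlation_matches_scipy_p(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        result = pearson_correlation(x, y)
        r, p = sps.pearsonr(x, y)
        assert result.statistic == pytest.approx(r) and result.p_value == pytest.approx(p)
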