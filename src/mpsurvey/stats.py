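"""Nonparametric and categorical test battery for survey comparisons.

Wraps the standard tests the survey analysis needs — Pearson chi-square
on particle cross-tabulations, Kruskal–Wallis with Dunn's post hoc for
size-by-category comparisons, Wilcoxon rank-sum, Welch's t and Pearson
correlation for morphometrics — behind a uniform :class:`TestResult`.

Conventions chosen to match the published analysis (R ``stats``):

* chi-square carries NO continuity correction — the published statistics
  (0.88, 7.02, 2.83) are uncorrected Pearson values;
* low expected counts (E < 5) produce a warning, not an error, because
  sparse species-composition tables are the normal case in this setting;
* Welch's unequal-variance t with Welch–Satterthwaite (fractional) df;
* rank statistics use midranks with the standard tie corrections.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import ContingencyTable

__all__ = [
    "TestResult",
    "LowExpectedCountWarning",
    "pearson_chi_square",
    "kruskal_wallis",
    "dunn_posthoc",
    "wilcoxon_rank_sum",
    "welch_t",
    "pearson_correlation",
]


class LowExpectedCountWarning(UserWarning):
    """Some expected cell counts are below 5; the χ² approximation is rough."""


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p-value, method."""

    statistic: float
    df: float | None
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


def pearson_chi_square(table: ContingencyTable) -> TestResult:
    """Pearson's chi-square test of independence, without continuity correction.

    statistic = Σ (O−E)²/E with E = (row total · column total)/grand
    total; df = (r−1)(c−1).  A zero row or column margin makes E
    undefined and raises; expected counts below 5 warn.
    """
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("chi-square needs at least 2 rows and 2 columns")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("zero row/column margin: expected counts undefined")
    stat, p, df, expected = sps.chi2_contingency(counts, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} of {expected.size} expected counts are < 5",
            LowExpectedCountWarning,
            stacklevel=2,
        )
    return TestResult(float(stat), float(df), float(p), "Pearson chi-square")


def _as_groups(values, groups) -> list[np.ndarray]:
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    if frame["value"].isna().any():
        raise ValueError("values must not contain NaN")
    samples = [g["value"].to_numpy() for _, g in frame.groupby("group", sort=True)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    return samples


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal–Wallis rank test across k groups (midranks, tie-corrected).

    df = k−1.  All-identical values give statistic 0 by convention rather
    than an error (scipy raises in that degenerate case).
    """
    samples = _as_groups(values, groups)
    k = len(samples)
    if np.ptp(np.concatenate(samples)) == 0:
        return TestResult(0.0, float(k - 1), 1.0, "Kruskal-Wallis")
    stat, p = sps.kruskal(*samples)
    return TestResult(float(stat), float(k - 1), float(p), "Kruskal-Wallis")


def dunn_posthoc(values, groups, adjust: str = "none") -> pd.DataFrame:
    """Dunn's post hoc pairwise comparisons after Kruskal–Wallis.

    For groups i, j with pooled-midrank means R̄ᵢ, R̄ⱼ over N total
    observations:

        z = (R̄ᵢ − R̄ⱼ) / sqrt( (N(N+1)/12 − T) · (1/nᵢ + 1/nⱼ) )

    with tie correction T = Σ(t³−t) / (12(N−1)) over tie groups of size
    t.  Two-sided p from the standard normal; ``adjust`` is "none",
    "holm" or "bonferroni" across the k(k−1)/2 pairs.

    Returns a DataFrame with columns group_1, group_2, z, p_value,
    p_adjusted.
    """
    if adjust not in ("none", "holm", "bonferroni"):
        raise ValueError(f"adjust must be 'none', 'holm' or 'bonferroni', got {adjust!r}")
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    labels = sorted(frame["group"].unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    frame["rank"] = sps.rankdata(frame["value"])

    n = len(frame)
    _, tie_counts = np.unique(frame["value"], return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)))
    variance_base = n * (n + 1) / 12.0 - tie_term

    mean_ranks = frame.groupby("group")["rank"].mean()
    sizes = frame.groupby("group")["rank"].size()

    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = float((mean_ranks[a] - mean_ranks[b]) / se)
        p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_1": a, "group_2": b, "z": z, "p_value": p})
    out = pd.DataFrame(rows)
    if adjust == "none":
        out["p_adjusted"] = out["p_value"]
    else:
        out["p_adjusted"] = multipletests(out["p_value"], method=adjust)[1]
    return out


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney) test.

    The statistic is the first sample's U (the R ``wilcox.test`` W); the
    p-value uses the normal approximation with midrank tie correction,
    without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=False)
    return TestResult(float(stat), None, float(p), "Wilcoxon rank-sum")


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("both samples have zero variance; t undefined")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), "Welch t")


def pearson_correlation(x, y) -> TestResult:
    """Pearson product-moment correlation r, with t-distributed p (df = n−2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(len(x) - 2), float(p), "Pearson correlation")
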