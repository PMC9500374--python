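import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import fisher_exact, mannwhitneyu, rankdata

from doublesub.genetic_code import codon_id
from doublesub.null_models import NullConfig, NullSignature, NullTally
from doublesub.selection_stats import (
    DoubleFractionRecord,
    bonferroni,
    build_comparisons,
    call_selection,
    class_summary,
    compute_df,
    fisher_double_vs_single,
    fisher_exact_pvalue,
    mann_whitney_df,
)


@pytest.mark.parametrize("b, a1, a2, expected", [(5, 10, 5, 0.25), (0, 7, 3, 0.0), (4, 0, 0, 1.0)])
def test_compute_df_examples(b, a1, a2, expected):
    assert compute_df(b, a1, a2).df == pytest.approx(expected)


def test_compute_df_undefined_and_invalid():
    rec = compute_df(0, 0, 0)
    assert not rec.defined and math.isnan(rec.df)
    with pytest.raises(ValueError):
        compute_df(-1, 0, 0)


def test_df_monotonicity():
    base = compute_df(3, 10, 10).df
    assert compute_df(4, 10, 10).df > base
    assert compute_df(3, 11, 10).df < base


def test_fisher_matches_scipy_on_random_tables():
    rng = np.random.default_rng(5)
    for _ in range(500):
        a, b, c, d = (int(x) for x in rng.integers(0, 80, 4))
        mine = fisher_exact_pvalue(a, b, c, d)
        ref = fisher_exact([[a, b], [c, d]])[1]
        assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12), (a, b, c, d)


def test_fisher_identical_rows_and_degenerate_columns():
    assert fisher_exact_pvalue(3, 30, 3, 30) == 1.0
    assert fisher_exact_pvalue(0, 10, 0, 10) == 1.0
    res = fisher_double_vs_single(DoubleFractionRecord(0, 5, 5), DoubleFractionRecord(0, 4, 4))
    assert res.pvalue == 1.0 and res.degenerate
    res = fisher_double_vs_single(DoubleFractionRecord(3, 30, 0), DoubleFractionRecord(3, 30, 0))
    assert not res.degenerate


def oracle_mw_two_sided(x, y):
    """Permutation enumeration via rank sums (independent of the U route)."""
    n = len(x)
    pooled = np.array(list(x) + list(y), dtype=float)
    ranks = rankdata(pooled)
    centre = n * (len(pooled) + 1) / 2.0
    obs = abs(ranks[:n].sum() - centre)
    hits = total = 0
    for comb in combinations(range(len(pooled)), n):
        if abs(ranks[list(comb)].sum() - centre) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def test_mann_whitney_examples():
    assert mann_whitney_df([0.1, 0.2, 0.3], [0.7, 0.8, 0.9]) == pytest.approx(0.1)
    assert mann_whitney_df([1, 1, 1], [1, 1, 1]) == pytest.approx(1.0)
    assert math.isnan(mann_whitney_df([], [0.5]))


def test_mann_whitney_exact_matches_enumeration_with_ties():
    rng = np.random.default_rng(3)
    grid = np.array([0.0, 0.1, 0.1, 0.2, 0.5, 0.5, 0.9])
    for n in range(1, 6):
        for m in range(1, 6):
            x = rng.choice(grid, n)
            y = rng.choice(grid, m)
            assert mann_whitney_df(x, y) == pytest.approx(oracle_mw_two_sided(x, y))


def test_mann_whitney_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(4)
    for n, m in [(3, 5), (6, 6), (8, 7)]:
        x = rng.normal(size=n)
        y = rng.normal(size=m)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert mann_whitney_df(x, y) == pytest.approx(ref)


def test_bonferroni_caps_and_preserves_order():
    assert bonferroni([0.01], m=5) == [0.05]
    assert bonferroni([0.5], m=10) == [1.0]
    ps = [0.001, 0.02, 0.3, float("nan")]
    adj = bonferroni(ps)  # family size 3 (NaN excluded)
    assert adj[:3] == pytest.approx([0.003, 0.06, 0.9])
    assert math.isnan(adj[3])
    assert adj[:3] == sorted(adj[:3])


@pytest.mark.parametrize(
    "cdf, ndf, p, expected",
    [
        (0.4, 0.05, 0.001, "positive"),
        (0.01, 0.20, 0.0002, "negative"),
        (0.4, 0.05, 0.3, "neutral"),
        (float("nan"), 0.1, 0.01, "untestable"),
    ],
)
def test_call_selection_rule(cdf, ndf, p, expected):
    assert call_selection(cdf, ndf, p, alpha=0.05) == expected


def _toy_counts():
    """Hand-built count matrices: one loaded {1,3} signature CTT->TTA."""
    singles = np.zeros((64, 64), dtype=int)
    doubles = np.zeros((64, 64), dtype=int)
    anc = codon_id("CTT")
    doubles[anc, codon_id("TTA")] = 12
    singles[anc, codon_id("TTT")] = 10
    singles[anc, codon_id("CTA")] = 14
    return singles, doubles


def _toy_null_tally(b=2, a1=60, a2=50):
    tally = NullTally()
    sig = NullSignature(NullConfig.NM2, ("C", "T"), ("T", "A"))
    x, y, u, v = 1, 3, 3, 0  # C,T,T,A as base ids
    tally.doubles[NullConfig.NM2][x, y, u, v] = b
    tally.singles_a[NullConfig.NM2][x, y, u] = a1
    tally.singles_b[NullConfig.NM2][x, u, v] = a2
    tally.contexts[NullConfig.NM2][x, u] = 500
    return tally, sig


def test_build_comparisons_matched_row():
    singles, doubles = _toy_counts()
    tally, sig = _toy_null_tally()
    table = build_comparisons(singles, doubles, tally)
    row = table[(table.ancestral == "CTT") & (table.final == "TTA")].iloc[0]
    assert row["class"] == "NS" and row.testable
    assert (row.b, row.a1, row.a2) == (12, 10, 14)
    assert (row.null_b, row.null_a1, row.null_a2) == (2, 60, 50)
    assert row.df == pytest.approx(12 / 36)
    assert row.null_df == pytest.approx(2 / 112)
    expected_p = fisher_exact_pvalue(12, 24, 2, 110)
    assert row.fisher_p == pytest.approx(expected_p)
    # Bonferroni over the performed comparisons (shared singles make the
    # sibling {1,3} signatures of CTT testable too)
    family = int(table.testable.sum())
    assert row.p_adjusted == pytest.approx(min(1.0, expected_p * family))
    assert row.call == "positive"


def test_build_comparisons_untestable_without_null_events():
    singles, doubles = _toy_counts()
    table = build_comparisons(singles, doubles, NullTally())
    row = table[(table.ancestral == "CTT") & (table.final == "TTA")].iloc[0]
    assert not row.testable and row.call == "untestable"


def test_alpha_one_splits_calls_by_df_direction():
    singles, doubles = _toy_counts()
    tally, _ = _toy_null_tally()
    table = build_comparisons(singles, doubles, tally, alpha=1.0)
    testable = table[table.testable]
    # with alpha = 1 the significance gate is void wherever p < 1; only DF
    # direction decides (exact DF ties and p = 1 rows stay neutral)
    for row in testable.itertuples():
        if row.p_adjusted < 1.0 and row.df != row.null_df:
            assert row.call == ("positive" if row.df > row.null_df else "negative")
        else:
            assert row.call == "neutral"
    assert (testable.call == "positive").sum() == 1


def test_class_summary_fractions_partition():
    singles, doubles = _toy_counts()
    tally, _ = _toy_null_tally()
    table = build_comparisons(singles, doubles, tally)
    summary = class_summary(table, tally)
    assert list(summary["class"]) == ["SS", "SN", "NS", "NN"]
    testable = summary[summary.n_testable > 0]
    total = testable[["frac_positive", "frac_negative", "frac_neutral"]].sum(axis=1)
    assert np.allclose(total, 1.0)
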