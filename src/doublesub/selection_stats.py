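"""Double-fraction statistics and selection tests.

The double fraction DF = b / (a1 + a2 + b) is the share of a double
substitution among itself and its two component single substitutions.
Selection on a codon double substitution is read off a matched comparison:
its DF against the DF of the double-synonymous null signature with the same
position pair and base changes, via a two-sided Fisher's exact test on
[[b, a1+a2], [b_null, a1_null+a2_null]].  Class-level trends are assessed by
Mann-Whitney U tests between per-signature DF value distributions.  The
Bonferroni correction is applied over the family of performed comparisons.

Fisher's exact test is computed in-house (conditional hypergeometric
two-sided test, summing all tables in the conditional support whose
probability does not exceed that of the observed table, with the customary
1+1e-7 tie tolerance).  The in-house route exists because the package needs
to evaluate the test over hundreds of thousands of tables when validating
against exhaustive enumeration; it agrees with ``scipy.stats.fisher_exact``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import mannwhitneyu

from .classification import ANALYSIS_CLASSES, PathClass, classify_double, intermediates
from .genetic_code import CodonChange, codon_id, enumerate_double_substitutions
from .null_models import NullSignature, NullTally, match_null

CALLS = ("positive", "negative", "neutral", "untestable")


@dataclass(frozen=True)
class DoubleFractionRecord:
    """Counts (b, a1, a2) and the DF statistic for one substitution signature."""

    b: int
    a1: int
    a2: int

    def __post_init__(self):
        if min(self.b, self.a1, self.a2) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.b + self.a1 + self.a2

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def df(self) -> float:
        return self.b / self.total if self.defined else float("nan")


def compute_df(b: int, a1: int, a2: int) -> DoubleFractionRecord:
    """DF = b/(a1+a2+b); undefined (NaN df) when all counts are zero."""
    return DoubleFractionRecord(b, a1, a2)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

_TIE_TOL = 1.0 + 1e-7


def fisher_family_pvalues(r1: int, r2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided exact p-values for every table with margins (r1, r2, c1).

    Returns ``(support, pvalues)`` where ``support`` are the admissible
    values of the top-left cell.
    """
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - c1 + k + 1)
        + gammaln(c1 + 1)
        + gammaln(r1 + r2 - c1 + 1)
        - gammaln(r1 + r2 + 1)
    )
    pmf = np.exp(logpmf)
    p = np.array([pmf[pmf <= pmf_k * _TIE_TOL].sum() for pmf_k in pmf])
    return k, np.minimum(p, 1.0)


def fisher_exact_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    support, pvals = fisher_family_pvalues(r1, r2, c1)
    return float(pvals[a - support[0]])


class FisherResult(NamedTuple):
    pvalue: float
    degenerate: bool  # a margin of the 2x2 table was empty


def fisher_double_vs_single(codon: DoubleFractionRecord, null: DoubleFractionRecord) -> FisherResult:
    """Fisher's exact test of doubles vs cumulative singles, codon vs null."""
    a, b = codon.b, codon.a1 + codon.a2
    c, d = null.b, null.a1 + null.a2
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    return FisherResult(fisher_exact_pvalue(a, b, c, d), degenerate)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

EXACT_MW_MAX = 8


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mann_whitney_df(class_dfs: Sequence[float], null_dfs: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value between two DF samples.

    For small samples (both sizes <= 8) the exact permutation distribution
    of U is enumerated, with ties contributing half counts; larger samples
    use the normal approximation with tie correction and continuity
    correction.  Returns NaN (untestable) if either sample is empty.
    """
    x = [float(v) for v in class_dfs if not math.isnan(v)]
    y = [float(v) for v in null_dfs if not math.isnan(v)]
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        return float("nan")
    if n <= EXACT_MW_MAX and m <= EXACT_MW_MAX:
        pooled = x + y
        centre = n * m / 2.0
        d_obs = abs(_u_statistic(x, y) - centre)
        hits = 0
        total = 0
        idx = range(n + m)
        for group1 in combinations(idx, n):
            g1 = set(group1)
            xs = [pooled[i] for i in group1]
            ys = [pooled[i] for i in idx if i not in g1]
            if abs(_u_statistic(xs, ys) - centre) >= d_obs - 1e-12:
                hits += 1
            total += 1
        return hits / total
    return float(mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def bonferroni(pvals: Sequence[float], m: int | None = None) -> list[float]:
    """Multiply by the family size (performed tests), cap at 1; NaN passes through."""
    arr = [float(p) for p in pvals]
    if m is None:
        m = sum(0 if math.isnan(p) else 1 for p in arr)
    return [p if math.isnan(p) else min(1.0, p * m) for p in arr]


def call_selection(codon_df: float, null_df: float, p_adjusted: float, alpha: float = 0.05) -> str:
    """positive / negative / neutral / untestable decision for one comparison."""
    if math.isnan(codon_df) or math.isnan(null_df) or math.isnan(p_adjusted):
        return "untestable"
    if p_adjusted < alpha:
        if codon_df > null_df:
            return "positive"
        if codon_df < null_df:
            return "negative"
    return "neutral"


# ---------------------------------------------------------------------------
# Matched comparisons and class summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    """One codon double substitution paired with its matched null signature."""

    change: CodonChange
    class_label: PathClass
    codon_record: DoubleFractionRecord
    null_record: DoubleFractionRecord
    null_signature: NullSignature
    fisher_p: float
    p_adjusted: float
    call: str


def build_comparisons(
    singles: np.ndarray,
    doubles: np.ndarray,
    null_tally: NullTally,
    alpha: float = 0.05,
    min_null_contexts: int = 1,
    orientation: str = "positional",
    correction_family: str = "all",
) -> pd.DataFrame:
    """Assemble the per-substitution comparison table.

    ``singles`` and ``doubles`` are (64, 64) ancestral x derived event-count
    matrices from :func:`doublesub.parsimony.codon_substitution_counts`.
    A comparison is testable when the codon and null records each have at
    least one event and the null signature has at least ``min_null_contexts``
    branch-contexts.  ``correction_family`` is ``"all"`` (Bonferroni over all
    testable comparisons) or ``"per_class"``.
    """
    rows = []
    for change in enumerate_double_substitutions():
        label = classify_double(change)
        if label not in ANALYSIS_CLASSES:
            continue
        sig = match_null(change, orientation=orientation)
        anc = codon_id(change.ancestral)
        der = codon_id(change.final)
        i1, i2 = intermediates(change)
        codon_rec = DoubleFractionRecord(
            int(doubles[anc, der]), int(singles[anc, codon_id(i1)]), int(singles[anc, codon_id(i2)])
        )
        if sig is None:
            null_rec = DoubleFractionRecord(0, 0, 0)
            n_ctx = 0
        else:
            b, a1, a2, n_ctx = null_tally.counts(sig)
            null_rec = DoubleFractionRecord(b, a1, a2)
        testable = sig is not None and codon_rec.defined and null_rec.defined and n_ctx >= min_null_contexts
        fisher_p = fisher_double_vs_single(codon_rec, null_rec).pvalue if testable else float("nan")
        rows.append(
            {
                "ancestral": change.ancestral,
                "final": change.final,
                "positions": ",".join(str(p) for p in sorted(change.positions)),
                "class": label.value,
                "b": codon_rec.b,
                "a1": codon_rec.a1,
                "a2": codon_rec.a2,
                "df": codon_rec.df,
                "null_config": sig.config.value if sig else "",
                "null_b": null_rec.b,
                "null_a1": null_rec.a1,
                "null_a2": null_rec.a2,
                "null_df": null_rec.df,
                "null_contexts": n_ctx,
                "testable": testable,
                "fisher_p": fisher_p,
            }
        )
    table = pd.DataFrame(rows)

    table["p_adjusted"] = float("nan")
    if correction_family == "per_class":
        for label in table["class"].unique():
            sel = table["class"] == label
            table.loc[sel, "p_adjusted"] = bonferroni(table.loc[sel, "fisher_p"])
    elif correction_family == "all":
        table["p_adjusted"] = bonferroni(table["fisher_p"])
    else:
        raise ValueError(f"unknown correction family: {correction_family}")

    table["call"] = [
        call_selection(row.df, row.null_df, row.p_adjusted, alpha) for row in table.itertuples()
    ]
    return table


def class_summary(comparisons: pd.DataFrame, null_tally: NullTally) -> pd.DataFrame:
    """Per-class call fractions and Mann-Whitney tests against NM1 and NM2.

    Call fractions are over testable comparisons in each class.  The
    Mann-Whitney samples are per-signature DF values: every class member
    with a defined codon DF on one side, every tallied NM1 (both framings
    pooled) or NM2 null signature on the other.
    """
    nm1_dfs = []
    nm2_dfs = []
    for sig in null_tally.signatures():
        b, a1, a2, _ = null_tally.counts(sig)
        rec = DoubleFractionRecord(b, a1, a2)
        (nm2_dfs if sig.config.value == "NM2" else nm1_dfs).append(rec.df)

    rows = []
    for label in ANALYSIS_CLASSES:
        sub = comparisons[comparisons["class"] == label.value]
        testable = sub[sub["testable"]]
        n_testable = len(testable)
        counts = {call: int((testable["call"] == call).sum()) for call in ("positive", "negative", "neutral")}
        class_dfs = sub.loc[sub["df"].notna(), "df"].tolist()
        rows.append(
            {
                "class": label.value,
                "n_signatures": len(sub),
                "n_testable": n_testable,
                "frac_positive": counts["positive"] / n_testable if n_testable else float("nan"),
                "frac_negative": counts["negative"] / n_testable if n_testable else float("nan"),
                "frac_neutral": counts["neutral"] / n_testable if n_testable else float("nan"),
                "mean_df": float(np.mean(class_dfs)) if class_dfs else float("nan"),
                "mw_p_nm1": mann_whitney_df(class_dfs, nm1_dfs),
                "mw_p_nm2": mann_whitney_df(class_dfs, nm2_dfs),
            }
        )
    return pd.DataFrame(rows)
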