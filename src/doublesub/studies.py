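"""Simulation studies validating the pipeline's statistical behaviour.

Three studies are bundled:

* a null calibration - no selection differential between codon and null
  contexts (all nonsynonymous changes accepted), checking that the matched
  Fisher comparisons reject at close to their nominal rate and that
  Bonferroni-corrected selection calls are (almost) never produced;
* a positive-selection recovery - one NN double substitution gets a large
  acceptance boost under strong background purifying selection, and the
  pipeline should call it positive in nearly every replicate;
* a purifying-selection pattern - doublet acceptance is suppressed for all
  nonsynonymous-final (SN/NN) doubles, which should depress the SN and NN
  DF distributions against both null models while leaving SS and NS flat.

The study scale (20 replicates of 2,000 genes x 300 codons) and the
calibration mutation regime are fixed here.  Calibration rates are an
instrument design, not a biological emulation: per-signature expected
counts must be large enough that Fisher's discrete conservatism is mild
(doublet rates well above the few-percent tandem fraction of real genomes,
kappa = 1 so no transversion signature is starved), and the doublet rate is
the same at base-pair separations 1, 2 and 3 so that the single-event
contamination that frame-crossing doublet halves add to codon windows and
null-model windows is as close to exchangeable as the window geometry
allows (exact for NM2, within ~6% on one NM1 slot).  See docs/methods.md
for the full derivation.
"""

from __future__ import annotations

import math

import numpy as np

from .classification import PathClass, classify_double
from .genetic_code import CodonChange, enumerate_double_substitutions
from .pipeline import AnalysisResult, analyze_alignments
from .synthetic_data import SimulationConfig, inject_positive_case, simulate_dataset

#: calibration-scale defaults (frozen; see module docstring)
CALIBRATION = dict(
    n_genes=2000,
    codons_per_gene=300,
    mu=0.04,
    kappa=1.0,
    mu_double_adj=0.01,
    mu_double_gap=0.01,
)

#: the boosted NN change used in the positive-selection recovery study
POSITIVE_CASE = CodonChange("TTT", "GCT")


def calibration_config(seed: int, f_nonsyn: float = 1.0, **overrides) -> SimulationConfig:
    kwargs = dict(CALIBRATION)
    kwargs.update(overrides)
    return SimulationConfig(seed=seed, f_nonsyn=f_nonsyn, **kwargs)


def _dataset_seed(seed: int, i: int) -> int:
    return (seed * 100003 + 7919 * i + 1) % (2**31 - 1)


def _analyze(cfg: SimulationConfig, alpha: float = 0.05) -> AnalysisResult:
    alignments, _ = simulate_dataset(cfg, collect_truth=False)
    return analyze_alignments(alignments, alpha=alpha)


def run_null_calibration(seed: int = 1, n_datasets: int = 20, alpha: float = 0.05, **overrides) -> dict:
    """False-positive behaviour of the matched comparisons with no selection.

    With ``f_nonsyn = 1`` and no boosts, codon and null contexts experience
    identical per-site event processes, so every comparison is a true null.
    Reports the pooled fraction of testable comparisons with unadjusted
    Fisher p < 0.05 (the empirical size), the +-3 binomial-standard-error
    band around the nominal 0.05 at the per-dataset comparison count, and
    the mean number of Bonferroni-significant selection calls per dataset.
    """
    n_testable, n_lt05, n_calls = [], [], []
    for i in range(n_datasets):
        res = _analyze(calibration_config(_dataset_seed(seed, i), f_nonsyn=1.0, **overrides), alpha=alpha)
        t = res.testable
        n_testable.append(len(t))
        n_lt05.append(int((t["fisher_p"] < 0.05).sum()))
        n_calls.append(int(t["call"].isin(["positive", "negative"]).sum()))
    total = sum(n_testable)
    frac = sum(n_lt05) / total if total else float("nan")
    n_per = total / n_datasets if n_datasets else float("nan")
    half_band = 3.0 * math.sqrt(0.05 * 0.95 / n_per) if n_per else float("nan")
    return {
        "n_datasets": n_datasets,
        "n_testable": n_testable,
        "n_p_lt_05": n_lt05,
        "n_significant_calls": n_calls,
        "mean_testable_per_dataset": n_per,
        "fp_fraction": frac,
        "band_halfwidth": half_band,
        "within_band": bool(abs(frac - 0.05) <= half_band),
        "mean_significant_calls": float(np.mean(n_calls)) if n_calls else float("nan"),
    }


def run_positive_recovery(
    seed: int = 1,
    n_datasets: int = 20,
    multiplier: float = 20.0,
    f_nonsyn: float = 0.1,
    change: CodonChange = POSITIVE_CASE,
    alpha: float = 0.05,
    **overrides,
) -> dict:
    """Power to recover an injected positively selected double substitution.

    Background nonsynonymous acceptance is ``f_nonsyn``; the target change
    is boosted so its doublet (and second-step) acceptance saturates.  The
    pipeline should call it positive after Bonferroni correction in nearly
    all replicates.
    """
    calls = []
    for i in range(n_datasets):
        cfg = inject_positive_case(
            calibration_config(_dataset_seed(seed, i) + 10**6, f_nonsyn=f_nonsyn, **overrides),
            change,
            multiplier,
        )
        res = _analyze(cfg, alpha=alpha)
        row = res.comparisons[
            (res.comparisons["ancestral"] == change.ancestral) & (res.comparisons["final"] == change.final)
        ]
        calls.append(row["call"].iloc[0] if len(row) else "missing")
    rate = sum(c == "positive" for c in calls) / len(calls) if calls else float("nan")
    return {"change": str(change), "calls": calls, "recovery_rate": rate, "n_datasets": n_datasets}


def nonsynonymous_final_doubles() -> list[CodonChange]:
    """All SN/NN double substitutions (nonsynonymous final, no stop on any path)."""
    return [
        ch
        for ch in enumerate_double_substitutions()
        if classify_double(ch) in (PathClass.SN, PathClass.NN)
    ]


def run_purifying_pattern(seed: int = 1, suppression: float = 0.1, alpha: float = 0.05, **overrides) -> dict:
    """Class-level Mann-Whitney pattern under suppressed nonsynonymous doubles.

    Every SN/NN double substitution gets acceptance multiplier
    ``suppression`` (applied to doublets and second steps), with singles
    unaffected (``f_nonsyn = 1``).  Expected qualitative pattern: SN and NN
    DF distributions significantly below both null models; SS and NS
    indistinguishable from them.
    """
    boost = {ch: suppression for ch in nonsynonymous_final_doubles()}
    cfg = calibration_config(_dataset_seed(seed, 0) + 2 * 10**6, f_nonsyn=1.0, boost=boost, **overrides)
    res = _analyze(cfg, alpha=alpha)
    out = {"summary": res.summary}
    for _, row in res.summary.iterrows():
        label = row["class"].lower()
        out[f"mw_p_{label}_nm1"] = float(row["mw_p_nm1"])
        out[f"mw_p_{label}_nm2"] = float(row["mw_p_nm2"])
        out[f"mean_df_{label}"] = float(row["mean_df"])
    return out
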