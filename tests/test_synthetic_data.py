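import numpy as np
import pandas as pd
import pytest

from doublesub.genetic_code import CodonChange, STOP_CODONS
from doublesub.parsimony import infer_dataset
from doublesub.synthetic_data import (
    SimulationConfig,
    inject_positive_case,
    replay_truth,
    simulate_dataset,
    truth_ingroup_codon_changes,
)


def test_zero_rates_give_identical_leaves():
    cfg = SimulationConfig(n_genes=4, codons_per_gene=20, seed=2, mu=0, mu_double_adj=0, mu_double_gap=0)
    alignments, truth = simulate_dataset(cfg)
    assert all(a.seq_in1 == a.seq_in2 == a.seq_out for a in alignments)
    assert len(truth.events) == 0
    ds = infer_dataset(alignments)
    assert len(ds.events) == 0


def test_same_seed_is_bit_identical():
    cfg = SimulationConfig(n_genes=5, codons_per_gene=40, seed=9)
    a1, t1 = simulate_dataset(cfg)
    a2, t2 = simulate_dataset(cfg)
    assert [x.seq_in1 for x in a1] == [y.seq_in1 for y in a2]
    assert [x.seq_in2 for x in a1] == [y.seq_in2 for y in a2]
    assert [x.seq_out for x in a1] == [y.seq_out for y in a2]
    pd.testing.assert_frame_equal(t1.events, t2.events)


def test_different_seed_differs():
    a1, _ = simulate_dataset(SimulationConfig(n_genes=2, codons_per_gene=40, seed=1))
    a2, _ = simulate_dataset(SimulationConfig(n_genes=2, codons_per_gene=40, seed=2))
    assert any(x.seq_in1 != y.seq_in1 for x, y in zip(a1, a2))


def test_truth_log_replay_reproduces_leaves(small_dataset):
    alignments, truth = small_dataset
    for aln in alignments:
        rebuilt = replay_truth(truth, aln.gene_id)
        assert rebuilt == {"in1": aln.seq_in1, "in2": aln.seq_in2, "out": aln.seq_out}


def test_jit_and_python_kernels_agree():
    cfg = SimulationConfig(n_genes=4, codons_per_gene=30, seed=13, f_nonsyn=0.3)
    a_jit, t_jit = simulate_dataset(cfg)
    a_py, t_py = simulate_dataset(cfg, use_python=True)
    assert [x.seq_in1 + x.seq_in2 + x.seq_out for x in a_jit] == [
        x.seq_in1 + x.seq_in2 + x.seq_out for x in a_py
    ]
    pd.testing.assert_frame_equal(t_jit.events, t_py.events)


def test_no_stop_codons_are_ever_created():
    cfg = SimulationConfig(n_genes=6, codons_per_gene=50, seed=21, f_nonsyn=1.0)
    alignments, _ = simulate_dataset(cfg)
    for aln in alignments:
        for seq in (aln.seq_in1, aln.seq_in2, aln.seq_out):
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & STOP_CODONS)


def test_inferred_events_converge_to_truth_at_low_rates():
    """Parsimony recovers the simulated events in the rare-event regime."""
    cfg = SimulationConfig(
        n_genes=300, codons_per_gene=200, seed=5, mu=1e-3, mu_double_adj=2e-4, mu_double_gap=1e-4, f_nonsyn=1.0
    )
    alignments, truth = simulate_dataset(cfg)
    ds = infer_dataset(alignments)
    true_changes = truth_ingroup_codon_changes(truth)
    n_true = len(true_changes)
    n_inferred = len(ds.events)
    assert n_true > 100
    assert abs(n_inferred - n_true) / n_true < 0.02
    # inferred per-codon changes are exactly the surviving truth changes
    key = lambda df: set(zip(df.gene_id, df.codon_index, df.branch, df.ancestral, df.derived))
    missing = key(true_changes) - key(ds.events)
    assert len(missing) / n_true < 0.02


def test_f_nonsyn_suppresses_nonsynonymous_events():
    base = SimulationConfig(n_genes=10, codons_per_gene=100, seed=3, f_nonsyn=1.0)
    strict = SimulationConfig(n_genes=10, codons_per_gene=100, seed=3, f_nonsyn=0.05)
    _, t1 = simulate_dataset(base)
    _, t2 = simulate_dataset(strict)
    frac1 = (t1.events.acceptance == "nonsynonymous").mean()
    frac2 = (t2.events.acceptance == "nonsynonymous").mean()
    assert frac2 < frac1 / 3


def test_inject_positive_case_validation():
    cfg = SimulationConfig(n_genes=1, codons_per_gene=10)
    boosted = inject_positive_case(cfg, CodonChange("TTT", "GCT"), 20.0)
    assert boosted.boost[CodonChange("TTT", "GCT")] == 20.0
    assert cfg.boost == {}  # original untouched
    with pytest.raises(ValueError):
        inject_positive_case(cfg, CodonChange("TCA", "TAG"), 5.0)  # stop final
    with pytest.raises(ValueError):
        inject_positive_case(cfg, CodonChange("AAA", "AAG"), 5.0)  # single


def test_boost_multiplier_one_changes_nothing():
    cfg = SimulationConfig(n_genes=3, codons_per_gene=40, seed=8, f_nonsyn=0.2)
    boosted = inject_positive_case(cfg, CodonChange("TTT", "GCT"), 1.0)
    a1, _ = simulate_dataset(cfg)
    a2, _ = simulate_dataset(boosted)
    assert [x.seq_in1 for x in a1] == [y.seq_in1 for y in a2]


def test_boost_elevates_target_double_frequency():
    change = CodonChange("TTT", "GCT")
    base = SimulationConfig(
        n_genes=200, codons_per_gene=150, seed=6, f_nonsyn=0.05, mu_double_adj=0.05
    )
    boosted = inject_positive_case(base, change, 100.0)

    def count_target(truth):
        ev = truth.events
        hits = ev[(ev.codon_before == "TTT") & (ev.codon_after == "GCT")]
        return len(hits)

    _, t_base = simulate_dataset(base)
    _, t_boost = simulate_dataset(boosted)
    assert count_target(t_boost) > 3 * max(count_target(t_base), 1)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(mu=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(kappa=0)
    with pytest.raises(ValueError):
        SimulationConfig(codon_frequencies={"TAA": 1.0})
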