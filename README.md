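# doublesub

Detecting positive and purifying selection on **double nucleotide
substitutions within codons** from species-triplet alignments.

Point mutations are usually modelled as independent, but a codon sometimes
changes at two positions on one branch — either through a single
multinucleotide mutation event or through two successive single
substitutions. Because the intermediate codon of a deleterious first step
can be rescued by a compensatory second step, such doubles are candidate
targets of positive selection; conversely, doubly nonsynonymous changes may
be purged more strongly than their component singles. `doublesub`
implements a mutational-bias-aware test for both regimes, for people
studying short-term coding-sequence evolution in closely related genome
trios (e.g. two ingroup primates or yeasts plus an outgroup).

## Method

For each gene, three aligned coding sequences related as
`((in1, in2), out)` are compared codon by codon. When the outgroup agrees
with one ingroup, parsimony assigns the substitution to the other ingroup's
terminal branch (at most one mutation per position). For every codon double
substitution X→Y with two changed positions, the pipeline counts

- `b` — double substitutions X→Y,
- `a1`, `a2` — the two component single substitutions X→I₁, X→I₂,

and summarises them as the **double fraction**

```
DF = b / (a1 + a2 + b)
```

Each double substitution is classified by path synonymy into **SS, SN, NS,
NN** (first letter: the single-step intermediates; second: the final codon;
paths through stop codons are excluded), and compared against a matched
**double-synonymous null model** built from adjacent codons: "artificial
codons" whose two variable sites can both change synonymously — a
fourfold-degenerate third position next to a twofold-degenerate first
position of a Leu/Arg codon (NM1, in its 231 and 312 framings) or two
fourfold third positions one codon apart (NM2). The null signature shares
the position pair and the exact ordered base changes with the codon double,
controlling for base composition and mutation spectrum. A two-sided
Fisher's exact test on `[[b, a1+a2], [b_null, a1_null+a2_null]]` with
Bonferroni correction yields a per-substitution call: **positive** (DF
above the null), **negative** (below), or **neutral**; Mann–Whitney U tests
compare whole-class DF distributions with each null model.

Because no processed trio data ship with the package, a synthetic-data
generator produces triplet alignments with configurable single-substitution
rate, transition/transversion bias, tandem and short-range doublet mutation
rates, synonymy-dependent acceptance, and per-substitution selection
boosts — with a replayable truth log, so the entire pipeline is testable.

## Worked example

```
$ doublesub run-all --config run.yaml --out demo
```

with `run.yaml`:

```yaml
outdir: demo
seed: 4
simulation: {n_genes: 6, codons_per_gene: 40, mu: 0.02,
             mu_double_adj: 0.005, mu_double_gap: 0.005}
```

prints the run log:

```
doublesub run, seed=4
alpha=0.05 orientation=positional min_null_contexts=1 correction_family=all
simulated 6 genes x 40 codons
events: 19 (singles=17, doubles=2, triples=0)
testable comparisons: 8
calls: positive=0, negative=0, neutral=8
```

19 substitution events were inferred on the two ingroup branches, 2 of
them codon doubles; 8 double-substitution signatures had both codon and
matched-null events and none deviated from its null after correction — as
expected for a neutral simulation this small. The stage artifacts
(`events.tsv`, `null_tally.tsv`, `comparisons.tsv`, `class_summary.tsv`)
land in `demo/`; each stage can also be re-run independently
(`doublesub simulate/infer/tally/classify/test/summarize`).

The numbered scripts under `analysis/` run the package's studies at scale:
the 1647-entry classification census (SN 718, NN 706, NS 20, SS 8, 195
stop-excluded), a no-selection calibration of the matched tests, the
recovery of an injected positively selected change, and the class-level
purifying-selection pattern.

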