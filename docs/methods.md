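# Methods

## Parsimony inference from species triplets

The unit of data is a codon-aware alignment of two ingroup sequences and an
outgroup, related as `((in1, in2), out)`. Sites are codon column-triples;
any codon containing a gap or ambiguity character in any sequence voids the
whole site. The five-way case analysis per site: all three codons equal —
ancestral state observed, no event; outgroup equal to exactly one ingroup —
the other ingroup carries a substitution on its terminal branch, with the
shared codon as ancestral state; ingroups equal but different from the
outgroup — the change sits on the internal or outgroup lineage and cannot
be polarized, so the site is skipped; all three different — skipped. Events
are inferred at codon granularity (all three positions jointly), so a
double substitution is one event with two changed positions on one branch;
three-position events are recorded but excluded from all DF tallies.
Events whose ancestral or derived codon is a stop are discarded, and
in-frame stop sites never enter the ancestral tally; the analysis concerns
sense-codon evolution only. Each polarizable site contributes two
branch-contexts to the ancestral tally (one opportunity per ingroup
branch). Because `b`, `a1` and `a2` for one signature share the same
ancestral codon, the DF statistic is computed directly on counts; the
per-codon ancestral tally is exported for users who need frequencies.

## Path-synonymy classification

Every double substitution with a sense ancestral codon (61 × 27 = 1647
changes) is classified by the synonymy of its two single-step intermediates
and its final codon: SS (everything synonymous), NS (synonymous final,
≥1 nonsynonymous intermediate), SN (nonsynonymous final, ≥1 synonymous
intermediate), NN (everything nonsynonymous). A stop final codon excludes
the change outright; otherwise a stop on either path excludes it (the
exclusion is of the change, not just the offending path). Stop-final
exclusion takes precedence — such changes never enter any tally, so the
intermediate test is moot. This resolution of the "at least one" wording
makes the four labels mutually exclusive and exhaustive; the census is
SN 718, NN 706, NS 20, SS 8, plus 79 stop-final and 116 stop-intermediate
exclusions.

## Null models and matching

The three null configurations are codon-like windows over adjacent codons
whose variable sites can change synonymously. With codon *i* required to
have a fourfold-degenerate third position: NM1 windows additionally require
codon *i+1* to be one of the eight Leu/Arg codons with a degenerate first
position (all carry a purine third position); the 231 framing treats
(i·2, i·3, (i+1)·1) as the artificial codon with i·2 invariant, the 312
framing treats (i·3, (i+1)·1, (i+1)·2) with (i+1)·2 invariant. NM2 requires
both codons fourfold at the third position and uses (i·3, (i+1)·3) with
(i+1)·1 invariant; its two genomic sites are 3 bp apart although the codon
positions it mirrors ({1,3}) are 2 bp apart — the window follows the
published configuration and the discrepancy is absorbed by the generator's
doublet model (below). On a given branch a window is used only if its
invariant site is unchanged. A fourfold-slot change is synonymous by
construction; a twofold-slot change is synonymous only within the family of
the ancestral codon (Leu C↔T, Arg C↔A); nonsynonymous twofold-slot changes
contribute nothing.

A codon double substitution is matched to the null configuration of its
position pair — {2,3} → NM1-231, {1,2} → NM1-312, {1,3} → NM2 — with
identical ordered base changes at the corresponding slots (the strictest
reading of signature matching, controlling base composition and mutation
spectrum). By default the fourfold slot aligns with the smaller codon
position; for {1,2} doubles a `mirrored` orientation switch swaps the slot
mapping. {2,3} and {1,2} doubles whose twofold-slot change is not C↔A or
C↔T have no synonymous null analogue and are reported untestable.

Two tally refinements keep the null exactly exchangeable with the codon
tallies under no selection:

1. **Family conditioning.** An ancestral C at the twofold slot belongs to
   either a Leu or an Arg context, and a given signature's doubles can only
   arise in one of them. Slot-a singles and window counts are therefore
   conditioned on the family (identified by the signature's synonymous
   derived base); without this, null denominators for C-slot signatures
   pool both families and deflate null DF about twofold.
2. **Sister-branch conditioning.** Under triplet parsimony a window double
   needs both codons untouched by the sister branch and outgroup, while a
   window single would also be counted when the sister branch changed the
   partner codon. At appreciable divergence this asymmetry deflates null DF
   by roughly the per-codon touch probability (~20% in the calibration
   regime; negligible at the ~1% per-codon divergences of real closely
   related trios). Windows are therefore used on a branch only when the
   sister branch left both codons unchanged, making the parsimony survival
   factors identical for window doubles, singles and opportunities — the
   same cancellation that holds trivially within one codon on the codon
   side.

## Statistical testing

Per matched comparison, a two-sided Fisher's exact test on
`[[b, a1+a2], [b_null, a1_null+a2_null]]`; a comparison is testable when
both records have at least one event and the null signature at least one
window (configurable minimum). The exact test is computed in-house as the
conditional hypergeometric two-sided test (summing all tables in the
conditional support whose probability does not exceed the observed table's,
with the customary 1+1e-7 tie tolerance); this vectorized-per-margin
implementation is needed to validate against exhaustive enumeration over
hundreds of thousands of tables, and it agrees with
`scipy.stats.fisher_exact` to 1e-9. Bonferroni correction multiplies by the
number of performed comparisons (untestable entries excluded); the family
is all testable comparisons of a run by default, per-class behind a flag.
A comparison is called positive/negative when its corrected p-value is
below α and its DF is above/below the null DF, neutral otherwise.

Class-level tests are two-sided Mann–Whitney U between per-signature DF
values of a class and of a null model (NM1 pools both framings). For both
sample sizes ≤ 8 the exact permutation distribution of U is enumerated with
ties contributing half counts; larger samples use scipy's normal
approximation with tie and continuity corrections.

## Synthetic data generator

Root coding sequences are sampled per gene from configurable sense-codon
frequencies (default uniform over 61); each of the three branches then
applies mutations in one deterministic left-to-right pass, drawing from a
single seeded RNG stream. Three processes act per branch: single
substitutions (probability `mu` per position; derived base drawn with
transition weight `kappa` against 1 per transversion), simultaneous
doublets at adjacent base pairs (`mu_double_adj`), and simultaneous
doublets at pairs 2 or 3 bp apart (`mu_double_gap`). Doublets are placed
frame-agnostically — including across codon boundaries — because the null
windows straddle codons (NM2's sites are 3 bp apart); a frame-restricted
doublet model would starve the null models of doubles and make every
comparison spuriously positive. Each position mutates at most once per
branch, which keeps the parsimony assumption exactly satisfiable. A
candidate is fixed with probability 1 when every affected codon change is
synonymous and `f_nonsyn` times the registered boost (capped at 1)
otherwise; stop-creating candidates are always rejected. Boosts are looked
up on the branch-cumulative codon change, so a registered double is
elevated both as a simultaneous doublet and as the second step on a
standing intermediate. The truth log records every applied event and
replays to the leaf sequences exactly.

Realistic defaults (`mu = 0.04`, `kappa = 2`, `mu_double_adj = 2e-3`,
`mu_double_gap = 1e-3`, `f_nonsyn = 0.25`) emulate a closely related
eukaryote trio: a few percent per-branch divergence, transition bias ~2,
doublets a few percent of single events, moderately strong purifying
selection. What the generator does not model: indels, recombination, rate
heterogeneity along genes, CpG hypermutability (representable only through
boost-style overrides), codon-usage bias (unless frequencies are supplied),
and alignment error — so passing tests demonstrate correctness of
inference and testing under the stated mutational model, not robustness to
real-data artifacts.

## Simulation studies and their regime

Three studies (in `doublesub.studies`, driven by `analysis/` and
`scripts/acceptance.py`) run at 20 replicates of 2,000 genes × 300 codons:

- **Null calibration** (`f_nonsyn = 1`, no boosts): codon and null windows
  then experience identical per-site event processes, so every comparison
  is a true null; the unadjusted Fisher rejection fraction should sit near
  0.05 and Bonferroni-significant calls near zero.
- **Positive recovery**: the NN change TTT→GCT boosted ×20 under
  `f_nonsyn = 0.1` should be called positive in nearly every replicate.
- **Purifying pattern**: acceptance ×0.1 for all SN/NN doubles (singles
  untouched) should depress SN and NN DF distributions against both null
  models while SS and NS stay flat.

The calibration mutation regime (`mu = 0.04`, `kappa = 1`,
`mu_double_adj = mu_double_gap = 0.01`, uniform roots) is an instrument
design, not an emulation: per-signature expected double counts must be
large enough (~20 codon-side) that the exact test's discrete conservatism
is mild, which requires doublet rates far above the few-percent tandem
fraction of real genomes and `kappa = 1` so no transversion signature is
starved; and the doublet rate is equal at separations 1–3 so the
single-event contamination that frame-crossing doublet halves add to codon
windows and null windows is identical (exactly so for NM2 and every codon
position, within one slot's worth — about 6% of singles — for NM1). The
calibration band is ±3 binomial standard errors of 0.05 at the
per-replicate comparison count (~820), acknowledging that an exact
conditional test cannot attain its nominal size under discreteness.

Known limitation: recovery of a single boosted change is power-limited by
the matched null window's rarity. The NM1 window of TTT→GCT occurs at only
a few thousand positions per replicate at this scale, putting a floor of
~0.45 on the standard error of the log odds ratio; with the observed
contrast the corrected test clears significance in roughly half the
replicates, not nearly all. Raising doublet rates does not help — window
survival under parsimony falls as the fourth power of per-codon
intactness — so reliable single-change recovery needs genome-scale data,
consistent with the method's intended use.

## Numerical and design choices

- Codons are uppercase DNA; positions 1-based; only the standard nuclear
  code is supported (the fourfold families derive from the code itself:
  Leu, Val, Ser, Pro, Thr, Ala, Arg, Gly).
- Intermediates are ordered by changed position (smaller first); table
  orders are lexicographic; all pipelines are deterministic given seeds,
  and stage artifacts are plain TSV sufficient to resume the run.
- Fisher p for a table with an empty margin is 1 with a `degenerate` flag;
  DF of an all-zero record is NaN and flagged undefined; Mann–Whitney with
  an empty sample is NaN (untestable).
- Replicate seeds derive linearly from the study seed; the simulation
  kernel consumes pre-drawn uniforms so the numba-compiled and pure-Python
  code paths are bit-identical.
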