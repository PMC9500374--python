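"""Synthetic triplet-alignment generator with known mutational and selective parameters.

The generator emulates the data the pipeline consumes: per-gene codon
alignments of two ingroup species and one outgroup related as
``((in1, in2), out)``.  A root coding sequence is sampled per gene
(no stops), and each of the three branches independently applies, in a
single deterministic left-to-right pass:

* single substitutions, per position with probability ``mu`` (derived base
  drawn with transition weight ``kappa`` against 1 per transversion);
* simultaneous doublet mutations at genomic base pairs: adjacent pairs with
  probability ``mu_double_adj``, and pairs 2 or 3 bp apart with probability
  ``mu_double_gap``.  Doublets are applied wherever the pair falls, including
  across codon boundaries - the adjacent-codon null-model sites experience
  the same doublet process as within-codon pairs.

Each candidate mutation respects the at-most-one-mutation-per-position rule
(positions already mutated on the branch are never hit again).  A candidate
is fixed with probability 1 when every affected codon change is synonymous,
and otherwise with probability ``f_nonsyn`` times the boost registered for
the branch-cumulative codon change (capped at 1); candidates creating stop
codons are always rejected.  Because the boost is looked up on the
branch-start -> proposed codon change, a registered double is elevated both
as a simultaneous doublet and as the second step on top of a standing
first-step intermediate.

All randomness comes from one ``numpy`` generator seeded from the config;
the mutation kernel consumes pre-drawn uniforms so the JIT-compiled and
pure-Python code paths are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classification import PathClass, classify_double
from .genetic_code import (
    BASES,
    BASE_INDEX,
    CODON_AA,
    CODONS,
    CodonChange,
    IS_STOP,
    SENSE_CODONS,
    codon_id,
)
from .parsimony import TripletAlignment, decode_sequence

try:  # pragma: no cover - exercised implicitly by every simulation test
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            fn.py_func = fn
            return fn

        return wrap if not (args and callable(args[0])) else wrap(args[0])


BRANCH_ORDER = ("in1", "in2", "out")
EVENT_KINDS = ("single", "double_adj", "double_gap2", "double_gap3")

#: transition partner and the two transversion alternatives, by base id
_TS = np.array([BASE_INDEX["G"], BASE_INDEX["T"], BASE_INDEX["A"], BASE_INDEX["C"]], dtype=np.int8)
_TV = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)  # (C,T),(A,G),(C,T),(A,G)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Defaults emulate a closely related eukaryote triplet: per-branch
    divergence of a few percent, transition bias ~2, tandem/gapped doublets
    a small fraction of single events, and moderately strong purifying
    selection on amino-acid changes.
    """

    n_genes: int = 2000
    codons_per_gene: int = 300
    seed: int = 0
    mu: float = 0.04
    kappa: float = 2.0
    mu_double_adj: float = 2e-3
    mu_double_gap: float = 1e-3
    f_nonsyn: float = 0.25
    boost: dict = field(default_factory=dict)  # CodonChange -> acceptance multiplier
    codon_frequencies: dict | None = None  # codon -> weight over sense codons

    def __post_init__(self):
        for name in ("mu", "mu_double_adj", "mu_double_gap", "f_nonsyn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_genes < 1 or self.codons_per_gene < 1:
            raise ValueError("n_genes and codons_per_gene must be positive")
        self.root_weights()  # validates codon_frequencies
        self.boost_matrix()  # validates boost entries

    def boost_matrix(self) -> np.ndarray:
        m = np.ones((64, 64))
        for change, mult in self.boost.items():
            if not isinstance(change, CodonChange):
                change = CodonChange(*change)
            if mult < 0:
                raise ValueError("boost multiplier must be non-negative")
            m[codon_id(change.ancestral), codon_id(change.final)] = mult
        return m

    def root_weights(self) -> np.ndarray:
        w = np.zeros(64)
        if self.codon_frequencies is None:
            for c in SENSE_CODONS:
                w[codon_id(c)] = 1.0
        else:
            for c, weight in self.codon_frequencies.items():
                if c not in SENSE_CODONS:
                    raise ValueError(f"root frequency given for non-sense codon {c}")
                if weight < 0:
                    raise ValueError("codon frequencies must be non-negative")
                w[codon_id(c)] = weight
        if w.sum() <= 0:
            raise ValueError("codon frequencies sum to zero")
        return w / w.sum()


@dataclass
class TruthLog:
    """Applied mutation events plus the root sequences needed to replay them."""

    events: pd.DataFrame
    roots: dict  # gene_id -> root sequence string


@njit(cache=False)
def _branch_kernel(
    seq,
    root_codons,
    u_adj,
    u_gap2,
    u_gap3,
    u_single,
    extras,
    mu,
    mu_adj,
    mu_gap,
    p_ts,
    f_nonsyn,
    aa,
    is_stop,
    boost,
    ev_kind,
    ev_pos1,
    ev_pos2,
    ev_b1,
    ev_b2,
):
    """Apply one branch's mutations to ``seq`` in place; returns event count.

    Deterministic traversal: positions left to right, and at each position
    the candidate order is adjacent doublet, 2-apart doublet, 3-apart
    doublet, then single.  ``extras`` is consumed only by candidates whose
    occurrence uniform fired and whose positions are all still unmutated.
    """
    L = seq.size
    occ = np.zeros(L, dtype=np.uint8)
    n_ev = 0
    c = 0  # extras cursor
    for p in range(L):
        for kind in range(4):
            if kind == 0:
                q = p + 1
                if q >= L or u_adj[p] >= mu_adj:
                    continue
            elif kind == 1:
                q = p + 2
                if q >= L or u_gap2[p] >= mu_gap:
                    continue
            elif kind == 2:
                q = p + 3
                if q >= L or u_gap3[p] >= mu_gap:
                    continue
            else:
                q = -1
                if u_single[p] >= mu:
                    continue
            if occ[p] == 1 or (q >= 0 and occ[q] == 1):
                continue

            # propose derived bases
            o1 = seq[p]
            u = extras[c]
            c += 1
            if u < p_ts:
                nb1 = _TS[o1]
            elif u < p_ts + (1.0 - p_ts) / 2.0:
                nb1 = _TV[o1, 0]
            else:
                nb1 = _TV[o1, 1]
            nb2 = np.int8(-1)
            if q >= 0:
                o2 = seq[q]
                u = extras[c]
                c += 1
                if u < p_ts:
                    nb2 = _TS[o2]
                elif u < p_ts + (1.0 - p_ts) / 2.0:
                    nb2 = _TV[o2, 0]
                else:
                    nb2 = _TV[o2, 1]
            u_acc = extras[c]
            c += 1

            # acceptance over the affected codon(s)
            acc = 1.0
            cod_a = p // 3
            cod_b = q // 3 if q >= 0 else cod_a
            for cod in range(cod_a, cod_b + 1):
                if cod != cod_a and cod != cod_b:
                    continue
                base0 = 3 * cod
                cur = 16 * seq[base0] + 4 * seq[base0 + 1] + seq[base0 + 2]
                new = 0
                for k in range(3):
                    b = seq[base0 + k]
                    if base0 + k == p:
                        b = nb1
                    elif q >= 0 and base0 + k == q:
                        b = nb2
                    new = 4 * new + b
                if new == cur:
                    continue
                if is_stop[new]:
                    acc = 0.0
                    break
                if aa[new] != aa[cur]:
                    mult = boost[root_codons[cod], new]
                    pa = f_nonsyn * mult
                    if pa > 1.0:
                        pa = 1.0
                    acc *= pa
            if u_acc < acc:
                seq[p] = nb1
                occ[p] = 1
                if q >= 0:
                    seq[q] = nb2
                    occ[q] = 1
                ev_kind[n_ev] = kind
                ev_pos1[n_ev] = p
                ev_pos2[n_ev] = q
                ev_b1[n_ev] = nb1
                ev_b2[n_ev] = nb2
                n_ev += 1
    return n_ev


_KIND_NAME = {0: "double_adj", 1: "double_gap2", 2: "double_gap3", 3: "single"}


def _simulate_gene(rng, cfg, boost_mx, root_bases, use_python=False, collect=True):
    """Apply all three branches to one gene; returns (leaf seqs, event rows)."""
    L = root_bases.size
    root_codons = (16 * root_bases[0::3] + 4 * root_bases[1::3] + root_bases[2::3]).astype(np.int16)
    p_ts = cfg.kappa / (cfg.kappa + 2.0)
    kernel = _branch_kernel.py_func if use_python else _branch_kernel

    leaves = {}
    rows = []
    for branch in BRANCH_ORDER:
        u_adj = rng.random(max(L - 1, 1))
        u_gap2 = rng.random(max(L - 2, 1))
        u_gap3 = rng.random(max(L - 3, 1))
        u_single = rng.random(L)
        n_triggered = int(
            (u_adj[: L - 1] < cfg.mu_double_adj).sum()
            + (u_gap2[: L - 2] < cfg.mu_double_gap).sum()
            + (u_gap3[: L - 3] < cfg.mu_double_gap).sum()
            + (u_single < cfg.mu).sum()
        )
        extras = rng.random(3 * n_triggered + 1)
        seq = root_bases.copy()
        ev_kind = np.empty(L, dtype=np.int8)
        ev_pos1 = np.empty(L, dtype=np.int32)
        ev_pos2 = np.empty(L, dtype=np.int32)
        ev_b1 = np.empty(L, dtype=np.int8)
        ev_b2 = np.empty(L, dtype=np.int8)
        n_ev = kernel(
            seq,
            root_codons,
            u_adj,
            u_gap2,
            u_gap3,
            u_single,
            extras,
            cfg.mu,
            cfg.mu_double_adj,
            cfg.mu_double_gap,
            p_ts,
            cfg.f_nonsyn,
            CODON_AA,
            IS_STOP,
            boost_mx,
            ev_kind,
            ev_pos1,
            ev_pos2,
            ev_b1,
            ev_b2,
        )
        leaves[branch] = seq
        for i in range(n_ev if collect else 0):
            rows.append(
                {
                    "branch": branch,
                    "kind": _KIND_NAME[int(ev_kind[i])],
                    "pos1": int(ev_pos1[i]) + 1,
                    "pos2": int(ev_pos2[i]) + 1 if ev_pos2[i] >= 0 else -1,
                    "alt1": BASES[int(ev_b1[i])],
                    "alt2": BASES[int(ev_b2[i])] if ev_b2[i] >= 0 else "",
                }
            )
    return leaves, rows


def _annotate_events(rows, root_seq):
    """Add reference bases, codon indices and codon-level change info.

    Events are replayed per branch in application order so the before/after
    codons reflect the sequence state at acceptance time.
    """
    state = {}
    for row in rows:
        br = row["branch"]
        if br not in state:
            state[br] = list(root_seq)
        s = state[br]
        p1 = row["pos1"] - 1
        row["ref1"] = root_seq[p1]
        row["codon_index"] = p1 // 3 + 1
        positions = [(p1, row["alt1"])]
        if row["pos2"] > 0:
            p2 = row["pos2"] - 1
            row["ref2"] = root_seq[p2]
            positions.append((p2, row["alt2"]))
        else:
            row["ref2"] = ""
        affected = sorted({p // 3 for p, _ in positions})
        before, after = [], []
        syn = True
        for cod in affected:
            b = "".join(s[3 * cod : 3 * cod + 3])
            t = list(b)
            for p, alt in positions:
                if p // 3 == cod:
                    t[p % 3] = alt
            a = "".join(t)
            before.append(b)
            after.append(a)
            if CODON_AA[codon_id(a)] != CODON_AA[codon_id(b)]:
                syn = False
        row["codon_before"] = ",".join(before)
        row["codon_after"] = ",".join(after)
        row["acceptance"] = "synonymous" if syn else "nonsynonymous"
        for p, alt in positions:
            s[p] = alt
    return rows


def simulate_dataset(cfg: SimulationConfig, use_python: bool = False, collect_truth: bool = True):
    """Generate a full dataset.

    Returns ``(alignments, truth)``: a list of :class:`TripletAlignment`
    (one per gene, IDs ``g0000``...) and a :class:`TruthLog`.  Bit-identical
    across runs for a given config; the sequences do not depend on
    ``collect_truth`` (it only skips the event-log assembly, which large
    statistical studies do not need).
    """
    rng = np.random.default_rng(cfg.seed)
    boost_mx = cfg.boost_matrix()
    weights = cfg.root_weights()
    alignments = []
    all_rows = []
    roots = {}
    for g in range(cfg.n_genes):
        gene_id = f"g{g:04d}"
        root_codon_ids = rng.choice(64, size=cfg.codons_per_gene, p=weights)
        root_bases = np.empty(3 * cfg.codons_per_gene, dtype=np.int8)
        root_bases[0::3] = root_codon_ids // 16
        root_bases[1::3] = (root_codon_ids // 4) % 4
        root_bases[2::3] = root_codon_ids % 4
        leaves, rows = _simulate_gene(rng, cfg, boost_mx, root_bases, use_python=use_python, collect=collect_truth)
        if collect_truth:
            root_seq = decode_sequence(root_bases)
            roots[gene_id] = root_seq
            for row in _annotate_events(rows, root_seq):
                row["gene_id"] = gene_id
                all_rows.append(row)
        alignments.append(
            TripletAlignment(
                gene_id,
                decode_sequence(leaves["in1"]),
                decode_sequence(leaves["in2"]),
                decode_sequence(leaves["out"]),
            )
        )
    columns = [
        "gene_id",
        "branch",
        "kind",
        "pos1",
        "pos2",
        "ref1",
        "alt1",
        "ref2",
        "alt2",
        "codon_index",
        "codon_before",
        "codon_after",
        "acceptance",
    ]
    events = pd.DataFrame(all_rows, columns=columns)
    return alignments, TruthLog(events, roots)


def replay_truth(truth: TruthLog, gene_id: str) -> dict:
    """Rebuild each branch's leaf sequence from the root and the event log."""
    root = truth.roots[gene_id]
    out = {}
    sub = truth.events[truth.events["gene_id"] == gene_id]
    for branch in BRANCH_ORDER:
        s = list(root)
        for row in sub[sub["branch"] == branch].itertuples():
            s[row.pos1 - 1] = row.alt1
            if row.pos2 > 0:
                s[row.pos2 - 1] = row.alt2
        out[branch] = "".join(s)
    return out


def truth_ingroup_codon_changes(truth: TruthLog) -> pd.DataFrame:
    """Net root -> leaf codon changes on the two ingroup branches.

    One row per (gene, branch, codon) whose leaf codon differs from the
    root codon; ``n_changed`` counts differing positions.  This is the
    ground truth that parsimony inference estimates.
    """
    rows = []
    for gene_id, root in truth.roots.items():
        leaves = replay_truth(truth, gene_id)
        for branch in ("in1", "in2"):
            leaf = leaves[branch]
            for i in range(0, len(root), 3):
                rc, lc = root[i : i + 3], leaf[i : i + 3]
                if rc != lc:
                    rows.append(
                        {
                            "gene_id": gene_id,
                            "branch": branch,
                            "codon_index": i // 3 + 1,
                            "ancestral": rc,
                            "derived": lc,
                            "n_changed": sum(a != b for a, b in zip(rc, lc)),
                        }
                    )
    return pd.DataFrame(rows, columns=["gene_id", "branch", "codon_index", "ancestral", "derived", "n_changed"])


def inject_positive_case(cfg: SimulationConfig, change: CodonChange, multiplier: float) -> SimulationConfig:
    """Config with elevated acceptance for one codon double substitution.

    The boost applies to the simultaneous doublet and, through the
    branch-cumulative lookup, to the second single step on top of a
    standing intermediate.
    """
    if change.n_changed != 2:
        raise ValueError(f"not a double substitution: {change}")
    if classify_double(change) is PathClass.EXCLUDED_STOP_FINAL:
        raise ValueError(f"stop-final change cannot be boosted: {change}")
    if multiplier < 0:
        raise ValueError("multiplier must be non-negative")
    new_boost = dict(cfg.boost)
    new_boost[change] = multiplier
    return replace(cfg, boost=new_boost)
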