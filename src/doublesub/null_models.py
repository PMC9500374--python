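"""Double-synonymous null models in adjacent codons.

Codon double substitutions are compared against "artificial codons" built
from neighbouring codon positions in which both variable sites can change
synonymously.  Three configurations are used, named by the codon positions
the 3-base window spans:

* ``NM1_231`` - [pos 2 of codon i (invariant), pos 3 of codon i (fourfold),
  pos 1 of codon i+1 (twofold)]; variable at artificial positions 2 and 3,
  the analogue of within-codon doubles at positions {2,3}.
* ``NM1_312`` - [pos 3 of codon i (fourfold), pos 1 of codon i+1 (twofold),
  pos 2 of codon i+1 (invariant)]; variable at artificial positions 1 and 2,
  the analogue of positions {1,2}.
* ``NM2`` - [pos 3 of codon i (fourfold), pos 1 of codon i+1 (invariant),
  pos 3 of codon i+1 (fourfold)]; variable at artificial positions 1 and 3,
  the analogue of positions {1,3}.  (The two genomic sites are 3 bp apart
  whereas codon positions 1 and 3 are 2 bp apart; the configuration follows
  the published design.)

A context qualifies when the ancestral codon i has a fourfold-degenerate
third position and the ancestral codon i+1 is, for NM1, one of the eight
Leu/Arg codons with a degenerate first position (these all carry a purine
third position) or, for NM2, another fourfold-third codon.  On a given
branch the window is used only if its invariant site did not change.
Fourfold-slot changes are synonymous by construction; twofold-slot changes
are synonymous only within the Leu (C<->T) or Arg (C<->A) family of the
ancestral codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .genetic_code import (
    BASES,
    BASE_INDEX,
    CODON_BASE,
    CodonChange,
    IS_FOURFOLD3,
    IS_TWOFOLD1,
    TWOFOLD1_PARTNER,
)
from .parsimony import DatasetInference


class NullConfig(str, Enum):
    NM1_231 = "NM1_231"
    NM1_312 = "NM1_312"
    NM2 = "NM2"


#: ordered base changes with a synonymous analogue at a twofold first position
TWOFOLD_COMPATIBLE = frozenset({("C", "A"), ("A", "C"), ("C", "T"), ("T", "C")})

#: which null configuration matches each within-codon position pair
CONFIG_FOR_PAIR = {(2, 3): NullConfig.NM1_231, (1, 2): NullConfig.NM1_312, (1, 3): NullConfig.NM2}


@dataclass(frozen=True)
class NullSignature:
    """(configuration, ordered base change at each variable slot).

    ``change_a`` is the fourfold slot (position 3 of codon i) for every
    configuration; ``change_b`` is the twofold slot for NM1 and the second
    fourfold slot for NM2.
    """

    config: NullConfig
    change_a: tuple[str, str]
    change_b: tuple[str, str]

    def __post_init__(self):
        for x, y in (self.change_a, self.change_b):
            if x not in BASE_INDEX or y not in BASE_INDEX or x == y:
                raise ValueError(f"invalid base change {x}->{y}")
        if self.config in (NullConfig.NM1_231, NullConfig.NM1_312) and self.change_b not in TWOFOLD_COMPATIBLE:
            raise ValueError(f"twofold slot change {self.change_b} has no synonymous analogue")

    def __str__(self) -> str:
        return f"{self.config.value}[{self.change_a[0]}>{self.change_a[1]},{self.change_b[0]}>{self.change_b[1]}]"


def match_null(change: CodonChange, orientation: str = "positional") -> NullSignature | None:
    """The null signature matched to a codon double substitution, if any.

    Matching is by position pair and identical ordered base changes at the
    corresponding variable slots.  ``orientation`` controls the slot mapping
    for {1,2} doubles: ``"positional"`` (default) aligns the fourfold slot
    with codon position 1 and the twofold slot with position 2, following
    artificial-codon position order; ``"mirrored"`` swaps them.  {2,3} and
    {1,2} doubles are unmatchable when the change falling on the twofold
    slot is not one of C<->A / C<->T.
    """
    if change.n_changed != 2:
        raise ValueError(f"not a double substitution: {change}")
    if orientation not in ("positional", "mirrored"):
        raise ValueError(f"unknown orientation: {orientation}")
    pair = tuple(sorted(change.positions))
    config = CONFIG_FOR_PAIR[pair]
    lo, hi = pair
    ch_lo = (change.ancestral[lo - 1], change.final[lo - 1])
    ch_hi = (change.ancestral[hi - 1], change.final[hi - 1])
    if config is NullConfig.NM2:
        return NullSignature(config, ch_lo, ch_hi)
    if config is NullConfig.NM1_312 and orientation == "mirrored":
        ch_a, ch_b = ch_hi, ch_lo
    else:
        ch_a, ch_b = ch_lo, ch_hi
    if ch_b not in TWOFOLD_COMPATIBLE:
        return None
    return NullSignature(config, ch_a, ch_b)


@dataclass
class NullTally:
    """Single/double synonymous substitution counts per null signature.

    Counts are held as dense arrays indexed by base ids: ``doubles[x,y,u,v]``
    for simultaneous changes x->y (slot a) and u->v (slot b);
    ``singles_a[x,y,u]`` for x->y alone with slot b ancestrally ``u`` and
    unchanged; ``singles_b[x,u,v]`` symmetrically; ``contexts[x,u]`` for the
    number of branch-contexts with that ancestral slot pair.
    """

    doubles: dict = field(default_factory=dict)
    singles_a: dict = field(default_factory=dict)  # NM1: [x, y, u, partner]; NM2: [x, y, u]
    singles_b: dict = field(default_factory=dict)
    contexts: dict = field(default_factory=dict)  # NM1: [x, u, partner]; NM2: [x, u]

    def __post_init__(self):
        for cfg in NullConfig:
            nm1 = cfg is not NullConfig.NM2
            self.doubles.setdefault(cfg, np.zeros((4, 4, 4, 4), dtype=np.int64))
            self.singles_a.setdefault(cfg, np.zeros((4, 4, 4, 4) if nm1 else (4, 4, 4), dtype=np.int64))
            self.singles_b.setdefault(cfg, np.zeros((4, 4, 4), dtype=np.int64))
            self.contexts.setdefault(cfg, np.zeros((4, 4, 4) if nm1 else (4, 4), dtype=np.int64))

    def counts(self, sig: NullSignature) -> tuple[int, int, int, int]:
        """(b, a1, a2, n_contexts) for one signature.

        For NM1, slot-a singles and context counts are conditioned on the
        amino-acid family of the twofold codon (identified by the
        signature's synonymous derived base v), so that the singles come
        from exactly the contexts in which the signature's doubles can
        occur: a C at the twofold slot belongs to Leu (partner T) or Arg
        (partner A) contexts, which are not interchangeable.
        """
        x, y = (BASE_INDEX[c] for c in sig.change_a)
        u, v = (BASE_INDEX[c] for c in sig.change_b)
        cfg = sig.config
        if cfg is NullConfig.NM2:
            a1 = int(self.singles_a[cfg][x, y, u])
            n = int(self.contexts[cfg][x, u])
        else:
            a1 = int(self.singles_a[cfg][x, y, u, v])
            n = int(self.contexts[cfg][x, u, v])
        return (int(self.doubles[cfg][x, y, u, v]), a1, int(self.singles_b[cfg][x, u, v]), n)

    def signatures(self, configs=None):
        """All signatures with at least one tallied event, in a fixed order."""
        configs = list(NullConfig) if configs is None else [NullConfig(c) for c in configs]
        out = []
        for cfg in configs:
            for x in range(4):
                for y in range(4):
                    if x == y:
                        continue
                    for u in range(4):
                        for v in range(4):
                            if u == v:
                                continue
                            if cfg is not NullConfig.NM2 and (BASES[u], BASES[v]) not in TWOFOLD_COMPATIBLE:
                                continue
                            sig = NullSignature(cfg, (BASES[x], BASES[y]), (BASES[u], BASES[v]))
                            b, a1, a2, n = self.counts(sig)
                            if b + a1 + a2 > 0 or n > 0:
                                out.append(sig)
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NullTally":
        """Rebuild a tally from its TSV representation (inverse of to_frame)."""
        tally = cls()
        for row in df.itertuples():
            cfg = NullConfig(row.config)
            x, y = (BASE_INDEX[c] for c in row.change_a.split(">"))
            u, v = (BASE_INDEX[c] for c in row.change_b.split(">"))
            tally.doubles[cfg][x, y, u, v] = row.b
            tally.singles_b[cfg][x, u, v] = row.a2
            if cfg is NullConfig.NM2:
                tally.singles_a[cfg][x, y, u] = row.a1
                tally.contexts[cfg][x, u] = max(tally.contexts[cfg][x, u], row.n_contexts)
            else:
                tally.singles_a[cfg][x, y, u, v] = row.a1
                tally.contexts[cfg][x, u, v] = max(tally.contexts[cfg][x, u, v], row.n_contexts)
        return tally

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sig in self.signatures():
            b, a1, a2, n = self.counts(sig)
            total = b + a1 + a2
            rows.append(
                {
                    "config": sig.config.value,
                    "change_a": f"{sig.change_a[0]}>{sig.change_a[1]}",
                    "change_b": f"{sig.change_b[0]}>{sig.change_b[1]}",
                    "b": b,
                    "a1": a1,
                    "a2": a2,
                    "DF": b / total if total else float("nan"),
                    "n_contexts": n,
                }
            )
        return pd.DataFrame(rows, columns=["config", "change_a", "change_b", "b", "a1", "a2", "DF", "n_contexts"])


def scan_null_contexts(ds: DatasetInference) -> pd.DataFrame:
    """Qualifying adjacent-codon contexts, judged on ancestral states.

    One row per adjacent polarized codon pair that qualifies for at least
    one configuration.  NM1 qualification covers both the 231 and 312
    framings of the same physical sites.
    """
    anc = ds.anc
    ok = (anc[:-1] >= 0) & (anc[1:] >= 0)
    i = np.flatnonzero(ok)
    ai = anc[i]
    aj = anc[i + 1]
    nm1 = IS_FOURFOLD3[ai] & IS_TWOFOLD1[aj]
    nm2 = IS_FOURFOLD3[ai] & IS_FOURFOLD3[aj]
    keep = nm1 | nm2
    from .genetic_code import CODONS

    return pd.DataFrame(
        {
            "gene_id": [ds.gene_ids[g] for g in ds.gene_of_site[i[keep]]],
            "codon_index": ds.codon_index_of_site[i[keep]],
            "ancestral_i": [CODONS[c] for c in ai[keep]],
            "ancestral_j": [CODONS[c] for c in aj[keep]],
            "nm1": nm1[keep],
            "nm2": nm2[keep],
        }
    )


def tally_null_events(ds: DatasetInference) -> NullTally:
    """Tally single and double synonymous events over all null contexts.

    Scans every adjacent polarized codon pair on both ingroup branches.  A
    double is counted when both variable slots changed synonymously on the
    branch; a single when exactly one did and the other slot is unchanged;
    windows whose invariant site changed, and nonsynonymous twofold-slot
    changes, contribute nothing.
    """
    tally = NullTally()
    anc = ds.anc
    ok = (anc[:-1] >= 0) & (anc[1:] >= 0)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return tally
    ai = anc[idx].astype(np.int64)
    aj = anc[idx + 1].astype(np.int64)
    nm1 = IS_FOURFOLD3[ai] & IS_TWOFOLD1[aj]
    nm2 = IS_FOURFOLD3[ai] & IS_FOURFOLD3[aj]

    B = CODON_BASE.astype(np.int64)
    for der, other in ((ds.der1, ds.der2), (ds.der2, ds.der1)):
        di = der[idx].astype(np.int64)
        dj = der[idx + 1].astype(np.int64)
        # Use a window on a branch only when the sister branch left both
        # codons unchanged.  A window double requires both codons to stay
        # polarizable against the sister branch and outgroup, whereas a
        # window single would otherwise also be counted when the sister
        # branch changed the partner codon; that asymmetry deflates null
        # DF at appreciable divergence.  Conditioning both singles and
        # doubles on a clean sister branch makes the parsimony survival
        # factors identical for every tallied quantity, mirroring the
        # within-codon tallies where they cancel trivially.
        sister_clean = (other[idx] == ai) & (other[idx + 1] == aj)
        x, y = B[ai, 2], B[di, 2]
        changed_a = x != y
        # NM1 slot b: first position of codon i+1
        u1, v1 = B[aj, 0], B[dj, 0]
        changed_b1 = u1 != v1
        syn_b1 = v1 == TWOFOLD1_PARTNER[aj]
        # NM2 slot b: third position of codon i+1
        u2, v2 = B[aj, 2], B[dj, 2]
        changed_b2 = u2 != v2

        partner = TWOFOLD1_PARTNER[aj].astype(np.int64)  # synonymous pos-1 alternative of codon i+1
        specs = (
            (NullConfig.NM1_231, nm1 & sister_clean & (B[ai, 1] == B[di, 1]), u1, v1, changed_b1, syn_b1),
            (NullConfig.NM1_312, nm1 & sister_clean & (B[aj, 1] == B[dj, 1]), u1, v1, changed_b1, syn_b1),
            (NullConfig.NM2, nm2 & sister_clean & (B[aj, 0] == B[dj, 0]), u2, v2, changed_b2, np.True_),
        )
        for cfg, active, u, v, changed_b, syn_b in specs:
            nm1_cfg = cfg is not NullConfig.NM2
            dbl = active & changed_a & changed_b & syn_b
            sa = active & changed_a & ~changed_b
            sb = active & ~changed_a & changed_b & syn_b
            if dbl.any():
                keys = ((x[dbl] * 4 + y[dbl]) * 4 + u[dbl]) * 4 + v[dbl]
                tally.doubles[cfg] += np.bincount(keys, minlength=256).reshape(4, 4, 4, 4)
            if sa.any():
                if nm1_cfg:
                    keys = ((x[sa] * 4 + y[sa]) * 4 + u[sa]) * 4 + partner[sa]
                    tally.singles_a[cfg] += np.bincount(keys, minlength=256).reshape(4, 4, 4, 4)
                else:
                    keys = (x[sa] * 4 + y[sa]) * 4 + u[sa]
                    tally.singles_a[cfg] += np.bincount(keys, minlength=64).reshape(4, 4, 4)
            if sb.any():
                keys = (x[sb] * 4 + u[sb]) * 4 + v[sb]
                tally.singles_b[cfg] += np.bincount(keys, minlength=64).reshape(4, 4, 4)
            if active.any():
                if nm1_cfg:
                    keys = (x[active] * 4 + u[active]) * 4 + partner[active]
                    tally.contexts[cfg] += np.bincount(keys, minlength=64).reshape(4, 4, 4)
                else:
                    keys = x[active] * 4 + u[active]
                    tally.contexts[cfg] += np.bincount(keys, minlength=16).reshape(4, 4)
    return tally
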