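"""Standard genetic code queries and enumeration of codon double substitutions.

All codon arithmetic in the package runs through this module.  Codons are
uppercase DNA strings over {A, C, G, T}; positions are 1-based.  Internally
codons are also handled as integer ids in ``range(64)`` (``16*b1 + 4*b2 + b3``
with A=0, C=1, G=2, T=3), and several numpy lookup tables are exported for the
vectorized pipeline stages.

Only the standard nuclear code is supported: the organisms this analysis is
aimed at (primates, *Saccharomyces* nuclear genes) all use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STOP_SYMBOL = "*"

#: transition partner of each base (A<->G, C<->T)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

_standard = CodonTable.unambiguous_dna_by_id[1]

#: all 64 codons in lexicographic order
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

#: codon -> amino acid one-letter symbol, stops mapped to ``STOP_SYMBOL``
CODON_TO_AA = {c: (STOP_SYMBOL if c in _standard.stop_codons else _standard.forward_table[c]) for c in CODONS}

STOP_CODONS = frozenset(_standard.stop_codons)
SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)


class CodonError(ValueError):
    """Raised for malformed codon input (wrong length or non-ACGT character)."""


class StopCodonError(ValueError):
    """Raised when a stop codon reaches an operation defined on sense codons only."""


def _check_codon(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3 or any(ch not in BASE_INDEX for ch in codon):
        raise CodonError(f"malformed codon: {codon!r}")
    return codon


def codon_id(codon: str) -> int:
    """Integer id of a codon (lexicographic rank, base-4 over A,C,G,T)."""
    _check_codon(codon)
    return 16 * BASE_INDEX[codon[0]] + 4 * BASE_INDEX[codon[1]] + BASE_INDEX[codon[2]]


def id_to_codon(cid: int) -> str:
    return CODONS[cid]


def translate(codon: str) -> str:
    """Translate a codon under the standard code; stops give ``'*'``."""
    return CODON_TO_AA[_check_codon(codon)]


def is_stop(codon: str) -> bool:
    return _check_codon(codon) in STOP_CODONS


def is_synonymous(c1: str, c2: str) -> bool:
    """True iff two sense codons encode the same amino acid.

    Stop codons are not comparable under the synonymy classification used
    here; passing one raises :class:`StopCodonError` so that callers apply
    their stop-exclusion rules explicitly.
    """
    a1, a2 = translate(c1), translate(c2)
    if a1 == STOP_SYMBOL or a2 == STOP_SYMBOL:
        raise StopCodonError(f"synonymy undefined for stop codon: {c1} vs {c2}")
    return a1 == a2


def is_fourfold_third_position(codon: str) -> bool:
    """True iff every third-position variant of the codon is synonymous.

    Exactly the 8 fourfold families qualify: Leu CTN, Val GTN, Ser TCN,
    Pro CCN, Thr ACN, Ala GCN, Arg CGN, Gly GGN.
    """
    if is_stop(codon):
        raise StopCodonError(f"stop codon: {codon}")
    aa = translate(codon)
    return all(CODON_TO_AA[codon[:2] + b] == aa for b in BASES)


# The two amino acids with a degenerate first position: Leu (CTR ~ TTR, C<->T)
# and Arg (CGR ~ AGR, C<->A).  All eight codons carry a purine third position.
TWOFOLD_FIRST_CODONS = frozenset({"CTA", "CTG", "TTA", "TTG", "CGA", "CGG", "AGA", "AGG"})


def is_twofold_first_position(codon: str) -> bool:
    """True iff the codon has a synonymous first-position alternative.

    Only Leu and Arg codons with a purine at position 3 qualify; for Leu the
    synonymous first-position swap is C<->T, for Arg it is C<->A.
    """
    if is_stop(codon):
        raise StopCodonError(f"stop codon: {codon}")
    return codon in TWOFOLD_FIRST_CODONS


def synonymous_first_position_partner(codon: str) -> str | None:
    """The base that replaces position 1 synonymously, or None."""
    if codon not in TWOFOLD_FIRST_CODONS:
        return None
    return {"C": "T", "T": "C"}[codon[0]] if translate(codon) == "L" else {"C": "A", "A": "C"}[codon[0]]


@dataclass(frozen=True)
class CodonChange:
    """An ancestral -> final codon pair with its set of changed positions.

    ``positions`` is always derived from the two codons (1-based indices
    where they differ); it is stored for convenience and validated on
    construction.
    """

    ancestral: str
    final: str
    positions: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        _check_codon(self.ancestral)
        _check_codon(self.final)
        diff = frozenset(i + 1 for i in range(3) if self.ancestral[i] != self.final[i])
        if self.positions is None:
            object.__setattr__(self, "positions", diff)
        elif frozenset(self.positions) != diff:
            raise ValueError(f"positions {set(self.positions)} inconsistent with {self.ancestral}->{self.final}")
        else:
            object.__setattr__(self, "positions", diff)

    @property
    def n_changed(self) -> int:
        return len(self.positions)

    def __str__(self) -> str:  # e.g. "AAA->GGA"
        return f"{self.ancestral}->{self.final}"


@lru_cache(maxsize=1)
def enumerate_double_substitutions() -> tuple:
    """Every codon double substitution with a sense ancestral codon.

    Returns a deterministic lexicographically ordered tuple of
    :class:`CodonChange` (ordered by ancestral codon, then final codon).
    Final codons may be stops; callers filter.  61 sense ancestors x 27
    two-position variants = 1647 entries.
    """
    out = []
    for anc in SENSE_CODONS:
        for fin in CODONS:
            if sum(a != b for a, b in zip(anc, fin)) == 2:
                out.append(CodonChange(anc, fin))
    return tuple(out)


# ---------------------------------------------------------------------------
# numpy lookup tables for the vectorized pipeline
# ---------------------------------------------------------------------------

#: amino-acid code per codon id; stops are 20, sense codons 0..19
AA_CODES = "ACDEFGHIKLMNPQRSTVWY" + STOP_SYMBOL
CODON_AA = np.array([AA_CODES.index(CODON_TO_AA[c]) for c in CODONS], dtype=np.int8)
IS_STOP = np.array([c in STOP_CODONS for c in CODONS], dtype=bool)
IS_FOURFOLD3 = np.array([(not IS_STOP[i]) and is_fourfold_third_position(CODONS[i]) for i in range(64)], dtype=bool)
IS_TWOFOLD1 = np.array([CODONS[i] in TWOFOLD_FIRST_CODONS for i in range(64)], dtype=bool)

#: base id at each codon position, per codon id
CODON_BASE = np.array([[BASE_INDEX[c[p]] for p in range(3)] for c in CODONS], dtype=np.int8)

#: for twofold-first codons: the base id that substitutes position 1 synonymously, else -1
TWOFOLD1_PARTNER = np.array(
    [BASE_INDEX[synonymous_first_position_partner(c)] if c in TWOFOLD_FIRST_CODONS else -1 for c in CODONS],
    dtype=np.int8,
)
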