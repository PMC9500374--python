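"""Path-synonymy classification of codon double substitutions.

A double substitution X -> Y (two changed positions in one codon) can be
realised through two single-step paths, each visiting one intermediate codon.
Each change is classified by the synonymy of its intermediates and of the
final codon relative to the ancestral one:

* ``SS`` - both intermediates and the final codon synonymous;
* ``NS`` - final synonymous, at least one intermediate nonsynonymous;
* ``SN`` - final nonsynonymous, at least one intermediate synonymous;
* ``NN`` - final and both intermediates nonsynonymous.

Changes whose final codon is a stop, or whose paths pass through a stop,
are excluded from the analysis (labelled ``EXCLUDED_STOP_FINAL`` /
``EXCLUDED_STOP_INTERMEDIATE``; the final-stop test takes precedence).
"""

from __future__ import annotations

from enum import Enum
from functools import lru_cache

import pandas as pd

from .genetic_code import (
    CodonChange,
    enumerate_double_substitutions,
    is_stop,
    is_synonymous,
)


class PathClass(str, Enum):
    SS = "SS"
    SN = "SN"
    NS = "NS"
    NN = "NN"
    EXCLUDED_STOP_FINAL = "EXCLUDED_STOP_FINAL"
    EXCLUDED_STOP_INTERMEDIATE = "EXCLUDED_STOP_INTERMEDIATE"


#: the four classes that enter selection comparisons
ANALYSIS_CLASSES = (PathClass.SS, PathClass.SN, PathClass.NS, PathClass.NN)


def intermediates(change: CodonChange) -> tuple[str, str]:
    """The two single-step intermediate codons of a double substitution.

    The first intermediate applies the change at the smaller codon position,
    the second applies the change at the larger one.
    """
    if change.n_changed != 2:
        raise ValueError(f"not a double substitution: {change}")
    p_lo, p_hi = sorted(change.positions)
    anc, fin = change.ancestral, change.final
    first = anc[: p_lo - 1] + fin[p_lo - 1] + anc[p_lo:]
    second = anc[: p_hi - 1] + fin[p_hi - 1] + anc[p_hi:]
    return first, second


def classify_double(change: CodonChange) -> PathClass:
    """Assign a double substitution to its path-synonymy class."""
    if is_stop(change.ancestral):
        raise ValueError(f"ancestral codon is a stop: {change}")
    if change.n_changed != 2:
        raise ValueError(f"not a double substitution: {change}")
    if is_stop(change.final):
        return PathClass.EXCLUDED_STOP_FINAL
    i1, i2 = intermediates(change)
    if is_stop(i1) or is_stop(i2):
        return PathClass.EXCLUDED_STOP_INTERMEDIATE
    final_syn = is_synonymous(change.ancestral, change.final)
    syn1 = is_synonymous(change.ancestral, i1)
    syn2 = is_synonymous(change.ancestral, i2)
    if final_syn:
        return PathClass.SS if (syn1 and syn2) else PathClass.NS
    return PathClass.SN if (syn1 or syn2) else PathClass.NN


@lru_cache(maxsize=1)
def classification_table() -> pd.DataFrame:
    """The full combinatorial classification of all 1647 double substitutions.

    Columns: ancestral, final, positions (e.g. ``"1,3"``), intermediate1,
    intermediate2, label.  Deterministic lexicographic order.
    """
    rows = []
    for change in enumerate_double_substitutions():
        i1, i2 = intermediates(change)
        rows.append(
            {
                "ancestral": change.ancestral,
                "final": change.final,
                "positions": ",".join(str(p) for p in sorted(change.positions)),
                "intermediate1": i1,
                "intermediate2": i2,
                "label": classify_double(change).value,
            }
        )
    return pd.DataFrame(rows)


def write_classification_table(path) -> pd.DataFrame:
    table = classification_table()
    table.to_csv(path, sep="\t", index=False)
    return table
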