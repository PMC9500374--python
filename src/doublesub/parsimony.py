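"""Parsimony inference of per-branch substitution events from species triplets.

The unit of data is a codon-aware alignment of three sequences: two ingroups
and one outgroup, related as ``((in1, in2), out)``.  Under the parsimony
principle (no more than one mutation per position), a codon site where the
outgroup agrees with one ingroup polarizes the site: the shared codon is the
ancestral state and the other ingroup carries a substitution on its terminal
branch.  Codon sites where both ingroups differ from the outgroup, or where
all three codons differ, cannot be polarized and are skipped, as are codon
columns containing gaps or ambiguity characters, and events whose ancestral
or derived codon is a stop.

Events are inferred at codon granularity: all three positions are compared
jointly, so a double substitution is a single event with two changed
positions on one branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import BASE_INDEX, CODONS, IS_STOP, STOP_CODONS

BRANCHES = ("in1", "in2")

_CHAR_TO_CODE = np.full(256, 5, dtype=np.int8)  # 5 = other/ambiguity
for _b, _i in BASE_INDEX.items():
    _CHAR_TO_CODE[ord(_b)] = _i
    _CHAR_TO_CODE[ord(_b.lower())] = _i
_CHAR_TO_CODE[ord("-")] = 4  # gap


def encode_sequence(seq: str) -> np.ndarray:
    """DNA string -> int8 codes (A,C,G,T -> 0..3; gap -> 4; other -> 5)."""
    return _CHAR_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT-N", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


@dataclass
class TripletAlignment:
    """A codon-aware alignment of (in1, in2, out) for one gene."""

    gene_id: str
    seq_in1: str
    seq_in2: str
    seq_out: str

    def __post_init__(self):
        n = len(self.seq_in1)
        if len(self.seq_in2) != n or len(self.seq_out) != n:
            raise ValueError(f"{self.gene_id}: sequences have unequal lengths")
        self.seq_in1 = self.seq_in1.upper()
        self.seq_in2 = self.seq_in2.upper()
        self.seq_out = self.seq_out.upper()

    def __len__(self) -> int:
        return len(self.seq_in1)

    def codon_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Encoded (n_codons, 3) arrays for in1, in2 and out."""
        if len(self) % 3 != 0:
            raise ValueError(f"{self.gene_id}: alignment length {len(self)} is not a multiple of 3")
        return tuple(encode_sequence(s).reshape(-1, 3) for s in (self.seq_in1, self.seq_in2, self.seq_out))


@dataclass(frozen=True)
class SubstitutionEvent:
    """One inferred substitution at one codon site on one ingroup branch."""

    gene_id: str
    codon_index: int  # 1-based
    branch: str  # "in1" | "in2"
    ancestral: str
    derived: str
    positions: frozenset

    def __post_init__(self):
        if self.ancestral == self.derived:
            raise ValueError("ancestral == derived")


@dataclass(frozen=True)
class SiteInference:
    """Outcome of the five-way parsimony case analysis at one codon site.

    ``ancestral`` is the polarized ancestral codon (None when the site cannot
    be polarized); ``counted`` says whether the site contributes two
    branch-contexts to the ancestral tally (identity sites and sense-codon
    event sites do; gap/ambiguity, unpolarizable and stop-involved sites do
    not).
    """

    event: tuple | None  # (branch, ancestral, derived) or None
    ancestral: str | None
    derived_in1: str | None
    derived_in2: str | None
    counted: bool


def infer_site_events(c_in1: str, c_in2: str, c_out: str) -> SiteInference:
    """Scalar reference implementation of the per-site case analysis."""
    for c in (c_in1, c_in2, c_out):
        if len(c) != 3:
            raise ValueError(f"not a codon: {c!r}")
    if any(ch not in BASE_INDEX for c in (c_in1, c_in2, c_out) for ch in c):
        return SiteInference(None, None, None, None, False)

    skipped = SiteInference(None, None, None, None, False)
    if c_in1 == c_in2:
        if c_in1 == c_out:  # identity
            counted = c_out not in _STOP_SET
            return SiteInference(None, c_out, c_out, c_out, counted)
        return skipped  # change on the internal/outgroup lineage: polarity ambiguous
    if c_in2 == c_out:  # event on in1
        ok = c_out not in _STOP_SET and c_in1 not in _STOP_SET
        return SiteInference(("in1", c_out, c_in1) if ok else None, c_out, c_in1, c_out, ok)
    if c_in1 == c_out:  # event on in2
        ok = c_out not in _STOP_SET and c_in2 not in _STOP_SET
        return SiteInference(("in2", c_out, c_in2) if ok else None, c_out, c_out, c_in2, ok)
    return skipped  # all three differ


_STOP_SET = STOP_CODONS


@dataclass
class DatasetInference:
    """Vectorized inference output for one or many genes.

    Site-indexed arrays are concatenated over genes with a ``-1`` ancestral
    sentinel separating genes, so adjacent-pair scans never cross a gene
    boundary.  ``events`` has columns gene_id, codon_index, branch,
    ancestral, derived, n_changed, positions.
    """

    events: pd.DataFrame
    ancestral_tally: np.ndarray  # shape (64,), counts of branch-contexts
    anc: np.ndarray  # polarized ancestral codon id per site, -1 when unpolarized
    der1: np.ndarray  # derived codon id on branch in1 (== anc when unchanged)
    der2: np.ndarray
    gene_of_site: np.ndarray  # index into gene_ids, -1 at sentinels
    codon_index_of_site: np.ndarray  # 1-based within-gene codon index, 0 at sentinels
    gene_ids: list = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


def _infer_arrays(m1: np.ndarray, m2: np.ndarray, mo: np.ndarray):
    """Vectorized five-way case analysis on (n, 3) encoded codon matrices."""
    valid = (m1 < 4).all(axis=1) & (m2 < 4).all(axis=1) & (mo < 4).all(axis=1)
    # codon ids are only meaningful on valid rows; clip to keep indexing safe
    w = np.array([16, 4, 1], dtype=np.int16)
    c1 = np.clip(m1, 0, 3).astype(np.int16) @ w
    c2 = np.clip(m2, 0, 3).astype(np.int16) @ w
    co = np.clip(mo, 0, 3).astype(np.int16) @ w

    eq12 = c1 == c2
    identity = valid & eq12 & (c1 == co)
    ev1 = valid & ~eq12 & (c2 == co)
    ev2 = valid & ~eq12 & (c1 == co)

    polarized = identity | ev1 | ev2
    anc = np.where(polarized, co, -1).astype(np.int16)
    der1 = np.where(ev1, c1, anc).astype(np.int16)
    der2 = np.where(ev2, c2, anc).astype(np.int16)

    stop_free = polarized & ~IS_STOP[np.clip(anc, 0, 63)]
    stop_free &= ~IS_STOP[np.clip(der1, 0, 63)] & ~IS_STOP[np.clip(der2, 0, 63)]
    counted = stop_free  # identity or sense-event sites
    ev1 &= stop_free
    ev2 &= stop_free
    return anc, der1, der2, ev1, ev2, counted


def _events_frame(gene_ids, gene_of_site, site_codon_index, anc, der, which, branch):
    idx = np.flatnonzero(which)
    if idx.size == 0:
        return pd.DataFrame(
            columns=["gene_id", "codon_index", "branch", "ancestral", "derived", "n_changed", "positions"]
        )
    a = anc[idx]
    d = der[idx]
    codon_arr = np.array(CODONS)
    anc_s = codon_arr[a]
    der_s = codon_arr[d]
    diff = np.array([[(ai // 16) != (di // 16), (ai // 4) % 4 != (di // 4) % 4, ai % 4 != di % 4] for ai, di in zip(a, d)])
    n_changed = diff.sum(axis=1)
    positions = [",".join(str(p + 1) for p in np.flatnonzero(row)) for row in diff]
    return pd.DataFrame(
        {
            "gene_id": [gene_ids[g] for g in gene_of_site[idx]],
            "codon_index": site_codon_index[idx],
            "branch": branch,
            "ancestral": anc_s,
            "derived": der_s,
            "n_changed": n_changed,
            "positions": positions,
        }
    )


def infer_dataset(alignments) -> DatasetInference:
    """Run parsimony inference over an iterable of :class:`TripletAlignment`."""
    anc_parts, der1_parts, der2_parts, gene_parts, cidx_parts = [], [], [], [], []
    ev1_parts, ev2_parts, counted_parts = [], [], []
    gene_ids = []
    sentinel = np.array([-1], dtype=np.int16)
    sentinel_gene = np.array([-1], dtype=np.int32)
    for aln in alignments:
        g = len(gene_ids)
        gene_ids.append(aln.gene_id)
        m1, m2, mo = aln.codon_matrices()
        anc, der1, der2, ev1, ev2, counted = _infer_arrays(m1, m2, mo)
        n = anc.size
        anc_parts += [anc, sentinel]
        der1_parts += [der1, sentinel]
        der2_parts += [der2, sentinel]
        gene_parts += [np.full(n, g, dtype=np.int32), sentinel_gene]
        cidx_parts += [np.arange(1, n + 1, dtype=np.int32), np.array([0], dtype=np.int32)]
        f = np.array([False])
        ev1_parts += [ev1, f]
        ev2_parts += [ev2, f]
        counted_parts += [counted, f]

    anc = np.concatenate(anc_parts) if anc_parts else np.empty(0, dtype=np.int16)
    der1 = np.concatenate(der1_parts) if der1_parts else np.empty(0, dtype=np.int16)
    der2 = np.concatenate(der2_parts) if der2_parts else np.empty(0, dtype=np.int16)
    gene_of_site = np.concatenate(gene_parts) if gene_parts else np.empty(0, dtype=np.int32)
    cidx = np.concatenate(cidx_parts) if cidx_parts else np.empty(0, dtype=np.int32)
    ev1 = np.concatenate(ev1_parts) if ev1_parts else np.empty(0, dtype=bool)
    ev2 = np.concatenate(ev2_parts) if ev2_parts else np.empty(0, dtype=bool)
    counted = np.concatenate(counted_parts) if counted_parts else np.empty(0, dtype=bool)

    tally = np.zeros(64, dtype=np.int64)
    if counted.any():
        tally += 2 * np.bincount(anc[counted], minlength=64)[:64]

    events = pd.concat(
        [
            _events_frame(gene_ids, gene_of_site, cidx, anc, der1, ev1, "in1"),
            _events_frame(gene_ids, gene_of_site, cidx, anc, der2, ev2, "in2"),
        ],
        ignore_index=True,
    )
    events = events.sort_values(["gene_id", "codon_index", "branch"], kind="stable").reset_index(drop=True)
    return DatasetInference(events, tally, anc, der1, der2, gene_of_site, cidx, gene_ids)


def infer_gene_events(aln: TripletAlignment):
    """Events and ancestral tally for a single gene.

    Returns ``(events, tally)`` where ``events`` is a list of
    :class:`SubstitutionEvent` and ``tally`` maps codon string -> count of
    ancestral branch-contexts.
    """
    ds = infer_dataset([aln])
    events = [
        SubstitutionEvent(
            gene_id=row.gene_id,
            codon_index=int(row.codon_index),
            branch=row.branch,
            ancestral=row.ancestral,
            derived=row.derived,
            positions=frozenset(int(p) for p in row.positions.split(",")),
        )
        for row in ds.events.itertuples()
    ]
    tally = {CODONS[i]: int(n) for i, n in enumerate(ds.ancestral_tally) if n}
    return events, tally


def codon_substitution_counts(events: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(64,64) count matrices of single and double substitution events."""
    singles = np.zeros((64, 64), dtype=np.int64)
    doubles = np.zeros((64, 64), dtype=np.int64)
    if len(events):
        codon_rank = {c: i for i, c in enumerate(CODONS)}
        a = events["ancestral"].map(codon_rank).to_numpy()
        d = events["derived"].map(codon_rank).to_numpy()
        n = events["n_changed"].to_numpy()
        for mat, k in ((singles, 1), (doubles, 2)):
            sel = n == k
            if sel.any():
                np.add.at(mat, (a[sel], d[sel]), 1)
    return singles, doubles
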