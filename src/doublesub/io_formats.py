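"""Readers and writers for on-disk artifacts, plus input QC.

On-disk formats are plain text: aligned FASTA per gene (three records),
tab-separated tables with header rows ('.' decimal, UTF-8), and a YAML run
config.  The gene manifest maps sequence record IDs to the three tree roles
(two ingroups, one outgroup).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import BASE_INDEX
from .parsimony import TripletAlignment

MANIFEST_COLUMNS = ["gene_id", "file", "id_in1", "id_in2", "id_out"]


class FormatError(ValueError):
    """Malformed input file (missing records, unequal lengths, bad manifest)."""


def read_triplet_fasta(path, id_in1: str, id_in2: str, id_out: str, gene_id: str | None = None) -> TripletAlignment:
    """Load one gene's aligned FASTA and assign the three tree roles."""
    path = Path(path)
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise FormatError(f"{path}: empty or unparseable FASTA")
    for role, rid in (("in1", id_in1), ("in2", id_in2), ("out", id_out)):
        if rid not in records:
            raise FormatError(f"{path}: record {rid!r} (role {role}) not found")
    seqs = [records[id_in1], records[id_in2], records[id_out]]
    if len({len(s) for s in seqs}) != 1:
        raise FormatError(f"{path}: records have unequal aligned lengths")
    return TripletAlignment(gene_id or path.stem, *seqs)


def write_triplet_fasta(path, aln: TripletAlignment, ids=("in1", "in2", "out")) -> None:
    records = [
        SeqRecord(Seq(seq), id=rid, description="")
        for rid, seq in zip(ids, (aln.seq_in1, aln.seq_in2, aln.seq_out))
    ]
    SeqIO.write(records, str(path), "fasta")


def read_manifest(path) -> pd.DataFrame:
    """Read the gene manifest TSV and check uniqueness and file existence."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    base = path.parent
    for f in df["file"]:
        if not (base / f).exists():
            raise FormatError(f"{path}: alignment file {f!r} does not exist")
    return df


def write_manifest(path, rows) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def load_alignments(manifest_path):
    """Yield TripletAlignments for every manifest row (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    for row in df.itertuples():
        yield read_triplet_fasta(
            manifest_path.parent / row.file, row.id_in1, row.id_in2, row.id_out, gene_id=row.gene_id
        )


@dataclass(frozen=True)
class QCReport:
    gene_id: str
    n_codons_in: int
    n_codons_removed: int
    removed_codon_columns: tuple  # 1-based original codon column indices


def qc_frame_filter(aln: TripletAlignment) -> tuple[TripletAlignment, QCReport]:
    """Drop codon column-triples containing gaps or ambiguity characters.

    The frame is anchored at alignment column 1 (inputs are CDS alignments
    by contract).  Raises :class:`FormatError` when the alignment length is
    not a multiple of 3 or nothing survives.  Retained codon columns keep
    their relative order; the report maps removals back to original codon
    column indices.
    """
    n = len(aln)
    if n % 3 != 0:
        raise FormatError(f"{aln.gene_id}: alignment length {n} is not reducible to codon frame")
    seqs = (aln.seq_in1, aln.seq_in2, aln.seq_out)
    keep, removed = [], []
    for i in range(0, n, 3):
        ok = all(ch in BASE_INDEX for s in seqs for ch in s[i : i + 3])
        (keep if ok else removed).append(i // 3 + 1)
    if not keep:
        raise FormatError(f"{aln.gene_id}: no codon columns survive QC")
    pick = lambda s: "".join(s[3 * (c - 1) : 3 * (c - 1) + 3] for c in keep)
    filtered = TripletAlignment(aln.gene_id, *(pick(s) for s in seqs))
    return filtered, QCReport(aln.gene_id, n // 3, len(removed), tuple(removed))


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_run_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_run_config(path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return loaded
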