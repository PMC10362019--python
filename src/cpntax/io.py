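"""FASTA and tabular readers/writers shared across the toolkit."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import N_RANKS, RANKS


class DuplicateIdError(ValueError):
    """Raised when a FASTA file contains repeated sequence identifiers."""


@dataclass(frozen=True)
class FastaRecord:
    """One sequence with its identifier and optional taxon binding.

    ``taxon`` is the genus+species name used to join the record to a lineage
    table row; it defaults to everything after the id in the description, or
    the id itself.
    """

    id: str
    seq: str
    description: str = ""
    taxon: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.taxon:
            object.__setattr__(self, "taxon", self._default_taxon())

    def _default_taxon(self) -> str:
        rest = self.description[len(self.id):].strip() if self.description else ""
        return rest or self.id


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read FASTA records; duplicate ids are an error."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        records.append(
            FastaRecord(id=rec.id, seq=str(rec.seq).upper(), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=_desc_tail(r))
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def _desc_tail(rec: FastaRecord) -> str:
    if rec.description.startswith(rec.id):
        return rec.description[len(rec.id):].strip()
    return rec.description


CLASSIFICATION_HEADER = (
    ["query"]
    + [f"{r}_{k}" for r in RANKS for k in ("taxon", "confidence")]
    + ["assigned_rank", "n_words", "unclassifiable"]
)


def write_classification_tsv(classifications: Sequence, path: str | Path,
                             header_comment: str | None = None) -> None:
    """Write fixrank-style rows: one taxon + confidence per rank per query."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CLASSIFICATION_HEADER)
        for c in classifications:
            row = [c.query_id]
            for taxon, conf in zip(c.taxa, c.confidences):
                row.extend([taxon, f"{conf:.6g}"])
            row.extend([
                c.assigned_rank or "unassigned",
                str(c.n_words),
                "1" if c.unclassifiable else "0",
            ])
            w.writerow(row)


def read_classification_tsv(path: str | Path) -> list:
    from .classifier import Classification

    out = []
    with open(path) as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    header, body = rows[0], rows[1:]
    if header != CLASSIFICATION_HEADER:
        raise ValueError("unrecognized classification TSV header")
    for row in body:
        taxa = tuple(row[1 + 2 * i] for i in range(N_RANKS))
        confs = tuple(float(row[2 + 2 * i]) for i in range(N_RANKS))
        assigned = row[1 + 2 * N_RANKS]
        out.append(
            Classification(
                query_id=row[0],
                taxa=taxa,
                confidences=confs,
                n_words=int(row[2 + 2 * N_RANKS]),
                unclassifiable=row[3 + 2 * N_RANKS] == "1",
                assigned_rank=None if assigned == "unassigned" else assigned,
            )
        )
    return out


def export_q2_inputs(training_set, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the curated sequences and a semicolon-delimited taxonomy TSV.

    The two files follow the layout consumed by external feature-classifier
    plugins: a plain FASTA and ``id<TAB>sk;ph;cl;or;fa;ge;sp`` with
    placeholder ranks emitted verbatim as ``-``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "q2_sequences.fasta"
    tax_path = out_dir / "q2_taxonomy.tsv"
    write_fasta(
        [FastaRecord(id=r.seq_id, seq=r.sequence) for r in training_set.records],
        fasta_path,
    )
    with open(tax_path, "w") as fh:
        fh.write("Feature ID\tTaxon\n")
        for r in training_set.records:
            fh.write(f"{r.seq_id}\t{';'.join(r.lineage.names)}\n")
    return fasta_path, tax_path
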