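"""Training-set curation: lineage reconciliation, deduplication, truncation.

The curated product binds each unique reference sequence to a
species-resolved lineage and records how many records survived each stage
(raw -> lineage-resolved -> deduplicated), since duplicate sequences inflate
apparent performance when the training set is reused as queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .io import FastaRecord
from .taxonomy import Lineage, TaxTree, build_rank_tree, drop_unresolved_species

log = logging.getLogger(__name__)

TRUNCATION_LENGTHS = (50, 150, 300, 450, "full")


class CurationError(ValueError):
    """Raised when curation leaves nothing to train on."""


@dataclass(frozen=True)
class TrainingRecord:
    seq_id: str
    sequence: str
    lineage: Lineage


@dataclass
class TrainingSet:
    """Curated references: unique sequences, each bound to a species leaf."""

    records: list[TrainingRecord]
    tree: TaxTree
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def species_paths(self) -> list[tuple[str, ...]]:
        seen: dict[tuple[str, ...], None] = {}
        for r in self.records:
            seen.setdefault(tuple(r.lineage.names), None)
        return list(seen)


def deduplicate_sequences(
    records: Sequence[FastaRecord],
) -> tuple[list[FastaRecord], int]:
    """Drop exact sequence duplicates (case-normalized); first wins.

    Identical sequences carrying different taxon labels are still collapsed
    to the first occurrence; the event is logged since it usually signals a
    reference-database annotation conflict.
    """
    seen: dict[str, FastaRecord] = {}
    kept = []
    for rec in records:
        key = rec.seq.upper()
        prior = seen.get(key)
        if prior is None:
            seen[key] = rec
            kept.append(rec)
        elif prior.taxon != rec.taxon:
            log.warning(
                "duplicate sequence with conflicting labels: kept %s (%s), "
                "dropped %s (%s)", prior.id, prior.taxon, rec.id, rec.taxon,
            )
    return kept, len(records) - len(kept)


def reconcile(
    records: Sequence[FastaRecord],
    entries: Sequence[tuple[str, Lineage]],
) -> TrainingSet:
    """Assemble the curated TrainingSet from FASTA records and lineages.

    Records whose taxon is unresolved at species rank (or absent from the
    table) are removed along with their taxonomy rows; exact duplicate
    sequences are then collapsed.  Provenance counts each stage.
    """
    n_raw = len(records)
    resolved_entries, _removed = drop_unresolved_species(entries)
    lookup = dict(resolved_entries)
    resolved = [r for r in records if r.taxon in lookup]
    n_resolved = len(resolved)
    deduped, _n_dup = deduplicate_sequences(resolved)
    if not deduped:
        raise CurationError("no trainable records after curation")
    used_entries = [(t, l) for t, l in resolved_entries
                    if any(r.taxon == t for r in deduped)]
    tree = build_rank_tree(used_entries)
    training = [
        TrainingRecord(seq_id=r.id, sequence=r.seq.upper(), lineage=lookup[r.taxon])
        for r in deduped
    ]
    return TrainingSet(
        records=training,
        tree=tree,
        provenance={
            "raw": n_raw,
            "lineage_resolved": n_resolved,
            "deduplicated": len(deduped),
        },
    )


def truncate_5prime(obj, length):
    """Cut sequences to their first ``length`` bases (5'-anchored).

    ``length`` may be a positive integer or the string ``"full"`` (identity).
    Sequences already shorter than ``length`` are kept whole.  Works on a
    TrainingSet, a list of TrainingRecord, or a list of FastaRecord.
    """
    if length == "full":
        return obj
    length = int(length)
    if length <= 0:
        raise ValueError("truncation length must be positive or 'full'")
    if isinstance(obj, TrainingSet):
        return TrainingSet(
            records=truncate_5prime(obj.records, length),
            tree=obj.tree,
            provenance=dict(obj.provenance),
        )
    out = []
    for rec in obj:
        if isinstance(rec, TrainingRecord):
            out.append(
                TrainingRecord(rec.seq_id, rec.sequence[:length], rec.lineage)
            )
        else:
            out.append(
                FastaRecord(id=rec.id, seq=rec.seq[:length],
                            description=rec.description, taxon=rec.taxon)
            )
    return out
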