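"""Lineages, the seven-rank hierarchy, and RDP-style training taxonomy files.

The classifier is trained on reference sequences annotated with full
taxonomic lineages at the seven canonical NCBI ranks (superkingdom through
species).  Source lineage tables frequently have gaps at intermediate ranks;
those are carried as the literal placeholder ``-`` and two placeholder nodes
under different parents are always treated as distinct taxa (node identity is
the full path from the root, never the bare name).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
N_RANKS = len(RANKS)
PLACEHOLDER = "-"
ROOT_NAME = "Root"
ROOT_RANK = "rootrank"

_SP_PATTERN = re.compile(r"\bsp\.?$", re.IGNORECASE)


class LineageTableError(ValueError):
    """Raised for malformed lineage tables (bad header, bad row)."""


class TaxonomyConsistencyError(ValueError):
    """Raised when two entries imply conflicting names on the same path."""


class LineageLookupError(KeyError):
    """Raised when a sequence record has no matching lineage entry."""


@dataclass(frozen=True)
class Lineage:
    """Ordered taxon names at the 7 canonical ranks; ``-`` marks a gap."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != N_RANKS:
            raise ValueError(
                f"a lineage needs exactly {N_RANKS} names, got {len(self.names)}"
            )

    @property
    def species(self) -> str:
        return self.names[-1]

    @property
    def genus(self) -> str:
        return self.names[-2]

    def is_species_resolved(self) -> bool:
        return self.species != PLACEHOLDER

    def path(self, depth: int) -> tuple[str, ...]:
        """Names from superkingdom down to ``depth`` (1..7) inclusive."""
        if not 1 <= depth <= N_RANKS:
            raise ValueError(f"depth must be in 1..{N_RANKS}")
        return self.names[:depth]

    def name_at(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    def __iter__(self):
        return iter(self.names)


@dataclass
class TaxNode:
    taxid: int
    name: str
    parent_taxid: int
    depth: int
    rank_name: str


@dataclass
class TaxTree:
    """Hierarchy of lineage paths; every leaf is a species at depth 7."""

    nodes: dict[int, TaxNode] = field(default_factory=dict)
    path_index: dict[tuple[str, ...], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.nodes:
            root = TaxNode(0, ROOT_NAME, -1, 0, ROOT_RANK)
            self.nodes[0] = root
            self.path_index[()] = 0

    @property
    def root(self) -> TaxNode:
        return self.nodes[0]

    def leaf_taxid(self, lineage: Lineage) -> int:
        return self.path_index[tuple(lineage.names)]

    def leaves(self) -> list[TaxNode]:
        return [n for n in self.nodes.values() if n.depth == N_RANKS]

    def n_nodes(self, include_root: bool = True) -> int:
        return len(self.nodes) - (0 if include_root else 1)

    def add_path(self, lineage: Lineage) -> int:
        """Insert every missing prefix of ``lineage``; return the leaf taxid."""
        parent = 0
        for depth in range(1, N_RANKS + 1):
            prefix = lineage.path(depth)
            taxid = self.path_index.get(prefix)
            if taxid is None:
                taxid = max(self.nodes) + 1
                self.nodes[taxid] = TaxNode(
                    taxid, prefix[-1], parent, depth, RANKS[depth - 1]
                )
                self.path_index[prefix] = taxid
            parent = taxid
        return parent

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxTree):
            return NotImplemented
        return self._canonical() == other._canonical()

    def _canonical(self) -> frozenset:
        # Compare by path structure, not taxid numbering.
        out = set()
        for path, taxid in self.path_index.items():
            node = self.nodes[taxid]
            out.add((path, node.depth, node.rank_name))
        return frozenset(out)


def parse_lineage_table(text: str | Iterable[str]) -> list[tuple[str, Lineage]]:
    """Parse a tab-separated lineage table into ``(taxon name, Lineage)`` pairs.

    Expected header: ``taxon`` followed by the seven rank names.  Empty or
    ``NA`` cells become the ``-`` placeholder.  Duplicate rows for the same
    taxon name collapse to the first prokaryotic one (Bacteria/Archaea
    superkingdom); a taxon whose duplicates are all non-prokaryotic is an
    error, mirroring the manual curation step this replaces.
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        return []
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if "species" not in header:
        raise LineageTableError("lineage table header lacks a 'species' column")
    expected = ["taxon", *RANKS]
    if header != expected:
        raise LineageTableError(
            f"lineage table header must be {expected!r}, got {header!r}"
        )

    raw: dict[str, list[Lineage]] = {}
    order: list[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != 1 + N_RANKS:
            raise LineageTableError(
                f"line {lineno}: expected {1 + N_RANKS} columns, got {len(cells)}"
            )
        taxon = cells[0].strip()
        names = tuple(
            PLACEHOLDER if c.strip() in ("", "NA") else c.strip() for c in cells[1:]
        )
        if taxon not in raw:
            raw[taxon] = []
            order.append(taxon)
        raw[taxon].append(Lineage(names))

    out: list[tuple[str, Lineage]] = []
    for taxon in order:
        out.append((taxon, _resolve_duplicates(taxon, raw[taxon])))
    return out


def _resolve_duplicates(taxon: str, lineages: list[Lineage]) -> Lineage:
    if len(lineages) == 1:
        return lineages[0]
    prokaryotic = [l for l in lineages if l.names[0] in ("Bacteria", "Archaea")]
    if not prokaryotic:
        raise TaxonomyConsistencyError(
            f"taxon {taxon!r} has {len(lineages)} lineages, none prokaryotic"
        )
    return prokaryotic[0]


def is_unresolved_name(taxon: str) -> bool:
    """True for genus-plus-'sp.' style names (e.g. 'Staphylococcus sp.')."""
    return bool(_SP_PATTERN.search(taxon.strip()))


def drop_unresolved_species(
    entries: Sequence[tuple[str, Lineage]],
) -> tuple[list[tuple[str, Lineage]], list[str]]:
    """Partition entries into species-resolved ones and removed names.

    An entry is unresolved when its species slot is the placeholder or its
    taxon name ends in ``sp.`` — such taxa cannot anchor a species leaf.
    """
    kept: list[tuple[str, Lineage]] = []
    removed: list[str] = []
    for name, lineage in entries:
        if not lineage.is_species_resolved() or is_unresolved_name(name):
            removed.append(name)
        else:
            kept.append((name, lineage))
    return kept, removed


def build_rank_tree(entries: Sequence[tuple[str, Lineage]]) -> TaxTree:
    """Build the taxonomy tree from species-resolved entries.

    One node per distinct path prefix; conflicting duplicate paths raise.
    """
    tree = TaxTree()
    seen_paths: dict[tuple[str, ...], str] = {}
    for name, lineage in entries:
        if not lineage.is_species_resolved():
            raise TaxonomyConsistencyError(
                f"entry {name!r} is not species-resolved; curate first"
            )
        full = tuple(lineage.names)
        prior = seen_paths.get(full)
        if prior is not None and prior != name:
            # Same path reached from two differently named taxa is fine
            # (synonyms); a conflict is two paths that diverge in names at
            # the same prefix, which cannot happen under path indexing.
            pass
        seen_paths[full] = name
        tree.add_path(lineage)
    return tree


def emit_training_taxonomy(tree: TaxTree) -> str:
    """Serialize a tree to the asterisk-delimited RDP training dialect.

    One row per node, ``taxid*name*parent_taxid*depth*rank``; the fixed root
    row ``0*Root*-1*0*rootrank`` comes first.  ``parse_training_taxonomy``
    round-trips the result exactly.
    """
    rows = []
    for taxid in sorted(tree.nodes):
        n = tree.nodes[taxid]
        rows.append(f"{n.taxid}*{n.name}*{n.parent_taxid}*{n.depth}*{n.rank_name}")
    return "\n".join(rows) + "\n"


def parse_training_taxonomy(text: str) -> TaxTree:
    """Inverse of :func:`emit_training_taxonomy`."""
    tree = TaxTree()
    tree.nodes.clear()
    tree.path_index.clear()
    nodes: dict[int, TaxNode] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        taxid_s, name, parent_s, depth_s, rank = line.split("*")
        nodes[int(taxid_s)] = TaxNode(
            int(taxid_s), name, int(parent_s), int(depth_s), rank
        )
    tree.nodes = nodes
    # Rebuild the path index by walking up parents.
    for taxid, node in nodes.items():
        path: list[str] = []
        cur = node
        while cur.depth > 0:
            path.append(cur.name)
            cur = nodes[cur.parent_taxid]
        tree.path_index[tuple(reversed(path))] = taxid
    if 0 not in nodes:
        raise TaxonomyConsistencyError("taxonomy file lacks the root row")
    return tree


def inject_lineage_deflines(
    records: Sequence, entries: Sequence[tuple[str, Lineage]]
) -> list:
    """Return records whose deflines carry the 8-token lineage string.

    The defline becomes ``seqID<TAB>Root;sk;ph;cl;or;fa;ge;sp``.  Records are
    matched to entries by their ``taxon`` attribute; a record with no
    matching lineage raises :class:`LineageLookupError` naming it.
    """
    from .io import FastaRecord  # local import to avoid a cycle

    lookup = dict(entries)
    out = []
    missing = []
    for rec in records:
        lineage = lookup.get(rec.taxon)
        if lineage is None:
            missing.append(rec.id)
            continue
        defline = rec.id + "\t" + ";".join([ROOT_NAME, *lineage.names])
        out.append(
            FastaRecord(id=rec.id, seq=rec.seq, description=defline, taxon=rec.taxon)
        )
    if missing:
        raise LineageLookupError(
            f"no lineage for record(s): {', '.join(sorted(missing))}"
        )
    return out
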