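"""Synthetic taxonomies, reference sequences, and query sets.

Emulates the structure of a curated barcode reference collection: a
seven-rank prokaryote-style taxonomy with multiple genera, several species
per genus, and species represented by one or more non-identical strain
sequences.  Sequences evolve down a star-shaped hierarchy by substitution
only (no indels), which keeps expected pairwise identities analytic:
mutating each site independently with probability p to a uniformly chosen
different base gives two descendants of a common ancestor an expected
per-site identity of (1-p)^2 + p^2/3.

Queries model short amplicon sequence variants: 5'-anchored truncations of
the references with independent point errors.  Off-target queries are
uniform random sequences, matching the operational definition of non-marker
amplification products (<55% identity to any reference).

The default configuration also plants the curation edge cases — an exact
duplicate sequence, a singleton species, a genus-sp. taxon that cannot be
resolved to species, and a lineage with a missing class rank — so the whole
curation path is exercised without real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FastaRecord
from .taxonomy import Lineage, PLACEHOLDER

_ALPH = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

# fixed substream labels so each generator stage is independent of call order
_STREAMS = {"taxonomy": 0, "references": 1, "queries": 2, "offtarget": 3}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Divergence rates are per-site substitution probabilities applied on the
    branch into each taxon: genus ancestors diverge from a common root at
    ``genus_divergence``, species from their genus ancestor, strains from
    their species ancestor.  Rates must be hierarchically ordered
    (strain < species < genus).
    """

    n_genera: int = 8
    species_per_genus: int = 3
    strains_per_species: int = 3
    singleton_species_per_genus: int = 14
    n_phyla: int = 4
    seq_length: int = 555
    genus_divergence: float = 0.25
    species_divergence: float = 0.08
    strain_divergence: float = 0.01
    query_length: int = 150
    query_error_rate: float = 0.005
    n_offtarget: int = 200
    seed: int = 17
    include_edge_cases: bool = True

    def __post_init__(self) -> None:
        for r in (self.genus_divergence, self.species_divergence,
                  self.strain_divergence):
            if not 0 <= r <= 0.75:
                raise ValueError("divergence rates must be in [0, 0.75]")
        if not (self.strain_divergence < self.species_divergence
                < self.genus_divergence):
            raise ValueError("rates must satisfy strain < species < genus")
        if self.n_phyla > self.n_genera:
            raise ValueError("need at least one genus per phylum")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, _STREAMS[stream]])
    )


def expected_pairwise_identity(p: float) -> float:
    """Expected per-site identity of two independent descendants of one ancestor.

    Each site mutates independently with probability ``p`` to one of the
    three other bases; identity needs both unchanged or both changed to the
    same base.
    """
    return (1 - p) ** 2 + p ** 2 / 3


def _genus_lineage(g: int, config: SimConfig) -> tuple[str, ...]:
    """Upper six ranks for genus index g (1-based), nested consistently."""
    phylum = (g - 1) * config.n_phyla // config.n_genera + 1
    return (
        "Bacteria",
        f"Phylum{phylum:02d}",
        f"Class{phylum:02d}",
        f"Order{g:02d}",
        f"Family{g:02d}",
        f"Genus{g:02d}",
    )


def simulate_taxonomy(config: SimConfig) -> list[tuple[str, Lineage]]:
    """Systematically named 7-rank lineages matching the configured counts.

    With ``include_edge_cases`` three extra taxa are appended: a singleton
    species whose class rank is a placeholder, an unresolvable genus-sp.
    taxon, and the species that will carry a duplicate sequence already
    exists in the core grid.
    """
    entries: list[tuple[str, Lineage]] = []
    n_species = config.species_per_genus + config.singleton_species_per_genus
    for g in range(1, config.n_genera + 1):
        upper = _genus_lineage(g, config)
        for s in range(1, n_species + 1):
            name = f"Genus{g:02d} species{s:02d}"
            entries.append((name, Lineage((*upper, name))))
    if config.include_edge_cases:
        g = config.n_genera + 1
        upper = list(_genus_lineage(g, config))
        upper[1] = "Phylum01"
        upper[2] = PLACEHOLDER  # missing class rank
        singleton = f"Genus{g:02d} species01"
        entries.append((singleton, Lineage((*upper, singleton))))
        g2 = config.n_genera + 2
        sp_name = f"Genus{g2:02d} sp."
        entries.append(
            (sp_name, Lineage((*_genus_lineage(g2, config), PLACEHOLDER)))
        )
    return entries


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    n = int(hit.sum())
    if n:
        # shift by 1..3 mod 4 guarantees a different base, uniformly
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(_ALPH[seq])


def simulate_reference_sequences(
    taxonomy: Sequence[tuple[str, Lineage]], config: SimConfig
) -> list[FastaRecord]:
    """Evolve one sequence per strain down the root→genus→species hierarchy.

    Strain counts follow the config for core species; edge-case taxa get a
    single strain, plus one exact duplicate record (strain divergence 0) to
    exercise deduplication.
    """
    rng = _rng(config, "references")
    root = rng.integers(0, 4, size=config.seq_length, dtype=np.int8)
    core_genera = {f"Genus{g:02d}" for g in range(1, config.n_genera + 1)}
    records: list[FastaRecord] = []
    genus_anc: dict[str, np.ndarray] = {}
    for taxon, lineage in taxonomy:
        genus = lineage.genus
        if genus not in genus_anc:
            genus_anc[genus] = _mutate(root, config.genus_divergence, rng)
        species_anc = _mutate(genus_anc[genus], config.species_divergence, rng)
        # species beyond the multi-strain grid are singletons (one record),
        # the dominant situation in curated barcode reference databases
        if taxon.split()[0] in core_genera:
            s_num = int(taxon.rsplit("species", 1)[-1])
            multi = s_num <= config.species_per_genus
            n_strains = config.strains_per_species if multi else 1
        else:
            n_strains = 1
        base_id = taxon.replace(" ", "_").replace(".", "")
        for k in range(1, n_strains + 1):
            strain = _mutate(species_anc, config.strain_divergence, rng)
            records.append(
                FastaRecord(
                    id=f"{base_id}_strain{k:02d}",
                    seq=_to_str(strain),
                    description=f"{base_id}_strain{k:02d} {taxon}",
                    taxon=taxon,
                )
            )
    if config.include_edge_cases and records:
        dup = records[0]
        records.append(
            FastaRecord(
                id=dup.id + "_dup",
                seq=dup.seq,
                description=f"{dup.id}_dup {dup.taxon}",
                taxon=dup.taxon,
            )
        )
    return records


def simulate_queries(
    references: Sequence[FastaRecord],
    config: SimConfig,
    taxonomy: Sequence[tuple[str, Lineage]] | None = None,
) -> tuple[list[FastaRecord], pd.DataFrame]:
    """5'-anchored truncations of the references with point errors.

    Returns the queries and a truth table mapping each query to its source
    record, taxon, and (when a taxonomy is supplied) full lineage.
    """
    rng = _rng(config, "queries")
    lineage_of = dict(taxonomy) if taxonomy else {}
    queries: list[FastaRecord] = []
    rows = []
    for ref in references:
        trunc = ref.seq[: config.query_length]
        arr = np.array([_BASE_INDEX[b] for b in trunc], dtype=np.int8)
        mutated = _mutate(arr, config.query_error_rate, rng)
        qid = f"q_{ref.id}"
        queries.append(FastaRecord(id=qid, seq=_to_str(mutated), taxon=ref.taxon))
        row = {"query": qid, "source": ref.id, "taxon": ref.taxon}
        lineage = lineage_of.get(ref.taxon)
        if lineage is not None:
            row["lineage"] = ";".join(lineage.names)
        rows.append(row)
    return queries, pd.DataFrame(rows)


def simulate_offtarget_queries(config: SimConfig) -> list[FastaRecord]:
    """Uniform random sequences of query length — off-target amplicons."""
    rng = _rng(config, "offtarget")
    out = []
    for i in range(config.n_offtarget):
        seq = rng.integers(0, 4, size=config.query_length, dtype=np.int8)
        out.append(FastaRecord(id=f"offtarget_{i:04d}", seq=_to_str(seq)))
    return out


@dataclass
class SimulatedStudy:
    config: SimConfig
    taxonomy: list[tuple[str, Lineage]]
    references: list[FastaRecord]
    queries: list[FastaRecord]
    truth: pd.DataFrame
    offtarget: list[FastaRecord]


def simulate_study(config: SimConfig | None = None) -> SimulatedStudy:
    """Generate the full benchmark: taxonomy, references, queries, off-target."""
    config = config or SimConfig()
    taxonomy = simulate_taxonomy(config)
    references = simulate_reference_sequences(taxonomy, config)
    queries, truth = simulate_queries(references, config, taxonomy)
    offtarget = simulate_offtarget_queries(config)
    return SimulatedStudy(config, taxonomy, references, queries, truth, offtarget)


def write_study(study: SimulatedStudy, out_dir) -> None:
    """Write refs.fasta, taxonomy.tsv, queries.fasta, offtarget.fasta, truth.tsv."""
    from pathlib import Path
    from .io import write_fasta
    from .taxonomy import RANKS

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(study.references, out / "refs.fasta")
    write_fasta(study.queries, out / "queries.fasta")
    write_fasta(study.offtarget, out / "offtarget.fasta")
    with open(out / "taxonomy.tsv", "w") as fh:
        fh.write("taxon\t" + "\t".join(RANKS) + "\n")
        for taxon, lineage in study.taxonomy:
            fh.write(taxon + "\t" + "\t".join(lineage.names) + "\n")
    study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
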