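import numpy as np
import pytest
from hypothesis import settings

from cpntax import (
    FastaRecord,
    Lineage,
    SimConfig,
    TrainingRecord,
    TrainingSet,
    build_rank_tree,
    reconcile,
    simulate_study,
    train,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def lineage(sk="Bacteria", ph="Phylum01", cl="Class01", od="Order01",
            fa="Family01", ge="Genus01", sp="Genus01 species01") -> Lineage:
    return Lineage((sk, ph, cl, od, fa, ge, sp))


def make_training_set(triples) -> TrainingSet:
    """Build a TrainingSet from (seq_id, sequence, Lineage) triples."""
    records = [TrainingRecord(i, s.upper(), l) for i, s, l in triples]
    entries = {}
    for r in records:
        entries[r.lineage.species] = r.lineage
    tree = build_rank_tree(list(entries.items()))
    return TrainingSet(records=records, tree=tree,
                       provenance={"raw": len(records),
                                   "lineage_resolved": len(records),
                                   "deduplicated": len(records)})


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic benchmark (study conditions of the evaluation)."""
    return simulate_study(SimConfig())


@pytest.fixture(scope="session")
def default_training(default_study):
    return reconcile(default_study.references, default_study.taxonomy)


@pytest.fixture(scope="session")
def default_model(default_training):
    return train(default_training)


@pytest.fixture()
def two_species_disjoint():
    """Two species whose 8-mer word sets are disjoint.

    Built from homopolymer-ish blocks so every window of one sequence
    contains a base the other sequence never uses.
    """
    seq_a = "A" * 30 + "C" * 30   # words only over {A,C}
    seq_b = "G" * 30 + "T" * 30   # words only over {G,T}
    return make_training_set([
        ("a1", seq_a, lineage(sp="Genus01 speciesA")),
        ("b1", seq_b, lineage(ph="Phylum02", cl="Class02", od="Order02",
                              fa="Family02", ge="Genus02",
                              sp="Genus02 speciesB")),
    ])
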