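"""Naive Bayes k-mer classifier with bootstrap rank confidence.

The model follows the word-presence (document-frequency) formulation used by
RDP-style classifiers: each training sequence is reduced to its set of
distinct 8-mers, and a candidate species s is scored for a query word set W
by

    log P(W | s) = sum_{w in W} log[ (m_s(w) + p(w)) / (M_s + 1) ]

where M_s is the number of training sequences of species s, m_s(w) how many
of them contain word w, and p(w) = (n(w) + 0.5) / (N + 1) the word prior over
all N training sequences.  Confidence at each rank is estimated by a
bootstrap: every trial scores a random with-replacement subsample of
|W|/8 query words, and the per-rank confidence is the fraction of trials
whose winning species falls under the modal ancestor at that rank.

Candidate units are species (the deepest trained rank); genus and higher
confidences follow from the lineage of each trial winner, so confidence is
non-increasing with depth by construction.

The per-species word-count matrix is stored dense over the 4^w vocabulary,
which is the right trade-off up to a few hundred species; very large
reference sets would want a sparse backend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .curation import TrainingSet
from .taxonomy import N_RANKS, RANKS, TaxTree, Lineage, build_rank_tree

MODEL_FORMAT = "cpntax-model"
MODEL_VERSION = 1

DEFAULT_WORD_SIZE = 8
DEFAULT_TRIALS = 100
DEFAULT_SUBSAMPLE_DIVISOR = 8
DEFAULT_ASSIGNMENT_CUTOFF = 0.8
DEFAULT_PHYLUM_FILTER_CUTOFF = 0.6

_BASE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BASE_LUT[_b] = _i

UNCLASSIFIED = "unclassified"


def tokenize_words(sequence: str, w: int = DEFAULT_WORD_SIZE) -> np.ndarray:
    """Distinct length-``w`` words of a sequence as sorted integer codes.

    Words are read over ACGT-only stretches; any window containing an
    ambiguity code (N or other IUPAC symbols) is skipped.  A sequence shorter
    than ``w`` yields an empty array.
    """
    if w < 1:
        raise ValueError("word size must be >= 1")
    arr = _BASE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if arr.size < w:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, w)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(w - 1, -1, -1, dtype=np.int64)
    codes = windows[valid].astype(np.int64) @ powers
    return np.unique(codes)


def decode_word(code: int, w: int = DEFAULT_WORD_SIZE) -> str:
    out = []
    for _ in range(w):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def word_prior(n_wi: int | np.ndarray, N: int):
    """Prior probability of observing a word in a training sequence.

    ``(n_wi + 0.5) / (N + 1)`` — strictly inside (0, 1) for any count.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return (np.asarray(n_wi, dtype=np.float64) + 0.5) / (N + 1)


def word_conditional(m_s, M_s: int, prior):
    """Species-conditional word probability ``(m_s + prior) / (M_s + 1)``."""
    return (np.asarray(m_s, dtype=np.float64) + prior) / (M_s + 1)


@dataclass
class Classification:
    """Per-rank (taxon, confidence) result for one query."""

    query_id: str
    taxa: tuple[str, ...]
    confidences: tuple[float, ...]
    n_words: int
    unclassifiable: bool = False
    assigned_rank: Optional[str] = None

    def confidence_at(self, rank: str) -> float:
        return self.confidences[RANKS.index(rank)]

    def taxon_at(self, rank: str) -> str:
        return self.taxa[RANKS.index(rank)]


@dataclass
class WordModel:
    """Fitted naive Bayes state over the 4^w word vocabulary."""

    w: int
    species_paths: list[tuple[str, ...]]
    M: np.ndarray              # (n_species,) sequence tallies
    m: np.ndarray              # (n_species, 4^w) per-species word document counts
    n_word: np.ndarray         # (4^w,) word document counts over all sequences
    N: int
    seq_species: dict[str, int]
    seq_words: dict[str, np.ndarray]
    seq_order: list[str]
    removed: set[str] = field(default_factory=set)
    tree: TaxTree | None = None

    @property
    def n_species(self) -> int:
        return len(self.species_paths)

    def active_species(self) -> np.ndarray:
        return self.M > 0

    def species_index(self, path: tuple[str, ...]) -> int:
        return self.species_paths.index(path)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WordModel):
            return NotImplemented
        return (
            self.w == other.w
            and self.N == other.N
            and self.species_paths == other.species_paths
            and np.array_equal(self.M, other.M)
            and np.array_equal(self.m, other.m)
            and np.array_equal(self.n_word, other.n_word)
            and self.seq_species == other.seq_species
            and self.seq_order == other.seq_order
            and self.removed == other.removed
            and set(self.seq_words) == set(other.seq_words)
            and all(np.array_equal(v, other.seq_words[k])
                    for k, v in self.seq_words.items())
        )


def train(training_set: TrainingSet, word_size: int = DEFAULT_WORD_SIZE) -> WordModel:
    """Fit the word model on a curated training set.

    Species identity is the full 7-rank lineage path; species are indexed in
    order of first appearance (the deterministic tie-break order for equal
    scores).
    """
    species_paths: list[tuple[str, ...]] = []
    species_index: dict[tuple[str, ...], int] = {}
    for rec in training_set.records:
        path = tuple(rec.lineage.names)
        if path not in species_index:
            species_index[path] = len(species_paths)
            species_paths.append(path)
    vocab = 4 ** word_size
    n_species = len(species_paths)
    M = np.zeros(n_species, dtype=np.int64)
    m = np.zeros((n_species, vocab), dtype=np.int32)
    n_word = np.zeros(vocab, dtype=np.int64)
    seq_species: dict[str, int] = {}
    seq_words: dict[str, np.ndarray] = {}
    seq_order: list[str] = []
    for rec in training_set.records:
        s = species_index[tuple(rec.lineage.names)]
        codes = tokenize_words(rec.sequence, word_size)
        if rec.seq_id in seq_species:
            raise ValueError(f"duplicate sequence id in training set: {rec.seq_id}")
        seq_species[rec.seq_id] = s
        seq_words[rec.seq_id] = codes
        seq_order.append(rec.seq_id)
        M[s] += 1
        m[s, codes] += 1
        n_word[codes] += 1
    return WordModel(
        w=word_size,
        species_paths=species_paths,
        M=M,
        m=m,
        n_word=n_word,
        N=len(training_set.records),
        seq_species=seq_species,
        seq_words=seq_words,
        seq_order=seq_order,
        tree=training_set.tree,
    )


def log_joint_score(word_codes: np.ndarray, species: int, model: WordModel) -> float:
    """Log joint probability of a query word set under one species."""
    word_codes = np.asarray(word_codes)
    if word_codes.size == 0:
        raise ValueError("cannot score an empty word set")
    prior = word_prior(model.n_word[word_codes], model.N)
    cond = word_conditional(model.m[species, word_codes], int(model.M[species]), prior)
    return float(np.log(cond).sum())


def _log_score_matrix(model: WordModel, word_codes: np.ndarray) -> np.ndarray:
    """(n_species, n_words) matrix of per-word log conditionals.

    Species with no remaining training sequences get -inf rows so they can
    never win a bootstrap trial.
    """
    prior = word_prior(model.n_word[word_codes], model.N)
    cond = (model.m[:, word_codes].astype(np.float64) + prior[None, :]) / (
        model.M[:, None] + 1
    )
    S = np.log(cond)
    S[~model.active_species(), :] = -np.inf
    return S


def _modal_prefixes(
    model: WordModel, votes: np.ndarray, trials: int
) -> tuple[tuple[str, ...], tuple[float, ...]]:
    """Per-rank modal ancestor taxa and their vote fractions."""
    taxa = []
    confs = []
    voted = np.nonzero(votes)[0]
    for depth in range(1, N_RANKS + 1):
        counts: dict[tuple[str, ...], int] = {}
        order: list[tuple[str, ...]] = []
        for s in voted:
            prefix = model.species_paths[s][:depth]
            if prefix not in counts:
                counts[prefix] = 0
                order.append(prefix)
            counts[prefix] += int(votes[s])
        best = order[0]
        for prefix in order[1:]:
            if counts[prefix] > counts[best]:
                best = prefix
        taxa.append(best[-1])
        confs.append(counts[best] / trials)
    return tuple(taxa), tuple(confs)


def classify_bootstrap(
    model: WordModel,
    sequence: str,
    query_id: str = "query",
    trials: int = DEFAULT_TRIALS,
    subsample_divisor: int = DEFAULT_SUBSAMPLE_DIVISOR,
    rng: np.random.Generator | int | None = 0,
) -> Classification:
    """Classify one query with bootstrap confidence at every rank.

    Each of ``trials`` trials draws ``max(1, |words| // subsample_divisor)``
    words with replacement and records the argmax-score species (ties break
    to the lowest training-order index).  A query yielding zero words returns
    a flagged unclassifiable record rather than raising, so one bad read
    cannot abort a batch.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    codes = tokenize_words(sequence, model.w)
    if codes.size == 0:
        return Classification(
            query_id=query_id,
            taxa=(UNCLASSIFIED,) * N_RANKS,
            confidences=(0.0,) * N_RANKS,
            n_words=0,
            unclassifiable=True,
        )
    S = _log_score_matrix(model, codes)
    k = max(1, codes.size // subsample_divisor)
    idx = rng.integers(0, codes.size, size=(trials, k))
    trial_scores = S[:, idx].sum(axis=2)          # (n_species, trials)
    winners = np.argmax(trial_scores, axis=0)     # lowest index wins ties
    votes = np.bincount(winners, minlength=model.n_species)
    taxa, confs = _modal_prefixes(model, votes, trials)
    return Classification(
        query_id=query_id, taxa=taxa, confidences=confs, n_words=int(codes.size)
    )


def classify_batch(
    model: WordModel,
    records: Sequence,
    trials: int = DEFAULT_TRIALS,
    subsample_divisor: int = DEFAULT_SUBSAMPLE_DIVISOR,
    seed: int = 0,
    cutoff: float | None = DEFAULT_ASSIGNMENT_CUTOFF,
) -> list[Classification]:
    """Classify FASTA-like records; per-query RNG substreams come from the
    batch seed and the query index, so results are reproducible."""
    out = []
    for i, rec in enumerate(records):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        c = classify_bootstrap(
            model, rec.seq, query_id=rec.id, trials=trials,
            subsample_divisor=subsample_divisor, rng=rng,
        )
        if cutoff is not None:
            assign_at_cutoff(c, cutoff)
        out.append(c)
    return out


def assign_at_cutoff(
    classification: Classification, cutoff: float
) -> tuple[str, str] | None:
    """Deepest rank whose confidence meets the cutoff, or None (unassigned).

    Also stamps ``assigned_rank`` on the classification.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    result = None
    for depth in range(N_RANKS - 1, -1, -1):
        if classification.confidences[depth] >= cutoff:
            result = (RANKS[depth], classification.taxa[depth])
            break
    classification.assigned_rank = result[0] if result else None
    return result


def remove_sequence(model: WordModel, seq_id: str) -> WordModel:
    """Subtract one training sequence's contributions in place.

    A species whose tally reaches zero drops out of the candidate set.
    ``restore_sequence`` is the exact inverse.  Returns the model for
    chaining.
    """
    if seq_id not in model.seq_species or seq_id in model.removed:
        raise KeyError(f"sequence not in model: {seq_id}")
    s = model.seq_species[seq_id]
    codes = model.seq_words[seq_id]
    model.M[s] -= 1
    model.m[s, codes] -= 1
    model.n_word[codes] -= 1
    model.N -= 1
    model.removed.add(seq_id)
    return model


def restore_sequence(model: WordModel, seq_id: str) -> WordModel:
    """Re-add a previously removed sequence; inverse of remove_sequence."""
    if seq_id not in model.removed:
        raise KeyError(f"sequence was not removed: {seq_id}")
    s = model.seq_species[seq_id]
    codes = model.seq_words[seq_id]
    model.M[s] += 1
    model.m[s, codes] += 1
    model.n_word[codes] += 1
    model.N += 1
    model.removed.discard(seq_id)
    return model


def filter_non_target(
    classifications: Iterable[Classification],
    phylum_cutoff: float = DEFAULT_PHYLUM_FILTER_CUTOFF,
) -> tuple[list[Classification], list[Classification]]:
    """Partition queries by phylum-rank confidence (>= cutoff is retained).

    Queries below the cutoff are treated as off-target amplicons, the
    recommended screen for reads that are not the marker gene at all.
    """
    retained, discarded = [], []
    for c in classifications:
        (retained if c.confidence_at("phylum") >= phylum_cutoff else discarded).append(c)
    return retained, discarded


def save_model(model: WordModel, path: str | Path) -> None:
    """Serialize to a single-file .npz container with a format version."""
    offsets = np.zeros(len(model.seq_order) + 1, dtype=np.int64)
    chunks = []
    for i, sid in enumerate(model.seq_order):
        codes = model.seq_words[sid]
        offsets[i + 1] = offsets[i] + codes.size
        chunks.append(codes)
    concat = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    meta = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "w": model.w,
        "N": model.N,
        "species_paths": [list(p) for p in model.species_paths],
        "seq_order": model.seq_order,
        "seq_species": [model.seq_species[sid] for sid in model.seq_order],
        "removed": sorted(model.removed),
    }
    np.savez_compressed(
        str(path),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        M=model.M,
        m=model.m,
        n_word=model.n_word,
        word_codes=concat,
        word_offsets=offsets,
    )


def load_model(path: str | Path) -> WordModel:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta.get("format") != MODEL_FORMAT:
            raise ValueError(f"not a {MODEL_FORMAT} file: {path}")
        if meta.get("version") != MODEL_VERSION:
            raise ValueError(f"unsupported model version: {meta.get('version')}")
        offsets = z["word_offsets"]
        concat = z["word_codes"]
        seq_order = list(meta["seq_order"])
        seq_words = {
            sid: concat[offsets[i]:offsets[i + 1]].copy()
            for i, sid in enumerate(seq_order)
        }
        return WordModel(
            w=int(meta["w"]),
            species_paths=[tuple(p) for p in meta["species_paths"]],
            M=z["M"].copy(),
            m=z["m"].copy(),
            n_word=z["n_word"].copy(),
            N=int(meta["N"]),
            seq_species=dict(zip(seq_order, meta["seq_species"])),
            seq_words=seq_words,
            seq_order=seq_order,
            removed=set(meta["removed"]),
        )
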