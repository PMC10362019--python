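"""Classifier evaluation: self-classification, leave-one-out, engine
comparison, and threshold screening.

Leave-one-out cross-validation removes each training sequence from the
fitted word model by decrementing its count contributions, classifies the
(optionally truncated) sequence against the remainder, and restores the
counts — algebraically identical to retraining from scratch without the
sequence, which is itself verified by a test on small fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .aligner import AlignmentHit, IDENTITY_THRESHOLD
from .classifier import (
    Classification,
    WordModel,
    assign_at_cutoff,
    classify_bootstrap,
    remove_sequence,
    restore_sequence,
    train,
)
from .curation import TrainingSet, truncate_5prime
from .taxonomy import N_RANKS, RANKS

DEFAULT_LOO_CUTOFF = 0.9
DEFAULT_LENGTHS = (50, 150, 300, 450, "full")


class EvaluationError(ValueError):
    pass


@dataclass
class SelfClassificationSummary:
    """Outcome bands when the training sequences are used as queries."""

    n_total: int
    n_species_conf_1: int          # species confidence exactly 1.0
    n_species_conf_band: int       # species confidence in [0.8, 1.0)
    n_below: int                   # species confidence < 0.8
    below_rank_counts: dict[str, int]  # assigned rank of the below-band queries

    @property
    def pct_species_conf_1(self) -> float:
        return 100.0 * self.n_species_conf_1 / self.n_total


@dataclass
class CVResult:
    """Per-rank leave-one-out accuracy for one query length."""

    length: object
    cutoff: float
    n_total: int
    n_correct: dict[str, int]
    accuracy: dict[str, float] = field(init=False)
    n_singleton: int = 0
    n_singleton_correct_species: int = 0
    n_multistrain: int = 0
    n_multistrain_correct_species: int = 0

    def __post_init__(self) -> None:
        self.accuracy = {
            r: self.n_correct[r] / self.n_total if self.n_total else 0.0
            for r in RANKS
        }

    @property
    def species_accuracy_multistrain(self) -> float:
        if not self.n_multistrain:
            return 0.0
        return self.n_multistrain_correct_species / self.n_multistrain

    @property
    def species_accuracy_singleton(self) -> float:
        if not self.n_singleton:
            return 0.0
        return self.n_singleton_correct_species / self.n_singleton


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class QuadrantSummary:
    """Counts in the four quadrants of the identity x confidence plane."""

    id_threshold: float
    conf_threshold: float
    upper_right: int = 0   # on-target identity, confident classification
    lower_right: int = 0   # on-target identity, low confidence
    upper_left: int = 0    # off-target identity, confident classification
    lower_left: int = 0    # off-target identity, low confidence

    @property
    def total(self) -> int:
        return self.upper_right + self.lower_right + self.upper_left + self.lower_left

    def percentages(self) -> dict[str, float]:
        t = self.total or 1
        return {
            k: 100.0 * getattr(self, k) / t
            for k in ("upper_right", "lower_right", "upper_left", "lower_left")
        }


def self_classification_summary(
    model: WordModel,
    training_set: TrainingSet,
    seed: int = 0,
    trials: int = 100,
    band: tuple[float, float] = (0.8, 1.0),
) -> SelfClassificationSummary:
    """Classify every training sequence against the full model (leave-in).

    Reports how many queries hit species confidence 1.0, how many fall in
    the ``band`` (default 0.8-0.99), and the assigned rank distribution of
    the rest at the band's lower edge as cutoff.
    """
    lo, hi = band
    if not 0 < lo < hi <= 1:
        raise EvaluationError("band must satisfy 0 < lo < hi <= 1")
    n1 = nband = nbelow = 0
    below_ranks: dict[str, int] = {}
    for i, rec in enumerate(training_set.records):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        c = classify_bootstrap(model, rec.sequence, rec.seq_id, trials=trials, rng=rng)
        conf = c.confidence_at("species")
        if conf >= hi:
            n1 += 1
        elif conf >= lo:
            nband += 1
        else:
            nbelow += 1
            assign_at_cutoff(c, lo)
            key = c.assigned_rank or "unassigned"
            below_ranks[key] = below_ranks.get(key, 0) + 1
    return SelfClassificationSummary(
        n_total=len(training_set.records),
        n_species_conf_1=n1,
        n_species_conf_band=nband,
        n_below=nbelow,
        below_rank_counts=below_ranks,
    )


def loo_cross_validation(
    training_set: TrainingSet,
    lengths: Sequence = DEFAULT_LENGTHS,
    cutoff: float = DEFAULT_LOO_CUTOFF,
    seed: int = 0,
    trials: int = 100,
    word_size: int = 8,
    truncate_training: bool = True,
) -> dict[object, CVResult]:
    """Leave-one-out cross-validation per query length.

    For each length L the training set (when ``truncate_training``) and the
    queries are truncated to their first L bases, the model is fitted, and
    each sequence is removed, classified, and restored.  A query counts as
    correct at rank r when the reported taxon matches its own lineage at r
    AND the confidence meets ``cutoff``.  Singleton species (one training
    sequence) are tracked separately: they can never be recovered at species
    rank.
    """
    results: dict[object, CVResult] = {}
    for length in lengths:
        ts = truncate_5prime(training_set, length) if truncate_training else training_set
        model = train(ts, word_size=word_size)
        strain_counts = np.bincount(
            [model.seq_species[r.seq_id] for r in ts.records],
            minlength=model.n_species,
        )
        n_correct = {r: 0 for r in RANKS}
        n_single = n_single_ok = n_multi = n_multi_ok = 0
        for i, rec in enumerate(ts.records):
            query_seq = (
                rec.sequence if truncate_training
                else truncate_5prime([rec], length)[0].sequence
            )
            remove_sequence(model, rec.seq_id)
            rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
            c = classify_bootstrap(model, query_seq, rec.seq_id, trials=trials, rng=rng)
            restore_sequence(model, rec.seq_id)
            truth = rec.lineage.names
            species_ok = False
            for d, rank in enumerate(RANKS):
                if c.taxa[d] == truth[d] and c.confidences[d] >= cutoff:
                    n_correct[rank] += 1
                    if rank == "species":
                        species_ok = True
            singleton = strain_counts[model.seq_species[rec.seq_id]] == 1
            if singleton:
                n_single += 1
                n_single_ok += species_ok
            else:
                n_multi += 1
                n_multi_ok += species_ok
        results[length] = CVResult(
            length=length,
            cutoff=cutoff,
            n_total=len(ts.records),
            n_correct=n_correct,
            n_singleton=n_single,
            n_singleton_correct_species=n_single_ok,
            n_multistrain=n_multi,
            n_multistrain_correct_species=n_multi_ok,
        )
    return results


def quadrant_analysis(
    classifications: Sequence[Classification],
    hits: Sequence[AlignmentHit],
    id_threshold: float = IDENTITY_THRESHOLD,
    conf_threshold: float = 0.8,
) -> QuadrantSummary:
    """Place each query in the (identity >= t) x (species conf >= c) plane."""
    conf_by_query = {c.query_id: c.confidence_at("species") for c in classifications}
    hit_by_query = {h.query_id: h.percent_identity for h in hits}
    if set(conf_by_query) != set(hit_by_query):
        raise EvaluationError("classifier and aligner saw different query sets")
    summary = QuadrantSummary(id_threshold=id_threshold, conf_threshold=conf_threshold)
    for qid, conf in conf_by_query.items():
        on_target = hit_by_query[qid] >= id_threshold
        confident = conf >= conf_threshold
        if on_target and confident:
            summary.upper_right += 1
        elif on_target:
            summary.lower_right += 1
        elif confident:
            summary.upper_left += 1
        else:
            summary.lower_left += 1
    return summary


def sensitivity_specificity(confusion: ConfusionCounts) -> tuple[float, float]:
    """sensitivity = tp/(tp+fn); specificity = tn/(tn+fp)."""
    if confusion.tp + confusion.fn == 0:
        raise EvaluationError("sensitivity undefined: no positives (tp+fn = 0)")
    if confusion.tn + confusion.fp == 0:
        raise EvaluationError("specificity undefined: no negatives (tn+fp = 0)")
    sens = confusion.tp / (confusion.tp + confusion.fn)
    spec = confusion.tn / (confusion.tn + confusion.fp)
    return sens, spec


def confusion_at_cutoff(
    classifications: Sequence[Classification],
    hits: Sequence[AlignmentHit],
    cutoff: float,
    rank: str = "phylum",
    id_threshold: float = IDENTITY_THRESHOLD,
) -> ConfusionCounts:
    """Confusion counts with nearest-neighbor identity as the gold standard.

    Gold positive: identity >= id_threshold (a true marker-gene sequence).
    Test positive: confidence at ``rank`` >= cutoff.
    """
    conf_by_query = {c.query_id: c.confidence_at(rank) for c in classifications}
    hit_by_query = {h.query_id: h.percent_identity for h in hits}
    if set(conf_by_query) != set(hit_by_query):
        raise EvaluationError("classifier and aligner saw different query sets")
    if not conf_by_query:
        raise EvaluationError("empty query set")
    cc = ConfusionCounts()
    for qid, conf in conf_by_query.items():
        gold = hit_by_query[qid] >= id_threshold
        test = conf >= cutoff
        if gold and test:
            cc.tp += 1
        elif gold:
            cc.fn += 1
        elif test:
            cc.fp += 1
        else:
            cc.tn += 1
    return cc


def threshold_screen(
    classifications: Sequence[Classification],
    hits: Sequence[AlignmentHit],
    cutoffs: Sequence[float] = (0.6, 0.8),
    rank: str = "phylum",
    id_threshold: float = IDENTITY_THRESHOLD,
) -> list[dict]:
    """Sensitivity/specificity of candidate confidence cutoffs at one rank."""
    rows = []
    for cutoff in cutoffs:
        cc = confusion_at_cutoff(classifications, hits, cutoff, rank, id_threshold)
        sens, spec = sensitivity_specificity(cc)
        rows.append(
            {
                "cutoff": cutoff,
                "rank": rank,
                "sensitivity": sens,
                "specificity": spec,
                "tp": cc.tp, "fp": cc.fp, "tn": cc.tn, "fn": cc.fn,
            }
        )
    return rows


def confidence_correlation(
    results_a: Sequence[Classification],
    results_b: Sequence[Classification],
    rank: str = "species",
) -> tuple[float, float]:
    """Spearman rank correlation of per-query confidences between two runs.

    Ties get average ranks; the p-value uses the large-sample t
    approximation.  Requires at least 3 shared queries.
    """
    a = {c.query_id: c.confidence_at(rank) for c in results_a}
    b = {c.query_id: c.confidence_at(rank) for c in results_b}
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise EvaluationError("need at least 3 shared queries")
    va = [a[q] for q in shared]
    vb = [b[q] for q in shared]
    res = stats.spearmanr(va, vb)
    return float(res.statistic), float(res.pvalue)
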