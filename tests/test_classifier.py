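"""Word model scoring, bootstrap classification, and leave-one-out algebra."""

import itertools
import math

import numpy as np
import pytest

from cpntax import (
    assign_at_cutoff,
    classify_batch,
    classify_bootstrap,
    filter_non_target,
    load_model,
    log_joint_score,
    remove_sequence,
    restore_sequence,
    save_model,
    tokenize_words,
    train,
    word_conditional,
    word_prior,
)
from cpntax.classifier import Classification, decode_word
from cpntax.taxonomy import RANKS

from conftest import lineage, make_training_set


def words_as_strings(seq, w=8):
    return {decode_word(c, w) for c in tokenize_words(seq, w)}


class TestTokenize:
    def test_enumerates_distinct_windows(self):
        assert words_as_strings("ACGTACGTAC") == {
            "ACGTACGT", "CGTACGTA", "GTACGTAC"
        }

    def test_windows_containing_ambiguity_are_skipped(self):
        seq = "ACGTNCGTACGT"
        expected = {seq[i:i + 8] for i in range(len(seq) - 7)
                    if "N" not in seq[i:i + 8]}
        assert words_as_strings(seq) == expected

    def test_short_sequence_yields_empty_set(self):
        assert tokenize_words("ACGT", 8).size == 0

    def test_lowercase_accepted(self):
        assert words_as_strings("acgtacgtac") == words_as_strings("ACGTACGTAC")


class TestWordProbabilities:
    @pytest.mark.parametrize("n,N,expected", [
        (0, 10, 0.5 / 11),
        (10, 10, 10.5 / 11),
        (5, 10, 0.5),
    ])
    def test_prior_values(self, n, N, expected):
        assert word_prior(n, N) == pytest.approx(expected)

    @pytest.mark.parametrize("m,M,p,expected", [
        (2, 3, 0.5 / 11, (2 + 0.5 / 11) / 4),
        (0, 1, 0.5, 0.25),
    ])
    def test_conditional_values(self, m, M, p, expected):
        assert word_conditional(m, M, p) == pytest.approx(expected)

    def test_conditional_strictly_below_one_when_saturated(self):
        for M in (1, 3, 10):
            assert 0 < word_conditional(M, M, 0.3) < 1


class TestLogJointScore:
    def test_single_word_single_sequence_species(self, two_species_disjoint):
        model = train(two_species_disjoint)
        word = tokenize_words("A" * 8, 8)
        prior = word_prior(int(model.n_word[word[0]]), model.N)
        expected = math.log((1 + prior) / 2)
        assert log_joint_score(word, 0, model) == pytest.approx(expected)

    def test_matching_species_outscores_nonmatching(self, two_species_disjoint):
        model = train(two_species_disjoint)
        words = tokenize_words("A" * 30 + "C" * 30, 8)
        # exhaustive arithmetic oracle over the same counts
        def brute(s):
            total = 0.0
            for c in words:
                p = (model.n_word[c] + 0.5) / (model.N + 1)
                total += math.log((model.m[s, c] + p) / (model.M[s] + 1))
            return total
        assert log_joint_score(words, 0, model) == pytest.approx(brute(0))
        assert brute(0) > brute(1)

    def test_empty_word_set_is_error(self, two_species_disjoint):
        model = train(two_species_disjoint)
        with pytest.raises(ValueError):
            log_joint_score(np.empty(0, dtype=int), 0, model)


class TestClassifyBootstrap:
    def test_disjoint_species_reaches_confidence_one(self, two_species_disjoint):
        model = train(two_species_disjoint)
        c = classify_bootstrap(model, "A" * 30 + "C" * 30, rng=0)
        assert c.taxon_at("species") == "Genus01 speciesA"
        assert c.confidence_at("species") == 1.0
        assert c.confidence_at("superkingdom") == 1.0

    def test_single_trial_confidences_are_zero_or_one(self, two_species_disjoint):
        model = train(two_species_disjoint)
        c = classify_bootstrap(model, "G" * 30 + "T" * 30, trials=1, rng=0)
        assert set(c.confidences) <= {0.0, 1.0}

    def test_confidences_are_multiples_of_one_over_trials(self, default_model):
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 150)])
        c = classify_bootstrap(default_model, seq, trials=50, rng=1)
        for conf in c.confidences:
            assert (conf * 50) == pytest.approx(round(conf * 50))

    def test_seeded_reproducibility(self, default_model):
        seq = "".join("ACGT"[i % 4] for i in range(150))
        a = classify_bootstrap(default_model, seq, rng=42)
        b = classify_bootstrap(default_model, seq, rng=42)
        assert a == b

    def test_zero_word_query_flagged_not_raised(self, default_model):
        c = classify_bootstrap(default_model, "NNNNNNNNNNNN", rng=0)
        assert c.unclassifiable
        assert all(v == 0.0 for v in c.confidences)

    def test_confidence_non_increasing_with_depth(self, default_model, default_study):
        for i, q in enumerate(default_study.queries[:25]):
            c = classify_bootstrap(default_model, q.seq, rng=i)
            confs = list(c.confidences)
            assert confs == sorted(confs, reverse=True)

    def test_batch_order_independent_substreams(self, default_model, default_study):
        full = classify_batch(default_model, default_study.queries[:4], seed=7)
        prefix = classify_batch(default_model, default_study.queries[:2], seed=7)
        assert full[:2] == prefix


class TestExhaustiveEnumerationOracle:
    """Monte-Carlo bootstrap confidence vs exact subsample enumeration.

    On a toy model with few species and a query of <=16 words, every ordered
    with-replacement subsample is enumerable, giving the exact trial-winner
    distribution; the simulated confidence must fall within binomial 3 sigma
    of the exact modal-ancestor probability.
    """

    def _toy(self):
        return make_training_set([
            ("a1", "ACACACACACAC", lineage(sp="Genus01 speciesA")),
            ("a2", "ACACACACACGT", lineage(sp="Genus01 speciesA")),
            ("b1", "TGTGTGTGTGTG", lineage(ge="Genus02", sp="Genus02 speciesB")),
            ("c1", "AGAGAGAGAGAG", lineage(ph="Phylum02", cl="Class02",
                                           od="Order02", fa="Family02",
                                           ge="Genus03", sp="Genus03 speciesC")),
        ])

    @pytest.mark.parametrize("query", [
        "ACACACACACAC",             # clear winner
        "ACACACACTGTGTGTGTGTG",     # words split between species A and B
        "AGAGAGAGAGACACACACAC",     # split between A and C
    ])
    def test_confidence_matches_enumeration(self, query):
        ts = self._toy()
        model = train(ts)
        codes = tokenize_words(query, 8)
        assert 1 <= codes.size <= 16
        k = max(1, codes.size // 8)
        # exact winner distribution by enumerating ordered subsamples
        S = np.array([[log_joint_score(np.array([c]), s, model)
                       for c in codes] for s in range(model.n_species)])
        wins = np.zeros(model.n_species)
        n_tuples = 0
        for combo in itertools.product(range(codes.size), repeat=k):
            scores = S[:, list(combo)].sum(axis=1)
            wins[int(np.argmax(scores))] += 1
            n_tuples += 1
        p_win = wins / n_tuples
        # exact per-rank modal-ancestor probability
        trials = 400
        c = classify_bootstrap(model, query, trials=trials, rng=123)
        for depth, rank in enumerate(RANKS):
            mass = {}
            for s, p in enumerate(p_win):
                mass.setdefault(model.species_paths[s][:depth + 1], 0.0)
                mass[model.species_paths[s][:depth + 1]] += p
            path, p_exact = max(mass.items(), key=lambda kv: kv[1])
            if c.taxa[depth] != path[-1]:
                continue  # near-tied modal taxon; the confidence bound
                          # below would compare different taxa
            sigma = math.sqrt(p_exact * (1 - p_exact) / trials)
            assert abs(c.confidences[depth] - p_exact) <= 3 * sigma + 1e-12


class TestAssignAtCutoff:
    def _cls(self, confs):
        return Classification("q", tuple(f"t{i}" for i in range(7)),
                              tuple(confs), n_words=10)

    def test_assigns_deepest_passing_rank(self):
        c = self._cls((1.0, 1.0, 1.0, 1.0, 1.0, 0.95, 0.6))
        assert assign_at_cutoff(c, 0.8) == ("genus", "t5")
        assert c.assigned_rank == "genus"

    def test_all_pass_gives_species(self):
        c = self._cls((1.0,) * 7)
        assert assign_at_cutoff(c, 0.8)[0] == "species"

    def test_none_pass_is_unassigned(self):
        c = self._cls((0.5,) * 7)
        assert assign_at_cutoff(c, 0.8) is None
        assert c.assigned_rank is None

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            assign_at_cutoff(self._cls((1.0,) * 7), 0.0)


class TestRemoveRestore:
    def test_remove_then_restore_is_identity(self, default_training):
        model = train(default_training)
        reference = train(default_training)
        sid = default_training.records[3].seq_id
        restore_sequence(remove_sequence(model, sid), sid)
        assert model == reference

    def test_singleton_species_drops_out_of_candidates(self, two_species_disjoint):
        model = train(two_species_disjoint)
        remove_sequence(model, "b1")
        c = classify_bootstrap(model, "G" * 30 + "T" * 30, rng=0)
        assert c.taxon_at("species") != "Genus02 speciesB"

    def test_unknown_id_raises(self, two_species_disjoint):
        model = train(two_species_disjoint)
        with pytest.raises(KeyError):
            remove_sequence(model, "nope")

    def test_double_removal_raises(self, two_species_disjoint):
        model = train(two_species_disjoint)
        remove_sequence(model, "a1")
        with pytest.raises(KeyError):
            remove_sequence(model, "a1")

    def test_decrement_equals_retrain_counts(self, default_training):
        """Count state after removal matches training without the sequence."""
        model = train(default_training)
        sid = default_training.records[0].seq_id
        remove_sequence(model, sid)
        from cpntax import TrainingSet

        smaller = TrainingSet(
            records=[r for r in default_training.records if r.seq_id != sid],
            tree=default_training.tree,
        )
        retrained = train(smaller)
        assert model.N == retrained.N
        assert np.array_equal(model.n_word, retrained.n_word)
        # species universe may differ in indexing only if a species vanished;
        # here the first record's species keeps other members or drops to 0
        for path, idx in ((p, i) for i, p in enumerate(model.species_paths)):
            if path in retrained.species_paths:
                j = retrained.species_paths.index(path)
                assert model.M[idx] == retrained.M[j]
                assert np.array_equal(model.m[idx], retrained.m[j])
            else:
                assert model.M[idx] == 0


class TestFilterNonTarget:
    def _with_phylum_conf(self, qid, conf):
        return Classification(qid, ("B",) * 7,
                              (1.0, conf, 0.0, 0.0, 0.0, 0.0, 0.0), 10)

    def test_boundary_inclusive(self):
        keep, drop = filter_non_target(
            [self._with_phylum_conf("a", 0.60), self._with_phylum_conf("b", 0.59)]
        )
        assert [c.query_id for c in keep] == ["a"]
        assert [c.query_id for c in drop] == ["b"]

    def test_empty_input(self):
        assert filter_non_target([]) == ([], [])


class TestModelSerialization:
    def test_round_trip_bit_exact(self, default_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(default_model, path)
        assert load_model(path) == default_model

    def test_version_check(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, meta=np.frombuffer(b'{"format":"other"}', dtype=np.uint8))
        with pytest.raises(ValueError):
            load_model(path)
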