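# Methods

## The classification model

`cpntax` implements a word-presence (document-frequency) naive Bayes
classifier over nucleotide 8-mers. Training reduces every reference
sequence to its set of distinct 8-mers read over ACGT-only stretches;
windows containing IUPAC ambiguity codes are skipped rather than expanded,
so an N in a read costs at most 8 words. The fitted state is the tally
N of training sequences, per-word document counts n(w), and per-species
counts M_s (sequences) and m_s(w) (sequences containing w).

A query word set W is scored per candidate species by
log P(W|s) = Σ_w log[(m_s(w) + p(w)) / (M_s + 1)] with word prior
p(w) = (n(w) + 0.5)/(N + 1). The candidate unit is the species — the
deepest rank carried by the training lineages; higher-rank results follow
from each trial winner's lineage rather than from separate per-rank models,
which makes per-rank confidence non-increasing with depth by construction
(the modal ancestor's vote count can only shrink as the path lengthens).

Bootstrap confidence: each of 100 trials draws max(1, |W|/8) words with
replacement and records the argmax species; ties break to the lowest
training-order index so a fixed seed gives bit-identical output. Per-query
RNG substreams are derived from (batch seed, query index), so classifying a
prefix of a batch reproduces the full batch's results for those queries.
Queries yielding zero words (shorter than 8 bases, or all-ambiguous) return
a flagged "unclassifiable" record instead of raising, so one bad read
cannot abort a batch.

Assignment uses the deepest rank with confidence ≥ 0.8 (the conventional
default); leave-one-out scoring uses 0.9; off-target filtering retains
queries with phylum confidence ≥ 0.6. All three, plus word size, trial
count, and the subsample divisor, live in `RunConfig`.

### Scale of the count matrix

m_s(w) is stored dense over the 4^8 = 65,536-word vocabulary
(species × 65,536 int32). This is the right trade-off up to a few hundred
species (tens of MB) and makes decremental leave-one-out a pair of vector
subtractions; reference sets with many thousands of species would want a
sparse backend, which is out of scope here.

## Leave-one-out cross-validation

Removing a sequence subtracts its contributions from N, n(w), M_s and
m_s(w); a species whose tally reaches zero leaves the candidate set. All
probabilities are recomputed from counts at classification time, so
decrement + restore is algebraically identical to retraining without the
sequence — and a test verifies classification-level equality against full
retraining on a 30-sequence fixture. A query is "accurate at rank r" when
the reported taxon matches truth at r *and* the confidence meets the
cutoff; the laxer reading (taxon match only) is obtainable by setting the
cutoff near zero. For the length study both the training and query sides
are truncated to the same 5'-anchored length before fitting (matched-length
retraining); `truncate_training=False` instead classifies truncated queries
against the full-length model.

Species with a single training sequence can never be recovered at species
rank by leave-one-out — their only evidence has been removed — so
`CVResult` reports species-rank accuracy separately for singleton and
multi-strain species rather than letting the mixture obscure both numbers.

## Nearest-neighbor comparator

The alignment engine reports, for each query, the reference with the
highest percent identity, where identity is counted over the optimal local
alignment but normalized by the **full query length**. Both strands are
searched; ties prefer the forward strand and then the earlier reference.

Scoring is EDNAFULL-style match/mismatch (+5/−4) with gap open 20 and gap
extension 10. The stiff gap penalties are deliberate: with identity
normalized by query length, permissive gap extension lets a random query
thread its bases through a long reference (approaching the longest-common-
subsequence regime) and exceed the ~55% identity floor that operationally
separates marker-gene sequences from off-target amplicons. An indel here
costs four matches, keeping optimal local hits compact — the behavior of a
seeded BLAST-then-refine search. On substitution-dominated comparisons
(the typical ASV case) gap parameters are irrelevant.

Among co-optimal alignments the identity count is not unique; the kernel
therefore maximizes (score, identities) lexicographically, which is exact
because both quantities accumulate additively along an alignment path.
This makes "identities of the optimal alignment" a well-defined function of
the sequence pair, checked against a pure-Python textbook Gotoh DP in the
tests. The kernel is numba-compiled; exhaustive search over desk-scale
reference sets (hundreds of sequences) runs at a few hundred alignments per
second, and an optional shared-k-mer prescreen can skip references without
ever changing the reported top hit.

## Curation

Lineages arrive as a TSV of taxon → seven canonical ranks (superkingdom …
species, standardizing on "superkingdom" for the top rank); empty or "NA"
cells become the placeholder `-`. Node identity in the taxonomy tree is the
full path from the root, never the bare name, so placeholder nodes under
different parents never merge. Taxa whose species slot is a placeholder or
whose name ends in " sp." are removed together with their sequences. When
one taxon name maps to several lineages, the first Bacteria/Archaea lineage
is kept (codifying the usual manual deletion of same-named eukaryotes); a
taxon with only non-prokaryotic lineages is an error. Duplicate sequences
are collapsed by exact string equality after uppercasing — no
reverse-complement or substring collapsing — keeping the first occurrence
and logging label conflicts. Provenance counts (raw → lineage-resolved →
deduplicated) ride along on the training set.

## The synthetic benchmark

The generator emulates a curated barcode reference collection and its
query workload:

- **Taxonomy**: 8 genera nested under 4 phyla (one class per phylum, one
  order/family per genus), each genus holding 3 multi-strain species
  (3 strains each) and 14 singleton species. The singleton-heavy mix
  mirrors real curated barcode databases, which favor taxonomic breadth
  over redundant per-species records; it also reproduces the observed
  behavior that roughly half of reference sequences have no non-identical
  conspecific partner and that off-target queries scatter across many
  low-count species instead of collapsing onto one. Edge cases planted by
  default: a singleton genus whose class rank is `-`, an unresolvable
  "Genus10 sp." taxon, and one exact duplicate sequence.
- **Sequences**: 555 bp, evolved root → genus → species → strain by
  substitution only, with per-site substitution probabilities 0.25 / 0.08 /
  0.01. Substitution-only evolution keeps expected pairwise identity
  analytic — two descendants of one ancestor at rate p agree per site with
  probability (1−p)² + p²/3 — which the calibration test checks. Indels are
  exercised separately in the aligner tests.
- **Queries**: one 150 bp 5'-anchored truncation per reference with 0.5%
  independent substitution errors, plus a truth table; 200 off-target
  queries drawn uniformly over ACGT. Uniform randomness matches the
  operational definition of off-target (<55% identity to any reference)
  rather than modelling diverged homologs.
- **Determinism**: every stage draws from its own fixed substream of the
  study seed, so outputs are byte-identical for a given seed regardless of
  which stages are invoked.

What the benchmark does *not* emulate: real barcode length variation,
compositional bias, indel-containing ASVs, chimeras, or abundance
structure. Passing tests therefore demonstrate correctness of the
machinery and recoverability under idealized divergence structure, not
field performance on real microbiome data.

## Numerical and design notes

- Scores are summed in log space; no underflow for any realistic word
  count.
- Bootstrap confidences are exact multiples of 1/trials.
- The Spearman comparison of matched-length vs full-length training uses
  scipy's large-sample t approximation for the p-value at every n; exact
  permutation is factorial and adds nothing at the benchmark's n.
- Model serialization is a single `.npz` container (format name + version
  in an embedded JSON header) that round-trips every count bit-exactly;
  the taxonomy text dialect is the asterisk-delimited
  `taxid*name*parent*depth*rank` layout with fixed root row
  `0*Root*-1*0*rootrank`, also round-trip tested.
- Problem sizes used by the shipped evaluation (185 training sequences,
  387 queries, 5 truncation lengths) were chosen so the whole benchmark,
  including the exhaustive nearest-neighbor search, completes in a few
  minutes on one CPU while still exercising every curation and evaluation
  branch.

## Known limitations

- Dense count storage bounds practical training sets to a few hundred
  species (see above).
- The 55% identity floor and the 0.6/0.8/0.9 confidence constants are
  conventions of the cpn60 workflow; other barcodes need their own
  calibration.
- The nearest-neighbor engine reports a single best hit; no E-values or
  multi-hit output.
- With very few singleton species in a *custom* simulation, off-target
  queries can deterministically attract to the species with the smallest
  sequence tally (the M_s+1 denominator); this is a property of the naive
  Bayes formula at small scale, visible in any sparsely covered reference
  set, and is why the default benchmark is singleton-rich.
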