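# Methods

## Concepts, vocabularies and surface normalisation

Every entity in the system is a *concept*: an id, one concept type out of a
closed set (`DISEASE`, `PATHOLOGICAL_OBSERVATION`, `ANATOMICAL_STRUCTURE`,
`PROTEIN_OR_MRNA`, `GENE_MUTATION`, `BIOLOGICAL_PROCESS`), a preferred label,
and a synonym set that always contains the preferred label.  Text maps onto
concepts through a normalised surface index.  Normalisation is deliberately
shallow:

- case folding and whitespace collapse;
- hyphens and underscores treated as token separators, which makes `BACE-1`,
  `BACE 1` and `BACE_1` equivalent (but *not* equal to the unhyphenated
  symbol `BACE1` — that equivalence, where wanted, is a synonym row);
- Greek letters spelled out (`β` ↔ `beta`, `α` ↔ `alpha`, …), so `IL-1β`
  and `IL-1beta` coincide;
- typographic apostrophes unified with ASCII ones.

No stemming or fuzzy matching is applied: synonym lists are assumed
exhaustive, and stemming risks merging distinct biomedical terms.  When the
source table carries no ids, ids are slugified preferred labels
(`Alzheimer's Disease` → `alzheimer-s-disease`).

Term matching is longest-match: all candidate synonym spans in a sentence
are enumerated and selected greedily by (token length descending, start
ascending) into a non-overlapping, sorted mention list.  A surface that maps
to several concepts yields one multi-concept mention; disambiguation is
deferred first to extraction type constraints and ultimately to curation.

## Relation lexicon and canonical direction

Relation verb phrases are grouped into five classes — `EXPRESSION`,
`UPREGULATION`, `PATHOLOGY_LINK`, `DISEASE_LINK`, `PATHWAY_MEMBERSHIP` —
each with canonical preferred relations (e.g. `IS EXPRESSED IN`,
`IS INCREASED IN`, `IS INVOLVED IN`, `IS ASSOCIATED WITH`) and surface
forms, with surfaces disjoint across classes.  Structure-side verbs
(`EXPRESSES`, `HAS CONSTITUENT`, `IS LOCATION OF`, `IS SITE OF ALTERATION
OF`, `HAS UPREGULATED`) are inverted on storage so that every stored triple
runs in one canonical direction (protein → structure, protein → disease).
One canonical direction makes the derivation queries single-sided.  A
network map (`RELATION_TYPE_MAP`) fixes which (subject type, object type)
pairs each class admits; it gates both extraction and table ingestion.

## Extraction

Documents are split into sentences at `.!?` + whitespace + capital/digit
boundaries, with an abbreviation guard (single capitals, `e.g.`, `et al.` …)
that can be turned off.  Extraction is strictly within-sentence: for each
relation phrase found in a sentence, every (subject mention before the verb,
object mention after the verb) pair within a token-gap bound (default 10
tokens per gap) and with an admissible type pair yields one proto-assertion
with status `PROTO`, provenance (source, doc, sentence, snippet) attached.
Negation cues (`not`, `no`, `never`, `failed to`, `absence of`) occurring
before the verb suppress extraction for that verb; negation *after* the verb
(e.g. "… but not thalamus") is deliberately left to curation, since the cue
scope is not decidable lexically.  Cross-sentence assertions and coreference
are out of scope: they cost precision without a linguistic layer and the
within-sentence rule keeps the pipeline reproducible.

Curation is a decision table keyed by (subject, relation, object, doc,
sentence); contradictory decisions are an error, unmatched decisions a
warning.  Accuracy of an accepted batch is audited by a simplified
single-sampling acceptance plan: sample `n` assertions without replacement
(default n = 125, acceptance number c = 3, seed mandatory), count errors
against a truth oracle, pass iff errors ≤ c.  The report carries point
accuracy 1 − errors/n and an exact Clopper–Pearson 95 % binomial interval.
When the plan size reaches the population a census is taken and the
accuracy is exact.  The (125, 3) default corresponds to a typical general
single-sampling plan for batches of a few thousand items near 1 % AQL; the
full ISO-style switching rules are not implemented.

## Structured-table ingestion

A mapping spec names subject/object columns, declares their types, fixes one
relation, optionally filters rows on constant column values, and declares a
direction (`forward`/`inverse`) for tables listed structure-first.  Each row
whose two surfaces resolve to a *unique* concept of the declared type
becomes one `ACCEPTED` assertion with row-level provenance (1-based data-row
number as doc id); unresolved, ambiguous and filtered rows are counted in a
skip report, so emitted + skipped always equals the row count.

## The network store

The intelligence network keys assertions by (subject, preferred relation,
object) — not by relation class — so distinct verbs between the same pair
stay distinct; class-level queries aggregate at read time.  Identical
triples merge by provenance union with deduplication, making merge
commutative and idempotent on the triple set; only `ACCEPTED` assertions are
admitted and every endpoint must exist in the concept table.  Serialisation
is a `.inet` directory (concepts TSV + assertions JSONL), sorted before
writing, so exports are byte-deterministic regardless of insertion order.

## Candidate derivation

`derive_candidates` chains three subset filters (expression in configured
regions → upregulation in configured diseases → pathology association) with
an evidence threshold of ≥ 1 supporting assertion per criterion
(configurable via `min_support`; the method is an existence filter, not a
ranking).  Novelty is decided only against provenance sources explicitly
tagged as biomarker-claim sources; with no tagged sources the verdict is
*indeterminate* rather than a silent "novel", because a false novelty claim
is worse than abstention.  Output is audited: per-step id sets and counts,
and per-candidate supporting triple keys, all deterministically ordered.

## Synthetic corpora

The generator plants a truth triple list into documents built from six
affirmative sentence frames (one of which interposes an eight-token relative
clause to stress the gap bound), with subject/object surfaces sampled from
synonym sets and verbs from forward surface forms when synonym substitution
is on.  Noise comes as distractor sentences (two vocabulary terms joined by
non-lexicon verbs) and negated variants (a truth triple with a cue before
the verb — generated, but *not* gold).  Defaults: 6 sentences per document,
synonym substitution on, noise rates 0, seed mandatory; every text-routed
truth triple is guaranteed at least one realisation, and a configurable
share of the truth can be emitted as structured-table rows instead.  Two
generator details exist purely to keep segmentation unambiguous: every
sentence starts with a capital, and no frame ends directly at a term (a
trailing "Apolipoprotein E." would look like an initial to the abbreviation
guard).

What the generator does **not** emulate: real abstract prose (hedging,
coordination, anaphora, enumerations), cross-sentence statements, OCR noise,
or ambiguous synonyms shared between concepts.  Perfect precision/recall on
clean synthetic corpora therefore demonstrates the internal consistency of
matcher + lexicon + extractor, not performance on PubMed text; the noisy
configurations (distractors, negation) probe robustness only against the
noise types the extractor claims to handle.

Scoring matches triples at (doc, sentence) granularity; precision, recall
and F1 report `None` (undefined), never 0, on empty denominators.

## Golden fixture

The shipped vocabulary fixture carries 13 disease sub-types, 44
pathological observations and 26 brain regions, plus a 25-protein candidate
vocabulary keyed by standard symbols.  The golden network adds 35 synthetic
filler proteins and plants assertions so the chain runs exactly 40 → 30 →
25: all 25 vocabulary proteins plus 15 fillers are expressed in regions,
the 25 plus 5 fillers are upregulated in Alzheimer's disease, and only the
25 carry pathology links.  Ten further decoys fail an earlier gate
(upregulated-but-not-expressed, pathology-linked-but-not-upregulated) to
verify that the filters really intersect.  Tagged biomarker-claim links
(`IS BIOMARKER FOR`, source `Telemakus`) exist for 23 of the 25, leaving
`PLAUR` and `CHAT` novel.

## Validation statistics

- **ANOVA** (raw): textbook one-way fixed-effects decomposition, p from the
  F(k−1, N−k) tail.  All-equal data returns F = 0, p = 1; zero within-group
  variance with a real between-group effect raises (F unbounded) rather than
  returning infinity.
- **ANOVA from summaries**: SS_between from group means about the weighted
  grand mean, SS_within = Σ(nᵢ−1)sᵢ².  This equals the raw ANOVA on any
  table with those summaries (tested to 1e-10 relative tolerance).
- **Spearman**: average ranks for ties, rho = Pearson on ranks.  The
  two-sided p is an exhaustive permutation test for n ≤ 8 (ranking commutes
  with permutation, so centred ranks are permuted directly) and the t
  approximation `t = rho·√((n−2)/(1−rho²))`, df = n−2, above that — the
  approximation is standard at the validation-cohort sizes (~80 per group),
  and exhaustive enumeration beyond n = 8 buys no practical accuracy for
  its factorial cost.  Constant inputs raise (rho undefined).
- **Normality**: Kolmogorov–Smirnov distance against a normal fitted by
  sample mean/SD.  Because the null parameters are estimated, the classical
  KS tail is wrong (Lilliefors); the p-value is a seeded Monte-Carlo
  estimate with the (b+1)/(B+1) continuity adjustment, default B = 2000.
  Shapiro–Wilk is not re-implemented; this KS/Lilliefors check is the
  package's single normality gate.
- "Corrected for protein loading" measurements are modelled as a pre-divided
  value column; no loading-correction algorithm is implemented because the
  correction is upstream of the statistics.
- No multiple-testing machinery and no hard-coded significance threshold:
  raw p-values are reported.

## Problem sizes and numerical choices

The synthetic evaluations use 200 documents × 6 sentences for the
extraction round trips, 60 documents for the end-to-end recovery, 500
seeded runs for the QC-coverage calibration, 100 random tables for the
ANOVA oracle comparison, and networks of ≤ 100 assertions for the
derivation oracle — sizes at which the brute-force oracles are exact and
the suite stays interactive.  Ties in term matching break by earliest
start; JSON is written with sorted keys and stable separators; all
randomness flows through explicit seeds (`random.Random` for sampling,
`numpy` Generators for simulation).

## Known limitations

- Dictionary-based matching only: no learned NER, no part-of-speech
  filtering, so an exhaustive synonym list is a hard requirement.
- The negation rule is lexical and pre-verbal only; post-verbal negation
  scope ("expressed in X but not Y") reaches curation as a false pairing.
- One assertion per distinct triple per sentence: repeated statements inside
  one sentence collapse.
- Sentences whose final token is a single capital letter merge with the next
  sentence when the abbreviation guard is on.
- The derivation is a boolean filter, not a score: it cannot rank candidates
  within the surviving set.
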