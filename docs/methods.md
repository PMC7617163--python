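# Methods

This note records the models, rules and numerical conventions the
package implements, the choices made where the design was genuinely
open, and what the synthetic fixtures do and do not demonstrate.

## Record model and deduplication

A citation record carries the searchable fields (title, abstract,
keywords), provenance (source database, accession map), and the metadata
the downstream rules need (DOI, year, authors, journal, pages,
publication type, retrieval date, retraction flag). DOIs are normalised
by lower-casing and stripping resolver prefixes (`https://doi.org/`,
`dx.doi.org`, `doi:`). uids prefer the source accession
(`pubmed:12345`), then the DOI, then a content hash of the normalised
title/year — so re-ingesting a file reproduces the same uids.

Two records are duplicates when (a) their normalised DOIs are identical,
or (b) there is no DOI conflict (at most one side has a DOI) **and**
their normalised titles have edit-distance similarity ≥ 0.95 **and**
they share the publication year and first-author surname. Title
normalisation lower-cases, folds diacritics (NFKD), and collapses
punctuation and whitespace runs; similarity is
`difflib.SequenceMatcher.ratio`. Groups are the transitive closure of
pairwise matches (union–find with a deterministic root rule), so the
result is independent of input order and idempotent. The kept member is
chosen by: has an abstract → has a DOI → smallest uid; empty fields of
the kept record are filled from the other members in uid order, and
accession maps are merged. Full parity with dedicated deduplication
services (manual-review queues, learned field weights) is a non-goal;
these rules are declared, versioned and replayable.

Incremental search updates deduplicate the incoming batch internally,
then against the existing records retrieved within a look-back window
(default 62 days — a conservative reading of "the previous two months").
Older duplicates slip through by design and are caught by the periodic
full deduplication pass; records missing retrieval dates degrade to
comparison against the whole store, with a logged warning.

Abstract-only flagging is deliberately conservative: a record is flagged
only when it lacks a usable full text (none attached, or fewer than
`min_words` = 500 words) **and** the metadata gives positive evidence —
a meeting/conference-abstract publication type or single-page
pagination. Absent metadata leaves the flag false. Flagged and retracted
records are excluded from all reporting but never deleted.

## Dictionaries

Terms expand over three axes before compilation:

- **separators** — every inter-token gap generalises over
  `{"", " ", "-", "*", "x", "×", " x ", " × "}`; a lone `x` between a
  digit and an uppercase letter is itself treated as a separator, so
  `3xTg` and `3 × Tg` are the same term. With more than three gaps the
  set drops to `{"", " ", "-"}` to bound the product (cap 4096 variants).
- **case** — mixed-case tokens also match fully upper-cased (`Tg`→`TG`);
  matching is case-insensitive except for short all-caps acronyms (≤ 3
  alphabetic characters, e.g. `AD`), which default to case-sensitive to
  limit spurious hits; a per-entry CSV override exists.
- **Greek** — Greek letters gain a transliterated variant (β→beta) with
  the original kept, so `Aβ` and `Abeta` co-match. The domain's
  literature uses both freely.

A trailing hyphen-separated `AD` token is optional (`3xTg-AD` also
matches `3 × Tg`): Alzheimer model names carry the disease suffix
inconsistently across journals. This is the package's declared
convention, as is the variant set above — the original pipeline's
expansion rules are not published, only their intent.

Word characters are letters **and digits**; underscore is a boundary.
Anchoring uses the lookarounds `(?<![^\W_]) … (?![^\W_])`, which blocks
`PAPP` and `APP23` while `APP/PS1` matches (the slash is a boundary).
Alternations are ordered longest-variant-first, so within one label the
longest synonym wins at a position and consumes its span — "Morris water
maze (MWM)" counts 2, not 3. Different labels may claim overlapping
spans: a text can legitimately evidence two models at once, and
cross-label exclusion would hide real co-mentions. A lexicon's version
is a content hash of its CSV and is stamped into every downstream tag
assignment; compiled dictionaries export as `label<TAB>expression` for
audit.

The model-sentence extractor truncates the document at a references
heading (mentions of models in cited titles are not evidence of use),
splits sentences with a rule-based splitter (terminator + whitespace +
capital, guarded by an English abbreviation list — no statistical model,
for determinism), and keeps sentences containing at least one cue
phrase. The default cue list (`obtained from`, `purchased from`,
`generated`, `bred`, `backcrossed`, `background`, `Jackson`,
`Charles River`, `transgenic`) is versioned configuration: the original
extraction pattern is unpublished, so parity is not claimed — the cue
list is the declared substitute and is validated through the harness,
not assumed.

## Tagging policy

The three surfaces are: `tiabkw` (title, abstract and keywords joined
with newline sentinels so no variant can match across fields), the full
text, and the concatenated extracted model sentences (model, sex and
species dictionaries only; intervention dictionaries are applied to
tiabkw alone because drug synonyms are too unspecific in full text).
When no full text is attached the full-text and model-sentence results
are omitted, not zero-filled — "no text to search" is distinct from
"searched and found nothing". Published threshold language of the form
"> 1 matches" is read strictly as count ≥ 2.

Assignments are a pure function of the stored per-surface counts and the
policy, so they can be replayed; the high-sensitivity toggle (any
full-text mention of a model, intervention or outcome) is likewise
replayable from stored evidence and is monotone — its assignment set is
a superset of the default's. Incremental corpus tagging reuses a
previous run only when both the lexicon-version map and the policy
version match exactly; any change forces a full re-tag, trading compute
for auditability.

## Validation harness and policy selection

True sensitivity of a dictionary cannot be measured without an
exhaustive gold standard, so the harness scores each method against the
union of human-verified tags found by **any** method: TP = the method's
verdict-true proposals, FP = its verdict-false proposals, FN = verified
tags it missed, TN = verdict-false candidates it did not propose. This
is the only reading that conserves TP + FN = |reference set| per method,
which the shipped reference table satisfies row by row. Sampled records
excluded during review (e.g. conference abstracts) are annotation rows
with a `skip` marker and take no part in any count. The eligible
sampling stratum requires ≥ 1 match per required category on every
applicable surface.

Metrics are kept as raw fractions; reported values are rounded to three
decimals, round-half-up, computed in exact integer arithmetic
(`(2·num·10³ + den) // (2·den)`), with a metric undefined exactly when
its denominator is zero.

Policy selection admits methods with precision strictly above
`floor − tolerance` (defaults 0.80 and 0.01; admissions at or below the
floor are warned as near misses — the tolerance exists because the
published selection itself admitted a 0.793-precision method under a
"> 0.80" rule). Per category the policy enables tiabkw when admitted
plus one non-tiabkw method: among admitted non-tiabkw methods within a
precision band (default 0.05) of the best, the one with the highest
sensitivity. The band operationalises "similar precision → prefer
sensitivity"; without it, a maximally sensitive but near-useless method
(specificity 0.05) would displace the model-sentence surface for sex. A
category whose only scored surface fails the floor keeps that sole
surface with a warning (the intervention case); when several methods
were scored and none is admitted, selection errors out and asks for a
manual choice.

The shipped reference table carries both the published confusion counts
and the published 3-decimal metric cells. The sensitivity and
specificity columns reproduce exactly from the counts; the model
category's precision column does not (printed 0.404/0.526/0.652/0.883/
0.793 vs computed 0.407/0.531/0.651/0.881/0.790), nor does the
intervention precision (printed 0.417 vs 85/202 = 0.421). The defining
formulas are authoritative for everything this package computes;
`reference_validation_table()` returns the table as printed (that is
what the published policy was selected from), and
`recompute_reference_metrics()` returns the counts rescored. Similarly,
of the published coverage percentages only the outcome figure
(16390/35546 = 46.1%) is consistent with its own quotient at 1-decimal
half-up rounding.

## Screening

The production classifier behind the published workflow is an externally
hosted service and is not reproducible; this module fixes the contract —
a deterministic-given-seed map from title+abstract text to an inclusion
probability — and ships a bag-of-words logistic regression as the
transparent baseline. Ties at the decision threshold count as included
(score ≥ threshold, default 0.5). Evaluation uses a stratified held-out
split (default 20%), a declared choice since the original validation
protocol is unstated; each evaluation appends a uniquely numbered run to
a CSV log, and drift flagging reports runs below declared floors
(defaults 0.90 sensitivity, 0.85 specificity). The published corpus
averages (95.1%/93.7%) depend on that external service and corpus and
are not targets here.

## Synthetic fixtures

The generator emulates the features the pipeline must be robust to:
terms planted in the title, abstract, full-text body, a provenance
sentence, or only in the references section; confusable strings that a
correct boundary rule must reject; duplicate records with
case/punctuation-perturbed titles; and screening sets drawn from
in-vivo vs clinical vocabularies whose overlap is controlled by a shift
parameter (0 = separable, 1 = identical distributions). Filler prose is
template sentences with slots — not character soup — so sentence
splitting and cue detection are realistically exercised, and it is
deliberately free of every dictionary term. The default dictionaries are
small enough to hand-verify: 12 models, 10 outcomes, 15 interventions,
4 species, 2 sexes.

Ground truth is defined as the tags the supplied policy is *expected* to
assign given the planted counts (a single full-text outcome mention is
below the two-mention threshold by design; references-only placements
contribute nothing). Passing recovery tests therefore demonstrates the
internal consistency of matcher, policy and generator — exact recovery
(precision = sensitivity = 1.0) on clean fixtures — not performance on
real literature, where synonym coverage, OCR noise, hyphenation across
lines and non-template prose dominate. The published validation table is
the only link to real-corpus performance in this package.

Sizes used by the default test and acceptance runs (the package's own
choices): 50–100-record corpora, 1000 random short texts for the
brute-force match oracle, an exhaustive metric sweep over confusion
counts ≤ 10 plus 20 000 seeded random 4-tuples with entries ≤ 500, and
200-text screening sets. All randomness is seed-driven; two runs with
the same seed are byte-identical.

## Known limitations

- Dedup thresholds (0.95 title similarity) are declared, not fitted;
  records with missing years or authors only merge via DOI.
- The sentence splitter mishandles unusual abbreviations and list-heavy
  prose; the references-heading detector requires the heading on its own
  line.
- Pathological (non-behavioural) outcome dictionaries, non-rodent model
  coverage, and statistical NER are out of scope, as are live database
  clients, PDF conversion, open-data detection and risk-of-bias scoring
  (accepted as input columns where relevant).
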