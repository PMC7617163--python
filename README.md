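# soles

A curation engine for **systematic online living evidence summaries**
(SOLES) of preclinical literature — built around the workflow used to
maintain a living evidence map of in vivo Alzheimer's disease research.

A SOLES pipeline continuously retrieves citations from bibliographic
databases, removes duplicate records, screens titles and abstracts for
in-vivo relevance, and tags each study by the **animal model**,
**intervention**, **outcome measure**, **species** and **sex** it
reports — so that researchers, funders and reviewers can see at a glance
what evidence exists and where the gaps are. This package implements the
curation core of that workflow as an importable library with a thin
`soles` command-line layer:

- **ingest** — readers/writers for RIS, MEDLINE/PubMed XML and a flat CSV
  dialect; DOI/title normalisation; deterministic fuzzy deduplication;
  incremental search-update merging; meeting-abstract flagging.
- **lexicon** — term lists compiled to boundary-anchored regular
  expressions with separator/case/Greek variant expansion, plus a
  rule-based extractor for full-text "model sentences" (where an animal
  model was obtained or how it was generated).
- **tagging** — match counting on three surfaces (title/abstract/keywords,
  full text, model sentences) combined under a per-category
  frequency-threshold policy with a high-sensitivity toggle.
- **screening** — a pluggable scorer contract with a transparent
  bag-of-words logistic baseline, held-out evaluation, an append-only run
  log, and drift flagging.
- **evaluation** — the tagging-validation harness: stratified sampling,
  scoring of methods against human TRUE/FALSE verdicts (sensitivity
  computed against the union of verified tags across all methods), and
  mechanical selection of the optimal combination policy.
- **reporting** — per-year counts, coverage tables, co-occurrence gap
  maps, and Boolean AND/OR filtered exports.
- **fixtures** — synthetic corpora with planted ground truth, confusable
  strings and known duplicates, so the whole pipeline is testable offline.

## The tagging model

Each dictionary label ℓ compiles to an alternation over its expanded
surface variants, anchored as `(?<![^\W_]) (v₁|v₂|…) (?![^\W_])` so that
letters **and digits** are word characters: `APP` never matches inside
`PAPP` or `APP23`, while `APP/PS1` still splits at the slash. For a
citation *c*, let *n*₍tiabkw₎, *n*₍ft₎, *n*₍ms₎ be the non-overlapping
match counts of ℓ on the three surfaces. The validated default policy
assigns ℓ when

| category              | rule                                   |
|-----------------------|----------------------------------------|
| model, species, sex   | *n*₍tiabkw₎ ≥ 1 **or** *n*₍ms₎ ≥ 1     |
| outcome               | *n*₍tiabkw₎ ≥ 1 **or** *n*₍ft₎ ≥ 2     |
| intervention          | *n*₍tiabkw₎ ≥ 1                        |

and the high-sensitivity toggle additionally admits *n*₍ft₎ ≥ 1 for
model, intervention and outcome. Validation metrics follow the standard
confusion-matrix definitions: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F1 = 2TP/(2TP+FP+FN); a method is
admitted into the policy when its precision exceeds 0.80 (within a 0.01
tolerance), and among admitted full-text/model-sentence methods of
similar precision the most sensitive is preferred.

## Worked example

```python
from soles import TermEntry, compile_term, select_policy
from soles.tagging import count_matches
from soles.evaluation import reference_validation_table

app = compile_term(TermEntry("APP", "model"))
for text in ("the APP gene", "PAPP", "APP23"):
    print(text, "->", count_matches(app, text).count)

selection = select_policy(reference_validation_table(),
                          precision_floor=0.80, tolerance=0.01)
print(selection.policy.rules["outcome"])
```

prints

```
the APP gene -> 1
PAPP -> 0
APP23 -> 0
CategoryRule(tiabkw_min=1, fulltext_min=2, model_sentence_min=None)
```

— the boundary rule rejects both confusables, and the policy derived
from the shipped validation table enables, for outcomes, one
title/abstract/keyword mention or two full-text mentions. The
`examples/` directory contains one narrative script per capability
(ingest+dedup, dictionary compilation, corpus tagging, validation and
policy selection, screening and reporting); each prints the numbers it
computes with a note on what they mean.

## Scope

Live database/API clients (PubMed, Web of Science, Scopus, Unpaywall,
CrossRef, OpenAlex), PDF/XML-to-text conversion, the hosted screening
service, open-data detection and risk-of-bias scoring tools, and the web
dashboard itself are out of scope; retraction status and
open-access/risk-of-bias scores are accepted as input columns, and this
package emits the dashboard-ready tables.
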