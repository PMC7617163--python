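"""Evaluate a screening scorer and build dashboard tables from a tagged corpus.

A bag-of-words logistic scorer is trained on synthetic in-vivo vs
clinical decisions, evaluated on a stratified held-out split, and logged
as a numbered run; drift tracking flags runs breaching the declared
sensitivity/specificity floors. The tagged corpus then feeds the
dashboard aggregations: per-year counts, coverage, a gap-map crosstab,
and a Boolean filtered export.
"""

from soles import (
    FilterQuery,
    counts_by_year,
    crosstab,
    evaluate_run,
    export_filtered,
    generate_corpus,
    generate_screening_set,
    performance_drift,
    tag_coverage,
    tag_corpus,
    train_scorer,
)
from soles.fixtures import Planting, SyntheticSpec, default_lexicons
from soles.screening import stratified_split

# --- screening ------------------------------------------------------------
texts, decisions = generate_screening_set(n_pos=80, n_neg=80, vocabulary_shift=0.2, seed=5)
train, test = stratified_split(decisions, test_fraction=0.2, seed=5)
scorer = train_scorer(train, texts, seed=5)
run = evaluate_run(scorer.score_many({d.uid: texts[d.uid] for d in test}), test,
                   run_id=1, train_size=len(train))
m = run.metrics.rounded()
print(f"screening run 1: sensitivity {m['sensitivity']}, specificity {m['specificity']}, "
      f"F1 {m['f1']} on {run.counts.total} held-out records")
print(f"runs breaching the 0.90/0.85 floors: {performance_drift([run])}")

# --- reporting ------------------------------------------------------------
spec = SyntheticSpec(
    n_citations=40,
    planted=[Planting("model", "APP/PS1", "title"),
             Planting("intervention", "donepezil", "abstract"),
             Planting("outcome", "Morris water maze", "abstract")],
    seed=8,
)
citations, fulltexts, _ = generate_corpus(spec)
tagged = tag_corpus(citations, fulltexts, default_lexicons())

years = counts_by_year(citations)
print(f"\npublications per year: {years}")
print("tag coverage (of 40 records):")
print(tag_coverage(tagged, total=40).to_string(index=False))

gap = crosstab(tagged, "intervention", "model").to_frame()
print(f"\ngap map cell donepezil x APP/PS1: {gap.loc['donepezil', 'APP/PS1']} citations")

subset = export_filtered(citations, tagged,
                         FilterQuery(text_terms='donepezil AND "water maze"'))
print(f"Boolean filter kept {len(subset)} of {len(citations)} records")
# Every record carries both terms in its title/abstract, so the filter
# keeps all of them; narrowing the query narrows the export.
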