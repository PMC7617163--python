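"""Tag a synthetic corpus and compare the default and high-sensitivity policies.

The generator plants a model name in every title, an intervention only in
the full-text body, and species/sex in a provenance ("model") sentence.
Under the default policy an intervention mentioned only in the full text
is NOT tagged — drug synonyms are too unspecific there — but the
high-sensitivity toggle admits any full-text mention.
"""

from soles import default_policy, generate_corpus, tag_corpus
from soles.fixtures import Planting, SyntheticSpec, default_lexicons

spec = SyntheticSpec(
    n_citations=30,
    fulltext_fraction=0.8,
    planted=[
        Planting("model", "5xFAD", "title"),
        Planting("intervention", "memantine", "fulltext_body", copies=2),
        Planting("species", "mouse", "model_sentence"),
    ],
    seed=42,
)
citations, fulltexts, truth = generate_corpus(spec)
lexicons = default_lexicons()

tagged = tag_corpus(citations, fulltexts, lexicons, default_policy())
relaxed = tag_corpus(citations, fulltexts, lexicons, default_policy(high_sensitivity=True))

for category in ("model", "species", "intervention"):
    n_default = len(tagged.assigned_uids(category))
    n_relaxed = len(relaxed.assigned_uids(category))
    print(f"{category:12s} default: {n_default:3d} tagged   high-sensitivity: {n_relaxed:3d}")
# model: 30/30 (title mention suffices), species: 24/24 (the 80% of
# records with a full text carry a provenance sentence), intervention:
# 0 under the default policy vs 24 with the toggle — the superset
# behaviour a systematic-review export relies on.

example = next(a for a in relaxed.assignments if a.category == "intervention" and a.assigned)
print(f"evidence behind {example.label!r} on {example.uid}: {example.evidence}")
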