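"""Match counting, the combination policy, and whole-corpus tagging."""

import random

import pytest

from soles.fixtures import Planting, SyntheticSpec, generate_corpus
from soles.ingest import CitationRecord, FullTextDocument
from soles.lexicon import TermEntry, build_lexicon, compile_term
from soles.tagging import (
    CategoryRule,
    PolicyError,
    MatchResult,
    TagPolicy,
    apply_policy,
    count_matches,
    default_policy,
    tag_corpus,
    tag_fields,
)


# ---------------------------------------------------------------------------
# count_matches


def test_longest_synonym_wins_and_consumes_its_span():
    pat = compile_term(
        TermEntry("Morris water maze", "outcome", synonyms=["water maze", "MWM", "Morris maze"])
    )
    result = count_matches(pat, "The Morris water maze (MWM) was used")
    assert result.count == 2
    texts = ["The Morris water maze (MWM) was used"[a:b] for a, b in result.spans]
    assert texts == ["Morris water maze", "MWM"]


def test_count_matches_empty_text():
    pat = compile_term(TermEntry("APP", "model"))
    result = count_matches(pat, "")
    assert result.count == 0 and result.spans == []


def test_app_counted_once_among_confusables():
    pat = compile_term(TermEntry("APP", "model"))
    assert count_matches(pat, "PAPP and APP and APP23").count == 1


# brute-force oracle: test every substring against every variant, apply the
# boundary rule by hand, then select leftmost-longest non-overlapping spans


def _is_word_char(ch: str) -> bool:
    return ch.isalnum() and ch != "_"


def brute_force_spans(pattern, text):
    norm = (lambda s: s) if pattern.case_sensitive else (lambda s: s.lower())
    variants = {norm(v) for v in pattern.variants}
    lengths = sorted({len(v) for v in variants})
    candidates = []
    n = len(text)
    for i in range(n):
        if i > 0 and _is_word_char(text[i - 1]):
            continue
        for length in lengths:
            j = i + length
            if j > n or (j < n and _is_word_char(text[j])):
                continue
            if norm(text[i:j]) in variants:
                candidates.append((i, j))
    candidates.sort(key=lambda span: (span[0], -(span[1] - span[0])))
    chosen, cursor = [], 0
    for a, b in candidates:
        if a >= cursor:
            chosen.append((a, b))
            cursor = b
    return chosen


_FRAGMENTS = [
    "APP", "PAPP", "APP23", "app", "Morris water maze", "water maze", "MWM",
    "maze", "3xTg-AD", "3 × Tg", "3xTg", "Tg", "mice", "the", "23", "/PS1",
    " ", " ", "-", "(", ")", ". ", "x", "3",
]


def test_count_matches_agrees_with_brute_force_oracle_on_random_texts():
    patterns = [
        compile_term(TermEntry("APP", "model")),
        compile_term(TermEntry("Morris water maze", "outcome",
                               synonyms=["water maze", "MWM", "Morris maze"])),
        compile_term(TermEntry("3xTg-AD", "model", synonyms=["3xTg"])),
    ]
    rng = random.Random(42)
    for _ in range(1000):
        text = "".join(rng.choice(_FRAGMENTS) for _ in range(rng.randint(1, 14)))[:200]
        for pat in patterns:
            got = count_matches(pat, text)
            assert got.spans == brute_force_spans(pat, text), (pat.label, text)


# ---------------------------------------------------------------------------
# tag_fields


def _lexicon_for(label, category, synonyms=()):
    return build_lexicon([TermEntry(label, category, synonyms=list(synonyms))],
                         category, version="t1")


def test_tag_fields_covers_each_available_surface():
    citation = CitationRecord(uid="c1", title="A 5xFAD study", abstract="", keywords=[])
    doc = FullTextDocument("c1", text=(
        "The 5xFAD line was obtained from The Jackson Laboratory. "
        "Separate 5xFAD cohorts were compared."
    ))
    results = tag_fields(citation, doc, _lexicon_for("5xFAD", "model"))
    by_field = {r.field: r for r in results}
    assert by_field["tiabkw"].count == 1
    assert by_field["fulltext"].count == 2
    assert by_field["model_sentence"].count == 1  # only the provenance sentence


def test_tag_fields_without_fulltext_omits_rather_than_zerofills():
    citation = CitationRecord(uid="c1", title="No mention here")
    results = tag_fields(citation, None, _lexicon_for("5xFAD", "model"))
    assert {r.field for r in results} == {"tiabkw"}
    assert results[0].count == 0


def test_intervention_gets_no_model_sentence_surface():
    citation = CitationRecord(uid="c1", title="donepezil trial")
    doc = FullTextDocument("c1", text="Animals were obtained from a supplier. donepezil given.")
    results = tag_fields(citation, doc, _lexicon_for("donepezil", "intervention"))
    assert {r.field for r in results} == {"tiabkw", "fulltext"}


def test_tiabkw_sentinel_blocks_cross_field_matches():
    # "water" ends the title, "maze" starts the abstract: not a match
    citation = CitationRecord(uid="c1", title="Effects on water", abstract="maze data follow")
    lex = _lexicon_for("water maze", "outcome")
    results = tag_fields(citation, None, lex)
    assert results[0].count == 0


# ---------------------------------------------------------------------------
# apply_policy


def _mr(uid, label, category, field, count):
    return MatchResult(uid=uid, label=label, category=category, field=field,
                       count=count, spans=[(i, i + 1) for i in range(0, 2 * count, 2)])


def test_single_fulltext_mention_is_not_enough_for_outcome():
    results = [_mr("u", "Morris water maze", "outcome", "tiabkw", 0),
               _mr("u", "Morris water maze", "outcome", "fulltext", 1)]
    [a] = apply_policy(results, default_policy())
    assert a.assigned is False


def test_one_model_sentence_mention_assigns_model():
    results = [_mr("u", "5xFAD", "model", "model_sentence", 1)]
    [a] = apply_policy(results, default_policy())
    assert a.assigned is True


def test_high_sensitivity_admits_any_fulltext_mention_for_intervention():
    results = [_mr("u", "donepezil", "intervention", "fulltext", 5)]
    [default] = apply_policy(results, default_policy())
    [relaxed] = apply_policy(results, default_policy(high_sensitivity=True))
    assert default.assigned is False and relaxed.assigned is True


def test_policy_without_category_entry_raises():
    policy = TagPolicy(rules={"model": CategoryRule(tiabkw_min=1)})
    with pytest.raises(PolicyError):
        apply_policy([_mr("u", "donepezil", "intervention", "tiabkw", 1)], policy)


def test_assignment_replay_from_stored_evidence(planted_corpus, lexicons):
    from soles.tagging import rule_satisfied

    citations, fulltexts, _ = planted_corpus
    policy = default_policy()
    tagged = tag_corpus(citations, fulltexts, lexicons, policy)
    for a in tagged.assignments:
        if a.label == "__untagged__":
            continue
        replayed = rule_satisfied(a.evidence, policy.rules[a.category],
                                  a.category, policy.high_sensitivity)
        assert replayed == a.assigned


def test_raising_thresholds_never_increases_assignments():
    results = []
    rng = random.Random(7)
    for i in range(60):
        results.append(_mr(f"u{i}", "Morris water maze", "outcome", "tiabkw", rng.randint(0, 2)))
        results.append(_mr(f"u{i}", "Morris water maze", "outcome", "fulltext", rng.randint(0, 4)))
    def n_assigned(tiabkw_min, fulltext_min):
        policy = TagPolicy(rules={"outcome": CategoryRule(tiabkw_min=tiabkw_min,
                                                          fulltext_min=fulltext_min)})
        return sum(a.assigned for a in apply_policy(results, policy))
    for lo_t, lo_f in [(1, 1), (1, 2), (2, 2)]:
        assert n_assigned(lo_t, lo_f) >= n_assigned(lo_t + 1, lo_f)
        assert n_assigned(lo_t, lo_f) >= n_assigned(lo_t, lo_f + 1)


# ---------------------------------------------------------------------------
# tag_corpus


def test_tag_corpus_is_deterministic_byte_identical(tmp_path, planted_corpus, lexicons):
    citations, fulltexts, _ = planted_corpus
    t1 = tag_corpus(citations, fulltexts, lexicons)
    t2 = tag_corpus(citations, fulltexts, lexicons)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    t1.to_csv(p1)
    t2.to_csv(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_tag_corpus_high_sensitivity_is_a_superset(planted_corpus, lexicons):
    citations, fulltexts, _ = planted_corpus
    base = tag_corpus(citations, fulltexts, lexicons, default_policy())
    for category in lexicons:
        default_uids = base.assigned_uids(category)
        hs_uids = base.assigned_uids(category, high_sensitivity=True)
        assert default_uids <= hs_uids


def test_tag_corpus_incremental_mode_reuses_previous_run(planted_corpus, lexicons):
    from soles.ingest import CitationSet

    citations, fulltexts, _ = planted_corpus
    first_half = CitationSet(citations.records[:25])
    tagged_half = tag_corpus(first_half, fulltexts, lexicons)
    tagged_all = tag_corpus(citations, fulltexts, lexicons, previous=tagged_half)
    fresh = tag_corpus(citations, fulltexts, lexicons)
    key = lambda t: sorted((a.uid, a.category, a.label, a.assigned) for a in t.assignments)
    assert key(tagged_all) == key(fresh)


def test_tag_corpus_empty_corpus(lexicons):
    from soles.ingest import CitationSet

    tagged = tag_corpus(CitationSet([]), {}, lexicons)
    assert len(tagged) == 0


def test_untagged_marker_emitted_per_category(lexicons):
    from soles.ingest import CitationSet

    rec = CitationRecord(uid="blank", title="Nothing relevant whatsoever")
    tagged = tag_corpus(CitationSet([rec]), {}, lexicons)
    markers = {a.category for a in tagged.assignments if a.label == "__untagged__"}
    assert markers == set(lexicons)
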