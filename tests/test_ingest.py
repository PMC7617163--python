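"""Citation ingestion, normalisation, deduplication and update merging."""

import random
from datetime import date, timedelta

import pytest

from soles.ingest import (
    CitationRecord,
    CitationSet,
    FullTextDocument,
    deduplicate,
    flag_abstract_only,
    merge_update,
    normalize_doi,
    read_citations,
    title_similarity,
    write_citations,
    _records_match,
)


def _rec(uid, title="A study of something", year=2020, doi=None, authors=("Smith, J.",),
         abstract="", **kw):
    return CitationRecord(uid=uid, title=title, year=year, doi=doi,
                          authors=list(authors), abstract=abstract, **kw)


# ---------------------------------------------------------------------------
# readers


def test_empty_csv_yields_empty_set(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("uid,title,abstract,keywords,authors,year,doi,journal,source_db,retracted\n")
    assert len(read_citations(p, format="csv")) == 0


def test_csv_reader_preserves_fields_and_tolerates_missing_abstract(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text(
        "uid,title,abstract,keywords,authors,year,doi,journal,source_db,retracted\n"
        "a1,First title,Some abstract,kw1;kw2,\"Smith, J.;Doe, A.\",2019,10.1/x,J One,pubmed,false\n"
        "a2,Second title,,maze,\"Lee, K.\",2021,,J Two,wos,true\n"
        "a3,Third title,Another abstract,,,2020,10.2/y,J Three,scopus,false\n"
    )
    cs = read_citations(p, format="csv")
    assert len(cs) == 3
    r1, r2, r3 = cs["a1"], cs["a2"], cs["a3"]
    assert r1.keywords == ["kw1", "kw2"]
    assert r1.authors == ["Smith, J.", "Doe, A."]
    assert r1.year == 2019 and r1.doi == "10.1/x" and r1.source_db == "pubmed"
    assert r2.abstract == "" and r2.retracted is True
    assert r3.authors == [] and r3.keywords == []


def test_ris_doi_is_normalized_and_uid_deterministic(tmp_path):
    p = tmp_path / "r.ris"
    p.write_text(
        "TY  - JOUR\nTI  - Amyloid pathology in rodents\nAU  - Smith, J.\n"
        "PY  - 2018\nDO  - https://doi.org/10.1/ABC\nJO  - J Test\nDB  - pubmed\n"
        "ID  - 12345\nER  - \n"
    )
    cs = read_citations(p, format="ris")
    assert len(cs) == 1
    rec = cs.records[0]
    assert rec.doi == "10.1/abc"
    assert rec.uid == "pubmed:12345"
    # reading the same file again assigns the same uid
    assert read_citations(p, format="ris").records[0].uid == rec.uid


def test_medline_xml_reader(tmp_path):
    p = tmp_path / "m.xml"
    p.write_text(
        """<PubmedArticleSet><PubmedArticle><MedlineCitation>
        <PMID>555</PMID>
        <Article>
          <Journal><Title>J Neuro</Title>
            <JournalIssue><PubDate><Year>2017</Year></PubDate></JournalIssue></Journal>
          <ArticleTitle>Tau spreading in models</ArticleTitle>
          <Pagination><MedlinePgn>10-19</MedlinePgn></Pagination>
          <ELocationID EIdType="doi">10.5/TAU</ELocationID>
          <Abstract><AbstractText>Background text.</AbstractText></Abstract>
          <AuthorList><Author><LastName>Ngu</LastName><ForeName>Mai</ForeName></Author></AuthorList>
        </Article>
        <KeywordList><Keyword>tau</Keyword></KeywordList>
        </MedlineCitation></PubmedArticle></PubmedArticleSet>"""
    )
    cs = read_citations(p, format="medline_xml")
    rec = cs.records[0]
    assert rec.uid == "pubmed:555"
    assert rec.title == "Tau spreading in models"
    assert rec.doi == "10.5/tau"
    assert rec.authors == ["Ngu, Mai"]
    assert rec.keywords == ["tau"]
    assert rec.year == 2017


@pytest.mark.parametrize("fmt", ["csv", "ris"])
def test_read_write_read_is_a_fixed_point(tmp_path, fmt):
    original = CitationSet([
        _rec("pubmed:1", title="Alpha study", doi="10.1/a", abstract="Text here",
             keywords=["k1", "k2"], journal="J A", source_db="pubmed",
             accessions={"pubmed": "1"}),
        _rec("wos:2", title="Beta study", year=2015, authors=("Lee, K.",),
             journal="J B", source_db="wos", accessions={"wos": "2"}),
    ])
    p = tmp_path / f"roundtrip.{fmt}"
    write_citations(original, p, format=fmt)
    again = read_citations(p, format=fmt)
    assert len(again) == len(original)
    for a, b in zip(original, again):
        for fieldname in ("uid", "title", "abstract", "keywords", "authors",
                          "year", "doi", "journal", "source_db"):
            assert getattr(a, fieldname) == getattr(b, fieldname), fieldname


def test_doi_normalization_strips_resolver_prefixes():
    assert normalize_doi("https://doi.org/10.1/ABC") == "10.1/abc"
    assert normalize_doi("doi:10.1/ABC") == "10.1/abc"
    assert normalize_doi("10.1/abc") == "10.1/abc"


# ---------------------------------------------------------------------------
# deduplication


def test_same_doi_different_source_merges():
    cs = CitationSet([
        _rec("pubmed:1", doi="10.1/x", source_db="pubmed"),
        _rec("wos:9", doi="https://doi.org/10.1/X", source_db="wos",
             title="A Study of Something!"),
    ])
    kept, dupes = deduplicate(cs)
    assert len(kept) == 1
    assert dupes.groups == [frozenset({"pubmed:1", "wos:9"})]


def test_title_case_punctuation_variants_merge_and_brute_force_agrees():
    base = [
        _rec(f"u{i}", title=f"Completely unrelated title number {i} with extra words",
             year=2000 + i, authors=(f"Auth{i}, A.",))
        for i in range(8)
    ]
    base.append(_rec("dupA", title="Synaptic deficits in aged cohorts: a longitudinal study",
                     year=2010, authors=("Vega, M.",), abstract="has one"))
    base.append(_rec("dupB", title="SYNAPTIC DEFICITS IN AGED COHORTS A LONGITUDINAL STUDY",
                     year=2010, authors=("Vega, M.",)))
    kept, dupes = deduplicate(CitationSet(base))
    assert len(kept) == 9
    assert dupes.groups == [frozenset({"dupA", "dupB"})]
    # keep-rule prefers the record with an abstract
    assert dupes.kept[frozenset({"dupA", "dupB"})] == "dupA"
    # brute-force pairwise comparison finds exactly the same matching pair
    pairs = {
        frozenset({a.uid, b.uid})
        for i, a in enumerate(base) for b in base[i + 1:] if _records_match(a, b)
    }
    assert pairs == {frozenset({"dupA", "dupB"})}


def test_same_title_but_conflicting_dois_do_not_merge():
    cs = CitationSet([
        _rec("a", title="Identical title", doi="10.1/one", year=2012, authors=("Kim, S.",)),
        _rec("b", title="Identical title", doi="10.1/two", year=2012, authors=("Kim, S.",)),
    ])
    kept, dupes = deduplicate(cs)
    assert len(kept) == 2 and dupes.groups == []


def test_dedup_is_idempotent_and_order_insensitive():
    records = [
        _rec("x1", doi="10.1/s", abstract="abs"),
        _rec("x2", doi="10.1/s"),
        _rec("x3", title="Another thing entirely", year=1999, authors=("Zed, Q.",)),
        _rec("x4", title="Another thing, entirely.", year=1999, authors=("Zed, Q.",)),
        _rec("x5", title="A third distinct record", year=2005, authors=("Moe, R.",)),
    ]
    kept_ref, dupes_ref = deduplicate(CitationSet(records))
    # idempotence
    kept_twice, dupes_twice = deduplicate(kept_ref)
    assert kept_twice.uids() == kept_ref.uids() and dupes_twice.groups == []
    # order-insensitivity
    rng = random.Random(3)
    for _ in range(5):
        shuffled = records[:]
        rng.shuffle(shuffled)
        kept_perm, dupes_perm = deduplicate(CitationSet(shuffled))
        assert set(kept_perm.uids()) == set(kept_ref.uids())
        assert set(dupes_perm.groups) == set(dupes_ref.groups)


def test_every_merged_group_replays_the_match_rule():
    records = [
        _rec("r1", doi="10.1/q"), _rec("r2", doi="10.1/q"),
        _rec("r3", title="Chains of similarity in cohorts", year=2011, authors=("Li, P.",)),
        _rec("r4", title="Chains of similarity in cohorts!", year=2011, authors=("Li, P.",)),
    ]
    by_uid = {r.uid: r for r in records}
    _, dupes = deduplicate(CitationSet(records))
    for grp in dupes.groups:
        members = [by_uid[u] for u in grp]
        for i, a in enumerate(members):
            # transitive closure: each member matches at least one other member
            assert any(_records_match(a, b) for j, b in enumerate(members) if i != j)


def test_title_similarity_reaches_one_for_case_punct_variants():
    assert title_similarity("Water-Maze performance, revisited",
                            "water maze performance revisited") == 1.0


# ---------------------------------------------------------------------------
# search-update merge


def _dated(uid, days_ago, **kw):
    return _rec(uid, retrieval_date=date(2024, 6, 1) - timedelta(days=days_ago), **kw)


def test_merge_update_identical_incoming_appends_nothing():
    existing = CitationSet([_dated("pubmed:1", 10, doi="10.1/a")])
    incoming = CitationSet([_rec("pubmed:1b", doi="10.1/a")])
    merged = merge_update(existing, incoming, as_of=date(2024, 6, 1))
    assert merged.uids() == ["pubmed:1"]


def test_merge_update_appends_only_novel_records():
    existing = CitationSet([
        _dated("e1", 30, doi="10.1/a"),
        _dated("e2", 30, doi="10.1/b"),
        _dated("e3", 400, doi="10.1/c"),
    ])
    incoming = CitationSet([
        _rec("i1", doi="10.1/a"),              # dup of e1 (within lookback)
        _rec("i2", doi="10.1/b"),              # dup of e2 (within lookback)
        _rec("i3", doi="10.1/n1", title="New one", year=2023),
        _rec("i4", doi="10.1/n2", title="New two", year=2023),
        _rec("i5", doi="10.1/n3", title="New three", year=2023),
    ])
    merged = merge_update(existing, incoming, as_of=date(2024, 6, 1))
    assert set(merged.uids()) == {"e1", "e2", "e3", "i3", "i4", "i5"}


def test_duplicate_of_old_record_slips_through_then_full_pass_catches_it():
    existing = CitationSet([_dated("e-old", 400, doi="10.1/old")])
    incoming = CitationSet([_rec("i-dup", doi="10.1/old")])
    merged = merge_update(existing, incoming, as_of=date(2024, 6, 1))
    assert set(merged.uids()) == {"e-old", "i-dup"}  # appended: outside lookback
    kept, dupes = deduplicate(merged)  # the periodic comprehensive pass
    assert len(kept) == 1 and dupes.groups == [frozenset({"e-old", "i-dup"})]


def test_merge_update_missing_dates_falls_back_to_all(caplog):
    existing = CitationSet([_rec("e1", doi="10.1/a")])  # no retrieval date
    incoming = CitationSet([_rec("i1", doi="10.1/a")])
    with caplog.at_level("WARNING"):
        merged = merge_update(existing, incoming)
    assert merged.uids() == ["e1"]
    assert any("retrieval date" in m for m in caplog.messages)


# ---------------------------------------------------------------------------
# abstract-only flag


def test_flag_abstract_only_rules():
    cs = CitationSet([
        _rec("with-text", title="Full paper"),
        _rec("meeting", title="Abstract only", pub_type="Meeting Abstract"),
        _rec("no-evidence", title="Unknown nature"),
        _rec("single-page", title="One pager", pages="S45"),
    ])
    fulltexts = {"with-text": FullTextDocument("with-text", text="word " * 4000)}
    flagged = flag_abstract_only(cs, fulltexts)
    assert flagged["with-text"].abstract_only_flag is False
    assert flagged["meeting"].abstract_only_flag is True
    assert flagged["no-evidence"].abstract_only_flag is False
    assert flagged["single-page"].abstract_only_flag is True


def test_flag_abstract_only_short_fulltext_does_not_count():
    cs = CitationSet([_rec("m", pub_type="Meeting Abstract")])
    stub = {"m": FullTextDocument("m", text="only a few words here")}
    assert flag_abstract_only(cs, stub, min_words=500)["m"].abstract_only_flag is True
    with pytest.raises(ValueError):
        flag_abstract_only(cs, {}, min_words=0)
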