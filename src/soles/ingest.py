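"""Reading, normalising, merging and deduplicating bibliographic citation records.

A living evidence summary accumulates records from several biomedical
databases (PubMed, Web of Science, Scopus), so the same publication is
routinely retrieved more than once, under slightly different metadata.
This module provides the record container, readers/writers for three
plain-text citation dialects (RIS, MEDLINE/PubMed XML, and a flat CSV),
a deterministic deduplicator, an incremental search-update merge, and a
heuristic flag for records that are conference abstracts rather than
full publications.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import re
import unicodedata
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from difflib import SequenceMatcher
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from lxml import etree

log = logging.getLogger(__name__)

SOURCE_DBS = ("pubmed", "wos", "scopus", "other")

#: similarity threshold on normalised titles for the fuzzy merge rule
TITLE_SIMILARITY_THRESHOLD = 0.95

#: default look-back window for incremental search-update deduplication
#: ("previous two months", read conservatively)
DEFAULT_LOOKBACK = timedelta(days=62)


class IngestError(Exception):
    """Raised for unreadable inputs or invalid citation sets."""


# ---------------------------------------------------------------------------
# record containers


@dataclass
class CitationRecord:
    """One bibliographic record with its searchable fields and provenance.

    ``uid`` is an opaque, stable identifier: the source database accession
    when one exists, otherwise a content hash, so re-ingesting the same
    file yields the same uids.
    """

    uid: str
    title: str = ""
    abstract: str = ""
    keywords: list[str] = field(default_factory=list)
    authors: list[str] = field(default_factory=list)
    year: int | None = None
    doi: str | None = None
    journal: str = ""
    source_db: str = "other"
    accessions: dict[str, str] = field(default_factory=dict)
    retracted: bool = False
    abstract_only_flag: bool = False
    pages: str = ""
    pub_type: str = ""
    retrieval_date: date | None = None

    def __post_init__(self) -> None:
        if self.doi:
            self.doi = normalize_doi(self.doi)
        if self.year is not None and not (1800 <= self.year <= 2100):
            raise IngestError(f"year {self.year} outside [1800, 2100] for uid {self.uid!r}")

    @property
    def tiabkw(self) -> str:
        """Title + abstract + keywords joined with a newline sentinel.

        The sentinel guarantees no dictionary variant can match across
        field boundaries (no variant contains a newline).
        """
        return "\n".join([self.title, self.abstract, *self.keywords])


@dataclass
class FullTextDocument:
    """Plain text of a publication, keyed by its citation uid."""

    uid: str
    text: str
    origin_format: str = "txt"  # pdf_converted | xml | txt

    @property
    def char_count(self) -> int:
        return len(self.text)

    @property
    def word_count(self) -> int:
        return len(self.text.split())


class CitationSet:
    """An ordered collection of :class:`CitationRecord` with unique uids."""

    def __init__(self, records: Iterable[CitationRecord] = ()):
        self.records: list[CitationRecord] = list(records)
        self._index: dict[str, CitationRecord] = {}
        for rec in self.records:
            if rec.uid in self._index:
                raise IngestError(f"duplicate uid in CitationSet: {rec.uid!r}")
            self._index[rec.uid] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CitationRecord]:
        return iter(self.records)

    def __contains__(self, uid: str) -> bool:
        return uid in self._index

    def __getitem__(self, uid: str) -> CitationRecord:
        return self._index[uid]

    def uids(self) -> list[str]:
        return [r.uid for r in self.records]


@dataclass
class DuplicateMap:
    """Which records were merged, and which member was kept for each group."""

    groups: list[frozenset[str]]
    kept: dict[frozenset[str], str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for grp in self.groups:
            if seen & grp:
                raise IngestError("duplicate groups are not disjoint")
            seen |= grp
            if self.kept[grp] not in grp:
                raise IngestError("kept uid not a member of its group")


# ---------------------------------------------------------------------------
# normalisation helpers

_DOI_PREFIX = re.compile(r"^(?:https?://(?:dx\.)?doi\.org/|doi:\s*)", re.IGNORECASE)


def normalize_doi(doi: str) -> str:
    """Lowercase a DOI and strip any resolver prefix."""
    return _DOI_PREFIX.sub("", doi.strip()).lower()


def _fold_diacritics(text: str) -> str:
    return "".join(
        ch for ch in unicodedata.normalize("NFKD", text) if not unicodedata.combining(ch)
    )


_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_title(title: str) -> str:
    """Dedup canonical form: folded, lowercased, punctuation collapsed to spaces."""
    return _NON_ALNUM.sub(" ", _fold_diacritics(title).lower()).strip()


def title_similarity(a: str, b: str) -> float:
    """Normalised edit-distance ratio between two canonicalised titles."""
    return SequenceMatcher(None, normalize_title(a), normalize_title(b)).ratio()


def first_author_surname(record: CitationRecord) -> str:
    if not record.authors:
        return ""
    first = record.authors[0]
    surname = first.split(",")[0] if "," in first else (first.split()[-1] if first.split() else "")
    return _fold_diacritics(surname).lower().strip()


def _content_hash(title: str, year: int | None, doi: str | None) -> str:
    basis = f"{normalize_title(title)}|{year or ''}|{doi or ''}"
    return hashlib.sha1(basis.encode("utf-8")).hexdigest()[:12]


def assign_uid(record: CitationRecord) -> str:
    """Deterministic uid: source accession preferred, content hash otherwise."""
    acc = record.accessions.get(record.source_db)
    if acc:
        return f"{record.source_db}:{acc}"
    if record.doi:
        return f"doi:{record.doi}"
    return f"hash:{_content_hash(record.title, record.year, record.doi)}"


# ---------------------------------------------------------------------------
# readers

CSV_COLUMNS = [
    "uid", "title", "abstract", "keywords", "authors", "year", "doi",
    "journal", "source_db", "retracted",
]
_CSV_OPTIONAL = ["abstract_only_flag", "pages", "pub_type", "retrieval_date", "accessions"]

RIS_TAGS = {"TY", "TI", "AB", "KW", "AU", "PY", "DO", "JO", "ER", "ID", "DB", "SP", "EP"}


def read_citations(path: str | Path, format: str) -> CitationSet:
    """Read a citation file in the named dialect into a :class:`CitationSet`.

    Malformed records are skipped with a logged warning; missing fields are
    left empty. uids are taken from the file when present, otherwise
    assigned deterministically from accession / DOI / content hash.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    readers = {"csv": _read_csv, "ris": _read_ris, "medline_xml": _read_medline_xml}
    if format not in readers:
        raise IngestError(f"unknown citation format {format!r}")
    records, skipped = readers[format](path)
    if skipped:
        log.warning("skipped %d malformed record(s) while reading %s", skipped, path)
    return CitationSet(records)


def _parse_year(raw: str) -> int | None:
    m = re.search(r"\b(1[89]\d\d|20\d\d|2100)\b", raw)
    return int(m.group(1)) if m else None


def _read_csv(path: Path) -> tuple[list[CitationRecord], int]:
    records: list[CitationRecord] = []
    skipped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return [], 0
        for i, row in enumerate(reader):
            try:
                accessions = {}
                for pair in (row.get("accessions") or "").split(";"):
                    if ":" in pair:
                        k, v = pair.split(":", 1)
                        accessions[k.strip()] = v.strip()
                rdate = row.get("retrieval_date") or ""
                rec = CitationRecord(
                    uid=row.get("uid") or "",
                    title=row.get("title") or "",
                    abstract=row.get("abstract") or "",
                    keywords=[k.strip() for k in (row.get("keywords") or "").split(";") if k.strip()],
                    authors=[a.strip() for a in (row.get("authors") or "").split(";") if a.strip()],
                    year=_parse_year(row.get("year") or ""),
                    doi=(row.get("doi") or None) or None,
                    journal=row.get("journal") or "",
                    source_db=(row.get("source_db") or "other").strip().lower() or "other",
                    accessions=accessions,
                    retracted=(row.get("retracted") or "").strip().lower() in ("true", "1", "yes"),
                    abstract_only_flag=(row.get("abstract_only_flag") or "").strip().lower()
                    in ("true", "1", "yes"),
                    pages=row.get("pages") or "",
                    pub_type=row.get("pub_type") or "",
                    retrieval_date=date.fromisoformat(rdate) if rdate else None,
                )
                if not rec.uid:
                    rec.uid = assign_uid(rec)
                records.append(rec)
            except (IngestError, ValueError) as exc:
                skipped += 1
                log.warning("skipping CSV row %d of %s: %s", i + 2, path, exc)
    return records, skipped


def _read_ris(path: Path) -> tuple[list[CitationRecord], int]:
    """Minimal RIS reader for the declared tag dialect.

    Tags: TY/TI/AB/KW/AU/PY/DO/JO/ER plus ID (accession), DB (source
    database) and SP/EP (pages). Records are terminated by ``ER  -``.
    """
    records: list[CitationRecord] = []
    skipped = 0
    current: dict[str, list[str]] = {}

    def flush() -> None:
        nonlocal skipped
        if not current:
            return
        try:
            db = (current.get("DB", ["other"])[0]).strip().lower()
            if db not in SOURCE_DBS:
                db = "other"
            sp = current.get("SP", [""])[0].strip()
            ep = current.get("EP", [""])[0].strip()
            pages = f"{sp}-{ep}" if sp and ep else sp
            rec = CitationRecord(
                uid="",
                title=" ".join(current.get("TI", [])).strip(),
                abstract=" ".join(current.get("AB", [])).strip(),
                keywords=[k.strip() for k in current.get("KW", []) if k.strip()],
                authors=[a.strip() for a in current.get("AU", []) if a.strip()],
                year=_parse_year(current.get("PY", [""])[0]),
                doi=current.get("DO", [None])[0],
                journal=current.get("JO", [""])[0].strip(),
                source_db=db,
                pub_type=current.get("TY", [""])[0].strip(),
                pages=pages,
            )
            if "ID" in current and current["ID"][0].strip():
                rec.accessions[rec.source_db] = current["ID"][0].strip()
            rec.uid = assign_uid(rec)
            records.append(rec)
        except (IngestError, ValueError) as exc:
            skipped += 1
            log.warning("skipping RIS record in %s: %s", path, exc)

    tag_re = re.compile(r"^([A-Z][A-Z0-9])  -\s?(.*)$")
    last_tag: str | None = None
    for line in path.read_text(encoding="utf-8").splitlines():
        m = tag_re.match(line)
        if m:
            tag, value = m.group(1), m.group(2).strip()
            if tag == "ER":
                flush()
                current = {}
                last_tag = None
            else:
                current.setdefault(tag, []).append(value)
                last_tag = tag
        elif line.strip() and last_tag:
            # continuation line belongs to the previous tag
            current[last_tag][-1] = (current[last_tag][-1] + " " + line.strip()).strip()
    flush()  # tolerate a missing trailing ER
    return records, skipped


def _read_medline_xml(path: Path) -> tuple[list[CitationRecord], int]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise IngestError(f"cannot parse MEDLINE XML {path}: {exc}") from exc
    records: list[CitationRecord] = []
    skipped = 0
    for art in tree.iter("PubmedArticle"):
        try:
            pmid = art.findtext(".//PMID") or ""
            tnode = art.find(".//ArticleTitle")
            title = "".join(tnode.itertext()).strip() if tnode is not None else ""
            abstract = " ".join(
                "".join(node.itertext()).strip() for node in art.findall(".//AbstractText")
            ).strip()
            keywords = [
                ("".join(k.itertext())).strip()
                for k in art.findall(".//KeywordList/Keyword")
                if "".join(k.itertext()).strip()
            ]
            authors = []
            for au in art.findall(".//AuthorList/Author"):
                last = au.findtext("LastName") or ""
                fore = au.findtext("ForeName") or au.findtext("Initials") or ""
                name = f"{last}, {fore}".strip(", ").strip()
                if name:
                    authors.append(name)
            doi = None
            for el in art.findall(".//ELocationID"):
                if el.get("EIdType") == "doi" and (el.text or "").strip():
                    doi = el.text.strip()
            if doi is None:
                for el in art.findall(".//ArticleIdList/ArticleId"):
                    if el.get("IdType") == "doi" and (el.text or "").strip():
                        doi = el.text.strip()
            year = _parse_year(
                art.findtext(".//JournalIssue/PubDate/Year")
                or art.findtext(".//JournalIssue/PubDate/MedlineDate")
                or ""
            )
            pub_types = [pt.text or "" for pt in art.findall(".//PublicationTypeList/PublicationType")]
            rec = CitationRecord(
                uid="",
                title=title,
                abstract=abstract,
                keywords=keywords,
                authors=authors,
                year=year,
                doi=doi,
                journal=art.findtext(".//Journal/Title") or "",
                source_db="pubmed",
                accessions={"pubmed": pmid} if pmid else {},
                pub_type="; ".join(t for t in pub_types if t),
                pages=art.findtext(".//Pagination/MedlinePgn") or "",
            )
            rec.uid = assign_uid(rec)
            records.append(rec)
        except (IngestError, ValueError) as exc:
            skipped += 1
            log.warning("skipping PubmedArticle in %s: %s", path, exc)
    return records, skipped


# ---------------------------------------------------------------------------
# writers (round-trip compatible with the readers above)


def write_citations(citations: CitationSet, path: str | Path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        _write_csv(citations, path)
    elif format == "ris":
        _write_ris(citations, path)
    else:
        raise IngestError(f"unsupported output format {format!r}")


def _write_csv(citations: CitationSet, path: Path) -> None:
    cols = CSV_COLUMNS + _CSV_OPTIONAL
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for r in citations:
            writer.writerow(
                {
                    "uid": r.uid,
                    "title": r.title,
                    "abstract": r.abstract,
                    "keywords": ";".join(r.keywords),
                    "authors": ";".join(r.authors),
                    "year": r.year if r.year is not None else "",
                    "doi": r.doi or "",
                    "journal": r.journal,
                    "source_db": r.source_db,
                    "retracted": str(r.retracted).lower(),
                    "abstract_only_flag": str(r.abstract_only_flag).lower(),
                    "pages": r.pages,
                    "pub_type": r.pub_type,
                    "retrieval_date": r.retrieval_date.isoformat() if r.retrieval_date else "",
                    "accessions": ";".join(f"{k}:{v}" for k, v in sorted(r.accessions.items())),
                }
            )


def _write_ris(citations: CitationSet, path: Path) -> None:
    lines: list[str] = []
    for r in citations:
        lines.append(f"TY  - {r.pub_type or 'JOUR'}")
        lines.append(f"TI  - {r.title}")
        if r.abstract:
            lines.append(f"AB  - {r.abstract}")
        for kw in r.keywords:
            lines.append(f"KW  - {kw}")
        for au in r.authors:
            lines.append(f"AU  - {au}")
        if r.year is not None:
            lines.append(f"PY  - {r.year}")
        if r.doi:
            lines.append(f"DO  - {r.doi}")
        if r.journal:
            lines.append(f"JO  - {r.journal}")
        acc = r.accessions.get(r.source_db)
        if acc:
            lines.append(f"ID  - {acc}")
        lines.append(f"DB  - {r.source_db}")
        if r.pages:
            lines.append(f"SP  - {r.pages.split('-')[0]}")
            if "-" in r.pages:
                lines.append(f"EP  - {r.pages.split('-', 1)[1]}")
        lines.append("ER  - ")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_fulltexts(path: str | Path) -> dict[str, FullTextDocument]:
    """Load full texts from a directory of ``<uid>.txt`` files or a uid,text CSV."""
    path = Path(path)
    docs: dict[str, FullTextDocument] = {}
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            docs[f.stem] = FullTextDocument(uid=f.stem, text=f.read_text(encoding="utf-8"))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                docs[row["uid"]] = FullTextDocument(uid=row["uid"], text=row.get("text", ""))
    return docs


def write_fulltexts(docs: Mapping[str, FullTextDocument], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for uid, doc in docs.items():
        if "/" in uid or uid.startswith("."):
            raise IngestError(f"uid {uid!r} cannot name a .txt file; use the CSV layout")
        (directory / f"{uid}.txt").write_text(doc.text, encoding="utf-8")


# ---------------------------------------------------------------------------
# deduplication


def _records_match(a: CitationRecord, b: CitationRecord) -> bool:
    """Pairwise duplicate rule.

    (a) identical normalised DOI, or (b) no DOI conflict AND title
    similarity >= threshold AND same year AND same first-author surname.
    """
    if a.doi and b.doi:
        return a.doi == b.doi
    # rule (b); reaching here means at most one DOI is present: no conflict
    if a.year != b.year:
        return False
    if first_author_surname(a) != first_author_surname(b):
        return False
    return title_similarity(a.title, b.title) >= TITLE_SIMILARITY_THRESHOLD


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root choice, independent of union order
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def _keep_preference(rec: CitationRecord) -> tuple:
    # prefer record with abstract, then with DOI, then smallest uid
    return (not bool(rec.abstract.strip()), rec.doi is None, rec.uid)


def _merge_group(members: list[CitationRecord]) -> CitationRecord:
    members = sorted(members, key=_keep_preference)
    kept = members[0]
    merged = replace(kept, accessions=dict(kept.accessions), keywords=list(kept.keywords),
                     authors=list(kept.authors))
    for other in sorted(members[1:], key=lambda r: r.uid):
        if not merged.abstract.strip() and other.abstract.strip():
            merged.abstract = other.abstract
        if merged.doi is None and other.doi:
            merged.doi = other.doi
        if merged.year is None and other.year is not None:
            merged.year = other.year
        if not merged.journal and other.journal:
            merged.journal = other.journal
        if not merged.keywords and other.keywords:
            merged.keywords = list(other.keywords)
        if not merged.authors and other.authors:
            merged.authors = list(other.authors)
        if not merged.pages and other.pages:
            merged.pages = other.pages
        for db, acc in other.accessions.items():
            merged.accessions.setdefault(db, acc)
        merged.retracted = merged.retracted or other.retracted
    return merged


def deduplicate(citations: CitationSet) -> tuple[CitationSet, DuplicateMap]:
    """Merge duplicate records; idempotent and insensitive to input order.

    Ambiguous chains are resolved by transitive closure of the pairwise
    rule. Each merged record keeps the preferred member's fields, filled
    from the other members where empty.
    """
    records = sorted(citations.records, key=lambda r: r.uid)
    uf = _UnionFind(r.uid for r in records)

    # exact-DOI blocking
    by_doi: dict[str, list[CitationRecord]] = {}
    for r in records:
        if r.doi:
            by_doi.setdefault(r.doi, []).append(r)
    for group in by_doi.values():
        for other in group[1:]:
            uf.union(group[0].uid, other.uid)

    # fuzzy rule, blocked on (year, first-author surname)
    by_key: dict[tuple, list[CitationRecord]] = {}
    for r in records:
        by_key.setdefault((r.year, first_author_surname(r)), []).append(r)
    for group in by_key.values():
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if uf.find(a.uid) != uf.find(b.uid) and _records_match(a, b):
                    uf.union(a.uid, b.uid)

    clusters: dict[str, list[CitationRecord]] = {}
    for r in records:
        clusters.setdefault(uf.find(r.uid), []).append(r)

    kept_records: list[CitationRecord] = []
    groups: list[frozenset[str]] = []
    kept_map: dict[frozenset[str], str] = {}
    for root in sorted(clusters):
        members = clusters[root]
        if len(members) == 1:
            kept_records.append(members[0])
            continue
        merged = _merge_group(members)
        kept_records.append(merged)
        grp = frozenset(m.uid for m in members)
        groups.append(grp)
        kept_map[grp] = merged.uid
    kept_records.sort(key=lambda r: r.uid)
    return CitationSet(kept_records), DuplicateMap(groups=groups, kept=kept_map)


def merge_update(
    existing: CitationSet,
    incoming: CitationSet,
    lookback: timedelta = DEFAULT_LOOKBACK,
    as_of: date | None = None,
) -> CitationSet:
    """Append only novel incoming records to an existing store.

    Incoming records are deduplicated against themselves and against the
    existing records retrieved within ``lookback`` of ``as_of`` (default:
    the most recent retrieval date on file). Existing records are never
    modified or removed; duplicates of records older than the window are
    appended and left for the periodic full deduplication pass.
    """
    deduped_incoming, _ = deduplicate(incoming)

    dates = [r.retrieval_date for r in existing if r.retrieval_date is not None]
    missing = len(existing) - len(dates)
    if missing and len(existing):
        log.warning(
            "%d existing record(s) lack a retrieval date; comparing against all of existing",
            missing,
        )
        window = list(existing.records)
    else:
        if as_of is None:
            as_of = max(dates, default=date.today())
        cutoff = as_of - lookback
        window = [r for r in existing if r.retrieval_date and r.retrieval_date >= cutoff]

    novel: list[CitationRecord] = []
    for rec in deduped_incoming:
        if rec.uid in existing:
            continue
        if any(_records_match(rec, old) for old in window):
            continue
        novel.append(rec)
    return CitationSet(list(existing.records) + novel)


# ---------------------------------------------------------------------------
# abstract-only flag

_MEETING_TYPES = re.compile(r"meeting abstract|conference abstract|congress", re.IGNORECASE)
_SINGLE_PAGE = re.compile(r"^\s*([A-Za-z]*\d+)\s*(?:-\s*\1\s*)?$")


def flag_abstract_only(
    citations: CitationSet,
    fulltexts: Mapping[str, FullTextDocument],
    min_words: int = 500,
) -> CitationSet:
    """Flag records that are highly likely to be meeting abstracts.

    A record is flagged when it has no usable full text (none attached, or
    attached text shorter than ``min_words`` words) AND its metadata gives
    positive evidence: a meeting-abstract publication type, or pagination
    denoting a single page. Records are flagged, never deleted; absent
    metadata leaves the flag false (insufficient evidence).
    """
    if min_words <= 0:
        raise ValueError("min_words must be positive")
    out: list[CitationRecord] = []
    for rec in citations:
        doc = fulltexts.get(rec.uid)
        has_fulltext = doc is not None and doc.word_count >= min_words
        flagged = False
        if not has_fulltext:
            if _MEETING_TYPES.search(rec.pub_type or ""):
                flagged = True
            elif rec.pages and _SINGLE_PAGE.match(rec.pages):
                flagged = True
        out.append(replace(rec, abstract_only_flag=flagged))
    return CitationSet(out)
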