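"""Dashboard-ready aggregations over a tagged corpus.

Everything a living-evidence dashboard plots is reduced here to plain
tables: publications per year, the proportion of the corpus tagged per
category, label-by-label co-occurrence matrices (evidence gap maps), and
Boolean filtered exports of citation subsets. Retracted records and
flagged meeting abstracts are excluded from all aggregations. The
interactive front end itself is out of scope: these functions emit the
tables behind it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .ingest import CitationRecord, CitationSet
from .lexicon import _BOUNDARY_L, _BOUNDARY_R
from .tagging import TaggedCorpus


class QueryError(Exception):
    """Malformed Boolean filter expression; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# aggregations


def _reportable(corpus: CitationSet) -> list[CitationRecord]:
    return [r for r in corpus if not r.retracted and not r.abstract_only_flag]


def counts_by_year(corpus: CitationSet) -> dict[int, int]:
    """Publications per year, excluding retracted and abstract-only records.

    Years with zero records are omitted; records without a year are not
    counted under any year.
    """
    counts: dict[int, int] = {}
    for rec in _reportable(corpus):
        if rec.year is not None:
            counts[rec.year] = counts.get(rec.year, 0) + 1
    return dict(sorted(counts.items()))


def coverage_percent(n_tagged: int, total: int) -> float:
    """100 * n_tagged / total, one decimal, round-half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    if n_tagged > total:
        raise ValueError("n_tagged cannot exceed total")
    # exact rational round-half-up at 1 dp: percent = 1000*n/total halved up
    scaled = (1000 * n_tagged * 2 + total) // (2 * total)
    return scaled / 10


def tag_coverage(tags: TaggedCorpus, total: int) -> pd.DataFrame:
    """Per-category count and percentage of citations with >= 1 assigned tag."""
    rows = []
    for category in sorted(tags.lexicon_versions):
        n_tagged = len(tags.assigned_uids(category))
        rows.append({
            "category": category,
            "n_tagged": n_tagged,
            "percent": coverage_percent(n_tagged, total),
        })
    return pd.DataFrame(rows, columns=["category", "n_tagged", "percent"])


@dataclass
class CrosstabMatrix:
    """Label-by-label matrix of distinct-citation co-occurrence counts."""

    row_category: str
    col_category: str
    row_labels: list[str]
    col_labels: list[str]
    cells: list[list[int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.row_labels, columns=self.col_labels)


def crosstab(
    tags: TaggedCorpus,
    cat_a: str,
    cat_b: str,
    labels_a: list[str] | None = None,
    labels_b: list[str] | None = None,
    row_groups: dict[str, str] | None = None,
    high_sensitivity: bool = False,
) -> CrosstabMatrix:
    """Gap-map crosstab: cell (i, j) counts distinct citations assigned both labels.

    When ``cat_a == cat_b`` the diagonal equals the per-label citation
    counts. ``row_groups`` maps labels to a parent group (e.g. drugs to a
    target class); rows are then aggregated per group, a citation counted
    once per group however many member labels it carries.
    """
    uids_by_label_a: dict[str, set[str]] = {}
    uids_by_label_b: dict[str, set[str]] = {}
    for uid in tags.uids():
        for label in tags.assigned_labels(uid, cat_a, high_sensitivity):
            uids_by_label_a.setdefault(label, set()).add(uid)
        for label in tags.assigned_labels(uid, cat_b, high_sensitivity):
            uids_by_label_b.setdefault(label, set()).add(uid)

    if row_groups:
        grouped: dict[str, set[str]] = {}
        for label, uids in uids_by_label_a.items():
            grouped.setdefault(row_groups.get(label, label), set()).update(uids)
        uids_by_label_a = grouped

    row_labels = labels_a if labels_a is not None else sorted(uids_by_label_a)
    col_labels = labels_b if labels_b is not None else sorted(uids_by_label_b)
    cells = [
        [len(uids_by_label_a.get(rl, set()) & uids_by_label_b.get(cl, set()))
         for cl in col_labels]
        for rl in row_labels
    ]
    return CrosstabMatrix(
        row_category=cat_a, col_category=cat_b,
        row_labels=list(row_labels), col_labels=list(col_labels), cells=cells,
    )


# ---------------------------------------------------------------------------
# Boolean filter queries

# grammar: expr := term (OR term)* ; term := factor (AND factor)* ;
# factor := WORD | "quoted phrase" | ( expr ).  AND binds tighter than OR.

_TOKEN = re.compile(r'\s*(?:(\()|(\))|"([^"]*)"|([^\s()]+))')


class _Node:
    def evaluate(self, text: str) -> bool:  # pragma: no cover - interface
        raise NotImplementedError


class _Term(_Node):
    def __init__(self, term: str):
        self.term = term
        self.pattern = re.compile(
            _BOUNDARY_L + re.escape(term) + _BOUNDARY_R, re.IGNORECASE
        )

    def evaluate(self, text: str) -> bool:
        return self.pattern.search(text) is not None


class _BoolOp(_Node):
    def __init__(self, op: str, operands: list[_Node]):
        self.op = op
        self.operands = operands

    def evaluate(self, text: str) -> bool:
        results = (n.evaluate(text) for n in self.operands)
        return all(results) if self.op == "AND" else any(results)


def parse_query(expression: str) -> _Node:
    """Parse a Boolean AND/OR expression over text terms.

    Terms are whitespace-delimited words or quoted phrases; AND binds
    tighter than OR; parentheses group. Raises :class:`QueryError` with
    the offending position on malformed input.
    """
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN.match(expression, pos)
        if not m or m.end() == pos:
            if expression[pos:].strip():
                raise QueryError("cannot tokenise expression", pos)
            break
        lparen, rparen, phrase, word = m.groups()
        if lparen:
            tokens.append(("LPAREN", "(", m.start(1)))
        elif rparen:
            tokens.append(("RPAREN", ")", m.start(2)))
        elif phrase is not None:
            tokens.append(("TERM", phrase, m.start(3)))
        elif word is not None:
            upper = word.upper()
            if upper in ("AND", "OR"):
                tokens.append((upper, word, m.start(4)))
            else:
                tokens.append(("TERM", word, m.start(4)))
        pos = m.end()

    index = 0

    def peek() -> tuple[str, str, int] | None:
        return tokens[index] if index < len(tokens) else None

    def take() -> tuple[str, str, int]:
        nonlocal index
        tok = tokens[index]
        index += 1
        return tok

    def parse_factor() -> _Node:
        tok = peek()
        if tok is None:
            raise QueryError("unexpected end of expression", len(expression))
        kind, value, at = take()
        if kind == "TERM":
            if not value.strip():
                raise QueryError("empty phrase", at)
            return _Term(value)
        if kind == "LPAREN":
            node = parse_expr()
            closing = peek()
            if closing is None or closing[0] != "RPAREN":
                raise QueryError("unbalanced parenthesis", at)
            take()
            return node
        raise QueryError(f"unexpected token {value!r}", at)

    def parse_term() -> _Node:
        operands = [parse_factor()]
        while (tok := peek()) is not None and tok[0] == "AND":
            take()
            operands.append(parse_factor())
        return operands[0] if len(operands) == 1 else _BoolOp("AND", operands)

    def parse_expr() -> _Node:
        operands = [parse_term()]
        while (tok := peek()) is not None and tok[0] == "OR":
            take()
            operands.append(parse_term())
        return operands[0] if len(operands) == 1 else _BoolOp("OR", operands)

    if not tokens:
        raise QueryError("empty expression", 0)
    node = parse_expr()
    if (tok := peek()) is not None:
        raise QueryError(f"unexpected token {tok[1]!r}", tok[2])
    return node


@dataclass
class FilterQuery:
    """A dashboard download filter.

    ``text_terms`` is a Boolean expression over title/abstract/keywords;
    ``tag_filters`` maps a category to the acceptable labels (a record
    must carry at least one per filtered category); ``high_sensitivity``
    switches tag filters to also accept any single full-text mention of a
    model, intervention or outcome. All filter kinds are conjoined.
    """

    text_terms: str | None = None
    tag_filters: dict[str, set[str]] = field(default_factory=dict)
    year_range: tuple[int, int] | None = None
    high_sensitivity: bool = False

    def __post_init__(self) -> None:
        if self.year_range is not None and self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be ordered (lo, hi)")


def export_filtered(
    corpus: CitationSet, tags: TaggedCorpus | None, query: FilterQuery
) -> CitationSet:
    """Citations matching a filter query, ready for CSV/RIS export."""
    node = parse_query(query.text_terms) if query.text_terms else None
    if query.tag_filters and tags is None:
        raise ValueError("tag_filters require a TaggedCorpus")
    out = []
    for rec in _reportable(corpus):
        if node is not None and not node.evaluate(rec.tiabkw):
            continue
        if query.year_range is not None:
            lo, hi = query.year_range
            if rec.year is None or not (lo <= rec.year <= hi):
                continue
        ok = True
        for category, wanted in query.tag_filters.items():
            assigned = tags.assigned_labels(rec.uid, category, query.high_sensitivity)
            if not assigned & set(wanted):
                ok = False
                break
        if ok:
            out.append(rec)
    return CitationSet(out)
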