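"""Match counting and the per-category frequency-threshold tagging policy.

A citation offers up to three matching surfaces: the concatenated
title/abstract/keywords (``tiabkw``), the full text, and the extracted
model sentences (model, sex and species dictionaries only — intervention
dictionaries are too non-specific for full text, and outcomes are scored
on the whole text). A tagging policy states, per category, the minimum
match count on each surface that justifies assigning the tag; the
default policy is the validated combination: one tiabkw mention for
every category, OR one model-sentence mention for model/sex/species, OR
two full-text mentions for outcomes. A high-sensitivity mode additionally
accepts any single full-text mention of a model, intervention or outcome,
trading precision for recall in systematic-review exports.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .ingest import CitationRecord, CitationSet, FullTextDocument
from .lexicon import (
    CATEGORIES,
    MODEL_SENTENCE_CATEGORIES,
    CompiledPattern,
    DEFAULT_MODEL_CUES,
    Lexicon,
    extract_model_sentences,
)

log = logging.getLogger(__name__)

FIELDS = ("tiabkw", "fulltext", "model_sentence")

#: categories the high-sensitivity toggle extends with any full-text mention
HIGH_SENSITIVITY_CATEGORIES = ("model", "intervention", "outcome")

#: marker label emitted when a citation has no evidence for a category
UNTAGGED = "__untagged__"


class PolicyError(Exception):
    """Raised for invalid policies or results without a policy entry."""


@dataclass
class MatchResult:
    """Match count and spans for one (citation, label, surface)."""

    uid: str
    label: str
    category: str
    field: str
    count: int
    spans: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.count == len(self.spans)
        for (a, b), (c, _d) in zip(self.spans, self.spans[1:]):
            assert a < b <= c, "spans must be sorted and non-overlapping"


@dataclass(frozen=True)
class CategoryRule:
    """Per-surface minimum match counts for one category (``None`` = surface unused)."""

    tiabkw_min: int | None = None
    fulltext_min: int | None = None
    model_sentence_min: int | None = None

    def __post_init__(self) -> None:
        mins = (self.tiabkw_min, self.fulltext_min, self.model_sentence_min)
        if all(m is None for m in mins):
            raise PolicyError("a category rule must set at least one threshold")
        if any(m is not None and m < 1 for m in mins):
            raise PolicyError("thresholds must be >= 1")

    def thresholds(self) -> dict[str, int]:
        out = {}
        for fld, m in zip(FIELDS, (self.tiabkw_min, self.fulltext_min, self.model_sentence_min)):
            if m is not None:
                out[fld] = m
        return out


@dataclass
class TagPolicy:
    """The full per-category tagging policy plus the high-sensitivity flag."""

    rules: dict[str, CategoryRule]
    high_sensitivity: bool = False

    @property
    def version(self) -> str:
        basis = repr(sorted((c, r.tiabkw_min, r.fulltext_min, r.model_sentence_min)
                            for c, r in self.rules.items()))
        basis += f"|hs={self.high_sensitivity}"
        return hashlib.sha256(basis.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "high_sensitivity": self.high_sensitivity,
            "rules": {
                c: {"tiabkw_min": r.tiabkw_min, "fulltext_min": r.fulltext_min,
                    "model_sentence_min": r.model_sentence_min}
                for c, r in self.rules.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TagPolicy":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        rules = {
            c: CategoryRule(
                tiabkw_min=v.get("tiabkw_min"),
                fulltext_min=v.get("fulltext_min"),
                model_sentence_min=v.get("model_sentence_min"),
            )
            for c, v in (data.get("rules") or {}).items()
        }
        return cls(rules=rules, high_sensitivity=bool(data.get("high_sensitivity", False)))


def default_policy(high_sensitivity: bool = False) -> TagPolicy:
    """The validated combination policy.

    model / species / sex: >=1 tiabkw OR >=1 model-sentence mention;
    outcome: >=1 tiabkw OR >=2 full-text mentions;
    intervention: >=1 tiabkw only (full-text matching not implemented —
    drug synonyms are too non-specific outside title/abstract).
    """
    return TagPolicy(
        rules={
            "model": CategoryRule(tiabkw_min=1, model_sentence_min=1),
            "species": CategoryRule(tiabkw_min=1, model_sentence_min=1),
            "sex": CategoryRule(tiabkw_min=1, model_sentence_min=1),
            "outcome": CategoryRule(tiabkw_min=1, fulltext_min=2),
            "intervention": CategoryRule(tiabkw_min=1),
        },
        high_sensitivity=high_sensitivity,
    )


@dataclass
class TagAssignment:
    """One per-citation, per-label decision with its field-level evidence.

    ``assigned`` is a pure function of ``evidence`` and the policy, so it
    can be replayed from the stored counts at any time.
    """

    uid: str
    category: str
    label: str
    assigned: bool
    evidence: dict[str, int]
    policy_version: str
    lexicon_version: str


# ---------------------------------------------------------------------------
# match counting


def count_matches(
    pattern: CompiledPattern, text: str, uid: str = "", field: str = "tiabkw"
) -> MatchResult:
    """Leftmost, non-overlapping scan of one label's pattern over a text.

    Within a label, when several synonyms could match at the same
    position the longest alternative wins and consumes its span (the
    alternation is compiled longest-first), so "Morris water maze" is one
    match, not a second hit for the embedded "water maze".
    """
    spans = [m.span() for m in pattern.regex.finditer(text)]
    return MatchResult(
        uid=uid, label=pattern.label, category=pattern.category,
        field=field, count=len(spans), spans=spans,
    )


def tag_fields(
    citation: CitationRecord,
    doc: FullTextDocument | None,
    lexicon: Lexicon,
    cues: Sequence[str] = DEFAULT_MODEL_CUES,
) -> list[MatchResult]:
    """Per-label match results on every surface available for a citation.

    When no full text is attached, full-text and model-sentence results
    are omitted entirely (not zero-filled): "no text to search" is
    distinct from "searched and found nothing". Model-sentence results
    are produced only for the model / sex / species dictionaries.
    """
    results: list[MatchResult] = []
    tiabkw_text = citation.tiabkw
    ms_text: str | None = None
    if doc is not None and lexicon.category in MODEL_SENTENCE_CATEGORIES:
        ms_text = "\n".join(extract_model_sentences(doc, cues))
    for pattern in lexicon:
        results.append(count_matches(pattern, tiabkw_text, uid=citation.uid, field="tiabkw"))
        if doc is not None:
            results.append(count_matches(pattern, doc.text, uid=citation.uid, field="fulltext"))
            if ms_text is not None:
                results.append(
                    count_matches(pattern, ms_text, uid=citation.uid, field="model_sentence")
                )
    return results


# ---------------------------------------------------------------------------
# policy application


def rule_satisfied(
    evidence: Mapping[str, int], rule: CategoryRule, category: str, high_sensitivity: bool
) -> bool:
    """OR over the enabled per-surface conditions, on the surfaces present."""
    for fld, minimum in rule.thresholds().items():
        if fld in evidence and evidence[fld] >= minimum:
            return True
    if high_sensitivity and category in HIGH_SENSITIVITY_CATEGORIES:
        if evidence.get("fulltext", 0) >= 1:
            return True
    return False


def apply_policy(
    results: Iterable[MatchResult],
    policy: TagPolicy,
    lexicon_versions: Mapping[str, str] | None = None,
) -> list[TagAssignment]:
    """Turn field-level match results into tag assignments under a policy."""
    lexicon_versions = lexicon_versions or {}
    grouped: dict[tuple[str, str, str], dict[str, int]] = {}
    for r in results:
        grouped.setdefault((r.uid, r.category, r.label), {})[r.field] = r.count
    assignments: list[TagAssignment] = []
    for (uid, category, label), evidence in sorted(grouped.items()):
        if category not in policy.rules:
            raise PolicyError(f"no policy entry for category {category!r}")
        assigned = rule_satisfied(evidence, policy.rules[category], category,
                                  policy.high_sensitivity)
        assignments.append(
            TagAssignment(
                uid=uid, category=category, label=label, assigned=assigned,
                evidence=dict(evidence), policy_version=policy.version,
                lexicon_version=lexicon_versions.get(category, "unversioned"),
            )
        )
    return assignments


# ---------------------------------------------------------------------------
# corpus tagging


@dataclass
class TaggedCorpus:
    """All tag assignments for a corpus, with the versions that produced them."""

    assignments: list[TagAssignment]
    policy_version: str
    lexicon_versions: dict[str, str]

    def __iter__(self):
        return iter(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)

    def assigned_labels(
        self, uid: str, category: str, high_sensitivity: bool = False
    ) -> set[str]:
        """Labels assigned to a citation; optionally replayed in high-sensitivity mode.

        High-sensitivity replay extends the stored decision with "any
        full-text mention" for model / intervention / outcome, computable
        from the stored evidence alone.
        """
        out = set()
        for a in self.assignments:
            if a.uid != uid or a.category != category or a.label == UNTAGGED:
                continue
            assigned = a.assigned
            if not assigned and high_sensitivity and category in HIGH_SENSITIVITY_CATEGORIES:
                assigned = a.evidence.get("fulltext", 0) >= 1
            if assigned:
                out.add(a.label)
        return out

    def assigned_uids(self, category: str, high_sensitivity: bool = False) -> set[str]:
        out = set()
        for a in self.assignments:
            if a.category != category or a.label == UNTAGGED:
                continue
            assigned = a.assigned
            if not assigned and high_sensitivity and category in HIGH_SENSITIVITY_CATEGORIES:
                assigned = a.evidence.get("fulltext", 0) >= 1
            if assigned:
                out.add(a.uid)
        return out

    def uids(self) -> set[str]:
        return {a.uid for a in self.assignments}

    def to_csv(self, path: str | Path) -> None:
        cols = ["uid", "category", "label", "assigned", "tiabkw_count", "fulltext_count",
                "model_sentence_count", "policy_version", "lexicon_version"]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for a in self.assignments:
                w.writerow({
                    "uid": a.uid, "category": a.category, "label": a.label,
                    "assigned": str(a.assigned).lower(),
                    "tiabkw_count": a.evidence.get("tiabkw", ""),
                    "fulltext_count": a.evidence.get("fulltext", ""),
                    "model_sentence_count": a.evidence.get("model_sentence", ""),
                    "policy_version": a.policy_version,
                    "lexicon_version": a.lexicon_version,
                })

    @classmethod
    def from_csv(cls, path: str | Path) -> "TaggedCorpus":
        assignments: list[TagAssignment] = []
        lexicon_versions: dict[str, str] = {}
        policy_version = ""
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                evidence = {}
                for fld, col in (("tiabkw", "tiabkw_count"), ("fulltext", "fulltext_count"),
                                 ("model_sentence", "model_sentence_count")):
                    if row.get(col, "") != "":
                        evidence[fld] = int(row[col])
                a = TagAssignment(
                    uid=row["uid"], category=row["category"], label=row["label"],
                    assigned=row["assigned"] == "true", evidence=evidence,
                    policy_version=row["policy_version"],
                    lexicon_version=row["lexicon_version"],
                )
                assignments.append(a)
                policy_version = a.policy_version
                lexicon_versions[a.category] = a.lexicon_version
        return cls(assignments=assignments, policy_version=policy_version,
                   lexicon_versions=lexicon_versions)


def tag_corpus(
    citations: CitationSet,
    fulltexts: Mapping[str, FullTextDocument],
    lexicons: Mapping[str, Lexicon],
    policy: TagPolicy | None = None,
    cues: Sequence[str] = DEFAULT_MODEL_CUES,
    previous: TaggedCorpus | None = None,
) -> TaggedCorpus:
    """Tag every citation in a corpus; deterministic given inputs and versions.

    Assignments are kept for every label with any nonzero evidence; a
    citation with no evidence in a category receives an explicit untagged
    marker. When a ``previous`` run with identical lexicon and policy
    versions is supplied, only citations absent from it are re-tagged and
    the rest of the previous output is reused (incremental mode); any
    version change forces a full re-tag.
    """
    policy = policy or default_policy()
    lexicon_versions = {cat: lex.version for cat, lex in lexicons.items()}

    reuse: list[TagAssignment] = []
    todo = citations.records
    if previous is not None:
        if (previous.policy_version == policy.version
                and previous.lexicon_versions == lexicon_versions):
            done = previous.uids()
            reuse = [a for a in previous.assignments if a.uid in done]
            todo = [c for c in citations if c.uid not in done]
        else:
            log.info("lexicon or policy version changed; full re-tag")

    assignments: list[TagAssignment] = list(reuse)
    for citation in todo:
        doc = fulltexts.get(citation.uid)
        results: list[MatchResult] = []
        for cat in sorted(lexicons):
            results.extend(tag_fields(citation, doc, lexicons[cat], cues))
        nonzero = [r for r in results if r.count > 0]
        per_label = apply_policy(nonzero, policy, lexicon_versions)
        covered = {a.category for a in per_label}
        assignments.extend(per_label)
        for cat in sorted(lexicons):
            if cat not in covered:
                assignments.append(
                    TagAssignment(
                        uid=citation.uid, category=cat, label=UNTAGGED, assigned=False,
                        evidence={}, policy_version=policy.version,
                        lexicon_version=lexicon_versions.get(cat, "unversioned"),
                    )
                )
    assignments.sort(key=lambda a: (a.uid, a.category, a.label))
    return TaggedCorpus(
        assignments=assignments,
        policy_version=policy.version,
        lexicon_versions=lexicon_versions,
    )
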