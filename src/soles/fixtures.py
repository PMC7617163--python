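"""Synthetic corpora with planted ground truth.

Every other module is testable offline against corpora generated here:
citation records with natural-ish filler prose, optional full texts,
dictionary terms planted at declared positions (title, abstract,
full-text body, a provenance sentence, or only in the references
section), known duplicate pairs, and screening sets drawn from in-vivo
vs clinical vocabularies with a controllable overlap. The generator also
plants confusable strings ("PAPP", "APP23") that a correctly
boundary-anchored dictionary must NOT match.

Ground truth is the set of tags the default policy is expected to
assign given the planted placements: a term planted only after the
references heading contributes nothing, and a term planted once in the
full-text body of an outcome is deliberately below the two-mention
threshold unless planted twice.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .ingest import CitationRecord, CitationSet, FullTextDocument, write_citations, write_fulltexts
from .lexicon import Lexicon, TermEntry, build_lexicon
from .tagging import TaggedCorpus, TagPolicy, UNTAGGED, default_policy, rule_satisfied


class FixtureError(Exception):
    pass


# ---------------------------------------------------------------------------
# the hand-verifiable synthetic dictionaries

_MODEL_TERMS = [
    ("APP/PS1", ["APPPS1"], "amyloid"),
    ("5xFAD", ["5XFAD"], "amyloid"),
    ("3xTg-AD", ["3xTg"], "combined"),
    ("Tg2576", [], "amyloid"),
    ("APP23", [], "amyloid"),
    ("APPSwe/PSEN1dE9", ["APPSwe/PSEN1de9"], "amyloid"),
    ("PDAPP", [], "amyloid"),
    ("TgCRND8", [], "amyloid"),
    ("J20", [], "amyloid"),
    ("rTg4510", [], "tau"),
    ("P301S", [], "tau"),
    ("SAMP8", [], "accelerated senescence"),
]

_OUTCOME_TERMS = [
    ("Morris water maze", ["water maze", "MWM", "Morris maze"], "spatial memory"),
    ("open field test", ["open field"], "locomotion"),
    ("novel object recognition", ["NOR"], "recognition memory"),
    ("Y-maze", [], "working memory"),
    ("elevated plus maze", ["EPM"], "anxiety"),
    ("fear conditioning", [], "associative memory"),
    ("Barnes maze", [], "spatial memory"),
    ("passive avoidance", [], "associative memory"),
    ("rotarod", ["rota-rod"], "motor"),
    ("radial arm maze", ["RAM"], "spatial memory"),
]

_INTERVENTION_TERMS = [
    ("donepezil", ["Aricept"], "Cholinergic system"),
    ("galantamine", [], "Cholinergic system"),
    ("rivastigmine", [], "Cholinergic system"),
    ("tacrine", [], "Cholinergic system"),
    ("huperzine A", [], "Cholinergic system"),
    ("memantine", [], "Glutamatergic system"),
    ("curcumin", [], "natural product"),
    ("resveratrol", [], "natural product"),
    ("melatonin", [], "natural product"),
    ("caffeine", [], "natural product"),
    ("lithium", [], "GSK-3"),
    ("rapamycin", [], "mTOR"),
    ("insulin", [], "metabolic"),
    ("ibuprofen", [], "anti-inflammatory"),
    ("minocycline", [], "anti-inflammatory"),
]

_SPECIES_TERMS = [
    ("mouse", ["mice", "murine"], None),
    ("rat", ["rats"], None),
    ("zebrafish", [], None),
    ("rabbit", ["rabbits"], None),
]

_SEX_TERMS = [("male", ["males"], None), ("female", ["females"], None)]


def default_lexicons() -> dict[str, Lexicon]:
    """Small, hand-verifiable dictionaries for all five categories."""
    tables = {
        "model": _MODEL_TERMS,
        "outcome": _OUTCOME_TERMS,
        "intervention": _INTERVENTION_TERMS,
        "species": _SPECIES_TERMS,
        "sex": _SEX_TERMS,
    }
    lexicons = {}
    for category, rows in tables.items():
        entries = [
            TermEntry(label, category, synonyms=list(syns), group=group)
            for label, syns, group in rows
        ]
        lexicons[category] = build_lexicon(entries, category,
                                           version=f"synthetic-{category}-1")
    return lexicons


def write_lexicon_csvs(directory: str | Path) -> dict[str, Path]:
    """Write the synthetic dictionaries in the loadable CSV dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "model": _MODEL_TERMS, "outcome": _OUTCOME_TERMS,
        "intervention": _INTERVENTION_TERMS, "species": _SPECIES_TERMS, "sex": _SEX_TERMS,
    }
    for category, rows in tables.items():
        path = directory / f"{category}.csv"
        lines = ["label,synonyms,group,case_sensitive"]
        for label, syns, group in rows:
            lines.append(f"\"{label}\",\"{'|'.join(syns)}\",\"{group or ''}\",")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths[category] = path
    return paths


# ---------------------------------------------------------------------------
# corpus generation

PLACEMENTS = ("title", "abstract", "fulltext_body", "model_sentence", "references_only")


@dataclass(frozen=True)
class Planting:
    category: str
    label: str
    placement: str
    copies: int = 1

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise FixtureError(f"unknown placement {self.placement!r}")
        if self.copies < 1:
            raise FixtureError("copies must be >= 1")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic corpus with planted ground truth."""

    n_citations: int = 50
    fulltext_fraction: float = 0.8
    planted: list[Planting] = field(default_factory=list)
    confusables: list[str] = field(default_factory=list)
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_citations < 1:
            raise FixtureError("n_citations must be >= 1")
        for frac in (self.fulltext_fraction, self.duplicate_fraction):
            if not (0.0 <= frac <= 1.0):
                raise FixtureError("fractions must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, keyed for direct comparison with outputs."""

    true_tags: dict[str, dict[str, set[str]]]
    duplicate_groups: list[set[str]]
    screening_labels: dict[str, bool]


# filler prose deliberately free of every synthetic dictionary term
_FILLER_TITLE = "Longitudinal observations on disease progression in an experimental cohort"
_FILLER_SENTENCES = [
    "Progressive cognitive decline remains a central challenge for therapy development.",
    "Tissue samples were processed according to standard protocols.",
    "Group allocation followed a predefined randomisation schedule.",
    "Statistical analysis was performed with appropriate corrections for multiple comparisons.",
    "The findings are discussed in the context of earlier reports.",
    "Further work will be required to establish the generality of these observations.",
    "Histological examination confirmed the expected regional distribution.",
    "All procedures complied with institutional welfare regulations.",
]

_TITLE_SLOT = "Effects observed with {term} in a controlled setting"
_ABSTRACT_SLOT = "Experiments employed the {term} paradigm under standard conditions."
_BODY_SLOT = "Additional measurements involving {term} were collected throughout the study."
_MODEL_SENTENCE_SLOT = (
    "The colony was obtained from The Jackson Laboratory and the {term} line was "
    "maintained on a congenic background."
)
_REFERENCE_SLOT = "Smith J, Jones K. Prior observations on {term}. J Res Notes. 2019;12:34-56."
_CONFUSABLE_SLOT = "Serum {term} levels were quantified at baseline."


def generate_corpus(
    spec: SyntheticSpec,
    policy: TagPolicy | None = None,
) -> tuple[CitationSet, dict[str, FullTextDocument], GroundTruth]:
    """Build a corpus whose correct tagging is known by construction.

    Deterministic given ``spec.seed``. Planted terms are embedded in
    template sentences at the declared placement in every record (surface
    placements that need a full text only apply to records that have
    one). ``GroundTruth.true_tags`` holds, per record, the tags the
    supplied policy (default: the validated combination policy) is
    expected to assign; references-only placements are excluded by
    construction. A ``duplicate_fraction`` of records is re-emitted with
    case/punctuation-perturbed titles and recorded as duplicate groups.
    """
    policy = policy or default_policy()
    rng = random.Random(spec.seed)
    n_fulltext = round(spec.fulltext_fraction * spec.n_citations)
    fulltext_uids = set(
        f"syn:{i:04d}" for i in sorted(rng.sample(range(spec.n_citations), n_fulltext))
    )

    records: list[CitationRecord] = []
    fulltexts: dict[str, FullTextDocument] = {}
    true_tags: dict[str, dict[str, set[str]]] = {}
    duplicate_groups: list[set[str]] = []
    screening_labels: dict[str, bool] = {}

    title_plants = [p for p in spec.planted if p.placement == "title"]
    abstract_plants = [p for p in spec.planted if p.placement == "abstract"]
    body_plants = [p for p in spec.planted if p.placement == "fulltext_body"]
    ms_plants = [p for p in spec.planted if p.placement == "model_sentence"]
    ref_plants = [p for p in spec.planted if p.placement == "references_only"]

    for i in range(spec.n_citations):
        uid = f"syn:{i:04d}"
        has_fulltext = uid in fulltext_uids

        title_bits = [_FILLER_TITLE + f" (series {i})"]
        for p in title_plants:
            title_bits.extend([_TITLE_SLOT.format(term=p.label)] * p.copies)
        title = ". ".join(title_bits)

        abstract_sents = [rng.choice(_FILLER_SENTENCES) for _ in range(2)]
        for p in abstract_plants:
            abstract_sents.extend([_ABSTRACT_SLOT.format(term=p.label)] * p.copies)
        for confusable in spec.confusables:
            abstract_sents.append(_CONFUSABLE_SLOT.format(term=confusable))
        abstract = " ".join(abstract_sents)

        rec = CitationRecord(
            uid=uid,
            title=title,
            abstract=abstract,
            keywords=["experimental study", "cohort"],
            authors=[f"Surname{i}, A.", "Collaborator, B."],
            year=2015 + (i % 8),
            doi=f"10.9999/syn.{i:04d}",
            journal="Journal of Synthetic Results",
            source_db="pubmed",
            accessions={"pubmed": f"{900000 + i}"},
        )
        records.append(rec)
        screening_labels[uid] = True

        # per-record evidence counts implied by the plantings
        evidence: dict[tuple[str, str], dict[str, int]] = {}

        def add(category: str, label: str, surface: str, copies: int) -> None:
            slot = evidence.setdefault((category, label), {})
            slot[surface] = slot.get(surface, 0) + copies

        for p in title_plants + abstract_plants:
            add(p.category, p.label, "tiabkw", p.copies)

        if has_fulltext:
            body_sents = [rng.choice(_FILLER_SENTENCES) for _ in range(3)]
            for p in body_plants:
                body_sents.extend([_BODY_SLOT.format(term=p.label)] * p.copies)
                add(p.category, p.label, "fulltext", p.copies)
            for p in ms_plants:
                body_sents.extend([_MODEL_SENTENCE_SLOT.format(term=p.label)] * p.copies)
                add(p.category, p.label, "fulltext", p.copies)
                add(p.category, p.label, "model_sentence", p.copies)
            text = " ".join(body_sents)
            if ref_plants:
                ref_lines = []
                for p in ref_plants:
                    ref_lines.extend([_REFERENCE_SLOT.format(term=p.label)] * p.copies)
                text += "\n\nReferences\n" + "\n".join(ref_lines)
            fulltexts[uid] = FullTextDocument(uid=uid, text=text)

        assigned: dict[str, set[str]] = {}
        for (category, label), counts in evidence.items():
            rule = policy.rules.get(category)
            if rule is None:
                continue
            if rule_satisfied(counts, rule, category, policy.high_sensitivity):
                assigned.setdefault(category, set()).add(label)
        true_tags[uid] = assigned

    # duplicates: perturbed-title re-emissions of a sample of records
    n_dupes = round(spec.duplicate_fraction * spec.n_citations)
    for i in sorted(rng.sample(range(spec.n_citations), n_dupes)):
        orig = records[i]
        dup_uid = f"{orig.uid}-dup"
        perturbed_title = orig.title.upper().replace(",", "").replace(".", "")
        dup = CitationRecord(
            uid=dup_uid,
            title=perturbed_title,
            abstract="",  # keep-rule prefers the original, which has one
            keywords=list(orig.keywords),
            authors=list(orig.authors),
            year=orig.year,
            doi=None,
            journal=orig.journal,
            source_db="wos",
        )
        records.append(dup)
        duplicate_groups.append({orig.uid, dup_uid})
        screening_labels[dup_uid] = screening_labels[orig.uid]
        # the duplicate keeps only its (perturbed) title, so its expected
        # tags come from title plantings alone
        dup_assigned: dict[str, set[str]] = {}
        for p in title_plants:
            rule = policy.rules.get(p.category)
            if rule is not None and rule_satisfied(
                {"tiabkw": p.copies}, rule, p.category, policy.high_sensitivity
            ):
                dup_assigned.setdefault(p.category, set()).add(p.label)
        true_tags[dup_uid] = dup_assigned

    return (
        CitationSet(records),
        fulltexts,
        GroundTruth(
            true_tags=true_tags,
            duplicate_groups=duplicate_groups,
            screening_labels=screening_labels,
        ),
    )


def write_corpus(
    citations: CitationSet,
    fulltexts: dict[str, FullTextDocument],
    directory: str | Path,
) -> None:
    """Write a generated corpus in the same dialects the ingest module reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_citations(citations, directory / "citations.csv", format="csv")
    write_citations(citations, directory / "citations.ris", format="ris")
    write_fulltexts(fulltexts, directory / "fulltexts")


def evaluate_against_truth(
    tagged: TaggedCorpus, truth: GroundTruth
) -> tuple[float, float]:
    """Precision and sensitivity of assignments against planted ground truth.

    Compared as sets of (uid, category, label) triples over the records
    the ground truth covers.
    """
    expected = {
        (uid, category, label)
        for uid, cats in truth.true_tags.items()
        for category, labels in cats.items()
        for label in labels
    }
    got = {
        (a.uid, a.category, a.label)
        for a in tagged.assignments
        if a.assigned and a.label != UNTAGGED and a.uid in truth.true_tags
    }
    precision = len(got & expected) / len(got) if got else 1.0
    sensitivity = len(got & expected) / len(expected) if expected else 1.0
    return precision, sensitivity


# ---------------------------------------------------------------------------
# screening sets

_INVIVO_VOCAB = (
    "transgenic", "littermates", "hippocampus", "behavioural", "rodent",
    "cortex", "plaque", "injection", "anaesthesia", "genotype", "cage",
    "husbandry", "stereotaxic", "perfusion", "immunohistochemistry",
)
_CLINICAL_VOCAB = (
    "patients", "clinical", "trial", "caregiver", "diagnosis", "hospital",
    "participants", "questionnaire", "elderly", "enrolment", "consent",
    "biomarker", "tomography", "nursing", "prevalence",
)

_TEXT_LENGTH = 18


def generate_screening_set(
    n_pos: int,
    n_neg: int,
    vocabulary_shift: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], list["LabelledDecision"]]:
    """Texts and decisions for exercising the screening task shape.

    Inclusions draw words from an in-vivo vocabulary, exclusions from a
    clinical one. ``vocabulary_shift`` controls overlap: at 0 the classes
    are separable by construction; at 1 each word is drawn from either
    vocabulary with equal probability, so the class distributions are
    identical and held-out performance approaches chance.
    """
    from .screening import LabelledDecision  # local import avoids a cycle

    if n_pos < 2 or n_neg < 2:
        raise FixtureError("need at least two citations per class")
    if not (0.0 <= vocabulary_shift <= 1.0):
        raise FixtureError("vocabulary_shift must lie in [0, 1]")
    rng = random.Random(seed)
    texts: dict[str, str] = {}
    decisions: list[LabelledDecision] = []

    def make_text(own: tuple[str, ...], other: tuple[str, ...]) -> str:
        words = []
        for _ in range(_TEXT_LENGTH):
            vocab = other if rng.random() < vocabulary_shift / 2 else own
            words.append(rng.choice(vocab))
        return " ".join(words)

    for i in range(n_pos):
        uid = f"pos:{i:04d}"
        texts[uid] = make_text(_INVIVO_VOCAB, _CLINICAL_VOCAB)
        decisions.append(LabelledDecision(uid=uid, included=True, n_reviewers=2))
    for i in range(n_neg):
        uid = f"neg:{i:04d}"
        texts[uid] = make_text(_CLINICAL_VOCAB, _INVIVO_VOCAB)
        decisions.append(LabelledDecision(uid=uid, included=False, n_reviewers=2))
    return texts, decisions
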