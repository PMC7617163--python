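"""Dictionaries of boundary-anchored match expressions for study-feature tagging.

Each tag category (animal model, intervention, outcome measure, species,
sex) is described by a term list: a canonical label plus synonyms. Terms
are expanded into surface variants (separator and case variation, Greek
transliteration) and compiled into a single alternation per label,
anchored so that letters AND digits count as word characters — "APP"
must not fire inside "PAPP" or "APP23", while "APP/PS1" still splits at
the slash.

Also here: the model-sentence extractor, a rule-based sentence splitter
with an abbreviation guard that pulls out full-text sentences describing
where an animal model was obtained or how it was generated. Applying the
model / sex / species dictionaries to those sentences alone is a much
higher-precision surface than the whole full text, which is dominated by
mentions of other people's work in the introduction and references.
"""

from __future__ import annotations

import csv
import hashlib
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .ingest import FullTextDocument

CATEGORIES = ("model", "intervention", "outcome", "species", "sex")

#: categories whose dictionaries are also applied to extracted model sentences
MODEL_SENTENCE_CATEGORIES = ("model", "sex", "species")


class LexiconError(Exception):
    """Raised for invalid term lists or uncompilable expressions."""


# ---------------------------------------------------------------------------
# variant expansion

#: separator surface forms substituted at every inter-token gap
SEPARATOR_VARIANTS = ("", " ", "-", "*", "x", "×", " x ", " × ")

#: reduced set used when the full product would explode combinatorially
_SEPARATOR_VARIANTS_SMALL = ("", " ", "-")

_VARIANT_CAP = 4096

#: trailing hyphenated tokens that may be dropped: Alzheimer model names
#: carry an optional disease suffix ("3xTg-AD" is also written "3xTg")
OPTIONAL_SUFFIX_TOKENS = frozenset({"AD"})

GREEK_TRANSLITERATION = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "κ": "kappa", "μ": "mu", "τ": "tau", "ω": "omega",
}

# a separator is a run of space/hyphen/asterisk/multiplication-sign, or a
# lone x between a digit and an uppercase letter ("3xTg")
_SEP_SPLIT = re.compile(r"(\s*[×*\-]\s*|\s+|(?<=[0-9])[xX](?=[A-Z]))")


def _transliterate_greek(term: str) -> str:
    out = term
    for greek, latin in GREEK_TRANSLITERATION.items():
        out = out.replace(greek, latin).replace(greek.upper(), latin)
    return out


def _token_case_forms(token: str) -> list[str]:
    # mixed-case tokens also match fully upper-cased ("Tg" -> "TG")
    if token.isupper() or token.islower() or not any(c.isalpha() for c in token):
        return [token]
    return [token, token.upper()]


def _split_tokens(term: str) -> list[str]:
    """Alternating tokens and separators; even indices are tokens."""
    parts = _SEP_SPLIT.split(term)
    return [p for p in parts if p != ""]


def _recombine(term: str, separators: Sequence[str]) -> list[str]:
    parts = _split_tokens(term)
    tokens = parts[0::2]
    if len(tokens) <= 1:
        return _token_case_forms(term)
    gaps = len(tokens) - 1
    token_forms = [_token_case_forms(t) for t in tokens]
    variants: list[str] = []
    for tok_combo in itertools.product(*token_forms):
        for sep_combo in itertools.product(separators, repeat=gaps):
            pieces = [tok_combo[0]]
            for sep, tok in zip(sep_combo, tok_combo[1:]):
                pieces.append(sep)
                pieces.append(tok)
            variants.append("".join(pieces))
            if len(variants) > _VARIANT_CAP:
                return variants
    return variants


def expand_variants(term: str) -> list[str]:
    """All surface forms generated for one term, the original first.

    Inter-token separators are generalised over space, hyphen, "×", "x",
    "*", and nothing; mixed-case tokens also appear fully upper-cased;
    Greek letters gain a transliterated form ("Aβ" also matches "Abeta");
    a trailing "-AD" disease suffix is optional. The list is deduplicated
    with the original term first.
    """
    if not term or not term.strip():
        raise LexiconError("cannot expand an empty term")
    term = term.strip()

    bases = [term]
    translit = _transliterate_greek(term)
    if translit != term:
        bases.append(translit)
    # optional trailing disease suffix: "3xTg-AD" -> also "3xTg"
    for base in list(bases):
        parts = _split_tokens(base)
        if len(parts) >= 3 and parts[-1] in OPTIONAL_SUFFIX_TOKENS:
            trimmed = "".join(parts[:-2]).strip()
            if trimmed:
                bases.append(trimmed)

    gaps = max(len(_split_tokens(b)[0::2]) - 1 for b in bases)
    seps = SEPARATOR_VARIANTS if gaps <= 3 else _SEPARATOR_VARIANTS_SMALL

    variants: list[str] = [term]
    for base in bases:
        variants.extend(_recombine(base, seps))

    seen: set[str] = set()
    out: list[str] = []
    for v in variants:
        if v and v not in seen:
            seen.add(v)
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# compilation

# word characters are letters and digits; underscore is a boundary
_BOUNDARY_L = r"(?<![^\W_])"
_BOUNDARY_R = r"(?![^\W_])"


@dataclass
class TermEntry:
    """One dictionary row: a canonical label and its synonyms.

    ``case_sensitive`` may be left as ``None``, in which case short
    all-caps acronyms (<= 3 characters, e.g. "AD") default to
    case-sensitive matching to limit spurious hits, and everything else
    matches case-insensitively.
    """

    label: str
    category: str
    synonyms: list[str] = field(default_factory=list)
    group: str | None = None
    case_sensitive: bool | None = None

    def __post_init__(self) -> None:
        if not self.label or not self.label.strip():
            raise LexiconError("term label must be non-empty")
        if self.category not in CATEGORIES:
            raise LexiconError(f"unknown category {self.category!r}")
        seen: set[str] = set()
        deduped = []
        for s in self.synonyms:
            if s and s not in seen:
                seen.add(s)
                deduped.append(s)
        self.synonyms = deduped

    @property
    def effective_case_sensitive(self) -> bool:
        if self.case_sensitive is not None:
            return self.case_sensitive
        return len(self.label) <= 3 and self.label.isupper() and self.label.isalpha()


@dataclass
class CompiledPattern:
    """A label's alternation over all expanded variants, boundary-anchored."""

    label: str
    category: str
    expression: str
    variant_count: int
    dictionary_version: str
    case_sensitive: bool = False
    variants: tuple[str, ...] = ()
    group: str | None = None

    def __post_init__(self) -> None:
        self._regex = re.compile(
            self.expression, 0 if self.case_sensitive else re.IGNORECASE
        )

    @property
    def regex(self) -> re.Pattern:
        return self._regex


def compile_term(entry: TermEntry, dictionary_version: str = "adhoc") -> CompiledPattern:
    """Compile a term entry into a single anchored match expression.

    The alternation is ordered longest-variant-first so that, at any
    position, the longest synonym wins and consumes its span.
    """
    variants: list[str] = []
    for source in [entry.label, *entry.synonyms]:
        try:
            expanded = expand_variants(source)
        except LexiconError as exc:
            raise LexiconError(
                f"synonym {source!r} of {entry.label!r} expands to an empty match"
            ) from exc
        for v in expanded:
            if not v.strip():
                raise LexiconError(
                    f"synonym {source!r} of {entry.label!r} expands to an empty match"
                )
            variants.append(v)
    seen: set[str] = set()
    unique = [v for v in variants if not (v in seen or seen.add(v))]
    ordered = sorted(unique, key=lambda v: (-len(v), v))
    expression = _BOUNDARY_L + "(?:" + "|".join(re.escape(v) for v in ordered) + ")" + _BOUNDARY_R
    try:
        re.compile(expression)
    except re.error as exc:  # pragma: no cover - escape() should prevent this
        raise LexiconError(f"expression for {entry.label!r} does not compile: {exc}") from exc
    return CompiledPattern(
        label=entry.label,
        category=entry.category,
        expression=expression,
        variant_count=len(unique),
        dictionary_version=dictionary_version,
        case_sensitive=entry.effective_case_sensitive,
        variants=tuple(unique),
        group=entry.group,
    )


@dataclass
class Lexicon:
    """A versioned category dictionary: one compiled pattern per label."""

    category: str
    patterns: list[CompiledPattern]
    version: str
    source_file: str = ""
    entries: list[TermEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [p.label for p in self.patterns]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise LexiconError(f"duplicate labels in {self.category} lexicon: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def label_groups(self) -> dict[str, str | None]:
        return {p.label: p.group for p in self.patterns}


def build_lexicon(
    entries: Iterable[TermEntry], category: str, version: str, source_file: str = ""
) -> Lexicon:
    entries = list(entries)
    labels = [e.label for e in entries]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise LexiconError(f"duplicate labels in {category} lexicon: {dupes}")
    patterns = [compile_term(e, dictionary_version=version) for e in entries]
    return Lexicon(
        category=category, patterns=patterns, version=version,
        source_file=source_file, entries=entries,
    )


def load_lexicon(path: str | Path, category: str) -> Lexicon:
    """Load a term-list CSV (label,synonyms,group,case_sensitive) and compile it.

    Synonyms are pipe-separated. The lexicon version is a content hash of
    the file, recorded in every downstream tag assignment.
    """
    path = Path(path)
    raw = path.read_bytes()
    version = hashlib.sha256(raw).hexdigest()[:12]
    entries: list[TermEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return Lexicon(category=category, patterns=[], version=version,
                           source_file=str(path))
        for row in reader:
            label = (row.get("label") or "").strip()
            if not label:
                continue
            cs_raw = (row.get("case_sensitive") or "").strip().lower()
            case_sensitive = None if cs_raw == "" else cs_raw in ("true", "1", "yes")
            entries.append(
                TermEntry(
                    label=label,
                    category=category,
                    synonyms=[s.strip() for s in (row.get("synonyms") or "").split("|") if s.strip()],
                    group=(row.get("group") or "").strip() or None,
                    case_sensitive=case_sensitive,
                )
            )
    return build_lexicon(entries, category, version, source_file=str(path))


def export_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write the compiled dictionary as ``label<TAB>expression`` lines for audit."""
    lines = [f"{p.label}\t{p.expression}" for p in lexicon.patterns]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def builtin_sex_lexicon() -> Lexicon:
    """Starter dictionary for animal sex: male / female and plurals."""
    entries = [
        TermEntry("male", "sex", synonyms=["males"], case_sensitive=False),
        TermEntry("female", "sex", synonyms=["females"], case_sensitive=False),
    ]
    return build_lexicon(entries, "sex", version="builtin-sex-1")


def builtin_species_lexicon() -> Lexicon:
    """Starter dictionary for the rodent species dominating neurodegeneration work."""
    entries = [
        TermEntry("mouse", "species", synonyms=["mice", "murine"], case_sensitive=False),
        TermEntry("rat", "species", synonyms=["rats"], case_sensitive=False),
    ]
    return build_lexicon(entries, "species", version="builtin-species-1")


# ---------------------------------------------------------------------------
# sentence splitting and the model-sentence extractor

#: cue phrases signalling a description of model provenance or generation;
#: versioned configuration, overridable per call
DEFAULT_MODEL_CUES = (
    "obtained from",
    "purchased from",
    "generated",
    "bred",
    "backcrossed",
    "background",
    "Jackson",
    "Charles River",
    "transgenic",
)

_ABBREVIATIONS = {
    "al", "fig", "figs", "eg", "e.g", "ie", "i.e", "vs", "dr", "no", "cf",
    "approx", "ca", "resp", "et", "etc", "st", "jr", "inc", "ltd",
}

_SENTENCE_BOUNDARY = re.compile(r"(?<=[.?!])\s+(?=[A-Z0-9(\"'])")

_REFERENCES_HEADING = re.compile(
    r"(?im)^\s*(?:references|bibliography|literature cited)\s*:?\s*$"
)


def strip_references(text: str) -> str:
    """Truncate a document at a detected references heading, if any."""
    m = _REFERENCES_HEADING.search(text)
    return text[: m.start()] if m else text


def _ends_with_abbreviation(chunk: str) -> bool:
    tail = chunk.rstrip()
    if not tail.endswith("."):
        return False
    last = tail[:-1].split()[-1] if tail[:-1].split() else ""
    last = last.strip("().,;").lower()
    # single initials ("J.") and guarded abbreviations do not end sentences
    return last in _ABBREVIATIONS or (len(last) == 1 and last.isalpha())


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence splitting with an English abbreviation guard."""
    pieces = _SENTENCE_BOUNDARY.split(text)
    sentences: list[str] = []
    for piece in pieces:
        piece = piece.strip()
        if not piece:
            continue
        if sentences and _ends_with_abbreviation(sentences[-1]):
            sentences[-1] = sentences[-1] + " " + piece
        else:
            sentences.append(piece)
    return sentences


def extract_model_sentences(
    doc: FullTextDocument, cues: Sequence[str] = DEFAULT_MODEL_CUES
) -> list[str]:
    """Full-text sentences that describe model provenance or generation.

    The document is truncated at a references heading (mentions of models
    in cited titles are not evidence of use), split into sentences, and
    filtered to those containing at least one cue phrase
    (case-insensitive). Order is preserved; duplicates are dropped.
    """
    if not cues:
        raise LexiconError("cue list must be non-empty")
    body = strip_references(doc.text)
    lowered = [c.lower() for c in cues]
    out: list[str] = []
    seen: set[str] = set()
    for sentence in split_sentences(body):
        low = sentence.lower()
        if any(c in low for c in lowered) and sentence not in seen:
            seen.add(sentence)
            out.append(sentence)
    return out
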