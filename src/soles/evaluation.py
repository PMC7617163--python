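"""Validation harness for the tagging dictionaries.

The tagging surfaces cannot be validated against an exhaustive gold
standard (nobody knows every study a dictionary *should* have tagged),
so the harness follows the design used to validate the AD-SOLES
dictionaries: draw a random subset of fully tagged studies, have a human
mark every proposed tag TRUE or FALSE, and score each tagging method
against the union of verified-true tags found by *any* method. That
union is the reference set, so a method's sensitivity is the proportion
of all verified tags it recovered ("versus all methods"), its precision
is the proportion of its own proposals that were verified, and its
specificity is the proportion of verified-false candidates it correctly
declined to propose.

``select_policy`` then turns a scored method table into the per-category
combination policy: methods must clear a precision floor, and among the
admitted full-text / model-sentence methods with similar precision the
most sensitive one is preferred.
"""

from __future__ import annotations

import csv
import logging
import random
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .tagging import CategoryRule, TaggedCorpus, TagPolicy, UNTAGGED

log = logging.getLogger(__name__)

#: the tagging methods compared by the validation study
METHODS = ("tiabkw", "fulltext_gt0", "fulltext_gt1", "fulltext_gt2", "model_sentence")

#: surface and minimum count each method corresponds to
METHOD_THRESHOLDS: dict[str, tuple[str, int]] = {
    "tiabkw": ("tiabkw", 1),
    "fulltext_gt0": ("fulltext", 1),
    "fulltext_gt1": ("fulltext", 2),
    "fulltext_gt2": ("fulltext", 3),
    "model_sentence": ("model_sentence", 1),
}

#: methods applicable per category (interventions: title/abstract/keywords only)
CATEGORY_METHODS: dict[str, tuple[str, ...]] = {
    "model": ("tiabkw", "fulltext_gt0", "fulltext_gt1", "fulltext_gt2", "model_sentence"),
    "sex": ("tiabkw", "fulltext_gt0", "fulltext_gt1", "fulltext_gt2", "model_sentence"),
    "species": ("tiabkw", "fulltext_gt0", "fulltext_gt1", "fulltext_gt2", "model_sentence"),
    "outcome": ("tiabkw", "fulltext_gt0", "fulltext_gt1", "fulltext_gt2"),
    "intervention": ("tiabkw",),
}


class EvaluationError(Exception):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _round_half_up(num: int, den: int, ndigits: int = 3) -> float:
    """Exact round-half-up of the rational num/den to ``ndigits`` decimals."""
    scale = 10 ** ndigits
    return (num * scale * 2 + den) // (2 * den) / scale


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity, specificity, precision and F1 derived from confusion counts.

    Raw fractions are retained; a metric is ``None`` exactly when its
    denominator is zero. ``rounded`` reports 3-decimal, round-half-up
    values computed in exact rational arithmetic from the counts.
    """

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    counts: ConfusionCounts | None = None

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "PerformanceMetrics":
        def ratio(num: int, den: int) -> float | None:
            return num / den if den else None

        return cls(
            sensitivity=ratio(c.tp, c.tp + c.fn),
            specificity=ratio(c.tn, c.tn + c.fp),
            precision=ratio(c.tp, c.tp + c.fp),
            f1=ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
            counts=c,
        )

    def rounded(self, ndigits: int = 3) -> dict[str, float | None]:
        if self.counts is not None:
            c = self.counts
            pairs = {
                "sensitivity": (c.tp, c.tp + c.fn),
                "specificity": (c.tn, c.tn + c.fp),
                "precision": (c.tp, c.tp + c.fp),
                "f1": (2 * c.tp, 2 * c.tp + c.fp + c.fn),
            }
            return {
                name: (_round_half_up(num, den, ndigits) if den else None)
                for name, (num, den) in pairs.items()
            }
        out = {}
        for name in ("sensitivity", "specificity", "precision", "f1"):
            value = getattr(self, name)
            if value is None:
                out[name] = None
            else:
                frac = Fraction(value).limit_denominator(10 ** 9)
                out[name] = _round_half_up(frac.numerator, frac.denominator, ndigits)
        return out


def compute_metrics(counts: ConfusionCounts) -> PerformanceMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
    F1 = harmonic mean of precision and sensitivity (= 2TP/(2TP+FP+FN))."""
    if counts.total == 0:
        raise EvaluationError("cannot compute metrics on all-zero counts")
    return PerformanceMetrics.from_counts(counts)


# ---------------------------------------------------------------------------
# annotations and method scoring


@dataclass(frozen=True)
class ValidationAnnotation:
    """One human TRUE/FALSE verdict on a proposed (citation, label, method) tag.

    ``skip`` marks records excluded during validation (e.g. a sampled
    study that turned out to be a conference abstract); skipped rows take
    no part in any count.
    """

    uid: str
    category: str
    label: str
    method: str
    verdict: bool
    skip: bool = False


def load_annotations(path: str | Path) -> list[ValidationAnnotation]:
    out: list[ValidationAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ValidationAnnotation(
                    uid=row["uid"], category=row["category"], label=row["label"],
                    method=row["method"],
                    verdict=(row.get("verdict") or "").strip().lower() in ("true", "1", "yes"),
                    skip=(row.get("skip") or "").strip().lower() in ("true", "1", "yes"),
                )
            )
    return out


@dataclass
class MethodScore:
    """One row of the method comparison table: counts + derived metrics."""

    category: str
    method: str
    counts: ConfusionCounts
    metrics: PerformanceMetrics

    @classmethod
    def from_counts(cls, category: str, method: str, counts: ConfusionCounts) -> "MethodScore":
        return cls(category=category, method=method, counts=counts,
                   metrics=compute_metrics(counts))


def score_methods(
    annotations: Iterable[ValidationAnnotation],
    tag_evidence: TaggedCorpus | None = None,
) -> list[MethodScore]:
    """Score every (category, method) against the all-methods reference set.

    For each category, the reference set is the union of verdict-true
    (uid, label) pairs across all methods. A method's TP are its
    verdict-true proposals; FP its verdict-false proposals; FN the
    reference tags it did not propose; TN the verdict-false candidates it
    did not propose. Hence TP + FN always equals the reference-set size.
    """
    annotations = [a for a in annotations if not a.skip]
    if tag_evidence is not None:
        evidence_keys = {
            (a.uid, a.category, a.label) for a in tag_evidence.assignments
            if a.label != UNTAGGED
        }
        orphans = sorted(
            {(a.uid, a.category, a.label) for a in annotations} - evidence_keys
        )
        if orphans:
            raise EvaluationError(
                f"annotations without a matching evidence row: {orphans[:10]}"
                + ("..." if len(orphans) > 10 else "")
            )

    by_category: dict[str, list[ValidationAnnotation]] = {}
    for a in annotations:
        by_category.setdefault(a.category, []).append(a)

    scores: list[MethodScore] = []
    for category in sorted(by_category):
        anns = by_category[category]
        verdicts: dict[tuple[str, str], bool] = {}
        for a in anns:
            key = (a.uid, a.label)
            if key in verdicts and verdicts[key] != a.verdict:
                raise EvaluationError(
                    f"inconsistent verdicts for {key} in category {category!r}"
                )
            verdicts[key] = a.verdict
        reference = {k for k, v in verdicts.items() if v}
        negatives = {k for k, v in verdicts.items() if not v}
        methods = sorted({a.method for a in anns},
                         key=lambda m: METHODS.index(m) if m in METHODS else len(METHODS))
        for method in methods:
            proposed = {(a.uid, a.label) for a in anns if a.method == method}
            counts = ConfusionCounts(
                tp=len(proposed & reference),
                fp=len(proposed & negatives),
                fn=len(reference - proposed),
                tn=len(negatives - proposed),
            )
            scores.append(MethodScore.from_counts(category, method, counts))
    return scores


# ---------------------------------------------------------------------------
# validation sampling


#: matching surfaces applicable per category
CATEGORY_SURFACES: dict[str, tuple[str, ...]] = {
    "model": ("tiabkw", "fulltext", "model_sentence"),
    "sex": ("tiabkw", "fulltext", "model_sentence"),
    "species": ("tiabkw", "fulltext", "model_sentence"),
    "outcome": ("tiabkw", "fulltext"),
    "intervention": ("tiabkw",),
}


def eligible_for_validation(
    tagged: TaggedCorpus, require: Sequence[str] = ("model", "sex", "species", "outcome")
) -> list[str]:
    """Citations carrying >= 1 match in every required category on every
    applicable surface — the stratum validation samples are drawn from."""
    by_uid: dict[str, list] = {}
    for a in tagged.assignments:
        if a.label != UNTAGGED:
            by_uid.setdefault(a.uid, []).append(a)
    out: list[str] = []
    for uid in sorted(tagged.uids()):
        ok = True
        for category in require:
            hit = {surface: False for surface in CATEGORY_SURFACES[category]}
            for a in by_uid.get(uid, []):
                if a.category != category:
                    continue
                for surface in hit:
                    if a.evidence.get(surface, 0) >= 1:
                        hit[surface] = True
            if not all(hit.values()):
                ok = False
                break
        if ok:
            out.append(uid)
    return out


def sample_for_validation(
    tagged: TaggedCorpus,
    n: int,
    seed: int,
    require: Sequence[str] = ("model", "sex", "species", "outcome"),
) -> list[str]:
    """Uniform sample (without replacement) of fully tagged citations."""
    if n < 1:
        raise EvaluationError("n must be >= 1")
    stratum = eligible_for_validation(tagged, require)
    log.info("validation stratum: %d eligible citation(s)", len(stratum))
    if len(stratum) < n:
        raise EvaluationError(
            f"eligible stratum has only {len(stratum)} record(s); cannot sample {n}"
        )
    return sorted(random.Random(seed).sample(stratum, n))


# ---------------------------------------------------------------------------
# optimal-policy selection


@dataclass
class PolicySelection:
    """The selected policy with the chosen method per category and any warnings."""

    policy: TagPolicy
    chosen: dict[str, list[str]]
    warnings: list[str]


def _method_to_rule(methods: Sequence[str]) -> CategoryRule:
    kwargs: dict[str, int] = {}
    for m in methods:
        fld, minimum = METHOD_THRESHOLDS[m]
        key = {"tiabkw": "tiabkw_min", "fulltext": "fulltext_min",
               "model_sentence": "model_sentence_min"}[fld]
        kwargs[key] = min(minimum, kwargs.get(key, minimum))
    return CategoryRule(**kwargs)


def select_policy(
    scores: Iterable[MethodScore],
    precision_floor: float = 0.80,
    tolerance: float = 0.01,
    similarity_band: float = 0.05,
) -> PolicySelection:
    """Derive the per-category tagging policy from a scored method table.

    A method is admitted when its precision exceeds ``precision_floor -
    tolerance``; admissions at or below the floor itself are flagged as
    near misses. Per category the policy enables the tiabkw surface when
    admitted, plus one non-tiabkw method: among admitted non-tiabkw
    methods whose precision lies within ``similarity_band`` of the best
    admitted precision, the one with the highest sensitivity ("similar
    precision -> prefer sensitivity"). A category whose only scored
    method fails the floor keeps that sole surface, with a warning;
    if several methods were scored and none is admitted, an error asks
    for a manual choice.
    """
    scores = list(scores)
    by_category: dict[str, list[MethodScore]] = {}
    for s in scores:
        by_category.setdefault(s.category, []).append(s)

    rules: dict[str, CategoryRule] = {}
    chosen: dict[str, list[str]] = {}
    warnings: list[str] = []
    for category in sorted(by_category):
        cat_scores = by_category[category]
        admitted = [
            s for s in cat_scores
            if s.metrics.precision is not None
            and s.metrics.precision > precision_floor - tolerance
        ]
        for s in admitted:
            if s.metrics.precision <= precision_floor:
                warnings.append(
                    f"{category}/{s.method}: precision {s.metrics.precision:.3f} admitted "
                    f"within tolerance below the {precision_floor:.2f} floor"
                )
        if not admitted:
            if len(cat_scores) == 1:
                sole = cat_scores[0]
                warnings.append(
                    f"{category}/{sole.method}: precision "
                    f"{(sole.metrics.precision if sole.metrics.precision is not None else float('nan')):.3f} "
                    f"below the floor but kept as the category's only implemented surface"
                )
                admitted = [sole]
            else:
                raise EvaluationError(
                    f"no method clears the precision floor for category {category!r}; "
                    "manual choice required"
                )
        selected: list[str] = []
        if any(s.method == "tiabkw" for s in admitted):
            selected.append("tiabkw")
        non_tiabkw = [s for s in admitted if s.method != "tiabkw"]
        if non_tiabkw:
            best_precision = max(s.metrics.precision for s in non_tiabkw)
            band = [s for s in non_tiabkw
                    if s.metrics.precision >= best_precision - similarity_band]
            band.sort(key=lambda s: (
                -(s.metrics.sensitivity if s.metrics.sensitivity is not None else -1.0),
                -(s.metrics.precision or 0.0),
                METHODS.index(s.method) if s.method in METHODS else len(METHODS),
            ))
            selected.append(band[0].method)
        rules[category] = _method_to_rule(selected)
        chosen[category] = selected
    for message in warnings:
        log.warning(message)
    return PolicySelection(
        policy=TagPolicy(rules=rules, high_sensitivity=False),
        chosen=chosen,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# published reference table


def _reference_rows() -> list[dict[str, str]]:
    path = resources.files("soles.data") / "tagging_validation_counts.csv"
    with path.open(encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def reference_validation_table() -> list[MethodScore]:
    """The published AD-SOLES tagging-validation method table, as printed.

    Each row carries the published confusion counts and the published
    3-decimal metric cells (blank = not printed). The printed metrics are
    attached verbatim — this is the table the published tagging policy
    was selected from, so policy-selection reproduction must consume the
    printed cells, a handful of which differ from TP/(TP+FP) etc. in the
    third decimal. Use :func:`recompute_reference_metrics` for metrics
    recomputed from the counts.
    """
    scores: list[MethodScore] = []
    for row in _reference_rows():
        counts = ConfusionCounts(
            tp=int(row["tp"]), fp=int(row["fp"]),
            tn=int(row["tn"] or 0), fn=int(row["fn"] or 0),
        )
        metrics = PerformanceMetrics(
            sensitivity=float(row["sensitivity"]) if row["sensitivity"] else None,
            specificity=float(row["specificity"]) if row["specificity"] else None,
            precision=float(row["precision"]) if row["precision"] else None,
            f1=None,
        )
        scores.append(MethodScore(category=row["category"], method=row["method"],
                                  counts=counts, metrics=metrics))
    return scores


def recompute_reference_metrics() -> list[MethodScore]:
    """The same reference table with metrics recomputed from the raw counts."""
    scores: list[MethodScore] = []
    for row in _reference_rows():
        counts = ConfusionCounts(
            tp=int(row["tp"]), fp=int(row["fp"]),
            tn=int(row["tn"] or 0), fn=int(row["fn"] or 0),
        )
        scores.append(MethodScore.from_counts(row["category"], row["method"], counts))
    return scores
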