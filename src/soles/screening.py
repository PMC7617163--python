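"""In-vivo-relevance screening: a pluggable scorer contract with run logging.

Screening decides, from title + abstract alone, whether a citation is
likely to report experiments in a living animal model. The production
classifier behind the published workflow is an externally hosted
service; this module defines the contract any scorer must satisfy (a
deterministic-given-seed map from text to an inclusion probability) and
ships a transparent baseline — a bag-of-words logistic regression — that
conforms to it. Every evaluation appends a uniquely identified run to a
performance log so sensitivity/specificity drift across retraining
cycles can be tracked, and runs breaching declared floors flagged.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline

from .evaluation import ConfusionCounts, PerformanceMetrics, compute_metrics

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5
DEFAULT_SENSITIVITY_FLOOR = 0.90
DEFAULT_SPECIFICITY_FLOOR = 0.85


class ScreeningError(Exception):
    pass


@dataclass(frozen=True)
class LabelledDecision:
    """One verified human screening decision for a citation."""

    uid: str
    included: bool
    n_reviewers: int = 1

    def __post_init__(self) -> None:
        if self.n_reviewers < 1:
            raise ScreeningError("n_reviewers must be >= 1")


def load_decisions(path: str | Path) -> list[LabelledDecision]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                LabelledDecision(
                    uid=row["uid"],
                    included=(row.get("included") or "").strip().lower() in ("true", "1", "yes"),
                    n_reviewers=int(row.get("n_reviewers") or 1),
                )
            )
    return out


class Scorer(Protocol):
    """Contract for a screening classifier: text in, inclusion probability out."""

    def score(self, text: str) -> float: ...

    def score_many(self, texts: Mapping[str, str]) -> dict[str, float]: ...


class BaselineScorer:
    """Bag-of-words logistic regression over title + abstract.

    Deterministic given the seed and the training data; any conforming
    scorer can stand in for it.
    """

    def __init__(self, pipeline: Pipeline, train_size: int, seed: int):
        self._pipeline = pipeline
        self.train_size = train_size
        self.seed = seed

    def score(self, text: str) -> float:
        return float(self._pipeline.predict_proba([text])[0, 1])

    def score_many(self, texts: Mapping[str, str]) -> dict[str, float]:
        uids = list(texts)
        if not uids:
            return {}
        probs = self._pipeline.predict_proba([texts[u] for u in uids])[:, 1]
        return {u: float(p) for u, p in zip(uids, probs)}


def train_scorer(
    decisions: Sequence[LabelledDecision],
    texts: Mapping[str, str],
    seed: int = 0,
) -> BaselineScorer:
    """Fit the baseline scorer on verified decisions and their texts.

    Requires at least two decisions per class; decisions verified by
    fewer than two reviewers are accepted but logged, since training data
    is expected to carry dual-reviewer agreement.
    """
    missing = [d.uid for d in decisions if d.uid not in texts]
    if missing:
        raise ScreeningError(f"decisions without a text: {missing[:5]}")
    weak = sum(1 for d in decisions if d.n_reviewers < 2)
    if weak:
        log.warning("%d training decision(s) verified by fewer than two reviewers", weak)
    y = [d.included for d in decisions]
    if sum(y) < 2 or len(y) - sum(y) < 2:
        raise ScreeningError("need at least two decisions per class to train")
    pipeline = Pipeline([
        ("bow", CountVectorizer(lowercase=True)),
        ("lr", LogisticRegression(max_iter=1000, random_state=seed)),
    ])
    pipeline.fit([texts[d.uid] for d in decisions], y)
    return BaselineScorer(pipeline, train_size=len(decisions), seed=seed)


def stratified_split(
    decisions: Sequence[LabelledDecision],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[LabelledDecision], list[LabelledDecision]]:
    """Held-out evaluation split, stratified on the inclusion label."""
    train, test = train_test_split(
        list(decisions),
        test_size=test_fraction,
        random_state=seed,
        stratify=[d.included for d in decisions],
    )
    return list(train), list(test)


@dataclass
class ScreeningRun:
    """One logged evaluation of a scorer against held-out truth."""

    run_id: int
    timestamp: str
    train_size: int
    threshold: float
    counts: ConfusionCounts
    metrics: PerformanceMetrics

    @property
    def sensitivity(self) -> float | None:
        return self.metrics.sensitivity

    @property
    def specificity(self) -> float | None:
        return self.metrics.specificity


def evaluate_run(
    scores: Mapping[str, float],
    truth: Sequence[LabelledDecision],
    threshold: float = DEFAULT_THRESHOLD,
    run_id: int = 1,
    train_size: int = 0,
    timestamp: str | None = None,
) -> ScreeningRun:
    """Threshold the scores and compute the run's performance metrics.

    A citation is predicted included when its score is >= the threshold
    (ties count as included). Every scored uid must carry a truth label.
    """
    if not truth:
        raise ScreeningError("empty truth")
    truth_map = {d.uid: d.included for d in truth}
    missing = [u for u in scores if u not in truth_map]
    if missing:
        raise ScreeningError(f"scored uids without truth: {missing[:5]}")
    tp = fp = tn = fn = 0
    for uid, score in scores.items():
        predicted = score >= threshold
        actual = truth_map[uid]
        if predicted and actual:
            tp += 1
        elif predicted and not actual:
            fp += 1
        elif not predicted and actual:
            fn += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return ScreeningRun(
        run_id=run_id,
        timestamp=timestamp or datetime.now(timezone.utc).isoformat(timespec="seconds"),
        train_size=train_size,
        threshold=threshold,
        counts=counts,
        metrics=compute_metrics(counts),
    )


def performance_drift(
    runs: Iterable[ScreeningRun],
    floor_sens: float = DEFAULT_SENSITIVITY_FLOOR,
    floor_spec: float = DEFAULT_SPECIFICITY_FLOOR,
) -> list[int]:
    """Run ids whose sensitivity or specificity breached the declared floors."""
    flagged = []
    for run in runs:
        s, p = run.sensitivity, run.specificity
        if (s is not None and s < floor_sens) or (p is not None and p < floor_spec):
            flagged.append(run.run_id)
    return flagged


class RunLog:
    """Append-only CSV log of screening runs with monotonically increasing ids."""

    COLUMNS = ["run_id", "timestamp", "train_size", "threshold",
               "tp", "fp", "tn", "fn", "sensitivity", "specificity", "precision", "f1"]

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def read(self) -> list[ScreeningRun]:
        if not self.path.exists():
            return []
        runs = []
        with open(self.path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                counts = ConfusionCounts(tp=int(row["tp"]), fp=int(row["fp"]),
                                         tn=int(row["tn"]), fn=int(row["fn"]))
                runs.append(ScreeningRun(
                    run_id=int(row["run_id"]), timestamp=row["timestamp"],
                    train_size=int(row["train_size"]), threshold=float(row["threshold"]),
                    counts=counts, metrics=compute_metrics(counts),
                ))
        return runs

    def next_run_id(self) -> int:
        runs = self.read()
        return (max(r.run_id for r in runs) + 1) if runs else 1

    def append(self, run: ScreeningRun) -> None:
        exists = self.path.exists()
        with open(self.path, "a", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=self.COLUMNS)
            if not exists:
                w.writeheader()
            rounded = run.metrics.rounded()
            w.writerow({
                "run_id": run.run_id, "timestamp": run.timestamp,
                "train_size": run.train_size, "threshold": run.threshold,
                "tp": run.counts.tp, "fp": run.counts.fp,
                "tn": run.counts.tn, "fn": run.counts.fn,
                "sensitivity": rounded["sensitivity"] if rounded["sensitivity"] is not None else "",
                "specificity": rounded["specificity"] if rounded["specificity"] is not None else "",
                "precision": rounded["precision"] if rounded["precision"] is not None else "",
                "f1": rounded["f1"] if rounded["f1"] is not None else "",
            })
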