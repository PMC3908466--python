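"""Evaluation, cross-validation, strategy comparison and error taxonomy.

Detection performance is measured with exact-span matching: a predicted
span is a true positive only if a gold span with the same sentence, token
boundaries and concept type exists.  Precision is TP/(TP+FP), recall
TP/(TP+FN), and the F-score their harmonic mean.  Cross-validation folds
are drawn over documents and fold scores are macro-averaged (mean of the
per-fold ratios).

The error taxonomy compares a single-type model against the all-types
model over the gold spans of the target type: spans the all-types model got
exactly right but the single-type model did not are split into boundary
errors (some overlapping single-type prediction exists) and no-detection
(none does); type confusion counts single-type predictions whose boundaries
exactly match a gold span of a different type that the all-types model
labeled correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import ConceptSpan, Corpus
from .hmm_tagger import TaggerConfig, tag, train_full
from .tag_schemes import project_types

__all__ = [
    "EvalResult",
    "CvReport",
    "ErrorTaxonomy",
    "StrategySweep",
    "StrategyComparison",
    "compare_strategies",
    "f_score",
    "evaluate",
    "make_folds",
    "cross_validate",
    "paired_t_test",
    "strategy_sweep",
    "classify_errors",
]

SpanSets = Mapping[str, Sequence[ConceptSpan]]


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalResult:
    """Per-type exact-match counts with derived precision/recall/F."""

    counts: dict[str, tuple[int, int, int]]  # ctype -> (TP, FP, FN)

    def tp(self, ctype: str) -> int:
        return self.counts[ctype][0]

    def fp(self, ctype: str) -> int:
        return self.counts[ctype][1]

    def fn(self, ctype: str) -> int:
        return self.counts[ctype][2]

    def precision(self, ctype: str) -> float:
        tp, fp, _ = self.counts[ctype]
        return tp / (tp + fp) if tp + fp else 0.0

    def recall(self, ctype: str) -> float:
        tp, _, fn = self.counts[ctype]
        return tp / (tp + fn) if tp + fn else 0.0

    def f(self, ctype: str) -> float:
        return f_score(self.precision(ctype), self.recall(ctype))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, (tp, fp, fn) in self.counts.items():
            rows.append(
                {
                    "ctype": t,
                    "TP": tp,
                    "FP": fp,
                    "FN": fn,
                    "Prec.": self.precision(t),
                    "Rec.": self.recall(t),
                    "F-score": self.f(t),
                }
            )
        return pd.DataFrame(rows).set_index("ctype")


def _normalize(spans) -> dict[str, list[ConceptSpan]]:
    if isinstance(spans, Mapping):
        return {k: list(v) for k, v in spans.items()}
    return {"": list(spans)}


def _check_no_overlap(spans: list[ConceptSpan], what: str) -> None:
    ordered = sorted(spans)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping {what} spans: {a} / {b}")


def evaluate(gold, predicted, types: Sequence[str] | None = None) -> EvalResult:
    """Exact-span-and-type matching of predictions against gold annotations.

    ``gold`` and ``predicted`` are lists of spans (single document) or
    mappings doc_id -> spans.  ``types`` fixes the row order of the result;
    by default all types present in either set, gold first.
    """
    gold_m, pred_m = _normalize(gold), _normalize(predicted)
    seen: list[str] = list(types) if types is not None else []
    counts = {t: [0, 0, 0] for t in seen}

    def bucket(t: str):
        if t not in counts:
            counts[t] = [0, 0, 0]
        return counts[t]

    for doc in sorted(set(gold_m) | set(pred_m)):
        g = gold_m.get(doc, [])
        p = pred_m.get(doc, [])
        _check_no_overlap(g, "gold")
        _check_no_overlap(p, "predicted")
        gset, pset = set(g), set(p)
        for sp in g:
            bucket(sp.ctype)
        for sp in p:
            bucket(sp.ctype)
        for sp in pset:
            if sp in gset:
                bucket(sp.ctype)[0] += 1
            else:
                bucket(sp.ctype)[1] += 1
        for sp in gset - pset:
            bucket(sp.ctype)[2] += 1
    return EvalResult({t: tuple(c) for t, c in counts.items()})


@dataclass
class CvReport:
    """Per-fold evaluation results with macro-averaged summaries."""

    types: list[str]
    folds: list[EvalResult]
    seed: int
    # per fold: doc_id -> predicted spans on the held-out documents
    predictions: list[dict[str, list[ConceptSpan]]] = field(default_factory=list)

    def merged_predictions(self) -> dict[str, list[ConceptSpan]]:
        out: dict[str, list[ConceptSpan]] = {}
        for fold in self.predictions:
            out.update(fold)
        return out

    def mean_precision(self, ctype: str) -> float:
        return float(np.mean([f.precision(ctype) for f in self.folds]))

    def mean_recall(self, ctype: str) -> float:
        return float(np.mean([f.recall(ctype) for f in self.folds]))

    def mean_f(self, ctype: str) -> float:
        return float(np.mean([f.f(ctype) for f in self.folds]))

    def fold_f(self, ctype: str) -> list[float]:
        return [f.f(ctype) for f in self.folds]

    def to_frame(self) -> pd.DataFrame:
        """Pooled counts plus macro-averaged ratios, one row per type."""
        rows = []
        for t in self.types:
            rows.append(
                {
                    "ctype": t,
                    "TP": sum(f.tp(t) for f in self.folds),
                    "FP": sum(f.fp(t) for f in self.folds),
                    "FN": sum(f.fn(t) for f in self.folds),
                    "Prec.": self.mean_precision(t),
                    "Rec.": self.mean_recall(t),
                    "F-score": self.mean_f(t),
                }
            )
        return pd.DataFrame(rows).set_index("ctype")


def make_folds(corpus: Corpus, k: int, seed: int) -> list[list[int]]:
    """Deterministic k-fold partition of document indices (sizes +/- 1)."""
    n = len(corpus.documents)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} documents available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [sorted(order[i::k].tolist()) for i in range(k)]


def cross_validate(
    corpus: Corpus,
    strategy_types: Sequence[str] | None = None,
    k: int = 10,
    seed: int = 0,
    config: TaggerConfig | None = None,
) -> CvReport:
    """k-fold cross-validation of the tagger under a detection strategy.

    For each fold the tagger is trained on the remaining documents (after
    projection onto ``strategy_types``) and applied to the held-out
    documents; per-fold P/R/F are macro-averaged in the report.
    """
    config = config or TaggerConfig()
    types = list(strategy_types) if strategy_types is not None else list(corpus.type_inventory)
    work = project_types(corpus, types)
    folds = make_folds(work, k, seed)
    results = []
    predictions = []
    all_idx = set(range(len(work.documents)))
    for fold in folds:
        train_c = work.subset(sorted(all_idx - set(fold)))
        model = train_full(train_c, config=config)
        gold = {work.documents[i].doc_id: work.documents[i].spans for i in fold}
        pred = {
            work.documents[i].doc_id: tag(model, work.documents[i]) for i in fold
        }
        results.append(evaluate(gold, pred, types=types))
        predictions.append(pred)
    return CvReport(types=types, folds=results, seed=seed, predictions=predictions)


def paired_t_test(fold_scores_a: Sequence[float], fold_scores_b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired t-test on per-fold scores.

    Degenerate convention: if every paired difference is identical, the
    test statistic is undefined; we report (0, 1) when the differences are
    all zero and (signed inf, 0) when they are identical and nonzero.
    """
    a = np.asarray(fold_scores_a, dtype=float)
    b = np.asarray(fold_scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length score vectors with k >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        return math.copysign(float("inf"), float(d.mean())), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class StrategySweep:
    """Mean target-type F-score per incremental type subset."""

    target_type: str
    subsets: list[list[str]]
    mean_f: list[float]
    reports: list[CvReport] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset": ["+".join(s) for s in self.subsets],
                "n_types": [len(s) for s in self.subsets],
                "mean_F": self.mean_f,
            }
        )

    def plot(self, ax=None):
        """Bar plot of target-type mean F by type subset (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * len(self.subsets) + 2, 3))
        ax.bar(range(len(self.subsets)), self.mean_f, color="steelblue")
        ax.set_xticks(range(len(self.subsets)))
        ax.set_xticklabels(["+".join(s) for s in self.subsets], rotation=30, ha="right")
        ax.set_ylabel(f"mean F ({self.target_type})")
        ax.set_ylim(0, 1)
        return ax


def strategy_sweep(
    corpus: Corpus,
    target_type: str,
    subsets: Sequence[Sequence[str]],
    k: int = 10,
    seed: int = 0,
    config: TaggerConfig | None = None,
) -> StrategySweep:
    """Cross-validate the tagger over incremental type subsets.

    Every subset must contain the target type; the reported series is the
    target type's macro-averaged F per subset (the rightmost/full subset is
    the all-types-at-once strategy).
    """
    subsets = [list(s) for s in subsets]
    for s in subsets:
        if target_type not in s:
            raise ValueError(f"subset {s} does not contain target {target_type!r}")
    reports = [cross_validate(corpus, s, k=k, seed=seed, config=config) for s in subsets]
    return StrategySweep(
        target_type=target_type,
        subsets=subsets,
        mean_f=[r.mean_f(target_type) for r in reports],
        reports=reports,
    )


@dataclass
class StrategyComparison:
    """All-types vs single-type cross-validation on one corpus."""

    target_type: str
    report_all: CvReport
    report_single: CvReport
    taxonomy: "ErrorTaxonomy"

    @property
    def gap(self) -> float:
        """Mean-F advantage of the all-types strategy for the target type."""
        return self.report_all.mean_f(self.target_type) - self.report_single.mean_f(
            self.target_type
        )


def compare_strategies(
    corpus: Corpus,
    target_type: str,
    k: int = 10,
    seed: int = 0,
    config: TaggerConfig | None = None,
) -> StrategyComparison:
    """Cross-validate all-types-at-once against one-type-at-a-time.

    Both strategies use the same document folds (same seed), so per-fold
    scores are paired; cross-validated predictions from both strategies are
    compared through the three-way error taxonomy against the full gold
    annotation.
    """
    rep_all = cross_validate(corpus, None, k=k, seed=seed, config=config)
    rep_single = cross_validate(corpus, [target_type], k=k, seed=seed, config=config)
    gold = {d.doc_id: list(d.spans) for d in corpus.documents}
    taxonomy = classify_errors(
        gold,
        rep_all.merged_predictions(),
        rep_single.merged_predictions(),
        target_type,
    )
    return StrategyComparison(
        target_type=target_type,
        report_all=rep_all,
        report_single=rep_single,
        taxonomy=taxonomy,
    )


@dataclass
class ErrorTaxonomy:
    """Additional errors of a single-type model vs the all-types model."""

    target_type: str
    type_confusion: int = 0
    boundary_error: int = 0
    no_detection: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ctype": self.target_type,
                    "Type confusion": self.type_confusion,
                    "Boundary error": self.boundary_error,
                    "No detection": self.no_detection,
                }
            ]
        ).set_index("ctype")


def classify_errors(gold, pred_all, pred_single, target_type: str) -> ErrorTaxonomy:
    """Three-way taxonomy of single-type errors relative to the all-types run.

    Inputs are span lists or doc_id -> span mappings; ``pred_single`` holds
    only target-type predictions.  Counting rules: over target-type gold
    spans exactly correct under ``pred_all`` and not under ``pred_single``,
    a boundary error is charged when some single-model span overlaps the
    gold span and a no-detection otherwise.  Type confusion counts
    single-model spans whose boundaries exactly match a gold span of a
    different type that the all-types model labeled with its true type.
    """
    gold_m, all_m, single_m = _normalize(gold), _normalize(pred_all), _normalize(pred_single)
    tax = ErrorTaxonomy(target_type=target_type)
    for doc in sorted(set(gold_m) | set(all_m) | set(single_m)):
        g = gold_m.get(doc, [])
        pa = set(all_m.get(doc, []))
        ps = list(single_m.get(doc, []))
        ps_set = set(ps)
        for gs in g:
            if gs.ctype != target_type or gs not in pa or gs in ps_set:
                continue
            if any(s.overlaps(gs) for s in ps):
                tax.boundary_error += 1
            else:
                tax.no_detection += 1
        gold_by_pos = {(s.sent_index, s.start, s.end): s for s in g}
        for s in ps:
            hit = gold_by_pos.get((s.sent_index, s.start, s.end))
            if hit is not None and hit.ctype != target_type and hit in pa:
                tax.type_confusion += 1
    return tax
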