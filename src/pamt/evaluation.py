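"""Repeated random subsampling cross-validation and diagnostic metrics.

The evaluation protocol mirrors small-sample diagnostic-accuracy
practice: the labelled corpus is repeatedly partitioned at random,
without replacement, into a training set and a validation set whose
class composition is fixed (default 3 positive + 7 negative); a fresh
model is fitted per repeat and the standard 2x2 metrics (sensitivity,
specificity, PPV, NPV, accuracy) plus the Youden index
(sens + spec - 1) are averaged over repeats.

Because every validation fold has the same composition, two identities
hold exactly for any predictor:

    mean acc    = (v_pos * mean sens + v_neg * mean spec) / (v_pos + v_neg)
    mean youden = mean sens + mean spec - 1

Repeats in which PPV or NPV is undefined (no predicted positives /
negatives) are excluded from that metric's mean and counted, never
imputed.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifiers import ModelBuilder
from .corpus import N_RATERS, NEGATIVE, POSITIVE, Corpus

__all__ = [
    "MetricSet",
    "CVConfig",
    "CVResult",
    "CertaintyProfile",
    "confusion_metrics",
    "youden_index",
    "fixed_composition_accuracy",
    "split_fixed_composition",
    "rrs_cv",
    "certainty_stratified_accuracy",
    "learning_curve",
    "feature_cooccurrence_correlation",
]

#: Certainty levels counted as "certain" (the rest are "uncertain").
CERTAIN_LEVELS = (5, 6)


def youden_index(sens: float, spec: float) -> float:
    """Youden's J = sensitivity + specificity - 1 (same scale as inputs)."""
    return sens + spec - 1.0


def fixed_composition_accuracy(
    sens: float, spec: float, val_pos: int = 3, val_neg: int = 7
) -> float:
    """Accuracy implied by sens/spec under a fixed validation composition.

    With every fold holding exactly ``val_pos`` positives and ``val_neg``
    negatives, per-fold accuracy is a fixed convex combination of
    per-fold sensitivity and specificity, so the identity also holds for
    the means.  Scale-agnostic (works on proportions or percentages).
    """
    return (val_pos * sens + val_neg * spec) / (val_pos + val_neg)


@dataclass
class MetricSet:
    """Diagnostic metrics; ratios with a zero denominator are None, not 0."""

    sens: float | None
    spec: float | None
    ppv: float | None
    npv: float | None
    acc: float
    youden: float | None
    counts: tuple[int, int, int, int] | None = None  # (TP, FP, TN, FN)

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "MetricSet":
        total = tp + fp + tn + fn
        if total == 0:
            raise ValueError("empty confusion matrix")
        sens = tp / (tp + fn) if (tp + fn) else None
        spec = tn / (tn + fp) if (tn + fp) else None
        return cls(
            sens=sens,
            spec=spec,
            ppv=tp / (tp + fp) if (tp + fp) else None,
            npv=tn / (tn + fn) if (tn + fn) else None,
            acc=(tp + tn) / total,
            youden=youden_index(sens, spec) if (sens is not None and spec is not None) else None,
            counts=(tp, fp, tn, fn),
        )


def confusion_metrics(y_true: Sequence[str], y_pred: Sequence[str]) -> MetricSet:
    """2x2 confusion metrics from aligned label sequences."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("cannot compute metrics on empty input")
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == POSITIVE:
            tp += p == POSITIVE
            fn += p != POSITIVE
        else:
            tn += p != POSITIVE
            fp += p == POSITIVE
    return MetricSet.from_counts(tp, fp, tn, fn)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol settings.

    ``leakage_mode="shared_space"`` selects one feature space on the
    whole corpus and reuses it across repeats (the historical protocol
    for this method); ``"strict"`` re-selects features inside each
    training fold, avoiding selection leakage.
    """

    repeats: int = 100
    val_pos: int = 3
    val_neg: int = 7
    seed: int = 0
    leakage_mode: str = "shared_space"

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.val_pos < 0 or self.val_neg < 0 or self.val_pos + self.val_neg < 1:
            raise ValueError("validation composition must be non-empty")
        if self.leakage_mode not in ("shared_space", "strict"):
            raise ValueError(f"unknown leakage_mode {self.leakage_mode!r}")


def split_fixed_composition(
    corpus: Corpus, cfg: CVConfig, repeat_index: int
) -> tuple[list[str], list[str]]:
    """One train/validation partition with fixed validation composition.

    Exactly ``cfg.val_pos`` positives and ``cfg.val_neg`` negatives are
    drawn without replacement into the validation set; the rest train.
    Deterministic given (seed, repeat_index): repeat r uses the rng
    stream seeded with seed + r.
    """
    pos_ids = [t.id for t in corpus if t.label == POSITIVE]
    neg_ids = [t.id for t in corpus if t.label == NEGATIVE]
    if len(pos_ids) < cfg.val_pos or len(neg_ids) < cfg.val_neg:
        raise ValueError(
            f"corpus has {len(pos_ids)} positives / {len(neg_ids)} negatives; "
            f"cannot hold out {cfg.val_pos}/{cfg.val_neg}"
        )
    rng = np.random.default_rng(cfg.seed + repeat_index)
    val = set(rng.choice(pos_ids, size=cfg.val_pos, replace=False))
    val |= set(rng.choice(neg_ids, size=cfg.val_neg, replace=False))
    train_ids = [i for i in corpus.ids() if i not in val]
    val_ids = [i for i in corpus.ids() if i in val]
    return train_ids, val_ids


def _mean_of_defined(values: list[float | None]) -> tuple[float | None, int]:
    defined = [v for v in values if v is not None]
    n_undef = len(values) - len(defined)
    return (sum(defined) / len(defined) if defined else None), n_undef


@dataclass
class CVResult:
    """Per-repeat metrics, their means, and per-case prediction records."""

    per_repeat: list[MetricSet]
    mean: MetricSet
    undefined_ppv_repeats: int
    undefined_npv_repeats: int
    #: case id -> list of booleans, one per repeat in which the case was
    #: held out for validation (True = predicted correctly).
    per_case_correct: dict[str, list[bool]] = field(default_factory=dict)
    config: CVConfig | None = None

    def to_csv(self, path: str | Path) -> None:
        cols = ["repeat", "sens", "spec", "ppv", "npv", "acc", "youden"]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for i, m in enumerate(self.per_repeat):
                w.writerow([i, m.sens, m.spec, m.ppv, m.npv, m.acc, m.youden])
            m = self.mean
            w.writerow(["mean", m.sens, m.spec, m.ppv, m.npv, m.acc, m.youden])

    def to_json(self) -> str:
        m = self.mean
        return json.dumps(
            {
                "repeats": len(self.per_repeat),
                "mean": {
                    "sens": m.sens,
                    "spec": m.spec,
                    "ppv": m.ppv,
                    "npv": m.npv,
                    "acc": m.acc,
                    "youden": m.youden,
                },
                "undefined_ppv_repeats": self.undefined_ppv_repeats,
                "undefined_npv_repeats": self.undefined_npv_repeats,
            }
        )


def _summarise(per_repeat: list[MetricSet]) -> tuple[MetricSet, int, int]:
    sens, _ = _mean_of_defined([m.sens for m in per_repeat])
    spec, _ = _mean_of_defined([m.spec for m in per_repeat])
    ppv, n_undef_ppv = _mean_of_defined([m.ppv for m in per_repeat])
    npv, n_undef_npv = _mean_of_defined([m.npv for m in per_repeat])
    acc = sum(m.acc for m in per_repeat) / len(per_repeat)
    youden = (
        youden_index(sens, spec) if sens is not None and spec is not None else None
    )
    mean = MetricSet(sens=sens, spec=spec, ppv=ppv, npv=npv, acc=acc, youden=youden)
    return mean, n_undef_ppv, n_undef_npv


def rrs_cv(corpus: Corpus, model_builder: ModelBuilder, cfg: CVConfig) -> CVResult:
    """Repeated random subsampling cross-validation.

    ``model_builder`` maps a list of training transcripts to a predictor
    (transcript -> label); it is called once per repeat.  Any feature
    selection shared across repeats belongs inside the builder's
    closure; re-selection per fold happens naturally when the builder
    selects from its training argument.
    """
    per_repeat: list[MetricSet] = []
    per_case: dict[str, list[bool]] = {}
    for r in range(cfg.repeats):
        train_ids, val_ids = split_fixed_composition(corpus, cfg, r)
        predictor = model_builder([corpus[i] for i in train_ids])
        y_true, y_pred = [], []
        for case_id in val_ids:
            t = corpus[case_id]
            pred = predictor(t)
            y_true.append(t.label)
            y_pred.append(pred)
            per_case.setdefault(case_id, []).append(pred == t.label)
        per_repeat.append(confusion_metrics(y_true, y_pred))
    mean, n_undef_ppv, n_undef_npv = _summarise(per_repeat)
    return CVResult(
        per_repeat=per_repeat,
        mean=mean,
        undefined_ppv_repeats=n_undef_ppv,
        undefined_npv_repeats=n_undef_npv,
        per_case_correct=per_case,
        config=cfg,
    )


@dataclass
class CertaintyProfile:
    """Model accuracy stratified by human-rater certainty level (0-6).

    Per-case correctness is the fraction of validation appearances the
    model got right; per-level accuracy averages it over the level's
    cases that appeared in validation at least once.  Levels 5-6 pool
    into the "certain" group, 0-4 into "uncertain".
    """

    per_level: dict[int, tuple[int, float | None]]  # level -> (n_cases, accuracy)
    certain_accuracy: float | None
    uncertain_accuracy: float | None
    per_case_correctness: dict[str, float]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["level", "n_cases", "accuracy"])
            for level in range(N_RATERS + 1):
                n, acc = self.per_level.get(level, (0, None))
                w.writerow([level, n, acc])
            w.writerow(["certain (5-6)", "", self.certain_accuracy])
            w.writerow(["uncertain (0-4)", "", self.uncertain_accuracy])


def certainty_stratified_accuracy(
    corpus: Corpus, per_case_correct: dict[str, list[bool]]
) -> CertaintyProfile:
    """Stratify per-case model correctness by rater certainty level.

    Every case must carry the full set of certainty votes.  Cases that
    never entered a validation fold contribute to the level counts but
    not to its accuracy.
    """
    levels: dict[str, int] = {}
    for t in corpus:
        if t.certainty_votes is None:
            raise ValueError(f"transcript {t.id!r} has no certainty votes")
        levels[t.id] = t.certainty_level
    per_case = {
        cid: sum(rec) / len(rec) for cid, rec in per_case_correct.items() if rec
    }
    per_level: dict[int, tuple[int, float | None]] = {}
    for level in range(N_RATERS + 1):
        ids = [cid for cid, lv in levels.items() if lv == level]
        scored = [per_case[cid] for cid in ids if cid in per_case]
        per_level[level] = (len(ids), sum(scored) / len(scored) if scored else None)

    def _group(level_set) -> float | None:
        scored = [
            per_case[cid]
            for cid, lv in levels.items()
            if lv in level_set and cid in per_case
        ]
        return sum(scored) / len(scored) if scored else None

    return CertaintyProfile(
        per_level=per_level,
        certain_accuracy=_group(set(CERTAIN_LEVELS)),
        uncertain_accuracy=_group(set(range(N_RATERS + 1)) - set(CERTAIN_LEVELS)),
        per_case_correctness=per_case,
    )


def learning_curve(
    corpus: Corpus,
    model_builder: ModelBuilder,
    train_sizes: Sequence[int],
    cfg: CVConfig,
) -> list[dict]:
    """Mean train/validation accuracy as the training set grows.

    For each requested size and each repeat, the fixed-composition
    validation fold is drawn exactly as in :func:`rrs_cv`; the training
    set is then a random subset of that size from the remaining pool
    (the whole pool when size equals it).  Subset draws are stratified
    to keep at least one case of each class.
    """
    pool_size = len(corpus) - cfg.val_pos - cfg.val_neg
    for s in train_sizes:
        if not 2 <= s <= pool_size:
            raise ValueError(f"train size {s} infeasible (pool is {pool_size})")
    records = []
    for s in train_sizes:
        train_accs, val_accs = [], []
        for r in range(cfg.repeats):
            train_ids, val_ids = split_fixed_composition(corpus, cfg, r)
            if s < len(train_ids):
                sub_rng = np.random.default_rng([cfg.seed, r, s])
                pos = [i for i in train_ids if corpus[i].label == POSITIVE]
                neg = [i for i in train_ids if corpus[i].label == NEGATIVE]
                n_pos = min(max(1, round(s * len(pos) / len(train_ids))), s - 1)
                chosen = set(sub_rng.choice(pos, size=n_pos, replace=False))
                chosen |= set(sub_rng.choice(neg, size=s - n_pos, replace=False))
                train_ids = [i for i in train_ids if i in chosen]
            predictor = model_builder([corpus[i] for i in train_ids])
            t_true = [corpus[i].label for i in train_ids]
            t_pred = [predictor(corpus[i]) for i in train_ids]
            v_true = [corpus[i].label for i in val_ids]
            v_pred = [predictor(corpus[i]) for i in val_ids]
            train_accs.append(confusion_metrics(t_true, t_pred).acc)
            val_accs.append(confusion_metrics(v_true, v_pred).acc)
        records.append(
            {
                "size": s,
                "train_accuracy": sum(train_accs) / len(train_accs),
                "val_accuracy": sum(val_accs) / len(val_accs),
            }
        )
    return records


def feature_cooccurrence_correlation(x: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of boolean term-occurrence indicators.

    Input is a (n_docs, n_terms) 0/1 matrix with n_docs >= 2.  Columns
    with no variation (term in every document or none) have undefined
    correlation and yield NaN rows/columns.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 documents")
    centred = x - x.mean(axis=0)
    cov = centred.T @ centred
    sd = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[:, sd == 0] = math.nan
    corr[sd == 0, :] = math.nan
    return corr
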