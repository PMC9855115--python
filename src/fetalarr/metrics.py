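"""Subject-level decisions and evaluation.

A subject's segments are classified by the CNN; the subject is called
arrhythmic when the fraction of arrhythmia-classified segments exceeds the
threshold ``th`` (strict).  In the ternary variant the fraction is
ARR / (ARR + NR), with moderate-classified segments excluded from the
denominator.  Cohort evaluation is leave-one-subject-out with per-fold
relabeling, so the held-out subject never influences the range table or the
training set of its own fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cnn as cnn_mod
from . import labeling as lab
from .types import (
    ARRHYTHMIA,
    ARRHYTHMIA_SEG,
    HEALTHY,
    MODERATE_SEG,
    NORMAL_SEG,
    RRISeries,
    Segment,
    SegmentPrediction,
    SubjectDecision,
)

DEFAULT_TH_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


# ---------------------------------------------------------------------------
# Ratios and decisions
# ---------------------------------------------------------------------------

def subject_ratio_binary(preds: list[SegmentPrediction]) -> float:
    """Fraction of the subject's segments classified as arrhythmia."""
    if not preds:
        raise ValueError("no predictions for subject")
    n_arr = sum(1 for p in preds if p.predicted == ARRHYTHMIA_SEG)
    return n_arr / len(preds)


def subject_ratio_ternary(preds: list[SegmentPrediction]) -> tuple[float, bool]:
    """ARR / (ARR + NR); moderate predictions leave the denominator.

    Returns (ratio, undefined_flag).  When every segment is classified
    moderate the ratio is undefined; the subject is flagged and will default
    to a healthy call.
    """
    if not preds:
        raise ValueError("no predictions for subject")
    n_arr = sum(1 for p in preds if p.predicted == ARRHYTHMIA_SEG)
    n_nr = sum(1 for p in preds if p.predicted == NORMAL_SEG)
    if n_arr + n_nr == 0:
        warnings.warn(
            f"subject {preds[0].subject_id}: all segments moderate — "
            "ratio undefined, defaulting to healthy",
            stacklevel=2,
        )
        return float("nan"), True
    return n_arr / (n_arr + n_nr), False


def classify_subject(ratio: float, th: float) -> str:
    """Arrhythmia call iff ratio strictly exceeds th (NaN never exceeds)."""
    if not 0.0 <= th <= 1.0:
        raise ValueError("th must lie in [0, 1]")
    return ARRHYTHMIA if ratio > th else HEALTHY


def make_decision(
    preds: list[SegmentPrediction],
    th: float,
    mode: str = "binary",
    true_class: str = "unknown",
) -> SubjectDecision:
    """Bundle one subject's segment predictions into a decision at ``th``."""
    n_arr = sum(1 for p in preds if p.predicted == ARRHYTHMIA_SEG)
    n_nr = sum(1 for p in preds if p.predicted == NORMAL_SEG)
    n_mod = sum(1 for p in preds if p.predicted == MODERATE_SEG)
    if mode == "binary":
        ratio, undefined = subject_ratio_binary(preds), False
    else:
        ratio, undefined = subject_ratio_ternary(preds)
    return SubjectDecision(
        subject_id=preds[0].subject_id,
        n_arr_segments=n_arr,
        n_nr_segments=n_nr,
        n_mod_segments=n_mod,
        ratio=ratio,
        th=th,
        predicted=HEALTHY if undefined else classify_subject(ratio, th),
        true_class=true_class,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsResult:
    specificity: float | None
    recall: float | None
    accuracy: float | None
    counts: ConfusionCounts
    undefined: list[str] = field(default_factory=list)


def confusion(decisions: list[SubjectDecision]) -> ConfusionCounts:
    c = ConfusionCounts()
    for d in decisions:
        if d.true_class not in (HEALTHY, ARRHYTHMIA):
            raise ValueError(f"decision for {d.subject_id} lacks a true class")
        if d.true_class == ARRHYTHMIA:
            if d.predicted == ARRHYTHMIA:
                c.TP += 1
            else:
                c.FN += 1
        else:
            if d.predicted == HEALTHY:
                c.TN += 1
            else:
                c.FP += 1
    return c


def compute_metrics(decisions: list[SubjectDecision]) -> MetricsResult:
    """Specificity TN/(TN+FP), recall TP/(TP+FN), accuracy (TP+TN)/all.

    A metric whose denominator is zero is reported as None and named in
    ``undefined``.
    """
    c = confusion(decisions)
    undefined = []
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else None
    if spec is None:
        undefined.append("specificity")
    rec = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    if rec is None:
        undefined.append("recall")
    acc = (c.TP + c.TN) / c.total if c.total else None
    if acc is None:
        undefined.append("accuracy")
    return MetricsResult(spec, rec, acc, c, undefined)


# ---------------------------------------------------------------------------
# Leave-one-subject-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Everything the evaluation needs for one subject."""

    subject_id: str
    true_class: str
    segments: list[Segment]
    rris: RRISeries


def _fold_labels(
    train_subjects: list[SubjectData],
    mode: str,
    x: float,
    moderate_target: float,
) -> tuple[list[Segment], list[str]]:
    segments = [s for subj in train_subjects for s in subj.segments]
    if mode == "histogram":
        table = lab.build_rri_histogram([subj.rris for subj in train_subjects])
        table = lab.classify_rri_ranges(table, x)
        labels = lab.label_segments(segments, table)
    elif mode == "simple":
        labels = lab.label_segments_simple(segments)
    elif mode == "per_subject":
        labels = []
        bands = {
            subj.subject_id: lab.subject_band(
                subj.rris, lab.calibrate_y(subj.rris, moderate_target)
            )
            for subj in train_subjects
            if subj.true_class == ARRHYTHMIA
        }
        for subj in train_subjects:
            for s in subj.segments:
                labels.append(
                    lab.label_segment_per_subject(s, bands.get(subj.subject_id))
                )
    else:
        raise ValueError(f"unknown labeling mode {mode!r}")
    return segments, labels


def loso_subject_ratios(
    subjects: list[SubjectData],
    x: float = 0.63,
    config: cnn_mod.CNNConfig | None = None,
    mode: str = "histogram",
    moderate_target: float = 0.5,
) -> dict[str, tuple[float, bool]]:
    """Held-out arrhythmia-segment ratio per subject under LOSO.

    For each fold the range table (or subject bands), training labels and the
    CNN are rebuilt from the remaining subjects only.  Returns
    ``{subject_id: (ratio, undefined_flag)}``.
    """
    n_per_class = {c: sum(1 for s in subjects if s.true_class == c) for c in (HEALTHY, ARRHYTHMIA)}
    if min(n_per_class.values()) < 2:
        raise ValueError(f"need at least 2 subjects per class, got {n_per_class}")
    classifier_mode = "ternary" if mode == "per_subject" else "binary"
    ratio_mode = "ternary" if mode == "per_subject" else "binary"
    base = config or cnn_mod.CNNConfig()
    ratios: dict[str, tuple[float, bool]] = {}
    for fold, held in enumerate(subjects):
        train_subjects = [s for s in subjects if s.subject_id != held.subject_id]
        try:
            segments, labels = _fold_labels(train_subjects, mode, x, moderate_target)
            X, y, _classes = cnn_mod.build_training_set(segments, labels, mode=classifier_mode)
        except ValueError as exc:
            warnings.warn(f"fold {held.subject_id} skipped: {exc}", stacklevel=2)
            continue
        cfg = cnn_mod.CNNConfig(
            **{
                **{f: getattr(base, f) for f in base.__dataclass_fields__},
                "n_classes": 3 if classifier_mode == "ternary" else 2,
                "seed": base.seed + fold,
            }
        )
        model = cnn_mod.train(cfg, X, y)
        preds = cnn_mod.predict(model, held.segments)
        if ratio_mode == "binary":
            ratios[held.subject_id] = (subject_ratio_binary(preds), False)
        else:
            ratios[held.subject_id] = subject_ratio_ternary(preds)
    return ratios


def sweep_thresholds(
    ratios: dict[str, tuple[float, bool]],
    true_classes: dict[str, str],
    th_grid=DEFAULT_TH_GRID,
    x: float | None = None,
    mode: str = "histogram",
) -> pd.DataFrame:
    """Metrics at every th for fixed per-subject ratios."""
    rows = []
    for th in th_grid:
        decisions = []
        for sid, (ratio, undefined) in ratios.items():
            predicted = HEALTHY if undefined else classify_subject(ratio, th)
            decisions.append(
                SubjectDecision(
                    subject_id=sid, n_arr_segments=0, n_nr_segments=0,
                    n_mod_segments=0, ratio=ratio, th=th, predicted=predicted,
                    true_class=true_classes[sid], undefined=undefined,
                )
            )
        m = compute_metrics(decisions)
        rows.append(
            {
                "x": x, "th": th, "labeling_mode": mode,
                "specificity": m.specificity, "recall": m.recall,
                "accuracy": m.accuracy,
                "TP": m.counts.TP, "TN": m.counts.TN,
                "FP": m.counts.FP, "FN": m.counts.FN,
            }
        )
    return pd.DataFrame(rows)


def loso_evaluate(
    subjects: list[SubjectData],
    x: float = 0.63,
    th_grid=DEFAULT_TH_GRID,
    config: cnn_mod.CNNConfig | None = None,
    mode: str = "histogram",
    moderate_target: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, tuple[float, bool]]]:
    """Full LOSO evaluation: metrics table over the th grid + subject ratios."""
    ratios = loso_subject_ratios(subjects, x=x, config=config, mode=mode,
                                 moderate_target=moderate_target)
    true_classes = {s.subject_id: s.true_class for s in subjects}
    table = sweep_thresholds(ratios, true_classes, th_grid, x=x, mode=mode)
    return table, ratios


def decisions_to_csv(decisions: list[SubjectDecision], path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": d.subject_id, "ratio": d.ratio, "th": d.th,
                "predicted": d.predicted, "true_class": d.true_class,
                "n_arr_segments": d.n_arr_segments,
                "n_nr_segments": d.n_nr_segments,
                "n_mod_segments": d.n_mod_segments, "undefined": d.undefined,
            }
            for d in decisions
        ]
    ).to_csv(path, index=False)
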