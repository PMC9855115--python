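import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetalarr import metrics as met
from fetalarr.types import (
    ARRHYTHMIA,
    ARRHYTHMIA_SEG,
    HEALTHY,
    MODERATE_SEG,
    NORMAL_SEG,
    SegmentPrediction,
    SubjectDecision,
)


def _preds(n_arr, n_nr, n_mod=0, sid="s"):
    mk = lambda lbl, i: SegmentPrediction(subject_id=sid, start_time=float(i),
                                          predicted=lbl)
    out = []
    i = 0
    for lbl, n in ((ARRHYTHMIA_SEG, n_arr), (NORMAL_SEG, n_nr), (MODERATE_SEG, n_mod)):
        for _ in range(n):
            out.append(mk(lbl, i))
            i += 1
    return out


def _decision(true_class, predicted):
    return SubjectDecision(subject_id="s", n_arr_segments=0, n_nr_segments=0,
                           n_mod_segments=0, ratio=0.0, th=0.5,
                           predicted=predicted, true_class=true_class)


def test_binary_ratio():
    assert met.subject_ratio_binary(_preds(200, 321)) == pytest.approx(200 / 521)
    with pytest.raises(ValueError):
        met.subject_ratio_binary([])


def test_ternary_ratio_excludes_moderate():
    ratio, undefined = met.subject_ratio_ternary(_preds(3, 5, 12))
    assert not undefined
    assert ratio == pytest.approx(3 / 8)


def test_ternary_ratio_all_moderate_is_undefined():
    with pytest.warns(UserWarning):
        ratio, undefined = met.subject_ratio_ternary(_preds(0, 0, 4))
    assert undefined and np.isnan(ratio)


def test_classify_subject_strict_threshold():
    assert met.classify_subject(0.63, 0.63) == HEALTHY
    assert met.classify_subject(np.nextafter(0.63, 1.0), 0.63) == ARRHYTHMIA
    assert met.classify_subject(float("nan"), 0.5) == HEALTHY
    with pytest.raises(ValueError):
        met.classify_subject(0.5, 1.5)


def test_make_decision_counts_and_call():
    d = met.make_decision(_preds(6, 4), th=0.5, true_class=ARRHYTHMIA)
    assert (d.n_arr_segments, d.n_nr_segments, d.n_mod_segments) == (6, 4, 0)
    assert d.ratio == pytest.approx(0.6)
    assert d.predicted == ARRHYTHMIA


def test_compute_metrics_hand_arithmetic():
    decisions = (
        [_decision(ARRHYTHMIA, ARRHYTHMIA)] * 10  # TP
        + [_decision(ARRHYTHMIA, HEALTHY)] * 2  # FN
        + [_decision(HEALTHY, HEALTHY)] * 13  # TN
        + [_decision(HEALTHY, ARRHYTHMIA)] * 1  # FP
    )
    m = met.compute_metrics(decisions)
    assert m.specificity == pytest.approx(13 / 14)
    assert m.recall == pytest.approx(10 / 12)
    assert m.accuracy == pytest.approx(23 / 26)
    assert (m.counts.TP, m.counts.TN, m.counts.FP, m.counts.FN) == (10, 13, 1, 2)


def test_compute_metrics_perfect_cohort():
    decisions = [_decision(HEALTHY, HEALTHY)] * 14 + [_decision(ARRHYTHMIA, ARRHYTHMIA)] * 12
    m = met.compute_metrics(decisions)
    assert m.specificity == m.recall == m.accuracy == 1.0


def test_compute_metrics_undefined_denominators():
    m = met.compute_metrics([_decision(HEALTHY, HEALTHY)] * 3)
    assert m.recall is None and "recall" in m.undefined
    assert m.specificity == 1.0


def test_compute_metrics_requires_true_class():
    with pytest.raises(ValueError):
        met.compute_metrics([_decision("unknown", HEALTHY)])


@settings(derandomize=True, max_examples=100)
@given(ratios=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
def test_arrhythmia_calls_non_increasing_in_th(ratios):
    grid = met.DEFAULT_TH_GRID
    calls = [
        sum(met.classify_subject(r, th) == ARRHYTHMIA for r in ratios) for th in grid
    ]
    assert all(b <= a for a, b in zip(calls, calls[1:]))


def test_sweep_thresholds_table():
    ratios = {"h1": (0.1, False), "h2": (0.7, False), "a1": (0.8, False), "a2": (0.4, False)}
    truth = {"h1": HEALTHY, "h2": HEALTHY, "a1": ARRHYTHMIA, "a2": ARRHYTHMIA}
    table = met.sweep_thresholds(ratios, truth, th_grid=(0.0, 0.5, 0.75, 1.0), x=0.63)
    assert len(table) == 4
    row = table[table.th == 0.5].iloc[0]
    assert (row.TP, row.TN, row.FP, row.FN) == (1, 1, 1, 1)
    assert row.accuracy == pytest.approx(0.5)
    row = table[table.th == 0.75].iloc[0]
    assert (row.TP, row.TN, row.FP, row.FN) == (1, 2, 0, 1)
    # at th = 1.0 nothing exceeds: all called healthy
    row = table[table.th == 1.0].iloc[0]
    assert (row.TP, row.FP) == (0, 0)


def test_sweep_thresholds_undefined_ratio_defaults_healthy():
    ratios = {"a1": (float("nan"), True)}
    table = met.sweep_thresholds(ratios, {"a1": ARRHYTHMIA}, th_grid=(0.0,))
    assert table.iloc[0].FN == 1


def test_loso_requires_two_subjects_per_class(extracted_cohort):
    with pytest.raises(ValueError):
        met.loso_subject_ratios(extracted_cohort[:3])


def test_decisions_to_csv(tmp_path):
    met.decisions_to_csv([_decision(HEALTHY, HEALTHY)], tmp_path / "d.csv")
    text = (tmp_path / "d.csv").read_text()
    assert text.startswith("subject_id,")
    assert len(text.strip().splitlines()) == 2
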