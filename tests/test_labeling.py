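import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetalarr import labeling as lab
from fetalarr.types import (
    ARRHYTHMIA,
    ARRHYTHMIA_SEG,
    HEALTHY,
    MODERATE_SEG,
    NORMAL_SEG,
    RRISeries,
    Segment,
)


def _series(intervals, true_class=HEALTHY, sid="s"):
    iv = np.asarray(intervals, dtype=float)
    starts = np.concatenate([[0.0], np.cumsum(iv)[:-1]])
    return RRISeries(intervals=iv, start_times=starts, end_times=starts + iv,
                     subject_id=sid, true_class=true_class)


def _segment(rris, subject_class=ARRHYTHMIA):
    return Segment(subject_id="s", start_time=0.0, samples=np.zeros(1500),
                   contained_rris=np.asarray(rris, float), subject_class=subject_class)


# -- histogram ---------------------------------------------------------------

def test_histogram_pools_classes_into_25ms_bins():
    t = lab.build_rri_histogram(
        [_series([410, 412, 430], HEALTHY), _series([410, 610], ARRHYTHMIA)]
    )
    assert t.n_bins == 32
    i = t.bin_index(410.0)
    assert t.healthy_count[i] == 2 and t.arrhythmia_count[i] == 1
    assert t.ratio[i] == pytest.approx(2.0)
    j = t.bin_index(610.0)
    assert t.healthy_count[j] == 0 and t.arrhythmia_count[j] == 1
    assert math.isinf(t.ratio[t.bin_index(430.0)])
    assert math.isnan(t.ratio[t.bin_index(100.0)])


def test_bin_index_edges():
    t = lab.build_rri_histogram([_series([400], HEALTHY), _series([400], ARRHYTHMIA)])
    assert t.bin_index(100.0) == 0
    assert t.bin_index(124.999) == 0
    assert t.bin_index(125.0) == 1
    assert t.bin_index(99.9) is None
    assert t.bin_index(900.0) is None


def test_classify_ratio_boundaries():
    x = 0.63
    assert lab.classify_ratio(1.5, x) == "N"
    assert lab.classify_ratio(math.inf, x) == "N"
    assert lab.classify_ratio(1.0, x) == "M"  # exactly 1 is not "more healthy"
    assert lab.classify_ratio(x, x) == "M"  # strict inequality at the threshold
    assert lab.classify_ratio(np.nextafter(x, 0.0), x) == "A"
    assert lab.classify_ratio(0.0, x) == "A"
    assert lab.classify_ratio(math.nan, x) == lab.CLASS_UNOBSERVED


def test_classify_rri_ranges_validates_x():
    t = lab.build_rri_histogram([_series([400], HEALTHY), _series([400], ARRHYTHMIA)])
    for bad in (0.0, -0.1, 1.01):
        with pytest.raises(ValueError):
            lab.classify_rri_ranges(t, bad)


@settings(derandomize=True, max_examples=200)
@given(
    ratio=st.floats(0.0, 2.0),
    x1=st.floats(0.01, 1.0),
    x2=st.floats(0.01, 1.0),
)
def test_arrhythmic_calls_monotone_in_x(ratio, x1, x2):
    """Raising x can only move bins toward (never away from) class A."""
    lo, hi = min(x1, x2), max(x1, x2)
    if lab.classify_ratio(ratio, lo) == "A":
        assert lab.classify_ratio(ratio, hi) == "A"


# -- segment labels ----------------------------------------------------------

def _classified_table():
    # healthy-dominated bin at 400-425, arrhythmia-dominated at 600-625
    t = lab.build_rri_histogram(
        [_series([410] * 9 + [610], HEALTHY), _series([410, 610, 610, 610], ARRHYTHMIA)]
    )
    return lab.classify_rri_ranges(t, 0.63)


def test_label_segment_precedence_arrhythmia_wins():
    t = _classified_table()
    assert lab.label_segment(_segment([410, 410, 610]), t) == ARRHYTHMIA_SEG
    assert lab.label_segment(_segment([410, 410]), t) == NORMAL_SEG


def test_label_segment_unobserved_bin_is_moderate():
    t = _classified_table()
    assert lab.label_segment(_segment([410, 150]), t) == MODERATE_SEG  # empty bin
    assert lab.label_segment(_segment([410, 950]), t) == MODERATE_SEG  # out of range


def test_label_segment_too_little_evidence_is_moderate():
    t = _classified_table()
    assert lab.label_segment(_segment([410]), t) == MODERATE_SEG


def test_healthy_subject_arrhythmia_label_demoted():
    t = _classified_table()
    seg = _segment([610, 610], subject_class=HEALTHY)
    assert lab.label_segment(seg, t) == MODERATE_SEG


def test_unclassified_table_rejected():
    t = lab.build_rri_histogram([_series([400], HEALTHY), _series([400], ARRHYTHMIA)])
    with pytest.raises(ValueError):
        lab.label_segment(_segment([400, 400]), t)


def test_label_segments_simple_inherits_subject_class():
    segs = [_segment([400], HEALTHY), _segment([400], ARRHYTHMIA)]
    assert lab.label_segments_simple(segs) == [NORMAL_SEG, ARRHYTHMIA_SEG]


# -- per-subject band --------------------------------------------------------

def test_subject_band_uses_population_sd():
    r = _series([380, 400, 420, 400])
    band = lab.subject_band(r, 1.0)
    sd = float(np.std(r.intervals))
    assert band.moderate_min == pytest.approx(400 - sd)
    assert band.moderate_max == pytest.approx(400 + sd)


def test_moderate_fraction_monotone_in_y(rng):
    r = _series(rng.normal(400, 40, size=500).clip(200, 700))
    ys = np.linspace(0.0, 8.0, 17)
    fr = [lab.moderate_fraction(r, y) for y in ys]
    assert all(b >= a for a, b in zip(fr, fr[1:]))
    assert fr[-1] == 1.0


def test_calibrate_y_reaches_each_target(rng):
    r = _series(rng.normal(400, 40, size=800).clip(200, 700), ARRHYTHMIA)
    for target in (0.5, 0.6, 0.7, 0.8, 0.9):
        y = lab.calibrate_y(r, target)
        frac = lab.moderate_fraction(r, y)
        assert frac >= target
        # smallest such y: slightly smaller y misses the target
        if y > 1e-3:
            assert lab.moderate_fraction(r, y - 1e-3) <= frac


def test_calibrate_y_constant_series_warns():
    r = _series([400.0] * 10)
    with pytest.warns(UserWarning):
        assert lab.calibrate_y(r, 0.5) == 0.0


def test_label_segment_per_subject_rules():
    band = lab.SubjectBand("a", 360.0, 440.0, 1.0)
    assert lab.label_segment_per_subject(_segment([400, 500]), band) == ARRHYTHMIA_SEG
    assert lab.label_segment_per_subject(_segment([400, 420]), band) == MODERATE_SEG
    assert lab.label_segment_per_subject(_segment([500], HEALTHY), None) == NORMAL_SEG
    with pytest.raises(ValueError):
        lab.label_segment_per_subject(_segment([500]), None)


# -- reference table ---------------------------------------------------------

def test_reference_table_shape():
    assert len(lab.REFERENCE_RANGE_TABLE) == 31
    assert len(lab.REFERENCE_X_GRID) == 5
    assert sum(len(c) for _, _, c in lab.REFERENCE_RANGE_TABLE) == 155
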