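import numpy as np
import pytest

from fetalarr import synthetic as syn
from fetalarr.types import ARRHYTHMIA, HEALTHY, ROLE_ABDOMINAL, ROLE_THORACIC


def _spec(**kw):
    defaults = dict(subject_id="s1", true_class=HEALTHY, seed=7)
    defaults.update(kw)
    return syn.SubjectSpec(**defaults)


def test_rri_sequence_is_deterministic():
    a = syn.generate_rri_sequence(_spec())
    b = syn.generate_rri_sequence(_spec())
    np.testing.assert_array_equal(a.intervals, b.intervals)


def test_rri_sequence_covers_duration_and_clips():
    r = syn.generate_rri_sequence(_spec(duration=60.0))
    assert r.end_times[-1] >= 60_000.0
    assert r.intervals.min() >= syn.RRI_CLIP_LO
    assert r.intervals.max() <= syn.RRI_CLIP_HI
    np.testing.assert_allclose(r.end_times - r.start_times, r.intervals)


def test_healthy_rri_moments_near_spec():
    r = syn.generate_rri_sequence(_spec(rri_mean=400.0, rri_sd=34.0, duration=300.0))
    assert abs(float(np.mean(r.intervals)) - 400.0) < 10.0
    assert abs(float(np.std(r.intervals)) - 34.0) < 8.0


def test_episodes_widen_the_interval_distribution():
    base = _spec(duration=300.0)
    arr = _spec(
        true_class=ARRHYTHMIA,
        arrhythmia_episode_rate=20.0,
        episode_rri_range=(480.0, 650.0),
        duration=300.0,
    )
    sd_h = float(np.std(syn.generate_rri_sequence(base).intervals))
    sd_a = float(np.std(syn.generate_rri_sequence(arr).intervals))
    assert sd_a > 1.5 * sd_h


def test_qrs_template_unit_amplitude_and_biphasic():
    tpl = syn.qrs_template(500.0)
    assert np.max(np.abs(tpl)) == pytest.approx(1.0)
    assert tpl[tpl.size // 2] == pytest.approx(np.max(tpl))
    assert tpl.min() < 0  # undershoot lobes exist


def test_synthesize_fecg_places_peaks_at_truth_times():
    r = syn.generate_rri_sequence(_spec(duration=30.0))
    fecg, peaks = syn.synthesize_fecg(r, fs=500.0)
    assert len(peaks) == len(r) + 1
    idx = np.round(peaks.times / 1000.0 * 500.0).astype(int)
    # every true peak sample sits at a local amplitude maximum of the clean train
    assert np.all(fecg.samples[idx] > 0.9)


def test_noise_sd_for_snr_matches_power_definition():
    sd = syn.noise_sd_for_snr(10.0, mean_rri_ms=400.0, fs=500.0)
    tpl = syn.qrs_template(500.0)
    p_signal = float(np.sum(tpl**2)) / (0.4 * 500.0)
    assert p_signal / sd**2 == pytest.approx(10.0)
    # higher SNR -> less noise
    assert syn.noise_sd_for_snr(20.0) < sd


def test_synthesize_aecg_structure_and_adc_grid():
    r = syn.generate_rri_sequence(_spec(duration=20.0))
    fecg, _ = syn.synthesize_fecg(r, fs=500.0)
    rec = syn.synthesize_aecg(fecg, syn.CohortSpec(), seed=3, true_class=HEALTHY)
    assert rec.channel_roles.count(ROLE_THORACIC) == 1
    assert rec.channel_roles.count(ROLE_ABDOMINAL) >= 4
    # samples snapped to the ADC grid
    q = rec.channels / syn.ADC_STEP
    np.testing.assert_allclose(q, np.round(q), atol=1e-9)
    assert np.max(np.abs(rec.channels)) <= syn.ADC_CLIP


def test_default_cohort_composition():
    cohort = syn.default_cohort_spec(seed=0)
    classes = [s.true_class for s in cohort.subjects]
    assert classes.count(HEALTHY) == 14
    assert classes.count(ARRHYTHMIA) == 12
    assert len({s.subject_id for s in cohort.subjects}) == 26
    assert all(s.seed < 2**31 for s in cohort.subjects)


def test_simulate_record_deterministic(study_cohort_spec):
    spec = study_cohort_spec.subjects[0]
    rec1, p1, r1 = syn.simulate_record(spec, study_cohort_spec)
    rec2, p2, r2 = syn.simulate_record(spec, study_cohort_spec)
    np.testing.assert_array_equal(rec1.channels, rec2.channels)
    np.testing.assert_array_equal(p1.times, p2.times)


def test_spec_validation():
    with pytest.raises(ValueError):
        _spec(rri_mean=-1.0)
    with pytest.raises(ValueError):
        _spec(episode_rri_range=(500.0, 400.0))
    with pytest.raises(ValueError):
        _spec(true_class="bogus")
    with pytest.raises(ValueError):
        syn.CohortSpec(maternal_amplitude_ratio=0.5)
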