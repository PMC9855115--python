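"""Shared fixtures.

The heavy session-scoped fixtures build one synthetic study cohort (the
package's default 14 healthy + 12 arrhythmic subjects at 120 s) and run the
full extraction chain on it exactly once, so the end-to-end evaluation tests
share the work.
"""

from __future__ import annotations

import numpy as np
import pytest

from fetalarr import synthetic as syn
from fetalarr.metrics import SubjectData
from fetalarr.pipeline import extract_fecg_and_rri
from fetalarr.segmentation import segment_signal

COHORT_SEED = 1


@pytest.fixture(scope="session")
def study_cohort_spec():
    return syn.default_cohort_spec(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def simulated_cohort(study_cohort_spec):
    """(record, true peaks, true RRIs) per subject, default noise."""
    return {
        spec.subject_id: syn.simulate_record(spec, study_cohort_spec)
        for spec in study_cohort_spec.subjects
    }


@pytest.fixture(scope="session")
def extracted_cohort(study_cohort_spec, simulated_cohort):
    """SubjectData per subject after the full extraction chain."""
    subjects = []
    for spec in study_cohort_spec.subjects:
        record, _peaks, _rris = simulated_cohort[spec.subject_id]
        fecg, _fpeaks, rris = extract_fecg_and_rri(record)
        subjects.append(
            SubjectData(spec.subject_id, spec.true_class, segment_signal(fecg, rris), rris)
        )
    return subjects


@pytest.fixture()
def one_subject_record(study_cohort_spec, simulated_cohort):
    """A single healthy subject's simulated record + ground truth."""
    spec = study_cohort_spec.subjects[0]
    record, peaks, rris = simulated_cohort[spec.subject_id]
    return spec, record, peaks, rris


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
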