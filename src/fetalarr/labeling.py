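"""RRI-distribution-based weak labeling of FECG segments.

The training labels come not from beat annotations but from the cohort-level
RR-interval histogram: intervals are pooled per class into 25 ms bins, each
bin's healthy/arrhythmia count ratio is computed, and bins are classified as

* ``N`` (normal)      — more healthy than arrhythmic intervals (ratio > 1),
* ``A`` (arrhythmic)  — ratio strictly below the threshold ``x``,
* ``M`` (moderate)    — in between (compatible with both origins).

A segment is then labeled by precedence over its contained intervals
(arrhythmia > moderate > normal), with arrhythmia-labeled segments of healthy
subjects demoted to moderate.  Moderate segments are excluded from binary
training — they are the windows whose interval evidence cannot adjudicate.

The per-subject variant instead brackets each arrhythmic subject's intervals
by mean ± y·SD: inside the band is moderate, outside is arrhythmic, and all
healthy-subject segments are normal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import (
    ARRHYTHMIA,
    ARRHYTHMIA_SEG,
    HEALTHY,
    MODERATE_SEG,
    NORMAL_SEG,
    RRISeries,
    Segment,
)

BIN_MS = 25.0
BIN_LO = 100.0
BIN_HI = 900.0

CLASS_A = "A"
CLASS_M = "M"
CLASS_N = "N"
CLASS_UNOBSERVED = "unobserved"

_RANGE_TO_SEGLABEL = {CLASS_A: ARRHYTHMIA_SEG, CLASS_M: MODERATE_SEG, CLASS_N: NORMAL_SEG}


@dataclass
class RRIRangeTable:
    """25 ms-binned per-class RRI counts with ratio and range classification.

    ``ratio`` is healthy_count / arrhythmia_count per bin (inf where only
    healthy intervals were observed, NaN where the bin is empty).
    """

    bin_edges: np.ndarray  # length n_bins + 1, contiguous, 25 ms apart
    healthy_count: np.ndarray
    arrhythmia_count: np.ndarray
    range_class: list[str] = field(default_factory=list)
    x: float | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.healthy_count = np.asarray(self.healthy_count, dtype=int)
        self.arrhythmia_count = np.asarray(self.arrhythmia_count, dtype=int)
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must be contiguous and uniform")
        if np.any(self.healthy_count < 0) or np.any(self.arrhythmia_count < 0):
            raise ValueError("counts must be non-negative")
        if not self.range_class:
            self.range_class = [CLASS_UNOBSERVED] * self.n_bins

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.healthy_count / self.arrhythmia_count
        r = np.where(
            (self.arrhythmia_count == 0) & (self.healthy_count > 0), np.inf, r
        )
        r = np.where(
            (self.arrhythmia_count == 0) & (self.healthy_count == 0), np.nan, r
        )
        return r

    def bin_index(self, rri_ms: float) -> int | None:
        """Index of the bin containing ``rri_ms``, or None if out of range."""
        if not (self.bin_edges[0] <= rri_ms < self.bin_edges[-1]):
            return None
        return int((rri_ms - self.bin_edges[0]) // (self.bin_edges[1] - self.bin_edges[0]))

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as a TSV table (range, counts, ratio, class)."""
        lines = ["range_ms\thealthy_count\tarrhythmia_count\tratio\tclass"]
        for i in range(self.n_bins):
            r = self.ratio[i]
            rs = "inf" if math.isinf(r) else ("nan" if math.isnan(r) else f"{r:.4f}")
            lines.append(
                f"{self.bin_edges[i]:g}-{self.bin_edges[i + 1]:g}\t"
                f"{self.healthy_count[i]}\t{self.arrhythmia_count[i]}\t{rs}\t"
                f"{self.range_class[i]}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def build_rri_histogram(
    cohort_rris: list[RRISeries],
    bin_lo: float = BIN_LO,
    bin_hi: float = BIN_HI,
    bin_ms: float = BIN_MS,
) -> RRIRangeTable:
    """Pool all subjects' RRIs per class into contiguous 25 ms bins."""
    if not cohort_rris:
        raise ValueError("empty cohort")
    edges = np.arange(bin_lo, bin_hi + bin_ms / 2, bin_ms)
    healthy = np.zeros(edges.size - 1, dtype=int)
    arr = np.zeros(edges.size - 1, dtype=int)
    for series in cohort_rris:
        counts, _ = np.histogram(series.intervals, bins=edges)
        if series.true_class == HEALTHY:
            healthy += counts
        elif series.true_class == ARRHYTHMIA:
            arr += counts
        else:
            raise ValueError(
                f"series {series.subject_id!r} has class {series.true_class!r}; "
                "histogram labeling needs healthy/arrhythmia"
            )
    return RRIRangeTable(bin_edges=edges, healthy_count=healthy, arrhythmia_count=arr)


def classify_ratio(ratio: float, x: float) -> str:
    """Range class for one bin's healthy/arrhythmia ratio at threshold ``x``.

    Normal when healthy intervals outnumber arrhythmic ones (ratio > 1,
    including the only-healthy inf case); arrhythmic when the ratio falls
    strictly below ``x``; moderate in between.  The strict ``< x`` reading is
    the one consistent with published range tables where a bin at exactly
    ratio = x stays moderate.
    """
    if math.isnan(ratio):
        return CLASS_UNOBSERVED
    if ratio > 1.0:
        return CLASS_N
    if ratio < x:
        return CLASS_A
    return CLASS_M


def classify_rri_ranges(table: RRIRangeTable, x: float) -> RRIRangeTable:
    """Classify every bin of ``table`` at threshold ``x`` (0 < x <= 1)."""
    if not 0.0 < x <= 1.0:
        raise ValueError(f"x must lie in (0, 1], got {x}")
    classes = [classify_ratio(float(r), x) for r in table.ratio]
    return RRIRangeTable(
        bin_edges=table.bin_edges,
        healthy_count=table.healthy_count,
        arrhythmia_count=table.arrhythmia_count,
        range_class=classes,
        x=x,
    )


def label_segment(segment: Segment, table: RRIRangeTable) -> str:
    """Histogram label for one segment.

    Precedence arrhythmia > moderate > normal over the contained intervals'
    bin classes; intervals in unobserved or out-of-range bins count as
    moderate; segments with too little interval evidence are moderate; an
    arrhythmia label on a healthy subject's segment is demoted to moderate.
    """
    if not table.range_class or table.x is None:
        raise ValueError("table must be classified first (classify_rri_ranges)")
    if segment.contained_rris.size < 2:
        return MODERATE_SEG
    label = NORMAL_SEG
    for rri in segment.contained_rris:
        bi = table.bin_index(float(rri))
        cls = table.range_class[bi] if bi is not None else CLASS_UNOBSERVED
        seg_cls = _RANGE_TO_SEGLABEL.get(cls, MODERATE_SEG)
        if seg_cls == ARRHYTHMIA_SEG:
            label = ARRHYTHMIA_SEG
            break
        if seg_cls == MODERATE_SEG:
            label = MODERATE_SEG
    if label == ARRHYTHMIA_SEG and segment.subject_class == HEALTHY:
        return MODERATE_SEG
    return label


def label_segments(segments: list[Segment], table: RRIRangeTable) -> list[str]:
    return [label_segment(s, table) for s in segments]


def label_segments_simple(segments: list[Segment]) -> list[str]:
    """Baseline labeling: every segment inherits its subject's class."""
    return [
        ARRHYTHMIA_SEG if s.subject_class == ARRHYTHMIA else NORMAL_SEG
        for s in segments
    ]


# ---------------------------------------------------------------------------
# Per-subject mean ± y·SD variant
# ---------------------------------------------------------------------------

@dataclass
class SubjectBand:
    """Per-subject moderate band [mean − y·SD, mean + y·SD] on the RRIs."""

    subject_id: str
    moderate_min: float
    moderate_max: float
    y: float


def subject_band(rris: RRISeries, y: float) -> SubjectBand:
    """Band mean ± y·SD (population SD) of one subject's intervals."""
    if len(rris) < 2:
        raise ValueError("need at least 2 RRIs for a subject band")
    if y < 0:
        raise ValueError("y must be non-negative")
    mean = float(np.mean(rris.intervals))
    sd = float(np.std(rris.intervals))  # population SD
    return SubjectBand(
        subject_id=rris.subject_id,
        moderate_min=mean - y * sd,
        moderate_max=mean + y * sd,
        y=y,
    )


def moderate_fraction(rris: RRISeries, y: float) -> float:
    """Fraction of the subject's intervals falling inside mean ± y·SD."""
    band = subject_band(rris, y)
    iv = rris.intervals
    return float(np.mean((iv >= band.moderate_min) & (iv <= band.moderate_max)))


def calibrate_y(
    rris: RRISeries, target_moderate_fraction: float, tol: float = 1e-4
) -> float:
    """Smallest y whose moderate fraction reaches the target, by bisection."""
    if not 0.0 < target_moderate_fraction <= 1.0:
        raise ValueError("target fraction must lie in (0, 1]")
    if float(np.std(rris.intervals)) == 0.0:
        warnings.warn("all RRIs identical — y = 0 already makes every RRI moderate",
                      stacklevel=2)
        return 0.0
    lo, hi = 0.0, 1.0
    while moderate_fraction(rris, hi) < target_moderate_fraction:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for finite data
            raise RuntimeError("calibration failed to bracket the target")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if moderate_fraction(rris, mid) >= target_moderate_fraction:
            hi = mid
        else:
            lo = mid
    return hi


def label_segment_per_subject(segment: Segment, band: SubjectBand | None) -> str:
    """Per-subject label: healthy segments normal; arrhythmic-subject
    segments arrhythmia if any contained interval leaves the band, else
    moderate."""
    if segment.subject_class == HEALTHY:
        return NORMAL_SEG
    if band is None:
        raise ValueError("arrhythmia-subject segment needs its subject's band")
    iv = segment.contained_rris
    if iv.size and np.any((iv < band.moderate_min) | (iv > band.moderate_max)):
        return ARRHYTHMIA_SEG
    return MODERATE_SEG


# ---------------------------------------------------------------------------
# Reference range table (clinical-cohort RRI ratios with published classes)
# ---------------------------------------------------------------------------

#: Published 25 ms RRI-range ratio table from a 14-healthy / 12-arrhythmia
#: clinical cohort, with the range classification at five thresholds
#: x = 0.50, 0.60, 0.63, 0.65, 0.70.  Used as an exact oracle for the range
#: classification rule: each row is (range_lo_ms, ratio, classes at each x).
REFERENCE_X_GRID = (0.50, 0.60, 0.63, 0.65, 0.70)
REFERENCE_RANGE_TABLE: list[tuple[float, float, tuple[str, ...]]] = [
    (100, 0.2000, ("A", "A", "A", "A", "A")),
    (125, 0.4000, ("A", "A", "A", "A", "A")),
    (150, 0.3846, ("A", "A", "A", "A", "A")),
    (175, 0.0870, ("A", "A", "A", "A", "A")),
    (200, 0.2000, ("A", "A", "A", "A", "A")),
    (225, 0.2113, ("A", "A", "A", "A", "A")),
    (250, 0.2541, ("A", "A", "A", "A", "A")),
    (275, 0.1312, ("A", "A", "A", "A", "A")),
    (300, 0.0427, ("A", "A", "A", "A", "A")),
    (325, 0.1233, ("A", "A", "A", "A", "A")),
    (350, 0.6093, ("M", "M", "A", "A", "A")),
    (375, 4.2561, ("N", "N", "N", "N", "N")),
    (400, 3.3120, ("N", "N", "N", "N", "N")),
    (425, 1.1848, ("N", "N", "N", "N", "N")),
    (450, 0.6470, ("M", "M", "M", "A", "A")),
    (475, 0.2834, ("A", "A", "A", "A", "A")),
    (500, 0.1530, ("A", "A", "A", "A", "A")),
    (525, 0.1506, ("A", "A", "A", "A", "A")),
    (550, 0.1387, ("A", "A", "A", "A", "A")),
    (575, 0.2712, ("A", "A", "A", "A", "A")),
    (600, 0.1389, ("A", "A", "A", "A", "A")),
    (625, 0.3571, ("A", "A", "A", "A", "A")),
    (650, 0.2105, ("A", "A", "A", "A", "A")),
    (675, 0.2353, ("A", "A", "A", "A", "A")),
    (700, 0.1111, ("A", "A", "A", "A", "A")),
    (725, 0.6667, ("M", "M", "M", "M", "A")),
    (750, 0.0000, ("A", "A", "A", "A", "A")),
    (775, 0.0000, ("A", "A", "A", "A", "A")),
    (800, 0.0000, ("A", "A", "A", "A", "A")),
    (825, 0.0000, ("A", "A", "A", "A", "A")),
    (850, 0.5000, ("M", "A", "A", "A", "A")),
]


def classify_reference_ratios(x_grid=REFERENCE_X_GRID) -> list[tuple[float, list[str]]]:
    """Classify the reference table's printed ratios at each threshold.

    Returns one (range_lo, [class per x]) entry per row, for diffing against
    the published classes.
    """
    return [
        (lo, [classify_ratio(ratio, x) for x in x_grid])
        for lo, ratio, _ in REFERENCE_RANGE_TABLE
    ]
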