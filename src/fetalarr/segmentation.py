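"""Sliding-window segmentation of the extracted FECG.

The FECG is cut into 3 s windows advanced in 1 s steps (so interior beats
appear in three overlapping windows).  Each segment records the RR intervals
whose *both* defining R-peaks fall inside the window — the labeling stage
only trusts interval evidence fully supported by the waveform in the window.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .types import FECGSignal, RRISeries, Segment

# A 3 s window at plausible fetal rates holds >= 4 beats; fewer contained
# intervals than this flags a detection failure for that window.
MIN_RRIS_PER_SEGMENT = 2


def segment_signal(
    fecg: FECGSignal,
    rris: RRISeries,
    window_s: float = 3.0,
    step_s: float = 1.0,
) -> list[Segment]:
    """Cut ``fecg`` into fixed windows and attach contained RR intervals.

    Produces ``floor((duration - window)/step) + 1`` segments of exactly
    ``window_s * fs`` samples.  Segments overlapping any invalid-mask region
    are dropped.  A too-short signal yields an empty list with a warning.
    """
    fs = fecg.fs
    n_win = int(round(window_s * fs))
    n_step = int(round(step_s * fs))
    n = fecg.samples.size
    if n < n_win:
        warnings.warn(
            f"signal of {n / fs:.2f} s is shorter than the {window_s} s window",
            stacklevel=2,
        )
        return []

    n_seg = (n - n_win) // n_step + 1
    segments = []
    for k in range(n_seg):
        i0 = k * n_step
        if fecg.valid_mask is not None and not fecg.valid_mask[i0 : i0 + n_win].all():
            continue
        start_ms = i0 / fs * 1000.0
        end_ms = start_ms + window_s * 1000.0
        inside = (rris.start_times >= start_ms) & (rris.end_times < end_ms)
        segments.append(
            Segment(
                subject_id=fecg.subject_id or rris.subject_id,
                start_time=start_ms,
                samples=fecg.samples[i0 : i0 + n_win],
                contained_rris=rris.intervals[inside],
                subject_class=rris.true_class,
            )
        )
    return segments


def expected_n_segments(duration_s: float, window_s: float = 3.0, step_s: float = 1.0) -> int:
    """Segment count for an uninterrupted signal of ``duration_s`` seconds."""
    if duration_s < window_s:
        return 0
    return int((duration_s - window_s) // step_s) + 1


# ---------------------------------------------------------------------------
# Segment store (NPZ: samples matrix + metadata arrays)
# ---------------------------------------------------------------------------

def save_segments(path: str | Path, segments: list[Segment], labels: list[str] | None = None) -> None:
    """Serialize segments (and optional labels) as a compressed NPZ table."""
    path = Path(path)
    if not segments:
        raise ValueError("no segments to save")
    np.savez_compressed(
        path,
        samples=np.stack([s.samples for s in segments]),
        subject_id=np.asarray([s.subject_id for s in segments]),
        start_ms=np.asarray([s.start_time for s in segments]),
        subject_class=np.asarray([s.subject_class for s in segments]),
        n_rris=np.asarray([s.contained_rris.size for s in segments]),
        rris_flat=np.concatenate([s.contained_rris for s in segments])
        if any(s.contained_rris.size for s in segments)
        else np.empty(0),
        labels=np.asarray(labels if labels is not None else []),
    )


def load_segments(path: str | Path) -> tuple[list[Segment], list[str] | None]:
    """Inverse of :func:`save_segments`."""
    data = np.load(Path(path), allow_pickle=False)
    counts = data["n_rris"]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    segments = [
        Segment(
            subject_id=str(data["subject_id"][i]),
            start_time=float(data["start_ms"][i]),
            samples=data["samples"][i],
            contained_rris=data["rris_flat"][offsets[i] : offsets[i + 1]],
            subject_class=str(data["subject_class"][i]),
        )
        for i in range(len(counts))
    ]
    labels = [str(x) for x in data["labels"]] if data["labels"].size else None
    return segments, labels
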