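"""Recording I/O: WFDB-style records, CSV, JSON sidecars, cohort manifests.

Implements a minimal reader/writer for the classic WFDB interchange layout
(``.hea`` text header plus an interleaved little-endian 16-bit ``.dat``
signal file, format 16) — the subset needed to store and exchange the
multichannel abdominal recordings this pipeline consumes — and a plain CSV
dialect (header row, one column per channel) with a JSON sidecar carrying
the sampling rate and subject class.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .types import ROLE_ABDOMINAL, ROLE_THORACIC, UNKNOWN, AECGRecord

WFDB_GAIN = 2048.0  # ADC units per signal unit, matches the synthesizer grid

# Channel-name patterns → role; first match wins, default is abdominal.
DEFAULT_ROLE_PATTERNS: list[tuple[str, str]] = [
    (r"(?i)thor|chest|maternal|mecg|direct", ROLE_THORACIC),
]


class RecordFormatError(ValueError):
    """Raised for malformed or unsupported record files."""


def infer_roles(
    channel_names: list[str],
    role_patterns: list[tuple[str, str]] | None = None,
) -> list[str]:
    """Map channel names to roles via a configurable pattern table."""
    patterns = role_patterns if role_patterns is not None else DEFAULT_ROLE_PATTERNS
    roles = []
    for name in channel_names:
        role = ROLE_ABDOMINAL
        for pat, r in patterns:
            if re.search(pat, name):
                role = r
                break
        roles.append(role)
    return roles


# ---------------------------------------------------------------------------
# WFDB (.hea/.dat, format 16)
# ---------------------------------------------------------------------------

def _write_wfdb(record: AECGRecord, base: Path) -> None:
    n_ch, n_samp = record.channels.shape
    adc = np.round(record.channels * WFDB_GAIN)
    if np.any(np.abs(adc) > 32767):
        raise RecordFormatError("signal amplitude exceeds 16-bit ADC range")
    adc = adc.astype("<i2")
    names = record.channel_names or [f"ch{i + 1}" for i in range(n_ch)]
    lines = [f"{base.name} {n_ch} {record.fs:g} {n_samp}"]
    checksums = (adc.astype(np.int64).sum(axis=1) & 0xFFFF).astype(np.int64)
    checksums = np.where(checksums >= 32768, checksums - 65536, checksums)
    for i in range(n_ch):
        lines.append(
            f"{base.name}.dat 16 {WFDB_GAIN:g}(0)/mV 16 0 "
            f"{adc[i, 0]} {checksums[i]} 0 {names[i]}"
        )
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    # interleaved sample-major layout
    adc.T.tobytes()
    base.with_suffix(".dat").write_bytes(adc.T.tobytes())


def _read_wfdb(hea_path: Path) -> tuple[np.ndarray, list[str], float]:
    text = hea_path.read_text().strip().splitlines()
    lines = [ln for ln in text if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise RecordFormatError(f"malformed WFDB header line: {lines[0]!r}")
    n_ch, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    if len(lines) - 1 < n_ch:
        raise RecordFormatError("header lists fewer signal lines than channels")
    gains, baselines, names, dat_names = [], [], [], []
    for ln in lines[1 : 1 + n_ch]:
        f = ln.split()
        dat_names.append(f[0])
        if f[1] != "16":
            raise RecordFormatError(f"unsupported WFDB signal format {f[1]!r}")
        m = re.match(r"([-\d.eE+]+)(?:\(([-\d]+)\))?(?:/.*)?$", f[2])
        if not m:
            raise RecordFormatError(f"cannot parse gain spec {f[2]!r}")
        gains.append(float(m.group(1)) or 200.0)
        baselines.append(int(m.group(2) or 0))
        names.append(f[8] if len(f) > 8 else f"ch{len(names) + 1}")
    if len(set(dat_names)) != 1:
        raise RecordFormatError("multi-file WFDB records are not supported")
    dat_path = hea_path.parent / dat_names[0]
    if not dat_path.exists():
        raise FileNotFoundError(f"signal file {dat_path} missing")
    raw = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    if raw.size != n_ch * n_samp:
        raise RecordFormatError(
            f"signal file holds {raw.size} samples, header promises {n_ch * n_samp}"
        )
    adc = raw.reshape(n_samp, n_ch).T.astype(float)
    phys = (adc - np.asarray(baselines)[:, None]) / np.asarray(gains)[:, None]
    return phys, names, fs


# ---------------------------------------------------------------------------
# CSV (+ JSON sidecar)
# ---------------------------------------------------------------------------

def _write_csv(record: AECGRecord, base: Path) -> None:
    names = record.channel_names or [f"ch{i + 1}" for i in range(record.n_channels)]
    path = base.with_suffix(".csv")
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(names)
        for row in record.channels.T:
            w.writerow([repr(float(v)) for v in row])
    sidecar = {
        "subject_id": record.subject_id,
        "true_class": record.true_class,
        "fs": record.fs,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar))


def _read_csv(path: Path, fs: float | None) -> tuple[np.ndarray, list[str], float]:
    with path.open() as fh:
        reader = csv.reader(fh)
        try:
            names = next(reader)
        except StopIteration:
            raise RecordFormatError(f"{path} is empty") from None
        rows = [[float(v) for v in row] for row in reader if row]
    if not rows:
        raise RecordFormatError(f"{path} has a header but no samples")
    widths = {len(r) for r in rows}
    if len(widths) != 1 or widths.pop() != len(names):
        raise RecordFormatError(f"{path} has inconsistent channel lengths")
    if fs is None:
        raise RecordFormatError(
            f"{path}: sampling rate unknown — provide fs or a JSON sidecar"
        )
    return np.asarray(rows).T, names, fs


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _load_sidecar(base: Path) -> dict:
    for cand in (base.with_suffix(".json"), base.with_suffix(".truth.json"),
                 base.parent / f"{base.name}.truth.json"):
        if cand.exists():
            return json.loads(cand.read_text())
    return {}


def read_record(
    path: str | Path,
    fs: float | None = None,
    role_patterns: list[tuple[str, str]] | None = None,
    roles: list[str] | None = None,
) -> AECGRecord:
    """Read a WFDB (.hea/.dat) or CSV record into an :class:`AECGRecord`.

    Channel roles are inferred from names through ``role_patterns`` unless
    ``roles`` overrides them explicitly.  The subject class comes from a JSON
    sidecar when present, else ``unknown``.
    """
    path = Path(path)
    if path.suffix == "":
        if path.with_suffix(".hea").exists():
            path = path.with_suffix(".hea")
        elif path.with_suffix(".csv").exists():
            path = path.with_suffix(".csv")
        else:
            raise FileNotFoundError(f"no .hea or .csv record at {path}")
    base = path.with_suffix("")
    sidecar = _load_sidecar(base)
    if path.suffix == ".hea":
        if not path.exists():
            raise FileNotFoundError(f"missing header {path}")
        channels, names, fs_read = _read_wfdb(path)
    elif path.suffix == ".csv":
        if not path.exists():
            raise FileNotFoundError(f"missing file {path}")
        channels, names, fs_read = _read_csv(path, fs or sidecar.get("fs"))
    else:
        raise RecordFormatError(f"unsupported record format {path.suffix!r}")
    return AECGRecord(
        subject_id=sidecar.get("subject_id", base.name),
        channels=channels,
        channel_roles=roles or infer_roles(names, role_patterns),
        channel_names=names,
        fs=fs_read,
        true_class=sidecar.get("true_class", UNKNOWN),
    )


def write_record(record: AECGRecord, path: str | Path, fmt: str = "wfdb") -> Path:
    """Write a record as WFDB (.hea/.dat pair) or CSV (+ JSON sidecar)."""
    if record.n_samples == 0:
        raise RecordFormatError("refusing to write a record with no samples")
    base = Path(path).with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "wfdb":
        _write_wfdb(record, base)
        return base.with_suffix(".hea")
    if fmt == "csv":
        _write_csv(record, base)
        return base.with_suffix(".csv")
    raise RecordFormatError(f"unknown output format {fmt!r}")


@dataclass
class CohortManifest:
    """Index of a cohort directory: (subject_id, record path, true class)."""

    records: list[tuple[str, Path, str]]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids in a manifest must be unique")

    def __len__(self) -> int:
        return len(self.records)


def scan_cohort(directory: str | Path) -> CohortManifest:
    """Build a manifest by scanning a directory for records with sidecars."""
    directory = Path(directory)
    entries = []
    seen = set()
    for p in sorted(directory.iterdir()):
        if p.suffix not in (".hea", ".csv"):
            continue
        base = p.with_suffix("")
        if base in seen:
            continue
        seen.add(base)
        side = _load_sidecar(base)
        entries.append(
            (side.get("subject_id", base.name), base, side.get("true_class", UNKNOWN))
        )
    if not entries:
        raise FileNotFoundError(f"no records found under {directory}")
    return CohortManifest(records=entries)
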