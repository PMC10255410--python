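"""Minimal EDF+C writer for synthetic runs.

Writes standard 16-bit EDF with an 'EDF Annotations' channel carrying
T0/T1/T2 cue markers as time-stamped annotation lists (TALs), in the layout
of the source motor-imagery recordings (64 signal channels + annotations).
Only the subset of the format the ingest path needs is produced: one fixed
record duration, per-channel symmetric physical scaling, microvolt units.

Reading is delegated to mne (see :mod:`riemanneeg.edf_ingest`); the
write-then-read round trip is exercised in the test suite.
"""

from __future__ import annotations

import datetime as _dt
import math
from pathlib import Path

import numpy as np

from .datatypes import RunRecord

_DIG_MAX = 32767
_RECORD_SECONDS = 1.0


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} > {width}")
    return s.ljust(width).encode("ascii")


def _num_str(value: float, width: int) -> str:
    """Render a number in the most precise form fitting an EDF numeric field."""
    for prec in range(10, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {value} in {width} characters")


def _num(value: float, width: int) -> bytes:
    return _field(_num_str(value, width), width)


def _annotation_payloads(run: RunRecord, n_records: int) -> list[bytes]:
    """Per-record TAL byte strings: record-start stamp plus events starting in it."""
    payloads = []
    events_by_record: dict[int, list[bytes]] = {}
    for ev in run.annotations:
        onset_s = ev.onset_sample / run.fs
        dur_s = ev.duration_samples / run.fs
        rec = min(int(onset_s // _RECORD_SECONDS), n_records - 1)
        tal = f"+{onset_s:.7g}\x15{dur_s:.7g}\x14{ev.code}\x14\x00".encode("ascii")
        events_by_record.setdefault(rec, []).append(tal)
    for r in range(n_records):
        stamp = f"+{r * _RECORD_SECONDS:.7g}\x14\x14\x00".encode("ascii")
        payloads.append(stamp + b"".join(events_by_record.get(r, [])))
    return payloads


def write_edf(path: str | Path, run: RunRecord, patient_id: str = "X", recording_id: str = "") -> Path:
    """Write one run (samples x channels, microvolts) as an EDF+C file."""
    path = Path(path)
    fs = run.fs
    spr = int(round(fs * _RECORD_SECONDS))
    if abs(spr - fs * _RECORD_SECONDS) > 1e-9:
        raise ValueError(f"sampling rate {fs} does not give integer samples per record")
    n_samples, n_channels = run.signal.shape
    n_records = max(math.ceil(n_samples / spr), 1)

    # pad the tail record with zeros; ingest truncates after the last trial
    padded = np.zeros((n_records * spr, n_channels))
    padded[:n_samples] = run.signal

    # symmetric per-channel physical range -> 16-bit digital; quantize with
    # the exact (8-character) value written to the header
    phys_max = np.maximum(np.abs(padded).max(axis=0) * 1.0001, 1e-6)
    phys_max = np.array([float(_num_str(v, 8)) for v in phys_max])
    phys_max = np.where(phys_max <= 0, 1e-6, phys_max)
    digital = np.clip(
        np.round(padded / phys_max[None, :] * _DIG_MAX), -_DIG_MAX - 1, _DIG_MAX
    ).astype("<i2")

    payloads = _annotation_payloads(run, n_records)
    ann_bytes = max(max(len(p) for p in payloads) + 2, 60)
    ann_bytes += ann_bytes % 2  # whole number of 2-byte samples
    ann_spr = ann_bytes // 2

    ns = n_channels + 1
    header_bytes = 256 * (ns + 1)
    now = _dt.datetime(2000, 1, 1, 0, 0, 0)

    labels = [c[:16] for c in run.channel_names] + ["EDF Annotations"]
    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field(patient_id, 80))
        fh.write(_field(recording_id or f"Startdate 01-JAN-2000 run{run.run_index}", 80))
        fh.write(_field(now.strftime("%d.%m.%y"), 8))
        fh.write(_field(now.strftime("%H.%M.%S"), 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("EDF+C", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_num(_RECORD_SECONDS, 8))
        fh.write(_field(str(ns), 4))
        for lab in labels:
            fh.write(_field(lab, 16))
        for _ in range(ns):
            fh.write(_field("", 80))  # transducer
        for i in range(ns):
            fh.write(_field("uV" if i < n_channels else "", 8))
        for i in range(ns):
            fh.write(_num(-phys_max[i], 8) if i < n_channels else _num(-1, 8))
        for i in range(ns):
            fh.write(_num(phys_max[i], 8) if i < n_channels else _num(1, 8))
        for _ in range(ns):
            fh.write(_num(-_DIG_MAX - 1, 8))
        for _ in range(ns):
            fh.write(_num(_DIG_MAX, 8))
        for _ in range(ns):
            fh.write(_field("", 80))  # prefiltering
        for i in range(ns):
            fh.write(_field(str(spr if i < n_channels else ann_spr), 8))
        for _ in range(ns):
            fh.write(_field("", 32))
        for r in range(n_records):
            fh.write(digital[r * spr : (r + 1) * spr].T.tobytes())
            fh.write(payloads[r].ljust(ann_bytes, b"\x00"))
    return path


def write_subject(
    out_dir: str | Path, runs: list[RunRecord], subject_id: str = "S001"
) -> list[Path]:
    """Write one subject's runs as <out_dir>/<subject>/<subject>R<nn>.edf."""
    out = Path(out_dir) / subject_id
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in runs:
        p = out / f"{subject_id}R{run.run_index:02d}.edf"
        write_edf(p, run, patient_id=subject_id)
        paths.append(p)
    return paths
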