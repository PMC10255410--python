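"""EDF+ ingest, subject qualification and trial labeling.

Runs are read with mne; the annotation column of the source files never
reaches the signal matrix (mne consumes the 'EDF Annotations' channel),
leaving the 64 EEG channels.  Unannotated readings after the end of the
last annotated trial are discarded.

The 14-run session layout (baseline runs 1-2; unilateral fist runs 3, 7, 11
executed / 4, 8, 12 imagined; bilateral fists-vs-feet runs 5, 9, 13
executed / 6, 10, 14 imagined) is stored as a data table
(``data/run_table.csv``), and the T1/T2 cue codes are mapped to the four
motor classes according to the run type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CLASS_INDEX, AnnotationEvent, IngestError, RunRecord

#: Subjects whose session files are incomplete or shorter than the layout
#: requires; the remaining 103 subjects qualify.
DEFAULT_EXCLUDED: frozenset[str] = frozenset(
    {"S088", "S089", "S092", "S100", "S104", "S106"}
)

#: Expected minimum motor-run length: 15 trials of ~8.3 s at 160 Hz.
EXPECTED_MIN_RUN_SAMPLES = 19000


def _run_table() -> pd.DataFrame:
    with resources.files("riemanneeg.data").joinpath("run_table.csv").open() as fh:
        return pd.read_csv(fh, dtype={"run_index": int})


_RUN_TABLE: pd.DataFrame | None = None


def run_table() -> pd.DataFrame:
    global _RUN_TABLE
    if _RUN_TABLE is None:
        _RUN_TABLE = _run_table().set_index("run_index")
    return _RUN_TABLE


def _normalize_channel(name: str) -> str:
    """Map a source-file channel label (e.g. 'Fc5.') to its canonical 10-10 name."""
    from .smr_synth import MONTAGE_64

    clean = name.strip().rstrip(".")
    lookup = {c.lower(): c for c in MONTAGE_64}
    return lookup.get(clean.lower(), clean)


def _infer_run_index(path: Path) -> int:
    m = re.search(r"R(\d{2})", path.stem)
    if not m:
        raise IngestError(f"cannot infer run index from file name: {path}")
    return int(m.group(1))


def read_run(path: str | Path, run_index: int | None = None) -> RunRecord:
    """Read one EDF+ run into a RunRecord (microvolts, 0-based sample onsets).

    Raises :class:`IngestError` for unreadable files or files without any
    T0/T1/T2 annotations.  Signal after the end of the last annotated trial
    is discarded.
    """
    import mne

    path = Path(path)
    if run_index is None:
        run_index = _infer_run_index(path)
    if not 1 <= run_index <= 14:
        raise IngestError(f"run index {run_index} outside the 14-run session layout")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - wrap any reader failure
        raise IngestError(f"cannot read EDF file {path}: {exc}") from exc

    picks = [i for i, ch in enumerate(raw.ch_names) if "annotation" not in ch.lower()]
    names = [_normalize_channel(raw.ch_names[i]) for i in picks]
    signal = raw.get_data(picks=picks).T * 1e6  # mne returns volts for uV channels

    fs = float(raw.info["sfreq"])
    events: list[AnnotationEvent] = []
    for onset, dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        if desc not in ("T0", "T1", "T2"):
            continue
        events.append(
            AnnotationEvent(desc, int(round(onset * fs)), max(int(round(dur * fs)), 1))
        )
    if not events:
        raise IngestError(f"no T0/T1/T2 annotations in {path}")
    events.sort(key=lambda e: e.onset_sample)
    last_end = events[-1].onset_sample + events[-1].duration_samples
    signal = signal[: min(last_end, signal.shape[0])]
    return RunRecord(
        signal=signal, channel_names=names, fs=fs, run_index=run_index, annotations=events
    )


@dataclass
class SubjectManifest:
    """The cohort roster: subject ids plus optional per-run sample counts."""

    subject_ids: list[str]
    run_samples: dict[str, dict[int, int]] = field(default_factory=dict)


def full_manifest() -> SubjectManifest:
    """The canonical 109-subject roster S001..S109."""
    return SubjectManifest(subject_ids=[f"S{i:03d}" for i in range(1, 110)])


def qualify_subjects(manifest: SubjectManifest) -> list[str]:
    """Return qualified subject ids, preserving manifest order.

    When per-run sample counts are supplied, a subject is excluded if any
    motor run (3-14) is missing or shorter than the session layout implies;
    otherwise the documented default exclusion set is applied.  The full
    S001-S109 roster qualifies exactly 103 subjects.
    """
    ids = manifest.subject_ids
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in manifest")
    qualified = []
    for sid in ids:
        if manifest.run_samples:
            runs = manifest.run_samples.get(sid, {})
            ok = all(
                runs.get(r, 0) >= EXPECTED_MIN_RUN_SAMPLES for r in range(3, 15)
            )
        else:
            ok = sid not in DEFAULT_EXCLUDED
        if ok:
            qualified.append(sid)
    return qualified


def renumber_subjects(qualified: list[str]) -> dict[str, int]:
    """Renumber qualified subjects 1..n preserving original order."""
    return {sid: i + 1 for i, sid in enumerate(qualified)}


def assemble_trials(
    runs: list[RunRecord], nature: str
) -> list[tuple[RunRecord, int, int]]:
    """Labeled motor-trial index for one subject and task nature.

    Returns (run, onset_sample, class_code) triples for T1/T2 trials of the
    runs matching ``nature`` (ME or MI); rest (T0) trials are discarded.
    T1 maps to left fist on unilateral runs and both fists on bilateral
    runs; T2 to right fist / both feet.
    """
    if nature not in ("ME", "MI"):
        raise ValueError(f"nature must be ME or MI, got {nature!r}")
    table = run_table()
    trials: list[tuple[RunRecord, int, int]] = []
    for run in runs:
        if run.run_index not in table.index:
            raise ValueError(f"run index {run.run_index} outside 1..14")
        row = table.loc[run.run_index]
        if row["nature"] != nature:
            continue
        class_of = {"T1": CLASS_INDEX[row["t1_class"]], "T2": CLASS_INDEX[row["t2_class"]]}
        for ev in run.annotations:
            if ev.code == "T0":
                continue
            trials.append((run, ev.onset_sample, class_of[ev.code]))
    return trials


def read_subject(subject_dir: str | Path) -> list[RunRecord]:
    """Read all EDF runs under one subject directory (SxxxRnn.edf layout)."""
    subject_dir = Path(subject_dir)
    paths = sorted(subject_dir.glob("*.edf"))
    if not paths:
        raise IngestError(f"no EDF files in {subject_dir}")
    return [read_run(p) for p in paths]


def trial_index_frame(
    trials: list[tuple[RunRecord, int, int]], subject_id: str, nature: str
) -> pd.DataFrame:
    """Exportable trial index (subject, run, onset_sample, class, nature)."""
    from .datatypes import CLASS_NAMES

    return pd.DataFrame(
        {
            "subject": subject_id,
            "run": [r.run_index for r, _, _ in trials],
            "onset_sample": [onset for _, onset, _ in trials],
            "class": [CLASS_NAMES[c] for _, _, c in trials],
            "nature": nature,
        }
    )
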