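"""Band-pass filtering, epoching and channel subsetting.

Order of operations matters: the continuous run is filtered first (a
fifth-order Butterworth band-pass over 8-30 Hz, the mu/beta band where
sensorimotor ERD/ERS lives), then trials are epoched from cue onset to
4.0 s.  Filtering after epoching is deliberately not offered, as edge
transients would differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .datatypes import EpochError, EpochSet, RunRecord

#: The 29 sensorimotor-area electrodes (10-10 names): all montage channels
#: whose label prefix is FC, C, CP, FT, T or TP.
SENSORIMOTOR_29: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "FT7", "FT8",
    "T7", "T8", "T9", "T10",
    "TP7", "TP8",
)


@dataclass
class FilterSpec:
    """Butterworth band-pass specification (default: order 5, 8-30 Hz, causal).

    mode 'zero_phase' applies the filter forward and backward
    (scipy sosfiltfilt), which cancels phase but doubles effective order.
    """

    order: int = 5
    band: tuple[float, float] = (8.0, 30.0)
    mode: str = "causal"

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")
        if self.mode not in ("causal", "zero_phase"):
            raise ValueError(f"filter mode must be causal or zero_phase, got {self.mode!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass
class ChannelSubset:
    """Named channel roster: full64, sensorimotor29, or a custom list."""

    name: str = "full64"
    channels: list[str] = field(default_factory=list)

    @classmethod
    def from_preset(cls, name: str, available: list[str] | None = None) -> "ChannelSubset":
        if name == "sensorimotor29":
            return cls(name=name, channels=list(SENSORIMOTOR_29))
        if name == "full64":
            return cls(name=name, channels=list(available) if available else [])
        raise ValueError(f"unknown channel preset {name!r}")


def design_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order sections for the band-pass; validates the band against Nyquist."""
    low, high = spec.band
    if high >= fs / 2.0:
        raise ValueError(f"band upper edge {high} Hz is not below Nyquist ({fs / 2} Hz)")
    return scipy.signal.butter(spec.order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(run: RunRecord, spec: FilterSpec | None = None) -> RunRecord:
    """Filter the continuous run per channel; length and annotations preserved."""
    spec = spec or FilterSpec()
    sos = design_bandpass(spec, run.fs)
    if spec.mode == "zero_phase":
        filtered = scipy.signal.sosfiltfilt(sos, run.signal, axis=0)
    else:
        filtered = scipy.signal.sosfilt(sos, run.signal, axis=0)
    return RunRecord(
        signal=np.ascontiguousarray(filtered),
        channel_names=list(run.channel_names),
        fs=run.fs,
        run_index=run.run_index,
        annotations=list(run.annotations),
    )


def epoch_trials(
    run: RunRecord,
    trial_index: list[tuple[int, int]],
    window_seconds: float = 4.0,
    nature: str = "ME",
    subject_id: str = "",
) -> EpochSet:
    """Cut fixed-length epochs from a run.

    trial_index is a list of (onset_sample, class_label) pairs; each trial
    contributes round(window_seconds * fs) consecutive samples per channel
    from its onset (half-open window).
    """
    n = int(round(window_seconds * run.fs))
    if n <= 0:
        raise EpochError(f"degenerate epoch window: {window_seconds} s at fs={run.fs}")
    n_trials = len(trial_index)
    data = np.empty((n_trials, run.n_channels, n))
    labels = np.empty(n_trials, dtype=int)
    for i, (onset, label) in enumerate(trial_index):
        if onset < 0 or onset + n > run.n_samples:
            raise EpochError(
                f"trial {i} (onset {onset}) overruns run of {run.n_samples} samples "
                f"with a {n}-sample window"
            )
        data[i] = run.signal[onset : onset + n].T
        labels[i] = label
    return EpochSet(
        data=data,
        labels=labels,
        channel_names=list(run.channel_names),
        fs=run.fs,
        nature=nature,
        subject_id=subject_id,
        window_seconds=window_seconds,
    )


def concat_epochs(sets: list[EpochSet]) -> EpochSet:
    """Concatenate EpochSets from the runs of one subject and nature."""
    if not sets:
        raise ValueError("no EpochSets to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.channel_names != first.channel_names or s.fs != first.fs or s.nature != first.nature:
            raise ValueError("EpochSets differ in channels, fs or nature")
    return EpochSet(
        data=np.concatenate([s.data for s in sets], axis=0),
        labels=np.concatenate([s.labels for s in sets]),
        channel_names=list(first.channel_names),
        fs=first.fs,
        nature=first.nature,
        subject_id=first.subject_id,
        window_seconds=first.window_seconds,
    )


def select_channels(epochs: EpochSet, subset: ChannelSubset | str) -> EpochSet:
    """Restrict (and reorder) the channel dimension to a named subset."""
    if isinstance(subset, str):
        subset = ChannelSubset.from_preset(subset, available=epochs.channel_names)
    names = subset.channels or list(epochs.channel_names)
    missing = [c for c in names if c not in epochs.channel_names]
    if missing:
        raise ValueError(f"unknown channel name(s): {', '.join(missing)}")
    idx = [epochs.channel_names.index(c) for c in names]
    return EpochSet(
        data=epochs.data[:, idx, :],
        labels=epochs.labels,
        channel_names=list(names),
        fs=epochs.fs,
        nature=epochs.nature,
        subject_id=epochs.subject_id,
        window_seconds=epochs.window_seconds,
    )
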