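"""Shared containers and exceptions for the decoding pipeline.

The pipeline moves data through three representations: continuous runs
(:class:`RunRecord`), epoched trials (:class:`EpochSet`) and per-trial
spatial covariance features (:class:`CovarianceSet`).  The four motor
classes are fixed and ordered; the integer codes double as the
deterministic tie-break order of the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed class order (left fist, right fist, both fists, both feet).
#: Classifier tie-breaks resolve to the lowest index in this order.
CLASS_NAMES: tuple[str, ...] = ("left_fist", "right_fist", "both_fists", "both_feet")
CLASS_INDEX: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}
N_CLASSES = 4

NATURES = ("ME", "MI")


class IngestError(RuntimeError):
    """A recording file could not be read or lacks required annotations."""


class EpochError(ValueError):
    """An epoch window cannot be cut from a run (overrun or degenerate window)."""


class DegenerateInputError(ValueError):
    """Numerically degenerate input, e.g. an all-zero epoch with zero trace."""


class ConfigError(ValueError):
    """An experiment configuration file is invalid."""


class ConvergenceWarning(UserWarning):
    """An iterative solver stopped at max_iter before reaching tolerance."""


@dataclass
class AnnotationEvent:
    """One cue annotation: T0 (rest) or T1/T2 (motor task).

    Onsets are 0-based sample indices; windows are half-open
    ``[onset, onset + duration)``.
    """

    code: str
    onset_sample: int
    duration_samples: int

    def __post_init__(self) -> None:
        if self.code not in ("T0", "T1", "T2"):
            raise ValueError(f"annotation code must be T0/T1/T2, got {self.code!r}")
        if self.onset_sample < 0:
            raise ValueError("annotation onset must be >= 0")
        if self.duration_samples <= 0:
            raise ValueError("annotation duration must be > 0")


@dataclass
class RunRecord:
    """One continuous recording run.

    signal is samples x channels (microvolts), annotations are sorted by
    onset.  ``run_index`` follows the 14-run session layout of the source
    dataset (1-2 baseline, 3-14 alternating task runs).
    """

    signal: np.ndarray
    channel_names: list[str]
    fs: float
    run_index: int
    annotations: list[AnnotationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be samples x channels")
        if self.signal.shape[1] != len(self.channel_names):
            raise ValueError(
                f"signal has {self.signal.shape[1]} columns but "
                f"{len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.annotations = sorted(self.annotations, key=lambda a: a.onset_sample)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]


@dataclass
class EpochSet:
    """Epoched trials: data is trials x channels x samples with one label per trial."""

    data: np.ndarray
    labels: np.ndarray
    channel_names: list[str]
    fs: float
    nature: str
    subject_id: str = ""
    window_seconds: float = 4.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match trial count")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel dimension must match channel_names")
        if self.nature not in NATURES:
            raise ValueError(f"nature must be one of {NATURES}")
        bad = set(self.labels.tolist()) - set(range(N_CLASSES))
        if bad:
            raise ValueError(f"labels outside the 4 motor classes: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class CovarianceSet:
    """Per-trial SPD covariance features: matrices is trials x channels x channels."""

    matrices: np.ndarray
    labels: np.ndarray
    nature: str = "ME"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be trials x n x n")
        if len(self.labels) != self.matrices.shape[0]:
            raise ValueError("labels length must match trial count")

    @property
    def n_trials(self) -> int:
        return self.matrices.shape[0]

    @property
    def dim(self) -> int:
        return self.matrices.shape[1]

    def subset(self, idx) -> "CovarianceSet":
        idx = np.asarray(idx)
        return CovarianceSet(
            matrices=self.matrices[idx],
            labels=self.labels[idx],
            nature=self.nature,
            subject_id=self.subject_id,
        )
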