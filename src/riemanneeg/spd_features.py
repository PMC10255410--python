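"""Trial covariance features.

Each epoched trial E (channels x samples) is summarized by its
trace-normalized spatial covariance matrix

    CM = E E^T / tr(E E^T),

a symmetric positive definite matrix with unit trace.  Trace normalization
makes the feature invariant to global amplitude scaling, so EDF physical
unit mismatches are benign downstream.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import CovarianceSet, DegenerateInputError, EpochSet


def estimate_scm(epoch: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance of one epoch (channels x samples)."""
    E = np.asarray(epoch, dtype=float)
    if E.ndim != 2:
        raise ValueError("epoch must be a channels x samples matrix")
    n_ch, n_samp = E.shape
    if n_samp <= n_ch:
        warnings.warn(
            f"epoch has {n_samp} samples for {n_ch} channels; the covariance "
            "estimate may be rank-deficient",
            stacklevel=2,
        )
    G = E @ E.T
    tr = float(np.trace(G))
    if not np.isfinite(tr) or tr <= 0.0:
        raise DegenerateInputError("epoch has zero (or non-finite) power; cannot normalize")
    CM = G / tr
    return 0.5 * (CM + CM.T)


def validate_spd(M: np.ndarray, eig_floor: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Symmetrize M and clip eigenvalues below ``eig_floor * trace``.

    Returns the (possibly repaired) matrix and a flag saying whether any
    repair beyond symmetrization was needed.  This is a numerical safety
    net, not part of the statistical model.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("validate_spd requires a square matrix")
    S = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(S)
    floor = eig_floor * float(np.trace(S))
    repaired = bool(w[0] < floor)
    if repaired:
        w = np.maximum(w, floor)
        S = (V * w) @ V.T
        S = 0.5 * (S + S.T)
    return S, repaired


def build_covariance_set(epochs: EpochSet, validate: bool = False) -> CovarianceSet:
    """Estimate one SPD covariance per trial, carrying labels through."""
    if epochs.n_trials == 0:
        raise ValueError("cannot build covariances from an empty EpochSet")
    mats = np.empty((epochs.n_trials, epochs.n_channels, epochs.n_channels))
    for i in range(epochs.n_trials):
        try:
            CM = estimate_scm(epochs.data[i])
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"trial {i}: {exc}") from exc
        if validate:
            CM, _ = validate_spd(CM)
        mats[i] = CM
    return CovarianceSet(
        matrices=mats,
        labels=epochs.labels,
        nature=epochs.nature,
        subject_id=epochs.subject_id,
    )
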