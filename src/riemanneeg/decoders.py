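"""MDM / FgMDM classifiers with online adaptation.

The base classifiers:

* **MDM** (minimum distance to Riemannian mean): one Karcher-mean prototype
  per class; a trial is assigned to the class of the nearest prototype under
  the affine-invariant distance.
* **FgMDM**: the training covariances are mapped to the tangent space at
  their grand Karcher mean, a Fisher geodesic (Fg) discriminant filter of
  rank K-1 is fitted there, every trial is filtered (project onto the
  discriminant subspace and exp-map back), and MDM runs on the filtered
  matrices.

Each base classifier supports six adaptation strategies, giving the twelve
variants MDM, MDMS, MDMU, MDMR, MDMRS, MDMRU, FgMDM, FgMDMS, FgMDMU,
FgMDMR, FgMDMRS, FgMDMRU:

* *baseline* - static after calibration;
* *supervised* (S) - after each streamed prediction, the prototype of the
  **true** class absorbs the trial (running geodesic mean); FgMDM variants
  additionally refit the reference and Fg filter with the trial appended;
* *unsupervised* (U) - same update, driven by the **predicted** label;
* *rebias* (R) - a running reference Karcher mean is updated with every
  incoming trial *before* prediction, and the trial is recentered at it;
  calibration covariances were recentered at the calibration reference
  before prototype estimation;
* *rebias_supervised* / *rebias_unsupervised* (RS/RU) - both levels at once:
  reference updated before, prototypes after each prediction.

All per-trial updates use the incremental geodesic mean with weight
1/(n+1), where n counts matrices already absorbed.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from . import manifold
from .datatypes import CovarianceSet
from .manifold import MeanSettings

ADAPTATIONS = (
    "baseline",
    "supervised",
    "unsupervised",
    "rebias",
    "rebias_supervised",
    "rebias_unsupervised",
)

_SUFFIX = {
    "baseline": "",
    "supervised": "S",
    "unsupervised": "U",
    "rebias": "R",
    "rebias_supervised": "RS",
    "rebias_unsupervised": "RU",
}

#: The twelve classifier names, as used throughout reports and the CLI.
CLASSIFIER_NAMES = tuple(
    base + _SUFFIX[a] for base in ("MDM", "FgMDM") for a in ADAPTATIONS
)


@dataclass(frozen=True)
class ClassifierSpec:
    """A (base, adaptation) pair; ``name`` gives the conventional abbreviation."""

    base: str = "MDM"
    adaptation: str = "baseline"

    def __post_init__(self) -> None:
        if self.base not in ("MDM", "FgMDM"):
            raise ValueError(f"base must be MDM or FgMDM, got {self.base!r}")
        if self.adaptation not in ADAPTATIONS:
            raise ValueError(f"unknown adaptation {self.adaptation!r}")

    @property
    def name(self) -> str:
        return self.base + _SUFFIX[self.adaptation]

    @property
    def uses_rebias(self) -> bool:
        return self.adaptation.startswith("rebias")

    @property
    def updates_prototypes(self) -> bool:
        return self.adaptation in (
            "supervised",
            "unsupervised",
            "rebias_supervised",
            "rebias_unsupervised",
        )

    @property
    def is_supervised(self) -> bool:
        return self.adaptation in ("supervised", "rebias_supervised")

    @classmethod
    def from_name(cls, name: str) -> "ClassifierSpec":
        for base in ("FgMDM", "MDM"):
            if name.startswith(base):
                suffix = name[len(base):]
                for adapt, s in _SUFFIX.items():
                    if s == suffix:
                        return cls(base=base, adaptation=adapt)
        raise ValueError(
            f"unknown classifier {name!r}; valid names: {', '.join(CLASSIFIER_NAMES)}"
        )


@dataclass
class FgModel:
    """Fisher geodesic filter: reference point, discriminant basis, ridge."""

    reference: np.ndarray
    basis: np.ndarray  # tangent_dim x (K-1), orthonormal columns
    ridge: float = 1e-3


@dataclass
class DecoderModel:
    """Fitted classifier state.

    prototypes[k] is the class-k mean SPD (in filtered/recentered space when
    the spec requires); counts[k] the number of matrices absorbed into it.
    For rebias variants, rebias_ref / rebias_count hold the running
    reference mean.  Fg variants keep the calibration covariances (already
    recentered for R* variants) so the online refits can append stream
    trials.
    """

    spec: ClassifierSpec
    classes: np.ndarray
    prototypes: dict[int, np.ndarray]
    counts: dict[int, int]
    fg: FgModel | None = None
    rebias_ref: np.ndarray | None = None
    rebias_count: int = 0
    train_matrices: np.ndarray | None = None
    train_labels: np.ndarray | None = None
    mean_settings: MeanSettings = field(default_factory=MeanSettings)
    refit_window: int | None = None

    @property
    def dim(self) -> int:
        return next(iter(self.prototypes.values())).shape[0]


@dataclass
class StreamResult:
    """Outcome of streaming a trial sequence through an adaptive decoder."""

    predictions: np.ndarray
    distances: np.ndarray  # n_trials x n_classes (inf for absent classes)
    truth: np.ndarray | None
    model: DecoderModel


def fg_filter_fit(
    matrices: np.ndarray,
    labels: np.ndarray,
    reference: np.ndarray,
    ridge: float = 1e-3,
) -> FgModel:
    """Fit the Fisher geodesic filter in the tangent space at ``reference``.

    Discriminant directions maximize between-class over within-class scatter
    of the tangent vectors (within-class scatter ridge-regularized by
    ``ridge * trace/dim``); the top K-1 generalized eigenvectors are kept
    and orthonormalized, so filtering is an orthogonal projection in the
    sqrt(2)-weighted tangent coordinates.
    """
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("Fg filter requires at least 2 classes")
    V = manifold.tangent_map(matrices, reference)
    d = V.shape[1]
    if d < len(classes) - 1:
        raise ValueError("tangent dimension smaller than K-1")
    grand = V.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for k in classes:
        Vk = V[labels == k]
        mk = Vk.mean(axis=0)
        Dk = Vk - mk
        Sw += Dk.T @ Dk
        dm = (mk - grand)[:, None]
        Sb += len(Vk) * (dm @ dm.T)
    Sw /= len(labels)
    Sb /= len(labels)
    Sw_reg = Sw + (ridge * np.trace(Sw) / d + 1e-12) * np.eye(d)
    try:
        w, U = scipy.linalg.eigh(Sb, Sw_reg)
    except scipy.linalg.LinAlgError as exc:
        raise RuntimeError(f"Fg filter scatter eigenproblem failed: {exc}") from exc
    k = len(classes) - 1
    top = U[:, np.argsort(w)[::-1][:k]]
    basis, _ = np.linalg.qr(top)
    return FgModel(reference=np.asarray(reference, float), basis=basis, ridge=ridge)


def fg_filter_apply(model: FgModel, C: np.ndarray) -> np.ndarray:
    """Filter an SPD matrix (or stack): tangent-map, project, exp-map back."""
    v = manifold.tangent_map(C, model.reference)
    proj = (v @ model.basis) @ model.basis.T
    return manifold.inverse_tangent_map(proj, model.reference)


def _class_prototypes(
    matrices: np.ndarray, labels: np.ndarray, settings: MeanSettings
) -> tuple[dict[int, np.ndarray], dict[int, int]]:
    protos: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for k in np.unique(labels):
        Xk = matrices[labels == k]
        protos[int(k)] = manifold.karcher_mean(Xk, settings)
        counts[int(k)] = len(Xk)
    return protos, counts


def fit(
    spec: ClassifierSpec,
    train: CovarianceSet,
    settings: MeanSettings | None = None,
    ridge: float = 1e-3,
    refit_window: int | None = None,
) -> DecoderModel:
    """Calibrate a decoder on a labeled covariance set."""
    settings = settings or MeanSettings()
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to fit a decoder")
    X = train.matrices
    y = train.labels

    rebias_ref = None
    rebias_count = 0
    if spec.uses_rebias:
        rebias_ref = manifold.karcher_mean(X, settings)
        rebias_count = len(X)
        X = manifold.recenter(X, rebias_ref)

    fg = None
    if spec.base == "FgMDM":
        reference = manifold.karcher_mean(X, settings)
        fg = fg_filter_fit(X, y, reference, ridge=ridge)
        Xf = fg_filter_apply(fg, X)
    else:
        Xf = X

    protos, counts = _class_prototypes(Xf, y, settings)
    keep_train = spec.base == "FgMDM" and spec.updates_prototypes
    return DecoderModel(
        spec=spec,
        classes=classes,
        prototypes=protos,
        counts=counts,
        fg=fg,
        rebias_ref=rebias_ref,
        rebias_count=rebias_count,
        train_matrices=X.copy() if keep_train else None,
        train_labels=y.copy() if keep_train else None,
        mean_settings=settings,
        refit_window=refit_window,
    )


def _distances(model: DecoderModel, C: np.ndarray) -> tuple[int, np.ndarray]:
    """Distances from one (already recentered/filtered) trial to all prototypes."""
    dists = np.array([manifold.riemannian_distance(model.prototypes[int(k)], C) for k in model.classes])
    label = int(model.classes[int(np.argmin(dists))])  # argmin -> lowest class index on ties
    return label, dists


def _transform_trial(model: DecoderModel, C: np.ndarray) -> np.ndarray:
    if model.spec.uses_rebias:
        assert model.rebias_ref is not None
        C = manifold.recenter(C, model.rebias_ref)
    if model.fg is not None:
        C = fg_filter_apply(model.fg, C)
    return C


def predict(model: DecoderModel, C: np.ndarray) -> tuple[int, np.ndarray]:
    """Classify one trial covariance; returns (label, per-class distances).

    The trial is recentered at the current rebias reference and/or Fg
    filtered as the variant requires; no model state is modified.
    """
    C = np.asarray(C, dtype=float)
    if C.shape != (model.dim, model.dim):
        raise ValueError(f"trial has shape {C.shape}, model dimension is {model.dim}")
    return _distances(model, _transform_trial(model, C))


def predict_batch(model: DecoderModel, covs: CovarianceSet) -> np.ndarray:
    return np.array([predict(model, C)[0] for C in covs.matrices])


def _refit_fg(model: DecoderModel) -> None:
    """Recompute reference, Fg filter and prototypes from calibration + seen trials."""
    X, y = model.train_matrices, model.train_labels
    if model.refit_window is not None and len(y) > model.refit_window:
        X = X[-model.refit_window:]
        y = y[-model.refit_window:]
    reference = manifold.karcher_mean(X, model.mean_settings)
    model.fg = fg_filter_fit(X, y, reference, ridge=model.fg.ridge)
    Xf = fg_filter_apply(model.fg, X)
    model.prototypes, model.counts = _class_prototypes(Xf, y, model.mean_settings)


def predict_stream(
    model: DecoderModel,
    stream: CovarianceSet,
    truth: np.ndarray | None = None,
) -> StreamResult:
    """Stream trials through the decoder with the variant's online adaptation.

    Trials are processed in the given order.  Supervised variants require
    ``truth``.  The input model is not modified; the adapted copy is
    returned in the result.
    """
    spec = model.spec
    if spec.is_supervised and truth is None:
        raise ValueError(f"{spec.name} requires true labels for the stream")
    model = copy.deepcopy(model)
    n = stream.n_trials
    preds = np.empty(n, dtype=int)
    dists = np.full((n, len(model.classes)), np.inf)
    for i in range(n):
        C = stream.matrices[i]
        if spec.uses_rebias:
            # reference absorbs the raw incoming trial before prediction
            model.rebias_ref = manifold.incremental_mean(
                model.rebias_ref, C, model.rebias_count
            )
            model.rebias_count += 1
            Cw = manifold.recenter(C, model.rebias_ref)
        else:
            Cw = C
        if model.fg is not None:
            Cf = fg_filter_apply(model.fg, Cw)
        else:
            Cf = Cw
        label, d = _distances(model, Cf)
        preds[i] = label
        dists[i] = d
        if spec.updates_prototypes:
            lab = int(truth[i]) if spec.is_supervised else label
            if spec.base == "FgMDM":
                # append the (recentered) trial and refit reference + filter
                model.train_matrices = np.concatenate(
                    [model.train_matrices, Cw[None]], axis=0
                )
                model.train_labels = np.append(model.train_labels, lab)
                _refit_fg(model)
            elif lab in model.prototypes:
                model.prototypes[lab] = manifold.incremental_mean(
                    model.prototypes[lab], Cw, model.counts[lab]
                )
                model.counts[lab] += 1
            else:
                warnings.warn(f"stream label {lab} unseen in calibration; skipped update")
    return StreamResult(
        predictions=preds,
        distances=dists,
        truth=None if truth is None else np.asarray(truth),
        model=model,
    )
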