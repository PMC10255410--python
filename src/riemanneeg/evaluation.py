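"""Cross-validation protocol, per-class metrics, cohort summaries and ITR.

Per subject: 10-fold stratified cross-validation over the 90 trials of one
task nature.  For each fold the decoder is calibrated on the out-of-fold
trials and the in-fold trials are streamed through it in their original
order with the variant's online adaptation active (adaptation state resets
at every fold boundary).  Across subjects, accuracies are summarized as
mean, sample SD and a Student-t 95% confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from . import decoders
from .datatypes import CLASS_NAMES, N_CLASSES, CovarianceSet
from .decoders import ClassifierSpec, DecoderModel
from .manifold import MeanSettings


@dataclass
class FoldPlan:
    """Stratified fold assignment: assignments[i] is the fold of trial i."""

    k: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> FoldPlan:
    """Shuffled within-class round-robin fold assignment.

    Indices of each class are shuffled and dealt to folds in turn, with the
    fold pointer carried across classes, so fold sizes differ by at most one
    and per-fold class counts stay within one of proportionality (90 trials
    balanced 22-23 over 4 classes at k=10 gives exactly 9 trials per fold
    with 2-3 per class).
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = np.empty(len(labels), dtype=int)
    pointer = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            warnings.warn(
                f"class {cls} has only {len(idx)} trials for {k} folds; "
                "some folds will lack it"
            )
        idx = rng.permutation(idx)
        for j, trial in enumerate(idx):
            assignments[trial] = (pointer + j) % k
        pointer = (pointer + len(idx)) % k
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass
class CVReport:
    """Per-subject cross-validation outcome for one classifier and setting."""

    classifier: str
    subject_id: str
    setting: str
    fold_accuracies: list[float]
    confusion: np.ndarray  # K x K, rows = truth, columns = prediction

    @property
    def accuracy(self) -> float:
        """Pooled accuracy: trace of the confusion matrix over total trials."""
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def evaluate_subject(
    spec: ClassifierSpec,
    covs: CovarianceSet,
    plan: FoldPlan,
    settings: MeanSettings | None = None,
) -> CVReport:
    """Calibrate-and-stream each fold; accumulate the pooled confusion matrix."""
    settings = settings or MeanSettings()
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    fold_acc = []
    for fold in range(plan.k):
        tr = plan.train_indices(fold)
        te = plan.test_indices(fold)
        if len(te) == 0:
            continue
        train = covs.subset(tr)
        test = covs.subset(te)
        if len(np.unique(train.labels)) < len(np.unique(covs.labels)):
            warnings.warn(f"fold {fold}: training set is missing a class; proceeding")
        model = decoders.fit(spec, train, settings=settings)
        result = decoders.predict_stream(model, test, truth=test.labels)
        for t, p in zip(test.labels, result.predictions):
            confusion[t, p] += 1
        fold_acc.append(float(np.mean(result.predictions == test.labels)))
    return CVReport(
        classifier=spec.name,
        subject_id=covs.subject_id,
        setting=covs.nature,
        fold_accuracies=fold_acc,
        confusion=confusion,
    )


def confusion_metrics(confusion: np.ndarray) -> pd.DataFrame:
    """Per-class TP/FP/FN, precision, recall and FP-source / FN-destination shares.

    fp_from_<class> is the fraction of a class's false positives whose true
    label was <class>; fn_to_<class> the fraction of its false negatives
    predicted as <class>.
    """
    M = np.asarray(confusion)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(M < 0):
        raise ValueError("confusion matrix must be nonnegative")
    if M.sum() == 0:
        raise ValueError("confusion matrix has no trials")
    K = M.shape[0]
    names = list(CLASS_NAMES[:K]) if K <= len(CLASS_NAMES) else [str(i) for i in range(K)]
    rows = []
    for k in range(K):
        tp = int(M[k, k])
        fp = int(M[:, k].sum() - tp)
        fn = int(M[k, :].sum() - tp)
        row = {
            "class": names[k],
            "TP": tp,
            "FP": fp,
            "FN": fn,
            "precision": tp / (tp + fp) if tp + fp else np.nan,
            "recall": tp / (tp + fn) if tp + fn else np.nan,
        }
        for j in range(K):
            if j == k:
                continue
            row[f"fp_from_{names[j]}"] = M[j, k] / fp if fp else np.nan
            row[f"fn_to_{names[j]}"] = M[k, j] / fn if fn else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


@dataclass
class CohortSummary:
    """Across-subject aggregation: mean, sample SD and a t-based CI."""

    n: int
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    confidence: float = 0.95


def cohort_summary(accuracies, confidence: float = 0.95) -> CohortSummary:
    """Mean +/- t(df=n-1) * SD/sqrt(n) two-sided confidence interval.

    SD uses the n-1 denominator.  With n=103 subjects the t quantile
    (~1.9835) differs from the normal one in the third decimal of the
    bounds, and the t interval is the one used throughout.
    """
    a = np.asarray(accuracies, dtype=float)
    if a.size < 2:
        raise ValueError("cohort summary requires at least 2 subjects")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    mean = float(a.mean())
    sd = float(a.std(ddof=1))
    half = scipy.stats.t.ppf((1 + confidence) / 2, df=a.size - 1) * sd / np.sqrt(a.size)
    return CohortSummary(
        n=int(a.size),
        mean=mean,
        sd=sd,
        ci_lower=mean - float(half),
        ci_upper=mean + float(half),
        confidence=confidence,
    )


def itr(P: float, N: int = 4, trial_seconds: float = 4.0) -> float:
    """Wolpaw information transfer rate in bits per minute.

    bits/trial = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)), with zero-
    probability terms contributing 0; multiplied by 60/trial_seconds.
    Accuracies below chance return 0 with a warning.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must be in [0, 1]")
    if trial_seconds <= 0:
        raise ValueError("trial_seconds must be positive")
    if P < 1.0 / N:
        warnings.warn(f"accuracy {P} below chance 1/{N}; ITR reported as 0")
        return 0.0
    bits = np.log2(N)
    if P > 0:
        bits += P * np.log2(P)
    if P < 1:
        bits += (1 - P) * np.log2((1 - P) / (N - 1))
    return float(bits * 60.0 / trial_seconds)
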