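"""Synthetic sensorimotor-EEG subjects with known manifold ground truth.

The generator emulates the statistical structure the decoders assume: each
subject has two task natures (motor execution, motor imagery), six 2-minute
runs per nature at 160 Hz sampling on a 64-channel 10-10 montage, each run
interleaving 15 cued motor trials with rest periods.  Per nature the 90
motor trials are balanced 22-23 over the four classes (left fist, right
fist, both fists, both feet).

Two signal models are available:

* ``covariance`` (default, the test workhorse): per trial a covariance is
  drawn Wishart-style around a class-specific SPD mean and the segment is
  filled with Gaussian samples from it.  Truth is known exactly on the
  manifold, so prototype recovery and classifier behavior can be checked
  quantitatively.
* ``oscillatory``: mu (10 Hz) and beta (22 Hz) sinusoids on top of 1/f
  noise, with ERD-style class-dependent power reduction at lateralized
  central channel blocks.  Closer in appearance to real sensorimotor
  rhythms, but truth is only approximate.

Class structure is injected by exp-map steps away from a shared base SPD,
with directions localized to C3/C4/Cz-like channel blocks: left-fist trials
modulate the right-hemisphere block (contralateral), right-fist the left
block, both-fists both lateral blocks, both-feet the central block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import manifold
from .datatypes import CLASS_NAMES, AnnotationEvent, CovarianceSet, RunRecord

#: 64-channel 10-10 montage in source-dataset order.
MONTAGE_64: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FT8",
    "T7", "T8", "T9", "T10",
    "TP7", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: ME runs alternate with MI runs in the 14-run session layout.
ME_RUNS = (3, 5, 7, 9, 11, 13)
MI_RUNS = (4, 6, 8, 10, 12, 14)

TASK_SECONDS = 4.1   # cue period; a 4.0 s epoch always fits
REST_SECONDS = 4.2


@dataclass
class SynthConfig:
    """Conditions for one synthetic subject.

    separation is the manifold distance scale between class-mean SPDs;
    noise_df the Wishart degrees of freedom controlling trial-to-trial
    covariance dispersion (larger = tighter concentration around the class
    mean); drift_strength scales a slowly varying congruence drift across
    trials (0 = stationary session).
    """

    n_channels: int = 64
    montage: list[str] | None = None
    fs: float = 160.0
    runs_per_nature: int = 6
    trials_per_run: int = 15
    n_classes: int = 4
    separation: float = 0.5
    drift_strength: float = 0.0
    noise_df: int = 640
    seed: int = 0
    mode: str = "covariance"
    signal_scale: float = 20.0  # microvolt-ish amplitude for EDF export

    def __post_init__(self) -> None:
        if self.n_classes != 4:
            raise ValueError("the paradigm has exactly 4 motor classes")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.separation < 0 or self.drift_strength < 0:
            raise ValueError("separation and drift_strength must be >= 0")
        if self.mode not in ("covariance", "oscillatory"):
            raise ValueError(f"unknown signal mode {self.mode!r}")
        if self.montage is None:
            if self.n_channels == 64:
                self.montage = list(MONTAGE_64)
            else:
                self.montage = [f"CH{i + 1}" for i in range(self.n_channels)]
        if len(self.montage) != self.n_channels:
            raise ValueError(
                f"montage has {len(self.montage)} names for {self.n_channels} channels"
            )


@dataclass
class ClassMeanSet:
    """The generative class prototypes: 4 unit-trace SPD matrices."""

    means: np.ndarray  # 4 x n x n
    labels: tuple[str, ...] = CLASS_NAMES
    rest: np.ndarray | None = None  # shared rest-state covariance
    base: np.ndarray | None = None


def _channel_blocks(n_channels: int, montage: list[str] | None = None):
    """Index blocks standing in for C3-, C4- and Cz-neighborhood electrodes."""
    if montage and "C3" in montage and "C4" in montage and "Cz" in montage:
        def around(name):
            i = montage.index(name)
            lo = max(i - 2, 0)
            return list(range(lo, min(lo + 5, n_channels)))
        return around("C3"), around("C4"), around("Cz")
    third = max(n_channels // 3, 1)
    left = list(range(0, third))
    center = list(range(third, min(2 * third, n_channels)))
    right = list(range(min(2 * third, n_channels - 1), n_channels))
    return left, right, center


def _block_direction(rng: np.random.Generator, n: int, blocks) -> np.ndarray:
    """Unit-norm symmetric direction supported on the given channel blocks."""
    D = np.zeros((n, n))
    for b in blocks:
        b = np.asarray(b)
        Sub = rng.standard_normal((len(b), len(b)))
        Sub = 0.5 * (Sub + Sub.T)
        D[np.ix_(b, b)] += Sub
    nrm = np.linalg.norm(D, "fro")
    if nrm == 0:
        raise ValueError("empty channel blocks")
    return D / nrm


def make_class_covariances(
    n_channels: int, separation: float, seed: int, montage: list[str] | None = None
) -> ClassMeanSet:
    """Build 4 unit-trace SPD class means a manifold distance ~separation apart.

    A shared base SPD is congruence-perturbed per class by an exp-map step of
    norm proportional to separation, in a class-specific direction localized
    to lateral/central channel blocks (contralateral organization: left fist
    -> right block, right fist -> left block, both fists -> both, both feet
    -> central).
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    # well-conditioned random base SPD
    A = rng.standard_normal((n_channels, 4 * n_channels))
    base = A @ A.T / (4 * n_channels) + np.eye(n_channels)
    base /= np.trace(base)

    left, right, center = _channel_blocks(n_channels, montage)
    directions = [
        _block_direction(rng, n_channels, [right]),          # left_fist
        _block_direction(rng, n_channels, [left]),           # right_fist
        _block_direction(rng, n_channels, [left, right]),    # both_fists
        _block_direction(rng, n_channels, [center]),         # both_feet
    ]
    Bs = manifold.sqrtm(base)
    means = np.empty((4, n_channels, n_channels))
    for k, D in enumerate(directions):
        M = Bs @ manifold.expm(separation * D) @ Bs
        M = 0.5 * (M + M.T)
        means[k] = M / np.trace(M)
    # rest state: its own direction, kept away from all 4 class means
    Dr = _block_direction(rng, n_channels, [list(range(n_channels))])
    R = Bs @ manifold.expm(-max(separation, 0.5) * Dr) @ Bs
    R = 0.5 * (R + R.T)
    return ClassMeanSet(means=means, rest=R / np.trace(R), base=base)


def _balanced_labels(rng: np.random.Generator, pair: tuple[int, int], total: int, n_major: int):
    """Shuffled label sequence for one run-type group: n_major of pair[0], rest pair[1]."""
    seq = np.array([pair[0]] * n_major + [pair[1]] * (total - n_major))
    rng.shuffle(seq)
    return seq


def _drift_transforms(
    rng: np.random.Generator, n_steps: int, strength: float, n: int
) -> np.ndarray:
    """Slowly varying SPD congruence factors G_t = expm(S_t / 2), S_t a random walk."""
    G = np.empty((n_steps, n, n))
    S = np.zeros((n, n))
    scale = strength / np.sqrt(max(n_steps, 1)) / np.sqrt(n)
    for t in range(n_steps):
        step = rng.standard_normal((n, n))
        S = S + scale * 0.5 * (step + step.T)
        G[t] = manifold.expm(0.5 * S)
    return G


def _wishart_sample(rng: np.random.Generator, L: np.ndarray, df: int) -> np.ndarray:
    """Draw (L X X^T L^T) / df with X ~ N(0, I), i.e. Wishart(Sigma, df)/df."""
    n = L.shape[0]
    X = rng.standard_normal((n, df))
    Y = L @ X
    return (Y @ Y.T) / df


def _covariance_segment(rng, cov, n_samples, scale):
    L = np.linalg.cholesky(cov)
    return scale * (rng.standard_normal((n_samples, cov.shape[0])) @ L.T)


def _pink_noise(rng, n_samples, n_channels, fs):
    """1/f-shaped noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_samples, n_channels))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    return np.fft.irfft(spec * shaping[:, None], n=n_samples, axis=0)


def _oscillatory_segment(rng, cfg, class_idx, blocks, n_samples):
    """Mu/beta sinusoids with ERD-style per-class attenuation plus 1/f noise."""
    left, right, center = blocks
    t = np.arange(n_samples) / cfg.fs
    seg = _pink_noise(rng, n_samples, cfg.n_channels, cfg.fs)
    amp = np.ones(cfg.n_channels)
    erd = 1.0 / (1.0 + cfg.separation)  # deeper ERD with stronger class structure
    if class_idx is not None:
        active = {0: right, 1: left, 2: left + right, 3: center}[class_idx]
        amp[np.asarray(active)] = erd
    for f0, a0 in ((10.0, 1.0), (22.0, 0.6)):
        phase = rng.uniform(0, 2 * np.pi, cfg.n_channels)
        seg += a0 * amp[None, :] * np.sin(2 * np.pi * f0 * t[:, None] + phase[None, :])
    return cfg.signal_scale * seg


def generate_subject(config: SynthConfig) -> list[RunRecord]:
    """Generate all motor runs of one synthetic subject (both natures).

    Each run alternates rest (T0, 4.2 s) and cued motor (T1/T2, 4.1 s)
    segments; annotations carry exact sample onsets and durations.  Per
    nature the 90 motor trials are balanced 22-23 per class.  Deterministic
    for a fixed config.seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cms = make_class_covariances(cfg.n_channels, cfg.separation, seed=cfg.seed, montage=cfg.montage)
    blocks = _channel_blocks(cfg.n_channels, cfg.montage)
    chol = [np.linalg.cholesky(m) for m in cms.means]
    chol_rest = np.linalg.cholesky(cms.rest)

    n_task = int(round(TASK_SECONDS * cfg.fs))
    n_rest = int(round(REST_SECONDS * cfg.fs))
    total_trials = cfg.runs_per_nature * cfg.trials_per_run

    runs: list[RunRecord] = []
    for nature, run_indices in (("ME", ME_RUNS), ("MI", MI_RUNS)):
        half = total_trials // 2
        # unilateral group: left gets the extra trial when odd; bilateral: feet
        lr_seq = _balanced_labels(rng, (0, 1), half, (half + 1) // 2)
        ff_seq = _balanced_labels(rng, (2, 3), total_trials - half, (total_trials - half) // 2)
        lr_runs = iter(np.array_split(lr_seq, cfg.runs_per_nature // 2))
        ff_runs = iter(np.array_split(ff_seq, cfg.runs_per_nature - cfg.runs_per_nature // 2))
        drift = (
            _drift_transforms(rng, total_trials, cfg.drift_strength, cfg.n_channels)
            if cfg.drift_strength > 0
            else None
        )
        trial_counter = 0
        for run_index in run_indices[: cfg.runs_per_nature]:
            is_lr = run_index in (3, 4, 7, 8, 11, 12)
            labels = next(lr_runs) if is_lr else next(ff_runs)
            segments: list[np.ndarray] = []
            annotations: list[AnnotationEvent] = []
            cursor = 0
            for label in labels:
                # rest segment
                if cfg.mode == "covariance":
                    rest_cov = _wishart_sample(rng, chol_rest, cfg.noise_df)
                    seg = _covariance_segment(rng, rest_cov, n_rest, cfg.signal_scale)
                else:
                    seg = _oscillatory_segment(rng, cfg, None, blocks, n_rest)
                segments.append(seg)
                annotations.append(AnnotationEvent("T0", cursor, n_rest))
                cursor += n_rest
                # task segment
                if cfg.mode == "covariance":
                    cov = _wishart_sample(rng, chol[label], cfg.noise_df)
                    if drift is not None:
                        G = drift[trial_counter]
                        cov = G @ cov @ G.T
                    seg = _covariance_segment(rng, cov, n_task, cfg.signal_scale)
                else:
                    seg = _oscillatory_segment(rng, cfg, int(label), blocks, n_task)
                segments.append(seg)
                code = "T1" if label in (0, 2) else "T2"
                annotations.append(AnnotationEvent(code, cursor, n_task))
                cursor += n_task
                trial_counter += 1
            runs.append(
                RunRecord(
                    signal=np.concatenate(segments, axis=0),
                    channel_names=list(cfg.montage),
                    fs=cfg.fs,
                    run_index=run_index,
                    annotations=annotations,
                )
            )
    return runs


def make_covariance_set(
    config: SynthConfig,
    n_trials: int = 90,
    nature: str = "ME",
    subject_id: str = "",
    class_means: ClassMeanSet | None = None,
) -> tuple[CovarianceSet, ClassMeanSet]:
    """Directly sample a balanced CovarianceSet around the class means.

    Bypasses signal synthesis: each trial covariance is a Wishart draw
    around its class mean (trace-normalized).  This is the fast path for
    classifier tests where only the manifold structure matters.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cms = class_means or make_class_covariances(
        cfg.n_channels, cfg.separation, seed=cfg.seed, montage=cfg.montage
    )
    base = n_trials // 4
    counts = [base + (1 if k < n_trials % 4 else 0) for k in range(4)]
    labels = np.concatenate([np.full(c, k) for k, c in enumerate(counts)])
    rng.shuffle(labels)
    chol = [np.linalg.cholesky(m) for m in cms.means]
    mats = np.empty((n_trials, cfg.n_channels, cfg.n_channels))
    for i, lab in enumerate(labels):
        W = _wishart_sample(rng, chol[lab], cfg.noise_df)
        mats[i] = W / np.trace(W)
    covs = CovarianceSet(matrices=mats, labels=labels, nature=nature, subject_id=subject_id)
    if cfg.drift_strength > 0:
        covs = apply_drift(covs, cfg.drift_strength, seed=cfg.seed + 1)
    return covs, cms


def apply_drift(covs: CovarianceSet, strength: float, seed: int) -> CovarianceSet:
    """Congruence-transform each trial by a slowly varying SPD trajectory.

    Emulates within-session nonstationarity: trial t is mapped to
    G_t C_t G_t with G_t = expm(S_t/2) and S_t a symmetric random walk whose
    step size scales with strength.  Labels are unchanged; strength 0 is the
    identity.
    """
    if strength < 0:
        raise ValueError("drift strength must be >= 0")
    if strength == 0:
        return CovarianceSet(
            matrices=covs.matrices.copy(),
            labels=covs.labels.copy(),
            nature=covs.nature,
            subject_id=covs.subject_id,
        )
    rng = np.random.default_rng(seed)
    G = _drift_transforms(rng, covs.n_trials, strength, covs.dim)
    mats = np.einsum("tij,tjk,tlk->til", G, covs.matrices, G)
    mats = 0.5 * (mats + np.swapaxes(mats, -1, -2))
    return CovarianceSet(
        matrices=mats, labels=covs.labels.copy(), nature=covs.nature, subject_id=covs.subject_id
    )


def shuffled_labels(covs: CovarianceSet, seed: int) -> CovarianceSet:
    """Return a copy with labels permuted (destroys class structure for chance-level checks)."""
    rng = np.random.default_rng(seed)
    labels = covs.labels.copy()
    rng.shuffle(labels)
    return replace_labels(covs, labels)


def replace_labels(covs: CovarianceSet, labels: np.ndarray) -> CovarianceSet:
    return CovarianceSet(
        matrices=covs.matrices, labels=labels, nature=covs.nature, subject_id=covs.subject_id
    )
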