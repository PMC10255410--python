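"""End-to-end experiment orchestration.

Pipeline per subject: obtain runs (synthetic generator or an EDF directory)
-> band-pass filter each continuous run -> assemble labeled motor trials per
nature -> epoch 0-4 s -> channel subset -> per-trial covariances -> k-fold
stratified CV per classifier.  Reports: a per-subject CSV, cohort-summary
JSON, and a classifiers x settings mean-accuracy grid CSV.

Every stochastic stage draws from a named sub-seed of the master seed
(numpy SeedSequence spawning), so a re-run with the same configuration
reproduces all report files.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf_ingest, evaluation, smr_synth, spd_features
from .config import ExperimentConfig
from .datatypes import ConfigError, EpochSet, RunRecord
from .decoders import ClassifierSpec
from .preprocess import (
    ChannelSubset,
    FilterSpec,
    bandpass_filter,
    concat_epochs,
    epoch_trials,
    select_channels,
)

log = logging.getLogger("riemanneeg")


def subject_seed(master_seed: int, subject_index: int) -> int:
    """Stable per-subject sub-seed below 2**31."""
    ss = np.random.SeedSequence([master_seed, subject_index])
    return int(ss.generate_state(1)[0] % (2**31))


def preprocess_subject(
    runs: list[RunRecord],
    nature: str,
    cfg: ExperimentConfig,
    subject_id: str,
) -> EpochSet:
    """Filter, assemble, epoch and concatenate one subject's trials of one nature."""
    spec = FilterSpec(order=cfg.filter_order, band=cfg.filter_band, mode=cfg.filter_mode)
    filtered = [bandpass_filter(r, spec) for r in runs]
    trials = edf_ingest.assemble_trials(filtered, nature)
    by_run: dict[int, list[tuple[int, int]]] = {}
    run_of: dict[int, RunRecord] = {}
    for run, onset, label in trials:
        by_run.setdefault(run.run_index, []).append((onset, label))
        run_of[run.run_index] = run
    sets = [
        epoch_trials(run_of[ri], idx, cfg.epoch_window_s, nature=nature, subject_id=subject_id)
        for ri, idx in sorted(by_run.items())
    ]
    return concat_epochs(sets)


def _subject_runs(cfg: ExperimentConfig, subject_index: int, subject_id: str):
    if cfg.source == "synthetic":
        synth_cfg = cfg.synth_config(seed=subject_seed(cfg.seed, subject_index))
        return smr_synth.generate_subject(synth_cfg)
    return edf_ingest.read_subject(Path(cfg.edf_dir) / subject_id)


def _subject_list(cfg: ExperimentConfig) -> list[str]:
    if cfg.source == "synthetic":
        return [f"SYN{i + 1:03d}" for i in range(cfg.n_subjects)]
    base = Path(cfg.edf_dir)
    if not base.is_dir():
        raise ConfigError(f"edf_dir {base} is not a directory")
    if cfg.subjects == "all-qualified":
        manifest = edf_ingest.SubjectManifest(
            subject_ids=sorted(p.name for p in base.iterdir() if p.is_dir())
        )
        return edf_ingest.qualify_subjects(manifest)
    return list(cfg.subjects)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the full grid and write reports; returns the report bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_log(out / "run.log")
    t0 = _dt.datetime.now()
    log.info("experiment start seed=%d source=%s", cfg.seed, cfg.source)

    subjects = _subject_list(cfg)
    rows = []
    failures = []
    for si, sid in enumerate(subjects):
        try:
            runs = _subject_runs(cfg, si, sid)
            for nature in cfg.natures:
                epochs_full = preprocess_subject(runs, nature, cfg, sid)
                for preset in cfg.channel_presets:
                    subset = ChannelSubset.from_preset(preset, available=epochs_full.channel_names)
                    epochs = select_channels(epochs_full, subset)
                    covs = spd_features.build_covariance_set(epochs)
                    plan = evaluation.stratified_folds(
                        covs.labels, k=cfg.cv_k, seed=subject_seed(cfg.seed, 10_000 + si)
                    )
                    for name in cfg.classifiers:
                        report = evaluation.evaluate_subject(
                            ClassifierSpec.from_name(name), covs, plan
                        )
                        rows.append(
                            {
                                "subject": sid,
                                "nature": nature,
                                "channels": preset,
                                "classifier": name,
                                "accuracy": report.accuracy,
                                "mean_fold_accuracy": report.mean_fold_accuracy,
                            }
                        )
                        log.info(
                            "%s %s %s %s acc=%.4f", sid, nature, preset, name, report.accuracy
                        )
        except Exception as exc:  # noqa: BLE001 - partial failures are logged and skipped
            failures.append(sid)
            log.warning("subject %s failed: %s", sid, exc)

    per_subject = pd.DataFrame(rows)
    per_subject.to_csv(out / "per_subject.csv", index=False)

    summaries = {}
    grid = {}
    if not per_subject.empty:
        for (nature, preset, name), grp in per_subject.groupby(
            ["nature", "channels", "classifier"]
        ):
            key = f"{name}/{nature}/{preset}"
            grid[(name, f"{nature}_{preset}")] = grp["accuracy"].mean()
            if len(grp) >= 2:
                s = evaluation.cohort_summary(grp["accuracy"].to_numpy() * 100.0)
                summaries[key] = {
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "ci_lower": s.ci_lower,
                    "ci_upper": s.ci_upper,
                }
    (out / "cohort_summary.json").write_text(json.dumps(summaries, indent=2, sort_keys=True))

    grid_df = (
        pd.Series(grid).unstack() if grid else pd.DataFrame()
    )
    grid_df.to_csv(out / "summary_grid.csv")

    log.info(
        "experiment done in %.1fs; %d subjects ok, %d failed",
        (_dt.datetime.now() - t0).total_seconds(),
        len(subjects) - len(failures),
        len(failures),
    )
    return {
        "per_subject": per_subject,
        "cohort_summaries": summaries,
        "summary_grid": grid_df,
        "failed_subjects": failures,
        "out_dir": str(out),
    }


def _setup_log(path: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(
        isinstance(h, logging.FileHandler) and h.baseFilename == str(path) for h in log.handlers
    ):
        handler = logging.FileHandler(path)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s", "%Y-%m-%dT%H:%M:%S")
        )
        log.addHandler(handler)
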