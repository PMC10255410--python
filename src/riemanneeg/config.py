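"""Experiment configuration: YAML schema, defaults and validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .datatypes import NATURES, ConfigError
from .decoders import CLASSIFIER_NAMES
from .smr_synth import SynthConfig

_TOP_KEYS = {
    "source",
    "edf_dir",
    "synth",
    "n_subjects",
    "subjects",
    "natures",
    "channel_presets",
    "classifiers",
    "cv",
    "filter",
    "epoch",
    "seed",
    "out_dir",
}
_SYNTH_KEYS = {
    "n_channels",
    "fs",
    "runs_per_nature",
    "trials_per_run",
    "separation",
    "drift_strength",
    "noise_df",
    "mode",
}
_CV_KEYS = {"k"}
_FILTER_KEYS = {"order", "band", "mode"}
_EPOCH_KEYS = {"window_s"}
_PRESETS = {"full64", "sensorimotor29"}


@dataclass
class ExperimentConfig:
    """Fully defaulted, validated experiment description."""

    source: str = "synthetic"
    edf_dir: str | None = None
    synth: dict = field(default_factory=dict)
    n_subjects: int = 5
    subjects: list[str] | str = "all-qualified"
    natures: list[str] = field(default_factory=lambda: ["ME", "MI"])
    channel_presets: list[str] = field(default_factory=lambda: ["full64", "sensorimotor29"])
    classifiers: list[str] = field(default_factory=lambda: list(CLASSIFIER_NAMES))
    cv_k: int = 10
    filter_order: int = 5
    filter_band: tuple[float, float] = (8.0, 30.0)
    filter_mode: str = "causal"
    epoch_window_s: float = 4.0
    seed: int = 0
    out_dir: str = "results"

    def synth_config(self, seed: int) -> SynthConfig:
        return SynthConfig(seed=seed, **self.synth)


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown config key(s) in {where}: {', '.join(sorted(unknown))}")


def build_config(raw: dict) -> ExperimentConfig:
    """Validate a raw mapping and fill in defaults."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    cfg = ExperimentConfig()

    cfg.source = raw.get("source", cfg.source)
    if cfg.source not in ("synthetic", "edf_dir"):
        raise ConfigError(f"source must be synthetic or edf_dir, got {cfg.source!r}")
    cfg.edf_dir = raw.get("edf_dir")
    if cfg.source == "edf_dir" and not cfg.edf_dir:
        raise ConfigError("source edf_dir requires an edf_dir path")

    synth = raw.get("synth", {}) or {}
    _check_keys(synth, _SYNTH_KEYS, "synth")
    cfg.synth = synth
    cfg.n_subjects = int(raw.get("n_subjects", cfg.n_subjects))
    cfg.subjects = raw.get("subjects", cfg.subjects)

    cfg.natures = list(raw.get("natures", cfg.natures))
    for n in cfg.natures:
        if n not in NATURES:
            raise ConfigError(f"unknown task nature {n!r}")
    cfg.channel_presets = list(raw.get("channel_presets", cfg.channel_presets))
    for p in cfg.channel_presets:
        if p not in _PRESETS:
            raise ConfigError(f"unknown channel preset {p!r}")
    if not cfg.natures or not cfg.channel_presets:
        raise ConfigError("settings grid (natures x channel_presets) must be nonempty")

    cfg.classifiers = list(raw.get("classifiers", cfg.classifiers))
    bad = [c for c in cfg.classifiers if c not in CLASSIFIER_NAMES]
    if bad:
        raise ConfigError(f"unknown classifier name(s): {', '.join(bad)}")

    cv = raw.get("cv", {}) or {}
    _check_keys(cv, _CV_KEYS, "cv")
    cfg.cv_k = int(cv.get("k", cfg.cv_k))
    if cfg.cv_k < 2:
        raise ConfigError("cv.k must be >= 2")

    filt = raw.get("filter", {}) or {}
    _check_keys(filt, _FILTER_KEYS, "filter")
    cfg.filter_order = int(filt.get("order", cfg.filter_order))
    band = filt.get("band", list(cfg.filter_band))
    if len(band) != 2 or not band[0] < band[1]:
        raise ConfigError(f"filter.band must be [low, high] with low < high, got {band}")
    cfg.filter_band = (float(band[0]), float(band[1]))
    cfg.filter_mode = filt.get("mode", cfg.filter_mode)

    epoch = raw.get("epoch", {}) or {}
    _check_keys(epoch, _EPOCH_KEYS, "epoch")
    cfg.epoch_window_s = float(epoch.get("window_s", cfg.epoch_window_s))
    if cfg.epoch_window_s <= 0:
        raise ConfigError("epoch.window_s must be positive")

    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.out_dir = str(raw.get("out_dir", cfg.out_dir))
    return cfg


def validate_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML (or JSON) configuration file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return build_config(raw or {})
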