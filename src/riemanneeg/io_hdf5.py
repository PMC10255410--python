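"""HDF5 serialization for epochs, covariance sets and fitted decoders."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .datatypes import CovarianceSet, EpochSet
from .decoders import ClassifierSpec, DecoderModel, FgModel
from .manifold import MeanSettings


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("labels", data=epochs.labels)
        f.attrs["channel_names"] = [c.encode() for c in epochs.channel_names]
        f.attrs["fs"] = epochs.fs
        f.attrs["nature"] = epochs.nature
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["window_seconds"] = epochs.window_seconds


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            labels=f["labels"][()],
            channel_names=[c.decode() for c in f.attrs["channel_names"]],
            fs=float(f.attrs["fs"]),
            nature=str(f.attrs["nature"]),
            subject_id=str(f.attrs["subject_id"]),
            window_seconds=float(f.attrs["window_seconds"]),
        )


def save_covariances(path: str | Path, covs: CovarianceSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("matrices", data=covs.matrices, compression="gzip")
        f.create_dataset("labels", data=covs.labels)
        f.attrs["nature"] = covs.nature
        f.attrs["subject_id"] = covs.subject_id


def load_covariances(path: str | Path) -> CovarianceSet:
    with h5py.File(path, "r") as f:
        return CovarianceSet(
            matrices=f["matrices"][()],
            labels=f["labels"][()],
            nature=str(f.attrs["nature"]),
            subject_id=str(f.attrs["subject_id"]),
        )


def save_model(path: str | Path, model: DecoderModel) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["base"] = model.spec.base
        f.attrs["adaptation"] = model.spec.adaptation
        f.create_dataset("classes", data=model.classes)
        for k in model.classes:
            g = f.create_group(f"prototype_{int(k)}")
            g.create_dataset("mean", data=model.prototypes[int(k)])
            g.attrs["count"] = model.counts[int(k)]
        if model.rebias_ref is not None:
            f.create_dataset("rebias_ref", data=model.rebias_ref)
            f.attrs["rebias_count"] = model.rebias_count
        if model.fg is not None:
            g = f.create_group("fg")
            g.create_dataset("reference", data=model.fg.reference)
            g.create_dataset("basis", data=model.fg.basis)
            g.attrs["ridge"] = model.fg.ridge
        if model.train_matrices is not None:
            f.create_dataset("train_matrices", data=model.train_matrices, compression="gzip")
            f.create_dataset("train_labels", data=model.train_labels)


def load_model(path: str | Path) -> DecoderModel:
    with h5py.File(path, "r") as f:
        spec = ClassifierSpec(base=str(f.attrs["base"]), adaptation=str(f.attrs["adaptation"]))
        classes = f["classes"][()]
        prototypes = {}
        counts = {}
        for k in classes:
            g = f[f"prototype_{int(k)}"]
            prototypes[int(k)] = g["mean"][()]
            counts[int(k)] = int(g.attrs["count"])
        fg = None
        if "fg" in f:
            fg = FgModel(
                reference=f["fg"]["reference"][()],
                basis=f["fg"]["basis"][()],
                ridge=float(f["fg"].attrs["ridge"]),
            )
        rebias_ref = f["rebias_ref"][()] if "rebias_ref" in f else None
        rebias_count = int(f.attrs.get("rebias_count", 0))
        train_m = f["train_matrices"][()] if "train_matrices" in f else None
        train_l = f["train_labels"][()] if "train_labels" in f else None
        return DecoderModel(
            spec=spec,
            classes=np.asarray(classes),
            prototypes=prototypes,
            counts=counts,
            fg=fg,
            rebias_ref=rebias_ref,
            rebias_count=rebias_count,
            train_matrices=train_m,
            train_labels=train_l,
            mean_settings=MeanSettings(),
        )
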