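"""HDF5 containers for trials, features, model checkpoints, and reports.

TrialSet layout: /data (float32, trials x channels x samples), /ratings
(trials x 2), optional /truth/A and /truth/sources for synthetic ground
truth, attributes ``fs`` and ``channel_names``.  A DEAP-shaped recording
(40 x 32 x 8064 @ 128 Hz) stored this way runs through the whole pipeline.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np

from .classify import ClassifierSpec, TrainedClassifier
from .decompose import SAEModel
from .evaluate import CVReport
from .features import FeatureSequence
from .synth import MixingGroundTruth, TrialSet

__all__ = [
    "FormatError",
    "save_trialset",
    "load_trialset",
    "save_features",
    "load_features",
    "save_sae",
    "load_sae",
    "save_classifier",
    "load_classifier",
    "save_report",
    "load_report",
    "export_ratings_csv",
]


class FormatError(ValueError):
    """A container file is missing a required dataset or attribute."""


def save_trialset(
    trials: TrialSet,
    path,
    truth: MixingGroundTruth | None = None,
    sources: np.ndarray | None = None,
) -> None:
    trials.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trials.data.astype(np.float32))
        f.create_dataset("ratings", data=np.asarray(trials.ratings, dtype=np.float64))
        f.attrs["fs"] = float(trials.fs)
        f.attrs["channel_names"] = [str(c) for c in trials.channel_names]
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("A", data=truth.A)
            g.attrs["noise_sd"] = truth.noise_sd
            g.attrs["seed"] = truth.seed
            if sources is not None:
                g.create_dataset("sources", data=sources.astype(np.float32))


def load_trialset(
    path, expected_channels: int | None = None, expected_fs: float | None = None
) -> TrialSet:
    """Read a TrialSet container, validating layout and (optionally) shape.

    Raises :class:`FormatError` naming the missing field, or ValueError on a
    shape/rate mismatch against the expectations.
    """
    if not Path(path).exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for name in ("data", "ratings"):
            if name not in f:
                raise FormatError(f"missing dataset /{name}")
        if "fs" not in f.attrs:
            raise FormatError("missing attribute 'fs'")
        data = np.asarray(f["data"], dtype=float)
        ratings = np.asarray(f["ratings"], dtype=float)
        fs = float(f.attrs["fs"])
        names = [str(c) for c in f.attrs.get(
            "channel_names", [f"EEG{i:02d}" for i in range(data.shape[1])]
        )]
    if expected_channels is not None and data.shape[1] != expected_channels:
        raise ValueError(
            f"file has {data.shape[1]} channels, config expects {expected_channels}"
        )
    if expected_fs is not None and fs != expected_fs:
        raise ValueError(f"file sampled at {fs} Hz, config expects {expected_fs}")
    ts = TrialSet(data=data, ratings=ratings, fs=fs, channel_names=names)
    ts.validate()
    return ts


def load_truth(path) -> tuple[MixingGroundTruth, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            raise FormatError("missing group /truth")
        g = f["truth"]
        truth = MixingGroundTruth(
            A=np.asarray(g["A"]),
            noise_sd=float(g.attrs.get("noise_sd", 0.0)),
            seed=int(g.attrs.get("seed", 0)),
        )
        sources = np.asarray(g["sources"], dtype=float) if "sources" in g else None
    return truth, sources


def save_features(sequences: list[FeatureSequence], path, labels=None) -> None:
    values = np.stack([s.values for s in sequences])
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=values.astype(np.float32))
        f.attrs["feature_names"] = [str(n) for n in sequences[0].feature_names]
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))


def load_features(path) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    with h5py.File(path, "r") as f:
        if "features" not in f:
            raise FormatError("missing dataset /features")
        values = np.asarray(f["features"], dtype=float)
        names = [str(n) for n in f.attrs.get("feature_names", [])]
        labels = np.asarray(f["labels"]) if "labels" in f else None
    return values, names, labels


def save_sae(model: SAEModel, path) -> None:
    with h5py.File(path, "w") as f:
        for i, (W, b) in enumerate(zip(model.weights, model.biases), start=1):
            f.create_dataset(f"W{i}", data=W)
            f.create_dataset(f"b{i}", data=b)
        f.create_dataset("mu", data=model.mu)
        f.create_dataset("sigma", data=model.sigma)
        f.attrs["widths"] = model.widths
        f.attrs["trained"] = model.trained
        if model.seed is not None:
            f.attrs["seed"] = model.seed
        if model.final_adjusted_r2 is not None:
            f.attrs["final_adjusted_r2"] = model.final_adjusted_r2


def load_sae(path) -> SAEModel:
    with h5py.File(path, "r") as f:
        widths = [int(w) for w in f.attrs["widths"]]
        n_layers = 2 * (len(widths) - 1)
        weights = [np.asarray(f[f"W{i}"]) for i in range(1, n_layers + 1)]
        biases = [np.asarray(f[f"b{i}"]) for i in range(1, n_layers + 1)]
        model = SAEModel(
            widths=widths, weights=weights, biases=biases,
            mu=np.asarray(f["mu"]), sigma=np.asarray(f["sigma"]),
            trained=bool(f.attrs.get("trained", False)),
            final_adjusted_r2=float(f.attrs["final_adjusted_r2"])
            if "final_adjusted_r2" in f.attrs else None,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
    return model


def save_classifier(model: TrainedClassifier, path) -> None:
    with h5py.File(path, "w") as f:
        for k, v in model.params.items():
            f.create_dataset(k, data=v)
        if model.feat_mu is not None:
            f.create_dataset("feat_mu", data=model.feat_mu)
            f.create_dataset("feat_sd", data=model.feat_sd)
        s = model.spec
        f.attrs["spec"] = json.dumps({
            "input_dim": s.input_dim, "seq_len": s.seq_len,
            "lstm_hidden": s.lstm_hidden, "fc_units": s.fc_units,
            "output_units": s.output_units, "dropout_lstm": s.dropout_lstm,
            "dropout_fc": s.dropout_fc,
        })
        f.attrs["trained"] = model.trained


def load_classifier(path) -> TrainedClassifier:
    with h5py.File(path, "r") as f:
        spec = ClassifierSpec(**json.loads(f.attrs["spec"]))
        params = {k: np.asarray(f[k]) for k in
                  ("W", "U", "b", "W_fc", "b_fc", "W_out", "b_out")}
        feat_mu = np.asarray(f["feat_mu"]) if "feat_mu" in f else None
        feat_sd = np.asarray(f["feat_sd"]) if "feat_sd" in f else None
        trained = bool(f.attrs.get("trained", False))
    return TrainedClassifier(spec=spec, params=params, feat_mu=feat_mu,
                             feat_sd=feat_sd, trained=trained)


def save_report(report: CVReport, path) -> None:
    """Persist a CV report: JSON next to a per-fold CSV (same stem)."""
    if not report.fold_accuracies:
        raise ValueError("report has no folds")
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2))
    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fold", "accuracy", "test_size"])
        sizes = report.fold_sizes or [None] * len(report.fold_accuracies)
        for i, (acc, n) in enumerate(zip(report.fold_accuracies, sizes)):
            w.writerow([i, repr(acc), n])


def load_report(path) -> CVReport:
    raw = json.loads(Path(path).read_text())
    return CVReport(**raw)


def export_ratings_csv(trials: TrialSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial", "valence", "arousal"])
        for i, (v, a) in enumerate(trials.ratings):
            w.writerow([i, repr(float(v)), repr(float(a))])
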