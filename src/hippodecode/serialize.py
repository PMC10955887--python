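"""Model-directory serialization.

A fitted decoder is written to a directory holding the estimator weights
in their native format (NumPy archives for the GNB/LSTM/CNN, pickle for
the scikit-learn SVM/MLP) plus a ``model.json`` sidecar with the
normalizer statistics, the input contract, the class map, the selected
hyperparameters and the seed, so a streaming process can validate inputs
before decoding.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np

from .decoders import DecoderModel, GnbModel, Normalizer
from .errors import FormatError
from .nn import CNNClassifier, LSTMClassifier

__all__ = ["save_model", "load_model"]

_SKLEARN_KINDS = ("svm", "mlp")


def save_model(model: DecoderModel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": model.kind,
        "contract": model.contract,
        "classes": model.classes.tolist(),
        "best_params": model.best_params,
        "seed": model.seed,
        "window": model.window,
        "normalizer": None
        if model.normalizer is None
        else {"mean": model.normalizer.mean.tolist(), "sd": model.normalizer.sd.tolist()},
        "cv_results": model.cv_results,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    est = model.estimator
    if model.kind == "gnb":
        np.savez(
            directory / "weights.npz",
            classes=est.classes,
            priors=est.priors,
            mu=est.mu,
            sigma=est.sigma,
        )
    elif model.kind in _SKLEARN_KINDS:
        (directory / "weights.pkl").write_bytes(pickle.dumps(est))
    else:  # lstm / cnn: parameter arrays + constructor settings
        np.savez(directory / "weights.npz", **est.params)
        settings = {
            "classes": est.classes_.tolist(),
            "lr": est.lr,
            "epochs": est.epochs,
            "batch_size": est.batch_size,
            "dropout": est.dropout,
            "seed": est.seed,
        }
        if model.kind == "lstm":
            settings["hidden"] = est.hidden
        else:
            settings.update(filters=est.filters, kernel=est.kernel, pool=est.pool)
        (directory / "net.json").write_text(json.dumps(settings))
    return directory


def load_model(directory: str | Path) -> DecoderModel:
    directory = Path(directory)
    meta_path = directory / "model.json"
    if not meta_path.exists():
        raise FormatError(f"{directory}: missing model.json sidecar")
    meta = json.loads(meta_path.read_text())
    kind = meta["kind"]
    if kind == "gnb":
        data = np.load(directory / "weights.npz", allow_pickle=True)
        est = GnbModel(data["classes"], data["priors"], data["mu"], data["sigma"])
    elif kind in _SKLEARN_KINDS:
        est = pickle.loads((directory / "weights.pkl").read_bytes())
    else:
        settings = json.loads((directory / "net.json").read_text())
        classes = np.asarray(settings.pop("classes"))
        cls = LSTMClassifier if kind == "lstm" else CNNClassifier
        est = cls(**settings)
        data = np.load(directory / "weights.npz")
        est.params = {k: data[k] for k in data.files}
        est.classes_ = classes
        if kind == "lstm":
            from .nn import _LSTMLayer

            est.l1 = _LSTMLayer.__new__(_LSTMLayer)
            est.l1.h = settings["hidden"]
            est.l1.prefix = "l1_"
            est.l1.params = est.params
            est.l2 = _LSTMLayer.__new__(_LSTMLayer)
            est.l2.h = settings["hidden"]
            est.l2.prefix = "l2_"
            est.l2.params = est.params
        else:
            t2f = est.params["Wd"].shape[0]
            est._flat_dim = t2f
    norm = meta["normalizer"]
    normalizer = (
        None
        if norm is None
        else Normalizer(np.asarray(norm["mean"]), np.asarray(norm["sd"]))
    )
    return DecoderModel(
        kind=kind,
        estimator=est,
        normalizer=normalizer,
        contract=meta["contract"],
        classes=np.asarray(meta["classes"]),
        cv_results=meta["cv_results"],
        best_params=meta["best_params"],
        seed=meta["seed"],
        window=meta["window"],
    )
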