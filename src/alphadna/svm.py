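"""Radial-kernel SVM over the 25-dimensional interface descriptor.

Defaults follow the published operating point: C = 0.1, gamma = 0.01,
and an asymmetric cost of 0.5 on the DNA-binding (+1) class.  The cost
asymmetry stands in for the historical optimiser's positive-class loss
weighting and is exposed as ``positive_cost_factor``; it is applied as
a per-class weight on C.  Features are used unscaled by default, with
an optional z-standardisation flag for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES

__all__ = ["SvmConfig", "TrainedModel", "train", "predict", "save_model", "load_model"]

N_FEATURES = 25


@dataclass(frozen=True)
class SvmConfig:
    C: float = 0.1
    gamma: float = 0.01
    positive_cost_factor: float = 0.5
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0 or self.positive_cost_factor <= 0:
            raise ValueError("C, gamma and positive_cost_factor must be positive")


@dataclass
class TrainedModel:
    """A fitted radial-kernel SVM plus its configuration snapshot."""

    estimator: Pipeline | SVC
    config: SvmConfig
    feature_fingerprint: tuple[str, ...]

    def predict(self, features) -> tuple[np.ndarray, np.ndarray]:
        x = _validate(features)
        labels = self.estimator.predict(x).astype(int)
        decision = self.estimator.decision_function(x)
        return labels, decision


def _validate(features) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_FEATURES:
        raise ValueError(f"features must be (n, {N_FEATURES}); got {x.shape}")
    if np.isnan(x).any():
        raise ValueError("features contain NaN")
    return x


def train(features, labels, config: SvmConfig = SvmConfig()) -> TrainedModel:
    """Fit the radial-kernel SVM on labelled 25-dim feature vectors.

    Labels are +1 for DNA-binding and -1 for non-binding; both classes
    must be present.  Fitting is deterministic for a fixed seed.
    """
    x = _validate(features)
    y = np.asarray(labels, dtype=int)
    if y.shape != (len(x),):
        raise ValueError("labels must align with feature rows")
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValueError("labels must be +1 / -1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for training")
    svc = SVC(
        kernel="rbf",
        C=config.C,
        gamma=config.gamma,
        class_weight={1: config.positive_cost_factor, -1: 1.0},
        random_state=config.seed,
    )
    est: Pipeline | SVC = svc
    if config.standardize:
        est = Pipeline([("scale", StandardScaler()), ("svc", svc)])
    est.fit(x, y)
    return TrainedModel(estimator=est, config=config, feature_fingerprint=FEATURE_NAMES)


def predict(model: TrainedModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (sign of the decision function) and margins."""
    return model.predict(features)


def save_model(model: TrainedModel, path) -> None:
    payload = {
        "format_version": 1,
        "estimator": model.estimator,
        "config": asdict(model.config),
        "feature_fingerprint": list(model.feature_fingerprint),
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(Path(path))
    if payload.get("format_version") != 1:
        raise ValueError("unsupported model file version")
    if tuple(payload["feature_fingerprint"]) != FEATURE_NAMES:
        raise ValueError("model feature order does not match this package version")
    return TrainedModel(
        estimator=payload["estimator"],
        config=SvmConfig(**payload["config"]),
        feature_fingerprint=tuple(payload["feature_fingerprint"]),
    )
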