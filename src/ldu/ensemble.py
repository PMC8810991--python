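"""Stage one: a deep ensemble of identically trained diagnostic networks.

K fully connected classifiers are trained on the same rows with different
random initializations (no bootstrap resampling); the spread of their
positive-class probabilities carries the epistemic uncertainty that stage
two consumes.  Members are ordinary cross-entropy MLPs and are fit with
scikit-learn; member ``i`` uses seed ``master_seed + i``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .synthetic import FeatureTable

__all__ = [
    "BaseClassifierSpec",
    "EnsembleModel",
    "EnsembleOutput",
    "train_ensemble",
    "predict",
    "majority_diagnosis",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class BaseClassifierSpec:
    """Architecture and training recipe for one ensemble member.

    The reference architecture is a fully connected net with two hidden
    layers; widths default to a desk-scale (32, 32).  Any estimator with a
    ``fit``/``predict_proba`` contract can stand in via ``train_ensemble``'s
    ``member_factory`` hook.
    """

    hidden_layer_sizes: tuple[int, ...] = (32, 32)
    activation: str = "relu"
    epochs: int = 60
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    optimizer: str = "adam"  # "adam" | "sgd"
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if not self.learning_rate > 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if any(w < 1 for w in self.hidden_layer_sizes):
            raise ValueError(f"hidden widths must be >= 1, got {self.hidden_layer_sizes}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"optimizer must be 'adam' or 'sgd', got {self.optimizer!r}")

    def build(self) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=self.hidden_layer_sizes,
            activation=self.activation,
            solver=self.optimizer,
            alpha=self.weight_decay,
            batch_size=self.batch_size,
            learning_rate_init=self.learning_rate,
            max_iter=self.epochs,
            random_state=self.seed,
        )


@dataclass
class EnsembleModel:
    """K trained members plus the metadata needed to reproduce them."""

    members: list
    spec: BaseClassifierSpec
    member_seeds: list[int]
    n_features: int

    @property
    def K(self) -> int:
        return len(self.members)


@dataclass
class EnsembleOutput:
    """Per-patient positive-class probabilities, one column per member."""

    sample_id: np.ndarray  # (n,)
    probs: np.ndarray  # (n, K) in [0, 1]
    member_seeds: list[int]
    label: np.ndarray | None = field(default=None)  # (n,) optional

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be a 2-D (n, K) matrix")
        if self.probs.shape[1] != len(self.member_seeds):
            raise ValueError("probs column count differs from member seed count")
        if self.probs.size and (
            not np.isfinite(self.probs).all()
            or self.probs.min() < 0.0
            or self.probs.max() > 1.0
        ):
            raise ValueError("member probabilities must be finite and lie in [0, 1]")
        if self.K < 2:
            raise ValueError(f"an ensemble needs K >= 2 members, got K={self.K}")

    @property
    def K(self) -> int:
        return int(self.probs.shape[1])

    def __len__(self) -> int:
        return int(self.probs.shape[0])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.probs, columns=[f"p_{k}" for k in range(self.K)]
        )
        frame.insert(0, "sample_id", self.sample_id)
        if self.label is not None:
            frame["label"] = self.label
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnsembleOutput":
        frame = pd.read_csv(path)
        prob_cols = [c for c in frame.columns if c.startswith("p_") and c[2:].isdigit()]
        prob_cols.sort(key=lambda c: int(c[2:]))
        label = frame["label"].to_numpy(dtype=int) if "label" in frame.columns else None
        return cls(
            frame["sample_id"].to_numpy(),
            frame[prob_cols].to_numpy(dtype=float),
            member_seeds=list(range(len(prob_cols))),
            label=label,
        )


def train_ensemble(
    train: FeatureTable,
    spec: BaseClassifierSpec,
    K: int = 50,
    master_seed: int = 0,
    member_factory=None,
) -> EnsembleModel:
    """Fit K members on identical rows, varying only the initialization.

    ``member_factory(spec)`` may supply any object with ``fit(X, y)`` and
    ``predict_proba(X)``; by default members are built from ``spec``.
    """
    if K < 2:
        raise ValueError(f"an ensemble needs K >= 2 members, got K={K}")
    if len(train) == 0:
        raise ValueError("training table is empty")
    classes = np.unique(train.label)
    if classes.size < 2:
        raise ValueError(
            f"training data contains a single class ({classes.tolist()}); "
            "both classes are required"
        )
    factory = member_factory or (lambda s: s.build())
    member_seeds = [master_seed + i for i in range(K)]
    members = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for i, seed in enumerate(member_seeds):
            model = factory(replace(spec, seed=seed))
            model.fit(train.features, train.label)
            loss = getattr(model, "loss_", 0.0)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged for ensemble member {i} (non-finite loss)"
                )
            members.append(model)
    return EnsembleModel(members, spec, member_seeds, train.n_features)


def predict(model: EnsembleModel, data: FeatureTable) -> EnsembleOutput:
    """Positive-class probability of every member on every row."""
    if data.n_features != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.n_features}, "
            f"data has {data.n_features}"
        )
    n = len(data)
    if n == 0:
        probs = np.empty((0, model.K))
    else:
        cols = []
        for member in model.members:
            p = member.predict_proba(data.features)
            positive = list(member.classes_).index(1)
            cols.append(np.clip(p[:, positive], 0.0, 1.0))
        probs = np.column_stack(cols)
    return EnsembleOutput(data.sample_id, probs, list(model.member_seeds), data.label)


def majority_diagnosis(output: EnsembleOutput | np.ndarray) -> np.ndarray:
    """Majority vote over members; per-member vote is prob >= 0.5.

    Vote ties (even K split) go to the positive class.  This is also the
    plain "diagnostic network without defer option" predictor used as the
    reference F1.
    """
    probs = output.probs if isinstance(output, EnsembleOutput) else np.asarray(output, dtype=float)
    probs = np.atleast_2d(probs)
    K = probs.shape[1]
    if K < 2:
        raise ValueError(f"majority vote needs K >= 2 members, got K={K}")
    votes = (probs >= 0.5).sum(axis=1)
    return (2 * votes >= K).astype(int)


def save_ensemble(model: EnsembleModel, directory: str | Path) -> None:
    """Persist members plus a JSON manifest (K, seeds, spec) in one directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "K": model.K,
        "member_seeds": model.member_seeds,
        "n_features": model.n_features,
        "spec": {
            "hidden_layer_sizes": list(model.spec.hidden_layer_sizes),
            "activation": model.spec.activation,
            "epochs": model.spec.epochs,
            "learning_rate": model.spec.learning_rate,
            "weight_decay": model.spec.weight_decay,
            "optimizer": model.spec.optimizer,
            "batch_size": model.spec.batch_size,
            "seed": model.spec.seed,
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for i, member in enumerate(model.members):
        joblib.dump(member, directory / f"member_{i:03d}.joblib")


def load_ensemble(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    raw = dict(manifest["spec"])
    raw["hidden_layer_sizes"] = tuple(raw["hidden_layer_sizes"])
    spec = BaseClassifierSpec(**raw)
    members = [
        joblib.load(directory / f"member_{i:03d}.joblib")
        for i in range(manifest["K"])
    ]
    return EnsembleModel(members, spec, list(manifest["member_seeds"]), manifest["n_features"])
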