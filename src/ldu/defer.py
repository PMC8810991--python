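"""Stage two: the learning-to-defer network and its weighted loss.

The defer network is a fully connected softmax classifier with C + 1 = 3
outputs (class 0, class 1, defer) trained on the K + 2 stage-one features.
No defer labels exist; the cost of deferring to an expert is taken as
constant, so every sample contributes a cross-entropy term toward its true
class and a second cross-entropy term toward the defer output:

    loss(x, target) = alpha * CE(target) + CE(defer)

``alpha`` trades diagnostic coverage against safety: large alpha makes the
target term dominate (defer almost nothing), small alpha makes the defer
term dominate (defer almost everything).  For a sample whose features imply
class confidence q, the loss-minimizing softmax prefers defer exactly when
alpha < 1 / q, so sweeping alpha through (1, 2) moves the deferred set from
"only maximally ambiguous" to "everything".

``alpha_on="defer"`` selects the alternative parameterization
``CE(target) + alpha * CE(defer)``, in which alpha *encourages* deferral as
it grows; the two coincide at alpha = 1 after rescaling.  The default
placement is on the target term so that increasing alpha always discourages
deferral, matching the documented monotone behavior of the method.

The network is implemented directly in numpy (ReLU hidden layers, minibatch
Adam or SGD, He initialization); it is deliberately small and fully
deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import log_softmax, softmax

from .ensemble import BaseClassifierSpec, EnsembleModel, predict, train_ensemble
from .synthetic import FeatureTable
from .uncertainty import build_stage2_features

__all__ = [
    "DEFER",
    "DeferModelSpec",
    "DeferNetwork",
    "TriageResult",
    "defer_loss",
    "train_defer_network",
    "triage",
    "LduPipeline",
    "train_ldu",
    "triage_ldu",
    "save_defer_network",
    "load_defer_network",
]

#: Sentinel stored in ``TriageResult.pred`` for deferred samples.
DEFER = -1

_N_CLASSES = 2
_DEFER_INDEX = _N_CLASSES  # defer is the last of the C + 1 outputs


@dataclass(frozen=True)
class DeferModelSpec:
    """Architecture and training recipe for the defer network.

    Defaults mirror the reference tabular configuration: two hidden layers
    of 100 nodes, 20 epochs of Adam at learning rate 9e-4.
    """

    alpha: float = 1.5
    hidden_layer_sizes: tuple[int, ...] = (100, 100)
    epochs: int = 20
    learning_rate: float = 9e-4
    optimizer: str = "adam"  # "adam" | "sgd"
    batch_size: int = 64
    seed: int = 0
    alpha_on: str = "target"  # "target" | "defer"

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if not self.learning_rate > 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if any(w < 1 for w in self.hidden_layer_sizes):
            raise ValueError(f"hidden widths must be >= 1, got {self.hidden_layer_sizes}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"optimizer must be 'adam' or 'sgd', got {self.optimizer!r}")
        if self.alpha_on not in ("target", "defer"):
            raise ValueError(f"alpha_on must be 'target' or 'defer', got {self.alpha_on!r}")

    @property
    def output_size(self) -> int:
        return _N_CLASSES + 1


def defer_loss(
    scores_row, target: int, alpha: float, alpha_on: str = "target"
) -> float:
    """Weighted defer loss of one raw-score row.

    ``alpha_on="target"`` (default): alpha * CE(target) + CE(defer).
    ``alpha_on="defer"``: CE(target) + alpha * CE(defer).
    CE(j) is the cross entropy -log softmax(scores)[j].
    """
    scores = np.asarray(scores_row, dtype=float)
    if scores.ndim != 1 or scores.shape[0] != _N_CLASSES + 1:
        raise ValueError(f"scores must be a {_N_CLASSES + 1}-vector")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if not 0 <= int(target) < _N_CLASSES:
        raise ValueError(f"target must be a class index in [0, {_N_CLASSES}), got {target}")
    if alpha_on not in ("target", "defer"):
        raise ValueError(f"alpha_on must be 'target' or 'defer', got {alpha_on!r}")
    log_p = log_softmax(scores)
    ce_target = -log_p[int(target)]
    ce_defer = -log_p[_DEFER_INDEX]
    if alpha_on == "target":
        return float(alpha * ce_target + ce_defer)
    return float(ce_target + alpha * ce_defer)


class DeferNetwork:
    """Fully connected ReLU network with a (C + 1)-way softmax head."""

    def __init__(self, n_inputs: int, spec: DeferModelSpec):
        self.n_inputs = int(n_inputs)
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        widths = [self.n_inputs, *spec.hidden_layer_sizes, spec.output_size]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for the ReLU layers
            self.weights.append(scale * rng.standard_normal((fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._rng = rng
        self.loss_curve_: list[float] = []

    # -- forward -----------------------------------------------------------
    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Raw output scores (logits), shape (n, C + 1)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_inputs:
            raise ValueError(
                f"feature width mismatch: model expects {self.n_inputs}, "
                f"got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        a, _ = self._forward(X)
        return a[-1]

    def _forward(self, X: np.ndarray):
        activations = [X]
        pre = []
        h = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            pre.append(z)
            h = z if i == len(self.weights) - 1 else np.maximum(z, 0.0)
            activations.append(h)
        return activations, pre

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, targets: np.ndarray) -> "DeferNetwork":
        spec = self.spec
        X = np.asarray(X, dtype=float)
        y = np.asarray(targets, dtype=int)
        n = X.shape[0]
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"feature width mismatch: model expects {self.n_inputs}, got {X.shape[1]}"
            )
        if n < 2 or np.unique(y).size < 2:
            raise ValueError("training needs >= 2 samples covering both classes")

        # per-sample gradient of the loss w.r.t. logits:
        #   alpha_on=target: (alpha + 1) p - (alpha e_target + e_defer)
        #   alpha_on=defer:  (1 + alpha) p - (e_target + alpha e_defer)
        w_target = spec.alpha if spec.alpha_on == "target" else 1.0
        w_defer = 1.0 if spec.alpha_on == "target" else spec.alpha
        total_w = w_target + w_defer

        adam_m = [np.zeros_like(W) for W in self.weights]
        adam_v = [np.zeros_like(W) for W in self.weights]
        adam_mb = [np.zeros_like(b) for b in self.biases]
        adam_vb = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        batch = min(spec.batch_size, n)
        for epoch in range(spec.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                xb, yb = X[idx], y[idx]
                m = xb.shape[0]
                activations, pre = self._forward(xb)
                logits = activations[-1]
                log_p = log_softmax(logits, axis=1)
                p = np.exp(log_p)
                epoch_loss += float(
                    -(w_target * log_p[np.arange(m), yb]).sum()
                    - (w_defer * log_p[:, _DEFER_INDEX]).sum()
                )

                grad = total_w * p
                grad[np.arange(m), yb] -= w_target
                grad[:, _DEFER_INDEX] -= w_defer
                grad /= m

                # backprop
                delta = grad
                grads_W = [None] * len(self.weights)
                grads_b = [None] * len(self.biases)
                for layer in range(len(self.weights) - 1, -1, -1):
                    grads_W[layer] = activations[layer].T @ delta
                    grads_b[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = (delta @ self.weights[layer].T) * (
                            pre[layer - 1] > 0.0
                        )

                step += 1
                for layer in range(len(self.weights)):
                    if spec.optimizer == "adam":
                        for g, w, mom, vel in (
                            (grads_W[layer], self.weights[layer], adam_m, adam_v),
                            (grads_b[layer], self.biases[layer], adam_mb, adam_vb),
                        ):
                            mom[layer] = beta1 * mom[layer] + (1 - beta1) * g
                            vel[layer] = beta2 * vel[layer] + (1 - beta2) * g * g
                            m_hat = mom[layer] / (1 - beta1**step)
                            v_hat = vel[layer] / (1 - beta2**step)
                            w -= spec.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                    else:
                        self.weights[layer] -= spec.learning_rate * grads_W[layer]
                        self.biases[layer] -= spec.learning_rate * grads_b[layer]

            mean_loss = epoch_loss / n
            if not np.isfinite(mean_loss):
                raise RuntimeError(
                    f"defer-network training diverged at epoch {epoch} "
                    "(non-finite loss)"
                )
            self.loss_curve_.append(mean_loss)
        return self


@dataclass
class TriageResult:
    """Per-patient diagnose-or-defer outcome with provenance.

    ``pred`` holds the predicted class for non-deferred samples and the
    sentinel :data:`DEFER` (-1) for deferred ones; ``scores`` are the
    normalized (C + 1)-way output probabilities where the producing
    algorithm has them (DT rows carry vote-derived scores).
    """

    deferred: np.ndarray  # (n,) bool
    pred: np.ndarray  # (n,) int, DEFER where deferred
    scores: np.ndarray  # (n, 3)
    algorithm: str
    param_name: str
    param_value: float
    sample_id: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.deferred = np.asarray(self.deferred, dtype=bool)
        self.pred = np.asarray(self.pred, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        n = self.deferred.shape[0]
        if self.pred.shape[0] != n or self.scores.shape[0] != n:
            raise ValueError("deferred, pred and scores row counts differ")
        if np.any(self.pred[self.deferred] != DEFER):
            raise ValueError("deferred samples must carry the DEFER sentinel")
        if np.any(~np.isin(self.pred[~self.deferred], (0, 1))):
            raise ValueError("non-deferred predictions must be 0 or 1")

    def __len__(self) -> int:
        return int(self.deferred.shape[0])

    @property
    def defer_rate(self) -> float:
        return float(self.deferred.mean()) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        decision = np.where(self.deferred, "defer", self.pred.astype(str))
        ids = (
            self.sample_id
            if self.sample_id is not None
            else np.arange(len(self)).astype(str)
        )
        return pd.DataFrame(
            {
                "sample_id": ids,
                "decision": decision,
                "score_class0": self.scores[:, 0],
                "score_class1": self.scores[:, 1],
                "score_defer": self.scores[:, 2],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def train_defer_network(
    features: np.ndarray, labels: np.ndarray, spec: DeferModelSpec
) -> DeferNetwork:
    """Fit the defer network on stage-one features; deterministic per seed."""
    features = np.asarray(features, dtype=float)
    net = DeferNetwork(features.shape[1], spec)
    return net.fit(features, labels)


def triage(
    model: DeferNetwork,
    features: np.ndarray,
    sample_id: np.ndarray | None = None,
    algorithm: str = "LDU",
) -> TriageResult:
    """Diagnose-or-defer by argmax over the C + 1 softmax outputs.

    A tie between the defer output and the best class breaks toward defer
    (deferral is the conservative action); a tie between the two classes
    breaks toward the positive class.
    """
    logits = model.decision_scores(np.asarray(features, dtype=float))
    probs = softmax(logits, axis=1)
    class_best = probs[:, :_N_CLASSES].max(axis=1)
    deferred = probs[:, _DEFER_INDEX] >= class_best
    pred = (probs[:, 1] >= probs[:, 0]).astype(int)
    pred[deferred] = DEFER
    return TriageResult(
        deferred=deferred,
        pred=pred,
        scores=probs,
        algorithm=algorithm,
        param_name="alpha",
        param_value=model.spec.alpha,
        sample_id=sample_id,
    )


@dataclass
class LduPipeline:
    """Trained two-stage model: ensemble (stage one) + defer network."""

    ensemble: EnsembleModel
    defer_model: DeferNetwork


def train_ldu(
    train: FeatureTable,
    base_spec: BaseClassifierSpec,
    K: int,
    defer_spec: DeferModelSpec,
    master_seed: int = 0,
    ensemble_model: EnsembleModel | None = None,
) -> LduPipeline:
    """Train both stages on one training table.

    Stage two is fit on the ensemble's probabilities for the same training
    rows (the single-split protocol).  A pre-trained ensemble may be passed
    to share stage one across an alpha sweep.
    """
    model = ensemble_model or train_ensemble(train, base_spec, K, master_seed)
    output = predict(model, train)
    features = build_stage2_features(output)
    defer_model = train_defer_network(features, train.label, defer_spec)
    return LduPipeline(model, defer_model)


def triage_ldu(pipeline: LduPipeline, data: FeatureTable) -> TriageResult:
    output = predict(pipeline.ensemble, data)
    features = build_stage2_features(output)
    return triage(
        pipeline.defer_model, features, sample_id=data.sample_id, algorithm="LDU"
    )


def save_defer_network(model: DeferNetwork, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = model.spec
    manifest = {
        "n_inputs": model.n_inputs,
        "spec": {
            "alpha": spec.alpha,
            "hidden_layer_sizes": list(spec.hidden_layer_sizes),
            "epochs": spec.epochs,
            "learning_rate": spec.learning_rate,
            "optimizer": spec.optimizer,
            "batch_size": spec.batch_size,
            "seed": spec.seed,
            "alpha_on": spec.alpha_on,
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    arrays = {}
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(directory / "weights.npz", **arrays)


def load_defer_network(directory: str | Path) -> DeferNetwork:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    raw = dict(manifest["spec"])
    raw["hidden_layer_sizes"] = tuple(raw["hidden_layer_sizes"])
    net = DeferNetwork(manifest["n_inputs"], DeferModelSpec(**raw))
    with np.load(directory / "weights.npz") as data:
        net.weights = [data[f"W{i}"] for i in range(len(net.weights))]
        net.biases = [data[f"b{i}"] for i in range(len(net.biases))]
    return net
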