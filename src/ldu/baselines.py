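"""Comparison triage algorithms: LD and DT.

* **LD** (learning to defer without uncertainty information): the
  diagnostic architecture with its output widened by one defer class,
  trained end-to-end on the raw features with the same weighted defer loss
  as the two-stage method.  It shares the loss implementation and the
  decision rule with the defer network — one source of truth.
* **DT** (direct triage by uncertainty): no learning at all; every patient
  whose entropy exceeds a threshold (strictly) is deferred, the rest
  receive the ensemble majority diagnosis.  At threshold 0 the deferred set
  is exactly the patients with nonzero entropy, which caps DT's defer rate
  at the fraction of patients with disagreeing members — the mechanism that
  makes DT inapplicable when members are unanimously (even wrongly)
  confident.  Diagnostic entropy is the default measure; ensemble entropy
  is available for the triage-by-continuous-entropy variant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .defer import DEFER, DeferModelSpec, DeferNetwork, TriageResult, triage
from .ensemble import BaseClassifierSpec, EnsembleOutput, majority_diagnosis
from .synthetic import FeatureTable
from .uncertainty import diagnostic_entropy, ensemble_entropy

__all__ = ["DtConfig", "LdModel", "train_ld", "triage_ld", "triage_dt"]


@dataclass(frozen=True)
class DtConfig:
    """Direct-triage settings: which entropy, and the cutoff in nats."""

    threshold: float
    entropy: str = "diagnostic"  # "diagnostic" | "ensemble"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError(f"threshold must be >= 0, got {self.threshold}")
        if self.entropy not in ("diagnostic", "ensemble"):
            raise ValueError(
                f"entropy must be 'diagnostic' or 'ensemble', got {self.entropy!r}"
            )


@dataclass
class LdModel:
    """A single end-to-end classifier-with-defer-output over raw features."""

    network: DeferNetwork
    n_features: int


def train_ld(
    train: FeatureTable,
    base_spec: BaseClassifierSpec,
    alpha: float,
    seed: int = 0,
    defer_spec: DeferModelSpec | None = None,
) -> LdModel:
    """Train the LD baseline.

    Unless overridden via ``defer_spec``, the network reuses the diagnostic
    architecture and training recipe from ``base_spec`` — only the output
    layer is widened by the defer class.
    """
    if len(train) == 0:
        raise ValueError("training table is empty")
    if np.unique(train.label).size < 2:
        raise ValueError("training data contains a single class; both are required")
    if defer_spec is None:
        spec = DeferModelSpec(
            alpha=alpha,
            hidden_layer_sizes=base_spec.hidden_layer_sizes,
            epochs=base_spec.epochs,
            learning_rate=base_spec.learning_rate,
            optimizer=base_spec.optimizer,
            batch_size=base_spec.batch_size,
            seed=seed,
        )
    else:
        spec = replace(defer_spec, alpha=alpha, seed=seed)
    network = DeferNetwork(train.n_features, spec).fit(train.features, train.label)
    return LdModel(network, train.n_features)


def triage_ld(model: LdModel, data: FeatureTable) -> TriageResult:
    result = triage(
        model.network, data.features, sample_id=data.sample_id, algorithm="LD"
    )
    return result


def triage_dt(output: EnsembleOutput, config: DtConfig) -> TriageResult:
    """Defer iff entropy > threshold (strict); classify the rest by majority vote."""
    measure = diagnostic_entropy if config.entropy == "diagnostic" else ensemble_entropy
    u = np.atleast_1d(measure(output.probs))
    deferred = u > config.threshold
    pred = majority_diagnosis(output)
    pred = pred.copy()
    pred[deferred] = DEFER
    # score columns mirror the vote fractions; defer "score" is 1 where deferred
    p1 = (output.probs >= 0.5).mean(axis=1)
    scores = np.column_stack(
        [
            np.where(deferred, 0.0, 1.0 - p1),
            np.where(deferred, 0.0, p1),
            deferred.astype(float),
        ]
    )
    return TriageResult(
        deferred=deferred,
        pred=pred,
        scores=scores,
        algorithm="DT",
        param_name="threshold",
        param_value=config.threshold,
        sample_id=output.sample_id,
    )
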