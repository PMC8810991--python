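"""Evaluation metrics and the alpha / threshold sweep protocol.

Two F1 scores are reported for every triage outcome: ``f1`` on the
non-deferred patients only, and ``f1_overall`` over the entire cohort under
the assumption that every deferred patient receives the correct diagnosis
from the human expert.  Accuracy, sensitivity and specificity are computed
on the non-deferred set.  Degenerate operating points (e.g. everything
deferred) are reported with explicit flags rather than dropped, so sweep
outputs stay rectangular; internal values are always fractions — percent
formatting belongs to the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import DtConfig, train_ld, triage_dt, triage_ld
from .defer import (
    DeferModelSpec,
    TriageResult,
    train_ldu,
    triage,
    triage_ldu,
)
from .ensemble import BaseClassifierSpec, predict, train_ensemble
from .synthetic import FeatureTable
from .uncertainty import build_stage2_features

__all__ = [
    "MetricsRow",
    "SweepRecord",
    "SweepResult",
    "OperatingPoint",
    "compute_metrics",
    "diagnostic_network_f1",
    "sweep",
    "operating_point",
    "records_to_frame",
    "plot_sweep",
]


@dataclass(frozen=True)
class MetricsRow:
    """One triage outcome summarized; NaN plus a flag marks 0/0 metrics."""

    defer_rate: float
    f1: float
    f1_overall: float
    accuracy: float
    sensitivity: float
    specificity: float
    n_non_deferred: int
    flags: tuple[str, ...] = ()


def _safe_div(num: float, den: float, flag: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(flag)
        return math.nan
    return num / den


def _binary_f1(pred: np.ndarray, truth: np.ndarray, flag: str, flags: list[str]) -> float:
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return _safe_div(2 * tp, 2 * tp + fp + fn, flag, flags)


def compute_metrics(triage_result: TriageResult, labels: np.ndarray) -> MetricsRow:
    """Positive-class metrics on the non-deferred set plus the overall F1."""
    labels = np.asarray(labels, dtype=int)
    n = len(triage_result)
    if labels.shape[0] != n:
        raise ValueError(
            f"labels length {labels.shape[0]} does not match triage length {n}"
        )
    if n == 0:
        raise ValueError("cannot compute metrics on an empty triage result")

    flags: list[str] = []
    kept = ~triage_result.deferred
    n_kept = int(kept.sum())
    defer_rate = 1.0 - n_kept / n

    if n_kept == 0:
        flags.append("no_non_deferred")
        f1 = accuracy = sensitivity = specificity = math.nan
    else:
        pred = triage_result.pred[kept]
        truth = labels[kept]
        tp = int(np.sum((pred == 1) & (truth == 1)))
        tn = int(np.sum((pred == 0) & (truth == 0)))
        fp = int(np.sum((pred == 1) & (truth == 0)))
        fn = int(np.sum((pred == 0) & (truth == 1)))
        f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "f1_undefined", flags)
        accuracy = (tp + tn) / n_kept
        sensitivity = _safe_div(tp, tp + fn, "sensitivity_undefined", flags)
        specificity = _safe_div(tn, tn + fp, "specificity_undefined", flags)

    # overall: deferred predictions replaced by the ground truth
    overall_pred = np.where(triage_result.deferred, labels, triage_result.pred)
    f1_overall = _binary_f1(overall_pred, labels, "f1_overall_undefined", flags)

    return MetricsRow(
        defer_rate=defer_rate,
        f1=f1,
        f1_overall=f1_overall,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        n_non_deferred=n_kept,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class SweepRecord:
    """One (algorithm, control value, seed) evaluation."""

    algorithm: str
    param_name: str
    param_value: float
    seed: int
    metrics: MetricsRow


@dataclass
class SweepResult:
    """Sweep records plus the no-defer diagnostic-network reference F1."""

    records: list[SweepRecord]
    diagnostic_f1: dict[int, float] = field(default_factory=dict)

    @property
    def diagnostic_f1_mean(self) -> float:
        return float(np.mean(list(self.diagnostic_f1.values())))


def diagnostic_network_f1(
    train: FeatureTable,
    test: FeatureTable,
    base_spec: BaseClassifierSpec,
    seed: int = 0,
) -> float:
    """F1 of a single diagnostic network (no defer option) on the test split."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    model = replace(base_spec, seed=seed).build()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        model.fit(train.features, train.label)
    pred = model.predict(test.features)
    flags: list[str] = []
    return _binary_f1(np.asarray(pred, dtype=int), test.label, "undefined", flags)


def _seed_plan(seed: int) -> dict[str, int]:
    """All per-run seeds derive from one integer (documented derivation)."""
    base = 1000 * seed
    return {"ensemble": base, "defer": base + 500, "ld": base + 700}


def sweep(
    algorithm: str,
    grid,
    train: FeatureTable,
    test: FeatureTable,
    base_spec: BaseClassifierSpec,
    defer_spec: DeferModelSpec | None = None,
    K: int = 10,
    seeds=(0,),
    dt_entropy: str = "diagnostic",
) -> SweepResult:
    """Evaluate one algorithm across a control-parameter grid.

    ``grid`` holds alpha values for LDU/LD and entropy thresholds for DT.
    One model is trained per grid point (no warm starting); DT reuses one
    ensemble per seed since thresholding needs no training.  The result also
    carries the per-seed diagnostic-network F1 reference.
    """
    algorithm = algorithm.upper()
    if algorithm not in ("LDU", "LD", "DT"):
        raise ValueError(f"algorithm must be LDU, LD or DT, got {algorithm!r}")
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid is empty")
    defer_spec = defer_spec or DeferModelSpec()

    records: list[SweepRecord] = []
    diag_f1: dict[int, float] = {}
    for seed in seeds:
        plan = _seed_plan(seed)
        diag_f1[seed] = diagnostic_network_f1(train, test, base_spec, plan["ensemble"])
        if algorithm in ("LDU", "DT"):
            model = train_ensemble(train, base_spec, K, plan["ensemble"])
            output_test = predict(model, test)
        if algorithm == "LDU":
            features_train = build_stage2_features(predict(model, train))
            features_test = build_stage2_features(output_test)
            for value in grid:
                spec = replace(defer_spec, alpha=float(value), seed=plan["defer"])
                from .defer import train_defer_network

                net = train_defer_network(features_train, train.label, spec)
                result = triage(
                    net, features_test, sample_id=test.sample_id, algorithm="LDU"
                )
                records.append(
                    SweepRecord("LDU", "alpha", float(value), seed,
                                compute_metrics(result, test.label))
                )
        elif algorithm == "LD":
            for value in grid:
                ld = train_ld(train, base_spec, float(value), seed=plan["ld"])
                result = triage_ld(ld, test)
                records.append(
                    SweepRecord("LD", "alpha", float(value), seed,
                                compute_metrics(result, test.label))
                )
        else:  # DT
            for value in grid:
                result = triage_dt(
                    output_test, DtConfig(threshold=float(value), entropy=dt_entropy)
                )
                records.append(
                    SweepRecord("DT", "threshold", float(value), seed,
                                compute_metrics(result, test.label))
                )
    return SweepResult(records, diag_f1)


@dataclass(frozen=True)
class OperatingPoint:
    """The cheapest qualifying sweep record for a target F1, if any."""

    reachable: bool
    record: SweepRecord | None
    target_f1: float

    @property
    def flags(self) -> tuple[str, ...]:
        return () if self.reachable else ("unreachable",)


def operating_point(records, target_f1: float) -> OperatingPoint:
    """Minimum-defer-rate record among those with F1 >= ``target_f1``."""
    records = list(records)
    if not records:
        raise ValueError("no sweep records given")
    qualifying = [
        r
        for r in records
        if not math.isnan(r.metrics.f1) and r.metrics.f1 >= target_f1
    ]
    if not qualifying:
        return OperatingPoint(False, None, target_f1)
    best = min(qualifying, key=lambda r: r.metrics.defer_rate)
    return OperatingPoint(True, best, target_f1)


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        m = r.metrics
        rows.append(
            {
                "algorithm": r.algorithm,
                "param_name": r.param_name,
                "param_value": r.param_value,
                "seed": r.seed,
                "defer_rate": m.defer_rate,
                "f1": m.f1,
                "f1_overall": m.f1_overall,
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "flags": ";".join(m.flags),
            }
        )
    return pd.DataFrame(rows)


def plot_sweep(
    records,
    path: str | Path,
    diagnostic_f1: float | None = None,
    title: str | None = None,
) -> None:
    """F1 / overall-F1 / defer-rate against the control parameter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = records_to_frame(records)
    grouped = (
        frame.groupby(["algorithm", "param_name", "param_value"], as_index=False)
        .mean(numeric_only=True)
        .sort_values("param_value")
    )
    algorithms = grouped["algorithm"].unique()
    fig, axes = plt.subplots(
        1, len(algorithms), figsize=(5 * len(algorithms), 4), squeeze=False
    )
    for ax, algo in zip(axes[0], algorithms):
        sub = grouped[grouped["algorithm"] == algo]
        x = sub["param_value"]
        ax.plot(x, sub["f1"], "r-", label="F1 (non-deferred)")
        ax.plot(x, sub["f1_overall"], "r--", label="F1 overall")
        ax.plot(x, sub["defer_rate"], "b-", label="defer rate")
        if diagnostic_f1 is not None:
            ax.axhline(diagnostic_f1, color="r", ls=":", label="diagnostic net F1")
        ax.set_xlabel(sub["param_name"].iloc[0])
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(algo)
        ax.legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
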