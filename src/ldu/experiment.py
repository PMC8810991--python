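"""End-to-end experiment runner: config validation, seeding, logging.

One YAML config drives the whole pipeline: simulate -> split ->
train ensemble -> uncertainty -> {LDU, LD, DT} sweeps -> metrics tables and
figures.  Every source of randomness derives from the single ``seed`` key,
so re-running with an identical config reproduces every output table
byte-for-byte (the manifest's timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .defer import DeferModelSpec
from .ensemble import BaseClassifierSpec, predict, train_ensemble
from .evaluation import plot_sweep, records_to_frame, sweep
from .synthetic import FeatureTable, GeneratorConfig, generate, split
from .uncertainty import UncertaintyFeatures

__all__ = ["RunConfig", "run_experiment", "load_run_config"]

log = logging.getLogger("ldu")


class ConfigError(ValueError):
    """Raised with the dotted path of the offending config field."""


@dataclass
class RunConfig:
    """Validated experiment configuration (see ``load_run_config``)."""

    data: GeneratorConfig = field(default_factory=GeneratorConfig)
    train_fraction: float = 0.7
    base_spec: BaseClassifierSpec = field(default_factory=BaseClassifierSpec)
    defer_spec: DeferModelSpec = field(default_factory=DeferModelSpec)
    K: int = 10
    ldu_alphas: tuple[float, ...] = (0.5, 0.8, 1.0, 1.2, 1.5, 2.0, 2.5, 3.0)
    ld_alphas: tuple[float, ...] = (0.5, 0.8, 1.0, 1.2, 1.5, 2.0, 2.5, 3.0)
    dt_thresholds: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.5, 0.69)
    seeds: tuple[int, ...] = (0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )
        if self.K < 2:
            raise ConfigError(f"K must be >= 2, got {self.K}")
        for name in ("ldu_alphas", "ld_alphas"):
            values = getattr(self, name)
            if values and min(values) <= 0:
                raise ConfigError(f"{name} must all be > 0, got {values}")
        if self.dt_thresholds and min(self.dt_thresholds) < 0:
            raise ConfigError(
                f"dt_thresholds must all be >= 0, got {self.dt_thresholds}"
            )
        if not self.seeds:
            raise ConfigError("seeds must be non-empty")


def _build_section(cls, raw: dict, path: str):
    try:
        return cls(**raw)
    except TypeError as exc:  # unknown key
        raise ConfigError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_run_config(source: str | Path | dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from YAML (path) or a dict."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    kwargs: dict = {}
    if "data" in raw:
        kwargs["data"] = _build_section(GeneratorConfig, dict(raw.pop("data")), "data")
    if "base_spec" in raw:
        section = dict(raw.pop("base_spec"))
        if "hidden_layer_sizes" in section:
            section["hidden_layer_sizes"] = tuple(section["hidden_layer_sizes"])
        kwargs["base_spec"] = _build_section(BaseClassifierSpec, section, "base_spec")
    if "defer_spec" in raw:
        section = dict(raw.pop("defer_spec"))
        if "hidden_layer_sizes" in section:
            section["hidden_layer_sizes"] = tuple(section["hidden_layer_sizes"])
        kwargs["defer_spec"] = _build_section(DeferModelSpec, section, "defer_spec")
    for key in ("ldu_alphas", "ld_alphas", "dt_thresholds", "seeds"):
        if key in raw:
            kwargs[key] = tuple(raw.pop(key))
    for key in ("train_fraction", "K", "seed"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ConfigError(f"unknown config keys: {sorted(raw)}")
    return _build_section(RunConfig, kwargs, "<root>")


def _config_digest(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.start = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.start
            if exc_type is None:
                log.info("stage %s: done in %.2fs", name, elapsed)
            else:
                log.error("stage %s: FAILED after %.2fs (%s)", name, elapsed, exc)
            return False

    return _Timer()


def run_experiment(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full pipeline and write all tables, figures and a manifest.

    On failure, partial outputs are kept and a ``FAILED`` marker names the
    stage that raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    current = "setup"
    try:
        with _stage("simulate"):
            current = "simulate"
            table = generate(config.data.with_seed(config.seed))
            table.to_csv(out / "cohort.csv")
        with _stage("split"):
            current = "split"
            train, test = split(table, config.train_fraction, config.seed)
            train.to_csv(out / "train.csv")
            test.to_csv(out / "test.csv")
        with _stage("ensemble+uncertainty"):
            current = "ensemble+uncertainty"
            model = train_ensemble(
                train, config.base_spec, config.K, 1000 * config.seed
            )
            output_test = predict(model, test)
            output_test.to_csv(out / "ensemble_test.csv")
            UncertaintyFeatures.from_output(output_test).to_csv(
                out / "uncertainty_test.csv"
            )

        sweeps = {}
        grids = {
            "LDU": config.ldu_alphas,
            "LD": config.ld_alphas,
            "DT": config.dt_thresholds,
        }
        for algo, grid in grids.items():
            if not grid:
                continue
            with _stage(f"sweep-{algo.lower()}"):
                current = f"sweep-{algo.lower()}"
                result = sweep(
                    algo,
                    grid,
                    train,
                    test,
                    config.base_spec,
                    config.defer_spec,
                    K=config.K,
                    seeds=config.seeds,
                )
                sweeps[algo] = result
                records_to_frame(result.records).to_csv(
                    out / f"sweep_{algo.lower()}.csv",
                    index=False,
                    float_format="%.10g",
                )
                plot_sweep(
                    result.records,
                    out / f"sweep_{algo.lower()}.png",
                    diagnostic_f1=result.diagnostic_f1_mean,
                    title=algo,
                )

        with _stage("manifest"):
            current = "manifest"
            diag = {
                algo: result.diagnostic_f1_mean for algo, result in sweeps.items()
            }
            manifest = {
                "config": asdict(config),
                "config_hash": _config_digest(config),
                "seed": config.seed,
                "sweep_seeds": list(config.seeds),
                "diagnostic_network_f1": diag,
                "versions": _versions(),
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, default=list)
            )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={current}\nerror={exc!r}\n")
        raise RuntimeError(f"experiment failed at stage {current!r}: {exc}") from exc
    return out


def _versions() -> dict[str, str]:
    import pandas
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
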