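"""Synthetic binary-diagnosis data with controllable difficulty structure.

The generator emulates the three regimes a deferral method has to cope
with in clinical cohorts:

* ``easy`` — well-separated class-conditional clusters; any reasonable
  classifier gets these right with high confidence.
* ``ambiguous`` — both classes drawn from one shared cluster, so the Bayes
  error inside the region is 0.5; an honest model is maximally uncertain.
* ``overconfident_wrong`` — samples whose features sit inside the easy
  region of the *opposite* class (the label is flipped relative to what the
  features say).  A well-trained ensemble classifies these confidently and
  unanimously wrong, which drives their vote entropy to zero — the regime
  in which entropy-threshold triage is blind.

Each class contributes the same number of rows, mirroring cohorts that are
down-sampled to class balance before modelling.  Subgroup tags are carried
for diagnostics only; models must never see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "GeneratorConfig",
    "FeatureTable",
    "generate",
    "split",
    "SUBGROUPS",
]

SUBGROUPS = ("easy", "ambiguous", "overconfident_wrong")

#: Position of the overconfident-wrong cluster along the inter-centroid
#: axis, as a fraction of the way from the origin to the opposite class's
#: easy centroid.  Slightly below 1 so that mislabeled samples are firmly
#: inside the opposite easy region (unanimous wrong votes) yet leave a
#: small continuous-probability signature a second-stage model can learn.
OCW_POSITION = 0.85


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling plan for one balanced synthetic cohort.

    Parameters
    ----------
    n_per_class:
        Rows generated for each of the two classes.
    n_features:
        Feature dimension.
    easy_fraction, ambiguous_fraction, overconfident_wrong_fraction:
        Per-class subgroup mix; must sum to 1.
    class_separation:
        Euclidean distance between the two easy-region centroids, in
        feature units.
    noise_sd:
        Isotropic Gaussian standard deviation within every region.
    seed:
        RNG seed; generation is fully deterministic given the config.
    """

    n_per_class: int = 1000
    n_features: int = 10
    easy_fraction: float = 0.6
    ambiguous_fraction: float = 0.3
    overconfident_wrong_fraction: float = 0.1
    class_separation: float = 6.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigurationError(
                f"n_per_class must be >= 1, got {self.n_per_class}"
            )
        if self.n_features < 1:
            raise ConfigurationError(
                f"n_features must be >= 1, got {self.n_features}"
            )
        if not self.noise_sd > 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        for name in (
            "easy_fraction",
            "ambiguous_fraction",
            "overconfident_wrong_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        total = (
            self.easy_fraction
            + self.ambiguous_fraction
            + self.overconfident_wrong_fraction
        )
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                "easy_fraction + ambiguous_fraction + "
                f"overconfident_wrong_fraction must equal 1, got {total!r}"
            )

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class FeatureTable:
    """A labeled patient feature matrix.

    ``subgroup`` is present only for synthetic cohorts and exists purely
    for evaluation diagnostics; classifiers and defer models receive only
    ``features``.
    """

    sample_id: np.ndarray  # (n,) str
    features: np.ndarray  # (n, d) float
    label: np.ndarray  # (n,) int in {0, 1}
    subgroup: np.ndarray | None = field(default=None)  # (n,) str or None

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.features = np.asarray(self.features, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        n = len(self.sample_id)
        if self.features.shape[0] != n or self.label.shape[0] != n:
            raise ValueError("sample_id, features and label row counts differ")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values")
        if not np.isin(self.label, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if self.subgroup is not None:
            self.subgroup = np.asarray(self.subgroup, dtype=object)
            if self.subgroup.shape[0] != n:
                raise ValueError("subgroup length differs from row count")

    def __len__(self) -> int:
        return int(self.label.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.features.shape[1])

    def take(self, index: np.ndarray) -> "FeatureTable":
        sub = None if self.subgroup is None else self.subgroup[index]
        return FeatureTable(
            self.sample_id[index], self.features[index], self.label[index], sub
        )

    def to_frame(self) -> pd.DataFrame:
        d = self.n_features
        frame = pd.DataFrame(
            self.features, columns=[f"f{j}" for j in range(d)]
        )
        frame.insert(0, "sample_id", self.sample_id)
        frame["label"] = self.label
        if self.subgroup is not None:
            frame["subgroup"] = self.subgroup
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        feature_cols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
        feature_cols.sort(key=lambda c: int(c[1:]))
        subgroup = (
            frame["subgroup"].to_numpy() if "subgroup" in frame.columns else None
        )
        return cls(
            frame["sample_id"].to_numpy(),
            frame[feature_cols].to_numpy(dtype=float),
            frame["label"].to_numpy(dtype=int),
            subgroup,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))


def _subgroup_counts(config: GeneratorConfig) -> dict[str, int]:
    """Per-class subgroup sizes; largest-remainder so they sum exactly."""
    n = config.n_per_class
    n_easy = int(round(config.easy_fraction * n))
    n_amb = int(round(config.ambiguous_fraction * n))
    n_ocw = n - n_easy - n_amb
    if n_ocw < 0:  # rounding pushed the first two over n
        n_amb += n_ocw
        n_ocw = 0
    return {"easy": n_easy, "ambiguous": n_amb, "overconfident_wrong": n_ocw}


def class_centroid(config: GeneratorConfig, label: int) -> np.ndarray:
    """Easy-region centroid of ``label``; classes sit symmetrically about 0."""
    half = config.class_separation / 2.0 / np.sqrt(config.n_features)
    sign = 1.0 if label == 1 else -1.0
    return np.full(config.n_features, sign * half)


def generate(config: GeneratorConfig) -> FeatureTable:
    """Draw a balanced cohort according to ``config``.

    Deterministic for a fixed config (including seed).  Easy samples of
    class y are drawn around that class's centroid; ambiguous samples of
    both classes share the centroid at the origin; overconfident-wrong
    samples labeled y are drawn near the *opposite* class's centroid
    (scaled by :data:`OCW_POSITION`), i.e. their features are consistent
    with class 1 - y.
    """
    rng = np.random.default_rng(config.seed)
    counts = _subgroup_counts(config)

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    tags: list[np.ndarray] = []
    for y in (0, 1):
        own = class_centroid(config, y)
        opposite = class_centroid(config, 1 - y)
        centers = {
            "easy": own,
            "ambiguous": np.zeros(config.n_features),
            "overconfident_wrong": OCW_POSITION * opposite,
        }
        for name in SUBGROUPS:
            k = counts[name]
            if k == 0:
                continue
            x = centers[name] + config.noise_sd * rng.standard_normal(
                (k, config.n_features)
            )
            blocks.append(x)
            labels.append(np.full(k, y, dtype=int))
            tags.append(np.full(k, name, dtype=object))

    features = np.vstack(blocks)
    label = np.concatenate(labels)
    subgroup = np.concatenate(tags)

    order = rng.permutation(features.shape[0])
    features, label, subgroup = features[order], label[order], subgroup[order]
    width = len(str(features.shape[0] - 1))
    sample_id = np.array(
        [f"s{i:0{width}d}" for i in range(features.shape[0])], dtype=object
    )
    return FeatureTable(sample_id, features, label, subgroup)


def split(
    table: FeatureTable, train_fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split (by label), deterministic per seed."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n = len(table)
    index = np.arange(n)
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty split for n={n}"
        )
    train_idx, test_idx = train_test_split(
        index,
        train_size=n_train,
        random_state=seed,
        shuffle=True,
        stratify=table.label,
    )
    return table.take(np.sort(train_idx)), table.take(np.sort(test_idx))
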