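"""Epistemic-uncertainty measures computed from ensemble probabilities.

Two per-patient quantities, both in nats:

* **ensemble entropy** ``u_e = -sum_k P_k ln P_k`` over the K member
  positive-class probabilities.  Note the P_k do not form a distribution
  over k, so this is a sum of per-member terms rather than a normalized
  entropy; it is implemented in exactly this form because the method is
  defined with it.  A proper per-member alternative,
  :func:`mean_binary_entropy`, is provided under its own name and is not
  the default anywhere.
* **diagnostic entropy** ``u_d = -sum_c P_c ln P_c`` over the class-vote
  fractions (a member votes class 1 iff its probability >= 0.5, the same
  convention as the majority diagnosis).  ``u_d`` is zero exactly when the
  members vote unanimously and is at most ``ln 2`` for binary tasks.

Concatenating the K member probabilities with (u_e, u_d) yields the
(K + 2)-dimensional input of the second-stage defer network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import EnsembleOutput

__all__ = [
    "ensemble_entropy",
    "diagnostic_entropy",
    "mean_binary_entropy",
    "vote_fractions",
    "build_stage2_features",
    "UncertaintyFeatures",
]


def _as_prob_matrix(probs) -> np.ndarray:
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    if not np.isfinite(p).all():
        raise ValueError("member probabilities must be finite")
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("member probabilities must lie in [0, 1]")
    return p


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln p with the 0 * ln 0 = 0 convention, elementwise."""
    out = np.zeros_like(p)
    mask = p > 0.0
    out[mask] = p[mask] * np.log(p[mask])
    return out


def ensemble_entropy(probs) -> np.ndarray | float:
    """-sum_k P_k ln P_k per row, in nats.

    Accepts a single K-vector (returns a float) or an (n, K) matrix
    (returns an (n,) array).
    """
    arr = np.asarray(probs, dtype=float)
    p = _as_prob_matrix(arr)
    u = -_xlogx(p).sum(axis=1)
    return float(u[0]) if arr.ndim == 1 else u


def mean_binary_entropy(probs) -> np.ndarray | float:
    """(1/K) sum_k [-P_k ln P_k - (1-P_k) ln(1-P_k)]: mean per-member
    binary entropy, a normalized alternative to :func:`ensemble_entropy`."""
    arr = np.asarray(probs, dtype=float)
    p = _as_prob_matrix(arr)
    u = -(_xlogx(p) + _xlogx(1.0 - p)).mean(axis=1)
    return float(u[0]) if arr.ndim == 1 else u


def vote_fractions(probs) -> np.ndarray:
    """(n, 2) class-vote fractions (P_0, P_1); vote rule prob >= 0.5 => 1."""
    p = _as_prob_matrix(np.asarray(probs, dtype=float))
    if p.shape[1] < 1:
        raise ValueError("need at least one member probability")
    p1 = (p >= 0.5).mean(axis=1)
    return np.column_stack([1.0 - p1, p1])


def diagnostic_entropy(probs) -> np.ndarray | float:
    """Entropy of the class-vote fractions per row, in nats.

    Zero iff members vote unanimously; at most ln 2 (votes split evenly).
    """
    arr = np.asarray(probs, dtype=float)
    fractions = vote_fractions(arr)
    u = -_xlogx(fractions).sum(axis=1)
    return float(u[0]) if arr.ndim == 1 else u


@dataclass
class UncertaintyFeatures:
    """Per-patient uncertainty summary aligned with an :class:`EnsembleOutput`."""

    sample_id: np.ndarray
    u_e: np.ndarray
    u_d: np.ndarray
    vote_fractions: np.ndarray  # (n, 2)

    @classmethod
    def from_output(cls, output: EnsembleOutput) -> "UncertaintyFeatures":
        return cls(
            sample_id=output.sample_id,
            u_e=np.atleast_1d(ensemble_entropy(output.probs)),
            u_d=np.atleast_1d(diagnostic_entropy(output.probs)),
            vote_fractions=vote_fractions(output.probs),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "u_e": self.u_e,
                "u_d": self.u_d,
                "p_vote_pos": self.vote_fractions[:, 1],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def build_stage2_features(output: EnsembleOutput) -> np.ndarray:
    """(n, K+2) defer-network input: member probabilities, then u_e, u_d."""
    u_e = np.atleast_1d(ensemble_entropy(output.probs))
    u_d = np.atleast_1d(diagnostic_entropy(output.probs))
    return np.column_stack([output.probs, u_e, u_d])
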