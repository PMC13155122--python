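"""Evaluation metrics: proportion RMSE, Jensen-Shannon divergence, cosine.

``rmse`` is the single shared implementation used both for evaluation and as
the L_p training regularizer; it accepts plain arrays or autodiff tensors so
gradients can flow through it during training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Union

import numpy as np

from .autodiff import Tensor


@dataclass
class ProportionMatrix:
    """Spots x cell-types proportions; rows sum to 1 or are exactly zero."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("proportions must be 2-D (spots x types)")
        if np.any(self.values < -1e-12):
            raise ValueError("proportions must be nonnegative")
        sums = self.values.sum(axis=1)
        bad = ~((np.abs(sums - 1) <= 1e-9) | (sums == 0))
        if np.any(bad):
            raise ValueError("each row must sum to 1 (tol 1e-9) or be zero")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_types(self) -> int:
        return self.values.shape[1]


def rmse(p: Union[np.ndarray, Tensor, "ProportionMatrix"],
         q: Union[np.ndarray, Tensor, "ProportionMatrix"]):
    """Root mean square error over all entries of two equal-shape matrices.

    sqrt(mean((p - q)^2)) over spots x cell types; this is both the
    evaluation metric and the proportion regularizer of the training loss.
    """
    if isinstance(p, ProportionMatrix):
        p = p.values
    if isinstance(q, ProportionMatrix):
        q = q.values
    if isinstance(p, Tensor) or isinstance(q, Tensor):
        p = p if isinstance(p, Tensor) else Tensor(p)
        q = q if isinstance(q, Tensor) else Tensor(q)
        if p.shape != q.shape:
            raise ValueError("shape mismatch")
        diff = p - q
        return ((diff * diff).mean()).sqrt()
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((p - q) ** 2)))


def _kl(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P||Q) with the 0*ln 0 := 0 convention (natural log)."""
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


def jsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log, bounded by ln 2).

    JS(P||Q) = 0.5*KL(P||M) + 0.5*KL(Q||M) with M = (P+Q)/2.
    """
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError("shape mismatch")
    if np.any(P < 0) or np.any(Q < 0):
        raise ValueError("inputs must be nonnegative")
    if abs(P.sum() - 1) > 1e-6 or abs(Q.sum() - 1) > 1e-6:
        raise ValueError("inputs must each sum to 1 (tolerance 1e-6)")
    M = (P + Q) / 2
    return 0.5 * _kl(P, M) + 0.5 * _kl(Q, M)


def per_spot_jsd(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise JSD between two proportion matrices.

    Rows are per-spot distributions; a spot where both rows are all-zero
    contributes 0, and a single zero row is handled by the 0*ln 0 convention.
    """
    if isinstance(p, ProportionMatrix):
        p = p.values
    if isinstance(q, ProportionMatrix):
        q = q.values
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("shape mismatch")
    out = np.zeros(p.shape[0])
    for i in range(p.shape[0]):
        pi, qi = p[i], q[i]
        if pi.sum() == 0 and qi.sum() == 0:
            continue
        M = (pi + qi) / 2
        out[i] = 0.5 * _kl(pi, M) + 0.5 * _kl(qi, M)
    return out


def per_spot_cosine(A_recon: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Cosine similarity between matching columns; zero-norm columns score 0."""
    A_recon = np.asarray(A_recon, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if A_recon.shape != Y.shape:
        raise ValueError("shape mismatch")
    na = np.linalg.norm(A_recon, axis=0)
    nb = np.linalg.norm(Y, axis=0)
    denom = na * nb
    out = np.zeros(A_recon.shape[1])
    ok = denom > 0
    out[ok] = (A_recon[:, ok] * Y[:, ok]).sum(axis=0) / denom[ok]
    return out


@dataclass
class EvaluationSummary:
    """Global and per-type agreement between predicted and true proportions."""

    global_rmse: float
    global_jsd: float
    per_type_rmse: np.ndarray
    per_type_jsd: np.ndarray
    per_spot_cosine: np.ndarray

    def to_dict(self) -> dict:
        return {
            "global_rmse": self.global_rmse,
            "global_jsd": self.global_jsd,
            "per_type_rmse": self.per_type_rmse.tolist(),
            "per_type_jsd": self.per_type_jsd.tolist(),
            "per_spot_cosine": self.per_spot_cosine.tolist(),
        }


def per_type_and_global(p: np.ndarray, q: np.ndarray,
                        recon: np.ndarray = None,
                        Y: np.ndarray = None) -> EvaluationSummary:
    """Summarize agreement: column-wise (per-type) RMSE, per-spot JSD
    averaged globally, and optional per-spot reconstruction cosine."""
    if isinstance(p, ProportionMatrix):
        p = p.values
    if isinstance(q, ProportionMatrix):
        q = q.values
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("shape mismatch")
    per_type = np.sqrt(np.mean((p - q) ** 2, axis=0))
    spot_jsd = per_spot_jsd(p, q)
    # per-type JSD: distribution of each type's mass across spots
    n_types = p.shape[1]
    type_jsd = np.zeros(n_types)
    for j in range(n_types):
        pj, qj = p[:, j], q[:, j]
        if pj.sum() > 0 and qj.sum() > 0:
            type_jsd[j] = jsd(pj / pj.sum(), qj / qj.sum())
        elif pj.sum() > 0 or qj.sum() > 0:
            type_jsd[j] = np.log(2.0)
    cos = per_spot_cosine(recon, Y) if recon is not None and Y is not None \
        else np.zeros(p.shape[0])
    return EvaluationSummary(global_rmse=rmse(p, q),
                             global_jsd=float(spot_jsd.mean()),
                             per_type_rmse=per_type,
                             per_type_jsd=type_jsd,
                             per_spot_cosine=cos)
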