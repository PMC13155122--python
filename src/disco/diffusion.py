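"""Discrete two-state diffusion over bipartite-graph edges.

Each edge of the cells x spots assignment graph is an independent two-state
(absent/present) Markov chain.  The forward process flips edges with
probability ``beta_t`` at step t (symmetric doubly stochastic kernel
Q_t = [[1-b, b], [b, 1-b]]), so that after T steps every edge is near the
uniform distribution; the reverse process uses the exact Bayes posterior
q(A_{t-1} | A_t, A_0), with the clean state A_0 supplied either exactly
(simulation/teaching) or as per-edge probabilities from the denoising network
(A0-parameterization).  A strictly increasing subsequence tau of timesteps
supports DDIM-style accelerated sampling with cumulative kernels.

For the symmetric kernel the off-diagonal of the cumulative product Qbar_t is
(1 - prod_{s<=t}(1 - 2*beta_s)) / 2, so mixing to uniform at the horizon
requires prod(1 - 2*beta_t) ~ 0; the default linear schedule (T=1000, beta
from 1e-4 to 0.02) satisfies this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .oracle import AssignmentMatrix

DENOM_EPS = 1e-12


@dataclass
class EdgeCategorical:
    """Per-edge Bernoulli parameters: probability that each edge is present."""

    prob1: np.ndarray

    def __post_init__(self) -> None:
        self.prob1 = np.asarray(self.prob1, dtype=np.float64)
        if np.any(self.prob1 < -1e-9) or np.any(self.prob1 > 1 + 1e-9):
            raise ValueError("edge probabilities must lie in [0, 1]")
        self.prob1 = np.clip(self.prob1, 0.0, 1.0)


@dataclass
class NoiseSchedule:
    """Flip-probability schedule with per-step and cumulative 2x2 kernels.

    Attributes
    ----------
    T : total step count
    betas : (T,) flip probabilities in (0, 0.5]
    Q : (T, 2, 2) per-step kernels, ``Q[t-1]`` is the step-t kernel
    Qbar : (T, 2, 2) cumulative kernels Q_1 ... Q_t
    tau : strictly increasing DDIM subsequence ending at T (1-based steps)
    """

    T: int
    betas: np.ndarray
    Q: np.ndarray
    Qbar: np.ndarray
    tau: np.ndarray

    def qbar(self, t: int) -> np.ndarray:
        """Cumulative kernel Qbar_t; Qbar_0 is the identity."""
        if t == 0:
            return np.eye(2)
        return self.Qbar[t - 1]

    def qbar_between(self, t_lo: int, t_hi: int) -> np.ndarray:
        """Partial cumulative kernel Qbar_{t_lo, t_hi} = Q_{t_lo+1} ... Q_{t_hi}."""
        if not 0 <= t_lo <= t_hi <= self.T:
            raise ValueError("need 0 <= t_lo <= t_hi <= T")
        out = np.eye(2)
        for t in range(t_lo + 1, t_hi + 1):
            out = out @ self.Q[t - 1]
        return out

    def to_json(self) -> str:
        return json.dumps({"T": self.T, "betas": self.betas.tolist(),
                           "tau": self.tau.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "NoiseSchedule":
        obj = json.loads(text)
        sched = _assemble(np.asarray(obj["betas"], dtype=np.float64))
        sched.tau = np.asarray(obj["tau"], dtype=np.int64)
        return sched


def _assemble(betas: np.ndarray, tau: Optional[np.ndarray] = None) -> NoiseSchedule:
    T = len(betas)
    Q = np.empty((T, 2, 2))
    Q[:, 0, 0] = Q[:, 1, 1] = 1.0 - betas
    Q[:, 0, 1] = Q[:, 1, 0] = betas
    Qbar = np.empty_like(Q)
    acc = np.eye(2)
    for t in range(T):
        acc = acc @ Q[t]
        Qbar[t] = acc
    if tau is None:
        tau = np.array([T], dtype=np.int64)
    return NoiseSchedule(T=T, betas=betas, Q=Q, Qbar=Qbar, tau=tau)


def make_schedule(T: int, beta_min: float = 1e-4, beta_max: float = 0.02,
                  kind: str = "linear", tau_count: Optional[int] = None) -> NoiseSchedule:
    """Build a noise schedule with monotone betas and a DDIM subsequence.

    ``tau`` holds ``tau_count`` evenly spaced integer steps ending at T
    (defaults to all T steps).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0 < beta_min <= beta_max <= 0.5) and not (beta_min == beta_max == 0.0 and T == 1):
        raise ValueError("need 0 < beta_min <= beta_max <= 0.5")
    if kind == "linear":
        betas = np.linspace(beta_min, beta_max, T)
    elif kind == "cosine":
        # smooth ramp between the same endpoints; still monotone, <= 0.5
        x = np.linspace(0.0, np.pi, T)
        betas = beta_min + (beta_max - beta_min) * (1 - np.cos(x)) / 2
    else:
        raise ValueError("kind must be 'linear' or 'cosine'")
    if tau_count is None:
        tau_count = T
    if not 1 <= tau_count <= T:
        raise ValueError("tau_count must be in 1..T")
    tau = np.unique(np.round(np.linspace(T / tau_count, T, tau_count)).astype(np.int64))
    tau = tau[tau >= 1]
    if tau[-1] != T:
        tau = np.append(tau, T)
    return _assemble(betas, tau)


def _as_binary(A: Union[np.ndarray, AssignmentMatrix]) -> np.ndarray:
    if isinstance(A, AssignmentMatrix):
        return A.entries
    return np.asarray(A, dtype=np.float64)


def forward_marginal(A0: Union[np.ndarray, AssignmentMatrix], t: int,
                     sched: NoiseSchedule) -> EdgeCategorical:
    """q(A_t | A_0) per edge: prob1 = Qbar_t[1,1] if edge set else Qbar_t[0,1]."""
    if not 1 <= t <= sched.T:
        raise ValueError("t out of range 1..T")
    A0 = _as_binary(A0)
    Qb = sched.qbar(t)
    prob1 = np.where(A0 > 0.5, Qb[1, 1], Qb[0, 1])
    return EdgeCategorical(prob1)


def sample_state(cat: EdgeCategorical, seed: int) -> np.ndarray:
    """Independent Bernoulli draw per edge (deterministic given seed)."""
    rng = np.random.default_rng(seed)
    return (rng.random(cat.prob1.shape) < cat.prob1).astype(np.float64)


def _posterior_kernel(At: np.ndarray, A0_prob1: np.ndarray,
                      K_step: np.ndarray, Qbar_prev: np.ndarray,
                      Qbar_now: np.ndarray) -> np.ndarray:
    """Closed-form per-edge posterior over the intermediate state.

    K_step is the kernel carrying the intermediate state to the observed one
    (single-step Q_t or cumulative Qbar_{tau_{i-1}, tau_i}); Qbar_prev and
    Qbar_now are the cumulative kernels to the intermediate and observed
    steps.  A0 may be soft (per-edge probability of state 1): because the
    Bayes numerator and denominator are both linear in the A0 one-hot row,
    plugging probabilities in is exact for the A0-parameterized reverse step.
    """
    a0_1 = A0_prob1
    a0_0 = 1.0 - a0_1
    # marginal of the intermediate state s given (soft) A0
    m0 = a0_0 * Qbar_prev[0, 0] + a0_1 * Qbar_prev[1, 0]
    m1 = a0_0 * Qbar_prev[0, 1] + a0_1 * Qbar_prev[1, 1]
    at = At > 0.5
    # likelihood of the observed state under each intermediate state
    lik0 = np.where(at, K_step[0, 1], K_step[0, 0])
    lik1 = np.where(at, K_step[1, 1], K_step[1, 0])
    num0 = lik0 * m0
    num1 = lik1 * m1
    denom = np.maximum(num0 + num1, DENOM_EPS)
    return num1 / denom


def posterior(At: Union[np.ndarray, AssignmentMatrix],
              A0: Union[np.ndarray, AssignmentMatrix, EdgeCategorical],
              t: int, sched: NoiseSchedule) -> EdgeCategorical:
    """Exact reverse posterior q(A_{t-1} | A_t, A_0) per edge (Bayes).

    A0 may be binary or an :class:`EdgeCategorical` of predicted edge
    probabilities (A0-parameterization).  Requires t >= 2; the t = 1 endpoint
    reads the predicted A_0 distribution out directly.
    """
    if not 2 <= t <= sched.T:
        raise ValueError("posterior requires 2 <= t <= T")
    At = _as_binary(At)
    a0 = A0.prob1 if isinstance(A0, EdgeCategorical) else _as_binary(A0)
    prob1 = _posterior_kernel(At, a0, sched.Q[t - 1], sched.qbar(t - 1),
                              sched.qbar(t))
    return EdgeCategorical(prob1)


def ddim_posterior(A_tau_i: Union[np.ndarray, AssignmentMatrix],
                   A0: Union[np.ndarray, AssignmentMatrix, EdgeCategorical],
                   i: int, sched: NoiseSchedule) -> EdgeCategorical:
    """Accelerated posterior q(A_{tau_{i-1}} | A_{tau_i}, A_0).

    ``i`` indexes the DDIM subsequence (1-based, 2 <= i <= K); the single-step
    kernel is replaced by the cumulative kernel over (tau_{i-1}, tau_i].
    """
    K = len(sched.tau)
    if not 2 <= i <= K:
        raise ValueError("subsequence index i must be in 2..K")
    t_lo = int(sched.tau[i - 2])
    t_hi = int(sched.tau[i - 1])
    At = _as_binary(A_tau_i)
    a0 = A0.prob1 if isinstance(A0, EdgeCategorical) else _as_binary(A0)
    prob1 = _posterior_kernel(At, a0, sched.qbar_between(t_lo, t_hi),
                              sched.qbar(t_lo), sched.qbar(t_hi))
    return EdgeCategorical(prob1)
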