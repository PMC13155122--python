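"""Training objective and loops for the diffusion deconvolution solver.

The composite loss is

    L = L_dpmm + lambda1 * L_p + lambda2 * L_f + lambda3 * L_d

where L_dpmm is the per-edge cross-entropy of the predicted clean assignment
(the variational bound of the discrete diffusion model collapses to this under
the A0-parameterization), L_p is the RMSE between soft predicted and true
cell-type proportions, L_f pushes edge probabilities toward {0,1}, and L_d is
the KL divergence between the predicted per-spot cell-mass distribution and
the uniform one.  The three regularizers act on the *soft* predicted edge
probabilities so the whole objective is differentiable.

Cell-type labels enter only through L_p; the network inputs remain label-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .autodiff import Adam, Tensor
from .bgnn import BGNNConfig, DenoiserParams, forward_soft, predict_A0
from .diffusion import (EdgeCategorical, NoiseSchedule, forward_marginal,
                        make_schedule, sample_state, ddim_posterior)
from .metrics import ProportionMatrix, per_spot_cosine, rmse
from .oracle import AssignmentMatrix, OracleCorpus, OracleInstance, \
    add_expression_noise, shuffle_genes

LOG_EPS = 1e-12

# L_p and the evaluation RMSE are one shared implementation
loss_p = rmse


@dataclass
class LossWeights:
    """Weights of the three deconvolution regularizers (default: all 1)."""

    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class TrainConfig:
    """Pretraining knobs.

    ``beta_min``/``beta_max`` must give a mixing schedule for the chosen T
    (prod(1 - 2*beta_t) ~ 0); the defaults match the T = 1000 horizon.
    ``batch_size`` counts instances accumulated per parameter update.
    """

    epochs: int = 10
    batch_size: int = 1
    learning_rate: float = 2e-4
    T: int = 1000
    beta_min: float = 1e-4
    beta_max: float = 0.02
    noise_level: float = 0.1
    gene_shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.T < 1:
            raise ValueError("epochs/batch_size/T out of range")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class FineTuneConfig:
    """Unsupervised adaptation of the decoder only (the starred variant)."""

    learning_rate: float = 1e-4
    epochs: int = 30
    ddim_steps: int = 10
    T: int = 1000
    seed: int = 0
    schedule: Optional[NoiseSchedule] = None


# ---------------------------------------------------------------------------
# loss components (each accepts plain arrays or autodiff tensors)
# ---------------------------------------------------------------------------

def _prob1_of(pred) -> Union[np.ndarray, Tensor]:
    if isinstance(pred, EdgeCategorical):
        return pred.prob1
    return pred


def loss_dpmm(pred, A0: Union[np.ndarray, AssignmentMatrix]) -> Union[float, Tensor]:
    """Mean per-edge negative log-likelihood of the true clean state."""
    prob1 = _prob1_of(pred)
    A0 = A0.entries if isinstance(A0, AssignmentMatrix) else np.asarray(A0, dtype=np.float64)
    if isinstance(prob1, Tensor):
        if prob1.shape != A0.shape:
            raise ValueError("shape mismatch")
        p_true = prob1 * A0 + (1.0 - prob1) * (1.0 - A0)
        return -(p_true.clip_min(LOG_EPS).log().mean())
    prob1 = np.asarray(prob1, dtype=np.float64)
    if prob1.shape != A0.shape:
        raise ValueError("shape mismatch")
    p_true = np.where(A0 > 0.5, prob1, 1.0 - prob1)
    return float(-np.mean(np.log(np.maximum(p_true, LOG_EPS))))


def soft_proportions(pred_prob1, cell_types: np.ndarray, n_types: int):
    """Soft cell-type proportions implied by edge probabilities.

    N_ij = sum over cells of type j of prob1(cell, spot i); q_ij = N_ij / N_i.
    Returns a :class:`ProportionMatrix` for array input, a Tensor (spots x
    types) for autodiff input.  Spots with zero soft mass get a zero row.
    """
    cell_types = np.asarray(cell_types, dtype=np.int64)
    if cell_types.min() < 0 or cell_types.max() >= n_types:
        raise ValueError("cell type labels must lie in 0..n_types-1")
    indicator = np.zeros((n_types, len(cell_types)))
    indicator[cell_types, np.arange(len(cell_types))] = 1.0
    if isinstance(pred_prob1, Tensor):
        counts = Tensor(indicator) @ pred_prob1          # types x spots
        counts = counts.swapaxes(0, 1)                   # spots x types
        totals = counts.sum(axis=1, keepdims=True).clip_min(LOG_EPS)
        return counts / totals
    prob1 = np.asarray(pred_prob1, dtype=np.float64)
    counts = (indicator @ prob1).T
    totals = counts.sum(axis=1, keepdims=True)
    q = np.divide(counts, totals, out=np.zeros_like(counts),
                  where=totals > 0)
    return ProportionMatrix(q)


def loss_f(A_soft) -> Union[float, Tensor]:
    """Binarization penalty: mean of A - A^2 (zero iff the matrix is 0/1)."""
    if isinstance(A_soft, Tensor):
        return (A_soft - A_soft * A_soft).mean()
    A = np.asarray(A_soft, dtype=np.float64)
    if np.any(A < 0) or np.any(A > 1):
        raise ValueError("entries must lie in [0, 1]")
    return float(np.mean(A - A ** 2))


def loss_d(A_soft, N_c: Optional[int] = None,
           N_s: Optional[int] = None) -> Union[float, Tensor]:
    """Density penalty: KL(column-mass distribution || uniform over spots).

    The empirical column-mass vector A^T 1 / N_c is renormalized to sum 1;
    0*ln 0 := 0.  An all-zero matrix is treated as uniform (KL = 0) with a
    warning.
    """
    if isinstance(A_soft, Tensor):
        n_s = A_soft.shape[1]
        mass = A_soft.sum(axis=0)
        total = mass.sum().clip_min(LOG_EPS)
        w = mass / total
        # sum w * log(w * n_s); clip keeps the log finite, 0*log0 -> 0
        return (w * (w * float(n_s)).clip_min(LOG_EPS).log()).sum()
    A = np.asarray(A_soft, dtype=np.float64)
    if np.any(A.sum(axis=0) < 0):
        raise ValueError("column sums must be nonnegative")
    n_s = A.shape[1]
    mass = A.sum(axis=0)
    total = mass.sum()
    if total == 0:
        warnings.warn("all-zero matrix in loss_d; defining KL(uniform,uniform)=0")
        return 0.0
    w = mass / total
    nz = w > 0
    return float(np.sum(w[nz] * np.log(w[nz] * n_s)))


def total_loss(parts: Sequence, weights: LossWeights):
    """L = L_dpmm + lambda1 L_p + lambda2 L_f + lambda3 L_d."""
    dpmm, lp, lf, ld = parts
    return dpmm + weights.lambda1 * lp + weights.lambda2 * lf \
        + weights.lambda3 * ld


def true_proportions(assignment: AssignmentMatrix, cell_types: np.ndarray,
                     n_types: int) -> ProportionMatrix:
    """Hard per-spot proportions implied by a feasible assignment."""
    return soft_proportions(assignment.entries, cell_types, n_types)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _instance_loss(inst: OracleInstance, Y: np.ndarray, t: int,
                   At: np.ndarray, params: DenoiserParams,
                   weights: LossWeights) -> Tuple[Tensor, Dict[str, float]]:
    A0 = inst.assignment.entries
    probs = forward_soft(inst.cells.expr, Y, At, t, params)
    prob1 = probs[..., 1]
    l_dpmm = loss_dpmm(prob1, A0)
    n_types = inst.cells.n_types
    p_true = true_proportions(inst.assignment, inst.cells.cell_types, n_types)
    q_soft = soft_proportions(prob1, inst.cells.cell_types, n_types)
    l_p = loss_p(Tensor(p_true.values), q_soft)
    l_f = loss_f(prob1)
    l_d = loss_d(prob1)
    total = total_loss((l_dpmm, l_p, l_f, l_d), weights)
    parts = {"dpmm": float(l_dpmm.data), "p": float(l_p.data),
             "f": float(l_f.data), "d": float(l_d.data),
             "total": float(total.data)}
    return total, parts


def train(corpus: OracleCorpus, model_config: Optional[BGNNConfig] = None,
          train_config: Optional[TrainConfig] = None,
          weights: Optional[LossWeights] = None,
          init_params: Optional[DenoiserParams] = None,
          max_steps: Optional[int] = None,
          ) -> Tuple[DenoiserParams, List[Dict[str, float]]]:
    """Train the denoiser on an oracle corpus.

    Per step: draw the next training instance, optionally shuffle its genes
    and add multiplicative noise to Y, draw t uniformly in 1..T, sample A_t
    from the forward marginal, run the network, and take an Adam step on the
    composite loss.  One instance per optimizer step unless ``batch_size``
    accumulates gradients over several.  Deterministic for a fixed seed.

    Returns the trained parameters and a per-epoch history of mean loss
    components on the train and validation splits.
    """
    train_config = train_config or TrainConfig()
    weights = weights or LossWeights()
    if init_params is not None:
        params = init_params.copy()
    else:
        params = DenoiserParams.init(model_config or BGNNConfig(),
                                     seed=train_config.seed)
    instances = corpus.train
    if not instances:
        raise ValueError("corpus has no training instances")
    sched = make_schedule(train_config.T, train_config.beta_min,
                          train_config.beta_max)
    rng = np.random.default_rng(train_config.seed)
    opt = Adam(params.blocks, lr=train_config.learning_rate)
    history: List[Dict[str, float]] = []
    step = 0  # one step = one parameter update (batch_size instances)
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(instances))
        sums: Dict[str, float] = {}
        n_seen = 0
        opt.zero_grad()
        in_batch = 0
        for idx in order:
            if max_steps is not None and step >= max_steps:
                break
            inst = instances[idx]
            if train_config.gene_shuffle:
                inst = shuffle_genes(inst, seed=int(rng.integers(2 ** 31)))
            Y = add_expression_noise(inst.spots_expr, train_config.noise_level,
                                     seed=int(rng.integers(2 ** 31)))
            t = int(rng.integers(1, train_config.T + 1))
            At = sample_state(forward_marginal(inst.assignment, t, sched),
                              seed=int(rng.integers(2 ** 31)))
            total, parts = _instance_loss(inst, Y, t, At, params, weights)
            if not np.isfinite(parts["total"]):
                raise FloatingPointError(
                    f"training diverged at step {step}: loss={parts['total']}")
            total.backward(np.asarray(1.0 / train_config.batch_size))
            in_batch += 1
            if in_batch == train_config.batch_size:
                opt.step()
                opt.zero_grad()
                in_batch = 0
                step += 1
            for k, val in parts.items():
                sums[k] = sums.get(k, 0.0) + val
            n_seen += 1
        if in_batch:
            opt.step()
            opt.zero_grad()
            step += 1
        if n_seen:
            rec = {"epoch": epoch, "split": "train", "steps": step}
            rec.update({k: v / n_seen for k, v in sums.items()})
            history.append(rec)
        val = _evaluate_split(corpus.validation, params, weights, sched, rng)
        if val is not None:
            val.update({"epoch": epoch, "split": "validation", "steps": step})
            history.append(val)
        if max_steps is not None and step >= max_steps:
            break
    return params, history


def _evaluate_split(instances, params, weights, sched, rng,
                    limit: int = 5) -> Optional[Dict[str, float]]:
    if not instances:
        return None
    sums: Dict[str, float] = {}
    subset = instances[:limit]
    for inst in subset:
        t = int(rng.integers(1, sched.T + 1))
        At = sample_state(forward_marginal(inst.assignment, t, sched),
                          seed=int(rng.integers(2 ** 31)))
        _, parts = _instance_loss(inst, inst.spots_expr, t, At, params, weights)
        for k, v in parts.items():
            sums[k] = sums.get(k, 0.0) + v
    return {k: v / len(subset) for k, v in sums.items()}


# ---------------------------------------------------------------------------
# fine-tuning (decoder only, reconstruction-cosine objective)
# ---------------------------------------------------------------------------

def _ddim_rollout_state(X: np.ndarray, Y: np.ndarray, params: DenoiserParams,
                        sched: NoiseSchedule, rng: np.random.Generator) -> Tuple[np.ndarray, int]:
    """Sample the reverse chain down to the last retained step (no gradients).

    Returns the binary state at tau_1 and tau_1 itself.
    """
    n_c = X.shape[1]
    n_s = Y.shape[1]
    A = (rng.random((n_c, n_s)) < 0.5).astype(np.float64)
    K = len(sched.tau)
    for i in range(K, 1, -1):
        t = int(sched.tau[i - 1])
        pred = predict_A0(A, X, Y, t, params)
        post = ddim_posterior(A, pred, i, sched)
        A = sample_state(post, seed=int(rng.integers(2 ** 31)))
    return A, int(sched.tau[0])


def fine_tune(params: DenoiserParams, X: np.ndarray, Y: np.ndarray,
              config: Optional[FineTuneConfig] = None) -> DenoiserParams:
    """Adapt only the decoder to a new dataset (the starred model variant).

    Each epoch: run a short DDIM rollout to the last retained step without
    gradients, make the final soft prediction with gradients, reconstruct
    spot profiles as X @ A_soft, and descend the negative mean per-spot
    cosine similarity to Y.  Spots with zero-norm observed profiles are
    excluded from the mean.  All non-decoder blocks are left untouched.
    """
    config = config or FineTuneConfig()
    params = params.copy()
    sched = config.schedule or make_schedule(config.T,
                                             tau_count=config.ddim_steps)
    rng = np.random.default_rng(config.seed)
    decoder = params.decoder_block_names()
    opt = Adam(params.blocks, lr=config.learning_rate)
    y_norm = np.linalg.norm(Y, axis=0)
    ok = y_norm > 0
    if not np.any(ok):
        raise ValueError("all spot profiles have zero norm")
    mask = ok.astype(np.float64)
    Yt = np.asarray(Y, dtype=np.float64)
    for _ in range(config.epochs):
        A1, t1 = _ddim_rollout_state(X, Y, params, sched, rng)
        probs = forward_soft(X, Y, A1, t1, params)
        prob1 = probs[..., 1]
        recon = Tensor(np.asarray(X, dtype=np.float64)) @ prob1
        dots = (recon * Yt).sum(axis=0)
        rnorm = (recon * recon).sum(axis=0).clip_min(1e-24).sqrt()
        cos = dots / (rnorm * np.maximum(y_norm, 1e-12))
        mean_cos = (cos * mask).sum() * (1.0 / mask.sum())
        loss = -mean_cos
        opt.zero_grad()
        loss.backward()
        opt.step(only=decoder)
    return params


def reconstruction_cosine(params: DenoiserParams, X: np.ndarray,
                          Y: np.ndarray, sched: NoiseSchedule,
                          seed: int = 0) -> float:
    """Mean per-spot cosine between X @ A_soft and Y after a DDIM rollout."""
    rng = np.random.default_rng(seed)
    A1, t1 = _ddim_rollout_state(X, Y, params, sched, rng)
    pred = predict_A0(A1, X, Y, t1, params)
    recon = np.asarray(X, dtype=np.float64) @ pred.prob1
    cos = per_spot_cosine(recon, np.asarray(Y, dtype=np.float64))
    ok = np.linalg.norm(Y, axis=0) > 0
    return float(cos[ok].mean())
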