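"""Deconvolution of a new (X, Y) pair with a trained denoiser.

The pipeline is: harmonize genes between reference and spatial data, sample an
initial assignment graph from the uniform prior, run the accelerated reverse
diffusion guided by (X, Y), decode the final soft prediction into a feasible
assignment (one spot per cell), and derive cell-type proportions, the
reconstructed spot profiles and per-spot cosine diagnostics.  Repeated
sampling plus a percentile bootstrap yields per-(spot, type) confidence
intervals for the proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .bgnn import DenoiserParams, predict_A0
from .diffusion import (EdgeCategorical, NoiseSchedule, ddim_posterior,
                        sample_state)
from .metrics import ProportionMatrix, per_spot_cosine
from .oracle import AssignmentMatrix
from .training import soft_proportions


@dataclass
class GenePlan:
    """Record of how genes were harmonized between reference and spots."""

    shared_ids: List[str]
    d: int
    mode: str  # "hvg_top{capacity}" or "first_d_weights"


@dataclass
class TrajectoryFrame:
    """Reverse-diffusion snapshot: retained step, soft proportions, cosine."""

    t: int
    proportions: np.ndarray
    per_spot_cosine: np.ndarray


@dataclass
class DeconvolutionResult:
    assignment: AssignmentMatrix
    proportions: ProportionMatrix
    reconstruction: np.ndarray
    per_spot_cosine: np.ndarray
    trajectory: Optional[List[TrajectoryFrame]] = None


@dataclass
class UncertaintyReport:
    """Bootstrap summary of repeated deconvolution runs."""

    mean: np.ndarray
    std: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_repeats: int
    n_bootstrap: int
    alpha: float

    @property
    def n_intervals(self) -> int:
        return int(self.mean.size)


def harmonize_genes(X: np.ndarray, Y: np.ndarray,
                    gene_ids_x: Sequence[str], gene_ids_y: Sequence[str],
                    capacity: int = 2000) -> Tuple[np.ndarray, np.ndarray, GenePlan]:
    """Intersect gene lists (X order) and cap at the embedding capacity.

    If the shared count d reaches ``capacity``, the top-``capacity`` highly
    variable genes (variance/mean dispersion of log1p pooled data) are kept;
    otherwise all d genes are kept and the model will use the first d rows of
    its embedding weights.
    """
    gene_ids_x = list(gene_ids_x)
    gene_ids_y = list(gene_ids_y)
    pos_y = {g: i for i, g in enumerate(gene_ids_y)}
    shared = [g for g in gene_ids_x if g in pos_y]
    if not shared:
        raise ValueError("no shared genes between reference and spots")
    ix = [gene_ids_x.index(g) for g in shared]
    iy = [pos_y[g] for g in shared]
    Xs = np.asarray(X, dtype=np.float64)[ix]
    Ys = np.asarray(Y, dtype=np.float64)[iy]
    d = len(shared)
    if d >= capacity:
        pooled = np.log1p(np.concatenate([Xs, Ys], axis=1))
        mean = pooled.mean(axis=1)
        var = pooled.var(axis=1)
        dispersion = np.divide(var, mean, out=np.zeros_like(var),
                               where=mean > 0)
        keep = np.sort(np.argsort(-dispersion, kind="stable")[:capacity])
        shared = [shared[i] for i in keep]
        Xs, Ys = Xs[keep], Ys[keep]
        plan = GenePlan(shared_ids=shared, d=capacity,
                        mode=f"hvg_top{capacity}")
    else:
        plan = GenePlan(shared_ids=shared, d=d, mode="first_d_weights")
    return Xs, Ys, plan


def decode_assignment(soft: EdgeCategorical) -> AssignmentMatrix:
    """Project soft edge probabilities onto the feasible space.

    Each cell is placed at the spot with maximal edge probability; ties break
    to the lowest spot index, so the output is always feasible.
    """
    best = soft.prob1.argmax(axis=1)  # argmax takes the first maximum
    entries = np.zeros_like(soft.prob1)
    entries[np.arange(soft.prob1.shape[0]), best] = 1.0
    return AssignmentMatrix(entries).require_feasible()


def proportions_from_assignment(A: AssignmentMatrix, cell_types: np.ndarray,
                                n_types: int) -> ProportionMatrix:
    """Hard count-based proportions per spot; empty spots get zero rows."""
    A.require_feasible()
    return soft_proportions(A.entries, cell_types, n_types)


def reconstruct_and_score(X: np.ndarray, A: AssignmentMatrix,
                          Y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Reconstruction X @ A and per-spot cosine similarity against Y."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != A.n_cells:
        raise ValueError("cell-count mismatch between X and A")
    recon = X @ A.entries
    return recon, per_spot_cosine(recon, np.asarray(Y, dtype=np.float64))


def deconvolve(X: np.ndarray, Y: np.ndarray, params: DenoiserParams,
               sched: NoiseSchedule, seed: int = 0,
               cell_types: Optional[np.ndarray] = None,
               n_types: Optional[int] = None,
               capture_trajectory: bool = False) -> DeconvolutionResult:
    """Sample one approximate assignment by reverse diffusion.

    Starts from a uniform random binary graph at t = T, iterates DDIM
    posterior sampling down the retained subsequence with the network's
    predicted clean state at each step, and reads out the predicted A_0
    distribution at the last retained step (the A0-parameterization
    endpoint).  ``cell_types`` are only needed for proportion output and the
    trajectory; the network itself never sees them.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    rng = np.random.default_rng(seed)
    n_c, n_s = X.shape[1], Y.shape[1]
    A = (rng.random((n_c, n_s)) < 0.5).astype(np.float64)
    K = len(sched.tau)
    trajectory: Optional[List[TrajectoryFrame]] = [] if capture_trajectory else None
    want_props = cell_types is not None and n_types is not None

    def _frame(t: int, soft: EdgeCategorical) -> TrajectoryFrame:
        props = soft_proportions(soft.prob1, cell_types, n_types).values \
            if want_props else np.zeros((n_s, 0))
        recon = X @ soft.prob1
        return TrajectoryFrame(t=t, proportions=props,
                               per_spot_cosine=per_spot_cosine(recon, Y))

    pred = None
    for i in range(K, 1, -1):
        t = int(sched.tau[i - 1])
        pred = predict_A0(A, X, Y, t, params)
        if trajectory is not None:
            trajectory.append(_frame(t, pred))
        post = ddim_posterior(A, pred, i, sched)
        A = sample_state(post, seed=int(rng.integers(2 ** 31)))
    t1 = int(sched.tau[0])
    pred = predict_A0(A, X, Y, t1, params)
    assignment = decode_assignment(pred)
    recon, cos = reconstruct_and_score(X, assignment, Y)
    if want_props:
        props = proportions_from_assignment(assignment, cell_types, n_types)
    else:
        props = ProportionMatrix(np.zeros((n_s, 1)))  # placeholder, no labels
    if trajectory is not None:
        # final frame mirrors the returned hard result exactly
        final_props = props.values if want_props else np.zeros((n_s, 0))
        trajectory.append(TrajectoryFrame(t=0, proportions=final_props,
                                          per_spot_cosine=cos))
    return DeconvolutionResult(assignment=assignment, proportions=props,
                               reconstruction=recon, per_spot_cosine=cos,
                               trajectory=trajectory)


def assignment_cost(X: np.ndarray, A: AssignmentMatrix, Y: np.ndarray) -> float:
    """The combinatorial-optimization objective ||X A - Y||_F."""
    return float(np.linalg.norm(np.asarray(X, dtype=np.float64) @ A.entries
                                - np.asarray(Y, dtype=np.float64)))


def deconvolve_best_of(X: np.ndarray, Y: np.ndarray, params: DenoiserParams,
                       sched: NoiseSchedule, n_candidates: int = 4,
                       seed: int = 0,
                       cell_types: Optional[np.ndarray] = None,
                       n_types: Optional[int] = None) -> DeconvolutionResult:
    """Sample several candidate solutions and keep the lowest-cost one.

    The deconvolution objective ||X A - Y||_F needs no ground truth, so the
    solver can score its own samples; with a stochastic sampler this is the
    natural way to spend extra inference budget.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    best: Optional[DeconvolutionResult] = None
    best_cost = np.inf
    for c in range(n_candidates):
        res = deconvolve(X, Y, params, sched, seed=seed + 131 * c,
                         cell_types=cell_types, n_types=n_types)
        cost = assignment_cost(X, res.assignment, Y)
        if cost < best_cost:
            best, best_cost = res, cost
    assert best is not None
    return best


def estimate_uncertainty(X: np.ndarray, Y: np.ndarray, params: DenoiserParams,
                         sched: NoiseSchedule, cell_types: np.ndarray,
                         n_types: int, n_repeats: int = 20,
                         n_bootstrap: int = 1000, alpha: float = 0.05,
                         seed: int = 0) -> UncertaintyReport:
    """Bootstrap confidence intervals for every (spot, type) proportion.

    Runs ``n_repeats`` independent reverse-diffusion samplings, treats the
    per-(spot, type) proportions as observations, and builds percentile
    bootstrap intervals of the mean at level ``alpha``.  Intervals are
    clamped to contain the observed mean, which percentile intervals can
    miss by a hair on tiny, highly skewed samples.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    reps = []
    for r in range(n_repeats):
        res = deconvolve(X, Y, params, sched, seed=seed + 1000 * (r + 1),
                         cell_types=cell_types, n_types=n_types)
        reps.append(res.proportions.values)
    obs = np.stack(reps)  # repeats x spots x types
    mean = obs.mean(axis=0)
    std = obs.std(axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_repeats, size=(n_bootstrap, n_repeats))
    boot_means = obs[idx].mean(axis=1)  # n_bootstrap x spots x types
    lo = np.quantile(boot_means, alpha / 2, axis=0)
    hi = np.quantile(boot_means, 1 - alpha / 2, axis=0)
    lo = np.minimum(lo, mean)
    hi = np.maximum(hi, mean)
    return UncertaintyReport(mean=mean, std=std, ci_lower=lo, ci_upper=hi,
                             n_repeats=n_repeats, n_bootstrap=n_bootstrap,
                             alpha=alpha)
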