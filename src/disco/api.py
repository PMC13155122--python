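"""High-level modelling interface.

``SpotDeconvolutionModel`` is built from a single-cell reference and a spot
matrix (plus per-cell type labels); ``fit()`` runs the reverse-diffusion
sampler with a trained denoiser and returns a ``DeconvolutionResults`` object
carrying the proportion estimates, their bootstrap uncertainties, per-spot
reconstruction diagnostics and a ``summary()`` table.

Example
-------
>>> model = SpotDeconvolutionModel(X, Y, cell_types=labels,
...                                gene_ids_x=genes, gene_ids_y=genes)
>>> res = model.fit(params, steps=10, seed=0, n_repeats=20)
>>> res.summary()          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .bgnn import DenoiserParams
from .diffusion import NoiseSchedule, make_schedule
from .inference import (DeconvolutionResult, GenePlan, UncertaintyReport,
                        deconvolve, estimate_uncertainty, harmonize_genes)
from .metrics import ProportionMatrix
from .training import FineTuneConfig, fine_tune


@dataclass
class DeconvolutionResults:
    """Fitted estimates with uncertainty and diagnostics."""

    result: DeconvolutionResult
    uncertainty: Optional[UncertaintyReport]
    gene_plan: GenePlan
    type_names: List[str]
    seed: int

    @property
    def proportions(self) -> ProportionMatrix:
        return self.result.proportions

    @property
    def per_spot_cosine(self) -> np.ndarray:
        return self.result.per_spot_cosine

    def proportions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.result.proportions.values,
                            columns=self.type_names)

    def summary(self) -> pd.DataFrame:
        """Per-type summary: mean proportion, bootstrap std and CI width."""
        props = self.result.proportions.values
        rows = []
        for k, name in enumerate(self.type_names):
            row = {"cell_type": name,
                   "mean_proportion": float(props[:, k].mean()),
                   "spots_present": int((props[:, k] > 0).sum())}
            if self.uncertainty is not None:
                row["mean_bootstrap_std"] = float(self.uncertainty.std[:, k].mean())
                row["mean_ci_width"] = float(
                    (self.uncertainty.ci_upper[:, k]
                     - self.uncertainty.ci_lower[:, k]).mean())
            rows.append(row)
        return pd.DataFrame(rows)

    def plot_proportions(self, spot_coords: Optional[np.ndarray] = None,
                         ax=None):
        """Stacked composition per spot (bar) or spatial scatter by type."""
        import matplotlib.pyplot as plt
        props = self.result.proportions.values
        if ax is None:
            _, ax = plt.subplots()
        if spot_coords is None:
            bottom = np.zeros(props.shape[0])
            xs = np.arange(props.shape[0])
            for k, name in enumerate(self.type_names):
                ax.bar(xs, props[:, k], bottom=bottom, label=name, width=1.0)
                bottom += props[:, k]
            ax.set_xlabel("spot")
            ax.set_ylabel("proportion")
        else:
            dom = props.argmax(axis=1)
            for k, name in enumerate(self.type_names):
                sel = dom == k
                ax.scatter(spot_coords[sel, 0], spot_coords[sel, 1],
                           label=name, s=12)
        ax.legend(fontsize="small")
        return ax


class SpotDeconvolutionModel:
    """Deconvolution task bound to one (reference, spatial) data pair.

    Parameters
    ----------
    X, Y : genes x cells / genes x spots expression matrices.
    cell_types : per-cell integer labels (0..n_types-1) or string labels.
    gene_ids_x, gene_ids_y : gene identifier lists; harmonized on construction.
    capacity : embedding gene capacity of the intended checkpoint.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray,
                 cell_types: Sequence, gene_ids_x: Sequence[str],
                 gene_ids_y: Sequence[str], capacity: int = 2000):
        labels = pd.Categorical(list(cell_types))
        self.type_names = [str(c) for c in labels.categories]
        self.cell_types = np.asarray(labels.codes, dtype=np.int64)
        self.n_types = len(self.type_names)
        self.X, self.Y, self.gene_plan = harmonize_genes(
            X, Y, gene_ids_x, gene_ids_y, capacity=capacity)

    @classmethod
    def from_dataframes(cls, sc_df: pd.DataFrame, st_df: pd.DataFrame,
                        cell_types: Sequence, **kw) -> "SpotDeconvolutionModel":
        """Build from genes x cells / genes x spots DataFrames."""
        return cls(sc_df.to_numpy(dtype=float), st_df.to_numpy(dtype=float),
                   cell_types, list(sc_df.index), list(st_df.index), **kw)

    @classmethod
    def from_anndata(cls, sc_adata, st_adata, type_key: str = "cell_type",
                     **kw) -> "SpotDeconvolutionModel":
        """Build from AnnData pairs (cells x genes convention)."""
        def dense(A):
            X = A.X
            return np.asarray(X.toarray() if hasattr(X, "toarray") else X,
                              dtype=np.float64).T
        return cls(dense(sc_adata), dense(st_adata),
                   list(sc_adata.obs[type_key]),
                   list(sc_adata.var_names), list(st_adata.var_names), **kw)

    def fit(self, params: DenoiserParams, steps: int = 100,
            schedule: Optional[NoiseSchedule] = None, seed: int = 0,
            n_repeats: int = 0, n_bootstrap: int = 1000, alpha: float = 0.05,
            fine_tune_first: bool = False,
            capture_trajectory: bool = False) -> DeconvolutionResults:
        """Run reverse-diffusion deconvolution (optionally with uncertainty).

        ``steps`` is the number of retained reverse steps K; ``n_repeats`` >
        1 additionally runs repeated sampling plus a percentile bootstrap.
        ``fine_tune_first`` applies the decoder-only cosine fine-tuning to a
        copy of the parameters before sampling.
        """
        sched = schedule or make_schedule(1000, tau_count=steps)
        if fine_tune_first:
            params = fine_tune(params, self.X, self.Y,
                               FineTuneConfig(schedule=sched, seed=seed))
        result = deconvolve(self.X, self.Y, params, sched, seed=seed,
                            cell_types=self.cell_types, n_types=self.n_types,
                            capture_trajectory=capture_trajectory)
        unc = None
        if n_repeats > 1:
            unc = estimate_uncertainty(self.X, self.Y, params, sched,
                                       self.cell_types, self.n_types,
                                       n_repeats=n_repeats,
                                       n_bootstrap=n_bootstrap, alpha=alpha,
                                       seed=seed)
        return DeconvolutionResults(result=result, uncertainty=unc,
                                    gene_plan=self.gene_plan,
                                    type_names=self.type_names, seed=seed)
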