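# disco

**Spatial transcriptomics deconvolution as combinatorial optimization,
solved by a discrete denoising-diffusion model over bipartite assignment
graphs.**

Spot-based spatial transcriptomics (e.g. Visium) measures, at each capture
spot, the summed expression of an unknown mixture of cells. `disco` assigns
the cells of a single-cell reference `X` (genes × N_c) to the spots of a
spatial matrix `Y` (genes × N_s) by searching the space of binary assignment
matrices

```
A* = argmin_{A ∈ A_D} ‖X·A − Y‖_F ,
A_D = { A ∈ {0,1}^{N_c×N_s} : every row has exactly one 1 } ,
```

from which each spot's cell count and cell-type proportions
`q_ij = N_ij / N_i` follow directly. The solver is a two-state discrete
diffusion model on the graph's edges: a forward process corrupts known
solutions toward uniform noise with kernels `Q_t = [[1−β_t, β_t], [β_t,
1−β_t]]`, and a bipartite anisotropic graph network is trained — on
simulated "oracle" instances `(X, Y, A)` with known assignments — to predict
the clean assignment, which drives the exact Bayes reverse sampler (with
DDIM-style accelerated jumps). Repeated sampling plus a percentile
bootstrap yields confidence intervals for every (spot, type) proportion.
See `docs/methods.md` for the full model description.

For whom: computational biologists who want cell-level (not just
type-fraction) deconvolution of spot data against a labelled single-cell
reference, and methods researchers interested in diffusion solvers for
assignment problems.

## Worked example

Pretrain the tiny desk-scale solver on simulated oracle data and deconvolve
a held-out instance:

```python
import numpy as np
from disco import SpotDeconvolutionModel, tiny_config
from disco.oracle import make_corpus
from disco.presets import (TINY_MAX_STEPS, tiny_generator, tiny_schedule,
                           tiny_train_config)
from disco.training import LossWeights, train, true_proportions
from disco.metrics import rmse

corpus = make_corpus(300, (8, 1, 1), tiny_generator(), seed=1)
params, history = train(corpus, tiny_config(), tiny_train_config(seed=0),
                        LossWeights(), max_steps=TINY_MAX_STEPS)

inst = corpus.test[0]                      # never seen during training
model = SpotDeconvolutionModel(
    inst.cells.expr, inst.spots_expr,
    cell_types=inst.cells.cell_types,
    gene_ids_x=inst.cells.gene_ids, gene_ids_y=inst.cells.gene_ids,
    capacity=64)
res = model.fit(params, schedule=tiny_schedule(), seed=7, n_repeats=20)

truth = true_proportions(inst.assignment, inst.cells.cell_types, 3)
print("proportion RMSE :", round(rmse(truth, res.proportions), 3))
print("mean spot cosine:", round(float(res.per_spot_cosine.mean()), 3))
print(res.summary().to_string(index=False))
```

Output (about two minutes of training on one CPU):

```
proportion RMSE : 0.164
mean spot cosine: 0.878
cell_type  mean_proportion  spots_present  mean_bootstrap_std  mean_ci_width
        0         0.342857              7            0.035731       0.030783
        1         0.285119              8            0.026519       0.022582
        2         0.372024              7            0.031935       0.027154
```

Reading it: the solver places each of the 60 reference cells in one of the
instance's 12 spots; per-spot type proportions deviate from the ground
truth by 0.16 RMSE (a random feasible assignment scores ≈ 0.44), the
reconstructed spot profiles `X·A` match the observed ones at cosine 0.88,
and the bootstrap columns summarize the spread of 20 repeated samplings per
(spot, type) proportion.

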