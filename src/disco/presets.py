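"""Problem-size presets.

``full_*`` mirrors the reference geometry of the solver (1224 cells, 2000
genes, 4 types, ~255 spots; 6-layer width-256 network, T = 1000).  ``tiny_*``
is the desk-scale preset used by the test-suite and the reproduction script:
300 instances of 60 cells x 40 genes x 3 types (~12 spots), a 2-layer
width-32 network, and a T = 50 schedule whose betas (1e-3..0.1) are chosen so
the chain still mixes to uniform at the horizon (prod(1 - 2*beta_t) ~ 0.006).

The tiny pretraining recipe uses gradient accumulation over 8 instances per
update, learning rate 3e-3, 2000 parameter updates, Y-noise augmentation at
level 0.1 and no gene shuffling; at this scale the permutation-robustness
that gene shuffling buys is not learnable and it only slows convergence.
"""

from __future__ import annotations

from .bgnn import BGNNConfig, tiny_config
from .diffusion import NoiseSchedule, make_schedule
from .oracle import GeneratorConfig
from .training import TrainConfig

TINY_T = 50
TINY_BETA_MIN = 1e-3
TINY_BETA_MAX = 0.1
TINY_MAX_STEPS = 2000

full_config = BGNNConfig


def tiny_generator() -> GeneratorConfig:
    return GeneratorConfig(n_cells=60, n_genes=40, n_types=3, window=0.25)


def tiny_schedule(tau_count: int = 2) -> NoiseSchedule:
    return make_schedule(TINY_T, TINY_BETA_MIN, TINY_BETA_MAX,
                         tau_count=tau_count)


def tiny_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(epochs=67, batch_size=8, learning_rate=3e-3,
                       T=TINY_T, beta_min=TINY_BETA_MIN,
                       beta_max=TINY_BETA_MAX, noise_level=0.1,
                       gene_shuffle=False, seed=seed)
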