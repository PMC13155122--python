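"""Bipartite anisotropic graph denoising network.

The denoiser maps a noisy assignment graph A_t together with the expression
matrices (X, Y) and the timestep t to per-edge probabilities of the clean
assignment A_0.  Cells and spots are embedded by *unshared* linear maps of
their (log1p, L2-normalized) expression profiles, edges by a learned
two-state lookup of the current binary edge value.  Each of ``n_layers``
rounds then performs

* temporal injection:  e'_ij = e_ij + ReLU(W h_t)            (shared h_t)
* edge update:         ReLU(LN(e' E + u_i M + v_j N))
* gated node updates:  ReLU(LN(u_i O + mean_j sigmoid(e_ij) * v_j P))
                       ReLU(LN(v_j Q + mean_i sigmoid(e_ij) * u_i R))

with post-activation residual connections, followed by a 2-layer MLP decoder
and a per-edge two-class softmax.  The network never sees cell-type labels or
spatial coordinates.

When the data have fewer genes than the embedding capacity, only the leading
gene rows of the embedding weights are used, so one pretrained checkpoint
serves datasets with any shared-gene count up to the capacity.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .autodiff import Tensor, no_grad, parameter
from .diffusion import EdgeCategorical

LN_EPS = 1e-5
SINUSOID_BASE = 10_000.0


@dataclass
class BGNNConfig:
    """Architecture hyperparameters (defaults mirror the full-scale solver)."""

    n_layers: int = 6
    width: int = 256
    gene_capacity: int = 2000
    time_feature_dim: int = 128
    decoder_hidden: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.n_layers, self.width, self.gene_capacity,
               self.time_feature_dim) < 1:
            raise ValueError("all BGNN dimensions must be positive")
        if self.time_feature_dim % 2:
            raise ValueError("time_feature_dim must be even")
        if self.decoder_hidden is None:
            self.decoder_hidden = self.width


def tiny_config() -> BGNNConfig:
    """Small preset used for tests and desk-scale experiments."""
    return BGNNConfig(n_layers=2, width=32, gene_capacity=64,
                      time_feature_dim=16)


def _block_shapes(config: BGNNConfig) -> Dict[str, Tuple[int, ...]]:
    d = config.width
    shapes: Dict[str, Tuple[int, ...]] = {
        "cell_embed.W": (config.gene_capacity, d), "cell_embed.b": (d,),
        "spot_embed.W": (config.gene_capacity, d), "spot_embed.b": (d,),
        "edge_embed.state": (2, d),
        "time_mlp.W1": (config.time_feature_dim, d), "time_mlp.b1": (d,),
        "time_mlp.W2": (d, d), "time_mlp.b2": (d,),
    }
    for l in range(config.n_layers):
        # the final layer has no node update: the decoder reads edges only,
        # so node embeddings produced after the last edge update feed nothing
        last = l == config.n_layers - 1
        for name in ("W", "E", "M", "N") if last else "WEMNOPQR":
            shapes[f"layer{l}.{name}"] = (d, d)
        for side in ("e",) if last else ("e", "u", "v"):
            shapes[f"layer{l}.ln_{side}.g"] = (d,)
            shapes[f"layer{l}.ln_{side}.b"] = (d,)
    shapes.update({
        "decoder.W1": (d, config.decoder_hidden),
        "decoder.b1": (config.decoder_hidden,),
        "decoder.W2": (config.decoder_hidden, 2),
        "decoder.b2": (2,),
    })
    return shapes


def parameter_count(config: BGNNConfig) -> int:
    """Exact learnable-parameter count implied by the config."""
    return sum(int(np.prod(s)) for s in _block_shapes(config).values())


@dataclass
class DenoiserParams:
    """All learnable weights, keyed by block name."""

    config: BGNNConfig
    blocks: Dict[str, Tensor]

    @classmethod
    def init(cls, config: BGNNConfig, seed: int = 0) -> "DenoiserParams":
        rng = np.random.default_rng(seed)
        blocks: Dict[str, Tensor] = {}
        for name, shape in _block_shapes(config).items():
            if name.endswith(".b") or name.endswith(".b1") or name.endswith(".b2"):
                data = np.zeros(shape)
            elif ".ln_" in name:
                data = np.ones(shape) if name.endswith(".g") else np.zeros(shape)
            elif name == "edge_embed.state":
                # the binary edge state is a 2-level categorical; a small
                # embedding keeps the expression pathway competitive with
                # the A_t-copying shortcut early in training
                data = rng.normal(0.0, 0.1, size=shape)
            else:
                fan_in = shape[0] if len(shape) > 1 else 1
                data = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)
            blocks[name] = parameter(data)
        # cell and spot embeddings start from the same projection so the two
        # streams are comparable at init; they stay unshared and diverge
        # during training (which is what absorbs batch effects)
        blocks["spot_embed.W"].data[:] = blocks["cell_embed.W"].data
        return cls(config=config, blocks=blocks)

    def n_parameters(self) -> int:
        return sum(int(b.data.size) for b in self.blocks.values())

    def decoder_block_names(self) -> List[str]:
        """The final output layer (2-layer decoder MLP)."""
        return [k for k in self.blocks if k.startswith("decoder.")]

    def copy(self) -> "DenoiserParams":
        return DenoiserParams(config=self.config,
                              blocks={k: parameter(v.data.copy())
                                      for k, v in self.blocks.items()})

    # checkpoint: single npz archive with a JSON config header
    def save(self, path: str) -> None:
        header = json.dumps({"format": "disco-checkpoint-v1",
                             "config": self.config.__dict__})
        arrays = {k.replace(".", "__"): v.data for k, v in self.blocks.items()}
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "DenoiserParams":
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            if header.get("format") != "disco-checkpoint-v1":
                raise ValueError("unrecognized checkpoint format")
            config = BGNNConfig(**header["config"])
            blocks = {k.replace("__", "."): parameter(z[k])
                      for k in z.files if k != "__header__"}
        expected = set(_block_shapes(config))
        if set(blocks) != expected:
            raise ValueError("checkpoint blocks do not match its config")
        return cls(config=config, blocks=blocks)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def time_features(t: int, dim: int) -> np.ndarray:
    """Sinusoidal timestep features: interleaved (sin, cos) pairs.

    Pair k uses angular scale base**(2k/dim) with base 1e4, so frequencies
    span 1 .. 1/base geometrically.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if dim % 2:
        raise ValueError("dim must be even")
    half = dim // 2
    scales = SINUSOID_BASE ** (2 * np.arange(half) / dim)
    angles = t / scales
    out = np.empty(dim)
    out[0::2] = np.sin(angles)
    out[1::2] = np.cos(angles)
    return out


def expression_features(M: np.ndarray) -> np.ndarray:
    """Per-profile features: log1p then L2 normalization of each column.

    Returns profiles as rows (columns x genes), ready for the embedding maps.
    Zero columns stay zero.  The embedding layer applies a sqrt(capacity)
    gain so node activations are O(1) for unit-norm inputs under the fan-in
    weight init, independent of the actual gene count.
    """
    F = np.log1p(np.asarray(M, dtype=np.float64)).T
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    return F / np.maximum(norms, 1e-12)


def _layernorm(x: Tensor, gain: Tensor, offset: Tensor) -> Tensor:
    m = x.mean(axis=-1, keepdims=True)
    xc = x - m
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * ((var + LN_EPS) ** -0.5) * gain + offset


def _softmax2(logits: Tensor) -> Tensor:
    shift = logits.data.max(axis=-1, keepdims=True)  # constant; exact gradient
    z = (logits - shift).exp()
    return z / z.sum(axis=-1, keepdims=True)


@dataclass
class LatentState:
    """Embeddings carried between layers (all autodiff tensors)."""

    e: Tensor  # cells x spots x d
    u: Tensor  # cells x d
    v: Tensor  # spots x d
    h_t: Tensor  # d


def _embed_tensors(X: np.ndarray, Y: np.ndarray, At: np.ndarray, t: int,
                   params: DenoiserParams) -> LatentState:
    cfg = params.config
    n_genes = X.shape[0]
    if Y.shape[0] != n_genes:
        raise ValueError("X and Y must share the gene dimension")
    if n_genes > cfg.gene_capacity:
        raise ValueError(
            f"{n_genes} genes exceed the embedding capacity "
            f"{cfg.gene_capacity}; select highly variable genes first")
    b = params.blocks
    xf = expression_features(X)  # cells x genes
    yf = expression_features(Y)  # spots x genes
    gain = float(np.sqrt(cfg.gene_capacity))  # O(1) acts for unit-norm input
    u = (Tensor(xf) @ b["cell_embed.W"][:n_genes]) * gain + b["cell_embed.b"]
    v = (Tensor(yf) @ b["spot_embed.W"][:n_genes]) * gain + b["spot_embed.b"]
    At = np.asarray(At, dtype=np.float64)
    e = (Tensor(1.0 - At[..., None]) * b["edge_embed.state"][0]
         + Tensor(At[..., None]) * b["edge_embed.state"][1])
    h = Tensor(time_features(t, cfg.time_feature_dim))
    h = ((h @ b["time_mlp.W1"] + b["time_mlp.b1"]).relu()
         @ b["time_mlp.W2"] + b["time_mlp.b2"])
    return LatentState(e=e, u=u, v=v, h_t=h)


def _temporal_inject(e: Tensor, h_t: Tensor, W: Tensor) -> Tensor:
    return e + (h_t @ W).relu()


def _edge_update(e_t: Tensor, u: Tensor, v: Tensor, blocks: Dict[str, Tensor],
                 l: int) -> Tensor:
    n_c = u.shape[0]
    n_s = v.shape[0]
    d = u.shape[1]
    pre = (e_t @ blocks[f"layer{l}.E"]
           + (u @ blocks[f"layer{l}.M"]).reshape(n_c, 1, d)
           + (v @ blocks[f"layer{l}.N"]).reshape(1, n_s, d))
    return _layernorm(pre, blocks[f"layer{l}.ln_e.g"],
                      blocks[f"layer{l}.ln_e.b"]).relu()


def _node_update(e_new: Tensor, u: Tensor, v: Tensor,
                 blocks: Dict[str, Tensor], l: int) -> Tuple[Tensor, Tensor]:
    n_c = u.shape[0]
    n_s = v.shape[0]
    d = u.shape[1]
    gate = e_new.sigmoid()
    vp = (v @ blocks[f"layer{l}.P"]).reshape(1, n_s, d)
    ur = (u @ blocks[f"layer{l}.R"]).reshape(n_c, 1, d)
    u_pre = u @ blocks[f"layer{l}.O"] + (gate * vp).mean(axis=1)
    v_pre = v @ blocks[f"layer{l}.Q"] + (gate * ur).mean(axis=0)
    u_new = _layernorm(u_pre, blocks[f"layer{l}.ln_u.g"],
                       blocks[f"layer{l}.ln_u.b"]).relu()
    v_new = _layernorm(v_pre, blocks[f"layer{l}.ln_v.g"],
                       blocks[f"layer{l}.ln_v.b"]).relu()
    return u_new, v_new


def _decode(e: Tensor, blocks: Dict[str, Tensor]) -> Tensor:
    h = (e @ blocks["decoder.W1"] + blocks["decoder.b1"]).relu()
    logits = h @ blocks["decoder.W2"] + blocks["decoder.b2"]
    return _softmax2(logits)


def forward_soft(X: np.ndarray, Y: np.ndarray, At: np.ndarray, t: int,
                 params: DenoiserParams) -> Tensor:
    """Full differentiable forward pass; returns per-edge class probabilities
    of shape (cells, spots, 2), with class 1 = edge present."""
    state = _embed_tensors(X, Y, At, t, params)
    e, u, v = state.e, state.u, state.v
    n_layers = params.config.n_layers
    for l in range(n_layers):
        e_t = _temporal_inject(e, state.h_t, params.blocks[f"layer{l}.W"])
        e_new = _edge_update(e_t, u, v, params.blocks, l)
        # post-activation residual connections; the last layer skips the
        # node update because only edge embeddings reach the decoder
        e = e + e_new
        if l < n_layers - 1:
            u_new, v_new = _node_update(e_new, u, v, params.blocks, l)
            u = u + u_new
            v = v + v_new
    return _decode(e, params.blocks)


def predict_A0(At: np.ndarray, X: np.ndarray, Y: np.ndarray, t: int,
               params: DenoiserParams,
               config: Optional[BGNNConfig] = None) -> EdgeCategorical:
    """Denoiser forward pass returning predicted clean-edge probabilities."""
    if config is not None and config != params.config:
        raise ValueError("config does not match the parameter set")
    for name, M in (("At", At), ("X", X), ("Y", Y)):
        if not np.all(np.isfinite(M)):
            raise FloatingPointError(f"non-finite entries in {name}")
    with no_grad():
        probs = forward_soft(X, Y, At, t, params)
    if not np.all(np.isfinite(probs.data)):
        raise FloatingPointError("non-finite network output")
    return EdgeCategorical(probs.data[..., 1])


# ---------------------------------------------------------------------------
# numpy-facing wrappers for the individual blocks (used by unit tests and
# anyone composing custom layers)
# ---------------------------------------------------------------------------

def embed_inputs(X: np.ndarray, Y: np.ndarray, At: np.ndarray,
                 params: DenoiserParams, t: int = 0) -> LatentState:
    """Initial embeddings (layer 0) of cells, spots and edges."""
    return _embed_tensors(X, Y, At, t, params)


def temporal_inject(e: np.ndarray, h_t_layer: np.ndarray,
                    W: np.ndarray) -> np.ndarray:
    """Add the rectified, projected time embedding to every edge embedding."""
    return _temporal_inject(Tensor(e), Tensor(h_t_layer), Tensor(W)).data


def edge_update(e_t: np.ndarray, u: np.ndarray, v: np.ndarray,
                params: DenoiserParams, layer: int) -> np.ndarray:
    return _edge_update(Tensor(e_t), Tensor(u), Tensor(v), params.blocks,
                        layer).data


def node_update(e_new: np.ndarray, u: np.ndarray, v: np.ndarray,
                params: DenoiserParams, layer: int) -> Tuple[np.ndarray, np.ndarray]:
    un, vn = _node_update(Tensor(e_new), Tensor(u), Tensor(v), params.blocks,
                          layer)
    return un.data, vn.data


def decode_edges(e_final: np.ndarray, params: DenoiserParams) -> EdgeCategorical:
    probs = _decode(Tensor(e_final), params.blocks)
    return EdgeCategorical(probs.data[..., 1])
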