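"""Oracle-instance simulation for training the deconvolution solver.

A supervised "oracle" instance is a triple (X, Y, A): a reference single-cell
expression matrix X (genes x cells), a spot matrix Y (genes x spots) and the
ground-truth binary assignment A (cells x spots) that generated Y = X @ A.
Instances are produced by simulating a spatially resolved single-cell slice
(cell types with distinct mean expression profiles, spatially coherent type
domains), then down-sampling to spot resolution by binning cells on a regular
grid and summing their expression per occupied grid square.

The expression model is deliberately simple: per-type gene means drawn
log-normal(0, 1), per-cell counts negative-binomial around the type mean
(gamma-Poisson mixture, dispersion ``nb_dispersion``).  Multiplicative
log-normal noise can be layered on Y to emulate platform/batch distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

SPATIAL_PATTERNS = ("clustered", "mosaic", "uniform")

#: Default spot edge length on the unit square.  Calibrated so that the
#: reference geometry (1224 cells, clustered types) aggregates to a mean
#: occupancy of roughly 4.8 cells per occupied spot (~255 spots).
DEFAULT_WINDOW = 1.0 / 16.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SingleCellSlice:
    """A spatially resolved single-cell expression slice.

    expr
        genes x cells nonnegative expression matrix.
    cell_types
        integer type label per cell, in ``0..n_types-1``.
    coords
        cells x 2 spatial positions (arbitrary length units).
    gene_ids
        ordered unique gene identifiers, one per expression row.
    """

    expr: np.ndarray
    cell_types: np.ndarray
    coords: np.ndarray
    gene_ids: List[str]

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=np.float64)
        self.cell_types = np.asarray(self.cell_types, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.expr.ndim != 2:
            raise ValueError("expr must be 2-D (genes x cells)")
        n_cells = self.expr.shape[1]
        if self.cell_types.shape != (n_cells,):
            raise ValueError("cell_types length must equal cell count")
        if self.coords.shape != (n_cells, 2):
            raise ValueError("coords must be cells x 2")
        if np.any(self.expr < 0):
            raise ValueError("expr must be nonnegative")
        if len(self.gene_ids) != self.expr.shape[0]:
            raise ValueError("gene_ids length must equal gene count")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.expr.shape[1]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_types(self) -> int:
        return int(self.cell_types.max()) + 1 if self.n_cells else 0


@dataclass
class AssignmentMatrix:
    """Binary cells x spots assignment; feasible iff each row has one 1."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        vals = np.unique(self.entries)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("assignment entries must be 0/1")
        self.entries = self.entries.astype(np.float64)

    @property
    def n_cells(self) -> int:
        return self.entries.shape[0]

    @property
    def n_spots(self) -> int:
        return self.entries.shape[1]

    def is_feasible(self) -> bool:
        return bool(np.all(self.entries.sum(axis=1) == 1))

    def require_feasible(self) -> "AssignmentMatrix":
        if not self.is_feasible():
            raise ValueError("assignment is not feasible (row sums must be 1)")
        return self

    def spot_index(self) -> np.ndarray:
        """Per-cell spot index (requires feasibility)."""
        self.require_feasible()
        return self.entries.argmax(axis=1)


@dataclass
class OracleInstance:
    """One supervised deconvolution task (X, Y, A) with geometry."""

    cells: SingleCellSlice
    spots_expr: np.ndarray
    assignment: AssignmentMatrix
    spot_coords: np.ndarray
    window: float

    def __post_init__(self) -> None:
        self.spots_expr = np.asarray(self.spots_expr, dtype=np.float64)
        self.assignment.require_feasible()
        if self.spots_expr.shape[1] != self.assignment.n_spots:
            raise ValueError("spot count mismatch between Y and A")
        if self.spots_expr.shape[0] != self.cells.n_genes:
            raise ValueError("gene count mismatch between X and Y")

    @property
    def n_spots(self) -> int:
        return self.assignment.n_spots


@dataclass
class OracleCorpus:
    """An ordered collection of instances with a train/val/test partition."""

    instances: List[OracleInstance]
    split: Tuple[np.ndarray, np.ndarray, np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        idx = np.concatenate([np.asarray(s) for s in self.split])
        if len(np.unique(idx)) != len(idx) or len(idx) != len(self.instances):
            raise ValueError("split must be a disjoint cover of all instances")

    @property
    def train(self) -> List[OracleInstance]:
        return [self.instances[i] for i in self.split[0]]

    @property
    def validation(self) -> List[OracleInstance]:
        return [self.instances[i] for i in self.split[1]]

    @property
    def test(self) -> List[OracleInstance]:
        return [self.instances[i] for i in self.split[2]]


@dataclass
class GeneratorConfig:
    """Knobs of the oracle simulator (defaults give the reference geometry)."""

    n_cells: int = 1224
    n_genes: int = 2000
    n_types: int = 4
    spatial_pattern: str = "clustered"
    window: float = DEFAULT_WINDOW
    noise_level: float = 0.0
    nb_dispersion: float = 0.5
    cluster_sigma: float = 0.16


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _type_positions(n_cells: int, n_types: int, pattern: str,
                    rng: np.random.Generator,
                    cluster_sigma: float) -> Tuple[np.ndarray, np.ndarray]:
    """Draw (cell_types, coords) on the unit square under a spatial pattern."""
    # near-equal type shares, remainder to the first types
    base = n_cells // n_types
    counts = np.full(n_types, base)
    counts[: n_cells - base * n_types] += 1
    types = np.repeat(np.arange(n_types), counts)
    rng.shuffle(types)

    if pattern == "uniform":
        coords = rng.uniform(0.0, 1.0, size=(n_cells, 2))
    elif pattern == "clustered":
        centers = rng.uniform(0.15, 0.85, size=(n_types, 2))
        coords = centers[types] + rng.normal(0.0, cluster_sigma, size=(n_cells, 2))
        coords = np.clip(coords, 0.0, 1.0)
    elif pattern == "mosaic":
        # checkerboard of sqrt(n_types)-ish patches, types tile cyclically
        k = max(2, int(np.ceil(np.sqrt(n_types))))
        patch = rng.integers(0, k, size=(n_cells, 2))
        patch_type = (patch[:, 0] * k + patch[:, 1]) % n_types
        types = patch_type.astype(np.int64)
        coords = (patch + rng.uniform(0.0, 1.0, size=(n_cells, 2))) / k
    else:
        raise ValueError(f"unknown spatial pattern {pattern!r}; "
                         f"choose one of {SPATIAL_PATTERNS}")
    return types.astype(np.int64), coords


def simulate_slice(n_cells: int, n_genes: int, n_types: int,
                   spatial_pattern: str = "clustered", seed: int = 0,
                   nb_dispersion: float = 0.5,
                   cluster_sigma: float = 0.16) -> SingleCellSlice:
    """Simulate a spatially resolved single-cell slice.

    Each cell type gets a distinct gene-wise mean profile drawn
    log-normal(0, 1); per-cell counts are negative-binomial around the type
    mean via a gamma-Poisson mixture.  Deterministic for a fixed seed.
    """
    if n_cells < 1 or n_genes < 1 or n_types < 1:
        raise ValueError("n_cells, n_genes and n_types must be >= 1")
    if n_types > n_cells:
        raise ValueError("n_types cannot exceed n_cells")
    rng = np.random.default_rng(seed)
    type_means = rng.lognormal(mean=0.0, sigma=1.0, size=(n_types, n_genes))
    types, coords = _type_positions(n_cells, n_types, spatial_pattern, rng,
                                    cluster_sigma)
    mu = type_means[types]  # cells x genes
    r = float(nb_dispersion)
    if r <= 0:
        raise ValueError("nb_dispersion must be positive")
    lam = rng.gamma(shape=r, scale=mu / r)
    expr = rng.poisson(lam).astype(np.float64).T  # genes x cells
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    return SingleCellSlice(expr=expr, cell_types=types, coords=coords,
                           gene_ids=gene_ids)


def bin_to_spots(cell_slice: SingleCellSlice,
                 window: float) -> Tuple[AssignmentMatrix, np.ndarray]:
    """Partition cells into spots by a regular grid of side ``window``.

    The grid is anchored at the coordinate bounding-box minimum with half-open
    squares [k*w, (k+1)*w); cells exactly on the max boundary fall into the
    last occupied bin.  Empty grid squares produce no spot.  Returns the
    (feasible) assignment and the spot centers, spots ordered by (ix, iy).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if cell_slice.n_cells == 0:
        raise ValueError("slice is empty")
    coords = cell_slice.coords
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    n_bins = np.maximum(1, np.ceil((hi - lo) / window - 1e-12).astype(int))
    ij = np.floor((coords - lo) / window).astype(int)
    ij = np.minimum(ij, n_bins - 1)  # max-boundary cells go to the last bin
    keys = ij[:, 0] * n_bins[1] + ij[:, 1]
    uniq, inverse = np.unique(keys, return_inverse=True)
    n_spots = len(uniq)
    entries = np.zeros((cell_slice.n_cells, n_spots))
    entries[np.arange(cell_slice.n_cells), inverse] = 1.0
    centers = np.stack([lo[0] + (uniq // n_bins[1] + 0.5) * window,
                        lo[1] + (uniq % n_bins[1] + 0.5) * window], axis=1)
    return AssignmentMatrix(entries), centers


def aggregate(expr: np.ndarray, assignment: AssignmentMatrix) -> np.ndarray:
    """Sum-aggregate cell expression into spots: Y = X @ A."""
    expr = np.asarray(expr, dtype=np.float64)
    if expr.shape[1] != assignment.n_cells:
        raise ValueError("expr column count must equal assignment row count")
    return expr @ assignment.entries


def add_expression_noise(Y: np.ndarray, level: float, seed: int = 0) -> np.ndarray:
    """Multiplicative log-normal perturbation of scale ``level`` (0 = identity).

    Factors are mean-one (exp(level*Z - level^2/2)) so the expected expression
    is preserved; for small levels the per-entry relative deviation has
    standard deviation ~ ``level``.
    """
    if level < 0:
        raise ValueError("noise level must be nonnegative")
    Y = np.asarray(Y, dtype=np.float64)
    if level == 0:
        return Y
    rng = np.random.default_rng(seed)
    factors = np.exp(level * rng.standard_normal(Y.shape) - 0.5 * level ** 2)
    return Y * factors


def shuffle_genes(instance: OracleInstance, seed: int) -> OracleInstance:
    """Apply one shared gene permutation to X and Y (assignment unchanged)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(instance.cells.n_genes)
    cells = replace(instance.cells,
                    expr=instance.cells.expr[perm],
                    gene_ids=[instance.cells.gene_ids[i] for i in perm])
    return OracleInstance(cells=cells,
                          spots_expr=instance.spots_expr[perm],
                          assignment=instance.assignment,
                          spot_coords=instance.spot_coords,
                          window=instance.window)


def make_instance(config: GeneratorConfig, seed: int) -> OracleInstance:
    """Simulate one oracle instance under ``config``."""
    cell_slice = simulate_slice(config.n_cells, config.n_genes, config.n_types,
                                config.spatial_pattern, seed,
                                nb_dispersion=config.nb_dispersion,
                                cluster_sigma=config.cluster_sigma)
    assignment, centers = bin_to_spots(cell_slice, config.window)
    Y = aggregate(cell_slice.expr, assignment)
    Y = add_expression_noise(Y, config.noise_level, seed=seed + 10_007)
    return OracleInstance(cells=cell_slice, spots_expr=Y,
                          assignment=assignment, spot_coords=centers,
                          window=config.window)


def make_gridded_instance(n_spots_x: int, n_spots_y: int,
                          cells_per_spot: int, n_genes: int, n_types: int,
                          seed: int = 0, window: float = 1.0,
                          nb_dispersion: float = 0.5) -> OracleInstance:
    """Simulate an instance with an exact spot grid (every bin occupied).

    Cells are dealt round-robin over the n_spots_x * n_spots_y grid squares
    with uniform jitter inside each square, so the spot count is exactly the
    grid size.  Cell types are assigned by horizontal band so neighbouring
    spots share types (a coarse clustered pattern); expression uses the same
    log-normal-mean / negative-binomial model as :func:`simulate_slice`.
    """
    n_spots = n_spots_x * n_spots_y
    n_cells = n_spots * cells_per_spot
    if min(n_spots_x, n_spots_y, cells_per_spot, n_genes, n_types) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    bins = np.tile(np.arange(n_spots), cells_per_spot)
    bx, by = bins // n_spots_y, bins % n_spots_y
    coords = (np.stack([bx, by], axis=1)
              + rng.uniform(0.05, 0.95, size=(n_cells, 2))) * window
    # types form horizontal bands with a sprinkle of noise
    types = np.minimum((bx * n_types) // n_spots_x, n_types - 1)
    flip = rng.random(n_cells) < 0.15
    types = np.where(flip, rng.integers(0, n_types, n_cells), types)
    type_means = rng.lognormal(0.0, 1.0, size=(n_types, n_genes))
    mu = type_means[types]
    lam = rng.gamma(shape=nb_dispersion, scale=mu / nb_dispersion)
    expr = rng.poisson(lam).astype(np.float64).T
    cells = SingleCellSlice(expr=expr, cell_types=types.astype(np.int64),
                            coords=coords,
                            gene_ids=[f"g{i:05d}" for i in range(n_genes)])
    # the assignment is known by construction (cell i lives in bins[i])
    entries = np.zeros((n_cells, n_spots))
    entries[np.arange(n_cells), bins] = 1.0
    assignment = AssignmentMatrix(entries)
    centers = (np.stack([np.arange(n_spots) // n_spots_y,
                         np.arange(n_spots) % n_spots_y], axis=1)
               + 0.5) * window
    Y = aggregate(expr, assignment)
    return OracleInstance(cells=cells, spots_expr=Y, assignment=assignment,
                          spot_coords=centers, window=window)


def split_sizes(n_instances: int, split_ratio: Sequence[float]) -> Tuple[int, int, int]:
    """Partition ``n_instances`` by ratio shares (largest-remainder rounding)."""
    ratio = np.asarray(split_ratio, dtype=np.float64)
    if len(ratio) != 3 or np.any(ratio <= 0):
        raise ValueError("split_ratio must be three positive numbers")
    shares = ratio / ratio.sum() * n_instances
    sizes = np.floor(shares).astype(int)
    rem = n_instances - sizes.sum()
    order = np.argsort(-(shares - sizes))
    for k in range(rem):
        sizes[order[k]] += 1
    return int(sizes[0]), int(sizes[1]), int(sizes[2])


def make_corpus(n_instances: int, split_ratio: Sequence[float] = (9000, 900, 100),
                generator_config: Optional[GeneratorConfig] = None,
                seed: int = 0) -> OracleCorpus:
    """Generate a corpus of instances with a train/validation/test partition.

    Instance ``i`` uses derived seed ``seed + i`` so corpora are reproducible
    and instances mutually independent; the split is by position, so test
    instances are never seen during training by construction.
    """
    if n_instances < 3:
        raise ValueError("need at least 3 instances (one per split)")
    config = generator_config or GeneratorConfig()
    n_tr, n_va, n_te = split_sizes(n_instances, split_ratio)
    instances = [make_instance(config, seed + i) for i in range(n_instances)]
    split = (np.arange(0, n_tr),
             np.arange(n_tr, n_tr + n_va),
             np.arange(n_tr + n_va, n_instances))
    return OracleCorpus(instances=instances, split=split, seed=seed)
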