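"""Self-organizing-map feature extraction for browsing behavior.

One SOM is trained *per user* on that user's record attribute vectors
(by default the file category alone, min-max scaled to [0, 1]).  The
trained grid is reduced to the user's behavioral signature: an 8x8
feature matrix in which each cell carries the dominant file category
among the records whose best-matching unit (BMU) is that cell,

    Cell(i,j) = argmax_c ft_c   (0 when no record maps to the cell),

which is then one-hot binarized (5 bits per cell, 320 bits for an 8x8
grid) for the downstream classifiers.

The online training rule is the classical Kohonen update: at step t an
input x is drawn at random, its BMU c = argmin_k ||x - m_k|| found, and
every unit moved toward x,

    m_k(t+1) = m_k(t) + h_ck(t) [x(t) - m_k(t)],

with a Gaussian neighborhood kernel h_ck(t) = alpha(t) exp(-||r_c -
r_k||^2 / (2 sigma(t)^2)) on the (hexagonal, by default) grid, and
linearly decaying alpha and sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from embar.errors import ValidationError
from embar.records import TifRecord, derive_attributes

#: Default cap on total online-update steps per map; auto step count is
#: min(epochs * n_records, this cap).
DEFAULT_STEP_CAP = 10_000

Schedule = Callable[[float], float]  # maps training progress in [0,1] to a value


def linear_schedule(start: float, end: float) -> Schedule:
    """Linear decay from ``start`` (progress 0) to ``end`` (progress 1)."""
    return lambda frac: start + (end - start) * frac


@dataclass
class SomTrainingParams:
    """Training hyperparameters for one map.

    ``epochs`` is the number of passes over the user's records; the total
    number of online steps is ``min(epochs * n_records, step_cap)``.  The
    learning rate alpha decays linearly 0.5 -> 0.01 and the neighborhood
    radius sigma 4 -> 1 over training, with a Gaussian kernel; all three
    are replaceable.
    """

    grid_rows: int = 8
    grid_cols: int = 8
    topology: str = "hexagonal"
    epochs: int = 500
    step_cap: int = DEFAULT_STEP_CAP
    alpha_schedule: Schedule = linear_schedule(0.5, 0.01)
    sigma_schedule: Schedule = linear_schedule(4.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValidationError("grid dimensions must be positive")
        if self.topology not in ("hexagonal", "rectangular"):
            raise ValidationError(f"unknown topology {self.topology!r}")
        if self.epochs <= 0 or self.step_cap <= 0:
            raise ValidationError("epochs and step_cap must be positive")

    def with_seed(self, seed: int) -> "SomTrainingParams":
        return replace(self, seed=seed)


def unit_positions(rows: int, cols: int, topology: str) -> np.ndarray:
    """Planar coordinates r_k of every unit, row-major.

    Hexagonal grids stagger odd rows by half a unit and compress row
    spacing to sqrt(3)/2, so planar Euclidean distance equals hex-lattice
    distance between unit centers.
    """
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    r, c = r.astype(float).ravel(), c.astype(float).ravel()
    if topology == "hexagonal":
        x = c + 0.5 * (r % 2)
        y = r * (np.sqrt(3.0) / 2.0)
    else:
        x, y = c, r
    return np.column_stack([x, y])


@dataclass
class SomGrid:
    """A trained map: one n-dimensional weight vector per grid unit."""

    weights: np.ndarray  # (n_units, input_dim)
    rows: int
    cols: int
    topology: str = "hexagonal"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim == 1:
            self.weights = self.weights[:, None]
        if self.weights.shape[0] != self.rows * self.cols:
            raise ValidationError(
                f"expected {self.rows * self.cols} weight vectors, "
                f"got {self.weights.shape[0]}")
        self.positions = unit_positions(self.rows, self.cols, self.topology)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    @property
    def input_dim(self) -> int:
        return self.weights.shape[1]

    def grid_sq_distances(self) -> np.ndarray:
        """(n_units, n_units) squared planar distances ||r_c - r_i||^2."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return (diff ** 2).sum(axis=2)


def _as_matrix(x: np.ndarray, dim: int, what: str) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != dim:
        raise ValidationError(
            f"{what} dimension {x.shape[1]} does not match map input_dim {dim}")
    return x


def find_bmu(grid: SomGrid, x: np.ndarray) -> int | np.ndarray:
    """Best-matching unit index: argmin_k ||x - m_k||, ties to lowest index.

    Accepts a single vector (returns an int) or a batch (returns an array).
    """
    single = np.asarray(x).ndim <= 1
    X = _as_matrix(x, grid.input_dim, "input")
    d2 = ((X[:, None, :] - grid.weights[None, :, :]) ** 2).sum(axis=2)
    bmus = d2.argmin(axis=1)
    return int(bmus[0]) if single else bmus


def update_weights(grid: SomGrid, x: np.ndarray, h: np.ndarray) -> SomGrid:
    """Move every unit toward x by its kernel fraction h_ck, in place.

    ``h`` is the per-unit kernel value (scalar broadcast allowed); values
    must lie in [0, 1].  h=1 snaps a unit onto x, h=0 leaves it unchanged.
    """
    h = np.broadcast_to(np.asarray(h, dtype=float), (grid.n_units,))
    if (h < 0).any() or (h > 1).any():
        raise ValidationError("neighborhood kernel values must lie in [0, 1]")
    x = np.asarray(x, dtype=float).reshape(1, -1)
    if x.shape[1] != grid.input_dim:
        raise ValidationError("input dimension mismatch in update_weights")
    grid.weights += h[:, None] * (x - grid.weights)
    return grid


def neighborhood_kernel(grid: SomGrid, bmu: int, progress: float,
                        params: SomTrainingParams,
                        sq_dists: np.ndarray | None = None) -> np.ndarray:
    """Gaussian kernel h_ck = alpha(t) exp(-||r_c - r_k||^2 / 2 sigma(t)^2)."""
    if sq_dists is None:
        sq_dists = grid.grid_sq_distances()
    alpha = params.alpha_schedule(progress)
    sigma = params.sigma_schedule(progress)
    return alpha * np.exp(-sq_dists[bmu] / (2.0 * sigma * sigma))


def train_som(vectors: np.ndarray, params: SomTrainingParams) -> SomGrid:
    """Train one map by online updates on randomly drawn input vectors.

    Deterministic given the seed: weight initialization (uniform inside
    the per-dimension data range) and the step-wise input draws come from
    one seeded generator.
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.ndim != 2 or X.size == 0:
        raise ValidationError("training requires a non-empty 2-D input array")
    n, dim = X.shape
    rng = np.random.default_rng(params.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    weights = rng.uniform(lo, np.where(hi > lo, hi, lo + 1e-9),
                          size=(params.grid_rows * params.grid_cols, dim))
    grid = SomGrid(weights, params.grid_rows, params.grid_cols, params.topology)

    steps = min(params.epochs * n, params.step_cap)
    sq_dists = grid.grid_sq_distances()
    W = grid.weights
    alpha, sigma = params.alpha_schedule, params.sigma_schedule
    draws = rng.integers(0, n, size=steps)
    denom = max(steps - 1, 1)
    for t in range(steps):
        x = X[draws[t]]
        bmu = int(((W - x) ** 2).sum(axis=1).argmin())
        frac = t / denom
        s = sigma(frac)
        h = alpha(frac) * np.exp(-sq_dists[bmu] / (2.0 * s * s))
        W += h[:, None] * (x - W)
    return grid


def quantization_error(grid: SomGrid, vectors: np.ndarray) -> float:
    """Mean Euclidean distance of each input to its BMU weight vector."""
    X = _as_matrix(vectors, grid.input_dim, "input")
    d2 = ((X[:, None, :] - grid.weights[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


N_CATEGORIES = 5


@dataclass
class FeatureMatrix:
    """Dominant-file-type matrix: per cell, code 0-5 (0 = no records mapped).

    ``counts[i, j, c-1]`` tallies how many records of category c mapped to
    cell (i, j); ``cells[i, j]`` is the argmax category (ties to the lowest
    code), or 0 for an empty cell.
    """

    cells: np.ndarray  # (rows, cols) int, values 0..5
    counts: np.ndarray | None = None  # (rows, cols, 5) int tallies

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=int)
        if ((self.cells < 0) | (self.cells > N_CATEGORIES)).any():
            raise ValidationError("cell codes must lie in 0..5")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=int)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape  # type: ignore[return-value]

    def to_text(self) -> str:
        """Plain-text rendering of the grid (rows of cell codes)."""
        return "\n".join(" ".join(str(v) for v in row) for row in self.cells)


def dominant_category(tallies: np.ndarray) -> int:
    """Cell code from a length-5 tally: 0 if empty, else lowest argmax + 1."""
    tallies = np.asarray(tallies)
    if tallies.sum() == 0:
        return 0
    return int(tallies.argmax()) + 1


def extract_feature_matrix(grid: SomGrid, vectors: np.ndarray,
                           categories: Sequence[int]) -> FeatureMatrix:
    """Tally BMU assignments per cell and category; reduce to dominant codes.

    The result is independent of record order: assignments are tallied,
    not sequential.
    """
    X = _as_matrix(vectors, grid.input_dim, "input")
    cats = np.asarray(categories, dtype=int)
    if len(cats) != len(X):
        raise ValidationError("one category code required per input vector")
    if ((cats < 1) | (cats > N_CATEGORIES)).any():
        raise ValidationError("category codes must lie in 1..5")
    bmus = find_bmu(grid, X)
    counts = np.zeros((grid.n_units, N_CATEGORIES), dtype=int)
    np.add.at(counts, (bmus, cats - 1), 1)
    nonempty = counts.sum(axis=1) > 0
    cells = np.where(nonempty, counts.argmax(axis=1) + 1, 0)
    return FeatureMatrix(cells.reshape(grid.rows, grid.cols),
                         counts.reshape(grid.rows, grid.cols, N_CATEGORIES))


def binarize(matrix: FeatureMatrix) -> np.ndarray:
    """One-hot encode the matrix: 5 bits per cell, empty cells all-zero.

    Cell code c in 1..5 sets bit c-1 of its 5-bit block; the flat vector
    has length rows * cols * 5 and at most one bit set per block.
    """
    flat = matrix.cells.ravel()
    bits = np.zeros((flat.size, N_CATEGORIES), dtype=np.uint8)
    nz = flat > 0
    bits[np.nonzero(nz)[0], flat[nz] - 1] = 1
    return bits.ravel()


def unbinarize(bits: np.ndarray, rows: int, cols: int) -> FeatureMatrix:
    """Invert :func:`binarize` back to the cell-code matrix."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size != rows * cols * N_CATEGORIES:
        raise ValidationError(
            f"expected {rows * cols * N_CATEGORIES} bits, got {bits.size}")
    blocks = bits.reshape(rows * cols, N_CATEGORIES)
    if (blocks.sum(axis=1) > 1).any():
        raise ValidationError("more than one bit set in a cell block")
    cells = np.where(blocks.sum(axis=1) > 0, blocks.argmax(axis=1) + 1, 0)
    return FeatureMatrix(cells.reshape(rows, cols))


#: Min-max scaling ranges for the three record attributes.
_ATTR_RANGES = {"category": (1, 5), "day_of_week": (1, 7), "hour": (0, 23)}


DEFAULT_ATTRIBUTES = ("category", "day_of_week", "hour")


def record_vectors(records: Sequence[TifRecord],
                   attributes: Sequence[str] = DEFAULT_ATTRIBUTES,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Record attribute vectors (min-max scaled to [0, 1]) plus categories.

    The default input concatenates category, day-of-week and hour.  Only
    the category carries class signal; day and hour spread a user's
    records across the map so that per-cell category tallies (and hence
    the dominant-type matrix) reflect the user's category mixture rather
    than collapsing every category onto a single unit.  Any attribute
    subset may be selected instead.
    """
    unknown = set(attributes) - set(_ATTR_RANGES)
    if unknown:
        raise ValidationError(f"unknown attributes {sorted(unknown)}")
    if not records:
        raise ValidationError("no records to vectorize")
    rows = []
    for r in records:
        derived = derive_attributes(r)
        values = {"category": r.category,
                  "day_of_week": derived.day_of_week,
                  "hour": derived.hour}
        rows.append([
            (values[a] - _ATTR_RANGES[a][0])
            / (_ATTR_RANGES[a][1] - _ATTR_RANGES[a][0])
            for a in attributes
        ])
    cats = np.array([r.category for r in records], dtype=int)
    return np.asarray(rows, dtype=float), cats
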