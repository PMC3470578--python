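"""Deterministic Kohonen self-organizing map.

Linear PCA initialization (first two principal axes spanning width and
height), sequential competitive learning with a Gaussian neighborhood and
linearly decaying adaptation gain and radius. There is no randomness
anywhere: identical inputs produce byte-identical grids and assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "SOMGrid",
    "TrainingSchedule",
    "default_schedule",
    "linear_initialize",
    "neighborhood",
    "train",
    "assign",
    "quantization_error",
]

logger = logging.getLogger(__name__)

#: target number of profile presentations for the default schedule
DEFAULT_TOTAL_ITERATIONS = 200_000


@dataclass
class SOMGrid:
    """Rectangular lattice of meta-EPs (codebook vectors).

    Node k sits at grid coordinates (row, col) = (k // width, k % width);
    ``weights`` has one row per node.
    """

    width: int
    height: int
    weights: np.ndarray  # (K, D)

    def __post_init__(self):
        if self.weights.shape[0] != self.width * self.height:
            raise ValidationError(
                f"weight rows {self.weights.shape[0]} != grid size {self.width * self.height}"
            )

    @property
    def n_nodes(self) -> int:
        return self.width * self.height

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def coords(self) -> np.ndarray:
        """(K, 2) array of (row, col) per node."""
        rows, cols = np.divmod(np.arange(self.n_nodes), self.width)
        return np.column_stack([rows, cols])

    def copy(self) -> "SOMGrid":
        return SOMGrid(self.width, self.height, self.weights.copy())


@dataclass
class TrainingSchedule:
    """Linearly interpolated learning parameters per epoch.

    Epoch e in [0, epochs) uses
    ``alpha = alpha_start + (alpha_end - alpha_start) * e / (epochs - 1)``
    (and likewise sigma); a single epoch uses the start values.
    """

    epochs: int
    alpha_start: float = 0.05
    alpha_end: float = 0.005
    sigma_start: float = 10.0
    sigma_end: float = 1.0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        # alpha 0 is allowed so a null-learning run can be expressed
        if not (0 <= self.alpha_end <= self.alpha_start <= 1):
            raise ValidationError("require 0 <= alpha_end <= alpha_start <= 1")
        if self.sigma_end <= 0 or self.sigma_start <= 0:
            raise ValidationError("sigma values must be > 0")
        if self.sigma_end > self.sigma_start:
            raise ValidationError("sigma schedule must be non-increasing")

    def at(self, epoch: int) -> tuple[float, float]:
        if self.epochs == 1:
            return self.alpha_start, self.sigma_start
        t = epoch / (self.epochs - 1)
        return (
            self.alpha_start + (self.alpha_end - self.alpha_start) * t,
            self.sigma_start + (self.sigma_end - self.sigma_start) * t,
        )


def default_schedule(n_profiles: int, grid_width: int = 40) -> TrainingSchedule:
    """Epochs chosen so epochs * n_profiles is close to 200,000 presentations."""
    if n_profiles <= 0:
        raise ValidationError("need at least one profile")
    epochs = max(1, round(DEFAULT_TOTAL_ITERATIONS / n_profiles))
    if n_profiles > DEFAULT_TOTAL_ITERATIONS:
        logger.warning(
            "profile count %d exceeds the iteration budget; using a single epoch", n_profiles
        )
    return TrainingSchedule(epochs=epochs, sigma_start=max(1.0, grid_width / 4))


def linear_initialize(
    profiles: np.ndarray, grid_shape: tuple[int, int], span: float = 2.0
) -> SOMGrid:
    """PCA-based deterministic initialization.

    The first principal axis varies along the grid width (columns), the second
    along the height (rows); positions map linearly onto [-1, +1] scaled by
    ``span * sqrt(eigenvalue)``, so the data mean sits at the grid center.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValidationError("profiles must be a non-empty 2-D array")
    width, height = grid_shape
    if width < 1 or height < 1:
        raise ValidationError("grid dimensions must be positive")
    mu = X.mean(axis=0)
    centered = X - mu
    cov = centered.T @ centered / max(1, X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    lam1 = eigvals[0] if len(eigvals) else 0.0
    u1 = eigvecs[:, 0] if len(eigvals) else np.zeros_like(mu)
    if len(eigvals) > 1 and eigvals[1] > 1e-12 * max(lam1, 1.0):
        lam2, u2 = eigvals[1], eigvecs[:, 1]
    else:
        logger.warning("second principal component is degenerate; using a flat axis")
        lam2 = 0.0
        u2 = eigvecs[:, 1] if eigvecs.shape[1] > 1 else np.zeros_like(u1)
    a = np.linspace(-1.0, 1.0, width) if width > 1 else np.zeros(1)
    b = np.linspace(-1.0, 1.0, height) if height > 1 else np.zeros(1)
    col_term = np.outer(a, span * np.sqrt(lam1) * u1)  # (width, D)
    row_term = np.outer(b, span * np.sqrt(lam2) * u2)  # (height, D)
    weights = (mu[None, None, :] + row_term[:, None, :] + col_term[None, :, :]).reshape(
        height * width, -1
    )
    return SOMGrid(width, height, weights)


def neighborhood(node_a, node_b, sigma: float) -> float:
    """Gaussian neighborhood exp(-d^2 / (2 sigma^2)) over grid distance; 1 at d=0."""
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    a = np.asarray(node_a, dtype=float)
    b = np.asarray(node_b, dtype=float)
    d2 = float(np.sum((a - b) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma * sigma)))


def assign(profiles: np.ndarray, grid: SOMGrid) -> np.ndarray:
    """Best-matching node per profile by squared Euclidean distance, ties to lowest index."""
    X = np.asarray(profiles, dtype=float)
    # ||x - w||^2 = ||x||^2 - 2 x.w + ||w||^2 ; the ||x||^2 term is constant per row
    w_norm = np.einsum("kd,kd->k", grid.weights, grid.weights)
    scores = -2.0 * X @ grid.weights.T + w_norm[None, :]
    return np.argmin(scores, axis=1)


def train(
    profiles: np.ndarray, grid: SOMGrid, schedule: TrainingSchedule
) -> tuple[SOMGrid, np.ndarray]:
    """Sequential Kohonen learning.

    Per epoch the gain and radius are fixed; profiles are presented in input
    order. For each presentation the winner j* minimizes the squared Euclidean
    distance (ties break to the lowest node index) and every meta-EP moves by
    ``x_k += alpha * h(k, j*; sigma) * (e - x_k)``. After the final epoch the
    assignment is recomputed once with frozen meta-EPs.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValidationError("profiles must be a non-empty 2-D array")
    if X.shape[1] != grid.dim:
        raise ValidationError(
            f"profile dimension {X.shape[1]} != meta-EP dimension {grid.dim}"
        )
    grid = grid.copy()
    W = grid.weights
    coords = grid.coords().astype(float)
    # pairwise squared grid distances, reused across epochs
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    for epoch in range(schedule.epochs):
        alpha, sigma = schedule.at(epoch)
        H = np.exp(-d2 / (2.0 * sigma * sigma))
        for x in X:
            diff = W - x
            winner = int(np.argmin(np.einsum("kd,kd->k", diff, diff)))
            W -= (alpha * H[winner])[:, None] * diff
    assignment = assign(X, grid)
    return grid, assignment


def quantization_error(profiles: np.ndarray, grid: SOMGrid, assignment: np.ndarray) -> float:
    """Mean Euclidean distance between each EP and its assigned meta-EP."""
    X = np.asarray(profiles, dtype=float)
    if len(assignment) != len(X):
        raise ValidationError("assignment length mismatch")
    diffs = X - grid.weights[assignment]
    return float(np.mean(np.linalg.norm(diffs, axis=1)))
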