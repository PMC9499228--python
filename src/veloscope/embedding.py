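"""Velocity-embedding procedures: linear, nonlinear-softmax, and Boolean.

A cell's high-dimensional velocity can be rendered in a 2-D embedding in two
ways.  If the embedding is a deterministic map ``E`` (PCA on log1p counts),
the *linear* procedure projects the extrapolated state and takes the
difference ``V_i = E(s_i + v_i dt*) - E(s_i)``.  For arbitrary embeddings the
*nonlinear* procedure weights the directions to the ``k`` nearest embedding
neighbors by the concordance between each neighbor displacement
``s_q - s_i`` (in the high-dimensional space) and the cell's velocity
displacement ``delta_s_i``; the weights are a softmax with kernel width
``sigma`` of either a Pearson correlation after a variance-stabilizing
transform, or of the *Boolean* fraction of sign-concordant coordinates.

An optional density correction subtracts the uniform-weight mean neighbor
displacement, so a cell whose velocity carries no directional information
(uniform weights) gets a zero arrow.  Cell arrows can be aggregated on a
regular grid with a Gaussian kernel over the nearest cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .pipeline import PCABasis, knn_neighbors

logger = logging.getLogger(__name__)

__all__ = [
    "EmbedConfig",
    "ArrowField",
    "linear_velocity_embedding",
    "transition_weights",
    "boolean_concordance",
    "nonlinear_velocity_embedding",
    "grid_aggregate",
]


@dataclass(frozen=True)
class EmbedConfig:
    k_embed_neighbors: int = 150
    sigma: float = 0.05
    transform: str = "sqrt"  # one of {"sqrt", "log", "none"}
    grid_shape: tuple[int, int] = (20, 20)
    grid_neighbors: int = 100
    grid_smoothing: float = 0.5
    density_correction: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.k_embed_neighbors < 1:
            raise ValueError("sigma must be > 0 and k >= 1")
        if self.transform not in ("sqrt", "log", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class ArrowField:
    """Per-cell 2-D arrows, optionally aggregated on a regular grid."""

    cell_coords: np.ndarray
    cell_arrows: np.ndarray
    method: str
    grid_points: np.ndarray | None = None
    grid_arrows: np.ndarray | None = None


def _variance_stabilize(x: np.ndarray, transform: str) -> np.ndarray:
    """Signed variance-stabilizing transform (handles negative displacements)."""
    if transform == "sqrt":
        return np.sign(x) * np.sqrt(np.abs(x))
    if transform == "log":
        return np.sign(x) * np.log1p(np.abs(x))
    return x


def linear_velocity_embedding(
    spliced: np.ndarray,
    extrapolated_spliced: np.ndarray,
    basis: PCABasis,
) -> ArrowField:
    """Arrows ``V_i = E(s_i + v_i dt*) - E(s_i)`` in a deterministic PCA basis.

    Both matrices must live in the count space the basis was built from; the
    extrapolated matrix must be non-negative (pre-clipped by the bounded
    extrapolation step).
    """
    if np.any(np.asarray(extrapolated_spliced) < 0):
        raise ValueError("extrapolated spliced matrix contains negative entries")
    coords = basis.transform(spliced)[:, :2]
    dest = basis.transform(extrapolated_spliced)[:, :2]
    return ArrowField(cell_coords=coords, cell_arrows=dest - coords, method="linear")


def boolean_concordance(displacement: np.ndarray, delta_s: np.ndarray) -> float:
    """Fraction of coordinates with matching signs (sign in {-1, 0, 1})."""
    displacement = np.asarray(displacement)
    delta_s = np.asarray(delta_s)
    if displacement.shape != delta_s.shape or displacement.size == 0:
        raise ValueError("need two equal-length, non-empty vectors")
    return float(np.mean(np.sign(displacement) == np.sign(delta_s)))


def _pearson_rows(d: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Correlation of each row of ``d`` (k, N) with the vector ``v`` (N,).

    Rows (or ``v``) with zero variance yield a neutral concordance of 0; these
    degenerate cases are logged by the caller.
    """
    dc = d - d.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    dn = np.sqrt((dc**2).sum(axis=1))
    vn = np.sqrt((vc**2).sum())
    out = np.zeros(d.shape[0])
    if vn == 0:
        return out
    valid = dn > 0
    out[valid] = (dc[valid] @ vc) / (dn[valid] * vn)
    return out


def transition_weights(
    displacements: np.ndarray,
    delta_s: np.ndarray,
    config: EmbedConfig | None = None,
    mode: str = "correlation",
) -> np.ndarray:
    """Softmax weights over one cell's neighbor displacements.

    ``displacements`` is (k, N): high-dimensional displacements ``s_q - s_i``
    to the ``k`` embedding neighbors; ``delta_s`` is the cell's velocity
    displacement (N,).  Concordance is the Pearson correlation after the
    configured variance-stabilizing transform (``mode="correlation"``) or the
    fraction of matching signs (``mode="boolean"``); weights are
    ``softmax(r / sigma)`` and sum to 1.
    """
    config = config or EmbedConfig()
    displacements = np.asarray(displacements, dtype=float)
    delta_s = np.asarray(delta_s, dtype=float)
    if mode == "correlation":
        d = _variance_stabilize(displacements, config.transform)
        v = _variance_stabilize(delta_s, config.transform)
        r = _pearson_rows(d, v)
    elif mode == "boolean":
        r = np.mean(np.sign(displacements) == np.sign(delta_s), axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    e = np.exp((r - r.max()) / config.sigma)
    return e / e.sum()


def nonlinear_velocity_embedding(
    embedding_coords: np.ndarray,
    high_dim: np.ndarray,
    delta_s: np.ndarray,
    config: EmbedConfig | None = None,
    mode: str = "correlation",
) -> ArrowField:
    """Expected embedded displacement under concordance-weighted transitions.

    Works in any 2-D embedding (PCA/t-SNE/UMAP coordinates).  For each cell,
    the arrow is the weighted mean of directions to its ``k`` nearest
    embedding neighbors, weighted by :func:`transition_weights`; with the
    density correction on, the uniform-weight mean direction is subtracted.
    Cells with a zero-norm velocity displacement get zero arrows.
    """
    config = config or EmbedConfig()
    coords = np.asarray(embedding_coords, dtype=float)
    high_dim = np.asarray(high_dim, dtype=float)
    delta_s = np.asarray(delta_s, dtype=float)
    n = coords.shape[0]
    neighbors = knn_neighbors(coords, config.k_embed_neighbors)
    arrows = np.zeros((n, 2))
    n_zero = 0
    for i in range(n):
        nb = neighbors[i]
        directions = coords[nb] - coords[i]
        if not np.any(delta_s[i]):
            n_zero += 1
            continue
        w = transition_weights(
            high_dim[nb] - high_dim[i], delta_s[i], config, mode=mode
        )
        arrows[i] = w @ directions
        if config.density_correction:
            arrows[i] -= directions.mean(axis=0)
    if n_zero:
        logger.info("nonlinear embedding: %d cells with zero delta_s", n_zero)
    method = "boolean" if mode == "boolean" else "nonlinear"
    return ArrowField(cell_coords=coords, cell_arrows=arrows, method=method)


def grid_aggregate(
    field: ArrowField, config: EmbedConfig | None = None
) -> ArrowField:
    """Aggregate cell arrows on a regular grid with a Gaussian kernel.

    For each grid point the arrow is the kernel-weighted mean over the
    ``grid_neighbors`` nearest cells, with bandwidth ``grid_smoothing`` times
    the mean grid spacing.
    """
    config = config or EmbedConfig()
    coords = field.cell_coords
    if coords.shape[0] < 1:
        raise ValueError("need at least one cell arrow")
    gx, gy = config.grid_shape
    xs = np.linspace(coords[:, 0].min(), coords[:, 0].max(), gx)
    ys = np.linspace(coords[:, 1].min(), coords[:, 1].max(), gy)
    spacing = 0.5 * (
        (xs[1] - xs[0] if gx > 1 else 1.0) + (ys[1] - ys[0] if gy > 1 else 1.0)
    )
    bandwidth = config.grid_smoothing * max(spacing, 1e-12)
    grid = np.array([(x, y) for x in xs for y in ys])
    d = cdist(grid, coords)
    k = min(config.grid_neighbors, coords.shape[0])
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    rows = np.arange(grid.shape[0])[:, None]
    w = np.exp(-0.5 * (d[rows, order] / bandwidth) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    grid_arrows = np.einsum("gk,gkd->gd", w, field.cell_arrows[order])
    return ArrowField(
        cell_coords=coords,
        cell_arrows=field.cell_arrows,
        method=field.method,
        grid_points=grid,
        grid_arrows=grid_arrows,
    )
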