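"""A transparent reimplementation of the velocyto-style estimation chain.

Steps, each exposed as a plain function over dense arrays:

1. filtering of low-count cells and genes, plus CV-vs-mean gene selection;
2. per-species count normalization (each cell's total rescaled to the dataset
   mean total, separately for spliced and unspliced);
3. PCA on log1p spliced counts, with a deterministic sign convention and
   out-of-sample projection;
4. k-nearest-neighbor pooling ("imputation") in the principal-component space,
   with the anchor cell included in its own pool;
5. per-gene linear fits of unspliced on spliced — on extremal quantiles of the
   imputed data (the steady-state heuristic for ``gamma/beta``) or on the full
   data — and cell-level velocities ``v_ij = u_ij - (gamma_j/beta_j s_ij + q_j)``;
6. a bounded extrapolation time ``dt* = min_{ij} s_ij/|v_ij|`` over entries
   with appreciably negative velocity, guaranteeing the extrapolated spliced
   state stays non-negative.

Neighbor ties are broken by ascending cell index throughout, making the whole
chain bit-deterministic for a fixed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ProcessedData",
    "GeneFit",
    "VelocityField",
    "PCABasis",
    "filter_cells_genes",
    "normalize_counts",
    "compute_pca",
    "knn_neighbors",
    "knn_impute",
    "fit_gamma_extrema",
    "fit_gamma_full",
    "compute_velocity",
    "extrapolation_time",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    cell_percentile_floor: float = 0.5
    min_gene_spliced_counts: int = 40
    min_cells_expressing: int = 30
    n_top_genes: int = 2000
    max_mean_expression: float = 35.0
    n_pcs: int = 25
    k_impute: int = 50
    do_filter: bool = True
    normalize: bool = False
    extremal_quantiles: tuple[float, float] = (0.05, 0.95)
    delta_t: float = 1.0
    floor: float = 1e-6
    corr_gene_filter: bool = False  # optional spliced-unspliced corr > 0.05 gate
    corr_threshold: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.extremal_quantiles
        if not (0 < lo <= 0.5 and 0.5 <= hi < 1):
            raise ValueError("extremal quantiles must straddle the median in (0,1)")
        if self.k_impute < 0 or self.n_pcs < 2:
            raise ValueError("k_impute must be >= 0 and n_pcs >= 2")


@dataclass
class GeneFit:
    """Per-gene linear fit ``u = slope * s + offset`` (slope estimates gamma/beta)."""

    slope: float
    offset: float
    method: str
    cells_used: np.ndarray
    ok: bool = True


@dataclass
class VelocityField:
    """Cell x gene velocities with a bounded physical extrapolation time."""

    v: np.ndarray
    delta_t_star: float
    extrapolated_spliced: np.ndarray
    failed_genes: np.ndarray


@dataclass
class PCABasis:
    """Centered PCA basis over log1p counts, with deterministic signs."""

    components: np.ndarray  # (n_pcs, n_features)
    mean: np.ndarray        # (n_features,) mean of log1p counts
    explained_variance: np.ndarray

    @property
    def n_features(self) -> int:
        return self.components.shape[1]

    def transform(self, counts: np.ndarray) -> np.ndarray:
        """Project raw (non-negative) counts: log1p, center, rotate."""
        x = np.log1p(np.asarray(counts, dtype=float))
        return (x - self.mean) @ self.components.T


@dataclass
class ProcessedData:
    """State of the processing chain, from filtering through imputation."""

    spliced: np.ndarray
    unspliced: np.ndarray
    cell_index: np.ndarray
    gene_index: np.ndarray
    basis: PCABasis | None = None
    pc_coords: np.ndarray | None = None
    neighbor_lists: np.ndarray | None = None
    imputed_spliced: np.ndarray | None = None
    imputed_unspliced: np.ndarray | None = None
    config: PipelineConfig | None = None


def filter_cells_genes(
    spliced: np.ndarray,
    unspliced: np.ndarray,
    config: PipelineConfig | None = None,
) -> ProcessedData:
    """Apply the cell and gene filters, in order.

    Cells below the ``cell_percentile_floor`` percentile of total unspliced
    counts are removed first.  Genes then need at least
    ``min_gene_spliced_counts`` total spliced counts and expression (spliced
    count > 0) in at least ``min_cells_expressing`` cells.  Finally the top
    ``n_top_genes`` genes by coefficient-of-variation-vs-mean score (residual
    above a log-log power-law fit of CV on mean) are kept, among genes whose
    mean spliced expression does not exceed ``max_mean_expression``.
    """
    config = config or PipelineConfig()
    spliced = np.asarray(spliced)
    unspliced = np.asarray(unspliced)

    cell_totals = unspliced.sum(axis=1)
    threshold = np.percentile(cell_totals, config.cell_percentile_floor)
    keep_cells = np.flatnonzero(cell_totals >= threshold)
    if keep_cells.size == 0:
        raise ValueError("cell total-count filter removed every cell")
    s = spliced[keep_cells]
    u = unspliced[keep_cells]
    logger.info("cell filter kept %d/%d cells", keep_cells.size, spliced.shape[0])

    gene_ok = (s.sum(axis=0) >= config.min_gene_spliced_counts) & (
        (s > 0).sum(axis=0) >= config.min_cells_expressing
    )
    if config.corr_gene_filter:
        su = s - s.mean(axis=0)
        uu = u - u.mean(axis=0)
        denom = np.sqrt((su**2).sum(axis=0) * (uu**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, (su * uu).sum(axis=0) / denom, 0.0)
        gene_ok &= corr > config.corr_threshold
    keep_genes = np.flatnonzero(gene_ok)
    if keep_genes.size == 0:
        raise ValueError("gene count/expression filter removed every gene")
    logger.info("gene count filter kept %d/%d genes", keep_genes.size, s.shape[1])

    if keep_genes.size > config.n_top_genes:
        sk = s[:, keep_genes]
        mean = sk.mean(axis=0)
        sd = sk.std(axis=0, ddof=0)
        eligible = mean <= config.max_mean_expression
        with np.errstate(divide="ignore"):
            log_mean = np.log(mean)
            log_cv = np.log(sd / mean)
        a, b = np.polyfit(log_mean[eligible], log_cv[eligible], 1)
        score = np.where(eligible, log_cv - (a * log_mean + b), -np.inf)
        order = np.argsort(-score, kind="stable")[: config.n_top_genes]
        keep_genes = keep_genes[np.sort(order)]
        logger.info("CV-vs-mean selection kept %d genes", keep_genes.size)

    return ProcessedData(
        spliced=s[:, keep_genes],
        unspliced=u[:, keep_genes],
        cell_index=keep_cells,
        gene_index=keep_genes,
        config=config,
    )


def normalize_counts(matrix: np.ndarray) -> np.ndarray:
    """Rescale each cell's total to the dataset mean total (one species)."""
    matrix = np.asarray(matrix, dtype=float)
    totals = matrix.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("cannot normalize a cell with zero total counts")
    return matrix * (totals.mean() / totals)[:, None]


def compute_pca(spliced: np.ndarray, n_pcs: int = 25) -> tuple[np.ndarray, PCABasis]:
    """Centered PCA of log1p spliced counts with a fixed sign convention.

    Each component's sign is flipped so that its largest-magnitude loading is
    positive, making results reproducible across runs and platforms.  Returns
    the cell coordinates and a :class:`PCABasis` usable for out-of-sample
    projection of extrapolated states.
    """
    x = np.log1p(np.asarray(spliced, dtype=float))
    mean = x.mean(axis=0)
    xc = x - mean
    rank = min(xc.shape)
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds the matrix rank bound {rank}")
    _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    comps = vt[:n_pcs]
    flip = np.sign(comps[np.arange(n_pcs), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    basis = PCABasis(
        components=comps,
        mean=mean,
        explained_variance=(svals[:n_pcs] ** 2) / max(1, xc.shape[0] - 1),
    )
    return xc @ comps.T, basis


def knn_neighbors(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` nearest neighbors per row (self excluded).

    Euclidean distance; ties broken by ascending cell index via a stable sort.
    """
    n = coords.shape[0]
    if not 0 <= k < n:
        raise ValueError("need 0 <= k < n_cells")
    if k == 0:
        return np.empty((n, 0), dtype=np.int64)
    d = cdist(coords, coords)
    order = np.argsort(d, axis=1, kind="stable")
    neighbors = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = order[i]
        neighbors[i] = row[row != i][:k]
    return neighbors


def knn_impute(
    matrices: tuple[np.ndarray, ...] | np.ndarray,
    pc_coords: np.ndarray,
    k: int,
    neighbor_lists: np.ndarray | None = None,
):
    """Pool each cell with its ``k`` nearest PCA neighbors (self included).

    Every value is replaced by the mean over ``{cell} + its k neighbors``;
    ``k = 0`` returns the input unchanged.  Passing a tuple of matrices pools
    each against the same neighbor sets.
    """
    single = isinstance(matrices, np.ndarray)
    mats = (matrices,) if single else tuple(matrices)
    if neighbor_lists is None:
        neighbor_lists = knn_neighbors(pc_coords, k)
    if neighbor_lists.shape[1] == 0:
        out = tuple(np.asarray(m, dtype=float).copy() for m in mats)
        return out[0] if single else out
    pool = np.concatenate(
        [np.arange(neighbor_lists.shape[0])[:, None], neighbor_lists], axis=1
    )
    out = tuple(np.asarray(m, dtype=float)[pool].mean(axis=1) for m in mats)
    return out[0] if single else out


def _ols_line(u: np.ndarray, s: np.ndarray) -> tuple[float, float] | None:
    s_mean = s.mean()
    var = ((s - s_mean) ** 2).sum()
    if var < 1e-12 * max(1.0, s_mean**2) or s.size < 2:
        return None
    slope = ((s - s_mean) * (u - u.mean())).sum() / var
    return float(slope), float(u.mean() - slope * s_mean)


def fit_gamma_extrema(
    imputed_u: np.ndarray,
    imputed_s: np.ndarray,
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> list[GeneFit]:
    """Per-gene OLS of u on s restricted to the extremal spliced quantiles.

    Cells whose imputed spliced value lies at or below the low quantile, or at
    or above the high quantile, are presumed near the steady states of the low
    and high transcription regimes; the fitted slope estimates ``gamma/beta``
    and the intercept is the offset ``q``.  Genes with constant spliced values
    among the extrema are flagged (``ok=False``) rather than fit.
    """
    lo_q, hi_q = quantiles
    fits = []
    for j in range(imputed_s.shape[1]):
        s = imputed_s[:, j]
        lo, hi = np.quantile(s, [lo_q, hi_q])
        cells = np.flatnonzero((s <= lo) | (s >= hi))
        line = _ols_line(imputed_u[cells, j], s[cells])
        if line is None:
            fits.append(GeneFit(np.nan, np.nan, "extremal", cells, ok=False))
        else:
            fits.append(GeneFit(line[0], line[1], "extremal", cells))
    return fits


def fit_gamma_full(u: np.ndarray, s: np.ndarray) -> list[GeneFit]:
    """Per-gene OLS of u on s over every cell (the k=0 / raw baseline)."""
    fits = []
    all_cells = np.arange(u.shape[0])
    for j in range(s.shape[1]):
        line = _ols_line(u[:, j], s[:, j])
        if line is None:
            fits.append(GeneFit(np.nan, np.nan, "full", all_cells, ok=False))
        else:
            fits.append(GeneFit(line[0], line[1], "full", all_cells))
    return fits


def compute_velocity(
    imputed_u: np.ndarray,
    imputed_s: np.ndarray,
    fits: list[GeneFit],
) -> tuple[np.ndarray, np.ndarray]:
    """Cell x gene velocities ``v_ij = u_ij - (slope_j s_ij + q_j)``.

    Genes whose fit failed get zero velocity; their indices are returned (and
    logged) so downstream consumers can exclude them.
    """
    slopes = np.array([f.slope for f in fits])
    offsets = np.array([f.offset for f in fits])
    ok = np.array([f.ok for f in fits])
    v = np.where(
        ok[None, :],
        imputed_u - (np.where(ok, slopes, 0.0)[None, :] * imputed_s
                     + np.where(ok, offsets, 0.0)[None, :]),
        0.0,
    )
    failed = np.flatnonzero(~ok)
    if failed.size:
        logger.info("velocity: %d genes with failed fits zeroed: %s",
                    failed.size, failed.tolist())
    return v, failed


def extrapolation_time(
    s_matrix: np.ndarray,
    v_matrix: np.ndarray,
    floor: float = 1e-6,
    fallback_delta_t: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Largest extrapolation time keeping every spliced value non-negative.

    ``dt* = min_{ij} s_ij / |v_ij|`` over entries with ``v_ij < -floor``; if no
    velocity is appreciably negative the conventional ``dt = 1`` is used.  The
    displacement is zeroed where ``s_ij < floor`` and ``v_ij < -floor`` (such
    entries are excluded from the minimum, which they would otherwise pin at
    zero), and residual negatives below the numeric floor are clipped at zero.
    """
    s = np.asarray(s_matrix, dtype=float)
    v = np.asarray(v_matrix, dtype=float)
    if s.shape != v.shape:
        raise ValueError("s and v must have the same shape")
    neg = v < -floor
    bounded = neg & (s >= floor)
    if np.any(bounded):
        delta_t_star = float((s[bounded] / np.abs(v[bounded])).min())
    else:
        delta_t_star = float(fallback_delta_t)
    delta_s = v * delta_t_star
    delta_s[neg & (s < floor)] = 0.0
    extrapolated = np.maximum(s + delta_s, 0.0)
    return delta_t_star, extrapolated


def run_pipeline(
    spliced: np.ndarray,
    unspliced: np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[ProcessedData, list[GeneFit], VelocityField]:
    """Run the full estimation chain on a pair of count matrices."""
    config = config or PipelineConfig()
    if config.do_filter:
        processed = filter_cells_genes(spliced, unspliced, config)
    else:
        processed = ProcessedData(
            spliced=np.asarray(spliced),
            unspliced=np.asarray(unspliced),
            cell_index=np.arange(np.asarray(spliced).shape[0]),
            gene_index=np.arange(np.asarray(spliced).shape[1]),
            config=config,
        )
    s, u = processed.spliced.astype(float), processed.unspliced.astype(float)
    if config.normalize:
        s = normalize_counts(s)
        u = normalize_counts(u)
    coords, basis = compute_pca(s, config.n_pcs)
    neighbors = knn_neighbors(coords, config.k_impute)
    imp_s, imp_u = knn_impute((s, u), coords, config.k_impute, neighbors)
    processed.basis = basis
    processed.pc_coords = coords
    processed.neighbor_lists = neighbors
    processed.imputed_spliced = imp_s
    processed.imputed_unspliced = imp_u

    fits = fit_gamma_extrema(imp_u, imp_s, config.extremal_quantiles)
    v, failed = compute_velocity(imp_u, imp_s, fits)
    delta_t_star, extrapolated = extrapolation_time(
        imp_s, v, floor=config.floor, fallback_delta_t=config.delta_t
    )
    field = VelocityField(
        v=v,
        delta_t_star=delta_t_star,
        extrapolated_spliced=extrapolated,
        failed_genes=failed,
    )
    return processed, fits, field
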