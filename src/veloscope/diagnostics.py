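"""Quantitative controls for velocity workflows.

* Jaccard degradation of k-nearest-neighborhoods along the processing chain
  (ambient counts -> PCA -> 2-D), quantifying how much of the local structure
  the embeddings that velocity arrows live in actually preserve.
* Angle deviations between paired 2-D arrow fields (e.g. a nonlinear
  embedding against the linear baseline, or against ground-truth arrows).
* The inferred fraction of upregulated cells per gene — the sign-level
  classifier that tends to be more stable than the fitted slope itself.
* A k-sweep of the imputation neighborhood, tracking the stability of the
  fitted gamma/beta and of the upregulated fraction.
* Moment recovery: fold deviations of kNN-pooled means/variances against the
  true instantaneous moments of a simulated dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pipeline import (
    GeneFit,
    PipelineConfig,
    compute_pca,
    fit_gamma_extrema,
    fit_gamma_full,
    knn_impute,
    knn_neighbors,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborhoodReport",
    "KSweepReport",
    "MomentRecoveryReport",
    "jaccard_distance",
    "knn_index_sets",
    "neighborhood_degradation",
    "angle_deviation",
    "upregulated_fraction",
    "k_sweep",
    "moment_recovery",
]


def jaccard_distance(set_a, set_b) -> float:
    """``d_J = (|A u B| - |A n B|) / |A u B|``; 0 for identical, 1 for disjoint."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("both sets are empty")
    return (len(union) - len(a & b)) / len(union)


def knn_index_sets(coords: np.ndarray, k: int) -> list[set]:
    """Per-cell k-nearest-neighbor index sets (anchor excluded, ties by index)."""
    return [set(row) for row in knn_neighbors(np.asarray(coords, float), k)]


@dataclass
class NeighborhoodReport:
    """Per-cell Jaccard distances for every ordered pair of stages."""

    stage_names: list[str]
    k: int
    distances: dict[tuple[str, str], np.ndarray]

    def mean(self, pair: tuple[str, str]) -> float:
        return float(self.distances[pair].mean())


def neighborhood_degradation(
    stages: list[tuple[str, np.ndarray]], k: int = 150
) -> NeighborhoodReport:
    """Jaccard distances between kNN sets of successive data representations.

    ``stages`` is an ordered list of (name, coords) over the same cells, e.g.
    [("ambient", log counts), ("pca", 25 PCs), ("embedding", 2-D coords)].
    Distances are computed for every ordered pair of stages.
    """
    n = stages[0][1].shape[0]
    if any(c.shape[0] != n for _, c in stages):
        raise ValueError("all representations must cover the same cells")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    sets = {name: knn_index_sets(coords, k) for name, coords in stages}
    names = [name for name, _ in stages]
    distances = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            distances[(a, b)] = np.array(
                [jaccard_distance(sets[a][c], sets[b][c]) for c in range(n)]
            )
    return NeighborhoodReport(stage_names=names, k=k, distances=distances)


def angle_deviation(arrows_a: np.ndarray, arrows_b: np.ndarray) -> np.ndarray:
    """Per-cell angles (degrees, [0, 180]) between paired 2-D arrow fields.

    Cells where either arrow has zero norm are excluded (and logged), not
    reported as zero degrees.
    """
    a = np.asarray(arrows_a, dtype=float)
    b = np.asarray(arrows_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("arrow fields must be paired")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    valid = (na > 0) & (nb > 0)
    if not np.all(valid):
        logger.info("angle deviation: excluded %d zero-norm arrows",
                    int((~valid).sum()))
    cosines = (a[valid] * b[valid]).sum(axis=1) / (na[valid] * nb[valid])
    return np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0)))


def upregulated_fraction(u: np.ndarray, s: np.ndarray, fit: GeneFit) -> float:
    """Fraction of cells strictly above the fitted line ``u = slope*s + q``."""
    return float(np.mean(u - (fit.slope * s + fit.offset) > 0))


@dataclass
class KSweepReport:
    k_values: list[int]
    slopes: np.ndarray          # (n_k, n_genes)
    upregulated: np.ndarray     # (n_k, n_genes)

    def cv_across_k(self, values: np.ndarray) -> np.ndarray:
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(np.abs(mean) > 0, sd / np.abs(mean), np.nan)

    @property
    def slope_cv(self) -> np.ndarray:
        return self.cv_across_k(self.slopes)

    @property
    def upregulated_cv(self) -> np.ndarray:
        return self.cv_across_k(self.upregulated)


def k_sweep(
    spliced: np.ndarray,
    unspliced: np.ndarray,
    k_values=(0, 5, 50, 150, 300, 550),
    config: PipelineConfig | None = None,
) -> KSweepReport:
    """Fit gamma/beta and the upregulated fraction across pooling sizes ``k``.

    ``k = 0`` is the raw case: ordinary regression on the unpooled data.  For
    ``k > 0`` counts are pooled over PCA neighborhoods and the extremal
    quantile fit is applied.  The PCA space is computed once from the raw
    log1p spliced counts, so only the pooling varies.
    """
    config = config or PipelineConfig(do_filter=False)
    s = np.asarray(spliced, dtype=float)
    u = np.asarray(unspliced, dtype=float)
    coords, _ = compute_pca(s, config.n_pcs)
    slopes = np.full((len(k_values), s.shape[1]), np.nan)
    upreg = np.full_like(slopes, np.nan)
    for row, k in enumerate(k_values):
        if k == 0:
            imp_s, imp_u = s, u
            fits = fit_gamma_full(imp_u, imp_s)
        else:
            imp_s, imp_u = knn_impute((s, u), coords, k)
            fits = fit_gamma_extrema(imp_u, imp_s, config.extremal_quantiles)
        for j, fit in enumerate(fits):
            if fit.ok:
                slopes[row, j] = fit.slope
                upreg[row, j] = upregulated_fraction(imp_u[:, j], imp_s[:, j], fit)
    return KSweepReport(k_values=list(k_values), slopes=slopes, upregulated=upreg)


def _fold_deviation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.maximum(a / b, b / a)


@dataclass
class MomentRecoveryReport:
    """Fold deviations of pooled moments against true instantaneous moments."""

    mean_folds_u: np.ndarray
    mean_folds_s: np.ndarray
    var_folds_u: np.ndarray
    var_folds_s: np.ndarray
    truth_floor: float

    @property
    def mean_folds(self) -> np.ndarray:
        return np.concatenate([self.mean_folds_u, self.mean_folds_s])

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.mean_folds, q))


def moment_recovery(
    dataset,
    imputed_u: np.ndarray,
    imputed_s: np.ndarray,
    neighbor_lists: np.ndarray,
    truth_floor: float = 0.1,
) -> MomentRecoveryReport:
    """Compare kNN-pooled means and variances with the true process moments.

    The pooled mean is the imputed value itself; the pooled variance is taken
    over each cell's pool (anchor plus neighbors) of raw counts.  Truth is the
    instantaneous Poisson moment ``mu(t_i)`` (variance equal to the mean).
    Fold deviations ``max(a/b, b/a)`` are collected for entries whose true
    moment is at least ``truth_floor``; the floor avoids division blow-up at
    near-zero means.  Pools with zero empirical variance against a positive
    true variance appear as infinite folds (flagged by the caller's
    percentile summaries).
    """
    mu_u, mu_s = dataset.true_means()
    pool = np.concatenate(
        [np.arange(neighbor_lists.shape[0])[:, None], neighbor_lists], axis=1
    )
    var_u_pooled = dataset.unspliced[pool].var(axis=1, ddof=0)
    var_s_pooled = dataset.spliced[pool].var(axis=1, ddof=0)

    sel_u = mu_u >= truth_floor
    sel_s = mu_s >= truth_floor
    return MomentRecoveryReport(
        mean_folds_u=_fold_deviation(imputed_u[sel_u], mu_u[sel_u]),
        mean_folds_s=_fold_deviation(imputed_s[sel_s], mu_s[sel_s]),
        var_folds_u=_fold_deviation(var_u_pooled[sel_u], mu_u[sel_u]),
        var_folds_s=_fold_deviation(var_s_pooled[sel_s], mu_s[sel_s]),
        truth_floor=truth_floor,
    )
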