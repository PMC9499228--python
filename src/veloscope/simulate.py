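"""Synthetic spliced/unspliced count datasets with known ground truth.

Three generators are provided, each drawing counts from the exact laws of the
models in :mod:`veloscope.models` (rather than from a stochastic simulation
algorithm, which the closed-form solutions make unnecessary):

* :func:`simulate_perturbation_reversion` — a perturbation/reversion process
  with cell-state structure A->B->A: all genes switch transcription rates at
  synchronized times ``tau_1 = 3`` and ``tau_2 = 7`` on a horizon ``T = 10``.
* :func:`simulate_multipotent` — A->B followed by a random terminal fate
  (C/D/E by default, equal probabilities), fates acting only after ``tau_2``.
* :func:`simulate_bursty_steady_state` — ten stationary "cell types"
  distinguished by burst frequencies and degradation rates; the ground-truth
  velocity is identically zero.

Rate parameters are drawn per gene from lognormal laws (transcription:
log-mean 0, log-sd 1; splicing: log-mean 1, log-sd 0.5; degradation: log-mean
0.5, log-sd 0.25 — splicing somewhat faster than degradation), and sampling
times uniformly on ``[0, T]``.  A single seed sequence is sub-streamed per
gene so that gene subsets are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    BurstModel,
    RateSchedule,
    bursty_moments,
    bursty_stationary_pmf,
    mean_trajectory,
)

__all__ = [
    "SimulationConfig",
    "BurstySimulationConfig",
    "SimulatedDataset",
    "simulate_perturbation_reversion",
    "simulate_multipotent",
    "simulate_bursty_steady_state",
    "ground_truth_principal_curve",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the transient (schedule-driven) simulations."""

    n_cells: int = 2000
    n_genes: int = 100
    horizon: float = 10.0
    switch_times: tuple[float, ...] = (3.0, 7.0)
    fate_probabilities: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    alpha_logmean: float = 0.0
    alpha_logsd: float = 1.0
    beta_logmean: float = 1.0
    beta_logsd: float = 0.5
    gamma_logmean: float = 0.5
    gamma_logsd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")
        if any(sd <= 0 for sd in (self.alpha_logsd, self.beta_logsd, self.gamma_logsd)):
            raise ValueError("distribution scales must be positive")
        fp = self.fate_probabilities
        if any(p < 0 for p in fp) or abs(sum(fp) - 1.0) > 1e-9:
            raise ValueError("fate probabilities must be >= 0 and sum to 1")


@dataclass(frozen=True)
class BurstySimulationConfig:
    """Study conditions for the stationary bursty simulation.

    Burst sizes are gene-specific and cell-type-independent; burst frequencies
    and degradation rates vary by cell type around gene-specific centers.  The
    splicing rate is fixed to 1 without loss of generality.  Parameter sets
    whose truncation area ``(mu_u + 5 sigma_u)(mu_s + 5 sigma_s)`` exceeds the
    rejection threshold are redrawn, capped at ``max_redraws`` attempts.
    """

    n_genes: int = 100
    n_cell_types: int = 10
    cells_per_type: int = 300
    burst_logmean: float = 0.3
    burst_logsd: float = 0.8
    burst_clip: tuple[float, float] = (0.05, 25.0)
    gamma_center_mean: float = -0.3
    gamma_center_sd: float = 0.3
    gamma_logsd: float = 0.1
    gamma_clip: tuple[float, float] = (0.08, 4.0)
    freq_logmean: float = -1.0
    freq_logsd: float = 0.5
    freq_clip: tuple[float, float] = (0.005, 1.0)
    reject_threshold: float = 1.5e4
    max_redraws: int = 1000
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return self.n_cell_types * self.cells_per_type


@dataclass
class SimulatedDataset:
    """Cell x gene spliced/unspliced counts with complete ground truth.

    ``gene_schedules`` maps each fate label to a list of per-gene
    :class:`RateSchedule` objects (transient simulations only).  For the
    stationary bursty simulation ``stationary`` is True, ``bursty_params``
    holds the per-gene / per-cell-type parameters, and the ground-truth
    velocity is zero by construction.
    """

    spliced: np.ndarray
    unspliced: np.ndarray
    cell_times: np.ndarray
    cell_fates: np.ndarray
    gene_schedules: dict[str, list[RateSchedule]]
    stationary: bool = False
    bursty_params: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spliced.shape != self.unspliced.shape:
            raise ValueError("spliced and unspliced shapes differ")
        if len(self.cell_times) != self.spliced.shape[0]:
            raise ValueError("cell_times length mismatch")

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[1]

    def true_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth instantaneous means ``(mu_u, mu_s)``, cell x gene."""
        mu_u = np.empty(self.spliced.shape, dtype=float)
        mu_s = np.empty_like(mu_u)
        if self.stationary:
            p = self.bursty_params
            for k, fate in enumerate(p["cell_types"]):
                rows = np.flatnonzero(self.cell_fates == fate)
                for j in range(self.n_genes):
                    m_u, m_s, _, _ = bursty_moments(
                        BurstModel(p["burst_size"][j]),
                        p["burst_freq"][j, k], p["beta"][j], p["gamma"][j, k],
                    )
                    mu_u[rows, j] = m_u
                    mu_s[rows, j] = m_s
            return mu_u, mu_s
        for fate, schedules in self.gene_schedules.items():
            rows = np.flatnonzero(self.cell_fates == fate)
            if rows.size == 0:
                continue
            for j, sched in enumerate(schedules):
                mu_u[rows, j], mu_s[rows, j] = mean_trajectory(
                    sched, self.cell_times[rows]
                )
        return mu_u, mu_s

    def true_gamma_beta(self) -> np.ndarray:
        """Ground-truth per-gene degradation-to-splicing ratio ``gamma/beta``."""
        if self.stationary:
            p = self.bursty_params
            return p["gamma"].mean(axis=1) / p["beta"]
        schedules = next(iter(self.gene_schedules.values()))
        return np.array([s.gamma / s.beta for s in schedules])

    def to_anndata(self):
        """Export as an AnnData with ``spliced``/``unspliced`` layers."""
        import anndata as ad
        import pandas as pd

        adata = ad.AnnData(
            X=self.spliced.astype(np.float64),
            layers={
                "spliced": self.spliced.copy(),
                "unspliced": self.unspliced.copy(),
            },
            obs=pd.DataFrame(
                {"process_time": self.cell_times, "fate": self.cell_fates},
                index=[f"cell_{i}" for i in range(self.n_cells)],
            ),
            var=pd.DataFrame(index=[f"gene_{j}" for j in range(self.n_genes)]),
        )
        if not self.stationary:
            schedules = next(iter(self.gene_schedules.values()))
            adata.var["beta"] = [s.beta for s in schedules]
            adata.var["gamma"] = [s.gamma for s in schedules]
        adata.uns["stationary"] = self.stationary
        adata.uns["seed"] = self.seed
        return adata


def _gene_streams(seed: int, n_genes: int):
    """One shared seed sequence, sub-streamed per gene plus a cell-level stream."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_genes + 1)
    return np.random.default_rng(children[0]), [
        np.random.default_rng(c) for c in children[1:]
    ]


def _draw_clipped_lognormal(rng, logmean, logsd, clip=None, size=None):
    x = rng.lognormal(logmean, logsd, size=size)
    if clip is not None:
        x = np.clip(x, *clip)
    return x


def simulate_perturbation_reversion(
    config: SimulationConfig | None = None,
) -> SimulatedDataset:
    """Perturbation/reversion (A->B->A) dataset with Poisson counts.

    Each gene carries a three-interval schedule ``(alpha_1, alpha_2, alpha_1)``
    with synchronized switch times.  Counts are independent Poissons with the
    exact instantaneous means — valid because the canonical solution is
    product-Poisson at every time.
    """
    config = config or SimulationConfig()
    cell_rng, gene_rngs = _gene_streams(config.seed, config.n_genes)
    times = cell_rng.uniform(0.0, config.horizon, size=config.n_cells)
    times.sort()

    spliced = np.empty((config.n_cells, config.n_genes), dtype=np.int64)
    unspliced = np.empty_like(spliced)
    schedules = []
    for j, rng in enumerate(gene_rngs):
        a1, a2 = _draw_clipped_lognormal(
            rng, config.alpha_logmean, config.alpha_logsd, size=2
        )
        beta = _draw_clipped_lognormal(rng, config.beta_logmean, config.beta_logsd)
        gamma = _draw_clipped_lognormal(rng, config.gamma_logmean, config.gamma_logsd)
        # empty switch_times gives the stationary (constant-rate) control
        alphas = (a1, a2, a1) if config.switch_times else (a1,)
        sched = RateSchedule(
            switch_times=config.switch_times,
            alphas=alphas,
            beta=float(beta),
            gamma=float(gamma),
            horizon=config.horizon,
        )
        schedules.append(sched)
        mu_u, mu_s = mean_trajectory(sched, times)
        unspliced[:, j] = rng.poisson(mu_u)
        spliced[:, j] = rng.poisson(mu_s)

    return SimulatedDataset(
        spliced=spliced,
        unspliced=unspliced,
        cell_times=times,
        cell_fates=np.array(["ABA"] * config.n_cells, dtype=object),
        gene_schedules={"ABA": schedules},
        seed=config.seed,
    )


def simulate_multipotent(
    config: SimulationConfig | None = None,
    fate_labels: tuple[str, ...] | None = None,
) -> SimulatedDataset:
    """Multipotent differentiation (AB followed by a random terminal fate).

    All cells share states A and B; after ``tau_2`` each cell follows its
    assigned fate's terminal transcription rate, drawn independently per fate
    from the same lognormal law.  Passing two fate probabilities gives the
    bifurcation variant AB(C/D).
    """
    config = config or SimulationConfig()
    n_fates = len(config.fate_probabilities)
    if fate_labels is None:
        fate_labels = tuple(chr(ord("C") + i) for i in range(n_fates))
    if len(fate_labels) != n_fates:
        raise ValueError("need one fate label per fate probability")

    cell_rng, gene_rngs = _gene_streams(config.seed, config.n_genes)
    times = cell_rng.uniform(0.0, config.horizon, size=config.n_cells)
    times.sort()
    fates = np.asarray(fate_labels, dtype=object)[
        cell_rng.choice(n_fates, size=config.n_cells, p=config.fate_probabilities)
    ]

    spliced = np.empty((config.n_cells, config.n_genes), dtype=np.int64)
    unspliced = np.empty_like(spliced)
    gene_schedules: dict[str, list[RateSchedule]] = {f: [] for f in fate_labels}
    for j, rng in enumerate(gene_rngs):
        a1, a2 = _draw_clipped_lognormal(
            rng, config.alpha_logmean, config.alpha_logsd, size=2
        )
        terminal = _draw_clipped_lognormal(
            rng, config.alpha_logmean, config.alpha_logsd, size=n_fates
        )
        beta = float(
            _draw_clipped_lognormal(rng, config.beta_logmean, config.beta_logsd)
        )
        gamma = float(
            _draw_clipped_lognormal(rng, config.gamma_logmean, config.gamma_logsd)
        )
        mu_u = np.empty(config.n_cells)
        mu_s = np.empty(config.n_cells)
        for f_idx, fate in enumerate(fate_labels):
            sched = RateSchedule(
                switch_times=config.switch_times,
                alphas=(a1, a2, float(terminal[f_idx])),
                beta=beta,
                gamma=gamma,
                horizon=config.horizon,
            )
            gene_schedules[fate].append(sched)
            rows = fates == fate
            if np.any(rows):
                mu_u[rows], mu_s[rows] = mean_trajectory(sched, times[rows])
        unspliced[:, j] = rng.poisson(mu_u)
        spliced[:, j] = rng.poisson(mu_s)

    return SimulatedDataset(
        spliced=spliced,
        unspliced=unspliced,
        cell_times=times,
        cell_fates=fates,
        gene_schedules=gene_schedules,
        seed=config.seed,
    )


def simulate_bursty_steady_state(
    config: BurstySimulationConfig | None = None,
) -> SimulatedDataset:
    """Stationary bursty dataset: cell types differ in burst frequency and decay.

    Counts are sampled directly from the analytic stationary joint PMF of each
    (gene, cell type) pair, so there are no transient dynamics and the
    ground-truth velocity is zero everywhere.
    """
    config = config or BurstySimulationConfig()
    cell_rng, gene_rngs = _gene_streams(config.seed, config.n_genes)
    n_types = config.n_cell_types
    cell_types = [f"type_{k}" for k in range(n_types)]
    fates = np.repeat(np.asarray(cell_types, dtype=object), config.cells_per_type)

    burst_size = np.empty(config.n_genes)
    beta = np.ones(config.n_genes)
    gamma = np.empty((config.n_genes, n_types))
    freq = np.empty((config.n_genes, n_types))
    spliced = np.empty((config.n_cells, config.n_genes), dtype=np.int64)
    unspliced = np.empty_like(spliced)

    for j, rng in enumerate(gene_rngs):
        b = float(
            _draw_clipped_lognormal(
                rng, config.burst_logmean, config.burst_logsd, config.burst_clip
            )
        )
        burst_size[j] = b
        gamma_center = rng.normal(config.gamma_center_mean, config.gamma_center_sd)
        burst = BurstModel(b)
        for k in range(n_types):
            for attempt in range(config.max_redraws + 1):
                g = float(
                    _draw_clipped_lognormal(
                        rng, gamma_center, config.gamma_logsd, config.gamma_clip
                    )
                )
                a = float(
                    _draw_clipped_lognormal(
                        rng, config.freq_logmean, config.freq_logsd, config.freq_clip
                    )
                )
                mu_u, mu_s, var_u, var_s = bursty_moments(burst, a, beta[j], g)
                area = (mu_u + 5 * np.sqrt(var_u)) * (mu_s + 5 * np.sqrt(var_s))
                if area <= config.reject_threshold:
                    break
            else:
                raise RuntimeError(
                    f"rejection cap reached for gene {j}, cell type {k}"
                )
            gamma[j, k] = g
            freq[j, k] = a
            # sampling straight from the truncated histogram is intended here,
            # so the deficit report is disabled
            pmf = bursty_stationary_pmf(burst, a, beta[j], g, deficit_tol=np.inf)
            flat = pmf.probs.ravel()
            flat = flat / flat.sum()
            draws = rng.choice(flat.size, size=config.cells_per_type, p=flat)
            xu, xs = np.unravel_index(draws, pmf.probs.shape)
            rows = slice(k * config.cells_per_type, (k + 1) * config.cells_per_type)
            unspliced[rows, j] = xu
            spliced[rows, j] = xs

    return SimulatedDataset(
        spliced=spliced,
        unspliced=unspliced,
        cell_times=np.zeros(config.n_cells),
        cell_fates=fates,
        gene_schedules={},
        stationary=True,
        bursty_params={
            "cell_types": cell_types,
            "burst_size": burst_size,
            "beta": beta,
            "gamma": gamma,
            "burst_freq": freq,
        },
        seed=config.seed,
    )


def ground_truth_principal_curve(
    dataset: SimulatedDataset,
    basis,
    n_grid: int = 200,
) -> dict[str, np.ndarray]:
    """Project the true mean-expression curve into a 2-D principal space.

    For each fate branch, the true gene-specific spliced means are evaluated on
    a time grid over ``[0, T]``, log-transformed, and projected through the
    supplied PCA basis (which must be built from the same count space — raw
    spliced counts for the simulations here).  Returns one ordered 2-D polyline
    per fate; branches of a multipotent dataset share a common prefix.
    """
    if dataset.stationary:
        raise ValueError("principal curves require a transient dataset")
    if basis.n_features != dataset.n_genes:
        raise ValueError(
            "basis feature dimension does not match the dataset gene space"
        )
    curves = {}
    for fate, schedules in dataset.gene_schedules.items():
        horizon = schedules[0].horizon
        grid = np.linspace(0.0, horizon, n_grid)
        mu_s = np.column_stack(
            [mean_trajectory(s, grid)[1] for s in schedules]
        )
        curves[fate] = basis.transform(mu_s)[:, :2]
    return curves
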