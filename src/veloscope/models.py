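"""Exact solutions for tractable stochastic models of transcription and splicing.

The central object is a two-species birth/catalysis/death network

    0 --alpha(t)--> U --beta--> S --gamma--> 0,

where ``alpha(t)`` is a piecewise-constant transcription rate, ``beta`` the
splicing rate, and ``gamma`` the degradation rate.  Driven by a deterministic
rate schedule and started from a Poisson state, the copy-number distribution
stays product-Poisson at every instant, with means solving the reaction rate
equations.  Cells sequenced without a synchronizing clock are modeled as draws
from the *occupation measure* of the process: the time-average of the
instantaneous law under a sampling measure over process time.

This module provides:

* closed-form mean trajectories for arbitrary piecewise-constant schedules;
* the exponential-integral closed form for the occupation-measure PGF of the
  one-species birth-death process;
* instantaneous and occupation-measure joint PMFs of the two-species model;
* the stationary joint PMF of the bursty (geometric burst) model, obtained by
  inverting its generating function with a 2-D FFT;
* fate-mixture generating functions; and
* per-interval net-velocity integrals and the moment identity
  ``E_f[d mu_s/dt] = beta*E_f[mu_u] - gamma*E_f[mu_s]``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expi, gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "RateSchedule",
    "SamplingMeasure",
    "JointPMF",
    "BurstModel",
    "MixtureModel",
    "mean_trajectory",
    "steady_state",
    "birth_death_occupation_pgf",
    "canonical_joint_pmf",
    "occupation_pmf",
    "occupation_means",
    "bursty_moments",
    "bursty_stationary_pmf",
    "mixture_pgf",
    "mixture_occupation_pmf",
    "net_velocity_integral",
]

#: relative threshold below which beta and gamma are treated as degenerate
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class RateSchedule:
    """Piecewise-constant transcription schedule with splicing/degradation rates.

    Parameters
    ----------
    switch_times
        Interior switch times ``tau_1 < ... < tau_{K-1}`` in ``(0, horizon)``.
    alphas
        Per-interval transcription rates, one per interval (``K`` values).
    beta
        Splicing rate (> 0).
    gamma
        Degradation rate (> 0).
    horizon
        Process-time horizon ``T`` (> 0).
    """

    switch_times: tuple[float, ...]
    alphas: tuple[float, ...]
    beta: float
    gamma: float
    horizon: float

    def __post_init__(self) -> None:
        st = tuple(float(t) for t in self.switch_times)
        al = tuple(float(a) for a in self.alphas)
        object.__setattr__(self, "switch_times", st)
        object.__setattr__(self, "alphas", al)
        if not (self.horizon > 0 and math.isfinite(self.horizon)):
            raise ValueError("horizon must be positive and finite")
        if not (self.beta > 0 and self.gamma > 0):
            raise ValueError("beta and gamma must be positive")
        if any(a < 0 or not math.isfinite(a) for a in al):
            raise ValueError("transcription rates must be finite and >= 0")
        if len(al) != len(st) + 1:
            raise ValueError("need len(alphas) == len(switch_times) + 1")
        bounds = (0.0,) + st + (self.horizon,)
        if any(b >= c for b, c in zip(bounds, bounds[1:])):
            raise ValueError("switch times must satisfy 0 < tau_1 < ... < T")

    @property
    def n_intervals(self) -> int:
        return len(self.alphas)

    @property
    def boundaries(self) -> np.ndarray:
        """Interval boundaries ``[0, tau_1, ..., tau_{K-1}, T]``."""
        return np.array((0.0,) + self.switch_times + (self.horizon,))

    def alpha_at(self, t: float) -> float:
        """Transcription rate at time ``t`` (last interval extends past T)."""
        k = int(np.searchsorted(np.asarray(self.switch_times), t, side="right"))
        return self.alphas[k]

    def steady_state(self) -> tuple[float, float]:
        """Fixed point ``(alpha_1/beta, alpha_1/gamma)`` of the first interval."""
        return self.alphas[0] / self.beta, self.alphas[0] / self.gamma


@dataclass(frozen=True)
class SamplingMeasure:
    """Sampling law of process times at which cells are observed.

    ``uniform`` has density ``1/T`` on ``[0, T]`` (plug-flow/batch sampling),
    ``exponential`` has rate ``1/T`` on ``[0, inf)`` (stirred-tank sampling),
    and ``dirac`` is a point mass at ``T`` (synchronized endpoint sampling).
    """

    kind: str = "uniform"
    horizon: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "exponential", "dirac"):
            raise ValueError(f"unknown sampling measure kind: {self.kind!r}")
        if not self.horizon > 0:
            raise ValueError("horizon must be positive")

    def nodes_and_weights(
        self, panels: int = 768, breakpoints: tuple[float, ...] = ()
    ) -> tuple[np.ndarray, np.ndarray]:
        """Quadrature nodes/weights integrating ``E_f[g(t)]`` to high accuracy.

        A fixed composite-Simpson panel rule, split at ``breakpoints`` (e.g.
        schedule switch times, where mean trajectories have kinks); callers can
        halve ``panels`` for a Richardson-style convergence check.
        """
        if self.kind == "dirac":
            return np.array([self.horizon]), np.array([1.0])
        end = self.horizon if self.kind == "uniform" else 30.0 * self.horizon
        edges = [0.0] + sorted(b for b in breakpoints if 0.0 < b < end) + [end]
        ts, ws = [], []
        for lo, hi in zip(edges, edges[1:]):
            seg = max(8, int(round(panels * (hi - lo) / end)))
            t, w = _simpson_nodes(lo, hi, seg)
            ts.append(t)
            ws.append(w)
        t = np.concatenate(ts)
        w = np.concatenate(ws)
        if self.kind == "uniform":
            return t, w / self.horizon
        # exponential, rate 1/T, truncated where residual mass < 1e-13
        return t, w * np.exp(-t / self.horizon) / self.horizon


def _simpson_nodes(a: float, b: float, panels: int) -> tuple[np.ndarray, np.ndarray]:
    """Composite Simpson nodes and weights on [a, b] with ``panels`` panels."""
    n = 2 * max(1, panels)
    t = np.linspace(a, b, n + 1)
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= (b - a) / (3.0 * n)
    return t, w


@dataclass
class JointPMF:
    """Truncated joint PMF over (unspliced, spliced) copy-number states.

    ``probs[x_u, x_s]`` covers ``[0, max_u] x [0, max_s]``.  ``truncated_mass``
    reports the estimated probability mass lost to (or aliased from) states
    beyond the truncation bounds.
    """

    probs: np.ndarray
    truncated_mass: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be a 2-D array")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")

    @property
    def max_u(self) -> int:
        return self.probs.shape[0] - 1

    @property
    def max_s(self) -> int:
        return self.probs.shape[1] - 1

    def marginal_u(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def marginal_s(self) -> np.ndarray:
        return self.probs.sum(axis=0)

    def mean(self) -> tuple[float, float]:
        xu = np.arange(self.probs.shape[0])
        xs = np.arange(self.probs.shape[1])
        return float(self.marginal_u() @ xu), float(self.marginal_s() @ xs)

    def total(self) -> float:
        return float(self.probs.sum())


def _truncation_bound(mu: float, sigma: float) -> int:
    """State-space truncation at ``mu + 5 sigma``, floored at 10."""
    return max(10, int(math.ceil(mu + 5.0 * sigma)))


@dataclass(frozen=True)
class BurstModel:
    """Geometric burst-size distribution with mean ``mean_burst`` molecules/event.

    The burst PGF is ``M(z) = 1 / (1 + b (1 - z))`` for a geometric law on
    {0, 1, 2, ...} with mean ``b``.
    """

    mean_burst: float
    family: str = "geometric"

    def __post_init__(self) -> None:
        if self.family != "geometric":
            raise ValueError("only geometric bursts are supported")
        if not self.mean_burst > 0:
            raise ValueError("mean burst size must be positive")

    def pgf_minus_one(self, u: np.ndarray) -> np.ndarray:
        """``M(1 + u) - 1 = b*u / (1 - b*u)`` evaluated at ``u = z - 1``."""
        bu = self.mean_burst * np.asarray(u)
        return bu / (1.0 - bu)


@dataclass(frozen=True)
class MixtureModel:
    """Finite mixture over fate-specific rate schedules.

    Each component is a :class:`RateSchedule` describing one cell fate; the
    weights are the fate probabilities.  Because the PGF (and hence the PMF) is
    linear in the mixing law, occupation measures of mixtures are convex
    combinations of the component occupation measures.
    """

    weights: tuple[float, ...]
    components: tuple[RateSchedule, ...]

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "components", tuple(self.components))
        if len(w) != len(self.components):
            raise ValueError("one weight per component required")
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")


# ---------------------------------------------------------------------------
# Mean trajectories
# ---------------------------------------------------------------------------

def _advance_interval(
    alpha: float, beta: float, gamma: float, u0: float, s0: float, tau: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (mu_u, mu_s) after elapsed time ``tau`` within one interval.

    For ``beta != gamma``::

        mu_u = a/b + (u0 - a/b) e^{-b tau}
        mu_s = a/g + (u0 - a/b) b/(g-b) (e^{-b tau} - e^{-g tau})
                   + (s0 - a/g) e^{-g tau}

    With ``|beta - gamma| < 1e-9 beta`` the removable singularity is evaluated
    through its limit ``(e^{-b tau} - e^{-g tau})/(g - b) -> tau e^{-b tau}``.
    """
    eb = np.exp(-beta * tau)
    eg = np.exp(-gamma * tau)
    du = u0 - alpha / beta
    ds = s0 - alpha / gamma
    mu_u = alpha / beta + du * eb
    if abs(beta - gamma) < _DEGENERATE_RTOL * beta:
        cross = du * beta * tau * eb
    else:
        cross = du * beta / (gamma - beta) * (eb - eg)
    mu_s = alpha / gamma + cross + ds * eg
    return mu_u, mu_s


def mean_trajectory(
    schedule: RateSchedule,
    times,
    init: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact piecewise mean trajectory ``(mu_u(t), mu_s(t))``.

    The solution is propagated across switch times as continuous initial
    conditions, so the trajectory is continuous in ``t``.  If ``init`` is
    omitted the system starts at the steady state of the first interval
    (``u0 = alpha_1/beta``, ``s0 = alpha_1/gamma``).  Times beyond the horizon
    are evaluated by extending the final interval's rate.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if init is None:
        u0, s0 = schedule.steady_state()
    else:
        u0, s0 = float(init[0]), float(init[1])

    bounds = schedule.boundaries
    mu_u = np.empty_like(t)
    mu_s = np.empty_like(t)
    u_start, s_start = u0, s0
    for k, alpha in enumerate(schedule.alphas):
        lo = bounds[k]
        hi = bounds[k + 1]
        last = k == schedule.n_intervals - 1
        mask = (t >= lo) & ((t <= hi) if last else (t < hi))
        if last:
            mask |= t > hi
        if np.any(mask):
            mu_u[mask], mu_s[mask] = _advance_interval(
                alpha, schedule.beta, schedule.gamma, u_start, s_start, t[mask] - lo
            )
        end_u, end_s = _advance_interval(
            alpha, schedule.beta, schedule.gamma, u_start, s_start,
            np.array([hi - lo]),
        )
        u_start, s_start = float(end_u[0]), float(end_s[0])
    if np.isscalar(times) or np.asarray(times).ndim == 0:
        return float(mu_u[0]), float(mu_s[0])
    return mu_u, mu_s


def steady_state(alpha: float, beta: float, gamma: float) -> tuple[float, float]:
    """Fixed point of the mean ODEs under a constant transcription rate."""
    return alpha / beta, alpha / gamma


# ---------------------------------------------------------------------------
# Birth-death occupation PGF
# ---------------------------------------------------------------------------

def birth_death_occupation_pgf(
    alpha: float, beta: float, y0: float, horizon: float, z
) -> np.ndarray | float:
    """Occupation-measure PGF ``H(z)`` of the birth-death process.

    The process ``0 -> X -> 0`` with production rate ``alpha`` and efflux rate
    ``beta``, started Poisson with mean ``y0`` and observed uniformly on
    ``[0, T]``, has instantaneous PGF ``G(z; t) = exp(u y(t))`` with
    ``u = z - 1`` and ``y(t) = c e^{-beta t} + alpha/beta``,
    ``c = y0 - alpha/beta``.  Averaging over time gives

        H(z) = e^{u alpha/beta} / (beta T) * [Ei(u c) - Ei(u c e^{-beta T})],

    where ``Ei`` is the (principal-value) exponential integral.  For ``c = 0``
    the mean is constant and ``H(z) = e^{u alpha/beta}``.
    """
    if not (beta > 0 and horizon > 0):
        raise ValueError("beta and horizon must be positive")
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    if np.any((z_arr < 0) | (z_arr > 1)):
        raise ValueError("z must lie in [0, 1]")
    u = z_arr - 1.0
    c = y0 - alpha / beta
    out = np.empty_like(u)
    base = np.exp(u * alpha / beta)
    if abs(c) < 1e-12 * max(1.0, abs(y0)):
        out[:] = base
    else:
        nz = u != 0
        out[~nz] = 1.0
        uc = u[nz] * c
        decayed = uc * math.exp(-beta * horizon)
        # Ei(x) ~ euler_gamma + ln|x| as x -> 0: used when e^{-beta T} underflows
        ei_decayed = np.where(
            decayed == 0.0,
            np.euler_gamma + np.log(np.abs(uc)) - beta * horizon,
            expi(decayed),
        )
        out[nz] = base[nz] / (beta * horizon) * (expi(uc) - ei_decayed)
    if np.isscalar(z) or np.asarray(z).ndim == 0:
        return float(out[0])
    return out


# ---------------------------------------------------------------------------
# Joint PMFs of the canonical model
# ---------------------------------------------------------------------------

def _poisson_pmf(grid: np.ndarray, mu) -> np.ndarray:
    """Poisson pmf on integer ``grid`` for scalar or vector mean ``mu``."""
    mu = np.asarray(mu, dtype=float)
    mu_safe = np.maximum(mu, 1e-300)
    logp = (
        grid * np.log(mu_safe)[..., None]
        - mu[..., None]
        - gammaln(grid + 1.0)
    )
    p = np.exp(logp)
    if np.any(mu == 0):
        zero = mu == 0
        p[zero] = 0.0
        p[zero, grid == 0] = 1.0
    return p


def _pmf_grid_bounds(mu_u, mu_s) -> tuple[int, int]:
    mu_u = np.max(np.atleast_1d(mu_u))
    mu_s = np.max(np.atleast_1d(mu_s))
    return (
        _truncation_bound(mu_u, math.sqrt(mu_u)),
        _truncation_bound(mu_s, math.sqrt(mu_s)),
    )


def canonical_joint_pmf(
    schedule: RateSchedule,
    t: float,
    init: tuple[float, float] | None = None,
    bounds: tuple[int, int] | None = None,
) -> JointPMF:
    """Instantaneous joint PMF: product of Poissons with the exact means.

    Started at (or propagated from) a Poisson state, the canonical two-species
    model remains product-Poisson at every time, with means given by
    :func:`mean_trajectory`.
    """
    if not 0 <= t <= schedule.horizon:
        raise ValueError("t must lie in [0, horizon]")
    mu_u, mu_s = mean_trajectory(schedule, float(t), init=init)
    if bounds is None:
        bounds = _pmf_grid_bounds(mu_u, mu_s)
    gu = np.arange(bounds[0] + 1, dtype=float)
    gs = np.arange(bounds[1] + 1, dtype=float)
    pu = _poisson_pmf(gu, mu_u)
    ps = _poisson_pmf(gs, mu_s)
    probs = np.outer(pu, ps)
    return JointPMF(probs=probs, truncated_mass=float(1.0 - probs.sum()))


def occupation_pmf(
    schedule: RateSchedule,
    measure: SamplingMeasure | None = None,
    panels: int = 768,
    tol: float = 1e-5,
) -> JointPMF:
    """Occupation-measure joint PMF: time-average of the instantaneous PMF.

    ``P(x) = E_f[P(x; t)]`` is computed by a fixed composite-Simpson panel rule
    under the sampling measure, with a half-resolution Richardson check; the
    achieved quadrature error estimate is raised if it exceeds ``tol``.
    For a constant schedule and uniform measure the result converges to the
    product-Poisson ergodic limit as ``T`` grows.
    """
    if measure is None:
        measure = SamplingMeasure("uniform", schedule.horizon)
    if measure.kind != "exponential" and measure.horizon > schedule.horizon + 1e-12:
        raise ValueError("sampling measure horizon exceeds schedule horizon")

    t_nodes, w = measure.nodes_and_weights(panels, schedule.switch_times)
    mu_u, mu_s = mean_trajectory(schedule, t_nodes)
    bounds = _pmf_grid_bounds(mu_u, mu_s)
    gu = np.arange(bounds[0] + 1, dtype=float)
    gs = np.arange(bounds[1] + 1, dtype=float)

    def average(nodes, weights):
        mu, ms = mean_trajectory(schedule, nodes)
        pu = _poisson_pmf(gu, mu)      # (n_t, Nu)
        ps = _poisson_pmf(gs, ms)      # (n_t, Ns)
        return np.einsum("t,tu,ts->us", weights, pu, ps)

    probs = average(t_nodes, w)
    if measure.kind != "dirac":
        t_half, w_half = measure.nodes_and_weights(panels // 2, schedule.switch_times)
        err = float(np.abs(probs - average(t_half, w_half)).max())
        if err > tol:
            raise RuntimeError(
                f"occupation-measure quadrature did not converge: estimated "
                f"error {err:.3g} > {tol:.3g}"
            )
    probs = np.clip(probs, 0.0, None)
    return JointPMF(probs=probs, truncated_mass=float(1.0 - probs.sum()))


def occupation_means(
    schedule: RateSchedule,
    measure: SamplingMeasure | None = None,
    panels: int = 768,
) -> tuple[float, float]:
    """Occupation-measure means ``(E_f[mu_u], E_f[mu_s])`` by panel quadrature."""
    if measure is None:
        measure = SamplingMeasure("uniform", schedule.horizon)
    t_nodes, w = measure.nodes_and_weights(panels, schedule.switch_times)
    mu_u, mu_s = mean_trajectory(schedule, t_nodes)
    return float(w @ mu_u), float(w @ mu_s)


# ---------------------------------------------------------------------------
# Bursty stationary model
# ---------------------------------------------------------------------------

def bursty_moments(
    burst: BurstModel, burst_freq: float, beta: float, gamma: float
) -> tuple[float, float, float, float]:
    """Stationary means and variances ``(mu_u, mu_s, var_u, var_s)``.

    For geometric bursts of mean ``b`` arriving at rate ``alpha``::

        mu_u = alpha b / beta           Fano_u = 1 + b
        mu_s = alpha b / gamma          Fano_s = 1 + b beta / (beta + gamma)
    """
    b = burst.mean_burst
    mu_u = burst_freq * b / beta
    mu_s = burst_freq * b / gamma
    var_u = mu_u * (1.0 + b)
    var_s = mu_s * (1.0 + b * beta / (beta + gamma))
    return mu_u, mu_s, var_u, var_s


def _bursty_log_pgf(
    burst: BurstModel,
    burst_freq: float,
    beta: float,
    gamma: float,
    g_u: np.ndarray,
    g_s: np.ndarray,
    n_quad: int = 96,
) -> np.ndarray:
    """log PGF ``phi(g) = alpha \\int_0^inf [M(U1(g; s)) - 1] ds`` on a grid.

    ``g_u``/``g_s`` are ``z - 1`` arguments (broadcastable).  The downstream
    characteristic is
    ``U1(s) = g_u e^{-beta s} + g_s beta/(beta-gamma) (e^{-gamma s}-e^{-beta s})``.
    The integral is mapped to [0, 1] through ``x = e^{-r s}``, ``r = min(beta,
    gamma)``, which makes the integrand bounded and smooth for Gauss-Legendre.
    """
    r = min(beta, gamma)
    x, wq = np.polynomial.legendre.leggauss(n_quad)
    x = 0.5 * (x + 1.0)
    wq = 0.5 * wq / r  # ds = -dx/(r x); the 1/x is folded into the exponents
    s = -np.log(x) / r
    eb = np.exp(-beta * s)
    eg = np.exp(-gamma * s)
    if abs(beta - gamma) < _DEGENERATE_RTOL * beta:
        cross = beta * s * eb
    else:
        cross = beta / (beta - gamma) * (eg - eb)
    # U1 over quadrature nodes for every grid point: shape (..., n_quad)
    u1 = g_u[..., None] * eb + g_s[..., None] * cross
    integrand = burst.pgf_minus_one(u1) / x
    return burst_freq * (integrand @ wq)


def bursty_stationary_pmf(
    burst: BurstModel,
    burst_freq: float,
    beta: float,
    gamma: float,
    truncation: tuple[int, int] | None = None,
    deficit_tol: float = 1e-4,
    n_quad: int = 96,
) -> JointPMF:
    """Stationary joint PMF of the bursty model via PGF inversion.

    The stationary PGF is evaluated on the 2-D unit-circle grid
    ``z = exp(2 pi i k / N)`` and inverted with a 2-D FFT.  Tiny negative
    entries from roundoff are clipped at ``-1e-8`` (an error is raised below
    that).  The mass in the outermost row/column estimates the truncation
    deficit; a deficit above ``deficit_tol`` is reported as an error.
    """
    if truncation is None:
        mu_u, mu_s, var_u, var_s = bursty_moments(burst, burst_freq, beta, gamma)
        truncation = (
            _truncation_bound(mu_u, math.sqrt(var_u)),
            _truncation_bound(mu_s, math.sqrt(var_s)),
        )
    nu, ns = truncation[0] + 1, truncation[1] + 1
    ku = np.arange(nu)
    ks = np.arange(ns)
    zu = np.exp(2j * np.pi * ku / nu) - 1.0
    zs = np.exp(2j * np.pi * ks / ns) - 1.0
    g_u, g_s = np.meshgrid(zu, zs, indexing="ij")
    pgf = np.exp(
        _bursty_log_pgf(burst, burst_freq, beta, gamma, g_u, g_s, n_quad=n_quad)
    )
    probs = np.fft.fft2(pgf).real / (nu * ns)
    if probs.min() < -1e-8:
        raise RuntimeError(
            f"PGF inversion produced negative mass {probs.min():.3g}"
        )
    probs = np.clip(probs, 0.0, None)
    deficit = float(probs[-1, :].sum() + probs[:, -1].sum())
    if deficit > deficit_tol:
        logger.warning(
            "bursty PMF truncation-mass deficit %.3g exceeds %.3g "
            "(boundary-mass estimate); widen the truncation to reduce aliasing",
            deficit, deficit_tol,
        )
    return JointPMF(probs=probs, truncated_mass=deficit)


# ---------------------------------------------------------------------------
# Fate mixtures
# ---------------------------------------------------------------------------

def _component_occupation_pgf(
    schedule: RateSchedule,
    measure: SamplingMeasure,
    z_u: float,
    z_s: float,
    panels: int = 768,
) -> float:
    t_nodes, w = measure.nodes_and_weights(panels, schedule.switch_times)
    mu_u, mu_s = mean_trajectory(schedule, t_nodes)
    g = np.exp(mu_u * (z_u - 1.0) + mu_s * (z_s - 1.0))
    return float(w @ g)


def mixture_pgf(
    mixture: MixtureModel,
    measure: SamplingMeasure,
    z_u: float,
    z_s: float,
) -> float:
    """Occupation-measure PGF of a fate mixture: ``sum_k w_k H_k(z_u, z_s)``."""
    return sum(
        w * _component_occupation_pgf(comp, measure, z_u, z_s)
        for w, comp in zip(mixture.weights, mixture.components)
    )


def mixture_occupation_pmf(
    mixture: MixtureModel,
    measure: SamplingMeasure | None = None,
    panels: int = 768,
) -> JointPMF:
    """Occupation PMF of a fate mixture, by linearity of the occupation measure."""
    parts = [
        occupation_pmf(comp, measure, panels=panels) for comp in mixture.components
    ]
    nu = max(p.probs.shape[0] for p in parts)
    ns = max(p.probs.shape[1] for p in parts)
    probs = np.zeros((nu, ns))
    for w, p in zip(mixture.weights, parts):
        probs[: p.probs.shape[0], : p.probs.shape[1]] += w * p.probs
    return JointPMF(probs=probs, truncated_mass=float(1.0 - probs.sum()))


# ---------------------------------------------------------------------------
# Net velocity integrals
# ---------------------------------------------------------------------------

def net_velocity_integral(
    schedule: RateSchedule,
    interval_index: int | None = None,
    init: tuple[float, float] | None = None,
) -> float:
    """Time-averaged net spliced velocity over one interval (or the horizon).

    Returns ``(1/Delta_k) * int_{I_k} d mu_s/dt dt``, which by the fundamental
    theorem of calculus equals the closed-form mean increment
    ``(mu_s(tau_k) - mu_s(tau_{k-1})) / Delta_k``, and by the moment identity
    equals ``beta * mean(mu_u) - gamma * mean(mu_s)`` over the interval under
    the uniform measure, regardless of the transcriptional dynamics.  The
    integral approaches zero as ``Delta_k`` grows: a long interval settles
    into its ergodic attractor.

    ``init`` gives ``(u0, s0)`` at the interval start; by default the state is
    propagated from the schedule's own initial condition.
    """
    bounds = schedule.boundaries
    if interval_index is None:
        lo, hi = bounds[0], bounds[-1]
    else:
        if not 0 <= interval_index < schedule.n_intervals:
            raise ValueError("interval_index out of range")
        lo, hi = bounds[interval_index], bounds[interval_index + 1]
    delta = hi - lo
    if delta <= 0:
        raise ValueError("interval length must be positive")
    if init is not None and interval_index is not None:
        alpha = schedule.alphas[interval_index]
        (mu_s_hi,) = _advance_interval(
            alpha, schedule.beta, schedule.gamma, init[0], init[1],
            np.array([delta]),
        )[1]
        return float((mu_s_hi - init[1]) / delta)
    _, mu_s = mean_trajectory(schedule, np.array([lo, hi]), init=init)
    return float((mu_s[1] - mu_s[0]) / delta)
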