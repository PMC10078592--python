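"""Marginal void probability and the semi-complete data likelihood (SCDL).

The SCDL fits the SCR model without data augmentation: the activity centers
of the never-detected individuals are integrated out analytically, leaving
the *marginal void probability*

    p* = P(an individual is never detected)
       = (1 / Lambda_tilde) * integral over habitat of
           lambda_tilde(s) * exp(-Lambda(o | s)) ds,

the AC-density-weighted average of the conditional void probability
``exp(-Lambda(o|s))``.  Because the AC intensity is piecewise constant over
habitat windows, the integral reduces to one definite integral per window,
evaluated here by the midpoint rule on a regular sub-lattice of nodes.

Because individual heterogeneity is not modelled, p* is shared by all
individuals and needs to be evaluated only once per parameter state;
:class:`VoidCalculator` caches the last value and counts evaluations so a
sampler can assert it recomputes exactly once per iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import poisson

from .density import DensityParams, window_intensities
from .detection import DetectionParams, baseline_intensities, integral_matrix
from .grids import WindowGrid

__all__ = [
    "VoidConfig",
    "VoidCalculator",
    "SCDLState",
    "void_probability",
    "scdl_log_likelihood",
]


@dataclass(frozen=True)
class VoidConfig:
    """Midpoint-rule configuration for the p* integral.

    ``nodes_per_window`` must be a perfect square K: nodes form a regular
    sqrt(K) x sqrt(K) lattice at sub-cell centers of each habitat window and
    each node carries weight area/K, so weights sum to the window area.
    With ``per_window=False`` the same count is interpreted as a *total*
    node budget, laid out as a single lattice over the habitat extent.
    """

    nodes_per_window: int = 100
    per_window: bool = True

    def __post_init__(self) -> None:
        k = int(math.isqrt(self.nodes_per_window))
        if k * k != self.nodes_per_window or self.nodes_per_window < 1:
            raise ValueError(
                f"nodes_per_window must be a positive perfect square, "
                f"got {self.nodes_per_window}"
            )


def _midpoint_nodes(habitat: WindowGrid, config: VoidConfig):
    """Node coordinates, their habitat-window index, and quadrature weights."""
    if config.per_window:
        k = math.isqrt(config.nodes_per_window)
        offs = (np.arange(k) + 0.5) / k
        ox, oy = np.meshgrid(offs, offs, indexing="ij")
        frac = np.column_stack([ox.ravel(), oy.ravel()])  # (K, 2) in [0,1]^2
        side = habitat.upper - habitat.lower  # (H, 2)
        nodes = (
            habitat.lower[:, None, :] + frac[None, :, :] * side[:, None, :]
        ).reshape(-1, 2)
        node_window = np.repeat(np.arange(habitat.n_windows), k * k)
        weights = np.repeat(habitat.areas / (k * k), k * k)
    else:
        k = math.isqrt(config.nodes_per_window)
        xmin, ymin, xmax, ymax = habitat.extent
        xs = xmin + (np.arange(k) + 0.5) * (xmax - xmin) / k
        ys = ymin + (np.arange(k) + 0.5) * (ymax - ymin) / k
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        nodes = np.column_stack([gx.ravel(), gy.ravel()])
        node_window = habitat.locate(nodes)
        weights = np.full(len(nodes), (xmax - xmin) * (ymax - ymin) / (k * k))
    return nodes, node_window, weights


class VoidCalculator:
    """Evaluates p* by the midpoint rule, caching against the parameter
    state so repeated queries within an MCMC iteration cost nothing."""

    def __init__(
        self, habitat: WindowGrid, detgrid: WindowGrid, config: VoidConfig | None = None
    ) -> None:
        self.habitat = habitat
        self.detgrid = detgrid
        self.config = config or VoidConfig()
        self.nodes, self.node_window, self.weights = _midpoint_nodes(
            habitat, self.config
        )
        self.n_evaluations = 0
        self._cache_key: tuple | None = None
        self._cache_value: float = np.nan
        self._integral_cache: tuple[float, np.ndarray] | None = None

    def _node_integrals(self, sigma: float) -> np.ndarray:
        """(K_total, L) kernel integral matrix at the quadrature nodes;
        cached on sigma since node positions never change."""
        if self._integral_cache is None or self._integral_cache[0] != sigma:
            I = integral_matrix(self.nodes, sigma, self.detgrid)
            self._integral_cache = (sigma, I)
        return self._integral_cache[1]

    @staticmethod
    def _key(dparams: DensityParams, oparams: DetectionParams) -> tuple:
        # beta0 cancels between lambda and Lambda, so it is excluded
        return (
            tuple(dparams.beta),
            oparams.theta0,
            tuple(oparams.theta),
            oparams.sigma,
        )

    def __call__(self, dparams: DensityParams, oparams: DetectionParams) -> float:
        key = self._key(dparams, oparams)
        if key == self._cache_key:
            return self._cache_value
        surface = window_intensities(self.habitat, dparams)
        b = baseline_intensities(oparams, self.detgrid)
        Lam_nodes = self._node_integrals(oparams.sigma) @ b  # Lambda(o | node)
        integrand = surface.lam[self.node_window] * np.exp(-Lam_nodes)
        p = float(self.weights @ integrand / surface.Lambda_total)
        p = min(max(p, 0.0), 1.0)
        self.n_evaluations += 1
        self._cache_key, self._cache_value = key, p
        return p


def void_probability(
    dparams: DensityParams,
    oparams: DetectionParams,
    habitat: WindowGrid,
    detgrid: WindowGrid,
    config: VoidConfig | None = None,
) -> float:
    """Marginal void probability p* in [0, 1] by the midpoint rule."""
    return VoidCalculator(habitat, detgrid, config)(dparams, oparams)


@dataclass
class SCDLState:
    """Population bookkeeping for the SCDL: observed count n, population
    size N >= n, and the current marginal void probability p*."""

    n_observed: int
    N: int
    p_star: float

    def __post_init__(self) -> None:
        if self.N < self.n_observed:
            raise ValueError(f"N={self.N} < n_observed={self.n_observed}")
        if not 0.0 <= self.p_star <= 1.0:
            raise ValueError(f"p_star={self.p_star} outside [0, 1]")


def scdl_log_likelihood(
    data,
    state: SCDLState,
    dparams: DensityParams,
    oparams: DetectionParams,
    habitat: WindowGrid,
    detgrid: WindowGrid,
    acs: np.ndarray,
    n_prior: str = "poisson",
    uniform_upper: int | None = None,
) -> float:
    """Semi-complete data log-likelihood at a given latent-AC configuration:

        log C(N, n) + (N - n) log p*
        + sum_i [ log Bernoulli-PP(s_i) + log detection-PP(y_i | s_i) ]
        + log prior(N)

    The N-prior is pluggable: ``"poisson"`` uses N ~ Poisson(Lambda_tilde),
    the prior induced by the Poisson point process for ACs (making beta0
    identifiable); ``"uniform"`` is discrete-uniform on {n, ..,
    uniform_upper}, under which beta0 cancels entirely.
    """
    from .density import log_bernoulli_pp
    from .detection import log_detection_pp

    n, N = state.n_observed, state.N
    if N < n:
        raise ValueError(f"N={N} < n={n}")
    acs = np.asarray(acs, float).reshape(-1, 2)
    if len(acs) != n:
        raise ValueError(f"{len(acs)} ACs for {n} observed individuals")

    surface = window_intensities(habitat, dparams)
    if n_prior == "poisson":
        log_prior = float(poisson.logpmf(N, surface.Lambda_total))
    elif n_prior == "uniform":
        upper = uniform_upper if uniform_upper is not None else 100 * max(n, 1)
        if N > upper:
            return -np.inf
        log_prior = -np.log(upper + 1.0)
    else:
        raise ValueError(f"unknown N-prior {n_prior!r}")

    if N > n:
        if state.p_star <= 0.0:
            return -np.inf
        void_term = (N - n) * np.log(state.p_star)
    else:
        void_term = 0.0
    log_choose = float(gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))

    obs = 0.0
    for (ind, locs), s in zip(data, acs):
        obs += log_bernoulli_pp(s, surface)
        obs += log_detection_pp(locs, s, oparams, detgrid)
    return log_choose + void_term + obs + log_prior
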