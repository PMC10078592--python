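"""Point-process models for activity-center (AC) density.

The number and placement of activity centers over the habitat region is
modelled as an inhomogeneous Poisson point process with a piecewise-constant
intensity surface: the habitat is tiled by windows, and within window ``h``

    log(lambda_h) = beta0 + sum_i beta_i * xi_ih

with window covariates ``xi``.  The integral of the intensity over the
habitat, ``Lambda = sum_h lambda_h * area_h``, is the expected population
size.

Conditioning a Poisson process on its total count yields a binomial point
process; for a single individual this is a Bernoulli point process whose
density at AC location ``s`` is ``lambda(s) / Lambda``.  Both log-densities
are provided here, together with the discretised "categorical" baseline in
which an AC is reduced to the containing window (located at its centroid).

The Poisson-process log-density omits the data-independent ``-log N!`` term:
it is constant in the parameters, so every MCMC use is invariant to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import WindowGrid, OutOfDomainError

__all__ = [
    "DensityParams",
    "IntensitySurface",
    "window_intensities",
    "log_bernoulli_pp",
    "log_poisson_pp_acs",
    "log_categorical_ac",
]

_LOG_CAP = 700.0  # exp overflows past this


@dataclass(frozen=True)
class DensityParams:
    """Log-linear density model: intercept ``beta0`` (log AC km^-2) and
    covariate slopes ``beta``."""

    beta0: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))


@dataclass
class IntensitySurface:
    """Per-window AC intensities and their integral over the habitat."""

    lam: np.ndarray          # (H,) AC km^-2
    log_lam: np.ndarray      # (H,)
    Lambda_total: float      # expected number of ACs
    grid: WindowGrid

    @property
    def log_Lambda(self) -> float:
        return float(np.log(self.Lambda_total))

    def log_lambda_at(self, points: np.ndarray) -> np.ndarray:
        """log intensity at arbitrary points; -inf outside the habitat."""
        idx = np.atleast_1d(self.grid.locate(points, strict=False))
        out = np.where(idx >= 0, self.log_lam[np.clip(idx, 0, None)], -np.inf)
        if np.asarray(points).ndim == 1:
            return out[0]
        return out


def window_intensities(grid: WindowGrid, params: DensityParams) -> IntensitySurface:
    """Evaluate the log-linear intensity model on a habitat grid."""
    if len(params.beta) != grid.covariates.shape[1]:
        raise ValueError(
            f"{len(params.beta)} slopes for {grid.covariates.shape[1]} covariates"
        )
    log_lam = params.beta0 + grid.covariates @ params.beta
    if not np.all(np.isfinite(log_lam)) or np.any(log_lam > _LOG_CAP):
        bad = int(np.argmax(~np.isfinite(log_lam) | (log_lam > _LOG_CAP)))
        raise FloatingPointError(
            f"non-finite or overflowing intensity in window {bad} "
            f"(log intensity {log_lam[bad]})"
        )
    lam = np.exp(log_lam)
    Lambda = float(lam @ grid.areas)
    return IntensitySurface(lam=lam, log_lam=log_lam, Lambda_total=Lambda, grid=grid)


def log_bernoulli_pp(
    s: np.ndarray,
    surface: IntensitySurface,
    grid: WindowGrid | None = None,
    strict: bool = False,
) -> float | np.ndarray:
    """Log-density of a single AC at ``s``: ``log lambda(s) - log Lambda``.

    Integrates to one over the habitat.  Outside the habitat the value is
    ``-inf`` so Metropolis proposals are rejected for free; ``strict=True``
    raises instead.
    """
    grid = grid or surface.grid
    pts = np.asarray(s, dtype=float)
    idx = np.atleast_1d(grid.locate(pts, strict=False))
    if strict and np.any(idx < 0):
        raise OutOfDomainError(f"AC outside the habitat: {pts}")
    val = np.where(
        idx >= 0, surface.log_lam[np.clip(idx, 0, None)] - surface.log_Lambda, -np.inf
    )
    if pts.ndim == 1:
        return float(val[0])
    return val


def log_poisson_pp_acs(
    acs,
    surface: IntensitySurface,
    grid: WindowGrid | None = None,
) -> float:
    """Unnormalised Poisson point-process log-density of an AC configuration:
    ``-Lambda + sum_i log lambda(s_i)`` (the ``-log N!`` constant is dropped).

    Any AC outside the habitat gives ``-inf``.
    """
    grid = grid or surface.grid
    coords = np.asarray(getattr(acs, "coords", acs), dtype=float).reshape(-1, 2)
    if len(coords) == 0:
        return -surface.Lambda_total
    idx = grid.locate(coords, strict=False)
    if np.any(idx < 0):
        return -np.inf
    return float(-surface.Lambda_total + surface.log_lam[idx].sum())


def log_categorical_ac(cell: int, surface: IntensitySurface) -> float:
    """Log-probability that an AC falls in habitat window ``cell`` under the
    discretised baseline model: ``log(lambda_h * area_h / Lambda)``.

    Downstream the AC coordinate used for such an individual is the window
    centroid.
    """
    h = int(cell)
    if h < 0 or h >= surface.grid.n_windows:
        raise IndexError(f"window index {cell} out of range")
    return float(
        surface.log_lam[h]
        + np.log(surface.grid.areas[h])
        - surface.log_Lambda
    )
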