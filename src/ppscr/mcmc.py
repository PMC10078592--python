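"""MCMC fitting of the point-process SCR model.

Two fitting strategies are provided:

* **Data augmentation (DA)** — the population is embedded in a super-
  population of size ``M = ceil(factor * n_observed)``; each individual
  carries a latent inclusion indicator ``z_i ~ Bernoulli(psi)`` and a
  latent activity center, and abundance is ``N = sum z``.  The density
  intercept ``beta0`` is not estimated under DA (it is absorbed by ``psi``);
  density is recovered post hoc as N times the normalised intensity.

* **Semi-complete data likelihood (SCDL)** — the activity centers of
  never-detected individuals are integrated out through the marginal void
  probability p*, and only ``u = N - n`` undetected individuals are tracked
  as a count.  Under the default N ~ Poisson(Lambda_tilde) prior (the prior
  induced by the Poisson point process for ACs) the full conditional of u
  is exactly Poisson(Lambda_tilde * p*), sampled in closed form, and
  ``beta0`` is identifiable.  A discrete-uniform N-prior is also available,
  under which ``beta0`` cancels and a random-walk integer sampler updates u.

Scalar parameters use adaptive random-walk Metropolis with per-parameter
scales (Robbins-Monro adaptation towards 44% acceptance, frozen after
burn-in); activity centers use a block random-walk Metropolis step on the
(x, y) pair with a bivariate normal proposal adapted towards 23.4%
acceptance; ``psi`` is Gibbs-sampled (Beta full conditional); ``z`` by
per-individual Bernoulli full conditionals.

Baseline variants used for method comparison: the AC distribution may be
the continuous Bernoulli point process (``ac_model="pp"``) or the
discretised categorical model over habitat cells with centroid ACs
(``"categorical"``); the observation model may be the continuous detection
point process (``detection_model="pp"``) or independent Poisson counts at
cell-center "detectors" (``"discrete"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, gammaln, logsumexp

from .data import DetectionData
from .density import DensityParams, window_intensities
from .detection import DetectionParams, integral_matrix, log_detection_pp
from .diagnostics import Chains
from .grids import WindowGrid
from .scdl import VoidCalculator, VoidConfig

__all__ = [
    "Priors",
    "MCMCConfig",
    "ModelSpec",
    "DAState",
    "da_log_posterior",
    "sample_ac_block",
    "BlockRWSampler",
    "run_mcmc",
]

_LOG_2PI = math.log(2.0 * math.pi)


def _norm_logpdf(x: float, sd: float) -> float:
    return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * _LOG_2PI


@dataclass(frozen=True)
class Priors:
    """Default priors: Normal(0, sd^2) on each beta/theta component
    (including intercepts), Uniform(0, sigma_upper) on the kernel scale,
    Uniform(0, 1) on the DA inclusion probability."""

    beta_sd: float = 10.0
    theta_sd: float = 10.0
    sigma_upper: float = 10.0

    def log_sigma(self, sigma: float) -> float:
        if 0.0 < sigma < self.sigma_upper:
            return -math.log(self.sigma_upper)
        return -np.inf


@dataclass
class MCMCConfig:
    """Sampler configuration.  ``mode`` selects the fitting strategy."""

    mode: str = "da"  # "da" | "scdl"
    iterations: int = 6000
    burn_in: int = 1000
    chains: int = 1
    seed: int = 0
    augmentation_factor: float = 2.0  # DA: M = ceil(factor * n_observed)
    nodes_per_window: int = 25  # SCDL: midpoint nodes for p*
    n_prior: str = "poisson"  # SCDL: "poisson" | "uniform"
    uniform_upper: int | None = None
    estimate_beta0: bool = True  # SCDL with Poisson N-prior only
    ac_model: str = "pp"  # "pp" | "categorical"
    detection_model: str = "pp"  # "pp" | "discrete"
    init: str = "centroid"  # "centroid" | "random"
    init_overrides: dict = field(default_factory=dict)
    sigma_init: float | None = None
    fix_all_z: bool = False  # DA: freeze z = 1 (requires M = n)
    fix_u_zero: bool = False  # SCDL: freeze u = 0 (N = n)
    save_acs: bool = False
    progress_every: int = 0

    def validate(self) -> None:
        if self.mode not in ("da", "scdl"):
            raise ValueError(f"unknown fitting mode {self.mode!r}")
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError(
                f"burn-in ({self.burn_in}) must be in [0, iterations)"
            )
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.mode == "da" and self.augmentation_factor < 1.0:
            raise ValueError("augmentation factor must be >= 1")
        if self.ac_model not in ("pp", "categorical"):
            raise ValueError(f"unknown ac_model {self.ac_model!r}")
        if self.detection_model not in ("pp", "discrete"):
            raise ValueError(f"unknown detection_model {self.detection_model!r}")
        if self.n_prior not in ("poisson", "uniform"):
            raise ValueError(f"unknown n_prior {self.n_prior!r}")


@dataclass
class ModelSpec:
    """Assembled model: grids, observed detections, priors."""

    habitat: WindowGrid
    detgrid: WindowGrid
    data: DetectionData
    priors: Priors = field(default_factory=Priors)


# ---------------------------------------------------------------------------
# DA posterior density (reference form, used directly in tests; the sampler
# evaluates the same quantity incrementally and vectorised)
# ---------------------------------------------------------------------------


@dataclass
class DAState:
    """Latent state under data augmentation."""

    M: int
    z: np.ndarray  # (M,) 0/1
    psi: float
    s: np.ndarray  # (M, 2)

    @property
    def N(self) -> int:
        return int(np.sum(self.z))


def da_log_posterior(
    state: DAState,
    dparams: DensityParams,
    oparams: DetectionParams,
    data: DetectionData,
    habitat: WindowGrid,
    detgrid: WindowGrid,
    priors: Priors = Priors(),
) -> float:
    """Joint log-posterior of the augmented model at one state:

        sum_i [ z_i (log psi + log detection-PP(y_i | s_i))
                + (1 - z_i) log(1 - psi)
                + log Bernoulli-PP(s_i) ]  + log priors.

    Individuals beyond the first ``len(data)`` are augmented all-zero
    histories.  An *observed* individual with z = 0 has posterior density
    zero (-inf).  ``beta0`` is fixed under DA, so only slope priors enter.
    """
    from .density import log_bernoulli_pp

    surface = window_intensities(habitat, dparams)
    n = len(data)
    if np.any(np.asarray(state.z[:n]) == 0):
        return -np.inf
    if not 0.0 < state.psi < 1.0:
        return -np.inf
    total = 0.0
    for i in range(state.M):
        zi = int(state.z[i])
        total += log_bernoulli_pp(state.s[i], surface)
        if zi:
            locs = data.locations[i] if i < n else np.zeros((0, 2))
            total += math.log(state.psi) + log_detection_pp(
                locs, state.s[i], oparams, detgrid
            )
        else:
            total += math.log1p(-state.psi)
    total += sum(_norm_logpdf(b, priors.beta_sd) for b in dparams.beta)
    total += _norm_logpdf(oparams.theta0, priors.theta_sd)
    total += sum(_norm_logpdf(t, priors.theta_sd) for t in oparams.theta)
    total += priors.log_sigma(oparams.sigma)
    return float(total)


# ---------------------------------------------------------------------------
# Block random-walk AC sampler
# ---------------------------------------------------------------------------


def sample_ac_block(
    current: np.ndarray,
    log_target,
    proposal_cov: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One Metropolis step with a bivariate normal proposal on the (x, y)
    pair.  A -inf target at the proposal (e.g. outside the habitat) is an
    automatic rejection, so the target never needs boundary tricks."""
    current = np.asarray(current, float)
    chol = np.linalg.cholesky(np.asarray(proposal_cov, float))
    prop = current + chol @ rng.standard_normal(2)
    lp_cur = log_target(current)
    if not np.isfinite(lp_cur):
        raise ValueError("log target is not finite at the current point")
    lp_prop = log_target(prop)
    if np.log(rng.uniform()) < lp_prop - lp_cur:
        return prop, True
    return current, False


class BlockRWSampler:
    """Adaptive block random-walk sampler for a 2-D target: isotropic
    normal proposal whose scale is adapted (Robbins-Monro) towards 23.4%
    acceptance; adaptation can be frozen (e.g. after burn-in)."""

    def __init__(
        self, log_target, init: np.ndarray, scale: float = 1.0,
        target_accept: float = 0.234,
    ) -> None:
        self.log_target = log_target
        self.state = np.asarray(init, float)
        self.log_scale = math.log(scale)
        self.target_accept = target_accept
        self.n_steps = 0
        self.n_accepted = 0
        self.adapting = True

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(self.n_steps, 1)

    def step(self, rng: np.random.Generator) -> np.ndarray:
        cov = math.exp(2 * self.log_scale) * np.eye(2)
        self.state, accepted = sample_ac_block(self.state, self.log_target, cov, rng)
        self.n_steps += 1
        self.n_accepted += int(accepted)
        if self.adapting:
            gain = min(0.25, self.n_steps ** -0.6)
            self.log_scale += gain * (float(accepted) - self.target_accept)
        return self.state


# ---------------------------------------------------------------------------
# Vectorised samplers
# ---------------------------------------------------------------------------


class _ObservedStats:
    """Sufficient statistics of the observed detections.

    For the continuous detection process the kernel term of individual i is
    ``-(sw2_i - 2 s.sw_i + M_i |s|^2) / (2 sigma^2)`` with sw/sw2 the sums
    of detection coordinates and squared norms; the discrete-detector model
    has the same form with detections replaced by count-weighted cell
    centers.  ``counts`` is the (n, L) per-window detection count matrix.
    """

    def __init__(self, data: DetectionData, detgrid: WindowGrid, model: str) -> None:
        data.validate_in_grid(detgrid)
        n, L = len(data), detgrid.n_windows
        self.counts = np.zeros((n, L))
        self.Mi = data.counts.astype(float)
        self.sw = np.zeros((n, 2))
        self.sw2 = np.zeros(n)
        centers = detgrid.centers
        for i, (_, locs) in enumerate(data):
            idx = detgrid.locate(locs)
            np.add.at(self.counts[i], idx, 1.0)
            pts = centers[idx] if model == "discrete" else locs
            self.sw[i] = pts.sum(axis=0)
            self.sw2[i] = np.sum(pts**2)

    def wd2(self, s: np.ndarray) -> np.ndarray:
        """Count-weighted squared distances from each individual's AC."""
        s = np.atleast_2d(s)
        return self.sw2 - 2.0 * np.sum(s * self.sw, axis=1) + self.Mi * np.sum(s**2, axis=1)

    def wd2_at_centers(self, centers: np.ndarray) -> np.ndarray:
        """(n, H) matrix of weighted squared distances at candidate cells."""
        c2 = np.sum(centers**2, axis=1)
        return (
            self.sw2[:, None]
            - 2.0 * self.sw @ centers.T
            + self.Mi[:, None] * c2[None, :]
        )


class _ScalarAdapter:
    """Robbins-Monro adaptation of per-parameter log proposal scales."""

    def __init__(self, names: list[str], init_scales: dict[str, float]):
        self.log_scale = {k: math.log(init_scales.get(k, 0.1)) for k in names}
        self.steps = {k: 0 for k in names}
        self.accepts = {k: 0 for k in names}
        self.adapting = True

    def scale(self, name: str) -> float:
        return math.exp(self.log_scale[name])

    def update(self, name: str, accepted: bool, target: float = 0.44) -> None:
        self.steps[name] += 1
        self.accepts[name] += int(accepted)
        if self.adapting:
            gain = min(0.25, self.steps[name] ** -0.6)
            self.log_scale[name] += gain * (float(accepted) - target)

    def rates(self) -> dict[str, float]:
        return {
            k: self.accepts[k] / max(self.steps[k], 1) for k in self.steps
        }


class _SamplerBase:
    """Shared state and updates for the DA and SCDL samplers.

    Maintains caches of the per-window intensity surface, the per-individual
    expected detection count ``Lam`` and detection-location term ``dloc``,
    and invalidates exactly the pieces each update touches.
    """

    def __init__(self, model: ModelSpec, config: MCMCConfig, rng: np.random.Generator):
        self.model = model
        self.config = config
        self.rng = rng
        self.habitat = model.habitat
        self.detgrid = model.detgrid
        self.priors = model.priors
        self.n_obs = len(model.data)
        self.stats = _ObservedStats(model.data, model.detgrid, config.detection_model)
        self.X = self.habitat.covariates  # (H, Ch)
        self.Z = self.detgrid.covariates  # (L, Cd)
        self.n_beta = self.X.shape[1]
        self.n_theta = self.Z.shape[1]
        self.log_areas = np.log(self.habitat.areas)
        self.op_counts = {"ac_intensity_evals": 0}
        self._det_centers = self.detgrid.centers
        self._cent_mat_sigma: float | None = None
        self._cent_mat: np.ndarray | None = None

    # -- detection-model kernels -------------------------------------------

    def _det_matrix(self, points: np.ndarray, sigma: float) -> np.ndarray:
        """(P, L) matrix whose product with b gives Lambda(o | s_p):
        window kernel integrals (continuous model) or point-kernel values at
        cell centers (discrete-detector model)."""
        if self.config.detection_model == "pp":
            return integral_matrix(points, sigma, self.detgrid)
        pts = np.atleast_2d(points)
        d2 = (
            np.sum(pts**2, axis=1)[:, None]
            - 2.0 * pts @ self._det_centers.T
            + np.sum(self._det_centers**2, axis=1)[None, :]
        )
        return np.exp(-d2 / (2.0 * sigma**2))

    def _centroid_det_matrix(self, sigma: float) -> np.ndarray:
        """Detection matrix at habitat-window centroids (categorical AC
        model); cached on sigma since centroids never move."""
        if self._cent_mat_sigma != sigma:
            self._cent_mat = self._det_matrix(self.habitat.centers, sigma)
            self._cent_mat_sigma = sigma
        return self._cent_mat

    # -- surface ------------------------------------------------------------

    def _surface(self, beta0: float, beta: np.ndarray):
        log_lam = beta0 + self.X @ beta
        logLam = float(logsumexp(log_lam + self.log_areas))
        return log_lam, logLam

    def _dloc(self, logb: np.ndarray, sigma: float, wd2: np.ndarray) -> np.ndarray:
        """Per-observed-individual detection location/count log-term."""
        return self.stats.counts @ logb - wd2 / (2.0 * sigma**2)

    # -- common initialisation ---------------------------------------------

    def _initial_acs(self, m: int) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.habitat.extent
        s = self.rng.uniform([xmin, ymin], [xmax, ymax], size=(m, 2))
        if self.config.init == "centroid":
            for i in range(min(self.n_obs, m)):
                locs = self.model.data.locations[i]
                if len(locs):
                    s[i] = locs.mean(axis=0)
        elif self.config.init != "random":
            raise ValueError(f"unknown init strategy {self.config.init!r}")
        return s

    def _initial_params(self) -> dict:
        ov = dict(self.config.init_overrides)
        sigma0 = self.config.sigma_init or 0.5 * self.priors.sigma_upper
        return {
            "beta0": float(ov.pop("beta0", 0.0)),
            "beta": np.array(
                [float(ov.pop(f"beta[{j}]", 0.0)) for j in range(self.n_beta)]
            ),
            "theta0": float(ov.pop("theta0", 0.0)),
            "theta": np.array(
                [float(ov.pop(f"theta[{j}]", 0.0)) for j in range(self.n_theta)]
            ),
            "sigma": float(ov.pop("sigma", sigma0)),
            **({} if not ov else self._bad_overrides(ov)),
        }

    @staticmethod
    def _bad_overrides(ov: dict):
        raise ValueError(f"unknown init overrides: {sorted(ov)}")


class _DASampler(_SamplerBase):
    def __init__(self, model, config, rng):
        super().__init__(model, config, rng)
        n = self.n_obs
        self.M = n if config.fix_all_z else int(math.ceil(config.augmentation_factor * n))
        if self.M < n:
            raise ValueError("augmented size smaller than the observed sample")
        p = self._initial_params()
        self.beta = p["beta"]
        self.theta0, self.theta, self.sigma = p["theta0"], p["theta"], p["sigma"]
        self.psi = 0.5
        self.s = self._initial_acs(self.M)
        if config.ac_model == "categorical":
            self.h = self.habitat.locate(self.s)
            self.s = self.habitat.centers[self.h]
        else:
            self.h = self.habitat.locate(self.s)
        self.z = np.zeros(self.M, dtype=bool)
        self.z[:n] = True
        if config.fix_all_z:
            self.z[:] = True
        self.adapt = _ScalarAdapter(
            [f"beta[{j}]" for j in range(self.n_beta)]
            + ["theta0", "sigma"]
            + [f"theta[{j}]" for j in range(self.n_theta)],
            {"sigma": 0.1 * self.sigma},
        )
        self.ac_scales = np.full(self.M, max(self.sigma, 0.1))
        self.ac_steps = 0
        self.ac_accepts = 0
        self._refresh_all()
        self._check_finite_init()

    # beta0 is fixed at 0 under DA (absorbed by psi)
    def _refresh_all(self) -> None:
        self.log_lam, self.logLam = self._surface(0.0, self.beta)
        self.logb = self.theta0 + self.Z @ self.theta
        self.b = np.exp(self.logb)
        self.mat = self._det_matrix(self.s, self.sigma)  # (M, L)
        self.Lam = self.mat @ self.b
        self.wd2 = self.stats.wd2(self.s[: self.n_obs])
        self.dloc = np.zeros(self.M)
        self.dloc[: self.n_obs] = self._dloc(self.logb, self.sigma, self.wd2)

    def _logdet_sum(self, Lam: np.ndarray, dloc: np.ndarray) -> float:
        """Detection log-likelihood summed over included individuals."""
        zi = self.z
        return float(-(Lam[zi].sum()) + dloc[zi].sum())

    def _check_finite_init(self) -> None:
        pieces = {
            "AC prior": self.log_lam[self.h].sum() - self.M * self.logLam,
            "detection likelihood": self._logdet_sum(self.Lam, self.dloc),
            "sigma prior": self.priors.log_sigma(self.sigma),
        }
        bad = [k for k, v in pieces.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(
                f"non-finite initial posterior; offending components: {bad}"
            )

    # -- updates ------------------------------------------------------------

    def _mh_scalar(self, name, delta_fn, apply_fn):
        scale = self.adapt.scale(name)
        delta = scale * self.rng.standard_normal()
        log_ratio = delta_fn(delta)
        accepted = np.log(self.rng.uniform()) < log_ratio
        if accepted:
            apply_fn(delta)
        self.adapt.update(name, accepted)

    def _update_beta(self):
        for j in range(self.n_beta):
            name = f"beta[{j}]"

            def delta_fn(d, j=j):
                new = self.beta.copy()
                new[j] += d
                log_lam, logLam = self._surface(0.0, new)
                prior = _norm_logpdf(new[j], self.priors.beta_sd) - _norm_logpdf(
                    self.beta[j], self.priors.beta_sd
                )
                self._cand = (new, log_lam, logLam)
                return (
                    log_lam[self.h].sum()
                    - self.log_lam[self.h].sum()
                    - self.M * (logLam - self.logLam)
                    + prior
                )

            def apply_fn(d):
                self.beta, self.log_lam, self.logLam = self._cand

            self._mh_scalar(name, delta_fn, apply_fn)

    def _update_theta0(self):
        def delta_fn(d):
            Lam_new = self.Lam * math.exp(d)
            dloc_new = self.dloc.copy()
            dloc_new[: self.n_obs] += self.stats.Mi * d
            prior = _norm_logpdf(self.theta0 + d, self.priors.theta_sd) - _norm_logpdf(
                self.theta0, self.priors.theta_sd
            )
            self._cand = (Lam_new, dloc_new, d)
            return (
                self._logdet_sum(Lam_new, dloc_new)
                - self._logdet_sum(self.Lam, self.dloc)
                + prior
            )

        def apply_fn(d):
            Lam_new, dloc_new, d = self._cand
            self.theta0 += d
            self.logb += d
            self.b = np.exp(self.logb)
            self.Lam, self.dloc = Lam_new, dloc_new

        self._mh_scalar("theta0", delta_fn, apply_fn)

    def _update_theta(self):
        for j in range(self.n_theta):
            name = f"theta[{j}]"

            def delta_fn(d, j=j):
                logb_new = self.logb + d * self.Z[:, j]
                b_new = np.exp(logb_new)
                Lam_new = self.mat @ b_new
                dloc_new = self.dloc.copy()
                dloc_new[: self.n_obs] += d * (self.stats.counts @ self.Z[:, j])
                prior = _norm_logpdf(
                    self.theta[j] + d, self.priors.theta_sd
                ) - _norm_logpdf(self.theta[j], self.priors.theta_sd)
                self._cand = (logb_new, b_new, Lam_new, dloc_new, d, j)
                return (
                    self._logdet_sum(Lam_new, dloc_new)
                    - self._logdet_sum(self.Lam, self.dloc)
                    + prior
                )

            def apply_fn(d):
                logb_new, b_new, Lam_new, dloc_new, d, j = self._cand
                self.theta[j] += d
                self.logb, self.b = logb_new, b_new
                self.Lam, self.dloc = Lam_new, dloc_new

            self._mh_scalar(name, delta_fn, apply_fn)

    def _update_sigma(self):
        def delta_fn(d):
            sig_new = self.sigma + d
            if not (0.0 < sig_new < self.priors.sigma_upper):
                self._cand = None
                return -np.inf
            mat_new = self._det_matrix(self.s, sig_new)
            Lam_new = mat_new @ self.b
            dloc_new = np.zeros(self.M)
            dloc_new[: self.n_obs] = self._dloc(self.logb, sig_new, self.wd2)
            self._cand = (sig_new, mat_new, Lam_new, dloc_new)
            return self._logdet_sum(Lam_new, dloc_new) - self._logdet_sum(
                self.Lam, self.dloc
            )

        def apply_fn(d):
            self.sigma, self.mat, self.Lam, self.dloc = self._cand
            self._cent_mat_sigma = None  # invalidate centroid cache

        self._mh_scalar("sigma", delta_fn, apply_fn)

    def _update_acs(self):
        if self.config.ac_model == "categorical":
            self._update_acs_categorical()
            return
        n = self.n_obs
        prop = self.s + self.ac_scales[:, None] * self.rng.standard_normal((self.M, 2))
        h_new = self.habitat.locate(prop, strict=False)
        inside = h_new >= 0
        logac_new = np.where(inside, self.log_lam[np.clip(h_new, 0, None)], -np.inf)
        mat_new = self._det_matrix(prop, self.sigma)
        Lam_new = mat_new @ self.b
        wd2_new = self.stats.wd2(prop[:n])
        dloc_new = np.zeros(self.M)
        dloc_new[:n] = self._dloc(self.logb, self.sigma, wd2_new)
        logdet_new = np.where(self.z, -Lam_new + dloc_new, 0.0)
        logdet_cur = np.where(self.z, -self.Lam + self.dloc, 0.0)
        delta = (logac_new - self.log_lam[self.h]) + (logdet_new - logdet_cur)
        acc = np.log(self.rng.uniform(size=self.M)) < delta
        self.s[acc] = prop[acc]
        self.h[acc] = h_new[acc]
        self.mat[acc] = mat_new[acc]
        self.Lam[acc] = Lam_new[acc]
        obs_acc = acc[:n]
        self.wd2[obs_acc] = wd2_new[obs_acc]
        self.dloc[:n][obs_acc] = dloc_new[:n][obs_acc]
        self.op_counts["ac_intensity_evals"] += self.M
        self.ac_steps += self.M
        self.ac_accepts += int(acc.sum())
        if self.adapt.adapting:
            t = self.op_counts["ac_intensity_evals"] // self.M
            gain = min(0.25, t ** -0.6)
            self.ac_scales *= np.exp(gain * (acc.astype(float) - 0.234))

    def _update_acs_categorical(self):
        n, H = self.n_obs, self.habitat.n_windows
        mat_cent = self._centroid_det_matrix(self.sigma)  # (H, L)
        Lam_cent = mat_cent @ self.b  # (H,)
        logpi = self.log_lam + self.log_areas  # unnormalised cell log-probs
        logits = np.tile(logpi, (self.M, 1))
        logits[self.z] -= Lam_cent[None, :]
        wd2_cent = self.stats.wd2_at_centers(self.habitat.centers)  # (n, H)
        logits[:n][self.z[:n]] -= (
            wd2_cent[self.z[:n]] / (2.0 * self.sigma**2)
        )
        gumb = -np.log(-np.log(self.rng.uniform(size=(self.M, H))))
        self.h = np.argmax(logits + gumb, axis=1)
        self.s = self.habitat.centers[self.h]
        self.mat = mat_cent[self.h]
        self.Lam = Lam_cent[self.h]
        self.wd2 = wd2_cent[np.arange(n), self.h[:n]]
        self.dloc = np.zeros(self.M)
        self.dloc[:n] = self._dloc(self.logb, self.sigma, self.wd2)
        self.op_counts["ac_intensity_evals"] += self.M * H

    def _update_z(self):
        if self.config.fix_all_z:
            return
        n = self.n_obs
        log_odds = (
            math.log(self.psi) - math.log1p(-self.psi) - self.Lam[n:]
        )
        p1 = expit(log_odds)
        self.z[n:] = self.rng.uniform(size=self.M - n) < p1

    def _update_psi(self):
        N = int(self.z.sum())
        self.psi = float(self.rng.beta(1 + N, 1 + self.M - N))

    def run(self) -> dict:
        cfg = self.config
        names = (
            [f"beta[{j}]" for j in range(self.n_beta)]
            + ["theta0"]
            + [f"theta[{j}]" for j in range(self.n_theta)]
            + ["sigma", "psi", "N"]
        )
        draws = {k: np.empty(cfg.iterations) for k in names}
        for t in range(cfg.iterations):
            if t == cfg.burn_in:
                self.adapt.adapting = False
            self._update_beta()
            self._update_theta0()
            self._update_theta()
            self._update_sigma()
            self._update_acs()
            self._update_z()
            self._update_psi()
            for j in range(self.n_beta):
                draws[f"beta[{j}]"][t] = self.beta[j]
            draws["theta0"][t] = self.theta0
            for j in range(self.n_theta):
                draws[f"theta[{j}]"][t] = self.theta[j]
            draws["sigma"][t] = self.sigma
            draws["psi"][t] = self.psi
            draws["N"][t] = self.z.sum()
        return draws

    def acceptance_rates(self) -> dict:
        rates = self.adapt.rates()
        rates["ac_block"] = self.ac_accepts / max(self.ac_steps, 1)
        return rates


class _SCDLSampler(_SamplerBase):
    def __init__(self, model, config, rng):
        super().__init__(model, config, rng)
        if config.ac_model != "pp" or config.detection_model != "pp":
            raise ValueError("SCDL fitting supports the point-process models only")
        self.void = VoidCalculator(
            self.habitat, self.detgrid, VoidConfig(config.nodes_per_window)
        )
        self.estimate_beta0 = config.estimate_beta0 and config.n_prior == "poisson"
        self.uniform_upper = (
            config.uniform_upper
            if config.uniform_upper is not None
            else 100 * max(self.n_obs, 1)
        )
        p = self._initial_params()
        self.beta0 = p["beta0"]
        self.beta = p["beta"]
        self.theta0, self.theta, self.sigma = p["theta0"], p["theta"], p["sigma"]
        self.s = self._initial_acs(self.n_obs)
        self.h = self.habitat.locate(self.s)
        self._refresh_all()
        u0 = self.Lam_tilde * self.p_star
        self.u = 0 if config.fix_u_zero else max(0, int(round(u0)))
        self.adapt = _ScalarAdapter(
            (["beta0"] if self.estimate_beta0 else [])
            + [f"beta[{j}]" for j in range(self.n_beta)]
            + ["theta0", "sigma", "u"]
            + [f"theta[{j}]" for j in range(self.n_theta)],
            {"sigma": 0.1 * self.sigma, "u": max(1.0, 0.3 * math.sqrt(u0 + 1.0))},
        )
        self.ac_scales = np.full(self.n_obs, max(self.sigma, 0.1))
        self.ac_steps = 0
        self.ac_accepts = 0
        self._check_finite_init()

    def _refresh_all(self):
        self.log_lam, self.logLam = self._surface(self.beta0, self.beta)
        self.Lam_tilde = math.exp(self.logLam)
        self.logb = self.theta0 + self.Z @ self.theta
        self.b = np.exp(self.logb)
        self.mat = self._det_matrix(self.s, self.sigma)
        self.Lam = self.mat @ self.b
        self.wd2 = self.stats.wd2(self.s)
        self.dloc = self._dloc(self.logb, self.sigma, self.wd2)
        self.p_star = self.void(
            DensityParams(self.beta0, self.beta),
            DetectionParams(self.theta0, self.theta, self.sigma),
        )

    def _check_finite_init(self):
        pieces = {
            "AC prior": self.log_lam[self.h].sum(),
            "detection likelihood": float(-self.Lam.sum() + self.dloc.sum()),
            "void probability": 0.0 if self.p_star > 0 or self.u == 0 else -np.inf,
            "sigma prior": self.priors.log_sigma(self.sigma),
        }
        bad = [k for k, v in pieces.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(
                f"non-finite initial posterior; offending components: {bad}"
            )

    # population/void part of the target, as a function of the surface and p*
    def _pop_term(self, logLam: float, p_star: float) -> float:
        u = self.u
        if u > 0 and p_star <= 0.0:
            return -np.inf
        void = u * math.log(p_star) if u > 0 else 0.0
        if self.config.n_prior == "poisson":
            return -math.exp(logLam) + u * logLam + void - float(gammaln(u + 1))
        # uniform N-prior: binomial coefficient, bounded support
        N = self.n_obs + u
        if N > self.uniform_upper:
            return -np.inf
        return float(
            gammaln(N + 1) - gammaln(self.n_obs + 1) - gammaln(u + 1)
        ) + void - self.n_obs * logLam

    def _p_star_at(self, beta, theta0, theta, sigma) -> float:
        return self.void(
            DensityParams(self.beta0, beta), DetectionParams(theta0, theta, sigma)
        )

    def _mh_scalar(self, name, delta_fn, apply_fn):
        scale = self.adapt.scale(name)
        delta = scale * self.rng.standard_normal()
        log_ratio = delta_fn(delta)
        accepted = np.log(self.rng.uniform()) < log_ratio
        if accepted:
            apply_fn(delta)
        self.adapt.update(name, accepted)

    def _update_u(self):
        if self.config.fix_u_zero:
            return
        if self.config.n_prior == "poisson":
            # conjugate full conditional: u ~ Poisson(Lambda_tilde * p*)
            self.u = int(self.rng.poisson(self.Lam_tilde * self.p_star))
            return
        step = max(1, int(round(self.adapt.scale("u"))))
        u_new = self.u + int(self.rng.integers(-step, step + 1))
        if u_new == self.u:
            self.adapt.update("u", False)
            return
        cur = self._pop_term(self.logLam, self.p_star)
        u_old, self.u = self.u, u_new
        new = -np.inf if u_new < 0 else self._pop_term(self.logLam, self.p_star)
        accepted = np.log(self.rng.uniform()) < new - cur
        if not accepted:
            self.u = u_old
        self.adapt.update("u", accepted)

    def _update_beta0(self):
        def delta_fn(d):
            logLam_new = self.logLam + d
            prior = _norm_logpdf(self.beta0 + d, self.priors.beta_sd) - _norm_logpdf(
                self.beta0, self.priors.beta_sd
            )
            self._cand = (d, logLam_new)
            return (
                self._pop_term(logLam_new, self.p_star)
                - self._pop_term(self.logLam, self.p_star)
                + self.n_obs * d  # sum_i log lambda(s_i) shifts by d each
                + prior
            )

        def apply_fn(d):
            d, logLam_new = self._cand
            self.beta0 += d
            self.log_lam = self.log_lam + d
            self.logLam = logLam_new
            self.Lam_tilde = math.exp(logLam_new)

        self._mh_scalar("beta0", delta_fn, apply_fn)

    def _update_beta(self):
        for j in range(self.n_beta):
            name = f"beta[{j}]"

            def delta_fn(d, j=j):
                new = self.beta.copy()
                new[j] += d
                log_lam, logLam = self._surface(self.beta0, new)
                p_new = self._p_star_at(new, self.theta0, self.theta, self.sigma)
                prior = _norm_logpdf(new[j], self.priors.beta_sd) - _norm_logpdf(
                    self.beta[j], self.priors.beta_sd
                )
                self._cand = (new, log_lam, logLam, p_new)
                return (
                    self._pop_term(logLam, p_new)
                    - self._pop_term(self.logLam, self.p_star)
                    + log_lam[self.h].sum()
                    - self.log_lam[self.h].sum()
                    + prior
                )

            def apply_fn(d):
                self.beta, self.log_lam, self.logLam, self.p_star = self._cand
                self.Lam_tilde = math.exp(self.logLam)

            self._mh_scalar(name, delta_fn, apply_fn)

    def _update_theta0(self):
        def delta_fn(d):
            p_new = self._p_star_at(self.beta, self.theta0 + d, self.theta, self.sigma)
            Lam_new = self.Lam * math.exp(d)
            dloc_new = self.dloc + self.stats.Mi * d
            prior = _norm_logpdf(self.theta0 + d, self.priors.theta_sd) - _norm_logpdf(
                self.theta0, self.priors.theta_sd
            )
            self._cand = (d, p_new, Lam_new, dloc_new)
            return (
                self._pop_term(self.logLam, p_new)
                - self._pop_term(self.logLam, self.p_star)
                + float(-(Lam_new - self.Lam).sum() + (dloc_new - self.dloc).sum())
                + prior
            )

        def apply_fn(d):
            d, p_new, Lam_new, dloc_new = self._cand
            self.theta0 += d
            self.logb += d
            self.b = np.exp(self.logb)
            self.p_star, self.Lam, self.dloc = p_new, Lam_new, dloc_new

        self._mh_scalar("theta0", delta_fn, apply_fn)

    def _update_theta(self):
        for j in range(self.n_theta):
            name = f"theta[{j}]"

            def delta_fn(d, j=j):
                new = self.theta.copy()
                new[j] += d
                logb_new = self.theta0 + self.Z @ new
                b_new = np.exp(logb_new)
                Lam_new = self.mat @ b_new
                dloc_new = self.dloc + d * (self.stats.counts @ self.Z[:, j])
                p_new = self._p_star_at(self.beta, self.theta0, new, self.sigma)
                prior = _norm_logpdf(new[j], self.priors.theta_sd) - _norm_logpdf(
                    self.theta[j], self.priors.theta_sd
                )
                self._cand = (new, logb_new, b_new, Lam_new, dloc_new, p_new)
                return (
                    self._pop_term(self.logLam, p_new)
                    - self._pop_term(self.logLam, self.p_star)
                    + float(-(Lam_new - self.Lam).sum() + (dloc_new - self.dloc).sum())
                    + prior
                )

            def apply_fn(d):
                (self.theta, self.logb, self.b, self.Lam, self.dloc, self.p_star) = (
                    self._cand
                )

            self._mh_scalar(name, delta_fn, apply_fn)

    def _update_sigma(self):
        def delta_fn(d):
            sig_new = self.sigma + d
            if not (0.0 < sig_new < self.priors.sigma_upper):
                self._cand = None
                return -np.inf
            mat_new = self._det_matrix(self.s, sig_new)
            Lam_new = mat_new @ self.b
            dloc_new = self._dloc(self.logb, sig_new, self.wd2)
            p_new = self._p_star_at(self.beta, self.theta0, self.theta, sig_new)
            self._cand = (sig_new, mat_new, Lam_new, dloc_new, p_new)
            return (
                self._pop_term(self.logLam, p_new)
                - self._pop_term(self.logLam, self.p_star)
                + float(-(Lam_new - self.Lam).sum() + (dloc_new - self.dloc).sum())
            )

        def apply_fn(d):
            (self.sigma, self.mat, self.Lam, self.dloc, self.p_star) = self._cand

        self._mh_scalar("sigma", delta_fn, apply_fn)

    def _update_acs(self):
        n = self.n_obs
        if n == 0:
            return
        prop = self.s + self.ac_scales[:, None] * self.rng.standard_normal((n, 2))
        h_new = self.habitat.locate(prop, strict=False)
        inside = h_new >= 0
        logac_new = np.where(inside, self.log_lam[np.clip(h_new, 0, None)], -np.inf)
        mat_new = self._det_matrix(prop, self.sigma)
        Lam_new = mat_new @ self.b
        wd2_new = self.stats.wd2(prop)
        dloc_new = self._dloc(self.logb, self.sigma, wd2_new)
        delta = (
            (logac_new - self.log_lam[self.h])
            + (-Lam_new + dloc_new)
            - (-self.Lam + self.dloc)
        )
        acc = np.log(self.rng.uniform(size=n)) < delta
        self.s[acc] = prop[acc]
        self.h[acc] = h_new[acc]
        self.mat[acc] = mat_new[acc]
        self.Lam[acc] = Lam_new[acc]
        self.wd2[acc] = wd2_new[acc]
        self.dloc[acc] = dloc_new[acc]
        self.op_counts["ac_intensity_evals"] += n
        self.ac_steps += n
        self.ac_accepts += int(acc.sum())
        if self.adapt.adapting:
            t = self.op_counts["ac_intensity_evals"] // n
            gain = min(0.25, t ** -0.6)
            self.ac_scales *= np.exp(gain * (acc.astype(float) - 0.234))

    def run(self) -> dict:
        cfg = self.config
        names = (
            (["beta0"] if self.estimate_beta0 else [])
            + [f"beta[{j}]" for j in range(self.n_beta)]
            + ["theta0"]
            + [f"theta[{j}]" for j in range(self.n_theta)]
            + ["sigma", "u", "N", "p_star"]
        )
        draws = {k: np.empty(cfg.iterations) for k in names}
        for t in range(cfg.iterations):
            if t == cfg.burn_in:
                self.adapt.adapting = False
            if self.estimate_beta0:
                self._update_beta0()
            self._update_beta()
            self._update_theta0()
            self._update_theta()
            self._update_sigma()
            self._update_acs()
            self._update_u()
            if self.estimate_beta0:
                draws["beta0"][t] = self.beta0
            for j in range(self.n_beta):
                draws[f"beta[{j}]"][t] = self.beta[j]
            draws["theta0"][t] = self.theta0
            for j in range(self.n_theta):
                draws[f"theta[{j}]"][t] = self.theta[j]
            draws["sigma"][t] = self.sigma
            draws["u"][t] = self.u
            draws["N"][t] = self.n_obs + self.u
            draws["p_star"][t] = self.p_star
        return draws

    def acceptance_rates(self) -> dict:
        rates = self.adapt.rates()
        rates["ac_block"] = self.ac_accepts / max(self.ac_steps, 1)
        return rates


def run_mcmc(model: ModelSpec, config: MCMCConfig) -> Chains:
    """Run one or more MCMC chains and return the posterior draws.

    Deterministic given ``config.seed``: chain c uses the generator seeded
    with ``[seed, c]``, so identical configs give bit-identical draws.
    """
    config.validate()
    all_draws: list[dict] = []
    acc_rates: list[dict] = []
    op_counts: list[dict] = []
    p_star_evals: list[int] = []
    for c in range(config.chains):
        rng = np.random.default_rng([int(config.seed), c])
        cls = _DASampler if config.mode == "da" else _SCDLSampler
        sampler = cls(model, config, rng)
        all_draws.append(sampler.run())
        acc_rates.append(sampler.acceptance_rates())
        op_counts.append(dict(sampler.op_counts))
        p_star_evals.append(
            sampler.void.n_evaluations if config.mode == "scdl" else 0
        )
    names = list(all_draws[0])
    draws = {k: np.stack([d[k] for d in all_draws]) for k in names}
    meta = {
        "mode": config.mode,
        "seed": int(config.seed),
        "iterations": config.iterations,
        "burn_in": config.burn_in,
        "n_observed": len(model.data),
        "acceptance_rates": acc_rates,
        "op_counts": op_counts,
        "p_star_evaluations": p_star_evals,
        "config": {
            k: v for k, v in asdict(config).items() if not isinstance(v, np.ndarray)
        },
    }
    return Chains(draws=draws, burn_in=config.burn_in, meta=meta)
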