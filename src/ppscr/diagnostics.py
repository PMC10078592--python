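"""Posterior containers and MCMC diagnostics (ESS, split R-hat, summaries).

Effective sample size uses Geyer's initial-monotone-sequence truncation of
the autocorrelation sum; R-hat is the rank-normalised split version.  Both
are delegated to ``arviz``, the standard implementation of these estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

__all__ = ["Chains", "ess", "rhat", "summarize"]


@dataclass
class Chains:
    """Posterior draws: one (n_chains, n_iterations) array per parameter,
    plus run metadata (burn-in, seed, acceptance rates, config echo)."""

    draws: dict[str, np.ndarray]
    burn_in: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.draws.values()}
        if len(shapes) > 1:
            raise ValueError(f"parameter draw arrays differ in shape: {shapes}")
        (shape,) = shapes or {(0, 0)}
        if self.burn_in >= shape[1] and shape[1] > 0:
            raise ValueError(f"burn-in {self.burn_in} >= iterations {shape[1]}")

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_iterations(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def posterior(self, name: str) -> np.ndarray:
        """Post-burn-in draws, shape (n_chains, n_kept)."""
        return self.draws[name][:, self.burn_in :]

    def flat(self, name: str) -> np.ndarray:
        return self.posterior(name).ravel()

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        nc, ni = self.n_chains, self.n_iterations
        rows["chain"] = np.repeat(np.arange(nc), ni)
        rows["iteration"] = np.tile(np.arange(ni), nc)
        for name, arr in self.draws.items():
            rows[name] = arr.ravel()
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, burn_in: int = 0) -> "Chains":
        if not {"chain", "iteration"}.issubset(df.columns):
            raise ValueError("chains table needs 'chain' and 'iteration' columns")
        sizes = df.groupby("chain").size()
        if sizes.nunique() != 1:
            raise ValueError(
                f"chains have unequal lengths {dict(sizes)} — file truncated?"
            )
        nc, ni = len(sizes), int(sizes.iloc[0])
        df = df.sort_values(["chain", "iteration"])
        draws = {
            c: df[c].to_numpy(float).reshape(nc, ni)
            for c in df.columns
            if c not in ("chain", "iteration")
        }
        return cls(draws=draws, burn_in=burn_in)

    @classmethod
    def from_csv(cls, path, burn_in: int = 0) -> "Chains":
        return cls.from_frame(pd.read_csv(path), burn_in=burn_in)


def ess(chain: np.ndarray) -> float:
    """Effective sample size of one or more chains (autocorrelation-based,
    initial-monotone-sequence truncation).  NaN for constant chains."""
    arr = np.atleast_2d(np.asarray(chain, float))
    if arr.shape[1] <= 10:
        raise ValueError("need more than 10 draws for an ESS estimate")
    if np.allclose(arr, arr.ravel()[0]):
        warnings.warn("constant chain: ESS undefined, returning NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.ess(az.convert_to_dataset(arr))["x"]))


def rhat(chains: np.ndarray) -> float:
    """Rank-normalised split R-hat across >= 2 chains."""
    arr = np.atleast_2d(np.asarray(chains, float))
    if arr.shape[0] < 2:
        raise ValueError("R-hat needs at least two chains")
    if np.allclose(arr, arr.ravel()[0]):
        warnings.warn("constant chains: R-hat undefined, returning NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.rhat(az.convert_to_dataset(arr))["x"]))


def summarize(chains: "Chains") -> pd.DataFrame:
    """Posterior summary per parameter: mean, SD, 2.5/50/97.5 percentiles,
    ESS, and R-hat (when >= 2 chains)."""
    rows = []
    for name in chains.parameter_names:
        post = chains.posterior(name)
        flat = post.ravel()
        constant = np.allclose(flat, flat[0]) if len(flat) else True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.percentile(flat, 2.5),
                    "median": np.percentile(flat, 50.0),
                    "q97.5": np.percentile(flat, 97.5),
                    "ess": float("nan") if constant else ess(post),
                    "rhat": (
                        rhat(post)
                        if chains.n_chains >= 2 and not constant
                        else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows).set_index("parameter")
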