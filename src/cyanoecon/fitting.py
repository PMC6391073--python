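"""Likelihood-based estimation of (tau, kd, sigma) from light--growth data.

The three photosynthesis parameters of the allocation model -- turnover
rate tau, photodamage probability kd and absorption cross-section sigma --
are estimated by evaluating the model's predicted steady-state growth rate
at every measured light intensity for each candidate triple on a
pre-defined grid, and scoring each candidate with the Gaussian negative
log-likelihood

    l(theta) = sum_i [ (y_i(theta) - x_i)^2 / e_i^2 + log(2 pi e_i^2) ]

where x_i are the measured specific growth rates with uncertainties e_i
and y_i(theta) the simulated rates.  Lower is better; the reported
optimum is the grid argmin.

The public surface follows the Model/Results convention:
``LightResponseModel(observations).fit(grid)`` returns a
``LightResponseResults`` with the best triple, the full ranked likelihood
table and a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .growth import light_response
from .params import EnvironmentalCondition, ModelParameters


@dataclass(frozen=True)
class GrowthObservation:
    """One light--growth measurement: intensity, rate x_i (h^-1), SD e_i."""

    I: float
    x: float
    e: float

    def __post_init__(self) -> None:
        if self.e <= 0:
            raise ValueError("observation uncertainty e must be > 0")
        if self.x < 0:
            raise ValueError("measured growth rate x must be >= 0")
        if self.I < 0:
            raise ValueError("light intensity must be >= 0")


def default_tau_grid() -> list[float]:
    return [50.0, 75.0, 100.0]


def default_kd_grid() -> list[float]:
    """Photodamage candidates: {5..9}e-7 plus {1..5}e-6."""
    return [k * 1e-7 for k in range(5, 10)] + [k * 1e-6 for k in range(1, 6)]


def default_sigma_grid() -> list[float]:
    """Cross-section candidates 0.1 ... 1.0 nm^2 in steps of 0.1."""
    return [round(0.1 * k, 10) for k in range(1, 11)]


@dataclass(frozen=True)
class FitGrid:
    """Candidate sets for the grid search over theta = (tau, kd, sigma)."""

    tau_values: tuple = tuple(default_tau_grid())
    kd_values: tuple = tuple(default_kd_grid())
    sigma_values: tuple = tuple(default_sigma_grid())

    def __post_init__(self) -> None:
        for name in ("tau_values", "kd_values", "sigma_values"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"{name} must be nonempty")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be strictly positive")
            if list(vals) != sorted(vals):
                raise ValueError(f"{name} must be sorted ascending")
            object.__setattr__(self, name, vals)

    def __iter__(self):
        for tau in self.tau_values:
            for kd in self.kd_values:
                for sigma in self.sigma_values:
                    yield (tau, kd, sigma)

    def __len__(self) -> int:
        return (len(self.tau_values) * len(self.kd_values)
                * len(self.sigma_values))


@dataclass
class LikelihoodResult:
    """Score of one candidate triple: l(theta) and per-point contributions."""

    theta: tuple[float, float, float]
    l: float
    per_point: pd.DataFrame

    def __post_init__(self) -> None:
        if not math.isfinite(self.l):
            raise ValueError("negative log-likelihood must be finite")
        total = float(self.per_point["contribution"].sum())
        if abs(total - self.l) > 1e-9:
            raise ValueError("per-point contributions do not sum to l")


def neg_log_likelihood(sim: Sequence[float], obs: Sequence[GrowthObservation],
                       theta: tuple[float, float, float] = (float("nan"),) * 3
                       ) -> LikelihoodResult:
    """Gaussian negative log-likelihood of simulated vs measured rates.

    ``sum_i (y_i - x_i)^2 / e_i^2 + log(2 pi e_i^2)``; lower is better.
    """
    sim = np.asarray(sim, dtype=float)
    if len(sim) != len(obs):
        raise ValueError(f"length mismatch: {len(sim)} simulated vs "
                         f"{len(obs)} observed")
    if len(obs) == 0:
        raise ValueError("at least one observation is required")
    x = np.array([o.x for o in obs])
    e = np.array([o.e for o in obs])
    if np.any(e <= 0):
        raise ValueError("all observation SDs must be > 0")
    contrib = (sim - x) ** 2 / e ** 2 + np.log(2.0 * np.pi * e ** 2)
    table = pd.DataFrame({
        "I": [o.I for o in obs], "x": x, "e": e, "y": sim,
        "contribution": contrib,
    })
    return LikelihoodResult(theta=tuple(theta), l=float(contrib.sum()),
                            per_point=table)


def grid_fit(obs: Sequence[GrowthObservation], grid: FitGrid | None = None,
             base_params: ModelParameters | None = None,
             cix: float = 100.0) -> tuple[LikelihoodResult, pd.DataFrame]:
    """Exhaustive grid search: best LikelihoodResult plus the ranked table.

    For every candidate theta the model is solved at every observed light
    intensity and scored with :func:`neg_log_likelihood`.  Ties in l are
    broken toward the smallest kd, then sigma, then tau (the least-damage,
    least-cost explanation).  Deterministic.
    """
    obs = list(obs)
    if len({o.I for o in obs}) < 2:
        raise ValueError("observations must span at least two intensities")
    grid = grid or FitGrid()
    base = base_params or ModelParameters()
    I_sorted = sorted({o.I for o in obs})
    rows = []
    best: LikelihoodResult | None = None
    failures = []
    for tau, kd, sigma in grid:
        params = base.with_theta(tau=tau, kd=kd, sigma=sigma)
        try:
            states = light_response(params, I_sorted, cix=cix)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(((tau, kd, sigma), str(exc)))
            continue
        mu_at = {st.env.I: st.mu for st in states}
        if any(st.status == "failed" for st in states):
            failures.append(((tau, kd, sigma), "solver failure"))
            continue
        sim = [mu_at[o.I] for o in obs]
        result = neg_log_likelihood(sim, obs, theta=(tau, kd, sigma))
        rows.append({"tau": tau, "kd": kd, "sigma": sigma, "l": result.l})
        key = (result.l, kd, sigma, tau)
        if best is None or key < (best.l, best.theta[1], best.theta[2],
                                  best.theta[0]):
            best = result
    if best is None:
        raise RuntimeError("all grid points failed: "
                           + "; ".join(f"{t}: {m}" for t, m in failures))
    table = pd.DataFrame(rows).sort_values(
        ["l", "kd", "sigma", "tau"]).reset_index(drop=True)
    return best, table


class LightResponseModel:
    """Phototrophic growth-law model bound to light--growth observations.

    Parameters
    ----------
    observations : sequence of GrowthObservation
        Measured (intensity, growth rate, SD) triples.
    base_params : ModelParameters, optional
        Non-fitted model constants (defaults to the packaged set).
    cix : float
        External inorganic carbon (mM) assumed during fitting.

    Examples
    --------
    >>> model = LightResponseModel.from_dataframe(df)  # doctest: +SKIP
    >>> res = model.fit()                              # doctest: +SKIP
    >>> print(res.summary())                           # doctest: +SKIP
    """

    def __init__(self, observations: Iterable[GrowthObservation],
                 base_params: ModelParameters | None = None,
                 cix: float = 100.0):
        self.observations = list(observations)
        if not self.observations:
            raise ValueError("observations must be nonempty")
        self.base_params = base_params or ModelParameters()
        self.cix = cix

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, light_col: str = "light",
                       mu_col: str = "mu", sd_col: str = "sd",
                       **kwargs) -> "LightResponseModel":
        """Build from a table with light / growth-rate / SD columns."""
        missing = {light_col, mu_col, sd_col} - set(df.columns)
        if missing:
            raise KeyError(f"missing columns: {sorted(missing)}")
        obs = [GrowthObservation(I=float(r[light_col]), x=float(r[mu_col]),
                                 e=float(r[sd_col]))
               for _, r in df.iterrows()]
        return cls(obs, **kwargs)

    def loglike_table(self, theta: tuple[float, float, float]
                      ) -> LikelihoodResult:
        """Score a single candidate triple against the observations."""
        tau, kd, sigma = theta
        params = self.base_params.with_theta(tau=tau, kd=kd, sigma=sigma)
        states = light_response(params,
                                sorted({o.I for o in self.observations}),
                                cix=self.cix)
        mu_at = {st.env.I: st.mu for st in states}
        sim = [mu_at[o.I] for o in self.observations]
        return neg_log_likelihood(sim, self.observations, theta=theta)

    def fit(self, grid: FitGrid | None = None) -> "LightResponseResults":
        best, table = grid_fit(self.observations, grid=grid,
                               base_params=self.base_params, cix=self.cix)
        return LightResponseResults(self, best, table, grid or FitGrid())


class LightResponseResults:
    """Grid-search fit results: estimates, ranked table, diagnostics."""

    def __init__(self, model: LightResponseModel, best: LikelihoodResult,
                 table: pd.DataFrame, grid: FitGrid):
        self.model = model
        self.best = best
        self.table = table
        self.grid = grid

    @property
    def params(self) -> dict[str, float]:
        tau, kd, sigma = self.best.theta
        return {"tau": tau, "kd": kd, "sigma": sigma}

    @property
    def llf(self) -> float:
        """Negative log-likelihood at the optimum (the fit criterion)."""
        return self.best.l

    @property
    def fitted_parameters(self) -> ModelParameters:
        return self.model.base_params.with_theta(**self.params)

    def predict(self, I_grid: Sequence[float]) -> pd.DataFrame:
        """Model growth rates on a light grid at the fitted triple."""
        from .growth import light_response_frame

        states = light_response(self.fitted_parameters, sorted(I_grid),
                                cix=self.model.cix)
        return light_response_frame(states)

    def grid_margin(self) -> pd.DataFrame:
        """Best l per parameter value (profile over the grid)."""
        out = []
        for name in ("tau", "kd", "sigma"):
            prof = self.table.groupby(name)["l"].min().reset_index()
            prof["parameter"] = name
            prof = prof.rename(columns={name: "value"})
            out.append(prof)
        return pd.concat(out, ignore_index=True)[["parameter", "value", "l"]]

    def summary(self) -> str:
        tau, kd, sigma = self.best.theta
        n = len(self.model.observations)
        lines = [
            "Light-response grid fit (Gaussian negative log-likelihood)",
            "=" * 58,
            f"observations:        {n}",
            f"grid size:           {len(self.grid)} candidate triples",
            f"scored candidates:   {len(self.table)}",
            "",
            f"tau    (PSU turnover)        {tau:10.4g} s^-1",
            f"kd     (photodamage prob.)   {kd:10.4g}",
            f"sigma  (cross-section)       {sigma:10.4g} nm^2",
            "",
            f"l(theta) at optimum:  {self.best.l:.4f}",
            "",
            "per-observation fit:",
            self.best.per_point.to_string(
                index=False, float_format=lambda v: f"{v:.5g}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        tau, kd, sigma = self.best.theta
        return (f"<LightResponseResults tau={tau:g} kd={kd:g} "
                f"sigma={sigma:g} l={self.best.l:.3f}>")
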