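"""Probabilistic sensitivity analysis and expected value of perfect information.

Four characterizations of the uncertainty of the calibrated natural-history
parameters are propagated through the screening CEA:

* **A1_posterior_plus_external** — calibrated parameters drawn from their
  joint posterior; external CEA parameters drawn from their fitted
  distributions.
* **A2_map_plus_external** — calibrated parameters fixed at the MAP
  estimate; external parameters drawn.
* **A3_posterior_only** — calibrated parameters drawn from the posterior;
  external parameters fixed at their point values.
* **A4_moments_independent_plus_external** — each calibrated parameter drawn
  independently from a beta (proportions) or lognormal (positive
  parameters) distribution moment-matched to its posterior mean and SD,
  deliberately discarding the posterior correlations; external parameters
  drawn.

Per-patient EVPI at willingness-to-pay ``wtp`` is
``E[max_s NB_s] - max_s E[NB_s]`` over the PSA draws, where
``NB_s = wtp * QALY_s - cost_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .calibration import PosteriorSample, PosteriorSummary, map_estimate
from .config import load_cea_config
from .microsim import precompute_transitions
from .model_core import LifeTable
from .params import CalibratedParams, FixedParams
from .screening_cea import CEAParams, default_cea_params, simulate_strategy

__all__ = ["UQApproach", "ExternalParamDistributions",
           "fit_external_distributions", "moment_match_beta",
           "moment_match_lognormal", "draw_parameters", "PSASample",
           "run_psa", "net_benefit", "evpi_curve", "default_wtp_grid"]


class UQApproach(Enum):
    """The four characterizations of calibrated-parameter uncertainty."""

    A1_posterior_plus_external = "A1"
    A2_map_plus_external = "A2"
    A3_posterior_only = "A3"
    A4_moments_independent_plus_external = "A4"


# ---------------------------------------------------------------------------
# External-parameter distributions fitted from value + 95% interval
# ---------------------------------------------------------------------------

# sampled utilities may not exceed 1; hazard ratios may not fall below 1
_CLIP_HI = {"util_preclin": 1.0, "util_early": 1.0, "util_late": 1.0}
_CLIP_LO = {"hr_low_risk": 1.0, "hr_high_risk": 1.0}


@dataclass(frozen=True)
class _FittedDist:
    name: str
    family: str            # beta | lognormal | fixed
    mean: float            # the printed point value (anchor)
    params: tuple          # (a, b) or (mu, sigma) or ()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "fixed":
            x = np.full(n, self.mean)
        elif self.family == "beta":
            x = rng.beta(*self.params, size=n)
        else:
            mu, sigma = self.params
            x = np.exp(rng.normal(mu, sigma, size=n))
        if self.name in _CLIP_HI:
            x = np.minimum(x, _CLIP_HI[self.name])
        if self.name in _CLIP_LO:
            x = np.maximum(x, _CLIP_LO[self.name])
        return x

    def percentiles(self) -> tuple:
        if self.family == "fixed":
            return (self.mean, self.mean)
        if self.family == "beta":
            d = stats.beta(*self.params)
        else:
            mu, sigma = self.params
            d = stats.lognorm(s=sigma, scale=np.exp(mu))
        return tuple(d.ppf([0.025, 0.975]))


@dataclass(frozen=True)
class ExternalParamDistributions:
    """Fitted PSA distributions of the external CEA parameters."""

    dists: tuple

    def names(self) -> tuple:
        return tuple(d.name for d in self.dists)

    def means(self) -> dict:
        return {d.name: d.mean for d in self.dists}

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        return pd.DataFrame({d.name: d.sample(n, rng) for d in self.dists})


def _fit_beta(value: float, lo: float, hi: float) -> tuple:
    """Beta hyperparameters: mean anchored at `value`, concentration chosen
    so the 2.5/97.5 percentiles best match (lo, hi) by least squares."""

    def objective(log_kappa: float) -> float:
        kappa = np.exp(log_kappa)
        a, b = value * kappa, (1.0 - value) * kappa
        q = stats.beta(a, b).ppf([0.025, 0.975])
        return float((q[0] - lo) ** 2 + (q[1] - hi) ** 2)

    res = minimize_scalar(objective, bounds=(np.log(2.0), np.log(1e7)),
                          method="bounded")
    kappa = float(np.exp(res.x))
    return (value * kappa, (1.0 - value) * kappa)


def _fit_lognormal(value: float, lo: float, hi: float) -> tuple:
    """Lognormal hyperparameters: arithmetic mean anchored at `value`,
    sigma chosen to best match the 95% interval (relative least squares)."""

    def objective(log_sigma: float) -> float:
        sigma = np.exp(log_sigma)
        mu = np.log(value) - 0.5 * sigma**2
        q = np.exp(mu + np.array([-1.959963984540054, 1.959963984540054]) * sigma)
        return float(((q[0] - lo) / value) ** 2 + ((q[1] - hi) / value) ** 2)

    res = minimize_scalar(objective, bounds=(np.log(1e-6), np.log(3.0)),
                          method="bounded")
    sigma = float(np.exp(res.x))
    return (float(np.log(value) - 0.5 * sigma**2), sigma)


def fit_external_distributions(table: Optional[dict] = None) -> ExternalParamDistributions:
    """Fit beta/lognormal PSA distributions to printed values and 95% ranges.

    ``table`` maps name -> {value, lo, hi, family}; the packaged CEA table
    is used when omitted. A degenerate range (lo == hi) yields a fixed
    parameter; a value outside its range is an error.
    """
    if table is None:
        table = load_cea_config()["external"]
    dists = []
    for name, spec in table.items():
        value, lo, hi = float(spec["value"]), float(spec["lo"]), float(spec["hi"])
        if lo > hi:
            raise ValueError(f"{name}: range lower bound exceeds upper bound")
        if not (lo <= value <= hi):
            raise ValueError(f"{name}: value {value} outside range ({lo}, {hi})")
        if lo == hi:
            dists.append(_FittedDist(name, "fixed", value, ()))
        elif spec["family"] == "beta":
            dists.append(_FittedDist(name, "beta", value, _fit_beta(value, lo, hi)))
        elif spec["family"] == "lognormal":
            dists.append(_FittedDist(name, "lognormal", value,
                                     _fit_lognormal(value, lo, hi)))
        else:
            raise ValueError(f"{name}: unknown family {spec['family']!r}")
    return ExternalParamDistributions(tuple(dists))


# ---------------------------------------------------------------------------
# Moment matching for approach A4
# ---------------------------------------------------------------------------

def moment_match_beta(mean: float, sd: float) -> tuple:
    """Beta(alpha, beta) with the given mean and SD."""
    if not (0.0 < mean < 1.0):
        raise ValueError("mean must lie in (0, 1)")
    var = sd * sd
    if not (0.0 < var < mean * (1.0 - mean)):
        raise ValueError("variance must lie in (0, mean*(1-mean))")
    factor = mean * (1.0 - mean) / var - 1.0
    return (mean * factor, (1.0 - mean) * factor)


def moment_match_lognormal(mean: float, sd: float) -> tuple:
    """Lognormal(mu, sigma) with the given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0")
    sigma2 = float(np.log1p((sd / mean) ** 2))
    return (float(np.log(mean) - 0.5 * sigma2), float(np.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# Parameter draws per approach
# ---------------------------------------------------------------------------

_PROPORTION_PARAMS = ("padeno", "psmall")


def draw_parameters(approach: UQApproach, posterior: PosteriorSample,
                    summary: PosteriorSummary,
                    ext: ExternalParamDistributions, n_psa: int,
                    seed: int) -> tuple:
    """Paired (theta_u, external) PSA draws for one UQ approach.

    Returns ``(theta, ext_draws)`` where ``theta`` is an (n_psa, 9) array in
    canonical parameter order and ``ext_draws`` a DataFrame of external
    parameters.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x95A]))
    names = list(posterior.names)
    if approach in (UQApproach.A1_posterior_plus_external,
                    UQApproach.A3_posterior_only):
        pool = posterior.resampled
        theta = pool[rng.integers(0, pool.shape[0], size=n_psa)]
    elif approach is UQApproach.A2_map_plus_external:
        mp = map_estimate(posterior)
        mp = mp.to_array() if isinstance(mp, CalibratedParams) else np.asarray(mp)
        theta = np.tile(mp, (n_psa, 1))
    elif approach is UQApproach.A4_moments_independent_plus_external:
        cols = []
        for name in names:
            m = float(summary.table.loc[name, "mean"])
            s = float(summary.table.loc[name, "sd"])
            if name in _PROPORTION_PARAMS:
                a, b_ = moment_match_beta(m, s)
                cols.append(rng.beta(a, b_, size=n_psa))
            else:
                mu, sigma = moment_match_lognormal(m, s)
                cols.append(np.exp(rng.normal(mu, sigma, size=n_psa)))
        theta = np.column_stack(cols)
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown approach {approach}")

    if approach is UQApproach.A3_posterior_only:
        ext_draws = pd.DataFrame({k: np.full(n_psa, v)
                                  for k, v in ext.means().items()})
    else:
        ext_draws = ext.sample(n_psa, rng)
    return theta, ext_draws


# ---------------------------------------------------------------------------
# PSA execution
# ---------------------------------------------------------------------------

@dataclass
class PSASample:
    """Per-draw CEA outcomes of both strategies for one UQ approach."""

    approach: UQApproach
    data: pd.DataFrame   # draw, cost_screen, qaly_screen, cost_none, qaly_none, dcost, dqaly
    n_micro: int
    seed: int

    def __len__(self) -> int:
        return len(self.data)


def run_psa(approach: UQApproach, posterior: PosteriorSample,
            summary: PosteriorSummary, ext: ExternalParamDistributions,
            theta_k: FixedParams, lt: LifeTable, n_psa: int, n_micro: int,
            seed: int, cea_base: Optional[CEAParams] = None,
            age_end: int = 100) -> PSASample:
    """Propagate one approach's parameter draws through the screening CEA.

    Each draw simulates an independent cohort of ``n_micro`` for both
    strategies with common random numbers across strategies; the whole PSA
    is deterministic given ``seed``.
    """
    if len(posterior.resample_idx) == 0:
        raise ValueError("posterior sample is empty")
    cea_base = cea_base or default_cea_params()
    theta, ext_draws = draw_parameters(approach, posterior, summary, ext,
                                       n_psa, seed)
    draw_seeds = np.random.SeedSequence([seed, 0xD12A3]).generate_state(
        n_psa, dtype=np.uint32)
    rows = np.empty((n_psa, 4))
    ext_fields = set(ext_draws.columns) & {f.name for f in
                                           CEAParams.__dataclass_fields__.values()}
    for i in range(n_psa):
        theta_u = CalibratedParams.from_array(theta[i])
        cea_i = replace(cea_base,
                        **{k: float(ext_draws.loc[i, k]) for k in ext_fields})
        s_i = int(draw_seeds[i])
        P = precompute_transitions(theta_u, theta_k, lt, 50, age_end,
                                   cea_i.onset_hrs)
        r_scr = simulate_strategy(theta_u, theta_k, lt, cea_i,
                                  "colonoscopy_q10", n_micro, s_i,
                                  age_end=age_end, P_stack=P)
        r_non = simulate_strategy(theta_u, theta_k, lt, cea_i, "no_screening",
                                  n_micro, s_i, age_end=age_end,
                                  P_stack=P[:1])
        rows[i] = (r_scr.mean_cost, r_scr.mean_qaly,
                   r_non.mean_cost, r_non.mean_qaly)
    df = pd.DataFrame(rows, columns=["cost_screen", "qaly_screen",
                                     "cost_none", "qaly_none"])
    df.insert(0, "draw", np.arange(n_psa))
    df["dcost"] = df["cost_screen"] - df["cost_none"]
    df["dqaly"] = df["qaly_screen"] - df["qaly_none"]
    return PSASample(approach=approach, data=df, n_micro=n_micro, seed=seed)


# ---------------------------------------------------------------------------
# Net benefit and EVPI
# ---------------------------------------------------------------------------

def net_benefit(cost, qaly, wtp: float):
    """Net monetary benefit ``wtp * QALY - cost`` (vectorised)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * np.asarray(qaly, dtype=float) - np.asarray(cost, dtype=float)


def default_wtp_grid(wtp_max: float = 150_000.0,
                     step: float = 1000.0) -> np.ndarray:
    return np.arange(0.0, wtp_max + step / 2, step)


def evpi_curve(psa: PSASample, wtp_grid=None) -> pd.DataFrame:
    """Per-patient EVPI across a willingness-to-pay grid.

    ``EVPI(wtp) = E[max_s NB_s] - max_s E[NB_s]`` over the PSA draws.
    Returns a DataFrame with columns ``wtp, evpi``.
    """
    if len(psa) == 0:
        raise ValueError("empty PSA sample")
    wtp_grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    cost = psa.data[["cost_none", "cost_screen"]].to_numpy()   # (n, S)
    qaly = psa.data[["qaly_none", "qaly_screen"]].to_numpy()
    evpi = np.empty(len(wtp_grid))
    for j, wtp in enumerate(wtp_grid):
        nb = net_benefit(cost, qaly, float(wtp))               # (n, S)
        evpi[j] = nb.max(axis=1).mean() - nb.mean(axis=0).max()
    return pd.DataFrame({"wtp": wtp_grid, "evpi": evpi})
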