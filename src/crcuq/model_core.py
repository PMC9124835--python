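"""Deterministic core of the nine-state CRC natural-history model.

The disease process is a continuous-time, age-inhomogeneous Markov chain.
Within each one-year cycle the transition intensities are held constant at
their value for the current integer age ``a``, collected in a 9x9 intensity
matrix ``Q(a)``; the annual transition-probability matrix is its matrix
exponential ``P(a) = expm(Q(a))``, which permits transitions across several
health states within a single year (e.g. small adenoma -> large adenoma ->
preclinical CRC). The deterministic cohort trace propagates state-occupancy
proportions from age 50 and yields the expected model outputs used as the
calibration likelihood mean; the stochastic engine in :mod:`crcuq.microsim`
converges to it as the cohort grows.

Modelling assumptions
---------------------
* Early clinical CRC does not progress to late clinical CRC: stage at
  clinical diagnosis is fixed and treatment is implicit in the
  stage-specific mortality rates.
* Ages are integer years, cycle length is one year, and the trace runs to a
  terminal age of 100 by default (lifetime horizon); no half-cycle
  correction is applied.
* Background mortality ``mu(a)`` is an annual *rate* entering ``Q(a)`` from
  every alive state.
* Incidence denominators are person-years alive without clinical CRC (the
  usual cancer-registry at-risk convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .params import (
    ADENOMA_STATES,
    ALIVE_STATES,
    AT_RISK_STATES,
    N_STATES,
    CalibratedParams,
    FixedParams,
    HealthState,
    InvalidParameterError,
)

__all__ = [
    "LifeTable",
    "AgeBins",
    "CohortTrace",
    "weibull_hazard",
    "build_intensity_matrix",
    "transition_probability_matrix",
    "initial_state_distribution",
    "cohort_trace",
    "model_outputs",
    "validate_intensity_matrix",
    "validate_transition_matrix",
]


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

class LifeTable:
    """Annual all-cause mortality rates mu(a) indexed by integer age."""

    def __init__(self, ages: Sequence[int], rates: Sequence[float]):
        ages = np.asarray(ages, dtype=int)
        rates = np.asarray(rates, dtype=float)
        if ages.ndim != 1 or ages.shape != rates.shape:
            raise ValueError("ages and rates must be 1-D and the same length")
        order = np.argsort(ages)
        ages, rates = ages[order], rates[order]
        if np.any(np.diff(ages) != 1):
            raise ValueError("life table ages must be consecutive integers")
        if np.any(rates < 0):
            raise ValueError("mortality rates must be non-negative")
        self.ages = ages
        self.rates = rates
        self._age0 = int(ages[0])

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def mu(self, age):
        """Mortality rate at integer age(s); raises on ages outside the table."""
        idx = np.asarray(age, dtype=int) - self._age0
        if np.any(idx < 0) or np.any(idx >= len(self.rates)):
            raise ValueError(f"age {age} outside life table range "
                             f"[{self.age_min}, {self.age_max}]")
        return self.rates[idx]

    def life_expectancy(self, age: int) -> float:
        """Remaining life expectancy at ``age`` under piecewise-constant hazards.

        Person-years lived during a year with rate ``m`` by someone alive at
        its start are ``(1 - exp(-m)) / m``; survivors past the table's last
        age contribute an exponential tail at the terminal rate.
        """
        sel = self.ages >= age
        m = self.rates[sel]
        surv_start = np.concatenate([[1.0], np.exp(-np.cumsum(m[:-1]))])
        with np.errstate(invalid="ignore", divide="ignore"):
            py = np.where(m > 0, (1.0 - np.exp(-m)) / np.where(m > 0, m, 1.0), 1.0)
        e = float(np.sum(surv_start * py))
        tail_surv = float(np.exp(-np.cumsum(m)[-1]))
        if m[-1] > 0:
            e += tail_surv / m[-1]
        return e

    # -- CSV round trip (header: age,mortality_rate) -----------------------
    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "mortality_rate": self.rates}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "mortality_rate"} <= set(df.columns):
            raise ValueError("life table CSV needs columns age,mortality_rate")
        return cls(df["age"].to_numpy(), df["mortality_rate"].to_numpy())


# ---------------------------------------------------------------------------
# Hazards and matrices
# ---------------------------------------------------------------------------

def weibull_hazard(a, l: float, gamma: float):
    """Weibull adenoma-onset hazard ``lambda1(a) = l * gamma * a**(gamma-1)``.

    Parameters are the scale ``l`` and shape ``gamma``; ``a`` is age in
    years. With ``gamma > 1`` the onset rate increases with age.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise InvalidParameterError("age must be non-negative")
    if l <= 0 or gamma <= 0:
        raise InvalidParameterError("Weibull scale and shape must be > 0")
    with np.errstate(divide="ignore"):
        out = l * gamma * np.power(a, gamma - 1.0)
    return out if out.ndim else float(out)


def validate_intensity_matrix(Q: np.ndarray, atol: float = 1e-12) -> None:
    Q = np.asarray(Q)
    if Q.shape != (N_STATES, N_STATES):
        raise ValueError(f"intensity matrix must be {N_STATES}x{N_STATES}")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("off-diagonal intensities must be >= 0")
    scale = max(1.0, float(np.abs(Q).max()))
    if np.any(np.abs(Q.sum(axis=1)) > atol * scale):
        raise ValueError("intensity matrix rows must sum to 0")
    for s in (HealthState.CRC_DEATH, HealthState.OTHER_DEATH):
        if np.any(Q[s] != 0.0):
            raise ValueError("absorbing-state rows must be all zero")


def validate_transition_matrix(P: np.ndarray, atol: float = 1e-10) -> None:
    P = np.asarray(P)
    if P.shape != (N_STATES, N_STATES):
        raise ValueError(f"transition matrix must be {N_STATES}x{N_STATES}")
    if np.any(P < -atol) or np.any(P > 1 + atol):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > atol):
        raise ValueError("transition matrix rows must sum to 1")


def build_intensity_matrix(theta_u: CalibratedParams, theta_k: FixedParams,
                           mu_a: float, a: float,
                           onset_hr: float = 1.0) -> np.ndarray:
    """Age-specific 9x9 transition intensity matrix Q(a).

    ``onset_hr`` multiplies the adenoma-onset hazard lambda1(a); it is 1 in
    the natural-history model and >1 after polypectomy (elevated recurrence).
    """
    if mu_a < 0:
        raise InvalidParameterError("mu(a) must be >= 0")
    if onset_hr <= 0:
        raise InvalidParameterError("onset hazard ratio must be > 0")
    S = HealthState
    Q = np.zeros((N_STATES, N_STATES))
    Q[S.NORMAL, S.SMALL_ADENOMA] = onset_hr * weibull_hazard(a, theta_u.l, theta_u.gamma)
    Q[S.SMALL_ADENOMA, S.LARGE_ADENOMA] = theta_u.lambda2
    Q[S.LARGE_ADENOMA, S.PRECLIN_EARLY] = theta_u.lambda3
    Q[S.PRECLIN_EARLY, S.PRECLIN_LATE] = theta_u.lambda4
    Q[S.PRECLIN_EARLY, S.CLIN_EARLY] = theta_u.lambda5
    Q[S.PRECLIN_LATE, S.CLIN_LATE] = theta_u.lambda6
    Q[S.CLIN_EARLY, S.CRC_DEATH] = theta_k.lambda7
    Q[S.CLIN_LATE, S.CRC_DEATH] = theta_k.lambda8
    for s in ALIVE_STATES:
        Q[s, S.OTHER_DEATH] = mu_a
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def transition_probability_matrix(Q: np.ndarray, t: float = 1.0) -> np.ndarray:
    """Annual transition-probability matrix ``P(a, t) = expm(t * Q(a))``."""
    validate_intensity_matrix(Q)
    P = expm(t * np.asarray(Q, dtype=float))
    # clip tiny negative round-off and renormalise rows
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def initial_state_distribution(theta_u: CalibratedParams,
                               theta_k: FixedParams) -> np.ndarray:
    """State distribution of the 50-year-old cohort.

    Prevalent adenomas split into small/large by ``psmall``; preclinical CRC
    prevalences come from the fixed parameters; the remainder is normal.
    """
    S = HealthState
    pi = np.zeros(N_STATES)
    pi[S.SMALL_ADENOMA] = theta_u.padeno * theta_u.psmall
    pi[S.LARGE_ADENOMA] = theta_u.padeno * (1.0 - theta_u.psmall)
    pi[S.PRECLIN_EARLY] = theta_k.p_preclin_early_50
    pi[S.PRECLIN_LATE] = theta_k.p_preclin_late_50
    remainder = 1.0 - pi.sum()
    if remainder < 0:
        raise InvalidParameterError(
            "padeno plus preclinical prevalences exceed 1")
    pi[S.NORMAL] = remainder
    return pi


# ---------------------------------------------------------------------------
# Cohort trace and outputs
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Deterministic state-occupancy trace of the model.

    ``occupancy[k]`` is the state distribution at the start of age
    ``ages[k]``; ``inc_early[k]``/``inc_late[k]`` are the proportions of the
    original cohort newly entering the clinical early/late states during the
    cycle ``ages[k] -> ages[k]+1``, and ``py_at_risk[k]`` the proportion
    alive without clinical CRC at the start of that cycle.
    """

    ages: np.ndarray          # (A,) start-of-cycle ages, last entry terminal
    occupancy: np.ndarray     # (A, 9)
    inc_early: np.ndarray     # (A-1,)
    inc_late: np.ndarray      # (A-1,)
    py_at_risk: np.ndarray    # (A-1,)

    def occupancy_at(self, age: int) -> np.ndarray:
        k = int(age) - int(self.ages[0])
        if not (0 <= k < len(self.ages)):
            raise ValueError(f"age {age} outside trace range")
        return self.occupancy[k]


def annual_transition_matrices(theta_u: CalibratedParams, theta_k: FixedParams,
                               lt: LifeTable, age_start: int, age_end: int,
                               onset_hr: float = 1.0) -> np.ndarray:
    """Stack of P(a) for a in [age_start, age_end), shape (A-1, 9, 9)."""
    if age_end <= age_start:
        raise ValueError("age_end must exceed age_start")
    if lt.age_min > age_start or lt.age_max < age_end - 1:
        raise ValueError("life table does not cover the simulated age range")
    out = np.empty((age_end - age_start, N_STATES, N_STATES))
    for k, a in enumerate(range(age_start, age_end)):
        Q = build_intensity_matrix(theta_u, theta_k, float(lt.mu(a)), a, onset_hr)
        out[k] = transition_probability_matrix(Q)
    return out


def cohort_trace(theta_u: CalibratedParams, theta_k: FixedParams,
                 lt: LifeTable, age_start: int = 50,
                 age_end: int = 100) -> CohortTrace:
    """Propagate the expected cohort from ``age_start`` to ``age_end``.

    This is the deterministic expectation of the microsimulation: occupancy
    at age a+1 equals occupancy at age a times P(a). Incidence flows are the
    occupancy-weighted one-year probabilities of ending a cycle in a
    clinical state having started it at risk.
    """
    P = annual_transition_matrices(theta_u, theta_k, lt, age_start, age_end)
    A = age_end - age_start + 1
    occ = np.empty((A, N_STATES))
    occ[0] = initial_state_distribution(theta_u, theta_k)
    inc_early = np.empty(A - 1)
    inc_late = np.empty(A - 1)
    py = np.empty(A - 1)
    risk = list(AT_RISK_STATES)
    for k in range(A - 1):
        at_risk_occ = occ[k, risk]
        inc_early[k] = at_risk_occ @ P[k][risk, HealthState.CLIN_EARLY]
        inc_late[k] = at_risk_occ @ P[k][risk, HealthState.CLIN_LATE]
        py[k] = at_risk_occ.sum()
        occ[k + 1] = occ[k] @ P[k]
    ages = np.arange(age_start, age_end + 1)
    return CohortTrace(ages, occ, inc_early, inc_late, py)


# ---------------------------------------------------------------------------
# Age bins and model outputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeBins:
    """Age scheme of the four output/target types.

    Adenoma prevalence and the small-adenoma proportion are cross-sectional
    at single ages; stage-specific clinical incidence is aggregated over
    inclusive multi-year age bins.
    """

    prevalence_ages: tuple = (55, 60, 65, 70)
    incidence_bins: tuple = ((52, 56), (57, 61), (62, 66), (67, 71),
                             (72, 76), (77, 81), (82, 86))

    @property
    def max_age(self) -> int:
        return max(max(self.prevalence_ages),
                   max(hi for _, hi in self.incidence_bins))


DEFAULT_BINS = AgeBins()

TARGET_TYPES = ("adenoma_prev", "prop_small", "inc_early", "inc_late")
PER_POP = 100_000.0  # incidence reporting scale: cases per 100,000 person-years


def _output_index(bins: AgeBins) -> pd.DataFrame:
    rows = []
    for a in bins.prevalence_ages:
        rows.append(("adenoma_prev", a, a))
    for a in bins.prevalence_ages:
        rows.append(("prop_small", a, a))
    for lo, hi in bins.incidence_bins:
        rows.append(("inc_early", lo, hi))
    for lo, hi in bins.incidence_bins:
        rows.append(("inc_late", lo, hi))
    return pd.DataFrame(rows, columns=["target_type", "age_lo", "age_hi"])


def model_outputs(trace: CohortTrace, bins: AgeBins = DEFAULT_BINS) -> pd.DataFrame:
    """Expected model outputs phi aligned to an age-bin scheme.

    Returns a DataFrame with columns ``target_type, age_lo, age_hi, value,
    defined``. Prevalence is (small+large)/alive; the small proportion is
    small/(small+large); incidence is per 100,000 person-years at risk.
    A bin whose denominator is zero is flagged ``defined=False`` with NaN
    value rather than silently reported as zero.
    """
    if bins.max_age + 1 > int(trace.ages[-1]):
        raise ValueError("age bins extend beyond the cohort trace")
    S = HealthState
    df = _output_index(bins)
    values = np.full(len(df), np.nan)
    defined = np.zeros(len(df), dtype=bool)
    i = 0
    for a in bins.prevalence_ages:
        occ = trace.occupancy_at(a)
        alive = occ[list(ALIVE_STATES)].sum()
        if alive > 0:
            values[i] = occ[list(ADENOMA_STATES)].sum() / alive
            defined[i] = True
        i += 1
    for a in bins.prevalence_ages:
        occ = trace.occupancy_at(a)
        both = occ[S.SMALL_ADENOMA] + occ[S.LARGE_ADENOMA]
        if both > 0:
            values[i] = occ[S.SMALL_ADENOMA] / both
            defined[i] = True
        i += 1
    age0 = int(trace.ages[0])
    for which in (trace.inc_early, trace.inc_late):
        for lo, hi in bins.incidence_bins:
            ks = np.arange(lo - age0, hi - age0 + 1)
            py = trace.py_at_risk[ks].sum()
            if py > 0:
                values[i] = PER_POP * which[ks].sum() / py
                defined[i] = True
            i += 1
    df["value"] = values
    df["defined"] = defined
    return df
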