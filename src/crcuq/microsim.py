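"""Individual-level stochastic engine for the natural-history model.

Each simulated person starts at age 50 in a state drawn from the initial
distribution and makes one categorical draw per year from the row of the
annual transition matrix P(a) for their current state. Because P(a) is a
matrix exponential, a single draw can move a person across several health
states (e.g. small adenoma to preclinical CRC); intermediate states within a
year are not observed, so incidence is recorded only when a year *ends* in a
clinical state having started at risk.

Reproducibility: all randomness flows from a single integer seed through
``numpy.random.SeedSequence`` children (one stream for the initial states
and transitions, one reserved for intervention hooks), so a given seed
yields identical paths regardless of how the surrounding code schedules
work, and the no-screening and screening arms of a cost-effectiveness pair
share their transition uniforms (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .model_core import AgeBins, DEFAULT_BINS, LifeTable, PER_POP, \
    annual_transition_matrices, initial_state_distribution, _output_index
from .params import (
    ADENOMA_STATES,
    CalibratedParams,
    FixedParams,
    HealthState,
)

__all__ = ["SimPaths", "simulate_individuals", "aggregate_outputs"]

#: risk classes for the post-polypectomy onset elevation
RISK_NONE, RISK_LOW, RISK_HIGH = 0, 1, 2


@dataclass
class SimPaths:
    """Simulated annual state paths for a cohort.

    ``states[i, k]`` is person ``i``'s state at the start of age
    ``ages[k]`` (after any intervention-hook relocation that year); the last
    column is the terminal state. ``risk_class`` is the person's final
    post-polypectomy risk class and ``next_due`` the next scheduled
    colonoscopy age (screening runs only).
    """

    ages: np.ndarray        # (A,)
    states: np.ndarray      # (n, A) int8
    risk_class: np.ndarray  # (n,) int8
    next_due: np.ndarray    # (n,) int16
    seed: int

    @property
    def n(self) -> int:
        return self.states.shape[0]

    def new_clinical(self, stage_state: HealthState) -> np.ndarray:
        """Boolean (n, A-1): year started at risk and ended in ``stage_state``."""
        at_risk = self.states[:, :-1] < HealthState.CLIN_EARLY
        return at_risk & (self.states[:, 1:] == int(stage_state))

    def to_frame(self) -> pd.DataFrame:
        """Long-format (person, age, state) export for debugging."""
        n, A = self.states.shape
        return pd.DataFrame({
            "person": np.repeat(np.arange(n), A),
            "age": np.tile(self.ages, n),
            "state": self.states.ravel(),
        })


def simulate_individuals(theta_u: CalibratedParams, theta_k: FixedParams,
                         lt: LifeTable, n: int, seed: int,
                         hook: Optional[Callable] = None,
                         age_start: int = 50, age_end: int = 100,
                         onset_hrs: tuple = (1.0,),
                         P_stack: Optional[np.ndarray] = None) -> SimPaths:
    """Simulate annual state paths for ``n`` individuals.

    Parameters
    ----------
    hook : callable, optional
        Called once per cycle *before* the transition draw as
        ``hook(age, states, risk_class, next_due, year_index)`` and may
        relocate individuals in place (polypectomy, screen detection) and
        record resource use. Dead individuals must be left untouched.
    onset_hrs : tuple of float
        Onset hazard ratio per risk class; index by ``risk_class``. The
        natural-history run uses the single class ``(1.0,)``.
    P_stack : ndarray (len(onset_hrs), A-1, 9, 9), optional
        Precomputed annual transition matrices (see
        :func:`precompute_transitions`); avoids recomputing the matrix
        exponentials when many replications share one parameter set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ages = np.arange(age_start, age_end + 1)
    T = len(ages) - 1
    if P_stack is None:
        P_stack = precompute_transitions(theta_u, theta_k, lt, age_start,
                                         age_end, onset_hrs)
    cumP = np.cumsum(P_stack, axis=3)  # (C, T, 9, 9)

    ss = np.random.SeedSequence(seed)
    child_paths, _child_hook = ss.spawn(2)
    rng = np.random.default_rng(child_paths)
    u_init = rng.random(n)
    u_trans = rng.random((n, T))

    pi0 = initial_state_distribution(theta_u, theta_k)
    cum0 = np.cumsum(pi0)
    states = np.empty((n, T + 1), dtype=np.int8)
    cur = np.searchsorted(cum0, u_init, side="left").astype(np.int8)
    risk = np.zeros(n, dtype=np.int8)
    next_due = np.full(n, -1, dtype=np.int16)

    for k in range(T):
        if hook is not None:
            hook(int(ages[k]), cur, risk, next_due, k)
        states[:, k] = cur
        rows = cumP[risk, k, cur]                       # (n, 9)
        cur = (rows >= u_trans[:, k, None]).argmax(axis=1).astype(np.int8)
    states[:, T] = cur
    return SimPaths(ages, states, risk, next_due, seed)


def precompute_transitions(theta_u: CalibratedParams, theta_k: FixedParams,
                           lt: LifeTable, age_start: int, age_end: int,
                           onset_hrs: tuple = (1.0,)) -> np.ndarray:
    """Annual transition matrices per risk class: (C, A-1, 9, 9)."""
    return np.stack([
        annual_transition_matrices(theta_u, theta_k, lt, age_start, age_end,
                                   onset_hr=hr)
        for hr in onset_hrs
    ])


def aggregate_outputs(paths: SimPaths, bins: AgeBins = DEFAULT_BINS) -> pd.DataFrame:
    """Cohort outputs from simulated paths, same conventions as
    :func:`crcuq.model_core.model_outputs`.

    Returns a DataFrame ``target_type, age_lo, age_hi, value, defined, n``.
    Bins with an empty at-risk denominator are flagged undefined.
    """
    if paths.n == 0:
        raise ValueError("empty path collection")
    if bins.max_age + 1 > int(paths.ages[-1]):
        raise ValueError("age bins extend beyond the simulated age range")
    S = HealthState
    states = paths.states
    age0 = int(paths.ages[0])
    df = _output_index(bins)
    values = np.full(len(df), np.nan)
    defined = np.zeros(len(df), dtype=bool)
    i = 0
    for a in bins.prevalence_ages:
        col = states[:, a - age0]
        alive = int(np.count_nonzero(col < S.CRC_DEATH))
        if alive > 0:
            adeno = int(np.count_nonzero(np.isin(col, ADENOMA_STATES)))
            values[i] = adeno / alive
            defined[i] = True
        i += 1
    for a in bins.prevalence_ages:
        col = states[:, a - age0]
        small = int(np.count_nonzero(col == S.SMALL_ADENOMA))
        large = int(np.count_nonzero(col == S.LARGE_ADENOMA))
        if small + large > 0:
            values[i] = small / (small + large)
            defined[i] = True
        i += 1
    at_risk = states[:, :-1] < S.CLIN_EARLY
    new_early = paths.new_clinical(S.CLIN_EARLY)
    new_late = paths.new_clinical(S.CLIN_LATE)
    for events in (new_early, new_late):
        for lo, hi in bins.incidence_bins:
            ks = slice(lo - age0, hi - age0 + 1)
            py = int(np.count_nonzero(at_risk[:, ks]))
            if py > 0:
                values[i] = PER_POP * int(np.count_nonzero(events[:, ks])) / py
                defined[i] = True
            i += 1
    df["value"] = values
    df["defined"] = defined
    df["n"] = paths.n
    return df
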