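"""Colonoscopy screening overlay and cost-effectiveness accrual.

The strategy evaluated is 10-yearly colonoscopy from age 50 to 85 versus no
screening. At a due exam, a detected adenoma is removed (polypectomy, back
to normal) and the person enters surveillance — every 5 years after a small
adenoma (low-risk class, onset hazard ratio 2) or every 3 years after a
large one (high-risk class, hazard ratio 3); risk classes only escalate.
After a negative exam the person reverts to the routine 10-year clock.
Detected preclinical CRC becomes clinical CRC of the same stage
(screen-detected treatment). False-positive findings in normal tissue carry
no cost beyond the already-counted colonoscopy.

Within a cycle the order of events is: screening/surveillance test -> state
relocation -> annual transition draw -> accrual. Each performed colonoscopy
adds its cost at the exam age; clinical states accrue annual stage-specific
cost and utility; anyone alive without clinical CRC accrues utility 1
(``util_preclin`` for preclinical CRC). All flows are discounted to age 50.
A person who dies during a cycle accrues neither that cycle's utility nor
its annual CRC cost (no half-cycle correction). Both strategies of a
comparison share transition random numbers when given the same seed
(common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import load_cea_config
from .microsim import RISK_HIGH, RISK_LOW, SimPaths, precompute_transitions, \
    simulate_individuals
from .model_core import LifeTable
from .params import CalibratedParams, FixedParams, HealthState, N_STATES

__all__ = ["CEAParams", "default_cea_params", "StrategyResult",
           "IncrementalResult", "simulate_strategy", "incremental_outcomes",
           "STRATEGIES"]

STRATEGIES = ("no_screening", "colonoscopy_q10")


@dataclass(frozen=True)
class CEAParams:
    """External (non-calibrated) parameters of the screening CEA."""

    sens_small: float = 0.773        # colonoscopy sensitivity, small adenoma
    sens_large_crc: float = 0.950    # sensitivity, large adenoma and CRC
    spec: float = 0.868              # specificity (normal tissue)
    hr_low_risk: float = 2.0         # onset HR after small-adenoma polypectomy
    hr_high_risk: float = 3.0        # onset HR after large-adenoma polypectomy
    cost_colonoscopy: float = 10_000.0
    cost_early_annual: float = 21_524.0
    cost_late_annual: float = 37_000.0
    util_preclin: float = 1.000
    util_early: float = 0.855
    util_late: float = 0.300
    discount_rate: float = 0.03
    screen_start: int = 50
    screen_stop: int = 85
    screen_interval: int = 10
    surveil_small: int = 5
    surveil_large: int = 3

    def __post_init__(self) -> None:
        for name in ("sens_small", "sens_large_crc", "spec",
                     "util_preclin", "util_early", "util_late"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.hr_low_risk < 1.0 or self.hr_high_risk < 1.0:
            raise ValueError("post-polypectomy hazard ratios must be >= 1")
        for name in ("cost_colonoscopy", "cost_early_annual", "cost_late_annual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def onset_hrs(self) -> tuple:
        """Onset hazard ratio per risk class (none, low, high)."""
        return (1.0, self.hr_low_risk, self.hr_high_risk)


def default_cea_params(**overrides) -> CEAParams:
    """CEA parameters at their point values from the packaged table."""
    cfg = load_cea_config()
    kwargs = {name: float(spec["value"]) for name, spec in cfg["external"].items()}
    kwargs.update({k: int(v) for k, v in cfg["schedule"].items()})
    kwargs["discount_rate"] = float(cfg["discount_rate"])
    kwargs.update(overrides)
    return CEAParams(**kwargs)


@dataclass
class StrategyResult:
    """Per-person discounted lifetime costs and QALYs for one strategy."""

    strategy: str
    cost: np.ndarray   # (n,)
    qaly: np.ndarray   # (n,)
    n: int
    seed: int
    n_colonoscopies: float = 0.0  # mean per person
    paths: SimPaths | None = None

    @property
    def mean_cost(self) -> float:
        return float(self.cost.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qaly.mean())


@dataclass(frozen=True)
class IncrementalResult:
    """Screening-minus-no-screening increments of mean cost and QALYs."""

    delta_cost: float
    delta_qaly: float


class _ScreeningHook:
    """Vectorised per-cycle screening/surveillance intervention.

    Mutates states, risk classes and next-due ages in place and records the
    colonoscopies performed. Uses its own random stream so the transition
    uniforms stay common across strategies.
    """

    def __init__(self, cea: CEAParams, n: int, n_years: int, seed: int):
        self.cea = cea
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5C12EE]))
        self._u_test = rng.random((n, n_years))
        self.colos = np.zeros((n, n_years), dtype=bool)

    def __call__(self, age: int, states: np.ndarray, risk: np.ndarray,
                 next_due: np.ndarray, k: int) -> None:
        cea = self.cea
        S = HealthState
        if age > cea.screen_stop:
            return
        if age == cea.screen_start:
            next_due[next_due < 0] = cea.screen_start
        due = (next_due == age) & (states < S.CLIN_EARLY)
        if not due.any():
            return
        self.colos[due, k] = True
        u = self._u_test[:, k]
        next_due[due] = age + cea.screen_interval  # default: negative exam

        hit_small = due & (states == S.SMALL_ADENOMA) & (u < cea.sens_small)
        states[hit_small] = S.NORMAL
        np.maximum(risk, RISK_LOW, out=risk, where=hit_small)
        next_due[hit_small] = age + cea.surveil_small

        hit_large = due & (states == S.LARGE_ADENOMA) & (u < cea.sens_large_crc)
        states[hit_large] = S.NORMAL
        np.maximum(risk, RISK_HIGH, out=risk, where=hit_large)
        next_due[hit_large] = age + cea.surveil_large

        hit_pe = due & (states == S.PRECLIN_EARLY) & (u < cea.sens_large_crc)
        states[hit_pe] = S.CLIN_EARLY
        hit_pl = due & (states == S.PRECLIN_LATE) & (u < cea.sens_large_crc)
        states[hit_pl] = S.CLIN_LATE


def _accrue(paths: SimPaths, cea: CEAParams,
            colos: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Discounted per-person cost and QALY totals from simulated paths."""
    S = HealthState
    T = paths.states.shape[1] - 1
    post = paths.states[:, :T]              # state after the exam, before draw
    alive_end = paths.states[:, 1:] < S.CRC_DEATH
    years = paths.ages[:T] - paths.ages[0]
    disc = (1.0 + cea.discount_rate) ** (-years.astype(float))

    util = np.ones(N_STATES)
    util[[S.PRECLIN_EARLY, S.PRECLIN_LATE]] = cea.util_preclin
    util[S.CLIN_EARLY] = cea.util_early
    util[S.CLIN_LATE] = cea.util_late
    util[[S.CRC_DEATH, S.OTHER_DEATH]] = 0.0
    annual_cost = np.zeros(N_STATES)
    annual_cost[S.CLIN_EARLY] = cea.cost_early_annual
    annual_cost[S.CLIN_LATE] = cea.cost_late_annual

    qaly = ((util[post] * alive_end) * disc).sum(axis=1)
    cost = ((annual_cost[post] * alive_end) * disc).sum(axis=1)
    if colos is not None:
        cost = cost + (colos * disc).sum(axis=1) * cea.cost_colonoscopy
    return cost, qaly


def simulate_strategy(theta_u: CalibratedParams, theta_k: FixedParams,
                      lt: LifeTable, cea: CEAParams, strategy: str,
                      n: int, seed: int, age_end: int = 100,
                      P_stack: np.ndarray | None = None,
                      keep_paths: bool = False) -> StrategyResult:
    """Simulate one strategy arm and accrue discounted costs and QALYs.

    Running both strategies with the same ``seed`` shares the initial-state
    and transition random numbers (common random numbers), so incremental
    outcomes isolate the effect of screening.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    age_start = 50
    n_years = age_end - age_start
    hook = None
    colos = None
    onset_hrs = (1.0,)
    if strategy == "colonoscopy_q10":
        onset_hrs = cea.onset_hrs
        hook = _ScreeningHook(cea, n, n_years, seed)
    if P_stack is None:
        P_stack = precompute_transitions(theta_u, theta_k, lt, age_start,
                                         age_end, onset_hrs)
    paths = simulate_individuals(theta_u, theta_k, lt, n, seed, hook=hook,
                                 age_start=age_start, age_end=age_end,
                                 onset_hrs=onset_hrs, P_stack=P_stack)
    if hook is not None:
        colos = hook.colos
    cost, qaly = _accrue(paths, cea, colos)
    return StrategyResult(
        strategy=strategy, cost=cost, qaly=qaly, n=n, seed=seed,
        n_colonoscopies=float(colos.sum(axis=1).mean()) if colos is not None else 0.0,
        paths=paths if keep_paths else None)


def incremental_outcomes(r_screen: StrategyResult,
                         r_none: StrategyResult) -> IncrementalResult:
    """Incremental mean cost and QALYs of screening vs no screening."""
    if r_screen.n != r_none.n:
        raise ValueError("strategy results come from different cohort sizes")
    return IncrementalResult(
        delta_cost=r_screen.mean_cost - r_none.mean_cost,
        delta_qaly=r_screen.mean_qaly - r_none.mean_qaly)
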